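"""Data model and I/O for sessions of simultaneously recorded spike trains.

A :class:`Session` bundles the units (with area labels), the per-trial task
structure of a memory-guided saccade experiment (event times, target location,
in/out receptive-field condition), and the spike times of every unit on every
trial.  It is the exchange object between data generators (task-emulating GLM
simulations, the ring attractor network) and the encoding-model pipeline.

Trials have unequal durations; everything downstream keeps the ragged
structure explicit (per-trial bin counts) rather than padding, so no phantom
time bins ever enter a likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "EventTimes",
    "TrialInfo",
    "Unit",
    "Session",
    "BinnedSession",
    "bin_spikes",
    "compute_psth",
    "read_session",
    "write_session",
    "generate_task_trials",
    "generate_compact_trials",
]

AREAS = ("LIP", "FEF", "SYNTH")
CONDITIONS = ("IN_RF", "OUT_RF")


class SessionFormatError(ValueError):
    """Raised when a serialized session container is malformed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EventTimes:
    """Task event times in seconds from trial start.

    The ordering ``fixation_on < target_on < target_off < go_signal <=
    saccade_onset`` is enforced.  In the task the target is flashed for
    ~200 ms and the memory delay (``go_signal - target_off``) is drawn
    from 0.5-2 s, but those ranges are properties of the task generators,
    not of the container.
    """

    fixation_on: float
    target_on: float
    target_off: float
    go_signal: float
    saccade_onset: float

    def validate(self) -> None:
        if not (self.fixation_on < self.target_on < self.target_off
                < self.go_signal <= self.saccade_onset):
            raise ValueError(
                "event times must satisfy fixation_on < target_on < "
                f"target_off < go_signal <= saccade_onset, got {self}")

    def get(self, name: str) -> float:
        if not hasattr(self, name):
            raise KeyError(f"unknown event {name!r}")
        return float(getattr(self, name))


@dataclass
class TrialInfo:
    events: EventTimes
    target_xy: np.ndarray  # degrees of visual angle, shape (2,)
    condition: str  # "IN_RF" | "OUT_RF"
    duration: float  # seconds
    valid: bool = True

    def __post_init__(self):
        self.target_xy = np.asarray(self.target_xy, dtype=float)

    def validate(self) -> None:
        self.events.validate()
        if self.duration < self.events.saccade_onset:
            raise ValueError("trial duration must cover the saccade onset")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        ecc = float(np.hypot(*self.target_xy))
        if not np.isfinite(ecc) or ecc <= 0:
            raise ValueError("target eccentricity must be finite and positive")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(*self.target_xy))

    @property
    def angle_deg(self) -> float:
        """Target direction in degrees, in [0, 360)."""
        return float(np.degrees(np.arctan2(self.target_xy[1],
                                           self.target_xy[0])) % 360.0)


@dataclass
class Unit:
    unit_id: str
    area: str = "SYNTH"
    channel: int = 0

    def validate(self) -> None:
        if self.area not in AREAS:
            raise ValueError(f"area must be one of {AREAS}, got {self.area!r}")


@dataclass
class Session:
    """Simultaneously recorded ensemble with trial structure.

    ``spikes[u][t]`` is a strictly sorted float array of spike times (s,
    relative to trial start) for unit ``u`` on trial ``t``.
    """

    units: list[Unit]
    trials: list[TrialInfo]
    spikes: list[list[np.ndarray]]  # [unit][trial] -> sorted times
    metadata: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def validate(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValueError("unit_id values must be unique within a session")
        for u in self.units:
            u.validate()
        for tr in self.trials:
            tr.validate()
        if len(self.spikes) != self.n_units:
            raise ValueError("spikes must have one entry per unit")
        for ui, per_trial in enumerate(self.spikes):
            if len(per_trial) != self.n_trials:
                raise ValueError(
                    f"unit {self.units[ui].unit_id}: expected "
                    f"{self.n_trials} spike lists, got {len(per_trial)}")
            for ti, st in enumerate(per_trial):
                st = np.asarray(st)
                if st.size and (np.any(np.diff(st) <= 0)):
                    raise ValueError(
                        f"unit {self.units[ui].unit_id} trial {ti}: spike "
                        "times must be strictly sorted")
                dur = self.trials[ti].duration
                if st.size and (st[0] < 0 or st[-1] >= dur):
                    raise ValueError(
                        f"unit {self.units[ui].unit_id} trial {ti}: spike "
                        f"times must lie in [0, {dur})")

    def valid_trial_indices(self) -> np.ndarray:
        return np.array([i for i, tr in enumerate(self.trials) if tr.valid],
                        dtype=int)

    def total_spikes(self) -> int:
        return int(sum(len(st) for per in self.spikes for st in per))

    def subset_units(self, idx) -> "Session":
        idx = np.asarray(idx, dtype=int)
        return Session(
            units=[self.units[i] for i in idx],
            trials=self.trials,
            spikes=[self.spikes[i] for i in idx],
            metadata=dict(self.metadata),
        )

    def subset_trials(self, idx) -> "Session":
        idx = np.asarray(idx, dtype=int)
        return Session(
            units=self.units,
            trials=[self.trials[i] for i in idx],
            spikes=[[per[i] for i in idx] for per in self.spikes],
            metadata=dict(self.metadata),
        )


@dataclass
class BinnedSession:
    """Spike counts on a 1 ms (default) grid, ragged across trials.

    ``counts[t]`` is an int array of shape (n_units, n_bins_t) with
    ``n_bins_t = ceil(duration_t / bin_width)``; bins are half-open
    ``[k*dt, (k+1)*dt)``.
    """

    counts: list[np.ndarray]  # per trial: (n_units, n_bins)
    bin_width: float
    session: Session

    @property
    def n_units(self) -> int:
        return self.session.n_units

    @property
    def n_trials(self) -> int:
        return len(self.counts)

    @property
    def n_bins(self) -> np.ndarray:
        return np.array([c.shape[1] for c in self.counts], dtype=int)

    def total_count(self) -> int:
        return int(sum(c.sum() for c in self.counts))


# ---------------------------------------------------------------------------
# Binning and PSTHs
# ---------------------------------------------------------------------------

def bin_spikes(session: Session, bin_width: float = 0.001) -> BinnedSession:
    """Discretize spike trains into half-open bins of width ``bin_width`` s.

    Total spike count is conserved exactly for any bin width.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    counts = []
    for ti, tr in enumerate(session.trials):
        nb = int(np.ceil(tr.duration / bin_width))
        mat = np.zeros((session.n_units, nb), dtype=np.int64)
        for ui in range(session.n_units):
            st = np.asarray(session.spikes[ui][ti], dtype=float)
            if st.size == 0:
                continue
            if st.min() < 0 or st.max() >= tr.duration:
                raise ValueError(
                    f"unit {session.units[ui].unit_id} trial {ti}: spike time "
                    f"outside [0, {tr.duration})")
            idx = np.floor(st / bin_width).astype(int)
            np.add.at(mat[ui], idx, 1)
        counts.append(mat)
    return BinnedSession(counts=counts, bin_width=bin_width, session=session)


def compute_psth(binned: BinnedSession, align_event: str,
                 window: tuple[float, float], smoothing_sd: float = 0.030,
                 group_by_condition: bool = True):
    """Trial-averaged firing rate aligned to a task event, in spikes/s.

    Counts are aligned to ``align_event``, averaged across trials (each
    aligned bin is divided by the number of trials covering it), converted
    to spikes/s, then smoothed with a Gaussian filter (SD ``smoothing_sd``
    seconds; reflection padding at the window edges so edge rates are not
    suppressed).  ``smoothing_sd=0`` returns the raw trial-averaged rate.

    Returns a dict ``unit_id -> condition -> dict(time=..., rate=...)``
    (condition key ``"all"`` when ``group_by_condition`` is false).
    A condition with no trials maps to ``None``.
    """
    if smoothing_sd < 0:
        raise ValueError("smoothing_sd must be >= 0")
    dt = binned.bin_width
    t0, t1 = window
    nb = int(round((t1 - t0) / dt))
    time = t0 + (np.arange(nb) + 0.5) * dt
    sess = binned.session
    groups = CONDITIONS if group_by_condition else ("all",)
    out = {}
    valid = set(sess.valid_trial_indices().tolist())
    for ui, unit in enumerate(sess.units):
        out[unit.unit_id] = {}
        for cond in groups:
            acc = np.zeros(nb)
            cov = np.zeros(nb)
            for ti, tr in enumerate(sess.trials):
                if ti not in valid:
                    continue
                if group_by_condition and tr.condition != cond:
                    continue
                ev = tr.events.get(align_event)
                # bin index offset so that aligned bin 0 starts at ev + t0
                off = int(round((ev + t0) / dt))
                ntr = binned.counts[ti].shape[1]
                lo = max(0, -off)
                hi = min(nb, ntr - off)
                if hi <= lo:
                    continue
                acc[lo:hi] += binned.counts[ti][ui, off + lo:off + hi]
                cov[lo:hi] += 1.0
            if not cov.any():
                out[unit.unit_id][cond] = None
                continue
            rate = np.where(cov > 0, acc / np.maximum(cov, 1.0) / dt, np.nan)
            if smoothing_sd > 0:
                rate = gaussian_filter1d(rate, smoothing_sd / dt,
                                         mode="reflect")
            out[unit.unit_id][cond] = {"time": time, "rate": rate}
    return out


# ---------------------------------------------------------------------------
# I/O: HDF5 container with a CSV+JSON fallback
# ---------------------------------------------------------------------------

def _trial_record(tr: TrialInfo) -> dict:
    d = asdict(tr)
    d["target_xy"] = [float(tr.target_xy[0]), float(tr.target_xy[1])]
    return d


def _trial_from_record(d: dict, where: str) -> TrialInfo:
    try:
        ev = EventTimes(**d["events"])
        return TrialInfo(events=ev, target_xy=np.asarray(d["target_xy"]),
                         condition=d["condition"], duration=d["duration"],
                         valid=bool(d.get("valid", True)))
    except (KeyError, TypeError) as e:
        raise SessionFormatError(f"{where}: malformed trial record: {e}")


def write_session(session: Session, path) -> None:
    """Write a session container.

    Paths ending in ``.h5``/``.hdf5`` use the HDF5 layout (groups /units,
    /trials, /spikes/<unit>/<trial>, /metadata); any other path is written
    as a directory holding ``spikes.csv`` (unit, trial, time) and
    ``meta.json`` (units, trials, metadata).  Round trips are lossless to
    1e-6 s in spike times.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        _write_hdf5(session, path)
    else:
        _write_csvdir(session, path)


def read_session(path) -> Session:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        sess = _read_hdf5(path)
    else:
        sess = _read_csvdir(path)
    sess.validate()
    return sess


def _write_hdf5(session: Session, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        ug = f.create_group("units")
        ug.create_dataset("id", data=np.array(
            [u.unit_id for u in session.units], dtype="S64"))
        ug.create_dataset("area", data=np.array(
            [u.area for u in session.units], dtype="S8"))
        ug.create_dataset("channel", data=np.array(
            [u.channel for u in session.units], dtype=np.int64))
        tg = f.create_group("trials")
        ev_names = ["fixation_on", "target_on", "target_off", "go_signal",
                    "saccade_onset"]
        for name in ev_names:
            tg.create_dataset(name, data=np.array(
                [tr.events.get(name) for tr in session.trials]))
        tg.create_dataset("target_xy", data=np.array(
            [tr.target_xy for tr in session.trials]))
        tg.create_dataset("condition", data=np.array(
            [tr.condition for tr in session.trials], dtype="S8"))
        tg.create_dataset("duration", data=np.array(
            [tr.duration for tr in session.trials]))
        tg.create_dataset("valid", data=np.array(
            [tr.valid for tr in session.trials], dtype=bool))
        sg = f.create_group("spikes")
        for ui, u in enumerate(session.units):
            gu = sg.create_group(u.unit_id)
            for ti in range(session.n_trials):
                gu.create_dataset(str(ti), data=np.asarray(
                    session.spikes[ui][ti], dtype=np.float64))
        f.create_dataset("metadata",
                         data=json.dumps(session.metadata, default=str))


def _read_hdf5(path: str) -> Session:
    import h5py

    with h5py.File(path, "r") as f:
        for group in ("units", "trials", "spikes"):
            if group not in f:
                raise SessionFormatError(f"{path}: missing group /{group}")
        ug = f["units"]
        try:
            ids = [s.decode() for s in ug["id"][...]]
            areas = [s.decode() for s in ug["area"][...]]
            chans = ug["channel"][...]
        except KeyError as e:
            raise SessionFormatError(f"{path}: /units missing field {e}")
        units = [Unit(i, a, int(c)) for i, a, c in zip(ids, areas, chans)]
        tg = f["trials"]
        try:
            n = len(tg["duration"])
            trials = []
            for i in range(n):
                ev = EventTimes(*(float(tg[name][i]) for name in
                                  ("fixation_on", "target_on", "target_off",
                                   "go_signal", "saccade_onset")))
                trials.append(TrialInfo(
                    events=ev, target_xy=tg["target_xy"][i],
                    condition=tg["condition"][i].decode(),
                    duration=float(tg["duration"][i]),
                    valid=bool(tg["valid"][i])))
        except KeyError as e:
            raise SessionFormatError(f"{path}: /trials missing field {e}")
        spikes = []
        for u in units:
            if u.unit_id not in f["spikes"]:
                raise SessionFormatError(
                    f"{path}: /spikes missing unit {u.unit_id}")
            gu = f["spikes"][u.unit_id]
            spikes.append([gu[str(ti)][...] for ti in range(len(trials))])
        meta = json.loads(f["metadata"][()]) if "metadata" in f else {}
    return Session(units=units, trials=trials, spikes=spikes, metadata=meta)


def _write_csvdir(session: Session, path: str) -> None:
    import os

    import pandas as pd

    os.makedirs(path, exist_ok=True)
    rows = []
    for ui, u in enumerate(session.units):
        for ti in range(session.n_trials):
            for t in session.spikes[ui][ti]:
                rows.append((u.unit_id, ti, float(t)))
    pd.DataFrame(rows, columns=["unit", "trial", "time"]).to_csv(
        os.path.join(path, "spikes.csv"), index=False, float_format="%.6f")
    meta = {
        "units": [asdict(u) for u in session.units],
        "trials": [_trial_record(tr) for tr in session.trials],
        "metadata": session.metadata,
    }
    with open(os.path.join(path, "meta.json"), "w") as f:
        json.dump(meta, f, indent=1, default=str)


def _read_csvdir(path: str) -> Session:
    import os

    import pandas as pd

    meta_path = os.path.join(path, "meta.json")
    spikes_path = os.path.join(path, "spikes.csv")
    if not os.path.exists(meta_path):
        raise SessionFormatError(f"{path}: missing meta.json")
    if not os.path.exists(spikes_path):
        raise SessionFormatError(f"{path}: missing spikes.csv")
    with open(meta_path) as f:
        meta = json.load(f)
    for key in ("units", "trials"):
        if key not in meta:
            raise SessionFormatError(f"{meta_path}: missing key {key!r}")
    units = [Unit(**u) for u in meta["units"]]
    trials = [_trial_from_record(d, meta_path) for d in meta["trials"]]
    df = pd.read_csv(spikes_path)
    spikes = [[np.array([], dtype=float) for _ in trials] for _ in units]
    uidx = {u.unit_id: i for i, u in enumerate(units)}
    for (unit, trial), grp in df.groupby(["unit", "trial"]):
        if str(unit) not in uidx:
            raise SessionFormatError(f"{spikes_path}: unknown unit {unit!r}")
        spikes[uidx[str(unit)]][int(trial)] = np.sort(
            grp["time"].to_numpy(dtype=float))
    return Session(units=units, trials=trials, spikes=spikes,
                   metadata=meta.get("metadata", {}))


# ---------------------------------------------------------------------------
# Task-trial generators
# ---------------------------------------------------------------------------

def _draw_target(rng: np.random.Generator) -> np.ndarray:
    """Target location: uniform direction, Gaussian eccentricity
    (mean 10 deg, SD 5 deg, truncated at 1 deg)."""
    ecc = max(1.0, rng.normal(10.0, 5.0))
    ang = rng.uniform(0, 2 * np.pi)
    return np.array([ecc * np.cos(ang), ecc * np.sin(ang)])


def generate_task_trials(n_trials: int, seed=None,
                         rng: np.random.Generator | None = None,
                         delay_range: tuple[float, float] = (0.5, 2.0),
                         fixation_range: tuple[float, float] = (1.0, 1.5),
                         target_flash: float = 0.2) -> list[TrialInfo]:
    """Memory-guided saccade trials with the task's timing statistics.

    Fixation-to-target interval uniform on ``fixation_range``, 200 ms target
    flash, delay uniform on ``delay_range`` (0.5-2 s), saccade 150-300 ms
    after the go signal.  IN_RF/OUT_RF is assigned by target hemifield
    (x > 0 is IN_RF).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_trials):
        fix = 0.05
        t_on = fix + rng.uniform(*fixation_range)
        t_off = t_on + target_flash
        go = t_off + rng.uniform(*delay_range)
        sacc = go + rng.uniform(0.15, 0.30)
        xy = _draw_target(rng)
        trials.append(TrialInfo(
            events=EventTimes(fix, t_on, t_off, go, sacc),
            target_xy=xy,
            condition="IN_RF" if xy[0] > 0 else "OUT_RF",
            duration=sacc + 0.3))
    return trials


def generate_compact_trials(n_trials: int, seed=None,
                            rng: np.random.Generator | None = None,
                            duration: float = 1.0) -> list[TrialInfo]:
    """Short fixed-duration trials with jittered events, for desk-scale
    simulation studies.

    Event timings are compressed relative to the real task (delay
    0.15-0.28 s) so that many trials fit in a small compute budget while
    both 800 ms task-kernel supports stay almost fully inside the trial;
    the jitter keeps target and saccade kernels identifiable.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_trials):
        fix = 0.02
        t_on = rng.uniform(0.05, 0.15)
        t_off = t_on + 0.2
        go = t_off + rng.uniform(0.15, 0.35)
        sacc = go + rng.uniform(0.05, 0.09)
        xy = _draw_target(rng)
        trials.append(TrialInfo(
            events=EventTimes(fix, t_on, t_off, go, sacc),
            target_xy=xy,
            condition="IN_RF" if xy[0] > 0 else "OUT_RF",
            duration=duration))
    return trials
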