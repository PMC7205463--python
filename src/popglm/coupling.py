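"""Summaries of fitted kernels: coupling statistics, trial-shuffle nulls,
PCA, time constants, predictive indices, epoch comparisons and tuning
relationships.

Coupling strength for a directed pair is the sum of the reconstructed
time-domain kernel (per-ms log gain over the 250 ms support): positive
sums are excitatory interactions, negative sums inhibitory.  The null
distribution is obtained by permuting the trial order of the predictor
neurons relative to the fitted neuron and refitting, which destroys noise
correlations while preserving each trial's own spike times and task
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import least_squares

from .glm import (ModelSpec, PopulationFit, SessionDesign, crossval_fit,
                  fit_population, heldout_deviance_explained)
from .spikedata import BinnedSession, bin_spikes

__all__ = [
    "coupling_weight", "coupling_gain", "classify_interaction",
    "compute_coupling_stats", "NullDistribution", "permutation_null",
    "significant_fraction", "PCASummary", "pca_kernels", "TimeConstant",
    "fit_time_constant", "predictive_index", "compute_predictive_indices",
    "fit_epoch_models", "TuningFit", "fit_tuning_curve",
    "unit_tuning_curves", "coupling_vs_tuning",
]


# ---------------------------------------------------------------------------
# Kernel summaries
# ---------------------------------------------------------------------------

def coupling_weight(kernel: np.ndarray) -> float:
    """Summed log gain of a time-domain kernel (excitatory > 0)."""
    return float(np.sum(kernel))


def coupling_gain(kernel: np.ndarray) -> float:
    """Maximum multiplicative gain exp(max kernel value); 1 for the zero
    kernel."""
    return float(np.exp(np.max(kernel)))


def classify_interaction(from_area: str, to_area: str,
                         strict: bool = False) -> str:
    """Directed area interaction label, e.g. (LIP, FEF) -> "LIP-FEF"."""
    known = {"LIP", "FEF"}
    if from_area in known and to_area in known:
        return f"{from_area}-{to_area}"
    if strict:
        raise ValueError(f"unknown area pair ({from_area}, {to_area})")
    return "SYNTH-SYNTH"


def compute_coupling_stats(popfit: PopulationFit) -> pd.DataFrame:
    """One row per directed pair: weight (summed log gain) and max gain."""
    area = dict(zip(popfit.unit_ids, popfit.areas))
    rows = []
    for to_uid in popfit.unit_ids:
        nf = popfit.fit_for(to_uid)
        for name in nf.column_map:
            if not name.startswith("coupling:"):
                continue
            from_uid = name.split(":", 1)[1]
            ker = nf.kernel(name)
            rows.append({
                "from": from_uid, "to": to_uid,
                "interaction": classify_interaction(area[from_uid],
                                                    area[to_uid]),
                "weight": coupling_weight(ker),
                "gain": coupling_gain(ker),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trial-shuffle permutation null
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    weights: pd.DataFrame  # columns: perm, from, to, interaction, weight, gain
    n_perm: int
    seed: int | None


def permutation_null(binned: BinnedSession, spec: ModelSpec, n_perm: int,
                     seed=None, warm: PopulationFit | None = None,
                     tol: float = 1e-5) -> NullDistribution:
    """Coupling weights from refits after trial-order permutation.

    For every permutation round, each predictor unit's trials are reordered
    by an independent random permutation; the fitted neuron's spikes, its
    response, and the task covariates are untouched, so the per-trial spike
    times and task alignment are preserved while interneuronal noise
    correlations are destroyed.  Fits warm-start from ``warm`` (typically
    the unpermuted fit), and use a slightly relaxed tolerance.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if binned.n_units < 2:
        raise ValueError("need >= 2 units for a coupling null")
    rng = np.random.default_rng(seed)
    sd = SessionDesign(binned, spec)
    n_valid = len(sd.valid_trials)
    frames = []
    for r in range(n_perm):
        perm = {ui: rng.permutation(n_valid)
                for ui in range(binned.n_units)}
        pf = fit_population(binned, spec, warm=warm, tol=tol, perm=perm,
                            cache=sd)
        stats = compute_coupling_stats(pf)
        stats.insert(0, "perm", r)
        frames.append(stats)
    return NullDistribution(weights=pd.concat(frames, ignore_index=True),
                            n_perm=n_perm,
                            seed=None if seed is None else int(seed))


def significant_fraction(stats: pd.DataFrame, null: NullDistribution,
                         by_interaction: bool = False,
                         two_sided: bool = False):
    """Fraction of real coupling weights beyond the null mean +/- 2 SD.

    One-sided (excitatory exceedance over mean + 2 SD) by default; the
    null mean and SD pool all permuted weights (within each interaction
    class when ``by_interaction``).
    """
    nw = null.weights

    def frac(real_w, null_w):
        m, s = null_w.mean(), null_w.std(ddof=1)
        if not np.isfinite(s) or s == 0:
            raise ValueError("degenerate null distribution (SD = 0)")
        hi = real_w > m + 2 * s
        if two_sided:
            return float(np.mean(hi | (real_w < m - 2 * s)))
        return float(np.mean(hi))

    if not by_interaction:
        return frac(stats["weight"].to_numpy(), nw["weight"].to_numpy())
    out = {}
    for inter, grp in stats.groupby("interaction"):
        out[inter] = frac(grp["weight"].to_numpy(),
                          nw.loc[nw.interaction == inter,
                                 "weight"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# PCA of kernels
# ---------------------------------------------------------------------------

@dataclass
class PCASummary:
    components: np.ndarray  # (n_components, n_lags)
    var_fraction: np.ndarray
    mean: np.ndarray
    scores: np.ndarray  # (n_kernels, n_components)
    n_kernels: int

    def reconstruct(self, n_components: int | None = None) -> np.ndarray:
        """Kernels rebuilt from the first ``n_components`` components
        (all components reproduce the input to numerical precision)."""
        n = len(self.components) if n_components is None else n_components
        return self.mean + self.scores[:, :n] @ self.components[:n]


def pca_kernels(kernels: np.ndarray, n_components: int | None = None
                ) -> PCASummary:
    """PCA of a stack of time-domain kernels (rows = kernels).

    Components are deterministic up to sign; the convention here is a
    positive integral (components whose sum is negative are flipped).
    """
    K = np.asarray(kernels, dtype=float)
    if K.ndim != 2 or K.shape[0] < 3:
        raise ValueError("need a 2-D stack of >= 3 kernels")
    mean = K.mean(axis=0)
    Xc = K - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    tot = var.sum()
    if tot == 0:
        raise ValueError("degenerate kernel group (zero variance)")
    flip = np.where(Vt.sum(axis=1) < 0, -1.0, 1.0)
    comps = Vt * flip[:, None]
    scores = (U * s) * flip[None, :]
    if n_components is not None:
        comps = comps[:n_components]
        var = var[:n_components]
        scores = scores[:, :n_components]
    return PCASummary(components=comps, var_fraction=var / tot, mean=mean,
                      scores=scores, n_kernels=K.shape[0])


# ---------------------------------------------------------------------------
# Double-exponential time constants
# ---------------------------------------------------------------------------

@dataclass
class TimeConstant:
    tau: float  # ms; tau of the larger-positive-amplitude component
    amplitudes: np.ndarray  # (2,)
    tau_pair: np.ndarray  # (2,) ms
    fit_r2: float
    excluded: bool
    reason: str = ""


def _double_exp(params, t):
    a1, tau1, a2, tau2 = params
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def fit_time_constant(kernel: np.ndarray, dt_ms: float = 1.0,
                      r2_threshold: float = 0.5) -> TimeConstant:
    """Least-squares double-exponential fit a1 e^{-t/tau1} + a2 e^{-t/tau2}.

    The reported tau belongs to the component with the larger positive
    amplitude.  Kernels dominated by refractoriness (most-negative value in
    the first 5 ms exceeding the positive peak in magnitude) or poorly fit
    (R^2 below ``r2_threshold``) are excluded.
    """
    k = np.asarray(kernel, dtype=float)
    if k.size * dt_ms < 100:
        raise ValueError("kernel support must span >= 100 ms")
    t = (np.arange(k.size) + 1.0) * dt_ms
    n5 = max(1, int(round(5.0 / dt_ms)))
    neg5 = -min(0.0, k[:n5].min())
    pos_peak = max(0.0, k.max())
    if neg5 > pos_peak:
        return TimeConstant(np.nan, np.zeros(2), np.zeros(2), np.nan,
                            excluded=True, reason="refractory-dominated")

    best = None
    amax = max(1e-3, 3 * np.abs(k).max())
    for t1, t2 in ((5.0, 50.0), (10.0, 100.0), (30.0, 200.0), (60.0, 400.0)):
        for s2 in (1.0, -1.0):
            x0 = (max(k[0], 0.05), t1, s2 * 0.05, t2)
            try:
                res = least_squares(
                    lambda p: _double_exp(p, t) - k, x0,
                    bounds=([-amax, 1.0, -amax, 1.0],
                            [amax, 1000.0, amax, 1000.0]))
            except ValueError:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        return TimeConstant(np.nan, np.zeros(2), np.zeros(2), np.nan,
                            excluded=True, reason="optimizer failure")
    a1, tau1, a2, tau2 = best.x
    sst = float(np.sum((k - k.mean()) ** 2))
    r2 = 1.0 - 2 * best.cost / sst if sst > 0 else np.nan
    amps = np.array([a1, a2])
    taus = np.array([tau1, tau2])
    if np.all(amps <= 0):
        return TimeConstant(np.nan, amps, taus, r2, excluded=True,
                            reason="no positive component")
    pos = np.where(amps > 0, amps, -np.inf)
    tau = float(taus[int(np.argmax(pos))])
    if not np.isfinite(r2) or r2 < r2_threshold:
        return TimeConstant(tau, amps, taus, r2, excluded=True,
                            reason=f"fit_r2 {r2:.2f} < {r2_threshold}")
    return TimeConstant(tau, amps, taus, r2, excluded=False)


# ---------------------------------------------------------------------------
# Predictive indices
# ---------------------------------------------------------------------------

def predictive_index(dev_full: float, dev_reduced: float,
                     eps: float = 1e-9) -> float:
    """(dev_full - dev_reduced) / dev_full, clipped to [0, 1].

    An index of 1 means the dropped term (coupling or history) carries all
    of the model's predictive power; 0 means it adds nothing.
    """
    if not np.isfinite(dev_full) or dev_full <= eps:
        return float("nan")
    return float(np.clip((dev_full - dev_reduced) / dev_full, 0.0, 1.0))


def compute_predictive_indices(binned: BinnedSession, spec: ModelSpec,
                               k_folds: int = 5, seed=0,
                               tol: float = 1e-6) -> pd.DataFrame:
    """Coupling and history indices per unit from cross-validated deviance
    explained of the full model vs. the reduced (dropped-term) models."""
    full = crossval_fit(binned, spec, k_folds=k_folds, seed=seed, tol=tol)
    no_coup = crossval_fit(binned, spec.without("coupling"),
                           k_folds=k_folds, seed=seed, tol=tol)
    no_hist = crossval_fit(binned, spec.without("history"),
                           k_folds=k_folds, seed=seed, tol=tol)
    rows = []
    for uid in full.unit_ids:
        d_full = heldout_deviance_explained(full.fit_for(uid))
        d_nc = heldout_deviance_explained(no_coup.fit_for(uid))
        d_nh = heldout_deviance_explained(no_hist.fit_for(uid))
        rows.append({
            "unit": uid,
            "dev_full": d_full,
            "coupling_index": predictive_index(d_full, d_nc),
            "history_index": predictive_index(d_full, d_nh),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Epoch-split models
# ---------------------------------------------------------------------------

def fit_epoch_models(binned: BinnedSession, spec: ModelSpec,
                     epochs: dict[str, tuple[str, float, float]],
                     tol: float = 1e-5):
    """Fit separate models restricted to named trial epochs.

    ``epochs`` maps a name to (align_event, start_s, end_s); all windows
    must have equal length so epoch comparisons are matched.  Trials on
    which a window is not fully resolvable are dropped for that epoch (the
    count is recorded).  Returns (per-epoch PopulationFit dict, per-epoch
    coupling weights table, pairwise comparison table with rank-sum shift
    and across-pair Pearson correlation).
    """
    lengths = {name: round(e[2] - e[1], 9) for name, e in epochs.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"epoch windows must have equal length: {lengths}")
    sess = binned.session
    fits: dict[str, PopulationFit] = {}
    dropped: dict[str, int] = {}
    tables = []
    for name, (ev, start, end) in epochs.items():
        keep = []
        for ti, tr in enumerate(sess.trials):
            if not tr.valid:
                continue
            t_ev = tr.events.get(ev)
            if t_ev + start >= 0 and t_ev + end <= tr.duration:
                keep.append(ti)
        dropped[name] = len(sess.valid_trial_indices()) - len(keep)
        sub = sess.subset_trials(keep)
        sub_binned = bin_spikes(sub, binned.bin_width)
        espec = replace(spec, epoch_window=(ev, start, end))
        pf = fit_population(sub_binned, espec, tol=tol)
        fits[name] = pf
        tab = compute_coupling_stats(pf)
        tab.insert(0, "epoch", name)
        tables.append(tab)
    weights = pd.concat(tables, ignore_index=True)

    names = list(epochs)
    comp_rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            wa = weights[weights.epoch == names[a]].set_index(["from", "to"])
            wb = weights[weights.epoch == names[b]].set_index(["from", "to"])
            common = wa.index.intersection(wb.index)
            x = wa.loc[common, "weight"].to_numpy()
            y = wb.loc[common, "weight"].to_numpy()
            rs = sps.ranksums(y, x)
            pr = sps.pearsonr(x, y) if len(x) > 2 else (np.nan, np.nan)
            comp_rows.append({
                "epoch_a": names[a], "epoch_b": names[b],
                "n_pairs": len(common),
                "mean_shift": float(np.mean(y) - np.mean(x)),
                "ranksum_stat": float(rs.statistic),
                "ranksum_p": float(rs.pvalue),
                "pearson_r": float(pr[0]),
            })
    comparison = pd.DataFrame(comp_rows)
    comparison.attrs["dropped_trials"] = dropped
    return fits, weights, comparison


# ---------------------------------------------------------------------------
# Spatial tuning
# ---------------------------------------------------------------------------

@dataclass
class TuningFit:
    preferred_angle: float  # degrees in [0, 360)
    width: float  # degrees
    amplitude: float  # spikes/s
    baseline: float  # spikes/s
    reliable: bool = True


def _circ_diff_deg(a, b):
    return (np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0


def fit_tuning_curve(angles_deg: np.ndarray, responses: np.ndarray
                     ) -> TuningFit:
    """1-D circular Gaussian tuning fit r(theta) = b + A exp(-d^2/2w^2)
    with d the wrapped angular distance to the preferred direction."""
    ang = np.asarray(angles_deg, dtype=float)
    r = np.asarray(responses, dtype=float)
    if ang.size < 4:
        raise ValueError("need responses at >= 4 target angles")

    def model(p):
        b, A, mu, w = p
        return b + A * np.exp(-0.5 * (_circ_diff_deg(ang, mu) / w) ** 2)

    rmax, rmin = r.max(), r.min()
    best = None
    for mu0 in ang[np.argsort(r)[-3:]]:
        x0 = (rmin, max(rmax - rmin, 1e-3), float(mu0), 45.0)
        res = least_squares(lambda p: model(p) - r, x0,
                            bounds=([-np.inf, 0.0, -360.0, 5.0],
                                    [np.inf, np.inf, 720.0, 180.0]))
        if best is None or res.cost < best.cost:
            best = res
    b, A, mu, w = best.x
    spread = rmax - rmin
    reliable = A > 0.1 * max(spread, 1e-9) and spread > 1e-6
    return TuningFit(preferred_angle=float(mu % 360.0), width=float(w),
                     amplitude=float(A), baseline=float(b),
                     reliable=bool(reliable))


def unit_tuning_curves(binned: BinnedSession,
                       window: tuple[str, float, float] = ("target_on", 0.05,
                                                           0.45),
                       n_angle_bins: int = 8) -> dict[str, TuningFit]:
    """Tuning curves from mean rates in a post-target window, with target
    directions grouped into ``n_angle_bins`` angular bins."""
    sess = binned.session
    ev, t0, t1 = window
    edges = np.linspace(0, 360, n_angle_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = {}
    for ui, unit in enumerate(sess.units):
        sums = np.zeros(n_angle_bins)
        time = np.zeros(n_angle_bins)
        for ti, tr in enumerate(sess.trials):
            if not tr.valid:
                continue
            t_ev = tr.events.get(ev)
            b0 = max(0, int((t_ev + t0) / binned.bin_width))
            b1 = min(binned.counts[ti].shape[1],
                     int((t_ev + t1) / binned.bin_width))
            if b1 <= b0:
                continue
            ai = min(n_angle_bins - 1, int(tr.angle_deg / 360 * n_angle_bins))
            sums[ai] += binned.counts[ti][ui, b0:b1].sum()
            time[ai] += (b1 - b0) * binned.bin_width
        ok = time > 0
        if ok.sum() < 4:
            raise ValueError(
                f"unit {unit.unit_id}: responses at only {ok.sum()} angles")
        out[unit.unit_id] = fit_tuning_curve(centers[ok], sums[ok] / time[ok])
    return out


def coupling_vs_tuning(stats: pd.DataFrame, tunings: dict[str, TuningFit],
                       n_bins: int = 4) -> pd.DataFrame:
    """Mean coupling weight binned by tuning-peak distance (0-180 deg)."""
    dist = []
    for _, row in stats.iterrows():
        ta, tb = tunings[row["from"]], tunings[row["to"]]
        dist.append(abs(_circ_diff_deg(ta.preferred_angle,
                                       tb.preferred_angle)))
    stats = stats.assign(tuning_distance=dist)
    edges = np.linspace(0, 180, n_bins + 1)
    stats["distance_bin"] = pd.cut(stats.tuning_distance, edges,
                                   include_lowest=True)
    g = stats.groupby("distance_bin", observed=True)["weight"]
    out = g.agg(["mean", "count"]).reset_index()
    out["bin_center"] = [iv.mid for iv in out.distance_bin]
    return out
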