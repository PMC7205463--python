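"""End-to-end orchestration: config validation, staged execution, seed
management and report generation.

A single declarative config (YAML mapping, schema below) names the data
source, the model variant and the analyses to run; every stochastic stage
derives its seed deterministically from the master seed and the stage
name, so a (config, seed) pair reproduces a run bit-for-bit.

Config schema (defaults in parentheses)::

    source:
      kind: synth-glm | synth-attractor | file
      path: <session path>              # kind=file
      n_units (6), n_trials (200), trial_style (compact|task)
      coupling_amp, coupling_prob       # synth-glm generator knobs
      scaled (true), j_pos (1.6), n_sampled (10)   # synth-attractor
    model:
      include_terms ([target, saccade, history, coupling])
      condition_split (true), ridge_strength (0.5), saccade_pre_ms (400)
    analysis:
      k_folds (5), n_perm (0), indices (false), tuning (false)
      epochs: {name: [align_event, start_s, end_s], ...}
    sweep:                               # optional, synth-attractor only
      jpos_values: [...]
    seed (0)
"""

from __future__ import annotations

import hashlib
import json
import os
import shutil

import numpy as np
import pandas as pd

from . import __version__
from .attractor import AttractorParams, attractor_model_spec, sweep_jpos, \
    simulate_session
from .coupling import (compute_coupling_stats, compute_predictive_indices,
                       fit_epoch_models, fit_time_constant, pca_kernels,
                       permutation_null, significant_fraction,
                       unit_tuning_curves, coupling_vs_tuning)
from .glm import (ModelSpec, crossval_fit, heldout_bits_per_spike,
                  heldout_deviance_explained, make_ground_truth_population,
                  save_population_fit, simulate_population)
from .spikedata import (Session, bin_spikes, generate_compact_trials,
                        generate_task_trials, read_session, write_session)

__all__ = ["validate_config", "stage_seed", "run_pipeline",
           "make_source_session", "write_report"]

_SOURCE_KINDS = {"synth-glm", "synth-attractor", "file"}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Fill defaults and validate; raises ConfigError naming the key."""
    cfg = json.loads(json.dumps(config))  # deep copy, JSON-serializable
    src = cfg.setdefault("source", {})
    kind = src.setdefault("kind", "synth-glm")
    if kind not in _SOURCE_KINDS:
        raise ConfigError(f"source.kind must be one of {_SOURCE_KINDS}")
    if kind == "file" and not src.get("path"):
        raise ConfigError("source.path required for source.kind=file")
    src.setdefault("n_units", 6)
    src.setdefault("n_trials", 200)
    src.setdefault("trial_style", "compact")
    if src["trial_style"] not in ("compact", "task"):
        raise ConfigError("source.trial_style must be compact|task")
    src.setdefault("scaled", True)
    src.setdefault("j_pos", 1.6)
    src.setdefault("n_sampled", 10)
    model = cfg.setdefault("model", {})
    try:
        ModelSpec.from_dict(model)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"model: {e}")
    ana = cfg.setdefault("analysis", {})
    ana.setdefault("k_folds", 5)
    ana.setdefault("n_perm", 0)
    ana.setdefault("indices", False)
    ana.setdefault("tuning", False)
    ana.setdefault("epochs", None)
    if ana["n_perm"] < 0:
        raise ConfigError("analysis.n_perm must be >= 0")
    if "sweep" in cfg and kind != "synth-attractor":
        raise ConfigError("sweep requires source.kind=synth-attractor")
    cfg.setdefault("seed", 0)
    return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def model_spec_from_config(cfg: dict) -> ModelSpec:
    spec = ModelSpec.from_dict(cfg.get("model", {}))
    if cfg["source"]["kind"] == "synth-attractor" and "model" not in cfg:
        spec = attractor_model_spec()
    return spec


def make_source_session(cfg: dict) -> Session:
    src = cfg["source"]
    seed = cfg.get("seed", 0)
    if src["kind"] == "file":
        return read_session(src["path"])
    if src["kind"] == "synth-glm":
        gt = make_ground_truth_population(
            src["n_units"], seed=stage_seed(seed, "ground-truth"),
            **{k: src[k] for k in ("coupling_amp", "coupling_prob")
               if k in src})
        gen = (generate_compact_trials if src["trial_style"] == "compact"
               else generate_task_trials)
        trials = gen(src["n_trials"], seed=stage_seed(seed, "trials"))
        return simulate_population(gt, trials,
                                   seed=stage_seed(seed, "simulate"))
    params = (AttractorParams.scaled(j_pos=src["j_pos"]) if src["scaled"]
              else AttractorParams(j_pos=src["j_pos"]))
    sess, _ = simulate_session(params, n_trials=src["n_trials"],
                               n_sampled=src["n_sampled"],
                               seed=stage_seed(seed, "attractor"))
    return sess


def run_pipeline(config: dict, out_dir: str) -> str:
    """Execute the configured pipeline; returns the artifact directory.

    Writes: session.h5, fits.h5, summary.json, coupling.csv, optional
    null.csv / indices.csv / epochs.csv / tuning.csv / sweep.csv, PCA and
    time-constant tables, manifest.json and report.md.  Partial outputs
    are removed if a stage fails.
    """
    cfg = validate_config(config)
    seed = cfg["seed"]
    os.makedirs(out_dir, exist_ok=True)
    try:
        return _run_stages(cfg, out_dir, seed)
    except Exception:
        shutil.rmtree(out_dir, ignore_errors=True)
        raise


def _run_stages(cfg: dict, out_dir: str, seed: int) -> str:
    def path(name):
        return os.path.join(out_dir, name)

    outputs = []

    if "sweep" in cfg:
        src = cfg["source"]
        params = (AttractorParams.scaled(j_pos=src["j_pos"])
                  if src["scaled"] else AttractorParams(j_pos=src["j_pos"]))
        _sessions, summary = sweep_jpos(
            cfg["sweep"]["jpos_values"], params, n_trials=src["n_trials"],
            n_sampled=src["n_sampled"], seed=stage_seed(seed, "sweep"))
        summary.to_csv(path("sweep.csv"), index=False)
        with open(path("sweep.json"), "w") as f:
            json.dump({"min_persistent_jpos":
                       summary.attrs["min_persistent_jpos"],
                       "rows": summary.to_dict("records")}, f, indent=1)
        outputs += ["sweep.csv", "sweep.json"]
        _write_manifest(cfg, out_dir, outputs)
        write_report(out_dir)
        return out_dir

    sess = make_source_session(cfg)
    write_session(sess, path("session.h5"))
    outputs.append("session.h5")

    spec = model_spec_from_config(cfg)
    binned = bin_spikes(sess, spec.bin_width)
    ana = cfg["analysis"]
    popfit = crossval_fit(binned, spec, k_folds=ana["k_folds"],
                          seed=stage_seed(seed, "folds"))
    save_population_fit(popfit, path("fits.h5"))
    outputs.append("fits.h5")

    summary = {
        "units": [{
            "unit": uid,
            "area": popfit.areas[i],
            "bits_per_spike": heldout_bits_per_spike(popfit.fits[i]),
            "deviance_explained":
                heldout_deviance_explained(popfit.fits[i]),
        } for i, uid in enumerate(popfit.unit_ids)],
    }

    stats = compute_coupling_stats(popfit)
    tcs = []
    for uid in popfit.unit_ids:
        nf = popfit.fit_for(uid)
        kers = [nf.kernel(n) for n in nf.column_map
                if n.startswith("coupling:")]
        if not kers:
            continue
        tc = fit_time_constant(np.mean(kers, axis=0))
        h_tc = (fit_time_constant(nf.kernel("history"))
                if "history" in nf.column_map else None)
        tcs.append({"unit": uid, "coupling_tau_ms": tc.tau,
                    "coupling_tau_excluded": tc.excluded,
                    "history_tau_ms": h_tc.tau if h_tc else np.nan,
                    "history_tau_excluded":
                        h_tc.excluded if h_tc else True})
    pd.DataFrame(tcs).to_csv(path("time_constants.csv"), index=False)
    outputs.append("time_constants.csv")

    pca_out = {}
    for inter, grp in stats.groupby("interaction"):
        kers = np.array([popfit.coupling_kernel(r["from"], r["to"])
                         for _, r in grp.iterrows()])
        if len(kers) >= 3:
            p = pca_kernels(kers, n_components=3)
            pca_out[inter] = {
                "var_fraction": p.var_fraction.tolist(),
                "n_kernels": p.n_kernels,
            }
    with open(path("pca.json"), "w") as f:
        json.dump(pca_out, f, indent=1)
    outputs.append("pca.json")

    if ana["n_perm"] > 0:
        null = permutation_null(binned, spec, ana["n_perm"],
                                seed=stage_seed(seed, "null"), warm=popfit)
        null.weights.to_csv(path("null.csv"), index=False)
        outputs.append("null.csv")
        nm = null.weights.weight.mean()
        ns = null.weights.weight.std(ddof=1)
        stats["null_mean"] = nm
        stats["null_sd"] = ns
        stats["significant"] = stats.weight > nm + 2 * ns
        summary["significant_fraction"] = significant_fraction(stats, null)
    stats.to_csv(path("coupling.csv"), index=False)
    outputs.append("coupling.csv")

    if ana["indices"]:
        idx = compute_predictive_indices(
            binned, spec, k_folds=ana["k_folds"],
            seed=stage_seed(seed, "folds"))
        idx.to_csv(path("indices.csv"), index=False)
        outputs.append("indices.csv")

    if ana["epochs"]:
        epochs = {k: tuple(v) for k, v in ana["epochs"].items()}
        _fits, weights, comparison = fit_epoch_models(binned, spec, epochs)
        weights.to_csv(path("epoch_weights.csv"), index=False)
        comparison.to_csv(path("epochs.csv"), index=False)
        outputs += ["epoch_weights.csv", "epochs.csv"]

    if ana["tuning"]:
        tunings = unit_tuning_curves(binned)
        rel = coupling_vs_tuning(stats, tunings)
        pd.DataFrame([{"unit": u, "preferred_angle": t.preferred_angle,
                       "width": t.width, "amplitude": t.amplitude,
                       "baseline": t.baseline, "reliable": t.reliable}
                      for u, t in tunings.items()]).to_csv(
            path("tuning.csv"), index=False)
        rel.drop(columns=["distance_bin"]).to_csv(
            path("coupling_vs_tuning.csv"), index=False)
        outputs += ["tuning.csv", "coupling_vs_tuning.csv"]

    with open(path("summary.json"), "w") as f:
        json.dump(summary, f, indent=1, default=float)
    outputs.append("summary.json")
    _write_manifest(cfg, out_dir, outputs)
    write_report(out_dir)
    return out_dir


def _write_manifest(cfg: dict, out_dir: str, outputs: list[str]) -> None:
    blob = json.dumps(cfg, sort_keys=True).encode()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "master_seed": cfg.get("seed", 0),
        "stage_seeds": {s: stage_seed(cfg.get("seed", 0), s)
                        for s in ("ground-truth", "trials", "simulate",
                                  "attractor", "folds", "null", "sweep")},
        "popglm_version": __version__,
        "outputs": outputs,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=1)


def write_report(out_dir: str) -> str:
    """Assemble a human-readable markdown report from the run artifacts."""
    lines = ["# popglm run report", ""]
    mpath = os.path.join(out_dir, "manifest.json")
    if os.path.exists(mpath):
        with open(mpath) as f:
            man = json.load(f)
        lines += [f"- version: {man['popglm_version']}",
                  f"- master seed: {man['master_seed']}",
                  f"- config hash: {man['config_sha256'][:16]}", ""]
    spath = os.path.join(out_dir, "summary.json")
    if os.path.exists(spath):
        with open(spath) as f:
            summ = json.load(f)
        lines.append("## Per-unit predictive performance\n")
        lines.append("| unit | area | bits/spike | deviance explained |")
        lines.append("|---|---|---|---|")
        for row in summ["units"]:
            lines.append(
                f"| {row['unit']} | {row['area']} | "
                f"{row['bits_per_spike']:.4f} | "
                f"{row['deviance_explained']:.4f} |")
        if "significant_fraction" in summ:
            lines.append(
                f"\nFraction of couplings above null mean + 2 SD: "
                f"{summ['significant_fraction']:.3f}")
        lines.append("")
    for name, title in (("coupling.csv", "Coupling (head)"),
                        ("sweep.csv", "Recurrent-strength sweep")):
        p = os.path.join(out_dir, name)
        if os.path.exists(p):
            df = pd.read_csv(p)
            lines.append(f"## {title}\n")
            lines.append(df.head(10).to_markdown(index=False))
            lines.append("")
    out = os.path.join(out_dir, "report.md")
    with open(out, "w") as f:
        f.write("\n".join(lines))
    return out
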