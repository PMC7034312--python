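"""End-to-end orchestration: simulate -> preprocess -> network -> stats.

One :func:`run_all` call executes the whole analysis reproducibly from a
YAML configuration with a mandatory master seed, writing tidy CSVs, a JSON
run manifest, a markdown report and (optionally) summary figures.  The
master seed deterministically derives every stage seed, so re-running with
the manifest's config reproduces all numeric outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .montage import CHANNEL_NAMES
from .preprocess import behavioral_summary, block_average, preprocess_recording, subject_activation
from .network import connectivity, threshold_sweep
from dataclasses import replace as _sim_replace

from .recording import write_recording, write_trial_log
from .simulate import default_config, simulate_group_dataset
from .stats import (
    brain_behavior_correlation,
    channel_group_test,
    independent_t,
    cohens_d,
    metric_sweep_test,
    significant_ranges,
)

__all__ = ["RunManifest", "validate_config", "run_all", "load_config", "default_run_config"]

log = logging.getLogger("nirsnet")

_SCHEMA: dict[str, dict[str, tuple]] = {
    # section -> key -> (type, validator or None)
    "simulate": {
        "n_ds": (int, lambda v: v >= 2),
        "n_td": (int, lambda v: v >= 2),
        "n_trials": (int, lambda v: v >= 1),
        "motion_rate_per_min": ((int, float), lambda v: v >= 0),
        "network_amp_um": ((int, float), lambda v: v >= 0),
        "within_corr": ((int, float), lambda v: 0 <= v <= 1),
    },
    "preprocess": {
        "band_low_hz": ((int, float), lambda v: v > 0),
        "band_high_hz": ((int, float), lambda v: v > 0),
        "motion_window_s": ((int, float), lambda v: v > 0),
        "motion_amp_threshold": ((int, float), lambda v: v > 0),
        "motion_std_threshold": ((int, float), lambda v: v > 0),
        "spline_smoothing": ((int, float), lambda v: 0 < v < 1),
        "activation_mode": (str, lambda v: v in ("mean", "peak")),
    },
    "network": {
        "mode": (str, lambda v: v in ("sparsity", "correlation")),
        "grid_start": ((int, float), lambda v: 0 < v <= 1),
        "grid_stop": ((int, float), lambda v: 0 < v <= 1),
        "grid_step": ((int, float), lambda v: v > 0),
        "n_null": (int, lambda v: v >= 1),
    },
    "stats": {
        "alpha": ((int, float), lambda v: 0 < v < 1),
        "fdr_method": (str, lambda v: v in ("bh", "storey")),
        "t_variant": (str, lambda v: v in ("welch", "pooled")),
        "behavior_channel": (str, lambda v: v in CHANNEL_NAMES),
    },
    "output": {
        "save_recordings": (bool, None),
        "figures": (bool, None),
    },
}


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seed, outputs, warnings."""

    config: dict
    seed: int
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def save(self, path: str) -> str:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
        return path


def default_run_config() -> dict:
    """The shipped default configuration as a dict."""
    text = (
        resources.files("nirsnet.data")
        .joinpath("default_config.yaml")
        .read_text(encoding="utf-8")
    )
    return yaml.safe_load(text)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = json.loads(json.dumps(path_or_dict))  # deep copy
    else:
        with open(path_or_dict, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    base = default_run_config()
    for section, vals in (cfg or {}).items():
        if isinstance(vals, dict) and section in base:
            base[section].update(vals)
        else:
            base[section] = vals
    return base


def validate_config(path_or_dict) -> list[str]:
    """Check every parameter against its domain; returns violations (empty = ok)."""
    violations: list[str] = []
    try:
        cfg = load_config(path_or_dict)
    except Exception as exc:
        return [f"config unreadable: {exc}"]
    if "seed" not in cfg or cfg["seed"] is None:
        violations.append("seed: a master seed is mandatory")
    elif not isinstance(cfg["seed"], int):
        violations.append("seed: must be an integer")
    for section, vals in cfg.items():
        if section == "seed":
            continue
        if section not in _SCHEMA:
            violations.append(f"{section}: unknown section")
            continue
        if not isinstance(vals, dict):
            violations.append(f"{section}: must be a mapping")
            continue
        for key, value in vals.items():
            if key not in _SCHEMA[section]:
                violations.append(f"{section}.{key}: unknown key")
                continue
            typ, check = _SCHEMA[section][key]
            if isinstance(value, bool) and typ is not bool:
                violations.append(f"{section}.{key}: wrong type")
            elif not isinstance(value, typ):
                violations.append(f"{section}.{key}: wrong type")
            elif check is not None and not check(value):
                violations.append(f"{section}.{key}: value {value!r} out of domain")
    net = cfg.get("network", {})
    if isinstance(net, dict) and not violations:
        if net["grid_start"] > net["grid_stop"]:
            violations.append("network.grid_start: exceeds grid_stop")
    pre = cfg.get("preprocess", {})
    if isinstance(pre, dict) and "band_low_hz" in pre and "band_high_hz" in pre:
        if pre["band_low_hz"] >= pre["band_high_hz"]:
            violations.append("preprocess.band_low_hz: must be below band_high_hz")
    return violations


def _float_csv(df: pd.DataFrame, path: str) -> str:
    df.to_csv(path, index=False)
    return path


def run_all(config, outdir: str) -> RunManifest:
    """Execute the full pipeline per a configuration; returns the manifest.

    ``config`` is a YAML path or a dict; missing keys take the shipped
    defaults.  All outputs land in ``outdir``.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    cfg = load_config(config)
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=cfg["seed"], version=__version__)

    # ---- simulate -----------------------------------------------------
    sim_cfg = default_config(seed=cfg["seed"])
    s = cfg["simulate"]
    sim_cfg = _sim_replace(
        sim_cfg,
        n_per_group={"DS": s["n_ds"], "TD": s["n_td"]},
        n_trials=s["n_trials"],
        motion_rate_per_min=s["motion_rate_per_min"],
        network_amp_um=s.get("network_amp_um", sim_cfg.network_amp_um),
        within_corr=s.get("within_corr", sim_cfg.within_corr),
    )
    log.info("simulating %s subjects", sum(sim_cfg.n_per_group.values()))
    dataset = simulate_group_dataset(sim_cfg)

    if cfg["output"]["save_recordings"]:
        rec_dir = os.path.join(outdir, "recordings")
        os.makedirs(rec_dir, exist_ok=True)
        for rec, tl in dataset:
            write_recording(rec, os.path.join(rec_dir, f"{rec.subject_id}.snirf"))
            write_trial_log(tl, os.path.join(rec_dir, f"{rec.subject_id}_trials.csv"))
        manifest.outputs["recordings"] = rec_dir

    # ---- preprocess ---------------------------------------------------
    p = cfg["preprocess"]
    grid = np.round(
        np.arange(
            cfg["network"]["grid_start"],
            cfg["network"]["grid_stop"] + 1e-9,
            cfg["network"]["grid_step"],
        ),
        10,
    )
    act_rows, beh_rows, metric_rows, curve_store, conn_store = [], [], [], {}, {}
    metrics_by_group: dict[str, dict[str, list]] = {}
    for rec, tl in dataset:
        h = preprocess_recording(
            rec,
            motion_window_s=p["motion_window_s"],
            motion_amp_threshold=p["motion_amp_threshold"],
            motion_std_threshold=p["motion_std_threshold"],
            spline_smoothing=p["spline_smoothing"],
            band_hz=(p["band_low_hz"], p["band_high_hz"]),
        )
        times, curves, n_used, n_dropped = block_average(h)
        if n_dropped:
            manifest.warnings.append(
                f"{rec.subject_id}: dropped {n_dropped} partial epochs"
            )
        curve_store.setdefault(rec.group, []).append(curves)
        act = subject_activation(h, mode=p["activation_mode"])
        acc, rt = behavioral_summary(tl)
        act_rows.append([rec.subject_id, rec.group, *act])
        beh_rows.append([rec.subject_id, rec.group, acc, rt])

        # ---- network ----
        c = connectivity(h)
        conn_store.setdefault(rec.group, []).append(c.r)
        sweep = threshold_sweep(
            c,
            mode=cfg["network"]["mode"],
            grid=grid,
            n_null=cfg["network"]["n_null"],
            seed=cfg["seed"],
        )
        gm = metrics_by_group.setdefault(
            rec.group, {"cp": [], "lp": [], "eg": [], "sigma": []}
        )
        gm["cp"].append([m.cp for m in sweep])
        gm["lp"].append([m.lp for m in sweep])
        gm["eg"].append([m.eg for m in sweep])
        gm["sigma"].append([m.sigma for m in sweep])
        for m in sweep:
            metric_rows.append(
                [
                    rec.subject_id, rec.group, m.mode, m.threshold, m.n_edges,
                    m.cp, m.lp, m.eg, m.sigma, m.c_rand, m.l_rand,
                    m.disconnected_pairs,
                ]
            )

    act_df = pd.DataFrame(act_rows, columns=["subject", "group", *CHANNEL_NAMES])
    beh_df = pd.DataFrame(beh_rows, columns=["subject", "group", "accuracy", "rt_ms"])
    met_df = pd.DataFrame(
        metric_rows,
        columns=[
            "subject", "group", "mode", "threshold", "n_edges", "cp", "lp",
            "eg", "sigma", "c_rand", "l_rand", "disconnected_pairs",
        ],
    )
    manifest.outputs["activations"] = _float_csv(act_df, os.path.join(outdir, "activations.csv"))
    manifest.outputs["behavior"] = _float_csv(beh_df, os.path.join(outdir, "behavior.csv"))
    manifest.outputs["metrics"] = _float_csv(met_df, os.path.join(outdir, "metrics.csv"))

    # ---- stats --------------------------------------------------------
    st = cfg["stats"]
    res_rows = []
    for measure in ("accuracy", "rt_ms"):
        x = beh_df.loc[beh_df.group == "DS", measure].to_numpy()
        y = beh_df.loc[beh_df.group == "TD", measure].to_numpy()
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        t, pval, _ = independent_t(x, y, st["t_variant"])
        try:
            d = cohens_d(x, y)
        except ValueError:  # constant measure in both groups
            d = np.nan
            manifest.warnings.append(f"effect size undefined for {measure}")
        res_rows.append(
            ["behavior", measure, np.nan, t, pval, d, np.nan, x.mean(), y.mean()]
        )
    acts = {
        g: act_df.loc[act_df.group == g, list(CHANNEL_NAMES)].to_numpy()
        for g in ("DS", "TD")
    }
    ch_res = channel_group_test(
        acts, "DS", "TD", list(CHANNEL_NAMES), st["t_variant"], st["fdr_method"]
    )
    for r in ch_res:
        res_rows.append(
            ["activation", r.label, np.nan, r.t, r.p, r.d, r.q, r.mean1, r.mean2]
        )
    metrics_arr = {
        g: {k: np.asarray(v) for k, v in gm.items()}
        for g, gm in metrics_by_group.items()
    }
    sweep_res = metric_sweep_test(
        metrics_arr, "DS", "TD", grid, st["t_variant"], st["fdr_method"]
    )
    sig_ranges = {}
    for name, results in sweep_res.items():
        for r in results:
            thr = float(r.label.rsplit("@", 1)[1])
            res_rows.append(
                ["network", name, thr, r.t, r.p, r.d, r.q, r.mean1, r.mean2]
            )
        sig_ranges[name] = significant_ranges(results, alpha=st["alpha"])
    res_df = pd.DataFrame(
        res_rows,
        columns=[
            "family", "measure", "threshold", "t", "p", "d", "q",
            "mean_DS", "mean_TD",
        ],
    )
    manifest.outputs["tests"] = _float_csv(res_df, os.path.join(outdir, "tests.csv"))

    corr_rows = []
    bc = st["behavior_channel"]
    for g in ("DS", "TD"):
        acc = beh_df.loc[beh_df.group == g, "accuracy"].to_numpy()
        if len(acc) < 3 or np.std(acc) == 0:
            manifest.warnings.append(
                f"brain-behavior correlation skipped for {g}: fewer than 3 "
                "subjects or constant accuracy"
            )
            corr_rows.append([g, bc, "accuracy", np.nan, np.nan])
            continue
        r, pval = brain_behavior_correlation(
            act_df.loc[act_df.group == g, bc].to_numpy(), acc
        )
        corr_rows.append([g, bc, "accuracy", r, pval])
    corr_df = pd.DataFrame(
        corr_rows, columns=["group", "channel", "behavior", "r", "p"]
    )
    manifest.outputs["correlations"] = _float_csv(
        corr_df, os.path.join(outdir, "correlations.csv")
    )

    # ---- report and figures ------------------------------------------
    if cfg["output"]["figures"]:
        try:
            _figures(outdir, times, curve_store, conn_store, met_df, grid, manifest)
        except Exception as exc:  # plotting must never kill an analysis run
            manifest.warnings.append(f"figure generation failed: {exc}")
    _report(outdir, res_df, corr_df, sig_ranges, manifest)
    manifest.save(os.path.join(outdir, "manifest.json"))
    return manifest


def _figures(outdir, times, curve_store, conn_store, met_df, grid, manifest):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = os.path.join(outdir, "figures")
    os.makedirs(fig_dir, exist_ok=True)

    fig, axes = plt.subplots(4, 4, figsize=(14, 10), sharex=True)
    for i, ch in enumerate(CHANNEL_NAMES):
        ax = axes.flat[i]
        for g, color in (("DS", "tab:red"), ("TD", "tab:blue")):
            mean_curve = np.mean(curve_store[g], axis=0)[i]
            ax.plot(times, mean_curve, color=color, label=g)
        ax.set_title(ch, fontsize=9)
    axes.flat[0].legend(fontsize=8)
    for ax in axes.flat[len(CHANNEL_NAMES):]:
        ax.axis("off")
    fig.suptitle("Group-mean trial-averaged dHbO (z-scores)")
    fig.savefig(os.path.join(fig_dir, "trial_curves.png"), dpi=110)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, g in zip(axes, ("DS", "TD")):
        im = ax.imshow(np.mean(conn_store[g], axis=0), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_title(f"{g} mean connectivity")
    fig.colorbar(im, ax=axes, shrink=0.8)
    fig.savefig(os.path.join(fig_dir, "connectivity.png"), dpi=110)
    plt.close(fig)

    fig, axes = plt.subplots(2, 2, figsize=(10, 7))
    for ax, name in zip(axes.flat, ("cp", "lp", "eg", "sigma")):
        for g, color in (("DS", "tab:red"), ("TD", "tab:blue")):
            sub = met_df[met_df.group == g]
            mean = sub.groupby("threshold")[name].mean()
            ax.plot(mean.index, mean.values, color=color, label=g)
        if name == "sigma":
            ax.axhline(1.0, ls="--", color="gray", lw=0.8)
        ax.set_title(name)
        ax.set_xlabel("threshold")
    axes.flat[0].legend()
    fig.tight_layout()
    fig.savefig(os.path.join(fig_dir, "metrics_vs_threshold.png"), dpi=110)
    plt.close(fig)
    manifest.outputs["figures"] = fig_dir


def _report(outdir, res_df, corr_df, sig_ranges, manifest):
    lines = ["# nirsnet run report", ""]
    lines.append(f"seed: {manifest.seed}; version: {manifest.version}")
    lines.append("")
    lines.append("## Behavioral and channel comparisons (DS vs TD)")
    lines.append("")
    lines.append("```\n" + res_df[res_df.family != "network"].to_string(index=False) + "\n```")
    lines.append("")
    lines.append("## Network metric sweep: significant threshold ranges (p < alpha)")
    lines.append("")
    for name, ranges in sig_ranges.items():
        pretty = ", ".join(f"{a:g}-{b:g}" for a, b in ranges) or "none"
        lines.append(f"- {name}: {pretty}")
    lines.append("")
    lines.append("## Brain-behavior correlation")
    lines.append("")
    lines.append("```\n" + corr_df.to_string(index=False) + "\n```")
    if manifest.warnings:
        lines.append("")
        lines.append("## Warnings")
        for w in manifest.warnings:
            lines.append(f"- {w}")
    path = os.path.join(outdir, "report.md")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    manifest.outputs["report"] = path
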