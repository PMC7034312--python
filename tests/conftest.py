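"""Shared fixtures: tiny fast configs plus one session-scoped full default run."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from nirsnet import (
    connectivity,
    default_config,
    preprocess_recording,
    simulate_group_dataset,
    subject_activation,
    behavioral_summary,
    threshold_sweep,
)

MASTER_SEED = 1
SWEEP_GRID = np.round(np.arange(0.2, 0.6 + 1e-9, 0.05), 10)
MID_GRID = slice(2, 7)  # thresholds 0.30-0.50


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast two-group configuration for smoke-level checks."""
    cfg = default_config(seed=MASTER_SEED)
    return replace(cfg, n_per_group={"DS": 2, "TD": 2}, n_trials=6)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default synthetic dataset (7 DS + 6 TD, fixed seed).

    Returns a dict with per-group activation scalars, behavioral summaries
    and network-metric arrays (n_subjects, n_thresholds) over SWEEP_GRID,
    shared by the slower whole-pipeline tests.
    """
    cfg = default_config(seed=MASTER_SEED)
    data = simulate_group_dataset(cfg)
    out = {
        "config": cfg,
        "grid": SWEEP_GRID,
        "activations": {"DS": [], "TD": []},
        "accuracy": {"DS": [], "TD": []},
        "rt": {"DS": [], "TD": []},
        "metrics": {
            g: {k: [] for k in ("cp", "lp", "eg", "sigma")} for g in ("DS", "TD")
        },
    }
    for rec, log in data:
        h = preprocess_recording(rec)
        out["activations"][rec.group].append(subject_activation(h))
        acc, rt = behavioral_summary(log)
        out["accuracy"][rec.group].append(acc)
        out["rt"][rec.group].append(rt)
        sweep = threshold_sweep(
            connectivity(h), mode="sparsity", grid=SWEEP_GRID, n_null=100,
            seed=MASTER_SEED,
        )
        for k in ("cp", "lp", "eg", "sigma"):
            out["metrics"][rec.group][k].append([getattr(m, k) for m in sweep])
    for g in ("DS", "TD"):
        out["activations"][g] = np.asarray(out["activations"][g])
        out["accuracy"][g] = np.asarray(out["accuracy"][g])
        out["rt"][g] = np.asarray(out["rt"][g])
        for k in out["metrics"][g]:
            out["metrics"][g][k] = np.asarray(out["metrics"][g][k])
    return out
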