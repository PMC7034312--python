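"""Two-sample inference, effect sizes, FDR and brain-behavior correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsnet import (
    brain_behavior_correlation,
    channel_group_test,
    cohens_d,
    fdr_adjust,
    independent_t,
    metric_sweep_test,
    significant_ranges,
    t_from_summary,
)


def test_t_from_summary_closed_forms():
    assert t_from_summary(1.0, 1.0, 1.0, 2.0) == 0.0
    assert t_from_summary(1.0, 1.0, 0.0, 1e-12) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        t_from_summary(1.0, 0.0, 0.0, 1.0)


def test_t_from_summary_matches_welch_on_samples():
    rng = np.random.default_rng(0)
    x, y = rng.standard_normal(7) + 1.0, rng.standard_normal(6)
    t_sum = t_from_summary(
        x.mean(), x.std(ddof=1) / np.sqrt(len(x)),
        y.mean(), y.std(ddof=1) / np.sqrt(len(y)),
    )
    t_welch, _, _ = independent_t(x, y, "welch")
    assert t_sum == pytest.approx(t_welch, abs=1e-10)


def test_independent_t_antisymmetry_and_degenerate_cases():
    rng = np.random.default_rng(1)
    x, y = rng.standard_normal(8), rng.standard_normal(5) + 0.5
    t1, p1, _ = independent_t(x, y)
    t2, p2, _ = independent_t(y, x)
    assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)
    t0, p0, _ = independent_t(np.ones(4), np.ones(4))
    assert t0 == 0.0 and p0 == 1.0
    with pytest.raises(ValueError):
        independent_t(x[:1], y)


def test_null_rejection_rate_is_near_nominal():
    rng = np.random.default_rng(2)
    rejections = 0
    n_sim = 200
    for _ in range(n_sim):
        x, y = rng.standard_normal(7), rng.standard_normal(6)
        _, p, _ = independent_t(x, y)
        rejections += p < 0.05
    assert 0.01 <= rejections / n_sim <= 0.12


@settings(max_examples=30, deadline=None, derandomize=True)
@given(shift=st.floats(-5, 5), seed=st.integers(0, 500))
def test_cohens_d_translation_invariance_and_shift_form(shift, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(9)
    y = rng.standard_normal(7)
    d0 = cohens_d(x, y)
    assert cohens_d(x + shift, y + shift) == pytest.approx(d0, abs=1e-9)
    # constant shift of one sample moves d by shift / pooled sd
    pooled = np.sqrt(
        ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
        / (len(x) + len(y) - 2)
    )
    assert cohens_d(x + shift, x) == pytest.approx(shift / x.std(ddof=1), abs=1e-9)
    del pooled
    assert cohens_d(x, x.copy()) == 0.0


def test_bh_step_up_hand_example_and_ties():
    q = fdr_adjust([0.01, 0.02, 0.04, 0.8], method="bh")
    assert q == pytest.approx([0.04, 0.04, 0.0533333333, 0.8])
    assert fdr_adjust([0.037]) == pytest.approx([0.037])
    assert fdr_adjust([0.01] * 13) == pytest.approx([0.01] * 13)
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.2])


def test_storey_q_values_are_ordered_and_bounded():
    p = np.array([0.001, 0.01, 0.2, 0.6, 0.9])
    q = fdr_adjust(p, method="storey")
    assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)
    assert np.all((q >= 0) & (q <= 1))
    # with pi0 = 1 Storey reduces to BH
    p2 = np.array([0.9, 0.95, 0.99])
    assert fdr_adjust(p2, "storey") == pytest.approx(fdr_adjust(p2, "bh"))


def test_bh_never_beats_uncorrected_thresholding():
    rng = np.random.default_rng(3)
    for _ in range(50):
        p = rng.uniform(size=13)
        q = fdr_adjust(p)
        assert (q < 0.05).sum() <= (p < 0.05).sum()
        assert np.all(q >= p - 1e-12)


def test_overwhelming_channel_effect_is_detected():
    rng = np.random.default_rng(4)
    a1 = rng.standard_normal((7, 13))
    a2 = rng.standard_normal((6, 13))
    a1[:, 5] += 10.0  # +10 SD shift in one channel
    res = channel_group_test({"g1": a1, "g2": a2}, "g1", "g2")
    by_label = {r.label: r for r in res}
    assert by_label["CH06"].q < 0.05
    assert by_label["CH06"].t > 0
    assert np.sign(by_label["CH06"].t) == np.sign(
        by_label["CH06"].mean1 - by_label["CH06"].mean2
    )


def test_family_type_one_error_is_controlled():
    rng = np.random.default_rng(5)
    n_sim, any_discovery = 200, 0
    for _ in range(n_sim):
        a1 = rng.standard_normal((7, 13))
        a2 = rng.standard_normal((6, 13))
        res = channel_group_test({"a": a1, "b": a2}, "a", "b")
        any_discovery += any(r.q < 0.05 for r in res)
    assert any_discovery / n_sim <= 0.10


def test_metric_sweep_test_families_and_ranges():
    rng = np.random.default_rng(6)
    thr = np.array([0.2, 0.3, 0.4, 0.5])
    m1 = {"eg": rng.standard_normal((7, 4))}
    m2 = {"eg": rng.standard_normal((6, 4))}
    m1["eg"][:, 1:3] += 3.0  # strong effect at two contiguous thresholds
    res = metric_sweep_test({"a": m1, "b": m2}, "a", "b", thr)["eg"]
    assert len(res) == 4
    ranges = significant_ranges(res)
    assert (0.3, 0.4) in ranges
    # undefined grid points are skipped
    m1["eg"][:, 0] = np.nan
    m2["eg"][:, 0] = np.nan
    res2 = metric_sweep_test({"a": m1, "b": m2}, "a", "b", thr)["eg"]
    assert len(res2) == 3


def test_correlation_null_rejects_at_the_critical_value():
    """|r| > 0.811 is the two-tailed alpha = .05 cutoff at n = 6; a null
    simulation should land near a 5% rejection rate."""
    rng = np.random.default_rng(7)
    n_sim, hits = 500, 0
    for _ in range(n_sim):
        x, y = rng.standard_normal(6), rng.standard_normal(6)
        r, _ = brain_behavior_correlation(x, y)
        hits += abs(r) > 0.811
    assert 0.02 <= hits / n_sim <= 0.09


def test_correlation_trivial_cases():
    x = np.arange(6.0)
    r, p = brain_behavior_correlation(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    with pytest.raises(ValueError):
        brain_behavior_correlation(x, np.ones(6))
    with pytest.raises(ValueError):
        brain_behavior_correlation(x[:2], x[:2])
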