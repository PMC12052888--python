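"""SAM weight, Welch test, fold change, conjunction gate, full DEP run."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from exodep import (
    DifferentialSpectralCounts,
    GateThresholds,
    SimulationConfig,
    gate_call,
    run_dep,
    sam_weight,
    signed_fold_change,
    simulate_counts,
    welch_one_tailed_p,
)
from exodep.enrichment import bh_adjust


# -- SAM weight ---------------------------------------------------------------


def test_sam_weight_direct_substitution():
    assert sam_weight(6, 2, 3, 1) == pytest.approx(2.0)
    assert sam_weight(6, 2, 3, 1, variant="sum") == pytest.approx(1.0)


def test_sam_weight_zero_numerator():
    assert sam_weight(4, 4, 3, 1) == 0.0


def test_sam_weight_degenerate_denominator_is_flagged():
    with pytest.warns(RuntimeWarning, match="degenerate"):
        w = sam_weight(6, 2, 1, 1)
    assert not np.isfinite(w)


def test_sam_weight_symmetries():
    """Difference variant is invariant under group swap; sum variant flips sign."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        mu1, mu2 = rng.uniform(0, 10, 2)
        d1, d2 = rng.uniform(0.1, 5, 2)
        if abs(d1 - d2) < 1e-9:
            continue
        assert sam_weight(mu1, mu2, d1, d2) == pytest.approx(sam_weight(mu2, mu1, d2, d1))
        assert sam_weight(mu1, mu2, d1, d2, "sum") == pytest.approx(-sam_weight(mu2, mu1, d2, d1, "sum"))


# -- Welch one-tailed test ----------------------------------------------------


def test_welch_identical_groups_give_half():
    assert welch_one_tailed_p([3, 5, 7], [3, 5, 7]) == pytest.approx(0.5)


def test_welch_equal_constant_groups_use_t0_convention():
    assert welch_one_tailed_p([5, 5, 5], [5, 5, 5, 5]) == pytest.approx(0.5)


def test_welch_extreme_separation():
    p = welch_one_tailed_p([10.1, 9.9, 10.0, 10.2], [0.1, 0.0, 0.2, -0.1, 0.1, 0.0, 0.1])
    assert p < 1e-6


def test_welch_p_at_most_half_and_direction_free():
    rng = np.random.default_rng(1)
    a = rng.normal(size=(200, 4))
    b = rng.normal(size=(200, 7))
    p = welch_one_tailed_p(a, b)
    assert np.all(p <= 0.5 + 1e-15)
    assert np.allclose(p, welch_one_tailed_p(b, a))


def test_welch_matches_reference_oracle_to_1e10():
    """1,000 random pairs against scipy's own Welch test (independent code path)."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        na, nb = rng.integers(2, 12), rng.integers(2, 12)
        a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=na)
        b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=nb)
        ours = welch_one_tailed_p(a, b)
        oracle = min(
            sps.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue,
            sps.ttest_ind(a, b, equal_var=False, alternative="less").pvalue,
        )
        assert abs(ours - oracle) <= 1e-10


def test_welch_requires_two_values():
    with pytest.raises(ValueError):
        welch_one_tailed_p([1.0], [1.0, 2.0])


# -- signed fold change -------------------------------------------------------


@pytest.mark.parametrize("a,b,expected", [(4, 2, 2.0), (2, 4, -2.0), (3, 3, 1.0)])
def test_fold_change_convention(a, b, expected):
    assert signed_fold_change(a, b) == pytest.approx(expected)


def test_fold_change_zero_mean_is_unique_marker():
    assert np.isnan(signed_fold_change(5, 0))
    assert np.isnan(signed_fold_change(0, 5))


def test_fold_change_both_zero_is_error():
    with pytest.raises(ValueError, match="both group means are zero"):
        signed_fold_change(0, 0)


def test_fold_change_pseudocount_regularizes_zero():
    assert signed_fold_change(5, 0, pseudocount=0.5) == pytest.approx(11.0)


@given(
    a=st.floats(min_value=1e-3, max_value=1e3),
    b=st.floats(min_value=1e-3, max_value=1e3),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_fold_change_antisymmetry(a, b):
    fc_ab = signed_fold_change(a, b)
    fc_ba = signed_fold_change(b, a)
    assert abs(fc_ab) >= 1 and abs(fc_ba) >= 1
    if not np.isclose(a, b):
        assert fc_ab == pytest.approx(-fc_ba, rel=1e-9)


# -- gate ---------------------------------------------------------------------


def test_gate_requires_all_three():
    th = GateThresholds(w_cut=0.8, p_cut=0.05, fc_cut=1.5)
    assert gate_call(1.0, 0.01, 2.0, th) == "up"
    assert gate_call(-1.0, 0.01, -2.0, th) == "down"
    assert gate_call(0.5, 0.01, 2.0, th) == "ns"  # W fails
    assert gate_call(1.0, 0.10, 2.0, th) == "ns"  # p fails
    assert gate_call(1.0, 0.01, 1.2, th) == "ns"  # FC fails
    assert gate_call(np.nan, 0.01, 2.0, th) == "ns"  # flagged W never passes
    assert gate_call(1.0, 0.01, np.nan, th) == "ns"  # unique-marker FC never passes


def test_gate_is_monotone_in_thresholds():
    """Loosening any threshold never turns up/down into ns."""
    rng = np.random.default_rng(3)
    tight = GateThresholds(w_cut=1.0, p_cut=0.03, fc_cut=1.8)
    loose = GateThresholds(w_cut=0.5, p_cut=0.10, fc_cut=1.5)
    for _ in range(500):
        w = rng.normal(0, 1.5)
        p = rng.uniform(0, 0.5)
        fc = rng.normal(0, 3)
        fc = np.sign(fc) * (1 + abs(fc))
        call_tight = gate_call(w, p, fc, tight)
        call_loose = gate_call(w, p, fc, loose)
        if call_tight != "ns":
            assert call_loose == call_tight


def test_gate_mismatched_sign_is_ns():
    # strong stats but FC below +cut and above -cut in the other direction
    assert gate_call(2.0, 0.001, -1.2) == "ns"


# -- BH adjustment ------------------------------------------------------------


def hand_bh(p):
    """Step-up BH computed directly from the definition (test oracle)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def test_bh_hand_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])


def test_bh_matches_hand_step_up_on_random_vectors():
    rng = np.random.default_rng(5)
    for _ in range(50):
        p = rng.uniform(size=rng.integers(1, 40))
        assert bh_adjust(p) == pytest.approx(hand_bh(p), abs=1e-12)


def test_bh_dominates_p_and_is_rank_monotone():
    rng = np.random.default_rng(6)
    p = rng.uniform(size=100)
    q = bh_adjust(p)
    assert np.all(q >= p - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


# -- full run -----------------------------------------------------------------


def test_run_dep_status_invariants(default_study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = run_dep(default_study.counts)
    th = GateThresholds()
    up = table[table.status == "up"]
    down = table[table.status == "down"]
    assert (up.fc >= th.fc_cut).all() and (up.w.abs() > th.w_cut).all() and (up.p < th.p_cut).all()
    assert (down.fc <= -th.fc_cut).all() and (down.w.abs() > th.w_cut).all() and (down.p < th.p_cut).all()
    tested = table[table.status.isin(["up", "down", "ns"])]
    assert np.all(tested.q >= tested.p - 1e-15)
    uniques = table[table.status.isin(["unique_a", "unique_b"])]
    assert uniques.q.isna().all() and uniques.fc.isna().all()


def test_run_dep_unique_counts_match_structure(default_study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = run_dep(default_study.counts)
    assert (table.status == "unique_a").sum() == 48
    assert (table.status == "unique_b").sum() == 41


def test_null_conjunction_fpr_below_directional_alpha():
    """Conjunction can only reduce the directional t-test's 0.10 family alpha."""
    called = total = 0
    for rep in range(25):
        cfg = SimulationConfig(n_up=0, n_down=0, n_unique_a=0, n_unique_b=0, seed=500 + rep)
        study = simulate_counts(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            table = run_dep(study.counts)
        called += table.status.isin(["up", "down"]).sum()
        total += len(table)
    fpr = called / total
    se = np.sqrt(0.10 * 0.90 / total)
    assert fpr <= 0.10 + 3 * se


def test_model_results_summary_and_metadata(default_study):
    model = DifferentialSpectralCounts(default_study.counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit()
    text = res.summary()
    assert "unique A:   48" in text and "|W| > 0.8" in text
    meta = res.run_metadata()
    assert meta["thresholds"]["fc_cut"] == 1.5
    assert sum(meta["status_counts"].values()) == len(res.table)
    assert res.venn().n_common == 417


def test_from_dataframe_constructor(tiny_matrix):
    model = DifferentialSpectralCounts.from_dataframe(tiny_matrix.values, (["A1", "A2"], ["B1", "B2", "B3"]))
    res = model.fit()
    assert set(res.table.columns) >= {"mu_a", "mu_b", "w", "p", "q", "fc", "log2fc", "status"}
    assert res.table.loc["P2", "status"] == "unique_b"


def test_thresholds_validated():
    with pytest.raises(ValueError):
        GateThresholds(fc_cut=0.5)
    with pytest.raises(ValueError):
        GateThresholds(p_cut=1.5)
    with pytest.raises(ValueError):
        GateThresholds(w_variant="ratio")
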