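"""Spectral-count filtering, differential testing and BH control."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nephrosig.phospho import (
    SpectralCountMatrix,
    attach_q_values,
    bh_adjust,
    differential_test,
    filter_min_support,
    select_downregulated,
    t_from_summary,
)
from nephrosig.synthetic import ScenarioConfig, gen_spectral_counts


def make_matrix(counts, n_ctrl=3):
    counts = np.atleast_2d(np.asarray(counts))
    n = counts.shape[1]
    return SpectralCountMatrix(
        proteins=[f"p{i}" for i in range(counts.shape[0])],
        samples=[f"s{j}" for j in range(n)],
        conditions=["control"] * n_ctrl + ["treated"] * (n - n_ctrl),
        counts=counts,
    )


def bh_oracle(p):
    """Brute-force step-up definition: q_i = min over ranks >= rank(i) of
    p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestFilterMinSupport:
    def test_low_treated_support_dropped(self):
        m = filter_min_support(make_matrix([[3, 2, 2, 0, 1, 0]]))
        assert m.proteins == []

    def test_boundary_sum_retained(self):
        m = filter_min_support(make_matrix([[2, 0, 0, 2, 0, 0]]))
        assert m.proteins == ["p0"]

    def test_per_replicate_mode_stricter(self):
        mat = make_matrix([[2, 2, 2, 2, 2, 1]])
        assert filter_min_support(mat, mode="sum").proteins == ["p0"]
        assert filter_min_support(mat, mode="per-replicate").proteins == []

    def test_matches_brute_force_double_sum(self, rng):
        counts = rng.poisson(1.5, size=(500, 6))
        mat = make_matrix(counts)
        kept = set(filter_min_support(mat, min_count=2).proteins)
        expected = {
            f"p{i}"
            for i in range(500)
            if counts[i, :3].sum() >= 2 and counts[i, 3:].sum() >= 2
        }
        assert kept == expected

    def test_empty_result_warns_not_raises(self):
        with pytest.warns(UserWarning, match="removed every protein"):
            filter_min_support(make_matrix([[0, 0, 0, 0, 0, 0]]))


class TestDifferentialTest:
    def test_published_summary_t_statistic(self):
        # control 18.7 +/- 1.2 vs treated 3.3 +/- 0.6 (mean +/- SEM)
        t = t_from_summary(18.7, 1.2, 3.3, 0.6)
        assert t == pytest.approx(11.478, abs=5e-3)

    def test_identical_groups_give_null_result(self):
        res = differential_test(make_matrix([[5, 5, 5, 5, 5, 5]]))
        assert res[0].t_statistic == 0.0
        assert res[0].p_value == 1.0

    def test_matches_welch_formula_per_protein(self, rng):
        counts = rng.poisson(10, size=(40, 6))
        res = differential_test(make_matrix(counts))
        for i, r in enumerate(res):
            ctrl, trt = counts[i, :3], counts[i, 3:]
            v1, v2 = ctrl.var(ddof=1), trt.var(ddof=1)
            if v1 == 0 and v2 == 0:
                continue
            t = (trt.mean() - ctrl.mean()) / np.sqrt(v1 / 3 + v2 / 3)
            assert r.t_statistic == pytest.approx(t, rel=1e-9)
            df = (v1 / 3 + v2 / 3) ** 2 / (
                (v1 / 3) ** 2 / 2 + (v2 / 3) ** 2 / 2
            )
            assert r.p_value == pytest.approx(
                2 * stats.t.sf(abs(t), df), rel=1e-9
            )

    def test_null_p_values_calibrated(self):
        """Null p-values are near-uniform and never anti-conservative.

        Counts are discrete, so at n = 3 the Welch p-distribution has mild
        atoms and sits slightly above uniform; the check bounds the CDF
        deviation and the false-positive rate rather than demanding exact
        continuity.
        """
        cfg = ScenarioConfig(rng_seed=9)
        cfg.phospho.planted_fraction = 0.0
        matrix, planted = gen_spectral_counts(cfg)
        assert planted == []
        res = differential_test(filter_min_support(matrix))
        p = np.array([r.p_value for r in res])
        assert stats.kstest(p, "uniform").statistic < 0.06
        fpr = (p < 0.05).mean()
        assert fpr <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / p.size)


class TestBhAdjust:
    def test_single_p_value_unchanged(self):
        q, rej = bh_adjust([0.01])
        assert q[0] == pytest.approx(0.01)
        assert rej[0]

    def test_hand_computed_step_up(self):
        q, _ = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_p_unchanged(self):
        q, _ = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            bh_adjust([0.1, np.nan])

    def test_matches_brute_force_definition_exactly(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 50))
            q, rej = bh_adjust(p)
            assert np.array_equal(q, bh_oracle(p))
            assert np.array_equal(rej, q <= 0.05)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(30)
            q, rej = bh_adjust(p)
            rej_sm, q_sm, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.allclose(q, q_sm, rtol=1e-12)
            assert np.array_equal(rej, rej_sm)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_q_dominates_p_and_preserves_order(self, p):
        q, _ = bh_adjust(p)
        p = np.asarray(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestSelectDownregulated:
    def test_ties_broken_by_t_then_identifier(self):
        counts = np.array(
            [
                [10, 10, 10, 2, 2, 2],
                [20, 20, 20, 4, 4, 4],
                [10, 10, 10, 30, 30, 30],
            ]
        )
        res = attach_q_values(differential_test(make_matrix(counts)))
        # p0 and p1 have zero within-group variance: identical p; up-regulated
        # p2 must never appear
        sel = select_downregulated(res, top_n=3)
        assert [r.protein for r in sel] == sorted(
            [r.protein for r in sel]
        )
        assert {r.protein for r in sel} == {"p0", "p1"}

    def test_warns_when_fewer_than_requested(self):
        res = attach_q_values(differential_test(make_matrix([[9, 10, 11, 1, 2, 3]])))
        with pytest.warns(UserWarning, match="qualify"):
            select_downregulated(res, top_n=76)

    def test_filter_then_test_equals_test_then_mask(self, rng):
        """Filtering before testing equals testing everything and masking."""
        counts = rng.poisson(2, size=(200, 6))
        mat = make_matrix(counts)
        filtered = filter_min_support(mat)
        direct = {r.protein: r for r in differential_test(filtered)}
        masked = {
            r.protein: r
            for r in differential_test(mat)
            if r.protein in set(filtered.proteins)
        }
        assert direct.keys() == masked.keys()
        for k in direct:
            assert direct[k].p_value == pytest.approx(masked[k].p_value, rel=1e-12)


class TestPlantedScenario:
    def test_selection_recovers_planted_proteins(self):
        cfg = ScenarioConfig(rng_seed=3)
        matrix, planted = gen_spectral_counts(cfg)
        res = differential_test(filter_min_support(matrix))
        qualifying = {
            r.protein
            for r in res
            if r.p_value < 0.05 and r.mean_treated < r.mean_control
        }
        recovery = len(qualifying & set(planted)) / len(planted)
        assert recovery >= 0.8
        top = select_downregulated(attach_q_values(res))
        assert len(top) == 76
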