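"""Reporting-odds-ratio computation, ranking and dual-risk outliers."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nephrosig.pharmacovigilance import (
    ContingencyCounts,
    FrequencyTable,
    build_contingency,
    compute_ror,
    dual_risk_profile,
    rank_drugs,
)
from nephrosig.synthetic import ScenarioConfig, gen_faers


def ror_oracle(a, b, c, d, z=1.96):
    """Independent direct evaluation of the ROR, its SE and CI."""
    ror = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, se, math.exp(math.log(ror) - z * se), math.exp(math.log(ror) + z * se)


class TestComputeRor:
    def test_proportional_rows_give_unity(self):
        r = compute_ror(ContingencyCounts(5, 95, 50, 950))
        assert r.ror == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high

    def test_high_precision_example(self):
        r = compute_ror(ContingencyCounts(10, 990, 100, 98900))
        assert r.ror == pytest.approx(9.98989898989899, rel=1e-12)
        assert r.ci_low == pytest.approx(5.199219122361559, rel=1e-9)
        assert r.ci_high == pytest.approx(19.19482127597945, rel=1e-9)

    def test_haldane_correction_on_zero_cell(self):
        r = compute_ror(ContingencyCounts(0, 100, 50, 9950))
        assert r.corrected
        oracle = ror_oracle(0.5, 100.5, 50.5, 9950.5)
        assert r.ror == pytest.approx(oracle[0], rel=1e-12)
        assert r.ror == pytest.approx(0.980, abs=5e-4)

    def test_zero_cell_without_correction_names_cell(self):
        with pytest.raises(ZeroDivisionError, match="f_dt"):
            compute_ror(ContingencyCounts(0, 100, 50, 9950), correction="none")

    def test_matches_independent_oracle_on_random_tables(self, rng):
        for _ in range(200):
            cells = rng.integers(1, 10_000, size=4)
            r = compute_ror(ContingencyCounts(*cells))
            ror, se, lo, hi = ror_oracle(*cells)
            assert r.ror == pytest.approx(ror, rel=1e-12)
            assert r.se_log_ror == pytest.approx(se, rel=1e-12)
            assert r.ci_low == pytest.approx(lo, rel=1e-12)
            assert r.ci_high == pytest.approx(hi, rel=1e-12)

    @given(
        cells=st.tuples(*[st.integers(1, 10**6)] * 4),
        k=st.integers(2, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_and_consistency(self, cells, k):
        """ROR is invariant to uniform scaling; exp(log_ror) = ror; CI brackets."""
        r1 = compute_ror(ContingencyCounts(*cells))
        r2 = compute_ror(ContingencyCounts(*(k * c for c in cells)))
        assert r2.ror == pytest.approx(r1.ror, rel=1e-9)
        assert math.exp(r1.log_ror) == pytest.approx(r1.ror, rel=1e-12)
        assert r1.ci_low <= r1.ror <= r1.ci_high

    def test_two_drug_class_inversion(self, small_freq_table):
        """Swapping index drug and comparator inverts the ROR on 2-drug classes."""
        table = small_freq_table
        table.drug_class = {"d1", "d2"}
        a = compute_ror(build_contingency(table, "d1", "glomerular"))
        b = compute_ror(build_contingency(table, "d2", "glomerular"))
        assert a.ror * b.ror == pytest.approx(1.0, rel=1e-12)


class TestBuildContingency:
    def test_direct_summation(self, small_freq_table):
        c = build_contingency(small_freq_table, "d1", "glomerular")
        assert c.as_tuple() == (5, 95, 70, 1330)

    def test_group_covering_all_terms_degenerates(self, small_freq_table):
        table = small_freq_table
        table.term_groups = {t: "everything" for t in ("t_glom", "t_hyp", "t_other")}
        c = build_contingency(table, "d1", "everything")
        assert c.f_dn == 0 and c.f_nn == 0
        assert compute_ror(c).corrected  # only computable via correction

    def test_unknown_drug_and_empty_group_error(self, small_freq_table):
        with pytest.raises(ValueError, match="not in the drug class"):
            build_contingency(small_freq_table, "dX", "glomerular")
        with pytest.raises(ValueError, match="no mapped terms"):
            build_contingency(small_freq_table, "d1", "tubular")

    def test_matches_brute_force_tally_on_synthetic_table(self):
        table = gen_faers(ScenarioConfig(rng_seed=4))
        drug, group = "drug_03", "glomerular"
        tally = {"dt": 0, "dn": 0, "nt": 0, "nn": 0}
        group_terms = {t for t, g in table.term_groups.items() if g == group}
        for row in table.records.itertuples():
            key = ("d" if row.drug == drug else "n") + (
                "t" if row.adr_term in group_terms else "n"
            )
            tally[key] += row.count
        c = build_contingency(table, drug, group)
        assert c.as_tuple() == (
            tally["dt"], tally["dn"], tally["nt"], tally["nn"],
        )


class TestRankDrugs:
    def test_identical_counts_rank_alphabetically_at_unity(self):
        rows = []
        for d in ("b", "a", "c"):
            rows += [(d, "t1", 10), (d, "t2", 90)]
        table = FrequencyTable(
            records=pd.DataFrame(rows, columns=["drug", "adr_term", "count"]),
            term_groups={"t1": "g"},
        )
        ranked = rank_drugs(table, "g")
        assert [d for d, _ in ranked] == ["a", "b", "c"]
        assert all(r.ror == pytest.approx(1.0) for _, r in ranked)

    def test_planted_drug_ranks_first(self):
        hits = 0
        for seed in range(20):
            table = gen_faers(ScenarioConfig(rng_seed=seed))
            hits += rank_drugs(table, "glomerular")[0][0] == "drug_00"
        assert hits >= 19

    def test_zero_group_drug_carries_correction_others_unaffected(self):
        rows = [("a", "t1", 0), ("a", "t2", 100)]
        for d in ("b", "c"):
            rows += [(d, "t1", 10), (d, "t2", 90)]
        table = FrequencyTable(
            records=pd.DataFrame(rows, columns=["drug", "adr_term", "count"]),
            term_groups={"t1": "g"},
        )
        by_drug = dict(rank_drugs(table, "g"))
        assert by_drug["a"].corrected
        assert not by_drug["b"].corrected
        assert by_drug["b"].ror == pytest.approx(
            compute_ror(ContingencyCounts(10, 90, 10, 190)).ror
        )


class TestDualRiskProfile:
    @staticmethod
    def _table_on_line(displace: float = 1.0):
        """Drugs exactly on the log-log identity line, one optionally displaced
        upward in group a only."""
        rows = []
        # enough background drugs that a single displaced drug cannot
        # dominate the residual SD (standardized residuals are bounded by
        # ~sqrt(n-2) when one point carries all the misfit)
        factors = [0.5, 1.0, 2.0, 4.0, 1.5, 0.8, 0.6, 1.2, 2.5, 3.0, 0.9, 1.8]
        for i, f in enumerate(factors):
            d = f"d{i}"
            boost = displace if i == 0 else 1.0
            rows += [
                (d, "ta", int(1000 * f * boost)),
                (d, "tb", int(1000 * f)),
                (d, "to", 100_000),
            ]
        return FrequencyTable(
            records=pd.DataFrame(rows, columns=["drug", "adr_term", "count"]),
            term_groups={"ta": "a", "tb": "b"},
        )

    def test_perfect_line_has_zero_residuals_no_outliers(self):
        rows = dual_risk_profile(self._table_on_line(), "a", "b")
        assert all(abs(r.residual) < 1e-6 for r in rows)
        assert not any(r.outlier for r in rows)

    def test_displaced_drug_is_the_only_outlier(self):
        rows = dual_risk_profile(self._table_on_line(displace=10.0), "a", "b")
        assert [r.drug for r in rows if r.outlier] == ["d0"]

    def test_underdetermined_line_raises(self):
        rows = []
        for d in ("a", "b", "c"):
            rows += [(d, "ta", 10), (d, "tb", 10), (d, "to", 100)]
        table = FrequencyTable(
            records=pd.DataFrame(rows, columns=["drug", "adr_term", "count"]),
            term_groups={"ta": "a", "tb": "b"},
        )
        with pytest.raises(ValueError, match=">= 4 usable drugs"):
            dual_risk_profile(table, "a", "b")

    def test_planted_scenario_flags_planted_drug(self):
        table = gen_faers(ScenarioConfig(rng_seed=0))
        rows = dual_risk_profile(table, "glomerular", "hypertension")
        planted = next(r for r in rows if r.drug == "drug_00")
        assert planted.outlier
        assert planted.ror_a > 4.0
        assert 0.5 < planted.ror_b < 2.0
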