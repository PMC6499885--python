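"""Reporting-odds-ratio disproportionality analysis within a drug class.

Spontaneous adverse-event report databases (FAERS-like extracts) give, for
every drug and every coded adverse-reaction term, the number of reports in
which the pair occurs.  For an index drug and an ADR group of interest the
2x2 contingency table is

    f_dt  reports of the index drug with a term in the group
    f_dn  reports of the index drug with any other term
    f_nt  reports of the comparator drugs (rest of the class) with the group
    f_nn  reports of the comparator drugs with any other term

and the reporting odds ratio is ROR = (f_dt/f_dn) / (f_nt/f_nn), with a
Woolf-type standard error of log(ROR),
SE = sqrt(1/f_dt + 1/f_dn + 1/f_nt + 1/f_nn), giving the log-normal
confidence interval exp(log ROR +/- z*SE).

The comparator is always the rest of the supplied drug class (a within-class
signal), never the whole database.  Beyond per-drug RORs this module builds
the dual-ADR risk profile: RORs for two ADR groups are regressed on each
other in log space across the class, and drugs whose standardized residual
exceeds a threshold are flagged as outliers (drugs with excess risk for one
ADR group that is not explained by their risk for the other).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyTable",
    "ContingencyCounts",
    "RorResult",
    "DualRiskRow",
    "build_contingency",
    "compute_ror",
    "rank_drugs",
    "dual_risk_profile",
]


@dataclass
class FrequencyTable:
    """Drug x ADR-term report counts with a flat term -> group mapping.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``drug``, ``adr_term``, ``count`` (nonnegative integers).
    term_groups : dict
        Maps ADR term -> group label.  Terms absent from the map belong to
        no group (they still count toward the "any other term" margins).
    drug_class : set
        The drugs forming the within-class comparator pool.  Must be a
        subset of the drugs present in ``records``.
    """

    records: pd.DataFrame
    term_groups: dict[str, str]
    drug_class: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        required = {"drug", "adr_term", "count"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        if (self.records["count"] < 0).any():
            raise ValueError("counts must be nonnegative")
        present = set(self.records["drug"].unique())
        if not self.drug_class:
            self.drug_class = present
        elif not self.drug_class <= present:
            absent = sorted(self.drug_class - present)
            raise ValueError(f"drug_class members absent from records: {absent}")

    def terms_in_group(self, group: str) -> set[str]:
        return {t for t, g in self.term_groups.items() if g == group}

    @classmethod
    def from_csv(
        cls,
        freq_path,
        groups_path,
        class_path=None,
    ) -> "FrequencyTable":
        """Load from the on-disk layout: a ``drug,adr_term,count`` CSV, a
        ``adr_term,group`` CSV and an optional one-drug-per-line class file."""
        records = pd.read_csv(freq_path)
        groups = pd.read_csv(groups_path)
        term_groups = dict(zip(groups["adr_term"], groups["group"]))
        drug_class: set[str] = set()
        if class_path is not None:
            with open(class_path) as fh:
                drug_class = {line.strip() for line in fh if line.strip()}
        return cls(records=records, term_groups=term_groups, drug_class=drug_class)


@dataclass(frozen=True)
class ContingencyCounts:
    """The four cells of the reporting-odds-ratio contingency table."""

    f_dt: float
    f_dn: float
    f_nt: float
    f_nn: float

    def __post_init__(self) -> None:
        for name in ("f_dt", "f_dn", "f_nt", "f_nn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.f_dt, self.f_dn, self.f_nt, self.f_nn)


@dataclass(frozen=True)
class RorResult:
    """ROR point estimate with its log-scale Woolf confidence interval."""

    ror: float
    log_ror: float
    se_log_ror: float
    ci_low: float
    ci_high: float
    corrected: bool = False


def build_contingency(
    table: FrequencyTable, drug: str, adr_group: str
) -> ContingencyCounts:
    """Collapse a frequency table into the 2x2 counts for one drug and group.

    The comparator pool is every other drug in ``table.drug_class``.
    """
    if drug not in table.drug_class:
        raise ValueError(f"drug {drug!r} is not in the drug class")
    group_terms = table.terms_in_group(adr_group)
    if not group_terms:
        raise ValueError(f"ADR group {adr_group!r} has no mapped terms")

    rec = table.records
    in_class = rec["drug"].isin(table.drug_class)
    is_drug = rec["drug"] == drug
    in_group = rec["adr_term"].isin(group_terms)

    f_dt = int(rec.loc[is_drug & in_group, "count"].sum())
    f_dn = int(rec.loc[is_drug & ~in_group, "count"].sum())
    f_nt = int(rec.loc[in_class & ~is_drug & in_group, "count"].sum())
    f_nn = int(rec.loc[in_class & ~is_drug & ~in_group, "count"].sum())
    return ContingencyCounts(f_dt, f_dn, f_nt, f_nn)


def compute_ror(
    counts: ContingencyCounts,
    z: float = 1.96,
    correction: str = "haldane",
) -> RorResult:
    """Compute the ROR, SE of log(ROR) and the log-normal CI.

    Zero cells are handled with the Haldane-Anscombe correction (+0.5 on all
    four cells) when ``correction="haldane"``; with ``correction="none"`` a
    zero cell raises, naming the offending cell.
    """
    cells = counts.as_tuple()
    corrected = False
    if any(c == 0 for c in cells):
        if correction == "haldane":
            cells = tuple(c + 0.5 for c in cells)
            corrected = True
        elif correction == "none":
            names = ("f_dt", "f_dn", "f_nt", "f_nn")
            zeros = [n for n, c in zip(names, cells) if c == 0]
            raise ZeroDivisionError(
                f"zero contingency cell(s) {zeros}; enable Haldane-Anscombe "
                "correction or supply nonzero counts"
            )
        else:
            raise ValueError(f"unknown correction {correction!r}")
    f_dt, f_dn, f_nt, f_nn = cells
    ror = (f_dt / f_dn) / (f_nt / f_nn)
    log_ror = math.log(ror)
    se = math.sqrt(1.0 / f_dt + 1.0 / f_dn + 1.0 / f_nt + 1.0 / f_nn)
    ci_low = math.exp(log_ror - z * se)
    ci_high = math.exp(log_ror + z * se)
    return RorResult(ror, log_ror, se, ci_low, ci_high, corrected)


def rank_drugs(
    table: FrequencyTable,
    adr_group: str,
    z: float = 1.96,
    correction: str = "haldane",
) -> list[tuple[str, RorResult]]:
    """Per-drug ROR for one ADR group, sorted by ROR descending.

    Ties are broken by drug identifier.  Drugs whose ROR cannot be computed
    (uncorrectable zero cells) are recorded with ``None`` and sort last.
    """
    if len(table.drug_class) < 2:
        raise ValueError("need at least two drugs in the class to rank")
    results: list[tuple[str, RorResult | None]] = []
    for drug in sorted(table.drug_class):
        counts = build_contingency(table, drug, adr_group)
        try:
            results.append((drug, compute_ror(counts, z=z, correction=correction)))
        except ZeroDivisionError:
            results.append((drug, None))
    results.sort(
        key=lambda dr: (-(dr[1].ror) if dr[1] is not None else math.inf, dr[0])
    )
    return results


@dataclass(frozen=True)
class DualRiskRow:
    """One drug's position in the two-ADR-group risk plane."""

    drug: str
    ror_a: float
    ror_b: float
    residual: float
    std_residual: float
    outlier: bool


def dual_risk_profile(
    table: FrequencyTable,
    group_a: str,
    group_b: str,
    flag_threshold: float = 2.0,
    z: float = 1.96,
    correction: str = "haldane",
) -> list[DualRiskRow]:
    """Dual-ADR risk profile: regress log ROR(group_a) on log ROR(group_b).

    Across the drug class an ordinary least-squares line is fitted in log-log
    space; each drug's vertical residual is standardized by the residual
    standard deviation (n - 2 degrees of freedom) and drugs with
    ``|standardized residual| > flag_threshold`` are flagged as outliers —
    drugs with excess group-a risk not explained by their group-b risk.
    """
    drugs, ror_a, ror_b = [], [], []
    for drug in sorted(table.drug_class):
        try:
            ra = compute_ror(
                build_contingency(table, drug, group_a), z=z, correction=correction
            )
            rb = compute_ror(
                build_contingency(table, drug, group_b), z=z, correction=correction
            )
        except ZeroDivisionError:
            continue
        drugs.append(drug)
        ror_a.append(ra.ror)
        ror_b.append(rb.ror)
    n = len(drugs)
    if n < 4:
        raise ValueError(f"dual-risk line needs >= 4 usable drugs, got {n}")
    y = np.log(ror_a)
    x = np.log(ror_b)
    design = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ coef
    resid_sd = float(np.sqrt(np.sum(residuals**2) / (n - 2)))
    rows = []
    for i, drug in enumerate(drugs):
        if resid_sd > 0:
            std_res = float(residuals[i] / resid_sd)
        else:
            std_res = 0.0
        rows.append(
            DualRiskRow(
                drug=drug,
                ror_a=float(ror_a[i]),
                ror_b=float(ror_b[i]),
                residual=float(residuals[i]),
                std_residual=std_res,
                outlier=abs(std_res) > flag_threshold,
            )
        )
    return rows
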