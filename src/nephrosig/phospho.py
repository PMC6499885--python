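"""Differential phosphoprotein abundance from label-free spectral counts.

Spectral counting uses the number of tandem-MS spectra matched to a protein
as a semi-quantitative abundance proxy.  The chain implemented here:

1. support filter — a protein is testable only if its summed counts reach a
   minimum (default 2) in *both* conditions,
2. per-protein two-sample t-test (Welch by default) of treated vs control
   replicate counts,
3. Benjamini–Hochberg step-up control of the false discovery rate,
4. selection of the top-N most significant downregulated proteins, the seed
   set for the downstream interactome analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpectralCountMatrix",
    "DifferentialResult",
    "filter_min_support",
    "differential_test",
    "t_from_summary",
    "bh_adjust",
    "attach_q_values",
    "select_downregulated",
    "results_to_frame",
]

CONTROL = "control"
TREATED = "treated"


@dataclass
class SpectralCountMatrix:
    """Protein x sample nonnegative integer count matrix with condition labels.

    ``counts`` has one row per protein and one column per sample;
    ``conditions`` holds one label per sample, each either ``"control"`` or
    ``"treated"``, with at least two replicates per condition.
    """

    proteins: list[str]
    samples: list[str]
    conditions: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.proteins), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.proteins)} proteins x {len(self.samples)} samples"
            )
        if len(self.conditions) != len(self.samples):
            raise ValueError("one condition label per sample required")
        bad = set(self.conditions) - {CONTROL, TREATED}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        for cond in (CONTROL, TREATED):
            if self.conditions.count(cond) < 2:
                raise ValueError(f"need >= 2 replicates in condition {cond!r}")
        if (self.counts < 0).any():
            raise ValueError("spectral counts must be nonnegative")

    def condition_mask(self, condition: str) -> np.ndarray:
        return np.array([c == condition for c in self.conditions])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.proteins, columns=self.samples)

    @classmethod
    def from_tsv(cls, counts_path, conditions_path) -> "SpectralCountMatrix":
        """Read a protein x sample TSV plus a ``sample,condition`` CSV."""
        frame = pd.read_csv(counts_path, sep="\t", index_col=0)
        cond = pd.read_csv(conditions_path)
        cond_map = dict(zip(cond["sample"], cond["condition"]))
        return cls(
            proteins=list(frame.index),
            samples=list(frame.columns),
            conditions=[cond_map[s] for s in frame.columns],
            counts=frame.to_numpy(),
        )

    def write_tsv(self, counts_path, conditions_path) -> None:
        self.to_frame().to_csv(counts_path, sep="\t", index_label="protein")
        pd.DataFrame({"sample": self.samples, "condition": self.conditions}).to_csv(
            conditions_path, index=False
        )


@dataclass(frozen=True)
class DifferentialResult:
    protein: str
    mean_control: float
    sem_control: float
    mean_treated: float
    sem_treated: float
    t_statistic: float
    p_value: float
    q_value: float | None = None
    direction: str = "none"  # up / down / none; set after BH rejection


def filter_min_support(
    matrix: SpectralCountMatrix, min_count: int = 2, mode: str = "sum"
) -> SpectralCountMatrix:
    """Keep proteins with enough spectral support in *both* conditions.

    ``mode="sum"`` (default) requires the summed counts per condition to be
    >= ``min_count``; ``mode="per-replicate"`` requires every replicate in
    both conditions to be >= ``min_count``.
    """
    ctrl = matrix.counts[:, matrix.condition_mask(CONTROL)]
    trt = matrix.counts[:, matrix.condition_mask(TREATED)]
    if mode == "sum":
        keep = (ctrl.sum(axis=1) >= min_count) & (trt.sum(axis=1) >= min_count)
    elif mode == "per-replicate":
        keep = (ctrl >= min_count).all(axis=1) & (trt >= min_count).all(axis=1)
    else:
        raise ValueError(f"unknown support mode {mode!r}")
    if not keep.any():
        warnings.warn("support filter removed every protein", stacklevel=2)
    return SpectralCountMatrix(
        proteins=[p for p, k in zip(matrix.proteins, keep) if k],
        samples=list(matrix.samples),
        conditions=list(matrix.conditions),
        counts=matrix.counts[keep],
    )


def differential_test(
    matrix: SpectralCountMatrix, equal_var: bool = False
) -> list[DifferentialResult]:
    """Per-protein two-sample t-test of treated vs control counts.

    Welch's unequal-variance form by default (``equal_var=False``); the
    pooled Student form is available.  Degenerate rows (zero variance in both
    groups and equal means) get t = 0, p = 1 by convention.
    """
    ctrl = matrix.counts[:, matrix.condition_mask(CONTROL)].astype(float)
    trt = matrix.counts[:, matrix.condition_mask(TREATED)].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows (all counts equal) trigger a precision warning and a
        # NaN statistic; they are mapped to t = 0, p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(trt, ctrl, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # 0/0 (zero variance, equal means): no evidence either way -> t=0, p=1;
    # nonzero difference over zero variance stays +/-inf with p = 0
    degenerate = np.isnan(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    p[np.isnan(p)] = 1.0

    n_c, n_t = ctrl.shape[1], trt.shape[1]
    mean_c, mean_t = ctrl.mean(axis=1), trt.mean(axis=1)
    sem_c = ctrl.std(axis=1, ddof=1) / np.sqrt(n_c)
    sem_t = trt.std(axis=1, ddof=1) / np.sqrt(n_t)
    return [
        DifferentialResult(
            protein=prot,
            mean_control=float(mean_c[i]),
            sem_control=float(sem_c[i]),
            mean_treated=float(mean_t[i]),
            sem_treated=float(sem_t[i]),
            t_statistic=float(t[i]),
            p_value=float(p[i]),
        )
        for i, prot in enumerate(matrix.proteins)
    ]


def t_from_summary(
    mean_a: float, sem_a: float, mean_b: float, sem_b: float
) -> float:
    """t statistic from group means and standard errors of the mean.

    t = (mean_a - mean_b) / sqrt(sem_a^2 + sem_b^2) — the from-summary entry
    point for published mean ± SEM pairs.
    """
    return (mean_a - mean_b) / np.hypot(sem_a, sem_b)


def bh_adjust(
    p_values, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up q-values and the rejection set at ``alpha``.

    q for the i-th smallest p-value is min over ranks j >= i of p_(j)*m/j,
    capped at 1 (the step-up definition, with monotonicity enforced).
    Returns ``(q_values, reject)`` in the input order; rejection is
    q <= alpha, equivalent to the largest-k step-up rule.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= alpha


def attach_q_values(
    results: list[DifferentialResult], alpha: float = 0.05
) -> list[DifferentialResult]:
    """BH-adjust a result list and set q-values and up/down directions.

    Direction is ``down`` (``up``) when the protein is BH-rejected at
    ``alpha`` and its treated mean is below (above) the control mean.
    """
    q, reject = bh_adjust([r.p_value for r in results], alpha=alpha)
    out = []
    for r, qi, rej in zip(results, q, reject):
        if rej and r.mean_treated < r.mean_control:
            direction = "down"
        elif rej and r.mean_treated > r.mean_control:
            direction = "up"
        else:
            direction = "none"
        out.append(
            DifferentialResult(
                protein=r.protein,
                mean_control=r.mean_control,
                sem_control=r.sem_control,
                mean_treated=r.mean_treated,
                sem_treated=r.sem_treated,
                t_statistic=r.t_statistic,
                p_value=r.p_value,
                q_value=float(qi),
                direction=direction,
            )
        )
    return out


def select_downregulated(
    results: list[DifferentialResult],
    alpha: float = 0.05,
    top_n: int = 76,
    use_raw_p: bool = True,
) -> list[DifferentialResult]:
    """Top-N downregulated proteins ranked by p-value ascending.

    Qualifying proteins have treated mean < control mean and raw p < alpha
    (``use_raw_p=True``, mirroring a raw-p selection with BH q reported
    alongside) or BH q <= alpha otherwise.  Ties in p are broken by |t|
    descending, then protein identifier.  If fewer than ``top_n`` qualify the
    full qualifying list is returned with a warning.
    """
    down = []
    for r in results:
        if r.mean_treated >= r.mean_control:
            continue
        if use_raw_p:
            if r.p_value < alpha:
                down.append(r)
        elif r.q_value is not None and r.q_value <= alpha:
            down.append(r)
    down.sort(key=lambda r: (r.p_value, -abs(r.t_statistic), r.protein))
    if len(down) < top_n:
        warnings.warn(
            f"only {len(down)} downregulated proteins qualify (requested {top_n})",
            stacklevel=2,
        )
    return down[:top_n]


def results_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
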