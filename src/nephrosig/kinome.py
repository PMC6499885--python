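"""Kinome selectivity filtering on percent-residual-activity panels.

An in vitro kinome panel records, for each kinase and each inhibitor, the
catalytic activity remaining under drug as a percent of the untreated
control (residual activity; < 50% residual means > 50% inhibition, values
above 100% indicate activation and never count as inhibition).

The chain: restrict to kinases inhibited below threshold by at least one
drug of the tested panel, intersect with a gene set of interest (e.g. all
genes under actin-related ontology terms), summarize mean residual activity
per drug, and report kinases inhibited by exactly one drug — drug-unique
off-targets that can explain a drug-unique phenotype.
"""

from __future__ import annotations

import re
import warnings

import pandas as pd

__all__ = [
    "KinomeMatrix",
    "GeneSet",
    "filter_active",
    "filter_gene_set",
    "mean_residual",
    "unique_inhibition",
    "actin_gene_set",
    "read_gmt",
]


class KinomeMatrix:
    """Kinase x drug percent-residual-activity matrix (pandas-backed)."""

    def __init__(self, residual_activity: pd.DataFrame):
        if residual_activity.isna().any().any():
            raise ValueError("panel has missing cells")
        if (residual_activity < 0).any().any():
            raise ValueError("residual activity cannot be negative")
        self.data = residual_activity.astype(float)

    @property
    def kinases(self) -> list[str]:
        return list(self.data.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path) -> "KinomeMatrix":
        return cls(pd.read_csv(path, index_col=0))

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index_label="kinase")


class GeneSet:
    """A labelled, non-empty set of gene identifiers (case-folded matching)."""

    def __init__(self, label: str, members) -> None:
        members = set(members)
        if not members:
            raise ValueError("gene set must be non-empty")
        self.label = label
        self.members = members
        self._folded = {str(m).casefold() for m in members}

    def __contains__(self, gene: str) -> bool:
        return str(gene).casefold() in self._folded

    def __len__(self) -> int:
        return len(self.members)


def read_gmt(path) -> dict[str, GeneSet]:
    """Read a GMT gene-set library (term, description, genes...)."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, _desc, *genes = parts
            genes = [g for g in genes if g]
            if genes:
                sets[term] = GeneSet(term, genes)
    return sets


def actin_gene_set(library: dict[str, GeneSet], pattern: str = "actin") -> GeneSet:
    """Union of member genes over library terms whose name matches ``pattern``.

    Case-insensitive regex over term names; the default aggregates every
    actin-related term of an ontology library into one set.
    """
    rx = re.compile(pattern, re.IGNORECASE)
    members: set[str] = set()
    matched = []
    for term, gs in library.items():
        if rx.search(term):
            matched.append(term)
            members |= gs.members
    if not members:
        raise ValueError(f"no library term matches pattern {pattern!r}")
    return GeneSet(f"aggregate[{pattern}] ({len(matched)} terms)", members)


def filter_active(
    m: KinomeMatrix, panel: list[str] | None = None, threshold: float = 50.0
) -> KinomeMatrix:
    """Keep kinases inhibited below ``threshold`` by >= 1 panel drug.

    A kinase whose residual activity is >= threshold under every panel drug
    carries no inhibition signal for the panel and is removed; the boundary
    (exactly ``threshold``) does not count as inhibition.
    """
    if panel is None:
        panel = m.drugs
    if not panel:
        raise ValueError("drug panel is empty")
    missing = set(panel) - set(m.drugs)
    if missing:
        raise ValueError(f"panel drugs absent from matrix: {sorted(missing)}")
    keep = (m.data[panel] < threshold).any(axis=1)
    return KinomeMatrix(m.data.loc[keep])


def filter_gene_set(m: KinomeMatrix, gs: GeneSet) -> KinomeMatrix:
    """Keep kinases that are members of the gene set (case-folded match)."""
    keep = [k for k in m.kinases if k in gs]
    if not keep:
        warnings.warn(f"no kinase belongs to gene set {gs.label!r}", stacklevel=2)
    return KinomeMatrix(m.data.loc[keep])


def mean_residual(m: KinomeMatrix) -> dict[str, float]:
    """Arithmetic mean residual activity per drug over the retained kinases."""
    if len(m) == 0:
        raise ValueError("cannot average over an empty kinase set")
    return m.data.mean(axis=0).to_dict()


def unique_inhibition(m: KinomeMatrix, threshold: float = 50.0) -> dict[str, str]:
    """Kinases inhibited (residual < threshold) under exactly one drug.

    Returns a kinase -> drug mapping; kinases inhibited by zero or several
    drugs are excluded.
    """
    below = m.data < threshold
    n_hits = below.sum(axis=1)
    out: dict[str, str] = {}
    for kinase in m.data.index[n_hits == 1]:
        out[kinase] = below.columns[below.loc[kinase]][0]
    return out
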