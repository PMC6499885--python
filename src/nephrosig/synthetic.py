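"""Seeded synthetic inputs with planted ground truth for every stage.

Each generator emulates the structure of one input of the nephrotoxicity
pipeline — an adverse-event frequency table, a spectral-count matrix, an
evidence-weighted interactome, a kinome residual-activity panel, grids of
AFM force curves, and viability plates — with effects planted at known
locations so downstream stages can be validated against ground truth:

* one drug with elevated reporting odds for one ADR group but not another,
* a fraction of proteins down-regulated by a known ratio,
* a densely interconnected seed module in the interactome,
* a kinase inhibited by exactly one drug (and a gene set containing it),
* spatially structured cell-stiffness fields, and
* four-parameter-logistic viability curves with known EC50.

All randomness flows from one scenario seed through independent per-stage
substreams, so any stage can be regenerated in isolation and identical
configurations yield identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .afm import ForceCurve, ProbeMetadata, hertz_force
from .dose_response import DoseResponseData, four_pl
from .kinome import GeneSet, KinomeMatrix
from .network import Interactome
from .pharmacovigilance import FrequencyTable
from .phospho import SpectralCountMatrix

__all__ = [
    "FaersParams",
    "PhosphoParams",
    "NetworkParams",
    "KinomeParams",
    "AfmParams",
    "DoseParams",
    "ScenarioConfig",
    "gen_faers",
    "gen_spectral_counts",
    "gen_interactome",
    "gen_kinome",
    "gen_force_curves",
    "gen_afm_group_study",
    "gen_dose_response",
]

# fixed substream indices per stage, so regenerating one stage never
# perturbs another
_STREAMS = {
    "faers": 0,
    "phospho": 1,
    "network": 2,
    "kinome": 3,
    "afm": 4,
    "dose": 5,
}


@dataclass
class FaersParams:
    """Adverse-event frequency-table scenario.

    A class of ``n_drugs`` drugs reports over ``n_adr_terms`` ADR terms, the
    first ``n_group_terms`` mapped to ``group_a`` and the next block to
    ``group_b`` (the dual-risk pair); counts are Poisson with per-drug-term
    mean ``baseline_rate``.  Background drugs carry a shared log-normal risk
    factor on *both* groups (drugs fall on the dual-risk correlation line);
    the planted drug's group-a counts are scaled so its population ROR
    against the rest of the class equals ``true_ror`` while its group-b ROR
    stays at 1 — the dual-risk outlier.
    """

    n_drugs: int = 30
    n_adr_terms: int = 100
    n_group_terms: int = 5
    baseline_rate: float = 40.0
    group_a: str = "glomerular"
    group_b: str = "hypertension"
    planted_drug: str | None = "drug_00"
    planted_adr_group: str = "glomerular"
    true_ror: float = 8.0
    drug_risk_sd: float = 0.3  # sd of log risk factor shared by both groups


@dataclass
class PhosphoParams:
    """Spectral-count scenario: 2130 proteins, n = 3 per condition, baseline
    Poisson mean 20; planted proteins drop to ``baseline * effect_ratio``
    (default 0.165, the scale of a strongly inhibited focal-adhesion
    protein: means near 20 vs 3.3 spectra)."""

    n_proteins: int = 2130
    n_replicates: int = 3
    baseline_mean: float = 20.0
    planted_fraction: float = 76 / 2130
    effect_ratio: float = 0.165
    overdispersion: float = 0.0  # negative-binomial dispersion; 0 = Poisson


@dataclass
class NetworkParams:
    """Random interactome with an optionally planted dense seed module.

    Erdos-Renyi background at ``mean_degree``; integer edge evidence drawn
    from ``evidence_probs`` (values 1, 2, ...).  With ``planted_density``
    > 1 the edge probability is multiplied by that factor within the seed
    set and between seeds and a same-sized pool of candidate shared
    intermediates.
    """

    n_nodes: int = 2130
    mean_degree: float = 10.0
    evidence_probs: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    planted_seed_size: int = 76
    planted_density: float = 5.0


@dataclass
class KinomeParams:
    """Residual-activity panel: 300 kinases against a six-drug panel.

    Non-planted kinases are inhibited by zero or >= 2 drugs (never exactly
    one), so the planted kinase is the unique single-drug hit by
    construction.  Residuals stay within [0, 120]% of control.
    """

    n_kinases: int = 300
    drugs: tuple[str, ...] = (
        "dasatinib", "imatinib", "nilotinib", "bosutinib", "vandetanib",
        "erlotinib",
    )
    planted_unique_pair: tuple[str, str] | None = ("LIMK1", "dasatinib")
    frac_promiscuous: float = 0.2  # kinases inhibited by >= 2 panel drugs
    actin_set_fraction: float = 0.15
    inhibited_range: tuple[float, float] = (5.0, 45.0)
    uninhibited_range: tuple[float, float] = (55.0, 115.0)


@dataclass
class AfmParams:
    """Force-curve grids: 6x6 arrays of 4-um indentations by default.

    ``field`` describes the true modulus field: ``{"kind": "uniform",
    "e_pa": E}`` or ``{"kind": "ridge", "background_pa": E0, "ridge_pa": E1,
    "ridge_rows": [...]}``.  ``substrate_slope_per_um`` > 0 plants the
    thin-sample artifact: the apparent modulus grows by that relative
    fraction per micrometre of depth.  Noise is multiplicative on force
    (``noise_rel``) plus a small absolute floor (``noise_abs_n``).
    """

    grid_shape: tuple[int, int] = (6, 6)
    spacing_m: float = 4e-6
    field: dict = field(
        default_factory=lambda: {"kind": "uniform", "e_pa": 10_000.0}
    )
    n_samples: int = 200
    max_indentation_m: float = 4e-6
    contact_offset_range_m: tuple[float, float] = (0.3e-6, 1.2e-6)
    noise_rel: float = 0.05
    noise_abs_n: float = 2e-11
    substrate_slope_per_um: float = 0.0
    spring_constant: float = 0.1
    tip_half_angle_deg: float = 35.0
    poisson_ratio: float = 0.5


@dataclass
class DoseParams:
    """Viability plates on an 8-point dilution from 0.5 to 50,000 nM.

    ``truth`` maps drug -> (bottom, top, hill, ec50_nM); the default plants
    a dasatinib-like EC50 of 253 nM with full kill.  Well noise is
    multiplicative with coefficient of variation ``noise_cv`` (the standard
    plate-reader error model) plus an additive floor of ``noise_floor_sd``
    percent-viability points.
    """

    truth: dict = field(
        default_factory=lambda: {"dasatinib": (0.0, 100.0, 1.0, 253.0)}
    )
    concentrations: tuple[float, ...] = tuple(
        np.round(np.logspace(math.log10(0.5), math.log10(50_000.0), 8), 4)
    )
    n_replicates: int = 4
    noise_cv: float = 0.05  # relative well noise
    noise_floor_sd: float = 0.0  # optional additive percent-viability floor
    vehicle_mean: float = 1.0  # raw absorbance units
    n_vehicle_wells: int = 8


@dataclass
class ScenarioConfig:
    """One seeded scenario covering every pipeline stage."""

    rng_seed: int = 0
    faers: FaersParams = field(default_factory=FaersParams)
    phospho: PhosphoParams = field(default_factory=PhosphoParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    kinome: KinomeParams = field(default_factory=KinomeParams)
    afm: AfmParams = field(default_factory=AfmParams)
    dose: DoseParams = field(default_factory=DoseParams)

    def rng(self, stage: str) -> np.random.Generator:
        """Independent substream for one stage of this scenario."""
        key = _STREAMS[stage]
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.rng_seed, spawn_key=(key,))
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        kwargs = {"rng_seed": raw.get("rng_seed", 0)}
        for name, sub in (
            ("faers", FaersParams), ("phospho", PhosphoParams),
            ("network", NetworkParams), ("kinome", KinomeParams),
            ("afm", AfmParams), ("dose", DoseParams),
        ):
            if name in raw:
                block = dict(raw[name])
                for k, v in block.items():
                    if isinstance(v, list):
                        block[k] = tuple(v)
                if name == "dose" and "truth" in block:
                    block["truth"] = {
                        d: tuple(p) for d, p in dict(block["truth"]).items()
                    }
                kwargs[name] = sub(**block)
        return cls(**kwargs)


def _plain(obj):
    """Recursively convert numpy scalars/tuples for YAML round-tripping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# --------------------------------------------------------------------------
# FAERS-like frequency tables


def gen_faers(config: ScenarioConfig) -> FrequencyTable:
    """Generate a drug x ADR-term frequency table with a dual-risk outlier.

    Counts are Poisson.  Background drugs share a log-normal risk factor on
    both special ADR groups; the planted drug's planted-group means are
    scaled so its *population* ROR against the pooled rest of the class is
    exactly ``true_ror``, while its other-group risk stays at 1.
    """
    p = config.faers
    if p.n_drugs < 2:
        raise ValueError("need >= 2 drugs (a comparator pool must exist)")
    if p.n_group_terms < 1 or 2 * p.n_group_terms > p.n_adr_terms:
        raise ValueError("ADR groups must be non-empty and fit in the term list")
    if p.true_ror <= 0:
        raise ValueError("true_ror must be positive")
    rng = config.rng("faers")

    drugs = [f"drug_{i:02d}" for i in range(p.n_drugs)]
    terms = [f"adr_{t:03d}" for t in range(p.n_adr_terms)]
    term_groups = {}
    for t in range(p.n_group_terms):
        term_groups[terms[t]] = p.group_a
    for t in range(p.n_group_terms, 2 * p.n_group_terms):
        term_groups[terms[t]] = p.group_b
    group_cols = {
        p.group_a: slice(0, p.n_group_terms),
        p.group_b: slice(p.n_group_terms, 2 * p.n_group_terms),
    }
    if p.planted_drug is not None and p.planted_drug not in drugs:
        raise ValueError(f"planted drug {p.planted_drug!r} outside drug list")
    if p.planted_adr_group not in group_cols:
        raise ValueError(f"planted group {p.planted_adr_group!r} is not generated")

    lam = np.full((p.n_drugs, p.n_adr_terms), p.baseline_rate)
    # shared per-drug risk factor puts background drugs on the dual-risk line
    risk = np.exp(rng.normal(0.0, p.drug_risk_sd, size=p.n_drugs))
    for g in (p.group_a, p.group_b):
        lam[:, group_cols[g]] *= risk[:, None]

    if p.planted_drug is not None:
        d = drugs.index(p.planted_drug)
        other = p.group_b if p.planted_adr_group == p.group_a else p.group_a
        lam[d, group_cols[p.planted_adr_group]] = p.baseline_rate
        lam[d, group_cols[other]] = p.baseline_rate  # risk factor 1 off-plant
        # scale the planted cells so the population ROR equals true_ror
        sl = group_cols[p.planted_adr_group]
        mask = np.ones(p.n_drugs, dtype=bool)
        mask[d] = False
        f_nt = lam[mask, sl].sum()
        f_nn = lam[mask].sum() - f_nt
        f_dn = lam[d].sum() - lam[d, sl].sum()
        lam[d, sl] *= p.true_ror * (f_nt / f_nn) * f_dn / lam[d, sl].sum()

    counts = rng.poisson(lam)
    records = pd.DataFrame(
        {
            "drug": np.repeat(drugs, p.n_adr_terms),
            "adr_term": np.tile(terms, p.n_drugs),
            "count": counts.ravel(),
        }
    )
    return FrequencyTable(
        records=records, term_groups=term_groups, drug_class=set(drugs)
    )


# --------------------------------------------------------------------------
# spectral counts


def gen_spectral_counts(
    config: ScenarioConfig,
) -> tuple[SpectralCountMatrix, list[str]]:
    """Generate a spectral-count matrix plus the list of planted proteins.

    Null proteins are Poisson(``baseline_mean``) in both conditions; planted
    proteins have treated mean ``baseline_mean * effect_ratio``.  With
    ``overdispersion`` r > 0 counts switch to a negative binomial with that
    inverse-dispersion (variance = mu + mu^2 / r).
    """
    p = config.phospho
    if p.n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    if not 0 <= p.planted_fraction < 1:
        raise ValueError("planted_fraction must lie in [0, 1)")
    if p.effect_ratio <= 0:
        raise ValueError("effect_ratio must be positive")
    if p.effect_ratio == 1.0 and p.planted_fraction > 0:
        raise ValueError(
            "effect_ratio = 1 with planted proteins makes the truth unidentifiable"
        )
    rng = config.rng("phospho")
    n_planted = int(round(p.planted_fraction * p.n_proteins))
    proteins = [f"prot_{i:04d}" for i in range(p.n_proteins)]
    planted = list(rng.choice(proteins, size=n_planted, replace=False))

    mu = np.full((p.n_proteins, 2 * p.n_replicates), p.baseline_mean)
    planted_idx = [proteins.index(q) for q in planted]
    mu[planted_idx, p.n_replicates:] = p.baseline_mean * p.effect_ratio

    if p.overdispersion > 0:
        r = p.overdispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    samples = [f"ctrl_{i + 1}" for i in range(p.n_replicates)] + [
        f"treat_{i + 1}" for i in range(p.n_replicates)
    ]
    conditions = ["control"] * p.n_replicates + ["treated"] * p.n_replicates
    matrix = SpectralCountMatrix(
        proteins=proteins, samples=samples, conditions=conditions, counts=counts
    )
    return matrix, sorted(planted)


# --------------------------------------------------------------------------
# interactome


def gen_interactome(
    config: ScenarioConfig,
    node_names: list[str] | None = None,
    planted_seeds: list[str] | None = None,
) -> tuple[Interactome, list[str]]:
    """Random evidence-weighted graph with an optional planted dense module.

    Background is Erdos-Renyi at the requested mean degree.  When
    ``planted_density`` > 1 the edge probability is multiplied by that
    factor among the ``planted_seed_size`` seed nodes and between seeds and
    an equal-sized pool of candidate shared intermediates, so the planted
    module is denser both internally and through shared neighbours.
    Returns the graph and the planted seed list.

    ``node_names`` relabels the graph onto an externally supplied universe
    (e.g. the proteins of a spectral-count experiment); ``planted_seeds``
    places the dense module at those named nodes instead of the first
    ``planted_seed_size``.
    """
    p = config.network
    if p.planted_seed_size >= p.n_nodes:
        raise ValueError("planted seed set must be smaller than the graph")
    p_edge = p.mean_degree / (p.n_nodes - 1)
    if not 0 < p_edge < 1:
        raise ValueError(
            f"mean degree {p.mean_degree} infeasible for {p.n_nodes} nodes"
        )
    rng = config.rng("network")
    if node_names is None:
        nodes = np.array([f"gene_{i:04d}" for i in range(p.n_nodes)])
    else:
        if len(node_names) != p.n_nodes:
            raise ValueError(
                f"{len(node_names)} node names for a {p.n_nodes}-node graph"
            )
        nodes = np.asarray(node_names)
    iu, ju = np.triu_indices(p.n_nodes, k=1)
    prob = np.full(iu.size, p_edge)

    k = p.planted_seed_size
    if planted_seeds is None:
        seeds_idx = np.arange(k)
    else:
        if len(planted_seeds) != k:
            raise ValueError(
                f"{len(planted_seeds)} planted seeds but planted_seed_size = {k}"
            )
        name_to_idx = {n: i for i, n in enumerate(nodes)}
        seeds_idx = np.array([name_to_idx[s] for s in planted_seeds])
    if p.planted_density != 1.0:
        non_seed = np.setdiff1d(np.arange(p.n_nodes), seeds_idx)
        pool_idx = non_seed[:k]
        boost_i = np.isin(iu, seeds_idx)
        boost_j = np.isin(ju, seeds_idx)
        pool_i = np.isin(iu, pool_idx)
        pool_j = np.isin(ju, pool_idx)
        boosted = (boost_i & boost_j) | (boost_i & pool_j) | (pool_i & boost_j)
        prob[boosted] = np.minimum(1.0, p_edge * p.planted_density)

    keep = rng.random(iu.size) < prob
    ia, ib = iu[keep], ju[keep]
    ev_probs = np.asarray(p.evidence_probs, dtype=float)
    ev_probs = ev_probs / ev_probs.sum()
    evidence = rng.choice(np.arange(1, ev_probs.size + 1), size=ia.size, p=ev_probs)
    edges = pd.DataFrame(
        {"node_a": nodes[ia], "node_b": nodes[ib], "evidence": evidence}
    )
    return Interactome(edges), list(nodes[seeds_idx])


# --------------------------------------------------------------------------
# kinome panel


def gen_kinome(config: ScenarioConfig) -> tuple[KinomeMatrix, GeneSet]:
    """Generate a residual-activity panel and an actin-style gene set.

    Every non-planted kinase is inhibited by zero or at least two panel
    drugs, so the planted (kinase, drug) pair is the only single-drug hit.
    The planted kinase is always a member of the returned gene set.
    """
    p = config.kinome
    if p.planted_unique_pair is not None:
        k_star, d_star = p.planted_unique_pair
        if d_star not in p.drugs:
            raise ValueError(f"planted drug {d_star!r} not in the panel")
    rng = config.rng("kinome")
    n_bg = p.n_kinases - (1 if p.planted_unique_pair else 0)
    kinases = [f"KIN_{i:03d}" for i in range(n_bg)]

    lo_i, hi_i = p.inhibited_range
    lo_u, hi_u = p.uninhibited_range
    n_drugs = len(p.drugs)
    resid = rng.uniform(lo_u, hi_u, size=(n_bg, n_drugs))
    promiscuous = rng.random(n_bg) < p.frac_promiscuous
    for i in np.flatnonzero(promiscuous):
        n_hits = rng.integers(2, n_drugs + 1)
        hit = rng.choice(n_drugs, size=n_hits, replace=False)
        resid[i, hit] = rng.uniform(lo_i, hi_i, size=n_hits)

    actin_members = set(
        rng.choice(kinases, size=int(p.actin_set_fraction * n_bg), replace=False)
    )
    if p.planted_unique_pair is not None:
        row = rng.uniform(lo_u, hi_u, size=n_drugs)
        row[p.drugs.index(d_star)] = rng.uniform(lo_i, hi_i)
        resid = np.vstack([resid, row])
        kinases = kinases + [k_star]
        actin_members.add(k_star)
    matrix = KinomeMatrix(
        pd.DataFrame(np.clip(resid, 0.0, 120.0), index=kinases, columns=list(p.drugs))
    )
    return matrix, GeneSet("actin_related", actin_members)


# --------------------------------------------------------------------------
# AFM force curves


def _true_field(p: AfmParams) -> np.ndarray:
    rows, cols = p.grid_shape
    spec = p.field
    kind = spec.get("kind", "uniform")
    if kind == "uniform":
        field_pa = np.full((rows, cols), float(spec["e_pa"]))
    elif kind == "ridge":
        field_pa = np.full((rows, cols), float(spec["background_pa"]))
        for r in spec["ridge_rows"]:
            field_pa[int(r), :] = float(spec["ridge_pa"])
    else:
        raise ValueError(f"unknown field kind {kind!r}")
    if (field_pa <= 0).any():
        raise ValueError("modulus field must be strictly positive")
    return field_pa


def gen_force_curves(
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ForceCurve], np.ndarray, np.ndarray]:
    """Generate a grid of approach curves over the configured modulus field.

    Each curve is a flat zero-force baseline up to a per-curve contact
    offset followed by the pyramidal Hertz force law for the local true
    modulus, with multiplicative force noise plus a small absolute noise
    floor.  With ``substrate_slope_per_um`` > 0 the generating modulus grows
    linearly with depth (the thin-sample stiffening artifact).  Returns the
    curves in row-major grid order, the true field (Pa), and the true
    per-curve contact offsets (m).
    """
    p = config.afm
    if p.noise_rel < 0 or p.noise_abs_n < 0:
        raise ValueError("noise parameters must be nonnegative")
    field_pa = _true_field(p)
    if rng is None:
        rng = config.rng("afm")
    probe = ProbeMetadata(
        spring_constant=p.spring_constant,
        tip_half_angle=math.radians(p.tip_half_angle_deg),
        poisson_ratio=p.poisson_ratio,
    )
    lo, hi = p.contact_offset_range_m
    curves = []
    offsets = []
    for e_true in field_pa.ravel():
        z0 = rng.uniform(lo, hi)
        offsets.append(z0)
        z = np.linspace(0.0, z0 + p.max_indentation_m, p.n_samples)
        delta = np.clip(z - z0, 0.0, None)
        e_local = e_true * (1.0 + p.substrate_slope_per_um * delta * 1e6)
        force = hertz_force(delta, 1.0, probe) * e_local
        noisy = force * (1.0 + rng.normal(0.0, p.noise_rel, size=z.size))
        noisy += rng.normal(0.0, p.noise_abs_n, size=z.size)
        curves.append(ForceCurve(z=z, force=noisy, probe=probe,
                                 max_indentation=p.max_indentation_m))
    return curves, field_pa, np.array(offsets)


def gen_afm_group_study(
    config: ScenarioConfig,
    group_means_pa: dict[str, float],
    n_cells: int = 20,
    cell_cv: float = 0.3,
) -> dict[str, list[list[ForceCurve]]]:
    """Per-treatment-group grids of curves for the elasticity comparison.

    Each cell's true modulus is log-normal around its group mean with
    coefficient of variation ``cell_cv``; each cell is probed with one
    uniform grid of the configured shape.
    """
    rng = config.rng("afm")
    sigma = math.sqrt(math.log(1.0 + cell_cv**2))
    out: dict[str, list[list[ForceCurve]]] = {}
    for group, mean_pa in group_means_pa.items():
        cells = []
        for _ in range(n_cells):
            e_cell = float(
                mean_pa * math.exp(rng.normal(-0.5 * sigma**2, sigma))
            )
            cfg = ScenarioConfig(
                rng_seed=config.rng_seed,
                afm=AfmParams(
                    **{**asdict(config.afm), "field": {"kind": "uniform", "e_pa": e_cell}}
                ),
            )
            curves, _, _ = gen_force_curves(cfg, rng=rng)
            cells.append(curves)
        out[group] = cells
    return out


# --------------------------------------------------------------------------
# dose-response plates


def gen_dose_response(
    config: ScenarioConfig,
) -> dict[str, DoseResponseData]:
    """Generate raw-scale viability plates per drug from the 4PL truth.

    Raw well values are ``viability/100 * vehicle_mean`` with multiplicative
    noise of coefficient of variation ``noise_cv`` plus an additive floor of
    ``noise_floor_sd`` viability points; vehicle wells carry the same noise
    around ``vehicle_mean``.
    """
    p = config.dose
    conc = np.asarray(p.concentrations, dtype=float)
    if (conc <= 0).any() or (np.diff(conc) <= 0).any():
        raise ValueError("concentrations must be positive and strictly increasing")
    rng = config.rng("dose")
    floor_sd = p.noise_floor_sd / 100.0 * p.vehicle_mean
    plates = {}
    for drug, (bottom, top, hill, ec50) in p.truth.items():
        v_true = four_pl(conc, bottom, top, hill, ec50)  # percent viability
        shape = (conc.size, p.n_replicates)
        raw = v_true[:, None] / 100.0 * p.vehicle_mean
        raw = raw * (1.0 + rng.normal(0.0, p.noise_cv, size=shape))
        raw = raw + rng.normal(0.0, floor_sd, size=shape)
        vehicle = p.vehicle_mean * (
            1.0 + rng.normal(0.0, p.noise_cv, size=p.n_vehicle_wells)
        ) + rng.normal(0.0, floor_sd, size=p.n_vehicle_wells)
        plates[drug] = DoseResponseData(
            concentrations=conc, responses=raw, vehicle_wells=vehicle
        )
    return plates
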