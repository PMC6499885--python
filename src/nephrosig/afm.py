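"""AFM single-cell elastography from approach force-indentation curves.

Each record is the advance phase of an AFM indentation: tip-sample position
``z`` (increasing into the cell) against cantilever force.  For a four-sided
pyramidal indenter (Bilodeau geometry) pressed into an incompressible
elastic half-space, the contact force law is

    F(delta) = (tan(theta) / sqrt(2)) * E / (1 - nu^2) * delta^2,

with indentation depth ``delta = z - z0`` past the contact point ``z0``,
tip half-angle ``theta`` and Poisson ratio ``nu``.

Pipeline per curve: the contact point is found by a grid search minimizing
the whole-curve least-squares residual of (flat baseline before z0, Hertz
law after z0); the apparent modulus ``E_fit`` comes from the same fit; the
depth-dependent pointwise modulus E(delta) inverts the force law sample by
sample and its depth trend flags substrate artifacts (apparent stiffening
with depth on thin samples).  Curves acquired on a spatial grid assemble
into an elastography map; per-cell median moduli feed a one-way ANOVA with
Tukey HSD across treatment groups.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "ProbeMetadata",
    "ForceCurve",
    "ElasticityResult",
    "ElastographyMap",
    "detect_contact_point",
    "hertz_fit",
    "hertz_force",
    "pointwise_modulus",
    "analyze_curve",
    "assemble_map",
    "compare_group_elasticity",
]


@dataclass(frozen=True)
class ProbeMetadata:
    """Cantilever and indenter constants.

    Defaults follow a soft-cell protocol: 0.1 N/m cantilever, 35-degree
    pyramid half-angle, incompressible sample (nu = 0.5).
    """

    spring_constant: float = 0.1  # N/m
    tip_half_angle: float = math.radians(35.0)  # rad
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")
        if not 0 < self.tip_half_angle < math.pi / 2:
            raise ValueError("tip half-angle must lie in (0, pi/2)")
        if not 0 <= self.poisson_ratio < 0.5 + 1e-9:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")

    @property
    def geometry_coefficient(self) -> float:
        """The prefactor tan(theta)/sqrt(2)/(1 - nu^2) so F = coef * E * delta^2."""
        return math.tan(self.tip_half_angle) / math.sqrt(2.0) / (
            1.0 - self.poisson_ratio**2
        )


@dataclass
class ForceCurve:
    """Approach-phase indentation curve: z (m, into the cell) vs force (N)."""

    z: np.ndarray
    force: np.ndarray
    probe: ProbeMetadata = field(default_factory=ProbeMetadata)
    max_indentation: float = 4e-6  # m

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.z.shape != self.force.shape or self.z.ndim != 1:
            raise ValueError("z and force must be equal-length 1-D arrays")
        if self.z.size < 20:
            raise ValueError("curve too short (< 20 samples)")
        if not np.all(np.isfinite(self.force)) or not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite samples in curve")

    @property
    def sample_spacing(self) -> float:
        return float(np.median(np.diff(self.z)))


@dataclass
class ElasticityResult:
    """Per-curve elastography readout."""

    contact_point: float  # m
    e_fit: float  # Pa
    fit_r2: float
    pointwise_delta: np.ndarray  # m
    pointwise_e: np.ndarray  # Pa
    e_median: float  # Pa
    substrate_flag: bool


def hertz_force(
    delta: np.ndarray, e_modulus: float, probe: ProbeMetadata
) -> np.ndarray:
    """Forward pyramidal Hertz model; zero force for negative depths."""
    delta = np.asarray(delta, dtype=float)
    return probe.geometry_coefficient * e_modulus * np.clip(delta, 0.0, None) ** 2


def _fit_at_candidate(
    z: np.ndarray, force: np.ndarray, i: int, coef: float
) -> tuple[float, float, float]:
    """Closed-form piecewise fit with contact at sample i.

    Returns (sum of squared residuals over the whole curve, E estimate,
    baseline force).  The baseline is the pre-contact mean; E solves the
    linear least squares of corrected force on delta^2, clipped at zero.
    """
    baseline = force[:i].mean() if i > 0 else 0.0
    f_corr = force - baseline
    delta = z[i:] - z[i]
    d2 = delta * delta
    denom = float(np.dot(d2, d2))
    e_hat = max(0.0, float(np.dot(f_corr[i:], d2)) / (coef * denom)) if denom > 0 else 0.0
    resid_post = f_corr[i:] - coef * e_hat * d2
    ss = float(np.dot(f_corr[:i], f_corr[:i])) + float(np.dot(resid_post, resid_post))
    return ss, e_hat, baseline


def _ss_at_z0(
    z: np.ndarray, force: np.ndarray, z0: float, coef: float
) -> tuple[float, float, float]:
    """Whole-curve squared residual of the piecewise model at continuous z0."""
    pre = z < z0
    baseline = force[pre].mean() if pre.any() else 0.0
    f_corr = force - baseline
    d2 = np.clip(z - z0, 0.0, None) ** 2
    denom = float(np.dot(d2, d2))
    e_hat = max(0.0, float(np.dot(f_corr, d2)) / (coef * denom)) if denom > 0 else 0.0
    resid = f_corr - coef * e_hat * d2
    return float(np.dot(resid, resid)), e_hat, baseline


def _force_onset_index(force: np.ndarray, sustained: int = 3) -> int:
    """First index from which the force stays above the baseline noise band.

    The baseline level and noise scale come robustly (median / MAD) from the
    leading fifth of the curve; the onset is the first sample followed by
    ``sustained`` consecutive samples above baseline + 5 sigma (with a tiny
    relative floor so noiseless curves resolve their exact first rise).
    """
    n = force.size
    head = force[: max(4, n // 5)]
    level = float(np.median(head))
    sigma = 1.4826 * float(np.median(np.abs(head - level)))
    span = float(np.max(np.abs(force - level))) or 1.0
    thresh = level + max(5.0 * sigma, 1e-9 * span)
    above = force > thresh
    for i in range(n - sustained + 1):
        if above[i : i + sustained].all():
            return i
    return n - 1


def detect_contact_point(
    curve: ForceCurve, min_post_samples: int = 10
) -> float:
    """Contact point by onset-bounded residual search with sub-sample refinement.

    Candidate contact samples run from the second sample up to the force
    onset (the first sustained rise above the baseline noise band) — the
    onset cap keeps the search from compensating non-Hertzian depth trends
    by sliding the contact deep into the indented region.  Each candidate is
    scored by the whole-curve squared residual of the piecewise model (flat
    baseline before, pyramidal Hertz after); the winner is then refined
    continuously between its neighbouring samples.  A curve whose best model
    is flat (fitted E = 0, i.e. no contact) raises.
    """
    z, force = curve.z, curve.force
    n = z.size
    last = n - min_post_samples
    if last < 1:
        raise ValueError(
            f"need >= {min_post_samples} post-contact samples after a baseline point"
        )
    coef = curve.probe.geometry_coefficient
    onset = _force_onset_index(force)
    hi = min(onset + 2, last)
    best = (np.inf, 0.0, 0.0, 1)
    for i in range(1, hi + 1):
        ss, e_hat, baseline = _fit_at_candidate(z, force, i, coef)
        if ss < best[0]:
            best = (ss, e_hat, baseline, i)
    _, e_hat, _, i_best = best
    if e_hat <= 0.0:
        raise ValueError("no contact detected: best fit has zero modulus")
    lo_z = z[max(i_best - 1, 0)]
    hi_z = z[min(i_best + 1, n - 1)]
    res = minimize_scalar(
        lambda z0: _ss_at_z0(z, force, z0, coef)[0],
        bounds=(lo_z, hi_z),
        method="bounded",
        options={"xatol": curve.sample_spacing * 1e-6},
    )
    z0_ref = float(res.x)
    if _ss_at_z0(z, force, z0_ref, coef)[0] <= best[0]:
        return z0_ref
    return float(z[i_best])


def hertz_fit(curve: ForceCurve, z0: float) -> tuple[float, float]:
    """Least-squares pyramidal Hertz fit past a known contact point.

    Returns ``(E_fit, r2)`` where r2 is the coefficient of determination of
    the Hertz model over the post-contact segment (baseline-corrected).
    E is constrained nonnegative (closed-form projection).
    """
    z, force = curve.z, curve.force
    pre = z < z0
    post = ~pre
    if post.sum() < 3:
        raise ValueError("degenerate indentation range: < 3 post-contact samples")
    baseline = force[pre].mean() if pre.any() else 0.0
    f_post = force[post] - baseline
    delta = z[post] - z0
    d2 = delta * delta
    denom = float(np.dot(d2, d2))
    if denom == 0.0:
        raise ValueError("degenerate indentation range: zero depth span")
    coef = curve.probe.geometry_coefficient
    e_fit = max(0.0, float(np.dot(f_post, d2)) / (coef * denom))
    resid = f_post - coef * e_fit * d2
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((f_post - f_post.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return e_fit, r2


def pointwise_modulus(
    curve: ForceCurve,
    z0: float,
    delta_min: float = 100e-9,
    rel_slope_threshold_per_um: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Depth-dependent apparent modulus by pointwise Hertz inversion.

    E(delta_i) = F_i (1 - nu^2) / ((tan theta / sqrt 2) delta_i^2) for every
    post-contact sample deeper than ``delta_min`` (shallow samples are
    excluded: the inversion blows up noise as delta -> 0).  Returns
    ``(delta, E(delta), E_median, substrate_flag)``; the flag fires when the
    least-squares slope of E against delta, normalized by the median,
    exceeds ``rel_slope_threshold_per_um`` (default +20% per micrometre) —
    apparent stiffening with depth, the signature of a substrate artifact.
    """
    z, force = curve.z, curve.force
    pre = z < z0
    baseline = force[pre].mean() if pre.any() else 0.0
    delta = z - z0
    sel = delta >= delta_min
    if not sel.any():
        raise ValueError(f"no sample deeper than delta_min = {delta_min:g} m")
    d = delta[sel]
    f_corr = force[sel] - baseline
    coef = curve.probe.geometry_coefficient
    e_point = f_corr / (coef * d * d)
    e_median = float(np.median(e_point))
    substrate_flag = False
    # depth trend from the deep half of the profile: shallow pointwise values
    # are hypersensitive to contact-point error (delta appears squared), so
    # the slope is estimated where the inversion is stable
    deep = d >= 0.5 * d.max()
    if deep.sum() >= 3 and e_median > 0:
        slope = np.polyfit(d[deep], e_point[deep], 1)[0]  # Pa per m
        rel_slope_per_um = slope / e_median * 1e-6
        substrate_flag = bool(rel_slope_per_um > rel_slope_threshold_per_um)
    return d, e_point, e_median, substrate_flag


def analyze_curve(
    curve: ForceCurve,
    delta_min: float = 100e-9,
    rel_slope_threshold_per_um: float = 0.2,
) -> ElasticityResult:
    """Full per-curve chain: contact point, Hertz fit, pointwise profile."""
    z0 = detect_contact_point(curve)
    e_fit, r2 = hertz_fit(curve, z0)
    d, e_point, e_median, flag = pointwise_modulus(
        curve, z0, delta_min=delta_min,
        rel_slope_threshold_per_um=rel_slope_threshold_per_um,
    )
    return ElasticityResult(
        contact_point=z0,
        e_fit=e_fit,
        fit_r2=r2,
        pointwise_delta=d,
        pointwise_e=e_point,
        e_median=e_median,
        substrate_flag=flag,
    )


@dataclass
class ElastographyMap:
    """Spatial grid of per-pixel elasticity results.

    Failed pixels hold NaN in the summary rasters and ``None`` in
    ``results``; they are reported, never interpolated.
    """

    shape: tuple[int, int]
    spacing: float  # m between adjacent pixels
    results: list[ElasticityResult | None]

    def __post_init__(self) -> None:
        if len(self.results) != self.shape[0] * self.shape[1]:
            raise ValueError(
                f"{len(self.results)} results do not fill grid {self.shape}"
            )

    def _raster(self, attr: str) -> np.ndarray:
        vals = [
            getattr(r, attr) if r is not None else np.nan for r in self.results
        ]
        return np.asarray(vals, dtype=float).reshape(self.shape)

    @property
    def e_fit_map(self) -> np.ndarray:
        return self._raster("e_fit")

    @property
    def e_median_map(self) -> np.ndarray:
        return self._raster("e_median")

    @property
    def n_failed(self) -> int:
        return sum(r is None for r in self.results)


def assemble_map(
    curves: list[ForceCurve],
    shape: tuple[int, int],
    spacing: float = 4e-6,
    delta_min: float = 100e-9,
    rel_slope_threshold_per_um: float = 0.2,
) -> ElastographyMap:
    """Analyze a grid of curves (row-major order) into an elastography map."""
    if len(curves) != shape[0] * shape[1]:
        raise ValueError(f"{len(curves)} curves do not fill grid {shape}")
    probes = {c.probe for c in curves}
    if len(probes) > 1:
        raise ValueError("curves in one map must share probe metadata")
    results: list[ElasticityResult | None] = []
    for c in curves:
        try:
            results.append(
                analyze_curve(
                    c, delta_min=delta_min,
                    rel_slope_threshold_per_um=rel_slope_threshold_per_um,
                )
            )
        except ValueError:
            results.append(None)
    return ElastographyMap(shape=shape, spacing=spacing, results=results)


def compare_group_elasticity(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA with Tukey HSD over per-cell median moduli by group.

    ``groups`` maps treatment label -> array of per-cell E_median values
    (>= 3 cells each).  Returns the ANOVA F and p plus Tukey-adjusted
    pairwise p-values keyed by label pair.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 treatment groups")
    labels = sorted(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    for g, a in zip(labels, arrays):
        if a.size < 3:
            raise ValueError(f"group {g!r} has < 3 cells")
    f_stat, p_value = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    pairwise = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairwise[(labels[i], labels[j])] = float(tukey.pvalue[i, j])
    return {
        "anova_f": float(f_stat),
        "anova_p": float(p_value),
        "tukey_p": pairwise,
        "group_means": {g: float(a.mean()) for g, a in zip(labels, arrays)},
    }


# --- on-disk layout: per-curve two-column text + one JSON metadata sidecar ---

def write_curves(directory, curves: list[ForceCurve], shape: tuple[int, int],
                 spacing: float = 4e-6) -> None:
    """Write curves as ``curve_####.txt`` (z in um, force in nN) + sidecar."""
    os.makedirs(directory, exist_ok=True)
    probe = curves[0].probe
    meta = {
        "n_curves": len(curves),
        "grid_shape": list(shape),
        "spacing_um": spacing * 1e6,
        "z_unit": "um",
        "force_unit": "nN",
        "spring_constant_N_per_m": probe.spring_constant,
        "tip_half_angle_deg": math.degrees(probe.tip_half_angle),
        "poisson_ratio": probe.poisson_ratio,
    }
    with open(os.path.join(directory, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    for i, c in enumerate(curves):
        np.savetxt(
            os.path.join(directory, f"curve_{i:04d}.txt"),
            np.column_stack([c.z * 1e6, c.force * 1e9]),
            header="z_um\tforce_nN", delimiter="\t",
        )


def read_curves(directory) -> tuple[list[ForceCurve], tuple[int, int], float]:
    """Read a curve directory written by :func:`write_curves`."""
    with open(os.path.join(directory, "meta.json")) as fh:
        meta = json.load(fh)
    probe = ProbeMetadata(
        spring_constant=meta["spring_constant_N_per_m"],
        tip_half_angle=math.radians(meta["tip_half_angle_deg"]),
        poisson_ratio=meta["poisson_ratio"],
    )
    curves = []
    for i in range(meta["n_curves"]):
        arr = np.loadtxt(os.path.join(directory, f"curve_{i:04d}.txt"))
        curves.append(ForceCurve(z=arr[:, 0] * 1e-6, force=arr[:, 1] * 1e-9,
                                 probe=probe))
    shape = tuple(meta["grid_shape"])
    return curves, shape, meta["spacing_um"] * 1e-6
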