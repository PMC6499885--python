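"""Four-parameter logistic dose-response fitting for viability assays.

Raw plate readings are normalized to the vehicle-control mean (percent
viability), then fitted with the four-parameter logistic (4PL)

    V(c) = bottom + (top - bottom) / (1 + (c / EC50)^hill),

parameterized internally in log10(EC50) and fitted on log concentration by
nonlinear least squares.  EC50s across biological replicates are summarized
by geometric mean and geometric SD, the natural statistics for a log-normal
quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseData",
    "FourPLFit",
    "normalize_viability",
    "fit_4pl",
    "four_pl",
    "summarize_ec50",
]


@dataclass
class DoseResponseData:
    """Viability plate: replicate responses per concentration + vehicle wells.

    ``responses`` has one row per concentration, one column per replicate.
    ``normalized`` marks whether responses are already percent-of-vehicle.
    """

    concentrations: np.ndarray  # nM, strictly positive, increasing
    responses: np.ndarray
    vehicle_wells: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be positive (nM)")
        if (np.diff(self.concentrations) <= 0).any():
            raise ValueError("concentrations must be strictly increasing")
        if self.responses.shape[0] != self.concentrations.size:
            raise ValueError("one response row per concentration required")
        if self.vehicle_wells is not None:
            self.vehicle_wells = np.asarray(self.vehicle_wells, dtype=float)


@dataclass
class FourPLFit:
    """Canonicalized 4PL parameters (top >= bottom, hill > 0 for decreasing
    response with dose when top is the low-dose asymptote)."""

    bottom: float
    top: float
    hill_slope: float
    ec50: float  # nM
    se: dict[str, float]
    converged: bool
    extrapolated_flag: bool
    r2: float


def four_pl(c, bottom, top, hill, ec50):
    """The 4PL law V(c) = bottom + (top - bottom)/(1 + (c/EC50)^hill)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ec50) ** hill)


def normalize_viability(data: DoseResponseData) -> DoseResponseData:
    """Express responses as percent of the vehicle-control mean."""
    if data.normalized:
        return data
    if data.vehicle_wells is None or data.vehicle_wells.size == 0:
        raise ValueError("no vehicle wells to normalize against")
    vehicle_mean = float(np.mean(data.vehicle_wells))
    if vehicle_mean <= 0:
        raise ValueError(f"vehicle mean must be positive, got {vehicle_mean:g}")
    return DoseResponseData(
        concentrations=data.concentrations,
        responses=data.responses / vehicle_mean * 100.0,
        vehicle_wells=data.vehicle_wells / vehicle_mean * 100.0,
        normalized=True,
    )


def _4pl_logx(logc, bottom, top, hill, log_ec50):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ec50)))


def fit_4pl(
    data: DoseResponseData,
    fix_top: float | None = None,
    fix_bottom: float | None = None,
) -> FourPLFit:
    """Nonlinear least-squares 4PL fit on log10 concentration.

    Initialization from data quartiles; log10(EC50) is bounded two decades
    beyond the tested range, and the fit is flagged as extrapolated when the
    fitted EC50 falls outside the tested concentrations.  Non-convergence is
    reported in the result, not raised.  ``fix_top``/``fix_bottom`` pin the
    asymptotes (e.g. top = 100 for vehicle-normalized viability).
    """
    if data.concentrations.size < 4:
        raise ValueError("a 4PL fit needs >= 4 distinct concentrations")
    logc = np.log10(np.repeat(data.concentrations, data.responses.shape[1]))
    y = data.responses.ravel()
    cmin, cmax = data.concentrations[0], data.concentrations[-1]

    # quartile-based initialization: asymptotes from the response extremes,
    # EC50 from the mid-response crossing, hill from the response direction
    y_by_conc = data.responses.mean(axis=1)
    top0 = float(np.max(y_by_conc))
    bot0 = float(np.min(y_by_conc))
    mid = 0.5 * (top0 + bot0)
    idx = int(np.argmin(np.abs(y_by_conc - mid)))
    log_ec50_0 = float(np.log10(data.concentrations[idx]))
    hill0 = 1.0 if y_by_conc[0] >= y_by_conc[-1] else -1.0

    span = max(top0 - bot0, 1.0)
    lo = [bot0 - 5 * span, top0 - 5 * span, -20.0, np.log10(cmin) - 2.0]
    hi = [bot0 + 5 * span, top0 + 5 * span, 20.0, np.log10(cmax) + 2.0]
    p0 = [bot0, top0, hill0, log_ec50_0]
    names = ["bottom", "top", "hill_slope", "log10_ec50"]

    if fix_bottom is not None:
        lo[0], hi[0], p0[0] = fix_bottom, fix_bottom + 1e-12, fix_bottom
    if fix_top is not None:
        lo[1], hi[1], p0[1] = fix_top, fix_top + 1e-12, fix_top

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                _4pl_logx, logc, y, p0=p0, bounds=(lo, hi), maxfev=20000
            )
    except RuntimeError:
        converged = False
        popt, pcov = np.array(p0), np.full((4, 4), np.nan)

    bottom, top, hill, log_ec50 = (float(v) for v in popt)
    perr = np.sqrt(np.diag(pcov))
    se = dict(zip(names, (float(s) for s in perr)))
    # canonical orientation: top is the larger asymptote; flipping the
    # asymptotes with hill -> -hill leaves the curve identical
    if top < bottom:
        bottom, top = top, bottom
        hill = -hill
        se["bottom"], se["top"] = se["top"], se["bottom"]
    ec50 = 10.0 ** log_ec50
    resid = y - _4pl_logx(logc, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return FourPLFit(
        bottom=bottom,
        top=top,
        hill_slope=hill,
        ec50=ec50,
        se=se,
        converged=converged,
        extrapolated_flag=bool(ec50 < cmin or ec50 > cmax),
        r2=r2,
    )


def summarize_ec50(fits: list[FourPLFit]) -> tuple[float, float]:
    """Geometric mean and geometric SD of converged replicate EC50s.

    geometric mean = exp(mean(log EC50)); geometric SD = exp(sd(log EC50))
    with the sample (n-1) standard deviation.
    """
    ec50s = np.array([f.ec50 for f in fits if f.converged], dtype=float)
    if ec50s.size < 2:
        raise ValueError("need >= 2 converged fits to summarize")
    if (ec50s <= 0).any():
        raise ValueError("EC50s must be positive")
    logs = np.log(ec50s)
    return float(np.exp(logs.mean())), float(np.exp(logs.std(ddof=1)))
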