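"""Dose-response analysis: Hill fits, EC50s, and low-dose linear trends.

Invasive area and maximum invasive distance are fitted with a
four-parameter decreasing Hill curve

    y(c) = bottom + (top - bottom) * EC50^h / (EC50^h + c^h)

by nonlinear least squares on per-dose means with multi-start EC50
initialization.  EC50 is the fitted half-maximal concentration between
the top and bottom asymptotes (standard Hill convention), not an
absolute-50%-reduction dose.  The Hill coefficient h is a free
parameter; a companion fit with h fixed at 1 is always reported for
comparison.  Roots and tips respond non-sigmoidally and are fitted
linearly on doses below a cutoff (default 500 nM) because higher doses
show offset effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .pipeline import PipelineError

__all__ = [
    "DoseResponseError",
    "DoseResponseSeries",
    "HillFit",
    "LinearFit",
    "hill_curve",
    "fit_hill",
    "ec50_ratio",
    "fit_linear_low_conc",
    "dose_response_pipeline",
]


class DoseResponseError(ValueError):
    """Invalid dose-response input or failed fit."""


@dataclass
class DoseResponseSeries:
    """Replicate metric values per concentration for one subtype."""

    metric_name: str
    subtype: str
    concentrations_nM: np.ndarray
    values: list  # one array of replicate values per concentration

    def __post_init__(self) -> None:
        self.concentrations_nM = np.asarray(self.concentrations_nM, dtype=float)
        if np.any(self.concentrations_nM < 0):
            raise DoseResponseError("concentrations must be >= 0")
        if len(self.values) != len(self.concentrations_nM):
            raise DoseResponseError("one replicate array per concentration required")

    def dose_means(self) -> np.ndarray:
        return np.array([float(np.mean(v)) for v in self.values])

    def dose_sems(self) -> np.ndarray:
        return np.array(
            [float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else np.nan for v in self.values]
        )


@dataclass
class HillFit:
    """Fitted Hill parameters; ``ec50_fixed_h1`` is the h=1 companion fit."""

    ec50_nM: float
    hill_coef: float
    top: float
    bottom: float
    rss: float
    r2: float
    converged: bool
    se: dict = field(default_factory=dict)
    ec50_fixed_h1: float | None = None


@dataclass
class LinearFit:
    """OLS line on dose means within the fit range."""

    slope_per_nM: float
    intercept: float
    upper_nM: float
    r2: float


def hill_curve(c, top, bottom, ec50, h, direction: str = "decreasing"):
    c = np.asarray(c, dtype=float)
    occ = c**h / (ec50**h + c**h)
    if direction == "decreasing":
        return bottom + (top - bottom) * (1.0 - occ)
    return bottom + (top - bottom) * occ


def _coerce_series(series, values=None, metric="metric", subtype="") -> DoseResponseSeries:
    if isinstance(series, DoseResponseSeries):
        return series
    conc = np.asarray(series, dtype=float)
    return DoseResponseSeries(metric_name=metric, subtype=subtype, concentrations_nM=conc, values=list(values))


def fit_hill(series, values=None, direction: str = "decreasing", r2_poor: float = 0.5) -> HillFit:
    """Nonlinear least-squares Hill fit on per-dose means.

    Accepts a :class:`DoseResponseSeries` or ``(concentrations, values)``.
    Requires >= 4 distinct concentrations.  EC50 starts span the
    observed concentration range (multi-start); the best converged fit
    is returned.  A fit with r^2 below ``r2_poor`` (e.g. data trending
    the wrong way) is flagged unconverged and reports no EC50.
    """
    s = _coerce_series(series, values)
    conc = s.concentrations_nM
    if len(np.unique(conc)) < 4:
        raise DoseResponseError("Hill fitting requires >= 4 distinct concentrations")
    y = s.dose_means()
    if not np.all(np.isfinite(y)):
        raise DoseResponseError("non-finite dose means")

    cpos = conc[conc > 0]
    lo, hi = float(cpos.min()), float(cpos.max())
    ymax, ymin = float(y.max()), float(y.min())
    yspan = max(ymax - ymin, 1e-12)
    # parameterize as (bottom, span) with span >= 0 so top >= bottom is
    # structural: data trending against `direction` cannot be absorbed
    # by swapping asymptotes and instead shows up as a poor fit.
    bounds = ([0.0, 0.0, lo / 50.0, 0.2], [ymax + 10 * yspan, 20 * yspan, hi * 50.0, 6.0])

    def model(c, bottom, span, ec50, h):
        return hill_curve(c, bottom + span, bottom, ec50, h, direction)

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        for ec50_0 in np.geomspace(lo, hi, 7):
            for h0 in (1.0, 2.0):
                try:
                    popt, pcov = curve_fit(
                        model,
                        conc,
                        y,
                        p0=[max(ymin, 1e-9), yspan, ec50_0, h0],
                        bounds=bounds,
                        maxfev=20000,
                    )
                except (RuntimeError, ValueError):
                    continue
                rss = float(np.sum((model(conc, *popt) - y) ** 2))
                if best is None or rss < best[0]:
                    best = (rss, popt, pcov)

    tss = float(np.sum((y - y.mean()) ** 2))
    if best is None:
        return HillFit(math.nan, math.nan, math.nan, math.nan, math.inf, -math.inf, False)
    rss, popt, pcov = best
    bottom, span, ec50, h = (float(v) for v in popt)
    top = bottom + span
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    se = {}
    if np.all(np.isfinite(pcov)):
        names = ("bottom", "span", "ec50_nM", "hill_coef")
        se = {n: float(math.sqrt(v)) if v >= 0 else math.nan for n, v in zip(names, np.diag(pcov))}
    converged = bool(r2 >= r2_poor)

    # companion fit with the Hill coefficient pinned at 1
    ec50_h1 = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt1, _ = curve_fit(
                lambda c, bottom, span, ec50: hill_curve(c, bottom + span, bottom, ec50, 1.0, direction),
                conc,
                y,
                p0=[max(ymin, 1e-9), yspan, math.sqrt(lo * hi)],
                bounds=([0.0, 0.0, lo / 50.0], [bounds[1][0], bounds[1][1], hi * 50.0]),
                maxfev=20000,
            )
        ec50_h1 = float(popt1[2])
    except (RuntimeError, ValueError):
        pass

    fit = HillFit(
        ec50_nM=ec50 if converged else math.nan,
        hill_coef=h,
        top=top,
        bottom=bottom,
        rss=rss,
        r2=r2,
        converged=converged,
        se=se,
        ec50_fixed_h1=ec50_h1,
    )
    return fit


def ec50_ratio(fit_a: HillFit, fit_b: HillFit) -> float:
    """EC50(a) / EC50(b); report to two decimals."""
    if not (fit_a.converged and fit_b.converged):
        raise DoseResponseError("EC50 ratio requires two converged fits")
    return fit_a.ec50_nM / fit_b.ec50_nM


def fit_linear_low_conc(series, values=None, upper_nM: float = 500.0) -> LinearFit:
    """OLS on dose means at concentrations <= ``upper_nM``.

    Doses above the cutoff are ignored entirely, so arbitrary
    perturbation there leaves the fit bit-identical.
    """
    s = _coerce_series(series, values)
    keep = s.concentrations_nM <= upper_nM
    conc = s.concentrations_nM[keep]
    if len(np.unique(conc)) < 3:
        raise DoseResponseError(f"need >= 3 distinct concentrations <= {upper_nM} nM")
    y = np.array([float(np.mean(v)) for v, k in zip(s.values, keep) if k])
    slope, intercept = np.polyfit(conc, y, 1)
    resid = y - (slope * conc + intercept)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
    return LinearFit(slope_per_nM=float(slope), intercept=float(intercept), upper_nM=upper_nM, r2=r2)


HILL_METRICS = ("invasive_area_um2", "max_invasive_distance_um")
LINEAR_METRICS = ("roots", "tips", "noninvasive_area_norm")


def dose_response_pipeline(measurements: pd.DataFrame, linear_upper_nM: float = 500.0) -> dict:
    """Per-subtype, per-metric dose-response report.

    ``measurements`` is long-format with columns ``subtype``,
    ``concentration_nM`` and one column per metric.  Hill fits are
    applied to the area/distance metrics, linear fits (below the
    cutoff, on values normalized to the zero-dose mean when a zero dose
    is present) to roots/tips and the normalized non-invasive area.
    With only a zero dose present, baselines are reported and no fits
    attempted.  Individual fit failures are recorded without aborting
    the other metrics.
    """
    required = {"subtype", "concentration_nM"}
    if not required <= set(measurements.columns):
        raise DoseResponseError(f"measurements must have columns {sorted(required)}")
    report: dict = {}
    for subtype, sub in measurements.groupby("subtype"):
        entry: dict = {"baselines": {}, "hill": {}, "linear": {}}
        concs = np.sort(sub["concentration_nM"].unique())
        zero = sub[sub["concentration_nM"] == 0]
        for metric in HILL_METRICS + LINEAR_METRICS:
            if metric not in sub.columns:
                continue
            if len(zero):
                entry["baselines"][metric] = float(zero[metric].mean())
            if len(concs[concs > 0]) == 0:
                continue
            groups = [sub.loc[sub["concentration_nM"] == c, metric].to_numpy() for c in concs]
            series = DoseResponseSeries(metric, str(subtype), concs, groups)
            try:
                if metric in HILL_METRICS:
                    entry["hill"][metric] = fit_hill(series)
                else:
                    if len(zero):
                        base = float(zero[metric].mean())
                        norm_vals = [v / base if base else v for v in groups]
                        series = DoseResponseSeries(metric, str(subtype), concs, norm_vals)
                    entry["linear"][metric] = fit_linear_low_conc(series, upper_nM=linear_upper_nM)
            except DoseResponseError as exc:
                entry.setdefault("failures", {})[metric] = str(exc)
        report[str(subtype)] = entry
    return report
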