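"""Time-resolved invasion quantification from intensity frames.

Brightfield time-lapse cannot be segmented into binary masks, so
dynamics are quantified as normalized intensity proxies: the
non-invasive signal inside a 100 um diameter circle centred on the
patternoid, the invasive signal over the XOR of that circle with a
larger ROI encompassing the whole structure, each divided by a
collagen-only background ROI per timepoint, and the invasive series
baseline-corrected at 3 h so replicates start from a common origin.
Subtype-specific trends are tested with a linear mixed-effects model
(Time x Subtype fixed effects, replicate random intercept).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import PixelCalibration
from .pipeline import PipelineError

__all__ = [
    "RoiSpec",
    "TimeSeriesRecord",
    "roi_timeseries",
    "background_normalize",
    "baseline_correct",
    "align_frames",
    "fit_longitudinal_trend",
]


@dataclass(frozen=True)
class RoiSpec:
    """Concentric measurement ROIs for one replicate.

    ``outer_radius_factor`` scales the inner radius to the circle
    "encompassing the entire structure" (default 3x); the background
    ROI must not overlap the outer circle.
    """

    center_px: tuple[float, float]
    cal: PixelCalibration
    inner_diameter_um: float = 100.0
    outer_radius_factor: float = 3.0
    background_center_px: tuple[float, float] = (0.0, 0.0)
    background_radius_um: float = 25.0

    def __post_init__(self) -> None:
        if self.inner_diameter_um <= 0 or self.outer_radius_factor <= 1:
            raise PipelineError("need inner_diameter_um > 0 and outer_radius_factor > 1")
        inner_r = self.inner_diameter_um / 2
        outer_r = inner_r * self.outer_radius_factor
        d_um = (
            math.hypot(
                self.background_center_px[0] - self.center_px[0],
                self.background_center_px[1] - self.center_px[1],
            )
            * self.cal.pixel_size_um
        )
        if d_um < outer_r + self.background_radius_um:
            raise PipelineError("background ROI overlaps the structure ROI")


@dataclass
class TimeSeriesRecord:
    """Normalized longitudinal signals of one replicate."""

    replicate_id: str
    subtype: str
    times_h: np.ndarray
    noninv_rel: np.ndarray
    inv_rel: np.ndarray
    background_mean: np.ndarray
    roi_spec: RoiSpec | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise PipelineError("times must be strictly ascending")
        for arr in (self.noninv_rel, self.inv_rel, self.background_mean):
            if not np.all(np.isfinite(np.asarray(arr, dtype=float))):
                raise PipelineError("signals must be finite")


def _disk_mask(shape, center, radius_px):
    cy, cx = center[1], center[0]
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2


def roi_timeseries(frames, spec: RoiSpec) -> pd.DataFrame:
    """Raw inner / invasive-annulus / background mean intensities per frame.

    The invasive signal is measured over outer XOR inner (for nested
    circles, the annulus between them).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    shape = frames.shape[1:]
    px = spec.cal.pixel_size_um
    inner_r = spec.inner_diameter_um / 2 / px
    outer_r = inner_r * spec.outer_radius_factor
    cx, cy = spec.center_px
    if cx - outer_r < -0.5 or cy - outer_r < -0.5 or cx + outer_r > shape[1] - 0.5 or cy + outer_r > shape[0] - 0.5:
        raise PipelineError("outer ROI extends beyond the frame")
    inner = _disk_mask(shape, spec.center_px, inner_r)
    outer = _disk_mask(shape, spec.center_px, outer_r)
    annulus = outer ^ inner
    bg = _disk_mask(shape, spec.background_center_px, spec.background_radius_um / px)
    if not bg.any():
        raise PipelineError("background ROI contains no pixels")
    rows = [
        {
            "frame": i,
            "inner_mean": float(f[inner].mean()),
            "invasive_mean": float(f[annulus].mean()),
            "background_mean": float(f[bg].mean()),
        }
        for i, f in enumerate(frames)
    ]
    return pd.DataFrame(rows)


def background_normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Divide each ROI signal by its timepoint's background mean."""
    if np.any(raw["background_mean"] <= 0):
        raise PipelineError("background mean must be > 0 at every timepoint")
    out = raw.copy()
    out["noninv_rel"] = raw["inner_mean"] / raw["background_mean"]
    out["inv_rel"] = raw["invasive_mean"] / raw["background_mean"]
    return out


def baseline_correct(times_h, values, baseline_time_h: float = 3.0, tol_h: float = 1.0):
    """Subtract the value at the timepoint nearest ``baseline_time_h``.

    The nearest timepoint must lie within ``tol_h``; the corrected
    series is zero at the baseline and the operation is idempotent up
    to that shared offset.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    i = int(np.argmin(np.abs(t - baseline_time_h)))
    if abs(t[i] - baseline_time_h) > tol_h:
        raise PipelineError(
            f"no timepoint within {tol_h} h of the {baseline_time_h} h baseline (nearest: {t[i]} h)"
        )
    return v - v[i]


def align_frames(frames) -> np.ndarray:
    """Estimated rigid translation of each frame relative to the first.

    Uses cross-correlation based registration; callers may shift their
    ROI centres by the returned per-frame ``(dx, dy)`` (fixed-ROI
    fallback: ignore the estimate).
    """
    from skimage.registration import phase_cross_correlation

    frames = np.asarray(frames, dtype=float)
    ref = frames[0]
    shifts = [(0.0, 0.0)]
    for f in frames[1:]:
        (dy, dx), _, _ = phase_cross_correlation(ref, f, upsample_factor=4)
        shifts.append((float(-dx), float(-dy)))
    return np.asarray(shifts)


def fit_longitudinal_trend(records, value_col: str = "noninv_rel") -> dict:
    """Linear mixed-effects model of a longitudinal signal.

    ``records`` is a long-format DataFrame (or list of
    :class:`TimeSeriesRecord`) with columns ``replicate``, ``subtype``,
    ``time_h`` and the value column.  Fixed effects: Time, Subtype and
    their interaction; random intercept per replicate.  Returns
    per-subtype slopes, interaction contrasts vs the reference subtype
    with p-values, and baseline (intercept) contrasts.
    """
    import statsmodels.formula.api as smf

    if not isinstance(records, pd.DataFrame):
        frames = []
        for r in records:
            frames.append(
                pd.DataFrame(
                    {
                        "replicate": r.replicate_id,
                        "subtype": r.subtype,
                        "time_h": r.times_h,
                        "noninv_rel": r.noninv_rel,
                        "inv_rel": r.inv_rel,
                    }
                )
            )
        records = pd.concat(frames, ignore_index=True)
    subtypes = sorted(records["subtype"].unique())
    if len(subtypes) < 2:
        raise PipelineError("need >= 2 subtypes for a subtype-trend contrast")
    counts = records.groupby("subtype")["replicate"].nunique()
    if (counts < 2).any():
        raise PipelineError(f"need >= 2 replicates per subtype; got {counts.to_dict()}")
    if records.groupby("replicate")["time_h"].nunique().min() < 3:
        raise PipelineError("need >= 3 timepoints per replicate")

    data = records.rename(columns={value_col: "y"})[["replicate", "subtype", "time_h", "y"]]
    fit = None
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("y ~ time_h * C(subtype)", data, groups=data["replicate"])
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                fit = model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError as exc:
                last_exc = exc
    if fit is None:
        raise PipelineError(
            "singular mixed-model design (no between-replicate variation or collinear factors)"
        ) from last_exc
    ref = subtypes[0]
    slopes = {ref: float(fit.params["time_h"])}
    interactions = {}
    baselines = {}
    for s in subtypes[1:]:
        term = f"time_h:C(subtype)[T.{s}]"
        base = f"C(subtype)[T.{s}]"
        slopes[s] = slopes[ref] + float(fit.params[term])
        interactions[s] = {"estimate": float(fit.params[term]), "p": float(fit.pvalues[term])}
        baselines[s] = {"estimate": float(fit.params[base]), "p": float(fit.pvalues[base])}
    return {
        "reference_subtype": ref,
        "slopes_per_h": slopes,
        "interaction_vs_reference": interactions,
        "baseline_vs_reference": baselines,
        "random_intercept_var": float(fit.cov_re.iloc[0, 0]),
        "residual_var": float(fit.scale),
        "converged": bool(fit.converged),
        "n_obs": int(len(data)),
    }
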