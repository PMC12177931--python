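"""Synthetic patternoid data with known ground truth.

The assay's microscopy data are not publicly deposited, so this module
generates inputs carrying the statistical structure the analysis
assumes: Poisson seeding counts per microcavity, branched invasion
masks whose roots/tips/branching factor/maximum distance are fixed by
construction, noisy grayscale renderings, 72 h area trajectories, and
dose-response cohorts following a decreasing Hill law.

Subtype profiles are parameterized from the published per-subtype
statistics where printed (roots, branching factor, maximum invasive
distance for the mesenchymal line, invasive-area moments) and from
field-plausible choices elsewhere; see ``docs/methods.md``.  The
invasive-area law is log-normal: the reported SD exceeds the mean,
indicating strong right skew, and a normal law would produce negative
areas.

All generators are reproducible given (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .geometry import ArrayLayout, CavityGeometry, GeometryError, PixelCalibration
from .morphometry import InvasionMetrics
from .pipeline import PatternoidMask

__all__ = [
    "SubtypeProfile",
    "DoseResponseTruth",
    "SUBTYPES",
    "E_9591",
    "MLOW_8028",
    "M_16992",
    "simulate_seeding",
    "generate_patternoid_mask",
    "render_intensity",
    "generate_timeseries",
    "generate_dose_response_cohort",
    "generate_overview_scan",
    "DEFAULT_QC_RATES",
]

# Minimum branch-segment length in um; keeps real tips well clear of the
# 10 um skeleton-spur pruning threshold used downstream.
_MIN_SEG_UM = 25.0


@dataclass(frozen=True)
class SubtypeProfile:
    """Morphological and kinetic parameters of one PDAC subtype.

    Roots and maximum invasive distance are drawn from (rounded/clipped)
    normal laws, the branching factor from a normal clipped at 1, and
    the invasive area from a log-normal.
    """

    name: str
    roots_mean: float
    roots_sd: float
    branching_factor_mean: float
    branching_factor_sd: float
    max_distance_mean_um: float
    max_distance_sd_um: float
    invasive_area_logmean: float
    invasive_area_logsd: float
    noninv_area_norm_mean: float
    branch_width_um: float
    growth_rate_r: float
    noninv_plateau_frac: float
    invasion_onset_h: float
    noninv_area_norm_sd: float = 0.05
    noninv_tau_h: float = 20.0
    noninv_baseline_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.roots_mean < 0 or self.roots_sd < 0:
            raise GeometryError("root statistics must be >= 0")
        if self.branching_factor_mean < 1:
            raise GeometryError("branching_factor_mean must be >= 1")
        if self.branching_factor_sd < 0 or self.max_distance_sd_um < 0:
            raise GeometryError("spreads must be >= 0")
        for f in (self.noninv_area_norm_mean, self.noninv_plateau_frac, self.noninv_baseline_frac):
            if not 0 <= f <= 1:
                raise GeometryError("fractions must lie in [0, 1]")


# Epithelial subtype: many evenly spaced, barely branched, short protrusions;
# largest non-invasive (cavity-filling) area; late, confinement-triggered
# invasion onset.
E_9591 = SubtypeProfile(
    name="E-9591",
    roots_mean=7.5,
    roots_sd=3.725,
    branching_factor_mean=1.56,
    branching_factor_sd=0.507,
    max_distance_mean_um=150.0,
    max_distance_sd_um=50.0,
    invasive_area_logmean=7.5,
    invasive_area_logsd=1.0,
    noninv_area_norm_mean=0.90,
    branch_width_um=6.0,
    growth_rate_r=0.025,
    noninv_plateau_frac=0.90,
    noninv_tau_h=29.0,
    invasion_onset_h=38.0,
)

# Hybrid EMT subtype: few thick collective strands, low branching,
# intermediate reach; slowest cavity expansion, plateauing around 40%.
MLOW_8028 = SubtypeProfile(
    name="Mlow-8028",
    roots_mean=4.15,
    roots_sd=2.492,
    branching_factor_mean=1.61,
    branching_factor_sd=0.530,
    max_distance_mean_um=250.0,
    max_distance_sd_um=85.0,
    invasive_area_logmean=8.0,
    invasive_area_logsd=1.3,
    noninv_area_norm_mean=0.70,
    branch_width_um=12.0,
    growth_rate_r=0.015,
    noninv_plateau_frac=0.40,
    noninv_tau_h=8.5,
    invasion_onset_h=27.0,
)

# Mesenchymal subtype: thin fractal branches, high branching factor,
# deepest reach, heavy-tailed invasive area; early unconfined invasion.
M_16992 = SubtypeProfile(
    name="M-16992",
    roots_mean=4.8,
    roots_sd=1.699,
    branching_factor_mean=3.15,
    branching_factor_sd=0.965,
    max_distance_mean_um=379.7,
    max_distance_sd_um=96.1,
    invasive_area_logmean=8.605,
    invasive_area_logsd=1.720,
    noninv_area_norm_mean=0.55,
    branch_width_um=5.0,
    growth_rate_r=0.018,
    noninv_plateau_frac=0.55,
    noninv_tau_h=20.0,
    invasion_onset_h=8.0,
)

SUBTYPES = {p.name: p for p in (E_9591, MLOW_8028, M_16992)}


@dataclass(frozen=True)
class DoseResponseTruth:
    """Ground-truth decreasing Hill law for dose-response cohorts."""

    ec50_nM: float
    hill_coef: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    noise_cv: float = 0.10

    def __post_init__(self) -> None:
        if not self.ec50_nM > 0 or not self.hill_coef > 0:
            raise GeometryError("ec50_nM and hill_coef must be > 0")
        if not (self.top >= self.bottom >= 0):
            raise GeometryError("need top >= bottom >= 0")

    def expected(self, conc_nM) -> np.ndarray:
        """Mean response at the given concentration(s)."""
        c = np.asarray(conc_nM, dtype=float)
        e = self.ec50_nM**self.hill_coef
        return self.bottom + (self.top - self.bottom) * e / (e + c**self.hill_coef)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_seeding(layout: ArrayLayout, mean_cells: float, seed) -> np.ndarray:
    """I.i.d. Poisson starting cell counts, one per cavity (row-major)."""
    if mean_cells < 0:
        raise GeometryError(f"mean_cells must be >= 0, got {mean_cells}")
    return _rng(seed).poisson(mean_cells, size=layout.n_cavities)


# ---------------------------------------------------------------------------
# Branched mask construction


def _plan_tips(rng: np.random.Generator, roots: int, bf: float) -> np.ndarray:
    """Tips per root: every root gets one, the excess is spread randomly."""
    total = max(roots, int(round(bf * roots)))
    alloc = np.ones(roots, dtype=int)
    extra = total - roots
    if extra > 0:
        alloc += rng.multinomial(extra, np.full(roots, 1.0 / roots))
    return alloc


def _grow_tree(start, tips, segments):
    """Recursive bifurcating tree toward pre-planned tip positions.

    ``start`` is the parent node in polar (r, theta); ``tips`` is a
    list of (r, theta) sorted by angle.  The tree splits by angle at
    each bifurcation, so sibling subtrees never cross.  Appends
    straight node-to-node segments to ``segments``.
    """
    k = len(tips)
    if k == 1:
        r_tip = max(tips[0][0], start[0] + _MIN_SEG_UM)
        segments.append((start, (r_tip, tips[0][1])))
        return
    depth = math.ceil(math.log2(k))
    room = min(r for r, _ in tips) - start[0]
    seg = max(8.0, min(_MIN_SEG_UM * 1.5, room / (depth + 1)))
    theta_mean = sum(t for _, t in tips) / k
    node = (start[0] + seg, theta_mean)
    segments.append((start, node))
    k1 = (k + 1) // 2
    _grow_tree(node, tips[:k1], segments)
    _grow_tree(node, tips[k1:], segments)


def _paint_mask(segments, r_disk_um, radius_um, width_um, cal):
    """Rasterize disk + branch strokes; returns pixels and centre.

    Strokes are capsules (rounded-cap thick segments) rasterized with
    sub-pixel accuracy, so the stroke width in um is calibration
    independent.
    """
    px = cal.pixel_size_um
    half = int(math.ceil(radius_um / px)) + 2
    n = 2 * half + 1
    c = float(half)
    yy, xx = np.mgrid[0:n, 0:n]
    dist_um = np.hypot(xx - c, yy - c) * px
    pixels = dist_um <= r_disk_um

    half_w = (width_um / 2.0) / px
    pad = int(math.ceil(half_w)) + 1
    for (r0, t0), (r1, t1) in segments:
        p = np.array([c + r0 * math.cos(t0) / px, c + r0 * math.sin(t0) / px])
        q = np.array([c + r1 * math.cos(t1) / px, c + r1 * math.sin(t1) / px])
        x0 = max(int(math.floor(min(p[0], q[0]))) - pad, 0)
        x1 = min(int(math.ceil(max(p[0], q[0]))) + pad, n - 1)
        y0 = max(int(math.floor(min(p[1], q[1]))) - pad, 0)
        y1 = min(int(math.ceil(max(p[1], q[1]))) + pad, n - 1)
        gy, gx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
        d = q - p
        len2 = float(d @ d)
        if len2 == 0:
            dist2 = (gx - p[0]) ** 2 + (gy - p[1]) ** 2
        else:
            t = ((gx - p[0]) * d[0] + (gy - p[1]) * d[1]) / len2
            t = np.clip(t, 0.0, 1.0)
            dist2 = (gx - (p[0] + t * d[0])) ** 2 + (gy - (p[1] + t * d[1])) ** 2
        pixels[y0 : y1 + 1, x0 : x1 + 1] |= dist2 <= half_w * half_w
    return pixels, (c, c)


def generate_patternoid_mask(
    profile: SubtypeProfile,
    geometry: CavityGeometry | None = None,
    cal: PixelCalibration | None = None,
    seed=0,
) -> tuple[PatternoidMask, InvasionMetrics]:
    """One synthetic patternoid mask plus its exact construction truth.

    The mask is a filled central disk (non-invasive body, radius set by
    the drawn normalized non-invasive area) plus ``roots`` bifurcating
    branch trees grown outward from well-separated boundary anchors.
    Total tips realise the drawn branching factor; the deepest tip ends
    at the drawn maximum invasive distance beyond the boundary (painting
    compensates for the stroke cap so the rasterized extent matches).

    Returns the mask and the ground-truth :class:`InvasionMetrics`
    realized by construction (areas are exact pixel counts of the
    painted mask).
    """
    geometry = geometry or CavityGeometry()
    cal = cal or PixelCalibration(2.27)
    rng = _rng(seed)
    R = geometry.radius_um
    px = cal.pixel_size_um

    norm = float(np.clip(rng.normal(profile.noninv_area_norm_mean, profile.noninv_area_norm_sd), 0.05, 1.0))
    r_disk = R * math.sqrt(norm)

    roots = int(np.clip(np.rint(rng.normal(profile.roots_mean, profile.roots_sd)), 0, None))
    # cap so adjacent boundary crossings stay resolvable at this width
    cap = max(1, int(2 * math.pi * R / (profile.branch_width_um + 4 * px)))
    roots = min(roots, cap)

    segments: list = []
    tips_total = 0
    dist_truth = 0.0
    if roots > 0:
        # branching factor >= 1 by definition (every root carries at least
        # one tip): a shifted gamma matches the profile mean and SD exactly
        # without the truncation bias a clipped normal would introduce
        bf_mu, bf_sd = profile.branching_factor_mean, profile.branching_factor_sd
        if bf_sd == 0 or bf_mu <= 1:
            bf = max(1.0, bf_mu)
        else:
            shape = ((bf_mu - 1.0) / bf_sd) ** 2
            scale = bf_sd**2 / (bf_mu - 1.0)
            bf = 1.0 + rng.gamma(shape, scale)
        alloc = _plan_tips(rng, roots, bf)
        tips_total = int(alloc.sum())
        D = float(max(3 * _MIN_SEG_UM, rng.normal(profile.max_distance_mean_um, profile.max_distance_sd_um)))
        dist_truth = D

        cap_comp = profile.branch_width_um / 2.0  # rounded stroke cap extent past the tip node
        d_max_eff = R + D - cap_comp

        theta0 = rng.uniform(0, 2 * math.pi)
        sector = 2 * math.pi / roots
        root_order = rng.permutation(roots)
        deep_root = int(root_order[0])  # carries the deepest tip
        # every tree runs an unbranched trunk past the root-counting
        # annulus before its first bifurcation, so one tree = one crossing
        trunk_r = R + 3 * px + profile.branch_width_um / 2 + 3.0
        for i in range(roots):
            theta_i = theta0 + i * sector + rng.uniform(-0.08, 0.08) * sector
            k = int(alloc[i])
            depth = math.ceil(math.log2(k)) if k > 1 else 0
            start_r = max(1.0, r_disk - 2 * px)
            min_tip = trunk_r + _MIN_SEG_UM * (depth + 1)
            tip_rs = R + rng.uniform(0.45, 0.90, size=k) * D - cap_comp
            tip_rs = np.clip(tip_rs, min_tip, d_max_eff)
            if i == deep_root:
                tip_rs[int(rng.integers(k))] = max(d_max_eff, min_tip)
            # evenly spaced tip slots across the root's sector keep
            # sibling tips resolvable after rasterization
            span = 0.72 * sector
            if k == 1:
                thetas = np.array([theta_i + rng.uniform(-0.2, 0.2) * span])
            else:
                slot = span / (k - 1)
                thetas = theta_i - span / 2 + slot * np.arange(k) + rng.uniform(-0.15, 0.15, size=k) * slot
            tips = sorted(zip(tip_rs, thetas), key=lambda t: t[1])
            trunk_end = (trunk_r, theta_i)
            segments.append(((start_r, theta_i), trunk_end))
            _grow_tree(trunk_end, tips, segments)
        # the realized depth: farthest node plus the painted stroke cap
        max_node_r = max(max(a[0], b[0]) for a, b in segments)
        dist_truth = max_node_r + cap_comp - R

    canvas_r = R + dist_truth + profile.branch_width_um + 10.0
    pixels, center = _paint_mask(segments, r_disk, canvas_r, profile.branch_width_um, cal)
    mask = PatternoidMask(pixels=pixels, cal=cal, cavity_center_px=center, cavity_radius_um=R)

    dist = mask.radial_distance_um()
    inside = dist <= R
    px_area = px * px
    noninv = float(np.count_nonzero(pixels & inside)) * px_area
    inv = float(np.count_nonzero(pixels & ~inside)) * px_area
    truth = InvasionMetrics(
        invasive_area_um2=inv,
        noninvasive_area_um2=noninv,
        noninvasive_area_norm=noninv / geometry.projected_area_um2,
        max_invasive_distance_um=dist_truth if roots > 0 else 0.0,
        roots=roots,
        tips=tips_total,
    )
    return mask, truth


def render_intensity(mask: PatternoidMask, snr: float, n_slices: int = 5, seed=0):
    """Grayscale 3D stack whose max-projection recovers the mask support.

    Each foreground pixel is assigned to one random slice.  SNR is the
    foreground excess over background divided by the noise SD (unit SD,
    background offset 5 keeps intensities non-negative).  ``snr=inf``
    renders noiselessly (0/1 values).
    """
    if not snr > 0:
        raise GeometryError("snr must be > 0")
    if n_slices < 1:
        raise GeometryError("n_slices must be >= 1")
    rng = _rng(seed)
    h, w = mask.pixels.shape
    fg = np.argwhere(mask.pixels)
    stack = np.zeros((n_slices, h, w), dtype=float)
    slice_of = rng.integers(n_slices, size=len(fg))
    if not math.isfinite(snr):
        stack[slice_of, fg[:, 0], fg[:, 1]] = 1.0
        return stack
    background = 5.0
    stack += rng.normal(background, 1.0, size=stack.shape)
    stack[slice_of, fg[:, 0], fg[:, 1]] += snr
    return np.clip(stack, 0.0, None)


def generate_timeseries(
    profile: SubtypeProfile, t_grid, seed=0, noise_sd: float = 0.01, baseline_sd: float = 0.02
):
    """Non-invasive fraction and invasive area over time, true and noisy.

    The non-invasive fraction follows a saturating-growth curve
    ``b + (plateau - b) * (1 - exp(-t/tau))``; the invasive area is zero
    before the subtype's invasion onset and then grows monotonically
    toward the subtype's mean area.  The observed columns add a
    replicate-level baseline offset (SD ``baseline_sd``, the
    between-replicate variability a mixed model absorbs as its random
    intercept) plus per-timepoint Gaussian noise; the ``*_true``
    columns stay noiseless.
    """
    import pandas as pd

    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise GeometryError("t_grid must be strictly ascending")
    if t[0] < 0 or t[-1] > 72:
        raise GeometryError("t_grid must lie within [0, 72] h")
    rng = _rng(seed)
    b, plateau, tau = profile.noninv_baseline_frac, profile.noninv_plateau_frac, profile.noninv_tau_h
    noninv_true = b + (plateau - b) * (1.0 - np.exp(-t / tau))
    a72 = math.exp(profile.invasive_area_logmean)
    onset = profile.invasion_onset_h
    rel = np.clip(t - onset, 0.0, None) / max(72.0 - onset, 1e-9)
    inv_true = a72 * rel**1.5
    offset = rng.normal(0.0, baseline_sd) if baseline_sd > 0 else 0.0
    noninv_obs = noninv_true + offset + rng.normal(0.0, noise_sd, size=t.shape)
    inv_obs = inv_true + offset * a72 + rng.normal(0.0, noise_sd * a72, size=t.shape)
    return pd.DataFrame(
        {
            "time_h": t,
            "noninv_frac_true": noninv_true,
            "noninv_frac": noninv_obs,
            "inv_area_true": inv_true,
            "inv_area": inv_obs,
        }
    )


def generate_dose_response_cohort(
    profile: SubtypeProfile,
    truth: DoseResponseTruth,
    concentrations_nM,
    n_per_dose: int,
    seed=0,
    metric_name: str = "invasive_area_um2",
):
    """Per-replicate metric values per dose under the decreasing Hill law.

    Noise is multiplicative log-normal with the truth's CV, scaled to
    unit mean so the expected response equals the Hill curve exactly.
    """
    import pandas as pd

    conc = np.asarray(concentrations_nM, dtype=float)
    if np.any(conc < 0):
        raise GeometryError("concentrations must be >= 0")
    rng = _rng(seed)
    sigma2 = math.log(1.0 + truth.noise_cv**2)
    sigma = math.sqrt(sigma2)
    rows = []
    for c in conc:
        mu = truth.expected(c)
        noise = np.exp(rng.normal(-sigma2 / 2.0, sigma, size=n_per_dose))
        for j, v in enumerate(mu * noise):
            rows.append({"subtype": profile.name, "concentration_nM": c, "replicate": j, "metric": metric_name, "value": v})
    return pd.DataFrame(rows)


DEFAULT_QC_RATES = {
    "agglomeration_d0": 0.20,
    "excess_cells_d0": 0.20,
    "invasive_at_drug_add_d1": 0.05,
    "staining_failure_d3": 0.05,
    "conjoined_d3": 0.10,
    "planar_growth_d3": 0.10,
    "collapsed_d3": 0.05,
}


def generate_overview_scan(
    layout: ArrayLayout,
    counts,
    qc_defect_rates: dict | None = None,
    seed=0,
    cal: PixelCalibration | None = None,
):
    """Day-0 overview image of the whole array plus the ground-truth table.

    Each cavity is rendered with its count of cell-sized dots;
    independent defects are injected at the given per-record rates and
    recorded as ground-truth QC flags.  Returns ``(image, records)``
    where ``records`` is a DataFrame with one row per cavity.
    """
    import pandas as pd

    from .geometry import array_centers

    counts = np.asarray(counts, dtype=int)
    if counts.shape != (layout.n_cavities,):
        raise GeometryError("counts length must equal rows*cols")
    rates = dict(DEFAULT_QC_RATES if qc_defect_rates is None else qc_defect_rates)
    cal = cal or PixelCalibration(10.0)
    rng = _rng(seed)

    px = cal.pixel_size_um
    centers = array_centers(layout)
    margin = layout.cavity.pitch_um / 2.0
    w = int((centers[:, 0].max() + margin) / px) + 1
    h = int((centers[:, 1].max() + margin) / px) + 1
    image = rng.normal(5.0, 1.0, size=(h, w)).clip(0)

    r_px = layout.cavity.radius_um / px
    cell_r = max(1, int(round(6.0 / px)))  # ~12 um cells
    rows = []
    for i, ((cx_um, cy_um), c0) in enumerate(zip(centers + margin, counts)):
        cx, cy = cx_um / px, cy_um / px
        flags = {flag: bool(rng.random() < rate) for flag, rate in rates.items()}
        if flags.get("agglomeration_d0"):
            _stamp_disk(image, cx, cy, 2 * cell_r, 30.0)
        else:
            for _ in range(int(c0)):
                ang = rng.uniform(0, 2 * math.pi)
                rad = math.sqrt(rng.random()) * max(r_px - cell_r, 0.0)
                _stamp_disk(image, cx + rad * math.cos(ang), cy + rad * math.sin(ang), cell_r, 20.0)
        if flags.get("excess_cells_d0"):
            for _ in range(3):
                ang = rng.uniform(0, 2 * math.pi)
                rad = r_px * rng.uniform(1.5, 2.5)
                _stamp_disk(image, cx + rad * math.cos(ang), cy + rad * math.sin(ang), cell_r, 20.0)
        rows.append(
            {
                "id": f"P{i:04d}",
                "row": i // layout.cols,
                "col": i % layout.cols,
                "c0": int(c0),
                **{k: int(v) for k, v in flags.items()},
            }
        )
    return image, pd.DataFrame(rows)


def _stamp_disk(image, cx, cy, r, value):
    h, w = image.shape
    x0, x1 = max(int(cx - r), 0), min(int(cx + r) + 1, w)
    y0, y1 = max(int(cy - r), 0), min(int(cy + r) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    image[y0:y1, x0:x1][inside] += value


def profile_to_dict(profile: SubtypeProfile) -> dict:
    """Serializable echo of a profile for sidecar configs."""
    return asdict(profile)
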