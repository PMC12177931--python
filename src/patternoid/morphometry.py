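"""Invasive morphometrics on binary patternoid masks.

Five parameters are extracted per patternoid: invasive area (cell
area beyond the cavity boundary), non-invasive area (cell area inside
the cavity) and its fraction of the 7854 um^2 projected cavity area,
maximum invasive distance (deepest penetration beyond the boundary),
and the numbers of invasive roots and tips whose ratio defines the
branching factor.

Algorithmic choices (the assay literature defines these parameters
only operationally):

* 8-connectivity is used everywhere.
* Roots are counted as distinct boundary crossings: connected
  components of the mask within a thin annulus just outside the
  boundary circle that also reach beyond the annulus.  Placing the
  band outside the boundary keeps the cavity-filling cell mass from
  ring-connecting all crossings.
* Tips are endpoints (exactly one neighbour) of the pruned topological
  skeleton, outside the cavity.  Spurs shorter than ``min_branch_um``
  (default 10 um, well below one cell diameter) are pruned as thinning
  artifacts.
* The maximum invasive distance is measured from the cavity *boundary*
  (distance from centre minus radius); measurement from the centre is
  available via ``from_boundary=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import label
from skimage.morphology import skeletonize

from .pipeline import PatternoidMask, PipelineError

__all__ = [
    "InvasionMetrics",
    "measure_areas",
    "max_invasive_distance",
    "skeletonize_and_prune",
    "count_roots",
    "count_tips",
    "measure_invasion",
    "build_heatmap",
    "DEFAULT_MIN_BRANCH_UM",
]

DEFAULT_MIN_BRANCH_UM = 10.0


@dataclass
class InvasionMetrics:
    """The five extracted invasive parameters of one patternoid.

    ``branching_factor`` is tips/roots and is NaN (undefined) when
    ``roots == 0``; undefined ratios are excluded from cohort means
    rather than set to zero.
    """

    invasive_area_um2: float
    noninvasive_area_um2: float
    noninvasive_area_norm: float
    max_invasive_distance_um: float
    roots: int
    tips: int

    @property
    def branching_factor(self) -> float:
        if self.roots == 0:
            return float("nan")
        return self.tips / self.roots


def _check_mask(mask: PatternoidMask) -> None:
    if not isinstance(mask, PatternoidMask):
        raise PipelineError("expected a PatternoidMask with cavity metadata")


def measure_areas(mask: PatternoidMask) -> tuple[float, float, float]:
    """(invasive, non-invasive, normalized non-invasive) areas.

    Non-invasive area counts true pixels whose centre lies inside the
    cavity circle; invasive area counts true pixels outside.  The
    normalized value divides by the projected cavity area pi*r^2.
    """
    _check_mask(mask)
    dist = mask.radial_distance_um()
    px_area = mask.cal.pixel_size_um**2
    inside = dist <= mask.cavity_radius_um
    noninv = float(np.count_nonzero(mask.pixels & inside)) * px_area
    inv = float(np.count_nonzero(mask.pixels & ~inside)) * px_area
    proj = math.pi * mask.cavity_radius_um**2
    return inv, noninv, noninv / proj


def max_invasive_distance(mask: PatternoidMask, from_boundary: bool = True) -> float:
    """Deepest penetration of the mask beyond the cavity boundary, in um.

    Zero when no mask pixel lies outside the cavity.
    """
    _check_mask(mask)
    dist = mask.radial_distance_um()
    outside = mask.pixels & (dist > mask.cavity_radius_um)
    if not outside.any():
        return 0.0
    d = float(dist[outside].max())
    return d - mask.cavity_radius_um if from_boundary else d


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    from scipy import ndimage as ndi

    return ndi.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")


def skeletonize_and_prune(
    mask_pixels: np.ndarray,
    min_branch_um: float = DEFAULT_MIN_BRANCH_UM,
    pixel_size_um: float = 1.0,
) -> np.ndarray:
    """Topology-preserving thinning with removal of short terminal spurs.

    A spur is a path from an endpoint to the nearest junction; spurs
    shorter than ``min_branch_um`` are deleted (isolated short segments
    with no junction are kept -- they are branches, not artifacts).
    """
    skel = skeletonize(np.asarray(mask_pixels, dtype=bool))
    min_px = int(math.floor(min_branch_um / pixel_size_um))
    if min_px < 1:
        return skel
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    changed = True
    while changed:
        changed = False
        counts = _neighbor_counts(skel)
        endpoints = np.argwhere(skel & (counts == 1))
        for ey, ex in endpoints:
            if not skel[ey, ex]:
                continue
            path = [(int(ey), int(ex))]
            prev = None
            cur = (int(ey), int(ex))
            hit_junction = False
            while len(path) <= min_px:
                nbrs = [
                    (cur[0] + dy, cur[1] + dx)
                    for dy, dx in offsets
                    if 0 <= cur[0] + dy < skel.shape[0]
                    and 0 <= cur[1] + dx < skel.shape[1]
                    and skel[cur[0] + dy, cur[1] + dx]
                    and (cur[0] + dy, cur[1] + dx) != prev
                ]
                if len(nbrs) == 0:
                    break  # isolated segment: keep
                if len(nbrs) > 1:
                    hit_junction = True
                    break
                prev, cur = cur, nbrs[0]
                path.append(cur)
            if hit_junction and len(path) <= min_px:
                for py, px in path:
                    skel[py, px] = False
                changed = True
    return skel


def _outside_band(mask: PatternoidMask, annulus_width_um: float):
    dist = mask.radial_distance_um()
    r = mask.cavity_radius_um
    band = (dist > r) & (dist <= r + annulus_width_um)
    beyond = dist > r + annulus_width_um
    return band, beyond


def count_roots(mask: PatternoidMask, annulus_width_um: float | None = None) -> int:
    """Number of distinct boundary crossings (initial invasion events).

    Counts 8-connected components of the mask outside the cavity that
    intersect the thin annulus ``(r, r + w]`` just outside the boundary
    AND extend beyond it.  Default annulus width is 2 px in um.
    """
    _check_mask(mask)
    if annulus_width_um is None:
        annulus_width_um = 2.0 * mask.cal.pixel_size_um
    band, beyond = _outside_band(mask, annulus_width_um)
    outside = mask.pixels & (band | beyond)
    labels = label(outside, connectivity=2)
    in_band = np.unique(labels[band & mask.pixels])
    past_band = np.unique(labels[beyond & mask.pixels])
    roots = np.intersect1d(in_band, past_band)
    return int(np.count_nonzero(roots))


def count_tips(mask: PatternoidMask, skeleton: np.ndarray) -> int:
    """Skeleton endpoints (exactly one 8-neighbour) outside the cavity."""
    _check_mask(mask)
    skeleton = np.asarray(skeleton, dtype=bool)
    if skeleton.shape != mask.pixels.shape:
        raise PipelineError("skeleton shape must match the mask")
    counts = _neighbor_counts(skeleton)
    dist = mask.radial_distance_um()
    ends = skeleton & (counts == 1) & (dist > mask.cavity_radius_um)
    return int(np.count_nonzero(ends))


def measure_invasion(
    mask: PatternoidMask,
    annulus_width_um: float | None = None,
    min_branch_um: float = DEFAULT_MIN_BRANCH_UM,
) -> InvasionMetrics:
    """Extract all five invasive parameters from one mask."""
    inv, noninv, norm = measure_areas(mask)
    dist = max_invasive_distance(mask)
    roots = count_roots(mask, annulus_width_um)
    if roots == 0:
        # non-invasive patternoid: no crossing, hence no tips and no depth
        tips = 0
        dist = 0.0
    else:
        skel = skeletonize_and_prune(mask.pixels, min_branch_um, mask.cal.pixel_size_um)
        tips = count_tips(mask, skel)
    return InvasionMetrics(
        invasive_area_um2=inv,
        noninvasive_area_um2=noninv,
        noninvasive_area_norm=norm,
        max_invasive_distance_um=dist,
        roots=roots,
        tips=tips,
    )


def build_heatmap(masks) -> tuple[np.ndarray, int]:
    """Per-pixel count of true values across aligned replicate masks.

    All masks must share one shape (and, for interpretability, cavity
    alignment).  Returns the integer count map and the replicate count;
    the map's maximum is bounded by the number of replicates.
    """
    arrays = [m.pixels if isinstance(m, PatternoidMask) else np.asarray(m, dtype=bool) for m in masks]
    if not arrays:
        raise PipelineError("no masks given")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise PipelineError("all replicate masks must share one shape")
    heat = np.zeros(shape, dtype=np.int64)
    for a in arrays:
        heat += a
    return heat, len(arrays)
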