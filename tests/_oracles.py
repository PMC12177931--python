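"""Independent brute-force reference implementations used only by tests.

Deliberately naive (pure-Python BFS flood fill, per-pixel loops,
exhaustive threshold search) so they share no code path with the
package implementations they check.
"""

from collections import deque

import numpy as np


def bfs_components(cells):
    """8-connected components of a set of (y, x) tuples via BFS flood fill."""
    cells = set(cells)
    comps = []
    while cells:
        seed = next(iter(cells))
        comp = {seed}
        cells.remove(seed)
        queue = deque([seed])
        while queue:
            y, x = queue.popleft()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    n = (y + dy, x + dx)
                    if n in cells:
                        cells.remove(n)
                        comp.add(n)
                        queue.append(n)
        comps.append(comp)
    return comps


def oracle_count_roots(mask, annulus_width_um=None):
    """Boundary-crossing count by flood fill over the outside region."""
    if annulus_width_um is None:
        annulus_width_um = 2.0 * mask.cal.pixel_size_um
    cx, cy = mask.cavity_center_px
    px = mask.cal.pixel_size_um
    r = mask.cavity_radius_um
    outside = []
    for (y, x) in np.argwhere(mask.pixels):
        d = ((x - cx) ** 2 + (y - cy) ** 2) ** 0.5 * px
        if d > r:
            outside.append((int(y), int(x)))
    count = 0
    for comp in bfs_components(outside):
        in_band = beyond = False
        for (y, x) in comp:
            d = ((x - cx) ** 2 + (y - cy) ** 2) ** 0.5 * px
            if d <= r + annulus_width_um:
                in_band = True
            else:
                beyond = True
        if in_band and beyond:
            count += 1
    return count


def oracle_max_distance(mask):
    """Exhaustive scan over true pixels for the deepest boundary penetration."""
    cx, cy = mask.cavity_center_px
    px = mask.cal.pixel_size_um
    best = 0.0
    for (y, x) in np.argwhere(mask.pixels):
        d = ((x - cx) ** 2 + (y - cy) ** 2) ** 0.5 * px
        if d > mask.cavity_radius_um:
            best = max(best, d - mask.cavity_radius_um)
    return best


def oracle_areas(mask):
    """Per-pixel loop: (invasive, non-invasive) areas in um^2."""
    cx, cy = mask.cavity_center_px
    px = mask.cal.pixel_size_um
    inv = noninv = 0
    for (y, x) in np.argwhere(mask.pixels):
        d = ((x - cx) ** 2 + (y - cy) ** 2) ** 0.5 * px
        if d <= mask.cavity_radius_um:
            noninv += 1
        else:
            inv += 1
    return inv * px * px, noninv * px * px


def oracle_projection(voxels, kind):
    """Naive per-pixel loop projection of a (z, y, x) stack."""
    z, h, w = voxels.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            col = [voxels[k, y, x] for k in range(z)]
            if kind == "max":
                out[y, x] = max(col)
            elif kind == "sum":
                out[y, x] = sum(col)
            elif kind == "std":
                m = sum(col) / z
                out[y, x] = (sum((v - m) ** 2 for v in col) / z) ** 0.5
    return out


def oracle_otsu(image, nbins=256):
    """Exhaustive search of the between-class-variance-maximizing threshold."""
    flat = np.asarray(image, dtype=float).ravel()
    lo, hi = flat.min(), flat.max()
    edges = np.linspace(lo, hi, nbins + 1)
    best_t, best_v = None, -1.0
    for t in edges[1:-1]:
        a, b = flat[flat <= t], flat[flat > t]
        if len(a) == 0 or len(b) == 0:
            continue
        v = len(a) * len(b) * (a.mean() - b.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def pooled_t(a, b):
    """Hand-computed pooled-variance two-sample t statistic."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    sa2 = sum((v - ma) ** 2 for v in a) / (na - 1)
    sb2 = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
    return (ma - mb) / (sp2 * (1 / na + 1 / nb)) ** 0.5
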