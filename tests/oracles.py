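"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — iterative fixed points, exhaustive
searches, closed-form hand formulas — and shares no code path with the
package.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

_FULL = np.ones((3, 3, 3), dtype=bool)


def iterative_reconstruction(marker: np.ndarray, mask: np.ndarray, max_iter: int = 10000) -> np.ndarray:
    """Geodesic dilation of marker under mask iterated to convergence
    (26-connectivity), the defining construction of morphological
    reconstruction by dilation."""
    cur = marker.astype(float).copy()
    for _ in range(max_iter):
        dil = ndimage.grey_dilation(cur, footprint=_FULL)
        nxt = np.minimum(dil, mask)
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt
    raise RuntimeError("geodesic dilation did not converge")


def exhaustive_otsu(data: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive search of the between-class-variance-maximizing threshold
    over all candidate histogram splits (256 uniform bins over [min, max]);
    ties resolved toward the lower bin. Returns the bin-center threshold."""
    flat = np.asarray(data, dtype=float).ravel()
    hist, edges = np.histogram(flat, bins=n_bins, range=(flat.min(), flat.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum()
    best_t, best_var = None, -1.0
    for t in range(n_bins - 1):
        n0 = hist[: t + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[: t + 1] * centers[: t + 1]).sum() / n0
        mu1 = (hist[t + 1 :] * centers[t + 1 :]).sum() / n1
        var = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return float(centers[best_t])


def ttest_closed_form(a, b, variant: str = "pooled"):
    """Textbook two-sample t: statistic, df and two-sided p, from scratch."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if variant == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = (a.mean() - b.mean()) / se
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def is_simple_point(local: np.ndarray) -> bool:
    """Topological simple-point test on a 3x3x3 neighborhood (center True):
    removal preserves topology iff the foreground 26-neighbors stay one
    26-connected component and the 6-adjacent background stays one
    6-connected component within the 18-neighborhood."""
    assert local.shape == (3, 3, 3) and local[1, 1, 1]
    fg = local.copy()
    fg[1, 1, 1] = False
    if not fg.any():
        return False  # isolated voxel: removal deletes a component
    lab, n = ndimage.label(fg, structure=np.ones((3, 3, 3), bool))
    if n != 1:
        return False
    bg = ~local
    # restrict background to the 18-neighborhood (faces + edges)
    mask18 = np.ones((3, 3, 3), bool)
    for corner in [(0, 0, 0), (0, 0, 2), (0, 2, 0), (0, 2, 2),
                   (2, 0, 0), (2, 0, 2), (2, 2, 0), (2, 2, 2)]:
        mask18[corner] = False
    bg18 = bg & mask18
    if not bg18.any():
        return False
    lab_bg, n_bg = ndimage.label(bg18, structure=ndimage.generate_binary_structure(3, 1))
    # count only background components 6-adjacent to the center
    adjacent = set()
    for dz, dy, dx in [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]:
        v = (1 + dz, 1 + dy, 1 + dx)
        if bg18[v]:
            adjacent.add(lab_bg[v])
    return len(adjacent) == 1


def count_components(mask: np.ndarray, connectivity: int) -> int:
    structure = ndimage.generate_binary_structure(mask.ndim, connectivity)
    return int(ndimage.label(mask, structure=structure)[1])


def disk_chord_profile(radius: float, n: int) -> np.ndarray:
    """Closed-form parallel projection of a disk centered on the rotation
    center (index n//2): chord length 2*sqrt(r^2 - s^2) at offset s."""
    s = np.arange(n) - n // 2
    out = np.zeros(n)
    inside = np.abs(s) < radius
    out[inside] = 2 * np.sqrt(radius**2 - s[inside] ** 2)
    return out


def random_blob_mask(rng: np.random.Generator, shape=(20, 20, 20), sigma=2.0, frac=0.25) -> np.ndarray:
    """Random smooth blob mask for topology tests."""
    noise = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(noise, sigma)
    thr = np.quantile(smooth, 1 - frac)
    return smooth > thr
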