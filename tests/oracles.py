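"""Independent brute-force reference implementations used by the tests.

These deliberately use plain Python loops and elementary formulas so they
share no code path with the package implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from osteotex.heightmap import HeightMap
from osteotex.surface import compute_acf, compute_material_ratio_curve, compute_sz

EIGHT = np.ones((3, 3), dtype=int)


def brute_force_sal(hm: HeightMap, s: float = 0.2) -> float:
    """Exhaustive scan over every ACF grid lag with ACF <= s."""
    grid = compute_acf(hm)
    acf = grid.acf
    cy, cx = grid.center
    best = np.inf
    for iy in range(acf.shape[0]):
        for ix in range(acf.shape[1]):
            if iy == cy and ix == cx:
                continue
            if acf[iy, ix] <= s:
                d = np.hypot((iy - cy) * grid.dy, (ix - cx) * grid.dx)
                if d < best:
                    best = d
    return float(best)


def brute_force_smr1(hm: HeightMap, window: float = 40.0, step: float = 0.5) -> float:
    """Equivalent-line construction with explicit loops and normal equations."""
    curve = compute_material_ratio_curve(hm)
    mr = np.arange(0.0, 100.0 + step / 2, step)
    c = np.interp(mr, curve.ratios, curve.heights)
    n_win = int(round(window / step))
    best_m, best_slope = 0, np.inf
    for m in range(0, len(mr) - n_win):
        slope = abs(c[m] - c[m + n_win]) / window
        if slope < best_slope - 1e-15:
            best_slope, best_m = slope, m
    xs = mr[best_m : best_m + n_win + 1]
    ys = c[best_m : best_m + n_win + 1]
    # explicit least squares: solve the 2x2 normal equations
    n = len(xs)
    sx, sy = float(np.sum(xs)), float(np.sum(ys))
    sxx, sxy = float(np.sum(xs * xs)), float(np.sum(xs * ys))
    det = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / det
    intercept = (sy - slope * sx) / n
    h0 = intercept
    if c[0] <= h0:
        return 0.0
    for k in range(1, len(mr)):
        if c[k] <= h0:
            c_hi, c_lo = c[k - 1], c[k]
            if c_hi == c_lo:
                return float(mr[k])
            return float(mr[k - 1] + (c_hi - h0) / (c_hi - c_lo) * step)
    return 100.0


def _strict_local_maxima(hm: HeightMap) -> list[tuple[int, int]]:
    z, mask = hm.heights, hm.mask
    ny, nx = z.shape
    out = []
    for r in range(ny):
        for c in range(nx):
            if not mask[r, c]:
                continue
            is_max = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < ny and 0 <= cc < nx and mask[rr, cc]:
                        if z[rr, cc] >= z[r, c]:
                            is_max = False
                            break
                if not is_max:
                    break
            if is_max:
                out.append((r, c))
    return out


def _prominence_of(hm: HeightMap, r: int, c: int) -> float:
    """Peak-to-saddle height by bisection over threshold levels.

    The saddle of a local maximum is the highest level L at which the
    8-connected component of {z >= L} containing it also contains a strictly
    higher cell; the global maximum has prominence max - min.
    """
    z, mask = hm.heights, hm.mask
    zp = z[r, c]
    levels = np.unique(z[mask & (z <= zp)])

    def connects_higher(L: float) -> bool:
        above = mask & (z >= L)
        lab, _ = ndimage.label(above, structure=EIGHT)
        comp = lab == lab[r, c]
        return bool(np.any(z[comp] > zp))

    if not connects_higher(levels[0]):
        zm = z[mask]
        return float(zm.max() - zm.min())  # global maximum
    lo, hi = 0, len(levels) - 1  # connects at lo; fails at hi (level == zp)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if connects_higher(levels[mid]):
            lo = mid
        else:
            hi = mid
    return float(zp - levels[lo])


def brute_force_peaks(hm: HeightMap, prune_frac: float = 0.05) -> list[tuple[int, int]]:
    """Significant peak locations: exhaustive local-maximum + saddle search.

    Applies the same border/mask filters as the package implementation:
    surviving peaks on the grid border or lacking four measured neighbours
    are dropped.
    """
    threshold = prune_frac * compute_sz(hm)
    ny, nx = hm.shape
    keep = []
    for (r, c) in _strict_local_maxima(hm):
        if _prominence_of(hm, r, c) < threshold:
            continue
        if r == 0 or c == 0 or r == ny - 1 or c == nx - 1:
            continue
        if not (hm.mask[r - 1, c] and hm.mask[r + 1, c]
                and hm.mask[r, c - 1] and hm.mask[r, c + 1]):
            continue
        keep.append((r, c))
    return sorted(keep)


def direct_waic(loglik: np.ndarray) -> float:
    """Two-pass WAIC formula, written out longhand."""
    S, n = loglik.shape
    lppd = 0.0
    p_waic = 0.0
    for i in range(n):
        col = loglik[:, i]
        m = max(col)
        lppd += m + np.log(sum(np.exp(v - m) for v in col) / S)
        mean = sum(col) / S
        p_waic += sum((v - mean) ** 2 for v in col) / (S - 1)
    return -2.0 * (lppd - p_waic)
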