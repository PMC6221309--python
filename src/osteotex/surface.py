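"""ISO 25178 areal surface-texture parameters computed from height maps.

Four parameters, one per ISO 25178 parameter family, characterise a bone
surface scan:

* ``Sa`` (µm) — arithmetic mean height: mean absolute deviation of heights
  from the mean plane (height family).
* ``Sal`` (µm) — autocorrelation length: shortest lag distance at which the
  normalised areal autocorrelation decays to a threshold ``s`` (spatial
  family; ``s = 0.2`` by default).
* ``Spc`` (1/µm) — arithmetic mean peak curvature over significant peaks
  (feature family); peaks are significant when their peak-to-saddle height
  (topographic prominence) survives Wolf pruning at a fraction of ``Sz``.
* ``Smr1`` (%) — upper material ratio delimiting the reduced-peak region of
  the areal material ratio (Abbott-Firestone) curve, via the equivalent-line
  construction of the Sk parameter family.

All statistics are computed over measured cells only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .heightmap import DegenerateSurfaceError, HeightMap

__all__ = [
    "TextureParameters",
    "MaterialRatioCurve",
    "PeakSet",
    "AcfGrid",
    "SalDecayWarning",
    "compute_sa",
    "compute_sq",
    "compute_sz",
    "compute_acf",
    "compute_sal",
    "compute_material_ratio_curve",
    "compute_smr1",
    "find_significant_peaks",
    "compute_spc",
    "compute_all_params",
]


class SalDecayWarning(UserWarning):
    """The ACF never decayed to the threshold within the searchable lags."""


@dataclass(frozen=True)
class TextureParameters:
    """The 4-vector of modeled texture parameters for one scan."""

    sa: float  # µm
    sal: float  # µm
    spc: float  # 1/µm
    smr1: float  # %

    def as_array(self) -> np.ndarray:
        return np.array([self.sa, self.sal, self.spc, self.smr1])

    COLUMNS = ("Sa_um", "Sal_um", "Spc_inv_um", "Smr1_pct")


@dataclass(frozen=True)
class MaterialRatioCurve:
    """Areal material ratio curve: smr(c) for a descending grid of heights c."""

    heights: np.ndarray  # descending thresholds c, µm
    ratios: np.ndarray  # smr(c), %, non-decreasing as c decreases

    def height_at_ratio(self, mr: np.ndarray | float) -> np.ndarray | float:
        """Invert the curve: height c at which smr(c) = mr (interpolated)."""
        return np.interp(mr, self.ratios, self.heights)

    def __post_init__(self):
        object.__setattr__(self, "heights", np.asarray(self.heights, dtype=float))
        object.__setattr__(self, "ratios", np.asarray(self.ratios, dtype=float))


@dataclass(frozen=True)
class PeakSet:
    """Significant peaks surviving Wolf pruning.

    ``locations`` are (row, col) grid indices of strict local maxima;
    ``curvatures`` are −½(∂²z/∂x² + ∂²z/∂y²) at each peak (1/µm);
    ``threshold`` is the pruning height used (µm).
    """

    locations: np.ndarray  # (n, 2) int
    curvatures: np.ndarray  # (n,) float, 1/µm
    threshold: float  # µm

    def __len__(self) -> int:
        return len(self.locations)


@dataclass(frozen=True)
class AcfGrid:
    """Normalised areal autocorrelation on the full lag grid.

    ``acf[iy, ix]`` is the correlation at lag ((ix − cx)·dx, (iy − cy)·dy);
    the grid covers lags −(n−1)…(n−1) in each axis and acf at the centre is 1.
    """

    acf: np.ndarray
    dx: float
    dy: float

    @property
    def center(self) -> tuple[int, int]:
        return (self.acf.shape[0] // 2, self.acf.shape[1] // 2)

    def lag_distances(self) -> np.ndarray:
        """Euclidean lag distance (µm) for every cell of the lag grid."""
        cy, cx = self.center
        iy = (np.arange(self.acf.shape[0]) - cy) * self.dy
        ix = (np.arange(self.acf.shape[1]) - cx) * self.dx
        return np.hypot(iy[:, None], ix[None, :])


# ---------------------------------------------------------------------------
# Height family
# ---------------------------------------------------------------------------

def compute_sa(hm: HeightMap) -> float:
    """Arithmetic mean height Sa (µm): mean |z − mean z| over measured cells."""
    hm.require_measured(2)
    z = hm.measured_values()
    return float(np.mean(np.abs(z - z.mean())))


def compute_sq(hm: HeightMap) -> float:
    """Root-mean-square height Sq (µm); internal helper."""
    hm.require_measured(2)
    z = hm.measured_values()
    return float(np.sqrt(np.mean((z - z.mean()) ** 2)))


def compute_sz(hm: HeightMap) -> float:
    """Maximum height Sz = max − min over measured cells (µm); helper."""
    hm.require_measured(2)
    z = hm.measured_values()
    return float(z.max() - z.min())


# ---------------------------------------------------------------------------
# Spatial family: ACF and Sal
# ---------------------------------------------------------------------------

def compute_acf(hm: HeightMap) -> AcfGrid:
    """Normalised areal autocorrelation of the mean-removed surface.

    The estimator zero-fills non-measured cells after removing the measured
    mean, computes the full (zero-padded, non-circular) autocorrelation by
    FFT, and normalises by the lag-0 value.  On full masks this equals the
    direct sum estimator.
    """
    hm.require_measured(2)
    z = np.where(hm.mask, hm.heights - hm.measured_values().mean(), 0.0)
    if not np.any(z[hm.mask] != 0.0):
        raise DegenerateSurfaceError("zero height variance: ACF undefined")
    ny, nx = z.shape
    fy, fx = 2 * ny - 1, 2 * nx - 1
    F = np.fft.rfft2(z, s=(fy, fx))
    ac = np.fft.irfft2(F * np.conj(F), s=(fy, fx))
    # rearrange circular layout so the zero lag sits at the grid centre
    ac = np.roll(np.roll(ac, ny - 1, axis=0), nx - 1, axis=1)
    ac = ac / ac[ny - 1, nx - 1]
    # enforce exact symmetry lost to FFT round-off
    ac = 0.5 * (ac + ac[::-1, ::-1])
    return AcfGrid(ac, hm.dx, hm.dy)


def compute_sal(hm: HeightMap, s: float = 0.2) -> float:
    """Autocorrelation length Sal (µm): fastest decay of the ACF to ``s``.

    The search is the discrete ISO construction: among all lag-grid points
    whose normalised ACF is ≤ s, the minimum Euclidean lag distance.  If no
    lag qualifies, the maximum searchable lag distance is returned and a
    :class:`SalDecayWarning` is emitted.
    """
    grid = compute_acf(hm)
    dist = grid.lag_distances()
    qualifies = grid.acf <= s
    cy, cx = grid.center
    qualifies[cy, cx] = False  # the zero lag (ACF = 1) never qualifies
    if not qualifies.any():
        warnings.warn(
            "ACF never decayed to the threshold within the grid; "
            "returning the maximum searchable lag",
            SalDecayWarning,
            stacklevel=2,
        )
        return float(dist.max())
    return float(dist[qualifies].min())


# ---------------------------------------------------------------------------
# Functional family: material ratio curve and Smr1
# ---------------------------------------------------------------------------

def compute_material_ratio_curve(hm: HeightMap, n_levels: int = 1024) -> MaterialRatioCurve:
    """Areal material ratio curve smr(c) on a dense descending height grid.

    smr(c) = 100 · #{z ≥ c} / N over measured cells, with c running from
    max(z) down to min(z).
    """
    hm.require_measured(2)
    z = np.sort(hm.measured_values())  # ascending
    zmax, zmin = z[-1], z[0]
    c = np.linspace(zmax, zmin, n_levels)  # descending
    # count of z >= c via searchsorted on the ascending sort
    counts = z.size - np.searchsorted(z, c, side="left")
    ratios = 100.0 * counts / z.size
    return MaterialRatioCurve(heights=c, ratios=ratios)


def _equivalent_line_height(mr_grid: np.ndarray, c_of_mr: np.ndarray,
                            window: float, step: float) -> float:
    """Intercept at mr = 0 of the equivalent line of the Sk construction.

    Slides a ``window``-wide interval along the material-ratio axis, picks the
    one with the smallest secant slope magnitude (ties: lowest position), and
    least-squares fits a straight line to the curve samples inside it.
    """
    n_win = int(round(window / step))
    best_m = 0
    best_slope = np.inf
    for m in range(0, len(mr_grid) - n_win):
        slope = abs(c_of_mr[m] - c_of_mr[m + n_win]) / window
        if slope < best_slope - 1e-15:
            best_slope = slope
            best_m = m
    xs = mr_grid[best_m : best_m + n_win + 1]
    ys = c_of_mr[best_m : best_m + n_win + 1]
    b, a = np.polyfit(xs, ys, 1)
    return float(a)  # value of the fitted line at mr = 0


def compute_smr1(hm: HeightMap, window: float = 40.0, step: float = 0.5) -> float:
    """Upper material ratio Smr1 (%).

    Equivalent-line construction of the Sk family: the material-ratio curve is
    sampled at ``step``-% increments; a ``window``-%-wide interval with the
    minimal secant slope is least-squares fitted by a straight line; Smr1 is
    the material ratio at which the curve reaches that line's height at
    mr = 0 %.
    """
    hm.require_measured(2)
    z = hm.measured_values()
    if z.max() == z.min():
        raise DegenerateSurfaceError("constant surface: Smr1 undefined")
    curve = compute_material_ratio_curve(hm)
    mr_grid = np.arange(0.0, 100.0 + step / 2, step)
    # invert the curve: height at each sampled material ratio
    c_of_mr = np.interp(mr_grid, curve.ratios, curve.heights)
    h0 = _equivalent_line_height(mr_grid, c_of_mr, window, step)
    # Smr1 = smallest material ratio where the curve falls to or below h0
    below = c_of_mr <= h0
    if below[0]:
        return 0.0
    if not below.any():
        return 100.0
    k = int(np.argmax(below))
    c_hi, c_lo = c_of_mr[k - 1], c_of_mr[k]
    if c_hi == c_lo:
        return float(mr_grid[k])
    frac = (c_hi - h0) / (c_hi - c_lo)
    return float(mr_grid[k - 1] + frac * step)


# ---------------------------------------------------------------------------
# Feature family: significant peaks and Spc
# ---------------------------------------------------------------------------

def _prominences(hm: HeightMap) -> tuple[np.ndarray, np.ndarray]:
    """Topographic prominence of every local maximum (8-connected).

    Watershed-style union-find over cells in descending height order: when a
    cell first connects two hills, the lower hill's peak dies at that saddle
    level with prominence = peak − saddle.  The global maximum receives
    prominence max − min.  Returns (peak_cells (m, 2), prominences (m,)).
    """
    z = hm.heights
    ny, nx = z.shape
    meas = hm.mask
    order = np.argsort(z[meas], kind="stable")[::-1]
    cells = np.argwhere(meas)[order]  # descending height, stable tie-break

    parent: dict[int, int] = {}
    peak_of: dict[int, int] = {}  # root -> flat index of its peak cell
    prom: dict[int, float] = {}  # flat peak index -> prominence

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    zf = z.ravel()
    for (r, c) in cells:
        idx = r * nx + c
        neigh_roots = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < ny and 0 <= cc < nx:
                    j = rr * nx + cc
                    if j in parent:
                        rt = find(j)
                        if rt not in neigh_roots:
                            neigh_roots.append(rt)
        parent[idx] = idx
        if not neigh_roots:
            peak_of[idx] = idx
            continue
        # attach to the hill with the highest peak; others die here (saddle)
        neigh_roots.sort(key=lambda rt: (-zf[peak_of[rt]], peak_of[rt]))
        survivor = neigh_roots[0]
        parent[idx] = survivor
        for rt in neigh_roots[1:]:
            dead_peak = peak_of[rt]
            prom[dead_peak] = zf[dead_peak] - zf[idx]
            parent[rt] = survivor

    zm = hm.measured_values()
    for root in {find(i) for i in parent}:
        prom[peak_of[root]] = float(zm.max() - zm.min())

    peaks = np.array([[i // nx, i % nx] for i in sorted(prom)], dtype=int)
    values = np.array([prom[i] for i in sorted(prom)], dtype=float)
    return peaks, values


def _peak_curvature(hm: HeightMap, r: int, c: int) -> float:
    """−½(z_xx + z_yy) by 3-point central differences at an interior cell."""
    z = hm.heights
    zxx = (z[r, c + 1] - 2.0 * z[r, c] + z[r, c - 1]) / hm.dx**2
    zyy = (z[r + 1, c] - 2.0 * z[r, c] + z[r - 1, c]) / hm.dy**2
    return -0.5 * (zxx + zyy)


def find_significant_peaks(hm: HeightMap, prune_frac: float = 0.05) -> PeakSet:
    """Significant peaks of the surface after Wolf pruning.

    Hills are the catchment basins of the inverted surface; a hill whose
    peak-to-saddle height (prominence) is below ``prune_frac · Sz`` is merged
    into its neighbour.  Peaks on the grid border, or without four measured
    neighbours for the curvature stencil, are discarded.
    """
    hm.require_measured(2)
    sz = compute_sz(hm)
    if sz == 0.0:
        raise DegenerateSurfaceError("constant surface: no peaks")
    threshold = prune_frac * sz
    peaks, prominences = _prominences(hm)
    ny, nx = hm.shape
    locs, curvs = [], []
    for (r, c), p in zip(peaks, prominences):
        if p < threshold:
            continue
        if r == 0 or c == 0 or r == ny - 1 or c == nx - 1:
            continue  # border: central-difference stencil unavailable
        if not (hm.mask[r - 1, c] and hm.mask[r + 1, c]
                and hm.mask[r, c - 1] and hm.mask[r, c + 1]):
            continue
        locs.append((r, c))
        curvs.append(_peak_curvature(hm, r, c))
    return PeakSet(
        locations=np.array(locs, dtype=int).reshape(-1, 2),
        curvatures=np.array(curvs, dtype=float),
        threshold=threshold,
    )


def compute_spc(hm: HeightMap, peaks: PeakSet | None = None) -> float:
    """Arithmetic mean peak curvature Spc (1/µm) over significant peaks."""
    if peaks is None:
        peaks = find_significant_peaks(hm)
    if len(peaks) == 0:
        raise DegenerateSurfaceError("no significant peaks: Spc undefined")
    return float(np.mean(peaks.curvatures))


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def compute_all_params(hm: HeightMap) -> TextureParameters:
    """The modeled 4-vector (Sa, Sal, Spc, Smr1) for one preprocessed scan."""
    return TextureParameters(
        sa=compute_sa(hm),
        sal=compute_sal(hm),
        spc=compute_spc(hm),
        smr1=compute_smr1(hm),
    )
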