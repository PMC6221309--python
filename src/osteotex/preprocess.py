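"""Metrological preprocessing of raw surface scans.

The chain turns a raw confocal scan into an analysis-ready height map:
acceptance QC on the measured fraction,
least-squares leveling, y/z mirroring for molds, robust outlier removal with
hole classification, neighbor-smoothing fill-in of small non-measured
regions, a Gaussian low-pass S-filter, and degree-2 polynomial form removal
(F-operator).  Stage order is fixed: leveling → mirroring (molds) → outlier
removal → fill-in → S-filter → form removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .heightmap import DegenerateSurfaceError, HeightMap
from .surface import compute_sq

logger = logging.getLogger(__name__)

#: 50 %-transmission constant of the ISO 16610-61 areal Gaussian filter
GAUSS_ALPHA = float(np.sqrt(np.log(2.0) / np.pi))


class QCRejectedError(ValueError):
    """Scan failed the measured-fraction acceptance rule."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration of the preprocessing chain.

    accept_fraction : minimum measured fraction for a scan to be accepted
        (inclusive bound).
    hole_fill_max : non-measured connected regions (8-connected) strictly
        smaller than this many cells are filled; larger holes stay
        non-measured.
    outlier_strength : robust-z threshold ("normal strength" = 3) applied to
        residuals from a 5x5 median-filtered surface.
    sfilter_cutoff : wavelength (µm) of 50 % amplitude transmission of the
        Gaussian low-pass S-filter; None disables the stage.
    form_degree : degree of the polynomial form removed by the F-operator.
    is_mold : mirror the y- and z-axes before analysis (mold scans are
        negative replicas of the bone surface).
    """

    accept_fraction: float = 0.95
    hole_fill_max: int = 225
    outlier_strength: float = 3.0
    sfilter_cutoff: float | None = 5.0
    form_degree: int = 2
    is_mold: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.accept_fraction <= 1.0):
            raise ValueError("accept_fraction must be in (0, 1]")
        if self.hole_fill_max < 0:
            raise ValueError("hole_fill_max must be >= 0")

    def for_mold(self, is_mold: bool = True) -> "PreprocessConfig":
        return replace(self, is_mold=is_mold)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_measured_fraction(hm: HeightMap, threshold: float = 0.95) -> tuple[bool, float]:
    """Acceptance rule: scans with >= threshold of the surface measured pass."""
    frac = hm.measured_fraction
    return (frac >= threshold), frac


# ---------------------------------------------------------------------------
# Leveling and form removal
# ---------------------------------------------------------------------------

def _poly_basis(hm: HeightMap, degree: int) -> np.ndarray:
    """Bivariate monomial basis up to ``degree`` on centred coordinates."""
    ny, nx = hm.shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * hm.dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * hm.dy
    # scale to O(1) for conditioning
    sx = max(abs(x).max(), 1.0)
    sy = max(abs(y).max(), 1.0)
    X, Y = np.meshgrid(x / sx, y / sy)
    cols = [np.ones_like(X)]
    for d in range(1, degree + 1):
        for j in range(d + 1):
            cols.append(X ** (d - j) * Y**j)
    return np.stack([c.ravel() for c in cols], axis=1)


def _fit_and_subtract(hm: HeightMap, degree: int) -> HeightMap:
    A = _poly_basis(hm, degree)
    m = hm.mask.ravel()
    z = hm.heights.ravel()[m]
    Am = A[m]
    n_terms = A.shape[1]
    if hm.n_measured < n_terms:
        raise DegenerateSurfaceError("too few measured points for the fit")
    coef, _, rank, _ = np.linalg.lstsq(Am, z, rcond=None)
    if rank < n_terms:
        raise DegenerateSurfaceError("rank-deficient polynomial fit")
    fitted = (A @ coef).reshape(hm.shape)
    out = hm.heights - fitted
    out[~hm.mask] = np.nan
    return hm.with_heights(out)


def level_lsq(hm: HeightMap) -> HeightMap:
    """Subtract the least-squares plane from the measured heights."""
    return _fit_and_subtract(hm, 1)


def remove_form_poly2(hm: HeightMap, degree: int = 2) -> HeightMap:
    """F-operator: subtract the least-squares bivariate polynomial of degree 2."""
    return _fit_and_subtract(hm, degree)


# ---------------------------------------------------------------------------
# Mold mirroring
# ---------------------------------------------------------------------------

def mirror_mold(hm: HeightMap) -> HeightMap:
    """Mirror the y- and z-axes: molds are negative replicas of the bone."""
    return hm.with_heights(-hm.heights[::-1, :], hm.mask[::-1, :])


# ---------------------------------------------------------------------------
# Outlier removal and hole classification
# ---------------------------------------------------------------------------

def remove_outliers(hm: HeightMap, cfg: PreprocessConfig = PreprocessConfig()) -> HeightMap:
    """Mark isolated outliers (including around edges) as non-measured.

    Residuals from a 5x5 median-filtered surface are tested against a robust-z
    rule: cells with |residual| > strength · 1.4826 · MAD become non-measured.
    The border ring is included in the same test (median filter uses nearest
    replication there).  Holes are not filled here; see
    :func:`fill_nonmeasured`.
    """
    z = hm.heights.copy()
    z[~hm.mask] = np.nan
    # median of the measured neighborhood; NaNs ignored via generic filter is
    # slow, so fill non-measured with local median beforehand
    filled = z.copy()
    if (~hm.mask).any():
        med_all = np.nanmedian(z[hm.mask]) if hm.mask.any() else 0.0
        filled[~hm.mask] = med_all
    smooth = ndimage.median_filter(filled, size=5, mode="nearest")
    resid = hm.heights - smooth
    rm = resid[hm.mask]
    mad = np.median(np.abs(rm - np.median(rm)))
    sigma = 1.4826 * mad
    if sigma == 0.0:
        sigma = float(np.std(rm))
    if sigma == 0.0:
        return hm.copy()
    bad = hm.mask & (np.abs(resid) > cfg.outlier_strength * sigma)
    new_mask = hm.mask & ~bad
    out = hm.heights.copy()
    out[~new_mask] = np.nan
    return hm.with_heights(out, new_mask)


def fillable_holes(hm: HeightMap, hole_fill_max: int = 225) -> np.ndarray:
    """Boolean map of non-measured cells in 8-connected components < cap."""
    holes = ~hm.mask
    labels, n = ndimage.label(holes, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(holes)
    sizes = ndimage.sum_labels(holes, labels, index=np.arange(1, n + 1))
    small = np.flatnonzero(sizes < hole_fill_max) + 1
    return np.isin(labels, small)


def fill_nonmeasured(hm: HeightMap, hole_fill_max: int = 225,
                     tol: float = 1e-6, max_iter: int = 10000) -> HeightMap:
    """Fill small non-measured regions by iterative neighbor-mean smoothing.

    Fillable cells are relaxed to the mean of their 4-neighbors (harmonic
    inpainting) until the largest per-iteration change is below ``tol`` µm.
    Harmonic interpolation reproduces planes exactly.  Filled cells become
    measured; larger holes stay non-measured.
    """
    fill = fillable_holes(hm, hole_fill_max)
    if not fill.any():
        return hm.copy()
    if not hm.mask.any():
        raise DegenerateSurfaceError("no measured cells to interpolate from")
    z = hm.heights.copy()
    z[~hm.mask] = np.nan
    # initialize fillable cells at the measured mean
    z[fill] = hm.measured_values().mean()
    known = hm.mask
    usable = known | fill  # cells participating in the relaxation
    zwork = np.where(usable, z, 0.0)
    wgt = usable.astype(float)
    for _ in range(max_iter):
        num = (np.roll(zwork, 1, 0) * np.roll(wgt, 1, 0)
               + np.roll(zwork, -1, 0) * np.roll(wgt, -1, 0)
               + np.roll(zwork, 1, 1) * np.roll(wgt, 1, 1)
               + np.roll(zwork, -1, 1) * np.roll(wgt, -1, 1))
        den = (np.roll(wgt, 1, 0) + np.roll(wgt, -1, 0)
               + np.roll(wgt, 1, 1) + np.roll(wgt, -1, 1))
        # np.roll wraps around the border; suppress wrapped contributions
        num[0, :] -= zwork[-1, :] * wgt[-1, :]
        den[0, :] -= wgt[-1, :]
        num[-1, :] -= zwork[0, :] * wgt[0, :]
        den[-1, :] -= wgt[0, :]
        num[:, 0] -= zwork[:, -1] * wgt[:, -1]
        den[:, 0] -= wgt[:, -1]
        num[:, -1] -= zwork[:, 0] * wgt[:, 0]
        den[:, -1] -= wgt[:, 0]
        upd = np.where((den > 0) & fill, num / np.maximum(den, 1.0), zwork)
        delta = np.max(np.abs(upd[fill] - zwork[fill])) if fill.any() else 0.0
        zwork = np.where(fill, upd, zwork)
        if delta < tol:
            break
    out = np.where(usable, zwork, np.nan)
    out[known] = hm.heights[known]
    return hm.with_heights(out, usable)


# ---------------------------------------------------------------------------
# S-filter
# ---------------------------------------------------------------------------

def sfilter_lowpass(hm: HeightMap, cutoff: float) -> HeightMap:
    """Gaussian low-pass S-filter with 50 % transmission at ``cutoff`` (µm).

    Amplitude transmission a(λ) = exp(−π (α·cutoff/λ)²) with α = √(ln2/π)
    (areal Gaussian weighting of ISO 16610-61); implemented as separable
    Gaussian smoothing with σ = α·cutoff/√(2π) in physical units.
    """
    if cutoff <= max(hm.dx, hm.dy):
        raise ValueError(
            f"S-filter cutoff {cutoff} µm must exceed the sampling step "
            f"({max(hm.dx, hm.dy)} µm)"
        )
    sigma = GAUSS_ALPHA * cutoff / np.sqrt(2.0 * np.pi)
    z = np.where(hm.mask, hm.heights, 0.0)
    w = hm.mask.astype(float)
    sig_px = (sigma / hm.dy, sigma / hm.dx)
    num = ndimage.gaussian_filter(z, sig_px, mode="nearest")
    den = ndimage.gaussian_filter(w, sig_px, mode="nearest")
    out = np.where(hm.mask & (den > 0), num / np.maximum(den, 1e-300), np.nan)
    return hm.with_heights(out)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def preprocess_pipeline(hm: HeightMap, cfg: PreprocessConfig = PreprocessConfig()) -> HeightMap:
    """Run the full metrological chain on a QC-accepted scan.

    Order: leveling → mirroring (if mold) → outlier removal → fill-in →
    S-filter → degree-2 form removal.  Raises :class:`QCRejectedError` if the
    scan fails the measured-fraction rule.  Per-stage measured fraction and Sq
    are logged.
    """
    ok, frac = qc_measured_fraction(hm, cfg.accept_fraction)
    if not ok:
        raise QCRejectedError(
            f"measured fraction {frac:.4f} below acceptance bound "
            f"{cfg.accept_fraction:.4f}"
        )

    def log_stage(name: str, h: HeightMap) -> None:
        logger.info(
            "stage=%s measured_fraction=%.4f sq_um=%.4f",
            name, h.measured_fraction, compute_sq(h),
        )

    out = level_lsq(hm)
    log_stage("level", out)
    if cfg.is_mold:
        out = mirror_mold(out)
        log_stage("mirror", out)
    out = remove_outliers(out, cfg)
    log_stage("outliers", out)
    out = fill_nonmeasured(out, cfg.hole_fill_max)
    log_stage("fill", out)
    if cfg.sfilter_cutoff is not None:
        out = sfilter_lowpass(out, cfg.sfilter_cutoff)
        log_stage("sfilter", out)
    out = remove_form_poly2(out, cfg.form_degree)
    log_stage("form", out)
    return out
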