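"""Synthetic stand-in for the bone use-wear experiment.

Three generators, increasingly abstract:

1. :func:`build_registry` — the experiment bookkeeping: 37 bone specimens in
   5 acquisition lots, each specimen in one of three manufacturing states
   (UW unworked, GS ground with sandstone, SF scraped with flint) and worn on
   one of three materials (FS fresh skin, PL processed leather, DB dry bark),
   with incremental mold samples taken on a fixed schedule (every 30 min for
   the first 90 min, every 90 min after) and five crosswise scan locations
   (C, D, P, L, R) per sample.  The default design yields 239 samples
   (37 bones + 202 molds).

2. :func:`simulate_base_surface` / :func:`apply_wear` / :func:`mold_of` — a
   mechanistic height-map simulator: lamellar bone microtopography with
   pores, manufacturing traces (dense fine scratches for GS, sparse deep
   furrows ~30-100 µm wide for SF), material- and time-dependent erosion
   (peak truncation and rounding plus fine 5-10 µm striations), and physical
   molding (y-flip, z-negation, registration jitter, slight peak rounding).

3. :func:`simulate_observation_table` — a parametric generator that mirrors
   the fitted model's own structure (fixed effects, crossed Gaussian random
   intercepts for specimen and lot, multivariate Student-t noise) and emits
   texture-parameter 4-vectors directly, bypassing surface simulation for
   fast statistical tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .heightmap import HeightMap

STATES = ("UW", "GS", "SF")
MATERIALS = ("FS", "PL", "DB")
LOCATIONS = ("C", "D", "P", "L", "R")
#: grouping used by the statistical model: Center, Distal+Proximal, Left+Right
LOCATION_GROUPS = {"C": "C", "D": "DP", "P": "DP", "L": "LR", "R": "LR"}

#: observation-table column order (frozen interface)
TABLE_COLUMNS = [
    "specimen", "lot", "state", "material", "time_min", "location",
    "is_mold", "is_rescan", "Sa_um", "Sal_um", "Spc_inv_um", "Smr1_pct",
]


# ---------------------------------------------------------------------------
# Experiment registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecimenInfo:
    specimen: str
    lot: str
    state: str
    material: str
    duration_min: int


@dataclass(frozen=True)
class Sample:
    """One physical sample: the bone itself or one of its molds."""

    specimen: str
    time_min: int
    is_mold: bool


@dataclass
class ExperimentRegistry:
    specimens: list[SpecimenInfo]
    samples: list[Sample]
    locations: tuple[str, ...] = LOCATIONS

    @property
    def lot_of(self) -> dict[str, str]:
        return {s.specimen: s.lot for s in self.specimens}

    @property
    def lots(self) -> list[str]:
        return sorted({s.lot for s in self.specimens})

    @property
    def n_specimens(self) -> int:
        return len(self.specimens)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_molds(self) -> int:
        return sum(1 for s in self.samples if s.is_mold)

    def specimen_info(self, specimen: str) -> SpecimenInfo:
        return next(s for s in self.specimens if s.specimen == specimen)


@dataclass(frozen=True)
class RegistryConfig:
    """Counts and schedule of the default experimental design.

    Durations are assigned from ``duration_pattern`` by specimen index; the
    default pattern yields 26 specimens at 180 min (5 molds each), 8 at
    270 min (6 molds) and 3 at 450 min (8 molds), i.e. 202 molds and 239
    samples in total.
    """

    n_specimens: int = 37
    lot_sizes: tuple[int, ...] = (8, 8, 7, 7, 7)
    duration_450_idx: tuple[int, ...] = (0, 12, 24)
    duration_270_idx: tuple[int, ...] = (1, 5, 9, 13, 17, 21, 25, 29)
    default_duration: int = 180

    def __post_init__(self) -> None:
        if sum(self.lot_sizes) != self.n_specimens:
            raise ValueError(
                f"lot sizes {self.lot_sizes} do not sum to {self.n_specimens}"
            )


def mold_schedule(duration_min: int) -> list[int]:
    """Mold times: 0, every 30 min to 90 min, then every 90 min to the end."""
    times = [t for t in (0, 30, 60, 90) if t <= duration_min]
    times += list(range(180, duration_min + 1, 90))
    return times


def build_registry(config: RegistryConfig | None = None, seed: int = 0) -> ExperimentRegistry:
    """Deterministic default registry of the experimental design.

    States and materials cycle through the 9 state x material cells so every
    cell holds at least 4 specimens; lots are contiguous blocks.  ``seed`` is
    accepted for interface symmetry with the other generators (the default
    registry is fully deterministic).
    """
    cfg = config or RegistryConfig()
    lot_ids = []
    for li, size in enumerate(cfg.lot_sizes):
        lot_ids += [f"L{li + 1}"] * size

    specimens: list[SpecimenInfo] = []
    for i in range(cfg.n_specimens):
        state = STATES[(i % 9) // 3]
        material = MATERIALS[i % 3]
        if i in cfg.duration_450_idx:
            dur = 450
        elif i in cfg.duration_270_idx:
            dur = 270
        else:
            dur = cfg.default_duration
        specimens.append(
            SpecimenInfo(f"S{i + 1:02d}", lot_ids[i], state, material, dur)
        )

    samples: list[Sample] = []
    for sp in specimens:
        for t in mold_schedule(sp.duration_min):
            samples.append(Sample(sp.specimen, t, is_mold=True))
        samples.append(Sample(sp.specimen, sp.duration_min, is_mold=False))
    return ExperimentRegistry(specimens=specimens, samples=samples)


# ---------------------------------------------------------------------------
# Mechanistic surface simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WearParams:
    """Rates and scales of the surface and observation generators.

    Wear rates are per-minute exponential-approach constants; fresh skin is
    the fastest abrasive, per the experimental findings.  ``truncate_share``
    and ``round_share`` set how much of the wear acts by peak truncation
    (plateau formation) vs. Gaussian rounding.  Surface texture scales are in
    µm.  The Student-t degrees of freedom and random-effect SDs parameterise
    the observation-table generator.
    """

    # material wear rates (1/min): FS fastest
    rates: dict[str, float] = field(
        default_factory=lambda: {"FS": 0.004, "PL": 0.0008, "DB": 0.002}
    )
    # share of wear acting as plateau truncation of the summits (rigid,
    # abrasive contact: dry bark), as overall rounding (supple polish:
    # skin and leather), and as valley blunting (moist skin penetrating
    # and polishing the furrow bottoms)
    truncate_share: dict[str, float] = field(
        default_factory=lambda: {"FS": 0.15, "PL": 0.0, "DB": 1.0}
    )
    round_share: dict[str, float] = field(
        default_factory=lambda: {"FS": 1.0, "PL": 1.0, "DB": 0.0}
    )
    valley_share: dict[str, float] = field(
        default_factory=lambda: {"FS": 1.0, "PL": 0.0, "DB": 0.0}
    )
    pore_density: float = 60.0  # pores per mm^2
    furrow_depth_um: dict[str, float] = field(
        default_factory=lambda: {"GS": 0.9, "SF": 2.8}
    )
    furrow_width_um: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"GS": (25.0, 45.0), "SF": (55.0, 100.0)}
    )
    background_sa_um: float = 0.25
    noise_um: float = 0.03
    # observation-table generator
    student_t_df: float = 5.0
    sd_specimen: float = 0.25
    sd_lot: float = 0.15
    error_scale: tuple[float, float, float, float] = (0.45, 0.35, 0.40, 0.50)
    b_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.student_t_df <= 2:
            raise ValueError("Student-t df must exceed 2 (finite variance)")
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("wear rates must be non-negative")


def _correlated_noise(rng: np.random.Generator, shape: tuple[int, int],
                      dx: float, lx_um: float, ly_um: float) -> np.ndarray:
    """Unit-variance Gaussian field with anisotropic correlation lengths."""
    w = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(w, (ly_um / dx / 2.355, lx_um / dx / 2.355),
                                mode="wrap")
    s = f.std()
    return f / (s if s > 0 else 1.0)


def _add_grooves(z: np.ndarray, rng: np.random.Generator, dx: float,
                 n_grooves: int, width_range: tuple[float, float],
                 depth_um: float, ridge_frac: float = 0.15) -> None:
    """Carve transverse grooves (running along y, varying with x) in place.

    Each groove is a Gaussian-profile channel with small raised ridges at its
    shoulders (burrs thrown up by the tool edge) and a slowly varying depth
    along its length.
    """
    ny, nx = z.shape
    x = np.arange(nx) * dx
    y_mod_phase = rng.uniform(0, 2 * np.pi, size=n_grooves)
    for k in range(n_grooves):
        x0 = rng.uniform(0, nx * dx)
        width = rng.uniform(*width_range)
        depth = depth_um * rng.uniform(0.6, 1.4)
        prof = np.exp(-0.5 * ((x - x0) / (width / 2.355)) ** 2)
        ridge = ridge_frac * depth * np.exp(
            -0.5 * ((np.abs(x - x0) - 0.8 * width) / (0.25 * width)) ** 2
        )
        along = 1.0 + 0.25 * np.sin(
            2 * np.pi * np.arange(ny) * dx / (nx * dx) * rng.integers(1, 4)
            + y_mod_phase[k]
        )
        z -= along[:, None] * (depth * prof)[None, :]
        z += along[:, None] * ridge[None, :]


def simulate_base_surface(
    state: str,
    porosity: float | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    dx: float = 1.5625,
    wp: WearParams | None = None,
) -> HeightMap:
    """Bone surface at time 0 for one manufacturing state.

    UW: low-amplitude anisotropic lamellar texture plus random pore
    depressions.  GS adds dense fine transverse scratches; SF adds sparse,
    deep transverse furrows 30-100 µm wide.  ``porosity`` (pores per mm²)
    defaults to the WearParams value.
    """
    if state not in STATES:
        raise ValueError(f"unknown manufacturing state {state!r}")
    wp = wp or WearParams()
    rng = np.random.default_rng(seed)
    ny, nx = shape
    # lamellar background: longer correlation along y (fibre direction)
    z = wp.background_sa_um / 0.8 * _correlated_noise(rng, shape, dx, 5.0, 14.0)
    z += wp.noise_um * rng.standard_normal(shape)

    # pores: Gaussian depressions
    area_mm2 = (ny * dx) * (nx * dx) * 1e-6
    density = wp.pore_density if porosity is None else porosity
    n_pores = rng.poisson(density * area_mm2)
    yy, xx = np.mgrid[0:ny, 0:nx] * dx
    for _ in range(n_pores):
        cx, cy = rng.uniform(0, nx * dx), rng.uniform(0, ny * dx)
        r = rng.uniform(3.0, 9.0)
        depth = rng.uniform(0.8, 2.5)
        z -= depth * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * r * r))

    if state == "GS":
        n = max(1, int(nx * dx / 18))  # dense fine scratches
        _add_grooves(z, rng, dx, n, wp.furrow_width_um["GS"],
                     wp.furrow_depth_um["GS"], ridge_frac=0.2)
    elif state == "SF":
        n = max(1, int(nx * dx / 60))  # sparse deep furrows
        _add_grooves(z, rng, dx, n, wp.furrow_width_um["SF"],
                     wp.furrow_depth_um["SF"], ridge_frac=0.25)

    meta = {"state": state, "seed": seed, "time_min": 0}
    return HeightMap.from_array(z, dx=dx, meta=meta)


def apply_wear(
    hm: HeightMap,
    material: str,
    minutes: float,
    wp: WearParams | None = None,
    seed: int = 0,
) -> HeightMap:
    """Material- and time-dependent erosion of a bone surface.

    Wear progresses as w(t) = 1 − exp(−rate·t).  Two height-dependent
    mechanisms act in material-specific mixture: *truncation* compresses
    heights above a moving quantile toward it (plateau formation on the
    contact zone), and *rounding* blends the surface toward a smoothed copy.
    Fine transverse striations 5-10 µm wide accumulate with wear.
    minutes = 0 returns the input unchanged.
    """
    if material not in MATERIALS:
        raise ValueError(f"unknown material type {material!r}")
    if minutes < 0:
        raise ValueError("minutes must be >= 0")
    wp = wp or WearParams()
    if minutes == 0:
        return hm.copy()
    rng = np.random.default_rng(seed)
    w = 1.0 - np.exp(-wp.rates[material] * minutes)
    z = hm.heights.copy()

    # truncation: heights above a moving quantile compressed toward it
    # (plateau formation under rigid abrasive contact)
    tshare = wp.truncate_share[material]
    if tshare > 0:
        q = 1.0 - 0.45 * w * tshare
        tau = np.nanquantile(z, q)
        above = z > tau
        z[above] = tau + (z[above] - tau) * (1.0 - 0.9 * w * tshare)

    # valley blunting: heights below a moving quantile pulled toward it
    # (moist, supple material polishing the furrow bottoms)
    vshare = wp.valley_share[material]
    if vshare > 0:
        taub = np.nanquantile(z, 0.45 * w * vshare)
        below = z < taub
        z[below] = taub + (z[below] - taub) * (1.0 - 0.75 * w * vshare)

    # rounding: blend toward a Gaussian-smoothed copy, weighted toward the
    # lower surface (summits persist as gentle domes)
    rshare = wp.round_share[material]
    if rshare > 0:
        smooth = ndimage.gaussian_filter(np.nan_to_num(z), 5.0 / hm.dx,
                                         mode="nearest")
        lo, hi = np.nanquantile(z, 0.05), np.nanquantile(z, 0.75)
        low_wt = np.clip((hi - z) / max(hi - lo, 1e-12), 0.0, 1.0)
        blend = np.clip(rshare * w * (low_wt + 0.3 * (1.0 - low_wt)), 0.0, 1.0)
        z = (1.0 - blend) * z + blend * smooth

    # fine material striations, 5-10 µm wide
    ny, nx = z.shape
    n_stri = int(2 * w * nx * hm.dx / 25)
    if n_stri > 0:
        _add_grooves(z, rng, hm.dx, n_stri, (5.0, 10.0), 0.12, ridge_frac=0.1)

    z[~hm.mask] = np.nan
    meta = dict(hm.meta)
    meta.update({"material": material, "time_min": minutes})
    out = hm.with_heights(z)
    out.meta = meta
    return out


def mold_of(
    hm: HeightMap,
    spc_bias: float = 0.3,
    jitter_px: float = 0.5,
    seed: int = 0,
) -> HeightMap:
    """Physical molding of a bone surface.

    The mold is the negative replica: rows flipped along y and heights
    negated.  ``jitter_px`` adds a sub-pixel registration shift (molds are
    never re-scanned in a perfectly identical frame) and ``spc_bias`` rounds
    the finest bone peaks slightly — mold material does not reach into the
    sharpest asperities, so mirrored-back molds show lower Spc than their
    bones.  With ``spc_bias=0, jitter_px=0`` the operation is exactly
    invertible by the preprocessing mirror.
    """
    rng = np.random.default_rng(seed)
    z = hm.heights.copy()
    if spc_bias > 0:
        # round only the sharpest summits: blend the top few percent of
        # heights toward a lightly smoothed copy
        smooth = ndimage.gaussian_filter(np.nan_to_num(z), 1.2, mode="nearest")
        thr = np.nanquantile(z, 0.9)
        hi = np.nanquantile(z, 0.999)
        wgt = spc_bias * np.clip((z - thr) / max(hi - thr, 1e-12), 0.0, 1.0)
        z = (1.0 - wgt) * z + wgt * smooth
    if jitter_px > 0:
        shift = rng.uniform(-jitter_px, jitter_px, size=2)
        z = ndimage.shift(np.nan_to_num(z), shift, order=3, mode="nearest")
    z = -z[::-1, :]
    meta = dict(hm.meta)
    meta["is_mold"] = True
    out = HeightMap(z, hm.mask[::-1, :].copy(), hm.dx, hm.dy, meta)
    return out


# ---------------------------------------------------------------------------
# Parametric observation generator (mirrors the statistical model)
# ---------------------------------------------------------------------------

def registry_scan_frame(registry: ExperimentRegistry,
                        rescan_specimens: int = 12) -> pd.DataFrame:
    """Scan-level metadata table for a registry (no texture values yet).

    Five crosswise locations per sample; optionally, the time-0 molds of the
    first ``rescan_specimens`` specimens are re-scanned a year later
    (``is_rescan`` rows), emulating the mold-stability check.
    """
    info = {s.specimen: s for s in registry.specimens}
    rows = []
    for sample in registry.samples:
        sp = info[sample.specimen]
        for loc in registry.locations:
            rows.append(
                dict(
                    specimen=sp.specimen, lot=sp.lot, state=sp.state,
                    material=sp.material, time_min=sample.time_min,
                    location=loc, is_mold=sample.is_mold, is_rescan=False,
                )
            )
    rescan_ids = {s.specimen for s in registry.specimens[:rescan_specimens]}
    extra = [
        dict(r, is_rescan=True)
        for r in rows
        if r["specimen"] in rescan_ids and r["is_mold"] and r["time_min"] == 0
    ]
    return pd.DataFrame(rows + extra)


def default_b_true(k: int = 16) -> np.ndarray:
    """Ground-truth fixed effects for the parametric generator (k x 4).

    Columns are (log Sa, log Sal, log Spc, log Smr1).  Rows follow the full
    interaction design: intercept, location LR/DP, bone-vs-mold, rescan,
    logTime, manufacture GS/SF, GS:logTime, SF:logTime, FS:logTime,
    PL:logTime, and the four three-way state:material:logTime terms.
    Values reproduce the study's qualitative geometry: state ordering at
    baseline, fresh skin declining Sa / rising Smr1 over time, lower Spc on
    molds.
    """
    B = np.zeros((16, 4))
    B[0] = [-0.7, 2.6, -2.6, 2.3]        # intercept (UW bone, location C)
    B[1] = [0.02, -0.03, 0.02, -0.02]    # location LR
    B[2] = [0.03, 0.02, -0.02, 0.01]     # location DP
    B[3] = [0.04, 0.02, -0.12, 0.03]     # bone-vs-mold (mold: lower Spc)
    B[4] = [0.01, 0.00, -0.01, 0.00]     # rescan test (molds stable)
    B[5] = [-0.02, 0.01, -0.01, 0.01]    # logTime (baseline DB slope)
    B[6] = [0.9, 0.55, 0.5, 0.35]        # manufacture GS
    B[7] = [1.5, 0.95, 0.8, 0.15]        # manufacture SF
    B[8] = [0.01, -0.01, -0.02, 0.00]    # GS : logTime
    B[9] = [0.02, -0.01, -0.02, -0.01]   # SF : logTime
    B[10] = [-0.16, 0.01, -0.10, 0.12]   # FS : logTime (fast transformation)
    B[11] = [-0.02, 0.00, -0.03, 0.01]   # PL : logTime
    B[12] = [0.06, 0.01, 0.02, -0.04]    # GS:FS:logTime (slower on worked bone)
    B[13] = [0.01, 0.00, 0.01, -0.01]    # GS:PL:logTime
    B[14] = [0.08, 0.01, 0.03, -0.05]    # SF:FS:logTime
    B[15] = [0.01, 0.00, 0.01, -0.01]    # SF:PL:logTime
    if k != 16:
        raise ValueError("the ground-truth effect matrix is defined for k=16")
    return B


def simulate_observation_table(
    registry: ExperimentRegistry,
    wp: WearParams | None = None,
    seed: int = 0,
    rescan_specimens: int = 12,
) -> pd.DataFrame:
    """Draw an observation table from the model's own generative structure.

    Lot and specimen intercepts are zero-mean Gaussians with SDs from
    ``wp``; rows receive multivariate Student-t noise with diagonal scale
    ``wp.error_scale`` and ``wp.student_t_df`` degrees of freedom.  The
    resulting log-scale 4-vectors are exponentiated into the raw-unit
    texture columns of the standard observation table.
    """
    from .model.design import build_fixed_design  # local to avoid cycle

    wp = wp or WearParams()
    if wp.student_t_df <= 2:
        raise ValueError("Student-t df must exceed 2")
    rng = np.random.default_rng(seed)
    frame = registry_scan_frame(registry, rescan_specimens=rescan_specimens)
    X, _ = build_fixed_design(frame, "M3")
    B = wp.b_true if wp.b_true is not None else default_b_true(X.shape[1])

    lots = registry.lots
    specs = [s.specimen for s in registry.specimens]
    u_lot = {l: rng.normal(0.0, wp.sd_lot, size=4) for l in lots}
    u_spec = {s: rng.normal(0.0, wp.sd_specimen, size=4) for s in specs}

    mean = X @ B
    mean += np.stack([u_spec[s] for s in frame["specimen"]])
    mean += np.stack([u_lot[l] for l in frame["lot"]])

    n = len(frame)
    scale = np.asarray(wp.error_scale)
    if np.any(scale > 0):
        g = rng.chisquare(wp.student_t_df, size=n) / wp.student_t_df
        noise = rng.standard_normal((n, 4)) * scale / np.sqrt(g)[:, None]
    else:
        noise = np.zeros((n, 4))
    logy = mean + noise

    out = frame.copy()
    for j, col in enumerate(("Sa_um", "Sal_um", "Spc_inv_um", "Smr1_pct")):
        out[col] = np.exp(logy[:, j])
    return out[TABLE_COLUMNS]
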