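"""Height-map container and file I/O.

A surface scan is a regular 2D grid of heights in micrometres with a boolean
mask of measured cells (confocal instruments routinely fail to measure steep
or poorly reflective cells).  Grid origin is the top-left corner; x runs along
columns, y along rows; ``dx``/``dy`` are the lateral spacings in µm.

Two text-friendly on-disk formats are supported:

* 32-bit float TIFF where NaN marks non-measured cells, with an optional JSON
  sidecar holding the lateral spacing and provenance;
* an ASCII matrix (``.asc``, whitespace-separated rows, ``nan`` for
  non-measured) with the same JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np


class DegenerateSurfaceError(ValueError):
    """Raised when a surface has too few measured points or zero variance."""


@dataclass
class HeightMap:
    """Regular grid of surface heights (µm) with a measured-cell mask.

    Parameters
    ----------
    heights : 2D float array, µm. Values at mask-False cells are ignored
        (conventionally NaN).
    mask : 2D bool array, True where the cell was measured.
    dx, dy : lateral spacing in µm (> 0).
    meta : free-form provenance dictionary.
    """

    heights: np.ndarray
    mask: np.ndarray
    dx: float
    dy: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2D grid")
        if self.heights.shape != self.mask.shape:
            raise ValueError(
                f"heights shape {self.heights.shape} != mask shape {self.mask.shape}"
            )
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError("lateral spacings dx, dy must be positive")

    # -- convenience -------------------------------------------------------
    @classmethod
    def from_array(
        cls,
        heights: np.ndarray,
        dx: float = 1.0,
        dy: float | None = None,
        meta: dict[str, Any] | None = None,
    ) -> "HeightMap":
        """Build a HeightMap from a plain array; NaNs become non-measured."""
        heights = np.asarray(heights, dtype=np.float64)
        mask = np.isfinite(heights)
        return cls(heights, mask, dx, dy if dy is not None else dx, meta or {})

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def n_measured(self) -> int:
        return int(self.mask.sum())

    @property
    def measured_fraction(self) -> float:
        return float(self.mask.mean())

    def measured_values(self) -> np.ndarray:
        """1D array of heights at measured cells."""
        return self.heights[self.mask]

    def copy(self) -> "HeightMap":
        return HeightMap(
            self.heights.copy(), self.mask.copy(), self.dx, self.dy, dict(self.meta)
        )

    def with_heights(self, heights: np.ndarray, mask: np.ndarray | None = None) -> "HeightMap":
        """New HeightMap sharing spacing/meta with replaced heights (and mask)."""
        return HeightMap(
            np.asarray(heights, dtype=np.float64),
            self.mask.copy() if mask is None else np.asarray(mask, dtype=bool),
            self.dx,
            self.dy,
            dict(self.meta),
        )

    def require_measured(self, n: int = 2) -> None:
        if self.n_measured < n:
            raise DegenerateSurfaceError(
                f"need at least {n} measured points, got {self.n_measured}"
            )


# -- I/O -------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_heightmap(hm: HeightMap, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write a HeightMap as float32 TIFF (NaN = non-measured) or ASCII matrix.

    The format is picked from the extension (``.tif``/``.tiff`` vs ``.asc``).
    A JSON sidecar with ``dx_um``, ``dy_um`` and ``meta`` is always written.
    """
    path = Path(path)
    z = hm.heights.astype(np.float32).copy()
    z[~hm.mask] = np.nan
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, z)
    elif path.suffix.lower() == ".asc":
        np.savetxt(path, z, fmt="%.9g")
    else:
        raise ValueError(f"unsupported height-map extension: {path.suffix}")
    sc = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    sc.write_text(
        json.dumps({"dx_um": hm.dx, "dy_um": hm.dy, "meta": hm.meta}, default=str)
    )


def read_heightmap(path: str | Path, sidecar: str | Path | None = None) -> HeightMap:
    """Read a HeightMap written by :func:`write_heightmap`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        z = np.asarray(tifffile.imread(path), dtype=np.float64)
    elif path.suffix.lower() == ".asc":
        z = np.loadtxt(path, dtype=np.float64)
    else:
        raise ValueError(f"unsupported height-map extension: {path.suffix}")
    sc = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    dx = dy = 1.0
    meta: dict[str, Any] = {}
    if sc.exists():
        info = json.loads(sc.read_text())
        dx = float(info.get("dx_um", 1.0))
        dy = float(info.get("dy_um", dx))
        meta = info.get("meta", {}) or {}
    return HeightMap.from_array(z, dx=dx, dy=dy, meta=meta)
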