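"""Fractal neutral landscapes and sequential habitat-loss gradients.

The simulated world is a binary raster (forest / open vegetation) of
100 x 100 cells at 10 m resolution, i.e. a 1 km^2 landscape.  Synthetic
landscapes are produced in two steps:

1. a real-valued fractal surface with tunable spatial autocorrelation
   (Hurst exponent ``hurst``), generated by 2-D spectral synthesis with
   power spectrum proportional to ``f**-(2*hurst + 2)``;
2. thresholding that one surface at a series of forest-cover levels by
   descending rank, which yields a *sequential* deforestation gradient:
   the forest cell set at any lower cover level is an exact subset of the
   forest set at any higher level, and the realised cover matches the
   nominal level up to integer rounding of the cell count.

High ``hurst`` (the default experiments use 0.9) produces large, smooth,
clumped habitat patches, so rank thresholding removes habitat from patch
edges first, emulating real-world sequential deforestation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FractalSurface",
    "LandscapeGrid",
    "GradientSet",
    "GridFormatError",
    "generate_surface",
    "make_gradient",
    "read_ascii_grid",
    "write_ascii_grid",
]

FOREST = 1
OPEN = 0


class GridFormatError(ValueError):
    """Raised when an ASCII grid file does not follow the Esri standard."""


@dataclass(frozen=True)
class FractalSurface:
    """A spatially autocorrelated random field on a regular grid."""

    values: np.ndarray
    hurst: float
    seed: int
    method: str = "spectral"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class LandscapeGrid:
    """Binary land-cover raster; 1 = forest, 0 = open vegetation.

    The world does not wrap in either direction (``wrap`` is kept as an
    explicit property so the simulator can assert it).
    """

    cover: np.ndarray
    cell_size: float = 10.0
    wrap: bool = False

    def __post_init__(self) -> None:
        cover = np.asarray(self.cover, dtype=np.int8)
        if cover.ndim != 2 or min(cover.shape) < 1:
            raise ValueError("cover must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not np.isin(cover, (FOREST, OPEN)).all():
            raise ValueError("cover must be binary (0 = open, 1 = forest)")
        object.__setattr__(self, "cover", cover)

    @property
    def n_rows(self) -> int:
        return self.cover.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cover.shape[1]

    @property
    def n_cells(self) -> int:
        return self.cover.size

    @property
    def forest_fraction(self) -> float:
        return float(self.cover.sum()) / self.n_cells

    def __eq__(self, other) -> bool:  # value semantics for tests
        return (
            isinstance(other, LandscapeGrid)
            and self.cell_size == other.cell_size
            and self.cover.shape == other.cover.shape
            and bool((self.cover == other.cover).all())
        )


@dataclass(frozen=True)
class GradientSet:
    """One base surface thresholded at an increasing series of cover levels."""

    surface: FractalSurface
    levels: tuple[float, ...]
    grids: tuple[LandscapeGrid, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.grids):
            raise ValueError("levels and grids must align")


def generate_surface(
    hurst: float, seed: int, n_rows: int = 100, n_cols: int = 100
) -> FractalSurface:
    """Generate a fractal surface by 2-D spectral synthesis.

    Complex Gaussian noise in the Fourier domain is scaled by
    ``f**-(hurst + 1)`` (power spectrum ``f**-(2*hurst + 2)``) and
    inverse-transformed; the real part is returned.  Roughness decreases
    as ``hurst`` approaches 1.  Deterministic for fixed arguments.
    """
    if not 0 < hurst <= 1:
        raise ValueError(f"hurst must lie in (0, 1], got {hurst}")
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid must be at least 2 x 2")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_rows, n_cols)) + 1j * rng.standard_normal(
        (n_rows, n_cols)
    )
    fy = np.fft.fftfreq(n_rows)[:, None]
    fx = np.fft.fftfreq(n_cols)[None, :]
    freq = np.hypot(fy, fx)
    amplitude = np.zeros_like(freq)
    nonzero = freq > 0
    amplitude[nonzero] = freq[nonzero] ** -(hurst + 1.0)
    values = np.fft.ifft2(noise * amplitude).real
    values = np.ascontiguousarray(values)
    values.setflags(write=False)
    return FractalSurface(values=values, hurst=hurst, seed=seed)


def make_gradient(
    surface: FractalSurface,
    levels: Sequence[float],
    cell_size: float = 10.0,
    min_cover: float = 0.0,
) -> GradientSet:
    """Threshold one surface at each cover level by descending value rank.

    A cell is forest at level ``c`` iff its surface rank (descending,
    ties broken by row-major position) falls within the top
    ``floor(c * n_cells)`` cells.  This makes the forest sets nested
    across levels and the realised cover exact up to integer rounding.

    ``min_cover`` sets a floor on the effective cover of every level
    (default 0, i.e. the nominal levels are honoured exactly).
    """
    levels = tuple(float(c) for c in levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    for c in levels:
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"cover level {c} outside [0, 1]")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly increasing")

    values = surface.values
    n_cells = values.size
    # Stable argsort of -values: ties fall back to flattened (row, col) order.
    order = np.argsort(-values.ravel(), kind="stable")
    rank = np.empty(n_cells, dtype=np.int64)
    rank[order] = np.arange(n_cells)

    grids = []
    for c in levels:
        k = int(np.floor(max(c, min_cover) * n_cells))
        cover = (rank < k).reshape(values.shape).astype(np.int8)
        grids.append(LandscapeGrid(cover=cover, cell_size=cell_size))
    return GradientSet(surface=surface, levels=levels, grids=tuple(grids))


# ---------------------------------------------------------------------------
# Esri ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def write_ascii_grid(grid: LandscapeGrid, path: str | Path) -> None:
    """Write a LandscapeGrid as an Esri ASCII grid (1 = forest, 0 = open)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {grid.cell_size:g}\n")
        fh.write("NODATA_value -9999\n")
        for row in grid.cover:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> LandscapeGrid:
    """Read a binary Esri ASCII grid into a LandscapeGrid.

    Raises GridFormatError naming the offending line on malformed
    headers, ragged rows, or non-binary cell values.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    idx = 0
    while idx < len(lines):
        parts = lines[idx].split()
        if not parts:
            idx += 1
            continue
        key = parts[0].lower()
        if key in _HEADER_KEYS or key == "nodata_value":
            if len(parts) != 2:
                raise GridFormatError(
                    f"{path}: line {idx + 1}: malformed header entry {lines[idx]!r}"
                )
            try:
                header[key] = float(parts[1])
            except ValueError:
                raise GridFormatError(
                    f"{path}: line {idx + 1}: non-numeric header value {parts[1]!r}"
                ) from None
            idx += 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridFormatError(f"{path}: missing header keys {missing}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    if n_cols < 1 or n_rows < 1 or header["ncols"] != n_cols or header["nrows"] != n_rows:
        raise GridFormatError(f"{path}: ncols/nrows must be positive integers")
    if header["cellsize"] <= 0:
        raise GridFormatError(f"{path}: cellsize must be positive")

    rows = []
    for offset, line in enumerate(lines[idx:]):
        lineno = idx + offset + 1
        parts = line.split()
        if not parts:
            continue
        if len(parts) != n_cols:
            raise GridFormatError(
                f"{path}: line {lineno}: expected {n_cols} values, got {len(parts)}"
            )
        try:
            row = [int(v) for v in parts]
        except ValueError:
            raise GridFormatError(
                f"{path}: line {lineno}: non-integer cell value"
            ) from None
        if any(v not in (FOREST, OPEN) for v in row):
            raise GridFormatError(
                f"{path}: line {lineno}: non-binary cell value (expected 0 or 1)"
            )
        rows.append(row)
    if len(rows) != n_rows:
        raise GridFormatError(
            f"{path}: expected {n_rows} data rows, got {len(rows)}"
        )
    return LandscapeGrid(
        cover=np.array(rows, dtype=np.int8), cell_size=header["cellsize"]
    )


def write_gradient(
    gradient: GradientSet, out_dir: str | Path, prefix: str = "landscape"
) -> Path:
    """Write one .asc per level plus a JSON manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for level, grid in zip(gradient.levels, gradient.grids):
        name = f"{prefix}_cover{round(level * 100):03d}.asc"
        write_ascii_grid(grid, out_dir / name)
        entries.append(
            {
                "level": level,
                "file": name,
                "realised_cover": grid.forest_fraction,
            }
        )
    manifest = {
        "hurst": gradient.surface.hurst,
        "seed": gradient.surface.seed,
        "method": gradient.surface.method,
        "levels": entries,
    }
    manifest_path = out_dir / f"{prefix}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
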