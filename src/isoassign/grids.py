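"""Georeferenced raster grids and aligned isoscape stacks.

The spatial carrier for every surface in the package is :class:`RasterGrid`,
a single-band grid of per-mil values on a regular lon/lat lattice with a
validity mask.  Grids are stored on disk as ESRI ASCII rasters (``.asc``), a
plain-text single-band format with an explicit nodata sentinel, so fixtures
and outputs stay portable and diffable.

Conventions
-----------
* Row 0 is the **northernmost** row (standard ESRI ASCII order).
* Cell centres carry the value: the centre of cell ``(row, col)`` is at
  ``lon = xllcorner + (col + 0.5) * cellsize`` and
  ``lat = yllcorner + (nrows - row - 0.5) * cellsize``.
* Invalid cells hold NaN in ``values`` and are excluded from every sum,
  sort and statistic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "RasterGrid",
    "IsoscapeStack",
    "ISOTOPE_ORDER",
    "read_raster",
    "write_raster",
    "align_stack",
]

#: Canonical isotope layer order used everywhere in the package.
ISOTOPE_ORDER = ("d2H", "d13C", "d15N")

DEFAULT_NODATA = -9999.0


class RasterError(ValueError):
    """Raised for malformed rasters or geometry violations."""


@dataclass(frozen=True)
class RasterGrid:
    """A single-band georeferenced grid with a validity mask.

    Parameters
    ----------
    values
        2-D float array; invalid cells are NaN.
    xllcorner, yllcorner
        Longitude/latitude of the lower-left corner of the grid, decimal
        degrees.
    cellsize
        Cell edge length in decimal degrees (identical in both axes).
    nodata
        Sentinel written to disk for invalid cells.
    """

    values: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float = 0.33
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] < 1 or vals.shape[1] < 1:
            raise RasterError(f"grid must be 2-D with >=1 row and column, got shape {vals.shape}")
        if not (np.isfinite(self.cellsize) and self.cellsize > 0):
            raise RasterError(f"cellsize must be strictly positive, got {self.cellsize}")
        vals = np.where(vals == self.nodata, np.nan, vals)
        if np.any(np.isinf(vals)):
            raise RasterError("valid cells must hold finite values (found inf)")
        object.__setattr__(self, "values", vals)

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean grid, True where the cell holds a finite value."""
        return np.isfinite(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.xllcorner - other.xllcorner) <= tol
            and abs(self.yllcorner - other.yllcorner) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the centre of cell ``(row, col)``; row 0 is north."""
        nrows = self.shape[0]
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.yllcorner + (nrows - row - 0.5) * self.cellsize
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (lon, lat) of every cell centre, each shaped like the grid."""
        nrows, ncols = self.shape
        lon = self.xllcorner + (np.arange(ncols) + 0.5) * self.cellsize
        lat = self.yllcorner + (nrows - np.arange(nrows) - 0.5) * self.cellsize
        return np.broadcast_to(lon, (nrows, ncols)).copy(), np.broadcast_to(lat[:, None], (nrows, ncols)).copy()

    # -- derivation -------------------------------------------------------

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        """Same geometry, new values (mask follows the new values' NaNs)."""
        return replace(self, values=np.asarray(values, dtype=float))

    def masked_where_invalid(self, mask: np.ndarray) -> "RasterGrid":
        """Return a grid whose cells outside ``mask`` are invalidated."""
        vals = np.where(mask, self.values, np.nan)
        return self.with_values(vals)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_raster(path: str | Path, nodata_policy: str = "mask") -> RasterGrid:
    """Read a single-band ESRI ASCII grid.

    ``nodata_policy`` is ``"mask"`` (nodata and non-finite cells become
    invalid, the default) or ``"strict"`` (any nodata cell raises).
    """
    path = Path(path)
    if not path.exists():
        raise RasterError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value", "dx", "dy"):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header and k not in ("cellsize",)]
    if "cellsize" not in header:
        dx, dy = header.get("dx"), header.get("dy")
        if dx is None or dy is None:
            missing.append("cellsize")
        elif abs(dx - dy) > 1e-12:
            raise RasterError(f"non-uniform cell size: dx={dx} differs from dy={dy}")
        else:
            header["cellsize"] = dx
    if missing:
        raise RasterError(f"{path}: missing header keys {missing}")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    try:
        data = np.loadtxt(lines[n_header:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise RasterError(f"{path}: unreadable grid body: {exc}") from exc
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise RasterError(
            f"{path}: body shape {data.shape} does not match header ({nrows}, {ncols})"
        )
    if nodata_policy == "strict" and np.any(data == nodata):
        raise RasterError(f"{path}: nodata cells present under strict policy")
    return RasterGrid(
        values=data,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=nodata,
    )


def write_raster(grid: RasterGrid, path: str | Path) -> Path:
    """Write a grid as an ESRI ASCII raster; returns the path written."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nrows, ncols = grid.shape
    out = np.where(grid.valid_mask, grid.values, grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner!r}\n")
        fh.write(f"yllcorner {grid.yllcorner!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# Isoscape stacks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsoscapeStack:
    """Aligned per-isotope mean-surface rasters (the mu_b vector field).

    All layers share geometry and the intersection validity mask, enforced
    at construction via :func:`align_stack`.  ``provenance`` records, per
    layer, where the surface came from and what calibration was applied.
    """

    layers: Mapping[str, RasterGrid]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise RasterError(
                f"multi-isotope stack needs >=2 layers, got {sorted(self.layers)}"
            )
        unknown = set(self.layers) - set(ISOTOPE_ORDER)
        if unknown:
            raise RasterError(f"unknown isotope layer(s): {sorted(unknown)}")

    @property
    def isotopes(self) -> tuple[str, ...]:
        """Layer names in canonical (d2H, d13C, d15N) order."""
        return tuple(iso for iso in ISOTOPE_ORDER if iso in self.layers)

    @property
    def template(self) -> RasterGrid:
        return self.layers[self.isotopes[0]]

    @property
    def valid_mask(self) -> np.ndarray:
        return self.template.valid_mask

    def __iter__(self) -> Iterator[tuple[str, RasterGrid]]:
        for iso in self.isotopes:
            yield iso, self.layers[iso]

    def __getitem__(self, isotope: str) -> RasterGrid:
        return self.layers[isotope]

    def __contains__(self, isotope: str) -> bool:
        return isotope in self.layers

    def mean_matrix(self, isotopes: tuple[str, ...] | None = None) -> np.ndarray:
        """Stack layer values as an (n_valid, d) matrix over valid cells."""
        isos = tuple(isotopes) if isotopes else self.isotopes
        mask = self.valid_mask
        return np.column_stack([self.layers[iso].values[mask] for iso in isos])

    def subset(self, isotopes: tuple[str, ...]) -> "IsoscapeStack":
        missing = [iso for iso in isotopes if iso not in self.layers]
        if missing:
            raise RasterError(f"stack is missing isotope layer(s): {missing}")
        return align_stack(
            {iso: self.layers[iso] for iso in isotopes},
            provenance={iso: self.provenance.get(iso, "") for iso in isotopes},
        )


def align_stack(
    layers: Mapping[str, RasterGrid],
    provenance: Mapping[str, str] | None = None,
) -> IsoscapeStack:
    """Verify layer geometry and build a stack on the intersection mask.

    No resampling is performed: any geometry mismatch (shape, origin or
    cell size) raises naming the offending layer.
    """
    if len(layers) < 2:
        raise RasterError(f"align_stack needs >=2 layers, got {len(layers)}")
    canonical = {iso: layers[iso] for iso in ISOTOPE_ORDER if iso in layers}
    extra = set(layers) - set(canonical)
    if extra:
        raise RasterError(f"unknown isotope layer(s): {sorted(extra)}")
    names = list(canonical)
    ref_name, ref = names[0], canonical[names[0]]
    for name in names[1:]:
        g = canonical[name]
        if g.shape != ref.shape:
            raise RasterError(
                f"layer {name!r} shape {g.shape} mismatches {ref_name!r} {ref.shape}"
            )
        if abs(g.cellsize - ref.cellsize) > 1e-9:
            raise RasterError(
                f"layer {name!r} cellsize {g.cellsize} mismatches {ref_name!r} {ref.cellsize}"
            )
        if abs(g.xllcorner - ref.xllcorner) > 1e-9 or abs(g.yllcorner - ref.yllcorner) > 1e-9:
            raise RasterError(
                f"layer {name!r} origin ({g.xllcorner}, {g.yllcorner}) mismatches "
                f"{ref_name!r} ({ref.xllcorner}, {ref.yllcorner})"
            )
    mask = np.logical_and.reduce([g.valid_mask for g in canonical.values()])
    if not mask.any():
        raise RasterError("intersection of layer masks is empty")
    aligned = {name: g.masked_where_invalid(mask) for name, g in canonical.items()}
    return IsoscapeStack(layers=aligned, provenance=dict(provenance or {}))
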