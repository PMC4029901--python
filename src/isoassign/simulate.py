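"""Synthetic isoscapes, feather cohorts and range polygons.

The generator reproduces the statistical structure the assignment model
assumes — smooth per-isotope mean fields over a gridded study region, a
spatially stationary variance-covariance, individuals whose isotope
vectors are MVN draws around their true origin cell's means — so every
pipeline stage is exercisable without any external download.  Nothing
here attempts geographic realism; see docs/methods.md for what the
generator does and does not emulate.

Mean fields are a linear plane (the large-scale gradient) plus seeded
Gaussian-filtered white noise (small-scale structure with a controllable
length scale).  True origins are written to a separate truth table that
assignment code never reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon, mapping

from .feathers import FeatherRecord, write_feathers
from .grids import IsoscapeStack, RasterGrid, align_stack, write_raster

__all__ = [
    "FieldSpec",
    "SimulationConfig",
    "make_isoscape",
    "make_stack",
    "simulate_feathers",
    "make_range_polygon",
    "write_bundle",
]

_ISO_INDEX = {"d2H": 0, "d13C": 1, "d15N": 2}


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one isotope's synthetic mean surface (permil units).

    ``gradient`` is (per-cell change along x, per-cell change along y);
    ``noise_amplitude`` is the standard deviation of the smooth noise and
    ``length_scale`` its correlation length in cells.
    """

    level: float
    gradient: tuple[float, float]
    noise_amplitude: float = 0.0
    length_scale: float = 4.0


def _default_fields() -> dict[str, FieldSpec]:
    # Feather-equivalent envelopes: d2H roughly -110..-20, d13C -22..-8,
    # d15N 5..13 permil across the default 48x40 grid.
    return {
        "d2H": FieldSpec(level=-65.0, gradient=(1.9, 0.4), noise_amplitude=6.0),
        "d13C": FieldSpec(level=-15.0, gradient=(-0.05, 0.28), noise_amplitude=1.2),
        "d15N": FieldSpec(level=9.0, gradient=(0.08, -0.12), noise_amplitude=0.9),
    }


def _default_sigma() -> np.ndarray:
    # Within-cell feather spread: sds (12, 1.8, 1.6) permil with mild
    # positive correlations (H-C 0.30, H-N 0.10, C-N 0.20).
    sd = np.array([12.0, 1.8, 1.6])
    corr = np.array([[1.0, 0.30, 0.10], [0.30, 1.0, 0.20], [0.10, 0.20, 1.0]])
    return corr * np.outer(sd, sd)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; outputs are pure functions of this."""

    seed: int = 0
    nrows: int = 40
    ncols: int = 48
    cellsize: float = 0.33
    xllcorner: float = -18.0
    yllcorner: float = -35.0
    fields: Mapping[str, FieldSpec] = field(default_factory=_default_fields)
    sigma_true: np.ndarray = field(default_factory=_default_sigma)
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"collared": 36, "pied": 24, "hybrid": 15}
    )
    #: hybrids split by maternal species (collared mothers, pied mothers)
    hybrid_maternal_split: tuple[int, int] = (5, 10)
    origin_scheme: str = "uniform"  # uniform | per_group_region | fixed
    fixed_origin: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma_true, dtype=float)
        eig = np.linalg.eigvalsh(sigma)
        if eig[0] <= 0:
            raise ValueError(f"sigma_true must be positive definite, min eig {eig[0]:.3e}")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if self.origin_scheme not in ("uniform", "per_group_region", "fixed"):
            raise ValueError(f"unknown origin scheme {self.origin_scheme!r}")
        object.__setattr__(self, "sigma_true", sigma)


def make_isoscape(config: SimulationConfig, isotope: str) -> RasterGrid:
    """Deterministic smooth mean field: plane + seeded smoothed noise."""
    spec = config.fields[isotope]
    rng = np.random.default_rng([config.seed, _ISO_INDEX[isotope]])
    cols = np.arange(config.ncols)
    rows = np.arange(config.nrows)
    gx, gy = spec.gradient
    # y increases northwards; row 0 is the northernmost row
    plane = spec.level + gx * (cols[None, :] - config.ncols / 2) + gy * (
        (config.nrows - 1 - rows[:, None]) - config.nrows / 2
    )
    if spec.noise_amplitude > 0:
        white = rng.standard_normal((config.nrows, config.ncols))
        smooth = ndimage.gaussian_filter(white, sigma=spec.length_scale, mode="reflect")
        sd = smooth.std()
        noise = spec.noise_amplitude * smooth / sd if sd > 0 else np.zeros_like(smooth)
    else:
        noise = 0.0
    return RasterGrid(
        values=plane + noise,
        xllcorner=config.xllcorner,
        yllcorner=config.yllcorner,
        cellsize=config.cellsize,
    )


def make_stack(config: SimulationConfig) -> IsoscapeStack:
    layers = {iso: make_isoscape(config, iso) for iso in config.fields}
    return align_stack(layers, provenance={iso: "synthetic" for iso in layers})


# ---------------------------------------------------------------------------
# Range polygons
# ---------------------------------------------------------------------------


def make_range_polygon(config: SimulationConfig, which: str) -> Polygon:
    """Rectangular stand-in wintering ranges in disjoint sub-regions.

    ``"west"`` occupies the western third of the grid (echoing a western
    wintering range), ``"southeast"`` the south-eastern quadrant.  The
    rectangles snap to cell edges so rasterized areas are exact.
    """
    cs = config.cellsize
    x0, y0 = config.xllcorner, config.yllcorner
    width, height = config.ncols * cs, config.nrows * cs
    if which == "west":
        return Polygon(
            [
                (x0 + 1 * cs, y0 + 0.25 * height),
                (x0 + width / 3, y0 + 0.25 * height),
                (x0 + width / 3, y0 + 0.85 * height),
                (x0 + 1 * cs, y0 + 0.85 * height),
            ]
        )
    if which == "southeast":
        return Polygon(
            [
                (x0 + 0.55 * width, y0 + 1 * cs),
                (x0 + width - 1 * cs, y0 + 1 * cs),
                (x0 + width - 1 * cs, y0 + 0.45 * height),
                (x0 + 0.55 * width, y0 + 0.45 * height),
            ]
        )
    raise ValueError(f"unknown range {which!r} (expected 'west' or 'southeast')")


def _cells_in_polygon(grid: RasterGrid, poly: Polygon) -> np.ndarray:
    import shapely

    lon, lat = grid.cell_centers()
    inside = shapely.contains_xy(poly, lon.ravel(), lat.ravel()).reshape(grid.shape)
    return inside & grid.valid_mask


# ---------------------------------------------------------------------------
# Feather cohorts
# ---------------------------------------------------------------------------

_GROUP_REGION = {"collared": "southeast", "pied": "west", "hybrid": "west"}


def simulate_feathers(
    config: SimulationConfig, stack: IsoscapeStack
) -> tuple[list[FeatherRecord], pd.DataFrame]:
    """Draw a cohort: origin cell per the origin scheme, then y* ~ MVN(mu_b, Sigma).

    Returns the records plus a truth table (id, group, true_row, true_col)
    that must be kept apart from any assignment input.
    """
    rng = np.random.default_rng([config.seed, 1000])
    mask = stack.valid_mask
    isotopes = stack.isotopes
    idx = {iso: i for i, iso in enumerate(("d2H", "d13C", "d15N"))}
    sel = [idx[iso] for iso in isotopes]
    sigma = config.sigma_true[np.ix_(sel, sel)]

    region_cells: dict[str, np.ndarray] = {}
    if config.origin_scheme == "per_group_region":
        for group, region in _GROUP_REGION.items():
            poly = make_range_polygon(config, region)
            cells = np.argwhere(_cells_in_polygon(stack.template, poly))
            if cells.size == 0:
                raise ValueError(f"origin region {region!r} has no valid cells")
            region_cells[group] = cells
    all_cells = np.argwhere(mask)
    if all_cells.size == 0:
        raise ValueError("no valid cells to draw origins from")

    records: list[FeatherRecord] = []
    truth_rows = []
    counter = 0
    maternal_pool = ["collared"] * config.hybrid_maternal_split[0] + [
        "pied"
    ] * config.hybrid_maternal_split[1]
    for group, n in config.group_sizes.items():
        for j in range(n):
            counter += 1
            if config.origin_scheme == "fixed":
                if config.fixed_origin is None:
                    raise ValueError("fixed origin scheme requires fixed_origin")
                row, col = config.fixed_origin
            elif config.origin_scheme == "per_group_region":
                cells = region_cells.get(group, all_cells)
                row, col = cells[rng.integers(len(cells))]
            else:
                row, col = all_cells[rng.integers(len(all_cells))]
            mu = np.array([stack[iso].values[row, col] for iso in isotopes])
            y = rng.multivariate_normal(mu, sigma, method="cholesky")
            maternal = None
            if group == "hybrid":
                maternal = maternal_pool[j % len(maternal_pool)] if j < len(maternal_pool) else (
                    "pied" if j % 2 else "collared"
                )
            rid = f"{group[:3]}_{counter:03d}"
            records.append(
                FeatherRecord(
                    id=rid,
                    group=group,
                    values={iso: float(v) for iso, v in zip(isotopes, y)},
                    maternal_species=maternal,
                )
            )
            truth_rows.append(
                {"id": rid, "group": group, "true_row": int(row), "true_col": int(col)}
            )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------


def write_bundle(
    config: SimulationConfig,
    outdir: str | Path,
    d2h_slope: float = 0.95,
    d2h_intercept: float = -12.0,
    d13c_discrimination: float = 2.0,
    d15n_discrimination: float = 5.0,
) -> dict[str, Path]:
    """Write a complete runnable input bundle.

    Feathers are drawn from the *feather* isoscapes; the environmental
    rasters on disk are back-transformed through the calibration so that
    running the pipeline's calibration step recovers the generating
    feather surfaces exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = make_stack(config)
    records, truth = simulate_feathers(config, stack)

    paths: dict[str, Path] = {}
    back = {
        "d2H": stack["d2H"].with_values((stack["d2H"].values - d2h_intercept) / d2h_slope),
        "d13C": stack["d13C"].with_values(stack["d13C"].values - d13c_discrimination),
        "d15N": stack["d15N"].with_values(stack["d15N"].values - d15n_discrimination),
    }
    fname = {"d2H": "d2h_precip.asc", "d13C": "d13c_plant.asc", "d15N": "d15n_plant.asc"}
    for iso, grid in back.items():
        if iso in stack.isotopes:
            paths[iso] = write_raster(grid, outdir / fname[iso])

    paths["feathers"] = write_feathers(records, outdir / "feathers.csv")
    truth.to_csv(outdir / "truth.csv", index=False)
    paths["truth"] = outdir / "truth.csv"

    features = []
    for name, region in (("west_range", "west"), ("southeast_range", "southeast")):
        poly = make_range_polygon(config, region)
        features.append(
            {"type": "Feature", "properties": {"name": name}, "geometry": mapping(poly)}
        )
    ranges_path = outdir / "ranges.geojson"
    with open(ranges_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=2)
    paths["ranges"] = ranges_path

    cfg = {
        "isoscapes": {
            "d2H": fname["d2H"],
            "d13C": fname["d13C"],
            "d15N": fname["d15N"],
        },
        "feathers": "feathers.csv",
        "ranges": "ranges.geojson",
        "output_dir": "results",
        "calibration": {
            "d2h_slope": d2h_slope,
            "d2h_intercept": d2h_intercept,
            "d13c_discrimination": d13c_discrimination,
            "d15n_discrimination": d15n_discrimination,
        },
        "isotope_subsets": [["d2H", "d13C", "d15N"], ["d2H", "d13C"]],
        "level": 0.67,
        "groups": ["collared", "pied", "hybrid"],
        "seed": config.seed,
    }
    cfg_path = outdir / "pipeline.yaml"
    import yaml

    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    paths["config"] = cfg_path
    return paths
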