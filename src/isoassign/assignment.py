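"""Multivariate-normal assignment of individuals to geographic origin.

The model: a feather grown in raster cell ``b`` has an isotope vector
distributed MVN(mu_b, Sigma), where mu_b is read off the calibrated
feather isoscapes and Sigma — the measurement/individual variance-
covariance — is assumed spatially stationary (identical at every cell).
For an individual with measured vector y*, evaluating the density

    f(b | y*) = (2 pi)^(-d/2) |Sigma|^(-1/2)
                exp(-1/2 (y* - mu_b)^T Sigma^{-1} (y* - mu_b))

over every valid cell yields a likelihood-of-origin surface.  The
individual's plausible origin region is the smallest set of cells whose
normalized likelihood mass reaches a stated odds level (0.67 by default);
those cells are coded 1, all others 0.  Group-level origin maps sum the
binary surfaces and rescale by the per-cell maximum count.

Numerics: densities are computed in log space via a Cholesky factor of
Sigma; exponentiation shifts by the per-surface maximum log density when
the raw densities would underflow (the shift is recorded, and every
downstream statistic is invariant to it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from scipy import linalg

from .feathers import FeatherRecord
from .grids import ISOTOPE_ORDER, IsoscapeStack, RasterGrid

__all__ = [
    "CovarianceModel",
    "LikelihoodSurface",
    "BinarySurface",
    "PopulationSurface",
    "RangeMask",
    "RangeConsistency",
    "estimate_covariance",
    "mvnpdf_surface",
    "binarize_upper_density",
    "aggregate_population",
    "rasterize_range",
    "range_consistency",
    "run_group_assignment",
]

#: Default odds level for the plausible-origin region.
DEFAULT_LEVEL = 0.67


class AssignmentError(ValueError):
    """Raised on degenerate covariance, geometry mismatch or empty input."""


class UniformSurfaceWarning(UserWarning):
    """Emitted when binarization meets a perfectly uniform surface."""


# ---------------------------------------------------------------------------
# Covariance estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovarianceModel:
    """The stationary variance-covariance of feather isotope vectors.

    ``sigma`` holds isotope variances on the diagonal and pairwise
    covariances off-diagonal, in the order given by ``isotopes``.  The
    sample mean is carried for diagnostics only; assignment uses the
    per-cell isoscape means.
    """

    isotopes: tuple[str, ...]
    mean: np.ndarray
    sigma: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=float)
        d = len(self.isotopes)
        if sigma.shape != (d, d):
            raise AssignmentError(
                f"sigma shape {sigma.shape} does not match {d} isotopes"
            )
        if not np.allclose(sigma, sigma.T, atol=1e-12):
            raise AssignmentError("sigma is not symmetric (tolerance 1e-12)")
        eigvals, eigvecs = np.linalg.eigh(sigma)
        if eigvals[0] <= 0:
            direction = ", ".join(
                f"{w:+.3f}*{iso}" for w, iso in zip(eigvecs[:, 0], self.isotopes)
            )
            raise AssignmentError(
                f"sigma is not positive definite (min eigenvalue {eigvals[0]:.3e}); "
                f"deficient direction: {direction}"
            )
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))

    def subset(self, isotopes: Sequence[str]) -> "CovarianceModel":
        idx = [self.isotopes.index(iso) for iso in isotopes]
        return CovarianceModel(
            isotopes=tuple(isotopes),
            mean=self.mean[idx],
            sigma=self.sigma[np.ix_(idx, idx)],
            n_samples=self.n_samples,
        )


def estimate_covariance(
    feathers: Sequence[FeatherRecord],
    isotopes: Sequence[str] | None = None,
    ridge: float = 0.0,
) -> CovarianceModel:
    """Maximum-likelihood covariance from complete-case isotope vectors.

    The MLE on n complete records is the 1/n scatter matrix
    ``Sigma = (1/n) sum_i (y_i - ybar)(y_i - ybar)^T``.  Records missing
    any selected isotope are dropped (their count is reported via a
    warning).  ``ridge`` optionally adds a small constant to the diagonal;
    it defaults to 0 and is never applied silently.
    """
    isos = tuple(isotopes) if isotopes else ISOTOPE_ORDER
    complete = [f for f in feathers if f.is_complete(isos)]
    n_dropped = len(feathers) - len(complete)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} record(s) missing one of {isos} dropped from covariance estimation",
            stacklevel=2,
        )
    d = len(isos)
    if len(complete) < d + 1:
        raise AssignmentError(
            f"need >= {d + 1} complete records for {d}-isotope covariance, "
            f"got {len(complete)}"
        )
    y = np.array([f.vector(isos) for f in complete])
    ybar = y.mean(axis=0)
    centered = y - ybar
    sigma = centered.T @ centered / len(complete)
    if ridge:
        sigma = sigma + ridge * np.eye(d)
        warnings.warn(f"ridge {ridge} added to covariance diagonal", stacklevel=2)
    return CovarianceModel(isotopes=isos, mean=ybar, sigma=sigma, n_samples=len(complete))


# ---------------------------------------------------------------------------
# Likelihood surfaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LikelihoodSurface:
    """Per-cell density f(b | y*) for one individual.

    ``log_shift`` is the constant subtracted from log densities before
    exponentiation when the raw densities would underflow; it is 0.0
    whenever true densities are representable.  All downstream statistics
    (normalization, binarization) are invariant to the shift.
    """

    grid: RasterGrid
    individual_id: str
    isotopes: tuple[str, ...]
    log_shift: float = 0.0

    def __post_init__(self) -> None:
        vals = self.grid.values[self.grid.valid_mask]
        if vals.size == 0:
            raise AssignmentError("likelihood surface has no valid cells")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise AssignmentError("likelihood values must be finite and >= 0")
        if not np.any(vals > 0):
            raise AssignmentError(
                f"likelihood surface for {self.individual_id!r} is zero everywhere"
            )


def mvnpdf_surface(
    record: FeatherRecord,
    stack: IsoscapeStack,
    cov: CovarianceModel,
    isotopes: Sequence[str] | None = None,
) -> LikelihoodSurface:
    """Evaluate the MVN density of y* against every valid cell's mu_b."""
    isos = tuple(isotopes) if isotopes else cov.isotopes
    missing = [iso for iso in isos if iso not in stack]
    if missing:
        raise AssignmentError(f"stack is missing isotope layer(s): {missing}")
    sub_cov = cov if isos == cov.isotopes else cov.subset(isos)
    y = record.vector(isos)
    d = len(isos)

    mask = stack.valid_mask
    mu = np.column_stack([stack[iso].values[mask] for iso in isos])  # (n_valid, d)
    diff = y[None, :] - mu

    try:
        chol = linalg.cholesky(sub_cov.sigma, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - guarded by CovarianceModel
        raise AssignmentError(f"covariance not positive definite: {exc}") from exc
    # Mahalanobis^2 via triangular solve: z = L^{-1} (y - mu)
    z = linalg.solve_triangular(chol, diff.T, lower=True)
    maha_sq = np.einsum("ij,ij->j", z, z)
    log_det = 2.0 * np.sum(np.log(np.diag(chol)))
    log_f = -0.5 * (d * np.log(2.0 * np.pi) + log_det + maha_sq)

    log_max = float(log_f.max())
    shift = 0.0
    if log_max < np.log(np.finfo(float).tiny) + 50.0:
        shift = log_max  # raw densities underflow; store shifted (scale-free) values
    dens = np.exp(log_f - shift)

    values = np.full(mask.shape, np.nan)
    values[mask] = dens
    return LikelihoodSurface(
        grid=stack.template.with_values(values),
        individual_id=record.id,
        isotopes=isos,
        log_shift=shift,
    )


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinarySurface:
    """The 0/1 plausible-origin map for one individual."""

    grid: RasterGrid
    achieved_mass: float
    individual_id: str
    level: float = DEFAULT_LEVEL

    def __post_init__(self) -> None:
        vals = self.grid.values[self.grid.valid_mask]
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise AssignmentError("binary surface must hold only 0/1 on valid cells")
        if self.achieved_mass < self.level - 1e-12:
            raise AssignmentError(
                f"achieved mass {self.achieved_mass} below requested level {self.level}"
            )


def coslat_weights(grid: RasterGrid) -> np.ndarray:
    """Cosine-latitude cell-area weights for the optional area-weighted mode."""
    _, lat = grid.cell_centers()
    return np.cos(np.deg2rad(lat))


def binarize_upper_density(
    surface: LikelihoodSurface,
    level: float = DEFAULT_LEVEL,
    weights: np.ndarray | None = None,
) -> BinarySurface:
    """Code the upper-``level`` odds region of a likelihood surface as 1.

    Valid-cell densities are normalized to sum to one, sorted descending,
    and the smallest prefix whose cumulative mass reaches ``level`` is
    selected; cells exactly tied with the last included value are all
    included, making the output order-independent.  A perfectly uniform
    surface therefore selects every cell (with a warning).

    By default every valid cell carries one unit of probability; pass
    ``weights`` (e.g. :func:`coslat_weights`) to weight cell mass by area.
    Ranking is always by density, so the selected region is unchanged in
    shape, only the mass accounting differs.
    """
    if not 0.0 < level < 1.0:
        raise AssignmentError(f"level must be in (0, 1), got {level}")
    mask = surface.grid.valid_mask
    dens = surface.grid.values[mask]
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape == mask.shape:
            w = w[mask]
        if w.shape != dens.shape or np.any(w <= 0):
            raise AssignmentError("weights must be positive and match the grid")
        cell_mass = dens * w
    else:
        cell_mass = dens
    total = cell_mass.sum()
    if total <= 0:
        raise AssignmentError("cannot binarize an all-zero surface")
    p = cell_mass / total

    order = np.argsort(dens, kind="stable")[::-1]  # rank by density
    cum = np.cumsum(p[order])
    k = int(np.searchsorted(cum, level - 1e-12)) + 1  # smallest prefix reaching level
    threshold = dens[order[k - 1]]
    selected = dens >= threshold  # full tie-class of the cut value
    achieved = float(p[selected].sum())

    if np.allclose(dens, dens[0]):
        warnings.warn(
            f"uniform likelihood surface for {surface.individual_id!r}: "
            "every valid cell is selected",
            UniformSurfaceWarning,
            stacklevel=2,
        )

    values = np.full(mask.shape, np.nan)
    values[mask] = selected.astype(float)
    return BinarySurface(
        grid=surface.grid.with_values(values),
        achieved_mass=achieved,
        individual_id=surface.individual_id,
        level=level,
    )


# ---------------------------------------------------------------------------
# Population aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSurface:
    """Per-cell counts of assigned individuals and the rescaled 0-1 map."""

    count: RasterGrid
    rescaled: RasterGrid
    group: str
    n_individuals: int
    max_count: int

    @property
    def max_count_proportion(self) -> float:
        """Max per-cell count over group sample size (the paper-style summary)."""
        return self.max_count / self.n_individuals


def aggregate_population(
    binaries: Sequence[BinarySurface], group: str = ""
) -> PopulationSurface:
    """Sum individual binary surfaces; rescale by the per-cell maximum."""
    if not binaries:
        raise AssignmentError("aggregate_population needs >=1 binary surface")
    template = binaries[0].grid
    for b in binaries[1:]:
        if not b.grid.same_geometry(template):
            raise AssignmentError(
                f"binary surface for {b.individual_id!r} has mismatched geometry"
            )
    mask = template.valid_mask
    counts = np.zeros(template.shape)
    for b in binaries:
        counts += np.where(b.grid.valid_mask, b.grid.values, 0.0)
    max_count = int(counts[mask].max())
    rescaled_vals = counts / max_count if max_count > 0 else counts
    count_vals = np.where(mask, counts, np.nan)
    rescaled_vals = np.where(mask, rescaled_vals, np.nan)
    return PopulationSurface(
        count=template.with_values(count_vals),
        rescaled=template.with_values(rescaled_vals),
        group=group,
        n_individuals=len(binaries),
        max_count=max_count,
    )


# ---------------------------------------------------------------------------
# Range masks and consistency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RangeMask:
    """Boolean raster marking a wintering-range polygon on the grid."""

    grid: RasterGrid  # 1.0 inside, 0.0 outside (valid cells only)
    name: str

    @property
    def mask(self) -> np.ndarray:
        return np.nan_to_num(self.grid.values) > 0.5


def rasterize_range(polygon, template: RasterGrid, name: str = "") -> RangeMask:
    """Mark cells whose centre lies inside ``polygon``.

    The result is intersected with the template's validity mask; a polygon
    covering no valid cell centre is an error.
    """
    lon, lat = template.cell_centers()
    inside = shapely.contains_xy(polygon, lon.ravel(), lat.ravel()).reshape(template.shape)
    inside &= template.valid_mask
    if not inside.any():
        raise AssignmentError(
            f"range polygon {name!r} covers no valid cell centre on the grid"
        )
    values = np.where(template.valid_mask, inside.astype(float), np.nan)
    return RangeMask(grid=template.with_values(values), name=name)


@dataclass(frozen=True)
class RangeConsistency:
    """Min/max proportion of a sample isotopically consistent with a range.

    Two conventions for the minimum are reported: over all in-range cells
    (``min_proportion``, which is 0 whenever any in-range cell received no
    assignments) and over in-range cells with a nonzero count
    (``min_proportion_nonzero``).
    """

    range_name: str
    group: str
    n: int
    min_proportion: float
    max_proportion: float
    min_proportion_nonzero: float


def range_consistency(
    pop: PopulationSurface, mask: RangeMask, n: int | None = None
) -> RangeConsistency:
    """Min and max per-cell assignment counts inside a range, over sample size."""
    if n is None:
        n = pop.n_individuals
    if n < 1:
        raise AssignmentError(f"sample size must be >= 1, got {n}")
    if not mask.grid.same_geometry(pop.count):
        raise AssignmentError("range mask geometry does not match population surface")
    inside = mask.mask
    if not inside.any():
        raise AssignmentError(f"range mask {mask.name!r} is empty")
    counts = pop.count.values[inside]
    nonzero = counts[counts > 0]
    return RangeConsistency(
        range_name=mask.name,
        group=pop.group,
        n=n,
        min_proportion=float(counts.min()) / n,
        max_proportion=float(counts.max()) / n,
        min_proportion_nonzero=(float(nonzero.min()) / n) if nonzero.size else 0.0,
    )


# ---------------------------------------------------------------------------
# Group-level orchestration
# ---------------------------------------------------------------------------


def run_group_assignment(
    feathers: Sequence[FeatherRecord],
    stack: IsoscapeStack,
    cov: CovarianceModel,
    isotopes: Sequence[str] | None = None,
    level: float = DEFAULT_LEVEL,
    group: str = "",
) -> tuple[list[BinarySurface], PopulationSurface]:
    """Deterministic mvnpdf -> binarize -> aggregate for one group."""
    isos = tuple(isotopes) if isotopes else cov.isotopes
    sub = stack.subset(isos) if set(isos) != set(stack.isotopes) else stack
    binaries = [
        binarize_upper_density(mvnpdf_surface(f, sub, cov, isos), level=level)
        for f in feathers
    ]
    return binaries, aggregate_population(binaries, group=group)
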