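"""The central assignment computation, checked against brute-force oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal
from shapely.geometry import Point, Polygon

from isoassign.assignment import (
    AssignmentError,
    BinarySurface,
    CovarianceModel,
    LikelihoodSurface,
    UniformSurfaceWarning,
    aggregate_population,
    binarize_upper_density,
    estimate_covariance,
    mvnpdf_surface,
    range_consistency,
    rasterize_range,
    run_group_assignment,
)
from isoassign.feathers import FeatherRecord
from isoassign.grids import RasterGrid, align_stack

from conftest import random_grid

ISO3 = ("d2H", "d13C", "d15N")


def record(values, rid="f1", group="pied"):
    return FeatherRecord(id=rid, group=group, values=dict(zip(ISO3, values)))


def random_stack(rng, shape=(5, 5), frac_invalid=0.1):
    spans = {"d2H": (-110, -20), "d13C": (-22, -8), "d15N": (4, 13)}
    layers = {}
    base = random_grid(rng, shape=shape, frac_invalid=frac_invalid)
    for iso, (lo, hi) in spans.items():
        vals = rng.uniform(lo, hi, size=shape)
        vals[~base.valid_mask] = np.nan
        layers[iso] = base.with_values(vals)
    return align_stack(layers)


def random_cov(rng, d=3, scale=(12.0, 1.8, 1.6)):
    a = rng.normal(size=(d, d))
    corr_seed = a @ a.T + d * np.eye(d)
    dinv = np.diag(1 / np.sqrt(np.diag(corr_seed)))
    corr = dinv @ corr_seed @ dinv
    s = np.diag(scale[:d])
    return s @ corr @ s


def surface_from(grid_vals, rid="f1"):
    g = RasterGrid(values=np.asarray(grid_vals, dtype=float), xllcorner=0, yllcorner=0, cellsize=1.0)
    return LikelihoodSurface(grid=g, individual_id=rid, isotopes=ISO3)


# ---------------------------------------------------------------------------
# Covariance estimation
# ---------------------------------------------------------------------------


class TestEstimateCovariance:
    def test_perfect_collinearity_is_an_error(self):
        recs = [
            FeatherRecord(id=f"f{i}", group="g", values={"d2H": v, "d13C": v})
            for i, v in enumerate((0.0, 2.0, -2.0))
        ]
        with pytest.raises(AssignmentError, match="positive definite"):
            estimate_covariance(recs, ("d2H", "d13C"))

    def test_matches_hand_computed_scatter_matrix(self):
        # four toy vectors; MLE is the 1/n scatter around the sample mean
        y = np.array([[-60.0, -12.0], [-64.0, -10.0], [-58.0, -14.0], [-66.0, -12.0]])
        recs = [record(v, rid=f"f{i}") for i, v in enumerate(np.column_stack([y, np.zeros(4)]))]
        cov = estimate_covariance(recs, ("d2H", "d13C"))
        centered = y - y.mean(axis=0)
        expect = centered.T @ centered / 4
        np.testing.assert_allclose(cov.sigma, expect, rtol=1e-12)
        np.testing.assert_allclose(cov.mean, y.mean(axis=0))
        assert cov.n_samples == 4

    def test_recovery_shrinks_with_n(self, rng):
        """MLE converges: within 5% entrywise of the generating Sigma at n=10000."""
        sigma_true = random_cov(rng)
        mu = np.array([-60.0, -12.0, 8.0])

        def fit(n):
            y = rng.multivariate_normal(mu, sigma_true, size=n)
            recs = [record(v, rid=f"f{i}") for i, v in enumerate(y)]
            return estimate_covariance(recs, ISO3).sigma

        scale = np.sqrt(np.outer(np.diag(sigma_true), np.diag(sigma_true)))
        err_small = np.max(np.abs(fit(100) - sigma_true) / scale)
        err_large = np.max(np.abs(fit(10_000) - sigma_true) / scale)
        assert err_large < err_small
        assert np.all(np.abs(fit(10_000) - sigma_true) <= 0.05 * scale)

    def test_incomplete_records_dropped_with_warning(self, rng):
        y = rng.multivariate_normal(np.zeros(3), np.eye(3) * 4, size=8)
        recs = [record(v, rid=f"f{i}") for i, v in enumerate(y)]
        recs.append(FeatherRecord(id="part", group="g", values={"d2H": -60.0, "d13C": -12.0}))
        with pytest.warns(UserWarning, match="1 record"):
            cov = estimate_covariance(recs, ISO3)
        assert cov.n_samples == 8

    def test_insufficient_n_errors(self):
        recs = [record([-60, -12, 8]), record([-61, -13, 9], rid="f2")]
        with pytest.raises(AssignmentError, match="need >="):
            estimate_covariance(recs, ISO3)

    def test_non_symmetric_sigma_rejected(self):
        s = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(AssignmentError, match="symmetric"):
            CovarianceModel(isotopes=("d2H", "d13C"), mean=np.zeros(2), sigma=s, n_samples=5)

    def test_deficient_direction_is_named(self):
        s = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(AssignmentError, match="d2H"):
            CovarianceModel(isotopes=("d2H", "d13C"), mean=np.zeros(2), sigma=s, n_samples=5)


# ---------------------------------------------------------------------------
# mvnpdf surfaces
# ---------------------------------------------------------------------------


class TestMvnpdfSurface:
    def test_density_at_exact_match_with_identity_sigma(self):
        vals = np.full((3, 3), -60.0)
        layers = {
            iso: RasterGrid(values=np.full((3, 3), v), xllcorner=0, yllcorner=0, cellsize=1.0)
            for iso, v in zip(ISO3, (-60.0, -12.0, 8.0))
        }
        stack = align_stack(layers)
        cov = CovarianceModel(isotopes=ISO3, mean=np.zeros(3), sigma=np.eye(3), n_samples=9)
        surf = mvnpdf_surface(record([-60.0, -12.0, 8.0]), stack, cov)
        # analytic maximum of a trivariate standard normal at its mean
        np.testing.assert_allclose(surf.grid.values, (2 * np.pi) ** -1.5, rtol=1e-12)
        assert vals.shape == surf.grid.shape

    def test_density_decreases_with_mahalanobis_distance(self, rng):
        stack = random_stack(rng, shape=(6, 6), frac_invalid=0.0)
        sigma = random_cov(rng)
        cov = CovarianceModel(isotopes=ISO3, mean=np.zeros(3), sigma=sigma, n_samples=10)
        y = np.array([-60.0, -12.0, 8.0])
        surf = mvnpdf_surface(record(y), stack, cov)
        si = np.linalg.inv(sigma)
        maha, dens = [], []
        for r in range(6):
            for c in range(6):
                diff = y - np.array([stack[iso].values[r, c] for iso in ISO3])
                maha.append(diff @ si @ diff)
                dens.append(surf.grid.values[r, c])
        order = np.argsort(maha)
        assert np.all(np.diff(np.array(dens)[order]) <= 1e-18)

    def test_matches_scipy_density_oracle(self, rng):
        """Cell-wise equality with an independent direct evaluation."""
        for _ in range(5):
            stack = random_stack(rng, shape=(5, 5), frac_invalid=0.15)
            sigma = random_cov(rng)
            cov = CovarianceModel(isotopes=ISO3, mean=np.zeros(3), sigma=sigma, n_samples=10)
            y = np.array([rng.uniform(-110, -20), rng.uniform(-22, -8), rng.uniform(4, 13)])
            surf = mvnpdf_surface(record(y), stack, cov)
            assert surf.log_shift == 0.0
            for r in range(5):
                for c in range(5):
                    if not stack.valid_mask[r, c]:
                        assert np.isnan(surf.grid.values[r, c])
                        continue
                    mu = np.array([stack[iso].values[r, c] for iso in ISO3])
                    expect = multivariate_normal(mean=mu, cov=sigma).pdf(y)
                    np.testing.assert_allclose(surf.grid.values[r, c], expect, rtol=1e-10)

    def test_underflow_handled_by_log_shift(self, rng):
        stack = random_stack(rng, shape=(4, 4), frac_invalid=0.0)
        tiny = np.diag([1e-6, 1e-6, 1e-6])
        cov = CovarianceModel(isotopes=ISO3, mean=np.zeros(3), sigma=tiny, n_samples=10)
        surf = mvnpdf_surface(record([500.0, 200.0, 300.0]), stack, cov)  # absurdly far
        assert surf.log_shift < 0
        vals = surf.grid.values[surf.grid.valid_mask]
        assert np.max(vals) == pytest.approx(1.0)  # shifted so the max is representable
        assert np.all(np.isfinite(vals))

    def test_missing_layer_errors(self, rng):
        stack = random_stack(rng).subset(("d2H", "d13C"))
        cov = CovarianceModel(isotopes=ISO3, mean=np.zeros(3), sigma=np.eye(3), n_samples=5)
        with pytest.raises(AssignmentError, match="d15N"):
            mvnpdf_surface(record([-60, -12, 8]), stack, cov, ISO3)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------


def brute_force_binarize(dens, level):
    """Independent sort-and-scan reference: smallest prefix + full tie class."""
    p = dens / dens.sum()
    order = np.argsort(-p)
    cum, included = 0.0, []
    for i in order:
        included.append(i)
        cum += p[i]
        if cum >= level - 1e-12:
            cut = p[i]
            included.extend(j for j in order if j not in included and p[j] == cut)
            break
    sel = np.zeros(len(p), dtype=bool)
    sel[included] = True
    return sel, p[sel].sum()


class TestBinarize:
    def test_uniform_surface_selects_everything_with_warning(self):
        surf = surface_from(np.full((10, 10), 0.01))
        with pytest.warns(UniformSurfaceWarning):
            b = binarize_upper_density(surf, level=0.67)
        assert np.all(b.grid.values == 1.0)
        assert b.achieved_mass == pytest.approx(1.0)

    def test_single_dominant_cell(self):
        vals = np.full((2, 5), 0.30 / 9)
        vals[0, 0] = 0.70
        b = binarize_upper_density(surface_from(vals), level=0.67)
        assert b.grid.values[0, 0] == 1.0
        assert np.sum(b.grid.values) == 1.0
        assert b.achieved_mass == pytest.approx(0.70)

    def test_matches_brute_force_scan(self, rng):
        for _ in range(20):
            shape = (rng.integers(2, 9), rng.integers(2, 9))
            vals = rng.exponential(size=shape)
            surf = surface_from(vals)
            b = binarize_upper_density(surf, level=0.67)
            sel, mass = brute_force_binarize(vals.ravel(), 0.67)
            np.testing.assert_array_equal(b.grid.values.ravel().astype(bool), sel)
            assert b.achieved_mass == pytest.approx(mass)
            assert b.achieved_mass >= 0.67

    def test_minimal_up_to_ties(self, rng):
        """Dropping the lowest included tie class pushes mass below the level."""
        for _ in range(10):
            vals = rng.exponential(size=(6, 6))
            b = binarize_upper_density(surface_from(vals), level=0.67)
            p = vals / vals.sum()
            included = p[b.grid.values == 1.0]
            cut = included.min()
            reduced = included[included > cut].sum()
            assert reduced < 0.67

    def test_level_monotonicity(self, rng):
        vals = rng.exponential(size=(7, 7))
        lo = binarize_upper_density(surface_from(vals), level=0.5)
        hi = binarize_upper_density(surface_from(vals), level=0.9)
        assert np.all(hi.grid.values >= lo.grid.values)

    def test_scale_invariance(self, rng):
        vals = rng.exponential(size=(6, 6))
        a = binarize_upper_density(surface_from(vals), level=0.67)
        b = binarize_upper_density(surface_from(vals * 3.7e5), level=0.67)
        np.testing.assert_array_equal(a.grid.values, b.grid.values)

    def test_invalid_level_rejected(self, rng):
        surf = surface_from(rng.exponential(size=(3, 3)))
        for level in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(AssignmentError, match="level"):
                binarize_upper_density(surf, level=level)

    def test_area_weighted_mode_changes_mass_not_ranking(self, rng):
        vals = rng.exponential(size=(6, 6))
        surf = surface_from(vals)
        w = rng.uniform(0.5, 1.0, size=(6, 6))
        b = binarize_upper_density(surf, level=0.67, weights=w)
        # selection is still a density superlevel set
        thresh = vals[b.grid.values == 1.0].min()
        np.testing.assert_array_equal(b.grid.values == 1.0, vals >= thresh)
        assert b.achieved_mass >= 0.67


# ---------------------------------------------------------------------------
# Aggregation, ranges, consistency
# ---------------------------------------------------------------------------


def binary_from(mask01, rid):
    g = RasterGrid(values=np.asarray(mask01, dtype=float), xllcorner=0, yllcorner=0, cellsize=1.0)
    return BinarySurface(grid=g, achieved_mass=1.0, individual_id=rid, level=0.67)


class TestAggregate:
    def test_single_individual_identity(self, rng):
        m = (rng.random((4, 4)) < 0.5).astype(float)
        m[0, 0] = 1.0
        pop = aggregate_population([binary_from(m, "f1")], group="g")
        np.testing.assert_array_equal(pop.count.values, m)
        np.testing.assert_array_equal(pop.rescaled.values, m)
        assert pop.max_count == 1

    def test_disjoint_regions_max_one(self):
        a = np.zeros((3, 3))
        a[0, :] = 1.0
        b = np.zeros((3, 3))
        b[2, :] = 1.0
        pop = aggregate_population([binary_from(a, "f1"), binary_from(b, "f2")])
        assert pop.max_count == 1
        assert set(np.unique(pop.rescaled.values)) <= {0.0, 1.0}

    def test_counts_match_brute_force(self, rng):
        masks = [(rng.random((5, 6)) < 0.4).astype(float) for _ in range(15)]
        masks[0][0, 0] = 1.0
        pop = aggregate_population([binary_from(m, f"f{i}") for i, m in enumerate(masks)])
        expect = np.zeros((5, 6))
        for m in masks:
            expect += m
        np.testing.assert_array_equal(pop.count.values, expect)
        np.testing.assert_allclose(pop.rescaled.values, expect / expect.max())
        assert np.nanmax(pop.rescaled.values) == 1.0
        assert pop.max_count_proportion == expect.max() / 15

    def test_geometry_mismatch_errors(self):
        a = binary_from(np.ones((3, 3)), "f1")
        g = RasterGrid(values=np.ones((3, 4)), xllcorner=0, yllcorner=0, cellsize=1.0)
        b = BinarySurface(grid=g, achieved_mass=1.0, individual_id="f2", level=0.67)
        with pytest.raises(AssignmentError, match="geometry"):
            aggregate_population([a, b])

    def test_empty_list_errors(self):
        with pytest.raises(AssignmentError, match=">=1"):
            aggregate_population([])


class TestRasterizeRange:
    def test_exact_rectangle_covers_nine_cells(self):
        template = RasterGrid(values=np.zeros((5, 5)), xllcorner=0, yllcorner=0, cellsize=1.0)
        poly = Polygon([(0, 0), (3, 0), (3, 3), (0, 3)])  # cells (rows 2..4, cols 0..2)
        mask = rasterize_range(poly, template, name="rect")
        assert mask.mask.sum() == 9

    def test_matches_point_in_polygon_over_centers(self, rng):
        template = random_grid(rng, shape=(8, 8), frac_invalid=0.1)
        w = 8 * template.cellsize
        poly = Polygon(
            [
                (template.xllcorner, template.yllcorner),
                (template.xllcorner + 0.53 * w, template.yllcorner),
                (template.xllcorner + 0.21 * w, template.yllcorner + w),
                (template.xllcorner, template.yllcorner + 0.7 * w),
            ]
        )
        mask = rasterize_range(poly, template, name="tri")
        for r in range(8):
            for c in range(8):
                lon, lat = template.cell_center(r, c)
                expect = poly.contains(Point(lon, lat)) and template.valid_mask[r, c]
                assert mask.mask[r, c] == expect

    def test_disjoint_polygon_errors(self, small_grid):
        poly = Polygon([(100, 100), (101, 100), (101, 101), (100, 101)])
        with pytest.raises(AssignmentError, match="no valid cell"):
            rasterize_range(poly, small_grid, name="far")

    def test_polygon_over_invalid_cells_errors(self):
        vals = np.ones((4, 4))
        vals[:2, :2] = np.nan
        g = RasterGrid(values=vals, xllcorner=0, yllcorner=0, cellsize=1.0)
        poly = Polygon([(0, 2), (2, 2), (2, 4), (0, 4)])  # exactly the invalid corner
        with pytest.raises(AssignmentError, match="no valid cell"):
            rasterize_range(poly, g, name="dead")


class TestRangeConsistency:
    def _pop(self, counts, n):
        g = RasterGrid(values=np.asarray(counts, dtype=float), xllcorner=0, yllcorner=0, cellsize=1.0)
        from isoassign.assignment import PopulationSurface

        mc = int(np.nanmax(counts))
        return PopulationSurface(
            count=g, rescaled=g.with_values(np.asarray(counts) / mc), group="g",
            n_individuals=n, max_count=mc,
        )

    def _mask(self, bool_grid):
        from isoassign.assignment import RangeMask

        g = RasterGrid(
            values=np.asarray(bool_grid, dtype=float), xllcorner=0, yllcorner=0, cellsize=1.0
        )
        return RangeMask(grid=g, name="r")

    def test_everyone_everywhere_gives_unity(self):
        pop = self._pop(np.full((2, 2), 10.0), 10)
        rc = range_consistency(pop, self._mask(np.ones((2, 2))), n=10)
        assert (rc.min_proportion, rc.max_proportion) == (1.0, 1.0)

    def test_enumerated_counts_both_conventions(self):
        counts = np.array([[0.0, 3.0], [7.0, 7.0]])
        rc = range_consistency(self._pop(counts, 10), self._mask(np.ones((2, 2))), n=10)
        assert rc.min_proportion == pytest.approx(0.0)
        assert rc.min_proportion_nonzero == pytest.approx(0.3)
        assert rc.max_proportion == pytest.approx(0.7)

    def test_order_properties(self, rng):
        for _ in range(5):
            n = 12
            counts = rng.integers(0, n + 1, size=(4, 4)).astype(float)
            counts[0, 0] = max(counts[0, 0], 1.0)
            inside = rng.random((4, 4)) < 0.6
            inside[0, 0] = True
            rc = range_consistency(self._pop(counts, n), self._mask(inside), n=n)
            assert rc.min_proportion <= rc.min_proportion_nonzero <= rc.max_proportion <= 1.0


# ---------------------------------------------------------------------------
# Group orchestration
# ---------------------------------------------------------------------------


class TestRunGroupAssignment:
    def test_group_of_one_equals_its_binary(self, rng):
        stack = random_stack(rng, shape=(6, 6))
        cov = CovarianceModel(isotopes=ISO3, mean=np.zeros(3), sigma=random_cov(rng), n_samples=5)
        rec = record([-60.0, -12.0, 8.0])
        binaries, pop = run_group_assignment([rec], stack, cov)
        np.testing.assert_array_equal(pop.rescaled.values, binaries[0].grid.values)

    def test_two_vs_three_isotope_variants(self, rng):
        stack = random_stack(rng, shape=(7, 7), frac_invalid=0.0)
        cov = CovarianceModel(isotopes=ISO3, mean=np.zeros(3), sigma=random_cov(rng), n_samples=8)
        recs = [record([-60.0 - i, -12.0, 8.0], rid=f"f{i}") for i in range(3)]
        _, pop3 = run_group_assignment(recs, stack, cov, ISO3)
        _, pop2 = run_group_assignment(recs, stack, cov, ("d2H", "d13C"))
        assert pop2.count.values.shape == pop3.count.values.shape
        assert not np.array_equal(pop2.count.values, pop3.count.values)

    def test_subset_consistency_with_constant_dropped_isotope(self, rng):
        """2-isotope run equals 3-isotope run when d15N is flat and uncorrelated."""
        base = random_stack(rng, shape=(6, 6), frac_invalid=0.0)
        flat = base["d15N"].with_values(np.full((6, 6), 8.0))
        stack = align_stack({"d2H": base["d2H"], "d13C": base["d13C"], "d15N": flat})
        s2 = random_cov(rng, d=2, scale=(12.0, 1.8))
        sigma = np.zeros((3, 3))
        sigma[:2, :2] = s2
        sigma[2, 2] = 1.6**2
        cov = CovarianceModel(isotopes=ISO3, mean=np.zeros(3), sigma=sigma, n_samples=9)
        recs = [record([-60.0 - 3 * i, -12.0 + i, 8.0], rid=f"f{i}") for i in range(4)]
        _, pop3 = run_group_assignment(recs, stack, cov, ISO3)
        _, pop2 = run_group_assignment(recs, stack, cov, ("d2H", "d13C"))
        np.testing.assert_array_equal(pop3.count.values, pop2.count.values)

    def test_end_to_end_matches_independent_recomputation(self, rng):
        """Per-cell counts equal an oracle built from scipy densities."""
        stack = random_stack(rng, shape=(8, 8), frac_invalid=0.1)
        sigma = random_cov(rng)
        cov = CovarianceModel(isotopes=ISO3, mean=np.zeros(3), sigma=sigma, n_samples=10)
        recs = [
            record(
                [rng.uniform(-110, -20), rng.uniform(-22, -8), rng.uniform(4, 13)],
                rid=f"f{i}",
            )
            for i in range(15)
        ]
        _, pop = run_group_assignment(recs, stack, cov, level=0.67)

        mask = stack.valid_mask
        expect = np.zeros(mask.shape)
        for rec in recs:
            y = rec.vector(ISO3)
            dens = np.zeros(mask.shape)
            for r in range(8):
                for c in range(8):
                    if mask[r, c]:
                        mu = np.array([stack[iso].values[r, c] for iso in ISO3])
                        dens[r, c] = multivariate_normal(mean=mu, cov=sigma).pdf(y)
            sel, _ = brute_force_binarize(dens[mask], 0.67)
            full = np.zeros(mask.shape, dtype=bool)
            full[mask] = sel
            expect += full
        np.testing.assert_array_equal(pop.count.values[mask], expect[mask])
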