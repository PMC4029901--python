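# Methods

## Assignment model

An individual's feather isotope vector **y\*** (any subset of δ²H, δ¹³C,
δ¹⁵N, in ‰) is modelled as multivariate normal around the predicted
feather means **μ**_b of its true origin cell *b*, with a single
variance–covariance matrix Σ shared by every cell (spatial stationarity).
The likelihood surface evaluates the MVN density of **y\*** at every
valid cell; nothing else about the cell (area, habitat, prior abundance)
enters, i.e. the implicit prior over cells is uniform.

Assumptions worth making explicit:

* **Stationary Σ.** The isotope covariance structure is identical
  everywhere on the map. Regionally varying covariance (e.g. agricultural
  δ¹⁵N enrichment) violates this; the package deliberately offers no
  non-stationary mode.
* **Σ from the unknown-origin sample.** Σ is estimated by maximum
  likelihood (the 1/n scatter matrix on complete cases) from the very
  feathers being assigned, pooled across all groups by default
  (`covariance_mode: per_group` re-estimates within each group). This
  conflates within-site measurement/individual variation with
  between-site spread when origins vary, which widens assignment regions;
  it is the operationally available estimate when no known-origin
  calibration set exists.
* **Isoscapes are treated as error-free means.** Isoscape model
  uncertainty is not propagated.

## Odds-region binarization

Valid-cell densities are normalized to sum to 1 and sorted in descending
order; the smallest prefix whose cumulative mass reaches the level
(default 0.67) is selected, then extended to include every cell exactly
tied with the last included value. Consequences: the achieved mass is
recorded and always ≥ the level; the selection is order-independent and
invariant to positive rescaling of the surface; a perfectly uniform
surface selects every cell (a warning is emitted). The cumulative-mass
reading of "upper 67%" follows the assignment literature's odds-region
usage; a raw-density-quantile reading would not guarantee any mass level.
By default every valid cell carries one unit of probability; an optional
area-weighted mode (cos-latitude cell weights) changes the mass
accounting but still ranks cells by density, so the selected region is a
density superlevel set either way.

## Numerics

* Densities are computed in log space through a Cholesky factor of Σ
  (triangular solve for the Mahalanobis term, log-determinant from the
  factor diagonal). Exponentiation subtracts the per-surface maximum log
  density only when raw densities would underflow; the shift is stored on
  the surface and every downstream statistic is invariant to it.
* Σ must be symmetric (≤1e−12) and positive definite; a failure names the
  deficient isotope direction (the eigenvector of the smallest
  eigenvalue). Degenerate Σ is never silently regularized — `ridge` adds
  a stated diagonal constant and logs it, default 0.
* Ties at the binarization threshold include the whole tie class
  (deterministic output); the level comparison uses a 1e−12 slack so that
  exact-mass prefixes are not missed to rounding.

## Isoscape and measurement calibration

Environmental surfaces are converted to feather surfaces before
assignment: δ²H via a user-supplied affine transfer function (slope and
intercept are **mandatory configuration** — they come from an external
regression of feather against precipitation values and no default could
be defended); δ¹³C and δ¹⁵N via constant plant-to-feather discrimination
offsets (+2‰ and +5‰ defaults).

Raw δ²H runs are calibrated by comparative equilibration: an OLS line
mapping measured to accepted values of the co-analysed keratin standards
(CFS −147±5‰, CHS −187±2‰, BWB-II −108±4‰), fitted per run. The
regression direction (accepted on measured) makes application a forward
map of raw sample values. The IAEA CH7 control is excluded from the fit
and appears only in QC. Reported sample values are means over available
replicates (triplicate by design; other counts are reported, not
rejected). QC flags any standard whose calibrated replicate spread
(max−min) exceeds a configurable bound, 4‰ by default; flagging never
removes data.

## Synthetic data generator

Each isotope's mean surface is a linear plane (the large-scale gradient)
plus Gaussian-filtered white noise with a set correlation length,
normalized to a set amplitude — enough spatial structure for assignment
to be informative, at desk-scale cost and fully deterministic given
(seed, config). Feather cohorts draw a true origin cell per individual
(uniform over valid cells, from per-group rectangular regions, or a fixed
cell) and then **y\*** ~ MVN(**μ**_b, Σ_true). True origins go to a
separate truth table that assignment code never reads.

Defaults, chosen once as field-plausible values: a 48×40 grid at 0.33°;
feather-equivalent envelopes δ²H ≈ −110…−20‰, δ¹³C ≈ −22…−8‰, δ¹⁵N ≈
5…13‰; Σ_true built from residual standard deviations (12, 1.8, 1.6)‰
with correlations (δ²H–δ¹³C 0.30, δ²H–δ¹⁵N 0.10, δ¹³C–δ¹⁵N 0.20); group
sizes 36/24/15 with the hybrid group split 5/10 by maternal species.
On-disk bundles back-transform the feather surfaces through the
calibration so the pipeline's calibration stage exactly recovers the
generating surfaces.

What the generator does **not** emulate: real African geography or
coastlines, isoscape model error, non-stationary covariance, diet and
microhabitat effects on δ¹³C/δ¹⁵N, or spatially clustered sampling.
Passing tests therefore demonstrate that the computation implements the
model faithfully and recovers known structure under the model's own
assumptions — not that assignments of real feathers are accurate, which
hinges on isoscape quality and the stationarity assumption.

## Calibration of the coverage checks

Two simulation regimes exercise the binary regions:

* **Fine-grid coverage.** With origins uniform over a 48×40 grid and
  assignment using the generating Σ, the posterior over cells is exactly
  the normalized likelihood, so the expected fraction of individuals
  whose true cell is coded 1 equals the expected achieved mass — just
  above the 0.67 level (measured ≈ 0.67–0.71 at 500 individuals).
* **Coarse-grid recovery.** When the per-cell mean step is ~3 residual
  standard deviations, origin regions shrink to one or two cells and the
  tie/overshoot effect raises the achieved mass, so the true-cell hit
  rate rises to ≥0.8 (measured ≈ 0.86 at 200 individuals on a 14×14
  grid). The signal-to-noise figure is per cell: step size in an
  isotope's mean surface divided by that isotope's residual sd.

## Design choices where the design was open

* **Raster dialect.** ESRI ASCII grids (plain text, single band, explicit
  nodata) are the canonical on-disk format: self-describing, diffable,
  and readable anywhere. Cell centres carry values; row 0 is north.
* **Min/max range consistency.** Whether the minimum should range over
  all in-range cells (trivially 0 when any cell is unassigned) or only
  over cells with nonzero counts is genuinely ambiguous; both are always
  computed (`min_proportion`, `min_proportion_nonzero`) and both appear
  in the output CSV.
* **Hybrid subgroup maps** partition the hybrid records by maternal
  species and re-run the identical pipeline; no separate computation.
* **Per-run equilibration lines** (not pooled across runs): instrument
  state differs between runs, and the run is the unit at which standards
  were co-analysed.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
grids from 5×5 (oracle comparisons against brute-force and
`scipy.stats.multivariate_normal` references, rtol 1e−10) to 48×40
(cohort analyses), cohorts of 75 (the default 36/24/15), 200–500
(coverage), and 10 000 (covariance recovery). The full default pipeline —
5 groups × 2 isotope subsets, maps and range statistics, run twice for a
determinism check — completes in seconds.

## Known limitations

* No reprojection or resampling: all layers must share geometry exactly.
* No posterior mapping without binarization, no abundance or
  ring-recovery priors, no non-stationary covariance.
* The δ²H transfer-function parameters must be supplied by the user;
  the package refuses to run without them.
* Range polygons are consumed as GeoJSON in the grid's own lon/lat space;
  no CRS handling.
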