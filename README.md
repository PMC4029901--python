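# isoassign

Spatially explicit multi-isotope assignment of migratory birds to their
moult origin.

Feathers are metabolically inert once grown, so the stable isotope ratios
locked into winter-grown feathers (δ²H vs VSMOW, δ¹³C vs VPDB, δ¹⁵N vs
AIR, all in ‰) record the environment of the wintering site where the
feather was moulted. Given gridded predictions of feather isotope values
across a candidate region ("isoscapes"), each sampled individual can be
assigned a likelihood-of-origin surface, and a population of samples can
be summarized as a map of how many individuals are isotopically
consistent with each cell. `isoassign` implements this workflow for
movement ecologists studying migratory connectivity — e.g. locating the
sub-Saharan wintering grounds of European breeding passerines and their
hybrids from feathers clipped on the breeding grounds.

## The model

For an individual with measured isotope vector **y\*** and a raster cell
*b* with predicted feather means **μ**_b, the likelihood of origin is the
multivariate normal density

    f(b | y*) = (2π)^(−d/2) |Σ|^(−1/2) exp(−½ (y* − μ_b)ᵀ Σ⁻¹ (y* − μ_b))

where *d* is the number of isotopes and Σ is the isotope
variance–covariance matrix, assumed spatially stationary (identical at
every cell) and estimated by maximum likelihood (the 1/n scatter matrix)
from the sampled feathers themselves. Cells in the **upper 67% of
normalized probability mass** — the smallest set of cells whose mass
reaches 0.67, ties included — are coded 1 (plausible origin), all others 0.
Summing the binary maps over a group's individuals and dividing by the
maximum per-cell count gives the population origin map; intersecting the
counts with a presumed wintering-range polygon yields the minimum and
maximum proportion of the sample isotopically consistent with that range.

Supporting stages: environmental→feather isoscape calibration (an affine
δ²H transfer function plus +2‰ / +5‰ plant-to-feather discrimination for
δ¹³C / δ¹⁵N), and comparative-equilibration calibration of raw δ²H runs
against keratin standards (CFS, CHS, BWB-II; IAEA CH7 as QC-only control)
with triplicate averaging and a 4‰ replicate-spread QC bound.

A fully tested synthetic-data generator produces isoscapes, feather
cohorts (default group sizes 36/24/15 with a 5/10 maternal split of the
hybrid group) and range polygons with the statistical structure the model
assumes, so the entire pipeline runs without any external data.

## Worked example

Generate a synthetic input bundle, run the full analysis, and summarize:

```sh
isoassign simulate --seed 42 --outdir demo
isoassign run demo/pipeline.yaml
isoassign report demo/results
```

which prints (abridged):

```
isoassign 0.1.0  config 888566378ad3880d
odds level: 0.67
  collared                   d2H+d13C+d15N  n=36  max_count=21  proportion=0.583
  pied                       d2H+d13C+d15N  n=24  max_count=12  proportion=0.500
  hybrid                     d2H+d13C+d15N  n=15  max_count=11  proportion=0.733
  hybrid_maternal_collared   d2H+d13C+d15N  n=5   max_count=5   proportion=1.000
  hybrid_maternal_pied       d2H+d13C+d15N  n=10  max_count=6   proportion=0.600
  ...
mean max-count proportion: 0.675 (range 0.500-1.000)
```

Each line is one group × isotope-subset analysis: `max_count` is the
largest number of that group's individuals assigned to any single cell,
and `proportion` divides it by the group's sample size — a high value
means the group's plausible origins pile up on common cells rather than
scattering. The run directory also holds per-analysis count and rescaled
(0–1) origin maps as ESRI ASCII rasters and `range_consistency.csv` with
the min/max proportion of each group consistent with each wintering-range
polygon (both zero-inclusive and zero-excluding minima are reported).

The same steps are available as library calls (`isoassign.pipeline.run`,
or the individual operations `mvnpdf_surface`, `binarize_upper_density`,
`aggregate_population`, `range_consistency`, …).

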