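# Methods

This note records the model, the numerical choices, and what the synthetic
test bed does and does not establish.

## Model and assumptions

The EQI is a linear composite of standardized indicator relative densities:
`EQI = Σ_i ω_i Z_i`. Its central assumption is that vegetation condition,
*relative to the best condition attainable in the same eco-geographical
zone and ecosystem type*, is a meaningful common scale across deserts,
tundra and rainforest. The stratified reference (`Fmax` per zone × type ×
year) is what makes a grassland pixel comparable to a forest pixel: each is
scored against its own reference population, not against the global
maximum. Consequences:

- A stratum's best pixel always scores IRD = 1, however degraded the
  stratum is in absolute terms. The index measures within-stratum relative
  condition, not absolute productivity.
- References are per year, so a stratum-wide collapse partially
  renormalizes away (the reference collapses too). The change analysis
  therefore detects *spatially differential* change within strata. A
  stratum entirely inside a changed area is the known blind spot; the
  `shared-baseline` standardization mode (below) mitigates the analogous
  drift in the z-scores but not the reference itself.

## Tunable parameters

| parameter | default | units / range | why |
|---|---|---|---|
| `reference_method` | `max` | max or upper percentile | the stratum maximum is the literal reference definition; `percentile` (`q = 0.99`) guards against single-pixel outliers in noisy products |
| standardization population | all valid pixels, per indicator, per year | — | global pooling keeps EQI comparable across strata, consistent with one study-wide classification; `per-stratum` pooling is available and removes between-stratum level differences |
| standardization σ | population (ddof = 0) | — | the z-score definition carries no sample correction; the difference is negligible at raster scale |
| `standardization` | `per-year` | per-year or shared-baseline | per-year re-estimation is the literal reading (references are per-year too); `shared-baseline` applies year-1 parameters to both years for ΔEQI free of re-standardization drift |
| `rho` | 0.85 | (0, 1] | cumulative contribution-rate threshold for retaining principal components |
| `loading_scale` | `unit` | unit or sqrt_eigenvalue | the importance formula does not fix whether loadings are raw unit eigenvectors or scaled by √α; both are implemented, `unit` is the default, and for the 3-indicator case the difference is small because retained contribution rates already weight the columns |
| loadings sign | absolute | — | signed loadings can produce negative importances, violating the weight contract (ω ≥ 0, Σω = 1); the signed variant exists behind a flag for sensitivity analysis |
| `n_classes` / breaks | 5, Jenks | — | five named levels; `brr-2016-2020` preset = (−0.97, −0.25, 0.44, 1.19) published thresholds |
| `jenks_sample_size` | 100 000 | pixels | exact DP on a seeded uniform subsample for very large rasters; seed recorded in provenance |
| `jenks_pooled_years` | true | — | both epochs share one set of breaks (one threshold set describes both years) |
| `change_thresholds` | ±0.05 | EQI units | the regional ecological-quality evaluation standard's significance band |
| `area_weighting` | pixel-count | or cell-area | cosine-of-latitude cell areas for geographic-CRS rasters |

## Numerical choices

- **Nearest-neighbor resampling** maps each output cell center to the
  nearest source cell center per axis; exact-half ties take the smaller
  row, then the smaller column (round-half-down on the fractional index).
  Output cells outside the source extent are nodata. No reprojection is
  performed: a CRS mismatch is an error, because silent reprojection hides
  georeferencing mistakes.
- **Grid alignment** compares integer shapes exactly and geotransform
  terms within 1e−9 (absolute).
- **Jenks** is the exact Fisher dynamic program on the sorted values,
  accelerated by divide-and-conquer monotone-argmin (the within-class SSE
  interval cost satisfies the concave Monge condition), O(k·n log n).
  Equal-cost partitions resolve to the one whose first class is smallest,
  then the second, and so on — realized by preferring the smaller split
  index at every suffix state. Breaks are the class maxima of classes
  1..k−1, matching the lower-open/upper-closed interval convention.
- **Eigendecomposition** uses the symmetric solver; eigenvalues are sorted
  descending, each eigenvector is signed so its largest-magnitude element
  is positive, and exactly tied eigenvalues are ordered by first differing
  loading. Weights are invariant to rotations within a tied eigenvalue
  block only in the symmetric cases covered by tests (e.g. a single
  retained component); when a tied block is partially retained the split
  of importance inside the block depends on the solver's basis.
- **Retained components**: `p` is the smallest count whose cumulative
  contribution rate reaches ρ (`searchsorted` on the cumulative sum, so a
  cumulative rate exactly equal to ρ retains that component).
- **Complete-case rule**: a pixel nodata in any indicator is excluded from
  references, standardization, PCA and EQI. A stratum left with zero
  observed pixels after this rule is dropped from the legend rather than
  failing the run (it has no reference population and no assessable
  pixels); a nonpositive reference is still a hard error because the
  relative density is undefined.
- **ASCII grids** are written with 17 significant digits, so float64
  values round-trip bit-exactly; this is what makes stage-wise CLI
  composition byte-identical to a single `run`.

## Synthetic scenarios

The generator fabricates what the method assumes: three nonnegative,
positively co-varying indicator fields on physical scales (LAI-like in
[0, 7], FVC-like in [0, 1], GPP-like in [0, 3000] — deliberately
heterogeneous units to stress the standardization), over contiguous
Voronoi-patch zones and land-cover, with sub-annual series, nodata holes
and paired epochs. Defaults: 200×200 cells at 1 km, 6 zones, 30 land-cover
patches over 7 first-level classes, Gaussian-copula target correlation 0.7
between all indicator pairs, a per-stratum common shift (sd 0.4) for
between-stratum contrast, 2% nodata in random disks per indicator-year, 4
sub-annual slices for LAI and 12 for FVC/GPP, and two planted 30×30 change
regions with EQI offsets +0.5 and −0.5.

Construction details that matter for interpreting tests:

- One sub-annual slice per indicator-year equals the annual field exactly
  and all others are scaled below it, so the MVC recovers the annual truth
  bit-exactly. This validates the compositing plumbing, not MVC's behavior
  on real phenology with residual cloud contamination.
- Planted increases pull year-2 values toward the year-1 stratum
  reference by a fraction `1 − exp(−|offset|)` of the remaining headroom;
  decreases scale values down by the same fraction. Each stratum's year-1
  reference pixel is held fixed, and land-cover patches touching a change
  region are forced to vegetation classes, so the sign of the planted
  ΔEQI is stable by construction and recoverable through the per-year
  reference step.
- Year 2 is identical to year 1 outside planted regions. Passing the
  sign-recovery test therefore shows the pipeline's arithmetic and
  renormalization behave correctly, not that the index is robust to
  inter-annual phenological noise, sensor drift, or LULC change — none of
  which the generator emulates.
- The copula targets Pearson correlation on the latent normals; after the
  quantile transform the realized correlation is slightly lower
  (≈ 0.68 for a 0.7 target), inside the tolerance the tests use.
- Sub-annual calendars are per indicator (quarterly vs 8-day style); the
  MVC composites each indicator over its own calendar, so no
  cross-calendar alignment exists or is needed.

## Design choices in open territory

- The importance formula is implemented with absolute loadings (see the
  weight contract above); the two-year weight average is renormalized to
  sum exactly 1 (a no-op up to rounding for valid inputs). Importances are
  normalized over all indicators, which is the only reading under which
  the weights always sum to 1.
- `Fmax` is computed per year (the reference definition indexes the
  year); Jenks breaks are estimated on the pooled two-epoch EQI values by
  default, since one set of level thresholds is meant to describe both
  epochs.
- Zone maps are inputs, not derived products: zone delineations are
  cartographic, and labels are treated as opaque strings.
- Change tables report both denominators — percent of the total valid
  study area and percent within the zone/type/stratum — because published
  change figures alternate between the two.

## Known limitations

- No reprojection, no mosaicking, no gap-filling, no QA masking: inputs
  must be co-registered single-CRS products.
- The maximum reference is outlier-sensitive; the percentile option is a
  blunt guard, not an outlier model.
- Jenks on a subsample is exact for the subsample, not the full raster;
  with the default 10⁵ sample the break jitter is far below the class
  widths, but very long-tailed EQI distributions may warrant a larger
  sample.
- Problem sizes in the test suite (200×200 end-to-end scenarios, 10⁵-point
  weighting experiments) are chosen to keep the full validation suite
  fast while leaving every estimate's sampling error well inside the
  asserted tolerances.
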