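# Methods

This note records the model, the conventions, and the design choices behind
`greenexposure`, in the order the pipeline runs.

## Raster model and preprocessing

A raster is a north-up grid of square cells in one projected planar
coordinate system (meters). The center of cell (row r, col c) is at
(origin_x + (c + 0.5)·s, origin_y − (r + 0.5)·s) for cell size s; every
point-in-cell decision in the package uses centers, which makes zonal
results exactly reproducible by exhaustive scans. Nodata exists in memory
only as a boolean mask; on disk it is a sentinel value (default −9999)
recorded in the GeoTIFF `GDAL_NODATA` tag. GeoTIFF I/O supports exactly the
subset the pipeline produces — one float64 band, square pixels,
`ModelPixelScale`/`ModelTiepoint` georeferencing — and a write/read round
trip is bit-exact.

Preprocessing order is fixed: integer-storage scaling (×10⁻⁴ for typical
satellite NDVI products) → NDVI (if starting from NIR/red bands) → bilinear
refinement to the working resolution → clip → water filter → stack. Water
(NDVI strictly < 0; zero survives) is masked *after* interpolation, so the
interpolator never mixes values across a mask edge and the water boundary is
resolved at the fine grid. Interpolation clamps to the nearest edge value
outside the hull of input centers, so border addresses lose no buffer cells
to resampling artifacts; where part of a 4-neighborhood is masked, the
remaining weights are renormalized, and a fully masked neighborhood yields a
masked output cell. Bilinear refinement cannot create values outside the
input range, so NDVI stays in [−1, 1] by construction.

## Exposure extraction

The exposure of address i in year t at radius r is the unweighted arithmetic
mean of valid cell values whose centers lie within distance r of the point
(boundary included). Choices worth stating:

- **Center-in-disc inclusion.** Area-weighted partial coverage was rejected:
  it is not exactly testable, and at a 100 m working cell against 300–1000 m
  radii the difference is second order.
- **Equal weights.** All included cells contribute equally; a distance-decay
  kernel is a natural refinement but changes the estimand and is out of
  scope.
- **Missingness.** Masked (water/nodata) cells carry no weight; a buffer
  with zero valid cells yields a missing value, never zero. Buffers
  truncated by the raster edge use whatever cells exist, with no
  renormalization penalty — mirroring addresses near a study-area border.

Default radii are 300, 600 and 1000 m; the exposure matrix always carries
the full years × radii cross product of columns.

## Statistical battery

All tests are two-sided and rank-based; exposure distributions are typically
skewed, so normal-theory tests are avoided throughout.

- **Summaries.** SD uses the n−1 divisor; skewness g1 = m3/m2^{3/2} and
  *excess* kurtosis g2 = m4/m2² − 3 use 1/n central moments (a constant
  sample reports both as undefined); quartiles interpolate linearly between
  order statistics.
- **Spearman matrix.** Per column pair, Pearson correlation of mid-ranks
  with pairwise deletion of missing values; two-sided p from the
  t-approximation on n − 2 df; Holm adjustment over the whole family of
  unique off-diagonal pairs. A constant column has no defined rank
  correlation and propagates as missing with a warning.
- **Wilcoxon rank-sum.** Statistic W = mid-rank sum of the first sample.
  For untied problems with na + nb ≤ 10 the two-sided p is computed by exact
  enumeration of all C(na+nb, na) rank allocations; otherwise by the normal
  approximation with tie-corrected variance and a 0.5 continuity
  correction. The approximation tracks the exact distribution to within
  0.05 once both samples have ≥ 3 observations; below that it is materially
  off (worst ≈ 0.13), which is precisely why the exact path exists.
- **Pairwise year tests.** Every unordered year pair within one radius
  (66 pairs for 12 years). The default is the *unpaired* rank-sum test — the
  literal reading of the design — even though year columns share addresses;
  a paired signed-rank variant is available behind a flag and is far more
  powerful against small common shifts. Holm families are scoped per radius
  by default, because results are reported as one triangle per buffer; a
  `global` scope pooling all radii is a switch.
- **Fligner–Killeen.** Normal scores Φ⁻¹(1/2 + r_i/(2(N+1))) of jointly
  mid-ranked absolute deviations from group medians; X² compares group score
  means against χ²(k−1). Chosen over Levene/Bartlett for robustness to
  non-normal exposures.
- **Holm.** Step-down: sort p ascending, adjusted_(i) = max_{j≤i}
  min(1, (m−j+1)p_(j)), returned in input order. Dominates Bonferroni,
  controls FWER under arbitrary dependence.
- **Trend.** OLS of *annual mean* exposure on calendar year (12 points per
  radius), matching how a trend line over yearly boxplots is drawn; fitting
  through address-level points would weight years by sample size instead.

Stored p-values are never rounded; display conventions (e.g. printing "0"
for p < 0.0005) are left to the caller.

## Monte Carlo sensitivity

A single random address sample could be unlucky, so the initial sample's
mean exposure at each (year, radius) is situated in a reference distribution
built from R = 100 draws of m = 1000 addresses (defaults; scaled down in the
shipped configuration) from the address pool *excluding* the initial
sample. Draws are without replacement within a draw and independent across
draws. The verdict is the literal ± 1 reference-SD band; a z-score and the
empirical percentile are reported alongside because a one-SD band is an
unusual acceptance region. R ≥ 2 is enforced (the reference SD is undefined
otherwise).

Under exchangeability — initial sample and pool drawn from one address
register — the initial mean's standard error is √(m/n_init) ≈ 0.45 of the
band half-width at the scaled sizes (n_init = 1000, m = 200), so the band
covers a well-behaved initial sample ≈ 95% of the time; the test suite
verifies ≥ 90% over 50 seeded register splits. When the initial sample and
the pool are *independently placed* point sets on a strongly autocorrelated
scene, both means carry independent patch-level noise that does not shrink
with m, and coverage at small scaled extents drops below the nominal
level. At full study scale (thousands of correlation lengths per extent)
the effect is negligible; at the shipped 20 km default extent it is visible
in `montecarlo.csv` and is a property of the scaled scene, not of the
procedure.

## Synthetic scenes

The generator fabricates what the analysis needs and nothing more:

- **Spatial structure.** Per year, Gaussian white noise smoothed with an
  isotropic Gaussian kernel (σ = spatial_range in map units), standardized
  to mean 0, SD 1. Kernel smoothing was chosen over spectral synthesis
  because the downstream checks depend only on the presence and scale of
  autocorrelation, not on the exact covariance family. `spatial_range`
  defaults to 500 m — a few native cells, so that neighbouring 300 m buffers
  overlap strongly while 10–20 km scenes still contain hundreds of roughly
  independent patches.
- **Temporal structure.** Latent fields evolve as f_t = ρ·f_{t−1} +
  √(1−ρ²)·e_t with independent standardized innovations: stationary, unit
  variance, lag-1 correlation ρ (default 0.8). Consecutive generated layers
  empirically recover ρ to within ±0.05 on a 200×200 grid. Note the
  implication: the correlation between years k apart decays like ρ^k, so
  distant-year exposure correlations in synthetic scenes fall toward zero,
  whereas real vegetation time series keep a high floor (land cover
  persists). Synthetic results therefore exercise the *machinery* of the
  correlation analysis, not the empirical correlation floor of any real
  region.
- **Level, trend, domain.** Observed layer = base_mean (0.55) +
  trend_per_year (0.002)·(year − first year) + marginal_sd (0.11)·f_t,
  clamped to [−1, 1]. Level and spread mimic summer NDVI summaries over a
  temperate, partly urbanized region.
- **Water.** The lowest `water_fraction` (default 6%) quantile of a fixed
  auxiliary smooth field is set to −0.3, giving spatially coherent lakes and
  canals rather than salt-and-pepper noise; the water filter later masks
  them.
- **Resolution.** Fields are simulated at the 250 m native cell and refined
  to 100 m through the same bilinear operator the real pipeline uses.
- **Addresses.** Uniform over the extent, or a uniform subset of a supplied
  discrete register (the cadastral case); all draws come from named
  sub-streams of one scene seed, so a single integer reproduces scene,
  water, and every address sample.

What the generator does **not** emulate: sensor noise, clouds, mixed pixels,
the seasonal cycle (each layer is one annual snapshot), non-uniform
settlement patterns, and the long-memory temporal dependence noted above.
Passing tests demonstrate the pipeline's correctness and the qualitative
mechanisms (scale smoothing, persistence recovery, calibrated tests), not
any real region's exposure statistics.

## Problem sizes and reproducibility

The shipped default configuration is a deliberately scaled replica of a
national-scale design: a 20 km × 20 km scene (200×200 cells at 100 m), 12
years, 3 radii, 500 addresses, a 2000-address pool, and R = 50, m = 100
Monte Carlo draws; it completes in seconds and the whole test suite in well
under a minute per heavy module. Calibration checks in the test suite use
2000 simulations per test; the Monte Carlo coverage check uses an
11,000-address register with 50 register splits. One top-level seed fans out
deterministically (via named seed sub-streams) to every stochastic stage;
rerunning any stage with the same configuration reproduces its outputs
byte-for-byte.

## Known limitations

- No coordinate re-projection: all inputs must share one projected CRS in
  meters.
- GeoTIFF support is limited to the single-band square-pixel subset
  described above; multi-band or tiled products from other toolchains should
  be converted first.
- The unpaired rank-sum default ignores the pairing of year columns by
  address and is conservative against small common shifts (see the paired
  flag).
- Buffer exposure treats the home point as the sole exposure source;
  mobility-based or network-based contexts are out of scope.
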