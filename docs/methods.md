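# Methods

## Surface model and tooth-row standardization

A tooth row is represented as a regular elevation grid (`HeightMap`,
mm units) whose row axis runs mesiodistally — teeth succeed one another
along rows — and whose column axis runs buccolingually. Input surfaces
are assumed pre-aligned with the occlusal plane ≈ xy and z pointing
occlusally; a convention flag on the rasterizer swaps the axes when a
scan is oriented the other way.

Meshes (PLY) and point clouds (XYZ) are rasterized by per-cell
**maximum** z: OPC concerns the exposed occlusal envelope, so the upper
surface of the sampled points is the right summary. Empty cells are
masked; masked holes of ≤ 2 cells are filled from their valid
4-neighbours, larger holes stay masked. Surfer DSAA ASCII grids are
read and written directly (blank sentinel 1.70141e38 → masked);
read∘write is the identity on values, mask and extents.

Every row is then resampled to **50 data rows per tooth** (a 4-tooth
row becomes 200 rows, a 1-tooth row 50 rows) by bilinear interpolation,
with the column count rescaled by the same factor so the aspect ratio
is preserved; only the row count is prescribed, the column count is
not. The mask is resampled conservatively: an output cell is masked if
any input cell contributing to its interpolation is masked. The final
grid spacing after scanning is not standardized here — scan resolutions
vary (50 µm–10 µm scans in the source collections), so spacing is
carried through from the input and only the rows-per-tooth count is
fixed.

## OPC and OPCR

Aspect is the azimuth of steepest descent, computed by central
differences on the four in-grid neighbours; border cells and cells
adjacent to masked cells have no aspect. Cells with gradient magnitude
below `flat_eps` (default 1e-6 × elevation range / mean spacing —
effectively "numerically flat") are excluded: a flat cell has no
meaningful orientation and should join no patch.

Aspects are binned into `n_bins` = 8 half-open sectors centred on the
compass directions; a boundary aspect belongs to the
counter-clockwise-higher bin, a fixed tie-break that makes the count
deterministic. Patches are 4-connected components (edge adjacency;
8-connectivity is available for sensitivity analysis) of equal-bin
cells; components smaller than `min_patch_size` = 3 cells are
discarded, the default of the original OPC tool lineage. The source
publications do not state their minimum patch size, and since the
original scans are not deposited, absolute published OPCR values
(e.g. 42.625 for *Neofelis*) are not reproducible by any choice; the
parameter is therefore exposed rather than tuned.

**Rotation is implemented as a bin-boundary offset**, not raster
re-interpolation: rigidly rotating a surface about the vertical axis
adds the same angle to every aspect, so offsetting the bin boundaries
by −θ is the exact grid analogue and avoids resampling artifacts. OPCR
is the mean of the 8 patch counts at offsets k·5.625°, k = 0…7.
Because the bins are 45°-periodic, offsets k·45° + θ reproduce the
counts at θ exactly; this and mirror symmetry (reflection across the
row axis permutes bins but preserves the count) are enforced as tests.

Average-tooth OPCR is the row OPCR divided by the tooth count; the
natural-log transform used by the statistics is applied downstream.

## Kinematic measures

Each specimen carries t (lateral translation, mm), d (ventral
rotational distance, mm), a (sagittal occlusal angle, degrees from
vertical) and w (glenoid fossae width, mm). Predictors are
rt = ln(t/w), rd = ln(d/w) and ln a — the divisions by w make the
motion measures relative to body size, and the common scale factor
cancels (multiplying t, d, w by a constant leaves rt, rd unchanged).
The angle a is kept strictly as a measured input: the packaged
measurements are not numerically consistent with recomputing it as
arctan(t/d), so no such relation is enforced.

The packaged table transcribes the published 34-specimen measurement
set (20 Carnivora, 14 Dasyuromorphia) at its printed precision. Two
printed statistics are **not** reproducible from the printed table and
are documented as such rather than patched: the Mann–Whitney U for
rd computes to 170 rather than the published 171 (one cross-order pair
differs by 1.5e-5 in d/w — a knife-edge that plausibly flips with the
authors' unrounded measurements), and the Pearson correlations of t and
d with w compute to 0.80 and 0.94 rather than the published 0.77 and
0.86 under every transform and subset convention tried.

## Order comparisons and association

Mann–Whitney U is reported for the first sample (convention: Carnivora
first), U = #{xᵢ > yⱼ} + ½·ties. The p-value is exact when both
samples have ≤ 25 observations and the pooled data has no ties
(feasible at 20 vs 14), otherwise a normal approximation with tie and
continuity correction. Because U depends only on ranks, any strictly
monotone transform (e.g. the log) leaves it unchanged — tested
explicitly. The upper-on-lower complexity association is an OLS fit
reported with r² and coefficient p-values.

## Maximum-likelihood GLS with Gaussian correlation

Single-predictor models are OLS fitted by ML (residual variance with
denominator n, so the reported log-likelihood is the maximized Gaussian
likelihood). Models with ≥ 2 predictors use GLS with residual
correlation exp(−(sᵢⱼ/ρ)²), the Gaussian (squared-exponential) kernel.

**Correlation distance space.** Nothing in the source analysis records
what sᵢⱼ is measured over. This package's convention: Euclidean
distance in the model's own unscaled log-predictor space, no nugget —
the choice consistent with exactly one extra parameter per correlated
model in the published df accounting. The alternative (standardized
predictors) is selectable. Under this convention the package's fits
agree with R's `nlme::gls(correlation = corGaus(form = ~predictors),
method = "ML")` to five decimals on all eight correlated fits of the
packaged table, and those independently computed values are frozen as
oracle constants in the test suite. The published best-model
log-likelihoods (27.733 upper, 20.214 lower) are ~0.9 higher/lower than
what this — or any of a dozen probed conventions — yields, so they are
treated as sensitive to an unrecorded convention; the selection-level
conclusions (which models rank where) are the reproducible quantities,
and for the upper response the AICc ranking {3, 4, 2, 1, 5} and all
weights match the published table within ±0.05. For the lower response
this convention ranks the three-motion-term model 4 first
(logLik 22.000, confirmed by nlme) where the publication ranks model 3
first; the published lower ranking is not recoverable under any probed
convention, and the package reports its own honestly computed table.

**ρ optimization.** β and σ are profiled analytically via the Cholesky
factor of the correlation matrix; ρ is maximized on a 60-point log grid
spanning [1e-6, 1e3] × median pairwise distance, then refined by
bounded scalar minimization (tolerance 1e-8 in log-likelihood). Ranges
that make the correlation matrix numerically non-positive-definite are
rejected (−inf), which also excludes the degenerate large-range ridge
this kernel develops without a nugget; the ρ→0 limit therefore competes
fairly, and a fit that reduces to OLS is reported with ρ flagged at the
bracket bound.

**K accounting** mirrors the published df column: coefficients
(intercept + slopes) + residual SD + range parameter when correlation
is used — K = 3 for the single-predictor model, 5 for two predictors,
6 for three.

## AICc, weights, confidence sets, averaging

AICc = −2 logLik + 2K + 2K(K+1)/(n−K−1), valid for non-nested ML fits;
Akaike weights are normalized exp(−Δ/2); the 95% confidence set is the
smallest AICc-ordered prefix with cumulative weight ≥ 0.95. Model
averaging over a scope (confidence set by default) renormalizes weights
within the scope and offers two conventions: **natural** (average each
term over the models containing it — the default, appropriate when a
term's effect is conditional on its inclusion) and **zero-substitution**
(absent terms count as zero, shrinking rarely-selected effects).

## Synthetic data: what it emulates and what it does not

Surfaces: planes (one aspect → OPC 1), n-faceted pyramids whose faces
descend toward configurable azimuths (n bin-centred faces → OPC n),
circular cones, and Gaussian cusp fields on a gentle base plane with
centres ≥ 4 widths apart by rejection sampling (≤ 10⁴ tries, then a
geometry error suggesting fewer cusps). Each isolated cusp's
orientation structure is analytically predictable — up to one patch per
occupied octant — giving a tunable OPC ladder. These surrogates have
exact, noise-free geometry; they validate the counting machinery, not
the segmentation of real worn, pitted enamel, so passing tests show
algorithmic correctness rather than robustness to scan artifacts.

Specimen tables: (ln_lower, rt, rd) are multivariate normal with the
packaged table's moments — means (4.54, −2.90, −2.21), SDs (0.59, 0.40,
0.36), correlations (0.46, −0.02, 0.59) — and the response follows the
best-supported generating model ln_upper = 0.89 + 0.79·ln_lower −
0.22·rd + ε with σ = 0.11 (iid by default; optionally Gaussian-kernel
correlated with range ρ). Body size is lognormal (ln w ~ N(3.81,
0.51)); t and d are back-formed from rt, rd and w so the emitted table
matches the packaged schema. Tooth counts and order labels are
schema-filling, not biological. Recovery experiments use 200 replicates
at n = 34 (coefficients within 3 SE ≥ 95% of the time) and 100
replicates at n = 200 (generating or nesting model in the 95%
confidence set ≥ 90%); those sizes keep the whole suite under a minute
while leaving comfortable Monte-Carlo margins.

All generators use a single seeded `numpy` Generator; fixed spec + seed
gives byte-identical output, and seeds are recorded in all emitted
metadata.

## Numerical choices and degenerate inputs

- Aspect tie-breaks and bin boundaries are fixed (half-open sectors,
  boundary to the higher bin) so counts are deterministic.
- An all-masked map, a degenerate (zero-extent) cloud, a singular
  design matrix, identical correlation positions, and n ≤ K + 1 for
  AICc each raise a typed error naming the offence.
- Surfer round-trips are bit-identical for finite values; 17
  significant digits are written.
- Fit failures inside a selection table annotate the offending row and
  leave the remaining ranking intact rather than aborting.

## Known limitations

- Absolute OPCR values for the published specimens are unreproducible
  (scans not deposited); only the statistical pipeline downstream of
  the packaged measurement table is exactly checkable.
- The GLS correlation-distance convention is an interpretation (see
  above); log-likelihoods of correlated fits, and with them the lower
  response's exact ranking, are sensitive to it.
- The min-patch-size default (3 cells) follows the OPC tool lineage,
  not a stated value.
- No mesh repair, registration or occlusion reconstruction: t, d, a
  are consumed as measured inputs.
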