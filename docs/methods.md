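# Methods

## Coordinate and calibration conventions

All rasters use 0-based `(row, column)` indexing; physical coordinates are
in micrometres with isotropic square pixels, and the centre of pixel
`(i, j)` is at `((j + 0.5)·s, (i + 0.5)·s)` for pixel size `s`.  External
files (cell CSVs, ROI JSON, junction CSVs) always carry μm coordinates; a
single floor rule maps μm to containing pixel, so a round trip through the
grid moves any point by at most half a pixel per axis.  Anisotropic
calibrations are rejected rather than approximated.  Grayscale masks are
binarized with a strict `value > threshold` rule so that binarization is
bit-exact and documentable.  Polygon ROIs are rasterized by the
pixel-centre-in-polygon rule; all spatial operations consume the raster
form.

## Distance model

Distances are measured **centre-to-centre**: the distance field is the exact
Euclidean distance transform of the vessel mask (pixel centres to nearest
vessel pixel centre, `scipy.ndimage.distance_transform_edt`), and per-cell
distances are computed from the cell's continuous μm coordinate to the
nearest vessel pixel centre with a k-d tree — never by looking up the
snapped pixel's field value.  This makes both quantities exactly checkable
against a brute-force minimum over all vessel pixels, which the test suite
asserts at zero tolerance.  An alternative edge-to-edge convention (distance
to the vessel boundary) would differ by up to one vessel radius; the
centre-to-centre choice is consistent across conditions, which is what
matters for contrasts.  Cells are matched against vessel pixels anywhere on
the grid, not only inside the ROI, because a vessel just outside a manually
drawn ROI boundary is still the biologically nearest vessel.  Cells whose
containing pixel falls outside the ROI are dropped with a logged count.

## Null models and their identities

Random placements are uniform over **extravascular ROI pixel centres**, not
continuous positions.  This discreteness buys exact identities: the
all-pixels distribution is literally the population that the repositioning
and matched-number nulls sample from, so the matched-number null converges
to it in KS distance at the `1/√n` rate (asserted at n = 10⁵, KS < 0.02),
and the pooled reposition mean converges to the population mean.
Intravascular pixels are excluded by default (the cells are extravascular by
biology); `allow_intravascular=True` restores them.

Seeding is counter-based: a master seed spawns one independent stream per
replicate (`numpy SeedSequence(seed, spawn_key=(r,))`), so replicate *r* is
reproducible in isolation and every stochastic operation is bitwise
reproducible from `(inputs, parameters, seed)` in single-threaded execution.

## Comparison statistic

Observed samples are compared to a null's pooled ECDF with the
Kolmogorov–Smirnov distance.  Both functions are right-continuous step
functions over a discrete, heavily tied support, so the supremum is
evaluated exactly from the upper and lower ECDF steps at the sample's jump
points (`ks_statistic`); generic continuous-distribution KS routines are not
valid here.  Significance comes from a Monte-Carlo construction: `n_mc`
synthetic samples of the observed size drawn from the pooled null, scored
with the same statistic, and an add-one p-value
`p = (1 + #{D_b ≥ D_obs})/(n_mc + 1)`, whose smallest attainable value is
`1/(n_mc + 1)`.  Calibration is verified by simulation: over 200 CSR
datasets of 100 cells the rejection fraction at p < 0.05 falls inside the
exact central 95% binomial interval around 0.05.  Defaults are
`n_reps = 1000` replicates and `n_mc = 999` (p resolution 0.001);
`n_mc < 19` is rejected outright.

## Attribution verdict

`attribute_shift` codifies the three-control reasoning into one table and a
verdict.  The three tests are deliberately asymmetric in character:

- **morphology** compares the two maps' exact all-pixel distributions — a
  population-level quantity with no sampling noise — so it is judged by a
  fixed KS threshold (default 0.05).  Identical maps give KS = 0 exactly;
  the test has a zero false-positive rate under "no morphology difference".
- **attraction** is a per-map sampling test (observed vs reposition null).
  Two such tests feed a single verdict, so the verdict uses a conservative
  level `verdict_alpha = 0.01` per map (Bonferroni-style familywise
  control ≈ 2%); the raw p-values are reported so a reader can apply any
  level they prefer.
- **number** is a bookkeeping comparison of observed cell counts (flagged
  above a 20% relative difference) plus the matched-number construction,
  which shows what the two maps produce at a common count.

The verdict string lists every implicated factor.  This rule is the
package's own formalization of an analysis that is usually argued
qualitatively; the output labels it as such.  Under the generator it
identifies attraction-only, number-only and morphology-only scenarios
correctly in ≥ 18/20 seeded trials at n = 500.

## Attraction model and estimator

The generator places cells on extravascular pixels with weight
`(1 − α) + α·e^(−d/λ)`.  The estimator fits the equivalent normalized
mixture `p(d) ∝ (1−α′)·g(d) + α′·g(d)·e^(−d/λ)/Z(λ)` with
`Z(λ) = E_g[e^(−d/λ)]`, where `g` is the empirical pixel distance density.
The two parametrizations describe the same density family with the same λ;
the weights map monotonically onto each other
(`α′ = αZ/(1−α+αZ)`, coinciding at 0 and 1).  Because `g` enters the
log-likelihood only as an additive constant, the fit reduces to maximizing
`Σ log((1−α′) + α′·e^(−dᵢ/λ)/Z(λ))` — no density smoothing or binning is
needed.  Optimization is L-BFGS-B over `α′ ∈ [0, 1]`,
`λ ∈ [0.1 μm, 2·max pixel distance]` from a 3×3 grid of starts; degenerate
pixel distributions (a single distance value) are flagged as
non-identifiable rather than fitted.

**Identifiability caveat:** λ is only resolvable when the map's
extravascular distances span several length scales.  On a dense network
whose distances rarely exceed λ, `e^(−d/λ)` is nearly linear over the
support and α/λ trade off; the parameter-recovery benchmark therefore runs
on a sparse map (distances 0–115 μm), where the median relative error of λ̂
at truth (α = 0.8, λ = 15 μm, n = 500) is ≈ 0.13 over 50 replicates, and
the median α̂ under CSR truth is ≈ 0.  Users fitting dense maps should treat
λ̂ with caution; the `converged` flag does not capture weak identifiability.

## Morphometry choices

Perimeter is the count of exposed pixel edges (4-connectivity) times `s` —
an exact integer computation that an independent per-pixel loop can verify.
Its known systematic bias on smooth shapes (→ 4/π for a disk, asserted
within 5% at s = diameter/200) is consistent across conditions, so
between-genotype contrasts are preserved; the estimator name is recorded in
the output.  Components use 8-connectivity, the standard complement of the
4-connected boundary.  Looping-vessel inclusion uses the component's
*minimum* pixel-centre distance to the junction polyline with an inclusive
`≤ band` rule (a centroid-distance variant is available); the core/annulus
split takes the central `core_fraction` (default 0.5) of the junction arc
length, assigning each component by the arc-length position of its nearest
point, and both raw counts and per-mm² densities are emitted because the
field reports either.  Tube networks are skeletonized
(`skimage.morphology.skeletonize`) and segments are traced between skeleton
nodes (pixels of 8-neighbour degree ≠ 2) with step lengths s/s√2; segments
shorter than 10 μm (default) are treated as skeletonization spurs, not
tubes.  Segment lengths near junctions carry a ±1–2 pixel ambiguity
inherent to thinning.

## Axial profiles

Each ROI pixel is assigned to the bin of its orthogonal projection onto the
axis (arc-length projection for polylines; points projecting beyond a
straight axis' endpoints are dropped).  A bin's value is the channel sum
over its pixels divided by the bin's pixel area in μm², minus the same
quantity over the out-of-tissue background region — so a constant tissue
intensity I over background b yields exactly (I − b)/s² in every covered
bin, negative values are preserved, and empty bins are missing (NaN), never
zero.  Bin width defaults to 25 μm.  The default axis is user-supplied
endpoints; `--axis auto` uses the ROI's major principal axis.

## Synthetic scenes: what they emulate and what they do not

Tubes are correlated random walks (step 6 μm, Gaussian heading increments
SD 0.3 rad, 60 steps) dilated to a physical radius via the distance
transform; two parameters (tube count, radius) span the contrast between a
dense fine network (area fraction ≈ 0.2, mean pixel distance ≈ 15 μm) and a
few larger vessels (area fraction ≈ 0.08, mean ≈ 45 μm).  The default
scene is a 400 × 600 px grid at 1 μm/px with an inscribed elliptical ROI;
tests and the acceptance script use 200 × 300 px scenes, which preserve all
the statistical structure at a quarter of the cost.  Intensity channels are
a mid-axis Gaussian bump and a central plateau over a constant background
with additive Gaussian noise clipped at zero.

The generator does **not** simulate microscopy physics — no PSF, no
bleed-through, no segmentation errors, no anisotropy, no 3D — and its cells
are placed at pixel centres.  Passing tests therefore demonstrate the
correctness and calibration of the *analysis* under its stated assumptions,
not robustness to segmentation quality; on real data the vessel mask and
cell centroids are upstream inputs whose quality bounds everything
downstream.

## Pipeline aggregation

The study pipeline summarizes per sample first, then aggregates mean ± SD
across samples within genotype (a pooled-cell mode is available by flag).
Cross-genotype attribution runs on one map pair per genotype pair (the first
sample of each, optionally with pooled distances), since the three-null
construction is defined per map; multi-map attribution would require a
hierarchical model that is out of scope.  Every run writes a manifest with
software version, parameters, seed, and SHA-256 checksums of all inputs;
re-running the same configuration reproduces all numeric outputs exactly.
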