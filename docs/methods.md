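# Methods

This note documents the models, numerical procedures, and design choices
behind `whiskerfit`. It states how quantities are computed; every empirical
number quoted in the README is produced by the test suite, the analysis
drivers, or `scripts/acceptance.py`.

## The problem

A whisker (vibrissa) is a tapered facial hair whose *intrinsic curvature* —
how the signed planar curvature κ varies with arc length s — shapes what the
follicle senses during contact. Given 2D traces digitized from flatbed
scans, the pipeline quantifies intrinsic curvature by fitting four competing
curve families and examines what each representation preserves.

## Preprocessing

1. **Units.** Pixel traces convert to mm at 25.4/dpi (scans at 6,400 dpi →
   3.97 µm/px).
2. **Smoothing.** Local regression (LOESS) of degree 2 with tricube
   weights, applied independently to x(u) and y(u) against cumulative chord
   length u, window spanning 4 mm of chord (the pixel-domain equivalent of
   a ~1,000 px window at 6,400 dpi; specifying it in mm keeps behaviour
   resolution-independent). Degree-2 local regression reproduces straight
   lines and parabolas exactly; traces shorter than the window fall back to
   one global quadratic with a warning. The smoother is written in-house
   because the degree-2 windowed fit is itself a specified primitive
   (library LOESS implementations available here are degree-1).
3. **Resampling.** Nodes are placed an exact 0.25 mm *chord* apart by
   walking the smoothed polyline (circle–polyline intersection); the tip is
   always retained, so the last segment may be shorter. Chord stepping
   makes the uniform-spacing invariant exact and resampling idempotent. The
   arc-length coordinate s is the cumulative chord sum; for whisker-scale
   curvature the chord–arc difference is O((κΔs)²/24) ≈ 10⁻⁵ relative.
4. **Standard orientation.** The base moves to the origin; the trace is
   rotated so the least-squares line (total least squares, i.e. principal
   axis) through a proximal fraction of nodes lies on +x; y is negated if
   the arc-length-weighted area ∫y ds is negative, making the whisker
   concave up. The area is weighted by ds, not dx: for "backwards"
   whiskers (tip running in −x) a trapezoidal ∫y dx is dominated by the
   return stroke with the wrong sign. A line fit (not a base-to-node
   chord) defines the proximal direction because it is robust to noise in
   the first few nodes. Note a concavity flip mirrors the whisker and
   negates its signed curvature, so Cesàro coefficients are reported in
   the flipped frame.
5. **Orientation bounds.** For each proximal fraction f ∈ {0.01, …, 0.20}
   (step 0.01) the alignment angle of the fraction's principal axis is
   computed; the extremes bound the orientation nuisance α during fitting.
   Fractions too short to contain two nodes at 0.25 mm spacing (whiskers
   under ~25 mm at f = 0.01) are skipped rather than treated as errors, or
   short whiskers could not be processed at all.
6. **Backwards truncation.** For the single-valued y(x) families
   (polynomial, fractional exponent) the trace is cut at the first node
   whose x falls below the running maximum; fewer than 10 remaining nodes
   is an error.

## Curve families

* **Polynomial** y = Σᵢ aᵢxⁱ over order sets (2), (3), (2,3), (2,3,4),
  (2,3,4,5); a₀ = a₁ = 0 by standard orientation.
* **Fractional exponent** y = a_β x^β, β real; bridges quadratic and cubic.
* **Elliptical arc** x²/A² + (y−B)²/B² = 1 parametrized
  (A sin t, B(1−cos t)), starting at the origin along +x. Its printed
  curvature formula κ(x,y) = A⁴B⁴/(A⁴y² + B⁴x²)^{3/2} is evaluated with y
  measured from the ellipse *center* (y−B in whisker coordinates): the
  centered reading reduces to 1/R on a circle, whereas the literal reading
  diverges at the origin. The *quarter fraction* 100·t_end/(π/2) flags
  backwards whiskers at values above 100%.
* **Cesàro / clothoid** κ(s) = A s + B; coordinate-free. Curves are
  generated from the tangent angle θ(s) = ψ₀ + B s + A s²/2 by cumulative
  5-point Gauss–Legendre quadrature per 0.25 mm step (accurate to ~10⁻¹²
  for whisker-scale coefficients). The *universal Euler spiral* is the
  member with κ(ŝ) = ŝ, parametrized via θ(ŝ) = ŝ²/2 so the defining
  property holds exactly; it evaluates through `scipy.special.fresnel`
  after rescaling. Shape classes follow the signs of (B, A) — quadrant 1:
  curvature positive at the base and growing tipward — plus an
  inflection-inside flag (−B/A ∈ (0, S)) and an all-positive-curvature
  flag; |A| < 10⁻⁸ mm⁻² or |B| < 10⁻⁸ mm⁻¹ count as zero and classify as
  positive, keeping the map total.

Discrete curvature of a node sequence is the derivative of the chord
direction angle with respect to arc length: segment angles are attributed
to segment midpoints and differenced; endpoints are linearly extrapolated.
For a clothoid the constant O(Δs²) offset of chord angles cancels in the
difference, so linear κ(s) profiles are recovered to better than
10⁻³ mm⁻¹ at 0.25 mm spacing.

## Orthogonal-distance fitting

Cartesian families are fit by alternating (i) orthogonal projection of
every node onto the current curve and (ii) constrained least squares on
the parameters with α ∈ [α_min, α_max]. The parameter step keeps the
projections fresh: each residual evaluation re-projects with warm-started,
safeguarded Newton iterations on the orthogonality condition
(p−q)·p′ = 0 (a coarse grid scan catches wrong-branch projections), so
the step solves both subproblems to joint stationarity; a full safeguarded
re-projection then confirms convergence, and the cycle repeats (up to 5
times) if any node changed branch. Signed residuals are positive on the
left of the oriented curve. Multistarts (default 5; studies use 2) are
drawn from a seeded generator, so fits are bit-reproducible. A
single-point `project_point` with a 4,096-point grid plus Newton
refinement agrees with 10⁵-sample brute-force sweeps to well below
10⁻⁶ mm on whisker-scale curves.

**Fractional exponent, one whisker.** Inner: (a_β, α) by least RSS at
fixed β. Outer: β ∈ [1.2, 4.5] minimizing the squared residual *sum*
(Σrᵢ)². Because the signed residual sum crosses zero both at the
generating exponent and, generically, at spurious exponents, the outer
criterion has multiple exact zeros; the implementation scans β in steps of
0.15, bisects every sign change of Σr (each bracketing an exact global
minimizer of (Σr)²), runs golden-section around the scan argmin for the
no-root case, and breaks the tie between candidates by the inner RSS. The
final β is resolved to 10⁻³.

**Fractional exponent, species level.** All whiskers share β; the inner
problem solves each whisker's (a_β, α) at the shared β, and the outer
criterion is Σ_whiskers (Σᵢ rᵢ)² — the whisker-level reading of the
species objective, consistent with the per-whisker criterion. α is refit
inside the outer search rather than frozen.

**Ellipse.** (A, B, α) with semi-axes bounded below at 1 mm (hitting the
bound is flagged); t_end is the tip node's projection parameter.
Initialization tries several assumed arc extents plus seeded multistarts.

**Cesàro.** The candidate curve is generated at the trace's own node arc
coordinates, anchored at the base, with free initial tangent ψ₀ — an
index-matched correspondence ("curve of equal arc length"), not a
projection. The trace is first rotated into a canonical frame (first
chord on +x) so the optimization is identical for any rigid pose of the
input; ψ₀ is reported back in the original frame. The objective is the
summed Euclidean distance Σ|dᵢ|, smoothed as √(dᵢ²+ε), ε = 10⁻²⁰ mm², for
differentiability; a plain least-squares pass on the coordinate residuals
warms up the ill-conditioned summed-distance refinement. Initialization
comes from a line fit of discrete curvature against s.

**Orientation bounds in practice.** For scanned data α is constrained to
the proximal-alignment interval, expressed relative to the standardized
pose as [α₀−a_max, α₀−a_min] (α₀ the applied alignment rotation, a_f the
alignment angle of fraction f). For *synthetic* whiskers, which are
generated in the standard frame, that interval strictly excludes the
generating pose (alignment angles of a concave-up curve bracket zero from
one side), so recovery studies and the fitting driver use a ±0.35 rad
envelope that contains both the alignment range and zero. This is a
property of ground-truth recovery, not of the method.

## Selection and statistics

* **Order selection.** Walking (2) → (2,3) → (2,3,4) → (2,3,4,5), a higher
  set is accepted iff its RSS is ≤ 10% of the previous accepted set's
  (it "eliminates at least 90% of the variation"); the walk stops at the
  first rejection. Population-level decisions sum RSS over whiskers.
  The rule's outcome depends on the noise floor: very clean synthetic
  power-law traces can accept order 4+, because the non-polynomial
  remainder still dominates the tiny pixelation residue.
* **Adjusted RSS** = RSS/(n−p), the standard residual-variance
  normalization for comparing families with different parameter counts.
* **Residual skewness** is the biased normalized third central moment.
* **β outlier filter**: the central [2.5, 97.5] percentile interval of the
  per-species β sample — the only reading of a "95% interval" that removes
  at most ~5% of whiskers.
* **Separability**: classic pooled-variance two-sample t-tests (the null
  states equal means *and* variances), classified at p < 0.01 (strong) and
  p < 0.1 (separable); no multiple-testing correction, and whiskers are
  treated as independent samples (within-animal correlation is ignored, a
  known simplification).

## Euler-spiral conformation

For A ≠ 0 the affine map ŝ(s) = ±√|A| s + B/√|A| (sign of A) places the
√|A|-scaled whisker on the universal spiral as the interval
[B/√|A|, B/√|A| ± √|A|S]. Negative A is handled by reversed traversal on
the same curve — by the spiral's odd symmetry this is congruent to the
whisker's mirror image, so geometric checks align with a reflection when
A < 0. Constant-curvature whiskers (A = 0) are circles and raise an
explicit error. Mean spiral location is the interval midpoint; Pearson
correlations are computed against row index (A=1, B=2, …, non-letter rows
excluded), column index, arc length, and mean curvature κ̄ = A S/2 + B.

## Contact-mechanics factor

For rigid rotation about the base with frictionless point contact, the
centripetal-to-external force ratio factors into a constant (mass,
inertia, center-of-mass geometry, time step — treated as an exogenous 1)
times the geometry at the contact node: **r_F²/sin θ**, with r_F the
base-to-contact chord and θ the tangent angle. The division by sin θ is
what re-derivation of the force balance yields, and it reproduces the
characteristic near-base spikes where θ → 0. Nodes with |sin θ| < 10⁻³
are masked as NaN rather than clipped, so downstream statistics see
missingness, not fabricated values. Model profiles are computed on each
fitted curve regenerated at 0.25 mm spacing in the trace's frame.

## Synthetic data

The generator emulates the study conditions: smooth planar curves from
each family (arc lengths drawn in ~10–60 mm for studies; 5–300 mm
supported), *pixelation* noise — coordinates rounded to the 25.4/dpi
grid, a ≤ half-pixel uniform error, matching flatbed-scan provenance
(additive Gaussian noise would not) — applied before an arbitrary rigid
placement; and array metadata with a caudal→rostral length gradient
(S = S_caudal·0.75^(col−1), mild row gradient, floor 5 mm).

Species laws: β ~ Normal(μ_β, σ_β) truncated to [1.5, 4] (defaults
μ = 2.5, σ = 0.15, the between-quadratic-and-cubic regime);
a_β = c·S^{1−β}·Lognormal(0, 0.25) with c = 0.6, the scale-consistent law
under which short whiskers carry large, variable coefficients. Cesàro
shapes are drawn dimensionlessly — a = AS² ~ N(1.4, 1.0), b = BS ~
N(0.3, 0.25), independent of identity and length — so the dimensional
coefficients scale as real whiskers do and the spiral location
b/√a + √a/2 is independent of row, column, and S by construction.

What the generator does **not** emulate: trace-extraction artifacts of the
scanner software, 3D out-of-plane bending, taper, and within-animal
correlation of shape parameters. Passing recovery tests therefore show
the estimator chain is correct and noise-robust at scan resolution, not
that real whiskers follow any one family.

## Study problem sizes and numerical tolerances

Validation studies run at desk scale: 50 whiskers per family for
noise-free recovery, 20 for noisy recovery, 100 (curve, point) pairs per
family against 10⁵-point brute force, 30 coefficient draws for curvature
consistency, 20 for spiral conformation, 3 populations × 12 whiskers per
kind for order selection, n = 100 per species (100 null replicates) for
separability, and 50 whiskers for shape-class percentages. Noise-free
recovery preprocesses without smoothing — with no noise to remove, the
smoother's small endpoint bias would only obscure estimator accuracy —
while all noisy studies run the full smooth+resample pipeline.

Key tolerances: projection Newton terminates at ~10⁻¹⁴ in the parameter;
ODR cycles stop at relative RSS change 10⁻¹²; the outer β search resolves
10⁻³; optimizer runs are seeded and bit-reproducible.

## Known limitations

* Local optimization only: multistarts reduce but do not eliminate the
  risk of local minima, and the (Σr)² outer criterion's root structure
  makes the RSS tie-break an essential, documented numerical choice.
* The ellipse family is weakly identified for near-straight whiskers
  (A → large, B → bound); such fits are flagged, mirroring its poor
  standing in the model comparison.
* The 16-type shape taxonomy is reproduced at quadrant + inflection +
  all-positive granularity, which suffices for every reported statistic.
* Index-matched Cesàro correspondence uses the trace's chord-sum arc
  coordinate; the ~10⁻⁵ relative chord–arc bias is far below the 1%
  recovery tolerances but is not zero.
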