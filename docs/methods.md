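# Methods

## Outline extraction and size measurement

A binary silhouette is labelled; exactly one foreground component of at
least 50 px is required. Its boundary is traced at the 0.5 iso-level of
the mask (sub-pixel marching squares), converted once to a y-up Cartesian
frame, resampled to `n_points` (default 64) positions equally spaced in
cumulative boundary arclength, and oriented counterclockwise. The start
point is relocated to the seed base. The base is not defined operationally
in classical seed-measurement protocols, so we use a reproducible rule:
align the outline to its principal axis and take the extreme vertex at the
axis end with the smaller local curvature radius (estimated from the
perpendicular spread of boundary points within 12% of the axis span of
each end; ties break toward smaller y). A manual `base_index` override is
available. Components touching the image border are flagged, not rejected.

Rasterization caveat: the traced boundary of a pixelated mask is a
staircase, so "equal arclength" refers to the traced contour; chord
lengths of the 64 points on a rasterized disk vary by a few percent even
though the spacing along the contour is exact. Perimeter and area of
smooth shapes ≥100 px across are reproduced to ~2%.

Size parameters: **length** = maximal caliper (Feret) extent of the
dorsal outline (rotating-calipers over the convex hull, so the measure is
orientation-independent; an image-axis variant is available via
`method="axis"`); **width** = maximal extent perpendicular to the length
axis; **thickness** = maximal extent of the lateral outline perpendicular
to its principal axis; **surface** = shoelace polygon area of the dorsal
outline. Units are whatever `scale` (length units per pixel) implies,
conventionally cm.

## Elliptic Fourier transform

The chain formulation: with edge increments Δx_p, Δy_p, Δt_p and
cumulative length t_p over perimeter T,

    A_n = T/(2 n² π²) Σ_p (Δx_p/Δt_p) [cos(2πn t_p/T) − cos(2πn t_{p−1}/T)]

and analogously B_n (sin terms), C_n, D_n for y, plus the DC offset
(A0, C0). A closed polygon of P vertices supports up to ⌊P/2⌋ harmonics.
An independent trapezoid-quadrature Fourier oracle (dense sampling of the
same piecewise-linear parameterization) agrees with the closed-form
coefficients to <1e-6 and guards the implementation in the tests.

Because the parameter is arclength, an elongated ellipse is *not* exactly
a single harmonic: a 2:1 ellipse leaks ~0.5% of its first-harmonic power
into H3 and A1 is a few percent below the semi-major axis. This is a
property of the chain parameterization shared by all implementations of
this formulation, and the tests assert exactness only for circles.

**Normalization.** The starting-point phase
θ = ½·atan2(2(A₁B₁+C₁D₁), A₁²+C₁²−B₁²−D₁²) is removed by rotating
harmonic n by nθ in its (cos, sin) plane; the orientation
ψ = atan2(C₁′, A₁′) is removed by a spatial rotation; all coefficients are
divided by the semi-major magnitude E = √(A₁′²+C₁′²); offsets are
discarded. Afterwards A₁ = 1, B₁ = C₁ = 0 and D₁ holds the residual
aspect of the first ellipse. θ is only defined modulo π; the two solutions
agree on odd harmonics and differ by a global sign on the even ones (the
compensating half-turn of ψ cancels the flip on odd harmonics). The
canonical form makes the first even-harmonic coefficient of appreciable
magnitude (A₂ in practice, the egg asymmetry of a seed) positive — a
deterministic choice that anchors the pointed seed base consistently.
Normalized coefficients are invariant to rotation, uniform scale,
translation and starting-vertex choice to ≤1e-6 (property-tested).

The retained shape vector concatenates (A, B, C, D) for harmonics 2–9,
dorsal view then lateral view: 64 numbers per seed, matching the
coefficient-table column order (`A1VD`…`D8VD`, `A1VL`…`D8VL`, where stored
column number h is retained harmonic h+1; the reader's `harmonic_offset`
documents this mapping). The harmonic budget is fixed at 8 retained
harmonics by prior calibration for these seeds; `harmonic_power_profile`
exists for re-examination but the pipeline default is not re-derived.

**Mean shapes** are coefficient-wise means re-expanded around the
canonical unit first harmonic (1, 0, 0, d̄) and inverse-transformed; the
aspect surrogate d̄ (default 0.6) affects only the drawing, never a
statistic.

## Sample-size stabilization

For one accession and one size parameter, an independent random k-subset
is drawn for each k = 1..n_max (default 30, lowered to the available count
with a flag; subsets are deliberately *not* nested, matching the protocol
of drawing each size separately) and its mean recorded. The stable size is
the smallest k from which every larger subset's mean stays within
±ε × full mean (ε default 0.025). "Stops fluctuating" is a visual
criterion in the original protocol; the band rule is the simplest
reproducible formalization, and ε is exposed. With the within-accession
size variation calibrated below (cv ≈ 0.07), means stabilize around 6–20
seeds, supporting the 20-seeds-per-accession convention.

## Rarefaction disparity

One PCA (centered, unit-variance by default — the convention of the
original analysis software; a flag disables scaling) is fitted over all
seeds of all species, in the 4-variable size space or the 64-variable
shape space. For each species with more than one accession, the centroid
is the mean score vector of *all* its seeds (the wording "dispersion
around the species centroid" implies a fixed centroid; a per-draw
recomputation is available by flag). Per replicate, `n_draw` (default 20)
seeds are drawn without replacement and each seed contributes
Σ_k v_k (s_ik − c_k)², v_k the explained-variance fraction of component
k over **all** components — a weighted *sum of squares*, not a distance,
so the units are quadratic in score units. The statistic is the mean and
sd of the replicate means over `n_replicates` (default 100). Species with
fewer than `n_draw` seeds raise unless `allow_small` (then the whole
species is drawn and flagged; the replicate sd is 0 by construction).
Tukey letters over the replicate values are attached. Because the
magnitude depends on the score scale of the fitted PCA, cross-study
comparisons should use ranks, which is also what the end-to-end checks
assert (the cultivated date palm ranks first in shape disparity).

## Inferential conventions

- **Nested ANOVA**: sequential sums of squares from group means (species,
  then accession-within-species, then residual), which for a purely
  nested design is the exact Type-I decomposition. The species effect is
  reported against both the residual mean square (the common software
  default) and the accession mean square (the hierarchical test), since
  seeds within an accession are not independent.
- **Tukey HSD**: studentized-range p-values; with unbalanced groups the
  default uses the harmonic-mean group size (the convention of the
  `HSD.test`-style tooling), with a Tukey–Kramer per-pair variant by
  flag. The compact letter display uses the insert-and-absorb algorithm;
  two groups share a letter iff their adjusted p ≥ α.
- **Nested MANOVA**: Pillai trace from the species hypothesis matrix and
  the residual-after-accession error matrix, with the standard F
  approximation; rank-deficient error matrices fall back to a
  pseudo-inverse and are flagged.
- **LDA**: pooled within-class covariance Gaussian model. Axes
  diagonalize the between-class scatter in the within metric; axis
  "variance explained" is proportion of between-class trace. Priors
  default to class frequencies ("proportional", the original software's
  default) with a "uniform" option. Size features enter unstandardized
  alongside coefficients — the within-class metric makes the fit
  scale-equivariant, so pre-scaling is unnecessary (property-tested).
  A singular pooled covariance triggers an automatic ridge
  (λ = 1e-8 × trace/p, with an absolute fallback for exactly zero
  scatter) and a warning: determinism over failure.
- **Leave-one-out** refits use exact downdates of the per-class sums and
  the cross-product matrix; a brute-force refit loop is the test oracle
  and matches allocation-for-allocation. The "mean" discriminant power is
  the *unweighted* mean over classes (the species-table convention); the
  seed-weighted mean is also reported.
- **Supplementary projection**: feral and unknown-status seeds are
  excluded from the two-group fit and projected afterwards; posteriors
  are the Gaussian linear-discriminant softmax.

## The synthetic panel

The generator is the package's study-conditions definition, calibrated
once to the published design and species summary table and then frozen.

- **Design**: 13 species / 84 accessions / 1625 seeds with the exact
  per-accession seed counts (20 where available; 591 date-palm seeds
  across 30 accessions, including 24 cultivars, 2 seedlings, 2 feral and
  2 unknown-status accessions).
- **Sizes**: trivariate lognormal (length, width, thickness) per species
  with means and total cvs from the summary table. Within-seed log-scale
  correlations: wild species L–W 0.85, L–T 0.82, W–T 0.93; cultivated
  (and feral) L–W 0.15, L–T 0.10, W–T 0.93 — the domestication
  decoupling. The total variance splits into a between-accession random
  effect and a within-accession part fixed at cv ≈ 0.07 (what makes
  accession means stabilize near 20 seeds). The date-palm status groups
  are offset so the species-level composite stays on the published means
  (cultivated 2.16 cm, feral 1.70, unknown-status 1.45 → composite
  2.08 cm). Seedling accessions take a strongly shrunk accession effect,
  encoding the reported size comparability of seedlings and cultivars.
- **Shapes**: generated in normalized coefficient space as a base seed
  shape (conserved egg asymmetry A₂ ≈ 0.07) plus a low-rank combination
  of six shared deformation modes (loadings decay as (2/n)^1.5 with
  harmonic rank) plus a small iid floor. Species are placed in mode space
  by a fixed score table that mirrors the reported affinities (sylvestris
  nearest the date palm; acaulis/loureiroi/reclinata mutually confusable;
  paludosa, caespitosa, canariensis, roebelenii distinctive); accession
  and seed effects perturb the scores. The low-rank structure is
  essential realism: iid coefficient noise in 64 dimensions would be
  linearly separable at absurd rates. Each seed's outline is then
  rebuilt at its drawn physical size and pushed through the *genuine*
  forward transform and normalization, so stored coefficients follow the
  same code path as real silhouettes, and the dorsal surface is the
  actual polygon area of the generated outline (preserving the
  length–surface coupling).
- **What it does not emulate**: real radicle grooves and textural detail,
  environment-by-accession interactions, measurement error of manual
  photography, or the exact per-cultivar coefficient values. End-to-end
  results on the panel therefore demonstrate that the pipeline recovers
  the *structure* it is pointed at (correlation patterns, variance
  concentration, discriminability ordering, projection behaviour), not
  that it reproduces any particular archive byte-for-byte.

Problem sizes used by the default test suite and the acceptance run — the
full 1625-seed panel for end-to-end statistics, 100–300-seed populations
for oracle comparisons, 20 seeded replicates for recovery bands — were
chosen to keep the whole suite fast while leaving Monte-Carlo bands well
clear of their thresholds.

## Degenerate inputs and numerical choices

Zero-length edges are deduplicated before the transform; an outline that
collapses after cleaning raises. Zero first-harmonic power cannot be
normalized. Constant columns cannot be standardized in PCA and name
themselves in the error. Constant responses yield zero SS and flagged
(NaN) F statistics rather than exceptions. t-tests on zero pooled
variance return (0, 1) by convention. All randomness flows through
`numpy.random.Generator` objects seeded from a single integer; repeated
runs with the same seed are byte-identical.

## Known limitations

- The species-level reproduction bands are structural, not printed-
  precision: a synthetic draw cannot (and should not) match archival data
  to rounding.
- Lognormal tails make extreme size maxima heavier than in the real
  measurements (bounded biological material).
- The rasterized-mask staircase slightly inflates perimeter relative to a
  smooth silhouette; subpixel contouring mitigates but does not remove it.
- The 180° canonical branch can flip for near-centrally-symmetric shapes
  whose even harmonics all vanish; seeds are far from this regime.
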