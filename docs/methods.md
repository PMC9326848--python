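# Methods

This note documents the statistical model behind `colocal`, the choices
made where the design was genuinely open, and what the synthetic studies
used for validation do and do not establish.

## Spatial model and score

Each image is treated as a marked point pattern: cell centroids in a
rectangular observation window W, marked by cell type. For an ordered
pair (i, j) — "j around i" — the empirical cross K-function is

    K̂_ij(r) = |W| / (n_i n_j) · Σ_{a ∈ i} Σ_{b ∈ j} 1[d_ab ≤ r] · e(a, b),

the (area-scaled) average number of type-j cells within r of a typical
type-i cell; under independence of the two processes E K = πr². For the
same-type case the zero-distance self-pairs are excluded and the
normaliser is n(n−1), the standard univariate convention.

Edge corrections for rectangular windows:

* `none` — e ≡ 1 (raw pair counts; biased near the boundary);
* `translation` (default) — e = |W| / ((L_x − |dx|)(L_y − |dy|)), the
  standard translation correction, cheap and well-defined for
  rectangles;
* `isotropic` — e = 1 / (fraction of the circle of radius d centred on
  the i-cell inside W), computed by an exact inclusion–exclusion over
  the four edges and corners; valid for all radii because opposite-edge
  exterior arcs can never overlap for an interior centre.

The default is `translation`; the choice is echoed in the results
configuration. Note that for `none` and `translation` the (i, j) and
(j, i) scores coincide exactly (same pairs, same symmetric weights, same
normaliser); only `isotropic` breaks the symmetry, because its circles
centre on the "from" cell.

The L-curve L̂(r) = √(K̂(r)/π) equals r under complete spatial
randomness, and the co-localization score is the plain sum (no
trapezoid weighting — each grid radius counts once)

    u = Σ_{r′ ∈ grid} [ L̂(r′) − r′ ],   default grid 10, 20, …, 100.

Radii are in the same (arbitrary) units as the coordinates; u is in
those units too and scales linearly when coordinates, window and radii
are scaled together. A single-radius grid is legal and reduces u to
L̂(r₀) − r₀. An image with zero cells of either type yields a missing
score that propagates to the inference stage, where it is dropped per
pair with a recorded count — never an exception.

K is evaluated sparsely: only pairs within the largest grid radius are
collected (KD-tree), sorted by distance, and accumulated; this is
algebraically identical to the dense double sum and is verified against
an independently coded brute-force oracle at 1e-10 relative tolerance
(the oracle's isotropic weight uses arc-interval measurement, a
different geometric algorithm than the closed form).

## Count-dependent variance and weights

The sampling variability of u explodes as the pair counts shrink, and
under clustered alternatives its mean moves too, so score rows are far
from equally informative. Following the u²-regression approach, the
surface

    fitted_u²(n_i, n_j) = c + g₁(log n_i) + g₂(log n_j)

is fitted by constrained least squares with each g_k non-increasing
(non-negative combinations of decreasing piecewise-linear ramps on up
to 8 quantile knots), so monotonicity holds by construction; it is also
probe-tested after every fit. Fitting u² deliberately conflates variance
and squared mean — both grow at low counts under clustering, and both
reasons to down-weight apply. Weights are 1/max(fitted, floor) with
floor = max(10⁻³ × median fitted, 10⁻¹²), normalised to mean 1 over
defined rows (cosmetic: both downstream models are invariant to a global
weight rescale, which is asserted in tests). Prediction outside the
fitted count range clamps to the range edge (flat extrapolation of a
monotone surface). Weights pool all ordered pairs by default —
`per_pair` surfaces are available but need ≥ 20 defined scores per pair.

Caveat: if cell number is confounded with the degree of co-localization
change, down-weighting low-count images can mask real differences; no
mitigation is attempted.

## Inference

Per ordered pair, with x the condition (treatment-coded against a
configurable reference level when categorical; multi-level conditions
yield one result per non-reference contrast) and optional covariates:

* linear model — weighted least squares, Var(ε_row) = σ²/w_row,
  two-sided t with df = n − p;
* mixed model — adds a subject random intercept α_s ~ N(0, τ²), used
  automatically when a subject grouping exists and any subject has more
  than one image.

The mixed model is fitted by REML, profiling the criterion over the
variance ratio λ = τ²/σ²: per-subject Woodbury identities reduce one
evaluation to O(subjects · p²), a deterministic coarse log-grid scan
brackets the optimum, and a bounded scalar minimisation (tolerance
1e-10) refines it — no random starts, so refits are bit-identical. λ = 0
is a legal boundary solution, flagged in the result. The criterion is
compared at λ = 0 and λ̂ with a small relative tolerance because a flat
profile (e.g. one image per subject with equal weights, where λ is
unidentified) drifts below the boundary value by float cancellation.

P-values for a fixed-effect contrast c use Satterthwaite's effective
degrees of freedom

    df = 2 [Var̂(c′β̂)]² / (g′ A g),

where g is the (numerical) gradient of the contrast variance with
respect to (τ², σ²) and A the inverse observed information of the REML
criterion (numerical Hessian, central differences away from the τ² = 0
boundary). At a boundary fit the model has collapsed to weighted least
squares and df = n − p is reported — the same behaviour lmerTest
exhibits, against which this implementation was verified to machine
precision on fixtures (β, SE, τ̂², σ̂² and boundary df all agree).

In the balanced intercept-dominated case the Satterthwaite df reproduces
the exact between-subject df (m − 2) to < 0.1, and the 95% CI for β
attains 92–98% coverage over 500 generating-model replicates.

Raw p-values are reported by default; Benjamini–Hochberg adjustment
across all tested pairs is available (and advisable when many types are
screened). The heatmap export writes sign(β)·(−log₁₀ p) with "from"
types on rows and "to" types on columns; untestable pairs are missing.

## Synthetic studies

The simulator generates the benchmark design: a 1000×1000-unit window,
40 subjects in two groups of 20, three images per subject, two cell
types. Per image, type A is homogeneous Poisson with expected count
drawn uniformly from {20, 40, …, 400}; type B is inhomogeneous Poisson
with intensity proportional to the disc-kernel density of the realised A
pattern (evaluated on a 128×128 pixel grid, renormalised to integrate to
one, scaled by an independent uniform count draw). Each subject draws a
co-localization bandwidth once from Poisson(sigma), with sigma = 40 in
group 1 and sigma + delta (delta = sigma/3) in group 2 under the
difference regime; both groups use sigma under the null. Following the
usual kernel-smoothing convention the uniform disc is scaled so its
standard deviation equals the bandwidth, i.e. the disc radius is twice
the draw — with a radius equal to the raw draw, group separation in the
score is much weaker and the benchmark AUCs reported for this class of
design are not attainable. Sharing the bandwidth across a subject's
images induces the subject-level correlation the random intercept is
meant for; a larger bandwidth spreads B more diffusely, so the
difference regime *lowers* group 2's u. Zero bandwidth draws are
redrawn; an empty A pattern falls back to homogeneous B (both logged in
the ground truth).

Randomness is a splittable seed-sequence tree (study seed → subject
stream + one stream per image; replicate r of regime g seeds from
(master_seed, g, r)), making every study and replicate bit-reproducible
in isolation.

Grid resolution enters only through the B-placement discretisation
(pixels of ~8 units at the default 128×128); image counts and scores are
insensitive to it well below the default radii scale.

What the synthetic studies do not emulate: more than two cell types,
segmentation or classification error, marker expression, irregular
windows, unequal group sizes, or spatial correlation between a subject's
images beyond the shared bandwidth. Passing benchmarks therefore
demonstrates the statistical machinery under the stated generative
model, not robustness to real-data artefacts.

## Benchmark evaluation

A benchmark run simulates n_null null and n_diff difference studies and
runs the full pipeline on each, keeping the A→B p-value per weighting
mode. The AUC of the ROC that ranks difference replicates as positives
by ascending p-value is computed by the rank (Mann–Whitney) formulation
with ties at ½ — identical to the trapezoid area under the empirical
ROC, and oracle-tested against exhaustive pair counting. Rejection rates
use strict inequality p < α and carry exact Clopper–Pearson 95%
intervals. Replicate failures are recorded and excluded; a run errors if
they reach 5%.

Problem sizes used by the shipped checks: the acceptance script runs
100 + 100 replicates of the full default design (the test suite uses
200 null + 100 difference), a scale at which the AUC's Monte-Carlo
standard error is ≈ 0.02–0.03; component-level checks use 50 oracle
patterns, 200 CSR images and 500 mixed-model replicates.

## Known limitations

* Only rectangular windows; no inhomogeneous K variants, no
  nearest-neighbour or touching-cell association measures.
* Random intercepts only — no random slopes or crossed designs.
* The u²-based weights inherit the mean/variance conflation discussed
  above.
* The Satterthwaite information matrix is numerical; in near-degenerate
  fits (information not positive definite) the df conservatively falls
  back to n − p.
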