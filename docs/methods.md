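# Methods

This note documents the models and numerical choices behind `canalmorph`: what
each stage computes, the defaults and why, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Landmark scheme and resampling

A canal system is digitised as four centreline polylines — anterior, posterior
and lateral canals plus the crus commune — pinned to five anchor landmarks at
the canal junctions (`ant_vestibule`, `post_vestibule`, `lat_posterior`,
`crus_apex`, `crus_base`; anatomy and ordering documented in
`canalmorph.resample`). Each curve is resampled to points equally spaced in
arc length *measured on the piecewise-linear polyline*; no spline is fitted.
This makes resampling deterministic, invariant to refinement of the input
polyline (inserting midpoints changes outputs by < 1e-9), and commutative with
rigid motions. Curve endpoints must land within a snap tolerance
(default 1e-6 × curve arc length) of their designated anchors and are replaced
by the exact anchor coordinates. Defaults of 28 semilandmarks per canal and 3
on the crus give k = 92 landmarks, of which 87 slide and 5 are fixed. The
three crus points are interior sliding points; the junction landmarks are
counted among the five anchors.

## Superimposition with sliding semilandmarks

Generalized Procrustes analysis removes position (centering), size (scaling to
unit centroid size — full Procrustes; centroid sizes in mm are stored
separately for allometry) and orientation (Kabsch rotation with reflections
forbidden: the smallest singular direction is sign-flipped when the
unconstrained optimum is improper). The consensus is recomputed each iteration
until it changes by less than `tol` (default 1e-8, usually 3–5 iterations).

Semilandmark sliding minimises thin-plate-spline bending energy against the
current consensus. The 3D TPS kernel is U(r) = −r, the conditionally positive
definite choice, so the bending-energy matrix (the k×k upper-left block of the
inverted TPS system) is PSD with all affine deformations in its null space.
Tangent directions are centred finite differences of each landmark's curve
neighbours, with the adjacent anchor serving as the neighbour at curve ends;
anchors never slide. With one sliding degree of freedom per semilandmark the
energy is quadratic in the slide amounts and the minimiser solves a small
linear system in closed form; an ill-conditioned system falls back to the
minimum-norm solution, and a slide that fails to reduce energy (numerically)
is skipped and logged.

Two numerical choices matter here:

* **Fresh sliding each iteration.** Slides are recomputed from the pristine
  configurations against the current consensus rather than accumulated;
  accumulated slides let points creep along the curves indefinitely.
* **Common-slide removal.** The mean sliding displacement across specimens is
  subtracted before the consensus update. That component is a pure
  reparametrization of the consensus along the curves — it carries no
  between-specimen shape information — and if left in place the consensus
  drifts by ~1e-3 per iteration instead of converging (observed on synthetic
  data); with it removed the algorithm reaches machine precision in 3–5
  iterations.

After convergence everything is rotated into a canonical frame built from the
consensus' principal axes (signs fixed by the largest-magnitude projection,
det +1), which makes outputs deterministic and invariant to arbitrary rigid
motions and scalings of the inputs.

## Ordination

PCA is an SVD of the column-centred shape variables; eigenvector signs follow
a fixed rule (largest-magnitude loading positive) for cross-platform
determinism. Out-of-sample specimens (fossils) are ordinary-Procrustes fitted
(centre, unit scale, rotate — no sliding) to the training consensus and
projected by multiplication with the eigenvectors; they never influence the
eigendecomposition, mirroring how specimens excluded from a morphospace are
placed into it. Shape warps at axis extremes invert the projection
(mean + score·axisᵀ).

The phylomorphospace places internal nodes at joint maximum-likelihood
ancestral estimates under Brownian motion, obtained by solving the
branch-length-weighted graph-Laplacian system per axis; the root estimate
coincides with the GLS mean (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹y.

Group separation across ordination axes is tested per axis by one-way ANOVA
with permutation p-values (the question asked of these tests is *which axes*
separate groups, which is inherently per-axis); a joint trace-statistic test
over all retained axes is reported alongside.

## Comparative statistics

The phylogenetic covariance C has entries equal to shared root-to-MRCA path
lengths. Multivariate phylogenetic signal is the Blomberg ratio generalised by
traces: with D the deviations of tip data from the GLS mean,
K = [tr(DᵀD)/tr(DᵀC⁻¹D)] / [(tr C − n/1ᵀC⁻¹1)/(n − 1)], so E[K] = 1 under
Brownian motion; significance comes from tip-label permutations with the
observed arrangement counted in numerator and denominator.

Procrustes ANOVA partitions tr(YᵀY) sequentially (Type I, terms in user
order — matching the conventional ANCOVA table layout) using nested QR/SVD
projector bases, which is numerically equivalent to partitioning squared
Procrustes distances and remains defined when variables outnumber specimens.
Significance is by RRPP: for each term the reduced-model (preceding terms)
residuals are permuted, added back to the reduced fit, and the term SS
recomputed; one permutation-index matrix is shared across terms per iteration,
p = (1 + #{SS* ≥ SS})/(1 + nperm) ≥ 1/(nperm + 1), and the effect size is
Z = (SS − mean SS*)/sd SS* on the raw SS distribution (a simple, monotone
standardisation; other software may standardise on a transformed scale, so Z
values are comparable within, not across, implementations). PGLS premultiplies
the data and the whole model matrix, intercept included, by the
eigendecomposition-based C^(−1/2); on a unit-depth star phylogeny it is
exactly the ordinary ANOVA. Pure Brownian motion is assumed throughout (no
Pagel's λ or OU scaling).

Pairwise group-mean tests use the Euclidean distance between group mean shapes
with a reduced-model (intercept-only) RRPP null — permuting residuals of the
group model instead deflates the null by the (n − g)/(n − 1) variance deficit
and measurably inflates type-I error. Phylogenetic residuals are per-column
GLS regressions (β = (XᵀC⁻¹X)⁻¹XᵀC⁻¹Y) returned in the original space.
Allometric slopes are OLS with t-based confidence intervals; in the log–log
convention a slope below 1 is negative allometry.

All permutation machinery takes an explicit seed; the default of 10,000
permutations/resamples applies wherever a test is reported.

## Classification

Before CVA the PC scores are reduced to the leading axes jointly representing
the variance target (default 99%): the largest axis count whose cumulative
variance does not exceed the target, capped at min(hard_cap,
n − g − 1) — default hard cap 40 — so the pooled within-group covariance stays
invertible and trailing noise axes are excluded. CVA axes are generalized
eigenvectors of the between-group against the pooled within-group covariance,
scaled so the pooled within-group covariance of the canonical scores is the
identity; Euclidean distance in CV space is therefore Mahalanobis distance D.
Pooled (not per-group) covariances are used everywhere — per-group estimates
are unstable at realistic group sizes. Cross-validation is leave-one-out with
the CVA refit without the held-out specimen each time.

Typicality probabilities compare a specimen's D to a group mean against a
bootstrap null: each of `nresample` draws resamples the group members with
replacement and contributes the original members' distances to the resampled
mean; the pooled null with a +1 correction gives
p = (1 + #{null ≥ d})/(1 + pooled count) ∈ (0, 1]. Distances are recomputed in
every draw (not drawn from the fixed empirical distance set). Membership is
rejected at p < 0.05; `rejected_all` marks specimens rejected by every group.
Calibration on held-out members of the generating distribution is ≈5–6%
rejection at α = 0.05 (slightly anticonservative by O(1/n) because the test
specimen's distance uses the estimated mean). Log-likelihoods are multivariate
normal densities with the pooled covariance; assignment is the argmax, ties
break by group-label order and are flagged, and a softmax-normalised relative
likelihood is reported beside the raw values since the assignment has no
"none of the above" alternative. Confidence ellipses scale the group
covariance by the χ²(2 d.f.) quantile.

Unknowns (fossils and unassigned species) go through the same PC reduction and
the trained canonical axes; they never influence the CVA fit. The pipeline's
full-dataset alignment (ontogenetic series included) feeds the CVA stage,
while the phylogenetic subset (largest adult male per species, matched to the
tree) feeds signal/PGLS — two alignments, selected in the configuration.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical* structure the analyses assume, not
real canal anatomy beyond the qualitative loop/torsion/crus geometry:

* **Template** — three near-circular loops in approximately orthogonal planes
  joined by a crus segment; parameters control in-plane eccentricity,
  sinusoidal out-of-plane torsion (zero at the endpoints, so torsion 0 gives
  exactly planar loops) and crus length.
* **Phylogeny** — a pure-birth ultrametric tree, depth normalised to 1, with
  every tip branch extended by 5% of the depth (the birth process stops at the
  n-th speciation, which would otherwise leave a zero-length cherry and a
  singular covariance).
* **Shape evolution** — Brownian motion along three fixed random orthonormal
  shape directions; default tip standard deviation 0.02 per dimension
  (rate 4e-4 per unit depth).
* **Ecomorphs** — six groups, each a distinct template-parameter deformation
  (anterior torsion for CG, anterior eccentricity for GB, lateral torsion for
  TC, lateral eccentricity for TG, crus length for Tr, posterior
  eccentricity+torsion for Tw), unit-normalised in shape space and scaled by
  `ecomorph_effect` (default 0.04 Procrustes units). Labels are assigned
  round-robin along a random species permutation, so groups are convergent
  scatters across the tree, never clades. Eight "unique" species get their own
  random mixture directions at 0.7× effect.
* **Noise and allometry** — isotropic landmark noise (default sd 5e-4 per
  coordinate, i.e. ≈0.008 Procrustes units at k = 92, making the default
  ecomorph effect five times the total noise); an allometric shape shift of
  0.03 Procrustes units per unit log centroid size along one fixed direction;
  ontogenetic size series per species; skull length generated so that log CS
  regresses on log skull length with slope 0.63 (negative allometry).
* **Covariates** — perch height/diameter drawn independently of shape unless
  `perch_association` is switched on.
* **Fossils** — offsets of 5× the ecomorph effect along mixtures of group and
  novel directions, far outside every group by construction.

Consequences for interpretation: passing tests show the pipeline recovers
known effects under these conditions; they do not show that real µCT data meet
them. In particular, any non-phylogenetic variance *attenuates K*: both
landmark measurement noise (the C⁻¹ weighting amplifies independent noise on
short terminal branches) and the allometric shape component (sizes are drawn
independently of the tree) pull the dataset-level K under pure BM below 1
(~0.83 on average at the defaults), which is why the BM-recovery check is run
at the generator's zero-noise, zero-allometry control and why a
phylogenetic-residual correction for size exists in the comparative module.
Real digitising error and real allometry do the same to empirical K values.

## Problem sizes and defaults used in checks

The test suite and acceptance script use the generator's default study design
(41 species, six ecomorph groups of 3–9 species, 8 unique species, 3-specimen
ontogenetic series ≈ 123 modern specimens, 5 fossils) for end-to-end runs, and
reduced permutation counts (500) over 1,000 replicates for the null
calibration sweeps; low-resolution schemes (6–8 semilandmarks per canal) are
used where only algorithmic properties are at stake. Reported calibration
quantities are recomputed, never stored.

## Known limitations

* Brownian motion only; no λ/OU covariance models and no combined
  ontogenetic-phylogenetic model (the two alignments are analysed separately).
* No missing-landmark estimation; configurations must share k.
* Typicality is bootstrap-based only (no parametric F approximation) and is
  mildly anticonservative for small groups.
* The Z effect-size convention (raw SS scale) may differ from other software.
* The canal template is a qualitative stand-in; synthetic results quantify
  method behaviour, not *Anolis* biology.
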