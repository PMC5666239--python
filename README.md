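# canalmorph

Geometric-morphometric and phylogenetic-comparative analysis of semicircular-canal
shape, built for testing ecomorphological convergence in *Anolis* lizards and for
placing out-of-sample (fossil) specimens against modern ecomorph groups.

The semicircular canals — the balance organ of the inner ear — are digitised as
centreline curves through the three canals (anterior, posterior, lateral) and the
crus commune. `canalmorph` covers the full analysis chain:

1. **Semilandmark scheme** — each centreline is resampled to equally-spaced
   (arc-length) semilandmarks anchored at five fixed junction landmarks; the
   default scheme (28 per canal + 3 crus + 5 anchors) gives k = 92 landmarks.
2. **Sliding-semilandmark GPA** — generalized Procrustes superimposition
   (translate, scale to unit centroid size, rotate) in which semilandmarks slide
   along their tangent directions to minimise the thin-plate-spline bending
   energy against the consensus (3D kernel U(r) = −r).
3. **Ordination** — PCA of the Procrustes shape variables, min/max shape warps by
   back-transformation through the eigenvectors, out-of-sample projection of
   fossils (ordinary Procrustes fit, then score = (x − x̄)·V), phylomorphospace
   with Brownian-motion (GLS) ancestral estimates, and per-axis permutation
   ANOVAs of group separation.
4. **Comparative statistics** — multivariate phylogenetic signal
   K = [tr(DᵀD)/tr(DᵀC⁻¹D)] / E_BM, with D the deviations from the GLS mean and
   C the shared-path-length covariance; Procrustes ANOVA/ANCOVA and phylogenetic
   GLS with sequential (Type I) trace sums of squares and residual-randomization
   permutation (RRPP); pairwise group-mean shape tests; phylogenetic regression
   residuals; allometric OLS slopes with t-based confidence intervals.
5. **Classification** — CVA on the leading PCs (within-group covariance
   whitened, so CV-space Euclidean distance is Mahalanobis distance D),
   leave-one-out cross-validation, bootstrap **typicality probabilities** of
   group membership (reject at p < 0.05), and multivariate-normal
   log-likelihood assignment, which always names a nearest group — the
   contrast between the two flags specimens outside every known group.
6. **Synthetic data** — a parametric canal template (loop eccentricity,
   out-of-plane torsion, crus length), a pure-birth ultrametric phylogeny,
   Brownian-motion shape evolution, convergent ecomorph offsets scattered
   across the tree, ontogenetic size series with a known allometric slope,
   and fossil outliers, all fully seeded — so every stage is testable against
   known ground truth.

## Worked example

```python
import numpy as np
from canalmorph.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(simulate={"n_species": 41, "n_per_species": 3},
                        nperm=999, nresample=999, seed=1)
results = run_pipeline(config)

print("phylogenetic subset n =", results["phylo_subset_n"])
print("PC1-3 variance fractions:",
      np.round(results["pc_variance_fractions"][:3], 3))
sig = results["phylo_signal"]
print(f"phylogenetic signal K = {sig['K']:.3f} (p = {sig['p']:.4f})")
```

prints (with the remaining result keys summarised the same way):

```
phylogenetic subset n = 41
PC1-3 variance fractions: [0.225 0.193 0.153]
phylogenetic signal K = 0.231 (p = 0.0910)
ecomorph R2 = 0.793 (p = 0.0010)
allometric slope = 0.629 (95% CI 0.624-0.635)
CVA: 40 PCs retained, LOO accuracy = 100.0%
fossils rejected by typicality: 5 of 5 | likelihood assignments: CG, Tw, Tw, GB, GB
```

Reading the output: the simulated radiation has 41 species (three specimens
each, an ontogenetic series); six convergent ecomorph offsets dominate shape, so
the group term explains most of the Procrustes variance and leave-one-out CVA
classification is perfect, while convergence drags the phylogenetic signal K
well below its Brownian-motion expectation of 1. The generator's size series
was built with a log CS / log skull-length slope of 0.63 (negative allometry),
which the regression recovers. The five fossils were generated far outside all
six groups: typicality rejects their membership in every group, yet the
log-likelihood rule — which has no "none of the above" option — still names a
nearest ecomorph for each.

The same stages are available from the shell:

```sh
canalmorph simulate --species 41 --seed 7 --outdir data/
canalmorph -v anova --landmarks data/landmarks.csv --metadata data/metadata.csv \
    --scheme data/scheme.json --terms ecomorph,log_cs --nperm 9999 --seed 1
canalmorph run --config pipeline.yaml
```

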