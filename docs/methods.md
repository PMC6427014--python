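# Methods

This package reimplements, as tested and reusable code, the multivariate
quantitative-genetics divergence workflow used to characterize germplasm
from replicated fruit-biometrics trials — here the bacaba-de-leque palm
(*Oenocarpus distichus*), evaluated on a completely randomized design of 15
genotypes × 14 fruits × 8 traits (fruit length FL and width WF in mm; fruit,
pulp and seed mass FM, PM, SM in g; pulp and almond thickness PT, AT in mm;
pulp yield per fruit PY in %). The raw measurements were never deposited;
what the study prints — the 15×15 Mahalanobis D² matrix, the per-trait
genetic-parameter table and two eigenvalue spectra — is bundled as text
fixtures (`bacaba/data/`), and everything else is validated on synthetic
trials with known truth.

## Model and estimators

**One-way ANOVA and genetic parameters.** For genotype *i*, fruit *k*,
trait *t*, the model is `y_ikt = mu_t + g_it + e_ikt`. In a balanced layout
with G genotypes and r replicates, the genotype mean square GMS estimates
`sigma2_e + r*sigma2_g` and the residue mean square RMS estimates
`sigma2_e`, giving

    sigma2_g = (GMS − RMS) / r          (clamped at 0 with a warning)
    h2mp     = 1 − RMS / GMS            (heritability of genotype means)
    CVe%     = 100·sqrt(RMS) / mean,  CVg% = 100·sqrt(sigma2_g) / mean

Balance is required, not silently patched: these estimators are undefined
otherwise. An explicit `allow_unbalanced=True` substitutes the harmonic
mean of the replicate counts, at the caller's risk. Note that `1 − RMS/GMS`
carries a small-sample bias of about `−(1 − h2mp)·df_g/(df_g − 2) + (1 −
h2mp)`; at G = 15 (df_g = 14) this is ≈ `−0.17·(1 − h2mp)`, i.e. −0.02 at
h2mp = 0.9. Recovery tests account for it; the pipeline reports the
classical estimator unchanged because that is what practitioners in this
analysis family publish.

**Scott-Knott grouping** of genotype means follows the original
likelihood-ratio recursion: at a node holding k sorted means, the
contiguous 2-partition maximizing the between-groups sum of squares B0 is
tested with `lambda = pi/(2(pi−2)) · B0 / sigma0²`, where `sigma0² =
[Σ(ȳ−ȳ̄)² + df_e·RMS/r]/(k + df_e)`, against the chi-square critical value
with the fractional degrees of freedom `k/(pi−2)`; the node splits while
lambda exceeds it. Default test level 5%.

**Multicollinearity screen.** Pearson correlations are computed over
genotype means by default (`corr_basis` would be the thing to change if a
residual-correlation screen were wanted; the divergence analysis itself
operates on means, and the choice is logged). Diagnostics: eigenvalues in
descending order; condition number CN = λ₁/λₚ classified weak (< 100),
moderate (100–1000) or severe (> 1000); condition indices σ₁/σⱼ =
sqrt(λ₁/λⱼ) — this, not λ₁/λⱼ, reproduces the published pairing of
singular value 0.0503 with condition index 46.60; VIFs as the diagonal of
R⁻¹ (spectral pseudo-inverse with a warning when λₚ ≤ 1e−12). The exclusion
loop removes the largest-VIF trait (ties resolve to the offender flagged by
the smallest eigenvalue, then to the later column) until CN < 100 and max
VIF ≤ 10.

**Mahalanobis D².** The weighting matrix Ψ is the pooled residual
covariance on the per-observation scale (error SSCP divided by its degrees
of freedom, G(r−1)); dividing by r instead would only rescale D² by r, and
the per-observation convention matches the magnitude of the published
matrix. D² is computed per pair through a Cholesky solve of Ψ rather than
an explicit inverse. Distance summaries count a pair as "above the mean"
only under strict inequality. Divergence runs on the post-exclusion trait
set.

**Singh contributions.** With δ the mean difference of a genotype pair and
w = Ψ⁻¹δ, the per-trait totals `S_j = Σ_pairs δ_j·w_j` decompose the total
pairwise D² exactly; CR% normalizes S to 100. Near-zero negative CR values
(numerical noise) are clamped with a warning; genuinely negative
contributions are reported as such.

**Tocher grouping.** θ is fixed once as the largest nearest-neighbour
distance in the full matrix. A group seeds with the closest remaining pair
(even if that distance exceeds θ — the pair still forms a group); the
remaining genotype with the smallest average distance to the group is
admitted while that average is ≤ θ, ties by label order; a final leftover
genotype forms a singleton. The admission statistic is deliberately the
candidate's average distance to the group: the alternative
(group-mean-after-inclusion ≤ θ) fails to reproduce the published
three-group partition on the bundled D² matrix (it merges all 15
genotypes into one group).

**UPGMA, Mojena cut, cophenetic correlation.** Average-linkage
agglomeration runs directly on the supplied D² values (no square root),
matching the scale of the published dendrogram; the merge history is also
exportable as an ultrametric Newick string (leaf depth = half the root
fusion level). The Mojena cut thresholds the fusion levels at `mean +
k·sd` with k = 1.25 (the Milligan–Cooper recommendation; the study does
not print its constant) and sample sd (ddof = 1; ddof = 2 available). On
the bundled matrix this yields exactly three groups identical to the
Tocher partition. The cophenetic correlation is the Pearson correlation of
the pairwise lowest-common-merge levels against the original distances
over the 105 unordered pairs. Representation fidelity is reported as
Kruskal stress-1 (`100·sqrt(Σ(d−d̂)²/Σd²)`) and distortion
(`100·(1 − Σd̂²/Σd²)`, floored at zero alongside the signed value); the
published 16%/20% figures do not state which representation or exact
formulas they refer to, so these are reported, never gated on.

**Canonical variables.** W is the pooled within-group covariance (same Ψ);
B the between-group covariance on the per-observation scale, `r·Σ(ȳᵢ −
ȳ)(ȳᵢ − ȳ)ᵀ/(G−1)`. The generalized eigenproblem is solved in the
symmetric reduced form `L⁻¹ B L⁻ᵀ` with W = LLᵀ (spectral pseudo-factor
with cutoff 1e−12·λmax if W is singular); weighting vectors a = L⁻ᵀu
satisfy aᵀWa = 1, so squared Euclidean distances between genotype scores in
the full canonical space equal D² exactly — an identity the tests assert at
1e−6. Eigenvector signs follow the convention that each vector's
largest-magnitude element is positive. With G − 1 < p the trailing
eigenvalues are zero and reported, not errored.

**Correlation networks.** The hard-limit adjacency is `H(r) = ½(sgn(|r| −
ρ) + 1)` with default ρ = 0; the boundary case |r| = ρ literally yields ½
and is kept as a connected edge tagged "boundary" (exactly-zero
correlations carry no edge — a weight-0 edge is meaningless). Display tiers
flag edges with |r| ≥ 0.3 and ≥ 0.7; the sign attribute supports the
conventional green/red rendering. The Fruchterman–Reingold layout is
implemented directly (repulsion k²/d, attraction d²/k weighted by |r|, k =
sqrt(area/n), linear cooling) so that it is deterministic under a seed and
its potential-energy trajectory is observable in tests; exports are
GraphML or DOT.

## Synthetic data

`simulate_population` draws `y_ikt = mu_t + c_it + g_it + e_ikt` with `g_i
~ MVN(0, G)`, `e_ik ~ MVN(0, E)` and c_i an optional planted cluster
centroid shift. Normality is the ANOVA-consistent choice.
`simulate_from_target_parameters` inverts the parameter definitions —
`G_tt = (CVg_t·mu_t/100)²`, `E_tt = r·G_tt·(1 − h2mp_t)/h2mp_t` — so the
estimators recover the targets in expectation. The default study
configuration uses the published design (15 × 14 × 8) and the published
means, CVg and h2mp per trait. No genetic correlation matrix was published,
so traits are uncorrelated by default; `derive_py=True` computes PY =
100·PM/FM per fruit instead, reproducing the ratio-trait collinearity
pathology (a derived PY has no closed-form variance components, so its
planted truth is NaN).

Planted clusters are additive mean shifts (G and E, hence heritabilities,
unchanged) with centroids at regular-simplex vertices in the per-trait
scale of a genotype mean's standard deviation sqrt(diag(G + E/r)), all
pairs of centroids equally far apart (6 sd per trait in rms by default).
Collinear centroid placement would make the two inter-cluster fusion
levels differ fourfold and defeat the Mojena cut for purely geometric
reasons.

What the generator does **not** emulate: non-normal and skewed trait
distributions, measurement truncation, spatial or pedigree structure among
palms, unbalanced losses (available only as an explicit robustness option),
and genetic correlations between traits. Passing recovery tests therefore
show estimator correctness under the model's own assumptions, not
robustness to their violation.

## Numerical and design choices

- Distance matrices must be symmetric to 1e−9 with zero diagonal;
  triangle-dialect CSVs are mirrored on read; writes always store the full
  square form. Genotype labels are opaque strings, never reindexed.
- Eigenvalues below 1e−12 are treated as exact zeros throughout;
  pseudo-inverses replace inverses with a warning.
- RMS = 0 (noise-free data) reports F = +inf with p = 0 and a warning;
  GMS < RMS clamps the genetic variance at zero with a warning.
- All Monte-Carlo tests use fixed seed sequences and are deterministic.
  Problem sizes in the test-suite oracles (e.g. 200–500 replicates of the
  15 × 14 design, 2000 genotypes for covariance convergence) were chosen as
  the smallest sizes at which Monte-Carlo error is clearly below the
  asserted tolerances.

## Known limitations

- The published cophenetic correlation (0.96) is not reproducible from the
  published D² matrix: UPGMA on those distances gives r = 0.76 under every
  standard linkage/scale variant we examined. The package reports the
  honest recomputation.
- The published mean distance 11.44 differs from the mean of the printed
  2-dp matrix entries (11.4322) by more than rounding of the mean alone
  can explain; agreement is asserted to one unit of the last printed digit.
- Tocher grouping, with the admission rule that reproduces the published
  partition, systematically fragments multivariate-normal planted clusters
  of roughly equal size: θ (largest nearest-neighbour distance) sits below
  the typical member-to-group average distance, and the effect is
  scale-invariant. Partition-recovery benchmarks should rely on
  UPGMA+Mojena, which recovers well-separated planted partitions
  essentially always.
- No mixed-model/REML estimation, no multi-environment designs, no
  alternative dissimilarities or linkages, no partial-correlation networks.
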