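# bacaba

Multivariate genetic-divergence analysis of replicated phenotype trials,
built around the classical germplasm-characterization workflow: per-trait
ANOVA with genetic parameters (CVg%, CVe%, progeny-mean heritability h²mp)
and Scott-Knott means grouping; multicollinearity screening of the trait
correlation matrix (condition number, condition indices, VIF, iterative
exclusion); Mahalanobis D² divergence between genotype means; Tocher
optimization grouping and UPGMA dendrograms with the Mojena cut and
cophenetic correlation; canonical variables; Singh per-trait contributions
to divergence; and signed, hard-thresholded trait-correlation networks.

The package is organized around the fruit-biometrics study of the Amazonian
palm *Oenocarpus distichus* (bacaba-de-leque): 15 genotypes × 14 fruits × 8
traits. The study's published D² matrix and genetic-parameter table are
bundled as text fixtures; since the raw measurements were never deposited,
a first-class synthetic-data generator reproduces the design with known
ground truth (planted heritabilities, genetic CVs, cluster structure) so
every stage can be validated end to end.

## The core quantities

For a balanced one-way layout with G genotypes and r replicates:

- `h²mp = 1 − RMS/GMS`, `σ²g = (GMS − RMS)/r`, `CVg% = 100·√σ²g / ȳ`
- `D²(i,i′) = (x̄ᵢ − x̄ᵢ′)ᵀ Ψ⁻¹ (x̄ᵢ − x̄ᵢ′)` with Ψ the pooled residual
  covariance (error SSCP / df)
- Tocher: groups grow while a candidate's average distance to the group
  stays below θ, the largest nearest-neighbour distance of the matrix
- Mojena cut: dendrogram cut at `mean + k·sd` of the UPGMA fusion levels
  (k = 1.25)
- Singh: `S_j = Σ_pairs δ_j (Ψ⁻¹δ)_j` decomposes total D² exactly by trait
- Network adjacency: `H(r) = ½(sgn(|r| − ρ) + 1)` with display tiers at
  |r| ≥ 0.3 and ≥ 0.7

See `docs/methods.md` for the full model, conventions and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole workflow; each writes
its tables under `results/`. Reproducing the published divergence
structure from the bundled D² matrix:

```sh
$ python analysis/01_reference_divergence.py
D2 range 0.07-48.10, mean 11.43
least divergent pair ('3', '15'), most divergent ('2', '8')
39% of pairs above the overall mean
Tocher (theta=13.32):
  group 1: 3 15 7 11 12 10 9 1 6 13 4 5
  group 2: 2 14
  group 3: 8
UPGMA + Mojena(k=1.25): 3 groups; cophenetic r = 0.761
```

Genotypes 3 and 15 are the least divergent pair (D² = 0.07), 2 and 8 the
most divergent (48.10); Tocher allocates 12 of the 15 palms (80%) to one
group, isolates the pair {2, 14} and leaves the most divergent genotype 8
alone — and the Mojena cut of the UPGMA dendrogram reproduces exactly the
same three groups. Scripts 02–07 then simulate a synthetic trial at the
same design (with pulp yield derived as PY = 100·PM/FM to plant the
ratio-trait collinearity), estimate its genetic parameters, screen and
exclude collinear traits, and rerun divergence, clustering, canonical
variables and the correlation networks against the planted truth.

The same stages are available as a CLI (`bacaba simulate|anova|
collinearity|distance|singh|cluster|canonical|network|run-all`) and as a
single call, `bacaba.pipeline.run_full(table)`.

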