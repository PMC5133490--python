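# Methods

## Model

`pathvc` treats a pathway's expression profile as the covariance structure of
a random effect.  For N individuals with phenotype y, fixed covariates X
(intercept, sex, age) and pedigree-derived expected relatedness Φ₂ (the 2φ
matrix), the alternative model is

    y = Xβ + g + p + e
    g ~ N(0, σ²_A Φ₂),  p ~ N(0, σ²_P S),  e ~ N(0, σ²_e I)

where S is an N×N similarity kernel built from the individuals' unit-scaled
expression over the pathway's probes.  The null model omits p.  Heritability
is h² = σ²_A/(σ²_A+σ²_P+σ²_e); the pathway's variance share is defined the
same way on σ²_P.

The pathway test is a likelihood-ratio test of σ²_P = 0.  Because the tested
parameter lies on the boundary of [0, ∞), the LRT statistic is referred to
the ½χ²₀ + ½χ²₁ mixture: p = ½·P(χ²₁ > Λ) for Λ > 0 and p = ½ at Λ = 0.  A
plain χ²₁ reference is available (`null_distribution="chi2_1"`) for
comparison; the mixture is the default.  In finite samples the point mass of
the statistic at zero typically exceeds ½ (we measure ≈0.64 under the null
study conditions below, because the expression kernel partly overlaps the
kinship structure), so the mixture p-values are mildly conservative: the
empirical size at the 5% level is ≈0.02–0.03 rather than exactly 0.05, and
never inflated.  This is the expected behaviour of boundary
variance-component tests, not an implementation artefact; the test suite
asserts size control at α ∈ {0.01, 0.05, 0.10} and two-sided calibration at
the working level 0.05.

## Similarity kernels

Sixteen metrics are implemented.  Three are similarities used directly —
profile correlation (each individual's profile centered by its own mean over
the pathway's probes), cosine, and extended Jaccard (Tanimoto,
xy/(xx+yy−xy)).  Thirteen are distances converted by s = 1/(1+d):
Bhattacharyya, Bray–Curtis, Canberra, Chebyshev, chord, divergence,
Euclidean, geodesic, Hellinger, Mahalanobis, Manhattan, Soergel and
Whittaker.  Formula conventions for the less standard ones:

- Canberra and divergence terms with zero denominators contribute 0.
- Chord is the Euclidean distance between ℓ2-normalized profiles; geodesic
  is the corresponding great-circle angle, computed as 2·arcsin(chord/2)
  (numerically exact at zero distance).
- Hellinger is the Bhattacharyya formula applied to ℓ1-normalized profiles;
  Whittaker is half the Manhattan distance between ℓ1-normalized profiles.
- Mahalanobis uses the probe covariance estimated across all individuals,
  with a ridge of 10⁻⁶ × mean diagonal added when the condition number
  exceeds 10¹⁰ (pathways with more probes than individuals are common).

Every metric is verified against a naive double-loop transcription of its
formula to 10⁻¹⁰, and against scikit-learn where it implements the same
metric.

Before model fitting a kernel is standardized to mean diagonal 1 (the
kinship scale, making σ² values comparable across pathways and methods) and
repaired to positive semidefiniteness by clipping negative eigenvalues at
zero; the repair flag and the pre-repair minimum eigenvalue are kept on the
matrix.  Repair is on by default because the Gaussian likelihood requires a
valid covariance; correlation kernels are Gram matrices of standardized
rows and need no repair in practice.  Degenerate inputs: constant profiles
get correlation 0 against everything (diagonal 1, warning); all-zero
profiles get cosine/Jaccard 0 off-diagonal (diagonal 1, warning);
single-probe pathways are allowed with a warning.

## Fitting

Maximum likelihood (the default; REML is available and valid for the LRT
here because null and alternative share X).  β is profiled out by GLS at
each variance point; the optimizer is L-BFGS-B on (σ²_A, σ²_P, σ²_e) with
analytic gradients, bounds at zero (a tiny positive floor on σ²_e keeps V
positive definite), and three starts — equal split, residual-heavy, and
last-kernel-heavy — because three-kernel problems are mildly multimodal.
The alternative model is additionally warm-started at the null solution
with σ²_P = 0, which guarantees the maximized alternative likelihood never
falls below the null's, so the LRT statistic is non-negative by
construction (it is clipped at 0 against rounding).  Single-kernel models
(the polygenic null) use an eigendecomposition fast path: one rotation of
y and X makes every likelihood evaluation O(n); multi-kernel models use a
dense Cholesky per evaluation.  Both routes are cross-checked against a
brute-force dense Gaussian formula (explicit inverse and determinant) to
10⁻⁸.  Convergence failures are flagged on the returned fit, not raised.

## Preprocessing

Fixed order: (1) shift the global minimum to exactly 1.0 and log2;
(2) quantile normalization (each column mapped onto the mean of the sorted
columns; ties get the mean of the reference values they span);
(3) per-probe OLS residualization on intercept, sex, age, age², sex×age
(rank-deficient designs fall back to the pseudoinverse with a warning);
(4) one representative probe per gene — a lone probe is kept, of two probes
the higher-variance one wins, of three or more the probe with the highest
mean pairwise Pearson correlation to the gene's other probes wins, with
ties broken by lexicographic probe id and zero-variance probes excluded
from the correlation; (5) per-probe scaling to [0, 1], with constant probes
mapped to all zeros (they then contribute nothing to any distance) and an
optional per-probe weight vector applied after scaling (default 1).
Missing values are rejected with a count of offending cells.

## Kinship

The expected-relatedness matrix is computed by the standard recursion
φ(i,i) = ½(1+φ(f,m)), φ(i,j) = ½(φ(f,j)+φ(m,j)) over a topological order,
with founders non-inbred and mutually unrelated; the stored matrix is 2φ.
Individuals with exactly one known parent get a synthetic unknown founder so
the recursion stays total.  Monozygotic twin pairs (which make 2φ
degenerate) are resolved either by dropping the second-listed twin — any
children are re-pointed to the kept, genetically identical twin — or by a
documented "merge" that sets the pair's mutual 2φ to the self value; merge
can leave the matrix indefinite when a twin has children (the single-entry
edit contradicts the child's one-sided kinship), in which case a warning is
raised.  Correctness is checked against 10,000-replicate gene-dropping
Monte Carlo and textbook values (parent–offspring 0.5, full sibs 0.5,
half sibs 0.25, first cousins 0.125, inbred self 1.25).

## Synthetic studies

The generator produces the study conditions the method is calibrated on.

- **Pedigrees.**  Within each family, founders are paired into couples;
  each mating produces `sibs_per_mating` offspring; offspring in non-final
  generations mate with a new married-in founder of opposite sex.  Defaults:
  20 families × 2 founders × 3 generations × 3 sibs per mating = 340
  individuals, giving the standard 2φ values {1, 0.5, 0.25, 0.125}.
- **Expression.**  Each probe is √h²_p·g + √(1−h²_p)·ε with g drawn
  multivariate normal with covariance Φ₂ (exact, per family block — not
  gene-dropping — to match the variance-component model being tested) and
  iid noise, so probe variance ≈ 1 and relative-pair covariance = h²_p·2φ.
  Default probe heritability 0.3, a typical bulk-expression value.
  Optionally some genes emit a second probe (shared genetic component,
  fresh noise) to exercise representative-probe selection.
- **Phenotypes.**  y = Σβⱼgⱼ + polygenic + environment.  Effects act on the
  causal probes' *genetic* components, not their noisy observed values, and
  the causal score is held fixed across replicates (it is tied to the
  expression data, as genotypes are); the residual polygenic part
  (covariance ∝ Φ₂) and iid environment are redrawn per replicate and
  scaled so the total additive fraction equals `trait_heritability` and the
  total variance is 1.  The causal-score variance h²_p·Σβ² must not exceed
  the trait heritability.  With zero heritability the phenotype is pure iid
  noise — the negative-control trait.
- **Covariates.**  Age uniform on [20, 80], sex from the pedigree; used
  only as fixed effects.
- **Determinism.**  Every quantity is a pure function of (config, seed);
  sub-streams are derived from the single seed via CRC32-keyed
  SeedSequences, so results are identical across processes.

What the generator does *not* emulate: genotype-level machinery (cis-eQTL
effects, linkage disequilibrium, sequence data), probe-level technical
artefacts (batch effects, missingness), or non-Gaussian trait
distributions.  Passing tests therefore demonstrate calibration and
recovery under the model's own assumptions, not robustness to real-data
violations of them.

## Calibration and power experiments

Two canned experiments define the reported numbers.

- **Type-I error** (`scripts/acceptance.py`): 20 three-generation families
  (340 individuals), a 20-probe heritable pathway (h²_p = 0.3), 200
  replicate phenotypes of pure noise; correlation kernel; boundary-mixture
  LRT at α = 0.05.  The empirical false-positive fraction is reported and
  should sit at or below ~0.05 (see the conservatism note above); the 99%
  binomial band at the nominal level is ≈[0.015, 0.095] for 200 replicates.
- **Decile power ordering** (test suite): 120 probes all causal with
  geometrically decaying effects (ratio 0.95, total causal variance 0.28 of
  a 0.33-heritable trait), 30 replicates, 20 families.  Probes are ranked
  into deciles by how many replicates each associates with — association is
  a GLS t-test using each replicate's fitted polygenic covariance — and
  each decile pathway is tested with the correlation and extended-Jaccard
  kernels.  Rejection rates fall monotonically with decile rank, and the
  top-decile pathway is rejected more often than the average of its
  component single-probe tests for both kernels (the aggregation advantage
  that motivates the method).  Problem sizes here are the package's chosen
  desk-scale defaults; larger runs sharpen the same picture.

## Pathway scan

`run_scan` aligns expression, phenotypes, covariates and kinship by inner
join on individual id (dropped ids are logged), fits one polygenic null per
phenotype, computes each (pathway, method) kernel once and reuses it across
phenotypes, and emits one row per (pathway, phenotype, method) with the LRT,
p value, variance share and PSD-repair flag.  Pathways matching no genes
are skipped and reported.  Multiple-testing control is Bonferroni (α/m,
reported at full precision; display rounding to two significant figures).
The inflation factor λ is median(observed statistic)/median(χ²₁)
(0.4549); with `reference="mixture"` the median of the *nonzero* statistics
is used instead, since the boundary null's zero mass carries no shape
information.  `size_vs_statistic` reports Spearman rank correlation between
pathway size and mean statistic (0, with a warning, when undefined), to
check that big pathways are not trivially favoured.

## Known limitations

- One pathway kernel at a time (no multi-kernel or kernel-fusion models);
  no dominance or household components; no longitudinal models.
- Genotype-based empirical kinship is not computed (a precomputed matrix
  can be supplied in place of the pedigree 2φ).
- The boundary-mixture p-values are conservative at desk-scale n; users
  wanting exact finite-sample calibration should permute or parametric-
  bootstrap the null.
- Dense linear algebra throughout: comfortable to a few thousand
  individuals, not beyond.
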