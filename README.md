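# pathvc — variance-component pathway analysis of gene expression in families

`pathvc` tests whether the expression of a *pathway* — a whole gene set, taken
jointly — explains phenotypic variation in family data, without first
requiring any single gene to be significant.  It is aimed at analysts working
with pedigree-based expression studies (extended families, heritable
transcript abundance, quantitative traits) who want a pathway-level
alternative to probe-by-probe association or overrepresentation tests.

## The model

For each pathway, the individuals' unit-scaled expression profiles over the
pathway's probes are turned into an N×N similarity kernel **S** (a correlation
matrix of profiles, an extended-Jaccard matrix, or one of 13
distance-derived kernels via s = 1/(1+d); 16 metrics in all).  The kernel is
added as a variance component to the polygenic mixed model:

    y = Xβ + g + p + e,
    g ~ N(0, σ²_A · Φ₂),   p ~ N(0, σ²_P · S),   e ~ N(0, σ²_e · I)

where Φ₂ is the expected-relatedness (2φ) matrix computed from the pedigree
and X holds intercept, sex and age.  The null model (σ²_P = 0) is the
standard polygenic model; the pathway's contribution is tested with a
likelihood-ratio test whose statistic is referred to the boundary mixture
½χ²₀ + ½χ²₁, and quantified as the proportion of variance
σ²_P / (σ²_A + σ²_P + σ²_e).

Because the kernels depend only on the expression data, they are computed
once and reused across any number of phenotypes.

## Worked example

The package ships a synthetic family-study generator, so the full workflow
runs without any external data:

```python
import numpy as np
import pathvc as pv

# 20 extended families with heritable expression for one 15-probe pathway
cfg = pv.SimConfig(n_families=20, n_probes=15, probe_heritability=0.4,
                   trait_heritability=0.0, n_replicates=1, seed=7)
study = pv.simulate_study(cfg)

expr = pv.scale_unit_interval(study.expression)
profiles = pv.ProfileSet(expr.values.T, expr.individual_ids, expr.probe_ids)
kernel = pv.compute_similarity(profiles, "correlation")

# a phenotype whose true variance shares are 30% pathway, 20% kinship, 50% noise
n = len(study.pedigree)
V = 0.3 * kernel.S + 0.2 * study.kinship.Phi2 + 0.5 * np.eye(n)
y = np.linalg.cholesky(V) @ np.random.default_rng(7).standard_normal(n)

X = np.column_stack([np.ones(n), study.covariates.sex, study.covariates.age])
null_fit, alt_fit = pv.fit_null_and_alternative(y, X, study.kinship.Phi2, kernel.S)
test = pv.lrt(null_fit, alt_fit)
shares = pv.variance_explained(alt_fit)

print(f"pathway share  = {shares['pathway']:.3f}   (simulated: 0.30)")
print(f"kinship share  = {shares['kinship']:.3f}   (simulated: 0.20)")
print(f"LRT statistic  = {test.statistic:.2f}, p = {test.p_value:.2e}")
```

Output:

```
pathway share  = 0.235   (simulated: 0.30)
kinship share  = 0.204   (simulated: 0.20)
LRT statistic  = 49.41, p = 1.04e-12
```

The fit attributes roughly the simulated shares of variance to the pathway
kernel and to kinship (single-replicate estimates scatter around the truth),
and the boundary LRT firmly rejects the kinship-only model — the pathway
explains variation beyond what relatedness alone accounts for.

The same workflow is available from the shell: `pathvc simulate`,
`pathvc kinship`, `pathvc similarity` and `pathvc scan` (see `--help`);
`pathvc scan` runs pathways × phenotypes × methods from TSV/ped/GMT inputs
and writes a results table plus an inflation report.

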