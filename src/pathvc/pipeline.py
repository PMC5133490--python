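"""Orchestration of the pathway scan: pathways x phenotypes x kernels.

A scan fits one polygenic null model per phenotype, computes each pathway's
similarity matrix once per metric, fits the pathway-augmented alternative for
every (pathway, phenotype, metric) triple, and collects boundary-LRT p values,
variance proportions and PSD-repair provenance.  Multiple-testing correction
is Bonferroni; the genomic inflation factor lambda summarizes the LRT
statistic distribution against its theoretical null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, spearmanr

from . import io as pio
from .kinship import KinshipMatrix
from .preprocess import CovariateTable, ExpressionMatrix
from .similarity import ProfileSet, canonical_method, compute_similarity
from .varcomp import MixedModelSpec, fit_ml, lrt, variance_explained

logger = logging.getLogger(__name__)

__all__ = [
    "PathwaySet",
    "ScanResult",
    "InflationReport",
    "load_gmt",
    "match_pathway_probes",
    "run_scan",
    "probe_association_counts",
    "bonferroni_threshold",
    "inflation_lambda",
    "size_vs_statistic",
]

CHI2_1_MEDIAN = float(chi2.ppf(0.5, df=1))  # 0.4549 to 4 d.p.


@dataclass
class PathwaySet:
    """Named gene sets: {name: (description, gene ids)}."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_lists(
        cls, gene_lists: list[list[str]], prefix: str = "pathway"
    ) -> "PathwaySet":
        return cls(
            {
                f"{prefix}_{k + 1:02d}": (f"{prefix} {k + 1}", list(genes))
                for k, genes in enumerate(gene_lists)
            }
        )


@dataclass
class ScanResult:
    """Per-(pathway, phenotype, method) rows plus skip bookkeeping."""

    table: pd.DataFrame
    skipped_pathways: dict[str, str] = field(default_factory=dict)
    n_null_fits: int = 0
    n_similarity_matrices: int = 0
    dropped_individuals: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class InflationReport:
    """Genomic inflation factor for a batch of LRT statistics."""

    lam: float
    n_tests: int
    reference: str


def load_gmt(path) -> PathwaySet:
    """Read a GMT file into a :class:`PathwaySet`."""
    return PathwaySet(pio.read_gmt(path))


def match_pathway_probes(
    pathways: PathwaySet, expr: ExpressionMatrix
) -> tuple[dict[str, list[str]], dict[str, dict[str, int]]]:
    """Map each pathway to the expression probes whose gene it contains.

    Expression must already be one probe per gene.  Returns (probe lists by
    pathway, match counts by pathway); pathways matching zero genes are
    omitted from the probe lists and flagged in the counts.
    """
    gene_to_probe: dict[str, str] = {}
    for p in expr.probe_ids:
        g = expr.probe_to_gene.get(p)
        if g is None:
            raise ValueError(f"probe {p} lacks a gene annotation")
        if g in gene_to_probe:
            raise ValueError(
                f"gene {g} has multiple probes; run select_representative_probes first"
            )
        gene_to_probe[g] = p
    probes_by_pathway: dict[str, list[str]] = {}
    counts: dict[str, dict[str, int]] = {}
    for name in pathways.names:
        genes = pathways.genes(name)
        matched = [gene_to_probe[g] for g in genes if g in gene_to_probe]
        counts[name] = {
            "n_genes_in_set": len(genes),
            "n_genes_matched": len(matched),
        }
        if not matched:
            warnings.warn(f"pathway {name!r} matches no expression genes; skipped")
            continue
        probes_by_pathway[name] = matched
    return probes_by_pathway, counts


def _align(
    expr: ExpressionMatrix,
    phenotypes: pd.DataFrame,
    covariates: CovariateTable,
    kinship: KinshipMatrix,
):
    """Inner-join all inputs on individual id, preserving expression order."""
    keep = [
        i
        for i in expr.individual_ids
        if i in set(phenotypes.index)
        and i in set(covariates.individual_ids)
        and i in set(kinship.individual_ids)
    ]
    if not keep:
        raise ValueError("no individuals shared across expression, phenotypes, covariates and kinship")
    dropped = {
        "expression": [i for i in expr.individual_ids if i not in keep],
        "phenotypes": [str(i) for i in phenotypes.index if i not in keep],
        "covariates": [i for i in covariates.individual_ids if i not in keep],
        "kinship": [i for i in kinship.individual_ids if i not in keep],
    }
    for src, ids in dropped.items():
        if ids:
            logger.info("alignment dropped %d individual(s) from %s", len(ids), src)
    return (
        expr.subset_individuals(keep),
        phenotypes.loc[keep],
        covariates.reorder(keep),
        kinship.reorder(keep),
        dropped,
    )


def run_scan(
    expr: ExpressionMatrix,
    pathways: PathwaySet,
    phenotypes: pd.DataFrame,
    covariates: CovariateTable,
    kinship: KinshipMatrix,
    methods: list[str] = ("correlation",),
    alpha: float = 0.05,
    null_distribution: str = "mixture",
    reml: bool = False,
) -> ScanResult:
    """Full scan over pathways x phenotypes x similarity methods.

    ``expr`` must be fully preprocessed (one probe per gene, values in
    [0, 1]).  ``phenotypes`` is an individuals x phenotypes frame.  One null
    fit per phenotype and one similarity matrix per (pathway, method) are
    computed and reused.
    """
    from .varcomp import fit_null_and_alternative  # local to avoid cycle noise

    methods = [canonical_method(m) for m in methods]
    expr, phenotypes, covariates, kinship, dropped = _align(
        expr, phenotypes, covariates, kinship
    )
    probes_by_pathway, counts = match_pathway_probes(pathways, expr)
    skipped = {
        name: "no genes matched"
        for name in pathways.names
        if name not in probes_by_pathway
    }

    X = np.column_stack(
        [np.ones(expr.n_individuals), covariates.sex, covariates.age]
    )
    pos = {p: i for i, p in enumerate(expr.probe_ids)}

    # similarity matrices once per (pathway, method)
    kernels: dict[tuple[str, str], object] = {}
    for name, probes in probes_by_pathway.items():
        rows = [pos[p] for p in probes]
        prof = ProfileSet(
            expr.values[rows].T, expr.individual_ids, list(probes)
        )
        for m in methods:
            kernels[(name, m)] = compute_similarity(prof, m)
    logger.info("computed %d similarity matrices", len(kernels))

    records = []
    n_null = 0
    for pheno_name in phenotypes.columns:
        y = phenotypes[pheno_name].to_numpy(dtype=float)
        null_spec = MixedModelSpec(y, X, [kinship.Phi2], ["kinship"])
        null_fit = fit_ml(null_spec, reml=reml)
        n_null += 1
        warm = np.array([null_fit.sigma2[0], 0.0, null_fit.sigma2[1]])
        for (name, m), sim in kernels.items():
            alt_spec = MixedModelSpec(
                y, X, [kinship.Phi2, sim.S], ["kinship", "pathway"]
            )
            alt_fit = fit_ml(alt_spec, reml=reml, extra_starts=[warm])
            test = lrt(null_fit, alt_fit, null_distribution=null_distribution)
            records.append(
                {
                    "pathway": name,
                    "phenotype": pheno_name,
                    "method": m,
                    "n_genes_in_set": counts[name]["n_genes_in_set"],
                    "n_genes_matched": counts[name]["n_genes_matched"],
                    "lrt_statistic": test.statistic,
                    "p_value": test.p_value,
                    "significant": test.p_value < alpha,
                    "pathway_var": alt_fit.pathway_var,
                    "h2_null": null_fit.h2,
                    "psd_repaired": sim.psd_repaired,
                    "converged": alt_fit.converged and null_fit.converged,
                }
            )
    table = pd.DataFrame.from_records(records)
    return ScanResult(
        table=table,
        skipped_pathways=skipped,
        n_null_fits=n_null,
        n_similarity_matrices=len(kernels),
        dropped_individuals=dropped,
    )


def probe_association_counts(
    expr: ExpressionMatrix,
    phenotypes: np.ndarray,
    X: np.ndarray,
    kinship: KinshipMatrix,
    alpha: float = 0.05,
    null_fits: list | None = None,
) -> dict[str, int]:
    """Count, per probe, the phenotype replicates it associates with.

    For each replicate a polygenic null model supplies the fitted covariance
    V = sigma2_A * Phi2 + sigma2_e * I; probe and phenotype are whitened by
    V^-1/2 and the probe's fixed effect tested by the GLS partial-correlation
    t-test at level ``alpha``.  This is the measured-covariance association
    scan used to rank probes for positive-control decile pathways.

    ``phenotypes`` is replicates x individuals, aligned with the expression
    columns.  Precomputed ``null_fits`` (one per replicate) are reused when
    given.
    """
    from scipy.linalg import cholesky, solve_triangular
    from scipy.stats import t as t_dist

    from .varcomp import MixedModelSpec, fit_ml

    Y = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    n = expr.n_individuals
    if Y.shape[1] != n:
        raise ValueError("phenotype columns do not match expression individuals")
    E = expr.values
    counts = {p: 0 for p in expr.probe_ids}
    df = n - X.shape[1] - 1
    tcrit = float(t_dist.ppf(1.0 - alpha / 2.0, df))
    for r in range(Y.shape[0]):
        if null_fits is not None:
            fit = null_fits[r]
        else:
            fit = fit_ml(MixedModelSpec(Y[r], X, [kinship.Phi2], ["kinship"]))
        s2 = fit.sigma2
        V = s2[0] * kinship.Phi2 + s2[1] * np.eye(n)
        L = cholesky(V, lower=True)
        yw = solve_triangular(L, Y[r], lower=True)
        Xw = solve_triangular(L, X, lower=True)
        Ew = solve_triangular(L, E.T, lower=True)
        Q, _ = np.linalg.qr(Xw)
        yr = yw - Q @ (Q.T @ yw)
        yr /= np.linalg.norm(yr)
        Er = Ew - Q @ (Q.T @ Ew)
        Er /= np.linalg.norm(Er, axis=0, keepdims=True)
        rho = np.clip(yr @ Er, -1.0, 1.0)
        tt = rho * np.sqrt(df / np.maximum(1.0 - rho**2, 1e-300))
        for k, pid in enumerate(expr.probe_ids):
            counts[pid] += bool(abs(tt[k]) > tcrit)
    return counts


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def inflation_lambda(
    statistics, reference: str = "chi2_1"
) -> InflationReport:
    """Genomic inflation factor for LRT statistics.

    lambda = median(observed) / median(reference).  The default reference is
    plain chi2 with 1 df (median 0.4549).  With ``reference="mixture"`` the
    half-point-mass-at-zero boundary null is used: its nonzero part is chi2_1,
    so lambda compares the median of the *nonzero* observed statistics to the
    chi2_1 median (the zero mass carries no shape information).
    """
    stats = np.asarray(list(statistics), dtype=float)
    if stats.size < 10:
        raise ValueError("need at least 10 statistics for an inflation factor")
    if reference == "chi2_1":
        med = float(np.median(stats))
    elif reference == "mixture":
        nonzero = stats[stats > 0]
        med = float(np.median(nonzero)) if nonzero.size else 0.0
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if med == 0.0:
        warnings.warn("all statistics are zero; lambda reported as 0")
        return InflationReport(0.0, int(stats.size), reference)
    return InflationReport(med / CHI2_1_MEDIAN, int(stats.size), reference)


def size_vs_statistic(
    results: ScanResult | pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Pathway size vs LRT statistic with a Spearman rank correlation.

    Used to check that large pathways are not trivially more significant.
    A constant column makes the correlation undefined; it is reported as 0.
    """
    table = results.table if isinstance(results, ScanResult) else results
    if table["pathway"].nunique() < 3:
        raise ValueError("need at least 3 pathways")
    pairs = (
        table.groupby("pathway")
        .agg(size=("n_genes_matched", "first"), statistic=("lrt_statistic", "mean"))
        .reset_index()
    )
    if pairs["size"].nunique() == 1 or pairs["statistic"].nunique() == 1:
        warnings.warn("constant sizes or statistics; rank correlation undefined, reported as 0")
        return pairs, 0.0
    rho = spearmanr(pairs["size"], pairs["statistic"]).statistic
    return pairs, float(rho)
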