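"""Expression preprocessing: from raw probe abundance to unit-scaled profiles.

The fixed pipeline order is

    shift_log2 -> quantile_normalize -> adjust_covariates
        -> select_representative_probes -> scale_unit_interval

after which each gene is represented by one probe whose values lie in [0, 1],
ready for pairwise similarity computation.  Missing values are not supported:
operations raise with a count of offending cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "CovariateTable",
    "shift_log2",
    "quantile_normalize",
    "adjust_covariates",
    "select_representative_probes",
    "scale_unit_interval",
    "preprocess_pipeline",
]


@dataclass
class ExpressionMatrix:
    """Probes-by-individuals abundance matrix with probe->gene annotation.

    ``genetic_values`` is an optional companion array of the same shape used
    by the simulator to carry each probe's additive-genetic component; real
    data never has it.
    """

    values: np.ndarray  # probes x individuals
    probe_ids: list[str]
    individual_ids: list[str]
    probe_to_gene: dict[str, str] = field(default_factory=dict)
    genetic_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.individual_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.individual_ids)} individuals"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.individual_ids)

    def subset_probes(self, probe_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.probe_ids.index(p) for p in probe_ids]
        return replace(
            self,
            values=self.values[idx],
            probe_ids=list(probe_ids),
            probe_to_gene={p: self.probe_to_gene[p] for p in probe_ids if p in self.probe_to_gene},
            genetic_values=None if self.genetic_values is None else self.genetic_values[idx],
        )

    def subset_individuals(self, individual_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.individual_ids.index(i) for i in individual_ids]
        return replace(
            self,
            values=self.values[:, idx],
            individual_ids=list(individual_ids),
            genetic_values=None if self.genetic_values is None else self.genetic_values[:, idx],
        )


@dataclass
class CovariateTable:
    """Per-individual sex (1 = male, 2 = female) and age in years."""

    individual_ids: list[str]
    sex: np.ndarray
    age: np.ndarray

    def __post_init__(self) -> None:
        self.sex = np.asarray(self.sex, dtype=float).ravel()
        self.age = np.asarray(self.age, dtype=float).ravel()
        n = len(self.individual_ids)
        if len(self.sex) != n or len(self.age) != n:
            raise ValueError("sex/age length does not match individual ids")

    def design_matrix(self) -> np.ndarray:
        """Intercept, sex, age, age^2 and sex*age columns (in that order)."""
        sex = self.sex - self.sex.mean()  # centering for numerical conditioning
        age = self.age
        return np.column_stack(
            [np.ones_like(age), sex, age, age**2, sex * age]
        )

    def reorder(self, individual_ids: list[str]) -> "CovariateTable":
        idx = [self.individual_ids.index(i) for i in individual_ids]
        return CovariateTable(list(individual_ids), self.sex[idx], self.age[idx])


def _check_finite(expr: ExpressionMatrix, op: str) -> None:
    bad = ~np.isfinite(expr.values)
    if bad.any():
        raise ValueError(f"{op}: {int(bad.sum())} missing/non-finite expression cells")


def shift_log2(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Shift the whole matrix so its minimum is exactly 1.0, then log2.

    The output minimum is therefore exactly 0.
    """
    _check_finite(expr, "shift_log2")
    shifted = expr.values + (1.0 - expr.values.min())
    return replace(expr, values=np.log2(shifted))


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every individual's value distribution onto the mean distribution.

    Each column is replaced by the row-wise mean of all sorted columns, placed
    back in the column's own rank order.  Ties receive the mean of the
    reference values they span (average ranks, linear interpolation).
    """
    _check_finite(expr, "quantile_normalize")
    X = expr.values
    n = X.shape[0]
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return replace(expr, values=out)


def adjust_covariates(expr: ExpressionMatrix, cov: CovariateTable) -> ExpressionMatrix:
    """Residualize every probe on sex, age, age^2 and sex*age by OLS.

    Output rows are orthogonal to the design columns.  A rank-deficient design
    (e.g. a single-sex sample) is handled by the pseudoinverse, which drops
    the collinear directions; a warning is emitted.
    """
    _check_finite(expr, "adjust_covariates")
    if list(cov.individual_ids) != list(expr.individual_ids):
        cov = cov.reorder(expr.individual_ids)
    D = cov.design_matrix()
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        warnings.warn(
            f"covariate design is rank deficient ({rank}/{D.shape[1]}); "
            "collinear columns are effectively dropped"
        )
    # residuals = (I - D D^+) Y' computed probe-wise via least squares
    coef, *_ = np.linalg.lstsq(D, expr.values.T, rcond=None)
    resid = expr.values - (D @ coef).T
    return replace(expr, values=resid)


def _representative_for(probes: list[str], X: np.ndarray) -> str:
    """Pick one representative probe for a gene.

    Single probe: keep it.  Two probes: the one with greater variance.  Three
    or more: the one with the highest mean pairwise Pearson correlation to the
    gene's other probes.  Ties break by lexicographic probe id; zero-variance
    probes are excluded from correlation (and if all are constant the first by
    id is kept with a warning).
    """
    order = np.argsort(probes)  # lexicographic tie-break baked into ordering
    probes_sorted = [probes[i] for i in order]
    Xs = X[order]
    if len(probes_sorted) == 1:
        return probes_sorted[0]
    variances = Xs.var(axis=1)
    if len(probes_sorted) == 2:
        return probes_sorted[int(np.argmax(variances))]
    ok = variances > 0
    if not ok.any():
        warnings.warn(
            f"all probes for a gene are constant; keeping {probes_sorted[0]}"
        )
        return probes_sorted[0]
    if ok.sum() == 1:
        return probes_sorted[int(np.flatnonzero(ok)[0])]
    sub = Xs[ok]
    R = np.corrcoef(sub)
    np.fill_diagonal(R, np.nan)
    mean_r = np.nanmean(R, axis=1)
    winner = int(np.flatnonzero(ok)[int(np.argmax(mean_r))])
    return probes_sorted[winner]


def select_representative_probes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Reduce to exactly one probe per gene (values untouched, rows dropped)."""
    _check_finite(expr, "select_representative_probes")
    missing = [p for p in expr.probe_ids if p not in expr.probe_to_gene]
    if missing:
        raise ValueError(f"{len(missing)} probes lack a gene annotation")
    by_gene: dict[str, list[str]] = {}
    for p in expr.probe_ids:
        by_gene.setdefault(expr.probe_to_gene[p], []).append(p)
    pos = {p: i for i, p in enumerate(expr.probe_ids)}
    keep: list[str] = []
    for gene, probes in by_gene.items():
        rows = np.array([pos[p] for p in probes])
        keep.append(_representative_for(probes, expr.values[rows]))
    keep = [p for p in expr.probe_ids if p in set(keep)]  # original row order
    return expr.subset_probes(keep)


def scale_unit_interval(
    expr: ExpressionMatrix, weights: np.ndarray | dict[str, float] | None = None
) -> ExpressionMatrix:
    """Scale each probe row to [0, 1] via (x - min) / (max - min).

    Constant rows become all zeros (they then contribute nothing to any
    distance) with a warning.  Optional per-probe ``weights`` multiply the
    scaled rows, allowing hypothesis-specific probe weighting; default is 1.
    """
    _check_finite(expr, "scale_unit_interval")
    X = expr.values
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    flat = (span == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant probe(s) scaled to all zeros"
        )
    safe = np.where(span == 0, 1.0, span)
    out = (X - lo) / safe
    out[flat, :] = 0.0
    if weights is not None:
        if isinstance(weights, dict):
            w = np.array([weights.get(p, 1.0) for p in expr.probe_ids])
        else:
            w = np.asarray(weights, dtype=float).ravel()
            if w.shape[0] != expr.n_probes:
                raise ValueError("weights length does not match probe count")
        out = out * w[:, None]
    return replace(expr, values=out)


def preprocess_pipeline(
    expr: ExpressionMatrix,
    cov: CovariateTable,
    weights: np.ndarray | dict[str, float] | None = None,
) -> ExpressionMatrix:
    """Run the full fixed-order preprocessing pipeline."""
    expr = shift_log2(expr)
    expr = quantile_normalize(expr)
    expr = adjust_covariates(expr, cov)
    expr = select_representative_probes(expr)
    return scale_unit_interval(expr, weights=weights)
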