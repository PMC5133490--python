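"""Synthetic family studies with known heritability and known causal pathways.

The generator emulates the study design the method was developed on: a set of
extended families, heritable probe-level expression, replicate phenotypes
whose additive-genetic fraction is controlled exactly, and a zero-heritability
null trait.  Every quantity downstream of the seed is a pure function of
(config, seed), so calibration and power experiments are reproducible.

Model, per family block with twice-kinship matrix Phi2:

* probe expression:  x = sqrt(h2_p) * g + sqrt(1 - h2_p) * e, with
  g ~ N(0, Phi2) and e iid N(0, I), so each probe has variance ~1 and
  cov(x_i, x_j) = h2_p * Phi2[i, j];
* phenotype:  y = score + polygenic + environment, where
  score = sum_j beta_j g_j over the causal probes' *genetic* components
  (fixed across replicates, as genotypes are), the polygenic part
  ~ N(0, (h2_t - var(score)) * Phi2) and the environmental part fill the
  total variance to 1, both redrawn per replicate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .kinship import MISSING, KinshipMatrix, Pedigree, PedigreeRecord, compute_kinship
from .preprocess import CovariateTable, ExpressionMatrix

__all__ = [
    "SimConfig",
    "SyntheticStudy",
    "simulate_pedigree",
    "simulate_expression",
    "simulate_covariates",
    "simulate_phenotype",
    "simulate_study",
    "build_decile_pathways",
]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study.

    Defaults mirror the design the method targets: 20 extended families of
    three generations (~340 individuals), trait heritability 0.33, and 200
    phenotype replicates.  ``trait_heritability = 0`` with no causal probes
    gives the null trait.  ``n_duplicate_probe_genes`` makes that many genes
    carry two probes, to exercise representative-probe selection.
    """

    n_families: int = 20
    founders_per_family: int = 2
    n_generations: int = 3
    sibs_per_mating: int = 3
    n_probes: int = 100
    probe_heritability: float = 0.3
    trait_heritability: float = 0.33
    n_causal_probes: int = 0
    effect_sizes: tuple[float, ...] = ()
    n_replicates: int = 200
    seed: int = 0
    n_duplicate_probe_genes: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_families",
            "founders_per_family",
            "n_generations",
            "sibs_per_mating",
            "n_probes",
            "n_replicates",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("probe_heritability", "trait_heritability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_causal_probes < 0 or self.n_causal_probes > self.n_probes:
            raise ValueError("n_causal_probes must be in [0, n_probes]")
        if len(self.effect_sizes) != self.n_causal_probes:
            raise ValueError("effect_sizes length must equal n_causal_probes")
        if self.n_duplicate_probe_genes > self.n_probes:
            raise ValueError("n_duplicate_probe_genes exceeds n_probes")


@dataclass
class SyntheticStudy:
    """A complete simulated data set plus its ground truth."""

    pedigree: Pedigree
    kinship: KinshipMatrix
    expression: ExpressionMatrix
    phenotypes: np.ndarray  # replicates x individuals
    causal_probe_ids: list[str]
    covariates: CovariateTable

    def __post_init__(self) -> None:
        n = len(self.pedigree)
        if self.phenotypes.shape[1] != n:
            raise ValueError("phenotype columns do not align with the pedigree")
        probes = set(self.expression.probe_ids)
        if not set(self.causal_probe_ids) <= probes:
            raise ValueError("causal probe ids not all present in the expression matrix")


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Deterministic sub-stream derived from the single config seed."""
    key = zlib.crc32(stream.encode("utf-8"))  # stable across processes
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    )


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Grow extended families deterministically from the config.

    Generation 1 founders are paired into couples; each mating produces
    ``sibs_per_mating`` offspring; offspring in non-final generations mate
    with a new married-in (founder) spouse of opposite sex.  The scheme yields
    the standard 2*phi values 1, 0.5, 0.25, 0.125 within families.
    """
    rng = _rng(config, "pedigree")
    records: list[PedigreeRecord] = []
    for fam in range(1, config.n_families + 1):
        fid = f"F{fam:03d}"
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{fid}_I{counter:03d}"

        founders = []
        for k in range(config.founders_per_family):
            founders.append(PedigreeRecord(fid, new_id(), sex=1 + (k % 2)))
        records.extend(founders)
        matings = [
            (founders[i].individual_id, founders[i + 1].individual_id)
            for i in range(0, len(founders) - 1, 2)
        ]
        for gen in range(2, config.n_generations + 1):
            next_matings = []
            for father, mother in matings:
                for _ in range(config.sibs_per_mating):
                    sex = int(rng.integers(1, 3))
                    child = PedigreeRecord(fid, new_id(), father, mother, sex)
                    records.append(child)
                    if gen < config.n_generations:
                        spouse = PedigreeRecord(fid, new_id(), sex=3 - sex)
                        records.append(spouse)
                        pair = (
                            (child.individual_id, spouse.individual_id)
                            if sex == 1
                            else (spouse.individual_id, child.individual_id)
                        )
                        next_matings.append(pair)
            matings = next_matings
    return Pedigree(records)


def _kinship_cholesky(kin: KinshipMatrix) -> np.ndarray:
    Phi2 = kin.Phi2
    return np.linalg.cholesky(Phi2 + 1e-10 * np.eye(Phi2.shape[0]))


def simulate_expression(
    ped: Pedigree, config: SimConfig, kinship: KinshipMatrix | None = None
) -> ExpressionMatrix:
    """Heritable probe expression with familial covariance h2_p * Phi2.

    The returned matrix carries each probe's additive-genetic component in
    ``genetic_values`` (used by :func:`simulate_phenotype`).  Probe ids are
    ``P0001...``; each maps to its own gene ``G0001...`` except that the first
    ``n_duplicate_probe_genes`` genes also receive a second probe (suffix
    ``_b``) sharing the gene's genetic component with fresh noise.
    """
    kin = compute_kinship(ped) if kinship is None else kinship
    if kin.individual_ids != ped.individual_ids:
        raise ValueError("kinship matrix does not match the pedigree order")
    rng = _rng(config, "expression")
    n = len(ped)
    p = config.n_probes
    h2 = config.probe_heritability
    L = _kinship_cholesky(kin)
    G = (L @ rng.standard_normal((n, p))).T  # p x n genetic values, var ~ 1
    E = rng.standard_normal((p, n))
    values = np.sqrt(h2) * G + np.sqrt(1.0 - h2) * E
    genetic = np.sqrt(h2) * G
    probe_ids = [f"P{k + 1:04d}" for k in range(p)]
    probe_to_gene = {pid: f"G{k + 1:04d}" for k, pid in enumerate(probe_ids)}
    if config.n_duplicate_probe_genes:
        k = config.n_duplicate_probe_genes
        E2 = rng.standard_normal((k, n))
        dup_values = np.sqrt(h2) * G[:k] + np.sqrt(1.0 - h2) * E2
        dup_ids = [f"P{j + 1:04d}_b" for j in range(k)]
        values = np.vstack([values, dup_values])
        genetic = np.vstack([genetic, np.sqrt(h2) * G[:k]])
        probe_ids = probe_ids + dup_ids
        for j, pid in enumerate(dup_ids):
            probe_to_gene[pid] = f"G{j + 1:04d}"
    return ExpressionMatrix(
        values=values,
        probe_ids=probe_ids,
        individual_ids=ped.individual_ids,
        probe_to_gene=probe_to_gene,
        genetic_values=genetic,
    )


def simulate_covariates(ped: Pedigree, config: SimConfig) -> CovariateTable:
    """Ages uniform on [20, 80]; sex taken from the pedigree records."""
    rng = _rng(config, "covariates")
    age = rng.uniform(20.0, 80.0, size=len(ped))
    sex = ped.sexes.astype(float)
    sex[sex == 0] = rng.integers(1, 3, size=int((sex == 0).sum()))
    return CovariateTable(ped.individual_ids, sex, age)


def simulate_phenotype(
    ped: Pedigree,
    expr: ExpressionMatrix,
    config: SimConfig,
    kinship: KinshipMatrix | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Replicate phenotypes with additive fraction = trait_heritability.

    Returns (replicates x individuals matrix, causal probe ids).  The causal
    score uses the probes' genetic components and is held fixed across
    replicates; polygenic and environmental parts are redrawn per replicate.
    With zero heritability the phenotype is pure iid noise (the null-trait
    analogue).
    """
    kin = compute_kinship(ped) if kinship is None else kinship
    rng = _rng(config, "phenotype")
    n = len(ped)
    h2_t = config.trait_heritability
    effects = np.asarray(config.effect_sizes, dtype=float)

    if config.n_causal_probes:
        if expr.genetic_values is None:
            raise ValueError(
                "expression matrix lacks genetic components; it must come "
                "from simulate_expression"
            )
        primary = [p for p in expr.probe_ids if not p.endswith("_b")]
        causal_ids = [
            str(p) for p in rng.choice(primary, size=config.n_causal_probes, replace=False)
        ]
        rows = [expr.probe_ids.index(p) for p in causal_ids]
        score = effects @ expr.genetic_values[rows]
        var_score = config.probe_heritability * float((effects**2).sum())
    else:
        causal_ids = []
        score = np.zeros(n)
        var_score = 0.0

    if var_score > h2_t + 1e-12:
        raise ValueError(
            f"causal score variance {var_score:.3f} exceeds trait "
            f"heritability {h2_t}; reduce effect sizes"
        )
    sd_poly = np.sqrt(max(h2_t - var_score, 0.0))
    sd_env = np.sqrt(1.0 - h2_t)
    L = _kinship_cholesky(kin)
    Y = np.empty((config.n_replicates, n))
    for r in range(config.n_replicates):
        poly = L @ rng.standard_normal(n)
        env = rng.standard_normal(n)
        Y[r] = score + sd_poly * poly + sd_env * env
    return Y, causal_ids


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Generate a full synthetic study from one config."""
    ped = simulate_pedigree(config)
    kin = compute_kinship(ped)
    expr = simulate_expression(ped, config, kinship=kin)
    phen, causal = simulate_phenotype(ped, expr, config, kinship=kin)
    cov = simulate_covariates(ped, config)
    return SyntheticStudy(ped, kin, expr, phen, causal, cov)


def build_decile_pathways(
    assoc_counts: dict[str, int], n_deciles: int = 10
) -> list[list[str]]:
    """Positive-control gene sets from per-probe association counts.

    Probes are ranked by how many replicate phenotypes they associate with
    (descending; ties broken by ascending probe id) and split into
    ``n_deciles`` near-equal bins.  Bin 1 holds the most-associated probes.
    """
    if any(c < 0 for c in assoc_counts.values()):
        raise ValueError("association counts must be >= 0")
    if len(assoc_counts) < n_deciles:
        raise ValueError(
            f"{len(assoc_counts)} probes cannot fill {n_deciles} deciles"
        )
    ordered = sorted(assoc_counts, key=lambda p: (-assoc_counts[p], p))
    return [list(chunk) for chunk in np.array_split(ordered, n_deciles)]
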