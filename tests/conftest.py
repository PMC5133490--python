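import numpy as np
import pytest

import pathvc as pv


def design_matrix(study: pv.SyntheticStudy) -> np.ndarray:
    """Intercept + sex + age fixed-effect design for a synthetic study."""
    n = len(study.pedigree)
    return np.column_stack([np.ones(n), study.covariates.sex, study.covariates.age])


def pathway_kernel(study: pv.SyntheticStudy, method: str = "correlation",
                   probe_ids: list[str] | None = None) -> pv.SimilarityMatrix:
    """Unit-scale the simulated expression and build one pathway kernel."""
    expr = study.expression if probe_ids is None else study.expression.subset_probes(probe_ids)
    expr = pv.scale_unit_interval(expr)
    prof = pv.ProfileSet(expr.values.T, expr.individual_ids, expr.probe_ids)
    return pv.compute_similarity(prof, method)


@pytest.fixture
def trio_pedigree() -> pv.Pedigree:
    return pv.Pedigree(
        [
            pv.PedigreeRecord("f1", "dad", sex=1),
            pv.PedigreeRecord("f1", "mom", sex=2),
            pv.PedigreeRecord("f1", "kid", "dad", "mom", 1),
        ]
    )


@pytest.fixture
def three_generation_pedigree() -> pv.Pedigree:
    """Two founder couples, full sibs, an avuncular link and first cousins."""
    P = pv.PedigreeRecord
    return pv.Pedigree(
        [
            P("f1", "gf1", sex=1),
            P("f1", "gm1", sex=2),
            P("f1", "gf2", sex=1),
            P("f1", "gm2", sex=2),
            P("f1", "dad", "gf1", "gm1", 1),
            P("f1", "unc", "gf1", "gm1", 1),
            P("f1", "mom", "gf2", "gm2", 2),
            P("f1", "aunt", sex=2),  # married-in founder
            P("f1", "kid1", "dad", "mom", 1),
            P("f1", "kid2", "dad", "mom", 2),
            P("f1", "cuz", "unc", "aunt", 1),
        ]
    )


@pytest.fixture(scope="session")
def null_calibration() -> dict:
    """Null-trait calibration run shared by the calibration tests.

    20 three-generation families (340 individuals), a 20-probe heritable
    pathway, 200 replicate phenotypes of pure independent noise.  For each
    replicate the kinship-only null and the kinship + correlation-kernel
    alternative are fitted by ML and the boundary-mixture LRT recorded.
    """
    cfg = pv.SimConfig(
        n_families=20,
        founders_per_family=2,
        n_generations=3,
        sibs_per_mating=3,
        n_probes=20,
        probe_heritability=0.3,
        trait_heritability=0.0,
        n_causal_probes=0,
        effect_sizes=(),
        n_replicates=200,
        seed=20230923,
    )
    study = pv.simulate_study(cfg)
    sim = pathway_kernel(study, "correlation")
    X = design_matrix(study)
    pvals, stats = [], []
    for r in range(cfg.n_replicates):
        null_fit, alt_fit = pv.fit_null_and_alternative(
            study.phenotypes[r], X, study.kinship.Phi2, sim.S
        )
        res = pv.lrt(null_fit, alt_fit)
        pvals.append(res.p_value)
        stats.append(res.statistic)
    return {
        "p_values": np.array(pvals),
        "statistics": np.array(stats),
        "n_replicates": cfg.n_replicates,
    }
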