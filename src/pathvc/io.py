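"""Plain-text readers and writers for the formats the tool exchanges.

Expression: TSV, probe rows x individual columns, first column ``probe_id``.
Annotation: TSV with columns ``probe_id``, ``gene_id``.
Covariates: TSV with columns ``individual_id``, ``sex``, ``age``.
Phenotypes: TSV, individual rows, first column ``individual_id``, one column
per phenotype (or replicate).
Pedigree: whitespace-delimited ped file ``FID IID FATHER MOTHER SEX`` with
``0`` for a missing parent; SEX 1 = male, 2 = female.
Gene sets: GMT (name, description, then gene ids, tab-separated).
Kinship / similarity matrices: TSV with individual ids as header and first
column; kinship also as a 3-column sparse list (id1, id2, value).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import KinshipMatrix, Pedigree, PedigreeRecord
from .preprocess import CovariateTable, ExpressionMatrix
from .similarity import SimilarityMatrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_covariates_tsv",
    "write_covariates_tsv",
    "read_phenotypes_tsv",
    "write_phenotypes_tsv",
    "read_ped",
    "write_ped",
    "read_gmt",
    "write_gmt",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_kinship_sparse",
]


def read_expression_tsv(
    path: str | Path, annotation: str | Path | None = None
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    probe_to_gene = read_annotation_tsv(annotation) if annotation else {}
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        probe_ids=[str(i) for i in df.index],
        individual_ids=[str(c) for c in df.columns],
        probe_to_gene=probe_to_gene,
    )


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().rename_axis("probe_id").to_csv(path, sep="\t")


def read_annotation_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise ValueError("annotation TSV needs columns probe_id and gene_id")
    return dict(zip(df["probe_id"], df["gene_id"]))


def write_annotation_tsv(probe_to_gene: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"probe_id": list(probe_to_gene), "gene_id": list(probe_to_gene.values())}
    ).to_csv(path, sep="\t", index=False)


def read_covariates_tsv(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t")
    need = {"individual_id", "sex", "age"}
    if not need <= set(df.columns):
        raise ValueError(f"covariate TSV needs columns {sorted(need)}")
    return CovariateTable(
        [str(i) for i in df["individual_id"]],
        df["sex"].to_numpy(dtype=float),
        df["age"].to_numpy(dtype=float),
    )


def write_covariates_tsv(cov: CovariateTable, path: str | Path) -> None:
    pd.DataFrame(
        {"individual_id": cov.individual_ids, "sex": cov.sex.astype(int), "age": cov.age}
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    """Individuals x phenotypes frame indexed by individual id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_phenotypes_tsv(
    phenotypes: np.ndarray,
    individual_ids: list[str],
    path: str | Path,
    prefix: str = "rep",
) -> None:
    """Write a replicates x individuals matrix as individual-rowed TSV."""
    df = pd.DataFrame(
        np.asarray(phenotypes).T,
        index=pd.Index(individual_ids, name="individual_id"),
        columns=[f"{prefix}{r + 1:03d}" for r in range(np.asarray(phenotypes).shape[0])],
    )
    df.to_csv(path, sep="\t")


def read_ped(path: str | Path) -> Pedigree:
    records = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        fid, iid, father, mother, sex = parts[:5]
        records.append(PedigreeRecord(fid, iid, father, mother, int(sex)))
    return Pedigree(records)


def write_ped(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in ped.records:
            fh.write(
                f"{r.family_id}\t{r.individual_id}\t{r.father_id}\t"
                f"{r.mother_id}\t{r.sex}\n"
            )


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file into {name: (description, genes)}.

    Duplicate genes within a set are dropped (first occurrence kept) with a
    warning; a line with fewer than 3 fields is an error naming the line.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    lines = Path(path).read_text().splitlines()
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}:{ln}: GMT line needs >= 3 tab-separated fields"
            )
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        uniq = list(dict.fromkeys(genes))
        if len(uniq) < len(genes):
            warnings.warn(f"gene set {name!r}: {len(genes) - len(uniq)} duplicate gene(s) dropped")
        if name in sets:
            raise ValueError(f"{path}:{ln}: duplicate gene-set name {name!r}")
        sets[name] = (desc, uniq)
    if not sets:
        warnings.warn(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError("matrix TSV row and column ids differ")
    return df.to_numpy(dtype=float), ids


def write_matrix_tsv(
    M: np.ndarray | KinshipMatrix | SimilarityMatrix,
    path: str | Path,
    individual_ids: list[str] | None = None,
) -> None:
    if isinstance(M, KinshipMatrix):
        arr, ids = M.Phi2, M.individual_ids
    elif isinstance(M, SimilarityMatrix):
        arr, ids = M.S, M.individual_ids
    else:
        arr, ids = np.asarray(M), individual_ids
        if ids is None:
            raise ValueError("individual_ids required for a bare array")
    pd.DataFrame(arr, index=ids, columns=ids).to_csv(path, sep="\t")


def write_kinship_sparse(kin: KinshipMatrix, path: str | Path, tol: float = 0.0) -> None:
    """Upper-triangular nonzero 2*phi entries as (id1, id2, value) rows."""
    ids = kin.individual_ids
    with open(path, "w") as fh:
        fh.write("id1\tid2\tphi2\n")
        n = len(ids)
        for i in range(n):
            for j in range(i, n):
                v = kin.Phi2[i, j]
                if abs(v) > tol:
                    fh.write(f"{ids[i]}\t{ids[j]}\t{v:.10g}\n")
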