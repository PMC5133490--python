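"""Pedigree handling and expected-relatedness (2*phi) matrices.

The additive-genetic covariance of a quantitative trait in a pedigree is
``sigma2_A * Phi2`` where ``Phi2`` holds twice the kinship coefficient
phi(i, j) — the probability that an allele drawn at random from individual i
is identical by descent to one drawn from j.  ``Phi2`` is the covariance
structure of the polygenic null model; pathway kernels are tested against it.

Founders are assumed non-inbred and mutually unrelated (the usual convention
in pedigree analysis), so a non-inbred individual has ``Phi2[i, i] == 1`` and
the matrix is block-diagonal across families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PedigreeRecord",
    "Pedigree",
    "KinshipMatrix",
    "PedigreeValidationReport",
    "validate_pedigree",
    "compute_kinship",
    "handle_mz_twins",
]

MISSING = "0"


@dataclass(frozen=True)
class PedigreeRecord:
    """One line of a PLINK-style ped file (FID IID FATHER MOTHER SEX)."""

    family_id: str
    individual_id: str
    father_id: str = MISSING
    mother_id: str = MISSING
    sex: int = 0  # 1 = male, 2 = female, 0 = unknown

    @property
    def is_founder(self) -> bool:
        return self.father_id == MISSING and self.mother_id == MISSING


@dataclass
class Pedigree:
    """An ordered collection of pedigree records.

    Record order is preserved and defines the row/column order of any kinship
    matrix computed from the pedigree.
    """

    records: list[PedigreeRecord]

    @property
    def individual_ids(self) -> list[str]:
        return [r.individual_id for r in self.records]

    @property
    def family_ids(self) -> list[str]:
        return [r.family_id for r in self.records]

    @property
    def sexes(self) -> np.ndarray:
        return np.array([r.sex for r in self.records], dtype=int)

    def __len__(self) -> int:
        return len(self.records)

    def record_for(self, individual_id: str) -> PedigreeRecord:
        for r in self.records:
            if r.individual_id == individual_id:
                return r
        raise KeyError(individual_id)


@dataclass
class KinshipMatrix:
    """Twice-kinship (2*phi) matrix with its individual order."""

    Phi2: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.Phi2 = np.asarray(self.Phi2, dtype=float)
        n = len(self.individual_ids)
        if self.Phi2.shape != (n, n):
            raise ValueError(
                f"kinship matrix shape {self.Phi2.shape} does not match "
                f"{n} individual ids"
            )

    def index_of(self, individual_id: str) -> int:
        return self.individual_ids.index(individual_id)

    def reorder(self, individual_ids: list[str]) -> "KinshipMatrix":
        idx = [self.individual_ids.index(i) for i in individual_ids]
        return KinshipMatrix(self.Phi2[np.ix_(idx, idx)], list(individual_ids))


@dataclass
class PedigreeValidationReport:
    cycles: list[list[str]] = field(default_factory=list)
    sex_inconsistent_parents: list[str] = field(default_factory=list)
    dangling_parent_ids: list[str] = field(default_factory=list)
    duplicate_individual_ids: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.cycles
            or self.sex_inconsistent_parents
            or self.dangling_parent_ids
            or self.duplicate_individual_ids
        )


def validate_pedigree(ped: Pedigree) -> PedigreeValidationReport:
    """Report structural problems without raising.

    Checks: duplicate individual ids, parents that are not listed as
    individuals, fathers recorded as female / mothers as male, and parentage
    cycles (an individual among its own ancestors).
    """
    report = PedigreeValidationReport()
    seen: set[str] = set()
    for r in ped.records:
        if r.individual_id in seen:
            report.duplicate_individual_ids.append(r.individual_id)
        seen.add(r.individual_id)

    by_id = {r.individual_id: r for r in ped.records}
    for r in ped.records:
        for pid, want_sex in ((r.father_id, 1), (r.mother_id, 2)):
            if pid == MISSING:
                continue
            parent = by_id.get(pid)
            if parent is None:
                report.dangling_parent_ids.append(pid)
            elif parent.sex != want_sex:
                report.sex_inconsistent_parents.append(pid)

    # cycle detection over the child -> parent graph
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {i: WHITE for i in by_id}

    def parents(i: str):
        r = by_id[i]
        return [p for p in (r.father_id, r.mother_id) if p != MISSING and p in by_id]

    for start in by_id:
        if color[start] != WHITE:
            continue
        stack = [(start, iter(parents(start)))]
        color[start] = GRAY
        path = [start]
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if color[p] == GRAY:
                    report.cycles.append(path[path.index(p):] + [p])
                elif color[p] == WHITE:
                    color[p] = GRAY
                    stack.append((p, iter(parents(p))))
                    path.append(p)
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()
                path.pop()
    return report


def _augment_single_parents(ped: Pedigree) -> list[PedigreeRecord]:
    """Give individuals with exactly one known parent a synthetic founder.

    Keeps the kinship recursion total: every non-founder has both a father and
    a mother.  Synthetic founders are appended after the original records and
    stripped from the returned matrix.
    """
    records = list(ped.records)
    extra: list[PedigreeRecord] = []
    counter = 0
    out = []
    for r in records:
        father, mother = r.father_id, r.mother_id
        if (father == MISSING) != (mother == MISSING):
            counter += 1
            if father == MISSING:
                father = f"__synthetic_founder_{counter}"
                extra.append(PedigreeRecord(r.family_id, father, sex=1))
            else:
                mother = f"__synthetic_founder_{counter}"
                extra.append(PedigreeRecord(r.family_id, mother, sex=2))
            r = PedigreeRecord(r.family_id, r.individual_id, father, mother, r.sex)
        out.append(r)
    return out + extra


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Compute the 2*phi matrix by the standard kinship recursion.

    phi(i, i) = 1/2 * (1 + phi(father_i, mother_i))
    phi(i, j) = 1/2 * (phi(father_i, j) + phi(mother_i, j))   (j no descendant)

    with founders non-inbred (phi = 1/2 with themselves) and mutually
    unrelated.  Individuals are processed in topological order so the second
    rule only ever pairs i with non-descendants.

    Raises ``ValueError`` on a cyclic pedigree.
    """
    records = _augment_single_parents(ped)
    ids = [r.individual_id for r in records]
    pos = {i: k for k, i in enumerate(ids)}
    n = len(records)

    # Kahn topological order over child -> parent edges
    n_pending = np.zeros(n, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    for k, r in enumerate(records):
        for pid in (r.father_id, r.mother_id):
            if pid != MISSING:
                if pid not in pos:
                    raise ValueError(f"parent {pid!r} is not in the pedigree")
                n_pending[k] += 1
                children[pos[pid]].append(k)
    order = [k for k in range(n) if n_pending[k] == 0]
    head = 0
    while head < len(order):
        for c in children[order[head]]:
            n_pending[c] -= 1
            if n_pending[c] == 0:
                order.append(c)
        head += 1
    if len(order) < n:
        stuck = [ids[k] for k in range(n) if n_pending[k] > 0]
        raise ValueError(f"pedigree contains a parentage cycle involving {stuck}")

    phi = np.zeros((n, n))
    done: list[int] = []
    for k in order:
        r = records[k]
        if r.is_founder:
            phi[k, k] = 0.5
        else:
            f, m = pos[r.father_id], pos[r.mother_id]
            phi[k, k] = 0.5 * (1.0 + phi[f, m])
            for j in done:
                v = 0.5 * (phi[f, j] + phi[m, j])
                phi[k, j] = phi[j, k] = v
        done.append(k)

    keep = [pos[i] for i in ped.individual_ids]
    return KinshipMatrix(2.0 * phi[np.ix_(keep, keep)], ped.individual_ids)


def handle_mz_twins(
    ped: Pedigree,
    mz_pairs: list[tuple[str, str]],
    mode: str = "drop-one",
) -> tuple[Pedigree, KinshipMatrix]:
    """Resolve monozygotic twin pairs, which make 2*phi degenerate.

    ``drop-one`` removes the second-listed twin of each pair (children of the
    dropped twin are re-pointed to the kept twin, who is genetically
    identical).  ``merge`` keeps both individuals but sets their mutual 2*phi
    entry to the kept twin's self 2*phi, i.e. treats them as genetic copies;
    the resulting matrix is PSD but singular.

    Returns the (possibly reduced) pedigree and the kinship matrix computed
    after the adjustment.
    """
    if mode not in ("drop-one", "merge"):
        raise ValueError(f"unknown MZ-twin mode {mode!r}")
    by_id = {r.individual_id: r for r in ped.records}
    for a, b in mz_pairs:
        ra, rb = by_id[a], by_id[b]
        if (ra.father_id, ra.mother_id) != (rb.father_id, rb.mother_id):
            raise ValueError(f"MZ pair ({a}, {b}) does not share both parents")

    if mode == "drop-one":
        drop = {b for _, b in mz_pairs}
        keep_for = {b: a for a, b in mz_pairs}
        new_records = []
        for r in ped.records:
            if r.individual_id in drop:
                continue
            father = keep_for.get(r.father_id, r.father_id)
            mother = keep_for.get(r.mother_id, r.mother_id)
            if (father, mother) != (r.father_id, r.mother_id):
                r = PedigreeRecord(r.family_id, r.individual_id, father, mother, r.sex)
            new_records.append(r)
        new_ped = Pedigree(new_records)
        return new_ped, compute_kinship(new_ped)

    kin = compute_kinship(ped)
    for a, b in mz_pairs:
        ia, ib = kin.index_of(a), kin.index_of(b)
        kin.Phi2[ia, ib] = kin.Phi2[ib, ia] = kin.Phi2[ia, ia]
    min_eig = np.linalg.eigvalsh(kin.Phi2).min()
    if min_eig < -1e-8:
        warnings.warn(
            f"merged-twin kinship matrix not PSD (min eigenvalue {min_eig:.3g})"
        )
    return ped, kin
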