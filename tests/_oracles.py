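"""Independent brute-force oracles used only by the tests.

Each function is a direct, slow transcription of the defining formula, kept
deliberately free of the package's own vectorized code paths.
"""

from __future__ import annotations

import math

import numpy as np

from pathvc.kinship import MISSING, Pedigree


def _pair_distance(x: np.ndarray, y: np.ndarray, method: str, Cinv=None) -> float:
    if method == "euclidean":
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))
    if method == "manhattan":
        return sum(abs(a - b) for a, b in zip(x, y))
    if method == "chebyshev":
        return max(abs(a - b) for a, b in zip(x, y))
    if method == "bhattacharyya":
        return math.sqrt(sum((math.sqrt(a) - math.sqrt(b)) ** 2 for a, b in zip(x, y)))
    if method == "divergence":
        tot = 0.0
        for a, b in zip(x, y):
            if a + b != 0:
                tot += (a - b) ** 2 / (a + b) ** 2
        return tot
    if method == "canberra":
        tot = 0.0
        for a, b in zip(x, y):
            den = abs(a) + abs(b)
            if den != 0:
                tot += abs(a - b) / den
        return tot
    if method == "braycurtis":
        den = sum(a + b for a, b in zip(x, y))
        num = sum(abs(a - b) for a, b in zip(x, y))
        return num / den if den != 0 else 0.0
    if method == "soergel":
        den = sum(max(a, b) for a, b in zip(x, y))
        num = sum(abs(a - b) for a, b in zip(x, y))
        return num / den if den != 0 else 0.0
    if method == "chord":
        nx = math.sqrt(sum(a * a for a in x))
        ny = math.sqrt(sum(b * b for b in y))
        xn = [a / nx for a in x] if nx else [0.0] * len(x)
        yn = [b / ny for b in y] if ny else [0.0] * len(y)
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(xn, yn)))
    if method == "geodesic":
        if np.array_equal(x, y):
            return 0.0  # arccos(1) exactly, avoiding catastrophic rounding
        nx = math.sqrt(sum(a * a for a in x))
        ny = math.sqrt(sum(b * b for b in y))
        if nx == 0 or ny == 0:
            return math.acos(0.0)
        c = sum(a * b for a, b in zip(x, y)) / (nx * ny)
        return math.acos(min(1.0, max(-1.0, c)))
    if method == "hellinger":
        sx, sy = sum(x), sum(y)
        xn = [a / sx for a in x] if sx else [0.0] * len(x)
        yn = [b / sy for b in y] if sy else [0.0] * len(y)
        return math.sqrt(sum((math.sqrt(a) - math.sqrt(b)) ** 2 for a, b in zip(xn, yn)))
    if method == "whittaker":
        sx, sy = sum(x), sum(y)
        xn = [a / sx for a in x] if sx else [0.0] * len(x)
        yn = [b / sy for b in y] if sy else [0.0] * len(y)
        return 0.5 * sum(abs(a - b) for a, b in zip(xn, yn))
    if method == "mahalanobis":
        d = np.asarray(x) - np.asarray(y)
        return math.sqrt(float(d @ Cinv @ d))
    raise ValueError(method)


def _pair_similarity(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "correlation":
        xc = [a - np.mean(x) for a in x]
        yc = [b - np.mean(y) for b in y]
        num = sum(a * b for a, b in zip(xc, yc))
        den = math.sqrt(sum(a * a for a in xc) * sum(b * b for b in yc))
        return num / den if den != 0 else (1.0 if np.array_equal(x, y) else 0.0)
    if method == "cosine":
        num = sum(a * b for a, b in zip(x, y))
        den = math.sqrt(sum(a * a for a in x)) * math.sqrt(sum(b * b for b in y))
        return num / den if den != 0 else (1.0 if np.array_equal(x, y) else 0.0)
    if method == "extended_jaccard":
        xy = sum(a * b for a, b in zip(x, y))
        xx = sum(a * a for a in x)
        yy = sum(b * b for b in y)
        den = xx + yy - xy
        return xy / den if den != 0 else (1.0 if np.array_equal(x, y) else 0.0)
    raise ValueError(method)


def naive_similarity_matrix(X: np.ndarray, method: str) -> np.ndarray:
    """Double-loop evaluation of one of the 16 metrics; distances are
    converted to similarities by 1/(1+d)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    S = np.zeros((n, n))
    Cinv = None
    if method == "mahalanobis":
        mean = X.mean(axis=0)
        C = np.zeros((X.shape[1], X.shape[1]))
        for row in X:
            d = row - mean
            C += np.outer(d, d)
        C /= X.shape[0] - 1
        Cinv = np.linalg.inv(C)
    direct = method in ("correlation", "cosine", "extended_jaccard")
    for i in range(n):
        for j in range(n):
            if direct:
                S[i, j] = _pair_similarity(X[i], X[j], method)
            else:
                S[i, j] = 1.0 / (1.0 + _pair_distance(X[i], X[j], method, Cinv))
    return S


def naive_loglik(theta, y, X, kernels) -> float:
    """Dense Gaussian log-likelihood with explicit inverse and determinant."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.shape[0]
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], kernels):
        V = V + t * np.asarray(K, dtype=float)
    Vinv = np.linalg.inv(V)
    beta = np.linalg.inv(X.T @ Vinv @ X) @ (X.T @ Vinv @ y)
    r = y - X @ beta
    sign, logdet = np.linalg.slogdet(V)
    return float(-0.5 * (logdet + r @ Vinv @ r + n * np.log(2 * np.pi)))


def gene_drop_phi2(ped: Pedigree, n_drops: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo 2*phi by dropping founder alleles through the pedigree.

    Founders receive unique allele labels; each child inherits one allele at
    random from each parent.  phi(i, j) is the average probability that a
    random allele of i matches (is identical by descent to) a random allele
    of j.
    """
    ids = ped.individual_ids
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    a1 = np.zeros((n, n_drops), dtype=np.int64)
    a2 = np.zeros((n, n_drops), dtype=np.int64)
    # process in an order where parents precede children
    remaining = list(ped.records)
    done: set[str] = set()
    label = 0
    while remaining:
        progressed = False
        for r in list(remaining):
            par = [p for p in (r.father_id, r.mother_id) if p != MISSING]
            if any(p not in done for p in par):
                continue
            k = pos[r.individual_id]
            if not par:
                a1[k] = label
                a2[k] = label + 1
                label += 2
            else:
                f, m = pos[r.father_id], pos[r.mother_id]
                pick_f = rng.integers(0, 2, size=n_drops).astype(bool)
                pick_m = rng.integers(0, 2, size=n_drops).astype(bool)
                a1[k] = np.where(pick_f, a1[f], a2[f])
                a2[k] = np.where(pick_m, a1[m], a2[m])
            done.add(r.individual_id)
            remaining.remove(r)
            progressed = True
        if not progressed:
            raise ValueError("pedigree not topologically orderable")
    phi = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            share = (
                (a1[i] == a1[j]).mean()
                + (a1[i] == a2[j]).mean()
                + (a2[i] == a1[j]).mean()
                + (a2[i] == a2[j]).mean()
            ) / 4.0
            phi[i, j] = phi[j, i] = share
    return 2.0 * phi
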