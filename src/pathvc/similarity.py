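"""Individual-by-individual pathway similarity kernels.

Given unit-scaled expression profiles restricted to one pathway's probes,
each of 16 metrics yields an N x N matrix summarizing how alike every pair of
individuals' profiles is.  Three metrics are similarities computed directly
(correlation, cosine, extended Jaccard); the other 13 are distances converted
to similarities by s = 1 / (1 + d).  The resulting kernel is standardized to
mean diagonal 1 and repaired to positive semidefiniteness before use as a
variance-component covariance structure.

Metric formulas, for profile rows x and y over the pathway's probes:

================  ============================================================
bhattacharyya     sqrt( sum_i (sqrt(x_i) - sqrt(y_i))^2 )
braycurtis        sum_i |x_i - y_i| / sum_i (x_i + y_i)
canberra          sum_i |x_i - y_i| / (|x_i| + |y_i|)   (0/0 terms -> 0)
chebyshev         max_i |x_i - y_i|
chord             || x/||x|| - y/||y|| ||_2
divergence        sum_i (x_i - y_i)^2 / (x_i + y_i)^2   (0/0 terms -> 0)
euclidean         sqrt( sum_i (x_i - y_i)^2 )
geodesic          arccos( x.y / (||x|| ||y||) )
hellinger         bhattacharyya applied to x/sum(x), y/sum(y)
mahalanobis       sqrt( (x-y)' C^-1 (x-y) ),  C = probe covariance
manhattan         sum_i |x_i - y_i|
soergel           sum_i |x_i - y_i| / sum_i max(x_i, y_i)
whittaker         sum_i | x_i/sum(x) - y_i/sum(y) | / 2
----------------  ------------------------------------------------------------
correlation       x.y / sqrt(x.x * y.y) for row-centered x, y
cosine            x.y / (||x|| ||y||)
extended_jaccard  x.y / (x.x + y.y - x.y)
================  ============================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

__all__ = [
    "ProfileSet",
    "SimilarityMatrix",
    "DISTANCE_METHODS",
    "SIMILARITY_METHODS",
    "ALL_METHODS",
    "canonical_method",
    "pairwise_distance",
    "distance_to_similarity",
    "direct_similarity",
    "compute_similarity",
    "make_psd",
    "standardize_vc_matrix",
]

DISTANCE_METHODS = (
    "bhattacharyya",
    "braycurtis",
    "canberra",
    "chebyshev",
    "chord",
    "divergence",
    "euclidean",
    "geodesic",
    "hellinger",
    "mahalanobis",
    "manhattan",
    "soergel",
    "whittaker",
)
SIMILARITY_METHODS = ("correlation", "cosine", "extended_jaccard")
ALL_METHODS = DISTANCE_METHODS + SIMILARITY_METHODS

# short tags as used in the field's reports (bhja, corr, dive, ejac, eucl ...)
_ALIASES = {
    "bhja": "bhattacharyya",
    "corr": "correlation",
    "cosi": "cosine",
    "dive": "divergence",
    "ejac": "extended_jaccard",
    "eucl": "euclidean",
    "manh": "manhattan",
    "cheb": "chebyshev",
    "tschebyscheff": "chebyshev",
    "bray": "braycurtis",
    "braycurtis": "braycurtis",
    "bray_curtis": "braycurtis",
    "canb": "canberra",
    "chor": "chord",
    "geod": "geodesic",
    "hell": "hellinger",
    "maha": "mahalanobis",
    "soer": "soergel",
    "whit": "whittaker",
    "tanimoto": "extended_jaccard",
}


def canonical_method(method: str) -> str:
    m = method.lower().replace("-", "_")
    m = _ALIASES.get(m, m)
    if m not in ALL_METHODS:
        raise ValueError(f"unknown similarity method {method!r}")
    return m


@dataclass
class ProfileSet:
    """Individuals-by-probes profile matrix for one pathway, values in [0, 1]."""

    X: np.ndarray  # individuals x probes
    individual_ids: list[str]
    probe_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.individual_ids), len(self.probe_ids)):
            raise ValueError("profile matrix shape inconsistent with id lists")
        if len(self.probe_ids) < 2:
            warnings.warn(
                "pathway profile has a single probe; distances collapse to "
                "1-D absolute differences"
            )

    @property
    def n(self) -> int:
        return len(self.individual_ids)


@dataclass
class SimilarityMatrix:
    """Symmetric N x N pathway kernel with PSD-repair provenance."""

    S: np.ndarray
    individual_ids: list[str]
    method: str
    psd_repaired: bool = False
    min_eigenvalue_before_repair: float | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.individual_ids)
        if self.S.shape != (n, n):
            raise ValueError("similarity matrix shape inconsistent with ids")
        if np.abs(self.S - self.S.T).max() > 1e-10:
            raise ValueError("similarity matrix is not symmetric")


def _rowwise(X: np.ndarray, pair_fn) -> np.ndarray:
    """Build an N x N matrix by applying pair_fn(x_i, X) for each row i."""
    n = X.shape[0]
    D = np.empty((n, n))
    for i in range(n):
        D[i] = pair_fn(X[i], X)
    return 0.5 * (D + D.T)  # exact symmetry


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with 0-denominator terms contributing 0."""
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den != 0)
    return out


def _l1_normalize(X: np.ndarray) -> np.ndarray:
    s = X.sum(axis=1, keepdims=True)
    return _safe_div(X, np.broadcast_to(s, X.shape))


def _cosine_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cosine similarity matrix and the boolean mask of zero-norm rows."""
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    G = (X @ X.T) / np.outer(safe, safe)
    G[zero, :] = 0.0
    G[:, zero] = 0.0
    np.fill_diagonal(G, np.where(zero, 1.0, G.diagonal()))
    return np.clip(0.5 * (G + G.T), -1.0, 1.0), zero


def mahalanobis_covariance(
    X: np.ndarray, ridge: float = 1e-6, cond_threshold: float = 1e10
) -> np.ndarray:
    """Probe covariance across individuals, ridge-regularized when needed.

    Pathways with more probes than individuals make the covariance singular;
    a ridge of ``ridge * mean(diag)`` is added whenever the condition number
    exceeds ``cond_threshold``.
    """
    C = np.cov(X, rowvar=False)
    C = np.atleast_2d(C)
    eig = np.linalg.eigvalsh(C)
    if eig[0] <= 0 or eig[-1] / max(eig[0], 1e-300) > cond_threshold:
        warnings.warn("singular/ill-conditioned probe covariance; adding ridge")
        C = C + ridge * np.mean(np.diag(C)) * np.eye(C.shape[0])
    return C


def pairwise_distance(
    P: ProfileSet | np.ndarray, method: str, cov: np.ndarray | None = None
) -> np.ndarray:
    """N x N distance matrix for one of the 13 distance-type metrics.

    ``cov`` overrides the Mahalanobis probe covariance (otherwise estimated
    from the profiles themselves).
    """
    X = P.X if isinstance(P, ProfileSet) else np.asarray(P, dtype=float)
    m = canonical_method(method)
    if m in SIMILARITY_METHODS:
        raise ValueError(f"{method!r} is a direct similarity, not a distance")

    if m == "euclidean":
        D = _rowwise(X, lambda x, Y: np.sqrt(((x - Y) ** 2).sum(axis=1)))
    elif m == "manhattan":
        D = _rowwise(X, lambda x, Y: np.abs(x - Y).sum(axis=1))
    elif m == "chebyshev":
        D = _rowwise(X, lambda x, Y: np.abs(x - Y).max(axis=1))
    elif m == "bhattacharyya":
        if (X < 0).any():
            raise ValueError("bhattacharyya requires non-negative values")
        R = np.sqrt(X)
        D = _rowwise(R, lambda x, Y: np.sqrt(((x - Y) ** 2).sum(axis=1)))
    elif m == "divergence":
        if (X < 0).any():
            raise ValueError("divergence requires non-negative values")
        D = _rowwise(
            X,
            lambda x, Y: _safe_div((x - Y) ** 2, (x + Y) ** 2).sum(axis=1),
        )
    elif m == "canberra":
        D = _rowwise(
            X,
            lambda x, Y: _safe_div(np.abs(x - Y), np.abs(x) + np.abs(Y)).sum(axis=1),
        )
    elif m == "braycurtis":
        D = _rowwise(
            X,
            lambda x, Y: _safe_div(
                np.abs(x - Y).sum(axis=1), (x + Y).sum(axis=1)
            ),
        )
    elif m == "soergel":
        D = _rowwise(
            X,
            lambda x, Y: _safe_div(
                np.abs(x - Y).sum(axis=1), np.maximum(x, Y).sum(axis=1)
            ),
        )
    elif m == "chord":
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        Xn = _safe_div(X, np.broadcast_to(norms, X.shape))
        D = _rowwise(Xn, lambda x, Y: np.sqrt(((x - Y) ** 2).sum(axis=1)))
    elif m == "geodesic":
        # via the chord: theta = 2*arcsin(chord/2), exact at zero distance
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        Xn = _safe_div(X, np.broadcast_to(norms, X.shape))
        C = _rowwise(Xn, lambda x, Y: np.sqrt(((x - Y) ** 2).sum(axis=1)))
        D = 2.0 * np.arcsin(np.clip(0.5 * C, 0.0, 1.0))
    elif m == "hellinger":
        if (X < 0).any():
            raise ValueError("hellinger requires non-negative values")
        R = np.sqrt(_l1_normalize(X))
        D = _rowwise(R, lambda x, Y: np.sqrt(((x - Y) ** 2).sum(axis=1)))
    elif m == "whittaker":
        P1 = _l1_normalize(X)
        D = _rowwise(P1, lambda x, Y: 0.5 * np.abs(x - Y).sum(axis=1))
    elif m == "mahalanobis":
        C = mahalanobis_covariance(X) if cov is None else np.asarray(cov, dtype=float)
        L = np.linalg.cholesky(C)
        Z = solve_triangular(L, X.T, lower=True).T  # whiten: rows are L^-1 x
        D = _rowwise(Z, lambda x, Y: np.sqrt(((x - Y) ** 2).sum(axis=1)))
    else:  # pragma: no cover
        raise AssertionError(m)

    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def distance_to_similarity(
    D: np.ndarray, method: str = "distance", individual_ids: list[str] | None = None
) -> SimilarityMatrix:
    """Convert a distance matrix via s = 1 / (1 + d)."""
    D = np.asarray(D, dtype=float)
    if (D < 0).any():
        raise ValueError("distance matrix has negative entries")
    if np.abs(D - D.T).max() > 1e-10:
        raise ValueError("distance matrix is not symmetric")
    if individual_ids is None:
        individual_ids = [str(i) for i in range(D.shape[0])]
    return SimilarityMatrix(1.0 / (1.0 + D), list(individual_ids), method)


def direct_similarity(P: ProfileSet | np.ndarray, method: str) -> SimilarityMatrix:
    """Correlation, cosine or extended-Jaccard similarity (no 1/(1+d))."""
    X = P.X if isinstance(P, ProfileSet) else np.asarray(P, dtype=float)
    ids = (
        P.individual_ids
        if isinstance(P, ProfileSet)
        else [str(i) for i in range(X.shape[0])]
    )
    m = canonical_method(method)
    if m == "correlation":
        # center each individual's profile by its own mean across probes
        Xc = X - X.mean(axis=1, keepdims=True)
        const = np.linalg.norm(Xc, axis=1) == 0
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant profile(s); their correlation "
                "entries set to 0 (diagonal 1)"
            )
        S, _ = _cosine_matrix(Xc)
    elif m == "cosine":
        S, zero = _cosine_matrix(X)
        if zero.any():
            warnings.warn(f"{int(zero.sum())} all-zero profile(s) in cosine")
    elif m == "extended_jaccard":
        G = X @ X.T
        sq = np.diag(G)
        den = sq[:, None] + sq[None, :] - G
        zero = sq == 0
        S = _safe_div(G, den)
        S[zero, :] = 0.0
        S[:, zero] = 0.0
        np.fill_diagonal(S, np.where(den.diagonal() == 0, 1.0, S.diagonal()))
        if zero.any():
            warnings.warn(f"{int(zero.sum())} all-zero profile(s) in extended Jaccard")
        S = 0.5 * (S + S.T)
    else:  # pragma: no cover
        raise AssertionError(m)
    return SimilarityMatrix(S, list(ids), m)


def compute_similarity(
    P: ProfileSet,
    method: str,
    standardize: bool = True,
    psd_repair: bool = True,
) -> SimilarityMatrix:
    """One-stop kernel computation for a pathway profile set.

    Distance metrics go through 1/(1+d); direct similarities do not.  By
    default the kernel is then standardized to mean diagonal 1 and clipped to
    PSD, making it directly usable as a variance-component covariance.
    """
    m = canonical_method(method)
    if m in SIMILARITY_METHODS:
        sim = direct_similarity(P, m)
    else:
        D = pairwise_distance(P, m)
        sim = distance_to_similarity(D, m, P.individual_ids)
    if standardize:
        sim = standardize_vc_matrix(sim)
    if psd_repair:
        sim = make_psd(sim)
    return sim


def make_psd(S: SimilarityMatrix, tol: float = 1e-8) -> SimilarityMatrix:
    """Clip negative eigenvalues to zero so the kernel is a valid covariance.

    If the smallest eigenvalue is already >= -tol the input is returned
    unchanged (flag stays false); otherwise the matrix is reassembled from the
    clipped spectrum and the pre-repair minimum eigenvalue recorded.
    """
    eigval, eigvec = np.linalg.eigh(S.S)
    lo = float(eigval.min())
    if lo >= -tol:
        return SimilarityMatrix(
            S.S, S.individual_ids, S.method, S.psd_repaired, lo
        )
    fixed = (eigvec * np.maximum(eigval, 0.0)) @ eigvec.T
    fixed = 0.5 * (fixed + fixed.T)
    return SimilarityMatrix(fixed, S.individual_ids, S.method, True, lo)


def standardize_vc_matrix(S: SimilarityMatrix) -> SimilarityMatrix:
    """Scale so the mean diagonal is 1 (the kinship 2*phi scale).

    Puts every kernel's variance component on a comparable scale so variance
    proportions can be compared across pathways and methods.
    """
    tr = float(np.trace(S.S))
    if tr <= 0:
        raise ValueError("cannot standardize a kernel with non-positive trace")
    return SimilarityMatrix(
        S.S * (len(S.individual_ids) / tr),
        S.individual_ids,
        S.method,
        S.psd_repaired,
        S.min_eigenvalue_before_repair,
    )
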