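"""Gaussian variance-component mixed models and the boundary LRT.

The model is

    y = X beta + sum_k u_k + e,     u_k ~ N(0, sigma2_k K_k),  e ~ N(0, sigma2_e I)

so V(theta) = sum_k sigma2_k K_k + sigma2_e I.  ``fit_ml`` maximizes the
profile log-likelihood (beta solved by GLS at each theta) over sigma2 >= 0
with a bounded quasi-Newton optimizer and multiple starts.  The pathway test
compares the kinship-only null against the model with one extra kernel; the
likelihood-ratio statistic for a single variance component on its boundary is
referred to the 1/2 chi2_0 + 1/2 chi2_1 mixture by default (a plain chi2_1
reference is available for comparison).

Heritability h2 is the kinship component's share of total variance; a pathway
kernel's share is its proportion of variance explained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

__all__ = [
    "MixedModelSpec",
    "VarCompFit",
    "LrtResult",
    "profile_loglik",
    "fit_ml",
    "fit_null_and_alternative",
    "lrt",
    "variance_explained",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixedModelSpec:
    """Phenotype, fixed-effect design and ordered covariance kernels.

    By convention the first kernel is the kinship 2*phi matrix and an optional
    second kernel is a pathway similarity matrix; the residual identity kernel
    is implicit and always last in the variance vector.
    """

    y: np.ndarray
    X: np.ndarray
    kernels: list[np.ndarray]
    kernel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            self.X = self.X.T
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            raise ValueError("X and y are not conformable")
        self.kernels = [np.asarray(K, dtype=float) for K in self.kernels]
        for K in self.kernels:
            if K.shape != (n, n):
                raise ValueError("kernel dimension does not match y")
            if np.abs(K - K.T).max() > 1e-8:
                raise ValueError("kernels must be symmetric")
        if not self.kernel_names:
            self.kernel_names = [f"K{k + 1}" for k in range(len(self.kernels))]
        if len(self.kernel_names) != len(self.kernels):
            raise ValueError("kernel_names length mismatch")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_components(self) -> int:
        """Number of variance parameters including the residual."""
        return len(self.kernels) + 1


@dataclass
class VarCompFit:
    """Maximum-likelihood fit of a variance-component model."""

    beta: np.ndarray
    sigma2: np.ndarray  # per-kernel components followed by the residual
    component_names: list[str]
    loglik: float
    converged: bool
    n_iter: int
    reml: bool = False
    spec: MixedModelSpec | None = None

    @property
    def sigma2_total(self) -> float:
        return float(self.sigma2.sum())

    @property
    def h2(self) -> float:
        """Share of variance on the first (kinship) kernel."""
        return float(self.sigma2[0] / self.sigma2_total)

    @property
    def pathway_var(self) -> float | None:
        """Share of variance on the second (pathway) kernel, if present."""
        if len(self.sigma2) < 3:
            return None
        return float(self.sigma2[1] / self.sigma2_total)


@dataclass
class LrtResult:
    """Likelihood-ratio test of one extra variance component."""

    statistic: float
    p_value: float
    null_distribution: str  # "mixture" (1/2 chi2_0 + 1/2 chi2_1) or "chi2_1"


def _build_v(theta: np.ndarray, spec: MixedModelSpec) -> np.ndarray:
    V = theta[-1] * np.eye(spec.n)
    for t, K in zip(theta[:-1], spec.kernels):
        if t != 0.0:
            V += t * K
    return V


def _loglik_dense(theta: np.ndarray, spec: MixedModelSpec, reml: bool):
    """Profile log-likelihood and its gradient via Cholesky of V."""
    n, X, y = spec.n, spec.X, spec.y
    V = _build_v(theta, spec)
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, np.full_like(theta, np.nan)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    Vi_y = cho_solve((c, low), y)
    Vi_X = cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    u = Vi_y - Vi_X @ beta  # = V^-1 r
    quad = float(r @ u)
    ll = -0.5 * (logdet + quad + n * _LOG2PI)
    if reml:
        p = X.shape[1]
        sign, logdet_x = np.linalg.slogdet(XtViX)
        ll += 0.5 * (p * _LOG2PI - logdet_x)
    # gradient: dl/dt_k = -1/2 [tr(P K_k) - u' K_k u], P = V^-1 (ML, envelope)
    Vi = cho_solve((c, low), np.eye(n))
    if reml:
        Vi = Vi - Vi_X @ np.linalg.solve(XtViX, Vi_X.T)
    grad = np.empty_like(theta)
    for k, K in enumerate(spec.kernels):
        grad[k] = -0.5 * (np.sum(Vi * K) - u @ K @ u)
    grad[-1] = -0.5 * (np.trace(Vi) - u @ u)
    return ll, grad


class _EigLik:
    """Fast single-kernel likelihood via one eigendecomposition.

    With V = t1 K + te I = U diag(t1 lam + te) U', a single rotation of y and
    X makes every likelihood evaluation O(n p^2).
    """

    def __init__(self, spec: MixedModelSpec, reml: bool):
        self.spec = spec
        self.reml = reml
        lam, U = np.linalg.eigh(spec.kernels[0])
        self.lam = np.maximum(lam, 0.0)
        self.yt = U.T @ spec.y
        self.Xt = U.T @ spec.X
        self.U = U

    def value_and_grad(self, theta: np.ndarray):
        n = self.spec.n
        d = theta[0] * self.lam + theta[1]
        if d.min() <= 0:
            return -np.inf, np.full_like(theta, np.nan), None
        w = 1.0 / d
        Xw = self.Xt * w[:, None]
        XtViX = self.Xt.T @ Xw
        beta = np.linalg.solve(XtViX, Xw.T @ self.yt)
        r = self.yt - self.Xt @ beta
        u = r * w
        quad = float(r @ u)
        ll = -0.5 * (np.log(d).sum() + quad + n * _LOG2PI)
        if self.reml:
            p = self.Xt.shape[1]
            sign, logdet_x = np.linalg.slogdet(XtViX)
            ll += 0.5 * (p * _LOG2PI - logdet_x)
            # REML trace uses P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1
            A = np.linalg.solve(XtViX, Xw.T)
            tr_lam = float((w * self.lam).sum() - np.sum((Xw.T * self.lam) * A))
            tr_id = float(w.sum() - np.sum(Xw.T * A))
        else:
            tr_lam = float((w * self.lam).sum())
            tr_id = float(w.sum())
        grad = np.array(
            [
                -0.5 * (tr_lam - float(u @ (self.lam * u))),
                -0.5 * (tr_id - float(u @ u)),
            ]
        )
        return ll, grad, beta


def profile_loglik(
    theta: np.ndarray, spec: MixedModelSpec, reml: bool = False
) -> float:
    """Log-likelihood at variance parameters ``theta`` with beta profiled out.

    ``theta`` holds one variance per kernel followed by the residual variance;
    V(theta) must be positive definite.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape[0] != spec.n_components:
        raise ValueError(
            f"expected {spec.n_components} variance parameters, got {theta.shape[0]}"
        )
    ll, _ = _loglik_dense(theta, spec, reml)
    if not np.isfinite(ll):
        raise ValueError(
            "V(theta) is not positive definite; check the kernels "
            f"({spec.kernel_names}) and the residual variance"
        )
    return ll


def _gls_beta(theta: np.ndarray, spec: MixedModelSpec) -> np.ndarray:
    V = _build_v(theta, spec)
    c, low = cho_factor(V, lower=True)
    Vi_y = cho_solve((c, low), spec.y)
    Vi_X = cho_solve((c, low), spec.X)
    return np.linalg.solve(spec.X.T @ Vi_X, spec.X.T @ Vi_y)


def _starting_points(spec: MixedModelSpec) -> list[np.ndarray]:
    """Equal-split, residual-heavy and last-kernel-heavy starts."""
    vy = float(np.var(spec.y))
    if vy == 0:
        vy = 1.0
    m = spec.n_components
    starts = [np.full(m, vy / m)]
    heavy_resid = np.full(m, 0.05 * vy / max(m - 1, 1))
    heavy_resid[-1] = 0.9 * vy
    starts.append(heavy_resid)
    heavy_last = np.full(m, 0.05 * vy / max(m - 1, 1))
    heavy_last[-2 if m > 1 else -1] = 0.9 * vy
    starts.append(heavy_last)
    return starts


def fit_ml(
    spec: MixedModelSpec,
    reml: bool = False,
    extra_starts: list[np.ndarray] | None = None,
    max_restarts: int = 2,
) -> VarCompFit:
    """Fit by (RE)ML over sigma2 >= 0 with multi-start L-BFGS-B.

    Non-convergence after restarts is flagged on the returned fit rather than
    raised.  ``extra_starts`` allows warm-starting (e.g. the alternative model
    at the null solution) to enforce likelihood nesting.
    """
    vy = float(np.var(spec.y))
    if vy == 0:
        vy = 1.0
    floor = 1e-10 * vy  # keeps V positive definite with PSD kernels
    m = spec.n_components
    bounds = [(0.0, None)] * (m - 1) + [(floor, None)]

    single_kernel = len(spec.kernels) == 1
    eig = _EigLik(spec, reml) if single_kernel else None

    def objective(theta):
        if single_kernel:
            ll, g, _ = eig.value_and_grad(theta)
        else:
            ll, g = _loglik_dense(theta, spec, reml)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(theta)
        return -ll, -g

    starts = _starting_points(spec)
    if extra_starts:
        for s in extra_starts:
            s = np.maximum(np.asarray(s, dtype=float), 0.0)
            s[-1] = max(s[-1], floor)
            starts.append(s)

    best = None
    total_iter = 0
    any_converged = False
    for attempt in range(max_restarts + 1):
        for x0 in starts:
            res = optimize.minimize(
                objective,
                np.maximum(x0, floor),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
            )
            total_iter += res.nit
            any_converged = any_converged or res.success
            if best is None or -res.fun > -best.fun:
                best = res
        if best is not None and np.isfinite(best.fun):
            break
        starts = [s * (1.0 + 0.5 * (attempt + 1)) for s in _starting_points(spec)]

    if best is None or not np.isfinite(best.fun):
        warnings.warn("variance-component fit failed to produce a finite likelihood")
        theta = np.array(_starting_points(spec)[0])
        return VarCompFit(
            beta=np.zeros(spec.X.shape[1]),
            sigma2=theta,
            component_names=spec.kernel_names + ["residual"],
            loglik=-np.inf,
            converged=False,
            n_iter=total_iter,
            reml=reml,
            spec=spec,
        )

    theta = np.maximum(best.x, 0.0)
    theta[-1] = max(theta[-1], floor)
    if single_kernel:
        _, _, beta = eig.value_and_grad(theta)
    else:
        beta = _gls_beta(theta, spec)
    if not any_converged:
        warnings.warn("variance-component optimizer did not report convergence")
    return VarCompFit(
        beta=np.asarray(beta),
        sigma2=theta,
        component_names=spec.kernel_names + ["residual"],
        loglik=float(-best.fun),
        converged=bool(any_converged),
        n_iter=total_iter,
        reml=reml,
        spec=spec,
    )


def fit_null_and_alternative(
    y: np.ndarray,
    X: np.ndarray,
    kinship: np.ndarray,
    pathway_kernel: np.ndarray,
    reml: bool = False,
    kernel_names: tuple[str, str] = ("kinship", "pathway"),
) -> tuple[VarCompFit, VarCompFit]:
    """Fit the polygenic null and the pathway-augmented alternative.

    The alternative is warm-started at the null solution (pathway variance 0),
    guaranteeing its maximized likelihood is never below the null's.
    """
    null_spec = MixedModelSpec(y, X, [kinship], [kernel_names[0]])
    null_fit = fit_ml(null_spec, reml=reml)
    warm = np.array([null_fit.sigma2[0], 0.0, null_fit.sigma2[1]])
    alt_spec = MixedModelSpec(y, X, [kinship, pathway_kernel], list(kernel_names))
    alt_fit = fit_ml(alt_spec, reml=reml, extra_starts=[warm])
    return null_fit, alt_fit


def lrt(
    null_fit: VarCompFit,
    alt_fit: VarCompFit,
    null_distribution: str = "mixture",
) -> LrtResult:
    """Likelihood-ratio test of the extra variance component.

    The statistic is max(0, 2 * (ll_alt - ll_null)).  Because the tested
    sigma2 sits on the boundary of its parameter space under the null, the
    default reference is the 1/2 chi2_0 + 1/2 chi2_1 mixture:
    p = 1/2 P(chi2_1 > stat) for stat > 0 and p = 1/2 at stat = 0.
    ``null_distribution="chi2_1"`` gives the naive chi2_1 p value instead.
    """
    if null_distribution not in ("mixture", "chi2_1"):
        raise ValueError(f"unknown null distribution {null_distribution!r}")
    if null_fit.spec is not None and alt_fit.spec is not None:
        if null_fit.spec.y.shape != alt_fit.spec.y.shape or not np.allclose(
            null_fit.spec.y, alt_fit.spec.y
        ):
            raise ValueError("null and alternative fits use different phenotypes")
        if null_fit.spec.X.shape != alt_fit.spec.X.shape or not np.allclose(
            null_fit.spec.X, alt_fit.spec.X
        ):
            raise ValueError("null and alternative fits use different designs")
        if len(alt_fit.spec.kernels) != len(null_fit.spec.kernels) + 1:
            raise ValueError("alternative must have exactly one extra kernel")
    stat = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))
    if null_distribution == "mixture":
        p = 0.5 if stat == 0.0 else 0.5 * float(chi2.sf(stat, df=1))
    else:
        p = 1.0 if stat == 0.0 else float(chi2.sf(stat, df=1))
    return LrtResult(statistic=stat, p_value=p, null_distribution=null_distribution)


def variance_explained(fit: VarCompFit) -> dict[str, float]:
    """Per-component proportion of total phenotypic variance (sums to 1)."""
    total = fit.sigma2_total
    if total <= 0:
        raise ValueError("total variance is not positive")
    return {
        name: float(s / total)
        for name, s in zip(fit.component_names, fit.sigma2)
    }
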