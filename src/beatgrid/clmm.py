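"""Cumulative-link mixed model for ordinal ratings, fitted from scratch.

The latent model for participant *i*, trial *j* with design row ``x_ij``:

    P(Y_ij <= k) = F(theta_k - x_ij' beta - b_i),      b_i ~ N(0, sigma_b^2)

with strictly increasing thresholds ``theta_1 < ... < theta_{K-1}`` for K
response categories and F the logistic (default) or normal CDF.  The
marginal likelihood integrates the participant intercept out by adaptive
Gauss–Hermite quadrature: per participant the integrand's mode and curvature
are located by Newton steps (the log-integrand is strictly concave for both
links), and the quadrature grid is centred and scaled there.  One node is
the Laplace approximation.

Optimization runs on an unconstrained parametrization — beta, the first
threshold, log threshold increments, and log sigma_b — by BFGS with an
analytic gradient (holding the adaptive nodes fixed, the standard
approximation for this family).  Standard errors come from the numerical
Hessian at the optimum, mapped to the natural scale by the delta method.

Unobserved extreme rating categories are collapsed before fitting and the
threshold indices are mapped back to the original 1-10 scale afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .design import ContrastScheme, DesignInfo, build_design

__all__ = [
    "ClmmSpec", "ClmmFit", "ConvergenceError",
    "fit_clmm", "loglik_by_quadrature", "empirical_thresholds",
]


class ConvergenceError(RuntimeError):
    """Raised when the optimizer cannot reach a stationary point."""


# ---------------------------------------------------------------------------
# link functions

def _logit_cdf(x):
    return special.expit(x)


def _logit_pdf(x):
    p = special.expit(x)
    return p * (1.0 - p)


def _logit_dpdf(x):
    p = special.expit(x)
    return p * (1.0 - p) * (1.0 - 2.0 * p)


_LINKS = {
    "logit": (_logit_cdf, _logit_pdf, _logit_dpdf),
    "probit": (stats.norm.cdf, stats.norm.pdf, lambda x: -x * stats.norm.pdf(x)),
}

_TINY = 1e-300


@dataclass(frozen=True)
class ClmmSpec:
    """Model options: link, quadrature nodes, random-intercept handling."""

    link: str = "logit"
    nodes: int = 15
    sigma_fixed: float | None = None   # 0.0 -> plain cumulative model
    scheme: ContrastScheme = field(default_factory=ContrastScheme)
    max_restarts: int = 3
    gtol: float = 1e-6


@dataclass
class ClmmFit:
    """A fitted cumulative-link mixed model."""

    beta: np.ndarray
    theta: np.ndarray            # thresholds on the observed-category scale
    sigma_b: float
    loglik: float
    n_obs: int
    n_groups: int
    vcov: np.ndarray             # natural scale: (beta, theta, [sigma_b])
    design: DesignInfo | None
    column_names: list[str]
    category_levels: np.ndarray  # original rating value per fitted category
    spec: ClmmSpec
    converged: bool
    grad_norm: float
    n_iter: int

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov)[: self.beta.size])

    @property
    def se_theta(self) -> np.ndarray:
        p = self.beta.size
        return np.sqrt(np.diag(self.vcov)[p: p + self.theta.size])

    @property
    def se_sigma_b(self) -> float:
        if self.spec.sigma_fixed is not None:
            return 0.0
        return float(np.sqrt(np.diag(self.vcov)[-1]))

    def params_named(self) -> pd.DataFrame:
        names = (list(self.column_names)
                 + [f"theta_{k}" for k in range(1, self.theta.size + 1)]
                 + ([] if self.spec.sigma_fixed is not None else ["sigma_b"]))
        est = np.concatenate([self.beta, self.theta,
                              [] if self.spec.sigma_fixed is not None else [self.sigma_b]])
        return pd.DataFrame({"parameter": names, "estimate": est,
                             "se": np.sqrt(np.diag(self.vcov))})


# ---------------------------------------------------------------------------
# internals

class _ClmmProblem:
    """Data + likelihood machinery on the internal parametrization."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                 n_cat: int, link: str = "logit", nodes: int = 15,
                 sigma_fixed: float | None = None):
        self.y = np.asarray(y, dtype=np.int64)
        self.X = np.asarray(X, dtype=float)
        self.g = np.asarray(groups, dtype=np.int64)
        self.K = int(n_cat)
        self.G = int(self.g.max()) + 1 if self.g.size else 0
        self.p = self.X.shape[1]
        self.cdf, self.pdf, self.dpdf = _LINKS[link]
        z, w = np.polynomial.hermite.hermgauss(nodes)
        self.z, self.logw = z, np.log(w)
        self.sigma_fixed = sigma_fixed
        self.mixed = sigma_fixed is None
        # bincount index helpers
        self.upper_has = self.y < self.K - 1
        self.lower_has = self.y > 0

    # -- parameter packing: [beta, theta1, log dtheta (K-2), log sigma?]
    def n_params(self) -> int:
        return self.p + (self.K - 1) + (1 if self.mixed else 0)

    def unpack(self, psi: np.ndarray):
        p, K = self.p, self.K
        beta = psi[:p]
        theta = np.empty(K - 1)
        theta[0] = psi[p]
        if K > 2:
            theta[1:] = psi[p] + np.cumsum(np.exp(psi[p + 1: p + K - 1]))
        sigma = np.exp(psi[-1]) if self.mixed else float(self.sigma_fixed)
        return beta, theta, sigma

    def pack(self, beta, theta, sigma):
        theta = np.asarray(theta, dtype=float)
        parts = [np.asarray(beta, dtype=float), [theta[0]]]
        if theta.size > 1:
            parts.append(np.log(np.diff(theta)))
        if self.mixed:
            parts.append([np.log(max(sigma, 1e-8))])
        return np.concatenate([np.atleast_1d(np.asarray(x, dtype=float)) for x in parts])

    def _bounds(self, theta, eta, b_obs):
        """Upper/lower link arguments per observation (b may be (n,) or (n, Q))."""
        up = np.where(self.upper_has, theta[np.minimum(self.y, self.K - 2)], np.inf)
        lo = np.where(self.lower_has, theta[np.maximum(self.y - 1, 0)], -np.inf)
        if np.ndim(b_obs) == 2:
            up, lo, eta = up[:, None], lo[:, None], np.reshape(eta, (-1, 1))
        return up - eta - b_obs, lo - eta - b_obs

    def _logp_terms(self, u, lo):
        """log p plus the pieces needed for derivatives, elementwise."""
        Fu = np.where(np.isinf(u), 1.0, self.cdf(np.nan_to_num(u, posinf=0.0)))
        Fl = np.where(np.isinf(lo), 0.0, self.cdf(np.nan_to_num(lo, neginf=0.0)))
        fu = np.where(np.isinf(u), 0.0, self.pdf(np.nan_to_num(u, posinf=0.0)))
        fl = np.where(np.isinf(lo), 0.0, self.pdf(np.nan_to_num(lo, neginf=0.0)))
        p = np.clip(Fu - Fl, _TINY, None)
        return np.log(p), p, fu, fl

    # -- conditional (fixed b) pieces -------------------------------------
    def _group_sum(self, values: np.ndarray) -> np.ndarray:
        """Sum per group; values is (n,) or (n, Q)."""
        if values.ndim == 1:
            return np.bincount(self.g, weights=values, minlength=self.G)
        out = np.zeros((self.G, values.shape[1]))
        np.add.at(out, self.g, values)
        return out

    def _find_modes(self, beta, theta, sigma, n_newton: int = 30):
        """Per-group mode and curvature of the log integrand (Newton)."""
        eta = self.X @ beta
        b = np.zeros(self.G)
        for _ in range(n_newton):
            u, lo = self._bounds(theta, eta, b[self.g])
            _, p, fu, fl = self._logp_terms(u, lo)
            dfu = np.where(np.isinf(u), 0.0, self.dpdf(np.nan_to_num(u, posinf=0.0)))
            dfl = np.where(np.isinf(lo), 0.0, self.dpdf(np.nan_to_num(lo, neginf=0.0)))
            s = (fu - fl) / p
            d1 = self._group_sum(-s) - b / sigma**2
            d2 = self._group_sum((dfu - dfl) / p - s**2) - 1.0 / sigma**2
            step = d1 / d2
            # d2 < 0 by log-concavity; damp huge steps for stability
            step = np.clip(step, -2.0, 2.0)
            b_new = b - step
            if np.max(np.abs(b_new - b)) < 1e-10:
                b = b_new
                break
            b = b_new
        u, lo = self._bounds(theta, eta, b[self.g])
        _, p, fu, fl = self._logp_terms(u, lo)
        dfu = np.where(np.isinf(u), 0.0, self.dpdf(np.nan_to_num(u, posinf=0.0)))
        dfl = np.where(np.isinf(lo), 0.0, self.dpdf(np.nan_to_num(lo, neginf=0.0)))
        s = (fu - fl) / p
        h = -(self._group_sum((dfu - dfl) / p - s**2) - 1.0 / sigma**2)
        return b, np.maximum(h, 1e-10), eta

    def loglik_grad(self, psi: np.ndarray, want_grad: bool = True):
        beta, theta, sigma = self.unpack(psi)
        if not self.mixed and self.sigma_fixed == 0.0:
            return self._loglik_grad_fixed(psi, beta, theta, want_grad)
        b_hat, h, eta = self._find_modes(beta, theta, sigma)
        s_i = 1.0 / np.sqrt(h)                       # (G,)
        nodes = b_hat[:, None] + np.sqrt(2.0) * s_i[:, None] * self.z[None, :]  # (G,Q)
        b_obs = nodes[self.g]                        # (n,Q)
        u, lo = self._bounds(theta, eta[:, None], b_obs)
        logp, p, fu, fl = self._logp_terms(u, lo)
        f_qb = self._group_sum(logp)                 # (G,Q) conditional loglik
        f_qb += stats.norm.logpdf(nodes, scale=sigma)
        m = self.logw[None, :] + self.z[None, :] ** 2 + f_qb
        mmax = m.max(axis=1, keepdims=True)
        sumexp = np.exp(m - mmax).sum(axis=1)
        ll = float(np.sum(np.log(np.sqrt(2.0) * s_i) + mmax[:, 0] + np.log(sumexp)))
        if not want_grad:
            return ll, None
        c = np.exp(m - mmax) / sumexp[:, None]       # posterior node weights (G,Q)
        c_obs = c[self.g]                            # (n,Q)
        dldeta = -(fu - fl) / p                      # (n,Q)
        wsum = (c_obs * dldeta).sum(axis=1)          # (n,)
        g_beta = self.X.T @ wsum
        # thresholds
        a_up = (c_obs * fu / p).sum(axis=1)
        a_lo = (c_obs * fl / p).sum(axis=1)
        g_theta = np.zeros(self.K - 1)
        np.add.at(g_theta, np.minimum(self.y, self.K - 2), np.where(self.upper_has, a_up, 0.0))
        np.add.at(g_theta, np.maximum(self.y - 1, 0), -np.where(self.lower_has, a_lo, 0.0))
        g_int = self._theta_chain(g_theta, psi)
        grads = [g_beta, g_int]
        if self.mixed:
            g_ls = float(np.sum(c * (nodes**2 / sigma**2 - 1.0)))
            grads.append([g_ls])
        return ll, np.concatenate([np.atleast_1d(np.asarray(x)) for x in grads])

    def _theta_chain(self, g_theta: np.ndarray, psi: np.ndarray) -> np.ndarray:
        """Map d/dtheta to the (theta1, log-increments) parametrization."""
        out = np.empty(self.K - 1)
        out[0] = g_theta.sum()
        if self.K > 2:
            rev_cum = np.cumsum(g_theta[::-1])[::-1]     # sum_{k>=m} g_theta[k]
            out[1:] = np.exp(psi[self.p + 1: self.p + self.K - 1]) * rev_cum[1:]
        return out

    def _loglik_grad_fixed(self, psi, beta, theta, want_grad):
        """sigma_b = 0: no random effect, plain cumulative model."""
        eta = self.X @ beta
        u, lo = self._bounds(theta, eta, 0.0)
        logp, p, fu, fl = self._logp_terms(u, lo)
        ll = float(logp.sum())
        if not want_grad:
            return ll, None
        dldeta = -(fu - fl) / p
        g_beta = self.X.T @ dldeta
        g_theta = np.zeros(self.K - 1)
        np.add.at(g_theta, np.minimum(self.y, self.K - 2), np.where(self.upper_has, fu / p, 0.0))
        np.add.at(g_theta, np.maximum(self.y - 1, 0), -np.where(self.lower_has, fl / p, 0.0))
        return ll, np.concatenate([g_beta, self._theta_chain(g_theta, psi)])

    # -- optimization ------------------------------------------------------
    def fit(self, psi0: np.ndarray | None = None, gtol: float = 1e-6,
            max_restarts: int = 3, seed: int = 0):
        if psi0 is None:
            theta0 = empirical_thresholds(self.y, self.K,
                                          link="logit" if self.cdf is _logit_cdf else "probit")
            psi0 = self.pack(np.zeros(self.p), theta0, 1.0)
        rng = np.random.default_rng(seed)
        best = None
        psi_start = np.asarray(psi0, dtype=float)
        for attempt in range(max_restarts + 1):
            res = optimize.minimize(
                lambda q: tuple(map(np.negative, self.loglik_grad(q))),
                psi_start, jac=True, method="BFGS",
                options={"gtol": gtol, "maxiter": 500})
            gnorm = float(np.max(np.abs(res.jac)))
            cand = (res, gnorm)
            if best is None or res.fun < best[0].fun:
                best = cand
            # accept a stationary-enough point (the frozen-node gradient is
            # an approximation, so BFGS may stop with success=False)
            if res.success or gnorm < 1e-4:
                best = cand
                break
            psi_start = np.asarray(psi0) + rng.normal(scale=0.1, size=psi0.size)
        return best


def empirical_thresholds(y: np.ndarray, n_cat: int, link: str = "logit") -> np.ndarray:
    """Thresholds of the null model: F^{-1} of the empirical cumulative shares."""
    counts = np.bincount(y, minlength=n_cat)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    cum = np.clip(cum, 1e-10, 1 - 1e-10)
    if link == "logit":
        return np.log(cum / (1 - cum))
    return stats.norm.ppf(cum)


def loglik_by_quadrature(y, X, groups, n_cat, beta, theta, sigma,
                         nodes: int = 15, link: str = "logit") -> float:
    """Marginal log-likelihood at fixed parameters (adaptive quadrature)."""
    prob = _ClmmProblem(y, X, groups, n_cat, link=link, nodes=nodes,
                        sigma_fixed=None if sigma > 0 else 0.0)
    if sigma > 0:
        psi = prob.pack(beta, theta, sigma)
    else:
        psi = prob.pack(beta, theta, 1.0)
    ll, _ = prob.loglik_grad(psi, want_grad=False)
    return ll


# ---------------------------------------------------------------------------
# public fitting interface

def _prepare(records: pd.DataFrame, design: DesignInfo | None, spec: ClmmSpec):
    if design is None:
        design = build_design(records, spec.scheme)
    ratings = records["rating"].to_numpy()
    levels = np.unique(ratings)
    if levels.size < 2:
        raise ValueError("need at least two observed rating categories")
    y = np.searchsorted(levels, ratings)
    pid, groups = np.unique(records["participant_id"].to_numpy(), return_inverse=True)
    if pid.size < 2 and spec.sigma_fixed is None:
        raise ValueError("mixed fit needs at least two participants")
    return design, y, groups, levels


def fit_clmm(records: pd.DataFrame, spec: ClmmSpec = ClmmSpec(),
             design: DesignInfo | None = None,
             start: dict | None = None,
             compute_vcov: bool = True,
             X: np.ndarray | None = None,
             column_names: list[str] | None = None) -> ClmmFit:
    """Fit the cumulative-link mixed model to a ratings table.

    ``records`` needs columns ``participant_id``, ``rating`` and the four
    predictors (unless an explicit design matrix ``X`` is supplied).
    Non-convergence raises :class:`ConvergenceError` with diagnostics.
    """
    if X is not None:
        ratings = records["rating"].to_numpy()
        levels = np.unique(ratings)
        if levels.size < 2:
            raise ValueError("need at least two observed rating categories")
        y = np.searchsorted(levels, ratings)
        _, groups = np.unique(records["participant_id"].to_numpy(), return_inverse=True)
        design = None
        names = column_names or [f"x{i}" for i in range(X.shape[1])]
    else:
        design, y, groups, levels = _prepare(records, design, spec)
        X = design.matrix
        names = design.column_names
    prob = _ClmmProblem(y, X, groups, n_cat=levels.size, link=spec.link,
                        nodes=spec.nodes, sigma_fixed=spec.sigma_fixed)
    psi0 = None
    if start is not None:
        psi0 = prob.pack(start["beta"], start["theta"],
                         start.get("sigma_b", 1.0))
    res, gnorm = prob.fit(psi0, gtol=spec.gtol, max_restarts=spec.max_restarts)
    converged = bool(res.success or gnorm < 1e-4)
    if not converged:
        raise ConvergenceError(
            f"CLMM optimizer did not converge: |grad|={gnorm:.3g}, "
            f"loglik={-res.fun:.6f}, message={res.message!r}")
    beta, theta, sigma = prob.unpack(res.x)
    vcov = np.full((prob.n_params(), prob.n_params()), np.nan)
    if compute_vcov:
        H = _numerical_hessian(lambda q: prob.loglik_grad(q)[1], res.x)
        vcov_int = np.linalg.pinv(-H)
        J = _natural_jacobian(prob, res.x)
        vcov = J @ vcov_int @ J.T
    return ClmmFit(
        beta=beta, theta=theta, sigma_b=float(sigma), loglik=float(-res.fun),
        n_obs=len(y), n_groups=prob.G, vcov=vcov, design=design,
        column_names=list(names), category_levels=levels, spec=spec,
        converged=converged, grad_norm=gnorm, n_iter=int(res.nit))


def _numerical_hessian(grad_fn, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        h = step * max(1.0, abs(x[i]))
        e = np.zeros(n)
        e[i] = h
        H[:, i] = (grad_fn(x + e) - grad_fn(x - e)) / (2 * h)
    return (H + H.T) / 2.0


def _natural_jacobian(prob: _ClmmProblem, psi: np.ndarray) -> np.ndarray:
    """d(beta, theta, sigma) / d(internal parametrization)."""
    p, K = prob.p, prob.K
    n = prob.n_params()
    J = np.zeros((n, n))
    J[:p, :p] = np.eye(p)
    J[p:p + K - 1, p] = 1.0
    for m in range(1, K - 1):
        J[p + m: p + K - 1, p + m] = np.exp(psi[p + m])
    if prob.mixed:
        J[-1, -1] = np.exp(psi[-1])
    return J
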