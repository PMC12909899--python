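"""Mixed-effects logistic regression via the Laplace approximation.

Fits a binomial GLMM with Gaussian random effects grouped by subject,

    logit P(y_ij = 1) = x_ij' beta + z_ij' b_i,      b_i ~ N(0, diag(sigma^2)),

by maximising the Laplace-approximated marginal likelihood: for each group the
random-effect vector is profiled out with an inner Newton optimisation and the
integral is replaced by the Gaussian approximation at the conditional mode.
Random effects are assumed independent (diagonal covariance).  Wald standard
errors come from the numerically differentiated observed information at the
optimum.  Maximum-likelihood estimation, so variance components are not
REML-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = ["FitResult", "SeparationError", "fit_mixed_logit"]


class SeparationError(RuntimeError):
    """Raised when the response is (quasi-)completely separated."""


@dataclass
class FitResult:
    """Coefficient/SE/p container shared by all regression stages."""

    terms: list
    coef: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    random_terms: list
    random_sd: np.ndarray
    n_obs: int
    n_groups: int
    converged: bool
    loglik: float
    meta: dict = field(default_factory=dict)

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {"coef": self.coef[i], "se": self.se[i],
                "z": self.zvalues[i], "p": self.pvalues[i]}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms, "estimate": self.coef, "se": self.se,
            "stat": self.zvalues, "p": self.pvalues,
        })


def _loglik_terms(eta: np.ndarray, y: np.ndarray) -> float:
    # sum_j [y eta - log(1 + e^eta)], numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _inner_mode(u0, y, eta_fx, Zs, max_iter=60, tol=1e-9):
    """Newton ascent of the penalised conditional log-likelihood in u.

    ``Zs`` is the random design already scaled by sigma, so the penalty is the
    standard-normal one and the Hessian (Zs' W Zs + I) is always positive
    definite, including at sigma = 0.
    """
    q = Zs.shape[1]
    u = u0.copy()
    eta = eta_fx + Zs @ u
    obj = _loglik_terms(eta, y) - 0.5 * float(u @ u)
    for _ in range(max_iter):
        mu = special.expit(eta)
        grad = Zs.T @ (y - mu) - u
        if np.max(np.abs(grad)) < tol:
            break
        w = mu * (1.0 - mu)
        H = Zs.T @ (Zs * w[:, None]) + np.eye(q)
        step = np.linalg.solve(H, grad)
        # backtracking line search on the penalised objective
        t = 1.0
        for _ in range(30):
            u_new = u + t * step
            eta_new = eta_fx + Zs @ u_new
            obj_new = _loglik_terms(eta_new, y) - 0.5 * float(u_new @ u_new)
            if obj_new >= obj - 1e-12:
                break
            t *= 0.5
        u, eta, obj = u_new, eta_new, obj_new
    mu = special.expit(eta)
    w = mu * (1.0 - mu)
    H = Zs.T @ (Zs * w[:, None]) + np.eye(q)
    return u, obj, H


def _laplace_negloglik(theta, groups, p, q, warm):
    beta = theta[:p]
    sigma = np.abs(theta[p:])
    total = 0.0
    for key, (X, Z, y) in groups.items():
        eta_fx = X @ beta
        Zs = Z * sigma[None, :]
        u0 = warm.get(key, np.zeros(q))
        u, obj, H = _inner_mode(u0, y, eta_fx, Zs)
        warm[key] = u
        sign, logdet = np.linalg.slogdet(H)
        total += obj - 0.5 * logdet
    return -total


def _check_separation(y, groups) -> None:
    if y.min() == y.max():
        raise SeparationError("response is constant across all observations")
    constant_within = all(yg.min() == yg.max() for _, (_, _, yg) in groups.items())
    if constant_within:
        raise SeparationError(
            "response is constant within every group: the random intercept is "
            "completely separated")


def _numerical_hessian(f, theta, free, h=1e-4):
    k = len(theta)
    H = np.zeros((k, k))
    idx = [i for i in range(k) if free[i]]
    steps = h * (1.0 + np.abs(theta))
    f0 = f(theta)
    for a in idx:
        for b in idx:
            if b < a:
                continue
            ta = np.array(theta); tb = np.array(theta)
            tc = np.array(theta); td = np.array(theta)
            ta[a] += steps[a]; ta[b] += steps[b]
            tb[a] += steps[a]; tb[b] -= steps[b]
            tc[a] -= steps[a]; tc[b] += steps[b]
            td[a] -= steps[a]; td[b] -= steps[b]
            H[a, b] = (f(ta) - f(tb) - f(tc) + f(td)) / (4 * steps[a] * steps[b])
            H[b, a] = H[a, b]
    return H


def fit_mixed_logit(data: pd.DataFrame, response: str, fixed: list,
                    random: list, group: str = "subject",
                    init_sigma: float = 0.3) -> FitResult:
    """Fit the mixed logit; listwise-deletes rows with undefined covariates.

    ``fixed`` lists fixed-effect column names (an intercept is always
    included); ``random`` lists random-effect terms, using ``"1"`` for the
    random intercept.  Non-convergence is flagged on the result rather than
    raised; complete separation raises :class:`SeparationError`.
    """
    cols = [response] + [c for c in fixed] + [c for c in random if c != "1"]
    sub = data.dropna(subset=list(dict.fromkeys(cols)))
    if len(sub) == 0:
        raise ValueError("no complete observations to fit")
    y_all = sub[response].to_numpy(dtype=float)
    if not np.isin(y_all, [0.0, 1.0]).all():
        raise ValueError(f"response {response!r} must be binary 0/1")

    X_all = np.column_stack([np.ones(len(sub))]
                            + [sub[c].to_numpy(dtype=float) for c in fixed])
    Z_all = np.column_stack([np.ones(len(sub)) if t == "1"
                             else sub[t].to_numpy(dtype=float) for t in random])
    terms = ["intercept"] + list(fixed)
    p, q = X_all.shape[1], Z_all.shape[1]

    keys, inv = np.unique(sub[group].to_numpy(), return_inverse=True)
    groups = {k: (X_all[inv == i], Z_all[inv == i], y_all[inv == i])
              for i, k in enumerate(keys)}
    _check_separation(y_all, groups)

    # plain-logistic warm start for the fixed effects (a few IRLS steps)
    beta0 = np.zeros(p)
    for _ in range(15):
        eta = X_all @ beta0
        mu = special.expit(eta)
        w = np.clip(mu * (1 - mu), 1e-6, None)
        try:
            beta_new = np.linalg.solve(X_all.T @ (X_all * w[:, None]),
                                       X_all.T @ (w * eta + (y_all - mu)))
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(beta_new)):
            break
        if np.max(np.abs(beta_new - beta0)) < 1e-8:
            beta0 = beta_new
            break
        beta0 = np.clip(beta_new, -15, 15)

    warm: dict = {}
    theta0 = np.concatenate([beta0, np.full(q, init_sigma)])
    nll = lambda th: _laplace_negloglik(th, groups, p, q, warm)
    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B",
        bounds=[(None, None)] * p + [(0.0, None)] * q,
        options={"maxiter": 300, "ftol": 1e-10, "gtol": 1e-6})

    theta = res.x
    beta, sigma = theta[:p], theta[p:]
    if np.any(np.abs(beta) > 12):
        bad = terms[int(np.argmax(np.abs(beta)))]
        raise SeparationError(
            f"term {bad!r} appears completely separated (|coef| > 12)")

    # observed information; variance components at the zero boundary are
    # excluded from the inversion
    free = np.concatenate([np.ones(p, dtype=bool), sigma > 1e-4])
    H = _numerical_hessian(nll, theta, free)
    se = np.full(p + q, np.nan)
    idx = np.where(free)[0]
    try:
        cov = np.linalg.inv(H[np.ix_(idx, idx)])
        d = np.diag(cov)
        se[idx] = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        pass
    se_beta = se[:p]
    z = beta / se_beta
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    return FitResult(
        terms=terms, coef=beta, se=se_beta, zvalues=z, pvalues=pvals,
        random_terms=["intercept" if t == "1" else t for t in random],
        random_sd=np.abs(sigma),
        n_obs=len(sub), n_groups=len(keys),
        converged=bool(res.success), loglik=-float(res.fun))
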