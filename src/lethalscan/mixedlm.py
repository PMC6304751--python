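"""Sparse mixed-model engine for the litter-trait animal models.

Fits y = Xb + Zu_a + Wu_s + e with u_a ~ N(0, A sigma_a^2) over pedigree
animals (the service sires), u_s ~ N(0, I sigma_s^2) over sows and
e ~ N(0, I sigma_e^2), by restricted maximum likelihood on Henderson's
mixed-model equations.  The REML log-likelihood is evaluated from a single
sparse factorization of the MME coefficient matrix

    C = [X Z W]' R^-1 [X Z W] + blockdiag(0, A^-1/sa2, I/ss2)

using the identities log|V| = log|R| + log|G| + log|T| and
log|X'V^-1 X| = log|C| - log|T| (T cancels, only log|C| is needed), and is
maximized derivative-free (Nelder-Mead) over the log variance ratios with
the residual variance profiled out.  For Poisson responses the same
machinery runs inside a penalized quasi-likelihood loop with the working
weights as fixed residual precisions.

No installed library fits a general pedigree covariance, which is why this
engine exists; it is deliberately small: two random terms, dense A inverse
(study-scale pedigrees), sparse everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse
from scipy.sparse.linalg import splu
from scipy.stats import norm

VAR_FLOOR = 1e-8


@dataclass
class MixedModelFit:
    beta: np.ndarray            # fixed-effect solutions
    se: np.ndarray              # their standard errors
    u_a: np.ndarray             # BLUP of the additive effects
    u_s: np.ndarray             # BLUP of the sow effects
    sigma_a2: float
    sigma_s2: float
    sigma_e2: float
    loglik: float               # -2 * restricted log-likelihood (up to const)
    n_obs: int
    fixed_names: list[str] = field(default_factory=list)
    cov_beta: np.ndarray | None = None  # p x p covariance of the fixed effects

    def wald(self, name_or_index) -> tuple[float, float, float]:
        """(estimate, SE, two-sided Wald P) for one fixed effect."""
        j = (self.fixed_names.index(name_or_index)
             if isinstance(name_or_index, str) else int(name_or_index))
        est, se = float(self.beta[j]), float(self.se[j])
        if se <= 0 or not np.isfinite(se):
            return est, se, float("nan")
        z = est / se
        return est, se, float(2.0 * norm.sf(abs(z)))


class _MME:
    """Precomputed cross-product blocks; assembles/factorizes C per evaluation."""

    def __init__(self, y, X, Z, W, Ainv, weights=None):
        self.n, self.p = X.shape
        self.qa = Ainv.shape[0]
        self.qs = W.shape[1]
        w = np.ones(self.n) if weights is None else np.asarray(weights, dtype=float)
        self.w = w
        Xw = X * w[:, None]
        self.XtX = X.T @ Xw
        self.XtZ = sparse.csr_matrix(Xw.T) @ Z
        self.XtW = sparse.csr_matrix(Xw.T) @ W
        Zw = sparse.diags(w) @ Z
        self.ZtZ = (Z.T @ Zw).tocsc()
        self.ZtW = (Z.T @ (sparse.diags(w) @ W)).tocsc()
        self.WtW = (W.T @ (sparse.diags(w) @ W)).tocsc()
        self.Xty = Xw.T @ y
        self.Zty = Z.T @ (w * y)
        self.Wty = W.T @ (w * y)
        self.yty = float(y @ (w * y))
        self.Ainv = sparse.csc_matrix(Ainv)
        self.Z, self.W, self.X, self.y = Z, W, X, y

    def assemble(self, ga_inv_scale: float, gs_inv_scale: float, phi: float):
        """C for G^-1 = blkdiag(Ainv*ga_inv_scale, I*gs_inv_scale), R^-1 = diag(w)/phi."""
        Iqs = sparse.identity(self.qs, format="csc")
        C = sparse.bmat([
            [sparse.csc_matrix(self.XtX / phi), self.XtZ / phi, self.XtW / phi],
            [None, self.ZtZ / phi + self.Ainv * ga_inv_scale, self.ZtW / phi],
            [None, None, self.WtW / phi + Iqs * gs_inv_scale],
        ], format="csc")
        C = sparse.triu(C) + sparse.triu(C, k=1).T
        r = np.concatenate([self.Xty, self.Zty, self.Wty]) / phi
        return C.tocsc(), r

    def solve(self, ga_inv_scale, gs_inv_scale, phi):
        C, r = self.assemble(ga_inv_scale, gs_inv_scale, phi)
        lu = splu(C, permc_spec="MMD_AT_PLUS_A")
        theta = lu.solve(r)
        logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        return theta, logdet, lu, r


def _reml_neg2ll_profiled(mme: _MME, log_lambda: np.ndarray) -> tuple[float, float]:
    """-2 REML log-likelihood with sigma_e^2 profiled, at variance ratios lambda."""
    la, ls = np.exp(log_lambda)
    theta, logdetC_lam, _, r = mme.solve(1.0 / la, 1.0 / ls, 1.0)
    ypy = mme.yty - float(r @ theta)            # y'Py * sigma_e^2
    dof = mme.n - mme.p
    ypy = max(ypy, VAR_FLOOR * dof)
    sigma_e2 = ypy / dof
    val = (dof * np.log(sigma_e2) + mme.qa * np.log(la) + mme.qs * np.log(ls)
           + logdetC_lam)
    return val, sigma_e2


def _reml_neg2ll_fixed_resid(mme: _MME, log_sigma: np.ndarray) -> float:
    """-2 REML log-likelihood with R^-1 = diag(w) fixed (PQL working scale)."""
    sa2, ss2 = np.exp(log_sigma)
    theta, logdetC, _, r = mme.solve(1.0 / sa2, 1.0 / ss2, 1.0)
    ypy = mme.yty - float(r @ theta)
    return mme.qa * np.log(sa2) + mme.qs * np.log(ss2) + logdetC + ypy


def _cov_fixed(mme: _MME, ga_inv_scale, gs_inv_scale, phi, scale: float) -> np.ndarray:
    """Covariance of the fixed effects: leading p x p block of C^-1 * scale."""
    C, _ = mme.assemble(ga_inv_scale, gs_inv_scale, phi)
    lu = splu(C)
    cov = np.empty((mme.p, mme.p))
    for j in range(mme.p):
        e = np.zeros(C.shape[0])
        e[j] = 1.0
        cov[:, j] = lu.solve(e)[:mme.p]
    cov = 0.5 * (cov + cov.T) * scale
    return cov


def fit_lmm(y, X, Z, W, Ainv, fixed_names=None, start=None,
            maxiter: int = 200, tol: float = 1e-6,
            fix_lambda: tuple[float, float] | None = None) -> MixedModelFit:
    """REML fit of the Gaussian animal model.

    Parameters are dense ``X`` (n x p), sparse ``Z`` (n x q_a incidence onto
    pedigree animals), sparse ``W`` (n x q_s incidence onto sows), and dense
    ``Ainv`` (inverse of the additive relationship matrix).  ``fix_lambda``
    pins the variance ratios (sigma_a2/sigma_e2, sigma_s2/sigma_e2) instead
    of estimating them (e.g. near-zero ratios reduce the fit to OLS).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient (aliased levels)")
    mme = _MME(y, X, sparse.csr_matrix(Z), sparse.csr_matrix(W), Ainv)
    if fix_lambda is not None:
        ll = np.log(np.maximum(fix_lambda, 1e-12))
    else:
        x0 = np.log(start) if start is not None else np.log([0.1, 0.1])

        def obj(ll):
            ll = np.clip(ll, -13.0, 7.0)
            return _reml_neg2ll_profiled(mme, ll)[0]

        res = optimize.minimize(obj, x0, method="Nelder-Mead",
                                options={"xatol": 1e-3, "fatol": tol, "maxiter": maxiter,
                                         "maxfev": maxiter})
        ll = np.clip(res.x, -13.0, 7.0)
    val, sigma_e2 = _reml_neg2ll_profiled(mme, ll)
    la, ls = np.exp(ll)
    sigma_a2 = max(la * sigma_e2, VAR_FLOOR)
    sigma_s2 = max(ls * sigma_e2, VAR_FLOOR)
    theta, _, _, _ = mme.solve(1.0 / la, 1.0 / ls, 1.0)
    p, qa = mme.p, mme.qa
    cov = _cov_fixed(mme, 1.0 / la, 1.0 / ls, 1.0, sigma_e2)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return MixedModelFit(theta[:p], se, theta[p:p + qa], theta[p + qa:],
                         sigma_a2, sigma_s2, sigma_e2, val, mme.n,
                         list(fixed_names) if fixed_names is not None else
                         [f"x{j}" for j in range(p)], cov_beta=cov)


def fit_poisson_glmm(y, X, Z, W, Ainv, fixed_names=None,
                     max_outer: int = 50, tol: float = 1e-5) -> MixedModelFit:
    """Poisson log-link GLMM fit by penalized quasi-likelihood (PQL).

    Iterates working response z = eta + (y - mu)/mu with weights mu through
    the weighted MME; variance components are re-estimated on the working
    scale each outer iteration (approximate REML with the residual precision
    fixed at the weights).
    """
    y = np.asarray(y, dtype=float)
    if np.all(y == 0):
        raise ValueError("all counts are zero; Poisson model cannot be fit")
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient (aliased levels)")
    Z = sparse.csr_matrix(Z)
    W = sparse.csr_matrix(W)
    n, p = X.shape
    qa = Ainv.shape[0]
    eta = np.log(np.maximum(y, 0.1))
    log_sigma = np.log([0.05, 0.05])
    theta = None
    for outer in range(max_outer):
        mu = np.exp(np.clip(eta, -20, 20))
        w = np.maximum(mu, 1e-8)
        z = eta + (y - mu) / w
        mme = _MME(z, X, Z, W, Ainv, weights=w)

        def obj(ls, _mme=mme):
            ls = np.clip(ls, -13.0, 5.0)
            return _reml_neg2ll_fixed_resid(_mme, ls)

        # the variance surface barely moves between outer iterations: search
        # it at the first and third iteration, freeze it afterwards
        if outer in (0, 2):
            res = optimize.minimize(obj, log_sigma, method="Nelder-Mead",
                                    options={"xatol": 1e-3, "fatol": 1e-4,
                                             "maxfev": 80 if outer == 0 else 40})
            log_sigma = np.clip(res.x, -13.0, 5.0)
        sa2, ss2 = np.exp(log_sigma)
        theta, _, _, _ = mme.solve(1.0 / sa2, 1.0 / ss2, 1.0)
        eta_new = X @ theta[:p] + Z @ theta[p:p + qa] + W @ theta[p + qa:]
        if np.max(np.abs(eta_new - eta)) < tol:
            eta = eta_new
            break
        eta = eta_new
    mu = np.exp(np.clip(eta, -20, 20))
    mme = _MME(eta + (y - mu) / np.maximum(mu, 1e-8), X, Z, W, Ainv,
               weights=np.maximum(mu, 1e-8))
    sa2, ss2 = np.exp(log_sigma)
    cov = _cov_fixed(mme, 1.0 / sa2, 1.0 / ss2, 1.0, 1.0)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return MixedModelFit(theta[:p], se, theta[p:p + qa], theta[p + qa:],
                         float(sa2), float(ss2), 1.0, float("nan"), n,
                         list(fixed_names) if fixed_names is not None else
                         [f"x{j}" for j in range(p)], cov_beta=cov)
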