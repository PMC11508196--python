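"""Marginal maximum-likelihood estimation of the two-level model (DTTL).

The two-level simplification admits a Gaussian marginal likelihood (the
cross-classified variant does not: no ML estimator exists for freely loaded
cross-classified factor models).  Per target, the observed rater rows are
jointly normal with a between-level covariance shared across rows (trait +
object-method structure) and a within-level covariance per row (unique
method + residual structure); balanced construct-blocked designs reduce this
to the closed-form sufficient-statistic likelihood of :mod:`ccmtmm._twolevel`.

Optimization runs on an unconstrained reparameterization (log variances,
Cholesky factors for the trait and object-method covariance matrices) with
method-of-moments starting values, which keeps every iterate inside the
parameter space and makes boundary (Heywood) solutions show up as variances
driven toward zero rather than as failures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

from ._twolevel import (TwoLevelStats, compute_stats,
                        implied_moment_structure, per_target_loglik,
                        saturated_loglik, two_level_loglik)
from .exceptions import ConfigError, ConvergenceWarning
from .model_spec import (MTMMModelSpec, ParameterLayout, ParameterSet,
                         dttl_degrees_of_freedom)
from .ratings_data import ScoreTable

__all__ = ["MLFit", "SrmrInputs", "FitVerdict", "fit_ml", "fit_indices",
           "evaluate_fit"]

_BOUNDARY_VAR = 1e-8


# ---------------------------------------------------------------------------
# unconstrained parameter transform
# ---------------------------------------------------------------------------

def _n_theta(spec: MTMMModelSpec) -> int:
    p, J, m = spec.n_indicators, spec.n_constructs, len(spec.om_index)
    return p + 2 * m + J * (J + 1) // 2 + m * (m + 1) // 2 + J + p


def _chol_to_vec(L: np.ndarray) -> np.ndarray:
    out = []
    for a in range(L.shape[0]):
        for b in range(a + 1):
            out.append(np.log(max(L[a, a], 1e-12)) if a == b else L[a, b])
    return np.asarray(out)


def _vec_to_chol(vec: np.ndarray, dim: int) -> np.ndarray:
    L = np.zeros((dim, dim))
    pos = 0
    for a in range(dim):
        for b in range(a + 1):
            L[a, b] = np.exp(np.clip(vec[pos], -30, 30)) if a == b else vec[pos]
            pos += 1
    return L


def _theta_to_params(theta: np.ndarray, spec: MTMMModelSpec) -> ParameterSet:
    p, J, m = spec.n_indicators, spec.n_constructs, len(spec.om_index)
    pos = 0

    def take(n):
        nonlocal pos
        chunk = theta[pos:pos + n]
        pos += n
        return chunk

    mu_flat = take(p)
    lam_T_flat = take(m)
    lam_UM_flat = take(m)
    L_T = _vec_to_chol(take(J * (J + 1) // 2), J)
    L_OM = _vec_to_chol(take(m * (m + 1) // 2), m)
    var_UM = np.exp(np.clip(take(J), -30, 30))
    var_eps = np.exp(np.clip(take(p), -30, 30))

    mu, lam_T, lam_UM, veps = {}, {}, {}, {}
    ip = 0
    inr = 0
    for j in spec.constructs:
        nj = len(spec.indicators[j])
        mu[j] = mu_flat[ip:ip + nj].copy()
        veps[j] = var_eps[ip:ip + nj].copy()
        lam_T[j] = np.concatenate([[1.0], lam_T_flat[inr:inr + nj - 1]])
        lam_UM[j] = np.concatenate([[1.0], lam_UM_flat[inr:inr + nj - 1]])
        ip += nj
        inr += nj - 1
    return ParameterSet(spec, mu=mu, lam_T=lam_T, var_eps=veps,
                        Sigma_T=L_T @ L_T.T, Sigma_OM=L_OM @ L_OM.T,
                        lam_UM=lam_UM, var_UM=var_UM, validate=False)


def _params_to_theta(params: ParameterSet) -> np.ndarray:
    spec = params.spec
    out = []
    for j in spec.constructs:
        out.extend(params.mu[j])
    for j in spec.constructs:
        out.extend(params.lam_T[j][1:])
    for j in spec.constructs:
        out.extend(params.lam_UM[j][1:])
    out.extend(_chol_to_vec(np.linalg.cholesky(_nudge_pd(params.Sigma_T))))
    m = len(spec.om_index)
    if m:
        out.extend(_chol_to_vec(np.linalg.cholesky(_nudge_pd(params.Sigma_OM))))
    out.extend(np.log(np.clip(params.var_UM, 1e-8, None)))
    for j in spec.constructs:
        out.extend(np.log(np.clip(params.var_eps[j], 1e-8, None)))
    return np.asarray(out)


def _nudge_pd(mat: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    if mat.size == 0:
        return mat
    w, v = np.linalg.eigh((mat + mat.T) / 2)
    return v @ np.diag(np.clip(w, floor, None)) @ v.T


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def _start_values(stats: TwoLevelStats, spec: MTMMModelSpec) -> ParameterSet:
    """Method-of-moments starting values from level-wise sample covariances."""
    slices = stats.block_slices()
    mu = {}
    lam_UM = {}
    var_UM = np.zeros(spec.n_constructs)
    var_eps = {}
    D = np.zeros((stats.p, stats.p))
    for jx, j in enumerate(spec.constructs):
        s = slices[j]
        Sw = stats.S_W[j]
        nj = Sw.shape[0]
        mu[j] = stats.ybar[s].copy()
        if nj >= 3 and abs(Sw[1, 2]) > 1e-8:
            tetrad = Sw[0, 1] * Sw[0, 2] / Sw[1, 2]
        else:
            tetrad = np.nan
        off = Sw[np.triu_indices(nj, 1)]
        v0 = tetrad if np.isfinite(tetrad) and 1e-4 < tetrad < 2 * Sw[0, 0] \
            else max(float(np.mean(off)), 0.05)
        var_UM[jx] = v0
        lam = np.clip(Sw[0, :] / v0, -3.0, 3.0)
        lam[0] = 1.0
        lam_UM[j] = lam
        var_eps[j] = np.clip(np.diag(Sw) - lam**2 * v0, 0.05, None)
        D[s, s] = (lam[:, None] * lam[None, :] * v0 + np.diag(var_eps[j])) / stats.k[j]
    B = stats.Psi_hat - D
    refs = [slices[j].start for j in spec.constructs]
    J = spec.n_constructs
    Sigma_T = np.zeros((J, J))
    lam_T = {}
    for a, j in enumerate(spec.constructs):
        Sigma_T[a, a] = max(B[refs[a], refs[a]], 0.05)
    for a in range(J):
        for b in range(a + 1, J):
            cap = 0.95 * np.sqrt(Sigma_T[a, a] * Sigma_T[b, b])
            Sigma_T[a, b] = Sigma_T[b, a] = float(np.clip(B[refs[a], refs[b]], -cap, cap))
    for a, j in enumerate(spec.constructs):
        s = slices[j]
        lam = np.clip(B[refs[a], s] / Sigma_T[a, a], -3.0, 3.0)
        lam[0] = 1.0
        lam_T[j] = lam
    om = spec.om_index
    m = len(om)
    Sigma_OM = np.zeros((m, m))
    pos_of = {}
    pos = 0
    for j in spec.constructs:
        for i in spec.indicators[j]:
            pos_of[(j, i)] = pos
            pos += 1
    for a in range(m):
        ja, ia = om[a]
        pa = pos_of[(ja, ia)]
        for b in range(a, m):
            jb, ib = om[b]
            pb = pos_of[(jb, ib)]
            ax = spec.constructs.index(ja)
            bx = spec.constructs.index(jb)
            lam_a = lam_T[ja][spec.indicators[ja].index(ia)]
            lam_b = lam_T[jb][spec.indicators[jb].index(ib)]
            resid = B[pa, pb] - lam_a * lam_b * Sigma_T[ax, bx]
            Sigma_OM[a, b] = Sigma_OM[b, a] = resid
    Sigma_OM = _nudge_pd(Sigma_OM, floor=0.02)
    return ParameterSet(spec, mu=mu, lam_T=lam_T, var_eps=var_eps,
                        Sigma_T=_nudge_pd(Sigma_T, floor=0.02), Sigma_OM=Sigma_OM,
                        lam_UM=lam_UM, var_UM=var_UM, validate=False)


# ---------------------------------------------------------------------------
# fit result containers
# ---------------------------------------------------------------------------

@dataclass
class SrmrInputs:
    """Observed and model-implied level-wise covariance matrices."""

    observed_within: dict[str, np.ndarray]
    implied_within: dict[str, np.ndarray]
    observed_between: np.ndarray
    implied_between: np.ndarray


@dataclass
class MLFit:
    """Result of a two-level maximum-likelihood fit."""

    estimates: ParameterSet
    se: np.ndarray
    se_names: list[str]
    loglik: float
    loglik_saturated: float
    chi2: float
    df: int
    p_value: float
    rmsea: float
    srmr_within: float
    srmr_between: float
    converged: bool
    grad_norm: float
    n_targets: int
    n_rows: int
    n_iter: int
    message: str = ""
    robust_se: np.ndarray | None = None

    def se_table(self):
        import pandas as pd
        cols = {"estimate": ParameterLayout(self.estimates.spec).flatten(self.estimates),
                "se": self.se}
        if self.robust_se is not None:
            cols["robust_se"] = self.robust_se
        return pd.DataFrame(cols, index=self.se_names)


@dataclass
class FitVerdict:
    """Cut-off based labels for the fit statistics, with conflicts listed."""

    labels: dict[str, str]
    overall: str
    conflicts: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def fit_ml(scores: ScoreTable, spec: MTMMModelSpec, *, robust_se: bool = False,
           compute_se: bool = True, start: ParameterSet | None = None,
           maxiter: int = 5000) -> MLFit:
    """Fit the two-level model by marginal maximum likelihood.

    Point estimates and fit statistics are deterministic given the starting
    values (method-of-moments by default).  Standard errors come from the
    observed information (finite-difference Hessian in the natural
    parameterization); ``robust_se=True`` additionally computes the
    Huber-White cluster sandwich over targets.
    """
    if spec.variant != "dttl":
        raise ConfigError("maximum likelihood is defined for the dttl variant only")
    stats = compute_stats(scores, spec)
    theta0 = _params_to_theta(start if start is not None else _start_values(stats, spec))

    def negll(theta):
        try:
            params = _theta_to_params(theta, spec)
            mu, within, Psi = implied_moment_structure(spec, params, stats.k)
            val = -two_level_loglik(stats, mu, within, Psi)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    res = optimize.minimize(negll, theta0, method="L-BFGS-B", jac="3-point",
                            options=dict(maxiter=maxiter, maxfun=10 * maxiter,
                                         ftol=1e-13, gtol=1e-8))
    # one restart from the solution: L-BFGS memory resets, often polishes
    res2 = optimize.minimize(negll, res.x, method="L-BFGS-B", jac="3-point",
                             options=dict(maxiter=maxiter, maxfun=10 * maxiter,
                                          ftol=1e-14, gtol=1e-9))
    if res2.fun <= res.fun:
        res = res2
    theta_hat = res.x
    grad = optimize.approx_fprime(theta_hat, negll, 1e-6)
    grad_norm = float(np.linalg.norm(grad))
    converged = bool(res.success or grad_norm < 1e-3)
    if not converged:
        warnings.warn(f"ML optimizer did not converge: {res.message} "
                      f"(gradient norm {grad_norm:.3g})", ConvergenceWarning,
                      stacklevel=2)

    params = _theta_to_params(theta_hat, spec)
    boundary = np.concatenate([params.var_UM]
                              + [params.var_eps[j] for j in spec.constructs])
    if np.any(boundary < _BOUNDARY_VAR):
        warnings.warn("variance estimate at the zero boundary (Heywood path); "
                      "clamped at zero", ConvergenceWarning, stacklevel=2)
        params.var_UM = np.where(params.var_UM < _BOUNDARY_VAR, 0.0, params.var_UM)
        for j in spec.constructs:
            params.var_eps[j] = np.where(params.var_eps[j] < _BOUNDARY_VAR, 0.0,
                                         params.var_eps[j])

    mu, within, Psi = implied_moment_structure(spec, params, stats.k)
    loglik = two_level_loglik(stats, mu, within, Psi)
    ll_sat = saturated_loglik(stats)
    chi2 = max(2.0 * (ll_sat - loglik), 0.0)
    df = dttl_degrees_of_freedom(spec)

    slices = stats.block_slices()
    D = np.zeros((stats.p, stats.p))
    for j in spec.constructs:
        s = slices[j]
        D[s, s] = within[j] / stats.k[j]
    srmr_inputs = SrmrInputs(
        observed_within={j: stats.S_W[j] for j in spec.constructs},
        implied_within=within,
        observed_between=stats.Psi_hat - D,
        implied_between=Psi - D,
    )
    rmsea, srmr_w, srmr_b, p_value = fit_indices(chi2, df, stats.n_rows, srmr_inputs)

    layout = ParameterLayout(spec)
    se = (_observed_information_se(stats, spec, layout, params) if compute_se
          else np.full(len(layout.names), np.nan))
    rob = _sandwich_se(stats, spec, layout, params) if robust_se else None

    return MLFit(estimates=params, se=se, se_names=list(layout.names),
                 loglik=float(loglik), loglik_saturated=float(ll_sat),
                 chi2=float(chi2), df=int(df), p_value=float(p_value),
                 rmsea=float(rmsea), srmr_within=float(srmr_w),
                 srmr_between=float(srmr_b), converged=converged,
                 grad_norm=grad_norm, n_targets=stats.G, n_rows=stats.n_rows,
                 n_iter=int(res.nit), message=str(res.message),
                 robust_se=rob)


def fit_indices(chi2: float, df: int, n: int, srmr_inputs: SrmrInputs | None = None):
    """(RMSEA, SRMR within, SRMR between, chi-square p-value).

    ``RMSEA = sqrt(max(chi2 - df, 0) / (df * n))`` with ``n`` the total
    number of level-1 rows (0 when df = 0).  SRMR at each level is the root
    mean square of covariance residuals standardized by the observed
    standard deviations at that level, over all unique elements including
    the diagonal.
    """
    if df < 0:
        raise ConfigError("df must be >= 0")
    rmsea = 0.0 if df == 0 else float(np.sqrt(max(chi2 - df, 0.0) / (df * n)))
    p_value = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    srmr_w = srmr_b = float("nan")
    if srmr_inputs is not None:
        resid_sq, count = 0.0, 0
        for j, obs in srmr_inputs.observed_within.items():
            imp = srmr_inputs.implied_within[j]
            sd = np.sqrt(np.clip(np.diag(obs), 1e-12, None))
            std = (obs - imp) / np.outer(sd, sd)
            iu = np.triu_indices(obs.shape[0])
            resid_sq += float(np.sum(std[iu] ** 2))
            count += len(iu[0])
        srmr_w = float(np.sqrt(resid_sq / count))
        obs, imp = srmr_inputs.observed_between, srmr_inputs.implied_between
        sd = np.sqrt(np.clip(np.diag(obs), 1e-12, None))
        std = (obs - imp) / np.outer(sd, sd)
        iu = np.triu_indices(obs.shape[0])
        srmr_b = float(np.sqrt(np.mean(std[iu] ** 2)))
    return rmsea, srmr_w, srmr_b, p_value


def evaluate_fit(fit: MLFit, *, good: float = 0.05, acceptable: float = 0.08,
                 alpha: float = 0.05) -> FitVerdict:
    """Label each fit statistic against the conventional cut-offs.

    The exact-fit test rejects when its p-value is below ``alpha``; RMSEA
    and the SRMRs are good when <= 0.05 and acceptable when <= 0.08 (both
    inclusive).  Conflicting statistics are listed rather than averaged
    away -- a model can fail the exact-fit test while the SRMRs look good.
    """
    labels = {"chi2": "reject" if fit.p_value < alpha else "not rejected"}
    for name, val in (("rmsea", fit.rmsea), ("srmr_within", fit.srmr_within),
                      ("srmr_between", fit.srmr_between)):
        if np.isnan(val):
            labels[name] = "unavailable"
        elif val <= good:
            labels[name] = "good"
        elif val <= acceptable:
            labels[name] = "acceptable"
        else:
            labels[name] = "reject"
    votes = [v for v in labels.values() if v != "unavailable"]
    rejects = [k for k, v in labels.items() if v == "reject"]
    supports = [k for k, v in labels.items()
                if v in ("good", "acceptable", "not rejected")]
    if rejects and supports:
        overall = "conflicting"
        conflicts = [f"{r} rejects while {s} supports the model"
                     for r in rejects for s in supports
                     if labels[s] in ("good", "acceptable")]
    elif rejects:
        overall, conflicts = "reject", []
    elif all(v in ("good", "not rejected") for v in votes):
        overall, conflicts = "good", []
    else:
        overall, conflicts = "acceptable", []
    return FitVerdict(labels=labels, overall=overall, conflicts=conflicts)


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------

def _natural_loglik_fn(stats, spec, layout):
    def fn(vec):
        params = layout.unflatten(vec, validate=False)
        try:
            mu, within, Psi = implied_moment_structure(spec, params, stats.k)
            return two_level_loglik(stats, mu, within, Psi)
        except np.linalg.LinAlgError:
            return -1e12
    return fn


def _fd_hessian(fn, x, rel_step=1e-4):
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.zeros((n, n))
    f0 = fn(x)
    for a in range(n):
        ea = np.zeros(n); ea[a] = h[a]
        H[a, a] = (fn(x + ea) - 2 * f0 + fn(x - ea)) / h[a] ** 2
        for b in range(a + 1, n):
            eb = np.zeros(n); eb[b] = h[b]
            H[a, b] = H[b, a] = (fn(x + ea + eb) - fn(x + ea - eb)
                                 - fn(x - ea + eb) + fn(x - ea - eb)) / (4 * h[a] * h[b])
    return H


def _observed_information_se(stats, spec, layout, params):
    fn = _natural_loglik_fn(stats, spec, layout)
    x = layout.flatten(params)
    H = _fd_hessian(fn, x)
    info = -H
    try:
        cov = np.linalg.inv(info)
        d = np.diag(cov).copy()
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        d = np.diag(cov).copy()
    bad = d <= 0
    if bad.any():
        warnings.warn("observed information not positive definite for "
                      f"{int(bad.sum())} parameter(s); their SEs are NaN",
                      ConvergenceWarning, stacklevel=3)
    d[bad] = np.nan
    return np.sqrt(d)


def _sandwich_se(stats, spec, layout, params):
    """Huber-White cluster-robust sandwich over targets."""
    x = layout.flatten(params)
    n = len(x)
    h = 1e-5 * np.maximum(1.0, np.abs(x))

    def per_target(vec):
        ps = layout.unflatten(vec, validate=False)
        mu, within, Psi = implied_moment_structure(spec, ps, stats.k)
        return per_target_loglik(stats, mu, within, Psi)

    scores_mat = np.zeros((stats.G, n))
    for a in range(n):
        ea = np.zeros(n); ea[a] = h[a]
        scores_mat[:, a] = (per_target(x + ea) - per_target(x - ea)) / (2 * h[a])
    B = scores_mat.T @ scores_mat
    fn = _natural_loglik_fn(stats, spec, layout)
    A = -_fd_hessian(fn, x)
    Ainv = np.linalg.pinv(A)
    cov = Ainv @ B @ Ainv
    d = np.diag(cov).copy()
    d[d <= 0] = np.nan
    return np.sqrt(d)
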