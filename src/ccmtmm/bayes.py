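"""Gibbs sampling for the cross-classified and two-level rating models.

All full conditionals are conjugate: latent effects are (multivariate)
normal, intercepts and loadings are normal, scalar variances are
inverse-gamma, and the trait and object-method covariance matrices are
inverse-Wishart.  One sweep updates, in order, the joint target-level block
(traits and object-method effects, drawn jointly per target), rater effects,
interaction / unique-method effects, the location parameters per indicator
(intercept plus free loadings, drawn jointly), residual variances, the
scalar method variances, and the two covariance matrices.

Convergence is monitored with the Gelman-Rubin potential scale reduction
(PSR) factor over all model parameters (never over latent effects, whose
number grows with the data).  In auto mode the sampler doubles its total
length and re-checks until the maximum PSR drops below the threshold; in
fixed mode it runs a preset number of iterations.  The first
``burn_in_fraction`` of each chain is discarded, so the PSR is computed
from the retained second halves.

Model fit is assessed with posterior predictive checking: for a subsample
of retained draws, a likelihood-ratio chi-square discrepancy between the
data's level-wise moments and the draw's implied moments is compared with
the same discrepancy for a replicated dataset simulated from the draw
(see :mod:`ccmtmm._twolevel` for the exact functional).
"""

from __future__ import annotations

import types
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.stats import invwishart

from ._twolevel import chi2_discrepancy, compute_stats
from .exceptions import ConfigError, ConvergenceWarning, DesignError
from .model_spec import MTMMModelSpec, ParameterLayout, ParameterSet
from .ratings_data import ScoreTable
from .simulate import SimulationConfig, simulate_ratings

__all__ = ["PriorSpec", "McmcConfig", "PosteriorDraws", "BppcResult",
           "fit_bayes", "compute_psr", "bppc"]


@dataclass
class PriorSpec:
    """Weakly informative default priors, all overridable.

    Intercepts and loadings: normal(0, ``loc_var``).  Scalar variances:
    inverse-gamma(``ig_shape``, ``ig_scale``), nearly flat by default.
    Covariance matrices of dimension d: inverse-Wishart with prior degrees
    of freedom ``iw_df0`` (None means the flat improper choice ``-(d+1)``,
    the default of mainstream Bayesian SEM software) and scale
    ``iw_scale_diag * I``.  A proper identity-scale prior
    (``iw_df0 = d + 1``, ``iw_scale_diag = 1``) is only weakly informative
    when the latent variances are near 1; for rating data with small or
    near-singular covariance blocks it dominates the smallest eigen
    directions, so the flat choice is the default.  The flat prior needs
    more targets than twice the block dimension to give a proper posterior.
    """

    loc_var: float = 1e6
    ig_shape: float = 0.001
    ig_scale: float = 0.001
    iw_df0: float | None = None
    iw_scale_diag: float = 0.0

    def iw_prior_df(self, dim: int) -> float:
        return -(dim + 1) if self.iw_df0 is None else self.iw_df0


@dataclass
class McmcConfig:
    """Sampler settings.

    ``mode="auto"`` doubles the chain length until the maximum PSR over all
    parameters falls below ``psr_threshold`` (checked from ``check_interval``
    iterations on) or ``max_iterations`` is reached; ``mode="fixed"`` runs
    exactly ``fixed_iterations``.  ``fix`` maps parameter names (layout
    names such as ``"var_T[c1]"``) to values held constant -- the remaining
    parameters are then sampled from their full conditionals given the
    fixed ones.
    """

    n_chains: int = 3
    mode: str = "auto"
    psr_threshold: float = 1.1
    check_interval: int = 100
    max_iterations: int = 20000
    fixed_iterations: int = 2000
    burn_in_fraction: float = 0.5
    seed: int = 0
    priors: PriorSpec = field(default_factory=PriorSpec)
    store_latent: bool = False
    fix: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "fixed"):
            raise ConfigError("mode must be 'auto' or 'fixed'")
        if self.mode == "auto" and self.n_chains < 2:
            raise ConfigError("auto (PSR) mode needs >= 2 chains")
        if not 0.0 < self.burn_in_fraction < 1.0:
            raise ConfigError("burn_in_fraction must be in (0, 1)")


@dataclass
class PosteriorDraws:
    """Post burn-in parameter draws from all chains, plus diagnostics."""

    chains: np.ndarray              # (n_chains, n_kept, n_params)
    names: list[str]
    spec: MTMMModelSpec
    psr: np.ndarray
    max_psr: float
    n_iterations_run: int
    converged: bool
    seed: int
    latent_T: np.ndarray | None = None   # (n_chains, n_kept_latent, G, J)
    latent_OM: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.chains.shape[0] * self.chains.shape[1]

    def stacked(self) -> np.ndarray:
        return self.chains.reshape(-1, self.chains.shape[-1])

    def extract(self, name: str) -> np.ndarray:
        return self.stacked()[:, self.names.index(name)]

    def posterior_mean_params(self) -> ParameterSet:
        layout = ParameterLayout(self.spec)
        return layout.unflatten(self.stacked().mean(axis=0), validate=False)

    def parameter_sets(self, thin: int = 1):
        layout = ParameterLayout(self.spec)
        for row in self.stacked()[::thin]:
            yield layout.unflatten(row, validate=False)

    def summary(self) -> pd.DataFrame:
        flat = self.stacked()
        return pd.DataFrame({
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "cri_2.5%": np.percentile(flat, 2.5, axis=0),
            "cri_97.5%": np.percentile(flat, 97.5, axis=0),
            "psr": self.psr,
        }, index=self.names)


@dataclass
class BppcResult:
    """Posterior predictive check via observed-vs-replicated chi-square."""

    mean_delta_chi2: float
    ci_low: float
    ci_high: float
    ppp: float
    n_replications: int
    delta_chi2: np.ndarray = field(repr=False, default=None)

    @property
    def maintained(self) -> bool:
        return (self.ci_low <= 0.0 <= self.ci_high) and self.ppp > 0.05


# ---------------------------------------------------------------------------
# PSR
# ---------------------------------------------------------------------------

def compute_psr(chains) -> np.ndarray:
    """Gelman-Rubin potential scale reduction per parameter.

    ``chains`` has shape (n_chains, n_iter) or (n_chains, n_iter, n_params).
    PSR = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B/n the variance of the chain means.  All-constant, equal
    chains give 1; constant but unequal chains give +inf.
    """
    arr = np.asarray(chains, float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    c, n, _ = arr.shape
    if c < 2:
        raise ConfigError("PSR needs at least 2 chains")
    if n < 4:
        raise ConfigError("PSR needs at least 4 retained iterations per chain")
    w = arr.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = arr.mean(axis=1).var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        psr = np.sqrt(((n - 1) / n * w + b_over_n) / w)
    zero_w = w <= 0
    psr[zero_w & (b_over_n <= 0)] = 1.0
    psr[zero_w & (b_over_n > 0)] = np.inf
    return float(psr[0]) if squeeze else psr


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _prepare_data(scores: ScoreTable, spec: MTMMModelSpec):
    """Per-construct complete (raters, targets, indicators) arrays."""
    data = {}
    raters = {}
    seen: dict[str, str] = {}
    for j in spec.constructs:
        if j not in scores.constructs:
            raise DesignError(f"construct {j!r} not in score table")
        rs, _, arr = scores.construct_array(j)
        order = [scores.indicators(j).index(i) for i in spec.indicators[j]]
        arr = arr[:, :, order]
        if np.isnan(arr).any():
            raise DesignError(
                f"construct {j!r} has missing cells within its rater block; the "
                "Gibbs sampler requires complete construct-blocked data"
            )
        for r in rs:
            if r in seen:
                raise DesignError(
                    f"rater {r!r} scores both {seen[r]!r} and {j!r}; estimation "
                    "here requires single-construct raters -- drop the rater "
                    "from one construct (as is common practice) or orthogonalize"
                )
            seen[r] = j
        data[j] = np.ascontiguousarray(arr)
        raters[j] = rs
    return data, raters


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _GibbsSampler:
    def __init__(self, spec: MTMMModelSpec, data: dict, priors: PriorSpec,
                 rng: np.random.Generator, overdispersion: float = 0.0):
        self.spec = spec
        self.data = data
        self.pri = priors
        self.rng = rng
        self.J = spec.n_constructs
        self.M = len(spec.om_index)
        self.G = next(iter(data.values())).shape[1]
        self.dtcc = spec.variant == "dtcc"
        self.layout = ParameterLayout(spec)
        # OM slot bookkeeping: slot index per (construct, indicator position)
        self.om_slot = {}
        for j in spec.constructs:
            slots = [spec.om_index.index((j, i)) if (j, i) in spec.om_index else -1
                     for i in spec.indicators[j]]
            self.om_slot[j] = np.asarray(slots)
        self._init_state(overdispersion)

    # -- initialization ---------------------------------------------------
    def _init_state(self, od: float) -> None:
        rng, spec = self.rng, self.spec
        G, J, M = self.G, self.J, self.M
        self.T = np.zeros((G, J))
        self.OM = np.zeros((G, M))
        self.R = {}
        self.INT = {}
        self.mu, self.lamT, self.lamR, self.lamM, self.veps = {}, {}, {}, {}, {}
        trait_init = np.zeros((G, J))
        for jx, j in enumerate(spec.constructs):
            Y = self.data[j]                      # (k, G, I)
            cell_mean = Y.mean(axis=(0, 1))
            self.mu[j] = cell_mean + od * 0.1 * rng.standard_normal(Y.shape[2])
            n_ind = Y.shape[2]
            self.lamT[j] = np.ones(n_ind)
            self.lamM[j] = np.ones(n_ind)
            if self.dtcc:
                self.lamR[j] = np.ones(n_ind)
            if od:
                for lam in (self.lamT[j], self.lamM[j]) + ((self.lamR[j],) if self.dtcc else ()):
                    lam[1:] += od * 0.1 * rng.standard_normal(n_ind - 1)
            v = Y.var(axis=(0, 1), ddof=1)
            self.veps[j] = 0.5 * v * np.exp(od * 0.2 * rng.standard_normal(n_ind))
            ref_target_mean = Y[:, :, 0].mean(axis=0)
            trait_init[:, jx] = ref_target_mean - ref_target_mean.mean()
            rater_dev = Y[:, :, 0].mean(axis=1) - Y[:, :, 0].mean()
            kj = Y.shape[0]
            self.R[j] = rater_dev.copy() if self.dtcc else None
            self.INT[j] = np.zeros((kj, G))
        self.T = trait_init
        St = np.cov(trait_init.T, ddof=1).reshape(J, J) + 0.1 * np.eye(J)
        self.Sigma_T = St * np.exp(od * 0.2 * self.rng.standard_normal())
        self.Sigma_OM = 0.3 * np.eye(M) if M else np.zeros((0, 0))
        self.var_R = np.full(J, 0.1) if self.dtcc else None
        self.var_M = np.full(J, 0.2)
        if od:
            self.var_M = self.var_M * np.exp(od * 0.3 * rng.standard_normal(J))
            if self.dtcc:
                self.var_R = self.var_R * np.exp(od * 0.3 * rng.standard_normal(J))

    # -- helpers ----------------------------------------------------------
    def _target_part(self, j: str) -> np.ndarray:
        """mu + lam_T*T + OM for construct j, shape (G, I_j)."""
        jx = self.spec.constructs.index(j)
        out = self.mu[j][None, :] + np.outer(self.T[:, jx], self.lamT[j])
        slots = self.om_slot[j]
        nz = slots >= 0
        if nz.any():
            out[:, nz] += self.OM[:, slots[nz]]
        return out

    def _rater_part(self, j: str) -> np.ndarray:
        """lam_R*R + lam_M*INT for construct j, shape (k, G, I_j)."""
        out = self.INT[j][:, :, None] * self.lamM[j][None, None, :]
        if self.dtcc:
            out = out + self.R[j][:, None, None] * self.lamR[j][None, None, :]
        return out

    # -- sweep ------------------------------------------------------------
    def step(self) -> np.ndarray:
        self._update_target_block()
        if self.dtcc:
            self._update_rater_effects()
        self._update_interaction_effects()
        self._update_locations()
        if self.dtcc:
            # extra joint (intercepts, rater effects) block: with few raters
            # the rater mean and the intercepts are strongly coupled, and
            # alternating scalar updates mix very slowly through that ridge
            self._update_mu_rater_joint()
        self._update_variances()
        return self.flat_params()

    def _update_mu_rater_joint(self) -> None:
        rng = self.rng
        tau0 = self.pri.loc_var
        for jx, j in enumerate(self.spec.constructs):
            Y = self.data[j]
            kj, G, n_ind = Y.shape
            jxc = self.spec.constructs.index(j)
            target = np.outer(self.T[:, jxc], self.lamT[j])
            slots = self.om_slot[j]
            nz = slots >= 0
            if nz.any():
                target[:, nz] += self.OM[:, slots[nz]]
            resid = (Y - target[None, :, :]
                     - self.INT[j][:, :, None] * self.lamM[j][None, None, :])
            ve = self.veps[j]
            lamR = self.lamR[j]
            dim = n_ind + kj
            P = np.zeros((dim, dim))
            P[:n_ind, :n_ind] = np.diag(kj * G / ve) + np.eye(n_ind) / tau0
            cross = G * lamR / ve                      # same for every rater
            P[:n_ind, n_ind:] = np.tile(cross[:, None], (1, kj))
            P[n_ind:, :n_ind] = P[:n_ind, n_ind:].T
            P[n_ind:, n_ind:] = np.eye(kj) * (G * float(lamR @ (lamR / ve))
                                              + 1.0 / self.var_R[jx])
            rhs = np.concatenate([
                resid.sum(axis=(0, 1)) / ve,
                np.einsum("rti,i->r", resid, lamR / ve),
            ])
            mean = np.linalg.solve(P, rhs)
            L = np.linalg.cholesky(P)
            draw = mean + solve_triangular(L, rng.standard_normal(dim),
                                           lower=True, trans="T")
            self.mu[j] = draw[:n_ind]
            self.R[j] = draw[n_ind:]

    def _update_target_block(self) -> None:
        spec, rng = self.spec, self.rng
        q = self.J + self.M
        P = np.zeros((q, q))
        P[:self.J, :self.J] = np.linalg.inv(self.Sigma_T)
        if self.M:
            P[self.J:, self.J:] = np.linalg.inv(self.Sigma_OM)
        rhs = np.zeros((self.G, q))
        for jx, j in enumerate(spec.constructs):
            Y = self.data[j]
            kj, _, n_ind = Y.shape
            A = np.zeros((n_ind, q))
            A[:, jx] = self.lamT[j]
            slots = self.om_slot[j]
            for ix in range(n_ind):
                if slots[ix] >= 0:
                    A[ix, self.J + slots[ix]] = 1.0
            Ainv_eps = A / self.veps[j][:, None]
            P += kj * A.T @ Ainv_eps
            resid = Y - self.mu[j][None, None, :] - self._rater_part(j)
            rhs += resid.sum(axis=0) @ Ainv_eps
        mean = np.linalg.solve(P, rhs.T).T
        L = np.linalg.cholesky(P)
        z = rng.standard_normal((q, self.G))
        draw = mean + solve_triangular(L, z, lower=True, trans="T").T
        self.T = draw[:, :self.J]
        self.OM = draw[:, self.J:]

    def _update_rater_effects(self) -> None:
        rng = self.rng
        for jx, j in enumerate(self.spec.constructs):
            Y = self.data[j]
            kj = Y.shape[0]
            d = (Y - self._target_part(j)[None, :, :]
                 - self.INT[j][:, :, None] * self.lamM[j][None, None, :])
            w = self.lamR[j] / self.veps[j]
            prec = 1.0 / self.var_R[jx] + self.G * float(self.lamR[j] @ w)
            mean = np.einsum("rti,i->r", d, w) / prec
            self.R[j] = mean + rng.standard_normal(kj) / np.sqrt(prec)

    def _update_interaction_effects(self) -> None:
        rng = self.rng
        for jx, j in enumerate(self.spec.constructs):
            Y = self.data[j]
            kj = Y.shape[0]
            c = Y - self._target_part(j)[None, :, :]
            if self.dtcc:
                c = c - self.R[j][:, None, None] * self.lamR[j][None, None, :]
            w = self.lamM[j] / self.veps[j]
            prec = 1.0 / self.var_M[jx] + float(self.lamM[j] @ w)
            mean = np.einsum("rti,i->rt", c, w) / prec
            self.INT[j] = mean + rng.standard_normal((kj, self.G)) / np.sqrt(prec)

    def _update_locations(self) -> None:
        rng = self.rng
        tau0 = self.pri.loc_var
        for jx, j in enumerate(self.spec.constructs):
            Y = self.data[j]
            kj, G, n_ind = Y.shape
            n = kj * G
            T_b = np.broadcast_to(self.T[:, jx], (kj, G)).ravel()
            INT_b = self.INT[j].ravel()
            if self.dtcc:
                R_b = np.broadcast_to(self.R[j][:, None], (kj, G)).ravel()
            slots = self.om_slot[j]
            for ix in range(n_ind):
                y = Y[:, :, ix].ravel().copy()
                if slots[ix] >= 0:
                    y -= np.broadcast_to(self.OM[:, slots[ix]], (kj, G)).ravel()
                ve = self.veps[j][ix]
                if ix == 0:
                    # reference indicator: loadings fixed to 1, intercept only
                    offset = T_b + INT_b + (R_b if self.dtcc else 0.0)
                    z = y - offset
                    prec = n / ve + 1.0 / tau0
                    mean = z.sum() / ve / prec
                    self.mu[j][ix] = mean + rng.standard_normal() / np.sqrt(prec)
                    continue
                cols = [np.ones(n), T_b] + ([R_b] if self.dtcc else []) + [INT_b]
                X = np.column_stack(cols)
                Vinv = X.T @ X / ve + np.eye(X.shape[1]) / tau0
                mean = np.linalg.solve(Vinv, X.T @ y / ve)
                Lv = np.linalg.cholesky(Vinv)
                draw = mean + solve_triangular(
                    Lv, rng.standard_normal(X.shape[1]), lower=True, trans="T")
                self.mu[j][ix] = draw[0]
                self.lamT[j][ix] = draw[1]
                if self.dtcc:
                    self.lamR[j][ix] = draw[2]
                    self.lamM[j][ix] = draw[3]
                else:
                    self.lamM[j][ix] = draw[2]

    def _update_variances(self) -> None:
        rng, pri = self.rng, self.pri
        # residual variances
        for jx, j in enumerate(self.spec.constructs):
            Y = self.data[j]
            kj, G, n_ind = Y.shape
            resid = Y - self._target_part(j)[None, :, :] - self._rater_part(j)
            ss = np.einsum("rti,rti->i", resid, resid)
            a_post = pri.ig_shape + 0.5 * kj * G
            b_post = pri.ig_scale + 0.5 * ss
            self.veps[j] = b_post / rng.gamma(a_post, 1.0, size=n_ind)
            # scalar method variances
            if self.dtcc:
                a_r = pri.ig_shape + 0.5 * kj
                b_r = pri.ig_scale + 0.5 * float(self.R[j] @ self.R[j])
                self.var_R[jx] = b_r / rng.gamma(a_r, 1.0)
            a_m = pri.ig_shape + 0.5 * kj * G
            b_m = pri.ig_scale + 0.5 * float(np.sum(self.INT[j] ** 2))
            self.var_M[jx] = b_m / rng.gamma(a_m, 1.0)
        # covariance matrices
        df_t = pri.iw_prior_df(self.J) + self.G
        scale_t = pri.iw_scale_diag * np.eye(self.J) + self.T.T @ self.T
        self.Sigma_T = np.atleast_2d(
            invwishart.rvs(df=df_t, scale=scale_t, random_state=rng))
        if self.M:
            df_om = pri.iw_prior_df(self.M) + self.G
            scale_om = pri.iw_scale_diag * np.eye(self.M) + self.OM.T @ self.OM
            self.Sigma_OM = np.atleast_2d(
                invwishart.rvs(df=df_om, scale=scale_om, random_state=rng))

    # -- parameter vector -------------------------------------------------
    def flat_params(self) -> np.ndarray:
        ns = types.SimpleNamespace(
            mu=self.mu, lam_T=self.lamT, var_eps=self.veps,
            Sigma_T=self.Sigma_T, Sigma_OM=self.Sigma_OM,
            lam_R=self.lamR if self.dtcc else None,
            lam_INT=self.lamM if self.dtcc else None,
            lam_UM=None if self.dtcc else self.lamM,
            var_R=self.var_R, var_INT=self.var_M if self.dtcc else None,
            var_UM=None if self.dtcc else self.var_M,
            cov_R={}, cov_INT={},
        )
        return self.layout.flatten(ns)

    def apply_fixes(self, idx: np.ndarray, values: np.ndarray) -> None:
        flat = self.flat_params()
        flat[idx] = values
        ps = self.layout.unflatten(flat, validate=False)
        for j in self.spec.constructs:
            self.mu[j] = ps.mu[j]
            self.lamT[j] = ps.lam_T[j]
            self.veps[j] = ps.var_eps[j]
            if self.dtcc:
                self.lamR[j] = ps.lam_R[j]
                self.lamM[j] = ps.lam_INT[j]
            else:
                self.lamM[j] = ps.lam_UM[j]
        self.Sigma_T = ps.Sigma_T
        self.Sigma_OM = ps.Sigma_OM
        if self.dtcc:
            self.var_R = ps.var_R
            self.var_M = ps.var_INT
        else:
            self.var_M = ps.var_UM


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_bayes(scores: ScoreTable, spec: MTMMModelSpec,
              config: McmcConfig | None = None) -> PosteriorDraws:
    """Sample the posterior of a DTCC or DTTL model by Gibbs sampling."""
    config = config or McmcConfig()
    data, _raters = _prepare_data(scores, spec)
    layout = ParameterLayout(spec)
    fix_idx = np.asarray([layout.names.index(k) for k in config.fix], int)
    fix_val = np.asarray(list(config.fix.values()), float)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    samplers = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        s = _GibbsSampler(spec, data, config.priors, rng,
                          overdispersion=1.0 if c else 0.0)
        if len(fix_idx):
            s.apply_fixes(fix_idx, fix_val)
        samplers.append(s)

    traces = [[] for _ in samplers]
    latent_T = [[] for _ in samplers] if config.store_latent else None
    latent_OM = [[] for _ in samplers] if config.store_latent else None

    def advance(n_more: int) -> None:
        for c, s in enumerate(samplers):
            for _ in range(n_more):
                vec = s.step()
                if len(fix_idx):
                    s.apply_fixes(fix_idx, fix_val)
                    vec = s.flat_params()
                traces[c].append(vec)
                if config.store_latent:
                    latent_T[c].append(s.T.copy())
                    latent_OM[c].append(s.OM.copy())

    def retained_array(n_total: int) -> np.ndarray:
        burn = int(np.floor(config.burn_in_fraction * n_total))
        return np.stack([np.asarray(t[burn:n_total]) for t in traces])

    if config.mode == "fixed":
        advance(config.fixed_iterations)
        n_total = config.fixed_iterations
        kept = retained_array(n_total)
        psr = (compute_psr(kept) if config.n_chains >= 2 and kept.shape[1] >= 4
               else np.full(len(layout.names), np.nan))
        max_psr = float(np.nanmax(psr)) if np.ndim(psr) else float(psr)
        converged = bool(max_psr < config.psr_threshold) if np.isfinite(max_psr) else False
    else:
        n_total = 0
        converged = False
        psr = np.full(len(layout.names), np.nan)
        checkpoint = config.check_interval
        while True:
            advance(checkpoint - n_total)
            n_total = checkpoint
            kept = retained_array(n_total)
            if kept.shape[1] >= 4:
                psr = compute_psr(kept)
                max_psr = float(np.max(psr))
                if max_psr < config.psr_threshold:
                    converged = True
                    break
            if n_total >= config.max_iterations:
                break
            checkpoint = min(2 * checkpoint, config.max_iterations)
        kept = retained_array(n_total)
        max_psr = float(np.max(psr)) if np.all(np.isfinite(psr)) else float("inf")
        if not converged:
            warnings.warn(
                f"Gibbs sampler not converged after {n_total} iterations "
                f"(max PSR = {max_psr:.3f} >= {config.psr_threshold}); "
                "draws returned flagged not-converged",
                ConvergenceWarning, stacklevel=2)

    burn = int(np.floor(config.burn_in_fraction * n_total))
    lat_T = lat_OM = None
    if config.store_latent:
        lat_T = np.stack([np.asarray(x[burn:n_total]) for x in latent_T])
        lat_OM = np.stack([np.asarray(x[burn:n_total]) for x in latent_OM])
    psr = np.asarray(psr, float)
    max_psr = float(np.max(psr)) if psr.size and np.all(np.isfinite(psr)) else float("nan")
    return PosteriorDraws(chains=kept, names=list(layout.names), spec=spec,
                          psr=psr, max_psr=max_psr,
                          n_iterations_run=n_total, converged=converged,
                          seed=config.seed, latent_T=lat_T, latent_OM=lat_OM)


# ---------------------------------------------------------------------------
# posterior predictive checking
# ---------------------------------------------------------------------------

def bppc(scores: ScoreTable, spec: MTMMModelSpec, draws: PosteriorDraws,
         n_replications: int = 500, seed: int | None = None) -> BppcResult:
    """Posterior predictive model check with a chi-square discrepancy.

    For each sampled draw the likelihood-ratio discrepancy of the observed
    data is compared with the discrepancy of a replicated dataset of
    identical design simulated from that draw; the posterior predictive
    p-value is the fraction of replications whose discrepancy is at least
    the observed one.
    """
    if draws.n_draws < 100:
        warnings.warn(f"only {draws.n_draws} retained draws; posterior "
                      "predictive summaries will be noisy", ConvergenceWarning,
                      stacklevel=2)
    stats_obs = compute_stats(scores, spec)
    raters = {j: scores.raters_for(j) for j in spec.constructs}
    layout = ParameterLayout(spec)
    flat = draws.stacked()
    n_rep = min(n_replications, flat.shape[0])
    idx = np.linspace(0, flat.shape[0] - 1, n_rep).astype(int)
    rng_seed = np.random.SeedSequence(draws.seed if seed is None else seed)
    child_seeds = rng_seed.spawn(n_rep)

    obs = np.empty(n_rep)
    rep = np.empty(n_rep)
    for k, (row, child) in enumerate(zip(flat[idx], child_seeds)):
        params = layout.unflatten(row, validate=False)
        obs[k] = chi2_discrepancy(stats_obs, spec, params)
        sim_cfg = SimulationConfig(
            spec=spec, params=params, n_targets=stats_obs.G, raters=raters,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        rep_scores, _ = simulate_ratings(sim_cfg)
        stats_rep = compute_stats(rep_scores, spec)
        rep[k] = chi2_discrepancy(stats_rep, spec, params)

    delta = obs - rep
    lo, hi = np.percentile(delta, [2.5, 97.5])
    return BppcResult(mean_delta_chi2=float(delta.mean()), ci_low=float(lo),
                      ci_high=float(hi), ppp=float(np.mean(rep >= obs)),
                      n_replications=n_rep, delta_chi2=delta)
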