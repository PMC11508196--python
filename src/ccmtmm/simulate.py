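"""Generate cross-classified rating data from a ParameterSet.

The generator is the exact sampling mirror of the model equations: target
traits and object-method effects are drawn jointly multivariate normal at
the target level, rater effects (cross-classified variant) per rater,
interaction / unique-method effects per rater-target pair, residuals per
cell, and the construct-blocked missingness pattern is applied according to
the rater assignment.  Ratings are continuous Gaussian by default; an
optional Likert discretization (round and clamp to a k-point scale) is
available as a robustness device only.

``model_implied_moments`` returns the mean vector and the level-wise
covariance blocks implied by a ParameterSet; it serves as the simulator's
oracle and as the moment engine for the two-level likelihood machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .model_spec import LatentEffects, MTMMModelSpec, ParameterSet
from .ratings_data import ScoreTable

__all__ = ["SimulationConfig", "ModelMoments", "simulate_ratings", "model_implied_moments"]


@dataclass
class SimulationConfig:
    """Design and generating parameters for one simulated dataset.

    ``raters`` maps construct -> list of rater ids (a rater id appearing
    under several constructs is a shared rater and induces estimable
    cross-construct rater covariances).  ``likert`` rounds and clamps scores
    to an integer scale with that many points (None keeps them continuous).
    """

    spec: MTMMModelSpec
    params: ParameterSet
    n_targets: int
    raters: dict[str, list[str]]
    seed: int = 0
    likert: int | None = None
    scale: tuple[float, float] = (1.0, 5.0)
    target_ids: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ConfigError("n_targets must be >= 1")
        if set(self.raters) != set(self.spec.constructs):
            raise ConfigError("raters must map every construct of the spec")
        if self.params.spec.variant != self.spec.variant:
            raise ConfigError("params variant does not match spec variant")


def _chol(mat: np.ndarray, name: str) -> np.ndarray:
    """Cholesky-like factor tolerating semidefinite matrices."""
    mat = np.atleast_2d(np.asarray(mat, float))
    if mat.size == 0:
        return mat
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh((mat + mat.T) / 2)
        if w.min() < -1e-8 * max(1.0, abs(w).max()):
            raise ConfigError(f"{name} is not positive semidefinite") from None
        return v * np.sqrt(np.clip(w, 0.0, None))


def _rater_level_cov(params: ParameterSet) -> np.ndarray:
    """J x J rater-effect covariance (diag variances + estimable covariances)."""
    spec = params.spec
    mat = np.diag(params.var_R)
    for (a, b), v in params.cov_R.items():
        ia, ib = spec.constructs.index(a), spec.constructs.index(b)
        mat[ia, ib] = mat[ib, ia] = v
    return mat


def _int_level_cov(params: ParameterSet) -> np.ndarray:
    spec = params.spec
    if spec.variant == "dttl":
        return np.diag(params.var_UM)
    mat = np.diag(params.var_INT)
    for (a, b), v in params.cov_INT.items():
        ia, ib = spec.constructs.index(a), spec.constructs.index(b)
        mat[ia, ib] = mat[ib, ia] = v
    return mat


def simulate_ratings(config: SimulationConfig) -> tuple[ScoreTable, LatentEffects]:
    """Draw one dataset; returns the score table and its latent effects.

    The latent effects are returned for recovery diagnostics only and are
    never consumed by the estimators.
    """
    spec, params = config.spec, config.params
    rng = np.random.default_rng(config.seed)
    G = config.n_targets
    J = spec.n_constructs
    M = len(spec.om_index)
    targets = (list(config.target_ids) if config.target_ids is not None
               else [f"t{k + 1}" for k in range(G)])
    if len(targets) != G:
        raise ConfigError("target_ids length must equal n_targets")

    L_T = _chol(params.Sigma_T, "Sigma_T")
    L_OM = _chol(params.Sigma_OM, "Sigma_OM")
    T = rng.standard_normal((G, J)) @ L_T.T
    OM = rng.standard_normal((G, M)) @ L_OM.T if M else np.zeros((G, 0))

    all_raters = list(dict.fromkeys(r for j in spec.constructs for r in config.raters[j]))
    assignment = {r: [j for j in spec.constructs if r in config.raters[j]]
                  for r in all_raters}

    # rater effects (cross-classified variant only), correlated across the
    # constructs a shared rater scores
    R_by_rater: dict[str, dict[str, float]] = {r: {} for r in all_raters}
    if spec.variant == "dtcc":
        Sigma_R = _rater_level_cov(params)
        for r in all_raters:
            idx = [spec.constructs.index(j) for j in assignment[r]]
            sub = Sigma_R[np.ix_(idx, idx)]
            draw = _chol(sub, "rater-effect covariance") @ rng.standard_normal(len(idx))
            for j, val in zip(assignment[r], draw):
                R_by_rater[r][j] = float(val)

    # interaction / unique-method effects per rater-target pair
    Sigma_I = _int_level_cov(params)
    INT_by_rater: dict[str, dict[str, np.ndarray]] = {}
    for r in all_raters:
        idx = [spec.constructs.index(j) for j in assignment[r]]
        sub = Sigma_I[np.ix_(idx, idx)]
        draws = rng.standard_normal((G, len(idx))) @ _chol(sub, "interaction covariance").T
        INT_by_rater[r] = {j: draws[:, k] for k, j in enumerate(assignment[r])}

    # assemble observed scores; columns ordered construct-major, reference first
    columns = pd.MultiIndex.from_tuples(
        [(j, i) for j in spec.constructs for i in spec.indicators[j]],
        names=["construct", "indicator"])
    index = pd.MultiIndex.from_product([targets, all_raters], names=["target", "rater"])
    table = np.full((len(index), len(columns)), np.nan)

    col_pos = {key: k for k, key in enumerate(columns)}
    row_pos = {(t, r): k for k, (t, r) in enumerate(index)}
    om_pos = {key: k for k, key in enumerate(spec.om_index)}

    for j in spec.constructs:
        jx = spec.constructs.index(j)
        inds = spec.indicators[j]
        lam_T = params.lam_T[j]
        lam_M = params.lam_INT[j] if spec.variant == "dtcc" else params.lam_UM[j]
        lam_R = params.lam_R[j] if spec.variant == "dtcc" else None
        mu = params.mu[j]
        sd_eps = np.sqrt(params.var_eps[j])
        for r in config.raters[j]:
            base = mu[None, :] + np.outer(T[:, jx], lam_T)
            for ix, i in enumerate(inds):
                if (j, i) in om_pos:
                    base[:, ix] += OM[:, om_pos[(j, i)]]
            if spec.variant == "dtcc":
                base += R_by_rater[r][j] * lam_R[None, :]
            base += np.outer(INT_by_rater[r][j], lam_M)
            base += rng.standard_normal((G, len(inds))) * sd_eps[None, :]
            rows = [row_pos[(t, r)] for t in targets]
            cols = [col_pos[(j, i)] for i in inds]
            table[np.ix_(rows, cols)] = base

    if config.likert is not None:
        lo, hi = config.scale
        table = np.clip(np.round(table), lo, hi)

    scores = ScoreTable(pd.DataFrame(table, index=index, columns=columns),
                        scale=config.scale)
    effects = LatentEffects(
        targets=targets,
        raters={j: list(config.raters[j]) for j in spec.constructs},
        T=T,
        OM=OM,
        R=({j: np.array([R_by_rater[r][j] for r in config.raters[j]])
            for j in spec.constructs} if spec.variant == "dtcc" else None),
        INT=({j: np.stack([INT_by_rater[r][j] for r in config.raters[j]])
              for j in spec.constructs} if spec.variant == "dtcc" else None),
        UM=({j: np.stack([INT_by_rater[r][j] for r in config.raters[j]])
             for j in spec.constructs} if spec.variant == "dttl" else None),
    )
    return scores, effects


@dataclass
class ModelMoments:
    """Mean vector and level-wise covariance blocks over all indicators.

    All matrices are indexed by ``spec.indicator_index`` order.  The total
    per-row covariance of a rating by a randomly drawn rater is
    ``Sigma_target + Sigma_rater + Sigma_interaction + Sigma_eps``.
    """

    index: list[tuple[str, str]]
    mu: np.ndarray
    Sigma_target: np.ndarray
    Sigma_rater: np.ndarray
    Sigma_interaction: np.ndarray
    Sigma_eps: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return (self.Sigma_target + self.Sigma_rater
                + self.Sigma_interaction + self.Sigma_eps)

    def total_variance(self, construct: str, indicator: str) -> float:
        k = self.index.index((construct, indicator))
        return float(self.total[k, k])


def model_implied_moments(spec: MTMMModelSpec, params: ParameterSet) -> ModelMoments:
    """Moments implied by the model equations, by classification level."""
    idx = spec.indicator_index
    p = len(idx)
    J = spec.n_constructs
    M = len(spec.om_index)

    Lam_T = np.zeros((p, J))
    C_OM = np.zeros((p, M))
    mu = np.zeros(p)
    for k, (j, i) in enumerate(idx):
        jx = spec.constructs.index(j)
        ix = spec.indicators[j].index(i)
        Lam_T[k, jx] = params.lam_T[j][ix]
        mu[k] = params.mu[j][ix]
        if (j, i) in spec.om_index:
            C_OM[k, spec.om_index.index((j, i))] = 1.0
    Sigma_target = Lam_T @ params.Sigma_T @ Lam_T.T
    if M:
        Sigma_target = Sigma_target + C_OM @ params.Sigma_OM @ C_OM.T

    Lam_M = np.zeros((p, J))
    for k, (j, i) in enumerate(idx):
        jx = spec.constructs.index(j)
        ix = spec.indicators[j].index(i)
        lam = (params.lam_INT[j] if spec.variant == "dtcc" else params.lam_UM[j])
        Lam_M[k, jx] = lam[ix]
    Sigma_interaction = Lam_M @ _int_level_cov(params) @ Lam_M.T

    if spec.variant == "dtcc":
        Lam_R = np.zeros((p, J))
        for k, (j, i) in enumerate(idx):
            jx = spec.constructs.index(j)
            ix = spec.indicators[j].index(i)
            Lam_R[k, jx] = params.lam_R[j][ix]
        Sigma_rater = Lam_R @ _rater_level_cov(params) @ Lam_R.T
    else:
        Sigma_rater = np.zeros((p, p))

    Sigma_eps = np.diag(np.concatenate([params.var_eps[j] for j in spec.constructs]))
    return ModelMoments(index=idx, mu=mu, Sigma_target=Sigma_target,
                        Sigma_rater=Sigma_rater, Sigma_interaction=Sigma_interaction,
                        Sigma_eps=Sigma_eps)
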