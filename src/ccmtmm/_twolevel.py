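"""Two-level sufficient statistics, Gaussian likelihood and chi-square discrepancy.

For balanced construct-blocked designs (every rater of a construct scores
every target on all of that construct's indicators) the marginal Gaussian
likelihood of the two-level model factors exactly into

  * a within part per construct: the pooled within-target scatter of the
    rater rows is Wishart with ``G * (k_j - 1)`` degrees of freedom and the
    within-level (rater-row) covariance ``Sigma_W_j``; and
  * a between part: the vector of per-target rater means over all ``p``
    indicators is iid normal with mean ``mu`` and covariance
    ``Psi = Sigma_B + blockdiag(Sigma_W_j / k_j)``.

Both parts depend on the data only through the sufficient statistics
computed here, so the likelihood, its saturated supremum and the
likelihood-ratio chi-square discrepancy are all closed-form.

For the cross-classified variant the same functional is used as a *moment
discrepancy* for posterior predictive checking: the within matrices then
include the rater-effect contribution (rater disagreement shows up in the
within-target scatter), while the between matrices exclude it (rater means
are shared by all targets and cancel from between-target deviations).
Observed and replicated datasets are always scored by the same functional,
which is what posterior predictive calibration requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError
from .model_spec import MTMMModelSpec, ParameterSet
from .ratings_data import ScoreTable
from .simulate import model_implied_moments

__all__ = ["TwoLevelStats", "compute_stats", "implied_moment_structure",
           "two_level_loglik", "saturated_loglik", "chi2_discrepancy"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class TwoLevelStats:
    """Sufficient statistics of a balanced construct-blocked score table."""

    constructs: list[str]
    indicators: dict[str, list[str]]
    G: int                           # number of targets
    k: dict[str, int]                # raters per construct
    S_W: dict[str, np.ndarray]       # pooled within covariance per construct
    W_t: dict[str, np.ndarray]       # per-target within scatter (G, p_j, p_j)
    ybar_t: np.ndarray               # per-target rater means, (G, p)
    ybar: np.ndarray                 # grand mean vector, (p,)
    Psi_hat: np.ndarray              # ML covariance of target means, (p, p)
    n_rows: int                      # total observed rater-target rows

    @property
    def p(self) -> int:
        return sum(len(v) for v in self.indicators.values())

    def block_slices(self) -> dict[str, slice]:
        out, pos = {}, 0
        for j in self.constructs:
            out[j] = slice(pos, pos + len(self.indicators[j]))
            pos += len(self.indicators[j])
        return out


def compute_stats(scores: ScoreTable, spec: MTMMModelSpec) -> TwoLevelStats:
    """Compute the sufficient statistics; requires a balanced design.

    Every rater of a construct must have scored all targets on all of the
    construct's indicators (the missing-by-design pattern of the study
    layout); rows with genuine missingness should be completed or dropped
    upstream.
    """
    targets = scores.targets
    G = len(targets)
    k: dict[str, int] = {}
    S_W: dict[str, np.ndarray] = {}
    W_t: dict[str, np.ndarray] = {}
    means = []
    n_rows = 0
    for j in spec.constructs:
        if j not in scores.constructs:
            raise DataError(f"construct {j!r} not present in the score table")
        raters, _, arr = scores.construct_array(j)
        # align indicator order with the spec
        order = [scores.indicators(j).index(i) for i in spec.indicators[j]]
        arr = arr[:, :, order]
        if np.isnan(arr).any():
            raise DataError(
                f"construct {j!r}: unbalanced or missing cells; the two-level "
                "statistics require every rater of a construct to score every "
                "target on all of its indicators"
            )
        kj = arr.shape[0]
        if kj < 2:
            raise DataError(f"construct {j!r} needs >=2 raters, got {kj}")
        k[j] = kj
        n_rows += kj * G
        m_t = arr.mean(axis=0)                       # (G, p_j)
        dev = arr - m_t[None, :, :]                  # (k, G, p_j)
        scatter = np.einsum("kgi,kgl->gil", dev, dev)  # (G, p_j, p_j)
        W_t[j] = scatter
        S_W[j] = scatter.sum(axis=0) / (G * (kj - 1))
        means.append(m_t)
    ybar_t = np.concatenate(means, axis=1)           # (G, p)
    ybar = ybar_t.mean(axis=0)
    dev = ybar_t - ybar[None, :]
    Psi_hat = dev.T @ dev / G                        # ML divisor
    return TwoLevelStats(constructs=list(spec.constructs),
                         indicators={j: list(spec.indicators[j]) for j in spec.constructs},
                         G=G, k=k, S_W=S_W, W_t=W_t, ybar_t=ybar_t, ybar=ybar,
                         Psi_hat=Psi_hat, n_rows=n_rows)


def implied_moment_structure(spec: MTMMModelSpec, params: ParameterSet,
                             k: dict[str, int]):
    """Model-implied (mu, within blocks, Psi) for the two-level functional.

    Within blocks carry rater + interaction/unique-method + residual
    variance; Psi carries target-level variance plus the interaction and
    residual contribution of averaging over ``k_j`` raters.  Rater effects
    never enter Psi (they are shared across targets).
    """
    mom = model_implied_moments(spec, params)
    slices = {}
    pos = 0
    for j in spec.constructs:
        slices[j] = slice(pos, pos + len(spec.indicators[j]))
        pos += len(spec.indicators[j])
    within = {}
    Psi = mom.Sigma_target.copy()
    for j in spec.constructs:
        s = slices[j]
        w_no_rater = mom.Sigma_interaction[s, s] + mom.Sigma_eps[s, s]
        within[j] = w_no_rater + mom.Sigma_rater[s, s]
        Psi[s, s] += w_no_rater / k[j]
    return mom.mu, within, Psi


def _logdet_and_inv(mat: np.ndarray):
    sign, logdet = np.linalg.slogdet(mat)
    if sign <= 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    return logdet, np.linalg.inv(mat)


def two_level_loglik(stats: TwoLevelStats, mu: np.ndarray,
                     within: dict[str, np.ndarray], Psi: np.ndarray) -> float:
    """Exact Gaussian log-likelihood of a balanced two-level dataset."""
    ll = 0.0
    for j in stats.constructs:
        pj = len(stats.indicators[j])
        n_w = stats.G * (stats.k[j] - 1)
        logdet, inv = _logdet_and_inv(within[j])
        ll -= 0.5 * n_w * (logdet + float(np.sum(inv * stats.S_W[j])) + pj * _LOG2PI)
    p = stats.p
    d = stats.ybar - mu
    logdet, inv = _logdet_and_inv(Psi)
    quad = float(np.sum(inv * stats.Psi_hat)) + float(d @ inv @ d)
    ll -= 0.5 * stats.G * (logdet + quad + p * _LOG2PI)
    return ll


def per_target_loglik(stats: TwoLevelStats, mu: np.ndarray,
                      within: dict[str, np.ndarray], Psi: np.ndarray) -> np.ndarray:
    """Per-target contributions to the two-level log-likelihood (sums to total)."""
    G = stats.G
    out = np.zeros(G)
    for j in stats.constructs:
        pj = len(stats.indicators[j])
        kj = stats.k[j]
        logdet, inv = _logdet_and_inv(within[j])
        quad = np.einsum("gil,il->g", stats.W_t[j], inv)
        out -= 0.5 * ((kj - 1) * (logdet + pj * _LOG2PI) + quad)
    logdet, inv = _logdet_and_inv(Psi)
    d = stats.ybar_t - mu[None, :]
    quad = np.einsum("gi,il,gl->g", d, inv, d)
    out -= 0.5 * (logdet + stats.p * _LOG2PI + quad)
    return out


def saturated_loglik(stats: TwoLevelStats) -> float:
    """Supremum of the two-level likelihood over unrestricted moments.

    Closed form for balanced designs: the within suprema are attained at
    the pooled within matrices, the between supremum at the ML covariance
    of the target means.  Within-level covariances across construct blocks
    are not identified under construct-blocked missingness and do not
    affect the supremum.
    """
    ll = 0.0
    for j in stats.constructs:
        pj = len(stats.indicators[j])
        n_w = stats.G * (stats.k[j] - 1)
        sign, logdet = np.linalg.slogdet(stats.S_W[j])
        if sign <= 0:
            raise DataError(f"singular pooled within matrix for construct {j!r}")
        ll -= 0.5 * n_w * (logdet + pj + pj * _LOG2PI)
    sign, logdet = np.linalg.slogdet(stats.Psi_hat)
    if sign <= 0:
        raise DataError("singular between-level covariance of target means")
    ll -= 0.5 * stats.G * (logdet + stats.p + stats.p * _LOG2PI)
    return ll


def chi2_discrepancy(stats: TwoLevelStats, spec: MTMMModelSpec,
                     params: ParameterSet) -> float:
    """Likelihood-ratio chi-square between data moments and implied moments."""
    mu, within, Psi = implied_moment_structure(spec, params, stats.k)
    return 2.0 * (saturated_loglik(stats)
                  - two_level_loglik(stats, mu, within, Psi))
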