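"""True-score variance decomposition and relative variance coefficients.

Because all latent variables within an observed rating are orthogonal, the
variance of each indicator splits exactly into target (trait), rater,
interaction (or unique-method), object-method and residual components.  On
top of the absolute components this module computes the full relative
coefficient suite:

* ``MIICC`` -- model-implied intraclass correlation: the share of true-score
  variance attributable to targets (trait variance, plus object-method
  variance for non-reference indicators).  ``MIICC = 1 - UMS``.
* ``RMS`` / ``IMS`` / ``UMS`` -- rater, interaction and unique-method
  specificity: true-score variance shares of the rater-related effects.
  In the two-level simplification rater effects are absorbed into the
  unique-method effect, so ``RMS = 0`` and ``IMS = UMS``.
* ``L2Con`` / ``L2OMS`` -- target-level consistency vs object-method
  specificity of a non-reference indicator (they sum to 1).
* ``L1Con`` / ``L1OMS`` -- the same two components relative to the total
  true-score variance.
* ``REL`` -- reliability: true-score variance over total variance.

Coefficients can be evaluated plug-in (at a point estimate) or per
posterior draw with credibility intervals.  The posterior mean of a ratio
is generally not the ratio of posterior means, which is why both reporting
modes are first-class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConvergenceWarning
from .model_spec import MTMMModelSpec, ParameterLayout, ParameterSet

__all__ = ["VarianceDecomposition", "DecompositionSummary", "COEFFICIENTS",
           "decompose", "decompose_posterior", "correlations"]

COEFFICIENTS = ["sigma2_total", "sigma2_true", "miicc", "rms", "ims", "ums",
                "l2con", "l2oms", "l1con", "l1oms", "rel"]


@dataclass
class VarianceDecomposition:
    """Absolute components and relative coefficients per indicator.

    ``table`` has one row per coefficient and one (construct, indicator)
    column; entries undefined for an indicator (level-2 coefficients of
    reference indicators, or anything with zero true-score variance) are
    NaN and the affected indicators are listed in ``flagged``.
    """

    table: pd.DataFrame
    components: pd.DataFrame          # absolute variance components
    variant: str
    flagged: list[tuple[str, str]] = field(default_factory=list)

    def coefficient(self, name: str, construct: str, indicator: str) -> float:
        return float(self.table.loc[name, (construct, indicator)])

    def rounded(self, decimals: int = 3) -> pd.DataFrame:
        """Report table rounded half-even (full precision stays in ``table``)."""
        return self.table.round(decimals)


@dataclass
class DecompositionSummary:
    """Posterior summary (mean and central 95% interval) per coefficient."""

    mean: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    mode: str = "per-draw"

    def coefficient(self, name: str, construct: str, indicator: str):
        key = (construct, indicator)
        return (float(self.mean.loc[name, key]),
                float(self.ci_low.loc[name, key]),
                float(self.ci_high.loc[name, key]))


def _components(params: ParameterSet, construct: str, indicator: str):
    """Absolute variance components (target, rater, interaction, OM, residual)."""
    spec = params.spec
    jx = spec.constructs.index(construct)
    ix = spec.indicators[construct].index(indicator)
    lam_t = params.lam_T[construct][ix]
    a = lam_t**2 * params.Sigma_T[jx, jx]
    d = params.om_variance(construct, indicator)
    if spec.variant == "dtcc":
        b = params.lam_R[construct][ix] ** 2 * params.var_R[jx]
        c = params.lam_INT[construct][ix] ** 2 * params.var_INT[jx]
    else:
        b = 0.0
        c = params.lam_UM[construct][ix] ** 2 * params.var_UM[jx]
    e = params.var_eps[construct][ix]
    return a, b, c, d, e


def decompose(params: ParameterSet,
              spec: MTMMModelSpec | None = None) -> VarianceDecomposition:
    """Closed-form plug-in decomposition of a ParameterSet.

    For two-level (dttl) parameter sets the unique-method effect plays the
    interaction role with no rater level, so rater specificity is
    identically 0 and interaction specificity equals unique-method
    specificity.
    """
    spec = spec or params.spec
    cols = pd.MultiIndex.from_tuples(spec.indicator_index,
                                     names=["construct", "indicator"])
    table = pd.DataFrame(np.nan, index=COEFFICIENTS, columns=cols)
    comp = pd.DataFrame(np.nan, index=["target", "rater", "interaction",
                                       "object_method", "residual"], columns=cols)
    flagged = []
    for j, i in spec.indicator_index:
        a, b, c, d, e = _components(params, j, i)
        comp[(j, i)] = [a, b, c, d, e]
        tau = a + b + c + d
        total = tau + e
        col = {"sigma2_total": total, "sigma2_true": tau}
        if tau <= 0:
            flagged.append((j, i))
            table[(j, i)] = pd.Series(col).reindex(COEFFICIENTS)
            continue
        col["miicc"] = (a + d) / tau
        col["rms"] = b / tau
        col["ims"] = c / tau
        col["ums"] = (b + c) / tau
        col["rel"] = tau / total if total > 0 else np.nan
        is_reference = (i == spec.reference(j))
        if not is_reference:
            col["l2con"] = a / (a + d) if a + d > 0 else np.nan
            col["l2oms"] = d / (a + d) if a + d > 0 else np.nan
            col["l1con"] = a / tau
            col["l1oms"] = d / tau
        table[(j, i)] = pd.Series(col).reindex(COEFFICIENTS)
    return VarianceDecomposition(table=table, components=comp,
                                 variant=spec.variant, flagged=flagged)


def _per_draw_tables(flat: np.ndarray, spec: MTMMModelSpec) -> np.ndarray:
    """Vectorized per-draw coefficient tables, shape (draws, coef, indicator).

    Mirrors :func:`decompose` exactly (the scalar path is the reference; the
    two are cross-checked in the test suite on degenerate draws).
    """
    layout = ParameterLayout(spec)
    name_ix = {n: k for k, n in enumerate(layout.names)}
    n = flat.shape[0]
    ones = np.ones(n)
    out = np.full((n, len(COEFFICIENTS), spec.n_indicators), np.nan)
    row = {name: k for k, name in enumerate(COEFFICIENTS)}
    for col, (j, i) in enumerate(spec.indicator_index):
        is_ref = i == spec.reference(j)
        lam_t = ones if is_ref else flat[:, name_ix[f"lam_T[{j}.{i}]"]]
        a = lam_t**2 * flat[:, name_ix[f"var_T[{j}]"]]
        d = np.zeros(n) if is_ref else flat[:, name_ix[f"var_OM[{j}.{i}]"]]
        if spec.variant == "dtcc":
            lam_r = ones if is_ref else flat[:, name_ix[f"lam_R[{j}.{i}]"]]
            lam_m = ones if is_ref else flat[:, name_ix[f"lam_INT[{j}.{i}]"]]
            b = lam_r**2 * flat[:, name_ix[f"var_R[{j}]"]]
            c = lam_m**2 * flat[:, name_ix[f"var_INT[{j}]"]]
        else:
            lam_m = ones if is_ref else flat[:, name_ix[f"lam_UM[{j}.{i}]"]]
            b = np.zeros(n)
            c = lam_m**2 * flat[:, name_ix[f"var_UM[{j}]"]]
        e = flat[:, name_ix[f"var_eps[{j}.{i}]"]]
        tau = a + b + c + d
        total = tau + e
        with np.errstate(divide="ignore", invalid="ignore"):
            valid = tau > 0
            tau_safe = np.where(valid, tau, np.nan)
            out[:, row["sigma2_total"], col] = total
            out[:, row["sigma2_true"], col] = tau
            out[:, row["miicc"], col] = (a + d) / tau_safe
            out[:, row["rms"], col] = b / tau_safe
            out[:, row["ims"], col] = c / tau_safe
            out[:, row["ums"], col] = (b + c) / tau_safe
            out[:, row["rel"], col] = np.where(total > 0, tau / total, np.nan)
            if not is_ref:
                ad = np.where(a + d > 0, a + d, np.nan)
                out[:, row["l2con"], col] = a / ad
                out[:, row["l2oms"], col] = d / ad
                out[:, row["l1con"], col] = a / tau_safe
                out[:, row["l1oms"], col] = d / tau_safe
    return out


def decompose_posterior(draws, spec: MTMMModelSpec | None = None,
                        thin: int = 1) -> DecompositionSummary:
    """Per-draw decomposition with posterior means and 95% credibility bounds."""
    spec = spec or draws.spec
    flat = draws.stacked()[::thin]
    if flat.shape[0] < 100:
        warnings.warn(f"only {flat.shape[0]} draws for the posterior "
                      "decomposition; intervals will be noisy",
                      ConvergenceWarning, stacklevel=2)
    arr = _per_draw_tables(flat, spec)         # (draws, coef, indicator)
    cols = pd.MultiIndex.from_tuples(spec.indicator_index,
                                     names=["construct", "indicator"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        mean = pd.DataFrame(np.nanmean(arr, axis=0), index=COEFFICIENTS, columns=cols)
        lo = pd.DataFrame(np.nanpercentile(arr, 2.5, axis=0),
                          index=COEFFICIENTS, columns=cols)
        hi = pd.DataFrame(np.nanpercentile(arr, 97.5, axis=0),
                          index=COEFFICIENTS, columns=cols)
    return DecompositionSummary(mean=mean, ci_low=lo, ci_high=hi, mode="per-draw")


def correlations(params: ParameterSet):
    """Trait and object-method correlation matrices (NaN for zero variances)."""
    spec = params.spec

    def corr(mat, labels):
        v = np.diag(mat).copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.sqrt(np.outer(v, v))
            r = np.where(denom > 0, mat / denom, np.nan)
        return pd.DataFrame(r, index=labels, columns=labels)

    trait = corr(params.Sigma_T, spec.constructs)
    om_labels = [f"{j}.{i}" for j, i in spec.om_index]
    om = corr(params.Sigma_OM, om_labels) if len(om_labels) else pd.DataFrame()
    return trait, om
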