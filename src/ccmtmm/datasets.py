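"""Reference designs and published parameter estimates for worked examples.

The estimates below come from an empirical divergent-thinking study in which
202 targets answered three alternate-uses tasks (objects: rope, garbage bag,
paperclip; rope is the reference indicator) and disjoint panels of
interchangeable raters scored the idea sets for two constructs, cleverness
(4 raters) and creative quality (3 raters), on a 1-5 scale.  Three model
fits are available: the cross-classified model estimated by Gibbs sampling
("dtcc"), and the two-level simplification estimated by Gibbs sampling
("dttl-b") and by full-information maximum likelihood ("dttl-ml").

These parameter sets serve as generating values for simulation studies and
as inputs for the worked variance-decomposition examples.
"""

from __future__ import annotations

import numpy as np

from .model_spec import MTMMModelSpec, ParameterSet

__all__ = [
    "CONSTRUCTS",
    "INDICATORS",
    "STUDY_RATERS",
    "N_TARGETS",
    "aut_study_spec",
    "aut_study_estimates",
]

CONSTRUCTS = ["cleverness", "creative_quality"]
INDICATORS = ["rope", "garbage_bag", "paperclip"]

#: Rater panels of the study design (disjoint across constructs).
STUDY_RATERS = {
    "cleverness": ["r1", "r3", "r4", "r5"],
    "creative_quality": ["r2", "r6", "r7"],
}

N_TARGETS = 202


def aut_study_spec(variant: str) -> MTMMModelSpec:
    """Model spec for the 2-construct x 3-indicator study design (disjoint raters)."""
    return MTMMModelSpec(
        variant=variant,
        constructs=list(CONSTRUCTS),
        indicators={j: list(INDICATORS) for j in CONSTRUCTS},
        rater_cov_estimable={(CONSTRUCTS[0], CONSTRUCTS[1]): False},
    )


def _sym(var: list[float], cov: list[float]) -> np.ndarray:
    """Symmetric matrix from variances and row-major upper off-diagonals."""
    m = len(var)
    out = np.diag(np.asarray(var, float))
    it = iter(cov)
    for a in range(m):
        for b in range(a + 1, m):
            out[a, b] = out[b, a] = next(it)
    return out


_ESTIMATES = {
    "dtcc": dict(
        mu={"cleverness": [2.993, 3.066, 3.026],
            "creative_quality": [2.907, 3.132, 2.927]},
        lam_T={"cleverness": [1, 0.489, 0.498],
               "creative_quality": [1, 0.540, 0.459]},
        lam_R={"cleverness": [1, 0.715, 0.502],
               "creative_quality": [1, 1.108, 0.583]},
        lam_INT={"cleverness": [1, 0.997, 0.908],
                 "creative_quality": [1, 0.932, 1.004]},
        var_eps={"cleverness": [0.324, 0.261, 0.273],
                 "creative_quality": [0.158, 0.209, 0.188]},
        Sigma_T=_sym([0.588, 0.223], [0.316]),
        # object-method order: (clev, garbage_bag), (clev, paperclip),
        #                      (cq, garbage_bag), (cq, paperclip)
        Sigma_OM=_sym([0.468, 0.429, 0.210, 0.182],
                      [0.187, 0.285, 0.075, 0.073, 0.251, 0.051]),
        var_R=[0.055, 0.328],
        var_INT=[0.047, 0.004],
    ),
    "dttl-b": dict(
        mu={"cleverness": [2.996, 3.055, 3.024],
            "creative_quality": [2.908, 3.124, 2.922]},
        lam_T={"cleverness": [1, 0.510, 0.514],
               "creative_quality": [1, 0.531, 0.461]},
        lam_UM={"cleverness": [1, 0.917, 0.762],
                "creative_quality": [1, 1.114, 0.596]},
        var_eps={"cleverness": [0.346, 0.257, 0.274],
                 "creative_quality": [0.183, 0.207, 0.208]},
        Sigma_T=_sym([0.564, 0.195], [0.310]),
        Sigma_OM=_sym([0.469, 0.424, 0.207, 0.180],
                      [0.182, 0.282, 0.079, 0.066, 0.251, 0.049]),
        var_UM=[0.084, 0.253],
    ),
    "dttl-ml": dict(
        mu={"cleverness": [2.993, 3.069, 3.030],
            "creative_quality": [2.904, 3.129, 2.926]},
        lam_T={"cleverness": [1, 0.521, 0.508],
               "creative_quality": [1, 0.598, 0.497]},
        lam_UM={"cleverness": [1, 0.775, 0.638],
                "creative_quality": [1, 1.163, 0.613]},
        var_eps={"cleverness": [0.321, 0.262, 0.275],
                 "creative_quality": [0.208, 0.195, 0.209]},
        Sigma_T=_sym([0.579, 0.156], [0.298]),
        Sigma_OM=_sym([0.456, 0.426, 0.170, 0.137],
                      [0.181, 0.162, 0.058, 0.054, 0.231, 0.007]),
        var_UM=[0.109, 0.240],
    ),
}


def aut_study_estimates(model: str = "dtcc") -> ParameterSet:
    """Published point estimates as a ParameterSet.

    ``model`` is one of ``"dtcc"``, ``"dttl-b"``, ``"dttl-ml"``.
    """
    if model not in _ESTIMATES:
        raise KeyError(f"model must be one of {sorted(_ESTIMATES)}, got {model!r}")
    variant = "dtcc" if model == "dtcc" else "dttl"
    spec = aut_study_spec(variant)
    return ParameterSet(spec, **_ESTIMATES[model])
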