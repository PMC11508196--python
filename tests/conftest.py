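import numpy as np
import pandas as pd
import pytest

import ccmtmm as cc
from ccmtmm.datasets import STUDY_RATERS


def random_parameter_set(spec, rng, near_singular=False):
    """Random valid ParameterSet for fuzzing decomposition identities."""
    J = spec.n_constructs
    m = len(spec.om_index)

    def rand_cov(dim):
        if dim == 0:
            return np.zeros((0, 0))
        a = rng.normal(size=(dim, dim + 2)) * 0.5
        mat = a @ a.T / (dim + 2)
        if near_singular:
            w, v = np.linalg.eigh(mat)
            w[0] *= 1e-6
            mat = v @ np.diag(w) @ v.T
        return mat

    def loadings(j):
        lam = rng.uniform(0.2, 1.5, size=len(spec.indicators[j]))
        lam[0] = 1.0
        return lam

    kw = dict(
        mu={j: rng.normal(3, 0.5, size=len(spec.indicators[j]))
            for j in spec.constructs},
        lam_T={j: loadings(j) for j in spec.constructs},
        var_eps={j: rng.uniform(0.05, 0.5, size=len(spec.indicators[j]))
                 for j in spec.constructs},
        Sigma_T=rand_cov(J) + 0.05 * np.eye(J),
        Sigma_OM=rand_cov(m) + (0.05 * np.eye(m) if m else 0),
    )
    if spec.variant == "dtcc":
        kw.update(lam_R={j: loadings(j) for j in spec.constructs},
                  lam_INT={j: loadings(j) for j in spec.constructs},
                  var_R=rng.uniform(0.01, 0.4, size=J),
                  var_INT=rng.uniform(0.01, 0.4, size=J))
    else:
        kw.update(lam_UM={j: loadings(j) for j in spec.constructs},
                  var_UM=rng.uniform(0.01, 0.4, size=J))
    return cc.ParameterSet(spec, **kw)


@pytest.fixture(scope="session")
def study_spec_dttl():
    return cc.aut_study_spec("dttl")


@pytest.fixture(scope="session")
def study_spec_dtcc():
    return cc.aut_study_spec("dtcc")


@pytest.fixture(scope="session")
def study_scores_dttl(study_spec_dttl):
    """One simulated dataset of the study design (202 targets, 4+3 raters)."""
    params = cc.aut_study_estimates("dttl-ml")
    cfg = cc.SimulationConfig(spec=study_spec_dttl, params=params, n_targets=202,
                              raters=STUDY_RATERS, seed=42)
    scores, effects = cc.simulate_ratings(cfg)
    return scores, effects, params


@pytest.fixture()
def toy_long_scores():
    """Tiny two-construct long table with disjoint rater panels."""
    rows = []
    rng = np.random.default_rng(0)
    for t in ["t1", "t2", "t3", "t4"]:
        for r, j in [("r1", "A"), ("r2", "A"), ("r3", "B"), ("r4", "B")]:
            for i in ["x", "y"]:
                rows.append((t, r, i, j, float(rng.integers(1, 6))))
    df = pd.DataFrame(rows, columns=["target", "rater", "indicator",
                                     "construct", "rating"])
    return cc.ScoreTable.from_long(df)
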