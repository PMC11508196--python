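"""Model structure for cross-classified CTC(M-1) rating models.

Two variants are supported.  The cross-classified model (``dtcc``) decomposes
an observed rating into

    Y[r,t,i,j] = mu[i,j] + lam_T[i,j] * T[t,j] + lam_R[i,j] * R[r,j]
                 + lam_INT[i,j] * INT[r,t,j] + OM[t,i,j] + eps[r,t,i,j]

where ``T`` is the target trait measured in the metric of the construct's
reference indicator, ``OM`` the target-level object-method residual of a
non-reference indicator (``OM = 0`` for reference indicators), ``R`` the
rater effect and ``INT`` the rater-target interaction effect.  The two-level
simplification (``dttl``) conglomerates rater and interaction effects into a
single unique-method effect ``UM[r,t,j]`` and has no rater level:

    Y[r,t,i,j] = mu[i,j] + lam_T[i,j] * T[t,j] + lam_UM[i,j] * UM[r,t,j]
                 + OM[t,i,j] + eps[r,t,i,j].

Identification is purely via the reference indicator: all its loadings are
fixed to 1 and all latent variances are free.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .exceptions import ConfigError, DesignWarning
from .ratings_data import DesignInfo

__all__ = [
    "MTMMModelSpec",
    "ParameterSet",
    "LatentEffects",
    "ParameterLayout",
    "build_spec",
    "count_free_parameters",
    "dttl_degrees_of_freedom",
    "conglomerate_to_dttl",
]

VARIANTS = ("dtcc", "dttl")


@dataclass
class MTMMModelSpec:
    """Declarative structure of a DTCC/DTTL model.

    ``indicators[j]`` lists the indicators of construct ``j`` in order; the
    first entry is the reference indicator whose loadings are fixed to 1.
    ``rater_cov_estimable[(j, j')]`` flags construct pairs whose rater- and
    interaction-effect covariances are estimable (requires shared raters).
    """

    variant: str
    constructs: list[str]
    indicators: dict[str, list[str]]
    rater_cov_estimable: dict[tuple[str, str], bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if not self.constructs:
            raise ConfigError("at least one construct required")
        for j in self.constructs:
            inds = self.indicators.get(j, [])
            if len(inds) == 0:
                raise ConfigError(f"construct {j!r} has zero indicators")
            if len(set(inds)) != len(inds):
                raise ConfigError(f"construct {j!r} has duplicate indicators")
        for pair in self.rater_cov_estimable:
            if not set(pair) <= set(self.constructs):
                raise ConfigError(f"unknown constructs in covariance flag {pair}")

    # -- structure helpers ------------------------------------------------
    @property
    def n_constructs(self) -> int:
        return len(self.constructs)

    @property
    def n_indicators(self) -> int:
        return sum(len(self.indicators[j]) for j in self.constructs)

    def reference(self, construct: str) -> str:
        return self.indicators[construct][0]

    @property
    def om_index(self) -> list[tuple[str, str]]:
        """(construct, indicator) pairs carrying an object-method effect."""
        return [(j, i) for j in self.constructs for i in self.indicators[j][1:]]

    @property
    def indicator_index(self) -> list[tuple[str, str]]:
        return [(j, i) for j in self.constructs for i in self.indicators[j]]

    def estimable_pairs(self) -> list[tuple[str, str]]:
        return [p for p, ok in sorted(self.rater_cov_estimable.items()) if ok]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "constructs": list(self.constructs),
            "indicators": {j: list(v) for j, v in self.indicators.items()},
            "rater_cov_estimable": {f"{a}|{b}": v
                                    for (a, b), v in self.rater_cov_estimable.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MTMMModelSpec":
        flags = {}
        for key, v in d.get("rater_cov_estimable", {}).items():
            a, b = key.split("|")
            flags[(a, b)] = bool(v)
        return cls(
            variant=d["variant"],
            constructs=list(d["constructs"]),
            indicators={j: list(v) for j, v in d["indicators"].items()},
            rater_cov_estimable=flags,
        )

    def to_yaml(self, path=None):
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "MTMMModelSpec":
        try:
            with open(path_or_text) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError):
            d = yaml.safe_load(path_or_text)
        if not isinstance(d, dict):
            raise ConfigError("model spec YAML must be a mapping")
        return cls.from_dict(d)


class ParameterSet:
    """All estimable parameters of a DTCC/DTTL model.

    Per construct ``j``: intercepts ``mu[j]``, trait loadings ``lam_T[j]``
    (reference fixed to 1), rater/interaction loadings ``lam_R[j]`` and
    ``lam_INT[j]`` (dtcc) or unique-method loadings ``lam_UM[j]`` (dttl),
    and residual variances ``var_eps[j]`` -- each an array over the
    construct's indicators.  Globally: the trait covariance matrix
    ``Sigma_T``, the object-method covariance matrix ``Sigma_OM`` (indexed
    by ``spec.om_index``), rater/interaction/unique-method variances per
    construct, and optional cross-construct rater/interaction covariances
    for estimable pairs.
    """

    def __init__(self, spec: MTMMModelSpec, *, mu, lam_T, var_eps, Sigma_T, Sigma_OM,
                 lam_R=None, lam_INT=None, lam_UM=None,
                 var_R=None, var_INT=None, var_UM=None,
                 cov_R=None, cov_INT=None, validate: bool = True):
        self.spec = spec
        self.mu = {j: np.asarray(mu[j], float) for j in spec.constructs}
        self.lam_T = {j: np.asarray(lam_T[j], float) for j in spec.constructs}
        self.var_eps = {j: np.asarray(var_eps[j], float) for j in spec.constructs}
        self.Sigma_T = np.atleast_2d(np.asarray(Sigma_T, float))
        m = len(spec.om_index)
        self.Sigma_OM = (np.asarray(Sigma_OM, float).reshape(m, m)
                         if m else np.zeros((0, 0)))
        if spec.variant == "dtcc":
            self.lam_R = {j: np.asarray(lam_R[j], float) for j in spec.constructs}
            self.lam_INT = {j: np.asarray(lam_INT[j], float) for j in spec.constructs}
            self.var_R = np.asarray(var_R, float)
            self.var_INT = np.asarray(var_INT, float)
            self.lam_UM = None
            self.var_UM = None
        else:
            self.lam_UM = {j: np.asarray(lam_UM[j], float) for j in spec.constructs}
            self.var_UM = np.asarray(var_UM, float)
            self.lam_R = self.lam_INT = None
            self.var_R = self.var_INT = None
        self.cov_R = dict(cov_R or {})
        self.cov_INT = dict(cov_INT or {})
        if validate:
            self.validate()

    def validate(self) -> None:
        spec = self.spec
        for j in spec.constructs:
            p = len(spec.indicators[j])
            for name in ("mu", "lam_T", "var_eps"):
                arr = getattr(self, name)[j]
                if arr.shape != (p,):
                    raise ConfigError(f"{name}[{j}] must have length {p}")
            if abs(self.lam_T[j][0] - 1.0) > 1e-12:
                raise ConfigError(f"reference trait loading for {j!r} must be 1")
            if np.any(self.var_eps[j] < 0):
                raise ConfigError(f"negative residual variance in construct {j!r}")
            if spec.variant == "dtcc":
                for name in ("lam_R", "lam_INT"):
                    if abs(getattr(self, name)[j][0] - 1.0) > 1e-12:
                        raise ConfigError(f"reference {name} loading for {j!r} must be 1")
            else:
                if abs(self.lam_UM[j][0] - 1.0) > 1e-12:
                    raise ConfigError(f"reference lam_UM loading for {j!r} must be 1")
        for name, mat in (("Sigma_T", self.Sigma_T), ("Sigma_OM", self.Sigma_OM)):
            if mat.size:
                if not np.allclose(mat, mat.T, atol=1e-10):
                    raise ConfigError(f"{name} is not symmetric")
                w = np.linalg.eigvalsh((mat + mat.T) / 2)
                if w.min() < -1e-8 * max(1.0, w.max()):
                    raise ConfigError(f"{name} is not positive semidefinite")
        for vec_name in ("var_R", "var_INT", "var_UM"):
            vec = getattr(self, vec_name)
            if vec is not None and np.any(vec < 0):
                raise ConfigError(f"negative {vec_name}")

    # -- indexing helpers -------------------------------------------------
    def om_variance(self, construct: str, indicator: str) -> float:
        """Object-method variance of a non-reference indicator (0 for reference)."""
        key = (construct, indicator)
        if key not in self.spec.om_index:
            return 0.0
        k = self.spec.om_index.index(key)
        return float(self.Sigma_OM[k, k])

    def trait_variance(self, construct: str) -> float:
        return float(self.Sigma_T[self.spec.constructs.index(construct),
                                  self.spec.constructs.index(construct)])

    def copy(self) -> "ParameterSet":
        layout = ParameterLayout(self.spec)
        return layout.unflatten(layout.flatten(self))

    def to_dict(self) -> dict:
        d = {
            "variant": self.spec.variant,
            "mu": {j: self.mu[j].tolist() for j in self.spec.constructs},
            "lam_T": {j: self.lam_T[j].tolist() for j in self.spec.constructs},
            "var_eps": {j: self.var_eps[j].tolist() for j in self.spec.constructs},
            "Sigma_T": self.Sigma_T.tolist(),
            "Sigma_OM": self.Sigma_OM.tolist(),
        }
        if self.spec.variant == "dtcc":
            d["lam_R"] = {j: self.lam_R[j].tolist() for j in self.spec.constructs}
            d["lam_INT"] = {j: self.lam_INT[j].tolist() for j in self.spec.constructs}
            d["var_R"] = self.var_R.tolist()
            d["var_INT"] = self.var_INT.tolist()
            d["cov_R"] = {f"{a}|{b}": v for (a, b), v in self.cov_R.items()}
            d["cov_INT"] = {f"{a}|{b}": v for (a, b), v in self.cov_INT.items()}
        else:
            d["lam_UM"] = {j: self.lam_UM[j].tolist() for j in self.spec.constructs}
            d["var_UM"] = self.var_UM.tolist()
        return d

    @classmethod
    def from_dict(cls, spec: MTMMModelSpec, d: dict) -> "ParameterSet":
        kw = dict(mu=d["mu"], lam_T=d["lam_T"], var_eps=d["var_eps"],
                  Sigma_T=d["Sigma_T"], Sigma_OM=d["Sigma_OM"])
        if spec.variant == "dtcc":
            kw.update(lam_R=d["lam_R"], lam_INT=d["lam_INT"],
                      var_R=d["var_R"], var_INT=d["var_INT"],
                      cov_R={tuple(k.split("|")): v for k, v in d.get("cov_R", {}).items()},
                      cov_INT={tuple(k.split("|")): v for k, v in d.get("cov_INT", {}).items()})
        else:
            kw.update(lam_UM=d["lam_UM"], var_UM=d["var_UM"])
        return cls(spec, **kw)

    def to_json(self, path=None):
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class LatentEffects:
    """Latent-effect scores underlying a simulated or reconstructed table.

    ``T`` has shape (n_targets, J); ``OM`` has shape (n_targets, M) in
    ``om_index`` order.  ``R`` maps construct -> rater-effect array and
    ``INT``/``UM`` map construct -> (raters, targets) arrays; entries are
    None for the variant that does not carry them.
    """

    targets: list[str]
    raters: dict[str, list[str]]
    T: np.ndarray
    OM: np.ndarray
    R: dict | None = None
    INT: dict | None = None
    UM: dict | None = None


class ParameterLayout:
    """Fixed flattening of a ParameterSet into a named vector.

    Used for MCMC monitoring (one trace per name), for the ML natural
    parameter vector, and as the ground truth for parameter counting.
    """

    def __init__(self, spec: MTMMModelSpec):
        self.spec = spec
        names: list[str] = []
        for j, i in spec.indicator_index:
            names.append(f"mu[{j}.{i}]")
        for j, i in spec.om_index:
            names.append(f"lam_T[{j}.{i}]")
        if spec.variant == "dtcc":
            for j, i in spec.om_index:
                names.append(f"lam_R[{j}.{i}]")
            for j, i in spec.om_index:
                names.append(f"lam_INT[{j}.{i}]")
        else:
            for j, i in spec.om_index:
                names.append(f"lam_UM[{j}.{i}]")
        J = spec.n_constructs
        cs = spec.constructs
        for a in range(J):
            for b in range(a, J):
                names.append(f"var_T[{cs[a]}]" if a == b
                             else f"cov_T[{cs[a]},{cs[b]}]")
        om = spec.om_index
        for a in range(len(om)):
            for b in range(a, len(om)):
                names.append(
                    f"var_OM[{om[a][0]}.{om[a][1]}]" if a == b
                    else f"cov_OM[{om[a][0]}.{om[a][1]},{om[b][0]}.{om[b][1]}]"
                )
        if spec.variant == "dtcc":
            for j in cs:
                names.append(f"var_R[{j}]")
            for a, b in spec.estimable_pairs():
                names.append(f"cov_R[{a},{b}]")
            for j in cs:
                names.append(f"var_INT[{j}]")
            for a, b in spec.estimable_pairs():
                names.append(f"cov_INT[{a},{b}]")
        else:
            for j in cs:
                names.append(f"var_UM[{j}]")
        for j, i in spec.indicator_index:
            names.append(f"var_eps[{j}.{i}]")
        self.names = names

    def __len__(self) -> int:
        return len(self.names)

    def flatten(self, ps: ParameterSet) -> np.ndarray:
        spec = self.spec
        out: list[float] = []
        for j in spec.constructs:
            out.extend(ps.mu[j])
        for j in spec.constructs:
            out.extend(ps.lam_T[j][1:])
        if spec.variant == "dtcc":
            for j in spec.constructs:
                out.extend(ps.lam_R[j][1:])
            for j in spec.constructs:
                out.extend(ps.lam_INT[j][1:])
        else:
            for j in spec.constructs:
                out.extend(ps.lam_UM[j][1:])
        J = spec.n_constructs
        for a in range(J):
            for b in range(a, J):
                out.append(ps.Sigma_T[a, b])
        m = len(spec.om_index)
        for a in range(m):
            for b in range(a, m):
                out.append(ps.Sigma_OM[a, b])
        if spec.variant == "dtcc":
            out.extend(ps.var_R)
            for pair in spec.estimable_pairs():
                out.append(ps.cov_R.get(pair, 0.0))
            out.extend(ps.var_INT)
            for pair in spec.estimable_pairs():
                out.append(ps.cov_INT.get(pair, 0.0))
        else:
            out.extend(ps.var_UM)
        for j in spec.constructs:
            out.extend(ps.var_eps[j])
        vec = np.asarray(out, float)
        assert vec.shape == (len(self.names),)
        return vec

    def unflatten(self, vec: np.ndarray, validate: bool = True) -> ParameterSet:
        spec = self.spec
        vec = np.asarray(vec, float)
        if vec.shape != (len(self.names),):
            raise ConfigError(f"parameter vector must have length {len(self.names)}")
        pos = 0

        def take(n):
            nonlocal pos
            chunk = vec[pos:pos + n]
            pos += n
            return chunk

        mu = {}
        for j in spec.constructs:
            mu[j] = take(len(spec.indicators[j])).copy()
        lam_T = {}
        for j in spec.constructs:
            lam_T[j] = np.concatenate([[1.0], take(len(spec.indicators[j]) - 1)])
        lam_R = lam_INT = lam_UM = None
        if spec.variant == "dtcc":
            lam_R = {j: np.concatenate([[1.0], take(len(spec.indicators[j]) - 1)])
                     for j in spec.constructs}
            lam_INT = {j: np.concatenate([[1.0], take(len(spec.indicators[j]) - 1)])
                       for j in spec.constructs}
        else:
            lam_UM = {j: np.concatenate([[1.0], take(len(spec.indicators[j]) - 1)])
                      for j in spec.constructs}
        J = spec.n_constructs
        Sigma_T = np.zeros((J, J))
        for a in range(J):
            for b in range(a, J):
                Sigma_T[a, b] = Sigma_T[b, a] = take(1)[0]
        m = len(spec.om_index)
        Sigma_OM = np.zeros((m, m))
        for a in range(m):
            for b in range(a, m):
                Sigma_OM[a, b] = Sigma_OM[b, a] = take(1)[0]
        var_R = var_INT = var_UM = None
        cov_R: dict = {}
        cov_INT: dict = {}
        if spec.variant == "dtcc":
            var_R = take(J).copy()
            for pair in spec.estimable_pairs():
                cov_R[pair] = float(take(1)[0])
            var_INT = take(J).copy()
            for pair in spec.estimable_pairs():
                cov_INT[pair] = float(take(1)[0])
        else:
            var_UM = take(J).copy()
        var_eps = {}
        for j in spec.constructs:
            var_eps[j] = take(len(spec.indicators[j])).copy()
        assert pos == len(vec)
        return ParameterSet(spec, mu=mu, lam_T=lam_T, var_eps=var_eps,
                            Sigma_T=Sigma_T, Sigma_OM=Sigma_OM,
                            lam_R=lam_R, lam_INT=lam_INT, lam_UM=lam_UM,
                            var_R=var_R, var_INT=var_INT, var_UM=var_UM,
                            cov_R=cov_R, cov_INT=cov_INT, validate=validate)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_spec(design: DesignInfo, variant: str) -> MTMMModelSpec:
    """Derive a model spec from a validated rating design.

    Cross-construct rater/interaction covariances are flagged estimable only
    where the design's rater sets overlap; with disjoint rater panels those
    covariances are excluded (the rater-related effects of different
    constructs are orthogonalized).
    """
    for j in design.constructs:
        n_ind = len(design.indicators[j])
        if n_ind == 0:
            raise ConfigError(f"construct {j!r} has zero indicators")
        if n_ind == 1:
            warnings.warn(
                f"construct {j!r} has a single indicator; no object-method "
                "effect can be separated for it",
                DesignWarning,
                stacklevel=2,
            )
    return MTMMModelSpec(
        variant=variant,
        constructs=list(design.constructs),
        indicators={j: list(design.indicators[j]) for j in design.constructs},
        rater_cov_estimable=dict(design.rater_cov_estimable),
    )


def count_free_parameters(spec: MTMMModelSpec) -> int:
    """Exact number of estimable parameters of the model."""
    p = spec.n_indicators
    J = spec.n_constructs
    m = len(spec.om_index)          # non-reference indicators
    n_pairs = len(spec.estimable_pairs())
    count = p                        # intercepts
    count += m                       # free trait loadings
    count += J * (J + 1) // 2        # Sigma_T
    count += m * (m + 1) // 2        # Sigma_OM
    count += p                       # residual variances
    if spec.variant == "dtcc":
        count += 2 * m               # free rater + interaction loadings
        count += 2 * (J + n_pairs)   # rater + interaction (co)variances
    else:
        count += m                   # free unique-method loadings
        count += J                   # unique-method variances
    return count


def dttl_degrees_of_freedom(spec: MTMMModelSpec) -> int:
    """Degrees of freedom of the two-level test of exact fit for the DTTL.

    The saturated two-level model is counted with ``p`` means and a full
    ``p x p`` covariance matrix at *each* level, i.e. ``p + p(p+1)``
    statistics for ``p`` total indicators, regardless of whether every
    within-level covariance is empirically identified under construct-blocked
    missingness.  This is the convention of standard two-level SEM software
    and is required to reproduce conventional df accounting; see the methods
    note for the distinction from the smaller number of effective (testable)
    constraints.
    """
    if spec.variant != "dttl":
        raise ConfigError("degrees of freedom are defined for the dttl variant only "
                          "(no ML fit exists for the cross-classified variant)")
    p = spec.n_indicators
    return p + p * (p + 1) - count_free_parameters(spec)


def conglomerate_to_dttl(params: ParameterSet,
                         dttl_spec: MTMMModelSpec | None = None) -> ParameterSet:
    """Map a cross-classified ParameterSet onto its two-level simplification.

    Rater and interaction effects are conglomerated into one unique-method
    effect per construct: ``var_UM = var_R + var_INT`` and the non-reference
    unique-method loadings are chosen so the conglomerate reproduces the
    marginal rater-related variance of each indicator,
    ``lam_UM^2 var_UM = lam_R^2 var_R + lam_INT^2 var_INT``.
    """
    spec = params.spec
    if spec.variant != "dtcc":
        raise ConfigError("conglomeration starts from a dtcc ParameterSet")
    if dttl_spec is None:
        dttl_spec = MTMMModelSpec(
            variant="dttl", constructs=list(spec.constructs),
            indicators={j: list(spec.indicators[j]) for j in spec.constructs},
            rater_cov_estimable={k: False for k in spec.rater_cov_estimable},
        )
    var_UM = params.var_R + params.var_INT
    lam_UM = {}
    for jx, j in enumerate(spec.constructs):
        num = (params.lam_R[j] ** 2 * params.var_R[jx]
               + params.lam_INT[j] ** 2 * params.var_INT[jx])
        lam_UM[j] = np.sqrt(num / var_UM[jx]) if var_UM[jx] > 0 else np.ones_like(num)
        lam_UM[j][0] = 1.0
    return ParameterSet(
        dttl_spec,
        mu={j: params.mu[j].copy() for j in spec.constructs},
        lam_T={j: params.lam_T[j].copy() for j in spec.constructs},
        var_eps={j: params.var_eps[j].copy() for j in spec.constructs},
        Sigma_T=params.Sigma_T.copy(),
        Sigma_OM=params.Sigma_OM.copy(),
        lam_UM=lam_UM,
        var_UM=var_UM,
    )
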