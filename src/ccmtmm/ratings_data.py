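"""Cross-classified rating data: containers, aggregation, design validation, ICCs.

Rating studies with interchangeable raters produce data cross-classified by
targets (the persons whose ideas are rated) and raters.  Each rater scores a
target on one or more indicators (tasks) belonging to a construct (the
creativity aspect being scored).  Raters are typically blocked by construct:
a rater either scores all indicators of a construct for every target or none
of them, so the missingness pattern of the wide table is construct-blocked
by design.

This module reads and writes such tables, aggregates idea-level ratings into
rater-target scores via a quantile of the idea distribution, infers and
validates the rating design, and computes classical two-way random-effects
agreement ICCs as a model-free baseline.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataError, DesignError, DesignWarning

__all__ = [
    "IdeaRatings",
    "ScoreTable",
    "DesignInfo",
    "ICCResult",
    "aggregate_scores",
    "validate_design",
    "icc_average_absolute",
    "QUANTILE_CONVENTIONS",
]

#: Mapping from user-facing quantile-convention names to numpy method names.
#: "linear" interpolates between closest order statistics (position
#: q*(n-1)+1), the common statistical default; "exclusive" uses Weibull
#: plotting positions; "nearest-rank" takes the smallest order statistic with
#: cumulative probability >= q.
QUANTILE_CONVENTIONS = {
    "linear": "linear",
    "exclusive": "weibull",
    "nearest-rank": "inverted_cdf",
    "median-unbiased": "median_unbiased",
}

_IDEA_COLUMNS = ["target", "rater", "indicator", "construct", "idea", "rating"]


@dataclass
class IdeaRatings:
    """Idea-level ratings in long format, before aggregation to scores.

    ``records`` must contain the columns ``target, rater, indicator,
    construct, idea, rating``.  ``scale`` holds the rating-scale bounds
    (metadata only; scores are never truncated to it).
    """

    records: pd.DataFrame
    scale: tuple[float, float] = (1.0, 5.0)

    def __post_init__(self) -> None:
        missing = [c for c in _IDEA_COLUMNS if c not in self.records.columns]
        if missing:
            raise DataError(f"idea ratings missing columns: {missing}")
        if len(self.records) == 0:
            raise DataError("idea ratings table is empty")
        df = self.records
        lo, hi = self.scale
        bad = df[(df["rating"] < lo) | (df["rating"] > hi)]
        if len(bad):
            raise DataError(
                f"{len(bad)} rating(s) outside the declared scale [{lo}, {hi}]"
            )
        dup = df.duplicated(subset=["target", "rater", "indicator", "construct", "idea"])
        if dup.any():
            raise DataError(
                f"{int(dup.sum())} duplicated (target, rater, indicator, construct, idea) keys"
            )

    @classmethod
    def from_csv(cls, path_or_buf, scale: tuple[float, float] = (1.0, 5.0)) -> "IdeaRatings":
        df = pd.read_csv(path_or_buf, dtype={"target": str, "rater": str,
                                             "indicator": str, "construct": str})
        return cls(df, scale=scale)


class ScoreTable:
    """Wide rater-target score table with construct-blocked missingness.

    Rows are (target, rater) pairs; columns are (construct, indicator) pairs;
    cells hold the aggregated score ``Y[r, t, i, j]`` or NaN for cells the
    rater did not score.  The underlying storage is a pandas DataFrame with
    MultiIndex rows and columns; column order fixes the indicator order per
    construct (the first indicator of each construct is the default reference
    indicator).
    """

    def __init__(self, data: pd.DataFrame, scale: tuple[float, float] = (1.0, 5.0)):
        if not isinstance(data.index, pd.MultiIndex) or data.index.nlevels != 2:
            raise DataError("ScoreTable rows must be a (target, rater) MultiIndex")
        if not isinstance(data.columns, pd.MultiIndex) or data.columns.nlevels != 2:
            raise DataError("ScoreTable columns must be a (construct, indicator) MultiIndex")
        if len(data) == 0 or data.shape[1] == 0:
            raise DataError("ScoreTable is empty")
        data = data.astype(float)
        data.index = data.index.set_names(["target", "rater"])
        data.columns = data.columns.set_names(["construct", "indicator"])
        self.data = data
        self.scale = tuple(scale)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_long(cls, df: pd.DataFrame, scale: tuple[float, float] = (1.0, 5.0)) -> "ScoreTable":
        """Build from a long table with columns target, rater, indicator, construct, rating."""
        need = ["target", "rater", "indicator", "construct", "rating"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise DataError(f"long score table missing columns: {missing}")
        wide = df.pivot_table(
            index=["target", "rater"], columns=["construct", "indicator"],
            values="rating", aggfunc="first", sort=False,
        )
        # preserve first-appearance order of constructs and indicators
        order = df[["construct", "indicator"]].drop_duplicates()
        cols = pd.MultiIndex.from_frame(order)
        wide = wide.reindex(columns=cols)
        return cls(wide, scale=scale)

    @classmethod
    def from_csv(cls, path_or_buf, scale: tuple[float, float] = (1.0, 5.0),
                 na_token: str = "NA") -> "ScoreTable":
        """Read a wide CSV written by :meth:`to_csv` (columns ``construct:indicator``)."""
        df = pd.read_csv(path_or_buf, dtype={"target": str, "rater": str},
                         na_values=[na_token, ""], keep_default_na=True,
                         float_precision="round_trip")
        if "target" not in df.columns or "rater" not in df.columns:
            raise DataError("wide score CSV must have 'target' and 'rater' columns")
        df = df.set_index(["target", "rater"])
        try:
            cols = pd.MultiIndex.from_tuples(
                [tuple(c.split(":", 1)) for c in df.columns],
                names=["construct", "indicator"],
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise DataError(f"cannot parse wide score columns: {exc}") from exc
        df.columns = cols
        return cls(df, scale=scale)

    def to_csv(self, path_or_buf=None, na_token: str = "NA"):
        out = self.data.copy()
        out.columns = [f"{c}:{i}" for c, i in out.columns]
        # %.17g guarantees binary round-tripping of the scores
        return out.to_csv(path_or_buf, na_rep=na_token, float_format="%.17g")

    # -- accessors --------------------------------------------------------
    @property
    def constructs(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values("construct")))

    def indicators(self, construct: str) -> list[str]:
        return [i for c, i in self.data.columns if c == construct]

    @property
    def targets(self) -> list[str]:
        return list(dict.fromkeys(self.data.index.get_level_values("target")))

    @property
    def raters(self) -> list[str]:
        return list(dict.fromkeys(self.data.index.get_level_values("rater")))

    def raters_for(self, construct: str) -> list[str]:
        """Raters with at least one observed cell for ``construct``."""
        block = self.data[construct]
        obs = block.notna().any(axis=1)
        seen = self.data.index.get_level_values("rater")[obs.to_numpy()]
        return list(dict.fromkeys(seen))

    def construct_array(self, construct: str) -> tuple[list[str], list[str], np.ndarray]:
        """Return (raters, targets, Y) with Y of shape (R, T, I) for one construct.

        Cells a rater never scored are NaN.  Targets/raters are in table order.
        """
        raters = self.raters_for(construct)
        targets = self.targets
        inds = self.indicators(construct)
        block = self.data[construct].reindex(columns=inds)
        arr = np.full((len(raters), len(targets), len(inds)), np.nan)
        r_pos = {r: k for k, r in enumerate(raters)}
        t_pos = {t: k for k, t in enumerate(targets)}
        for (t, r), row in block.iterrows():
            if r in r_pos:
                arr[r_pos[r], t_pos[t], :] = row.to_numpy()
        return raters, targets, arr

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScoreTable):
            return NotImplemented
        if self.scale != other.scale:
            return False
        if not self.data.index.equals(other.data.index):
            return False
        if list(self.data.columns) != list(other.data.columns):
            return False
        a, b = self.data.to_numpy(), other.data.to_numpy()
        return bool(np.all((a == b) | (np.isnan(a) & np.isnan(b))))

    def __repr__(self) -> str:
        return (f"ScoreTable({len(self.targets)} targets x {len(self.raters)} raters, "
                f"constructs={self.constructs})")


@dataclass
class DesignInfo:
    """Inferred rating design: who rated what, and which covariances are estimable.

    ``rater_assignment`` maps each rater to the set of constructs it scored.
    ``rater_cov_estimable[(j, j')]`` is True when at least one rater scored
    both constructs, which is the condition for cross-construct rater- and
    interaction-effect covariances to be estimable at all.
    """

    constructs: list[str]
    indicators: dict[str, list[str]]
    reference: dict[str, str]
    rater_assignment: dict[str, frozenset]
    n_targets: int
    n_raters: int
    rater_cov_estimable: dict[tuple[str, str], bool] = field(default_factory=dict)

    def raters_for(self, construct: str) -> list[str]:
        return [r for r, cs in self.rater_assignment.items() if construct in cs]


@dataclass
class ICCResult:
    """Average-measure absolute-agreement ICC with its 95% confidence interval."""

    icc: float
    ci_low: float
    ci_high: float
    k: int
    n: int

    def __post_init__(self) -> None:
        self.icc = float(min(max(self.icc, 0.0), 1.0))
        self.ci_low = float(min(max(self.ci_low, 0.0), self.icc))
        self.ci_high = float(min(max(self.ci_high, self.icc), 1.0))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def aggregate_scores(ideas: IdeaRatings, q: float = 0.75,
                     convention: str = "linear") -> ScoreTable:
    """Aggregate idea-level ratings to one score per (target, rater, indicator).

    For every (target, rater, indicator, construct) cell the score is the
    ``q``-quantile of the ratings of the ideas that the target produced, as
    judged by that rater.  The 0.75 quantile is preferred over the mean or
    median because it is robust against low-quality outlier ideas produced
    by otherwise creative targets.  Cells without any ideas become NaN.
    """
    if not 0.0 < q < 1.0:
        raise DataError(f"quantile q must be in (0, 1), got {q}")
    if convention not in QUANTILE_CONVENTIONS:
        raise DataError(
            f"unknown quantile convention {convention!r}; "
            f"choose from {sorted(QUANTILE_CONVENTIONS)}"
        )
    method = QUANTILE_CONVENTIONS[convention]
    df = ideas.records
    agg = (
        df.groupby(["target", "rater", "construct", "indicator"], sort=False)["rating"]
        .apply(lambda v: float(np.quantile(v.to_numpy(float), q, method=method)))
        .reset_index()
        .rename(columns={"rating": "rating"})
    )
    return ScoreTable.from_long(agg, scale=ideas.scale)


def validate_design(scores: ScoreTable) -> DesignInfo:
    """Infer the rating design from a score table and validate it.

    Raises :class:`DesignError` for raters with no observed cells, for
    within-construct partial missingness (a rater must score either all or
    none of a construct's indicators, per row), and for constructs with
    fewer than 2 raters or 2 targets.  Emits a :class:`DesignWarning` for
    raters spanning several constructs (cross-construct rater covariances
    become estimable, but samplers here require single-construct raters;
    such raters can be dropped from one construct, mirroring common
    practice).
    """
    constructs = scores.constructs
    indicators = {c: scores.indicators(c) for c in constructs}
    reference = {c: indicators[c][0] for c in constructs}

    assignment: dict[str, set] = {r: set() for r in scores.raters}
    for c in constructs:
        block = scores.data[c]
        obs = block.notna()
        row_any = obs.any(axis=1)
        row_all = obs.all(axis=1)
        partial = row_any & ~row_all
        if partial.any():
            bad = scores.data.index[partial.to_numpy()][:5].tolist()
            raise DesignError(
                f"construct {c!r}: rows with partially observed indicator blocks "
                f"(missingness must be construct-blocked): {bad}"
            )
        for r in scores.raters_for(c):
            assignment[r].add(c)

    empty = [r for r, cs in assignment.items() if not cs]
    if empty:
        raise DesignError(f"raters with no observed cells: {empty}")

    multi = {r: cs for r, cs in assignment.items() if len(cs) > 1}
    if multi:
        warnings.warn(
            f"raters scoring multiple constructs: {sorted(multi)}; cross-construct "
            "rater covariances are estimable only through them, and the samplers in "
            "this package require single-construct raters (consider dropping these "
            "raters from one construct)",
            DesignWarning,
            stacklevel=2,
        )

    n_targets = len(scores.targets)
    for c in constructs:
        k = len(scores.raters_for(c))
        if k < 2:
            raise DesignError(f"construct {c!r} has {k} rater(s); at least 2 required")
    if n_targets < 2:
        raise DesignError(f"only {n_targets} target(s); at least 2 required")

    estimable = {}
    for a in constructs:
        for b in constructs:
            if a < b:
                shared = any({a, b} <= cs for cs in assignment.values())
                estimable[(a, b)] = shared

    return DesignInfo(
        constructs=constructs,
        indicators=indicators,
        reference=reference,
        rater_assignment={r: frozenset(cs) for r, cs in assignment.items()},
        n_targets=n_targets,
        n_raters=len(assignment),
        rater_cov_estimable=estimable,
    )


def _icc_matrix(scores: ScoreTable, construct: str, indicator: str) -> np.ndarray:
    """Complete-case targets-by-raters matrix for one construct/indicator."""
    if construct not in scores.constructs:
        raise DataError(f"unknown construct {construct!r}")
    if indicator == "mean":
        block = scores.data[construct].mean(axis=1, skipna=False)
    else:
        if indicator not in scores.indicators(construct):
            raise DataError(f"unknown indicator {indicator!r} for construct {construct!r}")
        block = scores.data[(construct, indicator)]
    wide = block.unstack("rater")
    wide = wide.loc[:, wide.notna().any(axis=0)]  # raters observed for this construct
    wide = wide.dropna(axis=0, how="any")  # complete-case targets
    return wide.to_numpy(float)


def icc_average_absolute(scores: ScoreTable, construct: str,
                         indicator: str = "mean", alpha: float = 0.05) -> ICCResult:
    """Two-way random-effects, absolute-agreement, average-measure ICC.

    This is ICC(A,k) in the McGraw-Wong taxonomy: the reliability of the
    average of the k raters' scores, penalising both disagreement in ranking
    and systematic rater level differences.  The point estimate is

        ICC = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)

    with MS_R, MS_C, MS_E the target, rater and error mean squares of the
    two-way ANOVA.  The confidence interval uses the F construction with
    Satterthwaite degrees of freedom for the single-measure coefficient,
    stepped up to the average measure via the Spearman-Brown relation.
    Targets missing any rater for the construct are dropped (complete-case).
    """
    x = _icc_matrix(scores, construct, indicator)
    n, k = x.shape
    if n < 2 or k < 2:
        raise DataError(
            f"ICC needs >=2 complete-case targets and >=2 raters, got n={n}, k={k}"
        )
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if msr + (msc - mse) / n <= 0:
        icc_k = 0.0
    else:
        icc_k = (msr - mse) / (msr + (msc - mse) / n)

    # single-measure coefficient and its F-based interval (McGraw & Wong)
    denom1 = msr + (k - 1) * mse + k * (msc - mse) / n
    icc_1 = (msr - mse) / denom1 if denom1 > 0 else 0.0
    if mse <= 0:  # perfect within-cell agreement; interval degenerates
        return ICCResult(icc=icc_k, ci_low=icc_k, ci_high=icc_k, k=k, n=n)
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc_1 * fj + n * (1 + (k - 1) * icc_1) - k * icc_1) ** 2
    vd = (n - 1) * k**2 * icc_1**2 * fj**2 + (n * (1 + (k - 1) * icc_1) - k * icc_1) ** 2
    v = vn / vd
    f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lb1 = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    ub1 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    # Spearman-Brown step-up from single to average measure
    lb = lb1 * k / (1 + (k - 1) * lb1) if 1 + (k - 1) * lb1 != 0 else 0.0
    ub = ub1 * k / (1 + (k - 1) * ub1) if 1 + (k - 1) * ub1 != 0 else 1.0
    return ICCResult(icc=icc_k, ci_low=min(lb, ub), ci_high=max(lb, ub), k=k, n=n)
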