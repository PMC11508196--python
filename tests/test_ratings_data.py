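"""Score aggregation, design validation and agreement ICCs."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ccmtmm as cc
from ccmtmm.exceptions import DataError, DesignError, DesignWarning


def _ideas(ratings, target="t1", rater="r1", indicator="i1", construct="c1"):
    df = pd.DataFrame({
        "target": target, "rater": rater, "indicator": indicator,
        "construct": construct, "idea": range(1, len(ratings) + 1),
        "rating": ratings,
    })
    return cc.IdeaRatings(df)


class TestAggregateScores:
    @pytest.mark.parametrize("ratings, q, expected", [
        ([1, 2, 3, 4, 5], 0.75, 4.0),       # position 0.75*(5-1)+1 = 4th order stat
        ([3], 0.75, 3.0),                    # singleton
        ([3], 0.10, 3.0),
        ([2, 3], 0.75, 2.75),                # 2 + 0.75*(3-2)
    ])
    def test_linear_interpolation_quantile(self, ratings, q, expected):
        table = cc.aggregate_scores(_ideas(ratings), q=q)
        assert table.data.iloc[0, 0] == pytest.approx(expected)

    def test_alternative_conventions(self):
        table = cc.aggregate_scores(_ideas([1, 2, 3, 4, 5]), q=0.75,
                                    convention="nearest-rank")
        assert table.data.iloc[0, 0] == pytest.approx(4.0)
        with pytest.raises(DataError):
            cc.aggregate_scores(_ideas([1, 2]), convention="nope")

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.5, 2.0])
    def test_quantile_bounds_validated(self, q):
        with pytest.raises(DataError):
            cc.aggregate_scores(_ideas([1, 2, 3]), q=q)

    def test_empty_input_rejected(self):
        df = pd.DataFrame(columns=["target", "rater", "indicator",
                                   "construct", "idea", "rating"])
        with pytest.raises(DataError):
            cc.IdeaRatings(df)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(ratings=st.lists(st.integers(1, 5), min_size=1, max_size=8),
           bump=st.integers(0, 7), q=st.floats(0.05, 0.95))
    def test_monotone_in_idea_ratings(self, ratings, bump, q):
        """Raising any single idea rating never lowers the aggregate."""
        base = cc.aggregate_scores(_ideas(ratings), q=q).data.iloc[0, 0]
        idx = bump % len(ratings)
        raised = list(ratings)
        raised[idx] = 5
        upper = cc.aggregate_scores(_ideas(raised), q=q).data.iloc[0, 0]
        assert upper >= base - 1e-12

    def test_cells_without_ideas_are_na(self):
        df = pd.concat([_ideas([2, 4]).records,
                        _ideas([3], rater="r2", indicator="i2").records])
        table = cc.aggregate_scores(cc.IdeaRatings(df))
        assert table.data.isna().sum().sum() == 2  # off-cells of each rater


class TestScoreTableRoundTrip:
    def test_csv_round_trip_preserves_na_pattern(self, toy_long_scores):
        buf = io.StringIO(toy_long_scores.to_csv())
        back = cc.ScoreTable.from_csv(buf)
        assert back == toy_long_scores

    def test_round_trip_of_simulated_study_table(self, study_scores_dttl):
        scores, _, _ = study_scores_dttl
        back = cc.ScoreTable.from_csv(io.StringIO(scores.to_csv()))
        assert back == scores


class TestValidateDesign:
    def test_disjoint_panels_not_estimable(self, study_scores_dttl):
        scores, _, _ = study_scores_dttl
        design = cc.validate_design(scores)
        assert design.rater_assignment["r1"] == frozenset({"cleverness"})
        assert design.rater_assignment["r6"] == frozenset({"creative_quality"})
        assert design.rater_cov_estimable[("cleverness", "creative_quality")] is False
        assert design.n_targets == 202 and design.n_raters == 7

    def test_shared_raters_flagged_estimable_with_warning(self):
        rows = [(t, r, i, j, 3.0) for t in ["t1", "t2"] for r in ["r1", "r2"]
                for j in ["A", "B"] for i in ["x", "y"]]
        df = pd.DataFrame(rows, columns=["target", "rater", "indicator",
                                         "construct", "rating"])
        table = cc.ScoreTable.from_long(df)
        with pytest.warns(DesignWarning):
            design = cc.validate_design(table)
        assert design.rater_cov_estimable[("A", "B")] is True

    def test_rater_with_no_observed_cells_rejected(self, toy_long_scores):
        df = toy_long_scores.data.copy()
        df.loc[pd.IndexSlice[:, "r2"], :] = np.nan
        with pytest.raises(DesignError, match="r2"):
            cc.validate_design(cc.ScoreTable(df))

    def test_partial_construct_block_rejected(self, toy_long_scores):
        df = toy_long_scores.data.copy()
        df.iloc[0, 0] = np.nan  # one cell of an otherwise observed block
        with pytest.raises(DesignError, match="construct-blocked"):
            cc.validate_design(cc.ScoreTable(df))


def _score_table_from_matrix(x):
    """Targets-by-raters matrix as a single-indicator ScoreTable."""
    n, k = x.shape
    rows = [(f"t{t}", f"r{r}", "i1", "c1", x[t, r])
            for t in range(n) for r in range(k)]
    df = pd.DataFrame(rows, columns=["target", "rater", "indicator",
                                     "construct", "rating"])
    return cc.ScoreTable.from_long(df)


def _anova_icc_oracle(x):
    """Brute-force two-way ANOVA mean squares -> ICC(A,k)."""
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
    mse = (((x - x.mean(1, keepdims=True) - x.mean(0, keepdims=True) + grand) ** 2).sum()
           / ((n - 1) * (k - 1)))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestIcc:
    def test_perfect_agreement_gives_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        res = cc.icc_average_absolute(_score_table_from_matrix(x), "c1", "i1")
        assert res.icc == pytest.approx(1.0)

    def test_matches_mean_squares_oracle(self):
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])  # rater 2 shifted +1
        res = cc.icc_average_absolute(_score_table_from_matrix(x), "c1", "i1")
        assert res.icc == pytest.approx(_anova_icc_oracle(x), abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(3, 1, size=(5, 5)) + rng.normal(0, 0.5, size=(5, 1))
        res = cc.icc_average_absolute(_score_table_from_matrix(x), "c1", "i1")
        assert res.icc == pytest.approx(np.clip(_anova_icc_oracle(x), 0, 1), abs=1e-10)
        assert res.ci_low <= res.icc <= res.ci_high
        assert 0.0 <= res.ci_low and res.ci_high <= 1.0

    def test_matches_pingouin_point_and_interval(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x = rng.normal(3, 1, size=(12, 4)) + rng.normal(0, 0.6, size=(12, 1))
        res = cc.icc_average_absolute(_score_table_from_matrix(x), "c1", "i1")
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 4),
            "raters": np.tile(np.arange(4), 12),
            "scores": x.ravel(),
        })
        row = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="scores").set_index("Type").loc["ICC(A,k)"]
        ci_col = "CI95" if "CI95" in row.index else "CI95%"
        assert res.icc == pytest.approx(row["ICC"], abs=1e-8)
        assert res.ci_low == pytest.approx(row[ci_col][0], abs=5e-3)
        assert res.ci_high == pytest.approx(row[ci_col][1], abs=5e-3)

    def test_mean_of_indicators_uses_row_means(self, study_scores_dttl):
        scores, _, _ = study_scores_dttl
        res = cc.icc_average_absolute(scores, "cleverness", "mean")
        assert 0.0 <= res.icc <= 1.0 and res.k == 4 and res.n == 202

    def test_too_few_raters_rejected(self):
        x = np.array([[1.0], [2.0], [3.0]])
        with pytest.raises(DataError):
            cc.icc_average_absolute(_score_table_from_matrix(x), "c1", "i1")
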