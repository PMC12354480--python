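import itertools

import numpy as np
import pandas as pd
import pytest

from leafn.metrics import (anova_table, pnue, pool_regressions,
                           regressions_to_frame, tukey_letters, two_way_anova)


class TestPnue:
    def test_arithmetic(self):
        assert pnue(15.0, 2.0) == 7.5
        assert pnue(0.0, 2.0) == 0.0

    def test_scale_invariant(self):
        assert pnue(3.0 * 15.0, 3.0 * 2.0) == pytest.approx(pnue(15.0, 2.0))

    def test_nonpositive_na_rejected(self):
        with pytest.raises(ValueError):
            pnue(15.0, 0.0)

    def test_vectorized(self):
        out = pnue(np.array([10.0, 20.0]), np.array([2.0, 4.0]))
        np.testing.assert_allclose(out, [5.0, 5.0])


class TestPoolRegressions:
    def test_perfect_linear_fit(self, rng):
        x = rng.uniform(0, 1, 30)
        df = pd.DataFrame({"n_cb": x, "resp": 2.0 * x, "cultivar": ["A"] * 30})
        (pooled, *_) = pool_regressions(df, "resp", predictors=("n_cb",))
        assert pooled.slope == pytest.approx(2.0)
        assert pooled.r_squared == pytest.approx(1.0)

    def test_orthogonal_predictor_zero_slope(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        y = y - np.polyval(np.polyfit(x, y, 1), x)  # orthogonalize against x
        df = pd.DataFrame({"n_cb": x, "resp": y})
        (res,) = pool_regressions(df, "resp", predictors=("n_cb",), group_column="none")
        assert abs(res.slope) < 1e-9

    def test_constant_predictor_flagged(self):
        df = pd.DataFrame({"n_cb": [1.0] * 10, "resp": np.arange(10.0)})
        (res,) = pool_regressions(df, "resp", predictors=("n_cb",), group_column="none")
        assert "constant-predictor" in res.flags
        assert np.isnan(res.slope)

    def test_per_cultivar_and_pooled_reported(self, rng):
        df = pd.DataFrame(
            {
                "n_cb": rng.uniform(0, 1, 20),
                "resp": rng.uniform(0, 1, 20),
                "cultivar": ["FD"] * 10 + ["JF"] * 10,
            }
        )
        results = pool_regressions(df, "resp", predictors=("n_cb",))
        assert {r.group for r in results} == {"pooled", "FD", "JF"}

    def test_standardized_slope_is_pearson_r(self, rng):
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(size=50)
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        df = pd.DataFrame({"n_cb": xs, "resp": ys})
        (res,) = pool_regressions(df, "resp", predictors=("n_cb",), group_column="none")
        assert res.slope == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_too_few_cases_rejected(self):
        df = pd.DataFrame({"n_cb": [1.0, 2.0], "resp": [1.0, 2.0]})
        with pytest.raises(ValueError, match=">= 3"):
            pool_regressions(df, "resp", predictors=("n_cb",), group_column="none")


def _toy_2x2x2():
    # balanced 2x2 with 2 replicates; small integers so the oracle is exact
    rows = []
    data = {
        ("N0", "A"): (10.0, 12.0),
        ("N0", "B"): (14.0, 16.0),
        ("N1", "A"): (20.0, 22.0),
        ("N1", "B"): (18.0, 20.0),
    }
    for (n, v), ys in data.items():
        for y in ys:
            rows.append({"n_level": n, "cultivar": v, "y": y})
    return pd.DataFrame(rows)


def _manual_balanced_anova(df):
    """Textbook sums-of-squares oracle for a balanced two-way layout."""
    grand = df["y"].mean()
    a_means = df.groupby("n_level")["y"].mean()
    b_means = df.groupby("cultivar")["y"].mean()
    cell_means = df.groupby(["n_level", "cultivar"])["y"].mean()
    n_rep = df.groupby(["n_level", "cultivar"]).size().iloc[0]
    a, b = len(a_means), len(b_means)
    ss_a = n_rep * b * ((a_means - grand) ** 2).sum()
    ss_b = n_rep * a * ((b_means - grand) ** 2).sum()
    ss_cells = n_rep * ((cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_e = ((df["y"] - df.set_index(["n_level", "cultivar"]).index.map(cell_means)) ** 2).sum()
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = len(df) - a * b
    ms = lambda ss, d: ss / d  # noqa: E731
    return {
        "f_a": ms(ss_a, df_a) / ms(ss_e, df_e),
        "f_b": ms(ss_b, df_b) / ms(ss_e, df_e),
        "f_ab": ms(ss_ab, df_ab) / ms(ss_e, df_e),
        "ss": (ss_a, ss_b, ss_ab, ss_e),
    }


class TestTwoWayAnova:
    def test_matches_manual_oracle_on_toy_table(self):
        df = _toy_2x2x2()
        oracle = _manual_balanced_anova(df)
        res = two_way_anova(df, "y")
        assert res.f_nitrogen == pytest.approx(oracle["f_a"], rel=1e-10)
        assert res.f_variety == pytest.approx(oracle["f_b"], rel=1e-10)
        assert res.f_interaction == pytest.approx(oracle["f_ab"], rel=1e-10)

    def test_constant_response_gives_zero_f(self):
        df = _toy_2x2x2()
        df["y"] = 5.0
        res = two_way_anova(df, "y")
        assert res.f_nitrogen == 0.0
        assert res.f_variety == 0.0
        assert res.f_interaction == 0.0

    def test_pure_cultivar_shift(self, rng):
        """Additive cultivar effect only: huge variety F, interaction F near zero."""
        rows = []
        for n, v, r in itertools.product(("N0", "N1", "N2"), ("A", "B"), range(4)):
            y = (10.0 if v == "B" else 0.0) + rng.normal(0, 0.1)
            rows.append({"n_level": n, "cultivar": v, "y": y})
        res = two_way_anova(pd.DataFrame(rows), "y")
        assert res.f_variety > 100 * max(res.f_interaction, 1.0)

    def test_ss_decomposition(self, noisy_dataset):
        """SS(N) + SS(V) + SS(NxV) + SS(resid) = SS(total) on the balanced design."""
        truth = noisy_dataset.truth
        res = two_way_anova(truth, "na")
        parts = res.ss["nitrogen"] + res.ss["variety"] + res.ss["interaction"] + res.ss["residual"]
        assert parts == pytest.approx(res.ss["total"], rel=1e-8)

    def test_empty_cell_rejected(self):
        df = _toy_2x2x2()
        df = df[~((df["n_level"] == "N1") & (df["cultivar"] == "B"))]
        with pytest.raises(ValueError, match="N1"):
            two_way_anova(df, "y")

    def test_anova_table_shape(self, noisy_dataset):
        tab = anova_table(noisy_dataset.truth, ["na", "vcmax"])
        assert len(tab) == 6
        assert set(tab["factor"]) == {"nitrogen", "variety", "interaction"}


def test_tukey_letters_separates_clear_groups(rng):
    df = pd.DataFrame(
        {
            "g": np.repeat(["lo", "mid", "hi"], 10),
            "y": np.concatenate(
                [rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10), rng.normal(10, 0.1, 10)]
            ),
        }
    )
    letters = tukey_letters(df, "y", "g")
    assert len({letters["lo"], letters["mid"], letters["hi"]}) == 3


def test_regressions_to_frame_round_trips(rng):
    df = pd.DataFrame({"n_cb": rng.uniform(0, 1, 12), "resp": rng.uniform(0, 1, 12)})
    frame = regressions_to_frame(
        pool_regressions(df, "resp", predictors=("n_cb",), group_column="none")
    )
    assert list(frame.columns[:3]) == ["predictor", "response", "group"]
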