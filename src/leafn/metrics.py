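"""PNUE, pool-response regressions, and two-way ANOVA for the factorial design.

PNUE (photosynthetic nitrogen use efficiency) is the light-saturated net
photosynthetic rate per unit leaf nitrogen, Asat / Na
(umol CO2 g-1 N s-1). Each nitrogen pool is regressed against Pn and PNUE
by ordinary least squares, per cultivar and pooled; trait responses to the
cultivar x nitrogen factorial are tested with a two-way ANOVA (type-II sums
of squares, which coincide with type I/III on the balanced design).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "AnovaResult",
    "pnue",
    "pool_regressions",
    "two_way_anova",
    "anova_table",
    "regressions_to_frame",
    "tukey_letters",
]


def pnue(asat, na):
    """Photosynthetic nitrogen use efficiency: Asat / Na (umol CO2 g-1 N s-1)."""
    asat = np.asarray(asat, dtype=float)
    na = np.asarray(na, dtype=float)
    if np.any(na <= 0):
        raise ValueError("na must be > 0")
    out = asat / na
    return float(out) if out.ndim == 0 else out


@dataclass
class RegressionResult:
    predictor: str
    response: str
    group: str  # cultivar label or "pooled"
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    flags: list[str] = field(default_factory=list)


def _ols_one(x: np.ndarray, y: np.ndarray, predictor, response, group) -> RegressionResult:
    n = len(x)
    if n < 3:
        raise ValueError(f"{predictor} vs {response} [{group}]: need >= 3 complete cases, got {n}")
    flags = []
    if np.ptp(x) == 0:
        # constant predictor: slope undefined
        return RegressionResult(predictor, response, group, math.nan, float(np.mean(y)),
                                math.nan, math.nan, n, ["constant-predictor"])
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    return RegressionResult(predictor, response, group, float(res.slope),
                            float(res.intercept), float(r2), float(res.pvalue), n, flags)


def pool_regressions(
    table: pd.DataFrame,
    response_column: str,
    predictors: tuple[str, ...] = ("n_cb", "n_et", "n_cl", "n_nonpsn"),
    group_column: str = "cultivar",
    response_label: str | None = None,
) -> list[RegressionResult]:
    """OLS of a response (Pn or PNUE) on each nitrogen pool, per cultivar and pooled.

    ``table`` is wide (one row per sample with pool columns). Rows with a
    missing predictor or response are dropped per regression.
    """
    label = response_label or response_column
    results = []
    groups: list[tuple[str, pd.DataFrame]] = [("pooled", table)]
    if group_column in table.columns:
        groups += [(str(g), sub) for g, sub in table.groupby(group_column, sort=True)]
    for pred in predictors:
        if pred not in table.columns:
            raise KeyError(f"predictor column {pred!r} not in table")
        for gname, sub in groups:
            ok = sub[[pred, response_column]].dropna()
            results.append(
                _ols_one(ok[pred].to_numpy(), ok[response_column].to_numpy(), pred, label, gname)
            )
    return results


def regressions_to_frame(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "predictor": r.predictor, "response": r.response, "group": r.group,
            "slope": r.slope, "intercept": r.intercept, "r_squared": r.r_squared,
            "p_value": r.p_value, "n": r.n, "flags": ";".join(r.flags),
        }
        for r in results
    )


@dataclass
class AnovaResult:
    response: str
    f_nitrogen: float
    f_variety: float
    f_interaction: float
    p_nitrogen: float
    p_variety: float
    p_interaction: float
    df_nitrogen: int
    df_variety: int
    df_interaction: int
    df_residual: int
    ss: dict[str, float] = field(default_factory=dict)


def two_way_anova(
    trait_table: pd.DataFrame,
    response: str,
    nitrogen_column: str = "n_level",
    variety_column: str = "cultivar",
) -> AnovaResult:
    """Two-way ANOVA of a trait over nitrogen level x cultivar (type II SS).

    Requires every factor cell to hold >= 2 replicates. Terms whose sum of
    squares is numerically zero (e.g. a constant response) report F = 0.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = trait_table[[response, nitrogen_column, variety_column]].dropna().copy()
    df.columns = ["y", "N", "V"]
    counts = df.groupby(["N", "V"], sort=True).size()
    full = pd.MultiIndex.from_product([df["N"].unique(), df["V"].unique()])
    empty = [c for c in full if c not in counts.index] + list(counts.index[counts < 2])
    if empty:
        raise ValueError(f"cells with < 2 replicates: {sorted(set(map(tuple, empty)))}")

    model = smf.ols("y ~ C(N) * C(V)", data=df).fit()
    tab = anova_lm(model, typ=2)
    ss_resid = float(tab.loc["Residual", "sum_sq"])
    ss_total = float(((df["y"] - df["y"].mean()) ** 2).sum())

    def term(name):
        ss = float(tab.loc[name, "sum_sq"])
        dfree = int(tab.loc[name, "df"])
        f = float(tab.loc[name, "F"])
        p = float(tab.loc[name, "PR(>F)"])
        if ss <= 1e-12 * max(ss_total, 1.0):  # degenerate (constant) term
            f, p = 0.0, 1.0
        return f, p, dfree, ss

    f_n, p_n, df_n, ss_n = term("C(N)")
    f_v, p_v, df_v, ss_v = term("C(V)")
    f_i, p_i, df_i, ss_i = term("C(N):C(V)")
    return AnovaResult(
        response=response,
        f_nitrogen=f_n, f_variety=f_v, f_interaction=f_i,
        p_nitrogen=p_n, p_variety=p_v, p_interaction=p_i,
        df_nitrogen=df_n, df_variety=df_v, df_interaction=df_i,
        df_residual=int(tab.loc["Residual", "df"]),
        ss={"nitrogen": ss_n, "variety": ss_v, "interaction": ss_i,
            "residual": ss_resid, "total": ss_total},
    )


def anova_table(trait_table: pd.DataFrame, responses: list[str], **kwargs) -> pd.DataFrame:
    """Run two_way_anova over several responses; one tidy row per response x factor."""
    rows = []
    for resp in responses:
        res = two_way_anova(trait_table, resp, **kwargs)
        for factor, f, p, dfree in (
            ("nitrogen", res.f_nitrogen, res.p_nitrogen, res.df_nitrogen),
            ("variety", res.f_variety, res.p_variety, res.df_variety),
            ("interaction", res.f_interaction, res.p_interaction, res.df_interaction),
        ):
            rows.append({"response": resp, "factor": factor, "F": f, "p_value": p, "df": dfree})
    return pd.DataFrame(rows)


def tukey_letters(
    table: pd.DataFrame, response: str, group_column: str, alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display from Tukey HSD at the given alpha.

    Groups sharing a letter are not significantly different. Letters are
    assigned greedily on groups ordered by descending mean.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = table[[response, group_column]].dropna()
    hsd = pairwise_tukeyhsd(df[response], df[group_column], alpha=alpha)
    groups = list(hsd.groupsunique)
    k = len(groups)
    differ = np.zeros((k, k), dtype=bool)
    for (i, j), reject in zip(
        [(i, j) for i in range(k) for j in range(i + 1, k)], hsd.reject
    ):
        differ[i, j] = differ[j, i] = bool(reject)

    order = np.argsort([-df[df[group_column] == g][response].mean() for g in groups])
    letters: dict[int, str] = {i: "" for i in range(k)}
    next_letter = 0
    for idx in order:
        placed = False
        # try to join an existing letter: allowed iff no member of that letter differs
        for letter_ord in range(next_letter):
            letter = chr(ord("a") + letter_ord)
            members = [i for i in range(k) if letter in letters[i]]
            if members and not any(differ[idx, m] for m in members):
                letters[idx] += letter
                placed = True
                break
        if not placed:
            letters[idx] += chr(ord("a") + next_letter)
            next_letter += 1
    return {str(groups[i]): letters[i] for i in range(k)}


def plot_regressions(table: pd.DataFrame, results: list[RegressionResult],
                     response_column: str, path) -> None:
    """Scatter + fitted line per predictor panel (pooled fits). Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pooled = [r for r in results if r.group == "pooled" and not r.flags]
    fig, axes = plt.subplots(1, max(len(pooled), 1), figsize=(4 * max(len(pooled), 1), 3.5))
    axes = np.atleast_1d(axes)
    for ax, res in zip(axes, pooled):
        ok = table[[res.predictor, response_column]].dropna()
        ax.scatter(ok[res.predictor], ok[response_column], s=12)
        xs = np.linspace(ok[res.predictor].min(), ok[res.predictor].max(), 50)
        ax.plot(xs, res.intercept + res.slope * xs, "r-")
        ax.set_xlabel(res.predictor)
        ax.set_ylabel(res.response)
        ax.set_title(f"r2={res.r_squared:.2f}, p={res.p_value:.3g}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
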