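"""Random-forest importance of nitrogen pools with permutation significance.

A bagged regression forest is fit to a response (Pn or PNUE) on nitrogen
pool contents and fractions. Feature importance is %IncMSE: the mean
relative increase in out-of-bag (OOB) mean squared error when a feature's
OOB values are permuted, computed per tree and averaged — the classical
regression-forest importance. Significance follows the permutation scheme
of the rfPermute/A3 lineage, re-implemented: the forest is refit on
response-permuted copies of the data to build a null distribution for each
feature's %IncMSE and for the model's OOB explained variance, and empirical
p-values use +1 smoothing, p = (1 + #{null >= observed}) / (1 + n_perm).

Trees are sklearn ``DecisionTreeRegressor``s with the regression-forest
conventions (features per split = ceil(d/3), unlimited depth, min leaf 5);
the bootstrap, OOB bookkeeping and permutation machinery live here because
per-tree OOB permutation importance and permutation-null refits are not
exposed by stock forest estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ImportanceConfig",
    "FeatureImportance",
    "ImportanceResult",
    "rf_importance",
    "importance_report",
    "significance_stars",
]


@dataclass(frozen=True)
class ImportanceConfig:
    """Forest and permutation-test settings."""

    n_trees: int = 500
    n_null_permutations: int = 100
    seed: int = 0
    response: str = "Pn"
    features: tuple[str, ...] | None = None  # None: caller supplies columns
    max_features: int | None = None  # None: ceil(d / 3)
    min_samples_leaf: int = 5

    def __post_init__(self) -> None:
        if self.n_trees < 100:
            raise ValueError("n_trees must be >= 100")
        if self.n_null_permutations < 50:
            raise ValueError("n_null_permutations must be >= 50")


@dataclass
class FeatureImportance:
    feature: str
    inc_mse_pct: float
    z_score: float
    p_value: float


@dataclass
class ImportanceResult:
    response: str
    features: list[FeatureImportance]  # sorted by inc_mse_pct descending
    explained_variance_pct: float
    model_p_value: float
    oob_mse: float
    n: int
    config: ImportanceConfig = field(repr=False, default=None)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": f.feature,
                "inc_mse_pct": f.inc_mse_pct,
                "z_score": f.z_score,
                "p_value": f.p_value,
                "stars": significance_stars(f.p_value),
            }
            for f in self.features
        )


class _Forest:
    """Minimal bagged regression forest with per-tree OOB permutation importance."""

    def __init__(self, n_trees: int, max_features: int, min_samples_leaf: int):
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf

    def fit(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> "_Forest":
        n = len(y)
        self.X_ = np.asfortranarray(X, dtype=np.float32)
        self.y_ = np.asarray(y, dtype=np.float64)
        self.trees_ = []
        self.oob_ = []
        seeds = rng.integers(0, 2**31 - 1, size=self.n_trees)
        for s in seeds:
            idx = rng.integers(0, n, size=n)
            mask = np.ones(n, dtype=bool)
            mask[idx] = False
            tree = DecisionTreeRegressor(
                max_features=self.max_features,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(s),
            )
            tree.fit(self.X_[idx], self.y_[idx], check_input=False)
            self.trees_.append(tree)
            self.oob_.append(np.flatnonzero(mask))
        return self

    def oob_prediction(self) -> tuple[np.ndarray, np.ndarray]:
        """Aggregate OOB predictions; returns (pred, valid_mask)."""
        n = len(self.y_)
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, oob in zip(self.trees_, self.oob_):
            if len(oob) == 0:
                continue
            total[oob] += tree.predict(
                np.ascontiguousarray(self.X_[oob]), check_input=False
            )
            count[oob] += 1
        valid = count > 0
        pred = np.full(n, np.nan)
        pred[valid] = total[valid] / count[valid]
        return pred, valid

    def oob_mse(self) -> float:
        pred, valid = self.oob_prediction()
        return float(np.mean((self.y_[valid] - pred[valid]) ** 2))

    def explained_variance_pct(self) -> float:
        """OOB pseudo-R2 as a percentage: 100 * (1 - MSE_oob / Var(y))."""
        var = float(np.var(self.y_))
        return 100.0 * (1.0 - self.oob_mse() / var)

    def permutation_importance(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Per-feature %IncMSE and its z-score across trees.

        For each tree: MSE on its OOB rows, then MSE with each feature's OOB
        column permuted (one shared predict call over stacked copies).
        %IncMSE_f = 100 * mean_t(MSE_perm - MSE_oob) / mean_t(MSE_oob);
        z_f = mean_t(diff) / (sd_t(diff) / sqrt(T)).
        """
        d = self.X_.shape[1]
        diffs = np.zeros((self.n_trees, d))
        base = np.zeros(self.n_trees)
        for t, (tree, oob) in enumerate(zip(self.trees_, self.oob_)):
            m = len(oob)
            if m < 2:
                continue
            x_oob = self.X_[oob]
            y_oob = self.y_[oob]
            stacked = np.tile(x_oob, (d + 1, 1))
            for f in range(d):
                perm = rng.permutation(m)
                stacked[(f + 1) * m : (f + 2) * m, f] = x_oob[perm, f]
            pred = tree.predict(np.ascontiguousarray(stacked), check_input=False)
            pred = pred.reshape(d + 1, m)
            errs = np.mean((pred - y_oob) ** 2, axis=1)
            base[t] = errs[0]
            diffs[t] = errs[1:] - errs[0]
        mean_base = float(np.mean(base))
        mean_diff = diffs.mean(axis=0)
        sd_diff = diffs.std(axis=0, ddof=1)
        inc_pct = 100.0 * mean_diff / mean_base if mean_base > 0 else np.zeros(d)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(
                sd_diff > 0, mean_diff / (sd_diff / math.sqrt(self.n_trees)), 0.0
            )
        return inc_pct, z


def _fit_and_score(
    X, y, config: ImportanceConfig, rng
) -> tuple[np.ndarray, np.ndarray, float, float]:
    d = X.shape[1]
    mf = config.max_features or math.ceil(d / 3)
    forest = _Forest(config.n_trees, mf, config.min_samples_leaf).fit(X, y, rng)
    inc, z = forest.permutation_importance(rng)
    mse = forest.oob_mse()
    var = float(np.var(y))
    return inc, z, 100.0 * (1.0 - mse / var), mse


def rf_importance(table: pd.DataFrame, config: ImportanceConfig) -> ImportanceResult:
    """Permutation-tested random-forest importance of features for a response.

    ``table`` must contain the response column (``config.response``, or a
    column literally named as configured) and the feature columns. Rows with
    any missing value are dropped; at least 20 complete rows and 2 features
    are required. Fixed ``config.seed`` makes the result reproducible.
    """
    response_col = config.response
    if response_col not in table.columns:
        raise KeyError(f"response column {response_col!r} not in table")
    features = list(config.features) if config.features else [
        c for c in table.columns if c != response_col
    ]
    if len(features) < 2:
        raise ValueError("need >= 2 feature columns")
    data = table[features + [response_col]].dropna()
    if len(data) < 20:
        raise ValueError(f"need >= 20 complete rows, got {len(data)}")
    y = data[response_col].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response is constant; importance is undefined")
    X = data[features].to_numpy(dtype=float)

    ss = np.random.SeedSequence(config.seed)
    rng_obs, rng_null = (np.random.default_rng(s) for s in ss.spawn(2))

    obs_inc, obs_z, obs_ev, obs_mse = _fit_and_score(X, y, config, rng_obs)

    n_perm = config.n_null_permutations
    null_inc = np.zeros((n_perm, len(features)))
    null_ev = np.zeros(n_perm)
    for k in range(n_perm):
        y_perm = rng_null.permutation(y)
        null_inc[k], _, null_ev[k], _ = _fit_and_score(X, y_perm, config, rng_null)

    p_feat = (1.0 + np.sum(null_inc >= obs_inc[None, :], axis=0)) / (1.0 + n_perm)
    p_model = float((1.0 + np.sum(null_ev >= obs_ev)) / (1.0 + n_perm))

    feats = [
        FeatureImportance(feature=f, inc_mse_pct=float(i), z_score=float(z), p_value=float(p))
        for f, i, z, p in zip(features, obs_inc, obs_z, p_feat)
    ]
    feats.sort(key=lambda fi: fi.inc_mse_pct, reverse=True)
    return ImportanceResult(
        response=config.response,
        features=feats,
        explained_variance_pct=float(obs_ev),
        model_p_value=p_model,
        oob_mse=float(obs_mse),
        n=len(data),
        config=config,
    )


def significance_stars(p: float) -> str:
    """'**' below 0.01, '*' below 0.05, empty otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def importance_report(results: dict[str, ImportanceResult]) -> pd.DataFrame:
    """Combined ranked table with significance stars across responses."""
    frames = []
    for label, res in results.items():
        frame = res.as_frame()
        frame.insert(0, "response", label)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
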