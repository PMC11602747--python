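"""Random-forest permutation importance with a permutation-test null.

Ranks the soil indicators by how much each one contributes to predicting a
plot-level response (mean yield or SYI) with a bagged regression forest:

* **Importance** — the out-of-bag (OOB) mean squared error of the ensemble
  is recomputed with one predictor's OOB values permuted within each tree;
  the importance of predictor *j* is the percent increase of the
  tree-averaged OOB error, ``100 · (MSEⱼ − MSE₀) / MSE₀``.  No train/test
  split is needed: every tree is evaluated only on the samples left out of
  its bootstrap.

* **Significance** — the importance null distribution is built by refitting
  the whole forest on response-permuted data B times; the one-sided
  p-value uses the add-one estimator ``p = (1 + #{null ≥ observed}) /
  (1 + B)`` and therefore can never be exactly 0.

* **Fit quality** — variance explained (%) is ``100 · (1 − MSE_oob /
  Var(y))`` from the aggregated OOB predictions, the bagging analogue of
  R².

Trees are :class:`sklearn.tree.DecisionTreeRegressor` grown on bootstrap
samples drawn by this module, so the OOB sets and every random draw are
under one seeded generator and runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .errors import ConfigError, DegenerateDataError

__all__ = ["ImportanceConfig", "ImportanceResult", "fit_forest_importance",
           "permutation_pvalues", "importance_analysis"]


@dataclass(frozen=True)
class ImportanceConfig:
    """Forest and permutation-test settings.

    Defaults follow regression-forest convention: 1000 trees, a third of
    the predictors tried per split, minimum leaf size 5.
    """

    n_trees: int = 1000
    n_null_permutations: int = 99
    seed: int = 0
    response: str = "response"
    min_samples_leaf: int = 5

    def validate(self) -> None:
        if self.n_trees < 100:
            raise ConfigError("n_trees must be ≥ 100")
        if self.n_null_permutations < 99:
            raise ConfigError("n_null_permutations must be ≥ 99")
        if self.min_samples_leaf < 1:
            raise ConfigError("min_samples_leaf must be ≥ 1")


@dataclass
class ImportanceResult:
    """Per-predictor importance, significance and ranks for one response."""

    table: pd.DataFrame        # predictor, importance, p, rank
    variance_explained: float  # percent, OOB
    config: ImportanceConfig

    def top(self, k: int = 4) -> list[str]:
        return list(self.table.sort_values("rank")["predictor"].head(k))


def _check_inputs(predictors: pd.DataFrame, response) -> tuple[np.ndarray, np.ndarray, list[str]]:
    # canonical (sorted) predictor order: results depend on predictor names
    # and values only, never on the column order of the input frame
    names = sorted(c for c in predictors.columns if c not in ("plot_id", "treatment"))
    x = predictors[names].to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise DegenerateDataError("predictors and response differ in length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise DegenerateDataError("missing values: importance needs complete cases")
    if x.shape[0] < 10:
        raise DegenerateDataError(f"need ≥ 10 observations, got {x.shape[0]}")
    if np.ptp(y) == 0:
        raise DegenerateDataError("constant response; importance undefined")
    return x, y, names


def _forest_importance(x: np.ndarray, y: np.ndarray, config: ImportanceConfig,
                       rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """One forest fit; returns (importance %, OOB variance explained %)."""
    n, p = x.shape
    mtry = max(1, p // 3)
    base_err = 0.0
    perm_err = np.zeros(p)
    used = 0
    oob_pred_sum = np.zeros(n)
    oob_pred_cnt = np.zeros(n)

    for _ in range(config.n_trees):
        idx = rng.integers(0, n, size=n)
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        tree_seed = int(rng.integers(0, 2**31 - 1))
        tree = DecisionTreeRegressor(max_features=mtry,
                                     min_samples_leaf=config.min_samples_leaf,
                                     random_state=tree_seed)
        tree.fit(x[idx], y[idx])
        m = int(oob.sum())
        if m == 0:
            continue
        x_oob = x[oob]
        y_oob = y[oob]
        # one batched predict: baseline block + p permuted blocks
        stacked = np.tile(x_oob, (p + 1, 1))
        for j in range(p):
            block = stacked[(j + 1) * m:(j + 2) * m]
            block[:, j] = x_oob[rng.permutation(m), j]
        pred = tree.predict(stacked)
        baseline = pred[:m]
        oob_pred_sum[oob] += baseline
        oob_pred_cnt[oob] += 1
        base_err += float(((baseline - y_oob) ** 2).mean())
        perm = pred[m:].reshape(p, m)
        perm_err += ((perm - y_oob) ** 2).mean(axis=1)
        used += 1

    if used == 0:
        raise DegenerateDataError("no tree had out-of-bag samples")
    mse0 = base_err / used
    if mse0 == 0.0:
        importance = np.zeros(p)
    else:
        importance = 100.0 * (perm_err / used - mse0) / mse0

    covered = oob_pred_cnt > 0
    ensemble = oob_pred_sum[covered] / oob_pred_cnt[covered]
    mse_oob = float(((ensemble - y[covered]) ** 2).mean())
    var_y = float(y[covered].var())
    variance_explained = 100.0 * (1.0 - mse_oob / var_y)
    return importance, variance_explained


def _rng(config: ImportanceConfig, stream: int) -> np.random.Generator:
    # streams: 10 = observed forest, 11 = permutation null
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def fit_forest_importance(predictors: pd.DataFrame, response,
                          config: ImportanceConfig | None = None) -> ImportanceResult:
    """Fit the forest and rank predictors by OOB permutation importance.

    ``predictors`` is a frame of indicator columns (``plot_id`` and
    ``treatment`` columns are ignored if present); ``response`` a matching
    vector.  The p column is NaN until :func:`permutation_pvalues` (or
    :func:`importance_analysis`) fills it.
    """
    config = config or ImportanceConfig()
    config.validate()
    x, y, names = _check_inputs(predictors, response)
    importance, varexp = _forest_importance(x, y, config, _rng(config, 10))
    order = np.argsort(-importance, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(names) + 1)
    table = pd.DataFrame({
        "predictor": names,
        "importance": importance,
        "p": np.nan,
        "rank": rank,
    })
    return ImportanceResult(table, varexp, config)


def permutation_pvalues(predictors: pd.DataFrame, response,
                        config: ImportanceConfig | None = None,
                        observed: ImportanceResult | None = None) -> pd.Series:
    """Response-permutation p-values for every predictor's importance.

    The forest is refit ``n_null_permutations`` times on a shuffled
    response; each refit yields one null importance vector.  With the
    add-one estimator the smallest attainable p is ``1/(1 + B)``.
    """
    config = config or ImportanceConfig()
    if config.n_null_permutations <= 0:
        raise ConfigError("n_null_permutations must be positive")
    config.validate()
    x, y, names = _check_inputs(predictors, response)
    if observed is None:
        observed = fit_forest_importance(predictors, response, config)
    obs = observed.table.set_index("predictor")["importance"].reindex(names).to_numpy()

    null_rng = _rng(config, 11)
    exceed = np.zeros(len(names))
    for _ in range(config.n_null_permutations):
        y_perm = null_rng.permutation(y)
        null_imp, _ = _forest_importance(x, y_perm, config, null_rng)
        exceed += null_imp >= obs
    p = (1.0 + exceed) / (1.0 + config.n_null_permutations)
    return pd.Series(p, index=pd.Index(names, name="predictor"), name="p")


def importance_analysis(predictors: pd.DataFrame, response,
                        config: ImportanceConfig | None = None) -> ImportanceResult:
    """Importance, ranks, variance explained and permutation p-values."""
    config = config or ImportanceConfig()
    result = fit_forest_importance(predictors, response, config)
    p = permutation_pvalues(predictors, response, config, observed=result)
    result.table["p"] = result.table["predictor"].map(p).to_numpy()
    return result
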