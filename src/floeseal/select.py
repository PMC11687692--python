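"""Variable importance and model selection.

Two selection stages mirror the analysis workflow:

1. A bagged regression forest screens candidate covariates via conditional
   permutation feature importance (CPFI).  Classical permutation importance
   overstates correlated predictors; CPFI permutes each predictor *within
   cells* defined by the quantile grid of its correlated companions
   (|Spearman rho| above a threshold), so a variable only earns importance
   it does not share with its correlates.  The forest itself is a plain
   variance-split bagged ensemble — the conditional correction lives in the
   importance scheme, not the split test.

2. The surviving covariates enter an all-subsets search: every subset, plus
   the always-included segmented floe-area terms, is fitted as a segmented
   NB2 GLM and ranked by AIC; the top models go to k-fold (or
   leave-one-scene-out) cross-validation scored by binned MAPE and per-floe
   RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .segmented import SegmentedNegativeBinomial, fit_nb_glm
from .prediction import error_metrics

__all__ = [
    "BaggedForest",
    "fit_forest",
    "grid_search",
    "cpfi",
    "dredge_aic",
    "cross_validate",
]


# --------------------------------------------------------------------------
# forest
# --------------------------------------------------------------------------

@dataclass
class BaggedForest:
    """Bootstrap-aggregated regression trees with out-of-bag bookkeeping."""

    trees: list = field(default_factory=list)
    boot_idx: list = field(default_factory=list)  # in-bag row indices per tree
    feature_names: list = field(default_factory=list)
    oob_prediction: np.ndarray | None = None
    oob_metrics: dict = field(default_factory=dict)
    bootstrap: bool = True

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.mean([t.predict(X) for t in self.trees], axis=0)

    def oob_predict(self, X) -> np.ndarray:
        """OOB-honest prediction on the *training* rows of X.

        For each row, average only the trees whose bootstrap sample did not
        contain that row (requires ``X`` row-aligned with the training data).
        """
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        acc = np.zeros(n)
        cnt = np.zeros(n)
        for t, idx in zip(self.trees, self.boot_idx):
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            if oob.any():
                acc[oob] += t.predict(X[oob])
                cnt[oob] += 1
        with np.errstate(invalid="ignore"):
            pred = acc / cnt
        return pred


def _oob_metrics(y, pred) -> dict:
    ok = np.isfinite(pred)
    y, pred = y[ok], pred[ok]
    resid = y - pred
    ss = np.sum((y - y.mean()) ** 2)
    return {
        "rmse": float(np.sqrt(np.mean(resid ** 2))),
        "mae": float(np.mean(np.abs(resid))),
        "r2": float(1.0 - np.sum(resid ** 2) / ss) if ss > 0 else np.nan,
        # exact-match rate of the rounded prediction; reported only, never
        # used for selection (counts have no natural classification accuracy)
        "accuracy": float(np.mean(np.round(pred) == y)),
    }


def fit_forest(features: pd.DataFrame, y, ntree: int = 500, mtry: int | None = None,
               seed: int = 0, bootstrap: bool = True,
               min_samples_leaf: int = 5) -> BaggedForest:
    """Fit a bagged regression forest and score it on out-of-bag rows."""
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    names = list(features.columns) if isinstance(features, pd.DataFrame) else [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError(f"need at least 10 observations to grow a forest, got {n}")
    if ntree < 1:
        raise ValueError("ntree must be >= 1")
    mtry = mtry or max(1, p // 3)
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry must be in [1, {p}]")
    rng = np.random.default_rng(seed)
    forest = BaggedForest(feature_names=names, bootstrap=bootstrap)
    leaf = min_samples_leaf if bootstrap else 1
    for b in range(ntree):
        idx = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        tree = DecisionTreeRegressor(
            max_features=mtry, min_samples_leaf=leaf,
            random_state=int(rng.integers(0, 2**31 - 1)))
        tree.fit(X[idx], y[idx])
        forest.trees.append(tree)
        forest.boot_idx.append(idx)
    if bootstrap:
        forest.oob_prediction = forest.oob_predict(X)
        forest.oob_metrics = _oob_metrics(y, forest.oob_prediction)
    return forest


def grid_search(features: pd.DataFrame, y, ntree_grid, mtry_grid, seed: int = 0):
    """Exhaustive (ntree, mtry) search scored by OOB RMSE.

    Ties break toward the smaller ntree, then smaller mtry.  Returns
    ``(best_params, table)``.
    """
    ntree_grid, mtry_grid = list(ntree_grid), list(mtry_grid)
    if not ntree_grid or not mtry_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    rows = []
    for nt in ntree_grid:
        for mt in mtry_grid:
            f = fit_forest(features, y, ntree=nt, mtry=mt, seed=seed)
            rows.append({"ntree": nt, "mtry": mt, **f.oob_metrics})
    table = pd.DataFrame(rows)
    order = table.sort_values(["rmse", "ntree", "mtry"],
                              kind="mergesort").iloc[0]
    best = {"ntree": int(order["ntree"]), "mtry": int(order["mtry"])}
    return best, table


# --------------------------------------------------------------------------
# conditional permutation feature importance
# --------------------------------------------------------------------------

def _condition_cells(X: np.ndarray, conditioners: list[int], n_bins: int) -> np.ndarray:
    """Cell label per row from the quantile grid of the conditioning columns.

    The bin count is reduced until every occupied cell holds >= 2 rows (a
    singleton cell cannot be permuted).
    """
    n = X.shape[0]
    if not conditioners:
        return np.zeros(n, dtype=int)
    for nb in range(n_bins, 0, -1):
        labels = np.zeros(n, dtype=np.int64)
        for c in conditioners:
            qs = np.quantile(X[:, c], np.linspace(0, 1, nb + 1)[1:-1])
            labels = labels * (nb + 1) + np.searchsorted(qs, X[:, c], side="right")
        _, labels = np.unique(labels, return_inverse=True)
        counts = np.bincount(labels)
        if counts.min() >= 2:
            return labels
    return np.zeros(n, dtype=int)


def cpfi(forest: BaggedForest, features: pd.DataFrame, y,
         cond_threshold: float = 0.2, n_bins: int = 4, n_perm: int = 10,
         seed: int = 0) -> pd.DataFrame:
    """Conditional permutation feature importance on OOB error.

    For each predictor: find companions with |Spearman rho| above
    ``cond_threshold``, bin the data on their quantile grid, permute the
    predictor within bins, and record the increase in OOB MSE; importance is
    the mean over ``n_perm`` permutations (SD reported alongside).  With
    ``cond_threshold > 1`` no conditioning ever triggers and the measure
    reduces to classical permutation importance.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    base_pred = forest.oob_predict(X)
    ok = np.isfinite(base_pred)
    base_mse = np.mean((y[ok] - base_pred[ok]) ** 2)
    with np.errstate(invalid="ignore"):  # constant columns yield nan rho
        rho = stats.spearmanr(X).statistic if p > 1 else np.ones((1, 1))
    rho = np.atleast_2d(rho)
    rows = []
    for j in range(p):
        if np.ptp(X[:, j]) == 0:
            import warnings
            warnings.warn(f"predictor {forest.feature_names[j]} is constant; "
                          "importance set to 0")
            rows.append({"predictor": forest.feature_names[j], "importance": 0.0,
                         "sd": 0.0, "n_conditioners": 0, "conditioners": ""})
            continue
        conds = [k for k in range(p)
                 if k != j and np.isfinite(rho[j, k]) and abs(rho[j, k]) > cond_threshold]
        cells = _condition_cells(X, conds, n_bins)
        deltas = np.empty(n_perm)
        Xp = X.copy()
        for r in range(n_perm):
            for cell in np.unique(cells):
                rows_in = np.flatnonzero(cells == cell)
                Xp[rows_in, j] = X[rng.permutation(rows_in), j]
            pred = forest.oob_predict(Xp)
            okp = np.isfinite(pred)
            deltas[r] = np.mean((y[okp] - pred[okp]) ** 2) - base_mse
        Xp[:, j] = X[:, j]
        rows.append({"predictor": forest.feature_names[j],
                     "importance": float(deltas.mean()),
                     "sd": float(deltas.std(ddof=1)) if n_perm > 1 else 0.0,
                     "n_conditioners": len(conds),
                     "conditioners": ",".join(forest.feature_names[k] for k in conds)})
    table = pd.DataFrame(rows)
    table["rank"] = table["importance"].rank(ascending=False).astype(int)
    return table.sort_values("rank", ignore_index=True)


# --------------------------------------------------------------------------
# all-subsets AIC and cross-validation
# --------------------------------------------------------------------------

def dredge_aic(data: pd.DataFrame, y_col: str = "seal_count",
               seg_col: str = "area", optional_terms=(), n_breakpoints: int = 2,
               init="quantile", refit_breakpoints: bool = True,
               psi=None) -> pd.DataFrame:
    """Rank every covariate subset of a segmented NB2 model by AIC.

    The segmented floe-area terms (and intercept) are in every model; each of
    the ``2^p`` subsets of ``optional_terms`` is added in turn.  Set
    ``refit_breakpoints=False`` with explicit ``psi`` to hold breakpoints
    fixed across subsets (cheaper).  Non-converged fits are kept in the table
    with ``converged=False`` but excluded from the ranking.
    """
    optional_terms = list(optional_terms)
    p = len(optional_terms)
    if p > 12:
        raise ValueError("more than 12 optional terms (2^p fits) is not supported")
    y = data[y_col].to_numpy()
    seg = data[seg_col].to_numpy(dtype=float)
    rows = []
    for r in range(p + 1):
        for subset in combinations(optional_terms, r):
            exog = np.column_stack(
                [np.ones(len(data))] + [data[t].to_numpy(dtype=float) for t in subset])
            names = ["const"] + list(subset)
            try:
                if refit_breakpoints or psi is None:
                    model = SegmentedNegativeBinomial(
                        y, exog, seg, n_breakpoints=n_breakpoints, exog_names=names)
                    fit = model.fit(init=init)
                    k_par, llf, aic, conv = fit.k_params, fit.llf, fit.aic, fit.converged
                else:
                    psi_arr = np.asarray(psi, dtype=float)
                    design = np.column_stack(
                        [exog, seg[:, None],
                         np.maximum(0.0, seg[:, None] - psi_arr[None, :])])
                    fit = fit_nb_glm(design, y, exog_names=names + [seg_col] +
                                     [f"hinge_{i+1}" for i in range(len(psi_arr))],
                                     se=False)
                    k_par = len(fit.params) + 1
                    llf, aic, conv = fit.llf, 2 * k_par - 2 * fit.llf, fit.converged
                rows.append({"terms": "+".join(subset) or "(none)",
                             "k": k_par, "llf": llf, "aic": aic,
                             "converged": conv})
            except (RuntimeError, ValueError) as exc:
                rows.append({"terms": "+".join(subset) or "(none)", "k": np.nan,
                             "llf": np.nan, "aic": np.nan, "converged": False,
                             "error": str(exc)})
    table = pd.DataFrame(rows)
    ok = table["converged"].fillna(False).astype(bool) & table["aic"].notna()
    best = table.loc[ok, "aic"].min()
    table["delta_aic"] = np.where(ok, table["aic"] - best, np.nan)
    table["rank"] = table["delta_aic"].rank(method="first")
    return table.sort_values("rank", ignore_index=True)


def _kfold_indices(n: int, k: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return [np.sort(perm[i::k]) for i in range(k)]


def cross_validate(models: list[dict], data: pd.DataFrame, scheme: str = "kfold",
                   k: int = 5, seed: int = 0, y_col: str = "seal_count",
                   seg_col: str = "area", scene_col: str = "scene_id",
                   n_breakpoints: int = 2, init="quantile") -> dict:
    """Held-out MAPE/RMSE for candidate models; pick the best.

    ``models`` is a list of ``{"terms": [...]}`` covariate subsets.  Scheme
    "kfold" uses ``k`` shuffled folds (sizes differing by at most one);
    "leave-one-scene-out" holds out each scene in turn.  The final choice is
    the lowest mean held-out MAPE, ties broken by RMSE.
    """
    if not models:
        raise ValueError("need at least one candidate model")
    rng = np.random.default_rng(seed)
    if scheme == "kfold":
        folds = _kfold_indices(len(data), k, rng)
        labels = [f"fold_{i}" for i in range(k)]
    elif scheme in ("leave-one-scene-out", "loo-scene"):
        scenes = np.unique(data[scene_col])
        if scenes.size < 2:
            raise ValueError("leave-one-scene-out needs at least two scenes")
        folds = [np.flatnonzero(data[scene_col].to_numpy() == s) for s in scenes]
        labels = [f"scene_{s}" for s in scenes]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    per_fold = []
    summary = []
    for mi, spec in enumerate(models):
        terms = list(spec["terms"])
        mapes, rmses = [], []
        for lab, test_idx in zip(labels, folds):
            train = data.drop(data.index[test_idx])
            test = data.iloc[test_idx]
            exog = np.column_stack(
                [np.ones(len(train))] + [train[t].to_numpy(dtype=float) for t in terms])
            fit = SegmentedNegativeBinomial(
                train[y_col].to_numpy(), exog, train[seg_col].to_numpy(dtype=float),
                n_breakpoints=n_breakpoints,
                exog_names=["const"] + terms).fit(init=init)
            exog_t = np.column_stack(
                [np.ones(len(test))] + [test[t].to_numpy(dtype=float) for t in terms])
            mu = fit.predict(exog_t, seg_values=test[seg_col].to_numpy(dtype=float))
            m = error_metrics(test[y_col].to_numpy(), mu,
                              area=test[seg_col].to_numpy(dtype=float))
            mapes.append(m["mape"])
            rmses.append(m["rmse"])
            per_fold.append({"model": mi, "terms": "+".join(terms) or "(none)",
                             "fold": lab, **m})
        summary.append({"model": mi, "terms": "+".join(terms) or "(none)",
                        "mape": float(np.mean(mapes)), "rmse": float(np.mean(rmses))})
    summary = pd.DataFrame(summary).sort_values(
        ["mape", "rmse"], kind="mergesort", ignore_index=True)
    return {"scheme": scheme, "seed": seed, "per_fold": pd.DataFrame(per_fold),
            "summary": summary, "best": summary.iloc[0].to_dict()}
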