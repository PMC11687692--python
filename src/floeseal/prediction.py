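"""Prediction, bootstrap uncertainty, aggregation and residual diagnostics.

Scene-level abundance is the sum of per-floe expected counts; uncertainty
comes from nonparametric case resampling of floes (refit per replicate), with
confidence intervals as percentile bands of the replicate means and
prediction intervals as percentile bands of NB2 draws from each replicate's
(mu, theta) — so the PI carries both parameter and sampling noise and its
support is the non-negative integers.

MAPE needs care for counts that are mostly zero: the per-floe ratio is
undefined at zero observations, so MAPE here compares observed and predicted
*totals within log-spaced floe-size bins* (zero-observation bins dropped);
RMSE stays per-floe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "predict_counts",
    "bootstrap_intervals",
    "error_metrics",
    "binned_mape",
    "white_test",
    "residual_diagnostics",
    "scene_summary",
]


def predict_counts(model, floes: pd.DataFrame) -> np.ndarray:
    """Per-floe expected counts mu from a fitted or generative model.

    ``model`` is either a :class:`~floeseal.synth.SegmentedModelSpec` (has a
    ``mu`` method) or a fitted :class:`~floeseal.segmented.SegmentedNBResults`
    whose covariates are columns of ``floes``.
    """
    if hasattr(model, "mu"):
        try:
            return model.mu(floes)
        except KeyError as exc:
            raise ValueError(f"missing model covariates: [{exc.args[0]!r}]") from exc
    base_cols = [c for c in model.exog_names
                 if c != model.seg_name and not c.startswith("hinge_")]
    missing = [c for c in base_cols + [model.seg_name]
               if c != "const" and c not in floes.columns]
    if missing:
        raise ValueError(f"missing model covariates: {missing}")
    exog = np.column_stack([
        np.ones(len(floes)) if c == "const" else floes[c].to_numpy(dtype=float)
        for c in base_cols])
    return model.predict(exog, seg_values=floes[model.seg_name].to_numpy(dtype=float))


def bootstrap_intervals(fit_fn, data: pd.DataFrame, n_boot: int = 1000,
                        level: float = 0.95, seed: int = 0,
                        scene_col: str = "scene_id",
                        max_failure_rate: float = 0.05) -> dict:
    """Case-resampling bootstrap CIs and PIs for per-floe and scene counts.

    ``fit_fn(resampled_df)`` must return an object with a ``theta`` attribute
    that :func:`predict_counts` accepts; it is called on each of ``n_boot``
    resamples and its predictions are evaluated on the *original* floes.
    Raises RuntimeError when more than ``max_failure_rate`` of replicates
    fail to fit.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(data)
    alpha = (1.0 - level) / 2.0
    mus = np.empty((n_boot, n))
    draws = np.empty((n_boot, n), dtype=np.int64)
    failures = []
    b = 0
    attempts = 0
    while b < n_boot:
        attempts += 1
        sample = data.iloc[rng.integers(0, n, size=n)].reset_index(drop=True)
        try:
            fit = fit_fn(sample)
            mu = np.clip(predict_counts(fit, data), 1e-12, None)
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
            failures.append(str(exc))
            if len(failures) > max_failure_rate * n_boot:
                raise RuntimeError(
                    f"{len(failures)} of {attempts} bootstrap refits failed "
                    f"(> {max_failure_rate:.0%} of n_boot); diagnostics: "
                    + "; ".join(failures[:3])) from exc
            continue
        theta = float(fit.theta)
        mus[b] = mu
        draws[b] = rng.negative_binomial(theta, theta / (theta + mu))
        b += 1

    per_floe = pd.DataFrame({
        "mu_hat": mus.mean(axis=0),
        "ci_lo": np.quantile(mus, alpha, axis=0),
        "ci_hi": np.quantile(mus, 1 - alpha, axis=0),
        "pi_lo": np.quantile(draws, alpha, axis=0),
        "pi_hi": np.quantile(draws, 1 - alpha, axis=0),
    })
    scenes = None
    if scene_col in data.columns:
        rows = []
        scene_ids = data[scene_col].to_numpy()
        for s in np.unique(scene_ids):
            sel = scene_ids == s
            totals_mu = mus[:, sel].sum(axis=1)
            totals_draw = draws[:, sel].sum(axis=1)
            rows.append({
                "scene_id": s,
                "predicted": float(per_floe.loc[sel, "mu_hat"].sum()),
                "ci_lo": float(np.quantile(totals_mu, alpha)),
                "ci_hi": float(np.quantile(totals_mu, 1 - alpha)),
                "pi_lo": float(np.quantile(totals_draw, alpha)),
                "pi_hi": float(np.quantile(totals_draw, 1 - alpha)),
            })
        scenes = pd.DataFrame(rows)
    return {"per_floe": per_floe, "per_scene": scenes, "n_boot": n_boot,
            "level": level, "n_failures": len(failures)}


def error_metrics(observed, predicted, area=None, n_bins: int = 20) -> dict:
    """Per-floe RMSE and size-bin-aggregated MAPE.

    RMSE is the usual root-mean-square error on floe counts.  MAPE averages
    |observed - predicted| / observed over bin totals: log-spaced floe-size
    bins when ``area`` is given, equal-count groups in the given order
    otherwise; zero-observation bins are dropped.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    if area is not None:
        return {"rmse": rmse,
                "mape": binned_mape(observed, predicted, area, n_bins=n_bins)}
    groups = np.array_split(np.arange(observed.size), min(n_bins, observed.size))
    obs_t = np.array([observed[g].sum() for g in groups])
    pred_t = np.array([predicted[g].sum() for g in groups])
    keep = obs_t > 0
    if not keep.any():
        raise ValueError("all aggregation bins have zero observed counts; MAPE undefined")
    mape = float(np.mean(np.abs(obs_t[keep] - pred_t[keep]) / obs_t[keep]) * 100.0)
    return {"rmse": rmse, "mape": mape}


def binned_mape(observed, predicted, area, n_bins: int = 20) -> float:
    """MAPE on observed vs predicted totals in log-spaced floe-size bins."""
    area = np.asarray(area, dtype=float)
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    edges = np.geomspace(area.min(), area.max() * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.digitize(area, edges) - 1, 0, n_bins - 1)
    obs_t = np.bincount(which, weights=observed, minlength=n_bins)
    pred_t = np.bincount(which, weights=predicted, minlength=n_bins)
    keep = obs_t > 0
    if not keep.any():
        raise ValueError("all size bins have zero observed counts; MAPE undefined")
    return float(np.mean(np.abs(obs_t[keep] - pred_t[keep]) / obs_t[keep]) * 100.0)


def scene_summary(data: pd.DataFrame, mu: np.ndarray,
                  scene_col: str = "scene_id", y_col: str = "seal_count",
                  area_col: str = "area", n_bins: int = 20) -> pd.DataFrame:
    """Per-scene observed/predicted totals with RMSE and binned MAPE."""
    rows = []
    for s, grp in data.groupby(scene_col):
        sel = data[scene_col] == s
        m = mu[np.asarray(sel)]
        rows.append({
            "scene_id": s,
            "observed": int(grp[y_col].sum()),
            "predicted": float(m.sum()),
            "rmse": float(np.sqrt(np.mean((grp[y_col].to_numpy() - m) ** 2))),
            "mape": binned_mape(grp[y_col].to_numpy(), m,
                                grp[area_col].to_numpy(), n_bins=n_bins),
        })
    return pd.DataFrame(rows)


def plot_area_response(model, area_max: float = 500.0, covariates=None,
                       observed: pd.DataFrame | None = None, ax=None):
    """Plot expected seal count against floe area at fixed covariates.

    ``covariates`` maps the non-area covariates to the values held fixed
    (default: zero). Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    a = np.linspace(1.0, area_max, 512)
    base = {"rough_1000": 0.0, "sic_750": 0.0, "colony_dist": 0.0,
            **(covariates or {})}
    floes = pd.DataFrame({"area": a, **{k: np.full(a.size, v)
                                        for k, v in base.items()}})
    ax.plot(a, predict_counts(model, floes), color="firebrick",
            label="expected count")
    if observed is not None:
        ax.scatter(observed["area"], observed["seal_count"], s=4, alpha=0.3,
                   color="steelblue", label="observed")
    ax.set_xlabel("floe area (m$^2$)")
    ax.set_ylabel("seals per floe")
    ax.legend()
    return ax


def white_test(resid, mu) -> dict:
    """White's heteroscedasticity test, LM form.

    Regresses squared residuals on (1, mu, mu^2); the statistic n R^2 is
    referred to chi^2(2).
    """
    resid = np.asarray(resid, dtype=float)
    mu = np.asarray(mu, dtype=float)
    n = resid.size
    aux = np.column_stack([np.ones(n), mu, mu ** 2])
    e2 = resid ** 2
    coef, *_ = np.linalg.lstsq(aux, e2, rcond=None)
    fitted = aux @ coef
    ss_res = np.sum((e2 - fitted) ** 2)
    ss_tot = np.sum((e2 - e2.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    lm = n * r2
    return {"lm": float(lm), "p": float(stats.chi2.sf(lm, df=2))}


def residual_diagnostics(fit, data: pd.DataFrame, y_col: str = "seal_count") -> dict:
    """Pearson-residual correlation and White's heteroscedasticity test.

    Pearson residuals r_i = (y_i - mu_i) / sqrt(mu_i + mu_i^2 / theta) are
    correlated against mu_i (Fisher-z 95% CI); White's test is the LM form —
    regress r_i^2 on (1, mu_i, mu_i^2) and refer n R^2 to chi^2(2).
    """
    if len(data) < 30:
        raise ValueError("residual diagnostics need at least 30 observations")
    y = data[y_col].to_numpy(dtype=float)
    mu = np.asarray(predict_counts(fit, data), dtype=float)
    if np.ptp(mu) < 1e-12:
        raise ValueError("fitted means are constant; residual correlation undefined")
    var = mu + mu ** 2 / fit.theta
    resid = np.divide(y - mu, np.sqrt(var), out=np.zeros_like(mu),
                      where=var > 0)
    if np.ptp(resid) < 1e-12:
        raise ValueError("residuals are constant; correlation undefined")
    r, p_r = stats.pearsonr(resid, mu)
    n = len(y)
    z = np.arctanh(r)
    zse = 1.0 / np.sqrt(n - 3)
    ci = (float(np.tanh(z - 1.959964 * zse)), float(np.tanh(z + 1.959964 * zse)))

    w = white_test(resid, mu)
    return {"pearson_r": float(r), "pearson_ci": ci, "pearson_p": float(p_r),
            "white_lm": w["lm"], "white_p": w["p"]}
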