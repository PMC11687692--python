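"""Negative-binomial GLMs with estimated breakpoints in a segmented covariate.

The centrepiece is :class:`SegmentedNegativeBinomial`, a statsmodels-style model
for counts whose log-mean is piecewise linear in one covariate (here, ice-floe
area) with unknown breakpoint locations, on top of ordinary log-linear terms:

    log mu_i = x_i' beta  +  b1 * a_i  +  sum_k  d_k * h(a_i, psi_k)

where ``h(a, psi) = max(0, a - psi)`` is the hinge basis, ``d_k`` are slope
*increments* at each breakpoint ``psi_k``, and the counts are NB2,
``Var = mu + mu^2 / theta``.  Breakpoints are estimated by iterative
linearization: at the current psi the model is augmented with the indicator
column ``V_k = -1{a > psi_k}``; the fitted ratio ``gamma_k / d_k`` is the
first-order correction to ``psi_k``.  Iterating to a fixed point maximises the
profile likelihood in psi; the delta method on the ratio gives a standard
error for each breakpoint.

Also here: a plain NB2 GLM wrapper and the candidate-distribution comparison
(Poisson / NB / Gamma / Exponential / Log-normal with a log-linear mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

import statsmodels.api as sm
from statsmodels.tools import numdiff

__all__ = [
    "NBGLMResults",
    "SegmentedNBResults",
    "SegmentedNegativeBinomial",
    "fit_nb_glm",
    "fit_segmented",
    "hinge_design",
    "compare_distributions",
]


# --------------------------------------------------------------------------
# hinge basis
# --------------------------------------------------------------------------

def hinge_design(x, breakpoints):
    """Hinge columns ``h(x, psi) = max(0, x - psi)``, one per breakpoint.

    Parameters
    ----------
    x : array-like
        Values of the segmented covariate.
    breakpoints : sequence of float
        Strictly increasing breakpoint locations; each must lie inside the
        observed range of ``x``.

    Returns
    -------
    ndarray of shape (n, len(breakpoints))
    """
    x = np.asarray(x, dtype=float)
    psis = np.atleast_1d(np.asarray(breakpoints, dtype=float))
    if psis.size > 1 and np.any(np.diff(psis) <= 0):
        raise ValueError(f"breakpoints must be strictly increasing, got {psis.tolist()}")
    lo, hi = x.min(), x.max()
    outside = (psis <= lo) | (psis >= hi)
    if np.any(outside):
        raise ValueError(
            f"breakpoints {psis[outside].tolist()} lie outside the observed "
            f"range ({lo:g}, {hi:g}) of the segmented covariate"
        )
    return np.maximum(0.0, x[:, None] - psis[None, :])


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by greedy QR-style scan
        bad = []
        keep: list[int] = []
        for j in range(design.shape[1]):
            cand = design[:, keep + [j]]
            if np.linalg.matrix_rank(cand) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


# --------------------------------------------------------------------------
# plain NB2 GLM
# --------------------------------------------------------------------------

@dataclass
class NBGLMResults:
    """ML fit of a log-link NB2 regression.

    ``params``/``bse`` cover the mean-model coefficients; the dispersion
    ``theta`` (Var = mu + mu^2/theta) is reported separately with its own
    delta-method SE.  ``aic = 2k - 2 llf`` with k counting theta.
    """

    params: pd.Series
    bse: pd.Series
    theta: float
    theta_se: float
    llf: float
    aic: float
    converged: bool
    n_iter: int
    exog_names: list[str] = field(default_factory=list)

    @property
    def k_params(self) -> int:
        return len(self.params) + 1

    def linear_predictor(self, exog) -> np.ndarray:
        return np.asarray(exog, dtype=float) @ self.params.to_numpy()

    def predict(self, exog) -> np.ndarray:
        """Expected counts mu = exp(x'beta)."""
        return np.exp(self.linear_predictor(exog))

    def summary(self) -> str:
        lines = ["NB2 GLM (log link)", "-" * 46]
        lines.append(f"{'term':<24}{'coef':>10}{'se':>10}")
        for name in self.params.index:
            lines.append(f"{name:<24}{self.params[name]:>10.4g}{self.bse[name]:>10.3g}")
        lines.append(f"{'theta':<24}{self.theta:>10.4g}{self.theta_se:>10.3g}")
        lines.append(f"loglik {self.llf:.2f}   AIC {self.aic:.2f}   "
                     f"converged {self.converged} in {self.n_iter} it.")
        return "\n".join(lines)


def _nb2_loglik(y, mu, theta):
    mu = np.clip(mu, 1e-12, None)
    return float(np.sum(
        special.gammaln(y + theta) - special.gammaln(theta) - special.gammaln(y + 1)
        + theta * np.log(theta / (theta + mu)) + y * np.log(mu / (theta + mu))))


_LOG_THETA_MAX = 14.0  # theta ~ 1.2e6: operational Poisson limit


def fit_nb_glm(design, y, exog_names=None, start_params=None, maxiter=100,
               tol=1e-8, se=True) -> NBGLMResults:
    """Fit an NB2 count regression with log link by maximum likelihood.

    Alternates IRLS for the mean coefficients (at fixed dispersion) with a
    one-dimensional profile maximisation of the likelihood in log(theta),
    until the joint log-likelihood stabilises.  Standard errors come from
    the observed information of the joint (beta, log theta) likelihood.

    Parameters
    ----------
    design : (n, k) array or DataFrame
        Covariate matrix including the intercept column.
    y : (n,) array of non-negative integer counts.
    exog_names : optional column names (taken from a DataFrame when passed).
    start_params : optional warm start ``[beta..., alpha]``, ``alpha = 1/theta``.

    Raises
    ------
    ValueError on rank-deficient designs (names the collinear columns).
    """
    if isinstance(design, pd.DataFrame):
        exog_names = list(design.columns)
        design = design.to_numpy(dtype=float)
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if design.ndim != 2 or design.shape[0] != len(y):
        raise ValueError("design and y have incompatible shapes")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("y must contain non-negative integer counts")
    if exog_names is None:
        exog_names = [f"x{j}" for j in range(design.shape[1])]
    _check_full_rank(design, exog_names)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if start_params is not None:
            beta = np.asarray(start_params[:-1], dtype=float)
            log_theta = float(np.clip(-np.log(max(start_params[-1], 1e-10)),
                                      -3.0, _LOG_THETA_MAX))
        else:
            pois = sm.GLM(y, design, family=sm.families.Poisson()).fit(maxiter=50)
            beta = np.asarray(pois.params, dtype=float)
            mu = np.clip(pois.fittedvalues, 1e-10, None)
            excess = np.sum((y - mu) ** 2 - mu)
            alpha0 = max(excess / np.sum(mu ** 2), 1e-4)
            log_theta = float(np.clip(-np.log(alpha0), -3.0, _LOG_THETA_MAX))

        llf = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            fam = sm.families.NegativeBinomial(alpha=np.exp(-log_theta))
            try:
                glm = sm.GLM(y, design, family=fam).fit(start_params=beta, maxiter=50)
            except ValueError:
                # a stale warm start can land outside the family's domain;
                # fall back to the family's own initialisation
                glm = sm.GLM(y, design, family=fam).fit(maxiter=100)
            beta = np.asarray(glm.params, dtype=float)
            mu = np.clip(np.exp(np.clip(design @ beta, -500, 500)), 1e-12, None)

            neg = lambda lt: -_nb2_loglik(y, mu, np.exp(lt))
            res = optimize.minimize_scalar(
                neg, bounds=(-6.0, _LOG_THETA_MAX), method="bounded",
                options={"xatol": 1e-8})
            log_theta = float(res.x)
            new_llf = -float(res.fun)
            if abs(new_llf - llf) < tol * (1.0 + abs(new_llf)):
                llf = new_llf
                converged = True
                break
            llf = new_llf
        theta = float(np.exp(log_theta))

        # observed information of the joint (beta, log theta) likelihood
        def joint_ll(p):
            m = np.clip(np.exp(np.clip(design @ p[:-1], -500, 500)), 1e-12, None)
            return _nb2_loglik(y, m, np.exp(p[-1]))

        joint = np.append(beta, log_theta)
        bse_beta = np.full(design.shape[1], np.nan)
        lt_se = np.nan
        if se:
            try:
                hess = numdiff.approx_hess1(joint, joint_ll)
                cov = np.linalg.inv(-hess)
                d = np.diag(cov)
                if np.all(d[:-1] > 0):
                    bse_beta = np.sqrt(d[:-1])
                if d[-1] > 0:
                    lt_se = np.sqrt(d[-1])
            except np.linalg.LinAlgError:
                pass
    theta_se = theta * lt_se if np.isfinite(lt_se) else np.nan
    k = design.shape[1] + 1
    return NBGLMResults(
        params=pd.Series(beta, index=exog_names),
        bse=pd.Series(bse_beta, index=exog_names),
        theta=theta,
        theta_se=theta_se,
        llf=llf,
        aic=2 * k - 2 * llf,
        converged=converged,
        n_iter=n_iter,
        exog_names=exog_names,
    )


# --------------------------------------------------------------------------
# segmented model
# --------------------------------------------------------------------------

@dataclass
class SegmentedNBResults(NBGLMResults):
    """Results of a segmented NB2 fit.

    In ``params`` the segmented covariate appears as its first-segment slope
    plus one hinge *increment* per breakpoint (columns ``hinge_1``, ...); the
    derived per-segment slopes are in :attr:`segment_slopes`.  ``psi`` holds
    the estimated breakpoint locations with delta-method SEs in ``psi_se``.
    ``aic`` counts each breakpoint as a parameter.
    """

    psi: np.ndarray = field(default_factory=lambda: np.empty(0))
    psi_se: np.ndarray = field(default_factory=lambda: np.empty(0))
    seg_name: str = "area"
    trace: list = field(default_factory=list)
    n_starts: int = 1

    @property
    def k_params(self) -> int:
        return len(self.params) + len(self.psi) + 1

    @property
    def segment_slopes(self) -> np.ndarray:
        """Per-segment slopes of log mu in the segmented covariate."""
        base = self.params[self.seg_name]
        incs = [self.params[f"hinge_{k + 1}"] for k in range(len(self.psi))]
        return np.cumsum([base] + incs)

    def predict(self, exog=None, seg_values=None, data=None) -> np.ndarray:
        """Expected counts; pass either a full design or (exog, seg_values)."""
        if data is not None:
            exog, seg_values = _split_frame(data, self.exog_names, self.seg_name)
        if seg_values is not None:
            exog = np.column_stack([
                np.asarray(exog, dtype=float),
                np.asarray(seg_values, dtype=float),
                np.maximum(0.0, np.asarray(seg_values, dtype=float)[:, None]
                           - self.psi[None, :]),
            ])
        return np.exp(np.asarray(exog, dtype=float) @ self.params.to_numpy())

    def summary(self) -> str:
        lines = ["Segmented NB2 GLM (log link)", "=" * 56]
        lines.append(f"{'term':<28}{'coef':>12}{'se':>10}")
        for name in self.params.index:
            lines.append(f"{name:<28}{self.params[name]:>12.4g}{self.bse[name]:>10.3g}")
        for k, (p, s) in enumerate(zip(self.psi, self.psi_se)):
            lines.append(f"{f'breakpoint_{k+1} ({self.seg_name})':<28}{p:>12.4g}{s:>10.3g}")
        lines.append(f"{'theta':<28}{self.theta:>12.4g}{self.theta_se:>10.3g}")
        slopes = ", ".join(f"{s:.4g}" for s in self.segment_slopes)
        lines.append(f"per-segment slopes: {slopes}")
        lines.append(f"loglik {self.llf:.2f}   AIC {self.aic:.2f}   "
                     f"converged {self.converged}")
        return "\n".join(lines)


def _split_frame(data: pd.DataFrame, exog_names, seg_name):
    exog = data[[c for c in exog_names if c not in (seg_name,)
                 and not c.startswith("hinge_")]].to_numpy(dtype=float)
    return exog, data[seg_name].to_numpy(dtype=float)


class SegmentedNegativeBinomial:
    """NB2 count regression with 0-2 estimated breakpoints in one covariate.

    Parameters
    ----------
    endog : (n,) counts.
    exog : (n, p) non-segmented design (include the intercept column here).
    seg_values : (n,) the segmented covariate (ice-floe area, m^2).
    n_breakpoints : 0, 1 or 2.
    exog_names, seg_name : column labels for reporting.
    quantile_range : (lo, hi) fraction pair; breakpoint estimates are
        constrained to this quantile band of ``seg_values`` to avoid boundary
        degeneracy.
    """

    def __init__(self, endog, exog, seg_values, n_breakpoints=2,
                 exog_names=None, seg_name="area", quantile_range=(0.01, 0.99)):
        if isinstance(exog, pd.DataFrame):
            exog_names = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        self.endog = np.asarray(endog)
        self.exog = np.asarray(exog, dtype=float)
        self.seg_values = np.asarray(seg_values, dtype=float)
        if n_breakpoints not in (0, 1, 2):
            raise ValueError("n_breakpoints must be 0, 1 or 2")
        self.n_breakpoints = n_breakpoints
        self.exog_names = exog_names or [f"x{j}" for j in range(self.exog.shape[1])]
        self.seg_name = seg_name
        self.quantile_range = quantile_range
        if n_breakpoints and np.unique(self.seg_values).size < 20 * (n_breakpoints + 1):
            raise ValueError(
                "too few distinct segmented-covariate values "
                f"({np.unique(self.seg_values).size}) for {n_breakpoints} breakpoint(s)"
            )
        self._lo, self._hi = np.quantile(self.seg_values, quantile_range)

    # -- design helpers ----------------------------------------------------
    def _names(self, with_v, psis):
        names = self.exog_names + [self.seg_name]
        names += [f"hinge_{k + 1}" for k in range(len(psis))]
        if with_v:
            names += [f"V_{k + 1}" for k in range(len(psis))]
        return names

    def _design(self, psis, with_v=False):
        cols = [self.exog, self.seg_values[:, None]]
        if len(psis):
            cols.append(np.maximum(0.0, self.seg_values[:, None] - np.asarray(psis)[None, :]))
            if with_v:
                cols.append(-(self.seg_values[:, None] > np.asarray(psis)[None, :]).astype(float))
        return np.column_stack(cols)

    def _hinge_fit(self, psis, start=None, se=False) -> NBGLMResults:
        return fit_nb_glm(self._design(psis), self.endog,
                          exog_names=self._names(False, psis),
                          start_params=start, se=se)

    # -- fitting -----------------------------------------------------------
    def fit(self, init="quantile", tol=1e-6, max_iter=50, max_halving=6) -> SegmentedNBResults:
        """Estimate coefficients, dispersion and breakpoints.

        ``init`` is either "quantile" (multi-start from a quantile grid:
        5 starts for one breakpoint, a 3x3 grid for two) or an explicit list
        of starting breakpoints (one start).  The start with the best final
        log-likelihood wins.  Raises RuntimeError when every start fails,
        and when two breakpoints collapse onto each other.
        """
        if self.n_breakpoints == 0:
            base = self._hinge_fit([])
            return SegmentedNBResults(
                params=base.params, bse=base.bse, theta=base.theta,
                theta_se=base.theta_se, llf=base.llf,
                aic=2 * (len(base.params) + 1) - 2 * base.llf,
                converged=base.converged, n_iter=base.n_iter,
                exog_names=base.exog_names, psi=np.empty(0), psi_se=np.empty(0),
                seg_name=self.seg_name)

        starts = self._starts(init)
        best: SegmentedNBResults | None = None
        failures = []
        for psi0 in starts:
            try:
                cand = self._fit_one(np.asarray(psi0, dtype=float), tol,
                                     max_iter, max_halving)
            except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
                failures.append((list(psi0), str(exc)))
                continue
            if best is None or cand.llf > best.llf:
                best = cand
        if best is None:
            raise RuntimeError(
                "segmented fit failed from every start; trace: " + repr(failures))
        best.n_starts = len(starts)
        return best

    def _starts(self, init):
        if not (isinstance(init, str) and init == "quantile"):
            psi0 = np.atleast_1d(np.asarray(init, dtype=float))
            if psi0.ndim == 1 and psi0.size == self.n_breakpoints:
                return [psi0]
            return [np.asarray(p, dtype=float) for p in init]
        if self.n_breakpoints == 1:
            qs = np.quantile(self.seg_values, [0.1, 0.3, 0.5, 0.7, 0.9])
            return [[q] for q in qs]
        q1 = np.quantile(self.seg_values, [0.25, 0.5, 0.75])
        q2 = np.quantile(self.seg_values, [0.5, 0.75, 0.9])
        return [[a, b] for a in q1 for b in q2 if a < b]

    def _fit_one(self, psi, tol, max_iter, max_halving) -> SegmentedNBResults:
        psi = np.clip(np.sort(psi), self._lo, self._hi)
        span = self.seg_values.max() - self.seg_values.min()
        trace = []
        warm_h = None
        profile = self._hinge_fit(psi)
        warm_full = None
        converged = False
        n_iter = 0
        last_full = None
        stall = 0
        for n_iter in range(1, max_iter + 1):
            names = self._names(True, psi)
            full = fit_nb_glm(self._design(psi, with_v=True), self.endog,
                              exog_names=names, start_params=warm_full, se=False)
            last_full = full
            d = np.array([full.params[f"hinge_{k + 1}"] for k in range(len(psi))])
            g = np.array([full.params[f"V_{k + 1}"] for k in range(len(psi))])
            if np.any(np.abs(d) < 1e-12):
                raise RuntimeError("hinge coefficient vanished; breakpoint unidentified")
            delta = g / d
            # step-halving on the profile likelihood
            h = 1.0
            accepted = None
            for _ in range(max_halving + 1):
                cand_psi = np.clip(psi + h * delta, self._lo, self._hi)
                if len(cand_psi) == 2 and cand_psi[1] - cand_psi[0] < 1e-3 * span:
                    raise RuntimeError(
                        "breakpoints collapsed onto each other; refit with fewer breakpoints")
                try:
                    cand_fit = self._hinge_fit(cand_psi, start=warm_h)
                except (ValueError, np.linalg.LinAlgError):
                    h /= 2.0
                    continue
                if cand_fit.llf >= profile.llf - 1e-9 or h <= 2.0 ** -max_halving:
                    accepted = (cand_psi, cand_fit, h)
                    break
                h /= 2.0
            if accepted is None:
                break
            new_psi, new_profile, h = accepted
            rel = np.max(np.abs(new_psi - psi) / max(span, 1e-12))
            trace.append({"iter": n_iter, "psi": new_psi.tolist(),
                          "llf": new_profile.llf, "step": h})
            gain = new_profile.llf - profile.llf
            psi, profile = new_psi, new_profile
            warm_h = np.append(profile.params.to_numpy(), 1.0 / profile.theta)
            warm_full = np.concatenate([
                profile.params.to_numpy(), np.zeros(len(psi)),
                [1.0 / profile.theta]])
            # stop on a stationary psi, or on a profile-likelihood plateau
            # (psi wiggle below the likelihood resolution)
            stall = stall + 1 if gain < 1e-7 * (1.0 + abs(profile.llf)) else 0
            if rel < tol or stall >= 2:
                converged = True
                break

        if np.any(psi <= self._lo + 1e-9) or np.any(psi >= self._hi - 1e-9):
            raise RuntimeError(
                f"breakpoint stuck at the quantile boundary ({psi.tolist()})")
        # final fits with standard errors; delta-method SE of psi = gamma/d
        # from the augmented (hinge + indicator) fit at the solution
        profile = self._hinge_fit(psi, start=warm_h, se=True)
        final_full = fit_nb_glm(
            self._design(psi, with_v=True), self.endog,
            exog_names=self._names(True, psi),
            start_params=np.concatenate([profile.params.to_numpy(),
                                         np.zeros(len(psi)),
                                         [1.0 / profile.theta]]))
        d = np.array([final_full.params[f"hinge_{k + 1}"] for k in range(len(psi))])
        g_se = np.array([final_full.bse[f"V_{k + 1}"] for k in range(len(psi))])
        psi_se = g_se / np.abs(d)

        k = len(profile.params) + len(psi) + 1
        return SegmentedNBResults(
            params=profile.params, bse=profile.bse, theta=profile.theta,
            theta_se=profile.theta_se, llf=profile.llf,
            aic=2 * k - 2 * profile.llf, converged=converged and profile.converged,
            n_iter=n_iter, exog_names=self._names(False, psi),
            psi=psi, psi_se=psi_se, seg_name=self.seg_name, trace=trace)


def fit_segmented(design, y, seg_values, n_breakpoints=2, init="quantile",
                  exog_names=None, **kwargs) -> SegmentedNBResults:
    """Functional wrapper over :class:`SegmentedNegativeBinomial`."""
    model = SegmentedNegativeBinomial(y, design, seg_values,
                                      n_breakpoints=n_breakpoints,
                                      exog_names=exog_names, **kwargs)
    return model.fit(init=init)


# --------------------------------------------------------------------------
# candidate-distribution comparison
# --------------------------------------------------------------------------

def _ll_poisson(y, x):
    res = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
    return float(res.llf), 2

def _ll_nb(y, x):
    fit = fit_nb_glm(sm.add_constant(x), y)
    return fit.llf, 3

def _loglinear_ml(y, x, family):
    """Interval-censored ML fit of a positive family, mean exp(a + b x).

    Counts are matched to continuous laws through the probability of the
    unit-width interval (y - 1/2, y + 1/2] (left end clipped at 0), which
    keeps the log-likelihood a genuine probability and hence comparable with
    the discrete families' AIC.
    """
    hi = y + 0.5
    lo = np.maximum(y - 0.5, 0.0)

    def nll(p):
        a, b = p[0], p[1]
        loc = np.clip(a + b * x, -500, 500)
        mu = np.exp(loc)
        if family == "exponential":
            prob = stats.expon.cdf(hi, scale=mu) - stats.expon.cdf(lo, scale=mu)
        elif family == "gamma":
            shape = np.exp(np.clip(p[2], -10, 10))
            prob = (stats.gamma.cdf(hi, shape, scale=mu / shape)
                    - stats.gamma.cdf(lo, shape, scale=mu / shape))
        elif family == "lognormal":
            sigma = np.exp(np.clip(p[2], -10, 10))
            # log-scale location model: median exp(a + b x)
            prob = (stats.lognorm.cdf(hi, sigma, scale=mu)
                    - stats.lognorm.cdf(lo, sigma, scale=mu))
        else:
            raise ValueError(family)
        return -np.sum(np.log(np.clip(prob, 1e-300, None)))

    p0 = [np.log(y.mean() + 0.5), 0.0] + ([0.0] if family != "exponential" else [])
    res = optimize.minimize(nll, p0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8})
    k = len(p0)
    return -float(res.fun), k


def compare_distributions(y, area) -> pd.DataFrame:
    """Rank candidate count distributions for seals-per-floe vs floe area.

    Fits Poisson, NB2, Gamma, Exponential and Log-normal models whose mean
    (location, for the log-normal) is log-linear in ``area`` and tabulates
    log-likelihood and AIC, best first.  The continuous families, which put
    no mass on integers, enter through the interval-censored likelihood
    P(y - 1/2 < Y <= y + 1/2) so their AICs are commensurable with the
    discrete families'.
    """
    y = np.asarray(y, dtype=float)
    area = np.asarray(area, dtype=float)
    if np.all(y == 0):
        raise ValueError("all counts are zero; distribution comparison is degenerate")
    yc = y
    rows = []
    for fam, (ll, k) in {
        "poisson": _ll_poisson(y, area),
        "negative_binomial": _ll_nb(y, area),
        "gamma": _loglinear_ml(yc, area, "gamma"),
        "exponential": _loglinear_ml(yc, area, "exponential"),
        "lognormal": _loglinear_ml(yc, area, "lognormal"),
    }.items():
        rows.append({"family": fam, "k": k, "llf": ll, "aic": 2 * k - 2 * ll})
    table = pd.DataFrame(rows).sort_values("aic", ignore_index=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table
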