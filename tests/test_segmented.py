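"""NB2 GLM and breakpoint estimation: oracles, invariances, recovery."""

import numpy as np
import pandas as pd
import pytest

from floeseal.segmented import (
    SegmentedNegativeBinomial,
    compare_distributions,
    fit_nb_glm,
    fit_segmented,
    hinge_design,
)
from floeseal.synth import SegmentedModelSpec, simulate_survey_table

from conftest import nb_design


class TestHinge:
    def test_values(self):
        x = np.array([0.0, 49.84, 100.0])
        h = hinge_design(x, [49.84])
        assert h[1, 0] == 0.0
        assert h[2, 0] == pytest.approx(50.16)
        assert h[0, 0] == 0.0

    def test_breakpoint_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside the observed range"):
            hinge_design(np.linspace(0, 10, 30), [20.0])

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            hinge_design(np.linspace(0, 100, 30), [50.0, 30.0])

    def test_piecewise_predictor_continuous(self):
        x = np.linspace(0, 100, 10001)
        h = hinge_design(x, [30.0, 60.0])
        lp = 1.0 + 0.2 * x - 0.15 * h[:, 0] - 0.04 * h[:, 1]
        assert np.max(np.abs(np.diff(lp))) < 0.2 * (x[1] - x[0]) + 1e-12


class TestNBGLM:
    def test_intercept_only_mean_matching(self):
        y = np.full(50, 2)
        fit = fit_nb_glm(np.ones((50, 1)), y)
        assert fit.params.iloc[0] == pytest.approx(np.log(2), abs=1e-6)
        assert fit.predict(np.ones((1, 1)))[0] == pytest.approx(2.0, abs=1e-5)

    def test_poisson_data_gives_large_theta(self):
        rng = np.random.default_rng(0)
        wins = 0
        for rep in range(5):
            x = rng.normal(size=5000)
            y = rng.poisson(np.exp(1.0 + 0.3 * x))
            fit = fit_nb_glm(np.column_stack([np.ones(5000), x]), y)
            wins += fit.theta > 10
        assert wins >= 4

    def test_parameter_recovery_within_3se(self):
        """Simulated NB2 truth recovered within 3 SEs in >= 95% of cases."""
        rng = np.random.default_rng(1)
        beta = np.array([0.5, 0.8, -0.4])
        theta = 1.5
        hits = total = 0
        for rep in range(30):
            X = np.column_stack([np.ones(10_000), rng.normal(size=(10_000, 2))])
            mu = np.exp(X @ beta)
            y = rng.negative_binomial(theta, theta / (theta + mu))
            fit = fit_nb_glm(X, y)
            hits += int(np.sum(np.abs(fit.params.to_numpy() - beta) < 3 * fit.bse.to_numpy()))
            total += 3
        assert hits / total >= 0.95

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(40), np.arange(40.0), 2 * np.arange(40.0)])
        with pytest.raises(ValueError, match="x2"):
            fit_nb_glm(X, np.ones(40, dtype=int), exog_names=["const", "x1", "x2"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fit_nb_glm(np.ones((5, 1)), np.array([1, -1, 0, 2, 3]))

    def test_aic_identity(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(2.0, size=200)
        fit = fit_nb_glm(np.ones((200, 1)), y)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.llf)

    def test_covariate_rescale_invariance(self):
        """Multiplying a covariate by c divides its coefficient by c."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=3000)
        y = rng.poisson(np.exp(0.5 + 0.4 * x))
        X1 = np.column_stack([np.ones(3000), x])
        X2 = np.column_stack([np.ones(3000), 100.0 * x])
        f1 = fit_nb_glm(X1, y)
        f2 = fit_nb_glm(X2, y)
        assert f2.params.iloc[1] == pytest.approx(f1.params.iloc[1] / 100.0, rel=1e-4)


class TestSegmentedFit:
    def test_strong_single_kink_recovered(self):
        """A pronounced slope change at x=50 is located to sub-unit precision.

        Counts are discrete so an exactly noiseless construction is
        impossible; large Poisson-limit means push sampling noise far below
        the assertion tolerance.
        """
        rng = np.random.default_rng(4)
        x = np.tile(np.linspace(1, 100, 200), 10)
        lp = 2.0 + 0.06 * x - 0.12 * np.maximum(0.0, x - 50.0)
        y = rng.poisson(np.exp(lp) * 20)
        fit = fit_segmented(np.ones((x.size, 1)), y, x, n_breakpoints=1,
                            exog_names=["const"])
        assert fit.psi[0] == pytest.approx(50.0, abs=0.5)
        assert fit.converged

    def test_zero_breakpoints_matches_plain_glm(self, survey_10k):
        df = survey_10k.head(2000)
        X = np.column_stack([nb_design(df), df["area"].to_numpy()])
        plain = fit_nb_glm(X, df["seal_count"].to_numpy())
        seg = fit_segmented(nb_design(df), df["seal_count"].to_numpy(),
                            df["area"].to_numpy(), n_breakpoints=0)
        np.testing.assert_allclose(seg.params.to_numpy(), plain.params.to_numpy(),
                                   rtol=1e-6)
        assert seg.llf == pytest.approx(plain.llf, abs=1e-6)

    def test_profile_likelihood_oracle_single_breakpoint(self):
        """Muggeo solution matches a brute-force profile-likelihood grid.

        Grid candidates are midpoints of consecutive distinct x values; the
        iterative estimate must land within one grid step of the argmax.
        """
        rng = np.random.default_rng(5)
        misses = 0
        for rep in range(5):
            x = rng.choice(np.linspace(1, 100, 60), size=300)
            lp = -1.0 + 0.08 * x - 0.10 * np.maximum(0.0, x - rng.uniform(35, 65))
            theta = 2.0
            mu = np.exp(lp)
            y = rng.negative_binomial(theta, theta / (theta + mu))
            xs = np.unique(x)
            mids = (xs[1:] + xs[:-1]) / 2.0
            lo, hi = np.quantile(x, [0.01, 0.99])
            mids = mids[(mids > lo) & (mids < hi)]
            prof = [fit_nb_glm(np.column_stack(
                [np.ones(x.size), x, np.maximum(0.0, x - m)]), y, se=False).llf
                for m in mids]
            best = mids[int(np.argmax(prof))]
            step = np.max(np.diff(mids))
            fit = fit_segmented(np.ones((x.size, 1)), y, x, n_breakpoints=1,
                                exog_names=["const"])
            if abs(fit.psi[0] - best) > step:
                misses += 1
        assert misses == 0

    def test_likelihood_ascent_in_trace(self, survey_10k):
        df = survey_10k
        fit = fit_segmented(nb_design(df), df["seal_count"].to_numpy(),
                            df["area"].to_numpy(), n_breakpoints=2,
                            init=[30.0, 300.0])
        llfs = [step["llf"] for step in fit.trace]
        assert all(b - a > -1e-6 for a, b in zip(llfs, llfs[1:]))

    def test_psi_equivariance_under_rescaling(self, survey_10k):
        df = survey_10k.head(6000)
        y = df["seal_count"].to_numpy()
        a = df["area"].to_numpy()
        f1 = fit_segmented(nb_design(df), y, a, n_breakpoints=1, init=[40.0])
        f2 = fit_segmented(nb_design(df), y, 10.0 * a, n_breakpoints=1,
                           init=[400.0])
        assert f2.psi[0] == pytest.approx(10.0 * f1.psi[0], rel=1e-3)

    def test_segmented_aic_beats_unsegmented_on_kinked_data(self, survey_10k):
        df = survey_10k
        y = df["seal_count"].to_numpy()
        seg = fit_segmented(nb_design(df), y, df["area"].to_numpy(),
                            n_breakpoints=2, init=[30.0, 300.0])
        plain = fit_segmented(nb_design(df), y, df["area"].to_numpy(),
                              n_breakpoints=0)
        assert seg.aic < plain.aic

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            SegmentedNegativeBinomial(np.zeros(30, dtype=int), np.ones((30, 1)),
                                      np.tile([1.0, 2.0, 3.0], 10),
                                      n_breakpoints=1)

    def test_serialization_fields(self, survey_10k):
        df = survey_10k.head(4000)
        fit = fit_segmented(nb_design(df), df["seal_count"].to_numpy(),
                            df["area"].to_numpy(), n_breakpoints=1, init=[45.0])
        assert len(fit.psi) == len(fit.psi_se) == 1
        assert np.all(fit.psi_se > 0)
        assert len(fit.segment_slopes) == 2
        assert "breakpoint_1" in fit.summary()


class TestCompareDistributions:
    def test_five_rows_sorted(self, survey_10k):
        df = survey_10k.head(3000)
        table = compare_distributions(df["seal_count"].to_numpy(),
                                      df["area"].to_numpy())
        assert len(table) == 5
        assert set(table["family"]) == {"poisson", "negative_binomial", "gamma",
                                        "exponential", "lognormal"}
        assert table["aic"].is_monotonic_increasing

    def test_nb_wins_on_nb_data(self):
        rng = np.random.default_rng(6)
        wins = 0
        for rep in range(10):
            a = np.exp(rng.uniform(0, 5, size=2000))
            mu = np.exp(-1.5 + 0.02 * a)
            y = rng.negative_binomial(0.5, 0.5 / (0.5 + mu))
            if y.sum() == 0:
                continue
            table = compare_distributions(y, a)
            wins += table["family"].iloc[0] == "negative_binomial"
        assert wins >= 9

    def test_poisson_data_nests_within_nb(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 10, size=4000)
        y = rng.poisson(np.exp(0.2 + 0.1 * a))
        table = compare_distributions(y, a).set_index("family")
        gap = table.loc["negative_binomial", "aic"] - table.loc["poisson", "aic"]
        assert -0.5 < gap < 2.5

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            compare_distributions(np.zeros(100, dtype=int), np.ones(100))
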