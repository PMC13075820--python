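"""Cost analyses: NB regression, beta-binomial hatch model, binomial CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta as beta_dist

from resistqg.config import LifeHistoryConfig, SimulationConfig
from resistqg.life_history import (
    beta_binomial_loglik,
    binom_ci,
    fit_fecundity,
    fit_hatch,
    lr_test,
    summarize_costs,
)
from resistqg.simulate import simulate_life_history
from resistqg.tables import LifeHistoryTable


def _life_arrays(cfg):
    life = simulate_life_history(cfg)
    df = life.df
    cluster = (
        df["plant_id"].astype(str) + "/" + df["replicate_id"].astype(str)
        + "/" + df["treatment"]
    ).to_numpy()
    return life, df, cluster


class TestFecundity:
    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_fecundity(np.zeros(10), np.repeat(["control", "exposed"], 5))

    def test_poisson_limit_coefficients(self):
        # Poisson data: NB coefficients converge to the Poisson GLM fit
        rng = np.random.default_rng(7)
        treat = np.repeat(["control", "exposed"], 300)
        mu = np.where(treat == "exposed", 6.0, 9.0)
        y = rng.poisson(mu)
        fit = fit_fecundity(y, treat)
        import statsmodels.api as sm

        X = np.column_stack([np.ones(600), (treat == "exposed").astype(float)])
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fit.coefficients["intercept"] == pytest.approx(
            pois.params[0], abs=1e-3
        )
        assert fit.coefficients["treatment[exposed]"] == pytest.approx(
            pois.params[1], abs=1e-3
        )
        assert fit.dispersion_size > 100.0

    def test_group_mean_ratio_recovered_at_study_scale(self):
        # treated/control egg ratio 21.47/37.27 across simulated replicates
        ratios = []
        for seed in range(40):
            cfg = SimulationConfig(seed=seed)
            life, df, cluster = _life_arrays(cfg)
            fit = fit_fecundity(
                df["eggs_laid"].to_numpy(),
                df["treatment"].to_numpy(),
                df["disk_day"].to_numpy(),
                cluster,
                interaction=False,
            )
            ratios.append(np.exp(fit.coefficients["treatment[exposed]"]))
        target = 21.47 / 37.27
        assert abs(np.median(ratios) - target) / target < 0.15

    def test_cluster_mode_recorded(self):
        cfg = SimulationConfig(seed=0)
        life, df, cluster = _life_arrays(cfg)
        fit = fit_fecundity(
            df["eggs_laid"].to_numpy(), df["treatment"].to_numpy(),
            df["disk_day"].to_numpy(), cluster,
        )
        assert fit.mode == "cluster_robust"
        assert fit.n_clusters == 60


class TestLrTest:
    def test_identical_fits_give_zero_statistic(self):
        cfg = SimulationConfig(seed=3)
        life, df, cluster = _life_arrays(cfg)
        fit = fit_fecundity(
            df["eggs_laid"].to_numpy(), df["treatment"].to_numpy(),
            df["disk_day"].to_numpy(), cluster, interaction=False,
        )
        stat, dof, p = lr_test(fit, fit)
        assert stat == 0.0 and dof == 0 and p == 1.0

    def test_full_worse_than_reduced_raises(self):
        class Fit:
            def __init__(self, ll, k):
                self.loglik = ll
                self.n_params = k

        with pytest.raises(ValueError, match="optimization failure"):
            lr_test(Fit(-10.0, 5), Fit(-9.0, 3))

    def test_strong_effect_detected(self):
        # default config carries the study's fecundity and hatch contrasts
        detected = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed)
            life, df, cluster = _life_arrays(cfg)
            args = (
                df["eggs_laid"].to_numpy(), df["treatment"].to_numpy(),
                df["disk_day"].to_numpy(), cluster,
            )
            full = fit_fecundity(*args, interaction=False)
            null = fit_fecundity(
                *args, interaction=False, include_treatment=False
            )
            if lr_test(full, null)[2] < 0.05:
                detected += 1
        assert detected >= 8


class TestHatch:
    def test_beta_binomial_loglik_equals_binomial_at_zero_rho(self):
        rng = np.random.default_rng(1)
        n = rng.integers(1, 30, 50)
        k = rng.binomial(n, 0.3)
        mu = np.full(50, 0.3)
        from scipy.stats import binom

        expected = float(binom.logpmf(k, n, 0.3).sum())
        assert beta_binomial_loglik(k, n, mu, 0.0) == pytest.approx(expected)
        # and the rho -> 0 limit is continuous
        assert beta_binomial_loglik(k, n, mu, 1e-10) == pytest.approx(
            expected, abs=1e-4
        )

    def test_reduces_to_binomial_glm_without_overdispersion(self):
        rng = np.random.default_rng(2)
        treat = np.repeat(["control", "exposed"], 500)
        p = np.where(treat == "exposed", 0.16, 0.283)
        n = rng.integers(5, 40, 1000)
        k = rng.binomial(n, p)
        fit = fit_hatch(k, n - k, treat)
        import statsmodels.api as sm

        X = np.column_stack([np.ones(1000), (treat == "exposed").astype(float)])
        glm = sm.GLM(
            np.column_stack([k, n - k]), X, family=sm.families.Binomial()
        ).fit()
        assert fit.overdispersion == pytest.approx(0.0, abs=0.02)
        assert fit.coefficients["intercept"] == pytest.approx(
            glm.params[0], abs=1e-3
        )

    def test_hatch_probabilities_recovered_at_study_scale(self):
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=seed)
            life, df, cluster = _life_arrays(cfg)
            hatched = life.final_hatched()
            un = df["eggs_laid"].to_numpy() - hatched
            fit = fit_hatch(hatched, un, df["treatment"].to_numpy())
            p_control = fit.fitted_probability()
            p_exposed = fit.fitted_probability(**{"treatment[exposed]": True})
            if abs(p_control - 0.283) < 0.06 and abs(p_exposed - 0.16) < 0.05:
                hits += 1
        assert hits >= 18

    def test_boundary_all_hatched_flagged(self):
        treat = np.repeat(["control", "exposed"], 5)
        k = np.full(10, 8)
        fit = fit_hatch(k, np.zeros(10), treat)
        assert "boundary" in fit.flags
        assert fit.fitted_probability() > 0.999

    def test_day_effect_p_uniform_under_shuffled_null(self):
        # hatch day carries no signal once shuffled: LR p-values uniform
        from scipy.stats import kstest

        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            n = rng.integers(3, 25, 120)
            k = rng.binomial(n, 0.25)
            treat = np.repeat(["control", "exposed"], 60)
            day = rng.permutation(np.tile(np.arange(4, 8), 30))
            full = fit_hatch(k, n - k, treat, day=day)
            null = fit_hatch(k, n - k, treat)
            ps.append(lr_test(full, null)[2])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_substitution_note_present(self):
        treat = np.repeat(["control", "exposed"], 5)
        fit = fit_hatch(np.arange(1, 11), np.full(10, 5), treat)
        assert "beta-binomial" in fit.note


class TestBinomCI:
    def test_boundaries_exact(self):
        lo, hi = binom_ci(0, 50)
        assert lo == 0.0
        lo, hi = binom_ci(50, 50)
        assert hi == 1.0

    def test_clopper_pearson_matches_beta_quantiles(self):
        # independent beta-distribution oracle for 28 successes of 100
        lo, hi = binom_ci(28, 100, method="clopper-pearson")
        assert lo == pytest.approx(beta_dist.ppf(0.025, 28, 73), abs=1e-10)
        assert hi == pytest.approx(beta_dist.ppf(0.975, 29, 72), abs=1e-10)

    def test_wilson_method_available(self):
        lo, hi = binom_ci(28, 100, method="wilson")
        assert 0.19 < lo < 0.28 < hi < 0.39

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binom_ci(5, 4)
        with pytest.raises(ValueError):
            binom_ci(-1, 10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(k=st.integers(0, 200), n=st.integers(1, 200))
    def test_interval_contains_point_estimate(self, k, n):
        k = min(k, n)
        lo, hi = binom_ci(k, n)
        assert lo <= k / n <= hi

    def test_width_decreases_with_trials(self):
        widths = [
            np.diff(binom_ci(int(0.28 * n), n))[0] for n in (25, 100, 400, 1600)
        ]
        assert all(a > b for a, b in zip(widths, widths[1:]))


class TestSummarizeCosts:
    def test_identity_on_constructed_table(self):
        rows = []
        for plant in range(3):
            for rep in range(2):
                for disk in range(1, 5):
                    rows.append((plant, rep, "control", disk, 10, 2, 3))
                    rows.append((plant, rep, "exposed", disk, 5, 1, 1))
        df = pd.DataFrame(
            rows,
            columns=["plant_id", "replicate_id", "treatment", "disk_day",
                     "eggs_laid", "hatched_d4", "hatched_d8"],
        )
        costs = summarize_costs(LifeHistoryTable(df))
        assert costs["control"]["mean_total_eggs"] == pytest.approx(40.0)
        assert costs["exposed"]["mean_total_eggs"] == pytest.approx(20.0)
        assert costs["control"]["hatch_prop"] == pytest.approx(3 / 10)
        assert costs["exposed"]["hatch_prop"] == pytest.approx(1 / 5)

    def test_single_replicate_degenerate_ci(self):
        rows = [(0, 0, "control", d, 10, 3, 3) for d in range(1, 5)]
        df = pd.DataFrame(
            rows,
            columns=["plant_id", "replicate_id", "treatment", "disk_day",
                     "eggs_laid", "hatched_d4", "hatched_d8"],
        )
        costs = summarize_costs(LifeHistoryTable(df))
        assert costs["control"]["mean_total_eggs"] == pytest.approx(40.0)
        assert costs["control"]["ci_flag"] == "degenerate_ci"

    def test_empty_table_rejected(self):
        df = pd.DataFrame(
            columns=["plant_id", "replicate_id", "treatment", "disk_day",
                     "eggs_laid", "hatched_d4"]
        )
        with pytest.raises(ValueError, match="empty"):
            summarize_costs(LifeHistoryTable(df))
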