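import warnings

import arviz as az
import numpy as np
import pandas as pd
import pytest

from skinaniso.bayes import (
    McmcSettings,
    arcs_overlap,
    circular_hpdi,
    configuration_shift,
    fit_circular,
    fit_mvreg,
    hpdi,
    hpdi_overlap,
    significance_table,
)
from skinaniso.cohort import CircularParams, CohortGenConfig, generate_angles, generate_outcomes

FAST = McmcSettings(n_chains=2, n_iter=1000, seed=3)


def quiet_fit(df, settings=FAST, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_mvreg(df, settings, **kw)


class TestHpdi:
    def test_standard_normal_bounds(self, rng):
        draws = rng.standard_normal(200_000)
        lo, hi = hpdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_constant_draws(self):
        lo, hi = hpdi(np.full(500, 3.25), 0.95)
        assert lo == hi == 3.25

    def test_skewed_sample_shorter_than_equal_tailed(self, rng):
        draws = rng.gamma(2.0, 1.0, 50_000)
        lo, hi = hpdi(draws, 0.95)
        q = np.quantile(draws, [0.025, 0.975])
        assert hi - lo < q[1] - q[0]
        # brute-force window oracle
        x = np.sort(draws)
        k = int(np.ceil(0.95 * x.size))
        widths = x[k:] - x[: x.size - k]
        i = int(np.argmin(widths))
        assert (lo, hi) == (x[i], x[i + k])

    def test_matches_arviz_hdi(self, rng):
        draws = rng.gamma(3.0, 2.0, 20_000)
        lo, hi = hpdi(draws, 0.95)
        ref = az.hdi(draws, hdi_prob=0.95)
        assert lo == pytest.approx(ref[0], abs=0.05)
        assert hi == pytest.approx(ref[1], abs=0.05)

    def test_order_invariant_and_monotone_in_level(self, rng):
        draws = rng.standard_normal(5000)
        assert hpdi(draws) == hpdi(rng.permutation(draws))
        lo90, hi90 = hpdi(draws, 0.90)
        lo99, hi99 = hpdi(draws, 0.99)
        assert hi99 - lo99 > hi90 - lo90

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            hpdi(np.arange(50), 0.95)


class TestMvReg:
    def test_parameter_recovery_within_3_posterior_sd(self):
        cfg = CohortGenConfig(rng_seed=8)
        df = generate_outcomes(cfg)  # n = 156 rows, truth known
        post = quiet_fit(df)
        truth = np.vstack([cfg.intercept, cfg.coefficients.T])  # (p, 3)
        flat = post.coef.reshape(-1, 4, 3)
        means = flat.mean(axis=0)
        sds = flat.std(axis=0)
        assert np.all(np.abs(means - truth) < 3 * sds)

    def test_posterior_matches_ols_when_noise_tiny(self):
        cfg = CohortGenConfig(n_subjects=150, error_cov=np.eye(3) * 1e-8, rng_seed=9)
        df = generate_outcomes(cfg)
        post = quiet_fit(df)
        X = np.column_stack([np.ones(len(df)), df[["age", "gender", "config"]].to_numpy()])
        Y = df[["log_ecc", "area_scaled", "semi_minor"]].to_numpy()
        ols = np.linalg.lstsq(X, Y, rcond=None)[0]
        means = post.coef.reshape(-1, 4, 3).mean(axis=0)
        # agreement up to the prior's ridge shrinkage (lambda = 1e-4)
        np.testing.assert_allclose(means, ols, atol=5e-3)

    def test_gibbs_conditional_matches_ridge_closed_form(self):
        """With Sigma held fixed the posterior mean of the coefficients is the
        ridge solution (X'X + tau^-2 I)^-1 X'Y, exactly."""
        cfg = CohortGenConfig(rng_seed=10)
        df = generate_outcomes(cfg)
        sigma = cfg.error_cov
        # with Sigma fixed the draws are iid from the exact conditional, so
        # Monte-Carlo error shrinks as 1/sqrt(n_draws); 90k draws bring it
        # under the 1e-3 relative tolerance for every coefficient
        post = quiet_fit(
            df,
            McmcSettings(n_chains=2, n_iter=50_000, warmup_frac=0.1, seed=4),
            fixed_sigma=sigma,
        )
        X = np.column_stack([np.ones(len(df)), df[["age", "gender", "config"]].to_numpy()])
        Y = df[["log_ecc", "area_scaled", "semi_minor"]].to_numpy()
        lam = 100.0**-2
        ridge = np.linalg.solve(X.T @ X + lam * np.eye(4), X.T @ Y)
        means = post.coef.reshape(-1, 4, 3).mean(axis=0)
        scale = np.abs(ridge) + 1.0
        assert np.all(np.abs(means - ridge) / scale < 1e-3)

    def test_row_permutation_leaves_summaries_unchanged(self):
        cfg = CohortGenConfig(n_subjects=30, rng_seed=11)
        df = generate_outcomes(cfg)
        perm = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        t1 = significance_table(quiet_fit(df))
        t2 = significance_table(quiet_fit(perm))
        pd.testing.assert_frame_equal(t1, t2)

    def test_prior_scale_insensitivity(self):
        cfg = CohortGenConfig(rng_seed=12)
        df = generate_outcomes(cfg)
        m1 = significance_table(quiet_fit(df, FAST))["mean"].to_numpy()
        m2 = significance_table(
            quiet_fit(df, FAST, prior_scale=1000.0)
        )["mean"].to_numpy()
        np.testing.assert_allclose(m1, m2, rtol=0.05, atol=0.05)

    def test_collinear_design_rejected_with_names(self):
        cfg = CohortGenConfig(n_subjects=20, rng_seed=13)
        df = generate_outcomes(cfg)
        df["gender"] = 1.0  # constant column, collinear with intercept
        with pytest.raises(ValueError, match="collinear"):
            fit_mvreg(df, FAST)

    def test_diagnostics_attached(self):
        cfg = CohortGenConfig(n_subjects=30, rng_seed=14)
        post = quiet_fit(generate_outcomes(cfg))
        assert len(post.rhat) == 12 and len(post.ess) == 12
        assert (post.rhat["rhat"] < 1.05).all()


class TestSignificanceTable:
    @pytest.mark.parametrize(
        "lo, hi, expected",
        [
            (0.005, 0.009, True),  # interval excludes 0 -> significant
            (-0.006, 0.636, False),
            (-0.081, 0.144, False),
        ],
    )
    def test_zero_outside_hpdi_rule(self, lo, hi, expected):
        from skinaniso.bayes import interval_excludes_zero

        assert interval_excludes_zero(lo, hi) is expected

    def test_table_layout(self):
        cfg = CohortGenConfig(n_subjects=30, rng_seed=15)
        table = significance_table(quiet_fit(generate_outcomes(cfg)))
        assert len(table) == 12  # (intercept + 3 covariates) x 3 outcomes
        assert (table["hpdi_low"] <= table["mean"]).all()
        assert (table["mean"] <= table["hpdi_high"]).all()

    def test_strong_effect_flagged_significant(self):
        cfg = CohortGenConfig(rng_seed=16)
        table = significance_table(quiet_fit(generate_outcomes(cfg))).set_index(
            ["covariate", "outcome"]
        )
        # age effect on log eccentricity is strong under the defaults
        assert table.loc[("age", "log_ecc"), "significant"]


class TestCircular:
    def gen_angles(self, shift, n_per_group=100, seed=0, conc=8.0):
        cfg = CohortGenConfig(
            circular_params=CircularParams(40.0, shift, conc), rng_seed=seed
        )
        config = np.repeat([0, 1], n_per_group)
        rng = np.random.default_rng(seed)
        return generate_angles(cfg, config, rng=rng, size=config.size), config

    def test_zero_shift_hpdis_overlap(self):
        ang, config = self.gen_angles(0.0, seed=21)
        post = fit_circular(ang, config, FAST)
        assert hpdi_overlap(post.hpdi_axial[0], post.hpdi_axial[1], period=180.0)

    def test_large_shift_recovered_disjoint(self):
        ang, config = self.gen_angles(60.0, n_per_group=200, seed=22)
        post = fit_circular(ang, config, FAST)
        m0 = np.median(post.circular_mean_draws[0])
        m1 = np.median(post.circular_mean_draws[1])
        assert m0 == pytest.approx(40.0, abs=3.0)
        assert m1 == pytest.approx(100.0, abs=3.0)
        assert not hpdi_overlap(post.hpdi_axial[0], post.hpdi_axial[1], period=180.0)
        assert configuration_shift(post) == pytest.approx(60.0, abs=5.0)

    def test_single_configuration_baseline_only(self):
        ang, _ = self.gen_angles(0.0, seed=23)
        post = fit_circular(ang[:100], np.zeros(100), FAST)
        assert post.beta1 is None
        assert 0 in post.hpdi_axial and 1 not in post.hpdi_axial
        with pytest.raises(ValueError):
            configuration_shift(post)

    def test_identical_angles_warn_degenerate(self):
        ang = np.full(40, 45.0)
        config = np.repeat([0, 1], 20)
        with pytest.warns(UserWarning, match="degenerate"):
            post = fit_circular(ang, config, FAST)
        assert post.degenerate

    def test_too_few_angles_per_group(self):
        with pytest.raises(ValueError, match="10 angles"):
            fit_circular(np.full(12, 30.0), np.repeat([0, 1], 6), FAST)


class TestCircularIntervals:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((10, 30), (20, 40), True),
            ((10, 30), (40, 60), False),
            ((350, 10), (5, 20), True),  # wraparound
            ((350, 10), (20, 340), False),
        ],
    )
    def test_arc_overlap(self, a, b, expected):
        assert arcs_overlap(a, b) is expected

    def test_circular_hpdi_wraps_correctly(self, rng):
        # draws concentrated around 0/360 boundary
        draws = (rng.normal(0.0, 5.0, 20_000)) % 360.0
        lo, hi = circular_hpdi(draws, 0.95)
        assert lo > hi  # interval wraps through 0
        assert lo == pytest.approx(360 - 9.8, abs=0.8)
        assert hi == pytest.approx(9.8, abs=0.8)
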