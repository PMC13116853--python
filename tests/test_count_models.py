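import numpy as np
import pytest
from scipy import stats

from wireworm.count_models import (
    ConvergenceError,
    Family,
    compare_models,
    fit_count_model,
    predict_mean,
    validate_fit,
)
from wireworm.data import DataError, Species
from wireworm.simulate import GeneratorConfig, default_config, generate_dataset
from wireworm.data import complete_case_pairs


def _zinb_pairs(n=5000, a=-0.2, b=0.799, theta=1.2, pi=0.10, seed=42):
    cfg = GeneratorConfig(
        n_fields=1, points_per_field=n, field_effect_sd=0.0,
        soil_mean=0.5, soil_theta=1.0, soil_zi=0.0,
        trap_intercept=a, trap_slope=b, trap_theta=theta, trap_zi=pi, seed=seed,
    )
    return complete_case_pairs(generate_dataset(cfg, Species.A_brevis))


@pytest.fixture(scope="module")
def zinb_pairs():
    return _zinb_pairs()


@pytest.fixture(scope="module")
def all_fits(zinb_pairs):
    fams = [Family.poisson, Family.negbin, Family.zip, Family.zinb, Family.hurdle_nb]
    return {fam: fit_count_model(zinb_pairs, fam) for fam in fams}


class TestPoisson:
    def test_intercept_only_mle_is_sample_mean(self):
        y = np.array([0, 1, 2, 3] * 3, dtype=float)
        x = np.zeros_like(y)
        fit = fit_count_model((x, y), "poisson", intercept_only=True)
        mu = np.exp(fit.intercept)
        assert mu == pytest.approx(y.mean(), rel=1e-6)
        expected_ll = np.sum(stats.poisson.logpmf(y, y.mean()))
        assert fit.loglik == pytest.approx(expected_ll, rel=1e-8)

    def test_quasipoisson_same_point_estimates_scaled_se(self, zinb_pairs):
        p = fit_count_model(zinb_pairs, "poisson")
        q = fit_count_model(zinb_pairs, "quasipoisson")
        assert q.slope == pytest.approx(p.slope)
        assert q.aic is None and q.loglik is None
        assert q.slope_se > p.slope_se  # overdispersed data inflate the SE


class TestZinb:
    def test_parameter_recovery_within_three_se(self, all_fits):
        """ZINB fit on 5000 simulated points recovers (a, b, theta, pi)."""
        f = all_fits[Family.zinb]
        assert abs(f.intercept - (-0.2)) < 3 * f.intercept_se
        assert abs(f.slope - 0.799) < 3 * f.slope_se
        assert abs(f.theta - 1.2) / 1.2 < 0.25
        assert abs(f.zi_prob - 0.10) < 0.05

    def test_zinb_loglik_at_least_nb(self, all_fits):
        """At pi = 0 the ZINB mass equals the NB mass, so the ZINB MLE
        log-likelihood can never fall below the NB MLE log-likelihood."""
        assert all_fits[Family.zinb].loglik >= all_fits[Family.negbin].loglik - 1e-6

    def test_aic_bic_arithmetic(self, all_fits):
        for f in all_fits.values():
            if f.loglik is None:
                continue
            assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.n_params)
            assert f.bic == pytest.approx(-2 * f.loglik + f.n_params * np.log(f.nobs))

    def test_zero_freq_self_consistency(self, all_fits, zinb_pairs):
        """Predicted zero frequency matches the observed one on data
        generated from the fitted family."""
        v = validate_fit(all_fits[Family.zinb])
        n = len(zinb_pairs)
        se = np.sqrt(v.zero_freq_observed * (1 - v.zero_freq_observed) / n)
        assert abs(v.zero_freq_predicted - v.zero_freq_observed) < 4 * se

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DataError):
            fit_count_model((np.zeros(5), np.ones(5)), "zinb")


class TestDispersion:
    def test_poisson_fit_on_nb_data_overdispersed(self, all_fits):
        assert all_fits[Family.poisson].dispersion_stat > 1.5
        assert all_fits[Family.negbin].dispersion_stat == pytest.approx(1.0, abs=0.2)


class TestCompareModels:
    def test_aic_arithmetic_on_equal_logliks(self, all_fits):
        df = compare_models(list(all_fits.values()))
        assert df["delta_aic"].iloc[0] == 0.0
        assert df["aic"].is_monotonic_increasing

    def test_zinb_beats_poisson_and_zip_on_calibrated_data(self):
        """Model ranking on calibrated synthetic data reproduces the
        qualitative AIC ordering: ZINB above ZIP above Poisson."""
        cfg = default_config(Species.A_brevis, n_fields=40, points_per_field=50, seed=17)
        pairs = complete_case_pairs(generate_dataset(cfg, Species.A_brevis))
        fits = [fit_count_model(pairs, f) for f in (Family.poisson, Family.zip, Family.zinb)]
        df = compare_models(fits).set_index("family")
        assert df.loc["zinb", "aic"] < df.loc["zip", "aic"]
        assert df.loc["zinb", "aic"] < df.loc["poisson", "aic"]

    def test_poisson_data_keep_poisson_competitive(self):
        """Under a true Poisson process the Poisson fit is within 4 AIC of
        the best candidate (parsimony)."""
        rng = np.random.default_rng(23)
        n = 2000
        soil = rng.integers(0, 3, n).astype(float)
        trap = rng.poisson(np.exp(-0.2 + 0.6 * soil))
        fits = [
            fit_count_model((soil, trap.astype(float)), f)
            for f in (Family.poisson, Family.negbin, Family.zip)
        ]
        df = compare_models(fits).set_index("family")
        assert df.loc["poisson", "aic"] - df["aic"].min() < 4.0

    def test_differing_observation_sets_rejected(self, all_fits):
        other = fit_count_model(_zinb_pairs(n=500, seed=9), "poisson")
        with pytest.raises(DataError):
            compare_models([all_fits[Family.poisson], other])


class TestValidateAndPredict:
    def test_exact_predictions_give_zero_errors(self):
        y = np.array([0.0, 2.0])
        yhat = np.array([1.0, 1.0])
        rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
        mad = float(np.mean(np.abs(y - yhat)))
        assert rmse == 1.0 and mad == 1.0  # hand arithmetic for the definitions

    def test_irr_is_exp_slope(self, all_fits):
        v = validate_fit(all_fits[Family.zinb])
        assert v.irr == pytest.approx(np.exp(all_fits[Family.zinb].slope))

    def test_predict_mean_monotone_and_zero_slope_constant(self, all_fits):
        f = all_fits[Family.zinb]
        preds = [predict_mean(f, s) for s in range(5)]
        assert all(b > a for a, b in zip(preds, preds[1:]))
        with pytest.raises(DataError):
            predict_mean(f, -1)

    def test_predicted_mean_matches_printed_equation_scale(self):
        """The ustulatus-type count component exp(1.212 + 0.567*1) ~ 5.9
        expected larvae per trap at one soil larva."""
        assert np.exp(1.212 + 0.567) == pytest.approx(5.92, abs=0.02)


class TestHurdle:
    def test_hurdle_zero_component_matches_binary_part(self, all_fits, zinb_pairs):
        f = all_fits[Family.hurdle_nb]
        trap = np.array([p.trap_count for p in zinb_pairs], dtype=float)
        # detection part reproduces the observed positive fraction on average
        assert np.mean(1 - f.zero_prob) == pytest.approx(np.mean(trap > 0), abs=0.01)
        assert f.n_params == 5
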