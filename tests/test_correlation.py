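"""Power-law fitting, inversion, constant correlations, profile prediction."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from savrelease import reference
from savrelease.correlation import (
    PowerLaw,
    build_constant_correlations,
    fit_power_law,
    invert_power_law,
    predict_profile,
    predict_scalar,
    two_point_power_law,
)
from savrelease.exceptions import (
    DomainError,
    ExcludedConstantWarning,
    ExtrapolationWarning,
    RankError,
)
from savrelease.metrics import mdt
from savrelease.models import ModelFit, PeppasSahlin, Weibull
from savrelease.profiles import ReleaseProfile
from savrelease.synthetic import simulate_profile

GRID = (0.8, 1.0, 1.5, 2.0, 2.5, 3.3, 4.0, 5.0, 6.0)


def exact_pairs(a, p, grid=GRID):
    return [(s, a * s**p) for s in grid]


class TestFitPowerLaw:
    def test_exact_law_recovered(self):
        law = fit_power_law(exact_pairs(62.5, -1.3))
        assert law.coefficient == pytest.approx(62.5, rel=1e-10)
        assert law.exponent == pytest.approx(-1.3, rel=1e-10)
        assert law.r_squared == pytest.approx(1.0, abs=1e-12)
        assert law.domain == (0.8, 6.0)

    def test_reference_k1_interpolates_between_neighbours(self):
        pairs = [(s, k1) for s, (k1, _) in
                 reference.PEPPAS_SAHLIN_CONSTANTS["PVA-PDM"].items()]
        law = fit_power_law(pairs)
        k1_16 = predict_scalar(law, 1.6)
        assert 3.920 < k1_16 < 5.561
        assert predict_scalar(law, 1.0) == pytest.approx(2.5, abs=0.4)
        assert law.exponent > 0  # k1 grows with SA/V

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(RankError):
            fit_power_law([(1.0, 10.0), (1.0, 12.0)])
        with pytest.raises(DomainError):
            fit_power_law([(1.0, 10.0), (2.0, -1.0)])
        with pytest.raises(DomainError):
            fit_power_law([(1.0, 10.0)])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0.1, 100.0), st.floats(-3.0, 3.0), st.floats(0.01, 100.0))
    def test_scale_equivariance(self, a, p, scale):
        base = fit_power_law(exact_pairs(a, p))
        scaled = fit_power_law([(s, r * scale) for s, r in exact_pairs(a, p)])
        assert scaled.coefficient == pytest.approx(base.coefficient * scale, rel=1e-8)
        assert scaled.exponent == pytest.approx(base.exponent, abs=1e-8)


class TestPredictInvert:
    PDM = PowerLaw(62.5, -1.3, None, 2, (0.8, 6.0))
    PZQ = PowerLaw(73.487, -1.145, None, 2, (0.8, 6.0))

    def test_published_validation_points(self):
        assert predict_scalar(self.PDM, 0.90) == pytest.approx(71.70, rel=0.01)
        assert predict_scalar(self.PZQ, 1.30) == pytest.approx(54.42, abs=0.005)

    def test_unit_sav_returns_coefficient(self):
        assert predict_scalar(self.PZQ, 1.0) == 73.487

    def test_extrapolation_warns(self):
        with pytest.warns(ExtrapolationWarning):
            predict_scalar(self.PDM, 7.5)
        with pytest.raises(DomainError):
            predict_scalar(self.PDM, -1.0)

    def test_invert_at_coefficient_gives_unit_sav(self):
        assert invert_power_law(self.PZQ, 73.487) == pytest.approx(1.0, rel=1e-12)
        assert invert_power_law(self.PZQ, 54.42) == pytest.approx(1.30, abs=1e-3)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0.1, 6.0))
    def test_round_trip(self, sav):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            assert invert_power_law(
                self.PDM, predict_scalar(self.PDM, sav)
            ) == pytest.approx(sav, rel=1e-10)

    def test_flat_law_not_invertible(self):
        flat = PowerLaw(10.0, 0.0, None, 2, (1.0, 2.0))
        with pytest.raises(DomainError):
            invert_power_law(flat, 5.0)


class TestTwoPointCalibration:
    def test_exact_law_through_two_points(self):
        pairs = exact_pairs(62.5, -1.3)
        law = two_point_power_law(pairs[0], pairs[-1])
        assert law.coefficient == pytest.approx(62.5, rel=1e-12)
        assert law.exponent == pytest.approx(-1.3, rel=1e-12)
        assert law.r_squared is None

    def test_argument_order_irrelevant(self):
        a = two_point_power_law((0.8, 90.0), (6.0, 5.0))
        b = two_point_power_law((6.0, 5.0), (0.8, 90.0))
        assert a.coefficient == pytest.approx(b.coefficient, rel=1e-12)
        assert a.exponent == pytest.approx(b.exponent, rel=1e-12)

    def test_equal_sav_rejected(self):
        with pytest.raises(RankError):
            two_point_power_law((1.0, 10.0), (1.0, 20.0))

    def test_matches_full_fit_on_noise_free_data(self):
        pairs = exact_pairs(209.43, -1.71)
        full = fit_power_law(pairs)
        two = two_point_power_law(pairs[0], pairs[-1])
        assert two.coefficient == pytest.approx(full.coefficient, rel=1e-9)
        assert two.exponent == pytest.approx(full.exponent, abs=1e-9)

    def test_recovers_generating_exponent_from_noisy_study(self):
        # two-point calibration on simulated dissolution data at the extreme
        # SA/V ratios; compare to the law of the noise-free sampled MDTs
        points = {}
        truths = {}
        for i, sav in enumerate((0.8, 6.0)):
            reps = simulate_profile("PVA-PDM", sav, noise_sd=1.0, seed=100 + i)
            points[sav] = mdt(
                ReleaseProfile(
                    reps[0].times,
                    np.mean([r.releases for r in reps], axis=0),
                )
            )
            clean = simulate_profile("PVA-PDM", sav, noise_sd=0.0, seed=0,
                                     replicate_count=1)[0]
            truths[sav] = mdt(clean)
        noisy = two_point_power_law((0.8, points[0.8]), (6.0, points[6.0]))
        truth = two_point_power_law((0.8, truths[0.8]), (6.0, truths[6.0]))
        assert noisy.exponent == pytest.approx(truth.exponent, abs=0.15)


def fits_from_constants(constants, family):
    out = {}
    for sav, values in constants.items():
        if family == "peppas_sahlin":
            model = PeppasSahlin(k1=values[0], k2=values[1], n=0.79)
        else:
            model = Weibull(a=values[0], b=values[1])
        out[sav] = ModelFit(model=model, r_squared=1.0, fit_cap=98.0,
                            n_points_used=12)
    return out


class TestConstantCorrelations:
    def test_reference_weibull_block_sign_structure(self):
        corr = build_constant_correlations(
            fits_from_constants(reference.WEIBULL_CONSTANTS["PVA-PZQ"], "weibull")
        )
        assert corr.laws["a"].exponent < 0  # time scale falls with SA/V
        assert corr.laws["b"].exponent > 0  # curves grow more sigmoid

    def test_exact_power_law_constants_recovered(self):
        constants = {s: (4.0 * s**1.2, 0.02 * s**2.3) for s in GRID}
        corr = build_constant_correlations(
            fits_from_constants(constants, "peppas_sahlin"), n_bar=0.79
        )
        assert corr.laws["k1"].coefficient == pytest.approx(4.0, rel=1e-9)
        assert corr.laws["k1"].exponent == pytest.approx(1.2, abs=1e-9)
        assert corr.laws["k2"].exponent == pytest.approx(2.3, abs=1e-9)

    def test_reference_k1_prediction_brackets_neighbours(self):
        corr = build_constant_correlations(
            fits_from_constants(
                reference.PEPPAS_SAHLIN_CONSTANTS["PVA-PDM"], "peppas_sahlin"
            ),
            n_bar=0.79,
        )
        assert 3.920 < predict_scalar(corr.laws["k1"], 1.6) < 5.561

    def test_non_positive_constant_excluded_with_warning(self):
        constants = {s: (2.0 * s, 0.05 * s) for s in (1.0, 2.0, 4.0)}
        fits = fits_from_constants(constants, "peppas_sahlin")
        fits[0.5] = ModelFit(
            model=PeppasSahlin(k1=1.0, k2=0.0, n=0.79),
            r_squared=1.0, fit_cap=98.0, n_points_used=12,
        )
        with pytest.warns(ExcludedConstantWarning):
            corr = build_constant_correlations(fits, n_bar=0.79)
        assert corr.laws["k2"].n_points == 3  # the zero-k2 fit dropped

    def test_too_few_fits_rejected(self):
        fits = fits_from_constants({1.0: (2.0, 0.01)}, "peppas_sahlin")
        with pytest.raises(DomainError):
            build_constant_correlations(fits, n_bar=0.79)


class TestPredictProfile:
    @staticmethod
    def pzq_correlations():
        return build_constant_correlations(
            fits_from_constants(reference.WEIBULL_CONSTANTS["PVA-PZQ"], "weibull")
        )

    def test_zero_at_time_zero_and_capped(self):
        corr = self.pzq_correlations()
        profile = predict_profile(corr, 1.0, np.arange(0.0, 601.0, 1.0))
        assert profile.releases[0] == 0.0
        assert profile.releases.max() <= 100.0

    def test_higher_sav_releases_faster_pointwise(self):
        corr = self.pzq_correlations()
        t = np.arange(0.0, 301.0, 1.0)
        slow = predict_profile(corr, 1.0, t)
        fast = predict_profile(corr, 2.0, t)
        assert np.all(fast.releases >= slow.releases - 1e-9)

    def test_predicted_mdt_decreases_with_sav(self):
        corr = self.pzq_correlations()
        t = np.arange(0.0, 801.0, 0.5)
        mdts = [mdt(predict_profile(corr, s, t)) for s in (0.8, 1.5, 3.0, 6.0)]
        assert all(a > b for a, b in zip(mdts, mdts[1:]))
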