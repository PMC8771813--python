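import math

import numpy as np
import pytest

import fsadim as fd
from fsadim.calibration import (
    CalibrationRecord,
    CorrectionModel,
    apply_correction,
    calibrate,
    cmfsa,
    fit_alpha_closed_form,
    fit_correction,
    ideal_error_rate,
)


def make_model(exponents, coeffs, residual_stats=None, k_cal=5, n_cal=2500):
    return CorrectionModel(
        exponents=tuple(exponents),
        coeffs=tuple(coeffs),
        n_cal=n_cal,
        k_cal=k_cal,
        d_range=(2, 80),
        residual_stats=residual_stats,
    )


class TestClosedFormAlpha:
    def test_unbiased_records_give_zero(self):
        recs = [CalibrationRecord(d, np.full(4, float(d))) for d in (2, 5, 9)]
        assert fit_alpha_closed_form(recs) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_pair(self):
        recs = [
            CalibrationRecord(2, np.array([2.0])),
            CalibrationRecord(5, np.array([4.0])),
        ]
        expected = (0.0 * 2 + math.log(1.25) * 4) / (4 + 16)
        assert fit_alpha_closed_form(recs) == pytest.approx(expected)
        assert expected == pytest.approx(0.044629, abs=1e-6)

    def test_parameter_recovery_under_multiplicative_noise(self, rng):
        alpha = 0.03
        recs = []
        for D in range(2, 31):
            # invert d e^(alpha d) = D numerically, then jitter
            d = D
            for _ in range(60):
                d = D / math.exp(alpha * d)
            est = d * np.exp(rng.normal(0, 0.01, size=30))
            recs.append(CalibrationRecord(D, est))
        assert fit_alpha_closed_form(recs) == pytest.approx(alpha, abs=0.003)


class TestFitCorrection:
    def test_single_exponent_matches_closed_form_exactly(self, rng):
        recs = [
            CalibrationRecord(D, D * rng.uniform(0.6, 1.0, size=8))
            for D in (2, 7, 15, 30)
        ]
        model = fit_correction(recs, exponents=(1,), method="ols_all")
        assert model.coeffs[0] == pytest.approx(
            fit_alpha_closed_form(recs), rel=1e-12
        )

    def test_noise_free_multi_exponent_recovery(self):
        """Estimates placed exactly on the correction curve return the
        generating coefficients to linear-algebra precision."""
        from scipy.optimize import brentq

        true = {-1: 0.05, 1: 0.02, 2: 5e-4}

        def corr(d):
            return sum(a * d ** float(l) for l, a in true.items())

        recs = []
        for D in range(2, 40, 3):
            # the biased estimate d below D with ln(D/d) = corr(d)
            d = brentq(lambda t: math.log(D / t) - corr(t), 0.5, 2.0 * D)
            recs.append(CalibrationRecord(D, np.array([d])))
        model = fit_correction(recs, exponents=(-1, 1, 2), method="ols_all")
        np.testing.assert_allclose(
            model.coeffs, [true[-1], true[1], true[2]], atol=1e-10
        )

    def test_odr_means_agrees_with_ols_on_clean_data(self):
        recs = []
        for D in range(2, 30, 4):
            d = np.full(6, 0.8 * D)
            recs.append(CalibrationRecord(D, d))
        a = fit_correction(recs, exponents=(1,), method="ols_all").coeffs[0]
        b = fit_correction(recs, exponents=(1,), method="odr_means").coeffs[0]
        assert b == pytest.approx(a, rel=1e-4)

    def test_single_dimension_is_rejected(self):
        recs = [CalibrationRecord(5, np.array([4.0, 4.1]))]
        with pytest.raises(ValueError):
            fit_correction(recs, exponents=(1,))

    def test_residual_stats_populated(self, rng):
        recs = [
            CalibrationRecord(D, D * rng.uniform(0.7, 0.95, size=10))
            for D in (3, 8, 20)
        ]
        model = fit_correction(recs, exponents=(1,))
        assert set(model.residual_stats) == {3, 8, 20}
        for m, s in model.residual_stats.values():
            assert np.isfinite(m) and s >= 0


class TestApplyCorrection:
    def test_zero_coefficients_are_identity(self):
        model = make_model((1, 2), (0.0, 0.0))
        assert apply_correction(3.7, model, warn=False) == pytest.approx(3.7)

    def test_single_exponent_arithmetic(self):
        model = make_model((1,), (0.044629,))
        assert apply_correction(2.0, model, warn=False) == pytest.approx(
            2.0 * math.exp(0.089258), abs=1e-4
        )
        assert apply_correction(2.0, model, warn=False) == pytest.approx(2.1867, abs=1e-3)

    def test_monotone_when_coefficients_nonnegative(self):
        model = make_model((1, 2), (0.02, 0.0005))
        d = np.linspace(0.5, 60, 200)
        out = apply_correction(d, model, warn=False)
        assert np.all(np.diff(out) > 0)

    def test_small_d_limit_is_identity_with_unit_slope(self):
        model = make_model((1, 2, 3), (0.05, 0.001, 1e-5))
        eps = 1e-6
        assert apply_correction(eps, model, warn=False) / eps == pytest.approx(1.0, abs=1e-5)
        slope = (
            apply_correction(2 * eps, model, warn=False)
            - apply_correction(eps, model, warn=False)
        ) / eps
        assert slope == pytest.approx(1.0, abs=1e-4)

    def test_out_of_range_warns_but_returns(self):
        model = make_model((1,), (0.01,))
        with pytest.warns(RuntimeWarning):
            out = apply_correction(200.0, model)
        assert out > 200.0


class TestCalibrate:
    def test_reproducible_under_seed(self):
        kw = dict(n=200, k=2, d_min=2, d_max=6, n_realizations=3,
                  exponents=(1,), method="ols_all", seed=13, d_step=2)
        with pytest.warns(RuntimeWarning):
            a = calibrate(**kw)
        with pytest.warns(RuntimeWarning):
            b = calibrate(**kw)
        assert a.coeffs == b.coeffs
        assert a.residual_stats == b.residual_stats

    def test_degenerate_dimension_range_rejected(self):
        with pytest.raises(ValueError), pytest.warns(RuntimeWarning):
            calibrate(n=100, k=1, d_min=3, d_max=3, n_realizations=2,
                      exponents=(1,), seed=0)

    def test_narrow_regime_correction_recovers_dimensions(self):
        """Hard-boundary hypercubes at n = 1000, k = 1: the one-coefficient
        correction moves the systematically low raw estimates back to the
        diagonal for mid-range dimensions."""
        with pytest.warns(RuntimeWarning):
            model = calibrate(n=1000, k=1, d_min=2, d_max=30, n_realizations=5,
                              exponents=(1,), method="ols_all", seed=3, d_step=2)
        for D in (5, 10, 15):
            raws, corrected = [], []
            for i in range(5):
                cloud = fd.sample_hypercube(
                    fd.ManifoldSpec("hypercube", D, 1000, seed=500 + 31 * D + i)
                )
                raw = fd.mfsa(cloud, 1).value
                raws.append(raw)
                corrected.append(apply_correction(raw, model, warn=False))
            assert np.mean(raws) < D
            assert np.mean(corrected) == pytest.approx(D, rel=0.05)


class TestCmfsa:
    def test_identity_model_integer_rounding(self, monkeypatch):
        model = make_model((1,), (0.0,), k_cal=3, n_cal=100)
        cloud = fd.sample_hypercube(fd.ManifoldSpec("hypercube", 2, 100, seed=1))
        monkeypatch.setattr(
            "fsadim.calibration.mfsa",
            lambda c, k: fd.GlobalEstimate(3.4, "median", k, c.n),
        )
        est = cmfsa(cloud, 3, model, mode="integer")
        assert est.value == 3.0

    def test_mismatched_scale_warns(self):
        model = make_model((1,), (0.0,), k_cal=5, n_cal=100)
        cloud = fd.sample_hypercube(fd.ManifoldSpec("hypercube", 2, 100, seed=2))
        with pytest.warns(RuntimeWarning):
            cmfsa(cloud, 3, model, mode="fractal")

    def test_bad_mode_rejected(self):
        model = make_model((1,), (0.0,))
        cloud = fd.sample_hypercube(fd.ManifoldSpec("hypercube", 2, 100, seed=2))
        with pytest.raises(ValueError):
            cmfsa(cloud, 5, model, mode="both")


class TestIdealErrorRate:
    def test_zero_spread_means_zero_error(self):
        model = make_model((1,), (0.0,), residual_stats={10: (0.0, 0.0)})
        assert ideal_error_rate(model, 10) == 0.0

    def test_normal_arithmetic_case(self):
        # residual stats chosen so the corrected estimate has mean D and
        # sd 0.5 at D = 10: miss probability 1 - (Phi(1) - Phi(-1))
        s = math.sqrt(math.log(1 + (0.5 / 10.0) ** 2))
        m = 0.5 * s * s
        model = make_model((1,), (0.0,), residual_stats={10: (m, s)})
        assert ideal_error_rate(model, 10) == pytest.approx(0.3173, abs=2e-3)

    def test_matches_monte_carlo_rounding(self, rng):
        D, m, s = 12, 0.004, 0.02
        model = make_model((1,), (0.0,), residual_stats={D: (m, s)})
        draws = D * np.exp(-rng.normal(m, s, size=200_000))
        mc = np.mean(np.floor(draws + 0.5).astype(int) != D)
        assert ideal_error_rate(model, D) == pytest.approx(mc, abs=5e-3)

    def test_missing_stats_rejected(self):
        model = make_model((1,), (0.0,))
        with pytest.raises(ValueError):
            ideal_error_rate(model, 4)


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path):
        model = make_model(
            (-1, 1, 2, 3), (0.1, 0.02, -3e-4, 4e-6),
            residual_stats={2: (0.01, 0.005), 10: (-0.002, 0.01)},
        )
        path = tmp_path / "model.json"
        model.save(path)
        back = CorrectionModel.load(path)
        assert back == model

    def test_foreign_json_rejected(self, tmp_path):
        path = tmp_path / "other.json"
        path.write_text('{"something": 1}')
        with pytest.raises(ValueError):
            CorrectionModel.load(path)
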