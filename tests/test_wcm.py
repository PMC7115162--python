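import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import least_squares
from sklearn.base import clone

from sarbiomass.simulate import DEFAULT_COEFS_HH, DEFAULT_COEFS_HV
from sarbiomass.wcm import (
    DualPolInverter,
    InsufficientDataError,
    WaterCloudModel,
    WCMCoefficients,
    _forward,
    _jac_params,
    _records_to_arrays,
    calibrate_wcm,
    invert_records,
    invert_wcm,
    load_coefficients,
    save_coefficients,
    wcm_forward,
)

TIGHT = dict(tol=1e-18, max_iter=100)  # zero-residual fits need a deep stop


class TestForward:
    def test_zero_attenuation_leaves_bare_soil_term(self):
        coefs = WCMCoefficients(a=0.5, b=0.0, c=0.4, d=0.05, e1=1.0, e2=1.0)
        assert wcm_forward(coefs, 3.0, 0.25, 30.0) == pytest.approx(0.4 * 0.25 + 0.05)

    def test_vanishing_biomass_limit_is_soil_only(self):
        coefs = WCMCoefficients(a=0.5, b=0.3, c=0.4, d=0.05, e1=0.7, e2=0.9)
        limit = wcm_forward(coefs, 1e-12, 0.25, 30.0)
        assert limit == pytest.approx(0.4 * 0.25 + 0.05, rel=1e-6)
        assert wcm_forward(coefs, 0.0, 0.25, 30.0) == pytest.approx(0.4 * 0.25 + 0.05)

    def test_domain_errors(self):
        good = WCMCoefficients(a=0.5, b=0.3, c=0.4, d=0.05, e1=0.7, e2=0.9)
        with pytest.raises(ValueError):
            wcm_forward(good, -1.0, 0.2, 30.0)
        with pytest.raises(ValueError):
            wcm_forward(good, 1.0, 0.2, 90.0)
        bad_exponent = WCMCoefficients(a=0.5, b=0.3, c=0.4, d=0.05, e1=-0.1, e2=0.9)
        with pytest.raises(ValueError):
            wcm_forward(bad_exponent, 0.0, 0.2, 30.0)

    @settings(derandomize=True, max_examples=60)
    @given(
        mv1=st.floats(0.0, 0.5),
        mv2=st.floats(0.0, 0.5),
        biomass=st.floats(0.01, 8.0),
        theta=st.floats(15.0, 45.0),
    )
    def test_monotone_in_soil_moisture(self, mv1, mv2, biomass, theta):
        """With positive coefficients the soil term keeps d(sigma)/d(Mv) > 0."""
        coefs = DEFAULT_COEFS_HH
        lo, hi = sorted([mv1, mv2])
        if hi - lo < 1e-9:  # below float resolution of the soil term
            return
        assert wcm_forward(coefs, biomass, lo, theta) < wcm_forward(coefs, biomass, hi, theta)


class TestCalibration:
    def test_noise_free_recovery_reproduces_backscatter(self, noise_free):
        config, table, truth = noise_free
        for pol, key in (("HH", "sigma_hh_clean"), ("HV", "sigma_hv_clean")):
            fit = calibrate_wcm(table.records, pol, "wet", seed=7, **TIGHT)
            pred = wcm_forward(
                fit.coefficients,
                truth["wet_biomass"],
                truth["soil_moisture"],
                truth["incidence_angle"],
            )
            rel = np.abs(pred - truth[key]) / truth[key]
            assert rel.max() < 1e-6

    def test_too_few_records_raises(self, calibration_records):
        with pytest.raises(InsufficientDataError):
            calibrate_wcm(calibration_records[:5])

    def test_constant_biomass_warns_rank_deficiency(self, calibration_records):
        flat = [
            type(r)(**{**vars(r), "wet_biomass": 1.0, "dry_biomass": 0.5})
            for r in calibration_records[:8]
        ]
        with pytest.warns(RuntimeWarning, match="rank-deficien"):
            calibrate_wcm(flat, n_restarts=1, max_iter=2)

    def test_fixture_fit_beats_best_random_start(self, calibration_records):
        for pol in ("HH", "HV"):
            fit = calibrate_wcm(calibration_records, pol, "wet", seed=3)
            assert fit.sse < fit.best_initial_sse
            assert fit.iterations <= 100
            assert fit.sse == pytest.approx(float(fit.residuals @ fit.residuals))

    def test_same_seed_gives_bit_identical_fit(self, calibration_records):
        a = calibrate_wcm(calibration_records, "HV", "wet", seed=11)
        b = calibrate_wcm(calibration_records, "HV", "wet", seed=11)
        assert np.array_equal(a.coefficients.as_array(), b.coefficients.as_array())
        assert a.sse == b.sse and a.iterations == b.iterations

    def test_oracle_equivalence_on_noise_free_data(self, noise_free):
        """Own LM loop and a generic scipy optimizer agree to 1e-10 in SSE."""
        _, table, _ = noise_free
        for pol in ("HH", "HV"):
            L, Mv, theta, sigma = _records_to_arrays(list(table.records), pol, "wet")
            cos_t = np.cos(np.radians(theta))
            fit = calibrate_wcm(table.records, pol, "wet", seed=5, **TIGHT)
            starts = np.random.default_rng(5).uniform(0, 1, size=(20, 6))
            best = np.inf
            for x0 in starts:
                res = least_squares(
                    lambda p: _forward(p, L, Mv, cos_t) - sigma,
                    x0,
                    jac=lambda p: _jac_params(p, L, Mv, cos_t),
                    method="lm",
                    xtol=2.3e-16,
                    ftol=2.3e-16,
                    gtol=2.3e-16,
                    max_nfev=5000,
                )
                best = min(best, 2.0 * res.cost)
            assert abs(fit.sse - best) < 1e-10


class TestInversion:
    def test_forward_inverse_roundtrip(self, noise_free):
        config, table, truth = noise_free
        results = invert_records(config.true_coefs_hh, config.true_coefs_hv, table.records)
        L = np.array([r.biomass for r in results])
        Mv = np.array([r.soil_moisture for r in results])
        ok = (np.abs(L - truth["wet_biomass"]) < 1e-4) & (
            np.abs(Mv - truth["soil_moisture"]) < 1e-4
        )
        assert all(r.converged for r in results)
        assert ok.mean() >= 0.95

    def test_degenerate_attenuation_recovers_moisture_and_flags(self):
        chh = WCMCoefficients(0.1, 0.0, 0.5, 0.05, 1.0, 1.0, "HH")
        chv = WCMCoefficients(0.02, 0.0, 0.08, 0.004, 1.0, 1.0, "HV")
        mv_true = 0.27
        result = invert_wcm(
            chh,
            chv,
            wcm_forward(chh, 2.0, mv_true, 28.0),
            wcm_forward(chv, 2.0, mv_true, 28.0),
            28.0,
        )
        assert result.soil_moisture == pytest.approx(mv_true, abs=1e-9)
        assert not result.identifiable
        assert not result.converged

    def test_every_validation_row_gets_a_flagged_result(
        self, calibration_records, validation_records
    ):
        fit_hh = calibrate_wcm(calibration_records, "HH", "wet", seed=1)
        fit_hv = calibrate_wcm(calibration_records, "HV", "wet", seed=2)
        results = invert_records(fit_hh.coefficients, fit_hv.coefficients, validation_records)
        assert len(results) == len(validation_records) == 43
        for r in results:
            assert isinstance(r.converged, bool)
            assert r.iterations <= 400
            if r.converged:
                assert r.residual_norm <= 1e-6

    def test_mismatched_biomass_kind_rejected(self):
        chh = WCMCoefficients(0.1, 0.1, 0.5, 0.05, 1.0, 1.0, "HH", biomass_kind="wet")
        chv = WCMCoefficients(0.02, 0.1, 0.08, 0.004, 1.0, 1.0, "HV", biomass_kind="dry")
        with pytest.raises(ValueError, match="biomass kind"):
            invert_wcm(chh, chv, 0.1, 0.01, 28.0)

    def test_forward_invert_forward_identity_on_image(self, noise_free):
        """forward o invert o forward == forward for converged points."""
        config, table, truth = noise_free
        results = invert_records(config.true_coefs_hh, config.true_coefs_hv, table.records)
        for i, (r, shh) in enumerate(zip(results, truth["sigma_hh_clean"])):
            if r.converged:
                again = wcm_forward(
                    config.true_coefs_hh, r.biomass, r.soil_moisture,
                    truth["incidence_angle"][i],
                )
                assert again == pytest.approx(shh, abs=1e-6)


class TestEstimators:
    def test_water_cloud_model_fit_predict(self, noise_free):
        _, table, truth = noise_free
        X = np.column_stack(
            [truth["wet_biomass"], truth["soil_moisture"], truth["incidence_angle"]]
        )
        y = truth["sigma_hv_clean"]
        est = WaterCloudModel(polarization="HV", random_state=3, tol=1e-18)
        est.fit(X, y)
        assert np.allclose(est.predict(X), y, rtol=1e-6)
        assert est.score(X, y) > 0.999999
        # sklearn contract: cloneable, params round-trip
        est2 = clone(est)
        assert est2.get_params()["polarization"] == "HV"

    def test_dual_pol_inverter_predict_shape(self, noise_free):
        config, table, truth = noise_free
        inv = DualPolInverter(coefs_hh=config.true_coefs_hh, coefs_hv=config.true_coefs_hv)
        X = np.column_stack(
            [truth["sigma_hh_clean"], truth["sigma_hv_clean"], truth["incidence_angle"]]
        )
        out = inv.predict(X)
        assert out.shape == (len(table), 2)
        assert np.allclose(out[:, 0], truth["wet_biomass"], atol=1e-3)

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            WaterCloudModel().predict(np.ones((2, 3)))


def test_coefficients_serialization_roundtrip(tmp_path):
    coefs = WCMCoefficients(0.08, 0.1, 0.6, 0.06, 0.3, 1.0, "HV", biomass_kind="dry")
    path = tmp_path / "coefs.txt"
    save_coefficients(coefs, path, seed=9, sse=0.012)
    again = load_coefficients(path)
    assert again == coefs


def test_non_finite_coefficients_rejected():
    with pytest.raises(ValueError):
        WCMCoefficients(np.nan, 0.1, 0.6, 0.06, 0.3, 1.0)
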