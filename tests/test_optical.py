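import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import curve_fit
from sklearn.base import clone

from sarbiomass.optical import (
    OpticalBiomassModel,
    OpticalModel,
    calibrate_optical,
    compute_index,
    load_optical_model,
    predict_optical,
    save_optical_model,
)


class TestPredict:
    @pytest.mark.parametrize(
        "form, a, b, vi, expected",
        [
            ("NDVI_EXP", 1.0, 0.0, 0.0, 1.0),
            ("RTVI_LINEAR", 2.0, 3.0, 0.5, 4.0),
            ("SR_LOG", 2.0, 1.0, 1.0, 1.0),
            ("SRRE_LINEAR", -1.0, 0.5, 2.0, -1.5),
        ],
    )
    def test_functional_forms(self, form, a, b, vi, expected):
        model = OpticalModel(form=form, a=a, b=b)
        assert predict_optical(model, vi) == pytest.approx(expected)

    def test_log_form_rejects_nonpositive_index(self):
        model = OpticalModel(form="SR_LOG", a=1.0, b=0.0)
        with pytest.raises(ValueError):
            predict_optical(model, 0.0)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            OpticalModel(form="QUADRATIC", a=1.0, b=0.0)


class TestCalibrate:
    def test_noise_free_exponential_recovery(self):
        ndvi = np.linspace(0.1, 0.95, 23)
        biomass = 2.0 * np.exp(ndvi) - 1.0
        model = calibrate_optical(ndvi, biomass, form="NDVI_EXP", seed=0)
        assert model.a == pytest.approx(2.0, abs=1e-6)
        assert model.b == pytest.approx(-1.0, abs=1e-6)
        assert np.allclose(predict_optical(model, ndvi), biomass, atol=1e-6)

    def test_noise_free_log_recovery(self):
        sr = np.linspace(1.0, 12.0, 23)
        biomass = 3.0 * np.log(sr) + 0.2
        model = calibrate_optical(sr, biomass, form="SR_LOG", seed=1)
        assert model.a == pytest.approx(3.0, abs=1e-6)
        assert model.b == pytest.approx(0.2, abs=1e-6)

    @pytest.mark.parametrize("form", ["RTVI_LINEAR", "SRRE_LINEAR"])
    def test_linear_forms_match_closed_form_ols(self, calibration_records, form):
        vi = np.array([r.ndvi for r in calibration_records])
        y = np.array([r.wet_biomass for r in calibration_records])
        model = calibrate_optical(vi, y, form=form, seed=2)
        design = np.column_stack([vi, np.ones_like(vi)])
        a_ols, b_ols = np.linalg.lstsq(design, y, rcond=None)[0]
        assert model.a == pytest.approx(a_ols, abs=1e-8)
        assert model.b == pytest.approx(b_ols, abs=1e-8)

    def test_two_points_interpolate_exactly(self):
        model = calibrate_optical([0.2, 0.6], [1.0, 3.0], form="RTVI_LINEAR", seed=0)
        assert model.fit_sse == pytest.approx(0.0, abs=1e-16)
        assert predict_optical(model, 0.2) == pytest.approx(1.0, abs=1e-8)

    def test_fixture_fit_matches_independent_curve_fit(self, calibration_records):
        """Exponential NDVI fit agrees with scipy curve_fit at a held value."""
        vi = np.array([r.ndvi for r in calibration_records])
        y = np.array([r.wet_biomass for r in calibration_records])
        model = calibrate_optical(vi, y, form="NDVI_EXP", seed=4)
        (a_ref, b_ref), _ = curve_fit(lambda x, a, b: a * np.exp(x) + b, vi, y, p0=[1.0, 0.0])
        probe = 0.97088
        assert predict_optical(model, probe) == pytest.approx(
            a_ref * np.exp(probe) + b_ref, abs=1e-6
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            calibrate_optical([0.1, 0.2], [1.0], form="NDVI_EXP")
        with pytest.raises(ValueError, match="rank-deficien"):
            calibrate_optical([0.3, 0.3, 0.3], [1.0, 2.0, 3.0], form="RTVI_LINEAR")
        with pytest.raises(ValueError):
            calibrate_optical([0.1], [1.0], form="NDVI_EXP")
        with pytest.raises(ValueError):
            calibrate_optical([-0.1, 0.5], [1.0, 2.0], form="SR_LOG")


class TestEstimator:
    def test_fit_predict_and_clone(self, calibration_records):
        vi = np.array([r.ndvi for r in calibration_records])
        y = np.array([r.wet_biomass for r in calibration_records])
        est = OpticalBiomassModel(form="NDVI_EXP", random_state=0).fit(vi, y)
        assert est.predict(vi).shape == vi.shape
        assert est.sse_ >= 0
        clone(est)  # sklearn param contract

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            OpticalBiomassModel().predict([0.5])


class TestIndices:
    def test_default_formulas(self):
        assert compute_index({"nir": 0.3, "red": 0.3}, "NDVI") == 0.0
        assert compute_index({"nir": 0.4, "red": 0.1}, "SR") == pytest.approx(4.0)
        assert compute_index({"nir": 0.4, "red_edge": 0.2}, "SRRE") == pytest.approx(2.0)
        assert compute_index(
            {"nir": 0.4, "red_edge": 0.3, "green": 0.1}, "RTVI"
        ) == pytest.approx(7.0)

    def test_missing_band_named(self):
        with pytest.raises(KeyError, match="red_edge"):
            compute_index({"nir": 0.4, "green": 0.1}, "RTVI")

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            compute_index({"nir": 0.0, "red": 0.0}, "NDVI")

    def test_custom_formula_override(self):
        rtvi_core = lambda b: 100 * (b["nir"] - b["red_edge"]) - 10 * (b["nir"] - b["green"])
        assert compute_index(
            {"nir": 0.4, "red_edge": 0.3, "green": 0.1}, "RTVI", formula=rtvi_core
        ) == pytest.approx(7.0)

    @settings(derandomize=True, max_examples=60)
    @given(
        nir=st.floats(0.0, 1.0),
        red=st.floats(0.0, 1.0),
    )
    def test_ndvi_bounded(self, nir, red):
        if nir + red == 0:
            return
        assert -1.0 <= compute_index({"nir": nir, "red": red}, "NDVI") <= 1.0


def test_optical_model_serialization_roundtrip(tmp_path):
    model = OpticalModel(form="SR_LOG", a=2.5, b=-0.4, biomass_kind="dry",
                         fit_sse=0.33, iterations=7)
    path = tmp_path / "model.txt"
    save_optical_model(model, path, seed=5)
    assert load_optical_model(path) == model
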