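"""CA/IA surfaces, deviation functions, fitting and model selection."""

import numpy as np
import pytest

from toxmix import (
    DeviationSpec,
    FitResult,
    LogitCurve,
    SurfaceModel,
    ca_predict,
    deviation_g,
    fit_surface,
    ia_predict,
    likelihood_ratio_test,
    model_selection,
    predict_mortality,
    surface_grid,
)
from toxmix.exceptions import InsufficientDesignError, ToxmixError
from toxmix.mixture_surface import _gaussian_loglik


def _fit_result(form, sse, n_obs=16, n_free=None, reference="IA"):
    """Minimal FitResult for exercising the LR arithmetic directly."""
    curves = (LogitCurve(-2.0, 5.0), LogitCurve(-4.6, 3.5))
    model = SurfaceModel(reference, curves, DeviationSpec(form))
    free = {"none": 0, "SA": 1, "DR": 2, "DL": 2}[form] if n_free is None else n_free
    return FitResult(
        model=model,
        params={},
        sse=sse,
        loglik=_gaussian_loglik(sse, n_obs),
        r_squared=0.9,
        n_obs=n_obs,
        n_free=free,
        refit_singles=False,
        converged=True,
    )


class TestDeviationG:
    def test_zero_parameters_recover_reference(self):
        for form in ("none", "SA", "DR", "DL"):
            assert deviation_g(DeviationSpec(form), 0.3, 0.7, 1.5) == 0.0

    def test_closed_forms(self):
        assert deviation_g(DeviationSpec("SA", a=2.0), 0.5, 0.5) == pytest.approx(0.5)
        assert deviation_g(
            DeviationSpec("DR", a=1.0, b=2.0), 0.25, 0.75
        ) == pytest.approx(0.28125)
        assert deviation_g(
            DeviationSpec("DL", a=2.0, b=1.0), 0.5, 0.5, tu_total=1.0
        ) == pytest.approx(0.0)  # b=1 flips sign at the 1-TU level

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ToxmixError):
            deviation_g(DeviationSpec("SA", a=1.0), 0.5, 0.6)


class TestCAPredict:
    def test_single_compound_limit(self, cd_curve, zn_curve):
        model = SurfaceModel("CA", (cd_curve, zn_curve))
        assert ca_predict(model, 2.0, 0.0) == pytest.approx(
            predict_mortality(cd_curve, 2.0), abs=1e-10
        )
        assert ca_predict(model, 0.0, 10.0) == pytest.approx(
            predict_mortality(zn_curve, 10.0), abs=1e-10
        )

    def test_sham_combination_identity(self, cd_curve):
        """Mixing a compound with itself reproduces its own curve exactly."""
        model = SurfaceModel("CA", (cd_curve, cd_curve))
        for c in (0.5, 1.0, 2.75, 5.0, 12.0):
            assert ca_predict(model, c / 2, c / 2) == pytest.approx(
                predict_mortality(cd_curve, c), abs=1e-8
            )

    def test_equal_slope_half_tu_gives_half_effect(self):
        """Two curves at 0.5 TU each: the TU sum hits 1 exactly at F = 0.5."""
        c1 = LogitCurve(-2.0, 4.0)
        c2 = LogitCurve(-6.0, 4.0)
        model = SurfaceModel("CA", (c1, c2))
        f = ca_predict(model, 0.5 * c1.lc50, 0.5 * c2.lc50)
        assert f == pytest.approx(0.5, abs=1e-8)

    def test_rejects_double_zero(self, cd_curve, zn_curve):
        model = SurfaceModel("CA", (cd_curve, zn_curve))
        with pytest.raises(ToxmixError):
            ca_predict(model, 0.0, 0.0)


class TestIAPredict:
    def test_both_at_lc50(self, cd_curve, zn_curve):
        model = SurfaceModel("IA", (cd_curve, zn_curve))
        assert ia_predict(model, cd_curve.lc50, zn_curve.lc50) == pytest.approx(
            0.75, abs=1e-10
        )

    def test_hand_product(self, cd_curve, zn_curve):
        model = SurfaceModel("IA", (cd_curve, zn_curve))
        assert ia_predict(model, 0.6875, 5.105) == pytest.approx(0.1466, abs=5e-4)

    def test_single_compound_limit(self, cd_curve, zn_curve):
        model = SurfaceModel(
            "IA", (cd_curve, zn_curve), DeviationSpec("SA", a=-3.0)
        )
        assert ia_predict(model, 0.0, 8.0) == pytest.approx(
            predict_mortality(zn_curve, 8.0), abs=1e-10
        )


@pytest.mark.parametrize("reference", ["CA", "IA"])
@pytest.mark.parametrize("form", ["SA", "DR", "DL"])
def test_zero_deviation_equals_reference_pointwise(reference, form, cd_curve, zn_curve):
    """Every deviation form with a = b = 0 is the reference surface."""
    ref = SurfaceModel(reference, (cd_curve, zn_curve))
    dev = SurfaceModel(reference, (cd_curve, zn_curve), DeviationSpec(form))
    c1 = np.array([0.5, 1.0, 2.0, 2.75])
    c2 = np.array([3.0, 8.0, 15.0, 20.42])
    np.testing.assert_allclose(ref.predict(c1, c2), dev.predict(c1, c2), atol=1e-8)


def test_synergistic_deviation_raises_mortality(cd_curve, zn_curve):
    """a < 0 means synergism: predictions above the reference everywhere."""
    for reference in ("CA", "IA"):
        ref = SurfaceModel(reference, (cd_curve, zn_curve))
        syn = SurfaceModel(
            reference, (cd_curve, zn_curve), DeviationSpec("SA", a=-2.0)
        )
        c1, c2 = np.array([1.0, 2.0]), np.array([8.0, 12.0])
        assert np.all(syn.predict(c1, c2) > ref.predict(c1, c2))


def test_noise_free_reference_fit_is_exact(cd_curve, zn_curve, cd_zn_surface_data):
    """Fitting S/A to reference-generated data returns a ~ 0 and R^2 = 1."""
    model = SurfaceModel("IA", (cd_curve, zn_curve))
    data = cd_zn_surface_data.copy()
    data["obs_fraction"] = model.predict(
        data["conc_a"].to_numpy(), data["conc_b"].to_numpy()
    )
    fit = fit_surface(data, "IA", "SA", curves=(cd_curve, zn_curve))
    assert abs(fit.params["a"]) < 1e-3
    assert fit.r_squared == pytest.approx(1.0, abs=1e-8)


@pytest.mark.parametrize("reference", ["CA", "IA"])
@pytest.mark.parametrize(
    "form,a,b",
    [("SA", -2.0, 0.0), ("DR", -1.0, 2.0), ("DL", 1.0, 0.5)],
)
def test_parameter_recovery_noise_free(reference, form, a, b, cd_curve, zn_curve, cd_zn_surface_data):
    """Deviation parameters recovered to 1e-3 from noise-free surfaces."""
    truth = SurfaceModel(
        reference, (cd_curve, zn_curve), DeviationSpec(form, a=a, b=b)
    )
    data = cd_zn_surface_data.copy()
    data["obs_fraction"] = truth.predict(
        data["conc_a"].to_numpy(), data["conc_b"].to_numpy()
    )
    fit = fit_surface(
        data, reference, form, curves=(cd_curve, zn_curve), extra_starts=[[1.0, 1.0][: 1 if form == "SA" else 2]]
    )
    assert fit.params["a"] == pytest.approx(a, abs=1e-3)
    if form != "SA":
        assert fit.params["b"] == pytest.approx(b, abs=1e-3)


def test_fit_surface_guards(cd_curve, zn_curve):
    with pytest.raises(InsufficientDesignError):
        fit_surface(np.empty((0, 3)), "IA", curves=(cd_curve, zn_curve))
    flat = np.column_stack([[1, 2, 3], [5, 6, 7], [0.4, 0.4, 0.4]])
    with pytest.raises(Exception):
        fit_surface(flat, "IA", curves=(cd_curve, zn_curve))


class TestLikelihoodRatio:
    def test_identical_fits(self):
        parent = _fit_result("none", 0.5)
        child = _fit_result("SA", 0.5)
        cmp_ = likelihood_ratio_test(parent, child)
        assert cmp_.chi2 == 0.0 and cmp_.p_value == 1.0 and cmp_.df == 1

    def test_closed_form_statistic(self):
        """SSE ratio e with n = 16, df = 1: chi2 = 16, p ~ 6.3e-5."""
        parent = _fit_result("none", np.e)
        child = _fit_result("SA", 1.0)
        cmp_ = likelihood_ratio_test(parent, child)
        assert cmp_.chi2 == pytest.approx(16.0, rel=1e-12)
        assert cmp_.p_value == pytest.approx(6.33e-5, rel=0.01)

    def test_non_nested_rejected(self):
        with pytest.raises(ToxmixError):
            likelihood_ratio_test(_fit_result("DR", 1.0), _fit_result("DL", 0.9))

    def test_child_worse_floors_at_zero(self):
        with pytest.warns(UserWarning):
            cmp_ = likelihood_ratio_test(_fit_result("none", 1.0), _fit_result("SA", 1.1))
        assert cmp_.chi2 == 0.0


def test_sse_nesting_monotone_on_observed_data(cd_curve, zn_curve, cd_zn_surface_data):
    """SSE never increases down the reference -> S/A -> {DR, DL} ladder."""
    for reference in ("CA", "IA"):
        sel = model_selection(
            cd_zn_surface_data, reference, (cd_curve, zn_curve), refit_singles=False
        )
        sse = {form: fit.sse for form, fit in sel.fits.items()}
        assert sse["SA"] <= sse["none"] + 1e-12
        assert sse["DR"] <= sse["SA"] + 1e-12
        assert sse["DL"] <= sse["SA"] + 1e-12


def test_model_selection_recovers_dr_synergism(cd_curve, zn_curve, cd_zn_surface_data):
    """Strong dose-ratio-dependent synergism is detected against S/A."""
    truth = SurfaceModel(
        "IA", (cd_curve, zn_curve), DeviationSpec("DR", a=-3.0, b=6.0)
    )
    rng = np.random.default_rng(7)
    data = cd_zn_surface_data.copy()
    pred = truth.predict(data["conc_a"].to_numpy(), data["conc_b"].to_numpy())
    data["obs_fraction"] = np.clip(pred + rng.normal(0, 0.01, len(pred)), 0, 1)
    sel = model_selection(data, "IA", (cd_curve, zn_curve))
    assert sel.comparison("none", "DR").p_value < 0.05
    assert sel.comparison("SA", "DR").p_value < 0.05
    assert sel.fits["DR"].params["a"] < 0


def test_model_selection_report_shape(cd_curve, zn_curve, cd_zn_surface_data):
    sel = model_selection(cd_zn_surface_data, "CA", (cd_curve, zn_curve))
    frame = sel.to_frame()
    assert list(frame.columns) == ["CA", "SA", "DR", "DL"]
    assert "r_squared" in frame.index


class TestSurfaceGrid:
    def test_reference_grid_has_zero_g(self, cd_curve, zn_curve):
        model = SurfaceModel("CA", (cd_curve, zn_curve))
        grid = surface_grid(model, [0.25, 0.5], [0.25, 0.5])
        assert len(grid) == 4
        assert np.all(grid["g"] == 0.0)

    def test_shape_5x5(self, cd_curve, zn_curve):
        model = SurfaceModel("IA", (cd_curve, zn_curve))
        tu = np.linspace(0.1, 1.0, 5)
        assert len(surface_grid(model, tu, tu)) == 25

    def test_synergism_sign_convention(self, cd_curve, zn_curve):
        """a < 0 gives G < 0 and predictions above the reference inside the grid."""
        ref = SurfaceModel("IA", (cd_curve, zn_curve))
        syn = SurfaceModel("IA", (cd_curve, zn_curve), DeviationSpec("SA", a=-2.0))
        tu = [0.25, 0.5, 0.75]
        g_ref = surface_grid(ref, tu, tu)
        g_syn = surface_grid(syn, tu, tu)
        assert np.all(g_syn["g"] < 0)
        assert np.all(g_syn["predicted"].to_numpy() >= g_ref["predicted"].to_numpy())
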