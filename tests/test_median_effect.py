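"""Median-effect fitting: affected fractions, log-linearization, inverses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gastrosyn.median_effect import (
    MedianEffectModel,
    compute_fa,
    dose_for_fa,
    fit_median_effect,
    fit_study,
    predict_fa,
)
from gastrosyn.study import AffectedFraction, DoseResponseStudy

from conftest import exact_study


def study_from_means(treated_means: dict[float, float], control_mean: float, n: int = 2):
    doses, areas, ids = [], [], []
    for i in range(n):
        doses.append(0.0)
        areas.append(control_mean)
        ids.append(f"c{i}")
    for dose, mean in treated_means.items():
        for i in range(n):
            doses.append(dose)
            areas.append(mean)
            ids.append(f"{dose}-{i}")
    return DoseResponseStudy("t", ids, np.array(doses), np.array(areas))


class TestComputeFa:
    def test_half_damage_gives_half_affected(self):
        study = study_from_means({1.0: 50.0}, control_mean=100.0)
        (point,) = compute_fa(study)
        assert point.fa == pytest.approx(0.5)
        assert point.fu == pytest.approx(0.5)
        assert point.fa + point.fu == 1.0

    def test_zero_effect_clamps_to_eps(self):
        study = study_from_means({1.0: 100.0}, control_mean=100.0)
        with pytest.warns(UserWarning, match="clamped"):
            (point,) = compute_fa(study, clamp_eps=0.01)
        assert point.fa == 0.01
        assert point.clamped

    def test_full_protection_clamps_to_one_minus_eps(self):
        study = study_from_means({1.0: 0.0}, control_mean=100.0)
        with pytest.warns(UserWarning, match="clamped"):
            (point,) = compute_fa(study, clamp_eps=0.01)
        assert point.fa == 0.99

    def test_missing_control_raises(self):
        study = DoseResponseStudy("t", ["a", "b", "c"], [1.0, 2.0, 4.0], [10.0, 5.0, 2.0])
        with pytest.raises(ValueError, match="missing control"):
            compute_fa(study)

    def test_zero_control_mean_raises(self):
        study = study_from_means({1.0: 10.0}, control_mean=0.0)
        with pytest.raises(ValueError, match="degenerate control"):
            compute_fa(study)

    def test_duplicate_doses_pooled_by_mean(self):
        study = DoseResponseStudy(
            "t",
            ["c1", "c2", "a", "b"],
            [0.0, 0.0, 1.0, 1.0],
            [100.0, 100.0, 40.0, 60.0],
        )
        (point,) = compute_fa(study)
        assert point.fa == pytest.approx(0.5)
        assert point.n_animals == 2


class TestFit:
    def test_exact_unit_curve(self):
        # fa = 0.2, 0.5, 0.8 at doses 0.25, 1, 4 for Dm = m = 1
        points = [
            AffectedFraction(0.25, 0.2, 3),
            AffectedFraction(1.0, 0.5, 3),
            AffectedFraction(4.0, 0.8, 3),
        ]
        fit = fit_median_effect(points)
        assert fit.dm_ == pytest.approx(1.0, abs=1e-12)
        assert fit.m_ == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared_ == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("dm,m", [(17.40, 0.62), (0.004, 0.21), (11.50, 1.49), (1.0, 1.0)])
    def test_noiseless_forward_generate_refit(self, dm, m):
        doses = dm * np.array([0.2, 0.5, 1.0, 2.0, 5.0])
        fit = fit_study(exact_study(dm, m, doses), clamp_eps=1e-9)
        assert fit.dm_ == pytest.approx(dm, rel=1e-9)
        assert fit.m_ == pytest.approx(m, rel=1e-9)

    def test_noisy_fit_matches_grid_search_oracle(self, rng):
        # independent oracle: exhaustive grid over (Dm, m) minimizing SSE in
        # log-odds space; OLS must land within one grid cell of the argmin
        dm_true, m_true = 5.0, 0.9
        doses = dm_true * np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        fa_clean = (doses / dm_true) ** m_true / (1 + (doses / dm_true) ** m_true)
        odds = fa_clean / (1 - fa_clean) * np.exp(rng.normal(0, 0.1 * np.log(10), 5))
        fa = odds / (1 + odds)
        fit = MedianEffectModel().fit(doses, fa)

        y = np.log10(fa / (1 - fa))
        x = np.log10(doses)
        dm_grid = np.linspace(3.0, 8.0, 801)
        m_grid = np.linspace(0.5, 1.5, 801)
        sse = np.array(
            [[np.sum((m * x - m * np.log10(dmv) - y) ** 2) for dmv in dm_grid] for m in m_grid]
        )
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.m_ == pytest.approx(m_grid[i], abs=(m_grid[1] - m_grid[0]))
        assert fit.dm_ == pytest.approx(dm_grid[j], abs=(dm_grid[1] - dm_grid[0]))

    def test_too_few_points_raises(self):
        points = [AffectedFraction(1.0, 0.4, 3), AffectedFraction(2.0, 0.6, 3)]
        with pytest.raises(ValueError, match="at least 3"):
            fit_median_effect(points)

    def test_decreasing_response_flagged_not_fatal(self):
        points = [
            AffectedFraction(1.0, 0.8, 3),
            AffectedFraction(2.0, 0.5, 3),
            AffectedFraction(4.0, 0.2, 3),
        ]
        with pytest.warns(UserWarning, match="not monotone"):
            fit = fit_median_effect(points)
        assert not fit.increasing_

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_dose_scale_covariance(self, scale):
        # multiplying doses by c multiplies Dm by c and leaves m unchanged
        points = [
            AffectedFraction(0.5, 0.31, 3),
            AffectedFraction(1.0, 0.46, 3),
            AffectedFraction(2.0, 0.67, 3),
            AffectedFraction(4.0, 0.81, 3),
        ]
        base = fit_median_effect(points)
        scaled = fit_median_effect(
            [AffectedFraction(p.dose * scale, p.fa, p.n_animals) for p in points]
        )
        assert scaled.dm_ == pytest.approx(base.dm_ * scale, rel=1e-9)
        assert scaled.m_ == pytest.approx(base.m_, rel=1e-9)


class TestPredictInverse:
    def test_fa_at_median_dose_is_half(self):
        fit = MedianEffectModel.from_params(11.50, 1.49)
        assert predict_fa(fit, 11.50) == pytest.approx(0.5)

    def test_unit_curve_dose_nine(self, unit_fit):
        assert predict_fa(unit_fit, 9.0) == pytest.approx(0.9)

    def test_dose_for_half_is_dm_for_any_m(self):
        for m in (0.3, 1.0, 2.5):
            fit = MedianEffectModel.from_params(7.0, m)
            assert dose_for_fa(fit, 0.5) == pytest.approx(7.0)

    def test_dose_for_ninety_percent_protection(self):
        fit = MedianEffectModel.from_params(17.40, 0.62)
        assert dose_for_fa(fit, 0.9) == pytest.approx(17.40 * 9.0 ** (1 / 0.62), rel=1e-12)
        assert dose_for_fa(fit, 0.9) == pytest.approx(602.1, rel=1e-3)

    @pytest.mark.parametrize("fa", [0.1, 0.5, 0.9])
    def test_round_trip_identity(self, fa):
        fit = MedianEffectModel.from_params(3.3, 0.77)
        assert predict_fa(fit, dose_for_fa(fit, fa)) == pytest.approx(fa, abs=1e-12)

    @given(m=st.floats(0.1, 4.0), dm=st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, m, dm):
        fit = MedianEffectModel.from_params(dm, m)
        doses = dm * np.logspace(-2, 2, 25)
        fa = fit.predict(doses)
        assert np.all(np.diff(fa) > 0)
        assert np.all((fa > 0) & (fa < 1))
        grid = np.linspace(0.05, 0.95, 19)
        assert np.all(np.diff(fit.dose_for(grid)) > 0)

    def test_invalid_inputs_raise(self, unit_fit):
        with pytest.raises(ValueError):
            predict_fa(unit_fit, -1.0)
        with pytest.raises(ValueError):
            dose_for_fa(unit_fit, 1.0)


def test_sklearn_estimator_contract():
    from sklearn.base import clone

    model = MedianEffectModel(min_points=4)
    assert clone(model).get_params() == {"min_points": 4}
    doses = np.array([0.25, 0.5, 1.0, 2.0])
    fa = np.array([0.2, 0.33, 0.5, 0.67])
    fitted = model.fit(doses, fa)
    assert fitted.score(doses, fa) > 0.99  # R^2 on the fa scale
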