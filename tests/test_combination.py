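"""Combination design, median-effect fit on total dose, combination index."""

import numpy as np
import pytest

from gastrosyn.combination import (
    CHOU_CI_BANDS,
    DEFAULT_CI_BANDS,
    build_design,
    ci_curve,
    classify_ci,
    combination_index,
    fit_combination,
    theoretical_dm,
)
from gastrosyn.median_effect import MedianEffectModel
from gastrosyn.reference import combination_fit, single_drug_fit
from gastrosyn.simulate import GeneratorConfig, generate_combination


def bisect_dose(fit, fa, lo=1e-12, hi=1e12):
    """Independent oracle: invert the median-effect curve by pure bisection."""
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # bisection in log-dose
        ratio = (mid / fit.dm_) ** fit.m_
        if ratio / (1 + ratio) < fa:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


class TestDesign:
    def test_reference_equipotent_pair(self):
        design = build_design(0.004, 17.40, levels=[1.0])
        assert design.doses == [(0.004, 17.40)]
        assert design.total_doses[0] == pytest.approx(17.404)

    def test_unit_pair(self):
        design = build_design(1.0, 1.0, levels=[1.0])
        assert design.doses == [(1.0, 1.0)]
        assert design.total_doses[0] == 2.0

    def test_quarter_level(self):
        design = build_design(0.99, 11.50, levels=[0.25])
        (d1, d2) = design.doses[0]
        assert d1 == pytest.approx(0.2475)
        assert d2 == pytest.approx(2.875)

    def test_constant_ratio_across_levels(self):
        design = build_design(3.0, 7.0)
        pairs = np.array(design.doses)
        assert np.allclose(pairs[:, 0] / pairs[:, 1], 3.0 / 7.0)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            build_design(-1.0, 2.0)
        with pytest.raises(ValueError):
            build_design(1.0, 2.0, levels=[0.0])


class TestTheoreticalDm:
    @pytest.mark.parametrize(
        "dm1,dm2,expected",
        [(0.004, 17.40, 8.70), (0.99, 17.40, 9.19), (0.004, 11.50, 5.75), (0.99, 11.50, 6.24)],
    )
    def test_reference_values(self, dm1, dm2, expected):
        assert theoretical_dm(dm1, dm2) == pytest.approx(expected, abs=0.005)

    def test_symmetry_and_identity(self):
        assert theoretical_dm(4.0, 4.0) == 4.0
        assert theoretical_dm(2.0, 6.0) == theoretical_dm(6.0, 2.0)

    def test_non_positive_raises(self):
        with pytest.raises(ValueError):
            theoretical_dm(0.0, 1.0)


class TestFitCombination:
    def test_identical_drugs_additive_recovers_dm(self):
        cfg = GeneratorConfig(dm_true=1.0, m_true=1.0, area_noise_sigma_log=0.0, treatment_id="a")
        cfg2 = GeneratorConfig(dm_true=1.0, m_true=1.0, area_noise_sigma_log=0.0, treatment_id="b")
        combo = generate_combination(cfg, cfg2, interaction_ci=1.0, area_noise_sigma_log=0.0)
        fit = fit_combination(combo, clamp_eps=1e-8)
        assert fit.dm_ == pytest.approx(1.0, rel=1e-9)
        assert fit.m_ == pytest.approx(1.0, rel=1e-9)

    def test_forward_generate_refit_total_dose(self):
        # equal-m components: the Loewe-additive combination is itself
        # median-effect with Dm = (Dm1 + Dm2)/2 scaled by the target CI
        cfg1 = GeneratorConfig(dm_true=2.5, m_true=0.98, area_noise_sigma_log=0.0, treatment_id="a")
        cfg2 = GeneratorConfig(dm_true=10.2, m_true=0.98, area_noise_sigma_log=0.0, treatment_id="b")
        target_ci = 1.0
        combo = generate_combination(cfg1, cfg2, target_ci, area_noise_sigma_log=0.0)
        fit = fit_combination(combo, clamp_eps=1e-8)
        assert fit.dm_ == pytest.approx(theoretical_dm(2.5, 10.2), rel=1e-9)
        assert fit.m_ == pytest.approx(0.98, rel=1e-9)

    def test_scale_covariance_of_total_dose(self):
        cfg1 = GeneratorConfig(dm_true=1.0, m_true=1.0, area_noise_sigma_log=0.0, treatment_id="a")
        cfg2 = GeneratorConfig(dm_true=3.0, m_true=1.0, area_noise_sigma_log=0.0, treatment_id="b")
        combo = generate_combination(cfg1, cfg2, 1.0, area_noise_sigma_log=0.0)
        fit = fit_combination(combo, clamp_eps=1e-8)
        doubled = type(combo)(
            design=build_design(2.0, 6.0, combo.design.ratio_levels, "a", "b"),
            animal_ids=list(combo.animal_ids),
            dose1=combo.dose1 * 2,
            dose2=combo.dose2 * 2,
            areas=combo.areas.copy(),
        )
        fit2 = fit_combination(doubled, clamp_eps=1e-8)
        assert fit2.dm_ == pytest.approx(2 * fit.dm_, rel=1e-9)


class TestCombinationIndex:
    def test_ci50_reduces_to_dm_ratio(self):
        comb = MedianEffectModel.from_params(6.35, 0.98)
        f1 = single_drug_fit("TAE")
        f2 = single_drug_fit("bismuth_subsalicylate")
        ci = combination_index(0.5, comb, f1, f2)
        assert ci == pytest.approx(6.35 / theoretical_dm(0.004, 11.50), rel=1e-12)
        assert ci == pytest.approx(1.10, abs=0.01)

    def test_ci90_curcumin_bismuth(self):
        ci = combination_index(
            0.9,
            combination_fit("curcumin", "bismuth_subsalicylate"),
            single_drug_fit("curcumin"),
            single_drug_fit("bismuth_subsalicylate"),
        )
        assert ci == pytest.approx(0.99, abs=0.01)

    def test_exact_loewe_additive_equal_m_is_unity(self):
        f1 = MedianEffectModel.from_params(2.0, 1.3)
        f2 = MedianEffectModel.from_params(9.0, 1.3)
        comb = MedianEffectModel.from_params(theoretical_dm(2.0, 9.0), 1.3)
        for fa in np.linspace(0.05, 0.95, 19):
            assert combination_index(fa, comb, f1, f2) == pytest.approx(1.0, rel=1e-12)

    def test_ci50_identity_random_parameters(self, rng):
        # CI(0.5) = Dm_comb / ((Dm1 + Dm2)/2) for the equipotent design,
        # whatever the three m values are
        for _ in range(50):
            dm1, dm2, dmc = rng.uniform(0.01, 50.0, 3)
            m1, m2, mc = rng.uniform(0.2, 3.0, 3)
            comb = MedianEffectModel.from_params(dmc, mc)
            f1 = MedianEffectModel.from_params(dm1, m1)
            f2 = MedianEffectModel.from_params(dm2, m2)
            assert combination_index(0.5, comb, f1, f2) == pytest.approx(
                dmc / theoretical_dm(dm1, dm2), rel=1e-12
            )

    def test_closed_form_matches_bisection_oracle(self, rng):
        for _ in range(100):
            dm1, dm2, dmc = rng.uniform(0.01, 50.0, 3)
            m1, m2, mc = rng.uniform(0.2, 3.0, 3)
            fa = rng.uniform(0.05, 0.95)
            comb = MedianEffectModel.from_params(dmc, mc)
            f1 = MedianEffectModel.from_params(dm1, m1)
            f2 = MedianEffectModel.from_params(dm2, m2)
            share1 = dm1 / (dm1 + dm2)
            total = bisect_dose(comb, fa)
            oracle = total * share1 / bisect_dose(f1, fa) + total * (1 - share1) / bisect_dose(f2, fa)
            assert combination_index(fa, comb, f1, f2) == pytest.approx(oracle, rel=1e-9)

    def test_degenerate_second_drug_share(self):
        # as drug 2's dose share vanishes with identical curves, CI -> 1
        fit = MedianEffectModel.from_params(5.0, 1.0)
        ci = combination_index(0.7, fit, fit, fit, ratio=(1.0, 1e-12))
        assert ci == pytest.approx(1.0, rel=1e-9)

    def test_invalid_fa_raises(self, unit_fit):
        with pytest.raises(ValueError):
            combination_index(0.0, unit_fit, unit_fit, unit_fit)


class TestCiCurve:
    def test_equal_m_additive_flat_at_one(self):
        f1 = MedianEffectModel.from_params(1.0, 1.0)
        f2 = MedianEffectModel.from_params(4.0, 1.0)
        comb = MedianEffectModel.from_params(2.5, 1.0)
        result = ci_curve(comb, f1, f2)
        assert np.allclose(result.ci_values, 1.0, rtol=1e-12)
        assert set(result.ci_at) == {0.1, 0.5, 0.9}

    def test_reference_tae_ranitidine_shape(self):
        # antagonistic at median effect, crossing below 1 before fa = 0.9
        result = ci_curve(
            combination_fit("TAE", "ranitidine"),
            single_drug_fit("TAE"),
            single_drug_fit("ranitidine"),
            fa_grid=np.linspace(0.1, 0.9, 81),
        )
        assert np.all(np.diff(result.ci_values) < 0)
        assert result.ci_at[0.5] > 1.0 > result.ci_at[0.9]

    def test_continuity_on_dense_grid(self):
        grid = np.linspace(0.1, 0.9, 801)
        result = ci_curve(
            combination_fit("curcumin", "bismuth_subsalicylate"),
            single_drug_fit("curcumin"),
            single_drug_fit("bismuth_subsalicylate"),
            fa_grid=grid,
        )
        steps = np.abs(np.diff(np.log(result.ci_values)))
        assert steps.max() < 0.05  # no jumps beyond the grid-local scale

    def test_empty_grid_raises(self, unit_fit):
        with pytest.raises(ValueError, match="empty"):
            ci_curve(unit_fit, unit_fit, unit_fit, fa_grid=[])


class TestClassify:
    @pytest.mark.parametrize(
        "ci,label",
        [
            (3.57, "antagonism"),
            (0.99, "additive"),
            (1.0, "additive"),
            (0.32, "synergism"),
            (1.28, "additive"),
            (1.35, "antagonism"),
        ],
    )
    def test_default_bands_reproduce_reference_labels(self, ci, label):
        assert classify_ci(ci, DEFAULT_CI_BANDS) == label

    def test_strict_bands_preset(self):
        assert classify_ci(1.28, CHOU_CI_BANDS) == "antagonism"
        assert classify_ci(1.0, CHOU_CI_BANDS) == "additive"

    def test_invalid_bands_raise(self):
        with pytest.raises(ValueError):
            classify_ci(1.0, (1.2, 1.5))
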