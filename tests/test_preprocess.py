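"""The seven-step reduction protocol, stage by stage and end to end."""

import numpy as np
import pytest

from elastofit import (
    EngineeringCurve,
    HyperelasticParams,
    PipelineConfig,
    SpecimenGeometry,
    SyntheticSpecimenConfig,
    TrueCurve,
    fit_cubic_trend,
    generate_raw_specimen,
    postprocess_pipeline,
    resample_grid,
    shift_to_origin,
    to_stretch,
    to_true,
    trim_negative_loads,
    trim_post_yield,
    uniaxial_stress,
)
from elastofit.preprocess import EmptyCurveError, PipelineStageError


def _eng(strain, stress):
    return EngineeringCurve(np.asarray(strain, float), np.asarray(stress, float))


class TestTrimNegativeLoads:
    def test_leading_run_removed(self):
        c = trim_negative_loads(_eng([0, 1, 2, 3], [-0.01, -0.001, 0.02, 0.05]))
        np.testing.assert_allclose(c.eng_stress, [0.02, 0.05])
        np.testing.assert_allclose(c.eng_strain, [2, 3])

    def test_all_positive_unchanged(self):
        c = trim_negative_loads(_eng([0, 1, 2], [0.1, 0.2, 0.3]))
        assert len(c) == 3

    def test_interior_dip_retained_with_warning(self):
        with pytest.warns(UserWarning, match="interior dip"):
            c = trim_negative_loads(_eng([0, 1, 2, 3], [-0.1, 0.1, -0.05, 0.2]))
        np.testing.assert_allclose(c.eng_stress, [0.1, -0.05, 0.2])

    def test_all_nonpositive_raises(self):
        with pytest.raises(EmptyCurveError):
            trim_negative_loads(_eng([0, 1], [-0.1, 0.0]))


class TestTrimPostYield:
    def test_cut_at_global_max(self):
        c = trim_post_yield(_eng(range(5), [0.1, 0.5, 0.9, 0.7, 0.3]))
        np.testing.assert_allclose(c.eng_stress, [0.1, 0.5, 0.9])

    def test_monotone_curve_unchanged(self):
        c = trim_post_yield(_eng(range(4), [0.1, 0.2, 0.3, 0.4]))
        assert len(c) == 4

    def test_generator_injected_yield_count(self):
        params = HyperelasticParams("humphrey", 9e-4, 0.42)
        geom = SpecimenGeometry(gauge_length=30, width=10, thickness=3)
        cfg = SyntheticSpecimenConfig(params=params, geometry=geom,
                                      slack_points=0, seed=1)
        raw, truth = generate_raw_specimen(cfg)
        eng = _eng(raw.extension / 30.0, raw.load / 30.0)
        kept = trim_post_yield(eng)
        assert len(eng) - len(kept) == truth.post_yield_points


class TestShiftAndTrue:
    def test_shift_to_origin(self):
        c = shift_to_origin(_eng([0.02, 0.05, 0.1], [0.003, 0.01, 0.02]))
        assert c.eng_strain[0] == 0.0
        assert c.eng_stress[0] == 0.0
        np.testing.assert_allclose(c.eng_strain, [0, 0.03, 0.08])

    @pytest.mark.parametrize("op", [trim_negative_loads, trim_post_yield,
                                    shift_to_origin])
    def test_steps_idempotent(self, op):
        c = _eng([0.0, 0.1, 0.2, 0.3], [0.01, 0.05, 0.2, 0.4])
        once = op(c)
        twice = op(once)
        np.testing.assert_array_equal(once.eng_strain, twice.eng_strain)
        np.testing.assert_array_equal(once.eng_stress, twice.eng_stress)

    def test_true_conversion_examples(self):
        t = to_true(_eng([0.0, 0.5, np.e - 1.0], [1.0, 2.0, 1.0]))
        assert t.true_stress[0] == pytest.approx(1.0)
        assert t.true_strain[0] == 0.0
        assert t.true_stress[1] == pytest.approx(3.0)
        assert t.true_strain[1] == pytest.approx(np.log(1.5))
        assert t.true_strain[2] == pytest.approx(1.0)

    def test_true_conversion_invertible(self):
        rng = np.random.default_rng(7)
        strain = np.sort(rng.uniform(0, 1.5, 40))
        stress = rng.uniform(0, 2, 40)
        t = to_true(_eng(strain, stress))
        back_strain = np.expm1(t.true_strain)
        back_stress = t.true_stress / np.exp(t.true_strain)
        np.testing.assert_allclose(back_strain, strain, rtol=1e-12, atol=1e-14)
        np.testing.assert_allclose(back_stress, stress, rtol=1e-12)

    def test_strain_at_or_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            to_true(_eng([-1.0, 0.0], [0.1, 0.2]))


class TestTrendline:
    def test_exact_cubic_recovered(self):
        e = np.linspace(0, 0.8, 30)
        t = TrueCurve(e, 2 * e**3 + 0.5 * e)
        trend = fit_cubic_trend(t)
        np.testing.assert_allclose(trend.coefficients, [0, 0.5, 0, 2], atol=1e-10)
        assert trend.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_stress_flagged(self):
        t = TrueCurve(np.linspace(0, 1, 10), np.full(10, 0.5))
        with pytest.warns(UserWarning, match="undefined"):
            trend = fit_cubic_trend(t)
        assert np.isnan(trend.r_squared)

    def test_too_few_distinct_strains(self):
        t = TrueCurve(np.array([0.0, 0.0, 1.0, 1.0]), np.array([0, 0, 1, 1.0]))
        with pytest.raises(np.linalg.LinAlgError):
            fit_cubic_trend(t)

    def test_smooth_constitutive_curve_fits_well(self):
        e = np.linspace(1e-3, 0.7, 100)
        params = HyperelasticParams("mooney_rivlin", 1e-3, 1e-3)
        t = TrueCurve(e, uniaxial_stress(params, 1.0 + e))
        assert fit_cubic_trend(t).r_squared >= 0.99


class TestResampleAndStretch:
    def test_grid_construction(self):
        e = np.linspace(0, 0.06, 20)
        trend = fit_cubic_trend(TrueCurve(e, e))
        out = resample_grid(trend, strain_max=0.05, interval=0.01)
        np.testing.assert_allclose(out.true_strain, [0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(out.true_stress, out.true_strain, atol=1e-12)

    def test_no_extrapolation_beyond_data(self):
        e = np.linspace(0, 0.42, 20)
        trend = fit_cubic_trend(TrueCurve(e, 2 * e))
        out = resample_grid(trend, strain_max=1.0, interval=0.01)
        assert out.true_strain.max() <= 0.42 + 1e-12
        assert len(out) == 42

    def test_stretch_map_and_roundtrip(self):
        e = 0.01 * np.arange(1, 101)
        t = TrueCurve(e, e**2)
        s = to_stretch(t)
        np.testing.assert_allclose(s.stretch, 1.0 + e)
        np.testing.assert_allclose(s.stretch - 1.0, e)
        assert s.interval == pytest.approx(0.01)
        s_exp = to_stretch(t, mode="exp")
        np.testing.assert_allclose(s_exp.stretch, np.exp(e))


@pytest.fixture(scope="module")
def specimen():
    params = HyperelasticParams("humphrey", 1.2e-3, 0.5)
    geom = SpecimenGeometry(gauge_length=30, width=10, thickness=3)
    cfg = SyntheticSpecimenConfig(params=params, geometry=geom,
                                  slack_points=7, seed=2)
    raw, truth = generate_raw_specimen(cfg)
    return params, geom, raw, truth


class TestPipeline:
    def test_stage_counts_match_injected_structure(self, specimen):
        _, geom, raw, truth = specimen
        res = postprocess_pipeline(raw, geom)
        n0 = res.stage_counts["engineering_stress_strain"]
        assert n0 - res.stage_counts["trim_negative_loads"] == truth.slack_points
        assert (res.stage_counts["trim_negative_loads"]
                - res.stage_counts["trim_post_yield"]) == truth.post_yield_points

    def test_reduction_matches_generating_curve(self, specimen):
        params, geom, raw, _ = specimen
        res = postprocess_pipeline(raw, geom)
        clean = uniaxial_stress(params, res.curve.stretch)
        err = np.max(np.abs(res.curve.stress - clean)) / np.max(np.abs(clean))
        assert err <= 0.02

    def test_stretch_stays_in_unit_band(self, specimen):
        _, geom, raw, _ = specimen
        curve = postprocess_pipeline(raw, geom).curve
        assert curve.stretch.min() >= 1.0
        assert curve.stretch.max() <= 2.0 + 1e-12

    def test_origin_stress_approaches_trendline_intercept(self, specimen):
        # As the grid interval shrinks the first-node stress tends to the
        # cubic's intercept (which the origin shift keeps small relative
        # to the peak), so the curve approaches (1, ~0).
        _, geom, raw, _ = specimen
        results = [
            postprocess_pipeline(raw, geom, PipelineConfig(grid_interval=h))
            for h in (0.04, 0.01, 0.0025)
        ]
        a0 = results[0].trend.coefficients[0]
        gaps = [abs(r.curve.stress[0] - a0) for r in results]
        assert gaps[-1] < gaps[0]
        for r in results:
            assert abs(r.curve.stress[0]) <= 0.02 * r.curve.stress.max()

    def test_stage_error_names_stage(self):
        geom = SpecimenGeometry(gauge_length=30, width=10, thickness=3)
        from elastofit import RawTensileCurve
        raw = RawTensileCurve(np.arange(4.0), np.full(4, -1.0))
        with pytest.raises(PipelineStageError, match="trim_negative_loads"):
            postprocess_pipeline(raw, geom)
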