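import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from infraccess.layers import (
    DEFAULT_TYPE_CATALOG,
    CalibrationFit,
    EnvInputs,
    aggregate_category,
    apply_calibration,
    environmental_composite,
    fit_calibration,
    normalize_type_layer,
    sensitivity_catalog,
)

from conftest import make_layer


class TestTypeCatalog:
    def test_default_assignment(self):
        assert {t for t, c in DEFAULT_TYPE_CATALOG.items() if c == "economic"} == {
            "telecom", "energy", "transport",
        }
        assert {t for t, c in DEFAULT_TYPE_CATALOG.items() if c == "social"} == {
            "health", "education",
        }
        assert {t for t, c in DEFAULT_TYPE_CATALOG.items() if c == "environmental"} == {
            "water", "waste",
        }

    def test_sensitivity_remap_moves_water_and_waste(self):
        remap = sensitivity_catalog()
        assert remap["water"] == "economic"
        assert remap["waste"] == "social"
        assert all(c != "environmental" for c in remap.values())


class TestNormalize:
    def test_division_by_max(self):
        out = normalize_type_layer(make_layer([[2.0, 4.0]]))
        np.testing.assert_allclose(out.values, [[0.5, 1.0]])

    def test_constant_layer_all_ones(self):
        out = normalize_type_layer(make_layer([[3.0, 3.0], [3.0, 3.0]]))
        np.testing.assert_allclose(out.values, 1.0)

    def test_max_over_valid_cells_only(self):
        layer = make_layer([[0.0, 5.0], [np.nan, 10.0]])
        out = normalize_type_layer(layer)
        np.testing.assert_allclose(out.values[out.mask], [0.0, 0.5, 1.0])
        assert not out.mask[1, 0]

    @pytest.mark.parametrize("bad", [np.zeros((2, 2)), np.full((2, 2), np.nan)])
    def test_degenerate_layers_rejected(self, bad):
        with pytest.raises(ValueError):
            normalize_type_layer(make_layer(bad))

    @given(st.lists(st.floats(0.01, 1e6), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, values):
        layer = make_layer([values])
        once = normalize_type_layer(layer)
        twice = normalize_type_layer(once)
        np.testing.assert_allclose(twice.values, once.values)


class TestAggregate:
    def test_two_layer_mean(self):
        out = aggregate_category([make_layer([[0.2]]), make_layer([[0.6]])])
        assert out.values[0, 0] == pytest.approx(0.4)

    def test_single_layer_identity(self):
        layer = make_layer([[0.1, 0.9]])
        out = aggregate_category([layer])
        np.testing.assert_allclose(out.values, layer.values)

    def test_mean_over_valid_contributors(self):
        layers = [make_layer([[1.0]]), make_layer([[0.0]]), make_layer([[np.nan]])]
        out = aggregate_category(layers)
        assert out.values[0, 0] == pytest.approx(0.5)
        assert out.mask[0, 0]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_category([])

    def test_bounded_by_inputs(self, rng):
        layers = [make_layer(rng.random((5, 5))) for _ in range(4)]
        out = aggregate_category(layers)
        stack = np.stack([l.values for l in layers])
        assert np.all(out.values >= stack.min(axis=0) - 1e-12)
        assert np.all(out.values <= stack.max(axis=0) + 1e-12)


class TestEnvironmentalComposite:
    def test_hand_example(self):
        env = EnvInputs(
            ci_env=make_layer([[0.4]]),
            green=make_layer([[0.0]]),
            air=make_layer([[0.5]]),
            heat=make_layer([[0.5]]),
        )
        out = environmental_composite(env)
        # 0.5*0.4 + 0.5 * e^0 / (0.5 + 0.5) = 0.7
        assert out.values[0, 0] == pytest.approx(0.7)

    def test_matches_printed_form(self, rng):
        n = 200
        ci = rng.random((1, n))
        g = rng.random((1, n))
        a = rng.uniform(0.05, 1.0, (1, n))
        h = rng.uniform(0.05, 1.0, (1, n))
        out = environmental_composite(
            EnvInputs(make_layer(ci), make_layer(g), make_layer(a), make_layer(h))
        )
        direct = 0.5 * ci + 0.5 * np.exp(g) / np.log(np.exp(a) * np.exp(h))
        np.testing.assert_allclose(out.values, direct, atol=1e-12, rtol=0)

    def test_zero_denominator_is_finite(self):
        env = EnvInputs(
            ci_env=make_layer([[0.0]]),
            green=make_layer([[0.3]]),
            air=make_layer([[0.0]]),
            heat=make_layer([[0.0]]),
        )
        out = environmental_composite(env, epsilon=1e-6)
        assert np.isfinite(out.values[0, 0])
        assert out.values[0, 0] == pytest.approx(0.5 * np.exp(0.3) / 1e-6)

    def test_monotonicity(self):
        def env_value(ci, g, a, h):
            out = environmental_composite(
                EnvInputs(make_layer([[ci]]), make_layer([[g]]), make_layer([[a]]), make_layer([[h]]))
            )
            return out.values[0, 0]

        v0 = env_value(0.5, 0.5, 0.5, 0.5)
        assert env_value(0.6, 0.5, 0.5, 0.5) > v0  # increasing in CI_env
        assert env_value(0.5, 0.6, 0.5, 0.5) > v0  # increasing in Green
        assert env_value(0.5, 0.5, 0.6, 0.5) < v0  # decreasing in Air
        assert env_value(0.5, 0.5, 0.5, 0.6) < v0  # decreasing in Heat

    def test_masked_inputs_mask_output(self):
        env = EnvInputs(
            ci_env=make_layer([[0.4, 0.4]]),
            green=make_layer([[0.1, np.nan]]),
            air=make_layer([[0.2, 0.2]]),
            heat=make_layer([[0.2, 0.2]]),
        )
        out = environmental_composite(env)
        assert out.mask[0, 0] and not out.mask[0, 1]


class TestCalibration:
    def _world(self, rng, a, b, n=500):
        infra = make_layer(rng.uniform(0.01, 1.0, (1, n)))
        ntl = make_layer(np.exp(b) * infra.values**a)
        return infra, ntl

    def test_noise_free_recovery_of_printed_coefficients(self, rng):
        infra, ntl = self._world(rng, 1.58, 5.03)
        fit = fit_calibration(infra, ntl)
        assert fit.slope == pytest.approx(1.58, abs=1e-6)
        assert fit.intercept == pytest.approx(5.03, abs=1e-6)
        assert fit.r == pytest.approx(1.0, abs=1e-9)

    def test_identity_relation(self, rng):
        infra = make_layer(rng.uniform(0.1, 1.0, (1, 100)))
        fit = fit_calibration(infra, infra)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r == pytest.approx(1.0)

    def test_matches_closed_form_ols(self, rng):
        infra = make_layer(rng.uniform(0.01, 1.0, (1, 300)))
        ntl = make_layer(np.exp(rng.normal(2.0, 0.5, (1, 300))))
        fit = fit_calibration(infra, ntl)
        x, y = np.log(infra.values.ravel()), np.log(ntl.values.ravel())
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        assert fit.n == 300

    def test_zero_cells_excluded_from_fit(self, rng):
        vals = rng.uniform(0.1, 1.0, 50)
        vals[:10] = 0.0
        infra = make_layer([vals])
        ntl = make_layer([np.exp(1.2) * np.maximum(vals, 1e-12) ** 2.0])
        fit = fit_calibration(infra, ntl)
        assert fit.n == 40

    def test_too_few_cells_rejected(self):
        infra = make_layer([[0.5, 0.7]])
        with pytest.raises(ValueError, match=">= 3"):
            fit_calibration(infra, infra)

    def test_apply_printed_example(self):
        fit = CalibrationFit(slope=1.58, intercept=5.03, r=0.71, n=100)
        out = apply_calibration(make_layer([[1.0]]), fit)
        assert out.values[0, 0] == pytest.approx(np.exp(5.03))

    def test_apply_zero_convention_and_identity(self):
        fit = CalibrationFit(slope=1.0, intercept=0.0, r=1.0, n=10)
        layer = make_layer([[0.0, 0.3, 1.0]])
        out = apply_calibration(layer, fit)
        np.testing.assert_allclose(out.values, layer.values)
        assert out.values[0, 0] == 0.0

    def test_fit_then_apply_reproduces_power_law(self, rng):
        infra, ntl = self._world(rng, 1.58, 5.03)
        fit = fit_calibration(infra, ntl)
        out = apply_calibration(infra, fit)
        np.testing.assert_allclose(out.values, ntl.values, rtol=1e-10)

    def test_ranking_preserved(self, rng):
        fit = CalibrationFit(slope=1.58, intercept=5.03, r=0.9, n=10)
        vals = rng.random((1, 200))
        out = apply_calibration(make_layer(vals), fit)
        assert np.array_equal(np.argsort(vals.ravel()), np.argsort(out.values.ravel()))
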