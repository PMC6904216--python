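"""Double-Boltzmann fitting, polarity index, propensity correlations and
MTSET modification kinetics."""

import math

import numpy as np
import pytest
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from vsdkit.ephys import (
    BoltzmannFit, DoubleBoltzmannModel, ModificationKineticsModel, PoVCurve,
    double_boltzmann, fit_double_boltzmann, fit_modification_rate,
    polarity_index, propensity_correlation,
)
from vsdkit.synthetic import make_modification_course, make_pov_curve

VOLTS = np.arange(-150.0, 60.0, 10.0)

# a bipolar curve: strong hyperpolarization limb plus a weak depolarized one
TRUTH = BoltzmannFit(a1=1.0, o1=0.05, v1=-90.0, k1=0.08,
                     a2=0.35, o2=0.02, v2=10.0, k2=-0.09)


class TestDoubleBoltzmann:
    def test_noiseless_parameter_recovery(self):
        """Identifiable parameters recovered from noiseless generator output.

        The amplitude/offset block has a one-dimensional gauge freedom (a
        constant can be shuttled between O1 and the A/O pairs without changing
        the curve), so recovery is asserted on the identifiable combinations:
        V½ and k of each component, the two transition amplitudes A−O, and
        the two asymptotic levels A1+O2 and O1+A2.
        """
        curve = make_pov_curve(TRUTH, VOLTS, noise_sd=0.0)
        fit = fit_double_boltzmann(curve)
        identifiable = {
            "v1": (fit.v1, TRUTH.v1), "k1": (fit.k1, TRUTH.k1),
            "v2": (fit.v2, TRUTH.v2), "k2": (fit.k2, TRUTH.k2),
            "amp1": (fit.a1 - fit.o1, TRUTH.a1 - TRUTH.o1),
            "amp2": (fit.a2 - fit.o2, TRUTH.a2 - TRUTH.o2),
            "level_neg": (fit.a1 + fit.o2, TRUTH.a1 + TRUTH.o2),
            "level_pos": (fit.o1 + fit.a2, TRUTH.o1 + TRUTH.a2),
        }
        for name, (got, want) in identifiable.items():
            assert got == pytest.approx(want, rel=0.01, abs=1e-3), name
        np.testing.assert_allclose(fit.predict(VOLTS), curve.relative_po,
                                   atol=1e-6)

    def test_flat_curve_fits_flat(self):
        curve = PoVCurve(VOLTS, np.full(VOLTS.shape, 0.5))
        fit = fit_double_boltzmann(curve)
        np.testing.assert_allclose(fit.predict(VOLTS), 0.5, atol=1e-6)

    def test_single_component_data_matches_nested_oracle(self):
        single = BoltzmannFit(a1=1.0, o1=0.0, v1=-70.0, k1=0.07,
                              a2=0.0, o2=0.0, v2=50.0, k2=0.07)
        y = single.predict(VOLTS)
        fit = fit_double_boltzmann(PoVCurve(VOLTS, y))

        def one_boltz(v, a, o, vh, k):
            return o + (a - o) / (1.0 + np.exp(k * (v - vh)))

        popt, _ = curve_fit(one_boltz, VOLTS, y, p0=[1.0, 0.0, -60.0, 0.05],
                            maxfev=20000)
        rss_one = float(np.sum((one_boltz(VOLTS, *popt) - y) ** 2))
        assert fit.rss <= rss_one + 1e-8

    def test_component_ordering_convention(self):
        curve = make_pov_curve(TRUTH, VOLTS, noise_sd=0.0)
        fit = fit_double_boltzmann(curve)
        assert fit.v1 <= fit.v2

    def test_recovery_over_random_parameter_draws(self):
        rng = np.random.default_rng(2024)
        n_ok = 0
        for _ in range(50):
            truth = BoltzmannFit(
                a1=rng.uniform(0.5, 1.2), o1=rng.uniform(0.0, 0.1),
                v1=rng.uniform(-120.0, -60.0), k1=rng.uniform(0.05, 0.12),
                a2=rng.uniform(0.1, 0.6), o2=rng.uniform(0.0, 0.1),
                v2=rng.uniform(-20.0, 40.0), k2=-rng.uniform(0.05, 0.12))
            curve = make_pov_curve(truth, VOLTS, noise_sd=0.0)
            fit = fit_double_boltzmann(curve)
            pred_err = np.max(np.abs(fit.predict(VOLTS) - curve.relative_po))
            if pred_err < 1e-4:
                n_ok += 1
        # multi-start NLS may hit a local optimum on rare degenerate draws
        assert n_ok >= 47

    def test_summary_reports_parameters(self):
        res = DoubleBoltzmannModel(make_pov_curve(TRUTH, VOLTS)).fit()
        text = res.summary()
        assert "V1/2" in text and "RSS" in text

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="8"):
            DoubleBoltzmannModel(PoVCurve(VOLTS[:5], np.ones(5)))


class TestPolarityIndex:
    def test_ratio_definition(self):
        curve = PoVCurve(np.array([-150.0, -50.0, 50.0]),
                         np.array([0.9, 0.5, 0.1]))
        pi = polarity_index(curve)
        assert pi.index == pytest.approx(9.0)
        assert pi.source == "data"

    def test_symmetric_curve_gives_unity(self):
        curve = PoVCurve(np.array([-150.0, 0.0, 50.0]),
                         np.array([0.4, 0.8, 0.4]))
        assert polarity_index(curve).index == pytest.approx(1.0)

    def test_zero_positive_po_flagged_infinite(self):
        curve = PoVCurve(np.array([-150.0, -50.0, 50.0]),
                         np.array([0.9, 0.2, 0.0]))
        pi = polarity_index(curve)
        assert pi.infinite and math.isinf(pi.index)

    def test_scale_invariance(self):
        curve = PoVCurve(np.array([-150.0, -50.0, 50.0]),
                         np.array([0.9, 0.5, 0.3]))
        scaled = PoVCurve(curve.voltages, curve.relative_po * 37.0)
        assert polarity_index(scaled).index == pytest.approx(
            polarity_index(curve).index)

    def test_depolarization_activated_family_monotone(self):
        indices = []
        for a2 in (0.2, 0.5, 1.0):
            truth = BoltzmannFit(a1=0.05, o1=0.02, v1=-100.0, k1=0.08,
                                 a2=a2, o2=0.0, v2=0.0, k2=-0.08)
            fit = fit_double_boltzmann(make_pov_curve(truth, VOLTS))
            indices.append(polarity_index(fit).index)
        assert all(i < 1.0 for i in indices)
        assert indices == sorted(indices, reverse=True)


class TestPropensityCorrelation:
    def test_exact_exponential_relation_gives_unit_r(self):
        scale = {"A": 1.0, "V": 2.0, "L": 3.0, "S": 4.0}
        indices = {aa: 10.0 ** (-0.8 * v + 1.0) for aa, v in scale.items()}
        out = propensity_correlation(indices, scale)
        assert abs(out["r"]) == pytest.approx(1.0, abs=1e-12)
        assert out["slope"] == pytest.approx(-0.8, abs=1e-12)

    def test_matches_pearson_oracle(self):
        scale = {"A": 1.8, "V": 4.2, "L": 3.8, "S": -0.8, "Q": -3.5}
        rng = np.random.default_rng(5)
        indices = {aa: float(10.0 ** rng.normal()) for aa in scale}
        out = propensity_correlation(indices, scale)
        xs = [scale[aa] for aa in scale]
        ys = [math.log10(indices[aa]) for aa in scale]
        r, _ = pearsonr(xs, ys)
        assert out["r"] == pytest.approx(r, abs=1e-12)

    def test_constant_indices_flagged(self):
        scale = {"A": 1.0, "V": 2.0, "L": 3.0}
        out = propensity_correlation({aa: 5.0 for aa in scale}, scale)
        assert math.isnan(out["r"])

    def test_infinite_indices_excluded_with_warning(self):
        scale = {"A": 1.0, "V": 2.0, "L": 3.0, "S": 4.0}
        indices = {"A": 1.0, "V": 2.0, "L": 4.0, "S": float("inf")}
        with pytest.warns(UserWarning, match="excluded"):
            out = propensity_correlation(indices, scale)
        assert out["n"] == 3 and out["excluded"] == ["S"]

    def test_bundled_scales_resolve(self):
        for name in ("kyte_doolittle", "helix_propensity", "turn_propensity"):
            indices = {"A": 2.0, "V": 1.0, "L": 0.5, "S": 4.0}
            out = propensity_correlation(indices, name)
            assert -1.0 <= out["r"] <= 1.0


class TestModificationKinetics:
    def test_exact_activated_state_rate(self):
        # tau = 2.2727 s at 1 mM corresponds to 440 per molar second
        t = np.linspace(0.0, 10.0, 30)
        tau = 2.2727
        current = 3.0 - 2.0 * np.exp(-t / tau)
        fit = fit_modification_rate(t, current, concentration=1e-3)
        assert fit.k2nd == pytest.approx(440.0, rel=1e-3)

    def test_exact_rate_arithmetic(self):
        t = np.linspace(0.0, 40.0, 20)
        current = 1.0 + 2.0 * (1.0 - np.exp(-t / 10.0))
        fit = fit_modification_rate(t, current, concentration=0.1)
        assert fit.k2nd == pytest.approx(1.0, rel=1e-6)
        assert fit.tau == pytest.approx(10.0, rel=1e-6)

    def test_constant_current_flagged_no_change(self):
        t = np.linspace(0.0, 10.0, 10)
        fit = fit_modification_rate(t, np.ones_like(t), concentration=1e-3)
        assert fit.no_change

    def test_decreasing_current_supported(self):
        t = np.linspace(0.0, 10.0, 25)
        current = 0.2 + 0.8 * np.exp(-t / 3.0)
        fit = fit_modification_rate(t, current, concentration=1e-3)
        assert fit.tau == pytest.approx(3.0, rel=1e-6)
        assert fit.iinf < fit.i0

    def test_noisy_recovery_within_fitted_stderr(self):
        hits = 0
        for seed in range(20):
            t, current = make_modification_course(
                440.0, 1e-3, timepoints=20, noise_frac=0.02, seed=seed)
            fit = fit_modification_rate(t, current, concentration=1e-3)
            if abs(fit.k2nd - 440.0) <= 2.0 * fit.k2nd_stderr:
                hits += 1
        assert hits >= 17  # ~95% coverage expected from 2-sigma intervals

    def test_model_class_matches_function(self):
        t, current = make_modification_course(7.5, 1e-3, seed=1)
        a = ModificationKineticsModel(t, current, 1e-3).fit()
        b = fit_modification_rate(t, current, 1e-3)
        assert a.k2nd == b.k2nd
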