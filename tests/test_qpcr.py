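"""Signal layer: logistic amplification model, Ct calling, melt-peak extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloodlcl.qpcr import (
    AmplificationCurve,
    MeltCurve,
    call_ct,
    extract_tm_peaks,
    logistic_sdm_cycle,
    melt_temperature_grid,
    simulate_amplification,
    simulate_melt,
)


def dense_grid_sdm(template_copies, efficiency, midpoint_copies=8e11):
    """Independent oracle: second-derivative maximum of the noiseless logistic
    located by brute force on a dense cycle grid."""
    c = np.arange(1.0, 50.0, 1e-4)
    log_e = np.log(efficiency)
    z = c * log_e + np.log(template_copies) - np.log(midpoint_copies)
    f = 10.0 / (1.0 + np.exp(-z))
    d2 = np.gradient(np.gradient(f, c), c)
    return c[np.argmax(d2)]


def dense_grid_melt_peaks(products, width=0.25, amplitude=10.0, drift=0.01):
    """Independent oracle: maxima of -dF/dT of the noiseless melt model on a
    dense temperature grid."""
    t = np.arange(65.0, 95.0, 1e-4)
    f = 0.5 + drift * (95.0 - t)
    for tm, frac in products:
        f = f + amplitude * frac / (1.0 + np.exp((t - tm) / width))
    negd = -np.gradient(f, t)
    peaks = []
    for i in range(1, len(t) - 1):
        if negd[i] > negd[i - 1] and negd[i] >= negd[i + 1] and negd[i] > 0.1:
            peaks.append(t[i])
    return peaks


class TestSimulateAmplification:
    def test_zero_template_is_flat_baseline(self):
        curve = simulate_amplification(0.0, noise_sd=0.0)
        assert np.ptp(curve.fluorescence) == 0.0
        assert call_ct(curve).ct is None

    def test_doubling_template_shifts_inflection_by_one_cycle(self):
        ct_n = call_ct(simulate_amplification(5000.0)).ct
        ct_2n = call_ct(simulate_amplification(10000.0)).ct
        assert ct_n - ct_2n == pytest.approx(1.0, abs=0.05)

    def test_nominal_input_yields_interior_ct(self):
        res = call_ct(simulate_amplification(3000.0, efficiency=2.0))
        assert res.ct is not None and 1.0 < res.ct < 50.0

    @pytest.mark.parametrize("kwargs", [
        {"template_copies": -1.0},
        {"template_copies": 100.0, "noise_sd": -0.1},
        {"template_copies": 100.0, "efficiency": 2.5},
        {"template_copies": 100.0, "efficiency": 1.0},
        {"template_copies": 100.0, "plateau": 0.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate_amplification(**kwargs)


class TestCallCt:
    @pytest.mark.parametrize("copies,efficiency", [
        (10.0, 2.0), (300.0, 2.0), (3000.0, 2.0), (3e5, 2.0),
        (3000.0, 1.8), (3000.0, 1.5), (50.0, 1.9),
    ])
    def test_matches_analytic_curvature_maximum(self, copies, efficiency):
        curve = simulate_amplification(copies, efficiency=efficiency, noise_sd=0.0)
        res = call_ct(curve)
        assert res.called_by == "second_derivative_max"
        assert res.ct == pytest.approx(logistic_sdm_cycle(copies, efficiency), abs=0.3)

    def test_analytic_formula_agrees_with_dense_grid_oracle(self):
        assert logistic_sdm_cycle(3000.0, 2.0) == pytest.approx(
            dense_grid_sdm(3000.0, 2.0), abs=1e-3)
        assert logistic_sdm_cycle(500.0, 1.7) == pytest.approx(
            dense_grid_sdm(500.0, 1.7), abs=1e-3)

    def test_shift_equivariance(self):
        base = simulate_amplification(3000.0, noise_sd=0.0)
        ct0 = call_ct(base).ct
        shifted = np.concatenate([np.full(5, base.fluorescence[0]),
                                  base.fluorescence[:-5]])
        ct5 = call_ct(AmplificationCurve("s", "GAPDH", base.cycles, shifted)).ct
        assert ct5 - ct0 == pytest.approx(5.0, abs=0.05)

    def test_strictly_decreasing_in_template_and_log2_fold_spacing(self):
        copies = [100.0, 1000.0, 10000.0, 100000.0]
        cts = [call_ct(simulate_amplification(n, efficiency=2.0)).ct for n in copies]
        assert all(a > b for a, b in zip(cts, cts[1:]))
        for a, b in zip(cts, cts[1:]):
            assert a - b == pytest.approx(np.log2(10.0), abs=0.1)

    def test_noise_robustness_at_one_percent_of_plateau(self):
        """95th-percentile Ct deviation over 100 noisy replicates stays small."""
        ct0 = call_ct(simulate_amplification(3000.0, noise_sd=0.0)).ct
        devs = sorted(
            abs(call_ct(simulate_amplification(3000.0, noise_sd=0.1, seed=s)).ct - ct0)
            for s in range(100))
        assert devs[94] <= 0.2

    def test_refinement_modes_agree_on_noiseless_curves(self):
        curve = simulate_amplification(3000.0, noise_sd=0.0)
        ct_fit = call_ct(curve, refine="logistic_fit").ct
        ct_quad = call_ct(curve, refine="quadratic").ct
        assert ct_fit == pytest.approx(ct_quad, abs=0.3)

    def test_flat_noisy_baseline_is_no_amplification(self):
        rng = np.random.default_rng(0)
        f = 0.5 + rng.normal(0.0, 0.02, 50)
        res = call_ct(AmplificationCurve("s", "EBV", np.arange(1, 51), f))
        assert res.ct is None and res.called_by == "no_amplification"

    def test_short_curve_rejected(self):
        curve = AmplificationCurve("s", "EBV", np.arange(1, 7), np.zeros(6))
        with pytest.raises(ValueError):
            call_ct(curve)

    def test_late_drift_is_not_amplification(self):
        f = np.full(50, 0.5)
        f[-3:] = [0.8, 1.6, 3.0]  # rise only in the final cycles
        res = call_ct(AmplificationCurve("s", "EBV", np.arange(1, 51), f))
        assert res.ct is None


class TestMelt:
    def test_single_product_recovered_at_its_tm(self):
        curve = simulate_melt([(90.0, 0.8)], noise_sd=0.0)
        peaks = extract_tm_peaks(curve)
        assert len(peaks.peaks) == 1
        oracle = dense_grid_melt_peaks([(90.0, 0.8)])
        assert peaks.max_tm == pytest.approx(oracle[0], abs=0.2)
        assert peaks.max_tm == pytest.approx(90.0, abs=0.2)

    def test_empty_product_list_gives_no_peak(self):
        curve = simulate_melt([], noise_sd=0.0)
        assert extract_tm_peaks(curve).max_tm is None

    def test_two_products_both_recovered_max_is_higher(self):
        products = [(87.0, 0.3), (90.5, 0.7)]
        peaks = extract_tm_peaks(simulate_melt(products, noise_sd=0.0))
        assert len(peaks.peaks) == 2
        oracle = dense_grid_melt_peaks(products)
        for (tm, _), exp in zip(peaks.peaks, oracle):
            assert tm == pytest.approx(exp, abs=0.2)
        assert peaks.max_tm == pytest.approx(90.5, abs=0.2)

    def test_threshold_boundary_product_recovered(self):
        peaks = extract_tm_peaks(simulate_melt([(89.5, 0.8)], noise_sd=0.0))
        assert peaks.max_tm == pytest.approx(89.5, abs=0.2)

    def test_blood_like_profile_dimer_plus_specific(self):
        peaks = extract_tm_peaks(simulate_melt([(84.0, 0.25), (90.2, 0.7)], noise_sd=0.0))
        assert len(peaks.peaks) == 2
        assert peaks.max_tm > 89.5

    def test_monotone_decay_has_no_peak(self):
        t = melt_temperature_grid()
        f = 10.0 * np.exp(-0.05 * (t - 65.0))
        assert extract_tm_peaks(MeltCurve("s", "TCRB", t, f)).max_tm is None

    def test_tm_outside_window_rejected(self):
        with pytest.raises(ValueError):
            simulate_melt([(96.0, 0.5)])

    def test_fractions_over_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_melt([(85.0, 0.6), (90.0, 0.6)])

    def test_too_few_points_rejected(self):
        curve = MeltCurve("s", "TCRB", [65.0, 65.2, 65.4, 65.6], [4.0, 3.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            extract_tm_peaks(curve)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(tm=st.floats(min_value=66.5, max_value=93.5),
           frac=st.floats(min_value=0.3, max_value=1.0))
    def test_recovered_tm_within_one_grid_step(self, tm, frac):
        """Grid-bound property: noiseless recovery never errs by more than one
        0.2 degC acquisition step plus interpolation tolerance."""
        peaks = extract_tm_peaks(simulate_melt([(tm, frac)], noise_sd=0.0))
        assert peaks.max_tm is not None
        assert abs(peaks.max_tm - tm) <= 0.2 + 0.05
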