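import numpy as np
import pytest

from optonose import (
    FEATURE_NAMES,
    AssaySchedule,
    VOCKinetics,
    extract_features,
    first_derivative,
    fit_logistic,
    morphological_features,
)
from optonose.features import _logistic
from optonose.preprocessing import CycleWindow, estimate_baseline
from optonose.synthetic import simulate_cycle_values


def _brute_force_derivative(values, dt):
    """Independent oracle: explicit index-by-index finite differences."""
    n = len(values)
    out = np.empty(n)
    out[0] = (values[1] - values[0]) / dt
    out[-1] = (values[-1] - values[-2]) / dt
    for i in range(1, n - 1):
        out[i] = (values[i + 1] - values[i - 1]) / (2 * dt)
    return out


def _cycle(values, baseline=None, n_pre=10, **meta):
    values = np.asarray(values, float)
    if baseline is None:
        baseline = estimate_baseline(values, n_pre)
    defaults = dict(onset_index=0, voc="heptane", thickness_um=30.0, cycle_index=1)
    defaults.update(meta)
    return CycleWindow(values=values, baseline=baseline, **defaults)


@pytest.fixture(scope="module")
def sched():
    return AssaySchedule(n_cycles=1, exposure_s=5.0, recovery_s=15.0, sampling_hz=90.0)


class TestFirstDerivative:
    def test_constant_is_zero(self):
        np.testing.assert_array_equal(first_derivative(np.full(20, 3.0), 0.1), 0.0)

    def test_identity_ramp_is_one(self):
        dt = 0.25
        t = np.arange(40) * dt
        np.testing.assert_allclose(first_derivative(t, dt), 1.0, rtol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        values = rng.normal(size=50)
        dt = 1 / 90
        np.testing.assert_allclose(
            first_derivative(values, dt), _brute_force_derivative(values, dt), rtol=1e-12
        )

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            first_derivative(np.ones(2), 0.1)
        with pytest.raises(ValueError):
            first_derivative(np.ones(10), 0.0)


class TestMorphologicalFeatures:
    def test_flat_cycle_gives_zero_response_features(self, sched):
        cycle = _cycle(np.full(sched.cycle_samples, 50.0))
        f = morphological_features(cycle, sched)
        f1, f2, f3, f4, f5, f6, f7, f8, f9 = f
        assert f1 == f3 == f4 == f5 == f7 == f8 == 0.0
        assert f2 == 0.0  # earliest index on ties
        assert f6 == 0.0

    def test_symmetric_triangle(self, sched):
        # triangle of height h on baseline b: f1 = h/b, equal rise/decay slopes
        b, h = 100.0, 12.0
        n = sched.cycle_samples
        i0, ip, i1 = 200, 400, 600
        values = b + h * np.interp(np.arange(n), [i0, ip, i1], [0.0, 1.0, 0.0])
        cycle = _cycle(values, baseline=b)
        f1, f2, f3, f4, f5, f6, f7, f8, f9 = morphological_features(cycle, sched)
        assert f1 == pytest.approx(h / b, rel=1e-12)
        assert f2 == pytest.approx(ip / sched.sampling_hz, abs=1e-12)
        assert f9 == pytest.approx(1.0, rel=1e-9)
        assert f8 == 0.0
        # trapezoid oracle: explicit sum over panels
        dt = 1 / sched.sampling_hz
        sub = values - b
        expected_auc = sum((sub[i] + sub[i + 1]) / 2 * dt for i in range(n - 1))
        assert f3 == pytest.approx(expected_auc, rel=1e-12)

    def test_simulated_cycle_peak_relative_amplitude(self, film, sched):
        voc = VOCKinetics(name="acetone", amplitude=10.0, rise_rate=2.0, decay_rate=1.0)
        values = simulate_cycle_values(voc, film, sched)
        cycle = _cycle(values, baseline=film.baseline_level)
        f1 = morphological_features(cycle, sched)[0]
        assert f1 == pytest.approx(10.0 / film.baseline_level, rel=0.02)

    def test_wrong_length_raises(self, sched):
        with pytest.raises(ValueError, match="samples"):
            morphological_features(_cycle(np.zeros(10)), sched)


class TestLogisticFit:
    def test_noiseless_self_fit_recovers_parameters(self, sched):
        A, k, t0 = 1.0, 1.0, 2.5
        t = sched.cycle_times()
        values = 40.0 + _logistic(t, A, k, t0)
        fit = fit_logistic(_cycle(values, baseline=40.0), sched)
        assert fit.converged
        assert fit.A == pytest.approx(A, rel=1e-6)
        assert fit.k == pytest.approx(k, rel=1e-6)
        assert fit.t0 == pytest.approx(t0, rel=1e-6)
        assert fit.rss < 1e-12

    def test_flat_zero_segment_degenerates(self, sched):
        fit = fit_logistic(_cycle(np.full(sched.cycle_samples, 5.0), baseline=5.0), sched)
        assert not fit.converged
        assert fit.A == 0.0

    def test_noisy_fit_within_tolerance(self, sched, rng):
        A, k, t0 = 8.0, 1.4, 2.0
        t = sched.cycle_times()
        values = 100.0 + _logistic(t, A, k, t0) + rng.normal(0, 0.02 * A, t.size)
        fit = fit_logistic(_cycle(values, baseline=100.0), sched)
        assert fit.converged
        assert fit.A == pytest.approx(A, rel=0.05)
        assert fit.k == pytest.approx(k, rel=0.05)
        assert fit.t0 == pytest.approx(t0, rel=0.05)


class TestExtractFeatures:
    def test_vector_has_twelve_finite_entries(self, quiet_voc, film, sched):
        values = simulate_cycle_values(quiet_voc, film, sched)
        fv = extract_features(_cycle(values, baseline=film.baseline_level), sched)
        arr = fv.as_array()
        assert arr.shape == (12,)
        assert len(FEATURE_NAMES) == 12
        assert np.isfinite(arr).all()

    def test_identical_cycles_identical_vectors(self, quiet_voc, film, sched):
        values = simulate_cycle_values(quiet_voc, film, sched)
        a = extract_features(_cycle(values, baseline=film.baseline_level), sched)
        b = extract_features(_cycle(values.copy(), baseline=film.baseline_level), sched)
        np.testing.assert_array_equal(a.as_array(), b.as_array())

    def test_amplitude_only_difference(self, film, sched):
        common = dict(rise_rate=2.0, decay_rate=1.0, matrix_shift=0.0, noise_sd=0.0)
        small = VOCKinetics(name="acetone", amplitude=5.0, **common)
        large = VOCKinetics(name="acetone", amplitude=10.0, **common)
        fvs = []
        for voc in (small, large):
            values = simulate_cycle_values(voc, film, sched)
            fvs.append(extract_features(_cycle(values, baseline=film.baseline_level), sched))
        a, b = fvs
        assert b.f1_peak_rel_amplitude == pytest.approx(2 * a.f1_peak_rel_amplitude, rel=1e-9)
        assert b.f3_auc == pytest.approx(2 * a.f3_auc, rel=1e-9)
        assert b.f10_logistic_A == pytest.approx(2 * a.f10_logistic_A, rel=1e-6)
        assert b.f11_logistic_k == pytest.approx(a.f11_logistic_k, rel=1e-4)
        assert b.f12_logistic_t0 == pytest.approx(a.f12_logistic_t0, rel=1e-4)


class TestFeatureProperties:
    def test_scaling_baseline_subtracted_cycle(self, quiet_voc, film, sched):
        c = 3.0
        b = film.baseline_level
        base = simulate_cycle_values(quiet_voc, film, sched)
        scaled = b + c * (base - b)
        f = extract_features(_cycle(base, baseline=b), sched).as_array()
        g = extract_features(_cycle(scaled, baseline=b), sched).as_array()
        scaling = [2, 3, 4, 6, 7, 9]  # 0-based: f3 f4 f5 f7 f8 f10
        invariant_exact = [1, 5]  # f2, f6
        invariant_fit = [8, 10, 11]  # f9, f11, f12
        for i in scaling:
            assert g[i] == pytest.approx(c * f[i], rel=1e-6, abs=1e-9)
        for i in invariant_exact:
            assert g[i] == f[i]
        for i in invariant_fit:
            assert g[i] == pytest.approx(f[i], rel=1e-4, abs=1e-9)

    def test_time_shift_moves_peak_and_rise_times(self, quiet_voc, film, sched):
        # delay the whole response by rolling; response is ~0 at both ends
        b = film.baseline_level
        delta_samples = 36  # 0.4 s at 90 Hz
        delta = delta_samples / sched.sampling_hz
        base = simulate_cycle_values(quiet_voc, film, sched)
        shifted = np.roll(base - b, delta_samples)
        shifted[:delta_samples] = 0.0
        shifted += b
        f = extract_features(_cycle(base, baseline=b), sched).as_array()
        g = extract_features(_cycle(shifted, baseline=b), sched).as_array()
        assert g[1] - f[1] == pytest.approx(delta, abs=1e-9)  # f2
        assert g[5] - f[5] == pytest.approx(delta, abs=1e-9)  # f6
        # amplitude features invariant under pure delay
        assert g[0] == pytest.approx(f[0], rel=1e-9)  # f1
        assert g[3] == pytest.approx(f[3], rel=1e-6)  # f4

    def test_time_shift_moves_logistic_midpoint(self, sched):
        # a pure logistic saturating well inside exposure: the shifted fit
        # is a self-fit, so f12 moves by exactly the delay
        b, A, k, t0, delta = 50.0, 6.0, 3.0, 1.5, 0.4
        t = sched.cycle_times()
        f = extract_features(_cycle(b + _logistic(t, A, k, t0), baseline=b), sched).as_array()
        g = extract_features(
            _cycle(b + _logistic(t, A, k, t0 + delta), baseline=b), sched
        ).as_array()
        assert g[11] - f[11] == pytest.approx(delta, rel=1e-6)  # f12
        assert g[5] - f[5] == pytest.approx(delta, abs=1e-9)  # f6 at the midpoint
        assert g[9] == pytest.approx(f[9], rel=1e-6)  # f10 invariant
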