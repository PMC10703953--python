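"""PPG construction, LED superposition and the RED-dark-IR-dark acquisition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flickerox import (
    AmbientPair,
    CycleTiming,
    DistortionSpec,
    ParameterError,
    PwmSpec,
    SampledSignal,
    acquire,
    build_ppg_pair,
    generate_pwm,
    lowpass,
    superimpose,
    trim,
)

FS = 100_000.0


def short_constant_pair(level_red=20_000.0, level_ir=19_000.0, duration=0.5):
    flat = SampledSignal(np.full(int(duration * FS), 0.5), FS)
    return build_ppg_pair(flat, level_red, level_ir, 0.0, 0.0)


class TestBuildPpgPair:
    def test_default_levels(self, pulse_wave, ppg_pair):
        # AC set as a fraction of DC: 0.5% of 20000 and 0.9% of 19000 counts
        assert np.ptp(ppg_pair.red.values) == pytest.approx(100.0, rel=1e-9)
        assert np.ptp(ppg_pair.ir.values) == pytest.approx(171.0, rel=1e-9)
        assert ppg_pair.red.values.mean() == pytest.approx(20_000.0, rel=1e-3)
        assert ppg_pair.ir.values.mean() == pytest.approx(19_000.0, rel=1e-3)

    def test_ppg_is_inverted_pulse(self, pulse_wave, ppg_pair):
        # transmission falls at the systolic peak
        assert np.argmax(pulse_wave.values) == np.argmin(ppg_pair.red.values)

    def test_zero_ac_gives_constant_channel(self):
        pair = short_constant_pair()
        np.testing.assert_allclose(pair.red.values, 20_000.0)
        np.testing.assert_allclose(pair.ir.values, 19_000.0)

    def test_unnormalized_pulse_rejected(self):
        bad = SampledSignal(np.linspace(-1.0, 2.0, 100), FS)
        with pytest.raises(ParameterError):
            build_ppg_pair(bad)


class TestSuperimpose:
    def test_zero_factor_identity(self, ppg_pair, led_signal):
        d_red, d_ir, amb = superimpose(ppg_pair, led_signal, DistortionSpec(0.0))
        np.testing.assert_array_equal(d_red.values, ppg_pair.red.values)
        np.testing.assert_array_equal(d_ir.values, ppg_pair.ir.values)
        assert np.all(amb.red.values == 0.0)

    def test_perturbation_is_scaled_square_wave(self, ppg_pair, led_signal):
        d_red, _, _ = superimpose(ppg_pair, led_signal, DistortionSpec(2000.0))
        delta = d_red.values - ppg_pair.red.values
        assert set(np.unique(delta)) == {0.0, 2000.0}

    def test_red_ratio_scales_red_channel_only(self, ppg_pair, led_signal):
        spec = DistortionSpec(1000.0, red_ratio=1.1)
        _, _, amb = superimpose(ppg_pair, led_signal, spec)
        assert np.max(amb.red.values) == pytest.approx(1100.0)
        assert np.max(amb.ir.values) == pytest.approx(1000.0)

    def test_grid_mismatch_rejected(self, ppg_pair):
        short_led = generate_pwm(PwmSpec(), 1.0, FS)
        with pytest.raises(ParameterError):
            superimpose(ppg_pair, short_led, DistortionSpec(1.0))


class TestAcquire:
    def test_zero_ambient_constant_ppg_recovers_dc(self):
        pair = short_constant_pair()
        zero = pair.red.with_values(np.zeros(pair.red.n))
        red_out, ir_out = acquire(pair.red, pair.ir, zero)
        np.testing.assert_allclose(red_out.values, 20_000.0)
        np.testing.assert_allclose(ir_out.values, 19_000.0)
        assert red_out.sample_rate == pytest.approx(311.25)

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(c=st.floats(-1e4, 1e4, allow_nan=False))
    def test_constant_ambient_cancels_exactly(self, c):
        pair = short_constant_pair(duration=0.2)
        zero = pair.red.with_values(np.zeros(pair.red.n))
        base_red, base_ir = acquire(pair.red, pair.ir, zero)
        shift = pair.red.with_values(np.full(pair.red.n, c))
        red_out, ir_out = acquire(
            pair.red.with_values(pair.red.values + c),
            pair.ir.with_values(pair.ir.values + c),
            shift,
        )
        np.testing.assert_allclose(red_out.values, base_red.values, atol=1e-8)
        np.testing.assert_allclose(ir_out.values, base_ir.values, atol=1e-8)

    def test_always_on_led_equivalent_to_no_ambient(self, ppg_pair):
        led = generate_pwm(PwmSpec(duty=1.0), 12.0, FS)
        d_red, d_ir, amb = superimpose(ppg_pair, led, DistortionSpec(5000.0))
        zero = ppg_pair.red.with_values(np.zeros(ppg_pair.red.n))
        base_red, base_ir = acquire(ppg_pair.red, ppg_pair.ir, zero)
        red_out, ir_out = acquire(d_red, d_ir, amb)
        np.testing.assert_allclose(red_out.values, base_red.values, atol=1e-8)
        np.testing.assert_allclose(ir_out.values, base_ir.values, atol=1e-8)

    def test_linearity_in_ambient_term(self, ppg_pair, led_signal):
        zero = ppg_pair.red.with_values(np.zeros(ppg_pair.red.n))
        base_red, _ = acquire(ppg_pair.red, ppg_pair.ir, zero)

        def perturbation(k):
            d_red, d_ir, amb = superimpose(ppg_pair, led_signal, DistortionSpec(k))
            red_out, _ = acquire(d_red, d_ir, amb)
            return red_out.values - base_red.values

        np.testing.assert_allclose(
            perturbation(2000.0), 2.0 * perturbation(1000.0), atol=1e-6
        )

    def test_too_short_signal_rejected(self):
        tiny = SampledSignal(np.zeros(100), FS)
        with pytest.raises(ParameterError):
            acquire(tiny, tiny, tiny)

    def test_fixed_sample_grid_variant(self):
        pair = short_constant_pair()
        zero = pair.red.with_values(np.zeros(pair.red.n))
        timing = CycleTiming(cycle_samples=320)
        red_out, _ = acquire(pair.red, pair.ir, zero, timing)
        assert red_out.sample_rate == pytest.approx(FS / 320)
        np.testing.assert_allclose(red_out.values, 20_000.0)

    def test_overlapping_windows_rejected(self):
        pair = short_constant_pair()
        bad = CycleTiming(red_start=800e-6, ir_start=820e-6)
        with pytest.raises(ParameterError):
            acquire(pair.red, pair.ir, pair.red, bad)


def brute_force_alias(f_led: float, f_cycle: float, band: float = 5.0):
    """All |n·f_led - m·f_cycle| beat lines inside the analysis band, n,m <= 10."""
    lines = set()
    for n in range(1, 11):
        for m in range(1, 11):
            d = abs(n * f_led - m * f_cycle)
            if 0.05 < d <= band:
                lines.add(round(d, 6))
    return sorted(lines)


class TestAliasOracle:
    """Demodulated PWM light shows beat lines at |n·f_led − m·f_cycle|.

    The oracle is independent of the acquisition code: it enumerates harmonic
    differences of the two frequencies.  The simulated spectrum must put its
    dominant sub-5 Hz component on that lattice, and its lowest significant
    component at the lattice minimum (the alias fundamental).  For pairs whose
    higher lattice lines fall outside the band the dominant component is the
    fundamental itself.
    """

    @pytest.mark.parametrize(
        "f_led,f_cycle",
        [(207.0, 311.25), (208.0, 311.25), (206.0, 311.25), (207.0, 312.5)],
    )
    def test_demodulated_beats_match_harmonic_differences(self, f_led, f_cycle):
        lines = brute_force_alias(f_led, f_cycle)
        assert lines, "test grid must have an in-band alias"
        flat = SampledSignal(np.full(int(12.0 * FS), 0.5), FS)
        pair = build_ppg_pair(flat, ac_frac_red=0.0, ac_frac_ir=0.0)
        led = generate_pwm(PwmSpec(frequency=f_led), 12.0, FS)
        d_red, d_ir, amb = superimpose(pair, led, DistortionSpec(2000.0))
        red_out, _ = acquire(d_red, d_ir, amb, CycleTiming(cycle_frequency=f_cycle))
        filtered = trim(lowpass(red_out, 5.0), 0.5)
        v = filtered.values - filtered.values.mean()
        spec = np.abs(np.fft.rfft(v))
        freqs = np.fft.rfftfreq(v.size, 1.0 / filtered.sample_rate)
        band = (freqs > 0.05) & (freqs <= 5.0)
        resolution = 2.0 * filtered.sample_rate / v.size
        dominant = freqs[band][np.argmax(spec[band])]
        assert min(abs(dominant - l) for l in lines) <= resolution
        significant = freqs[band][spec[band] >= 0.2 * spec[band].max()]
        assert abs(significant.min() - lines[0]) <= resolution

    def test_no_beat_without_modulation(self):
        # constant light: demodulated output is flat, no in-band component
        flat = SampledSignal(np.full(int(2.0 * FS), 0.5), FS)
        pair = build_ppg_pair(flat, ac_frac_red=0.0, ac_frac_ir=0.0)
        led = generate_pwm(PwmSpec(duty=1.0), 2.0, FS)
        d_red, d_ir, amb = superimpose(pair, led, DistortionSpec(2000.0))
        red_out, _ = acquire(d_red, d_ir, amb)
        assert np.ptp(red_out.values) <= 1e-8
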