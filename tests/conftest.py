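"""Shared fixtures: the default study configuration, built once per session.

The full-rate stages (12 s at 100 kHz) dominate runtime, so the default pulse
wave, PPG pair and LED signal are session-scoped, as are the handful of
headline pipeline readings reused across test modules.
"""

import numpy as np
import pytest

from flickerox import (
    PpgPair,
    PulseWaveSpec,
    PwmSpec,
    SampledSignal,
    build_ppg_pair,
    generate_pwm,
    synthesize_pulse_wave,
)
from flickerox.experiments import run_pipeline

FS = 100_000.0
DURATION = 12.0


@pytest.fixture(scope="session")
def pulse_wave() -> SampledSignal:
    return synthesize_pulse_wave(PulseWaveSpec())


@pytest.fixture(scope="session")
def ppg_pair(pulse_wave) -> PpgPair:
    return build_ppg_pair(pulse_wave)


@pytest.fixture(scope="session")
def led_signal() -> SampledSignal:
    return generate_pwm(PwmSpec(), duration=DURATION, sample_rate=FS)


@pytest.fixture(scope="session")
def pipeline_runner(ppg_pair, led_signal):
    """Run the default pipeline at a given distortion factor, cached."""
    cache: dict = {}

    def run(factor: float, red_ratio: float = 1.0, cycle_frequency: float = 311.25):
        key = (factor, red_ratio, cycle_frequency)
        if key not in cache:
            cache[key] = run_pipeline(
                factor,
                red_ratio,
                cycle_frequency,
                _ppg_pair=ppg_pair,
                _led_signal=led_signal,
            )
        return cache[key]

    return run


@pytest.fixture(scope="session")
def baseline_reading(pipeline_runner):
    """Undistorted default pipeline reading (factor 0)."""
    return pipeline_runner(0.0)


@pytest.fixture(scope="session")
def constant_ppg_pair() -> PpgPair:
    """PPG pair with zero pulsatile component (AC fraction 0)."""
    flat = SampledSignal(np.full(int(DURATION * FS), 0.5), FS)
    return build_ppg_pair(flat, ac_frac_red=0.0, ac_frac_ir=0.0)
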