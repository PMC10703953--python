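"""Waveform containers, synthetic arterial pulse waves, filtering, resampling.

Everything downstream — LED light, photoplethysmograms (PPGs), demodulated
oximeter outputs — travels as a :class:`SampledSignal`: a uniformly sampled,
finite, real-valued waveform with an explicit sample rate.

The synthetic pulse-wave generator stands in for a recorded arterial blood
pressure signal: a strictly periodic train with one dominant systolic peak per
beat and a smaller dicrotic shoulder on the decay.  The headline oximetry
quantities depend only on the AC/DC fractions configured downstream and on
aliasing of the ambient light, not on the fine beat shape, so any realistic
single-peak-per-beat morphology is adequate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline


class ParameterError(ValueError):
    """Raised when a spec or operation parameter is out of its valid range."""


@dataclass(frozen=True)
class SampledSignal:
    """Uniformly sampled real-valued waveform.

    Parameters
    ----------
    values : ndarray
        Sample values, arbitrary units. Must be non-empty and finite.
    sample_rate : float
        Sampling rate in Hz. Must be positive.
    t0 : float
        Time of the first sample in seconds (default 0).
    """

    values: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ParameterError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(vals)):
            raise ParameterError("values must be finite")
        if not (self.sample_rate > 0):
            raise ParameterError("sample_rate must be positive")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Signal length in seconds (n / sample_rate)."""
        return self.n / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.sample_rate

    def with_values(self, values: np.ndarray) -> "SampledSignal":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class PulseWaveSpec:
    """Parameters of the synthetic arterial pulse wave.

    ``components`` are per-beat Gaussian bumps given as (amplitude,
    center, width) triples in beat-fraction units: the default is a dominant
    systolic peak at 30% of the beat plus a small dicrotic shoulder at 55%.
    The shoulder's amplitude/width are chosen so it never forms a secondary
    local maximum, keeping exactly one detectable peak per beat at any heart
    rate.
    """

    heart_rate: float = 140.0
    duration: float = 12.0
    sample_rate: float = 100_000.0
    components: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.30, 0.10),
        (0.15, 0.55, 0.12),
    )

    def __post_init__(self) -> None:
        if not (20.0 < self.heart_rate < 300.0):
            raise ParameterError("heart_rate must lie in (20, 300) bpm")
        if not (self.duration > 0):
            raise ParameterError("duration must be positive")
        if not (self.sample_rate > 0):
            raise ParameterError("sample_rate must be positive")
        if len(self.components) == 0:
            raise ParameterError("at least one morphology component required")
        for amp, center, width in self.components:
            if width <= 0 or amp <= 0 or not (0.0 <= center < 1.0):
                raise ParameterError("invalid morphology component")


def synthesize_pulse_wave(spec: PulseWaveSpec) -> SampledSignal:
    """Generate a periodic arterial-pressure-like waveform.

    The output is deterministic, strictly periodic at ``spec.heart_rate``,
    normalized to minimum 0 and peak-to-peak amplitude 1, and has exactly
    ``spec.duration * spec.sample_rate`` (rounded) samples.
    """
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    phase = (t * spec.heart_rate / 60.0) % 1.0
    wave = np.zeros(n)
    # wrap neighbouring beats so the waveform is exactly periodic in phase
    for amp, center, width in spec.components:
        for k in (-1.0, 0.0, 1.0):
            wave += amp * np.exp(-0.5 * ((phase - center - k) / width) ** 2)
    lo, hi = wave.min(), wave.max()
    return SampledSignal((wave - lo) / (hi - lo), spec.sample_rate)


def invert(sig: SampledSignal) -> SampledSignal:
    """Mirror a signal across its mid-level: out = (max + min) - in.

    Light transmitted through tissue falls when arterial volume rises, so a
    pressure-like wave inverts into a transmission-mode PPG.  Involution:
    ``invert(invert(s)) == s``.
    """
    v = sig.values
    return sig.with_values((v.max() + v.min()) - v)


def lowpass(
    sig: SampledSignal, cutoff: float, order: int = 4
) -> SampledSignal:
    """Zero-phase Butterworth low-pass filter.

    Applied forward-backward (``sosfiltfilt``) so peak positions are not
    phase-shifted; the effective magnitude response is the squared Butterworth
    response. DC is preserved.

    Raises
    ------
    ParameterError
        If ``cutoff`` is at or above the Nyquist frequency.
    """
    nyq = sig.sample_rate / 2.0
    if not (0 < cutoff < nyq):
        raise ParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyq} Hz)"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=sig.sample_rate, output="sos")
    return sig.with_values(sps.sosfiltfilt(sos, sig.values))


def resample(
    sig: SampledSignal, new_rate: float, method: str = "cubic"
) -> SampledSignal:
    """Resample onto a new uniform grid of the same duration.

    ``method`` is ``"cubic"`` (cubic-spline interpolation, default) or
    ``"fourier"`` (band-limited, via :func:`scipy.signal.resample`).
    """
    if not (new_rate > 0):
        raise ParameterError("new_rate must be positive")
    n_new = int(round(sig.n * new_rate / sig.sample_rate))
    if n_new < 1:
        raise ParameterError("new_rate too low for signal duration")
    if method == "cubic":
        t_new = np.arange(n_new) / new_rate
        spline = CubicSpline(sig.times - sig.t0, sig.values)
        # clamp extrapolation beyond the last original sample
        t_new = np.clip(t_new, 0.0, (sig.n - 1) / sig.sample_rate)
        vals = spline(t_new)
    elif method == "fourier":
        vals = sps.resample(sig.values, n_new)
    else:
        raise ParameterError(f"unknown resampling method {method!r}")
    return SampledSignal(vals, new_rate, t0=sig.t0)


def trim(sig: SampledSignal, edge: float) -> SampledSignal:
    """Drop ``edge`` seconds from each end (filter-transient guard)."""
    k = int(round(edge * sig.sample_rate))
    if 2 * k >= sig.n:
        raise ParameterError("trim would remove the whole signal")
    if k == 0:
        return sig
    return SampledSignal(
        sig.values[k:-k], sig.sample_rate, t0=sig.t0 + k / sig.sample_rate
    )
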