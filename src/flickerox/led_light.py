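"""PWM LED ambient-light generation and flicker metrics.

Dimmable LED luminaires are commonly driven by pulse-width modulation: the
diodes switch fully on and off at a fixed carrier frequency and the duty
fraction sets the mean brightness.  The lamp modelled here runs at 207 Hz
with a 37% duty in its non-dimmed mode and 13% fully dimmed; the light is
idealised as a 0/amplitude square wave.

Flicker metrics follow the lighting-engineering conventions: percent flicker
(modulation depth), flicker index (area above the mean over total area), and
— when a perceptual frequency-weighting function is supplied — the compact
flicker degree (CFD), a Pythagorean sum of weighted AC spectral components
normalised to the DC component.  The weighting curve is injectable, not
hard-coded: it encodes human flicker-perception sensitivity and lives outside
this model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .signal_core import ParameterError, SampledSignal


@dataclass(frozen=True)
class PwmSpec:
    """Parametric PWM light source.

    frequency : carrier frequency, Hz
    duty : on-fraction of each period, in (0, 1]
    amplitude : light level while on (arbitrary units)
    phase : time offset of the first on-edge, seconds
    """

    frequency: float = 207.0
    duty: float = 0.37
    amplitude: float = 1.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not (self.frequency > 0):
            raise ParameterError("frequency must be positive")
        if not (0.0 < self.duty <= 1.0):
            raise ParameterError("duty must lie in (0, 1]")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be non-negative")


@dataclass(frozen=True)
class FlickerReport:
    duty_fraction: float
    percent_flicker: float
    flicker_index: float
    cfd: Optional[float] = None


def generate_pwm(
    spec: PwmSpec, duration: float, sample_rate: float
) -> SampledSignal:
    """Sample an ideal PWM square wave: amplitude while on, 0 while off.

    ``sample_rate`` must be at least 10x the carrier frequency so that edges
    are resolved on the grid.
    """
    if sample_rate < 10 * spec.frequency:
        raise ParameterError(
            "sample_rate must be at least 10x the PWM frequency"
        )
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    period = 1.0 / spec.frequency
    pos = (t - spec.phase) % period
    values = np.where(pos < spec.duty * period, spec.amplitude, 0.0)
    return SampledSignal(values, sample_rate)


def flicker_metrics(
    light: SampledSignal,
    weighting: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> FlickerReport:
    """Compute duty fraction, percent flicker, flicker index and optional CFD.

    duty_fraction = mean / max; percent_flicker = 100 (max-min)/(max+min);
    flicker_index = (area above the mean) / (total area).  The CFD is
    computed only when ``weighting`` (a vectorised map from frequency in Hz
    to a perceptual weight) is supplied:
    ``100 * sqrt(sum_k (w(f_k) * A_k / A_0)^2)`` over the one-sided amplitude
    spectrum, with A_0 the DC (mean) level.

    Raises
    ------
    ParameterError
        If the light signal is all-zero (metrics undefined) or negative.
    """
    v = light.values
    if np.any(v < 0):
        raise ParameterError("light signal must be non-negative")
    vmax, vmin, vmean = v.max(), v.min(), v.mean()
    if vmax == 0.0:
        raise ParameterError("flicker metrics undefined for an all-zero signal")
    duty_fraction = vmean / vmax
    percent_flicker = 100.0 * (vmax - vmin) / (vmax + vmin)
    flicker_index = float(np.sum(np.clip(v - vmean, 0.0, None)) / np.sum(v))

    cfd = None
    if weighting is not None:
        spec = np.fft.rfft(v) / v.size
        freqs = np.fft.rfftfreq(v.size, d=1.0 / light.sample_rate)
        a0 = spec[0].real  # mean level
        amps = 2.0 * np.abs(spec[1:])  # one-sided AC amplitudes
        w = np.asarray(weighting(freqs[1:]), dtype=float)
        cfd = float(100.0 * np.sqrt(np.sum((w * amps / a0) ** 2)))

    return FlickerReport(
        duty_fraction=float(duty_fraction),
        percent_flicker=float(percent_flicker),
        flicker_index=flicker_index,
        cfd=cfd,
    )
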