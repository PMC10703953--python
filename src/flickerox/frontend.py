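"""Pulse-oximeter acquisition front end.

A transmissive oximeter alternately lights a red (660 nm) and an infrared
(940 nm) LED and reads a single broadband photodetector, interleaving dark
windows in which only ambient light reaches the detector.  Per measurement
cycle it averages a few consecutive detector samples in each window and
subtracts the adjacent dark average from each lit average, yielding one
red and one infrared output sample per cycle.  Constant ambient light cancels
exactly in this scheme; ambient light that varies within the cycle — a PWM
LED lamp — does not, and its residual aliases into the output at beat
frequencies |n·f_led − m·f_cycle|, the stroboscopic artifact this package
simulates.

Default geometry (100 kHz detector grid, 311.25 cycles/s): the red window
opens 800 µs into the cycle, each dark window 250 µs after its lit window
closes, the infrared window at 2.4 ms; every window averages 4 consecutive
samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Union

import numpy as np

from .signal_core import ParameterError, SampledSignal, invert


@dataclass(frozen=True)
class PpgPair:
    """Matched red/infrared PPGs on a common grid with their nominal levels.

    ``dc_*`` are mean detector counts; ``ac_frac_*`` the peak-to-peak
    pulsatile amplitude as a fraction of DC (0.5% red / 0.9% infrared by
    default, fixing the undistorted R at (0.005)/(0.009) ~ 0.556).
    """

    red: SampledSignal
    ir: SampledSignal
    dc_red: float
    dc_ir: float
    ac_frac_red: float
    ac_frac_ir: float

    def __post_init__(self) -> None:
        if self.red.n != self.ir.n or self.red.sample_rate != self.ir.sample_rate:
            raise ParameterError("red and ir PPGs must share a grid")


class AmbientPair(NamedTuple):
    """Ambient-only detector signal as seen in each channel's dark window."""

    red: SampledSignal
    ir: SampledSignal


@dataclass(frozen=True)
class CycleTiming:
    """Sample-level schedule of the RED-dark-IR-dark windows in one cycle.

    Offsets are seconds into the cycle; ``dark_lag`` is measured from the end
    of the preceding lit window.  ``cycle_samples``, when set, advances
    cycles by that exact count of detector samples instead of exact times
    (320 at 100 kHz reproduces a strict 3.2 ms cycle); by default cycle i
    starts at the exact time i / cycle_frequency and each window start is
    rounded to the nearest detector sample.
    """

    cycle_frequency: float = 311.25
    red_start: float = 800e-6
    ir_start: float = 2.4e-3
    dark_lag: float = 250e-6
    window_samples: int = 4
    cycle_samples: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.cycle_frequency > 0):
            raise ParameterError("cycle_frequency must be positive")
        if self.window_samples < 1:
            raise ParameterError("window_samples must be >= 1")
        for v in (self.red_start, self.ir_start, self.dark_lag):
            if v < 0:
                raise ParameterError("window offsets must be non-negative")

    def window_starts(self, sample_rate: float) -> tuple[int, int, int, int]:
        """Start offsets (in detector samples) of the four windows, and check
        that they fit one cycle without overlap."""
        w = self.window_samples / sample_rate
        starts_s = (
            self.red_start,
            self.red_start + w + self.dark_lag,
            self.ir_start,
            self.ir_start + w + self.dark_lag,
        )
        idx = tuple(int(round(s * sample_rate)) for s in starts_s)
        wlen = self.window_samples
        order = (idx[0], idx[1], idx[2], idx[3])
        for a, b in zip(order, order[1:]):
            if a + wlen > b:
                raise ParameterError("measurement windows overlap")
        cycle_len = (
            self.cycle_samples
            if self.cycle_samples is not None
            else sample_rate / self.cycle_frequency
        )
        if idx[3] + wlen > cycle_len:
            raise ParameterError("windows do not fit within one cycle")
        return idx


@dataclass(frozen=True)
class DistortionSpec:
    """Ambient-light coupling strength.

    ``factor`` scales the unit LED waveform into detector counts; ``red_ratio``
    multiplies the red channel's coupling (1.1 and 1.2 model the red PPG being
    distorted 10% / 20% more strongly than the infrared one).
    """

    factor: float = 0.0
    red_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.factor < 0:
            raise ParameterError("factor must be non-negative")
        if not (self.red_ratio > 0):
            raise ParameterError("red_ratio must be positive")


def build_ppg_pair(
    pulse: SampledSignal,
    dc_red: float = 20_000.0,
    dc_ir: float = 19_000.0,
    ac_frac_red: float = 0.005,
    ac_frac_ir: float = 0.009,
) -> PpgPair:
    """Turn a normalized [0, 1] pulse wave into a red/infrared PPG pair.

    Each channel is the inverted pulse (transmission falls during systole)
    scaled to a peak-to-peak amplitude of ``ac_frac * dc`` counts and shifted
    so its mean equals ``dc``.
    """
    if not (0 < dc_red and 0 < dc_ir):
        raise ParameterError("dc levels must be positive")
    for f in (ac_frac_red, ac_frac_ir):
        if not (0.0 <= f < 1.0):
            raise ParameterError("ac fractions must lie in [0, 1)")
    v = pulse.values
    if v.min() < -1e-9 or v.max() > 1 + 1e-9:
        raise ParameterError("pulse wave must be normalized to [0, 1]")
    ppg_shape = invert(pulse).values  # transmission PPG, still in [0, 1]

    def channel(dc: float, ac_frac: float) -> SampledSignal:
        vals = dc * (1.0 - ac_frac / 2.0) + dc * ac_frac * ppg_shape
        vals = vals + (dc - vals.mean())
        return SampledSignal(vals, pulse.sample_rate, t0=pulse.t0)

    return PpgPair(
        red=channel(dc_red, ac_frac_red),
        ir=channel(dc_ir, ac_frac_ir),
        dc_red=dc_red,
        dc_ir=dc_ir,
        ac_frac_red=ac_frac_red,
        ac_frac_ir=ac_frac_ir,
    )


def superimpose(
    ppg: PpgPair, led: SampledSignal, spec: DistortionSpec
) -> tuple[SampledSignal, SampledSignal, AmbientPair]:
    """Add scaled ambient LED light to both PPG channels.

    Returns the distorted red and infrared detector signals plus the
    ambient-only pair seen during the dark windows (red: factor·red_ratio·led,
    infrared: factor·led — each dark window sees the LED at the coupling of
    its own channel).
    """
    if led.n != ppg.red.n or led.sample_rate != ppg.red.sample_rate:
        raise ParameterError("LED signal must share the PPG grid")
    amb_red = led.with_values(spec.factor * spec.red_ratio * led.values)
    amb_ir = led.with_values(spec.factor * led.values)
    distorted_red = ppg.red.with_values(ppg.red.values + amb_red.values)
    distorted_ir = ppg.ir.with_values(ppg.ir.values + amb_ir.values)
    return distorted_red, distorted_ir, AmbientPair(amb_red, amb_ir)


def acquire(
    distorted_red: SampledSignal,
    distorted_ir: SampledSignal,
    ambient: Union[SampledSignal, AmbientPair],
    timing: CycleTiming = CycleTiming(),
) -> tuple[SampledSignal, SampledSignal]:
    """Run the RED-dark-IR-dark measurement cycle over the detector signals.

    For each cycle, the mean of ``window_samples`` consecutive detector
    samples in each lit window, minus the mean over the adjacent dark window
    of the ambient-only signal, gives one output sample per channel.  Outputs
    are returned at the cycle frequency; a trailing incomplete cycle is
    dropped.
    """
    fs = distorted_red.sample_rate
    for sig in (distorted_ir, *(ambient if isinstance(ambient, AmbientPair) else (ambient,))):
        if sig.sample_rate != fs or sig.n != distorted_red.n:
            raise ParameterError("all signals must share the detector grid")
    if isinstance(ambient, AmbientPair):
        amb_red, amb_ir = ambient.red.values, ambient.ir.values
    else:
        amb_red = amb_ir = ambient.values

    red_off, dark1_off, ir_off, dark2_off = timing.window_starts(fs)
    w = timing.window_samples
    n = distorted_red.n

    if timing.cycle_samples is not None:
        step = float(timing.cycle_samples)
        out_rate = fs / timing.cycle_samples
        n_cycles = int((n - (dark2_off + w)) // step) + 1 if n >= dark2_off + w else 0
        starts = (np.arange(n_cycles) * timing.cycle_samples).astype(np.int64)
    else:
        out_rate = timing.cycle_frequency
        # cycle i opens at the exact time i / f_cycle, rounded to the grid
        max_cycles = int(np.ceil(n / fs * timing.cycle_frequency)) + 1
        starts = np.round(
            np.arange(max_cycles) / timing.cycle_frequency * fs
        ).astype(np.int64)
        starts = starts[starts + dark2_off + w <= n]
        n_cycles = starts.size
    if n_cycles < 1:
        raise ParameterError("signal too short for one full measurement cycle")

    win = np.arange(w)

    def window_mean(source: np.ndarray, offset: int) -> np.ndarray:
        return source[(starts + offset)[:, None] + win[None, :]].mean(axis=1)

    red_out = window_mean(distorted_red.values, red_off) - window_mean(
        amb_red, dark1_off
    )
    ir_out = window_mean(distorted_ir.values, ir_off) - window_mean(
        amb_ir, dark2_off
    )
    t0 = distorted_red.t0
    return (
        SampledSignal(red_out, out_rate, t0=t0),
        SampledSignal(ir_out, out_rate, t0=t0),
    )
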