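"""From demodulated output PPGs to displayed oximeter quantities.

The displayed values follow the classic ratio-of-ratios scheme: per channel
the pulsatile (AC) amplitude is the mean of local maxima minus the mean of
local minima and the DC level is the signal mean; the double ratio

    R = (AC_red / DC_red) / (AC_ir / DC_ir)

is mapped to SpO2 through an empirical monotone-decreasing calibration curve.
The curve here is anchored at representative operating points of a
commercial transmissive oximeter — (0.55, 98), (0.68, 96), (0.94, 85) — and
extended smoothly with
monotone piecewise-cubic (PCHIP) interpolation; anchors are overridable.
Pulse rate is read from the infrared channel via local maxima at a minimum
0.2 s spacing, capping the reportable rate at 300 bpm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks

from .signal_core import ParameterError, SampledSignal, lowpass, trim

#: (R, SpO2 %) anchors: three printed operating points flanked by synthetic
#: end anchors shaping the curve over the supported R range.
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.40, 100.0),
    (0.55, 98.0),
    (0.68, 96.0),
    (0.94, 85.0),
    (1.40, 70.0),
    (2.00, 50.0),
)


@dataclass(frozen=True)
class AcDc:
    """Pulsatile amplitude and mean level of a PPG, in detector counts.

    ``degenerate`` flags signals where no extrema pair was found (AC is then
    reported as 0).
    """

    ac: float
    dc: float
    degenerate: bool = False


@dataclass(frozen=True)
class OximeterReading:
    """Displayed quantities plus the filtered PPGs they came from.

    ``r_value``/``spo2``/``pulse_rate`` are the raw computed values;
    ``r_display``/``spo2_display``/``pulse_display`` carry device-style
    rounding (2 decimals / integer / integer).
    """

    r_value: float
    spo2: float
    pulse_rate: float
    filtered_red: SampledSignal
    filtered_ir: SampledSignal
    degenerate: bool = False

    @property
    def r_display(self) -> float:
        # device-style readout truncates R toward zero (0.5556 shows as 0.55)
        return float(np.trunc(self.r_value * 100.0) / 100.0)

    @property
    def spo2_display(self) -> int:
        return int(round(self.spo2))

    @property
    def pulse_display(self) -> int:
        return int(round(self.pulse_rate))


class CalibrationCurve:
    """Monotone-decreasing map from the R double ratio to SpO2 (%).

    Built by monotone piecewise-cubic interpolation through ``anchors``;
    outside the anchored R range the curve is clamped to the end values, and
    SpO2 is always clamped to [0, 100].
    """

    def __init__(
        self, anchors: Sequence[tuple[float, float]] = DEFAULT_ANCHORS
    ) -> None:
        pts = sorted((float(r), float(s)) for r, s in anchors)
        r = np.array([p[0] for p in pts])
        s = np.array([p[1] for p in pts])
        if r.size < 2 or np.any(np.diff(r) <= 0):
            raise ParameterError("anchors must have strictly increasing R")
        if np.any(np.diff(s) >= 0):
            raise ParameterError("SpO2 anchors must be strictly decreasing in R")
        self.anchors = pts
        self._r_lo, self._r_hi = float(r[0]), float(r[-1])
        self._interp = PchipInterpolator(r, s)

    def __call__(self, r_value: float | np.ndarray) -> float | np.ndarray:
        r = np.clip(np.asarray(r_value, dtype=float), self._r_lo, self._r_hi)
        spo2 = np.clip(self._interp(r), 0.0, 100.0)
        return float(spo2) if np.isscalar(r_value) else spo2

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationCurve":
        """Load anchors from a two-column CSV with header ``r,spo2``."""
        df = pd.read_csv(path)
        return cls(tuple(zip(df["r"], df["spo2"])))


def build_calibration(
    anchors: Sequence[tuple[float, float]] = DEFAULT_ANCHORS,
) -> CalibrationCurve:
    return CalibrationCurve(anchors)


def _peak_distance(sample_rate: float, min_spacing: float) -> int:
    return max(1, int(np.ceil(min_spacing * sample_rate)))


def compute_acdc(ppg: SampledSignal, min_peak_spacing: float = 0.2) -> AcDc:
    """AC (mean of maxima minus mean of minima) and DC (mean) of a PPG.

    Extrema are local maxima/minima separated by at least
    ``min_peak_spacing`` seconds.  With no detectable extrema the result is
    flagged degenerate with AC = 0.
    """
    if ppg.duration <= 2 * min_peak_spacing:
        raise ParameterError("PPG shorter than twice the peak spacing")
    dist = _peak_distance(ppg.sample_rate, min_peak_spacing)
    maxima, _ = find_peaks(ppg.values, distance=dist)
    minima, _ = find_peaks(-ppg.values, distance=dist)
    dc = float(ppg.values.mean())
    if maxima.size == 0 or minima.size == 0:
        return AcDc(ac=0.0, dc=dc, degenerate=True)
    ac = float(ppg.values[maxima].mean() - ppg.values[minima].mean())
    return AcDc(ac=max(ac, 0.0), dc=dc)


def compute_r(red: AcDc, ir: AcDc) -> float:
    """Double ratio R = (AC_red/DC_red) / (AC_ir/DC_ir)."""
    if ir.ac <= 0 or ir.dc <= 0 or red.dc <= 0:
        raise ParameterError("R undefined: non-positive AC/DC component")
    return (red.ac / red.dc) / (ir.ac / ir.dc)


def estimate_pulse_rate(
    ppg: SampledSignal, min_spacing: float = 0.2, per_duration: bool = False
) -> float:
    """Pulse rate in bpm from local maxima at a minimum spacing.

    Default formula: 60·(N−1)/(t_last − t_first) over the detected maxima;
    ``per_duration=True`` uses 60·N/duration instead.  The spacing rule caps
    the reportable rate at 60/min_spacing (300 bpm at the default 0.2 s).
    Fewer than two peaks yield 0.
    """
    if ppg.duration < 1.0:
        raise ParameterError("need at least 1 s of signal")
    dist = _peak_distance(ppg.sample_rate, min_spacing)
    peaks, _ = find_peaks(ppg.values, distance=dist)
    cap = 60.0 / min_spacing
    if per_duration:
        return min(60.0 * peaks.size / ppg.duration, cap)
    if peaks.size < 2:
        return 0.0
    elapsed = (peaks[-1] - peaks[0]) / ppg.sample_rate
    return min(60.0 * (peaks.size - 1) / elapsed, cap)


def read_oximeter(
    red_out: SampledSignal,
    ir_out: SampledSignal,
    calibration: Optional[CalibrationCurve] = None,
    cutoff: float = 5.0,
    edge_trim: float = 0.5,
    min_peak_spacing: float = 0.2,
) -> OximeterReading:
    """Produce the displayed reading from the demodulated output PPGs.

    Pipeline: 5 Hz zero-phase low-pass on each channel, edge trim (filter
    transients), AC/DC per channel, R, SpO2 through the calibration curve,
    pulse rate from the filtered infrared channel.
    """
    if calibration is None:
        calibration = CalibrationCurve()
    f_red = trim(lowpass(red_out, cutoff), edge_trim)
    f_ir = trim(lowpass(ir_out, cutoff), edge_trim)
    red_acdc = compute_acdc(f_red, min_peak_spacing)
    ir_acdc = compute_acdc(f_ir, min_peak_spacing)
    degenerate = red_acdc.degenerate or ir_acdc.degenerate
    if degenerate or ir_acdc.ac <= 0:
        r_value, spo2 = float("nan"), float("nan")
        degenerate = True
    else:
        r_value = compute_r(red_acdc, ir_acdc)
        spo2 = calibration(r_value)
    pulse = estimate_pulse_rate(f_ir, min_spacing=min_peak_spacing)
    return OximeterReading(
        r_value=r_value,
        spo2=spo2,
        pulse_rate=pulse,
        filtered_red=f_red,
        filtered_ir=f_ir,
        degenerate=degenerate,
    )
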