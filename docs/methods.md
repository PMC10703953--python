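# Methods

## The model

`flickerox` simulates a transmissive pulse oximeter operating in the ambient
light of a pulse-width-modulated (PWM) LED lamp, to quantify how the
stroboscopic (aliasing) interaction between the lamp's flicker and the
oximeter's measurement cycle corrupts the displayed oxygen saturation (SpO2)
and pulse rate.

The simulated device works the way real ratio-of-ratios oximeters do:

1. **Photoplethysmograms (PPGs).** Light transmitted through perfused tissue
   carries a large constant (DC) component and a small pulsatile (AC)
   component that mirrors the arterial pressure wave. The model builds a
   red-channel and an infrared-channel PPG from one normalized pulse wave:
   each channel is the inverted pulse scaled to a peak-to-peak amplitude of
   `ac_frac × dc` detector counts and shifted to mean `dc`. Defaults:
   DC 20 000 (red) / 19 000 (infrared) counts, AC fractions 0.5% / 0.9%.
   These fix the undistorted double ratio at

       R = (AC_red/DC_red) / (AC_ir/DC_ir) = 0.005 / 0.009 ≈ 0.556.

2. **Ambient light.** The lamp is an ideal 0/1 square wave at 207 Hz with a
   37% duty fraction (13% when fully dimmed). It couples into the detector
   scaled by a *distortion factor* k (counts per unit light amplitude); an
   optional red:infrared coupling ratio distorts the red channel 10% or 20%
   more strongly.

3. **Acquisition.** A broadband photodetector is sampled at 100 kHz. Each
   measurement cycle (311.25 cycles/s) averages 4 consecutive samples in
   four windows — red LED lit (opening 800 µs into the cycle), dark (250 µs
   after the lit window closes), infrared lit (2.4 ms), dark — and subtracts
   each dark average from the adjacent lit average. Constant ambient light
   cancels exactly in this scheme; light that switches within the cycle does
   not, and its residual aliases into the demodulated output at the beat
   frequencies |n·f_led − m·f_cycle|. For f_led = 207 Hz and
   f_cycle = 311.25 Hz the in-band (< 5 Hz) beats form a harmonic stack at
   1.5, 3.0 and 4.5 Hz.

4. **Readout.** Both demodulated channels are low-pass filtered at 5 Hz,
   edge-trimmed, and reduced to AC (mean of local maxima minus mean of local
   minima, 0.2 s minimum spacing) and DC (mean). R maps to SpO2 through a
   monotone calibration curve; pulse rate comes from the maxima of the
   filtered infrared channel (same 0.2 s rule, capping the reportable rate
   at 300 bpm).

## Synthetic pulse wave

The generator stands in for a recorded arterial blood pressure waveform. A
beat is a sum of wrapped Gaussian bumps in beat-phase units: a dominant
systolic peak (amplitude 1.0, center 0.30, width 0.10) and a dicrotic
component (0.15, 0.55, 0.12) shaped as a shoulder on the systolic decay
rather than a separate local maximum, so every beat has exactly one
detectable peak at any heart rate. The waveform is strictly periodic,
deterministic, and normalized to [0, 1]. Defaults emulate a neonatal
monitoring scenario: 140 bpm for 12 s at 100 kHz.

What the generator does *not* emulate: beat-to-beat variability, respiratory
modulation, motion artifact, sensor noise, or the exact morphology of any
individual patient. The headline results are insensitive to this: they are
driven by the configured AC/DC fractions and by aliasing of the ambient
square wave, not by beat shape. Passing tests therefore demonstrate the
aliasing mechanism and the readout arithmetic, not fidelity to any clinical
waveform archive.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| LED frequency | 207 | Hz | PWM rate of the modelled examination lamp |
| LED duty | 0.37 | – | non-dimmed on-fraction (0.13 dimmed) |
| LED phase | 0 | s | not physically observable; see sensitivity below |
| cycle frequency | 311.25 | Hz | oximeter RED-dark-IR-dark repetition rate |
| window samples | 4 | – | 40 µs averaging window at 100 kHz |
| distortion factor k | 0–4750 | counts | ambient coupling; 4750 = DC_ir/4 |
| low-pass cutoff | 5 | Hz | output PPG smoothing band |
| peak spacing | 0.2 | s | extrema rule; caps pulse rate at 300 bpm |
| calibration anchors | (0.55, 98) (0.68, 96) (0.94, 85) | – | operating points; see below |

## Numerical choices

- **Filter:** 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`), so peak positions are not phase-shifted. The first and
  last 0.5 s of filtered outputs are excluded from AC/DC and peak analysis
  to suppress the filter transient. Order and cutoff are arguments.
- **Cycle scheduling:** cycle i opens at the exact time i/f_cycle with each
  window start rounded to the nearest 10 µs detector sample (at 311.25 Hz
  cycle lengths alternate between 321 and 322 samples). A
  `CycleTiming.cycle_samples` option advances cycles by a fixed sample count
  instead (320 reproduces a strict 3.2 ms cycle at the cost of the exact
  rate). For cycle rates too fast for the canonical absolute window offsets
  (e.g. 414 and 500 Hz) the offsets are scaled proportionally to the cycle
  period.
- **Dark windows:** each dark window sees the ambient LED term at its own
  channel's coupling (red dark: k·red_ratio·led); `acquire` also accepts a
  single ambient signal for both darks.
- **Calibration:** monotone piecewise-cubic (PCHIP) interpolation through
  the three operating anchors plus synthetic end anchors (0.40, 100),
  (1.40, 70), (2.00, 50) chosen for a conventional empirical-curve shape;
  clamped outside [0.40, 2.0] and to SpO2 ∈ [0, 100]. Anchors are
  overridable and loadable from CSV. SpO2 at the anchors is exact by
  construction; the computed quantity is R.
- **Display rounding:** R truncates toward zero at 2 decimals (0.5556 shows
  as 0.55, device-style); SpO2 and pulse rate round to integers. Raw values
  are retained on every reading.
- **Pulse-rate formula:** 60·(N−1)/(t_last − t_first) over detected maxima;
  an N/duration variant is available. Fewer than two maxima yield rate 0
  with a degenerate flag; a constant channel yields AC 0, degenerate.
- **Resampling:** cubic-spline by default, band-limited Fourier optionally.

## What the simulation shows

With the defaults, the undistorted pipeline reads R 0.55 → SpO2 98% at
140 bpm. Raising the ambient coupling k drags R toward the DC ratio
DC_ir/DC_red = 0.95 (SpO2 85%): the alias perturbation is identical in both
channels' AC amplitudes, so only the DC levels keep the channels apart. The
displayed saturation falls to 85% by k ≈ 1500–2000 (about a tenth of the
DC) and then holds — a realistic-looking, stable, *false* reading. Stronger
red-channel coupling (1.1×, 1.2×) pushes R above 1 and SpO2 lower still,
monotonically. At a cycle rate of exactly twice the LED frequency (414 Hz)
the residual is constant cycle-to-cycle and the reading returns to the
clean operating point.

## Sensitivity and known discrepancies

Three quantities are *not* robust observables of this system, and the
package's own sensitivity experiments (`phase_sensitivity`,
`frequency-study`) quantify why:

- **LED phase.** The lamp's phase relative to the first measurement cycle
  is not controllable or observable in practice. At 311.25 Hz the R plateau
  is phase-stable deep in saturation (spread ≈ 0.02 across an 8-point phase
  grid at k = 5000) but not in the transition region (spread ≈ 0.07 at
  k = 2000). A tolerance of ±0.02 on R at k = 2000 therefore cannot cover
  an arbitrary phase; results at that factor are quoted at phase 0.
- **Cycle rate 300 Hz.** 207/300 = 69/100, so the ambient residual is
  exactly periodic at 3 Hz and its in-band amplitude depends strongly on
  the LED phase: at k = 5000 the computed R spans roughly 0.70–1.06 across
  a phase sweep (phase 0 gives ≈ 1.00; fixed 333- and 334-sample cycle
  grids give 0.89 and 0.93). Any single quoted value at 300 Hz reflects an
  arbitrary phase; the package reports the phase-0 value and the spread.
- **Pulse-rate plateau.** The high-distortion pulse rate counts maxima of
  the filtered alias waveform. With an ideal square LED at exactly
  207.00 Hz the in-band alias stack (1.5/3.0/4.5 Hz, near-equal strength)
  produces 2–3 maxima per alias period and a plateau of ≈ 183 bpm. The
  alias fundamental is 3·|f_led − 207.5| Hz, so the plateau swings between
  ≈ 140 and ≈ 250 bpm as the lamp frequency moves within ±0.3 Hz — inside
  the precision to which such a lamp's PWM rate is typically known — and it
  is further halved if the lamp's finite edge rise/fall suppresses the
  higher alias harmonics to one maximum per period. The R/SpO2 plateau, by
  contrast, is insensitive to all of this. The pulse-rate plateau should be
  read qualitatively: a stable, physiologically plausible, wrong rate.

One more wobble worth noting: at phase 0 the equal-coupling sweep shows a
single-point R excursion to 0.97 (SpO2 display 84) at k = 3000 before
settling back to 0.95/85; the plateau level is the endpoint and median
value, not every grid point.

## Limitations

- The detector is an ideal broadband averager: no photodiode nonlinearity,
  saturation, shot noise, or wavelength-dependent response.
- The LED is an ideal 0/1 square wave; real lamps have finite rise/fall
  times, which mainly soften the high alias harmonics (see above).
- The compact flicker degree (CFD) requires a perceptual
  frequency-weighting curve that is standardized elsewhere;
  `flicker_metrics` computes it only when such a weighting function is
  injected, and no particular curve is bundled.
- No vendor signal-quality or motion-rejection logic is modelled; the
  device is a generic ratio-of-ratios oximeter.
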