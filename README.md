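# flickerox

Simulation of pulse-oximeter readings under flickering (pulse-width-modulated)
LED ambient light.

Modern LED luminaires are commonly dimmed by pulse-width modulation (PWM):
the diodes switch fully on and off at a fixed rate — here an examination lamp
at 207 Hz, lit 37% of the time. A transmissive pulse oximeter also works
stroboscopically: several hundred times per second it lights a red and an
infrared LED in turn and subtracts interleaved *dark* (ambient-only)
measurements, which cancels constant ambient light exactly. Ambient light
that switches *within* the measurement cycle does not cancel: it aliases
into the demodulated photoplethysmogram (PPG) at the beat frequencies
|n·f_led − m·f_cycle|, which fall inside the physiological band and survive
the device's 5 Hz smoothing filter. The result is a stable, plausible-looking
and wrong oxygen-saturation reading — clinically dangerous, since a falsely
low SpO2 invites unnecessary supplemental oxygen (a retinopathy risk in
preterm infants).

`flickerox` models this end to end, for researchers and clinical engineers
who want to study the mechanism quantitatively:

- synthetic arterial pulse wave (default 140 bpm, 12 s, 100 kHz) and
  red/infrared PPG pair (DC 20 000 / 19 000 counts, AC 0.5% / 0.9%);
- ideal PWM light source plus percent-flicker / flicker-index metrics (and a
  compact-flicker-degree hook for injectable perceptual weightings);
- the RED-dark-IR-dark acquisition cycle (311.25 cycles/s, 4-sample windows,
  dark subtraction) on a 100 kHz detector grid;
- the ratio-of-ratios readout

      R = (AC_red / DC_red) / (AC_ir / DC_ir)

  mapped to SpO2 through a monotone calibration curve anchored at
  (R, SpO2) = (0.55, 98), (0.68, 96), (0.94, 85), and peak-based pulse-rate
  estimation (0.2 s minimum spacing, 300 bpm cap);
- sweep experiments over distortion magnitude, red:infrared distortion
  ratio, oximeter cycle frequency and LED phase, with CSV/JSON outputs.

Everything is deterministic; identical configurations reproduce identical
output bytes.

## Worked example

A single simulated reading at distortion factor 2000 (ambient coupling of
about one tenth of the red DC level), equal coupling in both channels:

```bash
$ flickerox simulate --factor 2000
{
  "factor": 2000.0,
  "red_ratio": 1.0,
  "cycle_frequency": 311.25,
  "r_value": 0.9346423441896343,
  "r_display": 0.93,
  "spo2": 85,
  "pulse_rate_bpm": 191,
  "degenerate": false
}
```

The undistorted configuration (`--factor 0`) reads `r_display 0.55`,
`spo2 98`, `pulse_rate_bpm 140` — the true operating point. At factor 2000
the alias contribution dominates both channels' pulsatile amplitudes
equally, so R collapses toward the DC ratio 19000/20000 = 0.95 and the
displayed saturation drops from 98% to 85%, where it stays no matter how
bright the lamp. The displayed pulse rate (191 bpm here) is likewise an
artifact of the 1.5/3.0/4.5 Hz alias stack, not the 140 bpm source.

How the artifact depends on the oximeter's cycle rate at strong distortion:

```bash
$ flickerox frequency-study --factor 5000 --frequencies "311.25,300,414,500"
 factor  red_ratio  cycle_frequency  led_phase  r_value      spo2  pulse_rate
 5000.0        1.0           311.25        0.0 0.954232 84.473670  183.144346
 5000.0        1.0           300.00        0.0 0.995857 82.979327  182.163188
 5000.0        1.0           414.00        0.0 0.555549 97.921476  140.009394
 5000.0        1.0           500.00        0.0 0.805840 91.216718  180.197636
```

At exactly twice the LED frequency (414 Hz) every cycle samples the lamp at
the same phase, the dark subtraction cancels perfectly, and the clean
reading returns — the aliasing, not the brightness, is the mechanism.

Other commands: `flickerox sweep config.yaml` (distortion sweep from a YAML
configuration to CSV), `flickerox phase-sensitivity` (spread of R and pulse
rate across the LED phase grid), `flickerox make-fixtures` (export the
default pulse wave and LED signal as CSV). The same functionality is
available as a library; see `flickerox.experiments.run_pipeline` for the
one-call pipeline.

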