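"""CSV import/export for sampled waveforms.

Dialect: two columns with header ``time_s,value``.  On read, the sample rate
is inferred from the median time step; non-uniform grids (relative jitter
above 1e-6) are rejected rather than silently resampled.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .signal_core import ParameterError, SampledSignal


def write_signal_csv(sig: SampledSignal, path: str | Path) -> None:
    pd.DataFrame({"time_s": sig.times, "value": sig.values}).to_csv(
        path, index=False
    )


def read_signal_csv(path: str | Path, rel_jitter: float = 1e-6) -> SampledSignal:
    """Read a ``time_s,value`` CSV as a uniformly sampled signal.

    Raises
    ------
    ParameterError
        If fewer than two rows, or the time grid's jitter exceeds
        ``rel_jitter`` relative to the median step.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ParameterError(f"CSV must have a {col!r} column")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    if t.size < 2:
        raise ParameterError("need at least two samples to infer a rate")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0:
        raise ParameterError("time column must be strictly increasing")
    if np.max(np.abs(steps - dt)) > rel_jitter * dt:
        raise ParameterError(
            "non-uniform time grid: jitter exceeds tolerance"
        )
    return SampledSignal(v, sample_rate=1.0 / dt, t0=float(t[0]))
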