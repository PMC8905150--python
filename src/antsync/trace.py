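"""Regularly sampled activity series and their CSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ActivityTrace", "read_trace", "write_trace"]

# accepted header spellings, first entry is what we write
_TIME_COLUMNS = ("time_s", "t", "time")
_VALUE_COLUMNS = ("value", "activity", "proportion_active", "v")


@dataclass
class ActivityTrace:
    """A uniformly sampled activity record.

    ``values`` is the proportion of agents active (simulator output, in
    [0, 1]) or any nonnegative activity measure for empirical-style input.
    ``dt`` is the sampling interval in seconds, ``t0`` the time of the first
    sample.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("ActivityTrace needs a 1-D series of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ActivityTrace values must be finite")
        if self.dt <= 0:
            raise ValueError("sampling interval dt must be positive")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        """Span between first and last sample, seconds."""
        return self.dt * (self.values.size - 1)

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray) -> "ActivityTrace":
        """Same time base, new values (used by the filtering pipeline)."""
        return ActivityTrace(values=np.asarray(values, float), dt=self.dt, t0=self.t0)


def write_trace(path, trace: ActivityTrace) -> None:
    """Write a trace as two-column CSV with a ``time_s,value`` header."""
    df = pd.DataFrame({"time_s": trace.times, "value": trace.values})
    df.to_csv(path, index=False)


def read_trace(path) -> ActivityTrace:
    """Read a two-column time/value CSV.

    Header dialects ``time_s``/``t``/``time`` and ``value``/``activity``/
    ``proportion_active`` are accepted.  The time column must be uniformly
    spaced and strictly increasing.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    tcol = next((cols[c] for c in _TIME_COLUMNS if c in cols), None)
    vcol = next((cols[c] for c in _VALUE_COLUMNS if c in cols), None)
    if tcol is None or vcol is None:
        raise ValueError(
            f"trace CSV needs a time column {_TIME_COLUMNS} and a value column "
            f"{_VALUE_COLUMNS}; found {list(df.columns)}"
        )
    t = df[tcol].to_numpy(float)
    v = df[vcol].to_numpy(float)
    if np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0):
        raise ValueError("trace time column must be finite and strictly increasing")
    steps = np.diff(t)
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace is not uniformly sampled (required for filtering and CWT)")
    return ActivityTrace(values=v, dt=float(steps[0]), t0=float(t[0]))
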