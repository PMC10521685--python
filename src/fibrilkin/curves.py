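"""Sampled kinetic observables (turbidity, helix fraction, mean length, ...)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = ["KineticCurve"]


@dataclass(frozen=True)
class KineticCurve:
    """A time series of one scalar observable.

    Parameters
    ----------
    times : array-like
        Sample times in minutes, strictly increasing.
    values : array-like
        Observable values (OD340, helix fraction, monomer units, ...).
        NaN marks an undefined sample (e.g. mean length before any fibril
        exists); fitting operations reject NaN.
    label : str
        Free-text description of the observable and its units.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise DomainError("times and values must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise DomainError("times must be strictly increasing")
        if not np.all(np.isfinite(t)):
            raise DomainError("times must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    @property
    def sampling_interval(self) -> float:
        """Common sampling interval in minutes; raises if the grid is non-uniform."""
        dt = np.diff(self.times)
        if dt.size == 0:
            raise DomainError("single-sample curve has no sampling interval")
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-10):
            raise DomainError(
                "curve is not uniformly sampled; resample before operations "
                "that require a uniform grid"
            )
        return float(dt[0])

    def to_dataframe(self, value_col: str = "od340"):
        import pandas as pd

        return pd.DataFrame({"time_min": self.times, value_col: self.values})
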