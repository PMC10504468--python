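"""Composite linear/logarithmic time axis.

Cotranscriptional folding happens over a comparatively short window,
followed by a potentially much longer equilibration time.  The axis
therefore maps simulation time to a horizontal fraction in [0, 1] with
the end of transcription pinned at 0.75: the first 75% of the width is
linear in time over the transcription phase, and the remaining 25% is
logarithmic from the end of transcription to the last time point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

#: Fraction of axis width given to the (linear) transcription phase.
SPLIT = 0.75


@dataclass(frozen=True)
class TimeAxis:
    """Map between simulation time and horizontal axis fraction.

    ``t0`` is the first displayed time point, ``t_end`` the end of
    transcription, ``t_max`` the last time point.  The map is continuous
    and strictly increasing on [t0, t_max] with x(t0)=0, x(t_end)=0.75,
    x(t_max)=1.  Two degenerate shapes are supported: if the simulation
    stops at the end of transcription (t_end == t_max) the axis is fully
    linear; if no transcript growth is observed (t_end == t0 < t_max)
    it is fully logarithmic, which requires t0 > 0.
    """

    t0: float
    t_end: float
    t_max: float
    split: float = SPLIT

    def __post_init__(self) -> None:
        if not self.t0 <= self.t_end <= self.t_max:
            raise ParameterError(
                f"need t0 <= t_end <= t_max, got {self.t0}, {self.t_end}, {self.t_max}"
            )
        if self.mode == "log" and self.t0 <= 0:
            raise ParameterError("fully logarithmic axis requires t0 > 0")

    @property
    def mode(self) -> str:
        """'composite', 'linear' (t_end == t_max), or 'log' (t0 == t_end)."""
        if self.t0 == self.t_end == self.t_max:
            return "point"
        if self.t_end == self.t_max:
            return "linear"
        if self.t0 == self.t_end:
            return "log"
        return "composite"

    @classmethod
    def from_trajectory(cls, traj) -> "TimeAxis":
        """Build the axis for a trajectory.

        ``t0`` is the first time point of the file (not necessarily 0, so
        files starting mid-simulation still render); ``t_end`` comes from
        the first attainment of the final transcript length.  If the file
        shows no growth and starts at t=0, the first positive time point
        is substituted for ``t0`` so the logarithmic map is defined.
        """
        from .trajectory_io import transcription_end_time

        times = traj.times
        t0, t_max = times[0], times[-1]
        t_end = transcription_end_time(traj)
        if t_end == t0 < t_max and t0 <= 0:
            positive = [t for t in times if t > 0]
            t0 = t_end = positive[0]
        return cls(t0=t0, t_end=t_end, t_max=t_max)

    def time_to_x(self, t: float) -> float:
        """Horizontal fraction in [0, 1] for time ``t``.

        Times outside [t0, t_max] are clamped with a warning.
        """
        if t < self.t0 or t > self.t_max:
            warnings.warn(
                f"time {t} outside axis range [{self.t0}, {self.t_max}]; clamping",
                stacklevel=2,
            )
            t = min(max(t, self.t0), self.t_max)
        mode = self.mode
        if mode == "point":
            return self.split
        if mode == "linear":
            return (t - self.t0) / (self.t_max - self.t0)
        if mode == "log":
            return math.log(t / self.t0) / math.log(self.t_max / self.t0)
        if t <= self.t_end:
            return self.split * (t - self.t0) / (self.t_end - self.t0)
        return self.split + (1 - self.split) * math.log(t / self.t_end) / math.log(
            self.t_max / self.t_end
        )

    def x_to_time(self, x: float) -> float:
        """Inverse of :meth:`time_to_x`; round-trips within 1e-9 relative."""
        if not 0.0 <= x <= 1.0:
            raise ParameterError(f"axis fraction must be in [0, 1], got {x}")
        mode = self.mode
        if mode == "point":
            return self.t0
        if mode == "linear":
            return self.t0 + x * (self.t_max - self.t0)
        if mode == "log":
            return self.t0 * (self.t_max / self.t0) ** x
        if x <= self.split:
            return self.t0 + (x / self.split) * (self.t_end - self.t0)
        return self.t_end * (self.t_max / self.t_end) ** ((x - self.split) / (1 - self.split))

    def linear_ticks(self, n: int = 5) -> list[float]:
        """Evenly spaced tick times on the linear segment (cosmetic)."""
        if self.mode in ("point", "log"):
            return [self.t0]
        hi = self.t_max if self.mode == "linear" else self.t_end
        return list(np.linspace(self.t0, hi, n))

    def log_ticks(self) -> list[float]:
        """Decade tick times on the logarithmic segment (cosmetic)."""
        if self.mode in ("point", "linear"):
            return []
        lo = self.t0 if self.mode == "log" else self.t_end
        ticks = []
        d = math.ceil(math.log10(lo) - 1e-12)
        while 10.0**d <= self.t_max * (1 + 1e-12):
            if 10.0**d >= lo:
                ticks.append(10.0**d)
            d += 1
        return ticks
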