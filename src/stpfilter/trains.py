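"""Point-process and gridded-trace containers.

SpikeTrain and ReleaseTrain hold event times (and marks) of the
presynaptic point process x(t) and the marked release process
z(t) = sum_j k_j delta(t - t_j).  VesicleTrajectory, ConductanceTrace and
SignalTrace hold piecewise data on a uniform time grid.  All containers
read/write small plain-text formats (two-column text / CSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeTrain", "ReleaseTrain", "PopulationInput",
           "VesicleTrajectory", "ConductanceTrace", "SignalTrace"]


def _validate_times(times: np.ndarray, duration: float) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("event times must be one-dimensional")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if times.size:
        if not np.all(np.isfinite(times)):
            raise ValueError("event times must be finite")
        if np.any(np.diff(times) < 0):
            raise ValueError("event times must be sorted")
        if times[0] < 0 or times[-1] >= duration:
            raise ValueError("event times must lie in [0, duration)")
    return times


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) on [0, duration)."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", _validate_times(self.times, self.duration))

    def __len__(self) -> int:
        return self.times.size

    @property
    def rate(self) -> float:
        """Empirical event rate (Hz)."""
        return self.times.size / self.duration

    def save(self, path) -> None:
        np.savetxt(path, self.times, fmt="%.9f", header=f"duration_s={self.duration}")

    @classmethod
    def load(cls, path, duration: float | None = None) -> "SpikeTrain":
        with open(path) as fh:
            first = fh.readline()
        if duration is None:
            if not first.startswith("# duration_s="):
                raise ValueError("duration not given and not recorded in file header")
            duration = float(first.split("=", 1)[1])
        times = np.loadtxt(path, ndmin=1)
        return cls(times=times, duration=duration)


@dataclass(frozen=True)
class ReleaseTrain:
    """Marked release events: times (s) and vesicles released per event.

    Marks are integers for the stochastic model and nonnegative reals for
    the deterministic model; spikes that release nothing keep mark 0 so
    release events stay aligned with the driving spike train.
    """

    times: np.ndarray
    marks: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", _validate_times(self.times, self.duration))
        marks = np.asarray(self.marks, dtype=float)
        if marks.shape != self.times.shape:
            raise ValueError("marks and times must have equal length")
        if marks.size and marks.min() < 0:
            raise ValueError("marks must be nonnegative")
        object.__setattr__(self, "marks", marks)

    def __len__(self) -> int:
        return self.times.size

    @property
    def total_released(self) -> float:
        return float(self.marks.sum())

    @property
    def release_rate(self) -> float:
        """Mean vesicle release rate (vesicles/s)."""
        return self.total_released / self.duration

    def save(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.marks]),
                   fmt="%.9f", delimiter=",", header=f"time_s,mark duration_s={self.duration}")


@dataclass(frozen=True)
class PopulationInput:
    """A population of spike trains with common rate and pairwise sharing."""

    trains: tuple
    rate: float
    correlation: float

    def __post_init__(self) -> None:
        trains = tuple(self.trains)
        if not trains:
            raise ValueError("population must contain at least one train")
        d0 = trains[0].duration
        if any(t.duration != d0 for t in trains):
            raise ValueError("all trains must share one duration")
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError(f"correlation must lie in [0, 1], got {self.correlation}")
        object.__setattr__(self, "trains", trains)

    def __len__(self) -> int:
        return len(self.trains)

    @property
    def duration(self) -> float:
        return self.trains[0].duration

    def save(self, path) -> None:
        """Two-column text: train_id, time_s."""
        rows = [(i, t) for i, tr in enumerate(self.trains) for t in tr.times]
        arr = np.array(rows, dtype=float).reshape(-1, 2)
        np.savetxt(path, arr, fmt=["%d", "%.9f"], delimiter=",",
                   header=f"train_id,time_s duration_s={self.duration}")


@dataclass(frozen=True)
class _GridTrace:
    values: np.ndarray
    dt: float
    duration: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        n = int(round(self.duration / self.dt))
        if values.size != n:
            raise ValueError(f"trace length {values.size} != round(duration/dt) = {n}")
        object.__setattr__(self, "values", values)

    @property
    def t(self) -> np.ndarray:
        """Left bin edges of the uniform grid (s)."""
        return np.arange(self.values.size) * self.dt

    def save(self, path, name: str = "value") -> None:
        np.savetxt(path, np.column_stack([self.t, self.values]), fmt="%.9f",
                   delimiter=",", header=f"t_s,{name}")


@dataclass(frozen=True)
class SignalTrace(_GridTrace):
    """Rate-coded signal s(t) (Hz) on a uniform grid."""


@dataclass(frozen=True)
class VesicleTrajectory(_GridTrace):
    """Available vesicles v(t) sampled on a uniform grid."""

    n_sites: int = field(default=1)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.values.size and (self.values.min() < 0 or self.values.max() > self.n_sites):
            raise ValueError("v(t) must stay within [0, n_sites]")

    @property
    def v(self) -> np.ndarray:
        return self.values


@dataclass(frozen=True)
class ConductanceTrace(_GridTrace):
    """Postsynaptic conductance g(t) (rescaled units: vesicles/s)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.values.size and self.values.min() < -1e-9:
            raise ValueError("conductance must be nonnegative")

    @property
    def g(self) -> np.ndarray:
        return self.values
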