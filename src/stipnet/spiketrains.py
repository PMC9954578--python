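"""Spike-train containers.

A spike train is the ordered set of firing times of one neuron over a
simulation interval [0, T]; a :class:`SpikeTrainSet` collects one train per
neuron of a layer.  These are the universal information carriers of the
package: encoders produce them, the LIF simulator maps them layer to layer,
and the kernel module compares them through inner products.

All times are in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["SpikeTrain", "SpikeTrainSet", "ValidationError"]


class ValidationError(ValueError):
    """Raised when inputs violate a structural precondition."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of a single neuron over [0, interval_end].

    Parameters
    ----------
    times:
        Strictly increasing spike times in milliseconds.  The empty train
        (a silent neuron) is valid.
    interval_end:
        Duration T of the simulation interval in milliseconds.
    """

    times: np.ndarray
    interval_end: float

    def __init__(self, times: Iterable[float], interval_end: float):
        t = np.asarray(list(times) if not isinstance(times, np.ndarray) else times,
                       dtype=float).ravel()
        if interval_end <= 0:
            raise ValidationError(f"interval_end must be positive, got {interval_end}")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValidationError("spike times must be strictly increasing")
            if t[0] < 0 or t[-1] > interval_end:
                raise ValidationError(
                    f"spike times must lie in [0, {interval_end}], got range "
                    f"[{t[0]}, {t[-1]}]")
        t.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "interval_end", float(interval_end))

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def __len__(self) -> int:
        return self.n_spikes

    def concat(self, other: "SpikeTrain") -> "SpikeTrain":
        """Merge two trains on the same interval (times re-sorted)."""
        if other.interval_end != self.interval_end:
            raise ValidationError("cannot concatenate trains on different intervals")
        merged = np.sort(np.concatenate([self.times, other.times]))
        return SpikeTrain(merged, self.interval_end)


@dataclass(frozen=True)
class SpikeTrainSet:
    """One spike train per neuron of a layer, sharing an interval."""

    trains: tuple
    interval_end: float = field(init=False)

    def __init__(self, trains: Sequence[SpikeTrain]):
        trains = tuple(trains)
        if not trains:
            raise ValidationError("a SpikeTrainSet needs at least one train")
        T = trains[0].interval_end
        for tr in trains:
            if tr.interval_end != T:
                raise ValidationError("all trains must share interval_end")
        object.__setattr__(self, "trains", trains)
        object.__setattr__(self, "interval_end", T)

    @property
    def layer_size(self) -> int:
        return len(self.trains)

    def __len__(self) -> int:
        return self.layer_size

    def __iter__(self):
        return iter(self.trains)

    def __getitem__(self, i: int) -> SpikeTrain:
        return self.trains[i]

    @property
    def total_spikes(self) -> int:
        return sum(tr.n_spikes for tr in self.trains)

    # -- grid representation ------------------------------------------------
    # Clock-driven encoders and the LIF simulator place every spike on the
    # grid t_k = k*dt.  The count-matrix view below makes Gram computations a
    # single matrix product; see kernels.stip_matrix for the general path.

    def to_counts(self, dt: float) -> np.ndarray:
        """Spike-count matrix of shape (layer_size, n_steps) on the dt grid.

        Raises
        ------
        ValidationError
            If any spike time is not a multiple of dt (off the grid).
        """
        n_steps = _n_steps(self.interval_end, dt)
        counts = np.zeros((self.layer_size, n_steps), dtype=float)
        for i, tr in enumerate(self.trains):
            if tr.n_spikes == 0:
                continue
            idx = tr.times / dt
            k = np.rint(idx).astype(int)
            if np.any(np.abs(idx - k) > 1e-9) or np.any(k >= n_steps):
                raise ValidationError(
                    f"train {i} has spikes off the dt={dt} grid")
            np.add.at(counts[i], k, 1.0)
        return counts

    @staticmethod
    def from_counts(counts: np.ndarray, dt: float, interval_end: float) -> "SpikeTrainSet":
        """Inverse of :meth:`to_counts` for 0/1 count matrices."""
        counts = np.asarray(counts)
        trains = []
        for row in counts:
            (k,) = np.nonzero(row)
            trains.append(SpikeTrain(k * dt, interval_end))
        return SpikeTrainSet(trains)


def _n_steps(interval_end: float, dt: float) -> int:
    n = interval_end / dt
    n_int = int(round(n))
    if abs(n - n_int) > 1e-9 or n_int < 1:
        raise ValidationError(
            f"dt={dt} must divide interval_end={interval_end} into whole steps")
    return n_int
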