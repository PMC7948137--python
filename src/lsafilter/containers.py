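"""In-memory containers for epoched EEG data and scalp topographies.

An :class:`EpochSet` is the universal currency of every filter in this
package: a ``trials x channels x samples`` voltage array (µV, or µV/cm²
after a surface Laplacian) together with channel labels, a time axis and
the sampling rate.  A :class:`Topography` is one value per channel at a
single time point — what scalp maps and simulated ground-truth fields are
made of.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["EpochSet", "Topography"]


@dataclass
class Topography:
    """One value per channel at a single time point.

    Parameters
    ----------
    values : array, shape (n_channels,)
        Map values, finite.
    labels : sequence of str
        Channel labels aligned with ``values``.
    units : str
        Physical units, typically ``"uV"`` (voltage maps) or ``"uV/cm^2"``
        (current source density maps).
    """

    values: np.ndarray
    labels: list[str]
    units: str = "uV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(lab) for lab in self.labels]
        if self.values.ndim != 1:
            raise ValueError("Topography values must be one-dimensional")
        if len(self.labels) != self.values.size:
            raise ValueError(
                f"{len(self.labels)} labels for {self.values.size} values"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Topography values must be finite")

    def __getitem__(self, label: str) -> float:
        return float(self.values[_index(self.labels, label)])


@dataclass
class EpochSet:
    """Epoched EEG data: ``trials x channels x samples`` in µV.

    Parameters
    ----------
    data : array, shape (n_trials, n_channels, n_samples)
        Voltage (or CSD) values, finite.
    labels : sequence of str
        Channel labels aligned with the channel axis.
    times : array, shape (n_samples,)
        Sample times in seconds.
    srate : float
        Sampling rate in Hz.
    units : str
        Units of ``data``.
    """

    data: np.ndarray
    labels: list[str]
    times: np.ndarray
    srate: float
    units: str = "uV"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = [str(lab) for lab in self.labels]
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, samples); got shape {self.data.shape}"
            )
        n_trials, n_channels, n_samples = self.data.shape
        if len(self.labels) != n_channels:
            raise ValueError(
                f"{len(self.labels)} labels for {n_channels} data channels"
            )
        if len(set(lab.lower() for lab in self.labels)) != n_channels:
            raise ValueError("channel labels must be unique")
        if self.times.size != n_samples:
            raise ValueError(
                f"{self.times.size} time points for {n_samples} data samples"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        """Index of ``label`` along the channel axis (case-insensitive)."""
        return _index(self.labels, label)

    def sample_indices(self, window: tuple[float, float]) -> np.ndarray:
        """Indices of samples whose time lies inside ``window`` (inclusive)."""
        start, stop = float(window[0]), float(window[1])
        if stop < start:
            raise ValueError(f"window end {stop} precedes start {start}")
        idx = np.nonzero((self.times >= start) & (self.times <= stop))[0]
        if idx.size == 0:
            raise ValueError(
                f"window [{start}, {stop}] s contains no samples "
                f"(epoch spans [{self.times.min()}, {self.times.max()}] s)"
            )
        return idx

    def copy_with(self, **changes) -> "EpochSet":
        """A copy with ``data`` (and any other fields) replaced."""
        if "data" in changes:
            changes["data"] = np.array(changes["data"], dtype=float)
        return replace(self, **changes)


def _index(labels: Sequence[str], label: str) -> int:
    lower = [lab.lower() for lab in labels]
    try:
        return lower.index(str(label).lower())
    except ValueError:
        raise KeyError(f"channel {label!r} not found among {len(labels)} channels") from None
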