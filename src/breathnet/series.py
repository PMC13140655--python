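"""Core containers for event-sampled (breath-by-breath) physiological series.

A metabolic cart operated in breath-by-breath mode emits one sample per
respiratory cycle, so the sampling grid is the sequence of breaths rather
than wall-clock time.  All downstream analysis (transfer entropy, surrogate
testing, networks) is indexed on breaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The seven cardiorespiratory variables mapped as network nodes, in the
#: fixed order used everywhere (matrices, rankings, tie-breaks).
CHANNELS: tuple[str, ...] = ("HR", "RF", "VE", "VT", "VO2", "PETO2", "PETCO2")

#: Canonical condition and phase vocabularies for the three-arm cross-over
#: design (normoxic control, ~2500 m and ~3500 m simulated altitude).
CONDITIONS: tuple[str, ...] = ("CTR", "HY1", "HY2")
PHASES: tuple[str, ...] = ("rest", "exercise")


@dataclass
class BreathSeries:
    """One channel's values over a recording window, one value per breath.

    Parameters
    ----------
    channel : str
        Channel name (e.g. ``"HR"``).
    values : ndarray of float
        One value per respiratory cycle, in the channel's physiological
        units.
    breath_index : ndarray of int, optional
        0-based, strictly increasing breath indices.  Defaults to
        ``arange(len(values))``.
    """

    channel: str
    values: np.ndarray
    breath_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.breath_index is None:
            self.breath_index = np.arange(self.values.size)
        self.breath_index = np.asarray(self.breath_index, dtype=int)
        if self.breath_index.shape != self.values.shape:
            raise ValueError("breath_index and values must have equal length")
        if self.breath_index.size > 1 and np.any(np.diff(self.breath_index) <= 0):
            raise ValueError("breath_index must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray) -> "BreathSeries":
        """Copy of this series with ``values`` replaced (same breath grid)."""
        return BreathSeries(self.channel, np.asarray(values, dtype=float),
                            self.breath_index.copy())


@dataclass
class ParticipantRecording:
    """Seven parallel breath-sampled channels plus condition/phase labels.

    All channels share one breath grid, so every channel has the same
    length; operations that slice or clean a recording preserve this
    parallelism.
    """

    participant_id: str
    condition: str
    phase: str
    channels: dict[str, BreathSeries]
    times: np.ndarray | None = None  # optional per-breath time stamps (s)

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"recording is missing channels: {missing}")
        lengths = {name: len(s) for name, s in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channels must be parallel (equal length), got {lengths}")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.size != self.n_samples:
                raise ValueError("times must align with the breath grid")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def __getitem__(self, channel: str) -> BreathSeries:
        return self.channels[channel]

    def channel_matrix(self) -> np.ndarray:
        """Stack the channels as an ``(n_samples, 7)`` array in fixed order."""
        return np.column_stack([self.channels[c].values for c in CHANNELS])

    def map_channels(self, fn) -> "ParticipantRecording":
        """Apply ``fn(BreathSeries) -> BreathSeries`` to every channel."""
        new = {name: fn(series) for name, series in self.channels.items()}
        return replace(self, channels=new)
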