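"""In-memory containers for sampled traces and trial bundles."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stim import StimulusEpoch

__all__ = ["Trace", "TrialSet", "SpikeTrialSet", "DEFAULT_FS_HZ"]

DEFAULT_FS_HZ = 10_000.0


@dataclass
class Trace:
    """A single sampled response (mV for PSPs, pA for currents)."""

    values: np.ndarray
    fs_hz: float
    units: str
    epoch: StimulusEpoch | None = None
    cell_id: str = ""
    trial: int = 0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs_hz


@dataclass
class TrialSet:
    """The trial bundle for one (cell, stimulus, condition): shape (n_trials, n)."""

    traces: np.ndarray
    fs_hz: float
    units: str
    epoch: StimulusEpoch
    cell_id: str = ""
    condition: object | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("trial set contains non-finite samples")
        expected = int(round(self.epoch.total_s * self.fs_hz))
        if abs(self.traces.shape[1] - expected) > 1:
            raise ValueError(
                f"trace length {self.traces.shape[1]} does not match epoch duration "
                f"({expected} samples at {self.fs_hz:g} Hz)"
            )

    @property
    def n_trials(self) -> int:
        return self.traces.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.traces.shape[1]) / self.fs_hz

    @property
    def mean_trace(self) -> np.ndarray:
        return self.traces.mean(axis=0)

    def stim_slice(self) -> slice:
        t0, t1 = self.epoch.stim_window
        return slice(int(round(t0 * self.fs_hz)), int(round(t1 * self.fs_hz)))


@dataclass
class SpikeTrialSet:
    """Per-trial spike-time lists for one (cell, stimulus, condition)."""

    spike_times: list  # list of 1-D float arrays, seconds from epoch start
    epoch: StimulusEpoch
    cell_id: str = ""
    condition: object | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = [np.asarray(s, dtype=float) for s in self.spike_times]

    @property
    def n_trials(self) -> int:
        return len(self.spike_times)
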