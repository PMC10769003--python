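"""Response metrics for patch-clamp traces and spike trains.

Implements the quantities used to characterize center-surround receptive
fields across luminance:

* baseline subtraction against the pre-stimulus interval,
* stimulus-window **charge** (voltage clamp) and **peak depolarization**
  (current clamp), each averaged over the 4-trial bundle,
* size-tuning curves and the **surround suppression index**
  ``SSI = (Resp_max - Resp_1200um) / (Resp_max + Resp_1200um)``,
* receptive-field-center size (smallest spot reaching maximal response),
* cycle-averaged responses to sinusoidal contrast and the **rectification
  index** ``RI = (Resp_+100% - Resp_-100%) / (Resp_+100% + Resp_-100%)``,
* annulus transient/sustained decomposition,
* sliding-window (100 ms) peristimulus time histograms and stimulus-window
  spike counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import SpikeTrialSet, TrialSet

__all__ = [
    "UndefinedMetricError",
    "SizeTuningCurve",
    "CycleResponse",
    "baseline_subtract",
    "subtract_trialsets",
    "charge",
    "peak_depolarization",
    "size_tuning",
    "ssi",
    "rf_center_size",
    "rectification_index",
    "cycle_response",
    "annulus_metrics",
    "psth",
    "spike_count",
]


class UndefinedMetricError(ValueError):
    """Raised when a ratio metric is undefined (e.g. zero response)."""


# ------------------------------------------------------------------ containers

@dataclass
class SizeTuningCurve:
    """Per-cell response metric vs spot diameter."""

    diameters_um: np.ndarray
    resp: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.diameters_um = np.asarray(self.diameters_um, dtype=float)
        self.resp = np.asarray(self.resp, dtype=float)
        if self.diameters_um.size != self.resp.size or self.diameters_um.size == 0:
            raise ValueError("diameters and responses must be equal-length, non-empty")
        if np.unique(self.diameters_um).size != self.diameters_um.size:
            raise ValueError("duplicate diameters in size-tuning curve")

    @property
    def resp_max(self) -> float:
        return float(self.resp.max())

    @property
    def resp_1200(self) -> float:
        idx = np.flatnonzero(np.isclose(self.diameters_um, 1200.0))
        if idx.size == 0:
            raise UndefinedMetricError("no 1200 um entry; SSI undefined for this curve")
        return float(self.resp[idx[0]])


@dataclass
class CycleResponse:
    """Opposite-polarity excursion magnitudes of a cycle-averaged response."""

    freq_hz: float
    resp_plus: float
    resp_minus: float

    def __post_init__(self) -> None:
        if self.resp_plus < 0 or self.resp_minus < 0:
            raise ValueError("excursion magnitudes must be >= 0")


# ------------------------------------------------------------------ trace prep

def baseline_subtract(
    trial_set: TrialSet, window_s: tuple[float, float] | None = None
) -> TrialSet:
    """Subtract the mean over a pre-stimulus window (per trial).

    The default window is the full pre-stimulus span.  The removed baselines
    are retained in ``meta['baseline']``.
    """
    t0, _ = trial_set.epoch.stim_window
    if window_s is None:
        window_s = (0.0, t0)
    lo, hi = window_s
    if not (0.0 <= lo < hi <= t0 + 1e-12):
        raise ValueError("baseline window must lie within the pre-stimulus span")
    i0, i1 = int(round(lo * trial_set.fs_hz)), int(round(hi * trial_set.fs_hz))
    base = trial_set.traces[:, i0:i1].mean(axis=1, keepdims=True)
    out = dataclasses.replace(trial_set, traces=trial_set.traces - base)
    out.meta = dict(trial_set.meta, baseline=base.ravel().tolist())
    return out


def subtract_trialsets(a: TrialSet, b: TrialSet) -> TrialSet:
    """Per-timepoint paired subtraction of matched trial sets (e.g. control - TTX).

    Used to isolate a pharmacologically sensitive component; apply after
    baseline subtraction.  Epoch geometry and sampling must match.
    """
    if a.traces.shape != b.traces.shape or a.fs_hz != b.fs_hz:
        raise ValueError("trial sets must have matching shape and sampling rate")
    if a.epoch.label != b.epoch.label:
        raise ValueError("trial sets must come from the same stimulus epoch")
    out = dataclasses.replace(a, traces=a.traces - b.traces)
    out.meta = dict(a.meta, subtracted=True)
    return out


# --------------------------------------------------------------------- metrics

def charge(
    trial_set: TrialSet, stim_window_s: tuple[float, float] | None = None
) -> float:
    """Current integrated over the stimulus window, averaged across trials.

    Trapezoidal rule on baseline-subtracted current traces; returns the
    magnitude in pC (pA x s = pC).  The sign of the mean integral tells
    inward (negative) from outward current.
    """
    if trial_set.n_trials < 1:
        raise ValueError("need at least one trial")
    lo, hi = stim_window_s if stim_window_s is not None else trial_set.epoch.stim_window
    i0, i1 = int(round(lo * trial_set.fs_hz)), int(round(hi * trial_set.fs_hz))
    if i1 - i0 < 2:
        raise ValueError("stimulus window too short")
    seg = trial_set.traces[:, i0 : i1 + 1]
    q = np.trapezoid(seg, dx=1.0 / trial_set.fs_hz, axis=1)  # pA*s == pC
    return float(np.abs(q.mean()))


def peak_depolarization(
    trial_set: TrialSet,
    stim_window_s: tuple[float, float] | None = None,
    polarity: str = "positive",
) -> float:
    """Per-trial extremum over the stimulus window, averaged across trials (mV).

    ``polarity='positive'`` takes each trial's maximum (depolarization);
    ``'negative'`` takes the minimum (hyperpolarizing responses, sign kept).
    """
    lo, hi = stim_window_s if stim_window_s is not None else trial_set.epoch.stim_window
    i0, i1 = int(round(lo * trial_set.fs_hz)), int(round(hi * trial_set.fs_hz))
    if i1 <= i0:
        raise ValueError("empty stimulus window")
    seg = trial_set.traces[:, i0:i1]
    per_trial = seg.max(axis=1) if polarity == "positive" else seg.min(axis=1)
    return float(per_trial.mean())


def size_tuning(
    resp: Sequence[float], diameters_um: Sequence[float], units: str = ""
) -> SizeTuningCurve:
    """Assemble a size-tuning curve, sorted by ascending diameter."""
    d = np.asarray(diameters_um, dtype=float)
    r = np.asarray(resp, dtype=float)
    order = np.argsort(d)
    return SizeTuningCurve(diameters_um=d[order], resp=r[order], units=units)


def ssi(curve: SizeTuningCurve) -> float:
    """Surround suppression index: 0 = no suppression, 1 = complete.

    ``(Resp_max - Resp_1200um) / (Resp_max + Resp_1200um)`` with Resp_max the
    maximum over all spot sizes.  Undefined when the maximal response is not
    positive.
    """
    rmax, r1200 = curve.resp_max, curve.resp_1200
    if rmax <= 0:
        raise UndefinedMetricError("SSI undefined: maximal response is not positive")
    return (rmax - r1200) / (rmax + r1200)


def rf_center_size(curve: SizeTuningCurve, epsilon: float = 0.05) -> float:
    """Receptive-field-center size: smallest spot producing maximal response.

    Operationally, the smallest diameter whose response reaches
    ``(1 - epsilon) * Resp_max``; ``epsilon`` absorbs measurement noise in
    the "maximal" criterion (default 0.05).
    """
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")
    thr = (1.0 - epsilon) * curve.resp_max
    hit = np.flatnonzero(curve.resp >= thr)
    return float(curve.diameters_um[hit[0]])


def rectification_index(cycle: CycleResponse) -> float:
    """Rectification index in [-1, 1]: -1 negatively rectified, 0 linear, +1 positive."""
    tot = cycle.resp_plus + cycle.resp_minus
    if tot <= 0:
        raise UndefinedMetricError("RI undefined: both excursions are zero")
    return (cycle.resp_plus - cycle.resp_minus) / tot


def cycle_response(
    trial_set: TrialSet,
    discard_cycles: int = 1,
    baseline: str = "zero",
) -> CycleResponse:
    """Fold a sinusoid-epoch trial bundle into one cycle and measure its excursions.

    Trials are averaged, the first ``discard_cycles`` cycles are dropped as
    onset transient, and the remaining cycles are folded into a mean cycle.
    Excursions are measured from the pre-stimulus baseline (``'zero'``,
    assuming baseline-subtracted traces) or from the cycle mean
    (``baseline='cycle_mean'``): ``resp_plus`` is the maximum excursion above
    baseline, ``resp_minus`` the magnitude of the excursion below it.
    """
    epoch = trial_set.epoch
    if epoch.modulation != "sinusoid":
        raise ValueError("cycle_response requires a sinusoid epoch")
    fs = trial_set.fs_hz
    spc = int(round(fs / epoch.freq_hz))  # samples per cycle
    t0, t1 = epoch.stim_window
    i0 = int(round(t0 * fs)) + discard_cycles * spc
    i1 = int(round(t1 * fs))
    n_cycles = (i1 - i0) // spc
    if n_cycles < 1:
        raise ValueError("need at least one full cycle after discarding the first")
    mean = trial_set.mean_trace[i0 : i0 + n_cycles * spc]
    folded = mean.reshape(n_cycles, spc).mean(axis=0)
    ref = folded.mean() if baseline == "cycle_mean" else 0.0
    resp_plus = max(float(folded.max() - ref), 0.0)
    resp_minus = max(float(ref - folded.min()), 0.0)
    return CycleResponse(freq_hz=epoch.freq_hz, resp_plus=resp_plus, resp_minus=resp_minus)


def annulus_metrics(
    trial_set: TrialSet,
    transient_window_s: float = 0.2,
    sustained_fraction: float = 1.0 / 3.0,
    smooth_hz: float | None = 50.0,
) -> tuple[float, float]:
    """(transient_peak, sustained_level) of a surround-only (annulus) response.

    The transient peak is the signed extremum of the trial-averaged trace in
    the first ``transient_window_s`` of the stimulus; the sustained level is
    the mean over the final ``sustained_fraction`` of the stimulus window.
    The averaged trace is zero-phase low-pass filtered at ``smooth_hz``
    (default 50 Hz, well above the transient's bandwidth) before the
    extremum is taken: an extremum over a noisy window is an extreme-value
    statistic whose bias grows with the noise bandwidth.  ``smooth_hz=None``
    disables smoothing.
    """
    t0, t1 = trial_set.epoch.stim_window
    if t1 - t0 < transient_window_s:
        raise ValueError("stimulus shorter than the transient analysis window")
    fs = trial_set.fs_hz
    mean = trial_set.mean_trace
    if smooth_hz is not None and smooth_hz < fs / 2:
        from scipy import signal as _signal

        b, a = _signal.butter(2, smooth_hz / (fs / 2))
        mean = _signal.filtfilt(b, a, mean)
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    early = mean[i0 : i0 + int(round(transient_window_s * fs))]
    transient = float(early[np.abs(early).argmax()])
    late = mean[i1 - int(round((t1 - t0) * sustained_fraction * fs)) : i1]
    return transient, float(late.mean())


# ---------------------------------------------------------------------- spikes

def psth(
    spike_trains: Sequence[np.ndarray] | SpikeTrialSet,
    t_start: float,
    t_stop: float,
    window_s: float = 0.1,
    step_s: float = 0.001,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window peristimulus time histogram.

    ``rate(t)`` counts spikes (pooled over trials) inside the half-open
    window ``[t - w/2, t + w/2)`` divided by ``window_s * n_trials``.  With
    ``window_s`` an integer multiple of ``step_s`` and the grid covering all
    spikes by at least ``w/2`` on both sides, the discrete time integral of
    the rate times ``n_trials`` equals the total spike count exactly.

    Returns (times, rate_hz).
    """
    if window_s <= 0 or step_s <= 0:
        raise ValueError("window_s and step_s must be > 0")
    trains = spike_trains.spike_times if isinstance(spike_trains, SpikeTrialSet) else list(spike_trains)
    n_trials = max(len(trains), 1)
    times = np.arange(t_start, t_stop + step_s / 2, step_s)
    if trains and any(s.size for s in map(np.asarray, trains)):
        spikes = np.concatenate([np.asarray(s, float) for s in trains])
    else:
        spikes = np.empty(0)
    counts = np.zeros(times.size)
    if spikes.size:
        # difference-array accumulation of the boxcar each spike contributes
        lo = np.searchsorted(times, spikes - window_s / 2, side="left")
        hi = np.searchsorted(times, spikes + window_s / 2, side="left")
        diff = np.zeros(times.size + 1)
        np.add.at(diff, lo, 1.0)
        np.add.at(diff, hi, -1.0)
        counts = np.cumsum(diff[:-1])
    rate = counts / (window_s * n_trials)
    return times, rate


def spike_count(
    spike_trains: Sequence[np.ndarray] | SpikeTrialSet,
    window_s: tuple[float, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Spikes per trial in ``[start, end)`` plus the across-trial mean."""
    if isinstance(spike_trains, SpikeTrialSet):
        if window_s is None:
            window_s = spike_trains.epoch.stim_window
        trains = spike_trains.spike_times
    else:
        if window_s is None:
            raise ValueError("window_s is required for bare spike lists")
        trains = list(spike_trains)
    lo, hi = window_s
    per_trial = np.array(
        [int(np.count_nonzero((np.asarray(s) >= lo) & (np.asarray(s) < hi))) for s in trains]
    )
    mean = float(per_trial.mean()) if per_trial.size else 0.0
    return per_trial, mean
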