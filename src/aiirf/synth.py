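"""Phenomenological generative model of AII amacrine (and s-ONα ganglion) light responses.

The model captures the circuit structure that shapes AII receptive fields:

* **Center** — excitatory drive through two luminance-gated pathways: rod
  bipolar cells (AMPA-receptor mediated, blocked by NBQX) carry nearly all
  input at scotopic/mesopic backgrounds, ON cone bipolar cells (via Cx36 gap
  junctions, removed in the Cx36 knockout) carry photopic input.  Spatial
  summation is a normalized 2-D Gaussian of width ``sigma_c_um``.
* **Presynaptic surround** — divisive inhibition of bipolar-terminal output
  (GABA_C, blocked by TPMPA), split into a *transient* component driven by
  spiking wide-field amacrine cells (blocked by TTX; supplied by nNOS-1 cells
  at mesopic backgrounds) and a *sustained* component from horizontal cells
  (blocked by HEPES pH buffering).  Both are rectified ON-driven in the
  divisor; summation uses a wider Gaussian ``sigma_s_um``.
* **Direct (postsynaptic) surround** — subtractive GABA_A input onto the AII
  itself (blocked by gabazine), with the same transient/sustained split; its
  sustained part is linear, so negative-contrast annuli depolarize.
* **Narrow-field glycinergic input** — visible only in IPSC recordings at the
  photopic background, suppressed for spots larger than ~200 um.

Traces are sampled at 10 kHz.  Trial structure follows the experimental
design: 4 trials per stimulus, multiplied by a per-cell and a per-trial
lognormal gain, plus band-limited additive recording noise.  All randomness
derives from one master seed through counter-based streams so any subset of
cells/trials is reproducible independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import signal as _signal
from scipy.special import erf

from .containers import DEFAULT_FS_HZ, SpikeTrialSet, Trace, TrialSet
from .stim import StimulusEpoch, render_contrast

__all__ = [
    "CALIBRATED_BACKGROUNDS",
    "Condition",
    "BackgroundParams",
    "CircuitParams",
    "SurroundWeights",
    "spatial_drive",
    "pathway_gate",
    "surround_gate",
    "response_timecourse",
    "simulate_trace",
    "simulate_trialset",
    "simulate_spikes",
    "simulate_population",
]

#: photoisomerization-rate regimes the default calibration covers (R*/rod/s)
CALIBRATED_BACKGROUNDS = (0.5, 500.0, 25000.0)

_GENOTYPES = ("WT", "Cx36KO", "nNOS_ablated")
_DRUGS = ("NBQX", "TTX", "HEPES", "gabazine", "strychnine", "TPMPA")
_MODES = ("PSP", "EPSC", "IPSC", "spikes")
_CELLS = ("AII", "sONalpha")


@dataclass(frozen=True)
class Condition:
    """Genotype + drug set + recording mode + cell type.

    Drug concentrations from the recording conditions (TTX 500 nM, HEPES
    20 mM, gabazine 10 uM, strychnine 1 uM, TPMPA 50 uM, NBQX 10 uM) are
    metadata; each drug acts as a binary switch on the circuit component it
    blocks.  ``mode='IPSC'`` implies holding at the cation reversal
    (metadata only).
    """

    genotype: str = "WT"
    drugs: frozenset = frozenset()
    mode: str = "PSP"
    cell: str = "AII"

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", frozenset(self.drugs))
        if self.genotype not in _GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.mode not in _MODES:
            raise ValueError(f"unknown recording mode {self.mode!r}")
        if self.cell not in _CELLS:
            raise ValueError(f"unknown cell type {self.cell!r}")
        unknown = self.drugs - set(_DRUGS)
        if unknown:
            raise ValueError(f"unknown drugs {sorted(unknown)}")
        if self.mode == "spikes" and self.cell != "sONalpha":
            raise ValueError("spike recordings are only modelled for s-ONalpha RGCs")

    @property
    def label(self) -> str:
        drugs = "+".join(sorted(self.drugs)) if self.drugs else "ctrl"
        return f"{self.cell}_{self.mode}_{self.genotype}_{drugs}"

    @property
    def units(self) -> str:
        return {"PSP": "mV", "EPSC": "pA", "IPSC": "pA", "spikes": "s"}[self.mode]


@dataclass
class BackgroundParams:
    """Calibration entries for one background luminance."""

    a_center_mv: float = 10.0        # small-spot PSP plateau gain (mV per unit drive)
    a_epsc_pa: float = 50.0          # small-spot EPSC peak amplitude (pA, magnitude)
    a_ipsc_pa: float = 40.0          # wide-field direct-inhibition IPSC gain (pA)
    f_rbc: float = 1.0               # fraction of center drive through rod bipolars
    f_transient: float = 0.5         # transient (spiking-AC) fraction of the surround
    w_pre_psp: float = 0.0           # divisive presynaptic weight, current clamp
    w_pre_epsc: float = 0.0          # divisive presynaptic weight, voltage clamp
    w_pre_spk: float = 0.0           # divisive presynaptic weight, RGC spike model
    w_post_mv: float = 0.0           # subtractive direct-surround gain (mV)
    glycine_gain_pa: float = 0.0     # narrow-field glycinergic IPSC gain (pA)


@dataclass
class CircuitParams:
    """Full generator calibration: spatial scales, kinetics, noise and per-background gains."""

    sigma_c_um: float = 17.0         # AII receptive-field-center Gaussian width
    sigma_s_um: float = 300.0        # wide-field surround Gaussian width
    sigma_c_rgc_um: float = 45.0     # s-ONalpha center Gaussian width
    sigma_gly_c_um: float = 40.0     # glycinergic narrow-field center width
    sigma_gly_s_um: float = 70.0     # glycinergic suppressive width (vanishes > ~200 um)
    tau_on_s: float = 0.04           # center rise time constant
    tau_off_s: float = 0.04          # center decay time constant (equal to tau_on_s
                                     # by default so the surround-free model stays linear)
    tau_sus_s: float = 0.06          # sustained (horizontal-cell) surround time constant
    tau_trans_s: float = 0.09        # transient surround alpha-function time constant
    trans_delay_s: float = 0.06      # transient surround synaptic latency
    noise_sd_mv: float = 0.3         # additive recording noise, current clamp
    noise_sd_pa: float = 2.0         # additive recording noise, voltage clamp
    noise_bw_hz: float = 100.0       # noise bandwidth (low-pass corner)
    cell_cv: float = 0.3             # across-cell lognormal gain CV
    trial_cv: float = 0.05           # across-trial lognormal gain CV
    gabazine_boost: float = 1.3      # serial-inhibition release factor on w_pre
    rate_base_hz: float = 4.0        # RGC baseline firing rate
    rate_gain_hz: float = 160.0      # RGC rate per unit rectified drive
    w_post_spk: float = 0.4          # subtractive surround in the RGC drive (drive units)
    clip_mv: float = 40.0            # physiological clip for PSPs (|mV|)
    clip_pa: float = 600.0           # physiological clip for currents (|pA|)
    backgrounds: dict = field(
        default_factory=lambda: {bg: BackgroundParams() for bg in CALIBRATED_BACKGROUNDS}
    )

    def __post_init__(self) -> None:
        if not (self.sigma_s_um > self.sigma_c_um > 0):
            raise ValueError("require sigma_s_um > sigma_c_um > 0")
        self.backgrounds = {
            float(bg): (bp if isinstance(bp, BackgroundParams) else BackgroundParams(**bp))
            for bg, bp in self.backgrounds.items()
        }
        for bg, bp in self.backgrounds.items():
            if not 0.0 <= bp.f_rbc <= 1.0:
                raise ValueError(f"f_rbc out of [0,1] at background {bg}")
            if not 0.0 <= bp.f_transient <= 1.0:
                raise ValueError(f"f_transient out of [0,1] at background {bg}")
            for name in ("w_pre_psp", "w_pre_epsc", "w_pre_spk", "w_post_mv",
                         "a_center_mv", "a_epsc_pa", "a_ipsc_pa", "glycine_gain_pa"):
                if getattr(bp, name) < 0:
                    raise ValueError(f"{name} must be >= 0 at background {bg}")

    def at(self, background: float) -> BackgroundParams:
        bg = float(background)
        if bg not in self.backgrounds:
            raise KeyError(
                f"background {bg:g} R*/rod/s is not calibrated "
                f"(available: {sorted(self.backgrounds)})"
            )
        return self.backgrounds[bg]

    # --------------------------------------------------------------- serialize
    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "backgrounds"}
        d["backgrounds"] = {
            f"{bg:g}": dict(bp.__dict__) for bg, bp in sorted(self.backgrounds.items())
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        d = dict(d)
        d["backgrounds"] = {float(k): v for k, v in d.get("backgrounds", {}).items()}
        return cls(**d)

    def copy(self) -> "CircuitParams":
        return CircuitParams.from_dict(self.to_dict())


# --------------------------------------------------------------------- spatial

def _disc_integral(diameter_um: float, sigma_um: float) -> float:
    """Integral of a normalized 2-D Gaussian over a centered disc."""
    return 1.0 - float(np.exp(-(diameter_um ** 2) / (8.0 * sigma_um ** 2)))


def _strip_integral(lo: float, hi: float, sigma: float) -> float:
    """Integral of a 1-D unit Gaussian over [lo, hi]."""
    s = sigma * np.sqrt(2.0)
    return 0.5 * float(erf(hi / s) - erf(lo / s))


def _region_drive(epoch: StimulusEpoch, sigma_um: float) -> float:
    if epoch.shape == "uniform":
        return 1.0
    if epoch.shape == "spot":
        return _disc_integral(epoch.diameter_um, sigma_um)
    if epoch.shape == "annulus":
        return _disc_integral(epoch.outer_um, sigma_um) - _disc_integral(
            epoch.inner_um, sigma_um
        )
    if epoch.shape == "bar":
        along = _strip_integral(
            epoch.offset_um - epoch.bar_w_um / 2,
            epoch.offset_um + epoch.bar_w_um / 2,
            sigma_um,
        )
        across = _strip_integral(-epoch.bar_l_um / 2, epoch.bar_l_um / 2, sigma_um)
        return along * across
    raise ValueError(f"unsupported stimulus shape {epoch.shape!r}")


def spatial_drive(
    epoch: StimulusEpoch, params: CircuitParams, cell: str = "AII"
) -> tuple[float, float]:
    """(center_drive, surround_drive): fraction of each Gaussian covered by the stimulus.

    Closed form for spots: ``1 - exp(-d^2 / (8 sigma^2))``; annuli are the
    difference of two discs; bars use the product of 1-D Gaussian integrals.
    Both drives lie in [0, 1].
    """
    sigma_c = params.sigma_c_rgc_um if cell == "sONalpha" else params.sigma_c_um
    return (
        _region_drive(epoch, sigma_c),
        _region_drive(epoch, params.sigma_s_um),
    )


def glycine_drive(epoch: StimulusEpoch, params: CircuitParams) -> float:
    """Spatial profile of the narrow-field glycinergic IPSC (suppressed for large spots)."""
    c = _region_drive(epoch, params.sigma_gly_c_um)
    s = _region_drive(epoch, params.sigma_gly_s_um)
    return max(c - s, 0.0)


# ----------------------------------------------------------------------- gates

def pathway_gate(
    background: float, condition: Condition, params: CircuitParams
) -> float:
    """Center-gain multiplier from luminance-dependent pathway mixing.

    For AIIs: ``f_RBC * [NBQX off] + (1 - f_RBC) * [Cx36 intact]``.  The rod
    bipolar fraction ``f_RBC`` is ~1 at the scotopic background and ~0 at the
    photopic one, so NBQX silences dim-light responses while the Cx36 knockout
    silences photopic ones.  s-ONalpha RGCs keep their direct cone-bipolar
    excitation in the Cx36KO (only the AII-inherited surround is lost).
    """
    bp = params.at(background)
    if condition.cell == "sONalpha":
        return 0.0 if "NBQX" in condition.drugs else 1.0
    rbc = 0.0 if "NBQX" in condition.drugs else bp.f_rbc
    cbc = 0.0 if condition.genotype == "Cx36KO" else (1.0 - bp.f_rbc)
    return rbc + cbc


@dataclass(frozen=True)
class SurroundWeights:
    """Effective surround weights after genotype/drug gating.

    Components rather than totals are stored so that blocking the transient
    (TTX, nNOS ablation) leaves the sustained weight untouched and vice versa
    (HEPES).
    """

    w_pre_trans: float
    w_pre_sus: float
    w_post_trans: float
    w_post_sus: float

    @property
    def w_pre_eff(self) -> float:
        return self.w_pre_trans + self.w_pre_sus

    @property
    def w_post_eff(self) -> float:
        return self.w_post_trans + self.w_post_sus

    @property
    def f_trans_eff(self) -> float:
        tot = self.w_pre_eff
        return self.w_pre_trans / tot if tot > 0 else 0.0


def surround_gate(
    condition: Condition, background: float, params: CircuitParams
) -> SurroundWeights:
    """Apply genotype and pharmacology switches to the surround weights.

    TTX silences the spiking (transient) components; ablating nNOS-1 cells
    does the same but only at the mesopic background; HEPES removes the
    sustained horizontal-cell components; TPMPA removes all presynaptic
    (GABA_C) weight; gabazine removes the direct GABA_A surround and, through
    release of serial inhibition, *boosts* the presynaptic weight.
    """
    bp = params.at(background)
    if condition.cell == "sONalpha":
        w_pre, w_post, f_t = bp.w_pre_spk, params.w_post_spk, bp.f_transient
        if condition.genotype == "Cx36KO":
            # surround is inherited from AIIs through gap junctions
            return SurroundWeights(0.0, 0.0, 0.0, 0.0)
    else:
        w_pre = bp.w_pre_psp if condition.mode in ("PSP", "IPSC") else bp.w_pre_epsc
        w_post, f_t = bp.w_post_mv, bp.f_transient

    pre_t, pre_s = w_pre * f_t, w_pre * (1.0 - f_t)
    post_t, post_s = w_post * f_t, w_post * (1.0 - f_t)

    drugs = condition.drugs
    if "TTX" in drugs or (
        condition.genotype == "nNOS_ablated" and float(background) == 500.0
    ):
        pre_t = post_t = 0.0
    if "HEPES" in drugs:
        pre_s = post_s = 0.0
    if "gabazine" in drugs:
        pre_t, pre_s = pre_t * params.gabazine_boost, pre_s * params.gabazine_boost
        post_t = post_s = 0.0  # direct surround is GABA_A
    if "TPMPA" in drugs:
        pre_t = pre_s = 0.0
    return SurroundWeights(pre_t, pre_s, post_t, post_s)


# ------------------------------------------------------------------- temporal

def _lowpass(x: np.ndarray, fs: float, tau: float) -> np.ndarray:
    a = 1.0 - np.exp(-1.0 / (fs * tau))
    return _signal.lfilter([a], [1.0, -(1.0 - a)], x)


def _lowpass_asym(x: np.ndarray, fs: float, tau_rise: float, tau_fall: float) -> np.ndarray:
    """First-order low-pass with different rise and fall time constants.

    For piecewise-constant inputs (step stimuli) each segment relaxes
    exponentially toward its level, so the recursion has an exact closed
    form per segment; arbitrary inputs fall back to the sample loop.
    """
    if abs(tau_rise - tau_fall) < 1e-12:
        return _lowpass(x, fs, tau_rise)
    dt = 1.0 / fs
    breaks = np.flatnonzero(np.diff(x) != 0.0) + 1
    if breaks.size <= 8:
        y = np.empty_like(x)
        acc = 0.0
        for s0, s1 in zip(np.r_[0, breaks], np.r_[breaks, x.size]):
            level = x[s0]
            tau = tau_rise if level > acc else tau_fall
            decay = np.exp(-np.arange(1, s1 - s0 + 1) * dt / tau)
            y[s0:s1] = level + (acc - level) * decay
            acc = y[s1 - 1]
        return y
    a_r = 1.0 - np.exp(-dt / tau_rise)
    a_f = 1.0 - np.exp(-dt / tau_fall)
    y = np.empty_like(x)
    acc = 0.0
    for i in range(x.size):  # sequential by nature
        a = a_r if x[i] > acc else a_f
        acc += a * (x[i] - acc)
        y[i] = acc
    return y


def _alpha_kernel(fs: float, tau: float, delay: float) -> np.ndarray:
    """Alpha-function kernel with onset latency, normalized to unit peak for a unit onset."""
    n = int(round((delay + 8.0 * tau) * fs))
    t = np.arange(n) / fs - delay
    k = np.where(t > 0, (t / tau) * np.exp(1.0 - t / tau), 0.0)
    return k


def _transient_surround(x: np.ndarray, fs: float, params: CircuitParams) -> np.ndarray:
    """ON-onset-locked transient surround: alpha kernel driven by rises of rectified contrast.

    Driven only by increases of the positive (ON) half-wave of the contrast
    waveform, so negative-contrast stimuli never recruit it.
    """
    xp = np.maximum(x, 0.0)
    onset = np.maximum(np.diff(xp, prepend=0.0), 0.0)
    k = _alpha_kernel(fs, params.tau_trans_s, params.trans_delay_s)
    return _signal.oaconvolve(onset, k)[: x.size]


@dataclass
class Timecourse:
    """Noiseless response and its circuit decomposition."""

    times: np.ndarray
    values: np.ndarray          # mV (PSP), pA (EPSC/IPSC) or drive units (spikes)
    units: str
    center: np.ndarray          # center drive after division
    transient_surround: np.ndarray  # transient surround term entering the response
    sustained_surround: np.ndarray
    rate_hz: np.ndarray | None = None  # spikes mode only


def response_timecourse(
    epoch: StimulusEpoch,
    condition: Condition,
    params: CircuitParams,
    fs_hz: float = DEFAULT_FS_HZ,
) -> Timecourse:
    """Noiseless response of one cell to one epoch under one condition.

    The center drive is low-pass filtered contrast scaled by the spatial
    center integral and the pathway gate; the presynaptic surround divides
    it, the direct surround subtracts from it (current clamp only), and
    spike-mode output is an instantaneous rate through a rectifier.
    """
    bg = epoch.background_rstar
    bp = params.at(bg)
    n = int(round(epoch.total_s * fs_hz))
    t = np.arange(n) / fs_hz
    x = render_contrast(epoch, t)

    cd, sd = spatial_drive(epoch, params, cell=condition.cell)
    gate = pathway_gate(bg, condition, params)
    w = surround_gate(condition, bg, params)

    lc = _lowpass_asym(np.asarray(x, float), fs_hz, params.tau_on_s, params.tau_off_s)
    sus = _lowpass(np.asarray(x, float), fs_hz, params.tau_sus_s)
    trans = _transient_surround(np.asarray(x, float), fs_hz, params)

    den = 1.0 + sd * (w.w_pre_trans * trans + w.w_pre_sus * np.maximum(sus, 0.0))

    mode = condition.mode
    if mode == "PSP":
        center = bp.a_center_mv * gate * cd * lc / den
        tr_term = sd * w.w_post_trans * trans
        su_term = sd * w.w_post_sus * sus
        v = np.clip(center - tr_term - su_term, -params.clip_mv, params.clip_mv)
        return Timecourse(t, v, "mV", center, tr_term, su_term)
    if mode == "EPSC":
        center = -bp.a_epsc_pa * gate * cd * lc / den
        i = np.clip(center, -params.clip_pa, params.clip_pa)
        z = np.zeros_like(i)
        return Timecourse(t, i, "pA", center, z, z)
    if mode == "IPSC":
        # direct wide-field GABA_A inhibition (outward, positive at E_cation)
        f_t = bp.f_transient
        trans_blocked = "gabazine" in condition.drugs or "TTX" in condition.drugs or (
            condition.genotype == "nNOS_ablated" and float(bg) == 500.0
        )
        sus_blocked = "gabazine" in condition.drugs or "HEPES" in condition.drugs
        tr_term = (0.0 if trans_blocked else bp.a_ipsc_pa * sd * f_t) * trans
        su_term = (0.0 if sus_blocked else bp.a_ipsc_pa * sd * (1.0 - f_t)) * sus
        gly = 0.0
        if (
            float(bg) == 25000.0
            and "strychnine" not in condition.drugs
            and bp.glycine_gain_pa > 0.0
        ):
            gly = bp.glycine_gain_pa * glycine_drive(epoch, params)
        center = gly * np.maximum(lc, 0.0)
        i = np.clip(center + tr_term + su_term, -params.clip_pa, params.clip_pa)
        return Timecourse(t, i, "pA", center, tr_term, su_term)
    if mode == "spikes":
        center = gate * cd * lc / den
        tr_term = sd * w.w_post_trans * trans
        su_term = sd * w.w_post_sus * sus
        drive = center - tr_term - su_term
        rate = params.rate_base_hz + params.rate_gain_hz * np.maximum(drive, 0.0)
        return Timecourse(t, drive, "drive", center, tr_term, su_term, rate_hz=rate)
    raise ValueError(f"unsupported mode {mode!r}")


# ----------------------------------------------------------------------- noise

@lru_cache(maxsize=8)
def _noise_filter(fs: float, bw: float) -> tuple:
    b, a = _signal.butter(2, bw / (fs / 2.0))
    # empirical gain so filtered unit-variance white noise has unit sd
    probe = _signal.filtfilt(b, a, np.random.default_rng(0).standard_normal(200_000))
    return b, a, float(probe.std())


def _filtered_noise(rng: np.random.Generator, n: int, fs: float, bw: float) -> np.ndarray:
    b, a, gain = _noise_filter(fs, bw)
    pad = int(round(0.1 * fs))  # crop filter edge transients
    raw = _signal.filtfilt(b, a, rng.standard_normal(n + 2 * pad))
    return raw[pad : pad + n] / gain


def _key(s: object) -> int:
    return zlib.crc32(str(s).encode()) & 0x7FFFFFFF


def _stream(seed: int, *tags: object) -> np.random.Generator:
    """Counter-based substream: reproducible independently of simulation order."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_key(t) for t in tags))
    )


def _lognormal_gain(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    s2 = np.log1p(cv ** 2)
    return float(rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2)))


def cell_gain(params: CircuitParams, cell_id: object, seed: int) -> float:
    """Across-cell multiplicative gain, drawn once per cell (lognormal, mean 1)."""
    return _lognormal_gain(_stream(seed, "cellgain", cell_id), params.cell_cv)


# ------------------------------------------------------------------ simulation

def simulate_trace(
    epoch: StimulusEpoch,
    condition: Condition,
    params: CircuitParams,
    cell_id: object = 0,
    trial: int = 0,
    seed: int = 0,
    fs_hz: float = DEFAULT_FS_HZ,
    _timecourse: Timecourse | None = None,
) -> Trace:
    """One noisy trial: noiseless timecourse x cell gain x trial gain + recording noise."""
    tc = _timecourse or response_timecourse(epoch, condition, params, fs_hz)
    g_cell = cell_gain(params, cell_id, seed)
    rng = _stream(seed, "trial", cell_id, epoch.label, trial)
    g_trial = _lognormal_gain(rng, params.trial_cv)
    sd = params.noise_sd_mv if condition.mode == "PSP" else params.noise_sd_pa
    noise = sd * _filtered_noise(rng, tc.values.size, fs_hz, params.noise_bw_hz)
    values = tc.values * (g_cell * g_trial) + noise
    return Trace(
        values=values, fs_hz=fs_hz, units=tc.units, epoch=epoch,
        cell_id=str(cell_id), trial=trial, seed=seed,
        meta={"condition": condition.label},
    )


def simulate_trialset(
    epoch: StimulusEpoch,
    condition: Condition,
    params: CircuitParams,
    cell_id: object = 0,
    n_trials: int = 4,
    seed: int = 0,
    fs_hz: float = DEFAULT_FS_HZ,
) -> TrialSet:
    """The n-trial bundle (default 4) for one (cell, stimulus, condition)."""
    tc = response_timecourse(epoch, condition, params, fs_hz)
    rows = [
        simulate_trace(
            epoch, condition, params, cell_id, trial, seed, fs_hz, _timecourse=tc
        ).values
        for trial in range(n_trials)
    ]
    return TrialSet(
        traces=np.vstack(rows), fs_hz=fs_hz, units=tc.units, epoch=epoch,
        cell_id=str(cell_id), condition=condition, seed=seed,
    )


def simulate_spikes(
    epoch: StimulusEpoch,
    condition: Condition,
    params: CircuitParams,
    cell_id: object = 0,
    n_trials: int = 4,
    seed: int = 0,
    fs_hz: float = DEFAULT_FS_HZ,
) -> SpikeTrialSet:
    """Inhomogeneous-Poisson spike trains for an s-ONalpha RGC.

    Rate = ``rate_base + rate_gain * rectify(drive)``; the per-cell gain
    multiplies the driven part of the rate.
    """
    if condition.cell != "sONalpha":
        raise ValueError("spike simulation requires cell='sONalpha'")
    tc = response_timecourse(epoch, condition, params, fs_hz)
    g_cell = cell_gain(params, cell_id, seed)
    rate = params.rate_base_hz + g_cell * (tc.rate_hz - params.rate_base_hz)
    dt = 1.0 / fs_hz
    trains = []
    for trial in range(n_trials):
        rng = _stream(seed, "spikes", cell_id, epoch.label, trial)
        hits = rng.random(rate.size) < rate * dt
        trains.append(tc.times[hits])
    return SpikeTrialSet(
        spike_times=trains, epoch=epoch, cell_id=str(cell_id),
        condition=condition, seed=seed,
    )


def simulate_population(
    protocol: Sequence[StimulusEpoch],
    condition: Condition,
    params: CircuitParams,
    n_cells: int,
    n_trials: int = 4,
    seed: int = 0,
    fs_hz: float = DEFAULT_FS_HZ,
) -> dict:
    """Simulate ``n_cells`` cells over a protocol.

    Returns ``{cell_id: {epoch.label: TrialSet-or-SpikeTrialSet}}``; per-cell
    gains are drawn once per cell.  Timecourses are shared across cells and
    trials (the model is multiplicative in gain), so the cost is one
    noiseless solve per epoch plus noise per trial.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    out: dict = {}
    spikes = condition.mode == "spikes"
    tcs = {e.label: response_timecourse(e, condition, params, fs_hz) for e in protocol}
    for ci in range(n_cells):
        cell_id = f"cell{ci:02d}"
        per_cell = {}
        for e in protocol:
            if spikes:
                per_cell[e.label] = simulate_spikes(
                    e, condition, params, cell_id, n_trials, seed, fs_hz
                )
            else:
                tc = tcs[e.label]
                rows = [
                    simulate_trace(
                        e, condition, params, cell_id, tr, seed, fs_hz, _timecourse=tc
                    ).values
                    for tr in range(n_trials)
                ]
                per_cell[e.label] = TrialSet(
                    traces=np.vstack(rows), fs_hz=fs_hz, units=tc.units, epoch=e,
                    cell_id=cell_id, condition=condition, seed=seed,
                )
        out[cell_id] = per_cell
    return out
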