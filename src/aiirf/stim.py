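"""Visual stimulus protocols for receptive-field mapping.

Builds machine-readable epoch lists for the four stimulus classes used to
probe center-surround organization in the inner retina:

* spots of varying diameter (size-tuning / surround suppression),
* annuli that drive the surround in isolation,
* spots whose Weber contrast is modulated sinusoidally in time
  (rectification measurements), and
* narrow bars stepped across the field (receptive-field centering).

All geometry is cell-centered: the receptive-field center sits at the
origin and bar offsets are signed distances along the scanned axis.
Stimulus strength is Weber contrast ``(L_stim - L_bg) / L_bg`` atop a
steady background expressed as a photoisomerization rate (R*/rod/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StimulusEpoch",
    "DEFAULT_DIAMETERS_UM",
    "FRAME_RATE_HZ",
    "ROD_COLLECTING_AREA_UM2",
    "make_spot_protocol",
    "make_annulus_protocol",
    "make_sinusoid_protocol",
    "make_bar_protocol",
    "render_contrast",
]

FRAME_RATE_HZ = 60.0
#: rod collecting area used for photoisomerization-rate conversion (metadata only)
ROD_COLLECTING_AREA_UM2 = 0.85

#: default spot-diameter series, 10-1200 um.  Geometric-ish spacing with extra
#: resolution in the 88-150 um range so the smallest-spot-at-maximal-response
#: criterion can resolve receptive-field centers near 100 um.  The largest
#: diameter (1200 um) anchors the surround-suppression index.
DEFAULT_DIAMETERS_UM = (
    10.0, 30.0, 60.0, 88.0, 100.0, 115.0, 132.0, 150.0,
    240.0, 325.0, 450.0, 600.0, 850.0, 1200.0,
)

_SHAPES = ("spot", "annulus", "bar", "uniform")
_MODULATIONS = ("step", "sinusoid")


@dataclass
class StimulusEpoch:
    """One presented stimulus: geometry, contrast, background and timing."""

    shape: str
    contrast: float
    background_rstar: float
    diameter_um: float | None = None
    inner_um: float | None = None
    outer_um: float | None = None
    bar_w_um: float | None = None
    bar_l_um: float | None = None
    offset_um: float = 0.0
    bar_axis: str = "horizontal"
    t_pre_s: float = 0.5
    t_stim_s: float = 0.5
    t_post_s: float = 1.0
    modulation: str = "step"
    freq_hz: float | None = None
    frame_hz: float = FRAME_RATE_HZ
    frame_quantize: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown stimulus shape {self.shape!r}")
        if self.modulation not in _MODULATIONS:
            raise ValueError(f"unknown modulation {self.modulation!r}")
        for name in ("t_pre_s", "t_stim_s", "t_post_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.contrast < -1.0:
            raise ValueError(
                "Weber contrast cannot be below -1 (cannot darken below zero luminance)"
            )
        if self.background_rstar <= 0:
            raise ValueError("background photoisomerization rate must be > 0")
        if self.shape == "spot":
            if self.diameter_um is None or self.diameter_um <= 0:
                raise ValueError("spot epochs require diameter_um > 0")
        if self.shape == "annulus":
            if self.inner_um is None or self.outer_um is None:
                raise ValueError("annulus epochs require inner_um and outer_um")
            if not 0 <= self.inner_um < self.outer_um:
                raise ValueError("annulus requires 0 <= inner_um < outer_um")
        if self.shape == "bar":
            if not (self.bar_w_um and self.bar_l_um):
                raise ValueError("bar epochs require bar_w_um and bar_l_um > 0")
            if self.bar_axis not in ("horizontal", "vertical"):
                raise ValueError("bar_axis must be 'horizontal' or 'vertical'")
        if self.modulation == "sinusoid":
            if self.freq_hz is None or self.freq_hz <= 0:
                raise ValueError("sinusoid epochs require freq_hz > 0")
            if self.freq_hz > self.frame_hz / 2:
                raise ValueError(
                    f"freq_hz={self.freq_hz} exceeds the Nyquist limit of the "
                    f"{self.frame_hz:g} Hz frame rate"
                )
            n_cycles = self.t_stim_s * self.freq_hz
            if abs(n_cycles - round(n_cycles)) > 1e-9:
                raise ValueError("sinusoid epochs must contain an integer number of cycles")

    # ------------------------------------------------------------------ timing
    @property
    def total_s(self) -> float:
        return self.t_pre_s + self.t_stim_s + self.t_post_s

    @property
    def stim_window(self) -> tuple[float, float]:
        """(start, end) of the stimulus interval in seconds."""
        return (self.t_pre_s, self.t_pre_s + self.t_stim_s)

    @property
    def label(self) -> str:
        if self.shape == "spot":
            geom = f"d{self.diameter_um:g}"
        elif self.shape == "annulus":
            geom = f"ann{self.inner_um:g}-{self.outer_um:g}"
        elif self.shape == "bar":
            geom = f"bar{self.bar_axis[0]}{self.offset_um:+g}"
        else:
            geom = "uniform"
        mod = f"_sin{self.freq_hz:g}Hz" if self.modulation == "sinusoid" else ""
        return f"{self.shape}_{geom}_c{self.contrast:+g}_bg{self.background_rstar:g}{mod}"

    # --------------------------------------------------------------- serialize
    def to_dict(self) -> dict:
        d = asdict(self)
        d = {k: v for k, v in d.items() if v is not None and v != {}}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusEpoch":
        return cls(**d)


def _as_positive_list(values: Iterable[float], what: str) -> list[float]:
    out = [float(v) for v in values]
    if not out:
        raise ValueError(f"{what} list must be non-empty")
    if any(v <= 0 for v in out):
        raise ValueError(f"all {what} values must be > 0")
    return out


def _shuffle(epochs: list[StimulusEpoch], seed: int | None) -> list[StimulusEpoch]:
    """Pseudorandomize presentation order; the seed is recorded per epoch."""
    if seed is None:
        return epochs
    order = np.random.default_rng(seed).permutation(len(epochs))
    for e in epochs:
        e.meta["order_seed"] = int(seed)
    return [epochs[i] for i in order]


def make_spot_protocol(
    diameters_um: Sequence[float] = DEFAULT_DIAMETERS_UM,
    contrast: float = 1.0,
    background_rstar: float = 500.0,
    t_pre_s: float = 0.5,
    t_stim_s: float = 0.5,
    t_post_s: float = 1.0,
    order_seed: int | None = None,
) -> list[StimulusEpoch]:
    """Spot-diameter series characterizing center-surround organization.

    One epoch per diameter; the presentation order is pseudorandomized when
    ``order_seed`` is given.  Include 1200 um whenever the protocol will feed
    a surround-suppression index.
    """
    diameters = _as_positive_list(diameters_um, "diameter")
    epochs = [
        StimulusEpoch(
            shape="spot", diameter_um=d, contrast=contrast,
            background_rstar=background_rstar,
            t_pre_s=t_pre_s, t_stim_s=t_stim_s, t_post_s=t_post_s,
        )
        for d in diameters
    ]
    return _shuffle(epochs, order_seed)


def make_annulus_protocol(
    contrasts: Sequence[float] = (1.0,),
    background_rstar: float = 500.0,
    inner_um: float = 250.0,
    outer_um: float = 1000.0,
    t_pre_s: float = 0.5,
    t_stim_s: float = 0.5,
    t_post_s: float = 1.0,
    order_seed: int | None = None,
) -> list[StimulusEpoch]:
    """Annular stimuli (default 250 um inner / 1000 um outer diameter).

    Annuli drive the surround in isolation; negative contrasts probe the
    polarity of surround mechanisms.
    """
    contrasts = [float(c) for c in contrasts]
    if not contrasts:
        raise ValueError("contrast list must be non-empty")
    if any(c < -1.0 or c > 3.0 for c in contrasts):
        raise ValueError("annulus contrasts must lie within [-1, +3]")
    epochs = [
        StimulusEpoch(
            shape="annulus", contrast=c, inner_um=inner_um, outer_um=outer_um,
            background_rstar=background_rstar,
            t_pre_s=t_pre_s, t_stim_s=t_stim_s, t_post_s=t_post_s,
        )
        for c in contrasts
    ]
    return _shuffle(epochs, order_seed)


def make_sinusoid_protocol(
    freqs_hz: Sequence[float],
    diameters_um: Sequence[float] = (100.0, 1000.0),
    background_rstar: float = 500.0,
    contrast: float = 1.0,
    n_cycles: int | None = None,
    flank_s: float = 0.5,
    order_seed: int | None = None,
) -> list[StimulusEpoch]:
    """Sinusoidally contrast-modulated spots (Cartesian product freqs x diameters).

    Each epoch lasts an integer number of cycles (default 4) with ``flank_s``
    pre/post flanks at the background.  Frequencies must stay below the 30 Hz
    Nyquist limit of the 60 Hz projector frame rate.
    """
    freqs = [float(f) for f in freqs_hz]
    if not freqs:
        raise ValueError("frequency list must be non-empty")
    if any(f <= 0 or f > FRAME_RATE_HZ / 2 for f in freqs):
        raise ValueError("frequencies must lie in (0, 30] Hz (projector Nyquist)")
    diameters = _as_positive_list(diameters_um, "diameter")
    epochs = []
    for f in freqs:
        cyc = n_cycles if n_cycles is not None else 4
        for d in diameters:
            epochs.append(
                StimulusEpoch(
                    shape="spot", diameter_um=d, contrast=contrast,
                    background_rstar=background_rstar,
                    modulation="sinusoid", freq_hz=f,
                    t_pre_s=flank_s, t_stim_s=cyc / f, t_post_s=flank_s,
                )
            )
    return _shuffle(epochs, order_seed)


def make_bar_protocol(
    axis: str = "horizontal",
    spacing_um: float = 20.0,
    n_positions: int = 11,
    bar_w_um: float = 50.0,
    bar_l_um: float = 500.0,
    contrast: float = 1.0,
    background_rstar: float = 500.0,
    order_seed: int | None = None,
) -> list[StimulusEpoch]:
    """Bars stepped across one axis, symmetric about the origin.

    ``n_positions`` must be odd so the series is centered; with the default
    20 um spacing and 11 positions the offsets run -100 ... +100 um.
    """
    if spacing_um <= 0:
        raise ValueError("spacing_um must be > 0")
    if n_positions < 1 or n_positions % 2 == 0:
        raise ValueError("n_positions must be odd (series centered on the origin)")
    half = n_positions // 2
    offsets = [spacing_um * k for k in range(-half, half + 1)]
    epochs = [
        StimulusEpoch(
            shape="bar", bar_axis=axis, offset_um=off,
            bar_w_um=bar_w_um, bar_l_um=bar_l_um,
            contrast=contrast, background_rstar=background_rstar,
        )
        for off in offsets
    ]
    return _shuffle(epochs, order_seed)


def render_contrast(epoch: StimulusEpoch, t: float | np.ndarray) -> np.ndarray | float:
    """Weber contrast delivered by ``epoch`` at time ``t`` (seconds from epoch start).

    Zero outside the stimulus window.  For step epochs the epoch contrast is
    held through the window; for sinusoid epochs the contrast follows
    ``contrast * sin(2*pi*f*(t - t_pre))``, optionally sample-and-held at the
    projector frame rate when ``epoch.frame_quantize`` is set.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -1e-12) or np.any(t_arr > epoch.total_s + 1e-12):
        raise ValueError("t outside the epoch duration")
    t0, t1 = epoch.stim_window
    inside = (t_arr >= t0) & (t_arr < t1)
    if epoch.modulation == "step":
        out = np.where(inside, epoch.contrast, 0.0)
    else:
        phase_t = t_arr - t0
        if epoch.frame_quantize:
            phase_t = np.floor(phase_t * epoch.frame_hz) / epoch.frame_hz
        out = np.where(
            inside, epoch.contrast * np.sin(2 * math.pi * epoch.freq_hz * phase_t), 0.0
        )
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out
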