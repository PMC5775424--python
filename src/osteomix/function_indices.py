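"""Per-cell functional statistics: bone-resorbing and deformation indices.

The bone-resorbing index (BRI) quantifies proton secretion by
osteoclasts carrying a pH-sensitive probe: the mean probe fluorescence
inside the osteoclast (mOC) mask (signal) divided by the mean outside
(noise).  BRI = 1 means no local acidification; resorbing cells push it
above 1.  Time courses are sampled at the movie's frame interval
(5 min in the reference acquisition) and summarized by a windowed mean,
conventionally over 4 h ("4h-BRI").

The cell deformation index (CDI) is a motility proxy: the area changed
between two masks 10 min apart, divided by the area at the interval
start.  "Changed" defaults to the symmetric difference (lost + gained
pixels), the only convention that is zero iff the shapes are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_core import BinaryMask, Channel, ChannelImage, otsu_threshold, binarize

__all__ = [
    "BRISample",
    "BRISeries",
    "CDIResult",
    "compute_bri",
    "bri_series",
    "window_mean_bri",
    "compute_cdi",
]


@dataclass(frozen=True)
class BRISample:
    """One frame's resorption signal-to-noise ratio."""

    t_min: float
    signal: float   # mean probe intensity inside the mOC mask
    noise: float    # mean probe intensity outside
    bri: float

    def __post_init__(self) -> None:
        if self.noise <= 0:
            raise ValueError("noise mean must be positive")


@dataclass(frozen=True)
class BRISeries:
    samples: tuple[BRISample, ...]
    frame_interval_min: float

    def __post_init__(self) -> None:
        ts = np.array([s.t_min for s in self.samples])
        if len(ts) > 1:
            steps = np.diff(ts)
            if np.any(steps <= 0) or not np.allclose(steps, self.frame_interval_min):
                raise ValueError("samples must be uniformly spaced and increasing")

    @property
    def t_min(self) -> np.ndarray:
        return np.array([s.t_min for s in self.samples])

    @property
    def bri(self) -> np.ndarray:
        return np.array([s.bri for s in self.samples])


@dataclass(frozen=True)
class CDIResult:
    t0_min: float
    t1_min: float
    changed_area_px: int
    total_area_t0_px: int
    cdi: float


def compute_bri(probe: ChannelImage, moc_mask: BinaryMask,
                t_min: float = 0.0) -> BRISample:
    """Signal-to-noise of the pH probe over the osteoclast mask.

    Signal is the mean probe intensity over mask-true pixels, noise the
    mean over mask-false pixels; BRI is their ratio.  Invariant to
    rescaling the probe image by any positive constant.
    """
    px = np.asarray(probe.pixels, dtype=float)
    bits = moc_mask.bits
    if px.shape != bits.shape:
        raise ValueError("probe image and mOC mask must share shape")
    n_in = int(np.count_nonzero(bits))
    if n_in == 0 or n_in == bits.size:
        raise ValueError("mask must contain both inside and outside pixels")
    signal = float(px[bits].mean())
    noise = float(px[~bits].mean())
    if noise == 0:
        raise ZeroDivisionError("mean intensity outside the mask is zero")
    return BRISample(t_min=t_min, signal=signal, noise=noise, bri=signal / noise)


def bri_series(
    movie: list[tuple[ChannelImage, BinaryMask]],
    frame_interval_min: float = 5.0,
) -> BRISeries:
    """Per-frame BRI over a time-ordered (probe, mOC-mask) movie."""
    if not movie:
        raise ValueError("empty movie")
    samples = []
    for i, (probe, mask) in enumerate(movie):
        try:
            samples.append(compute_bri(probe, mask, t_min=i * frame_interval_min))
        except (ValueError, ZeroDivisionError) as exc:
            raise ValueError(f"frame {i}: {exc}") from exc
    return BRISeries(tuple(samples), frame_interval_min)


def bri_series_from_images(
    probes: list[ChannelImage],
    red_channels: list[ChannelImage],
    frame_interval_min: float = 5.0,
) -> BRISeries:
    """BRI series with per-frame Otsu-extracted mOC masks from the red channel."""
    movie = []
    for probe, red in zip(probes, red_channels, strict=True):
        mask = binarize(red, otsu_threshold(red))
        movie.append((probe, mask))
    return bri_series(movie, frame_interval_min)


def window_mean_bri(series: BRISeries, window_min: float = 240.0) -> float:
    """Mean BRI over t ∈ [0, window_min], both endpoints included.

    A 4-hour window at 5-min sampling therefore averages 49 samples.
    """
    ts = series.t_min
    if ts[-1] < window_min:
        raise ValueError(
            f"series spans {ts[-1]} min, shorter than the {window_min} min window")
    sel = (ts >= 0) & (ts <= window_min)
    return float(series.bri[sel].mean())


def compute_cdi(mask_t0: BinaryMask, mask_t1: BinaryMask,
                t0_min: float = 0.0, t1_min: float = 10.0,
                mode: str = "symmetric") -> CDIResult:
    """Area changed between two frames over the area at the first frame.

    *mode* selects what counts as change: ``symmetric`` (lost + gained,
    default) or ``gained_only``.
    """
    if mask_t0.shape != mask_t1.shape:
        raise ValueError("masks must share shape")
    a0, a1 = mask_t0.bits, mask_t1.bits
    total0 = int(np.count_nonzero(a0))
    if total0 == 0:
        raise ValueError("mask at t0 is empty: CDI undefined")
    if mode == "symmetric":
        changed = int(np.count_nonzero(a0 ^ a1))
    elif mode == "gained_only":
        changed = int(np.count_nonzero(a1 & ~a0))
    else:
        raise ValueError(f"unknown CDI mode {mode!r}")
    return CDIResult(t0_min=t0_min, t1_min=t1_min,
                     changed_area_px=changed, total_area_t0_px=total0,
                     cdi=changed / total0)


def cdi_series(masks: list[BinaryMask], interval_min: float = 10.0,
               mode: str = "symmetric") -> list[CDIResult]:
    """CDI for every consecutive pair in a mask sequence."""
    out = []
    for i in range(len(masks) - 1):
        out.append(compute_cdi(masks[i], masks[i + 1],
                               t0_min=i * interval_min,
                               t1_min=(i + 1) * interval_min, mode=mode))
    return out
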