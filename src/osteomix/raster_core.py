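"""Image I/O, automatic thresholding, mask cleanup and downscaling.

Every downstream statistic (cell mixture index, bone-resorbing index,
contact detection) starts from binary masks of the two fluorescence
channels: cyan (mature osteoblasts, mOBs) and red (mature osteoclasts,
mOCs).  This module produces those masks: Otsu binarization with
per-channel thresholds, removal of sub-cellular specks below a physical
area, and block-majority downscaling that trades resolution for
clustering speed.

Coordinates are 0-based ``(row, col)`` with row increasing downward.
Pixel size is carried on every image/mask so that area thresholds given
in µm² convert to pixel counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml
from scipy import ndimage
from skimage.measure import block_reduce

__all__ = [
    "Channel",
    "ChannelImage",
    "BinaryMask",
    "RasterConfig",
    "otsu_threshold",
    "binarize",
    "remove_small_components",
    "downscale_mask",
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
]


class Channel(enum.Enum):
    """Fluorescence channel identity."""

    MOB_CYAN = "mOB_cyan"
    MOC_RED = "mOC_red"
    PH_PROBE = "pH_probe"
    SHG = "SHG"


class DegenerateHistogramError(ValueError):
    """Raised when a channel image has a single intensity value."""


class EmptyForegroundError(ValueError):
    """Raised when a channel has no foreground after binarization/cleanup."""


@dataclass(frozen=True)
class ChannelImage:
    """A single-channel intensity raster (2D MIP or 3D stack).

    Parameters
    ----------
    pixels
        Non-negative intensity grid, ``(rows, cols)`` or ``(z, rows, cols)``.
    channel
        Which fluorophore/modality the grid records.
    pixel_size_um
        Edge length of one pixel in µm (in-plane).
    voxel_depth_um
        Slice spacing in µm; only meaningful for 3D stacks.
    """

    pixels: np.ndarray
    channel: Channel
    pixel_size_um: float = 1.0
    voxel_depth_um: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or min(px.shape) < 1:
            raise ValueError(f"expected 2D/3D grid, got shape {px.shape}")
        if np.issubdtype(px.dtype, np.floating) and np.any(px < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0 or self.voxel_depth_um <= 0:
            raise ValueError("pixel/voxel sizes must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """Boolean foreground mask sharing geometry with its source image."""

    bits: np.ndarray
    channel: Channel
    pixel_size_um: float = 1.0
    voxel_depth_um: float = 1.0

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=bool)
        if bits.ndim not in (2, 3):
            raise ValueError(f"expected 2D/3D mask, got shape {bits.shape}")
        if self.pixel_size_um <= 0 or self.voxel_depth_um <= 0:
            raise ValueError("pixel/voxel sizes must be positive")
        object.__setattr__(self, "bits", bits)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.bits.shape

    @property
    def area_um2(self) -> float:
        """Foreground area in µm² (2D masks)."""
        return float(np.count_nonzero(self.bits)) * self.pixel_size_um**2

    @property
    def volume_um3(self) -> float:
        """Foreground volume in µm³ (3D masks)."""
        return (
            float(np.count_nonzero(self.bits))
            * self.pixel_size_um**2
            * self.voxel_depth_um
        )


@dataclass
class RasterConfig:
    """Mask-extraction parameters.

    ``min_area_um2`` holds the inclusive exclusion thresholds: connected
    components whose area is ≤ the value are discarded (5 µm² for the
    cyan channel, 10 µm² for red by default).  ``downscale_factor`` is
    1/k with k an integer; valid range [1/16, 1].
    """

    pixel_size_um: float = 1.0
    voxel_depth_um: float = 1.0
    min_area_um2: dict = field(default_factory=lambda: {"cyan": 5.0, "red": 10.0})
    downscale_factor: float = 0.25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RasterConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in
                 ("pixel_size_um", "voxel_depth_um", "min_area_um2",
                  "downscale_factor") if k in raw}
        return cls(**known)


def otsu_threshold(image: ChannelImage) -> int:
    """Between-class-variance-maximizing intensity threshold.

    Operates on the integer histogram of the image; the returned value
    ``t`` is the cut such that background is ``intensity <= t`` and
    foreground ``intensity > t``.  Among ties the lowest maximizer is
    returned, making the result deterministic.

    Raises
    ------
    DegenerateHistogramError
        If the image holds a single intensity value (no cut can separate
        two classes).
    """
    px = np.asarray(image.pixels)
    if np.issubdtype(px.dtype, np.floating):
        px = np.round(px).astype(np.int64)
    flat = px.ravel().astype(np.int64)
    lo, hi = int(flat.min()), int(flat.max())
    if lo == hi:
        raise DegenerateHistogramError(
            f"channel {image.channel.value}: constant image (all {lo}), "
            "Otsu threshold undefined"
        )
    hist = np.bincount(flat - lo, minlength=hi - lo + 1).astype(np.float64)
    levels = np.arange(lo, hi + 1, dtype=np.float64)
    w0 = np.cumsum(hist)  # background weight for cut at each level
    w1 = w0[-1] - w0
    s0 = np.cumsum(hist * levels)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = s0 / w0
        mu1 = (s0[-1] - s0) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[~np.isfinite(var_between)] = -np.inf
    # last cut leaves an empty foreground class; never a valid threshold
    var_between[-1] = -np.inf
    return int(levels[int(np.argmax(var_between))])


def binarize(image: ChannelImage, threshold: float) -> BinaryMask:
    """Foreground = pixels with intensity strictly above *threshold*."""
    return BinaryMask(
        bits=np.asarray(image.pixels) > threshold,
        channel=image.channel,
        pixel_size_um=image.pixel_size_um,
        voxel_depth_um=image.voxel_depth_um,
    )


# 8-connectivity in 2D, 26-connectivity in 3D
def _full_structure(ndim: int) -> np.ndarray:
    return np.ones((3,) * ndim, dtype=bool)


def remove_small_components(mask: BinaryMask, max_excluded_area_um2: float) -> BinaryMask:
    """Drop 8-connected components with area ≤ *max_excluded_area_um2*.

    The exclusion is inclusive: a component whose area equals the
    threshold exactly is removed.  Components strictly larger survive
    unchanged, so the operation is idempotent.
    """
    if max_excluded_area_um2 <= 0:
        raise ValueError("max_excluded_area_um2 must be positive")
    if mask.bits.ndim != 2:
        raise ValueError("small-component removal is defined for 2D masks")
    labels, n = ndimage.label(mask.bits, structure=_full_structure(2))
    if n == 0:
        return mask
    px_area = mask.pixel_size_um**2
    counts = np.bincount(labels.ravel())  # counts[0] is background
    keep = counts * px_area > max_excluded_area_um2
    keep[0] = False
    return replace(mask, bits=keep[labels])


def downscale_mask(mask: BinaryMask, factor: float) -> BinaryMask:
    """Block-majority reduction by an integer factor ``1/k``.

    Each k×k block maps to one output pixel which is true iff at least
    half the block (after zero-padding to a multiple of k) is true.
    ``pixel_size_um`` scales by k so physical areas stay comparable.
    """
    if not (1 / 16 - 1e-12 <= factor <= 1 + 1e-12):
        raise ValueError(f"downscale factor {factor} outside [1/16, 1]")
    k = round(1 / factor)
    if abs(1 / k - factor) > 1e-9:
        raise ValueError(f"downscale factor must be 1/k for integer k, got {factor}")
    if k == 1:
        return mask
    frac = block_reduce(mask.bits.astype(np.float64), (k,) * mask.bits.ndim, np.mean)
    return replace(mask, bits=frac >= 0.5, pixel_size_um=mask.pixel_size_um * k)


def extract_channel_mask(
    image: ChannelImage,
    min_excluded_area_um2: float,
    downscale_factor: float = 0.25,
    threshold: float | None = None,
) -> tuple[BinaryMask, dict]:
    """Full Step-1 chain: threshold → binarize → size filter → downscale.

    Returns the mask plus a provenance dict recording the threshold used
    and how much foreground the size filter removed.  Size filtering runs
    at native resolution, where the µm² thresholds are meaningful.
    """
    if threshold is None:
        threshold = otsu_threshold(image)
    raw = binarize(image, threshold)
    cleaned = remove_small_components(raw, min_excluded_area_um2)
    out = downscale_mask(cleaned, downscale_factor)
    prov = {
        "channel": image.channel.value,
        "threshold": float(threshold),
        "raw_area_um2": raw.area_um2,
        "removed_area_um2": raw.area_um2 - cleaned.area_um2,
        "downscale_factor": downscale_factor,
    }
    return out, prov


# ---------------------------------------------------------------------------
# I/O: 8/16-bit grayscale TIFF (single- and multi-page) and PNG

def read_image(
    path: str | Path,
    channel: Channel,
    pixel_size_um: float = 1.0,
    voxel_depth_um: float = 1.0,
) -> ChannelImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    data = np.squeeze(np.asarray(data))
    if data.ndim == 3 and data.shape[-1] in (3, 4) and path.suffix.lower() == ".png":
        raise ValueError(f"{path}: expected grayscale, got {data.shape[-1]}-channel PNG")
    return ChannelImage(data, channel, pixel_size_um, voxel_depth_um)


def write_image(path: str | Path, image: ChannelImage) -> None:
    path = Path(path)
    data = np.asarray(image.pixels)
    if np.issubdtype(data.dtype, np.floating):
        data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Save as 0/255 8-bit raster (PNG or TIFF)."""
    data = np.where(mask.bits, 255, 0).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def read_mask(
    path: str | Path,
    channel: Channel,
    pixel_size_um: float = 1.0,
    voxel_depth_um: float = 1.0,
) -> BinaryMask:
    img = read_image(path, channel, pixel_size_um, voxel_depth_um)
    return BinaryMask(img.pixels > 0, channel, pixel_size_um, voxel_depth_um)
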