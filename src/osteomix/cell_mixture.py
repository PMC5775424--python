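"""Cell Mixture Index (CMI): spatial mixing of two cell populations.

Foreground pixels of the cyan (mOB) and red (mOC) masks are clustered
hierarchically on their coordinates alone (Ward linkage, color-blind).
Cutting the dendrogram into m clusters and measuring, per cluster, the
Gini-like impurity

    I_c = 1 - (Y_c**2 + R_c**2) / (Y_c + R_c)**2

gives the weighted-average impurity

    GLI(C_m) = sum_i ((Y_i + R_i) / N) * I_i,

a non-increasing function of m that is 0.5 when every cluster is an
even two-color mix and 0 when every cluster is pure.  The CMI is the
normalized log-weighted area under this curve:

    CMI = 2 / log2(N + 1) * sum_{m=1..N} log2((m + 1) / m) * GLI(C_m)

which lies in [0, 1]: 0 for fully segregated single-color colonies,
approaching 1 for maximally interleaved populations.  A power-of-two
approximation evaluates GLI only at m = 1, 2, 4, ..., 2**N' (N' the
largest integer with 2**N' <= N) and averages:

    CMI_approx = 2 / (N' + 1) * sum_j GLI(C_{2**j}).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage

from .raster_core import (
    BinaryMask,
    ChannelImage,
    EmptyForegroundError,
    extract_channel_mask,
)

__all__ = [
    "PixelColor",
    "LabeledPixelSet",
    "ClusterTree",
    "ClusterSet",
    "GLICurve",
    "CMIResult",
    "CMIConfig",
    "extract_labeled_pixels",
    "build_cluster_tree",
    "partition_at",
    "cluster_impurity",
    "gli",
    "gli_curve",
    "cmi_exact",
    "cmi_approx",
    "compute_cmi",
]


class PixelColor(enum.IntEnum):
    CYAN = 0
    RED = 1


class Schedule(str, enum.Enum):
    FULL = "full"
    POWERS_OF_TWO = "powers_of_two"


@dataclass(frozen=True)
class LabeledPixelSet:
    """Foreground pixel coordinates, each tagged cyan or red."""

    coords: np.ndarray   # (N, 2) float array of (row, col)
    colors: np.ndarray   # (N,) PixelColor values

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        colors = np.asarray(self.colors, dtype=np.int8)
        if coords.shape[0] != colors.shape[0]:
            raise ValueError("coords and colors must be parallel")
        if coords.shape[0] < 1:
            raise EmptyForegroundError("labeled pixel set is empty")
        if len(np.unique(coords, axis=0)) != coords.shape[0]:
            raise ValueError("pixel coordinates must be unique")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "colors", colors)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def y_total(self) -> int:
        return int(np.count_nonzero(self.colors == PixelColor.CYAN))

    @property
    def r_total(self) -> int:
        return int(np.count_nonzero(self.colors == PixelColor.RED))


@dataclass(frozen=True)
class ClusterTree:
    """Ward dendrogram over a pixel set (scipy linkage encoding)."""

    merges: np.ndarray  # (N-1, 4) scipy linkage matrix
    n_leaves: int

    def __post_init__(self) -> None:
        if self.merges.shape != (self.n_leaves - 1, 4):
            raise ValueError("linkage matrix must have N-1 rows")


@dataclass(frozen=True)
class ClusterSet:
    """A cut of the tree into m clusters with per-cluster color counts."""

    m: int
    labels: np.ndarray        # (N,) cluster index per pixel, in [0, m)
    y_counts: np.ndarray      # (m,) cyan pixels per cluster
    r_counts: np.ndarray      # (m,) red pixels per cluster

    @property
    def n(self) -> int:
        return int(self.y_counts.sum() + self.r_counts.sum())


@dataclass(frozen=True)
class GLICurve:
    """GLI as a function of cluster count m."""

    ms: np.ndarray        # cluster counts, increasing
    values: np.ndarray    # GLI(C_m), parallel to ms
    schedule: Schedule

    def value_at(self, m: int) -> float:
        idx = np.searchsorted(self.ms, m)
        if idx >= len(self.ms) or self.ms[idx] != m:
            raise ValueError(f"curve has no entry at m={m}")
        return float(self.values[idx])


@dataclass(frozen=True)
class CMIResult:
    cmi: float
    method: str                     # "exact" | "approx"
    n: int
    curve: GLICurve
    n_prime: int | None = None      # approx only
    areas_um2: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


@dataclass
class CMIConfig:
    """Pipeline parameters for :func:`compute_cmi`."""

    downscale_factor: float = 0.25
    min_area_um2_cyan: float = 5.0
    min_area_um2_red: float = 10.0
    method: str = "approx"          # exact feasible for N <= ~2000
    overlap_color: PixelColor = PixelColor.RED


def extract_labeled_pixels(cyan: BinaryMask, red: BinaryMask,
                           overlap_color: PixelColor = PixelColor.RED) -> LabeledPixelSet:
    """Collect foreground pixels of both masks into one labeled set.

    A pixel foreground in both channels is counted once and assigned
    *overlap_color* (red by default; overlap is rare after independent
    Otsu cuts).
    """
    if cyan.shape != red.shape:
        raise ValueError("cyan and red masks must share shape")
    both = cyan.bits | red.bits
    if not both.any():
        raise EmptyForegroundError("both masks empty: CMI undefined")
    coords = np.argwhere(both).astype(float)
    in_red = red.bits[both]
    in_cyan = cyan.bits[both]
    colors = np.where(in_red & ~in_cyan, PixelColor.RED,
                      np.where(in_cyan & ~in_red, PixelColor.CYAN,
                               overlap_color)).astype(np.int8)
    return LabeledPixelSet(coords, colors)


def build_cluster_tree(pixels: LabeledPixelSet) -> ClusterTree:
    """Ward-linkage agglomeration of pixel coordinates (color-blind)."""
    if pixels.n < 2:
        raise ValueError("need at least 2 pixels to build a cluster tree")
    merges = linkage(pixels.coords, method="ward")
    return ClusterTree(merges, pixels.n)


def partition_at(tree: ClusterTree, m: int, pixels: LabeledPixelSet) -> ClusterSet:
    """The m-cluster partition obtained by undoing the last m−1 merges."""
    n = tree.n_leaves
    if not 1 <= m <= n:
        raise ValueError(f"m={m} outside [1, {n}]")
    labels = cut_tree(tree.merges, n_clusters=m).ravel()
    y = np.bincount(labels[pixels.colors == PixelColor.CYAN], minlength=m)
    r = np.bincount(labels[pixels.colors == PixelColor.RED], minlength=m)
    return ClusterSet(m, labels, y, r)


def cluster_impurity(y_ci: int, r_ci: int) -> float:
    """Gini-like impurity of one cluster: 1 − (Y²+R²)/(Y+R)² ∈ [0, 0.5]."""
    total = y_ci + r_ci
    if total < 1:
        raise ValueError("impurity of an empty cluster is undefined")
    return 1.0 - (y_ci**2 + r_ci**2) / total**2


def gli(clusters: ClusterSet) -> float:
    """Size-weighted average impurity of a partition, in [0, 0.5]."""
    sizes = clusters.y_counts + clusters.r_counts
    n = sizes.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        imp = 1.0 - (clusters.y_counts.astype(float)**2
                     + clusters.r_counts.astype(float)**2) / sizes.astype(float)**2
    imp = np.where(sizes > 0, imp, 0.0)
    return float(np.sum(sizes / n * imp))


def _full_gli_values(tree: ClusterTree, pixels: LabeledPixelSet) -> np.ndarray:
    """GLI(C_m) for every m = 1..N, by replaying merges from singletons.

    Each merge combines two clusters; the weighted impurity updates in
    O(1), so the whole curve costs O(N) once the linkage exists.
    Returns values indexed so that out[m-1] = GLI(C_m).
    """
    n = pixels.n
    colors = pixels.colors
    # cluster id -> (Y, R); ids 0..n-1 are leaves, n.. are merge products
    y = np.zeros(2 * n - 1, dtype=np.int64)
    r = np.zeros(2 * n - 1, dtype=np.int64)
    y[:n] = colors == PixelColor.CYAN
    r[:n] = colors == PixelColor.RED

    def wimp(i: int) -> float:
        t = y[i] + r[i]
        return (t / n) * (1.0 - (y[i]**2 + r[i]**2) / t**2)

    out = np.empty(n, dtype=float)
    out[n - 1] = 0.0  # all singletons: every cluster pure
    total = 0.0
    for k in range(n - 1):
        a, b = int(tree.merges[k, 0]), int(tree.merges[k, 1])
        new = n + k
        y[new] = y[a] + y[b]
        r[new] = r[a] + r[b]
        total += wimp(new) - wimp(a) - wimp(b)
        # after k+1 merges there are n-(k+1) clusters
        out[n - k - 2] = total
    return np.maximum(out, 0.0)  # guard tiny negative rounding


def powers_of_two_schedule(n: int) -> tuple[np.ndarray, int]:
    """m' = 2^0..2^N' with N' the largest integer s.t. 2^N' <= n."""
    n_prime = int(np.floor(np.log2(n)))
    return 2 ** np.arange(n_prime + 1), n_prime


def gli_curve(tree: ClusterTree, pixels: LabeledPixelSet,
              schedule: Schedule | str = Schedule.FULL) -> GLICurve:
    """Evaluate GLI at every scheduled cluster count."""
    schedule = Schedule(schedule)
    values = _full_gli_values(tree, pixels)
    if schedule is Schedule.FULL:
        ms = np.arange(1, pixels.n + 1)
        return GLICurve(ms, values, schedule)
    ms, _ = powers_of_two_schedule(pixels.n)
    return GLICurve(ms, values[ms - 1], schedule)


def cmi_exact(curve: GLICurve, n: int) -> CMIResult:
    """Area under the GLI curve with log₂((m+1)/m) weights, normalized to [0, 1]."""
    if len(curve.ms) != n or curve.ms[0] != 1 or curve.ms[-1] != n:
        raise ValueError("exact CMI needs the full curve m = 1..N")
    m = curve.ms.astype(float)
    weights = np.log2((m + 1) / m)
    cmi = float(2.0 / np.log2(n + 1) * np.sum(weights * curve.values))
    return CMIResult(cmi=cmi, method="exact", n=n, curve=curve)


def cmi_approx(curve: GLICurve, n: int) -> CMIResult:
    """Power-of-two approximation: 2/(N'+1) · Σ_j GLI(C_{2^j})."""
    ms, n_prime = powers_of_two_schedule(n)
    if len(curve.ms) < len(ms) or not np.all(np.isin(ms, curve.ms)):
        raise ValueError("approx CMI needs entries at every power of two up to N")
    vals = np.array([curve.value_at(int(m)) for m in ms])
    cmi = float(2.0 / (n_prime + 1) * vals.sum())
    return CMIResult(cmi=cmi, method="approx", n=n, curve=curve, n_prime=n_prime)


def cmi_from_pixels(pixels: LabeledPixelSet, method: str = "approx") -> CMIResult:
    """Steps 2–4 on an already-labeled pixel set."""
    if pixels.n == 1:
        # single pixel: one pure cluster, CMI = 0 by construction
        curve = GLICurve(np.array([1]), np.array([0.0]), Schedule.FULL)
        res = CMIResult(cmi=0.0, method=method, n=1, curve=curve,
                        n_prime=0 if method == "approx" else None)
        return res
    tree = build_cluster_tree(pixels)
    if method == "exact":
        return cmi_exact(gli_curve(tree, pixels, Schedule.FULL), pixels.n)
    if method == "approx":
        return cmi_approx(gli_curve(tree, pixels, Schedule.POWERS_OF_TWO), pixels.n)
    raise ValueError(f"unknown CMI method {method!r}")


def compute_cmi(
    cyan: BinaryMask | ChannelImage,
    red: BinaryMask | ChannelImage,
    config: CMIConfig | None = None,
) -> CMIResult:
    """End-to-end CMI: Step 1 (mask extraction) through Step 4.

    Accepts either raw channel images (then Otsu thresholding, size
    filtering and downscaling run internally) or pre-binarized masks
    (then only downscaling runs).  Also reports per-channel foreground
    areas, measured before downscaling.
    """
    config = config or CMIConfig()
    prov: dict = {}

    def prepare(obj, min_area, name):
        if isinstance(obj, ChannelImage):
            mask, p = extract_channel_mask(obj, min_area, config.downscale_factor)
            prov[name] = p
            area = p["raw_area_um2"] - p["removed_area_um2"]
            return mask, area
        from .raster_core import downscale_mask, remove_small_components
        cleaned = remove_small_components(obj, min_area) if obj.bits.any() else obj
        area = cleaned.area_um2
        return downscale_mask(cleaned, config.downscale_factor), area

    cyan_mask, cyan_area = prepare(cyan, config.min_area_um2_cyan, "cyan")
    red_mask, red_area = prepare(red, config.min_area_um2_red, "red")
    for name, m in (("cyan", cyan_mask), ("red", red_mask)):
        if not m.bits.any():
            raise EmptyForegroundError(
                f"{name} channel has no foreground after mask extraction")
    pixels = extract_labeled_pixels(cyan_mask, red_mask, config.overlap_color)
    res = cmi_from_pixels(pixels, config.method)
    areas = {"cyan_um2": cyan_area, "red_um2": red_area}
    return CMIResult(cmi=res.cmi, method=res.method, n=res.n, curve=res.curve,
                     n_prime=res.n_prime, areas_um2=areas, provenance=prov)
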