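"""Forward/backward second-harmonic-generation (SHG) collagen metrics.

SHG microscopy of fibrillar collagen records two co-registered channels: the
forward-propagated signal, dominated by thick, mature, well-organized fibrils,
and the backward-propagated signal, dominated by thin, immature, disorganized
fibrils.  The forward/backward (F/B) ratio of summary statistics of the two
channels is therefore a semi-quantitative index of collagen maturity:

* **area** -- number of voxels above an adaptive background threshold,
* **density** -- mean intensity of those voxels,
* **intensity** -- area x density (total above-threshold signal),

each computed per z-slice, averaged over the stack, and finally expressed as
the forward/backward ratio of the stack means.

The background threshold is ``mu + sigma`` where ``mu`` and ``sigma`` are the
mean and *population* standard deviation of the whole 3-D channel (background
voxels included).  "Above threshold" is strict: voxels equal to the threshold
count as background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SHGStack",
    "ThresholdResult",
    "ChannelMetrics",
    "SHGRatios",
    "RegionGrid",
    "compute_threshold",
    "channel_metrics",
    "fb_ratios",
    "analyse_stack",
    "sample_regions",
    "read_stack",
    "write_stack",
]


@dataclass
class SHGStack:
    """Co-registered forward and backward 3-D intensity channels.

    Arrays are indexed ``(y, x, z)``: the third axis is the slicing (z) axis.
    Intensities are non-negative and live in the 16-bit range.
    """

    forward: np.ndarray
    backward: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (x, y, z) um
    label: str = ""

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward)
        self.backward = np.asarray(self.backward)
        if self.forward.shape != self.backward.shape:
            raise ValueError(
                f"channel shapes differ: {self.forward.shape} vs {self.backward.shape}"
            )
        if self.forward.ndim != 3:
            raise ValueError("channels must be 3-D (y, x, z)")
        if (self.forward < 0).any() or (self.backward < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class ThresholdResult:
    """Adaptive background threshold T = mu + sigma of a whole 3-D channel."""

    mu: float
    sigma: float

    @property
    def threshold(self) -> float:
        return self.mu + self.sigma


@dataclass(frozen=True)
class ChannelMetrics:
    """Per-slice and stack-averaged area / density / intensity of one channel.

    ``per_slice_intensity[i] == per_slice_area[i] * per_slice_density[i]``
    by construction; slices with zero area have density NaN and are excluded
    from ``mean_density`` (the mean intensity of an empty voxel set is
    undefined) while still contributing zeros to the area and intensity means.
    """

    per_slice_area: np.ndarray
    per_slice_density: np.ndarray
    per_slice_intensity: np.ndarray

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.per_slice_area))

    @property
    def mean_density(self) -> float:
        d = self.per_slice_density
        valid = ~np.isnan(d)
        if not valid.any():
            return float("nan")
        return float(np.mean(d[valid]))

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.per_slice_intensity))


@dataclass(frozen=True)
class SHGRatios:
    """Forward/backward ratios of the three stack-mean metrics."""

    fb_area: float
    fb_density: float
    fb_intensity: float


@dataclass(frozen=True)
class RegionGrid:
    """Randomly sampled imaging regions on a rows x cols tile grid."""

    grid_dims: tuple[int, int]
    selected: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        rows, cols = self.grid_dims
        n_cells = rows * cols
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected cells must be distinct")
        if any(not (0 <= c < n_cells) for c in self.selected):
            raise ValueError("selected cell index out of grid")


def compute_threshold(channel: np.ndarray) -> ThresholdResult:
    """Mean, population s.d. and threshold mu+sigma over all voxels."""
    channel = np.asarray(channel, dtype=np.float64)
    if channel.size == 0:
        raise ValueError("cannot threshold an empty channel")
    mu = float(channel.mean())
    sigma = float(channel.std())  # population s.d. (ddof=0)
    return ThresholdResult(mu=mu, sigma=sigma)


def channel_metrics(channel: np.ndarray, threshold: float) -> ChannelMetrics:
    """Per-slice area/density/intensity along the z (third) axis.

    Area counts voxels with intensity strictly greater than ``threshold``;
    density is their mean intensity; intensity is the product.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    above = channel > threshold
    # area per slice: sum over (y, x)
    area = above.sum(axis=(0, 1)).astype(np.float64)
    total = np.where(above, channel, 0.0).sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(area > 0, total / np.maximum(area, 1.0), np.nan)
    intensity = np.where(area > 0, area * density, 0.0)
    return ChannelMetrics(
        per_slice_area=area,
        per_slice_density=density,
        per_slice_intensity=intensity,
    )


def fb_ratios(forward: ChannelMetrics, backward: ChannelMetrics) -> SHGRatios:
    """Ratios of forward to backward stack means for each metric."""
    ratios = {}
    for name, f, b in (
        ("area", forward.mean_area, backward.mean_area),
        ("density", forward.mean_density, backward.mean_density),
        ("intensity", forward.mean_intensity, backward.mean_intensity),
    ):
        if not np.isfinite(b) or b == 0:
            raise ZeroDivisionError(
                f"backward stack-mean {name} is zero or undefined; F/B {name} ratio undefined"
            )
        ratios[f"fb_{name}"] = f / b
    return SHGRatios(**ratios)


def analyse_stack(
    stack: SHGStack,
) -> tuple[ThresholdResult, ThresholdResult, ChannelMetrics, ChannelMetrics, SHGRatios]:
    """Full per-stack analysis: thresholds per channel, metrics, F/B ratios.

    Thresholds are computed independently for the forward and backward
    channels (the two detectors have independent gains).
    """
    thr_f = compute_threshold(stack.forward)
    thr_b = compute_threshold(stack.backward)
    met_f = channel_metrics(stack.forward, thr_f.threshold)
    met_b = channel_metrics(stack.backward, thr_b.threshold)
    return thr_f, thr_b, met_f, met_b, fb_ratios(met_f, met_b)


def sample_regions(grid_dims: tuple[int, int], n: int, seed: int) -> RegionGrid:
    """Draw ``n`` distinct grid cells uniformly without replacement."""
    rows, cols = grid_dims
    n_cells = rows * cols
    if n > n_cells:
        raise ValueError(f"cannot sample {n} regions from a {rows}x{cols} grid")
    rng = np.random.default_rng(seed)
    selected = rng.choice(n_cells, size=n, replace=False)
    return RegionGrid(grid_dims=grid_dims, selected=tuple(int(c) for c in selected), seed=seed)


# ---------------------------------------------------------------------------
# I/O

def write_stack(stack: SHGStack, path: str | Path) -> None:
    """Write a two-channel 16-bit TIFF, channel order (forward, backward)."""
    data = np.stack(
        [
            np.round(np.clip(stack.forward, 0, 65535)).astype(np.uint16),
            np.round(np.clip(stack.backward, 0, 65535)).astype(np.uint16),
        ],
        axis=0,
    )
    # store as (channel, z, y, x) for TIFF convention
    data = np.transpose(data, (0, 3, 1, 2))
    meta = {
        "channel_order": ["forward", "backward"],
        "voxel_size_um": list(stack.voxel_size),
        "label": stack.label,
    }
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_stack(path: str | Path, channel_order: tuple[str, str] | None = None) -> SHGStack:
    """Read a two-channel TIFF written by :func:`write_stack`.

    ``channel_order`` overrides the metadata (e.g. ``("backward", "forward")``
    for stacks acquired with swapped detectors).
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    order = tuple(channel_order or meta.get("channel_order", ("forward", "backward")))
    if data.ndim != 4 or data.shape[0] != 2:
        raise ValueError(f"expected a (2, z, y, x) stack, got shape {data.shape}")
    channels = {order[i]: np.transpose(data[i], (1, 2, 0)) for i in range(2)}
    return SHGStack(
        forward=channels["forward"].astype(np.float64),
        backward=channels["backward"].astype(np.float64),
        voxel_size=tuple(meta.get("voxel_size_um", (1.0, 1.0, 1.0))),
        label=str(meta.get("label", "")),
    )


def metrics_frame(label: str, thr_f: ThresholdResult, thr_b: ThresholdResult,
                  met_f: ChannelMetrics, met_b: ChannelMetrics,
                  ratios: SHGRatios) -> pd.DataFrame:
    """One-row summary table for a stack, for CSV export."""
    row = {
        "stack": label,
        "mu_forward": thr_f.mu, "sigma_forward": thr_f.sigma,
        "threshold_forward": thr_f.threshold,
        "mu_backward": thr_b.mu, "sigma_backward": thr_b.sigma,
        "threshold_backward": thr_b.threshold,
        "mean_area_forward": met_f.mean_area,
        "mean_density_forward": met_f.mean_density,
        "mean_intensity_forward": met_f.mean_intensity,
        "mean_area_backward": met_b.mean_area,
        "mean_density_backward": met_b.mean_density,
        "mean_intensity_backward": met_b.mean_intensity,
        "fb_area": ratios.fb_area,
        "fb_density": ratios.fb_density,
        "fb_intensity": ratios.fb_intensity,
    }
    return pd.DataFrame([row])
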