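"""Reading cell-image stacks, quality gating, and image standardization.

Imaging flow cytometers export one small image per cell and channel.  The
ingestion boundary of this package is a multi-page TIFF whose pages cycle
through the channels cell by cell (e.g. brightfield, DAPI, gamma-H2AX,
brightfield, DAPI, ...).  Before any focus counting, cells are gated on four
brightfield features -- object area, background-subtracted mean intensity,
gradient RMS (a focus measure) and aspect ratio -- to remove debris,
doublets and out-of-focus objects, and all images are brought to a common
size and normalized 64x64 crops are produced for the neural network.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage import filters, measure
from sklearn.base import BaseEstimator

__all__ = [
    "CellRecord",
    "GatingFeatures",
    "GatingConfig",
    "QualityGate",
    "read_stack",
    "compute_gating_features",
    "apply_gate",
    "standardize_sizes",
    "crop_channel",
    "normalize01",
    "crop_and_normalize",
]

#: Channel name conventionally holding the brightfield image.
BRIGHTFIELD = "brightfield"
#: Channel name conventionally holding the gamma-H2AX immunofluorescence image.
GH2AX = "gh2ax"


@dataclasses.dataclass
class CellRecord:
    """One cell's per-channel images.

    All channel images share the same height x width.  Pixel values are
    nonnegative detector counts (float internally); ``pixel_size`` is
    optional metadata in micrometers per pixel and is never used in
    computations.
    """

    cell_id: str
    channels: Dict[str, np.ndarray]
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("CellRecord requires at least one channel")
        shapes = {ch: im.shape for ch, im in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel images differ in shape: {shapes}")
        for ch, im in self.channels.items():
            if im.ndim != 2:
                raise ValueError(f"channel {ch!r} is not a 2D image")
            if not np.all(np.isfinite(im)):
                raise ValueError(f"channel {ch!r} contains non-finite pixels")
        if BRIGHTFIELD not in self.channels and GH2AX not in self.channels:
            raise ValueError(
                "CellRecord needs at least one of 'brightfield' or 'gh2ax'"
            )

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape


@dataclasses.dataclass(frozen=True)
class GatingFeatures:
    """The four brightfield quality features used for cell gating."""

    area: float            # object-mask pixel count
    mean_pixel: float      # mean(mask) - median(2-px border ring); may be < 0
    gradient_rms: float    # RMS Sobel magnitude inside the mask
    aspect_ratio: float    # minor/major axis of the mask ellipse, in [0, 1]


@dataclasses.dataclass(frozen=True)
class GatingConfig:
    """Gate thresholds.

    Defaults are the vendor-software values used for 60x ImageStream data
    (area > 175, mean pixel > -20, gradient RMS > 50, aspect ratio >= 0.85).
    They are instrument- and unit-dependent; override them for data from any
    other source.
    """

    min_area: float = 175.0
    min_mean_pixel: float = -20.0
    min_gradient_rms: float = 50.0
    min_aspect_ratio: float = 0.85

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_aspect_ratio <= 1.0:
            raise ValueError("min_aspect_ratio must be in [0, 1]")


def read_stack(path, channel_map: Mapping[int, str]) -> List[CellRecord]:
    """Read a multi-page TIFF into one :class:`CellRecord` per cell.

    ``channel_map`` maps page index within the per-cell cycle to a channel
    name, e.g. ``{0: "brightfield", 1: "dapi", 2: "gh2ax"}``.  Page order in
    the file is cells x channel cycle; cell order is preserved.
    """
    path = Path(path)
    if not channel_map:
        raise ValueError("channel_map must not be empty")
    cycle = len(channel_map)
    if sorted(channel_map) != list(range(cycle)):
        raise ValueError("channel_map keys must be 0..n_channels-1")
    try:
        pages = tifffile.imread(path)
    except (FileNotFoundError, OSError) as exc:
        raise IOError(f"cannot read TIFF stack {path}: {exc}") from exc
    pages = np.atleast_3d(pages)
    if pages.ndim == 2:  # single page
        pages = pages[None]
    n_pages = pages.shape[0]
    if n_pages % cycle != 0:
        raise ValueError(
            f"page count {n_pages} is not divisible by the "
            f"{cycle}-channel cycle"
        )
    records = []
    for i in range(n_pages // cycle):
        channels = {
            channel_map[j]: np.asarray(pages[i * cycle + j], dtype=np.float64)
            for j in range(cycle)
        }
        records.append(CellRecord(cell_id=f"cell_{i:05d}", channels=channels))
    return records


def _object_mask(brightfield: np.ndarray) -> np.ndarray:
    """Largest connected component of the brightfield object.

    Brightfield cells can be darker or brighter than the background, so the
    image is transformed to absolute deviation from its median before Otsu
    thresholding.
    """
    dev = np.abs(brightfield - np.median(brightfield))
    if np.ptp(dev) == 0:
        return np.zeros(brightfield.shape, dtype=bool)
    thr = filters.threshold_otsu(dev)
    mask = dev > thr
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def _border_ring(shape: tuple, width: int = 2) -> np.ndarray:
    ring = np.zeros(shape, dtype=bool)
    ring[:width, :] = ring[-width:, :] = True
    ring[:, :width] = ring[:, -width:] = True
    return ring


def compute_gating_features(rec: CellRecord) -> GatingFeatures:
    """Compute the four gating features from the brightfield channel.

    An empty object mask (nothing detected) yields all-zero features, which
    the default gate rejects on area.
    """
    if BRIGHTFIELD not in rec.channels:
        raise ValueError("brightfield channel required for gating")
    bf = np.asarray(rec.channels[BRIGHTFIELD], dtype=np.float64)
    mask = _object_mask(bf)
    area = float(mask.sum())
    if area == 0:
        return GatingFeatures(0.0, 0.0, 0.0, 0.0)
    border_med = float(np.median(bf[_border_ring(bf.shape)]))
    mean_pixel = float(bf[mask].mean() - border_med)
    grad = filters.sobel(bf)
    gradient_rms = float(np.sqrt(np.mean(grad[mask] ** 2)))
    props = measure.regionprops(mask.astype(np.uint8))[0]
    major = props.axis_major_length
    minor = props.axis_minor_length
    aspect_ratio = float(minor / major) if major > 0 else 0.0
    return GatingFeatures(area, mean_pixel, gradient_rms, aspect_ratio)


def apply_gate(features: GatingFeatures, cfg: GatingConfig) -> bool:
    """True iff the cell passes all four thresholds.

    Area, mean pixel and gradient RMS use strict ``>``; aspect ratio is
    inclusive ``>=`` (matching the vendor gate definitions).
    """
    return bool(
        features.area > cfg.min_area
        and features.mean_pixel > cfg.min_mean_pixel
        and features.gradient_rms > cfg.min_gradient_rms
        and features.aspect_ratio >= cfg.min_aspect_ratio
    )


def _estimate_background(image: np.ndarray, width: int = 2) -> tuple:
    border = image[_border_ring(image.shape, width)]
    return float(np.mean(border)), float(np.std(border))


def _pad_to(image: np.ndarray, target: tuple, rng: np.random.Generator) -> np.ndarray:
    """Pad with samples matching the image's own border background, centered."""
    h, w = image.shape
    th, tw = target
    mean, sd = _estimate_background(image)
    out = rng.normal(mean, sd, size=target)
    np.clip(out, 0, None, out=out)
    r0 = (th - h) // 2
    c0 = (tw - w) // 2
    out[r0:r0 + h, c0:c0 + w] = image
    return out


def _center_crop(image: np.ndarray, target: tuple) -> np.ndarray:
    h, w = image.shape
    th, tw = target
    r0 = (h - th) // 2
    c0 = (w - tw) // 2
    return image[r0:r0 + th, c0:c0 + tw]


def standardize_sizes(
    records: Sequence[CellRecord], rng_seed: int = 0
) -> List[CellRecord]:
    """Bring all records to one common size.

    The target is the per-axis 99th percentile of input sizes; larger images
    are center-cropped and smaller images are padded with noise drawn from
    the image's own 2-pixel border background (clipped at zero).  Applying
    the function twice equals applying it once.
    """
    if not records:
        raise ValueError("standardize_sizes requires at least one record")
    heights = np.array([r.shape[0] for r in records])
    widths = np.array([r.shape[1] for r in records])
    th = int(np.percentile(heights, 99, method="lower"))
    tw = int(np.percentile(widths, 99, method="lower"))
    rng = np.random.default_rng(rng_seed)
    out: List[CellRecord] = []
    for rec in records:
        h, w = rec.shape
        channels = {}
        for ch, im in rec.channels.items():
            im = np.asarray(im, dtype=np.float64)
            if h > th or w > tw:
                im = _center_crop(im, (min(h, th), min(w, tw)))
            if im.shape[0] < th or im.shape[1] < tw:
                im = _pad_to(im, (th, tw), rng)
            channels[ch] = im
        out.append(CellRecord(rec.cell_id, channels, rec.pixel_size))
    return out


def crop_channel(rec: CellRecord, channel: str, size: int = 64) -> np.ndarray:
    """Raw ``size`` x ``size`` crop centered on the channel's intensity
    center of mass (clamped, not wrapped, at the borders).

    If the image is smaller than ``size`` it is background-padded first
    (deterministically per cell id).  Used both for the normalized network
    input and for photometry on the original counts.
    """
    if channel not in rec.channels:
        raise ValueError(f"channel {channel!r} not present")
    im = np.asarray(rec.channels[channel], dtype=np.float64)
    if im.shape[0] < size or im.shape[1] < size:
        rng = np.random.default_rng(abs(hash(rec.cell_id)) % (2**31))
        im = _pad_to(im, (max(im.shape[0], size), max(im.shape[1], size)), rng)
    total = im.sum()
    if total > 0:
        cy, cx = ndimage.center_of_mass(im)
    else:
        cy, cx = (im.shape[0] - 1) / 2.0, (im.shape[1] - 1) / 2.0
    r0 = int(round(cy - size / 2.0 + 0.5))
    c0 = int(round(cx - size / 2.0 + 0.5))
    r0 = min(max(r0, 0), im.shape[0] - size)
    c0 = min(max(c0, 0), im.shape[1] - size)
    return im[r0:r0 + size, c0:c0 + size]


def normalize01(image: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant image maps to all zeros."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def crop_and_normalize(
    rec: CellRecord, channel: str, size: int = 64
) -> np.ndarray:
    """Centered crop on the channel's intensity center of mass, min-max
    normalized to [0, 1] (constant crops map to all zeros)."""
    return normalize01(crop_channel(rec, channel, size))


class QualityGate(BaseEstimator):
    """scikit-learn-style gate over lists of :class:`CellRecord`.

    ``transform`` returns the records that pass the four-feature gate;
    ``gate_table`` returns a per-cell feature/decision table.  The gate is
    stateless (``fit`` records nothing beyond marking the estimator fitted),
    so it composes with sklearn pipelines operating on record lists.
    """

    def __init__(
        self,
        min_area: float = 175.0,
        min_mean_pixel: float = -20.0,
        min_gradient_rms: float = 50.0,
        min_aspect_ratio: float = 0.85,
    ):
        self.min_area = min_area
        self.min_mean_pixel = min_mean_pixel
        self.min_gradient_rms = min_gradient_rms
        self.min_aspect_ratio = min_aspect_ratio

    def _config(self) -> GatingConfig:
        return GatingConfig(
            self.min_area,
            self.min_mean_pixel,
            self.min_gradient_rms,
            self.min_aspect_ratio,
        )

    def fit(self, X: Sequence[CellRecord], y=None) -> "QualityGate":
        self.n_features_in_ = 4
        return self

    def transform(self, X: Sequence[CellRecord]) -> List[CellRecord]:
        cfg = self._config()
        return [
            rec
            for rec in X
            if apply_gate(compute_gating_features(rec), cfg)
        ]

    def fit_transform(self, X: Sequence[CellRecord], y=None) -> List[CellRecord]:
        return self.fit(X).transform(X)

    def gate_table(self, X: Sequence[CellRecord]):
        """Per-cell features and pass/fail decision as a DataFrame."""
        import pandas as pd

        cfg = self._config()
        rows = []
        for rec in X:
            f = compute_gating_features(rec)
            rows.append(
                {
                    "cell_id": rec.cell_id,
                    "area": f.area,
                    "mean_pixel": f.mean_pixel,
                    "gradient_rms": f.gradient_rms,
                    "aspect_ratio": f.aspect_ratio,
                    "passed_gate": apply_gate(f, cfg),
                }
            )
        return pd.DataFrame(rows)
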