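"""Synthetic cells, simulated foci, and the augmented training set.

Ground truth for focus detection in real cells does not exist, so the
network is trained on a hybrid set: images of untreated-like cells that are
verified (here: constructed) to contain zero foci, augmented with a random
number of simulated diffraction-limited foci.  Each focus is an isotropic
2D Gaussian

    F(x, y) = A / (2 pi sigma^2) * exp(-((x-x0)^2 + (y-y0)^2) / (2 sigma^2))

with sigma drawn uniformly from [0.75, 2.25] pixels and integrated
amplitude A = 3 sigma^3, a coupling that keeps the peak signal-to-noise
ratio of simulated spots in a regime where detection is challenging but
learnable.  Spot counts per augmented image are uniform on {0, ..., 10}.

The default study conditions are 200 zero-focus base cells, each augmented
8 times, giving 1,600 labeled training pairs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import tifffile

from .io_gating import BRIGHTFIELD, GH2AX, CellRecord, crop_and_normalize

__all__ = [
    "SpotParams",
    "SyntheticCellSpec",
    "TrainingPair",
    "render_spot",
    "amplitude_for_sigma",
    "make_base_cell",
    "inject_spots",
    "build_training_set",
    "make_evaluation_cells",
    "write_fixture_stack",
]

SIGMA_RANGE = (0.75, 2.25)   # pixels
COUNT_RANGE = (0, 10)        # foci per augmented image, inclusive
CROP_SIZE = 64               # network input side, pixels
EDGE_MARGIN = 3              # min spot distance from crop edge, pixels


def amplitude_for_sigma(sigma) -> np.ndarray:
    """Integrated amplitude law A = 3 sigma^3 coupling spot flux to width."""
    return 3.0 * np.asarray(sigma, dtype=float) ** 3


@dataclasses.dataclass(frozen=True)
class SpotParams:
    """Ground-truth parameters of one simulated focus.

    ``x0`` is the column and ``y0`` the row of the center (sub-pixel, 0-based
    with pixel centers at integer coordinates); ``sigma`` is the Gaussian
    standard deviation in pixels and ``A`` the integrated amplitude.
    """

    x0: float
    y0: float
    sigma: float
    A: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.A < 0:
            raise ValueError("A must be nonnegative")


@dataclasses.dataclass(frozen=True)
class SyntheticCellSpec:
    """Parameters of one synthetic untreated-like cell image.

    Units: pixels for geometry, detector counts for intensities.  Defaults
    emulate a 60x-magnification hematopoietic cell: an 80x80 frame, a 22-px
    radius cell, peak gamma-H2AX background of 200 counts and additive
    read-noise-like Gaussian noise of 6 counts (3% of peak).
    """

    image_size: int = 80
    cell_radius: float = 22.0
    background_level: float = 200.0
    noise_sd: float = 6.0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.cell_radius < self.image_size / 2:
            raise ValueError("require 0 < cell_radius < image_size/2")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("intensity parameters must be nonnegative")


@dataclasses.dataclass
class TrainingPair:
    """One augmented training sample.

    ``input_image`` is the normalized [0, 1] 64x64 crop containing the cell
    background plus injected spots; ``target_heatmap`` is the supervision
    signal: a unit-peak-height Gaussian of the same sigma at every true spot
    location (amplitude is deliberately not encoded -- the network's job is
    detection, photometry happens later on the original image); ``truth``
    lists the injected spots in crop coordinates.
    """

    input_image: np.ndarray
    target_heatmap: np.ndarray
    truth: List[SpotParams]


def render_spot(spot: SpotParams, size: int) -> np.ndarray:
    """Render one 2D Gaussian focus on a ``size`` x ``size`` zero background.

    The image integral converges to A as the support grows (>= 12 sigma of
    support keeps the truncation error below 0.5%).
    """
    if spot.sigma <= 0:
        raise ValueError("sigma must be positive")
    y = np.arange(size, dtype=np.float64)[:, None]
    x = np.arange(size, dtype=np.float64)[None, :]
    r2 = (x - spot.x0) ** 2 + (y - spot.y0) ** 2
    return (spot.A / (2.0 * np.pi * spot.sigma**2)) * np.exp(
        -r2 / (2.0 * spot.sigma**2)
    )


def _radial_profile(size: int, radius: float, peak: float) -> np.ndarray:
    """Smooth cell-shaped profile: raised-cosine taper, peak at center,
    exactly zero outside ``radius``."""
    c = (size - 1) / 2.0
    y = np.arange(size)[:, None] - c
    x = np.arange(size)[None, :] - c
    r = np.sqrt(x**2 + y**2) / radius
    prof = 0.5 * (1.0 + np.cos(np.pi * np.minimum(r, 1.0)))
    return peak * prof


def make_base_cell(spec: SyntheticCellSpec) -> CellRecord:
    """Generate one untreated-like cell (zero foci).

    The gamma-H2AX channel is a smooth radially decaying profile plus
    Gaussian noise, clipped at zero.  The brightfield channel is a bright
    textured disk with a sharp rim so the default quality gate accepts the
    cell.  Fully reproducible from ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.image_size
    gh = _radial_profile(n, spec.cell_radius, spec.background_level)
    if spec.noise_sd > 0:
        gh = gh + rng.normal(0.0, spec.noise_sd, size=(n, n))
    gh = np.clip(gh, 0.0, None)

    # Brightfield: background ~1000 counts, cell 150 counts brighter with
    # internal granularity so the in-focus gradient-RMS gate is satisfied.
    c = (n - 1) / 2.0
    yy = np.arange(n)[:, None] - c
    xx = np.arange(n)[None, :] - c
    disk = (xx**2 + yy**2) <= spec.cell_radius**2
    bf = np.full((n, n), 1000.0)
    texture = rng.normal(0.0, 60.0, size=(n, n))
    bf = bf + disk * (150.0 + texture)
    bf = np.clip(bf + rng.normal(0.0, 2.0, size=(n, n)), 0.0, None)
    return CellRecord(
        cell_id=f"synthetic_{spec.rng_seed}",
        channels={BRIGHTFIELD: bf, GH2AX: gh},
    )


def _cell_mask_for_centers(
    shape: Tuple[int, int], margin: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Allowed (row, col) center positions: inside the centered cell disk of
    radius 0.8 * (side/2 - margin), at least ``margin`` px from the edge."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rad = 0.8 * (min(h, w) / 2.0 - margin)
    y = np.arange(h)[:, None]
    x = np.arange(w)[None, :]
    ok = ((x - cx) ** 2 + (y - cy) ** 2) <= rad**2
    ok[:margin, :] = ok[-margin:, :] = False
    ok[:, :margin] = ok[:, -margin:] = False
    return np.nonzero(ok)


def inject_spots(
    base: np.ndarray,
    n_range: Tuple[int, int] = COUNT_RANGE,
    sigma_range: Tuple[float, float] = SIGMA_RANGE,
    rng: Optional[np.random.Generator] = None,
    amplitude_scale: float = 1.0,
    min_separation: float = 0.0,
) -> Tuple[np.ndarray, List[SpotParams]]:
    """Add n ~ uniform{n_range} simulated foci to a base image.

    Each spot draws sigma ~ uniform(sigma_range) and A = 3 sigma^3 *
    ``amplitude_scale`` (scale 1 for normalized-intensity images; pass the
    background level to express amplitudes in detector counts).  Centers are
    uniform over the central cell region, at least 3 px from the image edge;
    ``min_separation`` > 0 additionally enforces a minimum pairwise center
    distance (used by evaluation fixtures of well-separated spots).
    """
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = int(n_range[0]), int(n_range[1])
    if lo < 0 or hi < lo:
        raise ValueError("invalid spot-count range")
    if sigma_range[0] <= 0 or sigma_range[1] < sigma_range[0]:
        raise ValueError("invalid sigma range")
    n = int(rng.integers(lo, hi + 1))
    rows, cols = _cell_mask_for_centers(base.shape, EDGE_MARGIN)
    out = np.asarray(base, dtype=np.float64).copy()
    truth: List[SpotParams] = []
    attempts = 0
    while len(truth) < n:
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise RuntimeError("cannot place spots with requested separation")
        i = int(rng.integers(len(rows)))
        y0 = rows[i] + rng.uniform(-0.5, 0.5)
        x0 = cols[i] + rng.uniform(-0.5, 0.5)
        if min_separation > 0 and any(
            (s.x0 - x0) ** 2 + (s.y0 - y0) ** 2 < min_separation**2
            for s in truth
        ):
            continue
        sigma = float(rng.uniform(*sigma_range))
        A = float(amplitude_for_sigma(sigma) * amplitude_scale)
        spot = SpotParams(x0=float(x0), y0=float(y0), sigma=sigma, A=A)
        out += render_spot(spot, base.shape[0])
        truth.append(spot)
    return out, truth


def target_heatmap(
    truth: Sequence[SpotParams], size: int = CROP_SIZE
) -> np.ndarray:
    """Supervision heatmap: unit-peak Gaussian per true spot."""
    hm = np.zeros((size, size), dtype=np.float64)
    for s in truth:
        unit = SpotParams(s.x0, s.y0, s.sigma, 2.0 * np.pi * s.sigma**2)
        hm += render_spot(unit, size)
    return hm


def build_training_set(
    base_images: Sequence[CellRecord],
    pairs_per_base: int = 8,
    rng_seed: int = 0,
) -> List[TrainingPair]:
    """Augment each zero-focus base cell ``pairs_per_base`` times.

    With the default 200 bases x 8 augmentations this yields 1,600 training
    pairs.  For each pair the base's gamma-H2AX channel is cropped to 64x64
    around its center of mass and min-max normalized, spots with A = 3
    sigma^3 (normalized-intensity scale) are added, the result is rescaled
    by its new maximum back into [0, 1], and the unit-peak target heatmap is
    built from the truth list.  The whole set is a pure function of
    ``rng_seed``.
    """
    if not base_images:
        raise ValueError("need at least one base image")
    if pairs_per_base < 1:
        raise ValueError("pairs_per_base must be >= 1")
    rng = np.random.default_rng(rng_seed)
    pairs: List[TrainingPair] = []
    for rec in base_images:
        crop = crop_and_normalize(rec, GH2AX, CROP_SIZE)
        for _ in range(pairs_per_base):
            img, truth = inject_spots(crop, COUNT_RANGE, SIGMA_RANGE, rng)
            hi = img.max()
            if hi > 0:
                img = img / hi
            pairs.append(
                TrainingPair(
                    input_image=img.astype(np.float32),
                    target_heatmap=target_heatmap(truth).astype(np.float32),
                    truth=truth,
                )
            )
    return pairs


def make_evaluation_cells(
    n_cells: int,
    rng_seed: int = 0,
    n_range: Tuple[int, int] = COUNT_RANGE,
    min_separation: float = 0.0,
    spec: Optional[SyntheticCellSpec] = None,
) -> Tuple[List[CellRecord], List[List[SpotParams]]]:
    """Treated-like evaluation fixtures on the detector-count scale.

    Each cell is a fresh base (new seed) whose gamma-H2AX channel receives
    n ~ uniform{n_range} foci with amplitudes A = 3 sigma^3 expressed in
    counts via amplitude_scale = background_level, so a typical focus
    carries a few hundred integrated counts and the 100-count intensity
    threshold is meaningful.  Returns the cells and the per-cell truth lists
    (in full-frame coordinates).
    """
    if spec is None:
        spec = SyntheticCellSpec()
    rng = np.random.default_rng(rng_seed)
    cells: List[CellRecord] = []
    truths: List[List[SpotParams]] = []
    for i in range(n_cells):
        base_spec = dataclasses.replace(
            spec, rng_seed=int(rng.integers(2**31))
        )
        rec = make_base_cell(base_spec)
        img, truth = inject_spots(
            rec.channels[GH2AX],
            n_range=n_range,
            rng=rng,
            amplitude_scale=spec.background_level,
            min_separation=min_separation,
        )
        channels = dict(rec.channels)
        channels[GH2AX] = img
        cells.append(CellRecord(f"eval_{i:05d}", channels))
        truths.append(truth)
    return cells, truths


def write_fixture_stack(records: Sequence[CellRecord], path) -> Path:
    """Write records as a multi-page float32 TIFF readable by
    :func:`fociquant.io_gating.read_stack` (lossless for float32).

    Channels are written in sorted name order for every cell; the matching
    channel_map is ``{i: name for i, name in enumerate(sorted(names))}``.
    """
    path = Path(path)
    if not records:
        raise ValueError("no records to write")
    names = sorted(records[0].channels)
    pages = [
        np.asarray(rec.channels[ch], dtype=np.float32)
        for rec in records
        for ch in names
    ]
    try:
        tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    except OSError as exc:
        raise IOError(f"cannot write TIFF stack {path}: {exc}") from exc
    return path


def fixture_channel_map(records: Sequence[CellRecord]) -> dict:
    """Channel map matching :func:`write_fixture_stack` page order."""
    return {i: ch for i, ch in enumerate(sorted(records[0].channels))}
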