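"""Confocal quantifications: innervation density, 3-D puncta counting,
corrected total cell fluorescence, normalized ROI signal, and binary
innervation scoring.

All measurements operate on raw intensities — no normalization before
thresholding — because comparisons are only meaningful when the same
settings are applied across every image in a set.  Thresholds and size
gates are inclusive: a voxel exactly at the intensity threshold, or an
object exactly at a size bound, counts.  Regions of interest are
supplied as masks (drawn manually, as is standard for fan-shaped-body
work); automatic segmentation is out of scope.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import ndimage
from statsmodels.stats.proportion import proportion_confint

#: Default 3-D object-counter settings for presynaptic puncta.
DEFAULT_PUNCTA_THRESHOLD = 52
DEFAULT_MIN_SIZE = 2
DEFAULT_MAX_SIZE = 80
#: Default z spacing of confocal stacks in micrometres.
DEFAULT_Z_STEP_UM = 0.5


class RoiError(ValueError):
    """Empty or mismatched region-of-interest mask."""


@dataclasses.dataclass
class ImageStack:
    """3-D intensity array (z, y, x) with voxel spacing in micrometres."""

    voxels: np.ndarray
    z_step: float = DEFAULT_Z_STEP_UM
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3-D (z, y, x)")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        if self.z_step <= 0 or self.pixel_size <= 0:
            raise ValueError("voxel spacing must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        return self.z_step * self.pixel_size**2


@dataclasses.dataclass
class RoiMask:
    """Boolean region mask congruent with an image slice or volume."""

    mask: np.ndarray
    label: str = "dFSB"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    def volume_mask(self, shape: tuple[int, ...]) -> np.ndarray:
        """Broadcast a per-slice (2-D) mask over a 3-D stack if needed."""
        if self.mask.shape == shape:
            return self.mask
        if self.mask.ndim == 2 and self.mask.shape == shape[-2:]:
            return np.broadcast_to(self.mask, shape)
        raise RoiError(
            f"ROI shape {self.mask.shape} does not match image shape {shape}"
        )


@dataclasses.dataclass
class PunctaCountResult:
    """Count, ROI volume, and density of size-gated 3-D objects."""

    count: int
    roi_volume_voxels: int
    roi_volume_um3: float
    density_per_voxel: float
    density_per_um3: float
    sizes: np.ndarray


@dataclasses.dataclass
class PresenceResult:
    """Per-brain innervation calls with cohort percentage and 95% CI."""

    calls: list[bool]
    densities: list[float]
    n_positive: int
    n_total: int
    fraction: float
    ci_low: float
    ci_high: float


def innervation_density(
    image: np.ndarray, roi: RoiMask, threshold: float
) -> float:
    """Fraction of ROI pixels at or above ``threshold``.

    This implements neurite innervation density as (area occupied by
    thresholded signal) / (area of the ROI); the threshold must be held
    constant across a comparison set.  Monotone non-increasing in the
    threshold.
    """
    image = np.asarray(image)
    mask = roi.volume_mask(image.shape) if image.ndim == 3 else roi.mask
    if mask.shape != image.shape:
        raise RoiError(
            f"ROI shape {mask.shape} does not match image shape {image.shape}"
        )
    n = int(mask.sum())
    if n == 0:
        raise RoiError("empty ROI: innervation density undefined")
    return float((image[mask] >= threshold).sum() / n)


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def count_puncta_3d(
    stack: ImageStack,
    roi: RoiMask,
    intensity_threshold: float = DEFAULT_PUNCTA_THRESHOLD,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    connectivity: int = 26,
) -> PunctaCountResult:
    """Count size-gated connected components of supra-threshold voxels.

    Components use 26-neighbour connectivity by default (the common
    3-D object-counter behaviour).  Both size bounds are inclusive.
    The ROI volume is the number of ROI voxels with intensity >= 1
    (the object-counter volume settings: threshold 1, minimum size 1),
    so density * roi_volume = count exactly in voxel units.
    """
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18, or 26")
    vox = stack.voxels
    mask = roi.volume_mask(vox.shape)
    structure = ndimage.generate_binary_structure(
        3, _CONNECTIVITY_RANK[connectivity]
    )
    foreground = (vox >= intensity_threshold) & mask
    labels, n_objects = ndimage.label(foreground, structure=structure)
    if n_objects:
        sizes = np.bincount(labels.ravel())[1:]
    else:
        sizes = np.zeros(0, dtype=int)
    kept = (sizes >= min_size) & (sizes <= max_size)
    count = int(kept.sum())
    roi_volume = int(((vox >= 1) & mask).sum())
    if roi_volume == 0:
        raise RoiError("ROI volume is zero: density undefined")
    roi_um3 = roi_volume * stack.voxel_volume_um3
    return PunctaCountResult(
        count=count,
        roi_volume_voxels=roi_volume,
        roi_volume_um3=roi_um3,
        density_per_voxel=count / roi_volume,
        density_per_um3=count / roi_um3,
        sizes=sizes[kept],
    )


def ctcf(
    cell_integrated_density: float, cell_area: float, background_mean: float
) -> float:
    """Corrected total cell fluorescence.

    CTCF = integrated density of the cell ROI minus (cell area x mean
    background fluorescence).  May legitimately be negative for cells
    dimmer than background; the value is reported as-is.
    """
    if cell_area <= 0:
        raise ValueError("cell area must be positive")
    return float(cell_integrated_density - cell_area * background_mean)


def ctcf_from_rois(
    image: np.ndarray, cell: RoiMask, background: RoiMask
) -> float:
    """CTCF computed from a cell ROI and a background ROI on one image."""
    image = np.asarray(image, dtype=float)
    for r, name in ((cell, "cell"), (background, "background")):
        if r.mask.shape != image.shape:
            raise RoiError(f"{name} ROI shape mismatch")
        if not r.mask.any():
            raise RoiError(f"empty {name} ROI")
    integrated = float(image[cell.mask].sum())
    area = float(cell.mask.sum())
    bg_mean = float(image[background.mask].mean())
    return ctcf(integrated, area, bg_mean)


@dataclasses.dataclass
class NormalizedSignal:
    ratio: float
    mode: str
    signal_mean: float
    reference_mean: float


NORMALIZATION_MODES = ("adjacent_background", "same_roi_reference")


def normalized_roi_signal(
    signal_mean: float, reference_mean: float, mode: str
) -> NormalizedSignal:
    """Mean ROI signal divided by a reference mean.

    ``mode`` records the provenance of the reference: an adjacent
    background ROI (activity-reporter normalization) or a co-stain
    measured in the same ROI (e.g. a neuropil counterstain).
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"mode must be one of {NORMALIZATION_MODES}")
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive (normalization undefined)")
    return NormalizedSignal(
        ratio=float(signal_mean / reference_mean),
        mode=mode,
        signal_mean=float(signal_mean),
        reference_mean=float(reference_mean),
    )


def roi_mean(image: np.ndarray, roi: RoiMask) -> float:
    """Mean intensity inside a ROI."""
    image = np.asarray(image, dtype=float)
    if roi.mask.shape != image.shape:
        raise RoiError("ROI shape mismatch")
    if not roi.mask.any():
        raise RoiError("empty ROI")
    return float(image[roi.mask].mean())


def innervation_presence(
    items: list[tuple[np.ndarray, RoiMask]],
    threshold: float,
    min_fraction: float,
    confidence: float = 0.95,
) -> PresenceResult:
    """Binary innervation scoring across a cohort of brains.

    A brain is positive when its innervation density reaches
    ``min_fraction`` (the scoring criterion is an explicit, labelled
    assumption).  The cohort positive fraction carries an exact
    (Clopper-Pearson) binomial confidence interval.
    """
    if not items:
        raise ValueError("empty cohort")
    densities = [innervation_density(img, roi, threshold) for img, roi in items]
    calls = [d >= min_fraction for d in densities]
    k, n = sum(calls), len(calls)
    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method="beta")
    return PresenceResult(
        calls=calls,
        densities=densities,
        n_positive=k,
        n_total=n,
        fraction=k / n,
        ci_low=float(lo),
        ci_high=float(hi),
    )


# ---------------------------------------------------------------------------
# TIFF plumbing


def load_stack(
    path: str | Path,
    z_step: float = DEFAULT_Z_STEP_UM,
    pixel_size: float = 1.0,
) -> ImageStack:
    """Read a multi-page TIFF as an ImageStack."""
    import tifffile

    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return ImageStack(voxels=arr, z_step=z_step, pixel_size=pixel_size)


def load_roi(path: str | Path, label: str = "dFSB") -> RoiMask:
    """Read a 0/255 (or label) TIFF as a boolean ROI mask."""
    import tifffile

    arr = tifffile.imread(str(path))
    return RoiMask(mask=arr > 0, label=label)


def save_stack(stack: ImageStack, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(stack.voxels))
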