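"""Calibrated 3D volumes, binary masks, isotropic resampling and HU discretization.

Arrays are stored in ``(x, y, z)`` axis order; world coordinates (mm) are
``index * spacing + origin`` per axis.  All Hounsfield-unit (HU) processing
follows the fixed-bin-size convention used in CT radiomics: intensities are
clipped to a stated HU window and discretized to equal-width bins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

HU_MIN = -1024.0
HU_MAX = 3071.0

#: default fixed-bin discretization for calibrated lung CT
DEFAULT_BIN_SIZE_HU = 50.0
DEFAULT_HU_RANGE = (-1000.0, 200.0)


class GeometryError(ValueError):
    """Raised when a volume/mask pair disagrees on lattice geometry."""


class EmptyMaskError(ValueError):
    """Raised when a segmentation mask contains no foreground voxel."""


@dataclass
class VolumeGrid:
    """A calibrated scalar 3D lattice with physical spacing.

    Parameters
    ----------
    values : ndarray
        3D array of intensities (HU for CT input, arbitrary units for
        filtered volumes), axis order ``(x, y, z)``.
    spacing : tuple of float
        Voxel edge length in mm per axis.
    origin : tuple of float
        World position of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.values.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def is_isotropic(self) -> bool:
        return math.isclose(self.spacing[0], self.spacing[1]) and math.isclose(
            self.spacing[0], self.spacing[2]
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class SegmentationMask:
    """A binary region of interest aligned voxel-for-voxel with a VolumeGrid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values) > 0
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.values.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not self.values.any():
            raise EmptyMaskError("empty mask: no foreground voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


def check_geometry(vol: VolumeGrid, mask: SegmentationMask, atol: float = 1e-6) -> None:
    """Raise :class:`GeometryError` unless volume and mask share lattice geometry."""
    if vol.shape != mask.shape:
        raise GeometryError(f"shape mismatch: volume {vol.shape} vs mask {mask.shape}")
    if not np.allclose(vol.spacing, mask.spacing, atol=atol):
        raise GeometryError(
            f"spacing mismatch: volume {vol.spacing} vs mask {mask.spacing}"
        )
    if not np.allclose(vol.origin, mask.origin, atol=atol):
        raise GeometryError(f"origin mismatch: volume {vol.origin} vs mask {mask.origin}")


def _load_nifti(path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), origin


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI scalar volume; anisotropic input is accepted and flagged."""
    data, spacing, origin = _load_nifti(path)
    vol = VolumeGrid(data, spacing, origin)
    if not vol.is_isotropic:
        log.warning("%s: anisotropic spacing %s", path, spacing)
    return vol


def read_mask(path) -> SegmentationMask:
    """Read a NIfTI mask, binarized at > 0; an empty mask is an error."""
    data, spacing, origin = _load_nifti(path)
    return SegmentationMask(data, spacing, origin)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_volume(vol: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: SegmentationMask, path) -> None:
    img = nib.Nifti1Image(
        mask.values.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def resample_isotropic(
    vol: VolumeGrid, mask: SegmentationMask, target_spacing: float
) -> tuple[VolumeGrid, SegmentationMask]:
    """Resample a volume/mask pair to isotropic voxels of ``target_spacing`` mm.

    The volume is interpolated trilinearly, the mask by nearest neighbor and
    re-binarized.  The physical extent is preserved to within one voxel.

    Raises
    ------
    EmptyMaskError
        If the target spacing is so coarse that the ROI vanishes.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    check_geometry(vol, mask)
    factors = tuple(s / target_spacing for s in vol.spacing)
    if all(math.isclose(f, 1.0, rel_tol=1e-9) for f in factors):
        return vol, mask
    new_vals = ndimage.zoom(vol.values, factors, order=1, mode="nearest", grid_mode=True)
    new_mask = ndimage.zoom(
        mask.values.astype(np.float32), factors, order=0, mode="nearest", grid_mode=True
    )
    new_mask = new_mask > 0.5
    if not new_mask.any():
        raise EmptyMaskError(
            f"mask vanished at target spacing {target_spacing} mm "
            f"(ROI of {mask.n_voxels} voxels at {mask.spacing} mm)"
        )
    t = float(target_spacing)
    out_vol = VolumeGrid(new_vals, (t, t, t), vol.origin)
    out_mask = SegmentationMask(new_mask, (t, t, t), mask.origin)
    return out_vol, out_mask


def volumetric_ratio(spacing_a: float, spacing_b: float) -> float:
    """Voxel-volume ratio between two isotropic spacings, ``(a/b)**3``."""
    return (spacing_a / spacing_b) ** 3


@dataclass
class DiscretizedVolume:
    """Integer gray-level lattice: 0 outside the mask, 1..n_bins inside."""

    levels: np.ndarray
    n_bins: int
    bin_size: float
    range_low: float
    range_high: float
    mask: np.ndarray = field(repr=False)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # memo for texture intermediates shared across feature families
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize(
    vol: VolumeGrid,
    mask: SegmentationMask,
    bin_size: float = DEFAULT_BIN_SIZE_HU,
    hu_range: tuple[float, float] = DEFAULT_HU_RANGE,
) -> DiscretizedVolume:
    """Fixed-bin-size discretization over a stated intensity window.

    In-mask intensities are clipped to ``hu_range`` and assigned
    ``1 + floor((x - low) / bin_size)``; the top edge is inclusive in the
    last bin so that ``x == high`` maps to ``n_bins``.  Out-of-range values
    are clipped rather than excluded, keeping the mask volume identical
    across time points.
    """
    lo, hi = float(hu_range[0]), float(hu_range[1])
    if not lo < hi:
        raise ValueError(f"invalid range: {hu_range}")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    check_geometry(vol, mask)
    n_bins = int(math.ceil((hi - lo) / bin_size))
    clipped = np.clip(vol.values, lo, hi)
    idx = 1 + np.floor((clipped - lo) / bin_size).astype(np.int64)
    idx = np.minimum(idx, n_bins)  # top edge inclusive
    levels = np.where(mask.values, idx, 0)
    return DiscretizedVolume(
        levels=levels,
        n_bins=n_bins,
        bin_size=float(bin_size),
        range_low=lo,
        range_high=hi,
        mask=mask.values,
        spacing=vol.spacing,
    )


def discretize_adaptive(
    vol_values: np.ndarray,
    mask_values: np.ndarray,
    n_bins: int = 24,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> DiscretizedVolume:
    """Discretize with the bin range re-derived from the in-mask min/max.

    Used for filtered (wavelet) volumes whose values are no longer on the HU
    scale; keeps the same bin count as the calibrated configuration.  A
    constant region degenerates to a single occupied bin.
    """
    inside = vol_values[mask_values]
    lo, hi = float(inside.min()), float(inside.max())
    if hi <= lo:
        levels = np.where(mask_values, 1, 0)
        return DiscretizedVolume(levels, n_bins, 0.0, lo, lo, mask_values, spacing)
    bin_size = (hi - lo) / n_bins
    idx = 1 + np.floor((vol_values - lo) / bin_size).astype(np.int64)
    idx = np.clip(idx, 1, n_bins)
    levels = np.where(mask_values, idx, 0)
    return DiscretizedVolume(levels, n_bins, bin_size, lo, hi, mask_values, spacing)
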