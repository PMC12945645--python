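"""Volume data model and the shared spatial primitives.

A :class:`ScalarVolume` is a 3-D real-valued map on a :class:`GridSpec`
(world coordinates are MNI-style RAS millimeters, voxel indices 0-based,
``world = origin + index * voxel_size``). Everything downstream — SUVR,
rCBF, FA, statistic and p maps — is carried in this container.

I/O goes through NIfTI-1 via nibabel; only diagonal-plus-translation
affines are accepted because the pipeline operates strictly in an
already-normalized template space.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    EmptyMaskError,
    GridCompatibilityError,
    InvalidParameterError,
    UndefinedMeanError,
)

log = logging.getLogger(__name__)

#: FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_GRID_TOL_MM = 1e-6


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a voxel grid in MNI-style millimeter world coordinates.

    ``origin_mm`` is the world coordinate of the *center* of voxel (0,0,0);
    axes are ordered x/y/z (RAS).
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise InvalidParameterError(f"shape must be 3 positive ints, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidParameterError(
                f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def compatible(self, other: "GridSpec", tol_mm: float = _GRID_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol_mm for a, b in zip(self.voxel_size_mm, other.voxel_size_mm))
            and all(abs(a - b) <= tol_mm for a, b in zip(self.origin_mm, other.origin_mm))
        )

    def require_compatible(self, other: "GridSpec") -> None:
        if not self.compatible(other):
            raise GridCompatibilityError(f"incompatible grids: {self} vs {other}")

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1-D arrays of voxel-center world coordinates."""
        return tuple(
            self.origin_mm[a] + np.arange(self.shape[a]) * self.voxel_size_mm[a]
            for a in range(3)
        )

    def index_of(self, world_mm) -> tuple[int, int, int]:
        """Voxel whose center is nearest the world point (ties toward lower index)."""
        f = (np.asarray(world_mm, dtype=float) - np.asarray(self.origin_mm)) / np.asarray(
            self.voxel_size_mm)
        idx = np.ceil(f - 0.5).astype(int)  # exact half-way ties resolve downward
        return tuple(int(i) for i in idx)

    def world_of(self, index) -> np.ndarray:
        return np.asarray(self.origin_mm) + np.asarray(index, dtype=float) * np.asarray(
            self.voxel_size_mm)

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff


def mni_grid(voxel_mm: float = 3.0) -> GridSpec:
    """A grid covering the standard MNI bounding box.

    The box spans x in [-90, 90], y in [-126, 90], z in [-72, 108] mm, which
    at 1 mm gives the familiar 181 x 217 x 181 shape and at 3 mm 61 x 73 x 61.
    """
    if voxel_mm <= 0:
        raise InvalidParameterError("voxel_mm must be positive")
    lo = np.array([-90.0, -126.0, -72.0])
    hi = np.array([90.0, 90.0, 108.0])
    shape = tuple(int(np.floor((hi[a] - lo[a]) / voxel_mm)) + 1 for a in range(3))
    return GridSpec(shape=shape, voxel_size_mm=(voxel_mm,) * 3, origin_mm=tuple(lo))


@dataclass
class ScalarVolume:
    """One modality parameter (or statistic) per voxel; NaN outside brain."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise InvalidParameterError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}")

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy())


@dataclass
class BinaryMask:
    grid: GridSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != self.grid.shape:
            raise InvalidParameterError(
                f"mask shape {self.values.shape} != grid shape {self.grid.shape}")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def intersect(self, other: "BinaryMask") -> "BinaryMask":
        self.grid.require_compatible(other.grid)
        return BinaryMask(self.grid, self.values & other.values)


def gaussian_smooth(vol: ScalarVolume, fwhm_mm: float, boundary: str = "reflect") -> ScalarVolume:
    """Isotropic Gaussian smoothing with FWHM given in millimeters.

    Per-axis sigma in voxels is ``fwhm_mm * FWHM_TO_SIGMA / voxel_size``.
    NaNs are treated as zero with renormalization by the smoothed valid-voxel
    mask (standard masked smoothing); NaN itself propagates only within a
    one-voxel dilation of the original NaN region.
    """
    if not np.isfinite(fwhm_mm) or fwhm_mm <= 0:
        raise InvalidParameterError(f"fwhm_mm must be positive, got {fwhm_mm}")
    if boundary not in ("reflect", "zero"):
        raise InvalidParameterError(f"unknown boundary mode {boundary!r}")
    mode = "reflect" if boundary == "reflect" else "constant"
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in vol.grid.voxel_size_mm]
    finite = np.isfinite(vol.values)
    if finite.all():
        out = ndimage.gaussian_filter(vol.values, sigma=sigma_vox, mode=mode, cval=0.0)
        return ScalarVolume(vol.grid, out)
    filled = np.where(finite, vol.values, 0.0)
    sm = ndimage.gaussian_filter(filled, sigma=sigma_vox, mode=mode, cval=0.0)
    weight = ndimage.gaussian_filter(finite.astype(float), sigma=sigma_vox, mode=mode, cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(weight > 1e-12, sm / np.maximum(weight, 1e-300), np.nan)
    nan_halo = ndimage.binary_dilation(~finite)
    out[nan_halo] = np.nan
    return ScalarVolume(vol.grid, out)


def resample_isotropic(vol: ScalarVolume, target_mm: float) -> ScalarVolume:
    """Trilinear resampling onto an isotropic grid covering the same world extent.

    The world extent of a grid is taken edge-to-edge (half a voxel beyond the
    outermost voxel centers); the new grid tiles that extent with cubic voxels
    of side ``target_mm``, so a 2 mm volume interpolated to 1 mm doubles its
    shape, matching the paper-style "interpolate onto a 1-mm isotropic grid".
    """
    if target_mm <= 0:
        raise InvalidParameterError("target_mm must be positive")
    if vol.grid.n_voxels == 0 or vol.values.size == 0:
        raise InvalidParameterError("cannot resample an empty volume")
    g = vol.grid
    low_edge = np.asarray(g.origin_mm) - np.asarray(g.voxel_size_mm) / 2.0
    extent = np.asarray(g.shape) * np.asarray(g.voxel_size_mm)
    new_shape = tuple(max(1, int(np.ceil(extent[a] / target_mm - 1e-9))) for a in range(3))
    new_origin = tuple(low_edge + target_mm / 2.0)
    new_grid = GridSpec(shape=new_shape, voxel_size_mm=(target_mm,) * 3, origin_mm=new_origin)
    if new_grid.compatible(g):
        return ScalarVolume(g, vol.values.copy())
    # continuous index of each new voxel center in the old grid
    coords = np.meshgrid(*[
        (new_grid.origin_mm[a] + np.arange(new_shape[a]) * target_mm - g.origin_mm[a])
        / g.voxel_size_mm[a]
        for a in range(3)
    ], indexing="ij")
    out = ndimage.map_coordinates(vol.values, np.stack(coords), order=1, mode="nearest")
    return ScalarVolume(new_grid, out)


def whole_brain_mask(vol: ScalarVolume, fraction_of_mean: float = 0.35) -> BinaryMask:
    """Threshold mask: include voxels above ``fraction_of_mean`` times the
    mean over strictly positive voxels.

    The 0.35 default is a convention for artifact-free template-space data,
    not a published value.
    """
    if not 0.0 < fraction_of_mean < 1.0:
        raise InvalidParameterError("fraction_of_mean must be in (0, 1)")
    finite = np.isfinite(vol.values)
    pos = finite & (vol.values > 0)
    if not pos.any():
        raise EmptyMaskError("volume has no positive voxels")
    threshold = fraction_of_mean * float(vol.values[pos].mean())
    return BinaryMask(vol.grid, finite & (vol.values > threshold))


def masked_mean(vol: ScalarVolume, mask: BinaryMask) -> float:
    """Arithmetic mean of the volume inside the mask; NaN voxels are excluded."""
    vol.grid.require_compatible(mask.grid)
    if mask.n_voxels == 0:
        raise UndefinedMeanError("mask is empty")
    vals = vol.values[mask.values]
    finite = np.isfinite(vals)
    n_excluded = int((~finite).sum())
    if n_excluded:
        log.debug("masked_mean: excluded %d non-finite voxels", n_excluded)
    if not finite.any():
        raise UndefinedMeanError("all masked voxels are non-finite")
    return float(vals[finite].mean())


# ---------------------------------------------------------------------------
# NIfTI I/O

def _grid_from_affine(affine: np.ndarray, shape) -> GridSpec:
    lin = affine[:3, :3]
    off_diag = lin - np.diag(np.diag(lin))
    if np.abs(off_diag).max() > 1e-6:
        raise InvalidParameterError(
            "only diagonal-plus-translation affines are supported (volume must "
            "already be resampled to an axis-aligned template grid); got\n"
            f"{affine}")
    diag = np.diag(lin)
    if np.any(diag <= 0):
        raise InvalidParameterError(
            f"affine diagonal must be positive (RAS axis order expected), got {diag}")
    return GridSpec(shape=tuple(int(s) for s in shape[:3]),
                    voxel_size_mm=tuple(float(d) for d in diag),
                    origin_mm=tuple(float(t) for t in affine[:3, 3]))


def read_volume(path) -> ScalarVolume:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    return ScalarVolume(grid, np.asarray(img.dataobj, dtype=float))


def write_volume(vol: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), vol.grid.affine())
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    v = read_volume(path)
    return BinaryMask(v.grid, v.values > 0.5)


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.grid.affine())
    nib.save(img, str(path))
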