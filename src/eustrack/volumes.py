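"""3D volume handling: loading, resampling, oblique slicing, image preprocessing.

Conventions
-----------
* Right-handed world frame in millimetres; axes (x = left->right,
  y = posterior->anterior, z = inferior->superior).
* ``Volume3D.values`` is indexed ``[i, j, k]`` along (x, y, z); the origin is
  the world position of the centre of voxel ``(0, 0, 0)``.
* 2D images are indexed ``[row, col]`` with row running along the slice
  ``v_axis`` and column along ``u_axis``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Volume3D",
    "ObliqueSliceSpec",
    "GrayImage",
    "StructureMask",
    "load_volume",
    "save_volume",
    "resample_isotropic",
    "extract_oblique_slice",
    "mask_to_black",
    "median_filter",
]


class InputError(ValueError):
    """Unreadable or missing input data."""


class FormatError(ValueError):
    """Input parsed but violates format expectations."""


@dataclass
class Volume3D:
    """Axis-aligned 3D scalar grid with mm spacing — the CT/MRI stand-in."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("Volume3D requires a 3D array")
        if any(n < 2 for n in self.values.shape):
            raise ValueError("Volume3D requires >= 2 samples per axis")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive values (mm)")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector (mm)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-frame mm points (N x 3) to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - self.origin) / self.spacing

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) corners in mm of the voxel-centre grid."""
        high = self.origin + (np.array(self.shape) - 1) * self.spacing
        return self.origin.copy(), high


@dataclass
class ObliqueSliceSpec:
    """An arbitrarily oriented imaging plane through a volume.

    The plane is spanned by the orthonormal ``u_axis`` (image columns) and
    ``v_axis`` (image rows) around ``center``; ``extent`` and
    ``pixel_spacing`` are (u, v) pairs in mm.
    """

    center: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    extent: np.ndarray
    pixel_spacing: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.u_axis = np.asarray(self.u_axis, dtype=float)
        self.v_axis = np.asarray(self.v_axis, dtype=float)
        self.extent = np.asarray(self.extent, dtype=float)
        self.pixel_spacing = np.asarray(self.pixel_spacing, dtype=float)
        for name in ("center", "u_axis", "v_axis"):
            if getattr(self, name).shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
        if abs(np.linalg.norm(self.u_axis) - 1.0) > 1e-9:
            raise ValueError("u_axis must be a unit vector")
        if abs(np.linalg.norm(self.v_axis) - 1.0) > 1e-9:
            raise ValueError("v_axis must be a unit vector")
        if abs(float(self.u_axis @ self.v_axis)) > 1e-9:
            raise ValueError("u_axis and v_axis must be orthogonal")
        if self.extent.shape != (2,) or np.any(self.extent <= 0):
            raise ValueError("extent must be 2 positive values (mm)")
        if self.pixel_spacing.shape != (2,) or np.any(self.pixel_spacing <= 0):
            raise ValueError("pixel_spacing must be 2 positive values (mm)")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u_axis, self.v_axis)

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the sampled image."""
        nu = int(round(self.extent[0] / self.pixel_spacing[0]))
        nv = int(round(self.extent[1] / self.pixel_spacing[1]))
        return nv, nu

    def pixel_positions(self) -> np.ndarray:
        """World positions of every pixel, shape (rows, cols, 3).

        Pixel (i, j) sits at ``center + (i*dv - extent_v/2) v + (j*du -
        extent_u/2) u``.
        """
        nv, nu = self.shape
        du, dv = self.pixel_spacing
        uu = np.arange(nu) * du - self.extent[0] / 2.0
        vv = np.arange(nv) * dv - self.extent[1] / 2.0
        return (
            self.center[None, None, :]
            + vv[:, None, None] * self.v_axis[None, None, :]
            + uu[None, :, None] * self.u_axis[None, None, :]
        )

    def plane_coords(self, points_mm: np.ndarray) -> np.ndarray:
        """Project world points onto (u, v, w) plane coordinates (w = normal)."""
        rel = np.atleast_2d(points_mm) - self.center
        return np.stack(
            [rel @ self.u_axis, rel @ self.v_axis, rel @ self.normal], axis=-1
        )


@dataclass
class GrayImage:
    """2D scalar image with mm pixel spacing."""

    values: np.ndarray
    pixel_spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pixel_spacing = np.asarray(self.pixel_spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("GrayImage requires a 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if self.pixel_spacing.shape != (2,) or np.any(self.pixel_spacing <= 0):
            raise ValueError("pixel_spacing must be 2 positive values (mm)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class StructureMask:
    """Named boolean mask congruent with its parent volume or image grid."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)


def load_volume(path: str, format: str) -> Volume3D:
    """Read a 3D volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path:
        ``.nii``/``.nii.gz`` file for ``format="nifti"``; a directory of
        single-frame ``.dcm`` files for ``format="dicom_dir"``.
    format:
        One of ``{"nifti", "dicom_dir"}``.
    """
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_dir":
        return _load_dicom_dir(path)
    raise ValueError(f"unknown volume format: {format!r}")


def _load_nifti(path: str) -> Volume3D:
    import nibabel as nib

    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # pragma: no cover - nibabel error wording varies
        raise InputError(f"unreadable NIfTI file: {path}") from exc
    img = nib.as_closest_canonical(img)  # RAS+ = our (x, y, z) convention
    values = np.asarray(img.get_fdata(), dtype=float)
    if values.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI volume, got shape {values.shape}")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return Volume3D(values=values, spacing=spacing, origin=origin)


def _load_dicom_dir(path: str) -> Volume3D:
    import pydicom

    if not os.path.isdir(path):
        raise InputError(f"no such directory: {path}")
    files = sorted(
        os.path.join(path, f) for f in os.listdir(path) if f.lower().endswith(".dcm")
    )
    if len(files) < 2:
        raise InputError(f"need >= 2 DICOM slices in {path}")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(f))
        except Exception as exc:
            raise InputError(f"unreadable DICOM file: {f}") from exc
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    steps = np.diff(zs)
    if np.any(steps <= 0):
        raise FormatError("duplicate DICOM slice positions")
    # >1% deviation in slice step (e.g. a missing slice) is a broken series.
    if (steps.max() - steps.min()) > 0.01 * steps.mean():
        raise FormatError(
            f"inconsistent DICOM slice spacing: steps range "
            f"{steps.min():.3f}-{steps.max():.3f} mm"
        )
    first = slices[0]
    dy, dx = (float(v) for v in first.PixelSpacing)
    arrs = []
    for ds in slices:
        a = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        arrs.append(a * slope + inter)
    # DICOM pixel_array is [row, col] = [y, x]; reorder to [x, y, z].
    vol = np.stack(arrs, axis=-1).transpose(1, 0, 2)
    origin = np.asarray([float(v) for v in first.ImagePositionPatient], dtype=float)
    return Volume3D(values=vol, spacing=np.array([dx, dy, steps.mean()]), origin=origin)


def save_volume(vol: Volume3D, path: str) -> None:
    """Write a volume as NIfTI with a diagonal affine from spacing/origin."""
    import nibabel as nib

    affine = np.diag([*vol.spacing, 1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), path)


def resample_isotropic(vol: Volume3D, target_spacing: float) -> Volume3D:
    """Resample a volume to isotropic spacing by trilinear interpolation.

    The new grid starts at the old origin and keeps within the old physical
    bounding box, so no extrapolation occurs.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be > 0")
    old_n = np.array(vol.shape)
    extent = (old_n - 1) * vol.spacing
    new_n = np.floor(extent / target_spacing + 1e-9).astype(int) + 1
    grids = [np.arange(n) * target_spacing / sp for n, sp in zip(new_n, vol.spacing)]
    ii, jj, kk = np.meshgrid(*grids, indexing="ij")
    values = ndimage.map_coordinates(
        vol.values, np.stack([ii, jj, kk]), order=1, mode="nearest"
    )
    return Volume3D(
        values=values,
        spacing=np.full(3, float(target_spacing)),
        origin=vol.origin.copy(),
    )


def extract_oblique_slice(vol: Volume3D, spec: ObliqueSliceSpec) -> GrayImage:
    """Sample an arbitrarily oriented plane through a volume (trilinear).

    Samples outside the volume read as 0 (air/black), so endoscopic planes
    near the boundary still render. A plane entirely outside the volume is an
    error.
    """
    pos = spec.pixel_positions()
    idx = vol.world_to_index(pos.reshape(-1, 3))
    n = np.array(vol.shape)
    inside = np.all((idx >= -0.5) & (idx <= n - 0.5), axis=1)
    if not inside.any():
        raise ValueError("slice plane lies entirely outside the volume")
    values = ndimage.map_coordinates(
        vol.values, idx.T, order=1, mode="constant", cval=0.0
    ).reshape(pos.shape[:2])
    return GrayImage(values=values, pixel_spacing=spec.pixel_spacing.copy())


def mask_to_black(img: GrayImage, mask: StructureMask) -> GrayImage:
    """Zero out masked pixels (e.g. the tumour contour made hypoechoic)."""
    if mask.values.shape != img.values.shape:
        raise ValueError(
            f"mask shape {mask.values.shape} != image shape {img.values.shape}"
        )
    out = img.values.copy()
    out[mask.values] = 0.0
    return GrayImage(out, img.pixel_spacing.copy(), img.origin.copy())


def median_filter(img: GrayImage, window: int = 5) -> GrayImage:
    """Square median filter with edge-replicated borders.

    The default 5x5 window is the speckle-noise smoothing applied to every
    simulated image before feature extraction.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    out = ndimage.median_filter(img.values, size=window, mode="nearest")
    return GrayImage(out, img.pixel_spacing.copy(), img.origin.copy())
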