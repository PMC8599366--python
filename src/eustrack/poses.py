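"""Candidate probe-pose grids.

Two pose schemes are provided:

* the phantom grid — for each sphere target, the imaging plane is shifted
  along the scan-channel (probe) axis at fixed intervals around the target's
  axial station and rotated in-plane about that axis (the probe sliding along
  and twisting inside the channel);
* the patient-MRI scheme — seven oblique planes per candidate injection
  point: the axial plane tilted +/-15 degrees about the right-left and the
  posterior-anterior axes (radial-scanning views), plus a plane perpendicular
  to the axial one and its +/-15 degree rotations (linear-scanning views).

Each pose stores the fully resolved :class:`ObliqueSliceSpec` so dictionary
indices are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .volumes import ObliqueSliceSpec

__all__ = ["ProbePose", "PoseGrid", "build_phantom_pose_grid", "build_mri_pose_set"]


def _rotation_matrix(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(degrees)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


@dataclass
class ProbePose:
    """One candidate probe position: a labelled imaging plane."""

    label: str
    target_id: str
    plane: ObliqueSliceSpec
    offset: float  # mm along the shift axis
    rotation: float  # degrees about rotation_axis
    rotation_axis: np.ndarray

    def __post_init__(self) -> None:
        self.rotation_axis = np.asarray(self.rotation_axis, dtype=float)
        if not -180.0 <= self.rotation <= 180.0:
            raise ValueError("rotation must lie in [-180, 180] degrees")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "target_id": self.target_id,
            "offset": self.offset,
            "rotation": self.rotation,
            "rotation_axis": self.rotation_axis.tolist(),
            "plane": {
                "center": self.plane.center.tolist(),
                "u_axis": self.plane.u_axis.tolist(),
                "v_axis": self.plane.v_axis.tolist(),
                "extent": self.plane.extent.tolist(),
                "pixel_spacing": self.plane.pixel_spacing.tolist(),
            },
        }


@dataclass
class PoseGrid:
    """Ordered pose list with per-target bookkeeping."""

    poses: list[ProbePose]

    def __post_init__(self) -> None:
        labels = [p.label for p in self.poses]
        if len(set(labels)) != len(labels):
            raise ValueError("pose labels must be unique")

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    def __getitem__(self, i: int) -> ProbePose:
        return self.poses[i]

    @property
    def per_target_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.poses:
            counts[p.target_id] = counts.get(p.target_id, 0) + 1
        return counts

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump([p.to_dict() for p in self.poses], fh, indent=1)


def _plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A fixed orthonormal (u, v) pair perpendicular to ``axis``."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def build_phantom_pose_grid(
    target_centers: np.ndarray,
    n_offsets: int = 10,
    offset_step: float = 5.0,
    rotations: tuple[float, ...] = (0.0, 15.0, -15.0),
    axis: np.ndarray = (0.0, 0.0, 1.0),
    axis_origin: np.ndarray = (0.0, 0.0, 0.0),
    extent: tuple[float, float] = (100.0, 100.0),
    pixel_spacing: tuple[float, float] | None = None,
    image_size: int = 128,
) -> PoseGrid:
    """The per-target shift/rotation grid of the phantom experiment.

    For every target, ``n_offsets`` plane positions spaced ``offset_step`` mm
    along the probe (scan-channel) ``axis`` are centred on the target's axial
    station (offset indices ``-n//2 .. n - n//2 - 1``), and each position is
    rendered at every in-plane ``rotation`` about that axis. Planes are
    centred on the channel axis — where the probe actually sits — and are
    normal to it. Pose order: target, then rotation, then offset.
    """
    if n_offsets < 1:
        raise ValueError("n_offsets must be >= 1")
    if offset_step <= 0:
        raise ValueError("offset_step must be > 0")
    if len(rotations) == 0:
        raise ValueError("rotations must be non-empty")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    axis_origin = np.asarray(axis_origin, dtype=float)
    centers = np.atleast_2d(np.asarray(target_centers, dtype=float))
    extent = np.asarray(extent, dtype=float)
    if pixel_spacing is None:
        pixel_spacing = extent / image_size
    pixel_spacing = np.asarray(pixel_spacing, dtype=float)
    u0, v0 = _plane_basis(axis)
    offs = (np.arange(n_offsets) - n_offsets // 2) * offset_step
    poses: list[ProbePose] = []
    for t, c in enumerate(centers):
        station = float((c - axis_origin) @ axis)
        for rot in rotations:
            R = _rotation_matrix(axis, rot)
            u, v = R @ u0, R @ v0
            for off in offs:
                center = axis_origin + (station + off) * axis
                plane = ObliqueSliceSpec(center, u, v, extent, pixel_spacing)
                poses.append(
                    ProbePose(
                        label=f"t{t}_r{rot:+.0f}_o{off:+.0f}",
                        target_id=f"target_{t}",
                        plane=plane,
                        offset=float(off),
                        rotation=float(rot),
                        rotation_axis=axis,
                    )
                )
    return PoseGrid(poses)


def build_mri_pose_set(
    injection_points: list[dict],
    extent: tuple[float, float] = (100.0, 100.0),
    pixel_spacing: tuple[float, float] | None = None,
    image_size: int = 128,
    tilt: float = 15.0,
) -> PoseGrid:
    """Seven oblique planes per candidate injection point.

    Each entry of ``injection_points`` is a mapping with ``center`` (mm) and
    orthonormal ``rl_axis`` (right-left), ``pa_axis`` (posterior-anterior)
    and ``axial_axis`` local directions. Per point: the axial plane tilted
    +/-``tilt`` degrees about R-L (2) and about P-A (2), plus the
    perpendicular plane spanned by the R-L and axial axes with rotations
    {0, +tilt, -tilt} about the axial axis (3) — 7 poses, 42 for the usual
    six-point set (two injection points with two neighbours each).
    """
    extent = np.asarray(extent, dtype=float)
    if pixel_spacing is None:
        pixel_spacing = extent / image_size
    pixel_spacing = np.asarray(pixel_spacing, dtype=float)
    poses: list[ProbePose] = []
    for p_idx, pt in enumerate(injection_points):
        center = np.asarray(pt["center"], dtype=float)
        rl = np.asarray(pt["rl_axis"], dtype=float)
        pa = np.asarray(pt["pa_axis"], dtype=float)
        ax = np.asarray(pt["axial_axis"], dtype=float)
        M = np.stack([rl, pa, ax])
        if np.max(np.abs(M @ M.T - np.eye(3))) > 1e-6:
            raise ValueError(f"axes of point {p_idx} are not orthonormal")
        pid = pt.get("name", f"point_{p_idx}")

        def add(label, u, v, rot, rot_axis):
            poses.append(
                ProbePose(
                    label=f"{pid}_{label}",
                    target_id=pid,
                    plane=ObliqueSliceSpec(center, u, v, extent, pixel_spacing),
                    offset=0.0,
                    rotation=rot,
                    rotation_axis=rot_axis,
                )
            )

        for rot in (tilt, -tilt):  # radial-like: axial plane tilted about R-L
            R = _rotation_matrix(rl, rot)
            add(f"rl{rot:+.0f}", R @ rl, R @ pa, rot, rl)
        for rot in (tilt, -tilt):  # radial-like: axial plane tilted about P-A
            R = _rotation_matrix(pa, rot)
            add(f"pa{rot:+.0f}", R @ rl, R @ pa, rot, pa)
        for rot in (0.0, tilt, -tilt):  # linear-like: perpendicular plane
            R = _rotation_matrix(ax, rot)
            add(f"perp{rot:+.0f}", R @ rl, R @ ax, rot, ax)
    return PoseGrid(poses)
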