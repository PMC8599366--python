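"""Point-scatterer phantoms and synthetic fixture volumes.

Ultrasound speckle arises from coherent summation of echoes from sub-
resolution scatterers. We model tissue as a cloud of point scatterers with
Gaussian-distributed amplitudes whose standard deviation follows local
echogenicity: echogenic sphere targets get a boosted amplitude factor, the
fluid-filled scan channel scatters nothing, background tissue sits at factor
1. Two construction routes are provided, mirroring how a geometric training
phantom versus a patient slice bitmap would be turned into a scatter phantom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import GrayImage, ObliqueSliceSpec, StructureMask, Volume3D

__all__ = [
    "GeometricPhantomSpec",
    "ScattererField",
    "training_phantom_spec",
    "sample_geometric_scatterers",
    "sample_bitmap_scatterers",
    "generate_toy_volume",
]


@dataclass
class GeometricPhantomSpec:
    """Geometry of an EUS training phantom.

    ``spheres`` is a list of ``(center_mm, radius_mm, amplitude_factor)``;
    ``channel`` is ``(point_on_axis_mm, axis_direction, radius_mm)`` for the
    cylindrical scan-channel void. Region priority where shapes overlap:
    channel > sphere > background.
    """

    box_low: np.ndarray
    box_high: np.ndarray
    spheres: list[tuple[np.ndarray, float, float]]
    channel: tuple[np.ndarray, np.ndarray, float] | None = None
    background_amplitude: float = 1.0

    def __post_init__(self) -> None:
        self.box_low = np.asarray(self.box_low, dtype=float)
        self.box_high = np.asarray(self.box_high, dtype=float)
        if np.any(self.box_high <= self.box_low):
            raise ValueError("box_high must exceed box_low on every axis")
        if self.background_amplitude < 0:
            raise ValueError("amplitude factors must be >= 0")
        spheres = []
        for center, radius, amp in self.spheres:
            center = np.asarray(center, dtype=float)
            if radius <= 0:
                raise ValueError("sphere radii must be > 0")
            if amp < 0:
                raise ValueError("amplitude factors must be >= 0")
            if np.any(center - radius < self.box_low) or np.any(
                center + radius > self.box_high
            ):
                raise ValueError("spheres must lie inside the box")
            spheres.append((center, float(radius), float(amp)))
        self.spheres = spheres
        if self.channel is not None:
            point, axis, radius = self.channel
            axis = np.asarray(axis, dtype=float)
            axis = axis / np.linalg.norm(axis)
            if radius <= 0:
                raise ValueError("channel radius must be > 0")
            self.channel = (np.asarray(point, dtype=float), axis, float(radius))

    def amplitude_factor(self, points: np.ndarray) -> np.ndarray:
        """Per-point echogenicity factor with channel > sphere > background."""
        pts = np.atleast_2d(points)
        fac = np.full(len(pts), self.background_amplitude)
        for center, radius, amp in self.spheres:
            inside = np.sum((pts - center) ** 2, axis=1) <= radius**2
            fac[inside] = amp
        if self.channel is not None:
            point, axis, radius = self.channel
            rel = pts - point
            radial = rel - np.outer(rel @ axis, axis)
            fac[np.sum(radial**2, axis=1) <= radius**2] = 0.0
        return fac


@dataclass
class ScattererField:
    """Point scatterers (mm) with unitless amplitudes inside a bounding box."""

    positions: np.ndarray
    amplitudes: np.ndarray
    bounds: tuple[np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float).reshape(-1)
        low = np.asarray(self.bounds[0], dtype=float)
        high = np.asarray(self.bounds[1], dtype=float)
        self.bounds = (low, high)
        if len(self.positions) != len(self.amplitudes):
            raise ValueError("positions and amplitudes must have equal length")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        if len(self.positions) and (
            np.any(self.positions < low - 1e-9) or np.any(self.positions > high + 1e-9)
        ):
            raise ValueError("all positions must lie within bounds")

    def __len__(self) -> int:
        return len(self.positions)

    def to_csv(self, path: str) -> None:
        data = np.column_stack([self.positions, self.amplitudes])
        np.savetxt(path, data, delimiter=",", header="x,y,z,amplitude", comments="")

    @classmethod
    def from_csv(cls, path: str) -> "ScattererField":
        data = np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))
        pos = data[:, :3]
        low = pos.min(axis=0) if len(pos) else np.zeros(3)
        high = pos.max(axis=0) if len(pos) else np.ones(3)
        return cls(pos, data[:, 3], (low, high))


# --- default training-phantom geometry -------------------------------------
#
# Four echogenic 5-mm-radius sphere targets distributed around a 25-mm-radius
# central scan channel in homogeneous tissue-mimicking background. Sphere
# azimuths are jittered around the quadrant directions (keeping pairwise
# separation), radial stations fall outside the channel, and axial stations
# cluster within a few mm of mid-height so that a single probe plane can image
# all four targets at once — as in the training phantom, where every target is
# reachable from the scan channel.

_PHANTOM_Z_JITTER = np.array([0.0, 1.0, -1.0, 2.0])  # mm, per target


def training_phantom_spec(
    seed: int = 0,
    sphere_radius: float = 5.0,
    channel_radius: float = 25.0,
    sphere_amplitude: float = 6.0,
) -> GeometricPhantomSpec:
    """Seeded geometry of the four-target EUS training phantom stand-in."""
    rng = np.random.default_rng(seed)
    box_low = np.array([-50.0, -50.0, 0.0])
    box_high = np.array([50.0, 50.0, 90.0])
    z_mid = 45.0
    spheres = []
    for t in range(4):
        theta = np.deg2rad(90.0 * t + rng.uniform(-20.0, 20.0))
        rho = rng.uniform(channel_radius + sphere_radius + 4.0, 42.0)
        center = np.array(
            [rho * np.cos(theta), rho * np.sin(theta), z_mid + _PHANTOM_Z_JITTER[t]]
        )
        spheres.append((center, sphere_radius, sphere_amplitude))
    return GeometricPhantomSpec(
        box_low=box_low,
        box_high=box_high,
        spheres=spheres,
        channel=(np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]), channel_radius),
    )


def sample_geometric_scatterers(
    spec: GeometricPhantomSpec, density: float, seed: int
) -> ScattererField:
    """Draw a uniform scatterer cloud over the phantom box.

    ``density`` is scatterers per mm^3; amplitudes are standard-normal draws
    multiplied by the region's echogenicity factor. Fully reproducible for a
    fixed seed.
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    rng = np.random.default_rng(seed)
    volume = float(np.prod(spec.box_high - spec.box_low))
    n = int(round(density * volume))
    positions = rng.uniform(spec.box_low, spec.box_high, size=(n, 3))
    amplitudes = rng.standard_normal(n) * spec.amplitude_factor(positions)
    return ScattererField(positions, amplitudes, (spec.box_low, spec.box_high))


def sample_bitmap_scatterers(
    img: GrayImage,
    n: int,
    seed: int,
    slab_thickness: float = 5.0,
    plane: ObliqueSliceSpec | None = None,
) -> ScattererField:
    """Scatterers for a slice bitmap: intensity sets the amplitude factor.

    Scatterer positions are uniform over the image extent crossed with an
    elevation slab of ``slab_thickness`` mm. The factor is the bitmap value
    at the scatterer's in-plane position linearly rescaled to [0, 1]
    (zero stays zero), multiplying a standard-normal amplitude draw — so dark
    regions (e.g. a blacked-out tumour) scatter nothing and bright regions
    scatter strongly.

    If ``plane`` is given, positions are returned in the world frame of that
    plane; otherwise in a local frame with u = x, v = y, elevation = z,
    centred at the origin.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if img.values.size == 0:
        raise ValueError("img must be non-empty")
    if slab_thickness <= 0:
        raise ValueError("slab_thickness must be > 0")
    rng = np.random.default_rng(seed)
    nv, nu = img.shape
    du, dv = img.pixel_spacing
    extent_u, extent_v = nu * du, nv * dv
    u = rng.uniform(-extent_u / 2, extent_u / 2, size=n)
    v = rng.uniform(-extent_v / 2, extent_v / 2, size=n)
    w = rng.uniform(-slab_thickness / 2, slab_thickness / 2, size=n)
    # nearest-pixel bitmap lookup
    col = np.clip(np.round((u + extent_u / 2) / du - 0.5).astype(int), 0, nu - 1)
    row = np.clip(np.round((v + extent_v / 2) / dv - 0.5).astype(int), 0, nv - 1)
    vals = img.values[row, col]
    vmax = float(img.values.max())
    factor = np.clip(vals, 0.0, None) / vmax if vmax > 0 else np.zeros(n)
    amplitudes = rng.standard_normal(n) * factor
    if plane is None:
        positions = np.column_stack([u, v, w])
        low = np.array([-extent_u / 2, -extent_v / 2, -slab_thickness / 2])
        high = -low
        return ScattererField(positions, amplitudes, (low, high))
    positions = (
        plane.center
        + u[:, None] * plane.u_axis
        + v[:, None] * plane.v_axis
        + w[:, None] * plane.normal
    )
    low = positions.min(axis=0)
    high = positions.max(axis=0)
    return ScattererField(positions, amplitudes, (low, high))


def _sphere_mask(shape, spacing, origin, center, radius) -> np.ndarray:
    grids = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    xx, yy, zz = np.meshgrid(*grids, indexing="ij")
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (
        zz - center[2]
    ) ** 2 <= radius**2


def generate_toy_volume(
    kind: str, seed: int = 0, n_hydrogel: int = 3, spacing: float = 1.0
) -> tuple[Volume3D, list[StructureMask]]:
    """Synthetic stand-in volumes for the two study settings.

    ``eus_training_phantom``
        Homogeneous background with four bright 5-mm-radius spheres around a
        25-mm-radius central channel (CT of the training phantom).
    ``abdomen_like``
        Smooth textured background with one hypointense "tumor" ellipsoid, a
        bright "marker" dot inside it, and ``n_hydrogel`` bright "hydrogel"
        blobs (patient CT/MRI appearance).

    Returns the volume plus one :class:`StructureMask` per structure.
    """
    rng = np.random.default_rng(seed)
    if kind == "eus_training_phantom":
        spec = training_phantom_spec(seed=seed)
        shape = tuple(
            int(round((hi - lo) / spacing)) + 1
            for lo, hi in zip(spec.box_low, spec.box_high)
        )
        sp = np.full(3, spacing)
        vol = np.full(shape, 100.0)
        masks: list[StructureMask] = []
        for t, (center, radius, _) in enumerate(spec.spheres):
            m = _sphere_mask(shape, sp, spec.box_low, center, radius)
            vol[m] = 255.0
            masks.append(StructureMask(f"sphere_{t}", m))
        point, axis, radius = spec.channel
        grids = [spec.box_low[a] + np.arange(shape[a]) * sp[a] for a in range(3)]
        xx, yy, zz = np.meshgrid(*grids, indexing="ij")
        ch = (xx - point[0]) ** 2 + (yy - point[1]) ** 2 <= radius**2
        vol[ch] = 0.0
        masks.append(StructureMask("channel", ch))
        return Volume3D(vol, sp, spec.box_low.copy()), masks
    if kind == "abdomen_like":
        shape = (
            int(round(100 / spacing)) + 1,
            int(round(100 / spacing)) + 1,
            int(round(60 / spacing)) + 1,
        )
        sp = np.full(3, spacing)
        origin = np.array([-50.0, -50.0, 0.0])
        base = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=8.0 / spacing)
        base = 110.0 + 40.0 * base / max(np.abs(base).max(), 1e-12)
        grids = [origin[a] + np.arange(shape[a]) * sp[a] for a in range(3)]
        xx, yy, zz = np.meshgrid(*grids, indexing="ij")
        masks = []
        tumor_c = np.array([rng.uniform(-10, 10), rng.uniform(-10, 10), 30.0])
        axes = np.array([15.0, 12.0, 10.0])
        tumor = (
            ((xx - tumor_c[0]) / axes[0]) ** 2
            + ((yy - tumor_c[1]) / axes[1]) ** 2
            + ((zz - tumor_c[2]) / axes[2]) ** 2
        ) <= 1.0
        base[tumor] = 30.0
        masks.append(StructureMask("tumor", tumor))
        marker = _sphere_mask(shape, sp, origin, tumor_c, 1.5)
        base[marker] = 255.0
        masks.append(StructureMask("marker", marker))
        for h in range(n_hydrogel):
            theta = rng.uniform(0, 2 * np.pi)
            c = tumor_c + np.array(
                [20.0 * np.cos(theta), 20.0 * np.sin(theta), rng.uniform(-5, 5)]
            )
            blob = _sphere_mask(shape, sp, origin, c, rng.uniform(3.0, 5.0))
            base[blob] = 230.0
            masks.append(StructureMask(f"hydrogel_{h}", blob))
        return Volume3D(base, sp, origin), masks
    raise ValueError(f"unknown toy volume kind: {kind!r}")
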