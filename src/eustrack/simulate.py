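"""Convolution-model B-mode ultrasound simulator.

Renders a 2D B-mode image of a :class:`~eustrack.phantom.ScattererField` for
a given probe geometry and imaging plane. The full spatial-impulse-response
physics of array simulation is deliberately replaced by a separable
point-spread-function model:

* axial: Gaussian-modulated sinusoid at the probe centre frequency,
* lateral: Gaussian beam profile about each scanline (optionally widening
  linearly with depth, as an unfocused beam does),
* elevation: Gaussian-weighted slab selection around the imaging plane.

Scatterers inside the elevation slab are projected into plane coordinates and
deposited onto a fine RF grid (one line per scanline, axial samples at an
eighth of a wavelength); each line is convolved with the axial pulse, envelope
detection uses the analytic-signal magnitude, and the result is max-normalised
and log-compressed into the display dynamic range. Curvilinear arrays are
scan-converted from (beam angle, depth) fan coordinates to Cartesian pixels.

Speckle statistics and target geometry — what dictionary matching consumes —
are reproduced; diffraction detail is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .phantom import ScattererField
from .volumes import GrayImage, ObliqueSliceSpec

__all__ = [
    "ProbeSpec",
    "PSFModel",
    "BModeImage",
    "make_probe_preset",
    "simulate_bmode",
    "simulate_envelope",
    "scan_convert",
]

_EPS = 1e-12


@dataclass
class ProbeSpec:
    """Array geometry and pulse parameters of the simulated probe."""

    geometry: str  # "linear" | "curvilinear"
    n_elements: int
    center_frequency: float  # Hz
    element_width: float  # mm
    element_height: float  # mm
    pitch: float = 0.0  # mm, linear arrays
    array_radius: float = 0.0  # mm, curvilinear arrays
    angular_span: float = 0.0  # degrees, curvilinear arrays
    n_scanlines: int = 128
    speed_of_sound: float = 1.54e6  # mm/s
    fractional_bandwidth: float = 0.6

    def __post_init__(self) -> None:
        if self.geometry not in ("linear", "curvilinear"):
            raise ValueError(f"unknown probe geometry: {self.geometry!r}")
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be > 0")
        if self.n_elements < 2:
            raise ValueError("n_elements must be >= 2")
        if self.n_scanlines < 2:
            raise ValueError("n_scanlines must be >= 2")
        if not 0 < self.fractional_bandwidth <= 2:
            raise ValueError("fractional_bandwidth must be in (0, 2]")

    @property
    def wavelength(self) -> float:
        """Acoustic wavelength c/f in mm."""
        return self.speed_of_sound / self.center_frequency

    @property
    def aperture(self) -> float:
        """Active aperture width in mm."""
        if self.geometry == "linear":
            pitch = self.pitch if self.pitch > 0 else self.element_width
            return self.n_elements * pitch
        return 2 * self.array_radius * np.sin(np.deg2rad(self.angular_span) / 2)


@dataclass
class PSFModel:
    """Separable point-spread-function parameters.

    ``lateral_sigma`` of ``None`` selects the depth-dependent rule
    ``clip(depth * wavelength / aperture, lateral_sigma_min,
    lateral_sigma_max)``; a positive number fixes it.
    """

    lateral_sigma: float | None = None
    lateral_sigma_min: float = 0.3  # mm
    lateral_sigma_max: float = 2.0  # mm
    elevation_slab: float = 5.0  # mm

    def __post_init__(self) -> None:
        if self.lateral_sigma is not None and self.lateral_sigma <= 0:
            raise ValueError("lateral_sigma must be > 0")
        if self.elevation_slab <= 0:
            raise ValueError("elevation_slab must be > 0")

    def lateral_sigma_at(self, depth, probe: ProbeSpec):
        if self.lateral_sigma is not None:
            return np.full_like(np.asarray(depth, dtype=float), self.lateral_sigma)
        sig = np.asarray(depth, dtype=float) * probe.wavelength / probe.aperture
        return np.clip(sig, self.lateral_sigma_min, self.lateral_sigma_max)


@dataclass
class BModeImage:
    """Log-compressed B-mode display image mapped to [0, 255]."""

    values: np.ndarray
    pixel_spacing: np.ndarray
    dynamic_range: float
    plane: ObliqueSliceSpec | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pixel_spacing = np.asarray(self.pixel_spacing, dtype=float)
        if self.values.min() < -1e-9 or self.values.max() > 255 + 1e-9:
            raise ValueError("B-mode values must lie in [0, 255]")
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be > 0")

    def to_gray(self) -> GrayImage:
        return GrayImage(self.values.copy(), self.pixel_spacing.copy())


_PRESETS = {
    # linear endoscopic probe: 128 elements at 7.5 MHz, 0.29 x 0.41 mm elements
    "endoscopic_linear": dict(
        geometry="linear",
        n_elements=128,
        center_frequency=7.5e6,
        element_width=0.29,
        element_height=0.41,
        pitch=0.29,
        n_scanlines=128,
    ),
    # curvilinear endoscopic probe: 159 elements on a 91.1 mm radius,
    # reconstructed over 128 scanlines
    "endoscopic_curvilinear": dict(
        geometry="curvilinear",
        n_elements=159,
        center_frequency=7.5e6,
        element_width=0.29,
        element_height=0.41,
        array_radius=91.1,
        angular_span=60.0,
        n_scanlines=128,
    ),
}


def make_probe_preset(name: str) -> ProbeSpec:
    """Return one of the built-in endoscopic probe definitions."""
    if name not in _PRESETS:
        raise ValueError(
            f"unknown probe preset {name!r}; choose from {sorted(_PRESETS)}"
        )
    return ProbeSpec(**_PRESETS[name])


def _axial_pulse(probe: ProbeSpec, dz: float) -> np.ndarray:
    """Gaussian-modulated sinusoid sampled at dz (mm), unit peak."""
    lam = probe.wavelength
    sigma_z = lam * np.sqrt(2 * np.log(2)) / (np.pi * probe.fractional_bandwidth)
    half = int(np.ceil(4 * sigma_z / dz))
    z = np.arange(-half, half + 1) * dz
    return np.exp(-(z**2) / (2 * sigma_z**2)) * np.cos(2 * np.pi * z / lam)


def simulate_envelope(
    field: ScattererField,
    probe: ProbeSpec,
    psf: PSFModel,
    plane: ObliqueSliceSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Envelope-detected RF grid for an imaging plane.

    Returns ``(envelope, depth_axis_mm, line_axis)`` where ``envelope`` has
    shape (n_depth, n_scanlines). For linear probes ``line_axis`` is the
    lateral position of each scanline in plane-u coordinates (mm); for
    curvilinear probes it is the beam angle in degrees and depth is measured
    from the array face along each ray.

    The probe face sits on the top edge of the plane (v = -extent_v/2) with
    depth increasing along +v.
    """
    extent_u, extent_v = plane.extent
    dz = probe.wavelength / 8.0
    n_depth = int(np.ceil(extent_v / dz)) + 1
    n_lines = probe.n_scanlines

    uvw = plane.plane_coords(field.positions) if len(field) else np.zeros((0, 3))
    sigma_e = psf.elevation_slab / 4.0
    if len(field):
        in_slab = np.abs(uvw[:, 2]) <= psf.elevation_slab / 2.0
        uvw = uvw[in_slab]
        amps = field.amplitudes[in_slab] * np.exp(
            -(uvw[:, 2] ** 2) / (2 * sigma_e**2)
        )
    else:
        amps = np.zeros(0)

    rf = np.zeros((n_depth, n_lines))
    if probe.geometry == "linear":
        line_axis = (np.arange(n_lines) + 0.5) / n_lines * extent_u - extent_u / 2
        line_pitch = extent_u / n_lines
        u = uvw[:, 0]
        depth = uvw[:, 1] + extent_v / 2.0
        keep = (depth >= 0) & (depth <= extent_v)
        u, depth, amps = u[keep], depth[keep], amps[keep]
        sig = psf.lateral_sigma_at(depth, probe)
        lat_index = (u - line_axis[0]) / line_pitch
        _deposit(rf, depth / dz, lat_index, amps, sig / line_pitch, n_lines)
    else:
        span = np.deg2rad(probe.angular_span)
        angles = (np.arange(n_lines) + 0.5) / n_lines * span - span / 2
        dtheta = span / n_lines
        apex_v = -extent_v / 2.0 - probe.array_radius
        du_ = uvw[:, 0]
        dv_ = uvw[:, 1] - apex_v
        theta = np.arctan2(du_, dv_)
        rng_ = np.hypot(du_, dv_)
        depth = rng_ - probe.array_radius
        keep = (depth >= 0) & (depth <= extent_v) & (np.abs(theta) <= span / 2)
        theta, rng_, depth, amps = theta[keep], rng_[keep], depth[keep], amps[keep]
        sig = psf.lateral_sigma_at(depth, probe)
        # lateral Gaussian measured as arc length at the scatterer's range
        lat_index = (theta - angles[0]) / dtheta
        _deposit(rf, depth / dz, lat_index, amps, sig / (dtheta * rng_), n_lines)
        line_axis = np.rad2deg(angles)
    pulse = _axial_pulse(probe, dz)
    rf = signal.fftconvolve(rf, pulse[:, None], mode="same", axes=0)
    env = np.abs(signal.hilbert(rf, axis=0))
    depth_axis = np.arange(n_depth) * dz
    return env, depth_axis, line_axis


def _deposit(rf, depth_idx, lat_idx, amps, sigma_idx, n_lines) -> None:
    """Scatter amplitudes onto the RF grid: Gaussian in the lateral index,
    linear interpolation between the two nearest axial samples."""
    if len(amps) == 0:
        return
    n_depth = rf.shape[0]
    g0 = np.floor(depth_idx).astype(int)
    frac = depth_idx - g0
    g0 = np.clip(g0, 0, n_depth - 1)
    g1 = np.clip(g0 + 1, 0, n_depth - 1)
    k_max = int(np.ceil(3 * np.max(sigma_idx))) if len(amps) else 0
    j_near = np.round(lat_idx).astype(int)
    flat = rf.ravel()
    for k in range(-k_max, k_max + 1):
        j = j_near + k
        ok = (j >= 0) & (j < n_lines)
        if not ok.any():
            continue
        w = amps[ok] * np.exp(
            -((j[ok] - lat_idx[ok]) ** 2) / (2 * sigma_idx[ok] ** 2)
        )
        np.add.at(flat, g0[ok] * n_lines + j[ok], w * (1 - frac[ok]))
        np.add.at(flat, g1[ok] * n_lines + j[ok], w * frac[ok])


def _log_compress(env: np.ndarray, dynamic_range: float) -> np.ndarray:
    """Max-normalised dB mapping of an envelope onto [0, 255]."""
    peak = env.max()
    if peak <= 0:
        return np.zeros_like(env)
    db = 20.0 * np.log10(np.maximum(env / peak, _EPS))
    return np.clip((db + dynamic_range) / dynamic_range, 0.0, 1.0) * 255.0


def simulate_bmode(
    field: ScattererField,
    probe: ProbeSpec,
    psf: PSFModel,
    plane: ObliqueSliceSpec,
    image_size: int | tuple[int, int] = 128,
    dynamic_range: float = 60.0,
) -> BModeImage:
    """Render the B-mode image of a scatterer field on an imaging plane.

    ``image_size`` fixes the output pixel grid (rows, cols) over the plane's
    physical extent; pixel spacing is ``extent / image_size``. An empty
    in-slab scatterer set is valid and yields the minimum-intensity image.
    Because the envelope is max-normalised before log compression, globally
    rescaling all scatterer amplitudes leaves the image unchanged.
    """
    if isinstance(image_size, int):
        image_size = (image_size, image_size)
    nv, nu = image_size
    extent_u, extent_v = plane.extent
    pixel_spacing = np.array([extent_u / nu, extent_v / nv])

    env, depth_axis, line_axis = simulate_envelope(field, probe, psf, plane)
    if probe.geometry == "linear":
        # rows at pixel-centre depths, columns at pixel-centre lateral positions
        rows_mm = (np.arange(nv) + 0.5) * pixel_spacing[1]
        cols_mm = (np.arange(nu) + 0.5) * pixel_spacing[0] - extent_u / 2
        dz = depth_axis[1] - depth_axis[0]
        line_pitch = line_axis[1] - line_axis[0]
        ri = rows_mm / dz
        ci = (cols_mm - line_axis[0]) / line_pitch
        rr, cc = np.meshgrid(ri, ci, indexing="ij")
        img_env = ndimage.map_coordinates(
            env, np.stack([rr, cc]), order=1, mode="nearest"
        )
        values = _log_compress(img_env, dynamic_range)
    else:
        polar = _log_compress(env, dynamic_range)
        values = _fan_to_grid(
            polar, probe, depth_axis, nv, nu, pixel_spacing, extent_u, extent_v
        )
    return BModeImage(values, pixel_spacing, dynamic_range, plane)


def _fan_to_grid(polar, probe, depth_axis, nv, nu, pixel_spacing, extent_u, extent_v):
    """Resample a (depth, angle) fan onto a Cartesian grid of given shape.

    The fan apex (centre of array curvature) sits ``array_radius`` behind the
    array face, which is at depth 0 on the grid's top edge centre.
    """
    span = np.deg2rad(probe.angular_span)
    n_lines = polar.shape[1]
    dtheta = span / n_lines
    theta0 = -span / 2 + dtheta / 2
    dz = depth_axis[1] - depth_axis[0]
    x = (np.arange(nu) + 0.5) * pixel_spacing[0] - extent_u / 2
    y = (np.arange(nv) + 0.5) * pixel_spacing[1]
    xx, yy = np.meshgrid(x, y)
    yc = yy + probe.array_radius
    r = np.hypot(xx, yc)
    theta = np.arctan2(xx, yc)
    depth = r - probe.array_radius
    ri = depth / dz
    ci = (theta - theta0) / dtheta
    out = ndimage.map_coordinates(polar, np.stack([ri, ci]), order=1, cval=0.0)
    outside = (
        (np.abs(theta) > span / 2)
        | (depth < 0)
        | (depth > depth_axis[-1])
    )
    out[outside] = 0.0
    return out


def scan_convert(
    polar: np.ndarray, probe: ProbeSpec, pixel_spacing: float | tuple[float, float],
    depth_spacing: float | None = None,
) -> BModeImage:
    """Scan-convert a (depth, angle) polar grid to a Cartesian B-mode image.

    ``polar`` rows run over depth from the array face, columns over beam angle
    across ``probe.angular_span``. ``depth_spacing`` is the mm per polar row
    (defaults to one wavelength). Pixels outside the fan are 0.
    """
    if probe.geometry != "curvilinear":
        raise ValueError("scan_convert requires a curvilinear probe")
    if np.isscalar(pixel_spacing):
        pixel_spacing = (float(pixel_spacing), float(pixel_spacing))
    pixel_spacing = np.asarray(pixel_spacing, dtype=float)
    if depth_spacing is None:
        depth_spacing = probe.wavelength
    n_depth = polar.shape[0]
    max_depth = (n_depth - 1) * depth_spacing
    half_span = np.deg2rad(probe.angular_span) / 2
    half_width = (probe.array_radius + max_depth) * np.sin(half_span)
    nu = int(np.ceil(2 * half_width / pixel_spacing[0]))
    nv = int(np.ceil(max_depth / pixel_spacing[1]))
    depth_axis = np.arange(n_depth) * depth_spacing
    values = _fan_to_grid(
        np.asarray(polar, dtype=float), probe, depth_axis, nv, nu,
        pixel_spacing, 2 * half_width, max_depth,
    )
    values = np.clip(values, 0.0, 255.0)
    return BModeImage(values, pixel_spacing, 60.0, None)
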