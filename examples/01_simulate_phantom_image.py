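"""Simulate one endoscopic B-mode image of the training phantom.

Builds the four-sphere training-phantom geometry, scatters it, and renders
the probe plane that passes through the first target's axial station. The
printed numbers are the image's intensity range (log-compressed display
units) and the in-plane positions of the four echogenic spheres.
"""

import numpy as np

import eustrack as et

spec = et.training_phantom_spec(seed=0)
field = et.sample_geometric_scatterers(spec, density=1.0, seed=42)
centers = np.array([c for c, _, _ in spec.spheres])
grid = et.build_phantom_pose_grid(centers, n_offsets=1, rotations=(0.0,))

probe = et.make_probe_preset("endoscopic_linear")
image = et.simulate_bmode(field, probe, et.PSFModel(), grid[0].plane, 128)

print(f"probe: {probe.n_elements} elements at {probe.center_frequency/1e6} MHz")
print(f"image: {image.values.shape}, {image.pixel_spacing[0]:.2f} mm/px, "
      f"intensities {image.values.min():.0f}-{image.values.max():.0f}")
print("sphere positions in the plane (u = lateral, v = axial, mm):")
for k, c in enumerate(centers):
    u, v, w = grid[0].plane.plane_coords(c[None])[0]
    print(f"  sphere {k}: u = {u:+6.1f}, v = {v:+6.1f} (out-of-plane {w:+.1f})")
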