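"""Candidate pose planes for hydrogel injection points on MRI.

For each candidate injection point the scheme generates seven oblique
planes: the axial plane tilted +/-15 degrees about the right-left and
posterior-anterior axes (radial-scanning views) and a perpendicular plane
with its +/-15 degree rotations (linear-scanning views). Two injection
points with two neighbours each give the standard 6-point, 42-plane set.
"""

import numpy as np

from eustrack.poses import build_mri_pose_set

points = [
    {
        "name": f"p{k}",
        "center": [10.0 * k - 25.0, 5.0 * (k % 2), 30.0],
        "rl_axis": [1.0, 0.0, 0.0],
        "pa_axis": [0.0, 1.0, 0.0],
        "axial_axis": [0.0, 0.0, 1.0],
    }
    for k in range(6)
]
grid = build_mri_pose_set(points)
print(f"{len(points)} injection points -> {len(grid)} candidate planes")
print("planes for point p0:")
for pose in grid:
    if pose.target_id == "p0":
        n = np.round(pose.plane.normal, 3)
        print(f"  {pose.label:12s} rotation {pose.rotation:+5.1f} deg, "
              f"normal {n}")
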