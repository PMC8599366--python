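"""Shared fixtures.

The full-size phantom dictionary (4 targets x 30 poses at default density)
is expensive to build, so it is session-scoped and shared by the matcher,
evaluation and acceptance tests. Fast unit tests use the small scene.
"""

from __future__ import annotations

import numpy as np
import pytest

from eustrack.config import RunConfig
from eustrack.pipeline import build_phantom_dictionary


@pytest.fixture(scope="session")
def default_cfg() -> RunConfig:
    # pose index 5 = first target, zero rotation, zero offset: the plane
    # through the target stations where all four spheres are visible
    return RunConfig(target_pose_index=5)


@pytest.fixture(scope="session")
def phantom_dictionary(default_cfg):
    """(FeatureDictionary, (spec, grid, probe, psf, basis)) at defaults."""
    return build_phantom_dictionary(default_cfg)


@pytest.fixture(scope="session")
def small_scene():
    """A cheap single-target scene for fast pipeline unit tests."""
    import eustrack as et

    spec = et.training_phantom_spec(seed=3)
    centers = np.array([c for c, _, _ in spec.spheres])
    grid = et.build_phantom_pose_grid(
        centers[:1], n_offsets=2, offset_step=5.0, rotations=(0.0, 15.0),
        extent=(100.0, 100.0), image_size=64,
    )
    probe = et.make_probe_preset("endoscopic_linear")
    psf = et.PSFModel()
    field = et.sample_geometric_scatterers(spec, 0.5, seed=11)
    basis = et.HaarBasisSet(scales=(0, 1, 2), match_size=64)
    return spec, grid, probe, psf, field, basis


@pytest.fixture(scope="session")
def small_dictionary(small_scene):
    import eustrack as et

    spec, grid, probe, psf, field, basis = small_scene
    return et.build_dictionary(field, grid, probe, psf, basis, image_size=64)
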