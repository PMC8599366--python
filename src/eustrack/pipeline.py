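"""End-to-end phantom pipeline assembled from a :class:`RunConfig`.

Thin glue used by the command-line interface, the examples and the
reproducibility script: build the scene, the pose grid, the dictionary, a
noisy off-dictionary target, and score the match.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .evaluate import make_noisy_target, phantom_trial
from .haar import FeatureDictionary, HaarBasisSet, build_dictionary
from .phantom import (
    GeometricPhantomSpec,
    sample_geometric_scatterers,
    training_phantom_spec,
)
from .poses import PoseGrid, build_phantom_pose_grid
from .simulate import PSFModel, ProbeSpec, make_probe_preset

__all__ = ["assemble_scene", "build_phantom_dictionary", "run_phantom_localization"]


def assemble_scene(
    cfg: RunConfig,
) -> tuple[GeometricPhantomSpec, PoseGrid, ProbeSpec, PSFModel, HaarBasisSet]:
    """Phantom spec, pose grid, probe, PSF and Haar basis for a config."""
    spec = training_phantom_spec(
        seed=cfg.phantom_seed, sphere_amplitude=cfg.sphere_amplitude
    )
    centers = np.array([c for c, _, _ in spec.spheres])
    grid = build_phantom_pose_grid(
        centers,
        n_offsets=cfg.n_offsets,
        offset_step=cfg.offset_step_mm,
        rotations=tuple(cfg.rotations_deg),
        extent=tuple(cfg.plane_extent_mm),
        image_size=cfg.match_size,
    )
    probe = make_probe_preset(cfg.probe_preset)
    psf = PSFModel(
        lateral_sigma=cfg.lateral_sigma_mm, elevation_slab=cfg.elevation_slab_mm
    )
    basis = HaarBasisSet(
        scales=tuple(cfg.scales),
        base_support=cfg.base_support,
        stride_factor=cfg.stride_factor,
        match_size=cfg.match_size,
        template_ids=tuple(range(cfg.n_templates)),
    )
    return spec, grid, probe, psf, basis


def build_phantom_dictionary(cfg: RunConfig) -> tuple[FeatureDictionary, tuple]:
    """Scatter the phantom and build the full pose dictionary."""
    spec, grid, probe, psf, basis = assemble_scene(cfg)
    field = sample_geometric_scatterers(
        spec, cfg.scatterer_density_per_mm3, cfg.dictionary_seed
    )
    dictionary = build_dictionary(
        field,
        grid,
        probe,
        psf,
        basis,
        image_size=cfg.match_size,
        median_window=cfg.median_window,
        dynamic_range=cfg.dynamic_range_db,
    )
    return dictionary, (spec, grid, probe, psf, basis)


def run_phantom_localization(cfg: RunConfig, dictionary=None, scene=None):
    """Full localization trial: noisy re-seeded self-target, match, markers.

    Returns ``(match_result, marker_report, target_index)``.
    """
    if dictionary is None or scene is None:
        dictionary, scene = build_phantom_dictionary(cfg)
    spec, grid, probe, psf, basis = scene
    k = cfg.target_pose_index
    target = make_noisy_target(
        spec,
        grid[k].plane,
        probe,
        psf,
        cfg.scatterer_density_per_mm3,
        scatterer_seed=cfg.target_seed,
        noise_seed=cfg.noise_seed,
        noise_sigma=cfg.noise_sigma,
        image_size=cfg.match_size,
        dynamic_range=cfg.dynamic_range_db,
    )
    result, report = phantom_trial(
        dictionary, basis, target, n_markers=cfg.n_markers,
        median_window=cfg.median_window,
    )
    return result, report, k
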