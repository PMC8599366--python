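"""Haar-like feature extraction and the pose-tagged feature dictionary.

An image is encoded as an ordered vector of Haar-like feature responses
``V(s, t) = <I, phi_{s,t}>``: dot products of the image with rectangular
difference templates ``phi`` placed at dyadic scales ``s`` (support size
``base_support * 2**s``) and translations ``t``. Every response is computed
in constant time from the image's integral image (2D cumulative-sum table;
any axis-aligned rectangle sum costs four lookups).

Eight base templates are used — vertical/horizontal two-rectangle edges,
vertical/horizontal three-rectangle lines, a four-rectangle checkerboard, a
center-surround square, a diagonal two-rectangle split, and a full-support
average. Edge templates additionally vary their black/white split proportion.
Negative rectangles carry area-compensated weights so that every template
except the full-support average responds exactly zero to a constant image.

The feature dictionary pairs each candidate probe pose with the feature
vector of its simulated B-mode image; matching then reduces to comparing the
target's vector against every entry.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .phantom import ScattererField, sample_bitmap_scatterers
from .poses import PoseGrid, ProbePose
from .simulate import BModeImage, PSFModel, ProbeSpec, simulate_bmode
from .volumes import GrayImage, Volume3D, extract_oblique_slice, median_filter

__all__ = [
    "HaarTemplate",
    "HaarBasisSet",
    "FeatureIndex",
    "HaarFeatureVector",
    "DictionaryEntry",
    "FeatureDictionary",
    "integral_image",
    "eval_haar_feature",
    "enumerate_features",
    "extract_feature_vector",
    "build_dictionary",
    "dictionary_from_images",
]


@dataclass(frozen=True)
class HaarTemplate:
    """A named set of weighted axis-aligned rectangles over the unit square.

    Rectangles are ``(x0, y0, w, h, weight)`` with x along columns and y
    along rows, all in [0, 1]. ``variants`` lists alternative rectangle sets
    (e.g. different black/white split proportions).
    """

    name: str
    variants: tuple[tuple[tuple[float, float, float, float, float], ...], ...]


def _edge_variants(vertical: bool):
    out = []
    for p in (0.25, 0.5, 0.75):
        neg_w = -(1.0 - p) / p  # area-compensated: p*neg_w + (1-p)*1 = 0
        if vertical:
            out.append(((0.0, 0.0, p, 1.0, neg_w), (p, 0.0, 1.0 - p, 1.0, 1.0)))
        else:
            out.append(((0.0, 0.0, 1.0, p, neg_w), (0.0, p, 1.0, 1.0 - p, 1.0)))
    return tuple(out)


_TEMPLATES: tuple[HaarTemplate, ...] = (
    HaarTemplate("edge_vertical", _edge_variants(vertical=True)),
    HaarTemplate("edge_horizontal", _edge_variants(vertical=False)),
    HaarTemplate(
        "line_vertical",
        ((
            (0.0, 0.0, 0.25, 1.0, 1.0),
            (0.25, 0.0, 0.5, 1.0, -1.0),
            (0.75, 0.0, 0.25, 1.0, 1.0),
        ),),
    ),
    HaarTemplate(
        "line_horizontal",
        ((
            (0.0, 0.0, 1.0, 0.25, 1.0),
            (0.0, 0.25, 1.0, 0.5, -1.0),
            (0.0, 0.75, 1.0, 0.25, 1.0),
        ),),
    ),
    HaarTemplate(
        "checkerboard",
        ((
            (0.0, 0.0, 0.5, 0.5, 1.0),
            (0.5, 0.0, 0.5, 0.5, -1.0),
            (0.0, 0.5, 0.5, 0.5, -1.0),
            (0.5, 0.5, 0.5, 0.5, 1.0),
        ),),
    ),
    HaarTemplate(
        "center_surround",
        ((
            (0.25, 0.25, 0.5, 0.5, 1.0),
            (0.0, 0.0, 1.0, 0.25, -1.0 / 3.0),
            (0.0, 0.75, 1.0, 0.25, -1.0 / 3.0),
            (0.0, 0.25, 0.25, 0.5, -1.0 / 3.0),
            (0.75, 0.25, 0.25, 0.5, -1.0 / 3.0),
        ),),
    ),
    HaarTemplate(
        "diagonal",
        ((
            (0.0, 0.0, 0.5, 0.5, 1.0),
            (0.5, 0.5, 0.5, 0.5, -1.0),
        ),),
    ),
    HaarTemplate("average", (((0.0, 0.0, 1.0, 1.0, 1.0),),)),
)


@dataclass(frozen=True)
class HaarBasisSet:
    """The enumerable Haar feature family.

    ``scales`` are dyadic levels: the support of level ``s`` is
    ``base_support * 2**s`` pixels. ``stride_factor`` sets the translation
    stride as a fraction of the support (1.0 = non-overlapping tiling).
    ``match_size`` is the square resolution images are resized to before
    extraction, so target and dictionary vectors stay index-aligned.
    ``template_ids`` selects a subset of the eight base templates.
    """

    scales: tuple[int, ...] = (0, 1, 2, 3)
    base_support: int = 8
    stride_factor: float = 1.0
    match_size: int = 128
    template_ids: tuple[int, ...] = tuple(range(len(_TEMPLATES)))

    def __post_init__(self) -> None:
        if len(self.scales) == 0 or list(self.scales) != sorted(set(self.scales)):
            raise ValueError("scales must be non-empty and strictly increasing")
        if self.base_support < 2:
            raise ValueError("base_support must be >= 2")
        if not 0 < self.stride_factor:
            raise ValueError("stride_factor must be > 0")
        if any(t < 0 or t >= len(_TEMPLATES) for t in self.template_ids):
            raise ValueError("template_ids out of range")
        if len(self.template_ids) == 0:
            raise ValueError("template_ids must be non-empty")

    @property
    def templates(self) -> tuple[HaarTemplate, ...]:
        return tuple(_TEMPLATES[t] for t in self.template_ids)

    def support(self, scale: int) -> int:
        return self.base_support * 2**scale

    def stride(self, scale: int) -> int:
        return max(1, int(round(self.support(scale) * self.stride_factor)))

    def fingerprint(self) -> str:
        cfg = {
            "scales": list(self.scales),
            "base_support": self.base_support,
            "stride_factor": self.stride_factor,
            "match_size": self.match_size,
            "template_ids": list(self.template_ids),
        }
        return hashlib.sha1(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class FeatureIndex:
    """Address of one feature: (template, variant, scale, translation)."""

    template_id: int
    variant_id: int
    scale: int
    translation: tuple[int, int]  # (row, col) of the support's top-left pixel


@dataclass
class HaarFeatureVector:
    """Ordered feature responses grouped into contiguous scale blocks."""

    values: np.ndarray
    index_map: list[FeatureIndex]
    scale_blocks: list[tuple[int, int, int]]  # (start, stop, scale)
    basis_fingerprint: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.index_map):
            raise ValueError("values and index_map must have equal length")
        covered = sum(stop - start for start, stop, _ in self.scale_blocks)
        if covered != len(self.values):
            raise ValueError("scale_blocks must partition the index range")

    def __len__(self) -> int:
        return len(self.values)

    def block(self, k: int) -> np.ndarray:
        start, stop, _ = self.scale_blocks[k]
        return self.values[start:stop]


def integral_image(img: GrayImage | np.ndarray) -> np.ndarray:
    """Inclusive 2D cumulative sum: entry (i, j) = sum over rows<=i, cols<=j."""
    values = img.values if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
    if values.size == 0:
        raise ValueError("image must be non-empty")
    return values.cumsum(axis=0).cumsum(axis=1)


def _pad_integral(ii: np.ndarray) -> np.ndarray:
    out = np.zeros((ii.shape[0] + 1, ii.shape[1] + 1))
    out[1:, 1:] = ii
    return out


def _template_rects_px(basis: HaarBasisSet, template_id: int, variant_id: int,
                       scale: int):
    """Rectangles of one (template, variant) at a scale, in pixel units."""
    sup = basis.support(scale)
    rects = []
    for x0, y0, w, h, weight in basis.templates[template_id].variants[variant_id]:
        c0 = int(round(x0 * sup))
        c1 = int(round((x0 + w) * sup))
        r0 = int(round(y0 * sup))
        r1 = int(round((y0 + h) * sup))
        rects.append((r0, c0, r1, c1, weight))
    return rects


def eval_haar_feature(
    ii: np.ndarray, idx: FeatureIndex, basis: HaarBasisSet
) -> float:
    """Evaluate one feature from an (inclusive) integral image.

    Computed purely from four integral-image lookups per rectangle.
    """
    H, W = ii.shape
    sup = basis.support(idx.scale)
    tr, tc = idx.translation
    if tr < 0 or tc < 0 or tr + sup > H or tc + sup > W:
        raise ValueError(
            f"feature support {sup} at translation {idx.translation} exceeds "
            f"image shape {(H, W)}"
        )
    pad = _pad_integral(ii)
    total = 0.0
    for r0, c0, r1, c1, weight in _template_rects_px(
        basis, idx.template_id, idx.variant_id, idx.scale
    ):
        a, b = tr + r0, tr + r1
        c, d = tc + c0, tc + c1
        rect_sum = pad[b, d] - pad[a, d] - pad[b, c] + pad[a, c]
        total += weight * rect_sum
    return float(total)


def enumerate_features(
    basis: HaarBasisSet, image_size: int | tuple[int, int]
) -> list[FeatureIndex]:
    """Deterministic feature ordering: scale, template, variant, translation.

    Translations step by the basis stride at each scale, row-major.
    """
    if isinstance(image_size, int):
        image_size = (image_size, image_size)
    H, W = image_size
    if min(H, W) < basis.support(basis.scales[0]):
        raise ValueError("image smaller than the smallest feature support")
    out: list[FeatureIndex] = []
    for s in basis.scales:
        sup = basis.support(s)
        if sup > min(H, W):
            continue
        stride = basis.stride(s)
        rows = range(0, H - sup + 1, stride)
        cols = range(0, W - sup + 1, stride)
        for t_idx in range(len(basis.template_ids)):
            for v_idx in range(len(basis.templates[t_idx].variants)):
                for r in rows:
                    for c in cols:
                        out.append(FeatureIndex(t_idx, v_idx, s, (r, c)))
    return out


# cache of vectorised evaluation plans keyed by (fingerprint, image shape)
_PLAN_CACHE: dict[tuple, tuple] = {}


def _evaluation_plan(basis: HaarBasisSet, image_size: tuple[int, int]):
    key = (basis.fingerprint(), image_size)
    if key in _PLAN_CACHE:
        return _PLAN_CACHE[key]
    index_map = enumerate_features(basis, image_size)
    feat_of_rect, rows0, cols0, rows1, cols1, weights = [], [], [], [], [], []
    for k, idx in enumerate(index_map):
        for r0, c0, r1, c1, w in _template_rects_px(
            basis, idx.template_id, idx.variant_id, idx.scale
        ):
            tr, tc = idx.translation
            feat_of_rect.append(k)
            rows0.append(tr + r0)
            cols0.append(tc + c0)
            rows1.append(tr + r1)
            cols1.append(tc + c1)
            weights.append(w)
    scale_blocks = []
    start = 0
    for s in basis.scales:
        stop = start
        while stop < len(index_map) and index_map[stop].scale == s:
            stop += 1
        if stop > start:
            scale_blocks.append((start, stop, s))
        start = stop
    plan = (
        index_map,
        scale_blocks,
        np.asarray(feat_of_rect),
        np.asarray(rows0),
        np.asarray(cols0),
        np.asarray(rows1),
        np.asarray(cols1),
        np.asarray(weights, dtype=float),
    )
    _PLAN_CACHE[key] = plan
    return plan


def resize_to_match(img: GrayImage, match_size: int) -> GrayImage:
    """Bilinear resize to the square matching resolution (no-op if already)."""
    if img.shape == (match_size, match_size):
        return img
    scale = np.array(img.shape) / match_size
    out = _sk_resize(
        img.values, (match_size, match_size), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return GrayImage(out, img.pixel_spacing * scale[::-1], img.origin.copy())


def extract_feature_vector(img: GrayImage, basis: HaarBasisSet) -> HaarFeatureVector:
    """Full Haar feature vector of an image (one integral image per call)."""
    img = resize_to_match(img, basis.match_size)
    plan = _evaluation_plan(basis, img.shape)
    index_map, scale_blocks, feat, r0, c0, r1, c1, w = plan
    pad = _pad_integral(integral_image(img))
    rect_sums = pad[r1, c1] - pad[r0, c1] - pad[r1, c0] + pad[r0, c0]
    values = np.bincount(feat, weights=w * rect_sums, minlength=len(index_map))
    return HaarFeatureVector(values, index_map, scale_blocks, basis.fingerprint())


@dataclass
class DictionaryEntry:
    pose: ProbePose
    image: GrayImage  # raw simulated B-mode (pre median filter)
    vector: HaarFeatureVector | None  # None for invalid (plane missed data)

    @property
    def valid(self) -> bool:
        return self.vector is not None


@dataclass
class FeatureDictionary:
    """Pose-tagged Haar feature vectors of all simulated B-mode images."""

    entries: list[DictionaryEntry]
    basis_fingerprint: str
    median_window: int = 5

    def __post_init__(self) -> None:
        lengths = {len(e.vector) for e in self.entries if e.valid}
        if len(lengths) > 1:
            raise ValueError("all dictionary vectors must have equal length")
        for e in self.entries:
            if e.valid and e.vector.basis_fingerprint != self.basis_fingerprint:
                raise ValueError("entry fingerprint mismatch")

    def __len__(self) -> int:
        return len(self.entries)

    def valid_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.entries) if e.valid]

    def save(self, directory: str) -> None:
        """Persist as a JSON manifest plus a binary array of vectors."""
        os.makedirs(directory, exist_ok=True)
        manifest = {
            "basis_fingerprint": self.basis_fingerprint,
            "median_window": self.median_window,
            "entries": [
                {"pose": e.pose.to_dict(), "valid": e.valid}
                for e in self.entries
            ],
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        valid = self.valid_indices()
        if valid:
            np.save(
                os.path.join(directory, "vectors.npy"),
                np.stack([self.entries[i].vector.values for i in valid]),
            )
        np.save(
            os.path.join(directory, "images.npy"),
            np.stack([e.image.values for e in self.entries]),
        )


def _plane_intersects_box(plane, low, high) -> bool:
    pos = plane.pixel_positions()[::8, ::8].reshape(-1, 3)
    return bool(np.any(np.all((pos >= low) & (pos <= high), axis=1)))


def build_dictionary(
    field_or_volume: ScattererField | Volume3D,
    grid: PoseGrid,
    probe: ProbeSpec,
    psf: PSFModel,
    basis: HaarBasisSet,
    image_size: int | None = None,
    median_window: int = 5,
    seed: int = 0,
    bitmap_scatterers: int = 200_000,
    dynamic_range: float = 60.0,
) -> FeatureDictionary:
    """Simulate every pose's B-mode image and extract its feature vector.

    Scatterer fields are imaged directly. Volumes go through the bitmap
    route: the pose's interpolated slice becomes a scatterer slab whose
    amplitude factors follow slice intensity. Every simulated image is
    smoothed with a square median filter before feature extraction; entries
    whose plane misses the data entirely are flagged invalid and excluded
    from matching.
    """
    if len(grid) == 0:
        raise ValueError("pose grid must be non-empty")
    if image_size is None:
        image_size = basis.match_size
    entries: list[DictionaryEntry] = []
    ss = np.random.SeedSequence(seed)
    for i, pose in enumerate(grid):
        if isinstance(field_or_volume, ScattererField):
            low, high = field_or_volume.bounds
            valid = _plane_intersects_box(pose.plane, low, high)
            fld = field_or_volume
        else:
            low, high = field_or_volume.bounding_box()
            valid = _plane_intersects_box(pose.plane, low, high)
            fld = None
        if not valid:
            blank = GrayImage(
                np.zeros((image_size, image_size)),
                pose.plane.extent / image_size,
            )
            entries.append(DictionaryEntry(pose, blank, None))
            continue
        if fld is None:
            sl = extract_oblique_slice(field_or_volume, pose.plane)
            pose_seed = int(ss.spawn(1)[0].generate_state(1)[0] >> 1)
            fld = sample_bitmap_scatterers(
                sl, n=bitmap_scatterers, seed=pose_seed,
                slab_thickness=psf.elevation_slab, plane=pose.plane,
            )
        bmode = simulate_bmode(
            fld, probe, psf, pose.plane, image_size, dynamic_range
        )
        raw = bmode.to_gray()
        vec = extract_feature_vector(median_filter(raw, median_window), basis)
        entries.append(DictionaryEntry(pose, raw, vec))
    return FeatureDictionary(entries, basis.fingerprint(), median_window)


def dictionary_from_images(
    images: list[GrayImage],
    grid: PoseGrid,
    basis: HaarBasisSet,
    median_window: int = 5,
) -> FeatureDictionary:
    """Assemble a dictionary from already-rendered raw pose images.

    Simulated images depend only on the scene and probe, not on the Haar
    basis, so configuration sweeps re-extract vectors from one rendering.
    """
    if len(images) != len(grid):
        raise ValueError("one image per pose required")
    entries = [
        DictionaryEntry(
            pose, img, extract_feature_vector(median_filter(img, median_window), basis)
        )
        for pose, img in zip(grid, images)
    ]
    return FeatureDictionary(entries, basis.fingerprint(), median_window)
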