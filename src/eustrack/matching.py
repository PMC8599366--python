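"""Dictionary matching by per-scale-averaged normalized cross-correlation.

The target image's Haar feature vector is compared against every dictionary
entry. Within each scale block the zero-mean normalized cross-correlation

    NCC(u, v) = sum((u - mean(u)) (v - mean(v)))
                / sqrt(sum((u - mean(u))^2) sum((v - mean(v))^2))

is computed independently, and the match score is the arithmetic mean over
the scale blocks; the best-matched pose maximises that score. Averaging
per scale keeps the many fine-scale coefficients from drowning out the few
coarse-scale ones. A single whole-vector NCC and a non-centred (cosine)
variant are available as switches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .haar import FeatureDictionary, HaarBasisSet, HaarFeatureVector, \
    extract_feature_vector, resize_to_match
from .poses import ProbePose
from .volumes import GrayImage, median_filter

__all__ = ["MatchResult", "ncc", "match_score", "find_best_match"]


@dataclass
class MatchResult:
    """Outcome of matching a target image against the dictionary."""

    best_index: int
    best_pose: ProbePose
    score: float
    per_scale_ncc: list[float]
    ranking: list[int]  # valid entry indices, descending score

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "best_index": self.best_index,
                    "best_pose": self.best_pose.to_dict(),
                    "score": self.score,
                    "per_scale_ncc": self.per_scale_ncc,
                    "ranking": self.ranking,
                },
                fh,
                indent=1,
            )


def ncc(u: np.ndarray, v: np.ndarray, center: bool = True) -> float:
    """Zero-mean normalized cross-correlation of two equal-length vectors.

    Returns a value in [-1, 1]; a constant (zero-variance) vector carries no
    evidence and yields 0 by convention. ``center=False`` gives plain cosine
    similarity instead.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    if u.size < 2:
        raise ValueError("vectors must have length >= 2")
    if center:
        u = u - u.mean()
        v = v - v.mean()
    denom = np.sqrt((u @ u) * (v @ v))
    if denom == 0.0:
        return 0.0
    return float(np.clip((u @ v) / denom, -1.0, 1.0))


def match_score(
    entry_vector: HaarFeatureVector,
    target_vector: HaarFeatureVector,
    per_scale: bool = True,
    center: bool = True,
) -> tuple[float, list[float]]:
    """Mean per-scale NCC between two feature vectors of the same basis.

    With ``per_scale=False`` a single NCC over the whole vector is returned
    (the per-scale list then has one element).
    """
    if entry_vector.basis_fingerprint != target_vector.basis_fingerprint:
        raise ValueError("feature vectors come from different bases")
    if per_scale:
        scores = [
            ncc(entry_vector.block(k), target_vector.block(k), center=center)
            for k in range(len(entry_vector.scale_blocks))
        ]
    else:
        scores = [ncc(entry_vector.values, target_vector.values, center=center)]
    return float(np.mean(scores)), scores


def find_best_match(
    dictionary: FeatureDictionary,
    target: GrayImage,
    basis: HaarBasisSet,
    per_scale: bool = True,
    center: bool = True,
) -> MatchResult:
    """Locate the dictionary pose whose image best matches the target.

    The target is preprocessed exactly like the dictionary images (median
    filter, resize to the matching resolution) before feature extraction.
    Ties break to the lowest dictionary index.
    """
    if basis.fingerprint() != dictionary.basis_fingerprint:
        raise ValueError("basis fingerprint does not match the dictionary")
    valid = dictionary.valid_indices()
    if not valid:
        raise ValueError("dictionary has no valid entries to match against")
    prepped = median_filter(
        resize_to_match(target, basis.match_size), dictionary.median_window
    )
    tvec = extract_feature_vector(prepped, basis)
    scores: list[float] = []
    per_scale_scores: list[list[float]] = []
    for i in valid:
        s, blocks = match_score(
            dictionary.entries[i].vector, tvec, per_scale=per_scale, center=center
        )
        scores.append(s)
        per_scale_scores.append(blocks)
    order = np.argsort(-np.asarray(scores), kind="stable")
    ranking = [valid[k] for k in order]
    best_k = int(order[0])
    return MatchResult(
        best_index=valid[best_k],
        best_pose=dictionary.entries[valid[best_k]].pose,
        score=scores[best_k],
        per_scale_ncc=per_scale_scores[best_k],
        ranking=ranking,
    )
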