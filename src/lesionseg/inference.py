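"""Prediction and majority-vote ensembling.

A trained network maps a normalized volume to a per-voxel two-class
probability field; the predicted mask is the per-voxel argmax (for two
classes: lesion wherever its probability exceeds 0.5).  Independently
trained runs are fused by voxel-wise majority voting over their binary
masks — with three runs, a voxel is lesion when at least two runs say
so — which removes uncorrelated errors of the individual runs.  Voting
on averaged probabilities is available as a non-default option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lesionseg.errors import GeometryError, InvalidConfigError
from lesionseg.network import RatLesNetV2
from lesionseg.volume_io import SegmentationMask, VolumeImage, require_same_geometry

__all__ = [
    "ProbabilityMap",
    "EnsemblePrediction",
    "predict",
    "majority_vote",
    "average_probabilities",
    "ensemble_predict",
]


@dataclass
class ProbabilityMap:
    """Per-voxel two-class probabilities (non-lesion, lesion), sum 1."""

    data: np.ndarray  # (2, D, H, W)
    spacing: tuple[float, float, float]

    @property
    def lesion(self) -> np.ndarray:
        return self.data[1]


@dataclass
class EnsemblePrediction:
    member_masks: list[SegmentationMask]
    fused_mask: SegmentationMask


def predict(model: RatLesNetV2, v: VolumeImage) -> tuple[ProbabilityMap, SegmentationMask]:
    """Segment one (already normalized) volume.

    Returns the softmax probability map and the argmax mask, both in the
    input's geometry (internal padding is cropped away).
    """
    probs = model.predict_probs(v.data, training=False)
    mask = (probs[1] > probs[0]).astype(np.uint8)
    return (
        ProbabilityMap(data=probs.astype(np.float32), spacing=v.spacing),
        SegmentationMask(data=mask, spacing=v.spacing, affine=v.affine),
    )


def majority_vote(masks: list[SegmentationMask]) -> SegmentationMask:
    """Voxel-wise majority over an odd number of geometry-matched masks.

    Raises
    ------
    InvalidConfigError
        For an empty or even-sized ensemble (even counts can tie).
    GeometryError
        If the masks do not share a voxel grid.
    """
    if not masks:
        raise InvalidConfigError("need at least one mask")
    if len(masks) % 2 == 0:
        raise InvalidConfigError(
            f"even ensemble of {len(masks)} masks can tie; use an odd count"
        )
    for m in masks[1:]:
        require_same_geometry(masks[0], m)
    votes = np.sum([m.data.astype(np.int32) for m in masks], axis=0)
    fused = (votes > len(masks) / 2).astype(np.uint8)
    return SegmentationMask(data=fused, spacing=masks[0].spacing, affine=masks[0].affine)


def average_probabilities(maps: list[ProbabilityMap]) -> SegmentationMask:
    """Non-default fusion: average the members' probability maps, then argmax."""
    if not maps:
        raise InvalidConfigError("need at least one probability map")
    shapes = {m.data.shape for m in maps}
    if len(shapes) != 1:
        raise GeometryError(f"probability maps disagree in shape: {shapes}")
    mean = np.mean([m.data for m in maps], axis=0)
    return SegmentationMask(
        data=(mean[1] > mean[0]).astype(np.uint8), spacing=maps[0].spacing
    )


def ensemble_predict(
    models: list[RatLesNetV2], v: VolumeImage
) -> EnsemblePrediction:
    """Predict with every model and fuse by majority vote."""
    members = [predict(m, v)[1] for m in models]
    fused = majority_vote(members)
    return EnsemblePrediction(member_masks=members, fused_mask=fused)
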