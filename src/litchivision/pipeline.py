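"""End-to-end pipeline: stereo pair in, localized fruit clusters out.

Stage 2 (recognition): each of the four trained classifiers segments the
left image into a binary mask; each mask is cleaned, circle-Hough
transformed and deduplicated; the four circle lists are OR-fused and the
fused detections grouped into cluster categories A/B/C.  Stage 3
(matching): every cluster label is NCC-matched along its epipolar row of
the right image, the ordering/row constraints prune inconsistent
matches, and survivors are triangulated into 3-D.

Images larger than the working resolution are bilinearly resized to
640x480 first; smaller images pass through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from litchivision.classifiers import CLASSIFIER_KINDS, segment_image_all
from litchivision.cluster_recognition import FruitCluster, assign_categories
from litchivision.config import PipelineConfig
from litchivision.errors import MissingModelError
from litchivision.fruit_detection import (
    DetectedCircle,
    dedupe_circles,
    detect_circles_from_mask,
    fuse_detections,
)
from litchivision.stereo_camera import StereoRig
from litchivision.stereo_matching import (
    ClusterMatch,
    enforce_constraints,
    localize_matches,
    match_clusters,
)

logger = logging.getLogger("litchivision")


@dataclass
class PipelineResult:
    """All intermediate and final artifacts of one stereo pair."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    circles_per_classifier: dict[str, list[DetectedCircle]] = field(default_factory=dict)
    fused_circles: list[DetectedCircle] = field(default_factory=list)
    clusters: list[FruitCluster] = field(default_factory=list)
    matches: list[ClusterMatch] = field(default_factory=list)


def prepare_image(image: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Resize oversized inputs to the working resolution (bilinear)."""
    W, H = config.image_size
    h, w = image.shape[:2]
    if w <= W and h <= H:
        return np.asarray(image)
    out = resize(np.asarray(image, dtype=float), (H, W, image.shape[2]), order=1,
                 anti_aliasing=True, preserve_range=True)
    return np.clip(out, 0, 255).astype(np.uint8)


def detect_left_image(
    image: np.ndarray, models: dict, config: PipelineConfig
) -> PipelineResult:
    """Stage 2 on a single image: masks → circles → fused clusters."""
    for kind in CLASSIFIER_KINDS:
        if kind not in models:
            raise MissingModelError(f"missing trained model: {kind}")
    result = PipelineResult()
    result.masks = segment_image_all(image, models, stride=config.stride)
    for kind, mask in result.masks.items():
        circles = detect_circles_from_mask(
            mask, source=kind, sensitivity=config.sensitivity
        )
        result.circles_per_classifier[kind] = circles
        logger.info(
            "classifier %s: foreground %.1f%%, %d circles",
            kind, 100.0 * mask.mean(), len(circles),
        )
    result.fused_circles = fuse_detections(
        result.circles_per_classifier, threshold=config.dedup_threshold
    )
    W = image.shape[1]
    H = image.shape[0]
    result.clusters = assign_categories(
        result.fused_circles, diameter=config.cluster_diameter, image_size=(W, H)
    )
    cats = {"A": 0, "B": 0, "C": 0}
    for cl in result.clusters:
        cats[cl.category] += 1
    logger.info("fused %d circles into clusters %s", len(result.fused_circles), cats)
    return result


def run_pipeline(
    left_image: np.ndarray,
    right_image: np.ndarray,
    models: dict,
    config: PipelineConfig | None = None,
    rig: StereoRig | None = None,
) -> PipelineResult:
    """Full recognition + matching pipeline on a rectified stereo pair."""
    config = config or PipelineConfig()
    left = prepare_image(left_image, config)
    right = prepare_image(right_image, config)
    result = detect_left_image(left, models, config)
    matches = match_clusters(
        left, right, result.clusters,
        d_range=range(0, config.disparity_max + 1),
        threshold=config.ncc_threshold,
    )
    kept = enforce_constraints(matches, row_tolerance=config.row_tolerance)
    logger.info(
        "matching: %d candidates, %d kept after constraints", len(matches), len(kept)
    )
    if rig is not None:
        kept = localize_matches(rig, [m for m in kept if m.disparity > 0])
    result.matches = kept
    return result
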