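"""Synthetic stereo benchmark: recognition recall and matching comparison.

Runs the full pipeline over a batch of seeded scenes spanning the three
illumination modes and mixed cluster categories, scores recognition
against ground truth with the missed-cluster rules, measures the
fraction of non-occluded clusters matched at the correct (±1 px)
disparity, and compares the proposed cluster-label matcher against the
single-circle nearest-disparity baseline under occlusion (the cluster
label stays matchable when individual circles are distorted or missing
in one view).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from litchivision.cli import train_all
from litchivision.config import PipelineConfig
from litchivision.evaluation import (
    cht_baseline_match,
    match_detections_to_truth,
    matching_rate,
)
from litchivision.fruit_detection import detect_circles_from_mask, fuse_detections
from litchivision.classifiers import segment_image_all
from litchivision.pipeline import run_pipeline
from litchivision.synthetic_scenes import (
    ILLUMINATIONS,
    SceneSpec,
    generate_scene,
    generate_training_patches,
)

#: cluster plans cycled over the benchmark scenes (mixed A/B/C)
BENCHMARK_PLANS = ((1, 2, 3, 1), (2, 1, 3), (1, 3, 2, 1))
BENCHMARK_IMAGE_SIZE = (640, 480)


@dataclass
class BenchmarkResult:
    n_scenes: int = 0
    n_clusters: int = 0
    TP: int = 0
    FP: int = 0
    FN: int = 0
    matched_correct: int = 0
    matched_total: int = 0  # non-occluded clusters
    proposed_correct: int = 0  # over all clusters
    baseline_correct: int = 0
    n_fruits: int = 0
    per_scene: list[dict] = field(default_factory=list)

    @property
    def recall(self) -> float:
        return self.TP / self.n_clusters

    @property
    def match_rate_nonoccluded(self) -> float:
        return self.matched_correct / max(self.matched_total, 1)

    @property
    def proposed_match_rate(self) -> float:
        """Percent of clusters matched at the correct disparity."""
        return matching_rate(self.proposed_correct, self.n_clusters)

    @property
    def baseline_match_rate(self) -> float:
        """Percent of single fruits correctly paired by the circle baseline."""
        return matching_rate(self.baseline_correct, self.n_fruits)


def benchmark_specs(
    n_scenes: int,
    seed: int,
    occlusion_fraction: float = 0.3,
    image_size: tuple[int, int] = BENCHMARK_IMAGE_SIZE,
) -> list[SceneSpec]:
    return [
        SceneSpec(
            image_size=image_size,
            cluster_plan=BENCHMARK_PLANS[i % len(BENCHMARK_PLANS)],
            illumination=ILLUMINATIONS[i % len(ILLUMINATIONS)],
            occlusion_fraction=occlusion_fraction,
            seed=seed + i,
        )
        for i in range(n_scenes)
    ]


def train_benchmark_models(
    seed: int, n_per_class: int = 60, image_size=BENCHMARK_IMAGE_SIZE
) -> dict:
    patches, labels = generate_training_patches(
        n_per_class=n_per_class, seed=seed, image_size=image_size
    )
    config = PipelineConfig()
    config.seed = seed if seed > 0 else config.seed
    return train_all(patches, labels, config)


def _nearest_cluster_match(matches, center, tol: float = 50.0):
    # benchmark clusters are >= 120 px apart, so a 50 px credit radius is
    # unambiguous while tolerating the box-centre offset of partially
    # detected clusters
    best, best_d = None, tol
    for m in matches:
        d = float(np.hypot(m.left_center[0] - center[0], m.left_center[1] - center[1]))
        if d < best_d:
            best, best_d = m, d
    return best


def evaluate_scene(models: dict, spec: SceneSpec, config: PipelineConfig) -> dict:
    """Pipeline + scoring for one scene; returns raw per-scene counts."""
    left, right, truth = generate_scene(spec)
    result = run_pipeline(left, right, models, config)
    counts = match_detections_to_truth(result.clusters, truth)

    matched_total = matched_correct = proposed_correct = 0
    for tc in truth.clusters:
        m = _nearest_cluster_match(result.matches, tc.center)
        correct = m is not None and abs(m.disparity - tc.disparity) <= 1
        if correct:
            proposed_correct += 1
        if not tc.occluded:
            matched_total += 1
            matched_correct += int(correct)

    # single-circle baseline needs detections in the right image as well
    right_masks = segment_image_all(right, models, stride=config.stride)
    right_circles = fuse_detections(
        {
            kind: detect_circles_from_mask(m, source=kind, sensitivity=config.sensitivity)
            for kind, m in right_masks.items()
        },
        threshold=config.dedup_threshold,
    )
    pairs = cht_baseline_match(
        result.fused_circles, right_circles, d_max=config.disparity_max
    )
    # a fruit counts as correctly matched by the baseline when its left
    # circle is paired with the right-image circle of the same fruit
    # (correspondence-level credit, the analogue of a judged match)
    baseline_correct = 0
    for f in truth.fruits:
        li = None
        for i, c in enumerate(result.fused_circles):
            if np.hypot(c.x - f.left_center[0], c.y - f.left_center[1]) <= 25:
                li = i
                break
        if li is None:
            continue
        for pl, pr in pairs:
            if pl == li:
                rc = right_circles[pr]
                if (
                    np.hypot(rc.x - f.right_center[0], rc.y - f.right_center[1])
                    <= 25
                ):
                    baseline_correct += 1
                break

    return {
        "n_clusters": counts.n_clusters,
        "TP": counts.TP,
        "FP": counts.FP,
        "FN": counts.FN,
        "matched_total": matched_total,
        "matched_correct": matched_correct,
        "proposed_correct": proposed_correct,
        "baseline_correct": baseline_correct,
        "n_fruits": len(truth.fruits),
    }


def run_benchmark(
    n_scenes: int = 20,
    seed: int = 2017,
    occlusion_fraction: float = 0.3,
    models: dict | None = None,
    image_size: tuple[int, int] = BENCHMARK_IMAGE_SIZE,
) -> BenchmarkResult:
    """Full benchmark: train once, evaluate ``n_scenes`` seeded scenes."""
    if models is None:
        models = train_benchmark_models(seed)
    config = PipelineConfig(image_size=image_size)
    result = BenchmarkResult()
    for spec in benchmark_specs(
        n_scenes, seed + 1000, occlusion_fraction, image_size
    ):
        row = evaluate_scene(models, spec, config)
        result.per_scene.append(row)
        result.n_scenes += 1
        for key in (
            "n_clusters", "TP", "FP", "FN", "matched_total", "matched_correct",
            "proposed_correct", "baseline_correct", "n_fruits",
        ):
            setattr(result, key, getattr(result, key) + row[key])
    return result
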