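"""Recognition and matching metrics against ground truth.

Missed-cluster rules (per-fruit coverage is the fraction of the true
fruit disk covered by the assigned detection's circles):

* category A — the single fruit must be covered >= 25%,
* category B — missed if one or two of the fruits fall below 25%,
* category C — missed if two or more fruits fall below 25%.

Rates follow the standard detection formulas: TPR (= recall) =
TP/(TP+FN), FPR = FP/(FP+TP), FNR = FN/(FN+TP), precision = TP/(FP+TP),
F1 = 2PR/(P+R), all reported in percent and formatted half-up at two
decimals only for reports.  A nearest-disparity single-circle matcher
serves as the comparison baseline for cluster-level stereo matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from litchivision.cluster_recognition import FruitCluster
from litchivision.fruit_detection import DetectedCircle
from litchivision.synthetic_scenes import SceneTruth

COVERAGE_FRACTION = 0.25


@dataclass
class RecognitionCounts:
    """Per-condition cluster detection counts (TP + FN = n_clusters)."""

    condition: str
    n_clusters: int
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.n_clusters, self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")
        if self.TP + self.FN != self.n_clusters:
            raise ValueError("TP + FN must equal the number of true clusters")


@dataclass
class MetricsReport:
    """Detection rates in percent; ``degenerate`` flags TP + FP = 0."""

    tpr: float
    fpr: float
    fnr: float
    precision: float
    recall: float
    f1: float
    degenerate: bool = False

    def rounded(self, decimals: int = 2) -> dict[str, float]:
        """Half-up rounding at report precision (matches table formatting)."""

        def r(v):
            q = 10.0**decimals
            return float(np.floor(v * q + 0.5) / q)

        return {
            "tpr": r(self.tpr),
            "fpr": r(self.fpr),
            "fnr": r(self.fnr),
            "precision": r(self.precision),
            "recall": r(self.recall),
            "f1": r(self.f1),
        }


def compute_metrics(counts: RecognitionCounts) -> MetricsReport:
    """Rates from counts; full precision internally, rounding only at print."""
    TP, FP, FN = counts.TP, counts.FP, counts.FN
    if TP + FN == 0:
        raise ValueError("TP + FN must be positive")
    tpr = 100.0 * TP / (TP + FN)
    fnr = 100.0 * FN / (FN + TP)
    degenerate = (TP + FP) == 0
    if degenerate:
        fpr = 0.0
        precision = 0.0
    else:
        fpr = 100.0 * FP / (FP + TP)
        precision = 100.0 * TP / (FP + TP)
    recall = tpr
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return MetricsReport(tpr, fpr, fnr, precision, recall, f1, degenerate)


def matching_rate(n_correct: int, n_total: int) -> float:
    """Correct-matching percentage n_correct / n_total * 100."""
    if n_total <= 0:
        raise ValueError("matching rate undefined for an empty set")
    return 100.0 * n_correct / n_total


# ---------------------------------------------------------------------------
# detection-truth assignment
# ---------------------------------------------------------------------------


def _circle_overlap_area(r1: float, r2: float, dist: float) -> float:
    """Lens area of two intersecting circles."""
    if dist >= r1 + r2:
        return 0.0
    if dist <= abs(r1 - r2):
        r = min(r1, r2)
        return np.pi * r**2
    d1 = (dist**2 + r1**2 - r2**2) / (2 * dist)
    d2 = dist - d1
    a1 = r1**2 * np.arccos(np.clip(d1 / r1, -1, 1)) - d1 * np.sqrt(
        max(r1**2 - d1**2, 0.0)
    )
    a2 = r2**2 * np.arccos(np.clip(d2 / r2, -1, 1)) - d2 * np.sqrt(
        max(r2**2 - d2**2, 0.0)
    )
    return a1 + a2


def _fruit_coverage(fruit_center, fruit_radius, circles: list[DetectedCircle]) -> float:
    """Fraction of the true fruit disk covered by the best detected circle."""
    area = np.pi * fruit_radius**2
    best = 0.0
    for c in circles:
        dist = float(np.hypot(c.x - fruit_center[0], c.y - fruit_center[1]))
        best = max(best, _circle_overlap_area(fruit_radius, c.radius, dist))
    return best / area


def _box_overlap(a, b) -> float:
    w = min(a[2], b[2]) - max(a[0], b[0])
    h = min(a[3], b[3]) - max(a[1], b[1])
    return max(w, 0.0) * max(h, 0.0)


def _cluster_detected(true_fruits, detection: FruitCluster,
                      fraction: float) -> bool:
    coverages = [
        _fruit_coverage(f.left_center, f.radius, list(detection.members))
        for f in true_fruits
    ]
    below = sum(cov < fraction for cov in coverages)
    category = true_fruits[0].category
    if category == "A":
        return below == 0
    if category == "B":
        return below == 0  # one or two sub-25% fruits -> missed
    return below <= 1  # C: two or more sub-25% -> missed


def match_detections_to_truth(
    clusters: list[FruitCluster],
    truth: SceneTruth,
    fraction: float = COVERAGE_FRACTION,
    condition: str = "Total",
) -> RecognitionCounts:
    """Score detected clusters against ground truth.

    Detections are assigned one-to-one to true clusters greedily by
    descending merged-box overlap; an assigned cluster counts as TP only
    if its per-fruit coverage passes the category's missed rule, and
    unassigned detections count as FP.
    """
    fruits_by_cluster: dict[int, list] = {}
    for f in truth.fruits:
        fruits_by_cluster.setdefault(f.cluster_id, []).append(f)

    pairs = []
    for ti, tc in enumerate(truth.clusters):
        for di, det in enumerate(clusters):
            box = (det.label.xmin, det.label.ymin, det.label.xmax, det.label.ymax)
            ov = _box_overlap(tc.box, box)
            if ov > 0:
                pairs.append((ov, ti, di))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    assigned_t: dict[int, int] = {}
    used_d: set[int] = set()
    for ov, ti, di in pairs:
        if ti in assigned_t or di in used_d:
            continue
        assigned_t[ti] = di
        used_d.add(di)

    TP = 0
    for ti, tc in enumerate(truth.clusters):
        if ti not in assigned_t:
            continue
        det = clusters[assigned_t[ti]]
        if _cluster_detected(fruits_by_cluster[tc.cluster_id], det, fraction):
            TP += 1
    # every detection not credited as a successful cluster is a false positive
    FP = len(clusters) - TP
    FN = len(truth.clusters) - TP
    return RecognitionCounts(condition, len(truth.clusters), TP, FP, FN)


# ---------------------------------------------------------------------------
# single-circle CHT baseline matcher
# ---------------------------------------------------------------------------


def cht_baseline_match(
    left_circles: list[DetectedCircle],
    right_circles: list[DetectedCircle],
    radius_tolerance: float = 5.0,
    row_tolerance: float = 2.0,
    d_max: float = 200.0,
) -> list[tuple[int, int]]:
    """Pair single-fruit circles across the views, nearest disparity first.

    Candidates must agree in radius within ±5 px and row within ±2 px
    with non-negative disparity; greedy one-to-one assignment in order
    of increasing disparity.  This reproduces the failure mode of
    single-fruit matching under mutual occlusion: a fruit whose circle
    is distorted or absent in one view finds no partner.
    """
    cands = []
    for li, lc in enumerate(left_circles):
        for ri, rc in enumerate(right_circles):
            d = lc.x - rc.x
            if (
                abs(lc.radius - rc.radius) <= radius_tolerance
                and abs(lc.y - rc.y) <= row_tolerance
                and 0.0 <= d <= d_max
            ):
                cands.append((d, li, ri))
    cands.sort(key=lambda t: (t[0], t[1], t[2]))
    used_l: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for d, li, ri in cands:
        if li in used_l or ri in used_r:
            continue
        used_l.add(li)
        used_r.add(ri)
        pairs.append((li, ri))
    return pairs


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------


def recognition_report(rows: list[RecognitionCounts]):
    """Per-condition recognition table as a pandas DataFrame."""
    import pandas as pd

    records = []
    for counts in rows:
        rep = compute_metrics(counts).rounded()
        records.append(
            {
                "condition": counts.condition,
                "amount": counts.n_clusters,
                "TP": counts.TP,
                "tpr": rep["tpr"],
                "FP": counts.FP,
                "fpr": rep["fpr"],
                "FN": counts.FN,
                "fnr": rep["fnr"],
                "precision": rep["precision"],
                "recall": rep["recall"],
                "f1": rep["f1"],
            }
        )
    return pd.DataFrame.from_records(records)


def matching_report(rows: list[tuple[str, int, int]]):
    """Per-condition matching table: (condition, pairs, correct) rows."""
    import pandas as pd

    records = [
        {
            "condition": cond,
            "pairs": total,
            "correct": correct,
            "rate": float(np.floor(matching_rate(correct, total) * 100 + 0.5) / 100),
        }
        for cond, total, correct in rows
    ]
    return pd.DataFrame.from_records(records)
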