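"""Grouping single-fruit detections into cluster categories A / B / C.

Mature litchis grow in clusters; with images at 640x480 the average
single-fruit diameter is about 40 px, so two fruits whose geometric
centres lie strictly closer than 40 px belong to the same cluster.
Chained proximity is resolved by single-linkage connected components of
the < 40 px centre-distance graph:

* category **A** — a single fruit (component of size 1),
* category **B** — two clustered fruits (size 2),
* category **C** — multiple clustered fruits (size >= 3).

Clustered labels are merged into one box spanning the member labels'
extreme coordinates; the cluster's feature point (u, v) is the diagonal
intersection (midpoint) of that box.  Member circle centres of merged
clusters are dropped from the public geometry — only the cluster centre
remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from litchivision.errors import EmptyClusterError
from litchivision.fruit_detection import (
    DetectedCircle,
    FruitLabel,
    _distance_components,
    circle_to_label,
)

CLUSTER_DIAMETER = 40.0


@dataclass(frozen=True)
class FruitCluster:
    """One recognized cluster: category, member circles, merged label."""

    category: str  # "A" | "B" | "C"
    members: tuple[DetectedCircle, ...]
    label: FruitLabel

    @property
    def center(self) -> tuple[float, float]:
        """Feature point (u, v): diagonal intersection of the merged label."""
        return self.label.center

    @property
    def member_count(self) -> int:
        return len(self.members)

    @property
    def member_centers(self) -> list[tuple[float, float]] | None:
        """Centres of the member circles; None for merged (B/C) clusters,
        whose individual centres are deleted after merging."""
        if self.category == "A":
            return [(c.x, c.y) for c in self.members]
        return None


def _category_for(count: int) -> str:
    if count == 1:
        return "A"
    if count == 2:
        return "B"
    return "C"


def merge_labels(labels: list[FruitLabel]) -> FruitLabel:
    """Box spanning the min/max abscissas and ordinates of all labels."""
    if not labels:
        raise EmptyClusterError("cannot merge an empty label list")
    return FruitLabel(
        min(l.xmin for l in labels),
        min(l.ymin for l in labels),
        max(l.xmax for l in labels),
        max(l.ymax for l in labels),
    )


def cluster_center(cluster: FruitCluster) -> tuple[float, float]:
    """Diagonal intersection point of the cluster's merged label."""
    return cluster.label.center


def assign_categories(
    circles: list[DetectedCircle],
    diameter: float = CLUSTER_DIAMETER,
    image_size: tuple[int, int] | None = None,
) -> list[FruitCluster]:
    """Partition deduplicated circles into A/B/C clusters.

    Distances exactly equal to the 40 px threshold do *not* cluster (the
    rule is a strict inequality).  The output is sorted by cluster
    centre for order-independence; labels are clipped to ``image_size``
    when given, while the clustering itself uses unclipped geometry.
    """
    if not circles:
        return []
    centers = np.array([[c.x, c.y] for c in circles])
    clusters = []
    for comp in _distance_components(centers, diameter):
        members = tuple(sorted((circles[i] for i in comp), key=lambda c: (c.x, c.y)))
        labels = [circle_to_label(c, image_size) for c in members]
        merged = merge_labels(labels)
        clusters.append(FruitCluster(_category_for(len(members)), members, merged))
    clusters.sort(key=lambda cl: cl.center)
    return clusters


def clusters_to_json(clusters: list[FruitCluster]) -> list[dict]:
    return [
        {
            "category": cl.category,
            "label": [cl.label.xmin, cl.label.ymin, cl.label.xmax, cl.label.ymax],
            "center": list(cl.center),
            "member_count": cl.member_count,
        }
        for cl in clusters
    ]
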