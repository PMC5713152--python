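"""From binary fruit masks to single-fruit circle detections and labels.

Each classifier's mask is cleaned (dilation by a radius-10 disk, hole
filling, small-component removal), its Canny edges are fed to a circular
Hough transform over integer radii 30..50 px (the observed radius range
of mature litchi fruits at 640x480), near-duplicate circles closer than
15 px are merged, and every surviving circle is boxed by its minimum
circumscribed square ("label").  The four classifiers' detections are
fused with the OR rule: a fruit found by any one classifier survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny
from skimage.morphology import disk
from skimage.transform import hough_circle, hough_circle_peaks

from litchivision.errors import ParameterError

R_MIN, R_MAX = 30, 50
DEDUP_THRESHOLD = 15.0
DILATION_RADIUS = 10
SENSITIVITY = 0.97
#: components smaller than a disk of radius 15 are noise after dilation
MIN_COMPONENT_AREA = int(np.pi * 15**2)


@dataclass(frozen=True)
class DetectedCircle:
    """A single-fruit hypothesis: centre (x, y) px, radius px, Hough support."""

    x: float
    y: float
    radius: float
    score: float = 1.0
    source: str = "fused"

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class FruitLabel:
    """Minimum circumscribed axis-aligned square of a detected circle.

    ``vertices`` lists the 4 corners (x, y) clockwise from the top-left;
    they are clipped to the image bounds when a size is given.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    circle: DetectedCircle | None = field(default=None, compare=False)

    @property
    def vertices(self) -> list[tuple[float, float]]:
        return [
            (self.xmin, self.ymin),
            (self.xmax, self.ymin),
            (self.xmax, self.ymax),
            (self.xmin, self.ymax),
        ]

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))


def clean_mask(mask: np.ndarray, dilation_radius: int = DILATION_RADIUS) -> np.ndarray:
    """Morphological cleanup of a classifier mask.

    Dilation by a disk structuring element (radius 10) closes the small
    gaps left by specular spots, holes are filled, and components below
    the minimum plausible fruit area are removed.
    """
    mask = np.asarray(mask).astype(bool)
    if dilation_radius > 0:
        mask = ndi.binary_dilation(mask, structure=disk(dilation_radius))
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask)
    if n:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= MIN_COMPONENT_AREA
        keep[0] = False
        mask = keep[labels]
    return mask


def hough_circles(
    mask: np.ndarray,
    r_min: int = R_MIN,
    r_max: int = R_MAX,
    sensitivity: float = SENSITIVITY,
    source: str = "fused",
    max_circles: int = 64,
) -> list[DetectedCircle]:
    """Circular Hough transform on the Canny edges of a cleaned mask.

    The accumulator is normalized by the full perimeter support of each
    radius; peaks with support >= ``(1 − sensitivity) ** 0.46`` and centre
    separation >= the dedup threshold are returned strongest first.  The
    power mapping keeps the named sensitivity parameter monotone in its
    usual direction (higher sensitivity → weaker circles accepted) and is
    calibrated on synthetic disks: at sensitivity 0.97 the support floor
    is 0.2, which admits ideal disks (support ≈ 0.9) and the partial
    arcs that clustered or occluded fruits leave in a merged mask
    outline (support ≈ 0.25–0.5) while rejecting the phantom peaks
    that mask edges cast into the accumulator (support ≤ 0.15).
    """
    if r_min > r_max:
        raise ParameterError(f"r_min {r_min} > r_max {r_max}")
    mask = np.asarray(mask).astype(bool)
    if not np.any(mask):
        return []
    edges = canny(mask.astype(float), sigma=1.0)
    if not np.any(edges):
        return []
    radii = np.arange(r_min, r_max + 1)
    accum = hough_circle(edges, radii)
    threshold = float((1.0 - sensitivity) ** 0.46)
    sep = int(DEDUP_THRESHOLD)
    scores, cx, cy, rr = hough_circle_peaks(
        accum,
        radii,
        min_xdistance=sep,
        min_ydistance=sep,
        threshold=threshold,
        total_num_peaks=max_circles,
        normalize=True,
    )
    H, W = mask.shape
    out = []
    for s, x, y, r in zip(scores, cx, cy, rr):
        if 0 <= x < W and 0 <= y < H:
            out.append(
                DetectedCircle(float(x), float(y), float(r), float(s), source)
            )
    out.sort(key=lambda c: -c.score)
    return out


def _distance_components(centers: np.ndarray, threshold: float) -> list[list[int]]:
    """Single-linkage components of the strict < threshold distance graph."""
    n = len(centers)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if n:
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        for i in range(n):
            for j in range(i + 1, n):
                if d[i, j] < threshold:
                    parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def dedupe_circles(
    circles: list[DetectedCircle], threshold: float = DEDUP_THRESHOLD
) -> list[DetectedCircle]:
    """Merge circles whose centres are closer than the threshold.

    Circles form the single-linkage components of the strict
    ``< threshold`` centre-distance graph; each component collapses to
    one circle at the support-weighted mean centre and radius.  Sources
    are kept when unanimous, else marked "fused".
    """
    if not circles:
        return []
    centers = np.array([[c.x, c.y] for c in circles])
    merged = []
    for comp in _distance_components(centers, threshold):
        members = [circles[i] for i in comp]
        wts = np.array([max(c.score, 1e-12) for c in members])
        wts = wts / wts.sum()
        x = float(np.dot(wts, [c.x for c in members]))
        y = float(np.dot(wts, [c.y for c in members]))
        r = float(np.dot(wts, [c.radius for c in members]))
        score = float(max(c.score for c in members))
        sources = {c.source for c in members}
        source = members[0].source if len(sources) == 1 else "fused"
        merged.append(DetectedCircle(x, y, r, score, source))
    merged.sort(key=lambda c: (-c.score, c.x, c.y))
    return merged


def circle_to_label(
    circle: DetectedCircle, image_size: tuple[int, int] | None = None
) -> FruitLabel:
    """Minimum circumscribed square (x ± r, y ± r), clipped to the image.

    ``image_size`` is (width, height); when omitted the label is unclipped.
    """
    xmin, xmax = circle.x - circle.radius, circle.x + circle.radius
    ymin, ymax = circle.y - circle.radius, circle.y + circle.radius
    if image_size is not None:
        W, H = image_size
        xmin, xmax = max(xmin, 0.0), min(xmax, W - 1.0)
        ymin, ymax = max(ymin, 0.0), min(ymax, H - 1.0)
    return FruitLabel(xmin, ymin, xmax, ymax, circle=circle)


def fuse_detections(
    per_classifier: dict[str, list[DetectedCircle]] | list[list[DetectedCircle]],
    threshold: float = DEDUP_THRESHOLD,
) -> list[DetectedCircle]:
    """OR-fuse the four classifiers' circle lists.

    The union of all detections is deduplicated at the 15 px threshold,
    so a fruit found by any single classifier survives into the fused
    set, and coincident detections collapse to one circle.
    """
    if isinstance(per_classifier, dict):
        lists = list(per_classifier.values())
    else:
        lists = list(per_classifier)
    union = [replace(c, source=c.source) for lst in lists for c in lst]
    return dedupe_circles(union, threshold=threshold)


def detect_circles_from_mask(
    mask: np.ndarray,
    source: str = "fused",
    sensitivity: float = SENSITIVITY,
) -> list[DetectedCircle]:
    """clean_mask → Canny/Hough → dedupe, the per-classifier detection path."""
    cleaned = clean_mask(mask)
    circles = hough_circles(cleaned, sensitivity=sensitivity, source=source)
    return dedupe_circles(circles)


def detections_to_json(circles: list[DetectedCircle], image_size=None) -> list[dict]:
    out = []
    for c in circles:
        label = circle_to_label(c, image_size)
        out.append(
            {
                "center": [c.x, c.y],
                "radius": c.radius,
                "score": c.score,
                "label": [list(v) for v in label.vertices],
                "source": c.source,
            }
        )
    return out
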