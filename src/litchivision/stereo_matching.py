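"""NCC-based stereo matching of cluster labels and 3-D localization.

The merged label of each left-image cluster is the template; it is slid
along the same image row of the right image (epipolar constraint of a
rectified pair) and compared by zero-mean normalized cross-correlation

.. math::

    \\mathrm{NCC}(d) = \\frac{\\sum_{ij} [I_1 - \\bar I_1][I_2(\\cdot - d) - \\bar I_2]}
                        {\\sqrt{\\sum_{ij} [I_1 - \\bar I_1]^2}
                         \\sqrt{\\sum_{ij} [I_2(\\cdot - d) - \\bar I_2]^2}},

which is invariant to positive linear illumination changes.  The
disparity maximizing the score is accepted when the score reaches the
0.6 threshold; the ordering constraint then discards the lower-scoring
member of any left/right order inversion, and surviving matches are
triangulated into the left-camera frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from litchivision.cluster_recognition import FruitCluster
from litchivision.errors import UndefinedSimilarityError
from litchivision.features import grayscale
from litchivision.stereo_camera import StereoRig, triangulate

NCC_THRESHOLD = 0.6
DEFAULT_DISPARITY_MAX = 200
ROW_TOLERANCE = 1.0


@dataclass(frozen=True)
class ClusterMatch:
    """A matched cluster: disparity, NCC score, optional 3-D position."""

    cluster: FruitCluster
    disparity: int
    score: float
    world_point: np.ndarray | None = None

    @property
    def left_center(self) -> tuple[float, float]:
        return self.cluster.center

    @property
    def right_center(self) -> tuple[float, float]:
        u, v = self.cluster.center
        return (u - self.disparity, v)


def _template_arrays(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        arr = grayscale(arr)
    return arr


def ncc(
    left_image: np.ndarray,
    right_image: np.ndarray,
    template_box: tuple[int, int, int, int],
    d: int,
) -> float:
    """NCC between a left template and the right window at disparity d.

    ``template_box`` is (x0, y0, w, h) in left-image pixels; the right
    window is the same box shifted left by ``d``.  Both images may be
    RGB (converted to BT.601 luminance) or grayscale.

    Raises
    ------
    UndefinedSimilarityError
        If either window has zero variance.
    ValueError
        If a window falls outside its image.
    """
    L = _template_arrays(left_image)
    R = _template_arrays(right_image)
    x0, y0, w, h = template_box
    if x0 < 0 or y0 < 0 or x0 + w > L.shape[1] or y0 + h > L.shape[0]:
        raise ValueError("template outside left image")
    if x0 - d < 0 or x0 - d + w > R.shape[1] or y0 + h > R.shape[0]:
        raise ValueError("shifted window outside right image")
    t = L[y0 : y0 + h, x0 : x0 + w]
    win = R[y0 : y0 + h, x0 - d : x0 - d + w]
    t0 = t - t.mean()
    w0 = win - win.mean()
    nt = np.sqrt(np.sum(t0**2))
    nw = np.sqrt(np.sum(w0**2))
    if nt == 0 or nw == 0:
        raise UndefinedSimilarityError("zero-variance window in NCC")
    return float(np.clip(np.sum(t0 * w0) / (nt * nw), -1.0, 1.0))


def _ncc_profile(
    L: np.ndarray, R: np.ndarray, box: tuple[int, int, int, int], d_range
) -> tuple[np.ndarray, np.ndarray]:
    """Scores for all valid disparities; windows crossing the border are
    skipped rather than zero-padded (padding would bias the normalization)."""
    x0, y0, w, h = box
    t = L[y0 : y0 + h, x0 : x0 + w]
    t0 = t - t.mean()
    nt = np.sqrt(np.sum(t0**2))
    ds, scores = [], []
    if nt == 0:
        return np.array(ds), np.array(scores)
    for d in d_range:
        if x0 - d < 0 or x0 - d + w > R.shape[1]:
            continue
        win = R[y0 : y0 + h, x0 - d : x0 - d + w]
        w0 = win - win.mean()
        nw = np.sqrt(np.sum(w0**2))
        if nw == 0:
            continue
        ds.append(d)
        scores.append(np.sum(t0 * w0) / (nt * nw))
    return np.array(ds), np.array(scores)


def match_cluster(
    left_image: np.ndarray,
    right_image: np.ndarray,
    cluster: FruitCluster,
    d_range=None,
    threshold: float = NCC_THRESHOLD,
) -> ClusterMatch | None:
    """Best same-row NCC match of one cluster label in the right image.

    Searches integer disparities in ``d_range`` (default 0..200) and
    returns a match only when the best score reaches the threshold.
    """
    if d_range is None:
        d_range = range(0, DEFAULT_DISPARITY_MAX + 1)
    L = _template_arrays(left_image)
    R = _template_arrays(right_image)
    lab = cluster.label
    H, W = L.shape
    x0 = int(np.clip(np.floor(lab.xmin), 0, W - 1))
    y0 = int(np.clip(np.floor(lab.ymin), 0, H - 1))
    x1 = int(np.clip(np.ceil(lab.xmax), x0 + 1, W))
    y1 = int(np.clip(np.ceil(lab.ymax), y0 + 1, H))
    box = (x0, y0, x1 - x0, y1 - y0)
    ds, scores = _ncc_profile(L, R, box, d_range)
    if len(ds) == 0:
        return None
    best = int(np.argmax(scores))
    if scores[best] < threshold:
        return None
    return ClusterMatch(cluster, int(ds[best]), float(scores[best]))


def match_clusters(
    left_image: np.ndarray,
    right_image: np.ndarray,
    clusters: list[FruitCluster],
    d_range=None,
    threshold: float = NCC_THRESHOLD,
) -> list[ClusterMatch]:
    out = []
    for cl in clusters:
        m = match_cluster(left_image, right_image, cl, d_range, threshold)
        if m is not None:
            out.append(m)
    return out


def enforce_constraints(
    matches: list[ClusterMatch],
    row_tolerance: float = ROW_TOLERANCE,
    drop_unanchored: bool = False,
) -> list[ClusterMatch]:
    """Apply the epipolar-row and ordering constraints.

    Matches whose left and right centres differ by more than
    ``row_tolerance`` rows are discarded.  The ordering constraint
    (left-to-right order must agree between the two views) binds only
    pairs that share epipolar rows — i.e. whose cluster labels overlap
    vertically; objects in disjoint rows may legitimately swap
    horizontal order with depth.  Matches are admitted greedily by
    descending NCC score and any candidate that inverts the order
    against an already-admitted row-overlapping match is dropped — the
    lower-scoring member of each crossing pair loses.  With
    ``drop_unanchored`` the leftmost match is removed as well (a cluster
    with no left-side anchor in the right image cannot be ordered).
    """
    kept = [
        m
        for m in matches
        if abs(m.left_center[1] - m.right_center[1]) <= row_tolerance
    ]

    def rows_overlap(a: ClusterMatch, b: ClusterMatch) -> bool:
        la, lb = a.cluster.label, b.cluster.label
        return min(la.ymax, lb.ymax) >= max(la.ymin, lb.ymin)

    order = sorted(kept, key=lambda m: -m.score)
    admitted: list[ClusterMatch] = []
    for cand in order:
        ok = True
        for other in admitted:
            if not rows_overlap(cand, other):
                continue
            du = cand.left_center[0] - other.left_center[0]
            dv = cand.right_center[0] - other.right_center[0]
            if du * dv < 0 or (du == 0) != (dv == 0):
                ok = False
                break
        if ok:
            admitted.append(cand)
    admitted.sort(key=lambda m: m.left_center[0])
    if drop_unanchored and admitted:
        admitted = admitted[1:]
    return admitted


def localize_matches(rig: StereoRig, matches: list[ClusterMatch]) -> list[ClusterMatch]:
    """Triangulate each matched cluster centre into the left-camera frame."""
    out = []
    for m in matches:
        wp = triangulate(rig, m.left_center, m.disparity)
        out.append(replace(m, world_point=wp))
    return out


def matches_to_json(matches: list[ClusterMatch]) -> list[dict]:
    out = []
    for m in matches:
        doc = {
            "left_center": list(m.left_center),
            "right_center": list(m.right_center),
            "disparity": m.disparity,
            "score": m.score,
        }
        if m.world_point is not None:
            doc["world_mm"] = [float(v) for v in m.world_point]
        out.append(doc)
    return out
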