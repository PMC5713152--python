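"""Seeded synthetic stereo litchi scenes with full ground truth.

The generator emulates the orchard imaging conditions the pipeline is
built for: red, speckle-textured, roughly circular fruits of radius
30–50 px growing singly (category A) or in clusters of two (B) or more
(C) with centre spacings below the 40 px category threshold; a green /
brown canopy background with sky; three illumination modes (sunny
front-lighting with specular spots on the fruit, sunny back-lighting
with darkened fruit, and low-contrast cloudy light); and optional
partial occlusion by foreground leaves.  The right image of each stereo
pair is rendered by shifting every object left by its pinhole disparity
``d = ax · baseline / depth`` (200 mm baseline), so triangulating the
rendered disparity recovers the assigned depth within rounding.

Fruit surfaces carry multiplicative speckle plus radial shading rather
than a litchi-rind model: enough structure for the Tamura features and
the NCC matcher to be informative.  All randomness flows from the single
``seed`` of the :class:`SceneSpec`; the same spec yields byte-identical
images.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.optimize import brentq

from litchivision.cluster_recognition import CLUSTER_DIAMETER
from litchivision.errors import LayoutError
from litchivision.fruit_detection import _distance_components
from litchivision.stereo_camera import DEFAULT_BASELINE_MM

ILLUMINATIONS = ("sunny_front", "sunny_back", "cloudy")

#: depth assigned to the canopy background, mm
_BACKGROUND_DEPTH = 2500.0
#: minimum anchor distance between distinct clusters, px
_CLUSTER_SEPARATION = 170.0
#: minimum centre distance between fruits of different clusters, px
_MEMBER_SEPARATION = 120.0


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic stereo scene."""

    image_size: tuple[int, int] = (640, 480)  # (width, height)
    cluster_plan: tuple[int, ...] = (1, 2, 3, 1)
    radius_range: tuple[float, float] = (30.0, 50.0)
    spacing_range: tuple[float, float] = (26.0, 36.0)
    depth_range_mm: tuple[float, float] = (900.0, 1800.0)
    illumination: str = "cloudy"
    occlusion_fraction: float = 0.0
    occluded_cluster_rate: float = 0.5
    ax: float = 600.0
    baseline_mm: float = DEFAULT_BASELINE_MM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.illumination not in ILLUMINATIONS:
            raise ValueError(f"illumination must be one of {ILLUMINATIONS}")
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise ValueError("occlusion_fraction must be in [0, 1]")
        lo, hi = self.spacing_range
        if hi >= CLUSTER_DIAMETER:
            raise ValueError(
                "clustered spacings must stay below the 40 px category threshold"
            )


@dataclass
class FruitTruth:
    """Ground truth for one rendered fruit."""

    left_center: tuple[float, float]
    right_center: tuple[float, float]
    radius: float
    depth_mm: float
    disparity: int
    cluster_id: int
    category: str
    occluded: bool


@dataclass
class ClusterTruth:
    """Ground truth for one cluster: merged box of the member fruit labels."""

    cluster_id: int
    category: str
    box: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    center: tuple[float, float]
    disparity: int
    depth_mm: float
    occluded: bool


@dataclass
class SceneTruth:
    fruits: list[FruitTruth] = field(default_factory=list)
    clusters: list[ClusterTruth] = field(default_factory=list)

    def to_json(self, path) -> None:
        doc = {
            "fruits": [asdict(f) for f in self.fruits],
            "clusters": [asdict(c) for c in self.clusters],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SceneTruth":
        with open(path) as fh:
            doc = json.load(fh)
        fruits = [
            FruitTruth(
                tuple(f["left_center"]), tuple(f["right_center"]), f["radius"],
                f["depth_mm"], f["disparity"], f["cluster_id"], f["category"],
                f["occluded"],
            )
            for f in doc["fruits"]
        ]
        clusters = [
            ClusterTruth(
                c["cluster_id"], c["category"], tuple(c["box"]),
                tuple(c["center"]), c["disparity"], c["depth_mm"], c["occluded"],
            )
            for c in doc["clusters"]
        ]
        return cls(fruits, clusters)


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------


def _category_of(size: int) -> str:
    return "A" if size == 1 else ("B" if size == 2 else "C")


def _place_clusters(spec: SceneSpec, rng: np.random.Generator):
    """Sample cluster anchors, member offsets, radii and depths.

    Rejection-samples until every planned cluster fits inside both views
    and the single-linkage categories of the true centres reproduce the
    plan exactly; raises :class:`LayoutError` when the plan cannot be
    placed.
    """
    W, H = spec.image_size
    r_lo, r_hi = spec.radius_range
    d_max = int(round(spec.ax * spec.baseline_mm / spec.depth_range_mm[0]))
    margin = r_hi + 4.0
    x_lo, x_hi = margin + d_max, W - margin
    y_lo, y_hi = margin, H - margin
    if x_hi <= x_lo or y_hi <= y_lo:
        raise LayoutError("image too small for the fruit radii and disparities")

    for _ in range(300):
        anchors = []
        ok = True
        for _ in spec.cluster_plan:
            for _ in range(200):
                cand = np.array(
                    [rng.uniform(x_lo, x_hi), rng.uniform(y_lo, y_hi)]
                )
                if all(
                    np.linalg.norm(cand - a) >= _CLUSTER_SEPARATION for a in anchors
                ):
                    anchors.append(cand)
                    break
            else:
                ok = False
                break
        if not ok:
            continue

        centers, radii, cluster_ids = [], [], []
        for ci, size in enumerate(spec.cluster_plan):
            placed = [anchors[ci]]
            for _ in range(size - 1):
                for _ in range(200):
                    base = placed[rng.integers(len(placed))]
                    ang = rng.uniform(0, 2 * np.pi)
                    s = rng.uniform(*spec.spacing_range)
                    cand = base + s * np.array([np.cos(ang), np.sin(ang)])
                    if not (x_lo <= cand[0] <= x_hi and y_lo <= cand[1] <= y_hi):
                        continue
                    others = [
                        c for c, cid in zip(centers, cluster_ids) if cid != ci
                    ] + [a for ai, a in enumerate(anchors) if ai != ci]
                    if all(np.linalg.norm(cand - p) >= 18.0 for p in placed) and all(
                        np.linalg.norm(cand - o) >= _MEMBER_SEPARATION for o in others
                    ):
                        placed.append(cand)
                        break
                else:
                    ok = False
                    break
            if not ok:
                break
            for p in placed:
                centers.append(p)
                radii.append(rng.uniform(r_lo, r_hi))
                cluster_ids.append(ci)
        if not ok or not centers:
            continue

        # definitional closure: categories from the true centres must
        # reproduce the plan
        comps = _distance_components(np.array(centers), CLUSTER_DIAMETER)
        comp_ids = [sorted({cluster_ids[i] for i in comp}) for comp in comps]
        if sorted(map(tuple, comp_ids)) != sorted(
            (ci,) for ci in range(len(spec.cluster_plan))
        ):
            continue
        sizes_ok = all(
            len(comp) == spec.cluster_plan[ids[0]]
            for comp, ids in zip(comps, comp_ids)
        )
        if sizes_ok:
            return np.array(centers), np.array(radii), np.array(cluster_ids)
    raise LayoutError("could not place the cluster plan inside the image")


def _occlusion_offset(radius: float, fraction: float) -> float:
    """Centre distance of an equal-radius occluder covering the fraction."""
    if fraction <= 0:
        return 4.0 * radius
    target = fraction * np.pi * radius**2

    def lens(delta):
        if delta >= 2 * radius:
            return 0.0
        a = 2 * radius**2 * np.arccos(delta / (2 * radius))
        b = 0.5 * delta * np.sqrt(4 * radius**2 - delta**2)
        return a - b

    if fraction >= 1.0:
        return 0.0
    return float(brentq(lambda d: lens(d) - target, 0.0, 2 * radius))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _smooth_noise(rng: np.random.Generator, shape, scale: float = 2.0) -> np.ndarray:
    """Seeded multiplicative speckle field, smoothed to a few-px scale."""
    from scipy.ndimage import gaussian_filter

    noise = rng.uniform(-1.0, 1.0, size=shape)
    noise = gaussian_filter(noise, scale)
    span = np.abs(noise).max() + 1e-12
    return noise / span


def _fruit_patch(
    rng: np.random.Generator, radius: float, illumination: str
) -> tuple[np.ndarray, np.ndarray]:
    """RGB patch and alpha mask of one fruit (identical in both views)."""
    r = int(np.ceil(radius))
    size = 2 * r + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    rho = np.sqrt(xx**2 + yy**2)
    inside = rho <= radius
    shade = 1.0 - 0.45 * (rho / radius) ** 2
    speckle = 1.0 + 0.22 * _smooth_noise(rng, (size, size), scale=1.6)
    base = np.array(
        [200.0 + rng.uniform(-15, 25), 30.0 + rng.uniform(-10, 20),
         45.0 + rng.uniform(-10, 15)]
    )
    patch = base[None, None, :] * (shade * speckle)[..., None]
    if illumination == "sunny_front":
        # specular spot displaced toward the light
        sx, sy = -0.35 * radius, -0.35 * radius
        spot = np.exp(-(((xx - sx) ** 2 + (yy - sy) ** 2) / (0.18 * radius**2)))
        patch = patch + 220.0 * spot[..., None]
    elif illumination == "sunny_back":
        patch = patch * 0.5
    elif illumination == "cloudy":
        patch = patch * 0.82
    return np.clip(patch, 0, 255), inside


def _leaf_patch(
    rng: np.random.Generator, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Elongated green leaf used as an occluder."""
    r = int(np.ceil(radius))
    size = 2 * r + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    ang = rng.uniform(0, np.pi)
    u = xx * np.cos(ang) + yy * np.sin(ang)
    v = -xx * np.sin(ang) + yy * np.cos(ang)
    inside = (u / radius) ** 2 + (v / (0.72 * radius)) ** 2 <= 1.0
    base = np.array([40.0 + rng.uniform(0, 25), 110.0 + rng.uniform(0, 50),
                     35.0 + rng.uniform(0, 20)])
    texture = 1.0 + 0.18 * _smooth_noise(rng, (size, size), scale=2.5)
    patch = np.clip(base[None, None, :] * texture[..., None], 0, 255)
    return patch, inside


def _stamp(canvas: np.ndarray, patch: np.ndarray, mask: np.ndarray,
           cx: float, cy: float) -> None:
    """Alpha-stamp a patch centred at (cx, cy), clipped to the canvas."""
    H, W = canvas.shape[:2]
    ph, pw = mask.shape
    x0 = int(round(cx)) - pw // 2
    y0 = int(round(cy)) - ph // 2
    xs0, ys0 = max(x0, 0), max(y0, 0)
    xs1, ys1 = min(x0 + pw, W), min(y0 + ph, H)
    if xs0 >= xs1 or ys0 >= ys1:
        return
    sub = mask[ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0]
    canvas[ys0:ys1, xs0:xs1][sub] = patch[ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0][sub]


def _background(rng: np.random.Generator, width: int, height: int,
                illumination: str) -> np.ndarray:
    """Canopy backdrop: sky gradient, green foliage blobs, brown branches."""
    yy = np.linspace(0.0, 1.0, height)[:, None]
    sky = np.empty((height, width, 3))
    sky[..., 0] = 150 - 60 * yy
    sky[..., 1] = 170 - 60 * yy
    sky[..., 2] = 185 - 50 * yy
    canvas = sky
    n_leaves = max(30, width * height // 6000)
    for _ in range(n_leaves):
        r = rng.uniform(18, 55)
        patch, mask = _leaf_patch(rng, r)
        _stamp(canvas, patch, mask,
               rng.uniform(0, width), rng.uniform(height * 0.15, height))
    n_branches = max(4, width // 120)
    for _ in range(n_branches):
        x0, y0 = rng.uniform(0, width), rng.uniform(0, height)
        ang = rng.uniform(-0.7, 0.7) + rng.choice([0.0, np.pi / 2])
        length = rng.uniform(80, 220)
        thick = rng.uniform(3, 7)
        t = np.linspace(0, length, int(length * 2))
        xs = x0 + t * np.cos(ang)
        ys = y0 + t * np.sin(ang)
        shade = rng.uniform(0.8, 1.2)
        color = np.array([100.0, 70.0, 45.0]) * shade
        for dx in np.arange(-thick / 2, thick / 2 + 0.5, 0.5):
            xi = np.clip(np.round(xs + dx * np.sin(ang)).astype(int), 0, width - 1)
            yi = np.clip(np.round(ys - dx * np.cos(ang)).astype(int), 0, height - 1)
            canvas[yi, xi] = color
    if illumination == "sunny_front":
        canvas = canvas * 1.1 + 10
    elif illumination == "sunny_back":
        canvas = canvas * 1.05 + 25  # bright back-lit canopy, dark fruit
    elif illumination == "cloudy":
        canvas = (canvas - 128) * 0.7 + 120
    return np.clip(canvas, 0, 255)


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, SceneTruth]:
    """Render a stereo pair plus ground truth.

    Returns
    -------
    (left, right, truth)
        Two (H, W, 3) uint8 images and the :class:`SceneTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    W, H = spec.image_size
    d_bg = int(round(spec.ax * spec.baseline_mm / _BACKGROUND_DEPTH))
    backdrop = _background(rng, W + d_bg, H, spec.illumination)
    left = backdrop[:, d_bg:].copy()
    right = backdrop[:, :W].copy()

    truth = SceneTruth()
    if len(spec.cluster_plan) == 0:
        return left.astype(np.uint8), right.astype(np.uint8), truth

    centers, radii, cluster_ids = _place_clusters(spec, rng)

    depths = rng.uniform(*spec.depth_range_mm, size=len(spec.cluster_plan))
    # far clusters first so nearer fruit paints over farther fruit
    cluster_order = np.argsort(-depths)
    occluded_flags = [
        spec.occlusion_fraction > 0 and rng.random() < spec.occluded_cluster_rate
        for _ in spec.cluster_plan
    ]

    stamps = []  # (depth, patch, mask, cx, cy, d)
    for ci in cluster_order:
        depth = float(depths[ci])
        d = int(round(spec.ax * spec.baseline_mm / depth))
        member_idx = np.nonzero(cluster_ids == ci)[0]
        category = _category_of(len(member_idx))
        boxes = []
        for i in member_idx:
            (cx, cy), r = centers[i], float(radii[i])
            patch, mask = _fruit_patch(rng, r, spec.illumination)
            stamps.append(("fruit", patch, mask, cx, cy, d))
            truth.fruits.append(
                FruitTruth(
                    left_center=(float(cx), float(cy)),
                    right_center=(float(cx - d), float(cy)),
                    radius=r,
                    depth_mm=depth,
                    disparity=d,
                    cluster_id=int(ci),
                    category=category,
                    occluded=bool(occluded_flags[ci]),
                )
            )
            boxes.append((cx - r, cy - r, cx + r, cy + r))
            if occluded_flags[ci]:
                off = _occlusion_offset(r, spec.occlusion_fraction)
                ang = rng.uniform(0, 2 * np.pi)
                ox = cx + off * np.cos(ang)
                oy = cy + off * np.sin(ang)
                lpatch, lmask = _leaf_patch(rng, r)
                # occluders sit slightly in front of the fruit
                stamps.append(("leaf", lpatch, lmask, ox, oy, d + 3))
        xmin = min(b[0] for b in boxes)
        ymin = min(b[1] for b in boxes)
        xmax = max(b[2] for b in boxes)
        ymax = max(b[3] for b in boxes)
        truth.clusters.append(
            ClusterTruth(
                cluster_id=int(ci),
                category=category,
                box=(float(xmin), float(ymin), float(xmax), float(ymax)),
                center=(float(0.5 * (xmin + xmax)), float(0.5 * (ymin + ymax))),
                disparity=d,
                depth_mm=depth,
                occluded=bool(occluded_flags[ci]),
            )
        )

    # paint fruits in depth order, then their occluders on top
    for kind, patch, mask, cx, cy, d in [s for s in stamps if s[0] == "fruit"]:
        _stamp(left, patch, mask, cx, cy)
        _stamp(right, patch, mask, cx - d, cy)
    for kind, patch, mask, cx, cy, d in [s for s in stamps if s[0] == "leaf"]:
        _stamp(left, patch, mask, cx, cy)
        _stamp(right, patch, mask, cx - d, cy)

    truth.fruits.sort(key=lambda f: f.cluster_id)
    truth.clusters.sort(key=lambda c: c.cluster_id)
    return (
        np.clip(left, 0, 255).astype(np.uint8),
        np.clip(right, 0, 255).astype(np.uint8),
        truth,
    )


def generate_training_patches(
    n_per_class: int = 150,
    seed: int = 0,
    image_size: tuple[int, int] = (640, 480),
    patch_size: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled 40x40 training patches across the three illumination modes.

    Fruit patches are cropped around generated fruits; background
    patches from regions at least a diameter away from every fruit.
    Returns a ``(2 * n_per_class, 40, 40, 3)`` uint8 array and a binary
    label vector (1 = fruit).
    """
    if n_per_class < 2:
        raise ValueError("need at least 2 patches per class")
    rng = np.random.default_rng(seed)
    half = patch_size // 2
    fruit_patches: list[np.ndarray] = []
    bg_patches: list[np.ndarray] = []
    scene_seed = int(rng.integers(2**31 - 1))
    mode_cycle = 0
    while len(fruit_patches) < n_per_class or len(bg_patches) < n_per_class:
        spec = SceneSpec(
            image_size=image_size,
            cluster_plan=(1, 2, 3),
            illumination=ILLUMINATIONS[mode_cycle % 3],
            seed=scene_seed + mode_cycle,
        )
        mode_cycle += 1
        left, _, truth = generate_scene(spec)
        H, W = left.shape[:2]
        for f in truth.fruits:
            if len(fruit_patches) >= n_per_class:
                break
            cx, cy = f.left_center
            x0 = int(np.clip(round(cx) - half, 0, W - patch_size))
            y0 = int(np.clip(round(cy) - half, 0, H - patch_size))
            fruit_patches.append(left[y0 : y0 + patch_size, x0 : x0 + patch_size])
        centers = np.array([f.left_center for f in truth.fruits])
        radii = np.array([f.radius for f in truth.fruits])
        # background samples mirror manual cropping around the canopy: most
        # are fruit-free, but every third is taken just outside a fruit's
        # rim (a sliver of fruit in one corner), which sharpens the window
        # classifiers' boundary decisions
        clearance = radii + half * np.sqrt(2.0) + 3.0
        tries = 0
        while len(bg_patches) < n_per_class and tries < 400:
            tries += 1
            if tries % 3 == 0 and len(centers):
                i = int(rng.integers(len(centers)))
                ang = rng.uniform(0, 2 * np.pi)
                dist = radii[i] + half * rng.uniform(1.05, 1.3)
                mid = centers[i] + dist * np.array([np.cos(ang), np.sin(ang)])
                x0 = int(np.clip(round(mid[0]) - half, 0, W - patch_size))
                y0 = int(np.clip(round(mid[1]) - half, 0, H - patch_size))
                mid = np.array([x0 + half, y0 + half])
                near = np.linalg.norm(centers - mid, axis=1) - radii
                # keep only slivers: the patch centre stays off every fruit
                if np.all(near > 0.55 * half):
                    bg_patches.append(
                        left[y0 : y0 + patch_size, x0 : x0 + patch_size]
                    )
                continue
            x0 = int(rng.integers(0, W - patch_size))
            y0 = int(rng.integers(0, H - patch_size))
            mid = np.array([x0 + half, y0 + half])
            if np.all(np.linalg.norm(centers - mid, axis=1) > clearance):
                bg_patches.append(left[y0 : y0 + patch_size, x0 : x0 + patch_size])
    patches = np.stack(fruit_patches[:n_per_class] + bg_patches[:n_per_class])
    labels = np.concatenate([np.ones(n_per_class, int), np.zeros(n_per_class, int)])
    return patches, labels
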