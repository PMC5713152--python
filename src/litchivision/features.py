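"""The 10-dimensional colour + texture feature vector.

Mature litchi fruits are separated from leaves, branches and sky by four
*effective colour components* — the raw channel difference R−B, the HSI
intensity I = (R+G+B)/3, the Cb chrominance of YCbCr (BT.601 full-range,
+128 offset, so achromatic pixels map to 128) and the b* channel of
CIE L*a*b* (sRGB primaries, D65 white) — together with the six Tamura
perceptual texture statistics: coarseness, contrast, directionality,
line-likeness, regularity and roughness.

Feature vector layout (:data:`FEATURE_NAMES`)::

    [R-B, I, Cb, b*, coarseness, contrast, directionality,
     line-likeness, regularity, roughness]

Colour components are averaged over the analysis window; texture is
computed on the window's BT.601 luminance.  Patches must be at least
8x8 for the dyadic coarseness neighbourhoods; the canonical window is
the 40x40 training-patch size.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2lab

from litchivision.errors import BoundsError, ChannelError, PatchSizeError

FEATURE_NAMES = (
    "R-B",
    "I",
    "Cb",
    "b*",
    "coarseness",
    "contrast",
    "directionality",
    "line_likeness",
    "regularity",
    "roughness",
)

MIN_TEXTURE_SIZE = 8
PATCH_SIZE = 40

#: number of orientation bins over [0, pi) for directionality
N_DIR_BINS = 16
#: gradient-magnitude threshold below which pixels do not vote
_DIR_MAG_THRESHOLD = 12.0
#: co-occurrence displacement (px) for line-likeness
_LINE_DISTANCE = 4


def grayscale(image: np.ndarray) -> np.ndarray:
    """BT.601 luminance 0.299 R + 0.587 G + 0.114 B as float64."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim != 3 or img.shape[2] != 3:
        raise ChannelError(f"expected HxW or HxWx3 image, got {img.shape}")
    return img @ np.array([0.299, 0.587, 0.114])


def color_components(patch: np.ndarray) -> np.ndarray:
    """Per-pixel effective colour components of an RGB patch in [0, 255].

    Returns an (H, W, 4) float array ordered (R−B, I, Cb, b*).
    """
    img = np.asarray(patch, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ChannelError(f"expected HxWx3 colour input, got {img.shape}")
    R, G, B = img[..., 0], img[..., 1], img[..., 2]
    rb = R - B
    intensity = (R + G + B) / 3.0
    cb = 128.0 - 0.168736 * R - 0.331264 * G + 0.5 * B
    bstar = rgb2lab(np.clip(img, 0, 255) / 255.0)[..., 2]
    return np.stack([rb, intensity, cb, bstar], axis=-1)


def color_components_mean(patch: np.ndarray) -> np.ndarray:
    """Patch-averaged (R−B, I, Cb, b*), a length-4 vector."""
    return color_components(patch).mean(axis=(0, 1))


# ---------------------------------------------------------------------------
# Tamura texture statistics
# ---------------------------------------------------------------------------


from functools import lru_cache


@lru_cache(maxsize=64)
def _shift_index(n: int, d: int) -> np.ndarray:
    return np.clip(np.arange(n) + d, 0, n - 1)


@lru_cache(maxsize=8)
def _pixel_grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    return np.mgrid[0:h, 0:w]


def _shift(A: np.ndarray, d: int, axis: int) -> np.ndarray:
    """Shift with edge replication (no wrap-around)."""
    idx = _shift_index(A.shape[axis], d)
    return A[:, idx] if axis == 1 else A[idx]


def _coarseness_map(gray: np.ndarray, kmax: int = 5) -> np.ndarray:
    """Per-pixel best dyadic window size 2^k*.

    For every pixel, averages over 2^k x 2^k neighbourhoods are compared
    through horizontal/vertical differences of displaced means; the k
    maximizing the difference wins (ties to the smallest k).  Borders
    are handled by reflection/edge replication.  The window exponent is
    capped at ``kmax`` (2^5 = 32 px inside a 40x40 patch).
    """
    h, w = gray.shape
    kmax = int(min(kmax, np.floor(np.log2(max(min(h, w), 2)))))
    ebest = np.full((kmax, h, w), -1.0)
    for k in range(1, kmax + 1):
        size = 2**k
        A = ndi.uniform_filter(gray, size=size, mode="reflect")
        half = 2 ** (k - 1)
        eh = np.abs(_shift(A, half, axis=1) - _shift(A, -half, axis=1))
        ev = np.abs(_shift(A, half, axis=0) - _shift(A, -half, axis=0))
        e = np.maximum(eh, ev)
        # displaced averages are only meaningful where their support fits
        # inside the patch; padded borders would bias the scale choice
        if k > 1:
            margin = min(size, (min(h, w) - 1) // 2)
            valid = np.zeros((h, w), dtype=bool)
            valid[margin : h - margin, margin : w - margin] = True
            e = np.where(valid, e, -1.0)
        ebest[k - 1] = e
    kstar = np.argmax(ebest, axis=0) + 1  # ties -> smallest k
    return 2.0**kstar


def _coarseness(gray: np.ndarray, kmax: int = 5) -> float:
    """Mean best dyadic window size over the patch."""
    return float(np.mean(_coarseness_map(gray, kmax)))


def _contrast(gray: np.ndarray) -> float:
    """Tamura contrast sigma / kurtosis^(1/4); zero for flat patches."""
    mu = gray.mean()
    var = gray.var()
    if var <= 1e-10:  # guards round-off variance of flat patches
        return 0.0
    m4 = np.mean((gray - mu) ** 4)
    kurtosis = m4 / var**2
    return float(np.sqrt(var) / kurtosis**0.25)


def _gradient_angles(gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prewitt gradient magnitude and orientation folded into [0, pi)."""
    kx = np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], dtype=float)
    ky = kx.T
    dh = ndi.convolve(gray, kx, mode="reflect")
    dv = ndi.convolve(gray, ky, mode="reflect")
    mag = (np.abs(dh) + np.abs(dv)) / 2.0
    theta = np.mod(np.arctan2(dv, dh) + np.pi / 2.0, np.pi)
    return mag, theta


class _TextureFields:
    """Per-pixel texture fields computed once per patch.

    Full-patch and sub-window statistics are both read off these fields
    by slicing, so the quadrant features used by regularity share the
    full-patch gradient/coarseness context.
    """

    def __init__(self, gray: np.ndarray):
        self.gray = gray
        h, w = gray.shape
        self.coarse = _coarseness_map(gray)
        mag, theta = _gradient_angles(gray)
        self.mag, self.theta = mag, theta
        self.bins = np.minimum(
            (theta / np.pi * N_DIR_BINS).astype(int), N_DIR_BINS - 1
        )
        self.voting = mag >= _DIR_MAG_THRESHOLD
        # direction co-occurrence along the local edge direction
        dx = np.round(_LINE_DISTANCE * np.cos(theta)).astype(int)
        dy = np.round(_LINE_DISTANCE * np.sin(theta)).astype(int)
        yy, xx = _pixel_grid(h, w)
        y2 = np.clip(yy + dy, 0, h - 1)
        x2 = np.clip(xx + dx, 0, w - 1)
        self.keep = self.voting & self.voting[y2, x2]
        self.cosdiff = np.cos(
            (self.bins - self.bins[y2, x2]) * (2.0 * np.pi / N_DIR_BINS)
        )

    def directionality(self, sl=np.s_[:, :]) -> float:
        """Sharpness of the orientation histogram, in [0, 1].

        1 − normalized second moment of the histogram about its peak
        (wrap-around angular distance); a single dominant orientation
        scores near 1, an isotropic patch near 0.
        """
        voting = self.voting[sl]
        hist = np.bincount(self.bins[sl][voting], minlength=N_DIR_BINS).astype(float)
        total = hist.sum()
        if total == 0:
            hist = np.full(N_DIR_BINS, 1.0 / N_DIR_BINS)
        else:
            hist = hist / total
        peak = int(np.argmax(hist))
        centers = (np.arange(N_DIR_BINS) + 0.5) * np.pi / N_DIR_BINS
        delta = np.abs(centers - centers[peak])
        delta = np.minimum(delta, np.pi - delta)  # orientation wrap-around
        moment = float(np.sum(hist * delta**2))
        max_moment = (np.pi / 2.0) ** 2
        return float(1.0 - moment / max_moment)

    def line_likeness(self, sl=np.s_[:, :]) -> float:
        """Mean direction co-occurrence cosine along edge directions.

        Parallel structure scores near 1, random texture near 0.
        """
        keep = self.keep[sl]
        if not np.any(keep):
            return 0.0
        return float(np.mean(self.cosdiff[sl][keep]))


def _directionality(mag: np.ndarray, theta: np.ndarray) -> float:
    fields = _TextureFields.__new__(_TextureFields)
    fields.bins = np.minimum((theta / np.pi * N_DIR_BINS).astype(int), N_DIR_BINS - 1)
    fields.voting = mag >= _DIR_MAG_THRESHOLD
    return fields.directionality()


def _regularity(fields: _TextureFields, r: float = 0.25) -> float:
    """1 − r · (summed variability of the first four features over quadrants).

    Coarseness, contrast, directionality and line-likeness are evaluated
    on the 2x2 sub-window partition (sliced from the full-patch texture
    fields); each feature's standard deviation across the quadrants is
    normalized by its mean magnitude so the four contributions are
    comparable.  A perfectly homogeneous patch has regularity 1.
    """
    h, w = fields.gray.shape
    h2, w2 = h // 2, w // 2
    if min(h2, w2) < MIN_TEXTURE_SIZE:
        return 1.0
    slices = [
        np.s_[:h2, :w2],
        np.s_[:h2, w2:],
        np.s_[h2:, :w2],
        np.s_[h2:, w2:],
    ]
    vals = np.array(
        [
            [
                float(np.mean(fields.coarse[sl])),
                _contrast(fields.gray[sl]),
                fields.directionality(sl),
                fields.line_likeness(sl),
            ]
            for sl in slices
        ]
    )
    cv = vals.std(axis=0) / (np.abs(vals.mean(axis=0)) + 1e-12)
    return float(1.0 - r * cv.sum())


def tamura_features(patch: np.ndarray) -> np.ndarray:
    """Six Tamura texture statistics of a grayscale patch.

    Order: coarseness, contrast, directionality, line-likeness,
    regularity, roughness (= coarseness + contrast).

    Raises
    ------
    PatchSizeError
        If either side is smaller than :data:`MIN_TEXTURE_SIZE`.
    """
    gray = np.asarray(patch, dtype=float)
    if gray.ndim == 3:
        gray = grayscale(gray)
    if gray.ndim != 2:
        raise ChannelError(f"expected a 2-D grayscale patch, got {gray.shape}")
    if min(gray.shape) < MIN_TEXTURE_SIZE:
        raise PatchSizeError(
            f"patch {gray.shape} smaller than {MIN_TEXTURE_SIZE}x{MIN_TEXTURE_SIZE}"
        )
    fields = _TextureFields(gray)
    crs = float(np.mean(fields.coarse))
    con = _contrast(gray)
    fdir = fields.directionality()
    lin = fields.line_likeness()
    reg = _regularity(fields)
    rough = crs + con
    return np.array([crs, con, fdir, lin, reg, rough])


def window_features(image: np.ndarray, box: tuple[int, int, int, int]) -> np.ndarray:
    """10-feature vector of an analysis window.

    Parameters
    ----------
    image : (H, W, 3) array in [0, 255]
    box : (x0, y0, w, h)
        Top-left corner and size of the window, 0-based pixels.
    """
    x0, y0, w, h = box
    H, W = image.shape[:2]
    if x0 < 0 or y0 < 0 or x0 + w > W or y0 + h > H:
        raise BoundsError(f"window {box} outside {W}x{H} image")
    patch = np.asarray(image, dtype=float)[y0 : y0 + h, x0 : x0 + w]
    color = color_components_mean(patch)
    texture = tamura_features(grayscale(patch))
    return np.concatenate([color, texture])


def pixel_neighborhood_features(image: np.ndarray, pixel: tuple[int, int]) -> np.ndarray:
    """10-feature vector anchored on a single pixel.

    Colour components are averaged over the 3x3 neighbourhood (borders by
    reflection).  A 3x3 neighbourhood cannot support texture statistics,
    so the six texture components come from the 40x40 context window
    centred at the pixel, shifted inside the image near borders.
    """
    x, y = pixel
    img = np.asarray(image, dtype=float)
    H, W = img.shape[:2]
    if not (0 <= x < W and 0 <= y < H):
        raise BoundsError(f"pixel {pixel} outside {W}x{H} image")
    padded = np.pad(img, ((1, 1), (1, 1), (0, 0)), mode="reflect")
    neigh = padded[y : y + 3, x : x + 3]
    color = color_components_mean(neigh)

    half = PATCH_SIZE // 2
    x0 = int(np.clip(x - half, 0, max(W - PATCH_SIZE, 0)))
    y0 = int(np.clip(y - half, 0, max(H - PATCH_SIZE, 0)))
    ctx = grayscale(img[y0 : y0 + PATCH_SIZE, x0 : x0 + PATCH_SIZE])
    texture = tamura_features(ctx)
    return np.concatenate([color, texture])
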