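"""Four supervised fruit / non-fruit classifiers and mask segmentation.

Each classifier is trained on labelled 40x40 patches described by the
10-dimensional colour + Tamura feature vector (class ``c1`` = fruit,
``c2`` = non-fruit) and turns a colour image into one binary fruit mask:

* :class:`BayesClassifier` — naive Bayes with per-feature Gaussian
  class-conditionals and frequency priors,
* :class:`KnnClassifier` — k-nearest neighbours under cosine similarity
  (default k = 5, ties broken toward non-fruit),
* :class:`BpClassifier` — a three-layer sigmoid network (9 input neurons
  fed by the 3x3 pixel neighbourhood, hidden size J = round(sqrt(m+n)) + a,
  default J = 7) trained by full-batch gradient backpropagation,
* :class:`SvmClassifier` — a linear soft-margin SVM (C = 10), features
  z-scored internally.

The window classifiers slide a 40x40 sub-window over the image (default
stride 8); a pixel is foreground iff at least half of the windows
covering it vote fruit.  The BP network instead classifies candidate
pixels directly from their 3x3 grayscale neighbourhood, with a cheap
fruit-colour (R−B) gate learned from the training patches deciding which
pixels are candidates.

All models serialize to JSON and reload with bit-identical predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from litchivision.errors import (
    DegenerateProblemError,
    MissingModelError,
    ParameterError,
    UndefinedSimilarityError,
)
from litchivision.features import (
    PATCH_SIZE,
    color_components_mean,
    grayscale,
    tamura_features,
    window_features,
)

FRUIT, NON_FRUIT = 1, 0  # c1, c2

_VAR_FLOOR = 1e-9
DEFAULT_SEED = 1234


@dataclass
class TrainingSet:
    """Feature matrix (n, 10) plus binary labels (1 = fruit)."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2 or len(self.features) != len(self.labels):
            raise ValueError("features must be (n, d) matching labels")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite feature values")
        if len(np.unique(self.labels)) < 2:
            raise DegenerateProblemError("both classes must be present")


def patch_features(patches: np.ndarray) -> np.ndarray:
    """Stack of 10-feature vectors for an (n, 40, 40, 3) patch array."""
    return np.array(
        [window_features(p, (0, 0, p.shape[1], p.shape[0])) for p in patches]
    )


def training_set_from_patches(
    fruit_patches: np.ndarray, background_patches: np.ndarray
) -> TrainingSet:
    feats = np.vstack([patch_features(fruit_patches), patch_features(background_patches)])
    labels = np.concatenate(
        [np.ones(len(fruit_patches), int), np.zeros(len(background_patches), int)]
    )
    return TrainingSet(feats, labels)


# ---------------------------------------------------------------------------
# naive Bayes
# ---------------------------------------------------------------------------


class BayesClassifier:
    """Gaussian naive Bayes over the 10 features.

    Posterior P(c_i | X) ∝ P(c_i) ∏_j N(x_j; mean_ij, var_ij); a fruit
    decision requires P(c1 | X) > P(c2 | X).  Zero-variance features are
    floored at 1e-9 rather than rejected.
    """

    kind = "bayes"

    def __init__(self, priors, means, variances):
        self.priors = np.asarray(priors, dtype=float)  # [non-fruit, fruit]
        self.means = np.asarray(means, dtype=float)  # (2, d)
        self.variances = np.maximum(np.asarray(variances, dtype=float), _VAR_FLOOR)

    @classmethod
    def train(cls, data: TrainingSet) -> "BayesClassifier":
        priors, means, variances = [], [], []
        for c in (NON_FRUIT, FRUIT):
            Xc = data.features[data.labels == c]
            if len(Xc) < 2:
                raise DegenerateProblemError("need >= 2 samples per class")
            priors.append(len(Xc) / len(data.features))
            means.append(Xc.mean(axis=0))
            variances.append(Xc.var(axis=0))
        return cls(priors, means, variances)

    def log_joint(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((len(X), 2))
        for c in (NON_FRUIT, FRUIT):
            mean, var = self.means[c], self.variances[c]
            ll = -0.5 * np.sum(
                np.log(2 * np.pi * var) + (X - mean) ** 2 / var, axis=1
            )
            out[:, c] = np.log(self.priors[c]) + ll
        return out

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """Two-class posteriors [P(c2|X), P(c1|X)], rows summing to 1."""
        lj = self.log_joint(X)
        lj -= lj.max(axis=1, keepdims=True)
        p = np.exp(lj)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        post = self.posterior(X)
        return (post[:, FRUIT] > post[:, NON_FRUIT]).astype(int)

    def classify(self, x: np.ndarray) -> tuple[int, float]:
        """Single-sample decision and its posterior probability."""
        post = self.posterior(x)[0]
        label = FRUIT if post[FRUIT] > post[NON_FRUIT] else NON_FRUIT
        return label, float(post[label])

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "priors": self.priors.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "BayesClassifier":
        return cls(doc["priors"], doc["means"], doc["variances"])


# ---------------------------------------------------------------------------
# cosine-similarity KNN
# ---------------------------------------------------------------------------


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """sim(X, Y) = Σ x_i y_i / (sqrt(Σ x_i²) · sqrt(Σ y_i²)), in [−1, 1]."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise UndefinedSimilarityError("cosine similarity undefined for zero vector")
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


class KnnClassifier:
    """Instance-based classifier ranking stored samples by cosine similarity.

    The majority class among the k most similar training samples wins;
    exact ties go to non-fruit.
    """

    kind = "knn"

    def __init__(self, features, labels, k: int = 5):
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels, dtype=int)
        self.k = int(k)
        norms = np.linalg.norm(self.features, axis=1)
        if np.any(norms == 0):
            raise UndefinedSimilarityError("stored sample with zero norm")
        self._unit = self.features / norms[:, None]

    @classmethod
    def train(cls, data: TrainingSet, k: int = 5) -> "KnnClassifier":
        return cls(data.features, data.labels, k=k)

    def predict(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        k = self.k if k is None else int(k)
        if k <= 0:
            raise ParameterError("k must be positive")
        if k > len(self.labels):
            raise ParameterError(f"k={k} exceeds {len(self.labels)} stored samples")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise UndefinedSimilarityError("query with zero norm")
        sims = (X / norms[:, None]) @ self._unit.T
        # stable descending sort so equal similarities keep storage order
        order = np.argsort(-sims, axis=1, kind="stable")[:, :k]
        votes = self.labels[order].sum(axis=1)
        return (2 * votes > k).astype(int)  # tie -> non-fruit

    def classify(self, y: np.ndarray, k: int | None = None) -> int:
        return int(self.predict(y, k=k)[0])

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "k": self.k,
            "features": self.features.tolist(),
            "labels": self.labels.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "KnnClassifier":
        return cls(doc["features"], doc["labels"], k=doc["k"])


# ---------------------------------------------------------------------------
# BP (back-propagation) network
# ---------------------------------------------------------------------------


def hidden_size(m: int, n: int, a: int) -> int:
    """Hidden-layer width J = round(sqrt(m + n)) + a, a ∈ [1, 10].

    With m = 9 input neurons and n = 1 output this spans J ∈ [4, 13] and
    gives the working value J = 7 at a = 4.
    """
    if not 1 <= a <= 10 or int(a) != a:
        raise ParameterError("a must be an integer in [1, 10]")
    return int(round(np.sqrt(m + n))) + int(a)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


class BpClassifier:
    """Three-layer sigmoid network classifying pixels by 3x3 neighbourhood.

    Input: the 9 grayscale intensities of the 3x3 neighbourhood scaled to
    [0, 1]; output: one sigmoid unit thresholded at 0.5.  Training is
    plain full-batch gradient descent on the mean squared error, so the
    recorded ``loss_history`` decreases monotonically for a stable
    learning rate.  An R−B colour gate (midpoint of the class means on
    the training patches) restricts per-pixel classification to
    fruit-coloured candidates.
    """

    kind = "bp"
    m = 9
    n = 1

    def __init__(self, W1, b1, W2, b2, gate_threshold: float = -np.inf,
                 loss_history=None):
        self.W1 = np.asarray(W1, dtype=float)
        self.b1 = np.asarray(b1, dtype=float)
        self.W2 = np.asarray(W2, dtype=float)
        self.b2 = np.asarray(b2, dtype=float)
        self.gate_threshold = float(gate_threshold)
        self.loss_history = list(loss_history or [])

    @property
    def J(self) -> int:
        return self.W1.shape[1]

    @classmethod
    def train(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        J: int = 7,
        seed: int = DEFAULT_SEED,
        lr: float = 2.0,
        epochs: int = 3000,
        gate_threshold: float = -np.inf,
    ) -> "BpClassifier":
        """Fit on (n, 9) inputs and binary targets by batch backpropagation."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        if X.ndim != 2 or X.shape[1] != cls.m:
            raise ParameterError(f"BP input must be (n, {cls.m})")
        rng = np.random.default_rng(seed)
        W1 = rng.normal(0, 0.5, size=(cls.m, J))
        b1 = np.zeros(J)
        W2 = rng.normal(0, 0.5, size=(J, 1))
        b2 = np.zeros(1)
        losses = []
        n = len(X)
        for _ in range(epochs):
            H = sigmoid(X @ W1 + b1)
            out = sigmoid(H @ W2 + b2)
            err = out - y
            losses.append(float(np.mean(err**2)))
            # backprop through the two sigmoid layers
            d_out = 2.0 * err * out * (1 - out) / n
            dW2 = H.T @ d_out
            db2 = d_out.sum(axis=0)
            d_hid = (d_out @ W2.T) * H * (1 - H)
            dW1 = X.T @ d_hid
            db1 = d_hid.sum(axis=0)
            W2 -= lr * dW2
            b2 -= lr * db2
            W1 -= lr * dW1
            b1 -= lr * db1
        return cls(W1, b1, W2, b2, gate_threshold=gate_threshold, loss_history=losses)

    @classmethod
    def train_from_patches(
        cls,
        fruit_patches: np.ndarray,
        background_patches: np.ndarray,
        J: int = 7,
        seed: int = DEFAULT_SEED,
    ) -> "BpClassifier":
        """Train on the centre 3x3 neighbourhoods of labelled 40x40 patches."""
        def centers(patches):
            out = []
            for p in patches:
                g = grayscale(p)
                cy, cx = g.shape[0] // 2, g.shape[1] // 2
                out.append(g[cy - 1 : cy + 2, cx - 1 : cx + 2].ravel() / 255.0)
            return np.array(out)

        X = np.vstack([centers(fruit_patches), centers(background_patches)])
        y = np.concatenate(
            [np.ones(len(fruit_patches)), np.zeros(len(background_patches))]
        )
        rb_fruit = np.mean([color_components_mean(p)[0] for p in fruit_patches])
        rb_bg = np.mean([color_components_mean(p)[0] for p in background_patches])
        gate = 0.5 * (rb_fruit + rb_bg)
        return cls.train(X, y, J=J, seed=seed, gate_threshold=gate)

    def forward(self, X: np.ndarray) -> np.ndarray:
        H = sigmoid(np.asarray(X, dtype=float) @ self.W1 + self.b1)
        return sigmoid(H @ self.W2 + self.b2).ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.forward(np.atleast_2d(X)) > 0.5).astype(int)

    def classify(self, x: np.ndarray) -> int:
        return int(self.predict(x)[0])

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "gate_threshold": self.gate_threshold,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "BpClassifier":
        return cls(
            doc["W1"], doc["b1"], doc["W2"], doc["b2"],
            gate_threshold=doc.get("gate_threshold", -np.inf),
        )


# ---------------------------------------------------------------------------
# linear SVM
# ---------------------------------------------------------------------------


class SvmClassifier:
    """Linear soft-margin SVM (C = 10) on internally z-scored features.

    Decision f(x) = sgn(w*·x + b*); +1 maps to the fruit region.  The
    quadratic program min ½||w||² s.t. c_j (w·x_j + b) >= 1 (with slack)
    is solved by :class:`sklearn.svm.SVC` with a linear kernel; ``w*``
    and ``b*`` are stored explicitly so predictions need only a dot
    product and survive JSON round-trips bit-identically.
    """

    kind = "svm"
    C = 10.0

    def __init__(self, w, b, scale_mean, scale_std):
        self.w = np.asarray(w, dtype=float)
        self.b = float(b)
        self.scale_mean = np.asarray(scale_mean, dtype=float)
        self.scale_std = np.asarray(scale_std, dtype=float)

    @classmethod
    def train(cls, data: TrainingSet) -> "SvmClassifier":
        X, y = data.features, np.where(data.labels == FRUIT, 1, -1)
        if len(np.unique(y)) < 2:
            raise DegenerateProblemError("SVM needs both classes")
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
        Xs = (X - mean) / std
        svc = SVC(kernel="linear", C=cls.C)
        svc.fit(Xs, y)
        return cls(svc.coef_.ravel(), svc.intercept_[0], mean, std)

    def decision(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.atleast_2d(np.asarray(X, dtype=float)) - self.scale_mean) / self.scale_std
        return Xs @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision(X) > 0).astype(int)

    def classify(self, x: np.ndarray) -> int:
        return int(self.predict(x)[0])

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "w": self.w.tolist(),
            "b": self.b,
            "scale_mean": self.scale_mean.tolist(),
            "scale_std": self.scale_std.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SvmClassifier":
        return cls(doc["w"], doc["b"], doc["scale_mean"], doc["scale_std"])


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_REGISTRY = {
    c.kind: c for c in (BayesClassifier, KnnClassifier, BpClassifier, SvmClassifier)
}

CLASSIFIER_KINDS = tuple(_REGISTRY)


def save_model(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path):
    with open(path) as fh:
        doc = json.load(fh)
    kind = doc.get("kind")
    if kind not in _REGISTRY:
        raise MissingModelError(f"unknown classifier kind {kind!r} in {path}")
    return _REGISTRY[kind].from_dict(doc)


# ---------------------------------------------------------------------------
# image segmentation
# ---------------------------------------------------------------------------


def dump_features_csv(patches: np.ndarray, labels: np.ndarray, path) -> None:
    """Write one row per 40x40 patch: the 10 features plus its class label."""
    import pandas as pd

    from litchivision.features import FEATURE_NAMES

    frame = pd.DataFrame(patch_features(patches), columns=list(FEATURE_NAMES))
    frame["label"] = np.asarray(labels, dtype=int)
    frame.to_csv(path, index=False)


def window_grid(shape: tuple[int, int], stride: int, size: int = PATCH_SIZE):
    """Top-left corners of the sliding 40x40 windows, last row/col clamped."""
    H, W = shape[:2]
    xs = list(range(0, W - size + 1, stride))
    ys = list(range(0, H - size + 1, stride))
    if xs and xs[-1] != W - size:
        xs.append(W - size)
    if ys and ys[-1] != H - size:
        ys.append(H - size)
    return xs, ys


def compute_window_feature_grid(
    image: np.ndarray, stride: int = 8, size: int = PATCH_SIZE
):
    """Feature matrix for every sliding window; shared by the window models."""
    xs, ys = window_grid(image.shape, stride, size)
    boxes = [(x, y, size, size) for y in ys for x in xs]
    feats = np.array([window_features(image, b) for b in boxes])
    return boxes, feats


def _vote_mask(
    shape: tuple[int, int], boxes, positive: np.ndarray
) -> np.ndarray:
    """Pixel foreground iff >= half of the covering windows voted fruit."""
    H, W = shape[:2]
    votes = np.zeros((H, W), dtype=np.int32)
    cover = np.zeros((H, W), dtype=np.int32)
    for (x, y, w, h), pos in zip(boxes, positive):
        cover[y : y + h, x : x + w] += 1
        if pos:
            votes[y : y + h, x : x + w] += 1
    return (2 * votes >= cover) & (cover > 0)


def _bp_mask(image: np.ndarray, model: BpClassifier) -> np.ndarray:
    gray = grayscale(image) / 255.0
    H, W = gray.shape
    padded = np.pad(gray, 1, mode="reflect")
    # all 3x3 neighbourhoods as a (H*W, 9) matrix
    neigh = np.lib.stride_tricks.sliding_window_view(padded, (3, 3))
    X = neigh.reshape(H * W, 9)
    candidates = np.ones(H * W, dtype=bool)
    if np.isfinite(model.gate_threshold):
        img = np.asarray(image, dtype=float)
        rb = img[..., 0] - img[..., 2]
        candidates = (rb > model.gate_threshold).ravel()
    out = np.zeros(H * W, dtype=bool)
    if np.any(candidates):
        out[candidates] = model.forward(X[candidates]) > 0.5
    return out.reshape(H, W)


def segment_image(
    image: np.ndarray,
    model,
    stride: int = 8,
    window_votes: np.ndarray | None = None,
    boxes=None,
) -> np.ndarray:
    """Binary fruit mask of an RGB image under one trained classifier.

    For the window classifiers (bayes/knn/svm) windows on the stride grid
    are classified and vote their pixels; pass precomputed ``boxes`` and
    the per-window feature matrix as ``window_votes`` to share feature
    extraction between classifiers.  The BP classifier works per pixel.
    """
    image = np.asarray(image)
    if model.kind == "bp":
        return _bp_mask(image, model)
    if boxes is None or window_votes is None:
        boxes, feats = compute_window_feature_grid(image, stride=stride)
    else:
        feats = window_votes
    positive = model.predict(feats).astype(bool)
    return _vote_mask(image.shape, boxes, positive)


def segment_image_all(
    image: np.ndarray, models: dict, stride: int = 8
) -> dict[str, np.ndarray]:
    """One mask per classifier, computing window features only once."""
    for kind in CLASSIFIER_KINDS:
        if kind not in models:
            raise MissingModelError(f"missing trained model: {kind}")
    boxes, feats = compute_window_feature_grid(image, stride=stride)
    masks = {}
    for kind, model in models.items():
        if model.kind == "bp":
            masks[kind] = _bp_mask(image, model)
        else:
            masks[kind] = segment_image(
                image, model, stride=stride, window_votes=feats, boxes=boxes
            )
    return masks
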