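"""Pinhole camera geometry for the binocular rig.

Implements the projection model

.. math::

    c \\, [\\mu, \\gamma, 1]^T = M_1 M_2 X_w,

where ``M1 = [[ax, 0, mu0], [0, ay, gamma0], [0, 0, 1]]`` holds the
intrinsics and ``M2 = [R | T]`` the pose, together with

* calibration of a single camera from 3-D/2-D correspondences (direct
  linear transform for non-coplanar points, and the planar multi-pose
  homography method for a flat calibration board),
* composition of the two camera poses into the relative stereo transform
  ``R_rel = R_r R_l^T``, ``T_rel = T_r - R_rel T_l``, and
* disparity-based triangulation for a rectified rig with the default
  200 mm baseline.

Pixel convention: 0-based, x = column rightward, y = row downward,
origin at the top-left corner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from litchivision.errors import (
    InvalidPoseError,
    NonPositiveDisparityError,
    PointBehindCameraError,
    RankDeficiencyError,
)

DEFAULT_BASELINE_MM = 200.0

_ROT_TOL = 1e-9


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal scales (px) and principal point (px)."""

    ax: float
    ay: float
    mu0: float
    gamma0: float

    def __post_init__(self) -> None:
        if self.ax <= 0 or self.ay <= 0:
            raise ValueError("focal scales ax, ay must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 intrinsic matrix M1 (zero skew)."""
        return np.array(
            [
                [self.ax, 0.0, self.mu0],
                [0.0, self.ay, self.gamma0],
                [0.0, 0.0, 1.0],
            ]
        )


def _check_rotation(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidPoseError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R @ R.T, np.eye(3), atol=tol):
        raise InvalidPoseError("rotation is not orthonormal")
    if not np.isclose(np.linalg.det(R), 1.0, atol=tol):
        raise InvalidPoseError("rotation determinant is not +1")
    return R


@dataclass(frozen=True)
class CameraPose:
    """Rigid transform from the world frame into the camera frame (T in mm)."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", _check_rotation(self.R))
        T = np.asarray(self.T, dtype=float).reshape(3)
        object.__setattr__(self, "T", T)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map world points (..., 3) into camera coordinates."""
        points = np.asarray(points, dtype=float)
        return points @ self.R.T + self.T

    @classmethod
    def identity(cls) -> "CameraPose":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class StereoRig:
    """Two calibrated cameras plus their relative transform.

    ``R_rel``/``T_rel`` map left-camera coordinates into right-camera
    coordinates.  For a rectified rig ``R_rel`` is the identity and
    ``T_rel`` lies along -x, so ``baseline = ||T_rel||``.
    """

    left_intrinsics: CameraIntrinsics
    left_pose: CameraPose
    right_intrinsics: CameraIntrinsics
    right_pose: CameraPose
    R_rel: np.ndarray = field(default=None)  # type: ignore[assignment]
    T_rel: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.R_rel is None or self.T_rel is None:
            R_rel, T_rel = compose_stereo(self.left_pose, self.right_pose)
            object.__setattr__(self, "R_rel", R_rel)
            object.__setattr__(self, "T_rel", T_rel)
        else:
            object.__setattr__(self, "R_rel", _check_rotation(self.R_rel))
            object.__setattr__(
                self, "T_rel", np.asarray(self.T_rel, dtype=float).reshape(3)
            )

    @property
    def baseline(self) -> float:
        """Distance between the optical centres, in mm."""
        return float(np.linalg.norm(self.T_rel))

    @property
    def is_rectified(self) -> bool:
        off_axis = np.linalg.norm(self.T_rel[1:])
        return bool(
            np.allclose(self.R_rel, np.eye(3), atol=1e-9)
            and off_axis <= 1e-9 * max(1.0, self.baseline)
        )

    @classmethod
    def rectified(
        cls,
        intrinsics: CameraIntrinsics,
        baseline_mm: float = DEFAULT_BASELINE_MM,
    ) -> "StereoRig":
        """Canonical rectified rig: identical cameras, baseline along +x."""
        left = CameraPose.identity()
        right = CameraPose(np.eye(3), np.array([-baseline_mm, 0.0, 0.0]))
        return cls(intrinsics, left, intrinsics, right)

    def to_json(self, path, image_size=(640, 480)) -> None:
        doc = {
            "image_size": list(image_size),
            "left": _camera_doc(self.left_intrinsics, self.left_pose),
            "right": _camera_doc(self.right_intrinsics, self.right_pose),
            "baseline_mm": self.baseline,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StereoRig":
        with open(path) as fh:
            doc = json.load(fh)
        li, lp = _camera_from_doc(doc["left"])
        ri, rp = _camera_from_doc(doc["right"])
        return cls(li, lp, ri, rp)


def _camera_doc(intr: CameraIntrinsics, pose: CameraPose) -> dict:
    return {
        "ax": intr.ax,
        "ay": intr.ay,
        "mu0": intr.mu0,
        "gamma0": intr.gamma0,
        "R": pose.R.tolist(),
        "T": pose.T.tolist(),
    }


def _camera_from_doc(doc: dict) -> tuple[CameraIntrinsics, CameraPose]:
    intr = CameraIntrinsics(doc["ax"], doc["ay"], doc["mu0"], doc["gamma0"])
    pose = CameraPose(np.array(doc["R"]), np.array(doc["T"]))
    return intr, pose


def project_point(
    intrinsics: CameraIntrinsics, pose: CameraPose, point: np.ndarray
) -> tuple[float, float]:
    """Project a world point (mm) to pixel coordinates ``(mu, gamma)``.

    Raises
    ------
    PointBehindCameraError
        If the camera-frame depth of the point is not strictly positive.
    """
    pc = pose.apply(np.asarray(point, dtype=float).reshape(3))
    xc, yc, zc = pc
    if zc <= 0:
        raise PointBehindCameraError(f"camera-frame depth {zc:.3f} <= 0")
    mu = intrinsics.ax * xc / zc + intrinsics.mu0
    gamma = intrinsics.ay * yc / zc + intrinsics.gamma0
    return float(mu), float(gamma)


def project_points(
    intrinsics: CameraIntrinsics, pose: CameraPose, points: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`project_point` for an (n, 3) array."""
    pc = pose.apply(np.asarray(points, dtype=float).reshape(-1, 3))
    if np.any(pc[:, 2] <= 0):
        raise PointBehindCameraError("at least one point behind the camera")
    uv = pc[:, :2] * [intrinsics.ax, intrinsics.ay] / pc[:, 2:3]
    return uv + [intrinsics.mu0, intrinsics.gamma0]


def compose_stereo(
    left_pose: CameraPose, right_pose: CameraPose
) -> tuple[np.ndarray, np.ndarray]:
    """Relative transform taking left-camera coordinates to right-camera ones.

    Satisfies, for every world point ``p``,
    ``right_pose.apply(p) == R_rel @ left_pose.apply(p) + T_rel``.
    """
    R_rel = right_pose.R @ left_pose.R.T
    T_rel = right_pose.T - R_rel @ left_pose.T
    return R_rel, T_rel


def _normalize_2d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalization: similarity mapping pts to mean 0, rms sqrt(2)."""
    mean = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - mean) ** 2, axis=1)))
    s = np.sqrt(2.0) / max(rms, 1e-12)
    T = np.array([[s, 0, -s * mean[0]], [0, s, -s * mean[1]], [0, 0, 1]])
    ptsn = (pts - mean) * s
    return ptsn, T


def _normalize_3d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - mean) ** 2, axis=1)))
    s = np.sqrt(3.0) / max(rms, 1e-12)
    U = np.eye(4)
    U[:3, :3] *= s
    U[:3, 3] = -s * mean
    ptsn = (pts - mean) * s
    return ptsn, U


def calibrate_from_correspondences(
    world_points: np.ndarray, pixels: np.ndarray
) -> tuple[CameraIntrinsics, CameraPose]:
    """Recover intrinsics and pose from >= 6 non-coplanar correspondences.

    Direct linear transform on the 3x4 projection matrix, followed by an
    RQ decomposition into ``K [R | T]``.  The skew entry recovered by the
    DLT is discarded (the camera model has none); for correspondences
    generated by a zero-skew camera it is zero to numerical precision.

    Raises
    ------
    RankDeficiencyError
        For degenerate configurations (coplanar or collinear points).
    """
    X = np.asarray(world_points, dtype=float).reshape(-1, 3)
    uv = np.asarray(pixels, dtype=float).reshape(-1, 2)
    n = X.shape[0]
    if n < 6 or uv.shape[0] != n:
        raise ValueError("need >= 6 matched correspondences")
    # coplanarity check on the raw world points
    Xc = X - X.mean(axis=0)
    sv = np.linalg.svd(Xc, compute_uv=False)
    if sv[-1] < 1e-8 * max(sv[0], 1.0):
        raise RankDeficiencyError(
            "world points are coplanar/collinear; use calibrate_planar"
        )

    Xn, U = _normalize_3d(X)
    uvn, Tn = _normalize_2d(uv)
    A = np.zeros((2 * n, 12))
    Xh = np.hstack([Xn, np.ones((n, 1))])
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -uvn[:, 0:1] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -uvn[:, 1:2] * Xh
    _, svals, Vt = np.linalg.svd(A)
    if svals[-2] < 1e-10 * svals[0]:
        raise RankDeficiencyError("DLT system is rank deficient")
    P = Vt[-1].reshape(3, 4)
    P = np.linalg.inv(Tn) @ P @ U  # undo normalizations

    M = P[:, :3]
    if np.linalg.det(M) < 0:
        P = -P
        M = P[:, :3]
    # RQ decomposition of M into upper-triangular K and rotation R
    K, R = _rq(M)
    # enforce positive diagonal on K
    D = np.diag(np.sign(np.diag(K)))
    K = K @ D
    R = D @ R
    T = np.linalg.solve(K, P[:, 3])
    K /= K[2, 2]
    intr = CameraIntrinsics(ax=K[0, 0], ay=K[1, 1], mu0=K[0, 2], gamma0=K[1, 2])
    # re-orthonormalize against round-off
    Uu, _, Vv = np.linalg.svd(R)
    R = Uu @ Vv
    if np.linalg.det(R) < 0:  # pragma: no cover - sign already fixed above
        R = -R
    return intr, CameraPose(R, T)


def _rq(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """RQ decomposition via QR of the flipped transpose."""
    Pf = np.flipud(np.eye(3))
    Q, R_ = np.linalg.qr((Pf @ M).T)
    K = Pf @ R_.T @ Pf
    R = Pf @ Q.T
    return K, R


def calibrate_planar(
    board_points: np.ndarray, pixel_sets: list[np.ndarray]
) -> tuple[CameraIntrinsics, list[CameraPose]]:
    """Zhang-style calibration from a planar board seen in >= 3 poses.

    Parameters
    ----------
    board_points : (n, 2) array
        Board-frame corner coordinates (z = 0 plane), in mm.
    pixel_sets : list of (n, 2) arrays
        Observed pixel positions of the corners, one array per board pose.

    Returns
    -------
    (intrinsics, poses)
        Shared intrinsics and the board pose for each view.

    Raises
    ------
    RankDeficiencyError
        With fewer than 3 poses the zero-skew intrinsics are not
        identifiable from homographies.
    """
    if len(pixel_sets) < 3:
        raise RankDeficiencyError("planar calibration needs >= 3 board poses")
    B2 = np.asarray(board_points, dtype=float).reshape(-1, 2)
    Hs = [_homography(B2, np.asarray(px, dtype=float)) for px in pixel_sets]

    def v(H, i, j):
        return np.array(
            [
                H[0, i] * H[0, j],
                H[0, i] * H[1, j] + H[1, i] * H[0, j],
                H[1, i] * H[1, j],
                H[2, i] * H[0, j] + H[0, i] * H[2, j],
                H[2, i] * H[1, j] + H[1, i] * H[2, j],
                H[2, i] * H[2, j],
            ]
        )

    rows = []
    for H in Hs:
        rows.append(v(H, 0, 1))
        rows.append(v(H, 0, 0) - v(H, 1, 1))
    V = np.vstack(rows)
    _, svals, Vt = np.linalg.svd(V)
    b = Vt[-1]
    B11, B12, B22, B13, B23, B33 = b
    denom = B11 * B22 - B12**2
    if abs(denom) < 1e-16:
        raise RankDeficiencyError("degenerate homography set")
    gamma0 = (B12 * B13 - B11 * B23) / denom
    lam = B33 - (B13**2 + gamma0 * (B12 * B13 - B11 * B23)) / B11
    ax2 = lam / B11
    ay2 = lam * B11 / denom
    if ax2 <= 0 or ay2 <= 0:
        raise RankDeficiencyError("intrinsic solution not positive definite")
    ax = float(np.sqrt(ax2))
    ay = float(np.sqrt(ay2))
    skew = -B12 * ax2 * ay / lam
    mu0 = skew * gamma0 / ay - B13 * ax2 / lam
    intr = CameraIntrinsics(ax=ax, ay=ay, mu0=float(mu0), gamma0=float(gamma0))

    Kinv = np.linalg.inv(intr.matrix)
    poses = []
    for H in Hs:
        h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
        s = 1.0 / np.linalg.norm(Kinv @ h1)
        r1 = s * (Kinv @ h1)
        r2 = s * (Kinv @ h2)
        r3 = np.cross(r1, r2)
        T = s * (Kinv @ h3)
        Rapprox = np.column_stack([r1, r2, r3])
        Uu, _, Vv = np.linalg.svd(Rapprox)
        R = Uu @ Vv
        if np.linalg.det(R) < 0:
            R = Uu @ np.diag([1, 1, -1]) @ Vv
        if T[2] < 0:
            R = np.diag([-1.0, -1.0, 1.0]) @ R  # pragma: no cover
            T = -T  # pragma: no cover
        poses.append(CameraPose(R, T))
    return intr, poses


def _homography(src2d: np.ndarray, dst2d: np.ndarray) -> np.ndarray:
    """Normalized DLT homography mapping board (x, y) to pixels."""
    n = src2d.shape[0]
    sn, Ts = _normalize_2d(src2d)
    dn, Td = _normalize_2d(dst2d)
    A = np.zeros((2 * n, 9))
    sh = np.hstack([sn, np.ones((n, 1))])
    A[0::2, 0:3] = sh
    A[0::2, 6:9] = -dn[:, 0:1] * sh
    A[1::2, 3:6] = sh
    A[1::2, 6:9] = -dn[:, 1:2] * sh
    _, _, Vt = np.linalg.svd(A)
    H = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def reprojection_rms(
    intrinsics: CameraIntrinsics,
    pose: CameraPose,
    world_points: np.ndarray,
    pixels: np.ndarray,
) -> float:
    """Root-mean-square reprojection error in pixels."""
    proj = project_points(intrinsics, pose, world_points)
    err = proj - np.asarray(pixels, dtype=float).reshape(-1, 2)
    return float(np.sqrt(np.mean(np.sum(err**2, axis=1)) / 2.0))


def triangulate(
    rig: StereoRig, left_pixel: tuple[float, float], disparity: float
) -> np.ndarray:
    """Back-project a left-image pixel with disparity into the left-camera frame.

    For a rectified rig the depth is ``zc = ax * baseline / d``; x and y
    follow by inverting the projection.  Returned as an (x, y, z) mm array.

    Raises
    ------
    NonPositiveDisparityError
        If ``disparity <= 0``.
    ValueError
        If the rig is not rectified.
    """
    if disparity <= 0:
        raise NonPositiveDisparityError(f"disparity {disparity} <= 0")
    if not rig.is_rectified:
        raise ValueError("triangulate requires a rectified rig")
    intr = rig.left_intrinsics
    zc = intr.ax * rig.baseline / disparity
    mu, gamma = left_pixel
    xc = (mu - intr.mu0) * zc / intr.ax
    yc = (gamma - intr.gamma0) * zc / intr.ay
    return np.array([xc, yc, zc])
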