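"""Image-space acupoint localization by reference-model alignment.

The online localization chain mirrors how an acupuncturist transfers point
positions from an annotated dummy onto a real hand:

1.  2D landmarks detected on the input image are matched by name to the
    annotated landmarks of a 3D reference hand model; gross detector
    failures are rejected by random-sample consensus over a projective
    camera model (``match_landmarks``).
2.  The hand pose relative to the camera is estimated by minimizing the
    reprojection error of the matched landmarks (``estimate_pose``).
3.  The posed model — its landmarks and its annotated acupoints — is
    projected onto the image plane (``project_model``).
4.  Residual shape difference between the reference hand and the imaged
    hand is absorbed by an affine moving-least-squares deformation whose
    control points are (projected model landmark -> detected landmark);
    the projected acupoints ride along (``mls_deform``).

Landmark detection itself is pluggable: any source of named 2D points with
confidences can feed the chain (the synthetic ground-truth detector in
:mod:`acupilot.synth`, or annotation JSON files).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateConfigurationError,
    PointBehindCameraError,
    PoseInfeasibleError,
)

__all__ = [
    "ACUPOINT_NAMES",
    "HandModel3D",
    "LandmarkSet2D",
    "CameraModel",
    "Pose",
    "AcupointEstimate",
    "match_landmarks",
    "estimate_pose",
    "project_model",
    "mls_deform",
    "localize_acupoints",
]

#: Controlled vocabulary of the 18 hand acupoints, keyed by hand side.
ACUPOINT_NAMES = {
    "back": ("LU-11", "LI-1", "LI-2", "LI-3", "LI-4", "SJ-1", "SJ-2", "SJ-3",
             "SI-1", "SI-2", "SI-3", "SI-4", "HT-9"),
    "palm": ("LU-10", "PC-8", "PC-9", "HT-8", "HT-7"),
}
_ALL_ACUPOINTS = frozenset(ACUPOINT_NAMES["back"]) | frozenset(ACUPOINT_NAMES["palm"])


@dataclass
class HandModel3D:
    """Annotated reference hand: named 3D landmarks and acupoints (mm)."""

    landmarks: dict  # name -> (3,) array, mm
    acupoints: dict  # name -> (3,) array, mm
    sides: dict      # acupoint name -> "back" | "palm"
    mesh_path: str | None = None

    def __post_init__(self):
        self.landmarks = {k: np.asarray(v, float) for k, v in self.landmarks.items()}
        self.acupoints = {k: np.asarray(v, float) for k, v in self.acupoints.items()}
        if len(self.landmarks) < 6:
            raise ValueError("a hand model needs at least 6 landmarks")
        unknown = set(self.acupoints) - _ALL_ACUPOINTS
        if unknown:
            raise ValueError(f"unknown acupoint names: {sorted(unknown)}")
        if set(self.sides) != set(self.acupoints):
            raise ValueError("sides must tag exactly the acupoints")

    def acupoints_on_side(self, side: str) -> dict:
        return {n: p for n, p in self.acupoints.items() if self.sides[n] == side}

    def to_json(self, path) -> None:
        payload = {
            "landmarks": {k: list(v) for k, v in self.landmarks.items()},
            "acupoints": {k: list(v) for k, v in self.acupoints.items()},
            "sides": self.sides,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "HandModel3D":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(payload["landmarks"], payload["acupoints"], payload["sides"])


@dataclass
class LandmarkSet2D:
    """Named detected (or ground-truth) image landmarks with confidences.

    Image convention: origin top-left, x = column, y = row, 0-based.
    """

    points: dict  # name -> (2,) array, px
    confidence: dict | None = None
    side: str = "back"
    image_size: tuple = (640, 480)

    def __post_init__(self):
        self.points = {k: np.asarray(v, float) for k, v in self.points.items()}
        if self.confidence is None:
            self.confidence = {k: 1.0 for k in self.points}
        bad = [k for k, c in self.confidence.items() if not 0.0 <= c <= 1.0]
        if bad:
            raise ValueError(f"confidences outside [0, 1]: {bad}")
        if self.side not in ("back", "palm"):
            raise ValueError("side must be 'back' or 'palm'")

    def to_json(self, path) -> None:
        payload = {
            "image": {"width": self.image_size[0], "height": self.image_size[1]},
            "side": self.side,
            "points": {k: list(v) for k, v in self.points.items()},
            "confidence": self.confidence,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "LandmarkSet2D":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            payload["points"],
            payload.get("confidence"),
            payload.get("side", "back"),
            (payload["image"]["width"], payload["image"]["height"]),
        )


@dataclass
class CameraModel:
    """Pinhole intrinsics; the camera looks along its +z axis."""

    focal_px: float
    principal_point: tuple
    image_size: tuple = (640, 480)

    def __post_init__(self):
        if self.focal_px <= 0:
            raise ValueError("focal length must be positive")
        cx, cy = self.principal_point
        w, h = self.image_size
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError("principal point must lie inside the image")

    @property
    def intrinsic_matrix(self) -> np.ndarray:
        cx, cy = self.principal_point
        f = self.focal_px
        return np.array([[f, 0.0, cx], [0.0, f, cy], [0.0, 0.0, 1.0]])


@dataclass
class Pose:
    """Rigid model-to-camera transform: X_cam = R @ X_model + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, float)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal to 1e-9")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must have determinant +1")
        self.rotation = r
        self.translation = np.asarray(self.translation, float).reshape(3)

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class AcupointEstimate:
    """A localized acupoint: image position, optional robot position."""

    name: str
    image_xy: np.ndarray
    robot_xy: np.ndarray | None = None
    deformation_residual_px: float = field(default=0.0)


# ---------------------------------------------------------------------------
# projection and consensus matching


def _project(points: np.ndarray, pose: Pose, camera: CameraModel) -> np.ndarray:
    cam = pose.transform(points)
    z = cam[:, 2]
    uv = camera.focal_px * cam[:, :2] / z[:, None]
    cx, cy = camera.principal_point
    return uv + np.array([cx, cy])


def _dlt_projection_matrix(obj: np.ndarray, img: np.ndarray) -> np.ndarray:
    """Fit a 3x4 projection matrix from >=6 3D-2D pairs (direct linear transform)."""
    n = len(obj)
    a = np.zeros((2 * n, 12))
    xh = np.hstack([obj, np.ones((n, 1))])
    a[0::2, 0:4] = xh
    a[0::2, 8:12] = -img[:, 0:1] * xh
    a[1::2, 4:8] = xh
    a[1::2, 8:12] = -img[:, 1:2] * xh
    _, s, vt = np.linalg.svd(a)
    if s[10] < 1e-12 * s[0]:
        raise DegenerateConfigurationError("DLT system is rank-deficient")
    return vt[-1].reshape(3, 4)


def _reprojection_px(p: np.ndarray, obj: np.ndarray) -> np.ndarray:
    xh = np.hstack([obj, np.ones((len(obj), 1))])
    proj = xh @ p.T
    return proj[:, :2] / proj[:, 2:3]


def match_landmarks(
    detected: LandmarkSet2D,
    model: HandModel3D,
    max_outlier_fraction: float = 0.5,
    *,
    threshold_px: float = 3.0,
    iterations: int = 500,
    seed: int = 0,
) -> list[str]:
    """Consensus filtering of name-matched landmark correspondences.

    Random-sample consensus over a full projective camera fitted to
    six-point samples; correspondences whose reprojection error exceeds
    ``threshold_px`` under the consensus model are rejected.

    Returns the sorted inlier names (at least 6), or raises
    :class:`PoseInfeasibleError`.
    """
    names = sorted(set(detected.points) & set(model.landmarks))
    if len(names) < 6:
        raise PoseInfeasibleError(
            f"only {len(names)} shared landmark names; need at least 6"
        )
    obj = np.array([model.landmarks[n] for n in names])
    img = np.array([detected.points[n] for n in names])
    n = len(names)
    rng = np.random.default_rng(seed)

    best_inliers = np.zeros(n, bool)
    max_iter = iterations
    it = 0
    while it < max_iter:
        it += 1
        sample = rng.choice(n, size=6, replace=False)
        try:
            p = _dlt_projection_matrix(obj[sample], img[sample])
        except DegenerateConfigurationError:
            continue
        err = np.linalg.norm(_reprojection_px(p, obj) - img, axis=1)
        inliers = err < threshold_px
        if inliers.sum() > best_inliers.sum():
            best_inliers = inliers
            # adaptive stopping: enough iterations for 99% confidence
            w = max(inliers.sum() / n, 1e-3)
            needed = np.log(0.01) / np.log(max(1.0 - w**6, 1e-12))
            max_iter = min(iterations, max(int(np.ceil(needed)), 1))

    # Refit on the consensus set and re-classify with an adaptive threshold:
    # the fixed pixel threshold is a floor for gross-outlier rejection, but
    # honest detection noise above ~1 px would otherwise be rejected
    # wholesale, so the working threshold follows the robust residual scale.
    support = best_inliers if best_inliers.sum() >= 6 else np.ones(n, bool)
    for _ in range(2):
        try:
            p = _dlt_projection_matrix(obj[support], img[support])
        except DegenerateConfigurationError:
            break
        err = np.linalg.norm(_reprojection_px(p, obj) - img, axis=1)
        scale = 1.4826 * np.median(err)
        refined = err < max(threshold_px, 2.5 * scale)
        if refined.sum() >= 6:
            support = refined
    if support.sum() >= 6:
        best_inliers = support

    if best_inliers.sum() < 6:
        raise PoseInfeasibleError(
            f"consensus filter kept {int(best_inliers.sum())} of {n} "
            f"landmarks; at least 6 required (outlier fraction too high?)"
        )
    kept = [names[i] for i in np.flatnonzero(best_inliers)]
    if (n - len(kept)) / n > max_outlier_fraction:
        raise PoseInfeasibleError(
            f"{n - len(kept)}/{n} landmarks rejected exceeds the allowed "
            f"outlier fraction {max_outlier_fraction}"
        )
    return kept


def estimate_pose(
    inlier_names,
    detected: LandmarkSet2D,
    model: HandModel3D,
    camera: CameraModel,
    *,
    max_iterations: int = 50,
    step_tol: float = 1e-10,
) -> Pose:
    """Estimate the rigid model-to-camera pose from 2D-3D correspondences.

    DLT initialization (projection matrix decomposed with the known
    intrinsics) followed by Gauss-Newton refinement of the mean squared
    reprojection error; terminates when the update step norm falls below
    ``step_tol`` or after ``max_iterations`` iterations.
    """
    names = list(inlier_names)
    if len(names) < 6:
        raise PoseInfeasibleError("pose estimation needs at least 6 landmarks")
    obj = np.array([model.landmarks[n] for n in names])
    img = np.array([detected.points[n] for n in names])
    k_inv = np.linalg.inv(camera.intrinsic_matrix)

    def residual_rms(r, t):
        cam = obj @ r.T + t
        if np.any(cam[:, 2] <= 0):
            return np.inf
        uv = camera.focal_px * cam[:, :2] / cam[:, 2:3]
        uv += np.array(camera.principal_point)
        return float(np.sqrt(np.mean(np.sum((uv - img) ** 2, axis=1))))

    inits = []
    # full-projective DLT init (needs non-coplanar support)
    try:
        p = _dlt_projection_matrix(obj, img)
        m = k_inv @ p
        if np.linalg.det(m[:, :3]) < 0:
            m = -m
        u, s, vt = np.linalg.svd(m[:, :3])
        r = u @ vt
        if np.linalg.det(r) < 0:
            u[:, -1] *= -1
            r = u @ vt
        inits.append((r, m[:, 3] / s.mean()))
    except DegenerateConfigurationError:
        pass
    # planar-homography init: robust for the nearly flat hand, where the
    # projective DLT has a one-parameter ambiguity
    try:
        inits.append(_planar_pose_init(obj, img, k_inv))
    except (DegenerateConfigurationError, np.linalg.LinAlgError):
        pass
    inits = [(r, t) for r, t in inits if np.isfinite(residual_rms(r, t))]
    if not inits:
        raise DegenerateConfigurationError(
            "no feasible pose initialization (degenerate landmark geometry)"
        )
    r, t = min(inits, key=lambda rt: residual_rms(*rt))

    f = camera.focal_px
    cx, cy = camera.principal_point
    for _ in range(max_iterations):
        cam = obj @ r.T + t
        x, y, z = cam[:, 0], cam[:, 1], cam[:, 2]
        u_res = f * x / z + cx - img[:, 0]
        v_res = f * y / z + cy - img[:, 1]
        res = np.concatenate([u_res, v_res])

        # Jacobian wrt (rotation increment omega, translation)
        rx = obj @ r.T  # rotated object points (camera frame minus t)
        dcam_domega = np.zeros((len(obj), 3, 3))
        dcam_domega[:, 0, 1] = rx[:, 2]
        dcam_domega[:, 0, 2] = -rx[:, 1]
        dcam_domega[:, 1, 0] = -rx[:, 2]
        dcam_domega[:, 1, 2] = rx[:, 0]
        dcam_domega[:, 2, 0] = rx[:, 1]
        dcam_domega[:, 2, 1] = -rx[:, 0]
        du_dcam = np.stack(
            [f / z, np.zeros_like(z), -f * x / z**2], axis=1
        )
        dv_dcam = np.stack(
            [np.zeros_like(z), f / z, -f * y / z**2], axis=1
        )
        ju = np.hstack([
            np.einsum("ni,nij->nj", du_dcam, dcam_domega), du_dcam
        ])
        jv = np.hstack([
            np.einsum("ni,nij->nj", dv_dcam, dcam_domega), dv_dcam
        ])
        jac = np.vstack([ju, jv])

        step, *_ = np.linalg.lstsq(jac, -res, rcond=None)
        # damped update: halve the step while it worsens the fit or pushes
        # landmarks behind the camera
        base_rms = np.sqrt(np.mean(res**2))
        scale = 1.0
        for _ in range(10):
            r_new = Rotation.from_rotvec(scale * step[:3]).as_matrix() @ r
            t_new = t + scale * step[3:]
            if residual_rms(r_new, t_new) <= base_rms * (1 + 1e-12):
                break
            scale *= 0.5
        r, t = r_new, t_new
        if np.linalg.norm(scale * step) < step_tol:
            break
    if not np.isfinite(residual_rms(r, t)):
        raise DegenerateConfigurationError(
            "pose refinement places landmarks behind the camera"
        )
    # re-orthonormalize against accumulated floating-point drift
    u, _, vt = np.linalg.svd(r)
    r = u @ vt
    return Pose(r, t)


def _planar_pose_init(obj: np.ndarray, img: np.ndarray, k_inv: np.ndarray):
    """Pose init by fitting a homography on the best-fit object plane."""
    centroid = obj.mean(axis=0)
    _, _, vt = np.linalg.svd(obj - centroid)
    e1, e2 = vt[0], vt[1]
    plane_uv = (obj - centroid) @ np.stack([e1, e2]).T

    n = len(obj)
    a = np.zeros((2 * n, 9))
    uvh = np.hstack([plane_uv, np.ones((n, 1))])
    a[0::2, 0:3] = uvh
    a[0::2, 6:9] = -img[:, 0:1] * uvh
    a[1::2, 3:6] = uvh
    a[1::2, 6:9] = -img[:, 1:2] * uvh
    _, s, vh = np.linalg.svd(a)
    if s[7] < 1e-12 * s[0]:
        raise DegenerateConfigurationError("planar init is rank-deficient")
    h = vh[-1].reshape(3, 3)

    m = k_inv @ h
    lam = 2.0 / (np.linalg.norm(m[:, 0]) + np.linalg.norm(m[:, 1]))
    if m[2, 2] * lam < 0:  # keep the plane origin in front of the camera
        lam = -lam
    r1, r2 = lam * m[:, 0], lam * m[:, 1]
    r3 = np.cross(r1, r2)
    u, _, vt2 = np.linalg.svd(np.stack([r1, r2, r3], axis=1))
    r_plane = u @ vt2
    if np.linalg.det(r_plane) < 0:
        u[:, -1] *= -1
        r_plane = u @ vt2
    t_plane = lam * m[:, 2]

    basis = np.stack([e1, e2, np.cross(e1, e2)], axis=1)
    r_pose = r_plane @ basis.T
    t_pose = t_plane - r_pose @ centroid
    return r_pose, t_pose


def project_model(
    model: HandModel3D, pose: Pose, camera: CameraModel
) -> tuple[LandmarkSet2D, dict]:
    """Pinhole-project every landmark and acupoint of the posed model."""
    names = list(model.landmarks) + list(model.acupoints)
    pts = np.array([*model.landmarks.values(), *model.acupoints.values()])
    cam = pose.transform(pts)
    behind = [n for n, zc in zip(names, cam[:, 2]) if zc <= 1e-9]
    if behind:
        raise PointBehindCameraError(behind)
    uv = _project(pts, pose, camera)
    nl = len(model.landmarks)
    landmarks = LandmarkSet2D(
        dict(zip(names[:nl], uv[:nl])), image_size=camera.image_size
    )
    acupoints = dict(zip(names[nl:], uv[nl:]))
    return landmarks, acupoints


# ---------------------------------------------------------------------------
# moving-least-squares deformation


def mls_deform(
    control_src: Mapping,
    control_dst: Mapping,
    queries: Mapping,
    *,
    alpha: float = 1.0,
    eps: float = 1e-8,
) -> dict:
    """Affine moving-least-squares warp of named query points.

    For each query ``q`` the control points are weighted by
    ``w_i = 1 / (|q - c_i|^2 + eps)^alpha`` and the best weighted affine
    map is applied to ``q``.  The warp reproduces any global affine map of
    the controls exactly and interpolates the control displacements (a
    query at a control source lands on that control's destination, up to
    the ``eps`` regularization).
    """
    names = sorted(control_src)
    if set(control_dst) != set(names):
        raise ValueError("control_src and control_dst must share names")
    if len(names) < 3:
        raise DegenerateConfigurationError("MLS needs at least 3 control points")
    p = np.array([np.asarray(control_src[n], float) for n in names])
    q = np.array([np.asarray(control_dst[n], float) for n in names])
    spread = p - p.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-9 * (np.abs(spread).max() + 1)) < 2:
        raise DegenerateConfigurationError("control points are collinear")

    out = {}
    for name, v in queries.items():
        v = np.asarray(v, float)
        d2 = np.sum((p - v) ** 2, axis=1)
        w = 1.0 / (d2 + eps) ** alpha
        wsum = w.sum()
        pstar = (w[:, None] * p).sum(axis=0) / wsum
        qstar = (w[:, None] * q).sum(axis=0) / wsum
        phat = p - pstar
        qhat = q - qstar
        gram = (w[:, None, None] * phat[:, :, None] * phat[:, None, :]).sum(axis=0)
        cross = (w[:, None, None] * phat[:, :, None] * qhat[:, None, :]).sum(axis=0)
        m = np.linalg.solve(gram, cross)
        out[name] = (v - pstar) @ m + qstar
    return out


def localize_acupoints(
    detected: LandmarkSet2D,
    model: HandModel3D,
    camera: CameraModel,
    *,
    max_outlier_fraction: float = 0.5,
    ransac_threshold_px: float = 3.0,
    ransac_iterations: int = 500,
    seed: int = 0,
    mls_alpha: float = 1.0,
) -> list[AcupointEstimate]:
    """Full localization chain: consensus match, pose, project, deform.

    Only acupoints annotated on the imaged side (``detected.side``) are
    returned.
    """
    inliers = match_landmarks(
        detected, model, max_outlier_fraction,
        threshold_px=ransac_threshold_px, iterations=ransac_iterations,
        seed=seed,
    )
    pose = estimate_pose(inliers, detected, model, camera)
    projected_landmarks, projected_acupoints = project_model(model, pose, camera)

    control_src = {n: projected_landmarks.points[n] for n in inliers}
    control_dst = {n: detected.points[n] for n in inliers}
    queries = {
        n: p for n, p in projected_acupoints.items()
        if model.sides[n] == detected.side
    }
    warped = mls_deform(control_src, control_dst, queries, alpha=mls_alpha)

    ctrl = np.array([control_src[n] for n in inliers])
    resid = np.linalg.norm(
        np.array([control_dst[n] for n in inliers]) - ctrl, axis=1
    )
    estimates = []
    for name in sorted(warped):
        d = np.linalg.norm(ctrl - np.asarray(projected_acupoints[name]), axis=1)
        estimates.append(
            AcupointEstimate(name, warped[name],
                             deformation_residual_px=float(resid[np.argmin(d)]))
        )
    return estimates
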