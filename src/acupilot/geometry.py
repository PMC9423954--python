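"""Plane-to-plane perspective transforms and height-corrected hand-eye mapping.

A camera fixed above a robot workspace sees the robot's x-y travel plane
under a projective (perspective) map.  The map between image pixels (x, y)
and robot-arm millimetres (X, Y) on one plane is the eight-parameter
rational-linear transform

    X = (a x + b y + c) / (g x + h y + 1)
    Y = (d x + e y + f) / (g x + h y + 1)

fitted by linear least squares from point correspondences.  Targets that sit
above or below the calibration plane are handled by a second fitted
transform ``F`` (image at the offset height -> image at the calibration
height) interpolated entrywise by the signed height ratio ``k``:

    H(k) = k F + (1 - k) I,        p_robot = T H(k) p_image

so that H(0) = I (no correction) and H(1) = F (the fitted 1-step
correction) hold exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateConfigurationError,
    HorizonPointError,
    InsufficientDataError,
    SingularTransformError,
)

__all__ = [
    "Correspondence",
    "PerspectiveTransform",
    "HeightCalibration",
    "estimate_perspective",
    "apply_perspective",
    "invert_perspective",
    "estimate_height_calibration",
    "height_corrected_transform",
    "image_to_robot",
    "read_correspondences_csv",
    "write_correspondences_csv",
    "save_calibration",
    "load_calibration",
]

#: denominators g*x + h*y + 1 with magnitude below this are treated as zero
DENOM_TOL = 1e-9
#: |det| below this (for a matrix normalized to unit bottom-right entry)
#: declares the transform singular
DET_TOL = 1e-12


class Correspondence(NamedTuple):
    """A source point and its image under the transform (both length-2)."""

    src: tuple
    dst: tuple


@dataclass(frozen=True)
class PerspectiveTransform:
    """An invertible plane-to-plane projective map.

    Stored as a 3x3 homogeneous matrix whose bottom-right entry is fixed
    to 1, equivalent to the eight scalar parameters a..h.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("perspective matrix must be 3x3")
        if abs(m[2, 2]) < DENOM_TOL:
            raise SingularTransformError(
                "matrix cannot be normalized: bottom-right entry is zero"
            )
        m = m / m[2, 2]
        if abs(np.linalg.det(m)) < DET_TOL:
            raise SingularTransformError("perspective matrix is singular")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "PerspectiveTransform":
        return cls(np.eye(3))

    @classmethod
    def from_params(cls, a=1.0, b=0.0, c=0.0, d=0.0, e=1.0, f=0.0, g=0.0, h=0.0):
        return cls(np.array([[a, b, c], [d, e, f], [g, h, 1.0]]))

    @property
    def params(self) -> np.ndarray:
        """The eight parameters (a, b, c, d, e, f, g, h)."""
        m = self.matrix
        return np.array([m[0, 0], m[0, 1], m[0, 2],
                         m[1, 0], m[1, 1], m[1, 2],
                         m[2, 0], m[2, 1]])

    def __call__(self, points):
        return apply_perspective(self, points)

    def inverse(self) -> "PerspectiveTransform":
        return invert_perspective(self)

    def compose(self, other: "PerspectiveTransform") -> "PerspectiveTransform":
        """self after other: (self @ other)(p) = self(other(p))."""
        return PerspectiveTransform(self.matrix @ other.matrix)


@dataclass(frozen=True)
class HeightCalibration:
    """Height fine-tuning data: the fitted offset transform and its step.

    ``transform`` maps image coordinates observed at ``calibration_offset_cm``
    above the base plane to the image coordinates the same workspace point
    would have at the base plane.  ``calibration_height_cm`` records the
    absolute height of the base plane for bookkeeping only.
    """

    transform: PerspectiveTransform
    calibration_offset_cm: float
    calibration_height_cm: float = 0.0
    residual_rms: float = field(default=0.0, compare=False)

    def __post_init__(self):
        if self.calibration_offset_cm <= 0:
            raise ValueError("calibration_offset_cm must be positive")


def _as_points(points) -> tuple[np.ndarray, bool]:
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 2:
        raise ValueError("points must have shape (2,) or (n, 2)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    return pts, single


def _split_correspondences(correspondences) -> tuple[np.ndarray, np.ndarray]:
    src = np.asarray([c[0] for c in correspondences], dtype=float)
    dst = np.asarray([c[1] for c in correspondences], dtype=float)
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(dst))):
        raise ValueError("correspondences must be finite")
    return src, dst


def _hartley_normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity moving the centroid to the origin, mean radius to sqrt(2)."""
    centroid = pts.mean(axis=0)
    mean_dist = np.mean(np.linalg.norm(pts - centroid, axis=1))
    s = np.sqrt(2.0) / mean_dist if mean_dist > 0 else 1.0
    return np.array([[s, 0.0, -s * centroid[0]],
                     [0.0, s, -s * centroid[1]],
                     [0.0, 0.0, 1.0]])


def estimate_perspective(
    correspondences: Sequence, *, min_points: int = 4
) -> PerspectiveTransform:
    """Least-squares fit of the 8-parameter perspective transform.

    Each correspondence contributes the two linearized rows

        X (g x + h y + 1) = a x + b y + c
        Y (g x + h y + 1) = d x + e y + f

    Both point sets are Hartley-normalized before the solve for numerical
    conditioning, and the result is denormalized afterwards.  The algebraic
    residual of the linearized system is minimized, not the geometric
    transfer error.

    Raises
    ------
    InsufficientDataError
        Fewer than four correspondences.
    DegenerateConfigurationError
        Rank-deficient design matrix (e.g. collinear source points).
    """
    n = len(correspondences)
    if n < min_points:
        raise InsufficientDataError(
            f"need at least {min_points} correspondences, got {n}"
        )
    src, dst = _split_correspondences(correspondences)

    ns = _hartley_normalization(src)
    nd = _hartley_normalization(dst)
    sh = (ns[:2, :2] @ src.T).T + ns[:2, 2]
    dh = (nd[:2, :2] @ dst.T).T + nd[:2, 2]

    a = np.zeros((2 * n, 8))
    b = np.zeros(2 * n)
    x, y = sh[:, 0], sh[:, 1]
    u, v = dh[:, 0], dh[:, 1]
    a[0::2, 0] = x
    a[0::2, 1] = y
    a[0::2, 2] = 1.0
    a[0::2, 6] = -u * x
    a[0::2, 7] = -u * y
    b[0::2] = u
    a[1::2, 3] = x
    a[1::2, 4] = y
    a[1::2, 5] = 1.0
    a[1::2, 6] = -v * x
    a[1::2, 7] = -v * y
    b[1::2] = v

    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 8:
        raise DegenerateConfigurationError(
            "degenerate correspondence geometry (rank-deficient system)"
        )
    mn = np.array([[sol[0], sol[1], sol[2]],
                   [sol[3], sol[4], sol[5]],
                   [sol[6], sol[7], 1.0]])
    m = np.linalg.inv(nd) @ mn @ ns
    if abs(m[2, 2]) < DENOM_TOL:
        raise SingularTransformError(
            "fitted map has no 8-parameter representation "
            "(bottom-right entry vanishes)"
        )
    return PerspectiveTransform(m)


def apply_perspective(transform: PerspectiveTransform, points):
    """Map points through the transform; shape of input is preserved.

    Raises :class:`HorizonPointError` where the projective denominator
    g*x + h*y + 1 vanishes.
    """
    pts, single = _as_points(points)
    m = transform.matrix
    den = pts @ m[2, :2] + m[2, 2]
    if np.any(np.abs(den) < DENOM_TOL):
        raise HorizonPointError("projective denominator vanishes at input point")
    num = pts @ m[:2, :2].T + m[:2, 2]
    out = num / den[:, None]
    return out[0] if single else out


def invert_perspective(transform: PerspectiveTransform) -> PerspectiveTransform:
    """Matrix inverse, renormalized so the bottom-right entry is 1."""
    return PerspectiveTransform(np.linalg.inv(transform.matrix))


def estimate_height_calibration(
    corrs_offset_to_base: Sequence,
    offset_cm: float,
    *,
    calibration_height_cm: float = 0.0,
) -> HeightCalibration:
    """Fit the height fine-tuning transform F from an offset-plane point set.

    ``corrs_offset_to_base`` pairs the image coordinate of a workspace point
    seen ``offset_cm`` above the base plane with the image coordinate the
    same (X, Y) point has on the base plane.
    """
    if offset_cm <= 0:
        raise ValueError("offset_cm must be positive")
    f = estimate_perspective(corrs_offset_to_base)
    src, dst = _split_correspondences(corrs_offset_to_base)
    res = apply_perspective(f, src) - dst
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return HeightCalibration(f, offset_cm, calibration_height_cm, rms)


def height_corrected_transform(
    transform: PerspectiveTransform,
    calibration: HeightCalibration,
    k: float,
) -> PerspectiveTransform:
    """Compose the base map with the interpolated height correction H(k).

    H(k) = k F + (1 - k) I entrywise, renormalized; ``k`` is the signed
    height above the calibration plane in units of the calibration offset
    (fractional and negative values allowed).  Returns T  H(k).
    """
    hk = k * calibration.transform.matrix + (1.0 - k) * np.eye(3)
    try:
        h = PerspectiveTransform(hk)
    except SingularTransformError as exc:
        raise SingularTransformError(
            f"height interpolation H(k) is singular at k={k}"
        ) from exc
    return transform.compose(h)


def image_to_robot(
    transform: PerspectiveTransform,
    calibration: HeightCalibration | None,
    point,
    height_above_calibration_cm: float = 0.0,
):
    """Map an image point to robot coordinates with height correction.

    At ``height_above_calibration_cm == 0`` (or with no calibration given)
    this is exactly ``apply_perspective(transform, point)``.
    """
    if calibration is None or height_above_calibration_cm == 0.0:
        return apply_perspective(transform, point)
    k = height_above_calibration_cm / calibration.calibration_offset_cm
    return apply_perspective(
        height_corrected_transform(transform, calibration, k), point
    )


# ---------------------------------------------------------------------------
# file formats


def read_correspondences_csv(path) -> list[Correspondence]:
    """Read `src_x,src_y,dst_x,dst_y[,height_cm]` correspondences (px -> mm)."""
    df = pd.read_csv(path)
    required = {"src_x", "src_y", "dst_x", "dst_y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"correspondence CSV missing columns: {sorted(missing)}")
    return [
        Correspondence((row.src_x, row.src_y), (row.dst_x, row.dst_y))
        for row in df.itertuples()
    ]


def write_correspondences_csv(path, correspondences, height_cm=None) -> None:
    src, dst = _split_correspondences(correspondences)
    df = pd.DataFrame(
        {"src_x": src[:, 0], "src_y": src[:, 1],
         "dst_x": dst[:, 0], "dst_y": dst[:, 1]}
    )
    if height_cm is not None:
        df["height_cm"] = height_cm
    df.to_csv(path, index=False)


def save_calibration(
    path,
    transform: PerspectiveTransform,
    calibration: HeightCalibration | None = None,
    residuals=None,
) -> None:
    """Write the calibration result JSON (row-major 3x3 matrices)."""
    payload = {"T": transform.matrix.tolist()}
    if calibration is not None:
        payload["F"] = calibration.transform.matrix.tolist()
        payload["calibration_offset_cm"] = calibration.calibration_offset_cm
        payload["calibration_height_cm"] = calibration.calibration_height_cm
    if residuals is not None:
        payload["residuals"] = list(np.asarray(residuals, dtype=float))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_calibration(path) -> tuple[PerspectiveTransform, HeightCalibration | None]:
    with open(path) as fh:
        payload = json.load(fh)
    t = PerspectiveTransform(np.array(payload["T"]))
    calib = None
    if "F" in payload:
        calib = HeightCalibration(
            PerspectiveTransform(np.array(payload["F"])),
            payload.get("calibration_offset_cm", 1.0),
            payload.get("calibration_height_cm", 0.0),
        )
    return t, calib
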