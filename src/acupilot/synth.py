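"""Synthetic ground-truth scenes, calibration sets, and PPG signals.

This module stands in for the physical rig: a stylized 3D right hand with
21 skeleton-style landmarks and 18 named acupoints, a pinhole camera about
30 cm above the hand, a robot x-y travel plane at a calibration height,
and a wrist PPG sensor.  Every generator is a pure function of its seed
and parameters, and stores the exact ground truth (pixels, robot
coordinates, beat times) so analysis output can be scored against it.

The hand geometry is skeleton-proportioned rather than anatomically
scanned; it only needs to exercise the projective and deformation math
with realistic magnitudes (hand span ~180 mm filling ~60% of a 640x480
frame at 300 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import PointBehindCameraError
from .geometry import Correspondence, PerspectiveTransform
from .mapping import CameraModel, HandModel3D, LandmarkSet2D, Pose

__all__ = [
    "NoiseSpec",
    "SyntheticScene",
    "PPGTruth",
    "generate_hand_model",
    "generate_scene",
    "generate_calibration_points",
    "generate_ppg",
]

LANDMARK_NAMES = (
    "WRIST",
    "THUMB_CMC", "THUMB_MCP", "THUMB_IP", "THUMB_TIP",
    "INDEX_MCP", "INDEX_PIP", "INDEX_DIP", "INDEX_TIP",
    "MIDDLE_MCP", "MIDDLE_PIP", "MIDDLE_DIP", "MIDDLE_TIP",
    "RING_MCP", "RING_PIP", "RING_DIP", "RING_TIP",
    "PINKY_MCP", "PINKY_PIP", "PINKY_DIP", "PINKY_TIP",
)

# Normalized template (hand length ~1): x radial (thumb) positive, y distal,
# z height of the back-of-hand surface above the table.  Knuckles arch the
# z profile so the landmark cloud is usefully non-coplanar.
_TEMPLATE = {
    "WRIST": (0.00, 0.00, 0.030),
    "THUMB_CMC": (0.25, 0.12, 0.060),
    "THUMB_MCP": (0.42, 0.25, 0.080),
    "THUMB_IP": (0.54, 0.37, 0.060),
    "THUMB_TIP": (0.63, 0.47, 0.030),
    "INDEX_MCP": (0.20, 0.50, 0.130),
    "INDEX_PIP": (0.26, 0.68, 0.150),
    "INDEX_DIP": (0.29, 0.80, 0.090),
    "INDEX_TIP": (0.31, 0.90, 0.040),
    "MIDDLE_MCP": (0.06, 0.52, 0.140),
    "MIDDLE_PIP": (0.08, 0.72, 0.160),
    "MIDDLE_DIP": (0.09, 0.86, 0.100),
    "MIDDLE_TIP": (0.10, 0.97, 0.040),
    "RING_MCP": (-0.08, 0.50, 0.130),
    "RING_PIP": (-0.11, 0.69, 0.150),
    "RING_DIP": (-0.13, 0.82, 0.090),
    "RING_TIP": (-0.14, 0.92, 0.040),
    "PINKY_MCP": (-0.21, 0.46, 0.110),
    "PINKY_PIP": (-0.26, 0.60, 0.120),
    "PINKY_DIP": (-0.29, 0.70, 0.080),
    "PINKY_TIP": (-0.31, 0.78, 0.040),
}

# Acupoints as convex combinations of landmarks (guaranteeing they stay in
# the landmark footprint), with a vertical offset: back points ride on the
# dorsal surface, palm points sit one hand-thickness below it.
_ACUPOINT_RECIPES = {
    # name: (side, {landmark: weight}, z_offset in hand units)
    "LU-11": ("back", {"THUMB_TIP": 0.9, "THUMB_IP": 0.1}, 0.0),
    "LI-1": ("back", {"INDEX_TIP": 0.9, "INDEX_DIP": 0.1}, 0.0),
    "LI-2": ("back", {"INDEX_MCP": 0.7, "INDEX_PIP": 0.3}, 0.0),
    "LI-3": ("back", {"INDEX_MCP": 0.85, "WRIST": 0.15}, 0.0),
    "LI-4": ("back", {"INDEX_MCP": 0.45, "THUMB_MCP": 0.35, "WRIST": 0.20}, 0.0),
    "SJ-1": ("back", {"RING_TIP": 0.9, "RING_DIP": 0.1}, 0.0),
    "SJ-2": ("back", {"RING_MCP": 0.45, "PINKY_MCP": 0.45, "RING_PIP": 0.10}, 0.0),
    "SJ-3": ("back", {"RING_MCP": 0.40, "PINKY_MCP": 0.35, "WRIST": 0.25}, 0.0),
    "SI-1": ("back", {"PINKY_TIP": 0.9, "PINKY_DIP": 0.1}, 0.0),
    "SI-2": ("back", {"PINKY_PIP": 0.8, "PINKY_MCP": 0.2}, 0.0),
    "SI-3": ("back", {"PINKY_MCP": 0.85, "WRIST": 0.15}, 0.0),
    "SI-4": ("back", {"WRIST": 0.65, "PINKY_MCP": 0.35}, 0.0),
    "HT-9": ("back", {"PINKY_TIP": 0.85, "RING_TIP": 0.15}, 0.0),
    "LU-10": ("palm", {"THUMB_CMC": 0.5, "THUMB_MCP": 0.3, "WRIST": 0.2}, -0.10),
    "PC-8": ("palm", {"MIDDLE_MCP": 0.4, "RING_MCP": 0.3, "WRIST": 0.3}, -0.10),
    "PC-9": ("palm", {"MIDDLE_TIP": 0.95, "MIDDLE_DIP": 0.05}, -0.06),
    "HT-8": ("palm", {"RING_MCP": 0.5, "PINKY_MCP": 0.4, "WRIST": 0.1}, -0.10),
    "HT-7": ("palm", {"WRIST": 0.8, "PINKY_MCP": 0.2}, -0.06),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Noise injected into synthetic observations (all off by default)."""

    landmark_sigma_px: float = 0.0
    correspondence_sigma_mm: float = 0.0
    height_sigma_px: float = 0.0       # offset-plane correspondence noise
    ppg_snr_db: float = float("inf")
    outlier_count: int = 0
    outlier_magnitude_px: float = 50.0

    def __post_init__(self):
        if min(self.landmark_sigma_px, self.correspondence_sigma_mm,
               self.height_sigma_px) < 0:
            raise ValueError("noise sigmas must be non-negative")

    def without(self, source: str) -> "NoiseSpec":
        """Copy with one named noise source zeroed (for ablation)."""
        zero = {
            "landmark": {"landmark_sigma_px": 0.0, "outlier_count": 0},
            "correspondence": {"correspondence_sigma_mm": 0.0},
            "height": {"height_sigma_px": 0.0},
        }[source]
        return replace(self, **zero)


def generate_hand_model(seed: int = 0, scale_mm: float = 180.0,
                        jitter: float = 0.01) -> HandModel3D:
    """Deterministic 21-landmark, 18-acupoint reference hand (mm).

    ``scale_mm`` is the hand length; all coordinates scale linearly with
    it.  ``jitter`` adds a small seeded shape perturbation (in hand units)
    so different seeds give different individual hands.
    """
    if scale_mm <= 0:
        raise ValueError("scale_mm must be positive")
    rng = np.random.default_rng(seed)
    lm = {
        name: np.asarray(_TEMPLATE[name], float)
        + rng.normal(0.0, jitter, 3)
        for name in LANDMARK_NAMES
    }
    acupoints, sides = {}, {}
    for name, (side, weights, z_off) in _ACUPOINT_RECIPES.items():
        pt = sum(w * lm[k] for k, w in weights.items())
        pt = pt + np.array([0.0, 0.0, z_off])
        acupoints[name] = pt * scale_mm
        sides[name] = side
    landmarks = {k: v * scale_mm for k, v in lm.items()}
    return HandModel3D(landmarks, acupoints, sides)


def _rotation_zxy(yaw: float, tilt_x: float, tilt_y: float) -> np.ndarray:
    cz, sz = np.cos(yaw), np.sin(yaw)
    cx, sx = np.cos(tilt_x), np.sin(tilt_x)
    cy, sy = np.cos(tilt_y), np.sin(tilt_y)
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    return rz @ rx @ ry


def _look_at(camera_center: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rows of the world->camera rotation for a camera at C looking at T."""
    z = target - camera_center
    z = z / np.linalg.norm(z)
    up_hint = np.array([0.0, 1.0, 0.0])
    x = np.cross(up_hint, z)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return np.stack([x, y, z])


@dataclass
class SyntheticScene:
    """A fully ground-truthed rig: hand, camera, robot plane, noise, seed."""

    model: HandModel3D
    camera: CameraModel
    pose: Pose                       # model -> camera (what estimate_pose targets)
    hand_rotation: np.ndarray        # model -> world (robot frame, mm)
    hand_translation: np.ndarray
    camera_rotation: np.ndarray      # world -> camera rows
    camera_center: np.ndarray        # mm, world frame
    true_landmark_px: dict
    true_acupoint_px: dict
    true_acupoint_robot_mm: dict     # world (x, y) per acupoint
    true_acupoint_height_cm: dict    # world z / 10 per acupoint
    mm_per_px: float                 # projective scale at the hand surface
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    @property
    def projection_matrix(self) -> np.ndarray:
        k = self.camera.intrinsic_matrix
        return k @ np.hstack([
            self.camera_rotation,
            (-self.camera_rotation @ self.camera_center)[:, None],
        ])

    def plane_to_pixel_matrix(self, height_mm: float = 0.0) -> np.ndarray:
        """Homography: world (x, y) on the plane z = height_mm -> pixel."""
        p = self.projection_matrix
        return np.column_stack([p[:, 0], p[:, 1], height_mm * p[:, 2] + p[:, 3]])

    def world_plane_to_pixel(self, xy, height_mm: float = 0.0) -> np.ndarray:
        return PerspectiveTransform(
            self.plane_to_pixel_matrix(height_mm)
        )(np.asarray(xy, float))

    def true_image_to_robot(self) -> PerspectiveTransform:
        """Exact pixel -> robot map for points on the calibration plane."""
        return PerspectiveTransform(
            np.linalg.inv(self.plane_to_pixel_matrix(0.0))
        )

    def true_height_transform(self, offset_cm: float = 1.0) -> PerspectiveTransform:
        """Exact image-at-offset -> image-at-base map (the ideal F)."""
        h0 = self.plane_to_pixel_matrix(0.0)
        hh = self.plane_to_pixel_matrix(10.0 * offset_cm)
        return PerspectiveTransform(h0 @ np.linalg.inv(hh))


def generate_scene(
    model: HandModel3D | None = None,
    *,
    camera_distance_mm: float = 300.0,
    yaw_deg: float = 0.0,
    tilt_x_deg: float = 0.0,
    tilt_y_deg: float = 0.0,
    hand_offset_mm: tuple = (0.0, 0.0),
    hand_height_mm: float = 10.0,
    camera_offset_mm: tuple = (25.0, 18.0),
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> tuple[SyntheticScene, LandmarkSet2D]:
    """Pose a hand in the robot workspace and image it from above.

    The world frame is the robot frame: z = 0 is the calibration plane,
    units mm.  The camera sits ``camera_distance_mm`` above the hand with
    a small lateral offset (so its view is slightly off-nadir, as on a
    physical rig), looking at the hand.  Returns the ground-truth scene
    and the noisy landmark detections prescribed by ``noise``.
    """
    if camera_distance_mm <= 0:
        raise ValueError("camera_distance_mm must be positive")
    if model is None:
        model = generate_hand_model(seed)
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)

    r_hand = _rotation_zxy(
        np.deg2rad(yaw_deg), np.deg2rad(tilt_x_deg), np.deg2rad(tilt_y_deg)
    )
    lm_names = list(model.landmarks)
    lm_pts = np.array([model.landmarks[n] for n in lm_names])
    ap_names = list(model.acupoints)
    ap_pts = np.array([model.acupoints[n] for n in ap_names])

    centroid = lm_pts.mean(axis=0)
    t_hand = (
        np.array([hand_offset_mm[0], hand_offset_mm[1], hand_height_mm])
        - r_hand @ centroid
        + np.array([0.0, 0.0, (r_hand @ centroid)[2]])
    )
    lm_world = lm_pts @ r_hand.T + t_hand
    ap_world = ap_pts @ r_hand.T + t_hand
    # lift so the lowest back-surface point sits at hand_height_mm
    lift = hand_height_mm - lm_world[:, 2].min()
    t_hand = t_hand + np.array([0.0, 0.0, lift])
    lm_world = lm_world + np.array([0.0, 0.0, lift])
    ap_world = ap_world + np.array([0.0, 0.0, lift])

    surface_z = lm_world[:, 2].mean()
    cam_center = np.array([
        camera_offset_mm[0], camera_offset_mm[1],
        surface_z + camera_distance_mm,
    ])
    r_cam = _look_at(cam_center, np.array([0.0, 0.0, surface_z]))

    focal = 640.0  # 180 mm hand spans ~60% of 640 px at 300 mm
    camera = CameraModel(focal, (320.0, 240.0), (640, 480))
    pose = Pose(r_cam @ r_hand, r_cam @ (t_hand - cam_center))

    proj = np.hstack([r_cam, (-r_cam @ cam_center)[:, None]])

    def pixels(world):
        cam = world @ proj[:, :3].T + proj[:, 3]
        if np.any(cam[:, 2] <= 1e-9):
            bad = [n for n, z in zip(lm_names + ap_names, cam[:, 2]) if z <= 1e-9]
            raise PointBehindCameraError(bad)
        uv = focal * cam[:, :2] / cam[:, 2:3]
        return uv + np.array([320.0, 240.0]), cam[:, 2]

    lm_px, _ = pixels(lm_world)
    ap_px, ap_depth = pixels(ap_world)
    mm_per_px = float(np.mean(ap_depth) / focal)

    scene = SyntheticScene(
        model=model,
        camera=camera,
        pose=pose,
        hand_rotation=r_hand,
        hand_translation=t_hand,
        camera_rotation=r_cam,
        camera_center=cam_center,
        true_landmark_px=dict(zip(lm_names, lm_px)),
        true_acupoint_px=dict(zip(ap_names, ap_px)),
        true_acupoint_robot_mm={
            n: w[:2].copy() for n, w in zip(ap_names, ap_world)
        },
        true_acupoint_height_cm={
            n: float(w[2] / 10.0) for n, w in zip(ap_names, ap_world)
        },
        mm_per_px=mm_per_px,
        noise=noise,
        seed=seed,
    )

    noisy = lm_px + rng.normal(0.0, noise.landmark_sigma_px, lm_px.shape)
    if noise.outlier_count > 0:
        which = rng.choice(len(lm_names), noise.outlier_count, replace=False)
        for i in which:
            theta = rng.uniform(0, 2 * np.pi)
            noisy[i] += noise.outlier_magnitude_px * np.array(
                [np.cos(theta), np.sin(theta)]
            )
    detections = LandmarkSet2D(
        dict(zip(lm_names, noisy)), side="back", image_size=camera.image_size
    )
    return scene, detections


def generate_calibration_points(
    scene: SyntheticScene,
    n_base: int = 13,
    n_offset: int = 13,
    offset_cm: float = 1.0,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    workspace_mm: float = 80.0,
) -> tuple[list, list]:
    """Reference-point sets for hand-eye and height calibration.

    Base set: (pixel on the calibration plane, robot mm) pairs, with
    Gaussian mm noise on the robot side.  Offset set: (pixel of the same
    workspace point ``offset_cm`` higher, pixel on the base plane) pairs,
    with pixel noise on the base-plane side.
    """
    if min(n_base, n_offset) < 4:
        raise ValueError("need at least 4 reference points per set")
    noise = noise or scene.noise
    rng = np.random.default_rng(seed)

    xy_base = rng.uniform(-workspace_mm, workspace_mm, (n_base, 2))
    px_base = scene.world_plane_to_pixel(xy_base, 0.0)
    robot = xy_base + rng.normal(0.0, noise.correspondence_sigma_mm, xy_base.shape)
    base = [Correspondence(tuple(s), tuple(d)) for s, d in zip(px_base, robot)]

    xy_off = rng.uniform(-workspace_mm, workspace_mm, (n_offset, 2))
    px_at_offset = scene.world_plane_to_pixel(xy_off, 10.0 * offset_cm)
    px_at_base = scene.world_plane_to_pixel(xy_off, 0.0)
    px_at_base = px_at_base + rng.normal(0.0, noise.height_sigma_px, px_at_base.shape)
    off = [
        Correspondence(tuple(s), tuple(d))
        for s, d in zip(px_at_offset, px_at_base)
    ]
    return base, off


@dataclass
class PPGTruth:
    """Exact generator record for a synthetic PPG signal."""

    beat_times_s: np.ndarray
    beat_amplitudes_mv: np.ndarray
    hr_bpm: float
    hf_mod_hz: float
    hf_mod_depth_ms: float
    snr_db: float
    seed: int


def generate_ppg(
    duration_s: float = 300.0,
    fs_hz: float = 25.0,
    hr_bpm: float = 60.0,
    amplitude_mv: float = 1.0,
    hf_mod: tuple = (0.25, 0.0),
    snr_db: float = float("inf"),
    seed: int = 0,
    baseline_mv: float = 0.0,
    amplitude_ramp: float = 0.0,
):
    """Synthetic PPG: asymmetric Gaussian pulses with known beat times.

    Beat intervals follow PP(t) = 60000/HR + depth*sin(2*pi*f*t) ms with
    (f, depth) = ``hf_mod``; per-beat amplitudes ramp linearly by
    ``amplitude_ramp`` over the recording; white noise is added at
    ``snr_db``.  Returns (PPGSignal, PPGTruth).
    """
    from .ppg import PPGSignal  # local import to avoid a cycle

    if duration_s <= 0 or fs_hz < 20 or hr_bpm <= 0 or amplitude_mv <= 0:
        raise ValueError("invalid PPG generator parameters")
    mod_hz, depth_ms = hf_mod
    rng = np.random.default_rng(seed)

    beat_times = []
    t = 0.4
    while t < duration_s - 0.3:
        beat_times.append(t)
        pp_ms = 60000.0 / hr_bpm + depth_ms * np.sin(2 * np.pi * mod_hz * t)
        t += pp_ms / 1000.0
    beat_times = np.asarray(beat_times)
    n_beats = len(beat_times)
    if amplitude_ramp and n_beats > 1:
        ramp = 1.0 + amplitude_ramp * np.arange(n_beats) / (n_beats - 1)
    else:
        ramp = np.ones(n_beats)
    beat_amps = amplitude_mv * ramp

    times = np.arange(int(round(duration_s * fs_hz))) / fs_hz
    y = np.full_like(times, baseline_mv)
    pp_s = 60.0 / hr_bpm
    sig_l, sig_r = 0.10 * pp_s, 0.22 * pp_s
    for bt, amp in zip(beat_times, beat_amps):
        d = times - bt
        window = np.abs(d) < 4 * sig_r
        dl = d[window]
        pulse = np.where(
            dl < 0,
            np.exp(-0.5 * (dl / sig_l) ** 2),
            np.exp(-0.5 * (dl / sig_r) ** 2),
        )
        y[window] += amp * pulse

    if np.isfinite(snr_db):
        p_signal = np.mean((y - y.mean()) ** 2)
        p_noise = p_signal / 10.0 ** (snr_db / 10.0)
        y = y + rng.normal(0.0, np.sqrt(p_noise), y.shape)

    truth = PPGTruth(beat_times, beat_amps, hr_bpm, mod_hz, depth_ms,
                     snr_db, seed)
    return PPGSignal(y, fs_hz), truth
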