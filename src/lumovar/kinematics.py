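"""Marker-cluster kinematics: from 3-marker cluster trajectories to lumbar Euler angles.

Two clusters of three reflective markers (fixed over the T8 spinous process for the
thorax and over S1 for the pelvis) are tracked at a nominal 100 samples/s.  Each
cluster defines a segment-fixed orthonormal frame; the lumbar orientation is the
rotation of the thorax frame expressed in the pelvis frame, decomposed into Euler
angles in the order flexion/extension, lateral bending, axial rotation.

Axis convention (configurable at the cluster-geometry level, documented default):
at upright start the pelvis frame coincides with the global anatomical frame with
x mediolateral (flexion axis, positive rotation = forward flexion), y
anteroposterior (lateral-bending axis) and z vertical (axial-rotation axis).
Angles are reported in degrees throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

__all__ = [
    "AngleSeries",
    "MarkerTrial",
    "KinematicsError",
    "GimbalLockError",
    "DegenerateClusterError",
    "THORAX_MARKERS",
    "PELVIS_MARKERS",
    "AXIS_ORDER",
    "resample_to_rate",
    "cluster_orientation",
    "relative_rotation",
    "euler_compose",
    "euler_decompose",
    "markers_to_angles",
]

#: canonical marker labels, thorax cluster then pelvis cluster
THORAX_MARKERS = ("thorax_1", "thorax_2", "thorax_3")
PELVIS_MARKERS = ("pelvis_1", "pelvis_2", "pelvis_3")

#: Euler decomposition order (intrinsic x-y'-z'')
AXIS_ORDER = ("flexion_extension", "lateral_bending", "axial_rotation")

_EULER_SEQ = "XYZ"  # intrinsic: R = Rx(fe) @ Ry(lb) @ Rz(ar)


class KinematicsError(ValueError):
    """Base class for kinematics-stage failures."""


class GimbalLockError(KinematicsError):
    """Lateral bending too close to +/-90 deg for a unique Euler decomposition."""


class DegenerateClusterError(KinematicsError):
    """The three cluster markers are (near-)collinear."""


@dataclass
class AngleSeries:
    """Lumbar Euler-angle time series at a fixed sample rate.

    Attributes
    ----------
    angles : (n, 3) array, degrees, columns in :data:`AXIS_ORDER`.
    sample_rate : Hz.
    """

    angles: np.ndarray
    sample_rate: float
    axis_order: tuple = AXIS_ORDER

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != 3:
            raise KinematicsError(f"angles must be (n, 3), got {self.angles.shape}")
        if not np.isfinite(self.angles).all():
            raise KinematicsError("angles contain non-finite values")
        if self.sample_rate <= 0:
            raise KinematicsError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.angles.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    @property
    def flexion_extension(self) -> np.ndarray:
        return self.angles[:, 0]


@dataclass
class MarkerTrial:
    """Raw marker trajectories for one trial.

    ``positions`` maps marker label -> (n, 3) array of global coordinates in
    meters; missing samples are NaN.  ``timestamps`` is strictly increasing,
    in seconds, possibly non-uniform (the capture software records at a
    fluctuating 102/103 Hz).
    """

    timestamps: np.ndarray
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    nominal_rate: float = 100.0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.size < 2:
            raise KinematicsError("need at least 2 samples")
        if not (np.diff(self.timestamps) > 0).all():
            raise KinematicsError("timestamps must be strictly increasing")
        clean = {}
        for label, pos in self.positions.items():
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (self.timestamps.size, 3):
                raise KinematicsError(
                    f"marker {label!r}: positions shape {pos.shape} does not match "
                    f"{self.timestamps.size} timestamps"
                )
            clean[label] = pos
        self.positions = clean

    @property
    def markers(self) -> tuple:
        return tuple(self.positions)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


def resample_to_rate(trial: MarkerTrial, rate: float = 100.0, max_gap: float = 0.1) -> MarkerTrial:
    """Cubic-spline resample every marker coordinate onto a uniform grid.

    Missing samples (NaN) are bridged by the spline provided no gap between
    valid samples exceeds ``max_gap`` seconds; a longer dropout raises
    :class:`KinematicsError` naming the marker and interval.  The original
    time span is preserved.
    """
    if rate <= 0:
        raise KinematicsError("rate must be positive")
    t = trial.timestamps
    t0, t1 = t[0], t[-1]
    n_out = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
    grid = t0 + np.arange(n_out) / rate
    out: dict[str, np.ndarray] = {}
    for label, pos in trial.positions.items():
        res = np.empty((n_out, 3))
        for axis in range(3):
            x = pos[:, axis]
            valid = np.isfinite(x)
            if valid.sum() < 4:
                raise KinematicsError(
                    f"marker {label!r} axis {axis}: fewer than 4 valid samples"
                )
            tv = t[valid]
            gaps = np.diff(tv)
            if gaps.size and gaps.max() > max_gap + 1e-12:
                k = int(np.argmax(gaps))
                raise KinematicsError(
                    f"marker {label!r} axis {axis}: gap of {gaps[k]:.3f} s in "
                    f"[{tv[k]:.3f}, {tv[k + 1]:.3f}] exceeds {max_gap} s"
                )
            if tv[0] > t0 + max_gap + 1e-12 or tv[-1] < t1 - max_gap - 1e-12:
                raise KinematicsError(
                    f"marker {label!r} axis {axis}: missing data at trial boundary"
                )
            spline = CubicSpline(tv, x[valid])
            res[:, axis] = spline(grid)
        out[label] = res
    return MarkerTrial(timestamps=grid, positions=out, nominal_rate=rate)


def cluster_orientation(p1, p2, p3, *, area_tol: float = 1e-9) -> np.ndarray:
    """Orthonormal right-handed frame of a 3-marker cluster.

    Axis 1 is the normalized p1->p2 direction, axis 3 the normalized cross
    product of axis 1 with p1->p3, axis 2 completes the triad.  Returns the
    rotation matrix whose columns are the axes in global coordinates
    (determinant +1).  Broadcasts over leading dimensions.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    u = p2 - p1
    v = p3 - p1
    w = np.cross(u, v)
    w_norm = np.linalg.norm(w, axis=-1, keepdims=True)
    u_norm = np.linalg.norm(u, axis=-1, keepdims=True)
    # triangle area relative to edge length guards against collinearity
    if np.any(u_norm < area_tol) or np.any(w_norm / np.maximum(u_norm, area_tol) ** 2 < area_tol):
        raise DegenerateClusterError("cluster markers are collinear or coincident")
    e1 = u / u_norm
    e3 = w / w_norm
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3], axis=-1)


def _check_rotation(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise KinematicsError(f"expected (..., 3, 3) rotation, got {R.shape}")
    eye = np.eye(3)
    err = np.abs(np.swapaxes(R, -1, -2) @ R - eye).max()
    if err > tol:
        raise KinematicsError(f"matrix is not orthogonal (max |R'R - I| = {err:.2e})")
    if np.any(np.linalg.det(R) < 0):
        raise KinematicsError("matrix is a reflection (det < 0), not a rotation")
    return R


def relative_rotation(R_thorax: np.ndarray, R_pelvis: np.ndarray) -> np.ndarray:
    """Thorax orientation expressed in the pelvis frame: R_pelvis' @ R_thorax."""
    R_thorax = _check_rotation(R_thorax)
    R_pelvis = _check_rotation(R_pelvis)
    return np.swapaxes(R_pelvis, -1, -2) @ R_thorax


def euler_compose(angles, degrees: bool = True) -> np.ndarray:
    """Rotation matrix from (flexion-extension, lateral-bending, axial-rotation).

    Intrinsic x-y'-z'' sequence: R = Rx(fe) @ Ry(lb) @ Rz(ar).
    """
    angles = np.asarray(angles, dtype=float)
    return Rotation.from_euler(_EULER_SEQ, angles, degrees=degrees).as_matrix()


def euler_decompose(R: np.ndarray, degrees: bool = True, gimbal_margin: float = 1.0) -> np.ndarray:
    """Euler angles (fe, lb, ar) such that :func:`euler_compose` reproduces ``R``.

    Raises :class:`GimbalLockError` when lateral bending is within
    ``gimbal_margin`` degrees of +/-90 (the seated reaching task never
    approaches that posture; reaching it indicates corrupted input).
    """
    R = _check_rotation(R)
    sin_lb = np.clip(R[..., 0, 2], -1.0, 1.0)
    if np.any(np.abs(sin_lb) > np.sin(np.radians(90.0 - gimbal_margin))):
        raise GimbalLockError(
            f"lateral bending within {gimbal_margin} deg of gimbal lock"
        )
    ang = Rotation.from_matrix(R).as_euler(_EULER_SEQ, degrees=degrees)
    return ang


def markers_to_angles(trial: MarkerTrial, thorax=THORAX_MARKERS, pelvis=PELVIS_MARKERS) -> AngleSeries:
    """Full per-sample chain: cluster frames -> relative rotation -> Euler angles.

    Expects a trial already resampled to a uniform rate (see
    :func:`resample_to_rate`).
    """
    missing = [m for m in (*thorax, *pelvis) if m not in trial.positions]
    if missing:
        raise KinematicsError(f"trial is missing markers: {missing}")
    dt = np.diff(trial.timestamps)
    if not np.allclose(dt, dt[0], atol=1e-9):
        raise KinematicsError("trial must be uniformly sampled; run resample_to_rate first")
    rate = 1.0 / dt[0]
    R_t = cluster_orientation(*(trial.positions[m] for m in thorax))
    R_p = cluster_orientation(*(trial.positions[m] for m in pelvis))
    R_rel = relative_rotation(R_t, R_p)
    angles = euler_decompose(R_rel)
    return AngleSeries(angles=angles, sample_rate=rate)
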