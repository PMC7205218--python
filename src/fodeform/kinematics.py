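"""Rigid-body kinematics for marker-based motion capture.

Coordinate frames are built from marker triplets, orientations are
parameterized with a YXZ Cardan sequence (rotate about Y, then X, then Z),
and marker clouds can be re-expressed in a session-local frame so that
whole-body rigid motion drops out of every downstream feature.

Convention used throughout the package: Y is vertical (up), X points
toe-ward and Z completes a right-handed frame. Positions are millimetres,
angles radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateGeometryError, ParameterError

__all__ = [
    "MarkerTrajectorySet",
    "RigidFrame",
    "CardanAngles",
    "frame_from_three_markers",
    "triad_orientation",
    "cardan_yxz_from_rotation",
    "rotation_from_cardan_yxz",
    "relative_cardan",
    "express_in_local_frame",
    "interpolate_gaps",
    "lowpass_filter",
]

_ORTHO_TOL = 1e-9


@dataclass
class MarkerTrajectorySet:
    """Labeled 3D marker positions over uniformly sampled time frames.

    Parameters
    ----------
    labels
        One name per marker column.
    positions
        Array of shape ``(n_frames, n_markers, 3)`` in millimetres.
    rate
        Sampling rate in Hz (100 Hz for the optoelectronic sessions).
    """

    labels: list[str]
    positions: np.ndarray
    rate: float = 100.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.labels = list(self.labels)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ParameterError(
                f"positions must have shape (n_frames, n_markers, 3), got {self.positions.shape}"
            )
        if self.positions.shape[1] != len(self.labels):
            raise ParameterError(
                f"{len(self.labels)} labels but {self.positions.shape[1]} marker columns"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError("marker labels must be unique")
        if self.rate <= 0:
            raise ParameterError("sampling rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"marker {label!r} not in trajectory set") from None

    def marker(self, label: str) -> np.ndarray:
        """Trajectory of one marker, shape ``(n_frames, 3)``."""
        return self.positions[:, self.index(label), :]

    def subset(self, labels: list[str]) -> "MarkerTrajectorySet":
        idx = [self.index(lb) for lb in labels]
        return MarkerTrajectorySet(list(labels), self.positions[:, idx, :].copy(), self.rate)

    def copy(self) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(list(self.labels), self.positions.copy(), self.rate)


@dataclass
class RigidFrame:
    """A proper rigid transform: rotation matrix plus origin.

    ``rotation`` maps local coordinates to lab coordinates; ``origin`` is the
    frame origin expressed in the lab.
    """

    rotation: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ParameterError("rotation must be 3x3")
        if self.origin.shape != (3,):
            raise ParameterError("origin must be a 3-vector")

    @classmethod
    def identity(cls) -> "RigidFrame":
        return cls(np.eye(3), np.zeros(3))

    def is_valid(self, tol: float = _ORTHO_TOL) -> bool:
        R = self.rotation
        return (
            np.allclose(R @ R.T, np.eye(3), atol=tol)
            and abs(np.linalg.det(R) - 1.0) <= tol
        )

    def transform(self, local_points: np.ndarray) -> np.ndarray:
        """Map local coordinates into the lab frame."""
        pts = np.asarray(local_points, dtype=float)
        return pts @ self.rotation.T + self.origin


@dataclass
class CardanAngles:
    """YXZ Cardan angles (radians): R = Ry(theta_y) @ Rx(theta_x) @ Rz(theta_z)."""

    theta_y: float
    theta_x: float
    theta_z: float
    gimbal_lock: bool = field(default=False, compare=False)

    def as_array(self) -> np.ndarray:
        return np.array([self.theta_y, self.theta_x, self.theta_z])


def frame_from_three_markers(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    *,
    labels: tuple[str, str, str] | None = None,
    tol: float = 1e-8,
) -> RigidFrame:
    """Build a right-handed frame from three non-collinear markers.

    The origin sits on ``p1``, the first axis points toward ``p2`` and the
    third axis is normal to the marker plane; the second axis completes the
    right-handed set. The returned rotation maps local to lab coordinates.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    if np.any(~np.isfinite([p1, p2, p3])):
        raise DegenerateGeometryError(_degenerate_msg(labels, "non-finite marker position"))
    v1 = p2 - p1
    v2 = p3 - p1
    n1 = np.linalg.norm(v1)
    if n1 < tol:
        raise DegenerateGeometryError(_degenerate_msg(labels, "first two markers coincide"))
    x_axis = v1 / n1
    normal = np.cross(x_axis, v2)
    n3 = np.linalg.norm(normal)
    if n3 < tol:
        raise DegenerateGeometryError(_degenerate_msg(labels, "markers are collinear"))
    z_axis = normal / n3
    y_axis = np.cross(z_axis, x_axis)
    return RigidFrame(np.column_stack([x_axis, y_axis, z_axis]), p1)


def _degenerate_msg(labels: tuple[str, str, str] | None, why: str) -> str:
    if labels is None:
        return f"cannot build frame: {why}"
    return f"cannot build frame from markers {labels[0]}/{labels[1]}/{labels[2]}: {why}"


def triad_orientation(
    m1: np.ndarray,
    m2: np.ndarray,
    m3: np.ndarray,
    *,
    labels: tuple[str, str, str] | None = None,
) -> RigidFrame:
    """Orientation of one contour triad from its three branch markers.

    Marker ordering within the triad is fixed by label; the frame convention
    is the same as :func:`frame_from_three_markers`.
    """
    return frame_from_three_markers(m1, m2, m3, labels=labels)


def rotation_from_cardan_yxz(angles: CardanAngles | np.ndarray) -> np.ndarray:
    """Compose the rotation ``Ry(theta_y) @ Rx(theta_x) @ Rz(theta_z)``."""
    if isinstance(angles, CardanAngles):
        a, b, c = angles.theta_y, angles.theta_x, angles.theta_z
    else:
        a, b, c = np.asarray(angles, dtype=float)
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    return np.array(
        [
            [ca * cc + sa * sb * sc, -ca * sc + sa * sb * cc, sa * cb],
            [cb * sc, cb * cc, -sb],
            [-sa * cc + ca * sb * sc, sa * sc + ca * sb * cc, ca * cb],
        ]
    )


def cardan_yxz_from_rotation(
    R: np.ndarray, *, gimbal_tol: float = 1e-7, ortho_tol: float = 1e-6
) -> CardanAngles:
    """Decompose a proper rotation into YXZ Cardan angles (principal branch).

    ``theta_x`` lies in ``[-pi/2, pi/2]``. At gimbal lock (``|theta_x|``
    within ``gimbal_tol`` of ``pi/2``) only the sum/difference of theta_y and
    theta_z is defined; the convention here resolves it with ``theta_z = 0``
    and flags the result.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ParameterError("rotation must be 3x3")
    if not np.allclose(R @ R.T, np.eye(3), atol=ortho_tol) or np.linalg.det(R) < 0:
        raise ParameterError("matrix is not a proper rotation")
    sb = np.clip(-R[1, 2], -1.0, 1.0)
    theta_x = float(np.arcsin(sb))
    if np.pi / 2 - abs(theta_x) < gimbal_tol:
        # Singular: Y and Z rotations collapse onto one another.
        if sb > 0:
            theta_y = float(np.arctan2(R[0, 1], R[0, 0]))
        else:
            theta_y = float(np.arctan2(-R[0, 1], R[0, 0]))
        return CardanAngles(theta_y, theta_x, 0.0, gimbal_lock=True)
    theta_y = float(np.arctan2(R[0, 2], R[2, 2]))
    theta_z = float(np.arctan2(R[1, 0], R[1, 1]))
    return CardanAngles(theta_y, theta_x, theta_z)


def relative_cardan(triad: RigidFrame, back_triad: RigidFrame) -> CardanAngles:
    """YXZ angles of a triad's orientation relative to the back triad.

    Decomposes ``back_triad.rotation.T @ triad.rotation``: the back triad is
    the reference because it sits on the fixed heel cup and moves least.
    """
    return cardan_yxz_from_rotation(back_triad.rotation.T @ triad.rotation)


def express_in_local_frame(points: np.ndarray, frame: RigidFrame) -> np.ndarray:
    """Express lab-frame points in a local frame: ``R.T @ (x - origin)``.

    Works on a single point or any leading batch shape ``(..., 3)``. Because
    the local frame rides along with the markers that define it, a common
    rigid motion of the whole scene leaves the result unchanged.
    """
    pts = np.asarray(points, dtype=float)
    return (pts - frame.origin) @ frame.rotation


def interpolate_gaps(
    mts: MarkerTrajectorySet, *, max_gap: int = 10
) -> tuple[MarkerTrajectorySet, np.ndarray]:
    """Fill NaN marker gaps of at most ``max_gap`` frames by linear interpolation.

    Frames still containing NaNs afterwards (gaps too long, or gaps touching
    the recording boundary) are dropped. Returns the cleaned set and the
    indices of retained frames.
    """
    pos = mts.positions.copy()
    n = pos.shape[0]
    t = np.arange(n)
    for j in range(pos.shape[1]):
        for axis in range(3):
            col = pos[:, j, axis]
            bad = ~np.isfinite(col)
            if not bad.any() or bad.all():
                continue
            # Identify runs of missing samples and patch the short interior ones.
            run_start = None
            for i in range(n + 1):
                missing = i < n and bad[i]
                if missing and run_start is None:
                    run_start = i
                elif not missing and run_start is not None:
                    run_len = i - run_start
                    interior = run_start > 0 and i < n
                    if interior and run_len <= max_gap:
                        col[run_start:i] = np.interp(
                            t[run_start:i], [run_start - 1, i], [col[run_start - 1], col[i]]
                        )
                    run_start = None
            pos[:, j, axis] = col
    keep = np.isfinite(pos).all(axis=(1, 2))
    cleaned = MarkerTrajectorySet(list(mts.labels), pos[keep], mts.rate)
    return cleaned, np.nonzero(keep)[0]


def lowpass_filter(
    mts: MarkerTrajectorySet, cutoff: float = 8.0, order: int = 4
) -> MarkerTrajectorySet:
    """Zero-lag Butterworth low-pass of every marker trajectory.

    Forward-backward filtering (no phase shift) with a default 8 Hz cutoff:
    manual loading and gait kinematics live well below that, so this is the
    usual optical-mocap noise hygiene. Requires finite positions (fill gaps
    first).
    """
    from scipy import signal

    if cutoff <= 0 or cutoff >= mts.rate / 2:
        raise ParameterError(
            f"cutoff must lie in (0, {mts.rate / 2:g}) Hz for a {mts.rate:g} Hz recording"
        )
    if not np.isfinite(mts.positions).all():
        raise ParameterError("cannot filter trajectories containing NaNs; fill gaps first")
    b, a = signal.butter(order, cutoff / (mts.rate / 2))
    smoothed = signal.filtfilt(b, a, mts.positions, axis=0)
    return MarkerTrajectorySet(list(mts.labels), smoothed, mts.rate)
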