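"""From predicted walking surfaces to pure deformation fields.

The local-frame marker positions during walking mix residual rigid motion
(the three frame-defining markers themselves ride on a deforming structure)
with true surface deformation. The optimal rigid rototranslation between
each frame and the unloaded static configuration — the least-squares
rotation obtained by polar decomposition of the centered cross-covariance,
reflection-corrected, plus the centroid translation — is removed, leaving
the non-rigid residual. The signed vertical residual is the depression
(negative) / reformation (positive) of each surface point; stance phases
are detected from the load series and every cycle is resampled to 101
samples (0-100% stance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import DegenerateGeometryError, ParameterError
from .kinematics import RigidFrame

__all__ = [
    "DeformationField",
    "StanceCycle",
    "optimal_rototranslation",
    "remove_rigid_motion",
    "detect_stance",
    "normalize_to_stance",
    "depression_reformation",
    "stance_peaks",
    "deformation_field_from_positions",
]

N_STANCE_SAMPLES = 101


@dataclass
class StanceCycle:
    heel_strike_frame: int
    toe_off_frame: int

    def __post_init__(self) -> None:
        if self.toe_off_frame <= self.heel_strike_frame:
            raise ParameterError("toe off must come after heel strike")

    @property
    def duration(self) -> int:
        return self.toe_off_frame - self.heel_strike_frame


@dataclass
class DeformationField:
    """Signed vertical deformation, 55 points x 101 stance samples (mm)."""

    values: np.ndarray
    subject: str = ""
    condition: str = ""
    cycle: str = "mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_STANCE_SAMPLES:
            raise ParameterError(
                f"deformation field needs {N_STANCE_SAMPLES} stance samples, got {self.values.shape}"
            )


def optimal_rototranslation(
    static_points: np.ndarray, current_points: np.ndarray
) -> tuple[RigidFrame, np.ndarray]:
    """Least-squares rigid transform mapping the static cloud onto the current one.

    The rotation comes from the polar decomposition of the centered
    cross-covariance (via SVD, with the reflection corrected to det = +1);
    the translation aligns the centroids. Returns the transform and the
    residual displacements ``current - (R @ static + t)`` — the non-rigid
    deformation.
    """
    s = np.asarray(static_points, dtype=float)
    c = np.asarray(current_points, dtype=float)
    if s.shape != c.shape or s.ndim != 2 or s.shape[1] != 3:
        raise ParameterError("static and current point sets must be matching (n, 3) arrays")
    if len(s) < 3:
        raise DegenerateGeometryError("need at least 3 point pairs for a rigid fit")
    s_mean = s.mean(axis=0)
    c_mean = c.mean(axis=0)
    H = (s - s_mean).T @ (c - c_mean)
    if np.linalg.matrix_rank(H, tol=1e-9) < 2:
        raise DegenerateGeometryError("degenerate point cloud: cross-covariance rank < 2")
    U, _, Vt = linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = c_mean - R @ s_mean
    residuals = c - (s @ R.T + t)
    return RigidFrame(R, t), residuals


def remove_rigid_motion(
    static_points: np.ndarray, current_points: np.ndarray
) -> np.ndarray:
    """Current points mapped back into the static frame with the rigid part undone.

    The result is directly comparable, point by point, with the static
    configuration; its vertical offset from static is the signed deformation.
    """
    frame, _ = optimal_rototranslation(static_points, current_points)
    return (np.asarray(current_points, dtype=float) - frame.origin) @ frame.rotation


def detect_stance(
    load_series: np.ndarray,
    *,
    rate: float = 100.0,
    threshold_fraction: float = 0.05,
    min_duration_s: float = 0.2,
) -> list[StanceCycle]:
    """Stance cycles as contiguous supra-threshold runs of the load series.

    The threshold defaults to 5% of the per-trial peak; runs shorter than
    ``min_duration_s`` are discarded as load artefacts. An empty result (with
    a warning) means no gait was found.
    """
    load = np.asarray(load_series, dtype=float)
    if np.any(load < 0):
        raise ParameterError("load series must be non-negative")
    peak = load.max() if load.size else 0.0
    if peak <= 0:
        return []
    thr = threshold_fraction * peak
    above = load > thr
    min_frames = max(int(round(min_duration_s * rate)), 2)
    cycles: list[StanceCycle] = []
    start = None
    for i in range(len(above) + 1):
        on = i < len(above) and above[i]
        if on and start is None:
            start = i
        elif not on and start is not None:
            if i - start >= min_frames:
                cycles.append(StanceCycle(start, i))
            start = None
    if not cycles:
        import warnings

        warnings.warn("no stance cycles found in load series", stacklevel=2)
    return cycles


def normalize_to_stance(series: np.ndarray, cycle: StanceCycle) -> np.ndarray:
    """Resample a per-frame series onto 0-100% stance in 1% steps (101 samples).

    Linear interpolation; endpoints of the stance window are preserved.
    Accepts shape ``(n_frames,)`` or ``(n_frames, ...)``.
    """
    s = np.asarray(series, dtype=float)
    if cycle.toe_off_frame > len(s):
        raise ParameterError("stance cycle extends beyond the recording")
    if cycle.duration < 2:
        raise ParameterError("stance cycle must span at least 2 frames")
    window = s[cycle.heel_strike_frame : cycle.toe_off_frame]
    t_src = np.linspace(0.0, 1.0, len(window))
    t_dst = np.linspace(0.0, 1.0, N_STANCE_SAMPLES)
    if window.ndim == 1:
        return np.interp(t_dst, t_src, window)
    flat = window.reshape(len(window), -1)
    out = np.empty((N_STANCE_SAMPLES, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(t_dst, t_src, flat[:, j])
    return out.reshape((N_STANCE_SAMPLES,) + window.shape[1:])


def depression_reformation(
    transformed_positions: np.ndarray, static_reference: np.ndarray
) -> np.ndarray:
    """Signed vertical deformation: ``d = y_current - y_static`` per point.

    Both inputs must be in the same local frame with rigid motion already
    removed. Negative values are depression (point pressed below its
    unloaded static height), positive values reformation.
    """
    cur = np.asarray(transformed_positions, dtype=float)
    ref = np.asarray(static_reference, dtype=float)
    if cur.shape[-2:] != ref.shape:
        raise ParameterError("positions and static reference must share (n_points, 3)")
    return cur[..., 1] - ref[..., 1]


def deformation_field_from_positions(
    positions: np.ndarray,
    static_reference: np.ndarray,
    cycles: list[StanceCycle],
    *,
    subject: str = "",
    condition: str = "",
) -> tuple[list[DeformationField], DeformationField]:
    """Full conversion: rigid removal, signed deformation, stance normalization.

    ``positions`` is the per-frame (n_frames, 55, 3) local-frame surface;
    returns one field per stance cycle plus their per-cell mean.
    """
    pos = np.asarray(positions, dtype=float)
    ref = np.asarray(static_reference, dtype=float)
    if not cycles:
        raise ParameterError("need at least one stance cycle")
    n_frames = pos.shape[0]
    depth = np.empty((n_frames, ref.shape[0]))
    for i in range(n_frames):
        aligned = remove_rigid_motion(ref, pos[i])
        depth[i] = depression_reformation(aligned, ref)
    fields = []
    for k, cyc in enumerate(cycles):
        norm = normalize_to_stance(depth, cyc)  # (101, 55)
        fields.append(
            DeformationField(norm.T, subject=subject, condition=condition, cycle=str(k))
        )
    mean_vals = np.mean([f.values for f in fields], axis=0)
    mean_field = DeformationField(mean_vals, subject=subject, condition=condition, cycle="mean")
    return fields, mean_field


def stance_peaks(field: DeformationField) -> tuple[float, float]:
    """(max depression, max reformation): the most negative and most positive
    cell of the field. An all-zero field returns (0, 0)."""
    return float(field.values.min()), float(field.values.max())
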