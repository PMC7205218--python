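"""Synthetic deformable-orthosis simulator.

Generates training-session (stick loading on a heel-fixed orthosis) and
walking-session (gait with whole-body rigid motion) marker data with known
ground-truth deformation, so every pipeline stage can be exercised and
checked without measured recordings.

Model. The plantar surface is a 55-point foot-shaped grid. A point load of
magnitude ``F`` (N) at footprint location ``c`` depresses point ``i`` by

    w_i = -(F / k) * exp(-d_i^2 / (2 * sigma^2)),   d_i = ||p_i - c||,

with stiffness ``k`` (N/mm) and an isotropic Gaussian spread ``sigma``
(mm) standing in for honeycomb compliance; depression is clamped to zero on
the heel cup, which is fixed to the plate. Contour triads translate with
the local deformation and tilt with the local surface slope (rotation angle
= arctan of the deformation gradient), so triad orientation carries the
information the surrogate regression needs. The "sport" orthosis is more
compliant (smaller ``k``) than the "regular" one.

Axes: Y up, X toe-ward, Z lateral (medial negative); units mm, N, radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError
from .kinematics import MarkerTrajectorySet, RigidFrame
from .regions import TRIAD_TAGS, FootprintGeometry, region_centroids
from .regions import assign_load_region as assign_region

__all__ = [
    "FoModel",
    "SyntheticScene",
    "make_fo_model",
    "simulate_point_load",
    "simulate_training_session",
    "simulate_walking_session",
    "make_calibration_series",
    "SPORT_STIFFNESS",
    "REGULAR_STIFFNESS",
]

# Default stiffnesses: the sport orthosis deforms more than the regular one.
SPORT_STIFFNESS = 5.0  # N/mm
REGULAR_STIFFNESS = 12.0  # N/mm

_BRANCH_LENGTH = 20.0  # mm, triad branch length
# Three branches at 120 degrees in the triad plane.
_BRANCH_VECTORS = _BRANCH_LENGTH * np.array(
    [
        [1.0, 0.0, 0.0],
        [-0.5, 0.0, np.sqrt(3) / 2],
        [-0.5, 0.0, -np.sqrt(3) / 2],
    ]
)

# Half-width of the foot outline at each of the 11 longitudinal rows (mm):
# narrow heel, waisted midfoot, broad forefoot.
_ROW_HALFWIDTH = np.array([28, 32, 34, 34, 33, 33, 35, 40, 44, 45, 43], dtype=float)

# Contour anchor sites (x, z) for the six triads; y raised onto the contour wall.
_TRIAD_ANCHORS_XZ = {
    "MedF": (150.0, -44.0),
    "MedM": (105.0, -36.0),
    "MedB": (60.0, -34.0),
    "Back": (2.0, 0.0),
    "LatB": (60.0, 34.0),
    "LatF": (150.0, 44.0),
}
_TRIAD_ANCHOR_HEIGHT = 15.0  # mm above the plantar surface


@dataclass
class FoModel:
    """Parametric stand-in for one instrumented foot orthosis."""

    surface_points_static: np.ndarray  # (55, 3) mm
    triad_anchors: dict[str, np.ndarray]  # tag -> (3,) anchor position
    stiffness_k: float  # N/mm, load-to-depression gain
    kernel_sigma: float  # mm, spatial spread of the depression kernel
    heel_fixed_mask: np.ndarray  # (55,) bool, True where deformation is clamped
    footprint: FootprintGeometry = field(default_factory=FootprintGeometry)
    grid_shape: tuple[int, int] = (11, 5)

    def __post_init__(self) -> None:
        self.surface_points_static = np.asarray(self.surface_points_static, dtype=float)
        if self.surface_points_static.shape != (55, 3):
            raise ParameterError("the plantar surface carries exactly 55 markers")
        if set(self.triad_anchors) != set(TRIAD_TAGS):
            raise ParameterError(f"triads must carry the tags {TRIAD_TAGS}")
        if self.stiffness_k <= 0:
            raise ParameterError("stiffness_k must be positive")
        if self.kernel_sigma <= 0:
            raise ParameterError("kernel_sigma must be positive")
        self.heel_fixed_mask = np.asarray(self.heel_fixed_mask, dtype=bool)
        if self.heel_fixed_mask.shape != (55,):
            raise ParameterError("heel_fixed_mask must cover the 55 surface points")

    # -- marker bookkeeping ------------------------------------------------
    @property
    def surface_labels(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(55)]

    @property
    def triad_labels(self) -> list[str]:
        return [f"{tag}_{j + 1}" for tag in TRIAD_TAGS for j in range(3)]

    def triad_reference_markers(self) -> np.ndarray:
        """Unloaded (reference-pose) triad marker positions, shape (18, 3)."""
        out = np.empty((18, 3))
        for t, tag in enumerate(TRIAD_TAGS):
            out[3 * t : 3 * t + 3] = self.triad_anchors[tag] + _BRANCH_VECTORS
        return out


@dataclass
class SyntheticScene:
    """One simulated recording session with its ground truth.

    ``load_force`` is the calibrated load magnitude per frame; ``load_point``
    the footprint application point (NaN when unloaded); ``load_region`` the
    region tag used to place the event (empty string when unloaded).
    ``ground_truth_deformation`` holds the signed vertical displacement of the
    55 surface points per frame, before rigid motion and noise.
    """

    fo: FoModel
    frames: MarkerTrajectorySet
    load_force: np.ndarray  # (n,)
    load_point: np.ndarray  # (n, 2)
    load_region: np.ndarray  # (n,) object
    ground_truth_deformation: np.ndarray  # (n, 55)
    stance_events: list[tuple[int, int]] | None = None
    hidden_labels: frozenset[str] = frozenset()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if np.any(self.load_force < 0):
            raise ParameterError("load magnitudes must be non-negative")
        gt = self.ground_truth_deformation
        if np.any(gt[:, self.fo.heel_fixed_mask] != 0):
            raise ParameterError("heel-fixed points must have zero deformation")
        if self.stance_events is not None:
            flat = [f for ev in self.stance_events for f in ev]
            if any(b <= a for a, b in zip(flat, flat[1:])):
                raise ParameterError("stance events must be strictly increasing")


def make_fo_model(
    stiffness_k: float = SPORT_STIFFNESS,
    kernel_sigma: float = 25.0,
    seed: int = 0,
    *,
    heel_radius: float = 45.0,
) -> FoModel:
    """Build a three-quarter-length orthosis model on a 55-point grid.

    Deterministic for a given seed (the seed currently only fixes provenance;
    the geometry itself is analytic).
    """
    if stiffness_k <= 0:
        raise ParameterError("stiffness_k must be positive")
    if kernel_sigma <= 0:
        raise ParameterError("kernel_sigma must be positive")
    footprint = FootprintGeometry()
    xs = np.linspace(5.0, 195.0, 11)
    cols = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
    pts = np.empty((55, 3))
    for i, x in enumerate(xs):
        for j, c in enumerate(cols):
            pts[i * 5 + j] = (x, 0.0, c * _ROW_HALFWIDTH[i])
    heel_center = np.array([footprint.x_back, 0.0])
    d_heel = np.linalg.norm(pts[:, [0, 2]] - heel_center, axis=1)
    anchors = {
        tag: np.array([x, _TRIAD_ANCHOR_HEIGHT, z]) for tag, (x, z) in _TRIAD_ANCHORS_XZ.items()
    }
    return FoModel(
        surface_points_static=pts,
        triad_anchors=anchors,
        stiffness_k=float(stiffness_k),
        kernel_sigma=float(kernel_sigma),
        heel_fixed_mask=d_heel <= heel_radius,
        footprint=footprint,
    )


def _kernel(fo: FoModel, xy: np.ndarray, point: np.ndarray) -> np.ndarray:
    d2 = np.sum((xy - point) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * fo.kernel_sigma**2))


def deformation_at(fo: FoModel, point: np.ndarray, force: float, xy: np.ndarray) -> np.ndarray:
    """Unclamped vertical displacement of arbitrary footprint locations."""
    return -(force / fo.stiffness_k) * _kernel(fo, np.asarray(xy, dtype=float), point)


def surface_deformation(fo: FoModel, point: np.ndarray, force: float) -> np.ndarray:
    """Clamped vertical displacement of the 55 surface points, shape (55,)."""
    w = deformation_at(fo, point, force, fo.surface_points_static[:, [0, 2]])
    w[fo.heel_fixed_mask] = 0.0
    return w


def _tilt_rotation(fo: FoModel, point: np.ndarray, force: float, xy: np.ndarray) -> np.ndarray:
    """Rotation taking the vertical onto the deformed-surface normal at ``xy``."""
    delta = np.asarray(xy, dtype=float) - point
    g = (force / fo.stiffness_k) * _kernel(fo, xy, point) / fo.kernel_sigma**2 * delta
    # Surface normal of y = w(x, z): n ~ (-dw/dx, 1, -dw/dz).
    n = np.array([-g[0], 1.0, -g[1]])
    n /= np.linalg.norm(n)
    up = np.array([0.0, 1.0, 0.0])
    axis = np.cross(up, n)
    s = np.linalg.norm(axis)
    if s < 1e-15:
        return np.eye(3)
    axis /= s
    angle = np.arctan2(s, n[1])
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _triad_markers(fo: FoModel, point: np.ndarray, force: float) -> tuple[np.ndarray, list[RigidFrame]]:
    """Deformed triad markers (18, 3) and the pose of each triad."""
    markers = np.empty((18, 3))
    poses: list[RigidFrame] = []
    for t, tag in enumerate(TRIAD_TAGS):
        anchor = fo.triad_anchors[tag]
        xy = anchor[[0, 2]]
        w = float(deformation_at(fo, point, force, xy))
        R = _tilt_rotation(fo, point, force, xy)
        origin = anchor + np.array([0.0, w, 0.0])
        markers[3 * t : 3 * t + 3] = origin + _BRANCH_VECTORS @ R.T
        poses.append(RigidFrame(R, origin))
    return markers, poses


def simulate_point_load(
    fo: FoModel, point: np.ndarray, force: float
) -> tuple[np.ndarray, np.ndarray, list[RigidFrame], np.ndarray]:
    """Deform the orthosis under a single static point load.

    Returns ``(surface_positions, triad_markers, triad_poses, deformation)``
    where ``deformation`` is the signed vertical displacement per surface
    point. Zero force reproduces the reference configuration exactly.
    """
    if force < 0:
        raise ParameterError("force must be non-negative")
    point = np.asarray(point, dtype=float)
    fp = fo.footprint
    if not (
        fp.x_back - 1e-9 <= point[0] <= fp.x_back + fp.length + 1e-9
        and abs(point[1]) <= fp.half_width + 1e-9
    ):
        raise ParameterError(f"load point {point} outside the footprint bounding box")
    w = surface_deformation(fo, point, force)
    surface = fo.surface_points_static.copy()
    surface[:, 1] += w
    markers, poses = _triad_markers(fo, point, force)
    return surface, markers, poses, w


def _stick_markers(point: np.ndarray, tilt: np.ndarray, surface_y: float) -> np.ndarray:
    """Four markers rigidly framed on the loading stick above the tip."""
    tip = np.array([point[0], surface_y, point[1]])
    local = np.array(
        [[0.0, 60.0, 0.0], [0.0, 120.0, 0.0], [25.0, 90.0, 0.0], [0.0, 90.0, 25.0]]
    )
    return tip + local @ tilt.T


STICK_LABELS = ["Stick1", "Stick2", "Stick3", "Stick4"]
# Tip position expressed in the frame built from Stick1/Stick2/Stick3
# (one-off pointing calibration of the synthetic stick; rigid, so tilt-invariant).
STICK_TIP_OFFSET = np.array([-60.0, 0.0, 0.0])


def _small_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    from .kinematics import rotation_from_cardan_yxz

    ang = np.deg2rad(rng.uniform(-max_deg, max_deg, size=3))
    return rotation_from_cardan_yxz(ang)


def _load_events(
    fo: FoModel,
    n_loads_per_region: int,
    force_range: tuple[float, float],
    rng: np.random.Generator,
) -> list[tuple[str, np.ndarray, float]]:
    """Load events spread uniformly over the footprint area.

    Points are drawn uniformly over the whole footprint until every region
    holds at least ``n_loads_per_region`` events, mirroring a protocol that
    pokes the stick all over the surface: large regions accumulate
    proportionally more events, small ones still meet their quota.
    """
    fp = fo.footprint
    quota: dict[str, list] = {tag: [] for tag in region_centroids(fp)}
    while any(len(v) < n_loads_per_region for v in quota.values()):
        pt = np.array(
            [
                rng.uniform(fp.x_back, fp.x_back + fp.length),
                rng.uniform(-fp.half_width, fp.half_width),
            ]
        )
        tag = str(assign_region(pt, fp))
        quota[tag].append((tag, pt, float(rng.uniform(*force_range))))
    return [ev for evs in quota.values() for ev in evs]


def simulate_training_session(
    fo: FoModel,
    n_loads_per_region: int = 8,
    force_range: tuple[float, float] = (0.0, 120.0),
    noise_sd: float = 0.1,
    seed: int = 0,
    *,
    frames_per_event: int = 30,
    gap_frames: int = 5,
) -> SyntheticScene:
    """Simulate stick loading over all 10 regions with interleaved unloaded frames.

    Each load event ramps the force up and down with a half-sine profile at a
    point drawn uniformly within its region; ``gap_frames`` unloaded frames
    separate events so the < 0.1 N rejection filter has work to do. Gaussian
    position noise of ``noise_sd`` mm is added to every marker.
    """
    if n_loads_per_region < 1:
        raise ParameterError("n_loads_per_region must be >= 1")
    fmin, fmax = force_range
    if not (fmax > fmin >= 0):
        raise ParameterError("force_range must satisfy Fmax > Fmin >= 0")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    events = _load_events(fo, n_loads_per_region, (fmin, fmax), rng)
    rng.shuffle(events)

    n_frames = gap_frames + len(events) * (frames_per_event + gap_frames)
    n_markers = 55 + 18 + 4
    positions = np.empty((n_frames, n_markers, 3))
    force = np.zeros(n_frames)
    load_pt = np.full((n_frames, 2), np.nan)
    region = np.full(n_frames, "", dtype=object)
    gt = np.zeros((n_frames, 55))

    ref_surface = fo.surface_points_static
    ref_triads = fo.triad_reference_markers()
    idle_stick = _stick_markers(np.array([-60.0, 0.0]), np.eye(3), 150.0)

    profile = np.sin(np.pi * (np.arange(frames_per_event) + 0.5) / frames_per_event)
    f = 0
    for _ in range(gap_frames):
        positions[f] = np.vstack([ref_surface, ref_triads, idle_stick])
        f += 1
    for tag, pt, peak in events:
        stick_tilt = _small_rotation(rng, 8.0)
        for k in range(frames_per_event):
            fk = peak * profile[k]
            surface, triads, _, w = simulate_point_load(fo, pt, fk)
            tip_y = float(deformation_at(fo, pt, fk, pt))
            stick = _stick_markers(pt, stick_tilt, tip_y)
            positions[f] = np.vstack([surface, triads, stick])
            force[f] = fk
            load_pt[f] = pt
            region[f] = tag
            gt[f] = w
            f += 1
        for _ in range(gap_frames):
            positions[f] = np.vstack([ref_surface, ref_triads, idle_stick])
            f += 1
    assert f == n_frames

    if noise_sd > 0:
        positions += rng.normal(0.0, noise_sd, size=positions.shape)

    labels = fo.surface_labels + fo.triad_labels + STICK_LABELS
    frames = MarkerTrajectorySet(labels, positions, rate=100.0)
    return SyntheticScene(
        fo=fo,
        frames=frames,
        load_force=force,
        load_point=load_pt,
        load_region=region,
        ground_truth_deformation=gt,
        rng_seed=seed,
    )


def _rigid_motion(phase: np.ndarray, amp_mm: float, amp_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Smooth whole-body rototranslation over the trial, per frame.

    Returns per-frame rotations (n, 3, 3) and translations (n, 3); the motion
    is phase-locked to the gait cycle like trunk sway and vertical bounce.
    """
    from .kinematics import rotation_from_cardan_yxz

    n = len(phase)
    trans = np.column_stack(
        [
            0.5 * amp_mm * np.sin(2 * np.pi * phase),
            amp_mm * np.sin(4 * np.pi * phase),  # double bounce per cycle
            0.3 * amp_mm * np.cos(2 * np.pi * phase),
        ]
    )
    ang = np.deg2rad(amp_deg) * np.column_stack(
        [
            np.sin(2 * np.pi * phase),
            0.5 * np.sin(4 * np.pi * phase + 0.7),
            0.5 * np.cos(2 * np.pi * phase),
        ]
    )
    rots = np.empty((n, 3, 3))
    for i in range(n):
        rots[i] = rotation_from_cardan_yxz(ang[i])
    return rots, trans


def walking_load_path(fo: FoModel, s: np.ndarray) -> np.ndarray:
    """Application point along stance progress ``s`` in [0, 1]: heel -> medial midfoot -> forefoot."""
    fp = fo.footprint
    x = fp.x_back + (0.1 + 0.75 * s) * fp.length
    z = -20.0 * np.sin(np.pi * s)  # excursion toward the medial side
    return np.column_stack([x, z])


def simulate_walking_session(
    fo: FoModel,
    n_steps: int = 10,
    cadence_frames: int = 100,
    peak_force: float = 30.0,
    rigid_motion_amplitude: tuple[float, float] = (10.0, 5.0),
    noise_sd: float = 0.1,
    seed: int = 0,
    *,
    stance_fraction: float = 0.6,
) -> SyntheticScene:
    """Simulate gait: a rolling heel-to-toe load per stance plus rigid body motion.

    During each stance phase the application point travels from the heel
    through the medial midfoot to the forefoot while the force rises and
    falls (small 8%-of-peak plateau at contact so stance is unambiguous).
    Swing frames carry zero load. The whole orthosis additionally undergoes
    a smooth rototranslation of the given (mm, deg) amplitude, and surface
    markers are flagged hidden: during walking only the contour triads are
    observable through the shoe holes.
    """
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    if peak_force < 0:
        raise ParameterError("peak_force must be non-negative")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    amp_mm, amp_deg = rigid_motion_amplitude

    stance_len = max(int(round(stance_fraction * cadence_frames)), 2)
    n_frames = n_steps * cadence_frames + cadence_frames // 4
    force = np.zeros(n_frames)
    load_pt = np.full((n_frames, 2), np.nan)
    region = np.full(n_frames, "", dtype=object)
    gt = np.zeros((n_frames, 55))
    positions = np.empty((n_frames, 55 + 18, 3))

    events: list[tuple[int, int]] = []
    for step in range(n_steps):
        hs = cadence_frames // 8 + step * cadence_frames
        to = hs + stance_len
        events.append((hs, to))
        s = (np.arange(stance_len) + 0.5) / stance_len
        pts = walking_load_path(fo, s)
        prof = peak_force * (0.08 + 0.92 * np.sin(np.pi * s))
        force[hs:to] = prof
        load_pt[hs:to] = pts

    from .regions import assign_load_region

    loaded = force > 0
    region[loaded] = assign_load_region(load_pt[loaded], fo.footprint)

    ref_surface = fo.surface_points_static
    ref_triads = fo.triad_reference_markers()
    for i in range(n_frames):
        if loaded[i]:
            surface, triads, _, w = simulate_point_load(fo, load_pt[i], force[i])
            gt[i] = w
        else:
            surface, triads = ref_surface, ref_triads
        positions[i] = np.vstack([surface, triads])

    phase = np.arange(n_frames) / cadence_frames + rng.uniform(0, 1)
    rots, trans = _rigid_motion(phase, amp_mm, amp_deg)
    positions = np.einsum("nij,nmj->nmi", rots, positions) + trans[:, None, :]

    if noise_sd > 0:
        positions += rng.normal(0.0, noise_sd, size=positions.shape)

    labels = fo.surface_labels + fo.triad_labels
    frames = MarkerTrajectorySet(labels, positions, rate=100.0)
    return SyntheticScene(
        fo=fo,
        frames=frames,
        load_force=force,
        load_point=load_pt,
        load_region=region,
        ground_truth_deformation=gt,
        stance_events=events,
        hidden_labels=frozenset(fo.surface_labels),
        rng_seed=seed,
    )


def make_calibration_series(
    gain: float = 0.31,
    offset: float = 2.0,
    noise_sd: float = 0.5,
    n_points: int = 50,
    max_force: float = 200.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic load-cell calibration data: raw readings and reference forces.

    The true sensor law is ``force = gain * raw + offset`` with Gaussian
    reading noise, mimicking a compressive dead-weight calibration session.
    """
    rng = np.random.default_rng(seed)
    forces = np.linspace(0.0, max_force, n_points)
    raw = (forces - offset) / gain + rng.normal(0.0, noise_sd, size=n_points)
    return raw, forces
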