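"""Build supervised samples from a training-session recording.

Pipeline: calibrate the load cell, reject unloaded frames (< 0.1 N), locate
each load with the instrumented stick, assign it to one of the 10 footprint
regions, assemble the 15-element triad-orientation feature vector (OT) and
the 165-element plantar-surface target vector (MPS) per retained frame, then
stratify-shuffle into an 85/15 learning/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import CalibrationError, DegenerateGeometryError, ParameterError, PipelineError
from .kinematics import (
    MarkerTrajectorySet,
    RigidFrame,
    express_in_local_frame,
    frame_from_three_markers,
    relative_cardan,
    triad_orientation,
)
from .regions import REGION_LABELS, TRIAD_TAGS, FootprintGeometry, assign_load_region
from .synthetic import SyntheticScene

__all__ = [
    "LoadRecord",
    "TrainingDataset",
    "calibrate_load_cell",
    "filter_loaded_frames",
    "stick_tip_position",
    "assign_load_region",
    "stratified_shuffle_split",
    "orientation_features",
    "session_local_frame",
    "build_dataset",
    "LOAD_THRESHOLD",
    "LOCAL_FRAME_MARKERS",
    "FEATURE_TRIADS",
    "BACK_TRIAD",
]

LOAD_THRESHOLD = 0.1  # N; frames strictly below are omitted
# Session-local frame: the first marker of the Back, MedF and LatF triads.
# The widest available triangle: the longer the baselines between the three
# frame-defining markers, the smaller the frame rotation induced by their
# own (deformation- and noise-driven) motion, and that rotation is amplified
# by the lever arm to every expressed point. The tag-to-index map of the
# physical marker set is configurable.
LOCAL_FRAME_MARKERS = ("Back_1", "MedF_1", "LatF_1")
BACK_TRIAD = "Back"
FEATURE_TRIADS = tuple(t for t in TRIAD_TAGS if t != BACK_TRIAD)  # 5 triads -> 15 angles


@dataclass
class LoadRecord:
    """Calibrated load state of one retained frame."""

    frame_index: int
    force: float  # N
    application_point: np.ndarray  # (2,) footprint mm
    region: str

    def __post_init__(self) -> None:
        if self.force < 0:
            raise ParameterError("force must be non-negative")
        if self.force >= LOAD_THRESHOLD and self.region not in REGION_LABELS:
            raise ParameterError(f"loaded frame has invalid region {self.region!r}")


@dataclass
class TrainingDataset:
    """Paired (OT, MPS) samples with per-sample load provenance and split tag."""

    features: np.ndarray  # (n, 15)
    targets: np.ndarray  # (n, 165)
    loads: list[LoadRecord]
    split_tag: np.ndarray  # (n,) 'learning' | 'test'
    seed: int | None = None
    static_targets: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != 15:
            raise ParameterError("OT feature vectors must have length 15 (3 angles x 5 triads)")
        if self.targets.ndim != 2 or self.targets.shape[1] != 165:
            raise ParameterError("MPS target vectors must have length 165 (3 coords x 55 markers)")
        if len(self.loads) != len(self.features) or len(self.split_tag) != len(self.features):
            raise ParameterError("features, targets, loads and split tags must align")

    @property
    def regions(self) -> np.ndarray:
        return np.array([rec.region for rec in self.loads], dtype=object)

    def _select(self, tag: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.split_tag == tag
        return self.features[m], self.targets[m]

    @property
    def learning(self) -> tuple[np.ndarray, np.ndarray]:
        return self._select("learning")

    @property
    def test(self) -> tuple[np.ndarray, np.ndarray]:
        return self._select("test")


def calibrate_load_cell(
    raw_readings: np.ndarray, reference_forces: np.ndarray
) -> tuple[float, float, dict]:
    """Least-squares line mapping raw load-cell readings to newtons.

    Returns ``(gain, offset, report)`` such that ``force = gain * raw + offset``;
    the report carries residual statistics and the standard error of the gain.
    """
    raw = np.asarray(raw_readings, dtype=float)
    ref = np.asarray(reference_forces, dtype=float)
    if raw.shape != ref.shape or raw.ndim != 1:
        raise CalibrationError("readings and reference forces must be equal-length vectors")
    if len(np.unique(raw)) < 2:
        raise CalibrationError("need at least 2 distinct reference points to calibrate")
    res = stats.linregress(raw, ref)
    fitted = res.slope * raw + res.intercept
    report = {
        "residual_rms": float(np.sqrt(np.mean((ref - fitted) ** 2))),
        "residual_max": float(np.max(np.abs(ref - fitted))),
        "gain_stderr": float(res.stderr) if res.stderr is not None else np.nan,
        "r_squared": float(res.rvalue**2),
        "n_points": int(len(raw)),
    }
    return float(res.slope), float(res.intercept), report


def filter_loaded_frames(load_series: np.ndarray, threshold: float = LOAD_THRESHOLD) -> np.ndarray:
    """Indices of frames whose calibrated force is at or above the threshold.

    The rejection rule omits frames *strictly below* 0.1 N, so a force of
    exactly 0.1 N is retained. Order is preserved.
    """
    forces = np.asarray(load_series, dtype=float)
    return np.nonzero(forces >= threshold)[0]


def stick_tip_position(
    stick_markers: np.ndarray,
    tip_offset: np.ndarray,
    *,
    footprint_plane_y: float | None = None,
) -> np.ndarray:
    """Extrapolate the stick tip from >= 3 visible stick markers.

    ``tip_offset`` is the tip expressed in the frame of the first three
    markers (calibrated once from a static pointing trial). When
    ``footprint_plane_y`` is given the tip is returned as the 2D (x, z)
    projection onto that horizontal plane for region assignment.
    """
    m = np.asarray(stick_markers, dtype=float)
    visible = m[np.isfinite(m).all(axis=1)]
    if len(visible) < 3:
        raise DegenerateGeometryError("stick tip unavailable: fewer than 3 visible stick markers")
    frame = frame_from_three_markers(
        visible[0], visible[1], visible[2], labels=("Stick1", "Stick2", "Stick3")
    )
    tip = frame.transform(np.asarray(tip_offset, dtype=float))
    if footprint_plane_y is None:
        return tip
    return tip[[0, 2]]


def stratified_shuffle_split(
    regions: np.ndarray, learning_fraction: float = 0.85, seed: int = 0
) -> np.ndarray:
    """Per-region shuffled learning/test split, preserving region proportions.

    Every region contributes ``round(learning_fraction * n_region)`` samples
    to the learning set (all of them, with a warning, when it has fewer than
    2 samples). Deterministic for a given seed.
    """
    if not (0 < learning_fraction < 1):
        raise ParameterError("learning_fraction must lie in (0, 1)")
    regions = np.asarray(regions, dtype=object)
    rng = np.random.default_rng(seed)
    tags = np.full(len(regions), "learning", dtype=object)
    for reg in sorted(set(regions.tolist())):
        idx = np.nonzero(regions == reg)[0]
        if len(idx) < 2:
            warnings.warn(
                f"region {reg!r} has {len(idx)} sample(s); assigning all to the learning set",
                stacklevel=2,
            )
            continue
        perm = rng.permutation(len(idx))
        n_learn = int(round(learning_fraction * len(idx)))
        n_learn = min(max(n_learn, 1), len(idx) - 1)
        tags[idx[perm[n_learn:]]] = "test"
    return tags.astype(str)


def session_local_frame(
    mts_frame: np.ndarray,
    labels: list[str],
    frame_markers: tuple[str, str, str] = LOCAL_FRAME_MARKERS,
) -> RigidFrame:
    """Local coordinate frame of one time frame from the three designated markers."""
    idx = {lb: i for i, lb in enumerate(labels)}
    try:
        p1, p2, p3 = (mts_frame[idx[lb]] for lb in frame_markers)
    except KeyError as exc:
        raise ParameterError(f"frame marker {exc} missing from trajectory set") from None
    return frame_from_three_markers(p1, p2, p3, labels=frame_markers)


def _triad_frames(
    mts_frame: np.ndarray, labels: list[str]
) -> dict[str, RigidFrame]:
    idx = {lb: i for i, lb in enumerate(labels)}
    out = {}
    for tag in TRIAD_TAGS:
        names = (f"{tag}_1", f"{tag}_2", f"{tag}_3")
        out[tag] = triad_orientation(
            *(mts_frame[idx[n]] for n in names), labels=names
        )
    return out


def orientation_features(
    mts: MarkerTrajectorySet,
    *,
    static_markers: np.ndarray | None = None,
    frame_indices: np.ndarray | None = None,
) -> np.ndarray:
    """OT feature matrix: YXZ Cardan angles of each triad relative to the back triad.

    Five triads (the back triad is the reference and never appears among the
    feature blocks) times three angles gives 15 features per frame. When the
    unloaded static marker layout is supplied, each back-relative orientation
    is additionally referenced to its static counterpart so the static pose
    maps to the zero vector; this removes the constant mounting angles.
    """
    if frame_indices is None:
        frame_indices = np.arange(mts.n_frames)
    static_rel: dict[str, np.ndarray] | None = None
    if static_markers is not None:
        sf = _triad_frames(np.asarray(static_markers, dtype=float), mts.labels)
        static_rel = {
            tag: sf[BACK_TRIAD].rotation.T @ sf[tag].rotation for tag in FEATURE_TRIADS
        }
    feats = np.empty((len(frame_indices), 15))
    from .kinematics import cardan_yxz_from_rotation

    for row, fi in enumerate(frame_indices):
        frames = _triad_frames(mts.positions[fi], mts.labels)
        back = frames[BACK_TRIAD]
        for t, tag in enumerate(FEATURE_TRIADS):
            rel = back.rotation.T @ frames[tag].rotation
            if static_rel is not None:
                rel = static_rel[tag].T @ rel
            ang = cardan_yxz_from_rotation(rel)
            feats[row, 3 * t : 3 * t + 3] = ang.as_array()
    return feats


def surface_targets(
    mts: MarkerTrajectorySet,
    surface_labels: list[str],
    *,
    frame_indices: np.ndarray | None = None,
    frame_markers: tuple[str, str, str] = LOCAL_FRAME_MARKERS,
) -> np.ndarray:
    """MPS target matrix: surface markers expressed in the session-local frame.

    55 markers times 3 coordinates gives 165 targets per frame (mm).
    """
    if frame_indices is None:
        frame_indices = np.arange(mts.n_frames)
    sidx = [mts.index(lb) for lb in surface_labels]
    out = np.empty((len(frame_indices), 3 * len(sidx)))
    for row, fi in enumerate(frame_indices):
        lf = session_local_frame(mts.positions[fi], mts.labels, frame_markers)
        out[row] = express_in_local_frame(mts.positions[fi][sidx], lf).ravel()
    return out


def build_dataset(
    scene: SyntheticScene,
    *,
    learning_fraction: float = 0.85,
    seed: int = 0,
    threshold: float = LOAD_THRESHOLD,
    geometry: FootprintGeometry | None = None,
    filter_cutoff: float | None = None,
) -> TrainingDataset:
    """Assemble the supervised dataset from a training-session scene.

    Unloaded frames are rejected, loads are regionized from the recorded
    application point, and the retained frames are stratify-shuffled into
    learning (85%) and test (15%) sets. With ``filter_cutoff`` set, marker
    trajectories are low-pass filtered (zero lag) before features and
    targets are extracted.
    """
    geometry = geometry or scene.fo.footprint
    retained = filter_loaded_frames(scene.load_force, threshold)
    if len(retained) == 0:
        raise PipelineError("no loaded frames at or above the threshold; nothing to learn from")
    frames = scene.frames
    if filter_cutoff is not None:
        from .kinematics import lowpass_filter

        frames = lowpass_filter(frames, filter_cutoff)

    static_markers = np.vstack(
        [scene.fo.surface_points_static, scene.fo.triad_reference_markers()]
    )
    # Pad to the scene's full label set if stick markers are present.
    if len(scene.frames.labels) > static_markers.shape[0]:
        pad = np.zeros((len(scene.frames.labels) - static_markers.shape[0], 3))
        static_markers = np.vstack([static_markers, pad])

    feats = orientation_features(
        frames, static_markers=static_markers, frame_indices=retained
    )
    targets = surface_targets(frames, scene.fo.surface_labels, frame_indices=retained)

    loads = []
    for fi in retained:
        pt = scene.load_point[fi]
        loads.append(
            LoadRecord(
                frame_index=int(fi),
                force=float(scene.load_force[fi]),
                application_point=pt,
                region=str(assign_load_region(pt, geometry)),
            )
        )
    regions = np.array([rec.region for rec in loads], dtype=object)
    tags = stratified_shuffle_split(regions, learning_fraction, seed)

    static_lf = session_local_frame(static_markers, scene.frames.labels)
    static_targets = express_in_local_frame(
        scene.fo.surface_points_static, static_lf
    ).ravel()
    return TrainingDataset(
        features=feats,
        targets=targets,
        loads=loads,
        split_tag=tags,
        seed=seed,
        static_targets=static_targets,
    )
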