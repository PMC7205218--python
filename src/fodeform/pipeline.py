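"""End-to-end two-session workflow on synthetic scenes.

Simulate (or ingest) a training session per orthosis condition, build the
supervised dataset, train the surrogate, validate on the held-out test set,
simulate walking per subject, predict and extract deformation fields, and
compare the two conditions with the nonparametric SPM paired test.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dataset as ds_mod
from . import deformation as def_mod
from . import fileio, spm, validation
from .exceptions import PipelineError
from .kinematics import express_in_local_frame
from .model import FINAL_CONFIG, ModelConfig, TrainedModel, predict_surface, train
from .synthetic import (
    REGULAR_STIFFNESS,
    SPORT_STIFFNESS,
    FoModel,
    SyntheticScene,
    make_fo_model,
    simulate_training_session,
    simulate_walking_session,
    surface_deformation,
)

log = logging.getLogger("fodeform")

__all__ = ["PipelineConfig", "run_pipeline", "walking_deformation", "ground_truth_field"]

CONDITIONS = ("sport", "regular")


@dataclass
class PipelineConfig:
    """Declarative configuration of a full synthetic run.

    Defaults follow the measured protocol wherever it states a value: 0.1 N
    load rejection, 85/15 stratified split, 5-fold cross-validation, and the
    selected network architecture.
    """

    seed: int = 0
    # orthosis models
    sport_stiffness: float = SPORT_STIFFNESS
    regular_stiffness: float = REGULAR_STIFFNESS
    kernel_sigma: float = 25.0
    # training session
    n_loads_per_region: int = 8
    force_range: tuple[float, float] = (0.0, 120.0)
    training_noise_sd: float = 0.1
    load_threshold: float = 0.1
    learning_fraction: float = 0.85
    filter_cutoff: float | None = 8.0  # Hz; zero-lag low-pass of marker trajectories
    # surrogate
    model: ModelConfig = field(default_factory=lambda: FINAL_CONFIG)
    # walking session
    n_subjects: int = 8
    n_steps: int = 10
    cadence_frames: int = 100
    base_peak_force: float = 30.0
    rigid_motion_amplitude: tuple[float, float] = (10.0, 5.0)
    walking_noise_sd: float = 0.1
    # statistics
    alpha: float = 0.05
    n_permutations: int = 10_000

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, default=list)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _static_markers(fo: FoModel) -> np.ndarray:
    return np.vstack([fo.surface_points_static, fo.triad_reference_markers()])


def walking_deformation(
    scene: SyntheticScene,
    model: TrainedModel,
    *,
    subject: str = "",
    condition: str = "",
    filter_cutoff: float | None = None,
) -> tuple[def_mod.DeformationField, list[def_mod.DeformationField], list[def_mod.StanceCycle]]:
    """Predict the hidden surface during walking and convert it to deformation.

    Only the contour triads are observed; OT features per frame feed the
    surrogate, the optimal rigid rototranslation versus the unloaded static
    configuration is removed, and each stance is normalized to 101 samples.
    Returns the per-subject mean field, the per-cycle fields and the cycles.
    """
    static = _static_markers(scene.fo)
    frames = scene.frames
    if filter_cutoff is not None:
        from .kinematics import lowpass_filter

        frames = lowpass_filter(frames, filter_cutoff)
    feats = ds_mod.orientation_features(frames, static_markers=static)
    pred = predict_surface(model, feats)
    ok = np.isfinite(pred).all(axis=1)
    if not ok.all():
        log.warning("skipping %d frames with NaN features", int((~ok).sum()))
    positions = pred.reshape(len(pred), 55, 3)
    cycles = def_mod.detect_stance(scene.load_force, rate=scene.frames.rate)
    if not cycles:
        raise PipelineError("no stance cycles detected in the walking load series")
    fields, mean_field = def_mod.deformation_field_from_positions(
        positions,
        scene.fo.surface_points_static,
        cycles,
        subject=subject,
        condition=condition,
    )
    return mean_field, fields, cycles


def ground_truth_field(
    scene: SyntheticScene,
    cycles: list[def_mod.StanceCycle] | None = None,
    *,
    subject: str = "",
    condition: str = "",
) -> def_mod.DeformationField:
    """The simulator's true deformation, processed identically to predictions.

    The true deformed surface (no rigid motion, no noise) goes through the
    same rigid-removal and stance-normalization steps, so the comparison with
    a predicted field measures prediction error only, not the (shared)
    rigid-fit projection of the deformation definition.
    """
    if cycles is None:
        if scene.stance_events is None:
            raise PipelineError("scene has no stance events")
        cycles = [def_mod.StanceCycle(a, b) for a, b in scene.stance_events]
    positions = np.repeat(
        scene.fo.surface_points_static[None], scene.frames.n_frames, axis=0
    ).copy()
    positions[:, :, 1] += scene.ground_truth_deformation
    _, mean_field = def_mod.deformation_field_from_positions(
        positions,
        scene.fo.surface_points_static,
        cycles,
        subject=subject,
        condition=condition,
    )
    return mean_field


def _local_vertical(fo: FoModel) -> np.ndarray:
    """Lab vertical expressed in the static session-local frame."""
    lf = ds_mod.session_local_frame(_static_markers(fo), fo.surface_labels + fo.triad_labels)
    return lf.rotation.T @ np.array([0.0, 1.0, 0.0])


def _triad_vertical_series(scene: SyntheticScene, vertical: np.ndarray) -> np.ndarray:
    """Local-frame vertical coordinate of the 18 triad markers, (n_frames, 18)."""
    labels = scene.frames.labels
    tidx = [scene.frames.index(lb) for lb in scene.fo.triad_labels]
    out = np.empty((scene.frames.n_frames, len(tidx)))
    for i in range(scene.frames.n_frames):
        lf = ds_mod.session_local_frame(scene.frames.positions[i], labels)
        local = express_in_local_frame(scene.frames.positions[i][tidx], lf)
        out[i] = local @ vertical
    return out


def _spawn_seeds(seed: int, n: int) -> list[int]:
    states = np.random.SeedSequence(seed).generate_state(n).astype(np.int64)
    return [int(s % (2**31)) for s in states]


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full workflow; returns an artifacts dictionary.

    Artifacts: per-condition datasets, trained models and validation
    reports; per-subject deformation fields (and ground truth); the SPM
    comparison; and provenance (config hash, seeds). With ``outdir`` set,
    reports and fields are also written to disk.
    """
    seeds = _spawn_seeds(config.seed, 8 + 2 * config.n_subjects)
    log.info("pipeline start, config hash %s", config.config_hash())

    stiffness = {"sport": config.sport_stiffness, "regular": config.regular_stiffness}
    artifacts: dict = {"config": config, "config_hash": config.config_hash(), "conditions": {}}

    rng_subj = np.random.default_rng(seeds[0])
    peak_forces = config.base_peak_force * rng_subj.uniform(0.85, 1.15, size=config.n_subjects)

    for ci, cond in enumerate(CONDITIONS):
        fo = make_fo_model(stiffness[cond], config.kernel_sigma, seed=seeds[1 + ci])
        scene = simulate_training_session(
            fo,
            n_loads_per_region=config.n_loads_per_region,
            force_range=config.force_range,
            noise_sd=config.training_noise_sd,
            seed=seeds[3 + ci],
        )
        dataset = ds_mod.build_dataset(
            scene,
            learning_fraction=config.learning_fraction,
            seed=seeds[5 + ci],
            threshold=config.load_threshold,
            filter_cutoff=config.filter_cutoff,
        )
        x_learn, y_learn = dataset.learning
        model = train(x_learn, y_learn, config.model)
        x_test, y_test = dataset.test
        pred_test = predict_surface(model, x_test)
        rmse_pm, rmse_summary = validation.rmse(y_test, pred_test)
        maxdef = validation.max_deformation(y_test, dataset.static_targets)
        nrmse_pm, excluded = validation.nrmse(rmse_pm, maxdef, min_deformation=0.5)
        report = validation.ValidationReport(
            rmse_per_marker=rmse_pm,
            rmse_mean=rmse_summary["mean"],
            rmse_sd=rmse_summary["sd"],
            rmse_ci95=rmse_summary["ci95"],
            nrmse_per_marker=nrmse_pm,
            max_deformation_per_marker=maxdef,
            excluded_markers=excluded,
        )
        vertical = _local_vertical(fo)
        training_vert = _triad_vertical_series(scene, vertical)
        artifacts["conditions"][cond] = {
            "fo": fo,
            "training_scene": scene,
            "dataset": dataset,
            "model": model,
            "validation": report,
            "training_triad_vertical": training_vert,
            "subjects": {},
        }
        log.info(
            "%s: test RMSE %.3f +/- %.3f mm over %d test frames",
            cond,
            report.rmse_mean,
            report.rmse_sd,
            len(x_test),
        )

    # Walking: same subjects (same peak force and cadence) wear both orthoses.
    for s in range(config.n_subjects):
        for ci, cond in enumerate(CONDITIONS):
            cond_art = artifacts["conditions"][cond]
            fo = cond_art["fo"]
            wseed = seeds[8 + 2 * s + ci]
            scene = simulate_walking_session(
                fo,
                n_steps=config.n_steps,
                cadence_frames=config.cadence_frames,
                peak_force=float(peak_forces[s]),
                rigid_motion_amplitude=config.rigid_motion_amplitude,
                noise_sd=config.walking_noise_sd,
                seed=wseed,
            )
            mean_field, cyc_fields, cycles = walking_deformation(
                scene,
                cond_art["model"],
                subject=f"S{s + 1}",
                condition=cond,
                filter_cutoff=config.filter_cutoff,
            )
            gt_field = ground_truth_field(
                scene, cycles, subject=f"S{s + 1}", condition=cond
            )
            corr = float(
                np.corrcoef(mean_field.values.ravel(), gt_field.values.ravel())[0, 1]
            )
            vertical = _local_vertical(fo)
            walk_vert = _triad_vertical_series(scene, vertical)
            cond_art["subjects"][f"S{s + 1}"] = {
                "scene": scene,
                "field": mean_field,
                "cycle_fields": cyc_fields,
                "ground_truth_field": gt_field,
                "gt_correlation": corr,
                "peaks": def_mod.stance_peaks(mean_field),
                "walking_triad_vertical": walk_vert,
            }

    # Displacement coverage: walking ranges (pooled over subjects) inside training ranges.
    for cond in CONDITIONS:
        cond_art = artifacts["conditions"][cond]
        fo = cond_art["fo"]
        t_vert = cond_art["training_triad_vertical"]
        training_ranges = {
            lb: (float(t_vert[:, j].min()), float(t_vert[:, j].max()))
            for j, lb in enumerate(fo.triad_labels)
        }
        pooled = np.vstack(
            [sub["walking_triad_vertical"] for sub in cond_art["subjects"].values()]
        )
        walking_ranges = {
            lb: (float(pooled[:, j].min()), float(pooled[:, j].max()))
            for j, lb in enumerate(fo.triad_labels)
        }
        cond_art["validation"].displacement_coverage = validation.coverage_check(
            training_ranges, walking_ranges
        )
        # Regional load coverage: peak walking force vs peak training stick force.
        t_scene = cond_art["training_scene"]
        regions = sorted(set(t_scene.load_region[t_scene.load_region != ""].tolist()))
        train_load = {
            r: (0.0, float(t_scene.load_force[t_scene.load_region == r].max()))
            for r in regions
        }
        walk_load = {}
        for r in regions:
            peaks = []
            for sub in cond_art["subjects"].values():
                w = sub["scene"]
                m = w.load_region == r
                peaks.append(float(w.load_force[m].max()) if m.any() else 0.0)
            walk_load[r] = (0.0, max(peaks))
        cond_art["validation"].load_coverage = validation.coverage_check(train_load, walk_load)

    sport_fields = [
        artifacts["conditions"]["sport"]["subjects"][f"S{s + 1}"]["field"]
        for s in range(config.n_subjects)
    ]
    regular_fields = [
        artifacts["conditions"]["regular"]["subjects"][f"S{s + 1}"]["field"]
        for s in range(config.n_subjects)
    ]
    artifacts["spm"] = spm.compare_conditions(
        sport_fields,
        regular_fields,
        alpha=config.alpha,
        n_perm=config.n_permutations,
        seed=seeds[7],
    )

    if outdir is not None:
        _write_artifacts(artifacts, Path(outdir))
    return artifacts


def _write_artifacts(artifacts: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(artifacts["config"].to_json())
    for cond, art in artifacts["conditions"].items():
        cdir = outdir / cond
        cdir.mkdir(exist_ok=True)
        rep = art["validation"]
        (cdir / "validation.json").write_text(
            json.dumps(
                {
                    "rmse_mean_mm": rep.rmse_mean,
                    "rmse_sd_mm": rep.rmse_sd,
                    "rmse_ci95_mm": rep.rmse_ci95,
                    "rmse_per_marker_mm": rep.rmse_per_marker.tolist(),
                    "nrmse_per_marker_pct": np.nan_to_num(rep.nrmse_per_marker, nan=-1).tolist(),
                    "max_deformation_per_marker_mm": rep.max_deformation_per_marker.tolist(),
                    "displacement_coverage": rep.displacement_coverage,
                    "load_coverage": rep.load_coverage,
                },
                indent=1,
            )
        )
        for name, sub in art["subjects"].items():
            fileio.write_deformation_field_csv(
                cdir / f"deformation_{name}.csv", sub["field"].values
            )
        peaks = {name: sub["peaks"] for name, sub in art["subjects"].items()}
        (cdir / "peaks.json").write_text(json.dumps(peaks, indent=1))
    res = artifacts["spm"]
    fileio.write_deformation_field_csv(outdir / "spm_t_field.csv", res.t_field)
    (outdir / "spm.json").write_text(
        json.dumps(
            {
                "threshold": res.threshold,
                "alpha": res.alpha,
                "n_permutations": res.n_permutations,
                "exhaustive": res.exhaustive,
                "clusters": [
                    {"sign": c.sign, "extent": c.extent, "max_abs_t": c.max_abs_t}
                    for c in res.clusters
                ],
            },
            indent=1,
        )
    )
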