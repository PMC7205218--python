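"""Readers and writers for the formats the two sessions use.

TRC (tab-separated marker trajectories with the standard 5-line header),
wide CSV, optional C3D (requires the ``ezc3d`` package), the three-sheet
training-workbook layout (triad positions / triad orientations / plantar
surface positions), and dataset / report serialization.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import LoadRecord, TrainingDataset
from .exceptions import DataFormatError
from .kinematics import MarkerTrajectorySet
from .synthetic import SyntheticScene

__all__ = [
    "write_trc",
    "read_trc",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "read_trajectories",
    "read_c3d",
    "export_scene",
    "import_scene_tables",
    "write_s2_excel",
    "read_s2_excel",
    "write_dataset",
    "read_dataset",
    "write_deformation_field_csv",
]


# ---------------------------------------------------------------------------
# TRC


def write_trc(path, mts: MarkerTrajectorySet, units: str = "mm") -> None:
    path = Path(path)
    n_frames, n_markers = mts.n_frames, mts.n_markers
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
            "OrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(
            f"{mts.rate:g}\t{mts.rate:g}\t{n_frames}\t{n_markers}\t{units}\t{mts.rate:g}\t1\t{n_frames}\n"
        )
        fh.write("Frame#\tTime\t" + "\t\t\t".join(mts.labels) + "\t\t\t\n")
        sub = "".join(f"X{i + 1}\tY{i + 1}\tZ{i + 1}\t" for i in range(n_markers))
        fh.write("\t\t" + sub.rstrip("\t") + "\n")
        for f in range(n_frames):
            row = mts.positions[f].ravel()
            vals = "\t".join(f"{v:.6f}" for v in row)
            fh.write(f"{f + 1}\t{f / mts.rate:.5f}\t{vals}\n")


def read_trc(path) -> MarkerTrajectorySet:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5 or not lines[0].startswith("PathFileType"):
        raise DataFormatError(f"{path} is not a TRC file (missing PathFileType header)")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    meta = dict(zip(header_keys, header_vals))
    rate = float(meta.get("DataRate", 100.0))
    units = meta.get("Units", "mm").strip().lower()
    labels = [lb for lb in lines[3].split("\t")[2:] if lb.strip()]
    if len(set(labels)) != len(labels):
        raise DataFormatError("duplicate marker labels in TRC header")
    data = []
    for ln in lines[5:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        vals = [float(v) if v.strip() else np.nan for v in parts[2 : 2 + 3 * len(labels)]]
        if len(vals) != 3 * len(labels):
            raise DataFormatError(f"TRC data row has {len(vals)} values, expected {3 * len(labels)}")
        data.append(vals)
    positions = np.asarray(data).reshape(len(data), len(labels), 3)
    if units == "m":
        positions = positions * 1000.0
    elif units not in ("mm",):
        raise DataFormatError(f"unsupported TRC units {units!r} (expected mm or m)")
    return MarkerTrajectorySet(labels, positions, rate)


# ---------------------------------------------------------------------------
# wide CSV: one row per frame, columns <label>_X/<label>_Y/<label>_Z


def write_trajectories_csv(path, mts: MarkerTrajectorySet) -> None:
    cols = [f"{lb}_{ax}" for lb in mts.labels for ax in "XYZ"]
    df = pd.DataFrame(mts.positions.reshape(mts.n_frames, -1), columns=cols)
    df.insert(0, "frame", np.arange(mts.n_frames))
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={mts.rate:g} units=mm\n")
        df.to_csv(fh, index=False)


def read_trajectories_csv(path) -> MarkerTrajectorySet:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise DataFormatError("trajectory CSV must start with a '# rate_hz=...' header row")
        meta = dict(kv.split("=") for kv in first[1:].split())
        df = pd.read_csv(fh)
    if "frame" not in df.columns:
        raise DataFormatError("trajectory CSV missing 'frame' column header")
    labels = []
    for col in df.columns:
        if col.endswith("_X"):
            labels.append(col[:-2])
    if not labels:
        raise DataFormatError("trajectory CSV contains no <label>_X/_Y/_Z columns")
    positions = np.empty((len(df), len(labels), 3))
    for j, lb in enumerate(labels):
        for k, ax in enumerate("XYZ"):
            positions[:, j, k] = df[f"{lb}_{ax}"].to_numpy()
    rate = float(meta.get("rate_hz", 100.0))
    if meta.get("units", "mm") == "m":
        positions *= 1000.0
    return MarkerTrajectorySet(labels, positions, rate)


def read_c3d(path) -> MarkerTrajectorySet:
    """Optional C3D import; requires the ezc3d package."""
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise DataFormatError(
            "C3D import requires the optional 'ezc3d' package; use TRC or CSV instead"
        ) from exc
    c3d = ezc3d.c3d(str(path))  # pragma: no cover
    labels = c3d["parameters"]["POINT"]["LABELS"]["value"]  # pragma: no cover
    pts = np.transpose(c3d["data"]["points"][:3], (2, 1, 0))  # pragma: no cover
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])  # pragma: no cover
    return MarkerTrajectorySet(list(labels), pts, rate)  # pragma: no cover


def read_trajectories(path, fmt: str | None = None) -> MarkerTrajectorySet:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"trajectory file {path} does not exist")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "trc":
        return read_trc(path)
    if fmt == "csv":
        return read_trajectories_csv(path)
    if fmt == "c3d":
        return read_c3d(path)
    raise DataFormatError(f"unsupported trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# scene export: TRC + CSV sidecars


def export_scene(scene: SyntheticScene, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"trajectories": outdir / "trajectories.trc"}
    write_trc(paths["trajectories"], scene.frames)

    loads = pd.DataFrame(
        {
            "frame": np.arange(len(scene.load_force)),
            "force_n": scene.load_force,
            "point_x_mm": scene.load_point[:, 0],
            "point_z_mm": scene.load_point[:, 1],
            "region": scene.load_region,
        }
    )
    paths["loads"] = outdir / "loads.csv"
    loads.to_csv(paths["loads"], index=False)

    gt = pd.DataFrame(
        scene.ground_truth_deformation, columns=scene.fo.surface_labels
    )
    gt.insert(0, "frame", np.arange(len(gt)))
    paths["ground_truth"] = outdir / "ground_truth_deformation.csv"
    gt.to_csv(paths["ground_truth"], index=False)

    meta = {
        "rng_seed": scene.rng_seed,
        "stiffness_k": scene.fo.stiffness_k,
        "kernel_sigma": scene.fo.kernel_sigma,
        "hidden_labels": sorted(scene.hidden_labels),
        "stance_events": scene.stance_events,
    }
    paths["meta"] = outdir / "scene.json"
    paths["meta"].write_text(json.dumps(meta, indent=1))
    return paths


def import_scene_tables(outdir) -> dict:
    """Round-trip loader for an exported scene (tables, not a full FoModel)."""
    outdir = Path(outdir)
    mts = read_trc(outdir / "trajectories.trc")
    loads = pd.read_csv(outdir / "loads.csv")
    gt = pd.read_csv(outdir / "ground_truth_deformation.csv")
    meta = json.loads((outdir / "scene.json").read_text())
    return {
        "frames": mts,
        "loads": loads,
        "ground_truth": gt.drop(columns="frame").to_numpy(),
        "meta": meta,
    }


# ---------------------------------------------------------------------------
# three-sheet training workbook (triad positions / orientations / surface)


def write_s2_excel(
    path,
    triad_positions: pd.DataFrame,
    triad_orientations: pd.DataFrame,
    surface_positions: pd.DataFrame,
) -> None:
    with pd.ExcelWriter(path, engine="openpyxl") as xw:
        triad_positions.to_excel(xw, sheet_name="triad_positions", index=False)
        triad_orientations.to_excel(xw, sheet_name="triad_orientations", index=False)
        surface_positions.to_excel(xw, sheet_name="surface_positions", index=False)


def read_s2_excel(path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read the training-session workbook: three frame-aligned sheets.

    Sheet order is positional (triad marker positions, triad orientations,
    plantar-surface marker positions); column names are tolerated as-is.
    """
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"workbook {path} does not exist")
    sheets = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    if len(sheets) != 3:
        raise DataFormatError(
            f"expected 3 sheets (triad positions, triad orientations, surface positions); "
            f"found {list(sheets)}"
        )
    tri_pos, tri_ori, surf = sheets.values()
    n = {len(tri_pos), len(tri_ori), len(surf)}
    if len(n) != 1:
        raise DataFormatError(
            f"sheets disagree on frame count: {[len(s) for s in sheets.values()]}"
        )
    return tri_pos, tri_ori, surf


# ---------------------------------------------------------------------------
# dataset + report serialization


def write_dataset(ds: TrainingDataset, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": outdir / "features.csv",
        "targets": outdir / "targets.csv",
        "sidecar": outdir / "dataset.json",
    }
    pd.DataFrame(ds.features).to_csv(paths["features"], index=False)
    pd.DataFrame(ds.targets).to_csv(paths["targets"], index=False)
    sidecar = {
        "seed": ds.seed,
        "split_tag": ds.split_tag.tolist(),
        "loads": [
            {
                "frame_index": rec.frame_index,
                "force": rec.force,
                "application_point": np.asarray(rec.application_point, dtype=float).tolist(),
                "region": rec.region,
            }
            for rec in ds.loads
        ],
    }
    paths["sidecar"].write_text(json.dumps(sidecar))
    return paths


def read_dataset(outdir) -> TrainingDataset:
    outdir = Path(outdir)
    features = pd.read_csv(outdir / "features.csv").to_numpy()
    targets = pd.read_csv(outdir / "targets.csv").to_numpy()
    sidecar = json.loads((outdir / "dataset.json").read_text())
    loads = [
        LoadRecord(
            frame_index=rec["frame_index"],
            force=rec["force"],
            application_point=np.asarray(rec["application_point"]),
            region=rec["region"],
        )
        for rec in sidecar["loads"]
    ]
    return TrainingDataset(
        features=features,
        targets=targets,
        loads=loads,
        split_tag=np.asarray(sidecar["split_tag"], dtype=object).astype(str),
        seed=sidecar["seed"],
    )


def write_deformation_field_csv(path, values: np.ndarray) -> None:
    """One CSV per subject/condition: rows = 55 points, columns = 101 stance samples."""
    df = pd.DataFrame(
        np.asarray(values, dtype=float),
        columns=[f"stance_{p:03d}" for p in range(np.asarray(values).shape[1])],
    )
    df.insert(0, "point", [f"S{i + 1:02d}" for i in range(len(df))])
    df.to_csv(path, index=False)
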