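"""Model-quality metrics and training-vs-walking coverage checks.

Two complementary validations: (1) generalization error of the surrogate on
the held-out test set — per-marker RMSE between measured and predicted
positions, and NRMSE normalized to each marker's maximal deformation; (2) a
coverage check that the training session brackets the walking session, both
in triad vertical displacement (per triad marker) and in regional peak load
(peak pressure times sensor area vs. the stick force).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "ValidationReport",
    "rmse",
    "max_deformation",
    "nrmse",
    "displacement_range",
    "coverage_check",
    "peak_force_from_pressure",
]


@dataclass
class ValidationReport:
    rmse_per_marker: np.ndarray  # (55,) mm
    rmse_mean: float
    rmse_sd: float
    rmse_ci95: tuple[float, float]
    nrmse_per_marker: np.ndarray  # (55,) %, NaN where excluded
    max_deformation_per_marker: np.ndarray  # (55,) mm
    excluded_markers: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    displacement_coverage: dict | None = None
    load_coverage: dict | None = None


def _as_marker_series(arr: np.ndarray) -> np.ndarray:
    """Coerce (n_frames, 165) flat MPS vectors to (n_frames, 55, 3)."""
    a = np.asarray(arr, dtype=float)
    if a.ndim == 2 and a.shape[1] % 3 == 0:
        return a.reshape(a.shape[0], -1, 3)
    if a.ndim == 3 and a.shape[2] == 3:
        return a
    raise ParameterError(f"expected (n, 3m) or (n, m, 3) positions, got shape {a.shape}")


def rmse(measured: np.ndarray, predicted: np.ndarray) -> tuple[np.ndarray, dict]:
    """Per-marker RMSE (mm) between measured and predicted positions.

    Uses the 3D Euclidean convention: for each marker, the root of the mean
    squared 3D distance over frames. The summary gives mean +/- sd over the
    markers with a normal-theory 95% confidence interval for the mean.
    """
    m = _as_marker_series(measured)
    p = _as_marker_series(predicted)
    if m.shape != p.shape:
        raise ParameterError(f"shape mismatch: measured {m.shape} vs predicted {p.shape}")
    sq = np.sum((m - p) ** 2, axis=2)  # squared 3D distance per frame per marker
    per_marker = np.sqrt(np.mean(sq, axis=0))
    n_markers = per_marker.size
    mean = float(per_marker.mean())
    sd = float(per_marker.std(ddof=1)) if n_markers > 1 else 0.0
    half = 1.96 * sd / np.sqrt(n_markers)
    summary = {
        "mean": mean,
        "sd": sd,
        "ci95": (mean - half, mean + half),
        "n_markers": n_markers,
    }
    return per_marker, summary


def max_deformation(positions: np.ndarray, static_reference: np.ndarray) -> np.ndarray:
    """Per-marker maximal deformation: max over frames of the Euclidean
    distance to the unloaded static position (mm)."""
    pos = _as_marker_series(positions)
    ref = np.asarray(static_reference, dtype=float)
    if ref.ndim == 1:
        ref = ref.reshape(-1, 3)
    if ref.shape != pos.shape[1:]:
        raise ParameterError(f"static reference shape {ref.shape} does not match {pos.shape[1:]}")
    dist = np.linalg.norm(pos - ref[None], axis=2)
    return dist.max(axis=0)


def nrmse(
    rmse_per_marker: np.ndarray,
    max_deformation_per_marker: np.ndarray,
    *,
    min_deformation: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """NRMSE per marker as a percentage: 100 * rmse / max deformation.

    Markers whose maximal deformation is (numerically) zero cannot be
    normalized — typically the clamped heel-cup points — and are returned as
    NaN along with their indices.
    """
    r = np.asarray(rmse_per_marker, dtype=float)
    d = np.asarray(max_deformation_per_marker, dtype=float)
    if r.shape != d.shape:
        raise ParameterError("rmse and max-deformation vectors must align")
    out = np.full_like(r, np.nan)
    ok = d > min_deformation
    out[ok] = 100.0 * r[ok] / d[ok]
    return out, np.nonzero(~ok)[0]


def displacement_range(vertical_series: np.ndarray) -> np.ndarray:
    """Range (max - min, mm) of the vertical coordinate per triad marker.

    Input is the local-frame vertical (Y) series, shape ``(n_frames,)`` or
    ``(n_frames, n_markers)``; vertical displacement is the dominant,
    biomechanically meaningful component of triad motion.
    """
    s = np.asarray(vertical_series, dtype=float)
    return s.max(axis=0) - s.min(axis=0)


def coverage_check(
    training_ranges: dict[str, tuple[float, float]],
    walking_ranges: dict[str, tuple[float, float]],
) -> dict:
    """Check, item by item, that the walking interval lies inside the training one.

    Items are triad-marker labels (displacement check) or region labels (load
    check). Returns per-item booleans plus the violation margins; accurate
    walking-session predictions can only be expected where coverage holds.
    """
    if set(training_ranges) != set(walking_ranges):
        raise ParameterError("training and walking ranges must cover the same items")
    covered: dict[str, bool] = {}
    violations: dict[str, float] = {}
    for item in training_ranges:
        t_lo, t_hi = training_ranges[item]
        w_lo, w_hi = walking_ranges[item]
        ok = (w_lo >= t_lo) and (w_hi <= t_hi)
        covered[item] = bool(ok)
        if not ok:
            violations[item] = float(max(t_lo - w_lo, 0.0) + max(w_hi - t_hi, 0.0))
    return {
        "covered": covered,
        "all_covered": all(covered.values()),
        "violations": violations,
    }


def peak_force_from_pressure(peak_pressure: float, sensor_area: float) -> float:
    """Peak regional force (N) as peak pressure (Pa) times sensor area (m^2)."""
    if sensor_area <= 0:
        raise ParameterError("sensor area must be positive")
    if peak_pressure < 0:
        raise ParameterError("pressure must be non-negative")
    return float(peak_pressure * sensor_area)
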