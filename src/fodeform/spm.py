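"""Nonparametric statistical parametric mapping over deformation fields.

Paired comparison of two orthosis conditions across subjects over the whole
(surface point x stance time) domain: a paired t-statistic per cell, a
family-wise critical value from the sign-flip permutation distribution of
the field-wide maximum |t| (exhaustive enumeration of all 2^n flips when
feasible), and connected supra-threshold clusters on the surface-grid x
time lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .deformation import DeformationField
from .exceptions import ParameterError

__all__ = [
    "SpmResult",
    "Cluster",
    "paired_t_field",
    "permutation_threshold",
    "significant_clusters",
    "compare_conditions",
]

EXHAUSTIVE_LIMIT = 10_000  # enumerate all 2^n sign flips when 2^n <= this
SURFACE_GRID = (11, 5)  # the 55 surface points form an 11 x 5 foot-shaped grid


@dataclass
class Cluster:
    sign: int  # +1: condition A larger, -1: condition B larger
    extent: int  # number of cells
    max_abs_t: float
    cells: np.ndarray = field(repr=False)  # (extent, 2) indices into (point, time)


@dataclass
class SpmResult:
    t_field: np.ndarray
    threshold: float
    significant_mask: np.ndarray
    clusters: list[Cluster]
    n_permutations: int
    alpha: float
    exhaustive: bool


def _t_statistic(diffs: np.ndarray) -> np.ndarray:
    """Paired t over axis 0; 0/0 cells are defined as t = 0, x/0 as +/-inf."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where((sd == 0) & (mean == 0), 0.0, t)
        t = np.where((sd == 0) & (mean != 0), np.sign(mean) * np.inf, t)
    return t


def _stack_fields(fields: list[DeformationField] | np.ndarray) -> np.ndarray:
    if isinstance(fields, np.ndarray):
        return np.asarray(fields, dtype=float)
    return np.stack([f.values for f in fields])


def paired_t_field(
    a_fields: list[DeformationField] | np.ndarray,
    b_fields: list[DeformationField] | np.ndarray,
) -> np.ndarray:
    """Per-cell paired t-statistic of condition A minus condition B.

    Inputs are matched per-subject fields (same subject order in both lists).
    Zero-variance cells follow the 0/0 -> 0, x/0 -> +/-inf convention, the
    latter flagged by the infinity itself.
    """
    a = _stack_fields(a_fields)
    b = _stack_fields(b_fields)
    if a.shape != b.shape:
        raise ParameterError("condition A and B field stacks must have matching shapes")
    if a.shape[0] < 2:
        raise ParameterError("paired t-test needs at least 2 subjects")
    return _t_statistic(a - b)


def _max_abs_t_for_signs(diffs_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """max |t| over cells for each sign-flip assignment (vectorized).

    Sign flips leave each cell's mean of squares unchanged, so only the
    flipped mean needs recomputing; and with q = mean^2 / meansq the paired
    t satisfies t^2 = (n-1) q / (1 - q), a monotone map, so the field-wide
    max |t| is recovered from the field-wide max of q.
    """
    n = diffs_flat.shape[0]
    meansq = np.mean(diffs_flat**2, axis=0)  # (cells,) -- invariant under flips
    inv_meansq = np.zeros_like(meansq)
    np.divide(1.0, meansq, out=inv_meansq, where=meansq > 0)  # all-zero cells -> t = 0
    out = np.empty(len(signs))
    chunk = max(1, int(4e7 // max(diffs_flat.shape[1], 1)))
    for start in range(0, len(signs), chunk):
        S = signs[start : start + chunk]
        mean = (S @ diffs_flat) / n  # (chunk, cells)
        np.square(mean, out=mean)
        mean *= inv_meansq[None]
        qmax = np.max(mean, axis=1)
        with np.errstate(divide="ignore"):
            out[start : start + chunk] = np.sqrt((n - 1) * qmax / (1.0 - qmax))
    return out


def permutation_threshold(
    diffs: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, dict]:
    """Family-wise critical value from the sign-flip max-statistic distribution.

    For each permutation the per-subject difference fields are sign-flipped
    and the maximum |t| over all cells recorded; the threshold is the
    (1 - alpha) empirical quantile (ceil order statistic) of that
    distribution. All 2^n assignments are enumerated when 2^n <= 10,000
    (13 subjects -> 8,192, exhaustive and seed-independent); otherwise
    ``n_perm`` random flips are drawn.
    """
    if not (0 < alpha < 1):
        raise ParameterError("alpha must lie strictly between 0 and 1")
    d = np.asarray(diffs, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 subjects")
    flat = d.reshape(n, -1)
    if 2**n <= EXHAUSTIVE_LIMIT:
        # |t| is invariant under a global sign change, so the 2^n assignments
        # pair up; enumerating the 2^(n-1) representatives with the first
        # subject fixed at +1 yields the identical max-|t| distribution.
        total = 2**n
        half = 2 ** (n - 1)
        bits = (np.arange(half)[:, None] >> np.arange(n - 1)[None, :]) & 1
        signs = np.hstack([np.ones((half, 1)), 1.0 - 2.0 * bits])
        quantile_n = half
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        signs[0] = 1.0  # always include the identity assignment
        total = quantile_n = n_perm
        exhaustive = False
    maxima = _max_abs_t_for_signs(flat, signs)
    order = np.sort(maxima)
    k = int(np.ceil((1.0 - alpha) * quantile_n)) - 1
    threshold = float(order[min(k, quantile_n - 1)])
    info = {"n_permutations": int(total), "exhaustive": exhaustive, "maxima": maxima}
    return threshold, info


def significant_clusters(
    t_field: np.ndarray,
    threshold: float,
    *,
    grid_shape: tuple[int, int] = SURFACE_GRID,
) -> list[Cluster]:
    """Connected supra-threshold components of |t| on the (point-grid x time) lattice.

    The 55 surface points are unfolded onto their spatial grid so adjacency
    is 4-connected in space plus the two time neighbours (face connectivity
    on the 3D (rows, cols, time) lattice). Positive and negative excursions
    form separate clusters.
    """
    t = np.asarray(t_field, dtype=float)
    n_points, n_time = t.shape
    rows, cols = grid_shape
    if rows * cols != n_points:
        raise ParameterError(f"grid {grid_shape} does not tile {n_points} points")
    cube = t.reshape(rows, cols, n_time)
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = (sign * cube) > threshold
        labeled, n_comp = ndimage.label(mask)  # face connectivity by default
        for comp in range(1, n_comp + 1):
            rr, cc, tt = np.nonzero(labeled == comp)
            cells = np.column_stack([rr * cols + cc, tt])
            vals = np.abs(cube[rr, cc, tt])
            clusters.append(
                Cluster(sign=sign, extent=len(cells), max_abs_t=float(vals.max()), cells=cells)
            )
    clusters.sort(key=lambda c: -c.extent)
    return clusters


def compare_conditions(
    a_fields: list[DeformationField] | np.ndarray,
    b_fields: list[DeformationField] | np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    *,
    grid_shape: tuple[int, int] = SURFACE_GRID,
) -> SpmResult:
    """Full nonparametric paired comparison of two conditions.

    Two-tailed at the given alpha with max-statistic family-wise control;
    cells with |t| above the permutation threshold are significant.
    """
    a = _stack_fields(a_fields)
    b = _stack_fields(b_fields)
    t = paired_t_field(a, b)
    threshold, info = permutation_threshold(a - b, alpha=alpha, n_perm=n_perm, seed=seed)
    mask = np.abs(t) > threshold
    clusters = significant_clusters(t, threshold, grid_shape=grid_shape)
    return SpmResult(
        t_field=t,
        threshold=threshold,
        significant_mask=mask,
        clusters=clusters,
        n_permutations=info["n_permutations"],
        alpha=alpha,
        exhaustive=info["exhaustive"],
    )
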