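"""Footprint geometry and the 10-region load-application partition.

The orthosis plantar surface is divided into ten regions for stratifying
load events: a ring of nine boundary cells — medial front/middle/back,
lateral front/middle/back, and a back band split into back-medial, back
(central) and back-lateral — around a central "Mid" cell. Region boundaries
are expressed in normalized footprint coordinates so the partition scales
with any footprint geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError

REGION_LABELS = (
    "MedF",
    "MedM",
    "MedB",
    "BackMed",
    "Back",
    "BackLat",
    "LatB",
    "LatM",
    "LatF",
    "Mid",
)

TRIAD_TAGS = ("MedF", "MedM", "MedB", "Back", "LatB", "LatF")


@dataclass(frozen=True)
class FootprintGeometry:
    """Axis-aligned description of the orthosis footprint.

    ``length`` runs toe-ward along X from ``x_back``; ``half_width`` is the
    maximal medio-lateral extent (medial = negative Z). The fractional
    parameters position the internal region boundaries.
    """

    length: float = 200.0
    half_width: float = 45.0
    x_back: float = 0.0
    back_fraction: float = 0.25  # longitudinal extent of the Back* band
    central_halfwidth: float = 1 / 3  # |v| below this is the central column
    side_splits: tuple[float, float] = (0.5, 0.75)  # back/middle/front cut on the sides

    def __post_init__(self) -> None:
        if self.length <= 0 or self.half_width <= 0:
            raise ParameterError("footprint length and half_width must be positive")

    def normalized(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map footprint (x, z) mm to (u, v): u in [0,1] back->front, v in [-1,1] medial->lateral."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        u = (xy[:, 0] - self.x_back) / self.length
        v = xy[:, 1] / self.half_width
        return u, v

    def contains(self, xy: np.ndarray) -> np.ndarray:
        u, v = self.normalized(xy)
        return (u >= 0) & (u <= 1) & (np.abs(v) <= 1)


def assign_load_region(xy: np.ndarray, geometry: FootprintGeometry | None = None) -> np.ndarray:
    """Assign each 2D load point to one of the 10 region labels.

    Points outside the footprint fall back to the nearest region centroid.
    Vectorized; a single point returns a scalar numpy string.
    """
    geometry = geometry or FootprintGeometry()
    pts = np.atleast_2d(np.asarray(xy, dtype=float))
    u, v = geometry.normalized(pts)
    labels = np.empty(len(pts), dtype=object)

    s1, s2 = geometry.side_splits
    back = u < geometry.back_fraction
    central = np.abs(v) <= geometry.central_halfwidth
    medial = v < 0

    labels[back & medial & ~central] = "BackMed"
    labels[back & central] = "Back"
    labels[back & ~medial & ~central] = "BackLat"
    side_b = ~back & (u < s1)
    side_m = (u >= s1) & (u < s2)
    side_f = u >= s2
    labels[~back & central] = "Mid"
    labels[side_b & medial & ~central] = "MedB"
    labels[side_m & medial & ~central] = "MedM"
    labels[side_f & medial & ~central] = "MedF"
    labels[side_b & ~medial & ~central] = "LatB"
    labels[side_m & ~medial & ~central] = "LatM"
    labels[side_f & ~medial & ~central] = "LatF"

    outside = ~geometry.contains(pts)
    if outside.any():
        cent = region_centroids(geometry)
        names = list(cent.keys())
        carr = np.array([cent[k] for k in names])
        for i in np.nonzero(outside)[0]:
            d = np.linalg.norm(carr - pts[i], axis=1)
            labels[i] = names[int(np.argmin(d))]
    if np.asarray(xy).ndim == 1:
        return labels[0]
    return labels


def region_centroids(geometry: FootprintGeometry | None = None) -> dict[str, np.ndarray]:
    """Centroid (x, z) of each region cell, computed on a fine footprint grid."""
    geometry = geometry or FootprintGeometry()
    xs = np.linspace(geometry.x_back, geometry.x_back + geometry.length, 121)
    zs = np.linspace(-geometry.half_width, geometry.half_width, 61)
    gx, gz = np.meshgrid(xs, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gz.ravel()])
    # Interior points only, so centroids never sit on a cell boundary.
    eps = 1e-6
    inside = (
        (pts[:, 0] > geometry.x_back + eps)
        & (pts[:, 0] < geometry.x_back + geometry.length - eps)
        & (np.abs(pts[:, 1]) < geometry.half_width - eps)
    )
    pts = pts[inside]
    labels = assign_load_region(pts, geometry)
    out: dict[str, np.ndarray] = {}
    for name in REGION_LABELS:
        mask = labels == name
        if not mask.any():
            raise ParameterError(f"region {name} is empty under this footprint geometry")
        out[name] = pts[mask].mean(axis=0)
    return out
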