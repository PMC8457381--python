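"""Planimetric aortic valve area from leaflet orifice contours.

The anatomic valve area is measured from a stack of closed 3D contours, one
per slice parallel to the aortic annulus, each tracing the orifice boundary
on the leaflet tips.  Every contour is orthogonally projected onto the
annulus plane and the AVA is the minimum of the projected areas over all
slices.  Geometry coordinates are in mm; areas are reported in cm^2, the
unit the pressure model expects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon

from .errors import GeometryError, ValidationError
from .units import mm2_to_cm2

__all__ = [
    "ValveGeometry",
    "OrificeArea",
    "projected_area",
    "minimal_orifice_area",
]


def _as_unit(vec: Sequence[float]) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    if v.shape != (3,):
        raise ValidationError(f"expected a 3-vector, got shape {v.shape}")
    norm = np.linalg.norm(v)
    if norm == 0 or not np.isfinite(norm):
        raise ValidationError("normal vector must be non-zero and finite")
    return v / norm


@dataclass(frozen=True)
class ValveGeometry:
    """Annulus plane plus per-slice orifice contours (all coordinates mm).

    ``contours`` is an ordered list of (n, 3) vertex arrays; each polygon is
    implicitly closed (last vertex joins the first).
    """

    annulus_point: np.ndarray
    annulus_normal: np.ndarray
    contours: tuple

    def __post_init__(self) -> None:
        point = np.asarray(self.annulus_point, dtype=float)
        if point.shape != (3,):
            raise ValidationError("annulus_point must be a 3-vector")
        normal = _as_unit(self.annulus_normal)
        contours = tuple(np.asarray(c, dtype=float) for c in self.contours)
        for i, c in enumerate(contours):
            if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 3:
                raise ValidationError(
                    f"contour {i} must be an (n>=3, 3) vertex array, got shape {c.shape}"
                )
        object.__setattr__(self, "annulus_point", point)
        object.__setattr__(self, "annulus_normal", normal)
        object.__setattr__(self, "contours", contours)


@dataclass(frozen=True)
class OrificeArea:
    """Minimal projected orifice area with the slice it was found on."""

    area_cm2: float
    slice_index: int
    slice_areas_cm2: tuple


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis (u, v) for the plane with the given normal."""
    # pick the world axis least aligned with the normal to avoid degeneracy
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(normal)))] = 1.0
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def projected_area(contour: np.ndarray, normal: Sequence[float]) -> float:
    """Area (cm^2) of a closed 3D polygon projected along ``normal``.

    Vertices are expressed in an orthonormal in-plane basis of the
    projection plane and the enclosed area is the absolute shoelace area,
    so the winding direction of the contour does not matter.  Degenerate
    contours (fewer than 3 distinct vertices, collinear, or
    self-intersecting) raise :class:`GeometryError`.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"contour must be an (n, 3) array, got shape {pts.shape}")
    distinct = np.unique(np.round(pts, 9), axis=0)
    if distinct.shape[0] < 3:
        raise GeometryError("contour has fewer than 3 distinct vertices")
    n = _as_unit(normal)
    u, v = _plane_basis(n)
    planar = np.column_stack([pts @ u, pts @ v])
    poly = Polygon(planar)
    if not poly.is_valid:
        raise GeometryError("contour is self-intersecting after projection")
    area_mm2 = poly.area
    if area_mm2 <= 0:
        raise GeometryError("contour is degenerate (zero projected area)")
    return mm2_to_cm2(area_mm2)


def minimal_orifice_area(geom: ValveGeometry) -> OrificeArea:
    """AVA (cm^2): minimum projected contour area over all slices.

    Every slice contour is projected along the annulus normal; the reported
    result records which slice attained the minimum (earliest on ties).
    """
    if len(geom.contours) == 0:
        raise GeometryError("valve geometry contains no contours")
    areas = tuple(projected_area(c, geom.annulus_normal) for c in geom.contours)
    idx = int(np.argmin(areas))
    return OrificeArea(area_cm2=areas[idx], slice_index=idx, slice_areas_cm2=areas)
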