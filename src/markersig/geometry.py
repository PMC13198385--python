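"""Lasso selection on 2D/3D embeddings, selection algebra, axis picking.

A lasso is an implicitly closed polygon drawn in view coordinates.  Points
are tested with even-odd ray casting plus an explicit on-segment test, so
boundary points deterministically count as inside.  3D lassos use an
orthographic camera model: points are rotated by an orthonormal view
matrix, the first two view coordinates are tested against the polygon and
depth is ignored — a 3D lasso therefore behaves exactly like a 2D lasso on
the rotated coordinates.  Self-intersecting lassos follow even-odd
semantics and are not repaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SampleSelection, ValidationError

_ON_SEGMENT_TOL = 1e-12


@dataclass
class LassoPolygon:
    """Implicitly closed planar polygon with >= 3 vertices and non-zero area."""

    vertices: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("polygon vertices must be an (m, 2) array")
        if self.vertices.shape[0] < 3:
            raise ValidationError("polygon needs at least 3 vertices")
        if abs(self.signed_area) == 0.0:
            raise ValidationError("degenerate polygon (zero area)")

    @property
    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class ViewProjection:
    """Orthonormal 3x3 rotation from embedding to view coordinates.

    The view plane is spanned by the first two rows; the third row is the
    (discarded) depth axis.
    """

    rotation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        if self.rotation.shape != (3, 3):
            raise ValidationError("view rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValidationError("view rotation is not orthonormal (R R^T != I)")

    @classmethod
    def identity(cls) -> "ViewProjection":
        return cls(np.eye(3))


def _points_in_polygon(points: np.ndarray, polygon: LassoPolygon) -> np.ndarray:
    """Vectorized even-odd test; boundary points count as inside."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    v0 = polygon.vertices
    v1 = np.roll(v0, -1, axis=0)

    px = pts[:, 0][:, None]
    py = pts[:, 1][:, None]
    x0, y0 = v0[:, 0][None, :], v0[:, 1][None, :]
    x1, y1 = v1[:, 0][None, :], v1[:, 1][None, :]

    # on-segment: zero cross product and within the bounding box of the edge
    cross = (x1 - x0) * (py - y0) - (y1 - y0) * (px - x0)
    scale = np.hypot(x1 - x0, y1 - y0)
    on_edge = (np.abs(cross) <= _ON_SEGMENT_TOL * np.maximum(scale, 1.0)) & \
        (px >= np.minimum(x0, x1) - _ON_SEGMENT_TOL) & (px <= np.maximum(x0, x1) + _ON_SEGMENT_TOL) & \
        (py >= np.minimum(y0, y1) - _ON_SEGMENT_TOL) & (py <= np.maximum(y0, y1) + _ON_SEGMENT_TOL)
    on_boundary = on_edge.any(axis=1)

    # even-odd ray casting: horizontal ray towards +x; half-open vertex rule
    crosses = ((y0 > py) != (y1 > py)) & \
        (px < x0 + (py - y0) * (x1 - x0) / np.where(y1 == y0, np.inf, y1 - y0))
    inside = crosses.sum(axis=1) % 2 == 1
    return inside | on_boundary


def point_in_polygon(point, polygon: LassoPolygon) -> bool:
    """True iff the point is inside the polygon or on its boundary."""
    return bool(_points_in_polygon(np.asarray(point, dtype=np.float64)[None, :], polygon)[0])


def lasso_select_2d(embedding: np.ndarray, polygon: LassoPolygon,
                    axes: tuple[int, int] = (0, 1)) -> SampleSelection:
    """Select the samples whose 2D embedding coordinates fall in the lasso."""
    emb = np.asarray(embedding, dtype=np.float64)
    if emb.ndim != 2 or emb.shape[1] < 2:
        raise ValidationError("embedding must be an (n, >=2) array")
    pts = pick_axes(emb, axes) if axes != (0, 1) else emb[:, :2]
    return SampleSelection(_points_in_polygon(pts, polygon), provenance="lasso")


def lasso_select_3d(embedding: np.ndarray, view: ViewProjection,
                    polygon: LassoPolygon) -> SampleSelection:
    """Orthographic 3D lasso: rotate by the view, test (x, y), ignore depth."""
    emb = np.asarray(embedding, dtype=np.float64)
    if emb.ndim != 2 or emb.shape[1] != 3:
        raise ValidationError("3D lasso needs an (n, 3) embedding")
    projected = emb @ view.rotation.T
    return SampleSelection(_points_in_polygon(projected[:, :2], polygon), provenance="lasso3d")


def combine_selections(a: SampleSelection, b: SampleSelection, op: str) -> SampleSelection:
    """Element-wise selection algebra: union, intersection, or difference
    (``difference`` is a AND NOT b)."""
    if a.mask.shape != b.mask.shape:
        raise ValidationError("selection masks have different lengths")
    if op == "union":
        mask = a.mask | b.mask
    elif op == "intersection":
        mask = a.mask & b.mask
    elif op == "difference":
        mask = a.mask & ~b.mask
    else:
        raise ValueError(f"unknown set operation {op!r}")
    return SampleSelection(mask, provenance=f"({a.provenance}) {op} ({b.provenance})")


def pick_axes(embedding: np.ndarray, axes) -> np.ndarray:
    """Column subset of an embedding, in the requested axis order."""
    emb = np.asarray(embedding, dtype=np.float64)
    axes = tuple(int(a) for a in axes)
    if len(axes) not in (2, 3):
        raise ValueError("pick 2 or 3 axes")
    if len(set(axes)) != len(axes):
        raise ValueError(f"repeated axis in {axes}")
    d = emb.shape[1]
    for a in axes:
        if not 0 <= a < d:
            raise ValueError(f"axis {a} out of range for embedding of dimension {d}")
    return emb[:, list(axes)]
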