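"""Open-contour geometry: target unit vector fields, endpoint heatmaps,
field-walking contour extraction, and contour error metrics.

Coordinate convention (used everywhere in this package): 0-based,
``x`` = column, ``y`` = row, ``y`` increases downward, pixel centres at
integer coordinates.  A contour is an ordered open polyline of vertices
with a side tag (``left``/``right`` sacroiliac joint).

The target unit vector field (UVF) of a contour points, at every off-contour
pixel, toward the nearest contour vertex; within a narrow band around the
polyline itself it points along the contour toward the next vertex, so a
walker that steps repeatedly in the field direction is first attracted onto
the contour and then carried along it from the source endpoint to the sink
endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

Side = str  # "left" | "right"


# ---------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------


@dataclass
class Polyline:
    """Ordered open contour; ``vertices`` is an (N, 2) array of (x, y)."""

    vertices: np.ndarray
    side: Side | None = None
    present: bool = True
    converged: bool = True
    out_of_bounds: bool = False
    stalled: bool = False

    def __post_init__(self):
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if self.vertices.size == 0:
            self.vertices = np.zeros((0, 2))
        if self.present and self.vertices.shape[0] and not np.all(
            np.isfinite(self.vertices)
        ):
            raise ValueError("polyline vertices must be finite")

    @classmethod
    def absent(cls, side: Side | None = None) -> "Polyline":
        return cls(np.zeros((0, 2)), side=side, present=False)

    def __len__(self) -> int:
        return int(self.vertices.shape[0])

    def reverse(self) -> "Polyline":
        return replace(self, vertices=self.vertices[::-1].copy())

    def length(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1).sum())


@dataclass
class VectorField2D:
    """Per-pixel unit vectors; ``ux``/``uy`` are (H, W) arrays."""

    ux: np.ndarray
    uy: np.ndarray

    def __post_init__(self):
        self.ux = np.asarray(self.ux, dtype=float)
        self.uy = np.asarray(self.uy, dtype=float)
        if self.ux.shape != self.uy.shape or self.ux.ndim != 2:
            raise ValueError("ux/uy must be matching 2D arrays")

    @property
    def shape(self):
        return self.ux.shape

    def norms(self) -> np.ndarray:
        return np.hypot(self.ux, self.uy)


@dataclass
class Heatmap:
    """Isotropic Gaussian of distance to ``peak``, maximum value 1 at the peak."""

    values: np.ndarray
    peak: np.ndarray
    sigma: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.peak = np.asarray(self.peak, dtype=float)

    @property
    def shape(self):
        return self.values.shape

    def value_at(self, p) -> float:
        d2 = float(np.sum((np.asarray(p, dtype=float) - self.peak) ** 2))
        return float(np.exp(-d2 / (2.0 * self.sigma**2)))

    def argmax_point(self) -> np.ndarray:
        """Integer (x, y) of the grid argmax (first occurrence on ties)."""
        iy, ix = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return np.array([float(ix), float(iy)])

    @classmethod
    def zero(cls, shape) -> "Heatmap":
        return cls(np.zeros(shape), np.array([np.nan, np.nan]), sigma=1.0)


@dataclass
class SideTargets:
    field: VectorField2D
    source: Heatmap
    sink: Heatmap
    present: bool = True


@dataclass
class ContourTargets:
    """The 8 regression planes of one slice: per side a 2-plane UVF and
    source/sink heatmaps.  Absent sides carry all-zero planes."""

    left: SideTargets
    right: SideTargets

    PLANE_NAMES = (
        "left_ux", "left_uy", "left_src", "left_snk",
        "right_ux", "right_uy", "right_src", "right_snk",
    )

    def to_planes(self) -> np.ndarray:
        planes = []
        for st in (self.left, self.right):
            planes += [st.field.ux, st.field.uy, st.source.values, st.sink.values]
        return np.stack(planes)


@dataclass
class WalkParams:
    """Parameters of the field walker.

    ``stop_radius`` defaults to the sink heatmap's sigma; ``max_steps``
    defaults to four image diagonals, bounding runtime on pathological
    fields.  A source peak below ``presence_threshold`` declares the
    contour absent.  With ``midpoint`` (default) each step's direction is
    the renormalised average of the field at the current point and at a
    half-step ahead (Heun/midpoint rule); the step magnitude is always
    ``step_length``.  The midpoint rule damps the overshoot oscillation a
    discrete walker suffers next to attracting vertices.
    """

    step_length: float = 1.0
    stop_radius: float | None = None
    max_steps: int | None = None
    presence_threshold: float = 0.3
    midpoint: bool = True
    stall_window: int = 8  # steps; 0 disables stall detection
    stall_tol: float = 2.0  # net displacement below which the walk stalls

    def __post_init__(self):
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        if self.max_steps is not None and self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


# ---------------------------------------------------------------------
# Polyline helpers
# ---------------------------------------------------------------------


def nearest_vertex(p, poly: Polyline) -> tuple[int, float]:
    """Index and distance of the polyline vertex nearest to ``p``.

    Ties break toward the lowest index.
    """
    if not poly.present or len(poly) == 0:
        raise ValueError("nearest_vertex requires a present, non-empty polyline")
    d = np.linalg.norm(poly.vertices - np.asarray(p, dtype=float), axis=1)
    idx = int(np.argmin(d))  # argmin returns the first minimum
    return idx, float(d[idx])


def polyline_arclengths(vertices: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(poly: Polyline, n: int) -> Polyline:
    """Resample to ``n`` vertices uniformly in arclength (endpoints kept)."""
    if len(poly) < 2:
        raise ValueError("resampling requires >= 2 vertices")
    s = polyline_arclengths(poly.vertices)
    if s[-1] <= 0:
        raise ValueError("degenerate polyline")
    t = np.linspace(0.0, s[-1], n)
    x = np.interp(t, s, poly.vertices[:, 0])
    y = np.interp(t, s, poly.vertices[:, 1])
    return replace(poly, vertices=np.stack([x, y], axis=1))


def _segment_projection(points: np.ndarray, vertices: np.ndarray):
    """For each point: distance to the polyline and index of the nearest
    segment.  ``points`` (P,2), ``vertices`` (V,2) with V >= 2."""
    a = vertices[:-1]
    d = vertices[1:] - a
    L2 = np.maximum((d**2).sum(axis=1), 1e-300)
    diff = points[:, None, :] - a[None, :, :]
    t = np.clip((diff * d[None, :, :]).sum(axis=2) / L2[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    seg = dist2.argmin(axis=1)
    return np.sqrt(dist2[np.arange(len(points)), seg]), seg


def distance_to_polyline(points: np.ndarray, poly: Polyline) -> np.ndarray:
    dmin, _ = _segment_projection(np.atleast_2d(points), poly.vertices)
    return dmin


# ---------------------------------------------------------------------
# Target construction
# ---------------------------------------------------------------------


def build_target_uvf(
    poly: Polyline, shape: tuple[int, int], on_contour_radius: float = 1.5
) -> VectorField2D:
    """Target unit vector field of an open contour on an (H, W) grid.

    Off-contour pixels (further than ``on_contour_radius`` from the
    polyline) point toward the nearest annotated vertex; pixels lying on
    the contour point along it, toward the next vertex, so the contour's
    direction is preserved (the band past the last vertex reuses the final
    segment's direction).
    """
    if not poly.present or len(poly) < 2:
        raise ValueError("build_target_uvf requires a present polyline with >= 2 vertices")
    verts = poly.vertices
    if np.allclose(verts, verts[0]):
        raise ValueError("degenerate polyline: all vertices identical")
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    points = np.stack([xs.ravel(), ys.ravel()], axis=1)

    # off-contour: toward the nearest vertex
    tree = cKDTree(verts)
    _, vidx = tree.query(points)
    vec = verts[vidx] - points

    # on-contour band: along the segment nearest to the pixel
    dpoly, seg = _segment_projection(points, verts)
    on = dpoly <= on_contour_radius
    seg_dir = np.diff(verts, axis=0)
    seg_len = np.linalg.norm(seg_dir, axis=1)
    ok = seg_len > 0
    # zero-length segments (repeated vertices) borrow the next valid direction
    if not ok.all():
        for i in np.where(~ok)[0]:
            j = next((k for k in range(i + 1, len(ok)) if ok[k]), None)
            if j is None:
                j = next(k for k in range(i - 1, -1, -1) if ok[k])
            seg_dir[i] = seg_dir[j]
            seg_len[i] = seg_len[j]
    seg_unit = seg_dir / seg_len[:, None]
    vec[on] = seg_unit[seg[on]]

    norm = np.linalg.norm(vec, axis=1)
    if np.any(norm < 1e-12):
        # off-contour pixel exactly on a vertex cannot occur (it is in-band);
        # guard anyway for pathological radii
        bad = norm < 1e-12
        vec[bad] = seg_unit[seg[bad]]
        norm = np.linalg.norm(vec, axis=1)
    vec = vec / norm[:, None]
    return VectorField2D(vec[:, 0].reshape(h, w), vec[:, 1].reshape(h, w))


def gaussian_heatmap(peak, shape: tuple[int, int], sigma: float) -> Heatmap:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    h, w = shape
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    peak = np.asarray(peak, dtype=float)
    d2 = (xs - peak[0]) ** 2 + (ys - peak[1]) ** 2
    return Heatmap(np.exp(-d2 / (2.0 * sigma**2)), peak, sigma)


def build_endpoint_heatmaps(
    poly: Polyline, shape: tuple[int, int], sigma: float
) -> tuple[Heatmap, Heatmap]:
    """Source heatmap peaked at the first vertex, sink at the last."""
    if not poly.present or len(poly) < 2:
        raise ValueError("endpoint heatmaps require a present polyline")
    source = gaussian_heatmap(poly.vertices[0], shape, sigma)
    sink = gaussian_heatmap(poly.vertices[-1], shape, sigma)
    return source, sink


def suggest_sigma(
    area: float | None = None,
    contour_length: float | None = None,
    area_coeff: float = 0.05,
    length_coeff: float = 0.05,
) -> float:
    """Heatmap sigma proportional to the task region: ``area_coeff *
    sqrt(area)`` when a reference area (the sacrum between the two joints)
    exists, else ``length_coeff * contour_length``."""
    if area is not None and area > 0:
        return float(area_coeff * np.sqrt(area))
    if contour_length is not None and contour_length > 0:
        return float(length_coeff * contour_length)
    raise ValueError("provide a positive area or contour length")


def build_contour_targets(
    left: Polyline | None,
    right: Polyline | None,
    shape: tuple[int, int],
    sigma: float,
    on_contour_radius: float = 1.5,
) -> ContourTargets:
    """Assemble the 8-plane regression target for one slice."""

    def side_targets(poly: Polyline | None, side: Side) -> SideTargets:
        if poly is None or not poly.present or len(poly) < 2:
            z = np.zeros(shape)
            return SideTargets(
                VectorField2D(z.copy(), z.copy()),
                Heatmap.zero(shape),
                Heatmap.zero(shape),
                present=False,
            )
        fld = build_target_uvf(poly, shape, on_contour_radius)
        src, snk = build_endpoint_heatmaps(poly, shape, sigma)
        return SideTargets(fld, src, snk, present=True)

    return ContourTargets(side_targets(left, "left"), side_targets(right, "right"))


# ---------------------------------------------------------------------
# Field sampling and walking
# ---------------------------------------------------------------------


def sample_field(fld: VectorField2D, p) -> np.ndarray:
    """Bilinearly interpolated, renormalised unit vector at continuous ``p``."""
    x, y = float(p[0]), float(p[1])
    h, w = fld.shape
    if not (0.0 <= x <= w - 1 and 0.0 <= y <= h - 1):
        raise ValueError(f"point {(x, y)} outside field extent {(h, w)}")
    x0 = min(int(np.floor(x)), w - 2) if w > 1 else 0
    y0 = min(int(np.floor(y)), h - 2) if h > 1 else 0
    x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
    fx, fy = x - x0, y - y0
    wts = np.array(
        [(1 - fx) * (1 - fy), fx * (1 - fy), (1 - fx) * fy, fx * fy]
    )
    ux = np.array([fld.ux[y0, x0], fld.ux[y0, x1], fld.ux[y1, x0], fld.ux[y1, x1]])
    uy = np.array([fld.uy[y0, x0], fld.uy[y0, x1], fld.uy[y1, x0], fld.uy[y1, x1]])
    v = np.array([wts @ ux, wts @ uy])
    n = np.linalg.norm(v)
    if n < 1e-8:
        raise ValueError("ambiguous field: interpolated vector has near-zero norm")
    return v / n


def walk_contour(
    fld: VectorField2D,
    source: Heatmap,
    sink: Heatmap,
    params: WalkParams | None = None,
    side: Side | None = None,
) -> Polyline:
    """Extract an open contour by stepping along the field from source to sink.

    The walk starts at the source heatmap's argmax and repeats
    ``p <- p + step_length * field(p)`` until it comes within
    ``stop_radius`` of the sink argmax (the sink argmax is then appended
    as the final vertex), the step budget is exhausted (``converged``
    flag cleared), or the walker leaves the field (``out_of_bounds`` set).
    A source peak below ``presence_threshold`` yields an absent contour.
    """
    params = params or WalkParams()
    if fld.shape != source.shape or fld.shape != sink.shape:
        raise ValueError("field and heatmap shapes disagree")
    if float(source.values.max(initial=0.0)) < params.presence_threshold:
        return Polyline.absent(side)
    h, w = fld.shape
    stop_radius = params.stop_radius if params.stop_radius is not None else sink.sigma
    max_steps = params.max_steps
    if max_steps is None:
        max_steps = int(4 * np.hypot(h, w))
    p = source.argmax_point()
    target = sink.argmax_point()
    verts = [p.copy()]
    converged = False
    oob = False
    stalled = False
    # arm the sink test only after the walker has made minimal progress,
    # so a sink lying within stop_radius of the source cannot truncate the
    # contour to a single step
    min_steps = int(np.ceil(2.0 * stop_radius / params.step_length))
    for step_no in range(max_steps):
        if step_no >= min_steps and np.linalg.norm(p - target) <= stop_radius:
            if np.linalg.norm(p - target) > 1e-9:
                verts.append(target.copy())
            converged = True
            break
        try:
            v = sample_field(fld, p)
            if params.midpoint:
                pm = p + 0.5 * params.step_length * v
                pm = np.array(
                    [min(max(pm[0], 0.0), w - 1), min(max(pm[1], 0.0), h - 1)]
                )
                v2 = sample_field(fld, pm)
                s = v + v2
                n = np.linalg.norm(s)
                if n > 1e-8:
                    v = s / n
        except ValueError:
            oob = True
            break
        p = p + params.step_length * v
        if not (0.0 <= p[0] <= w - 1 and 0.0 <= p[1] <= h - 1):
            oob = True
            break
        verts.append(p.copy())
        # a walker bouncing in place (net displacement below stall_tol
        # over stall_window steps) will never progress; cut it off
        if (
            params.stall_window > 0
            and len(verts) > max(params.stall_window, min_steps)
            and np.linalg.norm(p - verts[-1 - params.stall_window])
            < params.stall_tol * params.step_length
        ):
            stalled = True
            break
    return Polyline(
        np.array(verts), side=side, present=True,
        converged=converged, out_of_bounds=oob, stalled=stalled,
    )


# ---------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------


def closest_point_rms(
    pred: Polyline,
    gt: Polyline,
    spacing_mm: float | None = None,
    symmetric: bool = False,
) -> float:
    """RMS of closest-point distances from ground-truth landmarks to the
    predicted contour vertices (optionally symmetrised; optionally scaled
    to millimetres by the in-plane pixel spacing)."""
    if not pred.present or not gt.present or len(pred) == 0 or len(gt) == 0:
        raise ValueError("closest_point_rms requires two present, non-empty polylines")
    d_gt, _ = cKDTree(pred.vertices).query(gt.vertices)
    d = d_gt
    if symmetric:
        d_pred, _ = cKDTree(gt.vertices).query(pred.vertices)
        d = np.concatenate([d_gt, d_pred])
    rms = float(np.sqrt(np.mean(d**2)))
    if spacing_mm is not None:
        rms *= float(spacing_mm)
    return rms


def error_quantiles(errors, proportions) -> list[tuple[float, float]]:
    """Empirical quantiles of an error sample at the given data proportions
    (linear interpolation between order statistics)."""
    errors = np.asarray(errors, dtype=float)
    proportions = list(proportions)
    if errors.size == 0:
        raise ValueError("empty error list")
    if any(not (0.0 < q <= 1.0) for q in proportions):
        raise ValueError("proportions must lie in (0, 1]")
    if any(b < a for a, b in zip(proportions, proportions[1:])):
        raise ValueError("proportions must be sorted ascending")
    qs = np.quantile(errors, proportions, method="linear")
    return [(float(p), float(q)) for p, q in zip(proportions, qs)]
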