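"""Virtual cells: polygonal cells anchored to the canvas, and their divisions.

The tissue is tiled by polygonal *v-cells* whose vertices are anchored to
canvas elements (barycentric coordinates) and therefore move with tissue
growth.  Divisions follow a noisy shortest-wall (Errera) rule: the nominal
new wall is the shortest chord through the cell's area centroid; the actual
wall is parallel to it, through a point displaced uniformly at random within
a disc of radius 0.25 x the nominal wall length, and is shortened slightly
where it meets the old walls.  A cell divides when it is competent (inside
the CDIV corridor) and its area exceeds a stochastic target drawn at birth
from normal(Ā, 0.2·Ā).

In the subepidermal model, intercellular air spaces are created by replacing
randomly chosen three-way vertices with small triangles that then expand
radially, shouldering the surrounding cells apart.

The tessellation is conforming throughout: wall endpoints inserted by a
division are also inserted into the neighbour sharing that wall, so cells
plus spaces tile the canvas exactly and edge-sharing adjacency is always
resolvable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi

from leafmorph.canvas import Canvas
from leafmorph.factors import FactorState, KRNParams, ModelVariant


# ----------------------------------------------------------------------
# parameters
# ----------------------------------------------------------------------

@dataclass
class DivisionParams:
    """Division-engine parameters (areas in μm², times in hours).

    ``pmf_min`` sets the competence corridor (0.184 subepidermis, 0.295
    epidermis); ``pgrad_gate`` applies to the epidermis only; competence is
    withdrawn tissue-wide when LATE reaches ``late_off`` and earlier in the
    epidermal midline (``late_off_midline``).
    """

    a_min: float = 150.0
    a_max: float = 300.0
    a_mid: float = 500.0
    pmf_max: float = 0.51
    pmf_min: float = 0.184
    sigma_frac: float = 0.2
    pgrad_gate: float | None = None       # epidermis: 0.628
    late_off: float = 0.1680
    late_off_midline: float | None = None  # epidermis: 0.0768
    a_prime: float = 0.0
    onset_t: float = 114.0
    # division geometry
    noise_frac: float = 0.25
    shorten_frac: float = 0.05
    target_floor_frac: float = 0.3
    min_divisible_area: float = 4.0
    # intercellular spaces (subepidermis)
    space_init_time: float = 120.0
    space_init_count: int = 30
    space_rate: float = 11.0              # h⁻¹
    space_init_area: float = 2.0          # μm²
    space_radial_rate: float = 0.0125     # h⁻¹ (areal growth 2.5 % h⁻¹)

    @classmethod
    def for_variant(cls, variant: ModelVariant) -> "DivisionParams":
        if variant.layer == "subepidermis":
            return cls(pmf_min=0.184, a_prime=variant.a_prime)
        return cls(pmf_min=0.295, pgrad_gate=0.628, late_off_midline=0.0768,
                   a_prime=variant.a_prime)


# ----------------------------------------------------------------------
# pure polygon geometry: the Errera rule
# ----------------------------------------------------------------------

def polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    """Area centroid (not the vertex mean; degenerate rings fall back to it)."""
    x, y = poly[:, 0], poly[:, 1]
    cr = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = 0.5 * cr.sum()
    if abs(a) < 1e-12:
        return poly.mean(axis=0)
    cx = ((x + np.roll(x, -1)) * cr).sum() / (6.0 * a)
    cy = ((y + np.roll(y, -1)) * cr).sum() / (6.0 * a)
    return np.array([cx, cy])


def _chord(poly: np.ndarray, point: np.ndarray, direction: np.ndarray):
    """Chord of the polygon along `direction` through `point`.

    Returns ``(i1, t1, i2, t2, length)`` -- the two boundary crossings as
    (edge index, edge parameter) -- or None if the point is not bracketed.
    For non-convex polygons the chord piece containing the point is used.
    """
    p = poly
    q = np.roll(poly, -1, axis=0)
    d = direction
    # signed distance of vertices from the line through `point`
    s_p = (p[:, 0] - point[0]) * d[1] - (p[:, 1] - point[1]) * d[0]
    s_q = (q[:, 0] - point[0]) * d[1] - (q[:, 1] - point[1]) * d[0]
    cross = (s_p > 0) != (s_q > 0)
    idx = np.where(cross)[0]
    if len(idx) < 2:
        return None
    t = s_p[idx] / (s_p[idx] - s_q[idx])
    pts = p[idx] + t[:, None] * (q[idx] - p[idx])
    # position of each crossing along the line
    u = (pts - point) @ d
    neg = u <= 0
    pos = u > 0
    if not neg.any() or not pos.any():
        return None
    a = np.argmax(np.where(neg, u, -np.inf))
    b = np.argmin(np.where(pos, u, np.inf))
    length = u[b] - u[a]
    return (int(idx[a]), float(t[a]), int(idx[b]), float(t[b]), float(length))


def _chord_lengths(poly: np.ndarray, point: np.ndarray,
                   dirs: np.ndarray) -> np.ndarray:
    """Chord length through `point` for many directions at once (vectorised
    counterpart of :func:`_chord`; inf where no bracketing chord exists)."""
    p = poly - point
    q = np.roll(poly, -1, axis=0) - point
    # signed distances of edge endpoints from each direction's line
    s_p = p[:, 0][:, None] * dirs[:, 1] - p[:, 1][:, None] * dirs[:, 0]
    s_q = q[:, 0][:, None] * dirs[:, 1] - q[:, 1][:, None] * dirs[:, 0]
    crossing = (s_p > 0) != (s_q > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        # non-crossing entries produce nan/inf and are masked below
        t = s_p / (s_p - s_q)
        pts_x = p[:, 0][:, None] + t * (q[:, 0] - p[:, 0])[:, None]
        pts_y = p[:, 1][:, None] + t * (q[:, 1] - p[:, 1])[:, None]
        u = pts_x * dirs[:, 0] + pts_y * dirs[:, 1]
        uneg = np.where(crossing & (u <= 0), u, -np.inf).max(axis=0)
        upos = np.where(crossing & (u > 0), u, np.inf).min(axis=0)
    return upos - uneg


def shortest_chord(poly: np.ndarray, point: np.ndarray,
                   coarse_step_deg: float = 0.5,
                   tie_axis: np.ndarray | None = None):
    """Global minimum-length chord through `point`.

    Directions are scanned at ``coarse_step_deg`` resolution (vectorised)
    and the best is refined by golden-section search.  Near-ties (within
    0.1 % in length) are broken towards the smallest angle to ``tie_axis``
    when given.
    """
    angles = np.arange(0.0, np.pi, np.deg2rad(coarse_step_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    lengths = _chord_lengths(poly, point, dirs)
    if not np.isfinite(lengths).any():
        return None, None
    lmin = lengths.min()
    cand = np.where(lengths <= lmin * 1.001)[0]
    if tie_axis is not None and len(cand) > 1:
        ax_angle = np.arctan2(tie_axis[1], tie_axis[0]) % np.pi
        dev = np.abs((angles[cand] - ax_angle + np.pi / 2) % np.pi - np.pi / 2)
        k0 = int(cand[np.argmin(dev)])
    else:
        k0 = int(np.argmin(lengths))

    # golden-section refinement on chord length vs angle
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    step = np.deg2rad(coarse_step_deg)
    lo, hi = angles[k0] - step, angles[k0] + step

    def f(th):
        r = _chord(poly, point, np.array([np.cos(th), np.sin(th)]))
        return (np.inf, None) if r is None else (r[4], r)

    c1 = hi - gr * (hi - lo)
    c2 = lo + gr * (hi - lo)
    f1, r1 = f(c1)
    f2, r2 = f(c2)
    for _ in range(16):
        if f1 <= f2:
            hi, c2, f2, r2 = c2, c1, f1, r1
            c1 = hi - gr * (hi - lo)
            f1, r1 = f(c1)
        else:
            lo, c1, f1, r1 = c1, c2, f2, r2
            c2 = lo + gr * (hi - lo)
            f2, r2 = f(c2)
    best = r1 if f1 <= f2 else r2
    th = c1 if f1 <= f2 else c2
    if best is None:
        th = angles[k0]
        best = _chord(poly, point, dirs[k0])
    return best, np.array([np.cos(th), np.sin(th)])


def errera_wall(poly: np.ndarray, rng: np.random.Generator,
                noise_frac: float = 0.25, tie_axis: np.ndarray | None = None,
                max_retries: int = 10):
    """Choose the division wall for a polygon under the noisy Errera rule.

    Returns ``(i1, t1, i2, t2)`` giving the wall endpoints as (edge index,
    parameter along edge).  With ``noise_frac = 0`` the nominal shortest
    wall is returned.  If every displaced wall exits the polygon or yields
    a sliver, the nominal wall is the fallback.
    """
    c = polygon_centroid(poly)
    nominal, direction = shortest_chord(poly, c, tie_axis=tie_axis)
    if nominal is None:
        return None
    if noise_frac <= 0:
        return nominal[:4]
    L = nominal[4]
    area = abs(polygon_area(poly))
    for _ in range(max_retries):
        r = noise_frac * L * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        pt = c + r * np.array([np.cos(phi), np.sin(phi)])
        trial = _chord(poly, pt, direction)
        if trial is None:
            continue
        a_piece = _split_areas(poly, trial)
        if a_piece is None:
            continue
        if min(a_piece) < 0.02 * area:
            continue  # sliver daughter, resample displacement
        return trial[:4]
    return nominal[:4]


def _split_areas(poly: np.ndarray, wall):
    i1, t1, i2, t2, _ = wall
    if i1 == i2:
        return None
    a, b = _split_polygons(poly, i1, t1, i2, t2)
    return abs(polygon_area(a)), abs(polygon_area(b))


def _split_polygons(poly: np.ndarray, i1: int, t1: float, i2: int, t2: float):
    """Coordinate polygons of the two daughters for a wall across edges i1, i2."""
    n = len(poly)
    e1 = poly[i1] + t1 * (poly[(i1 + 1) % n] - poly[i1])
    e2 = poly[i2] + t2 * (poly[(i2 + 1) % n] - poly[i2])
    if i1 > i2 or (i1 == i2 and t1 > t2):
        (i1, t1, e1), (i2, t2, e2) = (i2, t2, e2), (i1, t1, e1)
    ring_a = [e1] + [poly[k % n] for k in range(i1 + 1, i2 + 1)] + [e2]
    ring_b = [e2] + [poly[k % n] for k in range(i2 + 1, i1 + 1 + n)] + [e1]
    return np.asarray(ring_a), np.asarray(ring_b)


def errera_split(poly: np.ndarray, rng: np.random.Generator,
                 noise_frac: float = 0.25,
                 tie_axis: np.ndarray | None = None):
    """Divide a coordinate polygon; returns the two daughter polygons.

    Convenience wrapper over :func:`errera_wall` used by the parametric
    synthetic generator and by tests; daughters partition the mother exactly.
    """
    wall = errera_wall(poly, rng, noise_frac=noise_frac, tie_axis=tie_axis)
    if wall is None:
        raise ValueError("polygon admits no division wall")
    return _split_polygons(poly, *wall)


# ----------------------------------------------------------------------
# target areas
# ----------------------------------------------------------------------

def mean_target_area(pmf, pgrad, is_midline, layer: str,
                     params: DivisionParams, t: float):
    """Mean division target Ā (μm²) from local factor levels.

    Before 114 h every cell targets ``a_min``.  Afterwards lamina targets
    interpolate between ``a_min`` (PMF ≥ 0.51) and ``a_max`` (PMF at the
    competence threshold); midline targets are ``1.5·a_mid·PGRAD`` in the
    subepidermis and the constant ``a_mid`` in the epidermis.  Threshold
    mutants add ``a_prime`` to the lamina value.
    """
    pmf = np.asarray(pmf, dtype=float)
    pgrad = np.asarray(pgrad, dtype=float)
    is_midline = np.asarray(is_midline, dtype=bool)
    if t < params.onset_t:
        return np.full(pmf.shape, params.a_min)
    alpha = np.clip((params.pmf_max - pmf) / (params.pmf_max - params.pmf_min),
                    0.0, 1.0)
    lamina = params.a_min * (1.0 - alpha) + params.a_max * alpha + params.a_prime
    if layer == "subepidermis":
        midline = 1.5 * params.a_mid * pgrad
    else:
        midline = np.full(pmf.shape, params.a_mid)
    return np.where(is_midline, midline, lamina)


def sample_target(abar, rng: np.random.Generator,
                  sigma_frac: float = 0.2, floor_frac: float = 0.3):
    """Draw target areas A ~ normal(Ā, σ·Ā), truncated below at 0.3·Ā.

    The truncation guards against (3.5 σ) negative draws and perturbs the
    stated mean and SD by well under 0.1 %.
    """
    abar = np.asarray(abar, dtype=float)
    noise = rng.normal(0.0, sigma_frac, size=abar.shape)
    return abar * np.maximum(1.0 + noise, floor_frac)


# ----------------------------------------------------------------------
# the cell complex
# ----------------------------------------------------------------------

@dataclass
class VCell:
    """One virtual cell (or intercellular space) of the tessellation."""

    cid: int
    vertices: list           # ordered vertex ids, CCW
    parent_id: int | None
    birth_time: float
    region: str               # "lamina" | "midline"
    layer: str
    target_area: float = np.inf
    target_noise: float = 1.0  # multiplicative factor applied to Ā
    competent: bool = False
    is_space: bool = False


class CellComplex:
    """Conforming polygonal tessellation, optionally anchored to a canvas.

    With ``canvas=None`` the complex runs anchor-free: vertex positions are
    plain coordinates moved by the caller (used by the parametric synthetic
    generator); with a canvas, positions derive from barycentric anchors.
    """

    def __init__(self, canvas: Canvas | None):
        self.canvas = canvas
        self.vx_elem = np.empty(0, dtype=int)
        self.vx_bary = np.empty((0, 3))
        self.vx_xy = np.empty((0, 2))
        self.vx_boundary = np.empty(0, dtype=bool)
        self.cells: dict[int, VCell] = {}
        self._next_cid = 0
        self._edge_map: dict | None = None
        self.events: list[dict] = []
        self.space_events: list[dict] = []
        self._space_carry = 0.0
        self._flat = None          # (cids, order, flat_ids, starts)
        self._geom = None          # (areas_by_cid, centroids_by_cid)

    # -------------------------------------------------- vertices
    def add_vertices(self, xy: np.ndarray, boundary=None) -> np.ndarray:
        xy = np.atleast_2d(xy)
        if self.canvas is not None:
            elem, bary = self.canvas.locate(xy)
        else:
            elem = np.zeros(len(xy), dtype=int)
            bary = np.zeros((len(xy), 3))
        ids = np.arange(len(self.vx_elem), len(self.vx_elem) + len(xy))
        self.vx_elem = np.concatenate([self.vx_elem, elem])
        self.vx_bary = np.concatenate([self.vx_bary, bary])
        self.vx_xy = np.concatenate([self.vx_xy, xy])
        if boundary is None:
            boundary = np.zeros(len(xy), dtype=bool)
        self.vx_boundary = np.concatenate([self.vx_boundary,
                                           np.asarray(boundary, dtype=bool)])
        return ids

    def refresh_positions(self) -> None:
        """Recompute vertex positions from their canvas anchors (advection)."""
        if self.canvas is not None and len(self.vx_elem):
            self.vx_xy = self.canvas.anchor_positions(self.vx_elem, self.vx_bary)
            self._invalidate_geometry()

    def reanchor(self, ids: np.ndarray) -> None:
        """Re-anchor vertices after displacing them relative to the tissue."""
        if self.canvas is None:
            return
        elem, bary = self.canvas.locate(self.vx_xy[ids])
        self.vx_elem[ids] = elem
        self.vx_bary[ids] = bary

    # -------------------------------------------------- cells
    def add_cell(self, vertices, parent_id, birth_time, region, layer,
                 is_space=False) -> VCell:
        cell = VCell(cid=self._next_cid, vertices=list(vertices),
                     parent_id=parent_id, birth_time=birth_time,
                     region=region, layer=layer, is_space=is_space)
        self.cells[cell.cid] = cell
        self._next_cid += 1
        self._invalidate_geometry(topology_changed=True)
        return cell

    def polygon(self, cid: int) -> np.ndarray:
        return self.vx_xy[self.cells[cid].vertices]

    def live_cells(self, include_spaces=False):
        return [c for c in self.cells.values()
                if (include_spaces or not c.is_space)]

    def _invalidate_geometry(self, topology_changed=False) -> None:
        self._geom = None
        if topology_changed:
            self._flat = None

    def _geometry(self):
        """Vectorised areas and centroids for every cell (cached until the
        tessellation's topology or vertex positions change)."""
        if self._geom is not None:
            return self._geom
        if self._flat is None:
            cids = np.fromiter(self.cells.keys(), dtype=int,
                               count=len(self.cells))
            lens = np.array([len(self.cells[c].vertices) for c in cids])
            flat = np.concatenate([self.cells[c].vertices for c in cids]) \
                if len(cids) else np.empty(0, dtype=int)
            starts = np.concatenate([[0], np.cumsum(lens)])
            self._flat = (cids, flat.astype(int), starts)
        cids, flat, starts = self._flat
        if not len(cids):
            self._geom = ({}, {})
            return self._geom
        p = self.vx_xy[flat]
        # roll within each polygon: index of the "next" vertex
        nxt = np.arange(len(flat)) + 1
        nxt[starts[1:] - 1] = starts[:-1]
        q = self.vx_xy[flat[nxt]]
        cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
        seg = np.add.reduceat(cross, starts[:-1])
        areas = 0.5 * seg
        sx = np.add.reduceat((p[:, 0] + q[:, 0]) * cross, starts[:-1])
        sy = np.add.reduceat((p[:, 1] + q[:, 1]) * cross, starts[:-1])
        with np.errstate(divide="ignore", invalid="ignore"):
            cx = sx / (6.0 * areas)
            cy = sy / (6.0 * areas)
        # degenerate rings: fall back to the vertex mean
        bad = np.abs(areas) < 1e-12
        if bad.any():
            for k in np.where(bad)[0]:
                ids = flat[starts[k]:starts[k + 1]]
                cx[k], cy[k] = self.vx_xy[ids].mean(axis=0)
        self._geom = (dict(zip(cids.tolist(), areas)),
                      dict(zip(cids.tolist(),
                               np.stack([cx, cy], axis=1))))
        return self._geom

    def areas(self, cids=None) -> np.ndarray:
        by_cid, _ = self._geometry()
        if cids is None:
            cids = [c.cid for c in self.live_cells()]
        return np.array([by_cid[c] for c in cids])

    def centroids(self, cids) -> np.ndarray:
        _, by_cid = self._geometry()
        return np.array([by_cid[c] for c in cids]).reshape(len(cids), 2)

    def field_at_cells(self, nodal_values: np.ndarray, cids) -> np.ndarray:
        """Mean of a nodal canvas field over each cell's vertices
        (smooth-field approximation to the centroid value)."""
        vals = self.canvas.interpolate_nodal(nodal_values, self.vx_elem,
                                             self.vx_bary)
        return np.array([vals[self.cells[cid].vertices].mean() for cid in cids])

    # -------------------------------------------------- adjacency
    def edge_map(self) -> dict:
        """(min_vid, max_vid) -> list of incident cell ids (spaces included)."""
        if self._edge_map is None:
            em: dict = {}
            for cell in self.cells.values():
                vs = cell.vertices
                for a, b in zip(vs, vs[1:] + vs[:1]):
                    em.setdefault((a, b) if a < b else (b, a), []).append(cell.cid)
            self._edge_map = em
        return self._edge_map

    def neighbours(self, cid: int) -> set:
        em = self.edge_map()
        vs = self.cells[cid].vertices
        out = set()
        for a, b in zip(vs, vs[1:] + vs[:1]):
            for other in em.get((a, b) if a < b else (b, a), []):
                if other != cid:
                    out.add(other)
        return out

    def is_border_cell(self, cid: int) -> bool:
        em = self.edge_map()
        vs = self.cells[cid].vertices
        for a, b in zip(vs, vs[1:] + vs[:1]):
            if len(em[(a, b) if a < b else (b, a)]) < 2:
                return True
        return False

    # -------------------------------------------------- division
    def divide_cell(self, cid: int, t: float, rng: np.random.Generator,
                    params: DivisionParams,
                    tie_axis: np.ndarray | None = None):
        """Divide one cell in place; returns the two daughters.

        The wall endpoints are inserted into the mother's boundary edges and
        into the neighbours sharing those edges, keeping the tessellation
        conforming; daughter polygons partition the mother exactly.
        """
        cell = self.cells[cid]
        poly = self.vx_xy[cell.vertices]
        wall = errera_wall(poly, rng, noise_frac=params.noise_frac,
                           tie_axis=tie_axis)
        if wall is None:
            return None
        i1, t1, i2, t2 = wall
        if i1 == i2:
            return None
        if i1 > i2:
            (i1, t1), (i2, t2) = (i2, t2), (i1, t1)
        n = len(poly)
        e1 = poly[i1] + t1 * (poly[(i1 + 1) % n] - poly[i1])
        e2 = poly[i2] + t2 * (poly[(i2 + 1) % n] - poly[i2])

        # shorten the wall slightly: slide each endpoint along its host edge
        # towards the other endpoint's projection
        L = float(np.linalg.norm(e2 - e1))
        e1, t1 = _slide_endpoint(poly, i1, t1, e1, e2,
                                 params.shorten_frac * L)
        e2, t2 = _slide_endpoint(poly, i2, t2, e2, e1,
                                 params.shorten_frac * L)

        vids = cell.vertices
        edge1 = (vids[i1], vids[(i1 + 1) % n])
        edge2 = (vids[i2], vids[(i2 + 1) % n])
        on_bnd = np.array([
            self.vx_boundary[edge1[0]] and self.vx_boundary[edge1[1]],
            self.vx_boundary[edge2[0]] and self.vx_boundary[edge2[1]],
        ])
        w1, w2 = self.add_vertices(np.stack([e1, e2]), boundary=on_bnd)

        ring_a = [w1] + [vids[k % n] for k in range(i1 + 1, i2 + 1)] + [w2]
        ring_b = [w2] + [vids[k % n] for k in range(i2 + 1, i1 + 1 + n)] + [w1]

        em = self.edge_map()

        def ekey(a, b):
            return (a, b) if a < b else (b, a)

        # detach the mother from the adjacency map
        for a, b in zip(vids, vids[1:] + vids[:1]):
            lst = em.get(ekey(a, b))
            if lst and cid in lst:
                lst.remove(cid)
        # conforming insertion of the wall endpoints into the neighbours
        # across the split edges (the split edge keys disappear)
        for (a, b), w in ((edge1, w1), (edge2, w2)):
            inc = em.pop(ekey(a, b), [])
            for nb in inc:
                self._insert_in_cycle(nb, a, b, w)
                em.setdefault(ekey(a, w), []).append(nb)
                em.setdefault(ekey(w, b), []).append(nb)

        da = self.add_cell(ring_a, parent_id=cid, birth_time=t,
                           region=cell.region, layer=cell.layer)
        db = self.add_cell(ring_b, parent_id=cid, birth_time=t,
                           region=cell.region, layer=cell.layer)
        for d in (da, db):
            vs = d.vertices
            for a, b in zip(vs, vs[1:] + vs[:1]):
                em.setdefault(ekey(a, b), []).append(d.cid)

        mother_area = polygon_area(poly)
        del self.cells[cid]
        self._invalidate_geometry(topology_changed=True)
        cen = polygon_centroid(poly)
        dist = (float(self.canvas.distance_to_plb(cen[None])[0])
                if self.canvas is not None else np.nan)
        self.events.append({
            "time": t, "parent": cid, "daughters": (da.cid, db.cid),
            "mother_area": mother_area, "x": cen[0], "y": cen[1],
            "dist_plb": dist, "region": cell.region, "layer": cell.layer,
        })
        return da, db

    def _insert_in_cycle(self, cid: int, a: int, b: int, w: int) -> None:
        vs = self.cells[cid].vertices
        n = len(vs)
        for k in range(n):
            p, q = vs[k], vs[(k + 1) % n]
            if (p == a and q == b) or (p == b and q == a):
                vs.insert(k + 1, w)
                return

    # -------------------------------------------------- intercellular spaces
    def space_candidates(self):
        """Three-way interior vertices not touching an existing space,
        with their incident-cell lists."""
        v2c: dict[int, list[int]] = {}
        for cell in self.cells.values():
            for v in cell.vertices:
                v2c.setdefault(v, []).append(cell.cid)
        cand = [v for v, cs in v2c.items()
                if len(cs) == 3 and not self.vx_boundary[v]
                and not any(self.cells[c].is_space for c in cs)]
        return cand, v2c

    def create_space(self, t: float, rng: np.random.Generator,
                     params: DivisionParams, candidates=None, v2c=None,
                     max_attempts: int = 200) -> int | None:
        """Replace a random three-way interior vertex with a small triangle.

        Returns the vertex that was replaced, or None if no candidate
        admitted a valid triangle.
        """
        if candidates is None or v2c is None:
            candidates, v2c = self.space_candidates()
        if not candidates:
            return None
        order = rng.permutation(len(candidates))
        for k in order[:max_attempts]:
            v = candidates[k]
            if self._truncate_vertex(v, v2c[v], t, params):
                return v
        return None

    def _truncate_vertex(self, v: int, cids: list, t: float,
                         params: DivisionParams) -> bool:
        # the three walls leaving v; each shared by two of the three cells
        neigh: dict[int, list[int]] = {}
        for cid in cids:
            vs = self.cells[cid].vertices
            k = vs.index(v)
            for u in (vs[k - 1], vs[(k + 1) % len(vs)]):
                neigh.setdefault(u, []).append(cid)
        walls = [u for u, cs in neigh.items() if len(cs) == 2]
        if len(walls) != 3:
            return False
        p0 = self.vx_xy[v]
        dirs, dmax = [], []
        for u in walls:
            dv = self.vx_xy[u] - p0
            ln = np.linalg.norm(dv)
            if ln < 1e-9:
                return False
            dirs.append(dv / ln)
            dmax.append(ln)
        dirs = np.asarray(dirs)
        unit_pts = p0 + dirs
        a_unit = abs(polygon_area(unit_pts))
        if a_unit < 1e-6:
            return False
        d = np.sqrt(params.space_init_area / a_unit)
        if d > 0.45 * min(dmax):
            return False
        tri_xy = p0 + d * dirs
        new_ids = self.add_vertices(tri_xy)
        id_for_wall = dict(zip(walls, new_ids))

        self._invalidate_geometry(topology_changed=True)
        # rewire each incident cell: v -> the two new points on its two walls
        for cid in cids:
            vs = self.cells[cid].vertices
            k = vs.index(v)
            u_prev, u_next = vs[k - 1], vs[(k + 1) % len(vs)]
            vs[k:k + 1] = [id_for_wall[u_prev], id_for_wall[u_next]]

        # the space polygon, oriented CCW
        ring = list(new_ids)
        if polygon_area(self.vx_xy[ring]) < 0:
            ring.reverse()
        any_cell = self.cells[cids[0]]
        space = self.add_cell(ring, parent_id=None, birth_time=t,
                              region=any_cell.region, layer=any_cell.layer,
                              is_space=True)
        self._edge_map = None
        self.space_events.append({"time": t, "space": space.cid, "vertex": v})
        return True

    def grow_spaces(self, dt: float, params: DivisionParams) -> None:
        """Expand every space radially: vertex distance from the space centre
        grows at ``space_radial_rate`` per hour (areal rate twice that)."""
        factor = np.exp(params.space_radial_rate * dt)
        moved = []
        for cell in self.cells.values():
            if not cell.is_space:
                continue
            ids = np.asarray(cell.vertices)
            c = polygon_centroid(self.vx_xy[ids])
            self.vx_xy[ids] = c + factor * (self.vx_xy[ids] - c)
            moved.append(ids)
        if moved:
            self.reanchor(np.concatenate(moved))
            self._invalidate_geometry()


# ----------------------------------------------------------------------
# engine-level operations
# ----------------------------------------------------------------------

def _slide_endpoint(poly, i, ti, e_self, e_other, dist):
    """Slide a wall endpoint along its host edge by `dist` towards the
    projection of the opposite endpoint (the slight wall shortening)."""
    n = len(poly)
    a, b = poly[i], poly[(i + 1) % n]
    edge = b - a
    elen = np.linalg.norm(edge)
    if elen < 1e-12 or dist <= 0:
        return e_self, ti
    sign = 1.0 if np.dot(e_other - e_self, edge) > 0 else -1.0
    t_new = np.clip(ti + sign * dist / elen, 0.05, 0.95)
    return a + t_new * edge, float(t_new)


def update_competence(cc: CellComplex, state: FactorState,
                      params: DivisionParams, variant: ModelVariant) -> None:
    """Set each cell's CDIV competence flag from the current factor state.

    Competent iff PMF ≥ pmf_min at the cell, PGRAD ≥ the gate (epidermis
    only), and LATE below the arrest threshold (with the earlier midline
    threshold in the epidermis).
    """
    cells = cc.live_cells()
    if not cells:
        return
    cids = [c.cid for c in cells]
    pmf = cc.field_at_cells(state.pmf, cids)
    ok = pmf >= params.pmf_min
    if params.pgrad_gate is not None:
        pgrad = cc.field_at_cells(state.pgrad, cids)
        ok &= pgrad >= params.pgrad_gate
    # arrest when LATE *reaches* the threshold; tolerance absorbs the
    # floating-point gap between g_late*(183-148) and the printed 0.1680
    late = state.late
    ok &= late < params.late_off - 1e-9
    if params.late_off_midline is not None:
        mid = np.array([c.region == "midline" for c in cells])
        ok &= ~mid | (late < params.late_off_midline - 1e-9)
    for cell, flag in zip(cells, ok):
        cell.competent = bool(flag)


def assign_targets(cc: CellComplex, cids, state: FactorState,
                   params: DivisionParams, t: float,
                   rng: np.random.Generator) -> None:
    """Sample division targets for newborn cells from the local Ā."""
    if not len(cids):
        return
    pmf = cc.field_at_cells(state.pmf, cids)
    pgrad = cc.field_at_cells(state.pgrad, cids)
    mid = np.array([cc.cells[cid].region == "midline" for cid in cids])
    layer = cc.cells[cids[0]].layer
    abar = mean_target_area(pmf, pgrad, mid, layer, params, t)
    noise = np.maximum(1.0 + rng.normal(0.0, params.sigma_frac, len(cids)),
                       params.target_floor_frac)
    for cid, ab, u in zip(cids, abar, noise):
        cell = cc.cells[cid]
        cell.target_noise = float(u)
        cell.target_area = float(ab * u)


def attempt_divisions(cc: CellComplex, state: FactorState, t: float, dt: float,
                      rng: np.random.Generator, params: DivisionParams,
                      variant: ModelVariant) -> list:
    """Divide every competent cell whose area has reached its target.

    Each cell divides at most once per step.  Daughters draw fresh targets
    from the local Ā.  For the subepidermal midline, the PGRAD-dependent Ā
    is re-evaluated at check time (frozen per-cell noise), since that target
    tracks the advected gradient.
    """
    cells = [c for c in cc.live_cells() if c.competent]
    if not cells:
        return []
    cids = [c.cid for c in cells]
    areas = cc.areas(cids)

    if variant.layer == "subepidermis":
        sub_mid = [k for k, c in enumerate(cells) if c.region == "midline"]
        if sub_mid and t >= params.onset_t:
            mcids = [cids[k] for k in sub_mid]
            pgrad = cc.field_at_cells(state.pgrad, mcids)
            for k, pg in zip(sub_mid, pgrad):
                abar = 1.5 * params.a_mid * pg
                cells[k].target_area = abar * cells[k].target_noise

    new_ids = []
    events = []
    for cell, area in zip(cells, areas):
        if area < cell.target_area or area < 2 * params.min_divisible_area:
            continue
        # tie-break axis: local polarity (axis of anisotropic growth)
        cen = polygon_centroid(cc.vx_xy[cell.vertices])
        elem, _ = cc.canvas.locate(cen[None, :])
        axis = state.polarity[elem[0]]
        out = cc.divide_cell(cell.cid, t, rng, params, tie_axis=axis)
        if out is None:
            continue
        da, db = out
        new_ids.extend([da.cid, db.cid])
        events.append(cc.events[-1])
    assign_targets(cc, new_ids, state, params, t, rng)
    return events


def manage_spaces(cc: CellComplex, t: float, dt: float,
                  rng: np.random.Generator, params: DivisionParams,
                  variant: ModelVariant) -> None:
    """Create and grow intercellular spaces (subepidermal models only).

    30 spaces appear when the simulation crosses 120 h; afterwards new
    vertices are replaced at 11 h⁻¹.  Existing spaces expand radially at
    every step.
    """
    if variant.layer != "subepidermis":
        return
    t_init = params.space_init_time
    if t < t_init:
        return
    n_new = 0
    if not cc.space_events and t >= t_init:
        n_new = params.space_init_count
    else:
        cc._space_carry += params.space_rate * dt
        n_new = int(cc._space_carry)
        cc._space_carry -= n_new
    if n_new:
        candidates, v2c = cc.space_candidates()
        for _ in range(n_new):
            v = cc.create_space(t, rng, params, candidates, v2c)
            if v is None:
                break
            candidates.remove(v)
    cc.grow_spaces(dt, params)


# ----------------------------------------------------------------------
# initial packing
# ----------------------------------------------------------------------

def initial_cells(cc: CellComplex, variant: ModelVariant, params: KRNParams,
                  rng: np.random.Generator, mean_cell_area: float = 70.0,
                  t: float = 87.0) -> None:
    """Tile the initial canvas with a jittered-hexagonal Voronoi packing.

    Cell sizes follow the first tracked stage (mean area a calibration
    input, default 70 μm²).  Region labels (midline vs lamina) are assigned
    from the initial MID stripe and inherited through lineage.
    """
    from shapely.geometry import Point, Polygon

    canvas = cc.canvas
    outline = Polygon(canvas.nodes[canvas.boundary])
    outline = outline.buffer(0)
    spacing = np.sqrt(2.0 * mean_cell_area / np.sqrt(3.0))
    xmin, ymin, xmax, ymax = outline.bounds
    pad = 3 * spacing
    xs = np.arange(xmin - pad, xmax + pad, spacing)
    ys = np.arange(ymin - pad, ymax + pad, spacing * np.sqrt(3) / 2)
    X, Y = np.meshgrid(xs, ys)
    X[::2] += spacing / 2
    # jitter of half the lattice spacing gives a near-Poisson packing whose
    # neighbour-number spread matches natural epidermis (a regular lattice
    # would start the tissue with an unrealistic excess of hexagons)
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    pts = pts + rng.uniform(-0.5, 0.5, pts.shape) * spacing

    vor = Voronoi(pts)
    vertex_ids: dict[tuple, int] = {}

    def vid_of(xy):
        key = (round(xy[0], 6), round(xy[1], 6))
        if key not in vertex_ids:
            on_bnd = outline.exterior.distance(Point(xy)) < 1e-6
            vertex_ids[key] = int(cc.add_vertices(
                np.array([xy]), boundary=[on_bnd])[0])
        return vertex_ids[key]

    mid_hw = params.mid_halfwidth
    for p_idx, reg_idx in enumerate(vor.point_region):
        region = vor.regions[reg_idx]
        if not region or -1 in region:
            continue
        poly = Polygon(vor.vertices[region])
        if not poly.is_valid or poly.is_empty:
            continue
        clipped = poly.intersection(outline)
        if clipped.is_empty or clipped.geom_type != "Polygon":
            continue
        if clipped.area < 1.0:
            continue
        ring = np.asarray(clipped.exterior.coords)[:-1]
        if polygon_area(ring) < 0:
            ring = ring[::-1]
        ids = [vid_of(xy) for xy in ring]
        # drop consecutive duplicates from snapping
        ids = [v for k, v in enumerate(ids) if v != ids[k - 1]]
        if len(ids) < 3 or abs(polygon_area(cc.vx_xy[ids])) < 1.0:
            continue
        cen = polygon_centroid(ring)
        region_label = "midline" if abs(cen[0]) <= mid_hw else "lamina"
        cc.add_cell(ids, parent_id=None, birth_time=t,
                    region=region_label, layer=variant.layer)
    cc.refresh_positions()
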