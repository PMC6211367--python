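"""Triangulated tissue sheet ("canvas") and its geometry.

The canvas is a 2D finite-element mesh representing the growing leaf
primordium.  Nodes carry regulatory-factor concentrations (see
:mod:`leafmorph.factors`); elements carry polarity and specified growth.
Virtual cells and other material markers are anchored to elements through
barycentric coordinates and displaced with the tissue as it deforms.

Coordinate convention: x is mediolateral (midline at x = 0), y is
proximodistal and increases from the petiole base towards the leaf tip.
All lengths are in micrometres internally; organ-scale summaries are
reported in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.spatial import cKDTree


class CanvasError(ValueError):
    """Raised for degenerate geometry or invalid mesh states."""


@dataclass
class GeometryParams:
    """Shape of the initial primordium outline.

    The primordium is a rounded half-ellipse lamina on a short rectangular
    petiole stub.  Dimensions are calibration inputs matching the first
    tracked developmental stage (organ width of order 0.1 mm).

    Parameters
    ----------
    width : float
        Maximal lamina width in μm.
    lamina_length : float
        Proximodistal extent of the lamina (petiole-lamina boundary to tip), μm.
    petiole_length : float
        Length of the petiole stub below the petiole-lamina boundary, μm.
    petiole_width : float
        Width of the petiole stub, μm.
    tip_width_frac : float
        Residual half-width at the tip as a fraction of the maximal
        half-width (keeps the structured mesh non-degenerate at the apex).
    n_across, n_along : int
        Structured-grid resolution; the element count is
        ``2 * n_across * n_along`` (3000 at the default 30 x 50).
    """

    width: float = 100.0
    lamina_length: float = 150.0
    petiole_length: float = 40.0
    petiole_width: float = 65.0
    tip_width_frac: float = 0.25
    widest_frac: float = 0.45
    n_across: int = 30
    n_along: int = 50

    def validate(self) -> None:
        if min(self.width, self.lamina_length, self.petiole_length,
               self.petiole_width) <= 0:
            raise CanvasError("primordium dimensions must be positive")
        if self.petiole_width > self.width:
            raise CanvasError("petiole wider than lamina: outline would "
                              "self-intersect at the boundary")
        if not (0 < self.tip_width_frac < 1 and 0 < self.widest_frac < 1):
            raise CanvasError("shape fractions must lie in (0, 1)")
        if self.n_across < 2 or self.n_along < 2:
            raise CanvasError("mesh resolution too coarse")
        if self.n_across % 2:
            raise CanvasError("n_across must be even so a node column lies "
                              "exactly on the midline")


@dataclass
class Canvas:
    """Deforming triangulated tissue sheet.

    Attributes
    ----------
    nodes : (N, 2) float array of node positions, μm.
    elements : (M, 3) int array of CCW node-index triples.
    boundary : ordered node indices tracing the outline CCW.
    midline_nodes : node indices on the midline, ordered base -> tip.
    plb_node : index of the midline node anchored at the petiole-lamina
        boundary; all proximodistal distances are measured from it.
    base_nodes : node indices on the proximal (base) edge.
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary: np.ndarray
    midline_nodes: np.ndarray
    plb_node: int
    base_nodes: np.ndarray
    geometry: GeometryParams | None = None
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    # ------------------------------------------------------------------
    # basic measures
    # ------------------------------------------------------------------
    @property
    def element_count(self) -> int:
        return len(self.elements)

    def element_areas(self) -> np.ndarray:
        """Signed areas of all elements (positive for valid CCW elements)."""
        p = self.nodes[self.elements]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def area(self) -> float:
        """Total tissue area, μm²."""
        return float(self.element_areas().sum())

    def width(self) -> float:
        """Maximal mediolateral extent, μm."""
        x = self.nodes[self.boundary, 0]
        return float(x.max() - x.min())

    def length(self) -> float:
        y = self.nodes[:, 1]
        return float(y.max() - y.min())

    def is_valid(self, tol: float = 0.0) -> bool:
        return bool((self.element_areas() > tol).all())

    def copy(self) -> "Canvas":
        return Canvas(
            nodes=self.nodes.copy(),
            elements=self.elements,
            boundary=self.boundary,
            midline_nodes=self.midline_nodes,
            plb_node=self.plb_node,
            base_nodes=self.base_nodes,
            geometry=self.geometry,
        )

    # ------------------------------------------------------------------
    # proximodistal coordinate
    # ------------------------------------------------------------------
    def midline_arclength(self) -> np.ndarray:
        """Cumulative arc length along the midline node chain, base -> tip."""
        pts = self.nodes[self.midline_nodes]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def plb_position(self) -> float:
        """Arc-length position of the petiole-lamina boundary along the midline."""
        s = self.midline_arclength()
        k = int(np.where(self.midline_nodes == self.plb_node)[0][0])
        return float(s[k])

    def distance_to_plb(self, points: np.ndarray) -> np.ndarray:
        """Proximodistal distance from the petiole-lamina boundary, μm.

        Positive distally (towards the tip), negative in the petiole.  The
        proximodistal coordinate of a point is its position along the
        (deformed) midline material curve, looked up by y-station; this is
        the coordinate in which the division corridors (150/300/400 μm) are
        expressed.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        s = self.midline_arclength()
        ys = self.nodes[self.midline_nodes, 1]
        # y is monotone along the midline for the symmetric leaf shapes
        # produced here; fall back to sorted interpolation otherwise.
        order = np.argsort(ys)
        coord = np.interp(pts[:, 1], ys[order], s[order])
        return coord - self.plb_position()

    # ------------------------------------------------------------------
    # anchoring / interpolation
    # ------------------------------------------------------------------
    def _invalidate_cache(self) -> None:
        self._tree = None

    def _centroid_tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.element_centroids())
        return self._tree

    def barycentric(self, elem: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Barycentric coordinates of `points` w.r.t. elements `elem`."""
        tri = self.nodes[self.elements[elem]]
        a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
        v0 = b - a
        v1 = c - a
        v2 = points - a
        den = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
        w1 = (v2[:, 0] * v1[:, 1] - v2[:, 1] * v1[:, 0]) / den
        w2 = (v0[:, 0] * v2[:, 1] - v0[:, 1] * v2[:, 0]) / den
        return np.stack([1.0 - w1 - w2, w1, w2], axis=1)

    def locate(self, points: np.ndarray, k: int = 12):
        """Find the element containing each point.

        Returns ``(element_index, barycentric)`` arrays.  Points slightly
        outside the mesh (boundary rounding) are clamped to the nearest
        element with barycentric weights renormalised onto the simplex.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        tree = self._centroid_tree()
        kk = min(k, self.element_count)
        _, cand = tree.query(pts, k=kk)
        cand = np.atleast_2d(cand)
        elem = np.full(n, -1, dtype=int)
        bary = np.zeros((n, 3))
        best_score = np.full(n, -np.inf)
        best_elem = np.zeros(n, dtype=int)
        best_bary = np.zeros((n, 3))
        for j in range(cand.shape[1]):
            e = cand[:, j]
            w = self.barycentric(e, pts)
            inside = (w.min(axis=1) >= -1e-9) & (elem < 0)
            elem[inside] = e[inside]
            bary[inside] = w[inside]
            score = w.min(axis=1)
            better = score > best_score
            best_score[better] = score[better]
            best_elem[better] = e[better]
            best_bary[better] = w[better]
        miss = elem < 0
        if miss.any():
            # clamp onto the nearest candidate element
            w = np.clip(best_bary[miss], 0.0, None)
            w /= w.sum(axis=1, keepdims=True)
            elem[miss] = best_elem[miss]
            bary[miss] = w
        return elem, bary

    def anchor_positions(self, elem: np.ndarray, bary: np.ndarray) -> np.ndarray:
        """Current positions of anchored points (element + barycentric)."""
        tri = self.nodes[self.elements[elem]]
        return np.einsum("pk,pkd->pd", bary, tri)

    def interpolate_nodal(self, values: np.ndarray, elem: np.ndarray,
                          bary: np.ndarray) -> np.ndarray:
        """Interpolate a nodal field at anchored points."""
        return np.einsum("pk,pk->p", bary, values[self.elements[elem]])


# ----------------------------------------------------------------------
# construction
# ----------------------------------------------------------------------

def _halfwidth_profile(g: GeometryParams):
    """Monotone-smooth half-width h(y) for the primordium outline."""
    hw = g.width / 2.0
    hp = g.petiole_width / 2.0
    ht = g.tip_width_frac * hw
    lp, la = g.petiole_length, g.lamina_length
    # control points: constant petiole, widest at widest_frac of the lamina,
    # tapering to a rounded tip
    ys = np.array([0.0, lp * 0.999, lp + g.widest_frac * la,
                   lp + 0.8 * la, lp + la])
    hs = np.array([hp, hp, hw, 0.55 * hw + 0.45 * ht, ht])
    return PchipInterpolator(ys, hs)


def build_initial_canvas(geometry: GeometryParams | None = None) -> Canvas:
    """Build the initial primordium mesh.

    A structured grid in (across, along) parameter space is mapped onto the
    outline so the default resolution yields exactly 3000 triangles, a node
    column runs exactly along the midline, and the petiole-lamina boundary
    coincides with a node row.  Quads are split along alternating diagonals
    to avoid directional mesh bias.
    """
    g = geometry or GeometryParams()
    g.validate()
    h = _halfwidth_profile(g)
    total_len = g.petiole_length + g.lamina_length

    nu, nv = g.n_across, g.n_along
    # snap a grid row onto the petiole-lamina boundary
    yrows = np.linspace(0.0, total_len, nv + 1)
    j_plb = int(np.argmin(np.abs(yrows - g.petiole_length)))
    yrows[j_plb] = g.petiole_length

    hw = h(yrows)
    if (hw <= 0).any():
        raise CanvasError("outline half-width must stay positive")
    u = np.linspace(-1.0, 1.0, nu + 1)
    X = np.outer(hw, u)                      # (nv+1, nu+1)
    Y = np.repeat(yrows[:, None], nu + 1, axis=1)
    nodes = np.stack([X.ravel(), Y.ravel()], axis=1)

    def nid(j, i):
        return j * (nu + 1) + i

    elements = []
    for j in range(nv):
        for i in range(nu):
            n00, n10 = nid(j, i), nid(j, i + 1)
            n01, n11 = nid(j + 1, i), nid(j + 1, i + 1)
            if (i + j) % 2 == 0:
                elements.append((n00, n10, n11))
                elements.append((n00, n11, n01))
            else:
                elements.append((n00, n10, n01))
                elements.append((n10, n11, n01))
    elements = np.asarray(elements, dtype=np.int64)

    boundary = np.concatenate([
        [nid(0, i) for i in range(nu + 1)],          # base, left -> right
        [nid(j, nu) for j in range(1, nv + 1)],      # right flank
        [nid(nv, i) for i in range(nu - 1, -1, -1)], # tip row, right -> left
        [nid(j, 0) for j in range(nv - 1, 0, -1)],   # left flank
    ]).astype(np.int64)

    mid_col = nu // 2
    midline = np.array([nid(j, mid_col) for j in range(nv + 1)], dtype=np.int64)
    base = np.array([nid(0, i) for i in range(nu + 1)], dtype=np.int64)

    canvas = Canvas(
        nodes=nodes,
        elements=elements,
        boundary=boundary,
        midline_nodes=midline,
        plb_node=int(nid(j_plb, mid_col)),
        base_nodes=base,
        geometry=g,
    )
    areas = canvas.element_areas()
    if (areas <= 0).any():
        raise CanvasError("degenerate outline produced inverted elements")
    return canvas


def build_rectangle_canvas(width: float, height: float, n_across: int = 10,
                           n_along: int = 20,
                           plb_frac: float = 0.25) -> Canvas:
    """Rectangular canvas (tests, idealised geometries).

    The base edge is at y = 0, the midline at x = 0; the petiole-lamina
    boundary marker sits at ``plb_frac`` of the height.
    """
    if width <= 0 or height <= 0:
        raise CanvasError("degenerate outline: rectangle must have area")
    if n_across % 2:
        raise CanvasError("n_across must be even")
    nu, nv = n_across, n_along
    u = np.linspace(-width / 2, width / 2, nu + 1)
    yrows = np.linspace(0.0, height, nv + 1)
    j_plb = int(np.argmin(np.abs(yrows - plb_frac * height)))
    X, Y = np.meshgrid(u, yrows)
    nodes = np.stack([X.ravel(), Y.ravel()], axis=1)

    def nid(j, i):
        return j * (nu + 1) + i

    elements = []
    for j in range(nv):
        for i in range(nu):
            n00, n10 = nid(j, i), nid(j, i + 1)
            n01, n11 = nid(j + 1, i), nid(j + 1, i + 1)
            if (i + j) % 2 == 0:
                elements.append((n00, n10, n11))
                elements.append((n00, n11, n01))
            else:
                elements.append((n00, n10, n01))
                elements.append((n10, n11, n01))
    boundary = np.concatenate([
        [nid(0, i) for i in range(nu + 1)],
        [nid(j, nu) for j in range(1, nv + 1)],
        [nid(nv, i) for i in range(nu - 1, -1, -1)],
        [nid(j, 0) for j in range(nv - 1, 0, -1)],
    ]).astype(np.int64)
    mid_col = nu // 2
    return Canvas(
        nodes=nodes,
        elements=np.asarray(elements, dtype=np.int64),
        boundary=boundary,
        midline_nodes=np.array([nid(j, mid_col) for j in range(nv + 1)],
                               dtype=np.int64),
        plb_node=int(nid(j_plb, mid_col)),
        base_nodes=np.array([nid(0, i) for i in range(nu + 1)],
                            dtype=np.int64),
        geometry=None,
    )


def measure_leaf(canvas: Canvas) -> dict:
    """Organ-scale measurements: width (mm), area (mm²), nodal distance field (μm)."""
    return {
        "width_mm": canvas.width() / 1000.0,
        "area_mm2": canvas.area() / 1e6,
        "distance_to_plb_um": canvas.distance_to_plb(canvas.nodes),
    }
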