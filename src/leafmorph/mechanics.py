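"""Growth mechanics: from specified to resultant deformation.

Each element carries a *specified* growth tensor -- rates parallel and
perpendicular to its local polarity axis.  Over a step ``dt`` the element's
target deformation is a pure stretch by ``1 + k_par*dt`` along polarity and
``1 + k_per*dt`` across it.  Because neighbouring elements may specify
incompatible deformations, realized node positions are found by a
least-squares elastic-mismatch relaxation: minimise the area-weighted
Frobenius misfit between each element's realized and target deformation
gradients.  When the specified field is compatible (in particular, spatially
uniform), the misfit is exactly zero and resultant growth equals specified
growth; otherwise tissue connectivity redistributes the conflict, which is
the behaviour the model requires of the mechanics.

The misfit functional is quadratic in node positions and separable in x and
y, so each step costs two sparse solves with a shared factorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import factorized

from leafmorph.canvas import Canvas


class GrowthStepError(RuntimeError):
    """Raised when a growth step would invert elements; retry with smaller dt."""


@dataclass
class SpecifiedGrowth:
    """Per-element specified growth: rates (h⁻¹) and polarity axis.

    ``polarity`` holds unit vectors (M, 2); ``k_par`` applies along them,
    ``k_per`` across.  Both rates must be nonnegative -- every model formula
    is a product of nonnegative factors.
    """

    k_par: np.ndarray
    k_per: np.ndarray
    polarity: np.ndarray

    @classmethod
    def uniform(cls, n_elements: int, k_par: float, k_per: float,
                angle: float = np.pi / 2) -> "SpecifiedGrowth":
        d = np.array([np.cos(angle), np.sin(angle)])
        return cls(
            k_par=np.full(n_elements, float(k_par)),
            k_per=np.full(n_elements, float(k_per)),
            polarity=np.tile(d, (n_elements, 1)),
        )

    def validate(self, n_elements: int) -> None:
        for name, arr in (("k_par", self.k_par), ("k_per", self.k_per)):
            if len(arr) != n_elements:
                raise ValueError(f"{name} must be defined on every element")
            if (arr < 0).any():
                raise ValueError(f"{name} must be nonnegative")
        if self.polarity.shape != (n_elements, 2):
            raise ValueError("polarity must be (M, 2) unit vectors")


def _target_tensors(spec: SpecifiedGrowth, dt: float) -> np.ndarray:
    """Per-element target deformation F_t = R diag(1+k_par dt, 1+k_per dt) Rᵀ."""
    d = spec.polarity
    c, s = d[:, 0], d[:, 1]
    lp = 1.0 + spec.k_par * dt
    lq = 1.0 + spec.k_per * dt
    F = np.empty((len(lp), 2, 2))
    F[:, 0, 0] = lp * c * c + lq * s * s
    F[:, 0, 1] = (lp - lq) * c * s
    F[:, 1, 0] = F[:, 0, 1]
    F[:, 1, 1] = lp * s * s + lq * c * c
    return F


def _shape_gradients(canvas: Canvas):
    """Reference edge-matrix inverses B = D_ref⁻¹ per element, plus areas."""
    p = canvas.nodes[canvas.elements]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    B = np.empty((len(det), 2, 2))
    B[:, 0, 0] = d2[:, 1] / det
    B[:, 0, 1] = -d2[:, 0] / det
    B[:, 1, 0] = -d1[:, 1] / det
    B[:, 1, 1] = d1[:, 0] / det
    return B, 0.5 * det


def step_growth(canvas: Canvas, spec: SpecifiedGrowth, dt: float,
                max_substeps: int = 8) -> Canvas:
    """Advance the canvas by one growth step of duration ``dt`` (hours).

    Node positions are chosen to minimise the area-weighted misfit between
    realized and target per-element deformation gradients, with the rigid
    translation fixed by holding the base-edge mean position.  If the relaxed
    configuration would invert elements, the step is retried with internal
    sub-stepping before giving up.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    spec.validate(canvas.element_count)

    try:
        return _single_step(canvas, spec, dt)
    except GrowthStepError:
        pass
    n_sub = 2
    while n_sub <= max_substeps:
        try:
            out = canvas
            for _ in range(n_sub):
                out = _single_step(out, spec, dt / n_sub)
            return out
        except GrowthStepError:
            n_sub *= 2
    raise GrowthStepError(
        f"growth step dt={dt} h inverted elements even with {max_substeps} substeps")


def _single_step(canvas: Canvas, spec: SpecifiedGrowth, dt: float) -> Canvas:
    B, areas = _shape_gradients(canvas)
    Ft = _target_tensors(spec, dt)
    M = canvas.element_count
    N = len(canvas.nodes)
    w = np.sqrt(areas / areas.mean())

    # rows: 2 per element (deformation-gradient components for one coordinate);
    # the same sparse operator serves both the x and y systems.
    ele = canvas.elements
    # element e contributes rows 2e (b=0) and 2e+1 (b=1);
    # coefficient layout per row (b): [-(B[0,b]+B[1,b]), B[0,b], B[1,b]]
    rows = np.repeat(np.arange(2 * M), 3)
    coef = np.empty((M, 2, 3))
    coef[:, :, 1] = np.stack([B[:, 0, 0], B[:, 0, 1]], axis=1)
    coef[:, :, 2] = np.stack([B[:, 1, 0], B[:, 1, 1]], axis=1)
    coef[:, :, 0] = -(coef[:, :, 1] + coef[:, :, 2])
    coef *= w[:, None, None]
    cols = np.tile(ele[:, None, :], (1, 2, 1)).reshape(-1)
    data = coef.reshape(-1)
    A = sp.csr_matrix((data, (rows, cols)), shape=(2 * M, N))

    # translation constraint: mean base-node position is held
    nb = len(canvas.base_nodes)
    cvec = np.zeros(N)
    cvec[canvas.base_nodes] = 1.0 / nb
    crow = sp.csr_matrix(cvec)

    K = (A.T @ A + crow.T @ crow).tocsc()
    solve = factorized(K)

    new_nodes = np.empty_like(canvas.nodes)
    base_mean = canvas.nodes[canvas.base_nodes].mean(axis=0)
    for a in range(2):
        f = (Ft[:, a, :] * w[:, None]).reshape(-1)
        rhs = A.T @ f + cvec * base_mean[a]
        new_nodes[:, a] = solve(rhs)

    out = canvas.copy()
    out.nodes = new_nodes
    out._invalidate_cache()
    if not out.is_valid():
        raise GrowthStepError("element inversion during relaxation")
    return out


# ----------------------------------------------------------------------
# resultant growth measurement
# ----------------------------------------------------------------------

def _log_stretch(F: np.ndarray) -> np.ndarray:
    """Per-element log right-stretch tensor: 0.5·log(FᵀF), closed form 2x2."""
    C = np.einsum("eki,ekj->eij", F, F)
    # symmetric 2x2 eigendecomposition
    a, b, d = C[:, 0, 0], C[:, 0, 1], C[:, 1, 1]
    tr, det = a + d, a * d - b * b
    disc = np.sqrt(np.maximum((a - d) ** 2 / 4 + b * b, 0.0))
    l1 = tr / 2 + disc
    l2 = tr / 2 - disc
    l2 = np.maximum(l2, det / np.maximum(l1, 1e-300))  # numerical floor
    # eigenvector for l1
    v1 = np.where(
        (np.abs(b) > 1e-14)[:, None],
        np.stack([b, l1 - a], axis=1),
        np.where((a >= d)[:, None],
                 np.tile([1.0, 0.0], (len(a), 1)),
                 np.tile([0.0, 1.0], (len(a), 1))),
    )
    v1 /= np.linalg.norm(v1, axis=1, keepdims=True)
    v2 = np.stack([-v1[:, 1], v1[:, 0]], axis=1)
    h1 = 0.5 * np.log(l1)
    h2 = 0.5 * np.log(l2)
    L = (h1[:, None, None] * np.einsum("ei,ej->eij", v1, v1)
         + h2[:, None, None] * np.einsum("ei,ej->eij", v2, v2))
    return L


def midline_axes(canvas: Canvas) -> np.ndarray:
    """Per-element unit tangent of the midline material curve at the
    element's proximodistal station (the axis 'parallel to the midline')."""
    pts = canvas.nodes[canvas.midline_nodes]
    ys = pts[:, 1]
    tang = np.gradient(pts, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    cy = canvas.element_centroids()[:, 1]
    order = np.argsort(ys)
    tx = np.interp(cy, ys[order], tang[order, 0])
    ty = np.interp(cy, ys[order], tang[order, 1])
    ax = np.stack([tx, ty], axis=1)
    return ax / np.linalg.norm(ax, axis=1, keepdims=True)


def resultant_growth(canvas_t1: Canvas, canvas_t2: Canvas, dt: float,
                     axes: np.ndarray | None = None) -> dict:
    """Per-element resultant growth rates between two canvas states.

    Returns areal, midline-parallel and midline-perpendicular rates (h⁻¹),
    from the deformation gradient of each element: areal rate is
    ``ln(det F)/dt``; directional rates are projections of the log
    right-stretch tensor onto the midline axis of the *earlier* canvas, so
    parallel + perpendicular = areal exactly (trace identity).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if canvas_t1.elements is not canvas_t2.elements and not np.array_equal(
            canvas_t1.elements, canvas_t2.elements):
        raise ValueError("canvases must share mesh topology")

    B, _ = _shape_gradients(canvas_t1)
    p = canvas_t2.nodes[canvas_t2.elements]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    D2 = np.stack([d1, d2], axis=2)  # columns
    F = np.einsum("eab,ebc->eac", D2, B)

    detF = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
    L = _log_stretch(F) / dt
    if axes is None:
        axes = midline_axes(canvas_t1)
    perp = np.stack([-axes[:, 1], axes[:, 0]], axis=1)
    par_rate = np.einsum("ei,eij,ej->e", axes, L, axes)
    per_rate = np.einsum("ei,eij,ej->e", perp, L, perp)
    return {
        "areal": np.log(detF) / dt,
        "parallel": par_rate,
        "perpendicular": per_rate,
    }
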