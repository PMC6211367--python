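"""Regulatory factors and the growth regulatory network (KRN).

Factor inventory
----------------
Tissue-fixed, advected with the canvas (nodal concentrations, no diffusion):

* ``PGRAD`` -- proximodistal gradient, 1 at the base declining to a floor of
  ``b_pgrad`` distally; promotes growth parallel to polarity.
* ``MID`` -- midline stripe; inhibits growth perpendicular to polarity.
* ``LAM`` -- lamina marker, high in the lamina and low in the petiole;
  promotes perpendicular growth.
* ``PROXORG`` -- organiser of polarity, 1 on the base edge.

Diffusible:

* ``POL`` -- polarity factor, clamped to ``b_pol`` over PROXORG; its
  negative gradient sets the distally pointing polarity axis.
* ``PMF`` -- proximal mobile factor, held at 1 on a band at the
  petiole-lamina boundary, diffusing distally with decay; its thresholds
  define the division-competence corridors.

Global temporal factors:

* ``LATE`` -- rises from 148 h and drives growth decline / division arrest;
  in mature-stage variants it switches to exponential rise at 189 h.
* ``EARLYGROWTH`` -- 1 until 189 h, then declines linearly to 0.

Growth rates are products of ``pro``/``inh`` terms of these factors; each
model variant uses the formula set given in the model definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from leafmorph.canvas import Canvas
from leafmorph.mechanics import SpecifiedGrowth

# ----------------------------------------------------------------------
# elementary regulatory functions
# ----------------------------------------------------------------------

def pro(p, i):
    """Linear promotion multiplier 1 + p·i (elementwise)."""
    return 1.0 + p * np.asarray(i)


def inh(h, i):
    """Saturating inhibition multiplier 1 / (1 + h·i) (elementwise)."""
    return 1.0 / (1.0 + h * np.asarray(i))


# ----------------------------------------------------------------------
# parameters and variants
# ----------------------------------------------------------------------

@dataclass
class KRNParams:
    """Growth-regulatory-network parameters.

    Defaults are the published model parameter set; rates are per hour.
    ``d_pmf`` is in mm²·h⁻¹ with ``pmf_length_calibration`` a dimensionless
    calibration factor fixed so that the PMF thresholds 0.295 and 0.184 sit
    at roughly 300 μm and 400 μm from the petiole-lamina boundary in the
    early presets -- the stated correspondence between thresholds and
    corridor distances.  ``d_pol`` is a calibration (not part of the
    published table) chosen so POL spans the initial primordium smoothly
    within the 20 setup steps.
    """

    # polarity
    b_pol: float = 0.1
    mu_pol: float = 0.1           # h⁻¹
    d_pol: float = 5000.0         # μm² h⁻¹, calibration
    # growth
    b_pgrad: float = 0.195
    g_late: float = 0.0048        # h⁻¹
    p_pgrad: float = 0.041        # h⁻¹
    p_lam: float = 0.0235         # h⁻¹
    p_late: float = 0.7
    h_late: float = 2.2
    h_mid: float = 1.0
    mu_pmf: float = 0.3           # h⁻¹
    d_pmf: float = 0.01           # mm² h⁻¹
    p_pmf: float = 0.9
    pmf_length_calibration: float = 2.6
    pmftk_cap: float = 0.295
    # temporal breakpoints (h)
    late_onset: float = 148.0
    late_exp_onset: float = 189.0
    earlygrowth_onset: float = 189.0
    earlygrowth_slope: float = 0.0417  # h⁻¹
    # mature-stage inhibition coefficients
    h_eg_par: float = 0.24
    h_eg_per: float = 2.8
    # limit-free distal-inhibition coefficients
    lf_relief: float = 1.5
    lf_lam: float = 2.0
    lf_pgrad: float = 4.0
    lf_late_per: float = 1.2
    # limiting-cell-size thresholds (μm²)
    lcs_lamina: tuple = (4000.0, 8000.0)
    lcs_midline: tuple = (18000.0, 20000.0)
    # initial-profile calibrations
    mid_halfwidth: float = 14.0   # μm, half-width of the (widened) MID stripe
    lam_rise: float = 15.0        # μm, LAM sigmoid length scale at the plb
    pmf_dilution: bool = True     # PMF concentration diluted by growth

    @property
    def pmf_diffusion_um2(self) -> float:
        """Effective PMF diffusion coefficient, μm² h⁻¹."""
        return self.d_pmf * 1e6 * self.pmf_length_calibration

    @property
    def pmf_decay_length(self) -> float:
        """Static-domain decay length λ = sqrt(D/μ), μm."""
        return float(np.sqrt(self.pmf_diffusion_um2 / self.mu_pmf))


_EARLY = {"subepidermis_early", "epidermis_early"}
_MATURE_FORMULA = {"mature", "plate", "chamber_tuned"}
_KNOWN = _EARLY | _MATURE_FORMULA | {"limit_free", "limiting_cell_size"}


@dataclass
class ModelVariant:
    """A base model variant plus optional mutant modifiers.

    ``a_prime`` (μm²) offsets the lamina division target, ``k_prime``
    globally scales specified growth rates, ``t_prime`` (h) shifts the
    LATE/EARLYGROWTH schedule.  ``physiological_ratio`` compresses model
    ("physiological") time relative to actual time; growth-rate magnitudes
    scale with it while diffusion runs in actual time.
    """

    name: str
    a_prime: float = 0.0
    k_prime: float = 1.0
    t_prime: float = 0.0
    physiological_ratio: float = 1.0

    def __post_init__(self):
        if self.name not in _KNOWN:
            raise ValueError(f"unknown variant {self.name!r}; "
                             f"choose from {sorted(_KNOWN)}")
        if self.name == "plate":
            # plate-grown preset: slowed physiology and globally scaled rates
            if self.physiological_ratio == 1.0:
                self.physiological_ratio = 0.55
            if self.k_prime == 1.0:
                self.k_prime = 0.6
        elif self.name == "chamber_tuned":
            if self.physiological_ratio == 1.0:
                self.physiological_ratio = 0.75

    @property
    def layer(self) -> str:
        return "subepidermis" if self.name == "subepidermis_early" else "epidermis"

    @property
    def is_early(self) -> bool:
        return self.name in _EARLY

    @property
    def has_exponential_late(self) -> bool:
        return not self.is_early

    @property
    def rate_scale(self) -> float:
        """Net scaling of actual-time growth rates (k′ × physiological ratio)."""
        return self.k_prime * self.physiological_ratio

    def physiological_time(self, t: float, t_start: float = 87.0) -> float:
        """Map actual time to physiological time τ = t₀ + ratio·(t − t₀)."""
        return t_start + self.physiological_ratio * (t - t_start)

    def with_modifiers(self, **kw) -> "ModelVariant":
        return replace(self, **kw)


# ----------------------------------------------------------------------
# temporal factors
# ----------------------------------------------------------------------

def late_factor(t, params: KRNParams | None = None,
                variant: ModelVariant | None = None):
    """Temporal factor LATE at (physiological) time ``t`` in hours.

    Zero before onset (148 h), rising linearly with slope ``g_late``; in
    mature-stage variants it continues exponentially after 189 h with the
    branch constants chosen for continuity at the breakpoint.  A LATE-shift
    mutant displaces both breakpoints by ``t_prime``.
    """
    p = params or KRNParams()
    tp = variant.t_prime if variant is not None else 0.0
    t = np.asarray(t, dtype=float)
    t0 = p.late_onset + tp
    t1 = p.late_exp_onset + tp
    lin = np.where(t < t0, 0.0, p.g_late * (t - t0))
    if variant is not None and variant.has_exponential_late:
        span = p.late_exp_onset - p.late_onset        # 41 h
        B = 1.0 / span
        expo = p.g_late * span * np.exp(B * (t - t1))
        out = np.where(t >= t1, expo, lin)
    else:
        out = lin
    return out if out.ndim else float(out)


def earlygrowth_factor(t, variant: ModelVariant | None = None,
                       params: KRNParams | None = None):
    """Temporal factor EARLYGROWTH: 1 until 189 h, then a linear decline
    at 0.0417 h⁻¹ clamped at 0 (breakpoint shifted by t′ in LATE mutants)."""
    p = params or KRNParams()
    tp = variant.t_prime if variant is not None else 0.0
    t = np.asarray(t, dtype=float)
    t1 = p.earlygrowth_onset + tp
    out = np.clip(1.0 - p.earlygrowth_slope * np.maximum(t - t1, 0.0), 0.0, 1.0)
    return out if out.ndim else float(out)


# ----------------------------------------------------------------------
# factor state
# ----------------------------------------------------------------------

@dataclass
class FactorState:
    """All regulatory fields at one time point.

    Nodal arrays: ``pgrad, mid, lam, proxorg, pol, pmf``; per-element
    polarity unit vectors; scalars ``late`` and ``earlygrowth`` evaluated
    at the variant's physiological time.
    """

    pgrad: np.ndarray
    mid: np.ndarray
    lam: np.ndarray
    proxorg: np.ndarray
    pol: np.ndarray
    pmf: np.ndarray
    polarity: np.ndarray
    late: float = 0.0
    earlygrowth: float = 1.0
    pmftk_cap: float = 0.295

    @property
    def pmftk(self) -> np.ndarray:
        """PMF capped at 0.295 (the growth-promoting reading of PMF)."""
        return np.minimum(self.pmf, self.pmftk_cap)

    def copy(self) -> "FactorState":
        return FactorState(
            pgrad=self.pgrad.copy(), mid=self.mid.copy(), lam=self.lam.copy(),
            proxorg=self.proxorg.copy(), pol=self.pol.copy(),
            pmf=self.pmf.copy(), polarity=self.polarity.copy(),
            late=self.late, earlygrowth=self.earlygrowth,
            pmftk_cap=self.pmftk_cap,
        )


# ----------------------------------------------------------------------
# finite-element helpers (P1 diffusion-decay on the current mesh)
# ----------------------------------------------------------------------

def fem_matrices(canvas: Canvas):
    """Lumped mass vector and stiffness matrix for P1 elements."""
    ele = canvas.elements
    p = canvas.nodes[ele]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    area = 0.5 * det
    # shape-function gradients
    g = np.empty((len(ele), 3, 2))
    g[:, 1, 0] = d2[:, 1] / det
    g[:, 1, 1] = -d2[:, 0] / det
    g[:, 2, 0] = -d1[:, 1] / det
    g[:, 2, 1] = d1[:, 0] / det
    g[:, 0] = -(g[:, 1] + g[:, 2])
    Ke = np.einsum("eid,ejd->eij", g, g) * area[:, None, None]
    rows = np.repeat(ele, 3, axis=1).reshape(-1)
    cols = np.tile(ele, (1, 3)).reshape(-1)
    K = sp.csr_matrix((Ke.reshape(-1), (rows, cols)),
                      shape=(len(canvas.nodes),) * 2)
    mass = np.zeros(len(canvas.nodes))
    np.add.at(mass, ele.reshape(-1), np.repeat(area / 3.0, 3))
    return mass, K


def nodal_gradient_per_element(canvas: Canvas, values: np.ndarray) -> np.ndarray:
    """Per-element gradient of a nodal P1 field."""
    ele = canvas.elements
    p = canvas.nodes[ele]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    v = values[ele]
    gx = ((v[:, 1] - v[:, 0]) * d2[:, 1] - (v[:, 2] - v[:, 0]) * d1[:, 1]) / det
    gy = ((v[:, 2] - v[:, 0]) * d1[:, 0] - (v[:, 1] - v[:, 0]) * d2[:, 0]) / det
    return np.stack([gx, gy], axis=1)


def recovered_gradient(canvas: Canvas, values: np.ndarray) -> np.ndarray:
    """Per-element gradient smoothed by area-weighted nodal recovery.

    Raw P1 gradients alternate with the triangulation's diagonal parity;
    averaging to nodes and back cancels that artifact, which matters where
    the direction of a weak gradient is needed (polarity)."""
    g = nodal_gradient_per_element(canvas, values)
    areas = canvas.element_areas()
    ele = canvas.elements
    num = np.zeros((len(canvas.nodes), 2))
    den = np.zeros(len(canvas.nodes))
    w = (g * areas[:, None])
    for k in range(3):
        np.add.at(num, ele[:, k], w)
        np.add.at(den, ele[:, k], areas)
    gn = num / den[:, None]
    return gn[ele].mean(axis=1)


def _diffusion_decay_step(canvas: Canvas, c: np.ndarray, D: float, mu: float,
                          dt: float, dirichlet_nodes: np.ndarray,
                          dirichlet_value: float) -> np.ndarray:
    """One implicit-Euler step of ∂c/∂t = D ∇²c − μc with a Dirichlet band.

    Implicit Euler implies pure decay of an interior value v over one step
    is v/(1 + μ·dt) when D = 0 (documented scheme choice); the scheme is
    unconditionally stable on the growing mesh.
    """
    mass, K = fem_matrices(canvas)
    n = len(c)
    A = sp.diags(mass * (1.0 + mu * dt)) + (D * dt) * K
    b = mass * c
    A = A.tolil()
    for idx in dirichlet_nodes:
        A.rows[idx] = [idx]
        A.data[idx] = [1.0]
    b[dirichlet_nodes] = dirichlet_value
    return spsolve(A.tocsr(), b)


def update_pmf(canvas: Canvas, pmf: np.ndarray, dt: float,
               params: KRNParams) -> np.ndarray:
    """Advance PMF by ``dt`` hours on the current mesh.

    PMF is held at 1 on the material band of nodes straddling the
    petiole-lamina boundary and undergoes diffusion-decay elsewhere.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    band = _plb_band(canvas)
    out = _diffusion_decay_step(canvas, pmf, params.pmf_diffusion_um2,
                                params.mu_pmf, dt, band, 1.0)
    return np.clip(out, 0.0, 1.0)


def steady_pmf(canvas: Canvas, params: KRNParams) -> np.ndarray:
    """Stationary PMF profile (used to initialise the field at setup)."""
    band = _plb_band(canvas)
    mass, K = fem_matrices(canvas)
    A = (sp.diags(mass * params.mu_pmf)
         + params.pmf_diffusion_um2 * K).tolil()
    b = np.zeros(len(canvas.nodes))
    for idx in band:
        A.rows[idx] = [idx]
        A.data[idx] = [1.0]
    b[band] = 1.0
    return np.clip(spsolve(A.tocsr(), b), 0.0, 1.0)


def _plb_band(canvas: Canvas) -> np.ndarray:
    """Node band straddling the petiole-lamina boundary (material row)."""
    y_plb = canvas.nodes[canvas.plb_node, 1]
    ys = canvas.nodes[canvas.midline_nodes, 1]
    # half the local midline node spacing at the boundary
    k = int(np.searchsorted(np.sort(ys), y_plb))
    spacing = np.diff(np.sort(ys))
    half = 0.55 * spacing[min(max(k - 1, 0), len(spacing) - 1)]
    d = np.abs(canvas.nodes[:, 1] - y_plb)
    return np.where(d <= half)[0]


# ----------------------------------------------------------------------
# initial profiles and polarity
# ----------------------------------------------------------------------

def initial_profiles(canvas: Canvas, params: KRNParams) -> dict:
    """Analytic initial distributions of the tissue-fixed factors.

    PGRAD declines linearly from 1 at the base to ``b_pgrad`` at the tip;
    MID is a smooth stripe about the midline with half-width
    ``mid_halfwidth``; LAM rises sigmoidally from petiole to lamina across
    the petiole-lamina boundary; PROXORG marks the base edge.
    """
    x, y = canvas.nodes[:, 0], canvas.nodes[:, 1]
    L = y.max() - y.min()
    pgrad = 1.0 - (1.0 - params.b_pgrad) * (y - y.min()) / L
    mid = 1.0 / (1.0 + (np.abs(x) / params.mid_halfwidth) ** 6)
    d = canvas.distance_to_plb(canvas.nodes)
    lam = 1.0 / (1.0 + np.exp(-d / params.lam_rise))
    proxorg = np.zeros(len(x))
    proxorg[canvas.base_nodes] = 1.0
    return {"pgrad": pgrad, "mid": mid, "lam": lam, "proxorg": proxorg}


def establish_polarity(canvas: Canvas, proxorg: np.ndarray,
                       params: KRNParams, n_setup_steps: int = 20):
    """Establish POL by diffusion from the base and derive element polarity.

    POL is clamped to ``b_pol`` wherever PROXORG > 0 and diffuses with decay
    for 20 setup steps (1 h each) before growth starts.  The polarity axis
    of each element is the direction of −∇POL (pointing distally, down the
    gradient); elements with a vanishing gradient inherit the axis of the
    nearest resolved neighbour.
    """
    src = np.where(proxorg > 0)[0]
    pol = np.zeros(len(canvas.nodes))
    pol[src] = params.b_pol
    for _ in range(n_setup_steps):
        pol = _diffusion_decay_step(canvas, pol, params.d_pol, params.mu_pol,
                                    1.0, src, params.b_pol)
    pol = np.clip(pol, 0.0, params.b_pol)
    grad = recovered_gradient(canvas, pol)
    norm = np.linalg.norm(grad, axis=1)
    # a gradient far below the field's own scale (e.g. at the no-flux distal
    # edge) has a noise-dominated direction: treat as undefined and inherit
    ok = norm > max(1e-14, 0.08 * norm.max())
    polarity = np.zeros_like(grad)
    polarity[ok] = -grad[ok] / norm[ok, None]
    if (~ok).any():
        polarity = _fill_undefined(canvas, polarity, ok)
    return pol, polarity


def _fill_undefined(canvas: Canvas, polarity: np.ndarray,
                    ok: np.ndarray) -> np.ndarray:
    """Propagate polarity into elements where the gradient vanished."""
    from scipy.spatial import cKDTree

    cent = canvas.element_centroids()
    tree = cKDTree(cent[ok])
    _, j = tree.query(cent[~ok])
    polarity[~ok] = polarity[ok][j]
    return polarity


def advect_polarity(polarity: np.ndarray, canvas_before: Canvas,
                    canvas_after: Canvas) -> np.ndarray:
    """Push polarity vectors forward through a growth step (F·v, renormalised)."""
    from leafmorph.mechanics import _shape_gradients

    B, _ = _shape_gradients(canvas_before)
    p = canvas_after.nodes[canvas_after.elements]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    D2 = np.stack([d1, d2], axis=2)
    F = np.einsum("eab,ebc->eac", D2, B)
    v = np.einsum("eab,eb->ea", F, polarity)
    n = np.linalg.norm(v, axis=1, keepdims=True)
    return v / np.maximum(n, 1e-300)


def initialize_state(canvas: Canvas, params: KRNParams,
                     variant: ModelVariant) -> FactorState:
    """Set up all factor fields at the start of a simulation."""
    prof = initial_profiles(canvas, params)
    pol, polarity = establish_polarity(canvas, prof["proxorg"], params)
    pmf = steady_pmf(canvas, params)
    return FactorState(
        pgrad=prof["pgrad"], mid=prof["mid"], lam=prof["lam"],
        proxorg=prof["proxorg"], pol=pol, pmf=pmf, polarity=polarity,
        late=0.0, earlygrowth=1.0, pmftk_cap=params.pmftk_cap,
    )


# ----------------------------------------------------------------------
# specified growth
# ----------------------------------------------------------------------

def _nodal_to_element(canvas: Canvas, values: np.ndarray) -> np.ndarray:
    return values[canvas.elements].mean(axis=1)


def specified_growth(state: FactorState, params: KRNParams,
                     variant: ModelVariant, canvas: Canvas,
                     cell_area: np.ndarray | None = None) -> SpecifiedGrowth:
    """Evaluate the variant's growth formulas into per-element rates.

    ``state.late``/``state.earlygrowth`` must already be evaluated at the
    variant's physiological time.  The returned actual-time rates carry the
    mutant scale ``k_prime`` and the physiological-time compression: a
    variant running at ratio r realises r times the physiological-time rate
    per actual hour.  For the limiting-cell-size variant, ``cell_area``
    gives the area (μm²) of the v-cell over each element, and rates are
    scaled by ω = clamp((a₂ − ca)/(a₂ − a₁), 0, 1) with lamina and midline
    thresholds (4000, 8000) and (18000, 20000) μm².
    """
    pgrad = state.pgrad
    lam = state.lam
    mid = state.mid
    pmftk = state.pmftk
    il = state.late
    eg = state.earlygrowth

    name = variant.name
    if name in _EARLY:
        kpar = params.p_pgrad * pgrad * inh(params.h_late, il)
        kper = (params.p_lam * lam * pro(params.p_late, il)
                * inh(params.h_mid, mid) * pro(params.p_pmf, pmftk))
    elif name in _MATURE_FORMULA or name == "limiting_cell_size":
        kpar = (params.p_pgrad * pgrad * inh(params.h_late, il)
                * inh(params.h_eg_par, il * (1.0 - eg)))
        kper = (params.p_lam * lam * inh(params.h_mid, mid)
                * pro(params.p_pmf, pmftk) * pro(params.p_late, il * eg)
                * inh(params.h_eg_per, il * (1.0 - eg)))
    elif name == "limit_free":
        kpar = (params.p_pgrad * pgrad
                * inh(params.h_late, il * inh(params.lf_relief, 1.0 - eg))
                * inh(params.lf_lam, (1.0 - lam) * (1.0 - eg))
                * inh(params.lf_pgrad, (1.0 - pgrad) * (1.0 - eg)))
        kper = (params.p_lam * lam * inh(params.h_mid, mid)
                * pro(params.p_pmf, pmftk) * pro(params.p_late, il * eg)
                * inh(params.lf_late_per, il * (1.0 - eg))
                * inh(params.lf_pgrad, (1.0 - pgrad) * (1.0 - eg)))
    else:  # pragma: no cover - guarded by ModelVariant
        raise ValueError(f"unknown variant {name!r}")

    k_par_e = _nodal_to_element(canvas, kpar)
    k_per_e = _nodal_to_element(canvas, kper)

    if name == "limiting_cell_size":
        if cell_area is None:
            raise ValueError("limiting_cell_size requires per-element cell areas")
        mid_e = _nodal_to_element(canvas, mid) > 0.5
        a1 = np.where(mid_e, params.lcs_midline[0], params.lcs_lamina[0])
        a2 = np.where(mid_e, params.lcs_midline[1], params.lcs_lamina[1])
        omega = np.clip((a2 - cell_area) / (a2 - a1), 0.0, 1.0)
        k_par_e *= omega
        k_per_e *= omega

    scale = variant.rate_scale
    return SpecifiedGrowth(k_par=scale * k_par_e, k_per=scale * k_per_e,
                           polarity=state.polarity)
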