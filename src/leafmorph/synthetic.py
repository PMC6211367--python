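"""Synthetic tracking datasets with known ground truth.

Two sources:

* :func:`from_trajectory` exports a simulator trajectory as a
  :class:`~leafmorph.tracking.TrackingDataset` at a chosen sampling
  interval (about 12 h or 2 h, matching the two imaging regimes), with
  optional Gaussian vertex-click noise and occlusion-style dropout of
  contiguous cell patches.

* :func:`parametric_generate` builds a dataset from a fully prescribed
  process -- a Voronoi packing on a rectangle advected by a known growth
  field and divided by the noisy shortest-wall engine at a known threshold
  field -- and emits exact ground-truth tables, so every tracking metric
  has an analytically known answer to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from leafmorph.cells import CellComplex, polygon_area, polygon_centroid
from leafmorph.tracking import TrackingDataset


@dataclass
class SyntheticSpec:
    """Configuration of a synthetic dataset.

    ``growth_rates`` are linear elongation rates (h⁻¹) per axis, either a
    (kx, ky) pair or a callable ``f(points, t) -> (n, 2)`` field; a uniform
    isotropic pair (k, k) yields areal rate 2k everywhere.  ``abar`` is the
    mean division target (μm²), constant or callable ``f(points) -> (n,)``;
    division targets are drawn per cell at birth from normal(Ā, 0.2·Ā).
    ``vertex_noise_sd`` defaults to 0.5 μm, a sub-pixel stand-in for
    hand-clicked vertex error.
    """

    sampling_interval: float = 12.0
    t_start: float = 0.0
    t_end: float = 48.0
    vertex_noise_sd: float = 0.5
    dropout: float = 0.0
    seed: int = 0
    # parametric process
    domain: tuple = (0.0, 0.0, 300.0, 300.0)   # xmin, ymin, xmax, ymax
    mean_cell_area: float = 100.0
    growth_rates: object = (0.02, 0.02)
    abar: object = None                         # None -> no divisions
    sigma_frac: float = 0.2
    division_noise_frac: float = 0.25
    substep: float = 1.0

    def __post_init__(self):
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")
        if self.vertex_noise_sd < 0 or not (0 <= self.dropout < 1):
            raise ValueError("invalid noise/dropout settings")


# ----------------------------------------------------------------------
# export from a simulator trajectory
# ----------------------------------------------------------------------

def from_trajectory(traj, spec: SyntheticSpec):
    """Export a trajectory as a TrackingDataset plus ground truth.

    Vertices become tracked points at the sampled snapshot times with
    Gaussian positional noise; dropout removes contiguous patches of cells
    (with their whole lineage subtree, so retained lineages stay complete).
    Ground truth carries the simulator's division events and provenance.
    """
    rng = np.random.default_rng(spec.seed)
    snap_times = np.array([s.t for s in traj.snapshots])
    grid = np.arange(snap_times[0], snap_times[-1] + 1e-9,
                     spec.sampling_interval)
    picked = []
    for g in grid:
        k = int(np.argmin(np.abs(snap_times - g)))
        if abs(snap_times[k] - g) > 1e-6:
            raise ValueError(
                f"sampling grid point {g} h not covered by snapshots")
        picked.append(k)

    snaps = [traj.snapshots[k] for k in picked]
    drop_ids = _dropout_lineages(traj, snaps[0], spec, rng)

    vrows, crows, prows = [], [], []
    for snap in snaps:
        used = set()
        for c in snap.cells:
            if c["cid"] in drop_ids:
                continue
            crows.append({
                "t": snap.t, "cell_id": c["cid"],
                "vertices": " ".join(str(v) for v in c["vertices"]),
                "region": c["region"], "layer": c["layer"],
                "is_space": c["is_space"],
            })
            used.update(c["vertices"])
        used = np.array(sorted(used), dtype=int)
        xy = snap.vx_xy[used]
        if spec.vertex_noise_sd > 0:
            xy = xy + rng.normal(0.0, spec.vertex_noise_sd, xy.shape)
        for vid, p in zip(used, xy):
            vrows.append({"t": snap.t, "vertex_id": int(vid),
                          "x": p[0], "y": p[1]})
        prows.append({"t": snap.t, "x": snap.plb_xy[0], "y": snap.plb_xy[1]})

    lrows = []
    for ev in traj.division_events:
        if ev["parent"] in drop_ids:
            continue
        for d in ev["daughters"]:
            lrows.append({"parent_id": ev["parent"], "daughter_id": d,
                          "division_time": ev["time"]})

    ds = TrackingDataset(
        vertices=pd.DataFrame(vrows),
        cells=pd.DataFrame(crows),
        lineage=pd.DataFrame(lrows, columns=["parent_id", "daughter_id",
                                             "division_time"]),
        plb=pd.DataFrame(prows),
        metadata={
            "source": "trajectory",
            "sampling_interval": spec.sampling_interval,
            "vertex_noise_sd": spec.vertex_noise_sd,
            "dropout": spec.dropout,
            "midline_axis": (0.0, 1.0),
            "seed": spec.seed,
        },
    )
    truth = {
        "division_events": list(traj.division_events),
        "config": traj.config.provenance(),
    }
    return ds, truth


def _dropout_lineages(traj, first_snap, spec: SyntheticSpec, rng):
    """Pick a contiguous patch of cells at the first sampled time and drop
    it together with all descendants (occlusion-style dropout)."""
    if spec.dropout <= 0:
        return set()
    cells = [c for c in first_snap.cells if not c["is_space"]]
    n_drop = int(round(spec.dropout * len(cells)))
    if n_drop == 0:
        return set()
    # adjacency by shared vertices at the first sampled time
    by_vertex: dict = {}
    for c in cells:
        for v in c["vertices"]:
            by_vertex.setdefault(v, []).append(c["cid"])
    adj: dict = {c["cid"]: set() for c in cells}
    for inc in by_vertex.values():
        for a in inc:
            adj[a].update(b for b in inc if b != a)
    seed_cid = cells[rng.integers(len(cells))]["cid"]
    patch, frontier = {seed_cid}, [seed_cid]
    while frontier and len(patch) < n_drop:
        cur = frontier.pop(0)
        for nb in sorted(adj[cur]):
            if nb not in patch:
                patch.add(nb)
                frontier.append(nb)
                if len(patch) >= n_drop:
                    break
    # close under descent
    children: dict = {}
    for ev in traj.division_events:
        children[ev["parent"]] = list(ev["daughters"])
    out = set()
    stack = list(patch)
    while stack:
        cid = stack.pop()
        if cid in out:
            continue
        out.add(cid)
        stack.extend(children.get(cid, []))
    return out


# ----------------------------------------------------------------------
# parametric process
# ----------------------------------------------------------------------

def _rates_at(spec: SyntheticSpec, pts: np.ndarray, t: float) -> np.ndarray:
    g = spec.growth_rates
    if callable(g):
        return np.asarray(g(pts, t), dtype=float)
    return np.tile(np.asarray(g, dtype=float), (len(pts), 1))


def _abar_at(spec: SyntheticSpec, pts: np.ndarray) -> np.ndarray:
    a = spec.abar
    if a is None:
        return np.full(len(pts), np.inf)
    if callable(a):
        return np.asarray(a(pts), dtype=float)
    return np.full(len(pts), float(a))


def parametric_generate(spec: SyntheticSpec):
    """Generate a dataset from a prescribed growth/division process.

    Seeds a jittered-hexagonal Voronoi packing on the rectangle, advects
    vertices with the prescribed per-axis elongation rates (exact
    exponential update for uniform fields), divides cells by the noisy
    shortest-wall rule when area exceeds their drawn target, and samples
    the tessellation at the requested interval.  Returns the dataset and a
    ground-truth dict (true rates, per-division true Ā).
    """
    rng = np.random.default_rng(spec.seed)
    cc = _rect_packing(spec, rng)
    origin = np.array([(spec.domain[0] + spec.domain[2]) / 2.0,
                       spec.domain[1]])

    targets: dict = {}
    cids = [c.cid for c in cc.live_cells()]
    abar0 = _abar_at(spec, cc.centroids(cids))
    noise = np.maximum(1.0 + rng.normal(0.0, spec.sigma_frac, len(cids)), 0.3)
    for cid, ab, u in zip(cids, abar0, noise):
        targets[cid] = ab * u
    truth_divisions = []

    vrows, crows, prows = [], [], []
    t = spec.t_start
    next_sample = spec.t_start
    while True:
        if t >= next_sample - 1e-9:
            _record(cc, t, vrows, crows, prows, spec, rng, origin)
            next_sample += spec.sampling_interval
            if t >= spec.t_end - 1e-9:
                break
        dt = min(spec.substep, spec.t_end - t, next_sample - t)
        # advect: per-axis relative elongation about the domain origin
        rel = cc.vx_xy - origin
        k = _rates_at(spec, cc.vx_xy, t)
        cc.vx_xy = origin + rel * np.exp(k * dt)
        cc._invalidate_geometry()
        t += dt
        # fold check
        live = cc.live_cells()
        areas = cc.areas([c.cid for c in live])
        if (areas <= 0).any():
            bad = live[int(np.argmin(areas))]
            cen = polygon_centroid(cc.vx_xy[bad.vertices])
            raise ValueError(f"growth field folds the tissue near {cen}")
        if spec.abar is not None:
            for cell, area in zip(live, areas):
                if area >= targets[cell.cid]:
                    mother_cen = polygon_centroid(cc.vx_xy[cell.vertices])
                    out = cc.divide_cell(cell.cid, t, rng, _GEOM_PARAMS)
                    if out is None:
                        continue
                    da, db = out
                    cents = cc.centroids([da.cid, db.cid])
                    abars = _abar_at(spec, cents)
                    for d, ab in zip((da, db), abars):
                        u = max(1.0 + rng.normal(0.0, spec.sigma_frac), 0.3)
                        targets[d.cid] = ab * u
                    truth_divisions.append({
                        "parent": cell.cid, "time": t,
                        "mother_area": float(area),
                        "true_abar": float(
                            _abar_at(spec, mother_cen[None])[0]),
                    })

    lrows = []
    for ev in cc.events:
        for d in ev["daughters"]:
            lrows.append({"parent_id": ev["parent"], "daughter_id": d,
                          "division_time": ev["time"]})
    ds = TrackingDataset(
        vertices=pd.DataFrame(vrows),
        cells=pd.DataFrame(crows),
        lineage=pd.DataFrame(lrows, columns=["parent_id", "daughter_id",
                                             "division_time"]),
        plb=pd.DataFrame(prows),
        metadata={
            "source": "parametric",
            "sampling_interval": spec.sampling_interval,
            "vertex_noise_sd": spec.vertex_noise_sd,
            "dropout": 0.0,
            "midline_axis": (0.0, 1.0),
            "seed": spec.seed,
        },
    )
    truth = {
        "growth_rates": spec.growth_rates,
        "abar": spec.abar,
        "divisions": truth_divisions,
        "targets": targets,
    }
    return ds, truth


class _GeomOnly:
    noise_frac = 0.25
    shorten_frac = 0.05
    min_divisible_area = 4.0


_GEOM_PARAMS = _GeomOnly()


def _record(cc: CellComplex, t, vrows, crows, prows, spec, rng, origin):
    used = set()
    for c in cc.live_cells(include_spaces=True):
        crows.append({
            "t": t, "cell_id": c.cid,
            "vertices": " ".join(str(v) for v in c.vertices),
            "region": c.region, "layer": c.layer, "is_space": c.is_space,
        })
        used.update(c.vertices)
    used = np.array(sorted(used), dtype=int)
    xy = cc.vx_xy[used]
    if spec.vertex_noise_sd > 0:
        xy = xy + rng.normal(0.0, spec.vertex_noise_sd, xy.shape)
    for vid, p in zip(used, xy):
        vrows.append({"t": t, "vertex_id": int(vid), "x": p[0], "y": p[1]})
    prows.append({"t": t, "x": origin[0], "y": origin[1]})


def _rect_packing(spec: SyntheticSpec, rng) -> CellComplex:
    """Jittered-hexagonal Voronoi packing clipped to the domain rectangle."""
    from scipy.spatial import Voronoi
    from shapely.geometry import Point, Polygon, box

    xmin, ymin, xmax, ymax = spec.domain
    outline = box(xmin, ymin, xmax, ymax)
    spacing = np.sqrt(2.0 * spec.mean_cell_area / np.sqrt(3.0))
    pad = 3 * spacing
    xs = np.arange(xmin - pad, xmax + pad, spacing)
    ys = np.arange(ymin - pad, ymax + pad, spacing * np.sqrt(3) / 2)
    X, Y = np.meshgrid(xs, ys)
    X[::2] += spacing / 2
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    pts = pts + rng.uniform(-0.5, 0.5, pts.shape) * spacing

    vor = Voronoi(pts)
    cc = CellComplex(canvas=None)
    vertex_ids: dict = {}

    def vid_of(xy):
        key = (round(xy[0], 6), round(xy[1], 6))
        if key not in vertex_ids:
            on_bnd = outline.exterior.distance(Point(xy)) < 1e-6
            vertex_ids[key] = int(
                cc.add_vertices(np.array([xy]), boundary=[on_bnd])[0])
        return vertex_ids[key]

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
        ids = [v for k, v in enumerate(ids) if v != ids[k - 1]]
        if len(ids) < 3:
            continue
        cc.add_cell(ids, parent_id=None, birth_time=spec.t_start,
                    region="lamina", layer="epidermis")
    return cc
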