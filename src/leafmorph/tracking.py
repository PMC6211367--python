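"""Quantification of tracked-vertex datasets (real or synthetic).

A :class:`TrackingDataset` is the common tabular format for cell-resolution
time-lapse data: per-timepoint vertex coordinates, cell-vertex cycles with
region/layer labels, lineage links, and the petiole-lamina boundary
position.  The same format is produced by the synthetic generator
(:mod:`leafmorph.synthetic`) and can be populated from externally tracked
vertex tables.

Metrics implemented here: clone-aware relative areal growth rates
``ln(A2/A1)/(t2-t1)``, directional growth rates from per-cell affine fits
(log right-stretch tensor projected on the midline axis, so parallel +
perpendicular = areal), division-execution statistics with 1.96 x SEM
ranges, competence classification over a tracking interval, and
polygon-class (neighbour-number) distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FORMAT_VERSION = "1.0"


class LineageError(ValueError):
    """Raised when a metric needs lineage links that are missing/broken."""


@dataclass
class TrackingDataset:
    """Tabular tracked-vertex data.

    ``vertices``: columns (t, vertex_id, x, y) -- μm; vertex ids persist
    across timepoints (new-wall vertices appear at divisions).
    ``cells``: columns (t, cell_id, vertices, region, layer, is_space) with
    ``vertices`` a space-separated id cycle (CCW).
    ``lineage``: columns (parent_id, daughter_id, division_time).
    ``plb``: columns (t, x, y) -- petiole-lamina boundary position.
    ``metadata``: sampling interval, noise level, midline axis, source.
    """

    vertices: pd.DataFrame
    cells: pd.DataFrame
    lineage: pd.DataFrame
    plb: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self._vx_cache: dict = {}
        self._frame_cache: dict = {}

    # ------------------------------------------------------------- basics
    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.vertices["t"].unique())

    def _vx_at(self, t: float) -> dict:
        if t not in self._vx_cache:
            sub = self.vertices[self.vertices["t"] == t]
            self._vx_cache[t] = dict(
                zip(sub["vertex_id"], np.stack([sub["x"], sub["y"]], axis=1)))
        return self._vx_cache[t]

    def cells_at(self, t: float) -> pd.DataFrame:
        return self.cells[self.cells["t"] == t]

    def frame(self, t: float) -> dict:
        """Per-cell geometry at one timepoint: cell_id -> (area, centroid,
        region).  Cached; one vectorised pass per timepoint."""
        if t not in self._frame_cache:
            from leafmorph.cells import polygon_area, polygon_centroid

            vx = self._vx_at(t)
            out = {}
            for _, row in self.cells_at(t).iterrows():
                ids = [int(v) for v in row["vertices"].split()]
                poly = np.array([vx[i] for i in ids])
                out[row["cell_id"]] = (abs(polygon_area(poly)),
                                       polygon_centroid(poly), row["region"])
            self._frame_cache[t] = out
        return self._frame_cache[t]

    def cell_polygon(self, t: float, cell_id: int) -> np.ndarray:
        row = self.cells[(self.cells["t"] == t)
                         & (self.cells["cell_id"] == cell_id)]
        if row.empty:
            raise KeyError(f"cell {cell_id} absent at t={t}")
        vx = self._vx_at(t)
        ids = [int(v) for v in row.iloc[0]["vertices"].split()]
        return np.array([vx[i] for i in ids])

    def cell_area(self, t: float, cell_id: int) -> float:
        from leafmorph.cells import polygon_area

        return abs(polygon_area(self.cell_polygon(t, cell_id)))

    def midline_axis(self) -> np.ndarray:
        """Unit proximodistal axis: from metadata when present, otherwise the
        principal axis of the labelled midline-region cells."""
        if "midline_axis" in self.metadata:
            a = np.asarray(self.metadata["midline_axis"], dtype=float)
            return a / np.linalg.norm(a)
        t0 = self.timepoints[-1]
        sub = self.cells_at(t0)
        mid = sub[sub["region"] == "midline"]
        if mid.empty:
            return np.array([0.0, 1.0])
        cents = np.array([
            self.cell_polygon(t0, cid).mean(axis=0) for cid in mid["cell_id"]])
        cents = cents - cents.mean(axis=0)
        _, _, vt = np.linalg.svd(cents, full_matrices=False)
        a = vt[0]
        return a if a[1] >= 0 else -a

    def distance_to_plb(self, t: float, points: np.ndarray) -> np.ndarray:
        """Proximodistal distance from the petiole-lamina boundary (μm),
        positive distally, measured along the midline axis."""
        row = self.plb[self.plb["t"] == t]
        if row.empty:
            raise KeyError(f"no plb position recorded at t={t}")
        p0 = row.iloc[0][["x", "y"]].to_numpy(dtype=float)
        axis = self.midline_axis()
        return (np.atleast_2d(points) - p0) @ axis

    # ------------------------------------------------------------- lineage
    def daughters_of(self, cell_id: int):
        sub = self.lineage[self.lineage["parent_id"] == cell_id]
        return list(sub["daughter_id"]), (
            float(sub["division_time"].iloc[0]) if len(sub) else None)

    def birth_time_of(self, cell_id: int):
        sub = self.lineage[self.lineage["daughter_id"] == cell_id]
        return float(sub["division_time"].iloc[0]) if len(sub) else None

    def clone_members(self, cell_id: int, t: float) -> list:
        """Descendants of `cell_id` present at time t (the clone)."""
        present = set(self.cells_at(t)["cell_id"])
        out, stack = [], [cell_id]
        while stack:
            cid = stack.pop()
            if cid in present:
                out.append(cid)
                continue
            ds, _ = self.daughters_of(cid)
            if not ds:
                raise LineageError(
                    f"lineage of cell {cell_id} broken before t={t}")
            stack.extend(ds)
        return out

    # ------------------------------------------------------------- IO
    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.vertices.to_csv(d / "vertices.csv", index=False)
        self.cells.to_csv(d / "cells.csv", index=False)
        self.lineage.to_csv(d / "lineage.csv", index=False)
        self.plb.to_csv(d / "plb.csv", index=False)
        meta = dict(self.metadata, format_version=FORMAT_VERSION)
        (d / "metadata.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def read(cls, directory) -> "TrackingDataset":
        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        return cls(
            vertices=pd.read_csv(d / "vertices.csv"),
            cells=pd.read_csv(d / "cells.csv"),
            lineage=pd.read_csv(d / "lineage.csv"),
            plb=pd.read_csv(d / "plb.csv"),
            metadata=meta,
        )


# ----------------------------------------------------------------------
# growth rates
# ----------------------------------------------------------------------

def areal_growth_rate(dataset: TrackingDataset, cell_id: int,
                      t1: float, t2: float) -> float:
    """Clone-aware relative areal growth rate, h⁻¹.

    ``ln(A_clone(t2) / A(t1)) / (t2 - t1)`` where the clone area at t2 sums
    every descendant of the cell if it divided in the interval.
    """
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    a1 = dataset.cell_area(t1, cell_id)
    members = dataset.clone_members(cell_id, t2)
    a2 = sum(dataset.cell_area(t2, m) for m in members)
    return float(np.log(a2 / a1) / (t2 - t1))


def directional_growth_rates(dataset: TrackingDataset, cell_id: int,
                             t1: float, t2: float,
                             midline_axis: np.ndarray | None = None):
    """(parallel, perpendicular) growth rates from a per-cell affine fit.

    A least-squares affine map is fitted to the cell's tracked vertices
    shared between t1 and t2; the log right-stretch tensor of its linear
    part is projected on the midline axis.  The two rates sum to the areal
    rate of the fit (trace identity), and both are invariant to rigid
    rotation and translation.
    """
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    row1 = dataset.cells[(dataset.cells["t"] == t1)
                         & (dataset.cells["cell_id"] == cell_id)]
    if row1.empty:
        raise KeyError(f"cell {cell_id} absent at t={t1}")
    ids1 = [int(v) for v in row1.iloc[0]["vertices"].split()]
    vx1, vx2 = dataset._vx_at(t1), dataset._vx_at(t2)
    shared = [i for i in ids1 if i in vx2]
    if len(shared) < 3:
        raise LineageError("fewer than 3 tracked vertices shared")
    P = np.array([vx1[i] for i in shared])
    Q = np.array([vx2[i] for i in shared])
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-9) < 2:
        raise LineageError("collinear tracked vertices; tensor undefined")
    F, *_ = np.linalg.lstsq(Pc, Qc, rcond=None)
    F = F.T
    from leafmorph.mechanics import _log_stretch

    L = _log_stretch(F[None])[0] / (t2 - t1)
    a = midline_axis if midline_axis is not None else dataset.midline_axis()
    a = np.asarray(a, dtype=float)
    a = a / np.linalg.norm(a)
    p = np.array([-a[1], a[0]])
    return float(a @ L @ a), float(p @ L @ p)


# ----------------------------------------------------------------------
# division statistics
# ----------------------------------------------------------------------

def division_records(dataset: TrackingDataset,
                     window: tuple | None = None) -> pd.DataFrame:
    """One record per division executed in the window.

    Area at execution is the mother's area at the last sampled timepoint
    before the division (resolution limited by the sampling interval), with
    its distance to the petiole-lamina boundary at that timepoint; cycle
    duration is division time minus the mother's own birth, when tracked.
    """
    times = dataset.timepoints
    births = dict(zip(dataset.lineage["daughter_id"],
                      dataset.lineage["division_time"]))
    rows = []
    seen = set()
    for parent, tdiv in zip(dataset.lineage["parent_id"],
                            dataset.lineage["division_time"]):
        if parent in seen:
            continue
        seen.add(parent)
        tdiv = float(tdiv)
        if window is not None and not (window[0] <= tdiv <= window[1]):
            continue
        t_exec = None
        for t in times[times <= tdiv][::-1]:
            if parent in dataset.frame(t):
                t_exec = t
                break
        if t_exec is None:
            continue
        area, cen, region = dataset.frame(t_exec)[parent]
        dist = float(dataset.distance_to_plb(t_exec, cen[None])[0])
        birth = births.get(parent)
        rows.append({
            "cell_id": parent, "division_time": tdiv,
            "area_at_execution": area, "distance_to_plb": dist,
            "region": region,
            "cycle_duration": (tdiv - birth) if birth is not None else np.nan,
        })
    return pd.DataFrame(rows)


def division_statistics(dataset: TrackingDataset,
                        window: tuple | None = None,
                        proximal_limit: float = 150.0) -> pd.DataFrame:
    """Per-stratum mean ± 1.96·SEM of execution area and cycle duration.

    Strata: lamina within the proximal band [0, 150) μm of the
    petiole-lamina boundary, lamina beyond it [150, ∞), and the midline.
    Bands are half-open: an event exactly at the limit falls distally.
    """
    rec = division_records(dataset, window)
    if rec.empty:
        return pd.DataFrame(columns=["stratum", "n", "mean_area", "ci95_area",
                                     "mean_duration", "ci95_duration"])

    def stratum(r):
        if r["region"] == "midline":
            return "midline"
        return ("lamina_proximal" if r["distance_to_plb"] < proximal_limit
                else "lamina_distal")

    rec = rec.assign(stratum=rec.apply(stratum, axis=1))
    out = []
    for name in ("lamina_proximal", "lamina_distal", "midline"):
        sub = rec[rec["stratum"] == name]
        n = len(sub)
        row = {"stratum": name, "n": n}
        if n:
            row["mean_area"] = sub["area_at_execution"].mean()
            row["ci95_area"] = 1.96 * sub["area_at_execution"].std(ddof=1) / \
                np.sqrt(n) if n > 1 else 0.0
            dur = sub["cycle_duration"].dropna()
            if len(dur):
                row["mean_duration"] = dur.mean()
                row["ci95_duration"] = (1.96 * dur.std(ddof=1)
                                        / np.sqrt(len(dur))
                                        if len(dur) > 1 else 0.0)
        out.append(row)
    return pd.DataFrame(out)


# ----------------------------------------------------------------------
# competence classification
# ----------------------------------------------------------------------

def competence_classification(dataset: TrackingDataset,
                              interval: tuple) -> pd.DataFrame:
    """Classify cells present at the interval start by their division fate.

    ``divides_in_interval`` if the cell divides within the interval,
    ``divides_later`` if its division falls after it but within the tracked
    period, else ``never_divides``.  Cells whose record is truncated by the
    end of the dataset are conservatively ``never_divides`` with a
    truncation flag, matching the operational definition used for tracked
    leaves.
    """
    ta, tb = interval
    times = dataset.timepoints
    t0 = times[times >= ta][0] if (times >= ta).any() else times[-1]
    t_end = times[-1]
    out = []
    for _, row in dataset.cells_at(t0).iterrows():
        if row.get("is_space", False):
            continue
        cid = row["cell_id"]
        _, tdiv = dataset.daughters_of(cid)
        if tdiv is not None and ta <= tdiv <= tb:
            cls = "divides_in_interval"
        elif tdiv is not None and tdiv > tb:
            cls = "divides_later"
        else:
            cls = "never_divides"
        out.append({"cell_id": cid, "class": cls,
                    "truncated": tdiv is None and t_end <= tb})
    return pd.DataFrame(out)


# ----------------------------------------------------------------------
# topology
# ----------------------------------------------------------------------

def _topology_from_cycles(cycles: dict, spaces: set) -> pd.Series:
    """Neighbour-number frequencies from vertex-id cycles.

    Neighbours share at least one edge (vertex-id pair); border cells (any
    unshared edge) and intercellular spaces are excluded from the counts,
    although spaces do count as neighbours of adjacent cells.
    """
    edge_map: dict = {}
    for cid, vs in cycles.items():
        for a, b in zip(vs, list(vs[1:]) + [vs[0]]):
            edge_map.setdefault((a, b) if a < b else (b, a), []).append(cid)
    counts = {}
    for cid, vs in cycles.items():
        if cid in spaces:
            continue
        neigh = set()
        border = False
        for a, b in zip(vs, list(vs[1:]) + [vs[0]]):
            inc = edge_map[(a, b) if a < b else (b, a)]
            if len(inc) < 2:
                border = True
                break
            neigh.update(c for c in inc if c != cid)
        if border:
            continue
        counts[cid] = len(neigh)
    ns = np.arange(3, 13)
    vals = np.array([sum(1 for v in counts.values() if v == n) for n in ns],
                    dtype=float)
    total = vals.sum()
    freq = vals / total if total else vals
    return pd.Series(freq, index=ns, name="frequency")


def topology_distribution(source, t: float | None = None) -> pd.Series:
    """Frequency of n-sided (n-neighboured) cells, n = 3..12.

    ``source`` may be a TrackingDataset (with a timepoint ``t``) or a
    simulation Snapshot.  Frequencies sum to 1 over interior non-space cells.
    """
    if isinstance(source, TrackingDataset):
        tt = t if t is not None else source.timepoints[-1]
        sub = source.cells_at(tt)
        cycles = {row["cell_id"]: [int(v) for v in row["vertices"].split()]
                  for _, row in sub.iterrows()}
        spaces = {row["cell_id"] for _, row in sub.iterrows()
                  if row.get("is_space", False)}
    else:  # Snapshot
        cycles = {c["cid"]: list(c["vertices"]) for c in source.cells}
        spaces = {c["cid"] for c in source.cells if c["is_space"]}
    return _topology_from_cycles(cycles, spaces)
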