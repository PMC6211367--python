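"""Runnable model presets: the full growth + division simulation loop.

A preset couples the canvas mechanics, the regulatory network and the
division engine for one model variant.  Each 1 h step (default):

1. evaluate the temporal factors LATE and EARLYGROWTH at the variant's
   physiological time;
2. advance the diffusible PMF field on the current mesh (actual time);
3. evaluate specified growth rates and relax the canvas to its new shape;
4. advect everything anchored to the canvas (factor concentrations ride on
   nodes, polarity vectors are pushed forward, v-cell vertices follow their
   barycentric anchors; PMF is optionally diluted by local area expansion);
5. update division competence, execute threshold-crossing divisions, and
   manage intercellular spaces (subepidermal models).

Runs are bit-reproducible given (config, seed): a single seeded generator
drives every stochastic choice in a fixed order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from leafmorph.canvas import Canvas, GeometryParams, build_initial_canvas
from leafmorph.cells import (
    CellComplex,
    DivisionParams,
    assign_targets,
    attempt_divisions,
    initial_cells,
    manage_spaces,
    update_competence,
)
from leafmorph.factors import (
    FactorState,
    KRNParams,
    ModelVariant,
    advect_polarity,
    earlygrowth_factor,
    fem_matrices,
    initialize_state,
    late_factor,
    specified_growth,
    update_pmf,
)
from leafmorph.mechanics import step_growth

EARLY_OUTPUT_TIMES = (115.0, 132.0, 140.0, 147.0, 156.0, 164.0, 178.0)


def default_end_time(variant: ModelVariant) -> float:
    """Growth period end: 178 h for early presets, 412 h (physiological)
    otherwise -- stretched into actual time for slowed-physiology variants."""
    if variant.is_early:
        return 178.0
    return 87.0 + (412.0 - 87.0) / variant.physiological_ratio


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one run."""

    variant: ModelVariant
    t_start: float = 87.0
    t_end: float | None = None
    dt: float = 1.0
    seed: int = 0
    output_times: tuple | None = None
    geometry: GeometryParams = field(default_factory=GeometryParams)
    krn: KRNParams = field(default_factory=KRNParams)
    division: DivisionParams | None = None
    mean_initial_cell_area: float = 70.0
    cells_enabled: bool = True
    divisions_enabled: bool = True
    isotropic_control: bool = False  # replace (k_par, k_per) by their mean

    def __post_init__(self):
        if isinstance(self.variant, str):
            self.variant = ModelVariant(self.variant)
        if self.t_end is None:
            self.t_end = default_end_time(self.variant)
        if self.t_start >= self.t_end:
            raise ValueError("t_start must precede t_end")
        if self.division is None:
            self.division = DivisionParams.for_variant(self.variant)
        if self.output_times is None:
            if self.variant.is_early:
                self.output_times = EARLY_OUTPUT_TIMES
            else:
                ts = list(np.arange(self.t_start + 12.0, self.t_end, 12.0))
                self.output_times = tuple(ts + [self.t_end])

    def provenance(self) -> dict:
        return {
            "variant": dataclasses.asdict(self.variant),
            "seed": self.seed,
            "t_start": self.t_start,
            "t_end": self.t_end,
            "dt": self.dt,
        }

    # ------------------------------------------------------------------
    # structured text round-trip
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "variant": dataclasses.asdict(self.variant),
            "t_start": self.t_start, "t_end": self.t_end, "dt": self.dt,
            "seed": self.seed,
            "output_times": [float(t) for t in self.output_times],
            "geometry": dataclasses.asdict(self.geometry),
            "krn": dataclasses.asdict(self.krn),
            "division": dataclasses.asdict(self.division),
            "mean_initial_cell_area": self.mean_initial_cell_area,
            "cells_enabled": self.cells_enabled,
            "divisions_enabled": self.divisions_enabled,
            "isotropic_control": self.isotropic_control,
        }
        # tuples serialise as lists; normalise for exact round-trips
        d["krn"]["lcs_lamina"] = list(d["krn"]["lcs_lamina"])
        d["krn"]["lcs_midline"] = list(d["krn"]["lcs_midline"])
        return d

    def save(self, path) -> None:
        """Write the full configuration as a YAML key-value file."""
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "SimulationConfig":
        import yaml

        from leafmorph.canvas import GeometryParams
        from leafmorph.cells import DivisionParams

        with open(path) as fh:
            d = yaml.safe_load(fh)
        krn = d["krn"]
        krn["lcs_lamina"] = tuple(krn["lcs_lamina"])
        krn["lcs_midline"] = tuple(krn["lcs_midline"])
        return cls(
            variant=ModelVariant(**d["variant"]),
            t_start=d["t_start"], t_end=d["t_end"], dt=d["dt"],
            seed=d["seed"], output_times=tuple(d["output_times"]),
            geometry=GeometryParams(**d["geometry"]),
            krn=KRNParams(**krn),
            division=DivisionParams(**d["division"]),
            mean_initial_cell_area=d["mean_initial_cell_area"],
            cells_enabled=d["cells_enabled"],
            divisions_enabled=d["divisions_enabled"],
            isotropic_control=d["isotropic_control"],
        )


@dataclass
class Snapshot:
    """State captured at one output time."""

    t: float
    nodes: np.ndarray
    vx_xy: np.ndarray
    cells: list            # dicts: cid, vertices, parent, birth_time, ...
    plb_distance: np.ndarray | None   # per-cell distance to plb (μm)
    plb_xy: np.ndarray | None
    width_mm: float
    area_mm2: float
    pmf: np.ndarray
    late: float
    earlygrowth: float


@dataclass
class Trajectory:
    """Ordered snapshots plus event logs and provenance."""

    config: SimulationConfig
    canvas: Canvas
    snapshots: list
    division_events: list
    space_events: list
    final_state: FactorState
    final_cells: CellComplex | None

    @property
    def times(self):
        return [s.t for s in self.snapshots]


def _capture(t, canvas, cc, state) -> Snapshot:
    cells = []
    plb_d = None
    if cc is not None:
        cc.refresh_positions()
        live = list(cc.cells.values())
        cents = cc.centroids([c.cid for c in live]) if live else np.empty((0, 2))
        plb_d = canvas.distance_to_plb(cents) if len(cents) else np.empty(0)
        for c, cen, d in zip(live, cents, plb_d):
            cells.append({
                "cid": c.cid, "vertices": tuple(c.vertices),
                "parent": c.parent_id, "birth_time": c.birth_time,
                "region": c.region, "layer": c.layer,
                "competent": c.competent, "is_space": c.is_space,
                "target_area": c.target_area,
                "centroid": (float(cen[0]), float(cen[1])),
                "dist_plb": float(d),
            })
    return Snapshot(
        t=t,
        nodes=canvas.nodes.copy(),
        vx_xy=cc.vx_xy.copy() if cc is not None else np.empty((0, 2)),
        cells=cells,
        plb_distance=plb_d,
        plb_xy=canvas.nodes[canvas.plb_node].copy(),
        width_mm=canvas.width() / 1000.0,
        area_mm2=canvas.area() / 1e6,
        pmf=state.pmf.copy(),
        late=state.late,
        earlygrowth=state.earlygrowth,
    )


def _element_cell_areas(cc: CellComplex, canvas: Canvas) -> np.ndarray:
    """Area of the v-cell over each element (for size-limited growth).

    Cells are scattered onto elements through their vertex anchors (each
    element averages the areas of cells with a vertex anchored in it);
    vertex-free elements inherit from the nearest covered element. At the
    late stages where the feedback acts, cells and elements are of
    comparable size, so this smooth approximation tracks the ω field
    without any point-in-polygon searches.
    """
    from scipy.spatial import cKDTree

    live = cc.live_cells()
    M = canvas.element_count
    if not live:
        return np.zeros(M)
    cids = [c.cid for c in live]
    areas = np.abs(cc.areas(cids))
    total = np.zeros(M)
    count = np.zeros(M)
    for cell, a in zip(live, areas):
        elems = cc.vx_elem[cell.vertices]
        np.add.at(total, elems, a)
        np.add.at(count, elems, 1.0)
    covered = count > 0
    out = np.zeros(M)
    out[covered] = total[covered] / count[covered]
    if (~covered).any():
        cents = canvas.element_centroids()
        _, j = cKDTree(cents[covered]).query(cents[~covered])
        out[~covered] = out[covered][j]
    return out


def run_preset(config: SimulationConfig) -> Trajectory:
    """Run one preset end-to-end and return its trajectory."""
    rng = np.random.default_rng(config.seed)
    variant = config.variant
    params = config.krn
    dparams = config.division

    canvas = build_initial_canvas(config.geometry)
    state = initialize_state(canvas, params, variant)

    cc = None
    if config.cells_enabled:
        cc = CellComplex(canvas)
        initial_cells(cc, variant, params, rng,
                      mean_cell_area=config.mean_initial_cell_area,
                      t=config.t_start)
        tau0 = variant.physiological_time(config.t_start)
        state.late = float(late_factor(tau0, params, variant))
        state.earlygrowth = float(earlygrowth_factor(tau0, variant, params))
        assign_targets(cc, [c.cid for c in cc.live_cells()], state,
                       dparams, tau0, rng)
        update_competence(cc, state, dparams, variant)

    out_times = sorted(set(config.output_times))
    snapshots = []
    if config.t_start in out_times:
        snapshots.append(_capture(config.t_start, canvas, cc, state))

    t = config.t_start
    division_events = []
    while t < config.t_end - 1e-9:
        dt = min(config.dt, config.t_end - t)
        tau = variant.physiological_time(t)
        state.late = float(late_factor(tau, params, variant))
        state.earlygrowth = float(earlygrowth_factor(tau, variant, params))

        # diffusible factor (actual time)
        state.pmf = update_pmf(canvas, state.pmf, dt, params)

        # specified growth -> resultant deformation
        cell_area = None
        if variant.name == "limiting_cell_size" and cc is not None:
            cell_area = _element_cell_areas(cc, canvas)
        spec = specified_growth(state, params, variant, canvas,
                                cell_area=cell_area)
        if config.isotropic_control:
            k_iso = 0.5 * (spec.k_par + spec.k_per)
            spec.k_par = k_iso
            spec.k_per = k_iso.copy()
        mass_old, _ = fem_matrices(canvas)
        new_canvas = step_growth(canvas, spec, dt)

        # advection of anchored quantities
        state.polarity = advect_polarity(state.polarity, canvas, new_canvas)
        if params.pmf_dilution:
            mass_new, _ = fem_matrices(new_canvas)
            state.pmf = np.clip(state.pmf * mass_old / mass_new, 0.0, 1.0)
        canvas = new_canvas
        t += dt
        tau = variant.physiological_time(t)
        state.late = float(late_factor(tau, params, variant))
        state.earlygrowth = float(earlygrowth_factor(tau, variant, params))

        if cc is not None:
            cc.canvas = canvas
            cc.refresh_positions()
            update_competence(cc, state, dparams, variant)
            if config.divisions_enabled:
                evs = attempt_divisions(cc, state, t, dt, rng, dparams,
                                        variant)
                division_events.extend(evs)
            manage_spaces(cc, tau, dt, rng, dparams, variant)

        for ot in out_times:
            if abs(t - ot) < 1e-9:
                snapshots.append(_capture(t, canvas, cc, state))

    return Trajectory(
        config=config,
        canvas=canvas,
        snapshots=snapshots,
        division_events=division_events,
        space_events=list(cc.space_events) if cc is not None else [],
        final_state=state,
        final_cells=cc,
    )


# ----------------------------------------------------------------------
# summaries
# ----------------------------------------------------------------------

def summarize(trajectory: Trajectory):
    """Per-snapshot cell count, mean cell area (μm²), leaf area (mm²) and
    leaf width (mm), as a DataFrame."""
    import pandas as pd

    rows = []
    for snap in trajectory.snapshots:
        cells = [c for c in snap.cells if not c["is_space"]]
        if cells:
            areas = [_cell_area(snap, c) for c in cells]
            mean_area = float(np.mean(areas))
        else:
            mean_area = np.nan
        rows.append({
            "t": snap.t,
            "n_cells": len(cells),
            "mean_cell_area_um2": mean_area,
            "leaf_area_mm2": snap.area_mm2,
            "leaf_width_mm": snap.width_mm,
        })
    return pd.DataFrame(rows)


def _cell_area(snap: Snapshot, cell: dict) -> float:
    from leafmorph.cells import polygon_area

    return abs(polygon_area(snap.vx_xy[list(cell["vertices"])]))


MUTANT_SET = (
    {"a_prime": 85.0}, {"a_prime": -85.0},
    {"k_prime": 0.95}, {"k_prime": 1.05},
    {"t_prime": -6.0}, {"t_prime": 6.0},
)


def mutant_matrix(base_name: str = "limit_free", seed: int = 0,
                  config_kw: dict | None = None):
    """Run a base preset and its six single-parameter mutants.

    Mutants share the base seed so Monte-Carlo variance largely cancels in
    the deltas.  Returns a DataFrame of final cell count, mean cell area and
    leaf area, with percentage change versus the base.
    """
    import pandas as pd

    config_kw = config_kw or {}
    rows = []
    runs = [{}] + list(MUTANT_SET)
    for mod in runs:
        variant = ModelVariant(base_name, **mod)
        cfg = SimulationConfig(variant=variant, seed=seed, **config_kw)
        traj = run_preset(cfg)
        summary = summarize(traj).iloc[-1]
        label = "base" if not mod else "".join(
            f"{k.split('_')[0]}'={v:+g}" for k, v in mod.items())
        rows.append({
            "model": label,
            **{k: summary[k] for k in
               ("n_cells", "mean_cell_area_um2", "leaf_area_mm2",
                "leaf_width_mm")},
        })
    df = pd.DataFrame(rows).set_index("model")
    base = df.loc["base"]
    for col in df.columns:
        df[f"{col}_pct"] = 100.0 * (df[col] - base[col]) / base[col]
    return df
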