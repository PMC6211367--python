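import numpy as np
import pandas as pd
import pytest

from leafmorph.tracking import (
    LineageError,
    TrackingDataset,
    areal_growth_rate,
    competence_classification,
    directional_growth_rates,
    division_statistics,
    topology_distribution,
)


def build_dataset(frames, lineage=None, plb=None, metadata=None):
    """Assemble a TrackingDataset from per-time dicts:
    frames[t] = {"vertices": {vid: (x, y)}, "cells": {cid: (vid_cycle, region)}}
    """
    vrows, crows, prows = [], [], []
    for t, fr in frames.items():
        for vid, (x, y) in fr["vertices"].items():
            vrows.append({"t": t, "vertex_id": vid, "x": x, "y": y})
        for cid, spec in fr["cells"].items():
            cyc, region = spec if isinstance(spec, tuple) else (spec, "lamina")
            crows.append({"t": t, "cell_id": cid,
                          "vertices": " ".join(map(str, cyc)),
                          "region": region, "layer": "epidermis",
                          "is_space": False})
        prows.append({"t": t, "x": 0.0, "y": 0.0})
    return TrackingDataset(
        vertices=pd.DataFrame(vrows),
        cells=pd.DataFrame(crows),
        lineage=pd.DataFrame(lineage or [],
                             columns=["parent_id", "daughter_id",
                                      "division_time"]),
        plb=pd.DataFrame(prows if plb is None else plb),
        metadata=metadata or {"midline_axis": (0.0, 1.0)},
    )


def square(vids, x0, y0, s):
    return {vids[0]: (x0, y0), vids[1]: (x0 + s, y0),
            vids[2]: (x0 + s, y0 + s), vids[3]: (x0, y0 + s)}


class TestArealGrowthRate:
    def test_doubling_over_10h(self):
        s1, s2 = 10.0, 10.0 * np.sqrt(2)
        ds = build_dataset({
            0.0: {"vertices": square([1, 2, 3, 4], 0, 0, s1),
                  "cells": {0: [1, 2, 3, 4]}},
            10.0: {"vertices": square([1, 2, 3, 4], 0, 0, s2),
                   "cells": {0: [1, 2, 3, 4]}},
        })
        assert areal_growth_rate(ds, 0, 0.0, 10.0) == pytest.approx(
            np.log(2) / 10, rel=1e-9)

    def test_no_change_is_zero(self):
        ds = build_dataset({
            0.0: {"vertices": square([1, 2, 3, 4], 0, 0, 5.0),
                  "cells": {0: [1, 2, 3, 4]}},
            5.0: {"vertices": square([1, 2, 3, 4], 0, 0, 5.0),
                  "cells": {0: [1, 2, 3, 4]}},
        })
        assert areal_growth_rate(ds, 0, 0.0, 5.0) == 0.0

    def test_clone_area_after_division(self):
        # mother area 100 -> daughters 60 + 60 over 5 h: ln(1.2)/5
        v1 = square([1, 2, 3, 4], 0, 0, 10.0)
        vd = {**square([1, 2, 5, 6], 0, 0, np.sqrt(60)),
              **square([7, 8, 9, 10], 20, 0, np.sqrt(60))}
        ds = build_dataset(
            {0.0: {"vertices": v1, "cells": {0: [1, 2, 3, 4]}},
             5.0: {"vertices": vd, "cells": {1: [1, 2, 5, 6],
                                             2: [7, 8, 9, 10]}}},
            lineage=[{"parent_id": 0, "daughter_id": 1, "division_time": 2.0},
                     {"parent_id": 0, "daughter_id": 2, "division_time": 2.0}],
        )
        assert areal_growth_rate(ds, 0, 0.0, 5.0) == pytest.approx(
            np.log(1.2) / 5, rel=1e-9)

    def test_broken_lineage_flagged(self):
        ds = build_dataset({
            0.0: {"vertices": square([1, 2, 3, 4], 0, 0, 5.0),
                  "cells": {0: [1, 2, 3, 4]}},
            5.0: {"vertices": square([5, 6, 7, 8], 0, 0, 5.0),
                  "cells": {9: [5, 6, 7, 8]}},
        })
        with pytest.raises(LineageError):
            areal_growth_rate(ds, 0, 0.0, 5.0)


class TestDirectionalRates:
    def _two_frame(self, M, dt=10.0):
        p = np.array([[0.0, 0.0], [7.0, 1.0], [5.0, 9.0], [-1.0, 6.0]])
        q = p @ M.T
        f1 = {i + 1: tuple(p[i]) for i in range(4)}
        f2 = {i + 1: tuple(q[i]) for i in range(4)}
        return build_dataset({
            0.0: {"vertices": f1, "cells": {0: [1, 2, 3, 4]}},
            dt: {"vertices": f2, "cells": {0: [1, 2, 3, 4]}},
        })

    def test_pure_vertical_stretch(self):
        ds = self._two_frame(np.diag([1.0, 1.5]))
        par, per = directional_growth_rates(ds, 0, 0.0, 10.0,
                                            midline_axis=(0, 1))
        assert par == pytest.approx(np.log(1.5) / 10, rel=1e-9)
        assert per == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_gives_zero(self):
        th = np.deg2rad(35)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        par, per = directional_growth_rates(self._two_frame(R), 0, 0.0, 10.0,
                                            midline_axis=(0, 1))
        assert par == pytest.approx(0.0, abs=1e-12)
        assert per == pytest.approx(0.0, abs=1e-12)

    def test_shear_trace_identity(self):
        S = np.array([[1.0, 0.4], [0.0, 1.0]])
        ds = self._two_frame(S)
        par, per = directional_growth_rates(ds, 0, 0.0, 10.0,
                                            midline_axis=(0, 1))
        areal = areal_growth_rate(ds, 0, 0.0, 10.0)
        assert par + per == pytest.approx(areal, abs=1e-9)

    def test_collinear_vertices_flagged(self):
        f = {1: (0.0, 0.0), 2: (1.0, 1.0), 3: (2.0, 2.0), 4: (3.0, 3.0)}
        ds = build_dataset({0.0: {"vertices": f, "cells": {0: [1, 2, 3, 4]}},
                            1.0: {"vertices": f, "cells": {0: [1, 2, 3, 4]}}})
        with pytest.raises(LineageError):
            directional_growth_rates(ds, 0, 0.0, 1.0, midline_axis=(0, 1))

    def test_translation_invariance(self):
        M = np.diag([1.1, 1.3])
        ds1 = self._two_frame(M)
        p = np.array([[0.0, 0.0], [7.0, 1.0], [5.0, 9.0], [-1.0, 6.0]])
        q = p @ M.T + np.array([123.0, -45.0])
        ds2 = build_dataset({
            0.0: {"vertices": {i + 1: tuple(p[i]) for i in range(4)},
                  "cells": {0: [1, 2, 3, 4]}},
            10.0: {"vertices": {i + 1: tuple(q[i]) for i in range(4)},
                   "cells": {0: [1, 2, 3, 4]}},
        })
        r1 = directional_growth_rates(ds1, 0, 0.0, 10.0, midline_axis=(0, 1))
        r2 = directional_growth_rates(ds2, 0, 0.0, 10.0, midline_axis=(0, 1))
        np.testing.assert_allclose(r1, r2, atol=1e-12)


class TestDivisionStatistics:
    def _ds_with_divisions(self, dists, side=None):
        """One division per entry of `dists`: a square cell at the given
        proximodistal distance, constant area 150, divides at t=6."""
        frames = {0.0: {"vertices": {}, "cells": {}},
                  4.0: {"vertices": {}, "cells": {}},
                  8.0: {"vertices": {}, "cells": {}}}
        lineage = []
        s = np.sqrt(150.0)
        for k, d in enumerate(dists):
            vids = [100 * k + j for j in (1, 2, 3, 4)]
            for t in (0.0, 4.0):
                frames[t]["vertices"].update(
                    square(vids, 50.0 * k, d - s / 2, s))
                frames[t]["cells"][k] = (vids, "lamina")
            d1, d2 = 1000 + 2 * k, 1001 + 2 * k
            va = [200 * k + j for j in (11, 12, 13, 14)]
            vb = [200 * k + j for j in (15, 16, 17, 18)]
            frames[8.0]["vertices"].update(square(va, 50.0 * k, d, s / 2))
            frames[8.0]["vertices"].update(square(vb, 50.0 * k + 20, d, s / 2))
            frames[8.0]["cells"][d1] = (va, "lamina")
            frames[8.0]["cells"][d2] = (vb, "lamina")
            lineage += [
                {"parent_id": k, "daughter_id": d1, "division_time": 6.0},
                {"parent_id": k, "daughter_id": d2, "division_time": 6.0}]
        return build_dataset(frames, lineage=lineage)

    def test_constant_execution_area_zero_ci(self):
        ds = self._ds_with_divisions([50.0, 60.0, 70.0])
        out = division_statistics(ds).set_index("stratum")
        row = out.loc["lamina_proximal"]
        assert row["n"] == 3
        assert row["mean_area"] == pytest.approx(150.0, rel=1e-9)
        assert row["ci95_area"] == pytest.approx(0.0, abs=1e-9)

    def test_stratum_boundary_convention(self):
        # 149 μm falls proximally, 151 μm distally (half-open bands)
        ds = self._ds_with_divisions([149.0, 151.0])
        out = division_statistics(ds).set_index("stratum")
        assert out.loc["lamina_proximal", "n"] == 1
        assert out.loc["lamina_distal", "n"] == 1

    def test_ci_coverage_monte_carlo(self):
        # normal(150, 30) execution areas, n=100: the 1.96 SEM interval
        # should cover 150 in at least ~93 % of replicates
        rng = np.random.default_rng(0)
        n_rep = 2000
        cover = 0
        for _ in range(n_rep):
            x = rng.normal(150.0, 30.0, 100)
            half = 1.96 * x.std(ddof=1) / 10.0
            cover += abs(x.mean() - 150.0) <= half
        assert cover / n_rep >= 0.93


class TestCompetenceClassification:
    def _ds(self):
        f = {"vertices": square([1, 2, 3, 4], 0, 0, 5.0),
             "cells": {0: [1, 2, 3, 4]}}
        frames = {t: {"vertices": dict(f["vertices"]),
                      "cells": dict(f["cells"])} for t in (0.0, 10.0, 20.0)}
        return frames

    def test_three_classes(self):
        frames = self._ds()
        for t in frames:
            frames[t]["cells"].update({1: [1, 2, 3, 4], 2: [1, 2, 3, 4]})
        lineage = [
            {"parent_id": 0, "daughter_id": 10, "division_time": 5.0},
            {"parent_id": 0, "daughter_id": 11, "division_time": 5.0},
            {"parent_id": 1, "daughter_id": 12, "division_time": 15.0},
            {"parent_id": 1, "daughter_id": 13, "division_time": 15.0},
        ]
        ds = build_dataset(frames, lineage=lineage)
        out = competence_classification(ds, (0.0, 10.0)).set_index("cell_id")
        assert out.loc[0, "class"] == "divides_in_interval"
        assert out.loc[1, "class"] == "divides_later"
        assert out.loc[2, "class"] == "never_divides"

    def test_truncation_flag(self):
        ds = build_dataset(self._ds())
        out = competence_classification(ds, (0.0, 30.0))
        assert out.iloc[0]["class"] == "never_divides"
        assert bool(out.iloc[0]["truncated"])


class TestTopology:
    @staticmethod
    def hex_grid_cycles(nx=5, ny=5):
        """Honeycomb tiling as vertex-id cycles (shared ids)."""
        cells = {}
        vid = {}

        def v(xy):
            key = (round(xy[0], 6), round(xy[1], 6))
            if key not in vid:
                vid[key] = len(vid)
            return vid[key]

        ang = np.arange(6) * np.pi / 3
        corner = np.stack([np.cos(ang), np.sin(ang)], axis=1)
        for i in range(nx):
            for j in range(ny):
                c = np.array([1.5 * i, np.sqrt(3) * (j + (i % 2) / 2.0)])
                cells[i * ny + j] = [v(c + d) for d in corner]
        return cells

    def test_hexagonal_packing_interior_all_six(self):
        from leafmorph.tracking import _topology_from_cycles

        freq = _topology_from_cycles(self.hex_grid_cycles(7, 7), set())
        assert freq[6] == pytest.approx(1.0)
        assert freq.sum() == pytest.approx(1.0)

    def test_five_cell_fixture_hand_counted(self):
        from leafmorph.tracking import _topology_from_cycles

        # 2x2 block of squares surrounded by a ring cell: each inner square
        # touches 2 squares + the ring = 3 neighbours; none is a border cell
        cyc = {
            "a": [0, 1, 4, 3], "b": [1, 2, 5, 4],
            "c": [3, 4, 7, 6], "d": [4, 5, 8, 7],
            "ring": [0, 1, 2, 5, 8, 7, 6, 3],
        }
        freq = _topology_from_cycles(cyc, set())
        # hand count: each inner square touches 2 squares + the ring = 3;
        # the ring touches all 4 squares and has no unshared edge
        assert freq[3] == pytest.approx(0.8)
        assert freq[4] == pytest.approx(0.2)

    def test_frequencies_sum_to_one_on_simulation(self):
        from tests.conftest import coarse_config
        from leafmorph.presets import run_preset

        cfg = coarse_config("epidermis_early", seed=5, t_end=110.0,
                            output_times=(110.0,))
        traj = run_preset(cfg)
        freq = topology_distribution(traj.snapshots[-1])
        assert freq.sum() == pytest.approx(1.0)
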