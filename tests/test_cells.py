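import numpy as np
import pytest

from leafmorph.canvas import build_rectangle_canvas
from leafmorph.cells import (
    CellComplex,
    DivisionParams,
    attempt_divisions,
    errera_split,
    errera_wall,
    initial_cells,
    manage_spaces,
    mean_target_area,
    polygon_area,
    polygon_centroid,
    sample_target,
    shortest_chord,
    update_competence,
)
from leafmorph.factors import KRNParams, ModelVariant, late_factor


def regular_polygon(n, r=1.0):
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)


def brute_force_shortest(poly, point, n_angles=5000):
    """Independent oracle: dense scan over chord directions."""
    from leafmorph.cells import _chord

    best = np.inf
    for th in np.linspace(0.0, np.pi, n_angles, endpoint=False):
        r = _chord(poly, point, np.array([np.cos(th), np.sin(th)]))
        if r is not None and r[4] < best:
            best = r[4]
    return best


class TestErreraRule:
    def test_rectangle_shortest_wall_bisects_long_axis(self, rng):
        poly = np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 1.0], [0.0, 1.0]])
        a, b = errera_split(poly, rng, noise_frac=0.0)
        for d in (a, b):
            assert abs(polygon_area(d)) == pytest.approx(1.0, rel=1e-9)
            w = np.ptp(d[:, 0]), np.ptp(d[:, 1])
            assert w[0] == pytest.approx(1.0, rel=1e-6)  # unit squares
            assert w[1] == pytest.approx(1.0, rel=1e-6)

    def test_rectangle_wall_length_matches_brute_force(self, rng):
        poly = np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 1.0], [0.0, 1.0]])
        c = polygon_centroid(poly)
        wall, _ = shortest_chord(poly, c)
        assert wall[4] == pytest.approx(1.0, rel=1e-6)
        assert wall[4] == pytest.approx(brute_force_shortest(poly, c),
                                        rel=1e-4)

    def test_hexagon_wall_connects_opposite_edge_midpoints(self, rng):
        poly = regular_polygon(6)
        wall = errera_wall(poly, rng, noise_frac=0.0)
        i1, t1, i2, t2 = wall
        assert (i2 - i1) % 6 == 3          # opposite edges
        assert t1 == pytest.approx(0.5, abs=1e-3)
        assert t2 == pytest.approx(0.5, abs=1e-3)

    @pytest.mark.parametrize("n_vertices", [4, 5, 6, 7, 9])
    def test_daughters_partition_mother(self, n_vertices, rng):
        for trial in range(10):
            poly = regular_polygon(n_vertices, r=10.0)
            poly += rng.normal(0.0, 1.0, poly.shape)
            if polygon_area(poly) < 20:    # skip rare non-simple draws
                continue
            a, b = errera_split(poly, rng, noise_frac=0.25)
            total = abs(polygon_area(a)) + abs(polygon_area(b))
            assert total == pytest.approx(abs(polygon_area(poly)), rel=1e-9)

    def test_noise_displaces_wall_within_disc(self, rng):
        poly = regular_polygon(6, r=10.0)
        walls = {errera_wall(poly, rng, noise_frac=0.25) for _ in range(20)}
        assert len(walls) > 1              # placement is stochastic
        nominal = errera_wall(poly, rng, noise_frac=0.0)
        assert errera_wall(poly, np.random.default_rng(0), 0.0) == nominal


class TestErreraProperties:
    """Property-based checks of the wall-placement geometry."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def convex_polygon(angles, radii):
        th = np.sort(np.asarray(angles))
        return np.stack([np.asarray(radii) * np.cos(th),
                         np.asarray(radii) * np.sin(th)], axis=1)

    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.lists(st.floats(0.0, 2 * np.pi), min_size=5, max_size=9,
                 unique=True),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_split_partitions_any_star_polygon(self, seed, angles):
        rng = np.random.default_rng(seed)
        radii = rng.uniform(5.0, 20.0, len(angles))
        poly = self.convex_polygon(angles, radii)
        if abs(polygon_area(poly)) < 10.0:
            return  # degenerate draw: nearly collinear sampling
        a, b = errera_split(poly, rng, noise_frac=0.25)
        assert abs(polygon_area(a)) + abs(polygon_area(b)) == pytest.approx(
            abs(polygon_area(poly)), rel=1e-9)
        assert abs(polygon_area(a)) > 0 and abs(polygon_area(b)) > 0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_nominal_wall_is_global_minimum(self, seed):
        rng = np.random.default_rng(seed)
        th = np.sort(rng.uniform(0, 2 * np.pi, 7))
        if np.diff(th).min() < 0.05:
            return
        poly = np.stack([np.cos(th), np.sin(th)], axis=1) * \
            rng.uniform(5, 15)
        c = polygon_centroid(poly)
        wall, _ = shortest_chord(poly, c)
        assert wall[4] <= brute_force_shortest(poly, c, 2000) * (1 + 1e-3)


class TestTargetAreas:
    P = DivisionParams(pmf_min=0.295)  # epidermis-style

    def test_before_onset_amin_everywhere(self):
        out = mean_target_area([0.1, 0.9], [1.0, 1.0], [False, True],
                               "epidermis", self.P, t=100.0)
        np.testing.assert_allclose(out, 150.0)

    def test_lamina_interpolation_endpoints(self):
        out = mean_target_area([0.6, 0.295], [1.0, 1.0], [False, False],
                               "epidermis", self.P, t=120.0)
        assert out[0] == pytest.approx(150.0)   # PMF above PMF_max
        assert out[1] == pytest.approx(300.0)   # PMF at PMF_min

    def test_lamina_midpoint(self):
        pmf = (0.51 + 0.295) / 2
        out = mean_target_area([pmf], [1.0], [False], "epidermis", self.P,
                               t=120.0)
        assert out[0] == pytest.approx(225.0)

    def test_midline_rules_by_layer(self):
        epi = mean_target_area([0.4], [0.8], [True], "epidermis", self.P,
                               t=120.0)
        assert epi[0] == pytest.approx(500.0)
        sub = DivisionParams(pmf_min=0.184)
        out = mean_target_area([0.4], [1.0], [True], "subepidermis", sub,
                               t=120.0)
        assert out[0] == pytest.approx(750.0)   # 1.5 * 500 * 1

    def test_a_prime_offsets_lamina(self):
        p = DivisionParams(pmf_min=0.295, a_prime=-85.0)
        out = mean_target_area([0.6], [1.0], [False], "epidermis", p, t=120.0)
        assert out[0] == pytest.approx(65.0)

    def test_sample_target_moments(self):
        rng = np.random.default_rng(7)
        draws = sample_target(np.full(10_000, 150.0), rng)
        assert draws.mean() == pytest.approx(150.0, abs=1.0)
        assert draws.std() == pytest.approx(30.0, abs=1.0)
        assert (draws >= 0.3 * 150.0).all()

    def test_sample_target_degenerate_and_deterministic(self):
        out = sample_target(np.array([200.0]), np.random.default_rng(0),
                            sigma_frac=0.0)
        assert out[0] == 200.0
        a = sample_target(np.full(100, 150.0), np.random.default_rng(42))
        b = sample_target(np.full(100, 150.0), np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)


def small_complex(layer="epidermis", width=120.0, height=240.0,
                  cell_area=120.0, seed=0):
    canvas = build_rectangle_canvas(width, height, n_across=6, n_along=12)
    cc = CellComplex(canvas)
    variant = ModelVariant("subepidermis_early" if layer == "subepidermis"
                           else "epidermis_early")
    initial_cells(cc, variant, KRNParams(), np.random.default_rng(seed),
                  mean_cell_area=cell_area)
    return cc, variant


def uniform_state_for(canvas, pmf=1.0, pgrad=1.0, late=0.0):
    from leafmorph.factors import FactorState

    n = len(canvas.nodes)
    return FactorState(
        pgrad=np.full(n, pgrad), mid=np.zeros(n), lam=np.ones(n),
        proxorg=np.zeros(n), pol=np.zeros(n), pmf=np.full(n, pmf),
        polarity=np.tile([0.0, 1.0], (canvas.element_count, 1)),
        late=late,
    )


class TestCompetence:
    def test_subepidermis_pmf_gate(self):
        cc, variant = small_complex("subepidermis")
        params = DivisionParams.for_variant(variant)
        st = uniform_state_for(cc.canvas, pmf=0.2,
                               late=float(late_factor(150.0)))
        update_competence(cc, st, params, variant)
        assert all(c.competent for c in cc.live_cells())
        st.pmf[:] = 0.18
        update_competence(cc, st, params, variant)
        assert not any(c.competent for c in cc.live_cells())

    def test_epidermis_pgrad_gate(self):
        cc, variant = small_complex("epidermis")
        params = DivisionParams.for_variant(variant)
        st = uniform_state_for(cc.canvas, pmf=0.9, pgrad=0.5)
        update_competence(cc, st, params, variant)
        assert not any(c.competent for c in cc.live_cells())

    def test_late_arrest_everywhere_at_183h(self):
        cc, variant = small_complex("subepidermis")
        params = DivisionParams.for_variant(variant)
        st = uniform_state_for(cc.canvas, pmf=1.0,
                               late=float(late_factor(183.0)))
        update_competence(cc, st, params, variant)
        assert not any(c.competent for c in cc.live_cells())

    def test_epidermal_midline_arrests_earlier(self):
        cc, variant = small_complex("epidermis")
        params = DivisionParams.for_variant(variant)
        st = uniform_state_for(cc.canvas, pmf=0.9,
                               late=float(late_factor(170.0)))
        update_competence(cc, st, params, variant)
        by_region = {}
        for c in cc.live_cells():
            by_region.setdefault(c.region, set()).add(c.competent)
        assert by_region.get("midline") == {False}
        assert by_region.get("lamina") == {True}


class TestDivisions:
    def test_threshold_crossing_divides_and_conserves_area(self):
        cc, variant = small_complex("epidermis")
        params = DivisionParams.for_variant(variant)
        st = uniform_state_for(cc.canvas, pmf=0.9)
        update_competence(cc, st, params, variant)
        for c in cc.live_cells():
            c.target_area = 50.0
        # eligible = competent cells already over the 50 μm² target
        n0 = len(cc.live_cells())
        eligible = int((cc.areas() >= 50.0).sum())
        area0 = cc.areas().sum()
        events = attempt_divisions(cc, st, 120.0, 1.0,
                                   np.random.default_rng(1), params, variant)
        assert len(events) == eligible     # each divides exactly once
        assert len(cc.live_cells()) == n0 + eligible
        assert cc.areas().sum() == pytest.approx(area0, rel=1e-9)
        for ev in events:
            da, db = ev["daughters"]
            s = cc.areas([da, db]).sum()
            assert s == pytest.approx(ev["mother_area"], rel=1e-9)

    def test_noncompetent_never_divides(self):
        cc, variant = small_complex("epidermis")
        params = DivisionParams.for_variant(variant)
        st = uniform_state_for(cc.canvas, pmf=0.0)   # outside corridor
        update_competence(cc, st, params, variant)
        for c in cc.live_cells():
            c.target_area = 1.0
        events = attempt_divisions(cc, st, 120.0, 1.0,
                                   np.random.default_rng(1), params, variant)
        assert events == []

    def test_below_target_unchanged(self):
        cc, variant = small_complex("epidermis")
        params = DivisionParams.for_variant(variant)
        st = uniform_state_for(cc.canvas, pmf=0.9)
        update_competence(cc, st, params, variant)
        for c in cc.live_cells():
            c.target_area = 1e6
        events = attempt_divisions(cc, st, 120.0, 1.0,
                                   np.random.default_rng(1), params, variant)
        assert events == []

    def test_conforming_after_divisions(self):
        # every interior edge is shared by exactly two polygons
        cc, variant = small_complex("epidermis")
        params = DivisionParams.for_variant(variant)
        st = uniform_state_for(cc.canvas, pmf=0.9)
        update_competence(cc, st, params, variant)
        for c in cc.live_cells():
            c.target_area = 60.0
        attempt_divisions(cc, st, 120.0, 1.0, np.random.default_rng(1),
                          params, variant)
        cc._edge_map = None
        for edge, inc in cc.edge_map().items():
            assert 1 <= len(inc) <= 2


class TestIntercellularSpaces:
    def test_initialisation_count_and_layer_gating(self):
        cc, variant = small_complex("subepidermis", width=200.0, height=300.0,
                                    cell_area=80.0)
        params = DivisionParams.for_variant(variant)
        params = DivisionParams(pmf_min=0.184, space_init_count=10)
        rng = np.random.default_rng(0)
        manage_spaces(cc, 120.0, 1.0, rng, params, variant)
        spaces = [c for c in cc.cells.values() if c.is_space]
        assert len(spaces) == 10
        for s in spaces:
            assert abs(polygon_area(cc.vx_xy[s.vertices])) == pytest.approx(
                2.0, rel=0.05)
        # epidermis never forms spaces
        cc2, v2 = small_complex("epidermis")
        manage_spaces(cc2, 120.0, 1.0, rng, DivisionParams(pmf_min=0.295), v2)
        assert not any(c.is_space for c in cc2.cells.values())

    def test_no_spaces_before_120h(self):
        cc, variant = small_complex("subepidermis")
        params = DivisionParams(pmf_min=0.184)
        manage_spaces(cc, 119.0, 1.0, np.random.default_rng(0), params,
                      variant)
        assert not any(c.is_space for c in cc.cells.values())

    def test_replacement_rate_after_init(self):
        cc, variant = small_complex("subepidermis", width=260.0, height=400.0,
                                    cell_area=60.0)
        params = DivisionParams(pmf_min=0.184, space_init_count=5)
        rng = np.random.default_rng(0)
        manage_spaces(cc, 120.0, 1.0, rng, params, variant)
        manage_spaces(cc, 121.0, 1.0, rng, params, variant)
        spaces = [c for c in cc.cells.values() if c.is_space]
        assert len(spaces) == 5 + 11       # 11 h⁻¹ afterwards

    def test_radial_expansion_areal_rate(self):
        # 2.5 % h⁻¹ areal growth: factor e^{0.25} over 10 h within 1 %
        cc, variant = small_complex("subepidermis", width=200.0, height=300.0,
                                    cell_area=80.0)
        params = DivisionParams(pmf_min=0.184, space_init_count=3)
        rng = np.random.default_rng(0)
        manage_spaces(cc, 120.0, 1.0, rng, params, variant)
        sp = [c for c in cc.cells.values() if c.is_space]
        a0 = np.array([abs(polygon_area(cc.vx_xy[s.vertices])) for s in sp])
        for _ in range(10):
            cc.grow_spaces(1.0, params)
        a1 = np.array([abs(polygon_area(cc.vx_xy[s.vertices])) for s in sp])
        np.testing.assert_allclose(a1 / a0, np.exp(0.25), rtol=0.01)

    def test_tiling_preserved_with_spaces(self):
        cc, variant = small_complex("subepidermis", width=200.0, height=300.0,
                                    cell_area=80.0)
        params = DivisionParams(pmf_min=0.184, space_init_count=8)
        area0 = cc.areas([c.cid for c in cc.live_cells(include_spaces=True)]).sum()
        manage_spaces(cc, 120.0, 1.0, np.random.default_rng(0), params,
                      variant)
        allc = [c.cid for c in cc.live_cells(include_spaces=True)]
        assert cc.areas(allc).sum() == pytest.approx(area0, rel=5e-3)
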