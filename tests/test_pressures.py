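"""Critical-pressure formulas, outcome classification, design boundaries."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import railpattern as rp

UM = 1e-6
FIBRINOGEN = rp.get_fluid("fibrinogen_2p5")
COLLAGEN = rp.get_fluid("collagen_3")

positive_len = st.floats(min_value=1e-6, max_value=1e-2)


def brute_force_outcome(dpo, dpl, dph):
    """Independent oracle: apply the ordering rules directly to the
    three pressures (ties resolved by the same >= / <= conventions)."""
    if dpo >= dpl:
        return rp.OutcomeClass.FAIL_LR_BEFORE_PORT
    if dpl <= dph:
        return rp.OutcomeClass.FAIL_LR_AFTER_PORT
    if dpo >= dph:
        return rp.OutcomeClass.SUCCESS_CONTINUOUS
    return rp.OutcomeClass.SUCCESS_STEPWISE


class TestOpenPortPressure:
    def test_worked_water_value(self, water):
        # hemispherical cap at a 600 μm port
        assert rp.open_port_pressure(water, 600 * UM) == pytest.approx(479.8, rel=1e-3)

    def test_fibrinogen_hand_value(self):
        # 4 x 0.0570 / 6.0e-4
        assert rp.open_port_pressure(FIBRINOGEN, 600 * UM) == pytest.approx(380.0, rel=1e-9)

    def test_doubling_diameter_halves_pressure(self, water):
        p1 = rp.open_port_pressure(water, 300 * UM)
        p2 = rp.open_port_pressure(water, 600 * UM)
        assert p1 == pytest.approx(2 * p2, rel=1e-12)

    def test_vanishes_for_huge_port(self, water):
        assert rp.open_port_pressure(water, 1e6) < 1e-6

    def test_rejects_nonpositive_diameter(self, water):
        with pytest.raises(rp.DomainError):
            rp.open_port_pressure(water, 0.0)


class TestLowRailPressure:
    def test_worked_water_value(self, water):
        assert rp.low_rail_pressure(water, 100 * UM) == pytest.approx(1439.4, rel=1e-4)

    def test_collagen_hand_value(self):
        # 2 x 0.0617 / 1.0e-4
        assert rp.low_rail_pressure(COLLAGEN, 100 * UM) == pytest.approx(1234.0, rel=1e-9)

    def test_cos_theta_zero_annihilates(self, water):
        opts = rp.PressureModelOptions(cos_theta_override=0.0)
        assert rp.low_rail_pressure(water, 100 * UM, opts) == 0.0

    def test_eta_term_additive_as_printed(self, water):
        opts = rp.PressureModelOptions(include_eta_term=True, eta=5e-3)
        base = rp.low_rail_pressure(water, 100 * UM)
        with_eta = rp.low_rail_pressure(water, 100 * UM, opts)
        assert with_eta == pytest.approx(base + water.surface_tension / 5e-3, rel=1e-12)

    def test_rejects_nonpositive_height(self, water):
        with pytest.raises(rp.DomainError):
            rp.low_rail_pressure(water, -1e-4)


class TestHighRailPressure:
    def test_single_interface_matches_worked_value(self, water, single_interface_options):
        p = rp.high_rail_pressure(water, 300 * UM, 1e-3, single_interface_options)
        assert p == pytest.approx(311.9, rel=1e-3)

    def test_factor2_is_exactly_double(self, water, single_interface_options):
        p1 = rp.high_rail_pressure(water, 300 * UM, 1e-3, single_interface_options)
        p2 = rp.high_rail_pressure(water, 300 * UM, 1e-3)
        assert p2 == 2 * p1

    @given(h=positive_len, w=positive_len)
    def test_factor2_double_for_all_inputs(self, h, w):
        f = rp.get_fluid("water_numeric")
        si = rp.PressureModelOptions(hr_convention=rp.HRConvention.SINGLE_INTERFACE)
        assert rp.high_rail_pressure(f, h, w) == 2 * rp.high_rail_pressure(f, h, w, si)

    def test_wide_rail_degenerates_to_low_rail_form(self, water):
        # 2γ(1/w + 1/H) → 2γ/H as w → ∞, i.e. the low-rail formula at gap H
        p = rp.high_rail_pressure(water, 300 * UM, 1e6)
        assert p == pytest.approx(rp.low_rail_pressure(water, 300 * UM), rel=1e-6)


class TestCriticalPressures:
    def test_worked_triple(self, water, single_interface_options):
        geom = (600 * UM, 100 * UM, 300 * UM, 1000 * UM)
        ps = rp.critical_pressures(geom, water, single_interface_options)
        assert ps.dp_open == pytest.approx(479.8, rel=1e-3)
        assert ps.dp_low == pytest.approx(1439.4, rel=1e-4)
        assert ps.dp_high == pytest.approx(311.9, rel=1e-3)
        assert ps.fluid_name == "water_numeric"

    def test_linearity_in_surface_tension(self, water):
        geom = (600 * UM, 100 * UM, 300 * UM, 1000 * UM)
        doubled = rp.Fluid("2x", surface_tension=2 * water.surface_tension)
        a = rp.critical_pressures(geom, water)
        b = rp.critical_pressures(geom, doubled)
        for attr in ("dp_open", "dp_low", "dp_high"):
            assert getattr(b, attr) == pytest.approx(2 * getattr(a, attr), rel=1e-12)

    def test_fibrinogen_factor2_triple(self):
        geom = (600 * UM, 100 * UM, 300 * UM, 1000 * UM)
        ps = rp.critical_pressures(geom, FIBRINOGEN)
        assert ps.dp_open == pytest.approx(380.0, rel=1e-9)
        assert ps.dp_low == pytest.approx(1140.0, rel=1e-9)
        assert ps.dp_high == pytest.approx(494.0, rel=1e-9)

    def test_device_spec_equivalent_to_tuple(self, water, basic_device):
        geom = (600 * UM, 100 * UM, 300 * UM, 1000 * UM)
        a = rp.critical_pressures(geom, water)
        b = rp.critical_pressures(basic_device, water)
        assert (a.dp_open, a.dp_low, a.dp_high) == (b.dp_open, b.dp_low, b.dp_high)

    @given(
        d=positive_len, h=positive_len, hh=positive_len, w=positive_len,
        factor=st.floats(min_value=1.01, max_value=3.0),
    )
    def test_monotone_decreasing_in_each_length(self, d, h, hh, w, factor):
        f = rp.get_fluid("water_numeric")
        assert rp.open_port_pressure(f, d * factor) < rp.open_port_pressure(f, d)
        assert rp.low_rail_pressure(f, h * factor) < rp.low_rail_pressure(f, h)
        assert rp.high_rail_pressure(f, hh * factor, w) < rp.high_rail_pressure(f, hh, w)
        assert rp.high_rail_pressure(f, hh, w * factor) < rp.high_rail_pressure(f, hh, w)


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "geom_um,expected",
        [
            ((300, 100, 300, 1000), rp.OutcomeClass.SUCCESS_CONTINUOUS),
            ((300, 200, 300, 1000), rp.OutcomeClass.FAIL_LR_BEFORE_PORT),
            ((500, 175, 200, 1000), rp.OutcomeClass.FAIL_LR_AFTER_PORT),
        ],
    )
    def test_reference_geometries(self, water, geom_um, expected):
        geom = tuple(v * UM for v in geom_um)
        assert rp.classify_outcome(rp.critical_pressures(geom, water)) is expected

    def test_stepwise_success_exists(self, water):
        # low rail hardest, but lane interface harder than the port
        geom = (600 * UM, 100 * UM, 150 * UM, 1000 * UM)
        ps = rp.critical_pressures(geom, water)
        assert ps.dp_low > ps.dp_high > ps.dp_open
        assert rp.classify_outcome(ps) is rp.OutcomeClass.SUCCESS_STEPWISE

    def test_exact_tie_warns_boundary(self, water):
        geom = (200 * UM, 100 * UM, 300 * UM, 1000 * UM)  # D = 2h exactly
        ps = rp.critical_pressures(geom, water)
        with pytest.warns(rp.BoundaryWarning):
            outcome = rp.classify_outcome(ps)
        assert outcome is rp.OutcomeClass.FAIL_LR_BEFORE_PORT

    def test_fluid_independence_on_table_fluids(self):
        rng = np.random.default_rng(7)
        fluids = [rp.get_fluid(n) for n in ("water_table1", "fibrinogen_2p5", "collagen_3")]
        for _ in range(200):
            d, h, hh, w = rng.uniform(50, 1000, size=4) * UM
            outcomes = {
                rp.classify_outcome(rp.critical_pressures((d, h, hh, w), f))
                for f in fluids
            }
            assert len(outcomes) == 1

    def test_matches_brute_force_oracle_on_random_geometries(self):
        # 10^4 random geometries vs the independently stated ordering rules
        rng = np.random.default_rng(42)
        f = rp.get_fluid("water_numeric")
        g = f.surface_tension
        n_classes = set()
        for _ in range(10_000):
            d, h, hh, w = rng.uniform(20, 1500, size=4) * UM
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", rp.BoundaryWarning)
                got = rp.classify_outcome(rp.critical_pressures((d, h, hh, w), f))
            expected = brute_force_outcome(4 * g / d, 2 * g / h, 2 * g * (1 / w + 1 / hh))
            assert got is expected
            n_classes.add(got)
        assert len(n_classes) == 4  # the sweep exercises every class


class TestBoundaries:
    def test_port_boundary_is_twice_low_height(self):
        assert rp.boundary_port_diameter(100 * UM) == pytest.approx(200 * UM, rel=1e-12)
        assert rp.boundary_port_diameter(300 * UM) == pytest.approx(600 * UM, rel=1e-12)

    def test_port_boundary_pressure_balance(self, water):
        # Δp_O(D*) = Δp_L(h) to machine precision
        h = 100 * UM
        dstar = rp.boundary_port_diameter(h)
        dpo = rp.open_port_pressure(water, dstar)
        dpl = rp.low_rail_pressure(water, h)
        assert abs(dpl - dpo) < 1e-9 * dpl

    def test_high_rail_boundary_values(self):
        hstar = rp.boundary_high_rail(100 * UM, 1000 * UM)
        assert hstar == pytest.approx(111.111 * UM, rel=1e-4)
        # h = 175 μm puts the boundary at 212.1 μm, so H = 200 μm fails
        hstar2 = rp.boundary_high_rail(175 * UM, 1000 * UM)
        assert hstar2 == pytest.approx(212.12 * UM, rel=1e-4)
        assert 200 * UM < hstar2

    def test_high_rail_boundary_pressure_balance(self, water):
        h, w = 100 * UM, 1000 * UM
        hstar = rp.boundary_high_rail(h, w)
        dpl = rp.low_rail_pressure(water, h)
        dph = rp.high_rail_pressure(water, hstar, w)
        assert abs(dpl - dph) < 1e-9 * dpl

    def test_high_rail_boundary_no_solution(self):
        with pytest.raises(rp.NoSolutionError):
            rp.boundary_high_rail(1e-3, 1e-3)

    @given(h=st.floats(min_value=1e-6, max_value=9e-4))
    def test_boundary_tends_to_h_for_thin_gaps(self, h):
        w = 1e-3
        hstar = rp.boundary_high_rail(h, w)
        assert hstar >= h
        if h < 1e-5:
            assert hstar == pytest.approx(h, rel=2e-2)

    def test_classifier_flips_across_port_boundary(self, water):
        h = 100 * UM
        dstar = rp.boundary_port_diameter(h)
        below = rp.critical_pressures((dstar * 0.999, h, 300 * UM, 1e-3), water)
        above = rp.critical_pressures((dstar * 1.001, h, 300 * UM, 1e-3), water)
        assert rp.classify_outcome(below) is rp.OutcomeClass.FAIL_LR_BEFORE_PORT
        assert rp.classify_outcome(above) is not rp.OutcomeClass.FAIL_LR_BEFORE_PORT


class TestSafeAspirationWindow:
    def test_worked_window(self, water, single_interface_options):
        geom = (600 * UM, 100 * UM, 300 * UM, 1000 * UM)
        win = rp.safe_aspiration_window(rp.critical_pressures(geom, water, single_interface_options))
        assert win[0] == pytest.approx(479.8, rel=1e-3)
        assert win[1] == pytest.approx(1439.4, rel=1e-4)

    def test_empty_window_when_port_out_pins_low_rail(self, water):
        geom = (300 * UM, 200 * UM, 300 * UM, 1000 * UM)  # Δp_O > Δp_L
        assert rp.safe_aspiration_window(rp.critical_pressures(geom, water)) is None

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_window_emptiness_invariant_under_gamma_rescale(self, scale):
        opts = rp.PressureModelOptions(hr_convention=rp.HRConvention.SINGLE_INTERFACE)
        base = rp.get_fluid("water_numeric")
        scaled = rp.Fluid("s", surface_tension=base.surface_tension * scale)
        geom = (600 * UM, 100 * UM, 300 * UM, 1000 * UM)
        w1 = rp.safe_aspiration_window(rp.critical_pressures(geom, base, opts))
        w2 = rp.safe_aspiration_window(rp.critical_pressures(geom, scaled, opts))
        assert (w1 is None) == (w2 is None)
        if w1:
            assert w2[0] == pytest.approx(w1[0] * scale, rel=1e-12)
            assert w2[1] == pytest.approx(w1[1] * scale, rel=1e-12)


class TestPhaseDiagram:
    def test_worked_cell_is_successful(self):
        table = rp.phase_diagram("D_vs_h", fixed={"H_um": 300, "w_um": 1000})
        cell = table[(table.x_um == 100) & (table.y_um == 600)]
        assert len(cell) == 1
        assert rp.OutcomeClass(cell.outcome_class.iloc[0]).is_success

    def test_classes_fluid_invariant(self):
        t1 = rp.phase_diagram("H_vs_h", fluid=rp.get_fluid("water_table1"))
        t2 = rp.phase_diagram("H_vs_h", fluid=rp.get_fluid("collagen_3"))
        assert (t1.outcome_class == t2.outcome_class).all()

    def test_cells_straddling_port_boundary_differ(self):
        table = rp.phase_diagram("D_vs_h", fixed={"H_um": 300, "w_um": 1000})
        for h in (100.0, 150.0, 200.0):
            col = table[table.x_um == h].sort_values("y_um")
            below = col[col.y_um < 2 * h].outcome_class
            above = col[col.y_um > 2 * h].outcome_class
            if len(below) and len(above):
                assert below.iloc[-1] != above.iloc[0]

    def test_boundary_cells_marked_near_closed_form(self):
        table = rp.phase_diagram("D_vs_h", fixed={"H_um": 300, "w_um": 1000})
        marked = table[table.is_boundary]
        step = 10.0
        assert len(marked) > 0
        assert (np.abs(marked.y_um - 2 * marked.x_um) <= step / 2 + 1e-9).all()

    def test_degenerate_grid_rejected(self):
        with pytest.raises(rp.ConfigError):
            rp.phase_diagram("D_vs_h", grid={"h_um": (100.0, 50.0, 5.0)})

    def test_row_count_matches_grid(self):
        table = rp.phase_diagram(
            "D_vs_h",
            grid={"h_um": (50.0, 60.0, 5.0), "D_um": (100.0, 140.0, 10.0)},
        )
        assert len(table) == 3 * 5
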