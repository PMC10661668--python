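"""Unit and property tests for the electro-fluidic dosimetry model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stimchip.dosimetry import (
    ChannelGeometry,
    Edge,
    ElectrodeSpec,
    Electrolyte,
    ExcursionResult,
    ResistorNetwork,
    SampledTrace,
    StimulationProtocol,
    analyze_excursion,
    capacitance_from_cv,
    capacitive_discharge_time,
    channel_resistance,
    delivered_charge,
    disk_current_density,
    field_from_current,
    kcl_residuals,
    section_fields,
    solve_network,
)
from stimchip.errors import DomainError, InsufficientDataError, TopologyError
from stimchip.io import load_chamber_config

PBS = Electrolyte(1.5)  # S/m, physiological saline


class TestChannelResistance:
    def test_hand_evaluated_reference_channel(self):
        # L/(sigma*w*h) for a 10 mm x 7 mm x 0.8 mm channel in 1.5 S/m
        g = ChannelGeometry(10e-3, 7e-3, 0.8e-3)
        assert channel_resistance(g, PBS) == pytest.approx(1190.5, abs=0.1)

    def test_unit_case(self):
        assert channel_resistance(ChannelGeometry(1, 1, 1), Electrolyte(1.0)) == 1.0

    @given(scale=st.floats(1.1, 10))
    @settings(max_examples=25, derandomize=True)
    def test_linearity_in_length_and_width(self, scale):
        g = ChannelGeometry(10e-3, 7e-3, 0.8e-3)
        base = channel_resistance(g, PBS)
        longer = ChannelGeometry(g.length * scale, g.width, g.height)
        wider = ChannelGeometry(g.length, g.width * scale, g.height)
        assert channel_resistance(longer, PBS) == pytest.approx(base * scale)
        assert channel_resistance(wider, PBS) == pytest.approx(base / scale)

    @pytest.mark.parametrize("dims", [(0, 1, 1), (1, -1, 1), (1, 1, 0)])
    def test_nonpositive_dimension_rejected(self, dims):
        with pytest.raises(DomainError):
            ChannelGeometry(*dims)

    def test_nonpositive_conductivity_rejected(self):
        with pytest.raises(DomainError):
            Electrolyte(0.0)


class TestFieldFromCurrent:
    def test_zero_current_gives_zero_field(self):
        g = ChannelGeometry(10e-3, 7e-3, 0.8e-3)
        assert field_from_current(0.0, g, PBS) == 0.0

    def test_reference_current_round_trip(self):
        # A chosen so that 43.5 uA in 1.5 S/m produces 4.7 V/m; the formula
        # must invert itself (round-trip consistency, not geometry truth).
        i, E = 43.5e-6, 4.7
        area = i / (PBS.conductivity * E)
        g = ChannelGeometry(10e-3, area / 0.8e-3, 0.8e-3)
        assert g.cross_section == pytest.approx(6.17e-6, rel=1e-3)
        assert field_from_current(i, g, PBS) == pytest.approx(E)

    @given(i=st.floats(1e-9, 1e-2))
    @settings(max_examples=25, derandomize=True)
    def test_linearity_in_current(self, i):
        g = ChannelGeometry(10e-3, 7e-3, 0.8e-3)
        assert field_from_current(2 * i, g, PBS) == pytest.approx(
            2 * field_from_current(i, g, PBS), rel=1e-12
        )

    def test_negative_current_rejected(self):
        with pytest.raises(DomainError):
            field_from_current(-1e-6, ChannelGeometry(1, 1, 1), PBS)


def _two_branch(r1, r2, i_in=1e-3):
    e1 = Edge("a", "b", resistance=r1)
    e2 = Edge("a", "b", resistance=r2)
    net = ResistorNetwork(edges=(e1, e2), source=("a", "b", i_in))
    return net, e1, e2


class TestSolveNetwork:
    def test_single_series_branch_carries_all_current(self):
        e = Edge("a", "b", resistance=100.0)
        net = ResistorNetwork(edges=(e,), source=("a", "b", 2e-3))
        assert solve_network(net)[e] == pytest.approx(2e-3)

    def test_equal_parallel_resistors_split_evenly(self):
        net, e1, e2 = _two_branch(100.0, 100.0)
        currents = solve_network(net)
        assert currents[e1] == pytest.approx(0.5e-3)
        assert currents[e2] == pytest.approx(0.5e-3)

    def test_2R_2p2R_divider_matches_closed_form(self):
        # i1 = i * R2/(R1+R2): the 2R branch takes 2.2/4.2 = 52.38 %
        net, e1, e2 = _two_branch(2.0, 2.2, i_in=1.0)
        currents = solve_network(net)
        assert currents[e1] == pytest.approx(2.2 / 4.2, rel=1e-12)
        assert currents[e2] == pytest.approx(2.0 / 4.2, rel=1e-12)

    def test_disconnected_terminals_raise(self):
        e = Edge("a", "b", resistance=1.0)
        net = ResistorNetwork(edges=(e,), source=("a", "z", 1e-3))
        with pytest.raises(TopologyError):
            solve_network(net)

    @given(
        resistances=st.lists(st.floats(1.0, 1e4), min_size=2, max_size=6),
        i_in=st.floats(1e-6, 1e-2),
    )
    @settings(max_examples=60, derandomize=True)
    def test_kirchhoff_conservation_on_random_parallel_ladders(self, resistances, i_in):
        # Parallel branches, each a short series chain: KCL residual at every
        # node below 1e-9 of the source current.
        edges = []
        for k, r in enumerate(resistances):
            mid = f"m{k}"
            edges.append(Edge("a", mid, resistance=r))
            edges.append(Edge(mid, "b", resistance=r / 2 + 1.0))
        net = ResistorNetwork(edges=tuple(edges), source=("a", "b", i_in))
        currents = solve_network(net)
        residuals = kcl_residuals(net, currents)
        assert max(abs(v) for v in residuals.values()) < 1e-9 * i_in

    @given(r1=st.floats(1.0, 1e5), r2=st.floats(1.0, 1e5))
    @settings(max_examples=60, derandomize=True)
    def test_two_branch_divider_closed_form(self, r1, r2):
        net, e1, e2 = _two_branch(r1, r2, i_in=1.0)
        currents = solve_network(net)
        assert currents[e1] == pytest.approx(r2 / (r1 + r2), rel=1e-12)
        assert currents[e2] == pytest.approx(r1 / (r1 + r2), rel=1e-12)


class TestSectionFields:
    def test_example_chamber_fields_strictly_ordered(self, chamber_config):
        fields = section_fields(chamber_config.network)
        assert set(fields) == {"s1", "s2", "s3"}
        assert fields["s1"] > fields["s2"] > fields["s3"]

    def test_example_chamber_linearity_in_input_current(self, chamber_config):
        net = chamber_config.network
        base = section_fields(net)
        doubled = ResistorNetwork(
            edges=net.edges,
            source=(net.source[0], net.source[1], 2 * net.source[2]),
            electrolyte=net.electrolyte,
        )
        for label, value in section_fields(doubled).items():
            assert value == pytest.approx(2 * base[label], rel=1e-12)

    def test_zero_input_current_gives_zero_fields(self, chamber_config):
        net = chamber_config.network
        off = ResistorNetwork(
            edges=net.edges, source=(net.source[0], net.source[1], 0.0),
            electrolyte=net.electrolyte,
        )
        assert all(v == 0 for v in section_fields(off).values())


class TestElectrodeBudget:
    def test_reference_disk_current_density(self):
        # 43.5 uA on a 15 mm disk -> 24.6 uA/cm^2
        j = disk_current_density(43.5e-6, ElectrodeSpec(diameter=15e-3))
        assert j * 1e6 / 1e4 == pytest.approx(24.6, abs=0.05)

    def test_zero_current_and_area_scaling(self):
        e = ElectrodeSpec(diameter=15e-3)
        assert disk_current_density(0.0, e) == 0.0
        e2 = ElectrodeSpec(diameter=30e-3)
        assert disk_current_density(1e-6, e2) == pytest.approx(
            disk_current_density(1e-6, e) / 4
        )

    @pytest.mark.parametrize(
        "protocol, expected_mC",
        [
            (StimulationProtocol("pulsed", 1.29e-3, pulse_on=0.1, pulse_off=0.5,
                                 n_pulses=100), 12.9),
            (StimulationProtocol("dc", 43.5e-6, duration=600.0), 26.1),
            (StimulationProtocol("pulsed", 1.0, pulse_on=1.0, n_pulses=0), 0.0),
        ],
    )
    def test_delivered_charge(self, protocol, expected_mC):
        assert delivered_charge(protocol) * 1e3 == pytest.approx(expected_mC)

    @given(
        i=st.floats(1e-6, 1e-3),
        t_on=st.floats(1e-3, 10.0),
        n=st.integers(1, 500),
    )
    @settings(max_examples=40, derandomize=True)
    def test_pulsed_equals_dc_of_equivalent_on_time(self, i, t_on, n):
        pulsed = StimulationProtocol("pulsed", i, pulse_on=t_on, pulse_off=0.5,
                                     n_pulses=n)
        dc = StimulationProtocol("dc", i, duration=t_on * n)
        assert delivered_charge(pulsed) == pytest.approx(delivered_charge(dc))

    def test_capacitive_discharge_time(self):
        e = ElectrodeSpec(diameter=1e-2, capacitance=1.0, voltage_window=1.0)
        assert capacitive_discharge_time(e, 1.0) == 1.0
        assert capacitive_discharge_time(e, 2.0) == 0.5
        assert math.isinf(capacitive_discharge_time(e, 0.0))

    def test_charge_budget_round_trip_from_printed_window(self):
        # If the capacitive window at 43.5 uA is 12.5 min, the electrode's
        # C * dV product must be 32.6 mC; supplying that product back must
        # reproduce the window.
        i, t = 43.5e-6, 12.5 * 60
        q = i * t
        assert q * 1e3 == pytest.approx(32.6, abs=0.05)
        e = ElectrodeSpec(diameter=15e-3, capacitance=q / 0.6, voltage_window=0.6)
        assert capacitive_discharge_time(e, i) / 60 == pytest.approx(12.5, rel=1e-6)


class TestCapacitanceFromCV:
    def test_ideal_rectangular_cv(self):
        # Ideal capacitor at scan rate v: i = +/- C*v -> C recovered exactly.
        C_true, rate = 0.05, 1e-3
        v_window = np.linspace(0.0, 0.8, 401)
        V = np.concatenate([v_window, v_window[::-1][1:]])
        I = np.concatenate([np.full(401, C_true * rate), np.full(400, -C_true * rate)])
        C = capacitance_from_cv(SampledTrace(V, I), rate)
        assert C == pytest.approx(C_true, rel=1e-6)

    def test_zero_current_gives_zero_capacitance(self):
        V = np.concatenate([np.linspace(0, 1, 50), np.linspace(1, 0, 50)[1:]])
        assert capacitance_from_cv(SampledTrace(V, np.zeros_like(V)), 1e-3) == 0.0

    def test_triangular_cv_matches_rectangle_rule_oracle(self):
        # Independent oracle: fine-step left-rectangle integration of |i||dV|.
        rate = 2e-3
        V_up = np.linspace(0.0, 1.0, 2001)
        I_up = 0.01 * V_up  # current ramps with potential
        V = np.concatenate([V_up, V_up[::-1][1:]])
        I = np.concatenate([I_up, -I_up[::-1][1:]])
        riemann = float(np.sum(np.abs(I[:-1]) * np.abs(np.diff(V))))
        oracle = riemann / (2 * rate * 1.0)
        C = capacitance_from_cv(SampledTrace(V, I), rate)
        assert C == pytest.approx(oracle, rel=1e-3)

    def test_nonpositive_scan_rate_rejected(self):
        V = np.linspace(0, 1, 10)
        with pytest.raises(DomainError):
            capacitance_from_cv(SampledTrace(V, V), 0.0)

    def test_ideal_capacitor_recovery_at_fine_steps(self):
        # Round trip: <1% recovery at <=1 mV steps even with a slight tilt.
        C_true, rate = 0.1, 1e-3
        v = np.arange(0.0, 0.5 + 1e-12, 1e-3)
        i_fwd = C_true * rate * (1 + 0.001 * v)
        V = np.concatenate([v, v[::-1][1:]])
        I = np.concatenate([i_fwd, -i_fwd[::-1][1:]])
        C = capacitance_from_cv(SampledTrace(V, I), rate)
        assert abs(C - C_true) / C_true < 0.01


class TestAnalyzeExcursion:
    def test_pure_capacitor_ramp(self):
        t = np.linspace(0, 60, 200)
        a = 0.02  # V/s
        res = analyze_excursion(SampledTrace(t, a * t), i=1e-3)
        assert res.regime == "capacitive"
        assert res.transition_time is None
        assert res.c_eff == pytest.approx(1e-3 / a, rel=1e-9)

    def test_ramp_then_plateau_finds_breakpoint(self):
        t = np.linspace(0, 100, 401)
        t0 = 40.0
        V = np.where(t < t0, 0.01 * t, 0.01 * t0)
        res = analyze_excursion(SampledTrace(t, V), i=1e-3)
        assert res.regime == "faradaic_onset"
        assert res.transition_time == pytest.approx(t0, abs=1.0)
        assert res.c_eff == pytest.approx(0.1, rel=1e-6)

    def test_breakpoint_matches_brute_force_search(self):
        rng = np.random.default_rng(11)
        t = np.linspace(0, 100, 301)
        V = np.where(t < 62.0, 0.005 * t, 0.005 * 62.0) + rng.normal(0, 1e-4, t.size)
        res = analyze_excursion(SampledTrace(t, V), i=1e-3)

        def sse_line(x, y):
            A = np.vstack([x, np.ones_like(x)]).T
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            r = y - A @ coef
            return float(r @ r)

        best_k = min(range(2, t.size - 1),
                     key=lambda k: sse_line(t[:k], V[:k]) + sse_line(t[k:], V[k:]))
        assert res.breakpoint_index == best_k
        assert res.transition_time == pytest.approx(62.0, abs=2.0)

    def test_flat_trace_is_faradaic_dominant(self):
        t = np.linspace(0, 60, 100)
        res = analyze_excursion(SampledTrace(t, np.full_like(t, 0.2)), i=1e-3)
        assert res.regime == "faradaic_dominant"
        assert res.c_eff is None

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            analyze_excursion(SampledTrace(np.arange(3.0), np.arange(3.0)), 1e-3)

    def test_non_monotonic_time_axis_rejected(self):
        t = np.array([0.0, 1.0, 0.5, 2.0])
        with pytest.raises(DomainError):
            analyze_excursion(SampledTrace(t, t), 1e-3)


class TestConfigLoading:
    def test_example_config_round_trip(self, chamber_config):
        assert chamber_config.electrolyte.conductivity == 1.5
        assert chamber_config.network.source[2] == pytest.approx(43.5e-6)
        assert chamber_config.electrode.diameter == pytest.approx(15e-3)

    def test_missing_key_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("electrolyte: {sigma: 1.0}\n")
        with pytest.raises(DomainError):
            load_chamber_config(p)
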