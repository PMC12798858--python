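"""Cell assembly and integration: geometry arithmetic, passive RC/cable
oracles, holding-bias solution, stability of the standard model."""

import math

import numpy as np
import pytest

import fsneuron as fs
from fsneuron.cell import ConfigError
from fsneuron.features import measure_rin, measure_tau
from fsneuron.protocols import StepProtocol


class TestGeometry:
    def test_standard_discretization(self, standard_cell):
        # 140 um axon at 2 um -> 70 segments; 200 um dendrite -> 100
        assert standard_cell.n_axon == 70
        assert standard_cell.n_dend == 100
        assert standard_cell.n_nodes == 171
        assert standard_cell.soma_idx == 100

    def test_ais_span(self, standard_cell):
        # AIS 10-30 um covers exactly 10 segments; Nav1.6 lives only there
        k = [s.name for s in standard_cell.channels].index("nav16")
        gbar = standard_cell.gbar[k]
        nodes = np.flatnonzero(gbar > 0)
        assert nodes.min() == standard_cell.soma_idx + 1 + 5
        assert nodes.max() == standard_cell.soma_idx + 1 + 14

    def test_ais_segment_conductance(self, standard_cfg):
        # 20 nS/um^2 * pi * 0.8 um * 2 um = 100.53 nS per segment
        cell = fs.build_cell(standard_cfg)
        k = [s.name for s in cell.channels].index("nav16")
        seg = cell.gbar[k][cell.soma_idx + 1 + 7]
        assert seg == pytest.approx(20.0 * math.pi * 0.8 * 2.0, rel=1e-12)

    def test_total_ais_conductance_scales_linearly_with_length(self, standard_cfg):
        totals = []
        for L in (10.0, 20.0, 25.0, 30.0):
            cell = fs.build_cell(fs.with_overrides(standard_cfg,
                                                   {"ais": {"length_um": L}}))
            k = [s.name for s in cell.channels].index("nav16")
            totals.append(cell.gbar[k].sum())
        ratios = np.array(totals) / totals[0]
        assert ratios == pytest.approx([1.0, 2.0, 2.5, 3.0], rel=1e-9)

    def test_ais_past_axon_end_rejected(self, standard_cfg):
        bad = fs.with_overrides(standard_cfg, {"ais": {"start_um": 130.0,
                                                       "length_um": 20.0}})
        with pytest.raises(ConfigError, match="ais"):
            fs.build_cell(bad)

    def test_negative_density_rejected(self, standard_cfg):
        bad = fs.with_overrides(standard_cfg, {"ais": {"gkv1_nS_per_um2": -5.0}})
        with pytest.raises(ConfigError):
            fs.build_cell(bad)


class TestPassiveSoma:
    """Isolated 700 MOhm / 25 pF soma against the closed-form RC solution."""

    def test_holding_bias_ohms_law(self, passive_soma_cell):
        # (V_hold - E_leak) / R = (-70 + 68) mV / 700 MOhm = -2.857 pA
        bias = fs.solve_holding_bias(passive_soma_cell, -70.0)
        assert bias == pytest.approx(-2.0 / 700.0 * 1e3, rel=1e-6)

    def test_rc_charging_curve(self, passive_soma_cell):
        tr = fs.integrate(passive_soma_cell,
                          StepProtocol(amplitude=10.0, duration=250.0), dt=0.01)
        t = tr.t
        on = (t >= 20.0) & (t <= 270.0)
        expect = -70.0 + 7.0 * (1.0 - np.exp(-(t[on] - 20.0) / 17.5))
        assert np.allclose(tr.v_soma[on], expect, atol=0.07)  # 1% of 7 mV

    def test_measured_rin_and_tau(self, passive_soma_cell):
        tr = fs.integrate(passive_soma_cell,
                          StepProtocol(amplitude=10.0, duration=250.0), dt=0.01)
        assert measure_rin([tr], [10.0], 20.0, 250.0) == pytest.approx(700.0, rel=0.01)
        assert measure_tau(tr, 20.0) == pytest.approx(17.5, rel=0.02)

    def test_zero_protocol_stays_at_hold(self, passive_soma_cell):
        tr = fs.integrate(passive_soma_cell,
                          StepProtocol(amplitude=0.0, duration=100.0), dt=0.01)
        assert np.abs(tr.v_soma + 70.0).max() < 0.1


def _passive_linear_system(cfg):
    """Independent steady-state solve of the discretized passive network."""
    geo = cfg["geometry"]
    na = int(round(geo["axon"]["length_um"] / geo["axon"]["segment_length_um"]))
    nd = int(round(geo["dendrite"]["length_um"] / geo["dendrite"]["segment_length_um"]))
    n = nd + 1 + na
    soma = nd
    G = np.zeros((n, n))
    # leaks
    G[soma, soma] += 1e3 / geo["soma"]["leak_resistance_MOhm"]
    dend_area = math.pi * geo["dendrite"]["diameter_um"] * geo["dendrite"]["segment_length_um"]
    g_dend_leak = cfg["channels"]["leak_dend"]["regions"]["dendrite"] * dend_area
    for i in range(nd):
        G[i, i] += g_dend_leak
    # axial couplings
    def couple(i, j, r_MOhm):
        g = 1e3 / r_MOhm
        G[i, i] += g
        G[j, j] += g
        G[i, j] -= g
        G[j, i] -= g
    ra_d = geo["dendrite"]["ra_MOhm_per_um"] * geo["dendrite"]["segment_length_um"]
    for i in range(nd - 1):
        couple(i, i + 1, ra_d)
    couple(nd - 1, soma, ra_d / 2.0)
    ra_a = geo["axon"]["ra_MOhm_per_um"] * geo["axon"]["segment_length_um"]
    couple(soma, soma + 1, ra_a / 2.0)
    for i in range(soma + 1, n - 1):
        couple(i, i + 1, ra_a)
    return G, soma


class TestPassiveCable:
    def test_somatic_rin_matches_linear_algebra_oracle(self, passive_cable_cfg):
        G, soma = _passive_linear_system(passive_cable_cfg)
        rhs = np.zeros(len(G))
        rhs[soma] = 10.0                      # pA
        v = np.linalg.solve(G, rhs)           # deflection about E_leak
        rin_oracle = v[soma] / 10.0 * 1e3     # MOhm

        cell = fs.build_cell(passive_cable_cfg)
        tr = fs.integrate(cell, StepProtocol(amplitude=10.0, duration=400.0), dt=0.02)
        rin = measure_rin([tr], [10.0], 20.0, 400.0)
        assert rin == pytest.approx(rin_oracle, rel=0.02)

    def test_gates_remain_bounded_through_a_spike(self, small_cell):
        from fsneuron.protocols import find_rheobase

        rheo = find_rheobase(small_cell, duration=120.0, resolution=4.0)
        fs.integrate(small_cell, StepProtocol(amplitude=rheo + 20.0, duration=120.0))
        # engine state after the run (settled cache holds gate arrays)
        for (_, _, m, h) in small_cell._settle_cache.values():
            assert np.all((m >= 0) & (m <= 1))
            assert np.all((h >= 0) & (h <= 1))


class TestHoldingAndIntegration:
    def test_holding_accuracy_standard_cell(self, standard_cell):
        tr = fs.integrate(standard_cell, StepProtocol(amplitude=0.0, duration=200.0))
        assert np.abs(tr.v_soma + 70.0).max() < 0.1

    def test_hold_at_rest_needs_no_bias(self, standard_cfg):
        """Bias at the cell's own resting potential is (near) zero."""
        from fsneuron.experiments import baseline_features

        v_rest = baseline_features(standard_cfg)["v_rest"]
        cell = fs.build_cell(standard_cfg)
        bias = fs.solve_holding_bias(cell, v_rest)
        assert abs(bias) < 3.0   # pA; solver tolerance at the fixed point

    def test_invalid_dt_rejected(self, standard_cell):
        with pytest.raises(ValueError):
            fs.integrate(standard_cell, StepProtocol(amplitude=0.0), dt=-0.01)

    def test_trace_metadata_and_channels(self, standard_cell):
        tr = fs.integrate(standard_cell, StepProtocol(amplitude=0.0, duration=50.0))
        assert tr.channels == ("soma", "ais_mid")
        assert tr.metadata["model_digest"] == standard_cell.digest
        assert len(tr.vm) == len(tr.i_stim)
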