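import math

import numpy as np
import pytest

from spinesim.electrics import (bap_waveform, electrical_params, mg_block_factor,
                                simulate_potential, vdcc_gate_inf,
                                vdcc_open_fraction)
from spinesim.protocols import StimulusProtocol, bap_protocol


@pytest.fixture(scope="module")
def eparams(config, geometry):
    return electrical_params(config, geometry)


class TestMgBlock:
    def test_no_magnesium_means_no_block(self):
        for v in (-90.0, -40.0, 0.0, 40.0):
            assert mg_block_factor(v, 0.0) == pytest.approx(1.0)

    def test_monotone_in_voltage_and_asymptote(self):
        v = np.linspace(-120, 120, 200)
        b = mg_block_factor(v, 1.0)
        assert np.all(np.diff(b) > 0)
        assert mg_block_factor(1e4, 1.0) == pytest.approx(1.0)

    def test_sigmoid_value_at_rest(self):
        # 1 / (1 + [Mg]/3.57 * exp(-0.062 V)) at V = -70, [Mg] = 1
        expected = 1.0 / (1.0 + math.exp(0.062 * 70.0) / 3.57)
        assert mg_block_factor(-70.0, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_negative_magnesium_rejected(self):
        with pytest.raises(ValueError):
            mg_block_factor(-70.0, -1.0)


class TestSimulatePotential:
    def test_no_stimulus_stays_at_rest(self, eparams):
        times = np.linspace(0, 100, 2001)
        proto = StimulusProtocol(name="quiet", duration=100.0)
        v = simulate_potential(times, {}, eparams, proto)
        assert np.allclose(v.v_spine, eparams.v_rest, atol=1e-6)
        assert np.allclose(v.v_shaft, eparams.v_rest, atol=1e-6)

    def test_epsp_peak_monotone_in_synaptic_conductance(
            self, eparams, single_pulse_result):
        base = single_pulse_result
        times = base.voltage.times
        g = 85 * eparams.g_ampar * base.trajectories["sampar"].open_fraction
        peaks = []
        for scale in (0.5, 1.0, 2.0):
            v = simulate_potential(times, {"g_syn_ampar": scale * g}, eparams,
                                   base.protocol)
            peaks.append(v.epsp_spine)
        assert peaks[0] < peaks[1] < peaks[2]

    def test_resting_potential_restored_after_stimulus(self, single_pulse_result):
        v = single_pulse_result.voltage
        assert v.v_spine[-1] == pytest.approx(v.v_rest, abs=0.05)


class TestVdcc:
    def test_near_zero_activation_at_rest(self, eparams):
        assert vdcc_gate_inf(eparams.v_rest, eparams) < 1e-4

    def test_gate_relaxes_exponentially_at_clamped_voltage(self, eparams):
        """At a voltage step the gate must follow 1-exp(-t/tau) towards its
        steady-state value."""
        v_cmd = 0.0
        times = np.linspace(0, 10, 2001)
        gate = vdcc_open_fraction(times, np.full_like(times, v_cmd), eparams,
                                  v_init=eparams.v_rest)
        m_inf = vdcc_gate_inf(v_cmd, eparams)
        m0 = vdcc_gate_inf(eparams.v_rest, eparams)
        expected = (m_inf + (m0 - m_inf) * np.exp(-times / eparams.vdcc_tau)) \
            ** eparams.vdcc_power
        assert np.allclose(gate, expected, atol=1e-6)

    def test_sustained_depolarisation_approaches_steady_state(self, eparams):
        times = np.linspace(0, 50, 501)
        gate = vdcc_open_fraction(times, np.full_like(times, 20.0), eparams)
        assert gate[-1] == pytest.approx(
            vdcc_gate_inf(20.0, eparams) ** eparams.vdcc_power, abs=1e-6)


class TestBap:
    def test_zero_amplitude_waveform_gives_no_response(self, config, geometry):
        from dataclasses import replace
        p = replace(electrical_params(config, geometry), bap_amplitude=0.0)
        times = np.linspace(0, 100, 2001)
        v = simulate_potential(times, {}, p, bap_protocol(total_ms=100.0))
        assert np.allclose(v.v_spine, p.v_rest, atol=1e-6)
        assert np.allclose(v.gate_spine, v.gate_spine[0], atol=1e-8)

    def test_waveform_peaks_at_configured_amplitude(self, eparams):
        shape = bap_waveform(eparams)
        ts = np.linspace(0, 20, 20001)
        peak = max(shape(t) for t in ts)
        assert peak == pytest.approx(eparams.bap_amplitude, rel=1e-4)

    def test_bap_opens_vdcc_gates_in_both_compartments(self, eparams):
        times = np.linspace(0, 100, 4001)
        v = simulate_potential(times, {}, eparams, bap_protocol(total_ms=100.0))
        rest_gate = vdcc_gate_inf(eparams.v_rest, eparams) ** eparams.vdcc_power
        assert v.gate_spine.max() > 10 * rest_gate
        assert v.gate_shaft.max() > 10 * rest_gate

    def test_spine_peak_attenuated_relative_to_shaft_command(self, eparams):
        """Through a passive neck the spine follows the shaft with loss: its
        peak cannot exceed the commanded shaft peak (two-node RC circuit)."""
        times = np.linspace(0, 100, 4001)
        v = simulate_potential(times, {}, eparams, bap_protocol(total_ms=100.0))
        assert v.peak_spine <= v.peak_shaft + 1e-6
        assert v.epsp_spine > 0.5 * eparams.bap_amplitude  # but not decoupled
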