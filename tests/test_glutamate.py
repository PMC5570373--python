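import math

import numpy as np
import pytest

from spinesim.config import load_config
from spinesim.geometry import derive_geometry
from spinesim.glutamate import (MOLECULES_PER_UM3_PER_UM, astrocytic_pulse_trace,
                                glutamate_params, impulse_response, trace_at_zone)


def params_with(**over):
    over = {f"glutamate.{k}": v for k, v in over.items()}
    cfg = load_config(overrides=over)
    return glutamate_params(cfg), derive_geometry(cfg)


class TestImpulseResponse:
    def test_causality_far_from_source_at_early_time(self, glu_params, geometry):
        c = impulse_response(1500, 2.0, 1e-6, glu_params, geometry, "extrasynaptic")
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_mass_conserved_in_cleft_without_escape(self, geometry):
        p, g = params_with(cleft_escape_tau_ms=0, b_total_mM=0.0)
        for t in (0.01, 0.1, 1.0):
            r = np.linspace(0, 30.0, 60001)
            c = np.array([impulse_response(1500, ri, t, p, g, "synaptic")
                          for ri in r])
            total = np.trapezoid(c * MOLECULES_PER_UM3_PER_UM
                                 * 2 * math.pi * r, r) * g.cleft_height
            assert total == pytest.approx(1500, rel=1e-3)

    def test_mass_conserved_in_porous_medium_without_uptake(self, geometry):
        p, g = params_with(b_total_mM=0.0)
        for t in (0.05, 0.5):
            r = np.linspace(0, 30.0, 60001)
            c = np.array([impulse_response(1500, ri, t, p, g, "extrasynaptic")
                          for ri in r])
            # hemispheric volume element, scaled by the porosity fraction
            total = np.trapezoid(c * MOLECULES_PER_UM3_PER_UM
                                 * p.porosity_alpha * 2 * math.pi * r**2, r)
            assert total == pytest.approx(1500, rel=1e-3)

    def test_uptake_removes_mass_exponentially(self, glu_params, geometry):
        p0, g = params_with(b_total_mM=0.0)
        p1 = glu_params
        t = 0.5
        ratio = impulse_response(1500, 0.3, t, p1, g, "extrasynaptic") / \
            impulse_response(1500, 0.3, t, p0, g, "extrasynaptic")
        assert ratio == pytest.approx(math.exp(-p1.k_up * t), rel=1e-9)

    def test_tortuosity_one_reduces_to_free_hemispheric_diffusion(self, geometry):
        p, g = params_with(b_total_mM=0.0, tortuosity_lambda=1.0,
                           porosity_alpha=1.0)
        r, t = 0.4, 0.3
        expected = 2 * 1500 / (4 * math.pi * p.d_glu * (t + 1e-3)) ** 1.5 \
            * math.exp(-r * r / (4 * p.d_glu * (t + 1e-3))) / MOLECULES_PER_UM3_PER_UM
        got = impulse_response(1500, r, t, p, g, "extrasynaptic")
        assert got == pytest.approx(expected, rel=1e-12)

    def test_negative_time_or_distance_rejected(self, glu_params, geometry):
        with pytest.raises(ValueError):
            impulse_response(1500, -0.1, 1.0, glu_params, geometry)
        with pytest.raises(ValueError):
            impulse_response(1500, 0.1, -1.0, glu_params, geometry)


class TestTraceAtZone:
    def test_no_pulses_gives_resting_trace(self, glu_params, geometry):
        for zone, rest in (("synaptic", 0.0), ("perisynaptic", 0.25),
                           ("extrasynaptic", 0.25)):
            tr = trace_at_zone([], zone, glu_params, geometry, 50.0)
            assert np.allclose(tr.concentration, rest)

    def test_peak_is_linear_in_molecules_released(self, glu_params, geometry):
        for zone in ("synaptic", "perisynaptic", "extrasynaptic"):
            peaks = [trace_at_zone([0.0], zone, glu_params, geometry, 20.0,
                                   release=n).peak for n in (500, 1000, 2000)]
            evoked = [pk - trace_at_zone([], zone, glu_params, geometry,
                                         20.0).peak for pk in peaks]
            assert evoked[1] == pytest.approx(2 * evoked[0], rel=1e-6)
            assert evoked[2] == pytest.approx(4 * evoked[0], rel=1e-6)

    def test_transporter_block_spares_synapse_but_raises_spillover(self, geometry):
        peaks = {}
        for bt in (0.5, 0.0):
            p, g = params_with(b_total_mM=bt)
            peaks[bt] = {z: trace_at_zone([0.0], z, p, g, 20.0).peak
                         for z in ("synaptic", "perisynaptic", "extrasynaptic")}
        assert peaks[0.0]["synaptic"] == pytest.approx(peaks[0.5]["synaptic"],
                                                       rel=1e-9)
        assert peaks[0.0]["perisynaptic"] > peaks[0.5]["perisynaptic"]
        assert peaks[0.0]["extrasynaptic"] > peaks[0.5]["extrasynaptic"]

    def test_transporter_block_slows_spillover_decay(self, geometry):
        p1, g = params_with(b_total_mM=0.5)
        p0, _ = params_with(b_total_mM=0.0)
        t_late = 5.0
        c1 = trace_at_zone([0.0], "perisynaptic", p1, g, 20.0)(np.array([t_late]))
        c0 = trace_at_zone([0.0], "perisynaptic", p0, g, 20.0)(np.array([t_late]))
        assert c0[0] > c1[0]

    def test_unsorted_pulses_rejected(self, glu_params, geometry):
        with pytest.raises(ValueError):
            trace_at_zone([5.0, 1.0], "synaptic", glu_params, geometry, 20.0)

    def test_unknown_zone_rejected(self, glu_params, geometry):
        with pytest.raises(ValueError):
            trace_at_zone([0.0], "axonal", glu_params, geometry, 20.0)

    def test_scalar_evaluator_matches_vector_form(self, glu_params, geometry):
        tr = trace_at_zone([0.0, 10.0], "perisynaptic", glu_params, geometry, 40.0)
        ts = np.array([0.5, 3.0, 11.0, 35.0])
        vec = tr(ts)
        assert np.allclose([tr.scalar(t) for t in ts], vec, rtol=1e-12)

    def test_peak_agrees_with_radial_pde_oracle(self, glu_params, geometry):
        """Finite-difference solution of the porous-medium diffusion-uptake
        PDE over the same geometry reproduces the closed-form perisynaptic
        peak to better than 5%."""
        p = glu_params
        d, k = p.d_star, p.k_up
        r_obs = p.perisynaptic_radius
        dr = 0.004
        r = np.arange(dr, 3.0, dr)
        # half-space point source: initial narrow Gaussian of the closed form
        t0 = 5e-4
        c = 2 * 1500 / (p.porosity_alpha * (4 * math.pi * d * t0) ** 1.5) \
            * np.exp(-r * r / (4 * d * t0))
        dt = 0.2 * dr * dr / d
        steps = int(0.3 / dt)
        i_obs = int(round(r_obs / dr)) - 1
        peak_fd = 0.0
        for _ in range(steps):
            lap = np.empty_like(c)
            lap[1:-1] = (c[2:] - 2 * c[1:-1] + c[:-2]) / dr**2 \
                + (c[2:] - c[:-2]) / (r[1:-1] * dr)
            lap[0] = (c[1] - c[0]) * 2 / dr**2 + (c[1] - c[0]) / (r[0] * dr)
            lap[-1] = 0.0
            c = c + dt * (d * lap - k * c)
            peak_fd = max(peak_fd, c[i_obs])
        peak_fd /= MOLECULES_PER_UM3_PER_UM
        evoked = trace_at_zone([0.0], "perisynaptic", p, geometry, 20.0).peak \
            - p.glu_rest
        assert evoked == pytest.approx(peak_fd, rel=0.05)


class TestAstrocyticPulse:
    def test_square_pulse_applies_only_extrasynaptically(self, glu_params, geometry):
        tr = astrocytic_pulse_trace(20.0, 1000.0, glu_params, geometry, 100.0,
                                    onset_ms=10.0)
        assert tr.scalar(15.0) == pytest.approx(1000.25)
        assert tr.scalar(5.0) == pytest.approx(0.25)
        assert tr.scalar(40.0) == pytest.approx(0.25)
        syn = astrocytic_pulse_trace(20.0, 1000.0, glu_params, geometry, 100.0,
                                     onset_ms=10.0, zone="synaptic")
        assert np.allclose(syn.concentration, 0.0)

    def test_invalid_pulse_rejected(self, glu_params, geometry):
        with pytest.raises(ValueError):
            astrocytic_pulse_trace(0.0, 1000.0, glu_params, geometry, 100.0)
        with pytest.raises(ValueError):
            astrocytic_pulse_trace(5.0, -1.0, glu_params, geometry, 100.0)
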