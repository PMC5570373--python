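import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinesim.config import ConfigError, load_config
from spinesim.receptors import (build_scheme, integrate, integrate_schemes,
                                metrics_vs_control, q10_adjust, steady_state)


class TestQ10Adjust:
    def test_identity_at_reference_temperature(self):
        assert q10_adjust(7.3, 3.0, 25.0, 25.0) == 7.3

    @pytest.mark.parametrize("q10, dT, factor", [
        (3.0, 10.0, 3.0),
        (1.6, 20.0, 2.56),
        (2.0, -10.0, 0.5),
    ])
    def test_scaling_examples(self, q10, dT, factor):
        assert q10_adjust(1.0, q10, 20.0 + dT, 20.0) == pytest.approx(factor)

    def test_non_positive_q10_rejected(self):
        with pytest.raises(ValueError):
            q10_adjust(1.0, 0.0, 30.0, 20.0)

    @given(st.floats(0.5, 5.0), st.floats(10.0, 40.0), st.floats(10.0, 40.0),
           st.floats(10.0, 40.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_composition_over_temperature_steps(self, q10, t0, t1, t2):
        direct = q10_adjust(1.0, q10, t2, t0)
        stepped = q10_adjust(q10_adjust(1.0, q10, t1, t0), q10, t2, t1)
        assert direct == pytest.approx(stepped, rel=1e-9)


class TestSchemes:
    def test_nmdar_schemes_have_eight_states_ampar_seven(self, config):
        assert build_scheme("nr2a", config).n_states == 8
        assert build_scheme("nr2b", config).n_states == 8
        assert build_scheme("ampar", config).n_states == 7

    @pytest.mark.parametrize("subtype", ["nr2a", "nr2b", "ampar"])
    def test_generator_columns_sum_to_zero(self, config, subtype):
        s = build_scheme(subtype, config)
        for glu in (0.0, 1.0, 1000.0):
            scale = max(np.abs(s.generator(glu)).max(), 1.0)
            assert np.allclose(s.generator(glu).sum(axis=0), 0.0,
                               atol=1e-13 * scale)

    def test_unknown_subtype_raises_named_error(self, config):
        with pytest.raises(ConfigError, match="kainate"):
            build_scheme("kainate", config)

    def test_missing_rate_raises_configuration_error(self, config):
        cfg = config.copy()
        cfg["receptors.schemes.nr2a.transitions"][0] = {"from": "U", "to": "C1"}
        with pytest.raises(ConfigError, match="rate"):
            build_scheme("nr2a", cfg)

    def test_desensitisation_inhibition_scales_entry_rates(self, config):
        full = build_scheme("nr2a", config)
        inh = build_scheme("nr2a", config, desens_inhibition=0.5)
        i_d1 = full.index("D1")
        i_c2 = full.index("C2")
        assert inh.a0[i_d1, i_c2] == pytest.approx(0.5 * full.a0[i_d1, i_c2])
        # recovery from desensitisation is untouched
        assert inh.a0[i_c2, i_d1] == pytest.approx(full.a0[i_c2, i_d1])


class TestSteadyState:
    def test_zero_glutamate_leaves_all_receptors_unbound(self, config):
        for subtype in ("nr2a", "nr2b", "ampar"):
            s = build_scheme(subtype, config)
            p = steady_state(s, 0.0)
            assert p[s.index(s.unbound_state)] == pytest.approx(1.0, abs=1e-12)

    def test_negative_glutamate_rejected(self, config):
        with pytest.raises(ValueError):
            steady_state(build_scheme("nr2a", config), -1.0)

    @pytest.mark.parametrize("subtype", ["nr2a", "nr2b"])
    def test_null_space_matches_long_time_integration(self, config, subtype):
        """The algebraic stationary state agrees with integrating the ODEs
        for ten seconds at clamped glutamate."""
        s = build_scheme(subtype, config)
        glu = 5.0
        target = steady_state(s, glu)
        tr = integrate(s, lambda t: np.full(np.shape(t), glu), 10_000.0,
                       dt_out=50.0, initial_glu=0.0)
        assert np.allclose(tr.occupancy[-1], target, atol=1e-6)

    def test_open_and_desensitised_fractions_monotone_in_glutamate(self, config):
        for subtype in ("nr2a", "nr2b"):
            s = build_scheme(subtype, config)
            glus = np.geomspace(0.01, 100.0, 20)
            opens = [steady_state(s, g)[s.open_index].sum() for g in glus]
            des = [steady_state(s, g)[s.desensitised_index].sum() for g in glus]
            assert np.all(np.diff(opens) > -1e-12)
            assert np.all(np.diff(des) > -1e-12)


class TestIntegration:
    def test_occupancy_simplex_preserved_through_pulse_train(
            self, control_hfs_result):
        for cls in ("snr2a", "snr2b", "sampar"):
            occ = control_hfs_result.trajectories[cls].occupancy
            assert np.all(occ >= -1e-8)
            assert np.all(occ <= 1 + 1e-8)
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-8)

    def test_constant_glutamate_converges_to_steady_state(self, config):
        s = build_scheme("nr2b", config)
        glu = 2.0
        tr = integrate(s, lambda t: np.full(np.shape(t), glu), 20_000.0,
                       dt_out=100.0, initial_glu=0.0)
        assert np.allclose(tr.occupancy[-1], steady_state(s, glu), atol=1e-6)

    def test_saturating_step_desensitises_both_nmdar_subtypes_to_081(self, config):
        for subtype in ("nr2a", "nr2b"):
            s = build_scheme(subtype, config)
            tr = integrate(s, lambda t: np.full(np.shape(t), 100.0), 30_000.0,
                           dt_out=100.0, initial_glu=0.0)
            assert tr.desensitised_fraction[-1] == pytest.approx(0.81, abs=0.01)

    def test_stacked_integration_matches_individual(self, config, glu_params,
                                                    geometry):
        from spinesim.glutamate import trace_at_zone
        tr = trace_at_zone([0.0, 10.0], "synaptic", glu_params, geometry, 30.0)
        schemes = [build_scheme(s, config) for s in ("nr2a", "ampar")]
        stacked = integrate_schemes(schemes, tr, 30.0, breakpoints=[0.0, 10.0],
                                    initial_glu=0.0)
        for s, st_tr in zip(schemes, stacked):
            solo = integrate(s, tr, 30.0, breakpoints=[0.0, 10.0], initial_glu=0.0)
            assert np.allclose(st_tr.occupancy, solo.occupancy, atol=1e-7)


class TestMetrics:
    def test_control_against_itself_is_zero(self, single_pulse_result):
        tr = single_pulse_result.trajectories["snr2a"]
        m = metrics_vs_control(tr, tr)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in m.t_add.values())
        assert m.ca_add == 0.0

    def test_open_time_integral_matches_refined_trapezoid(self, config):
        s = build_scheme("nr2a", config)
        glu = lambda t: np.full(np.shape(t), 3.0)
        coarse = integrate(s, glu, 500.0, dt_out=0.5, initial_glu=0.0)
        fine = integrate(s, glu, 500.0, dt_out=0.25, initial_glu=0.0)
        i_coarse = np.trapezoid(coarse.open_fraction, coarse.times)
        i_fine = np.trapezoid(fine.open_fraction, fine.times)
        assert i_coarse == pytest.approx(i_fine, rel=1e-3)

    def test_mismatched_grids_rejected(self, config):
        s = build_scheme("nr2a", config)
        glu = lambda t: np.full(np.shape(t), 1.0)
        a = integrate(s, glu, 10.0, dt_out=0.5, initial_glu=0.0)
        b = integrate(s, glu, 10.0, dt_out=0.25, initial_glu=0.0)
        with pytest.raises(ValueError):
            metrics_vs_control(a, b)
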