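# Default parameter configuration for the spine simulator.
#
# Units are carried in key names.  Kinetic rate constants are given at the
# reference temperature of their section and are rescaled to `temperature_c`
# at load time using the Q10 class table below.  Quantities given with
# reference_temperature_c == temperature_c are left untouched.

temperature_c: 34.0

q10:
  diffusion: 1.3
  nmdar_kinetics: 3.0
  nmdar_conductance: 1.6
  ampar_kinetics: 2.4
  ampar_conductance: 1.5
  vdcc_kinetics: 3.0
  vdcc_conductance: 1.5
  pump_kinetics: 3.0
  buffer_kinetics: 2.15
  transporter_kinetics: 3.0

geometry:
  head_volume_um3: 0.1
  cleft_height_nm: 20.0
  psd_outer_radius_nm: 150.0
  perisynaptic_outer_radius_nm: 365.0
  psd_volume_fraction: 0.1
  neck_length_um: 0.5
  neck_radius_um: 0.1
  shaft_radius_um: 0.5
  shaft_length_um: 1.0
  force: false

glutamate:
  reference_temperature_c: 25.0
  d_glu_um2_per_ms: 0.33           # free diffusion coefficient at 25 C
  tortuosity_lambda: 1.4           # extrasynaptic hindrance, D* = D / lambda^2
  porosity_alpha: 0.38             # extracellular volume fraction outside cleft
  b_total_mM: 0.5                  # astrocytic transporter concentration
  k_on_transporter_per_mM_ms: 2.2  # pseudo-first-order uptake = k_on * B_total
  reference_temperature_transporter_c: 34.0
  glu_rest_uM: 0.25                # resting extrasynaptic glutamate
  molecules_per_vesicle: 1500
  release_spread_ms: 0.1           # finite emptying time of a vesicle
  cleft_escape_tau_ms: 0.5         # clearance of the cleft through the rim
  synaptic_radius_um: 0.075        # mid-PSD sampling point
  perisynaptic_radius_um: 0.257    # annulus midpoint
  extrasynaptic_distance_um: 0.48  # diffusion path to shaft receptors

receptors:
  counts:
    snr2a: 12
    snr2b: 8
    pnr2b: 3
    enr2b: 8
    sampar: 85
  eampar_density_per_um2: 20.0
  schemes:
    nr2a:
      reference_temperature_c: 23.0
      q10_class: nmdar_kinetics
      states: [U, C1, C2, D1, D2, P1, P2, O]
      unbound_state: U
      open_states: [O]
      desensitised_states: [D1, D2]
      conductance_pS: 45.0
      conductance_reference_temperature_c: 34.0
      ca_permeability_um3_per_ms: 2.5716e-5
      transitions:
        - {from: U,  to: C1, rate: 12.0,   glu_order: 1}   # uM^-1 s^-1, 2x per-site
        - {from: C1, to: U,  rate: 3.75}
        - {from: C1, to: C2, rate: 6.0,    glu_order: 1}
        - {from: C2, to: C1, rate: 7.5}
        - {from: C2, to: D1, rate: 2.4,    desensitising: true}   # kd1+
        - {from: D1, to: C2, rate: 0.270030}
        - {from: C2, to: D2, rate: 13.5,   desensitising: true}   # kd2+
        - {from: D2, to: C2, rate: 8.606770}
        - {from: C2, to: P1, rate: 45.0}
        - {from: P1, to: C2, rate: 150.0}
        - {from: P1, to: P2, rate: 120.0}
        - {from: P2, to: P1, rate: 300.0}
        - {from: P2, to: O,  rate: 900.0}
        - {from: O,  to: P2, rate: 104.577}
    nr2b:
      reference_temperature_c: 23.0
      q10_class: nmdar_kinetics
      states: [U, C1, C2, D1, D2, P1, P2, O]
      unbound_state: U
      open_states: [O]
      desensitised_states: [D1, D2]
      conductance_pS: 45.0
      conductance_reference_temperature_c: 34.0
      ca_permeability_um3_per_ms: 2.8463e-5
      transitions:
        - {from: U,  to: C1, rate: 12.0,   glu_order: 1}
        - {from: C1, to: U,  rate: 3.0}
        - {from: C1, to: C2, rate: 6.0,    glu_order: 1}
        - {from: C2, to: C1, rate: 6.0}
        - {from: C2, to: D1, rate: 1.8,    desensitising: true}
        - {from: D1, to: C2, rate: 0.334200}
        - {from: C2, to: D2, rate: 10.5,   desensitising: true}
        - {from: D2, to: C2, rate: 11.040265}
        - {from: C2, to: P1, rate: 36.0}
        - {from: P1, to: C2, rate: 144.0}
        - {from: P1, to: P2, rate: 90.0}
        - {from: P2, to: P1, rate: 281.25}
        - {from: P2, to: O,  rate: 360.0}
        - {from: O,  to: P2, rate: 184.0602}
    ampar:
      reference_temperature_c: 23.0
      q10_class: ampar_kinetics
      states: [C0, C1, C2, O, D1, D2, D3]
      unbound_state: C0
      open_states: [O]
      desensitised_states: [D1, D2, D3]
      conductance_pS: 30.0
      conductance_reference_temperature_c: 34.0
      ca_permeability_um3_per_ms: 0.0
      transitions:
        - {from: C0, to: C1, rate: 20.0,   glu_order: 1}
        - {from: C1, to: C0, rate: 800.0}
        - {from: C1, to: C2, rate: 10.0,   glu_order: 1}
        - {from: C2, to: C1, rate: 1600.0}
        - {from: C2, to: O,  rate: 3000.0}
        - {from: O,  to: C2, rate: 1500.0}
        - {from: C1, to: D1, rate: 20.0,   desensitising: true}
        - {from: D1, to: C1, rate: 4.0}
        - {from: C2, to: D2, rate: 60.0,   desensitising: true}
        - {from: D2, to: C2, rate: 6.0}
        - {from: O,  to: D3, rate: 80.0,   desensitising: true}
        - {from: D3, to: O,  rate: 8.0}

electrics:
  resting_potential_mV: -70.0
  reversal_ampar_mV: 0.0
  reversal_nmdar_mV: 0.0
  membrane_capacitance_pF_per_um2: 0.01
  leak_conductance_nS_per_um2: 0.005
  neck_resistance_Mohm: 157.0
  dendritic_load_resistance_Mohm: 250.0
  dendritic_load_capacitance_pF: 60.0
  mg_mM: 1.0
  mg_ic50_0mV_mM: 3.57             # Jahr-Stevens sigmoid parameters
  mg_slope_per_mV: 0.062
  vdcc:
    density_spine_per_um2: 30.0
    density_shaft_per_um2: 30.0
    ca_permeability_um3_per_ms: 3.0e-5
    vhalf_mV: 10.0
    slope_mV: 6.0
    tau_ms: 1.0
    gate_power: 2
  bap:
    amplitude_mV: 90.0
    rise_ms: 0.4
    decay_ms: 2.0
  pairing_voltage_mV: 0.0

calcium:
  ca_rest_uM: 0.05
  ca_out_mM: 2.0
  nmdar_ca_fraction: 0.1           # informational; permeabilities are per scheme
  d_ca_um2_per_ms: 0.03
  diffusion_distances_um:          # centre-to-centre distances between compartments
    psd_cytosol: 0.05
    cytosol_neck: 0.35
    neck_shaft: 0.55
  pmca:
    density_spine_per_um2: 555.0
    density_shaft_per_um2: 100.0
    turnover_per_s: 50.0
    km_uM: 0.8
    reference_temperature_c: 34.0
  ncx:
    density_spine_per_um2: 10.0
    density_shaft_per_um2: 20.0
    turnover_per_s: 600.0
    km_uM: 100.0
    reference_temperature_c: 34.0
  buffer:
    total_spine_uM: 10.0
    total_shaft_uM: 13.0
    k_on_per_uM_ms: 0.1
    k_off_per_ms: 0.2
    reference_temperature_c: 34.0

camkii:
  cam_total_uM: 30.0
  camkii_total_uM: 80.0
  k_lobe1_on_per_uM2_ms: 1.0e-4    # lumped two-Ca C-lobe loading
  k_lobe1_off_per_ms: 4.0
  k_lobe2_on_per_uM2_ms: 1.0e-4    # lumped two-Ca N-lobe loading
  k_lobe2_off_per_ms: 4.0
  k_cam_bind_per_uM_ms: 4.0e-4
  k_cam_unbind_per_ms: 0.002
  k_auto_per_ms: 0.05              # neighbour-catalysed, x active fraction^2
  v_phosphatase_uM_per_ms: 0.018
  km_phosphatase_uM: 0.3
  k_translocate_per_ms: 0.002
  k_return_per_ms: 2.0e-4
  k_slot_bind_per_uM_ms: 2.0e-6
  k_slot_unbind_per_ms: 1.0e-6
  slots_per_nr2b: 3.0
  psd_nr2b_count: 8

protocol:
  lfs_hz: 10.0
  hfs_hz: 100.0
  train_duration_ms: 1000.0
  tbs_pulses_per_burst: 4
  tbs_intra_burst_hz: 100.0
  tbs_bursts_per_train: 10
  tbs_burst_hz: 5.0
  tbs_inter_train_ms: 2000.0
  post_train_ms: 500.0
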