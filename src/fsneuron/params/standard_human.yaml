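# Standard ("human-calibrated") fast-spiking interneuron model.
#
# Geometry, passive constants and channel placement follow the published
# three-section layout: point soma (700 MOhm, 25 pF), 140 x 0.8 um axon
# (Cm 6 fF/um^2, Ra 0.9 MOhm/um) carrying a 20-um AIS starting 10 um from
# the soma, and a 200 x 1 um dendrite (Cm 12 fF/um^2).  Leak reversal
# -68 mV.  AIS Nav1.6 and Kv1 densities are the two sweep axes
# (20 nS/um^2 each under standard conditions).
#
# Gating-kinetics constants (midpoints, slopes, tau bounds, exponents) are
# not published for this model; the values below are effective first-order
# parameters in the shared tanh formalism, seeded from standard
# fast-spiking basket-cell models and calibrated against the reported
# baseline threshold, input resistance, apparent membrane time constant
# and the direction/magnitude of the AIS sweeps.  Every value can be
# overridden from a user config.
#
# Units (repo-wide): mV, ms, nS, pA, pF, um, fF/um^2, MOhm.

geometry:
  soma:
    cm_total_pF: 25.0
    leak_resistance_MOhm: 700.0
  axon:
    length_um: 140.0
    diameter_um: 0.8
    segment_length_um: 2.0
    cm_fF_per_um2: 6.0
    ra_MOhm_per_um: 0.9
  dendrite:
    length_um: 200.0
    diameter_um: 1.0
    segment_length_um: 2.0
    cm_fF_per_um2: 12.0
    # axial resistance scaled from the axon by cross-sectional area
    ra_MOhm_per_um: 0.576
    proximal_fraction: 0.2
  e_leak_mV: -68.0

ais:
  start_um: 10.0
  length_um: 20.0
  gnav16_nS_per_um2: 20.0
  gkv1_nS_per_um2: 20.0

channels:
  nav16:                      # low-threshold Na+, AIS only
    p: 1
    e_mV: 55.0
    regions: {ais: from_ais_nav16}
    activation:
      {v_half_mV: -7.451, v_slope_mV: 12.664,
       tau_max_ms: 0.12, tau_min_ms: 0.04, v_tau_half_mV: -30.0, v_tau_slope_mV: 30.0}
    inactivation:
      {v_half_mV: -39.926, v_slope_mV: -6.427,
       tau_max_ms: 2.50, tau_min_ms: 0.30, v_tau_half_mV: -48.0, v_tau_slope_mV: 16.0}
  nav12:                      # high-threshold Na+, soma + proximal dendrite
    p: 1
    e_mV: 55.0
    regions: {soma: 300.0, dendrite_proximal: 2.0}
    activation:
      {v_half_mV: 11.408, v_slope_mV: 14.0,
       tau_max_ms: 0.15, tau_min_ms: 0.04, v_tau_half_mV: -25.0, v_tau_slope_mV: 30.0}
    inactivation:
      {v_half_mV: -30.0, v_slope_mV: -8.0,
       tau_max_ms: 2.00, tau_min_ms: 0.30, v_tau_half_mV: -40.0, v_tau_slope_mV: 18.0}
  kv1:                        # low-voltage-activated K+, AIS only
    p: 1
    e_mV: -90.0
    regions: {ais: from_ais_kv1}
    activation:
      {v_half_mV: 15.165, v_slope_mV: 21.188,
       tau_max_ms: 7.235, tau_min_ms: 0.8, v_tau_half_mV: -50.0, v_tau_slope_mV: 25.0}
  kv3:                        # fast delayed rectifier, AIS + soma + dendrite
    p: 2
    e_mV: -90.0
    regions: {ais: 3.0, soma: 350.0, dendrite: 0.5}
    activation:
      {v_half_mV: -10.0, v_slope_mV: 12.0,
       tau_max_ms: 1.2, tau_min_ms: 0.15, v_tau_half_mV: -20.0, v_tau_slope_mV: 25.0}
  km:                         # slow non-inactivating M-type K+
    p: 1
    e_mV: -90.0
    regions: {soma: 2.018, dendrite: 0.00135}
    activation:
      {v_half_mV: -51.338, v_slope_mV: 14.275,
       tau_max_ms: 50.0, tau_min_ms: 15.0, v_tau_half_mV: -45.0, v_tau_slope_mV: 25.0}
  kir:                        # inward rectifier (opens with hyperpolarization)
    p: 1
    e_mV: -90.0
    regions: {soma: 2.0, dendrite: 0.002}
    activation:
      {v_half_mV: -80.0, v_slope_mV: -10.0,
       tau_max_ms: 8.0, tau_min_ms: 1.0, v_tau_half_mV: -80.0, v_tau_slope_mV: 20.0}
  ih:                         # hyperpolarization-activated cation current
    p: 1
    e_mV: -30.0
    regions: {soma: 2.663, dendrite: 0.00266}
    activation:
      {v_half_mV: -85.0, v_slope_mV: -9.0,
       tau_max_ms: 60.0, tau_min_ms: 20.0, v_tau_half_mV: -85.0, v_tau_slope_mV: 20.0}
  leak_dend:                  # distributed dendritic leak
    p: 0
    e_mV: -68.0
    regions: {dendrite: 0.005182}

simulation:
  dt_ms: 0.01
  v_hold_mV: -70.0
  settle_ms: 200.0
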