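# ssanet default parameter sets.
#
# Units throughout: ms, mV, nS, pA, pF, Hz, octaves.
#
# Provenance notes
# ----------------
# adex.default          : regular-spiking adaptive exponential I&F set
#                         (Brette & Gerstner 2005, table 1 values).
# noise.*               : point-conductance background model (Destexhe et al.
#                         2001 fluctuating-conductance parameters). Two presets:
#                         "high_spontaneous" has sigma_e tuned with
#                         ssanet.neurons.calibrate_noise_sigma to give ~5 Hz
#                         spontaneous firing of an isolated AdEx unit (AB/ABC
#                         regime); "low_spontaneous" keeps the original
#                         sigma_e = 3 nS (membrane fluctuations, few spikes;
#                         ABD regime).
# synapses.*            : kinetic AMPA/GABA_A rise/decay constants with a 1 ms
#                         square transmitter pulse; depressing classes add the
#                         slow inactive->recovered recovery constant (800 ms,
#                         cortical paired-pulse recovery scale). Pathway
#                         weights are the output of the shipped calibration
#                         sweep (ssanet.experiments.run_calibration): selected
#                         where median SSA index in the scaled oddball task is
#                         positive and stable under +/-20% weight changes, and
#                         (ABC) >=90% of tone responses carry 0 or 1 spike.
# jitter                : log-normal multiplicative heterogeneity applied to
#                         every synapse parameter at build time (sigma of log
#                         0.1, ~10% CV).
# tuning.*              : raised-Gaussian frequency tuning of the Poisson input
#                         sub-populations; bandwidth is the octave separation
#                         of the two half-rise frequencies.

adex:
  default:
    capacitance_pF: 281.0
    g_leak_nS: 30.0
    e_leak_mV: -70.6
    delta_T_mV: 2.0
    v_threshold_mV: -50.4
    tau_w_ms: 144.0
    a_nS: 4.0
    b_pA: 80.5
    v_reset_mV: -70.6
    v_cutoff_mV: 0.0

noise:
  high_spontaneous:
    g_e0_nS: 12.1
    g_i0_nS: 57.3
    sigma_e_nS: 23.4375
    sigma_i_nS: 6.6
    tau_e_ms: 2.728
    tau_i_ms: 10.49
    e_e_mV: 0.0
    e_i_mV: -75.0
    area_scale: 1.0
  low_spontaneous:
    g_e0_nS: 12.1
    g_i0_nS: 57.3
    sigma_e_nS: 3.0
    sigma_i_nS: 6.6
    tau_e_ms: 2.728
    tau_i_ms: 10.49
    e_e_mV: 0.0
    e_i_mV: -75.0
    area_scale: 1.0

synapses:
  A_B:
    kind: depressing
    tau_rise_ms: 1.0
    tau_decay_ms: 5.26
    pulse_ms: 1.0
    tau_rec_ms: 800.0
    weight_nS: 10.0
    e_rev_mV: 0.0
  A_C:
    kind: excitatory
    tau_rise_ms: 1.0
    tau_decay_ms: 5.26
    pulse_ms: 1.0
    tau_rec_ms: .inf
    weight_nS: 5.0
    e_rev_mV: 0.0
  C_B:
    kind: inhibitory
    tau_rise_ms: 1.0
    tau_decay_ms: 5.6
    pulse_ms: 1.0
    tau_rec_ms: .inf
    weight_nS: 30.0
    e_rev_mV: -75.0
  B_D:
    kind: depressing
    tau_rise_ms: 1.0
    tau_decay_ms: 5.26
    pulse_ms: 1.0
    tau_rec_ms: 800.0
    weight_nS: 12.0
    e_rev_mV: 0.0

jitter:
  sigma_log: 0.1
  params:
    - tau_rise_ms
    - tau_decay_ms
    - pulse_ms
    - tau_rec_ms
    - weight_nS
    - e_rev_mV

tuning:
  two_tone:
    n_subpop: 96
    span_octaves: 2.0
    spont_hz: 0.5
    max_hz: 100.0
    bandwidth_oct: 0.5
  multi_tone:
    n_subpop: 144
    span_octaves: 3.0
    spont_hz: 0.5
    max_hz: 100.0
    bandwidth_oct: 0.5
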