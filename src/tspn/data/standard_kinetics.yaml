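# Standard tSPN model cell: maximal conductances, reversal potentials and
# gating kinetics.  Version 1.
#
# The conductance complement (fast Na, delayed-rectifier K, M-type K,
# Ca-activated K, A-type K, H, persistent L-type Ca, ohmic leak, and an
# optional impalement leak), the maximal conductances and the reversal
# potentials are the standard-cell values.  Gating kinetics are
# parameterized Boltzmann steady states with bell-shaped time constants
# in the style of amphibian/rodent sympathetic-neuron models, calibrated
# at room temperature against the standard cell's reference behaviour:
# rest near -59 mV; input resistance ~0.6 GOhm intact and ~120 MOhm with
# a 7 nS impalement leak; threshold (dV/dt criterion) near -35 mV;
# repetitive firing at all suprathreshold currents when intact, with
# M/KCa-mediated spike-rate adaptation; M-dependent conversion to phasic
# firing under impalement load; A-mediated notch and onset delay from
# hyperpolarized holding; H-mediated sag at deep hyperpolarization;
# M-dependent rebound firing after release from a -50 mV hold.
#
# Kinetics are data, not code: alternative parameterizations can be
# swapped in without touching the integrator.
#
# Units: mV, ms, nS, uM.  Steady state 1/(1+exp((V-v_half)/slope));
# time constant tau_min + tau_amp/(exp((V-tau_v1)/tau_k1)
#                                 + exp(-(V-tau_v2)/tau_k2)).
version: 1
c_m: 100.0
calcium:
  lambda_free: 0.01
  alpha_conv: 0.002
  k_removal: 0.024
channels:
  Na:
    g_max: 300.0
    e_rev: 60.0
    activation:
      v_half: -38.0
      slope: -5.0
      exponent: 3
      tau_min: 0.15
      tau_amp: 30.0
      tau_v1: -47.0
      tau_k1: 3.0
      tau_v2: -47.0
      tau_k2: 4.0
    inactivation:
      v_half: -52.5
      slope: 4.0
      exponent: 1
      tau_min: 2.0
      tau_amp: 120.0
      tau_v1: -60.0
      tau_k1: 15.0
      tau_v2: -60.0
      tau_k2: 20.0
  Kd:
    g_max: 2000.0
    e_rev: -90.0
    activation:
      v_half: -10.0
      slope: -9.0
      exponent: 4
      tau_min: 2.0
      tau_amp: 60.0
      tau_v1: -50.0
      tau_k1: 15.0
      tau_v2: -50.0
      tau_k2: 30.0
  M:
    g_max: 50.0
    e_rev: -90.0
    activation:
      v_half: -27.0
      slope: -5.0
      exponent: 1
      tau_min: 60.0
      tau_amp: 300.0
      tau_v1: -27.0
      tau_k1: 60.0
      tau_v2: -27.0
      tau_k2: 15.0
  KCa:
    g_max: 50.0
    e_rev: -90.0
    calcium_dependent: true
    activation:
      kind: calcium
      ca_half: 0.6
      hill: 3
      exponent: 1
  A:
    g_max: 50.0
    e_rev: -90.0
    activation:
      v_half: -32.0
      slope: -9.0
      exponent: 1
      tau_min: 1.0
      tau_amp: 8.0
      tau_v1: -32.0
      tau_k1: 20.0
      tau_v2: -32.0
      tau_k2: 20.0
    inactivation:
      v_half: -80.0
      slope: 5.0
      exponent: 1
      tau_min: 12.0
      tau_amp: 80.0
      tau_v1: -45.0
      tau_k1: 20.0
      tau_v2: -62.0
      tau_k2: 3.0
  H:
    g_max: 1.0
    e_rev: -32.0
    activation:
      v_half: -88.0
      slope: 7.0
      exponent: 1
      tau_min: 100.0
      tau_amp: 1000.0
      tau_v1: -88.0
      tau_k1: 20.0
      tau_v2: -88.0
      tau_k2: 20.0
  CaL:
    g_max: 1.2
    e_rev: 120.0
    activation:
      v_half: -15.0
      slope: -5.0
      exponent: 1
      tau_min: 1.0
      tau_amp: 3.0
      tau_v1: -15.0
      tau_k1: 15.0
      tau_v2: -15.0
      tau_k2: 15.0
  leak:
    g_max: 1.0
    e_rev: -55.0
  imp:
    g_max: 0.0
    e_rev: -15.0
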