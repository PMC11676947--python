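# Default parameter presets for the thalamic TC-RE model.
#
# Units: mV, ms, nS, pA, pF throughout (pA/nS = mV, pF/nS = ms); rates in Hz.
# The "sleep" entries list only the parameters that change relative to awake;
# everything absent is inherited from the awake column of the same cell type.
# "spindle" is the sleep state with the reset potential moved above the spike
# onset threshold to promote rebound bursting.

cells:
  TC_awake:
    cm: 160.0
    gL: 10.0
    EL: -65.0
    Vt: -50.0
    Delta: 4.5
    a: 0.0
    b: 10.0
    tau_w: 200.0
    Qe: 1.0
    Qi: 6.0
    tau_e: 5.0
    tau_i: 5.0
    Ee: 0.0
    Ei: -80.0
    V_spike: -20.0
    V_reset: -50.0
    t_refrac: 5.0
  RE_awake:
    cm: 200.0
    gL: 10.0
    EL: -75.0
    Vt: -45.0
    Delta: 2.5
    a: 8.0
    b: 10.0
    tau_w: 200.0
    Qe: 4.0
    Qi: 1.0
    tau_e: 5.0
    tau_i: 5.0
    Ee: 0.0
    Ei: -80.0
    V_spike: -20.0
    V_reset: -55.0
    t_refrac: 5.0
  TC_sleep:
    inherits: TC_awake
    EL: -70.0
    gL: 9.5
    tau_w: 270.0
    a: 24.0
    b: 200.0
  RE_sleep:
    inherits: RE_awake
    EL: -85.0
    gL: 13.0
    tau_w: 230.0
    a: 28.0
    b: 20.0
  TC_spindle:
    inherits: TC_sleep
    V_reset: -48.0
  RE_spindle:
    inherits: RE_sleep
    V_reset: -42.0

network:
  N_tc: 500
  N_re: 500
  N_P: 8000
  N_S: 500
  # Connection probabilities per directed projection.  The intra-thalamic
  # values are printed in the text (5% between populations, 30% within RE);
  # the drive probabilities appear only in the network schematic and default
  # to the same 5% sparseness (flagged as assumptions).
  p:
    TC_RE: 0.05
    RE_TC: 0.05
    RE_RE: 0.30
    P_TC: 0.05     # assumption: schematic-only value
    P_RE: 0.05     # assumption: schematic-only value
    S_TC: 0.05     # assumption: schematic-only value
  # Drive synapses use the target cell's excitatory quantal increment (the
  # stronger cortico-RE amplitude is carried by RE's Qe = 4 nS), except the
  # sensory afferents onto TC: these are driver-type synapses, several-fold
  # stronger than the modulatory cortical ones, set to 6 nS so that the awake
  # network amplifies a sensory pulse roughly two-fold (assumption: the
  # schematic's quantal values are not printed in the text).
  Q_drive:
    S_TC: 6.0

classification:
  # AdEx bursts without T-channels decelerate (ISIs grow from ~12 ms to
  # ~100 ms before quiescence), so the intra-burst ceiling must be wide;
  # tonic trains are still rejected because they show no terminal quiescence.
  burst_isi_max: 100.0     # ms, intra-burst inter-spike interval ceiling
  quiescence_min: 100.0    # ms, silence after a cluster that marks a burst

step_protocol:
  # Current-step demonstration of the firing modes.  Amplitudes sit above the
  # fast (instantaneous) rheobase; for the burst states they lie below the
  # slow (adaptation-equilibrated) rheobase so firing cannot be sustained.
  t0: 200.0          # ms
  width: 800.0       # ms
  amplitude:         # pA
    TC_awake: 200.0
    TC_sleep: 600.0
    RE_awake: 500.0
    RE_sleep: 1000.0

transfer_function:
  normalization:
    muV0: -60.0
    dmuV0: 10.0
    sigmaV0: 4.0
    dsigmaV0: 6.0
    tauVN0: 0.5
    dtauVN0: 1.0
  # Reference effective-threshold polynomial amplitudes (mV) for the awake
  # cell types, one fit per cell type shared across awake/sleep states.
  coefficients:
    TC: [-47.31, 1.68, 0.97, -3.46, 0.47, -1.68, -6.46, 3.43, -1.14, 0.19]
    RE: [-40.77, -1.98, -3.12, 3.57, 1.39, -0.38, -0.33, 0.16, 0.26, -0.53]

mean_field:
  T: 5.0          # ms, adiabatic coarse-graining time (= rate bin width)
  dt: 0.5         # ms, forward-Euler step (<= T/10)
  fd_rate_step: 0.05   # Hz, floor of the finite-difference step for dF/dnu
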