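# Methods

`thalmf` models a generic lateral thalamic nucleus at two scales: a spiking
network of adaptive exponential integrate-and-fire (AdEx) neurons, and a
second-order mean-field whose transfer function is fitted semi-analytically
to single-cell simulations. This note records the model, the numerical
choices, and what the defaults do and do not capture.

## Single cells

Each cell follows the conductance-based AdEx dynamics

    cm dv/dt    = gL (EL - v) + gL Δ exp((v - Vt)/Δ) - w + Ge (Ee - v) + Gi (Ei - v) + I_ext
    τw dw/dt    = a (v - EL) - w,     w ← w + b at each spike

with spike detection at V_spike = -20 mV, reset to V_reset, and a 5 ms
refractory period during which v is clamped while w and the conductances
keep evolving. Synaptic conductances jump by Q per presynaptic spike and
decay exponentially (τe = τi = 5 ms). Two cell types (thalamocortical relay,
TC, and reticular, RE) each carry an awake and a sleep parameter set; the
"sleep" sets differ mainly in resting potential and adaptation strength
(TC: b = 200 pA, a = 24 nS). A "spindle" variant moves the reset potential
above the spike-onset threshold (TC -48 mV, RE -42 mV) to promote rebound
bursting. All parameters ship in `thalmf/data/presets.yaml`; unlisted sleep
entries inherit the awake value.

Integration is forward Euler at dt = 0.1 ms, with the spike-initiation
exponential evaluated at min(v, V_spike) to avoid overflow during the
upswing. The rest state is not an exact fixed point — the exponential term
leaves a ~0.2 mV residual depolarization — which is visible in the membrane
statistics.

### Firing-mode classification

Bursts are spike clusters (intra-cluster inter-spike intervals below
`burst_isi_max`) followed by at least `quiescence_min` of silence; tonic
trains lack the terminal quiescence; fewer than two spikes is silent.
Without T-type channels the AdEx bursts *decelerate*: intra-burst intervals
grow from ~12 ms to ~100 ms before quiescence, so `burst_isi_max` defaults
to 100 ms (a 15 ms ceiling would fragment every burst these presets
produce). Step-current amplitudes for the mode demonstration are per preset
(200/600/500/1000 pA for TC-awake/TC-sleep/RE-awake/RE-sleep): a bursting
state needs a current between its fast (instantaneous) rheobase and its
adaptation-equilibrated rheobase, and those windows do not overlap across
presets.

## Network

An Erdős–Rényi graph over 500 TC + 500 RE cells: TC→RE at p = 5 %
(Q = 4 nS, the RE excitatory quantal size), RE→TC at 5 % (Q = 6 nS), RE→RE
at 30 % (Q = 1 nS), no TC→TC connections and no RE self-edges. Two external
Poissonian drives: a cortical drive P (8000 units, 5 % onto both
populations) and a sensory drive S (500 units, 5 % onto TC only). Drive
synapses use the target's excitatory quantal size except the sensory
afferents, which are driver-type synapses of 6 nS — six-fold the modulatory
cortical size, consistent with the driver/modulator distinction of thalamic
afferents — chosen once so that the awake network amplifies a sensory pulse
roughly two-fold, its documented operating characteristic. Drive
probabilities and the sensory quantal size are assumptions (the source
values are not printed); they are flagged in the config.

Drive units emit spikes by per-step thinning of their rate; network spikes
are delivered at the next integration step (no axonal delays). Initial
potentials are jittered ±5 mV around rest to de-synchronize the startup;
the first 500 ms are discarded for stationary statistics. Population rates
are spike counts per bin over N·T_bin with T_bin = 5 ms. Membrane
statistics exclude samples within the refractory window after each spike,
matching what the mean-field describes.

## Transfer function

The semi-analytic transfer function maps input rates to an output rate
through the subthreshold moments. With K = pN synapses per channel and
rates ν (Hz), the conductance moments are μG = ν K τ Q and
σG = Q √(ν K τ / 2); the membrane moments follow as

    μV = (μGe Ee + μGi Ei + gL EL - w) / μG,      μG = μGe + μGi + gL
    σV² = Σ_s K_s ν_s (U_s τ_s)² / (2 (τm + τ_s)),   U_s = (Q_s/μG)(E_s - μV)
    τV  = Σ_s K_s ν_s (U_s τ_s)² / Σ_s [K_s ν_s (U_s τ_s)² / (τm + τ_s)]

with τm = cm/μG; τV reduces to τm + τ_s for a single weak channel, and the
zero-input limit uses τm + max(τe, τi) by convention. The output rate is

    ν_out = 1/(2 τV) · erfc( (V_thr_eff - μV) / (√2 σV) )

with an effective threshold given by a full second-order polynomial in the
normalized moments (μV - (-60))/10, (σV - 4)/6, (τVN - 0.5)/1, where
τVN = τV gL/cm. The ten amplitudes {P} are cell-type specific and shared
across awake/sleep states.

**Feature saturation.** The normalization delimits the fluctuation-driven
regime the polynomial is fitted on. Outside it a second-order polynomial
extrapolates without control — the threshold can outrun μV, capping the
rate where the cell should saturate — so the normalized features pass
through a smooth saturation x → c·tanh(x/c) with c = 3 (about 3.5 %
compression at one normalization unit, identity near the center). The
smooth form keeps the derivatives the mean-field differentiates
numerically continuous. Beyond the regime edge the erfc itself provides
the physical saturation.

**Fitting.** Rate tables are sampled by driving one cell with K_e·ν_e
excitatory and K_i·ν_i inhibitory Poisson trains, 5 s per point, averaged
over repetitions. The default grid is ν_e log-spaced over [2, 400] Hz (16
values) × ν_i ∈ {0, 5, 10, 20, 40} Hz, which brackets the firing onset at
every inhibition level so roughly half the grid is active; at least 30
active points are required. Stage 1 computes the stationary adaptation
w* = τw b ν_out + a (μV(w*) - EL) per point (damped fixed-point iteration,
0.01 pA tolerance), inverts the erfc for V_thr_eff where 0 < ν_out < 1/τV,
and solves the linear-in-{P} least squares. Stage 2 refines {P} by
nonlinear least squares in rate space, initialized at Stage 1, with w held
at the stationary value implied by the measured rates. Diagnostics report
the rate-space RMSE. The pipeline is exposed statsmodels-style
(`TransferFunctionModel(...).fit()` returning a results object with
`summary()`).

## Mean field

Two populations (e = TC, i = RE) evolve by the second-order master
equations with adaptation,

    T dν_μ/dt  = (F_μ - ν_μ) + ½ Σ_{λη} ∂²F_μ/∂ν_λ∂ν_η · c_{λη}
    T dc_μν/dt = δ_μν A_μμ + (F_μ-ν_μ)(F_ν-ν_ν) + Σ_λ [∂_λF_μ c_νλ + ∂_λF_ν c_μλ] - 2 c_μν
    τw dw_μ/dt = -w_μ + a (μV_μ - EL) + b τw ν_μ

with the finite-size source A_μμ = F_μ (1/T - F_μ)/N_μ and T = 5 ms (equal
to the rate bin of the network, and larger than the measured population
autocorrelation time, ~0.6 ms at P = 4 Hz). Derivatives of F are central
finite differences (step max(0.05 Hz, 10⁻³ ν); forward at the ν = 0
boundary). External drives fold into the excitatory rate argument with
weight K_D Q_D/(K_e Q_e) — exact for superposed Poisson conductance trains —
so cortical P enters TC and RE at 16 P and sensory S enters TC at 6 S.

Numerics: forward Euler at dt = 0.5 ms (= T/10); rates and covariance
diagonals clipped at zero; diagonal covariances additionally capped by the
all-or-none bound Var ≤ ν(1/T - ν) that any rate confined to [0, 1/T]
obeys, with the cross-covariance held to Cauchy–Schwarz. The caps matter
only in far-from-equilibrium transients, where the (F - ν)² source would
otherwise pump the covariances into a self-sustaining spurious attractor;
near fixed points clip events are absent. Stationary states are found by
relaxing the first-order system (no covariance transients), briefly
integrating the full system from small covariances, then polishing with a
root-finder; large root-finder jumps are distrusted in favour of long
integration. A follow-up integration from the fixed point flags
oscillatory regimes.

**Conductance noise.** Extra static conductances per adiabatic bin model
extracellular noise: an Ornstein–Uhlenbeck path (exact discretization,
stationary start), block-averaged per T and clipped at zero. The run-level
membrane fluctuation reported by noise protocols is
√(⟨σV²⟩_t + Var_t(μV)): the within-bin shotnoise variance plus the
noise-driven wander of μV across bins (the bin-internal σV alone *shrinks*
with added conductance because μG grows).

## Protocols and their defaults

- **Stimulus-shape scan**: split-Gaussian sensory pulses, peak amplitude
  10 Hz, right width 0.2 s, left width σl scanned; response = peak TC rate
  above the pre-stimulus baseline in [t0 - 3σl, t0 + 3σr], divided by the
  amplitude; background P = 1 Hz (the low-activity in-vivo-like state).
- **Gain**: least-squares slope of stationary TC rate vs sensory amplitude
  (≤ 20 Hz, the linear regime).
- **Noise-gain scan**: OU conductance noise (mean = sd = level, τ = 20 ms)
  applied to the TC population only — the population analog of a
  dynamic-clamp conductance injection into the responding cells; noise into
  both populations recruits RE and collapses the gain about five-fold too
  steeply to match the documented fluctuation axis. Levels {0, 3, 6, 9, 12}
  nS; gains from gated rectangular pulses (amplitudes {0, 5, 10} Hz, 1.6 s
  pulses, steady-state window = last half), averaged over noise
  realizations; the reported number is the linear slope of gain vs the
  run-level membrane fluctuation.
- **Conductance-response scan**: one shared Poisson source at 10 Hz onto
  every cell with quantal size Qe scanned; 4-parameter logistic fit, maximum
  slope = amp/(4·width). Single-cell backend measures spikes-out per
  spike-in (5 Hz train).
- **Input-ISI response**: P(output spike | preceding input ISI) for one TC
  cell under 10 Hz Poisson input; an input spike counts as answered if an
  output spike falls within 50 ms (or before the next input); bins of 50 ms
  up to 550 ms, low-occupancy bins flagged rather than dropped.
- **Autocorrelation time**: 1/e crossing of the normalized autocovariance,
  linearly interpolated between lags.
- **Firing-adaptation index**: F_adapt = 1 - F(w = w*)/F(w = 0), the
  relative rate drop once adaptation equilibrates, evaluated against a
  resting-potential offset and optionally averaged over conductance-noise
  draws. (The index is this package's own operationalization.)
- **Cortical turning point**: stationary scan over P; the reported P is the
  saturation knee of the RE curve (most negative second derivative,
  quadratically interpolated), which coincides with the sharp upturn of the
  TC response.
- **Spindle run**: kick + sustained-oscillation detection (spectral peak
  plus non-decaying amplitude over the trailing part of the run).
- **Connectivity scan**: γ ∈ [1, 10] scales the intra-thalamic connection
  probabilities from one tenth of the reference values to the reference
  values while quantal sizes scale as 10/γ, holding the total mean synaptic
  conductance K·Q fixed.

## What the generator emulates, and known limitations

The synthetic inputs are homogeneous Poisson drives and OU conductance
noise; real retinal or cortical spike trains carry temporal structure and
correlations that none of the validation exercises. Passing tests therefore
establish internal consistency between the two scales under these
idealized drives, not fidelity to recorded data.

- The mean-field underestimates the TC rate deep in the inhibited regime
  (network ~0.1–0.4 Hz vs mean-field ~0.02–0.17 Hz at P = 2–4 Hz):
  fluctuation-driven escapes of a nearly silenced population exceed a
  second-order description. RE parity is within one predicted sd
  throughout.
- The sensory gain in this reconstruction decays toward zero deep in the
  inhibited regime and recovers only past the turning point; it does not
  plateau near 0.7 Hz⁻¹ at large P. A plateau would require a weaker
  cortico-RE pathway, which destroys the inhibited-regime structure and the
  ~25 Hz turning point that the model does reproduce.
- The sleep-state conductance-response curve has no sharp ignition (it
  grows quasi-linearly to 80 nS), so its maximum logistic slope is ~85–90 %
  below awake rather than ~20 %.
- Self-sustained spindle oscillations do not emerge at these parameters in
  either backend: a hyperpolarizing kick produces exactly one synchronized
  rebound volley, but TC's strong spike-triggered adaptation cancels the
  rebound charge and the dense RE→RE shunt truncates the RE echo, so the
  cycle attenuates; the rate-based mean-field additionally cannot rebound
  at zero input because σV vanishes with the input rates. The spindle
  machinery (presets, the transfer-function refit for the modified resets —
  shipped in `thalmf/data/spindle_tf.tsv`, regenerable with
  `thalmf make-fixtures` —, kick protocols, oscillation detection, and the
  connectivity scan) is implemented and tested for its mechanics.

## Problem sizes used by the shipped checks

Full network runs use the complete 500+500 circuit for 10 s; transfer
function fits use the 80-point default grid with 10 repetitions of 5 s per
point (the full-scale mode with 100 repetitions is available); noise scans
use 5 OU amplitudes with 2 realizations each and 1.6 s gated pulses. These
sizes were chosen so every check completes on a single core in minutes
while keeping Monte-Carlo uncertainty below the tolerances being tested.
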