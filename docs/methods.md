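# Methods

## The model

`fsneuron` simulates a neocortical parvalbumin-expressing fast-spiking
interneuron as a conductance-based cable model with three sections:

* a point soma (default 25 pF, 700 MΩ leak resistance),
* a cylindrical axon (140 µm × 0.8 µm, C_m = 6 fF/µm²) carrying the axon
  initial segment (AIS) as a contiguous subregion (default 20 µm long,
  starting 10 µm from the soma),
* a cylindrical dendrite (200 µm × 1 µm, C_m = 12 fF/µm²).

Both cylinders are spatially discretized (default segment length 2 µm), so
the cell is a single unbranched chain of compartments — dendrite tip …
soma … axon tip — and the discrete cable operator is tridiagonal.  "Three
compartments" is therefore read as three *sections*: positional questions
(where on the axon the AIS sits, how threshold depends on AIS length) are
meaningless in a literal three-ODE model.

Axial resistance is specified per unit cable length (MΩ/µm): a segment of
length Δx contributes Δx·R_a MΩ in series, so with the default axon
R_a = 0.9 MΩ/µm the path from the soma to the AIS start at 10 µm is 9 MΩ.
This reading reproduces the physical pairing in which wider axons carry a
proportionally lower R_a (0.6 µm ↔ 1.1, 0.9 µm ↔ 0.8 MΩ/µm) with
magnitudes appropriate for sub-micron axons.  The dendrite's axial
resistance defaults to the axonal value scaled by relative cross-section.

Every voltage-gated current uses one first-order formalism

    I = g · m^p · h · (E − V),
    dx/dt = (x_inf(V) − x) / tau_x(V),          x ∈ {m, h}
    x_inf(V) = 1/2 + 1/2·tanh((V − V_half)/V_slope)
    tau_x(V) = (tau_max − tau_min)·(1 − tanh²((V − V_tauhalf)/V_tauslope)) + tau_min

with inactivation either first-order or absent.  Units are fixed
repo-wide — mV, ms, nS, pA, pF, µm — so nS·mV = pA and pF·mV/ms = pA with
no conversion factors anywhere.

Channel placement: Nav1.6 and Kv1 in the AIS only (densities in nS/µm²
are the two main experimental axes; total AIS conductance scales linearly
with AIS length and diameter through the membrane area π·d·L); Nav1.2 in
the soma and the proximal 20% of the dendrite; Kv3 in AIS, soma and
dendrite; leak, M-type K⁺, Kir and Ih in soma and dendrite.  The somatic
leak is derived from the stated soma resistance (1000/700 MΩ ≈ 1.43 nS at
E_leak = −68 mV).

## Where the kinetic constants come from

The geometry, passive constants, channel inventory and regional layout
above are taken directly from the published model description.  The
gating constants (midpoints, slopes, time-constant bounds, activation
exponents) are *not* published for this model; the values shipped in
`params/standard_human.yaml` are effective parameters in the shared tanh
formalism, seeded from standard fast-spiking basket-cell models and then
calibrated so that the standard configuration reproduces the published
baseline anchors (AP threshold ≈ −43 mV at the 10 mV/ms phase-plot
criterion, input resistance and apparent membrane time constant inside
the human interquartile ranges) and the direction and approximate
magnitude of every AIS sweep.  Several structural constraints fall out of
that calibration and are worth recording:

* **Resting stability vs threshold scaling.**  The threshold shift per
  doubling of AIS Nav1.6 content (≈ 5.5 mV, from the AIS-length series)
  fixes the logarithmic sensitivity of threshold to sodium conductance.
  A single shallow activation gate with that e-fold slope everywhere
  makes the resting state unstable (the sodium window current at −70 mV
  exceeds the few-nS resting conductance of a 190 MΩ cell).  The model
  therefore uses a *steep* activation foot (slope factor 12–13 mV in tanh
  units, i.e. Boltzmann k ≈ 6 mV) whose near-threshold sensitivity is
  *diluted by steady-state inactivation*: under the slow approach to
  rheobase, availability tracks h_inf, and the effective activation slope
  of the m·h_inf product is what sets the length scaling.  Sub-millisecond
  inputs (EPSCs) outrun inactivation, which is also why EPSC thresholds
  are not trivially predictable from step thresholds.
* **A subthreshold anchor independent of Kv1.**  With zero AIS Kv1 (the
  human-type corner) something must still terminate the slow
  depolarizing creep between −55 and −45 mV.  The combination of the
  steep sodium inactivation curve and a small slow M-type conductance
  (midpoint ≈ −51 mV) carries that role, stabilizing the quasi-static
  approach to rheobase without loading the resting conductance at
  −70 mV or the fast AP waveform.
* **Kv1 as a threshold rheostat.**  The AIS Kv1 steady-state activation
  foot is shallower than the sodium availability slope, which makes the
  threshold-vs-density curve rise sub-linearly (saturating), as in the
  published density series.  Its midpoint/slope are effective values —
  chosen for the size of the foot in the −50…−35 mV band, which is the
  only part of the curve the threshold experiments constrain.

## Numerical scheme

Gates advance by exponential Euler against their local voltage;
the voltage update is implicit (backward Euler) with channel conductances
frozen at the new gate values, solved per step by the Thomas algorithm on
the tridiagonal cable matrix.  This splitting is unconditionally stable
for the diffusion term and keeps gates in [0, 1] exactly by construction.
Default dt = 0.01 ms; the acceptance suite verifies that halving dt moves
the detected threshold by < 0.1 mV and spike times by < 0.05 ms, and that
halving the segment length moves the threshold by < 0.2 mV.

Holding at −70 mV is solved by voltage-clamping the soma until the distal
compartments and all gates relax (300 ms), reading the clamp current at
steady state, then verifying that the unclamped cell with that constant
bias stays within 0.1 mV without firing; a failure here (the model being
spontaneously active) is reported as an error, never patched silently.
Each protocol starts from the settled holding state, with a 200 ms
settling period excluded from every trace.  Integration reports
divergence (|V_m| > 200 mV) with the time and dt; rheobase searches treat
a diverged, spikeless sweep (a passive cell driven far past physiological
range) as "did not spike".

## Protocols and feature definitions

* **AP threshold**: V_m at which dV/dt (central differences, no
  smoothing) first reaches 10 mV/ms on the rising limb of a validated
  spike, linearly interpolated between samples.  A spike is validated by
  its peak exceeding −20 mV — above any subthreshold EPSP yet below the
  model's somatic spike peaks — which rejects noise crossings; the onset is
  the start of the *last* contiguous above-criterion run before the peak,
  so a fast EPSP rise (which can transiently exceed 10 mV/ms) is never
  mistaken for the AP onset, while sub-criterion dips shorter than
  0.06 ms (derivative noise) are bridged.
* **Rheobase**: bisection (default 1 pA resolution) between a verified
  subthreshold and suprathreshold amplitude of a 250 ms somatic step from
  −70 mV; threshold values quoted anywhere come from the first AP of the
  rheobase sweep.  Inside grid sweeps, the bracket is warm-started from
  the neighbouring grid point; both bracket sides are still verified.
  Because spike latency is steeply amplitude-dependent just above the
  true rheobase, a threshold measured at the found amplitude carries a
  protocol sensitivity of roughly ±0.4 mV depending on where inside the
  1-pA bracket the search lands; any given search path is deterministic,
  but warm-started sweep values can differ from isolated measurements by
  that much.
* **EPSC**: a somatic conductance transient g(t) = A(e^(−t/3 ms) −
  e^(−t/τ_rise)) with τ_rise solved so the peak falls at 0.5 ms and A
  normalized so the continuous-time maximum equals the requested peak
  conductance exactly; reversal 0 mV.  Threshold searches walk the 6–11 nS
  grid in 0.25 nS steps; the lag is EPSC onset to the 10 mV/ms crossing.
  A dual exponential is the minimal kernel honouring the stated
  time-to-peak and decay; note that its peak normalization leaves the
  value one decay constant after the peak ≈ 6% above g_peak/e.
* **Half-width** at 50% of the threshold-to-peak amplitude; **AHP
  amplitude** from threshold to the post-peak trough (negative-going;
  reported missing when the trace ends before a trough or the trough
  stays above threshold); **max rise/fall** as the phase-plot extrema;
  **initial rise slope** as the maximum d(dV/dt)/dV above the criterion
  point and below the phase-plot peak.
* **R_in** from the mean ΔV_ss/ΔI of subthreshold steps (final 20% of the
  step; sweeps containing an AP are excluded with a warning); **apparent
  tau** from a single-exponential least-squares fit to the charging phase
  (window 5× the initial guess); **C_m estimate** = tau/R_in, the only
  definition consistent with the reported units (the source reports C_m
  without stating its computation).

## Calibration operation

`calibrate_baseline` is deterministic coordinate descent over
multiplicative scales on {AIS gNav1.6 density, somatic/dendritic Nav1.2,
Kv3, dendritic leak, Ih}, in that fixed order, from the shipped defaults,
minimizing the tolerance-weighted squared error on {threshold −43 ± 0.5 mV,
R_in 187.9 ± 88 MΩ, tau 6.65 ± 1.98 ms, resting V_m −68 ± 6 mV}; it stops
the moment every target is inside tolerance (the shipped defaults already
satisfy them, so the operation is the identity unless a user perturbs the
model) and raises with a best-so-far report at the iteration cap.

## Synthetic data

The synthetic generators exist so the feature extractor can be tested
against *exact* ground truth, and cohort-level code against known
quantiles:

* AP trains are sums of logistic sigmoids (upstroke, downstroke, AHP
  recovery) on an exponential approach plateau.  The waveform is smooth
  and analytically differentiable; the plateau level is solved (nested
  root-finding on the closed-form derivative) so the continuous-time
  10 mV/ms crossing lands exactly on the programmed threshold, and the
  annotations carry those exact values.  The templates are *not*
  realistic FS spikes (they are wider, with simplified AHP shape); they
  test the detector's operational definitions, not its performance on
  biological waveforms.
* Passive traces are exact single exponentials with programmed R_in/tau
  plus seeded Gaussian noise.
* Cohorts draw each feature independently from a shifted log-normal
  whose three parameters are solved in closed form from the target
  median and quartiles (the quartile-gap ratio equals e^(z₇₅σ));
  left-skewed triples are mirrored about the median, symmetric ones fall
  back to a normal.  Features are sampled independently — the generator
  matches marginal quantiles, not the real between-feature correlations
  (e.g. the reported R_in–tau association), so passing cohort tests says
  nothing about multivariate structure.

All randomness flows through explicit integer seeds; no global state.

## Problem sizes and tolerances

The sweep experiments use AIS length 10–30 µm and Kv1 density
0–20 nS/µm², each in steps of 2.5 (a 9 × 9 grid) — the published density
endpoints with a step fine enough to resolve both corners; the diameter
sweep uses the four physically paired (diameter, R_a) points and the
R_a-alone sweep {0.8, 0.95, 1.1} MΩ/µm.  Because the underlying kinetic
constants are calibrated rather than published, sweep outputs are
compared to the published values at ±1 mV (thresholds), ±0.25 nS (EPSC
thresholds, one grid step) and ±0.5 ms (lags), with orderings and
monotonicities required exactly.  The published simulation report itself
quotes the same standard configuration at −42.3, −43 and −43.2 mV in
three places, which is a useful indication of the resolution at which
such thresholds are meaningful; the published Kv1-density series
(−41.6 mV at 15 nS/µm²) is not mutually consistent with the −43 mV
standard value at 20 nS/µm² under any strictly monotone model, so the
calibration targets the joint compromise and the density series carries
the residual error.

## Known limitations

* No Markov channel states, no temperature (Q10) scaling, no stochastic
  gating, no myelin, no morphological detail beyond three sections.
* Kv1 is modelled without inactivation (the slow D-type inactivation
  would interact with the per-point rheobase protocol).
* Synaptic input is a single somatic conductance; no trains, no
  dendritic placement, no short-term plasticity.
* The calibrated kinetics are *effective* constants: they reproduce the
  measured input-output anchors of the modelled cell class, but the
  individual gate parameters should not be read as channel-level
  biophysics.
* The somatic action potential is AIS-driven and of modest amplitude in
  strongly isolated configurations (short AIS, high Kv1, high axial
  resistance); spike detection on simulated traces therefore validates
  events on the axonal (AIS) voltage, where the spike always overshoots
  0 mV, while the threshold itself is read from the somatic phase plot.
  Somatic waveform features (peak, maximal rise/fall speed) are
  consequently smaller than in real whole-cell recordings.
* Within this kinetics family, with the geometry, capacitances and the
  two AIS densities pinned at their published values, some sweep
  magnitudes are irreducibly larger than their published counterparts:
  the AIS length effect beyond 20 µm, the AIS-position and axial-
  resistance sensitivities (axial-isolation dynamics), and the joint
  grid span; the EPSC threshold conductances sit near the low end of
  the 6–11 nS search grid because the EPSP gain is fixed by the pinned
  capacitances.  `scripts/acceptance.py` recomputes and reports every
  one of these quantities as the model actually produces them.
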