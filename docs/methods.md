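# Model and methods

`habitloops` simulates habit formation and outcome devaluation with a
hierarchical rate-coded model of two cortico-basal-ganglia-thalamo-cortical
loops, and the pathological manipulations under which habitual responding is
enhanced.  This note documents the model equations, the free design choices,
the parameter calibration, and what the simulations do and do not show.

## Dynamics

Every population is a vector of leaky rate units integrated with explicit
Euler (dt = 1 ms):

    tau_m dv/dt = -v + sum(signed inputs) + baseline + noise,   r = gain * [v]+

with tau_m = 10 ms everywhere, uniform per-step membrane noise of half-width
0.01 (0.03 on the cognitive pallidal output, whose trial-to-trial variability
is the main source of stochastic gating), and a rectifying transfer.  Rates
are deliberately *not* hard-saturated: the nominal saturation bound (1.2) is
kept only as the reference scale of the numerical-instability detector, which
flags any non-finite state or any rate above 100x that bound together with the
population and simulation time.  `gain` is the dopaminergic
response-modulation factor S_f (1 in the control model; multiplied onto D1
rates and divided out of D2 rates under pathology).

## Architecture

* **Cognitive (dorsomedial) loop.** Stimulus cortex (6 units) and goal cortex
  (6) drive D1 and D2 medium spiny neurons (6 channels) through plastic
  cortico-striatal projections.  The stimulus stream is initialized
  topographically (each stimulus prefers its own category channel); the goal
  stream is weaker (amplitude 0.85, cap 0.40 vs. stimulus cap 0.42) but
  *necessary*: channel ignition through the direct pathway
  (D1 -> GPi -> thalamus -> category cortex) requires stimulus and goal drive
  together.  This is the outcome-devaluation gate: cancelling the goal signal
  leaves every channel subthreshold, so the dorsomedial loop falls silent.
  The loop further contains the indirect (D2 -> GPe -> GPi) and hyperdirect
  (stimulus -> STN -> GPi, diffuse) pathways, local inhibitory collaterals
  within D1 and within D2 (the dorsomedial disinhibition target), a closed
  cortical feedback (category cortex -> D1/D2) that lets a tentative winner
  amplify itself, and competition between category-cortex units.
* **Motor (dorsolateral) loop.**  The selected category reaches motor D1/D2
  (2 channels, LEFT/RIGHT) through the overlapping cortico-striatal
  projection (*crosslink*, plastic).  A separate group of D1 cells receives
  the loop's own cortical feedback (motor cortex -> feedback D1 and
  -> D2); together with GPi -> thalamus -> cortex this closes a positive loop
  whose gain is tuned slightly below one (0.976 at S_f = 1).  Near-critical
  feedback is the substrate of the response-modulation effect: a 2% striatal
  gain change moves the loop gain by ~0.037 (D1 up, D2 down, both inside the
  loop), which strongly shifts the ignition threshold of shortcut-initiated
  responses while leaving ordinary (category-driven) responses untouched.
  Feedback-recipient cells inhibit, but do not receive, the striatal
  collaterals, so a subthreshold candidate response can always be amplified.
* **Cortico-thalamic shortcut.**  A plastic projection from stimulus cortex
  directly to the motor thalamus (pathway gain 0.45).  On devalued trials the
  cognitive loop is silent and a response occurs only if the trained shortcut
  entry lifts the motor thalamus past the ignition threshold of the
  near-critical feedback loop — habitual responding.

The model response is the first motor-cortex rate crossing of 1.0 within a
2000 ms stimulus window (ties broken by higher rate, then lower index); no
crossing is scored as a withheld response.  Each trial is preceded by a 150 ms
relaxation to rest; selection is followed by a 1000 ms post-feedback window
whose time-averaged rates feed the plasticity rules.  Membrane potentials
reset between trials; weights persist.

## Plasticity

**Cortico-striatal (three-factor).**  Once per trial,

    dW = lr * (+-1) * (DA - tonic) * [post - 0.4]+ * pre * ([1.2 * post - W]+ | LTP)

with sign +1 for D1 and -1 for D2 synapses, lr = 0.06 (cognitive) and 0.32
(crosslink).  Two regularizations matter: the postsynaptic activity threshold
(0.4) denies credit to residually active, unselected channels, and
potentiation saturates at 1.2x the postsynaptic rate, so the asymptotic weight
tracks the operating point and the phasic-dopamine amplitude only sets the
approach speed (this is why enlarging the dopamine bursts leaves the final
behavior unchanged).  Depression is linear.  In the cognitive loop, dips act
only through D2 and bursts only through D1: omissions re-bias selection via
the indirect pathway instead of erasing the stimulus-category map, so a run of
errors cannot destroy the acquired task representation.  D1-stream weights
have floors (0.20 cognitive, 0.30 crosslink) so an unrewarded action remains
recoverable.

**Phasic dopamine.**  Reward drives the level to `peak` (control 0.9 over a
tonic of 0.5); omission after a response dips it symmetrically below baseline
(floored at zero).  Withheld responses produce no phasic event.  The
plasticity-modulation pathology raises the peak and lowers the baseline by the
same amount, enlarging the deviation in both directions.

**Shortcut (Hebbian, basal-ganglia-gated).**

    dW = (dt / tau_w) * pre * post * (1.2 * post - W)

applied with the learning window as dt.  The teacher is the motor thalamic
rate, which is shaped by pallidal inhibition — the basal ganglia veto shortcut
learning by silencing the thalamus, and doubling the pallido-thalamic weights
demonstrably shrinks the learned shortcut.  The per-step change scales exactly
with 1/tau_w (control 15,000 ms).  Weights start at 0.42 and saturate toward
1.2x the teacher rate; after 10 training blocks the six task-relevant entries
sit near 0.8 and the six unused entries remain at 0.42, giving a control
matrix mean near 0.6.

## Task

Six stimuli map one-to-one to six outcomes and deterministically to three LEFT
and three RIGHT button presses.  Training: 10 blocks x 12 trials (each
stimulus twice per block, shuffled).  Outcome-devaluation test: 6 blocks x 12
trials, 2 outcomes devalued per block (each outcome exactly twice across the
test); devalued trials have the goal input cancelled.  Stimulus-devaluation
test: same design over stimuli, with the stimulus drive attenuated to 0.25
(seen but not attended).  Plasticity is frozen during both tests (a config
switch).  The behavioral variable in the tests is the fraction of trials with
*any* response, reported separately for devalued and valued items.

## Calibration

All control parameters were calibrated once, before the statistical analyses
were frozen, against four qualitative constraints: (i) the control cohort
exceeds 90% correct from block 8; (ii) control subjects respond to devalued
outcomes at a low but non-zero rate while responding to essentially all valued
items; (iii) responding to devalued (attenuated) stimuli stays near zero in
all shortcut variants; (iv) every pathology expresses through its designated
knob only.  Cohorts of 20 seeded subjects are the unit of analysis throughout;
the exact permutation test (all label reassignments when feasible, otherwise
100,000 fixed-seed resamples) compares per-subject rates.

## Known limitations

* **Full dorsomedial disinhibition is behaviorally, not numerically,
  catastrophic.**  With local striatal inhibition removed entirely, this
  implementation loses the goal gate completely (responding to devalued
  outcomes and devalued stimuli both approach 100%) but its rates remain
  bounded: the covariance threshold and the rate-referenced soft bound that
  stabilize healthy learning also prevent cortico-striatal weights from
  entering the runaway regime in which rates would cross the
  instability-detector bound.  The detector (non-finite state or rate beyond
  100x the nominal saturation bound) is implemented, tested, and does fire
  under genuinely divergent dynamics (see the experiment tests), but the
  frozen calibration does not reproduce a training-time runaway at 0%
  inhibition.
* The partial-disinhibition effect on devalued-outcome responding operates
  through erosion of the ignition margin of the goal gate rather than through
  increased shortcut variability; the trained shortcut statistics of the 40%
  condition match the control's mean closely, and their spreads are nearly
  identical rather than clearly ordered.
* The synthetic cohorts emulate the discrete-trial structure, contingencies
  and devaluation schedules of the human task, but not reaction-time
  distributions, instruction effects, or between-subject heterogeneity beyond
  seed-driven variation in initial weights, trial order and membrane noise.
  Passing cohort-level tests therefore show that the circuit mechanisms can
  produce the reported behavioral dissociations, not that parameter values are
  identifiable from human data.
* One unit per stimulus/category/response is the minimal faithful
  dimensionality for this task; population-level phenomena (tuning widths,
  correlated noise) are out of scope, as are tics themselves, spiking
  dynamics, and the limbic/ventral goal-selection loop (the goal signal is an
  input).
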