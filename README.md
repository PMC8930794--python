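# habitloops

A neuro-computational model of habit formation in hierarchical
cortico-basal-ganglia-thalamo-cortical loops, built to study how Tourette-like
pathophysiology — faster cortico-thalamic shortcut learning, enhanced
dopaminergic modulation of striatal medium spiny neurons, and reduced local
striatal inhibition — increases habitual responding in a
stimulus-response-outcome devaluation task.

## Who this is for

Computational neuroscientists and cognitive modelers who want a compact,
fully reproducible rate-coded implementation of the two-loop basal-ganglia
architecture with a learnable cortico-thalamic shortcut: every population,
pathway, plasticity rule and pathological manipulation is explicit, seeded and
testable, and whole simulated cohorts run in minutes on one CPU.

## The model in brief

Populations of leaky rectified rate units, `tau dv/dt = -v + I + b + noise`,
`r = S_f [v]+`, integrated with explicit Euler (dt = 1 ms), form two loops:

* a **cognitive loop** (dorsomedial striatum) that selects a cognitive
  category from a stimulus *and* a goal signal through direct
  (D1 -> GPi), indirect (D2 -> GPe -> GPi) and hyperdirect (cortex -> STN ->
  GPi) pathways — cancelling the goal (outcome devaluation) silences it;
* a **motor loop** (dorsolateral striatum) that turns the category into a
  LEFT/RIGHT button press, with motor cortex feeding back onto dedicated
  striatal cells so the loop amplifies candidate responses near-critically;
* a plastic **cortico-thalamic shortcut** from stimulus cortex straight to
  the motor thalamus, trained by a basal-ganglia-gated Hebbian rule
  `dW = (dt / tau_w) pre post (1.2 post - W)`: after training it can ignite
  the motor loop even when the cognitive loop is silent — a habit.

Cortico-striatal projections learn with a three-factor rule gated by the
phasic dopamine deviation (`dW ∝ ±(DA - tonic) · pre · post`, potentiation
soft-bounded by the postsynaptic rate).  Every manipulation studied is a
`PathologyConfig` knob: `shortcut_tau_w`, `shortcut_plastic`, the striatal
gain `sf` (with or without modulation of the feedback-recipient cells), the
phasic dopamine peak/baseline, and the fraction of local striatal inhibition
kept in each loop.  See `docs/methods.md` for the full equations, parameters
and limitations.

## Worked example

```bash
python examples/02_train_subject.py
```

```
learning curve (fraction correct per block):
  [0.92 1.   1.   1.   1.   1.   1.   1.   1.   1.  ]
outcome test : valued 1.00  devalued 0.17
stimulus test: valued 1.00  devalued 0.00
shortcut weights: mean 0.611  std 0.176
```

The control subject masters the 6-stimulus task within a block or two, keeps
responding to every still-valued item, and withholds most responses to
devalued outcomes — the 17% that remain are habitual responses driven by the
trained shortcut (task-relevant entries near 0.8, unused entries at their
initial 0.42, hence the matrix mean near 0.6).  Attenuated (devalued) stimuli
elicit no responses at all.  Contrast the shortcut-speed manipulation:

```bash
python examples/03_shortcut_speed.py
```

```
no_shortcut_plasticity   devalued-outcome rate 0.000   late training performance 1.00
control                  devalued-outcome rate 0.167   late training performance 1.00
fast_shortcut_6000       devalued-outcome rate 1.000   late training performance 0.89
permutation test, no shortcut vs tau=6000: p = 0.0022
```

Without shortcut plasticity habits never form; with a faster shortcut
(tau_w = 6,000 ms instead of 15,000 ms) responding to devalued outcomes
becomes pervasive while task learning stays high.
`examples/04_dopamine_modulation.py` shows the response-modulation
dissociation (a 2% striatal gain change matters only when it includes the
feedback-recipient cells), and `examples/01_single_trial.py` exposes the
selection dynamics of a single trial.

## Command line

```bash
habitloops run control --subjects 20 --seed 100 --outdir out/control
habitloops run "reduced_dms(0.4)" --subjects 20 --seed 100 --outdir out/dms40
habitloops compare out/control/summary.json out/dms40/summary.json
habitloops presets
```

`run` writes per-trial and per-subject CSVs, a JSON cohort summary, a
manifest, and figures (learning curve, valued/devalued bar charts); `compare`
reports permutation tests on all four response-rate metrics.

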