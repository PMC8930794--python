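"""Train one simulated subject and run both devaluation tests.

Runs the full protocol (10 x 12 training trials, then outcome- and
stimulus-devaluation tests with plasticity frozen) for a single control
subject and prints the learning curve, the response rates toward valued and
devalued items, and the trained shortcut statistics.  High valued-item rates
with much lower devalued-outcome rates indicate goal-directed control; the
devalued-outcome responses that remain are habits carried by the
cortico-thalamic shortcut.
"""
import numpy as np

from habitloops import preset, run_subject

subject = run_subject(preset("control"), seed=101)
print("learning curve (fraction correct per block):")
print(" ", np.round(subject.learning_curve, 2))
print(f"outcome test : valued {subject.rate_valued_outcome:.2f}  "
      f"devalued {subject.rate_devalued_outcome:.2f}")
print(f"stimulus test: valued {subject.rate_valued_stimulus:.2f}  "
      f"devalued {subject.rate_devalued_stimulus:.2f}")
print(f"shortcut weights: mean {subject.shortcut_mean:.3f}  "
      f"std {subject.shortcut_std:.3f}")
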