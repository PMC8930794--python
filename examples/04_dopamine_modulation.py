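"""The response-modulation dissociation (models A and B).

A 2% increase of striatal excitability (D1 up, D2 down) raises habitual
responding only when the modulation includes the cells that receive cortical
feedback from the motor loop (model A); sparing them (model B) abolishes the
effect.  Small cohorts for speed; the test suite uses 20 subjects.
"""
from habitloops import permutation_test, preset, run_cohort

control = run_cohort(preset("control"), 6, 100)
model_a = run_cohort(preset("da_response_mod(1.02)"), 6, 100)
model_b = run_cohort(preset("da_response_mod_no_feedback(1.02)"), 6, 100)
ctl = control.rates("rate_devalued_outcome")
for name, cohort in [("model A (full modulation)", model_a),
                     ("model B (feedback spared)", model_b)]:
    r = cohort.rates("rate_devalued_outcome")
    print(f"{name}: devalued-outcome rate {r.mean():.3f} vs control {ctl.mean():.3f}"
          f"  (p = {permutation_test(ctl, r):.4f})")
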