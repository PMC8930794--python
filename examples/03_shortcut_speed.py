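"""Faster shortcut learning produces more habitual responding.

Runs small matched-seed cohorts with shortcut learning disabled, at the
control time constant (15,000 ms) and at the fast one (6,000 ms), then prints
the mean rate of responding toward devalued outcomes and the permutation
p-value for the extreme pair.  More responses to devalued outcomes = more
habitual control.  (Cohorts of 6 keep this demo quick; analyses in the test
suite use 20.)
"""
from habitloops import permutation_test, preset, run_cohort

cohorts = {name: run_cohort(preset(name), n_subjects=6, base_seed=100)
           for name in ("no_shortcut_plasticity", "control", "fast_shortcut_6000")}
for name, cohort in cohorts.items():
    rates = cohort.rates("rate_devalued_outcome")
    perf = cohort.curve()[:, 7:].mean()
    print(f"{name:24s} devalued-outcome rate {rates.mean():.3f}   "
          f"late training performance {perf:.2f}")
p = permutation_test(cohorts["no_shortcut_plasticity"].rates("rate_devalued_outcome"),
                     cohorts["fast_shortcut_6000"].rates("rate_devalued_outcome"))
print(f"permutation test, no shortcut vs tau=6000: p = {p:.4f}")
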