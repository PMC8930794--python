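"""Build the control model and watch one trial's selection dynamics.

Builds a seeded control model, presents stimulus 0 with its goal, and prints
the category-cortex and motor-cortex rates while the decision forms, then the
response (the first motor-cortex rate to cross 1.0) and its latency.
"""
import numpy as np

from habitloops import build_model, build_task, encode_inputs, preset, read_response
from habitloops import _kernels

task = build_task(seed=1)
print("correct buttons:", task.correct_response)
model = build_model(task, preset("control"), seed=1)
_kernels.seed_noise(1)

drive = encode_inputs(task, stimulus=0, mode="train", devalued=False)
outcome = model.run_trial_selection(drive)
print(f"response={outcome.response}  reaction time={outcome.rt_ms:.0f} ms")
print("category cortex:", np.round(model.rates("cog_ctx"), 2),
      " (one channel near 1 = the selected cognitive category)")
print("motor cortex:   ", np.round(model.rates("mot_ctx"), 2),
      " (the winner crossed the decision threshold of 1.0)")
print("read_response():", read_response(model))
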