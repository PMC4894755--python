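"""Classifying motor responses to leg-load (campaniform sensilla) stimuli.

During inside turning, load stimuli to the leg stump evoke a mixture of
responses: retractor activation, retractor termination with protractor
activation, or no response at all.  The no-response stimuli cluster at a
preferred phase (~0.89) of the front-leg step cycle.  During outside
turning every stimulus activates the retractor.
"""

import numpy as np

import turncycle as tc

preset = tc.get_preset("load-inside")
gait = tc.make_steps(preset, 1001, seed=8)
trial = tc.make_load_trial(gait, preset, seed=9, n_stim=500)
cycles = tc.segment_steps(gait.touchdowns, gait.liftoffs)

pro_env = tc.condition_envelope(trial.protractor)   # rectify + 100 ms Gaussian
ret_env = tc.condition_envelope(trial.retractor)
responses = tc.classify_all(pro_env, ret_env, trial.stimuli, cycles)

n = len(responses)
for klass in ("RET_ACT", "PRO_ACT", "NONE"):
    frac = np.mean([r.klass == klass for r in responses])
    print(f"{klass:>8}: {100 * frac:5.1f} % of {n} stimuli")

agreement = np.mean([r.klass for r in responses] == trial.true_class)
print(f"classification matches generator ground truth for "
      f"{100 * agreement:.1f} % of stimuli")

_, cs = tc.response_vs_phase(responses, cycles, klass="NONE")
print(f"no-response phase preference: mean = {cs.mean_fraction:.3f} of the "
      f"step cycle, R = {cs.R:.2f}, Rayleigh p = {cs.p_rayleigh:.2g}")
print("-> failures to respond cluster late in the cycle, near touchdown")
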