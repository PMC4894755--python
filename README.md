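# turncycle

Analysis toolkit for body-side-specific motor output in a turning
insect: step-cycle statistics, EMG conditioning, load-stimulus response
classification, circular phase statistics, and central-pattern-generator
(CPG) rhythm analysis — together with a synthetic-data generator that
emulates the statistical structure of the recordings, so the whole
pipeline is testable end to end without any experimental data.

## The scientific problem

When a stick insect turns, the legs on the concave (inside) and convex
(outside) side of the turn do different jobs. The toolkit quantifies
this asymmetry at three levels:

- **Kinematics.** Step cycles are anchored at stance onset (touchdown,
  the anterior extreme position); the period *P* is the time between
  consecutive touchdowns. Inside steps are faster than outside steps
  (e.g. middle-leg periods ≈ 0.76 s vs ≈ 1.13 s), compared via Welch's
  *t*-test on per-sequence mean periods.
- **Reflex processing.** Load stimuli to the leg's strain sensors
  (campaniform sensilla) evoke, during inside turning, a mixture of
  responses: retractor activation, retractor termination with protractor
  activation, or no response. Responses are scored by the maximum
  retractor activation in a 150 ms post-stimulus window (normalized to
  control stimulations) and by the Michelson contrast
  *C* = (*a*<sub>post</sub> − *a*<sub>pre</sub>)/(*a*<sub>post</sub> + *a*<sub>pre</sub>) ∈ [−1, 1]
  of mean envelope activity in 100 ms windows around the stimulus.
  No-response stimuli cluster near phase 0.89 of the front-leg cycle.
- **Central rhythms.** Motoneuron spike phases φ within the step cycle
  are summarized by the mean resultant vector
  *R* e<sup>iθ̄</sup> = n⁻¹ Σ e<sup>i2πφ</sup> and tested for uniformity
  with the Rayleigh test (*Z* = *nR*², series-corrected p, α = 0.005):
  protractor activity peaks near 270°, retractor near 90° of the cycle.
  The pharmacologically activated CPG rhythm runs near 0.27 Hz in the
  quiescent animal and speeds up to ≈ 1.16 Hz during inside stepping;
  cycle frequency is the inverse mean inter-onset interval of detected
  bursts, and pro-/retractor alternation appears as a dip at lag 0 in
  their lag-wise Pearson cross-correlation.

## Worked example

```python
import turncycle as tc
from turncycle.synthetic import _phase_of

preset = tc.get_preset("fl-inside")           # front leg, inside turning
gait = tc.make_steps(preset, 300, seed=7)
pro, ret = tc.make_nerve_activity(gait, "inside", preset, seed=8)

cycles = tc.segment_steps(gait.touchdowns, gait.liftoffs)
stats = tc.period_stats(cycles)
cs = tc.mean_vector(_phase_of(pro.times, gait.touchdowns.times))
print(stats.mean, stats.sd)
print(cs.mean_angle, cs.R, cs.p_rayleigh)
```

prints (run as `examples/02_phase_coupling.py`):

```
protractor: n=9540 spikes, mean phase =  270.2 deg, R = 0.862, Rayleigh p = 2.2e-308 *
 retractor: n=9509 spikes, mean phase =   90.6 deg, R = 0.859, Rayleigh p = 2.2e-308 *
```

i.e. the protractor pool fires concentrated around 270° of the step
cycle and the retractor around 90° — alternating, phase-locked activity
with a highly significant phase preference — while the outside-turning
mode yields tonic, retractor-biased spiking with *R* at the
uniform-null level. The `examples/` directory holds one short script per
capability (step periods, phase coupling, load responses, CPG rhythm,
signal conditioning), each printing the numbers it computes and what
they mean.

A thin CLI mirrors the stages:

```sh
turncycle run --scenario pilocarpine --seed 4
turncycle generate --preset fl-inside --n-steps 300 --seed 2 --out events.csv
turncycle steps --events events.csv --out cycles.csv
```

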