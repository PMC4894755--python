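# Methods

This note documents the models, estimators and numerical conventions
the package implements, the design choices that were genuinely open,
and what the synthetic-data generator does and does not emulate.

## Phase conventions

Step-cycle phase is the fraction of the cycle elapsed since the last
touchdown (stance onset): φ = (t − t<sub>TD</sub>)/P ∈ [0, 1), where
P is that cycle's period. Nerve-activity peak parameters are given in
degrees (×360 conversion); all internal computation uses cycle
fractions. Times between stepping sequences have undefined phase (NaN)
and are excluded from circular summaries.

## Synthetic-data generator

The generator produces data with the statistical structure the
analyses assume, each condition under a named preset:

- **Step trains** (`make_steps`): periods are i.i.d.
  Normal(μ, σ) truncated below at 0.1 μ (sampling by rejection), with
  (μ, σ) per preset: front leg inside (0.83, 0.21) s, front leg outside
  (1.21, 0.37) s, middle leg inside (0.76, 0.15) s, middle leg outside
  (1.13, 0.28) s. Lift-off follows touchdown after a fixed duty
  fraction (default 0.6, a typical stance fraction at moderate walking
  speed). Cycles are contiguous; the analysis layer is responsible for
  pause handling.
- **Nerve activity** (`make_nerve_activity`). Inside mode:
  inhomogeneous Poisson spike trains generated by thinning against the
  von Mises rate profile r(t) = r₀ e^{κ cos(θ(t)−μ)}/I₀(κ), so the
  phase marginal of spikes is exactly von Mises(μ, κ) and the
  time-averaged rate is r₀ (default 40 spikes/s, κ = 4, protractor
  μ = 270°, retractor μ = 90°). Outside mode: homogeneous Poisson with
  the retractor rate fixed at 3× the protractor rate — a tonic,
  retractor-biased regime; the ratio is a configurable convention, as
  only the direction of the bias is constrained by the phenomenon.
- **Slow CPG rhythm** (`make_pilocarpine_rhythm`): alternating
  pro-/retractor burst cycles at 0.27 Hz (quiescent) or 1.16 Hz (during
  stepping intervals), protractor bursts in the first part of each
  cycle, retractor bursts anti-phase. Burst duty is 0.35 of the cycle,
  intra-burst spiking Poisson at 80 Hz, and cycle periods carry a 5%
  coefficient of variation — values chosen so that the default burst
  criterion separates both regimes cleanly while the trains still look
  irregular. The rhythm *resets at stepping-interval boundaries*: a
  cycle straddling a boundary is truncated and a fresh cycle starts at
  the new frequency. This models a prompt speed-up/relaxation and keeps
  interval-restricted frequency estimates unbiased by straddling
  cycles.
- **Load sessions** (`make_load_trial`): each stimulus is assigned
  RET_ACT / PRO_ACT / NONE with preset probabilities (inside turning:
  0.662 / 0.15 / 0.188; outside: 1 / 0 / 0). The PRO_ACT share is set
  mid-range of the observed 2–25% per-animal span. NONE stimuli get
  step-cycle phases from von Mises(0.89 × 2π, κ = 8); the other classes
  uniform phases. Stimuli occupy every other step cycle (starting from
  the second), so neighbouring 150 ms transients and the ±100 ms
  contrast windows never overlap and the first stimulus keeps a full
  pre-window. Envelopes are a constant baseline (0.2) with a 150 ms
  step transient (+2.0 for activation; suppression to 0 for
  termination) plus Gaussian noise (SD 0.05), clipped at zero. The
  stimulus command ramp itself is represented only by its onset time
  plus a stored 500 ms plateau: the mechanical ramp kinetics are a free
  parameter and do not enter the analysis.
- **EMG pairs** (`make_emg`): each muscle's true envelope is a von
  Mises bump of cycle phase (κ = 6, so antagonist bursts barely
  overlap); the recorded channel is its own envelope multiplying a
  white-noise interference carrier plus a crosstalk coefficient
  (default 0.3) times the antagonist's raw trace plus sensor noise.
  The additive-envelope assumption behind the crosstalk-subtraction
  procedure holds precisely because the antagonists alternate.
- **Contact voltage** (`make_contact_trace`): high in stance, low in
  swing, with 10 ms raised-cosine edges centred on the true events, so
  a mid-amplitude threshold crossing falls at the touchdown and the
  steepest slope at the lift-off.

All generators are deterministic in (preset, seed).

What the generator does **not** emulate: inter-animal variability
(presets fix one parameter set; the "between animals" spread of the
real data appears only through the seeds of independent synthetic
sequences), bimodal latency distributions from backward stepping,
co-contraction, electrode drift or movement artefacts, and any
biomechanics or membrane dynamics. Passing recovery tests therefore
show that the estimators are correct and well-calibrated for data of
this structure — not that they are robust to every artefact of real
recordings.

## Signal conditioning

- Boxcar smoothing averages over [t − T, t + T] (default T = 50 ms);
  Gaussian smoothing uses a kernel of total support equal to the stated
  width (default 100 ms) with σ = width/4, truncated at ±2σ and
  renormalized. "Width" of a running Gaussian average is ambiguous
  (σ? FWHM? support?); total support with σ = 25 ms is the convention
  adopted here.
- Edge handling: truncated windows renormalized by the weight actually
  inside the trace (no padding), so constants are fixed points of every
  smoother. With this scheme the trace mean is preserved exactly only
  when the signal's support stays a half-window clear of the edges;
  interior samples match the direct convolution to rounding error.
- Crosstalk subtraction: the agonist envelope is min-max normalized to
  [0, 1], the antagonist to [0, cap] (cap = 0.5, reflecting the smaller
  amplitude of bleed-through), subtracted pointwise, and clipped at 0 —
  rectified envelopes are non-negative by definition. A constant
  antagonist rescales to zero and leaves the agonist unchanged;
  constant segments in per-step normalization likewise map to zero.
- Event detection: touchdown is the interpolated threshold crossing
  (sub-sample resolution); lift-off is the steepest descending slope in
  the release transition, ties resolved to the earliest sample.
  Spike detection timestamps each supra-threshold excursion at its
  local maximum, merging excursions separated by less than a dead time
  (default 1 ms).

## Step-cycle analysis

Cycles pair each touchdown with the unique lift-off before the next
touchdown; cycles with zero or multiple lift-offs are rejected and
logged. Cycles whose period exceeds mean + 5 SD are flagged as walking
pauses and excluded — the analysis targets continuous stepping
sequences, and no sharper pause criterion is implied by the data
structure. Period comparisons use Welch's two-sided *t*-test on
per-sequence mean periods (the averaging unit of the study design;
rank-sum available as an alternative), with the Welch–Satterthwaite
degrees of freedom. Step-triggered averaging min-max normalizes each
step's segment, resamples it by linear interpolation onto a fixed
phase grid, and averages across steps; a common grid is required
because steps have unequal lengths.

## Load-response scoring

The peristimulus time histogram uses half-open bins with one edge at
lag 0. Response magnitude is the post-stimulus 150 ms envelope maximum
normalized to the mean maximum over control stimulations (controls:
stimuli with no touchdown within ±1 mean period). The Michelson
contrast is (post − pre)/(post + pre) over 100 ms windows, positive for
an increase after the stimulus; 0/0 is defined as 0 (a silent trace
shows no response). Classification thresholds are ±0.5 on the
contrast: retractor contrast ≥ 0.5 → RET_ACT; protractor contrast
≥ 0.5 with retractor contrast ≤ −0.5 → PRO_ACT; otherwise NONE. The
thresholds sit halfway between the noise-driven contrast (≈0) and the
transient-driven contrast (≳0.67 in magnitude after smoothing) and are
exposed as parameters. Phase-preference testing of a response class
requires at least 8 phased responses.

## Circular statistics

Weighted mean vector: R e^{iθ̄} = Σw e^{iθ}/Σw; spikes are weighted
equally, so an experiment's vector reflects its full spike count. The
Rayleigh p uses the second-order series approximation
p = e^{−Z}[1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)],
Z = nR², accurate to well under the 0.003–0.008 empirical type-I band
at α = 0.005 for n ≥ ~10; below n = 4 a seeded Monte-Carlo uniform
null (9999 draws) replaces the series. R < 10⁻¹² flags the mean
direction as undefined (NaN). Phase histograms use half-open bins
[k/n, (k+1)/n) and conserve total weight exactly.

## Rhythm analysis

Bursts are maximal spike runs with inter-spike intervals ≤ 0.2 s and at
least 3 spikes (both configurable; no criterion is dictated by the
phenomenon, these defaults separate the 0.27–1.16 Hz burst regimes from
tonic activity). Cycle frequency is the inverse mean inter-onset
interval restricted to the queried time window — robust below ten
cycles, where spectral estimates are not. Quiet-vs-stepping frequency
comparisons are paired *t*-tests (per-animal design) by default.
Cross-correlation is lag-wise Pearson on the overlapping segments, so
values are bounded in [−1, 1] and scale-free; r(lag) = corr(A(t),
B(t + lag)).

## Problem sizes and tolerances

Recovery checks use the sizes at which their standard errors make the
targets sharp: 500 cycles per preset for period means (3 SE), 2000 for
SDs, 300 steps for phase peaks (±5°), 120 s records for rhythm
frequencies (3 SE of the inter-onset mean), 500 stimuli for class
fractions (3 binomial SE) and the no-response phase (±0.03 cycles),
100-replicate Monte-Carlo for test power, and 10⁴ replicates for the
Rayleigh type-I band. Determinism is enforced end to end: every
generator and every pipeline run is a pure function of (config, seed).

## Known limitations

- The outside-mode 3:1 tonic bias and the load-session transient
  amplitudes are conventions; only their signs/directions are
  constrained by the phenomena they emulate.
- The Rayleigh series approximation degrades for n < 10 with heavy
  weighting; the Monte-Carlo fallback covers only n < 4.
- Lift-off detection assumes a monotone release ramp; oscillatory
  release transients (incomplete lift-offs) would need the manual
  review the original tarsal-contact method relied on.
- `compare_periods` treats per-sequence means as exchangeable units;
  repeated sequences from one animal violate independence and would
  need a mixed model, which the package does not provide.
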