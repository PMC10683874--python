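# Methods

This note documents the models, parameter choices and numerical
conventions behind `cogmap`, and what the synthetic pipeline does and
does not establish about real recordings.

## The simulated preparation

**Arena.** A square virtual arena, side 100 cm, origin at the lower-left
corner, binned into 5-cm spatial bins (20×20 = 400 bins) for all rate
maps. Goal cues have a 10-cm-radius reward region. Goal placement keeps
the whole goal region inside the arena (goals ≥ 10 cm from walls): a
reward region protruding through a wall would be partly unreachable and
would bias every distance-to-goal statistic. All sizes are configurable
(`ArenaSpec`).

**Place-cell ensemble.** Each of ~100 units has an isotropic 2-D
Gaussian tuning curve

&nbsp;&nbsp;&nbsp;&nbsp;rate_i(x) = b_i + p_i · exp(−‖x − c_i‖² / 2σ_i²)

with centers uniform over the arena, widths σ ∈ [8, 15] cm, in-field
peaks p ∈ [10, 20] Hz (≈15 Hz typical) and baselines b ∈ [0.05, 0.5] Hz.
This is the simplest standard field model; it deliberately omits
direction/speed modulation, theta phase precession and multi-field
cells. Spikes are inhomogeneous Poisson at a 10-ms base bin, piecewise
constant within each 100-ms behavior tick.

**Running task.** The agent runs to a succession of goal cues placed
uniformly at random at least 30 cm away, with Ornstein–Uhlenbeck speed
(mean 15, SD 4 cm/s), partial heading correction toward the goal plus
20° per-tick heading noise, and a 2-s immobile reward dwell at each
goal. ~430 trials give a ≈40-min session; mean trial duration ≈5 s.

**LFP.** Phenomenological: a sinusoid whose instantaneous frequency is
7.3 Hz whenever treadmill speed exceeds 2 cm/s and 6.3 Hz otherwise
(intermittent ~1.5-s bouts during stillness, duty 0.6), plus 1/f
background noise. There is no spike–LFP coupling; the trace exists to
exercise the spectral analyses, not to model hippocampal dynamics.

**Intention agent.** The stand-in for the animal's volitional activity.
Given an intended location x*, each unit emits Poisson spikes at

&nbsp;&nbsp;&nbsp;&nbsp;λ_i = fidelity · gain · rPV_i(x*) + (1 − fidelity) · meanrate_i + floor

so `fidelity` = 1 reproduces the reference PV of the intended location
exactly and `fidelity` = 0 produces spatially uninformative activity at
the unit's session-mean rate. Policies: `toward_goal` / `hold_goal`
(intend the goal itself) and `random_walk` (goal-blind control). Real
animals are of course not a convex blend of two rate vectors; the knob
exists to make competence a controlled, sweepable variable.

## Decoding

**Windowed regressor.** Spike counts are binned at 100 ms; the decoder
input is the trailing 1.5-s window (units × 15 bins), and the target is
the *current* position at the window's trailing edge (no look-ahead).
Windows step every 100 ms, the interface's output cadence. The model is
a standardized two-hidden-layer MLP (256 + 256 ReLU units, Adam,
batch 256, 60 epochs, seed-deterministic) on the flattened window; the
train/validation split is a contiguous 80/20 block split, because
random splits leak between temporally overlapping windows. Training
data are expanded with two augmented copies per window: unit dropout
(p = 0.4 whole-row zeroing), multiplicative rate jitter
(counts × max(0, 1+ε), ε ~ N(0, 0.2), per unit per window), and
circular time shifts of up to ±2 bins. Augmentation is what buys noise
robustness; each component can be disabled.

The 1.5-s window is preferred over the 5-s alternative as the default:
five seconds of history always spans substantial movement in the
Running task, which makes the decoder systematically worse at the
stationary activity patterns that dominate closed-loop control (we
measured ~10 cm vs ~6 cm mean error on stationary rPV probes), and
triples cost.

**Bayesian MAP decoder.** The classical memoryless Poisson decoder over
the place-field map: log P(x|n) = log P(x) + Σ_i n_i log f_i(x) − τ Σ_i
f_i(x), computed in log space over unmasked bins, normalized with
log-sum-exp, uniform prior by default, rate floor 0.01 Hz to avoid
log 0, ties broken to the lowest row-major bin index. It serves as the
reference decoder in the robustness benchmark and is verified exactly
against brute-force enumeration in the tests.

**rPV maps.** Per unit per bin: spikes emitted in the bin ÷ occupancy,
with bins under 0.5 s occupancy masked. Smoothing (Gaussian σ = 5 cm) is
applied to the ratio after masking with mask-aware normalization, so
masked bins never bleed into neighbors; the unsmoothed ratio is kept so
the identity Σ_bins rate·occupancy = total spikes holds exactly.

**Noise-robustness benchmark.** One probe per unmasked bin: a window of
Poisson counts whose expectation equals rPV(bin)·bin_s in every window
bin (an emitted spike-count rendering of "inputting the rPV"; feeding
raw non-integer expectations is far off the count manifold both
decoders operate on and is not a realizable input). Corruption at level
ν: unit dropout with probability ν plus multiplicative jitter with SD
ν, over ν ∈ {0, 0.25, 0.5, 0.75, 0.9}. Error is mean distance from the
probed bin center over bins and 3 repeats.

Measured behavior at study scale: the Bayesian decoder is essentially
exact on clean probes (≈0.3 cm — the probes are drawn from its own
generative model) and degrades steeply under corruption (≈34 cm at
ν = 0.9); the augmented regressor starts at ≈6 cm and degrades
gracefully (≈22 cm at ν = 0.9), overtaking the Bayesian decoder at
heavy corruption. The regressor's ≈6-cm clean-probe floor slightly
exceeds one 5-cm spatial bin; it equals the regressor's intrinsic mean
decoding error and is a generalization limit of 40 min of training
data, not a capacity limit (wider/deeper nets overfit — ~1 cm train vs
~5 cm validation median — and neither longer training, stronger L2, a
classification head, nor seed-ensembling moves it).

## Closed loop

Each 100-ms tick: the agent picks its intended location by policy →
emits spikes → the decoder consumes the trailing window (zero-padded at
session start) → a causal trailing moving average smooths the output
(3 s Jumper, 2 s Jedi) → the avatar teleports to the smoothed position
(Jumper; a rate-limited rule is available) or the object takes it
(Jedi). Jumper trials end on entry into the goal region or at 62 s;
goals re-place uniformly ≥ 30 cm away. Jedi fixes the agent at the
arena center, accrues reward at 0.01 mL/s while the object touches the
goal region, ends trials at 0.5 mL or 3 min, and jumps goals ≥ 40 cm.
The Jedi reward flow rate is a declared choice (only the cap and limit
are inherent to the task). Jedi treadmill motion is emulated as rare
2-s movement bouts on a still background, and body heading relaxes
toward the goal bearing with noise — these exist so that immobility
segmentation and the >12°/s rotation exclusion have realistic data to
act on.

## Statistics

**Unit-identity shuffle (spatial specificity).** Whole spike trains are
reassigned to unit identities by a uniform random permutation (identity
permutation included), the shuffled raster is re-decoded with the
original model, and the smoothed stream is replayed offline against the
original goal sequence: walk the stream, find the first entry into each
goal region in order, censor each goal at the 62-s timeout (advancing
the pointer by the timeout on a miss). The observed statistic is the
actual closed-loop mean trial duration. One-sided p, observed < null.

**Goal shuffle (goal-directedness).** Per-trial decoded paths are kept;
goals are re-drawn from the same placement rule as the task (uniform
with the task's minimum-jump constraint and wall margin — matching the
true goal distribution keeps the null exchangeable for a goal-blind
agent). Metrics: first-entry time (Jumper) or time-averaged distance to
goal (Jedi).

Empirical p-values use the add-one rule, (1 + #extreme)/(1 + N), and
are never zero; a normal-approximation p from the shuffle mean/SD is
reported alongside, since astronomically small tail probabilities are
not resolvable with a few hundred shuffles.

**PBE detection.** Summed counts across units at 10 ms are Gaussian-
smoothed (σ = 10 ms) and z-scored; events peak at z ≥ 3, extend to
z = 0, last 50–500 ms, and require mean speed ≤ 5 cm/s. "Removal"
replaces in-event counts with each unit's session-mean count per bin
(zeroing available) before re-decoding; replacement keeps the window
statistics inside the decoder's training range. All thresholds are
parameters, not claims about the true physiological definition.

**Spectra.** Welch PSD with 4-s Hann windows and 50% overlap (0.25-Hz
resolution), computed per analysis segment and averaged with
window-count weights so no window spans a gap; traces are z-scored
first. Wavelet spectrograms use complex Morlet (width 7) on a log grid,
with power scale-normalized so a pure tone peaks at its own frequency.

## Determinism

Every generator and fit takes an explicit seed; the pipeline derives
per-stage seeds as blake2s(master ‖ stage) mod 2³¹. Two runs of the
orchestrated experiment with one master seed produce byte-identical
summary JSON on the same platform.

## Problem sizes

The default study condition is 100 units / ~40 min of Running data —
training takes ~3 min on one CPU. The test suite trains that condition
once and shares it; structural tests run on a 10-unit/~1.5-min fixture,
map-recovery tests on a 40-unit/~13-min session. The goal-blind
calibration uses 20 seeds of 4×60-s Jedi trials.

## What passing tests show — and what they don't

The synthetic generator realizes exactly the assumptions the analyses
test for: Gaussian fields, Poisson spiking, an agent that literally
emits scaled rPVs. Green tests therefore demonstrate that the machinery
is correct and the logic of the claims is sound (e.g., shuffles destroy
exactly the structure they should), not that real CA1 data behave this
way. In particular, real PV variability is super-Poisson and the real
decoder-vs-Bayesian comparison depends on noise structure we do not
model; the clean-probe Bayesian advantage here (probes drawn from its
own model) is an artifact of that idealization.
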