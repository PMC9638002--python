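# Methods

This note documents the models, conventions, and design choices behind
each analysis stage, what the synthetic-session generator does and does
not emulate, and the numerical details a user would need to reproduce or
modify the pipeline.

## Session model and conventions

All analysis runs on the electrophysiology clock, in seconds; video frames
are mapped onto it once by `io_core.align_sync`.  Every time window is
half-open `[start, end)`.  An event block carries five anchors —
baseline start, stimulus presentation, first physical contact, event end
(stimulus removal), post end — with 5-min baseline, event, and post spans
by default.  Binned firing rates drop a trailing partial bin; this loses
at most one bin of data and keeps all bins identically distributed.

Sessions are stored as plain directories of TSV/array files so fixtures
remain inspectable and language-agnostic.  Floats are written with 17
significant digits and read back with round-trip parsing, making the
write/read cycle lossless.

### Synchronization

The camera emits a 5-V pulse on a random 80% of frames; the recording
system timestamps the received pulses.  After verifying that the sent and
received pulse trains match in count, pulse-emitting frames take their
received times directly and the remaining frames are linearly interpolated
in frame index (extrapolated at the ends at the locally implied frame
period).  With all pulses sent the mapping is exact for any monotone clock
relation; under the 80% regime the error is bounded by the clock's
deviation from linearity across one inter-pulse gap — far below one frame
period for realistic drift (the recovery benchmark measures ~1e-11 s at
1e-4 fractional drift).

### Unit quality control

Only the refractory criterion operates at this package's input boundary
(sorted spike times): the fraction of inter-spike intervals shorter than
2 ms must stay below 0.1%.  Amplitude and noise criteria belong to spike
sorting, upstream of this package.

## Response scoring

auROC is computed by the rank-sum identity with midrank ties,
`auROC = (R_event − n_e(n_e+1)/2) / (n_e n_b)`, which equals brute-force
pair counting with half credit for ties (the test suite verifies equality
to 1e-12 against an O(n·m) oracle).  The 50-spike floor is applied to the
*pooled* baseline+event spike count; the per-period reading is available
via configuration but pooled is the default because the criterion is a
single guard against unscorable low-rate units.

Categorization counts per-class average scores above +0.2: exactly one →
event-specific; several spanning the social (male/female) and non-social
(toy/food) divide → panresponsive; several on one side → multimodal_social
or multimodal_nonsocial; none above +0.2 but at least one below −0.2 →
decreased; otherwise nonresponsive.  Multimodal units count as responsive
for population vectors.

## Temporal dynamics

z-scored PSTHs use the event's own baseline binned at the *same* bin
width as the trace, so the z-scale is comparable across bin widths; the
baseline SD is floored at 0.1 Hz to keep z finite for baseline-silent
units.  Time-warping resamples the three segments
(pre-presentation, presentation→contact, contact→end) by cubic spline to
fixed lengths (50/100/50 samples by default — the common frame's segment
lengths are a display choice, not a measurement); anchor values are
preserved exactly, and all quantification uses the raw unwarped traces.

Latency to peak is the argmax of the 100-ms z trace between presentation
and contact, ties broken earliest — deterministic and assumption-free.
Onset synchrony compares |latency_i − latency_j| for unit pairs within an
event against the same pairs across different events with a two-sample KS
test; shared per-trial onsets make the within-event set stochastically
smaller.

A unit/event shows an *aftereffect* when its mean 10-s-bin z over the
3 minutes after stimulus removal exceeds 1.  The paper-level phrasing
admits either a per-bin-proportion or per-unit-mean reading; the mean was
chosen as the unit-level flag because it is monotone in the decay integral
and robust to single-bin noise.  A unit's overall flag is the majority
vote over the events it responded to (score > 0.2).  For a τ = 120 s decay
from gain g, the expected mean z over 180 s is
`√(10·r)·(g−1)·(τ/180)(1−e^{−180/τ}) ≈ 0.52·√(10r)(g−1)`, comfortably
above 1 for the generator's rates — which is why detection saturates near
100% and the recovered proportion tracks the injected one.

## Behavior

Cleaning thresholds likelihoods at 0.999 (experimenter-colored parts:
tailbase and ears) and 0.9 (others), removes inter-frame jumps > 30 arena
units as anatomically impossible, and interpolates linearly.  The 30
features comprise, per agent: head and tailbase velocity, spine length,
head angular velocity, 1-s-lagged tailbase velocity; between agents:
same-part distances (head, tailbase, nape, back), cross head↔tailbase
distances, head-direction angles from each head to the other's four
parts, head-angle difference, head-head minus head-tail distance,
head-direction difference, and 1-s rolling correlations of head and
tailbase coordinates.  The precise body-part pairing of the distance
features is configurable; the set above is the implemented default.

The classifier is an RBF support-vector machine on standardized features
with both 5-fold and leave-one-recording-out cross-validation.  Bout
post-processing merges same-label runs separated by less than 0.25 s
(whatever the interleaved labels — by construction such a stretch is
shorter than 8 frames at 30 Hz) and then deletes bouts shorter than 5
frames; merge-before-delete preserves fragmented long bouts, and the
operation is idempotent because any short run flanked by one label is
absorbed during the merge pass.

The toy-contact threshold is the inter-individual distance maximizing
balanced accuracy of contact vs non-contact on the social frames (the
reference implementation's "optimal threshold" left the objective
unstated; balanced accuracy is insensitive to class imbalance).  Food
interaction is a point-in-polygon test of the head against the eating
ROI.

Speed correlation bins firing at 50 ms, z-scores rate and speed, and
compares the cross-correlation at lag 0 with the mean over lags −20…−10 s.
Because slow speed fluctuations make that difference fluctuate far more
than the lag-to-lag scatter of the far window, the "none" band is
calibrated by circular shifts of the rate vector (24 shifts spanning
20–80% of the epoch), which destroy alignment while preserving both
autocorrelation structures; the class is "none" within ±2 calibrated SDs.

## Decoding

All decoders are LDA with the least-squares solver and Ledoit–Wolf
shrinkage — required because responsive units routinely outnumber events —
on standardized features, with uniform class priors: the event design is
balanced, and frequency priors would bias leave-one-out folds against the
held-out class (the held-out event's class is underrepresented in
training by construction).  Shuffle controls rerun the identical protocol
on permuted labels (500 permutations by default).  The neuron-dropping
curve redraws random unit subsets per size; category omission compares
the all-but-category decoder against size-matched random-subset controls.
Note that leave-one-out under label permutation is exactly at chance only
asymptotically; with very few events or near-duplicate feature rows it
acquires a small finite-sample bias, which is why chance-level assertions
use sessions with ≥ 16 events.

## Connectivity

CCG counts (target − projection) lags in 0.25-ms bins over ±50 ms.  Noise
mean and SD come from the bins with |lag| ∈ (5, 50] ms — outside the
putative synaptic window, ample mass (360 bins).  Peak detection uses
`scipy.signal.find_peaks` with height = mean + 3 SD, prominence = 3 SD
(the *increase* must exceed 3 SD, not just the absolute count), and width
≥ 0.75 ms at half prominence; a detection is kept only when the peak lag
is strictly positive, the left half-prominence crossing is ≥ 0 ms, both
units fired ≥ 100 spikes, and the peak bin holds ≥ 20 counts (the
20-spike rule is read as single-bin height; the integrated-count reading
is available via configuration).  Ties break by height, then smaller lag.
A zero-lag peak is rejected by the lag rule.

Connection strength divides the number of distinct target spikes falling
inside the peak's half-prominence lag extent (relative to any projection
spike) by the target's total spikes in the epoch; epoch-wise analyses
re-detect significance per epoch with the same criteria, so shorter
epochs carry proportionally larger noise SDs.  Category-pair enrichment
compares observed counts against 1,000 shuffles of the category labels
over the pooled projection+target node slots — the chance model in which
the same neurons are wired at random.

False positives of the 3-SD rule are rate-dependent: a noise bin can only
reach the 20-count floor when the rate product is high
(`r_p·r_t·T·0.25 ms ≳ 10`).  The detection benchmark therefore models the
recorded population's rate structure — high-rate (5–8 Hz,
interneuron-like) projection units, low-rate (1–3 Hz) targets — and wires
couplings node-disjointly, since chains and common input would themselves
induce real short-latency correlations.

## Waveforms

Trough-to-peak delay is measured on the peak-amplitude channel: global
minimum to the following maximum; a waveform whose dominant deflection is
positive and precedes the trough is inverted → irregular, excluded from
typing.  2-means on standardized (delay, baseline rate) with 10 restarts;
the longer-delay cluster is putative pyramidal.

Cross-day matching peak-normalizes each heatmap, centers it on its
peak-amplitude channel, and compares candidates within ±5 probe channels
by SSIM (best over ±1-channel shifts, absorbing off-by-one centering
under noise) with mean Pearson correlation over signal-bearing channels
(≥ 20% of max amplitude) as tie-breaker.  Acceptance requires SSIM ≥ 0.8
and correlation ≥ 0.9 — thresholds calibrated on the null distribution of
unrelated-unit pairs (95th percentiles ≈ 0.69 / 0.94), where they admit
0/600 unrelated pairs while accepting 600/600 true pairs at SNR 10;
assignment is greedy one-to-one by descending SSIM.  SNR here is the
conventional RMS(signal)/RMS(noise) of the heatmap.

## The synthetic generator

The generator emulates exactly the statistical structure the analyses
assume, no more:

- **Rates.**  Inhomogeneous Poisson with λ(t) = baseline × gain(t);
  baselines log-normal (median 0.5 spikes/s, log-SD 0.5; panresponsive
  median 2 spikes/s).  Event gain is uniform 3–6× (or fixed), applied from
  a per-trial common onset drawn uniformly between presentation and
  contact, with ±0.5 s per-unit jitter — the shared-onset structure the
  synchrony analysis must detect.  Decreased units use gain 1/g on one
  random class.  Panresponsive units add 3×, 2-s transients at
  presentation and removal.  Aftereffects multiply the post period by
  1 + (g−1)e^{−t/τ} (τ = 120 s), truncated at the block end, for an
  *exact* 30% of responsive units — the proportion is a population
  parameter of the design, not a per-unit coin flip, so recovered
  proportions estimate the detector rather than a binomial draw.
- **Coupling.**  Each projection spike triggers a target spike at
  +delay ± uniform jitter with the transfer probability; duplicates
  within 0.05 ms are dropped.  The generator's default jitter half-width
  is 0.5 ms, giving ~1-ms-wide CCG peaks like real monosynaptic pairs; a
  ±0.25 ms spread would occupy only two 0.25-ms bins and no 0.75-ms-wide
  peak criterion could ever accept it.
- **Sync.**  Frames at 30 Hz on the camera clock; the ephys clock runs at
  (1 + drift) with an offset; pulses on a random 80% of frames.
- **Behavior.**  Two agents in a 100×70 arena; each of the 7 labels is
  scripted kinematically (head-head: facing snout contact; approach:
  implanted closes from ≥ 40 units toward a stationary conspecific and
  stops short of contact range; following: aligned headings at
  greater-than-head distance; conspecific-contact: conspecific's snout at
  the implanted's flank while it faces away; …), with 10 body parts per
  agent on rigid-ish skeletons, coordinate noise, and i.i.d. low-likelihood
  dropouts.
- **Waveform cohorts.**  Extracellular-like templates (pre-trough bump,
  sharp trough, slower afterpeak, slow tail) with asymmetric spatial decay,
  dipole-inverted far field, and per-channel propagation tilt; day 2
  repeats each template with ≤ 2 channels of drift and additive noise.

What it does **not** emulate: oscillations and spike-train
autocorrelation structure beyond Poisson, rate drift and representational
drift, behavior-locked firing outside the injected gain windows, probe
geometry beyond a linear depth coordinate, and real pose-estimation error
structure (correlated dropouts, identity swaps).  Passing tests therefore
demonstrate correct recovery of the injected structure under the stated
noise model — they do not certify performance on pathologies the
generator omits.

## Problem sizes and determinism

The recovery benchmarks (package `ethospike.validation`, used by both the
test suite and `scripts/acceptance.py`) run at sizes chosen to make each
statistical claim well-resolved on a single CPU: 200 units for category
recovery, 50 units/20 couplings plus 1,000 independent pairs for
connectivity, 16-event gain-5 sessions with 500 label shuffles for
decoding, 100 responsive units for aftereffects, 4 minutes of balanced
scripted behavior for the classifier, and 100-unit cohorts for matching.
Every source of randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give bit-identical sessions
and results.
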