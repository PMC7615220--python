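# Methods

This note documents the models, estimators, defaults, and design choices
behind each `galpop` stage, and what the synthetic-data tests do and do
not establish about real recordings.

## Synthetic data model

The generators exist to make every downstream estimator testable against
planted ground truth.  They emulate the *structure* of the study's
recordings, not their biophysics.

**Calcium sessions** (`synthgen.generate_population_session`).  A session
is a neuron × time matrix at 20 Hz (default; the real recording rate is a
config field) over a 600 s assay.  Each trace is Gaussian noise
(`noise_sd`, default 0.1 fluorescence units) plus calcium transients
modeled as an instantaneous rise with single-exponential decay
(`calcium_decay_tau` = 1.5 s).  A rise time is deliberately omitted: the
latency analyses only require that transient *onsets* be well defined,
and a single-exponential kernel keeps amplitude arithmetic analytic for
oracle tests.

* A fraction `silent_fraction` of neurons, chosen by a seeded shuffle
  (never the first k indices, to avoid order artifacts in clustering
  tests), emits nothing but noise.
* Active neurons emit spontaneous transients at `spontaneous_rate`
  (events/min).  Event times follow a renewal process with an exponential
  gap shifted by a 4 s dead time, so the mean rate equals the nominal
  rate exactly while consecutive transients remain individually
  resolvable at the default decay constant — a plain Poisson process
  would overlap transients near the detection threshold and bias rate
  recovery tests for reasons unrelated to the estimator.
* Stimulus bouts (default 8 per stimulus, 2 s long, 6–10 s random gaps)
  are laid out sequentially; a session too short for the requested bouts
  raises a capacity error.  At every bout of a stimulus with a positive
  tuning-matrix entry, an active neuron emits an evoked transient whose
  amplitude is lognormal around that entry with CV 0.3 (nonnegative,
  realistic spread, exact in expectation) and whose onset lags the bout
  by a truncated-normal latency (mean `response_latency_mean`, SD 20% of
  the mean, floored at 0).
* Every stochastic draw that a downstream stage estimates — silent flags,
  evoked amplitudes and latencies, spontaneous times — is stored in the
  event table's `ground_truth`.

**Ethograms** (`synthgen.generate_ethogram`).  Bout labels follow a
Markov chain with a user-supplied row-stochastic matrix; dwell times are
exponential (per-behavior means); bouts abut.  Consecutive identical
labels are merged, so recovery tests should plant zero-diagonal matrices
(with self-transition mass, the estimable quantity is the conditional
transition matrix given a state change).

**Patch recordings** (`synthgen.generate_patch_record`).  Voltage is
Gaussian noise (0.5 mV) around the true resting potential at 20 kHz.
Spikes are triangular: a linear rise from threshold (resting + 20 mV) to
the peak over half the base and a symmetric fall, so the width at half
amplitude equals exactly half the base — an analytic half-width for
oracle tests.  Baseline spike times follow the same dead-time renewal
construction (5 ms dead time).  Current steps appended after the baseline
period depolarize the trace proportionally to the injected current and
add regularly spaced evoked spikes at a rate growing with current; steps
at or above `depol_block_current` instead produce a spike-free plateau
(default −25 mV).  The voltage-clamp current trace carries PSC events
(instant rise, 5 ms exponential decay, lognormal amplitudes around 20 pA)
whose sign is EPSC (negative) with probability `epsc_fraction`.

**State presets.**  `vir_like_population` / `d18_like_population` (and
the ethogram analogues) encode the qualitative state contrast as
generator parameters: the late-pregnancy-like preset has a higher silent
fraction (0.55 vs 0.2), lower spontaneous rate (1 vs 2 /min), fewer
retrieval-responsive neurons (30% vs 70%), stronger and more selective
pup tuning (3.0 vs 1.5 fluorescence units, non-pup stimuli weakened),
and shorter evoked latency (0.4 vs 1.0 s).  The behavioral presets put
transition mass on retrieve→crouch→nest-build chains (late pregnancy)
versus sniff→groom→nest-enter cycles (virgin).  These magnitudes are
choices, not measurements; what the directional tests establish is that
the *pipeline* recovers the planted ordering (fewer detected neurons,
lower activated fraction, shorter latency, higher selectivity, higher
separability), not that real populations behave this way.

### What the generators do not emulate

No source-extraction artifacts, neuropil contamination, motion, rise
kinetics, bleaching, cross-session registration error, burst firing,
channel kinetics, or pharmacology.  Passing recovery tests therefore
demonstrates estimator correctness under the stated noise model, not
robustness to all failure modes of real data.

## Event-aligned analysis (`evoked`)

**Z-scoring.**  Per neuron, (x − μ)/σ over baseline samples; the default
baseline is all samples outside any event window ± 2 s.  Neurons with
zero baseline SD are flagged constant with Z ≡ 0 rather than raising.
Z-scoring is idempotent to float precision.

**Transient detection.**  A transient is a run above μ + kσ (k = 3;
median/MAD-based on raw traces so transients do not inflate σ) lasting
≥ 0.2 s.  Two practical refinements: runs separated by ≤ 0.1 s are
bridged before the duration criterion (noise dips inside one transient),
and surviving events within 1 s of the previous event's end are absorbed
into it (re-crossings during the slow decay through the threshold would
otherwise double-count).  A neuron is *detected* (non-silent) if it has
at least one transient.

**Alignment.**  Windows of −2 … +5 s around bout onsets; events whose
window leaves the recording are dropped and counted.  Evoked amplitude =
mean Z over the response window (0–3 s) − mean Z over the pre-onset
baseline window.

**Activation test.**  Per-event differences (response-window mean −
baseline-window mean) enter a one-sided sign-permutation test: all 2^n
sign patterns when n ≤ 14 events, otherwise 10,000 seeded random
patterns.  Activated requires p < α (0.05) *and* a mean effect
≥ 0.5 Z.  The exact-enumeration branch makes the test conservative and
deterministic; note its granularity — with fewer than 5 events the
smallest attainable p is 1/16 > 0.05, so activation needs ≥ 5 bouts at
the default α.  Fewer than 3 events is reported as indeterminate.

**Onset latency.**  First post-onset time at which the mean aligned
trace holds ≥ 1 Z for ≥ 0.25 s contiguously; none if never.

**Clustering.**  Activated neurons' mean traces are unit-normalized and
clustered agglomeratively (correlation distance, average linkage).  When
the cluster count is not given it maximizes the silhouette over
2 … min(8, n−1).  Clusters are relabeled by ascending mean onset (ties by
smallest member id), neurons within a cluster ordered by onset then id,
which makes the display order invariant to input permutation.

**Activated fraction.**  Numerator: neurons passing the activation test;
denominator: detected (non-silent) neurons in that session — not all
recorded ROIs — so the fraction is well defined per session and matches
the detected-count notion used elsewhere.

## Tuning and selectivity (`tuning`)

The tuning index uses *rectified* window means (negative Z clipped to 0):
TI = (μ_resp − μ_base)/(μ_resp + μ_base + 1e-9), bounded in [−1, 1],
symmetric, and monotone in evoked amplitude.  The 1e-9 guards 0/0; a
neuron with no baseline activity and any positive response maps to
TI = 1.  The normalized variant is a min–max rescaling across the
session's neurons (rank-preserving; constant input maps to 0.5).

The selectivity score rectifies the two evoked amplitudes before the
ratio A_a/(A_a + A_b); both-zero maps to 0.5 (non-selective).
Rectification keeps the score in [0, 1] and gives suppressed neurons the
same anchor semantics as unresponsive ones.  The score satisfies
S(a,b) + S(b,a) = 1 identically and is invariant to positive rescaling
of the traces (property-tested).

Baseline activity is the detected-transient rate over event-free time,
undefined below 60 s of usable time.  The tuning-vs-baseline relation is
ordinary least squares on the normalized quantities; group-aware
(per-animal) inference is out of scope and flagged as such — the
regression here is the within-session descriptive fit.

## Separability (`separability`)

A sample is one (neuron, bout); its features are that neuron's mean Z in
consecutive temporal bins (default 0.5 s) over the bout-aligned window
(default 0–4 s).  This gives LDA a sample population while keeping the
features purely temporal.  The alternative reading — population vectors
per time bin as samples, one feature per neuron —
is available as `sample_mode="population_bins"` and is the right choice
for antisymmetric codes in which which-neuron-fires carries the stimulus
identity: a code in which half the neurons prefer each stimulus is
provably invisible to per-neuron samples (the class-conditional mixtures
coincide) but perfectly separable from population vectors; the test
suite demonstrates both regimes.  Separability is normally computed on
the detected-neuron subset (`evoked.select_detected`).

LDA uses the eigen solver with within-class scatter shrunk toward its
diagonal (Ledoit–Wolf `"auto"` by default, float override available),
keeping the fit well-posed when samples are scarce; each projection
axis's sign is fixed by making its largest-magnitude loading positive so
embeddings are fully deterministic.  The unsupervised partition is
k-means with k = number of stimuli, 50 restarts, fixed seed.  The Rand
index between that partition and the bout-stimulus labels is computed
from the contingency table and verified exhaustively against direct pair
enumeration.  Confidence ellipsoids are
{x : (x−μ)ᵀΣ⁻¹(x−μ) ≤ χ²_d(level)} per stimulus class, with a small
ridge on singular covariances.

## Behavioral statistics (`ethogram`)

Transition matrices are bout-level: consecutive identical labels merge
first, so self-transitions are structurally impossible and each row with
outgoing transitions is a probability vector (invariant-checked).  The
behavior universe defaults to the labels observed in the table; a
min-count filter is available but off by default.  Group comparisons run
a two-sided Mann–Whitney U test per edge on per-animal probabilities —
exact null when both groups have ≤ 8 animals (falling back to the
tie-corrected normal approximation under ties), flagged at raw p < 0.05.
No multiple-testing correction is applied by default; a
Benjamini–Hochberg switch exists but is off, matching the
raw-threshold edge-flagging convention.  Edges absent in every animal of
both groups are skipped and listed.

Retrieval latency is the onset of the first retrieval bout,
right-censored at assay end (default 600 s, configurable).  Survival
curves are Kaplan–Meier product-limit estimates with a log-rank test
across groups (delegated to lifelines); with no censoring the estimate
reduces exactly to the empirical survival function, which the tests
assert.

## Intracellular features (`ephys`)

Spike detection: upward crossings of an absolute threshold, default the
baseline voltage mode + 20 mV (mode from a 0.5 mV histogram — robust to
spikes and to resting-potential differences between groups), separated
by ≥ 2 ms.  The mode-relative default makes detection invariant to DC
offsets.  Baseline firing = count/window; resting potential = median
voltage with spikes masked ± 5 ms; *silent* means < 0.05 Hz over the
baseline window (no printed cutoff exists for this classification; the
threshold is explicit config).  AP half-width is the median per-spike
width at half amplitude between threshold and peak, with sub-sample
linear interpolation at the edges; clipped spikes are excluded with a
warning.

Depolarization block is this package's operationalization of the
"spiking collapses while the membrane stays depolarized" phenotype:
scanning steps in increasing current order, block is declared at the
first step whose spike count falls below 50% of the maximum over lower
steps while its mean voltage exceeds the spiking steps' mean by ≥ 5 mV;
cells in which no step elicits ≥ 2 spikes are reported indeterminate.

PSC detection: deflections of the current trace beyond a threshold
(default 5 pA) over the trace median, for at least 0.3 ms (rejects
single-sample noise), merged within half the decay-fit window; sign
assigns EPSC (negative at the configured holding potential, a convention
recorded in the output) versus IPSC.  An optional log-linear decay fit
discards events with time constants outside configurable bounds.

## Numerical and scope notes

* All generators are pure functions of their config including the seed;
  identical configs give bit-identical output.
* Problem sizes in the test suite (60–100 neurons, 300–600 s sessions,
  20-seed recovery loops, 500-replicate power/calibration runs) were
  chosen as the smallest sizes at which the statistical claims are
  meaningful — binomial/Poisson standard errors small enough to detect
  estimator bias, ≥ 19/20 directional criteria well above chance.
* Out of scope by design: raw-movie source extraction, spike
  deconvolution, cross-session neuron registration, mixed-effects
  estimation (delegated and labeled), conductance-level modeling, and
  morphological image analysis; spine density exists only as a numeric
  field in synthetic fixtures.
* Group labels for pharmacology (e.g. Tertiapin-Q) and receptor-knockout
  conditions are plain metadata; no mechanism is modeled.
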