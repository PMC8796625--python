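# Methods

This note documents the models, estimators, numerical choices and known
limitations of `ethoseq`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Switching-AR model of pose dynamics

Pose features are modeled as a K-state autoregressive HMM: a hidden Markov
chain `z_t` with row-stochastic transition matrix, and state-conditional
linear-Gaussian dynamics
`x_t = b_k + Σ_l A^(k)_l x_{t−l} + ε_t`, `ε_t ~ N(0, Σ_k)`.
Defaults follow the study design this pipeline reproduces: 30 fps,
20-minute sessions, 15 PCA dimensions, K = 15 states, R = 8 ensemble fits,
44 consensus syllables. The AR order L is not pinned down by the design;
the default is L = 1 (the minimal switching-dynamics model) and it is
configurable everywhere.

### Acquisition gaps

Recordings arrive in ~20 s blocks separated by 1–2 s storage gaps. The
generator's state chain runs continuously through gaps (a gap interrupts
storage, not behavior) while gap observations are emitted but masked.
All inference and statistics treat gaps conservatively: the likelihood
factorizes over contiguous valid blocks, each block restarts from the
initial distribution, and no bout or transition is ever counted across a
gap. With L = 1 this discards one conditioning frame per block
(~1 frame in 600 at the default gap geometry).

### Fitting

The fitter is expectation-maximization (Baum–Welch with AR-Gaussian
emissions), chosen for exact seed-reproducibility; the per-iteration total
log-likelihood is non-decreasing and fitting stops at a relative
improvement below `tol = 1e-4` ("equilibrium") or `max_iter = 200`.
Initialization is k-means (seeded, `n_init = 3`) on lag-stacked scores,
which avoids symmetric stagnation. M-steps use ridge-stabilized weighted
least squares (`ridge = 1e-8`) and covariance regularization
(`cov_reg = 1e-6·I`) so innovation covariances stay positive definite. A
state that loses essentially all responsibility (fewer expected frames
than its parameter count) triggers a re-seeded restart, logged; three
failures abort. Decoding is Viterbi per valid block (ties broken toward
the lowest state index, for determinism); the first L frames of a block
inherit the block's first decoded label, and blocks shorter than L+1
frames fall back to emission-only argmax under each state's stationary
observation distribution (logged).

Forward–backward and Viterbi inner loops are numba-compiled; all
randomness is drawn from numpy Generators outside the compiled code, so a
seed fully determines a fit.

## Ensemble consensus

Each valid frame's R-tuple of per-fit state labels is its signature.
Unique signatures are clustered with WPGMA (scipy's `weighted` linkage) on
normalized Hamming distance — each fit weighted equally, matching the view
of the R fits as exchangeable replicates. Design points the source design
leaves open, and how they are resolved here:

* **Distance**: normalized Hamming (positions differing / R). Any
  per-fit label permutation leaves the metric's geometry unchanged, which
  is the property that matters, since fits label states arbitrarily.
* **Weighting**: unique signatures enter the default clustering
  unweighted by frame count (clustering the deduplicated catalog); a
  count-weighted UPGMA variant (initial leaf weights = frame counts) is
  available via `count_weighted=True`.
* **The fixed-count cut**: the study's manual 44-way split is automated
  as `fcluster(..., maxclust)` on the WPGMA tree, with the dendrogram
  exported (Newick + merge-height CSV) for review. Reproducibility is
  preferred over curation; cuts are nested, so raising the cluster count
  only splits clusters.
* **Ordering**: syllables are re-indexed by descending total frame count,
  so syllable 0 is always the most-used motif.
* Catalogs larger than `max_signatures` (default 30,000) abort with an
  instruction to subsample rare signatures; unseen signatures (frozen map,
  new data) fall back to the nearest catalogued signature and are logged.

## Syllable statistics and genotype comparison

Per animal × syllable: frequency = bouts per minute of valid recording
("per minute of mouse activity" is read as valid recorded time — no
immobility-exclusion rule is specified anywhere); mean length = mean bout
duration (missing for unused syllables); proportion = % of valid time.
On gap-free data `frequency × mean_length = 0.6 × proportion` holds to
float precision and is asserted in tests; with gaps the deviation is
bounded by (gap-truncated bouts × frame time)/total time.

Group comparison is a Kruskal–Wallis omnibus per syllable × metric,
followed by Dunn's pairwise z-tests on pooled tie-corrected ranks
(`z = (R̄_i − R̄_j)/√((N(N+1)/12 − C)(1/n_i + 1/n_j))`,
`C = Σ(t³−t)/(12(N−1))`), two-sided normal p-values, flagged at
α = 0.05 when the omnibus also passes. No correction across syllables is
applied by default (per-syllable p < 0.05 is the reported convention);
Benjamini–Hochberg and friends are available via `p_adjust`. The
operating characteristics under the synthetic generator — type-I rate
within [0.02, 0.09] at α = 0.05 and ≥ 80% power for a halved-occupancy
effect at 6 vs 6 animals × 2 min — are measured, not assumed, in
`tests/test_acceptance.py`.

Transition networks pool transitions per genotype (matching per-genotype
network figures); consecutive distinct syllables form a directed edge,
weights are % of all transitions (summing to 100 before thresholding),
self-edges are structurally impossible, and edges below 0.01% are
excluded from export but kept in the returned matrix. Per-animal graphs
can be built by passing single-session lists.

## Synthetic cohorts

`build_demo_model` constructs well-separated states: state k is a damped
rotation (decay 0.9, distinct angles) around a distinct stationary mean
(radius 3.0) with isotropic innovations (SD 0.3), under a sticky
transition matrix (self-probability 0.95 → mean dwell ≈ 0.67 s at 30 fps,
a realistic syllable duration). Genotype effects scale the transition
matrix's columns for target states and re-normalize rows;
`multiplier_for_occupancy` inverts the resulting stationary-occupancy map
by bisection so an effect like "occupancy halved" is exact. Effects that
make a state numerically unreachable are rejected. Warm-up frames are
drawn from the initial state's stationary observation distribution
(discrete Lyapunov solution).

What the generator does *not* emulate: real pose features are
non-Gaussian and non-stationary within syllables, syllable dwell times
are not geometric, and tracking artifacts are absent (masks expose the
same interface without modeling artifact statistics). Passing recovery
tests therefore demonstrates correctness of the inference machinery, not
performance on real depth-video data.

## Synthetic EEG and the fast-ripple detector

Background is Gaussian noise shaped to a 1/f amplitude spectrum, low-
passed at the 2 kHz acquisition antialias filter and scaled to a target
SD (default 30 µV); nothing in the source design constrains the noise
model beyond plausibility. Injected events are constant-amplitude
sinusoidal bursts of n cycles with half-Hann (Tukey) tapers of half a
cycle per edge, so that the stated amplitude is the amplitude of every
interior oscillation rather than of a single central peak. Each burst is
calibrated against the *local* band-filtered baseline SD (250 ms
surrounding window, the same convention the detector uses), through the
measured gain of the detection filter at the burst frequency.

**Exact-amplitude fixtures.** The in-band background is suppressed under
the event window (the windowed raw background is subtracted, which
commutes through any linear detection filter) before the burst is added.
Without this, in-band interference makes the realized amplitude ratio a
random variable with SD ≈ 0.4 baseline SDs (the estimation floor
1/√(bandwidth × duration) for a 20 ms event), and no detector can then
separate 4× bursts from 2.5× bursts at the stated operating points. The
fixtures are therefore calibration-exact rather than
superposition-realistic; on real EEG, measured amplitudes would carry
that ±0.4 SD interference and near-threshold events would be detected
probabilistically.

The detector band-passes with an order-2 Butterworth (200–550 Hz),
forward–backward by default (zero phase, for event-timing fidelity, with
the caveat that attenuation doubles; a single-pass mode gives the literal
order-2 response). Amplitude is the analytic (Hilbert) envelope smoothed
over 4 ms, evaluated at the half-wave extrema of the filtered trace. The
250 ms surrounding baseline is 125 ms on each side of the candidate,
separated by a 10 ms guard and excluding the candidate itself (one-sided
at trace edges); a robust global MAD-based SD pre-screens candidates
before the local re-test. Supra-threshold half-waves within 6 ms of each
other form a run; an oscillation is a full cycle (two consecutive supra
half-waves), an event needs ≥ 4 oscillations, and events closer than
10 ms are merged (one physiological event should not fragment). All
thresholds are baseline-relative, so detection is invariant under trace
rescaling. Whether the original detector's baseline excluded the event,
and whether "amplitude" meant peak or envelope, is not documented
anywhere; the choices above are this package's, exposed in
`DetectorSpec`.

The study-scale visual confirmation step is replaced by exportable event
tables (`events_to_frame`) carrying channel, time, oscillation count,
peak ratio and intra-event frequency for human review.

## Problem sizes

The recovery studies run at 5 states / 5 feature dimensions / 6 animals ×
10 minutes with R = 8 fits; calibration and power studies use 2-minute
sessions (500 null and 100 effect cohorts); detector batteries use 20
traces × 10 bursts per condition. These sizes give tight Monte-Carlo
error on every measured rate while keeping the full suite and the
acceptance script each in the low minutes on a single CPU.

## Known limitations

* EM finds local optima; the ensemble-consensus design is itself the
  mitigation, but all R fits can in principle share a basin.
* WPGMA cuts need not be optimal partitions of the signature space; they
  are, however, deterministic and reviewable.
* The Dunn test relies on the normal approximation of rank means; at very
  small groups (n ≤ 4) its discreteness makes p-values coarse.
* EDF is supported read-only (via mne, optional extra); the native
  on-disk EEG format is HDF5.
* Syllable naming ("Sitting 8", "Forward move 7") is human annotation and
  only supported as an optional label map.
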