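# Methods

This note documents the models, algorithms and design choices behind
`fnirs_transfer`: what the synthetic cohort generator simulates, how the
preprocessing and the compact CNN are defined, what the transfer-learning
protocol measures, and which parts of real fNIRS data the simulation does
and does not capture.

## The scientific question

Training a deep classifier per BCI user is expensive: each new subject
contributes only minutes of labeled recordings, and brain signals vary
strongly between people. Homogeneous (same feature space, same label
space) subject-transfer asks whether a network pretrained on a pool of
*source* subjects, then fine-tuned with most of its parameters frozen,
reaches usable accuracy on a *new* subject with fewer training epochs and
less data than an identical network trained from scratch. The package
implements the full experimental loop for an fNIRS n-back (mental
workload) paradigm — from raw dual-wavelength optical density to the
statistical comparison of the two training regimes — with a synthetic
cohort generator standing in for recordings, so every stage is testable
without any data download.

## Block paradigm

The default schedule matches the multi-session working-memory protocol
the study design assumes: 3 sessions x 3 series per subject; each series
is 2 s of instructions, 40 s of task (20 trials) and 20 s of rest — 62 s
per series, 558 s and 180 trials per subject. Series within a session
always run 0-back, 2-back, 3-back. Per-sample labels partition the
timeline exactly (rounding is applied to cumulative block onsets, not to
individual durations, so counts always sum to the recording length). The
2 s instruction span is transient and belongs to no class; it is labeled
"unlabeled" and never epoched. The 250 ms beeps and the STOP cue of such
protocols are timing-only events; they produce no optical signal
component and are not modeled.

## Synthetic cohort generator

The forward model produces, per subject, a (36 channels x 2 wavelengths x
5580 samples) optical-density recording at 10 Hz with source-detector
separation 30 mm. Its components, in order:

1. **Load-dependent spatial activation.** All workload classes activate
   the same broad frontal channel patch; load adds a small, laterally
   shifted component that grows with n-back level, plus a weak parietal
   component at the highest load (`PopulationConfig.class_patterns`,
   scale `pattern_separation = 0.5`). These maps are population-level
   constants — identical for every subject up to channel gain — and are
   exactly the structure that subject transfer can exploit. Choosing
   mostly-shared maps with subtle class differences keeps the task
   non-trivial: a classifier cannot separate classes from topography at a
   glance, nor from amplitude alone.
2. **Workload-ordered amplitudes.** Peak dHbO per class defaults to
   (0.15, 0.35, 0.5) uM — the magnitude range of cortical activation
   responses reported for working-memory fNIRS — jittered per subject
   (sd 0.08 uM) and re-sorted so higher load never has lower amplitude.
3. **Trial-to-trial variability.** Each series' evoked amplitude is
   multiplied by a mean-one log-normal factor (sigma 0.35). This is the
   main source of within-subject difficulty: a weak-responding series is
   genuinely hard to classify, as in real data.
4. **Hemodynamics.** The per-channel boxcar is convolved with a canonical
   double-gamma HRF (peak ~6 s, undershoot ~16 s, ratio 1/6; per-subject
   delays drawn from narrow ranges). The kernel is normalized to unit
   sum, so a sustained block plateaus at the configured amplitude and
   dHbO stays on its physical uM scale. dHbR is modeled as -1/3 times the
   clean dHbO response — the simplest coupling consistent with the
   anticorrelated chromophore dynamics the paradigm measures.
5. **Systemic physiological noise.** Mayer waves (0.1 Hz), respiration
   (0.3 Hz) and cardiac pulsation (1.1 Hz) are simulated as *one* sinusoid
   each, with a random phase per subject and a per-channel loading in
   [0.5, 1.5] — global interference seen coherently by every channel, the
   way superficial physiology actually contaminates fNIRS. Slow drift is
   a sum of four sub-0.05 Hz components treated the same way; it survives
   the 0.2 Hz low-pass, as drifts do in practice. Independent white
   measurement noise is added per channel. Default amplitude ranges
   (uM-equivalent): Mayer 0.05-0.15, respiration 0.03-0.10, cardiac
   0.03-0.10, drift 0.10-0.30, white 0.05-0.15.
6. **Optics.** The modified Beer-Lambert law maps (dHbO, dHbR) to optical
   density at 760/850 nm using packaged extinction coefficients
   (1.4866e-4 / 3.8437e-4 and 2.5264e-4 / 1.7986e-4 OD per uM*mm), DPF 6.0
   at both wavelengths and the 30 mm separation. All constants are
   configuration, not hard-code.

Determinism: a cohort is a pure function of (configuration, master seed).
Per-subject seeds are spawned from the master seed via NumPy
`SeedSequence`; the same master seed reproduces a cohort bit for bit.

**What the generator does not model:** photon transport (no Monte-Carlo
optics), motion artifacts, optode-coupling dropouts, EEG, non-stationary
noise spectra, learning/fatigue effects across sessions, and any
systematic session-to-session drift. Consequently, passing tests show
that the *pipeline* behaves as specified under controlled conditions —
not that the accuracy levels transfer to real recordings. The synthetic
domain gap between subjects (gain jitter, amplitude jitter, HRF timing)
is also milder than real inter-subject variability, so transfer is
stronger here than one should expect in practice.

## Preprocessing

* **MBLL inversion** solves the per-channel, per-sample 2x2 linear system
  dOD(lambda)/(d*DPF(lambda)) = eps * dc. With the simulator's constants
  it is the exact inverse of the forward model (round-trip error below
  1e-9 relative, asserted in tests).
* **Low-pass filter**: zero-phase 4th-order Butterworth at 0.2 Hz
  (`filtfilt`, reflective edge padding). Zero-phase filtering applies the
  transfer function twice, so the effective gain is |H|^2; the tests
  check a 1 Hz probe tone against this analytic response. 0.2 Hz keeps
  the evoked response band while removing cardiac and respiratory power.
* **Epoching**: sliding windows of 10 s step 5 s within each labeled
  segment (7 windows per 40 s task block). Windows never straddle
  segment boundaries; each carries its (subject, series) group key.
  3-class mode (0/2/3-back) is the default; 4-class mode adds rest.
* **Normalization**: per-(channel, chromophore) z-scoring with statistics
  fit on training examples only and applied unchanged to held-out
  examples. For pretraining, each source subject is standardized on its
  own statistics before pooling, and target subjects are standardized per
  training fold — the same convention at both stages, with no test-set
  leakage anywhere.

## The compact CNN

Topology is fixed: conv - conv - maxpool - flatten - dense - softmax
output. An epoched example (channels x chromophores x window samples)
enters as a 2-D map of channels x samples with the two chromophores as
input depth. Every inter-layer size follows

    output_size = (N - F) / stride + 1

and must be a positive integer on both axes; `validate_spec` propagates
shapes layer by layer, reports per-layer parameter counts, and fails on
the offending layer otherwise. Parameter counts are reported in two
conventions: *standard* (W*H*depth*K + K — what the implementation
allocates) and a depth-free convention (W*H*K + K, mode name `paper`, as
compact architecture summaries sometimes print); the standard count is
what `Network.count_params()` matches.

Two stock architectures are provided:

| | conv1 | conv2 | pool | dense | params |
|---|---|---|---|---|---|
| `CnnSpec.default()` | 16 @ 3x5 | 32 @ 3x5 | 2x2 | 64 | ~1.5 M |
| `CnnSpec.reduced()` | 8 @ 4x10, stride (2,5) | 16 @ 2x4 | 2x2 | 32 | ~35 k |

The reduced network is the default for cohort-scale experiments; its
strided first convolution cuts compute by roughly two orders of magnitude
while keeping the same topology. Cohort-scale results in this package are
produced with the reduced network.

The training engine is a NumPy implementation: im2col/GEMM convolutions
(the patch matrix is materialized once per batch and shared between the
forward pass and the weight-gradient), argmax-tracked max-pooling,
softmax cross-entropy, and Adam (beta1 0.9, beta2 0.999). Compute dtype
is float32 by default; a float64 mode exists and is used by the
numerical-gradient test, which agrees with backpropagation to ~1e-8
relative. Initialization is He-normal from an explicit seed; training is
bit-reproducible given (data, seed). Prediction ties break to the lowest
class index. Parameters live in four named groups — conv1, conv2, dense,
output — each hashable for freeze verification.

Optimizer settings: pretraining uses Adam at 1e-3 for 20 epochs (batch
32) on the pooled source subjects. Target-subject training — fine-tuning
and the scratch baseline alike, so the comparison is like-for-like — uses
1e-4. The smaller target rate is standard fine-tuning practice and keeps
the epoch budget meaningful: at 1e-3 a scratch network converges within
10 epochs on ~40 windows and the learning curve the sweep measures
collapses to a flat line.

## Transfer protocol

* **Freeze plans.** Trainable groups must form a contiguous block ending
  at the output layer. Presets: `only-output`, `last-two-dense`
  (dense + output; the default), `unfreeze-through-conv2`,
  `unfreeze-through-conv1` (everything). `freezing_ablation` ranks all
  four by mean fine-tuning accuracy.
* **Cross-validation folds by series**, never by window: temporally
  adjacent, overlapping windows would otherwise leak across folds.
  Schemes: stratified 70:30 holdout (one test series per class drawn at
  random — plain random grouping can put all series of a class on one
  side), leave-one-series-out, and stratified group k-fold (default
  k = 3 on 9 series: every window predicted once, one test series per
  class per fold). Requesting more folds than series degrades to
  leave-one-series-out with a logged note. Window-level k-fold exists for
  comparison with protocols that fold over windows, but is not the
  default. A leakage guard asserts empty train/test group intersections.
* **Accuracy** is micro-averaged over pooled fold predictions:
  correct / total x 100.
* **Epoch-budget sweep.** Subjects split 16 source / 5 control / 5
  baseline in cohort order (roughly 60:20:20). One checkpoint is
  pretrained per master seed; each (group, subject, budget) cell then
  trains with a fresh seed derived from (master seed, group, subject,
  budget), so any cell can be reproduced in isolation. Control cells
  fine-tune under the default freeze plan; baseline cells train from
  random initialization. A note is logged when a group's mean accuracy
  declines from one budget to the next (over-fitting indicator).

On the default synthetic cohort this produces the expected picture:
control-group means sit high (~82-95%) from the smallest budget onwards
while baseline means climb steadily (~45% at 10 epochs to ~65-70% at 60),
so the fine-tuned network reaches its saturated accuracy at a smaller
budget than the scratch network — the core claim of the transfer
protocol. These numbers are what `examples/transfer_vs_scratch.py` and
the acceptance suite compute at run time; they are properties of the
synthetic conditions, not claims about real recordings.

## Statistics

`compare_groups` pairs subjects by row order across the two accuracy
tables and reports: per-budget means (rounded half-up to two decimals,
the tables' precision; unrounded values retained), Shapiro-Wilk W and p
per budget column per group (scipy's implementation of Royston's
approximation; n must be in [3, 5000] and non-constant), normal-quantile
(QQ) points at Blom plotting positions (i - 0.375)/(n + 0.25), and the
two-tailed paired t-test t = mean(d) / (sd(d)/sqrt(n)) with the n-1
sample standard deviation, df = n - 1. Identical samples return the
trivial t = 0, p = 1; constant nonzero differences are rejected as
degenerate. The budget-60 column is the default test column: on the
packaged reference tables it is the column that reproduces the published
t to three significant figures, and the published t was evidently
computed on unrounded accuracies (recomputing from the two-decimal cells
gives 17.869 against the printed 17.8723 — documented, not "corrected").
Groups smaller than three subjects get a means-only report with the
inferential fields unset.

## Packaged reference tables

`data/reference/{control_group,baseline_group}.csv` hold the published
subject x budget accuracy grids of the reference study (10 subjects,
budgets 10-60) in the same CSV codec `AccuracyTable` writes, and are
checksum-verified on load. `reproduce_reference_stats()` recomputes every
summary statistic from the raw cells; `scripts/acceptance.py` writes the
same quantities as JSON. `published_stats.json` stores the originally
printed summary numbers for side-by-side display only — nothing in the
package computes from it.

## Numerical and degenerate-input choices

* Rounding of reported means: decimal half-up at two decimals (so 82.755
  prints 82.76 regardless of binary float representation).
* Zero-variance channels in z-scoring: epsilon-guarded (1e-8) with a
  warning.
* Conv shapes that do not tile ((N - F) % stride != 0) are rejected, not
  truncated.
* `epochs = 0` training calls are exact no-ops; an all-frozen plan raises
  before touching parameters; a NaN loss aborts with the offending seed
  and configuration echoed.
* Folds whose training side lacks a class are skipped with a warning; if
  every fold is skipped the call errors out.
* Derived seeds are masked to [0, 2^31) so they stay valid for every
  consumer.

## Problem sizes used by the test and acceptance suites

Cohort-scale checks run the 26-subject cohort with the reduced network,
3-fold series CV for the single-seed comparison, and stratified holdout
for the ten-seed saturation-order replication; unit tests use miniature
specs (a 12-channel, 30-sample toy network) and short schedules
(1-2 sessions). These sizes are the package's chosen defaults for
desk-scale reproducibility; all of them are configuration, and nothing
in the code special-cases them.

## Known limitations

* The NumPy engine supports exactly the canonical topology (two convs,
  one pool, one dense, softmax); it is not a general autograd system.
* No dropout or batch normalization; the compact network does not need
  them at these data sizes, and their stochasticity would complicate
  bit-reproducibility.
* The SNIRF export writes a minimal, amplitude-style structure for
  interoperability checks; it is not a validated full implementation of
  the standard.
* Real-data ingestion is out of scope by design; the cohort reader
  documents the on-disk layout a user would need to match.
* 10-fold cross-validation over 9 series is impossible at series level;
  the package degrades to leave-one-series-out and says so, or folds
  over windows if explicitly requested.
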