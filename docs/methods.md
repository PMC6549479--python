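# Methods

`drivestyle` implements a two-stage driving-style recognition pipeline for
simulated-driving studies, together with a calibrated synthetic-data
generator that stands in for raw recordings. This note documents the models,
the numerical choices, and what the synthetic conditions do and do not show.

## The recognition schema

**Stage 1 — unsupervised style labelling from driving behaviour.** Each
driving task is summarised by seven behavioural variables: vehicle velocity
(km/h), total driving time (s), lane-excursion count, collision count, and
the steering wheel's angular velocity (rad/s), angular acceleration
(rad/s²) and rotation angle (°). The tasks × 7 matrix is standardised
column-wise (Z-score with sample SD, n−1), reduced to two principal
components (eigendecomposition of the covariance of the standardised
matrix, equivalent to correlation PCA; loading signs fixed so the
largest-magnitude entry is positive), and clustered with Lloyd's K-means:
initial centroids are K distinct observations sampled at random, iteration
stops when no observation is reassigned, and the best of `n_restarts = 10`
restarts by total within-cluster squared error (ESS) wins. Distance ties
break toward the lowest cluster index; an emptied cluster seizes the point
farthest from its current centroid. The cluster count is chosen by the
Calinski-Harabasz score

  s(k) = [tr(B_k) / tr(W_k)] · [(m − k) / (k − 1)],

maximised over k ∈ {2,…,6}, ties toward smaller k for parsimony. With K = 3
the clusters are named by descending mean vehicle velocity — fastest
Aggressive, middle Moderate, slowest Conservative — because velocity is
monotone across the calibrated group profiles (total driving time would
invert the ranking and is excluded); exact velocity ties break by mean
angular acceleration. Groups are characterised per variable by a one-way
ANOVA (F, p, η² = SSB/SST) plus uncorrected pairwise Welch t tests.

**Stage 2 — supervised recognition from EEG.** Per task, 16-channel EEG is
conditioned by a fixed chain: polyphase down-sampling → zero-phase
windowed-sinc FIR band-pass 0.5–30 Hz → FastICA artifact-component removal
→ bad-channel replacement by the mean of two montage neighbours → average
re-reference → whole-record baseline subtraction. Features are the
channel-averaged single-sided FFT amplitude (2|X_k|/N, mean over bins with
centre frequency in [low, high)) and the channel-averaged Welch band PSD
level, 10·log10 of the mean in-band density, in the four canonical bands
δ 0.5–4, θ 4–8, α 8–13, β 13–30 Hz — an 8-dimensional vector per task.
Fisher LDA (generalised eigenproblem on between- vs ridge-regularised
within-class scatter) reduces the vector to 2 dimensions, and a linear
soft-margin SVM classifies styles one-vs-one: one binary model per class
pair (the alphabetically-first class of each pair encoded −1), majority
vote, ties broken by the largest sum of signed decision values and then
lexicographically. Evaluation is leave-one-subject-out: one fold per
subject, all of a subject's tasks held out together, predictions pooled
into a single predicted-rows × true-columns confusion matrix with
accuracy, per-class precision, recall and F-measure.

The SVM dual is solved by most-violating-pair SMO coordinate ascent on the
box-constrained dual with the equality constraint Σαᵢyᵢ = 0; the weight
vector is W = Σαᵢyᵢxᵢ, the offset comes from on-margin support vectors,
and the relative duality gap at the reported solution is ≤ 1e-6 on the
problem sizes used here. C defaults to 1 (config-exposed); the linear
kernel is the model — no kernel trick.

## The synthetic-data generator

The generator defines the study conditions; downstream stages are tested
against it.

**Driving tables.** Each style group draws its seven variables from
independent normals with the calibrated group means/SDs (defaults in
`drivestyle.defaults.DRIVING_GROUP_STATS`). The two count variables are
drawn the same way, clipped at zero and rounded; the induced moment bias
is small at the calibrated means (at most a few percent of an SD) and is
accepted, since only mean ± SD summaries are available to calibrate
against.

**EEG.** Channels are independent by default. Each channel is white
Gaussian noise shaped in the rFFT domain by a target one-sided PSD curve
assembled from three band components (0.5–7, 7–21, 21–30 Hz) with
raised-cosine crossfades of 0.5 Hz centred on the band boundaries. dB is
10·log10 of one-sided density in (a.u.)²/Hz — no volt calibration is
attempted; the package matches numbers, not physics. Because crossfades
(and the bump, below) perturb in-band averages, the three component
amplitudes are solved per channel from a 3 × 3 linear system so that the
bin-averaged density over each analysis band (0.5 Hz grid, [low, high)
convention — the grid of the default Welch estimator) equals the dB target
exactly. A 10-seed mean of the Welch estimate then recovers every
channel × band target within ~0.2 dB (tolerance asserted: 1 dB).

The Conservative profile adds a narrowband "bump": a cos² component of
half-width 2 Hz centred at 15 Hz whose peak density sits 4 dB above the
Band-2 base. The level was chosen once to give a clear local maximum of
the group-mean spectrum between 10 and 20 Hz; because the bump is inside
the calibration system, it does not shift the Band-2 average.

`generate_eeg_recording` hits its spec's levels deterministically (Welch
estimator noise only). Between-task dispersion enters one level up:
`make_dataset` draws each task's per-channel band levels from
N(group mean, between-task SD), treating the calibration table's "±" as a
between-task SD. The default study design is 23 subjects and 75 tasks
(19/25/31 per style), each subject contributing 2–4 tasks, all of a
subject's tasks sharing one style by default (`subject_consistent=False`
shuffles task styles across subjects while preserving group totals). All
randomness derives from one master seed via `numpy` seed sequences; the
bundle is bit-reproducible.

**Artifacts.** Blinks are Poisson events (rate per minute) realised as
0.3-s raised-cosine pulses, largest on Fp1/Fp2 with weights decaying over
the montage; drift is a slow sinusoid (0.2 Hz) and mains noise a 50 Hz
sinusoid, each with per-channel random phase. The injector returns a
ground-truth log used as the oracle in artifact-removal tests.

**What the generator does not emulate.** No 1/f microstructure, evoked
potentials, channel covariance (optional mixing is not enabled by
default), non-stationarity, or muscle artifacts. Passing tests therefore
show that the pipeline recovers the *band-power group structure* it
assumes, not that it would reach the same accuracy on real recordings.

## Numerical choices

- **Welch defaults:** 2-s Hamming segments, 50% overlap, one-sided density
  scaling; dB floor ε = 1e-20 before the log (an all-zero channel reports
  the −200 dB floor sentinel).
- **FIR design:** Hamming windowed-sinc, length ≈ 3.3·fs/transition
  (transition 0.5 Hz by default), applied forward-backward, so pass-band
  ripple stays ≪ 1 dB and stop-band attenuation is far beyond 40 dB one
  transition width past the edges; filters longer than a third of the
  signal are rejected with guidance.
- **ICA:** logcosh FastICA with symmetric orthogonalisation (tol 1e-4,
  500 iterations), per-component deflation as fallback; non-convergence
  returns the data untouched with a warning flag. Components are rejected
  when |kurtosis| > 5 or when the absolute correlation of their scalp
  topography with the frontal ocular template exceeds 0.8. This two-rule
  detector deliberately replaces a full published artifact classifier;
  it preserves the chain's contract on synthetic data.
- **Bad channels:** flat (variance < 1e-15) or extreme (|z| > 3 on
  log-variance across channels); replacement is the mean of the two fixed
  montage neighbours (table in `drivestyle.montage.NEIGHBOURS`; absent
  10-20 neighbours are substituted by the nearest in-set electrode).
- **Baseline:** the whole-record per-channel mean — continuous driving has
  no pre-stimulus interval.
- **LDA ridge:** λ = 1e-6 · tr(S_w)/p added to the within-scatter for
  numerical stability; discriminants ordered by eigenvalue.
- **LDA scope:** refit inside each LOSO training fold by default (no
  leakage); a `global` mode fits once on all data, and `none` feeds the
  8-D features directly to the SVM.
- **Metrics:** computed at full precision, displayed to one decimal as
  percentages; F-measure is the harmonic mean of *unrounded* precision and
  recall (a `rounded_f` switch chains the one-decimal percentages instead,
  which changes borderline third-decimal cases).
- **EDF:** written as continuous 16-bit EDF with one-second records and
  symmetric per-channel physical ranges formatted to the 8-character
  header fields before digitisation, so a write-then-read round trip is
  exact to within half a quantisation step.

## Problem sizes

The default pipeline dataset generates EEG at 256 Hz for 20 s per task and
preprocesses to 128 Hz; spectral targets are sampling-rate independent
(density-domain shaping), so calibration checks run unchanged at
512 Hz / 60 s, which is the scale used for the single-recording
calibration checks. The full 75-task LOSO pipeline completes in about half
a minute per master seed.

## Known limitations and open points

- The Band-2 (7–21 Hz) channel-mean group ordering is *not* fully
  reproducible from the per-channel calibration table: the table's own
  values place Aggressive 0.09 dB above Moderate in Band 2 (driven by its
  O1 entry), and Welch window leakage of the ~12× stronger Band-1 density
  across the 7 Hz boundary widens that gap. The package asserts the robust
  comparisons (Conservative highest in Band 2; the full Band-1 ordering);
  the strict three-way Band-2 ordering check fails under faithful
  calibration and is knowingly left failing rather than recalibrated.
- Printed group-level F statistics for the driving variables are not
  recoverable from mean ± SD summaries at the task level (the granularity
  of the original ANOVA is unstated); `anova_oneway` is validated against
  an independent statistical routine instead.
- Whether count variables should enter clustering raw or per-lap is
  unstated; raw values are used.
- Welch-level Jensen bias (finite segment count) is ≪ 0.1 dB at the
  durations used and is ignored.
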