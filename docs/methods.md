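# Methods

This note documents the models, parameter choices and numerical decisions
behind `gaitintent`, and what the synthetic benchmark does and does not
establish about real recordings.

## Protocol and data model

A session is a continuous 256 Hz recording of 30 EEG channels (10/10
montage, linked-ears reference) and two bipolar EMG channels over the left
and right tibialis anterior, with auditory cue events. Each trial is a
relaxation period of ~10 s (uniform ±1 s jitter) opened by a `relax_cue`,
a `walk_cue`, and a self-paced movement onset 1–3 s later; twenty trials
form a phase and five phases a session (100 trials). All times are seconds
from recording start, sample indices are 0-based, and intervals are
half-open `[start, end)`.

EDF+C is the signal container (16-bit quantization between per-channel
physical limits set from the data range with 5 % headroom; events ride in
the annotation track, so round-trip event times are exact to the 0.1 ms
formatting resolution and samples to one quantization step). A CSV bundle
is supported where transparency matters more than size. Ground truth of
simulated sessions is a JSON sidecar, never embedded in the EDF.

## EMG onset detection

Per trial, the EMG between the relaxation cue and 5 s after the walk cue is
mean-removed and Hilbert transformed; the envelope is smoothed with a
centered 50 ms moving average (configurable) to suppress single-sample
spikes, and thresholded at 10 % of its maximum *within that trial's search
window* (per-trial rather than per-session maxima localize slow drifts in
electrode contact). The two EMG channels are fused by taking the channel
with the larger envelope peak. The onset is the first upward threshold
crossing minus a fixed 100 ms, the conventional correction for the lag
between activation onset and the envelope reaching a tenth of its peak.
Trials with an onset before the walk cue (protocol violation), no crossing,
or less than 6 s of pre-onset data are dropped with a logged reason; kept
trials carry exactly 6 s of EEG ending at (and excluding) the onset sample.

In the generator, the EMG burst's raised-cosine rise time (0.49 s) is set
analytically so the envelope's 10 % crossing falls ≈ 100 ms after
activation start — the same convention the detector's offset inverts:
for a raised-cosine rise of duration R the 10 % point sits at
R·acos(0.8)/π ≈ 0.205 R. With the default burst-to-baseline amplitude
ratio of 30 (resting tibialis EMG is nearly silent), the median absolute
onset error on synthetic sessions is ~35–40 ms.

## Artifact rejection

Two training-fold-only stages:

* **Joint-probability rejection.** Per channel, a 500-bin histogram over
  the pooled samples of all trials estimates the channel's empirical
  distribution; a trial's score is the mean log density of its own samples.
  A trial is rejected when any channel's score deviates more than 3 SD from
  that channel's mean score. Zero score variance (identical trials) rejects
  nothing.
* **ICA component cleaning.** FastICA is fitted on a 1–40 Hz band-passed
  copy of the concatenated training trials and applied, through the same
  unmixing, to the unfiltered data. The decomposition runs in the top-20
  principal subspace: estimating a full-rank unmixing over channels that
  carry a white sensor-noise floor does not converge (the extra directions
  are effectively Gaussian), while the artifact and physiological sources
  live in the leading subspace — standard EEG practice. Convergence
  tolerance is 1e-2 with up to 1000 iterations; on non-convergence the fit
  retries with a fresh seed and a 5× coarser tolerance, up to three
  attempts, then errors. A component's amplitude score is the maximum
  absolute value of its scalp-projected time course (RMS optional);
  components above mean + 2 SD of all scores are dropped and the rest
  back-projected. With the stored channel means the cleaning operator is an
  affine projection, hence exactly idempotent.

## MRCP and ERD characterization

* **MRCP**: zero-phase (forward–backward) second-order Butterworth
  band-pass at 0.1–1 Hz, then polyphase resampling to 10 Hz with the grid
  anchored at the epoch start. The band-pass itself is the anti-alias
  filter.
* **Time-frequency power**: Morlet wavelets on a 0.5 Hz grid over
  0.5–30 Hz, 6 cycles. Because a fixed-cycle wavelet (support ≈ 1.6 ×
  cycles/f) must fit inside the epoch, cycles shrink proportionally below
  ≈ 1.6 Hz on 6-s epochs; frequencies below 0.5 Hz are not represented at
  all. The time axis is decimated to 16 Hz.
* **ERD%**: 100 × (P − B)/B with P the across-trial mean power and B its
  mean over the [−4, −2] s baseline, so baseline columns of each frequency
  row average to zero by construction. Significance comes from a
  trial-level bootstrap (default 1000 resamples): bootstrap means evaluated
  at the baseline columns are centered at each column's observed mean —
  capturing the sampling variability of the mean rather than that
  variability plus the column-to-column spread, which would be
  conservative — pooled per frequency, and two-sided percentile thresholds
  at α = 0.05 mask the map. On stationary noise the masked fraction is
  ≈ 0.055 over 200 replicates, inside the [α/2, 2α] calibration band.
* **Grand averages** are balanced hierarchical means (trials within
  session, sessions within subject, then subjects), which differ from
  pooled means under unbalanced trial counts.

## Features and the two-layer detector

From ten sensorimotor channels (F3, Fz, F4, FC1, FC2, C3, Cz, C4, CP1,
CP2), 1-s windows slide in 125 ms steps over the 6-s epoch: 41 windows, of
which the 8 whose centers lie strictly after −1.5 s are labeled
pre-movement. The center-based strict rule is the unique labeling that
produces the 41/8 split for this geometry (start- or end-based rules give 5
or 12 positives). MRCP features are the ten 10 Hz samples per channel
nearest the window (the 125 ms step is incommensurate with the 100 ms
sample period, so windows live on the continuous axis and map to nearest
samples); ERD features are the natural-log mean square of the zero-phase
8–13 Hz band-passed epoch within the window, floored at log(1e-12 µV²).
Training features are normalized to unit Euclidean norm per dimension;
the scale factors carry unchanged to test folds (a per-window rule would
need no carried parameters, which is why per-dimension is the right
reading).

Each first layer is a two-class sparse discriminant solved by optimal
scoring: elastic-net regression of fixed class scores onto the centered
features, alternated with score re-estimation until the weights move less
than 1e-6 (for two classes the scores are determined up to sign, so this
settles in a couple of sweeps). The penalties enter as
(1/2n)‖z − Xβ‖² + l1‖β‖₁ + (l2/2)‖β‖²; with l1 = 0 the closed-form ridge
solution is used, whose direction is collinear with the ridge-LDA direction
(Σ + l2 I)⁻¹(μ₁ − μ₀). If a penalty drives every weight to zero, the
single largest-magnitude pre-thresholding weight is kept at its univariate
ridge value (so its scale stays comparable to regular fits) and the model
is flagged degenerate. Probabilities come from shared-variance Gaussians
with empirical priors on the projected scores — generative, like classical
LDA, rather than logistic calibration. The second layer is a linear
discriminant on the two first-layer probabilities, fitted on out-of-fold
probabilities from the inner loop (standard stacking), and a shared
threshold binarizes its posterior per window, causally.

Hyperparameters are selected by chronological inner cross-validation:
per layer, (l1, l2) maximizes that layer's best-over-threshold mean inner
trial-correct percentage; the shared threshold then maximizes the inner
ensemble percentage. Ties prefer non-degenerate fits, then larger l1
(sparser) and larger threshold (fewer false positives). Default grids:
l1 ∈ {0, 0.001, 0.01, 0.1, 1}, l2 ∈ {0.001, 0.01, 0.1, 1}, threshold
0.05…0.95 in steps of 0.05. On the easy synthetic benchmark many grid
points tie at the top score and the sparsity preference often reduces the
MRCP layer to its single best feature — a documented consequence of the
tie-break, not a defect, and performance is unaffected.

## Evaluation

Nested 5 × 5-fold chronological cross-validation over kept trials: test
folds are contiguous chronological blocks (sizes differing by at most one);
joint-probability rejection, ICA, normalization and the full inner search
run on training trials only, and everything fitted carries over unchanged
to the test fold, from which no trial is ever removed. A test trial is
correct iff it has at least one detection among its 8 pre-movement windows
and none among its 33 relaxation windows.

The chance level of that metric is estimated by relocating a contiguous
block of 8 predicted-positive windows uniformly among the 34 possible
positions; only the flush-right position satisfies both conditions, so the
analytic value is 100/34 ≈ 2.94 %, and the Monte-Carlo estimator converges
to it. Alternative readings of "interchanging the labels of a whole
sequence" (circular shift: 1/41 ≈ 2.4 %; i.i.d. relabeling: ≈ 0.06 %) give
different constants; the block-relocation form is implemented because it
preserves both class counts and contiguity.

Session-transfer evaluation trains (with inner CV) on one session and
applies everything unchanged to another, mirroring the fold carry-over
rules. Feature diagnostics are the squared point-biserial correlation per
feature, the selection consistency (share of models with nonzero weight
per feature) and the ERD:MRCP aggregate weight-magnitude ratio.

IMI scoring maps reverse-flagged items s → 8 − s and averages the six
subscales (interest/enjoyment, perceived competence, effort/importance,
pressure/tension, perceived choice, value/usefulness; 7/6/5/5/7/7 of the
37 items). The published inventory specifies only subscale names, so the
item→subscale map and reverse flags ship as editable data in `core_io`.
Performance–subscale Pearson correlations are Holm-adjusted across the six
subscales (step-down with the min(1, ·) clip, as in `statsmodels` and R's
`p.adjust`).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
amplitudes chosen once to define a high-signal benchmark:

* background: 15 shared 1/f sources with Gaussian-on-scalp topographies
  plus an independent per-channel floor (80 % / 20 % variance split),
  total RMS 10 µV. The shared sources carry a slow log-normal amplitude
  modulation (depth 0.6) because real EEG background is bursty
  (leptokurtic) — which is also exactly what makes the sources
  identifiable to ICA; purely Gaussian sources are not.
* MRCP: raised-cosine descent from −1.5 s to a −20 µV trough at +200 ms,
  topography peaking over Cz/FC1/FC2. The recovery mirrors the 1.7 s
  descent by default, making the pulse symmetric about its trough so that
  a zero-phase band-pass leaves the trough latency identifiable; the
  protocol constrains only the ramp start, the trough latency and the
  sign. A strongly asymmetric pulse shifts the band-passed extremum
  100–200 ms by construction (a magnitude-response effect, not phase).
* mu rhythm: 10 Hz sinusoid, fresh phase per trial, baseline 12 µV over
  C3/Cz/C4, envelope dropping by `erd_depth` = 0.6 from 1 s before onset
  with a ≤ 250 ms raised-cosine transition, recovering after movement end.
* EMG: 30–100 Hz noise, baseline RMS 8 µV, burst ratio 30, rise 0.49 s.
* artifacts: blinks (5 %/trial, 50–100 µV, 1–3 Hz frontal lobe) and
  whole-trial ×5 amplitude scalings (2 %/trial); optional premature
  movements (EMG burst before the walk cue) exercise protocol rejection.
* one master seed; trial k derives sub-seed (seed, 1000 + k), so any trial
  is reproducible in isolation.

The synthetic IMI draws a standard-normal latent motivation per
subject-session; interest/enjoyment and value/usefulness item propensities
are 4 + coupling·m with per-item Gaussian noise, dithered integer rounding
and clipping to 1–7, while the other subscales follow their own latents.
A synthetic performance percentage is linked to the latent deterministically
(64 + 15 m, clipped), so item noise alone sets the observable correlation;
the defaults (coupling 0.35, noise SD 1.2) put the population correlation
near 0.6 (measured ≈ 0.58–0.61 at n = 4000). Integer quantization caps the
noiseless-limit correlation at ≈ 0.994.

**What the benchmark shows — and does not.** Passing tests demonstrate
that every stage implements its contract and that the pipeline recovers
known embedded structure at favorable SNR, stays at chance when that
structure is absent, and respects train/test separation. The generator
does not model volume conduction from realistic sources, inter-subject
topography differences, session-to-session nonstationarity, lesion-specific
signal changes, or realistic artifact diversity — so synthetic detection
rates say nothing quantitative about clinical performance, where detection
in the 20–85 % range and large transfer losses are typical.

## Problem sizes used by the test suite and acceptance script

End-to-end runs use one default 100-trial high-SNR session and three
100-trial null sessions (no embedded MRCP/ERD); the chance level uses 10⁵
Monte-Carlo draws; ERD mask calibration uses 200 replicates of 10
one-channel trials at reduced frequency resolution with 150 bootstrap
resamples; sparsity monotonicity averages 20 seeded datasets; metric
agreement uses 10⁴ random sequences; motivation recovery uses 100
replicates of 21 subject-sessions. Unit tests run on 10–30-trial sessions
with reduced hyperparameter grids.

## Known limitations

* The EDF writer pads the final data record to a whole second (padding
  repeats the last sample); sessions generated by this package end on
  whole-second boundaries, so round trips preserve sample counts.
* FastICA component labeling is purely amplitude-based; no physiological
  classification of components is attempted.
* The detector is epoch-synchronous, as evaluated; no asynchronous
  streaming mode with refractory periods.
* The inner grid search refits each first layer per fold and grid point;
  with the default grids this dominates runtime (~1–2 min per session on
  one core).
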