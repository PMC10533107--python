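# Methods

## The estimation problem

The package estimates a continuous pain-intensity signal from two
modalities recorded during experimental pain stimulation: one
electrodermal activity (EDA) channel and 21 facial-activity channels, both
sampled at 25 Hz, with a per-sample stimulus label. Intensity is treated
either as a class (no pain + per-quality intensities) or as a normalized
continuous target, intensity/3 ∈ {0, 1/3, 2/3, 1}. Because the clinical
database of this task family is access-restricted, the package's synthetic
generator defines the study conditions under which everything is tested.

## Synthetic session generator

The generator emulates the stimulation protocol: per subject, 30 phasic
5-s stimuli per (quality, intensity) pair — 180 total — interleaved in
randomized order with pauses drawn uniformly from 8–12 s, then one tonic
60-s stimulus per pair followed by 300-s pauses. A 15-s lead-in and a 10-s
tail of baseline bracket the session (the tail guarantees trailing
windows exist). Default sessions last ≈ 81 minutes. Phasic and tonic parts
are generated as contiguous blocks (phasic first by default, configurable)
since label-based dataset filters are insensitive to block order.

**EDA model.** Tonic level (2 µS) + optional slow sinusoidal drift
(amplitude 0.05 µS, period 300 s) + one skin-conductance response per
stimulus + i.i.d. Gaussian noise. The SCR kernel is a difference of
exponentials (rise 0.75 s, decay 4 s — the standard SCR shape),
peak-normalized so the response peak is `eda_gain × intensity` with ~10%
multiplicative jitter, onset delayed by the subject's SCR latency (1–3 s).
Tonic stimuli produce a saturating plateau held over the stimulus and
released exponentially.

**Facial model.** A fixed subset of seven pain-responsive channels (brow
lowering, orbit tightening, nose wrinkling, upper-lip raising, mouth
opening) receives stimulus-locked bumps of amplitude
`facial_gain × intensity` scaled by a per-channel loading; all other
channels are pure noise. `facial_gain` derives from the subject's
expressiveness category 1–4 (0.4·(category−1), jittered ±20%): category-1
subjects show *no* facial pain response, which is exactly the situation
where the EDA modality must carry the signal.

**Subjects and splits.** Categories are assigned roughly uniformly;
per-subject gains, latency and noise are drawn from a seeded stream
spawned per subject (sessions are independent of generation order).
Subjects split 80/10/10 into train/val/test, stratified by category; every
split contains every stimulus intensity because every session does. Label
artifacts (codes −10/−11) overwrite labels — never signal — on random 1–4 s
spans, ~2% of samples by default.

**What the generator does not model:** habituation and sensitization
across repetitions, autocorrelated sensor noise, movement artifacts in the
signal itself, inter-stimulus sympathetic variation, or any coupling
between facial and EDA responses beyond their shared stimulus locking.
Passing tests therefore demonstrate that the pipeline recovers known
stimulus-locked structure, not that it would achieve any particular
accuracy on clinical recordings.

## Descriptors

Per whole second and per channel: min, max, mean and population standard
deviation (ddof 0) of the raw samples and of the first and second finite
differences — 12 features per channel (12 for EDA-D, 252 for FAD).
Derivatives are computed once over the full series and segmented by left
sample index, so near-boundary seconds use the samples that exist.
Descriptor frames are z-scored per subject over the subject's entire
recording (subjects never straddle splits, so no cross-split leakage;
whether the per-subject statistics should be restricted to an earlier
calibration period is an open deployment question). Zero-variance features
map to 0. Labels are shifted forward 3 s; a window's per-second label is
the within-second majority code, ties resolved toward artifact codes
first, then higher intensity, then heat before electrical. Model inputs
are 10 consecutive frames predicting the next second's label; the first 10
seconds yield no window.

## Datasets

Eleven datasets slice the windows by stimulus type and quality (PD, HPD,
EPD phasic; TD, HTD, ETD tonic; R\* reduced; no reduced heat-tonic dataset
exists — the heat-tonic set is already nearly balanced). Artifact windows
are dropped; each no-pain run is attributed to the pain sequence
immediately following it and kept only if that sequence is kept; trailing
no-pain windows are dropped. Reduction keeps, per pain sequence of m
windows, the m immediately preceding no-pain windows (all, if fewer
exist), which yields exactly 50% no-pain when every pause is long enough.
Filters act on a window's label second, not its 10-s feature history.
7-class encodings order classes BL, H1–H3, E1–E3; 4-class BL, 1–3. The
continuous target ignores quality (heat-2 and electrical-2 are both 2/3).

## Models

* **Random forests** (classifier and regressor): scikit-learn forests with
  100 trees, max depth 10, on flattened windows (120 or 2520 features).
* **LSTM variants**: a from-scratch numpy LSTM (sigmoid gates, ReLU
  candidate and cell-output activation), flatten, dense ReLU layer, and a
  softmax (categorical cross-entropy) or sigmoid (binary cross-entropy)
  head. Architectures: 4 units + dense 128 (A/C) or 8 units + dense 64
  (B/D), with 7, 4 or 1 output units. Weights: Glorot-uniform input and
  dense kernels, orthogonal recurrent kernels, forget-gate bias 1.
  Training: Adam (β₁ 0.9, β₂ 0.999, ε 10⁻⁷), batch size 512, shuffled
  mini-batches, global-norm gradient clipping at 5.0 (a stabilizer for the
  unbounded ReLU cell state). Backpropagation through time is verified
  against numerical gradients to 10⁻⁵ in the test suite. Per-dataset
  default architecture/learning-rate assignments are tabulated in
  `painmon.models.DEFAULT_ASSIGNMENTS`; the full-protocol profile trains
  2000 epochs, the desk-scale profiles 10–60 epochs (the package's test
  and example sizes — 10 subjects, 60 epochs for parameter recovery —
  train in about a minute on one CPU).
* **Sample weighting**: an RFc fit on the training FAD windows scores each
  window; windows whose score *for their own class* exceeds 0.3 (the
  clearly-expressed ones) are duplicated once, adjacently, before training
  the LSTM-SW variants. Reading the threshold against the true-class score
  (rather than the maximum score) is the package's resolution of an
  ambiguity; the alternative is a one-line change.
* **Trivial baseline**: all mass on the no-pain class / constant 0.

## Evaluation

Micro-averaged F1 pools true/false positives and false negatives over pain
classes only; the no-pain class is excluded from pooling, which is the
reading forced by the trivial baseline scoring exactly 0 (pooling all
classes would instead give it the no-pain prevalence). MSE and ICC(3,1)
compare classification and regression on the common [0, 1] intensity
scale; predicted classes map through the same intensity/3 encoding,
ignoring quality in the 7-class case. ICC(3,1) (two-way mixed, consistency,
single rater, k = 2 raters) is computed from the ANOVA decomposition with
windows as rows; it is exactly 0 for a constant prediction, 1 for
`y = x + c`, undefined (NaN) when both vectors are constant, and is
cross-checked against an independent implementation in the tests. ICC is
pooled over the test split's subjects, matching single-number-per-dataset
reporting.

## Numerical and design choices

* Population (ddof 0) std everywhere in descriptors.
* Argmax ties (fused or direct) resolve to the lowest class index.
* Regression predictions are sigmoid-bounded; forest regression outputs
  are clipped to [0, 1] before scoring.
* Random-forest class-score matrices are zero-padded to the dataset's full
  class set when a training split lacks a class.
* All randomness flows from one seed: the cohort spawns one child stream
  per subject; pipeline model seeds are derived by hashing
  (seed, dataset, model, modality) and stay below 2³¹.
* Degenerate inputs fail loudly: sessions shorter than 3 s, single-frame
  subjects, single-class classification training sets, misaligned fusion
  inputs.

## Known limitations

The synthetic cohort is far easier than clinical data — responses are
perfectly stimulus-locked and noise is white, so absolute metric values
(e.g. ICC ≈ 0.97 for EDA-D recurrent regression on the reduced phasic
dataset at the default desk-scale conditions) exceed what heterogeneous
real recordings yield; only the *orderings* the pipeline is designed to
expose (models beating the trivial baseline, EDA dominance for
low-expressiveness subjects, reduction balancing the class mix) transfer
as qualitative expectations. Tonic datasets are tiny by construction (six
stimuli per session), so their metrics are noisy at desk scale. The LSTM
runs on CPU in numpy; it is deliberately small and is not a
general-purpose deep-learning stack.
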