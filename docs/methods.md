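# Methods

## Signal model and conventions

Recordings are single-channel EEG sample arrays at a known rate (the
motivating acquisition: 256 Hz, 1 Hz high-pass, one right-frontal
referential channel).  All indexing is 0-based with half-open intervals
`[start, start + len)`; the "first half" of a recording (used for
dictionary training) and the "second half" (used for segment encoding)
split at sample `floor(length / 2)` — the split guarantees that
encoded segments come from data the dictionaries never saw, even for
individuals inside the dictionary-training fold.

Peri-ictal data are excluded by expanding each seizure event 300 s
backwards and 3600 s forwards, clipping to the record, and merging
overlaps.  Window and segment samplers draw start positions uniformly
over the admissible range and reject draws intersecting an exclusion
interval (up to 10 000 redraws per window before erroring with the
subject named).  Training-window quotas are split as evenly as
possible across subjects — `floor(total/n)` each, plus one for the
first `total mod n` subjects — so the grand total is exact and every
subject contributes at least the floor share.

## Shift-invariant k-means

The learner follows the assignment / collection / averaging scheme
described in the README.  Numerical choices:

- **Tie-breaking** in the argmax over (waveform k, shift tau): lowest k,
  then lowest tau (realized by flattening the similarity cube k-major
  and taking the first maximum).
- **Degenerate inputs**: a zero-norm sub-window or centroid has cosine
  similarity defined as 0 against everything.
- **Empty clusters** are re-seeded from the first P samples of a
  uniformly drawn training window, using the fit's own seeded generator,
  so runs stay deterministic.
- **All-negative-similarity windows** keep their argmax assignment (the
  assignment formula has no clamp) and therefore still increment the
  winning waveform's count downstream; only the reconstruction scale
  alpha is clamped at 0.
- **Initialization**: first P samples of K uniformly chosen windows
  without replacement.  Stopping: mean squared centroid change per
  point `(1/PK) sum_k ||c_k_prev - c_k||^2 <= 1e-4 * var`, where `var`
  is the variance of all training-window samples pooled (the "pointwise
  variance" read as a scalar), or 300 iterations.
- **Cross-correlations** over all shifts run through an FFT product for
  P >= 64 and direct dot products below; the two paths agree to 1e-8
  relative and the choice is purely a speed heuristic.
- Centroids are stored **unnormalized** (plain averages); cosine
  matching makes downstream use scale-free.

The reconstruction objective
`(1/M) sum_i min_{alpha>=0,k,tau} ||x_i - alpha S_tau(c_k)||^2` is
computed from the closed form
`||x||^2 - max_{k,tau} max(0, <W_tau(x), c_k>)^2 / ||c_k||^2`.  Note the
assignment step optimizes cosine similarity, not this squared error, so
the full objective need not decrease monotonically across iterations;
what is guaranteed (and tested) is that the averaging update cannot
increase the fixed-assignment unscaled error.

## Featurization

Bag-of-waves encoding uses non-overlapping L-sample windows by default
(trailing remainder discarded), assigning each window independently
under every class dictionary, so each dictionary's count block sums
exactly to the window count M.  A strided-window variant (stride
`L - P + 1` examines every possible shift) is available but off by
default.  TFIDF uses the natural logarithm and the smooth (+1)
convention; the transform is checked against scikit-learn's
`TfidfTransformer` in the tests.  All-zero bags produce a zero vector
with a warning rather than an error.  The bag-of-spectra baseline
clusters unit-norm one-sided FFT magnitude vectors (FFT length = window
length) with ordinary Euclidean k-means; on unit-norm vectors the
Euclidean and cosine orderings coincide.  Soft-counted waveform (SCW)
features slide mean-removed, l1-normalized waveforms over every sample
offset of the raw segment, with ties in the per-offset argmax broken by
lowest waveform index.

## Classification protocol

Models are scikit-learn logistic regressions (lbfgs, tol 1e-6,
unpenalized intercepts) over TFIDF features; grid values are treated as
the *inverse* regularization strength C (larger = weaker penalty), with
a default grid of 15 log-spaced values in [0.1, 10^4].  Classes are
weighted inversely to their frequency.  This last choice matters on
small cohorts: the leave-one-out protocol makes every training set
exactly one subject short of balance against the held-out individual,
and an unweighted fit lets the intercept encode that complement — with
weak features this *systematically inverts* predictions (a 12-subject
null cohort scores near 0 rather than near chance).  With balanced
weights, null cohorts score within binomial noise of chance and
separable cohorts are unaffected.

Hyperparameter selection: stratified group K-fold (grouping key =
subject, stratification label = task target, K_CV = 3) over training
subjects *outside* the dictionary fold; each fold's models train on the
dictionary subjects plus the other folds, with TFIDF refit on exactly
that training set.  Selection is by highest mean per-individual pooled
accuracy, ties broken by mean segment-wise accuracy, residual ties by
the smallest grid value.  When a class has fewer members than K_CV the
fold builder falls back to a label-interleaved round-robin partition of
subjects (still grouped by subject); single-class validation folds are
regenerated with a new seed when a multi-class draw exists and
otherwise retained with a warning — pooled accuracy remains defined on
them.

Per-individual prediction pools raw counts across segments before the
TFIDF transform (mean pooling of raw features for the dense SCW path);
binary decisions threshold at 0.5.  The factorized joint prediction
multiplies the strain distribution by the per-strain conditional
disease-genotype distributions.  A hard error is raised if a held-out
subject is found in any training structure.

## Evaluation and interpretation

Corrected resampled-t intervals use `1/n_splits` (generalizing the 1/5
term), the n-1 sample standard deviation, and the t quantile at
`df = n_splits - 1`; the formula is scale-equivariant so percent and
fraction inputs both work.  Confusion matrices put true classes on
rows.  AUC counts score ties as 1/2 (Mann-Whitney); merged ROC pools
score-label pairs across splits, skipping single-class splits with a
warning.

Shapley values use each LOO model's own coefficients, and ACSSV centers
each feature on the mean of the *pooled, transformed* per-subject
feature vectors of that model's training subjects (cached per model).
Waveform spectra use Welch with segment length `round(0.95 P)` and
overlap `round(0.90 P)` (for P = 256: two 243-sample Hann tapers at
offsets 0 and 13), zero-padded to 1024; peak-frequency search skips
bins below the 1 Hz acquisition high-pass.  Occurrence rates are
counts/minute within class, outside class, and overall.  The ranked
waveform report keeps positive-mean-coefficient features, sorts by
ACSSV descending, and annotates whether the feature's Shapley values
correlate positively or negatively with the class.

## Synthetic cohorts: what they emulate and what they do not

The generator realizes exactly the generative model the method assumes:
unit-norm canonical waveforms (Hann-windowed sinusoid rhythms; Gabor or
biphasic-spike transients), planted at Poisson event times without
overlapping supports, scaled by log-normal draws, in white (optionally
1/f-shaped) Gaussian noise.  Class structure lives purely in
per-genotype occurrence-rate vectors, mirroring the finding that
disease genotypes are marked by elevated rates of transients and
wild-types by elevated rates of rhythms.  SNR is defined as planted-
event RMS over the noise standard deviation within the event support.

Default desk-scale conditions, chosen once: 12 subjects in 2 genotypes,
2 h of recording per subject, 64 Hz sampling with P = 64 (1 s waveforms)
in L = 128 windows, K = 8 waveforms per dictionary, 4-waveform banks
with pairwise shift-max |cosine| <= 0.6, event SNR 5, 1500 training
windows and 144 five-minute segments per genotype.  These keep the full
pipeline under ~10 s while preserving the operating regime that matters:
the contrast-to-noise of a count feature grows like the square root of
the recording hours, so a rate contrast that is overwhelming over the
motivating studies' 100+ hour recordings must be represented at desk
scale either by more hours or by a larger rate contrast.  The
"strongly separated" test cohort uses symmetric signature waveforms at
2.0 vs 0.2 events/min; a single-signature 1.0-vs-0.1 contrast at desk
scale is only moderately separated (LOO accuracy ~0.75) and is tested
as above-chance rather than near-perfect.

What passing these tests does *not* show about real EEG: the generator
has no sleep architecture, no artifacts, no non-stationarity, no
between-subject waveform-shape variability, and events never overlap —
so recovery and accuracy here are upper bounds on what identically
configured runs would achieve on animal data.

## Known limitations

- K-means local optima: with K equal to the planted-waveform count the
  learner sometimes merges similar shapes (especially rhythm pairs more
  than ~0.8-cosine similar at best shift); slack centroids (K = planted
  + 4 at desk scale) make recovery reliable.
- The LOO protocol on small cohorts is pessimistically biased even with
  balanced class weights; below-chance accuracies on weak features are
  a property of the protocol, not a bug.
- Multichannel recordings, resampling, filtering and artifact rejection
  are out of scope; recordings are assumed pre-filtered.
- EDF files can be read (via mne) but not written; NPZ is the native
  recording container.
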