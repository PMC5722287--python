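# Methods

## Signal model and preprocessing

A `Recording` is a channels × samples matrix in microvolts with a
sampling rate, an ordered 10–20 montage and a state label
(`normal` / `fatigue`). Preprocessing applies a zero-phase IIR notch at
50 Hz (quality factor 30) and a zero-phase order-4 Butterworth band-pass
0.15–45 Hz, then cuts non-overlapping 1 s epochs from sample 0,
discarding the trailing partial window, so a recording of duration T
yields exactly ⌊T⌋ epochs. Zero-phase (forward–backward) filtering was
chosen so that filtering never shifts epoch boundaries; the specific
filter family and orders are this package's choice — the defaults are
conventional EEG practice and are recorded in every pipeline report.
Note that the 0.15 Hz high-pass edge rings for several seconds, so
attenuation measurements (and any steady-state analysis) should skip the
first and last few seconds of a filtered recording; the tests measure
the central 40 % of a 30 s signal.

## Entropy features

Four per-channel, per-epoch statistics quantify regularity. The
embedding entropies (AE, SE, FE) share the embedding dimension m = 2,
Chebyshev template distance, and tolerance r = 0.2 × SD recomputed from
each epoch's own standard deviation — which makes all three invariant to
offset and amplitude scaling of the epoch.

* **Spectral entropy (PE)**: Shannon entropy of the periodogram of the
  full epoch restricted to 0.15–45 Hz (DC excluded by the band), divided
  by log of the included bin count so that PE ∈ [0, 1]. A periodogram
  (not Welch) is used so that a 1 s epoch keeps 1 Hz resolution.
* **Approximate entropy (AE)**: Φ^m(r) − Φ^(m+1)(r) with self-matches
  included; defined and 0 on constant series.
* **Sample entropy (SE)**: −ln(A/B) over the first N−m templates at both
  lengths, self-matches excluded. Degenerate cases return finite
  sentinels with a warning: 0 when no m-length pair matches, ln(B) (the
  −ln(1/B) upper bound) when only the (m+1)-length count is zero — so
  feature matrices stay finite.
* **Fuzzy entropy (FE)**: templates are mean-centered and pair
  similarity is exp(−(d/r)^n) with gradient n = 2 (a standard choice;
  configurable), FE = ln φ^m − ln φ^(m+1).

AR comparison features are Yule–Walker coefficient estimates (biased
autocovariances, series demeaned) of order 10 by default; the innovation
variance is not a feature. A constant epoch yields a zero coefficient
vector with a warning. With 30 channels the AR mode produces
30 × order = 300 columns — the feature dimension is simply channels ×
order, unlike entropy fusion's channels × 4.

Features are fused by concatenation in channel-major, measure-minor
order (ch1: PE, AE, SE, FE; ch2: …). Column provenance (channel,
measure) is carried through all downstream column subsetting. Min-max
normalization to [−1, 1] is applied per feature column and, by default,
per subject; a constant column maps to the range midpoint. Inside any
cross-validation, normalization statistics are fit on training rows only
and applied to held-out rows (a leakage guard); a subject absent from
the training rows falls back to pooled statistics.

## Classifiers and evaluation

Four classifier families are wrapped behind one spec: RBF-SVM
(c = 2⁻¹, g = 2⁻⁵ by default; a log₂-lattice grid search with c
exponents −5…15 and g exponents −15…3 in steps of 2 is provided, ties
resolved toward the smallest c then g), a single-hidden-layer
feedforward network (20 logistic units trained with a quasi-Newton
batch optimizer), a random forest (500 trees, 22 candidate variables
per split clipped to the feature count), and KNN (5 neighbors).
Stochastic classifiers are refit over a configurable number of seeded
restarts (default 5) and their metrics averaged.

Leave-one-out cross-validation pools one held-out prediction per unit
into a single confusion matrix; metrics are Acc, Sn and Sp in percent
with fatigue as the positive class. The CV unit may be the epoch or the
subject. A caveat discovered during validation and worth knowing: with
*exactly class-balanced* epochs, epoch-unit LOO is structurally biased
at the null — deleting one epoch leaves the opposite class as the
training majority, and a majority-leaning classifier then mispredicts
every held-out epoch, driving null accuracy toward 0 % rather than
50 %. Subject-unit LOO keeps training folds balanced and behaves at
chance under the null, so the end-to-end sanity checks use subject-unit
folds. ROC and PR curves are computed over all score thresholds with
trapezoidal areas; the ROC area coincides with the Mann–Whitney rank
statistic.

## Electrode weighting

For N electrodes, single accuracies Acc(i) (only electrode i's feature
columns) and pairwise accuracies Acc(ij) (union of both electrodes'
columns, symmetric by construction) are computed under one fixed
classifier and CV protocol, and each electrode is scored

V_i = Acc(i) + Σ_{j≠i} (Acc(ij) + Acc(i) − Acc(j)) / N.

Accuracies enter as fractions in [0, 1]; the divisor is the electrode
count, generalizing the fixed 30-channel montage. Ranking is by
descending V with ties broken by montage order (stable sort). For scalp
display the weights are min-max rescaled to [0, 1], values below a 0.8
threshold are zeroed, the threshold is subtracted from the rest, and the
result is rounded to one decimal — leaving values in {0.0, 0.1, 0.2}.
Scalp regions (A: TP7/T5/P3/CP3, B: FCz, C: T4, D: O1/Oz/T6) are a
configuration mapping, not a geometric inference, and can be overridden.

## Synthetic cohorts

The generator emulates the study layout: 12 subjects, 30 effective
channels (10–20 montage without mastoid references), 1000 Hz, 300 s per
state — those are the defaults of `CohortSpec`. Each channel is a sum of
theta (4–7 Hz) and alpha (8–12 Hz) oscillations and white Gaussian
noise at fixed total power (RMS 10 µV). The one state-dependent
parameter is the *regularity factor* — the oscillatory share of channel
variance — 0.25 in the normal state, raised in the fatigue state by
effect_size × w_c of the headroom up to 0.9, where the channel weight
w_c is 1 on planted electrodes (default T6, P3, TP7, O1) and 0.3
elsewhere. Fatigue is modeled as increased narrowband regularity rather
than raw amplitude because regularity is precisely what the entropy
features measure. Oscillation frequency and phase are redrawn every 1 s
block so the signal is rhythmic without being trivially periodic.
Generation is deterministic in (seed, subject, state); at effect size 0
the two states are draws from the identical distribution.

What the generator does **not** reproduce: 1/f background spectra,
volume conduction and inter-channel correlation, ocular/muscle
artifacts, nonstationary drift, or genuine inter-subject variability
beyond independent noise draws. Passing end-to-end tests therefore
demonstrates that the pipeline recovers the signal property it targets
under controlled conditions — not that real recordings would yield the
same accuracies.

## Problem sizes used in tests and the acceptance run

Desk-scale cohorts keep the full structure (two states per subject,
planted channels, identical processing) at reduced sizes chosen so the
whole validation runs in minutes: classification recovery uses 3
subjects × 8 channels × 15 s per state at 128 Hz (90 epochs); electrode
recovery uses 2 subjects × 12 channels × 15 s with a stratified 50/50
holdout inside the accuracy matrix (the paired evaluations make LOO
needlessly expensive there, and the protocol stays uniform across
singles and pairs). Structural-count checks that depend only on
duration and subject count (300 epochs per 5-minute recording, 3600
epochs per state) run at full duration with a reduced channel count and
sampling rate, which provably leave those counts unchanged. Epoch-level
entropy separation checks use 256-sample epochs because the SE
estimator's own variance at 128 samples blurs paired comparisons.

## Numerical choices and degenerate inputs

Tolerances: oracle equivalence for AE/SE/FE and ROC area is asserted to
1e-10; affine-invariance of the entropies to 1e-9. Constant epochs
return 0 for all four entropies and a zero AR vector. Cross-validation
folds whose training rows lack a class are counted as errors with a
warning rather than aborting the run. EDF output quantizes to 16 bits
against a per-channel physical range chosen to survive the format's
8-character ASCII header fields exactly, so a round trip is accurate to
half a quantization step (~3·10⁻⁵ of the channel range).

## Known limitations

* The electrode weight V is a relative score; its absolute scale grows
  with the uniform accuracy level (uniform 0.9 accuracies give
  V = 1.5 at N = 3), so weights should be compared within one run, and
  the standardized form used for display.
* Epoch-unit LOO at the null is biased on balanced data (see above);
  prefer subject-unit LOO or holdout when estimating chance levels.
* Feedforward-net training uses a quasi-Newton batch optimizer; run-to-
  run variation is controlled by seeding and restart averaging, not
  eliminated.
* The synthetic generator's simplifications listed above mean reported
  accuracies characterize the method, not any real cohort.
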