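# entrofuse

Multiple-entropy-fusion analysis of two-state EEG, built for
driver-fatigue detection research: given multichannel recordings labeled
*normal* or *fatigue*, the package extracts per-channel regularity
features, classifies one-second epochs, and ranks electrodes by how much
fatigue-related information they carry — so a detector can run on a
handful of scalp sites instead of a full cap.

It is aimed at biomedical-signal researchers who want a tested,
scriptable reference implementation of this pipeline, together with a
synthetic cohort generator for end-to-end validation when no recordings
are at hand.

## The method

Recordings (channels × samples, microvolts) are notch-filtered at 50 Hz,
band-passed 0.15–45 Hz (zero-phase), and cut into 1 s epochs. Four
regularity statistics are computed per channel per epoch:

* **Spectral entropy (PE)** — Shannon entropy of the normalized
  periodogram over the analysis band, scaled to [0, 1] by log(#bins).
* **Approximate entropy (AE)** — Pincus's Φ^m(r) − Φ^(m+1)(r) with
  self-matches included.
* **Sample entropy (SE)** — Richman–Moorman's −ln(A/B), self-matches
  excluded.
* **Fuzzy entropy (FE)** — Chen's variant: mean-centered templates and a
  graded membership exp(−(d/r)^n) instead of a hard threshold.

All embedding entropies use Chebyshev distance, m = 2 and tolerance
r = 0.2·SD of the epoch at hand. Yule–Walker autoregressive coefficients
(order 10) are available as a comparison feature set. Features are fused
by channel-major concatenation — 30 channels × 4 measures = 120 columns —
and min-max normalized to [−1, 1] per subject:

    x' = (newMax − newMin) · (x − x_min) / (x_max − x_min) + newMin

Classification (RBF-SVM with c = 2⁻¹, g = 2⁻⁵; feedforward net with 20
hidden units; random forest with 500 trees; KNN) is evaluated by
leave-one-out cross-validation with accuracy, sensitivity and
specificity (fatigue = positive class) plus ROC/PR curves. Electrode i
is scored by

    V_i = Acc(i) + Σ_{j≠i} (Acc(ij) + Acc(i) − Acc(j)) / N

where Acc(i) is its single-electrode accuracy and Acc(ij) the accuracy
of the electrode pair; ranking V gives the reduced montage.

## Worked example

`examples/03_classify_loo.py` generates a small synthetic cohort
(3 subjects, 8 channels, 15 s per state, effect size 0.8), extracts the
fused entropy features and runs subject-wise leave-one-out with the
RBF-SVM:

```
epochs: 90, features: 32
Acc = 100.0%  Sn = 100.0%  Sp = 100.0%
confusion: TP=45 FP=0 TN=45 FN=0
ROC area = 1.000, PR area = 0.997
effect_size 0 control: Acc = 54.4% (chance level)
```

At effect size 0.8 the fatigue state's extra rhythmic regularity
separates the classes perfectly; with the effect removed the same
pipeline falls to chance, confirming there is no leakage.
`examples/04_select_electrodes.py` then ranks 12 electrodes by V and
recovers the four planted high-information sites at the top:

```
top-6 electrodes: ('TP7', 'T6', 'P3', 'O1', 'F4', 'F3')
all planted recovered: True
```

The other examples cover cohort simulation (01), the entropy measures
themselves (02), and the config-driven end-to-end pipeline (05). The
same stages are available on the command line:

```bash
entrofuse simulate --subjects 2 --effect-size 0.8 --seed 0 --out cohort/
entrofuse features cohort/*.tsv --out features.tsv
entrofuse evaluate features.tsv --classifier rbf_svm --cv loo --unit subject
entrofuse select-channels features.tsv --out weights.tsv
entrofuse run --config examples/pipeline_config.yaml
```

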