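"""Accuracy-weight electrode selection.

Not every scalp site carries fatigue-related information. Each
electrode i gets a weight built from classification accuracies obtained
with the same classifier and CV protocol throughout: Acc(i) using only
electrode i's features, and Acc(ij) using the union of electrodes i and
j's features (symmetric by construction). The weight is

    V_i = Acc(i) + sum_{j != i} (Acc(ij) + Acc(i) - Acc(j)) / N

with N the electrode count: an electrode scores high when it classifies
well alone, pairs well with the others, and outperforms them. Ranking V
gives a reduced montage; for display the weights are rescaled to [0, 1]
and thresholded (values below the threshold zeroed, the threshold
subtracted otherwise, one decimal kept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import CVSpec, ClassifierSpec, cv_accuracy
from .features import FeatureMatrix, NormalizationSpec


@dataclass(frozen=True)
class AccuracyMatrix:
    """Single and pairwise per-electrode accuracies (fractions in [0, 1])."""

    single: np.ndarray
    pairwise: np.ndarray
    electrode_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "single", np.asarray(self.single, dtype=float))
        object.__setattr__(self, "pairwise", np.asarray(self.pairwise, dtype=float))
        object.__setattr__(self, "electrode_names", tuple(self.electrode_names))
        n = len(self.electrode_names)
        if self.single.shape != (n,) or self.pairwise.shape != (n, n):
            raise ValueError("accuracy array shapes must match electrode count")
        off = ~np.eye(n, dtype=bool)
        for arr in (self.single, self.pairwise[off]):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("accuracies must lie in [0, 1]")
        if not np.allclose(self.pairwise, self.pairwise.T):
            raise ValueError("pairwise matrix must be symmetric")

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_names)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.pairwise, index=self.electrode_names, columns=self.electrode_names
        )
        np.fill_diagonal(df.values, self.single)
        return df


@dataclass(frozen=True)
class ElectrodeWeights:
    """Per-electrode weight V, optionally with its standardized display form."""

    values: np.ndarray
    electrode_names: tuple[str, ...]
    standardized: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "electrode_names", tuple(self.electrode_names))
        if self.values.shape != (len(self.electrode_names),):
            raise ValueError("one weight per electrode required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("weights must be finite")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.electrode_names, name="V")


def compute_accuracy_matrix(
    fm: FeatureMatrix,
    clf_spec: ClassifierSpec = ClassifierSpec(),
    cv: CVSpec = CVSpec(scheme="holdout"),
    normalization: NormalizationSpec | None = NormalizationSpec(),
) -> AccuracyMatrix:
    """Single- and pairwise-electrode accuracies under one fixed protocol.

    The feature matrix is expected to hold the fused features of all
    electrodes; columns are subset per electrode (single) and per
    unordered pair (union of both electrodes' columns), so every
    accuracy sees identical epochs and identical CV folds.
    """
    electrodes = fm.channels
    n = len(electrodes)
    if n < 2:
        raise ValueError("need at least two electrodes")
    if len(np.unique(fm.labels)) < 2:
        raise ValueError("both classes must be present")
    single = np.array(
        [cv_accuracy(fm.select_channels([e]), clf_spec, cv, normalization) for e in electrodes]
    )
    pairwise = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            acc = cv_accuracy(
                fm.select_channels([electrodes[i], electrodes[j]]),
                clf_spec,
                cv,
                normalization,
            )
            pairwise[i, j] = pairwise[j, i] = acc
    return AccuracyMatrix(single=single, pairwise=pairwise, electrode_names=electrodes)


def electrode_weights(acc: AccuracyMatrix) -> ElectrodeWeights:
    """Weight V_i = Acc(i) + sum_{j != i} (Acc(ij) + Acc(i) - Acc(j)) / N."""
    n = acc.n_electrodes
    v = np.empty(n)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        dev = sum(
            acc.pairwise[i, j] + acc.single[i] - acc.single[j] for j in others
        )
        v[i] = acc.single[i] + dev / n
    return ElectrodeWeights(values=v, electrode_names=acc.electrode_names)


def rank_electrodes(weights: ElectrodeWeights, k: int) -> tuple[str, ...]:
    """Top-k electrodes by descending weight; ties keep montage order."""
    n = len(weights.electrode_names)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    order = np.argsort(-weights.values, kind="stable")
    return tuple(weights.electrode_names[i] for i in order[:k])


def standardize_weights(
    weights: ElectrodeWeights, threshold: float = 0.8
) -> ElectrodeWeights:
    """Rescale V to [0, 1], zero below the threshold, subtract it otherwise.

    The surviving values are rounded to one decimal, the display
    convention for scalp-map export; after a threshold of 0.8 they lie
    in {0.0, 0.1, 0.2}.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    v = weights.values
    span = v.max() - v.min()
    scaled = np.full_like(v, 0.5) if span == 0 else (v - v.min()) / span
    out = np.where(scaled < threshold, 0.0, scaled - threshold)
    out = np.round(out, 1)
    return ElectrodeWeights(
        values=v, electrode_names=weights.electrode_names, standardized=out
    )
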