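"""Feature extraction, concatenation fusion and min-max normalization.

Per epoch, per channel the selected measures are computed and
concatenated channel-major (ch1: PE, AE, SE, FE; ch2: ...), giving
``n_channels * n_measures`` columns for entropy fusion (120 for a
30-channel montage with all four measures) or ``n_channels * order``
columns in AR mode. Features are then min-max rescaled to [-1, 1],
per subject by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .entropy import (
    MEASURES,
    ARSpec,
    EntropyParams,
    approximate_entropy,
    ar_coefficients,
    fuzzy_entropy,
    sample_entropy,
    spectral_entropy,
)
from .preprocessing import EpochSet

MODES = ("entropy_fusion", "entropy_subset", "ar")


@dataclass(frozen=True)
class FeatureMatrix:
    """Epochs x features with per-column (channel, measure) provenance."""

    values: np.ndarray
    feature_index: tuple[tuple[str, str], ...]
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels))
        object.__setattr__(self, "subject_ids", np.asarray(self.subject_ids))
        object.__setattr__(self, "feature_index", tuple(map(tuple, self.feature_index)))
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (epochs x features)")
        if self.values.shape[1] != len(self.feature_index):
            raise ValueError("feature_index length must match column count")
        if len(self.labels) != self.values.shape[0] or len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("labels/subject_ids must match row count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for ch, _ in self.feature_index:
            if ch not in seen:
                seen.append(ch)
        return tuple(seen)

    def select_channels(self, names: Sequence[str]) -> "FeatureMatrix":
        """Restrict columns to the given channels (order preserved)."""
        names = list(names)
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"channels not present in feature matrix: {missing}")
        cols = [i for i, (ch, _) in enumerate(self.feature_index) if ch in names]
        return FeatureMatrix(
            values=self.values[:, cols],
            feature_index=[self.feature_index[i] for i in cols],
            labels=self.labels,
            subject_ids=self.subject_ids,
        )

    def select_rows(self, idx) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[idx],
            feature_index=self.feature_index,
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{ch}|{meas}" for ch, meas in self.feature_index]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "state", self.labels)
        return df

    @staticmethod
    def from_dataframe(df: pd.DataFrame) -> "FeatureMatrix":
        meta = {"subject_id", "state"}
        feat_cols = [c for c in df.columns if c not in meta]
        index = []
        for c in feat_cols:
            if "|" not in c:
                raise ValueError(f"feature column {c!r} lacks 'channel|measure' form")
            ch, meas = c.split("|", 1)
            index.append((ch, meas))
        return FeatureMatrix(
            values=df[feat_cols].to_numpy(dtype=float),
            feature_index=index,
            labels=df["state"].to_numpy(),
            subject_ids=df["subject_id"].to_numpy(),
        )


def _entropy_row(epoch: np.ndarray, fs: float, measures, params: EntropyParams) -> list[float]:
    out = []
    for ch in epoch:
        for meas in measures:
            if meas == "PE":
                out.append(spectral_entropy(ch, fs))
            elif meas == "AE":
                out.append(approximate_entropy(ch, params))
            elif meas == "SE":
                out.append(sample_entropy(ch, params))
            elif meas == "FE":
                out.append(fuzzy_entropy(ch, params))
            else:
                raise ValueError(f"unknown measure {meas!r}")
    return out


def extract_feature_matrix(
    epochs: EpochSet,
    mode: str = "entropy_fusion",
    measures: Sequence[str] | None = None,
    entropy_params: EntropyParams = EntropyParams(),
    ar_spec: ARSpec = ARSpec(),
) -> FeatureMatrix:
    """Compute per-channel features for every epoch and fuse by concatenation.

    Parameters
    ----------
    epochs : EpochSet
    mode : {"entropy_fusion", "entropy_subset", "ar"}
        ``entropy_fusion`` uses all four measures (PE, AE, SE, FE);
        ``entropy_subset`` uses the non-empty subset in ``measures``;
        ``ar`` uses Yule-Walker AR coefficients of order
        ``ar_spec.order`` per channel.
    """
    if epochs.n_epochs == 0:
        raise ValueError("empty epoch set")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "entropy_fusion":
        measures = MEASURES
    elif mode == "entropy_subset":
        if not measures:
            raise ValueError("entropy_subset mode needs a non-empty measure list")
        bad = [m for m in measures if m not in MEASURES]
        if bad:
            raise ValueError(f"unknown measures {bad}; valid: {MEASURES}")
        measures = tuple(measures)

    if mode == "ar":
        index = [
            (ch, f"AR{k + 1}")
            for ch in epochs.channel_names
            for k in range(ar_spec.order)
        ]
        rows = [
            np.concatenate([ar_coefficients(chan, ar_spec) for chan in epoch])
            for epoch in epochs.epochs
        ]
    else:
        index = [(ch, meas) for ch in epochs.channel_names for meas in measures]
        rows = [
            _entropy_row(epoch, epochs.fs, measures, entropy_params)
            for epoch in epochs.epochs
        ]
    return FeatureMatrix(
        values=np.asarray(rows, dtype=float),
        feature_index=index,
        labels=epochs.labels,
        subject_ids=epochs.subject_ids,
    )


@dataclass(frozen=True)
class NormalizationSpec:
    """Min-max rescaling target range; per-subject fitting by default."""

    new_min: float = -1.0
    new_max: float = 1.0
    per_subject: bool = True

    def __post_init__(self) -> None:
        if not self.new_min < self.new_max:
            raise ValueError("new_min must be below new_max")


class MinMaxNormalizer:
    """Column-wise min-max rescaling x' = (newMax-newMin)(x-xmin)/(xmax-xmin)+newMin.

    Statistics (x_min, x_max) are learned from the rows passed to
    :meth:`fit` only — fit on training rows, apply to held-out rows to
    avoid leakage. With ``per_subject`` set, statistics are kept per
    subject; a subject unseen at fit time falls back to the pooled
    statistics. A constant column maps to the midpoint of the target
    range.
    """

    def __init__(self, spec: NormalizationSpec = NormalizationSpec()):
        self.spec = spec
        self._stats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._pooled: tuple[np.ndarray, np.ndarray] | None = None

    def fit(self, fm: FeatureMatrix) -> "MinMaxNormalizer":
        self._pooled = (fm.values.min(axis=0), fm.values.max(axis=0))
        self._stats = {}
        if self.spec.per_subject:
            for sid in np.unique(fm.subject_ids):
                rows = fm.values[fm.subject_ids == sid]
                self._stats[str(sid)] = (rows.min(axis=0), rows.max(axis=0))
        return self

    def _rescale(self, block: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        span = hi - lo
        mid = 0.5 * (self.spec.new_min + self.spec.new_max)
        out = np.full_like(block, mid)
        ok = span > 0
        scale = (self.spec.new_max - self.spec.new_min) / np.where(ok, span, 1.0)
        out[:, ok] = (
            (block[:, ok] - lo[ok]) * scale[ok] + self.spec.new_min
        )
        return out

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if self._pooled is None:
            raise RuntimeError("normalizer is not fitted")
        out = np.empty_like(fm.values)
        if self.spec.per_subject:
            for sid in np.unique(fm.subject_ids):
                mask = fm.subject_ids == sid
                lo, hi = self._stats.get(str(sid), self._pooled)
                out[mask] = self._rescale(fm.values[mask], lo, hi)
        else:
            lo, hi = self._pooled
            out[:] = self._rescale(fm.values, lo, hi)
        return replace(fm, values=out)


def minmax_normalize(
    fm: FeatureMatrix, spec: NormalizationSpec = NormalizationSpec()
) -> FeatureMatrix:
    """Fit-and-transform convenience for exploratory use (no train/test split)."""
    return MinMaxNormalizer(spec).fit(fm).transform(fm)
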