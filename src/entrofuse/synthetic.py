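"""Synthetic two-state multichannel EEG-like cohorts.

Each channel is a sum of band-limited rhythms (theta 4-7 Hz, alpha
8-12 Hz by default) and broadband Gaussian noise at a fixed total
power. The *regularity factor* — the fraction of channel variance
carried by the rhythms — is the single state-dependent quantity:
in the fatigue state it rises by ``effect_size * w_c`` of the available
headroom, where the channel weight ``w_c`` is 1 on planted
high-information electrodes and a small background weight elsewhere.
More rhythmic variance means a more predictable signal, so all four
entropy measures drop on affected channels — the signal property the
downstream features measure, modeled directly rather than through
amplitude alone.

Rhythm frequency and phase are redrawn every one-second block so the
signal is oscillatory without being trivially periodic. Everything is
reproducible from ``(seed, subject, state)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .montage import CHANNELS_30
from .preprocessing import Recording, STATES


@dataclass(frozen=True)
class StateParams:
    """Rhythm and noise structure shared by both states.

    ``base_regularity`` is the oscillatory variance fraction in the
    normal state; ``max_regularity`` caps what a fully affected channel
    reaches in the fatigue state.
    """

    bands: tuple[tuple[str, float, float], ...] = (
        ("theta", 4.0, 7.0),
        ("alpha", 8.0, 12.0),
    )
    base_regularity: float = 0.25
    max_regularity: float = 0.9
    background_weight: float = 0.3
    rms_uv: float = 10.0
    block_s: float = 1.0

    def __post_init__(self) -> None:
        for name, lo, hi in self.bands:
            if not 0 < lo < hi:
                raise ValueError(f"band {name!r} has invalid range ({lo}, {hi})")
        if not 0 <= self.base_regularity < self.max_regularity <= 1:
            raise ValueError("need 0 <= base_regularity < max_regularity <= 1")
        if not 0 <= self.background_weight <= 1:
            raise ValueError("background_weight must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Study-layout parameters: 12 subjects, 30 channels, 1000 Hz, 5 min
    per state by default."""

    n_subjects: int = 12
    channel_names: tuple[str, ...] = CHANNELS_30
    fs: float = 1000.0
    duration_s: float = 300.0
    effect_size: float = 0.8
    planted_electrodes: tuple[str, ...] = ("T6", "P3", "TP7", "O1")
    state_params: StateParams = field(default_factory=StateParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.effect_size <= 1:
            raise ValueError("effect_size must lie in [0, 1]")
        missing = [e for e in self.planted_electrodes if e not in self.channel_names]
        if missing:
            raise ValueError(f"planted electrodes not in montage: {missing}")
        for _, lo, hi in self.state_params.bands:
            if hi >= self.fs / 2:
                raise ValueError(f"band edge {hi} Hz at or above Nyquist ({self.fs / 2})")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def subject_ids(self) -> tuple[str, ...]:
        return tuple(f"sub{k + 1:02d}" for k in range(self.n_subjects))


def _regularity(spec: CohortSpec, channel: str, state: str) -> float:
    sp = spec.state_params
    if state == "normal":
        return sp.base_regularity
    w = 1.0 if channel in spec.planted_electrodes else sp.background_weight
    return sp.base_regularity + spec.effect_size * w * (
        sp.max_regularity - sp.base_regularity
    )


def generate_recording(subject_id: str, state: str, spec: CohortSpec) -> Recording:
    """One recording for one subject in one state.

    Deterministic in ``(spec.seed, subject index, state)``; at
    ``effect_size = 0`` both states draw from the identical
    distribution.
    """
    if state not in STATES:
        raise ValueError(f"state must be one of {STATES}")
    ids = spec.subject_ids()
    if subject_id not in ids:
        raise ValueError(f"unknown subject {subject_id!r}; cohort has {ids}")
    ss = np.random.SeedSequence(
        [spec.seed, ids.index(subject_id), STATES.index(state)]
    )
    rng = np.random.default_rng(ss)
    sp = spec.state_params
    n_samples = int(round(spec.duration_s * spec.fs))
    block = max(1, int(round(sp.block_s * spec.fs)))
    n_blocks = -(-n_samples // block)  # ceil
    n_ch, n_bands = spec.n_channels, len(sp.bands)
    total_var = sp.rms_uv ** 2

    # per-block random frequency within band and random phase
    lows = np.array([b[1] for b in sp.bands])
    highs = np.array([b[2] for b in sp.bands])
    freqs = rng.uniform(lows, highs, size=(n_blocks, n_ch, n_bands))
    phases = rng.uniform(0, 2 * np.pi, size=(n_blocks, n_ch, n_bands))
    t = np.arange(block) / spec.fs
    waves = np.sin(
        2 * np.pi * freqs[..., None] * t + phases[..., None]
    )  # (blocks, ch, bands, block)

    q = np.array([_regularity(spec, ch, state) for ch in spec.channel_names])
    band_var = q * total_var / n_bands  # equal split across rhythms
    amp = np.sqrt(2.0 * band_var)  # sinusoid of amplitude a has variance a^2/2
    osc = (waves * amp[None, :, None, None]).sum(axis=2)
    osc = osc.transpose(1, 0, 2).reshape(n_ch, n_blocks * block)[:, :n_samples]
    noise = rng.standard_normal((n_ch, n_samples)) * np.sqrt(
        (1.0 - q)[:, None] * total_var
    )
    return Recording(
        subject_id=subject_id,
        state=state,
        signal=osc + noise,
        fs=spec.fs,
        channel_names=spec.channel_names,
    )


def iter_cohort(spec: CohortSpec) -> Iterator[Recording]:
    """Yield one normal and one fatigue recording per subject, in order."""
    for sid in spec.subject_ids():
        for state in STATES:
            yield generate_recording(sid, state, spec)


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Materialize the whole cohort (2 recordings per subject)."""
    return list(iter_cohort(spec))


def desk_spec(
    seed: int = 0,
    effect_size: float = 0.8,
    n_subjects: int = 2,
    n_channels: int = 8,
    fs: float = 128.0,
    duration_s: float = 20.0,
) -> CohortSpec:
    """A small cohort for fast experiments and worked examples.

    The montage keeps the four default planted electrodes and fills the
    remaining slots with midline/background sites. Structure (two
    states per subject, per-channel effects, rhythm model) is identical
    to the full-size default; only the sizes shrink.
    """
    background = [c for c in ("Fz", "Cz", "T4", "Oz", "F3", "F4", "C3", "C4",
                              "P4", "Pz", "O2", "FCz") ]
    planted = ("T6", "P3", "TP7", "O1")
    if n_channels < len(planted) + 1:
        raise ValueError("desk montage needs room for the planted electrodes")
    names = tuple(background[: n_channels - len(planted)]) + planted
    return CohortSpec(
        n_subjects=n_subjects,
        channel_names=names,
        fs=fs,
        duration_s=duration_s,
        effect_size=effect_size,
        planted_electrodes=planted,
        seed=seed,
    )
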