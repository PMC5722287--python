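"""Default 10-20 electrode montage and scalp-region groupings.

The default montage is the 30 effective channels of a 32-channel cap
(linked-mastoid references A1/A2 excluded), using old-nomenclature
temporal labels (T3/T4, T5/T6).
"""

from __future__ import annotations

#: 30 effective scalp channels, cap order (frontal to occipital).
CHANNELS_30: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T3", "C3", "Cz", "C4", "T4",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)

#: Scalp regions used for reduced-montage evaluation. A and D cover the
#: left and middle posterior cortex, B the midline central strip, C the
#: right temporal area. Supplied as configuration, not derived from
#: electrode geometry; override freely.
DEFAULT_REGIONS: dict[str, tuple[str, ...]] = {
    "A": ("TP7", "T5", "P3", "CP3"),
    "B": ("FCz",),
    "C": ("T4",),
    "D": ("O1", "Oz", "T6"),
}


def validate_channels(names: tuple[str, ...], montage: tuple[str, ...] = CHANNELS_30) -> None:
    """Raise ValueError if any name is absent from the montage."""
    unknown = [n for n in names if n not in montage]
    if unknown:
        raise ValueError(f"channels not in montage: {unknown}")
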