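"""Readers and writers for recordings, feature tables and reports.

Two recording formats are supported: European Data Format (EDF, 16-bit)
and a plain delimited dialect (one tab-separated row per channel) — in
both cases a JSON sidecar ``<stem>.json`` next to the data file carries
the sampling rate, channel names, subject id and state label, since
neither format has a standard slot for a vigilance-state label. EDF
files are read through MNE; writing uses a small built-in EDF writer
(16-bit quantization against per-channel physical ranges).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .preprocessing import Recording
from .selection import AccuracyMatrix, ElectrodeWeights


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_sidecar(rec: Recording, path: Path) -> None:
    meta = {
        "subject_id": rec.subject_id,
        "state": rec.state,
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"sidecar header {sc} not found")
    meta = json.loads(sc.read_text())
    for key in ("fs", "channel_names"):
        if key not in meta:
            raise ValueError(f"sidecar {sc} missing required field {key!r}")
    return meta


def write_recording(rec: Recording, path: str | Path, fmt: str | None = None) -> Path:
    """Write a recording as delimited text or EDF, plus its JSON sidecar.

    Format is inferred from the extension (``.edf`` vs anything else)
    unless ``fmt`` is given explicitly.
    """
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "delimited")
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "delimited":
        np.savetxt(path, rec.signal, delimiter="\t", fmt="%.6f")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    _write_sidecar(rec, path)
    return path


def read_recording(path: str | Path, state: str | None = None) -> Recording:
    """Read a recording (EDF or delimited) with its sidecar metadata.

    ``state`` overrides or supplies the vigilance-state label; a missing
    label is an error because every downstream step needs it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        signal, fs, names = _read_edf(path)
        meta: dict = {}
        if _sidecar_path(path).exists():
            meta = json.loads(_sidecar_path(path).read_text())
    else:
        meta = _read_sidecar(path)
        signal = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
        fs = float(meta["fs"])
        names = tuple(meta["channel_names"])
        if signal.shape[0] != len(names):
            raise ValueError(
                f"{path}: {signal.shape[0]} signal rows but "
                f"{len(names)} channel names in sidecar"
            )
    state = state or meta.get("state")
    if state is None:
        raise ValueError(
            f"{path}: state label required (no sidecar label and no override)"
        )
    return Recording(
        subject_id=str(meta.get("subject_id", path.stem)),
        state=state,
        signal=signal,
        fs=fs,
        channel_names=names,
    )


def _pad(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _header_range(value: float) -> float:
    """Smallest 8-char-representable number >= value."""
    for digits in (6, 5, 4, 3):
        for candidate in (value, value * 1.01):
            s = f"{candidate:.{digits}g}"
            if len(s) <= 7 and float(s) >= value:  # leave room for a sign
                return float(s)
    return float(f"{value * 1.01:.1e}")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: 1-second data records, 16-bit samples."""
    fs_int = int(round(rec.fs))
    if abs(rec.fs - fs_int) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = rec.n_samples // fs_int
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    if n_records * fs_int != rec.n_samples:
        warnings.warn("EDF writer truncating trailing partial second")
    data = rec.signal[:, : n_records * fs_int]
    ns = rec.n_channels
    # physical range must survive the 8-char ASCII header field exactly,
    # so quantize against the value the header will actually carry
    phys_max = np.array(
        [_header_range(m) for m in np.maximum(np.abs(data).max(axis=1), 1e-6)]
    )
    scale = phys_max / 32767.0
    digital = np.clip(np.round(data / scale[:, None]), -32767, 32767).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad(rec.subject_id, 80),
            _pad(f"state={rec.state}", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + ns)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    sig = b"".join(_pad(n, 16) for n in rec.channel_names)
    sig += b"".join(_pad("", 80) for _ in range(ns))  # transducer
    sig += b"".join(_pad("uV", 8) for _ in range(ns))
    sig += b"".join(_pad(f"{-m:g}", 8) for m in phys_max)
    sig += b"".join(_pad(f"{m:g}", 8) for m in phys_max)
    sig += b"".join(_pad("-32767", 8) for _ in range(ns))
    sig += b"".join(_pad("32767", 8) for _ in range(ns))
    sig += b"".join(_pad("", 80) for _ in range(ns))  # prefiltering
    sig += b"".join(_pad(str(fs_int), 8) for _ in range(ns))
    sig += b"".join(_pad("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header + sig)
        # records: for each record, all samples of signal 1, then signal 2, ...
        rec3 = digital.reshape(ns, n_records, fs_int).transpose(1, 0, 2)
        fh.write(rec3.tobytes())


def _read_edf(path: Path):
    import mne  # deferred: heavy import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # MNE returns volts for uV-dimensioned channels
    return signal, float(raw.info["sfreq"]), tuple(raw.ch_names)


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    fm.to_dataframe().to_csv(path, sep="\t", index=False)
    return path


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    return FeatureMatrix.from_dataframe(pd.read_csv(path, sep="\t"))


def write_accuracy_matrix(acc: AccuracyMatrix, path: str | Path) -> Path:
    path = Path(path)
    acc.to_dataframe().to_csv(path, sep="\t", index_label="electrode")
    return path


def write_weights(weights: ElectrodeWeights, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"electrode": weights.electrode_names, "V": weights.values})
    if weights.standardized is not None:
        df["standardized"] = weights.standardized
    df.to_csv(path, sep="\t", index=False)
    return path


def read_weights(path: str | Path) -> ElectrodeWeights:
    df = pd.read_csv(path, sep="\t")
    return ElectrodeWeights(
        values=df["V"].to_numpy(),
        electrode_names=tuple(df["electrode"]),
        standardized=df["standardized"].to_numpy() if "standardized" in df else None,
    )


def write_report(report_dict: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report_dict, indent=1, sort_keys=True))
    return path
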