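"""Reading and writing multichannel EEG recordings.

A :class:`Recording` is the package's uniform in-memory representation of a
multichannel intracranial EEG signal: a ``channels x samples`` float matrix in
microvolts, a sampling rate, ordered channel names, and (optionally) an
epileptogenesis stage label and subject identifier.

Two interchange formats are supported:

* **CSV** — one header line of channel names, then one row per sample
  (columns = channels). The sampling rate is not representable in CSV and must
  be supplied by the caller on read.
* **EDF** (European Data Format) — read through :mod:`mne`; written by a
  minimal 16-bit EDF writer with one-second data records. The subject id and
  stage label are stored in the EDF patient / recording identification fields
  and recovered on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Stage",
    "Recording",
    "CANONICAL_CHANNELS",
    "read_recording",
    "write_recording",
    "FormatError",
    "ConfigurationError",
]

#: Hippocampal / reference electrode montage used throughout the package:
#: bilateral CA1, CA3, dentate gyrus, plus two neocortical reference channels.
CANONICAL_CHANNELS = ["CA1L", "CA1R", "CA3L", "CA3R", "DGL", "DGR", "Ref1", "Ref2"]

#: Physical range (microvolts) assumed when quantizing to 16-bit EDF samples.
EDF_PHYSICAL_RANGE_UV = 5000.0

_EDF_DIG_MIN = -32768
_EDF_DIG_MAX = 32767


class FormatError(ValueError):
    """Malformed input file (ragged rows, bad header, ...)."""


class ConfigurationError(ValueError):
    """Missing or inconsistent configuration (e.g. CSV without a sampling rate)."""


class Stage(str, Enum):
    """Epileptogenesis stage of a recording.

    ``NORMAL`` is the pre-insult baseline, ``ACUTE`` the status-epilepticus
    period, and ``CHRONIC`` the later period of spontaneous recurrent
    seizures. Class indices (0/1/2) follow this order everywhere.
    """

    NORMAL = "normal"
    ACUTE = "acute"
    CHRONIC = "chronic"
    UNKNOWN = "unknown"

    @property
    def class_index(self) -> int:
        if self is Stage.UNKNOWN:
            raise ValueError("unknown stage has no class index")
        return {"normal": 0, "acute": 1, "chronic": 2}[self.value]

    @classmethod
    def from_index(cls, idx: int) -> "Stage":
        return [cls.NORMAL, cls.ACUTE, cls.CHRONIC][int(idx)]

    @classmethod
    def coerce(cls, value) -> "Stage":
        if isinstance(value, Stage):
            return value
        if value is None:
            return cls.UNKNOWN
        return cls(str(value).strip().lower())


@dataclass
class Recording:
    """A labeled multichannel signal (``channels x samples``, microvolts)."""

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=lambda: list(CANONICAL_CHANNELS))
    stage: Stage = Stage.UNKNOWN
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] < 1:
            raise ValueError("a Recording needs at least one channel")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        self.stage = Stage.coerce(self.stage)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data)


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("edf", "csv"):
            raise ConfigurationError(f"unsupported format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise ConfigurationError(f"cannot infer format from suffix {suffix!r}")


def read_recording(
    path,
    format: Optional[str] = None,
    fs_override: Optional[float] = None,
    stage=None,
    subject_id: Optional[str] = None,
) -> Recording:
    """Read an EDF or CSV recording into a :class:`Recording`.

    CSV files are rows = samples, columns = channels, with a one-line header
    of channel names; they carry no sampling rate, so ``fs_override`` is
    required. For EDF the rate comes from the header and ``fs_override`` is
    ignored. ``stage`` / ``subject_id`` override whatever the file carries.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "csv":
        if fs_override is None:
            raise ConfigurationError("CSV carries no sampling rate; pass fs_override")
        rec = _read_csv(path, fs_override)
    else:
        rec = _read_edf(path)
        if fs_override is not None:
            rec = replace(rec, fs=float(fs_override))
    if stage is not None:
        rec = replace(rec, stage=Stage.coerce(stage))
    if subject_id is not None:
        rec = replace(rec, subject_id=subject_id)
    return rec


def write_recording(rec: Recording, path, format: Optional[str] = None) -> None:
    """Write a :class:`Recording` to CSV (full float precision) or EDF.

    EDF quantizes to 16 bits over a fixed +/-5000 uV physical range, so the
    round-trip error is bounded by one quantization step
    (``2 * 5000 / 65535`` uV).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(rec, path)
    else:
        _write_edf(rec, path)


# ---------------------------------------------------------------------------
# CSV

def _read_csv(path: Path, fs: float) -> Recording:
    try:
        df = pd.read_csv(path, header=0, dtype=float)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"malformed CSV {path}: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"ragged or non-numeric rows in {path}")
    names = [str(c) for c in df.columns]
    return Recording(df.to_numpy().T, fs=fs, channel_names=names)


def _write_csv(rec: Recording, path: Path) -> None:
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# EDF

def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw + b" " * (width - len(raw))


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: 16-bit samples, one-second data records.

    Requires an integer sampling rate (samples per 1-s record must be a
    whole number). Samples are clipped to the +/-5000 uV physical range.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ConfigurationError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per channel
    n_full = rec.n_samples // spr
    remainder = rec.n_samples - n_full * spr
    n_records = n_full + (1 if remainder else 0)
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    nch = rec.n_channels

    pmin, pmax = -EDF_PHYSICAL_RANGE_UV, EDF_PHYSICAL_RANGE_UV
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)

    now = datetime(2000, 1, 1)
    header = io.BytesIO()
    header.write(_pad("0", 8))
    header.write(_pad(rec.subject_id or "X", 80))
    header.write(_pad(f"Startdate 01-JAN-2000 stage={rec.stage.value}", 80))
    header.write(_pad(now.strftime("%d.%m.%y"), 8))
    header.write(_pad(now.strftime("%H.%M.%S"), 8))
    header.write(_pad(str(256 * (1 + nch)), 8))
    header.write(_pad("", 44))
    header.write(_pad(str(n_records), 8))
    header.write(_pad("1", 8))  # record duration, seconds
    header.write(_pad(str(nch), 4))
    for name in rec.channel_names:
        header.write(_pad(name, 16))
    for _ in range(nch):
        header.write(_pad("", 80))  # transducer
    for _ in range(nch):
        header.write(_pad("uV", 8))
    for _ in range(nch):
        header.write(_pad(f"{pmin:g}", 8))
    for _ in range(nch):
        header.write(_pad(f"{pmax:g}", 8))
    for _ in range(nch):
        header.write(_pad(str(_EDF_DIG_MIN), 8))
    for _ in range(nch):
        header.write(_pad(str(_EDF_DIG_MAX), 8))
    for _ in range(nch):
        header.write(_pad("", 80))  # prefiltering
    for _ in range(nch):
        header.write(_pad(str(spr), 8))
    for _ in range(nch):
        header.write(_pad("", 32))  # reserved

    # pad the final partial record with the physical midpoint (0 uV)
    padded = np.zeros((nch, n_records * spr))
    padded[:, : rec.n_samples] = np.clip(rec.data, pmin, pmax)
    digital = np.rint((padded - pmin) * scale + _EDF_DIG_MIN).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def _read_edf_id_fields(path: Path) -> tuple[str, Stage]:
    with open(path, "rb") as fh:
        head = fh.read(168)
    patient = head[8:88].decode("ascii", errors="replace").strip()
    recording_id = head[88:168].decode("ascii", errors="replace").strip()
    stage = Stage.UNKNOWN
    for token in recording_id.split():
        if token.startswith("stage="):
            try:
                stage = Stage.coerce(token.split("=", 1)[1])
            except ValueError:
                pass
    return patient, stage


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    subject, stage = _read_edf_id_fields(path)
    if subject in ("", "X"):
        subject = ""
    return Recording(
        data_uv,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        stage=stage,
        subject_id=subject,
    )
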