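"""Epoch segmentation and Haar-wavelet band extraction.

Recordings are cut into non-overlapping fixed-length epochs (1 s by default),
and each epoch channel is reduced to the fast-ripple band (250-500 Hz) by a
Haar discrete wavelet decomposition: the signal is reconstructed from only the
detail levels whose dyadic band ``[fs/2^(j+1), fs/2^j]`` overlaps the
requested band, with the approximation coefficients zeroed. At 1000 Hz the
250-500 Hz band is exactly the level-1 detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .signal_io import Recording, Stage

__all__ = [
    "Epoch",
    "BandSpec",
    "FAST_RIPPLE_BAND",
    "segment_epochs",
    "segment_equal",
    "haar_band_filter",
    "band_detail_levels",
    "preprocess_recording",
]


@dataclass
class Epoch:
    """One fixed-length segment of a recording (``channels x samples``)."""

    data: np.ndarray
    index: int
    stage: Stage = Stage.UNKNOWN
    subject_id: str = ""
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.stage = Stage.coerce(self.stage)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band extracted by dyadic wavelet decomposition."""

    low: float = 250.0
    high: float = 500.0
    wavelet: str = "haar"

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high, got [{self.low}, {self.high}]")


#: The band of interest downstream: fast ripples, 250-500 Hz.
FAST_RIPPLE_BAND = BandSpec(250.0, 500.0, "haar")


def segment_epochs(rec: Recording, epoch_seconds: float = 1.0) -> list[Epoch]:
    """Cut a recording into non-overlapping epochs of ``epoch_seconds``.

    Returns ``floor(n_samples / epoch_samples)`` epochs in temporal order;
    trailing remainder samples are discarded. An epoch longer than the
    recording yields an empty list.
    """
    n_per = rec.fs * epoch_seconds
    if n_per <= 0 or abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(
            f"fs * epoch_seconds must be a positive integer, got {n_per}"
        )
    n_per = int(round(n_per))
    n_epochs = rec.n_samples // n_per
    return [
        Epoch(
            rec.data[:, i * n_per : (i + 1) * n_per],
            index=i,
            stage=rec.stage,
            subject_id=rec.subject_id,
            channel_names=list(rec.channel_names),
        )
        for i in range(n_epochs)
    ]


def segment_equal(rec: Recording, n_parts: int) -> list[Epoch]:
    """Divide a recording into ``n_parts`` equal-length epochs.

    If the sample count is not divisible, the largest divisible prefix is
    used and the remainder dropped.
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    n_per = rec.n_samples // n_parts
    if n_per < 1:
        raise ValueError(f"recording too short to split into {n_parts} parts")
    return [
        Epoch(
            rec.data[:, i * n_per : (i + 1) * n_per],
            index=i,
            stage=rec.stage,
            subject_id=rec.subject_id,
            channel_names=list(rec.channel_names),
        )
        for i in range(n_parts)
    ]


def band_detail_levels(fs: float, band: BandSpec) -> list[int]:
    """Detail levels whose dyadic band strictly overlaps ``[band.low, band.high]``.

    Level ``j`` covers ``[fs/2^(j+1), fs/2^j]``; overlap is strict so bands
    that merely touch at an endpoint are excluded. For fs=1000 and 250-500 Hz
    this returns ``[1]``.
    """
    if band.high > fs / 2 + 1e-9:
        raise ValueError(
            f"band.high={band.high} exceeds Nyquist frequency {fs / 2}"
        )
    levels = []
    j = 1
    while fs / 2**j > band.low * (1 - 1e-12):
        lo, hi = fs / 2 ** (j + 1), fs / 2**j
        if max(lo, band.low) < min(hi, band.high):
            levels.append(j)
        j += 1
    return levels


def haar_band_filter(x, fs: float, band: BandSpec = FAST_RIPPLE_BAND) -> np.ndarray:
    """Band-limit a 1-D signal by dyadic wavelet subband reconstruction.

    Decomposes to the minimum depth covering ``band.low``, zeroes the
    approximation and all detail levels outside the band, and reconstructs.
    Odd-length inputs are right-padded by edge replication and trimmed after
    reconstruction. Output has the same length as the input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("haar_band_filter expects a 1-D sequence")
    if len(x) < 2:
        raise ValueError("sequence too short to filter")
    keep = band_detail_levels(fs, band)
    if not keep:
        return np.zeros_like(x)
    depth = max(keep)

    n = len(x)
    pad_to = int(np.ceil(n / 2**depth)) * 2**depth
    if pad_to > n:
        x = np.pad(x, (0, pad_to - n), mode="edge")

    coeffs = pywt.wavedec(x, band.wavelet, level=depth)
    # coeffs = [approx, detail_depth, ..., detail_1]
    out = [np.zeros_like(coeffs[0])]
    for pos, c in enumerate(coeffs[1:], start=1):
        level = depth - pos + 1
        out.append(c if level in keep else np.zeros_like(c))
    y = pywt.waverec(out, band.wavelet)
    return y[:n]


def preprocess_recording(
    rec: Recording,
    epoch_seconds: float = 1.0,
    band: BandSpec = FAST_RIPPLE_BAND,
) -> list[Epoch]:
    """Segment into epochs, then band-limit each channel of each epoch."""
    epochs = segment_epochs(rec, epoch_seconds)
    for ep in epochs:
        filtered = np.empty_like(ep.data)
        for c in range(ep.n_channels):
            filtered[c] = haar_band_filter(ep.data[c], rec.fs, band)
        ep.data = filtered
    return epochs
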