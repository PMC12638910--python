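"""Welch spectra, relative band power and per-segment feature vectors.

Each kept 10-s segment is reduced to 84 relative power spectral density
(PSD) features: 14 channels x 6 canonical bands, every value being the
band power divided by total power over the analysed 1-45 Hz range.
Relative powers are scale invariant, which makes them robust to the
uncalibrated gain of consumer EEG amplifiers.

The band edges follow common consumer-EEG conventions (the six-band
split with low/high beta) and are configurable; they are an analysis
choice, not a physical constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal

from .core import Montage, Segment

__all__ = [
    "BandSet",
    "DEFAULT_BANDS",
    "FeatureVector",
    "welch_psd",
    "relative_band_power",
    "average_amplitude",
    "feature_vector",
    "features_table",
]

#: Analysed spectrum; content outside it is treated as filter artifact.
ANALYSIS_RANGE: tuple[float, float] = (1.0, 45.0)


@dataclass(frozen=True)
class BandSet:
    """Ordered, non-overlapping frequency bands, half-open ``[low, high)``."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_high = 0.0
        for name, low, high in self.bands:
            if not (0.0 < low < high):
                raise ValueError(f"band {name}: need 0 < low < high")
            if low < prev_high:
                raise ValueError(f"band {name} overlaps the previous band")
            prev_high = high

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def range(self, name: str) -> tuple[float, float]:
        for n, low, high in self.bands:
            if n == name:
                return low, high
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def validate_for_fs(self, fs: float) -> None:
        if self.bands[-1][2] > fs / 2:
            raise ValueError("band edges exceed the Nyquist frequency")


DEFAULT_BANDS = BandSet((
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("low_beta", 12.0, 16.0),
    ("high_beta", 16.0, 25.0),
    ("gamma", 25.0, 45.0),
))


@dataclass(frozen=True)
class FeatureVector:
    """84 relative-PSD features, channel-major, with session labels."""

    values: np.ndarray
    names: tuple[str, ...]
    subject: str
    session: int
    task: str
    stage: int
    segment: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.values.shape != (len(self.names),):
            raise ValueError("values and names length mismatch")


def _as_array(seg_or_data) -> np.ndarray:
    if isinstance(seg_or_data, Segment):
        return seg_or_data.data
    return np.asarray(seg_or_data, float)


def welch_psd(
    seg_or_data,
    fs: float | None = None,
    window_sec: float = 2.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD per channel.

    Defaults: 2-s Hamming windows with 50 % overlap, i.e. nine averaged
    windows per 10-s segment and a 0.5 Hz frequency resolution at 128 Hz.

    Returns ``(freqs, psd)`` with ``psd`` shaped channels x freqs in
    uV^2/Hz.
    """
    data = _as_array(seg_or_data)
    if fs is None:
        if not isinstance(seg_or_data, Segment):
            raise ValueError("fs required when passing a bare array")
        fs = seg_or_data.fs
    nperseg = int(round(window_sec * fs))
    if data.shape[-1] < nperseg:
        raise ValueError(
            f"segment ({data.shape[-1]} samples) shorter than one Welch "
            f"window ({nperseg} samples)"
        )
    freqs, psd = signal.welch(
        data, fs=fs, window="hamming", nperseg=nperseg,
        noverlap=int(nperseg * overlap), detrend="constant", axis=-1,
    )
    return freqs, psd


def relative_band_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands: BandSet = DEFAULT_BANDS,
    total_range: tuple[float, float] = ANALYSIS_RANGE,
) -> np.ndarray:
    """Band power divided by total power over ``total_range``.

    Band membership is half-open (``low <= f < high``) so that bands
    tiling the analysis range sum exactly to one.  Returns an array
    shaped channels x n_bands with entries in [0, 1].
    """
    psd = np.atleast_2d(np.asarray(psd, float))
    lo, hi = total_range
    total_mask = (freqs >= lo) & (freqs < hi)
    total = psd[:, total_mask].sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("degenerate segment: zero total power in the analysis range")
    out = np.empty((psd.shape[0], len(bands)))
    for j, (_, low, high) in enumerate(bands):
        mask = (freqs >= low) & (freqs < high) & total_mask
        out[:, j] = psd[:, mask].sum(axis=1) / total
    return out


def average_amplitude(seg_or_data) -> np.ndarray:
    """Mean absolute voltage per channel (uV).

    After high-pass filtering the raw mean is ~0, so the magnitude
    statistic is the meaningful per-channel amplitude summary used for
    topographic maps.
    """
    data = _as_array(seg_or_data)
    return np.abs(data).mean(axis=-1)


def rms_amplitude(seg_or_data) -> np.ndarray:
    """Root-mean-square voltage per channel (uV); alternative summary."""
    data = _as_array(seg_or_data)
    return np.sqrt((data ** 2).mean(axis=-1))


def feature_names(montage: Montage, bands: BandSet = DEFAULT_BANDS) -> tuple[str, ...]:
    """Channel-major feature naming, e.g. ``O1_alpha``."""
    return tuple(
        f"{ch}_{band}" for ch in montage.channel_names for band in bands.names
    )


def feature_vector(seg: Segment, bands: BandSet = DEFAULT_BANDS) -> FeatureVector:
    """Channel-major concatenation of the per-channel relative band powers."""
    if not seg.qc.is_kept:
        raise ValueError(f"feature extraction requires a kept segment, qc={seg.qc}")
    bands.validate_for_fs(seg.fs)
    freqs, psd = welch_psd(seg)
    rel = relative_band_power(freqs, psd, bands)
    return FeatureVector(
        values=rel.ravel(),
        names=feature_names(seg.montage, bands),
        subject=seg.meta.subject,
        session=seg.meta.session,
        task=seg.meta.task,
        stage=seg.meta.stage,
        segment=seg.index,
    )


LABEL_COLUMNS = ("subject", "session", "task", "stage", "segment")


def features_table(
    segments: Iterable[Segment],
    bands: BandSet = DEFAULT_BANDS,
    include_amplitude: bool = True,
) -> pd.DataFrame:
    """Tidy table: one row per kept segment, labels + 84 features.

    When ``include_amplitude`` is set, per-channel mean absolute
    amplitude columns (``<ch>_amp``) are appended for the time-domain
    comparisons.
    """
    rows = []
    for seg in segments:
        if not seg.qc.is_kept:
            continue
        fv = feature_vector(seg, bands)
        row: dict[str, object] = {
            "subject": fv.subject, "session": fv.session, "task": fv.task,
            "stage": fv.stage, "segment": fv.segment,
        }
        row.update(zip(fv.names, fv.values))
        if include_amplitude:
            amp = average_amplitude(seg)
            row.update({
                f"{ch}_amp": a
                for ch, a in zip(seg.montage.channel_names, amp)
            })
        rows.append(row)
    return pd.DataFrame(rows)
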