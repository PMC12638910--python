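"""Preprocessing and segment-level quality control.

The pipeline mirrors a standard consumer-EEG cleaning chain:

1. zero-phase 1 Hz high-pass + 50 Hz notch filtering of the raw
   recording;
2. discard of the first 30 s (setup transients), slicing of the rest
   into non-overlapping 10-s windows, linear detrend per channel;
3. per-window outlier rule: a sample is an outlier when
   ``|y - mean| > 3 * std``; if any single lead has outliers in more
   than half of its samples the window is discarded, otherwise outliers
   are replaced by the nearest non-outlier sample of the same lead;
4. amplitude rejection: any remaining sample with ``|v| > 150 uV``
   discards the window.

A note on the outlier statistics: ``mean``/``std`` are computed over the
*whole* 10-s window pooled across all leads.  Computed per lead they
could never flag more than one ninth of that lead's samples (Chebyshev's
inequality bounds the fraction beyond three standard deviations), which
would make the half-lead discard rule unreachable; pooling across leads
keeps the per-lead threshold anchored to the head-wide noise level and
makes a single saturated lead detectable.  :func:`count_outliers`
accepts explicit statistics so both conventions are available.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import signal

from .core import QCStatus, Recording, Segment

__all__ = [
    "filter_recording",
    "slice_segments",
    "count_outliers",
    "qc_segment",
    "qc_report",
    "preprocess",
]

log = logging.getLogger(__name__)

SETTLE_DISCARD_S = 30.0
SEGMENT_LENGTH_S = 10.0
OUTLIER_K = 3.0
AMPLITUDE_LIMIT_UV = 150.0


def filter_recording(
    rec: Recording,
    highpass_hz: float = 1.0,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    order: int = 4,
) -> Recording:
    """Zero-phase high-pass and line-notch filtering.

    Uses a 4th-order Butterworth high-pass and an IIR notch, both
    applied forward-backward so filtering adds no phase lag (a lag would
    distort cross-channel phase measures downstream).  Requires
    ``fs > 2 * notch_hz`` so the notch is below Nyquist.
    """
    if rec.fs <= 2 * notch_hz:
        raise ValueError(
            f"fs={rec.fs} too low for a {notch_hz} Hz notch filter")
    sos = signal.butter(order, highpass_hz, btype="highpass", fs=rec.fs,
                        output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=-1)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=rec.fs)
    data = signal.filtfilt(b, a, data, axis=-1)
    return rec.copy_with(data=data)


def slice_segments(
    rec: Recording,
    discard_s: float = SETTLE_DISCARD_S,
    seglen_s: float = SEGMENT_LENGTH_S,
) -> list[Segment]:
    """Non-overlapping detrended windows starting after the settling discard.

    Windows are ``seglen_s`` long starting at ``discard_s``; a trailing
    remainder shorter than one window is dropped.  Each window is
    linearly detrended per channel.  A recording too short for a single
    window yields an empty list with a logged warning.
    """
    start0 = int(round(discard_s * rec.fs))
    wlen = int(round(seglen_s * rec.fs))
    n_windows = (rec.n_samples - start0) // wlen
    if n_windows <= 0:
        log.warning(
            "recording %s (%.1f s) too short for any %g-s segment after the "
            "%g-s discard; returning no segments",
            rec.meta, rec.duration, seglen_s, discard_s)
        return []
    segments = []
    for i in range(int(n_windows)):
        a = start0 + i * wlen
        data = signal.detrend(rec.data[:, a:a + wlen], axis=-1, type="linear")
        segments.append(Segment(
            data=data, fs=rec.fs, montage=rec.montage, meta=rec.meta,
            index=i, start_sample=a))
    return segments


def count_outliers(
    channel_data: np.ndarray,
    k: float = OUTLIER_K,
    mean: float | None = None,
    std: float | None = None,
) -> int:
    """Number of samples with ``|y - mean| > k * std`` (strict).

    With ``mean``/``std`` omitted they are computed from
    ``channel_data`` itself (sample standard deviation); ``std = 0``
    gives zero outliers because the inequality is strict.
    """
    x = np.asarray(channel_data, float)
    if x.size == 0:
        raise ValueError("channel_data must be non-empty")
    if mean is None:
        mean = float(x.mean())
    if std is None:
        std = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return int(np.count_nonzero(np.abs(x - mean) > k * std))


def _nearest_fill(x: np.ndarray, bad: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Replace flagged samples by the nearest non-flagged sample.

    Distance ties resolve to the earlier sample.  Returns the corrected
    copy and the list of corrected indices.
    """
    bad_idx = np.flatnonzero(bad)
    if bad_idx.size == 0:
        return x, []
    good_idx = np.flatnonzero(~bad)
    if good_idx.size == 0:  # unreachable under the half-lead rule
        return x, []
    pos = np.searchsorted(good_idx, bad_idx)
    left = np.clip(pos - 1, 0, good_idx.size - 1)
    right = np.clip(pos, 0, good_idx.size - 1)
    d_left = np.abs(bad_idx - good_idx[left])
    d_right = np.abs(good_idx[right] - bad_idx)
    pick = np.where(d_left <= d_right, good_idx[left], good_idx[right])
    out = x.copy()
    out[bad_idx] = x[pick]
    return out, bad_idx.tolist()


def qc_segment(
    seg: Segment,
    k: float = OUTLIER_K,
    amplitude_limit: float = AMPLITUDE_LIMIT_UV,
) -> Segment:
    """Apply the outlier and amplitude rules to a pending segment.

    Check order: (a) any lead with outliers in strictly more than half
    of its samples discards the segment; (b) otherwise outliers are
    corrected by nearest-neighbour interpolation; (c) the amplitude rule
    then runs on the corrected data.  The returned segment carries the
    terminal status, corrected data and per-channel corrected indices.
    """
    if seg.qc is not QCStatus.PENDING:
        raise ValueError(f"segment already quality-controlled: {seg.qc}")
    data = seg.data
    n = data.shape[1]
    pooled_mean = float(data.mean())
    pooled_std = float(data.std(ddof=1))
    bad = np.abs(data - pooled_mean) > k * pooled_std
    counts = bad.sum(axis=1)
    if np.any(counts > n / 2):
        return replace(seg, qc=QCStatus.DISCARDED_OUTLIERS)
    corrections: dict[str, list[int]] = {}
    corrected = data
    if counts.any():
        corrected = data.copy()
        for c in range(data.shape[0]):
            if counts[c]:
                corrected[c], idx = _nearest_fill(data[c], bad[c])
                corrections[seg.montage.channel_names[c]] = idx
    if np.any(np.abs(corrected) > amplitude_limit):
        return replace(seg, data=corrected, qc=QCStatus.DISCARDED_AMPLITUDE,
                       corrections=corrections)
    status = QCStatus.KEPT_CORRECTED if corrections else QCStatus.KEPT
    return replace(seg, data=corrected, qc=status, corrections=corrections)


def qc_report(segments: list[Segment]) -> dict[str, int]:
    """Counts of segments per terminal status (they sum to the total)."""
    report = {status.value: 0 for status in QCStatus if status.is_terminal}
    for seg in segments:
        report[seg.qc.value] = report.get(seg.qc.value, 0) + 1
    report["total"] = len(segments)
    report["kept_total"] = (report["kept"] + report["kept_corrected"])
    return report


def preprocess(rec: Recording) -> tuple[list[Segment], dict[str, int]]:
    """Filter, slice and quality-control one recording.

    Independent-component-based artifact removal is deliberately not
    part of the default chain (no principled component-selection rule is
    available for a 14-channel montage); a hook can be inserted between
    filtering and slicing by callers that have one.
    """
    filtered = filter_recording(rec)
    segments = [qc_segment(s) for s in slice_segments(filtered)]
    return segments, qc_report(segments)
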