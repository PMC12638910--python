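"""Synthetic 14-channel EEG with controllable oscillatory structure.

The generator emulates the study conditions of an 11-week, three-task
online-learning curriculum recorded with a 128 Hz consumer headset:

* per-channel, per-band oscillation amplitudes that depend on the
  learning stage and task (alpha decreasing / high-beta increasing
  across stages in the lab and quiz tasks, the qualitative directions
  reported for such curricula);
* optional channel-pair phase coupling with a fixed lag, giving
  analytic phase-locking targets;
* 1/f-shaped Gaussian background noise;
* seed-reproducible artifact injection (spikes, dense spike bursts,
  linear drift, whole-head high-amplitude excursions) with a complete
  ledger of injected sample spans, so quality-control decisions can be
  traced back to ground truth.

The signal model is deliberately simple - a sum of amplitude-modulated
sinusoids plus shaped noise - because the downstream features are
spectral: it gives exact control over band content without a
biophysical forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ArtifactEvent,
    Montage,
    Recording,
    SessionMeta,
    Segment,
    QCStatus,
    TASKS,
    emotiv_montage,
)
from .spectral import BandSet, DEFAULT_BANDS, features_table

__all__ = [
    "ArtifactSpec",
    "Coupling",
    "SynthConfig",
    "baseline_profile",
    "stage_task_profile",
    "generate_session",
    "generate_segment",
    "inject_artifacts",
    "apply_events",
    "make_stage_dataset",
    "make_feature_dataset",
]

#: Baseline oscillation peak amplitudes (uV) per band, loosely matching
#: resting adult scalp EEG proportions at frontal/posterior sites.
BASELINE_BAND_AMPLITUDE: dict[str, float] = {
    "delta": 12.0, "theta": 9.0, "alpha": 10.0,
    "low_beta": 6.0, "high_beta": 5.0, "gamma": 3.0,
}

#: Qualitative stage trends per (task, band): +1 means the band amplitude
#: grows from stage 1 to stage 3, -1 that it declines.  Directions follow
#: the reported curriculum-stage band-power trends (alpha suppression in
#: labs, stage-1 alpha deficit in lecture/quiz, late high-beta rise in
#: labs and quizzes).
STAGE_TRENDS: dict[tuple[str, str], float] = {
    ("lecture", "alpha"): +1.0,
    ("quiz", "alpha"): +1.0,
    ("lab", "alpha"): -1.0,
    ("lab", "low_beta"): -1.0,
    ("lab", "high_beta"): +1.0,
    ("quiz", "high_beta"): +1.0,
}

#: Overall amplitude trend per task (whole-head gain across stages).
AMPLITUDE_TRENDS: dict[str, float] = {"lecture": +1.0, "lab": -1.0, "quiz": -1.0}

#: Relative band-amplitude shift per unit effect size per stage step.
TREND_SLOPE = 0.15
GAIN_SLOPE = 0.08


@dataclass(frozen=True)
class ArtifactSpec:
    """Expected artifact events per minute of recording, with amplitudes.

    * ``spike``: single-sample transient on one channel;
    * ``spike_burst``: dense alternating-sign transients filling more
      than half of a 10-s window on one channel (breaks the half-lead
      outlier rule downstream);
    * ``drift``: slow linear baseline ramp on one channel (removed by
      the 1 Hz high-pass, so quality control should keep it);
    * ``excursion``: whole-head ~3 Hz wave exceeding the 150 uV
      amplitude-rejection threshold.
    """

    spike_rate: float = 0.0
    burst_rate: float = 0.0
    drift_rate: float = 0.0
    excursion_rate: float = 0.0
    spike_amplitude: float = 100.0
    burst_amplitude: float = 150.0
    drift_amplitude: float = 80.0
    excursion_amplitude: float = 220.0
    burst_duration: float = 7.0
    drift_duration: float = 15.0
    excursion_duration: float = 10.0

    def __post_init__(self) -> None:
        for name in ("spike_rate", "burst_rate", "drift_rate", "excursion_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def any_rate(self) -> bool:
        return any(
            r > 0
            for r in (self.spike_rate, self.burst_rate,
                      self.drift_rate, self.excursion_rate)
        )


@dataclass(frozen=True)
class Coupling:
    """Shared band-limited oscillator copied onto two channels.

    Channel ``b`` receives the oscillator delayed by ``phase_lag``
    radians, mixed with an independent oscillator by ``strength``:
    strength 1 gives a constant nonzero lag (phase-locking index 1),
    strength 0 two unrelated oscillations.
    """

    chan_a: str
    chan_b: str
    band: str
    phase_lag: float
    strength: float
    amplitude: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must be in [0, 1]")


@dataclass(frozen=True)
class SynthConfig:
    """Full description of one synthetic session.

    ``band_profiles`` is a channels x bands matrix of oscillation peak
    amplitudes in uV (row order = montage order, column order = band
    order).  ``None`` selects the stage/task default profile.
    """

    fs: float = 128.0
    duration: float = 100.0
    meta: SessionMeta = field(
        default_factory=lambda: SessionMeta("S01", 1, "lecture"))
    band_profiles: np.ndarray | None = None
    coupling: tuple[Coupling, ...] = ()
    noise_sd: float = 10.0
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0
    effect_size: float = 1.0
    modulation_depth: float = 0.2
    bands: BandSet = DEFAULT_BANDS

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def baseline_profile(montage: Montage, bands: BandSet = DEFAULT_BANDS) -> np.ndarray:
    """Stage/task-independent channels x bands amplitude matrix (uV)."""
    row = np.array([BASELINE_BAND_AMPLITUDE.get(b, 5.0) for b in bands.names])
    return np.tile(row, (montage.n_channels, 1))


def stage_task_profile(
    stage: int,
    task: str,
    effect_size: float = 1.0,
    montage: Montage | None = None,
    bands: BandSet = DEFAULT_BANDS,
    trend_channels: Sequence[str] | None = None,
    trend_bands: Sequence[str] | None = None,
) -> np.ndarray:
    """Band-amplitude profile with stage/task trends applied.

    ``effect_size`` scales the stage-dependent shifts; 0 makes all
    stages draw from the identical generative law.  ``trend_channels``
    and ``trend_bands`` restrict the stage effect to a channel / band
    subset (useful for planting a single informative feature).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if stage not in (1, 2, 3):
        raise ValueError("stage must be 1, 2 or 3")
    montage = montage or emotiv_montage()
    prof = baseline_profile(montage, bands)
    if effect_size == 0:
        return prof
    s = stage - 2  # stage offset in {-1, 0, +1}
    if trend_channels is None:
        ch_mask = np.ones(montage.n_channels, bool)
    else:
        ch_mask = np.array(
            [c in set(trend_channels) for c in montage.channel_names], bool)
    for j, band in enumerate(bands.names):
        t = STAGE_TRENDS.get((task, band), 0.0)
        if trend_bands is not None and band not in set(trend_bands):
            t = 0.0
        if t:
            prof[ch_mask, j] *= 1.0 + TREND_SLOPE * effect_size * t * s
    gain = 1.0 + GAIN_SLOPE * effect_size * AMPLITUDE_TRENDS.get(task, 0.0) * s
    prof[ch_mask] *= gain
    return np.clip(prof, 0.0, None)


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n: int,
                      fs: float, sd: float) -> np.ndarray:
    """Gaussian noise with a 1/f amplitude spectrum above 1 Hz."""
    if sd == 0:
        return np.zeros((n_channels, n))
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shape[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * shape, n=n, axis=-1)
    scale = shaped.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    return shaped / scale * sd


def _render_oscillations(
    rng: np.random.Generator,
    profile: np.ndarray,
    bands: BandSet,
    montage: Montage,
    fs: float,
    n: int,
    coupling: Sequence[Coupling],
    modulation_depth: float,
) -> np.ndarray:
    t = np.arange(n) / fs
    n_ch = montage.n_channels
    n_bands = len(bands)
    lows = np.array([b[1] for b in bands])
    widths = np.array([b[2] - b[1] for b in bands])
    # one oscillator per channel x band, frequency drawn inside the band
    f = rng.uniform(lows + 0.15 * widths, lows + 0.85 * widths,
                    size=(n_ch, n_bands))
    phase = rng.uniform(0, 2 * np.pi, size=(n_ch, n_bands))
    if modulation_depth > 0:
        fm = rng.uniform(0.05, 0.3, size=(n_ch, n_bands))
        pm = rng.uniform(0, 2 * np.pi, size=(n_ch, n_bands))
    active = profile.ravel() > 0
    amp = profile.reshape(-1, 1)[active]
    osc = np.sin(2 * np.pi * f.reshape(-1, 1)[active] * t[None, :]
                 + phase.reshape(-1, 1)[active])
    if modulation_depth > 0:
        osc *= 1.0 + modulation_depth * np.sin(
            2 * np.pi * fm.reshape(-1, 1)[active] * t[None, :]
            + pm.reshape(-1, 1)[active])
    data = np.zeros((n_ch * n_bands, n))
    data[active] = amp * osc
    data = data.reshape(n_ch, n_bands, n).sum(axis=1)
    for cp in coupling:
        ia = montage.index(cp.chan_a)
        ib = montage.index(cp.chan_b)
        low, high = bands.range(cp.band)
        width = high - low
        f = rng.uniform(low + 0.2 * width, high - 0.2 * width)
        phase = rng.uniform(0, 2 * np.pi)
        theta = 2 * np.pi * f * t + phase
        data[ia] += cp.amplitude * np.sin(theta)
        data[ib] += cp.amplitude * cp.strength * np.sin(theta - cp.phase_lag)
        if cp.strength < 1.0:
            f2 = rng.uniform(low + 0.2 * width, high - 0.2 * width)
            p2 = rng.uniform(0, 2 * np.pi)
            data[ib] += (cp.amplitude * (1.0 - cp.strength)
                         * np.sin(2 * np.pi * f2 * t + p2))
    return data


def generate_session(
    config: SynthConfig, montage: Montage | None = None
) -> Recording:
    """Synthesize one continuous session as a :class:`Recording`.

    The duration must allow at least one quality-controllable window
    after the 30-s settling discard, i.e. at least 40 s.  Identical
    configurations produce bit-identical output.
    """
    montage = montage or emotiv_montage()
    if config.duration < 40.0:
        raise ValueError(
            "duration must be >= 40 s so at least one 10-s segment survives "
            "the 30-s settling discard")
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    profile = config.band_profiles
    if profile is None:
        profile = stage_task_profile(
            config.meta.stage, config.meta.task, config.effect_size,
            montage, config.bands)
    profile = np.asarray(profile, float)
    if profile.shape != (montage.n_channels, len(config.bands)):
        raise ValueError(
            f"band_profiles must be {montage.n_channels} x {len(config.bands)}")
    data = _render_oscillations(
        rng, profile, config.bands, montage, config.fs, n,
        config.coupling, config.modulation_depth)
    data += _one_over_f_noise(rng, montage.n_channels, n, config.fs,
                              config.noise_sd)
    rec = Recording(data=data, fs=config.fs, montage=montage, meta=config.meta)
    if config.artifact_spec.any_rate:
        rec = inject_artifacts(rec, config.artifact_spec,
                               int(rng.integers(2 ** 31)))
    return rec


def generate_segment(
    stage: int,
    task: str,
    effect_size: float,
    rng: np.random.Generator,
    montage: Montage | None = None,
    bands: BandSet = DEFAULT_BANDS,
    fs: float = 128.0,
    seglen: float = 10.0,
    noise_sd: float = 10.0,
    band_jitter_sd: float = 0.12,
    gain_jitter_sd: float = 0.10,
    trend_channels: Sequence[str] | None = None,
    trend_bands: Sequence[str] | None = None,
) -> np.ndarray:
    """Fast path: one independent 10-s window drawn from the session model.

    Adds per-window lognormal band-amplitude and gain jitter, the
    between-segment variability a session recording would show.
    Intended for calibration studies that need thousands of independent
    windows without paying for full-session synthesis and slicing.
    """
    montage = montage or emotiv_montage()
    profile = stage_task_profile(stage, task, effect_size, montage, bands,
                                 trend_channels, trend_bands)
    if band_jitter_sd > 0:
        profile = profile * rng.lognormal(
            0.0, band_jitter_sd, size=profile.shape)
    if gain_jitter_sd > 0:
        profile = profile * rng.lognormal(0.0, gain_jitter_sd)
    n = int(round(seglen * fs))
    data = _render_oscillations(rng, profile, bands, montage, fs, n, (), 0.2)
    data += _one_over_f_noise(rng, montage.n_channels, n, fs, noise_sd)
    return data


def apply_events(
    rec: Recording, events: Sequence[ArtifactEvent]
) -> Recording:
    """Add artifact waveforms described by ``events`` to a copy of ``rec``.

    Deterministic: the waveform of each event is a pure function of its
    ledger entry, so a ledger round-trip fully reconstructs what was
    injected.  Events are appended to the recording's artifact ledger.
    """
    data = rec.data.copy()
    n = rec.n_samples
    for ev in events:
        start, stop = max(ev.start, 0), min(ev.stop, n)
        if stop <= start:
            continue
        span = stop - start
        if ev.channel == "*":
            rows = slice(None)
        else:
            rows = rec.montage.index(ev.channel)
        if ev.kind == "spike":
            data[rows, start] += ev.amplitude
        elif ev.kind == "spike_burst":
            burst = np.full(span, ev.amplitude)
            burst[1::2] *= -1.0
            data[rows, start:stop] += burst
        elif ev.kind == "drift":
            data[rows, start:stop] += np.linspace(0.0, ev.amplitude, span)
        elif ev.kind == "excursion":
            t = np.arange(span) / rec.fs
            data[rows, start:stop] += ev.amplitude * np.sin(
                2 * np.pi * 3.0 * t + np.pi / 4)
        else:
            raise ValueError(f"unknown artifact kind {ev.kind!r}")
    return rec.copy_with(data=data,
                         artifacts=rec.artifacts + tuple(events))


def inject_artifacts(
    rec: Recording, spec: ArtifactSpec, seed: int
) -> Recording:
    """Draw artifact events at the rates in ``spec`` and apply them.

    Event counts are Poisson with mean ``rate * minutes``; positions are
    uniform over the recording.  With all rates zero the input is
    returned unchanged (same object, no ledger entries).
    """
    if not spec.any_rate:
        return rec
    rng = np.random.default_rng(seed)
    minutes = rec.duration / 60.0
    n = rec.n_samples
    fs = rec.fs
    events: list[ArtifactEvent] = []

    def _channel() -> str:
        return rec.montage.channel_names[
            int(rng.integers(rec.montage.n_channels))]

    for _ in range(rng.poisson(spec.spike_rate * minutes)):
        pos = int(rng.integers(n))
        amp = spec.spike_amplitude * (1 if rng.random() < 0.5 else -1)
        events.append(ArtifactEvent("spike", _channel(), pos, pos + 1, amp))
    for _ in range(rng.poisson(spec.burst_rate * minutes)):
        span = int(spec.burst_duration * fs)
        start = int(rng.integers(max(n - span, 1)))
        events.append(ArtifactEvent("spike_burst", _channel(), start,
                                    start + span, spec.burst_amplitude))
    for _ in range(rng.poisson(spec.drift_rate * minutes)):
        span = int(spec.drift_duration * fs)
        start = int(rng.integers(max(n - span, 1)))
        events.append(ArtifactEvent("drift", _channel(), start, start + span,
                                    spec.drift_amplitude))
    for _ in range(rng.poisson(spec.excursion_rate * minutes)):
        span = int(spec.excursion_duration * fs)
        start = int(rng.integers(max(n - span, 1)))
        events.append(ArtifactEvent("excursion", "*", start, start + span,
                                    spec.excursion_amplitude))
    return apply_events(rec, events)


#: Maximum sessions per stage compatible with the 1-3 / 4-6 / 7-11 mapping.
_STAGE_SESSION_POOL = {1: (1, 2, 3), 2: (4, 5, 6), 3: (7, 8, 9, 10, 11)}


def make_stage_dataset(
    n_subjects: int = 6,
    sessions_per_stage: tuple[int, int, int] = (3, 3, 5),
    tasks: Sequence[str] = TASKS,
    effect_size: float = 1.0,
    duration: float = 100.0,
    noise_sd: float = 10.0,
    seed: int = 0,
    artifact_spec: ArtifactSpec | None = None,
) -> list[Recording]:
    """Stage-labelled recordings for the full subject x session x task grid.

    Session indices are drawn from the canonical stage pools so that the
    session -> stage mapping (1-3, 4-6, 7-11) always holds; at most
    (3, 3, 5) sessions per stage are therefore possible.  With
    ``effect_size`` 0 every recording follows the identical generative
    law regardless of its stage label.
    """
    rng = np.random.default_rng(seed)
    recs: list[Recording] = []
    for stage, n_sessions in zip((1, 2, 3), sessions_per_stage):
        pool = _STAGE_SESSION_POOL[stage]
        if n_sessions > len(pool):
            raise ValueError(
                f"stage {stage} supports at most {len(pool)} sessions")
        for subj in range(n_subjects):
            subject = f"S{subj + 1:02d}"
            for session in pool[:n_sessions]:
                for task in tasks:
                    cfg = SynthConfig(
                        duration=duration,
                        meta=SessionMeta(subject, session, task),
                        noise_sd=noise_sd,
                        effect_size=effect_size,
                        seed=int(rng.integers(2 ** 31)),
                        artifact_spec=artifact_spec or ArtifactSpec(),
                    )
                    recs.append(generate_session(cfg))
    return recs


def make_feature_dataset(
    n_per_stage: int,
    effect_size: float = 1.0,
    seed: int = 0,
    task: str = "lab",
    stages: Sequence[int] = (1, 2, 3),
    noise_sd: float = 10.0,
    bands: BandSet = DEFAULT_BANDS,
    trend_channels: Sequence[str] | None = None,
    trend_bands: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Feature table of independent synthetic windows, bypassing QC.

    Each row is one independent 10-s window pushed through the spectral
    extractor; segments are clean by construction so quality control
    would keep them all.  Stage labels use representative session
    indices (2, 5, 9).
    """
    rng = np.random.default_rng(seed)
    montage = emotiv_montage()
    session_for_stage = {1: 2, 2: 5, 3: 9}
    segments = []
    for stage in stages:
        meta = SessionMeta("SYN", session_for_stage[stage], task)
        for i in range(n_per_stage):
            data = generate_segment(
                stage, task, effect_size, rng, montage, bands,
                noise_sd=noise_sd, trend_channels=trend_channels,
                trend_bands=trend_bands)
            segments.append(Segment(
                data=data, fs=128.0, montage=montage, meta=meta,
                index=i, start_sample=0, qc=QCStatus.KEPT))
    return features_table(segments, bands)
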