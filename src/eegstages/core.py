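"""Core containers: montage, recording and segment objects.

The pipeline targets a 14-channel saline-electrode consumer headset
(Emotiv EPOC+ style) sampled at 128 Hz, with electrodes placed on the
international 10-20 system.  All voltages are in microvolts (uV).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: Canonical channel order of the 14-channel EPOC+ montage.
EMOTIV14_CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

# Approximate 2-D positions on a top-view unit-circle head (x: left->right,
# y: back->front).  Outer-ring electrodes sit on the 10% circle at the
# standard 36-degree spacing; intermediate electrodes use common template
# values.  Only relative geometry matters (long-range edge rule, plotting).
_TEMPLATE_POSITIONS: dict[str, tuple[float, float]] = {
    "AF3": (-0.31, 0.78), "AF4": (0.31, 0.78),
    "F7": (-0.81, 0.59), "F8": (0.81, 0.59),
    "F3": (-0.40, 0.55), "F4": (0.40, 0.55),
    "FC5": (-0.69, 0.29), "FC6": (0.69, 0.29),
    "T7": (-1.00, 0.00), "T8": (1.00, 0.00),
    "P7": (-0.81, -0.59), "P8": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

TASKS: tuple[str, ...] = ("lecture", "lab", "quiz")

#: Session -> learning-stage mapping of the 11-week curriculum:
#: sessions 1-3 = basic knowledge, 4-6 = core knowledge, 7-11 = application.
def stage_for_session(session: int) -> int:
    if not 1 <= session <= 11:
        raise ValueError(f"session index must be in 1..11, got {session}")
    if session <= 3:
        return 1
    if session <= 6:
        return 2
    return 3


@dataclass(frozen=True)
class Montage:
    """Electrode set with template scalp coordinates.

    Invariants: exactly 14 unique channel names with a balanced 7/7
    left/right hemisphere split (the montage has no midline electrodes).
    """

    channel_names: tuple[str, ...]
    positions: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.channel_names) != 14:
            raise ValueError("montage must have exactly 14 channels")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        missing = [c for c in self.channel_names if c not in self.positions]
        if missing:
            raise ValueError(f"positions missing for channels: {missing}")
        n_left = sum(1 for c in self.channel_names if self.positions[c][0] < 0)
        n_right = sum(1 for c in self.channel_names if self.positions[c][0] > 0)
        if n_left != n_right:
            raise ValueError("left/right channel counts must be equal")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def hemisphere(self, channel: str) -> str:
        x = self.positions[channel][0]
        if x < 0:
            return "left"
        if x > 0:
            return "right"
        return "midline"

    def channels_in(self, hemisphere: str) -> tuple[str, ...]:
        """Channel names in ``hemisphere`` ('left', 'right' or 'whole')."""
        if hemisphere == "whole":
            return self.channel_names
        return tuple(c for c in self.channel_names if self.hemisphere(c) == hemisphere)

    def index(self, channel: str) -> int:
        return self.channel_names.index(channel)

    def position_array(self) -> np.ndarray:
        return np.array([self.positions[c] for c in self.channel_names], float)


def emotiv_montage() -> Montage:
    """The standard 14-channel EPOC+ montage with template 10-20 positions."""
    return Montage(EMOTIV14_CHANNELS, dict(_TEMPLATE_POSITIONS))


@dataclass(frozen=True)
class SessionMeta:
    """Identity of one weekly recording session.

    The learning stage is a deterministic function of the session index
    and therefore derived, never stored independently.
    """

    subject: str
    session: int
    task: str

    def __post_init__(self) -> None:
        stage_for_session(self.session)  # validates the range
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")

    @property
    def stage(self) -> int:
        return stage_for_session(self.session)


@dataclass(frozen=True)
class ArtifactEvent:
    """One injected artifact: kind, affected channel(s) and sample span.

    ``channel`` is a channel name or ``"*"`` for whole-head events.
    ``start``/``stop`` are sample indices into the raw recording
    (half-open, ``stop`` exclusive).
    """

    kind: str
    channel: str
    start: int
    stop: int
    amplitude: float


@dataclass
class Recording:
    """Continuous multichannel EEG: channels x samples, in uV."""

    data: np.ndarray
    fs: float
    montage: Montage
    meta: SessionMeta
    artifacts: tuple[ArtifactEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        if "data" not in kw:
            kw["data"] = self.data.copy()
        return replace(self, **kw)


class QCStatus(str, enum.Enum):
    PENDING = "pending"
    KEPT = "kept"
    KEPT_CORRECTED = "kept_corrected"
    DISCARDED_OUTLIERS = "discarded_outliers"
    DISCARDED_AMPLITUDE = "discarded_amplitude"

    @property
    def is_kept(self) -> bool:
        return self in (QCStatus.KEPT, QCStatus.KEPT_CORRECTED)

    @property
    def is_terminal(self) -> bool:
        return self is not QCStatus.PENDING


@dataclass
class Segment:
    """One 10-second channels x samples analysis window with QC state."""

    data: np.ndarray
    fs: float
    montage: Montage
    meta: SessionMeta
    index: int
    start_sample: int
    qc: QCStatus = QCStatus.PENDING
    corrections: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_span(self) -> tuple[int, int]:
        """Half-open sample range of this segment in the raw recording."""
        return self.start_sample, self.start_sample + self.n_samples
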