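"""Core data containers: raw EEG recordings, hypnograms, artifact masks, subjects.

The canonical montage is the 19-channel international 10-20 arrangement, in
the fixed order used throughout the package (connectivity matrices, CSV
headers, EDF channel order all follow it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

#: Canonical 19-channel 10-20 montage order.
MONTAGE_10_20: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: Sleep-stage labels (Rechtschaffen & Kales).  Stages 1 and 2 are carried in
#: hypnograms but never analysed.
STAGE_LABELS: tuple[str, ...] = ("W", "1", "2", "3", "4", "REM")

#: Stages the network analysis runs on.
ANALYSIS_STAGES: tuple[str, ...] = ("W", "3", "4", "REM")


@dataclass
class RawRecording:
    """Continuous multi-channel EEG.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        EEG amplitude in microvolts.
    fs : float
        Sampling rate in Hz.  Must exceed 64 Hz so the beta band (<= 32 Hz)
        sits below Nyquist.
    channel_labels : sequence of str
        Channel names; for the canonical pipeline this is ``MONTAGE_10_20``.
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = MONTAGE_10_20

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2:
            raise InvalidParameterError("samples must be a 2-D (channels x time) array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise InvalidParameterError(
                f"{self.samples.shape[0]} rows but {len(self.channel_labels)} channel labels"
            )
        if not self.fs > 64:
            raise InvalidParameterError(f"fs must exceed 64 Hz, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs


@dataclass
class Hypnogram:
    """Stage label per fixed-length scoring epoch.

    Time is 0-based; scoring epoch ``k`` covers the half-open interval
    ``[k * scoring_epoch_s, (k + 1) * scoring_epoch_s)`` seconds.
    """

    stages: tuple[str, ...]
    scoring_epoch_s: float = 20.0

    def __post_init__(self) -> None:
        self.stages = tuple(str(s) for s in self.stages)
        bad = sorted(set(self.stages) - set(STAGE_LABELS))
        if bad:
            raise InvalidParameterError(f"unknown stage labels: {bad}")
        if not self.scoring_epoch_s > 0:
            raise InvalidParameterError("scoring_epoch_s must be positive")

    def __len__(self) -> int:
        return len(self.stages)

    def onset_s(self, epoch_index: int) -> float:
        return epoch_index * self.scoring_epoch_s

    def sleep_onset_epoch(self) -> int | None:
        """Index of the first non-wake scoring epoch, or None if never asleep."""
        for k, s in enumerate(self.stages):
            if s != "W":
                return k
        return None


@dataclass
class ArtifactMask:
    """Per-scoring-epoch clean/artifact flags (True = clean, usable)."""

    clean: np.ndarray

    def __post_init__(self) -> None:
        self.clean = np.asarray(self.clean, dtype=bool)
        if self.clean.ndim != 1:
            raise InvalidParameterError("clean must be a 1-D boolean array")

    def __len__(self) -> int:
        return len(self.clean)


@dataclass
class SubjectRecord:
    """Per-subject metadata used by the group statistics."""

    subject_id: str
    sex: str  # "M" or "F"
    age: float
    bdi: int
    group: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise InvalidParameterError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not (0 <= int(self.bdi) <= 39):
            raise InvalidParameterError(f"BDI score must lie in [0, 39], got {self.bdi}")
        self.bdi = int(self.bdi)
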