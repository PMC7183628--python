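"""Epoch selection and segmentation.

For each analysed stage (pre-sleep wakefulness, stage 3, stage 4, REM) the
pipeline takes the chronologically first three artifact-free 20-s scoring
epochs and divides each into four contiguous 5-s segments, giving the twelve
segments per subject-stage on which one multivariate autoregressive model is
fitted.  A spectral-power homogeneity report (per-band coefficient of
variation across segments) documents how stationary the selection is; it is
reported, never used to reject subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .bands import BandSet, DEFAULT_BANDS
from .errors import InsufficientDataError, InvalidParameterError
from .recording import ArtifactMask, Hypnogram, RawRecording


@dataclass
class Epoch:
    """One selected scoring epoch of raw EEG (channels x samples)."""

    samples: np.ndarray
    fs: float
    stage: str
    epoch_index: int
    onset_s: float
    channel_labels: tuple[str, ...] = ()


@dataclass
class EpochSet:
    """The analysis segments of one subject x one stage.

    ``segments`` has shape (n_segments, n_channels, n_samples); with the
    default parameters that is (12, 19, 5 * fs).
    """

    subject_id: str
    stage: str
    segments: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    segment_len_s: float = 5.0
    source_epoch_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        if self.segments.ndim != 3:
            raise InvalidParameterError("segments must be 3-D (segment, channel, sample)")
        expect = int(round(self.segment_len_s * self.fs))
        if self.segments.shape[2] != expect:
            raise InvalidParameterError(
                f"segments have {self.segments.shape[2]} samples, expected "
                f"{expect} (= segment_len_s * fs)"
            )

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def n_channels(self) -> int:
        return self.segments.shape[1]


@dataclass
class HomogeneityReport:
    """Band-power dispersion across the segments of one EpochSet.

    ``band_power`` is a (n_segments, n_bands) table of channel-averaged band
    powers (uV^2); ``cv`` the per-band coefficient of variation (std/mean)
    across segments.  ``passed`` is True when every band's CV is at or below
    the threshold.
    """

    band_names: tuple[str, ...]
    band_power: np.ndarray
    cv: np.ndarray
    cv_threshold: float
    passed: bool
    details: dict = field(default_factory=dict)


def select_clean_epochs(
    rec: RawRecording,
    hyp: Hypnogram,
    mask: ArtifactMask,
    stage: str,
    n: int = 3,
    epoch_len_s: float = 20.0,
) -> list[Epoch]:
    """Pick the chronologically first ``n`` clean scoring epochs of ``stage``.

    Wakefulness is restricted to the period preceding sleep onset (epochs
    before the first non-wake scoring epoch); sleep stages are taken
    regardless of sleep-cycle position.  Raises
    :class:`~somnonet.errors.InsufficientDataError` naming the stage when
    fewer than ``n`` clean epochs exist.
    """
    if stage not in ("W", "3", "4", "REM"):
        raise InvalidParameterError(f"stage must be one of W/3/4/REM, got {stage!r}")
    if abs(epoch_len_s - hyp.scoring_epoch_s) > 1e-9:
        raise InvalidParameterError(
            f"epoch_len_s={epoch_len_s} does not match the hypnogram's "
            f"scoring epoch of {hyp.scoring_epoch_s} s"
        )
    if len(mask) < len(hyp):
        raise InvalidParameterError("artifact mask shorter than hypnogram")

    n_fit = int(rec.duration_s // hyp.scoring_epoch_s)
    last = min(len(hyp), n_fit)
    limit = last
    if stage == "W":
        onset = hyp.sleep_onset_epoch()
        if onset is not None:
            limit = min(limit, onset)

    samples_per = int(round(hyp.scoring_epoch_s * rec.fs))
    picked: list[Epoch] = []
    for k in range(limit):
        if hyp.stages[k] == stage and mask.clean[k]:
            sl = rec.samples[:, k * samples_per:(k + 1) * samples_per]
            picked.append(Epoch(sl.copy(), rec.fs, stage, k, hyp.onset_s(k), rec.channel_labels))
            if len(picked) == n:
                break
    if len(picked) < n:
        raise InsufficientDataError(
            f"stage {stage}: only {len(picked)} clean scoring epoch(s) available, need {n}"
        )
    return picked


def split_epochs(
    epochs: list[Epoch],
    segment_len_s: float = 5.0,
    subject_id: str = "",
) -> EpochSet:
    """Divide each selected scoring epoch into contiguous non-overlapping segments.

    Three 20-s epochs at the default 5-s segment length yield the canonical
    twelve segments.  The partition is exact: concatenating a quartet of
    segments reproduces its source epoch bit for bit.
    """
    if not epochs:
        raise InvalidParameterError("no epochs to split")
    fs = epochs[0].fs
    stage = epochs[0].stage
    seg_samp = segment_len_s * fs
    if abs(seg_samp - round(seg_samp)) > 1e-9:
        raise InvalidParameterError(
            f"segment_len_s * fs = {seg_samp} is not a whole number of samples"
        )
    seg_samp = int(round(seg_samp))

    segments, sources = [], []
    for ep in epochs:
        n_samp = ep.samples.shape[1]
        if n_samp % seg_samp != 0:
            raise InvalidParameterError(
                f"epoch length {n_samp / fs:.3f} s is not divisible by "
                f"segment_len_s={segment_len_s}"
            )
        for j in range(n_samp // seg_samp):
            segments.append(ep.samples[:, j * seg_samp:(j + 1) * seg_samp])
            sources.append(ep.epoch_index)

    return EpochSet(
        subject_id=subject_id,
        stage=stage,
        segments=np.stack(segments),
        fs=fs,
        channel_labels=getattr(epochs[0], "channel_labels", ()) or (),
        segment_len_s=segment_len_s,
        source_epoch_ids=tuple(sources),
    )


def spectral_homogeneity(
    es: EpochSet,
    bands: BandSet = DEFAULT_BANDS,
    cv_threshold: float = 0.5,
) -> HomogeneityReport:
    """Check spectral-power homogeneity of the segments in ``es``.

    Each segment's Welch periodogram is integrated per band and averaged over
    channels; the per-band coefficient of variation across segments measures
    dispersion.  The report always carries all segments; ``passed`` is the
    only judgement and has no side effect on the pipeline.
    """
    if es.n_segments < 2:
        raise InvalidParameterError("need at least 2 segments for a homogeneity check")

    n_samp = es.segments.shape[2]
    nperseg = min(n_samp, int(round(4 * es.fs)))
    freqs, psd = _signal.welch(es.segments, fs=es.fs, nperseg=nperseg, axis=2)
    # psd: (n_segments, n_channels, n_freqs), units uV^2/Hz
    names = tuple(bands)
    power = np.empty((es.n_segments, len(names)))
    for b, name in enumerate(names):
        lo, hi = bands[name]
        m = (freqs >= lo) & (freqs < hi)
        if not m.any():
            power[:, b] = 0.0
            continue
        band_p = np.trapezoid(psd[:, :, m], freqs[m], axis=2)  # per segment, channel
        power[:, b] = band_p.mean(axis=1)

    mean = power.mean(axis=0)
    std = power.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, std / mean, 0.0)
    return HomogeneityReport(
        band_names=names,
        band_power=power,
        cv=cv,
        cv_threshold=cv_threshold,
        passed=bool(np.all(cv <= cv_threshold)),
        details={"nperseg": nperseg, "ddof": 1},
    )
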