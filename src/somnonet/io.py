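"""File formats: EDF raw EEG, CSV hypnograms/masks/subjects/matrices/metrics.

EDF writing is a minimal self-contained 16-bit implementation of the
European Data Format (one data record per second, per-channel physical
range set from the signal extrema); reading goes through ``mne`` so a
round-trip crosses two independent codecs.  Everything tabular is plain CSV
for diffability.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidParameterError
from .mvgc import ConnectivityMatrix
from .recording import MONTAGE_10_20, ArtifactMask, Hypnogram, RawRecording, SubjectRecord

__all__ = [
    "write_edf", "read_edf",
    "write_hypnogram_csv", "read_hypnogram_csv",
    "write_artifact_csv", "read_artifact_csv",
    "write_subjects_csv", "read_subjects_csv",
    "write_matrix_csv", "read_matrix_csv",
]


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: RawRecording, path, record_duration_s: float = 1.0,
              start: str = "01.01.07 00.00.00") -> Path:
    """Write a RawRecording as a 16-bit EDF file.

    Per-channel physical min/max are set from the signal extrema so the
    quantization step is as small as the format allows.  The recording is
    truncated to a whole number of data records.
    """
    path = Path(path)
    fs = rec.fs
    spr = record_duration_s * fs
    if abs(spr - round(spr)) > 1e-9:
        raise InvalidParameterError("record_duration_s * fs must be an integer")
    spr = int(round(spr))
    n_rec = rec.n_times // spr
    if n_rec < 1:
        raise InvalidParameterError("recording shorter than one data record")
    ns = rec.n_channels
    date_s, time_s = start.split()

    pmins, pmaxs, scaled = [], [], []
    dmin, dmax = -32768, 32767
    for ch in range(ns):
        x = rec.samples[ch, : n_rec * spr]
        lo, hi = float(x.min()), float(x.max())
        if hi - lo < 1e-9:
            lo, hi = lo - 1.0, hi + 1.0
        pmins.append(lo)
        pmaxs.append(hi)
        gain = (dmax - dmin) / (hi - lo)
        d = np.round((x - lo) * gain + dmin).astype("<i2")
        scaled.append(d)

    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))                     # patient id
        f.write(_pad("Startdate X X X X", 80))           # recording id
        f.write(_pad(date_s, 8))
        f.write(_pad(time_s, 8))
        f.write(_pad(str(256 * (ns + 1)), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad(f"{record_duration_s:g}", 8))
        f.write(_pad(str(ns), 4))
        for lab in rec.channel_labels:
            f.write(_pad(f"EEG {lab}", 16))
        for _ in range(ns):
            f.write(_pad("", 80))                        # transducer
        for _ in range(ns):
            f.write(_pad("uV", 8))
        for v in pmins:
            f.write(_pad(f"{v:.6g}"[:8], 8))
        for v in pmaxs:
            f.write(_pad(f"{v:.6g}"[:8], 8))
        for _ in range(ns):
            f.write(_pad(str(dmin), 8))
        for _ in range(ns):
            f.write(_pad(str(dmax), 8))
        for _ in range(ns):
            f.write(_pad("", 80))                        # prefiltering
        for _ in range(ns):
            f.write(_pad(str(spr), 8))
        for _ in range(ns):
            f.write(_pad("", 32))
        for r in range(n_rec):
            for ch in range(ns):
                f.write(scaled[ch][r * spr:(r + 1) * spr].tobytes())
    return path


def _parse_edf_header(path: Path) -> dict:
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        ns = int(head[252:256].decode("ascii").strip())
        sig = f.read(256 * ns)
    labels = [sig[16 * i:16 * (i + 1)].decode("ascii").strip() for i in range(ns)]
    off = 16 * ns + 80 * ns + 8 * ns + 8 * ns + 8 * ns + 8 * ns + 8 * ns + 80 * ns
    spr = [int(sig[off + 8 * i: off + 8 * (i + 1)].decode("ascii").strip()) for i in range(ns)]
    return {"n_signals": ns, "labels": labels, "samples_per_record": spr,
            "record_duration": float(head[244:252].decode("ascii").strip())}


def _canon(label: str) -> str:
    lab = label.strip()
    if lab.upper().startswith("EEG "):
        lab = lab[4:].strip()
    return lab.split("-")[0].strip().lower()


def read_edf(path, montage: tuple[str, ...] = MONTAGE_10_20) -> RawRecording:
    """Read an EDF/EDF+ file and return the canonical 19-channel recording.

    Channels are matched to the montage case-insensitively (an ``EEG ``
    prefix or reference suffix like ``-A1`` is tolerated) and reordered to
    the canonical montage order; extra channels are dropped.  Missing
    montage channels or heterogeneous EEG sampling rates raise FormatError.
    """
    import mne

    path = Path(path)
    hdr = _parse_edf_header(path)
    canon_by_idx = [_canon(lab) for lab in hdr["labels"]]
    wanted = {m.lower(): m for m in montage}
    rates = {hdr["samples_per_record"][i] / hdr["record_duration"]
             for i, c in enumerate(canon_by_idx) if c in wanted}
    if len(rates) > 1:
        raise FormatError(f"{path}: heterogeneous EEG sampling rates {sorted(rates)}")
    present = {c for c in canon_by_idx if c in wanted}
    missing = [m for m in montage if m.lower() not in present]
    if missing:
        raise FormatError(f"{path}: missing montage channel(s): {', '.join(missing)}")

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    name_map = {_canon(nm): nm for nm in raw.ch_names}
    picks = [name_map[m.lower()] for m in montage]
    data = raw.get_data(picks=picks, units="uV")
    return RawRecording(samples=data, fs=float(raw.info["sfreq"]), channel_labels=montage)


# ---------------------------------------------------------------------------
# CSV formats

def write_hypnogram_csv(hyp: Hypnogram, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "epoch_index": range(len(hyp)),
        "onset_s": [hyp.onset_s(k) for k in range(len(hyp))],
        "stage": list(hyp.stages),
    })
    df.to_csv(path, index=False)
    return path


def read_hypnogram_csv(path) -> Hypnogram:
    df = pd.read_csv(path, dtype={"stage": str})
    if len(df) > 1:
        step = float(df["onset_s"].iloc[1] - df["onset_s"].iloc[0])
    else:
        step = 20.0
    return Hypnogram(stages=tuple(df["stage"]), scoring_epoch_s=step)


def write_artifact_csv(mask: ArtifactMask, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "epoch_index": range(len(mask)),
        "clean": mask.clean.astype(int),
    }).to_csv(path, index=False)
    return path


def read_artifact_csv(path) -> ArtifactMask:
    df = pd.read_csv(path)
    return ArtifactMask(clean=df["clean"].to_numpy().astype(bool))


def write_subjects_csv(subjects: list[SubjectRecord], path) -> Path:
    path = Path(path)
    pd.DataFrame([{
        "subject_id": s.subject_id, "sex": s.sex, "age": s.age, "bdi": s.bdi,
        "group": s.group,
    } for s in subjects]).to_csv(path, index=False)
    return path


def read_subjects_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str, "sex": str})


def write_matrix_csv(cm: ConnectivityMatrix, path, sidecar: dict | None = None) -> Path:
    """Connectivity matrix as labelled CSV plus a JSON provenance sidecar."""
    path = Path(path)
    labels = list(cm.channel_labels) or [f"ch{i}" for i in range(cm.n_channels)]
    pd.DataFrame(cm.values, index=labels, columns=labels).to_csv(path)
    meta = {"domain": cm.domain, "max_clamp": cm.max_clamp, **cm.meta}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))
    return path


def read_matrix_csv(path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = {}
    sc = path.with_suffix(".json")
    if sc.exists():
        meta = json.loads(sc.read_text())
    return ConnectivityMatrix(
        values=df.to_numpy(), domain=str(meta.get("domain", "time")),
        channel_labels=tuple(df.columns), meta=meta,
    )
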