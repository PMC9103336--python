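"""Readers and writers for recordings, annotations, features and results.

On-disk layout of a dataset directory::

    <dir>/manifest.csv                   id,label,snr_db,fhr_bpm,mhr_bpm,seed
    <dir>/<id>.csv                       waveforms: '# fs=1000' line, then
                                         header M,A1,A2,A3, one row per sample
    <dir>/<id>.mqrs.txt, <id>.fqrs.txt   one R-peak sample index per line

Feature tables are plain CSV with segment_id, label and the 45 named
feature columns.  Spectrogram tensors travel as NPZ containers keyed by
segment id.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fecgsqi.errors import FormatError
from fecgsqi.sqi import FEATURE_NAMES, FeatureVector
from fecgsqi.synth import CHANNEL_NAMES, Recording

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_dataset",
    "read_dataset",
    "write_annotation",
    "read_annotation",
    "write_features_csv",
    "read_features_csv",
    "write_json",
]


def write_annotation(path: str | Path, indices: np.ndarray) -> None:
    Path(path).write_text("".join(f"{int(i)}\n" for i in indices))


def read_annotation(path: str | Path) -> np.ndarray:
    text = Path(path).read_text().split()
    try:
        idx = np.asarray([int(t) for t in text], dtype=np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: annotation files carry one integer per line") from exc
    if idx.size and np.any(np.diff(idx) <= 0):
        raise FormatError(f"{path}: annotation indices must be strictly increasing")
    return idx


def write_recording_csv(path: str | Path, recording: Recording) -> None:
    """Waveform CSV with an `# fs=` comment line and M,A1,A2,A3 columns."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={recording.fs:g}\n")
        fh.write(",".join(CHANNEL_NAMES) + "\n")
        np.savetxt(fh, recording.channels.T, delimiter=",", fmt="%.10g")
    base = path.with_suffix("")
    if recording.mqrs.size:
        write_annotation(base.with_suffix(".mqrs.txt"), recording.mqrs)
    if recording.fqrs.size:
        write_annotation(base.with_suffix(".fqrs.txt"), recording.fqrs)


def read_recording_csv(path: str | Path, label: str = "unknown") -> Recording:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise FormatError(f"{path}:1: expected a '# fs=<rate>' comment line")
        try:
            fs = float(first.split("=", 1)[1])
        except ValueError as exc:
            raise FormatError(f"{path}:1: unparseable sampling rate") from exc
        frame = pd.read_csv(fh)
    missing = [c for c in CHANNEL_NAMES if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing channel column(s) {missing}")
    base = path.with_suffix("")
    kwargs = {}
    for ann in ("mqrs", "fqrs"):
        ann_path = base.with_suffix(f".{ann}.txt")
        if ann_path.exists():
            kwargs[ann] = read_annotation(ann_path)
    return Recording(
        channels=frame[list(CHANNEL_NAMES)].to_numpy().T,
        fs=fs,
        label=label,
        id=path.stem,
        **kwargs,
    )


def write_dataset(out_dir: str | Path, recordings: list[Recording]) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        write_recording_csv(out_dir / f"{rec.id}.csv", rec)
        rows.append(
            {
                "id": rec.id,
                "label": rec.label,
                "snr_db": rec.meta.get("target_foetal_snr_db", np.nan),
                "fhr_bpm": rec.meta.get("fhr_bpm", np.nan),
                "mhr_bpm": rec.meta.get("mhr_bpm", np.nan),
                "seed": rec.meta.get("seed", -1),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)


def read_dataset(in_dir: str | Path) -> list[Recording]:
    in_dir = Path(in_dir)
    manifest = in_dir / "manifest.csv"
    if not manifest.exists():
        raise FormatError(f"{in_dir}: no manifest.csv found")
    rows = pd.read_csv(manifest)
    recordings = []
    for _, row in rows.iterrows():
        rec = read_recording_csv(in_dir / f"{row['id']}.csv", label=str(row["label"]))
        rec.meta.update(
            {k: row[k] for k in ("snr_db", "fhr_bpm", "mhr_bpm", "seed") if k in row}
        )
        recordings.append(rec)
    return recordings


def write_features_csv(path: str | Path, vectors: list[FeatureVector], labels: list[str]) -> None:
    rows = []
    for vec, label in zip(vectors, labels):
        row = {"segment_id": vec.segment_id, "label": label}
        row.update(vec.as_dict())
        rows.append(row)
    pd.DataFrame(rows, columns=["segment_id", "label", *FEATURE_NAMES]).to_csv(path, index=False)


def read_features_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Returns (feature matrix (n, 45), binary labels, segment ids)."""
    frame = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing feature column(s) {missing[:3]}...")
    x = frame[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = (frame["label"].astype(str) == "good").to_numpy().astype(int)
    return x, y, frame["segment_id"].astype(str).tolist()


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_coerce) + "\n")


def _coerce(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
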