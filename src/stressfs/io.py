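"""Readers and writers for recordings and schedules.

Recordings come in as EDF (via MNE) or plain numeric CSV/TSV.  The text
layout is: first line = channel names, one subsequent line per channel with
its samples.  The sampling rate travels in a ``<file>.meta.yaml`` sidecar
(key ``fs``) unless passed explicitly.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import yaml

from .preprocessing import EEGRecording

__all__ = ["read_edf", "read_recording_csv", "write_recording_csv", "read_schedule_csv"]


def read_edf(path) -> EEGRecording:
    """Load a European Data Format recording (all channels, microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # MNE stores EEG in volts; convert to microvolts.
    return EEGRecording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
    )


def _sidecar_fs(path: Path) -> float:
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"no sampling rate given and no sidecar {sidecar.name} found"
        )
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    return float(meta["fs"])


def read_recording_csv(path, fs: float | None = None) -> EEGRecording:
    """Read a channels-as-rows CSV/TSV recording (see module docstring)."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        names = [c.strip() for c in next(reader)]
        rows = [[float(v) for v in row] for row in reader if row]
    if len(rows) != len(names):
        raise ValueError(
            f"{len(names)} channel names but {len(rows)} channel rows in {path.name}"
        )
    if fs is None:
        fs = _sidecar_fs(path)
    return EEGRecording(np.asarray(rows), fs, tuple(names))


def write_recording_csv(rec: EEGRecording, path) -> None:
    """Inverse of :func:`read_recording_csv`, including the fs sidecar."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(rec.channel_names)
        for row in rec.data:
            writer.writerow([repr(float(v)) for v in row])
    with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
        yaml.safe_dump({"fs": float(rec.fs)}, fh)


def read_schedule_csv(path) -> list[tuple[float, int | None]]:
    """Epoch schedule CSV with columns ``start_s,label`` (label may be blank)."""
    out: list[tuple[float, int | None]] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            label = row.get("label", "")
            out.append(
                (float(row["start_s"]), int(label) if label not in ("", None) else None)
            )
    return out
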