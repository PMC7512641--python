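"""Reading and writing recordings and cohort manifests.

EDF reading goes through mne.  Writing uses a minimal 16-bit EDF encoder
implemented here (continuous recordings, one-second data records), since no
installed library exports EDF; round-tripping through mne's reader is part of
the test suite.  A plain TSV matrix format is provided as a lossless text
fallback.  Cohorts are described by a delimited manifest
(subject_id, class, file, seed).
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CHANNELS_1020, EEGRecording

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF (one-second records, 'uV' units).

    ``fs`` must be a whole number of samples per second; the tail beyond the
    last whole second is dropped.  Physical scaling is per channel over the
    written data range, so quantization error is at most range/65535.
    """
    path = Path(path)
    fs = recording.fs
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError(f"EDF export needs an integer sampling rate, got fs={fs}")
    n_records = recording.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    ns = recording.n_channels
    data = recording.samples[:, : n_records * spr]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad(recording.subject_id or "X", 80),
        _pad(f"Startdate 01-JAN-2000 {recording.class_label}", 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (1 + ns)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    fields = [
        [f"EEG {ch}" for ch in recording.channel_labels],
        ["" for _ in range(ns)],
        ["uV" for _ in range(ns)],
        [f"{v:.8g}"[:8] for v in phys_min],
        [f"{v:.8g}"[:8] for v in phys_max],
        [str(_EDF_DIG_MIN) for _ in range(ns)],
        [str(_EDF_DIG_MAX) for _ in range(ns)],
        ["" for _ in range(ns)],
        [str(spr) for _ in range(ns)],
        ["" for _ in range(ns)],
    ]
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    sig_header = b"".join(
        b"".join(_pad(v, w) for v in col) for col, w in zip(fields, widths)
    )

    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * scale[:, None] + _EDF_DIG_MIN)
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")
    # EDF body: records consecutive; within a record, channels consecutive.
    body = (
        digital.reshape(ns, n_records, spr)
        .transpose(1, 0, 2)
        .tobytes()
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header + body)
    return path


def read_edf(
    path: str | Path,
    subject_id: str = "",
    class_label: str = "unknown",
    reorder: bool = True,
) -> EEGRecording:
    """Read an EDF file via mne into an :class:`EEGRecording` (microvolts).

    Channel labels are matched case-insensitively against the 19-name 10-20
    canon (an ``EEG `` prefix is stripped) and reordered to canonical order;
    unmatched channels keep their file order after the matched ones.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads EEG in volts
    labels = [ch[4:] if ch.upper().startswith("EEG ") else ch for ch in raw.ch_names]
    if reorder:
        canon = {name.lower(): name for name in CHANNELS_1020}
        matched, extra = {}, []
        for i, lab in enumerate(labels):
            key = lab.strip().lower()
            if key in canon:
                matched[canon[key]] = i
            else:
                extra.append(i)
        order = [matched[name] for name in CHANNELS_1020 if name in matched] + extra
        data = data[order]
        labels = [
            canon.get(labels[i].strip().lower(), labels[i].strip()) for i in order
        ]
    if not subject_id:
        subject_id = Path(path).stem
    return EEGRecording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(labels),
        subject_id=subject_id,
        class_label=class_label,
    )


def write_csv(recording: EEGRecording, path: str | Path) -> Path:
    """Lossless text fallback: TSV, one column per channel, '#'-prefixed header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={recording.fs!r}\n")
        fh.write(f"# subject_id={recording.subject_id}\n")
        fh.write(f"# class_label={recording.class_label}\n")
        fh.write("\t".join(recording.channel_labels) + "\n")
        np.savetxt(fh, recording.samples.T, fmt="%.17g", delimiter="\t")
    return path


def read_csv(path: str | Path) -> EEGRecording:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            line = fh.readline()
        labels = tuple(line.strip().split("\t"))
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return EEGRecording(
        samples=data.T,
        fs=float(meta.get("fs", "256.0")),
        channel_labels=labels,
        subject_id=meta.get("subject_id", path.stem),
        class_label=meta.get("class_label", "unknown"),
    )


def write_cohort(
    recordings: list[EEGRecording],
    out_dir: str | Path,
    fmt: str = "edf",
    seed: int | None = None,
) -> Path:
    """Write one file per subject plus a ``manifest.tsv``; returns the manifest path."""
    if fmt not in ("edf", "csv"):
        raise ValueError(f"fmt must be 'edf' or 'csv', got {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.{fmt}"
        if fmt == "edf":
            write_edf(rec, out_dir / fname)
        else:
            write_csv(rec, out_dir / fname)
        rows.append({
            "subject_id": rec.subject_id,
            "class": rec.class_label,
            "file": fname,
            "seed": "" if seed is None else seed,
        })
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_cohort(manifest_path: str | Path) -> list[EEGRecording]:
    """Load every recording listed in a cohort manifest."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t")
    base = manifest_path.parent
    recs = []
    for _, row in table.iterrows():
        f = base / str(row["file"])
        if f.suffix.lower() == ".edf":
            rec = read_edf(f, subject_id=str(row["subject_id"]),
                           class_label=str(row["class"]))
        else:
            rec = read_csv(f)
        recs.append(rec)
    return recs
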