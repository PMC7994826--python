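"""Dataset I/O: CSV records with a manifest, and a minimal WFDB reader.

The native on-disk layout is one CSV file per record (one sample per row,
no header) plus a manifest CSV with columns ``id,path,label,fs``; paths are
resolved relative to the manifest's directory.  A small reader for
WFDB-style records (text ``.hea`` header plus format-16 binary ``.dat``)
is provided as a convenience for PhysioNet-downloaded data.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TimeSeries

__all__ = ["read_csv_dataset", "write_csv_dataset", "read_wfdb_record"]


def write_csv_dataset(records: list[TimeSeries], outdir: str | Path) -> Path:
    """Write records and their manifest under ``outdir``; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.id}.csv"
        np.savetxt(outdir / fname, rec.samples, fmt="%.17g")
        rows.append({"id": rec.id, "path": fname, "label": rec.label, "fs": rec.fs})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_csv_dataset(manifest_path: str | Path) -> list[TimeSeries]:
    """Load every record listed in a manifest CSV.

    Errors are specific: a duplicate id, a missing record file (named), or
    a non-numeric sample cell (with its row number).
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path, dtype={"id": str, "path": str, "label": str})
    for col in ("id", "path", "fs"):
        if col not in table.columns:
            raise ValueError(f"manifest is missing required column {col!r}")
    if table["id"].duplicated().any():
        dup = table.loc[table["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate record id {dup!r} in manifest")
    records = []
    for row in table.itertuples(index=False):
        path = base / row.path
        if not path.exists():
            raise FileNotFoundError(f"record file not found: {path}")
        samples = []
        with open(path, newline="") as fh:
            for lineno, line in enumerate(csv.reader(fh), start=1):
                if not line:
                    continue
                try:
                    samples.append(float(line[0]))
                except ValueError:
                    raise ValueError(
                        f"non-numeric sample {line[0]!r} at row {lineno} of {path}"
                    ) from None
        label = None if pd.isna(getattr(row, "label", None)) else row.label
        records.append(TimeSeries(id=row.id, samples=np.asarray(samples), fs=float(row.fs), label=label))
    return records


def read_wfdb_record(path: str | Path, channel: int = 0, label: str | None = None) -> TimeSeries:
    """Read one channel of a WFDB record (``.hea`` header + format-16 ``.dat``).

    ``path`` is the record path without extension.  Samples are converted to
    physical units via ``(adc - baseline) / gain``.  Only signal format 16
    (16-bit little-endian two's complement, channels interleaved) is
    supported; other formats raise.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    if not (0 <= channel < n_sig):
        raise ValueError(f"channel {channel} out of range; record has {n_sig} signal(s)")
    sig_lines = lines[1 : 1 + n_sig]
    gains, baselines, files, fmts = [], [], [], []
    for ln in sig_lines:
        tok = ln.split()
        files.append(tok[0])
        fmt = tok[1].split("x")[0].split(":")[0].split("+")[0]
        fmts.append(fmt)
        gain_tok = tok[2] if len(tok) > 2 else "200"
        gain_part = gain_tok.split("/")[0]
        if "(" in gain_part:
            g, b = gain_part.split("(")
            gains.append(float(g))
            baselines.append(float(b.rstrip(")")))
        else:
            gains.append(float(gain_part))
            baselines.append(float(tok[4]) if len(tok) > 4 else 0.0)
    if fmts[channel] != "16":
        raise NotImplementedError(f"unsupported WFDB signal format {fmts[channel]!r}; only 16")
    dat = path.parent / files[channel]
    if not dat.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    adc = raw[channel::n_sig].astype(float)
    samples = (adc - baselines[channel]) / gains[channel]
    return TimeSeries(id=path.stem, samples=samples, fs=fs, label=label)
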