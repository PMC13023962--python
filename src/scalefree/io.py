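"""Cohort serialization and ingestion.

A cohort on disk is a directory with a ``metadata.csv`` table (one row
per channel: subject_id, region, channel, fs, age, sex, optional
ground-truth exponent columns, and a ``file`` column naming the signal
file relative to the directory) plus the per-channel signal files.
Signals are delimited text (one sample per line, full float precision)
or EDF; EDF reading goes through MNE and is converted to microvolts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import TimeSeries
from .spectral import SpectrumEstimate
from .synthetic import Cohort

__all__ = ["write_cohort", "read_channel_table", "export_spectrum_csv"]

REQUIRED_COLUMNS = ("subject_id", "region", "channel", "fs")


def write_cohort(cohort: Cohort, path) -> Path:
    """Write a cohort as metadata.csv + one text file per channel."""
    path = Path(path)
    (path / "channels").mkdir(parents=True, exist_ok=True)
    rows = []
    truth = cohort.truth.set_index("channel") if "channel" in cohort.truth else None
    for ts in cohort.channels:
        fname = f"channels/{ts.channel_id}.txt"
        np.savetxt(path / fname, ts.samples, fmt="%.17g")
        row = {"subject_id": ts.subject_id, "region": ts.region,
               "channel": ts.channel_id, "fs": ts.fs, "age": ts.age,
               "sex": ts.sex, "file": fname}
        if truth is not None and ts.channel_id in truth.index:
            for col in truth.columns:
                if col.startswith("true_beta"):
                    row[col] = truth.loc[ts.channel_id, col]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path / "metadata.csv", index=False)
    return path


def _read_edf_channel(file: Path, channel: str) -> tuple[np.ndarray, float]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF files requires the 'mne' package "
                          "(install scalefree[edf])") from exc
    raw = mne.io.read_raw_edf(file, preload=True, verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(f"channel: {channel!r} not found in {file.name} "
                         f"(has {raw.ch_names})")
    data = raw.get_data(picks=[channel])[0] * 1e6  # MNE returns volts
    return data, float(raw.info["sfreq"])


def read_channel_table(path) -> Cohort:
    """Load a cohort from a metadata table.

    ``path`` is the cohort directory (containing ``metadata.csv``) or the
    metadata CSV itself.  Channels with non-finite samples are rejected
    collectively with a per-channel report; a sampling-rate mismatch
    between metadata and an EDF header is an error.
    """
    path = Path(path)
    meta_path = path / "metadata.csv" if path.is_dir() else path
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata table not found: {meta_path}")
    root = meta_path.parent
    table = pd.read_csv(meta_path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metadata: missing required columns {missing}")
    has_file = "file" in table.columns
    has_inline = "samples" in table.columns
    if not has_file and not has_inline:
        raise ValueError("metadata: needs a 'file' or 'samples' column")
    channels, bad = [], []
    for _, row in table.iterrows():
        fs = float(row["fs"])
        if has_file and isinstance(row.get("file"), str):
            file = root / row["file"]
            if not file.exists():
                bad.append((row["channel"], f"file not found: {file}"))
                continue
            if file.suffix.lower() == ".edf":
                samples, fs_file = _read_edf_channel(file, str(row["channel"]))
                if abs(fs_file - fs) > 1e-6:
                    bad.append((row["channel"],
                                f"fs mismatch: metadata {fs}, EDF {fs_file}"))
                    continue
            else:
                samples = np.loadtxt(file, dtype=float)
        else:
            samples = np.fromstring(str(row["samples"]), sep=";")
        if samples.size < 2 or not np.all(np.isfinite(samples)):
            bad.append((row["channel"], "non-finite or too-short signal"))
            continue
        channels.append(TimeSeries(
            samples, fs, subject_id=str(row["subject_id"]),
            region=str(row["region"]), channel_id=str(row["channel"]),
            age=float(row["age"]) if "age" in table and pd.notna(row.get("age")) else None,
            sex=str(row["sex"]) if "sex" in table and pd.notna(row.get("sex")) else None))
    if bad:
        report = "; ".join(f"{ch}: {why}" for ch, why in bad)
        raise ValueError(f"metadata: {len(bad)} unreadable channels ({report})")
    return Cohort(channels=channels, truth=table, spec=None)


def export_spectrum_csv(sp: SpectrumEstimate, path) -> Path:
    """Write a spectrum as (freq_hz, psd) CSV with a JSON settings sidecar."""
    path = Path(path)
    pd.DataFrame({"freq_hz": sp.freqs, "psd": sp.psd}).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    settings = {k: v for k, v in sp.settings.items()}
    sidecar.write_text(json.dumps(settings, default=str, indent=2))
    return path
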