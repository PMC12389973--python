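"""Dataset persistence: NPZ numeric archives with CSV manifests.

A dataset directory contains one ``<subject_id>.npz`` per subject (keys:
``data`` [L x T] and ``sampling_rate``) plus ``manifest.csv`` with columns
subject_id, label, domain_id, file, sampling_rate. Lead fields are stored as
``leadfield.npz`` (key ``gain``) plus ``roi_map.csv`` (source_index,
roi_index, roi_name).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import roi_labels
from .synthetic import EEGRecording, LeadField


def write_dataset(recordings: list[EEGRecording], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.npz"
        np.savez(out / fname, data=rec.data, sampling_rate=rec.sampling_rate,
                 channel_names=np.array(rec.channel_names))
        rows.append({"subject_id": rec.subject_id, "label": rec.label,
                     "domain_id": rec.domain_id, "file": fname,
                     "sampling_rate": rec.sampling_rate})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(in_dir: str | Path) -> list[EEGRecording]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    recs = []
    for row in manifest.itertuples():
        with np.load(in_dir / row.file) as npz:
            recs.append(EEGRecording(
                data=npz["data"],
                sampling_rate=float(npz["sampling_rate"]),
                channel_names=[str(c) for c in npz["channel_names"]],
                subject_id=str(row.subject_id),
                label=int(row.label),
                domain_id=str(row.domain_id),
            ))
    return recs


def write_lead_field(lf: LeadField, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "leadfield.npz", gain=lf.gain,
             source_orientation=lf.source_orientation)
    labels = roi_labels()
    n = lf.n_rois
    names = labels if n == len(labels) else [f"ROI-{i + 1}" for i in range(n)]
    pd.DataFrame({
        "source_index": np.arange(lf.n_sources),
        "roi_index": lf.roi_of_source,
        "roi_name": [names[r - 1] for r in lf.roi_of_source],
    }).to_csv(out / "roi_map.csv", index=False)
    return out / "leadfield.npz"


def read_lead_field(in_dir: str | Path) -> LeadField:
    in_dir = Path(in_dir)
    with np.load(in_dir / "leadfield.npz") as npz:
        gain = npz["gain"]
        orient = npz["source_orientation"]
    roi_map = pd.read_csv(in_dir / "roi_map.csv")
    return LeadField(gain=gain,
                     roi_of_source=roi_map["roi_index"].to_numpy(np.int64),
                     source_orientation=orient)


def write_history(history: list[dict], path: str | Path) -> None:
    """Structured run log as JSON lines."""
    with open(path, "w") as fh:
        for row in history:
            fh.write(json.dumps(row) + "\n")
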