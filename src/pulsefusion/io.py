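"""Flat-file formats: recording CSV, GSR CSV, panel CSV, cohort manifest.

All inter-stage data are plain CSV/JSON. Formats:

* recording CSV — columns ``time_s, amplitude``; uniform, strictly
  increasing timestamps.
* raw GSR CSV — columns ``acupoint_code, side, time_s, resistance_ohm``.
* panel CSV — a single row of 24 named columns (``<channel>_kohm``),
  values in kilo-ohms for readability (stored internally in ohms).
* cohort manifest JSON — subject ids, labels, recording paths and panels.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataFormatError
from .gsrpanel import CHANNELS, GSRPanel, GSRSample
from .preprocess import PPGRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_panel",
    "read_panel",
    "read_gsr_samples",
    "write_gsr_samples",
    "write_cohort",
    "read_cohort_manifest",
]


def write_recording(recording: PPGRecording, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame({"time_s": recording.times, "amplitude": recording.samples})
    frame.to_csv(path, index=False, float_format="%.8g")
    return path


def read_recording(path: str | Path, expected_rate: float | None = None) -> PPGRecording:
    """Read and validate a two-column recording CSV.

    Timestamps must be strictly increasing and uniform; the inferred
    sampling rate must match ``expected_rate`` (when given) within 0.1%.
    Offending rows are reported by line number (1-based, header = line 1).
    """
    path = Path(path)
    frame = pd.read_csv(path)
    required = {"time_s", "amplitude"}
    if not required.issubset(frame.columns):
        raise DataFormatError(f"{path}: expected columns {sorted(required)}")
    bad = frame.index[frame[["time_s", "amplitude"]].isna().any(axis=1)]
    if len(bad):
        raise DataFormatError(f"{path}: NaN at line {int(bad[0]) + 2}")
    t = frame["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.argmax(dt <= 0)) + 3
        raise DataFormatError(f"{path}: non-increasing timestamp at line {line}")
    median_dt = float(np.median(dt))
    irregular = np.abs(dt - median_dt) > 1e-3 * median_dt
    if np.any(irregular):
        line = int(np.argmax(irregular)) + 3
        raise DataFormatError(f"{path}: non-uniform sampling interval at line {line}")
    rate = 1.0 / median_dt
    if expected_rate is not None and abs(rate - expected_rate) > 1e-3 * expected_rate:
        raise DataFormatError(
            f"{path}: inferred rate {rate:.4f} Hz does not match declared {expected_rate} Hz"
        )
    return PPGRecording(
        samples=frame["amplitude"].to_numpy(dtype=float),
        sampling_rate=rate,
        start_time=float(t[0]),
        subject_id=path.stem,
    )


def write_panel(panel: GSRPanel, path: str | Path) -> Path:
    path = Path(path)
    row = {f"{c}_kohm": v / 1e3 for c, v in zip(CHANNELS, panel.values)}
    pd.DataFrame([row]).to_csv(path, index=False, float_format="%.10g")
    return path


def read_panel(path: str | Path) -> GSRPanel:
    frame = pd.read_csv(path)
    missing = [c for c in CHANNELS if f"{c}_kohm" not in frame.columns]
    if missing:
        raise DataFormatError(f"{path}: missing panel columns for {missing}")
    if len(frame) != 1:
        raise DataFormatError(f"{path}: a panel CSV holds exactly one row")
    values = np.array([frame[f"{c}_kohm"].iloc[0] for c in CHANNELS], dtype=float) * 1e3
    return GSRPanel(values=values)


def write_gsr_samples(samples: list[GSRSample], path: str | Path) -> Path:
    path = Path(path)
    frames = []
    for s in samples:
        t = np.arange(s.samples.size) / s.sampling_rate
        frames.append(
            pd.DataFrame(
                {
                    "acupoint_code": s.acupoint_code,
                    "side": s.side,
                    "time_s": t,
                    "resistance_ohm": s.samples,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
    return path


def read_gsr_samples(path: str | Path) -> list[GSRSample]:
    path = Path(path)
    frame = pd.read_csv(path)
    required = {"acupoint_code", "side", "time_s", "resistance_ohm"}
    if not required.issubset(frame.columns):
        raise DataFormatError(f"{path}: expected columns {sorted(required)}")
    out = []
    for (code, side), group in frame.groupby(["acupoint_code", "side"], sort=False):
        t = group["time_s"].to_numpy(dtype=float)
        rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 200.0
        out.append(
            GSRSample(
                acupoint_code=str(code),
                side=str(side),
                samples=group["resistance_ohm"].to_numpy(dtype=float),
                sampling_rate=rate,
            )
        )
    return out


def write_cohort(records, out_dir: str | Path) -> Path:
    """Write each subject's recording CSV plus a manifest JSON with labels
    and GSR panels; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": []}
    for record in records:
        rec_path = out_dir / f"{record.subject_id}_ppg.csv"
        write_recording(record.recording, rec_path)
        manifest["subjects"].append(
            {
                "subject_id": record.subject_id,
                "label": int(record.label),
                "recording": rec_path.name,
                "sampling_rate": record.recording.sampling_rate,
                "gsr_panel_ohm": record.gsr_panel.as_dict(),
            }
        )
    manifest_path = out_dir / "cohort.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort_manifest(manifest_path: str | Path):
    """Load a cohort written by :func:`write_cohort` back into subject
    records."""
    from .synth import SubjectRecord  # local import: io must not depend on synth at import time

    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    records = []
    for entry in manifest["subjects"]:
        recording = read_recording(
            manifest_path.parent / entry["recording"], expected_rate=entry["sampling_rate"]
        )
        recording = replace(recording, subject_id=entry["subject_id"])
        panel = GSRPanel(values=np.array([entry["gsr_panel_ohm"][c] for c in CHANNELS]))
        records.append(
            SubjectRecord(
                subject_id=entry["subject_id"],
                label=int(entry["label"]),
                recording=recording,
                gsr_panel=panel,
            )
        )
    return records
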