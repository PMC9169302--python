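"""Disk formats: WAV audio, JSON-lines corpus metadata, CSV feature tables.

A corpus on disk is one directory of mono 16-bit PCM WAV files at the
sensor rate (9603 Hz) plus a ``metadata.jsonl`` table with one JSON
record per file (filename, labels, timestamp, temperature, validity and,
for synthetic recordings, the drawn ground truth). Feature tables are
one CSV per feature (row per recording, label columns appended) with a
``manifest.json`` sidecar describing dimensions and provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from wingbeat.dataset import LabeledCorpus
from wingbeat.dsp import FEATURE_DIMS, FEATURE_NAMES
from wingbeat.sensor_sim import WingbeatRecording

_PCM_SCALE = 32767


def export_audio(recording: WingbeatRecording, path: str | Path) -> Path:
    """Write one recording as a mono 16-bit PCM WAV at its sampling rate.

    Samples in [-1, 1] map to the full signed 16-bit range, so a read-back
    agrees with the original within one quantization step (1/32767).
    """
    if len(np.asarray(recording.samples)) == 0:
        raise ValueError("cannot export an empty recording")
    path = Path(path)
    pcm = np.round(np.clip(recording.samples, -1.0, 1.0) * _PCM_SCALE).astype(np.int16)
    wavfile.write(path, int(recording.sampling_rate), pcm)
    return path


def read_audio(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file back to float samples in [-1, 1] and its sample rate."""
    rate, pcm = wavfile.read(path)
    if pcm.dtype == np.int16:
        samples = pcm.astype(float) / _PCM_SCALE
    else:
        samples = pcm.astype(float)
    return samples, int(rate)


def _meta_record(rec: WingbeatRecording, filename: str) -> dict:
    return {
        "filename": filename,
        "species": rec.species,
        "sex": rec.sex,
        "genus": rec.genus,
        "timestamp": rec.timestamp,
        "temperature_C": rec.ambient_temperature,
        "valid": rec.valid,
        "true_f1": rec.true_f1,
        "true_peak_power_db": rec.true_peak_power_db,
        "true_duration_ms": rec.true_duration_ms,
    }


def save_corpus(corpus: LabeledCorpus, directory: str | Path) -> Path:
    """Write a corpus as WAV files plus a metadata.jsonl table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = []
    for i, rec in enumerate(corpus.recordings):
        filename = f"rec_{i:06d}.wav"
        export_audio(rec, directory / filename)
        lines.append(json.dumps(_meta_record(rec, filename)))
    (directory / "metadata.jsonl").write_text("\n".join(lines) + "\n")
    return directory


def load_corpus(directory: str | Path) -> LabeledCorpus:
    """Read a corpus directory written by :func:`save_corpus`."""
    directory = Path(directory)
    meta_path = directory / "metadata.jsonl"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.jsonl in {directory}")
    recordings = []
    for line in meta_path.read_text().splitlines():
        if not line.strip():
            continue
        meta = json.loads(line)
        samples, rate = read_audio(directory / meta["filename"])
        recordings.append(
            WingbeatRecording(
                samples=samples,
                sampling_rate=rate,
                timestamp=meta["timestamp"],
                ambient_temperature=meta["temperature_C"],
                species=meta["species"],
                sex=meta["sex"],
                genus=meta["genus"],
                valid=meta["valid"],
                true_f1=meta.get("true_f1"),
                true_peak_power_db=meta.get("true_peak_power_db"),
                true_duration_ms=meta.get("true_duration_ms"),
            )
        )
    return LabeledCorpus(recordings=recordings)


def write_feature_tables(
    corpus: LabeledCorpus, directory: str | Path, feature_matrices: dict[str, np.ndarray]
) -> Path:
    """One CSV per feature (values + label columns) and a manifest sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels = pd.DataFrame(
        {
            "species": corpus.labels("species"),
            "sex": corpus.labels("sex"),
            "genus": corpus.labels("genus"),
        }
    )
    manifest = {}
    for name, X in feature_matrices.items():
        cols = [f"{name}_{j}" for j in range(X.shape[1])]
        df = pd.concat([pd.DataFrame(X, columns=cols), labels], axis=1)
        df.to_csv(directory / f"{name}.csv", index=False)
        manifest[name] = {"n_rows": int(X.shape[0]), "n_values": int(X.shape[1]),
                          "expected_values": FEATURE_DIMS[name]}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def read_feature_table(directory: str | Path, feature: str) -> tuple[np.ndarray, pd.DataFrame]:
    """Read one feature CSV back into (values matrix, label frame)."""
    if feature not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature!r}")
    df = pd.read_csv(Path(directory) / f"{feature}.csv")
    label_cols = ["species", "sex", "genus"]
    X = df.drop(columns=label_cols).to_numpy(dtype=float)
    return X, df[label_cols]
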