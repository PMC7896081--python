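"""File formats: CSV annotation tables and HDF5 time-series layouts.

Conventions stated in every file: intervals are half-open, 0-based, frame
units at 100 Hz (tables carry seconds; seconds x 100 -> frames exactly).
Unvoiced frames are NaN in ``/stim/f0`` and empty fields in F0 CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import SchemaError
from .features import PitchFeatureSet, StimulusFeatures
from .preproc import NeuralRecording
from .synth import ElectrodeTruth, SyntheticGroundTruth, SyntheticStimulus

SYLLABLE_COLUMNS = ["sentence_id", "speaker_id", "syllable_onset_s", "vowel_onset_s"]
PHRASE_COLUMNS = ["phrase_id", "start_s", "end_s"]


# ---------------------------------------------------------------------------
# CSV tables


def write_syllable_table(path, table: pd.DataFrame) -> None:
    cols = SYLLABLE_COLUMNS + (["tone"] if "tone" in table.columns else [])
    table[cols].to_csv(path, index=False)


def read_syllable_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path)
    missing = [c for c in SYLLABLE_COLUMNS if c not in tab.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if "tone" in tab.columns:
        bad = ~tab["tone"].isin([1, 2, 3, 4])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: invalid tone {tab['tone'].iloc[row]!r} at row {row} "
                "(column 'tone'; valid values 1-4)"
            )
        tab["tone"] = tab["tone"].astype(int)
    return tab


def write_phrase_table(path, table: pd.DataFrame) -> None:
    table[PHRASE_COLUMNS].to_csv(path, index=False)


def read_phrase_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path)
    missing = [c for c in PHRASE_COLUMNS if c not in tab.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if (tab["end_s"] <= tab["start_s"]).any():
        row = int(np.flatnonzero((tab["end_s"] <= tab["start_s"]).to_numpy())[0])
        raise SchemaError(f"{path}: end_s <= start_s at row {row}")
    return tab


def write_f0_csv(path, f0: np.ndarray, fs: float = 100.0) -> None:
    """Two-column CSV (time_s, f0_hz); unvoiced frames have an empty field."""
    t = np.arange(f0.size) / fs
    with open(path, "w") as fh:
        fh.write("time_s,f0_hz\n")
        for ti, v in zip(t, f0):
            fh.write(f"{ti:.2f},{'' if not np.isfinite(v) else f'{v:.6g}'}\n")


def read_f0_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (f0 with NaN on unvoiced frames, voicing bool array)."""
    tab = pd.read_csv(path)
    for col in ("time_s", "f0_hz"):
        if col not in tab.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    f0 = tab["f0_hz"].to_numpy(dtype=float)
    return f0, np.isfinite(f0)


# ---------------------------------------------------------------------------
# HDF5 layouts


def _require_attr(grp, name: str, path) -> float:
    if name not in grp.attrs:
        raise SchemaError(f"{path}: missing required attribute {name!r} on {grp.name!r}")
    return grp.attrs[name]


def write_stimulus(directory, stimulus: SyntheticStimulus) -> None:
    """Stimulus -> syllables.csv, phrases.csv, stim.h5 (/stim/f0 etc., fs attr)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_syllable_table(directory / "syllables.csv", stimulus.syllable_table)
    write_phrase_table(directory / "phrases.csv", stimulus.phrase_table)
    with h5py.File(directory / "stim.h5", "w") as fh:
        grp = fh.create_group("stim")
        grp.attrs["fs"] = stimulus.fs
        grp.attrs["intervals"] = "half-open, 0-based, frame units at fs"
        grp.create_dataset("f0", data=stimulus.f0)
        grp.create_dataset("voicing", data=stimulus.voicing.astype(np.uint8))
        grp.create_dataset("intensity", data=stimulus.intensity)


def read_stimulus(directory) -> SyntheticStimulus:
    directory = Path(directory)
    syl = read_syllable_table(directory / "syllables.csv")
    phr = read_phrase_table(directory / "phrases.csv")
    with h5py.File(directory / "stim.h5", "r") as fh:
        grp = fh["stim"]
        fs = float(_require_attr(grp, "fs", directory / "stim.h5"))
        f0 = grp["f0"][()]
        voicing = grp["voicing"][()].astype(bool)
        intensity = grp["intensity"][()]
    return SyntheticStimulus(
        f0=f0, voicing=voicing, intensity=intensity,
        syllable_table=syl, phrase_table=phr, fs=fs,
    )


def write_features(path, features: StimulusFeatures) -> None:
    """Features -> HDF5 /features/* plus a JSON sidecar with bin edges."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("features")
        grp.attrs["fs"] = features.fs
        grp.create_dataset("spectrum", data=features.spectrum)
        grp.create_dataset("intensity", data=features.intensity)
        p = grp.create_group("pitch")
        for name in ("logf0", "rel_pitch_z", "pitch_change_val",
                     "abs_pitch_bins", "rel_pitch_bins", "pitch_change_bins"):
            p.create_dataset(name, data=getattr(features.pitch, name))
        if features.tone_onehot is not None:
            grp.create_dataset("tone_onehot", data=features.tone_onehot)
    sidecar = {
        "bin_edges": {k: v.tolist() for k, v in features.pitch.bin_edges.items()},
        "intervals": "half-open, 0-based, frame units at 100 Hz",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_features(path, syllable_table, phrase_table) -> StimulusFeatures:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    edges = {k: np.asarray(v) for k, v in sidecar["bin_edges"].items()}
    with h5py.File(path, "r") as fh:
        grp = fh["features"]
        fs = float(_require_attr(grp, "fs", path))
        p = grp["pitch"]
        pitch = PitchFeatureSet(
            logf0=p["logf0"][()],
            rel_pitch_z=p["rel_pitch_z"][()],
            pitch_change_val=p["pitch_change_val"][()],
            abs_pitch_bins=p["abs_pitch_bins"][()],
            rel_pitch_bins=p["rel_pitch_bins"][()],
            pitch_change_bins=p["pitch_change_bins"][()],
            bin_edges=edges,
        )
        tone = grp["tone_onehot"][()] if "tone_onehot" in grp else None
        return StimulusFeatures(
            spectrum=grp["spectrum"][()],
            intensity=grp["intensity"][()],
            pitch=pitch,
            tone_onehot=tone,
            syllable_table=syllable_table,
            phrase_table=phrase_table,
            fs=fs,
        )


def write_recording(path, recording: NeuralRecording, meta_csv=None) -> None:
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("neural")
        grp.create_dataset("high_gamma", data=recording.high_gamma)
        grp.create_dataset("fs", data=recording.fs)
        grp.create_dataset("blocks", data=np.asarray(recording.block_spans))
        if recording.bad_frames is not None:
            grp.create_dataset("bad_frames", data=recording.bad_frames.astype(np.uint8))
    if meta_csv is not None and recording.electrode_meta is not None:
        recording.electrode_meta.to_csv(meta_csv, index=False)


def read_recording(path, meta_csv=None) -> NeuralRecording:
    with h5py.File(path, "r") as fh:
        grp = fh["neural"]
        if "fs" not in grp:
            raise SchemaError(f"{path}: missing dataset 'fs' under /neural")
        hg = grp["high_gamma"][()]
        fs = float(grp["fs"][()])
        blocks = [tuple(int(x) for x in row) for row in grp["blocks"][()]]
        bad = grp["bad_frames"][()].astype(bool) if "bad_frames" in grp else None
    meta = pd.read_csv(meta_csv) if meta_csv is not None else None
    return NeuralRecording(
        high_gamma=hg, block_spans=blocks, fs=fs, electrode_meta=meta, bad_frames=bad
    )


def write_truth(path, truth: SyntheticGroundTruth) -> None:
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("truth")
        grp.attrs["max_lag"] = truth.max_lag
        for i, e in enumerate(truth.electrodes):
            g = grp.create_group(f"electrode{i:04d}")
            g.attrs["noise_sd"] = e.noise_sd
            g.attrs["categorical_gain"] = e.categorical_gain
            g.attrs["onset_gain"] = e.onset_gain
            g.create_dataset("tone_pattern", data=e.tone_pattern)
            for s, w in e.weights.items():
                g.create_dataset(f"weights/{s}", data=w)


def read_truth(path) -> SyntheticGroundTruth:
    with h5py.File(path, "r") as fh:
        grp = fh["truth"]
        max_lag = int(_require_attr(grp, "max_lag", path))
        electrodes = []
        for key in sorted(grp):
            g = grp[key]
            weights = {}
            if "weights" in g:
                for s in g["weights"]:
                    weights[s] = g["weights"][s][()]
            electrodes.append(
                ElectrodeTruth(
                    weights=weights,
                    noise_sd=float(g.attrs["noise_sd"]),
                    categorical_gain=float(g.attrs["categorical_gain"]),
                    onset_gain=float(g.attrs["onset_gain"]),
                    tone_pattern=g["tone_pattern"][()],
                )
            )
    return SyntheticGroundTruth(electrodes=electrodes, max_lag=max_lag)
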