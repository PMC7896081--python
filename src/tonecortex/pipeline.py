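"""End-to-end driver: synthetic study from stimulus generation to decoding.

One global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence`` so each stage is reproducible in isolation and
under partial reruns.  Every run directory gets a JSON report of headline
metrics stamped with a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import decoding, electrodes, features as feat, io, synth, trf
from .errors import PipelineError
from .preproc import epoch

logger = logging.getLogger(__name__)

STAGES = ("synth", "features", "neural", "electrodes", "trf", "decode")


@dataclass
class RunConfig:
    """Configuration of the full synthetic study."""

    seed: int = 0
    out_dir: str = "run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # stimulus
    n_sentences: int = 120
    # neural population: electrodes per generative class
    n_pitch_electrodes: int = 8
    n_categorical_electrodes: int = 8
    n_onset_electrodes: int = 4
    n_null_electrodes: int = 4
    noise_sd: float = 1.0
    categorical_gain: float = 1.5
    onset_gain: float = 2.0
    max_lag: int = 15
    # trf / unique variance
    full_sets: list[str] = field(default_factory=lambda: ["intensity", "rel_pitch", "pitch_change"])
    probe_sets: list = field(default_factory=lambda: ["rel_pitch", "pitch_change"])
    n_perm: int = 100
    n_reps: int = 3
    # decoding
    epoch_window_s: tuple[float, float] = (0.1, 0.35)
    outer_folds: int = 3
    inner_folds: int = 5
    n_lambdas: int = 4
    rsa_n_perm: int = 50

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages; returns the report dict (also written to disk).

    Stages must run in order; a later stage without its upstream artifact
    raises ``PipelineError`` naming the stage to run first.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    t0 = time.time()
    state: dict = {}

    def enabled(stage):
        return stage in config.stages

    def need(key, stage):
        if key not in state:
            raise PipelineError(f"missing upstream artifact {key!r}: run stage {stage!r} first")
        return state[key]

    if enabled("synth"):
        stim = synth.make_stimulus(config.n_sentences, seed=child_seed(config.seed, "synth"))
        io.write_stimulus(out / "stimulus", stim)
        state["stimulus"] = stim
        report["stages"]["synth"] = {
            "n_syllables": len(stim.syllable_table),
            "n_phrases": len(stim.phrase_table),
            "duration_s": stim.n_frames / stim.fs,
        }

    if enabled("features"):
        stim = need("stimulus", "synth")
        fs_all = feat.build_stimulus_features(stim, seed=child_seed(config.seed, "features"))
        io.write_features(out / "features.h5", fs_all)
        state["features"] = fs_all
        report["stages"]["features"] = {"n_frames": fs_all.n_frames}

    if enabled("neural"):
        stim = need("stimulus", "synth")
        fs_all = need("features", "features")
        dims = fs_all.set_dims(config.full_sets)
        assignments = (
            [["rel_pitch", "pitch_change"]] * config.n_pitch_electrodes
            + [[]] * (config.n_categorical_electrodes + config.n_onset_electrodes + config.n_null_electrodes)
        )
        truth = synth.random_truth(
            dims, assignments, config.max_lag,
            seed=child_seed(config.seed, "truth"), noise_sd=config.noise_sd,
        )
        k = config.n_pitch_electrodes
        rng = np.random.default_rng(child_seed(config.seed, "gains"))
        for e in truth.electrodes[k : k + config.n_categorical_electrodes]:
            e.categorical_gain = config.categorical_gain
            e.tone_pattern = rng.standard_normal(4)
        for e in truth.electrodes[
            k + config.n_categorical_electrodes :
            k + config.n_categorical_electrodes + config.n_onset_electrodes
        ]:
            e.onset_gain = config.onset_gain
        io.write_truth(out / "truth.h5", truth)
        rec = synth.make_neural(
            stim, fs_all, truth, seed=child_seed(config.seed, "neural"),
            noise_relative=False,
        )
        io.write_recording(out / "neural.h5", rec, out / "electrodes.csv")
        state["truth"], state["recording"] = truth, rec
        report["stages"]["neural"] = {"n_electrodes": rec.n_electrodes}

    if enabled("electrodes"):
        stim = need("stimulus", "synth")
        rec = need("recording", "neural")
        fs100 = rec.fs
        onsets = np.round(stim.phrase_table["start_s"].to_numpy() * fs100).astype(int)
        offsets = np.round(stim.phrase_table["end_s"].to_numpy() * fs100).astype(int)
        flags = electrodes.detect_speech_responsive(rec, onsets, offsets)
        vowel = np.round(stim.syllable_table["vowel_onset_s"].to_numpy() * fs100).astype(int)
        win = (int(0.2 * fs100), int(1.0 * fs100))
        trials, kept = epoch(rec, vowel, win)
        tones = stim.syllable_table["tone"].to_numpy()[kept]
        tone_flags = electrodes.detect_tone_discriminant(
            trials, tones, speech_responsive=flags["speech_responsive"].to_numpy()
        )
        flags = flags.merge(tone_flags, on="electrode_id")
        flags.to_csv(out / "electrode_flags.csv", index=False)
        state["flags"] = flags
        state["vowel_epochs"] = (trials, tones, kept)
        report["stages"]["electrodes"] = electrodes.summarize_population(flags)

    if enabled("trf"):
        fs_all = need("features", "features")
        rec = need("recording", "neural")
        decomps = trf.unique_variance(
            rec.high_gamma, fs_all, config.full_sets, [config.probe_sets],
            max_lag=config.max_lag, n_reps=config.n_reps, n_perm=config.n_perm,
            seed=child_seed(config.seed, "trf"),
        )
        probe = "+".join(config.probe_sets)
        state["decomps"] = {i: d for i, d in enumerate(decomps)}
        summary = electrodes.summarize_population(
            need("flags", "electrodes"), state["decomps"]
        ) if "flags" in state else {}
        report["stages"]["trf"] = {
            "probe": probe,
            "mean_full_r2": float(np.mean([d.full_r2 for d in decomps])),
            "n_significant": int(sum(d.significant[probe] for d in decomps)),
            **{k: v for k, v in summary.items() if "significant" in k},
        }

    if enabled("decode"):
        stim = need("stimulus", "synth")
        rec = need("recording", "neural")
        trials, tones, kept = need("vowel_epochs", "electrodes")
        pre = int(-config.epoch_window_s[0] * rec.fs) if config.epoch_window_s[0] < 0 else 0
        cfg = decoding.DecodeConfig(
            outer_folds=config.outer_folds, inner_folds=config.inner_folds,
            n_lambdas=config.n_lambdas, seed=child_seed(config.seed, "decode"),
        )
        resp = state["flags"]["speech_responsive"].to_numpy() if "flags" in state else None
        sub = np.flatnonzero(resp) if resp is not None and resp.any() else None
        cfg.electrode_subset = sub
        result = decoding.sliding_decode(trials[:, :, : int(0.45 * rec.fs)], tones, cfg)
        # RSA partition on mean relative pitch height per token
        syl_spans = feat.syllable_spans(stim.syllable_table, stim.phrase_table, rec.fs)
        rel = need("features", "features").pitch.rel_pitch_z
        vals = np.array([np.nanmean(rel[a:b]) for a, b in syl_spans])[kept]
        groups = decoding.rsa_partition(tones, vals)
        s = result.window_starts[result.peak_window]
        Xpk, fgroups = decoding._window_features(
            trials[:, sub if sub is not None else slice(None)], s, cfg.window_len
        )
        rsa_cfg = decoding.DecodeConfig(
            outer_folds=2, inner_folds=2, lambda_grid=np.array([1e-3]),
            seed=child_seed(config.seed, "rsa"),
        )
        rsa = decoding.rsa_rdm_and_ci(
            Xpk, groups, rsa_cfg, feature_groups=fgroups,
            n_perm=config.rsa_n_perm, seed=child_seed(config.seed, "rsa_perm"),
        )
        report["stages"]["decode"] = {
            "peak_acc": result.peak_acc,
            "peak_window_start": int(s),
            "ci": rsa.ci,
            "ci_p": rsa.p,
        }
        state["decode"] = (result, rsa)
    else:
        report["stages"]["decode"] = {"skipped": True}

    for stage in STAGES:
        if stage not in config.stages and stage not in report["stages"]:
            report["stages"][stage] = {"skipped": True}
    report["runtime_s"] = round(time.time() - t0, 2)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
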