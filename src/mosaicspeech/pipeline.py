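"""End-to-end orchestration: stimuli -> MPS confound check -> simulated
responses -> statistics -> report, from one configuration.

Stages are pure functions over a :class:`RunConfig`; every output file gets
a JSON sidecar tracing it to the config and master seed.  The behavioural
simulation runs at the full study design (participant counts and sentence
inventories), while audio synthesis and the MPS stage run on a small
per-language sentence subset — simulated responses are driven by the
psychometric model, not by the rendered audio, so the audio stage is
demonstrative and its size is a pure compute choice.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .audio import write_wav
from .degrade import make_mosaic_speech, make_noise_vocoded
from .experiment import aggregate, generate_design
from .filterbank import zwicker_band_edges
from .mps import MPSParams, compute_mps, pixelwise_anova
from .stats import BetaBinomial, LogisticGLMM
from .synthetic import (
    LanguageProfile,
    PsychometricParams,
    expand_units,
    generate_pseudo_speech,
    generate_sentence_inventory,
    japanese_profile,
    mandarin_profile,
    simulate_listener,
)

__all__ = [
    "RunConfig",
    "ValidationError",
    "run_stimulus_stage",
    "run_response_stage",
    "run_analysis_stage",
    "run_all",
]

logger = logging.getLogger("mosaicspeech")

RESPONSE_COLUMNS = {
    "participant", "language", "sentence", "block", "is_practice",
    "segment_duration_ms", "norm_segment_duration_ms",
    "n_units", "n_correct", "n_tone_only_errors",
}


class ValidationError(ValueError):
    """Input table does not match the expected schema."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full synthetic run.

    Defaults mirror the study design: conditions 0 (noise-vocoded control),
    40, 80, 160, 320 ms; 16 non-tonal and 15 tonal participants; 6 blocks
    of 5 trials with block 1 as practice.
    """

    conditions: tuple[float, ...] = (0.0, 40.0, 80.0, 160.0, 320.0)
    n_participants: dict = field(
        default_factory=lambda: {"japanese": 16, "mandarin": 15}
    )
    n_blocks: int = 6
    n_audio_sentences: int = 2  # audio/MPS subset per language
    audio_units: int = 8  # units per rendered pseudo-sentence
    f_min: float = 50.0
    f_max: float = 6400.0
    sample_rate: float = 44100.0
    seed: int = 0
    output_dir: str = "mosaicspeech_run"
    psychometric: PsychometricParams = field(default_factory=PsychometricParams)
    run_mps: bool = True

    def profiles(self) -> dict[str, LanguageProfile]:
        return {"japanese": japanese_profile(), "mandarin": mandarin_profile()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "conditions" in raw:
            raw["conditions"] = tuple(float(c) for c in raw["conditions"])
        if "psychometric" in raw:
            raw["psychometric"] = PsychometricParams(**raw["psychometric"])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d


def _seed_for(config: RunConfig, stage: str, index: int = 0) -> np.random.SeedSequence:
    digest = hashlib.sha256(f"{stage}:{index}".encode()).digest()
    salt = int.from_bytes(digest[:4], "big")
    return np.random.SeedSequence([config.seed, salt])


def _sidecar(path: Path, config: RunConfig, stage: str, extra: dict | None = None) -> None:
    payload = {
        "package": "mosaicspeech",
        "version": __version__,
        "stage": stage,
        "master_seed": config.seed,
        "config": config.to_dict(),
    }
    payload.update(extra or {})
    path.write_text(json.dumps(payload, indent=2, default=str))


def run_stimulus_stage(config: RunConfig) -> pd.DataFrame:
    """Render pseudo-speech and its degraded variants to WAV files.

    One stimulus per (language, sentence, condition); 0 ms means noise
    vocoding, any positive duration means mosaicking.  Returns the manifest
    (also written as ``stimuli/manifest.csv``) with a content checksum per
    file.
    """
    t0 = time.monotonic()
    outdir = Path(config.output_dir) / "stimuli"
    if not outdir.exists():
        logger.info("creating output directory %s", outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bands = zwicker_band_edges(config.f_min, config.f_max)
    rows = []
    for lang, profile in config.profiles().items():
        for sid in range(config.n_audio_sentences):
            sig, annot = generate_pseudo_speech(
                profile, config.audio_units, _seed_for(config, f"audio:{lang}", sid),
                config.sample_rate,
            )
            annot_path = outdir / f"{lang}_s{sid}_units.csv"
            annot.to_csv(annot_path, index=False)
            for cond in config.conditions:
                seed = int(
                    _seed_for(config, f"degrade:{lang}:{cond}", sid).generate_state(1)[0]
                    % (2**31)
                )
                if cond == 0:
                    stim = make_noise_vocoded(sig, bands, seed)
                else:
                    stim = make_mosaic_speech(sig, bands, cond, seed)
                name = f"{lang}_s{sid}_{stim.kind}_{int(cond)}ms"
                wav_path = outdir / f"{name}.wav"
                write_wav(wav_path, stim.audio)
                stim.write_sidecar(outdir / f"{name}.json")
                rows.append(
                    {
                        "language": lang,
                        "sentence": sid,
                        "kind": stim.kind,
                        "segment_duration_ms": cond,
                        "path": str(wav_path),
                        "annotation": str(annot_path),
                        "sha256": hashlib.sha256(
                            stim.audio.samples.tobytes()
                        ).hexdigest(),
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    _sidecar(outdir / "stage.json", config, "stimulus", {"n_stimuli": len(manifest)})
    logger.info("stimulus stage: %d files in %.1fs", len(manifest), time.monotonic() - t0)
    return manifest


def run_response_stage(config: RunConfig) -> pd.DataFrame:
    """Generate designs and simulated listener responses for both languages."""
    t0 = time.monotonic()
    outdir = Path(config.output_dir) / "responses"
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for lang, profile in config.profiles().items():
        sentences, _units = generate_sentence_inventory(
            profile, _seed_for(config, f"inventory:{lang}")
        )
        design = generate_design(
            profile.n_sentences,
            list(config.conditions),
            config.n_blocks,
            _seed_for(config, f"design:{lang}"),
            n_participants=config.n_participants.get(lang, 1),
        )
        resp = simulate_listener(
            design, sentences, config.psychometric, _seed_for(config, f"listener:{lang}")
        )
        frames.append(resp)
    responses = pd.concat(frames, ignore_index=True)
    responses.to_csv(outdir / "responses.csv", index=False)
    _sidecar(outdir / "stage.json", config, "response", {"n_trials": len(responses)})
    logger.info("response stage: %d trials in %.1fs", len(responses), time.monotonic() - t0)
    return responses


def run_analysis_stage(
    config: RunConfig,
    manifest: pd.DataFrame | None,
    responses: pd.DataFrame,
) -> dict:
    """Score-free analysis: intelligibility table, model fits, MPS p-maps.

    Practice blocks and (for the model fits, matching the study's analysis)
    the 0-ms control condition are excluded.  Returns a report dict, also
    written under ``<output_dir>/report``.
    """
    t0 = time.monotonic()
    if responses is None or len(responses) == 0:
        raise ValidationError("responses table is empty")
    missing = RESPONSE_COLUMNS - set(responses.columns)
    if missing:
        raise ValidationError(f"responses missing columns: {sorted(missing)}")
    outdir = Path(config.output_dir) / "report"
    outdir.mkdir(parents=True, exist_ok=True)

    scored = responses[~responses["is_practice"]].reset_index(drop=True)
    curve = aggregate(scored)
    curve.to_csv(outdir / "intelligibility_by_condition.csv", index=False)

    fits = {}
    main = scored[scored["segment_duration_ms"] > 0].reset_index(drop=True)
    units = expand_units(main)
    terms = [
        "language", "norm_segment_duration_ms", "language:norm_segment_duration_ms",
    ]
    glmm = LogisticGLMM.from_dataframe(units, "correct", terms, "participant").fit()
    fits["logistic_glmm"] = glmm.to_dict()
    bb = BetaBinomial.from_dataframe(main, "n_correct", "n_units", terms).fit()
    fits["beta_binomial"] = bb.to_dict()
    (outdir / "fits.json").write_text(json.dumps(fits, indent=2))

    mps_summary = None
    if config.run_mps and manifest is not None and len(manifest):
        mps_rows, maps = [], []
        mosaic = manifest[manifest["kind"] == "mosaic"]
        for rec in mosaic.itertuples(index=False):
            from .audio import read_wav

            m = compute_mps(read_wav(rec.path))
            maps.append(m.power)
            mps_rows.append(
                (rec.segment_duration_ms, rec.language, rec.sentence)
            )
        if mps_rows:
            sds, langs, sents = map(np.asarray, zip(*mps_rows))
            # align map shapes (stimuli can differ by a frame)
            min_shape = tuple(np.min([m.shape for m in maps], axis=0))
            stack = np.stack([m[: min_shape[0], : min_shape[1]] for m in maps])
            pmaps = pixelwise_anova(stack, sds, langs, sents, hot_language="mandarin")
            np.savez(
                outdir / "mps_pvalue_maps.npz",
                p_sd=pmaps.p_sd, p_lg=pmaps.p_lg, p_interaction=pmaps.p_interaction,
                sign_sd=pmaps.sign_sd, sign_lg=pmaps.sign_lg,
                sign_interaction=pmaps.sign_interaction,
            )
            _plot_pmaps(pmaps, outdir / "mps_pvalue_maps.png")
            mps_summary = {
                "n_maps": int(stack.shape[0]),
                "frac_p_sd_lt_05": float((pmaps.p_sd < 0.05).mean()),
                "frac_p_lg_lt_05": float((pmaps.p_lg < 0.05).mean()),
                "frac_p_interaction_lt_05": float((pmaps.p_interaction < 0.05).mean()),
            }

    report = {
        "intelligibility": curve.to_dict(orient="records"),
        "fits": fits,
        "mps": mps_summary,
        "elapsed_s": time.monotonic() - t0,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    _sidecar(outdir / "stage.json", config, "analysis")
    logger.info("analysis stage finished in %.1fs", report["elapsed_s"])
    return report


def _plot_pmaps(pmaps, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    panels = [
        ("segment duration", pmaps.p_sd, pmaps.sign_sd),
        ("language", pmaps.p_lg, pmaps.sign_lg),
        ("interaction", pmaps.p_interaction, pmaps.sign_interaction),
    ]
    for ax, (title, p, sign) in zip(axes, panels):
        signed = sign * -np.log10(np.maximum(p, 1e-12))
        vmax = max(np.abs(signed).max(), 1.0)
        im = ax.imshow(signed, aspect="auto", origin="lower", cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax)
        ax.set_title(f"{title}: signed -log10 p")
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_all(config: RunConfig) -> dict:
    """Stimuli, responses, analysis — the full synthetic study."""
    manifest = run_stimulus_stage(config)
    responses = run_response_stage(config)
    return run_analysis_stage(config, manifest, responses)
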