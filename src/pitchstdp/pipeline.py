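"""End-to-end orchestration: synth -> periphery -> train -> analyze -> rank.

Every stage writes plain-text artifacts (CSV tables, JSON sidecars, WAVs
for stimuli) plus a provenance record, so a run is reproducible from its
output directory alone.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, plasticity, ranking, stimuli
from .config import RunConfig
from .periphery import build_cochlear_map, place_code, spatiotemporal_map
from .plasticity import TrainedModel, TrainingResult, single_type_schedule, mixed_type_schedule, train

log = logging.getLogger("pitchstdp")

STAGES = ("synth", "periphery", "train", "analyze", "rank")


def _write_provenance(outdir: Path, config: RunConfig, stage: str) -> None:
    rec = config.provenance()
    rec["stage"] = stage
    (outdir / f"{stage}.provenance.json").write_text(json.dumps(rec, indent=2))


def stage_synth(config: RunConfig, outdir: Path) -> pd.DataFrame:
    """Write the full built-in stimulus set as WAVs plus a manifest table."""
    stim_dir = outdir / "stimuli"
    stim_dir.mkdir(parents=True, exist_ok=True)
    ladder = stimuli.semitone_ladder(config.ladder_low_hz, config.ladder_high_hz)
    rows = []
    sets = {
        "tone": [(f, stimuli.synth_pure_tone(f)) for f in ladder],
        "vowel_a": [(f, stimuli.vowel_a(f)) for f in ladder],
        "vowel_i": [(f, stimuli.vowel_i(f)) for f in ladder],
        "vowel_a_tel": [(f, stimuli.telephone_filter(stimuli.vowel_a(f))) for f in ladder],
        "vowel_i_tel": [(f, stimuli.telephone_filter(stimuli.vowel_i(f))) for f in ladder],
    }
    for stype, items in sets.items():
        for f, w in items:
            path = stim_dir / f"{stype}_{f:.2f}Hz.wav"
            stimuli.write_wav(w, path)
            rows.append({"label": w.label, "type": stype, "pitch_hz": f, "path": str(path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "stimulus_manifest.csv", index=False)
    _write_provenance(outdir, config, "synth")
    return manifest


def stage_periphery(config: RunConfig, outdir: Path) -> pd.DataFrame:
    """Place codes for every stimulus in the manifest."""
    manifest_path = outdir / "stimulus_manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError("missing stimulus manifest; run the 'synth' stage first")
    manifest = pd.read_csv(manifest_path)
    cmap = build_cochlear_map(config.n_channels)
    codes = {}
    for _, row in manifest.iterrows():
        w = stimuli.read_wav(row["path"])
        codes[row["label"]] = place_code(spatiotemporal_map(w, cmap)).rates
    df = pd.DataFrame(codes, index=cmap.cfs_hz)
    df.index.name = "cf_hz"
    df.to_csv(outdir / "place_codes.csv")
    _write_provenance(outdir, config, "periphery")
    return df


def _build_schedule(config: RunConfig, categories) -> plasticity.TrainingSchedule:
    n_pres = config.presentations()
    if config.training_mode == "mixed-type":
        return mixed_type_schedule(categories, n_pres, seed=config.seed)
    return single_type_schedule(config.training_type, categories, n_pres, seed=config.seed)


def stage_train(config: RunConfig, outdir: Path) -> TrainingResult:
    ladder = stimuli.semitone_ladder(config.ladder_low_hz, config.ladder_high_hz)
    schedule = _build_schedule(config, list(ladder))
    t0 = time.time()
    result = train(
        schedule,
        config.stdp,
        config.lif,
        cmap=build_cochlear_map(config.n_channels),
        peak_rate=config.peak_rate,
        eta_scale=config.eta_scale,
    )
    log.info("training finished in %.1f s", time.time() - t0)
    w = result.model.weights
    pd.DataFrame(w.w, index=w.row_labels, columns=np.round(w.col_labels, 2)).to_csv(
        outdir / "weights.csv"
    )
    result.trace.to_csv(outdir / "learning_trace.csv", index=False)
    _write_provenance(outdir, config, "train")
    return result


def _heatmap(matrix, path, xlabel, ylabel):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.imshow(matrix, aspect="auto", origin="lower", cmap="Greys")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def stage_analyze(config: RunConfig, outdir: Path, result: TrainingResult) -> dict:
    ladder = stimuli.semitone_ladder(config.ladder_low_hz, config.ladder_high_hz)
    tones = [stimuli.synth_pure_tone(f) for f in ladder]
    vsm = analysis.vs_matrix(
        result.model, tones, list(ladder), interval_s=config.vs_interval_s, seed=config.seed + 1
    )
    pd.DataFrame(vsm.values, index=vsm.neuron_labels, columns=vsm.stimulus_freqs).to_csv(
        outdir / "vs_matrix.csv"
    )
    stacked = analysis.stacked_isih(
        result.model, tones, list(ladder), n_reps=config.isih_reps, seed=config.seed + 2
    )
    pd.DataFrame(
        stacked.matrix(), index=stacked.pitches_hz, columns=stacked.rows[0].bin_centers_ms
    ).to_csv(outdir / "stacked_isih.csv")
    _heatmap(vsm.values, outdir / "vs_matrix.png", "stimulus pitch index", "pitch neuron")
    _heatmap(stacked.matrix(), outdir / "stacked_isih.png", "interval (ms)", "pitch category")
    _write_provenance(outdir, config, "analyze")
    return {"vs_matrix": vsm, "stacked_isih": stacked}


def isih_pool(
    model: TrainedModel,
    categories,
    filtered: bool = False,
    n_reps: int = 10,
    seed: int = 0,
) -> dict:
    """Smoothed pooled ISIHs for both vowels at every pitch, keyed (type, idx)."""
    pool = {}
    seqs = np.random.SeedSequence(seed).spawn(2 * len(categories))
    for vi, (vtype, maker) in enumerate((("a", stimuli.vowel_a), ("i", stimuli.vowel_i))):
        for k, f in enumerate(categories):
            w = maker(float(f))
            if filtered:
                w = stimuli.telephone_filter(w)
            h = analysis.model_isih(
                model, w, n_reps=n_reps, seed=seqs[vi * len(categories) + k], pitch_label=float(f)
            )
            pool[(vtype, k)] = h.smoothed
    return pool


def stage_rank(config: RunConfig, outdir: Path, result: TrainingResult) -> dict:
    ladder = stimuli.semitone_ladder(config.ladder_low_hz, config.ladder_high_hz)
    out = {}
    for name, filtered in (("original", False), ("filtered", True)):
        pool = isih_pool(
            result.model,
            list(ladder),
            filtered=filtered,
            n_reps=config.isih_reps,
            seed=config.seed + 3,
        )
        df = ranking.run_experiment(config.ranking, pool)
        df.to_csv(outdir / f"ranking_{name}.csv", index=False)
        out[name] = df
    _write_provenance(outdir, config, "rank")
    return out


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Execute the requested stages in order, returning in-memory artifacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    stages = [s for s in STAGES if s in stages]
    for stage in stages:
        t0 = time.time()
        if stage == "synth":
            artifacts["manifest"] = stage_synth(config, outdir)
        elif stage == "periphery":
            if "manifest" not in artifacts and not (outdir / "stimulus_manifest.csv").exists():
                stage_synth(config, outdir)
            artifacts["place_codes"] = stage_periphery(config, outdir)
        elif stage == "train":
            artifacts["training"] = stage_train(config, outdir)
        elif stage in ("analyze", "rank"):
            if "training" not in artifacts:
                raise RuntimeError(f"stage '{stage}' needs trained weights; run the 'train' stage first")
            if stage == "analyze":
                artifacts["analysis"] = stage_analyze(config, outdir, artifacts["training"])
            else:
                artifacts["ranking"] = stage_rank(config, outdir, artifacts["training"])
        log.info("stage %-9s done in %.1f s", stage, time.time() - t0)
    return artifacts


# --- Miniature deterministic bundle for fast checks -------------------------

def make_fixtures(seed: int = 0) -> dict:
    """Small deterministic bundle: 3 pitch categories, 20 channels, short training.

    Returns the untrained and trained models, the learning trace, and
    trained/untrained vector-strength matrices for the 3 tones.
    """
    categories = [110.0, 220.0, 440.0]
    cmap = build_cochlear_map(n_channels=20, d_min_mm=3.0, step_mm=(22.9 - 3.0) / 19)
    schedule = single_type_schedule("tone", categories, n_presentations=20, seed=seed)
    result = train(schedule, eta_scale=500.0, cmap=cmap)
    untrained = TrainedModel.untrained(categories, cmap)
    tones = [stimuli.synth_pure_tone(f) for f in categories]
    vs_trained = analysis.vs_matrix(result.model, tones, categories, interval_s=2.5, seed=seed + 1)
    vs_untrained = analysis.vs_matrix(untrained, tones, categories, interval_s=2.5, seed=seed + 1)
    return {
        "model": result.model,
        "untrained": untrained,
        "trace": result.trace,
        "vs_trained": vs_trained,
        "vs_untrained": vs_untrained,
    }
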