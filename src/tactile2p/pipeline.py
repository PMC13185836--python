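"""End-to-end orchestration: simulate -> behavior -> traces -> responses ->
population -> decoding, with per-stage logging of exclusions and a JSON
summary keyed by config hash and seed."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, decoding, population, responses, traces as tr
from .config import RunConfig, SimConfig, merged_params
from .io import write_aligned, write_json, write_traces, write_trials
from .synth import SyntheticSession, generate_cohort, hypo_mouse, wt_mouse

log = logging.getLogger("tactile2p")

GROUP_PRESETS = {"wt": wt_mouse, "hypo": hypo_mouse}


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage tag."""


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]


def analyze_session(session: SyntheticSession, params: dict | None = None,
                    seed: int = 0, decode: bool = True) -> dict:
    """Full single-session analysis; returns a flat metrics dict.

    Stages: preprocessing (neuropil correction, baseline, dF/F), z-scored
    alignment with first-lick masking, recruitment classification against the
    per-neuron null, population statistics, single-neuron d', and (optionally)
    frame-by-frame Hit/Miss decoding with its shuffled baseline.
    """
    p = merged_params(params)
    trials = session.trial_table
    rng = np.random.default_rng(seed)

    out: dict = {"mouse_id": session.ground_truth.mouse_id,
                 "group": session.ground_truth.group}
    try:
        out.update(behavior.session_metrics(trials))
    except Exception as e:
        raise StageError(f"[behavior] {e}") from e

    tp = p["traces"]
    try:
        dff_traces, neuron_ok = tr.preprocess(
            session.traces, tp["neuropil_coeff"], tp["baseline_window_s"])
        aligned = tr.zscore_align(
            dff_traces, trials, session.traces.frame_rate_hz,
            celltype=session.traces.celltype,
            pre_s=tp["pre_s"], stim_s=tp["stim_s"], post_s=tp["post_s"],
            min_valid_stim_frames=tp["min_valid_stim_frames"],
            neuron_ok=neuron_ok,
        )
    except Exception as e:
        raise StageError(f"[traces] {e}") from e
    log.info("traces: %d/%d neurons usable, %d/%d trials aligned",
             aligned.neuron_ok.sum(), session.traces.n_neurons,
             aligned.n_trials, len(trials))

    rp = p["responses"]
    try:
        # z-score the full recording with the same mu/sigma used in alignment
        # so the null lives on the same scale as the stimulus windows.
        sd_safe = np.where(aligned.sigma > 0, aligned.sigma, np.nan)
        z_full = (dff_traces - aligned.mu[:, None]) / sd_safe[:, None]
        eligible = responses.eligibility_mask(
            z_full.shape[1], aligned.trial_meta, session.traces.frame_rate_hz)
        null = responses.build_null(
            z_full, eligible, np.random.default_rng(seed + 1), n=rp["n_null"],
            upper_pct=rp["null_upper_pct"], lower_pct=rp["null_lower_pct"])
        rec = responses.classify_session(
            aligned, null, activation_pct=rp["activation_pct"],
            inhibition_pct=rp["inhibition_pct"],
            inhibition_mode=rp["inhibition_mode"],
            min_valid_stim_frames=tp["min_valid_stim_frames"])
        dp = responses.dprime(aligned)
        out["encoder_fraction"] = dp.encoder_fraction
    except Exception as e:
        raise StageError(f"[responses] {e}") from e
    log.info("responses: %d/%d trials classifiable", rec.trial_ok.sum(), rec.labels.shape[0])

    try:
        out.update(population.animal_summary(aligned, rec))
    except Exception as e:
        raise StageError(f"[population] {e}") from e

    if decode:
        dpar = p["decoding"]
        try:
            res = decoding.decode_session(
                aligned, np.random.default_rng(seed + 2),
                c_grid=tuple(dpar["c_grid"]), outer_folds=dpar["outer_folds"],
                inner_folds=dpar["inner_folds"])
            out.update(decoding.window_summary(res))
        except ValueError as e:
            log.info("decoding skipped for %s: %s", out["mouse_id"], e)
            out["decoding_skipped"] = str(e)
        except Exception as e:
            raise StageError(f"[decoding] {e}") from e
    return out


def run_pipeline(cfg: RunConfig, write_fixtures: bool = False) -> dict:
    """Simulate a cohort per config and analyze every session.

    Returns the summary bundle (also written to ``out_dir``): per-mouse tidy
    metric rows, subgroup labels from hit-rate clustering, config hash, seed.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = []
    for g in cfg.groups:
        if g not in GROUP_PRESETS:
            raise StageError(f"[simulate] unknown group preset {g!r}")
        specs.append(GROUP_PRESETS[g](mouse_id=g))
    sessions = generate_cohort(cfg.sim, specs, cfg.seed,
                               n_mice_per_group=cfg.n_mice_per_group)

    rows = []
    for i, s in enumerate(sessions):
        if write_fixtures:
            stem = out_dir / s.ground_truth.mouse_id
            write_trials(s.trial_table, f"{stem}_trials.csv")
            write_traces(s.traces, f"{stem}_traces.h5", events=s.trial_table)
        rows.append(analyze_session(s, cfg.params, seed=cfg.seed + 1000 + i,
                                    decode=cfg.decode))
    metrics = pd.DataFrame(rows)

    # Subgrouping on mice x amplitude hit-rate profiles.
    mats, mids = [], []
    for s in sessions:
        pa = behavior.per_amplitude_hits(s.trial_table)
        mats.append((pa["hits"] / pa["n"]).to_numpy())
        mids.append(s.ground_truth.mouse_id)
    if len(mats) >= 2 and len({m.shape for m in np.asarray(mats, dtype=object)}) <= 1:
        sub = behavior.cluster_subgroups(np.vstack(mats), seed=cfg.seed)
        metrics["subgroup"] = sub.names

    metrics_path = out_dir / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    summary = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "n_sessions": len(sessions),
        "metrics_csv": str(metrics_path),
        "group_means": {
            g: metrics[metrics["group"] == g].select_dtypes("number").mean().to_dict()
            for g in cfg.groups
        },
    }
    write_json(summary, out_dir / "summary.json")
    cfg.to_json(out_dir / "config.json")
    return {"metrics": metrics, "summary": summary, "sessions": sessions}
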