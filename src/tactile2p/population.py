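"""Population-level ensemble statistics.

Trinary trial-response vectors per neuron (activated +1, inhibited -1,
non-responsive 0) feed a pairwise cosine-similarity measure of ensemble
coordination; recruitment labels feed the per-trial excitation/inhibition
ratio and the population signal-to-noise ratio (recruited fraction during
stimulation relative to spontaneous recruitment during catch trials);
z-scored windows feed the single-cell SNR. Catch-trial analysis windows are
placed at the scheduled (sham) stimulus time of each No-Go trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .responses import RecruitmentResult, trial_mean_stim_z
from .traces import AlignedTensor, INTERNEURON, PYRAMIDAL


@dataclass
class CosineResult:
    mean_similarity: float
    n_pairs: int
    n_excluded_zero: int         # neurons dropped for all-zero vectors


def cosine_similarity_mean(vectors: np.ndarray, celltype: np.ndarray | None = None,
                           celltype_filter: int | None = None) -> CosineResult:
    """Mean off-diagonal pairwise cosine similarity of trinary response vectors.

    ``vectors`` is neurons x trials with entries in {-1, 0, +1}. All-zero
    vectors have no direction and are excluded (their count is reported).
    Optionally restricts to one cell type before pairing.
    """
    V = np.asarray(vectors, dtype=float)
    if celltype_filter is not None:
        if celltype is None:
            raise ValueError("celltype labels required for a cell-type filter")
        V = V[np.asarray(celltype) == celltype_filter]
    norms = np.linalg.norm(V, axis=1)
    nonzero = norms > 0
    n_excluded = int((~nonzero).sum())
    V = V[nonzero]
    if V.shape[0] < 2:
        return CosineResult(mean_similarity=np.nan, n_pairs=0, n_excluded_zero=n_excluded)
    U = V / np.linalg.norm(V, axis=1, keepdims=True)
    S = U @ U.T
    iu = np.triu_indices(S.shape[0], k=1)
    return CosineResult(
        mean_similarity=float(S[iu].mean()),
        n_pairs=len(iu[0]),
        n_excluded_zero=n_excluded,
    )


def response_vectors(res: RecruitmentResult, trial_sel: np.ndarray | None = None) -> np.ndarray:
    """Neurons x trials trinary matrix from recruitment labels."""
    labels = res.labels
    if trial_sel is not None:
        labels = labels[np.asarray(trial_sel)]
    return labels.T.astype(float)


@dataclass
class EIRatioResult:
    per_trial: np.ndarray        # NaN where undefined (no activated interneurons)
    n_undefined: int
    mean: float                  # over defined trials


def ei_ratio(res: RecruitmentResult, trial_sel: np.ndarray | None = None) -> EIRatioResult:
    """Activated pyramidal count over activated interneuron count, per trial.

    Trials with zero activated interneurons are undefined and excluded from
    the mean (their count is reported).
    """
    labels = res.labels
    sel = np.arange(labels.shape[0]) if trial_sel is None else np.flatnonzero(trial_sel)
    pyr = res.celltype == PYRAMIDAL
    inh = res.celltype == INTERNEURON
    out = np.full(len(sel), np.nan)
    for i, t in enumerate(sel):
        n_p = int((labels[t, pyr] == 1).sum())
        n_i = int((labels[t, inh] == 1).sum())
        if n_i > 0:
            out[i] = n_p / n_i
    defined = np.isfinite(out)
    return EIRatioResult(
        per_trial=out,
        n_undefined=int((~defined).sum()),
        mean=float(out[defined].mean()) if defined.any() else np.nan,
    )


@dataclass
class SNRRecord:
    single_cell: np.ndarray | None = None     # per neuron
    population_per_trial: np.ndarray | None = None
    population_mean: float = np.nan
    catch_mean_fraction: float = np.nan
    defined: bool = True


def _catch_mask(meta: pd.DataFrame) -> np.ndarray:
    return (meta["trial_type"] == "nogo").to_numpy()


def single_cell_snr(aligned: AlignedTensor, trial_sel: np.ndarray | None = None) -> SNRRecord:
    """Per neuron: mean over trials of |trial-mean stim z - mean catch z|.

    Catch activity is the mean stimulation-window z over No-Go (sham-window)
    trials. ``trial_sel`` restricts the stimulus-trial set (e.g. detected
    only); catch trials are always the No-Go rows.
    """
    meta = aligned.trial_meta
    catch = _catch_mask(meta) & ~aligned.low_valid_trials
    if catch.sum() == 0:
        raise ValueError("no catch trials available for SNR reference")
    stim = (~_catch_mask(meta)) & ~aligned.low_valid_trials
    stim &= meta["stim_offset_s"].notna().to_numpy()  # delivered stimuli only
    if trial_sel is not None:
        stim &= np.asarray(trial_sel)
    stats = trial_mean_stim_z(aligned)
    catch_mean = np.nanmean(stats[catch], axis=0)
    diffs = np.abs(stats[stim] - catch_mean[None, :])
    return SNRRecord(single_cell=np.nanmean(diffs, axis=0))


def population_snr(res: RecruitmentResult, trial_sel: np.ndarray | None = None,
                   celltype_filter: int | None = None) -> SNRRecord:
    """Per-trial recruited fraction over the mean catch-trial recruited fraction.

    Undefined (flagged) when no neuron was ever recruited on catch trials.
    """
    meta = res.trial_meta
    catch = _catch_mask(meta) & res.trial_ok
    stim = (~_catch_mask(meta)) & res.trial_ok & meta["stim_offset_s"].notna().to_numpy()
    if trial_sel is not None:
        stim &= np.asarray(trial_sel)
    sel_neurons = np.ones(res.labels.shape[1], dtype=bool)
    if celltype_filter is not None:
        sel_neurons = res.celltype == celltype_filter
    frac = (res.labels[:, sel_neurons] != 0).mean(axis=1)
    catch_mean = float(frac[catch].mean()) if catch.any() else np.nan
    if not np.isfinite(catch_mean) or catch_mean == 0:
        return SNRRecord(population_per_trial=None, population_mean=np.nan,
                         catch_mean_fraction=catch_mean, defined=False)
    per_trial = frac[stim] / catch_mean
    return SNRRecord(
        population_per_trial=per_trial,
        population_mean=float(per_trial.mean()) if per_trial.size else np.nan,
        catch_mean_fraction=catch_mean,
    )


def correlated_ensemble_ratio(res: RecruitmentResult,
                              celltype_filter: int | None = None) -> float:
    """Mean pairwise cosine during stimulation over that during catch trials."""
    meta = res.trial_meta
    catch = _catch_mask(meta) & res.trial_ok
    stim = (~_catch_mask(meta)) & res.trial_ok & meta["stim_offset_s"].notna().to_numpy()
    cs = cosine_similarity_mean(response_vectors(res, stim), res.celltype, celltype_filter)
    cc = cosine_similarity_mean(response_vectors(res, catch), res.celltype, celltype_filter)
    if not np.isfinite(cc.mean_similarity) or cc.mean_similarity == 0:
        return np.nan
    return cs.mean_similarity / cc.mean_similarity


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    defined: bool


def snr_recruitment_correlation(snr_per_animal: np.ndarray,
                                recruited_fraction_per_animal: np.ndarray) -> RegressionResult:
    """OLS of per-animal recruited fraction on per-animal single-cell SNR."""
    x = np.asarray(snr_per_animal, dtype=float)
    y = np.asarray(recruited_fraction_per_animal, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 animals for the regression")
    if np.allclose(x, x[0]):
        return RegressionResult(np.nan, np.nan, np.nan, np.nan, defined=False)
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r=float(res.rvalue), p=float(res.pvalue), defined=True)


def animal_summary(aligned: AlignedTensor, res: RecruitmentResult) -> dict:
    """Per-animal condition aggregates ready for group-level statistics."""
    meta = res.trial_meta
    detected = (meta["outcome"] == "Hit").to_numpy()
    nondetected = (meta["outcome"] == "Miss").to_numpy()
    stim = (~_catch_mask(meta)) & meta["stim_offset_s"].notna().to_numpy()
    out: dict = {}
    for ct, name in ((PYRAMIDAL, "pyr"), (INTERNEURON, "inh")):
        cs = cosine_similarity_mean(response_vectors(res, stim & res.trial_ok),
                                    res.celltype, ct)
        out[f"cosine_{name}"] = cs.mean_similarity
        psnr = population_snr(res, celltype_filter=ct)
        out[f"population_snr_{name}"] = psnr.population_mean
        psnr_det = population_snr(res, trial_sel=detected, celltype_filter=ct)
        out[f"population_snr_detected_{name}"] = psnr_det.population_mean
        sel = res.celltype == ct
        frac = (res.labels[:, sel] != 0).mean(axis=1) if sel.any() else np.full(len(meta), np.nan)
        usable = res.trial_ok & stim
        out[f"recruited_fraction_{name}"] = float(frac[usable].mean()) if usable.any() else np.nan
    ei = ei_ratio(res, stim & res.trial_ok)
    out["ei_ratio"] = ei.mean
    ei_det = ei_ratio(res, detected & res.trial_ok)
    ei_non = ei_ratio(res, nondetected & res.trial_ok)
    out["ei_ratio_detected"] = ei_det.mean
    out["ei_ratio_nondetected"] = ei_non.mean
    try:
        out["single_cell_snr"] = float(np.nanmean(single_cell_snr(aligned).single_cell))
        out["single_cell_snr_detected"] = float(
            np.nanmean(single_cell_snr(aligned, detected).single_cell))
    except ValueError:
        out["single_cell_snr"] = np.nan
        out["single_cell_snr_detected"] = np.nan
    return out
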