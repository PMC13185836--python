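"""Per-trial stimulus-evoked response classification and single-neuron metrics.

The recruitment test compares, for each neuron and trial, the 85th percentile
of the z-scored activity during the (pre-first-lick) stimulation window with
the 95th percentile of a per-neuron null distribution built from 1,999 frames
sampled outside stimulus and reward periods; exceeding it labels the
neuron-trial activated (+1). Inhibition uses the mirrored rule by default
(10th stimulus percentile below the null's 5th percentile -> -1), consistent
with a two-sided p < 0.05 reading; a literal mode comparing against the upper
null percentile is available. The module also computes recruitment
proportions by condition, response peak amplitude/delay, and a per-neuron
sensitivity index d' separating detected from non-detected trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import AlignedTensor, INTERNEURON, PYRAMIDAL


@dataclass
class NullDistribution:
    """Per-neuron null sample of z values at randomly chosen eligible frames."""

    samples: np.ndarray          # neurons x n_samples
    upper: np.ndarray            # per-neuron upper percentile (default 95th)
    lower: np.ndarray            # per-neuron lower percentile (default 5th)
    n_samples: int
    with_replacement: bool
    upper_pct: float = 95.0
    lower_pct: float = 5.0


def eligibility_mask(n_frames: int, trials: pd.DataFrame, frame_rate_hz: float,
                     response_window_s: float = 2.0) -> np.ndarray:
    """Frames usable for the null: outside stimulus and reward periods.

    Excluded per trial: stimulus onset to offset for delivered stimuli, plus
    the response window after the stimulus on rewarded (Hit) trials.
    """
    ok = np.ones(n_frames, dtype=bool)

    def blank(t0: float, t1: float) -> None:
        a = max(int(np.floor(t0 * frame_rate_hz)), 0)
        b = min(int(np.ceil(t1 * frame_rate_hz)), n_frames)
        ok[a:b] = False

    for _, tr in trials.iterrows():
        onset = tr["stim_onset_s"]
        offset = tr.get("stim_offset_s", np.nan)
        if pd.notna(offset):
            blank(float(onset), float(offset))
            if tr.get("outcome", "") == "Hit":
                blank(float(offset), float(offset) + response_window_s)
    return ok


def build_null(z_trace: np.ndarray, eligible: np.ndarray, rng: np.random.Generator,
               n: int = 1999, upper_pct: float = 95.0,
               lower_pct: float = 5.0) -> NullDistribution:
    """Sample ``n`` eligible frames per neuron and store the null percentiles.

    One frame sample is shared across neurons (the time points are a property
    of the recording, not of a cell). Sampling is without replacement; if
    fewer than ``n`` frames are eligible, sampling falls back to replacement
    and the result is flagged.
    """
    z_trace = np.atleast_2d(np.asarray(z_trace, dtype=float))
    idx_pool = np.flatnonzero(eligible)
    if idx_pool.size == 0:
        raise ValueError("no eligible frames for the null distribution")
    replace = idx_pool.size < n
    chosen = rng.choice(idx_pool, size=n, replace=replace)
    samples = z_trace[:, chosen]
    return NullDistribution(
        samples=samples,
        upper=np.nanpercentile(samples, upper_pct, axis=1),
        lower=np.nanpercentile(samples, lower_pct, axis=1),
        n_samples=n,
        with_replacement=bool(replace),
        upper_pct=upper_pct,
        lower_pct=lower_pct,
    )


def classify_trial(z_window_valid: np.ndarray, null_upper: float, null_lower: float,
                   activation_pct: float = 85.0, inhibition_pct: float = 10.0,
                   inhibition_mode: str = "symmetric") -> int:
    """Label one neuron-trial as activated (+1), inhibited (-1) or neither (0).

    Activated when the ``activation_pct`` percentile of the valid stimulation
    z-scores exceeds the null's upper percentile; inhibited when the
    ``inhibition_pct`` percentile falls below the null's lower percentile
    (``symmetric`` mode) or below the null's *upper* percentile (``literal``
    mode). If both rules fire, the larger percentile exceedance wins; exact
    ties yield 0.
    """
    v = np.asarray(z_window_valid, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need >= 2 valid stimulation frames to classify")
    act_stat = float(np.percentile(v, activation_pct))
    inh_stat = float(np.percentile(v, inhibition_pct))
    inh_ref = null_lower if inhibition_mode == "symmetric" else null_upper
    act = act_stat > null_upper
    inh = inh_stat < inh_ref
    if act and inh:
        exc_act = act_stat - null_upper
        exc_inh = inh_ref - inh_stat
        if exc_act > exc_inh:
            return 1
        if exc_inh > exc_act:
            return -1
        return 0
    if act:
        return 1
    if inh:
        return -1
    return 0


@dataclass
class RecruitmentResult:
    """Trial x neuron recruitment labels plus bookkeeping."""

    labels: np.ndarray           # trials x neurons in {-1, 0, +1}
    trial_ok: np.ndarray         # trials with enough valid stimulation frames
    null: NullDistribution
    trial_meta: pd.DataFrame
    celltype: np.ndarray

    def recruited_fraction(self, trial: int, celltype: int | None = None) -> float:
        """Fraction of (optionally type-restricted) neurons recruited on a trial."""
        sel = np.ones(self.labels.shape[1], dtype=bool)
        if celltype is not None:
            sel &= self.celltype == celltype
        if sel.sum() == 0:
            return np.nan
        return float((self.labels[trial, sel] != 0).mean())


def classify_session(aligned: AlignedTensor, null: NullDistribution,
                     activation_pct: float = 85.0, inhibition_pct: float = 10.0,
                     inhibition_mode: str = "symmetric",
                     min_valid_stim_frames: int = 2) -> RecruitmentResult:
    """Run the randomization test on every neuron-trial of an aligned session."""
    n_trials, n_neurons = aligned.n_trials, aligned.n_neurons
    labels = np.zeros((n_trials, n_neurons), dtype=int)
    trial_ok = np.ones(n_trials, dtype=bool)
    sl = aligned.window.stim_slice
    for t in range(n_trials):
        m = aligned.valid_mask[t, sl]
        if m.sum() < min_valid_stim_frames:
            trial_ok[t] = False
            continue
        for nrn in range(n_neurons):
            if not aligned.neuron_ok[nrn]:
                continue
            v = aligned.z[t, nrn, sl][m]
            labels[t, nrn] = classify_trial(
                v, float(null.upper[nrn]), float(null.lower[nrn]),
                activation_pct=activation_pct, inhibition_pct=inhibition_pct,
                inhibition_mode=inhibition_mode,
            )
    return RecruitmentResult(labels=labels, trial_ok=trial_ok, null=null,
                             trial_meta=aligned.trial_meta, celltype=aligned.celltype)


def recruitment_proportions(res: RecruitmentResult,
                            by: tuple[str, ...] = ("amplitude_um", "detected")) -> pd.DataFrame:
    """Mean per-trial recruited fraction by condition and cell type.

    For each condition cell: the per-trial fraction of same-type neurons with a
    nonzero label, averaged over the condition's usable trials. Conditions are
    built from trial metadata columns; ``detected`` is derived from the outcome
    (Hit = detected, Miss = non-detected; No-Go rows get NA).
    """
    meta = res.trial_meta.copy()
    outcomes = meta["outcome"].to_numpy()
    meta["detected"] = pd.array(
        [o == "Hit" if o in ("Hit", "Miss") else pd.NA for o in outcomes],
        dtype="boolean",
    )
    rows = []
    for ct, ct_name in ((PYRAMIDAL, "pyramidal"), (INTERNEURON, "interneuron")):
        sel = res.celltype == ct
        if sel.sum() == 0:
            continue
        frac = (res.labels[:, sel] != 0).mean(axis=1)
        df = meta.copy()
        df["recruited_fraction"] = frac
        df = df[res.trial_ok]
        grouped = df.groupby(list(by), dropna=False)["recruited_fraction"]
        agg = grouped.agg(["mean", "count"]).reset_index()
        agg["celltype"] = ct_name
        rows.append(agg)
    out = pd.concat(rows, ignore_index=True)
    return out.rename(columns={"mean": "recruited_fraction", "count": "n_trials"})


@dataclass
class PeakMetrics:
    """Peak response amplitude and delay per recruited neuron-trial."""

    table: pd.DataFrame  # columns: trial, neuron, label, peak_z, delay_frames, delay_ms


def peak_metrics(aligned: AlignedTensor, res: RecruitmentResult) -> PeakMetrics:
    """Peak z (max for activated, min for inhibited) and its delay from onset.

    Only recruited neuron-trials contribute; the peak is searched over valid
    (pre-first-lick) stimulation frames, and the delay is counted in frames
    from stimulus onset, converted to ms via the frame rate.
    """
    fr = aligned.window.frame_rate_hz
    sl = aligned.window.stim_slice
    recs = []
    for t, nrn in zip(*np.nonzero(res.labels)):
        m = aligned.valid_mask[t, sl]
        if not m.any():
            continue
        v = aligned.z[t, nrn, sl]
        idx_valid = np.flatnonzero(m)
        vals = v[idx_valid]
        if res.labels[t, nrn] > 0:
            j = int(idx_valid[np.argmax(vals)])
        else:
            j = int(idx_valid[np.argmin(vals)])
        recs.append({
            "trial": int(t), "neuron": int(nrn), "label": int(res.labels[t, nrn]),
            "peak_z": float(v[j]), "delay_frames": j,
            "delay_ms": 1000.0 * j / fr,
        })
    cols = ["trial", "neuron", "label", "peak_z", "delay_frames", "delay_ms"]
    return PeakMetrics(table=pd.DataFrame(recs, columns=cols))


@dataclass
class DPrimeResult:
    dprime: np.ndarray           # per neuron, NaN when undefined
    encoder_fraction: float      # fraction of defined neurons with d' > 1
    n_detected: int
    n_nondetected: int


def trial_mean_stim_z(aligned: AlignedTensor) -> np.ndarray:
    """Mean valid stimulation-window z per trial x neuron (NaN when no frames)."""
    sl = aligned.window.stim_slice
    z = aligned.z[:, :, sl]
    m = aligned.valid_mask[:, sl]
    out = np.full((aligned.n_trials, aligned.n_neurons), np.nan)
    for t in range(aligned.n_trials):
        if m[t].any():
            out[t] = np.nanmean(z[t][:, m[t]], axis=1)
    return out


def dprime(aligned: AlignedTensor, threshold: float = 1.0) -> DPrimeResult:
    """Single-neuron sensitivity index between detected and non-detected trials.

    d' = (mean_det - mean_non) / sqrt((var_det + var_non) / 2) on the
    per-trial mean stimulation-window z. Neurons need >= 2 trials per class
    and a positive pooled variance, else NaN. The encoder fraction is the
    share of defined neurons with d' above ``threshold``.
    """
    meta = aligned.trial_meta
    det = (meta["outcome"] == "Hit").to_numpy()
    non = (meta["outcome"] == "Miss").to_numpy()
    usable = ~aligned.low_valid_trials
    det &= usable
    non &= usable
    stats = trial_mean_stim_z(aligned)
    n_neurons = aligned.n_neurons
    d = np.full(n_neurons, np.nan)
    if det.sum() >= 2 and non.sum() >= 2:
        a, b = stats[det], stats[non]
        mu_d, mu_n = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
        v_d, v_n = np.nanvar(a, axis=0, ddof=1), np.nanvar(b, axis=0, ddof=1)
        pooled = 0.5 * (v_d + v_n)
        ok = pooled > 0
        d[ok] = (mu_d[ok] - mu_n[ok]) / np.sqrt(pooled[ok])
    d[~aligned.neuron_ok] = np.nan
    defined = np.isfinite(d)
    frac = float((d[defined] > threshold).mean()) if defined.any() else np.nan
    return DPrimeResult(dprime=d, encoder_fraction=frac,
                        n_detected=int(det.sum()), n_nondetected=int(non.sum()))
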