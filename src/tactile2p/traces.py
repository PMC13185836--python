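"""Fluorescence preprocessing: neuropil correction, baseline, dF/F, z-scored
event alignment and display smoothing.

The processing chain mirrors standard two-photon practice for somatic GCaMP
recordings: the neuropil signal scaled by 0.7 is subtracted from each ROI
trace, the baseline is the mean of the 10-s segment with the lowest standard
deviation, dF/F is computed against that scalar baseline, and per-neuron
z-scores are referenced to the pooled 1-s pre-stimulus periods across trials.
All stimulus-window statistics respect a per-trial validity mask that blanks
frames from the animal's first lick onward, so movement-related activity never
contaminates evoked-response measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

PYRAMIDAL, INTERNEURON = 0, 1


@dataclass
class TraceSet:
    """Raw session fluorescence: neurons x frames ROI and neuropil traces."""

    F: np.ndarray
    Fneu: np.ndarray
    celltype: np.ndarray  # 0 = pyramidal, 1 = interneuron
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.Fneu = np.asarray(self.Fneu, dtype=float)
        self.celltype = np.asarray(self.celltype, dtype=int)
        if self.F.shape != self.Fneu.shape:
            raise ValueError(f"F {self.F.shape} and Fneu {self.Fneu.shape} differ in shape")
        if self.celltype.shape[0] != self.F.shape[0]:
            raise ValueError("celltype length must equal number of neurons")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]


@dataclass
class WindowSpec:
    """Peri-stimulus window geometry in frames."""

    pre: int
    stim: int
    post: int
    frame_rate_hz: float

    @classmethod
    def from_seconds(cls, frame_rate_hz: float, pre_s: float = 1.0,
                     stim_s: float = 0.5, post_s: float = 0.5) -> "WindowSpec":
        return cls(
            pre=int(round(pre_s * frame_rate_hz)),
            stim=int(round(stim_s * frame_rate_hz)),
            post=int(round(post_s * frame_rate_hz)),
            frame_rate_hz=frame_rate_hz,
        )

    @property
    def n_frames(self) -> int:
        return self.pre + self.stim + self.post

    @property
    def stim_slice(self) -> slice:
        return slice(self.pre, self.pre + self.stim)

    def frame_times_s(self) -> np.ndarray:
        """Time of each window frame relative to stimulus onset."""
        return (np.arange(self.n_frames) - self.pre) / self.frame_rate_hz


@dataclass
class AlignedTensor:
    """Event-aligned activity: trials x neurons x frames plus masks/metadata.

    ``z`` holds z-scored dF/F, ``dff`` the un-normalized dF/F (the decoder's
    feature space). ``valid_mask[t, f]`` is False from the first-lick frame of
    trial ``t`` onward; stimulus-window statistics must only use valid frames.
    ``neuron_ok`` flags neurons that survived baseline/sigma checks; excluded
    neurons carry NaN rows.
    """

    z: np.ndarray
    dff: np.ndarray
    valid_mask: np.ndarray
    window: WindowSpec
    trial_meta: pd.DataFrame
    celltype: np.ndarray
    neuron_ok: np.ndarray
    onset_frames: np.ndarray
    low_valid_trials: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    mu: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_trials(self) -> int:
        return self.z.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.z.shape[1]

    def stim_z_valid(self, trial: int, neuron: int) -> np.ndarray:
        """Valid-frame z-scores of one neuron in one trial's stimulation window."""
        sl = self.window.stim_slice
        m = self.valid_mask[trial, sl]
        return self.z[trial, neuron, sl][m]

    def n_valid_stim_frames(self, trial: int) -> int:
        return int(self.valid_mask[trial, self.window.stim_slice].sum())


def neuropil_correct(F: np.ndarray, Fneu: np.ndarray, coeff: float = 0.7) -> np.ndarray:
    """Subtract the scaled neuropil trace from the ROI trace.

    F_corrected = F - coeff * F_neuropil, elementwise; ``coeff`` defaults to
    the conventional 0.7 for somatic GCaMP ROIs.
    """
    F = np.asarray(F, dtype=float)
    Fneu = np.asarray(Fneu, dtype=float)
    if F.shape != Fneu.shape:
        raise ValueError(f"shape mismatch: F {F.shape} vs Fneu {Fneu.shape}")
    return F - coeff * Fneu


def baseline_f(trace: np.ndarray, frame_rate_hz: float, window_s: float = 10.0) -> float:
    """Mean of the ``window_s``-second window with the lowest SD (ties: earliest).

    The quiet-window mean serves as the dF/F baseline; recordings shorter than
    the window are rejected.
    """
    trace = np.asarray(trace, dtype=float)
    w = int(round(window_s * frame_rate_hz))
    n = trace.shape[-1]
    if n < w:
        raise ValueError(f"recording has {n} frames, needs >= {w} for a {window_s}-s baseline window")
    # Sliding mean/variance via cumulative sums (stride 1 frame).
    c1 = np.concatenate([[0.0], np.cumsum(trace)])
    c2 = np.concatenate([[0.0], np.cumsum(trace ** 2)])
    means = (c1[w:] - c1[:-w]) / w
    var = (c2[w:] - c2[:-w]) / w - means ** 2
    var = np.maximum(var, 0.0)
    idx = int(np.argmin(np.round(var, 12)))  # argmin takes earliest on exact ties
    return float(means[idx])


def dff(F_corr: np.ndarray, baseline: float) -> np.ndarray:
    """(F - F0) / F0 against a scalar baseline; baseline must be positive."""
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return (np.asarray(F_corr, dtype=float) - baseline) / baseline


def onset_frame(onset_s: float, frame_rate_hz: float) -> int:
    """First frame index at or after the stimulus onset time (0-based)."""
    return int(np.ceil(onset_s * frame_rate_hz - 1e-9))


def zscore_align(
    dff_traces: np.ndarray,
    trials: pd.DataFrame,
    frame_rate_hz: float,
    celltype: np.ndarray | None = None,
    pre_s: float = 1.0,
    stim_s: float = 0.5,
    post_s: float = 0.5,
    min_valid_stim_frames: int = 2,
    neuron_ok: np.ndarray | None = None,
) -> AlignedTensor:
    """Cut peri-stimulus windows and z-score against pooled pre-stimulus frames.

    For each neuron, mu and sigma are computed from the concatenated 1-s
    pre-stimulus frames of all alignable trials; z = (dF/F - mu) / sigma is
    then applied to every trial window. Neurons with sigma == 0 are flagged
    (``neuron_ok`` False) and their rows set to NaN. ``valid_mask`` goes False
    from the first-lick frame onward within each trial's window; trials with
    fewer than ``min_valid_stim_frames`` valid stimulation frames are flagged
    in ``low_valid_trials``.

    ``trials`` must carry ``stim_onset_s`` (sham time for No-Go rows) and may
    carry ``first_lick_s``. Trials whose window does not fit in the recording
    are dropped from the tensor (reported via the returned ``trial_meta``).
    """
    dff_traces = np.asarray(dff_traces, dtype=float)
    n_neurons, n_frames = dff_traces.shape
    win = WindowSpec.from_seconds(frame_rate_hz, pre_s, stim_s, post_s)
    if celltype is None:
        celltype = np.zeros(n_neurons, dtype=int)
    if neuron_ok is None:
        neuron_ok = np.ones(n_neurons, dtype=bool)
    neuron_ok = neuron_ok.copy()

    rows = []
    starts = []
    for _, tr in trials.iterrows():
        f0 = onset_frame(float(tr["stim_onset_s"]), frame_rate_hz)
        start = f0 - win.pre
        if start < 0 or f0 + win.stim + win.post > n_frames:
            continue
        rows.append(tr)
        starts.append(start)
    if not rows:
        raise ValueError("no trial window fits inside the recording")
    meta = pd.DataFrame(rows).reset_index(drop=True)
    starts_arr = np.asarray(starts)
    onset_frames = starts_arr + win.pre

    n_trials = len(starts)
    windows = np.empty((n_trials, n_neurons, win.n_frames))
    for i, s in enumerate(starts_arr):
        windows[i] = dff_traces[:, s:s + win.n_frames]

    # Pooled pre-stimulus frames across all trials, per neuron.
    pre_pool = windows[:, :, : win.pre].transpose(1, 0, 2).reshape(n_neurons, -1)
    mu = pre_pool.mean(axis=1)
    sigma = pre_pool.std(axis=1)
    degenerate = sigma == 0
    neuron_ok &= ~degenerate
    sigma_safe = np.where(sigma > 0, sigma, np.nan)
    z = (windows - mu[None, :, None]) / sigma_safe[None, :, None]
    z[:, ~neuron_ok, :] = np.nan
    dff_win = windows.copy()
    dff_win[:, ~neuron_ok, :] = np.nan

    valid = np.ones((n_trials, win.n_frames), dtype=bool)
    if "first_lick_s" in meta.columns:
        for i in range(n_trials):
            lick = meta.loc[i, "first_lick_s"]
            if pd.notna(lick):
                lick_frame = onset_frame(float(lick), frame_rate_hz) - int(starts_arr[i])
                if lick_frame < win.n_frames:
                    valid[i, max(lick_frame, 0):] = False

    low_valid = valid[:, win.stim_slice].sum(axis=1) < min_valid_stim_frames

    return AlignedTensor(
        z=z, dff=dff_win, valid_mask=valid, window=win, trial_meta=meta,
        celltype=np.asarray(celltype, dtype=int), neuron_ok=neuron_ok,
        onset_frames=onset_frames, low_valid_trials=low_valid,
        mu=mu, sigma=sigma,
    )


def preprocess(traces: TraceSet, neuropil_coeff: float = 0.7,
               baseline_window_s: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Neuropil-correct, baseline and dF/F every neuron of a session.

    Returns ``(dff_traces, neuron_ok)``: neurons with non-positive baseline are
    flagged False in ``neuron_ok`` and carry NaN rows (they are excluded from
    every downstream statistic).
    """
    F_corr = neuropil_correct(traces.F, traces.Fneu, neuropil_coeff)
    out = np.full_like(F_corr, np.nan)
    ok = np.ones(traces.n_neurons, dtype=bool)
    for i in range(traces.n_neurons):
        b = baseline_f(F_corr[i], traces.frame_rate_hz, baseline_window_s)
        if b <= 0:
            ok[i] = False
            continue
        out[i] = dff(F_corr[i], b)
    return out, ok


def smooth_for_plot(trace: np.ndarray, window: int = 10, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing for display only; analyses use raw traces."""
    trace = np.asarray(trace, dtype=float)
    if trace.shape[-1] < window:
        import warnings

        warnings.warn("trace shorter than smoothing window; returning unsmoothed copy")
        return trace.copy()
    return savgol_filter(trace, window_length=window, polyorder=polyorder, axis=-1)
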