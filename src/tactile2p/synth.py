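"""Synthetic Go/No-Go cohort generator.

Produces seeded trial tables and calcium-fluorescence containers with the
statistical structure the analysis pipeline assumes: a logistic psychometric
governing detection, detection-dependent neuronal recruitment that scales with
stimulus amplitude, an exponential-decay calcium kernel, a shared low-pass
"gain" signal that sets ensemble coordination, and a neuropil channel built so
that the standard 0.7-coefficient correction removes the contaminant in
expectation.

Two presets are provided: ``wt_mouse`` (control-like) and ``hypo_mouse``
(hyposensitive-like: higher threshold, weaker and later recruitment, reduced
shared gain). The presets encode directional contrasts between groups, not
quantitative claims about any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .config import ConfigError, SimConfig
from .traces import INTERNEURON, PYRAMIDAL, TraceSet

OUTCOMES = ("Hit", "Miss", "CR", "FA")


@dataclass
class GroundTruthMouse:
    """Generative parameters for one simulated animal.

    Behavioral side: P(lick | amplitude) = (1 - lapse) * logistic(slope *
    (amp - threshold)); No-Go licks occur at a fixed false-alarm rate.
    Neural side: per Go trial each neuron is recruited with probability
    ``recruit_prob(amp, detected)``; recruited neurons emit an exponential
    calcium transient (tau ``kernel_tau_s``) with per-mouse latency; a shared
    low-pass Gaussian-process signal injects trial-to-trial coordination.
    """

    mouse_id: str = "m0"
    group: str = "wt"
    threshold_um: float = 4.0
    slope: float = 0.9          # logit slope per um
    lapse_rate: float = 0.0
    fa_rate: float = 0.15
    # recruitment model: p = detect_factor * (p_catch + (p_max - p_catch)
    #                    * logistic((amp - neural_threshold) / neural_width))
    recruit_p_max: float = 0.35
    recruit_p_catch: float = 0.05
    neural_threshold_um: float = 4.0
    neural_width_um: float = 2.0
    nondetected_factor: float = 0.5
    evoked_amp_gain: float = 1.0      # dF/F units at reference amplitude
    evoked_amp_ref_um: float = 8.0
    latency_s: float = 0.04
    latency_jitter_s: float = 0.02
    shared_gain_loading: float = 0.30
    inhibited_cell_fraction: float = 0.15
    baseline_f: float = 100.0
    baseline_noise_sd: float = 3.0
    neuropil_ratio: float = 0.7
    kernel_tau_s: float = 0.2

    def __post_init__(self) -> None:
        for name in ("lapse_rate", "fa_rate", "recruit_p_max", "recruit_p_catch",
                     "nondetected_factor", "inhibited_cell_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.kernel_tau_s <= 0:
            raise ConfigError("kernel_tau_s must be positive")

    def p_lick(self, amplitude_um: np.ndarray | float) -> np.ndarray:
        """Psychometric probability of licking on a Go trial."""
        a = np.asarray(amplitude_um, dtype=float)
        return (1.0 - self.lapse_rate) * expit(self.slope * (a - self.threshold_um))

    def recruit_prob(self, amplitude_um: float | None, detected: bool) -> float:
        """Per-trial probability that a neuron is recruited by the stimulus."""
        if amplitude_um is None:  # catch trial: spontaneous recruitment only
            return self.recruit_p_catch
        base = self.recruit_p_catch + (self.recruit_p_max - self.recruit_p_catch) * float(
            expit((amplitude_um - self.neural_threshold_um) / self.neural_width_um)
        )
        if not detected:
            base *= self.nondetected_factor
        return float(min(base, 1.0))


def wt_mouse(mouse_id: str = "wt0", **kw) -> GroundTruthMouse:
    """Control-like preset: 4-um threshold, full recruitment and coordination."""
    return GroundTruthMouse(mouse_id=mouse_id, group="wt", **kw)


def hypo_mouse(mouse_id: str = "hypo0", **kw) -> GroundTruthMouse:
    """Hyposensitive-like preset.

    Relative to the control preset: +4 um detection threshold, recruitment
    probability and detected-trial evoked gain scaled by 0.6, +60 ms response
    latency, shared-gain loading halved. These are directional contrasts.
    """
    base = wt_mouse(mouse_id=mouse_id)
    params = dict(
        mouse_id=mouse_id,
        group="hypo",
        threshold_um=base.threshold_um + 4.0,
        neural_threshold_um=base.neural_threshold_um + 4.0,
        recruit_p_max=base.recruit_p_max * 0.6,
        evoked_amp_gain=base.evoked_amp_gain * 0.6,
        latency_s=base.latency_s + 0.060,
        shared_gain_loading=base.shared_gain_loading * 0.5,
    )
    params.update(kw)
    return GroundTruthMouse(**params)


@dataclass
class SyntheticSession:
    """One simulated session: behavior + fluorescence + generative truth."""

    trial_table: pd.DataFrame
    traces: TraceSet
    ground_truth: GroundTruthMouse
    recruit_truth: np.ndarray | None = None  # trials x neurons {-1, 0, +1}


def generate_trial_sequence(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Pseudorandomized trial sequence with balanced amplitude counts.

    Go trials receive amplitudes as evenly as possible (counts within +-1);
    the Go/No-Go order and amplitude assignment are shuffled, and onset times
    accumulate from a lead-in period through per-trial ITIs drawn uniformly
    from ``cfg.iti_range_s``.
    """
    n_go = int(round(cfg.n_trials * cfg.go_fraction))
    n_nogo = cfg.n_trials - n_go
    amps = np.array(cfg.amplitudes_um, dtype=float)
    reps = np.full(len(amps), n_go // len(amps))
    extra = rng.choice(len(amps), size=n_go % len(amps), replace=False)
    reps[extra] += 1
    go_amps = np.repeat(amps, reps)
    rng.shuffle(go_amps)

    trial_type = np.array(["go"] * n_go + ["nogo"] * n_nogo)
    rng.shuffle(trial_type)
    amplitude = np.full(cfg.n_trials, np.nan)
    amplitude[trial_type == "go"] = go_amps

    itis = rng.uniform(*cfg.iti_range_s, size=cfg.n_trials)
    trial_len = cfg.stim_dur_s + cfg.response_window_s
    onsets = cfg.lead_in_s + np.cumsum(itis) + np.arange(cfg.n_trials) * trial_len

    df = pd.DataFrame({
        "trial_idx": np.arange(cfg.n_trials),
        "trial_type": trial_type,
        "amplitude_um": amplitude,
        "freq_hz": np.where(trial_type == "go", cfg.stim_freq_hz, np.nan),
        "stim_onset_s": onsets,
        "stim_offset_s": np.where(trial_type == "go", onsets + cfg.stim_dur_s, np.nan),
        "first_lick_s": np.full(cfg.n_trials, np.nan),
        "outcome": np.full(cfg.n_trials, "", dtype=object),
        "timeout": np.zeros(cfg.n_trials, dtype=bool),
    })
    return df


def simulate_behavior(trials: pd.DataFrame, mouse: GroundTruthMouse,
                      rng: np.random.Generator,
                      response_window_s: float = 2.0,
                      timeout_rate: float = 0.02,
                      min_lick_latency_s: float = 0.1) -> pd.DataFrame:
    """Fill outcomes and first-lick times from the mouse's psychometric.

    Go trials become Hit with probability ``mouse.p_lick(amplitude)`` (Miss
    otherwise); a small fraction are timeout-cancelled before stimulus
    delivery. No-Go trials become FA with probability ``mouse.fa_rate``.
    First-lick times are uniform on [onset + min latency, onset + response
    window].
    """
    out = trials.copy()
    is_go = out["trial_type"].to_numpy() == "go"
    n = len(out)
    timeout = is_go & (rng.random(n) < timeout_rate)
    licked = np.zeros(n, dtype=bool)
    amps = out["amplitude_um"].to_numpy()
    p = np.where(is_go & ~timeout, mouse.p_lick(np.nan_to_num(amps)), 0.0)
    p = np.where(~is_go, mouse.fa_rate, p)
    licked = rng.random(n) < p

    outcome = np.where(is_go, np.where(licked, "Hit", "Miss"),
                       np.where(licked, "FA", "CR"))
    outcome = np.where(timeout, "Timeout", outcome)

    onsets = out["stim_onset_s"].to_numpy()
    lick_t = onsets + rng.uniform(min_lick_latency_s, response_window_s, size=n)
    out["first_lick_s"] = np.where(licked & ~timeout, lick_t, np.nan)
    out["outcome"] = outcome
    out["timeout"] = timeout
    # Cancelled stimulus: no delivery on timeout trials.
    out.loc[timeout, "stim_offset_s"] = np.nan
    return out


def _shared_signal(n_frames: int, frame_rate_hz: float, rng: np.random.Generator,
                   cutoff_hz: float = 1.0) -> np.ndarray:
    """Low-pass-filtered unit-variance Gaussian process (the common gain)."""
    white = rng.standard_normal(n_frames)
    sigma_frames = frame_rate_hz / (2.0 * np.pi * cutoff_hz)
    sig = gaussian_filter1d(white, sigma_frames)
    sd = sig.std()
    return sig / sd if sd > 0 else sig


def _calcium_kernel(tau_s: float, frame_rate_hz: float, dur_s: float = 2.0) -> np.ndarray:
    t = np.arange(int(round(dur_s * frame_rate_hz))) / frame_rate_hz
    return np.exp(-t / tau_s)


def simulate_traces(trials: pd.DataFrame, mouse: GroundTruthMouse, cfg: SimConfig,
                    rng: np.random.Generator,
                    n_neurons: int | None = None) -> tuple[TraceSet, np.ndarray]:
    """Synthesize raw F / Fneu traces consistent with the simulated behavior.

    Per neuron: F(t) = baseline + evoked transients on recruited trials +
    shared_gain_loading * common(t) + 0.7 * neuropil contaminant + noise;
    Fneu(t) carries the contaminant plus independent noise so that
    F - 0.7 * Fneu removes it in expectation. Inhibited-type cells (a fixed
    fraction) emit negative-going transients. Returns the TraceSet and the
    ground-truth recruitment matrix (trials x neurons, {-1, 0, +1}).
    """
    if n_neurons is None:
        n_neurons = int(rng.integers(cfg.n_neurons_range[0], cfg.n_neurons_range[1] + 1))
    lo, hi = cfg.n_neurons_range
    if not lo <= n_neurons <= hi:
        raise ConfigError(f"n_neurons={n_neurons} outside configured range [{lo}, {hi}]")

    total_s = float(trials["stim_onset_s"].max()) + cfg.stim_dur_s + cfg.response_window_s + 5.0
    n_frames = int(round(total_s * cfg.frame_rate_hz))
    fr = cfg.frame_rate_hz

    n_inh = int(round(n_neurons * cfg.interneuron_fraction))
    celltype = np.array([INTERNEURON] * n_inh + [PYRAMIDAL] * (n_neurons - n_inh))
    rng.shuffle(celltype)
    sign = np.where(rng.random(n_neurons) < mouse.inhibited_cell_fraction, -1.0, 1.0)

    common = _shared_signal(n_frames, fr, rng)
    kernel = _calcium_kernel(mouse.kernel_tau_s, fr)
    klen = len(kernel)

    # Per-neuron gains around the mouse-level means.
    amp_gain = mouse.evoked_amp_gain * rng.lognormal(0.0, 0.25, size=n_neurons)
    loading = mouse.shared_gain_loading * rng.lognormal(0.0, 0.25, size=n_neurons)

    evoked = np.zeros((n_neurons, n_frames))
    recruit = np.zeros((len(trials), n_neurons), dtype=int)
    stim_delivered = trials["stim_offset_s"].notna().to_numpy()
    onsets = trials["stim_onset_s"].to_numpy()
    amps = trials["amplitude_um"].to_numpy()
    outcomes = trials["outcome"].to_numpy()

    for t_idx in range(len(trials)):
        onset_fr = int(np.ceil(onsets[t_idx] * fr - 1e-9))
        if stim_delivered[t_idx]:
            detected = outcomes[t_idx] == "Hit"
            p = mouse.recruit_prob(amps[t_idx], detected)
            amp_scale = amps[t_idx] / mouse.evoked_amp_ref_um
        else:
            # No stimulus (catch / timeout): spontaneous recruitment only.
            p = mouse.recruit_p_catch
            amp_scale = 0.5
        hits = rng.random(n_neurons) < p
        if not hits.any():
            continue
        recruit[t_idx, hits] = sign[hits].astype(int)
        for n_idx in np.flatnonzero(hits):
            lat = max(mouse.latency_s + rng.normal(0.0, mouse.latency_jitter_s), 0.0)
            start = onset_fr + int(round(lat * fr))
            if start >= n_frames:
                continue
            seg = min(klen, n_frames - start)
            a = sign[n_idx] * amp_gain[n_idx] * amp_scale * rng.lognormal(0.0, 0.2)
            evoked[n_idx, start:start + seg] += a * kernel[:seg]

    base = mouse.baseline_f
    contaminant = 0.2 * base * np.abs(common)  # shared neuropil fluctuation, a.u.
    dff_signal = evoked + loading[:, None] * common[None, :] * 0.1
    noise = rng.normal(0.0, mouse.baseline_noise_sd, size=(n_neurons, n_frames))
    neu_noise = rng.normal(0.0, mouse.baseline_noise_sd * 0.5, size=(n_neurons, n_frames))

    Fneu = mouse.neuropil_ratio * base + contaminant[None, :] + neu_noise
    F = base * (1.0 + dff_signal) + 0.7 * (mouse.neuropil_ratio * base + contaminant[None, :]) + noise

    ts = TraceSet(F=F, Fneu=Fneu, celltype=celltype, frame_rate_hz=fr)
    return ts, recruit


def simulate_session(cfg: SimConfig, mouse: GroundTruthMouse,
                     rng: np.random.Generator,
                     n_neurons: int | None = None,
                     with_traces: bool = True) -> SyntheticSession:
    """Trial sequence -> behavior -> traces for one mouse/session."""
    trials = generate_trial_sequence(cfg, rng)
    trials = simulate_behavior(trials, mouse, rng,
                               response_window_s=cfg.response_window_s,
                               timeout_rate=cfg.timeout_rate)
    trials.insert(0, "session", 0)
    trials.insert(0, "group", mouse.group)
    trials.insert(0, "mouse_id", mouse.mouse_id)
    if with_traces:
        ts, recruit = simulate_traces(trials, mouse, cfg, rng, n_neurons=n_neurons)
    else:
        ts = TraceSet(F=np.zeros((1, 1)), Fneu=np.zeros((1, 1)),
                      celltype=np.zeros(1, dtype=int), frame_rate_hz=cfg.frame_rate_hz)
        recruit = None
    return SyntheticSession(trial_table=trials, traces=ts,
                            ground_truth=mouse, recruit_truth=recruit)


def generate_cohort(cfg: SimConfig, group_specs: Sequence[GroundTruthMouse],
                    rng_seed: int, n_mice_per_group: int = 1,
                    with_traces: bool = True,
                    n_neurons: int | None = None) -> list[SyntheticSession]:
    """Seeded cohort: ``n_mice_per_group`` replicates of each group template.

    Each mouse gets an independent child generator spawned from the seed, so
    the cohort is reproducible as a whole and per mouse. Mouse ids are
    ``{template id}_{replicate}``; duplicates raise.
    """
    if not group_specs:
        raise ConfigError("need at least one group spec")
    if n_mice_per_group <= 0:
        raise ConfigError("n_mice_per_group must be >= 1")
    ss = np.random.SeedSequence(rng_seed)
    sessions: list[SyntheticSession] = []
    seen: set[str] = set()
    children = ss.spawn(len(group_specs) * n_mice_per_group)
    k = 0
    for spec in group_specs:
        for rep in range(n_mice_per_group):
            mid = f"{spec.mouse_id}_{rep}"
            if mid in seen:
                raise ConfigError(f"duplicate mouse id {mid}")
            seen.add(mid)
            mouse = replace(spec, mouse_id=mid)
            rng = np.random.default_rng(children[k])
            k += 1
            sessions.append(simulate_session(cfg, mouse, rng,
                                             n_neurons=n_neurons,
                                             with_traces=with_traces))
    return sessions
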