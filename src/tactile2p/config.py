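"""Configuration objects for simulation and pipeline runs.

All parameters that downstream modules consume are gathered in two frozen-ish
dataclasses: :class:`SimConfig` (session structure of the Go/No-Go vibrotactile
task plus imaging geometry) and :class:`RunConfig` (paths, seeds and the
analysis parameter blocks). Both serialize to/from plain JSON dictionaries so
that a run is reproducible from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Structure of one simulated Go/No-Go session.

    Defaults follow the task design: testing sessions of 300 pseudorandomized
    trials at a 90:10 Go:No-Go ratio over six vibrotactile amplitudes
    (2-12 um, 10 Hz, 500 ms), training sessions at 75:25 with a single 40 Hz
    stimulus, two-photon imaging at 30.96 Hz.
    """

    phase: str = "testing"  # "training" | "testing"
    n_trials: int = 300
    go_fraction: float = 0.90
    amplitudes_um: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    stim_freq_hz: float = 10.0
    stim_dur_s: float = 0.5
    response_window_s: float = 2.0
    iti_range_s: tuple[float, float] = (5.0, 10.0)
    lead_in_s: float = 12.0
    timeout_rate: float = 0.02
    frame_rate_hz: float = 30.96
    n_neurons_range: tuple[int, int] = (50, 150)
    interneuron_fraction: float = 0.20

    @classmethod
    def training(cls, **kw: Any) -> "SimConfig":
        base = dict(
            phase="training",
            go_fraction=0.75,
            amplitudes_um=(15.0,),
            stim_freq_hz=40.0,
        )
        base.update(kw)
        return cls(**base)

    def __post_init__(self) -> None:
        if not 0.0 < self.go_fraction <= 1.0:
            raise ConfigError(f"go_fraction must be in (0, 1], got {self.go_fraction}")
        if self.n_trials <= 0:
            raise ConfigError("n_trials must be positive")
        if len(self.amplitudes_um) == 0:
            raise ConfigError("amplitude list is empty")
        amps = tuple(float(a) for a in self.amplitudes_um)
        if any(a <= 0 for a in amps):
            raise ConfigError("amplitudes must be strictly positive")
        if list(amps) != sorted(amps):
            raise ConfigError("amplitudes must be sorted ascending")
        self.amplitudes_um = amps
        if self.frame_rate_hz <= 0:
            raise ConfigError("frame_rate_hz must be positive")
        lo, hi = self.n_neurons_range
        if not (0 < lo <= hi):
            raise ConfigError("n_neurons_range must satisfy 0 < lo <= hi")
        if self.iti_range_s[0] > self.iti_range_s[1]:
            raise ConfigError("iti_range_s must be (lo, hi) with lo <= hi")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        for key in ("amplitudes_um", "iti_range_s", "n_neurons_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


# Analysis-side defaults, one block per pipeline stage. Values are the ones
# the analysis modules use unless a caller overrides them.
DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "traces": {
        "neuropil_coeff": 0.7,
        "baseline_window_s": 10.0,
        "pre_s": 1.0,
        "stim_s": 0.5,
        "post_s": 0.5,
        "min_valid_stim_frames": 2,
    },
    "responses": {
        "n_null": 1999,
        "activation_pct": 85.0,
        "inhibition_pct": 10.0,
        "null_upper_pct": 95.0,
        "null_lower_pct": 5.0,
        "inhibition_mode": "symmetric",  # or "literal"
    },
    "behavior": {
        "qc_max_fa_rate": 0.40,
        "train_hit_criterion": 0.80,
        "train_fa_criterion": 0.30,
        "pretrain_hit_criterion": 0.80,
        "pretrain_spont_criterion": 0.40,
    },
    "decoding": {
        "c_grid": (1e-4, 1e-3, 1e-2, 1e-1, 1.0),
        "outer_folds": 4,
        "inner_folds": 3,
        "stim_window_ms": (0.0, 500.0),
        "prestim_window_ms": (-200.0, 0.0),
    },
}


@dataclass
class RunConfig:
    """Everything needed to re-run the pipeline end to end."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    simulate: bool = True
    decode: bool = True
    n_mice_per_group: int = 3
    groups: tuple[str, ...] = ("wt", "hypo")
    sim: SimConfig = field(default_factory=SimConfig)
    params: dict[str, dict[str, Any]] = field(
        default_factory=lambda: json.loads(json.dumps(DEFAULT_PARAMS))
    )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "groups" in d and isinstance(d["groups"], list):
            d["groups"] = tuple(d["groups"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def param(self, block: str, key: str) -> Any:
        return self.params[block][key]


def merged_params(overrides: dict[str, dict[str, Any]] | None = None) -> dict[str, dict[str, Any]]:
    """Deep-merge ``overrides`` onto the default analysis parameters."""
    out = json.loads(json.dumps(DEFAULT_PARAMS))
    for block, kv in (overrides or {}).items():
        out.setdefault(block, {}).update(kv)
    return out
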