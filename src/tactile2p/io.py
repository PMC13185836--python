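"""On-disk formats: trials.csv, traces.h5, aligned.h5 and JSON configs.

CSV carries tabular behavior, HDF5 carries fluorescence tensors, JSON carries
configuration and run summaries. Readers validate schema and invariants and
report offending rows rather than failing silently.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .traces import AlignedTensor, TraceSet, WindowSpec

TRIAL_COLUMNS = [
    "mouse_id", "group", "session", "trial_idx", "trial_type", "amplitude_um",
    "freq_hz", "stim_onset_s", "stim_offset_s", "first_lick_s", "outcome", "timeout",
]
VALID_OUTCOMES = {"Hit", "Miss", "CR", "FA", "Timeout", ""}


class SchemaError(ValueError):
    """Input file violates the expected schema."""


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Load and validate a trial table; rows sorted by onset within session."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad_outcome = ~df["outcome"].fillna("").isin(VALID_OUTCOMES)
    if bad_outcome.any():
        rows = df.index[bad_outcome].tolist()[:10]
        raise SchemaError(f"{path}: unknown outcome codes at rows {rows}")
    is_go = df["trial_type"] == "go"
    no_amp = is_go & df["amplitude_um"].isna()
    if no_amp.any():
        rows = df.index[no_amp].tolist()[:10]
        raise SchemaError(f"{path}: Go rows missing amplitude at rows {rows}")
    df = df.sort_values(["mouse_id", "session", "stim_onset_s"], kind="stable")
    for (_, _), g in df.groupby(["mouse_id", "session"]):
        d = g["stim_onset_s"].diff().dropna()
        if (d <= 0).any():
            row = g.index[1:][(d <= 0).to_numpy()].tolist()[:5]
            raise SchemaError(f"{path}: non-monotone onset times near rows {row}")
    df["timeout"] = df["timeout"].astype(bool)
    return df.reset_index(drop=True)


def write_traces(ts: TraceSet, path: str | Path,
                 events: pd.DataFrame | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("F", data=ts.F)
        f.create_dataset("Fneu", data=ts.Fneu)
        f.create_dataset("celltype", data=ts.celltype)
        f.create_dataset("frame_rate_hz", data=float(ts.frame_rate_hz))
        if events is not None:
            g = f.create_group("events")
            for col in ("stim_onset_s", "stim_offset_s", "first_lick_s"):
                if col in events:
                    g.create_dataset(col, data=events[col].to_numpy(dtype=float))


def read_traces(path: str | Path) -> TraceSet:
    with h5py.File(path, "r") as f:
        for name in ("F", "Fneu", "celltype", "frame_rate_hz"):
            if name not in f:
                raise SchemaError(f"{path}: missing dataset /{name}")
        F = f["F"][()]
        Fneu = f["Fneu"][()]
        celltype = f["celltype"][()]
        fr = float(f["frame_rate_hz"][()])
    if F.shape != Fneu.shape:
        raise SchemaError(f"{path}: F {F.shape} vs Fneu {Fneu.shape} shape mismatch")
    bad = ~np.isin(celltype, (0, 1))
    if bad.any():
        raise SchemaError(f"{path}: invalid celltype codes {np.unique(celltype[bad])}")
    return TraceSet(F=F, Fneu=Fneu, celltype=celltype, frame_rate_hz=fr)


def write_aligned(at: AlignedTensor, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("z", data=at.z)
        f.create_dataset("dff", data=at.dff)
        f.create_dataset("valid_mask", data=at.valid_mask)
        f.create_dataset("celltype", data=at.celltype)
        f.create_dataset("neuron_ok", data=at.neuron_ok)
        f.create_dataset("onset_frames", data=at.onset_frames)
        f.create_dataset("low_valid_trials", data=at.low_valid_trials)
        w = f.create_group("window_spec")
        for k in ("pre", "stim", "post", "frame_rate_hz"):
            w.attrs[k] = getattr(at.window, k)
        f.create_dataset("trial_meta_json",
                         data=at.trial_meta.to_json(orient="split"))


def read_aligned(path: str | Path) -> AlignedTensor:
    import io as _io

    with h5py.File(path, "r") as f:
        w = f["window_spec"].attrs
        window = WindowSpec(pre=int(w["pre"]), stim=int(w["stim"]),
                            post=int(w["post"]), frame_rate_hz=float(w["frame_rate_hz"]))
        meta_json = f["trial_meta_json"][()]
        if isinstance(meta_json, bytes):
            meta_json = meta_json.decode()
        meta = pd.read_json(_io.StringIO(meta_json), orient="split")
        return AlignedTensor(
            z=f["z"][()], dff=f["dff"][()], valid_mask=f["valid_mask"][()].astype(bool),
            window=window, trial_meta=meta, celltype=f["celltype"][()],
            neuron_ok=f["neuron_ok"][()].astype(bool),
            onset_frames=f["onset_frames"][()],
            low_valid_trials=f["low_valid_trials"][()].astype(bool),
        )


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
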