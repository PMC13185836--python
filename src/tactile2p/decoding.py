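"""Frame-by-frame population decoding of trial outcome (Hit vs Miss).

For every peri-stimulus frame a separate L2-penalized logistic regression is
trained on the population vector of single-frame dF/F values, with nested
cross-validation: an outer 4-fold split yields test predictions, and an inner
3-fold stratified search on each training split picks the regularization
strength C from {1e-4, 1e-3, 1e-2, 1e-1, 1}. Classes are balanced beforehand
by random undersampling of the majority class. Chance level is estimated by
rerunning the identical procedure with training labels permuted within each
outer fold. Reported per frame: overall accuracy, Hit accuracy
P(pred Hit | Hit) and Miss error P(pred Hit | Miss), for true and shuffled
labels, plus stimulation-window (0-500 ms) and pre-stimulus (-200-0 ms)
averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .traces import AlignedTensor, INTERNEURON, PYRAMIDAL

C_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)


def balance_classes(labels: np.ndarray, rng: np.random.Generator,
                    min_per_class: int = 4) -> np.ndarray:
    """Indices after random undersampling of the majority class.

    Keeps every minority-class trial and a uniform without-replacement sample
    of the majority class of the same size. Raises if either class has fewer
    than ``min_per_class`` trials (4 outer folds need 4 per class).
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if counts.min() < min_per_class:
        raise ValueError(
            f"minority class has {counts.min()} trials; need >= {min_per_class}")
    n_keep = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) > n_keep:
            idx = rng.choice(idx, size=n_keep, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def _fit_one(X: np.ndarray, y: np.ndarray, C: float) -> LogisticRegression:
    # L2 penalty (sklearn's default) with strength 1/C.
    return LogisticRegression(C=C, solver="lbfgs", max_iter=1000).fit(X, y)


def _inner_select_c(X: np.ndarray, y: np.ndarray, c_grid, inner_folds: int,
                    seed: int) -> float:
    """Pick C by stratified inner CV accuracy on the training split."""
    best_c, best_acc = c_grid[0], -1.0
    n_splits = min(inner_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        return c_grid[len(c_grid) // 2]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for C in c_grid:
        accs = []
        for tr, te in skf.split(X, y):
            if len(np.unique(y[tr])) < 2:
                continue
            clf = _fit_one(X[tr], y[tr], C)
            accs.append((clf.predict(X[te]) == y[te]).mean())
        acc = float(np.mean(accs)) if accs else 0.0
        if acc > best_acc:
            best_acc, best_c = acc, C
    return best_c


@dataclass
class DecodingResult:
    """Per-frame decoding curves and window summaries for one session."""

    frame_times_s: np.ndarray
    accuracy: np.ndarray          # per frame, pooled over outer test folds
    hit_accuracy: np.ndarray      # P(pred Hit | true Hit)
    miss_error: np.ndarray        # P(pred Hit | true Miss)
    shuffled_accuracy: np.ndarray
    shuffled_hit_accuracy: np.ndarray
    shuffled_miss_error: np.ndarray
    n_trials: int
    n_neurons: int
    selected_c: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame_ms": self.frame_times_s * 1000.0,
            "accuracy": self.accuracy,
            "hit_acc": self.hit_accuracy,
            "miss_err": self.miss_error,
            "shuffled_accuracy": self.shuffled_accuracy,
            "shuffled_hit_acc": self.shuffled_hit_accuracy,
            "shuffled_miss_err": self.shuffled_miss_error,
        })


def _rates(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    acc = float((y_pred == y_true).mean())
    hit = float((y_pred[y_true == 1] == 1).mean()) if (y_true == 1).any() else np.nan
    merr = float((y_pred[y_true == 0] == 1).mean()) if (y_true == 0).any() else np.nan
    return acc, hit, merr


def fit_frame_classifiers(features: np.ndarray, labels: np.ndarray,
                          frame_times_s: np.ndarray,
                          rng: np.random.Generator,
                          c_grid=C_GRID, outer_folds: int = 4,
                          inner_folds: int = 3,
                          shuffle_labels: bool = False) -> DecodingResult:
    """Nested-CV per-frame decoding on a balanced trials x neurons x frames array.

    Outer folds are stratified and shared across frames; inner selection sees
    only the outer training split. With ``shuffle_labels`` the training labels
    of each outer fold are permuted (test labels untouched), giving the
    chance-level baseline with identical folds and pipeline.
    """
    X_all = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_trials, n_neurons, n_frames = X_all.shape
    if n_trials < 2 * outer_folds:
        raise ValueError(f"need >= {2 * outer_folds} balanced trials")

    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True,
                            random_state=int(rng.integers(2**31 - 1)))
    splits = list(outer.split(np.zeros(n_trials), y))
    # Per-fold permutation of training labels (shuffled baseline only).
    perms = [rng.permutation(len(tr)) for tr, _ in splits]
    inner_seed = int(rng.integers(2**31 - 1))

    acc = np.zeros(n_frames)
    hit = np.zeros(n_frames)
    merr = np.zeros(n_frames)
    sel_c = np.zeros(n_frames)
    for f in range(n_frames):
        X = X_all[:, :, f]
        X = np.nan_to_num(X, nan=0.0)
        y_pred = np.empty(n_trials, dtype=int)
        cs = []
        for k, (tr, te) in enumerate(splits):
            y_tr = y[tr]
            if shuffle_labels:
                y_tr = y_tr[perms[k]]
            if len(np.unique(y_tr)) < 2 or np.allclose(X[tr].std(axis=0), 0):
                # Degenerate training fold: intercept-only behaviour.
                maj = int(np.bincount(y_tr).argmax())
                y_pred[te] = maj
                continue
            C = _inner_select_c(X[tr], y_tr, c_grid, inner_folds, inner_seed + k)
            cs.append(C)
            clf = _fit_one(X[tr], y_tr, C)
            y_pred[te] = clf.predict(X[te])
        acc[f], hit[f], merr[f] = _rates(y, y_pred)
        sel_c[f] = np.median(cs) if cs else np.nan

    zeros = np.zeros(n_frames)
    return DecodingResult(
        frame_times_s=np.asarray(frame_times_s, dtype=float),
        accuracy=acc, hit_accuracy=hit, miss_error=merr,
        shuffled_accuracy=zeros.copy(), shuffled_hit_accuracy=zeros.copy(),
        shuffled_miss_error=zeros.copy(),
        n_trials=n_trials, n_neurons=n_neurons, selected_c=sel_c,
    )


def shuffled_baseline(features: np.ndarray, labels: np.ndarray,
                      frame_times_s: np.ndarray, rng: np.random.Generator,
                      **kw) -> DecodingResult:
    """Chance-level curves: same pipeline with per-fold permuted training labels."""
    return fit_frame_classifiers(features, labels, frame_times_s, rng,
                                 shuffle_labels=True, **kw)


def window_average(result: DecodingResult, window_ms: tuple[float, float],
                   curve: str = "accuracy") -> float:
    """Mean of a per-frame curve over a time window (ms relative to onset).

    The window covers round(duration * frame_rate) frames starting at the
    first frame at/after the window start — e.g. 15 frames for 0-500 ms and
    6 frames for -200-0 ms at 30.96 Hz.
    """
    t_ms = result.frame_times_s * 1000.0
    if len(t_ms) > 1:
        fr = 1000.0 / (t_ms[1] - t_ms[0])
    else:
        fr = 0.0
    start = int(np.searchsorted(t_ms, window_ms[0] - 1e-9))
    n = int(round((window_ms[1] - window_ms[0]) / 1000.0 * fr)) if fr else 1
    sel = slice(start, min(start + max(n, 1), len(t_ms)))
    if sel.start >= len(t_ms) or sel.start == sel.stop:
        raise ValueError(f"no frames in window {window_ms}")
    return float(np.asarray(getattr(result, curve))[sel].mean())


def decode_session(aligned: AlignedTensor, rng: np.random.Generator,
                   celltype_filter: int | None = None,
                   feature: str = "dff",
                   c_grid=C_GRID, outer_folds: int = 4,
                   inner_folds: int = 3,
                   with_shuffled: bool = True) -> DecodingResult:
    """End-to-end session decoding: select Hit/Miss trials, balance, fit, shuffle.

    ``celltype_filter`` restricts the feature set to one cell type (separate
    excitatory/inhibitory decoders); ``feature`` chooses raw dF/F (default) or
    z-scored activity.
    """
    meta = aligned.trial_meta
    is_hit = (meta["outcome"] == "Hit").to_numpy()
    is_miss = (meta["outcome"] == "Miss").to_numpy()
    sel_trials = np.flatnonzero(is_hit | is_miss)
    labels = is_hit[sel_trials].astype(int)

    keep = balance_classes(labels, rng)
    idx = sel_trials[keep]
    y = labels[keep]

    data = aligned.dff if feature == "dff" else aligned.z
    nsel = aligned.neuron_ok.copy()
    if celltype_filter is not None:
        nsel &= aligned.celltype == celltype_filter
    if nsel.sum() < 2:
        raise ValueError("need >= 2 neurons after cell-type restriction")
    X = data[np.ix_(idx, np.flatnonzero(nsel))]
    times = aligned.window.frame_times_s()

    res = fit_frame_classifiers(X, y, times, rng, c_grid=c_grid,
                                outer_folds=outer_folds, inner_folds=inner_folds)
    if with_shuffled:
        sh = shuffled_baseline(X, y, times, rng, c_grid=c_grid,
                               outer_folds=outer_folds, inner_folds=inner_folds)
        res.shuffled_accuracy = sh.accuracy
        res.shuffled_hit_accuracy = sh.hit_accuracy
        res.shuffled_miss_error = sh.miss_error
    return res


STIM_WINDOW_MS = (0.0, 500.0)
PRESTIM_WINDOW_MS = (-200.0, 0.0)


def window_summary(result: DecodingResult) -> dict:
    """Stimulation- and pre-stimulus-window means of all curves."""
    out = {}
    for name, win in (("stim", STIM_WINDOW_MS), ("prestim", PRESTIM_WINDOW_MS)):
        for curve in ("accuracy", "hit_accuracy", "miss_error",
                      "shuffled_accuracy", "shuffled_hit_accuracy"):
            out[f"{name}_{curve}"] = window_average(result, win, curve)
    return out
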