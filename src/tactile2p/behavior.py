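"""Behavioral analysis of the Go/No-Go vibrotactile detection task.

Outcome rates, psychometric (binomial-logit) fits with threshold and
perceptual-accuracy readouts, the signal-detection relative criterion c',
trial-by-trial variability profiles, session quality control, learning
criteria and k-means subgrouping of hit-rate profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.cluster import KMeans


@dataclass
class OutcomeRates:
    """Per-session outcome proportions.

    Timeout-cancelled Go trials (no stimulus delivered) are excluded from the
    Go denominator; their fraction of all Go trials is the pre-stimulus
    spontaneous licking rate.
    """

    hit_rate: float
    miss_rate: float
    cr_rate: float
    fa_rate: float
    prestim_lick_rate: float
    n_go: int
    n_nogo: int
    go_defined: bool = True
    nogo_defined: bool = True


@dataclass
class PsychometricFit:
    """Binomial GLM (logit link) of Hit probability on stimulus amplitude."""

    amplitudes_um: np.ndarray
    hit_rates: np.ndarray
    n_trials: np.ndarray
    intercept: float
    slope: float
    threshold_um: float          # amplitude at fitted P = 0.5
    accuracy_slope: float        # max derivative of the fitted curve (= slope/4)
    threshold_defined: bool
    ridge_fallback: bool = False

    def predict(self, amplitude_um: np.ndarray | float) -> np.ndarray:
        from scipy.special import expit

        return expit(self.intercept + self.slope * np.asarray(amplitude_um, dtype=float))


@dataclass
class CriterionC:
    """Relative criterion c' from signal detection theory."""

    c_prime: float
    z_hit: float
    z_fa: float
    defined: bool


@dataclass
class VariabilityProfile:
    """Trial-by-trial variability: per-amplitude variance of the Hit indicator."""

    amplitudes_um: np.ndarray
    variances: np.ndarray
    n_trials: np.ndarray
    mean_variance: float
    low_n: np.ndarray
    triplet_amplitudes: np.ndarray | None = None  # (thr-2, thr, thr+2) as delivered
    triplet_variances: np.ndarray | None = None


def compute_rates(trials: pd.DataFrame) -> OutcomeRates:
    """Outcome rates from a completed trial table.

    Hit = Hits / delivered Go; FA = FAs / No-Go; prestim lick rate =
    timeouts / all Go. Zero-denominator rates are flagged undefined rather
    than silently NaN.
    """
    t = trials
    is_go = t["trial_type"] == "go"
    timeout = t["timeout"].astype(bool) if "timeout" in t else (t["outcome"] == "Timeout")
    go_all = int(is_go.sum())
    go_delivered = t[is_go & ~timeout]
    nogo = t[~is_go]
    n_go, n_nogo = len(go_delivered), len(nogo)

    go_ok = n_go > 0
    nogo_ok = n_nogo > 0
    hits = int((go_delivered["outcome"] == "Hit").sum())
    fas = int((nogo["outcome"] == "FA").sum())
    hit_rate = hits / n_go if go_ok else np.nan
    fa_rate = fas / n_nogo if nogo_ok else np.nan
    return OutcomeRates(
        hit_rate=hit_rate,
        miss_rate=1.0 - hit_rate if go_ok else np.nan,
        cr_rate=1.0 - fa_rate if nogo_ok else np.nan,
        fa_rate=fa_rate,
        prestim_lick_rate=int(timeout[is_go].sum()) / go_all if go_all else np.nan,
        n_go=n_go,
        n_nogo=n_nogo,
        go_defined=go_ok,
        nogo_defined=nogo_ok,
    )


def per_amplitude_hits(trials: pd.DataFrame) -> pd.DataFrame:
    """Tidy (amplitude, hits, n) table over delivered Go trials."""
    is_go = trials["trial_type"] == "go"
    timeout = trials["timeout"].astype(bool) if "timeout" in trials else False
    go = trials[is_go & ~timeout]
    grp = go.groupby("amplitude_um")["outcome"]
    out = pd.DataFrame({
        "amplitude_um": grp.size().index.to_numpy(dtype=float),
        "hits": grp.apply(lambda s: int((s == "Hit").sum())).to_numpy(),
        "n": grp.size().to_numpy(),
    })
    return out.reset_index(drop=True)


def fit_psychometric(per_amp: pd.DataFrame, ridge_alpha: float = 1e-3) -> PsychometricFit:
    """Fit Hit probability vs amplitude with a binomial GLM (logit link).

    The detection threshold is the amplitude where the fitted curve crosses
    0.5 (= -intercept/slope, the sigmoid inflection); perceptual accuracy is
    the maximum slope of the fitted probability curve (slope/4). Degenerate
    data (all hit rates ~0 or ~1, or non-positive slope) yield an undefined
    threshold flag. Perfect separation triggers a small-L2 ridge refit,
    flagged in the result.
    """
    amps = per_amp["amplitude_um"].to_numpy(dtype=float)
    hits = per_amp["hits"].to_numpy(dtype=float)
    n = per_amp["n"].to_numpy(dtype=float)
    if len(amps) < 2 or (n > 0).sum() < 2:
        raise ValueError("need >= 2 amplitudes with trials to fit a psychometric curve")
    rates = np.divide(hits, n, out=np.full_like(hits, np.nan), where=n > 0)

    X = sm.add_constant(amps)
    y = np.column_stack([hits, n - hits])
    ridge = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            params = np.asarray(res.params)
            eta = X @ params
            # Linear predictor far in the saturated tails at observed points
            # means the likelihood is unbounded (perfect separation).
            if not np.all(np.isfinite(params)) or np.abs(eta).max() > 30:
                raise ValueError("separation")
        except Exception:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                alpha=ridge_alpha, L1_wt=0.0)
            params = np.asarray(res.params)
            ridge = True
    intercept, slope = float(params[0]), float(params[1])

    degenerate = np.nanmax(rates) < 0.05 or np.nanmin(rates) > 0.95
    defined = slope > 0 and not degenerate
    threshold = -intercept / slope if defined else np.nan
    return PsychometricFit(
        amplitudes_um=amps, hit_rates=rates, n_trials=n.astype(int),
        intercept=intercept, slope=slope,
        threshold_um=float(threshold),
        accuracy_slope=slope / 4.0,
        threshold_defined=bool(defined),
        ridge_fallback=ridge,
    )


def criterion_c_prime(hit_rate: float, fa_rate: float, n_go: int, n_nogo: int) -> CriterionC:
    """Relative criterion c' = -(1/2) * (z(Hit) + z(FA)) / (z(Hit) - z(FA)).

    Rates are clipped to [1/(2n), 1 - 1/(2n)] before the normal-quantile
    transform (the standard correction for 0/1 rates). Equal quantiles make
    the ratio undefined; flagged, not raised.
    """
    for r in (hit_rate, fa_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate {r} outside [0, 1]")
    h = float(np.clip(hit_rate, 1.0 / (2 * n_go), 1.0 - 1.0 / (2 * n_go)))
    f = float(np.clip(fa_rate, 1.0 / (2 * n_nogo), 1.0 - 1.0 / (2 * n_nogo)))
    zh, zf = norm.ppf(h), norm.ppf(f)
    if zh == zf:
        return CriterionC(c_prime=np.nan, z_hit=zh, z_fa=zf, defined=False)
    return CriterionC(c_prime=-0.5 * (zh + zf) / (zh - zf), z_hit=zh, z_fa=zf, defined=True)


def tbt_variability(trials: pd.DataFrame, threshold_um: float | None = None,
                    triplet_step_um: float = 2.0) -> VariabilityProfile:
    """Variance of the Hit indicator across delivered Go trials per amplitude.

    The population (ddof=0) variance of a Bernoulli indicator, p*(1-p), is
    bounded by 0.25: maximal when detection is at chance, zero when responses
    are fully consistent. With a detection threshold available, the profile
    is also read out at the nearest delivered amplitudes to threshold - 2,
    threshold, and threshold + 2 um.
    """
    pa = per_amplitude_hits(trials)
    amps = pa["amplitude_um"].to_numpy()
    n = pa["n"].to_numpy()
    p = pa["hits"].to_numpy() / n
    var = p * (1.0 - p)
    low_n = n < 2
    prof = VariabilityProfile(
        amplitudes_um=amps, variances=var, n_trials=n,
        mean_variance=float(np.mean(var)), low_n=low_n,
    )
    if threshold_um is not None and np.isfinite(threshold_um):
        targets = np.array([threshold_um - triplet_step_um, threshold_um,
                            threshold_um + triplet_step_um])
        idx = np.array([int(np.argmin(np.abs(amps - t))) for t in targets])
        prof.triplet_amplitudes = amps[idx]
        prof.triplet_variances = var[idx]
    return prof


def session_qc(trials: pd.DataFrame, max_fa_rate: float = 0.40) -> bool:
    """Include a testing session iff its false-alarm rate is strictly below 40%."""
    rates = compute_rates(trials)
    if not rates.nogo_defined:
        return False
    return rates.fa_rate < max_fa_rate


def learning_criterion(daily_rates: pd.DataFrame, phase: str = "training",
                       hit_criterion: float | None = None,
                       fa_criterion: float | None = None) -> pd.DataFrame:
    """Rolling 3-day learning criteria.

    ``daily_rates`` needs one row per day with ``hit_rate`` and, for the
    training phase, ``fa_rate`` (for pre-training, ``prestim_lick_rate``).
    Training passes when the 3-day rolling means reach >= 80% Hits and < 30%
    FAs; pre-training requires >= 80% Hits and < 40% spontaneous licking.
    Returns the input with a ``pass`` column (NaN-propagating: the first two
    days are insufficient data).
    """
    if len(daily_rates) < 3:
        out = daily_rates.copy()
        out["pass"] = pd.NA
        out.attrs["insufficient_data"] = True
        return out
    if phase == "training":
        hit_c = 0.80 if hit_criterion is None else hit_criterion
        fa_c = 0.30 if fa_criterion is None else fa_criterion
        other = daily_rates["fa_rate"]
    elif phase == "pretraining":
        hit_c = 0.80 if hit_criterion is None else hit_criterion
        fa_c = 0.40 if fa_criterion is None else fa_criterion
        other = daily_rates["prestim_lick_rate"]
    else:
        raise ValueError(f"unknown phase {phase!r}")
    hit_roll = daily_rates["hit_rate"].rolling(3).mean()
    other_roll = other.rolling(3).mean()
    out = daily_rates.copy()
    passed = (hit_roll >= hit_c) & (other_roll < fa_c)
    out["pass"] = passed.where(hit_roll.notna(), pd.NA)
    out.attrs["insufficient_data"] = False
    return out


@dataclass
class SubgroupResult:
    labels: np.ndarray            # 0 = higher-sensitivity cluster, 1 = hyposensitive-like
    names: np.ndarray             # "typical" / "hyposensitive-like" per mouse
    centers: np.ndarray
    degenerate: bool
    imputed: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def cluster_subgroups(hit_rate_matrix: np.ndarray, seed: int = 0,
                      n_init: int = 10) -> SubgroupResult:
    """k-means (k=2) on mice x amplitude hit-rate profiles.

    The cluster with the lower mean hit rate is labelled hyposensitive-like.
    Missing entries are imputed by the within-mouse mean (flagged). Identical
    profiles make the split degenerate; flagged rather than raised.
    """
    X = np.asarray(hit_rate_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a mice x amplitudes matrix with >= 2 mice")
    imputed = np.zeros(X.shape[0], dtype=bool)
    if np.isnan(X).any():
        X = X.copy()
        for i in range(X.shape[0]):
            row = X[i]
            if np.isnan(row).any():
                imputed[i] = True
                row[np.isnan(row)] = np.nanmean(row)
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed).fit(X)
    means = np.array([X[km.labels_ == k].mean() if (km.labels_ == k).any() else np.nan
                      for k in range(2)])
    degenerate = np.allclose(X, X[0]) or np.isnan(means).any()
    # Relabel: 1 = lower mean hit rate = hyposensitive-like.
    hypo_cluster = int(np.nanargmin(means))
    labels = (km.labels_ == hypo_cluster).astype(int)
    names = np.where(labels == 1, "hyposensitive-like", "typical")
    centers = km.cluster_centers_[[1 - hypo_cluster, hypo_cluster]]
    return SubgroupResult(labels=labels, names=names, centers=centers,
                          degenerate=bool(degenerate), imputed=imputed)


def session_metrics(trials: pd.DataFrame) -> dict:
    """Convenience bundle: rates, psychometric fit, c', variability for one table."""
    rates = compute_rates(trials)
    fit = fit_psychometric(per_amplitude_hits(trials))
    c = criterion_c_prime(rates.hit_rate, rates.fa_rate, rates.n_go, rates.n_nogo)
    var = tbt_variability(trials, fit.threshold_um if fit.threshold_defined else None)
    return {
        "hit_rate": rates.hit_rate, "fa_rate": rates.fa_rate,
        "prestim_lick_rate": rates.prestim_lick_rate,
        "threshold_um": fit.threshold_um, "slope": fit.slope,
        "accuracy_slope": fit.accuracy_slope,
        "c_prime": c.c_prime, "mean_variance": var.mean_variance,
        "qc_include": session_qc(trials),
    }
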