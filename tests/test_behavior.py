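"""Behavioral metrics: rates, psychometric fit, criterion c', variability,
QC, learning criteria and subgrouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tactile2p import behavior as bh
from tactile2p.config import SimConfig
from tactile2p.synth import generate_trial_sequence, simulate_behavior, wt_mouse


def make_trials(outcomes, trial_types=None, amplitudes=None, timeouts=None):
    n = len(outcomes)
    if trial_types is None:
        trial_types = ["go" if o in ("Hit", "Miss", "Timeout") else "nogo" for o in outcomes]
    df = pd.DataFrame({
        "trial_type": trial_types,
        "outcome": outcomes,
        "amplitude_um": amplitudes if amplitudes is not None
        else [6.0 if t == "go" else np.nan for t in trial_types],
        "timeout": timeouts if timeouts is not None else [o == "Timeout" for o in outcomes],
    })
    df["stim_onset_s"] = np.arange(n) * 10.0 + 15.0
    df["stim_offset_s"] = np.where((df.trial_type == "go") & ~df.timeout,
                                   df.stim_onset_s + 0.5, np.nan)
    return df


class TestRates:
    def test_direct_ratios(self):
        trials = make_trials(["Hit"] * 8 + ["Miss"] * 2 + ["FA"] + ["CR"] * 4)
        r = bh.compute_rates(trials)
        assert r.hit_rate == pytest.approx(0.8)
        assert r.fa_rate == pytest.approx(0.2)
        assert r.miss_rate == pytest.approx(0.2)
        assert r.cr_rate == pytest.approx(0.8)

    def test_all_cr_gives_zero_fa(self):
        trials = make_trials(["Hit"] * 5 + ["CR"] * 5)
        assert bh.compute_rates(trials).fa_rate == 0.0

    def test_timeouts_excluded_from_go_denominator(self):
        trials = make_trials(["Hit"] * 4 + ["Timeout"] * 2 + ["CR"] * 2)
        r = bh.compute_rates(trials)
        assert r.hit_rate == pytest.approx(1.0)
        assert r.n_go == 4
        assert r.prestim_lick_rate == pytest.approx(2 / 6)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        cfg = SimConfig(n_trials=200)
        trials = simulate_behavior(generate_trial_sequence(cfg, rng), wt_mouse(), rng)
        r = bh.compute_rates(trials)
        # independent row-by-row tally
        hits = misses = fas = crs = n_go = n_nogo = 0
        for _, row in trials.iterrows():
            if row.trial_type == "go":
                if row.timeout:
                    continue
                n_go += 1
                hits += row.outcome == "Hit"
                misses += row.outcome == "Miss"
            else:
                n_nogo += 1
                fas += row.outcome == "FA"
                crs += row.outcome == "CR"
        assert r.hit_rate == pytest.approx(hits / n_go, rel=1e-12)
        assert r.fa_rate == pytest.approx(fas / n_nogo, rel=1e-12)

    def test_zero_nogo_flagged_undefined(self):
        trials = make_trials(["Hit"] * 5)
        r = bh.compute_rates(trials)
        assert not r.nogo_defined


class TestPsychometric:
    def test_threshold_recovery_from_logistic_generator(self):
        rng = np.random.default_rng(1)
        amps = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        from scipy.special import expit

        p = expit(1.0 * (amps - 6.0))
        n = 200
        hits = rng.binomial(n, p)
        fit = bh.fit_psychometric(pd.DataFrame(
            {"amplitude_um": amps, "hits": hits, "n": n}))
        assert fit.threshold_defined
        assert fit.threshold_um == pytest.approx(6.0, abs=0.5)
        assert fit.slope == pytest.approx(1.0, abs=0.3)

    def test_all_zero_rates_flagged_undefined(self):
        fit = bh.fit_psychometric(pd.DataFrame(
            {"amplitude_um": [2.0, 6.0, 10.0], "hits": [0, 0, 0], "n": [50, 50, 50]}))
        assert not fit.threshold_defined

    def test_symmetric_rates_around_4um(self):
        # Hit rates symmetric around 4 um -> threshold at 4 um.
        amps = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        rates = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        n = 100
        fit = bh.fit_psychometric(pd.DataFrame(
            {"amplitude_um": amps, "hits": (rates * n).astype(int), "n": n}))
        assert fit.threshold_um == pytest.approx(4.0, abs=0.1)

    def test_threshold_monotone_under_uniform_rate_shift(self):
        amps = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        from scipy.special import expit

        base = expit(0.8 * (amps - 7.0))
        lifted = np.clip(base + 0.15, 0, 1)
        n = 400
        f0 = bh.fit_psychometric(pd.DataFrame(
            {"amplitude_um": amps, "hits": np.round(base * n), "n": n}))
        f1 = bh.fit_psychometric(pd.DataFrame(
            {"amplitude_um": amps, "hits": np.round(lifted * n), "n": n}))
        assert f1.threshold_um < f0.threshold_um

    def test_perfect_separation_falls_back_to_ridge(self):
        fit = bh.fit_psychometric(pd.DataFrame(
            {"amplitude_um": [2.0, 4.0, 8.0, 10.0],
             "hits": [0, 0, 30, 30], "n": [30, 30, 30, 30]}))
        assert fit.ridge_fallback
        assert np.isfinite(fit.threshold_um)
        assert 4.0 < fit.threshold_um < 8.0


class TestCriterion:
    def test_symmetric_rates_give_zero(self):
        c = bh.criterion_c_prime(0.8, 0.2, 1000, 1000)
        assert c.c_prime == pytest.approx(0.0, abs=1e-12)

    def test_equal_rates_flagged_undefined(self):
        c = bh.criterion_c_prime(0.5, 0.5, 100, 100)
        assert not c.defined

    def test_frozen_quantile_oracle(self):
        # Precomputed from normal quantiles: z(0.9)=1.2815515655446004,
        # z(0.4)=-0.2533471031357997 -> c' = -0.3349421311612642.
        c = bh.criterion_c_prime(0.9, 0.4, 1000, 1000)
        assert c.c_prime == pytest.approx(-0.3349421311612642, abs=1e-12)

    @given(h=st.floats(0.05, 0.95), f=st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, h, f):
        """Swapping hit <-> 1-fa and fa <-> 1-hit flips the sign of c'."""
        a = bh.criterion_c_prime(h, f, 1000, 1000)
        b = bh.criterion_c_prime(1 - f, 1 - h, 1000, 1000)
        if a.defined and b.defined:
            assert a.c_prime == pytest.approx(-b.c_prime, abs=1e-9)


class TestVariability:
    def test_chance_detection_maximizes_variance(self):
        trials = make_trials(["Hit", "Miss"] * 10, amplitudes=[6.0] * 20)
        prof = bh.tbt_variability(trials)
        assert prof.variances[0] == pytest.approx(0.25)

    def test_consistent_detection_zeroes_variance(self):
        trials = make_trials(["Hit"] * 10, amplitudes=[6.0] * 10)
        prof = bh.tbt_variability(trials)
        assert prof.variances[0] == pytest.approx(0.0)

    def test_matches_brute_force_sample_variance(self):
        rng = np.random.default_rng(3)
        cfg = SimConfig(n_trials=300)
        trials = simulate_behavior(generate_trial_sequence(cfg, rng), wt_mouse(), rng)
        prof = bh.tbt_variability(trials)
        for amp, var in zip(prof.amplitudes_um, prof.variances):
            go = trials[(trials.trial_type == "go") & ~trials.timeout
                        & (trials.amplitude_um == amp)]
            ind = (go.outcome == "Hit").to_numpy(dtype=float)
            assert var == pytest.approx(ind.var(ddof=0), rel=1e-12)

    def test_variance_bound(self):
        rng = np.random.default_rng(4)
        cfg = SimConfig(n_trials=300)
        trials = simulate_behavior(generate_trial_sequence(cfg, rng), wt_mouse(), rng)
        prof = bh.tbt_variability(trials, threshold_um=6.0)
        assert (prof.variances <= 0.25 + 1e-12).all()
        assert prof.triplet_amplitudes is not None
        assert list(prof.triplet_amplitudes) == [4.0, 6.0, 8.0]


class TestQCAndLearning:
    @pytest.mark.parametrize("n_fa,expected", [(0, True), (7, True), (8, False)])
    def test_qc_boundary_strict(self, n_fa, expected):
        # 20 No-Go trials: 8 FAs = 40% -> excluded (strict inequality).
        trials = make_trials(["Hit"] * 30 + ["FA"] * n_fa + ["CR"] * (20 - n_fa))
        assert bh.session_qc(trials) is expected

    def test_learning_pass_and_fail(self):
        daily = pd.DataFrame({"hit_rate": [0.85] * 3, "fa_rate": [0.2] * 3})
        out = bh.learning_criterion(daily, "training")
        assert bool(out["pass"].iloc[-1])
        daily = pd.DataFrame({"hit_rate": [0.85] * 3, "fa_rate": [0.35] * 3})
        out = bh.learning_criterion(daily, "training")
        assert not bool(out["pass"].iloc[-1])

    def test_learning_first_pass_day_matches_rolling_scan(self):
        rng = np.random.default_rng(5)
        hit = np.clip(np.linspace(0.4, 0.95, 12) + rng.normal(0, 0.03, 12), 0, 1)
        fa = np.clip(np.linspace(0.6, 0.1, 12) + rng.normal(0, 0.03, 12), 0, 1)
        daily = pd.DataFrame({"hit_rate": hit, "fa_rate": fa})
        out = bh.learning_criterion(daily, "training")
        # independent rolling-window scan
        first = None
        for i in range(2, 12):
            if hit[i - 2:i + 1].mean() >= 0.80 and fa[i - 2:i + 1].mean() < 0.30:
                first = i
                break
        got = out.index[out["pass"].fillna(False)].min()
        assert got == first

    def test_too_few_days_flagged(self):
        daily = pd.DataFrame({"hit_rate": [0.9, 0.9], "fa_rate": [0.1, 0.1]})
        out = bh.learning_criterion(daily, "training")
        assert out.attrs["insufficient_data"]


class TestSubgroups:
    def test_separated_groups_recovered(self):
        rng = np.random.default_rng(6)
        hi = np.clip(rng.normal(0.85, 0.03, size=(6, 6)), 0, 1)
        lo = np.clip(rng.normal(0.45, 0.03, size=(6, 6)), 0, 1)
        X = np.vstack([hi, lo])
        res = bh.cluster_subgroups(X, seed=0)
        assert (res.labels[:6] == 0).all()
        assert (res.labels[6:] == 1).all()
        assert (res.names[6:] == "hyposensitive-like").all()

    def test_identical_rows_flagged_degenerate(self):
        X = np.full((4, 6), 0.7)
        res = bh.cluster_subgroups(X, seed=0)
        assert res.degenerate

    def test_partition_invariant_to_seed(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0.8, 0.05, (5, 6)), rng.normal(0.3, 0.05, (5, 6))])
        a = bh.cluster_subgroups(X, seed=0).labels
        b = bh.cluster_subgroups(X, seed=123).labels
        assert (a == b).all()

    def test_single_mouse_rejected(self):
        with pytest.raises(ValueError):
            bh.cluster_subgroups(np.ones((1, 6)))
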