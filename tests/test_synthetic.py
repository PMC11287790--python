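"""Generator contracts: SDT consistency, balance, determinism, staircase
convergence, pupil coupling, epoch morphology."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from metarousal import erp, pupil, sdt
from metarousal.synthetic import (
    EpochGenConfig,
    ObserverConfig,
    SessionConfig,
    StaircaseConfig,
    StudyConfig,
    make_study,
    simulate_behavior,
    simulate_epochs,
    simulate_pupil,
    simulate_session,
    simulate_staircase,
)


class TestBehavior:
    def test_accuracy_closed_form(self):
        obs = ObserverConfig(d_prime_true=2.0, criterion_true=0.0,
                             n_trials=100_000)
        tab = simulate_behavior(obs, SessionConfig(p_missed=0.0), seed=1)
        acc = (tab["stimulus"] == tab["response"]).mean()
        assert acc == pytest.approx(ndtr(1.0), abs=0.005)

    def test_zero_sensitivity_is_chance(self):
        obs = ObserverConfig(d_prime_true=0.0, criterion_true=0.4,
                             n_trials=50_000)
        tab = simulate_behavior(obs, SessionConfig(p_missed=0.0), seed=2)
        acc = (tab["stimulus"] == tab["response"]).mean()
        assert acc == pytest.approx(0.5, abs=0.01)

    def test_hit_fa_rates_converge(self):
        d, c = 1.2, 0.3
        obs = ObserverConfig(d_prime_true=d, criterion_true=c,
                             n_trials=100_000)
        tab = simulate_behavior(obs, SessionConfig(p_missed=0.0), seed=3)
        counts = sdt.tabulate_counts(tab).type1_table()
        for s, p_true in ((1, ndtr(d / 2 - c)), (0, ndtr(-d / 2 - c))):
            n = counts[s].sum()
            p_obs = counts[s, 1] / n
            se = np.sqrt(p_true * (1 - p_true) / n)
            assert abs(p_obs - p_true) < 3 * se

    def test_block_balance_exact(self):
        obs = ObserverConfig(n_trials=601)
        tab = simulate_behavior(obs, SessionConfig(), seed=4)
        for _, blk in tab.groupby("block"):
            frac = blk["stimulus"].eq("cw").mean()
            assert abs(frac - 0.5) <= 0.5 / len(blk) + 1e-12  # exact up to odd count

    def test_session_balance_exact_even(self):
        tab = simulate_behavior(ObserverConfig(n_trials=600),
                                SessionConfig(), seed=5)
        assert tab["stimulus"].eq("cw").sum() == 300

    def test_rts_within_window(self):
        tab = simulate_behavior(ObserverConfig(n_trials=20_000),
                                SessionConfig(), seed=6)
        rt = tab.loc[tab["response"] != "none", "rt_ms"]
        assert rt.between(100, 1400).all()

    def test_missed_trials_have_no_rt(self):
        tab = simulate_behavior(ObserverConfig(n_trials=20_000),
                                SessionConfig(p_missed=0.05), seed=7)
        missed = tab["response"].eq("none")
        assert missed.mean() == pytest.approx(0.05, abs=0.01)
        assert tab.loc[missed, "rt_ms"].isna().all()
        assert tab.loc[missed, "confidence"].eq("none").all()

    def test_nonfinite_config_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ObserverConfig(d_prime_true=np.nan)
        with pytest.raises(ValueError):
            ObserverConfig(p_cw=1.5)


class TestPupil:
    def test_block_mean_zero(self):
        tab = simulate_behavior(ObserverConfig(n_trials=400), SessionConfig(), 8)
        out = simulate_pupil(tab, SessionConfig(), seed=9)
        for _, blk in out.groupby("block"):
            assert blk["pupil_baseline_pct"].mean() == pytest.approx(0.0, abs=5e-3)

    def test_latent_bins_equally_populated(self):
        tab = simulate_behavior(ObserverConfig(n_trials=500), SessionConfig(), 8)
        out = simulate_pupil(tab, SessionConfig(), seed=9)
        for _, blk in out.groupby("block"):
            counts = blk["pupil_bin_true"].value_counts()
            assert counts.max() - counts.min() <= 1

    def test_uncoupled_dprime_flat(self):
        obs = ObserverConfig(n_trials=50_000)
        tab = simulate_session(obs, SessionConfig(p_missed=0.0), seed=10)
        tab["subject"], tab["session"] = 0, 1
        binned = pupil.assign_bins(tab)
        table = pupil.per_bin_behavior(binned)
        assert table["d_prime"].max() - table["d_prime"].min() < 0.15

    def test_coupled_dprime_inverted_u(self):
        """a1 > 0, a2 < 0 recovered in sign by the per-bin SDT fits."""
        a1, a2 = 0.4, -0.06
        sess = SessionConfig(p_missed=0.0,
                             pupil_coupling=(1.2 - (3 * a1 + 9 * a2), a1, a2))
        obs = ObserverConfig(n_trials=100_000)
        tab = simulate_session(obs, sess, seed=11)
        tab["subject"], tab["session"] = 0, 1
        table = pupil.per_bin_behavior(pupil.assign_bins(tab))
        coefs = np.polyfit(table["bin"], table["d_prime"], 2)
        assert coefs[1] > 0 and coefs[0] < 0  # linear +, quadratic -


class TestStaircase:
    def test_weighted_up_down_tracks_75(self):
        accs = [simulate_staircase(StaircaseConfig(), s).accuracy_at_threshold
                for s in range(20)]
        assert np.mean(accs) == pytest.approx(0.75, abs=0.03)

    def test_equal_weights_track_50(self):
        # with the 0.5 lower asymptote, a 1:1 staircase has zero drift only
        # where the observer is at chance; start it there and it stays
        cfg = StaircaseConfig(weight_ratio=1.0, start_opacity=0.1,
                              psychometric=(0.5, 0.1))
        accs = [simulate_staircase(cfg, s).accuracy_at_threshold
                for s in range(20)]
        assert np.mean(accs) == pytest.approx(0.5, abs=0.04)

    def test_always_correct_monotone_decrease(self):
        # threshold far below zero: the observer is always correct
        cfg = StaircaseConfig(psychometric=(-10.0, 0.02), max_trials=500)
        run = simulate_staircase(cfg, 0)
        assert len(run.reversal_indices) == 0
        assert (np.diff(run.opacities) <= 0).all()
        assert run.opacities.min() >= 0.0

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError, match="weight_ratio"):
            StaircaseConfig(weight_ratio=0.0)


class TestEpochs:
    @staticmethod
    def _trials(n=40, seed=0, drug="PLC"):
        obs = ObserverConfig(n_trials=n)
        tab = simulate_behavior(obs, SessionConfig(drug_label=drug,
                                                   p_missed=0.0), seed)
        return tab

    def test_missing_roi_channel_named(self):
        with pytest.raises(ValueError, match="CPz"):
            EpochGenConfig(channel_names=["Fz", "F1", "F2", "CP1", "CP2", "Oz"])

    def test_zero_kappa_zero_metacognitive_effect(self):
        cfg = EpochGenConfig(sfreq=128, window=(-0.7, 1.5), noise_sd=0.0,
                             fp_gain={"base": -2.0, "kappa": 0.0, "drug_term": 0.0})
        tab = self._trials(n=200, seed=1)
        ep = simulate_epochs(tab, cfg, seed=2)
        rl = erp.response_lock(erp.baseline_correct(ep), (-0.6, 0.05))
        tc = erp.roi_average(rl, "FP")
        meta = rl.metadata
        amp = {}
        for a in ("correct", "error"):
            for c in ("high", "low"):
                m = (meta["accuracy"] == a) & (meta["confidence"] == c)
                amp[(a, c)] = float(erp.window_mean(
                    tc[m.to_numpy()].mean(axis=0), rl.times, (-0.3, 0.0)))
        me = erp.metacog_effect(amp[("correct", "high")], amp[("correct", "low")],
                                amp[("error", "low")], amp[("error", "high")])
        # finite-sample residual from centroparietal leakage into the
        # frontal ROI (cells differ in RT draws), not a kappa effect
        assert me == pytest.approx(0.0, abs=0.05)

    def test_positive_kappa_positive_effect_noiseless(self):
        cfg = EpochGenConfig(sfreq=128, window=(-0.7, 1.5), noise_sd=0.0,
                             fp_gain={"base": -2.0, "kappa": 1.0, "drug_term": 0.0})
        tab = self._trials(n=200, seed=1)
        ep = simulate_epochs(tab, cfg, seed=2)
        rl = erp.response_lock(erp.baseline_correct(ep), (-0.6, 0.05))
        tc = erp.roi_average(rl, "FP")
        meta = rl.metadata
        amp = {}
        for a in ("correct", "error"):
            for c in ("high", "low"):
                m = ((meta["accuracy"] == a) & (meta["confidence"] == c)).to_numpy()
                amp[(a, c)] = float(erp.window_mean(
                    tc[m].mean(axis=0), rl.times, (-0.1, 0.0)))
        me = erp.metacog_effect(amp[("correct", "high")], amp[("correct", "low")],
                                amp[("error", "low")], amp[("error", "high")])
        assert me > 1.0  # ~4 * kappa at the response, minus ramp-up dilution

    def test_accuracy_term_raises_correct_cpp(self):
        cfg = EpochGenConfig(sfreq=128, window=(-0.7, 1.5), noise_sd=0.0)
        tab = self._trials(n=300, seed=3)
        ep = simulate_epochs(tab, cfg, seed=4)
        rl = erp.response_lock(erp.baseline_correct(ep), (-0.6, 0.05))
        tc = erp.roi_average(rl, "CPP")
        correct = rl.metadata["accuracy"].eq("correct").to_numpy()
        diff = (erp.window_mean(tc[correct].mean(axis=0), rl.times, (-0.2, 0.0))
                - erp.window_mean(tc[~correct].mean(axis=0), rl.times, (-0.2, 0.0)))
        assert diff > 0

    def test_epoch_shapes_and_metadata(self):
        cfg = EpochGenConfig(sfreq=128, window=(-0.2, 0.8))
        tab = self._trials(n=25, seed=5)
        ep = simulate_epochs(tab, cfg, seed=6)
        assert ep.data.shape == (25, len(cfg.channel_names), len(ep.times))
        assert ep.lock == "stimulus"
        assert "accuracy" in ep.metadata


class TestStudyBundle:
    def test_config_echo_and_balance(self):
        cfg = StudyConfig(n_subjects=3, n_trials=200,
                          pupil_coupling_rel=None, hold_meta_d=False)
        bundle = make_study(cfg, seed=0)
        assert bundle.trials["subject"].nunique() == 3
        assert set(bundle.trials["drug"]) == {"PLC", "DNP", "ATX"}
        for (_, _), sess in bundle.trials.groupby(["subject", "session"]):
            assert len(sess) == 200
            assert sess["stimulus"].eq("cw").sum() == 100  # exactly 50% CW
        assert len(bundle.ground_truth) == 9

    def test_determinism_same_seed(self):
        cfg = StudyConfig(n_subjects=2, n_trials=100,
                          pupil_coupling_rel=None, hold_meta_d=False)
        a = make_study(cfg, seed=42)
        b = make_study(cfg, seed=42)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        ea = a.session_epochs(0, "PLC", EpochGenConfig(sfreq=128, window=(0, 0.5)))
        eb = b.session_epochs(0, "PLC", EpochGenConfig(sfreq=128, window=(0, 0.5)))
        np.testing.assert_array_equal(ea.data, eb.data)

    def test_different_seed_differs(self):
        cfg = StudyConfig(n_subjects=1, n_trials=100,
                          pupil_coupling_rel=None, hold_meta_d=False)
        a = make_study(cfg, seed=1)
        b = make_study(cfg, seed=2)
        assert not a.trials["rt_ms"].equals(b.trials["rt_ms"])

    def test_atx_raises_dprime_not_meta(self):
        """Ground truth: the catecholaminergic session gets higher d' with
        the generative meta-d' held at the no-drug level."""
        cfg = StudyConfig(n_subjects=2, n_trials=100)
        truth = make_study(cfg, seed=3).ground_truth
        for _, subj in truth.groupby("subject"):
            atx = subj[subj["drug"] == "ATX"].iloc[0]
            plc = subj[subj["drug"] == "PLC"].iloc[0]
            assert atx["d_prime_true"] > plc["d_prime_true"]
            assert atx["sigma_meta"] > plc["sigma_meta"]
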