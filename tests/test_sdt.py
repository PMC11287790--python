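"""Single-subject SDT: exclusion rules, counts, type-1 fits, meta-d' MLE,
efficiency scores."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from metarousal import sdt
from metarousal.synthetic import (
    ObserverConfig,
    SessionConfig,
    generative_meta_d,
    simulate_behavior,
)


def _trials(rts, responses=None):
    n = len(rts)
    return pd.DataFrame({
        "stimulus": ["cw"] * n,
        "response": responses or ["cw"] * n,
        "confidence": ["high"] * n,
        "rt_ms": rts,
        "fixation_lost": [0] * n,
    })


class TestExcludeTrials:
    def test_rt_window_rule(self):
        df = _trials([50.0, 500.0, 1500.0])
        out, rep = sdt.exclude_trials(df)
        assert len(out) == 1 and out["rt_ms"].iloc[0] == 500.0
        assert rep.n_rt_fast == 1 and rep.n_rt_slow == 1 and rep.n_retained == 1

    def test_identity_when_nothing_applies(self):
        df = _trials([200.0, 900.0, 1400.0])
        out, rep = sdt.exclude_trials(df)
        pd.testing.assert_frame_equal(out, df)
        assert rep.n_retained == 3 and rep.n_missed == 0

    def test_missed_and_fixation(self):
        df = _trials([np.nan, 500.0, 600.0], responses=["none", "cw", "cw"])
        df.loc[2, "fixation_lost"] = 1
        out, rep = sdt.exclude_trials(df)
        assert rep.n_missed == 1 and rep.n_fixation_lost == 1
        assert len(out) == 1

    def test_empty_result_errors(self):
        with pytest.raises(ValueError, match="no analyzable"):
            sdt.exclude_trials(_trials([50.0, 1500.0]))

    def test_report_matches_generator_bookkeeping(self):
        obs = ObserverConfig(n_trials=2000)
        tab = simulate_behavior(obs, SessionConfig(p_missed=0.02), seed=7)
        n_missed_true = int(tab["response"].eq("none").sum())
        out, rep = sdt.exclude_trials(tab)
        assert rep.n_missed == n_missed_true
        assert rep.n_rt_fast == rep.n_rt_slow == 0  # generator truncates RTs
        assert rep.n_retained == len(tab) - n_missed_true


class TestTabulate:
    def test_one_trial_per_type1_cell(self, tiny_trials):
        c = sdt.tabulate_counts(tiny_trials)
        assert c.counts[:, :, 1].sum() == 4  # all high confidence
        assert (c.counts[:, :, 1] == 1).all()
        assert (c.counts[:, :, 0] == 0).all()

    def test_row_order_invariance(self, tiny_trials):
        a = sdt.tabulate_counts(tiny_trials)
        b = sdt.tabulate_counts(tiny_trials.sample(frac=1, random_state=3))
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_unknown_label_rejected(self, tiny_trials):
        bad = tiny_trials.copy()
        bad.loc[0, "response"] = "up"
        with pytest.raises(ValueError, match="response"):
            sdt.tabulate_counts(bad)

    def test_cell_proportions_match_closed_form(self):
        d, c = 1.0, 0.2
        obs = ObserverConfig(d_prime_true=d, criterion_true=c,
                             sigma_meta=0.0, conf_criteria=(0.8, 0.8),
                             n_trials=40_000)
        tab = simulate_behavior(obs, SessionConfig(p_missed=0.0), seed=2)
        counts = sdt.tabulate_counts(tab).counts
        n_cw = counts[1].sum()
        # P(respond cw | cw) = Phi(d/2 - c)
        p = ndtr(d / 2 - c)
        se = np.sqrt(p * (1 - p) / n_cw)
        assert abs(counts[1, 1].sum() / n_cw - p) < 3 * se


class TestType1:
    @staticmethod
    def _counts_from_rates(h, fa, n=10_000):
        cells = np.zeros((2, 2, 2))
        cells[1, 1, 1] = round(h * n)
        cells[1, 0, 1] = n - round(h * n)
        cells[0, 1, 1] = round(fa * n)
        cells[0, 0, 1] = n - round(fa * n)
        return sdt.ConfusionCounts(cells)

    def test_chance_rates(self):
        t1 = sdt.type1_sdt(self._counts_from_rates(0.5, 0.5))
        assert t1.d_prime == pytest.approx(0.0, abs=1e-9)
        assert t1.criterion == pytest.approx(0.0, abs=1e-9)

    def test_unit_z_rates(self):
        t1 = sdt.type1_sdt(self._counts_from_rates(0.8413, 0.1587))
        assert t1.d_prime == pytest.approx(2.0, abs=0.01)
        assert t1.criterion == pytest.approx(0.0, abs=0.005)

    def test_half_count_correction_on_perfect_rates(self):
        t1 = sdt.type1_sdt(self._counts_from_rates(1.0, 0.0, n=100))
        assert np.isfinite(t1.d_prime)
        assert t1.hit_rate == pytest.approx(1 - 1 / 200)

    def test_degenerate_table_rejected(self):
        cells = np.zeros((2, 2, 2))
        cells[1, 1, 1] = 10
        with pytest.raises(ValueError, match="both stimulus"):
            sdt.type1_sdt(sdt.ConfusionCounts(cells))

    def test_recovery_large_n(self):
        obs = ObserverConfig(d_prime_true=1.5, criterion_true=0.2,
                             n_trials=100_000)
        tab = simulate_behavior(obs, SessionConfig(p_missed=0.0), seed=5)
        t1 = sdt.type1_sdt(sdt.tabulate_counts(tab))
        assert t1.d_prime == pytest.approx(1.5, abs=0.05)
        assert t1.criterion == pytest.approx(0.2, abs=0.05)


class TestMetaD:
    def test_ideal_observer_meta_d_equals_d(self, ideal_counts):
        t1 = sdt.type1_sdt(ideal_counts)
        fit = sdt.fit_meta_d(ideal_counts, t1)
        assert fit.converged
        assert fit.meta_d == pytest.approx(1.5, abs=0.1)

    def test_coin_flip_confidence_gives_zero(self):
        obs = ObserverConfig(d_prime_true=1.5, n_trials=100_000)
        tab = simulate_behavior(obs, SessionConfig(p_missed=0.0), seed=11)
        rng = np.random.default_rng(0)
        tab["confidence"] = np.where(rng.random(len(tab)) < 0.5, "high", "low")
        counts = sdt.tabulate_counts(tab)
        fit = sdt.fit_meta_d(counts)
        assert fit.meta_d == pytest.approx(0.0, abs=0.1)

    def test_meta_noise_shrinks_meta_d(self):
        obs = ObserverConfig(d_prime_true=1.5, sigma_meta=1.0, n_trials=50_000)
        tab = simulate_behavior(obs, SessionConfig(p_missed=0.0), seed=12)
        counts = sdt.tabulate_counts(tab)
        t1 = sdt.type1_sdt(counts)
        fit = sdt.fit_meta_d(counts, t1)
        assert 0.0 < fit.meta_d < t1.d_prime

    def test_zero_dprime_fallback_flagged(self):
        obs = ObserverConfig(d_prime_true=0.0, n_trials=20_000)
        tab = simulate_behavior(obs, SessionConfig(p_missed=0.0), seed=13)
        counts = sdt.tabulate_counts(tab)
        t1 = sdt.type1_sdt(counts)
        if abs(t1.d_prime) < 1e-3:  # sampling may push it just past epsilon
            fit = sdt.fit_meta_d(counts, t1)
            assert fit.anchoring_fallback
            assert fit.meta_c == pytest.approx(t1.criterion)

    def test_parameter_recovery_grid(self):
        """Median bias of d-hat < 0.05 and meta-d-hat < 0.15 at n = 10^4."""
        d_bias, m_bias = [], []
        seed = 0
        for d in (0.5, 1.0, 1.5, 2.0):
            for sm in (0.0, 0.5, 1.0):
                truth = generative_meta_d(d, sm)
                for _ in range(3):
                    seed += 1
                    obs = ObserverConfig(d_prime_true=d, sigma_meta=sm,
                                         n_trials=10_000)
                    tab = simulate_behavior(obs, SessionConfig(p_missed=0.0),
                                            seed=seed)
                    counts = sdt.tabulate_counts(tab)
                    t1 = sdt.type1_sdt(counts)
                    fit = sdt.fit_meta_d(counts, t1)
                    d_bias.append(t1.d_prime - d)
                    m_bias.append(fit.meta_d - truth)
        assert abs(np.median(d_bias)) < 0.05
        assert abs(np.median(m_bias)) < 0.15

    def test_fitted_probabilities_match_observed(self, ideal_counts):
        """At the MLE, predicted response-conditional high-confidence rates
        reproduce the observed proportions on large samples."""
        t1 = sdt.type1_sdt(ideal_counts)
        fit = sdt.fit_meta_d(ideal_counts, t1)
        counts = ideal_counts.counts
        # observed pooled P(high | response)
        for r in (0, 1):
            obs_p = counts[:, r, 1].sum() / counts[:, r, :].sum()
            # predicted, pooled over stimulus with generative weights
            mu = np.array([-fit.meta_d / 2, fit.meta_d / 2])
            if r == 1:
                den = ndtr(mu - fit.meta_c)
                num = ndtr(mu - fit.c2[1])
            else:
                den = ndtr(fit.meta_c - mu)
                num = ndtr(fit.c2[0] - mu)
            w = counts[:, r, :].sum(axis=1)
            pred = (num / den * w).sum() / w.sum()
            assert pred == pytest.approx(obs_p, abs=0.02)


class TestEfficiency:
    def test_group_mean_style_arithmetic(self):
        fit = sdt.MetaDFit(0.75, 0.0, (0, 0), 0.0, True, 1)
        t1 = sdt.TypeOneEstimates(1.46, 0.0, 0.8, 0.2)
        eff = sdt.efficiency(fit, t1)
        assert eff.m_diff == pytest.approx(-0.71)

    def test_identity_and_ratio(self):
        fit = sdt.MetaDFit(0.75, 0.0, (0, 0), 0.0, True, 1)
        t1 = sdt.TypeOneEstimates(1.5, 0.0, 0.8, 0.2)
        eff = sdt.efficiency(fit, t1)
        assert eff.m_diff == fit.meta_d - t1.d_prime  # exact
        assert eff.m_ratio == pytest.approx(0.5)
        fit2 = sdt.MetaDFit(1.5, 0.0, (0, 0), 0.0, True, 1)
        eff2 = sdt.efficiency(fit2, t1)
        assert eff2.m_diff == 0.0 and eff2.m_ratio == 1.0

    def test_zero_dprime_flagged(self):
        fit = sdt.MetaDFit(0.5, 0.0, (0, 0), 0.0, True, 1)
        t1 = sdt.TypeOneEstimates(0.0, 0.0, 0.5, 0.5)
        eff = sdt.efficiency(fit, t1)
        assert not eff.m_ratio_defined and eff.m_ratio is None

    def test_negative_ratio_log_undefined(self):
        fit = sdt.MetaDFit(-0.3, 0.0, (0, 0), 0.0, True, 1)
        t1 = sdt.TypeOneEstimates(1.0, 0.0, 0.7, 0.3)
        eff = sdt.efficiency(fit, t1)
        assert eff.m_ratio == pytest.approx(-0.3)
        assert eff.log_m_ratio is None


class TestConfidenceRate:
    @pytest.mark.parametrize("conf,expected", [
        (["high"] * 4, 1.0), (["low"] * 4, 0.0), (["high", "low"] * 2, 0.5),
    ])
    def test_rates(self, tiny_trials, conf, expected):
        df = tiny_trials.copy()
        df["confidence"] = conf
        assert sdt.confidence_rate(df) == expected

    def test_zero_offset_criteria_always_high(self):
        obs = ObserverConfig(conf_criteria=(0.0, 0.0), sigma_meta=0.0,
                             n_trials=5000)
        tab = simulate_behavior(obs, SessionConfig(p_missed=0.0), seed=3)
        assert sdt.confidence_rate(tab) == pytest.approx(1.0)
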