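"""LDA, AUC, balancing, temporal generalization, and GAT cluster tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from metarousal import decoding, erp
from metarousal.synthetic import (
    EpochGenConfig,
    ObserverConfig,
    SessionConfig,
    simulate_behavior,
    simulate_epochs,
)


def _brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
        ([4, 3, 2, 1], [0, 0, 1, 1], 0.0),
        ([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], 0.75),
    ])
    def test_examples(self, scores, labels, expected):
        assert decoding.auc(scores, labels) == pytest.approx(expected)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=24),
           st.integers(0, 2**30))
    def test_matches_brute_force_and_sklearn(self, scores, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, len(scores))
        if labels.sum() in (0, len(labels)):
            labels[0] = 1 - labels[0]
        ours = decoding.auc(scores, labels)
        assert ours == pytest.approx(_brute_force_auc(scores, labels))
        assert ours == pytest.approx(roc_auc_score(labels, scores))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**30))
    def test_label_flip_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, 20)
        labels = rng.integers(0, 2, 20)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        assert decoding.auc(scores, labels) == pytest.approx(
            1.0 - decoding.auc(scores, 1 - labels))

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="single class"):
            decoding.auc([1.0, 2.0], [1, 1])


class TestLda:
    def test_full_shrinkage_is_mean_difference(self, rng):
        x = rng.normal(0, 1, (60, 5))
        y = rng.integers(0, 2, 60)
        m = decoding.fit_lda(x, y, shrinkage=1.0)
        md = x[y == 1].mean(axis=0) - x[y == 0].mean(axis=0)
        ratio = m.weights / md
        assert np.allclose(ratio, ratio[0])

    def test_separable_toy_signs(self):
        x = np.array([[0, 0.0], [0, 1], [3, 0], [3, 1]])
        y = np.array([0, 0, 1, 1])
        m = decoding.fit_lda(x, y, shrinkage=0.5)
        dv = decoding.decision_values(m, x)
        assert (np.sign(dv) == np.array([-1, -1, 1, 1])).all()

    def test_string_labels_class_order(self):
        x = np.array([[0.0], [0.1], [3.0], [3.1]])
        y = np.array(["ccw", "ccw", "cw", "cw"])
        m = decoding.fit_lda(x, y, shrinkage=0.5)
        assert decoding.decision_values(m, np.array([[5.0]]))[0] > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            decoding.fit_lda(np.ones((4, 2)), [1, 1, 1, 1])


class TestBalance:
    def test_already_balanced_identity_size(self):
        labels = np.repeat(["a", "b", "c", "d"], 10)
        idx = decoding.balance_undersample(labels, seed=0)
        assert len(idx) == 40

    def test_undersamples_to_minimum(self):
        labels = np.array(["a"] * 10 + ["b"] * 6 + ["c"] * 8 + ["d"] * 6)
        idx = decoding.balance_undersample(labels, seed=0)
        assert len(idx) == 24
        counts = pd.Series(labels[idx]).value_counts()
        assert (counts == 6).all()

    def test_seed_changes_membership_not_counts(self):
        labels = np.array(["a"] * 10 + ["b"] * 6)
        a = decoding.balance_undersample(labels, seed=0)
        b = decoding.balance_undersample(labels, seed=1)
        assert len(a) == len(b) == 12
        assert not np.array_equal(a, b)

    def test_dataframe_strata(self):
        df = pd.DataFrame({"stimulus": ["cw", "cw", "ccw", "ccw", "ccw"],
                           "accuracy": ["correct"] * 5})
        idx = decoding.balance_undersample(df, seed=0)
        assert len(idx) == 4


def _pattern_epochs(n=120, snr=2.0, window=(0.1, 0.6), seed=0, sfreq=64,
                    span=(0.0, 0.8), follows="stimulus"):
    obs = ObserverConfig(n_trials=n)
    tab = simulate_behavior(obs, SessionConfig(p_missed=0.0), seed)
    cfg = EpochGenConfig(sfreq=sfreq, window=span, pattern_snr=snr,
                         pattern_window=window, noise_ar=0.8,
                         pattern_follows=follows,
                         cpp_gain={"base": 0, "accuracy_term": 0,
                                   "confidence_term": 0, "drug_term": 0},
                         fp_gain={"base": 0, "kappa": 0, "drug_term": 0})
    return simulate_epochs(tab, cfg, seed + 1)


class TestGat:
    def test_no_pattern_is_chance(self):
        ep = _pattern_epochs(n=100, snr=0.0)
        g = decoding.gat_within(ep, k=10, seed=0)
        assert abs(g.mean() - 0.5) < 0.03

    def test_static_pattern_generalizes_within_window(self):
        ep = _pattern_epochs(n=120, snr=2.0, window=(0.2, 0.7))
        g = decoding.gat_within(ep, k=6, seed=0)
        t = ep.times
        inside = np.ix_((t >= 0.25) & (t < 0.65), (t >= 0.25) & (t < 0.65))
        outside = np.ix_(t < 0.15, t < 0.15)
        assert g[inside].mean() > 0.75          # on and off diagonal
        assert abs(g[outside].mean() - 0.5) < 0.05

    def test_chained_pattern_confined_to_diagonal(self, rng):
        # a fresh random topography per timepoint: decodable only on-diagonal
        n, ch, t = 120, 12, 20
        y = rng.integers(0, 2, n)
        noise = rng.normal(0, 1, (n, ch, t))
        topo = rng.normal(0, 1, (t, ch))
        topo /= np.linalg.norm(topo, axis=1, keepdims=True)
        sig = 1.5 * (2 * y - 1)[:, None, None] * topo.T[None, :, :]
        g = decoding.gat_within(noise + sig, labels=y, k=6, seed=0)
        diag = np.diag(g).mean()
        off = g[np.abs(np.subtract.outer(range(t), range(t))) > 3].mean()
        assert diag > 0.75
        assert abs(off - 0.5) < 0.05

    def test_k_exceeding_class_count_rejected(self):
        ep = _pattern_epochs(n=16)
        with pytest.raises(ValueError, match="exceeds"):
            decoding.gat_within(ep, k=10, seed=0)


class TestGatCross:
    def test_delayed_pattern_offsets_from_diagonal(self):
        train = _pattern_epochs(n=100, window=(0.1, 0.3), seed=3)
        test = _pattern_epochs(n=100, window=(0.3, 0.5), seed=4)
        mats = decoding.gat_cross(train, test, seed=0)
        g = mats["all"]
        t = train.times
        tr = (t >= 0.12) & (t < 0.28)
        te_hit = (t >= 0.32) & (t < 0.48)
        te_miss = (t >= 0.1) & (t < 0.26)
        assert g[np.ix_(tr, te_hit)].mean() > 0.7
        assert abs(g[np.ix_(tr, te_miss)].mean() - 0.5) < 0.06

    def test_error_trials_below_chance_with_response_pattern(self):
        train = _pattern_epochs(n=120, seed=5)
        test = _pattern_epochs(n=200, seed=6, follows="response")
        test.metadata["accuracy"] = np.where(
            test.metadata["response"] == test.metadata["stimulus"],
            "correct", "error")
        mats = decoding.gat_cross(
            train, test,
            subconditions=[{"accuracy": "correct"}, {"accuracy": "error"}],
            seed=0)
        t = train.times
        sel = np.ix_((t >= 0.15) & (t < 0.55), (t >= 0.15) & (t < 0.55))
        assert mats[("correct",)][sel].mean() > 0.6
        assert mats[("error",)][sel].mean() < 0.4

    def test_channel_mismatch_rejected(self):
        train = _pattern_epochs(n=40)
        test = _pattern_epochs(n=40)
        test.channels = list(reversed(test.channels))
        with pytest.raises(ValueError, match="channel layout"):
            decoding.gat_cross(train, test)


class TestActivationPattern:
    def test_identity_covariance_proportional_to_weights(self, rng):
        x = rng.normal(0, 1, (5000, 4))
        m = decoding.fit_lda(x, rng.integers(0, 2, 5000), shrinkage=0.5)
        pat = decoding.activation_pattern(m, x)
        cos = pat @ m.weights / (np.linalg.norm(pat) * np.linalg.norm(m.weights))
        assert cos > 0.99  # spherical data: pattern parallel to weights

    def test_recovers_injected_topography(self):
        ep = _pattern_epochs(n=400, snr=3.0, window=(0.1, 0.7), seed=8)
        t_idx = int(np.argmin(np.abs(ep.times - 0.4)))
        x = ep.data[:, :, t_idx]
        y = ep.metadata["stimulus"].to_numpy()
        m = decoding.fit_lda(x, y)
        pat = decoding.activation_pattern(m, x)
        # reconstruct the generator's fixed topography
        cfg = EpochGenConfig()
        from metarousal._montage import channel_positions
        pos = channel_positions(cfg.channel_names)
        prng = np.random.default_rng(cfg.pattern_seed)
        true = prng.standard_normal(len(pos)) * np.exp(
            -((pos[:, 1] + 0.7) / 0.45) ** 2)
        true /= np.linalg.norm(true)
        r = np.corrcoef(pat, true)[0, 1]
        assert abs(r) > 0.9

    def test_scaling_linearity(self, rng):
        x = rng.normal(0, 1, (200, 4))
        m = decoding.fit_lda(x, rng.integers(0, 2, 200), shrinkage=0.5)
        a = decoding.activation_pattern(m, x)
        b = decoding.activation_pattern(m, 3.0 * x)
        np.testing.assert_allclose(b, 9.0 * a, rtol=1e-10)


class TestGatClusters:
    def test_injected_block_detected(self, rng):
        mats = 0.5 + rng.normal(0, 0.02, (12, 20, 20))
        mats[:, 5:12, 5:12] += 0.08
        res = decoding.cluster_test_gat(mats, n_perm=255, seed=0)
        sig = res.significant()
        assert sig
        mask = res.mask()
        assert mask[5:12, 5:12].mean() > 0.8

    def test_constant_chance_input_degenerate(self):
        mats = np.full((6, 8, 8), 0.5)
        res = decoding.cluster_test_gat(mats, n_perm=100, seed=0)
        assert res.degenerate and res.clusters == []

    def test_extract_cluster_auc_single_point(self):
        mask = np.zeros((4, 4), bool)
        mask[2, 3] = True
        gat = [{"all": np.arange(16.0).reshape(4, 4)}]
        table = decoding.extract_cluster_auc(gat, mask)
        assert table["auc"].iloc[0] == 11.0

    def test_extract_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            decoding.extract_cluster_auc([], np.zeros((3, 3), bool))
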