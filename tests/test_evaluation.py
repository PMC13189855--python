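import numpy as np
import pytest

from rnpqa.evaluation import (
    ZScorePanel,
    feature_sensitivity,
    per_interface_eval,
    quantile_scores,
    ranking_loss,
    selection_metrics,
    topk_sum_z,
    z_casp16,
    zscores,
)


class TestRankingLoss:
    def test_perfect_predictor_zero(self):
        assert ranking_loss([0.2, 0.9, 0.5], [0.1, 0.8, 0.3]) == 0.0

    def test_direct_substitution(self):
        assert ranking_loss([0.9, 0.5], [0.1, 0.9]) == pytest.approx(0.4)

    def test_constant_truth_always_zero(self):
        assert ranking_loss([0.5, 0.5, 0.5], [1, 2, 3]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ranking_loss([], [])


class TestZScores:
    def test_no_outliers_single_pass(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        z = zscores(v)
        np.testing.assert_allclose(z, (v - v.mean()) / v.std())

    def test_outlier_exclusion_shifts_reference(self):
        # 19 values near 1.0 plus one extreme low outlier
        v = np.concatenate([np.linspace(0.9, 1.1, 19), [-10.0]])
        z1 = (v - v.mean()) / v.std()
        assert z1[-1] < -2  # it is an outlier on the first pass
        z = zscores(v)
        ref = v[:19]
        np.testing.assert_allclose(z[:19], (ref - ref.mean()) / ref.std(), atol=1e-12)
        # the good models' final Z mean is ~0, not dragged up by the outlier
        assert abs(z[:19].mean()) < 1e-9

    def test_constant_values_all_zero(self):
        assert (zscores([3.0, 3.0, 3.0]) == 0).all()


class TestZCasp16:
    def _panel(self, fold, iface):
        n = np.full(4, float(fold))
        m = np.full(4, float(iface))
        return ZScorePanel(z_tm=n, z_gdt_ts=n, z_lddt=n, z_ics=m, z_ips=m, z_ilddt=m)

    def test_unit_everything_gives_one(self):
        assert z_casp16(self._panel(1, 1)) == pytest.approx(1.0)

    def test_fold_block_weight(self):
        assert z_casp16(self._panel(1, 0)) == pytest.approx(0.3)

    def test_interface_block_weight(self):
        assert z_casp16(self._panel(0, 1)) == pytest.approx(0.7)

    def test_linear_in_components(self):
        rng = np.random.default_rng(0)
        a = ZScorePanel(*[rng.normal(size=5) for _ in range(6)])
        b = ZScorePanel(*[rng.normal(size=5) for _ in range(6)])
        s = ZScorePanel(*[getattr(a, f) + getattr(b, f) for f in
                          ("z_tm", "z_gdt_ts", "z_lddt", "z_ics", "z_ips", "z_ilddt")])
        np.testing.assert_allclose(z_casp16(s), z_casp16(a) + z_casp16(b), atol=1e-12)

    def test_missing_component_rejected(self):
        p = self._panel(1, 1)
        p.z_ips = None
        with pytest.raises(ValueError):
            z_casp16(p)


class TestTopkSumZ:
    def test_all_negative_gives_zero(self):
        assert topk_sum_z([3, 2, 1], [-1, -2, -3], k=2) == 0.0

    def test_clip_and_sum(self):
        mh = [0.9, 0.8, 0.7, 0.1]
        z = [1.2, -0.5, 0.3, 9.9]
        assert topk_sum_z(mh, z, k=3) == pytest.approx(1.5)

    def test_k_equals_n(self):
        z = [1.0, -1.0, 2.0]
        assert topk_sum_z([1, 2, 3], z, k=3) == pytest.approx(3.0)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            topk_sum_z([1.0], [1.0], k=2)


class TestQuantiles:
    def test_best_model_scores_100(self):
        q = quantile_scores([0.5, 1.0, 2.0, 4.0])
        assert q[0] == pytest.approx(100.0)

    def test_worst_model_scores_100_over_n(self):
        q = quantile_scores([1.0, 2.0, 3.0, 4.0, 5.0])
        assert q[-1] == pytest.approx(100.0 / 5)

    def test_ties_all_score_100(self):
        assert (quantile_scores([2.0, 2.0, 2.0]) == 100.0).all()

    def test_antitone_in_irmsd(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 20, size=50)
        q = quantile_scores(x)
        order = np.argsort(x)
        assert (np.diff(q[order]) <= 0).all()
        assert q.max() == pytest.approx(100.0)


class TestSelectionMetrics:
    def test_perfect_predictor_best_quantile_100(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, size=200)
        succ, recall, avg_q, best_q = selection_metrics(-x, x, k=5)
        assert best_q == pytest.approx(100.0)
        assert succ == 1.0

    def test_k_equals_n_always_succeeds(self):
        x = np.linspace(1, 5, 120)
        succ, recall, *_ = selection_metrics(np.zeros(120), x, k=120)
        assert succ == 1.0
        assert recall == pytest.approx(100.0)

    def test_invariant_under_monotone_transform_of_predictions(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, size=150)
        mh = rng.normal(size=150)
        a = selection_metrics(mh, x, k=5)
        b = selection_metrics(np.exp(2 * mh), x, k=5)
        assert a == b

    def test_random_predictor_recall_matches_simulation(self):
        """Monte-Carlo oracle: for a random predictor the expected recall is
        100*k/N (each true-top model lands in the top k with prob k/N)."""
        rng = np.random.default_rng(4)
        n, k, trials = 1000, 5, 200
        x = rng.uniform(0, 30, size=n)  # fixed ensemble, distinct iRMSDs
        recalls = []
        for _ in range(trials):
            mh = rng.normal(size=n)
            _, recall, *_ = selection_metrics(mh, x, k=k)
            recalls.append(recall)
        expected = 100.0 * k / n
        se = np.std(recalls) / np.sqrt(trials)
        assert abs(np.mean(recalls) - expected) < 4 * se + 1e-9


class TestPerInterfaceEval:
    def test_perfect_entries(self):
        entries = [
            ("t1", ("A", "R"), [0.1, 0.5, 0.9], [0.1, 0.5, 0.9], 1.0),
            ("t2", ("B", "R"), [0.3, 0.2, 0.8], [0.3, 0.2, 0.8], 1.0),
        ]
        sp, pe, rl = per_interface_eval(entries)
        assert sp == pytest.approx(1.0) and pe == pytest.approx(1.0) and rl == 0.0

    def test_negative_correlation_clipped_to_zero(self):
        entries = [("t1", ("A", "R"), [0.9, 0.5, 0.1], [0.1, 0.5, 0.9], 1.0)]
        sp, pe, _ = per_interface_eval(entries)
        assert sp == 0.0 and pe == 0.0

    def test_equal_target_weighting(self):
        # target t1 has two interfaces (each perfect), t2 one (anticorrelated)
        perfect = ([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        anti = ([0.9, 0.5, 0.1], [0.1, 0.5, 0.9])
        entries = [
            ("t1", ("A", "R"), *perfect, 1.0),
            ("t1", ("B", "R"), *perfect, 1.0),
            ("t2", ("A", "R"), *anti, 1.0),
        ]
        sp, _, _ = per_interface_eval(entries)
        # equal target representation: t1 contributes 1 (two halves), t2 contributes 0
        assert sp == pytest.approx(0.5)

    def test_coverage_filter(self):
        entries = [("t1", ("A", "R"), [0.1, 0.9], [0.1, 0.9], 0.5)]
        with pytest.raises(ValueError):
            per_interface_eval(entries, coverage_min=0.6)


class TestFeatureSensitivity:
    def test_zeroing_an_already_zero_channel_is_null(self, toy_graph, model_params, model_config):
        from rnpqa.features import DEFAULT_LAYOUT

        ch = DEFAULT_LAYOUT.node_slice("pred_rsa").start  # provider-less, all zero
        s = feature_sensitivity(model_params, model_config, [toy_graph], ch, kind="node")
        assert s == 0.0

    def test_informative_channel_moves_outputs(self, toy_graph, model_params, model_config):
        from rnpqa.features import DEFAULT_LAYOUT

        ch = DEFAULT_LAYOUT.node_slice("com_geometry").start
        s = feature_sensitivity(model_params, model_config, [toy_graph], ch, kind="node")
        assert s > 0.0

    def test_unknown_channel_rejected(self, toy_graph, model_params, model_config):
        with pytest.raises(ValueError):
            feature_sensitivity(model_params, model_config, [toy_graph], 99, kind="node")
        with pytest.raises(ValueError):
            feature_sensitivity(model_params, model_config, [toy_graph], 0, kind="bogus")
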