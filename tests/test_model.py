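"""Training harness: metrics, sampling, folds, pair features, end-to-end fits."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from muscle_mda.features import AttributeMatrix, SimilarityMatrix
from muscle_mda.model import (
    AssociationDataset,
    MuscleModel,
    TrainConfig,
    build_pair_features,
    compute_metrics,
    kfold_split,
    make_dataset,
    run_cv,
    sample_negatives,
)
from muscle_mda.gat import GatConfig
from muscle_mda.synthetic import SyntheticConfig, generate_world


class TestComputeMetrics:
    def test_perfect_separation(self):
        rep = compute_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert rep.auc == 1.0
        assert rep.aupr == 1.0
        assert rep.accuracy == 1.0
        assert rep.mcc == 1.0

    def test_confusion_matrix_example(self):
        # TP=9 FN=1 TN=9 FP=1
        labels = [1] * 10 + [0] * 10
        scores = [0.9] * 9 + [0.1] + [0.1] * 9 + [0.9]
        rep = compute_metrics(labels, scores)
        assert rep.accuracy == pytest.approx(0.9)
        assert rep.sensitivity == pytest.approx(0.9)
        assert rep.specificity == pytest.approx(0.9)
        assert rep.precision == pytest.approx(0.9)
        assert rep.mcc == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(0.9)

    def test_auc_equals_rank_sum_with_ties(self, rng):
        # labels scored by their own values: midranks make AUC the
        # Mann-Whitney U divided by n_pos * n_neg
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = labels.astype(float)  # maximal ties
        from scipy.stats import rankdata
        ranks = rankdata(scores)
        n_pos = labels.sum()
        n_neg = len(labels) - n_pos
        u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
        rep = compute_metrics(labels, scores)
        assert rep.auc == pytest.approx(u / (n_pos * n_neg))

    def test_matches_sklearn_reference(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # provoke ties
            rep = compute_metrics(labels, scores)
            assert rep.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)
            assert rep.aupr == pytest.approx(
                average_precision_score(labels, scores), abs=1e-10
            )

    def test_one_class_input_rejected(self):
        with pytest.raises(ValueError, match="positive and one negative"):
            compute_metrics([1, 1], [0.5, 0.6])

    def test_mcc_bounds_and_accuracy_identity(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 30))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.random(n)
            rep = compute_metrics(labels, scores)
            assert -1.0 <= rep.mcc <= 1.0
            pred = scores >= 0.5
            assert rep.accuracy == (pred == labels).sum() / n


class TestSampleNegatives:
    def test_forced_single_choice(self):
        positives = {("m1", "d1"), ("m1", "d2"), ("m2", "d1")}
        got = sample_negatives(positives, ["m1", "m2"], ["d1", "d2"], 1, seed=0)
        assert got == [("m2", "d2")]

    def test_deterministic_under_seed(self):
        positives = {("m0", "d0")}
        mirnas = [f"m{i}" for i in range(10)]
        diseases = [f"d{i}" for i in range(10)]
        a = sample_negatives(positives, mirnas, diseases, 20, seed=5)
        b = sample_negatives(positives, mirnas, diseases, 20, seed=5)
        assert a == b
        assert not set(a) & positives

    def test_equal_count_balance(self):
        positives = {(f"m{i}", "d0") for i in range(4)}
        got = sample_negatives(positives, [f"m{i}" for i in range(4)],
                               ["d0", "d1", "d2"], len(positives), seed=1)
        assert len(got) == len(positives)

    def test_insufficient_universe_rejected(self):
        with pytest.raises(ValueError, match="cannot sample"):
            sample_negatives({("m1", "d1")}, ["m1"], ["d1"], 1, seed=0)


class TestKfoldSplit:
    def test_equal_fold_sizes(self):
        labels = np.array([0, 1] * 5)
        assign = kfold_split(labels, 5, seed=0)
        assert sorted(np.bincount(assign)) == [2, 2, 2, 2, 2]

    def test_partition_property(self, rng):
        labels = rng.integers(0, 2, 37)
        labels[:2] = [0, 1]
        assign = kfold_split(labels, 5, seed=3)
        assert set(assign) == set(range(5))
        assert len(assign) == 37  # every pair in exactly one test fold

    def test_stratification(self, rng):
        labels = np.r_[np.ones(50, dtype=int), np.zeros(50, dtype=int)]
        assign = kfold_split(labels, 5, seed=1)
        for f in range(5):
            frac = labels[assign == f].mean()
            assert abs(frac - 0.5) <= 1 / 20


class TestBuildPairFeatures:
    @pytest.fixture
    def toy_blocks(self, rng):
        mir = ("m0", "m1")
        dis = tuple(f"d{i}" for i in range(4))
        dm = AttributeMatrix("DM", mir, rng.standard_normal((2, 66)))
        dd = SimilarityMatrix("DD", dis, np.eye(4))
        fused = rng.standard_normal((6, 8))  # 2 miRNAs + 4 diseases, d = 8
        return fused, dm, dd

    def test_width_is_sum_of_blocks(self, toy_blocks):
        fused, dm, dd = toy_blocks
        vec = build_pair_features(fused, dm, dd, ("m0", "d2"))
        assert vec.shape == (8 + 66 + 8 + 4,)

    def test_zero_fused_leaves_attribute_blocks(self, toy_blocks):
        _, dm, dd = toy_blocks
        vec = build_pair_features(np.zeros((6, 8)), dm, dd, ("m1", "d0"))
        np.testing.assert_array_equal(vec[:8], 0.0)
        np.testing.assert_array_equal(vec[8:74], dm.values[1])
        np.testing.assert_array_equal(vec[74:82], 0.0)
        np.testing.assert_array_equal(vec[82:], dd.values[0])

    def test_attr_only_ablation_drops_topology(self, toy_blocks):
        fused, dm, dd = toy_blocks
        vec = build_pair_features(fused, dm, dd, ("m0", "d1"),
                                  feature_set=frozenset({"attr"}))
        assert vec.shape == (66 + 4,)

    def test_unknown_id_rejected(self, toy_blocks):
        fused, dm, dd = toy_blocks
        with pytest.raises(KeyError, match="m9"):
            build_pair_features(fused, dm, dd, ("m9", "d0"))


@pytest.fixture(scope="module")
def tiny_world():
    cfg = SyntheticConfig(n_mirna=24, n_disease=18, n_drug=12, n_mrna=20,
                          n_lncrna=14, edge_density=0.15, seed=11)
    return generate_world(cfg)


@pytest.fixture(scope="module")
def tiny_fit(tiny_world):
    inputs = tiny_world.model_inputs()
    ds = tiny_world.dataset(folds=5)
    tc = TrainConfig(epochs=8, lr=5e-3, seed=2,
                     gat=GatConfig(feature_dim=12, hidden=6, heads=2,
                                   layers=1, embed_dim=8))
    model = MuscleModel(inputs, ds, tc)
    train_idx = np.nonzero(ds.fold_assignments != 0)[0]
    return model, model.fit(train_idx), ds


class TestFit:
    def test_loss_trace_decreases(self, tiny_fit):
        _, res, _ = tiny_fit
        assert len(res.loss_trace) == 8
        assert res.loss_trace[-1] < res.loss_trace[0]

    def test_predict_scores_in_unit_interval(self, tiny_fit):
        _, res, ds = tiny_fit
        scores = res.predict(list(ds.pairs[:10]))
        assert scores.shape == (10,)
        assert ((scores > 0) & (scores < 1)).all()

    def test_summary_mentions_metrics(self, tiny_fit):
        _, res, _ = tiny_fit
        text = res.summary()
        for token in ("auc", "mcc", "fusion strategy", "msaff"):
            assert token in text

    def test_seeded_determinism(self, tiny_world):
        inputs = tiny_world.model_inputs()
        ds = tiny_world.dataset(folds=5)
        tc = TrainConfig(epochs=4, seed=9,
                         gat=GatConfig(feature_dim=8, hidden=4, heads=1,
                                       layers=1, embed_dim=4))
        traces = []
        for _ in range(2):
            res = MuscleModel(inputs, ds, tc).fit()
            traces.append(res.loss_trace)
        np.testing.assert_array_equal(traces[0], traces[1])

    def test_gip_uses_training_positives_only(self, tiny_world):
        # masking out one training positive changes KM; masking a test
        # positive must not
        inputs = tiny_world.model_inputs()
        ds = tiny_world.dataset(folds=5)
        model = MuscleModel(inputs, ds, TrainConfig())
        assign = ds.fold_assignments
        train_idx = np.nonzero(assign != 0)[0]
        pairs = [ds.pairs[i] for i in train_idx]
        labels = ds.labels[train_idx]
        dm_a, _ = model._fold_attributes(pairs, labels)
        test_idx = np.nonzero((assign == 0) & (ds.labels == 1))[0]
        extra = [ds.pairs[i] for i in train_idx] + [ds.pairs[test_idx[0]]]
        dm_b, _ = model._fold_attributes(extra, np.r_[labels, 0])  # label 0: ignored
        np.testing.assert_array_equal(dm_a.values, dm_b.values)


class TestRunCv:
    def test_fold_reports_and_disjoint_tests(self, tiny_world):
        inputs = tiny_world.model_inputs()
        ds = tiny_world.dataset(folds=5)
        tc = TrainConfig(epochs=4, seed=3, feature_set=frozenset({"attr"}))
        results = run_cv(inputs, ds, tc)
        assert len(results.reports) == 5
        assert "Average" in results.summary()
        # disjointness is guaranteed by the fold assignment
        assign = ds.fold_assignments
        for f in range(5):
            assert (assign == f).sum() > 0

    def test_results_tsv_roundtrip(self, tiny_world, tmp_path):
        inputs = tiny_world.model_inputs()
        ds = tiny_world.dataset(folds=5)
        tc = TrainConfig(epochs=3, seed=3, feature_set=frozenset({"attr"}))
        results = run_cv(inputs, ds, tc)
        out = tmp_path / "cv.tsv"
        results.to_tsv(out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 1 + 5 + 2  # header, folds, mean, sd
        assert lines[0].startswith("fold\tauc")


class TestModes:
    def test_early_stopping_on_embedding_drift(self, tiny_world):
        inputs = tiny_world.model_inputs()
        ds = tiny_world.dataset(folds=5)
        tc = TrainConfig(epochs=50, seed=2,
                         gat=GatConfig(feature_dim=8, hidden=4, heads=1,
                                       layers=1, embed_dim=4,
                                       early_stop_tol=1e6))
        res = MuscleModel(inputs, ds, tc).fit()
        # an absurdly loose tolerance trips the drift criterion immediately
        assert len(res.loss_trace) < 50

    def test_single_hetero_graph_mode(self, tiny_world):
        inputs = tiny_world.model_inputs()
        ds = tiny_world.dataset(folds=5)
        tc = TrainConfig(epochs=4, seed=2, single_graph=True,
                         gat=GatConfig(feature_dim=8, hidden=4, heads=1,
                                       layers=1, embed_dim=4))
        model = MuscleModel(inputs, ds, tc)
        assert len(model._views) == 1
        assert model._views[0].view == "SHG"
        # one graph over all five entity classes
        n_expected = (24 + 18 + 12 + 20 + 14)
        assert model._views[0].n_nodes == n_expected
        res = model.fit(np.arange(40))
        assert res.fusion is None  # fusion module is bypassed for one view
        assert res.predict(list(ds.pairs[:5])).shape == (5,)

    def test_mean_auc_increases_with_planted_signal_strength(self):
        small = dict(n_mirna=40, n_disease=32, n_drug=20, n_mrna=30,
                     n_lncrna=25, edge_density=0.12)
        aucs = []
        for signal in (0.0, 1.5, 3.0):
            world = generate_world(SyntheticConfig(seed=17, signal=signal, **small))
            tc = TrainConfig(epochs=40, lr=5e-3, seed=17,
                             feature_set=frozenset({"attr"}))
            res = run_cv(world.model_inputs(), world.dataset(folds=5), tc)
            aucs.append(res.mean.auc)
        assert aucs[0] < aucs[1] < aucs[2]


class TestTrainConfigValidation:
    def test_folds_restricted(self):
        with pytest.raises(ValueError, match="folds"):
            TrainConfig(folds=7)

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            TrainConfig(feature_set=frozenset())

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            TrainConfig(feature_set=frozenset({"attr", "protein"}))
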