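"""Decoy generation, descriptor pruning, balancing, classifier training."""

import numpy as np
import pytest

from achescreen.chemclust import MoleculeRecord
from achescreen.mlscreen import (
    DescriptorTable,
    TrainedModel,
    balance_decoys_kmeans,
    compute_descriptors,
    evaluate_models,
    generate_decoys,
    load_model,
    prune_correlated,
    save_model,
    select_model,
    split_actives,
    train_models,
    _props,
)
from achescreen.scoring import MetricReport
from achescreen.synthdata import GeneratorConfig, gen_descriptor_blobs


def _separable_table(n=60, seed=0):
    rng = np.random.default_rng(seed)
    x = np.vstack([rng.normal(0, 1, (n // 2, 6)), rng.normal(4, 1, (n // 2, 6))])
    labels = ["decoy"] * (n // 2) + ["active"] * (n // 2)
    return DescriptorTable(
        mol_ids=[f"m{i}" for i in range(n)],
        descriptor_names=[f"d{i}" for i in range(6)],
        values=x,
        labels=labels,
    )


class TestSplit:
    def test_fifty_eight_actives_split_47_11(self):
        actives = [MoleculeRecord(f"m{i}", "C") for i in range(58)]
        split = split_actives(actives, seed=3)
        assert (len(split.train_actives), len(split.test_actives)) == (47, 11)

    def test_exact_fraction(self):
        actives = [MoleculeRecord(f"m{i}", "C") for i in range(10)]
        split = split_actives(actives, seed=0)
        assert (len(split.train_actives), len(split.test_actives)) == (8, 2)

    def test_deterministic_and_disjoint(self):
        actives = [MoleculeRecord(f"m{i}", "C") for i in range(20)]
        s1, s2 = split_actives(actives, seed=5), split_actives(actives, seed=5)
        ids = lambda lst: {m.mol_id for m in lst}
        assert ids(s1.test_actives) == ids(s2.test_actives)
        assert not ids(s1.test_actives) & ids(s1.train_actives)

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            split_actives([MoleculeRecord("m", "C")])


class TestGenerateDecoys:
    ACTIVE = MoleculeRecord("act", "CCCCc1ccc2c(c1)cccn2")

    def _pool(self):
        # carbazole-family molecules: similar size range, different scaffold
        pool = [
            MoleculeRecord(f"p{i}", "C" * i + "c1ccc2c(c1)[nH]c3ccccc23")
            for i in range(1, 12)
        ]
        # wildly property-mismatched entries that must never be returned
        pool.append(MoleculeRecord("big", "C" * 40 + "c1ccc2c(c1)[nH]c3ccccc23"))
        return pool

    def test_zero_actives_zero_decoys(self):
        decoys, shortfall = generate_decoys([], self._pool(), ratio=5)
        assert decoys == [] and shortfall == {}

    def test_returned_decoys_satisfy_constraints(self):
        decoys, _ = generate_decoys([self.ACTIVE], self._pool(), ratio=10)
        ap = _props(self.ACTIVE.structure)
        from achescreen.mlscreen import DEFAULT_PROPERTY_BINS
        for d in decoys:
            dp = _props(d.structure)
            for k, w in DEFAULT_PROPERTY_BINS.items():
                assert abs(dp[k] - ap[k]) <= w
        assert all(d.mol_id != "big" for d in decoys)

    def test_planted_matches_are_exactly_returned(self):
        decoys, shortfall = generate_decoys([self.ACTIVE], self._pool(), ratio=50)
        matched = set()
        ap = _props(self.ACTIVE.structure)
        from achescreen.mlscreen import DEFAULT_PROPERTY_BINS
        for p in self._pool():
            pp = _props(p.structure)
            if all(abs(pp[k] - ap[k]) <= w for k, w in DEFAULT_PROPERTY_BINS.items()):
                matched.add(p.mol_id)
        assert {d.mol_id for d in decoys} == matched
        assert shortfall["act"] == 50 - len(matched)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            generate_decoys([self.ACTIVE], [], ratio=5)


class TestPruneCorrelated:
    def test_duplicated_column_keeps_one(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 30)
        t = DescriptorTable(
            mol_ids=[f"m{i}" for i in range(30)],
            descriptor_names=["x", "x_copy"],
            values=np.column_stack([x, x]),
        )
        assert prune_correlated(t) == ["x"]

    def test_scaled_duplicate_and_independent(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 40)
        y = rng.uniform(0, 1, 40)
        t = DescriptorTable(
            mol_ids=[f"m{i}" for i in range(40)],
            descriptor_names=["x", "x2", "y"],
            values=np.column_stack([x, 2 * x, y]),
        )
        # x and 2x min-max scale identically -> variance tie -> column order
        assert prune_correlated(t) == ["x", "y"]

    def test_sub_threshold_pair_both_kept(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 200)
        y = 0.85 * x + np.sqrt(1 - 0.85**2) * rng.normal(0, 1, 200)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(r) < 0.9  # construction sanity
        t = DescriptorTable(
            mol_ids=[f"m{i}" for i in range(200)],
            descriptor_names=["x", "y"],
            values=np.column_stack([x, y]),
        )
        assert prune_correlated(t) == ["x", "y"]

    def test_no_retained_pair_violates_cut(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, (80, 3))
        noisy = base[:, [0, 0, 1, 1, 2]] + rng.normal(0, 0.05, (80, 5))
        t = DescriptorTable(
            mol_ids=[f"m{i}" for i in range(80)],
            descriptor_names=[f"d{i}" for i in range(5)],
            values=noisy,
        )
        kept = prune_correlated(t)
        idx = [t.descriptor_names.index(k) for k in kept]
        corr = np.corrcoef(t.values[:, idx], rowvar=False)
        off = corr[~np.eye(len(idx), dtype=bool)]
        assert (np.abs(off) < 0.9).all()

    def test_constant_column_dropped_with_warning(self):
        t = DescriptorTable(
            mol_ids=["a", "b", "c"],
            descriptor_names=["const", "x", "y"],
            values=np.array([[1.0, 0.0, 5.0], [1.0, 1.0, 3.0], [1.0, 2.0, 4.0]]),
        )
        with pytest.warns(UserWarning, match="constant"):
            kept = prune_correlated(t)
        assert "const" not in kept


class TestBalanceDecoys:
    def test_k_equals_n_returns_all(self):
        x, ids, _, _ = gen_descriptor_blobs(3, 2, 3, GeneratorConfig(seed=0))
        t = DescriptorTable(mol_ids=ids, descriptor_names=["a", "b", "c"], values=x)
        got = balance_decoys_kmeans(t, k=len(ids), seed=0)
        assert sorted(got) == sorted(ids)

    def test_two_planted_blobs(self):
        x, ids, labels, exemplars = gen_descriptor_blobs(15, 2, 4, GeneratorConfig(seed=4))
        t = DescriptorTable(mol_ids=ids, descriptor_names=[f"d{i}" for i in range(4)], values=x)
        got = balance_decoys_kmeans(t, k=2, seed=4)
        assert set(got) == set(exemplars)

    def test_output_size_equals_k(self):
        x, ids, _, _ = gen_descriptor_blobs(10, 4, 3, GeneratorConfig(seed=5))
        t = DescriptorTable(mol_ids=ids, descriptor_names=["a", "b", "c"], values=x)
        for k in (1, 3, 7):
            got = balance_decoys_kmeans(t, k=k, seed=5)
            assert len(got) == k == len(set(got))

    def test_k_too_large_rejected(self):
        x, ids, _, _ = gen_descriptor_blobs(2, 2, 2, GeneratorConfig(seed=6))
        t = DescriptorTable(mol_ids=ids, descriptor_names=["a", "b"], values=x)
        with pytest.raises(ValueError):
            balance_decoys_kmeans(t, k=5, seed=6)


class TestTrainEvaluate:
    def test_separable_set_all_algorithms_perfect(self):
        models = train_models(_separable_table(), seed=0)
        assert len(models) == 4
        for m in models:
            assert m.cv_roc_auc == pytest.approx(1.0)

    def test_same_seed_same_hyperparameters(self):
        t = _separable_table(seed=1)
        m1 = train_models(t, seed=7)
        m2 = train_models(t, seed=7)
        assert [m.hyperparameters for m in m1] == [m.hyperparameters for m in m2]

    def test_shuffled_labels_near_chance(self):
        t = _separable_table(n=60, seed=2)
        aucs = []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            shuffled = list(rng.permutation(t.labels))
            ts = DescriptorTable(
                mol_ids=t.mol_ids, descriptor_names=t.descriptor_names,
                values=t.values, labels=shuffled,
            )
            aucs.extend(m.cv_roc_auc for m in train_models(ts, seed=seed))
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_evaluation_matches_confusion_recomputation(self):
        t = _separable_table(seed=3)
        models = evaluate_models(train_models(t, seed=0), t)
        for m in models:
            scores = m.predict_scores(t)
            y = np.array([lab == "active" for lab in t.labels])
            pred = scores >= 0.5
            assert m.test_metrics.tp == int((pred & y).sum())
            assert m.test_metrics.tn == int((~pred & ~y).sum())

    def test_separable_test_roc_auc_near_one(self):
        train = _separable_table(n=60, seed=4)
        test = _separable_table(n=40, seed=5)
        models = evaluate_models(train_models(train, seed=0), test)
        for m in models:
            assert m.test_metrics.roc_auc >= 0.99


class TestSelectModel:
    def _candidate(self, algo, spec):
        report = MetricReport(tp=1, tn=1, fp=0, fn=0, recall=1.0,
                              specificity=spec, accuracy=1.0, bacc=1.0, roc_auc=1.0)
        return TrainedModel(
            algorithm=algo, estimator=None, hyperparameters={},
            retained_descriptors=[], cv_roc_auc=1.0, seed=0, test_metrics=report,
        )

    def test_single_candidate_returned(self):
        c = self._candidate("svm", 0.9)
        assert select_model([c], {"svm": (0.8, 0.9, 0.7)}) is c

    def test_argmax_of_four_term_sum(self):
        cands = [
            self._candidate("logistic_regression", 0.8),   # 0.8+0.8+0.8+0.8=3.2
            self._candidate("svm", 0.9),                   # 3.5
            self._candidate("decision_tree", 0.5),         # 2.9
            self._candidate("random_forest", 0.7),         # 3.1
        ]
        extra = {
            "logistic_regression": (0.8, 0.8, 0.8),
            "svm": (0.9, 0.9, 0.8),
            "decision_tree": (0.8, 0.8, 0.8),
            "random_forest": (0.8, 0.8, 0.8),
        }
        assert select_model(cands, extra).algorithm == "svm"

    def test_exact_tie_prefers_random_forest(self):
        cands = [self._candidate(a, 0.9) for a in
                 ("decision_tree", "random_forest", "svm", "logistic_regression")]
        extra = {a: (0.9, 0.9, 0.9) for a in
                 ("decision_tree", "random_forest", "svm", "logistic_regression")}
        assert select_model(cands, extra).algorithm == "random_forest"

    def test_missing_term_rejected(self):
        c = self._candidate("svm", 0.9)
        with pytest.raises(ValueError):
            select_model([c], {})


class TestRoundTrips:
    def test_model_save_load(self, tmp_path):
        t = _separable_table(seed=6)
        m = train_models(t, seed=0)[0]
        path = tmp_path / "model.joblib"
        save_model(m, path)
        loaded = load_model(path)
        assert loaded.algorithm == m.algorithm
        assert loaded.retained_descriptors == m.retained_descriptors
        assert np.allclose(loaded.predict_scores(t), m.predict_scores(t))

    def test_descriptor_computation(self, tiny_molecules):
        table = compute_descriptors(tiny_molecules)
        assert table.values.shape == (3, 10)
        assert table.mol_ids == ["m1", "m2", "m3"]
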