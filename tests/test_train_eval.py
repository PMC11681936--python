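"""Negative sampling, metrics oracles, training behavior, cross-validation."""

import numpy as np
import pytest

import peppinet.train_eval as te
from peppinet.config import RunConfig
from peppinet.fixtures import FixtureSpec, make_planted_dataset
from peppinet.train_eval import (
    PairDataset,
    SamplePair,
    _mean_report,
    compute_metrics,
    cross_validate,
    sample_negatives,
    train,
)


def _rank_auc(labels, scores):
    """Mann-Whitney oracle: fraction of correctly ordered (pos, neg) pairs."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestSampleNegatives:
    def _positives(self):
        return [SamplePair("r1", "p1", 1), SamplePair("r2", "p2", 1),
                SamplePair("r3", "p3", 1)]

    def test_exhausts_the_non_positive_grid(self):
        negs = sample_negatives(self._positives(), 6, seed=0)
        keys = {(p.receptor_id, p.peptide_id) for p in negs}
        assert len(negs) == 6 and len(keys) == 6
        full = {(f"r{i}", f"p{j}") for i in (1, 2, 3) for j in (1, 2, 3)}
        taken = {("r1", "p1"), ("r2", "p2"), ("r3", "p3")}
        assert keys == full - taken
        assert all(p.label == 0 for p in negs)

    def test_zero_request_returns_empty(self):
        assert sample_negatives(self._positives(), 0, seed=0) == []

    def test_deterministic_given_seed(self):
        a = sample_negatives(self._positives(), 4, seed=9)
        b = sample_negatives(self._positives(), 4, seed=9)
        assert [p.key() for p in a] == [p.key() for p in b]

    def test_shortfall_error_names_the_deficit(self):
        with pytest.raises(ValueError, match="shortfall 1"):
            sample_negatives(self._positives(), 7, seed=0)


class TestComputeMetrics:
    def test_confusion_formulas_on_fixed_counts(self):
        # TP=2, FP=1, TN=3, FN=0
        labels = [1, 1, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.7, 0.2, 0.1, 0.05]
        rep = compute_metrics(labels, scores)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (2, 1, 3, 0)
        assert rep.acc == pytest.approx(5 / 6)
        assert rep.prec == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(1.0)
        assert rep.spec == pytest.approx(3 / 4)
        assert rep.f1 == pytest.approx(0.8)

    def test_perfect_separation_gives_all_ones(self):
        labels = [1] * 5 + [0] * 5
        scores = [0.9] * 5 + [0.1] * 5
        rep = compute_metrics(labels, scores)
        for v in (rep.acc, rep.prec, rep.recall, rep.spec, rep.f1, rep.auc,
                  rep.auprc):
            assert v == pytest.approx(1.0)

    def test_auc_equals_rank_statistic_oracle(self):
        g = np.random.default_rng(7)
        for _ in range(200):
            n = int(g.integers(4, 40))
            labels = g.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(g.random(n), 2)  # coarse grid forces ties
            rep = compute_metrics(labels, scores)
            assert rep.auc == pytest.approx(_rank_auc(labels, scores),
                                            abs=1e-9)

    def test_single_class_reports_missing_auc_with_warning(self):
        with pytest.warns(UserWarning, match="single-class"):
            rep = compute_metrics([1, 1, 1], [0.2, 0.6, 0.9])
        assert rep.auc is None and rep.auprc is None

    def test_zero_denominator_reported_as_zero_with_warning(self):
        # no positive predictions and no true positives -> Prec undefined
        with pytest.warns(UserWarning, match="Prec"):
            rep = compute_metrics([1, 0], [0.1, 0.2])
        assert rep.prec == 0.0

    def test_counts_partition_the_sample(self, rng):
        labels = rng.integers(0, 2, size=50)
        scores = rng.random(50)
        rep = compute_metrics(labels, scores)
        assert rep.n == 50


class TestAucConventions:
    def test_fold_mean_and_pooled_differ_on_constructed_folds(self):
        # fold 1 separates perfectly (AUC 1); fold 2 is all ties (AUC 0.5)
        fold1 = ([0, 1], [0.1, 0.9])
        fold2 = ([0, 1], [0.5, 0.5])
        reps = [compute_metrics(*fold1), compute_metrics(*fold2)]
        mean_rep = _mean_report(reps)
        assert mean_rep.auc == pytest.approx(0.75)
        pooled_labels = fold1[0] + fold2[0]
        pooled_scores = fold1[1] + fold2[1]
        pooled = compute_metrics(pooled_labels, pooled_scores)
        assert pooled.auc == pytest.approx(_rank_auc(pooled_labels,
                                                     pooled_scores))
        assert pooled.auc == pytest.approx(0.875)
        assert mean_rep.auc != pooled.auc

    def test_identical_folds_make_conventions_agree(self):
        fold = ([0, 1, 1, 0], [0.2, 0.8, 0.6, 0.4])
        reps = [compute_metrics(*fold) for _ in range(3)]
        mean_rep = _mean_report(reps)
        pooled = compute_metrics(fold[0] * 3, fold[1] * 3)
        assert mean_rep.auc == pytest.approx(pooled.auc)


@pytest.fixture(scope="module")
def small_dataset():
    return make_planted_dataset(FixtureSpec(seed=11, n_pairs=60))


@pytest.fixture(scope="module")
def fast_config():
    return RunConfig.test_profile(seed=11, epochs=4)


class TestTrain:
    def test_loss_decreases_over_training(self, small_dataset, fast_config):
        _, hist = train(small_dataset, fast_config)
        assert hist["loss"][-1] < hist["loss"][0]

    def test_same_seed_reproduces_final_loss(self, small_dataset, fast_config):
        _, h1 = train(small_dataset, fast_config)
        _, h2 = train(small_dataset, fast_config)
        assert abs(h1["final_loss"] - h2["final_loss"]) < 1e-6

    def test_zero_learning_rate_freezes_parameters(self, small_dataset):
        cfg = RunConfig.test_profile(seed=11, epochs=2, learning_rate=0.0)
        from peppinet.model import PepPIModel

        reference = PepPIModel(cfg)
        initial = [p.data.copy() for p in reference.parameters()]
        model, _ = train(small_dataset, cfg)
        for p, q in zip(model.parameters(), initial):
            np.testing.assert_array_equal(p.data, q)

    def test_single_class_dataset_rejected(self, small_dataset, fast_config):
        pos_only = PairDataset(
            [p for p in small_dataset.pairs if p.label == 1],
            small_dataset.chains, small_dataset.embeddings,
        )
        with pytest.raises(ValueError, match="both classes"):
            train(pos_only, fast_config)


class TestCrossValidate:
    def test_folds_partition_the_dataset(self, small_dataset, fast_config):
        result = cross_validate(small_dataset, fast_config, k=5, seed=3)
        folds = np.array([p.split_fold for p in small_dataset.pairs])
        assert set(folds) == set(range(5))
        sizes = [int((folds == f).sum()) for f in range(5)]
        assert sum(sizes) == len(small_dataset)
        assert max(sizes) - min(sizes) <= 1
        assert len(result["per_fold"]) == 5

    def test_every_fold_contains_both_classes(self, small_dataset, fast_config):
        cross_validate(small_dataset, fast_config, k=5, seed=3)
        labels = small_dataset.labels()
        folds = np.array([p.split_fold for p in small_dataset.pairs])
        for f in range(5):
            fold_labels = labels[folds == f]
            assert fold_labels.min() == 0 and fold_labels.max() == 1

    def test_k_exceeding_n_rejected(self, small_dataset, fast_config):
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(small_dataset, fast_config, k=1000)


class TestChainDisjointSplit:
    def test_no_chain_appears_on_both_sides(self, small_dataset):
        tr, tst = te.chain_disjoint_split(small_dataset, 0.3, seed=0)
        train_chains = ({p.receptor_id for p in tr.pairs}
                        | {p.peptide_id for p in tr.pairs})
        test_chains = ({p.receptor_id for p in tst.pairs}
                       | {p.peptide_id for p in tst.pairs})
        assert train_chains.isdisjoint(test_chains)
        assert len(tr) > 0 and len(tst) > 0


def test_metrics_csv_schema(tmp_path, small_dataset, fast_config):
    result = cross_validate(small_dataset, fast_config, k=3, seed=1)
    path = tmp_path / "metrics.csv"
    te.write_metrics_csv(path, result)
    import pandas as pd

    df = pd.read_csv(path)
    assert list(df["fold"]) == ["0", "1", "2", "mean", "pooled"]
    assert {"ACC", "AUC", "AUPRC", "TP"} <= set(df.columns)
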