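"""Classifier metrics, split protocol, five-method fitting and recall."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gruchem.screen import (
    ConfusionMatrix,
    cross_validate,
    compute_descriptors,
    descriptor_names,
    fit_classifiers,
    make_split,
    metrics_from_cm,
    repeat_fit,
    retrospective_recall,
    roc_points,
)
from gruchem.synthdata import LabeledSpec, gen_labeled


class TestMetrics:
    def test_published_confusion_matrix(self):
        """The 644-sample independent-test matrix reproduces the printed
        metric row: Acc 0.86, Spe 0.90, Sen 0.71, MCC 0.60, Random Acc 0.647."""
        rep = metrics_from_cm(ConfusionMatrix(tp=102, fp=49, fn=42, tn=451))
        r = rep.rounded()
        assert r["acc"] == 0.86
        assert r["spe"] == 0.90
        assert r["sen"] == 0.71
        assert r["mcc"] == 0.60
        assert r["random_acc"] == 0.647

    def test_perfect_prediction(self):
        rep = metrics_from_cm(ConfusionMatrix(tp=30, fp=0, fn=0, tn=70))
        assert rep.acc == 1.0 and rep.mcc == 1.0

    def test_degenerate_all_positive_predictor(self):
        rep = metrics_from_cm(ConfusionMatrix(tp=50, fp=50, fn=0, tn=0))
        assert rep.sen == 1.0 and rep.spe == 0.0
        assert rep.mcc is None  # undefined, not silently 0

    def test_identities_against_per_sample_recomputation(self):
        """Brute-force metrics from raw predictions match the closed forms."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            y = rng.integers(0, 2, 200)
            p = rng.integers(0, 2, 200)
            tp = int(((y == 1) & (p == 1)).sum())
            fp = int(((y == 0) & (p == 1)).sum())
            fn = int(((y == 1) & (p == 0)).sum())
            tn = int(((y == 0) & (p == 0)).sum())
            rep = metrics_from_cm(ConfusionMatrix(tp, fp, fn, tn))
            assert rep.acc == pytest.approx((p == y).mean())
            if rep.mcc is not None:
                assert rep.mcc == pytest.approx(np.corrcoef(y, p)[0, 1], abs=1e-12)

    @given(st.tuples(st.integers(0, 500), st.integers(0, 500),
                     st.integers(0, 500), st.integers(0, 500)))
    @settings(max_examples=150, derandomize=True)
    def test_metric_ranges_and_identities_hold(self, counts):
        """On arbitrary confusion matrices all defined metrics stay inside
        their ranges and satisfy the complement identities."""
        tp, fp, fn, tn = counts
        if tp + fp + fn + tn == 0:
            return
        rep = metrics_from_cm(ConfusionMatrix(tp, fp, fn, tn))
        assert 0.0 <= rep.acc <= 1.0
        assert 0.0 <= rep.random_acc <= 1.0
        if rep.sen is not None:
            assert rep.sen == pytest.approx(1 - fn / (tp + fn))
        if rep.spe is not None:
            assert rep.spe == pytest.approx(1 - fp / (tn + fp))
        if rep.mcc is not None:
            assert -1.0 <= rep.mcc <= 1.0

    def test_random_acc_is_marginal_shuffle_expectation(self):
        """random_acc equals the Monte-Carlo accuracy of a predictor whose
        outputs are the true predictions randomly re-paired with labels."""
        rng = np.random.default_rng(1)
        y = np.array([1] * 144 + [0] * 500)
        p = np.array([1] * 151 + [0] * 493)
        rep = metrics_from_cm(ConfusionMatrix(tp=102, fp=49, fn=42, tn=451))
        n_shuffles = 100_000
        accs = np.empty(n_shuffles)
        for i in range(n_shuffles):
            accs[i] = (y == rng.permutation(p)).mean()
        assert abs(accs.mean() - rep.random_acc) < 0.005


class TestDescriptors:
    def test_registry_has_200_entries(self):
        names = descriptor_names()
        assert len(names) == 200
        assert len(set(names)) == 200

    def test_row_width_and_determinism(self):
        table, problems = compute_descriptors(["c1ccccc1", "C1=CC=CC=C1"])
        assert problems == []
        assert table.shape == (2, 201)  # smiles column + 200 descriptors
        # same molecule, different writing -> identical rows
        assert (table.iloc[0, 1:] == table.iloc[1, 1:]).all()

    def test_ethanol_hbond_counts(self):
        table, _ = compute_descriptors(["CCO"])
        assert table["NumHDonors"].iloc[0] == 1
        assert table["NumHAcceptors"].iloc[0] == 1

    def test_unparseable_rejected_with_report(self):
        table, problems = compute_descriptors(["CCO", "C("])
        assert len(table) == 1
        assert problems[0]["error"] == "unparseable"


class TestSplitAndFit:
    def test_split_is_stratified_6_4(self):
        y = np.array([1] * 100 + [0] * 200)
        split = make_split(y, seed=0)
        assert (y[split.train] == 1).sum() == 60
        assert (y[split.validation] == 1).sum() == 40
        assert set(split.train) & set(split.validation) == set()

    def test_separable_data_all_methods_perfect(self):
        # spread the class signal over enough columns that every method,
        # including distance-based KNN, sees a clean margin
        X, y = gen_labeled(LabeledSpec(n_pos=60, n_neg=60, effect_size=5.0,
                                       n_informative=50, seed=0))
        split = make_split(y, seed=0)
        res = fit_classifiers(X, y, split, seed=0)
        for method, by_split in res.items():
            assert by_split["validation"].acc == 1.0, method

    def test_label_permutation_null_mcc(self):
        """With labels shuffled, validation MCC averages ~0 (|mean| < 0.1)."""
        X, y = gen_labeled(LabeledSpec(n_pos=100, n_neg=100, effect_size=3.0,
                                       seed=1))
        mccs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            yp = rng.permutation(y)
            split = make_split(yp, seed=seed)
            rep = fit_classifiers(X, yp, split, methods=("LR",),
                                  seed=seed)["LR"]["validation"]
            mccs.append(0.0 if rep.mcc is None else rep.mcc)
        assert abs(np.mean(mccs)) < 0.1

    def test_single_class_training_split_errors(self):
        X, y = gen_labeled(LabeledSpec(n_pos=10, n_neg=10, seed=0))
        from gruchem.screen import LabeledSplit
        bad = LabeledSplit(train=np.arange(5), validation=np.arange(10, 20))
        with pytest.raises(ValueError, match="single class"):
            fit_classifiers(X, y, bad)

    def test_repeat_protocol_returns_mean_and_sd(self):
        X, y = gen_labeled(LabeledSpec(n_pos=40, n_neg=40, effect_size=2.0,
                                       seed=2))
        agg = repeat_fit(X, y, methods=("LR", "GNB"), repeats=3, seed=5)
        assert set(agg.columns) == {"method", "split", "metric", "mean", "sd"}
        assert set(agg["method"]) == {"LR", "GNB"}
        accs = agg[(agg.metric == "acc") & (agg.split == "validation")]
        assert ((accs["mean"] >= 0) & (accs["mean"] <= 1)).all()


class TestCrossValidation:
    def test_separable_mean_accuracy_one(self):
        X, y = gen_labeled(LabeledSpec(n_pos=40, n_neg=40, effect_size=5.0,
                                       seed=3))
        df = cross_validate(X, y, k=5, seed=0)
        accs = df[df.metric == "acc"]["value"]
        assert accs.mean() == 1.0

    def test_leave_one_out_boundary(self):
        X, y = gen_labeled(LabeledSpec(n_pos=5, n_neg=5, effect_size=5.0,
                                       seed=4))
        df = cross_validate(X, y, k=5, seed=0)  # k = class size
        assert len(df) > 0

    def test_k_larger_than_class_errors(self):
        X, y = gen_labeled(LabeledSpec(n_pos=3, n_neg=50, seed=5))
        with pytest.raises(ValueError):
            cross_validate(X, y, k=5, seed=0)

    def test_fold_assignment_reproducible(self):
        X, y = gen_labeled(LabeledSpec(n_pos=30, n_neg=30, effect_size=1.0,
                                       seed=6))
        a = cross_validate(X, y, k=4, seed=9)
        b = cross_validate(X, y, k=4, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestRocPoints:
    def test_perfect_scores_reach_corner(self):
        y = np.array([0, 0, 1, 1])
        df = roc_points(y, np.array([0.1, 0.2, 0.8, 0.9]))
        # a perfect ranking passes through (fpr=0, tpr=1)
        assert ((df.fpr == 0) & (df.tpr == 1)).any()
        assert df.fpr.is_monotonic_increasing


class TestRecall:
    def test_superset_gives_one(self):
        held = ["CCO", "c1ccccc1"]
        gen = ["CCO", "c1ccccc1", "CCN"]
        assert retrospective_recall(gen, held) == 1.0

    def test_disjoint_gives_zero(self):
        assert retrospective_recall(["CCN"], ["CCO"]) == 0.0

    def test_canonical_matching(self):
        # the same molecule written two ways still matches
        assert retrospective_recall(["OCC"], ["CCO"]) == 1.0

    def test_monotone_in_generated_prefix(self):
        rng = np.random.default_rng(0)
        from gruchem.synthdata import CorpusSpec, gen_corpus
        pool = [r.canonical for r in gen_corpus(CorpusSpec(n=120, seed=13))]
        held = list(rng.choice(pool, size=20, replace=False))
        prev = 0.0
        for n in (10, 30, 60, 90, 120):
            rec = retrospective_recall(pool[:n], held)
            assert rec >= prev
            prev = rec
        assert prev == 1.0  # full pool contains every held-out string

    def test_predicted_positive_gate(self):
        gen = ["CCO", "CCN"]
        held = ["CCO", "CCN"]
        gated = retrospective_recall(gen, held, predicted_positive={"CCO"})
        assert gated == 0.5

    def test_empty_held_out_errors(self):
        with pytest.raises(ValueError):
            retrospective_recall(["CCO"], [])
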