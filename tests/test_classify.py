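import numpy as np
import pytest

from ductlayers.classify import (
    TASKS,
    EvalConfig,
    TaskDataset,
    balanced_subsample,
    compute_metrics,
    fit_task_model,
    hierarchical_predict,
    loo_evaluate,
    make_task_dataset,
)
from ductlayers.label_model import ValidationError


def _samples(diag_counts, d=4, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for diag, n in diag_counts.items():
        for _ in range(n):
            out.append((rng.standard_normal(d), diag))
    return out


class TestTaskSpecs:
    def test_three_tasks(self):
        assert list(TASKS) == [
            "invasive_vs_noninvasive",
            "preinvasive_vs_benign",
            "dcis_vs_atypia",
        ]

    def test_task1_includes_all_positive_invasive(self):
        t = TASKS["invasive_vs_noninvasive"]
        assert t.include_filter == {"benign", "atypia", "dcis", "invasive"}
        assert t.positive_classes == {"invasive"}

    def test_task2(self):
        t = TASKS["preinvasive_vs_benign"]
        assert t.include_filter == {"benign", "atypia", "dcis"}
        assert t.positive_classes == {"atypia", "dcis"}

    def test_task3(self):
        t = TASKS["dcis_vs_atypia"]
        assert t.include_filter == {"atypia", "dcis"}
        assert t.positive_classes == {"dcis"}


class TestMakeTaskDataset:
    def test_task1_one_of_each(self):
        samples = _samples({"benign": 2, "atypia": 2, "dcis": 2, "invasive": 2})
        ds = make_task_dataset(samples, TASKS["invasive_vs_noninvasive"])
        assert len(ds.y) == 8
        assert int(ds.y.sum()) == 2

    def test_task3_filters_to_two_classes(self):
        samples = _samples({"benign": 2, "atypia": 2, "dcis": 2, "invasive": 2})
        ds = make_task_dataset(samples, TASKS["dcis_vs_atypia"])
        assert len(ds.y) == 4
        assert int(ds.y.sum()) == 2  # dcis positive

    def test_too_few_per_class(self):
        samples = _samples({"atypia": 4})
        with pytest.raises(ValidationError, match="2 samples per class"):
            make_task_dataset(samples, TASKS["dcis_vs_atypia"])

    def test_all_benign_under_task3(self):
        samples = _samples({"benign": 4})
        with pytest.raises(ValidationError):
            make_task_dataset(samples, TASKS["dcis_vs_atypia"])

    def test_unknown_diagnosis(self):
        with pytest.raises(ValidationError):
            make_task_dataset([(np.zeros(3), "adh")], TASKS["dcis_vs_atypia"])

    def test_unequal_feature_lengths(self):
        samples = [(np.zeros(3), "dcis"), (np.zeros(4), "atypia")] * 2
        with pytest.raises(ValidationError, match="unequal"):
            make_task_dataset(samples, TASKS["dcis_vs_atypia"])


class TestBalancedSubsample:
    def test_downsamples_to_minority(self):
        y = np.r_[np.ones(10, int), np.zeros(30, int)]
        idx = balanced_subsample(y, np.random.default_rng(0))
        assert len(idx) == 20
        assert int(y[idx].sum()) == 10

    def test_already_balanced_unchanged_sizes(self):
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        idx = balanced_subsample(y, np.random.default_rng(0))
        assert len(idx) == 10
        assert sorted(idx) == list(range(10))

    def test_deterministic_given_seed(self):
        y = np.r_[np.ones(12, int), np.zeros(40, int)]
        a = balanced_subsample(y, np.random.default_rng(7))
        b = balanced_subsample(y, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_without_replacement(self):
        y = np.r_[np.ones(8, int), np.zeros(20, int)]
        idx = balanced_subsample(y, np.random.default_rng(3))
        assert len(set(idx.tolist())) == len(idx)


class TestComputeMetrics:
    def test_all_correct(self):
        acc, sens, spec, *_ = compute_metrics(
            np.array([1, 0, 1]), np.array([1, 0, 1])
        )
        assert (acc, sens, spec) == (1.0, 1.0, 1.0)

    def test_worked_contingency(self):
        # TP=7, FN=3, TN=90, FP=2
        truths = np.r_[np.ones(10, int), np.zeros(92, int)]
        preds = np.r_[np.ones(7, int), np.zeros(3, int), np.zeros(90, int), np.ones(2, int)]
        acc, sens, spec, tp, tn, fp, fn = compute_metrics(preds, truths)
        assert (tp, tn, fp, fn) == (7, 90, 2, 3)
        assert sens == pytest.approx(0.70)
        assert spec == pytest.approx(90 / 92)
        assert acc == pytest.approx(97 / 102)

    def test_zero_positives_sensitivity_nan(self, caplog):
        with caplog.at_level("WARNING"):
            _, sens, spec, *_ = compute_metrics(np.zeros(4, int), np.zeros(4, int))
        assert np.isnan(sens)
        assert spec == 1.0
        assert any("sensitivity undefined" in r.message for r in caplog.records)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            compute_metrics(np.zeros(3, int), np.zeros(4, int))


def _gaussian_dataset(n_per_class, d, gap, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            rng.standard_normal((n_per_class, d)) + gap / 2,
            rng.standard_normal((n_per_class, d)) - gap / 2,
        ]
    )
    y = np.r_[np.ones(n_per_class, int), np.zeros(n_per_class, int)]
    return TaskDataset(task=TASKS["dcis_vs_atypia"], X=X, y=y)


class TestLooEvaluate:
    def test_separable_clouds(self):
        ds = _gaussian_dataset(15, 10, gap=20, seed=1)
        res = loo_evaluate(ds, EvalConfig(n_repeats=2, base_seed=0))
        assert res.mean_accuracy >= 0.99

    def test_every_sample_predicted_once_per_repeat(self):
        ds = _gaussian_dataset(8, 5, gap=1, seed=2)
        res = loo_evaluate(ds, EvalConfig(n_repeats=3, base_seed=0))
        n = len(ds.y)
        totals = res.tp + res.tn + res.fp + res.fn
        assert (totals == n).all()

    def test_determinism(self):
        ds = _gaussian_dataset(6, 4, gap=2, seed=3)
        cfg = EvalConfig(n_repeats=1, base_seed=42)
        a = loo_evaluate(ds, cfg)
        b = loo_evaluate(ds, cfg)
        assert np.array_equal(a.accuracy, b.accuracy)
        assert np.array_equal(a.tp, b.tp)
        assert np.array_equal(a.fn, b.fn)

    def test_metrics_consistent_with_contingency(self):
        ds = _gaussian_dataset(7, 4, gap=1, seed=4)
        res = loo_evaluate(ds, EvalConfig(n_repeats=4, base_seed=0))
        for r in range(res.n_repeats):
            tp, tn, fp, fn = res.tp[r], res.tn[r], res.fp[r], res.fn[r]
            assert res.accuracy[r] == pytest.approx(
                (tp + tn) / (tp + tn + fp + fn), abs=1e-12
            )
            if tp + fn:
                assert res.sensitivity[r] == pytest.approx(tp / (tp + fn), abs=1e-12)
            if tn + fp:
                assert res.specificity[r] == pytest.approx(tn / (tn + fp), abs=1e-12)

    def test_chance_level_quick(self):
        # light version of the chance-level acceptance criterion: average
        # over several independent uninformative datasets
        accs = []
        for s in range(6):
            rng = np.random.default_rng(900 + s)
            X = rng.standard_normal((40, 20))
            y = np.zeros(40, int)
            y[rng.choice(40, 20, replace=False)] = 1
            ds = TaskDataset(task=TASKS["dcis_vs_atypia"], X=X, y=y)
            res = loo_evaluate(ds, EvalConfig(n_repeats=2, base_seed=s))
            accs.append(res.mean_accuracy)
        assert 0.35 <= float(np.mean(accs)) <= 0.65

    def test_requires_two_per_class(self):
        ds = TaskDataset(
            task=TASKS["dcis_vs_atypia"],
            X=np.zeros((3, 2)),
            y=np.array([1, 0, 0]),
        )
        with pytest.raises(ValidationError):
            loo_evaluate(ds, EvalConfig(n_repeats=1))

    def test_pooled_metrics(self):
        ds = _gaussian_dataset(6, 4, gap=2, seed=5)
        res = loo_evaluate(ds, EvalConfig(n_repeats=2, base_seed=0))
        pooled = res.pooled
        tp, tn = res.tp.sum(), res.tn.sum()
        total = tp + tn + res.fp.sum() + res.fn.sum()
        assert pooled["accuracy"] == pytest.approx((tp + tn) / total)


class _FakeModel:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(np.atleast_2d(X)), self.value)


class TestHierarchicalPredict:
    def _models(self, t1, t2, t3):
        return {
            "invasive_vs_noninvasive": _FakeModel(t1),
            "preinvasive_vs_benign": _FakeModel(t2),
            "dcis_vs_atypia": _FakeModel(t3),
        }

    def test_task1_positive_wins(self):
        assert hierarchical_predict(np.zeros(4), self._models(1, 0, 0)) == "invasive"
        assert hierarchical_predict(np.zeros(4), self._models(1, 1, 1)) == "invasive"

    def test_negative_negative_benign(self):
        assert hierarchical_predict(np.zeros(4), self._models(0, 0, 1)) == "benign"

    def test_negative_positive_positive_dcis(self):
        assert hierarchical_predict(np.zeros(4), self._models(0, 1, 1)) == "dcis"

    def test_negative_positive_negative_atypia(self):
        assert hierarchical_predict(np.zeros(4), self._models(0, 1, 0)) == "atypia"

    def test_missing_model(self):
        models = self._models(0, 1, 0)
        del models["dcis_vs_atypia"]
        with pytest.raises(ValidationError, match="dcis_vs_atypia"):
            hierarchical_predict(np.zeros(4), models)

    def test_fitted_cascade_on_separable_features(self):
        # real models: each diagnosis gets its own well-separated cluster
        rng = np.random.default_rng(0)
        centers = {
            "benign": np.r_[20, 0, 0, 0.0],
            "atypia": np.r_[0, 20, 0, 0.0],
            "dcis": np.r_[0, 0, 20, 0.0],
            "invasive": np.r_[0, 0, 0, 20.0],
        }
        samples = [
            (centers[d] + rng.standard_normal(4) * 0.1, d)
            for d in centers
            for _ in range(10)
        ]
        cfg = EvalConfig(n_repeats=1, base_seed=0)
        models = {
            name: fit_task_model(make_task_dataset(samples, task), cfg)
            for name, task in TASKS.items()
        }
        for diag, center in centers.items():
            assert hierarchical_predict(center, models) == diag
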