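"""Logistic models, factorized prediction, CV selection, the LOO protocol,
and the combinatorial sex-majority baselines."""

import numpy as np
import pandas as pd
import pytest

from bowaves.classify import (
    CohortTable,
    default_reg_grid,
    fit_logistic,
    loo_evaluate,
    naive_majority_loo_accuracy,
    predict_factorized,
    predict_subject,
    select_hyperparameter,
    tsc1_panel_cohort,
    FactorizedModel,
)
from bowaves.features import BagOfWaves


class TestFitLogistic:
    def test_separable_toy_reaches_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(-2, 0.3, (15, 2)), rng.normal(2, 0.3, (15, 2))])
        y = np.array(["neg"] * 15 + ["pos"] * 15)
        m = fit_logistic(X, y, reg_C=1e4)
        assert (m.predict(X) == y).all()

    def test_probabilities_sum_to_one(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.choice(["a", "b", "c"], 30)
        m = fit_logistic(X, y, reg_C=1.0)
        proba = m.predict_proba(rng.standard_normal((10, 4)))
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_logistic(rng.standard_normal((5, 2)), np.array(["a"] * 5), 1.0)

    def test_objective_no_worse_than_zero_model(self, rng):
        # optimizer sanity: penalized NLL at the fit is <= at the zero model
        X = rng.standard_normal((40, 3))
        y = rng.choice(["a", "b"], 40)
        C = 0.5
        m = fit_logistic(X, y, reg_C=C)
        p1 = m.predict_proba(X)[np.arange(40), [m.classes.index(c) for c in y]]
        nll = -np.mean(np.log(p1)) + np.sum(m.coefficients**2) / (2 * C * 40)
        assert nll <= -np.log(0.5) + 1e-9


def _bag(counts, duration=60.0, subject=""):
    counts = np.asarray(counts)
    return BagOfWaves(counts, [(0, len(counts))], subject_id=subject, duration_s=duration)


class TestPredictSubject:
    def test_single_segment_equals_segment_level_prediction(self, rng):
        from bowaves.features import apply_tfidf, fit_tfidf

        bags = [_bag(rng.integers(0, 5, 4) + 1) for _ in range(10)]
        tfidf = fit_tfidf(bags)
        X = np.array([apply_tfidf(b, tfidf).values for b in bags])
        y = np.array(["u", "v"] * 5)
        m = fit_logistic(X, y, 1.0, tfidf=tfidf)
        proba = predict_subject(m, [bags[0]])
        direct = m.predict_proba(X[0][None, :])[0]
        assert np.allclose([proba[c] for c in m.classes], direct)
        assert sum(proba.values()) == pytest.approx(1.0)

    def test_pooling_beats_majority_vote_on_constructed_example(self):
        # two low-count segments vote one way, one high-count segment the
        # other; count pooling follows the mass, majority vote the ballots
        from bowaves.features import TfidfWeights

        tfidf = TfidfWeights(np.ones(2), 3, np.zeros(2))
        m = fit_logistic(
            np.array([[1.0, 0.0], [0.0, 1.0]]), np.array(["x", "y"]), 1e4, tfidf=tfidf
        )
        segs = [_bag([3, 1]), _bag([3, 1]), _bag([1, 40])]
        pooled = predict_subject(m, segs)
        votes = [max(predict_subject(m, [s]), key=lambda c: predict_subject(m, [s])[c]) for s in segs]
        assert max(pooled, key=pooled.get) == "y"
        assert votes.count("x") == 2  # majority vote disagrees


class Stub:
    """Fixed-probability classifier stand-in for factorized-prediction math."""

    def __init__(self, classes, proba):
        self.classes = classes
        self._p = proba
        self.tfidf = None
        self.scaler = None

    def transform(self, X):
        return np.atleast_2d(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return np.array([self._p])


class TestFactorized:
    def test_joint_products_and_normalization(self, rng):
        # strain probabilities (0.5, 0.3, 0.2) with per-strain conditionals
        # (0.8,0.2), (0.5,0.5), (0.1,0.9) -> known joint table
        fm = FactorizedModel(
            strain_model=Stub(["s1", "s2", "s3"], [0.5, 0.3, 0.2]),
            conditional_models={
                "s1": Stub(["Het", "WT"], [0.8, 0.2]),
                "s2": Stub(["Het", "WT"], [0.5, 0.5]),
                "s3": Stub(["Het", "WT"], [0.1, 0.9]),
            },
        )
        joint = predict_factorized(fm, np.zeros((1, 2)))
        assert joint[("s1", "Het")] == pytest.approx(0.40)
        assert joint[("s1", "WT")] == pytest.approx(0.10)
        assert joint[("s2", "Het")] == pytest.approx(0.15)
        assert joint[("s2", "WT")] == pytest.approx(0.15)
        assert joint[("s3", "Het")] == pytest.approx(0.02)
        assert joint[("s3", "WT")] == pytest.approx(0.18)
        assert sum(joint.values()) == pytest.approx(1.0)

    def test_one_hot_strain_reduces_to_conditional(self):
        fm = FactorizedModel(
            strain_model=Stub(["s1", "s2"], [1.0, 0.0]),
            conditional_models={
                "s1": Stub(["Het", "WT"], [0.7, 0.3]),
                "s2": Stub(["Het", "WT"], [0.9, 0.1]),
            },
        )
        joint = predict_factorized(fm, np.zeros((1, 2)))
        assert joint[("s1", "Het")] == pytest.approx(0.7)
        assert joint[("s2", "Het")] == pytest.approx(0.0)

    def test_missing_conditional_model_raises(self):
        fm = FactorizedModel(
            strain_model=Stub(["s1", "s2"], [0.5, 0.5]),
            conditional_models={"s1": Stub(["Het", "WT"], [0.5, 0.5])},
        )
        with pytest.raises(KeyError):
            predict_factorized(fm, np.zeros((1, 2)))


def _synthetic_bags(n_per_class, segs, shift, seed, n_features=6):
    """Count bags with a Poisson rate bump on feature 0 for class 'pos'."""
    gen = np.random.default_rng(seed)
    bags, labels = {}, {}
    for i in range(2 * n_per_class):
        label = "pos" if i < n_per_class else "neg"
        lam = np.full(n_features, 20.0)
        if label == "pos":
            lam[0] += shift
        sid = f"x{i:02d}"
        bags[sid] = [_bag(gen.poisson(lam), subject=sid) for _ in range(segs)]
        labels[sid] = label
    return bags, labels


class TestHyperparameterSelection:
    def test_default_grid_is_15_log_spaced(self):
        grid = default_reg_grid()
        assert len(grid) == 15
        assert grid[0] == pytest.approx(0.1)
        assert grid[-1] == pytest.approx(1e4)
        assert np.allclose(np.diff(np.log10(grid)), np.log10(grid[1] / grid[0]))

    @staticmethod
    def _rigged_fitter(pooled_acc_by_C, segment_acc_by_C):
        """Build a _fit_on_subjects replacement whose models are right with
        the given per-C probabilities (subject labels read off the feature)."""

        class Rigged:
            tfidf = None
            scaler = None
            classes = ["neg", "pos"]

            def __init__(self, C):
                self.C = C
                self.reg_C = C
                self._i = 0

            def transform(self, X):
                return np.atleast_2d(np.asarray(X, dtype=float))

            def predict_proba(self, X):
                X = np.atleast_2d(X)
                out = []
                for x in X:
                    truth = "pos" if x[0] > 0 else "neg"
                    # deterministic pseudo-random correctness stream per C
                    self._i += 1
                    correct_pool = pooled_acc_by_C[self.C]
                    pred = truth if (self._i * 0.6180339887) % 1 < correct_pool else (
                        "neg" if truth == "pos" else "pos"
                    )
                    out.append([0.9, 0.1] if pred == "neg" else [0.1, 0.9])
                return np.array(out)

            def predict(self, X):
                proba = self.predict_proba(X)
                return np.asarray(self.classes)[np.argmax(proba, axis=1)]

        def fake_fit(subjects, bags_by_subject, labels_by_subject, reg_C, task):
            return Rigged(reg_C)

        return fake_fit

    def test_dominating_value_selected(self, monkeypatch):
        import bowaves.classify as mod

        # C=100 is always right, C=0.001 always wrong: strict dominance
        fake = self._rigged_fitter({100.0: 1.01, 1e-3: -0.01}, None)
        monkeypatch.setattr(mod, "_fit_on_subjects", fake)
        bags = {f"x{i}": [np.array([1.0 if i < 3 else -1.0])] for i in range(6)}
        labels = {f"x{i}": ("pos" if i < 3 else "neg") for i in range(6)}
        C = mod.select_hyperparameter(
            list(bags), [], bags, labels, grid=[1e-3, 100.0], K_CV=3, seed=0
        )
        assert C == 100.0

    def test_residual_tie_broken_by_smallest_grid_value(self):
        # all-identical counts: every candidate scores identically, so the
        # tie cascades to the smallest value (strongest regularization)
        bags = {f"x{i}": [_bag([5, 5, 5])] * 4 for i in range(6)}
        labels = {f"x{i}": ("pos" if i < 3 else "neg") for i in range(6)}
        C = select_hyperparameter(
            list(bags), [], bags, labels, grid=[0.5, 7.0, 300.0], K_CV=3, seed=1
        )
        assert C == 0.5


class TestLooEvaluate:
    def _cohort(self, labels):
        rows = [
            {"subject_id": s, "strain": "A", "tsc": lab, "sex": "F", "fold": i % 2}
            for i, (s, lab) in enumerate(labels.items())
        ]
        return CohortTable(pd.DataFrame(rows))

    def test_only_non_dictionary_subjects_scored(self):
        bags, labels = _synthetic_bags(4, segs=4, shift=30.0, seed=2)
        cohort = self._cohort(labels)
        res = loo_evaluate(cohort, bags, dict_fold=0, task="tsc", grid=[1.0, 100.0], seed=0)
        fold1 = set(cohort.fold_subjects(1))
        assert set(res.records["subject_id"]) == fold1

    def test_separated_classes_classified_correctly(self):
        bags, labels = _synthetic_bags(5, segs=8, shift=40.0, seed=3)
        cohort = self._cohort(labels)
        accs = []
        for fold in (0, 1):
            res = loo_evaluate(cohort, bags, fold, task="tsc", grid=[1.0, 100.0], seed=0)
            accs.append(res.accuracy)
        assert np.mean(accs) >= 0.9

    def test_record_fields_and_probabilities(self):
        bags, labels = _synthetic_bags(4, segs=4, shift=30.0, seed=4)
        cohort = self._cohort(labels)
        res = loo_evaluate(cohort, bags, 0, task="tsc", grid=[10.0], seed=0)
        p = res.records[["p_neg", "p_pos"]].to_numpy()
        assert np.allclose(p.sum(axis=1), 1.0)
        assert res.task == "tsc"


class TestTaskRestriction:
    def test_conditional_task_restricts_to_the_strain(self):
        gen = np.random.default_rng(5)
        rows, bags = [], {}
        for i in range(12):
            strain = "X" if i < 6 else "Y"
            tsc = "Het" if i % 2 else "WT"
            sid = f"s{i:02d}"
            rows.append({"subject_id": sid, "strain": strain, "tsc": tsc,
                         "sex": "F", "fold": i % 2})
            lam = np.full(4, 15.0)
            if tsc == "Het":
                lam[0] += 30.0
            bags[sid] = [_bag(gen.poisson(lam), subject=sid) for _ in range(6)]
        cohort = CohortTable(pd.DataFrame(rows))
        res = loo_evaluate(cohort, bags, 0, task="tsc_given_strain:X",
                           grid=[1.0, 100.0], K_CV=2, seed=0)
        scored = set(res.records["subject_id"])
        x_fold1 = {r["subject_id"] for r in rows if r["strain"] == "X" and r["fold"] == 1}
        assert scored == x_fold1

    def test_joint_task_label_combines_strain_and_tsc(self):
        from bowaves.classify import task_label

        row = pd.Series({"strain": "DBA2", "tsc": "Het"})
        assert task_label(row, "joint") == "DBA2-Het"
        assert task_label(row, "strain") == "DBA2"
        assert task_label(row, "tsc_given_strain:DBA2") == "Het"
        with pytest.raises(ValueError):
            task_label(row, "nonsense")


class TestStudyResultSummary:
    def test_multi_split_summary_reports_ci(self):
        from bowaves.classify import LeaveOneOutStudy, LOOResult, LOOStudyResult

        study = LeaveOneOutStudy(
            CohortTable(pd.DataFrame([
                {"subject_id": f"s{i}", "strain": "A", "tsc": "Het" if i % 2 else "WT",
                 "sex": "F", "fold": i % 2}
                for i in range(10)
            ])),
            recordings={}, task="tsc", n_splits=5,
        )
        gen = np.random.default_rng(0)

        def fake_split(acc):
            n = 10
            correct = int(round(acc * n))
            true = ["Het"] * n
            pred = ["Het"] * correct + ["WT"] * (n - correct)
            rec = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                                "true": true, "predicted": pred, "reg_C": 1.0})
            return [LOOResult(rec.iloc[:5]), LOOResult(rec.iloc[5:])]

        accs = [0.7, 0.8, 0.9, 0.8, 0.7]
        result = LOOStudyResult(study, [fake_split(a) for a in accs])
        assert result.split_accuracies == pytest.approx(accs)
        mean, sd, lo, hi = result.confidence_interval()
        assert mean == pytest.approx(np.mean(accs))
        assert lo < mean < hi
        text = result.summary()
        assert "95% CI" in text and "task='tsc'" in text


@pytest.fixture(scope="module")
def cohort():
    return tsc1_panel_cohort()


class TestNaiveMajorityBaselines:

    def test_cohort_marginals(self, cohort):
        t = cohort.table
        assert len(t) == 45
        assert t.groupby("strain").size().to_dict() == {"BXD87": 17, "C57B6": 14, "DBA2": 14}
        assert t.groupby("tsc").size().to_dict() == {"Het": 22, "WT": 23}
        assert t.groupby("sex").size().to_dict() == {"F": 26, "M": 19}

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(target="strain", covariate="sex"), 9 / 45),
            (dict(target="tsc", covariate="sex"), 27 / 45),
            (dict(target="tsc", covariate="sex", conditioning_strain="BXD87"), 12 / 17),
            (dict(target="tsc", covariate="sex", conditioning_strain="DBA2"), 7 / 14),
            (dict(target="tsc", covariate="sex", conditioning_strain="C57B6"), 6 / 14),
            (dict(target="joint", covariate="sex"), 3.5 / 45),
        ],
    )
    def test_sex_majority_loo_rates(self, cohort, kwargs, expected):
        assert naive_majority_loo_accuracy(cohort, **kwargs) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(target="strain"), 17 / 45),
            (dict(target="joint"), 10 / 45),
            (dict(target="tsc", conditioning_strain="BXD87"), 10 / 17),
            (dict(target="tsc", conditioning_strain="DBA2"), 8 / 14),
            (dict(target="tsc", conditioning_strain="C57B6"), 8 / 14),
        ],
    )
    def test_chance_rates_are_majority_proportions(self, cohort, kwargs, expected):
        acc = naive_majority_loo_accuracy(cohort, remove_held_out=False, **kwargs)
        assert acc == pytest.approx(expected)

    def test_single_class_cohort_is_always_right(self):
        rows = [
            {"subject_id": f"s{i}", "strain": "A", "tsc": "Het", "sex": "F", "fold": 0}
            for i in range(4)
        ]
        c = CohortTable(pd.DataFrame(rows))
        assert naive_majority_loo_accuracy(c, target="tsc") == 1.0
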