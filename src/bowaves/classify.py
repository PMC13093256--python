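"""Genotype classification from bag-of-waves features.

Implements l2-regularized (multinomial) logistic regression over TFIDF
features, per-individual pooled prediction, factorized strain -> disease
classification, nested stratified-group cross-validation for the
regularization hyperparameter, the leave-one-individual-out (LOO)
protocol, and combinatorial sex-majority baselines.

The protocol: individuals are split into two folds.  One fold trains the
per-genotype waveform dictionaries; every individual of the *other* fold
is scored by a classifier trained on all remaining individuals (with the
hyperparameter selected by cross-validation over non-dictionary
individuals only), so no held-out individual ever touches dictionary
training, TFIDF estimation, hyperparameter selection, or model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold

from .features import BagOfWaves, TfidfWeights, apply_tfidf, fit_tfidf, pool_bags

__all__ = [
    "CohortTable",
    "ClassifierModel",
    "FactorizedModel",
    "LOOResult",
    "default_reg_grid",
    "tsc1_panel_cohort",
    "fit_logistic",
    "predict_subject",
    "predict_factorized",
    "select_hyperparameter",
    "loo_evaluate",
    "naive_majority_loo_accuracy",
    "LeaveOneOutStudy",
]


def default_reg_grid() -> np.ndarray:
    """15 logarithmically spaced inverse-regularization values in [1e-1, 1e4]."""
    return np.logspace(-1, 4, 15)


@dataclass
class CohortTable:
    """Per-subject metadata: strain, disease (TSC) genotype, sex, and fold."""

    table: pd.DataFrame

    REQUIRED = ("subject_id", "strain", "tsc", "sex", "fold")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"cohort table missing columns {missing}")
        if self.table["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subjects(self) -> list[str]:
        return list(self.table["subject_id"])

    def label(self, subject_id: str, task: str) -> str:
        row = self.table.set_index("subject_id").loc[subject_id]
        return task_label(row, task)

    def fold_subjects(self, fold: int) -> list[str]:
        return list(self.table.loc[self.table["fold"] == fold, "subject_id"])

    def reassign_folds(self, seed: int) -> "CohortTable":
        """Pseudo-random fold assignment with equal odds per subject."""
        rng = np.random.default_rng(seed)
        t = self.table.copy()
        t["fold"] = rng.integers(0, 2, size=len(t))
        return CohortTable(t)


def task_label(row: pd.Series, task: str) -> str:
    """Map a cohort row to the label for a classification task."""
    if task == "strain":
        return str(row["strain"])
    if task == "tsc" or task.startswith("tsc_given_strain"):
        return str(row["tsc"])
    if task == "joint":
        return f"{row['strain']}-{row['tsc']}"
    raise ValueError(f"unknown task {task!r}")


def tsc1_panel_cohort() -> CohortTable:
    """The 45-mouse TSC1 haploinsufficiency panel cohort.

    Three background strains (BXD87, DBA2, C57B6) crossed with the
    presence (Het) or absence (WT) of a germline *TSC1* knockout, both
    sexes, with the published first-split two-fold assignment.
    """
    # (strain, tsc, sex): (fold0 count, fold1 count)
    cells = {
        ("BXD87", "Het", "F"): (3, 4),
        ("BXD87", "Het", "M"): (2, 1),
        ("BXD87", "WT", "F"): (1, 1),
        ("BXD87", "WT", "M"): (2, 3),
        ("DBA2", "Het", "F"): (1, 3),
        ("DBA2", "Het", "M"): (2, 0),
        ("DBA2", "WT", "F"): (3, 0),
        ("DBA2", "WT", "M"): (1, 4),
        ("C57B6", "Het", "F"): (3, 1),
        ("C57B6", "Het", "M"): (0, 2),
        ("C57B6", "WT", "F"): (4, 2),
        ("C57B6", "WT", "M"): (0, 2),
    }
    rows = []
    i = 0
    for (strain, tsc, sex), folds in cells.items():
        for fold, n in enumerate(folds):
            for _ in range(n):
                rows.append(
                    {"subject_id": f"m{i:02d}", "strain": strain, "tsc": tsc, "sex": sex, "fold": fold}
                )
                i += 1
    return CohortTable(pd.DataFrame(rows))


@dataclass
class ClassifierModel:
    """A fitted (multinomial) logistic-regression classifier.

    Stores classes in sklearn order, the raw intercepts/coefficients, the
    selected inverse-regularization strength, and the feature transform
    (TFIDF weights for count features, or standardizer statistics for
    dense features).
    """

    classes: list[str]
    intercepts: np.ndarray  # sklearn shape: (1,) binary, (|Y|,) multinomial
    coefficients: np.ndarray  # sklearn shape: (1, D) binary, (|Y|, D) multinomial
    reg_C: float
    tfidf: TfidfWeights | None = None
    scaler: tuple[np.ndarray, np.ndarray] | None = None  # (mean, scale) for dense features
    task: str = ""
    feature_means: np.ndarray | None = None  # training mean of transformed features

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return X @ self.coefficients.T + self.intercepts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, columns ordered as ``classes``."""
        scores = self.decision(X)
        if self.coefficients.shape[0] == 1:  # binary: score is for classes[1]
            p1 = 1.0 / (1.0 + np.exp(-scores[:, 0]))
            return np.column_stack([1.0 - p1, p1])
        z = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.asarray(self.classes)[np.argmax(proba, axis=1)]

    def class_coefficients(self, y: str) -> tuple[float, np.ndarray]:
        """(intercept, coefficient vector) for the linear score of class y.

        For a binary model the stored row scores ``classes[1]``; class 0
        gets the negated parameters.
        """
        idx = self.classes.index(y)
        if self.coefficients.shape[0] == 1:
            sign = 1.0 if idx == 1 else -1.0
            return sign * float(self.intercepts[0]), sign * self.coefficients[0]
        return float(self.intercepts[idx]), self.coefficients[idx]

    def transform(self, bags_or_X) -> np.ndarray:
        """Apply the stored feature transform to segment bags / dense rows."""
        if self.tfidf is not None:
            return np.array([apply_tfidf(b, self.tfidf).values for b in bags_or_X])
        X = np.atleast_2d(np.asarray(bags_or_X, dtype=float))
        if self.scaler is not None:
            mean, scale = self.scaler
            return (X - mean) / scale
        return X


def fit_logistic(
    X: np.ndarray,
    labels: np.ndarray,
    reg_C: float,
    task: str = "",
    tfidf: TfidfWeights | None = None,
    scaler: tuple[np.ndarray, np.ndarray] | None = None,
) -> ClassifierModel:
    """Fit an l2-penalized logistic regression on transformed features.

    ``reg_C`` is the inverse regularization strength (larger = weaker
    penalty); intercepts are unpenalized.  Classes are weighted inversely
    to their frequency: the leave-one-out protocol makes every training
    set one subject short of balance against the held-out individual, and
    an unweighted fit lets the intercept encode that complement, which
    systematically inverts predictions on small cohorts when the feature
    signal is weak.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    # sklearn's default penalty is the l2 ridge term; C is its inverse strength
    lr = LogisticRegression(C=reg_C, solver="lbfgs", max_iter=10_000, tol=1e-6, class_weight="balanced").fit(X, labels)
    return ClassifierModel(
        classes=[str(c) for c in lr.classes_],
        intercepts=lr.intercept_.copy(),
        coefficients=lr.coef_.copy(),
        reg_C=float(reg_C),
        tfidf=tfidf,
        scaler=scaler,
        task=task,
        feature_means=X.mean(axis=0),
    )


def pooled_feature(model: ClassifierModel, bags) -> np.ndarray:
    """Per-individual feature: count pooling + TFIDF, or mean pooling for dense."""
    if model.tfidf is not None:
        pooled = pool_bags(list(bags))
        return apply_tfidf(pooled, model.tfidf).values
    X = np.atleast_2d(np.asarray(bags, dtype=float))
    mean_vec = X.mean(axis=0)
    return model.transform(mean_vec)[0]


def predict_subject(model: ClassifierModel, bags) -> dict[str, float]:
    """Pooled class distribution for one individual's segment features."""
    x = pooled_feature(model, bags)
    proba = model.predict_proba(x[None, :])[0]
    return dict(zip(model.classes, proba.tolist()))


@dataclass
class FactorizedModel:
    """Strain model plus per-strain conditional disease-genotype models."""

    strain_model: ClassifierModel
    conditional_models: dict[str, ClassifierModel]


def predict_factorized(fmodel: FactorizedModel, bags) -> dict[tuple[str, str], float]:
    """Joint distribution p(strain, tsc | x) = p1(strain|x) * p2(tsc|x, strain)."""
    p1 = predict_subject(fmodel.strain_model, bags)
    joint: dict[tuple[str, str], float] = {}
    for strain, p_strain in p1.items():
        if strain not in fmodel.conditional_models:
            raise KeyError(f"no conditional model for strain {strain!r}")
        p2 = predict_subject(fmodel.conditional_models[strain], bags)
        for tsc, p_tsc in p2.items():
            joint[(strain, tsc)] = p_strain * p_tsc
    return joint


# ---------------------------------------------------------------------------
# Hyperparameter selection and the LOO protocol
# ---------------------------------------------------------------------------


def _fit_on_subjects(subjects, bags_by_subject, labels_by_subject, reg_C, task):
    """Fit feature transform + logistic regression on the given subjects' segments.

    Count bags get TFIDF; dense feature rows (e.g. soft-counted waveform
    features) get standard scaling.
    """
    train_feats, train_labels = [], []
    for s in subjects:
        for b in bags_by_subject[s]:
            train_feats.append(b)
            train_labels.append(labels_by_subject[s])
    if isinstance(train_feats[0], BagOfWaves):
        tfidf = fit_tfidf(train_feats)
        X = np.array([apply_tfidf(b, tfidf).values for b in train_feats])
        return fit_logistic(X, np.array(train_labels), reg_C, task=task, tfidf=tfidf)
    X = np.asarray(train_feats, dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return fit_logistic(
        (X - mean) / scale, np.array(train_labels), reg_C, task=task, scaler=(mean, scale)
    )


def _cv_folds(subjects, labels_by_subject, K_CV, seed, max_retries=20):
    """Stratified group folds over subjects.

    Grouping key is the subject (all segments of an individual stay in one
    fold); stratification label is the task target.  If a draw leaves a
    validation fold with a single class it is regenerated with a new seed
    (logged); if no multi-class draw exists (tiny fold sizes) the last
    draw is used — pooled accuracy remains well defined on such folds.
    """
    import warnings as _warnings

    subjects = list(subjects)
    y = np.array([labels_by_subject[s] for s in subjects])
    groups = np.arange(len(subjects))
    min_class = min(np.unique(y, return_counts=True)[1])
    n_splits = min(K_CV, len(subjects))
    if min_class < n_splits:
        # too few members of some class for stratified folding: fall back to a
        # label-interleaved round-robin partition of subjects (still grouped)
        rng = np.random.default_rng(seed)
        order = sorted(rng.permutation(len(subjects)), key=lambda i: y[i])
        folds = [[subjects[i] for i in order[j::n_splits]] for j in range(n_splits)]
        return [f for f in folds if f]
    folds = None
    for retry in range(max_retries):
        sgkf = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=int(seed) + retry)
        with _warnings.catch_warnings():
            # tiny cohorts trip sklearn's "least populated class" notice; the
            # single-class-fold handling below covers the actual risk
            _warnings.simplefilter("ignore", UserWarning)
            folds = [
                [subjects[i] for i in val_idx]
                for _, val_idx in sgkf.split(np.zeros(len(y)), y, groups)
            ]
        if all(len({labels_by_subject[s] for s in f}) > 1 for f in folds if len(f) > 1):
            if retry:
                _warnings.warn(f"validation folds regenerated {retry} time(s)", stacklevel=2)
            return folds
    _warnings.warn("single-class validation fold retained after retries", stacklevel=2)
    return folds


def select_hyperparameter(
    train_subjects,
    dict_fold_subjects,
    bags_by_subject,
    labels_by_subject,
    grid=None,
    K_CV: int = 3,
    task: str = "",
    seed: int = 0,
) -> float:
    """Choose the inverse-regularization strength by nested group CV.

    Validation folds are drawn only from training subjects outside the
    dictionary fold (their features may be distributed differently from
    dictionary-fold subjects).  Selection is by highest mean
    per-individual pooled accuracy, ties broken by mean segment-wise
    accuracy, residual ties by the smallest grid value.
    """
    if grid is None:
        grid = default_reg_grid()
    grid = np.asarray(grid, dtype=float)
    dict_set = set(dict_fold_subjects)
    cv_pool = [s for s in train_subjects if s not in dict_set]
    folds = _cv_folds(cv_pool, labels_by_subject, K_CV, seed)
    pooled_acc = np.zeros(len(grid))
    segment_acc = np.zeros(len(grid))
    for val_subjects in folds:
        val_set = set(val_subjects)
        cv_train = [s for s in train_subjects if s not in val_set]
        for gi, C in enumerate(grid):
            model = _fit_on_subjects(cv_train, bags_by_subject, labels_by_subject, C, task)
            hits, seg_hits, seg_n = 0.0, 0.0, 0
            for s in val_subjects:
                proba = predict_subject(model, bags_by_subject[s])
                pred = max(proba, key=proba.get)
                hits += pred == labels_by_subject[s]
                X = model.transform(bags_by_subject[s])
                seg_pred = model.predict(X)
                seg_hits += float(np.sum(seg_pred == labels_by_subject[s]))
                seg_n += len(seg_pred)
            pooled_acc[gi] += hits / len(val_subjects)
            segment_acc[gi] += seg_hits / max(seg_n, 1)
    # lexicographic: pooled accuracy, then segment accuracy, then smallest C
    order = np.lexsort((grid, -segment_acc, -pooled_acc))
    return float(grid[order[0]])


@dataclass
class LOOResult:
    """Per-held-out-subject predictions for one dictionary fold."""

    records: pd.DataFrame  # subject_id, true, predicted, reg_C, p_<class>...
    models: dict[str, ClassifierModel] = field(default_factory=dict)
    dict_fold: int | None = None
    task: str = ""

    @property
    def accuracy(self) -> float:
        return float((self.records["true"] == self.records["predicted"]).mean())


def loo_evaluate(
    cohort: CohortTable,
    bags_by_subject: dict,
    dict_fold: int,
    task: str = "strain",
    grid=None,
    K_CV: int = 3,
    seed: int = 0,
    keep_models: bool = True,
) -> LOOResult:
    """Leave-one-individual-out evaluation for one dictionary fold.

    ``bags_by_subject`` maps every subject to its list of segment bags
    encoded against the dictionaries learned from fold ``dict_fold``.
    Each subject outside that fold is scored by a model trained on all
    other subjects; a hard error is raised if the held-out subject leaks
    into any training structure.
    """
    table = cohort.table
    if task.startswith("tsc_given_strain:"):
        strain = task.split(":", 1)[1]
        table = table[table["strain"] == strain]
    labels_by_subject = {
        r["subject_id"]: task_label(r, task) for _, r in table.iterrows()
    }
    all_subjects = list(table["subject_id"])
    dict_subjects = [s for s in all_subjects if int(table.set_index("subject_id").loc[s, "fold"]) == dict_fold]
    test_subjects = [s for s in all_subjects if s not in set(dict_subjects)]
    rows, models = [], {}
    classes = sorted(set(labels_by_subject.values()))
    for s in test_subjects:
        train = [t for t in all_subjects if t != s]
        if s in train or s in dict_subjects:
            raise RuntimeError(f"leakage: held-out subject {s} found in a training structure")
        C = select_hyperparameter(
            train, dict_subjects, bags_by_subject, labels_by_subject,
            grid=grid, K_CV=K_CV, task=task, seed=seed,
        )
        model = _fit_on_subjects(train, bags_by_subject, labels_by_subject, C, task)
        proba = predict_subject(model, bags_by_subject[s])
        pred = max(proba, key=proba.get)
        row = {
            "subject_id": s,
            "true": labels_by_subject[s],
            "predicted": pred,
            "reg_C": C,
        }
        for c in classes:
            row[f"p_{c}"] = proba.get(c, 0.0)
        rows.append(row)
        if keep_models:
            models[s] = model
    return LOOResult(pd.DataFrame(rows), models=models, dict_fold=dict_fold, task=task)


# ---------------------------------------------------------------------------
# Combinatorial sex-majority / chance baselines
# ---------------------------------------------------------------------------


def _expected_correct(counts: pd.Series, true_label: str) -> float:
    """Expected correctness predicting a majority label; m-way ties -> 1/m."""
    if counts.empty:
        return 0.0
    top = counts.max()
    tied = counts[counts == top].index
    return (1.0 / len(tied)) if true_label in tied else 0.0


def naive_majority_loo_accuracy(
    cohort: CohortTable,
    target: str,
    covariate: str | None = None,
    conditioning_strain: str | None = None,
    remove_held_out: bool = True,
) -> float:
    """Expected LOO accuracy of a majority-label rule (fraction in [0, 1]).

    For each subject: remove it (if ``remove_held_out``), then predict the
    majority ``target`` label among remaining subjects sharing its
    ``covariate`` value (e.g. sex), or the overall majority if no
    covariate.  m-way ties contribute 1/m expected correctness.  With no
    covariate and no removal this reduces to the majority-class
    proportion, the chance rate.
    """
    table = cohort.table
    if conditioning_strain is not None:
        table = table[table["strain"] == conditioning_strain]
    if table.empty:
        raise ValueError("empty cohort after conditioning")
    if target == "joint":
        labels = table["strain"].astype(str) + "-" + table["tsc"].astype(str)
    else:
        labels = table[target].astype(str)
    table = table.assign(_label=labels.values)
    total = 0.0
    for idx, row in table.iterrows():
        pool = table.drop(index=idx) if remove_held_out else table
        if covariate is not None:
            pool = pool[pool[covariate] == row[covariate]]
        counts = pool["_label"].value_counts()
        total += _expected_correct(counts, row["_label"])
    return total / len(table)


# ---------------------------------------------------------------------------
# Study-level model object
# ---------------------------------------------------------------------------


class LeaveOneOutStudy:
    """End-to-end genotype classification study over a cohort of recordings.

    Statsmodels-style model object: construct from a cohort table,
    per-subject recordings, and hyperparameters; :meth:`fit` runs
    dictionary learning, encoding, and the repeated two-fold LOO protocol
    and returns a :class:`LOOStudyResult`.

    Parameters
    ----------
    cohort : CohortTable
        Subject metadata (strain, tsc, sex, fold).
    recordings : dict
        ``subject_id -> Recording``.
    task : str
        One of ``strain``, ``tsc``, ``joint``, or ``tsc_given_strain:<s>``.
    K, P, L : int
        Waveforms per dictionary, waveform length and window length
        (samples).
    windows_per_dict, segments_per_dict : int
        Training windows per genotype dictionary; encoded segments per
        genotype (split evenly across its subjects).
    seg_len_s : float
        Segment duration in seconds.
    n_splits : int
        Repeated random two-fold splits (split 0 keeps the cohort's own
        fold column; further splits reassign folds from seeds 1..n-1).
    """

    def __init__(
        self,
        cohort: CohortTable,
        recordings: dict,
        task: str = "strain",
        K: int = 200,
        P: int = 256,
        L: int = 512,
        windows_per_dict: int = 40_000,
        segments_per_dict: int = 480,
        seg_len_s: float = 3600.0,
        grid=None,
        K_CV: int = 3,
        n_splits: int = 1,
        seed: int = 0,
    ):
        self.cohort = cohort
        self.recordings = recordings
        self.task = task
        self.K, self.P, self.L = K, P, L
        self.windows_per_dict = windows_per_dict
        self.segments_per_dict = segments_per_dict
        self.seg_len_s = seg_len_s
        self.grid = default_reg_grid() if grid is None else np.asarray(grid, dtype=float)
        self.K_CV = K_CV
        self.n_splits = n_splits
        self.seed = seed

    # -- pipeline pieces -------------------------------------------------
    def _genotype_groups(self, table: pd.DataFrame):
        return table.groupby(["strain", "tsc"], sort=True)

    def learn_dictionaries(self, cohort: CohortTable, dict_fold: int, seed: int):
        """One dictionary per genotype from the dictionary fold's subjects."""
        from .dictionary import fit_shift_invariant_kmeans
        from .signal import sample_training_windows

        dicts = []
        table = cohort.table[cohort.table["fold"] == dict_fold]
        for (strain, tsc), grp in self._genotype_groups(table):
            recs = [self.recordings[s] for s in grp["subject_id"]]
            batch = sample_training_windows(
                recs, self.windows_per_dict, self.L, half="first", seed=seed
            )
            d = fit_shift_invariant_kmeans(
                batch, self.K, self.P, seed=seed, class_label=f"{strain}-{tsc}", fold=dict_fold
            )
            dicts.append(d)
        return dicts

    def encode_cohort(self, cohort: CohortTable, dicts, seed: int):
        """Per-subject segment bags against the fold's dictionaries."""
        from .features import encode_bow
        from .signal import sample_segments

        n_subjects_per_geno = cohort.table.groupby(["strain", "tsc"])["subject_id"].count()
        bags_by_subject: dict[str, list[BagOfWaves]] = {s: [] for s in cohort.subjects}
        for (strain, tsc), grp in self._genotype_groups(cohort.table):
            recs = [self.recordings[s] for s in grp["subject_id"]]
            n_seg = self.segments_per_dict - self.segments_per_dict % len(recs)
            segs = sample_segments(recs, n_seg, self.seg_len_s, half="second", seed=seed)
            for rec, start, samples in segs:
                bag = encode_bow(
                    samples, dicts, subject_id=rec.subject_id, start=start, rate=rec.rate, L=self.L
                )
                bags_by_subject[rec.subject_id].append(bag)
        return bags_by_subject

    # -- fitting ---------------------------------------------------------
    def fit(self, keep_models: bool = False) -> "LOOStudyResult":
        split_results = []
        for r in range(self.n_splits):
            cohort = self.cohort if r == 0 else self.cohort.reassign_folds(self.seed + 1000 + r)
            fold_results = []
            for dict_fold in (0, 1):
                seed_r = self.seed + 10 * r + dict_fold
                dicts = self.learn_dictionaries(cohort, dict_fold, seed_r)
                bags = self.encode_cohort(cohort, dicts, seed_r)
                res = loo_evaluate(
                    cohort, bags, dict_fold, task=self.task, grid=self.grid,
                    K_CV=self.K_CV, seed=seed_r, keep_models=keep_models,
                )
                fold_results.append(res)
            split_results.append(fold_results)
        return LOOStudyResult(self, split_results)


class LOOStudyResult:
    """Fitted study: per-split/fold LOO predictions with accuracy summaries."""

    def __init__(self, study: LeaveOneOutStudy, split_results):
        self.study = study
        self.split_results = split_results

    @property
    def split_accuracies(self) -> np.ndarray:
        """Accuracy per split, pooled over both dictionary folds."""
        accs = []
        for folds in self.split_results:
            records = pd.concat([r.records for r in folds], ignore_index=True)
            accs.append(float((records["true"] == records["predicted"]).mean()))
        return np.array(accs)

    @property
    def accuracy(self) -> float:
        return float(self.split_accuracies.mean())

    def predictions(self, split: int = 0) -> pd.DataFrame:
        return pd.concat([r.records for r in self.split_results[split]], ignore_index=True)

    def confidence_interval(self, level: float = 0.95):
        from .evaluate import SplitAccuracies, corrected_resampled_ci

        n = len(self.study.cohort)
        acc = SplitAccuracies(
            values=self.split_accuracies, n_tr=n - 1, n_te=n
        )
        return corrected_resampled_ci(acc, level)

    def summary(self) -> str:
        lines = [
            f"Leave-one-out study: task={self.study.task!r}",
            f"subjects={len(self.study.cohort)}  splits={len(self.split_results)}  "
            f"K={self.study.K} P={self.study.P} L={self.study.L}",
            "",
            "split  accuracy",
        ]
        for i, v in enumerate(self.split_accuracies):
            lines.append(f"{i:>5d}  {v:8.3f}")
        if len(self.split_results) >= 2:
            mean, sd, lo, hi = self.confidence_interval()
            lines.append("")
            lines.append(
                f"mean accuracy {100 * mean:.1f}%  sd {100 * sd:.1f}  "
                f"95% CI ({100 * lo:.1f}, {100 * hi:.1f})"
            )
        else:
            lines.append("")
            lines.append(f"accuracy {100 * self.accuracy:.1f}% (single split; no CI)")
        return "\n".join(lines)
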