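"""SVM discrimination of two groups from density-profile feature vectors.

Each subject's feature vector is one topology metric evaluated over the
link-density sweep (20 values by default).  A soft-margin SVM with a
polynomial kernel (gamma 0.25) is trained on a stratified split (75%
training by default); the penalty C is chosen by grid search over 10
log-spaced values in [1, 1000] using cross-validation on the training
split only, and the selection is then checked by stratified 10-fold
cross-validation.  Discrimination is additionally validated with a ROC
curve: the AUC, a stratified-bootstrap 95% CI, and a permutation p value
against AUC = 0.5.

For group-level correlation networks no subject-level profile exists, so
per-subject features are derived by a leave-one-out jackknife: subject
s's vector is the full-group profile minus the profile of the group
rebuilt without s, i.e. s's marginal contribution to the group network's
topology.

Features are standardised (zero mean, unit variance per density column)
inside the model pipeline, so scaling parameters are always learned on
training data only — polynomial kernels are scale sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    cross_val_predict,
    cross_val_score,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import TopologyProfile, topology_profile
from .networks import ROIFeatureTable, build_group_correlation


class DegenerateFeatureError(ValueError):
    """All feature columns are constant; nothing to classify on."""


@dataclass
class SVMConfig:
    """Classifier settings.

    ``C_grid`` defaults to 10 log-spaced points on [1, 1000]; ``gamma``
    to 0.25; the polynomial degree is part of the grid (2-4, default
    centre 3) because the source protocol leaves it unstated.
    """

    kernel: str = "poly"
    gamma: float = 0.25
    C_grid: tuple = tuple(np.logspace(0, 3, 10))
    degree_grid: tuple = (2, 3, 4)
    coef0: float = 1.0
    train_fraction: float = 0.75
    n_folds: int = 10
    standardize: bool = True
    n_boot: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if any(c <= 0 for c in self.C_grid):
            raise ValueError("C values must be positive")


@dataclass
class ClassificationReport:
    """Accuracies (percent), chosen hyperparameters and ROC validation."""

    metric: str
    groups: tuple
    train_fraction: float
    training_accuracy: float
    testing_accuracy: float
    cv_accuracy: float
    fold_accuracies: np.ndarray
    chosen_C: float
    chosen_degree: int
    auc: float
    auc_ci95: tuple
    auc_p_value: float

    def __post_init__(self) -> None:
        for acc in (self.training_accuracy, self.testing_accuracy, self.cv_accuracy):
            if not 0 <= acc <= 100:
                raise ValueError("accuracies must be percentages in [0, 100]")
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must lie in [0, 1]")

    def summary(self) -> str:
        lo, hi = self.auc_ci95
        return (
            f"SVM classification ({self.metric}; {self.groups[0]} vs {self.groups[1]})\n"
            f"  train fraction     : {self.train_fraction:.0%}\n"
            f"  chosen C / degree  : {self.chosen_C:.4g} / {self.chosen_degree}\n"
            f"  training accuracy  : {self.training_accuracy:.1f}%\n"
            f"  testing accuracy   : {self.testing_accuracy:.1f}%\n"
            f"  {len(self.fold_accuracies)}-fold CV accuracy : {self.cv_accuracy:.1f}%\n"
            f"  ROC AUC            : {self.auc:.2f} (95% CI {lo:.2f}-{hi:.2f}, "
            f"p = {self.auc_p_value:.4g})"
        )


def build_feature_vectors(
    profiles: list, metric: str
) -> tuple[np.ndarray, np.ndarray]:
    """Stack one metric's density series into a subjects x densities matrix.

    Labels are taken from each profile's ``entity_id`` prefix before the
    first ``/`` (convention: ``"GROUP/subject"``); profiles whose id has
    no ``/`` use the whole id as the label.
    """
    if not profiles:
        raise ValueError("no profiles given")
    grid = np.asarray(profiles[0].densities)
    rows, labels = [], []
    for p in profiles:
        if not np.allclose(np.asarray(p.densities), grid):
            raise ValueError("profiles have mismatched density grids")
        rows.append(p[metric])
        labels.append(p.entity_id.split("/", 1)[0])
    X = np.vstack(rows)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    if np.all(X.std(axis=0) == 0):
        raise DegenerateFeatureError(
            f"metric {metric!r} is constant across all subjects"
        )
    return X, y


def jackknife_group_profiles(
    table: ROIFeatureTable,
    group,
    densities,
    metric: str,
    ranking: str = "signed",
) -> list:
    """Subject-level profiles from one group's correlation network.

    For each subject s, the group network is rebuilt without s and
    subject s's profile is (full-group profile) - (leave-s-out profile):
    the subject's marginal contribution to the group topology.
    """
    sub = table.subset(group)
    if sub.n_subjects < 4:
        raise ValueError("jackknife needs at least 4 subjects in the group")
    densities = np.asarray(densities, dtype=float)

    def group_profile(values: np.ndarray) -> np.ndarray:
        t = ROIFeatureTable(
            subject_ids=[f"s{k}" for k in range(values.shape[0])],
            group_labels=[str(group)] * values.shape[0],
            region_names=list(sub.region_names),
            values=values,
            feature=sub.feature,
        )
        corr = build_group_correlation(t, str(group))
        return topology_profile(corr.r, densities, which=(metric,), ranking=ranking)[metric]

    full = group_profile(sub.values)
    out = []
    for s in range(sub.n_subjects):
        loo = group_profile(np.delete(sub.values, s, axis=0))
        out.append(
            TopologyProfile(
                entity_id=f"{group}/{sub.subject_ids[s]}",
                densities=densities,
                metrics={metric: full - loo},
            )
        )
    return out


def _make_pipeline(config: SVMConfig, C: float = 1.0, degree: int = 3) -> Pipeline:
    steps = []
    if config.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(
        (
            "svc",
            SVC(
                kernel=config.kernel,
                gamma=config.gamma,
                coef0=config.coef0,
                C=C,
                degree=degree,
            ),
        )
    )
    return Pipeline(steps)


def train_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    config: SVMConfig,
    metric: str = "",
) -> ClassificationReport:
    """Grid-searched SVM with held-out testing and k-fold CV validation.

    The data are split once (stratified, ``train_fraction``); C and the
    polynomial degree are selected by grid search maximising CV accuracy
    on the training split; training / held-out testing accuracies come
    from that fitted model, and the overall CV accuracy refits the chosen
    pipeline under stratified k-fold CV on the full data.  ROC scores are
    cross-validated decision values, so every subject is scored by a
    model that never saw it.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    if counts.min() < config.n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects; "
            f"{config.n_folds}-fold stratified CV needs at least {config.n_folds}"
        )
    if np.all(X.std(axis=0) == 0):
        raise DegenerateFeatureError("all feature columns are constant")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        train_size=config.train_fraction,
        stratify=y,
        random_state=config.seed,
    )
    inner_folds = min(config.n_folds, int(np.unique(y_tr, return_counts=True)[1].min()))
    inner_cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=config.seed)
    search = GridSearchCV(
        _make_pipeline(config),
        {"svc__C": list(config.C_grid), "svc__degree": list(config.degree_grid)},
        cv=inner_cv,
        scoring="accuracy",
    )
    search.fit(X_tr, y_tr)
    chosen_C = float(search.best_params_["svc__C"])
    chosen_degree = int(search.best_params_["svc__degree"])
    best = search.best_estimator_
    training_accuracy = 100.0 * best.score(X_tr, y_tr)
    testing_accuracy = 100.0 * best.score(X_te, y_te)

    outer_cv = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed + 1
    )
    chosen = _make_pipeline(config, C=chosen_C, degree=chosen_degree)
    fold_acc = cross_val_score(clone(chosen), X, y, cv=outer_cv, scoring="accuracy")
    cv_accuracy = 100.0 * float(fold_acc.mean())

    scores = cross_val_predict(
        clone(chosen), X, y, cv=outer_cv, method="decision_function"
    )
    # decision_function is signed toward the lexicographically larger class
    y_bin = (y == classes[1]).astype(int)
    auc, ci, p = roc_analysis(scores, y_bin, n_boot=config.n_boot, seed=config.seed + 2)

    return ClassificationReport(
        metric=metric,
        groups=(str(classes[0]), str(classes[1])),
        train_fraction=config.train_fraction,
        training_accuracy=training_accuracy,
        testing_accuracy=testing_accuracy,
        cv_accuracy=cv_accuracy,
        fold_accuracies=100.0 * fold_acc,
        chosen_C=chosen_C,
        chosen_degree=chosen_degree,
        auc=auc,
        auc_ci95=ci,
        auc_p_value=p,
    )


def _auc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the rank statistic: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    allv = np.concatenate([pos, neg])
    order = np.argsort(allv, kind="stable")  # midranks handle ties below
    rank = np.empty(allv.size)
    sorted_v = allv[order]
    i = 0
    while i < allv.size:
        j = i
        while j + 1 < allv.size and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        rank[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    r_pos = rank[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_analysis(
    decision_scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    n_perm: int = 2000,
) -> tuple[float, tuple, float]:
    """AUC with a stratified-bootstrap 95% CI and a permutation p value.

    The AUC is the Mann-Whitney rank statistic (probability that a random
    positive outranks a random negative, ties counted half).  The CI
    resamples positives and negatives separately; the p value permutes
    the labels and counts |AUC* - 0.5| >= |AUC - 0.5| with the add-one
    correction.
    """
    scores = np.asarray(decision_scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    auc = _auc_rank(scores, y)

    rng = np.random.default_rng(seed)
    ipos = np.flatnonzero(y == 1)
    ineg = np.flatnonzero(y == 0)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(ipos, ipos.size, replace=True)
        bn = rng.choice(ineg, ineg.size, replace=True)
        idx = np.concatenate([bp, bn])
        boot[b] = _auc_rank(scores[idx], y[idx])
    ci = (
        float(np.clip(np.percentile(boot, 2.5), 0, 1)),
        float(np.clip(np.percentile(boot, 97.5), 0, 1)),
    )

    exceed = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        if abs(_auc_rank(scores, yp) - 0.5) >= abs(auc - 0.5) - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return auc, ci, p
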