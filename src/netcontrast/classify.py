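"""Stratified nested-CV linear SVM with permutation null and feature weights.

Classifies fear vs. neutral rows of a feature matrix (one row per
participant x condition) with a linear maximum-margin classifier.  Folds
are assigned at the participant level — both condition rows of a
participant share a fold, so no within-subject leakage — and stratified
so that each fold holds approximately equal numbers of participants from
each dataset.  The inner CV selects the misclassification-cost parameter
``c`` by accuracy (ties go to the smallest ``c``); the permutation null
shuffles condition labels within participant, the exchangeable unit of a
paired design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "FeatureMatrix",
    "CVConfig",
    "ClassificationResult",
    "make_folds",
    "nested_cv",
    "macro_dice",
    "permutation_classification",
    "degenerate_report",
]

CLASSES = ("fear", "neutral")


@dataclass
class FeatureMatrix:
    """Per-row features with labels, participant groups and dataset strata."""

    x: np.ndarray
    labels: np.ndarray        # "fear" / "neutral" per row
    participants: np.ndarray  # participant id per row
    datasets: np.ndarray      # dataset id per row
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim == 1:
            self.x = self.x[:, None]
        self.labels = np.asarray(self.labels)
        self.participants = np.asarray(self.participants)
        self.datasets = np.asarray(self.datasets)
        if not (len(self.x) == len(self.labels) == len(self.participants)
                == len(self.datasets)):
            raise ValueError("row counts of x, labels, groups, strata differ")
        if np.isnan(self.x).any():
            raise ValueError("feature matrix contains missing values")
        for pid in np.unique(self.participants):
            rows = self.labels[self.participants == pid]
            if sorted(rows) != sorted(CLASSES):
                raise ValueError(
                    f"participant {pid!r} must have exactly one row per condition"
                )
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.x.shape[1])]

    @property
    def participant_ids(self) -> np.ndarray:
        return np.unique(self.participants)

    def participant_dataset(self) -> pd.Series:
        pairs = pd.DataFrame(
            {"participant": self.participants, "dataset": self.datasets}
        ).drop_duplicates()
        return pairs.set_index("participant")["dataset"]


@dataclass
class CVConfig:
    k_folds: int = 4
    c_grid: tuple[float, ...] = tuple(float(c) for c in range(1, 11))
    n_permutations: int = 1000
    weight_z_threshold: float = 1.96
    inner_folds: int = 3
    add_one_p: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not self.c_grid or any(c <= 0 for c in self.c_grid):
            raise ValueError("c_grid must be nonempty and positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class ClassificationResult:
    mean_accuracy: float          # percent
    mean_dice: float              # macro dice in [0, 1]
    p_perm: float
    mean_weights: np.ndarray
    weight_z: np.ndarray
    flagged_features: list[str]
    null_accuracies: np.ndarray
    true_accuracies: np.ndarray
    n_single_class_runs: int
    n_runs: int
    feature_names: list[str]


def make_folds(
    groups: np.ndarray,
    strata: np.ndarray,
    k: int,
    seed: int,
) -> pd.Series:
    """Assign each participant to one of ``k`` folds, stratified by dataset.

    Within each dataset, participants are shuffled and dealt round-robin
    starting from a random fold, so per-dataset counts across folds differ
    by at most one.  Returns a Series mapping participant id -> fold.
    """
    rng = np.random.default_rng(seed)
    dataset_of: dict = {}
    for g, s in zip(np.asarray(groups), np.asarray(strata)):
        if g in dataset_of and dataset_of[g] != s:
            raise ValueError("a participant maps to more than one dataset")
        dataset_of[g] = s
    assignment: dict = {}
    for ds in sorted(set(dataset_of.values())):
        members = sorted(g for g, s in dataset_of.items() if s == ds)
        order = rng.permutation(len(members))
        start = int(rng.integers(k))
        for pos, idx in enumerate(order):
            assignment[members[idx]] = (start + pos) % k
    return pd.Series(assignment, name="fold")


def macro_dice(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Unweighted mean over classes of ``2 TP / (2 TP + FP + FN)``.

    A class absent from both vectors contributes 1 by convention.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    scores = []
    for cls in CLASSES:
        tp = np.sum((y_true == cls) & (y_pred == cls))
        fp = np.sum((y_true != cls) & (y_pred == cls))
        fn = np.sum((y_true == cls) & (y_pred != cls))
        denom = 2 * tp + fp + fn
        scores.append(1.0 if denom == 0 else 2.0 * tp / denom)
    return float(np.mean(scores))


def _fit_predict(x_tr, y_tr, x_te, c: float):
    """Standardize on train statistics, fit a linear SVM, predict test rows.

    Standardization uses the training fold's mean and (population) SD only,
    so no test information leaks into the transform.
    """
    mu = x_tr.mean(axis=0)
    sd = x_tr.std(axis=0)
    sd[sd == 0] = 1.0
    clf = SVC(kernel="linear", C=c)
    clf.fit((x_tr - mu) / sd, y_tr)
    return clf, clf.predict((x_te - mu) / sd)


def nested_cv(
    features: FeatureMatrix,
    folds: pd.Series,
    config: CVConfig,
    seed: int,
    labels: np.ndarray | None = None,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """One round of nested cross-validation.

    Returns ``(accuracy_percent, macro_dice, mean_weights, predictions)``
    with outer-fold test predictions pooled before scoring and primal
    weight vectors averaged across outer folds.  ``labels`` optionally
    overrides the feature matrix's labels (used for null permutations).
    """
    y = features.labels if labels is None else np.asarray(labels)
    x = features.x
    fold_of = folds.to_dict()
    row_fold = np.array([fold_of[p] for p in features.participants])
    k = int(folds.max()) + 1
    rng = np.random.default_rng(seed)
    pd_map = features.participant_dataset()

    pooled_true: list = []
    pooled_pred: list = []
    weight_sum = np.zeros(x.shape[1])
    n_fitted = 0
    for fold in range(k):
        test = row_fold == fold
        train = ~test
        if not test.any():
            continue  # stratified dealing can leave a fold empty
        if len(np.unique(y[train])) < 2:
            raise ValueError("training fold contains a single class")
        if len(config.c_grid) == 1:
            best_c = config.c_grid[0]
        else:
            train_parts = np.unique(features.participants[train])
            inner_k = min(config.inner_folds, len(train_parts))
            inner_folds = make_folds(
                train_parts,
                pd_map.loc[train_parts].to_numpy(),
                inner_k,
                int(rng.integers(2**31)),
            )
            inner_fold_of = inner_folds.to_dict()
            tr_rows = np.flatnonzero(train)
            inner_row_fold = np.array(
                [inner_fold_of[p] for p in features.participants[tr_rows]]
            )
            best_c = None
            best_acc = -1.0
            for c in config.c_grid:  # ascending: ties keep the smallest c
                correct = 0
                total = 0
                for ifold in range(inner_k):
                    i_te = tr_rows[inner_row_fold == ifold]
                    i_tr = tr_rows[inner_row_fold != ifold]
                    if len(i_te) == 0 or len(np.unique(y[i_tr])) < 2:
                        continue
                    _, pred = _fit_predict(x[i_tr], y[i_tr], x[i_te], c)
                    correct += int(np.sum(pred == y[i_te]))
                    total += len(i_te)
                acc = correct / total if total else 0.0
                if acc > best_acc:
                    best_acc = acc
                    best_c = c
        clf, pred = _fit_predict(x[train], y[train], x[test], best_c)
        # coef_ sign convention: align to fear-vs-neutral orientation
        w = clf.coef_.ravel().copy()
        if list(clf.classes_) == ["fear", "neutral"]:
            w = -w  # make positive weights point toward "fear"
        weight_sum += w
        n_fitted += 1
        pooled_true.extend(y[test])
        pooled_pred.extend(pred)

    pooled_true_arr = np.asarray(pooled_true)
    pooled_pred_arr = np.asarray(pooled_pred)
    accuracy = 100.0 * float(np.mean(pooled_pred_arr == pooled_true_arr))
    dice = macro_dice(pooled_true_arr, pooled_pred_arr)
    return accuracy, dice, weight_sum / max(n_fitted, 1), pooled_pred_arr


def _shuffled_labels(features: FeatureMatrix, rng: np.random.Generator
                     ) -> np.ndarray:
    """Swap each participant's pair of condition labels with probability ½."""
    labels = features.labels.copy()
    for pid in features.participant_ids:
        if rng.uniform() < 0.5:
            rows = features.participants == pid
            swapped = np.where(labels[rows] == "fear", "neutral", "fear")
            labels[rows] = swapped
    return labels


def permutation_classification(
    features: FeatureMatrix, config: CVConfig
) -> ClassificationResult:
    """Repeated nested CV plus a label-shuffled null distribution.

    The true run repeats nested CV ``n_permutations`` times with freshly
    drawn stratified folds and averages accuracy, dice and weights; the
    null run repeats it with condition labels swapped at random within
    each participant.  ``p_perm`` is the fraction of null accuracies at or
    above the true mean accuracy (optionally with the add-one correction).
    Feature z-scores standardize the mean weights across features.
    """
    rng = np.random.default_rng(config.seed)
    n_feat = features.x.shape[1]
    accs = np.empty(config.n_permutations)
    dices = np.empty(config.n_permutations)
    weights = np.zeros(n_feat)
    single_class = 0
    for r in range(config.n_permutations):
        folds = make_folds(
            features.participants, features.datasets, config.k_folds,
            int(rng.integers(2**31)),
        )
        acc, dice, w, pred = nested_cv(
            features, folds, config, int(rng.integers(2**31))
        )
        accs[r] = acc
        dices[r] = dice
        weights += w
        if len(np.unique(pred)) == 1:
            single_class += 1
    mean_acc = float(accs.mean())
    mean_dice = float(dices.mean())
    mean_weights = weights / config.n_permutations

    null_accs = np.empty(config.n_permutations)
    for r in range(config.n_permutations):
        labels = _shuffled_labels(features, rng)
        folds = make_folds(
            features.participants, features.datasets, config.k_folds,
            int(rng.integers(2**31)),
        )
        acc, _, _, _ = nested_cv(
            features, folds, config, int(rng.integers(2**31)), labels=labels
        )
        null_accs[r] = acc

    count = int(np.sum(null_accs >= mean_acc))
    if config.add_one_p:
        p_perm = (count + 1) / (config.n_permutations + 1)
    else:
        p_perm = count / config.n_permutations

    sd = mean_weights.std()
    if sd > 0:
        weight_z = (mean_weights - mean_weights.mean()) / sd
    else:
        weight_z = np.zeros(n_feat)
    flagged = [
        name
        for name, z in zip(features.feature_names, weight_z)
        if abs(z) > config.weight_z_threshold
    ]
    return ClassificationResult(
        mean_accuracy=mean_acc,
        mean_dice=mean_dice,
        p_perm=float(p_perm),
        mean_weights=mean_weights,
        weight_z=weight_z,
        flagged_features=flagged,
        null_accuracies=null_accs,
        true_accuracies=accs,
        n_single_class_runs=single_class,
        n_runs=config.n_permutations,
        feature_names=list(features.feature_names),
    )


def degenerate_report(result: ClassificationResult) -> dict:
    """Flag classifiers that collapse to a single predicted class.

    On a balanced paired design a constant prediction forces accuracy to
    50% and macro dice to 1/3 (the predicted class scores 2/3, the other
    0); the report states those forced values alongside the flag.
    """
    if result.n_runs == 0:
        raise ValueError("empty classification result")
    collapsed = result.n_single_class_runs == result.n_runs
    return {
        "degenerate": bool(collapsed),
        "n_single_class_runs": result.n_single_class_runs,
        "n_runs": result.n_runs,
        "forced_accuracy_percent": 50.0,
        "forced_macro_dice": round(1.0 / 3.0, 3),
        "observed_accuracy_percent": result.mean_accuracy,
        "observed_macro_dice": result.mean_dice,
    }


def features_from_metrics(long_table: pd.DataFrame) -> FeatureMatrix:
    """Build a feature matrix from a long metric table (node_id columns)."""
    wide = long_table.pivot_table(
        index=["participant_id", "dataset_id", "condition"],
        columns="node_id",
        values="value",
    ).reset_index()
    node_cols = [c for c in wide.columns
                 if c not in ("participant_id", "dataset_id", "condition")]
    return FeatureMatrix(
        x=wide[node_cols].to_numpy(dtype=float),
        labels=wide["condition"].to_numpy(),
        participants=wide["participant_id"].to_numpy(),
        datasets=wide["dataset_id"].to_numpy(),
        feature_names=[f"node_{c}" for c in node_cols],
    )
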