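"""Group-aware repeated-partition classification evaluation.

Preprocessing method combinations are compared by the chance-corrected
agreement (Cohen's kappa) of off-the-shelf classifiers over repeated
80:20 train/test partitions.  Partitioning is done at the *patient* level
("hold-n-out"): all repeated measurements of one patient fall wholly on
one side of every split, so replicate correlation cannot leak between
train and test.  Every fitted statistic of the preprocessing pipeline
(column stats, quantile reference, centroid, log offset) is derived from
the training rows only.

kappa = (P0 - Pe) / (1 - Pe)
      = 2 (TP*TN - FN*FP) / ((TP+FP)(FP+TN) + (TP+FN)(FN+TN))

where P0 is the observed accuracy and Pe the accuracy expected by chance;
the two forms are algebraically identical for a binary confusion table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .matrix import SpectrumMatrix
from .pipeline import MethodCombo, PipelineError, apply_combo

__all__ = [
    "CLASSIFIERS",
    "PartitionPlan",
    "ConfusionCounts",
    "KappaResult",
    "make_partitions",
    "cohens_kappa",
    "cohens_kappa_po_pe",
    "kappa_interpretation",
    "evaluate",
]


def _make_classifier(name: str, random_state: int):
    if name == "knn":
        return KNeighborsClassifier()
    if name == "svm":
        return SVC(random_state=random_state)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "nbc":
        return GaussianNB()
    if name == "rfc":
        return RandomForestClassifier(random_state=random_state)
    raise ValueError(f"unknown classifier {name!r}; choose from {sorted(CLASSIFIERS)}")


CLASSIFIERS = ("knn", "svm", "lda", "nbc", "rfc")

# small hyperparameter grids searched by nested CV when tune=True
PARAM_GRIDS: dict[str, dict[str, list]] = {
    "knn": {"n_neighbors": [3, 5, 7]},
    "svm": {"C": [0.1, 1.0, 10.0]},
    "lda": {},
    "nbc": {"var_smoothing": [1e-9, 1e-7]},
    "rfc": {"max_features": ["sqrt", None]},
}


@dataclass(frozen=True)
class PartitionPlan:
    """Patient-level train/test splits, stratified by class."""

    splits: tuple[tuple[frozenset, frozenset], ...]
    n_partitions: int
    test_fraction: float
    seed: int


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def add(self, other: "ConfusionCounts") -> None:
        self.TP += other.TP
        self.TN += other.TN
        self.FP += other.FP
        self.FN += other.FN


@dataclass(frozen=True)
class KappaResult:
    """Mean/std kappa over partitions plus the summed confusion matrix."""

    kappa_mean: float
    kappa_std: float
    summed_confusion: ConfusionCounts
    accuracy: float
    per_partition_kappas: np.ndarray
    n_failed_partitions: int
    model: str
    combo_name: str

    @property
    def interpretation(self) -> str:
        return kappa_interpretation(self.kappa_mean)


def kappa_interpretation(kappa: float) -> str:
    """Level-of-agreement label for a kappa value (McHugh's bands)."""
    if kappa <= 0.20:
        return "none"
    if kappa <= 0.39:
        return "minimal"
    if kappa <= 0.59:
        return "weak"
    if kappa <= 0.79:
        return "moderate"
    if kappa <= 0.90:
        return "strong"
    return "almost perfect"


def cohens_kappa(confusion: ConfusionCounts) -> float:
    """Cohen's kappa from a binary confusion table (algebraic closed form)."""
    tp, tn, fp, fn = confusion.TP, confusion.TN, confusion.FP, confusion.FN
    if confusion.total <= 0:
        raise ValueError("empty confusion table")
    denom = (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn)
    if denom == 0:
        raise ValueError("degenerate confusion table: kappa denominator is 0")
    return 2.0 * (tp * tn - fn * fp) / denom


def cohens_kappa_po_pe(confusion: ConfusionCounts) -> float:
    """Cohen's kappa via observed vs chance agreement, (P0 - Pe)/(1 - Pe)."""
    tp, tn, fp, fn = confusion.TP, confusion.TN, confusion.FP, confusion.FN
    n = confusion.total
    if n <= 0:
        raise ValueError("empty confusion table")
    p0 = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    if pe == 1.0:
        raise ValueError("degenerate confusion table: chance agreement is 1")
    return (p0 - pe) / (1.0 - pe)


def make_partitions(
    patient_ids: np.ndarray,
    labels: np.ndarray,
    n_partitions: int = 50,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> PartitionPlan:
    """Draw repeated patient-level splits, stratified by class.

    ``patient_ids`` and ``labels`` are per-measurement; each patient's
    label must be constant across their measurements.  Within each class
    a fraction ``test_fraction`` of the patients (at least one) is held
    out per split, so both classes are present in every test set.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")

    patient_label: dict[object, str] = {}
    for pid, lab in zip(patient_ids.tolist(), labels.tolist()):
        lab = str(lab)
        if patient_label.setdefault(pid, lab) != lab:
            raise ValueError(f"patient {pid!r} carries conflicting class labels")
    classes = sorted(set(patient_label.values()))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, found {classes}")
    by_class = {c: sorted(str(p) for p, l in patient_label.items() if l == c)
                for c in classes}
    for c, pats in by_class.items():
        if len(pats) < 2:
            raise ValueError(f"class {c!r} has only {len(pats)} patient(s); need >= 2")

    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_partitions):
        test: set = set()
        for c in classes:
            pats = by_class[c]
            n_test = min(len(pats) - 1, max(1, round(test_fraction * len(pats))))
            picked = rng.permutation(len(pats))[:n_test]
            test.update(pats[i] for i in picked)
        train = {str(p) for p in patient_label} - test
        splits.append((frozenset(train), frozenset(test)))
    return PartitionPlan(
        splits=tuple(splits),
        n_partitions=n_partitions,
        test_fraction=test_fraction,
        seed=seed,
    )


def _split_confusion(
    y_true: np.ndarray, y_pred: np.ndarray, positive: str
) -> ConfusionCounts:
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        TP=int(np.sum(t & p)),
        TN=int(np.sum(~t & ~p)),
        FP=int(np.sum(~t & p)),
        FN=int(np.sum(t & ~p)),
    )


def evaluate(
    matrix: SpectrumMatrix,
    combo: MethodCombo,
    model: str,
    plan: PartitionPlan,
    tune: bool = False,
) -> KappaResult:
    """Score one method combination with one classifier over all partitions.

    Per split: the combination is applied with the training rows as the
    fit matrix, the classifier is trained on the processed training rows
    and predicts the processed test rows; the split's confusion table
    yields one kappa, and all tables are summed for the overall accuracy.
    Splits on which preprocessing or the classifier fails (or kappa is
    degenerate) are skipped and counted in ``n_failed_partitions``.

    With ``tune=True`` a small documented hyperparameter grid is searched
    by 5-fold cross-validation on the training split only.
    """
    labels = matrix.require_binary_labels()
    classes = sorted({str(v) for v in labels.tolist()})
    positive = classes[1]
    y_all = np.array([str(v) for v in labels.tolist()])
    pid_all = np.array([str(v) for v in matrix.patient_id.tolist()])

    kappas: list[float] = []
    summed = ConfusionCounts()
    n_failed = 0
    for split_no, (train_pat, test_pat) in enumerate(plan.splits):
        train_mask = np.isin(pid_all, list(train_pat))
        test_mask = np.isin(pid_all, list(test_pat))
        try:
            train = matrix.rows(train_mask)
            test = matrix.rows(test_mask)
            train_proc = apply_combo(train, combo)
            test_proc = apply_combo(test, combo, fit_matrix=train)

            clf = _make_classifier(model, random_state=plan.seed + split_no)
            grid = PARAM_GRIDS.get(model, {})
            if tune and grid:
                clf = GridSearchCV(clf, grid, cv=5)
            clf.fit(train_proc.intensities, y_all[train_mask])
            y_pred = np.asarray(clf.predict(test_proc.intensities), dtype=object)
            y_pred = np.array([str(v) for v in y_pred.tolist()])

            conf = _split_confusion(y_all[test_mask], y_pred, positive)
            kappas.append(cohens_kappa(conf))
            summed.add(conf)
        except (PipelineError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue

    if not kappas:
        raise ValueError(
            f"all {plan.n_partitions} partitions failed for combo {combo.name} "
            f"with model {model!r}"
        )
    kappas_arr = np.asarray(kappas)
    return KappaResult(
        kappa_mean=float(kappas_arr.mean()),
        kappa_std=float(kappas_arr.std(ddof=1)) if kappas_arr.size > 1 else 0.0,
        summed_confusion=summed,
        accuracy=(summed.TP + summed.TN) / summed.total,
        per_partition_kappas=kappas_arr,
        n_failed_partitions=n_failed,
        model=model,
        combo_name=combo.name,
    )
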