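"""Descriptor-based virtual screening: five classical classifiers and the
full evaluation-metric suite.

Molecules are described by a frozen registry of 200 fragmental and
topological RDKit descriptors (``gruchem/data/descriptors_200.txt``).  Five
methods — SVM (RBF, C=1, gamma='auto'), k-nearest neighbours, Gaussian
naive Bayes, random forest and L1 logistic regression (C=0.5, tol=1e-3,
max_iter=200) — are fitted on a stratified 6:4 train/validation split and
scored with AUC, MCC, accuracy, specificity, sensitivity and random
accuracy (the chance-agreement expected accuracy of a marginal-preserving
random predictor, as in Cohen's kappa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "ClassifierReport",
    "LabeledSplit",
    "descriptor_names",
    "compute_descriptors",
    "metrics_from_cm",
    "make_split",
    "fit_classifiers",
    "repeat_fit",
    "cross_validate",
    "roc_points",
    "retrospective_recall",
]

METHODS = ("SVM", "KNN", "GNB", "RF", "LR")


@lru_cache(maxsize=1)
def descriptor_names() -> list[str]:
    """The frozen 200-descriptor registry, in manifest order."""
    text = resources.files("gruchem").joinpath("data/descriptors_200.txt").read_text()
    names = [ln.strip() for ln in text.splitlines()
             if ln.strip() and not ln.startswith("#")]
    return names


def compute_descriptors(smiles: Sequence[str]) -> tuple[pd.DataFrame, list[dict]]:
    """Compute the 200-descriptor table for a list of SMILES.

    Returns the table (one row per input, indexed by position, with a
    ``smiles`` column of canonical strings) and a list of per-row problem
    reports: unparseable strings are rejected (row dropped) and descriptors
    that fail for a molecule are imputed as 0 and flagged.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    names = descriptor_names()
    funcs = dict(Descriptors._descList)
    rows, keep_smiles, problems = [], [], []
    for i, s in enumerate(smiles):
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            problems.append({"row": i, "smiles": s, "error": "unparseable"})
            continue
        vals = []
        for name in names:
            try:
                v = float(funcs[name](mol))
                if not math.isfinite(v):
                    raise ValueError("non-finite")
            except Exception:
                problems.append({"row": i, "smiles": s,
                                 "descriptor": name, "error": "imputed 0"})
                v = 0.0
            vals.append(v)
        rows.append(vals)
        keep_smiles.append(Chem.MolToSmiles(mol))
    df = pd.DataFrame(rows, columns=names)
    df.insert(0, "smiles", keep_smiles)
    return df, problems


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ClassifierReport:
    """All evaluation numbers for one method on one split.

    Metrics whose denominator is zero are ``None`` (undefined), never 0.
    """

    method: str
    cm: ConfusionMatrix
    acc: float | None
    spe: float | None
    sen: float | None
    mcc: float | None
    random_acc: float | None
    auc: float | None = None

    def rounded(self) -> dict:
        """Display rounding: 2 decimals, 3 for random_acc."""
        def r(x, nd):
            return None if x is None else round(x, nd)
        return {"method": self.method, "acc": r(self.acc, 2),
                "spe": r(self.spe, 2), "sen": r(self.sen, 2),
                "mcc": r(self.mcc, 2), "random_acc": r(self.random_acc, 3),
                "auc": r(self.auc, 2)}


def metrics_from_cm(cm: ConfusionMatrix, method: str = "") -> ClassifierReport:
    """Acc/Spe/Sen/MCC/Random-Acc from a confusion matrix.

    random_acc is the expected accuracy of a random predictor that keeps
    both the condition and the prediction marginals:
    [(TP+FN)(TP+FP) + (TN+FP)(TN+FN)] / total².
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = (tp + tn) / total
    sen = tp / (tp + fn) if tp + fn > 0 else None
    spe = tn / (tn + fp) if tn + fp > 0 else None
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else None
    random_acc = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / total ** 2
    return ClassifierReport(method=method, cm=cm, acc=acc, spe=spe, sen=sen,
                            mcc=mcc, random_acc=random_acc)


def _cm_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


# ---------------------------------------------------------------------------
# splits and model fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledSplit:
    """Disjoint train/validation (and optional test) index sets."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray | None = None

    def __post_init__(self):
        a, b = set(self.train.tolist()), set(self.validation.tolist())
        if a & b:
            raise ValueError("train and validation sets overlap")
        if self.test is not None and (set(self.test.tolist()) & (a | b)):
            raise ValueError("test set overlaps train/validation")


def make_split(y: np.ndarray, train_frac: float = 0.6,
               seed: int = 0) -> LabeledSplit:
    """Stratified random train/validation split (default 6:4 per class)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y).astype(int)
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        k = int(round(train_frac * len(idx)))
        train_idx.extend(idx[:k].tolist())
        val_idx.extend(idx[k:].tolist())
    return LabeledSplit(train=np.sort(np.array(train_idx)),
                        validation=np.sort(np.array(val_idx)))


def _build_model(method: str, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    if method == "SVM":
        clf = SVC(kernel="rbf", C=1.0, gamma="auto")
    elif method == "KNN":
        clf = KNeighborsClassifier()
    elif method == "GNB":
        clf = GaussianNB()
    elif method == "RF":
        clf = RandomForestClassifier(random_state=seed)
    elif method == "LR":
        clf = LogisticRegression(C=0.5, tol=1e-3, max_iter=200,
                                 penalty="l1", solver="liblinear",
                                 random_state=seed)
    else:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    # descriptors span wildly different scales; standardize on the training
    # fold (harmless for RF, necessary for SVM/KNN/LR)
    return make_pipeline(StandardScaler(), clf)


def _positive_score(pipe, X: np.ndarray) -> np.ndarray:
    clf = pipe[-1]
    if hasattr(clf, "decision_function"):
        return pipe.decision_function(X)
    proba = pipe.predict_proba(X)
    pos_col = list(clf.classes_).index(1)
    return proba[:, pos_col]


def fit_classifiers(table: pd.DataFrame, y: np.ndarray, split: LabeledSplit,
                    methods: Sequence[str] = METHODS,
                    seed: int = 0) -> dict[str, dict[str, ClassifierReport]]:
    """Fit each method on the training set; report on train and validation.

    Returns ``{method: {"train": report, "validation": report}}``.
    """
    from sklearn.metrics import roc_auc_score

    X = table.drop(columns=["smiles"], errors="ignore").to_numpy(dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y[split.train])) < 2:
        raise ValueError("training split contains a single class")
    out: dict[str, dict[str, ClassifierReport]] = {}
    for method in methods:
        pipe = _build_model(method, seed)
        pipe.fit(X[split.train], y[split.train])
        for name, idx in (("train", split.train), ("validation", split.validation)):
            pred = pipe.predict(X[idx])
            rep = metrics_from_cm(_cm_from_predictions(y[idx], pred), method)
            if len(np.unique(y[idx])) == 2:
                rep.auc = float(roc_auc_score(y[idx], _positive_score(pipe, X[idx])))
            out.setdefault(method, {})[name] = rep
    return out


def repeat_fit(table: pd.DataFrame, y: np.ndarray,
               methods: Sequence[str] = METHODS, repeats: int = 10,
               train_frac: float = 0.6, seed: int = 0) -> pd.DataFrame:
    """The repeat-10 protocol: re-split and re-fit, report mean ± sd.

    Returns a tidy frame (method, split, metric, mean, sd) over repeats.
    """
    rows = []
    for rep in range(repeats):
        split = make_split(y, train_frac=train_frac, seed=seed + rep)
        res = fit_classifiers(table, y, split, methods, seed=seed + rep)
        for method, by_split in res.items():
            for split_name, report in by_split.items():
                for metric in ("auc", "mcc", "acc", "spe", "sen", "random_acc"):
                    val = getattr(report, metric)
                    if val is not None:
                        rows.append({"repeat": rep, "method": method,
                                     "split": split_name, "metric": metric,
                                     "value": val})
    df = pd.DataFrame(rows)
    agg = (df.groupby(["method", "split", "metric"])["value"]
             .agg(["mean", "std"]).reset_index()
             .rename(columns={"std": "sd"}))
    return agg


def cross_validate(table: pd.DataFrame, y: np.ndarray, k: int = 5,
                   methods: Sequence[str] = ("LR",),
                   seed: int = 0) -> pd.DataFrame:
    """Stratified k-fold cross-validation; per-fold reports + mean ± sd."""
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y).astype(int)
    counts = np.bincount(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smaller class size {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    X_idx = np.arange(len(y))
    rows = []
    for fold, (tr, va) in enumerate(skf.split(X_idx, y)):
        split = LabeledSplit(train=tr, validation=va)
        res = fit_classifiers(table, y, split, methods, seed=seed)
        for method, by_split in res.items():
            rep = by_split["validation"]
            for metric in ("auc", "mcc", "acc", "spe", "sen", "random_acc"):
                val = getattr(rep, metric)
                if val is not None:
                    rows.append({"fold": fold, "method": method,
                                 "metric": metric, "value": val})
    return pd.DataFrame(rows)


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for the positive class."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(y_true, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------------
# retrospective recall
# ---------------------------------------------------------------------------

def retrospective_recall(generated: Iterable[str],
                         held_out_positives: Iterable[str],
                         predicted_positive: set[str] | None = None) -> float:
    """Fraction of held-out actives rediscovered among the generated set.

    Matching is by canonical-SMILES identity (charge and stereo sensitive).
    If ``predicted_positive`` is given (canonical strings the screening
    model calls positive), a held-out active only counts when its string is
    both generated *and* predicted positive — the full generate-then-screen
    protocol.  Without it, plain set membership is used.
    """
    from gruchem.corpus import canonicalize

    def canon(strings):
        out = set()
        for s in strings:
            rec = canonicalize(s)
            if rec.is_valid:
                out.add(rec.canonical)
        return out

    held = canon(held_out_positives)
    if not held:
        raise ValueError("held-out positive set is empty")
    gen = canon(generated)
    if predicted_positive is not None:
        gen = gen & canon(predicted_positive)
    return len(held & gen) / len(held)
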