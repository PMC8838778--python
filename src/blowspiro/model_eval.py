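"""Age-group binning, classifier evaluation and significance testing.

Recordings are labelled by age group — contiguous bins of 1, 2, 3, 4, 5 or
10 years anchored at the youngest study age (17) — and eight standard
classifiers are compared under stratified k-fold cross-validation:
K-nearest neighbours, C-SVC (RBF), random forest (300 trees), decision
tree, Gaussian naive Bayes, logistic regression, and linear and quadratic
discriminant analysis.

Metrics are accuracy, sensitivity and specificity; for multiclass problems
the latter two are one-vs-rest per class, macro-averaged over classes
present in the truth.  Classifier pairs are compared with two-sided paired
t-tests on fold-wise accuracy, Bonferroni-corrected over all pairs.

SMOTE is applied inside each training fold by default (no information
leaks from validation folds into oversampling); ``presplit_smote`` instead
balances the whole table before splitting, which inflates metrics and is
kept as an explicit, reported option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .feature_pipeline import FEATURE_COLUMNS, prescreen, smote_balance

CLASSIFIER_NAMES = ("knn", "svc", "rf", "dt", "nb", "lr", "lda", "qda")


class RegularizedQDA:
    """Gaussian quadratic discriminant analysis with ridge-regularized
    per-class covariances.

    Each class gets its own covariance Sigma_c + reg * I, so the classifier
    stays defined when a class has fewer members than features (common here:
    11 age groups from a few hundred recordings and ~30 features).
    """

    def __init__(self, reg: float = 0.1):
        self.reg = reg

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegularizedQDA":
        X = np.asarray(X, dtype=np.float64)
        self.classes_ = np.unique(y)
        p = X.shape[1]
        self.means_, self.precisions_, self.logdets_, self.priors_ = [], [], [], []
        for c in self.classes_:
            Xc = X[y == c]
            mu = Xc.mean(axis=0)
            cov = np.cov(Xc, rowvar=False, ddof=1) if len(Xc) > 1 else np.eye(p)
            cov = np.atleast_2d(cov) + self.reg * np.eye(p)
            sign, logdet = np.linalg.slogdet(cov)
            self.means_.append(mu)
            self.precisions_.append(np.linalg.inv(cov))
            self.logdets_.append(logdet)
            self.priors_.append(len(Xc) / len(X))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        scores = np.empty((X.shape[0], len(self.classes_)))
        for i, (mu, prec, logdet, prior) in enumerate(
            zip(self.means_, self.precisions_, self.logdets_, self.priors_)
        ):
            d = X - mu
            maha = np.einsum("ij,jk,ik->i", d, prec, d)
            scores[:, i] = -0.5 * (maha + logdet) + np.log(prior)
        return self.classes_[np.argmax(scores, axis=1)]


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the eight supported classifiers at its canonical
    defaults (random forest uses 300 trees)."""
    factories = {
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
        "svc": lambda: SVC(kernel="rbf", C=1.0, random_state=seed),
        "rf": lambda: RandomForestClassifier(n_estimators=300, random_state=seed),
        "dt": lambda: DecisionTreeClassifier(random_state=seed),
        "nb": lambda: GaussianNB(),
        "lr": lambda: LogisticRegression(max_iter=2000, random_state=seed),
        "lda": lambda: LinearDiscriminantAnalysis(),
        "qda": lambda: RegularizedQDA(reg=0.1),
    }
    if name not in factories:
        raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")
    return factories[name]()


@dataclass(frozen=True)
class AgeBinning:
    """Half-open age bins of fixed width anchored at ``start``."""

    start: float = 17.0
    end: float = 67.0
    width: float = 5.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must be < end")
        if self.width <= 0:
            raise ValueError("width must be positive")


@dataclass(frozen=True)
class EvalResult:
    classifier: str
    accuracy: float
    sensitivity: float
    specificity: float
    per_fold: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)


def bin_ages(ages: np.ndarray, b: AgeBinning) -> np.ndarray:
    """Map each age to its bin index floor((age - start) / width)."""
    ages = np.asarray(ages, dtype=np.float64)
    bad = ages[(ages < b.start) | (ages > b.end)]
    if bad.size:
        raise ValueError(f"age(s) outside [{b.start}, {b.end}]: {bad.tolist()}")
    return np.floor((ages - b.start) / b.width).astype(int)


def confusion_matrix_counts(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    return cm


def confusion_metrics(cm: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, macro sensitivity, macro specificity) of a truth x
    prediction count matrix.

    Sensitivity and specificity are one-vs-rest per class and averaged,
    unweighted, over classes that appear in the truth.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if cm.size == 0 or total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = np.trace(cm) / total
    sens, spec = [], []
    for c in range(cm.shape[0]):
        tp = cm[c, c]
        fn = cm[c, :].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:  # class absent from truth
            continue
        sens.append(tp / (tp + fn))
        spec.append(tn / (tn + fp) if tn + fp > 0 else 0.0)
    return float(accuracy), float(np.mean(sens)), float(np.mean(spec))


def train_eval(
    table: pd.DataFrame,
    labels: np.ndarray,
    classifier: str = "qda",
    n_folds: int = 10,
    seed: int = 0,
    smote: bool = True,
    presplit_smote: bool = False,
    smote_k: int = 5,
) -> EvalResult:
    """Stratified k-fold evaluation of one classifier.

    Features are standardized per training fold; with ``smote`` the
    training fold is SMOTE-balanced before fitting (``presplit_smote`` balances
    the full table before splitting instead).  ``n_folds`` is reduced
    automatically when the smallest class has fewer members.  Deterministic
    given the seed.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    if counts.min() < 2:
        raise ValueError(
            f"class {classes[counts.argmin()]} has a single member; widen the age bins"
        )
    if presplit_smote and smote:
        table, labels, _ = smote_balance(table, labels, k=smote_k, seed=seed)
        classes, counts = np.unique(labels, return_counts=True)
    k = int(min(n_folds, counts.min()))
    feats = [c for c in table.columns if c in FEATURE_COLUMNS]
    X = table[feats].to_numpy(dtype=np.float64)
    n_classes = int(labels.max()) + 1
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc, fold_sens, fold_spec = [], [], []
    pooled = np.zeros((n_classes, n_classes), dtype=int)
    for fold_i, (tr, te) in enumerate(skf.split(X, labels)):
        X_tr, y_tr = X[tr], labels[tr]
        if smote and not presplit_smote:
            tr_tab = pd.DataFrame(X_tr, columns=feats)
            if np.unique(y_tr, return_counts=True)[1].min() >= 2:
                tr_tab, y_tr, _ = smote_balance(tr_tab, y_tr, k=smote_k,
                                                seed=seed * 1000 + fold_i)
                X_tr = tr_tab[feats].to_numpy(dtype=np.float64)
        scaler = StandardScaler().fit(X_tr)
        clf = make_classifier(classifier, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(scaler.transform(X_tr), y_tr)
            y_pred = clf.predict(scaler.transform(X[te]))
        cm = confusion_matrix_counts(labels[te], y_pred, n_classes)
        pooled += cm
        a, s, sp = confusion_metrics(cm)
        fold_acc.append(a)
        fold_sens.append(s)
        fold_spec.append(sp)
    acc, sens, spec = confusion_metrics(pooled)
    return EvalResult(
        classifier=classifier, accuracy=acc, sensitivity=sens, specificity=spec,
        per_fold={"accuracy": fold_acc, "sensitivity": fold_sens, "specificity": fold_spec},
        config={"n_folds": k, "seed": seed, "smote": smote, "presplit_smote": presplit_smote},
    )


def compare_classifiers(
    results: list[EvalResult], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise two-sided paired t-tests on fold-wise accuracy.

    Returns (p-value matrix, boolean significance matrix) with the
    Bonferroni-corrected level alpha / n_pairs.  Zero-variance differences
    are exact: p = 1 when the mean difference is 0, else p = 0.
    """
    names = [r.classifier for r in results]
    n_folds = {len(r.per_fold["accuracy"]) for r in results}
    if len(n_folds) != 1:
        raise ValueError("results have mismatched fold counts; pairing undefined")
    n = len(results)
    n_pairs = n * (n - 1) // 2
    pvals = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = np.asarray(results[i].per_fold["accuracy"])
            b = np.asarray(results[j].per_fold["accuracy"])
            d = a - b
            if np.allclose(d.std(), 0.0):
                p = 1.0 if np.allclose(d.mean(), 0.0) else 0.0
            else:
                p = float(stats.ttest_rel(a, b).pvalue)
            pvals[i, j] = pvals[j, i] = p
    level = alpha / max(n_pairs, 1)
    pmat = pd.DataFrame(pvals, index=names, columns=names)
    sig = (pmat < level) & ~np.eye(n, dtype=bool)
    return pmat, sig


def run_experiment(
    table: pd.DataFrame,
    widths: tuple[float, ...] = (1, 2, 3, 4, 5, 10),
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
    binning_start: float = 17.0,
    binning_end: float = 67.0,
    seed: int = 0,
    smote: bool = True,
    presplit_smote: bool = False,
    corr_threshold: float = 0.9,
    evr_target: float = 0.999,
) -> pd.DataFrame:
    """Full grid: for each bin width, prescreen then evaluate every
    classifier; returns a tidy report (one row per width x classifier)."""
    records = []
    for width in widths:
        binning = AgeBinning(start=binning_start, end=binning_end, width=width)
        labels = bin_ages(table["age"].to_numpy(), binning)
        # relabel to contiguous 0..n-1 so absent bins don't create empty classes
        uniq = np.unique(labels)
        labels = np.searchsorted(uniq, labels)
        screened, _ = prescreen(table, corr_threshold, evr_target)
        for clf in classifiers:
            try:
                res = train_eval(screened, labels, clf, seed=seed,
                                 smote=smote, presplit_smote=presplit_smote)
            except ValueError as exc:
                warnings.warn(f"width {width}, {clf}: {exc}")
                continue
            records.append({
                "width": width, "classifier": clf,
                "accuracy": res.accuracy, "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "n_folds": res.config["n_folds"], "seed": seed,
                "smote_mode": "presplit" if presplit_smote else ("fold" if smote else "off"),
            })
    return pd.DataFrame.from_records(records)
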