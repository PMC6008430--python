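"""Leave-one-out classification of signal-level feature vectors.

The evaluation protocol mirrors the study: features are z-scored, a model
is trained on n−1 signals and tested on the held-out one, n times; the
report gives the confusion matrix, per-class true-positive rate
TPR_c = 100 · correct_c / total_c and overall accuracy
100 · correct / n (both in percent).

Three classifier families cover the published grid:

* kNN with cityblock / euclidean / Mahalanobis distance and equal,
  inverse-distance (1/d) or squared-inverse (1/d²) vote weighting.  The
  Mahalanobis covariance is estimated from each training fold with a
  small ridge.
* Random forests (scikit-learn) with the printed tree counts.
* LS-SVM: the least-squares SVM, solved as the linear system
  ``[[0, yᵀ], [y, Ω + I/C]] [b, α]ᵀ = [0, 1]`` with Ω = yyᵀ∘K, combined
  one-vs-one for multi-class.  Kernels: linear, cubic polynomial
  (xᵀz + 1)³ and RBF exp(−‖x−z‖²/(2σ²)).

Baselines: a random guess scores 100/#classes; always predicting the
majority class scores 100·max(count)/total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier

from .signal_io import CLASS_LABELS, FEATURE_COLUMNS

DISEASE_LABELS = ("LQT1", "HCM", "CPVT")

#: The five class arrangements: 1.x = three diseases (normal-only,
#: abnormal-only, pooled); 2.x = diseases + controls (normal-only, pooled).
ARRANGEMENTS = ("1.1", "1.2", "1.3", "2.1", "2.2")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration of the evaluation grid."""

    family: str  # knn | random_forest | ls_svm
    metric: str = "euclidean"  # knn: cityblock | euclidean | mahalanobis
    weighting: str = "equal"  # knn: equal | inverse | squared_inverse
    k: int = 1
    n_trees: int = 100
    kernel: str = "rbf"  # ls_svm: linear | poly3 | rbf
    C: float = 1.0
    sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("knn", "random_forest", "ls_svm"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "knn":
            if self.metric not in ("cityblock", "euclidean", "mahalanobis"):
                raise ValueError(f"unknown knn metric {self.metric!r}")
            if self.weighting not in ("equal", "inverse", "squared_inverse"):
                raise ValueError(f"unknown weighting {self.weighting!r}")
            if self.k < 1:
                raise ValueError("k must be >= 1")
        if self.family == "ls_svm":
            if self.kernel not in ("linear", "poly3", "rbf"):
                raise ValueError(f"unknown kernel {self.kernel!r}")
            if self.C <= 0 or self.sigma <= 0:
                raise ValueError("C and sigma must be > 0")

    def describe(self) -> str:
        if self.family == "knn":
            return (f"kNN, {self.metric} metric, "
                    f"{self.weighting.replace('_', ' ')} weighting, k={self.k}")
        if self.family == "random_forest":
            return f"Random forests, {self.n_trees} trees"
        if self.kernel == "rbf":
            return f"LS-SVM RBF kernel, C={self.C:g}, sigma={self.sigma:g}"
        if self.kernel == "poly3":
            return f"LS-SVM cubic kernel, C={self.C:g}"
        return f"LS-SVM linear kernel, C={self.C:g}"


#: Published grid for the three-disease pooled arrangement.
GRID_3CLASS: tuple[ClassifierSpec, ...] = (
    ClassifierSpec("knn", metric="cityblock", weighting="equal", k=1),
    ClassifierSpec("knn", metric="cityblock", weighting="inverse", k=5),
    ClassifierSpec("knn", metric="cityblock", weighting="squared_inverse", k=5),
    ClassifierSpec("random_forest", n_trees=35),
    ClassifierSpec("ls_svm", kernel="poly3", C=2.0 ** -5),
    ClassifierSpec("ls_svm", kernel="rbf", C=2.0, sigma=2.0),
)

#: Published grid for the four-class (diseases + controls) arrangement.
GRID_4CLASS: tuple[ClassifierSpec, ...] = (
    ClassifierSpec("knn", metric="cityblock", weighting="equal", k=5),
    ClassifierSpec("knn", metric="cityblock", weighting="inverse", k=5),
    ClassifierSpec("knn", metric="cityblock", weighting="squared_inverse", k=5),
    ClassifierSpec("knn", metric="mahalanobis", weighting="equal", k=1),
    ClassifierSpec("knn", metric="mahalanobis", weighting="inverse", k=1),
    ClassifierSpec("knn", metric="mahalanobis", weighting="squared_inverse", k=11),
    ClassifierSpec("random_forest", n_trees=54),
    ClassifierSpec("ls_svm", kernel="rbf", C=2.0 ** 4, sigma=2.0),
)


@dataclass
class EvalReport:
    """Leave-one-out result for one (arrangement, classifier) pair."""

    arrangement: str
    spec: ClassifierSpec
    confusion: pd.DataFrame  # rows: true class, columns: predicted
    tpr: dict[str, float]  # percent, per class
    accuracy: float  # percent
    standardize_mode: str = "global"

    def summary_row(self) -> dict:
        row = {"arrangement": self.arrangement, "method": self.spec.describe()}
        for lbl in CLASS_LABELS:
            if lbl in self.tpr:
                row[f"TPR_{lbl}"] = self.tpr[lbl]
        row["accuracy"] = self.accuracy
        return row


def baselines(class_counts) -> tuple[float, float]:
    """(random-guess accuracy, majority-class accuracy), both in percent.

    ``class_counts`` is a mapping or sequence of per-class signal counts.
    """
    counts = np.asarray(
        list(class_counts.values()) if hasattr(class_counts, "values")
        else list(class_counts), dtype=float,
    )
    if (counts < 0).any():
        raise ValueError("class counts must be >= 0")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total signal count must be > 0")
    return 100.0 / len(counts), 100.0 * counts.max() / total


def select_arrangement(table: pd.DataFrame, arrangement: str) -> pd.DataFrame:
    """Subset the feature table for one of the five class arrangements.

    1.1 / 1.2 / 1.3: normal-only / abnormal-only / pooled signals of the
    three diseases.  2.1: normal-only signals of diseases and controls.
    2.2: all signals of all four classes — the control class keeps its few
    abnormal signals inside WT (they are never a class of their own).
    Requires ``label`` and ``abnormal`` columns.
    """
    if arrangement not in ARRANGEMENTS:
        raise ValueError(f"unknown arrangement {arrangement!r}; one of {ARRANGEMENTS}")
    is_disease = table["label"].isin(DISEASE_LABELS)
    normal = ~table["abnormal"].astype(bool)
    if arrangement == "1.1":
        mask = is_disease & normal
    elif arrangement == "1.2":
        mask = is_disease & ~normal
    elif arrangement == "1.3":
        mask = is_disease
    elif arrangement == "2.1":
        mask = normal
    else:  # 2.2
        mask = pd.Series(True, index=table.index)
    return table.loc[mask].reset_index(drop=True)


def standardize(
    table: pd.DataFrame, feature_cols: tuple[str, ...] = FEATURE_COLUMNS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score each feature column; returns (table, transform parameters).

    Zero-variance columns are mapped to 0.  This is the dataset-global
    mode (the study standardizes once before leave-one-out); leakage-safe
    per-fold standardization is available via
    ``loo_evaluate(..., standardize_mode="per_fold")``.
    """
    out = table.copy()
    mean = out.loc[:, list(feature_cols)].mean()
    sd = out.loc[:, list(feature_cols)].std(ddof=0)
    sd_safe = sd.replace(0.0, 1.0)
    out.loc[:, list(feature_cols)] = (
        out.loc[:, list(feature_cols)] - mean
    ) / sd_safe
    params = pd.DataFrame({"mean": mean, "sd": sd})
    return out, params


# ---------------------------------------------------------------- kernels

def _kernel(X1: np.ndarray, X2: np.ndarray, spec: ClassifierSpec) -> np.ndarray:
    if spec.kernel == "linear":
        return X1 @ X2.T
    if spec.kernel == "poly3":
        return (X1 @ X2.T + 1.0) ** 3
    sq = cdist(X1, X2, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * spec.sigma**2))


def _lssvm_train(K: np.ndarray, y_pm: np.ndarray, C: float):
    """Solve the LS-SVM linear system for one binary problem."""
    n = len(y_pm)
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = y_pm
    A[1:, 0] = y_pm
    A[1:, 1:] = np.outer(y_pm, y_pm) * K + np.eye(n) / C
    rhs = np.concatenate([[0.0], np.ones(n)])
    sol = np.linalg.solve(A, rhs)
    return sol[0], sol[1:]  # b, alpha


def _pick(votes: np.ndarray, priority: np.ndarray) -> int:
    """Argmax with ties broken by a fixed priority permutation."""
    best = np.flatnonzero(votes == votes.max())
    return int(best[np.argmin(priority[best])])


def _predict_knn(X_tr, y_tr, x, spec: ClassifierSpec, n_classes, priority):
    if spec.metric == "mahalanobis":
        cov = np.cov(X_tr, rowvar=False)
        cov = np.atleast_2d(cov)
        ridge = 1e-6 * np.mean(np.diag(cov))
        cov = cov + max(ridge, 1e-12) * np.eye(cov.shape[0])
        if np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError(
                "training-fold covariance is singular even after ridge "
                "regularization; use the euclidean metric instead"
            )
        VI = np.linalg.inv(cov)
        d = cdist(x[None, :], X_tr, metric="mahalanobis", VI=VI)[0]
    else:
        d = cdist(x[None, :], X_tr, metric=spec.metric)[0]
    k = min(spec.k, len(d))
    nn = np.argpartition(d, k - 1)[:k]
    dn = d[nn]
    if spec.weighting == "equal":
        w = np.ones(k)
    else:
        exact = dn < 1e-12
        if exact.any():
            w = exact.astype(float)  # an identical case dominates the vote
        else:
            w = 1.0 / dn if spec.weighting == "inverse" else 1.0 / dn**2
    votes = np.bincount(y_tr[nn], weights=w, minlength=n_classes)
    return _pick(votes, priority)


def _predict_lssvm(X_tr, y_tr, x, spec: ClassifierSpec, n_classes, priority):
    votes = np.zeros(n_classes)
    for p in range(n_classes):
        for q in range(p + 1, n_classes):
            sel = (y_tr == p) | (y_tr == q)
            if not sel.any():
                continue
            Xs, ys = X_tr[sel], y_tr[sel]
            y_pm = np.where(ys == p, 1.0, -1.0)
            K = _kernel(Xs, Xs, spec)
            b, alpha = _lssvm_train(K, y_pm, spec.C)
            f = float((alpha * y_pm) @ _kernel(Xs, x[None, :], spec)[:, 0] + b)
            votes[p if f >= 0 else q] += 1.0
    return _pick(votes, priority)


def loo_evaluate(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    arrangement: str = "",
    feature_cols: tuple[str, ...] = FEATURE_COLUMNS,
    standardize_mode: str = "global",
) -> EvalReport:
    """Leave-one-out evaluation of one classifier on one feature table.

    Exactly n fits, each tested on the held-out signal; deterministic for
    a fixed ``spec.seed`` (which drives forest construction and
    tie-breaking).  ``standardize_mode="global"`` z-scores the whole table
    first (the study's literal order of operations); ``"per_fold"`` uses
    training-fold statistics only.
    """
    if standardize_mode not in ("global", "per_fold"):
        raise ValueError(f"unknown standardize_mode {standardize_mode!r}")
    classes = [lbl for lbl in CLASS_LABELS if lbl in set(table["label"])]
    extra = [lbl for lbl in dict.fromkeys(table["label"]) if lbl not in classes]
    classes += extra
    n_classes = len(classes)
    if len(table) < n_classes + 1:
        raise ValueError("need at least one more signal than classes")
    code = {lbl: i for i, lbl in enumerate(classes)}
    y = table["label"].map(code).to_numpy()
    X_raw = table.loc[:, list(feature_cols)].to_numpy(dtype=float)
    if standardize_mode == "global":
        sd = X_raw.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X_all = (X_raw - X_raw.mean(axis=0)) / sd
    else:
        X_all = X_raw

    rng = np.random.default_rng(spec.seed)
    priority = rng.permutation(n_classes)
    n = len(y)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        X_tr, y_tr, x = X_all[train], y[train], X_all[i]
        if standardize_mode == "per_fold":
            mu, s = X_tr.mean(axis=0), X_tr.std(axis=0, ddof=0)
            s[s == 0] = 1.0
            X_tr, x = (X_tr - mu) / s, (x - mu) / s
        if spec.family == "knn":
            preds[i] = _predict_knn(X_tr, y_tr, x, spec, n_classes, priority)
        elif spec.family == "ls_svm":
            preds[i] = _predict_lssvm(X_tr, y_tr, x, spec, n_classes, priority)
        else:
            clf = RandomForestClassifier(
                n_estimators=spec.n_trees, max_features="sqrt",
                random_state=spec.seed, n_jobs=1,
            )
            clf.fit(X_tr, y_tr)
            preds[i] = int(clf.predict(x[None, :])[0])

    conf = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(conf, (y, preds), 1)
    confusion = pd.DataFrame(conf, index=classes, columns=classes)
    row_totals = conf.sum(axis=1)
    tpr = {
        lbl: 100.0 * conf[i, i] / row_totals[i] if row_totals[i] else float("nan")
        for i, lbl in enumerate(classes)
    }
    accuracy = 100.0 * np.trace(conf) / n
    return EvalReport(arrangement, spec, confusion, tpr, accuracy, standardize_mode)


def run_grid(
    table: pd.DataFrame,
    arrangements: "list[str]",
    specs: "list[ClassifierSpec]",
    feature_cols: tuple[str, ...] = FEATURE_COLUMNS,
    standardize_mode: str = "global",
) -> tuple[list[EvalReport], pd.DataFrame]:
    """Evaluate every (arrangement, spec) pair; return reports + ranked table.

    The ranked table mirrors the published layout (one row per
    configuration, TPR columns in LQT1, HCM, CPVT, WT order, accuracy
    last) with the best-accuracy row per arrangement flagged.
    """
    reports = []
    for arr in arrangements:
        sub = select_arrangement(table, arr)
        for spec in specs:
            reports.append(
                loo_evaluate(sub, spec, arrangement=arr,
                             feature_cols=feature_cols,
                             standardize_mode=standardize_mode)
            )
    ranked = pd.DataFrame([r.summary_row() for r in reports])
    ranked["best"] = False
    for arr, grp in ranked.groupby("arrangement"):
        ranked.loc[grp["accuracy"].idxmax(), "best"] = True
    return reports, ranked
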