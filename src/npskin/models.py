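"""QSPR classifier families, evaluation metrics, and variable importance.

The selection grid crosses the four data-division methods with four
classifier families (PLS-DA, decision tree, kernel SVM, random forest
with 500 trees); each cell is the percent accuracy on the common random
hold-out set.  k-nearest neighbours is implemented as a fifth family but
excluded from the headline grid by default.

Agreement beyond chance is measured by Cohen's kappa computed from the
confusion matrix,

    kappa = (N * sum_i m_ii - sum_i G_i C_i) / (N^2 - sum_i G_i C_i),

with ``N`` total predictions, ``m_ii`` the diagonal counts, ``G_i`` the
row (true-class) and ``C_i`` the column (predicted-class) marginals.

PLS variable importance in projection is

    VIP_j = sqrt( J * sum_f w~_jf^2 SSY_f / sum_f SSY_f ),

with per-component-normalized x-weights ``w~`` and per-component
explained sum of squares ``SSY_f``; the scores satisfy
``sum_j VIP_j^2 = J`` exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from npskin.datamodel import (
    DEPTH_CLASSES,
    DatasetError,
    FeatureMatrix,
    depth_to_int,
    feature_group_columns,
    int_to_depth,
)
from npskin.splitting import SPLIT_METHODS, holdout_split, split_modeling

CLASSIFIER_FAMILIES = ("decision_tree", "random_forest", "knn", "pls_da", "ksvm")
#: headline grid rows (k-NN implemented but reported separately)
GRID_FAMILIES = ("pls_da", "decision_tree", "ksvm", "random_forest")


@dataclass
class ClassifierSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in CLASSIFIER_FAMILIES:
            raise DatasetError(f"unknown classifier family {self.family!r}")
        if self.family == "random_forest":
            self.hyperparameters.setdefault("n_estimators", 500)
            if self.hyperparameters["n_estimators"] < 1:
                raise DatasetError("random forest needs >= 1 tree")


class PLSDAClassifier:
    """PLS-DA: one-hot PLS dimension reduction, LDA on the latent scores.

    Class-membership columns are regressed on the descriptors with
    ``n_components`` latent components; a linear discriminant fitted on
    the x-scores assigns classes — the standard two-step PLS-DA
    formulation, which places class boundaries by the score-space class
    structure rather than by the raw least-squares responses.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        Y = np.zeros((len(y), len(self.classes_)))
        for k, c in enumerate(self.classes_):
            Y[y == c, k] = 1.0
        ncomp = min(self.n_components, X.shape[1], len(X) - 1)
        self.pls_ = PLSRegression(n_components=ncomp, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.pls_.fit(X, Y)
            self.lda_ = LinearDiscriminantAnalysis()
            self.lda_.fit(self.pls_.transform(X), y)
        return self

    def predict(self, X):
        return self.lda_.predict(self.pls_.transform(X))

    def vip(self) -> np.ndarray:
        """VIP scores of the fitted model (see :func:`vip_scores`)."""
        pls = self.pls_
        W = pls.x_weights_  # (J, F)
        T = pls.x_scores_  # (n, F)
        Q = pls.y_loadings_  # (K, F)
        ssy = np.array([
            (T[:, f] ** 2).sum() * (Q[:, f] ** 2).sum() for f in range(W.shape[1])
        ])
        return vip_scores(VIPInputs(W=W, ssy=ssy))


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width from the median pairwise squared distance."""
    X = np.asarray(X, float)
    if len(X) > 500:
        X = X[np.linspace(0, len(X) - 1, 500).astype(int)]
    d2 = pdist(X, "sqeuclidean")
    med = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
    return 1.0 / med


class _ModelWrapper:
    """Fitted model predicting string depth labels.

    Labels are trained as ordinal codes 0 (Surface) .. 4 (Distant), so
    estimator tie-breaks toward the lowest code resolve toward the
    shallower layer.
    """

    def __init__(self, est, spec: ClassifierSpec, classes_as_int: bool):
        self.est = est
        self.spec = spec
        self._int = classes_as_int

    def predict(self, X) -> np.ndarray:
        pred = self.est.predict(np.asarray(X, float))
        return int_to_depth(pred) if self._int else np.asarray(pred)


def train_classifier(spec: ClassifierSpec, X_train, y_train) -> _ModelWrapper:
    """Fit one classifier family on encoded training data."""
    X = np.asarray(X_train, float)
    y = np.asarray(y_train)
    if len(np.unique(y)) < 2:
        raise DatasetError("training data contains a single class")
    hp = dict(spec.hyperparameters)
    yi = depth_to_int(y)
    as_int = True
    if spec.family == "decision_tree":
        est = DecisionTreeClassifier(
            max_depth=hp.get("max_depth"), random_state=spec.seed
        )
    elif spec.family == "random_forest":
        est = RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 500),
            max_features=hp.get("max_features", "sqrt"),
            random_state=spec.seed,
            n_jobs=1,
        )
    elif spec.family == "knn":
        est = KNeighborsClassifier(n_neighbors=hp.get("k", 5))
    elif spec.family == "pls_da":
        est = PLSDAClassifier(n_components=hp.get("n_components", 2))
    elif spec.family == "ksvm":
        gamma = hp.get("gamma") or median_heuristic_gamma(X)
        est = SVC(
            kernel="rbf", C=hp.get("C", 10.0), gamma=gamma,
            decision_function_shape="ovo", random_state=spec.seed,
        )
    est.fit(X, yi)
    return _ModelWrapper(est, spec, as_int)


#: per-family hyperparameter grids searched on the validation set
TUNING_GRIDS = {
    "decision_tree": [{"max_depth": d} for d in (None, 3, 5, 8, 12)],
    "random_forest": [{"max_features": f} for f in ("sqrt", None)],
    "knn": [{"k": k} for k in (1, 3, 5, 7, 9)],
    "pls_da": [{"n_components": f} for f in range(1, 11)],
    "ksvm": [
        {"C": c, "gamma_scale": g}
        for c in (1.0, 10.0, 100.0, 1000.0)
        for g in (0.25, 0.5, 1.0, 2.0)
    ],
}


def tune_classifier(
    family: str, X_train, y_train, X_val, y_val, seed: int = 0
) -> tuple[_ModelWrapper, dict]:
    """Grid-search the family's hyperparameters by validation accuracy.

    Returns the best model refitted on train+validation together with
    the winning hyperparameters.
    """
    best_acc, best_hp, best_model = -1.0, {}, None
    gamma0 = median_heuristic_gamma(np.asarray(X_train, float))
    for hp in TUNING_GRIDS[family]:
        hp = dict(hp)
        if "gamma_scale" in hp:
            hp["gamma"] = gamma0 * hp.pop("gamma_scale")
        if family == "pls_da" and hp["n_components"] > np.asarray(X_train).shape[1]:
            continue
        model = train_classifier(ClassifierSpec(family, hp, seed), X_train, y_train)
        acc, _, _ = evaluate(model, X_val, y_val)
        if acc > best_acc:
            best_acc, best_hp, best_model = acc, hp, model
    X_all = np.vstack([X_train, X_val])
    y_all = np.concatenate([np.asarray(y_train), np.asarray(y_val)])
    final = train_classifier(ClassifierSpec(family, dict(best_hp), seed), X_all, y_all)
    return final, best_hp


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """k x k counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    labels: tuple[str, ...] = DEPTH_CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise DatasetError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise DatasetError("negative confusion counts")

    @property
    def N(self) -> float:
        return float(self.counts.sum())

    @property
    def m_ii(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def G(self) -> np.ndarray:  # true-class marginals (rows)
        return self.counts.sum(axis=1)

    @property
    def C(self) -> np.ndarray:  # predicted-class marginals (columns)
        return self.counts.sum(axis=0)

    def accuracy(self) -> float:
        return 100.0 * self.m_ii.sum() / self.N

    def kappa(self) -> float:
        gc = float(np.dot(self.G, self.C))
        denom = self.N**2 - gc
        if denom == 0:
            return 0.0
        return (self.N * self.m_ii.sum() - gc) / denom

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def confusion_matrix_from_labels(y_true, y_pred, labels=DEPTH_CLASSES) -> ConfusionMatrix:
    lut = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))
    extra = set()
    for t, p in zip(y_true, y_pred):
        if t not in lut or p not in lut:
            extra.add(p if p not in lut else t)
            continue
        counts[lut[t], lut[p]] += 1
    if extra:
        warnings.warn(f"labels outside the class set counted as errors: {extra}")
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


def evaluate(model, X, y) -> tuple[float, float, ConfusionMatrix]:
    """Percent accuracy, Cohen's kappa and the confusion matrix."""
    y = np.asarray(y)
    if len(y) == 0:
        raise DatasetError("empty evaluation set")
    pred = model.predict(np.asarray(X, float))
    cm = confusion_matrix_from_labels(y, pred)
    return cm.accuracy(), cm.kappa(), cm


# ---------------------------------------------------------------------------
# variable importance
# ---------------------------------------------------------------------------


@dataclass
class VIPInputs:
    """x-weights ``W`` (J x F) and per-component explained SS ``ssy``."""

    W: np.ndarray
    ssy: np.ndarray

    def __post_init__(self):
        self.W = np.atleast_2d(np.asarray(self.W, float))
        self.ssy = np.asarray(self.ssy, float).ravel()
        if self.W.shape[1] != len(self.ssy):
            raise DatasetError("W columns must match len(ssy)")
        if np.any(self.ssy < 0):
            raise DatasetError("SSY must be non-negative")
        if self.ssy.sum() <= 0:
            raise DatasetError("zero total explained sum of squares")

    @property
    def J(self) -> int:
        return self.W.shape[0]

    @property
    def F(self) -> int:
        return self.W.shape[1]


def vip_scores(inputs: VIPInputs) -> np.ndarray:
    """Variable importance in projection for each of the J x-variables."""
    W = inputs.W
    norms = np.sqrt((W**2).sum(axis=0))
    norms[norms == 0] = 1.0
    W2 = (W / norms) ** 2
    return np.sqrt(inputs.J * (W2 @ inputs.ssy) / inputs.ssy.sum())


@dataclass
class ImportanceTable:
    """Per-descriptor importance on a 0-100 scale, overall and per layer.

    The top descriptor of the overall model maps to 100; the comparative
    reporting threshold used in figures is 10.
    """

    scores: pd.DataFrame  # index: descriptor, columns: overall + layers
    method: str = "permutation"
    threshold: float = 10.0
    raw: pd.DataFrame | None = None  # unscaled mean accuracy drops

    def ranked(self, column: str = "overall") -> pd.Series:
        return self.scores[column].sort_values(ascending=False)


def permutation_importance_table(
    model,
    fm_val: FeatureMatrix,
    y_val,
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceTable:
    """Grouped permutation importance on validation data.

    Each named descriptor (one-hot groups permuted jointly) is shuffled
    ``n_repeats`` times; importance is the mean accuracy drop, rescaled
    so the strongest overall descriptor scores 100.  Per-layer scores
    repeat the computation on the one-vs-rest agreement for that layer.
    Constant columns get importance 0.
    """
    rng = np.random.default_rng(seed)
    X = fm_val.values
    y = np.asarray(y_val)
    groups = feature_group_columns(fm_val)
    base_pred = model.predict(X)
    base_acc = float(np.mean(base_pred == y))
    base_layer = {
        c: float(np.mean((base_pred == c) == (y == c))) for c in DEPTH_CLASSES
    }
    drops = {}
    layer_drops = {c: {} for c in DEPTH_CLASSES}
    for name, cols in groups.items():
        if np.all(X[:, cols] == X[0, cols]):
            drops[name] = 0.0
            for c in DEPTH_CLASSES:
                layer_drops[c][name] = 0.0
            continue
        accs, laccs = [], {c: [] for c in DEPTH_CLASSES}
        for _ in range(n_repeats):
            Xp = X.copy()
            perm = rng.permutation(len(X))
            Xp[:, cols] = Xp[np.ix_(perm, cols)]
            pred = model.predict(Xp)
            accs.append(float(np.mean(pred == y)))
            for c in DEPTH_CLASSES:
                laccs[c].append(float(np.mean((pred == c) == (y == c))))
        drops[name] = base_acc - float(np.mean(accs))
        for c in DEPTH_CLASSES:
            layer_drops[c][name] = base_layer[c] - float(np.mean(laccs[c]))

    table = pd.DataFrame({"overall": drops})
    for c in DEPTH_CLASSES:
        table[c] = pd.Series(layer_drops[c])
    top = table["overall"].max()
    scale = 100.0 / top if top > 0 else 0.0
    scaled = (table * scale).clip(lower=0.0)
    return ImportanceTable(scores=scaled, method="permutation", raw=table)


# ---------------------------------------------------------------------------
# selection grid
# ---------------------------------------------------------------------------


@dataclass
class GridResult:
    """Splitter x classifier hold-out accuracies with marginal averages."""

    accuracy: pd.DataFrame  # rows: classifiers (+Average), cols: splitters (+Average)
    kappa: pd.DataFrame
    confusions: dict[tuple[str, str], ConfusionMatrix]
    assignments: dict[str, object]
    best_hyperparameters: dict[tuple[str, str], dict]


def selection_grid(
    fm: FeatureMatrix,
    y,
    seed: int = 0,
    splitters=SPLIT_METHODS,
    classifiers=GRID_FAMILIES,
    holdout_fraction: float = 0.2,
    train_fraction: float = 0.75,
    tune: bool = True,
) -> GridResult:
    """Cross every division method with every classifier family.

    The hold-out cut (random, common to all cells) is made first; each
    splitter then divides the modelling rows into train / validation,
    hyperparameters are searched on validation, and the refitted model
    is scored on the untouched hold-out rows.
    """
    if fm.missing_mask.any():
        raise DatasetError("selection grid requires an imputed matrix")
    y = np.asarray(y)
    ids = list(range(fm.n_records))
    modeling, holdout = holdout_split(ids, fraction=holdout_fraction, seed=seed)
    X = fm.values
    acc = pd.DataFrame(index=list(classifiers), columns=list(splitters), dtype=float)
    kap = acc.copy()
    confusions, assignments, best_hp = {}, {}, {}
    for sp in splitters:
        assign = split_modeling(
            sp, X[modeling], modeling, train_fraction=train_fraction, seed=seed + 1
        )
        assign.holdout_ids = list(holdout)
        assignments[sp] = assign
        tr, va = assign.train_ids, assign.validation_ids
        for fam in classifiers:
            if tune:
                model, hp = tune_classifier(
                    fam, X[tr], y[tr], X[va], y[va], seed=seed
                )
            else:
                model = train_classifier(
                    ClassifierSpec(fam, seed=seed),
                    np.vstack([X[tr], X[va]]),
                    np.concatenate([y[tr], y[va]]),
                )
                hp = {}
            a, k, cm = evaluate(model, X[holdout], y[holdout])
            acc.loc[fam, sp] = a
            kap.loc[fam, sp] = k
            confusions[(fam, sp)] = cm
            best_hp[(fam, sp)] = hp
    acc["Average"] = acc.mean(axis=1)
    acc.loc["Average"] = acc.mean(axis=0)
    kap["Average"] = kap.mean(axis=1)
    kap.loc["Average"] = kap.mean(axis=0)
    return GridResult(
        accuracy=acc, kappa=kap, confusions=confusions,
        assignments=assignments, best_hyperparameters=best_hp,
    )
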