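"""Candidate model zoo and the two stacked generalizations (FSGC / SSGR).

The framework uses two Wolpert stacks: a *classifier* stack (FSGC) whose
cross-validated variety-classification accuracy drives wavelength selection,
and a *regressor* stack (SSGR) that predicts nitrogen and organic matter —
jointly — from the selected channels.

Stacking is implemented directly (out-of-fold base predictions feed a meta
learner; base learners then refit on all rows) rather than via
``sklearn.ensemble.StackingClassifier``, because the regression stack needs
joint multi-output meta-features (all base predictions for both targets seen
by one meta ridge). The scikit-learn stacking estimators serve as an
independent cross-check in the test-suite.

Default hyperparameters are the grid-search optima reported for the study's
data (SVM: C=1, gamma=0.01, RBF; logistic: C=100, l2, newton-cg; KNN:
1 neighbor, uniform, Euclidean; random forest: 200 trees, depth 80;
MLP: tanh, alpha=1e-4; ridge: strength 0.1).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression, Ridge, RidgeClassifier
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.svm import SVC, SVR

__all__ = [
    "ModelSpec",
    "StackSpec",
    "FittedStack",
    "BenchmarkRow",
    "default_model_specs",
    "default_regressor_specs",
    "grid_search_cv",
    "benchmark_candidates",
    "select_stack_members",
    "build_fsgc",
    "build_ssgr",
    "fit_stack",
    "predict_stack",
    "cv_accuracy",
]

CLASSIFIER_FAMILIES = ("svm", "knn", "logistic", "ridge", "mlp", "gaussian_nb", "random_forest")
REGRESSOR_FAMILIES = ("svr", "knn", "ridge", "mlp", "pls", "random_forest")


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus hyperparameters, flavored classifier or regressor."""

    family: str
    task: str = "classifier"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in ("classifier", "regressor"):
            raise ValueError("task must be 'classifier' or 'regressor'")
        valid = CLASSIFIER_FAMILIES if self.task == "classifier" else REGRESSOR_FAMILIES
        if self.family not in valid:
            raise ValueError(f"family {self.family!r} is not a valid {self.task}")

    def to_estimator(self, seed: int | None = None):
        """Build the scikit-learn estimator configured by this spec."""
        hp = dict(self.hyperparameters)
        if self.task == "classifier":
            return _build_classifier(self.family, hp, seed)
        return _build_regressor(self.family, hp, seed)

    def to_json(self) -> str:
        hp = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.hyperparameters.items()}
        return json.dumps({"family": self.family, "task": self.task, "hyperparameters": hp})

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        obj = json.loads(text)
        return cls(obj["family"], obj["task"], obj.get("hyperparameters", {}))


def _build_classifier(family: str, hp: dict, seed: int | None):
    if family == "svm":
        return SVC(C=hp.get("C", 1.0), gamma=hp.get("gamma", 0.01), kernel=hp.get("kernel", "rbf"))
    if family == "logistic":
        kwargs = dict(
            C=hp.get("C", 100.0),
            solver=hp.get("solver", "newton-cg"),
            max_iter=hp.get("max_iter", 500),
        )
        # l2 is sklearn's default; forwarding it explicitly is deprecated
        if hp.get("penalty", "l2") != "l2":
            kwargs["penalty"] = hp["penalty"]
        return LogisticRegression(**kwargs)
    if family == "knn":
        return KNeighborsClassifier(
            n_neighbors=hp.get("n_neighbors", 1),
            weights=hp.get("weights", "uniform"),
            metric=hp.get("metric", "euclidean"),
        )
    if family == "ridge":
        # ridge-penalized least squares on one-hot labels (standard ridge classifier)
        return RidgeClassifier(alpha=hp.get("regularization_strength", 0.1))
    if family == "mlp":
        return MLPClassifier(
            activation=hp.get("activation", "tanh"),
            alpha=hp.get("alpha", 1e-4),
            hidden_layer_sizes=tuple(hp.get("hidden_layer_sizes", (100,))),
            learning_rate=hp.get("learning_rate", "constant"),
            solver=hp.get("solver", "adam"),
            max_iter=hp.get("max_iter", 2000),
            random_state=seed,
        )
    if family == "gaussian_nb":
        return GaussianNB()
    if family == "random_forest":
        return RandomForestClassifier(
            max_depth=hp.get("max_depth", 80),
            max_features=hp.get("max_features", 2),
            min_samples_leaf=hp.get("min_samples_leaf", 3),
            min_samples_split=hp.get("min_samples_split", 10),
            n_estimators=hp.get("n_estimators", 200),
            random_state=seed,
        )
    raise ValueError(f"unknown classifier family {family!r}")


def _build_regressor(family: str, hp: dict, seed: int | None):
    if family == "svr":
        return SVR(C=hp.get("C", 1.0), gamma=hp.get("gamma", 0.01), kernel=hp.get("kernel", "rbf"))
    if family == "knn":
        return KNeighborsRegressor(
            n_neighbors=hp.get("n_neighbors", 1),
            weights=hp.get("weights", "uniform"),
            metric=hp.get("metric", "euclidean"),
        )
    if family == "ridge":
        return Ridge(alpha=hp.get("regularization_strength", 0.1))
    if family == "mlp":
        return MLPRegressor(
            activation=hp.get("activation", "tanh"),
            alpha=hp.get("alpha", 1e-4),
            hidden_layer_sizes=tuple(hp.get("hidden_layer_sizes", (100,))),
            solver=hp.get("solver", "adam"),
            max_iter=hp.get("max_iter", 2000),
            random_state=seed,
        )
    if family == "pls":
        from sklearn.cross_decomposition import PLSRegression

        return PLSRegression(n_components=hp.get("n_latent", 9))
    if family == "random_forest":
        return RandomForestRegressor(
            n_estimators=hp.get("n_estimators", 200), random_state=seed
        )
    raise ValueError(f"unknown regressor family {family!r}")


def default_model_specs() -> dict[str, ModelSpec]:
    """Printed-optimum specs for the seven classifier families plus SVR/PLS."""
    return {
        "svm": ModelSpec("svm", "classifier", {"C": 1.0, "gamma": 0.01, "kernel": "rbf"}),
        "logistic": ModelSpec(
            "logistic", "classifier", {"C": 100.0, "penalty": "l2", "solver": "newton-cg"}
        ),
        "knn": ModelSpec(
            "knn", "classifier", {"n_neighbors": 1, "weights": "uniform", "metric": "euclidean"}
        ),
        "ridge": ModelSpec("ridge", "classifier", {"regularization_strength": 0.1}),
        "mlp": ModelSpec(
            "mlp",
            "classifier",
            {"activation": "tanh", "alpha": 1e-4, "hidden_layer_sizes": (100,)},
        ),
        "gaussian_nb": ModelSpec("gaussian_nb", "classifier", {}),
        "random_forest": ModelSpec(
            "random_forest",
            "classifier",
            {
                "max_depth": 80,
                "max_features": 2,
                "min_samples_leaf": 3,
                "min_samples_split": 10,
                "n_estimators": 200,
            },
        ),
        "svr": ModelSpec("svr", "regressor", {"C": 1.0, "gamma": 0.01, "kernel": "rbf"}),
        "pls": ModelSpec("pls", "regressor", {"n_latent": 9}),
    }


def default_regressor_specs() -> dict[str, ModelSpec]:
    """Regression counterparts sharing the classifier hyperparameters."""
    return {
        "svr": ModelSpec("svr", "regressor", {"C": 1.0, "gamma": 0.01, "kernel": "rbf"}),
        "knn": ModelSpec(
            "knn", "regressor", {"n_neighbors": 1, "weights": "uniform", "metric": "euclidean"}
        ),
        "ridge": ModelSpec("ridge", "regressor", {"regularization_strength": 0.1}),
        "mlp": ModelSpec(
            "mlp", "regressor", {"activation": "tanh", "alpha": 1e-4, "hidden_layer_sizes": (100,)}
        ),
        "pls": ModelSpec("pls", "regressor", {"n_latent": 9}),
    }


def grid_search_cv(
    family: str,
    grid: dict[str, list],
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    task: str = "classifier",
    seed: int = 0,
) -> tuple[ModelSpec, float]:
    """Exhaustive k-fold grid search; ties go to the first grid point.

    Classification uses stratified folds and accuracy; regression plain
    shuffled folds and negative RMSE.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    base = ModelSpec(family, task, {}).to_estimator(seed=seed)
    # translate spec-level hyperparameter names to estimator params
    alias = {"regularization_strength": "alpha", "n_latent": "n_components"}
    sk_grid = {alias.get(k, k): v for k, v in grid.items()}
    if task == "classifier":
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        scoring = "accuracy"
    else:
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        scoring = "neg_root_mean_squared_error"
    search = GridSearchCV(base, sk_grid, cv=cv, scoring=scoring)
    search.fit(X, y)
    inv = {v: k for k, v in alias.items()}
    best = {inv.get(k, k): v for k, v in search.best_params_.items()}
    return ModelSpec(family, task, best), float(search.best_score_)


@dataclass
class BenchmarkRow:
    """Screening result for one candidate family."""

    family: str
    accuracy: float
    fit_time: float  # mean wall seconds per CV fit+score (informational)


def benchmark_candidates(
    dataset, families=CLASSIFIER_FAMILIES, folds: int = 5, seed: int = 0
) -> list[BenchmarkRow]:
    """Cross-validated variety-classification accuracy and timing per family.

    Rows come back sorted by (accuracy desc, time asc) — the screening order
    used to pick stack members.
    """
    specs = default_model_specs()
    X, y = dataset.reflectance, dataset.variety
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for family in families:
        spec = specs.get(family, ModelSpec(family, "classifier", {}))
        est = spec.to_estimator(seed=seed)
        t0 = time.perf_counter()
        scores = cross_val_score(est, X, y, cv=cv, scoring="accuracy")
        elapsed = (time.perf_counter() - t0) / folds
        rows.append(BenchmarkRow(family=family, accuracy=float(scores.mean()), fit_time=elapsed))
    rows.sort(key=lambda r: (-r.accuracy, r.fit_time))
    return rows


def select_stack_members(rows: list[BenchmarkRow], k: int = 4) -> list[str]:
    """Top-k families by (accuracy desc, time asc)."""
    if k < 2:
        raise ValueError("a stack needs at least 2 members")
    if k > len(rows):
        raise ValueError("k exceeds the number of benchmarked families")
    ranked = sorted(rows, key=lambda r: (-r.accuracy, r.fit_time))
    return [r.family for r in ranked[:k]]


@dataclass
class StackSpec:
    """Base learners + meta learner of one stacked generalization."""

    base: list[ModelSpec]
    meta: ModelSpec
    internal_folds: int = 5
    task: str = "classifier"

    def __post_init__(self) -> None:
        if len(self.base) < 2:
            raise ValueError("a stack needs at least 2 base members")
        for spec in self.base:
            if spec.task != self.task:
                raise ValueError(
                    f"base member {spec.family!r} is a {spec.task}, but the stack is a {self.task}"
                )
        if self.meta.task != self.task:
            raise ValueError("meta learner task must match the stack task")

    def to_json(self) -> str:
        return json.dumps(
            {
                "base": [json.loads(m.to_json()) for m in self.base],
                "meta": json.loads(self.meta.to_json()),
                "internal_folds": self.internal_folds,
                "task": self.task,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StackSpec":
        obj = json.loads(text)
        return cls(
            base=[ModelSpec(m["family"], m["task"], m.get("hyperparameters", {})) for m in obj["base"]],
            meta=ModelSpec(obj["meta"]["family"], obj["meta"]["task"], obj["meta"].get("hyperparameters", {})),
            internal_folds=obj.get("internal_folds", 5),
            task=obj["task"],
        )


def build_fsgc(members: list[ModelSpec] | None = None, internal_folds: int = 5) -> StackSpec:
    """The classification stack: SVM, KNN, logistic and ridge base learners
    (the four screening survivors) with a logistic-regression meta learner."""
    if members is None:
        specs = default_model_specs()
        members = [specs["svm"], specs["knn"], specs["logistic"], specs["ridge"]]
    return StackSpec(
        base=list(members),
        meta=ModelSpec("logistic", "classifier", {"C": 1.0, "solver": "newton-cg", "max_iter": 200}),
        internal_folds=internal_folds,
        task="classifier",
    )


def build_ssgr(members: list[ModelSpec] | None = None, internal_folds: int = 5) -> StackSpec:
    """The regression stack: the FSGC members with logistic regression (binary
    only) swapped for an MLP regressor; ridge meta learner; predicts N and OM
    jointly."""
    if members is None:
        specs = default_regressor_specs()
        members = [specs["svr"], specs["knn"], specs["mlp"], specs["ridge"]]
    return StackSpec(
        base=list(members),
        meta=ModelSpec("ridge", "regressor", {"regularization_strength": 0.1}),
        internal_folds=internal_folds,
        task="regressor",
    )


@dataclass
class FittedStack:
    """Fitted state of a stack: full-data base learners + OOF-trained meta."""

    spec: StackSpec
    base_models: list  # classifier: one estimator per member; regressor: list per member (one per target)
    meta_model: object
    classes_: np.ndarray | None
    n_features: int
    n_targets: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_stack(self, X)


def fit_stack(spec: StackSpec, X: np.ndarray, y: np.ndarray, seed: int = 0) -> FittedStack:
    """Wolpert stacking: meta learner trains on out-of-fold base predictions.

    Each base learner produces out-of-fold predictions via internal
    (stratified) k-fold on the training rows; the meta learner is trained on
    those; base learners are then refit on all rows. Classifier
    meta-features are class-probability vectors where the family supports
    them and decision scores otherwise; regressor meta-features are the raw
    per-target predictions of every member, concatenated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < spec.internal_folds:
        raise ValueError("fewer rows than internal folds")
    rng_seed = int(seed) % (2**31)
    if spec.task == "classifier":
        classes = np.unique(y)
        min_class = int(np.unique(y, return_counts=True)[1].min())
        if min_class < 2:
            raise ValueError("every class needs >= 2 training rows for stratified stacking")
        # cap internal folds so every class appears in every training fold
        n_splits = min(spec.internal_folds, min_class)
        folds = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rng_seed)
        split = list(folds.split(X, y))
        meta_blocks = []
        for j, member in enumerate(spec.base):
            oof = None
            for tr, te in split:
                est = member.to_estimator(seed=rng_seed + j)
                est.fit(X[tr], y[tr])
                feats = _classifier_meta_features(est, X[te], classes)
                if oof is None:
                    oof = np.zeros((n, feats.shape[1]))
                oof[te] = feats
            meta_blocks.append(oof)
        Z = np.hstack(meta_blocks)
        meta = spec.meta.to_estimator(seed=rng_seed)
        meta.fit(Z, y)
        base_models = []
        for j, member in enumerate(spec.base):
            est = member.to_estimator(seed=rng_seed + j)
            est.fit(X, y)
            base_models.append(est)
        return FittedStack(spec, base_models, meta, classes, X.shape[1], 1)

    Y = y.reshape(n, -1).astype(float)
    n_targets = Y.shape[1]
    folds = KFold(n_splits=spec.internal_folds, shuffle=True, random_state=rng_seed)
    split = list(folds.split(X))
    meta_blocks = []
    for j, member in enumerate(spec.base):
        oof = np.zeros((n, n_targets))
        for tr, te in split:
            for t in range(n_targets):
                est = member.to_estimator(seed=rng_seed + j)
                est.fit(X[tr], Y[tr, t])
                oof[te, t] = np.ravel(est.predict(X[te]))
        meta_blocks.append(oof)
    Z = np.hstack(meta_blocks)
    meta = spec.meta.to_estimator(seed=rng_seed)
    meta.fit(Z, Y if n_targets > 1 else Y[:, 0])
    base_models = []
    for j, member in enumerate(spec.base):
        per_target = []
        for t in range(n_targets):
            est = member.to_estimator(seed=rng_seed + j)
            est.fit(X, Y[:, t])
            per_target.append(est)
        base_models.append(per_target)
    return FittedStack(spec, base_models, meta, None, X.shape[1], n_targets)


def _classifier_meta_features(est, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Per-class probability columns, or decision scores where unsupported."""
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(X)
        out = np.zeros((X.shape[0], classes.size))
        col = {c: i for i, c in enumerate(classes)}
        for i, c in enumerate(est.classes_):
            out[:, col[c]] = proba[:, i]
        return out
    scores = est.decision_function(X)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[1] == classes.size:
        return scores
    out = np.zeros((X.shape[0], classes.size))
    col = {c: i for i, c in enumerate(classes)}
    for i, c in enumerate(est.classes_):
        out[:, col[c]] = scores[:, i] if scores.shape[1] > 1 else scores[:, 0]
    return out


def predict_stack(fitted: FittedStack, X: np.ndarray) -> np.ndarray:
    """Meta-learner prediction from base-learner outputs on new rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != fitted.n_features:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} features, stack was trained on {fitted.n_features}"
        )
    if fitted.spec.task == "classifier":
        blocks = [
            _classifier_meta_features(est, X, fitted.classes_) for est in fitted.base_models
        ]
        return fitted.meta_model.predict(np.hstack(blocks))
    blocks = []
    for per_target in fitted.base_models:
        preds = np.column_stack([np.ravel(est.predict(X)) for est in per_target])
        blocks.append(preds)
    out = fitted.meta_model.predict(np.hstack(blocks))
    return np.asarray(out)


def cv_accuracy(spec: StackSpec, X: np.ndarray, y: np.ndarray, folds: int = 5, seed: int = 0) -> float:
    """Mean stratified k-fold accuracy of the whole stack (refit per fold)."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng_seed = int(seed) % (2**31)
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() >= folds:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
        split = cv.split(X, y)
    else:
        cv = KFold(n_splits=folds, shuffle=True, random_state=rng_seed)
        split = cv.split(X)
    accs = []
    for tr, te in split:
        fitted = fit_stack(spec, X[tr], y[tr], seed=rng_seed)
        accs.append(float(np.mean(predict_stack(fitted, X[te]) == y[te])))
    return float(np.mean(accs))
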