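"""Regression models, chemometric metrics, and the selector comparison harness.

Metrics follow the usual multivariate-calibration conventions: R²c / RMSEC
on the calibration set, R²p / RMSEP on the prediction set, and a
pseudounivariate limit of detection LOD = 3.3·s_res/|b₁| from the
least-squares line of predicted on true concentrations (the 3.3 factor is
the conventional ~95%/95% false-positive/false-negative choice; it is
configurable because no single LOD definition is universal in multivariate
calibration).

The comparison harness mirrors the two study comparisons: feature selectors
(wrapper PSO with a stacked or single-SVM fitness, a genetic algorithm, and
lasso) each feeding a shared multi-output ridge; and the regressor lineup
(stacked regressor vs ridge, SVR, PLS at several latent-variable counts) on
a fixed calibration/prediction split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import Lasso, LassoCV, Ridge
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .data import (
    FeatureMask,
    SpectraDataset,
    apply_feature_mask,
    split_calibration_prediction,
    standardize_apply,
    standardize_fit,
)
from .models import ModelSpec, StackSpec, default_model_specs
from .pso import PSOConfig, make_subset_fitness, run_pso

__all__ = [
    "Metrics",
    "ComparisonRow",
    "GAConfig",
    "r_squared",
    "rmse",
    "lod",
    "fit_ridge_multioutput",
    "fit_pls",
    "lasso_select",
    "ga_select",
    "pso_svm_select",
    "evaluate_model",
    "evaluate_predictions",
    "compare_feature_selectors",
]


@dataclass
class Metrics:
    """Calibration/prediction figures of merit for one target property."""

    r2c: float
    rmsec: float
    r2p: float
    rmsep: float
    lod: float


@dataclass
class ComparisonRow:
    """One selector (or baseline) scored through the shared ridge regressor."""

    selector: str
    regressor: str
    n_selected: int
    r2c: float
    rmsec: float
    r2p: float
    rmsep: float


@dataclass
class GAConfig:
    """Generational GA settings: tournament selection, one-point crossover,
    per-bit mutation, elitism of one."""

    population: int = 50
    generations: int = 10
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # default 1/D at run time
    tournament: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


# ---------------------------------------------------------------------------
# Metrics


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SSE/SST."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size < 2:
        raise ValueError("need at least 2 points")
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        raise ValueError("y_true is constant; R^2 undefined")
    sse = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - sse / sst


def rmse(y_true, y_pred) -> float:
    """Root-mean-square error."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0:
        raise ValueError("empty vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def lod(y_true, y_pred, factor: float = 3.3) -> float:
    """Pseudounivariate limit of detection: factor * s_res / |slope|.

    Slope and residual SD come from the ordinary least-squares line of
    predicted on true concentration; a perfect prediction yields 0."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size < 3:
        raise ValueError("LOD needs at least 3 points")
    fit = sps.linregress(y_true, y_pred)
    if fit.slope == 0:
        raise ValueError("zero slope; LOD undefined")
    resid = y_pred - (fit.intercept + fit.slope * y_true)
    s_res = float(np.sqrt(np.sum(resid**2) / (y_true.size - 2)))
    return factor * s_res / abs(fit.slope)


# ---------------------------------------------------------------------------
# Regressors


def fit_ridge_multioutput(X, Y, strength: float = 0.1) -> Ridge:
    """Closed-form ridge least squares, shared penalty across outputs."""
    if strength < 0:
        raise ValueError("strength must be >= 0")
    model = Ridge(alpha=strength)
    model.fit(np.asarray(X, dtype=float), np.asarray(Y, dtype=float))
    return model


def fit_pls(X, Y, n_latent: int) -> Pipeline:
    """PLS regression with ``n_latent`` components on standardized features.

    Targets are internally centered/scaled by the PLS fit and predictions
    returned on the original scale."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    limit = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_latent <= limit:
        raise ValueError(f"n_latent must be in [1, {limit}]")
    model = Pipeline(
        [("scale", StandardScaler()), ("pls", PLSRegression(n_components=n_latent, scale=True))]
    )
    model.fit(X, Y)
    return model


# ---------------------------------------------------------------------------
# Baseline selectors


def lasso_select(X, Y, strength: float | None = None, seed: int = 0) -> FeatureMask:
    """Channels with nonzero L1-penalized coefficients for either target.

    Features and targets are standardized before the fit; when ``strength``
    is omitted it is chosen per target by 5-fold CV over a logarithmic
    grid."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).reshape(X.shape[0], -1)
    Xs = StandardScaler().fit_transform(X)
    bits = np.zeros(X.shape[1], dtype=np.int8)
    for t in range(Y.shape[1]):
        y = Y[:, t]
        ys = (y - y.mean()) / (y.std() or 1.0)
        if strength is None:
            model = LassoCV(alphas=np.logspace(-4, 0, 30), cv=5, random_state=seed, max_iter=5000)
        else:
            if strength <= 0:
                raise ValueError("strength must be > 0")
            model = Lasso(alpha=strength, max_iter=5000)
        model.fit(Xs, ys)
        bits[np.abs(model.coef_) > 1e-10] = 1
    if not bits.any():
        raise ValueError("lasso selected no channels; use a smaller strength")
    return FeatureMask(bits)


def ga_select(dataset: SpectraDataset, fitness, config: GAConfig) -> FeatureMask:
    """Generational genetic algorithm on channel bit-strings.

    Tournament selection, one-point crossover, per-bit flip mutation
    (default rate 1/D), elitism of one; returns the best mask ever seen."""
    rng = np.random.default_rng(config.seed)
    D = dataset.n_channels
    p_mut = config.mutation_prob if config.mutation_prob is not None else 1.0 / D

    def repaired(bits):
        if not bits.any():
            bits[rng.integers(D)] = 1
        return bits

    pop = [repaired((rng.uniform(size=D) < 0.5).astype(np.int8)) for _ in range(config.population)]
    fits = [fitness(FeatureMask(b), dataset) for b in pop]
    best_i = int(np.argmax(fits))
    best_bits, best_f = pop[best_i].copy(), fits[best_i]

    for _ in range(config.generations):
        children = [best_bits.copy()]  # elitism
        while len(children) < config.population:
            parents = []
            for _ in range(2):
                idx = rng.integers(0, config.population, size=config.tournament)
                parents.append(pop[idx[int(np.argmax([fits[i] for i in idx]))]])
            a, b = parents[0].copy(), parents[1].copy()
            if rng.uniform() < config.crossover_prob and D > 1:
                cut = int(rng.integers(1, D))
                a = np.concatenate([parents[0][:cut], parents[1][cut:]])
            flip = rng.uniform(size=D) < p_mut
            a = np.where(flip, 1 - a, a).astype(np.int8)
            children.append(repaired(a))
        pop = children
        fits = [fitness(FeatureMask(b), dataset) for b in pop]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_f:
            best_f, best_bits = fits[gen_best], pop[gen_best].copy()
    return FeatureMask(best_bits)


def pso_svm_select(
    dataset: SpectraDataset,
    config: PSOConfig,
    alpha: float | None = None,
    folds: int | None = None,
) -> FeatureMask:
    """The PSO wrapper with a single RBF SVM (C=1, gamma=0.01) as fitness model."""
    svm = default_model_specs()["svm"]
    fitness = make_subset_fitness(
        dataset,
        svm,
        alpha=config.alpha if alpha is None else alpha,
        folds=config.fitness_folds if folds is None else folds,
        seed=config.seed,
    )
    mask, _ = run_pso(dataset, fitness, config)
    return mask


# ---------------------------------------------------------------------------
# Evaluation harnesses


def evaluate_predictions(y_cal, p_cal, y_pred, p_pred, lod_factor: float = 3.3) -> Metrics:
    return Metrics(
        r2c=r_squared(y_cal, p_cal),
        rmsec=rmse(y_cal, p_cal),
        r2p=r_squared(y_pred, p_pred),
        rmsep=rmse(y_pred, p_pred),
        lod=lod(y_pred, p_pred, factor=lod_factor),
    )


def evaluate_model(model, cal: SpectraDataset, pred: SpectraDataset, lod_factor: float = 3.3) -> dict[str, Metrics]:
    """Fit-quality table for a fitted two-target regressor: per property,
    R²c/RMSEC on the calibration set and R²p/RMSEP/LOD on the prediction set."""
    p_cal = np.asarray(model.predict(cal.reflectance), dtype=float).reshape(cal.n_spectra, -1)
    p_pred = np.asarray(model.predict(pred.reflectance), dtype=float).reshape(pred.n_spectra, -1)
    out = {}
    for t, name in enumerate(("nitrogen", "organic_matter")[: p_cal.shape[1]]):
        out[name] = evaluate_predictions(
            getattr(cal, name), p_cal[:, t], getattr(pred, name), p_pred[:, t], lod_factor
        )
    return out


def _joint_metrics(Y_true_cal, Y_hat_cal, Y_true_pred, Y_hat_pred):
    """Single R²/RMSE over both targets: standardize each target to unit SD
    on the calibration truth, then pool the standardized residuals."""
    mu = Y_true_cal.mean(axis=0)
    sd = Y_true_cal.std(axis=0, ddof=1)
    zc_t, zc_p = (Y_true_cal - mu) / sd, (Y_hat_cal - mu) / sd
    zp_t, zp_p = (Y_true_pred - mu) / sd, (Y_hat_pred - mu) / sd
    return (
        r_squared(zc_t.ravel(), zc_p.ravel()),
        rmse(zc_t.ravel(), zc_p.ravel()),
        r_squared(zp_t.ravel(), zp_p.ravel()),
        rmse(zp_t.ravel(), zp_p.ravel()),
    )


def compare_feature_selectors(
    dataset: SpectraDataset,
    selectors: list[str],
    seed: int = 0,
    fsgc: StackSpec | None = None,
    pso_config: PSOConfig | None = None,
    ga_config: GAConfig | None = None,
    prediction_fraction: float = 0.25,
    ridge_strength: float = 0.1,
) -> list[ComparisonRow]:
    """Score selectors through a shared multi-output ridge.

    Pipeline per selector: split (stratified by variety) → standardize on
    calibration → select channels *on the calibration set only* → fit
    ridge(strength) on the masked calibration spectra → joint two-target
    R²/RMSE on both sets. ``"none"`` rows use every channel."""
    if not selectors:
        raise ValueError("selectors list is empty")
    if "none" not in selectors:
        selectors = ["none", *selectors]  # always report the no-selection reference
    from .models import build_fsgc

    split = split_calibration_prediction(dataset, prediction_fraction, seed=seed)
    cal, pred = dataset.subset(split.calibration), dataset.subset(split.prediction)
    scaler = standardize_fit(cal)
    cal_s, pred_s = standardize_apply(scaler, cal), standardize_apply(scaler, pred)
    pso_config = pso_config or PSOConfig(seed=seed)
    ga_config = ga_config or GAConfig(seed=seed)
    fsgc = fsgc or build_fsgc()

    rows = []
    for name in selectors:
        if name == "none":
            mask = FeatureMask(np.ones(dataset.n_channels, dtype=np.int8))
        elif name == "lasso":
            mask = lasso_select(cal_s.reflectance, cal_s.targets, seed=seed)
        elif name == "ga":
            fitness = make_subset_fitness(
                cal_s, fsgc, alpha=pso_config.alpha, folds=pso_config.fitness_folds, seed=seed
            )
            mask = ga_select(cal_s, fitness, ga_config)
        elif name == "pso-svm":
            mask = pso_svm_select(cal_s, pso_config)
        elif name == "pso-fsgc":
            fitness = make_subset_fitness(
                cal_s, fsgc, alpha=pso_config.alpha, folds=pso_config.fitness_folds, seed=seed
            )
            mask, _ = run_pso(cal_s, fitness, pso_config)
        else:
            raise ValueError(f"unknown selector {name!r}")
        cal_m, pred_m = apply_feature_mask(cal_s, mask), apply_feature_mask(pred_s, mask)
        model = fit_ridge_multioutput(cal_m.reflectance, cal_m.targets, ridge_strength)
        r2c, rmsec, r2p, rmsep = _joint_metrics(
            cal_m.targets,
            model.predict(cal_m.reflectance),
            pred_m.targets,
            model.predict(pred_m.reflectance),
        )
        rows.append(
            ComparisonRow(
                selector=name,
                regressor="ridge",
                n_selected=mask.n_selected,
                r2c=r2c,
                rmsec=rmsec,
                r2p=r2p,
                rmsep=rmsep,
            )
        )
    return rows
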