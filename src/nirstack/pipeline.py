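"""End-to-end workflow: load/simulate → smooth → split → standardize →
select wavelengths → train the stacked regressor (and baselines) → evaluate.

A :class:`RunConfig` (JSON or YAML) fixes every stage and a single global
seed; two runs with the same config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .data import (
    FeatureMask,
    SpectraDataset,
    apply_feature_mask,
    bin_channels,
    expand_mask,
    read_spectra_csv,
    savgol_smooth,
    split_calibration_prediction,
    standardize_apply,
    standardize_fit,
)
from .evaluation import (
    GAConfig,
    Metrics,
    evaluate_model,
    fit_pls,
    fit_ridge_multioutput,
)
from .models import build_fsgc, build_ssgr, default_model_specs, fit_stack
from .pso import PSOConfig, make_subset_fitness, run_pso
from .synthetic import GeneratorConfig, generate_dataset

log = logging.getLogger("nirstack")

__all__ = ["RunConfig", "parse_config", "run_full_pipeline"]

_SELECTORS = ("pso-fsgc", "pso-svm", "ga", "lasso", "none")
_REGRESSORS = ("ssgr", "ridge", "svr", "pls3", "pls6", "pls9")


@dataclass
class RunConfig:
    """Validated settings for a full run; defaults are the tuned study
    settings where the study states them (alpha 0.5, 50 particles,
    10 iterations, 5-fold grids, 75:25 split)."""

    input_csv: str | None = None  # None → simulate
    output_dir: str = "nirstack_run"
    preset: str = "paper"  # simulate preset when no input_csv
    noise_sd: float = 0.005
    window: int = 11
    polyorder: int = 2
    prediction_fraction: float = 0.25
    stratify: bool = True
    group_by_sample: bool = False
    selector: str = "pso-fsgc"
    alpha: float = 0.5
    particles: int = 50
    iterations: int = 10
    fitness_folds: int = 3
    bin_width: int = 10
    regressors: tuple[str, ...] = ("ssgr", "ridge")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.selector not in _SELECTORS:
            raise ValueError(f"selector must be one of {_SELECTORS}")
        for r in self.regressors:
            if r not in _REGRESSORS:
                raise ValueError(f"regressor must be one of {_REGRESSORS}")
        if self.preset not in ("paper", "reduced", "tiny"):
            raise ValueError("preset must be paper, reduced or tiny")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def parse_config(path) -> RunConfig:
    """Read a JSON or YAML run config; unknown keys are an error; an empty
    file yields the all-defaults config."""
    text = Path(path).read_text()
    if not text.strip():
        return RunConfig()
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        obj = yaml.safe_load(text)
    else:
        obj = json.loads(text)
    if obj is None:
        return RunConfig()
    if not isinstance(obj, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(obj) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "regressors" in obj:
        obj["regressors"] = tuple(obj["regressors"])
    return RunConfig(**obj)


def _select(config: RunConfig, cal_s: SpectraDataset):
    """Run the configured selector on the (binned) calibration set; returns
    (mask on the working grid, fitness history, working calibration set)."""
    work = bin_channels(cal_s, config.bin_width) if config.bin_width > 1 else cal_s
    pso_cfg = PSOConfig(
        n_particles=config.particles,
        n_iterations=config.iterations,
        alpha=config.alpha,
        seed=config.seed,
        fitness_folds=config.fitness_folds,
    )
    history: list[float] = []
    if config.selector == "none":
        mask = FeatureMask(np.ones(work.n_channels, dtype=np.int8))
    elif config.selector == "lasso":
        from .evaluation import lasso_select

        mask = lasso_select(work.reflectance, work.targets, seed=config.seed)
    elif config.selector == "ga":
        fitness = make_subset_fitness(
            work, build_fsgc(), alpha=config.alpha, folds=config.fitness_folds, seed=config.seed
        )
        from .evaluation import ga_select

        mask = ga_select(
            work, fitness, GAConfig(population=config.particles, generations=config.iterations, seed=config.seed)
        )
    elif config.selector == "pso-svm":
        from .evaluation import pso_svm_select

        mask = pso_svm_select(work, pso_cfg)
    else:  # pso-fsgc
        fitness = make_subset_fitness(
            work, build_fsgc(), alpha=config.alpha, folds=config.fitness_folds, seed=config.seed
        )
        mask, history = run_pso(work, fitness, pso_cfg)
    return mask, history, work


class _StackRegressor:
    """predict() adapter around a fitted stack."""

    def __init__(self, fitted):
        self.fitted = fitted

    def predict(self, X):
        return self.fitted.predict(X)


def _fit_regressor(name: str, X, Y, seed: int):
    if name == "ssgr":
        return _StackRegressor(fit_stack(build_ssgr(), X, Y, seed=seed))
    if name == "ridge":
        return fit_ridge_multioutput(X, Y, 0.1)
    if name == "svr":
        from sklearn.multioutput import MultiOutputRegressor

        svr = default_model_specs()["svr"].to_estimator()
        model = MultiOutputRegressor(svr)
        model.fit(X, Y)
        return model
    if name.startswith("pls"):
        return fit_pls(X, Y, int(name[3:]))
    raise ValueError(name)


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the whole workflow and write mask JSON, metrics CSV and a run
    report into ``config.output_dir``. Returns the report dict."""
    t_start = time.perf_counter()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if config.input_csv is not None:
            path = Path(config.input_csv)
            if not path.exists():
                raise FileNotFoundError(f"input spectra file not found: {path}")
            dataset = read_spectra_csv(path)
            truth = None
        else:
            gen = getattr(GeneratorConfig, config.preset)(seed=config.seed, noise_sd=config.noise_sd)
            dataset, truth = generate_dataset(gen)
        log.info("loaded %d spectra x %d channels", dataset.n_spectra, dataset.n_channels)

        stage = "smooth"
        dataset = savgol_smooth(dataset, config.window, config.polyorder)

        stage = "split"
        split = split_calibration_prediction(
            dataset,
            config.prediction_fraction,
            seed=config.seed,
            stratify_by_variety=config.stratify,
            group_by_sample=config.group_by_sample,
        )
        cal, pred = dataset.subset(split.calibration), dataset.subset(split.prediction)

        stage = "standardize"
        scaler = standardize_fit(cal)
        cal_s, pred_s = standardize_apply(scaler, cal), standardize_apply(scaler, pred)

        stage = "select"
        t0 = time.perf_counter()
        mask, history, work_cal = _select(config, cal_s)
        log.info("selector %s picked %d/%d channels in %.1fs",
                 config.selector, mask.n_selected, work_cal.n_channels, time.perf_counter() - t0)
        work_pred = bin_channels(pred_s, config.bin_width) if config.bin_width > 1 else pred_s
        cal_m, pred_m = apply_feature_mask(work_cal, mask), apply_feature_mask(work_pred, mask)
        full_mask = (
            expand_mask(mask, config.bin_width, dataset.n_channels)
            if config.bin_width > 1
            else mask
        )
        mask_json = {
            "wavelengths_selected": full_mask.selected_wavelengths(dataset.grid).tolist(),
            "n_selected": full_mask.n_selected,
            "working_grid_selected": mask.selected_wavelengths(work_cal.grid).tolist(),
            "fitness_history": list(history),
        }
        (out / "mask.json").write_text(json.dumps(mask_json, indent=1))

        stage = "train"
        metrics: dict[str, dict[str, Metrics]] = {}
        for name in config.regressors:
            t0 = time.perf_counter()
            model = _fit_regressor(name, cal_m.reflectance, cal_m.targets, config.seed)
            metrics[name] = evaluate_model(model, cal_m, pred_m)
            log.info("regressor %s fitted+scored in %.1fs", name, time.perf_counter() - t0)

        stage = "report"
        rows = ["property,method,R2c,RMSEC,R2p,RMSEP,LOD"]
        for name, per_prop in metrics.items():
            for prop, m in per_prop.items():
                rows.append(
                    f"{prop},{name},{m.r2c:.6f},{m.rmsec:.6f},{m.r2p:.6f},{m.rmsep:.6f},{m.lod:.6f}"
                )
        (out / "metrics.csv").write_text("\n".join(rows) + "\n")
        report = {
            "version": __version__,
            "config": config.to_dict(),
            "seed": config.seed,
            "n_spectra": dataset.n_spectra,
            "n_channels": dataset.n_channels,
            "split": {"calibration": int(split.calibration.size), "prediction": int(split.prediction.size)},
            "selected_wavelengths": mask_json["wavelengths_selected"],
            "n_selected": full_mask.n_selected,
            "fitness_history": list(history),
            "metrics": {
                name: {prop: dataclasses.asdict(m) for prop, m in per_prop.items()}
                for name, per_prop in metrics.items()
            },
            "elapsed_s": round(time.perf_counter() - t_start, 2),
        }
        (out / "report.json").write_text(json.dumps(report, indent=1))
        return report
    except Exception as exc:
        log.error("pipeline failed at stage %r: %s", stage, exc)
        raise
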