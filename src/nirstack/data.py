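"""Spectra data model, I/O and preprocessing for Vis-NIR reflectance tables.

The central container is :class:`SpectraDataset`: a matrix of reflectance
spectra (one row per measurement) on a common wavelength grid, with
per-spectrum metadata — fertilizer variety (1–9), sample id, replicate id,
and the two reference concentrations (nitrogen and organic matter).

Preprocessing follows the usual chemometrics pipeline: Savitzky–Golay
smoothing of each spectrum, leakage-free standardization (fit on the
calibration set only), wavelength masking, and a stratified
calibration/prediction split.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "WavelengthGrid",
    "SpectraDataset",
    "Scaler",
    "FeatureMask",
    "SplitIndices",
    "read_spectra_csv",
    "write_spectra_csv",
    "savgol_smooth",
    "standardize_fit",
    "standardize_apply",
    "apply_feature_mask",
    "split_calibration_prediction",
    "mean_spectrum_by_variety",
    "bin_channels",
    "expand_mask",
]

METADATA_COLUMNS = ("variety", "sample_id", "replicate_id", "nitrogen", "organic_matter")


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing vector of channel center wavelengths in nm."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D vector")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    @classmethod
    def canonical(cls) -> "WavelengthGrid":
        """The 2151-channel integer-nm grid 350..2500 of the resampled ASD output."""
        return cls(np.arange(350.0, 2501.0))

    def __len__(self) -> int:
        return self.wavelengths.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and np.allclose(
            self.wavelengths, other.wavelengths
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.wavelengths.size, float(self.wavelengths[0]), float(self.wavelengths[-1])))


@dataclass
class SpectraDataset:
    """Reflectance spectra plus per-spectrum metadata.

    Invariants (checked at construction): reflectance has one column per
    grid channel, metadata vectors have one entry per spectrum, no missing
    values, and all replicates of a sample share variety and concentrations.
    """

    grid: WavelengthGrid
    reflectance: np.ndarray
    variety: np.ndarray
    sample_id: np.ndarray
    replicate_id: np.ndarray
    nitrogen: np.ndarray
    organic_matter: np.ndarray

    def __post_init__(self) -> None:
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.reflectance.size == 0:
            self.reflectance = self.reflectance.reshape(0, len(self.grid))
        n = self.reflectance.shape[0]
        if self.reflectance.shape[1] != len(self.grid):
            raise ValueError(
                f"reflectance has {self.reflectance.shape[1]} columns but grid has {len(self.grid)} channels"
            )
        self.variety = np.asarray(self.variety, dtype=int)
        self.sample_id = np.asarray(self.sample_id, dtype=int)
        self.replicate_id = np.asarray(self.replicate_id, dtype=int)
        self.nitrogen = np.asarray(self.nitrogen, dtype=float)
        self.organic_matter = np.asarray(self.organic_matter, dtype=float)
        for name in METADATA_COLUMNS:
            if getattr(self, name).shape != (n,):
                raise ValueError(f"metadata column {name!r} must have length {n}")
        if n and (np.isnan(self.reflectance).any() or np.isnan(self.nitrogen).any() or np.isnan(self.organic_matter).any()):
            raise ValueError("missing values are not allowed in reflectance or targets")
        # replicates of one sample must agree on variety and both targets
        for sid in np.unique(self.sample_id):
            rows = self.sample_id == sid
            for name in ("variety", "nitrogen", "organic_matter"):
                vals = getattr(self, name)[rows]
                if np.ptp(vals) != 0:
                    raise ValueError(f"replicates of sample {sid} disagree on {name}")

    @property
    def n_spectra(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.reflectance.shape[1]

    @property
    def targets(self) -> np.ndarray:
        """(n, 2) matrix of [nitrogen, organic_matter]."""
        return np.column_stack([self.nitrogen, self.organic_matter])

    def subset(self, rows: np.ndarray) -> "SpectraDataset":
        """Dataset restricted to the given row indices (or boolean mask)."""
        rows = np.asarray(rows)
        return SpectraDataset(
            grid=self.grid,
            reflectance=self.reflectance[rows],
            variety=self.variety[rows],
            sample_id=self.sample_id[rows],
            replicate_id=self.replicate_id[rows],
            nitrogen=self.nitrogen[rows],
            organic_matter=self.organic_matter[rows],
        )

    def with_reflectance(self, reflectance: np.ndarray, grid: WavelengthGrid | None = None) -> "SpectraDataset":
        return SpectraDataset(
            grid=self.grid if grid is None else grid,
            reflectance=reflectance,
            variety=self.variety,
            sample_id=self.sample_id,
            replicate_id=self.replicate_id,
            nitrogen=self.nitrogen,
            organic_matter=self.organic_matter,
        )


@dataclass
class Scaler:
    """Per-channel mean/SD computed on a calibration set (sample SD, ddof=1)."""

    grid: WavelengthGrid
    mean: np.ndarray
    sd: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "wavelengths": self.grid.wavelengths.tolist(),
                "mean": self.mean.tolist(),
                "sd": self.sd.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Scaler":
        obj = json.loads(text)
        return cls(
            grid=WavelengthGrid(np.asarray(obj["wavelengths"])),
            mean=np.asarray(obj["mean"], dtype=float),
            sd=np.asarray(obj["sd"], dtype=float),
        )


@dataclass(frozen=True)
class FeatureMask:
    """Binary selection vector over wavelength channels (1 = selected)."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if bits.ndim != 1:
            raise ValueError("mask must be 1-D")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        object.__setattr__(self, "bits", bits.astype(np.int8))

    def __len__(self) -> int:
        return self.bits.size

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def selected_wavelengths(self, grid: WavelengthGrid) -> np.ndarray:
        return grid.wavelengths[self.indices]

    def wavelength_runs(self, grid: "WavelengthGrid") -> list[tuple[float, float]]:
        """Maximal runs of consecutively selected channels as (start, end) nm."""
        runs = []
        start = None
        for j in range(self.bits.size):
            if self.bits[j] and start is None:
                start = j
            elif not self.bits[j] and start is not None:
                runs.append((float(grid.wavelengths[start]), float(grid.wavelengths[j - 1])))
                start = None
        if start is not None:
            runs.append((float(grid.wavelengths[start]), float(grid.wavelengths[-1])))
        return runs

    def jaccard(self, other: "FeatureMask") -> float:
        """Jaccard overlap |A ∩ B| / |A ∪ B| of two masks of equal length."""
        a, b = self.bits.astype(bool), other.bits.astype(bool)
        union = np.logical_or(a, b).sum()
        if union == 0:
            return 1.0
        return float(np.logical_and(a, b).sum() / union)


@dataclass
class SplitIndices:
    """Disjoint calibration/prediction row indices covering a dataset."""

    calibration: np.ndarray
    prediction: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {"calibration": self.calibration.tolist(), "prediction": self.prediction.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitIndices":
        obj = json.loads(text)
        return cls(
            calibration=np.asarray(obj["calibration"], dtype=int),
            prediction=np.asarray(obj["prediction"], dtype=int),
        )


# ---------------------------------------------------------------------------
# CSV I/O


def write_spectra_csv(dataset: SpectraDataset, path) -> None:
    """Write a dataset as CSV: metadata columns, then one column per wavelength."""
    frame = pd.DataFrame(
        {
            "variety": dataset.variety,
            "sample_id": dataset.sample_id,
            "replicate_id": dataset.replicate_id,
            "nitrogen": dataset.nitrogen,
            "organic_matter": dataset.organic_matter,
        }
    )
    wl_cols = pd.DataFrame(
        dataset.reflectance, columns=[_format_wavelength(w) for w in dataset.grid.wavelengths]
    )
    pd.concat([frame, wl_cols], axis=1).to_csv(path, index=False, float_format="%.17g")


def _format_wavelength(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else repr(float(w))


def read_spectra_csv(path) -> SpectraDataset:
    """Read a spectra CSV written by :func:`write_spectra_csv`.

    Wavelength columns are identified as every numerically-named column and
    are sorted ascending; the five metadata columns are required.
    """
    frame = pd.read_csv(path)
    for col in METADATA_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"spectra CSV is missing required metadata column {col!r}")
    wl_cols = []
    for col in frame.columns:
        if col in METADATA_COLUMNS:
            continue
        try:
            wl_cols.append((float(col), col))
        except ValueError as exc:
            raise ValueError(f"column {col!r} is neither metadata nor a wavelength in nm") from exc
    wl_cols.sort(key=lambda t: t[0])
    wavelengths = np.array([w for w, _ in wl_cols])
    if wavelengths.size and np.any(np.diff(wavelengths) <= 0):
        dup = wl_cols[int(np.argmin(np.diff(wavelengths)))][1]
        raise ValueError(f"duplicate wavelength column {dup!r}")
    reflectance = frame[[c for _, c in wl_cols]].to_numpy(dtype=float)
    return SpectraDataset(
        grid=WavelengthGrid(wavelengths),
        reflectance=reflectance,
        variety=frame["variety"].to_numpy(),
        sample_id=frame["sample_id"].to_numpy(),
        replicate_id=frame["replicate_id"].to_numpy(),
        nitrogen=frame["nitrogen"].to_numpy(dtype=float),
        organic_matter=frame["organic_matter"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Preprocessing


def savgol_smooth(dataset: SpectraDataset, window: int = 11, polyorder: int = 2) -> SpectraDataset:
    """Savitzky–Golay least-squares polynomial smoothing of each spectrum.

    ``window`` is an odd channel count; ``polyorder`` the degree of the local
    polynomial. Metadata are untouched.
    """
    if window % 2 == 0:
        raise ValueError("Savitzky–Golay window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than the window")
    if window > dataset.n_channels:
        raise ValueError("window exceeds the number of channels")
    smoothed = savgol_filter(dataset.reflectance, window_length=window, polyorder=polyorder, axis=1)
    return dataset.with_reflectance(smoothed)


def standardize_fit(calibration: SpectraDataset) -> Scaler:
    """Per-channel mean and sample SD of the calibration spectra."""
    if calibration.n_spectra < 2:
        raise ValueError("standardization needs at least 2 calibration spectra")
    mean = calibration.reflectance.mean(axis=0)
    sd = calibration.reflectance.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd <= 0)
    if zero.size:
        wl = calibration.grid.wavelengths[zero[0]]
        raise ValueError(f"channel at {wl:g} nm has zero variance in the calibration set")
    return Scaler(grid=calibration.grid, mean=mean, sd=sd)


def standardize_apply(scaler: Scaler, dataset: SpectraDataset) -> SpectraDataset:
    """(x − mean) / SD per channel, using the scaler's calibration statistics."""
    if scaler.grid != dataset.grid:
        raise ValueError("scaler grid does not match dataset grid")
    return dataset.with_reflectance((dataset.reflectance - scaler.mean) / scaler.sd)


def apply_feature_mask(dataset: SpectraDataset, mask: FeatureMask) -> SpectraDataset:
    """Restrict the dataset (and its grid) to the selected channels."""
    if len(mask) != dataset.n_channels:
        raise ValueError("mask length does not match channel count")
    if mask.n_selected == 0:
        raise ValueError("mask selects no channels")
    idx = mask.indices
    return dataset.with_reflectance(
        dataset.reflectance[:, idx], grid=WavelengthGrid(dataset.grid.wavelengths[idx])
    )


def split_calibration_prediction(
    dataset: SpectraDataset,
    prediction_fraction: float = 0.25,
    seed: int = 0,
    stratify_by_variety: bool = True,
    group_by_sample: bool = False,
) -> SplitIndices:
    """Deterministic calibration/prediction split of the spectra.

    The prediction set holds ``ceil(fraction * n)`` spectra; under
    stratification the per-variety counts follow largest-remainder
    apportionment of that total (ties broken by variety order), which gives
    203 prediction / 607 calibration spectra for the 810-spectrum design at
    fraction 0.25. ``group_by_sample`` allocates whole samples (all three
    replicates together) to avoid replicate leakage across the split.
    """
    n = dataset.n_spectra
    if not 0 < prediction_fraction < 1:
        raise ValueError("prediction_fraction must be in (0, 1)")
    n_pred = math.ceil(prediction_fraction * n)
    if n_pred >= n:
        raise ValueError("prediction fraction leaves an empty calibration set")
    rng = np.random.default_rng(seed)

    if group_by_sample:
        units = np.unique(dataset.sample_id)
        unit_rows = {u: np.flatnonzero(dataset.sample_id == u) for u in units}
        unit_variety = {u: dataset.variety[unit_rows[u][0]] for u in units}
        n_pred_units = math.ceil(prediction_fraction * units.size)
        chosen = _allocate(units, np.array([unit_variety[u] for u in units]),
                           n_pred_units, stratify_by_variety, rng)
        pred_rows = np.sort(np.concatenate([unit_rows[u] for u in chosen]))
    else:
        rows = np.arange(n)
        chosen = _allocate(rows, dataset.variety, n_pred, stratify_by_variety, rng)
        pred_rows = np.sort(chosen)

    cal_rows = np.setdiff1d(np.arange(n), pred_rows)
    return SplitIndices(calibration=cal_rows, prediction=pred_rows)


def _allocate(units, labels, n_pick, stratify, rng):
    if not stratify:
        return rng.choice(units, size=n_pick, replace=False)
    varieties = np.unique(labels)
    ideal = np.array([np.sum(labels == v) for v in varieties]) * n_pick / units.size
    counts = np.floor(ideal).astype(int)
    frac = ideal - counts
    short = n_pick - counts.sum()
    # largest fractional remainder first; ties by variety order (stable sort)
    order = np.argsort(-frac, kind="stable")
    counts[order[:short]] += 1
    picks = []
    for v, c in zip(varieties, counts):
        pool = units[labels == v]
        picks.append(rng.choice(pool, size=c, replace=False))
    return np.concatenate(picks)


def mean_spectrum_by_variety(dataset: SpectraDataset) -> np.ndarray:
    """Arithmetic mean reflectance per variety; rows ordered by variety label."""
    varieties = np.unique(dataset.variety)
    return np.vstack(
        [dataset.reflectance[dataset.variety == v].mean(axis=0) for v in varieties]
    )


# ---------------------------------------------------------------------------
# Channel binning (fitness tractability for wrapper selection)


def bin_channels(dataset: SpectraDataset, width: int) -> SpectraDataset:
    """Average consecutive blocks of ``width`` channels (trailing partial block kept).

    Used to down-bin the 2151-channel grid before wrapper selection; masks
    found on the binned grid expand back with :func:`expand_mask`.
    """
    if width < 1:
        raise ValueError("bin width must be >= 1")
    if width == 1:
        return dataset
    d = dataset.n_channels
    edges = np.arange(0, d + width, width)
    edges[-1] = min(edges[-1], d)
    edges = np.unique(edges)
    refl = np.stack(
        [dataset.reflectance[:, a:b].mean(axis=1) for a, b in zip(edges[:-1], edges[1:])], axis=1
    )
    centers = np.array(
        [dataset.grid.wavelengths[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
    )
    return dataset.with_reflectance(refl, grid=WavelengthGrid(centers))


def expand_mask(mask: FeatureMask, width: int, n_channels: int) -> FeatureMask:
    """Expand a mask on a binned grid back to the full grid (block-wise)."""
    bits = np.zeros(n_channels, dtype=np.int8)
    for j in mask.indices:
        bits[j * width : min((j + 1) * width, n_channels)] = 1
    return FeatureMask(bits)
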