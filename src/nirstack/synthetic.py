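"""Synthetic Vis-NIR reflectance generator emulating the fertilizer study design.

The study measured 9 commercial organic-fertilizer varieties, 30 samples per
variety, 3 replicate spectra per sample (810 spectra) on the 350–2500 nm
grid, with reference nitrogen (N) and organic-matter (OM) concentrations per
variety summarized by min/max/mean/SD. No public accession of the spectra
exists, so this module generates datasets with the same design and with
known ground truth:

* concentrations are drawn Normal(mean, SD) per variety from the published
  summary statistics (no min/max truncation — several rows are internally
  inconsistent with any bounded distribution, so the means/SDs are taken as
  the generative truth and min/max kept as metadata only);
* each variety has a shared smooth baseline plus Gaussian absorption bands;
  band depths couple linearly to N and OM (Beer–Lambert-style), so a known
  set of "informative" channels carries the concentration signal;
* per-spectrum random baseline shifts mimic the loading-density/particle-size
  scatter seen in the real spectra, and i.i.d. channel noise mimics detector
  noise.

Because the between-variety class signal lives in the band depths (baselines
are common to all varieties), wavelength selectors driven by variety
classification are steered toward the same channels that carry the N/OM
signal — mirroring the logic of the two-stage selection-then-regression
framework, and giving recovery tests a ground-truth mask to score against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FeatureMask, SpectraDataset, WavelengthGrid

__all__ = [
    "Table1Stats",
    "PropertyStats",
    "Band",
    "VarietyProfile",
    "GeneratorConfig",
    "table1_stats",
    "sample_concentrations",
    "build_variety_profiles",
    "generate_spectrum",
    "generate_dataset",
    "ground_truth_mask",
]


@dataclass(frozen=True)
class PropertyStats:
    """Min/max/mean/SD of one concentration for one variety."""

    min: float
    max: float
    mean: float
    sd: float


@dataclass(frozen=True)
class Table1Stats:
    """Published per-variety concentration statistics (varieties 1–9)."""

    nitrogen: dict[int, PropertyStats]
    organic_matter: dict[int, PropertyStats]

    def of(self, prop: str, variety: int) -> PropertyStats:
        table = self.nitrogen if prop in ("N", "nitrogen") else self.organic_matter
        return table[variety]


# Published concentration statistics: per variety 1..9, (min, max, mean, SD).
_N_ROWS = {
    1: (1.460, 1.480, 1.470, 0.010),
    2: (2.030, 2.070, 2.047, 0.020),
    3: (1.540, 1.560, 1.550, 0.010),
    4: (1.220, 1.260, 1.237, 0.020),
    5: (2.110, 2.160, 2.140, 0.026),
    6: (1.350, 1.360, 1.353, 0.005),
    7: (2.220, 2.240, 2.230, 0.010),
    8: (1.220, 5.330, 2.107, 1.117),
    9: (5.190, 5.330, 5.250, 0.072),
}
_OM_ROWS = {
    1: (55.97, 56.12, 56.02, 0.083),
    2: (40.23, 40.34, 40.30, 0.058),
    3: (40.56, 40.98, 40.78, 0.210),
    4: (58.15, 58.22, 58.19, 0.035),
    5: (57.11, 57.46, 57.29, 0.175),
    6: (47.12, 47.29, 47.22, 0.090),
    7: (54.12, 54.33, 54.25, 0.111),
    8: (40.23, 58.22, 50.21, 6.348),
    9: (45.65, 45.98, 45.78, 0.175),
}


def table1_stats() -> Table1Stats:
    """The published per-variety N and OM summary statistics, verbatim."""
    return Table1Stats(
        nitrogen={v: PropertyStats(*row) for v, row in _N_ROWS.items()},
        organic_matter={v: PropertyStats(*row) for v, row in _OM_ROWS.items()},
    )


def sample_concentrations(
    stats: Table1Stats, variety: int, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n i.i.d. Normal(mean, SD) concentration pairs for one variety."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ns = stats.nitrogen[variety]
    os_ = stats.organic_matter[variety]
    nitrogen = rng.normal(ns.mean, ns.sd, size=n)
    organic = rng.normal(os_.mean, os_.sd, size=n)
    return nitrogen, organic


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band.

    ``depth`` and the couplings enter the spectrum as
    ``(depth + n_coupling*N + om_coupling*OM) * exp(-(λ-center)²/2σ²)``;
    absorption dips carry negative signs, so a negative coupling deepens the
    band as the concentration rises.
    """

    center: float
    sigma: float
    depth: float
    n_coupling: float = 0.0
    om_coupling: float = 0.0


@dataclass
class VarietyProfile:
    """Per-variety spectral physics: shared baseline + absorption bands."""

    baseline: np.ndarray
    bands: list[Band]
    baseline_shift_sd: float


@dataclass
class GeneratorConfig:
    """Study design and noise settings of the synthetic generator.

    Defaults reproduce the study's design: 9 varieties x 30 samples x
    3 replicates on the canonical 2151-channel grid, channel noise SD 0.005
    and per-spectrum baseline shift SD 0.01 (reflectance units). The
    informative ranges are the wavelength windows where concentration
    couplings live.
    """

    n_varieties: int = 9
    samples_per_variety: int = 30
    replicates: int = 3
    grid: WavelengthGrid = field(default_factory=WavelengthGrid.canonical)
    noise_sd: float = 0.005
    baseline_shift_sd: float = 0.01
    seed: int = 0
    band_sigma_scale: float = 1.0
    informative_ranges: tuple[tuple[float, float], ...] = (
        (400.0, 600.0),
        (900.0, 1000.0),
        (1400.0, 1600.0),
        (1800.0, 2300.0),
    )

    def __post_init__(self) -> None:
        if min(self.n_varieties, self.samples_per_variety, self.replicates) < 1:
            raise ValueError("design counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def paper(cls, seed: int = 0, **kw) -> "GeneratorConfig":
        """The full study design (810 spectra, 2151 channels)."""
        return cls(seed=seed, **kw)

    @classmethod
    def reduced(cls, seed: int = 0, **kw) -> "GeneratorConfig":
        """Fast benchmark: 64 channels (8 concentration-informative),
        9x10x1 = 90 spectra.

        The grid mixes channels placed on the coupled-band supports
        (informative), on the uncoupled water/signature bands, and evenly
        spread uninformative filler channels."""
        structured = np.array(
            [500.0, 844.0, 970.0, 1470.0, 1490.0, 1510.0, 1530.0, 1733.0, 1930.0, 2100.0, 2135.0, 2310.0]
        )
        # keep filler channels clear of every coupled-band support so the
        # informative set stays exactly the eight intended channels
        coupled_zones = ((460.0, 540.0), (1430.0, 1565.0), (1885.0, 1975.0), (2050.0, 2150.0))
        candidates = np.linspace(355.0, 2495.0, 240)
        ok = np.ones(candidates.size, dtype=bool)
        for lo_z, hi_z in coupled_zones:
            ok &= ~((candidates >= lo_z) & (candidates <= hi_z))
        ok &= np.all(np.abs(candidates[:, None] - structured[None, :]) > 10.0, axis=1)
        pool = candidates[ok]
        take = np.linspace(0, pool.size - 1, 64 - structured.size).round().astype(int)
        grid = np.unique(np.concatenate([structured, pool[take]]))
        kw.setdefault("grid", WavelengthGrid(grid))
        kw.setdefault("samples_per_variety", 10)
        kw.setdefault("replicates", 1)
        kw.setdefault("band_sigma_scale", 0.35)
        return cls(seed=seed, **kw)

    @classmethod
    def tiny(cls, seed: int = 0, **kw) -> "GeneratorConfig":
        """8-channel problem for exhaustive-search oracle tests (D = 8)."""
        kw.setdefault(
            "grid",
            WavelengthGrid(np.array([450.0, 550.0, 970.0, 1450.0, 1520.0, 1930.0, 2100.0, 2400.0])),
        )
        kw.setdefault("samples_per_variety", 10)
        kw.setdefault("replicates", 1)
        kw.setdefault("band_sigma_scale", 0.3)
        return cls(seed=seed, **kw)


# Concentration couplings (reflectance units per concentration unit),
# negative = band deepens as the concentration rises. They are *universal*
# across varieties, Beer–Lambert-style: the same absorber has the same
# sensitivity everywhere, so one global calibration exists. Variety-specific
# "matrix effect" offsets on the coupled band depths are kept small relative
# to the concentration signal.
_A_1930 = -0.040
_A_2100 = -0.030
_A_VIS = -0.015
_B_OM = -0.004
_B_SIG = -0.002  # weak OM coupling of the 1400–1550 nm signature peaks
_JITTER_N = 0.002  # matrix-effect depth offset range at N-coupled bands
_JITTER_OM = 0.003  # and at the OM-coupled band

# Signature-peak windows (nm) for the varieties that show them; the peaks
# are organic-matter absorption features, so they carry a weak OM coupling
# on top of a variety-specific base depth.
_EXTRA_PEAK_WINDOW = {1: (1462.0, 1480.0), 3: (1480.0, 1500.0), 8: (1500.0, 1520.0), 9: (1522.0, 1535.0)}


def build_variety_profiles(
    config: GeneratorConfig, rng: np.random.Generator
) -> list[VarietyProfile]:
    """Construct the nine variety profiles.

    Every variety shares (i) the two N-coupled bands of the 1887–2200 nm
    absorption region (1930, 2100 nm) and (ii) an OM-coupled band at
    1520 nm, with universal couplings plus a small per-variety matrix-effect
    depth offset. Varieties 1, 3, 8 and 9 carry an extra signature peak in
    1462–1535 nm (distinct windows per variety) — an organic absorption
    feature, so it adds a weak OM coupling to its variety-specific depth;
    odd varieties carry a visible-range N-coupled band at 500 nm and an
    uncoupled water band at 970 nm (so even varieties have no band below
    1300 nm); variety 9 additionally shows its three signature bands at
    844, 1733 and 2310 nm (uncoupled). Between-variety class information
    therefore lives in the signature peaks and in the coupled-band depths
    (via the variety-specific concentration means), keeping the class
    signal and the concentration signal on overlapping channels.
    """
    wl = config.grid.wavelengths
    lo, hi = wl[0], wl[-1]
    t = (wl - 350.0) / 2150.0
    baseline = 0.42 + 0.30 * t - 0.18 * t**2  # common gentle convex curve
    s = config.band_sigma_scale
    profiles = []
    for v in range(1, config.n_varieties + 1):
        bands = [
            Band(1930.0, 35.0 * s, _jitter(rng, _JITTER_N), _A_1930, 0.0),
            Band(2100.0, 40.0 * s, _jitter(rng, _JITTER_N), _A_2100, 0.0),
            Band(1520.0, 25.0 * s, _jitter(rng, _JITTER_OM), 0.0, _B_OM),
        ]
        if v in _EXTRA_PEAK_WINDOW:
            a, b = _EXTRA_PEAK_WINDOW[v]
            bands.append(
                Band(float(rng.uniform(a, b)), 20.0 * s, -float(rng.uniform(0.05, 0.10)), 0.0, _B_SIG)
            )
        if v % 2 == 1:
            bands.append(Band(500.0, 30.0 * s, _jitter(rng, _JITTER_N), _A_VIS, 0.0))
            bands.append(Band(970.0, 25.0 * s, -float(rng.uniform(0.03, 0.05))))
        if v == 9:
            for c in (844.0, 1733.0, 2310.0):
                bands.append(Band(c, 15.0 * s, -float(rng.uniform(0.05, 0.09))))
        bands = [b for b in bands if lo <= b.center <= hi]
        if not bands:
            raise ValueError("no band center falls inside the wavelength grid")
        profiles.append(
            VarietyProfile(
                baseline=baseline.copy(), bands=bands, baseline_shift_sd=config.baseline_shift_sd
            )
        )
    return profiles


def _jitter(rng: np.random.Generator, j: float) -> float:
    return float(rng.uniform(-j, j))


def generate_spectrum(
    profile: VarietyProfile,
    nitrogen: float,
    organic_matter: float,
    rng: np.random.Generator,
    grid: WavelengthGrid,
    noise_sd: float = 0.005,
) -> np.ndarray:
    """One reflectance spectrum: baseline + shift + concentration-coupled bands + noise."""
    wl = grid.wavelengths
    refl = profile.baseline.copy()
    if profile.baseline_shift_sd > 0:
        refl = refl + rng.normal(0.0, profile.baseline_shift_sd)
    for band in profile.bands:
        amp = band.depth + band.n_coupling * nitrogen + band.om_coupling * organic_matter
        refl = refl + amp * np.exp(-0.5 * ((wl - band.center) / band.sigma) ** 2)
    if noise_sd > 0:
        refl = refl + rng.normal(0.0, noise_sd, size=wl.size)
    return np.clip(refl, 0.001, 1.2)


def generate_dataset(config: GeneratorConfig) -> tuple[SpectraDataset, FeatureMask]:
    """Generate the full synthetic study and its ground-truth informative mask.

    Returns ``n_varieties * samples_per_variety`` samples, each measured
    ``replicates`` times (replicates share concentrations but have
    independent shift and noise), plus the mask of channels whose reflectance
    is coupled to N or OM.
    """
    rng = np.random.default_rng(config.seed)
    stats = table1_stats()
    profiles = build_variety_profiles(config, rng)
    rows, variety, sample_id, replicate_id, n_vals, om_vals = [], [], [], [], [], []
    sid = 0
    for v in range(1, config.n_varieties + 1):
        v_stats = ((v - 1) % 9) + 1  # reuse published rows cyclically if >9 varieties
        nitro, organic = sample_concentrations(stats, v_stats, config.samples_per_variety, rng)
        for i in range(config.samples_per_variety):
            sid += 1
            for rep in range(1, config.replicates + 1):
                rows.append(
                    generate_spectrum(
                        profiles[v - 1], nitro[i], organic[i], rng, config.grid, config.noise_sd
                    )
                )
                variety.append(v)
                sample_id.append(sid)
                replicate_id.append(rep)
                n_vals.append(nitro[i])
                om_vals.append(organic[i])
    dataset = SpectraDataset(
        grid=config.grid,
        reflectance=np.vstack(rows),
        variety=variety,
        sample_id=sample_id,
        replicate_id=replicate_id,
        nitrogen=n_vals,
        organic_matter=om_vals,
    )
    return dataset, ground_truth_mask(profiles, config.grid)


def ground_truth_mask(
    profiles: list[VarietyProfile], grid: WavelengthGrid, threshold: float = 0.01
) -> FeatureMask:
    """Channels where any variety's concentration coupling is materially nonzero.

    A channel counts as informative when, for some coupled band, the Gaussian
    weight exceeds ``threshold`` of its peak (i.e. the channel sees more than
    that fraction of the band's concentration sensitivity).
    """
    wl = grid.wavelengths
    bits = np.zeros(wl.size, dtype=np.int8)
    for profile in profiles:
        for band in profile.bands:
            if band.n_coupling == 0.0 and band.om_coupling == 0.0:
                continue
            weight = np.exp(-0.5 * ((wl - band.center) / band.sigma) ** 2)
            bits[weight > threshold] = 1
    return FeatureMask(bits)
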