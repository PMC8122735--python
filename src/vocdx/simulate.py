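"""Synthetic cohorts of GC-IMS spectra and GC-TOF-MS peak tables.

The generator emulates a urinary-volatilome case/control study of liver
disease: a cohort split into hepatocellular-carcinoma (HCC), fibrotic and
non-fibrotic groups (default sizes 20/7/31), GC-IMS intensity maps that are
sparse chemical signal on a large grid — a dominant reactant-ion peak (RIP)
line plus discrete 2D-Gaussian VOC peaks — and deconvolved GC-TOF-MS peak
tables with class-dependent abundance shifts. Planted markers with a fold
change of 1 in every group encode the null; raising a fold change plants a
class-discriminating VOC.

All randomness descends from a single integer seed; each sample draws from
an independent substream derived from ``(seed, crc32(sample_id))``, so
cohorts are reproducible sample-by-sample.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectrum import GCIMSSpectrum

GROUP_HCC = "HCC"
GROUP_FIBROSIS = "fibrosis"
GROUP_NONFIBROSIS = "non-fibrosis"
GROUPS = (GROUP_HCC, GROUP_FIBROSIS, GROUP_NONFIBROSIS)

#: Gaussian cross-sections are set to exact zero beyond this many sigma,
#: so signal-free regions of the map are truly zero.
_TRUNCATE_SIGMA = 5.0


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition: group sizes and the master seed."""

    n_hcc: int = 20
    n_fibrosis: int = 7
    n_nonfibrosis: int = 31
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hcc", "n_fibrosis", "n_nonfibrosis"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.n_hcc + self.n_fibrosis + self.n_nonfibrosis


@dataclass(frozen=True)
class MarkerSpec:
    """A planted VOC peak on the GC-IMS map.

    ``fold_change`` maps group name -> positive multiplier applied to
    ``base_intensity`` for samples of that group (missing groups get 1.0);
    ``biological_cv`` is the coefficient of variation of a lognormal
    between-sample multiplier with mean 1.
    """

    location: tuple[float, float]  # (retention time s, drift time ms)
    base_intensity: float
    fold_change: Mapping[str, float] = field(default_factory=dict)
    peak_width: tuple[float, float] = (6.0, 0.12)  # (sigma_rt s, sigma_dt ms)
    biological_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be > 0")
        if any(v <= 0 for v in self.fold_change.values()):
            raise ValueError("fold_change multipliers must be > 0")
        if self.peak_width[0] <= 0 or self.peak_width[1] <= 0:
            raise ValueError("peak widths must be > 0")
        if self.biological_cv < 0:
            raise ValueError("biological_cv must be >= 0")

    def multiplier(self, group: str | None) -> float:
        return float(self.fold_change.get(group, 1.0)) if group else 1.0


@dataclass(frozen=True)
class ChemicalSpec:
    """A planted chemical in the GC-TOF-MS peak table.

    The deconvolved peak height is drawn lognormally around
    ``base_height * fold_change[group]``; area follows from height and the
    (gently jittered) peak width.
    """

    chemical: str
    retention_time_min: float
    base_height: float
    fold_change: Mapping[str, float] = field(default_factory=dict)
    width_min: float = 0.05
    biological_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.base_height <= 0:
            raise ValueError("base_height must be > 0")
        if any(v <= 0 for v in self.fold_change.values()):
            raise ValueError("fold_change multipliers must be > 0")
        if self.width_min <= 0:
            raise ValueError("width_min must be > 0")
        if self.biological_cv < 0:
            raise ValueError("biological_cv must be >= 0")
        if self.retention_time_min < 0:
            raise ValueError("retention_time_min must be >= 0")

    def multiplier(self, group: str | None) -> float:
        return float(self.fold_change.get(group, 1.0)) if group else 1.0


@dataclass(frozen=True)
class NoiseSpec:
    """Instrument background: flat baseline, additive noise, and the RIP.

    The reactant-ion peak (RIP) is the dominant carrier-gas response line:
    a constant-intensity column along retention time with a Gaussian
    cross-section in drift time. It must dominate the background
    (``baseline_level + 3 * additive_sd < rip_intensity``).
    """

    baseline_level: float = 10.0
    additive_sd: float = 5.0
    rip_position: float = 7.5  # drift time, ms
    rip_intensity: float = 1000.0
    rip_width: float = 0.08  # sigma, ms

    def __post_init__(self) -> None:
        if self.baseline_level < 0 or self.additive_sd < 0:
            raise ValueError("baseline_level and additive_sd must be >= 0")
        if self.rip_width <= 0:
            raise ValueError("rip_width must be > 0")
        if not self.baseline_level + 3 * self.additive_sd < self.rip_intensity:
            raise ValueError(
                "RIP must dominate: require baseline_level + 3*additive_sd "
                "< rip_intensity"
            )


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Independent, reproducible substream for one sample."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(sample_id.encode())])
    )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the cohort label table.

    Returns a DataFrame with columns ``sample_id`` and ``group`` containing
    exactly the requested number of samples per group, in a seed-determined
    shuffled order (mimicking accession order in a real study).
    """
    ids, groups = [], []
    for prefix, group, n in (
        ("H", GROUP_HCC, spec.n_hcc),
        ("F", GROUP_FIBROSIS, spec.n_fibrosis),
        ("N", GROUP_NONFIBROSIS, spec.n_nonfibrosis),
    ):
        for i in range(n):
            ids.append(f"{prefix}{i + 1:03d}")
            groups.append(group)
    table = pd.DataFrame({"sample_id": ids, "group": groups})
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    order = rng.permutation(len(table))
    return table.iloc[order].reset_index(drop=True)


def simulate_gcims(
    sample_id: str,
    group: str | None,
    markers: Sequence[MarkerSpec],
    noise: NoiseSpec,
    grid: tuple[int, int] = (256, 128),
    rt_range: tuple[float, float] = (0.0, 600.0),
    dt_range: tuple[float, float] = (6.0, 16.0),
    seed: int = 0,
) -> GCIMSSpectrum:
    """Simulate one GC-IMS spectrum.

    The intensity map is ``baseline + RIP column profile + sum of 2D
    Gaussian peaks + additive Gaussian noise``, truncated at zero. Each
    marker's apex intensity is ``base_intensity * fold_change[group] *
    lognormal(biological_cv)``.

    Raises ``ValueError`` for grids smaller than 8x8 or markers outside the
    axis extent.
    """
    n_rt, n_dt = grid
    if n_rt < 8 or n_dt < 8:
        raise ValueError("grid must be at least 8x8")
    rt_axis = np.linspace(rt_range[0], rt_range[1], n_rt)
    dt_axis = np.linspace(dt_range[0], dt_range[1], n_dt)
    for m in markers:
        rt0, dt0 = m.location
        if not (rt_axis[0] <= rt0 <= rt_axis[-1] and dt_axis[0] <= dt0 <= dt_axis[-1]):
            raise ValueError(
                f"marker at (rt={rt0}s, dt={dt0}ms) lies outside the axis "
                f"ranges rt={rt_range}, dt={dt_range}"
            )

    rng = _sample_rng(seed, sample_id)
    intensities = np.full((n_rt, n_dt), float(noise.baseline_level))

    # RIP: constant along retention time, Gaussian in drift time,
    # truncated to exact zero beyond _TRUNCATE_SIGMA sigma.
    z = (dt_axis - noise.rip_position) / noise.rip_width
    rip = noise.rip_intensity * np.exp(-0.5 * z * z)
    rip[np.abs(z) > _TRUNCATE_SIGMA] = 0.0
    intensities += rip[np.newaxis, :]

    for m in markers:
        apex = m.base_intensity * m.multiplier(group) * _lognormal_factor(
            rng, m.biological_cv
        )
        zr = (rt_axis - m.location[0]) / m.peak_width[0]
        zd = (dt_axis - m.location[1]) / m.peak_width[1]
        pr = np.exp(-0.5 * zr * zr)
        pd_ = np.exp(-0.5 * zd * zd)
        pr[np.abs(zr) > _TRUNCATE_SIGMA] = 0.0
        pd_[np.abs(zd) > _TRUNCATE_SIGMA] = 0.0
        intensities += apex * np.outer(pr, pd_)

    if noise.additive_sd > 0:
        intensities += rng.normal(0.0, noise.additive_sd, size=intensities.shape)
    np.clip(intensities, 0.0, None, out=intensities)

    return GCIMSSpectrum(
        intensities=intensities,
        rt_axis=rt_axis,
        dt_axis=dt_axis,
        sample_id=sample_id,
        group=group,
        metadata={"seed": int(seed), "generator": "simulate_gcims"},
    )


def simulate_ims_cohort(
    cohort: pd.DataFrame,
    markers: Sequence[MarkerSpec],
    noise: NoiseSpec | None = None,
    grid: tuple[int, int] = (256, 128),
    seed: int = 0,
    **kwargs,
) -> list[GCIMSSpectrum]:
    """Simulate one spectrum per cohort row (shared grid and axes)."""
    noise = noise or NoiseSpec()
    return [
        simulate_gcims(row.sample_id, row.group, markers, noise, grid, seed=seed, **kwargs)
        for row in cohort.itertuples(index=False)
    ]


# Peak-area conversion for a Gaussian-shaped chromatographic peak of given
# height and FWHM-like width: area ~= 1.0645 * height * width.
_GAUSS_AREA = 1.0645


def simulate_peak_table(
    sample_id: str,
    group: str | None,
    chemicals: Sequence[ChemicalSpec],
    detection: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one sample's deconvolved GC-TOF-MS peak list.

    ``detection = (height_floor, dropout_prob)``: peaks whose drawn height
    falls below the floor, or that are hit by random dropout (emulating
    headspace non-detection), are absent from the table.

    Returns a DataFrame with columns ``sample_id, chemical,
    retention_time_min, height, width, area``.
    """
    height_floor, dropout_prob = detection
    if not 0.0 <= dropout_prob <= 1.0:
        raise ValueError("dropout_prob must be in [0, 1]")
    rng = _sample_rng(seed, sample_id)
    rows = []
    for chem in chemicals:
        height = chem.base_height * chem.multiplier(group) * _lognormal_factor(
            rng, chem.biological_cv
        )
        width = chem.width_min * _lognormal_factor(rng, 0.05)
        rt = max(0.0, chem.retention_time_min + rng.normal(0.0, 0.005))
        dropped = rng.uniform() < dropout_prob
        if dropped or height < height_floor:
            continue
        rows.append(
            {
                "sample_id": sample_id,
                "chemical": chem.chemical,
                "retention_time_min": rt,
                "height": height,
                "width": width,
                "area": _GAUSS_AREA * height * width,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chemical", "retention_time_min", "height", "width", "area"],
    )


def simulate_tofms_cohort(
    cohort: pd.DataFrame,
    chemicals: Sequence[ChemicalSpec],
    detection: tuple[float, float] = (0.0, 0.05),
    seed: int = 0,
) -> pd.DataFrame:
    """Concatenate per-sample peak tables for a whole cohort."""
    tables = [
        simulate_peak_table(row.sample_id, row.group, chemicals, detection, seed)
        for row in cohort.itertuples(index=False)
    ]
    return pd.concat(tables, ignore_index=True)


def _scaled(folds: dict[str, float], effect_scale: float) -> dict[str, float]:
    """Exponentiate fold changes: scale 1 keeps them, scale 0 is the null."""
    return {g: float(f) ** effect_scale for g, f in folds.items()}


def default_markers(effect_scale: float = 1.0, n_null: int = 12) -> list[MarkerSpec]:
    """Study-condition GC-IMS marker panel.

    A handful of class-discriminating VOC peaks (HCC-shifted, one
    fibrosis-shifted) plus ``n_null`` unshifted clutter peaks at fixed
    positions, so the map carries sparse signal on a mostly-empty grid.
    ``effect_scale`` exponentiates every fold change: 1.0 reproduces the
    study conditions, 0.0 removes all class effects (the global null).
    """
    s = effect_scale
    markers = [
        MarkerSpec((210.0, 8.9), 400.0, _scaled({GROUP_HCC: 2.5}, s), (6.0, 0.12), 0.25),
        MarkerSpec((150.0, 9.6), 300.0, _scaled({GROUP_HCC: 0.4}, s), (5.0, 0.10), 0.25),
        MarkerSpec((320.0, 10.4), 250.0, _scaled({GROUP_HCC: 1.6, GROUP_FIBROSIS: 1.4}, s), (7.0, 0.15), 0.3),
        MarkerSpec((450.0, 11.2), 200.0, _scaled({GROUP_FIBROSIS: 1.5}, s), (6.0, 0.12), 0.3),
    ]
    rng = np.random.default_rng(20210422)  # fixed panel layout, not per-run noise
    for _ in range(n_null):
        rt0 = float(rng.uniform(60.0, 560.0))
        dt0 = float(rng.uniform(8.2, 14.5))
        base = float(rng.uniform(80.0, 350.0))
        markers.append(MarkerSpec((rt0, dt0), base, {}, (6.0, 0.12), 0.3))
    return markers


#: Named chemicals of the study panel: (name, retention time min, HCC fold).
#: 2-butanone is elevated in HCC; the remaining six are depleted.
_STUDY_CHEMICALS = [
    ("4-Methyl-2,4-bis(p-hydroxyphenyl)pent-1-ene, 2TMS derivative", 15.25, 0.35),
    ("2-Butanone", 2.5998, 2.0),
    ("2-Hexanone", 4.5684, 0.5),
    ("Benzene, 1-ethyl-2-methyl-", 6.3215, 0.5),
    ("3-Butene-1,2-diol, 1-(2-furanyl)-", 12.1318, 0.5),
    ("Bicyclo[4.1.0]heptane, 3,7,7-trimethyl-", 8.2054, 0.5),
    ("Sulpiride", 13.861, 0.5),
]

# Base peak heights sit at TOF detector-count scale so that typical areas
# (~ height * width) clear the default deconvolution rejects.
_BASE_HEIGHT = 6e5


def default_chemicals(
    n_null: int = 85, biological_cv: float = 0.4, effect_scale: float = 1.0
) -> list[ChemicalSpec]:
    """Study-condition GC-TOF-MS chemical panel.

    Seven named HCC-shifted chemicals plus ``n_null`` null compounds with
    lognormally spread base heights, yielding on the order of 70-110
    detected peaks per sample under the default detection settings.
    ``effect_scale`` exponentiates the fold changes (0.0 => global null).
    """
    chems = [
        ChemicalSpec(
            name, rt, _BASE_HEIGHT, _scaled({GROUP_HCC: fold}, effect_scale),
            0.05, biological_cv,
        )
        for name, rt, fold in _STUDY_CHEMICALS
    ]
    rng = np.random.default_rng(20210423)  # fixed panel layout
    for i in range(n_null):
        base = float(np.exp(rng.normal(np.log(_BASE_HEIGHT), 1.0)))
        rt = float(rng.uniform(1.0, 24.0))
        chems.append(
            ChemicalSpec(f"compound_{i + 8:03d}", rt, base, {}, 0.05, biological_cv)
        )
    return chems
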