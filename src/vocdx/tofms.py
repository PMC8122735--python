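"""GC-TOF-MS branch: peak-reject filtering, chemical abundance matrices,
per-chemical nonparametric testing, and direct-feature classification.

The input is a deconvolved per-sample peak table (chemical label,
retention time in minutes, height, width, area) as produced by upstream
integration/deconvolution software. This module applies the reject
filter, aggregates peaks into a samples x chemicals abundance matrix
(summed area; a chemical not detected in a sample counts as zero
abundance — headspace non-detection is informative), tests each chemical
between two groups with a two-sided Mann-Whitney rank-sum test, and
reports the significant chemicals with the direction of the abundance
change in the case group.

Because there are only tens of chemicals, classification uses them
directly as features with no additional feature reduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crossval import CVConfig, CVResult, run_cv

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ["sample_id", "chemical", "retention_time_min", "height", "width", "area"]


def validate_peak_table(peaks: pd.DataFrame) -> pd.DataFrame:
    """Check the peak-table schema and value constraints."""
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    if len(peaks):
        if (peaks["height"] <= 0).any() or (peaks["area"] <= 0).any():
            raise ValueError("height and area must be > 0")
        if (peaks["width"] <= 0).any():
            raise ValueError("width must be > 0")
        if (peaks["retention_time_min"] < 0).any():
            raise ValueError("retention_time_min must be >= 0")
    return peaks


@dataclass(frozen=True)
class RejectSettings:
    """Deconvolution reject thresholds.

    Defaults follow common practice for urinary-headspace work: global
    height reject 10,000, global width reject 0.01 min, baseline threshold
    3, global area reject 10,000. ``baseline_threshold`` belongs to the
    upstream deconvolution software; it is stored and echoed in reports
    but defines no additional row filter on a post-deconvolution table.
    """

    height_reject: float = 10_000.0
    width_reject: float = 0.01
    baseline_threshold: float = 3.0
    area_reject: float = 10_000.0

    def __post_init__(self) -> None:
        if min(self.height_reject, self.width_reject, self.baseline_threshold, self.area_reject) < 0:
            raise ValueError("reject settings must be >= 0")


@dataclass
class ChemicalResult:
    """Outcome of the two-group test for one chemical."""

    chemical: str
    retention_time_min: float
    p_value: float
    direction: str  # "higher" | "lower" | "undetermined", for the case group
    case_median: float
    control_median: float


def filter_peaks(peaks: pd.DataFrame, settings: RejectSettings | None = None) -> pd.DataFrame:
    """Apply the reject filter: keep rows with height, area and width at or
    above their rejects (>=, keep-at-boundary). Row order is preserved;
    the filter is idempotent."""
    settings = settings or RejectSettings()
    validate_peak_table(peaks)
    if not len(peaks):
        return peaks.copy()
    mask = (
        (peaks["height"] >= settings.height_reject)
        & (peaks["area"] >= settings.area_reject)
        & (peaks["width"] >= settings.width_reject)
    )
    logger.info(
        "reject filter kept %d/%d peaks (baseline_threshold=%g echoed, no row filter)",
        int(mask.sum()), len(peaks), settings.baseline_threshold,
    )
    return peaks.loc[mask].copy()


def aggregate_chemicals(
    peaks: pd.DataFrame, labels: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Samples x chemicals abundance matrix plus representative retention times.

    Each cell is the summed peak area of that chemical in that sample
    (duplicate rows for one (sample, chemical) pair are summed and logged);
    a chemical absent from a sample gives 0. ``labels`` (sample_id, group)
    adds rows for samples with no surviving peaks. The representative
    retention time is the median observed per chemical.
    """
    validate_peak_table(peaks)
    dupes = peaks.duplicated(subset=["sample_id", "chemical"]).sum()
    if dupes:
        logger.info("summing %d duplicate (sample, chemical) peak rows", dupes)
    abundance = peaks.pivot_table(
        index="sample_id", columns="chemical", values="area", aggfunc="sum", fill_value=0.0
    )
    if labels is not None:
        abundance = abundance.reindex(labels["sample_id"], fill_value=0.0)
    abundance.columns.name = None
    abundance.index.name = "sample_id"
    rep_rt = peaks.groupby("chemical")["retention_time_min"].median()
    return abundance.astype(float), rep_rt


def test_chemicals(
    abundance: pd.DataFrame,
    groups: pd.Series,
    case_group: str,
    control_group: str | None = None,
) -> list[ChemicalResult]:
    """Two-sided Mann-Whitney rank-sum test per chemical.

    ``groups`` maps sample_id -> group label. The direction is read off
    the group medians (case vs control); exactly equal medians give
    "undetermined", which the significance filter excludes. Chemicals
    constant across all samples get p = 1.

    Retention times are not carried here; merge with the representative
    retention times from :func:`aggregate_chemicals` for reporting.
    """
    groups = groups.reindex(abundance.index)
    case_mask = (groups == case_group).to_numpy()
    if control_group is None:
        control_mask = (groups != case_group).to_numpy() & groups.notna().to_numpy()
    else:
        control_mask = (groups == control_group).to_numpy()
    if case_mask.sum() == 0 or control_mask.sum() == 0:
        raise ValueError("both groups must be non-empty")
    results: list[ChemicalResult] = []
    values = abundance.to_numpy(dtype=float)
    case, control = values[case_mask], values[control_mask]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(case, control, alternative="two-sided", axis=0, method="auto")
    pvals = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    for j, chemical in enumerate(abundance.columns):
        col = values[case_mask | control_mask, j]
        p = pvals[j]
        if np.ptp(col) == 0 or not np.isfinite(p):
            p = 1.0
        case_med = float(np.median(case[:, j]))
        ctrl_med = float(np.median(control[:, j]))
        if case_med > ctrl_med:
            direction = "higher"
        elif case_med < ctrl_med:
            direction = "lower"
        else:
            direction = "undetermined"
        results.append(
            ChemicalResult(
                chemical=str(chemical),
                retention_time_min=float("nan"),
                p_value=float(min(max(p, np.finfo(float).tiny), 1.0)),
                direction=direction,
                case_median=case_med,
                control_median=ctrl_med,
            )
        )
    return results


def significant_chemicals(
    results: list[ChemicalResult], alpha: float = 0.05, bh_correction: bool = False
) -> list[ChemicalResult]:
    """Chemicals with p strictly below alpha, sorted by ascending p.

    No multiplicity correction by default (raw p < 0.05, matching common
    exploratory practice); ``bh_correction=True`` applies
    Benjamini-Hochberg and filters on the adjusted values instead.
    Undetermined directions are excluded from the significant set.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not results:
        return []
    p = np.array([r.p_value for r in results])
    crit = stats.false_discovery_control(p, method="bh") if bh_correction else p
    keep = [
        r for r, c in zip(results, crit)
        if c < alpha and r.direction != "undetermined"
    ]
    return sorted(keep, key=lambda r: r.p_value)


def chemical_report(
    results: list[ChemicalResult],
    rep_rt: pd.Series | None = None,
    case_group: str = "case",
) -> pd.DataFrame:
    """Render results as a report table: No., RetentionTime(min), Chemical,
    p-value, Abundance Change."""
    rows = []
    for i, r in enumerate(sorted(results, key=lambda r: r.p_value), start=1):
        rt = r.retention_time_min
        if rep_rt is not None and r.chemical in rep_rt.index:
            rt = float(rep_rt[r.chemical])
        change = (
            f"{r.direction.capitalize()} for {case_group}"
            if r.direction in ("higher", "lower")
            else "Undetermined"
        )
        rows.append(
            {
                "No.": i,
                "RetentionTime(min)": round(rt, 4) if np.isfinite(rt) else np.nan,
                "Chemical": r.chemical,
                "p-value": r.p_value,
                "Abundance Change": change,
            }
        )
    return pd.DataFrame(rows, columns=["No.", "RetentionTime(min)", "Chemical", "p-value", "Abundance Change"])


def classify_chemical_features(
    abundance: pd.DataFrame, labels: np.ndarray, cfg: CVConfig
) -> CVResult:
    """Cross-validated classification on the chemical features directly.

    Delegates to the shared CV driver with feature selection disabled
    (every chemical is used in every fold) — the feature space is small
    enough that no reduction is needed.
    """
    cfg_all = CVConfig(
        n_folds=cfg.n_folds,
        n_features=abundance.shape[1],
        classifier=cfg.classifier,
        seed=cfg.seed,
    )
    result = run_cv(abundance.to_numpy(dtype=float), labels, cfg_all)
    result.sample_ids = list(abundance.index)
    return result


def count_peaks(peaks: pd.DataFrame, groups: pd.Series, comparison: tuple[str, str]) -> int:
    """Mean number of distinct detected peaks per sample, over the samples
    of the two compared groups, rounded to an integer."""
    validate_peak_table(peaks)
    wanted = groups[groups.isin(comparison)].index
    if len(wanted) == 0 or not len(peaks):
        return 0
    sub = peaks[peaks["sample_id"].isin(wanted)]
    per_sample = sub.groupby("sample_id")["chemical"].nunique()
    per_sample = per_sample.reindex(wanted, fill_value=0)
    return int(round(float(per_sample.mean())))
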