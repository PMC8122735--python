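"""Model/Results surface over the discrimination and chemical-panel
procedures, in the fit/summary style of statistical modelling packages.

Two entry points:

* :class:`GCIMSDiscriminationModel` — built from preprocessed GC-IMS
  feature matrices (or raw spectra via :meth:`from_spectra`); ``fit()``
  runs the cross-validated Wilcoxon-filtered classifier and returns a
  :class:`DiscriminationResults` carrying collated out-of-fold scores,
  the ROC/AUC with bootstrap CIs, the Youden-optimal threshold and the
  accuracy panel, with ``summary()`` rendering a report row.
* :class:`ChemicalPanelModel` — built from a deconvolved GC-TOF-MS peak
  table and cohort labels; ``fit()`` applies the reject filter, tests
  each chemical and returns a :class:`ChemicalPanelResults` with the
  significant-chemical table; ``fit_classifier()`` additionally runs
  direct-feature classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import diagnostics, preprocess, tofms
from .crossval import CVConfig, CVResult, LabelVector, run_cv
from .preprocess import CropRegion, FeatureMatrix
from .spectrum import GCIMSSpectrum


@dataclass
class DiscriminationResults:
    """Fitted cross-validated discrimination results."""

    cv: CVResult
    report: diagnostics.DiagnosticReport
    roc: diagnostics.ROCResult
    comparison: str
    classifier: str

    @property
    def auc(self) -> float:
        return self.roc.auc

    @property
    def threshold(self) -> float | None:
        return self.report.threshold

    def summary(self) -> str:
        return self.report.summary(self.comparison, self.classifier)

    def to_frame(self) -> pd.DataFrame:
        """Per-sample out-of-fold scores (sample_id, fold, probability, label)."""
        return self.cv.to_frame()

    def report_row(self) -> dict:
        """Report row as a flat dict (rounded metrics with CI tuples)."""
        r = self.report
        row: dict = {"comparison": self.comparison, "classifier": self.classifier}
        row.update(r.rounded())
        for name in ("auc", "sensitivity", "specificity", "ppv", "npv"):
            ci = getattr(r, f"{name}_ci")
            row[f"{name}_ci_lo"] = diagnostics.round2(ci[0]) if ci else None
            row[f"{name}_ci_hi"] = diagnostics.round2(ci[1]) if ci else None
        row["threshold"] = r.threshold
        return row

    def plot_roc(self, ax=None):
        """Plot the ROC curve (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(np.r_[0.0, self.roc.fpr], np.r_[0.0, self.roc.tpr], drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"{self.comparison} (AUC = {self.auc:.2f})")
        return ax


class GCIMSDiscriminationModel:
    """Cross-validated GC-IMS volatilome discrimination between two groups.

    Parameters
    ----------
    features : FeatureMatrix or ndarray
        Preprocessed (cropped, thresholded, flattened) spectra.
    labels : LabelVector, or sequence of group names with positive_class.
    positive_class : str, required when ``labels`` is a sequence of names.
    comparison : str, report label (e.g. ``"HCC vs. Fibrosis"``).
    """

    def __init__(
        self,
        features: FeatureMatrix | np.ndarray,
        labels: LabelVector | Sequence[str] | np.ndarray,
        positive_class: str | None = None,
        comparison: str = "",
    ) -> None:
        self.features = features
        if isinstance(labels, LabelVector):
            self.labels = labels
        else:
            labels = list(labels)
            if positive_class is None:
                raise ValueError("positive_class is required with raw group labels")
            ids = (
                list(features.sample_ids)
                if isinstance(features, FeatureMatrix)
                else [f"sample_{i}" for i in range(len(labels))]
            )
            self.labels = LabelVector.from_groups(ids, labels, positive_class)
        self.comparison = comparison or f"{self.labels.positive_class} vs. rest"

    @classmethod
    def from_spectra(
        cls,
        spectra: Sequence[GCIMSSpectrum],
        positive_class: str,
        region: CropRegion | None = None,
        quantile: float = 0.99,
        multiplier: float = 1.0,
        comparison: str = "",
    ) -> "GCIMSDiscriminationModel":
        """Preprocess labelled spectra (crop -> threshold -> flatten) and
        build the model. The default crop keeps the central section of the
        map, excluding the reactant-ion line and the edges."""
        region = region or CropRegion.from_fractions(spectra[0].shape)
        fm = preprocess.preprocess_stack(spectra, region, quantile=quantile, multiplier=multiplier)
        groups = [s.group or "" for s in spectra]
        return cls(fm, groups, positive_class=positive_class, comparison=comparison)

    def fit(
        self,
        classifier: str = "random_forest",
        n_folds: int = 10,
        n_features: int = 100,
        seed: int = 0,
        bootstrap: int = 2000,
    ) -> DiscriminationResults:
        """Run the cross-validated pipeline and evaluate the collated scores."""
        cfg = CVConfig(n_folds=n_folds, n_features=n_features, classifier=classifier, seed=seed)
        cv = run_cv(self.features, self.labels, cfg)
        roc = diagnostics.roc_auc(cv.proba, cv.y)
        report = diagnostics.evaluate_scores(
            cv.proba, cv.y, positive_class=self.labels.positive_class, B=bootstrap, seed=seed
        )
        return DiscriminationResults(
            cv=cv, report=report, roc=roc, comparison=self.comparison, classifier=classifier
        )


@dataclass
class ChemicalPanelResults:
    """Per-chemical test outcomes for a two-group comparison."""

    results: list[tofms.ChemicalResult]
    significant: list[tofms.ChemicalResult]
    rep_rt: pd.Series
    abundance: pd.DataFrame
    case_group: str
    alpha: float
    mean_peaks_per_sample: int

    def summary(self) -> pd.DataFrame:
        """Report table of the significant chemicals (No., RetentionTime(min),
        Chemical, p-value, Abundance Change)."""
        return tofms.chemical_report(self.significant, self.rep_rt, self.case_group)

    def all_results(self) -> pd.DataFrame:
        return tofms.chemical_report(self.results, self.rep_rt, self.case_group)


class ChemicalPanelModel:
    """GC-TOF-MS chemical panel: reject-filter, aggregate, test.

    Parameters
    ----------
    peaks : DataFrame
        Deconvolved peak table (sample_id, chemical, retention_time_min,
        height, width, area).
    labels : DataFrame with columns (sample_id, group).
    case_group, control_group : groups compared; ``control_group=None``
        pools every non-case sample.
    """

    def __init__(
        self,
        peaks: pd.DataFrame,
        labels: pd.DataFrame,
        case_group: str,
        control_group: str | None = None,
    ) -> None:
        self.peaks = tofms.validate_peak_table(peaks)
        self.labels = labels
        self.case_group = case_group
        self.control_group = control_group

    def _comparison_labels(self) -> pd.DataFrame:
        if self.control_group is None:
            return self.labels
        mask = self.labels["group"].isin([self.case_group, self.control_group])
        return self.labels[mask]

    def fit(
        self,
        reject: tofms.RejectSettings | None = None,
        alpha: float = 0.05,
        bh_correction: bool = False,
    ) -> ChemicalPanelResults:
        """Filter peaks, aggregate abundances, and test every chemical."""
        labels = self._comparison_labels().reset_index(drop=True)
        filtered = tofms.filter_peaks(self.peaks, reject or tofms.RejectSettings())
        filtered = filtered[filtered["sample_id"].isin(labels["sample_id"])]
        abundance, rep_rt = tofms.aggregate_chemicals(filtered, labels)
        groups = labels.set_index("sample_id")["group"]
        results = tofms.test_chemicals(abundance, groups, self.case_group, self.control_group)
        significant = tofms.significant_chemicals(results, alpha=alpha, bh_correction=bh_correction)
        mean_peaks = tofms.count_peaks(
            filtered,
            groups,
            (self.case_group, self.control_group) if self.control_group else tuple(groups.unique()),
        )
        return ChemicalPanelResults(
            results=results,
            significant=significant,
            rep_rt=rep_rt,
            abundance=abundance,
            case_group=self.case_group,
            alpha=alpha,
            mean_peaks_per_sample=mean_peaks,
        )

    def fit_classifier(
        self,
        classifier: str = "gradient_boosting",
        n_folds: int = 10,
        seed: int = 0,
        reject: tofms.RejectSettings | None = None,
        bootstrap: int = 2000,
    ) -> DiscriminationResults:
        """Direct-feature classification on the chemical abundances."""
        labels = self._comparison_labels().reset_index(drop=True)
        filtered = tofms.filter_peaks(self.peaks, reject or tofms.RejectSettings())
        filtered = filtered[filtered["sample_id"].isin(labels["sample_id"])]
        abundance, _ = tofms.aggregate_chemicals(filtered, labels)
        y = (labels.set_index("sample_id").loc[abundance.index, "group"] == self.case_group).astype(int)
        cfg = CVConfig(n_folds=n_folds, n_features=100, classifier=classifier, seed=seed)
        cv = tofms.classify_chemical_features(abundance, y.to_numpy(), cfg)
        cv.positive_class = self.case_group
        roc = diagnostics.roc_auc(cv.proba, cv.y)
        report = diagnostics.evaluate_scores(
            cv.proba, cv.y, positive_class=self.case_group, B=bootstrap, seed=seed
        )
        comparison = f"{self.case_group} vs. {self.control_group or 'rest'}"
        return DiscriminationResults(
            cv=cv, report=report, roc=roc, comparison=comparison, classifier=classifier
        )
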