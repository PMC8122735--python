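"""End-to-end run orchestration with a single validated config.

``run_pipeline`` executes simulate -> preprocess -> train-eval -> tofms ->
report, writing a deterministic artifact set (cohort CSV, spectrum
container, out-of-fold score CSVs, diagnostic report CSV, significant-
chemical CSV) plus a JSON manifest recording the effective parameters,
per-stage seeds and content hashes. One global seed deterministically
derives per-stage seeds, so stages are reproducible in isolation.

Manifest hashes cover logical content (canonical CSV bytes, raw array
bytes) rather than container file bytes, so rerunning a config yields a
hash-identical manifest even though binary containers embed timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import simulate as sim
from .model import ChemicalPanelModel, GCIMSDiscriminationModel
from .preprocess import CropRegion
from .spectrum import write_hdf5
from .tofms import RejectSettings

ClassifierName = Literal[
    "logistic_regression", "gradient_boosting", "random_forest", "linear_regression"
]

logger = logging.getLogger(__name__)

COMPARISONS: dict[str, tuple[str, str]] = {
    # comparison name -> (positive/case group, control group)
    "hcc-vs-fibrosis": (sim.GROUP_HCC, sim.GROUP_FIBROSIS),
    "hcc-vs-nonfibrosis": (sim.GROUP_HCC, sim.GROUP_NONFIBROSIS),
    "fibrosis-vs-nonfibrosis": (sim.GROUP_FIBROSIS, sim.GROUP_NONFIBROSIS),
}


class CohortConfig(BaseModel):
    n_hcc: int = Field(20, ge=0)
    n_fibrosis: int = Field(7, ge=0)
    n_nonfibrosis: int = Field(31, ge=0)


class SimulateConfig(BaseModel):
    grid: tuple[int, int] = (256, 128)
    effect_scale: float = Field(1.0, ge=0)  # 1 = study effects, 0 = null
    n_null_markers: int = Field(12, ge=0)
    n_null_chemicals: int = Field(85, ge=0)
    detection_height_floor: float = Field(0.0, ge=0)
    detection_dropout: float = Field(0.05, ge=0, le=1)


class PreprocessConfig(BaseModel):
    rt_window: tuple[float, float] = (0.1, 0.9)  # fractional crop, retention
    dt_window: tuple[float, float] = (0.2, 0.95)  # fractional crop, drift
    quantile: float = Field(0.99, ge=0, le=1)
    multiplier: float = Field(1.0, gt=0)
    global_threshold: bool = False


class CVBlock(BaseModel):
    n_folds: int = Field(10, ge=2)
    n_features: int = Field(100, ge=1)
    classifier: ClassifierName = "random_forest"
    bootstrap: int = Field(2000, ge=100)


class TofmsConfig(BaseModel):
    height_reject: float = Field(10_000.0, ge=0)
    width_reject: float = Field(0.01, ge=0)
    baseline_threshold: float = Field(3.0, ge=0)
    area_reject: float = Field(10_000.0, ge=0)
    alpha: float = Field(0.05, gt=0, lt=1)
    classifier: ClassifierName = "gradient_boosting"


class RunConfig(BaseModel):
    """Validated pipeline configuration (YAML-loadable)."""

    cohort: CohortConfig = CohortConfig()
    simulate: SimulateConfig = SimulateConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    cv: CVBlock = CVBlock()
    tofms: TofmsConfig = TofmsConfig()
    comparisons: list[str] = ["hcc-vs-fibrosis", "hcc-vs-nonfibrosis", "fibrosis-vs-nonfibrosis"]
    seed: int = 0

    @model_validator(mode="after")
    def _check_comparisons(self) -> "RunConfig":
        unknown = [c for c in self.comparisons if c not in COMPARISONS]
        if unknown:
            raise ValueError(f"unknown comparisons {unknown}; known: {sorted(COMPARISONS)}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> str:
    text = df.to_csv(index=False, lineterminator="\n", float_format="%.10g")
    path.write_text(text)
    return _sha256_bytes(text.encode())


def run_pipeline(config: RunConfig, out_dir: str | Path, write_spectra: bool = True) -> Path:
    """Run every stage under ``config`` and write the artifact set.

    Returns the run directory; raises at the failing stage with its name.
    A rerun with the same config produces a hash-identical manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.model_dump(mode="json"),
        "seeds": {},
        "artifacts": {},
        "results": {},
    }
    stage = "simulate"
    try:
        seed_sim = stage_seed(config.seed, "simulate")
        manifest["seeds"]["simulate"] = seed_sim
        cohort = sim.make_cohort(
            sim.CohortSpec(
                config.cohort.n_hcc, config.cohort.n_fibrosis,
                config.cohort.n_nonfibrosis, seed=seed_sim,
            )
        )
        manifest["artifacts"]["cohort.csv"] = _write_csv(cohort, out / "cohort.csv")
        markers = sim.default_markers(
            effect_scale=config.simulate.effect_scale, n_null=config.simulate.n_null_markers
        )
        spectra = sim.simulate_ims_cohort(
            cohort, markers, grid=tuple(config.simulate.grid), seed=seed_sim
        )
        manifest["artifacts"]["spectra_content"] = _sha256_bytes(
            b"".join(s.intensities.tobytes() for s in spectra)
        )
        if write_spectra:
            write_hdf5(spectra, out / "spectra.h5")
        chemicals = sim.default_chemicals(
            n_null=config.simulate.n_null_chemicals,
            effect_scale=config.simulate.effect_scale,
        )
        peaks = sim.simulate_tofms_cohort(
            cohort, chemicals,
            detection=(config.simulate.detection_height_floor, config.simulate.detection_dropout),
            seed=seed_sim,
        )
        manifest["artifacts"]["peak_table.csv"] = _write_csv(peaks, out / "peak_table.csv")

        stage = "preprocess+train-eval"
        report_rows = []
        for comparison in config.comparisons:
            positive, control = COMPARISONS[comparison]
            keep = cohort["group"].isin([positive, control]).to_numpy()
            sub = [s for s, k in zip(spectra, keep) if k]
            region = CropRegion.from_fractions(
                sub[0].shape, config.preprocess.rt_window, config.preprocess.dt_window
            )
            model = GCIMSDiscriminationModel.from_spectra(
                sub, positive_class=positive, region=region,
                quantile=config.preprocess.quantile,
                multiplier=config.preprocess.multiplier,
                comparison=comparison,
            )
            seed_cv = stage_seed(config.seed, f"cv:{comparison}")
            manifest["seeds"][f"cv:{comparison}"] = seed_cv
            res = model.fit(
                classifier=config.cv.classifier,
                n_folds=min(config.cv.n_folds, len(sub)),
                n_features=config.cv.n_features,
                seed=seed_cv,
                bootstrap=config.cv.bootstrap,
            )
            name = f"cv_{comparison}.csv"
            manifest["artifacts"][name] = _write_csv(res.to_frame(), out / name)
            report_rows.append(res.report_row())
            manifest["results"][f"auc:{comparison}"] = res.auc
            logger.info("%s: AUC=%.3f threshold=%.3f", comparison, res.auc, res.threshold)
        report = pd.DataFrame(report_rows)
        manifest["artifacts"]["diagnostic_report.csv"] = _write_csv(
            report, out / "diagnostic_report.csv"
        )

        stage = "tofms"
        for comparison in config.comparisons:
            positive, control = COMPARISONS[comparison]
            panel = ChemicalPanelModel(peaks, cohort, positive, control)
            reject = RejectSettings(
                height_reject=config.tofms.height_reject,
                width_reject=config.tofms.width_reject,
                baseline_threshold=config.tofms.baseline_threshold,
                area_reject=config.tofms.area_reject,
            )
            fit = panel.fit(reject=reject, alpha=config.tofms.alpha)
            name = f"chemicals_{comparison}.csv"
            manifest["artifacts"][name] = _write_csv(fit.summary(), out / name)
            manifest["results"][f"n_significant:{comparison}"] = len(fit.significant)
            manifest["results"][f"mean_peaks:{comparison}"] = fit.mean_peaks_per_sample
    except Exception as exc:  # annotate failures with the stage name
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
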