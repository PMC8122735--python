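"""Two-stage GC-IMS pre-processing: crop, then threshold-to-zero.

A raw GC-IMS map is high-dimensional but carries little chemical
information outside a central region. Pre-processing therefore (1) crops
the analysis window — the same manually chosen index window for every
sample — and (2) zeroes every value strictly below a background-derived
threshold, leaving sparse chemical signal. The cropped, thresholded maps
are then flattened row-major into a samples x features matrix whose
columns remain traceable to (retention, drift) grid cells.

Coordinate convention: 0-based, half-open index ranges ``[start, stop)``
on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectrum import GCIMSSpectrum


@dataclass(frozen=True)
class CropRegion:
    """Half-open index window ``[rt_start, rt_stop) x [dt_start, dt_stop)``."""

    rt_start: int
    rt_stop: int
    dt_start: int
    dt_stop: int

    def validate(self, shape: tuple[int, int]) -> None:
        n_rt, n_dt = shape
        for name, start, stop, n in (
            ("rt", self.rt_start, self.rt_stop, n_rt),
            ("dt", self.dt_start, self.dt_stop, n_dt),
        ):
            if not (0 <= start < stop <= n):
                raise ValueError(
                    f"invalid {name} range [{start}, {stop}) for axis length {n}"
                )

    @classmethod
    def from_margins(cls, shape: tuple[int, int], margin: float = 0.1) -> "CropRegion":
        """Symmetric fractional-margin window (default: drop 10% per side)."""
        n_rt, n_dt = shape
        r0, d0 = int(round(margin * n_rt)), int(round(margin * n_dt))
        return cls(r0, n_rt - r0, d0, n_dt - d0)

    @classmethod
    def from_fractions(
        cls,
        shape: tuple[int, int],
        rt: tuple[float, float] = (0.1, 0.9),
        dt: tuple[float, float] = (0.2, 0.95),
    ) -> "CropRegion":
        """Fractional analysis window.

        The default drops 10% of retention time per side and crops drift
        time to the central 20-95% band, which excludes the reactant-ion
        line sitting near the low-drift-time edge of the map.
        """
        n_rt, n_dt = shape
        return cls(
            int(round(rt[0] * n_rt)), int(round(rt[1] * n_rt)),
            int(round(dt[0] * n_dt)), int(round(dt[1] * n_dt)),
        )


def crop(spectrum: GCIMSSpectrum, region: CropRegion) -> GCIMSSpectrum:
    """Crop a spectrum to ``region``; axes and values are exact sub-slices."""
    region.validate(spectrum.shape)
    meta = dict(spectrum.metadata)
    meta["preprocess_steps"] = list(meta.get("preprocess_steps", [])) + ["crop"]
    return GCIMSSpectrum(
        intensities=spectrum.intensities[
            region.rt_start : region.rt_stop, region.dt_start : region.dt_stop
        ].copy(),
        rt_axis=spectrum.rt_axis[region.rt_start : region.rt_stop].copy(),
        dt_axis=spectrum.dt_axis[region.dt_start : region.dt_stop].copy(),
        sample_id=spectrum.sample_id,
        group=spectrum.group,
        metadata=meta,
    )


def estimate_background_threshold(
    spectrum: GCIMSSpectrum,
    background_region: CropRegion,
    quantile: float = 0.99,
    multiplier: float = 1.0,
) -> float:
    """Background-noise threshold: ``multiplier x upper quantile`` of the
    intensities in a signal-free window.

    The background window must be disjoint from the analysis crop (the
    caller's responsibility — typically a margin strip outside it).
    """
    background_region.validate(spectrum.shape)
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must be in [0, 1]")
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    values = spectrum.intensities[
        background_region.rt_start : background_region.rt_stop,
        background_region.dt_start : background_region.dt_stop,
    ]
    return float(multiplier * np.quantile(values, quantile))


def apply_threshold(spectrum: GCIMSSpectrum, tau: float) -> GCIMSSpectrum:
    """Zero every value strictly below ``tau``; values >= tau pass unchanged.

    Idempotent; ``tau = 0`` is the identity on a nonnegative map.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    out = spectrum.intensities.copy()
    out[out < tau] = 0.0
    meta = dict(spectrum.metadata)
    meta["preprocess_steps"] = list(meta.get("preprocess_steps", [])) + ["threshold"]
    meta["threshold_tau"] = float(tau)
    return spectrum.copy_with(intensities=out, metadata=meta)


@dataclass
class FeatureMatrix:
    """Samples x flattened-feature intensities with cell traceability.

    ``feature_index[j]`` is the (rt index, dt index) grid cell of column
    ``j`` in the shared cropped grid; ``shape2d`` is that grid's shape.
    """

    values: np.ndarray  # (n_samples, n_features)
    feature_index: list[tuple[int, int]]
    sample_ids: list[str]
    shape2d: tuple[int, int]
    rt_axis: np.ndarray | None = None
    dt_axis: np.ndarray | None = None
    groups: list[str | None] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (samples x features)")
        if len(self.feature_index) != self.values.shape[1]:
            raise ValueError("feature_index length must equal n_features")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length must equal n_samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def unflatten(self, row: int) -> np.ndarray:
        """Recover one sample's 2D cropped map from its flattened row."""
        return self.values[row].reshape(self.shape2d)


def flatten_stack(spectra: Sequence[GCIMSSpectrum]) -> FeatureMatrix:
    """Flatten same-shaped spectra row-major into a feature matrix.

    All spectra must share the grid (shape and axes); a mismatch raises an
    error naming the offending samples. Row order follows input order.
    """
    if not spectra:
        raise ValueError("no spectra to flatten")
    ref = spectra[0]
    bad = [
        s.sample_id
        for s in spectra
        if s.shape != ref.shape
        or not np.array_equal(s.rt_axis, ref.rt_axis)
        or not np.array_equal(s.dt_axis, ref.dt_axis)
    ]
    if bad:
        raise ValueError(f"spectra with mismatched shape/axes: {bad}")
    n_rt, n_dt = ref.shape
    values = np.stack([s.intensities.ravel(order="C") for s in spectra])
    feature_index = [(i, j) for i in range(n_rt) for j in range(n_dt)]
    return FeatureMatrix(
        values=values,
        feature_index=feature_index,
        sample_ids=[s.sample_id for s in spectra],
        shape2d=(n_rt, n_dt),
        rt_axis=ref.rt_axis.copy(),
        dt_axis=ref.dt_axis.copy(),
        groups=[s.group for s in spectra],
    )


def preprocess_spectrum(
    spectrum: GCIMSSpectrum,
    region: CropRegion,
    background_region: CropRegion | None = None,
    quantile: float = 0.99,
    multiplier: float = 1.0,
    tau: float | None = None,
) -> GCIMSSpectrum:
    """Run the two-stage pipeline on one spectrum, in the fixed order
    crop -> threshold.

    The threshold is estimated on the *uncropped* map from
    ``background_region`` (default: the leading retention-time strip above
    the crop window, restricted to the crop's drift-time columns — disjoint
    from the crop and clear of the reactant-ion line) unless a global
    ``tau`` is supplied. The applied steps are recorded in the output
    metadata as ``["crop", "threshold"]``.
    """
    if tau is None:
        if background_region is None:
            if region.rt_start == 0:
                raise ValueError(
                    "no default background strip exists when the crop starts "
                    "at row 0; pass background_region or tau explicitly"
                )
            background_region = CropRegion(
                0, region.rt_start, region.dt_start, region.dt_stop
            )
        tau = estimate_background_threshold(
            spectrum, background_region, quantile, multiplier
        )
    cropped = crop(spectrum, region)
    return apply_threshold(cropped, tau)


def preprocess_stack(
    spectra: Sequence[GCIMSSpectrum],
    region: CropRegion,
    background_region: CropRegion | None = None,
    quantile: float = 0.99,
    multiplier: float = 1.0,
    global_threshold: bool = False,
) -> FeatureMatrix:
    """Preprocess a cohort of spectra and flatten to a feature matrix.

    By default the threshold is per-sample; with ``global_threshold=True``
    one tau (the median of the per-sample estimates) is applied to all.
    """
    if global_threshold:
        taus = []
        for s in spectra:
            bg = background_region or CropRegion(
                0, max(1, region.rt_start), region.dt_start, region.dt_stop
            )
            taus.append(estimate_background_threshold(s, bg, quantile, multiplier))
        tau = float(np.median(taus))
        processed = [preprocess_spectrum(s, region, tau=tau) for s in spectra]
    else:
        processed = [
            preprocess_spectrum(s, region, background_region, quantile, multiplier)
            for s in spectra
        ]
    return flatten_stack(processed)
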