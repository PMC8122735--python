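"""GC-IMS spectrum container and on-disk formats.

A GC-IMS measurement of one urine-headspace sample is a dense nonnegative
2D intensity map: rows are gas-chromatograph retention times (seconds),
columns are ion-mobility drift times (milliseconds). Two interchangeable
on-disk representations are provided: a plain-text matrix CSV with a JSON
sidecar carrying the axes and metadata, and an HDF5 container holding many
spectra in one file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np


@dataclass
class GCIMSSpectrum:
    """One sample's intensity map with axis coordinates and metadata.

    Parameters
    ----------
    intensities : ndarray, shape (n_rt, n_dt)
        Nonnegative, finite intensities in arbitrary instrument units.
    rt_axis : ndarray, shape (n_rt,)
        Retention-time coordinates in seconds, strictly increasing.
    dt_axis : ndarray, shape (n_dt,)
        Drift-time coordinates in milliseconds, strictly increasing.
    sample_id : str
    group : str or None
        Cohort label, e.g. ``"HCC"``; optional for unlabelled data.
    metadata : dict
        Free-form provenance (generator parameters, preprocessing steps).
    """

    intensities: np.ndarray
    rt_axis: np.ndarray
    dt_axis: np.ndarray
    sample_id: str
    group: str | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.rt_axis = np.asarray(self.rt_axis, dtype=float)
        self.dt_axis = np.asarray(self.dt_axis, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2D matrix")
        if self.intensities.shape != (self.rt_axis.size, self.dt_axis.size):
            raise ValueError(
                f"shape {self.intensities.shape} does not match axes "
                f"({self.rt_axis.size}, {self.dt_axis.size})"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        for name, ax in (("rt_axis", self.rt_axis), ("dt_axis", self.dt_axis)):
            if ax.size and np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def copy_with(self, **kwargs: Any) -> "GCIMSSpectrum":
        """Return a copy with selected fields replaced."""
        out = dict(
            intensities=self.intensities.copy(),
            rt_axis=self.rt_axis.copy(),
            dt_axis=self.dt_axis.copy(),
            sample_id=self.sample_id,
            group=self.group,
            metadata=dict(self.metadata),
        )
        out.update(kwargs)
        return GCIMSSpectrum(**out)


def write_csv(spectrum: GCIMSSpectrum, path: str | Path) -> Path:
    """Write the intensity matrix as CSV plus a ``.json`` sidecar.

    The CSV holds the bare matrix (rows = retention time, columns = drift
    time, no header); axes, sample id, group and metadata go to
    ``<stem>.json`` next to it.
    """
    path = Path(path)
    np.savetxt(path, spectrum.intensities, delimiter=",", fmt="%.8g")
    sidecar = path.with_suffix(".json")
    payload = {
        "sample_id": spectrum.sample_id,
        "group": spectrum.group,
        "rt_axis_s": spectrum.rt_axis.tolist(),
        "dt_axis_ms": spectrum.dt_axis.tolist(),
        "metadata": spectrum.metadata,
    }
    sidecar.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_csv(path: str | Path) -> GCIMSSpectrum:
    """Read a matrix CSV + JSON sidecar written by :func:`write_csv`."""
    path = Path(path)
    intensities = np.atleast_2d(np.loadtxt(path, delimiter=","))
    payload = json.loads(path.with_suffix(".json").read_text())
    return GCIMSSpectrum(
        intensities=intensities,
        rt_axis=np.asarray(payload["rt_axis_s"]),
        dt_axis=np.asarray(payload["dt_axis_ms"]),
        sample_id=payload["sample_id"],
        group=payload.get("group"),
        metadata=payload.get("metadata", {}),
    )


def write_hdf5(spectra: list[GCIMSSpectrum], path: str | Path) -> Path:
    """Store many spectra in one HDF5 file (one group per sample)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        for s in spectra:
            g = f.create_group(s.sample_id)
            g.create_dataset("intensities", data=s.intensities)
            g.create_dataset("rt_axis_s", data=s.rt_axis)
            g.create_dataset("dt_axis_ms", data=s.dt_axis)
            g.attrs["sample_id"] = s.sample_id
            g.attrs["group"] = s.group if s.group is not None else ""
            g.attrs["metadata_json"] = json.dumps(s.metadata, sort_keys=True)
    return path


def read_hdf5(path: str | Path) -> list[GCIMSSpectrum]:
    """Read all spectra from an HDF5 container, sorted by sample id."""
    import h5py

    out: list[GCIMSSpectrum] = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            group = g.attrs["group"] or None
            out.append(
                GCIMSSpectrum(
                    intensities=g["intensities"][...],
                    rt_axis=g["rt_axis_s"][...],
                    dt_axis=g["dt_axis_ms"][...],
                    sample_id=str(g.attrs["sample_id"]),
                    group=str(group) if group else None,
                    metadata=json.loads(g.attrs["metadata_json"]),
                )
            )
    return out
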