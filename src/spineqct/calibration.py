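"""Phantom-based HU -> BMD calibration.

Every scan session includes a hydroxyapatite phantom with rods of known
density (mg/cm^3).  An ordinary least-squares line through (rod mean HU,
rod nominal density) converts Hounsfield units to volumetric BMD.  One
calibration is fitted per session — scanner drift between sessions is
exactly what the in-scan phantom corrects for — and rod ROIs are eroded
by one voxel in-plane before averaging to avoid the partial-volume rim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage, stats
from skimage.morphology import disk

from .errors import CalibrationError
from .volume import CTVolume

__all__ = ["CalibrationModel", "fit_calibration", "measure_rod_hu", "hu_to_bmd",
           "calibrate_session"]


@dataclass(frozen=True)
class CalibrationModel:
    """Linear HU -> BMD map: density = slope * HU + intercept."""

    slope: float       # mg/cm^3 per HU
    intercept: float   # mg/cm^3
    r_squared: float
    n_rods: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope == 0:
            raise CalibrationError(f"slope: must be finite and nonzero, got {self.slope}")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise CalibrationError(f"r_squared: must lie in [0, 1], got {self.r_squared}")
        if self.n_rods < 2:
            raise CalibrationError(f"n_rods: need at least 2 rods, got {self.n_rods}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_calibration(rod_mean_hu, rod_densities) -> CalibrationModel:
    """OLS fit of nominal rod density (mg/cm^3) on measured rod mean HU."""
    hu = np.asarray(rod_mean_hu, dtype=float)
    rho = np.asarray(rod_densities, dtype=float)
    if hu.shape != rho.shape or hu.ndim != 1:
        raise CalibrationError(
            f"rod lists must be equal-length 1-D, got {hu.shape} and {rho.shape}"
        )
    if hu.size < 2:
        raise CalibrationError(f"need at least 2 rods, got {hu.size}")
    if np.ptp(hu) == 0:
        raise CalibrationError("degenerate rods: all mean HU values identical")
    fit = stats.linregress(hu, rho)
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_rods=int(hu.size),
    )


def measure_rod_hu(
    volume: CTVolume,
    rod_mask: CTVolume,
    erosion_mm: float = 1.0,
) -> dict[int, float]:
    """Mean HU per rod label after in-plane erosion, label-ordered.

    ``rod_mask`` is an integer label volume (0 = background); each nonzero
    label is one rod.  Erosion by more than the rod radius empties the ROI
    and raises, naming the rod.
    """
    labels = rod_mask.data
    if labels.shape != volume.shape:
        raise CalibrationError("rod_mask grid does not match volume")
    rod_labels = np.unique(labels)
    rod_labels = rod_labels[rod_labels != 0]
    if rod_labels.size == 0:
        raise CalibrationError("rod_mask: no rod labels present")

    r = int(round(erosion_mm / volume.spacing[0]))
    footprint = disk(r)[:, :, None] if r > 0 else None

    means: dict[int, float] = {}
    for lab in rod_labels:
        m = labels == lab
        if footprint is not None:
            m = ndimage.binary_erosion(m, structure=footprint)
        if not m.any():
            raise CalibrationError(
                f"rod label {int(lab)}: empty after {erosion_mm} mm erosion"
            )
        means[int(lab)] = float(volume.data[m].mean())
    return means


def hu_to_bmd(hu_value, model: CalibrationModel):
    """Convert HU to mg/cm^3 hydroxyapatite.  Affine, so it commutes with means."""
    return model.slope * np.asarray(hu_value, dtype=float) + model.intercept


def calibrate_session(
    volume: CTVolume,
    rod_mask: CTVolume,
    rod_densities_by_label: dict[int, float],
    erosion_mm: float = 1.0,
) -> CalibrationModel:
    """Measure the session's rods and fit its calibration line."""
    means = measure_rod_hu(volume, rod_mask, erosion_mm)
    labels = sorted(means)
    missing = [lab for lab in labels if lab not in rod_densities_by_label]
    if missing:
        raise CalibrationError(f"no nominal density for rod labels {missing}")
    return fit_calibration(
        [means[lab] for lab in labels],
        [rod_densities_by_label[lab] for lab in labels],
    )
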