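"""Paraspinal muscle CSA and attenuation-based density at the L1 mid-slice.

Measurements are taken on a single axial slice — the mid-vertebral level,
defined as the (lower) median mask-bearing slice of the vertebral body
mask, mapped from preflight so levels stay matched across sessions.
Muscle contours are *inputs* (labels from the generator, or operator
contours); this module measures, it does not segment.

Voxels outside the closed window [-50, 150] HU are excluded before
anything is computed, removing pure fat, tendon and bone at the contour
periphery.  Per muscle, left and right sides are averaged; total CSA is
the sum of the four side-averaged CSAs and total density their CSA-
weighted mean attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MeasurementError, ValidationError
from .volume import CTVolume

__all__ = [
    "HU_WINDOW",
    "MuscleMeasurement",
    "MuscleTotals",
    "select_mid_slice",
    "measure_muscle",
    "compute_totals",
    "measure_session_muscles",
]

HU_WINDOW = (-50.0, 150.0)


@dataclass(frozen=True)
class MuscleMeasurement:
    """One muscle contour on one slice, after the HU window."""

    muscle_name: str
    side: str
    csa: float                 # mm^2, retained voxels only
    density: float             # mean HU of retained voxels; NaN if none retained
    retained_voxels: int
    excluded_voxels: int

    @property
    def density_defined(self) -> bool:
        return self.retained_voxels > 0


@dataclass(frozen=True)
class MuscleTotals:
    total_csa: float        # mm^2, sum of the four side-averaged CSAs
    total_density: float    # HU, CSA-weighted mean of side-averaged densities
    per_muscle_csa: dict    # name -> side-averaged CSA
    per_muscle_density: dict


def select_mid_slice(body_mask: CTVolume | np.ndarray) -> int:
    """Lower-median axial index of the mask-bearing slices."""
    mask = body_mask.data if isinstance(body_mask, CTVolume) else body_mask
    occupied = np.flatnonzero(np.asarray(mask).astype(bool).any(axis=(0, 1)))
    if occupied.size == 0:
        raise MeasurementError("body mask: empty, cannot select mid-slice")
    return int(occupied[(occupied.size - 1) // 2])


def measure_muscle(
    slice_hu: np.ndarray,
    contour: np.ndarray,
    voxel_area_mm2: float,
    window: tuple[float, float] = HU_WINDOW,
    muscle_name: str = "",
    side: str = "",
) -> MuscleMeasurement:
    """Apply the HU window inside a contour; CSA and density from retained voxels.

    The window is closed at both ends.  A contour whose voxels are all
    excluded yields csa 0 with density flagged undefined (NaN) — never a
    silent zero density.
    """
    contour = np.asarray(contour).astype(bool)
    if contour.shape != np.asarray(slice_hu).shape:
        raise ValidationError("contour: shape does not match slice")
    n_contour = int(contour.sum())
    if n_contour == 0:
        raise MeasurementError(f"contour {muscle_name}/{side}: empty")
    lo, hi = window
    vals = np.asarray(slice_hu, dtype=float)[contour]
    keep = (vals >= lo) & (vals <= hi)
    n_keep = int(keep.sum())
    return MuscleMeasurement(
        muscle_name=muscle_name,
        side=side,
        csa=n_keep * float(voxel_area_mm2),
        density=float(vals[keep].mean()) if n_keep else float("nan"),
        retained_voxels=n_keep,
        excluded_voxels=n_contour - n_keep,
    )


def compute_totals(
    measurements: list[MuscleMeasurement],
    side_combine: str = "average",
    allow_missing_side: bool = False,
) -> MuscleTotals:
    """Side-combine per muscle, then sum CSAs and CSA-weight densities.

    ``side_combine="average"`` (default) averages left/right CSA and
    density per muscle before totals; ``"sum"`` adds the two CSAs instead
    (densities are always side-averaged).  Muscles with no retained voxels
    contribute zero CSA and no weight to the density.
    """
    if side_combine not in ("average", "sum"):
        raise ValidationError(f"side_combine: must be 'average' or 'sum', got {side_combine!r}")
    by_name: dict[str, dict[str, MuscleMeasurement]] = {}
    for m in measurements:
        by_name.setdefault(m.muscle_name, {})[m.side] = m

    per_csa, per_density = {}, {}
    for name, sides in by_name.items():
        missing = {"left", "right"} - set(sides)
        if missing and not allow_missing_side:
            raise MeasurementError(
                f"muscle {name!r}: missing side(s) {sorted(missing)} "
                "(pass allow_missing_side=True to measure one-sided)"
            )
        ms = list(sides.values())
        csas = [m.csa for m in ms]
        per_csa[name] = float(np.sum(csas) if side_combine == "sum" else np.mean(csas))
        dens = [m.density for m in ms if m.density_defined]
        per_density[name] = float(np.mean(dens)) if dens else float("nan")

    total_csa = float(sum(per_csa.values()))
    weighted = [
        (per_csa[n], per_density[n]) for n in per_csa
        if per_csa[n] > 0 and np.isfinite(per_density[n])
    ]
    if weighted:
        w = np.array([c for c, _ in weighted])
        d = np.array([x for _, x in weighted])
        total_density = float((w * d).sum() / w.sum())
    else:
        total_density = float("nan")
    return MuscleTotals(total_csa, total_density, per_csa, per_density)


def measure_session_muscles(
    volume: CTVolume,
    labels: CTVolume,
    muscle_legend: dict,
    mid_slice: int,
    window: tuple[float, float] = HU_WINDOW,
    side_combine: str = "average",
) -> MuscleTotals:
    """Measure all muscles of one session at the given axial slice.

    ``muscle_legend`` maps label code -> {"name", "side"} (as produced by
    the generator or a contouring tool).
    """
    if not 0 <= mid_slice < volume.shape[2]:
        raise MeasurementError(f"mid_slice {mid_slice} outside volume extent")
    hu = volume.data[:, :, mid_slice]
    lab = labels.data[:, :, mid_slice]
    voxel_area = volume.spacing[0] * volume.spacing[1]
    measurements = []
    for code, meta in muscle_legend.items():
        contour = lab == int(code)
        measurements.append(
            measure_muscle(hu, contour, voxel_area, window,
                           muscle_name=meta["name"], side=meta["side"])
        )
    return compute_totals(measurements, side_combine=side_combine)
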