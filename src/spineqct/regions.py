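"""Trabecular mask construction, regional partition, and bone metrics.

The vertebral-body mask is stripped of cortical bone (in-plane erosion)
and endplates (axial trim) to give the trabecular mask, which is then
tiled into three axial slabs — inferior, transverse (middle), superior —
by cumulative fraction of the trabecular slices.  Global trabecular vBMD
is the calibrated mean over the whole mask; by construction it equals the
voxel-count-weighted mean of the three regional values.

All masks are defined once on the preflight grid and mapped into other
sessions by the registration module (matched regions of interest); they
are never re-segmented per session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .calibration import CalibrationModel, hu_to_bmd
from .errors import MeasurementError, ValidationError
from .volume import CTVolume

__all__ = [
    "TrabecularMask",
    "RegionPartition",
    "BoneMetrics",
    "slab_counts",
    "extract_trabecular_mask",
    "partition_regions",
    "compute_bone_metrics",
]

REGIONS = ("inferior", "transverse", "superior")


def slab_counts(n_slices: int, fractions=(1 / 3, 1 / 3, 1 / 3)) -> tuple[int, int, int]:
    """Slices per region for an ``n_slices`` axial extent.

    ``fractions`` is (inferior, transverse, superior) and must sum to 1.
    Inferior and superior get ``floor(f * n)`` slices; remainder slices go
    to the transverse (middle) slab.
    """
    f = np.asarray(fractions, dtype=float)
    if f.shape != (3,) or np.any(f < 0) or not np.isclose(f.sum(), 1.0):
        raise ValidationError(
            f"fractions: need three non-negative numbers summing to 1, got {fractions}"
        )
    n_inf = int(np.floor(f[0] * n_slices))
    n_sup = int(np.floor(f[2] * n_slices))
    n_trans = n_slices - n_inf - n_sup
    return n_inf, n_trans, n_sup


@dataclass
class TrabecularMask:
    """Binary trabecular mask on the preflight grid, with provenance."""

    mask: CTVolume
    cortical_margin_mm: float
    endplate_margin_mm: float

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask.data))


@dataclass
class RegionPartition:
    """Three disjoint slabs that exactly tile the trabecular mask."""

    superior: CTVolume
    transverse: CTVolume
    inferior: CTVolume
    split_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def as_dict(self) -> dict[str, CTVolume]:
        return {"inferior": self.inferior, "transverse": self.transverse,
                "superior": self.superior}

    def union(self) -> np.ndarray:
        return self.superior.data | self.transverse.data | self.inferior.data

    def voxel_counts(self) -> dict[str, int]:
        return {name: int(np.count_nonzero(m.data)) for name, m in self.as_dict().items()}


@dataclass
class BoneMetrics:
    """Calibrated global and regional trabecular BMD (mg/cm^3).

    ``global_weights`` are the per-region voxel counts the global value
    aggregates over; the global equals the weight-weighted mean of the
    regional values exactly.
    """

    global_tb_vbmd: float
    rbmd_superior: float
    rbmd_transverse: float
    rbmd_inferior: float
    voxel_counts: dict[str, int] = field(default_factory=dict)
    global_weights: dict[str, int] = field(default_factory=dict)

    def regional(self) -> dict[str, float]:
        return {"inferior": self.rbmd_inferior, "transverse": self.rbmd_transverse,
                "superior": self.rbmd_superior}


def _inplane_margin_voxels(margin_mm: float, spacing) -> int:
    sx, sy = spacing[0], spacing[1]
    if not np.isclose(sx, sy):
        raise ValidationError(
            f"spacing: in-plane erosion assumes isotropic in-plane spacing, got {sx} x {sy}"
        )
    return int(round(margin_mm / sx))


def extract_trabecular_mask(
    body_mask: CTVolume,
    cortical_margin_mm: float = 3.0,
    endplate_margin_mm: float = 3.0,
) -> TrabecularMask:
    """Erode the body mask in-plane and trim its axial ends.

    ``cortical_margin_mm`` is converted to an in-plane disk radius,
    ``endplate_margin_mm`` to a number of axial slices removed from each
    end of the mask's occupied extent.  The result must be non-empty.
    """
    if cortical_margin_mm < 0 or endplate_margin_mm < 0:
        raise ValidationError("margins: cortical_margin_mm and endplate_margin_mm must be >= 0")
    body = body_mask.data.astype(bool)
    if not body.any():
        raise MeasurementError("body_mask: empty mask")

    r = _inplane_margin_voxels(cortical_margin_mm, body_mask.spacing)
    if r > 0:
        footprint = disk(r)[:, :, None]  # in-plane only: no erosion along axis 2
        trab = ndimage.binary_erosion(body, structure=footprint)
    else:
        trab = body.copy()

    n_trim = int(round(endplate_margin_mm / body_mask.spacing[2]))
    if n_trim > 0:
        occupied = np.flatnonzero(trab.any(axis=(0, 1)))
        if occupied.size <= 2 * n_trim:
            raise MeasurementError(
                "margins consume the whole body: remaining voxel count 0"
            )
        kill = np.concatenate([occupied[:n_trim], occupied[-n_trim:]])
        trab[:, :, kill] = False

    if not trab.any():
        raise MeasurementError("margins consume the whole body: remaining voxel count 0")
    return TrabecularMask(body_mask.like(trab), cortical_margin_mm, endplate_margin_mm)


def partition_regions(
    trabecular: TrabecularMask | CTVolume,
    fractions=(1 / 3, 1 / 3, 1 / 3),
) -> RegionPartition:
    """Tile the trabecular mask into inferior / transverse / superior slabs.

    Whole axial slices are assigned inferior -> superior by cumulative
    fraction of the mask-bearing slices (remainder to the transverse
    slab), so the three regions are pairwise disjoint and their union is
    exactly the input mask.
    """
    mask_vol = trabecular.mask if isinstance(trabecular, TrabecularMask) else trabecular
    mask = mask_vol.data.astype(bool)
    occupied = np.flatnonzero(mask.any(axis=(0, 1)))
    if occupied.size < 3:
        raise MeasurementError(
            f"trabecular mask spans {occupied.size} slices; need at least 3 to partition"
        )
    n_inf, n_trans, n_sup = slab_counts(occupied.size, fractions)

    out = {}
    slabs = {
        "inferior": occupied[:n_inf],
        "transverse": occupied[n_inf:n_inf + n_trans],
        "superior": occupied[n_inf + n_trans:],
    }
    for name, slices in slabs.items():
        m = np.zeros_like(mask)
        if slices.size:
            m[:, :, slices] = mask[:, :, slices]
        out[name] = mask_vol.like(m)
    return RegionPartition(
        superior=out["superior"], transverse=out["transverse"],
        inferior=out["inferior"], split_fractions=tuple(fractions),
    )


def compute_bone_metrics(
    session_volume: CTVolume,
    partition: RegionPartition,
    model: CalibrationModel,
    global_weights: dict[str, int] | None = None,
) -> BoneMetrics:
    """Calibrated mean BMD per region and over the whole trabecular mask.

    ``global_weights`` optionally fixes the per-region voxel weights used
    for the global aggregate — in a matched-ROI longitudinal design the
    preflight counts, so the global composition stays identical across
    sessions even when mapped masks lose a few edge voxels.  The
    calibration is affine, so the global equals the weight-weighted mean
    of the regional values exactly.
    """
    hu = session_volume.data
    counts, rbmd, mean_hu = {}, {}, {}
    for name, mask in partition.as_dict().items():
        m = mask.data.astype(bool)
        n = int(np.count_nonzero(m))
        if n == 0:
            raise MeasurementError(f"region '{name}': empty in session grid")
        if m.shape != hu.shape:
            raise MeasurementError(f"region '{name}': mask grid does not match session volume")
        counts[name] = n
        mean_hu[name] = float(hu[m].mean())
        rbmd[name] = hu_to_bmd(mean_hu[name], model)
    weights = dict(global_weights) if global_weights else counts
    if set(weights) != set(counts) or any(w <= 0 for w in weights.values()):
        raise MeasurementError(f"global_weights: need positive weights for {REGIONS}")
    total_w = sum(weights.values())
    global_bmd = hu_to_bmd(
        sum(weights[r] * mean_hu[r] for r in weights) / total_w, model
    )
    return BoneMetrics(
        global_tb_vbmd=global_bmd,
        rbmd_superior=rbmd["superior"],
        rbmd_transverse=rbmd["transverse"],
        rbmd_inferior=rbmd["inferior"],
        voxel_counts=counts,
        global_weights=weights,
    )
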