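"""Synthetic CT cohort generator.

Builds seeded, fully ground-truthed lumbar-spine CT cohorts that emulate a
longitudinal spaceflight study design: 17 subjects scanned at up to three
sessions (preflight, postflight, follow-up after ~12 months of
readaptation), mission durations drawn from the multiset
{4,4,5,5,5,6x7,7x5} months, and two subjects missing the follow-up scan.

Each session is a 3-D HU volume plus an integer label map containing:

* an L1-like vertebral body — an elliptic cylinder with a cortical shell,
  flat endplate slabs, and a trabecular interior split into inferior /
  transverse / superior slabs, each rendered at its own injected density;
* four paired paraspinal muscles (erector spinae, transversospinalis,
  psoas major, quadratus lumborum) as elliptic cylinders whose voxels are
  a Bernoulli lean/fat mixture (fat falls below the -50 HU analysis
  window, so fat infiltration lowers CSA but not in-window attenuation;
  in-window attenuation is steered via the lean-tissue HU);
* a calibration phantom with rods of known hydroxyapatite density.

Intensities are synthesised through the *inverse* of a known linear
HU->BMD calibration, sessions are displaced by known rigid offsets, and
every injected density, rate, and transform is recorded in a ground-truth
table, so the full analysis pipeline can be scored against exact truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .regions import REGIONS, slab_counts
from .registration import RigidTransform
from .volume import CTVolume, save_nifti

__all__ = [
    "GridSpec",
    "VertebraSpec",
    "MuscleSpec",
    "PhantomSpec",
    "SubjectTrajectory",
    "CohortConfig",
    "SessionImage",
    "SubjectData",
    "Cohort",
    "LABELS",
    "default_muscles",
    "render_session",
    "sample_trajectories",
    "generate_cohort",
]

SESSIONS = ("preflight", "postflight", "followup")

# label codes of the rendered segmentation
LABELS = {
    "trabecular": 1,
    "cortical": 2,
    "endplate": 3,
    "posterior_elements": 4,
}
ROD_LABEL_BASE = 10    # rod i -> 10 + i
MUSCLE_LABEL_BASE = 20  # muscle j (template order) -> 20 + j

#: z sub-sample offsets (units of slice pitch / 3) and weights per profile
SLICE_PROFILES = {
    "point": ((0.0,), (1.0,)),
    "box": ((-1.0, -0.5, 0.0, 0.5, 1.0), (1.0, 1.0, 1.0, 1.0, 1.0)),
    "triangle": ((-0.8, -0.4, 0.0, 0.4, 0.8), (1.0, 2.0, 3.0, 2.0, 1.0)),
}

MUSCLE_NAMES = (
    "erector_spinae",
    "transversospinalis",
    "psoas_major",
    "quadratus_lumborum",
)


@dataclass(frozen=True)
class GridSpec:
    """Reconstruction grid: shape, spacing (mm) and a centred world origin."""

    shape: tuple[int, int, int] = (96, 96, 40)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)

    @property
    def origin(self) -> tuple[float, float, float]:
        return tuple(-(n - 1) / 2 * s for n, s in zip(self.shape, self.spacing))

    def empty(self, dtype=float) -> CTVolume:
        return CTVolume(np.zeros(self.shape, dtype=dtype), self.spacing, self.origin)

    def slice_centers_z(self) -> np.ndarray:
        return self.origin[2] + np.arange(self.shape[2]) * self.spacing[2]


@dataclass(frozen=True)
class LinearHUMap:
    """The generator's ground-truth calibration: density = slope*HU + intercept."""

    slope: float = 0.78    # mg/cm^3 per HU
    intercept: float = -3.2

    def density_to_hu(self, density):
        if self.slope == 0 or not np.isfinite(self.slope):
            raise ValidationError("calibration_truth.slope: must be finite and nonzero")
        return (np.asarray(density, dtype=float) - self.intercept) / self.slope

    def hu_to_density(self, hu):
        return self.slope * np.asarray(hu, dtype=float) + self.intercept


@dataclass(frozen=True)
class VertebraSpec:
    """Stylised vertebral body: elliptic cylinder + shell + endplate slabs."""

    body_half_axes: tuple[float, float] = (20.0, 13.0)  # (lateral, AP) semi-axes, mm
    body_height: float = 30.6                           # mm along the longitudinal axis
    cortical_thickness: float = 2.0                     # in-plane shell, mm
    endplate_thickness: float = 3.3                     # axial slab at each end, mm
    regional_trabecular_density: dict = field(
        default_factory=lambda: {"superior": 178.9, "transverse": 177.5, "inferior": 196.5}
    )                                                   # mg/cm^3 per region
    posterior_elements: bool = True
    center: tuple[float, float, float] = (0.0, 10.0, 0.0)
    region_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    #: trabecular slab adjacent to each endplate that takes the adjacent
    #: region's density; the analysis excludes it via its endplate margin,
    #: so mapped-mask edge voxels sample same-density tissue
    region_transition_mm: float = 3.0
    cortical_density: float = 550.0    # mg/cm^3
    endplate_density: float = 450.0
    posterior_density: float = 350.0

    def validate(self) -> None:
        if any(a <= 0 for a in self.body_half_axes):
            raise ValidationError(f"body_half_axes: must be > 0, got {self.body_half_axes}")
        if self.body_height <= 0:
            raise ValidationError(f"body_height: must be > 0, got {self.body_height}")
        if self.cortical_thickness <= 0 or self.endplate_thickness <= 0:
            raise ValidationError(
                "cortical_thickness/endplate_thickness: must be > 0, got "
                f"{self.cortical_thickness}/{self.endplate_thickness}"
            )
        if self.cortical_thickness + self.endplate_thickness >= self.body_height / 2:
            raise ValidationError(
                "cortical_thickness + endplate_thickness must be < body_height/2"
            )
        if self.region_transition_mm < 0:
            raise ValidationError(
                f"region_transition_mm: must be >= 0, got {self.region_transition_mm}"
            )
        if set(self.regional_trabecular_density) != set(REGIONS):
            raise ValidationError(
                f"regional_trabecular_density: need keys {REGIONS}, "
                f"got {tuple(self.regional_trabecular_density)}"
            )
        for r, d in self.regional_trabecular_density.items():
            if d < 0:
                raise ValidationError(f"regional_trabecular_density[{r!r}]: must be >= 0, got {d}")

    def with_percent_change(self, percent_by_region: dict) -> "VertebraSpec":
        """Copy with each regional density scaled by (1 + pct/100)."""
        dens = {
            r: self.regional_trabecular_density[r] * (1 + percent_by_region[r] / 100.0)
            for r in REGIONS
        }
        return replace(self, regional_trabecular_density=dens)


@dataclass(frozen=True)
class MuscleSpec:
    """One paraspinal muscle: elliptic cylinder with a Bernoulli fat mixture."""

    muscle_name: str
    side: str                              # "left" | "right"
    center_xy: tuple[float, float]         # mm, axial plane
    area: float                            # geometric contour area, mm^2
    lean_fraction: float = 0.92            # P(voxel is lean)
    lean_hu: float = 50.0
    fat_hu: float = -100.0
    aspect: float = 1.0                    # in-plane semi-axis ratio a_x / a_y
    z_half_extent: float = 19.8            # mm

    def validate(self) -> None:
        if self.muscle_name not in MUSCLE_NAMES:
            raise ValidationError(
                f"muscle_name: {self.muscle_name!r} not one of {MUSCLE_NAMES}"
            )
        if self.side not in ("left", "right"):
            raise ValidationError(f"side: must be 'left' or 'right', got {self.side!r}")
        if self.area <= 0:
            raise ValidationError(f"area: must be > 0, got {self.area}")
        if not 0 <= self.lean_fraction <= 1:
            raise ValidationError(f"lean_fraction: must be in [0, 1], got {self.lean_fraction}")
        if not (self.fat_hu < -50 <= self.lean_hu <= 150):
            raise ValidationError(
                "lean_hu/fat_hu: need fat_hu < -50 <= lean_hu <= 150, got "
                f"fat_hu={self.fat_hu}, lean_hu={self.lean_hu}"
            )
        if self.aspect <= 0 or self.z_half_extent <= 0:
            raise ValidationError("aspect/z_half_extent: must be > 0")

    @property
    def semi_axes(self) -> tuple[float, float]:
        ay = float(np.sqrt(self.area / (np.pi * self.aspect)))
        return self.aspect * ay, ay

    def scaled(self, csa_percent: float, density_percent: float) -> "MuscleSpec":
        """Copy with geometric area and lean HU scaled by the given percent changes."""
        return replace(
            self,
            area=self.area * (1 + csa_percent / 100.0),
            lean_hu=self.lean_hu * (1 + density_percent / 100.0),
        )


def default_muscles(
    lean_fraction: float = 0.92,
    lean_hu: float = 50.0,
    fat_hu: float = -100.0,
) -> list[MuscleSpec]:
    """The four paired paraspinal muscles at L1 (stylised sizes and positions)."""
    template = [
        # name, |x| centre, y centre, area mm^2, aspect
        # placed with >=2.5 mm nominal clearance so contours stay disjoint
        # under per-subject jitter and size variation
        ("erector_spinae", 30.0, -20.0, 415.0, 11 / 12),
        ("transversospinalis", 9.5, -12.0, 151.0, 0.75),
        ("psoas_major", 15.5, 30.0, 176.0, 0.875),
        ("quadratus_lumborum", 33.0, 3.0, 176.0, 8 / 7),
    ]
    out = []
    for name, ax, y, area, aspect in template:
        for side, sign in (("left", -1.0), ("right", 1.0)):
            out.append(
                MuscleSpec(
                    muscle_name=name, side=side, center_xy=(sign * ax, y),
                    area=area, lean_fraction=lean_fraction, lean_hu=lean_hu,
                    fat_hu=fat_hu, aspect=aspect,
                )
            )
    return out


@dataclass(frozen=True)
class PhantomSpec:
    """In-scan calibration phantom: parallel rods of known density."""

    rod_nominal_densities: tuple[float, ...] = (0.0, 100.0, 200.0)  # mg/cm^3 HA
    rod_radius: float = 5.0                                          # mm
    rod_positions: tuple[tuple[float, float], ...] = ((-30.0, -41.0), (0.0, -41.0), (30.0, -41.0))

    def validate(self) -> None:
        if len(set(self.rod_nominal_densities)) < 2:
            raise ValidationError(
                "rod_nominal_densities: need at least 2 distinct densities, got "
                f"{self.rod_nominal_densities}"
            )
        if len(self.rod_positions) != len(self.rod_nominal_densities):
            raise ValidationError("rod_positions: one position per rod density required")
        if self.rod_radius <= 0:
            raise ValidationError(f"rod_radius: must be > 0, got {self.rod_radius}")
        pos = np.asarray(self.rod_positions, dtype=float)
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if np.linalg.norm(pos[i] - pos[j]) < 2 * self.rod_radius:
                    raise ValidationError(f"rod_positions: rods {i} and {j} overlap")

    def labels(self) -> dict[int, float]:
        return {ROD_LABEL_BASE + i: d for i, d in enumerate(self.rod_nominal_densities)}


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _region_z_bounds(vertebra: VertebraSpec, grid: GridSpec) -> tuple[float, float]:
    """Scene-space z planes separating the three trabecular slabs.

    Derived from the reference grid's slice centres with the same
    floor/remainder rule the analysis partition uses, so injected regional
    densities align with the analysed slabs slice-for-slice.  The
    transition slabs next to the endplates are excluded from the split and
    fall to the adjacent (inferior/superior) region by the bound tests.
    """
    cz = vertebra.center[2]
    half_interior = (vertebra.body_height / 2 - vertebra.endplate_thickness
                     - vertebra.region_transition_mm)
    centers = grid.slice_centers_z()
    interior = centers[np.abs(centers - cz) <= half_interior + 1e-9]
    if interior.size < 3:
        raise ValidationError(
            "body_height: trabecular interior spans fewer than 3 slices on this grid"
        )
    n_inf, n_trans, n_sup = slab_counts(interior.size, vertebra.region_fractions)
    z_lo = (interior[n_inf - 1] + interior[n_inf]) / 2 if n_inf > 0 else interior[0] - 1e-9
    hi_start = n_inf + n_trans
    z_hi = (
        (interior[hi_start - 1] + interior[hi_start]) / 2
        if n_sup > 0 else interior[-1] + 1e-9
    )
    return float(z_lo), float(z_hi)


def render_session(
    vertebra: VertebraSpec,
    muscles: list[MuscleSpec],
    phantom: PhantomSpec,
    calibration_truth: LinearHUMap,
    noise_sd: float,
    rng: np.random.Generator,
    grid: GridSpec = GridSpec(),
    offset: RigidTransform | None = None,
    background_hu: float = 0.0,
    background_heterogeneity_hu: float = 12.0,
    slice_profile: str = "triangle",
) -> tuple[CTVolume, CTVolume, dict]:
    """Render one scan session: HU volume + label map + label legend.

    ``offset`` is the subject's rigid repositioning for this session: it
    maps scene (preflight) points into this session's world space, so the
    anatomy is evaluated at the inversely-transformed voxel centres —
    analytically, with no interpolation.
    """
    vertebra.validate()
    for m in muscles:
        m.validate()
    phantom.validate()
    if noise_sd < 0:
        raise ValidationError(f"noise_sd: must be >= 0, got {noise_sd}")

    vol = grid.empty(float)
    X, Y, Z = vol.world_coordinates()

    def scene_coords(dz: float):
        """Scene-frame coordinates of voxel centres shifted by dz (mm, world z)."""
        if offset is not None and not (
            np.allclose(offset.matrix, np.eye(3))
            and np.allclose(offset.translation, 0)
        ):
            inv = offset.inverse()
            pts = np.stack([X.ravel(), Y.ravel(), (Z + dz).ravel()], axis=1)
            scene = inv.apply(pts)
            return (scene[:, 0].reshape(X.shape), scene[:, 1].reshape(X.shape),
                    scene[:, 2].reshape(X.shape))
        return X, Y, Z + dz

    z_lo, z_hi = _region_z_bounds(vertebra, grid)
    cx, cy, cz = vertebra.center
    ax, ay = vertebra.body_half_axes
    half_h = vertebra.body_height / 2
    ct = vertebra.cortical_thickness

    def bone_fields(PX, PY, PZ):
        """Deterministic HU and label at scene points (bone, rods, background)."""
        # smooth soft-tissue heterogeneity, fixed in the anatomy's frame:
        # real scans are not piecewise constant, and this band-limited
        # component is what gives serial-scan registration continuous
        # sub-voxel sensitivity; it never touches a measured tissue
        het = background_heterogeneity_hu * (
            np.sin(2 * np.pi * PX / 23.0 + 0.7)
            + np.sin(2 * np.pi * PY / 31.0 + 2.1)
            + np.sin(2 * np.pi * PZ / 17.0 + 4.2)
        ) / 3.0
        hu = float(background_hu) + het
        labels = np.zeros(grid.shape, dtype=np.int16)
        in_body_z = np.abs(PZ - cz) <= half_h
        body_xy = ((PX - cx) / ax) ** 2 + ((PY - cy) / ay) ** 2 <= 1
        body = body_xy & in_body_z
        endplate = body & (np.abs(PZ - cz) > half_h - vertebra.endplate_thickness)
        interior = body & ~endplate
        inner_xy = ((PX - cx) / (ax - ct)) ** 2 + ((PY - cy) / (ay - ct)) ** 2 <= 1
        cortical = interior & ~inner_xy
        trabecular = interior & inner_xy

        if vertebra.posterior_elements:
            post = (
                (np.abs(PX - cx) <= 4.0)
                & (PY >= cy - ay - 11.0)
                & (PY <= cy - ay - 1.0)
                & in_body_z
            )
            hu[post] = calibration_truth.density_to_hu(vertebra.posterior_density)
            labels[post] = LABELS["posterior_elements"]

        hu[cortical] = calibration_truth.density_to_hu(vertebra.cortical_density)
        labels[cortical] = LABELS["cortical"]
        hu[endplate] = calibration_truth.density_to_hu(vertebra.endplate_density)
        labels[endplate] = LABELS["endplate"]

        region_masks = {
            "inferior": trabecular & (PZ < z_lo),
            "transverse": trabecular & (PZ >= z_lo) & (PZ <= z_hi),
            "superior": trabecular & (PZ > z_hi),
        }
        for region, mask in region_masks.items():
            hu[mask] = calibration_truth.density_to_hu(
                vertebra.regional_trabecular_density[region]
            )
            labels[mask] = LABELS["trabecular"]

        for i, ((rx, ry), rho) in enumerate(
            zip(phantom.rod_positions, phantom.rod_nominal_densities)
        ):
            m = (PX - rx) ** 2 + (PY - ry) ** 2 <= phantom.rod_radius**2
            hu[m] = calibration_truth.density_to_hu(rho)
            labels[m] = ROD_LABEL_BASE + i
        return hu, labels

    # slice sensitivity profile: a CT slice integrates through its
    # thickness, so the deterministic scene is averaged over weighted z
    # sub-samples around each slice centre (axial SSPs are approximately
    # triangular).  Sub-sample reach stays under half the slice pitch, so
    # measured-tissue interfaces — which the vertebra geometry places at
    # mid-slice planes — are never straddled in an unshifted render.
    try:
        offsets, weights = SLICE_PROFILES[slice_profile]
    except KeyError:
        raise ValidationError(
            f"slice_profile: must be one of {sorted(SLICE_PROFILES)}, got {slice_profile!r}"
        ) from None
    scale = grid.spacing[2] / 3.0
    w = np.asarray(weights, float)
    w = w / w.sum()
    hu = np.zeros(grid.shape)
    for dz, wi in zip(offsets, w):
        hu += wi * bone_fields(*scene_coords(dz * scale))[0]
    PX, PY, PZ = scene_coords(0.0)
    labels = bone_fields(PX, PY, PZ)[1]

    muscle_legend = {}
    for j, spec in enumerate(muscles):
        sa_x, sa_y = spec.semi_axes
        mx, my = spec.center_xy
        m = (
            (((PX - mx) / sa_x) ** 2 + ((PY - my) / sa_y) ** 2 <= 1)
            & (np.abs(PZ - cz) <= spec.z_half_extent)
        )
        lean = rng.random(int(m.sum())) < spec.lean_fraction
        vals = np.where(lean, spec.lean_hu, spec.fat_hu)
        hu[m] = vals
        lab = MUSCLE_LABEL_BASE + j
        labels[m] = lab
        muscle_legend[lab] = {"name": spec.muscle_name, "side": spec.side}

    rod_legend = {
        ROD_LABEL_BASE + i: rho
        for i, rho in enumerate(phantom.rod_nominal_densities)
    }

    if noise_sd > 0:
        hu = hu + rng.normal(0.0, noise_sd, hu.shape)

    legend = {
        "bone": dict(LABELS),
        "rods": rod_legend,          # label -> nominal density (mg/cm^3)
        "muscles": muscle_legend,    # label -> {name, side}
    }
    return vol.like(hu), vol.like(labels), legend


# ---------------------------------------------------------------------------
# cohort design
# ---------------------------------------------------------------------------

#: Study-design distributions the generator emulates (mean, SD).
#: Regional flight/readaptation rates are %/month of trabecular BMD;
#: muscle rates are %/month of total CSA and in-window density.
DEFAULT_PREFLIGHT_DENSITY = {
    "superior": (178.9, 32.4),
    "transverse": (177.5, 29.6),
    "inferior": (196.5, 32.4),
}
DEFAULT_FLIGHT_RATE = {
    "superior": (-1.08, 1.13),
    "transverse": (-0.72, 0.77),
    "inferior": (-0.51, 1.17),
}
DEFAULT_READAPT_RATE = {
    "superior": (0.39, 0.80),
    "transverse": (0.01, 0.56),
    "inferior": (0.05, 0.85),
}
DEFAULT_MISSION_POOL = (4, 4, 5, 5, 5, 6, 6, 6, 6, 6, 6, 6, 7, 7, 7, 7, 7)


@dataclass(frozen=True)
class SubjectTrajectory:
    """Per-subject injected effects and session repositioning."""

    subject_id: str
    mission_months: float
    readapt_months: float
    has_followup: bool
    flight_rate_per_region: dict      # %/month
    readapt_rate_per_region: dict     # %/month
    muscle_csa_flight_rate: float     # %/month
    muscle_density_flight_rate: float
    muscle_csa_readapt_rate: float
    muscle_density_readapt_rate: float
    session_offsets: dict             # session -> (angles_zyx_deg, translation_mm)

    def validate(self, allowed_months=(4, 5, 6, 7)) -> None:
        if allowed_months is not None and self.mission_months not in allowed_months:
            raise ValidationError(
                f"mission_months: {self.mission_months} not in {allowed_months}"
            )
        rates = [
            *self.flight_rate_per_region.values(),
            *self.readapt_rate_per_region.values(),
            self.muscle_csa_flight_rate, self.muscle_density_flight_rate,
            self.muscle_csa_readapt_rate, self.muscle_density_readapt_rate,
        ]
        if not np.all(np.isfinite(rates)):
            raise ValidationError("rates: all injected rates must be finite")
        ang, tr = self.session_offsets["preflight"]
        if np.any(np.asarray(ang) != 0) or np.any(np.asarray(tr) != 0):
            raise ValidationError("session_offsets['preflight']: must be identity")

    def flight_percent(self, region: str) -> float:
        return self.flight_rate_per_region[region] * self.mission_months

    def readapt_percent(self, region: str) -> float:
        return self.readapt_rate_per_region[region] * self.readapt_months

    def followup_percent(self, region: str) -> float:
        """Follow-up vs preflight percent difference (compounded)."""
        f = 1 + self.flight_percent(region) / 100.0
        r = 1 + self.readapt_percent(region) / 100.0
        return (f * r - 1) * 100.0

    def offset_transform(self, session: str) -> RigidTransform:
        ang, tr = self.session_offsets[session]
        return RigidTransform.from_angles(ang, tr, center=(0.0, 0.0, 0.0),
                                          fixed_space_id="preflight",
                                          moving_space_id=session)


@dataclass
class CohortConfig:
    """Everything that defines a synthetic cohort; the seed fixes all randomness."""

    n_subjects: int = 17
    n_followup: int = 15
    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)
    noise_sd: float = 10.0   # HU

    mission_months_pool: tuple = DEFAULT_MISSION_POOL
    readapt_months: float = 12.0

    preflight_density: dict = field(default_factory=lambda: dict(DEFAULT_PREFLIGHT_DENSITY))
    #: within-subject correlation of the three regional baseline densities
    #: (regional BMD varies together across subjects; marginals preserved)
    regional_density_correlation: float = 0.9
    flight_rate: dict = field(default_factory=lambda: dict(DEFAULT_FLIGHT_RATE))
    readapt_rate: dict = field(default_factory=lambda: dict(DEFAULT_READAPT_RATE))
    #: regions whose *flight* effect is drawn as a total percent change
    #: (mean, sd) instead of a %/month rate
    flight_percent_override: dict = field(default_factory=dict)
    #: regions whose follow-up-vs-preflight percent difference is drawn
    #: directly (mean, sd); the readaptation rate is solved to match
    followup_percent_override: dict = field(default_factory=dict)

    muscle_csa_flight: tuple[float, float] = (-1.02, 1.29)
    muscle_density_flight: tuple[float, float] = (-0.83, 0.89)
    muscle_csa_readapt: tuple[float, float] = (0.72, 0.78)
    muscle_density_readapt: tuple[float, float] = (0.28, 0.55)

    lean_fraction: float = 0.92
    lean_hu: float = 50.0
    fat_hu: float = -100.0
    #: between-subject coefficient of variation of muscle size (left/right
    #: symmetric), plus sub-voxel placement jitter per subject
    muscle_area_cv: float = 0.10

    max_translation_mm: float = 5.0
    max_rotation_deg: float = 5.0
    #: slice sensitivity profile of the scanner ("triangle", "box", "point")
    slice_profile: str = "triangle"
    calibration_truth: LinearHUMap = field(default_factory=LinearHUMap)
    vertebra: VertebraSpec = field(default_factory=VertebraSpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)

    #: draw per-cohort effect samples standardised to the exact target
    #: moments (variance-reduction for recovery experiments)
    standardize_draws: bool = False

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError(f"n_subjects: must be >= 1, got {self.n_subjects}")
        if not 0 <= self.n_followup <= self.n_subjects:
            raise ValidationError(
                f"n_followup: must be in [0, n_subjects], got {self.n_followup}"
            )
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd: must be >= 0, got {self.noise_sd}")
        if len(self.mission_months_pool) < self.n_subjects:
            raise ValidationError(
                "mission_months_pool: need at least one duration per subject"
            )
        if self.readapt_months <= 0:
            raise ValidationError(f"readapt_months: must be > 0, got {self.readapt_months}")
        self.vertebra.validate()
        self.phantom.validate()

    def base_muscles(self) -> list[MuscleSpec]:
        return default_muscles(self.lean_fraction, self.lean_hu, self.fat_hu)


def _draw(rng, mean, sd, n, standardize):
    if sd < 0:
        raise ValidationError(f"distribution sd: must be >= 0, got {sd}")
    if sd == 0:
        return np.full(n, float(mean))
    x = rng.normal(mean, sd, n)
    if standardize and n >= 2:
        s = x.std(ddof=1)
        z = (x - x.mean()) / s if s > 0 else np.zeros(n)
        x = mean + sd * z
    return x


def _draw_split(rng, mean, sd, n, n_head, standardize):
    """Draw n values; when standardising, match moments over the first n_head."""
    if not standardize or n_head < 2:
        return _draw(rng, mean, sd, n, standardize)
    head = _draw(rng, mean, sd, n_head, True)
    tail = _draw(rng, mean, sd, n - n_head, False)
    return np.concatenate([head, tail])


def sample_trajectories(config: CohortConfig, rng: np.random.Generator) -> list[SubjectTrajectory]:
    """Draw the per-subject injected effects and session offsets."""
    config.validate()
    n, n_fu = config.n_subjects, config.n_followup
    std = config.standardize_draws

    months = np.array(config.mission_months_pool[: n] if n <= len(config.mission_months_pool)
                      else config.mission_months_pool, dtype=float)
    months = months[:n]
    rng.shuffle(months)

    flight_pct = {}
    flight_rate = {}
    for r in REGIONS:
        if r in config.flight_percent_override:
            m, s = config.flight_percent_override[r]
            pct = _draw(rng, m, s, n, std)
            flight_pct[r] = pct
            flight_rate[r] = pct / months
        else:
            m, s = config.flight_rate[r]
            rate = _draw(rng, m, s, n, std)
            flight_rate[r] = rate
            flight_pct[r] = rate * months

    readapt_rate = {}
    for r in REGIONS:
        if r in config.followup_percent_override:
            m, s = config.followup_percent_override[r]
            fu_pct = _draw_split(rng, m, s, n, n_fu, std)
            rd_pct = ((1 + fu_pct / 100.0) / (1 + flight_pct[r] / 100.0) - 1) * 100.0
            readapt_rate[r] = rd_pct / config.readapt_months
        else:
            m, s = config.readapt_rate[r]
            readapt_rate[r] = _draw_split(rng, m, s, n, n_fu, std)

    csa_f = _draw(rng, *config.muscle_csa_flight, n, std)
    den_f = _draw(rng, *config.muscle_density_flight, n, std)
    csa_r = _draw_split(rng, *config.muscle_csa_readapt, n, n_fu, std)
    den_r = _draw_split(rng, *config.muscle_density_readapt, n, n_fu, std)

    trajectories = []
    for i in range(n):
        offsets = {"preflight": ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))}
        for sess in ("postflight", "followup"):
            ang = tuple(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg, 3))
            tr = tuple(rng.uniform(-config.max_translation_mm, config.max_translation_mm, 3))
            offsets[sess] = (ang, tr)
        traj = SubjectTrajectory(
            subject_id=f"S{i + 1:02d}",
            mission_months=float(months[i]),
            readapt_months=float(config.readapt_months),
            has_followup=i < n_fu,
            flight_rate_per_region={r: float(flight_rate[r][i]) for r in REGIONS},
            readapt_rate_per_region={r: float(readapt_rate[r][i]) for r in REGIONS},
            muscle_csa_flight_rate=float(csa_f[i]),
            muscle_density_flight_rate=float(den_f[i]),
            muscle_csa_readapt_rate=float(csa_r[i]),
            muscle_density_readapt_rate=float(den_r[i]),
            session_offsets=offsets,
        )
        traj.validate(allowed_months=None)
        trajectories.append(traj)
    return trajectories


@dataclass
class SessionImage:
    subject_id: str
    session: str
    volume: CTVolume
    labels: CTVolume
    legend: dict


@dataclass
class SubjectData:
    trajectory: SubjectTrajectory
    sessions: dict[str, SessionImage]
    vertebra_by_session: dict[str, VertebraSpec]
    muscles_by_session: dict[str, list[MuscleSpec]]


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SubjectData]
    truth: pd.DataFrame

    @property
    def rod_densities_by_label(self) -> dict[int, float]:
        return self.config.phantom.labels()


def _subject_preflight_specs(config, rng):
    c = config.regional_density_correlation
    if not 0 <= c <= 1:
        raise ValidationError(f"regional_density_correlation: must be in [0, 1], got {c}")
    z_shared = rng.standard_normal()
    dens = {}
    for r in REGIONS:
        mean, sd = config.preflight_density[r]
        z = np.sqrt(c) * z_shared + np.sqrt(1 - c) * rng.standard_normal()
        dens[r] = float(max(mean + sd * z, 20.0))
    vert = replace(config.vertebra, regional_trabecular_density=dens)

    muscles = []
    size_factor = {}   # per muscle name: left/right symmetric
    jitter = {}
    for m in config.base_muscles():
        if m.muscle_name not in size_factor:
            size_factor[m.muscle_name] = float(
                np.exp(rng.normal(0.0, config.muscle_area_cv))
            )
            jitter[m.muscle_name] = rng.uniform(-0.5, 0.5, 2)
        dx, dy = jitter[m.muscle_name]
        sign = -1.0 if m.center_xy[0] < 0 else 1.0
        muscles.append(replace(
            m,
            area=m.area * size_factor[m.muscle_name],
            center_xy=(m.center_xy[0] + sign * dx, m.center_xy[1] + dy),
        ))
    return vert, muscles


def _session_specs(traj, vert_pre, muscles_pre):
    """Vertebra and muscle specs per session, scaled by the injected effects."""
    out_v = {"preflight": vert_pre}
    out_m = {"preflight": muscles_pre}
    t = traj.mission_months
    flight_pct = {r: traj.flight_rate_per_region[r] * t for r in REGIONS}
    out_v["postflight"] = vert_pre.with_percent_change(flight_pct)
    csa_f = traj.muscle_csa_flight_rate * t
    den_f = traj.muscle_density_flight_rate * t
    out_m["postflight"] = [m.scaled(csa_f, den_f) for m in muscles_pre]
    if traj.has_followup:
        rd = traj.readapt_months
        fu_pct = {r: traj.followup_percent(r) for r in REGIONS}
        out_v["followup"] = vert_pre.with_percent_change(fu_pct)
        csa_fu = ((1 + csa_f / 100) * (1 + traj.muscle_csa_readapt_rate * rd / 100) - 1) * 100
        den_fu = ((1 + den_f / 100) * (1 + traj.muscle_density_readapt_rate * rd / 100) - 1) * 100
        out_m["followup"] = [m.scaled(csa_fu, den_fu) for m in muscles_pre]
    return out_v, out_m


def _truth_rows(traj: SubjectTrajectory, verts, muscs) -> list[dict]:
    rows = []
    pre_v = verts["preflight"]
    pre_csa = _expected_total_csa(muscs["preflight"])
    for session in SESSIONS:
        if session not in verts:
            continue
        v = verts[session]
        ang, tr = traj.session_offsets[session]
        row = {
            "subject_id": traj.subject_id,
            "session": session,
            "mission_months": traj.mission_months,
            "readapt_months": traj.readapt_months,
            "has_followup": traj.has_followup,
            "true_muscle_total_csa": _expected_total_csa(muscs[session]),
            "true_muscle_total_density": muscs[session][0].lean_hu,
            "offset_rx_deg": ang[0], "offset_ry_deg": ang[1], "offset_rz_deg": ang[2],
            "offset_tx_mm": tr[0], "offset_ty_mm": tr[1], "offset_tz_mm": tr[2],
        }
        for r in REGIONS:
            rho = v.regional_trabecular_density[r]
            rho0 = pre_v.regional_trabecular_density[r]
            row[f"true_density_{r}"] = rho
            row[f"true_percent_{r}"] = (
                np.nan if session == "preflight" else (rho - rho0) / rho0 * 100.0
            )
            row[f"flight_rate_{r}"] = traj.flight_rate_per_region[r]
            row[f"readapt_rate_{r}"] = traj.readapt_rate_per_region[r]
        row["true_muscle_csa_percent"] = (
            np.nan if session == "preflight"
            else (row["true_muscle_total_csa"] - pre_csa) / pre_csa * 100.0
        )
        row["muscle_csa_flight_rate"] = traj.muscle_csa_flight_rate
        row["muscle_density_flight_rate"] = traj.muscle_density_flight_rate
        row["muscle_csa_readapt_rate"] = traj.muscle_csa_readapt_rate
        row["muscle_density_readapt_rate"] = traj.muscle_density_readapt_rate
        rows.append(row)
    return rows


def _expected_total_csa(muscles: list[MuscleSpec]) -> float:
    """Analytic expectation of the measured total CSA (side-averaged, lean only)."""
    per_name: dict[str, list[float]] = {}
    for m in muscles:
        per_name.setdefault(m.muscle_name, []).append(m.area * m.lean_fraction)
    return float(sum(np.mean(v) for v in per_name.values()))


def generate_cohort(config: CohortConfig, out_dir=None) -> Cohort:
    """Generate the full cohort (optionally writing it to disk).

    Regeneration with the same config (including seed) is bit-identical.
    On disk each subject-session becomes ``<sid>_<session>_ct.nii.gz`` and
    ``..._labels.nii.gz`` plus a shared ``labels.json`` legend and a
    ``ground_truth.csv`` sidecar.
    """
    config.validate()
    traj_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    trajectories = sample_trajectories(config, traj_rng)

    subjects = []
    truth_rows = []
    legend_out = None
    for si, traj in enumerate(trajectories):
        subj_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, si]))
        vert_pre, muscles_pre = _subject_preflight_specs(config, subj_rng)
        verts, muscs = _session_specs(traj, vert_pre, muscles_pre)
        sessions = {}
        for sj, session in enumerate(SESSIONS):
            if session not in verts:
                continue
            sess_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 2, si, sj])
            )
            offset = traj.offset_transform(session)
            vol, labels, legend = render_session(
                verts[session], muscs[session], config.phantom,
                config.calibration_truth, config.noise_sd, sess_rng,
                grid=config.grid, offset=offset,
                slice_profile=config.slice_profile,
            )
            sessions[session] = SessionImage(traj.subject_id, session, vol, labels, legend)
            legend_out = legend
        subjects.append(SubjectData(traj, sessions, verts, muscs))
        truth_rows.extend(_truth_rows(traj, verts, muscs))

    truth = pd.DataFrame(truth_rows)
    cohort = Cohort(config=config, subjects=subjects, truth=truth)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            for subj in cohort.subjects:
                for session, img in subj.sessions.items():
                    stem = f"{img.subject_id}_{session}"
                    save_nifti(img.volume, out / f"{stem}_ct.nii.gz")
                    save_nifti(img.labels, out / f"{stem}_labels.nii.gz")
            with open(out / "labels.json", "w") as fh:
                json.dump(legend_out, fh, indent=2)
            truth.to_csv(out / "ground_truth.csv", index=False)
        except OSError as exc:
            raise OSError(f"failed writing cohort to {out}: {exc}") from exc
    return cohort
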