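"""Pipeline orchestration: simulate -> analyze -> stats.

The per-session image analysis follows the acquisition protocol's order:
calibrate (in-scan phantom) -> register session to preflight -> map the
preflight-defined trabecular masks forward -> regional BMD -> muscle
morphometry at the matched mid-vertebral slice.  Analysis of one subject
is independent of the others; a failing subject is skipped with a logged
reason rather than aborting the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import muscle as muscle_mod
from . import regions as regions_mod
from .calibration import calibrate_session
from .errors import ReportError, SpineQCTError, ValidationError
from .registration import (RegistrationOptions, map_mask_to_session,
                           register_rigid)
from .stats import METRICS, build_report, write_report
from .synthetic import (Cohort, CohortConfig, GridSpec, SessionImage,
                        generate_cohort)
from .volume import CTVolume, load_nifti

__all__ = [
    "AnalysisOptions",
    "RunConfig",
    "analyze_subject_sessions",
    "analyze_cohort",
    "run_simulate",
    "run_analyze",
    "run_stats",
]

log = logging.getLogger("spineqct")

BONE_LABELS = (1, 2, 3)  # trabecular, cortical shell, endplate = vertebral body
MUSCLE_LABEL_MIN = 20    # labels >= 20 are muscle contours


@dataclass
class AnalysisOptions:
    """All analysis thresholds in one place — no hidden constants."""

    cortical_margin_mm: float = 3.0
    # endplate thickness (3 mm) + one-slice buffer: mapped-mask edge voxels
    # must never sample endplate through the registration residual
    endplate_margin_mm: float = 6.0
    # partial-volume guard: mapped-mask voxels whose preflight-space
    # longitudinal position is within this distance of an internal slab
    # boundary are excluded (slice-averaged voxels there mix adjacent
    # regions); preflight voxels always sit >= half a slice away
    boundary_guard_mm: float = 1.0
    region_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    hu_window: tuple[float, float] = (-50.0, 150.0)
    rod_erosion_mm: float = 1.0
    side_combine: str = "average"
    readapt_denominator: str = "readapt_months"
    registration: RegistrationOptions = field(default_factory=RegistrationOptions)


@dataclass
class RunConfig:
    """Disk-run configuration: cohort design + analysis options + paths."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    out_root: str = "runs/default"
    seed: int = 0

    def __post_init__(self) -> None:
        self.cohort.seed = self.seed

    @property
    def cohort_dir(self) -> Path:
        return Path(self.out_root) / "cohort"

    @property
    def analysis_dir(self) -> Path:
        return Path(self.out_root) / "analysis"

    @property
    def report_dir(self) -> Path:
        return Path(self.out_root) / "report"

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(dc_type, data):
            if not data:
                return dc_type()
            fields = {f.name: f for f in dataclasses.fields(dc_type)}
            unknown = set(data) - set(fields)
            if unknown:
                raise ValidationError(f"{dc_type.__name__}: unknown fields {sorted(unknown)}")
            kwargs = {}
            for key, val in data.items():
                ftype = fields[key].type
                if key == "grid":
                    val = GridSpec(**{k: tuple(v) for k, v in val.items()})
                elif key == "registration":
                    val = build(RegistrationOptions, val)
                elif isinstance(val, list):
                    val = tuple(tuple(v) if isinstance(v, list) else v for v in val)
                kwargs[key] = val
            return dc_type(**kwargs)

        cfg = cls(
            cohort=build(CohortConfig, raw.get("cohort")),
            analysis=build(AnalysisOptions, raw.get("analysis")),
            out_root=raw.get("out_root", "runs/default"),
            seed=int(raw.get("seed", 0)),
        )
        return cfg


def _bone_body_mask(labels: CTVolume) -> CTVolume:
    return labels.like(np.isin(labels.data, BONE_LABELS))


def _rod_label_volume(labels: CTVolume, rod_labels) -> CTVolume:
    data = np.where(np.isin(labels.data, list(rod_labels)), labels.data, 0)
    return labels.like(data.astype(labels.data.dtype))


def _muscle_legend(legend: dict) -> dict:
    return {int(k): v for k, v in legend["muscles"].items()}


def _internal_boundaries_z(partition, grid_vol: CTVolume) -> list[float]:
    """Preflight-space z of the inferior/transverse and transverse/superior
    interfaces (midpoints between the adjacent occupied slices)."""
    z0, dz = grid_vol.origin[2], grid_vol.spacing[2]
    bounds = []
    for lower, upper in (("inferior", "transverse"), ("transverse", "superior")):
        lo = partition.as_dict()[lower].data.any(axis=(0, 1))
        hi = partition.as_dict()[upper].data.any(axis=(0, 1))
        if lo.any() and hi.any():
            k_lo = np.flatnonzero(lo)[-1]
            k_hi = np.flatnonzero(hi)[0]
            bounds.append(z0 + dz * (k_lo + k_hi) / 2.0)
    return bounds


def _apply_boundary_guard(masks: dict, transform, session_vol: CTVolume,
                          boundaries_z, guard_mm: float) -> dict:
    """Drop mapped voxels whose preflight-space z lies within guard_mm of an
    internal slab boundary (partial-volume zone of the slice profile)."""
    if guard_mm <= 0 or not boundaries_z:
        return masks
    X, Y, Z = session_vol.world_coordinates()
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    pre_z = transform.inverse().apply(pts)[:, 2].reshape(X.shape)
    near = np.zeros(session_vol.shape, dtype=bool)
    for b in boundaries_z:
        near |= np.abs(pre_z - b) < guard_mm
    return {name: m.like(m.data.astype(bool) & ~near) for name, m in masks.items()}


def analyze_subject_sessions(
    sessions: dict[str, SessionImage],
    rod_densities_by_label: dict[int, float],
    options: AnalysisOptions | None = None,
) -> tuple[dict[str, dict], dict]:
    """Run the full image analysis for one subject.

    Returns per-session metric dicts (keys of :data:`spineqct.stats.METRICS`)
    and a sidecar dict with calibration, transform, and voxel-count
    provenance per session.
    """
    opts = options or AnalysisOptions()
    if "preflight" not in sessions:
        raise ReportError("subject has no preflight session")
    pre = sessions["preflight"]

    body_pre = _bone_body_mask(pre.labels)
    trab = regions_mod.extract_trabecular_mask(
        body_pre, opts.cortical_margin_mm, opts.endplate_margin_mm
    )
    partition = regions_mod.partition_regions(trab, opts.region_fractions)
    mid_pre = muscle_mod.select_mid_slice(body_pre)

    results: dict[str, dict] = {}
    sidecars: dict = {}
    for name, img in sessions.items():
        rods = _rod_label_volume(img.labels, rod_densities_by_label)
        cal = calibrate_session(img.volume, rods, rod_densities_by_label,
                                opts.rod_erosion_mm)

        if name == "preflight":
            part_s, mid, transform, reg_info = partition, mid_pre, None, None
        else:
            # similarity evaluated outside the muscle contours: muscles
            # change size/composition between sessions and are not rigid
            # with the vertebra; bone, rods and body outline drive the fit
            metric_mask = pre.labels.like(pre.labels.data < MUSCLE_LABEL_MIN)
            reg = register_rigid(img.volume, pre.volume, opts.registration,
                                 fixed_mask=metric_mask)
            if not reg.converged:
                log.warning("%s/%s: registration did not converge (%s)",
                            img.subject_id, name, reg.stop_description)
            transform = reg.transform
            mapped = {
                r: map_mask_to_session(mask, transform, img.volume)
                for r, mask in partition.as_dict().items()
            }
            mapped = _apply_boundary_guard(
                mapped, transform, img.volume,
                _internal_boundaries_z(partition, pre.volume),
                opts.boundary_guard_mm,
            )
            part_s = regions_mod.RegionPartition(
                superior=mapped["superior"], transverse=mapped["transverse"],
                inferior=mapped["inferior"], split_fractions=partition.split_fractions,
            )
            body_s = map_mask_to_session(body_pre, transform, img.volume)
            mid = muscle_mod.select_mid_slice(body_s)
            reg_info = {
                "final_metric": reg.final_metric,
                "converged": reg.converged,
                "iterations": reg.iterations,
            }

        bone = regions_mod.compute_bone_metrics(
            img.volume, part_s, cal, global_weights=partition.voxel_counts()
        )
        totals = muscle_mod.measure_session_muscles(
            img.volume, img.labels, _muscle_legend(img.legend), mid,
            window=opts.hu_window, side_combine=opts.side_combine,
        )
        # through-plane obliquity correction: an axial slice through a
        # session tilted by theta cuts the muscles obliquely and inflates
        # in-plane areas by sec(theta); the registration rotation gives
        # cos(theta) as R[2,2], so project areas back to the preflight
        # axial plane
        obliquity = 1.0 if transform is None else float(transform.matrix[2, 2])
        csa = totals.total_csa * obliquity
        results[name] = {
            "global_tb_vbmd": bone.global_tb_vbmd,
            "rbmd_superior": bone.rbmd_superior,
            "rbmd_transverse": bone.rbmd_transverse,
            "rbmd_inferior": bone.rbmd_inferior,
            "total_muscle_csa": csa,
            "total_muscle_density": totals.total_density,
        }
        sidecars[name] = {
            "calibration": dataclasses.asdict(cal),
            "transform": transform.to_dict() if transform is not None else None,
            "registration": reg_info,
            "region_voxel_counts": bone.voxel_counts,
            "mid_slice": int(mid),
        }
    return results, sidecars


def analyze_cohort(
    cohort: Cohort,
    options: AnalysisOptions | None = None,
    on_error: str = "raise",
) -> tuple[pd.DataFrame, dict]:
    """Analyze every subject of an in-memory cohort into a cohort table.

    ``on_error="skip"`` logs and drops a failing subject (the CLI's
    behaviour); ``"raise"`` propagates.
    """
    if on_error not in ("raise", "skip"):
        raise ValidationError(f"on_error: must be 'raise' or 'skip', got {on_error!r}")
    rows, sidecars, skipped = [], {}, []
    rod_densities = cohort.rod_densities_by_label
    for subj in cohort.subjects:
        sid = subj.trajectory.subject_id
        try:
            metrics, side = analyze_subject_sessions(subj.sessions, rod_densities, options)
        except SpineQCTError as exc:
            if on_error == "raise":
                raise
            log.error("subject %s skipped: %s", sid, exc)
            skipped.append(sid)
            continue
        sidecars[sid] = side
        for session, vals in metrics.items():
            rows.append({
                "subject_id": sid,
                "session": session,
                "mission_months": subj.trajectory.mission_months,
                "readapt_months": subj.trajectory.readapt_months,
                **vals,
            })
    table = pd.DataFrame(rows)
    return table, {"sidecars": sidecars, "skipped": skipped}


# ---------------------------------------------------------------------------
# disk-based runs (CLI back-end)
# ---------------------------------------------------------------------------

def run_simulate(config: RunConfig, force: bool = False) -> Path:
    """Generate the synthetic cohort on disk with a config-hash manifest."""
    out = config.cohort_dir
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{out} already contains a cohort (use --force to overwrite)")
    log.info("simulating cohort (n=%d, seed=%d) -> %s",
             config.cohort.n_subjects, config.cohort.seed, out)
    generate_cohort(config.cohort, out_dir=out)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.cohort.seed,
        "n_subjects": config.cohort.n_subjects,
        "n_followup": config.cohort.n_followup,
        "grid_shape": list(config.cohort.grid.shape),
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def load_cohort_from_disk(cohort_dir, config: CohortConfig) -> Cohort:
    """Reassemble a disk cohort (volumes, labels, legend, ground truth)."""
    from .synthetic import SubjectData, SubjectTrajectory, SESSIONS

    cohort_dir = Path(cohort_dir)
    truth = pd.read_csv(cohort_dir / "ground_truth.csv")
    with open(cohort_dir / "labels.json") as fh:
        legend = json.load(fh)
    legend = {
        "bone": legend["bone"],
        "rods": {int(k): v for k, v in legend["rods"].items()},
        "muscles": {int(k): v for k, v in legend["muscles"].items()},
    }
    subjects = []
    for sid, group in truth.groupby("subject_id", sort=True):
        g0 = group.iloc[0]
        sessions = {}
        offsets = {}
        for _, row in group.iterrows():
            session = row["session"]
            stem = cohort_dir / f"{sid}_{session}"
            ct_path = stem.with_name(stem.name + "_ct.nii.gz")
            lab_path = stem.with_name(stem.name + "_labels.nii.gz")
            if not ct_path.exists() or not lab_path.exists():
                raise FileNotFoundError(f"missing session files for {sid}/{session}")
            vol = load_nifti(ct_path)
            labels = load_nifti(lab_path)
            labels.data = labels.data.astype(np.int16)
            sessions[session] = SessionImage(sid, session, vol, labels, legend)
            offsets[session] = (
                (row["offset_rx_deg"], row["offset_ry_deg"], row["offset_rz_deg"]),
                (row["offset_tx_mm"], row["offset_ty_mm"], row["offset_tz_mm"]),
            )
        traj = SubjectTrajectory(
            subject_id=sid,
            mission_months=float(g0["mission_months"]),
            readapt_months=float(g0["readapt_months"]),
            has_followup=bool(g0["has_followup"]),
            flight_rate_per_region={r: float(g0[f"flight_rate_{r}"]) for r in regions_mod.REGIONS},
            readapt_rate_per_region={r: float(g0[f"readapt_rate_{r}"]) for r in regions_mod.REGIONS},
            muscle_csa_flight_rate=float(g0["muscle_csa_flight_rate"]),
            muscle_density_flight_rate=float(g0["muscle_density_flight_rate"]),
            muscle_csa_readapt_rate=float(g0["muscle_csa_readapt_rate"]),
            muscle_density_readapt_rate=float(g0["muscle_density_readapt_rate"]),
            session_offsets=offsets,
        )
        subjects.append(SubjectData(traj, sessions, {}, {}))
    return Cohort(config=config, subjects=subjects, truth=truth)


def run_analyze(config: RunConfig) -> tuple[Path, list[str]]:
    """Analyze the simulated cohort on disk into a CohortTable CSV + sidecars.

    Returns the table path and the list of skipped subjects.
    """
    cohort = load_cohort_from_disk(config.cohort_dir, config.cohort)
    table, info = analyze_cohort(cohort, config.analysis, on_error="skip")
    out = config.analysis_dir
    out.mkdir(parents=True, exist_ok=True)
    table_path = out / "cohort_table.csv"
    table.to_csv(table_path, index=False)
    for sid, side in info["sidecars"].items():
        with open(out / f"{sid}_sidecar.json", "w") as fh:
            json.dump(side, fh, indent=2, default=float)
    log.info("analyzed %d subjects (%d skipped) -> %s",
             len(info["sidecars"]), len(info["skipped"]), table_path)
    return table_path, info["skipped"]


def run_stats(config: RunConfig, plots: bool = False) -> Path:
    """Build the statistics report from the cohort table."""
    table_path = config.analysis_dir / "cohort_table.csv"
    if not table_path.exists():
        raise FileNotFoundError(f"no cohort table at {table_path}; run analyze first")
    table = pd.read_csv(table_path)
    report = build_report(table, readapt_denominator=config.analysis.readapt_denominator)
    write_report(report, config.report_dir)
    if plots:
        from .stats import plot_report

        plot_report(table, report, config.report_dir)
    log.info("report written to %s", config.report_dir)
    return config.report_dir
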