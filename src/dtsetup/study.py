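"""Parameter-study harness: end-to-end sweeps of accuracy vs acquisition parameters.

Runs the full simulate -> reconstruct -> register chain over factorial
grids of arc length, arc separation, and reconstruction slice spacing,
with known applied shifts as ground truth, and reports per-axis accuracy
(|found - applied| per room axis).  Per-cell failures (failed
cross-correlation, out-of-range shifts) are recorded as failed rows and
never abort a sweep.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .dts_recon import DTSVolume, ReconConfig, reconstruct_treatment_dts
from .geometry import AcquisitionGeometry, ArcSpec
from .phantoms import PhantomSpec, Shift3D, apply_shift, build_phantom, preset_phantom
from .projection import acquire_arc
from .registration import MatchConfig, RegistrationError

__all__ = [
    "PerAxisError",
    "SweepConfig",
    "SweepResult",
    "evaluate_error",
    "run_sweep",
    "random_shifts",
    "clip_depth_extent",
]

log = logging.getLogger(__name__)


class PerAxisError(NamedTuple):
    """Absolute registration error per room axis (mm) and its 3D magnitude."""

    x: float
    y: float
    z: float
    magnitude: float


def evaluate_error(found: Shift3D, applied: Shift3D) -> PerAxisError:
    """Per-axis accuracy: |found - applied| per axis plus the Euclidean magnitude."""
    d = found.as_array() - applied.as_array()
    if not np.all(np.isfinite(d)):
        raise ValueError("shifts must be finite")
    return PerAxisError(abs(d[0]), abs(d[1]), abs(d[2]), float(np.linalg.norm(d)))


def random_shifts(n: int, max_component: float, seed: int) -> list[Shift3D]:
    """Seeded random couch shifts, uniform per component in [-max, +max] mm."""
    rng = np.random.default_rng(seed)
    return [Shift3D(*rng.uniform(-max_component, max_component, 3)) for _ in range(n)]


@dataclass(frozen=True)
class SweepConfig:
    """Factorial sweep definition.

    ``shifts`` may be given explicitly; otherwise ``n_shifts`` random
    shifts of at most ``shift_max`` mm per component are drawn from
    ``seed``.  Arcs are placed at ``base_theta_c`` and
    ``base_theta_c + separation``.
    """

    phantom: PhantomSpec | str = "rectangular"
    arc_lengths: tuple[float, ...] = (5.0, 10.0, 20.0)
    separations: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)
    slice_spacings: tuple[float, ...] = (3.0,)
    shifts: tuple[Shift3D, ...] | None = None
    n_shifts: int = 5
    shift_max: float = 5.0
    seed: int = 0
    noise_sigma: float = 0.01
    base_theta_c: float = 305.0
    angular_step: float = 0.5
    clip_hu: float | tuple[float, float] = 1200.0
    deblur_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (self.arc_lengths and self.separations and self.slice_spacings):
            raise ValueError("parameter lists must be non-empty")

    def resolved_shifts(self) -> list[Shift3D]:
        if self.shifts is not None:
            return list(self.shifts)
        return random_shifts(self.n_shifts, self.shift_max, self.seed)

    def resolved_phantom(self) -> PhantomSpec:
        if isinstance(self.phantom, str):
            return preset_phantom(self.phantom, clip_hu=self.clip_hu)
        return self.phantom


@dataclass
class SweepResult:
    """One row per (parameter cell x shift); failures carry their reason."""

    rows: pd.DataFrame
    config: SweepConfig

    def summary(self) -> pd.DataFrame:
        """Mean/std per parameter cell over the successful repeats."""
        ok = self.rows[~self.rows["failed"]]
        return (
            ok.groupby(["slice_spacing", "arc_length", "separation"])[
                ["err_x", "err_y", "err_z", "err_3d"]
            ]
            .agg(["mean", "std"])
            .reset_index()
        )

    def accuracy_table(self, slice_spacing: float | None = None) -> pd.DataFrame:
        """Separation x (arc length, axis) grid of mean per-axis errors (mm).

        Mirrors the phantom accuracy table layout: rows are arc separations
        (descending), columns arc lengths x (X, Y, Z).
        """
        df = self.rows[~self.rows["failed"]]
        if slice_spacing is not None:
            df = df[df["slice_spacing"] == slice_spacing]
        pivot = df.pivot_table(
            index="separation", columns="arc_length",
            values=["err_x", "err_y", "err_z"], aggfunc="mean",
        )
        pivot = pivot.sort_index(ascending=False)
        pivot.columns = [
            f"L{int(arc)}_{name[-1].upper()}" for name, arc in pivot.columns
        ]
        return pivot[sorted(pivot.columns, key=lambda c: (-int(c[1:c.index('_')]), c[-1]))]

    def n_failed(self) -> int:
        return int(self.rows["failed"].sum())

    def save(self, csv_path: str) -> None:
        self.rows.to_csv(csv_path, index=False)

    def plot_errors(self, against: str, path: str) -> None:
        """Plot mean 3D error vs a swept parameter (requires matplotlib).

        ``against`` is one of ``arc_length``, ``separation``,
        ``slice_spacing``; the figure is written to ``path``.
        """
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ok = self.rows[~self.rows["failed"]]
        means = ok.groupby(against)["err_3d"].agg(["mean", "std"])
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.errorbar(means.index, means["mean"], yerr=means["std"].fillna(0.0),
                    marker="o", capsize=3)
        ax.set_xlabel(against.replace("_", " "))
        ax.set_ylabel("mean 3D registration error (mm)")
        ax.grid(alpha=0.3)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def run_sweep(
    cfg: SweepConfig,
    geom: AcquisitionGeometry = AcquisitionGeometry(),
    match_cfg: MatchConfig | None = None,
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> SweepResult:
    """Full factorial sweep: every (slice spacing x arc length x separation x shift).

    Each cell simulates two arcs (at ``base_theta_c`` and base + separation),
    reconstructs treatment and reference DTS volumes, registers, and
    evaluates the per-axis error against the applied shift.  Reference
    reconstructions and treatment acquisitions are memoized across cells
    that share them, and the whole sweep is deterministic for a given
    config (seeded noise per acquisition).
    """
    spec = cfg.resolved_phantom()
    planning = build_phantom(spec, voxel_spacing)
    shifts = cfg.resolved_shifts()
    shifted_vols = [apply_shift(planning, s) for s in shifts]

    ref_cache: dict = {}
    ps_cache: dict = {}
    trt_cache: dict = {}

    def projections_for(theta_c: float, length: float, shift_idx: int):
        key = (theta_c, length, shift_idx)
        if key not in ps_cache:
            arc = ArcSpec(theta_c=theta_c % 360.0, arc_length=length, angular_step=cfg.angular_step)
            # per-acquisition seed: deterministic, distinct per (arc, shift)
            seed = (cfg.seed * 1000003 + hash(key) % 100003) % (2**31)
            ps_cache[key] = acquire_arc(
                shifted_vols[shift_idx], arc, geom,
                noise_sigma=cfg.noise_sigma, seed=seed,
            )
        return ps_cache[key]

    def treatment_for(theta_c: float, length: float, spacing: float, shift_idx: int):
        key = (theta_c, length, spacing, shift_idx)
        if key not in trt_cache:
            ps = projections_for(theta_c, length, shift_idx)
            rc = ReconConfig.treatment_default(
                slice_spacing=spacing, deblur_fraction=cfg.deblur_fraction
            )
            trt_cache[key] = (ps, reconstruct_treatment_dts(ps, rc))
        return trt_cache[key]

    records = []
    for spacing in cfg.slice_spacings:
        recon_cfg = ReconConfig.treatment_default(
            slice_spacing=spacing, deblur_fraction=cfg.deblur_fraction
        )
        for length in cfg.arc_lengths:
            for sep in cfg.separations:
                thetas = (cfg.base_theta_c % 360.0, (cfg.base_theta_c + sep) % 360.0)
                for k, shift in enumerate(shifts):
                    rec = {
                        "slice_spacing": spacing, "arc_length": length,
                        "separation": sep, "shift_index": k,
                        "applied_x": shift.x, "applied_y": shift.y, "applied_z": shift.z,
                    }
                    try:
                        ps_list = [projections_for(t, length, k) for t in thetas]
                        # reuse cached treatment reconstructions via register's recon path
                        report = _register_cached(
                            planning, ps_list, recon_cfg, match_cfg, ref_cache,
                            [treatment_for(t, length, spacing, k)[1] for t in thetas],
                        )
                        err = evaluate_error(report.shift, shift)
                        rec.update(
                            found_x=report.shift.x, found_y=report.shift.y,
                            found_z=report.shift.z,
                            err_x=err.x, err_y=err.y, err_z=err.z, err_3d=err.magnitude,
                            ncc_min=min(m.ncc for m in report.matches),
                            n_valid=sum(m.valid for m in report.matches),
                            condition=report.result.condition,
                            failed=False, reason="",
                        )
                    except (RegistrationError, ValueError) as exc:
                        rec.update(
                            found_x=np.nan, found_y=np.nan, found_z=np.nan,
                            err_x=np.nan, err_y=np.nan, err_z=np.nan, err_3d=np.nan,
                            ncc_min=np.nan, n_valid=0, condition=np.nan,
                            failed=True, reason=str(exc),
                        )
                        log.warning("cell failed (spacing=%s L=%s sep=%s shift=%s): %s",
                                    spacing, length, sep, k, exc)
                    records.append(rec)
                    log.info("cell done: spacing=%s L=%s sep=%s shift=%s", spacing, length, sep, k)
    return SweepResult(rows=pd.DataFrame.from_records(records), config=cfg)


def _register_cached(planning, ps_list, recon_cfg, match_cfg, ref_cache, trt_dts_list):
    """register() with precomputed treatment DTS volumes (sweep fast path)."""
    from .dts_recon import reconstruct_reference_dts
    from .registration import (MatchConfig, _auto_template_center, match_template,
                               prefilter, triangulate)

    match_cfg = match_cfg or MatchConfig()
    ref_cfg = ReconConfig.reference_default(
        initial_depth=recon_cfg.initial_depth,
        slice_spacing=recon_cfg.slice_spacing,
        deblur_fraction=recon_cfg.deblur_fraction,
        in_plane_pixel=recon_cfg.in_plane_pixel,
        final_volume=(recon_cfg.final_volume[0], recon_cfg.final_volume[1], 33.0),
    )
    from .registration import MatchResult, RegistrationReport

    matches = []
    for ps, trt_dts in zip(ps_list, trt_dts_list):
        key = (
            ps.arc.theta_c, ps.arc.arc_length, ps.arc.angular_step,
            ref_cfg.slice_spacing, ref_cfg.deblur_fraction, ref_cfg.in_plane_pixel,
            ps.geom.sad, ps.geom.sid,
        )
        if key not in ref_cache:
            ref_cache[key] = reconstruct_reference_dts(planning, ps.arc, ps.geom, ref_cfg)
        ref_dts = ref_cache[key]
        cfg = match_cfg
        if cfg.template_center is None:
            center = _auto_template_center(planning, ref_dts.frame)
            cfg = dataclasses.replace(cfg, template_center=tuple(center))
        matches.append(
            match_template(
                prefilter(ref_dts, cfg.gaussian_sigma),
                prefilter(trt_dts, cfg.gaussian_sigma),
                cfg,
            )
        )
    return RegistrationReport(matches=matches, result=triangulate(matches))


def clip_depth_extent(
    dts: DTSVolume,
    center_uv: tuple[float, float] = (0.0, 0.0),
    radius: float = 6.0,
    background_margin: float = 12.0,
) -> int:
    """Number of slices in which a clip is observed.

    A slice counts if its maximum inside the clip region (in-plane disc of
    ``radius`` mm around ``center_uv``) exceeds the background level plus
    50% of the clip's peak excess over background.  Background is the
    median of the volume outside ``background_margin`` mm of the clip
    position.
    """
    ucoord, vcoord, _ = dts.axis_coords()
    du = ucoord - center_uv[0]
    dv = vcoord - center_uv[1]
    r2 = du[:, None] ** 2 + dv[None, :] ** 2
    clip_mask = r2 <= radius**2
    bg_mask = r2 > background_margin**2
    if not clip_mask.any() or not bg_mask.any():
        raise ValueError("clip/background regions empty; check center and radii")
    background = float(np.median(dts.data[bg_mask, :]))
    peak = float(np.max(dts.data[clip_mask, :]))
    threshold = background + 0.5 * (peak - background)
    per_slice_max = dts.data[clip_mask, :].max(axis=0)
    return int(np.count_nonzero(per_slice_max > threshold))
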