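"""Template matching of reference/treatment DTS pairs and multi-arc triangulation.

A user-defined template around the clip cluster in the reference DTS is
cross-correlated (zero-mean normalized) against the treatment DTS over a
bounded search lattice; the per-arc in-plane displacements are then fused
across two or more arcs by weighted least squares into a single 3D couch
shift.  A single arc's depth (w) displacement is unreliable — tomosynthesis
has poor depth resolution — so depth equations carry zero weight by default
and depth is recovered from the geometry of multiple arcs instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import match_template as _skimage_match_template

from .dts_recon import DTSVolume, ReconConfig, reconstruct_reference_dts, reconstruct_treatment_dts
from .geometry import AcquisitionGeometry, ArcSpec, BeamFrame, arc_separation, project_point
from .phantoms import ClipSpec, CTVolume, Shift3D
from .projection import ProjectionSet

__all__ = [
    "MatchConfig",
    "MatchResult",
    "TriangulationResult",
    "RegistrationReport",
    "RegistrationError",
    "prefilter",
    "match_template",
    "triangulate",
    "register",
    "score_arc_orientation",
]


class RegistrationError(RuntimeError):
    """Raised when no valid cross-correlation match is available."""


@dataclass(frozen=True)
class MatchConfig:
    """Search region (full widths, mm), Gaussian prefilter width, template definition.

    ``template_center`` is the template center in beam-frame mm (``None``:
    derived from the clip centroid); ``template_size`` the cube side in mm.
    ``min_ncc`` operationalizes a failed cross-correlation match.
    """

    search_region: tuple[float, float, float] = (15.0, 15.0, 15.0)
    gaussian_sigma: float = 1.5
    template_center: tuple[float, float, float] | None = None
    template_size: float = 24.0
    min_ncc: float = 0.3

    def __post_init__(self) -> None:
        if min(self.search_region) <= 0:
            raise ValueError("search_region must be > 0")
        if not 0.0 < self.min_ncc < 1.0:
            raise ValueError("min_ncc must be in (0, 1)")
        if self.template_size <= 0:
            raise ValueError("template_size must be > 0")


@dataclass
class MatchResult:
    """Per-arc match: displacement (beam-frame u, v, w mm) of treatment vs reference."""

    displacement: np.ndarray
    ncc: float
    valid: bool
    arc: ArcSpec
    frame: BeamFrame
    reason: str = ""


@dataclass
class TriangulationResult:
    """Least-squares 3D shift from >= 1 per-arc matches (room coordinates)."""

    shift: Shift3D
    condition: float
    arcs_used: int
    separation: float | None
    valid3d: bool


@dataclass
class RegistrationReport:
    """Full registration outcome: per-arc matches plus the triangulated shift."""

    matches: list[MatchResult]
    result: TriangulationResult

    @property
    def shift(self) -> Shift3D:
        return self.result.shift

    def to_json(self) -> str:
        return json.dumps(
            {
                "shift_mm": list(self.result.shift.as_array()),
                "valid3d": self.result.valid3d,
                "arcs_used": self.result.arcs_used,
                "separation_deg": self.result.separation,
                "condition": self.result.condition,
                "matches": [
                    {
                        "theta_c": m.arc.theta_c,
                        "arc_length": m.arc.arc_length,
                        "displacement_uvw_mm": list(np.asarray(m.displacement, dtype=float)),
                        "ncc": m.ncc,
                        "valid": m.valid,
                        "reason": m.reason,
                    }
                    for m in self.matches
                ],
            },
            indent=2,
        )


def prefilter(v: DTSVolume, sigma: float) -> DTSVolume:
    """In-plane (per-slice) Gaussian smoothing; ``sigma`` in mm, 0 = identity.

    Applied to both members of a DTS pair before matching to reduce their
    difference in resolution quality.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        data = v.data.copy()
    else:
        s = sigma / v.in_plane_pixel
        data = ndimage.gaussian_filter(v.data, sigma=(s, s, 0.0), mode="nearest")
    return DTSVolume(
        data=data, slice_spacing=v.slice_spacing, in_plane_pixel=v.in_plane_pixel,
        frame=v.frame, arc=v.arc, geom=v.geom, kind=v.kind,
        deblur_fraction=v.deblur_fraction, coverage=v.coverage,
    )


def _quadratic_offset(cm1: float, c0: float, cp1: float) -> float:
    """Sub-sample vertex of the parabola through three equispaced samples."""
    denom = cm1 - 2.0 * c0 + cp1
    if abs(denom) < 1e-15:
        return 0.0
    off = 0.5 * (cm1 - cp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def match_template(ref: DTSVolume, trt: DTSVolume, cfg: MatchConfig) -> MatchResult:
    """Zero-mean NCC match of a reference template inside the treatment volume.

    The template is shifted over the integer displacement lattice within
    +/- half the search region; the peak is refined to sub-voxel precision
    by a separable quadratic fit.  The displacement maps the treatment
    content onto the reference: it equals the beam-frame components of the
    applied couch shift.  Ties are broken toward the smallest displacement
    magnitude, then lexicographically.
    """
    if abs(ref.arc.theta_c - trt.arc.theta_c) > 1e-9:
        raise ValueError("reference and treatment DTS must share the arc orientation")
    if abs(ref.slice_spacing - trt.slice_spacing) > 1e-9 or abs(ref.in_plane_pixel - trt.in_plane_pixel) > 1e-9:
        raise ValueError("reference and treatment DTS must share the voxel lattice")

    steps = np.array([ref.in_plane_pixel, ref.in_plane_pixel, ref.slice_spacing])
    half_search = np.array(cfg.search_region) / 2.0
    n_search = np.maximum(np.floor(half_search / steps + 1e-9).astype(int), 1)

    center = np.array(cfg.template_center if cfg.template_center is not None else (0.0, 0.0, 0.0))
    c_ref = np.rint(ref.beam_to_index(center)).astype(int)
    half_t = np.maximum(np.rint((cfg.template_size / 2.0) / steps).astype(int), 0)
    half_t[2] = max(half_t[2], 1)

    lo = c_ref - half_t
    hi = c_ref + half_t
    if np.any(lo < 0) or np.any(hi > np.array(ref.shape) - 1):
        raise ValueError("template extends outside the reference volume")
    template = ref.data[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1]
    if float(np.std(template)) < 1e-12:
        raise ValueError("degenerate template (zero variance)")

    # the treatment volume shares the isocenter-centered lattice; map the
    # template corner into it and expand by the search half-widths
    c_trt = np.rint(trt.beam_to_index(center)).astype(int)
    tlo = c_trt - half_t - n_search
    thi = c_trt + half_t + n_search
    if np.any(tlo < 0) or np.any(thi > np.array(trt.shape) - 1):
        raise ValueError("search region extends outside the treatment volume")
    image = trt.data[tlo[0]: thi[0] + 1, tlo[1]: thi[1] + 1, tlo[2]: thi[2] + 1]

    ncc = _skimage_match_template(image, template)  # shape 2*n_search + 1
    assert ncc.shape == tuple(2 * n_search + 1)

    # peak with tie-break: smallest |displacement|, then lexicographic
    peak_val = float(np.max(ncc))
    cand = np.argwhere(ncc >= peak_val - 1e-12)
    disp_idx = cand - n_search
    order = np.lexsort(
        (disp_idx[:, 2], disp_idx[:, 1], disp_idx[:, 0], np.sum((disp_idx * steps) ** 2, axis=1))
    )
    best = cand[order[0]]
    d_idx = best - n_search

    at_edge = (best == 0) | (best == np.array(ncc.shape) - 1)
    sub = np.zeros(3)
    for ax in range(3):
        if at_edge[ax]:
            continue
        im1 = best.copy(); im1[ax] -= 1
        ip1 = best.copy(); ip1[ax] += 1
        sub[ax] = _quadratic_offset(ncc[tuple(im1)], peak_val, ncc[tuple(ip1)])

    displacement = (d_idx + sub) * steps
    # an in-plane peak on the search boundary means the shift may exceed the
    # search region; a depth (w) peak on the boundary is common even for
    # in-range shifts because the depth correlation profile is nearly flat,
    # and the depth component is discarded by triangulation anyway
    inplane_boundary = bool(at_edge[0] or at_edge[1])
    valid = (peak_val >= cfg.min_ncc) and not inplane_boundary
    reason = ""
    if inplane_boundary:
        reason = "peak on search-region boundary (shift may exceed the search region)"
    elif peak_val < cfg.min_ncc:
        reason = f"cross-correlation failed (ncc {peak_val:.3f} < {cfg.min_ncc})"
    elif at_edge[2]:
        reason = "depth peak at search boundary (depth component unreliable)"
    return MatchResult(
        displacement=displacement, ncc=peak_val, valid=valid,
        arc=ref.arc, frame=ref.frame, reason=reason,
    )


def triangulate(matches: list[MatchResult], w_depth: float = 0.0) -> TriangulationResult:
    """Weighted least-squares fusion of per-arc displacements into a room-frame shift.

    Each valid match contributes its two in-plane equations
    ``u . s = d_u`` and ``v . s = d_v`` at weight 1 and its depth equation
    ``w . s = d_w`` at weight ``w_depth`` (default 0: depth discarded).
    With a single arc the system is rank deficient; the result is flagged
    3D-invalid and depth falls back to the arc's own (unreliable) ``w``
    component.
    """
    valid = [m for m in matches if m.valid]
    if not valid:
        details = "; ".join(
            f"theta_c={m.arc.theta_c}: ncc={m.ncc:.3f} ({m.reason})" for m in matches
        )
        raise RegistrationError(f"registration failed: no valid matches [{details}]")

    if len(valid) == 1:
        m = valid[0]
        d = np.asarray(m.displacement, dtype=float)
        s = m.frame.to_room(d)
        return TriangulationResult(
            shift=Shift3D(*s), condition=float("inf"), arcs_used=1,
            separation=None, valid3d=False,
        )

    rows, rhs, wts = [], [], []
    for m in valid:
        d = np.asarray(m.displacement, dtype=float)
        rows += [m.frame.u, m.frame.v]
        rhs += [d[0], d[1]]
        wts += [1.0, 1.0]
        if w_depth > 0:
            rows.append(m.frame.w)
            rhs.append(d[2])
            wts.append(w_depth)
    A = np.asarray(rows) * np.sqrt(np.asarray(wts))[:, None]
    b = np.asarray(rhs) * np.sqrt(np.asarray(wts))
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    condition = float(sv[0] / sv[-1]) if sv[-1] > 1e-12 * sv[0] else float("inf")
    seps = [
        arc_separation(a.arc.theta_c, b_.arc.theta_c)
        for i, a in enumerate(valid) for b_ in valid[i + 1:]
    ]
    return TriangulationResult(
        shift=Shift3D(*sol), condition=condition, arcs_used=len(valid),
        separation=min(seps) if seps else None, valid3d=rank == 3,
    )


def _auto_template_center(ref_ct: CTVolume, frame: BeamFrame) -> np.ndarray:
    """Template center (beam-frame mm) from the clip centroid of the planning CT."""
    if ref_ct.clips:
        centroid = np.mean([c.center for c in ref_ct.clips], axis=0)
        return frame.to_beam(centroid)
    return np.zeros(3)


def register(
    ref_ct: CTVolume,
    ps_list: list[ProjectionSet],
    match_cfg: MatchConfig | None = None,
    recon_cfg: ReconConfig | None = None,
    w_depth: float = 0.0,
    reference_cache: dict | None = None,
) -> RegistrationReport:
    """End-to-end registration: reconstruct, prefilter, match per arc, triangulate.

    ``reference_cache`` (optional dict) memoizes reference reconstructions
    keyed by arc and reconstruction parameters; useful when registering
    many treatment acquisitions against one planning CT.
    """
    match_cfg = match_cfg or MatchConfig()
    recon_cfg = recon_cfg or ReconConfig.treatment_default()
    ref_cfg = ReconConfig.reference_default(
        initial_depth=recon_cfg.initial_depth,
        slice_spacing=recon_cfg.slice_spacing,
        deblur_fraction=recon_cfg.deblur_fraction,
        in_plane_pixel=recon_cfg.in_plane_pixel,
        final_volume=(recon_cfg.final_volume[0], recon_cfg.final_volume[1], 33.0),
    )

    matches: list[MatchResult] = []
    for ps in ps_list:
        key = (
            ps.arc.theta_c, ps.arc.arc_length, ps.arc.angular_step,
            ref_cfg.slice_spacing, ref_cfg.deblur_fraction, ref_cfg.in_plane_pixel,
            ps.geom.sad, ps.geom.sid,
        )
        if reference_cache is not None and key in reference_cache:
            ref_dts = reference_cache[key]
        else:
            ref_dts = reconstruct_reference_dts(ref_ct, ps.arc, ps.geom, ref_cfg)
            if reference_cache is not None:
                reference_cache[key] = ref_dts
        trt_dts = reconstruct_treatment_dts(ps, recon_cfg)

        cfg = match_cfg
        if cfg.template_center is None:
            center = _auto_template_center(ref_ct, ref_dts.frame)
            cfg = MatchConfig(
                search_region=cfg.search_region, gaussian_sigma=cfg.gaussian_sigma,
                template_center=tuple(center), template_size=cfg.template_size,
                min_ncc=cfg.min_ncc,
            )
        ref_f = prefilter(ref_dts, cfg.gaussian_sigma)
        trt_f = prefilter(trt_dts, cfg.gaussian_sigma)
        matches.append(match_template(ref_f, trt_f, cfg))

    result = triangulate(matches, w_depth=w_depth)
    return RegistrationReport(matches=matches, result=result)


@dataclass
class OrientationScore:
    """Clip-distribution quality of a candidate arc orientation (beam's-eye view)."""

    score: float
    insufficient_clips: bool
    overlap: bool
    bev_positions: np.ndarray
    retained: list[int]


def score_arc_orientation(
    clips: list[ClipSpec],
    theta_c: float,
    geom: AcquisitionGeometry = AcquisitionGeometry(),
    min_separation: float = 3.0,
) -> OrientationScore:
    """Score a candidate arc by clip separation in its beam's-eye view.

    Clip centers are perspectively projected along the central beam and
    rescaled to the isocenter plane.  Flags: ``overlap`` if any pair is
    closer than ``min_separation`` mm in the BEV; ``insufficient_clips``
    if fewer than three clips are pairwise well separated.  The score is
    the minimum pairwise BEV separation among the retained (well separated)
    clips.
    """
    if not clips:
        raise ValueError("need at least one clip")
    centers = np.array([c.center for c in clips])
    bev = project_point(centers, theta_c, geom) * (geom.sad / geom.sid)
    bev = np.atleast_2d(bev)

    n = len(clips)
    dists = np.linalg.norm(bev[:, None, :] - bev[None, :, :], axis=-1)
    overlap = bool(n >= 2 and np.min(dists[np.triu_indices(n, 1)]) < min_separation)

    # greedy retained subset: keep a clip if it stays >= min_separation from all kept
    retained: list[int] = []
    for i in range(n):
        if all(dists[i, j] >= min_separation for j in retained):
            retained.append(i)
    insufficient = len(retained) < 3
    if len(retained) >= 2:
        sub = dists[np.ix_(retained, retained)]
        score = float(np.min(sub[np.triu_indices(len(retained), 1)]))
    else:
        score = 0.0
    return OrientationScore(
        score=score, insufficient_clips=insufficient, overlap=overlap,
        bev_positions=bev, retained=retained,
    )
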