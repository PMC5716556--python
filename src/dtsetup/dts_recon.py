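"""Shift-and-add tomosynthesis reconstruction with out-of-plane deblurring.

Treatment DTS volumes are reconstructed from short-arc projections by
back-projecting every projection onto a stack of depth planes perpendicular
to the central beam and averaging: a structure lying in a given plane is in
focus there (all back-projected rays agree), while out-of-plane structures
smear along the in-plane direction of the tomographic sweep.

Deblurring follows the classic selective-plane-removal idea: for each slice
an estimate of the out-of-plane signal is formed as the mean of the other
slices in a window covering a configurable fraction of the initial stack,
each rescaled along the diverging beam to the target slice's geometry, and
subtracted.  A larger fraction removes more out-of-plane leakage at the
cost of extra computation.

Reference DTS volumes are produced from the planning CT by reslicing it
into the beam frame, reprojecting the resliced volume into virtual
projections (DRRs), and running the identical back-projection/deblurring
chain, so the reference and treatment volumes share their artifact
structure and can be cross-correlated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import AcquisitionGeometry, ArcSpec, BeamFrame, arc_angles, beam_frame
from .phantoms import AIR_HU, CTVolume
from .projection import ProjectionSet, _forward_project_mu, hu_to_mu

__all__ = [
    "ReconConfig",
    "DTSVolume",
    "backproject",
    "deblur",
    "reconstruct_treatment_dts",
    "reslice_ct",
    "reconstruct_reference_dts",
]


def _odd_count(extent: float, step: float) -> int:
    """Slice/pixel count covering ``extent`` at ``step``: rounded up, odd."""
    n = int(math.ceil(extent / step - 1e-9))
    return n + 1 if n % 2 == 0 else n


@dataclass(frozen=True)
class ReconConfig:
    """Reconstruction parameters.

    ``initial_depth``: extent (mm) of the initial back-projection stack,
    deliberately larger than the final volume so the deblurring window can
    see out-of-plane structure.  ``final_volume``: (u, v, w) extents in mm
    of the cropped output (treatment default 60 x 60 x 75, reference
    default 60 x 60 x 33).  ``deblur_fraction``: fraction of the initial
    stack used as the subtraction window.
    """

    initial_depth: float = 150.0
    final_volume: tuple[float, float, float] = (60.0, 60.0, 75.0)
    slice_spacing: float = 3.0
    deblur_fraction: float = 1.0
    in_plane_pixel: float = 1.0

    def __post_init__(self) -> None:
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be > 0")
        if not 0.0 < self.deblur_fraction <= 1.0:
            raise ValueError("deblur_fraction must be in (0, 1]")
        if self.final_volume[2] > self.initial_depth:
            raise ValueError("final depth must not exceed initial_depth")
        if self.in_plane_pixel <= 0:
            raise ValueError("in_plane_pixel must be > 0")

    @classmethod
    def treatment_default(cls, **kw) -> "ReconConfig":
        return cls(**kw)

    @classmethod
    def reference_default(cls, **kw) -> "ReconConfig":
        kw.setdefault("final_volume", (60.0, 60.0, 33.0))
        return cls(**kw)


@dataclass
class DTSVolume:
    """A tomosynthesis volume sliced along the central beam direction.

    ``data[iu, iv, iw]``: slices stacked along ``w`` (depth), each slice in
    the (u, v) plane, isocenter-centered with an odd slice count.
    """

    data: np.ndarray
    slice_spacing: float
    in_plane_pixel: float
    frame: BeamFrame
    arc: ArcSpec
    geom: AcquisitionGeometry
    kind: str = "raw"
    deblur_fraction: float | None = None
    coverage: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Beam-frame (u, v, w) coordinates (mm) of the voxel centers."""
        nu, nv, nw = self.data.shape
        return (
            (np.arange(nu) - (nu - 1) / 2.0) * self.in_plane_pixel,
            (np.arange(nv) - (nv - 1) / 2.0) * self.in_plane_pixel,
            (np.arange(nw) - (nw - 1) / 2.0) * self.slice_spacing,
        )

    def beam_to_index(self, q: np.ndarray) -> np.ndarray:
        """Beam-frame mm -> continuous voxel index."""
        q = np.asarray(q, dtype=float)
        n = np.array(self.data.shape)
        step = np.array([self.in_plane_pixel, self.in_plane_pixel, self.slice_spacing])
        return q / step + (n - 1) / 2.0

    def save(self, path: str) -> None:
        """MetaImage volume plus a JSON sidecar with the DTS metadata."""
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T))
        img.SetSpacing((self.in_plane_pixel, self.in_plane_pixel, self.slice_spacing))
        sitk.WriteImage(img, str(path))
        meta = {
            "theta_c": self.arc.theta_c, "arc_length": self.arc.arc_length,
            "angular_step": self.arc.angular_step,
            "slice_spacing": self.slice_spacing, "in_plane_pixel": self.in_plane_pixel,
            "deblur_fraction": self.deblur_fraction, "kind": self.kind,
            "frame": {"u": list(self.frame.u), "v": list(self.frame.v), "w": list(self.frame.w)},
            "geometry": {"sad": self.geom.sad, "sid": self.geom.sid},
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def backproject(ps: ProjectionSet, cfg: ReconConfig) -> DTSVolume:
    """Shift-and-add back-projection onto depth planes of the central beam.

    For each depth plane (spanning ``initial_depth`` around the isocenter,
    perpendicular to the central beam of the arc) and each in-plane voxel,
    the value is the mean over projections of the projection image sampled
    (bilinearly) at the voxel's perspective projection.  Voxels projecting
    off-detector are excluded from the mean; voxels covered by no
    projection are zero and flagged in ``coverage``.
    """
    if len(ps.projections) < 2:
        raise ValueError("back-projection needs at least 2 projections")
    cframe = beam_frame(ps.arc.theta_c)
    geom = ps.geom

    nu = _odd_count(cfg.final_volume[0], cfg.in_plane_pixel)
    nv = _odd_count(cfg.final_volume[1], cfg.in_plane_pixel)
    nw = _odd_count(cfg.initial_depth, cfg.slice_spacing)
    ucoord = (np.arange(nu) - (nu - 1) / 2.0) * cfg.in_plane_pixel
    vcoord = (np.arange(nv) - (nv - 1) / 2.0) * cfg.in_plane_pixel
    wcoord = (np.arange(nw) - (nw - 1) / 2.0) * cfg.slice_spacing

    # room positions of all stack voxels, (nu, nv, nw, 3)
    pts = (
        ucoord[:, None, None, None] * cframe.u
        + vcoord[None, :, None, None] * cframe.v
        + wcoord[None, None, :, None] * cframe.w
    ).reshape(-1, 3)

    acc = np.zeros(pts.shape[0])
    cnt = np.zeros(pts.shape[0], dtype=np.int32)
    pitch_u, pitch_v = geom.pixel_pitch
    npx_u, npx_v = geom.detector_pixels
    for proj in ps.projections:
        fr = beam_frame(proj.gantry_angle)
        src = -geom.sad * fr.w
        r = pts - src
        depth = r @ fr.w
        scale = geom.sid / depth
        cu = (r @ fr.u) * scale / pitch_u + (npx_u - 1) / 2.0
        cv = (r @ fr.v) * scale / pitch_v + (npx_v - 1) / 2.0
        vals = ndimage.map_coordinates(
            proj.pixels, np.stack([cu, cv]), order=1, mode="constant", cval=np.nan
        )
        ok = np.isfinite(vals)
        acc[ok] += vals[ok]
        cnt += ok

    data = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0).reshape(nu, nv, nw)
    coverage = (cnt == len(ps.projections)).reshape(nu, nv, nw)
    return DTSVolume(
        data=data, slice_spacing=cfg.slice_spacing, in_plane_pixel=cfg.in_plane_pixel,
        frame=cframe, arc=ps.arc, geom=geom, kind="raw", coverage=coverage,
    )


def _crop_centered(data: np.ndarray, counts: tuple[int, int, int]) -> np.ndarray:
    slices = []
    for n_in, n_out in zip(data.shape, counts):
        lo = (n_in - n_out) // 2
        slices.append(slice(lo, lo + n_out))
    return data[tuple(slices)]


def deblur(raw: DTSVolume, cfg: ReconConfig) -> DTSVolume:
    """Subtract the shifted-mean out-of-plane estimate and crop to the final volume.

    For output slice ``i``, the other slices in a centered window covering
    ``deblur_fraction`` of the initial stack are each rescaled about the
    central ray to slice ``i``'s diverging-beam geometry (scale
    (sad + w_j)/(sad + w_i) in sampling space) and averaged; the average is
    subtracted from slice ``i``.  A window containing only slice ``i``
    itself reduces to the identity.
    """
    data = raw.data
    nu, nv, nw = data.shape
    n_win = max(1, int(round(cfg.deblur_fraction * nw)))
    if n_win > nw:
        raise ValueError("deblur window exceeds the stack")
    half = n_win // 2
    sad = raw.geom.sad
    _, _, wcoord = raw.axis_coords()

    iu = np.arange(nu, dtype=float)
    iv = np.arange(nv, dtype=float)
    cu0 = (nu - 1) / 2.0
    cv0 = (nv - 1) / 2.0
    gu, gv = np.meshgrid(iu - cu0, iv - cv0, indexing="ij")

    out = np.empty_like(data)
    for i in range(nw):
        jlo = max(0, i - half)
        jhi = min(nw - 1, i + half)
        js = np.array([j for j in range(jlo, jhi + 1) if j != i])
        if js.size == 0:
            out[..., i] = data[..., i]
            continue
        # sample slice j at coordinates scaled by (sad+w_j)/(sad+w_i):
        # structure in focus at plane j appears in plane i magnified by the inverse
        scales = (sad + wcoord[js]) / (sad + wcoord[i])
        cu = gu[..., None] * scales + cu0
        cv = gv[..., None] * scales + cv0
        cj = np.broadcast_to(js.astype(float), cu.shape)
        est = ndimage.map_coordinates(
            data, np.stack([cu, cv, cj]), order=1, mode="nearest"
        ).mean(axis=-1)
        out[..., i] = data[..., i] - est

    counts = (nu, nv, _odd_count(cfg.final_volume[2], cfg.slice_spacing))
    cropped = _crop_centered(out, counts)
    coverage = (
        _crop_centered(raw.coverage, counts) if raw.coverage is not None else None
    )
    return DTSVolume(
        data=cropped, slice_spacing=raw.slice_spacing, in_plane_pixel=raw.in_plane_pixel,
        frame=raw.frame, arc=raw.arc, geom=raw.geom, kind=raw.kind,
        deblur_fraction=cfg.deblur_fraction, coverage=coverage,
    )


def reconstruct_treatment_dts(ps: ProjectionSet, cfg: ReconConfig | None = None) -> DTSVolume:
    """Back-project then deblur a treatment acquisition (final 60 x 60 x 75 mm by default)."""
    cfg = cfg or ReconConfig.treatment_default()
    vol = deblur(backproject(ps, cfg), cfg)
    vol.kind = "treatment"
    return vol


def reslice_ct(
    vol: CTVolume, frame: BeamFrame, cfg: ReconConfig | None = None, pad: float = 20.0
) -> CTVolume:
    """Trilinearly resample a CT onto a beam-aligned (u, v, w) grid.

    The grid covers the reconstruction footprint (final in-plane extent,
    initial depth) plus ``pad`` mm so that diverging rays used by the DRR
    step stay inside.  Raises if the requested grid exits the CT volume.
    """
    cfg = cfg or ReconConfig.reference_default()
    step = float(min(vol.spacing))
    half_u = cfg.final_volume[0] / 2.0 + pad
    half_v = cfg.final_volume[1] / 2.0 + pad
    half_w = cfg.initial_depth / 2.0 + pad
    nu = 2 * int(math.ceil(half_u / step)) + 1
    nv = 2 * int(math.ceil(half_v / step)) + 1
    nw = 2 * int(math.ceil(half_w / step)) + 1
    ucoord = (np.arange(nu) - (nu - 1) / 2.0) * step
    vcoord = (np.arange(nv) - (nv - 1) / 2.0) * step
    wcoord = (np.arange(nw) - (nw - 1) / 2.0) * step

    pts = (
        ucoord[:, None, None, None] * frame.u
        + vcoord[None, :, None, None] * frame.v
        + wcoord[None, None, :, None] * frame.w
    ).reshape(-1, 3)
    idx = vol.world_to_index(pts)

    # the final (unpadded) reconstruction volume must lie inside the CT
    n = np.array(vol.shape)
    core_mask = (
        (np.abs(ucoord[:, None, None]) <= cfg.final_volume[0] / 2.0 + 1e-9)
        & (np.abs(vcoord[None, :, None]) <= cfg.final_volume[1] / 2.0 + 1e-9)
        & (np.abs(wcoord[None, None, :]) <= cfg.final_volume[2] / 2.0 + 1e-9)
    ).reshape(-1)
    inside = np.all((idx >= 0) & (idx <= n - 1), axis=1)
    if not np.all(inside[core_mask]):
        n_out = int(np.count_nonzero(~inside[core_mask]))
        raise ValueError(
            f"reconstruction volume exits the CT: {n_out} of "
            f"{int(core_mask.sum())} core voxels fall outside the CT grid"
        )

    vals = ndimage.map_coordinates(
        np.asarray(vol.voxels, dtype=float), idx.T, order=1, mode="constant", cval=AIR_HU
    ).reshape(nu, nv, nw)

    # origin = room position of voxel (0,0,0): -half extents along each beam axis
    origin_world = ucoord[0] * frame.u + vcoord[0] * frame.v + wcoord[0] * frame.w
    axes = np.column_stack([frame.u, frame.v, frame.w])
    return CTVolume(voxels=vals, spacing=(step, step, step),
                    origin=tuple(origin_world), axes=axes)


def reconstruct_reference_dts(
    vol: CTVolume,
    arc: ArcSpec,
    geom: AcquisitionGeometry = AcquisitionGeometry(),
    cfg: ReconConfig | None = None,
) -> DTSVolume:
    """Reference DTS from a planning CT: reslice -> DRR -> back-project -> deblur.

    The virtual projections are noise-free; the final depth defaults to
    33 mm (the reference volume only needs to contain the template plus
    the matching search region).
    """
    cfg = cfg or ReconConfig.reference_default()
    frame = beam_frame(arc.theta_c)
    resliced = reslice_ct(vol, frame, cfg)
    mu = hu_to_mu(resliced.voxels)
    projections = [
        _forward_project_mu(mu, resliced, float(a), geom) for a in arc_angles(arc)
    ]
    ps = ProjectionSet(projections=projections, arc=arc, geom=geom, noise_sigma=0.0)
    out = deblur(backproject(ps, cfg), cfg)
    out.kind = "reference"
    return out
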