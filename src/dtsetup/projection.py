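"""Cone-beam projection simulation: DRRs / treatment acquisitions with optional noise.

Projections are line integrals of the linear attenuation coefficient
(dimensionless, mu * mm) on the detector grid.  The treatment acquisition
adds i.i.d. Gaussian noise on the line integrals; virtual projections
(DRRs) for the reference path are computed noise-free through the same
ray model, which keeps the two reconstruction paths algebraically
comparable.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from ._ray import raycast
from .geometry import AcquisitionGeometry, ArcSpec, arc_angles, beam_frame
from .phantoms import CTVolume

__all__ = [
    "Projection",
    "ProjectionSet",
    "hu_to_mu",
    "forward_project",
    "acquire_arc",
    "MU_WATER",
]

#: linear attenuation of water at imaging energy, mm^-1
MU_WATER = 0.02


def hu_to_mu(hu, mu_water: float = MU_WATER):
    """Hounsfield units -> linear attenuation (mm^-1), clamped at zero.

    mu = mu_water * (1 + HU/1000); water (0 HU) -> mu_water, air (-1000) -> 0.
    """
    return np.maximum(mu_water * (1.0 + np.asarray(hu, dtype=float) / 1000.0), 0.0)


@dataclass
class Projection:
    """One cone-beam projection: ``pixels[iu, iv]`` line integrals at a gantry angle."""

    pixels: np.ndarray
    gantry_angle: float
    geom: AcquisitionGeometry

    def detector_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Detector (u, v) mm coordinates of the pixel centers."""
        pu, pv = self.geom.pixel_pitch
        nu, nv = self.geom.detector_pixels
        return (
            (np.arange(nu) - (nu - 1) / 2.0) * pu,
            (np.arange(nv) - (nv - 1) / 2.0) * pv,
        )


@dataclass
class ProjectionSet:
    """An ordered short-arc acquisition sharing one geometry."""

    projections: list[Projection]
    arc: ArcSpec
    geom: AcquisitionGeometry
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        # angles must advance monotonically along the arc (mod 360 unwrap)
        ang = np.array([p.gantry_angle for p in self.projections])
        if len(ang) > 1:
            d = np.mod(np.diff(ang) + 180.0, 360.0) - 180.0
            if np.any(d <= 0):
                raise ValueError("projection angles must be strictly increasing along the arc")

    @property
    def angles(self) -> np.ndarray:
        return np.array([p.gantry_angle for p in self.projections])

    def save(self, directory: str) -> None:
        """Write the projections as TIFF stacks plus a JSON sidecar."""
        import tifffile

        os.makedirs(directory, exist_ok=True)
        for i, p in enumerate(self.projections):
            tifffile.imwrite(os.path.join(directory, f"proj_{i:03d}.tif"),
                             p.pixels.astype(np.float32))
        meta = {
            "angles": [float(p.gantry_angle) for p in self.projections],
            "arc": {"theta_c": self.arc.theta_c, "arc_length": self.arc.arc_length,
                    "angular_step": self.arc.angular_step},
            "geometry": {"sad": self.geom.sad, "sid": self.geom.sid,
                         "detector_size": list(self.geom.detector_size),
                         "detector_pixels": list(self.geom.detector_pixels)},
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }
        with open(os.path.join(directory, "projections.json"), "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, directory: str) -> "ProjectionSet":
        import tifffile

        with open(os.path.join(directory, "projections.json")) as fh:
            meta = json.load(fh)
        geom = AcquisitionGeometry(
            sad=meta["geometry"]["sad"], sid=meta["geometry"]["sid"],
            detector_size=tuple(meta["geometry"]["detector_size"]),
            detector_pixels=tuple(meta["geometry"]["detector_pixels"]))
        arc = ArcSpec(**meta["arc"])
        projections = [
            Projection(
                pixels=tifffile.imread(os.path.join(directory, f"proj_{i:03d}.tif")).astype(float),
                gantry_angle=a, geom=geom)
            for i, a in enumerate(meta["angles"])
        ]
        return cls(projections=projections, arc=arc, geom=geom,
                   noise_sigma=meta.get("noise_sigma", 0.0), seed=meta.get("seed"))


def _clip_rays(src_idx: np.ndarray, dir_idx: np.ndarray, shape: tuple[int, int, int]):
    """Slab-clip rays against the index box [0, n-1] per axis.

    Returns (t0, t1) world-path parameters (mm); t1 <= t0 marks a miss.
    """
    eps = 1e-6
    lo = np.zeros(3) + eps
    hi = np.array(shape, dtype=float) - 1.0 - eps
    t0 = np.zeros(dir_idx.shape[0])
    t1 = np.full(dir_idx.shape[0], np.inf)
    for k in range(3):
        d = dir_idx[:, k]
        s = src_idx[k]
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = (lo[k] - s) / d
            tb = (hi[k] - s) / d
        near = np.minimum(ta, tb)
        far = np.maximum(ta, tb)
        parallel = np.abs(d) < 1e-12
        inside = (s >= lo[k]) & (s <= hi[k])
        near = np.where(parallel, np.where(inside, -np.inf, np.inf), near)
        far = np.where(parallel, np.where(inside, np.inf, -np.inf), far)
        t0 = np.maximum(t0, near)
        t1 = np.minimum(t1, far)
    return t0, np.maximum(t1, t0)


def _forward_project_mu(
    mu: np.ndarray, vol: CTVolume, angle: float, geom: AcquisitionGeometry,
    step: float | None = None,
) -> Projection:
    """Core DRR: ray-integrate a precomputed attenuation volume."""
    frame = beam_frame(angle)
    src = -geom.sad * frame.w

    # detector pixel world positions
    det_u, det_v = (
        (np.arange(npx) - (npx - 1) / 2.0) * pitch
        for npx, pitch in zip(geom.detector_pixels, geom.pixel_pitch)
    )
    center = src + geom.sid * frame.w
    uu, vv = np.meshgrid(det_u, det_v, indexing="ij")
    pts = center + uu[..., None] * frame.u + vv[..., None] * frame.v
    d = pts.reshape(-1, 3) - src
    d /= np.linalg.norm(d, axis=1, keepdims=True)

    # volume must be fully in front of the source along the central ray
    n = np.array(vol.shape)
    corners_idx = np.array([[i, j, k] for i in (0, n[0] - 1) for j in (0, n[1] - 1) for k in (0, n[2] - 1)])
    corners = vol.index_to_world(corners_idx)
    if np.any((corners - src) @ frame.w <= 0):
        raise ValueError(f"volume extends behind the source at gantry angle {angle}")

    spacing = np.asarray(vol.spacing)
    src_idx = vol.world_to_index(src)[0]
    dir_idx = (d @ vol.axes) / spacing
    t0, t1 = _clip_rays(src_idx, dir_idx, vol.shape)
    t1 = np.minimum(t1, geom.sid + float(np.max(n * spacing)))

    if step is None:
        step = 0.5 * float(np.min(spacing))
    vals = raycast(
        np.ascontiguousarray(mu, dtype=np.float64), src_idx,
        np.ascontiguousarray(dir_idx), t0, t1, step,
    )
    return Projection(pixels=vals.reshape(geom.detector_pixels), gantry_angle=angle, geom=geom)


def forward_project(
    vol: CTVolume, angle: float, geom: AcquisitionGeometry, step: float | None = None
) -> Projection:
    """Virtual projection (DRR) of a CT volume at one gantry angle.

    Each pixel is the ray integral of ``hu_to_mu(vol)`` from the source to
    that detector pixel, trilinearly sampled at half-voxel steps.
    """
    return _forward_project_mu(hu_to_mu(vol.voxels), vol, angle, geom, step)


def acquire_arc(
    vol: CTVolume,
    arc: ArcSpec,
    geom: AcquisitionGeometry = AcquisitionGeometry(),
    noise_sigma: float = 0.01,
    seed: int | None = 0,
) -> ProjectionSet:
    """Simulate a short-arc treatment acquisition.

    One projection per arc angle; Gaussian noise of std ``noise_sigma`` is
    added to the line integrals (skipped entirely when sigma is 0, making
    the noise-free path bit-identical to per-angle ``forward_project``).
    """
    mu = hu_to_mu(vol.voxels)
    rng = np.random.default_rng(seed)
    projections = []
    for angle in arc_angles(arc):
        try:
            proj = _forward_project_mu(mu, vol, float(angle), geom)
        except ValueError as exc:
            raise ValueError(f"projection failed at gantry angle {angle}: {exc}") from exc
        if noise_sigma > 0:
            proj.pixels = proj.pixels + rng.normal(0.0, noise_sigma, proj.pixels.shape)
        projections.append(proj)
    return ProjectionSet(projections=projections, arc=arc, geom=geom,
                         noise_sigma=noise_sigma, seed=seed)
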