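"""Digital phantoms: voxelized planning-CT volumes with embedded surgical clips.

A phantom is a water-equivalent body (box or hemiellipsoid) containing small
high-density clips that act as registration surrogates, mimicking the
physical quality-assurance phantoms used to validate clip-based patient
setup.  Known rigid shifts applied to the rendered volume provide the
ground truth against which registration accuracy is measured.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "ClipSpec",
    "PhantomSpec",
    "CTVolume",
    "Shift3D",
    "build_phantom",
    "preset_phantom",
    "apply_shift",
]

AIR_HU = -1000.0
#: air margin (mm) added around the body so that shifts up to the
#: registration search half-width (7.5 mm) never push anatomy off the grid
AIR_MARGIN = 10.0
#: vertical air clearance (mm): a planning scan of a flat phantom always
#: images well beyond the slab, and beam-aligned reference reconstruction
#: volumes at tangential gantry angles need the extra vertical coverage
AIR_MARGIN_Z = 20.0


@dataclass(frozen=True)
class ClipSpec:
    """A surgical clip modelled as a finite cylinder.

    ``center`` (mm, room coordinates), ``axis`` (unit long-axis direction),
    ``length``/``diameter`` in mm, ``hu`` the clip Hounsfield value.
    """

    center: tuple[float, float, float]
    axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    length: float = 4.0
    diameter: float = 1.0
    hu: float = 1200.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("clip length and diameter must be > 0")
        if not -1000.0 <= self.hu <= 4000.0:
            raise ValueError(f"clip hu {self.hu} outside [-1000, 4000]")
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if n < 1e-12:
            raise ValueError("clip axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(ax / n))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    def surface_points(self, n_ring: int = 8) -> np.ndarray:
        """Sample points on the cylinder surface (used for containment checks)."""
        a = np.array(self.axis)
        ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(a, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        r = self.diameter / 2.0
        h = self.length / 2.0
        pts = []
        for end in (-h, h):
            for phi in np.linspace(0, 2 * np.pi, n_ring, endpoint=False):
                pts.append(np.array(self.center) + end * a + r * (np.cos(phi) * e1 + np.sin(phi) * e2))
        return np.array(pts)


@dataclass(frozen=True)
class PhantomSpec:
    """Body geometry plus clip inventory.

    ``body_size`` gives the full extents (mm).  ``shape`` is ``box`` or
    ``hemiellipsoid`` (flat face down, dome toward +z); the body is
    centered laterally/longitudinally on the isocenter.
    """

    body_size: tuple[float, float, float]
    body_hu: float = 0.0
    clips: tuple[ClipSpec, ...] = ()
    shape: str = "box"

    def __post_init__(self) -> None:
        if self.shape not in ("box", "hemiellipsoid"):
            raise ValueError(f"unknown body shape {self.shape!r}")
        if min(self.body_size) <= 0:
            raise ValueError("body_size components must be > 0")
        object.__setattr__(self, "clips", tuple(self.clips))
        object.__setattr__(self, "body_size", tuple(float(s) for s in self.body_size))
        for i, clip in enumerate(self.clips):
            pts = clip.surface_points()
            if not np.all(self._inside_body(pts)):
                raise ValueError(f"clip {i} (center {clip.center}) extends outside the body")

    def _inside_body(self, pts: np.ndarray) -> np.ndarray:
        """Boolean mask: which points (n, 3) lie inside the body."""
        pts = np.atleast_2d(pts)
        bx, by, bz = self.body_size
        if self.shape == "box":
            return (
                (np.abs(pts[:, 0]) <= bx / 2)
                & (np.abs(pts[:, 1]) <= by / 2)
                & (np.abs(pts[:, 2]) <= bz / 2)
            )
        # hemiellipsoid: semi-axes (bx/2, by/2, bz), flat base at z = -bz/2
        a, b, c = bx / 2, by / 2, bz
        z0 = -bz / 2
        inside = (
            (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 + ((pts[:, 2] - z0) / c) ** 2
        ) <= 1.0
        return inside & (pts[:, 2] >= z0)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "body_size": [float(s) for s in self.body_size],
                "body_hu": float(self.body_hu),
                "shape": self.shape,
                "clips": [
                    {
                        "center": [float(x) for x in c.center],
                        "axis": [float(x) for x in c.axis],
                        "length": float(c.length),
                        "diameter": float(c.diameter),
                        "hu": float(c.hu),
                    }
                    for c in self.clips
                ],
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        d = yaml.safe_load(text)
        clips = tuple(ClipSpec(center=tuple(c["center"]), axis=tuple(c.get("axis", (0, 1, 0))),
                               length=c.get("length", 4.0), diameter=c.get("diameter", 1.0),
                               hu=c.get("hu", 1200.0)) for c in d.get("clips", []))
        return cls(body_size=tuple(d["body_size"]), body_hu=d.get("body_hu", 0.0),
                   clips=clips, shape=d.get("shape", "box"))


@dataclass(frozen=True)
class Shift3D:
    """Rigid couch shift in room coordinates (mm): x lateral, y longitudinal, z vertical."""

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("shift components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.as_array()))

    def __neg__(self) -> "Shift3D":
        return Shift3D(-self.x, -self.y, -self.z)


@dataclass
class CTVolume:
    """A scalar HU volume on a regular grid.

    ``voxels[ix, iy, iz]`` with room position
    ``origin + axes @ (index * spacing)``; ``axes`` columns are the room
    directions of the index axes (identity for axial volumes, a beam-frame
    rotation for resliced volumes).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    spec: PhantomSpec | None = None
    #: current clip primitives (tracks applied shifts; spec stays as built)
    clips: tuple[ClipSpec, ...] | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a 3D grid with >= 1 voxel per axis")
        if min(self.spacing) <= 0:
            raise ValueError("spacing components must be > 0")
        self.axes = np.asarray(self.axes, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + (idx * np.asarray(self.spacing)) @ self.axes.T

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return ((pts - np.asarray(self.origin)) @ self.axes) / np.asarray(self.spacing)

    def save(self, path: str) -> None:
        """Write as MetaImage (.mha) or NIfTI (.nii/.nii.gz), mm spacing in the header."""
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(self.voxels.T))  # -> [z, y, x]
        img.SetSpacing(tuple(float(s) for s in self.spacing))
        img.SetOrigin(tuple(float(o) for o in self.origin))
        img.SetDirection(tuple(self.axes.flatten()))
        sitk.WriteImage(img, str(path))

    @classmethod
    def load(cls, path: str) -> "CTVolume":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        voxels = sitk.GetArrayFromImage(img).T  # [z, y, x] -> [x, y, z]
        return cls(
            voxels=np.asarray(voxels, dtype=float),
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
            axes=np.array(img.GetDirection()).reshape(3, 3),
        )


def _render_clip(
    voxels: np.ndarray,
    spacing: np.ndarray,
    origin: np.ndarray,
    clip: ClipSpec,
    body_hu: float,
    supersample: int = 12,
) -> None:
    """Rasterize one cylindrical clip with partial-volume anti-aliasing.

    Each voxel overlapping the cylinder gets a volume-fraction-weighted
    blend of clip HU and background HU, the fraction estimated on a
    ``supersample**3`` midpoint sub-grid.  Deterministic.
    """
    c = np.array(clip.center)
    a = np.array(clip.axis)
    h = clip.length / 2.0
    r = clip.diameter / 2.0
    reach = h + r  # bounding radius
    lo = np.floor((c - reach - origin) / spacing).astype(int) - 1
    hi = np.ceil((c + reach - origin) / spacing).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(voxels.shape) - 1)
    if np.any(lo > hi):
        return
    ix, iy, iz = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
    centers = origin + np.stack([gx, gy, gz], axis=-1) * spacing  # (nx,ny,nz,3)

    off1 = (np.arange(supersample) + 0.5) / supersample - 0.5
    ox, oy, oz = np.meshgrid(off1, off1, off1, indexing="ij")
    offsets = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3) * spacing  # (s^3, 3)

    pts = centers[..., None, :] + offsets  # (nx,ny,nz,s^3,3)
    d = pts - c
    along = d @ a
    radial2 = np.sum(d * d, axis=-1) - along**2
    inside = (np.abs(along) <= h) & (radial2 <= r * r)
    frac = inside.mean(axis=-1)

    block = voxels[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    block[...] = (1.0 - frac) * block + frac * clip.hu


def build_phantom(
    spec: PhantomSpec,
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    margin: tuple[float, float, float] = (AIR_MARGIN, AIR_MARGIN, AIR_MARGIN_Z),
) -> CTVolume:
    """Voxelize a phantom spec onto a regular grid.

    The grid covers the body plus an air margin on every side (>= 10 mm;
    20 mm vertically, mirroring the vertical clearance of a real planning
    scan), with an odd voxel count per axis so the isocenter (room origin)
    is a voxel center.  Clips are rendered as anti-aliased cylinders;
    background inside the body is ``body_hu``, outside is air (-1000 HU).
    """
    spacing = np.asarray(voxel_spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("voxel_spacing must be > 0")
    extent = np.asarray(spec.body_size) + 2 * np.asarray(margin, dtype=float)
    n = np.ceil(extent / spacing).astype(int) + 1
    n += 1 - (n % 2)  # odd counts: isocenter on a voxel center
    origin = -(n - 1) / 2.0 * spacing

    idx = [np.arange(n[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*idx, indexing="ij")
    pts = origin + np.stack([gx, gy, gz], axis=-1) * spacing
    inside = spec._inside_body(pts.reshape(-1, 3)).reshape(tuple(n))

    voxels = np.full(tuple(n), AIR_HU, dtype=float)
    voxels[inside] = spec.body_hu

    # anti-alias the body surface: voxels adjacent to the inside/outside
    # transition get a volume-fraction blend so ray path lengths through the
    # rendered body match the continuous body extent (a plain binary fill
    # inflates every face by half a voxel)
    dil = ndimage.binary_dilation(inside)
    ero = ndimage.binary_erosion(inside)
    boundary = dil & ~ero
    if boundary.any():
        ss = 4
        off1 = (np.arange(ss) + 0.5) / ss - 0.5
        ox, oy, oz = np.meshgrid(off1, off1, off1, indexing="ij")
        offsets = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3) * spacing
        bpts = pts[boundary]  # (nb, 3)
        sub = bpts[:, None, :] + offsets  # (nb, ss^3, 3)
        frac = (
            spec._inside_body(sub.reshape(-1, 3))
            .reshape(len(bpts), -1)
            .mean(axis=1)
        )
        voxels[boundary] = AIR_HU + frac * (spec.body_hu - AIR_HU)

    for clip in spec.clips:
        _render_clip(voxels, spacing, origin, clip, spec.body_hu)

    return CTVolume(
        voxels=voxels,
        spacing=tuple(spacing),
        origin=tuple(origin),
        spec=spec,
        clips=spec.clips,
    )


#: clip layouts for the presets: centers spread through the target region so
#: that every clinically relevant beam's-eye view sees them well separated
_RECT_CLIP_LAYOUT = (
    ((0.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
    ((-15.0, 12.0, 6.0), (1.0, 0.0, 0.0)),
    ((14.0, -10.0, -7.0), (0.0, 0.6, 0.8)),
    ((-12.0, -14.0, 5.0), (0.8, 0.0, 0.6)),
    ((12.0, 15.0, -5.0), (0.707, 0.707, 0.0)),
)


def preset_phantom(
    name: str,
    clip_hu: float | tuple[float, float] = 1200.0,
) -> PhantomSpec:
    """Built-in phantom presets.

    ``rectangular``: a 120 x 200 x 40 mm water-equivalent box with five
    1 x 4 mm surgical clips.  ``breast``: a 100 x 100 x 60 mm water
    hemiellipsoid (representative breast mold) with the same five clips.
    ``clip_hu`` may be a single value or a (lo, hi) range distributed
    across the clips.
    """
    if name not in ("rectangular", "breast"):
        raise ValueError(f"unknown preset {name!r}; valid presets: 'rectangular', 'breast'")
    if isinstance(clip_hu, (tuple, list)):
        hus = np.linspace(clip_hu[0], clip_hu[1], len(_RECT_CLIP_LAYOUT))
    else:
        hus = np.full(len(_RECT_CLIP_LAYOUT), float(clip_hu))
    clips = tuple(
        ClipSpec(center=c, axis=a, length=4.0, diameter=1.0, hu=float(hu))
        for (c, a), hu in zip(_RECT_CLIP_LAYOUT, hus)
    )
    if name == "rectangular":
        return PhantomSpec(body_size=(120.0, 200.0, 40.0), clips=clips, shape="box")
    return PhantomSpec(body_size=(100.0, 100.0, 60.0), clips=clips, shape="hemiellipsoid")


def apply_shift(volume: CTVolume, shift: Shift3D) -> CTVolume:
    """Rigidly translate a volume by ``shift`` (trilinear resampling).

    The returned "treatment-day" volume is the planning volume displaced by
    +shift, so a correct registration reports a couch correction equal to
    ``shift``.  Raises if the shift would push any clip off the grid.
    """
    s = shift.as_array()
    spacing = np.asarray(volume.spacing)
    n = np.array(volume.shape)
    grid_lo = np.asarray(volume.origin)
    grid_hi = grid_lo + (n - 1) * spacing
    clips = volume.clips or ()
    for i, clip in enumerate(clips):
        reach = clip.length / 2.0 + clip.diameter / 2.0
        c = np.array(clip.center) + s
        if np.any(c - reach < grid_lo) or np.any(c + reach > grid_hi):
            raise ValueError(f"shift {tuple(s)} would move clip {i} outside the grid")

    if np.allclose(s, 0.0):
        shifted = volume.voxels.copy()
    else:
        shifted = ndimage.shift(
            volume.voxels, s / spacing, order=1, mode="constant", cval=AIR_HU
        )

    new_clips = (
        tuple(
            dataclasses.replace(c, center=tuple(np.array(c.center) + s)) for c in clips
        )
        if volume.clips is not None
        else None
    )
    return CTVolume(
        voxels=shifted,
        spacing=volume.spacing,
        origin=volume.origin,
        axes=volume.axes.copy(),
        spec=volume.spec,
        clips=new_clips,
    )
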