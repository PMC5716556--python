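"""Acquisition geometry: gantry-angle conventions, beam frames, and point projection.

Room coordinates follow IEC 61217 with the isocenter at the origin:
``x`` lateral (toward patient left), ``y`` longitudinal (superior),
``z`` vertical (anterior).  Gantry angle 0 deg puts the kV source directly
above the isocenter; the angle increases toward patient left.  All
distances are millimetres, all angles degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionGeometry",
    "ArcSpec",
    "BeamFrame",
    "arc_angles",
    "beam_frame",
    "project_point",
    "DEFAULT_GEOMETRY",
    "COMPACT_GEOMETRY",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """kV imaging chain: source-to-isocenter / source-to-detector distances and detector grid.

    The default (sad 1000, sid 1500) is the standard Varian OBI layout.  The
    ``compact`` preset (sad 500, sid 1000) reproduces the alternative distances
    sometimes quoted for this chain (imager 50 cm from isocenter, source
    100 cm from imager); both are retained because neither is universal.
    """

    sad: float = 1000.0
    sid: float = 1500.0
    detector_size: tuple[float, float] = (300.0, 300.0)
    detector_pixels: tuple[int, int] = (300, 300)

    def __post_init__(self) -> None:
        if not 0.0 < self.sad < self.sid:
            raise ValueError(f"require 0 < sad < sid, got sad={self.sad}, sid={self.sid}")
        if min(self.detector_pixels) < 16:
            raise ValueError("detector needs at least 16 pixels per axis")

    @property
    def pixel_pitch(self) -> tuple[float, float]:
        """Detector pixel size (mm) along the (u, v) detector axes."""
        return (
            self.detector_size[0] / self.detector_pixels[0],
            self.detector_size[1] / self.detector_pixels[1],
        )

    @property
    def magnification(self) -> float:
        """Magnification of the isocenter plane onto the detector (sid/sad)."""
        return self.sid / self.sad


DEFAULT_GEOMETRY = AcquisitionGeometry()
COMPACT_GEOMETRY = AcquisitionGeometry(sad=500.0, sid=1000.0)

GEOMETRY_PRESETS = {"default": DEFAULT_GEOMETRY, "compact": COMPACT_GEOMETRY}


@dataclass(frozen=True)
class ArcSpec:
    """A short tomosynthesis acquisition arc.

    ``theta_c`` is the middle arc angle (gantry angle at arc center),
    ``arc_length`` the angular span, ``angular_step`` the per-projection
    angular increment.
    """

    theta_c: float
    arc_length: float
    angular_step: float = 0.5

    def __post_init__(self) -> None:
        if self.arc_length <= 0:
            raise ValueError("arc_length must be > 0")
        if self.angular_step <= 0:
            raise ValueError("angular_step must be > 0")
        if self.angular_step > self.arc_length:
            raise ValueError("angular_step must not exceed arc_length")


@dataclass(frozen=True)
class BeamFrame:
    """Orthonormal right-handed triad attached to the central beam.

    ``w`` points from the source toward the isocenter (depth direction),
    ``v`` is the longitudinal room axis, ``u = v x w`` completes the
    in-plane detector axes.  Tomosynthesis slices live in the (u, v) plane.
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def matrix(self) -> np.ndarray:
        """Rows (u, v, w): maps room vectors to beam-frame components."""
        return np.vstack([self.u, self.v, self.w])

    def to_beam(self, p: np.ndarray) -> np.ndarray:
        """Room coordinates -> beam-frame (u, v, w) components."""
        return self.matrix() @ np.asarray(p, dtype=float)

    def to_room(self, q: np.ndarray) -> np.ndarray:
        """Beam-frame (u, v, w) components -> room coordinates."""
        return self.matrix().T @ np.asarray(q, dtype=float)


def arc_angles(arc: ArcSpec) -> np.ndarray:
    """Gantry angles of the projections in an arc.

    Evenly spaced from ``theta_c - arc_length/2`` to ``theta_c + arc_length/2``
    inclusive; ``floor(arc_length/step) + 1`` angles, wrapped to [0, 360).
    """
    n = int(math.floor(arc.arc_length / arc.angular_step + 1e-9)) + 1
    start = arc.theta_c - arc.arc_length / 2.0
    return np.mod(start + np.arange(n) * arc.angular_step, 360.0)


def beam_frame(theta_c: float) -> BeamFrame:
    """Beam frame for gantry angle ``theta_c`` (degrees, IEC 61217)."""
    t = math.radians(theta_c)
    # source sits at +sad * (sin t, 0, cos t); w points source -> isocenter
    w = np.array([-math.sin(t), 0.0, -math.cos(t)])
    v = np.array([0.0, 1.0, 0.0])
    u = np.cross(v, w)
    return BeamFrame(u=u, v=v, w=w)


def source_position(theta_c: float, geom: AcquisitionGeometry) -> np.ndarray:
    """Room coordinates of the kV source at the given gantry angle."""
    return -geom.sad * beam_frame(theta_c).w


def project_point(
    p: np.ndarray, gantry_angle: float, geom: AcquisitionGeometry
) -> np.ndarray:
    """Perspective (pinhole) projection of room point(s) onto the detector.

    The detector plane is perpendicular to the central ray at distance
    ``sid`` from the source and centered on it.  Returns detector (u, v)
    offsets in mm; points may be a single 3-vector or an (n, 3) array.

    Raises ``ValueError`` for points at or behind the source plane.
    """
    frame = beam_frame(gantry_angle)
    src = -geom.sad * frame.w
    pts = np.atleast_2d(np.asarray(p, dtype=float))
    r = pts - src
    depth = r @ frame.w
    if np.any(depth <= 1e-9):
        raise ValueError("point at or behind the source plane")
    scale = geom.sid / depth
    det = np.stack([(r @ frame.u) * scale, (r @ frame.v) * scale], axis=-1)
    return det[0] if np.asarray(p).ndim == 1 else det


def arc_separation(theta_1: float, theta_2: float) -> float:
    """Angular separation between two arc centers, wrapped to [0, 180]."""
    d = abs(theta_1 - theta_2) % 360.0
    return min(d, 360.0 - d)
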