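"""Shared fixtures: phantoms, geometries, and cached heavy reconstructions.

Session-scoped fixtures memoize the expensive simulation products
(projection sets, reference reconstructions) so independent tests can
share them without re-running the pipeline.
"""

from __future__ import annotations

import pytest

import dtsetup as dt
from dtsetup.dts_recon import ReconConfig


#: compact acquisition geometry for unit tests: same sad/sid as the clinical
#: default but a smaller detector, enough to cover the reconstruction
#: footprint at magnification
SMALL_GEOM = dt.AcquisitionGeometry(detector_size=(160.0, 160.0), detector_pixels=(160, 160))


@pytest.fixture(scope="session")
def small_geom() -> dt.AcquisitionGeometry:
    return SMALL_GEOM


@pytest.fixture(scope="session")
def rect_spec() -> dt.PhantomSpec:
    return dt.preset_phantom("rectangular")


@pytest.fixture(scope="session")
def rect_vol(rect_spec) -> dt.CTVolume:
    return dt.build_phantom(rect_spec)


@pytest.fixture(scope="session")
def point_clip_vol() -> dt.CTVolume:
    """One near-point clip in air: isolates the system's impulse response.

    The air background (body_hu = -1000) removes the body line-integral
    pedestal so depth profiles measure the clip response alone.
    """
    clip = dt.ClipSpec(center=(0.0, 0.0, 0.0), axis=(0.0, 1.0, 0.0),
                       length=2.0, diameter=1.0, hu=2000.0)
    spec = dt.PhantomSpec(body_size=(60.0, 60.0, 40.0), body_hu=-1000.0,
                          clips=(clip,), shape="box")
    return dt.build_phantom(spec)


@pytest.fixture(scope="session")
def reference_cache() -> dict:
    """Shared memo for reference DTS reconstructions across tests."""
    return {}


@pytest.fixture(scope="session")
def small_dts(point_clip_vol, small_geom) -> dt.DTSVolume:
    """One treatment DTS of the point-clip phantom (noise-free, 10 deg arc)."""
    ps = dt.acquire_arc(point_clip_vol, dt.ArcSpec(305.0, 10.0), small_geom,
                        noise_sigma=0.0, seed=0)
    return dt.reconstruct_treatment_dts(ps, ReconConfig.treatment_default())
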