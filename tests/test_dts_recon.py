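"""Shift-and-add reconstruction, deblurring, reslicing, reference synthesis."""

import numpy as np
import pytest

import dtsetup as dt
from dtsetup.dts_recon import ReconConfig, _odd_count, backproject, deblur, reslice_ct
from dtsetup.geometry import beam_frame
from dtsetup.projection import Projection, ProjectionSet


def _depth_profile(dts, radius=4.0):
    """Max value per slice inside an in-plane disc around the isocenter."""
    u, v, _ = dts.axis_coords()
    mask = (u[:, None] ** 2 + v[None, :] ** 2) <= radius**2
    return dts.data[mask, :].max(axis=0)


def _fwhm(profile, spacing):
    """Full width at half max of a 1D profile, linear interpolation at the edges."""
    p = profile - profile.min()
    half = p.max() / 2.0
    above = np.where(p >= half)[0]
    return (above[-1] - above[0] + 1) * spacing


class TestStackLayout:
    @pytest.mark.parametrize(
        "extent, step, expected",
        [(75.0, 3.0, 25), (33.0, 3.0, 11), (150.0, 3.0, 51), (33.0, 1.0, 33),
         (75.0, 7.0, 11), (24.0, 7.0, 5)],
    )
    def test_slice_counts_round_up_to_odd(self, extent, step, expected):
        assert _odd_count(extent, step) == expected

    def test_treatment_volume_spans_default_extents(self, small_dts):
        nu, nv, nw = small_dts.shape
        assert (nu - 1) * small_dts.in_plane_pixel >= 60.0
        assert nw == 25  # 75 mm at 3 mm spacing
        assert nw % 2 == 1


class TestBackproject:
    def test_zero_projections_give_zero_stack(self, small_geom):
        arc = dt.ArcSpec(0.0, 2.0, 1.0)
        projections = [
            Projection(pixels=np.zeros(small_geom.detector_pixels), gantry_angle=a,
                       geom=small_geom)
            for a in (359.0, 0.0, 1.0)
        ]
        ps = ProjectionSet(projections=projections, arc=arc, geom=small_geom)
        raw = backproject(ps, ReconConfig())
        assert np.allclose(raw.data, 0.0)

    def test_point_clip_focuses_at_stack_center(self, point_clip_vol, small_geom):
        ps = dt.acquire_arc(point_clip_vol, dt.ArcSpec(305.0, 10.0), small_geom,
                            noise_sigma=0.0)
        raw = backproject(ps, ReconConfig())
        center = np.array(raw.shape) // 2
        peak = np.unravel_index(np.argmax(raw.data), raw.shape)
        assert np.all(np.abs(np.array(peak) - center) <= 1)

    def test_linearity_of_backprojection(self, point_clip_vol, small_geom):
        ps = dt.acquire_arc(point_clip_vol, dt.ArcSpec(305.0, 6.0, 2.0), small_geom,
                            noise_sigma=0.0)
        cfg = ReconConfig()
        raw1 = backproject(ps, cfg).data
        scaled = ProjectionSet(
            projections=[Projection(pixels=2.5 * p.pixels, gantry_angle=p.gantry_angle,
                                    geom=small_geom) for p in ps.projections],
            arc=ps.arc, geom=small_geom)
        raw2 = backproject(scaled, cfg).data
        assert np.allclose(raw2, 2.5 * raw1, rtol=1e-6, atol=1e-12)

    def test_off_detector_voxels_flagged_not_zero_filled(self, point_clip_vol):
        # a detector too small to cover the reconstruction footprint: corner
        # voxels project off-detector in every projection -> value 0 and
        # coverage flag cleared; central voxels remain fully covered
        tiny = dt.AcquisitionGeometry(detector_size=(40.0, 40.0),
                                      detector_pixels=(40, 40))
        ps = dt.acquire_arc(point_clip_vol, dt.ArcSpec(305.0, 4.0, 2.0), tiny,
                            noise_sigma=0.0)
        raw = backproject(ps, ReconConfig())
        assert raw.coverage is not None
        assert not raw.coverage[0, 0, 0]
        assert raw.data[0, 0, 0] == 0.0
        c = tuple(np.array(raw.shape) // 2)
        assert raw.coverage[c]

    def test_single_projection_rejected(self, small_geom):
        arc = dt.ArcSpec(0.0, 1.0, 1.0)
        ps = ProjectionSet(
            projections=[Projection(pixels=np.zeros(small_geom.detector_pixels),
                                    gantry_angle=0.0, geom=small_geom)],
            arc=arc, geom=small_geom)
        with pytest.raises(ValueError, match="at least 2"):
            backproject(ps, ReconConfig())


class TestDeblur:
    def _impulse_stack(self, small_geom):
        """Synthetic raw stack with two in-focus impulses in different planes."""
        cfg = ReconConfig(slice_spacing=3.0)
        data = np.zeros((41, 41, 51))
        # plane 25 (center): in-focus impulse; plane 15: second impulse whose
        # leakage smears along u in other planes (crude tomosynthesis smear)
        for j in range(51):
            spread = abs(j - 25)
            data[20 - spread // 2: 20 + spread // 2 + 1, 20, j] += 1.0 / (1 + spread)
            spread2 = abs(j - 15)
            data[10 - spread2 // 2: 10 + spread2 // 2 + 1, 20, j] += 1.0 / (1 + spread2)
        frame = beam_frame(305.0)
        return dt.DTSVolume(
            data=data, slice_spacing=3.0, in_plane_pixel=1.0, frame=frame,
            arc=dt.ArcSpec(305.0, 10.0), geom=small_geom, kind="raw"), cfg

    def test_window_of_one_slice_is_identity(self, small_geom):
        stack, _ = self._impulse_stack(small_geom)
        cfg = ReconConfig(slice_spacing=3.0, deblur_fraction=1.0 / 51.0)
        out = deblur(stack, cfg)
        lo = (51 - out.shape[2]) // 2
        assert np.allclose(out.data, stack.data[:, :, lo: lo + out.shape[2]])

    def test_out_of_plane_feature_suppressed_by_half(self, small_geom):
        stack, cfg = self._impulse_stack(small_geom)
        none = deblur(stack, ReconConfig(slice_spacing=3.0, deblur_fraction=1.0 / 51.0))
        full = deblur(stack, ReconConfig(slice_spacing=3.0, deblur_fraction=1.0))
        k = none.shape[2] // 2  # central slice = in-focus plane of impulse A
        # impulse B lives in raw plane 15 -> leaks into the central slice at u=10
        leak_before = none.data[10, 20, k]
        leak_after = full.data[10, 20, k]
        assert leak_after <= 0.5 * leak_before

    def test_deblurring_lowers_background_variance_vs_raw(self, rect_vol, small_geom):
        # subtracting the out-of-plane estimate flattens the background of
        # the in-focus slice relative to the plain shift-and-add stack
        ps = dt.acquire_arc(rect_vol, dt.ArcSpec(305.0, 10.0), small_geom,
                            noise_sigma=0.0)
        raw = backproject(ps, ReconConfig())
        full = deblur(raw, ReconConfig(deblur_fraction=1.0))
        k_raw = raw.shape[2] // 2
        k = full.shape[2] // 2
        u, v, _ = full.axis_coords()
        bg = (u[:, None] ** 2 + v[None, :] ** 2) >= 24.0**2
        assert full.data[bg, k].var() < raw.data[bg, k_raw].var()


class TestArcLengthBehavior:
    @pytest.fixture(scope="class")
    def stacks_by_arc_length(self, point_clip_vol, small_geom):
        out = {}
        for L in (3.0, 5.0, 8.0, 10.0, 15.0):
            ps = dt.acquire_arc(point_clip_vol, dt.ArcSpec(305.0, L), small_geom,
                                noise_sigma=0.0)
            out[L] = backproject(ps, ReconConfig())
        return out

    def test_depth_fwhm_monotone_in_arc_length(self, stacks_by_arc_length):
        fwhm = {
            L: _fwhm(_depth_profile(raw), raw.slice_spacing)
            for L, raw in stacks_by_arc_length.items()
        }
        widths = [fwhm[L] for L in (3.0, 5.0, 8.0, 10.0, 15.0)]
        assert all(a >= b for a, b in zip(widths, widths[1:]))
        assert fwhm[3.0] > fwhm[15.0]  # strictly larger at the smallest arc

    def test_background_noise_monotone_in_arc_length(self, point_clip_vol, small_geom):
        # isolate the propagated projection noise as (noisy - noise-free)
        # reconstruction; its std must not increase with arc length because
        # longer arcs average more projections
        stds = []
        for L in (3.0, 5.0, 8.0, 10.0, 15.0):
            clean = dt.acquire_arc(point_clip_vol, dt.ArcSpec(305.0, L), small_geom,
                                   noise_sigma=0.0)
            noisy = dt.acquire_arc(point_clip_vol, dt.ArcSpec(305.0, L), small_geom,
                                   noise_sigma=0.02, seed=11)
            d0 = dt.reconstruct_treatment_dts(clean, ReconConfig())
            d1 = dt.reconstruct_treatment_dts(noisy, ReconConfig())
            stds.append((d1.data - d0.data).std())
        assert all(a >= b for a, b in zip(stds, stds[1:]))
        assert stds[0] > stds[-1]


class TestResliceCT:
    def test_vertical_beam_is_axis_permutation(self):
        spec = dt.PhantomSpec(body_size=(80, 80, 70), clips=(
            dt.ClipSpec(center=(5.0, -7.0, 3.0), axis=(1, 0, 0), length=4.0,
                        diameter=2.0, hu=1500.0),))
        vol = dt.build_phantom(spec)
        cfg = ReconConfig(initial_depth=40.0, final_volume=(40.0, 40.0, 20.0))
        res = reslice_ct(vol, beam_frame(0.0), cfg, pad=5.0)
        # at theta_c=0: u=(-1,0,0), v=(0,1,0), w=(0,0,-1) -> value at beam
        # coords (u,v,w) equals the CT at room (-u, v, -w); both grids are
        # integer aligned so the resampling is exact
        q = np.array([6.0, -7.0, 1.0])
        p_room = -q[0] * np.array([1.0, 0, 0]) + q[1] * np.array([0, 1.0, 0]) - q[2] * np.array([0, 0, 1.0])
        i_res = np.rint(res.world_to_index(p_room)[0]).astype(int)
        i_ct = np.rint(vol.world_to_index(p_room)[0]).astype(int)
        assert res.voxels[tuple(i_res)] == pytest.approx(vol.voxels[tuple(i_ct)], abs=1e-9)

    def test_clip_centroid_preserved(self):
        clip = dt.ClipSpec(center=(4.0, 6.0, -3.0), axis=(0, 1, 0), length=4.0,
                           diameter=2.0, hu=1500.0)
        spec = dt.PhantomSpec(body_size=(80, 80, 70), clips=(clip,))
        vol = dt.build_phantom(spec)
        frame = beam_frame(305.0)
        cfg = ReconConfig(initial_depth=60.0, final_volume=(50.0, 50.0, 30.0))
        res = reslice_ct(vol, frame, cfg, pad=10.0)
        thresh = 400.0
        idx = np.argwhere(res.voxels > thresh)
        wts = res.voxels[res.voxels > thresh]
        com = (idx * wts[:, None]).sum(axis=0) / wts.sum()
        centroid_room = res.index_to_world(com)[0]
        assert np.allclose(centroid_room, clip.center, atol=0.5)

    def test_rotation_roundtrip_within_interpolation(self):
        spec = dt.PhantomSpec(body_size=(80, 80, 70), clips=(
            dt.ClipSpec(center=(0.0, 0.0, 0.0), axis=(0, 1, 0), length=6.0,
                        diameter=3.0, hu=1000.0),))
        vol = dt.build_phantom(spec)
        cfg = ReconConfig(initial_depth=40.0, final_volume=(40.0, 40.0, 20.0))
        res = reslice_ct(vol, beam_frame(305.0), cfg, pad=10.0)
        back = reslice_ct(res, beam_frame(0.0), ReconConfig(
            initial_depth=20.0, final_volume=(20.0, 20.0, 10.0)), pad=2.0)
        # compare against direct reslice of the original at theta 0
        direct = reslice_ct(vol, beam_frame(0.0), ReconConfig(
            initial_depth=20.0, final_volume=(20.0, 20.0, 10.0)), pad=2.0)
        # interpolation error concentrates at the 1000-HU clip boundary;
        # smooth regions must agree closely
        err_smooth = np.abs(back.voxels - direct.voxels)[direct.voxels < 100]
        assert np.percentile(err_smooth, 95) < 60.0
        assert np.median(np.abs(back.voxels - direct.voxels)) < 10.0

    def test_volume_exiting_ct_is_reported(self):
        spec = dt.PhantomSpec(body_size=(40, 40, 30), clips=())
        vol = dt.build_phantom(spec)
        with pytest.raises(ValueError, match="exits the CT"):
            reslice_ct(vol, beam_frame(305.0), ReconConfig())  # 150 mm depth >> CT


class TestReferenceDTS:
    def test_reference_volume_spans_default_extents(self, point_clip_vol, small_geom):
        ref = dt.reconstruct_reference_dts(point_clip_vol, dt.ArcSpec(305.0, 10.0),
                                           small_geom)
        assert ref.shape[2] == 11  # 33 mm at 3 mm spacing
        assert ref.kind == "reference"

    def test_uniform_ct_gives_structureless_slices(self, small_geom):
        spec = dt.PhantomSpec(body_size=(120, 120, 100), clips=())
        vol = dt.build_phantom(spec, (2.0, 2.0, 2.0))
        ref = dt.reconstruct_reference_dts(vol, dt.ArcSpec(0.0, 10.0), small_geom)
        # no structure: central region variation at the interpolation /
        # beam-divergence level relative to the raw line-integral scale
        central = ref.data[10:-10, 10:-10, :]
        assert np.ptp(central) < 1e-3 * 0.02 * 100  # << any clip signal

    def test_reference_correlates_with_treatment_at_zero_offset(self, rect_vol, small_geom):
        arc = dt.ArcSpec(305.0, 10.0)
        ps = dt.acquire_arc(rect_vol, arc, small_geom, noise_sigma=0.0)
        trt = dt.reconstruct_treatment_dts(ps)
        ref = dt.reconstruct_reference_dts(rect_vol, arc, small_geom)
        a = trt.data[:, :, trt.shape[2] // 2]
        b = ref.data[:, :, ref.shape[2] // 2]
        a = a - a.mean()
        b = b - b.mean()
        ncc = float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))
        assert ncc > 0.9
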