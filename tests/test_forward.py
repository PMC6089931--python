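"""Forward model: projection, Fresnel propagation, detector and artefacts."""

import math

import numpy as np
import pytest
from scipy import ndimage, optimize

import phasetomo as pt
from phasetomo.forward import (apply_detector, apply_distortion,
                               bake_ring_seeds, inject_zingers, project,
                               transmit_and_propagate)


def _uniform_disc_phantom(g=128, radius=40.0, value=1e-7):
    dy, dx = np.mgrid[0:g, 0:g] - (g - 1) / 2.0
    disc = (np.hypot(dy, dx) <= radius).astype(float) * value
    return pt.Phantom(disc, disc, np.zeros((g, g), dtype=np.uint8),
                      voxel_um=1.0)


class TestProject:
    def test_central_ray_equals_chord(self):
        ph = _uniform_disc_phantom(g=128, radius=40.0, value=1e-7)
        d, _ = project(ph, [0.0])
        # central ray chord = 2 * R * value, lengths in metres (voxel 1 um)
        expected = 2 * 40.0 * 1e-7 * 1e-6
        assert d[0, 0, 64] == pytest.approx(expected, rel=0.01)

    def test_zero_phantom_gives_zero_sinogram(self):
        ph = pt.Phantom(np.zeros((64, 64)), np.zeros((64, 64)),
                        np.zeros((64, 64), dtype=np.uint8), voxel_um=1.0)
        d, b = project(ph, [0.0, 45.0, 90.0])
        assert np.allclose(d, 0) and np.allclose(b, 0)

    def test_centred_disc_rotationally_invariant(self):
        # disc centred on the rotation axis (column n//2), feathered edge
        g = 128
        dy, dx = np.mgrid[0:g, 0:g]
        cov = np.clip(40.0 - np.hypot(dy - g // 2, dx - g // 2) + 0.5, 0, 1) * 1e-7
        ph = pt.Phantom(cov, cov, np.zeros((g, g), dtype=np.uint8), voxel_um=1.0)
        d, _ = project(ph, [0.0, 30.0, 77.0, 145.0])
        for k in range(1, 4):
            assert np.allclose(d[0, k], d[0, 0], atol=0.02 * d[0, 0].max())

    def test_empty_angle_list(self):
        with pytest.raises(ValueError):
            project(_uniform_disc_phantom(), [])


class TestPropagation:
    def test_contact_plane_is_beer_lambert(self, beam25):
        b_line = np.linspace(0, 5e-10, 64)
        inten = transmit_and_propagate(np.zeros(64), b_line, beam25, 0.0, 1.625)
        expected = np.exp(-4 * math.pi * b_line / beam25.wavelength_m)
        assert np.allclose(inten, expected, rtol=1e-12)

    def test_pure_phase_object_invisible_at_contact(self, beam25):
        inten = transmit_and_propagate(np.linspace(0, 1e-9, 64), np.zeros(64),
                                       beam25, 0.0, 1.625)
        assert np.allclose(inten, 1.0)

    def test_fringe_offset_scales_as_sqrt_lambda_pd(self, beam25):
        n = 2048
        d_line = np.zeros(n)
        d_line[n // 2:] = 1e-9  # phase step edge
        offsets = []
        for pd in (40.0, 160.0, 640.0):
            inten = transmit_and_propagate(d_line, np.zeros(n), beam25, pd, 0.2)
            offsets.append(int(np.argmax(inten[n // 2: n // 2 + 400])))
        assert offsets[1] / offsets[0] == pytest.approx(2.0, rel=0.15)
        assert offsets[2] / offsets[1] == pytest.approx(2.0, rel=0.15)

    def test_fringe_contrast_of_small_feature_grows_with_pd(self, beam25):
        # a ~4 px feature stays in its near field across the whole screening
        # range, so its fringe contrast keeps growing
        n = 1024
        x = np.arange(n) - n / 2
        d_line = 1e-9 * np.exp(-x ** 2 / (2 * 2.0 ** 2))
        peaks = []
        for pd in (20.0, 40.0, 80.0, 160.0, 320.0):
            inten = transmit_and_propagate(d_line, np.zeros(n), beam25, pd, 1.625)
            peaks.append(np.ptp(inten))
        assert all(b >= a for a, b in zip(peaks, peaks[1:]))

    def test_negative_pd_rejected(self, beam25):
        with pytest.raises(ValueError):
            transmit_and_propagate(np.zeros(8), np.zeros(8), beam25, -1.0, 1.0)


class TestDetector:
    def test_flat_saturation_operating_point(self):
        frame = apply_detector(np.ones((64, 256)), rng=0)
        above_dark = frame.mean() - 100.0
        assert above_dark == pytest.approx(0.85 * 2 ** 16, rel=0.005)

    def test_beam_off_gives_dark_level(self):
        frame = apply_detector(np.zeros((32, 32)), dark_level=200.0, rng=1)
        assert frame.mean() == pytest.approx(200.0, rel=0.05)

    def test_exposure_scaling(self):
        lo = apply_detector(np.full((64, 64), 0.4), exposure_fraction=0.3, rng=2)
        hi = apply_detector(np.full((64, 64), 0.4), exposure_fraction=0.6, rng=3)
        assert (hi.mean() - 100) == pytest.approx(2 * (lo.mean() - 100), rel=0.02)

    def test_noiseless_is_exact_expectation(self):
        inten = np.full((8, 8), 0.5)
        frame = apply_detector(inten, photon_noise=False)
        assert np.allclose(frame, 100.0 + 0.5 * 0.85 * 2 ** 16)

    def test_invalid_exposure(self):
        with pytest.raises(ValueError):
            apply_detector(np.ones((4, 4)), exposure_fraction=0.0)


class TestZingers:
    def test_zero_rate_is_identity(self):
        frame = np.random.default_rng(0).poisson(1000, (32, 32)).astype(float)
        out, coords = inject_zingers(frame, 0)
        assert np.array_equal(out, frame) and coords == []

    def test_exact_streak_count(self):
        frame = np.zeros((64, 64))
        _, coords = inject_zingers(frame, 20, rng=4)
        assert len(coords) == 20

    def test_injected_pixels_exceed_local_median(self):
        rng = np.random.default_rng(5)
        frame = rng.poisson(50000, (128, 128)).astype(float)
        out, coords = inject_zingers(frame, 15, (5000.0, 30000.0), rng=rng)
        med = ndimage.median_filter(out, size=3)
        for streak in coords:
            assert any(out[y, x] - med[y, x] >= 4000.0 for (y, x) in streak)


class TestDistortion:
    def test_identity_model(self):
        frame = np.random.default_rng(0).normal(size=(64, 64))
        model = pt.DistortionModel((31.5, 31.5), 0.0, 0.0)
        assert np.array_equal(apply_distortion(frame, model), frame)

    def test_dot_grid_displacement_matches_radial_model(self):
        # independent oracle: solve r_u = r_d (1 + k1 r_d^2 + k2 r_d^4) for
        # each dot with a scalar root finder and compare with the centroid
        # of the imaged dot
        g = 256
        k1, k2 = 2e-6, 1e-12
        c = (g - 1) / 2.0
        frame = np.zeros((g, g))
        dots = [(64, 64), (64, 192), (192, 64), (128, 200), (40, 128)]
        yy, xx = np.mgrid[0:g, 0:g]
        for (dy0, dx0) in dots:
            frame += np.exp(-(((yy - dy0) ** 2 + (xx - dx0) ** 2) / (2 * 2.0 ** 2)))
        model = pt.DistortionModel((c, c), k1, k2)
        warped = apply_distortion(frame, model)
        for (dy0, dx0) in dots:
            r_u = math.hypot(dy0 - c, dx0 - c)
            r_d = optimize.brentq(
                lambda r: r * (1 + k1 * r * r + k2 * r ** 4) - r_u, 0, r_u + 1)
            exp_y = c + (dy0 - c) * r_d / r_u
            exp_x = c + (dx0 - c) * r_d / r_u
            win = warped[int(exp_y) - 6: int(exp_y) + 7,
                         int(exp_x) - 6: int(exp_x) + 7]
            cy, cx = ndimage.center_of_mass(win)
            got_y = int(exp_y) - 6 + cy
            got_x = int(exp_x) - 6 + cx
            assert math.hypot(got_y - exp_y, got_x - exp_x) < 0.2

    def test_displacement_grows_with_radius(self):
        g = 128
        c = (g - 1) / 2.0
        model = pt.DistortionModel((c, c), 5e-6, 0.0)
        radii = np.array([10.0, 25.0, 45.0, 60.0])
        displacement = radii * model.scale(radii) - radii
        assert np.all(np.diff(displacement) > 0)

    def test_mean_intensity_conserved(self):
        rng = np.random.default_rng(1)
        frame = ndimage.gaussian_filter(rng.normal(1.0, 0.1, (128, 128)), 3)
        model = pt.DistortionModel((70.0, 60.0), 1.2e-6, 1e-13)
        warped = apply_distortion(frame, model)
        assert warped.mean() == pytest.approx(frame.mean(), rel=0.005)


class TestRingSeeds:
    def test_zero_density_unchanged(self):
        prof = np.ones((1, 64))
        assert np.array_equal(bake_ring_seeds(prof, 0.0, rng=0), prof)

    def test_defect_pattern_is_fixed_across_frames(self):
        ph = pt.make_cord_phantom(grid_px=128, seed=3, n_vessels=4,
                                  n_somata=0, vessel_diameters_px=(3, 4))
        geom = pt.ScanGeometry(pt.BeamSpec(25), pt.DetectorSpec(128, 1, 1.625),
                               0.0, 8)
        art = pt.ArtefactConfig(photon_noise=False, flat_gradient=0.0,
                                ring_defect_density=0.1)
        pset = pt.simulate_scan(ph, geom, art, seed=6)
        # identical gain pattern in every frame: the per-column ratio to the
        # defect-free simulation is angle-independent
        clean = pt.simulate_scan(ph, geom, pt.ArtefactConfig(
            photon_noise=False, flat_gradient=0.0), seed=6)
        ratio = (pset.frames - 100.0) / (clean.frames - 100.0)
        assert np.allclose(ratio, ratio[0], atol=1e-9)


class TestSimulateScan:
    def test_frame_count_includes_check_projection(self, cord_phantom):
        geom = pt.ScanGeometry(pt.BeamSpec(25), pt.DetectorSpec(256, 1, 1.625),
                               0.0, 16, extra_check_projection=True)
        pset = pt.simulate_scan(cord_phantom, geom, seed=0)
        assert pset.n_frames == 17

    def test_determinism(self, cord_phantom):
        geom = pt.ScanGeometry(pt.BeamSpec(25), pt.DetectorSpec(256, 1, 1.625),
                               20.0, 8)
        a = pt.simulate_scan(cord_phantom, geom, pt.ArtefactConfig(zinger_rate=5),
                             seed=12)
        b = pt.simulate_scan(cord_phantom, geom, pt.ArtefactConfig(zinger_rate=5),
                             seed=12)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.flats, b.flats)
        assert np.array_equal(a.darks, b.darks)

    def test_beer_lambert_oracle(self, clean_scan, cord_phantom, beam25):
        # noiseless, artefact-free, PD = 0: -ln(T) equals 4*pi*B/lambda
        _, b_lines = project(cord_phantom, clean_scan.geometry.angles_deg)
        flat = clean_scan.flats.mean(axis=0)
        dark = clean_scan.darks.mean(axis=0)
        trans = (clean_scan.frames[:, 0, :] - dark[0]) / (flat[0] - dark[0])
        expected = 4 * math.pi * b_lines[0] / beam25.wavelength_m
        assert np.allclose(-np.log(np.clip(trans, 1e-9, None)), expected,
                           atol=0.02 * expected.max())

    def test_transparent_phantom_reproduces_flat(self):
        g = 64
        empty = pt.Phantom(np.zeros((g, g)), np.zeros((g, g)),
                           np.zeros((g, g), dtype=np.uint8), voxel_um=1.0)
        geom = pt.ScanGeometry(pt.BeamSpec(25), pt.DetectorSpec(g, 1, 1.0),
                               0.0, 4)
        art = pt.ArtefactConfig(photon_noise=False)
        pset = pt.simulate_scan(empty, geom, art, seed=0)
        assert np.allclose(pset.frames, pset.flats.mean(axis=0), rtol=1e-12)

    def test_grid_detector_mismatch(self, cord_phantom):
        geom = pt.ScanGeometry(pt.BeamSpec(25), pt.DetectorSpec(128, 1, 1.625),
                               0.0, 4)
        with pytest.raises(ValueError):
            pt.simulate_scan(cord_phantom, geom, seed=0)
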