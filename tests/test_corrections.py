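"""Correction chain: zingers, flat/dark, distortion, rings."""

import numpy as np
import pytest
from scipy import ndimage

import phasetomo as pt
from phasetomo.corrections import (DegenerateInputError, CorrectionReport,
                                   estimate_distortion_center,
                                   flat_dark_correct, remove_zingers,
                                   suppress_rings, undistort, correct_scan)
from phasetomo.forward import apply_distortion, inject_zingers


class TestRemoveZingers:
    def test_low_false_positive_rate_on_clean_frame(self):
        frame = np.random.default_rng(0).poisson(50000, (256, 256)).astype(float)
        _, n = remove_zingers(frame, 3, 8.0)
        assert n / frame.size < 1e-4

    def test_recovers_injected_streaks(self):
        rng = np.random.default_rng(1)
        frame = rng.poisson(50000, (128, 256)).astype(float)
        dirty, coords = inject_zingers(frame, 20, (5000.0, 30000.0), rng=rng)
        cleaned, _ = remove_zingers(dirty, 3, 8.0)
        touched = sum(
            any(cleaned[y, x] != dirty[y, x] for (y, x) in streak)
            for streak in coords
        )
        assert touched >= 19

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        frame = rng.poisson(50000, (128, 128)).astype(float)
        dirty, _ = inject_zingers(frame, 20, rng=rng)
        once, _ = remove_zingers(dirty)
        twice, n2 = remove_zingers(once)
        assert n2 / frame.size < 1e-3

    def test_even_neighbourhood_rejected(self):
        with pytest.raises(ValueError):
            remove_zingers(np.zeros((8, 8)), neighbourhood_px=4)


class TestFlatDark:
    def test_algebraic_identities(self):
        flat = np.full((4, 8), 1000.0)
        dark = np.full((4, 8), 100.0)
        assert np.allclose(flat_dark_correct(flat, flat, dark), 1.0)
        assert np.allclose(flat_dark_correct(dark, flat, dark), 1e-6)
        mixed = dark + 0.3 * (flat - dark)
        assert np.allclose(flat_dark_correct(mixed, flat, dark), 0.3)

    def test_transmission_of_30pct_absorber(self):
        flat = np.full((2, 2), 55000.0)
        dark = np.full((2, 2), 100.0)
        frame = dark + 0.7 * (flat - dark)
        assert np.allclose(flat_dark_correct(frame, flat, dark), 0.7)

    def test_broken_calibration_names_pixel_count(self):
        flat = np.full((4, 4), 100.0)
        dark = np.full((4, 4), 100.0)
        dark[0, :2] = 50.0
        with pytest.raises(ValueError, match="14"):
            flat_dark_correct(flat, flat, dark)


class TestUndistort:
    def test_round_trip(self):
        rng = np.random.default_rng(3)
        img = ndimage.gaussian_filter(rng.normal(size=(128, 128)), 4)
        model = pt.DistortionModel((70.0, 58.0), 1.2e-6, 1e-13)
        back = undistort(apply_distortion(img, model), model)
        core = np.s_[5:-5, 5:-5]
        assert np.max(np.abs(back[core] - img[core])) < 0.01 * np.ptp(img)

    def test_identity_model(self):
        img = np.random.default_rng(4).normal(size=(32, 32))
        model = pt.DistortionModel((15.5, 15.5), 0.0, 0.0)
        assert np.array_equal(undistort(img, model), img)

    def test_extreme_coefficients_raise(self):
        model = pt.DistortionModel((15.5, 15.5), -3e-3, 0.0)
        with pytest.raises(RuntimeError):
            undistort(np.ones((32, 32)), model)


@pytest.fixture(scope="module")
def distorted_pair():
    """Noiseless 0/180-degree frame pair from a 3-D cord scan."""
    ph = pt.make_cord_phantom(grid_px=256, seed=2, n_somata=4, n_slices=96)
    c_true = ((256 - 1) / 2.0 + 15, (96 - 1) / 2.0 - 10)
    k1, k2 = 1.2e-6, 1e-12
    dist = pt.DistortionModel(c_true, k1, k2)
    geom = pt.ScanGeometry(pt.BeamSpec(25), pt.DetectorSpec(256, 96, 1.625),
                           0.0, 2, extra_check_projection=True)
    art = pt.ArtefactConfig(distortion=dist, photon_noise=False)
    pset = pt.simulate_scan(ph, geom, art, seed=11)
    flat = pset.flats.mean(0)
    dark = pset.darks.mean(0)
    t0 = (pset.frames[0] - dark) / (flat - dark)
    t180 = (pset.frames[-1] - dark) / (flat - dark)
    return t0, t180, c_true, k1, k2


class TestDistortionCenter:
    def test_zero_distortion_tie_break_returns_frame_center(self):
        rng = np.random.default_rng(5)
        frame = ndimage.gaussian_filter(rng.normal(size=(64, 128)), 2)
        (cx, cy), _ = estimate_distortion_center(frame, frame[:, ::-1], 0.0, 0.0)
        assert (cx, cy) == (63.5, 31.5)

    def test_featureless_frames_rejected(self):
        with pytest.raises(DegenerateInputError):
            estimate_distortion_center(np.ones((32, 32)), np.ones((32, 32)),
                                       1e-6, 0.0)

    def test_x_center_recovered(self, distorted_pair):
        t0, t180, c_true, k1, k2 = distorted_pair
        (cx, cy), _ = estimate_distortion_center(t0, t180, k1, k2)
        assert abs(cx - c_true[0]) <= 2.0

    def test_score_landscape_minimum_near_truth(self, distorted_pair):
        from phasetomo.corrections import _align_and_score
        t0, t180, c_true, k1, k2 = distorted_pair

        def score(cx, cy):
            m = pt.DistortionModel((cx, cy), k1, k2)
            return _align_and_score(undistort(t0, m), undistort(t180, m)[:, ::-1])

        s_true = score(*c_true)
        assert s_true <= score(c_true[0] + 50, c_true[1])
        assert s_true <= score(c_true[0] - 50, c_true[1])


class TestSuppressRings:
    def test_constant_column_offset_removed(self):
        rng = np.random.default_rng(6)
        sino = ndimage.gaussian_filter(rng.normal(1.0, 0.1, (90, 128)), 5)
        spiked = sino.copy()
        spiked[:, 60] += 0.5
        out = suppress_rings(spiked, 31)
        residual = out[:, 60].mean() - sino[:, 60].mean()
        assert abs(residual) < 0.05 * 0.5

    def test_ring_free_sinogram_barely_changed(self):
        rng = np.random.default_rng(7)
        sino = ndimage.gaussian_filter(rng.normal(1.0, 0.2, (90, 128)), 6)
        out = suppress_rings(sino, 31)
        assert np.sqrt(np.mean((out - sino) ** 2)) < 0.01 * np.sqrt(np.mean(sino ** 2))

    def test_global_mean_preserved(self):
        rng = np.random.default_rng(8)
        sino = rng.normal(5.0, 1.0, (45, 64))
        out = suppress_rings(sino, 9)
        assert out.mean() == pytest.approx(sino.mean(), rel=1e-12)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            suppress_rings(np.ones((10, 32)), 33)

    def test_reconstruction_ring_power_reduced(self, cord_phantom):
        from skimage.transform import warp_polar

        def ring_power(sl):
            polar = warp_polar(sl, radius=sl.shape[0] // 2 - 4)
            prof = polar.mean(axis=0)
            smooth = ndimage.median_filter(prof, size=9, mode="nearest")
            return float(np.var(prof - smooth))

        geom = pt.ScanGeometry(pt.BeamSpec(25), pt.DetectorSpec(256, 1, 1.625),
                               0.0, 360)
        art = pt.ArtefactConfig(ring_defect_density=0.05)
        pset = pt.simulate_scan(cord_phantom, geom, art, seed=9)
        raw = pt.reconstruct_scan(pset, suppress_rings_flag=False).slices[0]
        sup = pt.reconstruct_scan(pset, suppress_rings_flag=True).slices[0]
        assert ring_power(raw) / ring_power(sup) >= 5.0


class TestChain:
    def test_stage_order_recorded(self, noisy_scan):
        _, report = correct_scan(noisy_scan)
        assert report.stages == ("zingers", "flat_dark")

    def test_negative_counts_rejected_in_report(self):
        with pytest.raises(ValueError):
            CorrectionReport(zingers_removed=[-1])

    def test_full_chain_improves_psnr_against_artefact_free(self, cord_phantom):
        from phasetomo.quality import ROI, psnr
        geom = pt.ScanGeometry(pt.BeamSpec(25), pt.DetectorSpec(256, 1, 1.625),
                               0.0, 360)
        dist = pt.DistortionModel(((256 - 1) / 2.0 + 8, 0.0), 1.0e-6, 0.0)
        art = pt.ArtefactConfig(zinger_rate=20, ring_defect_density=0.03,
                                distortion=dist)
        dirty = pt.simulate_scan(cord_phantom, geom, art, seed=9)
        clean = pt.simulate_scan(cord_phantom, geom, pt.ArtefactConfig(), seed=9)
        ref = pt.reconstruct_scan(clean, suppress_rings_flag=False).slices[0]
        corrected = pt.reconstruct_scan(dirty).slices[0]
        uncorrected = pt.reconstruct_scan(dirty, corrections=False,
                                          suppress_rings_flag=False,
                                          distortion=None).slices[0]
        roi = ROI.centered((256, 256), 160)
        assert psnr(roi.extract(ref), roi.extract(corrected)) > \
            psnr(roi.extract(ref), roi.extract(uncorrected))
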