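"""Vesicle contour detection and sub-pixel refinement on synthetic images."""

import numpy as np
import pytest

from memcurv import (
    detect_contour,
    fit_circle,
    refine_overlapping_pair,
    refine_subpixel,
    render_vesicle_image,
    track_vesicle,
)
from memcurv.errors import SingularFitError


class TestDetectContour:
    def test_noiseless_ring_maxima(self):
        img, truth = render_vesicle_image(R=50.0, centre=(128.0, 128.0), snr=np.inf)
        det = detect_contour(img, (128.0, 128.0), n_rays=90, smooth_sigma=0)
        ok = det[det["ok"]]
        assert len(ok) >= 85
        assert np.all(np.abs(ok["radius"] - 50.0) <= 0.5 + 1e-9)

    def test_uniform_image_flags_all_rays(self):
        img = np.ones((64, 64))
        det = detect_contour(img, (32.0, 32.0), n_rays=16, smooth_sigma=0)
        assert not det["ok"].any()

    def test_offset_guess_still_finds_perimeter(self):
        img, truth = render_vesicle_image(R=50.0, centre=(128.0, 128.0), snr=np.inf)
        guess = (131.0, 128.0)
        det = detect_contour(img, guess, n_rays=90, smooth_sigma=0)
        ok = det[det["ok"]]
        # per-ray local perimeter radius from the offset guess, exact geometry
        dx = 128.0 - 131.0
        for _, row in ok.iterrows():
            ca, sa = np.cos(row["angle"]), np.sin(row["angle"])
            # distance from guess to circle along this ray
            b = dx * ca
            r_true = b + np.sqrt(b ** 2 + 50.0 ** 2 - dx ** 2)
            assert abs(row["radius_refined"] - r_true) < 1.0


class TestSubpixel:
    def test_symmetric_peak_on_sample(self):
        x = np.arange(101, dtype=float)
        prof = -(x - 50.0) ** 2
        pos, ok = refine_subpixel(prof, 50)
        assert ok
        assert pos == pytest.approx(50.0, abs=1e-9)

    def test_gaussian_peak_off_sample(self):
        x = np.arange(101, dtype=float)
        prof = np.exp(-0.5 * ((x - 50.3) / 3.0) ** 2)
        pos, ok = refine_subpixel(prof, int(np.argmax(prof)))
        assert ok
        assert pos == pytest.approx(50.3, abs=0.05)

    def test_linear_ramp_flags_failure(self):
        prof = np.arange(20, dtype=float)
        pos, ok = refine_subpixel(prof, 10)
        assert not ok
        assert pos == 10.0


class TestFitCircle:
    def test_three_points_exact(self):
        t = np.array([0.1, 1.7, 4.0])
        pts = np.column_stack([5 + 3 * np.cos(t), -2 + 3 * np.sin(t)])
        fit = fit_circle(pts)
        assert fit.centre[0] == pytest.approx(5.0)
        assert fit.centre[1] == pytest.approx(-2.0)
        assert fit.radius == pytest.approx(3.0)
        assert fit.residual_rms < 1e-9

    def test_noisy_circle_radius_unbiased(self):
        t = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        radii = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = np.column_stack([50 * np.cos(t), 50 * np.sin(t)])
            pts += rng.normal(0, 0.3, pts.shape)
            radii.append(fit_circle(pts).radius)
        assert np.mean(radii) == pytest.approx(50.0, abs=0.05)

    def test_collinear_raises(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(SingularFitError):
            fit_circle(pts)

    def test_identical_points_raise(self):
        with pytest.raises(SingularFitError):
            fit_circle(np.ones((5, 2)))


class TestFullPipeline:
    @pytest.mark.parametrize("snr", [5.0, 10.0])
    def test_centre_and_radius_accuracy(self, snr):
        """Detect -> refine -> fit achieves < 0.1 px over 50 noise seeds."""
        errs_c, errs_r = [], []
        for seed in range(50):
            img, truth = render_vesicle_image(
                R=50.0, centre=(127.4, 129.1), snr=snr, seed=seed)
            fit = track_vesicle(img, (126.0, 128.0))
            errs_c.append(np.hypot(fit.centre[0] - 127.4, fit.centre[1] - 129.1))
            errs_r.append(abs(fit.radius - 50.0))
        assert np.mean(errs_c) < 0.1
        assert np.mean(errs_r) < 0.1

    def test_rotated_image_rotates_fit(self):
        img, _ = render_vesicle_image(R=40.0, centre=(100.0, 120.0), snr=np.inf,
                                      shape=(256, 256))
        fit = track_vesicle(img, (100.0, 120.0))
        img90 = np.rot90(img)  # (row, col) -> (col, n_rows-1-row)
        ny = img.shape[0]
        fit90 = track_vesicle(img90, (120.0, ny - 1 - 100.0))
        assert fit90.centre[0] == pytest.approx(fit.centre[1], abs=0.05)
        assert fit90.centre[1] == pytest.approx(ny - 1 - fit.centre[0], abs=0.05)


class TestOverlappingPair:
    def test_well_separated_recovery(self):
        # particles near the vesicle centre, far from the bright ring
        img, truth = render_vesicle_image(
            R=100.0, centre=(128.0, 128.0), snr=np.inf, shape=(256, 256),
            particle_positions=[(120.0, 128.0), (135.0, 128.0)], particle_sigma=2.0)
        patch = img[108:148, 100:156]
        centres, ok = refine_overlapping_pair(
            patch, ((19.0, 21.0), (36.0, 19.0)), sigma_guess=2.0)
        assert ok
        got = centres + np.array([100.0, 108.0])
        assert np.allclose(sorted(got[:, 0]), [120.0, 135.0], atol=0.02)
        assert np.allclose(got[:, 1], 128.0, atol=0.02)

    def test_overlapping_separation_unbiased(self):
        # two spots 1.2 sigma apart: centroid methods bias them together,
        # the joint fit must not (mean error < 0.05 px over 100 seeds)
        sig = 2.0
        sep_true = 1.2 * sig
        seps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y, x = np.mgrid[0:40, 0:40]
            x1, x2 = 20 - sep_true / 2, 20 + sep_true / 2
            img = (np.exp(-((x - x1) ** 2 + (y - 20.0) ** 2) / (2 * sig ** 2))
                   + np.exp(-((x - x2) ** 2 + (y - 20.0) ** 2) / (2 * sig ** 2)))
            img += rng.normal(0, 0.01, img.shape)
            centres, ok = refine_overlapping_pair(
                img, ((x1 + 0.4, 20.0), (x2 - 0.4, 20.0)), sigma_guess=sig)
            if ok:
                seps.append(np.hypot(*(centres[1] - centres[0])))
        assert len(seps) > 90
        assert np.mean(seps) == pytest.approx(sep_true, abs=0.05)

    def test_single_spot_fed_as_pair_is_flagged(self):
        y, x = np.mgrid[0:40, 0:40]
        img = np.exp(-((x - 20.0) ** 2 + (y - 20.0) ** 2) / (2 * 2.0 ** 2))
        centres, ok = refine_overlapping_pair(img, ((19.0, 20.0), (21.0, 20.0)))
        assert not ok
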