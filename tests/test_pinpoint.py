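import numpy as np
import pytest

from vfinger import (NoPointError, PhantomSpec, Stroke, Volume, make_phantom,
                     ppa_c, ppa_n, ppa_single, project_point, screen_to_ray)
from vfinger.pinpoint import _mean_shift_peak, read_markers, write_markers


class TestMeanShift:
    positions = np.arange(40, dtype=float)

    def test_single_nonzero_sample(self):
        prof = np.zeros(40)
        prof[7] = 5.0
        idx, confident = _mean_shift_peak(self.positions, prof)
        assert idx == 7 and confident

    def test_gaussian_profile_converges_to_center(self):
        prof = np.exp(-((self.positions - 12.0) ** 2) / (2 * 2.0**2))
        idx, _ = _mean_shift_peak(self.positions, prof)
        assert abs(idx - 12.0) <= 1.0

    def test_two_peaks_converges_to_dominant(self):
        prof = (100 * np.exp(-((self.positions - 10) ** 2) / 8)
                + 50 * np.exp(-((self.positions - 30) ** 2) / 8))
        idx, _ = _mean_shift_peak(self.positions, prof)
        assert abs(idx - 10) <= 1

    def test_flat_profile_not_confident(self):
        idx, confident = _mean_shift_peak(self.positions, np.full(40, 3.0))
        assert not confident


def test_ppa_single_on_blob_ray(blob_phantom, cam_z):
    ray = screen_to_ray((16, 16), cam_z, blob_phantom.volume)
    res = ppa_single(ray, 0)
    assert np.linalg.norm(res.location - blob_phantom.center) < 1.0
    assert res.confident


def test_ppa_single_affine_intensity_invariance(blob_phantom, cam_z):
    ray = screen_to_ray((16, 16), cam_z, blob_phantom.volume)
    res = ppa_single(ray, 0)
    scaled = type(ray)(ray.origin, ray.direction, ray.samples,
                       2.5 * ray.intensities + 11.0)
    res2 = ppa_single(scaled, 0)
    np.testing.assert_allclose(res.location, res2.location)


def test_ppa_single_empty_ray_raises(blob_phantom, cam_z):
    ray = screen_to_ray((500, 500), cam_z, blob_phantom.volume)
    with pytest.raises(NoPointError):
        ppa_single(ray, 0)


class TestPpaC:
    def _two_channel(self):
        # ch0 blob at z=10 intensity 200; ch1 blob at z=22 intensity 150
        data = np.zeros((32, 32, 32, 2), dtype=np.uint8)
        data[16, 16, 10, 0] = 200
        data[16, 16, 22, 1] = 150
        return Volume(data)

    def test_single_channel_reduces_to_ppa_single(self, blob_phantom, cam_z):
        ray = screen_to_ray((16, 16), cam_z, blob_phantom.volume)
        a = ppa_single(ray, 0)
        b = ppa_c((16, 16), cam_z, blob_phantom.volume)
        np.testing.assert_allclose(a.location, b.location)

    def test_brightest_channel_wins(self, cam_z):
        res = ppa_c((16, 16), cam_z, self._two_channel())
        assert res.channel == 0 and res.intensity == 200

    def test_tie_goes_to_lowest_channel(self, cam_z):
        vol = self._two_channel()
        vol.data[16, 16, 22, 1] = 200
        assert ppa_c((16, 16), cam_z, vol).channel == 0

    def test_user_fixed_channel(self, cam_z):
        res = ppa_c((16, 16), cam_z, self._two_channel(), channel=1)
        assert res.channel == 1 and res.location[2] == pytest.approx(22, abs=1)

    def test_miss_raises(self, blob_phantom, cam_z):
        with pytest.raises(NoPointError):
            ppa_c((400, 400), cam_z, blob_phantom.volume)


class TestPpaN:
    def test_single_point_falls_back_to_ppa_c(self, blob_phantom, cam_z):
        a = ppa_n(Stroke([[16, 16]]), cam_z, blob_phantom.volume)
        b = ppa_c((16, 16), cam_z, blob_phantom.volume)
        np.testing.assert_allclose(a.location, b.location)

    def test_clean_tube_equals_first_curve_knot(self, tube_phantom, cam_z):
        from vfinger import cda2, simulate_stroke

        stroke = simulate_stroke(tube_phantom.centerline, cam_z, 5, 0.0, seed=0)
        res = ppa_n(stroke, cam_z, tube_phantom.volume, presmooth_sigma=0.0)
        # dedup keeps points >= 3 px apart; the reference runs the same stroke
        pts = [stroke.points[0]]
        for p in stroke.points[1:]:
            if np.linalg.norm(p - pts[-1]) >= 3.0:
                pts.append(p)
        ref = cda2(Stroke(np.array(pts)), cam_z, tube_phantom.volume)
        np.testing.assert_allclose(res.location, ref.knots[0])

    def test_noisy_blob_monte_carlo(self, cam_z):
        spec = PhantomSpec("blob", peak=200, background=20, sigma=2.0,
                           noise_sigma=100, seed=1, params={"center": (16, 16, 16)})
        ph = make_phantom(spec, (32, 32, 32))
        rng = np.random.default_rng(1)
        hits_n = 0
        err_n = []
        err_c = []
        for _ in range(100):
            click = project_point(ph.center, cam_z) + rng.uniform(-1, 1, 2)
            micro = Stroke(np.array([click + (dx, 0) for dx in (0, 1, 2, 3, 4)]))
            rn = ppa_n(micro, cam_z, ph.volume)
            e = np.linalg.norm(rn.location - ph.center)
            err_n.append(e)
            hits_n += e <= 2.0
            try:
                rc = ppa_c(click, cam_z, ph.volume)
                err_c.append(np.linalg.norm(rc.location - ph.center))
            except NoPointError:
                err_c.append(np.inf)
        assert hits_n >= 95
        # the noise-robust variant beats the plain pinpoint on average
        assert np.mean(err_n) <= np.mean(err_c)


def test_marker_csv_roundtrip_one_based(tmp_path, blob_phantom, cam_z):
    res = ppa_c((16, 16), cam_z, blob_phantom.volume)
    path = tmp_path / "m.csv"
    write_markers([res], path, names=["soma"])
    text = path.read_text()
    assert "17.0" in text  # 1-based on disk
    back = read_markers(path)
    np.testing.assert_allclose(back[0].location, res.location)
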