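"""CT simulation: projector physics, noise model, reconstruction, phantoms."""

import numpy as np
import pytest

from oracles import aa_disk

from ldct_benchmark.sim import (Geometry, SimConfig, Sinogram, backproject, fbp,
                                forward_project, insert_noise, make_phantom, simulate_case, to_hu)
from ldct_benchmark.sim.geometry import GeometryError
from ldct_benchmark.sim.phantom import ORGAN_FOR_EXAM, ExamTypeError, PhantomConfig


@pytest.fixture(scope="module")
def disk_geometry():
    return Geometry.standard(image_size=256, fov=350.0, n_angles=512)


@pytest.fixture(scope="module")
def disk_image():
    return aa_disk(256, 350.0, radius=20.0, value=0.02)


@pytest.fixture(scope="module")
def disk_sinogram(disk_image, disk_geometry):
    return forward_project(disk_image, disk_geometry)


class TestGeometry:
    def test_detector_must_cover_diagonal(self):
        with pytest.raises(GeometryError):
            Geometry(n_detectors=100, detector_spacing=1.0, angles=np.array([0.0, 1.0]),
                     image_size=256, fov=350.0)

    def test_angles_must_increase(self):
        with pytest.raises(GeometryError):
            Geometry(n_detectors=600, detector_spacing=1.0,
                     angles=np.array([0.5, 0.5]), image_size=256, fov=350.0)


class TestForwardProject:
    def test_zero_image_gives_zero_sinogram(self, disk_geometry):
        sino = forward_project(np.zeros((256, 256)), disk_geometry)
        assert np.all(sino.data == 0.0)

    def test_central_ray_line_integral_matches_chord(self, disk_sinogram):
        # uniform disk mu=0.02/mm, radius 20 mm -> central chord integral 2*r*mu = 0.8
        assert disk_sinogram.data[0].max() == pytest.approx(0.8, rel=0.01)

    def test_rotational_symmetry_of_centered_disk(self, disk_sinogram):
        profiles = disk_sinogram.data
        dev = profiles - profiles.mean(axis=0)
        assert float(np.sqrt(np.mean(dev**2))) < 0.01  # interpolation tolerance in the bulk
        assert np.max(np.abs(dev)) < 0.1               # worst case sits on the disk edge

    def test_linearity(self, disk_geometry, rng):
        a = rng.random((256, 256)) * 0.02
        b = rng.random((256, 256)) * 0.02
        lhs = forward_project(a + b, disk_geometry).data
        rhs = forward_project(a, disk_geometry).data + forward_project(b, disk_geometry).data
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-12)

    def test_rejects_non_square(self, disk_geometry):
        with pytest.raises(GeometryError):
            forward_project(np.zeros((256, 128)), disk_geometry)

    def test_adjoint_consistency(self, rng):
        # <R x, y> == <x, R^T y> with R^T the unfiltered backprojection
        geom = Geometry.standard(image_size=32, fov=64.0, n_angles=24)
        for _ in range(5):
            x = rng.normal(size=(32, 32))
            y = rng.normal(size=(geom.n_angles, geom.n_detectors))
            lhs = float(np.sum(forward_project(x, geom).data * y))
            rhs = float(np.sum(x * backproject(Sinogram(data=y, geometry=geom))))
            assert lhs == pytest.approx(rhs, rel=1e-6)


class TestInsertNoise:
    def test_noiseless_limit_at_full_dose_huge_flux(self):
        geom = Geometry.standard(image_size=64, fov=64.0, n_angles=8)
        p = np.linspace(0.0, 5.0, geom.n_detectors)[None, :].repeat(geom.n_angles, axis=0)
        noisy = insert_noise(Sinogram(data=p, geometry=geom), 1.0, 1e12, seed=0)
        assert np.max(np.abs(noisy.data - p)) < 1e-3

    def test_variance_matches_delta_method(self):
        # var(p') ~ exp(p) / (d * I0) for p=1, d=0.25, I0=1e5
        geom = Geometry(n_detectors=100_000, detector_spacing=1.0,
                        angles=np.array([0.0]), image_size=2, fov=2.0)
        p = np.full((1, 100_000), 1.0)
        noisy = insert_noise(Sinogram(data=p, geometry=geom), 0.25, 1e5, seed=7)
        expected = np.exp(1.0) / (0.25 * 1e5)
        assert float(np.var(noisy.data)) == pytest.approx(expected, rel=0.05)

    def test_variance_scales_inversely_with_dose(self):
        geom = Geometry(n_detectors=100_000, detector_spacing=1.0,
                        angles=np.array([0.0]), image_size=2, fov=2.0)
        p = np.full((1, 100_000), 1.0)
        v10 = np.var(insert_noise(Sinogram(data=p, geometry=geom), 0.10, 1e5, seed=1).data)
        v25 = np.var(insert_noise(Sinogram(data=p, geometry=geom), 0.25, 1e5, seed=2).data)
        assert v10 / v25 == pytest.approx(2.5, rel=0.10)

    def test_photon_starved_rays_stay_finite(self):
        geom = Geometry(n_detectors=1000, detector_spacing=1.0,
                        angles=np.array([0.0]), image_size=2, fov=2.0)
        p = np.full((1, 1000), 30.0)  # mean counts << 1
        noisy = insert_noise(Sinogram(data=p, geometry=geom), 0.1, 1e4, seed=3)
        assert np.all(np.isfinite(noisy.data))

    @pytest.mark.parametrize("dose,flux", [(0.0, 1e5), (1.5, 1e5), (0.5, 0.0)])
    def test_rejects_invalid_dose_or_flux(self, dose, flux):
        geom = Geometry.standard(image_size=16, fov=16.0, n_angles=4)
        sino = Sinogram(data=np.zeros((4, geom.n_detectors)), geometry=geom)
        with pytest.raises(ValueError):
            insert_noise(sino, dose, flux, seed=0)


class TestFBP:
    def test_zero_sinogram_gives_zero_image(self, disk_geometry):
        sino = Sinogram(data=np.zeros((512, disk_geometry.n_detectors)), geometry=disk_geometry)
        assert np.all(fbp(sino) == 0.0)

    def test_disk_reconstruction_accuracy(self, disk_image, disk_sinogram):
        rec = fbp(disk_sinogram, "ramp")
        hu = to_hu(rec, 0.02)
        hu_true = to_hu(disk_image, 0.02)
        n, h = 256, 350.0 / 256
        c = (n - 1) / 2
        idx = np.arange(n)
        xx, yy = np.meshgrid((idx - c) * h, (idx - c) * h)
        inside = np.sqrt(xx**2 + yy**2) <= 20.0 - 2 * h
        rmse = np.sqrt(np.mean((hu[inside] - hu_true[inside]) ** 2))
        assert rmse < 30.0

    def test_linearity(self, disk_geometry, rng):
        a = Sinogram(data=rng.normal(size=(512, disk_geometry.n_detectors)), geometry=disk_geometry)
        b = Sinogram(data=rng.normal(size=(512, disk_geometry.n_detectors)), geometry=disk_geometry)
        ab = Sinogram(data=a.data + b.data, geometry=disk_geometry)
        lhs = fbp(ab)
        rhs = fbp(a) + fbp(b)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-12)

    def test_rmse_decreases_with_angle_count(self, disk_image):
        errors = []
        for n_angles in (64, 128, 256, 512):
            geom = Geometry.standard(image_size=256, fov=350.0, n_angles=n_angles)
            rec = fbp(forward_project(disk_image, geom), "ramp")
            errors.append(float(np.sqrt(np.mean((rec - disk_image) ** 2))))
        assert all(a > b for a, b in zip(errors, errors[1:]))

    def test_unknown_filter_rejected(self, disk_sinogram):
        with pytest.raises(ValueError):
            fbp(disk_sinogram, "shepp-logan")


class TestToHU:
    @pytest.mark.parametrize("mu,expected", [(0.02, 0.0), (0.0, -1000.0), (0.04, 1000.0)])
    def test_hounsfield_definition(self, mu, expected):
        assert to_hu(np.array([mu]), 0.02)[0] == pytest.approx(expected)

    def test_rejects_nonpositive_mu_water(self):
        with pytest.raises(ValueError):
            to_hu(np.zeros(3), 0.0)


class TestPhantom:
    CFG = PhantomConfig(image_size=96, fov=350.0, n_slices_range=(3, 4))

    def test_unknown_exam_type_rejected(self):
        with pytest.raises(ExamTypeError):
            make_phantom("pelvis", seed=0, config=self.CFG)

    def test_deterministic_from_seed(self):
        a = make_phantom("head", seed=7, config=self.CFG)
        b = make_phantom("head", seed=7, config=self.CFG)
        np.testing.assert_array_equal(a.attenuation_map, b.attenuation_map)
        assert a.lesion_boxes[0].box == b.lesion_boxes[0].box

    def test_lung_attenuation_tracks_config(self):
        cfg = PhantomConfig(image_size=96, fov=350.0, n_slices_range=(3, 4))
        ph = make_phantom("chest", seed=0, config=cfg)
        hu = to_hu(ph.attenuation_map, cfg.mu_water)
        # lesion voxels are brighter than lung background; exclude the lesion box
        lung = ph.organ_masks["lung"].copy()
        z0, z1, y0, y1, x0, x1 = ph.lesion_boxes[0].box
        lung[z0:z1, y0:y1, x0:x1] = False
        assert abs(float(hu[lung].mean()) - cfg.lung.hu) <= cfg.lung.jitter + 1.0

    @pytest.mark.parametrize("exam_type", ["abdomen", "head", "chest"])
    def test_lesion_boxes_inside_organ_for_many_seeds(self, exam_type):
        organ = ORGAN_FOR_EXAM[exam_type]
        for seed in range(100):
            ph = make_phantom(exam_type, seed=seed, config=self.CFG)
            for lesion in ph.lesion_boxes:
                z0, z1, y0, y1, x0, x1 = lesion.box
                assert np.all(ph.organ_masks[organ][z0:z1, y0:y1, x0:x1])

    def test_masks_inside_body(self):
        ph = make_phantom("abdomen", seed=3, config=self.CFG)
        for name, mask in ph.organ_masks.items():
            assert not np.any(mask & ~ph.organ_masks["body"]) or name == "body"


class TestSimulateCase:
    def test_bit_identical_for_same_seed(self, desk_config):
        a = simulate_case("head", seed=5, config=desk_config)
        b = simulate_case("head", seed=5, config=desk_config)
        np.testing.assert_array_equal(a.low.hu, b.low.hu)
        np.testing.assert_array_equal(a.high.hu, b.high.hu)

    def test_default_chest_dose_is_ten_percent(self, desk_config):
        assert desk_config.dose_fractions["chest"] == 0.10
        assert desk_config.dose_fractions["abdomen"] == 0.25
        assert desk_config.dose_fractions["head"] == 0.25

    def test_pair_shares_masks_and_patient(self, abdomen_pair):
        assert abdomen_pair.high.patient_id == abdomen_pair.low.patient_id
        assert abdomen_pair.high.hu.shape == abdomen_pair.low.hu.shape
        assert "liver" in abdomen_pair.organ_masks

    def test_noise_ordering_across_doses(self):
        # organ-ROI HU noise: 10% dose > 25% dose > full dose, for most seeds
        cfg = SimConfig(phantom=PhantomConfig(image_size=96, fov=350.0, n_slices_range=(1, 1)),
                        n_angles=96)
        wins = 0
        n_trials = 20
        for seed in range(n_trials):
            stds = []
            for d in (0.10, 0.25, 1.0):
                pair = simulate_case("abdomen", seed=seed, dose_fraction=d, config=cfg)
                organ = pair.organ_masks["liver"][0]
                stds.append(float(np.std(pair.low.hu[0][organ] - pair.high.hu[0][organ])))
            wins += stds[0] > stds[1] > stds[2]
        assert wins >= int(0.95 * n_trials)
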