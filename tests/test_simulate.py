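"""Hologram formation model, truth maps, and training-data distributions."""

import numpy as np
import pytest
from scipy import stats

from holomass.optics import OpticalConfig, Particle
from holomass.simulate import (
    DatasetFormatError,
    Scene,
    SceneParams,
    SequenceParams,
    aliasing_z_limit,
    read_dataset,
    render_truth_maps,
    sample_runet_scene,
    sample_wacnet_sequence,
    simulate_hologram,
    write_dataset,
)

CFG = OpticalConfig()
PITCH = CFG.pixel_pitch_um


def particle_at(px, py, z=800.0, mass=100.0, diameter=6.0):
    return Particle.from_dry_mass(px * PITCH, py * PITCH, z, diameter / 2, mass, CFG)


class TestHologramFormation:
    def test_empty_scene_is_unity(self):
        holo = simulate_hologram(Scene([], CFG, image_shape=(64, 64)))
        assert np.array_equal(holo.pixels, np.ones((64, 64)))

    def test_fringes_centered_on_particle(self):
        # keep the particle near mid-field so ring clipping at the image
        # border does not bias the centroid
        holo = simulate_hologram(
            Scene([particle_at(36.0, 30.0)], CFG, image_shape=(64, 64))
        )
        w = np.abs(holo.pixels - 1.0)
        yy, xx = np.mgrid[0:64, 0:64]
        cx = (xx * w).sum() / w.sum()
        cy = (yy * w).sum() / w.sum()
        assert abs(cx - 36.0) < 1.0 and abs(cy - 30.0) < 1.0
        # radial symmetry: fringe energy balances across the center line
        qa = w[:, :36].sum() - w[:, :8].sum()
        qb = w[:, 36:].sum() - w[:, 64 - 8 :].sum()
        assert abs(qa - qb) / (qa + qb) < 0.15

    def test_weak_scattering_superposition(self):
        p1 = particle_at(20.0, 32.0, mass=50.0, diameter=6.0)
        p2 = particle_at(52.0, 32.0, mass=50.0, diameter=6.0)
        both = simulate_hologram(Scene([p1, p2], CFG, image_shape=(64, 64))).pixels
        i1 = simulate_hologram(Scene([p1], CFG, image_shape=(64, 64))).pixels
        i2 = simulate_hologram(Scene([p2], CFG, image_shape=(64, 64))).pixels
        contrast = max(np.abs(i1 - 1).max(), np.abs(i2 - 1).max())
        assert np.abs(both - (i1 + i2 - 1.0)).max() < 0.05 * contrast

    def test_shift_equivariance_whole_pixels(self):
        shift = 7
        h1 = simulate_hologram(
            Scene([particle_at(24.0, 32.0)], CFG, image_shape=(64, 64))
        ).pixels
        h2 = simulate_hologram(
            Scene([particle_at(24.0 + shift, 32.0)], CFG, image_shape=(64, 64))
        ).pixels
        crop1 = h1[:, 8 : 64 - 8 - shift]
        crop2 = h2[:, 8 + shift : 64 - 8]
        assert np.abs(crop1 - crop2).max() < 1e-6

    def test_fringe_scale_grows_with_distance(self):
        """The first fringe ring widens as the particle moves away."""

        def ring_scale(z):
            holo = simulate_hologram(
                Scene([particle_at(32.0, 32.0, z=z)], CFG, image_shape=(64, 64))
            )
            w = np.abs(holo.pixels - 1.0)
            yy, xx = np.mgrid[0:64, 0:64]
            r = np.hypot(xx - 32.0, yy - 32.0)
            return (r * w).sum() / w.sum()

        assert ring_scale(600.0) < ring_scale(1200.0)

    def test_noise_preserves_unit_mean(self):
        scene = Scene([], CFG, image_shape=(64, 64), noise_sigma=0.01,
                      gradient_amplitude=0.02)
        holo = simulate_hologram(scene, rng_seed=5)
        assert holo.pixels.min() >= 0.0
        assert abs(holo.pixels.mean() - 1.0) < 3 * 0.01 / np.sqrt(64 * 64) + 0.005

    def test_axial_limit_enforced_and_named(self):
        zlim = aliasing_z_limit(64, PITCH, CFG.medium_wavelength_um)
        with pytest.raises(ValueError, match="anti-aliasing limit"):
            simulate_hologram(
                Scene([particle_at(32.0, 32.0, z=zlim + 100)], CFG, image_shape=(64, 64))
            )

    def test_particle_outside_field_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_hologram(
                Scene([particle_at(80.0, 32.0)], CFG, image_shape=(64, 64))
            )

    def test_deterministic_given_seed(self):
        scene = Scene([particle_at(30.0, 30.0)], CFG, image_shape=(64, 64),
                      noise_sigma=0.01)
        a = simulate_hologram(scene, rng_seed=9).pixels
        b = simulate_hologram(scene, rng_seed=9).pixels
        assert np.array_equal(a, b)


class TestTruthMaps:
    def test_empty_scene_all_zero(self):
        maps = render_truth_maps(Scene([], CFG, image_shape=(64, 64)))
        assert maps.seg.sum() == 0 and not maps.offset_mask.any()

    def test_offsets_vanish_at_center_pixel(self):
        scene = Scene([particle_at(40.0, 40.0)], CFG, image_shape=(128, 128))
        maps = render_truth_maps(scene)
        assert maps.dx[40, 40] == 0.0 and maps.dy[40, 40] == 0.0

    def test_offset_sign_points_toward_center(self):
        scene = Scene([particle_at(64.0, 64.0)], CFG, image_shape=(128, 128))
        maps = render_truth_maps(scene)
        # pixel 4 px left of the center: the center lies at larger x
        assert maps.dx[64, 60] == 4.0 and maps.dy[64, 60] == 0.0
        assert maps.dx[60, 64] == 0.0 and maps.dy[60, 64] == 4.0

    def test_disk_carries_z_and_mass(self):
        p = particle_at(32.0, 32.0, z=777.0, mass=123.0)
        maps = render_truth_maps(Scene([p], CFG, image_shape=(64, 64)))
        assert maps.seg[32, 32] == 1.0
        assert maps.z[32, 32] == pytest.approx(777.0)
        assert maps.mass[32, 32] == pytest.approx(123.0)
        assert maps.z[0, 0] == 0.0 and maps.mass[0, 0] == 0.0

    def test_nearest_particle_owns_overlap(self):
        p1 = particle_at(30.0, 32.0, mass=100.0, diameter=9.0)
        p2 = particle_at(33.0, 32.0, mass=200.0, diameter=9.0)
        maps = render_truth_maps(Scene([p1, p2], CFG, image_shape=(64, 64)))
        assert maps.mass[32, 30] == pytest.approx(100.0)
        assert maps.mass[32, 33] == pytest.approx(200.0)


class TestSceneSampling:
    def test_mass_and_diameter_ranges(self):
        params = SceneParams(image_shape=(64, 64), n_particles=(1, 3),
                             z_range_um=(500, 1500))
        rng = np.random.default_rng(0)
        masses, diams = [], []
        for _ in range(2000):
            scene = sample_runet_scene(rng, CFG, params)
            for p in scene.particles:
                masses.append(p.dry_mass)
                diams.append(2 * p.radius)
        assert min(masses) >= 1.0 and max(masses) <= 995.0
        assert min(diams) >= 1.5 and max(diams) <= 10.0
        # diameters approximately uniform on [1.5, 10]
        ks = stats.kstest(diams, stats.uniform(1.5, 8.5).cdf)
        assert ks.pvalue > 0.01

    def test_same_seed_same_scene(self):
        params = SceneParams(image_shape=(64, 64), z_range_um=(500, 1500))
        s1 = sample_runet_scene(42, CFG, params)
        s2 = sample_runet_scene(42, CFG, params)
        assert [(p.x, p.y, p.z, p.dry_mass) for p in s1.particles] == [
            (p.x, p.y, p.z, p.dry_mass) for p in s2.particles
        ]


class TestSequenceSampling:
    PARAMS = SequenceParams(z_range_um=(500, 1500), distractor_prob=1.0)

    def test_main_particle_stays_centered(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            s = sample_wacnet_sequence(rng, CFG, self.PARAMS)
            assert s.frames.shape == (15, 64, 64)
        # residual offset after re-centering is within ±1 px by construction;
        # verify via the brightest-contrast centroid of a clean sequence
        clean = SequenceParams(z_range_um=(500, 1500), distractor_prob=0.0,
                               noise_sigma=0.0)
        s = sample_wacnet_sequence(3, CFG, clean)
        for frame in s.frames:
            w = np.abs(frame - 1.0)
            yy, xx = np.mgrid[0:64, 0:64]
            cx = (xx * w).sum() / w.sum()
            cy = (yy * w).sum() / w.sum()
            assert abs(cx - 32.0) <= 1.5 and abs(cy - 32.0) <= 1.5

    def test_distractor_speed_range(self):
        rng = np.random.default_rng(2)
        speeds = []
        for _ in range(100):
            s = sample_wacnet_sequence(rng, CFG, self.PARAMS)
            speeds.extend(d["speed_px"] for d in s.distractors)
        assert speeds and min(speeds) >= 1.0 and max(speeds) <= 7.0

    def test_bit_identical_for_same_seed(self):
        a = sample_wacnet_sequence(99, CFG, self.PARAMS)
        b = sample_wacnet_sequence(99, CFG, self.PARAMS)
        assert np.array_equal(a.frames, b.frames)
        assert a.target_mass == b.target_mass

    def test_targets_constant_over_sequence(self):
        s = sample_wacnet_sequence(5, CFG, self.PARAMS)
        assert np.isscalar(s.target_mass) and np.isscalar(s.target_radius)
        assert s.target_optical_volume == pytest.approx(
            s.target_mass * CFG.dn_dc_ml_g, rel=1e-9
        )


class TestDatasetRoundTrip:
    def test_hologram_dataset_lossless(self, tmp_path):
        params = SceneParams(image_shape=(64, 64), z_range_um=(500, 1500))
        rng = np.random.default_rng(3)
        samples = []
        for _ in range(5):
            scene = sample_runet_scene(rng, CFG, params)
            samples.append((simulate_hologram(scene, 1), render_truth_maps(scene)))
        path = tmp_path / "set.h5"
        write_dataset(samples, path, meta={"seed": 3})
        back, meta = read_dataset(path)
        assert meta["seed"] == 3
        for (h0, t0), (h1, t1) in zip(samples, back):
            assert np.array_equal(h0.pixels, h1.pixels)
            assert np.array_equal(t0.mass, t1.mass)
            assert np.array_equal(t0.dx, t1.dx)

    def test_sequence_dataset_lossless(self, tmp_path):
        params = SequenceParams(z_range_um=(500, 1500))
        samples = [sample_wacnet_sequence(i, CFG, params) for i in range(3)]
        path = tmp_path / "seqs.h5"
        write_dataset(samples, path)
        back, _ = read_dataset(path)
        for s0, s1 in zip(samples, back):
            assert np.array_equal(s0.frames, s1.frames)
            assert s0.target_mass == s1.target_mass
            assert s1.seed == s0.seed

    def test_overwrite_guard(self, tmp_path):
        params = SequenceParams(z_range_um=(500, 1500))
        samples = [sample_wacnet_sequence(0, CFG, params)]
        path = tmp_path / "x.h5"
        write_dataset(samples, path)
        with pytest.raises(FileExistsError):
            write_dataset(samples, path)
        write_dataset(samples, path, overwrite=True)

    def test_truncated_file_raises_format_error(self, tmp_path):
        params = SequenceParams(z_range_um=(500, 1500))
        path = tmp_path / "t.h5"
        write_dataset([sample_wacnet_sequence(0, CFG, params)], path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 3])
        with pytest.raises(DatasetFormatError):
            read_dataset(path)
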