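"""Clock-scan radial operators: closed-form disk/ring/Gaussian cases,
inside/outside apportioning, and the KS comparison against a brute-force
ECDF oracle."""

import numpy as np
import pytest

from synquant.radialmap import (
    antigen_centered_actin,
    inside_outside_fraction,
    ks_compare,
    peripheral_fraction,
    radial_profile,
    thirds_distribution,
)
from synquant.scenegen import SceneConfig, generate_scene


@pytest.fixture
def uniform_disk(disk_geometry, channel_scene):
    shape, center, radius = (256, 256), (128.0, 128.0), 80.0
    geom = disk_geometry(shape, center, radius)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    r = np.hypot(yy - center[0], xx - center[1])
    scene = channel_scene(10.0 * (r <= radius), "antigen")
    return scene, geom, r, radius


class TestRadialProfile:
    def test_uniform_disk_flat_inside_zero_beyond(self, uniform_disk):
        scene, geom, _, _ = uniform_disk
        prof = radial_profile(scene, geom, "antigen")
        inner = prof.mean_intensity[5:95]
        assert np.allclose(inner, 10.0, rtol=0.01)
        assert np.nanmax(prof.mean_intensity[105:]) < 0.1

    def test_fraction_normalized(self, uniform_disk):
        scene, geom, _, _ = uniform_disk
        prof = radial_profile(scene, geom, "antigen")
        assert prof.fraction_of_total.sum() == pytest.approx(1.0, abs=1e-9)

    def test_ring_at_half_radius_peaks_in_50pct_bin(
        self, disk_geometry, channel_scene
    ):
        geom = disk_geometry((256, 256), (128.0, 128.0), 80.0)
        yy, xx = np.mgrid[0:256, 0:256].astype(float)
        r = np.hypot(yy - 128.0, xx - 128.0)
        ring = np.exp(-((r - 40.0) ** 2) / (2 * 1.0**2))
        prof = radial_profile(channel_scene(ring, "antigen"), geom, "antigen")
        assert abs(int(np.argmax(prof.fraction_of_total)) - 50) <= 1

    def test_centered_gaussian_mass_in_inner_third(
        self, disk_geometry, channel_scene
    ):
        # sigma = 0.1 R: numerically ~99.6% of mass within rho < 1/3
        geom = disk_geometry((256, 256), (128.0, 128.0), 80.0)
        yy, xx = np.mgrid[0:256, 0:256].astype(float)
        r = np.hypot(yy - 128.0, xx - 128.0)
        g = np.exp(-(r**2) / (2 * (0.1 * 80.0) ** 2))
        prof = radial_profile(channel_scene(g, "antigen"), geom, "antigen")
        assert prof.fraction_of_total[:33].sum() >= 0.95

    def test_centroid_outside_mask_rejected(self, disk_geometry, channel_scene):
        geom = disk_geometry((128, 128), (64.0, 64.0), 30.0)
        geom.cell_mask = geom.cell_mask & False
        scene = channel_scene(np.ones((128, 128)), "antigen")
        with pytest.raises(ValueError, match="degenerate"):
            radial_profile(scene, geom, "antigen")


class TestPeripheralAndThirds:
    def test_uniform_disk_outer_quarter_is_43_75(self, uniform_disk):
        scene, geom, _, _ = uniform_disk
        prof = radial_profile(scene, geom, "antigen")
        assert peripheral_fraction(prof) == pytest.approx(43.75, abs=1.0)

    def test_uniform_disk_thirds_are_annulus_areas(self, uniform_disk):
        scene, geom, _, _ = uniform_disk
        prof = radial_profile(scene, geom, "antigen")
        thirds = thirds_distribution(prof)
        for got, want in zip(thirds, (100 / 9, 300 / 9, 500 / 9)):
            assert got == pytest.approx(want, abs=1.0)
        assert sum(thirds) == pytest.approx(100.0, abs=1e-6)

    def test_boundary_signal_is_fully_peripheral(self, disk_geometry, channel_scene):
        geom = disk_geometry((256, 256), (128.0, 128.0), 80.0)
        yy, xx = np.mgrid[0:256, 0:256].astype(float)
        r = np.hypot(yy - 128.0, xx - 128.0)
        shell = np.exp(-((r - 77.0) ** 2) / 0.5)  # fully within (0.75, 1.0]·R
        prof = radial_profile(channel_scene(shell, "antigen"), geom, "antigen")
        assert peripheral_fraction(prof) == pytest.approx(100.0, abs=1.0)

    def test_central_signal_is_zero_peripheral(self, disk_geometry, channel_scene):
        geom = disk_geometry((256, 256), (128.0, 128.0), 80.0)
        yy, xx = np.mgrid[0:256, 0:256].astype(float)
        r = np.hypot(yy - 128.0, xx - 128.0)
        spot = np.exp(-(r**2) / 8.0)
        prof = radial_profile(channel_scene(spot, "antigen"), geom, "antigen")
        assert peripheral_fraction(prof) == pytest.approx(0.0, abs=0.1)
        thirds = thirds_distribution(prof)
        assert thirds[0] == pytest.approx(100.0, abs=0.1)

    def test_ring_at_half_radius_all_in_middle_third(
        self, disk_geometry, channel_scene
    ):
        geom = disk_geometry((256, 256), (128.0, 128.0), 80.0)
        yy, xx = np.mgrid[0:256, 0:256].astype(float)
        r = np.hypot(yy - 128.0, xx - 128.0)
        ring = np.exp(-((r - 40.0) ** 2) / 2.0)
        prof = radial_profile(channel_scene(ring, "antigen"), geom, "antigen")
        assert thirds_distribution(prof)[1] == pytest.approx(100.0, abs=0.5)

    def test_invalid_cut_rejected(self, uniform_disk):
        scene, geom, _, _ = uniform_disk
        prof = radial_profile(scene, geom, "antigen")
        with pytest.raises(ValueError):
            peripheral_fraction(prof, cut=1.5)


class TestInsideOutside:
    def test_all_signal_inside_gives_100(self, disk_geometry, channel_scene):
        geom = disk_geometry((128, 128), (64.0, 64.0), 40.0)
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        r = np.hypot(yy - 64.0, xx - 64.0)
        img = 10.0 * (r <= 30.0)  # strictly interior
        rf = inside_outside_fraction(channel_scene(img, "antigen"), geom, "antigen")
        assert rf.inside_pct == 100.0
        assert rf.inside_pct + rf.outside_pct == pytest.approx(100.0, abs=1e-9)

    def test_contour_pixel_counts_inside(self, disk_geometry, channel_scene):
        geom = disk_geometry((128, 128), (64.0, 64.0), 40.0)
        img = np.zeros((128, 128))
        img[64, 104] = 5.0  # exactly on the contour (rho == 1)
        rf = inside_outside_fraction(channel_scene(img, "antigen"), geom, "antigen")
        assert rf.inside_pct == 100.0

    def test_zero_signal_rejected(self, disk_geometry, channel_scene):
        geom = disk_geometry((128, 128), (64.0, 64.0), 40.0)
        with pytest.raises(ValueError, match="no signal"):
            inside_outside_fraction(
                channel_scene(np.zeros((128, 128)), "antigen"), geom, "antigen"
            )

    def test_thirds_sum_to_100(self, disk_geometry, channel_scene):
        geom = disk_geometry((128, 128), (64.0, 64.0), 40.0)
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 10, (128, 128))
        rf = inside_outside_fraction(channel_scene(img, "antigen"), geom, "antigen")
        assert sum(rf.thirds_pct) == pytest.approx(100.0, abs=1e-9)


class TestAntigenCenteredActin:
    def test_uniform_actin_gives_annulus_areas(self, disk_geometry, channel_scene):
        geom = disk_geometry((128, 128), (64.0, 64.0), 40.0)
        scene = channel_scene(np.full((128, 128), 4.0), "actin")
        f = antigen_centered_actin(scene, geom, (64.0, 64.0), radius_um=1.5)
        expected = np.diff((np.arange(11) / 10.0) ** 2)
        assert np.allclose(f, expected, atol=1e-9)

    def test_rim_shell_lands_in_outer_bin(self, disk_geometry, channel_scene):
        geom = disk_geometry((128, 128), (64.0, 64.0), 40.0)
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        d = np.hypot(yy - 64.0, xx - 64.0)
        shell = np.exp(-((d - 14.3) ** 2) / 0.05)  # 1.5 um = 15 px; rim bin
        f = antigen_centered_actin(channel_scene(shell, "actin"), geom, (64.0, 64.0))
        assert f[-1] >= 0.95

    def test_zero_actin_rejected(self, disk_geometry, channel_scene):
        geom = disk_geometry((128, 128), (64.0, 64.0), 40.0)
        with pytest.raises(ValueError, match="no actin"):
            antigen_centered_actin(
                channel_scene(np.zeros((128, 128)), "actin"), geom, (64.0, 64.0)
            )

    def test_circle_outside_image_rejected(self, disk_geometry, channel_scene):
        geom = disk_geometry((128, 128), (64.0, 64.0), 40.0)
        scene = channel_scene(np.ones((128, 128)), "actin")
        with pytest.raises(ValueError, match="outside the image"):
            antigen_centered_actin(scene, geom, (500.0, 500.0))


class TestKSCompare:
    def test_identical_samples_have_zero_D(self):
        d, _ = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_disjoint_supports_have_D_one(self):
        d, p = ks_compare([1.0, 2.0], [10.0, 11.0])
        assert d == 1.0
        assert p < 0.5

    def test_matches_brute_force_ecdf(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 4.0])
        # oracle: exhaustive ECDF difference over all sample points
        grid = np.concatenate([a, b])
        ecdf_a = np.array([(a <= x).mean() for x in grid])
        ecdf_b = np.array([(b <= x).mean() for x in grid])
        expected = np.abs(ecdf_a - ecdf_b).max()
        d, _ = ks_compare(a, b)
        assert d == pytest.approx(expected, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])


class TestRotationInvariance:
    def test_quarter_turn_changes_nothing(self):
        from synquant.scenegen import Scene
        from synquant.segment import segment_cell

        scene = generate_scene(SceneConfig(seed=9, antigen_inside_fraction=0.7))
        rot = Scene(
            planes=np.rot90(scene.planes, axes=(2, 3)).copy(),
            channel_roles=scene.channel_roles,
            pixel_size_um=scene.pixel_size_um,
        )
        vals = []
        for s in (scene, rot):
            geom = segment_cell(s, "brightfield")
            rf = inside_outside_fraction(s, geom, "antigen", background="auto")
            vals.append((rf.inside_pct, rf.peripheral_quarter_pct))
        assert vals[0][0] == pytest.approx(vals[1][0], rel=0.01)
        assert vals[0][1] == pytest.approx(vals[1][1], rel=0.01)


class TestRecoveryMonotonicity:
    def test_mean_inside_pct_monotone_in_configured_fraction(self):
        from synquant.segment import segment_cell

        means = []
        for frac in (0.2, 0.5, 0.8):
            vals = []
            for seed in range(8):
                scene = generate_scene(
                    SceneConfig(antigen_inside_fraction=frac, seed=100 + seed)
                )
                geom = segment_cell(scene, "brightfield")
                rf = inside_outside_fraction(
                    scene, geom, "antigen", background="auto"
                )
                vals.append(rf.inside_pct)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
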