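"""Bead-quadrant actin scoring and the synaptic-interface ROI: sector-area
arithmetic cases, partition/invariance properties, timecourse clearance,
and a brute-force point-in-polygon oracle for interface MFI."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from synquant.beadsynapse import (
    interface_mfi,
    quadrant_actin,
    quadrant_timecourse,
    synaptic_interface_roi,
)
from synquant.scenegen import (
    Scene,
    generate_bead_timecourse,
    make_preset,
)
from synquant.segment import Bead, detect_beads, segment_cell


@pytest.fixture
def east_bead_setup(disk_geometry):
    """Circular cell with a large bead due east, rendered with anti-aliased
    edges so sector sums approach their continuum values."""
    shape = (256, 256)
    geom = disk_geometry(shape, (128.3, 50.6), 40.0)
    bead = Bead(center=(128.3, 190.6), radius_px=40.0)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    db = np.hypot(yy - bead.center[0], xx - bead.center[1])
    edge = np.clip(1.2 * bead.radius_px + 0.5 - db, 0, 1)
    return geom, bead, xx, edge


def _actin_scene(img):
    return Scene(
        planes=np.asarray(img, float)[None, None],
        channel_roles={0: "actin"},
        pixel_size_um=0.1,
    )


class TestQuadrantActin:
    def test_uniform_region_gives_equal_quarters(self, east_bead_setup):
        geom, bead, _, edge = east_bead_setup
        q = quadrant_actin(_actin_scene(3.0 * edge), geom, bead)
        assert np.allclose(q.percentages, 25.0, atol=1.0)
        assert sum(q.percentages) == pytest.approx(100.0, abs=1e-9)

    def test_proximal_only_gives_100(self, east_bead_setup):
        geom, bead, xx, edge = east_bead_setup
        yy = np.mgrid[0:256, 0:256][0].astype(float)
        phi = np.arctan2(yy - bead.center[0], xx - bead.center[1])
        # proximal = toward the cell (due west of the bead)
        prox = np.abs(np.angle(np.exp(1j * (phi - np.pi)))) < np.deg2rad(40)
        q = quadrant_actin(_actin_scene(5.0 * edge * prox), geom, bead)
        assert q.percentages[0] == pytest.approx(100.0, abs=0.5)

    def test_cell_facing_half_disk_sector_areas(self, east_bead_setup):
        geom, bead, xx, edge = east_bead_setup
        halfcov = np.clip(bead.center[1] + 0.5 - xx, 0, 1)
        q = quadrant_actin(_actin_scene(5.0 * edge * halfcov), geom, bead)
        for got, want in zip(q.percentages, (50.0, 25.0, 25.0, 0.0)):
            assert got == pytest.approx(want, abs=1.0)

    def test_zero_actin_rejected(self, east_bead_setup):
        geom, bead, _, _ = east_bead_setup
        with pytest.raises(ValueError, match="zero actin"):
            quadrant_actin(_actin_scene(np.zeros((256, 256))), geom, bead)

    @given(gain=st.floats(min_value=0.01, max_value=1000.0))
    @settings(
        max_examples=20,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    def test_invariant_to_global_gain(self, east_bead_setup, gain):
        geom, bead, xx, edge = east_bead_setup
        base = edge * (1.0 + 0.5 * np.cos(0.1 * xx))
        q1 = quadrant_actin(_actin_scene(base), geom, bead)
        q2 = quadrant_actin(_actin_scene(gain * base), geom, bead)
        assert np.allclose(q1.percentages, q2.percentages, atol=1e-9)

    def test_sectors_partition_the_region(self, east_bead_setup):
        # every region pixel in exactly one sector: sector sums of a
        # counting image reproduce the region pixel count
        geom, bead, _, _ = east_bead_setup
        ones = np.ones((256, 256))
        q = quadrant_actin(_actin_scene(ones), geom, bead)
        region_px = int(q.region.sum())
        total = sum(q.percentages) / 100.0 * region_px
        assert total == pytest.approx(region_px, abs=1e-6)


class TestQuadrantTimecourse:
    def _score_series(self, name, seed, clearances):
        cfg = make_preset(name, seed=seed)
        scenes = generate_bead_timecourse(cfg, clearances)
        geoms, beads = [], []
        for s in scenes:
            bs = detect_beads(s, 1.5)
            geoms.append(segment_cell(s, "actin", beads=bs))
            beads.append(bs[0])
        return quadrant_timecourse(scenes, geoms, beads)

    def test_ramped_clearance_monotone_proximal_decline(self):
        scores, clearance = self._score_series(
            "control_bead", 21, (0.0, 0.33, 0.66, 1.0)
        )
        prox = [s.percentages[0] for s in scores]
        assert all(a > b for a, b in zip(prox, prox[1:]))
        assert clearance > 0

    def test_static_scene_has_zero_clearance(self):
        scores, clearance = self._score_series("ko_bead", 22, (0.3, 0.3))
        assert clearance == pytest.approx(0.0, abs=1e-9)

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError, match="2 timepoints"):
            quadrant_timecourse([None], [None], [None])


class TestSynapticROI:
    def test_east_bead_rectangle_axis_aligned(self, east_bead_setup):
        geom, bead, _, _ = east_bead_setup
        roi = synaptic_interface_roi(geom, bead)
        # bead due east -> long axis along -x (bead to cell), rectangle
        # axis-aligned: vertex rows at center +- width/2
        rows = np.sort(np.unique(np.round(roi.rectangle[:, 0], 6)))
        assert len(rows) == 2
        assert rows[1] - rows[0] == pytest.approx(geom.equivalent_radius_px / 2)
        assert roi.center[0] == pytest.approx(128.3)
        # midpoint between nearest contour point (x=90.6) and bead center
        assert roi.center[1] == pytest.approx((90.6 + 190.6) / 2, abs=0.1)

    def test_area_closed_form(self, east_bead_setup):
        from shapely.geometry import Polygon

        geom, bead, _, _ = east_bead_setup
        roi = synaptic_interface_roi(geom, bead)
        expected = (geom.equivalent_radius_px / 2) * (2 * bead.radius_px)
        assert Polygon(roi.rectangle).area == pytest.approx(expected, rel=1e-9)

    def test_rotation_equivariance(self, disk_geometry):
        from shapely.geometry import Polygon

        geom_e = disk_geometry((256, 256), (128.0, 128.0), 40.0)
        roi_e = synaptic_interface_roi(geom_e, Bead(center=(128.0, 190.0), radius_px=15.0))
        roi_n = synaptic_interface_roi(geom_e, Bead(center=(66.0, 128.0), radius_px=15.0))
        # rotating the bead placement by 90 degrees rotates the ROI
        rot = np.array(
            [[128.0 + (v[1] - 128.0) * -1, 128.0 + (v[0] - 128.0)] for v in roi_e.rectangle]
        )
        assert Polygon(rot).symmetric_difference(Polygon(roi_n.rectangle)).area == (
            pytest.approx(0.0, abs=1e-6)
        )

    def test_bead_inside_cell_rejected(self, disk_geometry):
        geom = disk_geometry((128, 128), (64.0, 64.0), 40.0)
        with pytest.raises(ValueError, match="inside the cell"):
            synaptic_interface_roi(geom, Bead(center=(64.0, 70.0), radius_px=10.0))


class TestInterfaceMFI:
    def test_constant_image(self, east_bead_setup):
        geom, bead, _, _ = east_bead_setup
        roi = synaptic_interface_roi(geom, bead)
        scene = _actin_scene(np.full((256, 256), 7.0))
        assert interface_mfi(scene, roi, "actin") == pytest.approx(7.0)

    def test_linearity(self, east_bead_setup):
        geom, bead, xx, _ = east_bead_setup
        roi = synaptic_interface_roi(geom, bead)
        img = 1.0 + np.cos(0.07 * xx)
        m1 = interface_mfi(_actin_scene(img), roi, "actin")
        m2 = interface_mfi(_actin_scene(2.0 * img), roi, "actin")
        assert m2 == pytest.approx(2.0 * m1, rel=1e-12)

    def test_matches_brute_force_point_in_polygon(self, disk_geometry):
        # oracle: shapely point-in-polygon over every pixel of a 64x64 image
        from shapely.geometry import Point, Polygon

        geom = disk_geometry((64, 64), (32.0, 20.0), 14.0)
        bead = Bead(center=(33.5, 50.2), radius_px=8.0)
        roi = synaptic_interface_roi(geom, bead)
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 100, (64, 64))
        poly = Polygon(roi.rectangle)
        vals = [
            img[y, x]
            for y in range(64)
            for x in range(64)
            if poly.contains(Point(y, x))
        ]
        expected = float(np.mean(vals))
        got = interface_mfi(_actin_scene(img), roi, "actin")
        assert got == pytest.approx(expected, rel=1e-9)

    def test_empty_roi_rejected(self, disk_geometry):
        geom = disk_geometry((64, 64), (32.3, 20.0), 10.0)
        bead = Bead(center=(32.3, 50.4), radius_px=0.1)
        geom.equivalent_radius_px = 0.2
        roi = synaptic_interface_roi(geom, bead)
        with pytest.raises(ValueError, match="no pixel"):
            interface_mfi(_actin_scene(np.ones((64, 64))), roi, "actin")
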