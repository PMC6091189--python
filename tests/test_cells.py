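import numpy as np
import pytest
from skimage import draw

from conftest import full_geometry
from musclehca.cells import (
    call_satellites,
    detect_marker_objects,
    quantify_vessels,
    satellite_vessel_distances,
)
from musclehca.nuclei import BlobParams, DetectedObject, detect_nuclei, nuclei_mask
from musclehca.synthetic import SynthParams, generate_section


def make_blob(object_id, origin, mask, role="pax7", scale=1.0):
    rows, cols = np.nonzero(mask)
    obj = DetectedObject(
        object_id=object_id, mask=mask, origin=origin,
        area_um2=float(mask.sum()) * scale * scale,
        centroid_xy_um=((rows.mean() + origin[0]) * scale,
                        (cols.mean() + origin[1]) * scale),
        mean_intensity=100.0, channel_role=role,
    )
    obj._scale = scale
    return obj


class TestDetectMarkerObjects:
    def test_blank_channel(self):
        assert detect_marker_objects(np.zeros((32, 32)), "pax7", 1.0) == []

    def test_bad_role(self):
        with pytest.raises(ValueError):
            detect_marker_objects(np.zeros((8, 8)), "dapi", 1.0)

    def test_planted_pax7_recovered(self, marker_section):
        section, truth = marker_section
        planted = truth.objects[truth.objects.kind == "pax7"]
        detected = detect_marker_objects(section.channel("pax7"), "pax7", 1.0)
        assert abs(len(detected) - len(planted)) <= 1

    def test_below_min_area_excluded(self):
        img = np.full((40, 40), 5.0)
        img[20, 20] = 250.0  # single pixel, below every floor
        params = BlobParams(min_area_um2=8.0, max_area_um2=120.0,
                            smooth_sigma_px=0.0)
        assert detect_marker_objects(img, "pax7", 1.0, params) == []


class TestCallSatellites:
    def test_constructed_overlap_accept_and_reject(self, cnf_geometry):
        fm, morphs, rois, imgs = cnf_geometry
        # take a genuine sc pixel so the position rule passes
        fid = next(iter(rois))
        rs = rois[fid]
        r0, c0 = rs.origin
        sc_px = np.argwhere(rs.roi_sc)[0] + (r0, c0)
        blob = np.ones((10, 10), dtype=bool)  # 100 px blob
        origin = (int(sc_px[0]) - 5, int(sc_px[1]) - 5)

        nmask = np.zeros(fm.labels.shape, dtype=bool)
        nmask[origin[0] : origin[0] + 10, origin[1] : origin[1] + 10] = True
        nmask[origin[0], origin[1] : origin[1] + 5] = False  # 95/100 overlap
        calls = call_satellites([make_blob(1, origin, blob)], nmask, rois, imgs)
        assert calls[0].overlap_fraction == pytest.approx(0.95)
        assert calls[0].accepted and calls[0].fiber_id == fid

        nmask80 = np.zeros(fm.labels.shape, dtype=bool)
        nmask80[origin[0] : origin[0] + 8, origin[1] : origin[1] + 10] = True
        calls = call_satellites([make_blob(1, origin, blob)], nmask80, rois, imgs)
        assert calls[0].overlap_fraction == pytest.approx(0.80)
        assert not calls[0].accepted

    def test_good_overlap_wrong_position_rejected(self, cnf_geometry):
        fm, morphs, rois, imgs = cnf_geometry
        fid = next(iter(rois))
        rs = rois[fid]
        r0, c0 = rs.origin
        cnf_px = np.argwhere(rs.roi_cnf)
        cnf_px = cnf_px[len(cnf_px) // 2] + (r0, c0)  # central pixel
        blob = np.ones((4, 4), dtype=bool)
        origin = (int(cnf_px[0]) - 2, int(cnf_px[1]) - 2)
        nmask = np.ones(fm.labels.shape, dtype=bool)  # full overlap
        calls = call_satellites([make_blob(1, origin, blob)], nmask, rois, imgs)
        assert calls[0].overlap_fraction == 1.0
        assert not calls[0].accepted  # not sub-laminal

    def test_threshold_monotonicity(self, marker_section, marker_geometry):
        section, truth = marker_section
        fm, morphs, rois, imgs = marker_geometry
        nuclei = detect_nuclei(section.channel("dapi"), 1.0)
        nmask = nuclei_mask(nuclei, fm.labels.shape)
        pax7 = detect_marker_objects(section.channel("pax7"), "pax7", 1.0)
        accepted = [
            sum(c.accepted for c in
                call_satellites(pax7, nmask, rois, imgs, overlap_threshold=t))
            for t in (0.95, 0.90, 0.70, 0.50)
        ]
        assert accepted == sorted(accepted)  # lowering never decreases

    def test_recovery_against_truth(self, marker_section, marker_geometry):
        section, truth = marker_section
        fm, morphs, rois, imgs = marker_geometry
        nuclei = detect_nuclei(section.channel("dapi"), 1.0)
        nmask = nuclei_mask(nuclei, fm.labels.shape)
        pax7 = detect_marker_objects(section.channel("pax7"), "pax7", 1.0)
        calls = call_satellites(pax7, nmask, rois, imgs)
        planted = int(truth.fibers.n_satellites.sum())
        assert sum(c.accepted for c in calls) == pytest.approx(planted, rel=0.10)


class TestQuantifyVessels:
    def test_density_arithmetic(self, cnf_geometry):
        fm = cnf_geometry[0]
        rois = cnf_geometry[2]
        # fabricate a section mask of exactly 1 mm^2 at 1 um/px
        mask = np.zeros((1100, 1100), dtype=bool)
        mask[:1000, :1000] = True
        blob = np.ones((2, 2), dtype=bool)
        objs = [make_blob(i, (7 * i, 10), blob, role="cd31") for i in range(1, 151)]
        vm = quantify_vessels(objs, {}, mask, 1.0)
        assert vm.density_per_mm2 == pytest.approx(150.0)

    def test_object_inside_fiber_counts_for_no_fiber(self, cnf_geometry):
        fm, morphs, rois, imgs = cnf_geometry
        fid = next(iter(rois))
        rs = rois[fid]
        r0, c0 = rs.origin
        inner = np.argwhere(rs.roi_cnf)[0] + (r0, c0)
        blob = np.ones((2, 2), dtype=bool)
        obj = make_blob(1, (int(inner[0]), int(inner[1])), blob, role="cd31")
        vm = quantify_vessels([obj], rois, fm.section_mask, 1.0)
        assert sum(vm.per_fiber_counts.values()) == 0
        assert vm.density_per_mm2 > 0
        assert vm.pct_area > 0

    def test_per_fiber_modal_count(self):
        # thick walls isolate each fiber's band from its neighbours'
        params = SynthParams(n_fibers=100, wall_um=7.0,
                             vessels_per_fiber_dist={4: 1.0},
                             channels=("laminin", "cd31"))
        section, truth = generate_section(params, seed=3)
        fm, morphs, rois, imgs = full_geometry(section)
        cd31 = detect_marker_objects(section.channel("cd31"), "cd31", 1.0)
        vm = quantify_vessels(cd31, rois, fm.section_mask, 1.0)
        counts = list(vm.per_fiber_counts.values())
        modal = max(set(counts), key=counts.count)
        assert abs(modal - 4) <= 1

    def test_pct_area_recovers_painted_fraction(self):
        params = SynthParams(n_fibers=100, vessels_per_fiber_dist={4: 1.0},
                             channels=("laminin", "cd31"), noise_sigma=1.0,
                             blur_sigma=0.0, vessel_radius_um=4.5)
        section, truth = generate_section(params, seed=1)
        fm, morphs, rois, imgs = full_geometry(section)
        cd31 = detect_marker_objects(section.channel("cd31"), "cd31", 1.0)
        vm = quantify_vessels(cd31, rois, fm.section_mask, 1.0)
        chan = section.channel("cd31")
        painted = 100.0 * ((chan > 100) & fm.section_mask).sum() / fm.section_mask.sum()
        assert vm.pct_area == pytest.approx(painted, abs=0.5)

    def test_zero_section_area(self):
        with pytest.raises(ValueError):
            quantify_vessels([], {}, np.zeros((4, 4), dtype=bool), 1.0)


class TestSatelliteVesselDistances:
    def _sat(self, object_id, xy):
        from musclehca.cells import SatelliteCall

        return SatelliteCall(object_id=object_id, overlap_fraction=1.0,
                             fiber_id=1, accepted=True, centroid_xy_um=xy)

    def _vessel(self, object_id, xy):
        blob = np.ones((1, 1), dtype=bool)
        obj = make_blob(object_id, (0, 0), blob, role="cd31")
        obj.centroid_xy_um = xy
        return obj

    def test_three_four_five(self):
        sats = [self._sat(1, (0.0, 0.0))]
        vessels = [self._vessel(1, (3.0, 4.0)), self._vessel(2, (10.0, 0.0))]
        assert satellite_vessel_distances(sats, vessels)[1] == pytest.approx(5.0)

    def test_coincident_zero(self):
        sats = [self._sat(1, (2.0, 2.0))]
        assert satellite_vessel_distances(sats, [self._vessel(1, (2.0, 2.0))])[1] == 0.0

    def test_no_vessels_missing(self):
        out = satellite_vessel_distances([self._sat(1, (0.0, 0.0))], [])
        assert out[1] is None

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        sats = [self._sat(i, tuple(rng.uniform(0, 100, 2))) for i in range(1, 8)]
        vessels = [self._vessel(i, tuple(rng.uniform(0, 100, 2)))
                   for i in range(1, 20)]
        out = satellite_vessel_distances(sats, vessels)
        for s in sats:
            expected = min(
                np.hypot(s.centroid_xy_um[0] - v.centroid_xy_um[0],
                         s.centroid_xy_um[1] - v.centroid_xy_um[1])
                for v in vessels
            )
            assert out[s.object_id] == pytest.approx(expected)
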