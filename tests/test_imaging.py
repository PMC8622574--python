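"""Plate segmentation against rendered ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from beanbolus import imaging, synth
from conftest import match_by_centroid


class TestCalibrate:
    def test_arithmetic(self):
        assert imaging.calibrate(10.0, 100.0).mm_per_px == pytest.approx(0.1)

    @pytest.mark.parametrize("mm,px", [(0.0, 100.0), (10.0, 0.0), (-1.0, 5.0)])
    def test_invalid(self, mm, px):
        with pytest.raises(ValueError):
            imaging.calibrate(mm, px)


class TestIsolatePlate:
    def test_mask_matches_rendered_disc(self, oracle_plate):
        _, image, truth = oracle_plate
        mask = imaging.isolate_plate(image)
        inter = (mask & truth.plate_mask).sum()
        union = (mask | truth.plate_mask).sum()
        assert inter / union >= 0.98

    def test_all_black_image(self):
        with pytest.raises(imaging.PlateNotFoundError):
            imaging.isolate_plate(np.zeros((50, 50, 3), dtype=np.uint8))

    def test_full_frame_plate(self):
        img = np.empty((60, 60, 3), dtype=np.uint8)
        img[...] = synth.PLATE_BLUE
        mask = imaging.isolate_plate(img)
        assert mask.all()


class TestRemoveReflections:
    def test_noop_without_reflections(self):
        spec = synth.PlateSpec(n_white=2, n_black=2, image_size_px=500, min_area_mm2=2.0, seed=5)
        image, truth = synth.render_plate(spec)
        cal = imaging.calibrate(truth.marker_length_mm, truth.marker_length_px)
        plate = imaging.isolate_plate(image)
        cleaned = imaging.remove_reflections(image, plate, cal)
        np.testing.assert_array_equal(cleaned, plate)

    def test_reflections_removed_particles_kept(self, oracle_plate, oracle_calibration, oracle_segmentation):
        # 3 reflection blobs rendered; full pipeline recovers exactly the
        # true particle count, so reflections are gone and no particle lost
        _, _, truth = oracle_plate
        assert len(oracle_segmentation) == len(truth.particles)

    def test_large_bright_particle_retained(self):
        # a 4 mm^2 cotyledon particle must survive the reflection filter
        spec = synth.PlateSpec(
            n_white=1, n_black=0, rr_white=(4.0, 8.0), image_size_px=500,
            min_area_mm2=3.5, seed=2,
        )
        image, truth = synth.render_plate(spec)
        cal = imaging.calibrate(truth.marker_length_mm, truth.marker_length_px)
        rec = imaging.segment_image(image, cal)
        assert len(rec) == 1


class TestDetectAndMeasure:
    def test_empty_plate_zero_regions(self):
        image, truth = synth.render_plate(
            synth.PlateSpec(n_white=0, n_black=0, image_size_px=500, seed=0)
        )
        plate = imaging.isolate_plate(image)
        rec = imaging.detect_particles(image, plate)
        assert len(rec) == 0

    def test_exact_count(self, oracle_plate, oracle_segmentation):
        _, _, truth = oracle_plate
        assert len(oracle_segmentation) == len(truth.particles)

    def test_one_pixel_separation_preserved(self):
        img = np.empty((60, 60, 3), dtype=np.uint8)
        img[...] = synth.PLATE_BLUE
        img[20:25, 20:25] = synth.WHITE_PARTICLE
        img[20:25, 26:31] = synth.BLACK_PARTICLE  # 1 px gap at column 25
        rec = imaging.detect_particles(img, np.ones((60, 60), dtype=bool))
        assert len(rec) == 2

    def test_area_arithmetic(self):
        rec = pd.DataFrame({"particle_id": [1], "pixel_count": [400]})
        out = imaging.measure_areas(rec, imaging.Calibration(0.05))
        assert out["area_mm2"].iloc[0] == pytest.approx(1.0)

    def test_zero_pixel_regions_excluded(self):
        rec = pd.DataFrame({"particle_id": [1, 2], "pixel_count": [0, 10]})
        out = imaging.measure_areas(rec, imaging.Calibration(0.1))
        assert out["particle_id"].tolist() == [2]

    def test_missing_calibration(self):
        with pytest.raises(ValueError):
            imaging.measure_areas(pd.DataFrame({"particle_id": [], "pixel_count": []}), None)

    def test_area_error_within_three_percent(self, oracle_plate, oracle_segmentation):
        _, _, truth = oracle_plate
        tp, rc = match_by_centroid(truth.particles, oracle_segmentation)
        rel = np.abs(rc["area_mm2"].to_numpy() - tp["area_mm2"].to_numpy()) / tp[
            "area_mm2"
        ].to_numpy()
        assert rel.mean() <= 0.03
        assert rel.max() <= 0.03

    def test_area_conservation(self, oracle_plate, oracle_calibration, oracle_segmentation):
        _, _, truth = oracle_plate
        plate_area = truth.plate_mask.sum() * oracle_calibration.mm2_per_px
        assert oracle_segmentation["area_mm2"].sum() <= plate_area


class TestClassify:
    def test_perfect_agreement_with_truth(self, oracle_plate, oracle_segmentation):
        _, _, truth = oracle_plate
        tp, rc = match_by_centroid(truth.particles, oracle_segmentation)
        assert (tp["class"].to_numpy() == rc["class"].to_numpy()).all()

    def test_two_particle_case(self):
        rec = pd.DataFrame(
            {
                "particle_id": [1, 2],
                "mean_r": [20.0, 240.0],
                "mean_g": [20.0, 240.0],
                "mean_b": [20.0, 230.0],
            }
        )
        out = imaging.classify_particles(rec)
        assert out["class"].tolist() == ["black", "white"]

    def test_identical_colours_single_class_warning(self):
        rec = pd.DataFrame(
            {
                "particle_id": [1, 2, 3],
                "mean_r": [200.0] * 3,
                "mean_g": [200.0] * 3,
                "mean_b": [200.0] * 3,
            }
        )
        with pytest.warns(UserWarning):
            out = imaging.classify_particles(rec)
        assert (out["class"] == "white").all()

    def test_deterministic(self, oracle_segmentation):
        a = imaging.classify_particles(oracle_segmentation.drop(columns="class"), seed=0)
        b = imaging.classify_particles(oracle_segmentation.drop(columns="class"), seed=0)
        assert (a["class"] == b["class"]).all()


class TestSieve:
    def test_small_particle_removed(self):
        rec = pd.DataFrame({"particle_id": [1, 2], "area_mm2": [0.5, 5.0]})
        out = imaging.apply_sieve_filter(rec, 1.0)
        assert out["particle_id"].tolist() == [2]

    def test_zero_threshold_is_identity(self):
        rec = pd.DataFrame({"particle_id": [1, 2], "area_mm2": [0.5, 5.0]})
        assert len(imaging.apply_sieve_filter(rec, 0.0)) == 2

    @given(st.lists(st.floats(0.01, 50), min_size=1, max_size=30), st.floats(0, 5), st.floats(0, 5))
    def test_monotone_in_threshold(self, areas, t1, t2):
        rec = pd.DataFrame({"particle_id": range(len(areas)), "area_mm2": areas})
        lo, hi = sorted([t1, t2])
        assert len(imaging.apply_sieve_filter(rec, hi)) <= len(
            imaging.apply_sieve_filter(rec, lo)
        )


class TestAnalyzeBolus:
    def _plates(self, seeds, **kw):
        out = []
        for s in seeds:
            spec = synth.PlateSpec(
                n_white=5, n_black=4, image_size_px=500, min_area_mm2=2.0, seed=s, **kw
            )
            out.append(synth.render_plate(spec))
        return out

    def test_pooling_additivity(self):
        plates = self._plates([11, 12])
        truth0 = plates[0][1]
        cal = imaging.calibrate(truth0.marker_length_mm, truth0.marker_length_px)
        pooled = imaging.analyze_bolus([p[0] for p in plates], cal)
        per_image = [imaging.segment_image(p[0], cal) for p in plates]
        assert len(pooled) == sum(len(x) for x in per_image)
        assert pooled["particle_id"].is_unique

    def test_single_image_matches_pipeline(self):
        (img, truth), = self._plates([13])
        cal = imaging.calibrate(truth.marker_length_mm, truth.marker_length_px)
        pooled = imaging.analyze_bolus([img], cal)
        single = imaging.segment_image(img, cal)
        assert len(pooled) == len(single)
        np.testing.assert_allclose(
            pooled["area_mm2"].to_numpy(), single["area_mm2"].to_numpy()
        )

    def test_class_counts_match_truth(self):
        plates = self._plates([14, 15])
        truth0 = plates[0][1]
        cal = imaging.calibrate(truth0.marker_length_mm, truth0.marker_length_px)
        pooled = imaging.analyze_bolus([p[0] for p in plates], cal)
        want = pd.concat([p[1].particles for p in plates])["class"].value_counts()
        got = pooled["class"].value_counts()
        assert got.to_dict() == want.to_dict()

    def test_requires_images(self):
        with pytest.raises(ValueError):
            imaging.analyze_bolus([], imaging.Calibration(0.1))
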