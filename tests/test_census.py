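"""Particle detection, contour-length measurement and monomer/dimer census."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import origamiqc as oq
from origamiqc.census import Particle, census_from_labels, measure_contour_length


def particle_from_coords(coords):
    coords = np.asarray(coords)
    return Particle(pixel_set=coords, centroid=tuple(coords.mean(axis=0)))


class TestDetect:
    def test_all_mica_scene_has_no_particles(self):
        spec = oq.SceneSpec(n_monomers=0, n_dimers=0, n_staples=0, seed=0)
        hm, _ = oq.generate_afm_scene(spec)
        assert oq.detect_particles(hm, 1.0) == []

    def test_threshold_above_max_vacuous(self):
        spec = oq.SceneSpec(width_px=512, height_px=512, n_monomers=3,
                            n_dimers=0, n_staples=0, seed=1)
        hm, _ = oq.generate_afm_scene(spec)
        assert oq.detect_particles(hm, hm.heights.max() + 1) == []

    def test_counts_nonoverlapping_rods(self):
        spec = oq.SceneSpec(width_px=512, height_px=512, n_monomers=5,
                            n_dimers=0, n_staples=0, seed=2)
        hm, truth = oq.generate_afm_scene(spec)
        particles = oq.detect_particles(hm, 1.0, min_area_px=6)
        assert len(particles) == len(truth.particles) == 5

    def test_deterministic_centroid_order(self):
        spec = oq.SceneSpec(width_px=512, height_px=512, n_monomers=4,
                            n_dimers=1, n_staples=0, seed=3)
        hm, _ = oq.generate_afm_scene(spec)
        particles = oq.detect_particles(hm, 1.0)
        cents = [p.centroid for p in particles]
        assert cents == sorted(cents)

    def test_min_area_must_be_positive(self):
        hm = oq.HeightMap(np.zeros((50, 50)), 1.0)
        with pytest.raises(ValueError):
            oq.detect_particles(hm, 0.5, min_area_px=0)


class TestContourLength:
    def test_straight_rod_exact_length(self):
        # 51 collinear pixels = 50 inter-pixel steps
        p = particle_from_coords([[5, c] for c in range(10, 61)])
        assert measure_contour_length(p, 10.0) == pytest.approx(500.0, abs=10.0)

    def test_axis_aligned_rod_is_exact(self):
        for n_px in (10, 25, 80):
            p = particle_from_coords([[0, c] for c in range(n_px)])
            assert measure_contour_length(p, 2.0) == (n_px - 1) * 2.0

    def test_l_shape_spans_both_arms(self):
        coords = [[r, 0] for r in range(11)] + [[10, c] for c in range(1, 11)]
        p = particle_from_coords(coords)
        assert measure_contour_length(p, 10.0) == pytest.approx(200.0, abs=20.0)

    def test_diagonal_steps_count_sqrt2(self):
        p = particle_from_coords([[i, i] for i in range(11)])
        assert measure_contour_length(p, 1.0) == pytest.approx(10 * np.sqrt(2))

    def test_single_pixel_warns_and_returns_zero(self):
        p = particle_from_coords([[3, 3]])
        with pytest.warns(UserWarning, match="single-pixel"):
            assert measure_contour_length(p, 5.0) == 0.0


class TestClassify:
    @pytest.mark.parametrize("length,expected", [
        (500.0, "monomer"),
        (1000.0, "dimer"),
        (750.0, "dimer"),    # boundary belongs to the dimer window
        (749.999, "monomer"),
        (120.0, "other"),    # fragment
        (1600.0, "other"),   # aggregate
    ])
    def test_reference_lengths(self, length, expected):
        assert oq.classify_by_length(length) == expected

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            oq.classify_by_length(-1.0)

    def test_window_bounds_validated(self):
        with pytest.raises(ValueError):
            oq.classify_by_length(500.0, window=0.7)
        with pytest.raises(ValueError):
            oq.classify_by_length(500.0, monomer_ref_nm=1000, dimer_ref_nm=500)


class TestCensus:
    def test_simple_fraction(self):
        cen = census_from_labels(["monomer", "monomer", "dimer"])
        assert cen.dimer_fraction == pytest.approx(1 / 3)
        assert cen.monomer_fraction + cen.dimer_fraction == pytest.approx(1.0)

    def test_empty_census_undefined_fractions(self):
        cen = census_from_labels([])
        assert cen.n_monomer == cen.n_dimer == 0
        assert cen.dimer_fraction is None

    def test_other_excluded_from_denominator(self):
        cen = census_from_labels(["monomer", "dimer", "other", "other"])
        assert cen.dimer_fraction == pytest.approx(0.5)

    @given(st.lists(st.sampled_from(["monomer", "dimer", "other"]), max_size=40))
    def test_permutation_invariance(self, labels):
        cen1 = census_from_labels(labels)
        cen2 = census_from_labels(labels[::-1])
        assert (cen1.n_monomer, cen1.n_dimer, cen1.n_other) == \
            (cen2.n_monomer, cen2.n_dimer, cen2.n_other)

    def test_generated_sample_census_matches_truth(self):
        sample = oq.generate_length_sample(273, 0.21, length_cv=0.05, seed=8)
        cen = oq.census_from_lengths([x for x, _ in sample])
        assert cen.dimer_fraction == pytest.approx(57 / 273, abs=0.02)


class TestPredictContourLength:
    def test_monomer_design_length(self):
        # 32 segments of 42 bp at 0.34 nm/bp
        length = oq.predict_contour_length(32, 42, 0.34)
        assert length == pytest.approx(456.96)
        assert oq.round_sig(length) == 460.0

    def test_dimer_design_length(self):
        # two 32-segment halves plus a 2/3-segment splint: 64 2/3 segments
        length = oq.predict_contour_length(64 + 2 / 3, 42, 0.34)
        assert length == pytest.approx(923.44, abs=0.005)
        assert oq.round_sig(length) == 920.0

    def test_zero_segments(self):
        assert oq.predict_contour_length(0, 42, 0.34) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            oq.predict_contour_length(-1, 42, 0.34)


class TestEndToEnd:
    def test_detect_measure_classify_recovers_mix(self):
        spec = oq.SceneSpec(width_px=512, height_px=512, n_monomers=4,
                            n_dimers=4, n_staples=0, seed=12)
        hm, _ = oq.generate_afm_scene(spec)
        _, cen = oq.analyze_map(hm, 1.0)
        assert cen.n_monomer == 4 and cen.n_dimer == 4
        assert cen.dimer_fraction == pytest.approx(0.5, abs=0.05)
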