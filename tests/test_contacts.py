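"""ER-mitochondria contact extraction, GAP binning and coverage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import interval_union_length, point_to_polygon_distance

from mitoquant.contacts import (
    AnnotatedScene,
    ContactSite,
    bin_gaps,
    extract_contacts,
    sample_distances,
    summarize,
)
from mitoquant.synthetic import EMSceneSpec, gen_em_scene


def _square(cx, cy, half):
    return np.array(
        [[cx - half, cy - half], [cx + half, cy - half],
         [cx + half, cy + half], [cx - half, cy + half]]
    )


class TestSampleDistances:
    def test_parallel_segment_constant_offset(self):
        mito = _square(0, 0, 100)
        er = np.array([[-80.0, 130.0], [80.0, 130.0]])  # 30 nm above the top edge
        out = sample_distances(er, [mito], step_nm=5.0)
        assert np.allclose(out.distance_nm, 30.0, atol=0.5)

    def test_point_on_boundary_distance_zero(self):
        mito = _square(0, 0, 100)
        er = np.array([[100.0, -50.0], [100.0, 50.0]])  # along the right edge
        out = sample_distances(er, [mito], step_nm=10.0)
        assert np.allclose(out.distance_nm, 0.0, atol=1e-9)

    def test_interior_point_distance_zero(self):
        mito = _square(0, 0, 100)
        er = np.array([[-20.0, 0.0], [20.0, 0.0]])
        out = sample_distances(er, [mito], step_nm=10.0)
        assert np.allclose(out.distance_nm, 0.0)

    def test_nearest_mito_id_matches_brute_force(self):
        m0, m1 = _square(-200, 0, 100), _square(205, 0, 100)
        er = np.array([[-2.0, -50.0], [-2.0, 50.0]])  # slightly nearer m0
        out = sample_distances(er, [m0, m1], step_nm=25.0)
        for row in out.itertuples():
            pt = np.array([-2.0, row.arc_nm - 50.0])
            d0 = point_to_polygon_distance(pt, m0)
            d1 = point_to_polygon_distance(pt, m1)
            assert row.nearest_mito == (0 if d0 <= d1 else 1)
            assert row.distance_nm == pytest.approx(min(d0, d1), abs=0.1)

    def test_empty_scene_raises(self):
        with pytest.raises(ValueError):
            sample_distances(np.array([[0.0, 0.0], [1.0, 1.0]]), [], 5.0)


class TestExtractContacts:
    def test_uniform_run(self):
        """A 200 nm run at constant 20 nm gives one contact in [15,30)."""
        mito = _square(0, 0, 100)
        scene = AnnotatedScene([mito], [np.array([[-100.0, 120.0], [100.0, 120.0]])])
        cs = extract_contacts(scene, step_nm=5.0)
        assert len(cs) == 1
        c = cs[0]
        assert c.length_nm == pytest.approx(200.0, abs=10.0)
        assert c.gap_nm == pytest.approx(20.0, abs=0.5)
        assert c.gap_bin == "15-30"

    def test_far_er_no_contacts(self):
        scene = AnnotatedScene(
            [_square(0, 0, 100)], [np.array([[-100.0, 200.0], [100.0, 200.0]])]
        )
        assert extract_contacts(scene, step_nm=5.0) == []

    def test_two_dips_two_contacts(self):
        """An ER trace dipping under 60 nm twice yields two contacts; the
        run structure matches a direct scan of the sampled sequence."""
        mito = _square(0, 0, 100)
        xs = np.linspace(-150, 150, 61)
        ys = 140 + 80 * np.cos(xs / 150 * 2 * np.pi)  # two dips toward the surface
        er = np.column_stack([xs, ys])
        scene = AnnotatedScene([mito], [er])
        cs = extract_contacts(scene, step_nm=5.0)
        samples = sample_distances(er, [mito], step_nm=5.0)
        near = samples.distance_nm.values <= 60.0
        runs = np.diff(np.concatenate([[0], near.astype(int), [0]]))
        assert len(cs) == (runs == 1).sum() == 2

    def test_run_splits_when_nearest_mito_changes(self):
        m0, m1 = _square(-110, 0, 100), _square(110, 0, 100)
        er = np.array([[-150.0, 120.0], [150.0, 120.0]])
        cs = extract_contacts(AnnotatedScene([m0, m1], [er]), step_nm=5.0)
        assert len(cs) == 2
        assert {c.mito_id for c in cs} == {0, 1}


class TestBinGaps:
    def test_one_contact_per_bin(self):
        cs = [
            ContactSite(i, 0, 0, 100.0, g, b, ())
            for i, (g, b) in enumerate([(5, "0-15"), (20, "15-30"), (45, "30-60")])
        ]
        assert bin_gaps(cs) == {"0-15": 1, "15-30": 1, "30-60": 1}

    def test_boundary_15_goes_right(self):
        c = ContactSite(0, 0, 0, 100.0, 15.0, "15-30", ())
        assert bin_gaps([c]) == {"0-15": 0, "15-30": 1, "30-60": 0}

    def test_empty(self):
        assert bin_gaps([]) == {"0-15": 0, "15-30": 0, "30-60": 0}

    def test_gap_above_60_raises(self):
        with pytest.raises(ValueError):
            bin_gaps([ContactSite(0, 0, 0, 100.0, 65.0, "30-60", ())])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(gaps=st.lists(st.floats(0.0, 60.0), max_size=20))
    def test_partition(self, gaps):
        cs = [ContactSite(i, 0, 0, 1.0, g, "", ()) for i, g in enumerate(gaps)]
        assert sum(bin_gaps(cs).values()) == len(gaps)


class TestSummarize:
    def test_coverage_by_construction(self):
        s = gen_em_scene(
            EMSceneSpec(n_mito=1, mito_radius_nm=400,
                        er_segments=((0, 20.0, 0.2 * 2 * np.pi * 420),), seed=1)
        )
        out = summarize(extract_contacts(s.scene, step_nm=5.0), s.scene)
        assert out.percent_perimeter_covered == pytest.approx(20.0, abs=1.0)
        assert out.contacts_per_mito == 1.0

    def test_overlapping_arcs_use_union(self):
        """Two ER traces over the same perimeter stretch are not double
        counted (checked against a discretized interval-union oracle)."""
        mito = _square(0, 0, 100)
        er_a = np.array([[-80.0, 110.0], [40.0, 110.0]])
        er_b = np.array([[-40.0, 120.0], [80.0, 120.0]])
        scene = AnnotatedScene([mito], [er_a, er_b])
        cs = extract_contacts(scene, step_nm=5.0)
        out = summarize(cs, scene)
        intervals = [iv for c in cs for iv in c.projected_arcs]
        oracle = interval_union_length(intervals)
        assert out.percent_perimeter_covered == pytest.approx(100 * oracle / 800.0, abs=0.5)
        assert out.percent_perimeter_covered < 100.0

    def test_contacts_per_mito(self):
        s = gen_em_scene(
            EMSceneSpec(n_mito=2,
                        er_segments=((0, 10.0, 300.0), (0, 40.0, 300.0), (1, 25.0, 300.0)),
                        seed=2)
        )
        out = summarize(extract_contacts(s.scene), s.scene)
        assert out.contacts_per_mito == pytest.approx(1.5)

    def test_step_halving_converges(self):
        s = gen_em_scene(EMSceneSpec(seed=3))
        a = summarize(extract_contacts(s.scene, step_nm=5.0), s.scene)
        b = summarize(extract_contacts(s.scene, step_nm=2.5), s.scene)
        assert b.mean_contact_length_nm == pytest.approx(a.mean_contact_length_nm, rel=0.01)
        assert b.percent_perimeter_covered == pytest.approx(a.percent_perimeter_covered, rel=0.01)

    def test_no_mitochondria_raises(self):
        with pytest.raises(ValueError):
            summarize([], AnnotatedScene([], []))
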