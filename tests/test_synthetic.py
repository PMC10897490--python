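"""The synthetic generators and the consistency of their ground truth."""

import numpy as np
import pytest

from oracles import moment_ar

from mitoquant.synthetic import (
    EMSceneSpec,
    MorphologySpec,
    PAGFPSpec,
    PlacementError,
    TimelapseSpec,
    gen_em_scene,
    gen_morphology_image,
    gen_pagfp_series,
    gen_timelapse,
)


class TestMorphologyGenerator:
    def test_blob_only_cell_is_fragmented_with_unit_ar(self):
        s = gen_morphology_image(
            MorphologySpec(n_tubules=0, n_blobs=20, psf_sigma_px=0,
                           gaussian_sd=0, poisson_scale=0, seed=1)
        )
        assert s.true_class == "Fragmented"
        assert np.allclose(s.objects.true_ar, 1.0, atol=0.05)

    def test_tubule_ar_matches_moment_oracle(self):
        """True tubule ARs equal a brute-force moment oracle on the mask."""
        s = gen_morphology_image(MorphologySpec(n_tubules=20, n_blobs=0, seed=2))
        assert s.true_class == "Elongated"
        for row in s.objects.itertuples():
            oracle = moment_ar(s.labels == row.object_id)
            assert row.true_ar == pytest.approx(oracle, rel=0.02)

    def test_same_seed_bitwise_identical(self):
        spec = MorphologySpec(seed=7)
        a, b = gen_morphology_image(spec), gen_morphology_image(spec)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.labels, b.labels)

    def test_objects_clear_of_borders(self):
        s = gen_morphology_image(MorphologySpec(seed=3))
        assert not s.labels[0].any() and not s.labels[-1].any()
        assert not s.labels[:, 0].any() and not s.labels[:, -1].any()

    def test_impossible_packing_raises(self):
        with pytest.raises(PlacementError):
            gen_morphology_image(
                MorphologySpec(n_tubules=0, n_blobs=200, blob_radius_px=10,
                               image_size_px=(96, 96), seed=0)
            )

    def test_curved_tubule_ar_close_to_straight_tube(self):
        """Bounded curvature keeps each tubule's AR within ~5% of the same
        tube rendered without the bow (both measured by the moment oracle)."""
        from mitoquant.synthetic import _tubule_mask

        s = gen_morphology_image(MorphologySpec(n_tubules=15, n_blobs=0, seed=11))
        up = 4  # supersample so pixelation noise does not mask the curvature effect
        for row in s.objects.itertuples():
            patch = int(up * (row.length_px + row.width_px + 6))
            curved = _tubule_mask(up * row.length_px, up * row.width_px,
                                  up * row.bow_px, row.angle_rad, patch)
            straight = _tubule_mask(up * row.length_px, up * row.width_px, 0.0,
                                    row.angle_rad, patch)
            assert moment_ar(curved) == pytest.approx(moment_ar(straight), rel=0.05)


class TestTimelapseGenerator:
    def test_spot_frame_count_matches_dwell(self):
        """An 18 s dwell at 3 s/frame puts the spot on 7 consecutive frames."""
        s = gen_timelapse(TimelapseSpec(n_events=1, dwell_dist=("point", 18.0),
                                        gaussian_sd=0, seed=4))
        e = s.events.iloc[0]
        assert e.end_frame - e.start_frame == 6
        spot_frames = [t for t in range(s.stack.shape[0]) if s.stack[t, 0].max() > 50]
        assert spot_frames == list(range(int(e.start_frame), int(e.end_frame) + 1))

    def test_all_fused_reduces_object_count(self):
        from scipy import ndimage as ndi
        s = gen_timelapse(TimelapseSpec(n_events=4, p_fusion=1.0, seed=5))
        assert (s.events.outcome == "fused").all()
        first = ndi.label(s.stack[0, 1] > 60)[1]
        last = ndi.label(s.stack[-1, 1] > 60)[1]
        assert first == 8 and last == 4

    def test_point_mass_dwell_exact(self):
        s = gen_timelapse(TimelapseSpec(n_events=8, dwell_dist=("point", 30.0), seed=6))
        assert (s.events.duration_s == 30.0).all()

    def test_too_long_event_raises(self):
        with pytest.raises(ValueError):
            gen_timelapse(TimelapseSpec(n_frames=10, dwell_dist=("point", 300.0), seed=0))

    def test_determinism(self):
        spec = TimelapseSpec(n_events=2, seed=8)
        assert np.array_equal(gen_timelapse(spec).stack, gen_timelapse(spec).stack)


class TestEMSceneGenerator:
    def test_truth_table_respects_60nm_rule(self):
        s = gen_em_scene(
            EMSceneSpec(n_mito=2, er_segments=((0, 20.0, 400.0), (1, 100.0, 400.0)), seed=1)
        )
        assert len(s.contacts) == 1
        assert s.contacts.iloc[0].gap_nm == 20.0
        assert len(s.scene.er_polylines) == 2  # far segment still drawn

    def test_programmed_bins(self):
        s = gen_em_scene(
            EMSceneSpec(n_mito=1, er_segments=((0, 10.0, 300.0), (0, 40.0, 300.0)), seed=2)
        )
        assert sorted(s.contacts.gap_bin) == ["0-15", "30-60"]

    def test_coverage_fraction_by_construction(self):
        """One arc spanning 20% of the perimeter angle covers 20%."""
        R = 400.0
        s = gen_em_scene(EMSceneSpec(n_mito=1, mito_radius_nm=R,
                                     er_segments=((0, 20.0, 0.2 * 2 * np.pi * (R + 20)),),
                                     seed=3))
        assert s.summary["percent_perimeter_covered"] == pytest.approx(20.0, abs=0.1)

    def test_determinism(self):
        spec = EMSceneSpec(seed=9)
        a, b = gen_em_scene(spec), gen_em_scene(spec)
        for pa, pb in zip(a.scene.er_polylines, b.scene.er_polylines):
            assert np.array_equal(pa, pb)


class TestPAGFPGenerator:
    def test_no_spread_truth_flat(self):
        s = gen_pagfp_series(PAGFPSpec(roi_fraction=0.2, spread_fractions=(0.2, 0.2, 0.2), seed=1))
        assert np.allclose(s.true_normalized_area, 1.0)

    def test_spread_ratios(self):
        s = gen_pagfp_series(PAGFPSpec(roi_fraction=0.2, spread_fractions=(0.2, 0.6, 1.0), seed=2))
        assert s.true_normalized_area == pytest.approx([1.0, 3.0, 5.0], rel=0.05)

    def test_containment_bound(self):
        """Spread never exceeds component area over initial ROI area."""
        s = gen_pagfp_series(PAGFPSpec(roi_fraction=0.25, spread_fractions=(0.25, 0.8, 1.0), seed=3))
        roi_area = (s.roi[1] - s.roi[0]) * (s.roi[3] - s.roi[2])
        comp_area = s.mito_mask[s.roi[0]:s.roi[1], :].sum()
        assert s.true_normalized_area[-1] <= comp_area / roi_area + 1e-9

    def test_invalid_specs_raise(self):
        with pytest.raises(ValueError):
            PAGFPSpec(activated_component=5)
        with pytest.raises(ValueError):
            PAGFPSpec(spread_fractions=(0.2, 0.1, 0.3))
        with pytest.raises(ValueError):
            PAGFPSpec(roi_fraction=0.3, spread_fractions=(0.2, 0.5, 0.8))
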