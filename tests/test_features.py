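"""Segmentation, 101-point normalization, statistics and feature matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imugait.core import SIDES, SensorStream, Trial
from imugait.events import GaitEvent, GaitSequence
from imugait.features import (
    MODES,
    build_feature_matrix,
    extract_trial_features,
    feature_manifest,
    segment_cycle,
    time_domain_stats,
    time_normalize,
)


class TestSegmentCycle:
    def test_half_open_convention_on_a_ramp(self):
        ramp = np.arange(100)
        seg = segment_cycle(ramp, 10, 20)
        np.testing.assert_array_equal(seg, np.arange(10, 20))

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            segment_cycle(np.arange(100), 10, 10)
        with pytest.raises(ValueError):
            segment_cycle(np.arange(100), 90, 110)

    def test_consecutive_cycles_tile_without_overlap(self):
        x = np.arange(50)
        a = segment_cycle(x, 0, 20)
        b = segment_cycle(x, 20, 50)
        np.testing.assert_array_equal(np.concatenate([a, b]), x)

    def test_simulator_stride_contains_one_midswing(self, quiet_filtered, quiet_sequence):
        filtered, truth = quiet_filtered
        for side in SIDES:
            lo, hi = quiet_sequence.stride_bounds(side)
            inside = [(m, lo < m < hi) for m in truth.ms[side]]
            assert sum(flag for _, flag in inside) == 1


class TestTimeNormalize:
    def test_output_length_101_and_endpoints_preserved(self, rng):
        seg = rng.normal(size=137)
        out = time_normalize(seg)
        assert len(out) == 101
        assert out[0] == seg[0] and out[-1] == seg[-1]

    def test_identity_on_101_point_input(self, rng):
        seg = rng.normal(size=101)
        np.testing.assert_allclose(time_normalize(seg), seg, atol=1e-12)

    def test_linear_ramp_stays_linear(self):
        out = time_normalize(np.linspace(0, 1, 50))
        np.testing.assert_allclose(out, np.linspace(0, 1, 101), atol=1e-9)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            time_normalize(np.array([1.0]))

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(2, 400))
    def test_endpoint_preservation_property(self, n):
        seg = np.sin(np.arange(n) * 0.37) + np.arange(n) * 0.01
        out = time_normalize(seg)
        assert len(out) == 101
        assert out[0] == pytest.approx(seg[0], abs=1e-12)
        assert out[-1] == pytest.approx(seg[-1], abs=1e-12)
        # interpolation never exceeds the segment's range
        assert out.min() >= seg.min() - 1e-12 and out.max() <= seg.max() + 1e-12


class TestTimeDomainStats:
    def test_constant_cycle(self):
        s = time_domain_stats(np.full(101, 5.0))
        assert s == {"mean": 5.0, "variance": 0.0, "kurtosis": 0.0, "std": 0.0}

    def test_hand_computed_small_sample(self):
        # population moments of {1,2,3,4,5}
        s = time_domain_stats(np.array([1.0, 2, 3, 4, 5]))
        assert s["mean"] == pytest.approx(3.0)
        assert s["variance"] == pytest.approx(2.0)
        assert s["std"] == pytest.approx(np.sqrt(2.0))
        assert s["variance"] == pytest.approx(s["std"] ** 2)

    def test_sample_variance_option(self):
        s = time_domain_stats(np.array([1.0, 2, 3, 4, 5]), population=False)
        assert s["variance"] == pytest.approx(2.5)

    def test_gaussian_kurtosis_near_zero(self, rng):
        s = time_domain_stats(rng.normal(size=100_000))
        assert abs(s["kurtosis"]) < 0.1


class TestFeatureMatrix:
    @pytest.mark.parametrize(
        "mode,n_cols",
        [
            ("time_domain", 192),
            ("temporal", 17),
            ("combined", 209),
            ("placement:L5", 65),
            ("placement:foot", 65),
            ("placement:shank", 65),
            ("placement:thigh", 65),
        ],
    )
    def test_manifest_column_counts(self, mode, n_cols):
        manifest = feature_manifest(mode)
        assert len(manifest) == n_cols
        assert len(set(manifest)) == n_cols  # unique names

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            feature_manifest("frequency_domain")

    @pytest.mark.parametrize("mode", MODES)
    def test_extracted_row_matches_manifest(self, quiet_filtered, quiet_sequence, mode):
        filtered, _ = quiet_filtered
        row = extract_trial_features(filtered, quiet_sequence, mode)
        assert list(row.index) == feature_manifest(mode)
        assert np.isfinite(row.to_numpy(dtype=float)).all()

    def test_l5_contributes_to_both_strides(self):
        manifest = feature_manifest("time_domain")
        assert sum(n.startswith("strideR_L5") for n in manifest) == 24
        assert sum(n.startswith("strideL_L5") for n in manifest) == 24
        # unilateral sensors only contribute to their own side's stride
        assert not any("strideR_foot_L" in n for n in manifest)
        assert not any("strideL_shank_R" in n for n in manifest)

    def test_cohort_matrix_shape_and_labels(self, cohort_features_combined):
        fm = cohort_features_combined
        assert fm.frame.shape[1] == 209
        assert set(fm.labels) == {"healthy", "stroke", "other_neuro"}
        assert not fm.frame.isna().any().any()

    def test_side_permutation_permutes_feature_columns(self, quiet_filtered, quiet_sequence):
        # metamorphic: mirroring L<->R streams and event sides maps each
        # stride-side feature onto its mirrored counterpart
        filtered, _ = quiet_filtered

        def flip(name: str) -> str:
            import re

            name = re.sub(
                r"(foot|shank|thigh)_(L|R)",
                lambda m: f"{m.group(1)}_{'R' if m.group(2) == 'L' else 'L'}",
                name,
            )
            return re.sub(
                r"stride(L|R)",
                lambda m: f"stride{'R' if m.group(1) == 'L' else 'L'}",
                name,
            )

        mirrored_streams = {}
        for p, s in filtered.streams.items():
            q = flip(p) if p != "L5" else p
            mirrored_streams[q] = SensorStream(q, s.accel.copy(), s.gyro.copy(), s.fs)
        mirrored = Trial("m", "m", filtered.group_label, mirrored_streams)
        swapped = GaitSequence(
            [
                GaitEvent(e.time, e.index, "L" if e.side == "R" else "R", e.kind)
                for e in quiet_sequence.events
            ],
            quiet_sequence.fs,
        )
        base = extract_trial_features(filtered, quiet_sequence, "time_domain")
        perm = extract_trial_features(mirrored, swapped, "time_domain")
        for name in base.index:
            assert perm[flip(name)] == pytest.approx(base[name], rel=1e-12)

    def test_build_feature_matrix_row_per_trial(self, cohort_pairs):
        pairs, _ = cohort_pairs
        fm = build_feature_matrix(pairs, mode="temporal")
        assert fm.frame.shape == (len(pairs), 17)
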