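import math

import numpy as np
import pytest

from dyadmotion.features import silence_ratio
from dyadmotion.mocap_io import ExcessMissingDataError, interpolate_missing
from dyadmotion.rating_stats import spearman
from dyadmotion.synthetic import (
    COUPLING_LABELS,
    GroundTruth,
    SyntheticDyadSpec,
    SyntheticSpecError,
    classify_onsets,
    generate_cohort,
    generate_dyad,
    inject_missing,
)


class TestGenerateDyad:
    def test_single_planted_movement_moves_only_inside_interval(self):
        spec = SyntheticDyadSpec(
            duration_s=20.0, seed=0, noise_sd_m=0.0, spike_rate_per_min=0.0,
            mother_episodes=[(10.0, 12.0)], infant_episodes=[],
        )
        mother, infant, gt = generate_dyad(spec)
        fs = spec.sampling_rate_hz
        disp = np.linalg.norm(mother.positions - mother.positions[0], axis=2)
        before = disp[: int(10 * fs)]
        after = disp[int(12 * fs) + 1 :]
        inside = disp[int(10.5 * fs) : int(11.5 * fs)]
        assert np.abs(before).max() < 1e-12
        assert np.allclose(after, after[0])  # static at the displaced position
        assert inside.max() > 0.05
        assert np.abs(infant.positions - infant.positions[0]).max() < 1e-12
        assert np.allclose(gt.mother_segments, [[10.0, 12.0]])

    def test_deterministic_given_seed(self):
        spec = dict(duration_s=25.0, seed=42, p_co=0.4, p_alt=0.3,
                    spike_rate_per_min=3.0, missing_fraction=0.02)
        a = generate_dyad(SyntheticDyadSpec(**spec))
        b = generate_dyad(SyntheticDyadSpec(**spec))
        for x, y in zip(a[:2], b[:2]):
            assert np.array_equal(x.positions, y.positions, equal_nan=True)
            assert np.array_equal(x.validity, y.validity)
        assert a[2].to_json() == b[2].to_json()

    def test_different_seed_differs(self):
        a = generate_dyad(SyntheticDyadSpec(duration_s=25.0, seed=1))
        b = generate_dyad(SyntheticDyadSpec(duration_s=25.0, seed=2))
        assert not np.array_equal(a[0].positions, b[0].positions)

    def test_planted_durations_and_gaps_survive_cleaning_floor(self):
        _, _, gt = generate_dyad(SyntheticDyadSpec(duration_s=120.0, seed=5, p_co=0.5, p_alt=0.3))
        for seg in (gt.mother_segments, gt.infant_segments):
            assert (seg[:, 1] - seg[:, 0] >= 0.5 - 1 / 240).all()
            if len(seg) > 1:
                assert (seg[1:, 0] - seg[:-1, 1] >= 0.5 - 1 / 240).all()

    def test_full_coactive_coupling_fixed_latency(self):
        """p_co = 1 with fixed 0.5 s latency: every infant onset is 0.5 s after
        a mother onset while she is still moving; labels all coactive and
        consistent with an exhaustive interval check of the definitions."""
        spec = SyntheticDyadSpec(
            duration_s=120.0, seed=9, p_co=1.0, latency_min_s=0.5, latency_max_s=0.5,
            noise_sd_m=0.0,
        )
        _, _, gt = generate_dyad(spec)
        assert len(gt.infant_segments) >= 5
        assert all(lab == "coactive" for lab in gt.infant_labels)
        assert np.allclose(gt.infant_latencies, 0.5, atol=1 / 240)
        for t_on in gt.infant_segments[:, 0]:
            host = [
                (on, off) for on, off in gt.mother_segments if on <= t_on < off
            ]
            assert len(host) == 1
            assert t_on - host[0][0] == pytest.approx(0.5, abs=1 / 240)
        assert classify_onsets(gt.infant_segments, gt.mother_segments) == gt.infant_labels

    def test_planted_labels_agree_with_definition_check(self):
        _, _, gt = generate_dyad(
            SyntheticDyadSpec(duration_s=120.0, seed=3, p_co=0.4, p_alt=0.4)
        )
        assert set(gt.infant_labels) <= set(COUPLING_LABELS)
        assert classify_onsets(gt.infant_segments, gt.mother_segments) == gt.infant_labels

    @pytest.mark.parametrize(
        "field,value",
        [
            ("duration_s", -1.0),
            ("p_co", 0.8),  # together with p_alt=0.5 sums above 1
            ("latency_max_s", 2.0),
            ("noise_sd_m", -0.1),
            ("missing_fraction", 1.5),
            ("min_duration_s", 0.2),
        ],
    )
    def test_invalid_spec_names_field(self, field, value):
        kwargs = {"p_alt": 0.5} if field == "p_co" else {}
        kwargs[field] = value
        with pytest.raises(SyntheticSpecError, match=field.split("_")[0]):
            generate_dyad(SyntheticDyadSpec(**kwargs))

    def test_ground_truth_json_roundtrip(self):
        _, _, gt = generate_dyad(SyntheticDyadSpec(duration_s=30.0, seed=2, p_co=0.5))
        back = GroundTruth.from_json(gt.to_json())
        assert np.allclose(back.infant_segments, gt.infant_segments)
        assert back.infant_labels == gt.infant_labels


class TestInjectMissing:
    def base(self, n=300 * 240 // 10):
        spec = SyntheticDyadSpec(duration_s=30.0, seed=0, noise_sd_m=0.0)
        return generate_dyad(spec)[0]

    def test_zero_fraction_identity(self):
        mts = self.base()
        out = inject_missing(mts, 0.0, 0.5, seed=1)
        assert np.array_equal(out.positions, mts.positions)
        assert out.validity.all()

    def test_fraction_respected_within_one_run(self):
        mts = self.base()
        out = inject_missing(mts, 0.04, 0.5, seed=1)
        run = int(0.5 * 240)
        for j in range(out.n_markers):
            missing = (~out.validity[:, j]).sum()
            assert missing <= 0.04 * out.n_frames + run
            assert missing >= 0.04 * out.n_frames - run
        valid = out.validity
        assert np.array_equal(out.positions[valid], mts.positions[valid])

    def test_four_percent_accepted_ten_percent_rejected(self):
        mts = self.base()
        ok = inject_missing(mts, 0.04, 0.5, seed=2)
        interpolate_missing(ok)  # must not raise
        bad = inject_missing(mts, 0.10, 0.5, seed=2)
        with pytest.raises(ExcessMissingDataError):
            interpolate_missing(bad)

    def test_invalid_fraction_raises(self):
        with pytest.raises(SyntheticSpecError, match="missing_fraction"):
            inject_missing(self.base(), 1.2, 0.5, seed=0)


class TestGenerateCohort:
    def ground_truth_silence(self, dyad):
        dyad.realize() if dyad.ground_truth is None else None
        gt = dyad.ground_truth
        return silence_ratio(gt.segment_list("infant"), gt.segment_list("mother"))

    def gt_silence_from_spec(self, dyad):
        # silence straight from the planted schedules (no rendering needed)
        from dyadmotion.segmentation import MovementSegmentList

        w = (0.0, dyad.spec.duration_s)
        inf = MovementSegmentList("infant", "upper_body", w, np.array(dyad.spec.infant_episodes))
        mot = MovementSegmentList("mother", "upper_body", w, np.array(dyad.spec.mother_episodes))
        return silence_ratio(inf, mot)

    def test_unknown_target_lists_valid_names(self):
        with pytest.raises(SyntheticSpecError, match="silence_ratio"):
            generate_cohort(10, "sparkle_ratio", 0.5, seed=0)

    def test_planted_rho_one_monotone_by_construction(self):
        dyads, ratings = generate_cohort(30, "silence_ratio", 1.0, seed=0)
        silences = [self.gt_silence_from_spec(d) for d in dyads]
        rho, _ = spearman(silences, ratings["synthetic_composite"].to_numpy())
        assert rho == 1.0

    def test_planted_rho_zero_null_bound(self):
        n = 40
        hits = 0
        for seed in range(20):
            dyads, ratings = generate_cohort(n, "silence_ratio", 0.0, seed=seed)
            silences = [self.gt_silence_from_spec(d) for d in dyads]
            rho, _ = spearman(silences, ratings["synthetic_composite"].to_numpy())
            hits += abs(rho) < 2 / math.sqrt(n)
        assert hits >= 16  # ~95% nominal; allow binomial slack

    def test_planted_rho_recovered_at_large_n(self):
        dyads, ratings = generate_cohort(200, "silence_ratio", 0.6, seed=7)
        silences = [self.gt_silence_from_spec(d) for d in dyads]
        rho, _ = spearman(silences, ratings["synthetic_composite"].to_numpy())
        assert rho == pytest.approx(0.6, abs=0.12)

    def test_composite_on_rating_scale(self):
        _, ratings = generate_cohort(50, "overlap_ratio", -0.4, seed=1)
        vals = ratings["synthetic_composite"]
        assert (vals > 1).all() and (vals < 5).all()

    def test_preconditions(self):
        with pytest.raises(SyntheticSpecError, match="rho"):
            generate_cohort(10, "silence_ratio", 1.2, seed=0)
        with pytest.raises(SyntheticSpecError, match="n_dyads"):
            generate_cohort(2, "silence_ratio", 0.5, seed=0)
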