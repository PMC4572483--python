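import itertools
import math

import numpy as np
import pandas as pd
import pytest

from oculokit.io_types import FixationEvent
from oculokit.saccade_metrics import (
    amplitude_error,
    count_trial_saccades,
    gap_overlap_effect,
    identify_main_saccade,
    removal_rate,
    saccade_latency,
    sqrt_transform_trim,
    time_to_first_target_fixation,
)

from .conftest import make_saccade, make_saccade_trial


def fix(onset, offset, xy):
    return FixationEvent(onset, offset, tuple(map(float, xy)))


class TestTimeToFirstFixation:
    def test_basic_arithmetic(self):
        trial = make_saccade_trial(target=(10.0, 0.0), condition="overlap")  # onset 300
        fixations = [fix(0, 280, (0, 0)), fix(650, 1200, (9.8, 0.3))]
        assert time_to_first_target_fixation(trial, fixations) == 350.0

    def test_never_on_target(self):
        trial = make_saccade_trial(target=(10.0, 0.0))
        fixations = [fix(0, 700, (0, 0)), fix(900, 5000, (5.0, 0.0))]
        assert time_to_first_target_fixation(trial, fixations) is None

    def test_ongoing_fixation_clamped_to_zero(self):
        trial = make_saccade_trial(target=(2.0, 0.0), condition="gap")  # onset 700
        fixations = [fix(0, 3000, (1.0, 0.0))]  # within 2.5 deg of (2, 0) all along
        assert time_to_first_target_fixation(trial, fixations) == 0.0

    def test_outside_response_window(self):
        trial = make_saccade_trial(target=(10.0, 0.0), condition="gap")
        fixations = [fix(700 + 5500, 9000, (10.0, 0.0))]
        assert time_to_first_target_fixation(trial, fixations) is None

    def test_radius_is_inclusive_boundary(self):
        trial = make_saccade_trial(target=(10.0, 0.0), condition="gap")
        fixations = [fix(1000, 2000, (7.5, 0.0))]  # exactly 2.5 away
        assert time_to_first_target_fixation(trial, fixations) == 300.0


class TestIdentifyMainSaccade:
    def test_single_clean_saccade_selected(self):
        trial = make_saccade_trial(target=(10.0, 0.0), condition="gap")  # onset 700
        s = make_saccade(900, 950, (0.1, 0.0), (9.5, 0.2), ordinal=1)
        res = identify_main_saccade(trial, [s])
        assert res.status == "selected"
        assert res.latency_ms == 200.0
        assert res.saccade.ordinal == 1

    def test_pre_target_saccade_skipped(self):
        trial = make_saccade_trial(target=(10.0, 0.0), condition="gap")
        s1 = make_saccade(650, 690, (0, 0), (3.0, 0.0), ordinal=1)  # before onset 700
        s2 = make_saccade(900, 950, (0.1, 0.0), (9.5, 0.0), ordinal=2)
        res = identify_main_saccade(trial, [s1, s2])
        assert res.status == "selected"
        assert res.saccade is s2

    def test_sixth_saccade_discards_trial(self):
        trial = make_saccade_trial(target=(10.0, 0.0), condition="gap")
        events = [make_saccade(750, 780, (0, 0), (0, 1.0), ordinal=1)]  # 90 deg off
        for k in range(2, 6):  # ordinals 2..5 contain blinks
            events.append(make_saccade(800 + 100 * k, 830 + 100 * k, (0.2, 0),
                                       (5.0, 0.1), contains_blink=True, ordinal=k))
        events.append(make_saccade(1500, 1550, (0.2, 0), (9.6, 0.1), ordinal=6))
        res = identify_main_saccade(trial, events)
        assert res.status == "discarded"

    def test_start_too_far_from_centre_removed(self):
        trial = make_saccade_trial(target=(10.0, 0.0), condition="gap")
        s = make_saccade(900, 950, (3.0, 0.0), (9.5, 0.0), ordinal=1)
        res = identify_main_saccade(trial, [s])
        assert res.status == "no_candidate"

    def test_wrong_direction_removed(self):
        trial = make_saccade_trial(target=(10.0, 0.0), condition="gap")
        s = make_saccade(900, 950, (0.0, 0.0), (-9.5, 0.0), ordinal=1)
        assert identify_main_saccade(trial, [s]).status == "no_candidate"

    def test_filter_order_insensitive(self, rng):
        # the four removal rules are independent predicates: any application
        # order yields the same survivor set
        trial = make_saccade_trial(target=(10.0, 0.0), condition="gap")

        def predicates(trial):
            return [
                lambda s: not s.contains_blink,
                lambda s: s.onset_ms >= trial.target_onset_ms,
                lambda s: math.hypot(*s.start_xy) <= 2.5,
                lambda s: _direction_ok(s, trial),
            ]

        def _direction_ok(s, trial):
            dx, dy = s.displacement
            tx, ty = trial.target_location
            n1, n2 = math.hypot(dx, dy), math.hypot(tx, ty)
            if n1 == 0:
                return False
            cos = (dx * tx + dy * ty) / (n1 * n2)
            return math.degrees(math.acos(max(-1, min(1, cos)))) <= 45.0

        for _ in range(50):
            events = []
            t = 600.0
            for k in range(1, rng.integers(1, 8).item() + 1):
                start = (rng.uniform(-4, 4), rng.uniform(-1, 1))
                end = (start[0] + rng.uniform(-12, 12), start[1] + rng.uniform(-3, 3))
                if math.hypot(end[0] - start[0], end[1] - start[1]) < 1e-6:
                    continue
                events.append(make_saccade(
                    t, t + 40, start, end,
                    contains_blink=bool(rng.random() < 0.2), ordinal=k,
                ))
                t += rng.uniform(100, 400)
            survivor_sets = []
            for order in itertools.permutations(range(4)):
                preds = predicates(trial)
                remaining = [
                    s for s in events if all(preds[i](s) for i in order)
                ]
                survivor_sets.append(tuple(id(s) for s in remaining))
            assert len(set(survivor_sets)) == 1
            # and the module agrees with the composed filter
            res = identify_main_saccade(trial, events)
            remaining = [s for s in events if all(p(s) for p in predicates(trial))]
            if not remaining:
                assert res.status == "no_candidate"
            elif remaining[0].ordinal > 5:
                assert res.status == "discarded"
            else:
                assert res.saccade is remaining[0]


class TestLatencyAndAmplitudeError:
    def test_latency(self):
        trial = make_saccade_trial(target=(10.0, 0.0), condition="overlap")  # onset 300
        s = make_saccade(520, 570, (0, 0), (9.5, 0), ordinal=1)
        res = identify_main_saccade(trial, [s])
        assert saccade_latency(res) == 220.0

    def test_latency_missing_when_removed(self):
        trial = make_saccade_trial(target=(10.0, 0.0))
        res = identify_main_saccade(trial, [])
        assert saccade_latency(res) is None
        assert amplitude_error(res, trial) is None

    @pytest.mark.parametrize(
        "amp,expected", [(10.0, 0.0), (7.5, -2.5), (11.0, 1.0)]
    )
    def test_amplitude_error_sign(self, amp, expected):
        trial = make_saccade_trial(target=(10.0, 0.0), condition="gap")
        s = make_saccade(900, 950, (0, 0), (amp, 0), ordinal=1)
        res = identify_main_saccade(trial, [s])
        assert amplitude_error(res, trial) == pytest.approx(expected)


class TestSqrtTransformTrim:
    def test_constant_vector_nothing_removed(self):
        vals = [100.0] * 6
        transformed, keep = sqrt_transform_trim(vals, ["a"] * 6)
        assert keep.all()
        np.testing.assert_allclose(transformed, 10.0)

    def test_single_outlier_removed(self):
        # note |z| can only exceed 2 for n >= 6 (max |z| is (n-1)/sqrt(n)),
        # so the base values are repeated around the one extreme entry
        vals = [100.0, 121.0, 144.0, 169.0] * 3 + [40_000.0]
        transformed, keep = sqrt_transform_trim(vals, ["a"] * 13)
        # reference recomputation with the plain formula
        z = (transformed - transformed.mean()) / transformed.std(ddof=1)
        assert (np.abs(z) > 2).sum() == 1
        assert keep.tolist() == [True] * 12 + [False]

    def test_idempotent_on_own_output(self):
        vals = [100.0, 121.0, 144.0, 169.0] * 3 + [40_000.0]
        _, keep = sqrt_transform_trim(vals, ["a"] * 13)
        vals2 = np.asarray(vals)[keep]
        _, keep2 = sqrt_transform_trim(vals2, ["a"] * len(vals2))
        assert keep2.all()

    def test_small_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="trim skipped"):
            _, keep = sqrt_transform_trim([1.0, 2.0], ["a", "a"])
        assert keep.all()

    def test_grouping_is_independent(self):
        vals = [100.0, 110.0, 105.0, 9.0, 10.0, 11.0]
        groups = ["a", "a", "a", "b", "b", "b"]
        _, keep = sqrt_transform_trim(vals, groups)
        assert keep.all()  # neither group has an outlier relative to itself

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sqrt_transform_trim([-1.0, 2.0, 3.0], ["a"] * 3)


class TestCountsAndRemoval:
    def test_count_after_target_onset(self):
        trial = make_saccade_trial(target=(10.0, 0.0), condition="gap")  # onset 700
        events = [
            make_saccade(600, 650, (0, 0), (3, 0)),           # before onset
            make_saccade(900, 950, (0, 0), (8, 0)),           # counts
            make_saccade(1200, 1250, (8, 0), (10.4, 0)),      # counts
            make_saccade(1500, 1550, (10.4, 0), (11.9, 0)),   # 1.5 deg, too small
            make_saccade(1800, 1850, (11.9, 0), (9.0, 0), contains_blink=True),
            make_saccade(2100, 2150, (9.0, 0), (12.0, 0)),    # counts
        ]
        assert count_trial_saccades(trial, events) == 3

    def test_count_matches_brute_force(self, rng):
        trial = make_saccade_trial(target=(10.0, 0.0), condition="gap")
        events = []
        t = 400.0
        for _ in range(25):
            amp = rng.uniform(0.5, 6.0)
            events.append(make_saccade(t, t + 40, (0, 0), (amp, 0),
                                       contains_blink=bool(rng.random() < 0.3)))
            t += rng.uniform(60, 300)
        expected = sum(
            1 for s in events
            if s.onset_ms >= 700.0 and not s.contains_blink and s.amplitude > 2.0
        )
        assert count_trial_saccades(trial, events) == expected

    def test_removal_rate(self):
        from oculokit.saccade_metrics import MainSaccadeResult

        results = [MainSaccadeResult(trial_id=str(i), status="selected")
                   for i in range(36)]
        results += [MainSaccadeResult(trial_id="d", status="discarded")] * 2
        results += [MainSaccadeResult(trial_id="n", status="no_candidate")] * 2
        assert removal_rate(results) == pytest.approx(0.10)
        assert removal_rate(results[:36]) == 0.0


class TestGapOverlapEffect:
    @staticmethod
    def rows(records):
        return pd.DataFrame(
            records, columns=["participant_id", "group", "condition", "value"]
        )

    def test_identical_conditions_zero_contrast(self):
        df = self.rows([
            ("p1", "g", "gap", 400.0), ("p1", "g", "overlap", 400.0),
            ("p2", "g", "gap", 300.0), ("p2", "g", "overlap", 300.0),
        ])
        per_part, per_group = gap_overlap_effect(df)
        assert (per_part["contrast"] == 0).all()
        assert per_group["mean"].iloc[0] == 0.0

    def test_antisymmetric_under_label_swap(self):
        df = self.rows([
            ("p1", "g", "gap", 250.0), ("p1", "g", "overlap", 420.0),
            ("p2", "g", "gap", 260.0), ("p2", "g", "overlap", 380.0),
        ])
        _, fwd = gap_overlap_effect(df)
        swapped = df.copy()
        swapped["condition"] = swapped["condition"].map(
            {"gap": "overlap", "overlap": "gap"}
        )
        _, rev = gap_overlap_effect(swapped)
        assert fwd["mean"].iloc[0] == pytest.approx(-rev["mean"].iloc[0])

    def test_participant_missing_condition_excluded(self):
        df = self.rows([
            ("p1", "g", "gap", 250.0), ("p1", "g", "overlap", 420.0),
            ("p2", "g", "gap", 260.0),
        ])
        with pytest.warns(UserWarning, match="missing a condition"):
            per_part, _ = gap_overlap_effect(df)
        assert list(per_part["participant_id"]) == ["p1"]
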