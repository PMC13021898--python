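"""Design generators: printed trial counts, congruence, timing, constraints."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from rsk import design as dsg
from rsk.kinematogram import KHAKI, LEFTWARD, RIGHTWARD, WHITE


def _trial(task, direction, majority, motion_c=0.95, color_c=0.95):
    return {
        "task": task,
        "direction": direction,
        "majority_color": majority,
        "motion_coherence": motion_c,
        "color_coherence": color_c,
    }


class TestSignedCongruence:
    def test_color_task_congruent_motion(self):
        # khaki -> left; 95% leftward motion supports the same (left) response
        t = _trial(dsg.COLOR, LEFTWARD, KHAKI)
        assert dsg.signed_distractor_congruence(t) == pytest.approx(95.0)

    def test_color_task_incongruent_motion(self):
        t = _trial(dsg.COLOR, RIGHTWARD, KHAKI)
        assert dsg.signed_distractor_congruence(t) == pytest.approx(-95.0)

    def test_motion_task_congruent_color(self):
        # rightward target; white maps to the right key under the default mapping
        t = _trial(dsg.MOTION, RIGHTWARD, WHITE)
        assert dsg.signed_distractor_congruence(t) == pytest.approx(95.0)

    def test_univalent_trial_rejected(self):
        with pytest.raises(dsg.UnivalentTrialError):
            dsg.signed_distractor_congruence(
                _trial(dsg.MOTION, LEFTWARD, KHAKI, motion_c=0.5, color_c=1.0)
            )
        with pytest.raises(dsg.UnivalentTrialError):
            dsg.signed_distractor_congruence(
                _trial(dsg.COLOR, LEFTWARD, KHAKI, motion_c=0.0)
            )

    @settings(derandomize=True, max_examples=60)
    @given(
        task=stn.sampled_from([dsg.MOTION, dsg.COLOR]),
        direction=stn.sampled_from([LEFTWARD, RIGHTWARD]),
        majority=stn.sampled_from([KHAKI, WHITE]),
        motion_c=stn.sampled_from([0.05, 0.45, 0.95]),
        color_c=stn.sampled_from([0.55, 0.75, 0.95]),
        flipped=stn.booleans(),
    )
    def test_antisymmetry(self, task, direction, majority, motion_c, color_c, flipped):
        """Flipping the distractor dimension or the color mapping flips the sign."""
        mapping = dsg.ResponseMapping(color_mapping_flipped=flipped)
        t = _trial(task, direction, majority, motion_c, color_c)
        base = dsg.signed_distractor_congruence(t, mapping)
        if task == dsg.COLOR:
            other = _trial(
                task,
                RIGHTWARD if direction == LEFTWARD else LEFTWARD,
                majority, motion_c, color_c,
            )
        else:
            other = _trial(
                task, direction,
                WHITE if majority == KHAKI else KHAKI,
                motion_c, color_c,
            )
        assert dsg.signed_distractor_congruence(other, mapping) == pytest.approx(-base)
        antimapping = dsg.ResponseMapping(color_mapping_flipped=not flipped)
        flipped_sign = dsg.signed_distractor_congruence(t, antimapping)
        assert flipped_sign == pytest.approx(-base)


class TestExperiment1:
    def test_exp1a_counts(self):
        plan = dsg.build_exp1a_design(seed=7)
        t = plan.trials
        assert len(t) == 120
        assert int((t["direction"] == LEFTWARD).sum()) == 60
        assert t.groupby("block_index").size().tolist() == [60, 60]
        # each of the 10 levels appears 12 times (2 colors x 6 replicates)
        assert t.groupby("motion_coherence").size().eq(12).all()
        assert (t["color_coherence"] == 1.0).all()
        assert t["congruent"].isna().all()

    def test_exp1b_counts(self):
        plan = dsg.build_exp1b_design(seed=7)
        t = plan.trials
        assert len(t) == 60
        assert (t["motion_coherence"] == 0.0).all()
        assert t["majority_color"].value_counts().tolist() == [30, 30]
        assert sorted(t["color_coherence"].unique()) == [0.55, 0.65, 0.75, 0.85, 0.95]

    def test_run_length_constraint(self):
        for seed in range(5):
            t = dsg.build_exp1a_design(seed=seed).trials
            for _, block in t.groupby("block_index"):
                assert dsg._max_run(block["correct_response"].tolist()) <= 4


@pytest.fixture(scope="module")
def plan():
    return dsg.build_exp2_design(seed=3, first_task=dsg.COLOR)


class TestExperiment2:
    def test_counts(self, plan):
        t = plan.trials
        assert len(t) == 800
        assert t["task"].value_counts().to_dict() == {dsg.MOTION: 400, dsg.COLOR: 400}
        assert t.groupby("block_index").size().eq(50).all()
        # the first series of blocks holds the first task
        assert set(t[t["block_index"] < 8]["task"]) == {dsg.COLOR}

    def test_unique_stimulus_cells(self, plan):
        t = plan.trials
        for _, sub in t.groupby("task"):
            cells = sub.groupby(["majority_color", "direction"]).size()
            # 25 unique stimuli x 4 replicates per majority x direction cell
            assert cells.eq(100).all()
            combos = sub.groupby(
                ["motion_coherence", "direction", "color_coherence", "majority_color"]
            ).size()
            assert len(combos) == 100 and combos.eq(4).all()

    def test_signed_congruence_level_counts(self, plan):
        t = plan.trials
        for task, expected in ((dsg.COLOR, 20), (dsg.MOTION, 10)):
            sub = t[t["task"] == task]
            levels = {
                dsg.signed_distractor_congruence(row)
                for _, row in sub.iterrows()
            }
            assert len(levels) == expected

    def test_congruency_balanced(self, plan):
        counts = plan.trials["congruent"].value_counts()
        assert counts[True] == 400 and counts[False] == 400


class TestExperiment3:
    def test_totals_and_sandwich(self, exp3_plan):
        t = exp3_plan.trials
        assert len(t) == 768
        assert t["sequence_type"].value_counts().to_dict() == {
            "single": 256, "repeat": 256, "switch": 256,
        }
        single = t[t["sequence_type"] == "single"]
        assert single["task"].value_counts().to_dict() == {
            dsg.MOTION: 128, dsg.COLOR: 128,
        }
        single_blocks = sorted(single["block_index"].unique())
        assert single_blocks == [0, 1, 10, 11]

    def test_mixed_block_structure(self, exp3_plan):
        t = exp3_plan.trials
        for b in range(2, 10):
            block = exp3_plan.block(b)
            assert block["sequence_type"].value_counts().to_dict() == {
                "switch": 32, "repeat": 32,
            }
            assert block.groupby(["sequence_type", "task"]).size().eq(16).all()
            assert dsg._max_run(block["sequence_type"].tolist()) <= 4
            assert dsg._max_run(block["correct_response"].tolist()) <= 4
            assert int(block["congruent"].sum()) == 32

    def test_fixed_coherence_and_csi_layout(self, exp3_plan):
        t = exp3_plan.trials
        assert (t["motion_coherence"] == 0.75).all()
        assert (t["color_coherence"] == 0.75).all()
        per_block_csi = t.groupby("block_index")["csi_ms"].nunique()
        assert per_block_csi.eq(1).all()
        single = t[t["sequence_type"] == "single"]
        assert single.groupby(["task", "csi_ms"]).size().eq(64).all()

    def test_first_mixed_trial_typed_relative_to_previous_block(self):
        plan = dsg.build_exp3_design(seed=5, first_task=dsg.COLOR)
        t = plan.trials
        for b in range(2, 10):
            first = plan.block(b).iloc[0]
            prev_task = plan.block(b - 1).iloc[-1]["task"]
            expected = "repeat" if first["task"] == prev_task else "switch"
            assert first["sequence_type"] == expected

    def test_deterministic_given_seed_and_flags(self):
        a = dsg.build_exp3_design(seed=9, first_task=dsg.COLOR, color_mapping_flipped=True)
        b = dsg.build_exp3_design(seed=9, first_task=dsg.COLOR, color_mapping_flipped=True)
        pd.testing.assert_frame_equal(a.trials, b.trials)

    def test_bad_csi_order_rejected(self):
        with pytest.raises(ValueError):
            dsg.build_exp3_design(seed=0, csi_block_order=[200] * 8)


class TestTimeline:
    @pytest.mark.parametrize("csi, blank", [(200, 800), (800, 200)])
    def test_rsi_constant_across_csi(self, csi, blank):
        events = dsg.trial_timeline({"csi_ms": float(csi)})
        names = [e[0] for e in events]
        assert names == ["blank", "fixation", "cue", "stimulus"]
        durations = dict((e[0], e[2]) for e in events)
        assert durations["blank"] == blank
        stimulus_onset = events[-1][1]
        assert stimulus_onset == 2000  # the response-stimulus interval

    def test_uncued_timeline(self):
        events = dsg.trial_timeline({"csi_ms": np.nan})
        assert events == [("fixation", 0, 1000), ("stimulus", 1000, 2000)]

    def test_invalid_csi_rejected(self):
        with pytest.raises(ValueError):
            dsg.trial_timeline({"csi_ms": 500.0})
        with pytest.raises(ValueError):
            dsg.TimingConfig(csi_ms=500)

    def test_timing_config_invariant(self):
        for csi in (200, 800):
            timing = dsg.TimingConfig(csi_ms=csi)
            assert timing.blank_ms + timing.fixation_ms + timing.csi_ms == 2000
            assert timing.rsi_ms == 2000


class TestValidatePlan:
    def test_valid_plans_have_zero_violations(self):
        for seed in range(3):
            for exp in ("1a", "1b", "2", "3"):
                report = dsg.validate_plan(dsg.build_design(exp, seed))
                assert report.ok, report.violations

    def test_run_length_violation_flagged(self):
        plan = dsg.build_exp1a_design(seed=1)
        trials = plan.trials.copy()
        trials.loc[:5, "correct_response"] = dsg.LEFT
        report = dsg.validate_plan(dsg.ExperimentPlan("1a", trials, plan.metadata))
        assert any("run" in v for v in report.violations)

    def test_exp2_reports_trials_per_task(self):
        report = dsg.validate_plan(dsg.build_exp2_design(seed=2))
        assert report.summary["trials_per_task"] == {dsg.MOTION: 400, dsg.COLOR: 400}


def test_counterbalancing_balanced_over_eight():
    table = dsg.counterbalancing_assignment(16)
    assert table["first_task"].value_counts().eq(8).all()
    assert table["color_mapping_flipped"].value_counts().eq(8).all()
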