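"""Behavior state machine: input labels, legality gate, end-to-end timelines."""

import numpy as np
import pytest

from fallsense import (
    BehaviorState as S,
    FeatureFrame,
    InputEvent,
    PipelineConfig,
    classify_input,
    default_table,
    fsm_step,
    run_fsm,
    run_pipeline,
)
from fallsense.behavior_fsm import TransitionTable
from fallsense.simulate import TrialSpec, simulate_trial


def frame(t=0.0, g=1.0, roll=0.0, pitch=0.0, alt=0.0, dp=0.0, dg=0.0):
    return FeatureFrame(t=t, g_value=g, roll=roll, pitch=pitch, yaw=0.0,
                        altitude=alt, dp_window=dp, dg_window=dg)


def ticks(values, start=0.0, step=0.1):
    """Build a frame sequence from a list of per-tick overrides."""
    return [frame(t=start + i * step, **v) for i, v in enumerate(values)]


class TestClassifyInput:
    def test_quiescent_upright_is_standing_compatible(self, config):
        ev = classify_input(frame(g=1.0, pitch=2.0), config)
        assert ev.label is S.STANDING

    def test_chair_height_drop_labels_sitting_down(self, config):
        """0.45 m drop across the 1.5 s window, no fall rule."""
        frames = ticks(
            [{"alt": 0.0} for _ in range(15)]
            + [{"alt": -0.45} for _ in range(10)]
        )
        ev = classify_input(frames[-1], config, history=frames[:-1])
        assert ev.label is S.SITTING_DOWN

    def test_chair_height_rise_labels_standing_up(self, config):
        frames = ticks(
            [{"alt": -0.45} for _ in range(15)]
            + [{"alt": 0.0} for _ in range(10)]
        )
        ev = classify_input(frames[-1], config, history=frames[:-1])
        assert ev.label is S.STANDING_UP

    def test_fall_rule_wins_over_everything(self, config):
        f = frame(dg=700 / 512, dp=4.0, pitch=80.0, alt=-1.0)
        assert classify_input(f, config).label is S.FALLING

    def test_sustained_lean_labels_lying(self, config):
        frames = ticks([{"pitch": 75.0} for _ in range(12)])
        ev = classify_input(frames[-1], config, history=frames[:-1])
        assert ev.label is S.LYING

    def test_momentary_lean_is_not_lying(self, config):
        frames = ticks([{"pitch": 0.0} for _ in range(10)] + [{"pitch": 75.0}] * 2)
        ev = classify_input(frames[-1], config, history=frames[:-1])
        assert ev.label is not S.LYING


class TestFsmStep:
    def test_direct_standing_to_sitting_is_rejected(self):
        """The misjudgment guard: STANDING + SITTING input does not match."""
        table = default_table()
        state, action = fsm_step(S.STANDING, InputEvent(S.SITTING, frame()), table)
        assert state is S.STANDING and action is None

    def test_legal_chain_standing_to_sitting_via_sitting_down(self):
        table = default_table()
        state, action = fsm_step(S.STANDING, InputEvent(S.SITTING_DOWN, frame()), table)
        assert state is S.SITTING_DOWN and action == "sitting_down"
        state, action = fsm_step(state, InputEvent(S.STANDING, frame()), table)
        assert state is S.SITTING and action == "sit_down"

    @pytest.mark.parametrize("state", list(S))
    def test_self_input_is_noop(self, state):
        out, action = fsm_step(state, InputEvent(state, frame()), default_table())
        assert out is state and action is None

    @pytest.mark.parametrize(
        "origin", [S.STANDING, S.WALKING, S.SITTING, S.STANDING_UP, S.SITTING_DOWN]
    )
    def test_falling_reachable_from_all_active_states(self, origin):
        state, _ = fsm_step(origin, InputEvent(S.FALLING, frame()), default_table())
        assert state is S.FALLING


class TestTableProperties:
    def test_fuzzed_sequences_never_leave_the_table(self):
        """1e4 random input sequences: every change of state is a table entry."""
        table = default_table()
        rng = np.random.default_rng(0)
        states = list(S)
        for _ in range(10_000):
            state = S.INITIAL
            for label_idx in rng.integers(0, len(states), size=12):
                label = states[label_idx]
                nxt, _ = fsm_step(state, InputEvent(label, frame()), table)
                if nxt is not state:
                    assert table.lookup(state, label)[0] is nxt
                state = nxt

    def test_removing_an_entry_only_shrinks_reachability(self):
        def reachable(table: TransitionTable) -> set:
            seen = {S.INITIAL}
            frontier = [S.INITIAL]
            while frontier:
                cur = frontier.pop()
                for (state, _), (nxt, _) in table.entries.items():
                    if state is cur and nxt not in seen:
                        seen.add(nxt)
                        frontier.append(nxt)
            return seen

        full = default_table()
        base = reachable(full)
        for key in list(full.entries):
            assert reachable(full.without(*key)) <= base

    def test_duplicate_entries_rejected(self):
        rows = [("STANDING", "WALKING", "WALKING", "walk")] * 2
        with pytest.raises(ValueError):
            TransitionTable.from_rows(rows)

    def test_table_csv_round_trip(self, tmp_path):
        table = default_table()
        path = tmp_path / "table.csv"
        table.to_csv(path)
        assert TransitionTable.from_csv(path).entries == table.entries


class TestRunFsm:
    def test_quiescent_trace_never_initializes(self, config):
        frames = ticks([{} for _ in range(80)])
        run = run_fsm(frames, config)
        assert run.never_initialized
        assert all(s is S.INITIAL for s in run.states)

    def test_empty_frames_rejected(self, config):
        with pytest.raises(ValueError):
            run_fsm([], config)

    def test_determinism_identical_timelines(self, config):
        log, _ = simulate_trial(TrialSpec("B", "forward", seed=11))
        r1 = run_pipeline(log, config)
        r2 = run_pipeline(log, config)
        assert r1.fsm.states == r2.fsm.states
        assert r1.fsm.actions == r2.fsm.actions

    def test_protocol_walk_then_fall_timeline(self, config):
        """Stand -> walk -> fall forward: WALKING then FALLING in order."""
        log, truth = simulate_trial(TrialSpec("B", "forward", seed=7))
        run = run_pipeline(log, config).fsm
        values = [s.value for s in run.states]
        assert "WALKING" in values and "FALLING" in values
        assert values.index("WALKING") < values.index("FALLING")
        t_falling = run.times[values.index("FALLING")]
        assert abs(t_falling - truth.fall_time) < 2.0

    def test_sit_stand_sit_cycle_emits_actions_in_order(self, config):
        log, _ = simulate_trial(
            TrialSpec("ADL", "none", seed=5, params={"adl_kind": "sit_cycle"})
        )
        run = run_pipeline(log, config).fsm
        posture_actions = [a for _, a in run.actions if a in ("sit_down", "stand_up")]
        assert posture_actions == ["sit_down", "stand_up", "sit_down"]

    def test_timeline_csv_export(self, tmp_path, config):
        frames = ticks([{} for _ in range(5)])
        run = run_fsm(frames, config)
        path = tmp_path / "timeline.csv"
        run.to_csv(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "t,state,action"
        assert len(lines) == 6
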