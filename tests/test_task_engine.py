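"""Task-engine tests: sequence construction, scoring, staircase dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efmt.responders import ResponderModel, chance_responder, perfect_responder
from efmt.task_engine import (
    FACE_LABELS,
    SHAPE_LABELS,
    AdaptivePolicy,
    BlockResult,
    BlockSpec,
    ScoringError,
    SequenceError,
    Stimulus,
    TrialItem,
    generate_block_sequence,
    next_session_start,
    run_session,
    score_block,
    update_difficulty,
)


def rescan_flags(items, n):
    """Independent re-scan oracle: recompute target/lure flags from labels."""
    labels = [it.stimulus.label for it in items]
    out = []
    for p in range(len(labels)):
        if p < n:
            out.append((False, False))
            continue
        tgt = labels[p] == labels[p - n]
        lure = False
        if not tgt:
            for lag in (n - 1, n + 1):
                if lag >= 1 and p - lag >= 0 and labels[p] == labels[p - lag]:
                    lure = True
        out.append((tgt, lure))
    return out


class TestSequenceGeneration:
    def test_single_label_override_forces_all_targets(self, rng):
        spec = BlockSpec(n_level=1, n_scored_items=15)
        items = generate_block_sequence(spec, ["happy"], rng)
        scored = [it for it in items if it.position >= 1]
        assert len(items) == 16
        assert all(it.is_target for it in scored)

    def test_exact_target_count_verified_by_rescan(self, rng):
        spec = BlockSpec(n_level=2, n_scored_items=15, target_rate=1 / 3, lure_rate=0.0)
        items = generate_block_sequence(spec, FACE_LABELS, rng)
        flags = rescan_flags(items, 2)
        assert sum(t for t, _ in flags) == 5
        assert sum(l for _, l in flags) == 0
        for it, (tgt, lure) in zip(items, flags):
            assert it.is_target == tgt and it.is_lure == lure

    @pytest.mark.parametrize("n_level,scored,tr,lr", [
        (1, 15, 1 / 3, 0.2), (2, 15, 1 / 3, 0.2), (3, 15, 0.4, 0.0),
        (5, 20, 0.25, 0.3), (1, 6, 1 / 3, 0.0),
    ])
    @pytest.mark.parametrize("modality,labels", [("face", FACE_LABELS),
                                                 ("shape", SHAPE_LABELS)])
    def test_counts_and_flags_match_spec_across_designs(self, n_level, scored, tr, lr,
                                                        modality, labels):
        rng = np.random.default_rng(n_level * 100 + scored)
        spec = BlockSpec(n_level=n_level, n_scored_items=scored,
                         target_rate=tr, lure_rate=lr)
        items = generate_block_sequence(spec, labels, rng, modality=modality)
        assert len(items) == scored + n_level
        flags = rescan_flags(items, n_level)
        assert sum(t for t, _ in flags) == spec.n_targets
        assert sum(l for _, l in flags) == spec.n_lures
        for it, (tgt, lure) in zip(items, flags):
            assert (it.is_target, it.is_lure) == (tgt, lure)
        assert all(it.stimulus.modality == modality for it in items)

    def test_timing_one_second_stimulus_one_second_fixation(self, rng):
        items = generate_block_sequence(BlockSpec(n_level=2), FACE_LABELS, rng)
        assert all(it.stim_dur_s == 1.0 and it.fixation_dur_s == 1.0 for it in items)
        assert items[3].onset_s == pytest.approx(3 * 2.0)

    def test_reproducible_from_seed(self):
        spec = BlockSpec(n_level=3)
        a = generate_block_sequence(spec, FACE_LABELS, np.random.default_rng(99))
        b = generate_block_sequence(spec, FACE_LABELS, np.random.default_rng(99))
        assert [it.stimulus.label for it in a] == [it.stimulus.label for it in b]

    def test_too_few_categories_rejected(self, rng):
        with pytest.raises(SequenceError, match="at least 3"):
            generate_block_sequence(BlockSpec(n_level=1), ["happy", "sad"], rng)

    def test_infeasible_rates_rejected(self):
        with pytest.raises(ValueError):
            BlockSpec(n_level=1, target_rate=0.7, lure_rate=0.5)

    def test_invalid_modality_rejected(self):
        with pytest.raises(ValueError):
            Stimulus(id="x", modality="sound", label="beep")


class TestScoring:
    def _respond_all(self, items, spec, fn):
        for it in items:
            if it.position >= spec.n_level:
                it.response = fn(it)
        return items

    def test_all_correct_gives_perfect_accuracy(self, rng):
        spec = BlockSpec(n_level=2)
        items = generate_block_sequence(spec, FACE_LABELS, rng)
        self._respond_all(items, spec, lambda it: "match" if it.is_target else "nonmatch")
        res = score_block(items, spec)
        assert res.accuracy == 1.0 and res.misses == 0 and res.false_alarms == 0
        assert res.n_scored == spec.n_scored_items

    def test_all_omitted_scores_zero(self, rng):
        spec = BlockSpec(n_level=1)
        items = generate_block_sequence(spec, FACE_LABELS, rng)
        self._respond_all(items, spec, lambda it: "none")
        res = score_block(items, spec)
        assert res.accuracy == 0.0
        assert res.n_scored == spec.n_scored_items

    def test_hand_built_six_item_block(self):
        # N=1 block, 6 scored items, 2 targets; all responses correct
        labels = ["happy", "sad", "sad", "angry", "angry", "fearful", "neutral"]
        spec = BlockSpec(n_level=1, n_scored_items=6, target_rate=2 / 6, lure_rate=0.0)
        items = []
        for p, lab in enumerate(labels):
            tgt = p >= 1 and lab == labels[p - 1]
            items.append(TrialItem(position=p,
                                   stimulus=Stimulus(id=str(p), modality="face", label=lab),
                                   is_target=tgt, is_lure=False,
                                   response=None if p < 1 else ("match" if tgt else "nonmatch")))
        res = score_block(items, spec)
        assert res.accuracy == 1.0 and res.hits == 2 and res.correct_rejections == 4

    def test_missing_response_error_names_positions(self, rng):
        spec = BlockSpec(n_level=1)
        items = generate_block_sequence(spec, FACE_LABELS, rng)
        with pytest.raises(ScoringError, match=r"positions \[1"):
            score_block(items, spec)


class TestStaircase:
    def test_threshold_table(self):
        pol = AdaptivePolicy()
        mk = lambda n, acc: BlockResult(n, acc, 0, 0, 0, 0)
        assert update_difficulty(pol, mk(2, 1.0)) == 3
        assert update_difficulty(pol, mk(1, 0.0)) == 1       # clamped at n_min
        assert update_difficulty(pol, mk(4, 0.75)) == 4      # between thresholds
        assert update_difficulty(pol, mk(15, 1.0)) == 15     # clamped at n_max
        assert update_difficulty(pol, mk(3, 0.60)) == 2      # down inclusive

    @settings(max_examples=200, derandomize=True)
    @given(n=st.integers(1, 15), a1=st.floats(0, 1), a2=st.floats(0, 1))
    def test_monotone_in_accuracy(self, n, a1, a2):
        pol = AdaptivePolicy()
        lo, hi = sorted([a1, a2])
        mk = lambda acc: BlockResult(n, acc, 0, 0, 0, 0)
        assert update_difficulty(pol, mk(lo)) <= update_difficulty(pol, mk(hi))

    def test_perfect_responder_climbs_one_per_block(self, rng):
        s = run_session(1, 1, perfect_responder, AdaptivePolicy(), rng)
        assert s.n_levels == list(range(1, 16))
        assert s.end_n == 15 and s.mean_n == pytest.approx(8.0)

    def test_chance_responder_stays_at_floor(self):
        rng = np.random.default_rng(11)
        s = run_session(1, 1, chance_responder(), AdaptivePolicy(), rng)
        assert s.n_levels == [1] * 15

    def test_levels_never_leave_bounds_and_session1_starts_at_1(self, rng):
        pol = AdaptivePolicy(n_max=4)
        s = run_session(1, 1, perfect_responder, pol, rng)
        assert s.start_n == 1
        assert all(pol.n_min <= n <= pol.n_max for n in s.n_levels)
        with pytest.raises(ValueError):
            run_session(1, 3, perfect_responder, pol, rng)

    def test_modality_does_not_change_dynamics(self):
        model = ResponderModel(capacity=3.0)
        a = run_session(1, 1, model, AdaptivePolicy(), np.random.default_rng(5),
                        modality="face")
        b = run_session(1, 1, model, AdaptivePolicy(), np.random.default_rng(5),
                        modality="shape")
        assert a.n_levels == b.n_levels and a.end_n == b.end_n

    def test_responder_failure_flags_incomplete(self, rng):
        calls = {"n": 0}

        def flaky(item, n, r):
            calls["n"] += 1
            if calls["n"] > 40:
                raise RuntimeError("hardware glitch")
            return "match" if item.is_target else "nonmatch"

        s = run_session(1, 1, flaky, AdaptivePolicy(), rng)
        assert not s.complete and len(s.blocks) < 15
        assert next_session_start(s, AdaptivePolicy()) == 1

    def test_staircase_equilibrates_near_capacity(self):
        # logistic observer with 75%-accuracy point at N = 4
        model = ResponderModel(capacity=4.0, slope=0.5)
        pol = AdaptivePolicy()
        rng = np.random.default_rng(303)
        levels = []
        prev = run_session(1, 1, model, pol, rng)
        levels += prev.n_levels[5:]   # discard burn-in from the forced N=1 start
        for s in range(2, 9):
            prev = run_session(s, next_session_start(prev, pol), model, pol, rng)
            levels += prev.n_levels
        assert abs(np.mean(levels) - 4.0) <= 1.0


class TestCarryover:
    def _session_with_levels(self, levels):
        blocks = [BlockResult(n, 0.75, 0, 0, 0, 0) for n in levels]
        from efmt.task_engine import SessionResult
        return SessionResult(session_index=1, start_n=levels[0], blocks=blocks,
                             mean_n=float(np.mean(levels)), end_n=levels[-1],
                             modality="face")

    def test_last_rule_uses_end_n(self):
        s = self._session_with_levels([2, 3, 4])
        s.end_n = 4
        assert next_session_start(s, AdaptivePolicy(carryover_rule="last")) == 4

    def test_all_ones_gives_one_for_any_rule(self):
        for rule in ("last", "modal", "rounded_mean"):
            s = self._session_with_levels([1] * 15)
            assert next_session_start(s, AdaptivePolicy(carryover_rule=rule)) == 1

    def test_rounded_mean_of_1_to_15_is_8(self):
        s = self._session_with_levels(list(range(1, 16)))
        assert next_session_start(s, AdaptivePolicy(carryover_rule="rounded_mean")) == 8


class TestResponderModel:
    @settings(max_examples=100, derandomize=True)
    @given(cap=st.floats(0, 10), slope=st.floats(0.2, 3), lapse=st.floats(0, 0.4))
    def test_accuracy_nonincreasing_in_load(self, cap, slope, lapse):
        m = ResponderModel(capacity=cap, slope=slope, lapse=lapse)
        accs = [m.accuracy(n) for n in range(1, 16)]
        assert all(a >= b for a, b in zip(accs, accs[1:]))
        assert all(0.05 <= a <= 1.0 for a in accs)

    def test_capacity_is_75_percent_point(self):
        m = ResponderModel(capacity=3.0, slope=1.0)
        assert m.accuracy(3) == pytest.approx(0.75)
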