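"""Trial-schedule generation, simulated behavior, yoking, and recoding."""
from __future__ import annotations

import numpy as np
import pytest

from rulefmri.design import (
    BehaviorParams,
    Condition,
    DesignConfigError,
    DesignStructureError,
    IMPLEMENTATION,
    LEARNING,
    TimingConfig,
    YokeLedger,
    generate_design,
    generate_subject,
    recode_repetitions_by_accuracy,
    simulate_te_behavior,
    yoke_observation,
)


# ---------------------------------------------------------------------------
# Structure of the full default session
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def full_design():
    return generate_subject("sub-01", seed=3, n_blocks=24)


def test_default_session_structure(full_design):
    d = full_design
    assert d.n_blocks == 24
    assert d.n_runs == 4
    assert d.n_trials == 24 * 32
    for block in range(1, 25):
        assert sum(t.block == block for t in d.trials) == 32
    assert len(d.unique_stimuli) == 108  # 24 experimental + 3 practice blocks


def test_runs_hold_two_blocks_per_condition(full_design):
    for run in full_design.runs:
        blocks = full_design.blocks_in_run(run)
        assert len(blocks) == 6
        conds = [full_design.block_condition(b) for b in blocks]
        for c in Condition:
            assert conds.count(c) == 2


def test_repetition_chunks(full_design):
    """Every stimulus appears exactly once per repetition level before any
    stimulus advances to the next level."""
    for block in range(1, 25):
        trials = sorted(
            (t for t in full_design.trials if t.block == block), key=lambda t: t.onset
        )
        for chunk_start in range(0, 32, 4):
            chunk = trials[chunk_start : chunk_start + 4]
            assert len({t.stimulus for t in chunk}) == 4
            assert len({t.repetition for t in chunk}) == 1
            assert chunk[0].repetition == chunk_start // 4 + 1


def test_stage_labels_follow_repetition(full_design):
    for t in full_design.trials:
        assert t.stage == (LEARNING if t.repetition <= 4 else IMPLEMENTATION)


def test_stimuli_unique_across_blocks(full_design):
    seen: set[int] = set()
    for block in range(1, 25):
        stims = {t.stimulus for t in full_design.trials if t.block == block}
        assert len(stims) == 4
        assert not stims & seen
        seen |= stims


def test_timing_intervals(full_design):
    timing = full_design.timing
    lo, hi = timing.iti_range
    for run in full_design.runs:
        trials = full_design.trials_in_run(run)
        for block in full_design.blocks_in_run(run):
            bt = sorted((t for t in trials if t.block == block), key=lambda t: t.onset)
            cond = bt[0].condition
            fb = (
                timing.response_feedback_duration + timing.accuracy_feedback_duration
                if cond is not Condition.INSTRUCTION
                else 0.0
            )
            for a, b in zip(bt, bt[1:]):
                gap = b.onset - (a.onset + a.duration)
                extra = fb if a.stage == LEARNING else 0.0
                if a.repetition == 4 and b.repetition == 5:
                    extra += timing.warning_duration
                assert lo + extra - 1e-9 <= gap <= hi + extra + 1e-9


def test_generation_is_deterministic():
    a = generate_subject("s", seed=42, n_blocks=6)
    b = generate_subject("s", seed=42, n_blocks=6)
    assert [(t.onset, t.stimulus, t.correct, t.rt) for t in a.trials] == [
        (t.onset, t.stimulus, t.correct, t.rt) for t in b.trials
    ]
    c = generate_subject("s", seed=43, n_blocks=6)
    assert [t.stimulus for t in a.trials] != [t.stimulus for t in c.trials]


def test_invalid_block_count_rejected():
    with pytest.raises(DesignConfigError):
        generate_design(n_blocks=7)
    with pytest.raises(DesignConfigError):
        generate_design(n_blocks=0)


def test_invalid_timing_rejected():
    with pytest.raises(DesignConfigError):
        generate_design(timing=TimingConfig(trial_duration=-1.0))
    with pytest.raises(DesignConfigError):
        generate_design(timing=TimingConfig(iti_range=(4.0, 2.0)))


# ---------------------------------------------------------------------------
# Simulated behavior
# ---------------------------------------------------------------------------

def test_behavior_population(small_design):
    for t in small_design.trials:
        assert t.correct is not None
        if t.condition is Condition.INSTRUCTION and t.stage == LEARNING:
            assert t.response is None and t.rt is None
        if t.condition is Condition.OBSERVATION and t.stage == LEARNING:
            assert t.rt is None  # observed responses carry no RT
        if t.stage == IMPLEMENTATION:
            assert t.response is not None and t.rt is not None
            assert 0.15 <= t.rt <= t.duration


def test_te_accuracy_recovery():
    """Observed accuracy per repetition matches the generating probabilities
    within 3 Monte-Carlo standard errors (many blocks pooled)."""
    behavior = BehaviorParams()
    designs = [
        generate_subject(f"s{i}", seed=100 + i, n_blocks=24) for i in range(10)
    ]
    te = [
        t
        for d in designs
        for t in d.trials
        if t.condition is Condition.TRIAL_AND_ERROR and t.stage == LEARNING
    ]
    for rep in (1, 2, 3, 4):
        vals = [t.correct for t in te if t.repetition == rep]
        p = behavior.accuracy_by_repetition[rep - 1]
        se = np.sqrt(p * (1 - p) / len(vals))
        assert abs(np.mean(vals) - p) < 3 * max(se, 1e-3)


def test_eliminate_tried_strategy():
    """Under eliminate_tried, a wrong response is never repeated for the same
    stimulus while untried wrong options remain."""
    design = generate_subject("s", seed=5, n_blocks=24)
    for block in design.blocks_of_condition(Condition.TRIAL_AND_ERROR):
        by_stim: dict[int, list] = {}
        for t in sorted(design.trials, key=lambda x: x.onset):
            if t.block == block and t.stage == LEARNING:
                by_stim.setdefault(t.stimulus, []).append(t)
        for stim, seq in by_stim.items():
            wrong_seen: set[int] = set()
            for t in seq:
                if not t.correct:
                    untried = {1, 2, 3, 4} - wrong_seen - {
                        design.stimulus_response_map[block][stim]
                    }
                    if untried:
                        assert t.response not in wrong_seen
                    wrong_seen.add(t.response)


# ---------------------------------------------------------------------------
# Yoking
# ---------------------------------------------------------------------------

def test_yoking_replays_source_record():
    source = generate_subject("src", seed=21, n_blocks=6)
    ledger = YokeLedger.from_design(source, cohort_set_index=0)
    target = generate_design("tgt", seed=22, n_blocks=6)
    simulate_te_behavior(target)
    yoke_observation(target, ledger)
    obs = sorted(
        (
            t
            for t in target.trials
            if t.condition is Condition.OBSERVATION and t.stage == LEARNING
        ),
        key=lambda t: (t.run, t.onset),
    )
    assert [(t.response, t.correct) for t in obs] == [
        (r, c) for r, c, _ in ledger.records
    ]


def test_yoking_count_mismatch_raises():
    source = generate_subject("src", seed=21, n_blocks=12)  # 2x the TE trials
    ledger = YokeLedger.from_design(source)
    target = generate_design("tgt", seed=22, n_blocks=6)
    simulate_te_behavior(target)
    with pytest.raises(DesignStructureError, match="records"):
        yoke_observation(target, ledger)


def test_ledger_requires_resolved_source():
    source = generate_design("src", seed=21, n_blocks=6)  # no behavior yet
    with pytest.raises(DesignStructureError, match="unresolved"):
        YokeLedger.from_design(source)


# ---------------------------------------------------------------------------
# Accuracy-based repetition recoding
# ---------------------------------------------------------------------------

def test_recoding_counters():
    """(incorrect, correct, correct, correct) at learning -> incorrect 1 and
    correct 1..3; an all-correct stage keeps the within-stage rank."""
    design = generate_design("s", seed=8, n_blocks=6)
    simulate_te_behavior(design)
    yoke_observation(design)
    # overwrite one stimulus's learning outcomes deterministically
    block = design.blocks_of_condition(Condition.TRIAL_AND_ERROR)[0]
    trials = sorted(
        (t for t in design.trials if t.block == block and t.stage == LEARNING),
        key=lambda t: t.onset,
    )
    stim = trials[0].stimulus
    seq = [t for t in trials if t.stimulus == stim]
    for t, correct in zip(seq, (False, True, True, True)):
        t.correct = correct
    recode_repetitions_by_accuracy(design)
    assert [t.recoded_repetition for t in seq] == [1, 1, 2, 3]
    # instruction learning is all-correct: recoded equals within-stage rank
    ins_block = design.blocks_of_condition(Condition.INSTRUCTION)[0]
    ins = sorted(
        (t for t in design.trials if t.block == ins_block and t.stage == LEARNING),
        key=lambda t: t.onset,
    )
    ins_stim = ins[0].stimulus
    assert [t.recoded_repetition for t in ins if t.stimulus == ins_stim] == [1, 2, 3, 4]


def test_recoding_is_stage_local(small_design):
    """Counters restart at the implementation stage."""
    for block in range(1, 7):
        for stim in {
            t.stimulus for t in small_design.trials if t.block == block
        }:
            impl = sorted(
                (
                    t
                    for t in small_design.trials
                    if t.block == block and t.stimulus == stim and t.stage == IMPLEMENTATION
                ),
                key=lambda t: t.onset,
            )
            firsts = [t.recoded_repetition for t in impl]
            assert 1 in firsts  # some counter restarts at 1 within the stage
            assert max(firsts) <= 4


def test_recoding_requires_behavior():
    design = generate_design("s", seed=8, n_blocks=6)
    with pytest.raises(DesignStructureError, match="recode"):
        recode_repetitions_by_accuracy(design)


def test_events_table_roundtrip_columns(small_design):
    table = small_design.events_table()
    assert {"onset", "duration", "trial_type", "condition", "stimulus"} <= set(
        table.columns
    )
    n_aux = len(small_design.aux_events)
    assert len(table) == small_design.n_trials + n_aux
    assert (table.groupby("run")["onset"].apply(lambda s: s.is_monotonic_increasing)).all()
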