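"""Trial schedule generation for the rapid stimulus-response (S-R) rule learning task.

One subject's session consists of blocks of 4 novel stimuli, each repeated 8
times: repetitions 1-4 form the *learning* stage (rules acquired by
instruction, trial-and-error, or observation) and repetitions 5-8 the
*implementation* stage (all conditions respond). Stimuli are sequenced in
*repetition chunks*: every stimulus of a block appears exactly once at the
current repetition level before any stimulus advances to the next level.

The default session is 24 blocks of 32 trials (4 runs x 6 blocks, 2 blocks
per learning condition per run) plus 3 non-analyzed practice blocks, drawing
on a pool of 108 unique stimuli.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "LEARNING",
    "IMPLEMENTATION",
    "TimingConfig",
    "BehaviorParams",
    "TrialEvent",
    "AuxEvent",
    "ExperimentDesign",
    "YokeLedger",
    "generate_design",
    "simulate_te_behavior",
    "yoke_observation",
    "recode_repetitions_by_accuracy",
    "generate_subject",
]

LEARNING = "learning"
IMPLEMENTATION = "implementation"

N_STIMULI_PER_BLOCK = 4
N_REPETITIONS = 8
TRIALS_PER_BLOCK = N_STIMULI_PER_BLOCK * N_REPETITIONS
BLOCKS_PER_RUN = 6
STIMULUS_POOL_SIZE = 108  # 24 experimental blocks x 4 + 3 practice blocks x 4


class Condition(str, enum.Enum):
    """The three ways an S-R rule can be acquired during the learning stage."""

    INSTRUCTION = "instruction"
    TRIAL_AND_ERROR = "trial_and_error"
    OBSERVATION = "observation"

    def __str__(self) -> str:  # keeps events tables readable
        return self.value


class DesignConfigError(ValueError):
    """Raised for invalid timing or behavior configuration."""


class DesignStructureError(ValueError):
    """Raised when a structural contract of the design is violated."""


@dataclass(frozen=True)
class TimingConfig:
    """Trial and block timing, in seconds.

    Defaults follow the study procedure: trials stay on screen for at most
    1.5 s, inter-trial fixation is jittered uniformly on [2, 4] s, blocks
    open with a 2 s fixation and a 2.5 s condition cue, the implementation
    stage is announced by a 2 s warning, and each block closes with 3 s of
    accuracy feedback. Block onsets are jittered by 2 or 4 s.
    """

    trial_duration: float = 1.5
    iti_range: tuple[float, float] = (2.0, 4.0)
    cue_duration: float = 2.5
    warning_duration: float = 2.0
    fixation_duration: float = 2.0
    response_feedback_duration: float = 0.7
    accuracy_feedback_duration: float = 0.7
    block_feedback_duration: float = 3.0
    block_onset_jitter: tuple[float, ...] = (2.0, 4.0)

    def validate(self) -> None:
        durations = (
            self.trial_duration,
            self.cue_duration,
            self.warning_duration,
            self.fixation_duration,
            self.response_feedback_duration,
            self.accuracy_feedback_duration,
            self.block_feedback_duration,
        )
        if any(d < 0 for d in durations):
            raise DesignConfigError("durations must be nonnegative")
        lo, hi = self.iti_range
        if lo < 0 or hi < lo:
            raise DesignConfigError(f"invalid ITI range {self.iti_range}")
        if any(j < 0 for j in self.block_onset_jitter):
            raise DesignConfigError("block-onset jitter must be nonnegative")


@dataclass(frozen=True)
class BehaviorParams:
    """Parameters of simulated responding.

    ``accuracy_by_repetition`` holds the probability of a correct response at
    trial-and-error learning repetitions 1-4; the default starts at chance
    among 4 responses and reaches near-ceiling by repetition 4. RT means
    follow the observed shape: fast guessing at repetition 1, a retrieval
    slow-down at repetition 2, then speeding with automatization.
    """

    accuracy_by_repetition: tuple[float, float, float, float] = (0.25, 0.80, 0.93, 0.97)
    rt_mean_by_repetition: tuple[float, float, float, float] = (0.75, 0.95, 0.85, 0.78)
    rt_sd: float = 0.15
    response_strategy: str = "eliminate_tried"  # or "uniform_guess"
    implementation_accuracy: float = 0.96
    implementation_rt_mean: float = 0.72

    def validate(self) -> None:
        if len(self.accuracy_by_repetition) != 4:
            raise DesignConfigError("accuracy_by_repetition needs 4 entries")
        if any(not 0.0 <= p <= 1.0 for p in self.accuracy_by_repetition):
            raise DesignConfigError("accuracies must lie in [0, 1]")
        if any(m <= 0 or m >= 1.5 for m in self.rt_mean_by_repetition):
            raise DesignConfigError("RT means must lie in (0, 1.5) s")
        if self.rt_sd <= 0:
            raise DesignConfigError("rt_sd must be positive")
        if self.response_strategy not in ("eliminate_tried", "uniform_guess"):
            raise DesignConfigError(
                f"unknown response strategy {self.response_strategy!r}"
            )
        if not 0.0 <= self.implementation_accuracy <= 1.0:
            raise DesignConfigError("implementation_accuracy must lie in [0, 1]")


@dataclass
class TrialEvent:
    """One stimulus presentation."""

    run: int
    block: int
    condition: Condition
    stage: str  # "learning" | "implementation"
    stimulus: int
    repetition: int  # 1-8 across the block
    onset: float  # seconds from run start
    duration: float
    response: int | None = None
    correct: bool | None = None
    rt: float | None = None
    recoded_repetition: int | None = None
    practice: bool = False


@dataclass
class AuxEvent:
    """A non-trial event: condition cue, stage warning, or block feedback."""

    kind: str  # "cue" | "warning" | "block_feedback"
    onset: float
    duration: float
    run: int
    block: int
    condition: Condition


@dataclass
class ExperimentDesign:
    """The complete trial-by-trial schedule of one subject."""

    subject_id: str
    trials: list[TrialEvent]
    aux_events: list[AuxEvent]
    stimulus_response_map: dict[int, dict[int, int]]  # block -> stimulus -> response
    seed: int
    timing: TimingConfig = field(default_factory=TimingConfig)
    practice_trials: list[TrialEvent] = field(default_factory=list)

    # -- structure queries ---------------------------------------------------
    @property
    def n_blocks(self) -> int:
        return len({t.block for t in self.trials})

    @property
    def n_runs(self) -> int:
        return len({t.run for t in self.trials})

    @property
    def runs(self) -> list[int]:
        return sorted({t.run for t in self.trials})

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def unique_stimuli(self) -> set[int]:
        stims = {t.stimulus for t in self.trials}
        stims.update(t.stimulus for t in self.practice_trials)
        return stims

    def trials_in_run(self, run: int) -> list[TrialEvent]:
        return [t for t in self.trials if t.run == run]

    def aux_in_run(self, run: int) -> list[AuxEvent]:
        return [a for a in self.aux_events if a.run == run]

    def blocks_in_run(self, run: int) -> list[int]:
        return sorted({t.block for t in self.trials_in_run(run)})

    def block_condition(self, block: int) -> Condition:
        for t in self.trials:
            if t.block == block:
                return t.condition
        raise DesignStructureError(f"no such block: {block}")

    def blocks_of_condition(self, condition: Condition) -> list[int]:
        return sorted({t.block for t in self.trials if t.condition == condition})

    def run_duration(self, run: int, tail: float = 8.0) -> float:
        """Seconds from run start until after the last event (plus a tail
        covering the hemodynamic response)."""
        ends = [t.onset + t.duration for t in self.trials_in_run(run)]
        ends += [a.onset + a.duration for a in self.aux_in_run(run)]
        return max(ends) + tail

    def events_table(self, run: int | None = None) -> pd.DataFrame:
        """All events as a BIDS-style long table (one row per event)."""
        rows = []
        trials = self.trials if run is None else self.trials_in_run(run)
        aux = self.aux_events if run is None else self.aux_in_run(run)
        for t in trials:
            rows.append(
                dict(
                    onset=t.onset,
                    duration=t.duration,
                    trial_type="trial",
                    run=t.run,
                    block=t.block,
                    condition=t.condition.value,
                    stage=t.stage,
                    stimulus=t.stimulus,
                    repetition=t.repetition,
                    recoded_repetition=t.recoded_repetition,
                    response=t.response,
                    correct=t.correct,
                    rt=t.rt,
                )
            )
        for a in aux:
            rows.append(
                dict(
                    onset=a.onset,
                    duration=a.duration,
                    trial_type=a.kind,
                    run=a.run,
                    block=a.block,
                    condition=a.condition.value,
                    stage=None,
                    stimulus=None,
                    repetition=None,
                    recoded_repetition=None,
                    response=None,
                    correct=None,
                    rt=None,
                )
            )
        df = pd.DataFrame(rows)
        return df.sort_values(["run", "onset"], kind="stable").reset_index(drop=True)

    def validate(self) -> None:
        """Assert the structural invariants of the schedule."""
        for t in self.trials:
            expected_stage = LEARNING if t.repetition <= 4 else IMPLEMENTATION
            if t.stage != expected_stage:
                raise DesignStructureError(
                    f"repetition {t.repetition} labeled {t.stage}"
                )
        for block in sorted({t.block for t in self.trials}):
            block_trials = [t for t in self.trials if t.block == block]
            if len(block_trials) != TRIALS_PER_BLOCK:
                raise DesignStructureError(
                    f"block {block} has {len(block_trials)} trials"
                )
            counts: dict[tuple[int, int], int] = {}
            for t in block_trials:
                counts[(t.stimulus, t.repetition)] = (
                    counts.get((t.stimulus, t.repetition), 0) + 1
                )
            if any(v != 1 for v in counts.values()) or len(counts) != 32:
                raise DesignStructureError(
                    f"block {block} violates the 4-stimuli x 8-repetitions grid"
                )
        for run in self.runs:
            onsets = [t.onset for t in self.trials_in_run(run)]
            if not np.all(np.diff(onsets) > 0):
                raise DesignStructureError(f"onsets not increasing in run {run}")


@dataclass
class YokeLedger:
    """Trial-and-error learning record of a source subject, replayed as the
    observed feedback of a yoked subject's observation blocks."""

    cohort_set_index: int
    records: list[tuple[int, bool, float]]  # (response, correct, rt) in trial order

    @classmethod
    def from_design(cls, design: ExperimentDesign, cohort_set_index: int = 0) -> "YokeLedger":
        trials = sorted(
            (
                t
                for t in design.trials
                if t.condition is Condition.TRIAL_AND_ERROR and t.stage == LEARNING
            ),
            key=lambda t: (t.run, t.onset),
        )
        missing = [t for t in trials if t.correct is None]
        if missing:
            raise DesignStructureError(
                "source design has unresolved trial-and-error learning trials"
            )
        return cls(
            cohort_set_index=cohort_set_index,
            records=[(t.response, bool(t.correct), t.rt) for t in trials],
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _seed_streams(seed: int) -> dict[str, np.random.Generator]:
    """One master seed deterministically split into independent streams."""
    ss = np.random.SeedSequence(seed)
    design_ss, behavior_ss, obs_ss = ss.spawn(3)
    return {
        "design": np.random.default_rng(design_ss),
        "behavior": np.random.default_rng(behavior_ss),
        "observation": np.random.default_rng(obs_ss),
    }


def _layout_block(
    rng: np.random.Generator,
    timing: TimingConfig,
    run: int,
    block: int,
    condition: Condition,
    stimuli: list[int],
    t0: float,
    practice: bool,
) -> tuple[list[TrialEvent], list[AuxEvent], float]:
    trials: list[TrialEvent] = []
    aux: list[AuxEvent] = []
    t = t0 + timing.fixation_duration
    aux.append(AuxEvent("cue", t, timing.cue_duration, run, block, condition))
    t += timing.cue_duration

    # during learning, trial-and-error and observation trials are followed by
    # response feedback and correct/incorrect feedback; instruction learning
    # and all implementation trials are not
    learning_fb = (
        timing.response_feedback_duration + timing.accuracy_feedback_duration
        if condition is not Condition.INSTRUCTION
        else 0.0
    )
    for repetition in range(1, N_REPETITIONS + 1):
        stage = LEARNING if repetition <= 4 else IMPLEMENTATION
        if repetition == 5:
            aux.append(
                AuxEvent("warning", t, timing.warning_duration, run, block, condition)
            )
            t += timing.warning_duration
        order = rng.permutation(len(stimuli))
        for k in order:
            trials.append(
                TrialEvent(
                    run=run,
                    block=block,
                    condition=condition,
                    stage=stage,
                    stimulus=stimuli[k],
                    repetition=repetition,
                    onset=t,
                    duration=timing.trial_duration,
                    practice=practice,
                )
            )
            t += timing.trial_duration
            if stage == LEARNING:
                t += learning_fb
            t += rng.uniform(*timing.iti_range)
    aux.append(
        AuxEvent("block_feedback", t, timing.block_feedback_duration, run, block, condition)
    )
    t += timing.block_feedback_duration
    return trials, aux, t


def generate_design(
    subject_id: str = "sub-01",
    behavior: BehaviorParams | None = None,
    timing: TimingConfig | None = None,
    seed: int = 0,
    n_blocks: int = 24,
    n_practice_blocks: int = 3,
) -> ExperimentDesign:
    """Generate a subject's trial schedule (responses left empty).

    ``n_blocks`` must be a multiple of 6 (each run holds 6 blocks, 2 per
    learning condition); the default of 24 blocks yields the full 768-trial
    session. Condition order within runs, stimulus-to-block assignment,
    within-chunk stimulus order, and all jitters are drawn from ``seed``.
    """
    timing = timing or TimingConfig()
    timing.validate()
    if behavior is not None:
        behavior.validate()
    if n_blocks <= 0 or n_blocks % BLOCKS_PER_RUN != 0:
        raise DesignConfigError(
            f"n_blocks must be a positive multiple of {BLOCKS_PER_RUN}"
        )
    rng = _seed_streams(seed)["design"]

    n_runs = n_blocks // BLOCKS_PER_RUN
    total_blocks = n_blocks + n_practice_blocks
    pool_size = max(STIMULUS_POOL_SIZE, total_blocks * N_STIMULI_PER_BLOCK)
    pool = rng.permutation(np.arange(1, pool_size + 1))
    block_stimuli = {
        b + 1: sorted(pool[b * 4 : b * 4 + 4].tolist()) for b in range(total_blocks)
    }

    sr_map: dict[int, dict[int, int]] = {}
    for b in range(1, total_blocks + 1):
        responses = rng.permutation(np.arange(1, 5))
        sr_map[b] = {s: int(r) for s, r in zip(block_stimuli[b], responses)}

    trials: list[TrialEvent] = []
    aux: list[AuxEvent] = []
    block = 0
    for run in range(1, n_runs + 1):
        conditions = [
            Condition.INSTRUCTION,
            Condition.INSTRUCTION,
            Condition.TRIAL_AND_ERROR,
            Condition.TRIAL_AND_ERROR,
            Condition.OBSERVATION,
            Condition.OBSERVATION,
        ]
        order = rng.permutation(len(conditions))
        t = 0.0
        for j in order:
            block += 1
            t += float(rng.choice(timing.block_onset_jitter))
            bt, ba, t = _layout_block(
                rng, timing, run, block, conditions[j], block_stimuli[block], t, False
            )
            trials.extend(bt)
            aux.extend(ba)

    practice: list[TrialEvent] = []
    practice_conditions = [
        Condition.INSTRUCTION,
        Condition.TRIAL_AND_ERROR,
        Condition.OBSERVATION,
    ]
    t = 0.0
    for i in range(n_practice_blocks):
        block += 1
        cond = practice_conditions[i % 3]
        bt, _, t = _layout_block(
            rng, timing, 0, block, cond, block_stimuli[block], t, True
        )
        practice.extend(bt)

    design = ExperimentDesign(
        subject_id=subject_id,
        trials=trials,
        aux_events=aux,
        stimulus_response_map=sr_map,
        seed=seed,
        timing=timing,
        practice_trials=practice,
    )
    design.validate()
    return design


# ---------------------------------------------------------------------------
# Simulated behavior
# ---------------------------------------------------------------------------

def _draw_rt(rng: np.random.Generator, mean: float, sd: float, cap: float) -> float:
    return float(np.clip(rng.normal(mean, sd), 0.15, cap))


def _fill_responding_learning(
    trials: list[TrialEvent],
    sr_map: dict[int, dict[int, int]],
    behavior: BehaviorParams,
    rng: np.random.Generator,
    with_rt: bool,
) -> None:
    """Fill learning-stage responses for one block of overt/observed responding."""
    tried: dict[int, set[int]] = {}
    for t in sorted(trials, key=lambda x: x.onset):
        correct_resp = sr_map[t.block][t.stimulus]
        p = behavior.accuracy_by_repetition[t.repetition - 1]
        correct = bool(rng.random() < p)
        if correct:
            resp = correct_resp
        else:
            options = {1, 2, 3, 4} - {correct_resp}
            if behavior.response_strategy == "eliminate_tried":
                remaining = options - tried.setdefault(t.stimulus, set())
                options = remaining or options
            resp = int(rng.choice(sorted(options)))
        tried.setdefault(t.stimulus, set()).add(resp)
        t.response = resp
        t.correct = correct
        t.rt = (
            _draw_rt(
                rng,
                behavior.rt_mean_by_repetition[t.repetition - 1],
                behavior.rt_sd,
                t.duration,
            )
            if with_rt
            else None
        )


def _fill_implementation(
    trials: list[TrialEvent],
    sr_map: dict[int, dict[int, int]],
    behavior: BehaviorParams,
    rng: np.random.Generator,
) -> None:
    for t in sorted(trials, key=lambda x: x.onset):
        correct_resp = sr_map[t.block][t.stimulus]
        correct = bool(rng.random() < behavior.implementation_accuracy)
        t.correct = correct
        t.response = (
            correct_resp
            if correct
            else int(rng.choice(sorted({1, 2, 3, 4} - {correct_resp})))
        )
        t.rt = _draw_rt(rng, behavior.implementation_rt_mean, behavior.rt_sd, t.duration)


def simulate_te_behavior(
    design: ExperimentDesign,
    behavior: BehaviorParams | None = None,
    seed: int | None = None,
) -> ExperimentDesign:
    """Simulate responding: trial-and-error learning trials and all
    implementation trials gain responses; instruction learning trials are
    marked correct (no response required).

    Correctness at trial-and-error learning repetition ``r`` is Bernoulli with
    probability ``accuracy_by_repetition[r-1]``; under the ``eliminate_tried``
    strategy an incorrect response is drawn uniformly from the responses not
    yet tried for that stimulus in its block. Modifies ``design`` in place and
    returns it. When ``seed`` is None the design's behavior stream is used.
    """
    behavior = behavior or BehaviorParams()
    behavior.validate()
    rng = (
        _seed_streams(design.seed)["behavior"]
        if seed is None
        else np.random.default_rng(seed)
    )
    for group in (design.trials, design.practice_trials):
        for t in group:
            if t.condition is Condition.INSTRUCTION and t.stage == LEARNING:
                t.correct = True
                t.response = None
                t.rt = None
        for block in sorted({t.block for t in group}):
            te_learning = [
                t
                for t in group
                if t.block == block
                and t.stage == LEARNING
                and t.condition is Condition.TRIAL_AND_ERROR
            ]
            if te_learning:
                _fill_responding_learning(
                    te_learning, design.stimulus_response_map, behavior, rng, True
                )
            impl = [t for t in group if t.block == block and t.stage == IMPLEMENTATION]
            _fill_implementation(impl, design.stimulus_response_map, behavior, rng)
    return design


def yoke_observation(
    design: ExperimentDesign,
    ledger: YokeLedger | None = None,
    behavior: BehaviorParams | None = None,
) -> ExperimentDesign:
    """Fill observation learning trials with observed responses and feedback.

    With a ledger, the source subject's trial-and-error learning record is
    replayed trial for trial onto this subject's observation learning trials.
    Without one (the first cohort set), observed responding is simulated from
    default (pilot-like) behavioral parameters.
    """
    obs_learning = sorted(
        (
            t
            for t in design.trials
            if t.condition is Condition.OBSERVATION and t.stage == LEARNING
        ),
        key=lambda t: (t.run, t.onset),
    )
    behavior = behavior or BehaviorParams()
    rng = _seed_streams(design.seed)["observation"]
    # practice observation blocks are never yoked; fill them from defaults
    practice_obs = [
        t
        for t in design.practice_trials
        if t.condition is Condition.OBSERVATION and t.stage == LEARNING
    ]
    for block in sorted({t.block for t in practice_obs}):
        _fill_responding_learning(
            [t for t in practice_obs if t.block == block],
            design.stimulus_response_map,
            behavior,
            rng,
            with_rt=False,
        )
    if ledger is None:
        for block in sorted({t.block for t in obs_learning}):
            _fill_responding_learning(
                [t for t in obs_learning if t.block == block],
                design.stimulus_response_map,
                behavior,
                rng,
                with_rt=False,
            )
        return design
    if len(ledger.records) != len(obs_learning):
        raise DesignStructureError(
            f"yoke ledger holds {len(ledger.records)} records but the design "
            f"has {len(obs_learning)} observation learning trials"
        )
    for t, (resp, correct, _rt) in zip(obs_learning, ledger.records):
        t.response = resp
        t.correct = correct
        t.rt = None  # observed, not produced, responses carry no RT
    return design


def recode_repetitions_by_accuracy(design: ExperimentDesign) -> ExperimentDesign:
    """Re-code stimulus repetitions by accuracy within each stage.

    For each (block, stimulus, stage), correct trials receive
    ``recoded_repetition`` 1..n in temporal order and incorrect trials
    independently 1..m; in an all-correct stage the recoded repetition equals
    the within-stage repetition rank. Instruction learning trials are all
    coded correct.
    """
    for group in (design.trials, design.practice_trials):
        keys = {(t.block, t.stimulus, t.stage) for t in group}
        for key in keys:
            seq = sorted(
                (t for t in group if (t.block, t.stimulus, t.stage) == key),
                key=lambda t: t.onset,
            )
            n_correct = 0
            n_incorrect = 0
            for t in seq:
                if t.correct is None:
                    raise DesignStructureError(
                        "cannot recode repetitions before responses are populated"
                    )
                if t.correct:
                    n_correct += 1
                    t.recoded_repetition = n_correct
                else:
                    n_incorrect += 1
                    t.recoded_repetition = n_incorrect
    return design


def generate_subject(
    subject_id: str = "sub-01",
    behavior: BehaviorParams | None = None,
    timing: TimingConfig | None = None,
    seed: int = 0,
    n_blocks: int = 24,
    ledger: YokeLedger | None = None,
) -> ExperimentDesign:
    """Convenience chain: generate the schedule, simulate behavior, yoke the
    observation condition, and recode repetitions by accuracy."""
    design = generate_design(
        subject_id=subject_id, behavior=behavior, timing=timing, seed=seed, n_blocks=n_blocks
    )
    simulate_te_behavior(design, behavior)
    yoke_observation(design, ledger, behavior)
    recode_repetitions_by_accuracy(design)
    return design
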