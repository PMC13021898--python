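"""Trial plans for the RSK experiments: mappings, congruence, timing, sequencing.

Four designs are generated exactly as run in the original study:

* **1a** — motion task, univalent stimuli (uniform crowd color), 10 motion
  coherence levels x 2 uniform colors x 6 replicates = 120 trials in 2
  blocks of 60.
* **1b** — color task, 0% motion coherence, 5 color-coherence levels x 2
  majority colors x 6 replicates = 60 trials in one block.
* **2** — both tasks over the full bivalent grid: 10 motion levels x 10
  color conditions, each replicated 4 times per task = 400 trials per task
  in blocks of 50.
* **3** — cued task switching at fixed 75/75 coherence: a sandwich of
  2 single-task blocks, 8 mixed-task blocks, 2 single-task blocks, 64
  trials each, CSI (cue-stimulus interval) of 200 or 800 ms blocked, with
  the response-stimulus interval held at 2000 ms.

All orders are pseudorandomized by rejection sampling (shuffle, check the
run-length constraints, retry), deterministic given the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kinematogram import KHAKI, LEFTWARD, RIGHTWARD, WHITE

__all__ = [
    "MOTION",
    "COLOR",
    "LEFT",
    "RIGHT",
    "SHORT_CSI_MS",
    "LONG_CSI_MS",
    "TRIAL_COLUMNS",
    "ResponseMapping",
    "TimingConfig",
    "ExperimentPlan",
    "PlanValidationReport",
    "GenerationError",
    "UnivalentTrialError",
    "is_bivalent",
    "signed_distractor_congruence",
    "build_exp1a_design",
    "build_exp1b_design",
    "build_exp2_design",
    "build_exp3_design",
    "build_design",
    "trial_timeline",
    "validate_plan",
    "counterbalancing_assignment",
    "attach_previous_congruency",
]

MOTION = "motion"
COLOR = "color"
TASKS = (MOTION, COLOR)

LEFT = "left"
RIGHT = "right"

SHORT_CSI_MS = 200
LONG_CSI_MS = 800

#: Canonical column order of a trial record / trial log.
TRIAL_COLUMNS = [
    "participant_id",
    "experiment",
    "block_index",
    "trial_index",
    "task",
    "motion_coherence",
    "direction",
    "color_coherence",
    "majority_color",
    "csi_ms",
    "sequence_type",
    "congruent",
    "congruency_n_minus_1",
    "correct_response",
    "response",
    "rt_ms",
    "correct",
]

MOTION_COHERENCE_LEVELS = tuple(np.arange(5, 100, 10) / 100.0)  # 0.05 .. 0.95
COLOR_COHERENCE_LEVELS = tuple(np.arange(55, 100, 10) / 100.0)  # 0.55 .. 0.95


class GenerationError(RuntimeError):
    """Sequencing constraints could not be satisfied within the attempt cap."""


class UnivalentTrialError(ValueError):
    """Congruence is undefined for a stimulus affording only one response."""


@dataclass(frozen=True)
class ResponseMapping:
    """Stimulus-response mapping shared by the two tasks.

    The motion mapping is fixed and spatially compatible (leftward motion ->
    left key, rightward -> right key).  The color mapping (khaki -> left,
    white -> right by default) is counterbalanced across participants via
    ``color_mapping_flipped``.
    """

    color_mapping_flipped: bool = False

    def motion_side(self, direction: str) -> str:
        if direction == LEFTWARD:
            return LEFT
        if direction == RIGHTWARD:
            return RIGHT
        raise ValueError(f"unknown direction {direction!r}")

    def color_side(self, majority_color: str) -> str:
        if majority_color not in (KHAKI, WHITE):
            raise ValueError(f"unknown color {majority_color!r}")
        base = LEFT if majority_color == KHAKI else RIGHT
        if self.color_mapping_flipped:
            return RIGHT if base == LEFT else LEFT
        return base

    def correct_side(self, task: str, direction, majority_color) -> str:
        """Response side required by the task-relevant dimension."""
        if task == MOTION:
            return self.motion_side(direction)
        if task == COLOR:
            return self.color_side(majority_color)
        raise ValueError(f"unknown task {task!r}")

    def distractor_side(self, task: str, direction, majority_color):
        """Response side the task-irrelevant dimension maps to (None if absent)."""
        if task == MOTION:
            return self.color_side(majority_color)
        if task == COLOR:
            if direction is None or (isinstance(direction, float) and np.isnan(direction)):
                return None
            return self.motion_side(direction)
        raise ValueError(f"unknown task {task!r}")


@dataclass(frozen=True)
class TimingConfig:
    """Within-trial timing.

    In the task-switching design the cue appears for ``csi_ms`` (200 or 800
    ms) between fixation and stimulus, and the post-response blank lasts
    ``1000 - csi_ms`` so that blank + fixation + CSI — the response-stimulus
    interval — equals 2000 ms for both CSIs.  With ``csi_ms=None`` the trial
    is uncued (fixation then stimulus), as in the single-task experiments.
    """

    fixation_ms: int = 1000
    csi_ms: int | None = None
    max_stim_ms: int = 2000

    def __post_init__(self) -> None:
        if self.csi_ms is not None and self.csi_ms not in (SHORT_CSI_MS, LONG_CSI_MS):
            raise ValueError(
                f"csi_ms must be {SHORT_CSI_MS}, {LONG_CSI_MS} or None, got {self.csi_ms}"
            )

    @property
    def blank_ms(self) -> int | None:
        if self.csi_ms is None:
            return None
        return 1000 - self.csi_ms

    @property
    def rsi_ms(self) -> int | None:
        """Response-to-stimulus interval; constant across CSI by construction."""
        if self.csi_ms is None:
            return None
        return self.blank_ms + self.fixation_ms + self.csi_ms


@dataclass
class ExperimentPlan:
    """Ordered trial records of one experiment, plus generation metadata."""

    experiment: str
    trials: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def block(self, index: int) -> pd.DataFrame:
        return self.trials[self.trials["block_index"] == index]

    @property
    def n_blocks(self) -> int:
        return int(self.trials["block_index"].nunique())


def is_bivalent(motion_coherence: float, color_coherence: float) -> bool:
    """Whether a stimulus affords a response under both task rules.

    A crowd with no coherent motion has no direction signal, and a fully
    uniform crowd (100% color coherence) is treated as carrying no competing
    color decision, so both are univalent for congruence purposes.
    """
    return motion_coherence > 0.0 and color_coherence < 1.0


def _congruent(
    task: str,
    direction,
    majority_color,
    mapping: ResponseMapping,
) -> bool:
    correct = mapping.correct_side(task, direction, majority_color)
    distractor = mapping.distractor_side(task, direction, majority_color)
    return correct == distractor


def signed_distractor_congruence(
    trial,
    mapping: ResponseMapping = ResponseMapping(),
) -> float:
    """Signed distractor congruence of a bivalent trial, in percent.

    The magnitude is the distractor dimension's coherence x 100; the sign is
    positive when the distractor maps (via the response mapping) onto the same
    response as the correct one, negative otherwise.  In the color task the
    distractor is motion, spanning 20 signed levels (±5..±95); in the motion
    task it is color, spanning 10 signed levels (±55..±95).

    ``trial`` is any mapping-like record (``pandas.Series`` row or dict) with
    the trial-log stimulus fields.
    """
    motion_c = float(trial["motion_coherence"])
    color_c = float(trial["color_coherence"])
    if not is_bivalent(motion_c, color_c):
        raise UnivalentTrialError(
            "signed distractor congruence is undefined for univalent stimuli"
        )
    task = trial["task"]
    magnitude = 100.0 * (motion_c if task == COLOR else color_c)
    sign = 1.0 if _congruent(task, trial["direction"], trial["majority_color"], mapping) else -1.0
    return sign * magnitude


# ---------------------------------------------------------------------------
# pseudorandomization helpers
# ---------------------------------------------------------------------------


def _max_run(values: Sequence) -> int:
    best = run = 1
    vals = list(values)
    for prev, cur in zip(vals, vals[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best if vals else 0


def _shuffle_with_run_limit(
    df: pd.DataFrame,
    key: str | list[str],
    rng: np.random.Generator,
    max_run: int = 4,
    max_attempts: int = 10_000,
) -> pd.DataFrame:
    """Shuffle rows until no run of identical ``key`` values exceeds ``max_run``."""
    keys = [key] if isinstance(key, str) else list(key)
    for _ in range(max_attempts):
        shuffled = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
        if all(_max_run(shuffled[k].tolist()) <= max_run for k in keys):
            return shuffled
    raise GenerationError(
        f"could not satisfy run-length constraint on {keys} in {max_attempts} attempts"
    )


def _partition_blocks(
    df: pd.DataFrame, block_size: int, rng: np.random.Generator
) -> list[pd.DataFrame]:
    if len(df) % block_size:
        raise ValueError("trial count is not a multiple of the block size")
    shuffled = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    return [
        shuffled.iloc[i : i + block_size].reset_index(drop=True)
        for i in range(0, len(df), block_size)
    ]


def _assemble(
    experiment: str,
    blocks: list[pd.DataFrame],
    mapping: ResponseMapping,
    metadata: dict,
) -> ExperimentPlan:
    """Stamp indices, congruence bookkeeping and column order onto raw blocks."""
    out = []
    for b_idx, block in enumerate(blocks):
        block = block.copy()
        block["block_index"] = b_idx
        block["trial_index"] = np.arange(len(block))
        out.append(block)
    trials = pd.concat(out, ignore_index=True)
    trials["experiment"] = experiment
    trials["participant_id"] = 0

    bivalent = [
        is_bivalent(m, c)
        for m, c in zip(trials["motion_coherence"], trials["color_coherence"])
    ]
    congruent = [
        _congruent(t, d, mc, mapping) if biv else pd.NA
        for biv, t, d, mc in zip(
            bivalent, trials["task"], trials["direction"], trials["majority_color"]
        )
    ]
    trials["congruent"] = pd.array(congruent, dtype="boolean")
    trials["correct_response"] = [
        mapping.correct_side(t, d, mc)
        for t, d, mc in zip(trials["task"], trials["direction"], trials["majority_color"])
    ]
    trials["response"] = pd.array([pd.NA] * len(trials), dtype="string")
    trials["rt_ms"] = np.nan
    trials["correct"] = pd.array([pd.NA] * len(trials), dtype="boolean")
    trials = attach_previous_congruency(trials)
    trials = trials[TRIAL_COLUMNS]
    return ExperimentPlan(experiment=experiment, trials=trials, metadata=metadata)


def attach_previous_congruency(trials: pd.DataFrame) -> pd.DataFrame:
    """Set ``congruency_n_minus_1`` to the previous trial's congruent flag.

    Computed within (participant, block); the first trial of a block has no
    well-defined previous trial and gets NA.
    """
    trials = trials.copy()
    shifted = trials.groupby(["participant_id", "block_index"], sort=False)[
        "congruent"
    ].shift(1)
    trials["congruency_n_minus_1"] = pd.array(shifted, dtype="boolean")
    return trials


# ---------------------------------------------------------------------------
# experiment builders
# ---------------------------------------------------------------------------


def build_exp1a_design(
    seed: int, mapping: ResponseMapping | None = None
) -> ExperimentPlan:
    """Motion task with univalent (uniform-color) stimuli.

    10 motion-coherence levels (5..95%) x 2 uniform colors x 6 replicates =
    120 trials; leftward/rightward balanced within every level x color cell;
    2 blocks of 60, pseudorandomized with at most 4 consecutive trials
    requiring the same response.
    """
    mapping = mapping or ResponseMapping()
    rng = np.random.default_rng(seed)
    rows = []
    for color in (KHAKI, WHITE):
        for level in MOTION_COHERENCE_LEVELS:
            for rep in range(6):
                rows.append(
                    {
                        "task": MOTION,
                        "motion_coherence": level,
                        "direction": LEFTWARD if rep % 2 == 0 else RIGHTWARD,
                        "color_coherence": 1.0,
                        "majority_color": color,
                        "csi_ms": np.nan,
                        "sequence_type": "single",
                    }
                )
    df = pd.DataFrame(rows)
    blocks = [
        _shuffle_with_run_limit(b, "direction", rng)
        for b in _partition_blocks(df, 60, rng)
    ]
    return _assemble("1a", blocks, mapping, {"seed": seed})


def build_exp1b_design(
    seed: int, mapping: ResponseMapping | None = None
) -> ExperimentPlan:
    """Color task with no coherent motion.

    5 color-coherence levels (55..95%) x 2 majority colors x 6 replicates =
    60 trials in one block; motion coherence fixed at 0 (all agents move on
    random linear paths, so there is no direction signal).
    """
    mapping = mapping or ResponseMapping()
    rng = np.random.default_rng(seed)
    rows = []
    for color in (KHAKI, WHITE):
        for level in COLOR_COHERENCE_LEVELS:
            for rep in range(6):
                rows.append(
                    {
                        "task": COLOR,
                        "motion_coherence": 0.0,
                        # direction is irrelevant at 0% coherence; kept balanced
                        # so exported stimuli remain well-formed
                        "direction": LEFTWARD if rep % 2 == 0 else RIGHTWARD,
                        "color_coherence": level,
                        "majority_color": color,
                        "csi_ms": np.nan,
                        "sequence_type": "single",
                    }
                )
    df = pd.DataFrame(rows)
    block = _shuffle_with_run_limit(df, "majority_color", rng)
    return _assemble("1b", [block], mapping, {"seed": seed})


def _exp2_stimulus_grid(
    rng: np.random.Generator, max_attempts: int = 1000
) -> pd.DataFrame:
    """The 100 unique bivalent stimuli of the full coherence grid.

    10 motion levels x (5 color levels x 2 majority colors); directions are
    assigned so that each majority x direction cell holds exactly 25 stimuli
    (5 leftward and 5 rightward per majority x color-level row), which makes
    congruent and incongruent trials equally probable.  The draw is rejected
    until every motion level occurs both congruently and incongruently, so
    the color task spans all 20 signed distractor-congruence levels.
    """
    for _ in range(max_attempts):
        rows = []
        for majority in (KHAKI, WHITE):
            for c_level in COLOR_COHERENCE_LEVELS:
                directions = np.array([LEFTWARD] * 5 + [RIGHTWARD] * 5, dtype=object)
                rng.shuffle(directions)
                for m_level, direction in zip(MOTION_COHERENCE_LEVELS, directions):
                    rows.append(
                        {
                            "motion_coherence": m_level,
                            "direction": direction,
                            "color_coherence": c_level,
                            "majority_color": majority,
                        }
                    )
        grid = pd.DataFrame(rows)
        congruent = (grid["majority_color"] == KHAKI) == (
            grid["direction"] == LEFTWARD
        )
        signs_per_level = congruent.groupby(grid["motion_coherence"]).nunique()
        if (signs_per_level == 2).all():
            return grid
    raise GenerationError(
        f"could not cover all signed congruence levels in {max_attempts} attempts"
    )


def build_exp2_design(
    seed: int,
    first_task: str = MOTION,
    mapping: ResponseMapping | None = None,
) -> ExperimentPlan:
    """Both tasks over the full bivalent grid, in two single-task series.

    Each of the 100 unique stimuli is replicated 4 times per task (400 trials
    per task, 800 total), presented in blocks of 50 with at most 4 consecutive
    trials requiring the same response.  The series for ``first_task`` comes
    first.
    """
    if first_task not in TASKS:
        raise ValueError(f"first_task must be one of {TASKS}")
    mapping = mapping or ResponseMapping()
    rng = np.random.default_rng(seed)
    grid = _exp2_stimulus_grid(rng)
    second = COLOR if first_task == MOTION else MOTION
    blocks = []
    for task in (first_task, second):
        trials = pd.concat([grid] * 4, ignore_index=True)
        trials["task"] = task
        trials["csi_ms"] = np.nan
        trials["sequence_type"] = "single"
        trials["_response_key"] = [
            mapping.correct_side(task, d, mc)
            for d, mc in zip(trials["direction"], trials["majority_color"])
        ]
        for raw in _partition_blocks(trials, 50, rng):
            blocks.append(
                _shuffle_with_run_limit(raw, "_response_key", rng).drop(
                    columns="_response_key"
                )
            )
    return _assemble(
        "2", blocks, mapping, {"seed": seed, "first_task": first_task}
    )


DEFAULT_MIXED_CSI_ORDER = (200, 800, 800, 200, 200, 800, 800, 200)
#: CSIs of the four single-task blocks (order: first task, second task,
#: second task again, first task again), giving each task x CSI cell one block.
SINGLE_CSI_ORDER = (200, 800, 200, 800)
EXP3_COHERENCE = 0.75


def _exp3_stimulus_pool() -> pd.DataFrame:
    """64 stimuli per block: 16 per direction x majority combination."""
    rows = []
    for direction in (LEFTWARD, RIGHTWARD):
        for majority in (KHAKI, WHITE):
            rows.extend(
                {
                    "motion_coherence": EXP3_COHERENCE,
                    "direction": direction,
                    "color_coherence": EXP3_COHERENCE,
                    "majority_color": majority,
                }
                for _ in range(16)
            )
    return pd.DataFrame(rows)


def _mixed_block_tasks(
    prev_task: str, rng: np.random.Generator, max_attempts: int
) -> tuple[list[str], list[str]]:
    """Task and nominal sequence-type lists for one 64-trial mixed block.

    Rejection-samples a permutation of 32 switch + 32 repeat flags.  The task
    sequence follows deterministically from the previous block's last task:
    each switch toggles the task.  Accepts when repeat trials split 16/16
    across tasks (switches alternate and split 16/16 automatically) and no
    more than 4 consecutive trials share a sequence type.
    """
    flags = np.array(["switch"] * 32 + ["repeat"] * 32, dtype=object)
    for _ in range(max_attempts):
        rng.shuffle(flags)
        if _max_run(flags) > 4:
            continue
        tasks = []
        cur = prev_task
        for f in flags:
            if f == "switch":
                cur = COLOR if cur == MOTION else MOTION
            tasks.append(cur)
        n_repeat_motion = sum(
            1 for f, t in zip(flags, tasks) if f == "repeat" and t == MOTION
        )
        if n_repeat_motion != 16:
            continue
        return list(tasks), list(flags)
    raise GenerationError(
        "could not build a mixed-block task sequence "
        f"(prev_task={prev_task}) in {max_attempts} attempts"
    )


def build_exp3_design(
    seed: int,
    first_task: str = MOTION,
    csi_block_order: Sequence[int] | None = None,
    color_mapping_flipped: bool = False,
    max_attempts: int = 10_000,
) -> ExperimentPlan:
    """Cued task-switching sandwich design at fixed 75/75 coherence.

    12 blocks of 64 trials: single-task blocks of the two tasks, eight
    mixed-task blocks, then the two single-task blocks in reverse task order.
    Mixed blocks hold 32 switch and 32 repeat trials, equally distributed
    across tasks; majority color and direction are equiprobable in every
    block; at most 4 consecutive trials share a sequence type or a response
    key.  ``csi_block_order`` gives the CSI of the eight mixed blocks (four
    short, four long; default ABBA-BAAB-like alternation); CSI is constant
    within a block.
    """
    if first_task not in TASKS:
        raise ValueError(f"first_task must be one of {TASKS}")
    csi_order = tuple(csi_block_order or DEFAULT_MIXED_CSI_ORDER)
    if len(csi_order) != 8 or sorted(csi_order) != [200] * 4 + [800] * 4:
        raise ValueError("csi_block_order must contain four 200s and four 800s")
    mapping = ResponseMapping(color_mapping_flipped=color_mapping_flipped)
    rng = np.random.default_rng(seed)
    second = COLOR if first_task == MOTION else MOTION

    block_tasks: list = [first_task, second] + ["mixed"] * 8 + [second, first_task]
    single_csis = iter(SINGLE_CSI_ORDER)
    mixed_csis = iter(csi_order)

    blocks: list[pd.DataFrame] = []
    prev_task = None
    for b_idx, b_task in enumerate(block_tasks):
        pool = _exp3_stimulus_pool()
        if b_task != "mixed":
            block = pool.copy()
            block["task"] = b_task
            block["sequence_type"] = "single"
            block["csi_ms"] = float(next(single_csis))
            block["_response_key"] = [
                mapping.correct_side(b_task, d, mc)
                for d, mc in zip(block["direction"], block["majority_color"])
            ]
            block = _shuffle_with_run_limit(
                block, "_response_key", rng, max_attempts=max_attempts
            ).drop(columns="_response_key")
            prev_task = b_task
        else:
            tasks, flags = _mixed_block_tasks(prev_task, rng, max_attempts)
            for _ in range(max_attempts):
                stim = pool.iloc[rng.permutation(len(pool))].reset_index(drop=True)
                responses = [
                    mapping.correct_side(t, d, mc)
                    for t, d, mc in zip(tasks, stim["direction"], stim["majority_color"])
                ]
                if _max_run(responses) <= 4:
                    break
            else:
                raise GenerationError(
                    f"could not satisfy the response run constraint in mixed "
                    f"block {b_idx} within {max_attempts} attempts"
                )
            block = stim
            block["task"] = tasks
            block["sequence_type"] = flags
            block["csi_ms"] = float(next(mixed_csis))
            prev_task = tasks[-1]
        blocks.append(block)

    return _assemble(
        "3",
        blocks,
        mapping,
        {
            "seed": seed,
            "first_task": first_task,
            "csi_block_order": list(csi_order),
            "single_csi_order": list(SINGLE_CSI_ORDER),
            "color_mapping_flipped": color_mapping_flipped,
        },
    )


_BUILDERS = {
    "1a": build_exp1a_design,
    "1b": build_exp1b_design,
    "2": build_exp2_design,
    "3": build_exp3_design,
}


def build_design(experiment: str, seed: int, **kwargs) -> ExperimentPlan:
    """Dispatch to the builder for ``experiment`` in {'1a','1b','2','3'}."""
    try:
        builder = _BUILDERS[experiment]
    except KeyError:
        raise ValueError(f"unknown experiment {experiment!r}") from None
    return builder(seed, **kwargs)


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------


def trial_timeline(
    trial, timing: TimingConfig | None = None
) -> list[tuple[str, int, int]]:
    """Ordered (event, onset_ms, duration_ms) list for one trial.

    Onsets are measured from the previous trial's response (or block start).
    Cued trials run blank -> fixation -> cue -> stimulus with the blank
    lasting ``1000 - CSI`` ms, so the stimulus always starts 2000 ms after
    the previous response regardless of CSI.  Uncued trials (single-task
    experiments) run fixation -> stimulus.
    """
    timing = timing or TimingConfig()
    csi = trial["csi_ms"] if hasattr(trial, "__getitem__") else trial.csi_ms
    if csi is None or (isinstance(csi, float) and np.isnan(csi)):
        csi = timing.csi_ms
    if csi is None:
        return [
            ("fixation", 0, timing.fixation_ms),
            ("stimulus", timing.fixation_ms, timing.max_stim_ms),
        ]
    csi = int(csi)
    if csi not in (SHORT_CSI_MS, LONG_CSI_MS):
        raise ValueError(f"csi_ms must be {SHORT_CSI_MS} or {LONG_CSI_MS}, got {csi}")
    blank = 1000 - csi
    return [
        ("blank", 0, blank),
        ("fixation", blank, timing.fixation_ms),
        ("cue", blank + timing.fixation_ms, csi),
        ("stimulus", blank + timing.fixation_ms + csi, timing.max_stim_ms),
    ]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class PlanValidationReport:
    """Outcome of :func:`validate_plan`: summary counts plus violations."""

    experiment: str
    summary: dict
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _check(report: PlanValidationReport, condition: bool, message: str) -> None:
    if not condition:
        report.violations.append(message)


def validate_plan(plan: ExperimentPlan) -> PlanValidationReport:
    """Report-only constraint checker for any generated (or imported) plan."""
    t = plan.trials
    report = PlanValidationReport(experiment=plan.experiment, summary={})
    missing = [c for c in TRIAL_COLUMNS if c not in t.columns]
    if missing:
        report.violations.append(f"missing columns: {missing}")
        return report

    run_resp = max(
        (_max_run(b["correct_response"].tolist()) for _, b in t.groupby("block_index")),
        default=0,
    )
    report.summary["n_trials"] = len(t)
    report.summary["n_blocks"] = int(t["block_index"].nunique())
    report.summary["max_response_run"] = run_resp
    report.summary["coherence_grid"] = sorted(
        set(zip(t["motion_coherence"], t["color_coherence"]))
    )
    _check(report, run_resp <= 4, f"response-key run of {run_resp} exceeds 4")
    for b_idx, b in t.groupby("block_index"):
        _check(
            report,
            list(b["trial_index"]) == list(range(len(b))),
            f"block {b_idx}: trial_index not contiguous from 0",
        )

    exp = plan.experiment
    if exp == "1a":
        _check(report, len(t) == 120, f"expected 120 trials, got {len(t)}")
        _check(report, report.summary["n_blocks"] == 2, "expected 2 blocks")
        _check(
            report,
            (t.groupby("block_index").size() == 60).all(),
            "expected blocks of 60",
        )
        n_left = int((t["direction"] == LEFTWARD).sum())
        _check(report, n_left == 60, f"expected 60 leftward trials, got {n_left}")
        cells = t.groupby(["motion_coherence", "majority_color"]).size()
        _check(report, (cells == 6).all(), "each level x color cell must hold 6 trials")
        _check(report, (t["color_coherence"] == 1.0).all(), "color coherence must be 100%")
    elif exp == "1b":
        _check(report, len(t) == 60, f"expected 60 trials, got {len(t)}")
        _check(report, (t["motion_coherence"] == 0.0).all(), "motion coherence must be 0")
        per_majority = t["majority_color"].value_counts()
        _check(
            report,
            per_majority.get(KHAKI, 0) == 30 and per_majority.get(WHITE, 0) == 30,
            "expected 30 khaki-majority and 30 white-majority trials",
        )
        cells = t.groupby(["color_coherence", "majority_color"]).size()
        _check(report, (cells == 6).all(), "each level x majority cell must hold 6 trials")
    elif exp == "2":
        _check(report, len(t) == 800, f"expected 800 trials, got {len(t)}")
        per_task = t["task"].value_counts()
        report.summary["trials_per_task"] = per_task.to_dict()
        _check(
            report,
            per_task.get(MOTION, 0) == 400 and per_task.get(COLOR, 0) == 400,
            "expected 400 trials per task",
        )
        _check(
            report,
            (t.groupby("block_index").size() == 50).all(),
            "expected blocks of 50",
        )
        for task, sub in t.groupby("task"):
            cells = sub.groupby(["majority_color", "direction"]).size()
            _check(
                report,
                (cells == 100).all(),
                f"{task} task: each majority x direction cell must hold 100 trials "
                "(25 unique stimuli x 4 replicates)",
            )
            combos = sub.groupby(
                ["motion_coherence", "direction", "color_coherence", "majority_color"]
            ).size()
            _check(
                report,
                len(combos) == 100 and (combos == 4).all(),
                f"{task} task: expected 100 unique stimuli x 4 replicates",
            )
            levels = {
                signed_distractor_congruence(row, ResponseMapping())
                for _, row in sub.drop_duplicates(
                    ["motion_coherence", "direction", "color_coherence", "majority_color"]
                ).iterrows()
            }
            expected = 20 if task == COLOR else 10
            _check(
                report,
                len(levels) == expected,
                f"{task} task: expected {expected} signed congruence levels, got {len(levels)}",
            )
    elif exp == "3":
        _check(report, len(t) == 768, f"expected 768 trials, got {len(t)}")
        _check(report, report.summary["n_blocks"] == 12, "expected 12 blocks")
        seq_totals = t["sequence_type"].value_counts().to_dict()
        report.summary["sequence_totals"] = seq_totals
        for kind in ("single", "repeat", "switch"):
            _check(
                report,
                seq_totals.get(kind, 0) == 256,
                f"expected 256 {kind} trials, got {seq_totals.get(kind, 0)}",
            )
        single = t[t["sequence_type"] == "single"]
        per_task_single = single["task"].value_counts()
        _check(
            report,
            per_task_single.get(MOTION, 0) == 128 and per_task_single.get(COLOR, 0) == 128,
            "expected 128 single-task trials per task",
        )
        _check(
            report,
            (t["motion_coherence"] == EXP3_COHERENCE).all()
            and (t["color_coherence"] == EXP3_COHERENCE).all(),
            "all stimuli must be at 75% motion and 75% color coherence",
        )
        _check(
            report,
            t["congruent"].notna().all(),
            "every 75/75 stimulus must have a defined congruency",
        )
        for b_idx, b in t.groupby("block_index"):
            _check(report, len(b) == 64, f"block {b_idx}: expected 64 trials")
            _check(
                report,
                b["csi_ms"].nunique() == 1,
                f"block {b_idx}: CSI must be constant within the block",
            )
            for col, want in (
                ("direction", {LEFTWARD: 32, RIGHTWARD: 32}),
                ("majority_color", {KHAKI: 32, WHITE: 32}),
            ):
                counts = b[col].value_counts().to_dict()
                _check(
                    report,
                    counts == want,
                    f"block {b_idx}: {col} counts {counts} != {want}",
                )
            n_congruent = int(b["congruent"].sum())
            _check(
                report,
                n_congruent == 32,
                f"block {b_idx}: expected 32 congruent trials, got {n_congruent}",
            )
            if set(b["sequence_type"]) != {"single"}:
                type_counts = b["sequence_type"].value_counts().to_dict()
                _check(
                    report,
                    type_counts.get("switch", 0) == 32
                    and type_counts.get("repeat", 0) == 32,
                    f"block {b_idx}: expected 32 switch + 32 repeat, got {type_counts}",
                )
                cell = b.groupby(["sequence_type", "task"]).size()
                _check(
                    report,
                    (cell == 16).all(),
                    f"block {b_idx}: switch/repeat must split 16 per task",
                )
                run_type = _max_run(b["sequence_type"].tolist())
                _check(
                    report,
                    run_type <= 4,
                    f"block {b_idx}: sequence-type run of {run_type} exceeds 4",
                )
        mixed_csis = sorted(
            t[t["sequence_type"].isin(["repeat", "switch"])]
            .groupby("block_index")["csi_ms"]
            .first()
            .tolist()
        )
        _check(
            report,
            mixed_csis == [200.0] * 4 + [800.0] * 4,
            f"expected four short and four long mixed-block CSIs, got {mixed_csis}",
        )
        single_cells = single.groupby(["task", "csi_ms"]).size()
        _check(
            report,
            len(single_cells) == 4 and (single_cells == 64).all(),
            "each single-task task x CSI cell must hold 64 trials",
        )
    else:
        report.violations.append(f"unknown experiment {exp!r}")
    return report


# ---------------------------------------------------------------------------
# counterbalancing
# ---------------------------------------------------------------------------


def counterbalancing_assignment(n_participants: int) -> pd.DataFrame:
    """Balanced participant-level counterbalancing flags.

    Cycles through the 8 combinations of first task x color-mapping flip x
    mixed-CSI block order (the default order or its short/long reversal), so
    any multiple of 8 participants is exactly balanced.
    """
    reversed_order = tuple(800 if c == 200 else 200 for c in DEFAULT_MIXED_CSI_ORDER)
    combos = list(
        itertools.product(
            (MOTION, COLOR), (False, True), (DEFAULT_MIXED_CSI_ORDER, reversed_order)
        )
    )
    rows = []
    for pid in range(n_participants):
        first_task, flipped, csi_order = combos[pid % len(combos)]
        rows.append(
            {
                "participant_id": pid,
                "first_task": first_task,
                "color_mapping_flipped": flipped,
                "csi_block_order": list(csi_order),
            }
        )
    return pd.DataFrame(rows)
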