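"""Synthetic observer: drift-diffusion decisions with task-switching costs.

The observer exists so the analysis pipeline can be exercised end-to-end on
trial logs with the qualitative structure reported for human participants:
accuracy rising and RT falling with target coherence, a distractor-congruence
effect in the color task only (task dominance), switch and mixing costs,
preparation (CSI) benefits, and an asymmetric switch cost after incongruent
color trials.  It is a generative stand-in, not a fitted model of any
participant.

Mechanism
---------
Each trial is a single-stage drift-diffusion race to symmetric boundaries
(+boundary = right response).  The drift is a weighted sum of signed target
and distractor evidence; evidence is signed by the response side the
dimension maps to (right positive).  Motion evidence is the motion coherence
itself (0 = no signal); color evidence is ``2*(coherence - 0.5)`` so a
50% majority carries no signal.

Sequential structure is injected through three channels:

* additive RT penalties — a mixed-block penalty on every mixed-block trial
  (mixing cost), a switch penalty on switch trials (switch cost), an inertia
  penalty when switching to the dominant motion task after an incongruent
  trial (asymmetric switch cost), minus a preparation benefit on mixed-block
  trials at the long CSI.  Additive RT penalties make the cost estimators of
  the analysis module unbiased for the injected constants.
* task-set intrusions — with some probability a mixed-block response is
  emitted under the *irrelevant* dimension's rule, which produces an error
  only on incongruent trials.  The rate is larger at the short CSI and larger
  again on switch trials, generating the error cost, the error-rate mixing
  cost and its preparatory reduction without touching correct-trial RTs.
* lapses — a small probability of a uniform random response.

Trials whose accumulator never crosses a boundary within the stimulus
lifetime (minus the trial's RT penalties) are timeouts: no response, scored
as errors downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .design import (
    COLOR,
    LEFT,
    MOTION,
    RIGHT,
    LONG_CSI_MS,
    SHORT_CSI_MS,
    ExperimentPlan,
    ResponseMapping,
)
from .kinematogram import LEFTWARD, RIGHTWARD

__all__ = [
    "ObserverParams",
    "ObserverState",
    "default_params",
    "drift_rate",
    "simulate_trial",
    "simulate_participant",
]


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of the synthetic participant.

    Drift gains are in evidence units per second per unit signed evidence;
    ``boundary`` is in evidence units, ``noise_sd`` in evidence per sqrt(s).
    Time parameters are in milliseconds.  Defaults are tuned to the sign
    patterns of the study (motion dominance, positive costs, residual switch
    cost, asymmetry), not to human effect magnitudes.
    """

    k_target_motion: float = 7.5
    k_target_color: float = 10.5
    k_distractor_in_color_task: float = 1.8
    k_distractor_in_motion_task: float = 0.0
    boundary: float = 1.0
    noise_sd: float = 0.8
    t0_ms: float = 300.0
    mixed_block_penalty_ms: float = 100.0
    switch_penalty_ms: float = 40.0
    inertia_penalty_ms: float = 35.0
    csi_benefit_ms: float = 30.0
    lapse_rate: float = 0.01
    intrusion_rate_short_csi: float = 0.05
    intrusion_rate_long_csi: float = 0.005
    intrusion_rate_switch_extra: float = 0.05

    def __post_init__(self) -> None:
        if self.boundary <= 0:
            raise ValueError("boundary must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.t0_ms < 0:
            raise ValueError("t0_ms must be non-negative")
        for name in (
            "mixed_block_penalty_ms",
            "switch_penalty_ms",
            "inertia_penalty_ms",
            "csi_benefit_ms",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must be in [0, 0.1]")
        for name in (
            "intrusion_rate_short_csi",
            "intrusion_rate_long_csi",
            "intrusion_rate_switch_extra",
        ):
            if not 0.0 <= getattr(self, name) <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5]")

    def replace(self, **kwargs) -> "ObserverParams":
        return ObserverParams(**{**asdict(self), **kwargs})

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ObserverParams":
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown observer parameters: {sorted(unknown)}")
        return cls(**dict(d))


def default_params() -> ObserverParams:
    """Documented defaults reproducing the study's qualitative sign patterns."""
    return ObserverParams()


@dataclass
class ObserverState:
    """Sequential context carried across trials; reset at block boundaries."""

    previous_task: str | None = None
    previous_congruent: bool | None = None
    block_context: str = "single"  # "single" | "mixed"


def _signed_motion_evidence(motion_coherence: float, direction) -> float:
    if motion_coherence == 0 or direction is None:
        return 0.0
    if isinstance(direction, float) and np.isnan(direction):
        return 0.0
    return motion_coherence * (1.0 if direction == RIGHTWARD else -1.0)


def _signed_color_evidence(
    color_coherence: float, majority_color, mapping: ResponseMapping
) -> float:
    if majority_color is None:
        return 0.0
    strength = 2.0 * (color_coherence - 0.5)
    if strength <= 0:
        return 0.0
    side = mapping.color_side(majority_color)
    return strength * (1.0 if side == RIGHT else -1.0)


def drift_rate(
    trial, params: ObserverParams, mapping: ResponseMapping = ResponseMapping()
) -> float:
    """Signed drift (evidence/s) for one trial; positive favors the right key.

    ``v = k_task * s_target + k_distractor * s_distractor`` where the signed
    evidence of a dimension is its strength times the sign of the response
    side it maps to.  An absent dimension contributes zero.
    """
    s_motion = _signed_motion_evidence(trial["motion_coherence"], trial["direction"])
    s_color = _signed_color_evidence(
        trial["color_coherence"], trial["majority_color"], mapping
    )
    if trial["task"] == MOTION:
        return params.k_target_motion * s_motion + (
            params.k_distractor_in_motion_task * s_color
        )
    return params.k_target_color * s_color + (
        params.k_distractor_in_color_task * s_motion
    )


def _first_passage_batch(
    v: np.ndarray,
    max_steps: np.ndarray,
    params: ObserverParams,
    rng: np.random.Generator,
    dt_s: float = 0.001,
    chunk: int = 250,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Euler first-passage times for a batch of diffusions.

    Returns (decision step counts, crossing signs); a step count of -1 marks
    a timeout (no crossing within that trial's ``max_steps``).
    """
    n = len(v)
    cross_step = np.full(n, -1, dtype=int)
    sign = np.zeros(n, dtype=float)
    x = np.zeros(n, dtype=float)
    active = np.arange(n)
    a = params.boundary
    sqrt_dt = np.sqrt(dt_s)
    done_steps = 0
    limit = int(max_steps.max()) if n else 0
    while active.size and done_steps < limit:
        width = min(chunk, limit - done_steps)
        drift = v[active, None] * dt_s
        if params.noise_sd > 0:
            incr = drift + params.noise_sd * sqrt_dt * rng.standard_normal(
                (active.size, width)
            )
        else:
            incr = np.broadcast_to(drift, (active.size, width)).copy()
        path = x[active, None] + np.cumsum(incr, axis=1)
        hit = np.abs(path) >= a
        any_hit = hit.any(axis=1)
        first = np.where(any_hit, hit.argmax(axis=1), width - 1)
        idx_hit = active[any_hit]
        steps_at_hit = done_steps + first[any_hit] + 1
        cross_step[idx_hit] = steps_at_hit
        sign[idx_hit] = np.sign(path[any_hit, first[any_hit]])
        # survivors continue from the end of the chunk
        survivors = active[~any_hit]
        x[survivors] = path[~any_hit, -1]
        done_steps += width
        survivors = survivors[max_steps[survivors] > done_steps]
        active = survivors
    # crossings after a trial's own deadline are timeouts
    late = (cross_step > max_steps) | (cross_step < 0)
    cross_step[late] = -1
    sign[late] = 0.0
    return cross_step, sign


def _trial_penalty_ms(
    task: str,
    sequence_type: str,
    csi_ms,
    prev_congruent,
    params: ObserverParams,
) -> float:
    if sequence_type not in ("repeat", "switch"):
        return 0.0
    penalty = params.mixed_block_penalty_ms
    if sequence_type == "switch":
        penalty += params.switch_penalty_ms
        if task == MOTION and prev_congruent is False:
            penalty += params.inertia_penalty_ms
    if csi_ms == LONG_CSI_MS:
        penalty -= params.csi_benefit_ms
    return max(penalty, 0.0)


def _intrusion_rate(
    sequence_type: str, csi_ms, params: ObserverParams
) -> float:
    if sequence_type not in ("repeat", "switch"):
        return 0.0
    rate = (
        params.intrusion_rate_long_csi
        if csi_ms == LONG_CSI_MS
        else params.intrusion_rate_short_csi
    )
    if sequence_type == "switch":
        rate += params.intrusion_rate_switch_extra
    return rate


def _complete_log(
    trials: pd.DataFrame,
    params: ObserverParams,
    mapping: ResponseMapping,
    rng: np.random.Generator,
    dt_ms: float,
) -> pd.DataFrame:
    """Fill response, rt_ms and correct for every row of ``trials`` in order."""
    n = len(trials)
    v = np.array(
        [drift_rate(row, params, mapping) for _, row in trials.iterrows()]
    )
    prev_cong = trials["congruency_n_minus_1"].tolist()
    penalties = np.array(
        [
            _trial_penalty_ms(task, seq, csi, (None if pd.isna(pc) else bool(pc)), params)
            for task, seq, csi, pc in zip(
                trials["task"], trials["sequence_type"], trials["csi_ms"], prev_cong
            )
        ]
    )
    intrusion_p = np.array(
        [
            _intrusion_rate(seq, csi, params)
            for seq, csi in zip(trials["sequence_type"], trials["csi_ms"])
        ]
    )
    max_stim_ms = 2000.0
    dt_s = dt_ms / 1000.0
    max_steps = np.maximum(
        ((max_stim_ms - penalties) / dt_ms).astype(int), 1
    )
    steps, sign = _first_passage_batch(v, max_steps, params, rng, dt_s=dt_s)

    responded = steps > 0
    rt = np.where(
        responded,
        np.maximum(steps * dt_ms + penalties, 0.0) + params.t0_ms,
        np.nan,
    )
    response = np.where(sign > 0, RIGHT, LEFT).astype(object)
    response[~responded] = None

    # task-set intrusion: answer by the irrelevant dimension's rule
    u_intrude = rng.uniform(size=n)
    distractor_side = np.array(
        [
            mapping.distractor_side(task, d, mc)
            for task, d, mc in zip(
                trials["task"], trials["direction"], trials["majority_color"]
            )
        ],
        dtype=object,
    )
    intrude = (
        responded
        & (u_intrude < intrusion_p)
        & np.array([s is not None for s in distractor_side])
    )
    response[intrude] = distractor_side[intrude]

    # lapses: fair coin
    u_lapse = rng.uniform(size=n)
    lapse = responded & (u_lapse < params.lapse_rate)
    coin = rng.uniform(size=n) < 0.5
    response[lapse] = np.where(coin[lapse], LEFT, RIGHT)

    correct = np.array(
        [
            (r is not None) and (r == cr)
            for r, cr in zip(response, trials["correct_response"])
        ]
    )

    out = trials.copy()
    out["response"] = pd.array(
        [r if r is not None else pd.NA for r in response], dtype="string"
    )
    out["rt_ms"] = rt
    out["correct"] = pd.array(list(correct), dtype="boolean")
    return out


def simulate_participant(
    plan: ExperimentPlan,
    params: ObserverParams | None = None,
    seed: int = 0,
    participant_id: int = 0,
    mapping: ResponseMapping | None = None,
    dt_ms: float = 1.0,
) -> pd.DataFrame:
    """Simulate one synthetic participant over a full plan.

    Sequential context (previous task and congruency, block membership) is
    read from the plan's ``sequence_type`` and ``congruency_n_minus_1``
    columns, which the design builders maintain.  Deterministic given
    ``seed``; returns the plan's trials with response columns filled.
    """
    params = params or default_params()
    if mapping is None:
        flipped = bool(plan.metadata.get("color_mapping_flipped", False))
        mapping = ResponseMapping(color_mapping_flipped=flipped)
    rng = np.random.default_rng(seed)
    log = _complete_log(plan.trials, params, mapping, rng, dt_ms)
    log["participant_id"] = participant_id
    return log


def simulate_trial(
    trial,
    params: ObserverParams | None = None,
    state: ObserverState | None = None,
    seed: int = 0,
    mapping: ResponseMapping | None = None,
    dt_ms: float = 1.0,
) -> pd.Series:
    """Simulate a single trial given explicit sequential context.

    ``state`` supplies the previous task and previous congruency; the trial's
    own ``sequence_type``/``csi_ms`` fields position it in the design.  The
    returned Series carries ``response``, ``rt_ms`` and ``correct``.
    """
    params = params or default_params()
    state = state or ObserverState()
    mapping = mapping or ResponseMapping()
    row = pd.Series(dict(trial))
    if "congruency_n_minus_1" not in row or pd.isna(row.get("congruency_n_minus_1")):
        row["congruency_n_minus_1"] = (
            pd.NA if state.previous_congruent is None else state.previous_congruent
        )
    frame = pd.DataFrame([row])
    rng = np.random.default_rng(seed)
    return _complete_log(frame, params, mapping, rng, dt_ms).iloc[0]
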