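"""Frame-by-frame simulation of the random soldier kinematogram (RSK).

The RSK is a random-dot-kinematogram variant in which the moving elements
("agents", soldiers in the original application) carry two independently
parametrized dimensions:

* **motion coherence** — the fraction of agents translating in a common
  horizontal direction (leftward or rightward); the remaining agents move on
  fixed random linear paths.
* **color coherence** — the fraction of agents bearing the majority uniform
  color (khaki or white).

The simulation lives on a 2-D square arena measured in degrees of visual
angle.  Rendering (sprites, perspective) is presentation-layer and out of
scope; positions, headings and colors fully determine the stimulus.

Conventions
-----------
* ``x`` increases rightward, ``y`` upward, origin at the bottom-left corner.
* Rightward coherent motion is heading ``0``; leftward is heading ``pi``.
* Agents that would exit the arena re-enter on the opposite side (toroidal
  wrap), keeping density constant; identity (color, heading) is preserved.
* All randomness flows through :class:`numpy.random.Generator` seeded from
  ``StimulusSpec.seed``; a seed fully determines the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KHAKI",
    "WHITE",
    "LEFTWARD",
    "RIGHTWARD",
    "ArenaConfig",
    "StimulusSpec",
    "AgentState",
    "Agents",
    "StimulusFrames",
    "init_agents",
    "step",
    "simulate",
    "measure_motion_coherence",
    "trajectory_to_dataframe",
]

KHAKI = "khaki"
WHITE = "white"
LEFTWARD = "leftward"
RIGHTWARD = "rightward"

_COLORS = (KHAKI, WHITE)
_DIRECTIONS = (LEFTWARD, RIGHTWARD)


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (0.5 -> 1)."""
    return int(np.floor(x + 0.5))


class InsufficientDataError(ValueError):
    """Raised when a measurement needs more frames than were provided."""


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and timing of the stimulus arena.

    Defaults are the study conditions: an 18-degree square presented at 75 Hz,
    100 agents moving at 5 deg/s, with a 2000 ms maximum stimulus lifetime.
    """

    side_deg: float = 18.0
    fps: float = 75.0
    speed_deg_s: float = 5.0
    n_agents: int = 100
    duration_ms: float = 2000.0

    def __post_init__(self) -> None:
        if self.side_deg <= 0:
            raise ValueError("side_deg must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.speed_deg_s < 0:
            raise ValueError("speed_deg_s must be non-negative")
        if self.n_agents < 2:
            raise ValueError("n_agents must be at least 2")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")

    @property
    def step_deg(self) -> float:
        """Per-frame displacement of every agent along its heading."""
        return self.speed_deg_s / self.fps

    @property
    def n_frames(self) -> int:
        """Number of frames in a full-lifetime stimulus."""
        return round_half_up(self.duration_ms / 1000.0 * self.fps)


@dataclass(frozen=True)
class StimulusSpec:
    """Coherence parameters of one RSK trial.

    ``motion_coherence`` is the fraction of agents sharing the coherent
    horizontal direction (0 to 1).  ``color_coherence`` is the fraction of
    agents wearing ``majority_color`` and is only meaningful from 0.5
    (no majority) to 1 (uniform crowd).  ``seed`` fully determines the
    stimulus given an :class:`ArenaConfig`.
    """

    motion_coherence: float
    direction: str = LEFTWARD
    color_coherence: float = 0.75
    majority_color: str = KHAKI
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.motion_coherence <= 1.0:
            raise ValueError("motion_coherence must be in [0, 1]")
        if not 0.5 <= self.color_coherence <= 1.0:
            raise ValueError("color_coherence must be in [0.5, 1]")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")
        if self.majority_color not in _COLORS:
            raise ValueError(f"majority_color must be one of {_COLORS}")


@dataclass(frozen=True)
class AgentState:
    """One agent at one moment: position (deg), heading (rad), static attributes."""

    x: float
    y: float
    heading: float
    color: str
    is_coherent: bool


@dataclass
class Agents:
    """Vectorized ensemble of agent states.

    Positions are an ``(n, 2)`` array in arena coordinates; ``heading``,
    ``color`` and ``is_coherent`` are per-agent and constant over a trial.
    Supports ``len()`` and indexing, which yields :class:`AgentState`.
    """

    xy: np.ndarray
    heading: np.ndarray
    color: np.ndarray
    is_coherent: np.ndarray

    def __len__(self) -> int:
        return self.xy.shape[0]

    def __getitem__(self, i: int) -> AgentState:
        return AgentState(
            x=float(self.xy[i, 0]),
            y=float(self.xy[i, 1]),
            heading=float(self.heading[i]),
            color=str(self.color[i]),
            is_coherent=bool(self.is_coherent[i]),
        )

    def __iter__(self) -> Iterator[AgentState]:
        return (self[i] for i in range(len(self)))


def init_agents(spec: StimulusSpec, config: ArenaConfig = ArenaConfig()) -> Agents:
    """Draw the initial agent ensemble for one trial.

    Exactly ``round(motion_coherence * n_agents)`` agents are coherent, with
    heading 0 (rightward) or pi (leftward); the rest receive headings drawn
    uniformly on [0, 2*pi), fixed for the whole trial (every agent moves on a
    linear path).  Exactly ``round(color_coherence * n_agents)`` agents carry
    the majority color, assigned by an independent random permutation, so
    color and motion-group membership are statistically independent.  Initial
    positions are i.i.d. uniform over the arena.
    """
    rng = np.random.default_rng(spec.seed)
    n = config.n_agents

    n_coherent = round_half_up(spec.motion_coherence * n)
    coherent_heading = 0.0 if spec.direction == RIGHTWARD else np.pi

    heading = rng.uniform(0.0, 2.0 * np.pi, size=n)
    is_coherent = np.zeros(n, dtype=bool)
    coherent_idx = rng.permutation(n)[:n_coherent]
    is_coherent[coherent_idx] = True
    heading[is_coherent] = coherent_heading

    n_majority = round_half_up(spec.color_coherence * n)
    minority = KHAKI if spec.majority_color == WHITE else WHITE
    color = np.full(n, minority, dtype=object)
    color[rng.permutation(n)[:n_majority]] = spec.majority_color

    xy = rng.uniform(0.0, config.side_deg, size=(n, 2))
    return Agents(xy=xy, heading=heading, color=color, is_coherent=is_coherent)


def step(agents: Agents, config: ArenaConfig = ArenaConfig()) -> Agents:
    """Advance every agent one frame along its heading, wrapping toroidally."""
    d = config.step_deg
    delta = np.column_stack((np.cos(agents.heading), np.sin(agents.heading))) * d
    xy = np.mod(agents.xy + delta, config.side_deg)
    return Agents(
        xy=xy,
        heading=agents.heading,
        color=agents.color,
        is_coherent=agents.is_coherent,
    )


@dataclass
class StimulusFrames:
    """Full trajectory of one simulated stimulus.

    ``positions`` has shape ``(n_frames, n_agents, 2)``.  Static per-agent
    attributes (heading, color, coherence flag) are stored once.
    """

    spec: StimulusSpec
    config: ArenaConfig
    positions: np.ndarray
    heading: np.ndarray
    color: np.ndarray
    is_coherent: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> Agents:
        return Agents(
            xy=self.positions[i],
            heading=self.heading,
            color=self.color,
            is_coherent=self.is_coherent,
        )


def simulate(spec: StimulusSpec, config: ArenaConfig = ArenaConfig()) -> StimulusFrames:
    """Simulate a full-lifetime stimulus; bit-reproducible given ``spec.seed``."""
    agents = init_agents(spec, config)
    n_frames = config.n_frames
    positions = np.empty((n_frames, config.n_agents, 2), dtype=float)
    positions[0] = agents.xy
    for i in range(1, n_frames):
        agents = step(agents, config)
        positions[i] = agents.xy
    return StimulusFrames(
        spec=spec,
        config=config,
        positions=positions,
        heading=agents.heading,
        color=agents.color,
        is_coherent=agents.is_coherent,
    )


def _wrapped_displacement(positions: np.ndarray, side: float) -> np.ndarray:
    """Frame-to-frame displacements corrected for toroidal wrap.

    Assumes per-frame steps are smaller than half the arena side, which holds
    for any plausible speed/fps combination.
    """
    raw = np.diff(positions, axis=0)
    return (raw + side / 2.0) % side - side / 2.0


def measure_motion_coherence(frames: StimulusFrames, atol: float = 1e-9) -> float:
    """Estimate motion coherence from a simulated trajectory (self-check oracle).

    Counts the fraction of agents whose wrap-corrected displacement is exactly
    horizontal (|dy| < atol, |dx| > atol) in the modal horizontal direction.
    Under continuous uniform noise headings, a noise agent is exactly
    horizontal with probability zero, so the estimate equals the generating
    coherence.

    Raises
    ------
    InsufficientDataError
        If fewer than two frames are available.
    """
    if frames.n_frames < 2:
        raise InsufficientDataError("need at least two frames to measure motion")
    disp = _wrapped_displacement(frames.positions, frames.config.side_deg)
    # headings are constant, so the first frame pair characterizes every agent
    dx, dy = disp[0, :, 0], disp[0, :, 1]
    horizontal = (np.abs(dy) < atol) & (np.abs(dx) > atol)
    if not horizontal.any():
        return 0.0
    modal_sign = np.sign(np.sum(dx[horizontal]))
    coherent = horizontal & (np.sign(dx) == modal_sign)
    return float(coherent.sum() / frames.n_agents)


def measure_speed(frames: StimulusFrames) -> float:
    """Mean translational speed (deg/s) of coherent agents, from trajectories.

    Computes the mean wrap-corrected per-frame displacement magnitude of the
    coherently moving agents across all frame pairs and scales by the frame
    rate.  Falls back to all agents when the stimulus has no coherent agents
    (every agent moves at the same nominal speed).
    """
    if frames.n_frames < 2:
        raise InsufficientDataError("need at least two frames to measure speed")
    disp = _wrapped_displacement(frames.positions, frames.config.side_deg)
    mask = frames.is_coherent if frames.is_coherent.any() else np.ones(
        frames.n_agents, dtype=bool
    )
    per_frame = np.linalg.norm(disp[:, mask, :], axis=2)
    return float(per_frame.mean() * frames.config.fps)


def trajectory_to_dataframe(frames: StimulusFrames) -> pd.DataFrame:
    """Tidy trajectory export: one row per (frame, agent)."""
    n_f, n_a = frames.n_frames, frames.n_agents
    frame_idx = np.repeat(np.arange(n_f), n_a)
    agent_idx = np.tile(np.arange(n_a), n_f)
    return pd.DataFrame(
        {
            "frame": frame_idx,
            "agent_id": agent_idx,
            "x_deg": frames.positions[:, :, 0].ravel(),
            "y_deg": frames.positions[:, :, 1].ravel(),
            "heading_rad": np.tile(frames.heading, n_f),
            "color": np.tile(frames.color, n_f),
            "is_coherent": np.tile(frames.is_coherent, n_f),
        }
    )
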