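"""Grid-tracking experiment protocol: blocks, episodes, trajectories, errors.

The experiment is a continuous cursor-tracking task on an 11x6 grid.  A
session has 15 blocks of 8 episodes; each episode displays a randomly
generated goal trajectory of 10-15 grid steps ("movement events").  Blocks
1-3 are unassisted, 4-9 use gravity-compensation assistance and 10-15 the
EMG-driven myoprocessor; within each assisted phase the five variable blocks
carry error rates that are a random permutation of {0, 0, 30, 30, 30}%.  In
error blocks, 30% of movement events are overridden with a purposeful
control error (unnecessary inflation or release of assistance), onset-locked
to the moment the cursor moves fully into the next grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

SCHEMES = ("unassisted", "gravity", "myoprocessor")
ERROR_TYPES = ("inflate", "release", "none")

#: grid dimensions of the tracking task
N_COLS = 11
N_ROWS = 6

# 4-neighbour steps on the grid
_STEPS = ((1, 0), (-1, 0), (0, 1), (0, -1))


@dataclass(frozen=True)
class GridTask:
    """A goal trajectory on the tracking grid.

    ``trajectory`` is an ordered list of (col, row) cells; consecutive cells
    are 4-neighbour adjacent and the path is self-avoiding.
    """

    trajectory: tuple[tuple[int, int], ...]
    n_cols: int = N_COLS
    n_rows: int = N_ROWS

    def __post_init__(self) -> None:
        for c, r in self.trajectory:
            if not (0 <= c < self.n_cols and 0 <= r < self.n_rows):
                raise ValueError(f"cell ({c},{r}) outside {self.n_cols}x{self.n_rows} grid")
        for (c0, r0), (c1, r1) in zip(self.trajectory, self.trajectory[1:]):
            if abs(c0 - c1) + abs(r0 - r1) != 1:
                raise ValueError("consecutive trajectory cells must be 4-neighbour adjacent")
        if len(set(self.trajectory)) != len(self.trajectory):
            raise ValueError("trajectory must be self-avoiding")

    def __len__(self) -> int:
        return len(self.trajectory)


@dataclass(frozen=True)
class ExperimentEvent:
    """One movement event (= one trial), onset-locked to cell entry."""

    block_id: int
    episode_id: int
    event_id: int
    onset_time: float
    scheme: str
    is_error: bool = False
    error_type: str = "none"
    is_correct_step: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.error_type not in ERROR_TYPES:
            raise ValueError(f"unknown error type {self.error_type!r}")
        if self.is_error and (self.scheme == "unassisted" or self.error_type == "none"):
            raise ValueError("error events require an assisted scheme and a concrete error type")


@dataclass(frozen=True)
class BlockSpec:
    scheme: str
    error_rate: float

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")


@dataclass(frozen=True)
class SessionProtocol:
    """Block structure of one session (15 blocks, 8 episodes per block)."""

    blocks: tuple[BlockSpec, ...]
    episodes_per_block: int = 8
    events_per_episode: tuple[int, int] = (10, 15)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.events_per_episode
        if not (1 <= lo <= hi):
            raise ValueError("events_per_episode must be an increasing positive range")
        if self.episodes_per_block < 1:
            raise ValueError("episodes_per_block must be >= 1")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class ProtocolTiming:
    """Stochastic timing model for event onsets.

    Movement events are movement-locked, not clock-locked: the onset spacing
    is the duration of the cursor step that precedes it.  Durations are drawn
    uniformly from ``movement_duration_range`` seconds unless a callable
    ``movement_duration`` (rng -> seconds) overrides it, e.g. with durations
    obtained from the closed-loop control simulator.
    """

    movement_duration_range: tuple[float, float] = (1.2, 1.8)
    episode_gap: float = 2.0
    block_gap: float = 3.0
    movement_duration: Callable[[np.random.Generator], float] | None = None

    def draw_duration(self, rng: np.random.Generator) -> float:
        if self.movement_duration is not None:
            return float(self.movement_duration(rng))
        lo, hi = self.movement_duration_range
        return float(rng.uniform(lo, hi))


def generate_trajectory(
    rng: np.random.Generator,
    length_range: Sequence[int] = (10, 15),
    n_cols: int = N_COLS,
    n_rows: int = N_ROWS,
    max_tries: int = 1000,
) -> GridTask:
    """Draw a random self-avoiding 4-neighbour path on the grid.

    The cell count is drawn uniformly from ``length_range`` (inclusive).
    Raises ``RuntimeError`` if no valid path is found within ``max_tries``
    restart attempts (cannot happen for the default 10-15 on 11x6, but
    guards degenerate grids).
    """
    lo, hi = int(length_range[0]), int(length_range[-1])
    if lo < 1 or hi < lo:
        raise ValueError("length_range must be a positive increasing range")
    target = int(rng.integers(lo, hi + 1))
    for _ in range(max_tries):
        path = [(int(rng.integers(n_cols)), int(rng.integers(n_rows)))]
        seen = {path[0]}
        while len(path) < target:
            c, r = path[-1]
            options = [
                (c + dc, r + dr)
                for dc, dr in _STEPS
                if 0 <= c + dc < n_cols and 0 <= r + dr < n_rows and (c + dc, r + dr) not in seen
            ]
            if not options:
                break  # dead end; restart the walk
            nxt = options[int(rng.integers(len(options)))]
            path.append(nxt)
            seen.add(nxt)
        if len(path) == target:
            return GridTask(trajectory=tuple(path), n_cols=n_cols, n_rows=n_rows)
    raise RuntimeError(f"no self-avoiding path of length {target} found in {max_tries} tries")


def build_protocol(seed: int = 0) -> SessionProtocol:
    """Build the 15-block session protocol.

    Blocks 1-3 unassisted (0%), 4 gravity 0%, 5-9 gravity with a seeded
    permutation of {0, 0, 30, 30, 30}%, 10 myoprocessor 0%, 11-15
    myoprocessor with an independent permutation of the same multiset.
    """
    rng = np.random.default_rng(seed)
    rates = np.array([0.0, 0.0, 0.3, 0.3, 0.3])
    blocks: list[BlockSpec] = [BlockSpec("unassisted", 0.0) for _ in range(3)]
    blocks.append(BlockSpec("gravity", 0.0))
    blocks += [BlockSpec("gravity", float(r)) for r in rng.permutation(rates)]
    blocks.append(BlockSpec("myoprocessor", 0.0))
    blocks += [BlockSpec("myoprocessor", float(r)) for r in rng.permutation(rates)]
    return SessionProtocol(blocks=tuple(blocks), rng_seed=int(seed))


def inject_errors(
    events: Sequence[ExperimentEvent],
    rate: float,
    rng: np.random.Generator,
    exclude_episode_edges: bool = False,
) -> list[ExperimentEvent]:
    """Mark ``round(rate * N)`` events of one block as control errors.

    Error positions are uniform over the block's events; the error type is
    drawn uniformly from {inflate, release}.  Events must all belong to one
    block of an assisted scheme when ``rate > 0``.
    ``exclude_episode_edges`` removes each episode's first and last event
    from the eligible positions (off by default).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    events = list(events)
    n_err = int(round(rate * len(events)))
    if n_err == 0:
        return events
    if len({e.block_id for e in events}) != 1:
        raise ValueError("inject_errors expects events from exactly one block")
    eligible = np.arange(len(events))
    if exclude_episode_edges:
        per_episode: dict[int, list[int]] = {}
        for i, e in enumerate(events):
            per_episode.setdefault(e.episode_id, []).append(i)
        interior = [i for idxs in per_episode.values() for i in idxs[1:-1]]
        eligible = np.asarray(sorted(interior))
        if len(eligible) < n_err:
            raise ValueError("not enough interior events for the requested rate")
    picks = rng.choice(eligible, size=n_err, replace=False)
    out = events.copy()
    for i in picks:
        etype = ERROR_TYPES[int(rng.integers(2))]
        out[i] = replace(out[i], is_error=True, error_type=etype, is_correct_step=False)
    return out


def generate_session_events(
    protocol: SessionProtocol,
    rng: np.random.Generator | None = None,
    timing: ProtocolTiming | None = None,
    p_correct: float = 0.985,
) -> list[ExperimentEvent]:
    """Roll out the full session: trajectories, onsets, correctness, errors.

    Non-error steps are scored correct with probability ``p_correct``
    (tracking slips); error steps are never correct.  Onsets within an
    episode increase strictly by the drawn movement duration.
    """
    rng = np.random.default_rng(protocol.rng_seed) if rng is None else rng
    timing = timing or ProtocolTiming()
    all_events: list[ExperimentEvent] = []
    t = 0.0
    for b, block in enumerate(protocol.blocks):
        block_events: list[ExperimentEvent] = []
        for ep in range(protocol.episodes_per_block):
            task = generate_trajectory(rng, protocol.events_per_episode)
            for ev in range(len(task)):
                t += timing.draw_duration(rng)
                block_events.append(
                    ExperimentEvent(
                        block_id=b,
                        episode_id=ep,
                        event_id=ev,
                        onset_time=t,
                        scheme=block.scheme,
                        is_correct_step=bool(rng.random() < p_correct),
                    )
                )
            t += timing.episode_gap
        all_events.extend(inject_errors(block_events, block.error_rate, rng))
        t += timing.block_gap
    return all_events


def trajectory_accuracy(
    events: Sequence[ExperimentEvent],
    protocol: SessionProtocol | None = None,
) -> float:
    """Percentage of correct steps out of all steps.

    When ``protocol`` is given, events are first restricted to non-error
    blocks (assigned error rate 0), the condition under which tracking
    accuracy is scored.
    """
    events = list(events)
    if protocol is not None:
        keep = {i for i, blk in enumerate(protocol.blocks) if blk.error_rate == 0.0}
        events = [e for e in events if e.block_id in keep]
    if not events:
        raise ValueError("no events to score")
    return 100.0 * sum(e.is_correct_step for e in events) / len(events)
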