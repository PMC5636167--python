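"""Heuristic reference agents for the single-food foraging task.

Four hand-coded policies bracket the learned network's performance, from a
correlated random walk up to an exhaustive 5-move lookahead:

* ``random_walk`` - keep heading with 98% probability, else turn 45 degrees
  left or right (1% each).
* ``adjacent_grab`` - step onto any directly adjacent food, otherwise walk
  randomly.
* ``nearest_food`` - head toward the closest visible food particle
  (Chebyshev distance, consistent with 8-directional moves).
* ``exhaustive5`` - enumerate all 8^5 five-move sequences within the visual
  field (positions clamped to the field, food not double-counted within a
  rollout), maximize food obtained, prefer earlier acquisition among ties,
  then choose uniformly; fall back to the random walk when no food is
  visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import exhaustive5_scores
from .environment import DIRECTIONS, Move, apply_move, init_world, visual_field

__all__ = [
    "random_walk_step", "adjacent_grab_step", "nearest_food_step",
    "exhaustive5_step", "run_baseline", "BaselineResult", "HEURISTICS",
]

# compass (angular) ordering used for 45-degree turns
_COMPASS = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_COMPASS_INDEX = {d: i for i, d in enumerate(_COMPASS)}


def random_walk_step(prev_direction, rng: np.random.Generator) -> Move:
    """98% keep going straight, 1% turn 45 deg left, 1% turn 45 deg right."""
    if prev_direction is None:
        return Move(DIRECTIONS[int(rng.integers(8))])
    u = rng.random()
    if u < 0.98:
        return Move(prev_direction)
    turn = -1 if u < 0.99 else 1
    i = _COMPASS_INDEX[prev_direction]
    return Move(_COMPASS[(i + turn) % 8])


def _food_offsets(field: np.ndarray):
    """(dr, dc) offsets of visible food relative to the agent."""
    side = field.shape[0]
    half = side // 2
    rr, cc = np.nonzero(field)
    return rr - half, cc - half


def adjacent_grab_step(field: np.ndarray, prev_direction, rng) -> Move:
    """Move onto any directly adjacent food; otherwise walk randomly."""
    dr, dc = _food_offsets(field)
    adj = np.maximum(np.abs(dr), np.abs(dc)) == 1
    if adj.any():
        k = int(rng.integers(int(adj.sum())))
        i = np.flatnonzero(adj)[k]
        return Move((int(dr[i]), int(dc[i])))
    return random_walk_step(prev_direction, rng)


def nearest_food_step(field: np.ndarray, prev_direction, rng) -> Move:
    """Head toward the closest visible food (Chebyshev metric)."""
    dr, dc = _food_offsets(field)
    if len(dr) == 0:
        return random_walk_step(prev_direction, rng)
    dist = np.maximum(np.abs(dr), np.abs(dc))
    nearest = np.flatnonzero(dist == dist.min())
    i = int(nearest[int(rng.integers(len(nearest)))])
    return Move((int(np.sign(dr[i])), int(np.sign(dc[i]))))


def exhaustive5_step(field: np.ndarray, prev_direction, rng) -> Move:
    """First move of the best 5-move rollout; random walk if no food visible.

    Ties between equally good rollouts are resolved by picking one optimal
    *sequence* uniformly at random, so a first move backed by more optimal
    completions is proportionally more likely.
    """
    if not field.any():
        return random_walk_step(prev_direction, rng)
    scores, counts = exhaustive5_scores(np.ascontiguousarray(field, dtype=np.bool_))
    best = scores.max()
    if best <= 0:  # no rollout reaches food (cannot happen in a 7x7 field)
        return random_walk_step(prev_direction, rng)
    weights = np.where(scores == best, counts, 0).astype(float)
    d = int(rng.choice(8, p=weights / weights.sum()))
    return Move(DIRECTIONS[d])


HEURISTICS = {
    "random_walk": lambda field, prev, rng: random_walk_step(prev, rng),
    "adjacent_grab": adjacent_grab_step,
    "nearest_food": nearest_food_step,
    "exhaustive5": exhaustive5_step,
}


@dataclass
class BaselineResult:
    kind: str
    n_moves: int
    n_food: int

    @property
    def acquisition_rate(self) -> float:
        return self.n_food / self.n_moves


def run_baseline(
    kind: str,
    n_moves: int = 50_000,
    rng_seed: int = 0,
    density: float = 0.10,
    world_size: int = 50,
) -> BaselineResult:
    """Run a heuristic agent on the single-food environment.

    Returns the food-per-move acquisition rate over ``n_moves`` moves.
    """
    if kind not in HEURISTICS:
        raise ValueError(f"unknown heuristic {kind!r}; choose from {sorted(HEURISTICS)}")
    step_fn = HEURISTICS[kind]
    master = np.random.default_rng(rng_seed)
    world = init_world(task="single", density=density, size=world_size,
                       rng=int(master.integers(2**31)))
    rng = np.random.default_rng(int(master.integers(2**31)))
    prev = None
    n_food = 0
    for _ in range(n_moves):
        field = visual_field(world).reshape(7, 7)
        move = step_fn(field, prev, rng)
        prev = move.direction
        if apply_move(world, move) == "food":
            n_food += 1
    return BaselineResult(kind, n_moves, n_food)
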