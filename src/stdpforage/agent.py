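"""The foraging agent: decision rule, reward schedule and training driver.

Each epoch the agent (i) presents its 7x7 visual field to the network,
(ii) moves in the direction coded by the output cell with the most spikes in
the first half of the epoch (ties broken uniformly; silence repeats the
previous direction), (iii) consumes any food at the destination and
(iv) broadcasts the resulting reward/punishment, which converts stored STDP
tags into weight changes.  A small probability of ignoring the network and
moving randomly - escalating while no food is found - breaks movement loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import DIRECTIONS, Move, World, apply_move, init_world, visual_field
from .network import (EpochRecord, Network, NetworkConfig, build_network,
                      calibrate_excitability)
from .plasticity import RewardSignal

__all__ = [
    "DecisionPolicy", "Metrics", "TrainResult", "decide", "reward_for",
    "train", "measure_ties_and_zeros", "output_cell_of_direction",
]

#: output-layer cell index (3x3 row-major) for each of the 8 directions;
#: the centre cell (index 4) is never mapped to a move.
_CELL_OF_DIR = tuple(d if d < 4 else d + 1 for d in range(8))


def output_cell_of_direction(d: int) -> int:
    return _CELL_OF_DIR[d]


@dataclass
class DecisionPolicy:
    """Random-move override schedule.

    The override probability has a constant floor (1%) and an escalating
    component that grows with every foodless move and resets when food is
    obtained: the simple task starts at 0.5% and adds 0.5% per foodless move,
    the pattern task starts at 0 and adds 1% per foodless move.
    """

    start: float = 0.005
    increment: float = 0.005
    floor: float = 0.01
    foodless_moves: int = 0

    @classmethod
    def for_task(cls, task: str) -> "DecisionPolicy":
        if task == "pairs":
            return cls(start=0.0, increment=0.01)
        return cls()

    @property
    def probability(self) -> float:
        p = max(self.floor, self.start + self.increment * self.foodless_moves)
        return min(p, 1.0)

    def update(self, food_obtained: bool) -> None:
        self.foodless_moves = 0 if food_obtained else self.foodless_moves + 1


def decide(
    record: EpochRecord,
    policy: DecisionPolicy,
    prev_direction: tuple,
    rng: np.random.Generator,
) -> tuple:
    """Choose the next move from first-half output spike counts.

    Returns ``(move, was_random, was_tie, was_zero)``.  With probability
    ``policy.probability`` the network output is ignored and a uniform random
    direction taken; otherwise the argmax over the 8 direction cells decides,
    ties are broken uniformly, and total silence repeats ``prev_direction``.
    """
    counts = record.counts_output_half
    dir_counts = np.array([counts[_CELL_OF_DIR[d]] for d in range(8)])
    best = dir_counts.max()
    was_zero = best == 0
    was_tie = (not was_zero) and int((dir_counts == best).sum()) > 1
    if rng.random() < policy.probability:
        return Move(DIRECTIONS[int(rng.integers(8))]), True, was_tie, was_zero
    if was_zero:
        return Move(prev_direction), False, False, True
    candidates = np.flatnonzero(dir_counts == best)
    d = int(candidates[int(rng.integers(len(candidates)))])
    return Move(DIRECTIONS[d]), False, was_tie, was_zero


def _field_sampler(task, density, pair_density, world_size, side):
    """Visual-field sampler with the task's food statistics (for calibration)."""
    def sample(rng):
        world = init_world(task=task, density=density, pair_density=pair_density,
                           size=world_size, rng=rng)
        return visual_field(world, side=side)
    return sample


_REWARDS = {
    ("single", "food"): 1.0,
    ("single", "none"): -0.1,
    ("pairs", "good_food"): 1.0,
    ("pairs", "bad_food"): -0.5,
    ("pairs", "none"): -0.01,
}


def reward_for(outcome: str, task: str) -> RewardSignal:
    """Reward/punishment scaling for a move outcome under the given task."""
    try:
        return RewardSignal(_REWARDS[(task, outcome)])
    except KeyError:
        raise ValueError(f"no reward defined for outcome {outcome!r} in task {task!r}")


@dataclass
class Metrics:
    """Per-epoch time series recorded during training."""

    ema: np.ndarray
    outcome: np.ndarray           # 0 none, 1 food/good, -1 bad
    hidden_spikes: np.ndarray
    output_spikes: np.ndarray
    was_random: np.ndarray
    was_tie: np.ndarray
    was_zero: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ema": self.ema, "outcome": self.outcome,
            "hidden_spikes": self.hidden_spikes,
            "output_spikes": self.output_spikes,
            "was_random": self.was_random, "was_tie": self.was_tie,
            "was_zero": self.was_zero,
        })

    def discrimination_accuracy(self, window: int = 2000) -> float:
        """good / (good + bad) food over the trailing ``window`` moves."""
        tail = self.outcome[-window:]
        good = int((tail == 1).sum())
        bad = int((tail == -1).sum())
        return good / (good + bad) if good + bad else float("nan")


@dataclass
class TrainResult:
    metrics: Metrics
    network: Network
    world: World
    config: NetworkConfig
    task: str

    @property
    def final_ema(self) -> float:
        return float(self.metrics.ema[-1])


def measure_ties_and_zeros(records) -> dict:
    """Count tied-argmax epochs and silent-output epochs.

    A tie is an epoch whose first-half direction-cell maximum is nonzero and
    shared by at least two cells; a zero is an epoch with no output spikes at
    all.
    """
    ties = zeros = 0
    for rec in records:
        counts = np.asarray(rec.counts_output_half)
        dir_counts = np.array([counts[_CELL_OF_DIR[d]] for d in range(8)])
        best = dir_counts.max()
        if np.asarray(rec.counts_output).sum() == 0:
            zeros += 1
        elif best > 0 and int((dir_counts == best).sum()) > 1:
            ties += 1
    return {"ties": ties, "zeros": zeros}


def train(
    config: NetworkConfig | None = None,
    task: str = "single",
    n_epochs: int = 20_000,
    rng_seed: int = 0,
    ema_alpha: float = 0.002,
    density: float = 0.10,
    pair_density: float = 0.025,
    world_size: int = 50,
    network: Network | None = None,
    callback=None,
) -> TrainResult:
    """Run the full perception -> decision -> action -> reward loop.

    The EMA food-acquisition rate uses smoothing constant ``ema_alpha`` per
    move (default 0.002, roughly a 500-move memory).  For the pattern task,
    input->hidden inhibition defaults to off (it reduces the reliability of
    pair detection in the hidden layer) unless a config is supplied.
    ``callback(epoch, result_so_far)`` allows checkpoints/sweeps.
    """
    if config is None:
        if task == "pairs":
            config = NetworkConfig(use_inh_in=False, wmax_frac_in=0.6)
        else:
            config = NetworkConfig()
    master = np.random.default_rng(rng_seed)
    net = network if network is not None else build_network(config, int(master.integers(2**31)))
    world = init_world(task=task, density=density, pair_density=pair_density,
                       size=world_size, rng=int(master.integers(2**31)))
    if network is None and config.auto_calibrate:
        calibrate_excitability(
            net, _field_sampler(task, density, pair_density, world_size,
                                config.input_side),
            rng_seed=int(master.integers(2**31)))
    rng = np.random.default_rng(int(master.integers(2**31)))
    policy = DecisionPolicy.for_task(task)

    ema = np.zeros(n_epochs)
    outcome_code = np.zeros(n_epochs, dtype=np.int8)
    hidden_spikes = np.zeros(n_epochs, dtype=np.int64)
    output_spikes = np.zeros(n_epochs, dtype=np.int64)
    was_random = np.zeros(n_epochs, dtype=np.bool_)
    was_tie = np.zeros(n_epochs, dtype=np.bool_)
    was_zero = np.zeros(n_epochs, dtype=np.bool_)

    prev_dir = DIRECTIONS[int(rng.integers(8))]
    ema_val = 0.0
    result = TrainResult(
        Metrics(ema, outcome_code, hidden_spikes, output_spikes,
                was_random, was_tie, was_zero),
        net, world, config, task)

    for e in range(n_epochs):
        stim = visual_field(world, side=config.input_side)
        rec = net.run_epoch(stim)
        move, rnd, tie, zero = decide(rec, policy, prev_dir, rng)
        prev_dir = move.direction
        outcome = apply_move(world, move)
        got_food = outcome in ("food", "good_food", "bad_food")
        net.apply_reward_epoch(reward_for(outcome, task))
        net.epoch_housekeeping(rec)
        policy.update(got_food)

        ema_val = (1 - ema_alpha) * ema_val + ema_alpha * float(got_food)
        ema[e] = ema_val
        outcome_code[e] = -1 if outcome == "bad_food" else (1 if got_food else 0)
        hidden_spikes[e] = rec.counts_hidden.sum()
        output_spikes[e] = rec.counts_output.sum()
        was_random[e] = rnd
        was_tie[e] = tie
        was_zero[e] = zero
        if callback is not None:
            callback(e, result)
    return result
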