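"""Virtual foraging environment.

A toroidal grid (default 50x50) of food particles.  In the *single* task, 10%
of cells carry one food particle each; a consumed particle respawns at a
random empty cell so density is stationary.  In the *pairs* task, food comes
in two-cell patterns - horizontal pairs (rewarded) and vertical pairs
(punished) in equal numbers, with rewarded-particle density 2.5% of cells -
and no pattern is ever placed adjacent (8-neighbourhood) to another, so a
pair of co-active inputs is always unambiguous.  Stepping on either cell of a
pair consumes the whole pair, which respawns elsewhere with the same
orientation.

Grid boundaries wrap around (movement and the visual field are toroidal),
which keeps the food-density statistics stationary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "World", "Move", "DIRECTIONS", "init_world", "visual_field",
    "apply_move", "world_to_text", "world_from_text",
]

EMPTY, FOOD, HPAIR, VPAIR = 0, 1, 2, 3
_CHARS = {EMPTY: ".", FOOD: "o", HPAIR: "H", VPAIR: "V"}
_CODES = {v: k for k, v in _CHARS.items()}

#: The 8 compass moves in row-major order (dr, dc), diagonals included.
DIRECTIONS: tuple = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass(frozen=True)
class Move:
    """A one-cell displacement in one of the 8 compass directions."""

    direction: tuple

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"not a compass direction: {self.direction}")


@dataclass
class World:
    grid: np.ndarray  # int8 codes: 0 empty, 1 food, 2 horizontal, 3 vertical
    agent_pos: tuple
    agent_heading: tuple = (0, 1)
    task: str = "single"
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def shape(self):
        return self.grid.shape

    def occupied(self) -> int:
        return int((self.grid != EMPTY).sum())


def _neighbourhood_free(grid, cells) -> bool:
    """True if the 8-neighbourhood of `cells` holds no pattern outside `cells`."""
    n_r, n_c = grid.shape
    own = set(cells)
    for (r, c) in cells:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = (r + dr) % n_r, (c + dc) % n_c
                if (rr, cc) not in own and grid[rr, cc] != EMPTY:
                    return False
    return True


def _place_pair(grid, code, rng, max_tries=20_000, forbid=None):
    n_r, n_c = grid.shape
    for _ in range(max_tries):
        r = int(rng.integers(n_r))
        c = int(rng.integers(n_c))
        if code == HPAIR:
            cells = [(r, c), (r, (c + 1) % n_c)]
        else:
            cells = [(r, c), ((r + 1) % n_r, c)]
        if forbid is not None and any(cell == forbid for cell in cells):
            continue
        if all(grid[x] == EMPTY for x in cells) and _neighbourhood_free(grid, cells):
            for x in cells:
                grid[x] = code
            return
    raise RuntimeError("could not place food pattern after bounded retries")


def init_world(
    task: str = "single",
    density: float = 0.10,
    size: int = 50,
    rng: np.random.Generator | int | None = None,
    pair_density: float = 0.025,
) -> World:
    """Build a fresh world.

    single: round(density * size^2) food cells placed uniformly at random,
    never on the agent's start cell.  pairs: equal numbers of horizontal and
    vertical two-cell patterns until the rewarded-particle count reaches
    ``pair_density * size^2``, obeying the non-adjacency constraint.
    """
    if task not in ("single", "pairs"):
        raise ValueError("task must be 'single' or 'pairs'")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    grid = np.zeros((size, size), dtype=np.int8)
    agent = (int(rng.integers(size)), int(rng.integers(size)))
    if task == "single":
        n_food = round(density * size * size)
        flat = np.arange(size * size)
        flat = flat[flat != agent[0] * size + agent[1]]
        chosen = rng.choice(flat, size=n_food, replace=False)
        grid.flat[chosen] = FOOD
    else:
        n_pairs = max(1, round(pair_density * size * size / 2))
        for _ in range(n_pairs):
            _place_pair(grid, HPAIR, rng, forbid=agent)
        for _ in range(n_pairs):
            _place_pair(grid, VPAIR, rng, forbid=agent)
    return World(grid=grid, agent_pos=agent, task=task, rng=rng)


def visual_field(world: World, side: int = 7) -> np.ndarray:
    """Food presence in the ``side x side`` window centred on the agent.

    Flattened row-major boolean vector of length side**2; the centre entry
    (the agent's own cell) is always False.  The window wraps toroidally.
    """
    r, c = world.agent_pos
    n_r, n_c = world.shape
    half = side // 2
    rows = (np.arange(r - half, r + half + 1)) % n_r
    cols = (np.arange(c - half, c + half + 1)) % n_c
    window = world.grid[np.ix_(rows, cols)] != EMPTY
    window[half, half] = False
    return window.reshape(-1)


def _pair_partner(world: World, pos):
    """The other cell of the pattern at `pos`."""
    r, c = pos
    n_r, n_c = world.shape
    code = world.grid[pos]
    if code == HPAIR:
        for cc in ((c - 1) % n_c, (c + 1) % n_c):
            if world.grid[r, cc] == HPAIR:
                return (r, cc)
    else:
        for rr in ((r - 1) % n_r, (r + 1) % n_r):
            if world.grid[rr, c] == VPAIR:
                return (rr, c)
    raise ValueError("pattern cell without partner")


def _respawn_food(world: World) -> None:
    empties = np.flatnonzero(world.grid.reshape(-1) == EMPTY)
    r, c = world.agent_pos
    empties = empties[empties != r * world.shape[1] + c]
    world.grid.flat[int(world.rng.choice(empties))] = FOOD


def apply_move(world: World, move: Move) -> str:
    """Displace the agent and consume any food at the destination.

    Returns the outcome: ``none``, ``food`` (single task), ``good_food``
    (horizontal pair) or ``bad_food`` (vertical pair).  Consumed food
    respawns immediately at a random location (pairs keep their
    orientation), so occupancy is conserved.
    """
    dr, dc = move.direction
    n_r, n_c = world.shape
    r = (world.agent_pos[0] + dr) % n_r
    c = (world.agent_pos[1] + dc) % n_c
    world.agent_pos = (r, c)
    world.agent_heading = move.direction
    code = int(world.grid[r, c])
    if code == EMPTY:
        return "none"
    if code == FOOD:
        world.grid[r, c] = EMPTY
        _respawn_food(world)
        return "food"
    partner = _pair_partner(world, (r, c))
    world.grid[r, c] = EMPTY
    world.grid[partner] = EMPTY
    _place_pair(world.grid, code, world.rng, forbid=world.agent_pos)
    return "good_food" if code == HPAIR else "bad_food"


# ---------------------------------------------------------------------------
# plain-text serialization ('.' empty, 'o' food, 'H'/'V' pattern, '@' agent)
# ---------------------------------------------------------------------------


def world_to_text(world: World) -> str:
    lines = []
    for r in range(world.shape[0]):
        row = "".join(_CHARS[int(v)] for v in world.grid[r])
        lines.append(row)
    r, c = world.agent_pos
    lines[r] = lines[r][:c] + "@" + lines[r][c + 1:]
    return "\n".join(lines) + "\n"


def world_from_text(text: str, task: str | None = None,
                    rng: np.random.Generator | int | None = None) -> World:
    """Parse the documented grid format; '@' (optional) marks the agent.

    Pattern layouts are validated: every H/V cell must belong to exactly one
    two-cell pattern and no pattern may touch another (8-neighbourhood).
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return World(grid=np.zeros((0, 0), dtype=np.int8), agent_pos=(0, 0),
                     task=task or "single",
                     rng=np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng)
    width = len(lines[0])
    if any(len(ln) != width for ln in lines):
        raise ValueError("ragged grid layout")
    grid = np.zeros((len(lines), width), dtype=np.int8)
    agent = None
    for r, ln in enumerate(lines):
        for c, ch in enumerate(ln):
            if ch == "@":
                agent = (r, c)
            elif ch in _CODES:
                grid[r, c] = _CODES[ch]
            else:
                raise ValueError(f"malformed layout character {ch!r}")
    if agent is None:
        agent = (len(lines) // 2, width // 2)
    world = World(grid=grid, agent_pos=agent,
                  task=task or ("pairs" if (grid >= HPAIR).any() else "single"),
                  rng=np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng)
    _validate_patterns(world)
    return world


def _validate_patterns(world: World) -> None:
    grid = world.grid
    n_r, n_c = grid.shape
    for r in range(n_r):
        for c in range(n_c):
            code = int(grid[r, c])
            if code in (HPAIR, VPAIR):
                partner = _pair_partner(world, (r, c))
                if not _neighbourhood_free(grid, [(r, c), partner]):
                    raise ValueError("adjacent food patterns in layout")
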