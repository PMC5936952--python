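"""Cellular-automaton model of atrial tissue with re-entrant drivers.

The tissue is an L x L square lattice of cells.  Every cell is coupled to
its longitudinal (same-row) neighbours, forming muscle fibres that run
along the x (column) direction with open ends.  Transverse couplings
between vertically adjacent fibres exist independently with probability
``nu``; rows are periodic, giving a cylindrical geometry.  Each cell
follows the excitable-medium cycle resting -> excited (1 step) ->
refractory (tau steps) -> resting, and a pacemaker excites the column-0
cells every ``T_pace`` steps.

Re-entrant circuits (the drivers of fibrillation) are inserted
artificially: the transverse couplings above and below a run of
``segment_length`` cells are removed, leaving a closed rectangular
conduction loop between two fibres whose perimeter exceeds the
refractory period, so a wave seeded on the loop circulates indefinitely
and radiates fibrillatory activity into the bulk.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

RESTING = 0
EXCITED = 1
# Refractory cells carry clock values 2..tau+1; an excited cell becomes
# refractory with clock tau+1 which counts down to 2 and then to resting.

DEFAULT_SEGMENT_LENGTH = 28


class ConfigurationError(ValueError):
    """Invalid model configuration."""


class PlacementError(ValueError):
    """A circuit, probe or electrode does not fit in the lattice."""


class InitializationError(RuntimeError):
    """Fibrillation failed to establish itself (e.g. unsustainable circuit)."""


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of the lattice model.

    dt_ms is metadata linking one automaton step to physical time: with
    the defaults the refractory period is tau*dt_ms = 150 ms and the
    sinus pacing interval is T_pace*dt_ms = 660 ms.
    """

    L: int = 200
    nu: float = 0.2
    delta: float = 0.0
    epsilon: float = 0.05
    tau: int = 50
    T_pace: int = 220
    dt_ms: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.L < 10:
            raise ConfigurationError(f"L must be >= 10, got {self.L}")
        for name in ("nu", "delta", "epsilon"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.tau < 1:
            raise ConfigurationError(f"tau must be >= 1, got {self.tau}")
        if self.T_pace <= self.tau:
            raise ConfigurationError(
                f"T_pace ({self.T_pace}) must exceed tau ({self.tau})"
            )

    @property
    def refractory_ms(self) -> float:
        return self.tau * self.dt_ms

    @property
    def pacing_ms(self) -> float:
        return self.T_pace * self.dt_ms

    @property
    def fibrillation_threshold(self) -> float:
        """Active-cell count above which the tissue is fibrillating (1.1*L)."""
        return 1.1 * self.L


@dataclass(frozen=True)
class EctopicSpec:
    """A focal source: one cell forcibly excited every ``period`` steps."""

    position: tuple[int, int]
    period: int = 60

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ConfigurationError(f"period must be >= 1, got {self.period}")


@dataclass
class Tissue:
    """Lattice connectivity: transverse couplings and dysfunctional flags.

    ``transverse_up[r, c]`` is True when cell (r, c) is coupled to cell
    ((r+1) % L, c).  Longitudinal couplings are implicit and complete
    along each row, open at columns 0 and L-1.
    """

    config: ModelConfig
    transverse_up: np.ndarray
    dysfunctional: np.ndarray
    ectopics: list[EctopicSpec] = field(default_factory=list)

    @property
    def L(self) -> int:
        return self.config.L

    def copy(self) -> "Tissue":
        return Tissue(
            config=self.config,
            transverse_up=self.transverse_up.copy(),
            dysfunctional=self.dysfunctional.copy(),
            ectopics=list(self.ectopics),
        )


@dataclass(frozen=True)
class CircuitSpec:
    """An artificially inserted rectangular re-entrant circuit.

    The circuit occupies two fibres (rows ``anchor[0]`` and
    ``anchor[0]+1 mod L``) over ``segment_length + 2`` columns starting
    at the anchor column; its perimeter in cell-to-cell steps is
    ``path_length``, which must exceed tau for the circulation to be
    sustainable.
    """

    anchor: tuple[int, int]
    segment_length: int = DEFAULT_SEGMENT_LENGTH

    @property
    def n_cols(self) -> int:
        return self.segment_length + 2

    @property
    def path_length(self) -> int:
        return 2 * (self.n_cols - 1) + 2

    @property
    def rows(self) -> tuple[int, int]:
        return self.anchor[0], self.anchor[0] + 1  # caller wraps mod L

    @property
    def col_range(self) -> tuple[int, int]:
        """Inclusive column extent (c_lo, c_hi) of the footprint."""
        return self.anchor[1], self.anchor[1] + self.n_cols - 1

    def footprint(self, L: int) -> set[tuple[int, int]]:
        r, c = self.anchor
        return {
            ((r + dr) % L, c + dc)
            for dr in (0, 1)
            for dc in range(self.n_cols)
        }

    def centre(self, L: int) -> tuple[float, float]:
        r, c = self.anchor
        return ((r + 0.5) % L, c + (self.n_cols - 1) / 2.0)


def _rng(rng: np.random.Generator | int | None, config: ModelConfig) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        rng = config.seed
    return np.random.default_rng(rng)


def build_tissue(config: ModelConfig, rng: np.random.Generator | int | None = None) -> Tissue:
    """Draw a random tissue: Bernoulli(nu) transverse couplings and
    Bernoulli(delta) dysfunctional flags, independently per cell."""
    gen = _rng(rng, config)
    L = config.L
    transverse_up = gen.random((L, L)) < config.nu
    dysfunctional = gen.random((L, L)) < config.delta
    return Tissue(config=config, transverse_up=transverse_up, dysfunctional=dysfunctional)


def insert_circuit(
    tissue: Tissue,
    anchor: tuple[int, int],
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
) -> CircuitSpec:
    """Carve a rectangular re-entrant circuit into the tissue.

    The transverse couplings above and below the ``segment_length``
    cells to the right of the anchor are removed; the couplings closing
    the loop at both ends of the span are forced present.  Idempotent.
    """
    L = tissue.L
    r, c = int(anchor[0]) % L, int(anchor[1])
    c_end = c + segment_length + 1  # rightmost footprint column
    if c < 0 or c_end > L - 1:
        raise PlacementError(
            f"circuit anchored at column {c} with segment {segment_length} "
            f"does not fit inside the open boundaries (L={L})"
        )
    cols = np.arange(c + 1, c + segment_length + 1)
    tissue.transverse_up[r, cols] = False            # couplings to the fibre above
    tissue.transverse_up[(r - 1) % L, cols] = False  # couplings to the fibre below
    # Close the loop between rows r and r+1 at both ends of the span.
    tissue.transverse_up[r, c] = True
    tissue.transverse_up[r, c_end] = True
    return CircuitSpec(anchor=(r, c), segment_length=segment_length)


def circuit_path(circuit: CircuitSpec, L: int) -> list[tuple[int, int]]:
    """The circulation path, in propagation order, starting at the
    rightmost cell of the lower fibre and moving up, then leftward along
    the upper fibre, down at the left end and rightward back."""
    r, c = circuit.anchor
    ru = (r + 1) % L
    c_end = c + circuit.n_cols - 1
    path: list[tuple[int, int]] = []
    path.extend((ru, col) for col in range(c_end, c - 1, -1))   # leftward, upper fibre
    path.extend((r, col) for col in range(c, c_end + 1))        # rightward, lower fibre
    return path


def empty_state(config: ModelConfig) -> np.ndarray:
    return np.zeros((config.L, config.L), dtype=np.int16)


def seed_circuit_excitation(tissue: Tissue, circuit: CircuitSpec) -> np.ndarray:
    """Preset cell states so one wavefront circulates the circuit.

    The head (rightmost cell of the lower fibre) is excited; the
    min(tau, path_length-1) cells behind it along the circulation path
    carry descending refractory clocks, so propagation can only proceed
    forwards around the loop.
    """
    cfg = tissue.config
    if circuit.path_length <= cfg.tau:
        import warnings

        warnings.warn(
            f"circuit path length {circuit.path_length} <= tau {cfg.tau}: "
            "the circulation cannot self-sustain",
            stacklevel=2,
        )
    state = empty_state(cfg)
    path = circuit_path(circuit, tissue.L)
    head = path[-1]
    state[head] = EXCITED
    n_wake = min(cfg.tau, circuit.path_length - 1)
    for i in range(1, n_wake + 1):
        cell = path[-1 - i]
        state[cell] = cfg.tau + 2 - i  # excited i steps ago
    return state


def insert_ectopic(tissue: Tissue, spec: EctopicSpec) -> Tissue:
    """Register a focal source on the tissue (applied during stepping)."""
    r, c = spec.position
    if not (0 <= r < tissue.L and 0 <= c < tissue.L):
        raise PlacementError(f"ectopic position {spec.position} outside lattice")
    tissue.ectopics.append(spec)
    return tissue


def step(
    tissue: Tissue,
    state: np.ndarray,
    t: int,
    rng: np.random.Generator | None = None,
    pacing: bool = True,
) -> np.ndarray:
    """Synchronous update from the state at step ``t`` to step ``t+1``.

    Resting cells with at least one excited coupled neighbour become
    excited (dysfunctional cells fail each attempt with probability
    epsilon); excited cells become refractory for tau steps; refractory
    clocks count down.  The pacemaker excites resting column-0 cells
    whenever (t+1) is a multiple of T_pace, and registered ectopic
    sources fire on multiples of their period, skipping beats when the
    cell is not resting.
    """
    cfg = tissue.config
    L = cfg.L
    excited = state == EXCITED

    has_excited_neighbour = np.zeros((L, L), dtype=bool)
    has_excited_neighbour[:, 1:] |= excited[:, :-1]
    has_excited_neighbour[:, :-1] |= excited[:, 1:]
    up = tissue.transverse_up
    has_excited_neighbour |= up & np.roll(excited, -1, axis=0)
    has_excited_neighbour |= np.roll(up & excited, 1, axis=0)

    new = np.where(state > 2, state - 1, 0).astype(state.dtype)
    new[excited] = cfg.tau + 1

    to_excite = (state == RESTING) & has_excited_neighbour
    if cfg.delta > 0.0 and cfg.epsilon > 0.0:
        if rng is None:
            raise ValueError("an rng is required when dysfunctional cells are present")
        attempts = to_excite & tissue.dysfunctional
        if attempts.any():
            fails = np.zeros((L, L), dtype=bool)
            idx = np.nonzero(attempts)
            fails[idx] = rng.random(idx[0].size) < cfg.epsilon
            to_excite &= ~fails
    new[to_excite] = EXCITED

    t_next = t + 1
    if pacing and t_next % cfg.T_pace == 0:
        col0 = new[:, 0] == RESTING
        new[col0, 0] = EXCITED
    for ect in tissue.ectopics:
        if t_next % ect.period == 0 and new[ect.position] == RESTING:
            new[ect.position] = EXCITED
    return new


def count_active(state: np.ndarray) -> int:
    return int(np.count_nonzero(state == EXCITED))


def is_fibrillating(state: np.ndarray, config: ModelConfig) -> bool:
    return count_active(state) > config.fibrillation_threshold


class Simulation:
    """Mutable wrapper advancing (tissue, state, t) with fixed settings.

    If no initial state is given the simulation starts quiescent with
    the pacemaker firing at t=0 (when pacing is enabled).
    """

    def __init__(
        self,
        tissue: Tissue,
        state: np.ndarray | None = None,
        rng: np.random.Generator | int | None = None,
        pacing: bool = True,
        t: int = 0,
    ) -> None:
        self.tissue = tissue
        self.config = tissue.config
        self.pacing = pacing
        self.rng = _rng(rng, tissue.config)
        self.t = t
        if state is None:
            state = empty_state(tissue.config)
            if pacing and t == 0:
                state[:, 0] = EXCITED
        self.state = state

    def step(self, n: int = 1) -> np.ndarray:
        for _ in range(n):
            self.state = step(self.tissue, self.state, self.t, self.rng, self.pacing)
            self.t += 1
        return self.state


def initialize_af(
    tissue: Tissue,
    circuits: CircuitSpec | list[CircuitSpec],
    rng: np.random.Generator | int | None = None,
    pacing: bool = True,
    max_steps: int | None = None,
) -> tuple[Simulation, int]:
    """Seed the circuit(s) and run until fibrillation has filled the tissue.

    Termination requires that every column has hosted at least one
    excitation since seeding and that the fibrillation criterion
    (active count > 1.1 L) has held at least once; a look-ahead then
    confirms activity persists (a transient wave from an unsustainable
    circuit can sweep the tissue once and die).  Raises
    InitializationError if activity dies out or the horizon passes
    without fibrillation.
    """
    if isinstance(circuits, CircuitSpec):
        circuits = [circuits]
    cfg = tissue.config
    if max_steps is None:
        max_steps = 8 * cfg.L + 2 * cfg.T_pace
    state = empty_state(cfg)
    for circ in circuits:
        seeded = seed_circuit_excitation(tissue, circ)
        state = np.maximum(state, seeded)
    if pacing:
        col0 = state[:, 0] == RESTING
        state[col0, 0] = EXCITED
    sim = Simulation(tissue, state=state, rng=rng, pacing=pacing)

    columns_visited = (state == EXCITED).any(axis=0)
    fib_seen = is_fibrillating(state, cfg)
    while sim.t < max_steps:
        if columns_visited.all() and fib_seen:
            _confirm_persistence(sim, confirm_steps=6 * cfg.tau)
            return sim, sim.t
        sim.step()
        excited_cols = (sim.state == EXCITED).any(axis=0)
        if not excited_cols.any() and not tissue.ectopics and not pacing:
            raise InitializationError("electrical activity died out during initialization")
        columns_visited |= excited_cols
        fib_seen = fib_seen or is_fibrillating(sim.state, cfg)
    raise InitializationError(
        f"fibrillation did not establish within {max_steps} steps "
        "(circuit may be unsustainable)"
    )


def _confirm_persistence(sim: Simulation, confirm_steps: int) -> None:
    """Run a throwaway copy of the simulation forward; raise if the
    electrical activity (beyond pacemaker beats) dies out."""
    import copy

    probe = Simulation(
        sim.tissue,
        state=sim.state.copy(),
        rng=copy.deepcopy(sim.rng),
        pacing=False,  # only self-sustained activity counts
        t=sim.t,
    )
    for _ in range(confirm_steps):
        probe.step()
        if not (probe.state == EXCITED).any():
            raise InitializationError(
                "activity died out shortly after filling the tissue "
                "(transient wave, no persistent driver)"
            )


def save_snapshot(path, sim: Simulation) -> None:
    """Persist tissue connectivity and the current state as compressed
    arrays, with the configuration and step index embedded for replay."""
    cfg = dataclasses.asdict(sim.config)
    np.savez_compressed(
        path,
        transverse_up=sim.tissue.transverse_up,
        dysfunctional=sim.tissue.dysfunctional,
        state=sim.state,
        t=np.array([sim.t]),
        config_json=np.frombuffer(
            __import__("json").dumps(cfg).encode(), dtype=np.uint8
        ),
    )


def load_snapshot(path, pacing: bool = True) -> Simulation:
    import json

    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
        tissue = Tissue(
            config=cfg,
            transverse_up=data["transverse_up"],
            dysfunctional=data["dysfunctional"],
        )
        return Simulation(
            tissue, state=data["state"], pacing=pacing, t=int(data["t"][0])
        )


def sample_anchor(
    config: ModelConfig,
    rng: np.random.Generator,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
) -> tuple[int, int]:
    """Uniform circuit anchor with the whole footprint inside the open
    column boundaries."""
    row = int(rng.integers(0, config.L))
    col = int(rng.integers(0, config.L - segment_length - 2))
    return row, col


def sample_two_anchors(
    config: ModelConfig,
    rng: np.random.Generator,
    min_row_separation: int = 10,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
) -> list[tuple[int, int]]:
    """Two circuit anchors with vertical (row) separation >= the minimum
    on the periodic row circle, resampling the second until it fits."""
    L = config.L
    first = sample_anchor(config, rng, segment_length)
    while True:
        second = sample_anchor(config, rng, segment_length)
        d = abs(first[0] - second[0])
        if min(d, L - d) >= min_row_separation:
            return [first, second]
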