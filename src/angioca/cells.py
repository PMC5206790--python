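"""Tumour-cell state machine, cell cycle, and space-constrained division.

Cells are one of proliferative (P), quiescent (Q), apoptotic (A) or
necrotic (N).  Oxygen shortage arrests cells in G1 (P -> Q, reversible);
severe shortage kills any living cell (-> N).  A proliferative cell that
completes mitosis divides if it finds room in its Moore neighbourhood, or
by pushing one neighbour a single row outward; otherwise it eventually
enters apoptosis.  Daughter cells inherit the mother's cycle duration with
a small truncated-Gaussian perturbation applied to the G1 share only.

Two equivalent code paths exist: a scalar, per-cell API (:class:`Cell`,
:func:`update_state`, :func:`advance_cycle`) that states the rules one
cell at a time, and vectorized grid-level sweeps used by the driver
(:func:`update_states_grid`, :func:`advance_cycles_grid`).  A test
cross-checks the two on randomized configurations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .core import A, EMPTY, N, P, Q, ModelParams, SimulationGrid, neighbours8

logger = logging.getLogger("angioca")

G1, S, G2, M = 0, 1, 2, 3
PHASE_NAMES = {G1: "G1", S: "S", G2: "G2", M: "M"}


@dataclass(frozen=True)
class Cell:
    """Snapshot of one tumour cell."""

    state: int                       # core.P / Q / A / N
    mu: float                        # full cycle duration, h
    phase: int = G1                  # G1, S, G2 or M
    phase_clock: float = 0.0         # h elapsed in the current phase
    phase_durations: tuple = ()      # (G1, S, G2, M) durations, h; sums to mu
    division_ready: bool = False

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("cycle duration mu must be positive")
        if not self.phase_durations:
            object.__setattr__(self, "phase_durations", (self.mu - 13.0, 8.0, 4.0, 1.0))
        if abs(sum(self.phase_durations) - self.mu) > 1e-9:
            raise ValueError("phase durations must sum to mu")

    @property
    def alive(self) -> bool:
        return self.state in (P, Q)


def cell_from_grid(grid: SimulationGrid, index: tuple[int, int]) -> Cell:
    i, j = index
    if grid.state[i, j] == EMPTY:
        raise ValueError(f"no cell at {index}")
    mu = float(grid.mu[i, j])
    g1 = float(grid.g1_duration[i, j])
    pr = grid.params
    return Cell(
        state=int(grid.state[i, j]),
        mu=mu,
        phase=int(grid.phase[i, j]),
        phase_clock=float(grid.phase_clock[i, j]),
        phase_durations=(g1, pr.s_duration, pr.g2_duration, pr.m_duration),
        division_ready=bool(np.isfinite(grid.ready_since[i, j])),
    )


# -- scalar rules ----------------------------------------------------------

def update_state(cell: Cell, O_local: float, params: ModelParams) -> Cell:
    """Apply the oxygen-driven state transitions to one cell.

    Necrosis (any phase) takes precedence; quiescence induction is gated on
    G1; quiescent cells revert to P as soon as oxygen is back to normal.
    Dead cells are left untouched (logged no-op).
    """
    if not cell.alive:
        logger.debug("update_state called on dead cell (state %s): no-op", cell.state)
        return cell
    if O_local < params.O_necrosis:
        return replace(cell, state=N, division_ready=False)
    if cell.state == P and cell.phase == G1 and O_local < params.O_quiescence:
        return replace(cell, state=Q)
    if cell.state == Q and O_local >= params.O_quiescence:
        return replace(cell, state=P)
    return cell


def draw_daughter_cycle(mu_mother: float, sigma: float, rng: np.random.Generator) -> float:
    """Daughter cycle duration: Gaussian(mu_mother, sigma) truncated to
    mu_mother +/- 3 sigma.  Only the G1 share of the cycle absorbs the
    change; S, G2 and M are copied from the mother by the caller."""
    if mu_mother <= 0:
        raise ValueError("mu_mother must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return mu_mother
    while True:
        draw = rng.normal(mu_mother, sigma)
        if abs(draw - mu_mother) <= 3.0 * sigma:
            return draw


def advance_cycle(cell: Cell, dt: float, O_local: float = np.inf) -> Cell:
    """Progress the cycle clock of a proliferative cell by ``dt`` hours.

    Quiescent and dead cells are arrested.  Completion of M flags the cell
    division-ready; the clock then freezes until the division resolves.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if cell.state != P or cell.division_ready:
        return cell
    phase, clock = cell.phase, cell.phase_clock + dt
    durations = cell.phase_durations
    while clock >= durations[phase]:
        if phase == M:
            # keep the overshoot beyond M in the clock; it is credited to
            # the daughters' G1 so hourly scheduling does not stretch the
            # effective cycle
            return replace(cell, phase=M, phase_clock=clock, division_ready=True)
        clock -= durations[phase]
        phase += 1
    return replace(cell, phase=phase, phase_clock=clock)


# -- division --------------------------------------------------------------

def _place_daughter(grid: SimulationGrid, mother: tuple[int, int],
                    target: tuple[int, int], rng: np.random.Generator) -> None:
    pr = grid.params
    mi, mj = mother
    ti, tj = target
    mu_d = draw_daughter_cycle(float(grid.mu[mi, mj]), pr.sigma_cycle, rng)
    # only G1 absorbs the inherited change; S/G2/M copied from the mother
    g1_d = mu_d - (pr.s_duration + pr.g2_duration + pr.m_duration)
    # overshoot beyond M accrued under hourly scheduling starts the new G1
    over = min(max(float(grid.phase_clock[mi, mj]) - pr.m_duration, 0.0),
               grid.params.dt_cell)
    grid.state[ti, tj] = P
    grid.mu[ti, tj] = mu_d
    grid.g1_duration[ti, tj] = max(g1_d, 1e-6)
    grid.phase[ti, tj] = G1
    grid.phase_clock[ti, tj] = over
    grid.ready_since[ti, tj] = np.nan
    grid.death_clock[ti, tj] = np.nan
    # mother restarts her cycle with her own mu
    grid.phase[mi, mj] = G1
    grid.phase_clock[mi, mj] = over
    grid.ready_since[mi, mj] = np.nan


def _move_cell(grid: SimulationGrid, src: tuple[int, int], dst: tuple[int, int]) -> None:
    for arr in (grid.state, grid.mu, grid.g1_duration, grid.phase,
                grid.phase_clock, grid.ready_since, grid.death_clock):
        arr[dst] = arr[src]
    grid.state[src] = EMPTY
    grid.ready_since[src] = np.nan
    grid.death_clock[src] = np.nan


def attempt_division(grid: SimulationGrid, index: tuple[int, int],
                     rng: np.random.Generator,
                     apoptosis_on_failure: bool = True) -> str:
    """Resolve one division attempt of the ready cell at ``index``.

    Returns ``"placed"`` (free Moore neighbour), ``"pushed"`` (one neighbour
    displaced into the second ring, daughter takes its element),
    ``"apoptosis"`` (no room, mother dies) or ``"blocked"`` (no room but
    ``apoptosis_on_failure`` is False, so the cell will retry)."""
    i, j = index
    if grid.state[i, j] != P:
        raise ValueError(f"attempt_division on non-P cell at {index}")
    if not np.isfinite(grid.ready_since[i, j]):
        raise ValueError(f"attempt_division on mid-cycle cell at {index}")
    nbs = neighbours8(index, grid.n)
    free = [c for c in nbs if grid.state[c] == EMPTY]
    if free:
        target = free[rng.integers(len(free))]
        _place_daughter(grid, index, target, rng)
        return "placed"
    # case (ii): push one occupied neighbour into a free element of ITS
    # Moore neighbourhood (necessarily beyond the first occupied row)
    pushable = []
    for nb in nbs:
        slots = [c for c in neighbours8(nb, grid.n)
                 if grid.state[c] == EMPTY and c != index]
        if slots:
            pushable.append((nb, slots))
    if pushable:
        nb, slots = pushable[rng.integers(len(pushable))]
        dst = slots[rng.integers(len(slots))]
        _move_cell(grid, nb, dst)
        _place_daughter(grid, index, nb, rng)
        return "pushed"
    if apoptosis_on_failure:
        grid.state[i, j] = A
        grid.ready_since[i, j] = np.nan
        grid.death_clock[i, j] = grid.clock
        return "apoptosis"
    return "blocked"


def division_case(occupied_ring1: np.ndarray, occupied_ring2: np.ndarray) -> str:
    """Brute-force classifier of the division rule on a 5x5 patch.

    ``occupied_ring1``: 8 booleans (Moore ring of the mother, row-major
    order); ``occupied_ring2``: 16 booleans (outer ring of the 5x5 patch,
    row-major).  Used as the independent oracle in tests."""
    patch = np.zeros((5, 5), dtype=bool)
    patch[2, 2] = True
    ring1 = [(i, j) for i in range(1, 4) for j in range(1, 4) if (i, j) != (2, 2)]
    ring2 = [(i, j) for i in range(5) for j in range(5)
             if i in (0, 4) or j in (0, 4)]
    for c, occ in zip(ring1, occupied_ring1):
        patch[c] = occ
    for c, occ in zip(ring2, occupied_ring2):
        patch[c] = occ
    if any(not patch[c] for c in ring1):
        return "placed"
    for nb in ring1:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                c = (nb[0] + di, nb[1] + dj)
                if c == nb or c == (2, 2):
                    continue
                if 0 <= c[0] < 5 and 0 <= c[1] < 5 and not patch[c]:
                    return "pushed"
    return "apoptosis"


# -- vectorized grid sweeps (driver hot path) ------------------------------

def update_states_grid(grid: SimulationGrid) -> int:
    """Oxygen-driven state transitions for every living cell; returns the
    number of necrotic deaths this sweep."""
    pr = grid.params
    O = grid.O
    living = grid.living
    necrose = living & (O < pr.O_necrosis)
    grid.state[necrose] = N
    grid.death_clock[necrose] = grid.clock
    grid.ready_since[necrose] = np.nan
    to_q = (grid.state == P) & (grid.phase == G1) & (O < pr.O_quiescence)
    grid.state[to_q] = Q
    grid.ready_since[to_q] = np.nan
    to_p = (grid.state == Q) & (O >= pr.O_quiescence)
    grid.state[to_p] = P
    return int(np.sum(necrose))


def advance_cycles_grid(grid: SimulationGrid, dt: float) -> None:
    """Vectorized cycle progression of all P cells (Q cells are arrested)."""
    pr = grid.params
    fixed = np.array([0.0, pr.s_duration, pr.g2_duration, pr.m_duration])
    active = (grid.state == P) & ~np.isfinite(grid.ready_since)
    grid.phase_clock[active] += dt
    while True:
        durations = np.where(grid.phase == G1, grid.g1_duration, fixed[grid.phase])
        roll = active & (grid.phase_clock >= durations)
        if not roll.any():
            break
        done = roll & (grid.phase == M)
        if done.any():
            grid.ready_since[done] = grid.clock
            # phase_clock keeps the overshoot beyond M (credited at division)
            active &= ~done
            roll &= ~done
        grid.phase_clock[roll] -= durations[roll]
        grid.phase[roll] += 1


def process_divisions(grid: SimulationGrid, rng: np.random.Generator) -> dict:
    """Attempt division for every ready cell in randomized order.

    A blocked cell retries on later sweeps and commits to apoptosis once it
    has been ready for ``division_retry_window`` hours."""
    pr = grid.params
    ready = (grid.state == P) & np.isfinite(grid.ready_since)
    coords = np.argwhere(ready)
    if len(coords) == 0:
        return {"placed": 0, "pushed": 0, "apoptosis": 0, "blocked": 0}
    order = rng.permutation(len(coords))
    tally = {"placed": 0, "pushed": 0, "apoptosis": 0, "blocked": 0}
    for idx in order:
        i, j = map(int, coords[idx])
        if grid.state[i, j] != P or not np.isfinite(grid.ready_since[i, j]):
            continue  # displaced or changed earlier in this sweep
        give_up = grid.clock - grid.ready_since[i, j] >= pr.division_retry_window
        outcome = attempt_division(grid, (i, j), rng, apoptosis_on_failure=give_up)
        tally[outcome] += 1
    return tally


def clear_lysed(grid: SimulationGrid) -> int:
    """Free elements whose dead occupant exceeded the lysis delay."""
    pr = grid.params
    dead = (grid.state == A) | (grid.state == N)
    lysed = dead & (grid.clock - grid.death_clock >= pr.lysis_delay)
    grid.state[lysed] = EMPTY
    grid.death_clock[lysed] = np.nan
    return int(np.sum(lysed))


def seed_cell(grid: SimulationGrid, index: tuple[int, int],
              rng: np.random.Generator, state: int = P) -> None:
    """Place an initial cell with cycle position drawn uniformly over the
    cycle, so a freshly seeded population is desynchronized."""
    pr = grid.params
    i, j = index
    mu = pr.mu_0
    g1 = mu - (pr.s_duration + pr.g2_duration + pr.m_duration)
    t = rng.uniform(0.0, mu)
    durations = (g1, pr.s_duration, pr.g2_duration, pr.m_duration)
    phase = 0
    while t >= durations[phase]:
        t -= durations[phase]
        phase += 1
    grid.state[i, j] = state
    grid.mu[i, j] = mu
    grid.g1_duration[i, j] = g1
    grid.phase[i, j] = phase
    grid.phase_clock[i, j] = t
    grid.ready_since[i, j] = np.nan
    grid.death_clock[i, j] = np.nan
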