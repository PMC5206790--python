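"""Time-loop orchestration of one simulated tumour.

One automaton step is one simulated hour and applies, in fixed order:
field update (explicit V/p/m sub-stepping, quasi-steady oxygen), capillary
and matrix degradation, oxygen-driven cell-state transitions, cell-cycle
advance plus divisions, then sprout initiation and tip migration.  The
default run spans 28 simulated days with daily bookkeeping and field
snapshots at days 3, 7, 14 and 28.

Runs are bitwise reproducible from the run seed: a single RNG drives cell
update order, division tie-breaks and all sprouting stochasticity.  The
driver also enforces an exact population ledger every step (living-cell
change = divisions - deaths), aborting with a state dump if it is ever
violated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .cells import advance_cycles_grid, clear_lysed, process_divisions, update_states_grid
from .core import ModelParams, SimulationGrid
from .fields import integrate_fields, update_oxygen
from .initialization import SyntheticCase, build_case, generate_synthetic_case
from .vasculature import (Sprout, VesselNetwork, degrade_capillaries, degrade_matrix,
                          initiate_sprouts, migrate_sprout_tips, sprout_edge_indicator)

logger = logging.getLogger("angioca")


@dataclass
class RunSpec:
    """What to simulate: either a synthetic case seed or a prebuilt case."""

    case_seed: int = 1
    run_seed: int = 0
    duration_days: float = 28.0
    snapshot_days: tuple = (3, 7, 14, 28)
    params: ModelParams = dc_field(default_factory=ModelParams)
    case: SyntheticCase | None = None   # overrides case_seed when given

    def __post_init__(self):
        if self.duration_days < 0:
            raise ValueError("duration_days must be non-negative")


@dataclass
class SimulationResult:
    spec: RunSpec
    record: pd.DataFrame                 # one row per day
    snapshots: dict                      # day -> dict of arrays
    grid: SimulationGrid
    network: VesselNetwork
    sprouts: list
    stats: dict                          # cumulative divisions / deaths

    def record_csv(self) -> str:
        return self.record.to_csv(index=False, float_format="%.10g")


class BookkeepingError(RuntimeError):
    """The exact division/death ledger failed (indicates a driver bug)."""


def simulation_step(grid: SimulationGrid, network: VesselNetwork,
                    sprouts: list[Sprout], origins: set,
                    rng: np.random.Generator, stats: dict) -> None:
    """Advance the whole model by one automaton step (``dt_cell`` hours)."""
    pr = grid.params
    dt = pr.dt_cell
    living_before = int(np.sum(grid.living))

    # 1. diffusive fields (sources frozen over the step), quasi-steady O
    grid.sprout_edges = sprout_edge_indicator(sprouts, grid)
    integrate_fields(grid, dt)
    update_oxygen(grid, dt)

    # 2. protease-driven degradation
    degrade_capillaries(grid)
    degrade_matrix(grid, dt)

    # 3. oxygen-driven state transitions
    necrosed = update_states_grid(grid)

    # 4. cycle progression and divisions
    advance_cycles_grid(grid, dt)
    tally = process_divisions(grid, rng)

    # 5. angiogenesis (origin spacing applies to currently active sprouts)
    origins.clear()
    origins.update(sp.origin for sp in sprouts if sp.active)
    new = initiate_sprouts(grid, network, rng, dt, origins)
    sprouts.extend(new)
    branches = migrate_sprout_tips(sprouts, grid, network, rng, dt)
    sprouts.extend(branches)
    network.sync_grid(grid)

    # 6. clear lysed debris, advance the clock
    clear_lysed(grid)
    grid.clock += dt

    divisions = tally["placed"] + tally["pushed"]
    deaths = necrosed + tally["apoptosis"]
    living_after = int(np.sum(grid.living))
    stats["divisions"] = stats.get("divisions", 0) + divisions
    stats["deaths"] = stats.get("deaths", 0) + deaths
    if living_after - living_before != divisions - deaths:
        raise BookkeepingError(
            f"population ledger broken at t={grid.clock} h: "
            f"living {living_before}->{living_after}, "
            f"divisions {divisions}, deaths {deaths}")


def _snapshot(grid: SimulationGrid, sprouts: list[Sprout]) -> dict:
    return {
        "state": grid.state.copy(),
        "V": grid.V.copy(),
        "O": grid.O.copy(),
        "E": grid.E.copy(),
        "vessel_mask": (grid.vessel_weight_cache > 0).astype(np.uint8),
        "intensity": analysis.render_intensity(grid.state),
    }


def run_simulation(spec: RunSpec) -> SimulationResult:
    """Simulate one tumour case from day 0 to ``duration_days``."""
    pr = spec.params
    rng = np.random.default_rng(spec.run_seed)
    case = spec.case if spec.case is not None else generate_synthetic_case(
        spec.case_seed, pr)
    grid, entry_node = build_case(case, pr, rng)
    network = grid.network
    sprouts: list[Sprout] = []
    origins: set = set()
    stats: dict = {}

    rows = []
    snapshots: dict = {}

    def record_day(day: float) -> None:
        counts = grid.counts()
        living_mask = grid.living
        eff = analysis.effective_area(living_mask, pr.dx)
        app = analysis.apparent_area(living_mask, pr.dx)
        rows.append({
            "day": day,
            "n_P": counts["P"], "n_Q": counts["Q"],
            "n_A": counts["A"], "n_N": counts["N"],
            "effective_area_mm2": eff,
            "apparent_area_mm2": app,
            "neovessel_length_mm": network.total_length(pr.dx, kind="neovessel"),
            "active_sprouts": sum(s.active for s in sprouts),
        })

    record_day(0.0)
    snapshots[0] = _snapshot(grid, sprouts)

    steps_per_day = int(round(24.0 / pr.dt_cell))
    total_steps = int(round(spec.duration_days * steps_per_day))
    try:
        for step in range(1, total_steps + 1):
            simulation_step(grid, network, sprouts, origins, rng, stats)
            if step % steps_per_day == 0:
                day = step / steps_per_day
                record_day(day)
                counts = grid.counts()
                logger.info("day %5.1f  P=%d Q=%d A=%d N=%d sprouts=%d",
                            day, counts["P"], counts["Q"], counts["A"],
                            counts["N"], sum(s.active for s in sprouts))
                if any(abs(day - d) < 1e-9 for d in spec.snapshot_days):
                    snapshots[int(day)] = _snapshot(grid, sprouts)
    except Exception:
        dump = Path("scratch")
        try:
            dump.mkdir(exist_ok=True)
            np.savez(dump / f"postmortem_case{spec.case_seed}.npz",
                     state=grid.state, O=grid.O, V=grid.V, E=grid.E, p=grid.p)
            logger.error("simulation aborted; state dumped to %s", dump)
        except OSError:
            pass
        raise

    record = pd.DataFrame(rows)
    return SimulationResult(spec=spec, record=record, snapshots=snapshots,
                            grid=grid, network=network, sprouts=sprouts,
                            stats=stats)


def run_batch(case_seeds, run_seed: int, params: ModelParams | None = None,
              duration_days: float = 28.0) -> list[SimulationResult]:
    """Run one simulation per case seed; per-case run seeds are derived
    from ``run_seed`` through a SeedSequence (independent, reproducible)."""
    params = params if params is not None else ModelParams()
    children = np.random.SeedSequence(run_seed).spawn(len(case_seeds))
    results = []
    for case_seed, child in zip(case_seeds, children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        spec = RunSpec(case_seed=int(case_seed), run_seed=sub_seed,
                       duration_days=duration_days, params=params)
        logger.info("batch: case seed %s (run seed %s)", case_seed, sub_seed)
        results.append(run_simulation(spec))
    return results
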