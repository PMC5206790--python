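"""Shared domain types: model parameters, lattice geometry, simulation grid.

The simulator couples a cellular automaton of tumour cells (one cell per
lattice element at most) to four reaction-diffusion fields -- VEGF ``V``,
oxygen ``O``, tumour proteases ``p`` and endothelial (sprout) proteases
``m`` -- and to a vasculature made of an implicit capillary density ``E``
plus discrete vessel segments on the edges and diagonals of the lattice
elements.  Everything downstream (cell dynamics, vasculature, hemodynamics,
field integration, the driver) shares the :class:`ModelParams` and
:class:`SimulationGrid` defined here.

Concentrations are normalized: the physiological oxygen level under an
intact capillary bed (``E = E_0``) and baseline uptake ``k_0`` is 1 by
construction, which fixes the intravascular level ``O_v = 1 + k_0/(gamma *
E_0)``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

logger = logging.getLogger("angioca")

# Cell-state codes stored in SimulationGrid.state
EMPTY, P, Q, A, N = 0, 1, 2, 3, 4
STATE_NAMES = {EMPTY: "empty", P: "P", Q: "Q", A: "A", N: "N"}
LIVING_STATES = (P, Q)
DEAD_STATES = (A, N)


class ConfigError(ValueError):
    """Raised when a configuration file cannot be parsed or validated."""


@dataclass
class ModelParams:
    """All tunable model parameters.

    Rates are per hour, diffusion coefficients in mm^2/h, lengths in mm and
    vessel radii in micrometres.  Concentrations are dimensionless
    (normalized); production/uptake rates act on those normalized units.
    """

    # --- reaction-diffusion coefficients (VEGF, oxygen, proteases) ---
    D_V: float = 0.104        # VEGF diffusion, mm^2/h
    D_O: float = 2.41e-3      # oxygen diffusion, mm^2/h-equivalent
    D_p: float = 1.73e-3      # tumour-protease diffusion, mm^2/h
    D_m: float = 10.4e-3      # sprout-protease diffusion, mm^2/h
    alpha_V: float = 0.0145   # VEGF production per quiescent cell, 1/h
    alpha_p: float = 3600.0   # protease production per proliferative cell, 1/h
    alpha_m: float = 130.0    # protease production per sprout edge, 1/h
    nu_V: float = 0.65        # VEGF decay, 1/h
    nu_p: float = 0.21        # tumour-protease decay, 1/h
    nu_m: float = 1.30        # sprout-protease decay, 1/h
    lambda_V: float = 1.0     # VEGF consumption by endothelium per unit vessel weight, 1/h
    V_max: float = 0.06       # receptor-saturation cap on VEGF uptake
    gamma_v_base: float = 4.8  # vessel oxygen permeability scale (x R/R_min), 1/(mm h)
    O_v: float = 1.5          # intravascular oxygen (normalized); = 1 + k_0/(gamma*E_0)
    k_0: float = 2.4          # oxygen uptake, normal tissue, 1/h
    k_P: float = 4.8          # oxygen uptake, proliferative cells (2*k_0), 1/h
    k_Q: float = 2.4          # oxygen uptake, quiescent cells, 1/h

    # --- lattice & capillary field ---
    E_0: float = 1.0          # baseline implicit capillary density (dimensionless)
    grid_n: int = 200
    dx: float = 0.02          # element size, mm (~one tumour-cell diameter)

    # --- thresholds (calibration values, see docs/methods.md) ---
    O_quiescence: float = 0.5   # below: G1 cells arrest (P -> Q)
    O_necrosis: float = 0.002    # below: any living cell dies (-> N)
    V_sprout: float = 2.4e-3    # VEGF level gating sprout initiation
    p_degrade: float = 2900.0   # protease level destroying the capillary field

    # --- cell cycle ---
    mu_0: float = 34.0            # initial cell-cycle duration, h
    sigma_cycle: float = 0.2      # SD of daughter G1 inheritance, h
    s_duration: float = 8.0       # S-phase, h
    g2_duration: float = 4.0      # G2-phase, h
    m_duration: float = 1.0       # M-phase, h
    lysis_delay: float = 48.0     # h a dead cell keeps occupying its element
    division_retry_window: float = 24.0  # h a blocked division-ready cell retries before apoptosis

    # --- vessels, hemodynamics, adaptation ---
    R_min: float = 3.0            # um, lower bound on vessel caliber
    R_max: float = 150.0          # um, upper bound
    R_init: float = 15.0          # um, initial caliber of segmented vessels (30 um diameter)
    R_ref: float = 40.0           # um, fixed caliber of the reference vessel (80 um diameter)
    R_neo: float = 6.0            # um, caliber assigned to neovessel segments
    viscosity: float = 1.0        # arbitrary consistent units (only pressures are physical)
    entry_pressure: float = 13.0  # kPa at the reference-vessel entry node
    boundary_pressure: float = 2.0  # kPa at vessel endpoints touching the domain border
    adapt_tau_ref: float = 10.0   # shear reference in the adaptation stimulus
    adapt_q_ref: float = 2e4      # flow reference in the metabolic stimulus
    adapt_k_meta: float = 0.8     # metabolic stimulus weight
    adapt_meta_cap: float = 3.0   # cap on the metabolic log term (dead ends shrink)
    adapt_k_shrink: float = 0.5   # constant shrinking tendency
    adapt_step: float = 0.05      # Euler step on log-radius per iteration
    adapt_tol: float = 1e-4       # max relative diameter change at convergence
    adapt_max_iter: int = 500

    # --- sprouting angiogenesis (constants deferred by the model literature;
    #     exposed as calibration keys) ---
    sprout_prob_scale: float = 0.08  # initiation probability per candidate node per h at V = 2*V_sprout
    branch_prob: float = 0.05        # tip branching probability per step when V > 2*V_sprout
    sprout_spacing: int = 4          # min Chebyshev distance between sprout origins, elements
    sprout_min_steps: int = 4        # steps before a tip may rejoin the network (no instant loops)
    tip_chemotaxis: float = 2000.0   # weighting of the local VEGF difference in tip steps
    tip_move_prob: float = 0.5       # probability a tip advances in a given hour
    matrix_bonus: float = 1.0        # preference multiplier for degraded matrix
    neo_perm_factor: float = 30.0    # permeability multiplier of perfused (leaky) neovessels

    # --- extracellular matrix ---
    matrix_rate: float = 5e-4     # integrity loss per unit m per h

    # --- numerics / scheduling ---
    dt_cell: float = 1.0          # automaton step, h
    substep_safety: float = 0.9   # fraction of the explicit stability limit for V,p,m
    oxygen_mode: str = "steady"   # "steady" (quasi-steady solve) or "explicit"
    vegf_weight_includes_unperfused: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nonneg = (
            "D_V D_O D_p D_m alpha_V alpha_p alpha_m nu_V nu_p nu_m lambda_V "
            "V_max gamma_v_base O_v k_0 k_P k_Q E_0 O_quiescence O_necrosis "
            "V_sprout p_degrade sigma_cycle lysis_delay matrix_rate "
            "sprout_prob_scale branch_prob tip_chemotaxis matrix_bonus"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"parameter {name!r} must be non-negative, got {getattr(self, name)}")
        if not (self.k_P >= self.k_0 >= self.k_Q):
            raise ConfigError("oxygen uptake ordering k_P >= k_0 >= k_Q violated")
        if self.grid_n <= 0:
            raise ConfigError("grid_n must be positive")
        if self.dx <= 0:
            raise ConfigError("dx must be positive")
        if self.mu_0 <= 0:
            raise ConfigError("mu_0 must be positive")
        if self.s_duration + self.g2_duration + self.m_duration >= self.mu_0:
            raise ConfigError("S+G2+M durations must leave a positive G1 share of mu_0")
        if not (0 <= self.O_necrosis <= self.O_quiescence):
            raise ConfigError("need 0 <= O_necrosis <= O_quiescence")
        if not (0 < self.R_min <= self.R_init <= self.R_max):
            raise ConfigError("vessel radii must satisfy R_min <= R_init <= R_max")
        if self.oxygen_mode not in ("steady", "explicit"):
            raise ConfigError("oxygen_mode must be 'steady' or 'explicit'")

    # -- config I/O -------------------------------------------------------

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]

    @classmethod
    def from_dict(cls, values: dict) -> "ModelParams":
        known = set(cls.field_names())
        unknown = set(values) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**values)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **overrides) -> "ModelParams":
        return dataclasses.replace(self, **overrides)


def load_config(path: str | Path | None) -> ModelParams:
    """Read a flat key-value (YAML) config; absent keys fall back to defaults.

    ``path=None`` returns pure defaults.  All effective values are logged.
    """
    values: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"configuration file not found: {path}")
        try:
            loaded = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse configuration {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"configuration {path} must be a flat key-value mapping")
        values = loaded
    params = ModelParams.from_dict(values)
    for name in params.field_names():
        logger.info("config %-28s = %s", name, getattr(params, name))
    return params


def save_config(params: ModelParams, path: str | Path) -> None:
    """Write every parameter so that load_config round-trips exactly."""
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))


# -- symbol table -----------------------------------------------------------
# One entry per symbol of the field equations and of the vessel-weight
# definition, mapping to the attribute that realizes it.  ``@`` prefixes
# name SimulationGrid / GridElement attributes rather than ModelParams ones.
EQUATION_SYMBOLS: dict[str, str] = {
    "D_V": "D_V", "D_O": "D_O", "D_p": "D_p", "D_m": "D_m",
    "alpha_V": "alpha_V", "alpha_p": "alpha_p", "alpha_m": "alpha_m",
    "nu_V": "nu_V", "nu_p": "nu_p", "nu_m": "nu_m",
    "lambda_V": "lambda_V", "V_max": "V_max",
    "gamma_v": "gamma_v_base", "O_v": "O_v",
    "k_0": "k_0", "k_P": "k_P", "k_Q": "k_Q",
    "V": "@V", "O": "@O", "p": "@p", "m": "@m",
    "E": "@E", "W": "@vessel_weight_cache", "n_sprout": "@sprout_edges",
}


def neighbours8(index: tuple[int, int], n: int) -> list[tuple[int, int]]:
    """Moore neighbourhood of ``index`` on an ``n`` x ``n`` lattice, clipped
    at the domain boundary."""
    i, j = index
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"index {index} outside {n}x{n} grid")
    out = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            a, b = i + di, j + dj
            if 0 <= a < n and 0 <= b < n:
                out.append((a, b))
    return out


class GridElement:
    """Read/write view on one lattice element of a :class:`SimulationGrid`."""

    __slots__ = ("_grid", "index")

    def __init__(self, grid: "SimulationGrid", index: tuple[int, int]):
        self._grid = grid
        self.index = index

    @property
    def state(self) -> int:
        return int(self._grid.state[self.index])

    @property
    def occupant(self):
        """A :class:`angioca.cells.Cell` snapshot, or None if empty."""
        if self._grid.state[self.index] == EMPTY:
            return None
        from .cells import cell_from_grid

        return cell_from_grid(self._grid, self.index)

    @property
    def E(self) -> float:
        return float(self._grid.E[self.index])

    @E.setter
    def E(self, value: float) -> None:
        if value < 0:
            raise ValueError("capillary density E cannot be negative")
        self._grid.E[self.index] = value

    @property
    def matrix(self) -> float:
        return float(self._grid.matrix[self.index])

    @property
    def segments(self) -> list:
        if self._grid.network is None:
            return []
        return self._grid.network.segments_in_element(self.index)


class SimulationGrid:
    """State of one simulated tissue patch.

    Cell attributes are stored as dense per-element arrays (struct of
    arrays) for speed; :meth:`element` exposes the object view used by the
    element-level API and the tests.
    """

    def __init__(self, params: ModelParams):
        self.params = params
        n = params.grid_n
        self.n = n
        self.dx = params.dx
        self.clock = 0.0  # simulated hours

        # cellular automaton state
        self.state = np.zeros((n, n), dtype=np.int8)
        self.mu = np.zeros((n, n))            # cycle duration, h
        self.g1_duration = np.zeros((n, n))   # inherited G1 share, h
        self.phase = np.zeros((n, n), dtype=np.int8)  # 0 G1, 1 S, 2 G2, 3 M
        self.phase_clock = np.zeros((n, n))
        self.ready_since = np.full((n, n), np.nan)  # h at which division became due
        self.death_clock = np.full((n, n), np.nan)  # h of death (lysis timer)

        # vasculature
        self.E = np.full((n, n), params.E_0)
        self.matrix = np.ones((n, n))
        self.vessel_weight_cache = np.zeros((n, n))  # sum of segment lengths (edges halved, diagonals full; no E)
        self.perfused_length_cache = np.zeros((n, n))  # same sum restricted to perfused segments
        self.exchange_weight = np.zeros((n, n))      # permeability-scaled perfused length (no E)
        self.sprout_edges = np.zeros((n, n), dtype=np.int16)  # active sprout segments per element
        self.network = None  # vasculature.VesselNetwork, attached by initialization

        # diffusive fields; oxygen starts at the physiological level
        self.V = np.zeros((n, n))
        self.O = np.ones((n, n))
        self.p = np.zeros((n, n))
        self.m = np.zeros((n, n))

    # -- views ------------------------------------------------------------

    def element(self, i: int, j: int) -> GridElement:
        if not (0 <= i < self.n and 0 <= j < self.n):
            raise IndexError(f"({i}, {j}) outside {self.n}x{self.n} grid")
        return GridElement(self, (i, j))

    def elements(self) -> Iterator[GridElement]:
        for i in range(self.n):
            for j in range(self.n):
                yield GridElement(self, (i, j))

    def neighbours8(self, index: tuple[int, int]) -> list[tuple[int, int]]:
        return neighbours8(index, self.n)

    # -- masks and bookkeeping -------------------------------------------

    @property
    def living(self) -> np.ndarray:
        return (self.state == P) | (self.state == Q)

    @property
    def occupied(self) -> np.ndarray:
        return self.state != EMPTY

    def counts(self) -> dict[str, int]:
        return {
            "P": int(np.sum(self.state == P)),
            "Q": int(np.sum(self.state == Q)),
            "A": int(np.sum(self.state == A)),
            "N": int(np.sum(self.state == N)),
        }

    def uptake_map(self) -> np.ndarray:
        """Per-element oxygen uptake rate k_{i,j} selected by cell state."""
        k = np.full((self.n, self.n), self.params.k_0)
        k[self.state == P] = self.params.k_P
        k[self.state == Q] = self.params.k_Q
        k[(self.state == A) | (self.state == N)] = 0.0
        return k

    def vegf_weight_map(self) -> np.ndarray:
        """Vessel weight W used in the VEGF consumption term.

        By default all segments count (unperfused sprouts still carry
        endothelial cells that take up VEGF); set
        ``vegf_weight_includes_unperfused = False`` to restrict the sum to
        perfused segments.
        """
        if self.params.vegf_weight_includes_unperfused:
            return self.vessel_weight_cache + self.E
        return self.perfused_length_cache + self.E

    def oxygen_exchange_map(self) -> np.ndarray:
        """Permeability-scaled exchange coefficient gamma_v * W (per h)."""
        return self.params.gamma_v_base * (self.exchange_weight + self.E)
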