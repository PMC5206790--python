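"""Explicit and quasi-steady integration of the coupled reaction-diffusion
fields V (VEGF), O (oxygen), p (tumour proteases) and m (sprout proteases).

The four equations on the lattice are

    dV/dt = D_V lap(V) + alpha_V [Q] - nu_V V - lambda_V W min(V, V_max)
    dO/dt = D_O lap(O) + gamma_v W (O_v - O) - k O
    dp/dt = D_p lap(p) + alpha_p [P] - nu_p p
    dm/dt = D_m lap(m) + alpha_m [n] - nu_m m

with homogeneous Neumann (no-flux) boundaries; [Q], [P] and [n] are the
indicator arrays of quiescent cells, proliferative cells and active sprout
edges, W is the vessel weight and k the state-dependent oxygen uptake.
The Laplacian is the 5-point stencil in flux form (boundary neighbours
mirrored), which conserves mass exactly in the absence of reactions.

V, p and m are integrated by forward Euler at a fraction of the explicit
stability limit ``dx^2 / (4 D)``, each species sub-stepping at its own
limit (compiled inner loops).  Oxygen equilibrates in seconds, far faster
than the hourly automaton step, so the default mode solves its linear
steady state directly once per step; explicit integration of O is kept as
a validation mode and the two agree to a fraction of a percent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numba import njit

from .core import ModelParams, P, Q, SimulationGrid

logger = logging.getLogger("angioca")


@dataclass
class FieldSet:
    """The four concentration arrays (views onto the grid state)."""

    V: np.ndarray
    O: np.ndarray
    p: np.ndarray
    m: np.ndarray

    def __post_init__(self):
        shapes = {a.shape for a in (self.V, self.O, self.p, self.m)}
        if len(shapes) != 1:
            raise ValueError("field arrays must share one shape")


def grid_fields(grid: SimulationGrid) -> FieldSet:
    return FieldSet(grid.V, grid.O, grid.p, grid.m)


def stability_limit(D: float, dx: float) -> float:
    """Largest explicitly stable forward-Euler step for diffusivity D."""
    if D <= 0:
        return math.inf
    return dx * dx / (4.0 * D)


def laplacian(C: np.ndarray, dx: float) -> np.ndarray:
    """5-point Laplacian, flux form, mirrored (no-flux) boundaries."""
    L = np.zeros_like(C)
    L[1:, :] += C[:-1, :] - C[1:, :]
    L[:-1, :] += C[1:, :] - C[:-1, :]
    L[:, 1:] += C[:, :-1] - C[:, 1:]
    L[:, :-1] += C[:, 1:] - C[:, :-1]
    return L / (dx * dx)


# -- compiled substep kernels ----------------------------------------------

@njit(cache=True, fastmath=True)
def _substeps_linear(C, D, nu, src, dx, dt, nsub):  # pragma: no cover - compiled
    n0, n1 = C.shape
    r = dt * D / (dx * dx)
    buf = np.empty_like(C)
    for it in range(nsub):
        A = C if it % 2 == 0 else buf
        B = buf if it % 2 == 0 else C
        for i in range(n0):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < n0 - 1 else n0 - 1
            for j in (0, n1 - 1):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < n1 - 1 else n1 - 1
                lap = A[im, j] + A[ip, j] + A[i, jm] + A[i, jp] - 4.0 * A[i, j]
                val = A[i, j] + r * lap + dt * (src[i, j] - nu * A[i, j])
                B[i, j] = val if val > 0.0 else 0.0
            for j in range(1, n1 - 1):
                lap = A[im, j] + A[ip, j] + A[i, j - 1] + A[i, j + 1] - 4.0 * A[i, j]
                val = A[i, j] + r * lap + dt * (src[i, j] - nu * A[i, j])
                B[i, j] = val if val > 0.0 else 0.0
    if nsub % 2 == 1:
        C[:, :] = buf


@njit(cache=True, fastmath=True)
def _substeps_vegf(C, D, nu, src, lam_w, vmax, dx, dt, nsub):  # pragma: no cover - compiled
    n0, n1 = C.shape
    r = dt * D / (dx * dx)
    buf = np.empty_like(C)
    for it in range(nsub):
        A = C if it % 2 == 0 else buf
        B = buf if it % 2 == 0 else C
        for i in range(n0):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < n0 - 1 else n0 - 1
            for j in (0, n1 - 1):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < n1 - 1 else n1 - 1
                lap = A[im, j] + A[ip, j] + A[i, jm] + A[i, jp] - 4.0 * A[i, j]
                uptake = A[i, j] if A[i, j] < vmax else vmax
                val = A[i, j] + r * lap + dt * (src[i, j] - nu * A[i, j]
                                                - lam_w[i, j] * uptake)
                B[i, j] = val if val > 0.0 else 0.0
            for j in range(1, n1 - 1):
                lap = A[im, j] + A[ip, j] + A[i, j - 1] + A[i, j + 1] - 4.0 * A[i, j]
                uptake = A[i, j] if A[i, j] < vmax else vmax
                val = A[i, j] + r * lap + dt * (src[i, j] - nu * A[i, j]
                                                - lam_w[i, j] * uptake)
                B[i, j] = val if val > 0.0 else 0.0
    if nsub % 2 == 1:
        C[:, :] = buf


# -- single explicit step (reference path; the kernels must match it) ------

def step_fields(grid: SimulationGrid, dt: float, include_oxygen: bool = True) -> None:
    """One forward-Euler update of all fields (in place).

    Raises if ``dt`` exceeds the explicit stability limit of any stepped
    species.  Source indicators are read from the current grid state.
    """
    pr = grid.params
    diffs = [pr.D_V, pr.D_p, pr.D_m] + ([pr.D_O] if include_oxygen else [])
    limit = min(stability_limit(D, pr.dx) for D in diffs)
    if dt > limit * (1.0 + 1e-12):
        raise ValueError(f"dt={dt} exceeds explicit stability limit {limit:.3e} h")

    q_src = pr.alpha_V * (grid.state == Q)
    p_src = pr.alpha_p * (grid.state == P)
    m_src = pr.alpha_m * (grid.sprout_edges > 0)
    w_vegf = grid.vegf_weight_map()

    new_V = grid.V + dt * (pr.D_V * laplacian(grid.V, pr.dx) + q_src
                           - pr.nu_V * grid.V
                           - pr.lambda_V * w_vegf * np.minimum(grid.V, pr.V_max))
    new_p = grid.p + dt * (pr.D_p * laplacian(grid.p, pr.dx) + p_src - pr.nu_p * grid.p)
    new_m = grid.m + dt * (pr.D_m * laplacian(grid.m, pr.dx) + m_src - pr.nu_m * grid.m)
    if include_oxygen:
        G = grid.oxygen_exchange_map()
        k = grid.uptake_map()
        new_O = grid.O + dt * (pr.D_O * laplacian(grid.O, pr.dx)
                               + G * (pr.O_v - grid.O) - k * grid.O)
        np.clip(new_O, 0.0, None, out=grid.O)
    np.clip(new_V, 0.0, None, out=grid.V)
    np.clip(new_p, 0.0, None, out=grid.p)
    np.clip(new_m, 0.0, None, out=grid.m)


def integrate_fields(grid: SimulationGrid, dt_total: float) -> None:
    """Advance V, p and m by ``dt_total`` hours with per-species explicit
    sub-stepping at ``substep_safety`` times the stability limit (sources
    frozen over the interval).  Oxygen is handled separately."""
    pr = grid.params
    q_src = (pr.alpha_V * (grid.state == Q)).astype(np.float64)
    p_src = (pr.alpha_p * (grid.state == P)).astype(np.float64)
    m_src = (pr.alpha_m * (grid.sprout_edges > 0)).astype(np.float64)
    lam_w = pr.lambda_V * grid.vegf_weight_map()

    for C, D, nu, src in ((grid.p, pr.D_p, pr.nu_p, p_src),
                          (grid.m, pr.D_m, pr.nu_m, m_src)):
        nsub = max(1, math.ceil(dt_total / (pr.substep_safety * stability_limit(D, pr.dx))))
        _substeps_linear(C, D, nu, src, pr.dx, dt_total / nsub, nsub)
    nsub = max(1, math.ceil(dt_total / (pr.substep_safety * stability_limit(pr.D_V, pr.dx))))
    _substeps_vegf(grid.V, pr.D_V, pr.nu_V, q_src, lam_w, pr.V_max,
                   pr.dx, dt_total / nsub, nsub)


# -- quasi-steady oxygen ---------------------------------------------------

_LAP_CACHE: dict[tuple[int, float], sp.csr_matrix] = {}


def _neumann_laplacian(n: int, dx: float) -> sp.csr_matrix:
    """Sparse 5-point Laplacian with no-flux boundaries on an n x n grid."""
    key = (n, dx)
    if key not in _LAP_CACHE:
        one = sp.diags([np.ones(n - 1), np.ones(n - 1)], [-1, 1], format="csr")
        deg = sp.diags(np.asarray(one.sum(axis=1)).ravel())
        lap1 = one - deg
        eye = sp.identity(n, format="csr")
        _LAP_CACHE[key] = (sp.kron(lap1, eye) + sp.kron(eye, lap1)).tocsr() / (dx * dx)
    return _LAP_CACHE[key]


def steady_oxygen(grid: SimulationGrid, x0: np.ndarray | None = None) -> np.ndarray:
    """Solve the steady oxygen problem
    ``D_O lap(O) + G (O_v - O) - k O = 0`` with no-flux boundaries.

    Conjugate gradients with diagonal preconditioning and warm start (the
    system is symmetric positive definite whenever any exchange or uptake
    is present); falls back to a direct sparse solve if CG stalls.  With no
    exchange and no uptake anywhere the problem is singular: the current
    mean of the O field is returned uniformly, with a warning.
    """
    pr = grid.params
    n = grid.n
    G = grid.oxygen_exchange_map().ravel()
    k = grid.uptake_map().ravel()
    absorb = G + k
    if not np.any(absorb > 0):
        logger.warning("steady_oxygen: no vessels and no uptake anywhere; "
                       "steady state undetermined, returning uniform field")
        return np.full((n, n), float(grid.O.mean()))
    lap = _neumann_laplacian(n, pr.dx)
    A = (-pr.D_O) * lap + sp.diags(absorb)
    rhs = G * pr.O_v
    guess = (x0 if x0 is not None else grid.O).ravel().astype(np.float64).copy()
    M = sp.diags(1.0 / (A.diagonal() + 1e-300))
    sol, info = spla.cg(A, rhs, x0=guess, rtol=1e-8, atol=0.0, maxiter=2000, M=M)
    if info != 0:
        logger.warning("steady_oxygen: CG did not converge (info=%s); "
                       "falling back to direct solve", info)
        sol = spla.spsolve(A.tocsc(), rhs)
    out = sol.reshape(n, n)
    np.clip(out, 0.0, None, out=out)
    return out


def update_oxygen(grid: SimulationGrid, dt: float) -> None:
    """Refresh the O field: quasi-steady solve (default) or explicit
    integration at the oxygen stability limit (validation mode)."""
    pr = grid.params
    if pr.oxygen_mode == "steady":
        grid.O[:, :] = steady_oxygen(grid)
        return
    G = grid.oxygen_exchange_map()
    k = grid.uptake_map()
    # explicit stability needs the full spectral bound: diffusion plus the
    # (possibly strong) local absorption G + k
    lam_max = 8.0 * pr.D_O / (pr.dx * pr.dx) + float(np.max(G + k))
    nsub = max(1, math.ceil(dt * lam_max / (2.0 * pr.substep_safety)))
    sub_dt = dt / nsub
    for _ in range(nsub):
        new_O = grid.O + sub_dt * (pr.D_O * laplacian(grid.O, pr.dx)
                                   + G * (pr.O_v - grid.O) - k * grid.O)
        np.clip(new_O, 0.0, None, out=grid.O)
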