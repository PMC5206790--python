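"""Poiseuille network flow and structural vessel adaptation.

Blood flow through the segmented network is modelled as laminar Poiseuille
flow: each segment has conductance ``g = pi R^4 / (8 eta L)`` and node
pressures solve the Kirchhoff conservation system with Dirichlet pressures
imposed at the entry node (13 kPa) and at every vessel endpoint touching
the domain border (2 kPa).  Vessel diameters then adapt iteratively under
a wall-shear-stress stimulus, a metabolic (low-flow) stimulus and a
constant shrinking tendency, in the spirit of the Pries structural
adaptation rule, until a steady state; the reference vessel is held fixed
to anchor the network.  The adapted network is the initial vascular
condition of a simulation -- flow is not re-solved during tumour growth.

Units: pressures are physical (kPa); viscosity, conductance and flow are
in arbitrary but mutually consistent units, which is sufficient because
only pressure boundary conditions are prescribed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import ModelParams
from .vasculature import VesselNetwork, VesselSegment

logger = logging.getLogger("angioca")

Node = tuple[int, int]


class SingularFlowError(RuntimeError):
    """A connected component of the network has no pressure boundary node."""


@dataclass
class FlowState:
    node_pressure: dict            # node -> kPa
    segment_flow: dict             # id(segment) -> signed flow, a -> b positive
    wall_shear: dict               # id(segment) -> |tau|

    def flow(self, seg: VesselSegment) -> float:
        return self.segment_flow[id(seg)]

    def shear(self, seg: VesselSegment) -> float:
        return self.wall_shear[id(seg)]

    def max_residual(self, network: VesselNetwork, dirichlet: set[Node]) -> float:
        """Largest net-flow imbalance at any interior node, relative to the
        largest segment flow (Kirchhoff check)."""
        net = {}
        for s in network.segments:
            q = self.segment_flow[id(s)]
            net[s.a] = net.get(s.a, 0.0) + q
            net[s.b] = net.get(s.b, 0.0) - q
        interior = [abs(v) for nd, v in net.items() if nd not in dirichlet]
        scale = max((abs(q) for q in self.segment_flow.values()), default=1.0)
        return max(interior, default=0.0) / max(scale, 1e-300)

    def to_csv(self) -> str:
        lines = ["node_r,node_c,pressure_kPa"]
        for (r, c), pres in sorted(self.node_pressure.items()):
            lines.append(f"{r},{c},{pres:.10g}")
        return "\n".join(lines) + "\n"


def conductance(seg: VesselSegment, dx: float, viscosity: float) -> float:
    return math.pi * seg.radius ** 4 / (8.0 * viscosity * seg.length(dx))


def boundary_nodes(network: VesselNetwork, n: int) -> set[Node]:
    """Vessel endpoints (degree-1 nodes) lying on the domain border.

    Mid-vessel nodes that merely graze the border are not endpoints and
    carry no imposed pressure."""
    return {nd for nd in network.nodes()
            if (nd[0] in (0, n) or nd[1] in (0, n))
            and len(network.node_segments(nd)) == 1}


def solve_flow(network: VesselNetwork, entry_node: Node, params: ModelParams,
               n: int) -> FlowState:
    """Solve the linear Kirchhoff system for node pressures and flows.

    Dirichlet conditions: ``entry_pressure`` at the entry node,
    ``boundary_pressure`` at every border endpoint.  Raises
    :class:`SingularFlowError` for components without any imposed pressure.
    """
    if len(network) == 0:
        raise ValueError("empty vessel network")
    dirichlet: dict[Node, float] = {nd: params.boundary_pressure
                                    for nd in boundary_nodes(network, n)}
    dirichlet[entry_node] = params.entry_pressure

    graph = network.to_graph(params.dx)
    for comp in nx.connected_components(graph):
        if not comp & set(dirichlet):
            raise SingularFlowError(
                f"component of {len(comp)} nodes (e.g. {next(iter(comp))}) has "
                "no entry or boundary node; pressures are undetermined")

    nodes = list(graph.nodes)
    unknown = [nd for nd in nodes if nd not in dirichlet]
    index = {nd: k for k, nd in enumerate(unknown)}
    m = len(unknown)
    rows, cols, vals = [], [], []
    rhs = np.zeros(m)
    for s in network.segments:
        g = conductance(s, params.dx, params.viscosity)
        for u, v in ((s.a, s.b), (s.b, s.a)):
            if u in index:
                k = index[u]
                rows.append(k); cols.append(k); vals.append(g)
                if v in index:
                    rows.append(k); cols.append(index[v]); vals.append(-g)
                else:
                    rhs[k] += g * dirichlet[v]
    pressures = dict(dirichlet)
    if m:
        mat = sp.csr_matrix((vals, (rows, cols)), shape=(m, m))
        sol = spla.spsolve(mat.tocsc(), rhs)
        pressures.update({nd: float(sol[index[nd]]) for nd in unknown})

    flows, shears = {}, {}
    for s in network.segments:
        g = conductance(s, params.dx, params.viscosity)
        q = g * (pressures[s.a] - pressures[s.b])
        flows[id(s)] = q
        shears[id(s)] = 4.0 * params.viscosity * abs(q) / (math.pi * s.radius ** 3)
    return FlowState(pressures, flows, shears)


def adaptation_stimulus(seg: VesselSegment, flow: FlowState, params: ModelParams) -> float:
    """Net growth stimulus on log-radius: wall shear (growth at high shear),
    metabolic (growth at low flow) and a constant shrinking term."""
    eps = 1e-12
    tau = flow.shear(seg)
    q = abs(flow.flow(seg))
    s_tau = math.log10((tau + eps) / params.adapt_tau_ref)
    s_meta = params.adapt_k_meta * min(
        math.log10(1.0 + params.adapt_q_ref / (q + eps)), params.adapt_meta_cap)
    return s_tau + s_meta - params.adapt_k_shrink


def adapt_diameters(network: VesselNetwork, entry_node: Node, params: ModelParams,
                    n: int, max_iter: int | None = None) -> FlowState:
    """Iterate flow solve + radius update to the adaptation steady state.

    Deterministic (no RNG).  Radii are clamped to [R_min, R_max] at every
    iteration and reference (``fixed``) segments never change.  Returns the
    final flow state; warns if ``max_iter`` is reached without meeting the
    relative-change tolerance.
    """
    max_iter = max_iter if max_iter is not None else params.adapt_max_iter
    flow = solve_flow(network, entry_node, params, n)
    free = [s for s in network.segments if not s.fixed]
    for it in range(max_iter):
        if not free:
            logger.info("adapt_diameters: only fixed vessels; nothing to adapt")
            return flow
        max_rel = 0.0
        for s in free:
            stim = adaptation_stimulus(s, flow, params)
            new_r = s.radius * math.exp(params.adapt_step * stim)
            new_r = min(max(new_r, params.R_min), params.R_max)
            max_rel = max(max_rel, abs(new_r - s.radius) / s.radius)
            s.radius = new_r
        flow = solve_flow(network, entry_node, params, n)
        if max_rel < params.adapt_tol:
            logger.info("adapt_diameters converged after %d iterations", it + 1)
            return flow
    logger.warning("adapt_diameters: no convergence after %d iterations "
                   "(last max relative change %.3g); returning current state",
                   max_iter, max_rel)
    return flow
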