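"""Vessel network on the lattice, capillary/matrix degradation, sprouting.

Vessels live on the *corner lattice* of the simulation grid: a segment
joins two corner nodes and occupies either an edge of a grid element
(length ``dx``, shared between the two flanking elements, so each gets
half the length) or a diagonal (length ``dx * sqrt(2)``, belonging to a
single element).  The per-element *vessel weight*

    W_ij = sum over segments of (L_b / 2  or  L_d) + E_ij

couples the discrete network and the implicit capillary density ``E`` to
the reaction-diffusion fields: W drives VEGF consumption, and its
permeability-scaled counterpart (gamma_v x R/R_min per segment) drives
oxygen exchange.

Sprouting angiogenesis follows the standard lattice scheme: sprouts
initiate stochastically on perfused vessels where VEGF exceeds a
threshold, tips migrate one lattice step per hour at most, biased up the
VEGF gradient with a preference for degraded matrix, may branch where
VEGF is high, and anastomose on contact with another vessel, at which
point the new loop is considered perfused.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import N as NECROTIC
from .core import ModelParams, SimulationGrid

logger = logging.getLogger("angioca")

Node = tuple[int, int]
SQRT2 = math.sqrt(2.0)


@dataclass
class VesselSegment:
    a: Node
    b: Node
    radius: float                  # um
    kind: str = "preexisting"      # or "neovessel"
    perfused: bool = True
    fixed: bool = False            # reference vessel: diameter never adapts

    def __post_init__(self):
        dr = abs(self.a[0] - self.b[0])
        dc = abs(self.a[1] - self.b[1])
        if (dr, dc) not in ((0, 1), (1, 0), (1, 1)):
            raise ValueError(f"segment {self.a}-{self.b} is not a lattice edge or diagonal")
        self.placement = "diagonal" if dr == 1 and dc == 1 else "edge"

    def length(self, dx: float) -> float:
        return dx * SQRT2 if self.placement == "diagonal" else dx

    def elements(self, n: int) -> list[tuple[int, int]]:
        """Grid elements this segment contributes to (1 for a diagonal,
        up to 2 for a shared edge)."""
        (r1, c1), (r2, c2) = self.a, self.b
        if self.placement == "diagonal":
            el = (min(r1, r2), min(c1, c2))
            return [el] if 0 <= el[0] < n and 0 <= el[1] < n else []
        if r1 == r2:  # horizontal edge: elements above and below
            c = min(c1, c2)
            cands = [(r1 - 1, c), (r1, c)]
        else:         # vertical edge: elements left and right
            r = min(r1, r2)
            cands = [(r, c1 - 1), (r, c1)]
        return [(i, j) for (i, j) in cands if 0 <= i < n and 0 <= j < n]

    def contribution(self, element: tuple[int, int], dx: float) -> float:
        """Length this segment adds to the weight of ``element`` (edges are
        shared between two elements and count half)."""
        L = self.length(dx)
        return L if self.placement == "diagonal" else L / 2.0


class VesselNetwork:
    """Graph of vessel segments joined at corner-lattice nodes."""

    def __init__(self):
        self.segments: list[VesselSegment] = []
        self._by_key: dict[frozenset, VesselSegment] = {}
        self._by_node: dict[Node, list[VesselSegment]] = {}

    def __len__(self) -> int:
        return len(self.segments)

    def has_segment(self, a: Node, b: Node) -> bool:
        return frozenset((a, b)) in self._by_key

    def has_node(self, node: Node) -> bool:
        return node in self._by_node

    def node_segments(self, node: Node) -> list[VesselSegment]:
        return self._by_node.get(node, [])

    def add_segment(self, a: Node, b: Node, radius: float,
                    kind: str = "preexisting", perfused: bool = True) -> VesselSegment:
        key = frozenset((a, b))
        if key in self._by_key:
            return self._by_key[key]
        seg = VesselSegment(a, b, radius, kind, perfused)
        self.segments.append(seg)
        self._by_key[key] = seg
        for node in (a, b):
            self._by_node.setdefault(node, []).append(seg)
        return seg

    def segments_in_element(self, element: tuple[int, int], n: int | None = None) -> list[VesselSegment]:
        n = n if n is not None else 10 ** 9
        return [s for s in self.segments if element in s.elements(n)]

    def nodes(self) -> list[Node]:
        return list(self._by_node)

    def total_length(self, dx: float, kind: str | None = None) -> float:
        return sum(s.length(dx) for s in self.segments if kind is None or s.kind == kind)

    def to_graph(self, dx: float) -> nx.Graph:
        g = nx.Graph()
        for s in self.segments:
            g.add_edge(s.a, s.b, segment=s, length=s.length(dx))
        return g

    # -- grid coupling ----------------------------------------------------

    def sync_grid(self, grid: SimulationGrid) -> None:
        """Recompute the per-element weight caches from the segment list."""
        pr = grid.params
        grid.vessel_weight_cache[:] = 0.0
        grid.perfused_length_cache[:] = 0.0
        grid.exchange_weight[:] = 0.0
        for s in self.segments:
            perm = s.radius / pr.R_min
            if s.kind == "neovessel":
                perm *= pr.neo_perm_factor
            for el in s.elements(grid.n):
                contrib = s.contribution(el, grid.dx)
                grid.vessel_weight_cache[el] += contrib
                if s.perfused:
                    grid.perfused_length_cache[el] += contrib
                    grid.exchange_weight[el] += perm * contrib

    # -- plain-text I/O ---------------------------------------------------

    def to_edge_list(self) -> str:
        lines = ["# r1 c1 r2 c2 radius_um kind perfused"]
        for s in self.segments:
            lines.append(f"{s.a[0]} {s.a[1]} {s.b[0]} {s.b[1]} "
                         f"{s.radius:.6g} {s.kind} {int(s.perfused)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_edge_list(cls, text: str) -> "VesselNetwork":
        net = cls()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            r1, c1, r2, c2, radius, kind, perf = line.split()
            net.add_segment((int(r1), int(c1)), (int(r2), int(c2)),
                            float(radius), kind, bool(int(perf)))
        return net

    def overlay_mask(self, n: int) -> np.ndarray:
        """Binary n x n image of the elements traversed by any segment."""
        mask = np.zeros((n, n), dtype=np.uint8)
        for s in self.segments:
            for el in s.elements(n):
                mask[el] = 255
        return mask


def vessel_weight(grid: SimulationGrid, element: tuple[int, int],
                  network: VesselNetwork | None = None) -> float:
    """Per-element vessel weight W: segment lengths (edges halved,
    diagonals full) plus the capillary density E, computed directly from
    the network (authoritative; the grid caches are the fast path)."""
    net = network if network is not None else grid.network
    total = float(grid.E[element])
    if net is not None:
        for s in net.segments:
            if element in s.elements(grid.n):
                total += s.contribution(element, grid.dx)
    return total


# -- degradation -----------------------------------------------------------

def degrade_capillaries(grid: SimulationGrid) -> int:
    """Destroy the implicit capillary field (E -> 0, irreversible) wherever
    tumour proteases exceed the threshold; returns elements degraded now."""
    hit = (grid.p > grid.params.p_degrade) & (grid.E > 0)
    grid.E[hit] = 0.0
    return int(np.sum(hit))


def degrade_matrix(grid: SimulationGrid, dt: float) -> None:
    """Matrix integrity decays at ``matrix_rate * m`` per hour, floored at 0."""
    grid.matrix -= grid.params.matrix_rate * grid.m * dt
    np.clip(grid.matrix, 0.0, 1.0, out=grid.matrix)


# -- sprouting -------------------------------------------------------------

@dataclass
class Sprout:
    origin: Node
    tip: Node
    path: list = field(default_factory=list)       # VesselSegments, in order
    nodes: list = field(default_factory=list)      # visited nodes, in order
    age: float = 0.0
    active: bool = True
    perfused: bool = False

    def __post_init__(self):
        if not self.nodes:
            self.nodes = [self.origin]


def _node_field_value(field2d: np.ndarray, node: Node) -> float:
    """Field value at a corner node: mean over the (up to 4) touching elements."""
    n = field2d.shape[0]
    r, c = node
    vals = [field2d[i, j]
            for i in (r - 1, r) for j in (c - 1, c)
            if 0 <= i < n and 0 <= j < n]
    return float(np.mean(vals))


def initiate_sprouts(grid: SimulationGrid, network: VesselNetwork,
                     rng: np.random.Generator, dt: float,
                     active_origins: set[Node] | None = None) -> list[Sprout]:
    """Spawn new sprouts on perfused vessel nodes where VEGF exceeds the
    threshold.  Initiation is stochastic with probability increasing in V;
    origins keep a minimum Chebyshev spacing from one another."""
    pr = grid.params
    origins = set(active_origins) if active_origins else set()
    new: list[Sprout] = []
    nodes = [nd for nd in network.nodes()
             if any(s.perfused for s in network.node_segments(nd))]
    rng.shuffle(nodes)
    for node in nodes:
        v = _node_field_value(grid.V, node)
        if v <= pr.V_sprout:
            continue
        if any(max(abs(node[0] - o[0]), abs(node[1] - o[1])) < pr.sprout_spacing
               for o in origins):
            continue
        prob = min(1.0, pr.sprout_prob_scale * dt * max(v / pr.V_sprout - 1.0, 0.0))
        if rng.random() < prob:
            new.append(Sprout(origin=node, tip=node))
            origins.add(node)
    return new


_DIRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _step_blocked(grid: SimulationGrid, a: Node, b: Node) -> bool:
    """A tip never migrates through necrotic debris: a diagonal step is
    blocked if its element is necrotic; an edge step if both flanking
    elements are."""
    seg_els = VesselSegment(a, b, 1.0, "neovessel", False).elements(grid.n)
    if not seg_els:
        return False
    states = [grid.state[el] == NECROTIC for el in seg_els]
    return all(states)


def migrate_sprout_tips(sprouts: list[Sprout], grid: SimulationGrid,
                        network: VesselNetwork, rng: np.random.Generator,
                        dt: float) -> list[Sprout]:
    """Advance every active sprout tip by at most one lattice step.

    Direction weights combine chemotaxis (exponential in the local VEGF
    difference) with a preference for degraded matrix.  Contact with
    another vessel anastomoses the sprout; high VEGF may trigger branching.
    Returns newly created branch sprouts."""
    pr = grid.params
    n_nodes = grid.n  # corner indices run 0..n inclusive
    branches: list[Sprout] = []
    order = rng.permutation(len(sprouts))
    for k in order:
        sp = sprouts[k]
        if not sp.active:
            continue
        sp.age += dt
        if rng.random() >= pr.tip_move_prob:
            continue
        r, c = sp.tip
        v_here = _node_field_value(grid.V, sp.tip)
        cands, weights = [], []
        own = set(sp.nodes)
        young = len(sp.path) < pr.sprout_min_steps
        for dr, dc in _DIRS:
            node = (r + dr, c + dc)
            if not (0 <= node[0] <= n_nodes and 0 <= node[1] <= n_nodes):
                continue
            if node in own:
                continue
            if network.has_segment(sp.tip, node):
                continue
            if young and network.has_node(node):
                continue  # too short to loop back onto the network
            if _step_blocked(grid, sp.tip, node):
                continue
            dv = _node_field_value(grid.V, node) - v_here
            mat = 1.0 - _node_field_value(grid.matrix, node)
            w = math.exp(min(pr.tip_chemotaxis * dv, 50.0)) * (1.0 + pr.matrix_bonus * mat)
            cands.append(node)
            weights.append(w)
        if not cands:
            continue
        weights = np.asarray(weights)
        target = cands[rng.choice(len(cands), p=weights / weights.sum())]
        hit_vessel = network.has_node(target)
        seg = network.add_segment(sp.tip, target, pr.R_neo,
                                  kind="neovessel", perfused=False)
        seg.sprout = sp
        sp.path.append(seg)
        sp.nodes.append(target)
        sp.tip = target
        if hit_vessel:
            # anastomosis closes a loop.  Every sprout originates on the
            # perfused network, so the loop through the junction is a flow
            # path: perfuse this sprout and any sprout owning the contacted
            # segments.
            contacted = [s for s in network.node_segments(target) if s is not seg]
            sp.active = False
            sp.perfused = True
            for s in sp.path:
                s.perfused = True
            for s in contacted:
                other = getattr(s, "sprout", None)
                if other is not None and not other.perfused:
                    other.perfused = True
                    for s2 in other.path:
                        s2.perfused = True
            continue
        if (_node_field_value(grid.V, target) > 2.0 * pr.V_sprout
                and rng.random() < pr.branch_prob):
            branches.append(Sprout(origin=target, tip=target))
    return branches


def sprout_edge_indicator(sprouts: list[Sprout], grid: SimulationGrid) -> np.ndarray:
    """Per-element count of active (still migrating) sprout segments: the
    source indicator for endothelial protease production."""
    ind = np.zeros((grid.n, grid.n), dtype=np.int16)
    for sp in sprouts:
        if not sp.active:
            continue
        for s in sp.path:
            for el in s.elements(grid.n):
                ind[el] += 1
    return ind
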