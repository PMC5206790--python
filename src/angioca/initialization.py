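"""Initial virtual tumour and vasculature.

The tumour is built image-style: a grayscale fluorescence-like image is
thresholded at three ascending levels into nested regions (low / medium /
high cell density), each region is resized to the computation grid,
realized as sparse / medium / dense cell occupancy through grey-level
Gaussian noise and re-thresholding, and the three binary images are summed
into the initial occupancy.  Only the bulk of the tumour (largest
connected component, after a small dilation) is kept; every occupied
element receives a proliferative cell.

The vasculature is built from vessel centre-line polylines: each polyline
is rasterized onto lattice edges and diagonals, the reference vessel
(carrying the flow entry point) is fixed at 80 um diameter, all others
start at 30 um, and the hemodynamics module adapts diameters to a steady
state under 13 kPa entry / 2 kPa border pressures.

Because no reference images ship with the package, a seeded synthetic-case
generator emulates the experimental inputs: a granular blob with three
concentric density zones plus a handful of vessel polylines with one entry
point.  The generator's defaults define the standard study conditions used
by the tests and the batch analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import binary_dilation, binary_fill_holes, gaussian_filter
from scipy.stats import norm
from skimage.measure import label
from skimage.morphology import disk
from skimage.transform import resize

from .core import ModelParams, SimulationGrid
from .cells import seed_cell
from .fields import steady_oxygen
from .hemodynamics import FlowState, adapt_diameters
from .vasculature import VesselNetwork

logger = logging.getLogger("angioca")

BACKGROUND, LOW, MEDIUM, HIGH = 0, 1, 2, 3
DEFAULT_FILL_PROBS = (0.15, 0.5, 0.85)  # sparse / medium / dense occupancy


@dataclass
class DensityMap:
    """Density labels on the grid plus the realized cell occupancy."""

    labels: np.ndarray     # uint8 in {BACKGROUND, LOW, MEDIUM, HIGH}
    occupancy: np.ndarray  # bool; occupied only where labels != BACKGROUND

    def __post_init__(self):
        if self.labels.shape != self.occupancy.shape:
            raise ValueError("labels and occupancy must share a shape")
        if np.any(self.occupancy & (self.labels == BACKGROUND)):
            raise ValueError("occupancy outside labelled regions")


@dataclass
class SyntheticCase:
    """Stand-in for one experimental input (synthetic, generated from a seed):
    a granular tumour image with three density zones and a few vessel
    polylines with one flow entry point."""

    seed: int
    image: np.ndarray                      # uint8 grayscale
    thresholds: tuple                      # three ascending grey levels
    polylines: list                        # arrays of (r, c) corner-lattice coords
    entry_point: tuple                     # (r, c), lies on a polyline
    entry_polyline: int = 0
    fill_probs: tuple | None = None        # per-case density fills (low/med/high)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        iio.imwrite(directory / "tumour.png", self.image)
        lines = ["polyline,point,r,c"]
        for k, poly in enumerate(self.polylines):
            for idx, (r, c) in enumerate(poly):
                lines.append(f"{k},{idx},{r:.4f},{c:.4f}")
        (directory / "vessels.csv").write_text("\n".join(lines) + "\n")
        fills = "" if self.fill_probs is None else (
            "fills " + " ".join(f"{f:.4f}" for f in self.fill_probs) + "\n")
        (directory / "case.txt").write_text(
            f"seed {self.seed}\nthresholds {self.thresholds[0]} "
            f"{self.thresholds[1]} {self.thresholds[2]}\n"
            f"entry {self.entry_point[0]:.4f} {self.entry_point[1]:.4f} "
            f"{self.entry_polyline}\n" + fills)


# -- tumour from image -----------------------------------------------------

def tumour_from_image(image: np.ndarray, thresholds, params: ModelParams,
                      rng: np.random.Generator,
                      fill_probs=DEFAULT_FILL_PROBS,
                      bulk_dilation: int = 2) -> DensityMap:
    """Three-threshold density extraction and stochastic occupancy.

    ``thresholds`` must be strictly ascending within the image range; the
    nested super-threshold regions give low/medium/high density zones,
    resized (area-averaged) to ``grid_n``, realized as Bernoulli occupancy
    through Gaussian grey-level noise + re-threshold at per-zone fill
    probabilities, and restricted to the tumour bulk (largest connected
    component after dilation by ``bulk_dilation``)."""
    t1, t2, t3 = thresholds
    if not (t1 < t2 < t3):
        raise ValueError(f"thresholds must be strictly ascending, got {thresholds}")
    img = np.asarray(image, dtype=float)
    n = params.grid_n

    nested = []
    for t in (t1, t2, t3):
        mask = img >= t
        resized = resize(mask.astype(float), (n, n), order=1,
                         anti_aliasing=True, preserve_range=True) > 0.5
        nested.append(resized)
    low, med, high = nested
    labels = np.zeros((n, n), dtype=np.uint8)
    labels[low] = LOW
    labels[med] = MEDIUM
    labels[high] = HIGH

    occupancy = np.zeros((n, n), dtype=bool)
    noise = rng.normal(size=(n, n))  # one grey-level noise field, re-thresholded per zone
    for lab, fill in zip((LOW, MEDIUM, HIGH), fill_probs):
        zone = labels == lab
        occupancy[zone] = noise[zone] < norm.ppf(fill)

    if not occupancy.any():
        logger.warning("tumour_from_image: empty tumour after thresholding")
        return DensityMap(labels, occupancy)

    # keep only the tumour bulk: largest connected component of the
    # dilated occupancy (scattered outliers are dropped)
    dilated = binary_dilation(occupancy, structure=disk(bulk_dilation))
    comp = label(dilated, connectivity=2)
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    occupancy &= comp == sizes.argmax()
    return DensityMap(labels, occupancy)


def place_cells(grid: SimulationGrid, density: DensityMap,
                rng: np.random.Generator) -> int:
    """Seed one proliferative cell per occupied element (desynchronized
    cycle positions); returns the number of cells placed."""
    coords = np.argwhere(density.occupancy)
    for i, j in coords:
        seed_cell(grid, (int(i), int(j)), rng)
    return len(coords)


# -- vessels from polylines ------------------------------------------------

def _rasterize_polyline(points: np.ndarray, n: int) -> list[tuple[int, int]]:
    """8-connected chain of corner-lattice nodes following the polyline."""
    nodes: list[tuple[int, int]] = []
    pts = np.asarray(points, dtype=float)
    for k in range(len(pts) - 1):
        a, b = pts[k], pts[k + 1]
        steps = max(1, int(math.ceil(4 * max(abs(b[0] - a[0]), abs(b[1] - a[1])))))
        for t in np.linspace(0.0, 1.0, steps + 1):
            node = tuple(int(round(v)) for v in a + t * (b - a))
            node = (min(max(node[0], 0), n), min(max(node[1], 0), n))
            if not nodes or node != nodes[-1]:
                nodes.append(node)
    # remove any non-adjacent jumps left by rounding (should not occur at
    # this sampling density, but guard anyway)
    chain = [nodes[0]]
    for node in nodes[1:]:
        dr, dc = node[0] - chain[-1][0], node[1] - chain[-1][1]
        if max(abs(dr), abs(dc)) > 1:
            chain.append((chain[-1][0] + int(np.sign(dr)), chain[-1][1] + int(np.sign(dc))))
        if node != chain[-1]:
            chain.append(node)
    return chain


def vessels_from_polylines(polylines, entry_point, params: ModelParams,
                           entry_polyline: int | None = None
                           ) -> tuple[VesselNetwork, tuple[int, int]]:
    """Rasterize vessel centre-lines onto the lattice.

    The polyline carrying the entry point becomes the reference vessel
    (fixed 80 um diameter); all other segments start at 30 um.  Parallel
    duplicate vessels are kept as drawn (merging venule/arteriole pairs is
    a modelling choice left to whoever traces the polylines).
    """
    n = params.grid_n
    chains = [_rasterize_polyline(p, n) for p in polylines]
    entry = (float(entry_point[0]), float(entry_point[1]))
    best, best_d = None, math.inf
    for k, chain in enumerate(chains):
        for node in chain:
            d = math.hypot(node[0] - entry[0], node[1] - entry[1])
            if d < best_d:
                best, best_d = (k, node), d
    if best is None or best_d > 1.5:
        raise ValueError(f"entry point {entry_point} does not lie on any polyline "
                         f"(nearest rasterized node is {best_d:.2f} elements away)")
    ref_idx = entry_polyline if entry_polyline is not None else best[0]
    entry_node = best[1]

    net = VesselNetwork()
    for k, chain in enumerate(chains):
        is_ref = k == ref_idx
        radius = params.R_ref if is_ref else params.R_init
        for a, b in zip(chain[:-1], chain[1:]):
            seg = net.add_segment(a, b, radius, kind="preexisting", perfused=True)
            if is_ref:
                seg.fixed = True
                seg.radius = params.R_ref
    return net, entry_node


def build_initial_vasculature(network: VesselNetwork, entry_node,
                              params: ModelParams) -> FlowState:
    """Hemodynamic initialization: perfuse at the entry, adapt diameters to
    the steady state.  Deterministic for a given network.

    Segments that end up carrying essentially no flow (dead-end branches
    not connected to a pressure drop) are marked unperfused: they neither
    exchange oxygen nor seed sprouts."""
    flow = adapt_diameters(network, entry_node, params, params.grid_n)
    q_scale = max((abs(flow.flow(s)) for s in network.segments), default=0.0)
    # only strictly flowless segments (pressure-isolated dead ends) are
    # unperfused; a collapsed but still-flowing capillary remains perfused
    for s in network.segments:
        s.perfused = abs(flow.flow(s)) > 1e-9 * q_scale
    return flow


# -- synthetic case generator ---------------------------------------------

def generate_synthetic_case(seed: int, params: ModelParams | None = None,
                            image_size: int = 256,
                            blob_radius_frac: float = 0.15,
                            n_branches: int | None = None) -> SyntheticCase:
    """Emulate one experimental input from a seed (fully reproducible).

    The tumour image is a wobbly blob with three concentric intensity
    zones (dense core, medium annulus, dim rim) under multiplicative
    granular speckle, plus a few scattered faint cells outside the bulk.
    Vessels are one border-to-border main vessel passing near the blob
    (its border end is the entry point) and several branches.
    """
    params = params if params is not None else ModelParams()
    rng = np.random.default_rng(seed)
    n_img = image_size
    n = params.grid_n

    # --- tumour image ---
    cy, cx = (n_img / 2 * (1 + rng.uniform(-0.08, 0.08)) for _ in range(2))
    # substantial case-to-case size heterogeneity, as in real tumour batches
    r0 = blob_radius_frac * n_img * rng.uniform(0.92, 1.08)
    yy, xx = np.mgrid[0:n_img, 0:n_img]
    ang = np.arctan2(yy - cy, xx - cx)
    rad = np.hypot(yy - cy, xx - cx)
    wobble = np.ones_like(ang)
    modes = []
    for kmode in range(2, 6):
        amp, phase = rng.uniform(0.0, 0.06), rng.uniform(0, 2 * np.pi)
        modes.append((kmode, amp, phase))
        wobble += amp * np.cos(kmode * ang + phase)
    rho = rad / (r0 * wobble)
    # zone radii and the sparse-zone cellularity vary between cases, as
    # they do between real grafts; they shape each case's early growth.
    # Drawn from a dedicated stream so the blob/vessel geometry draws are
    # unaffected by these extra parameters.
    rng_density = np.random.default_rng(seed + 9_999_991)
    r_high = rng_density.uniform(0.30, 0.40)
    r_med = rng_density.uniform(0.43, 0.53)
    fill_low = rng_density.uniform(0.12, 0.18)
    img = np.full((n_img, n_img), 15.0)
    img[rho < 1.0] = 85.0
    img[rho < r_med] = 150.0
    img[rho < r_high] = 215.0
    # scattered faint cells outside the bulk (excluded by bulk selection)
    for _ in range(rng.integers(5, 12)):
        sy, sx = rng.integers(0, n_img, size=2)
        if rho[sy, sx] > 1.3:
            img[max(sy - 1, 0):sy + 2, max(sx - 1, 0):sx + 2] = 90.0
    # granular multiplicative speckle (day-3 texture)
    speckle = gaussian_filter(rng.normal(size=(n_img, n_img)), sigma=1.5)
    speckle /= max(np.abs(speckle).max(), 1e-12)
    img *= 1.0 + 0.25 * speckle
    image = np.clip(img, 0, 255).astype(np.uint8)
    thresholds = (50, 117, 182)

    # --- vessel polylines (corner-lattice units, 0..n) ---
    scale = n / n_img
    bc = np.array([cy, cx]) * scale  # blob centre, grid units
    br = r0 * scale
    # main vessel: straight-ish border-to-border line at a controlled
    # distance from the blob centre, with a gentle wiggle
    def _snap_end_to_border(poly: np.ndarray, which: int) -> None:
        """Pin a terminal point onto the nearest domain border (a vessel
        end that left the frame must sit exactly on it to carry the
        boundary pressure)."""
        pt = poly[which].copy()
        dists = np.minimum(pt, n - pt)
        ax = int(np.argmin(dists))
        pt[ax] = 0.0 if pt[ax] < n - pt[ax] else float(n)
        poly[which] = np.clip(pt, 0, n)

    theta = rng.uniform(0, 2 * np.pi)
    direction = np.array([math.cos(theta), math.sin(theta)])
    normal = np.array([-direction[1], direction[0]])
    offset = (br + rng.uniform(0.11, 0.14) * n)
    anchor = bc + offset * normal
    ts = np.linspace(-1.5 * n, 1.5 * n, 401)
    wiggle = 0.02 * n * np.sin(ts / n * 2 * np.pi + rng.uniform(0, 2 * np.pi))
    main = np.stack([anchor + t * direction + w * normal for t, w in zip(ts, wiggle)])
    keep = [(0 <= r <= n) and (0 <= c <= n) for r, c in main]
    main = main[keep]
    _snap_end_to_border(main, 0)
    _snap_end_to_border(main, -1)
    polylines = [main]
    entry_point = tuple(main[0])

    def _clip_to_frame(branch: np.ndarray):
        inside = np.array([(0 <= r <= n) and (0 <= c <= n) for r, c in branch])
        if not inside[0]:
            return None
        cut = len(branch) if inside.all() else int(np.argmin(inside))
        out = branch[:cut]
        if len(out) < 5:
            return None
        if cut < len(inside):  # left the frame: pin the end to the border
            _snap_end_to_border(out, -1)
        return out

    # one guaranteed feeding branch skirting the tumour rim at a controlled
    # distance: leaves the main vessel roughly radially, turns at the point
    # of closest approach and runs tangentially on to the border, so it
    # always carries flow.  The rim distance is the case property that sets
    # how soon angiogenic sprouts can reach the hypoxic tissue.
    start = main[rng.integers(len(main) // 4, 3 * len(main) // 4)]
    u = start - bc
    u = u / max(np.linalg.norm(u), 1e-9)
    ang = rng.uniform(-0.5, 0.5)
    u = np.array([u[0] * math.cos(ang) - u[1] * math.sin(ang),
                  u[0] * math.sin(ang) + u[1] * math.cos(ang)])
    # distance measured from the actual (wobbled) rim at this angle
    theta_u = math.atan2(u[0], u[1])
    rim_local = br * (1.0 + sum(a * math.cos(k * theta_u + ph)
                                for k, a, ph in modes))
    d_star = rim_local + rng.uniform(8.0, 12.0)
    turn = bc + d_star * u
    tangent = np.array([-u[1], u[0]]) * (1.0 if rng.random() < 0.5 else -1.0)
    leg1 = np.stack([start + t * (turn - start)
                     for t in np.linspace(0, 1, 30)])
    leg2 = np.stack([turn + t * tangent for t in np.arange(2.0, 1.6 * n, 2.0)])
    near = _clip_to_frame(np.vstack([leg1, leg2]))
    if near is not None:
        polylines.append(near)

    # further branches add case-to-case variation in vascular supply; they
    # must keep clear of the tumour (only the near branch approaches it)
    k_br = int(n_branches) if n_branches is not None else int(rng.integers(1, 4))
    clearance = 1.25 * br + 6.0
    for _ in range(k_br):
        for _attempt in range(10):
            start = main[rng.integers(len(main) // 5, 4 * len(main) // 5)]
            aim = bc + rng.uniform(1.5, 2.2) * br * np.array(
                [math.cos(a := rng.uniform(0, 2 * np.pi)), math.sin(a)])
            heading = aim - start
            heading = heading / max(np.linalg.norm(heading), 1e-9)
            length = rng.uniform(0.8, 1.6) * n
            ts_b = np.arange(0.0, length, 2.0)
            curve = 0.03 * n * np.sin(ts_b / max(length, 1) * np.pi * rng.uniform(0.5, 1.5))
            nrm = np.array([-heading[1], heading[0]])
            branch = _clip_to_frame(np.stack(
                [start + t * heading + w * nrm for t, w in zip(ts_b, curve)]))
            if branch is None:
                continue
            if np.min(np.linalg.norm(branch - bc, axis=1)) < clearance:
                continue
            polylines.append(branch)
            break

    return SyntheticCase(seed=seed, image=image, thresholds=thresholds,
                         polylines=polylines, entry_point=entry_point,
                         entry_polyline=0,
                         fill_probs=(fill_low, 0.5, 0.85))


def load_case(directory: str | Path) -> SyntheticCase:
    """Read a case saved by :meth:`SyntheticCase.save` (tumour image as
    PNG, vessel polylines as CSV, thresholds and entry point as text)."""
    directory = Path(directory)
    image = iio.imread(directory / "tumour.png")
    polylines: dict[int, list] = {}
    for line in (directory / "vessels.csv").read_text().splitlines()[1:]:
        k, _idx, r, c = line.split(",")
        polylines.setdefault(int(k), []).append((float(r), float(c)))
    meta = dict(line.split(maxsplit=1)
                for line in (directory / "case.txt").read_text().splitlines())
    thresholds = tuple(int(v) for v in meta["thresholds"].split())
    er, ec, epoly = meta["entry"].split()
    fills = (tuple(float(v) for v in meta["fills"].split())
             if "fills" in meta else None)
    return SyntheticCase(seed=int(meta["seed"]), image=np.asarray(image),
                         thresholds=thresholds,
                         polylines=[np.array(polylines[k]) for k in sorted(polylines)],
                         entry_point=(float(er), float(ec)),
                         entry_polyline=int(epoly), fill_probs=fills)


def save_initial_state(grid: SimulationGrid, directory: str | Path) -> None:
    """Write the built initial state: occupancy/vessel PNG overlays plus a
    machine-readable per-cell CSV a driver run can be compared against."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / "occupancy.png",
                ((grid.state > 0) * 255).astype(np.uint8))
    if grid.network is not None:
        iio.imwrite(directory / "vessel_overlay.png",
                    grid.network.overlay_mask(grid.n))
        (directory / "vessels.txt").write_text(grid.network.to_edge_list())
    rows = ["i,j,state,mu_h,phase,phase_clock_h"]
    for i, j in np.argwhere(grid.state > 0):
        rows.append(f"{i},{j},{int(grid.state[i, j])},{grid.mu[i, j]:.6g},"
                    f"{int(grid.phase[i, j])},{grid.phase_clock[i, j]:.6g}")
    (directory / "cells.csv").write_text("\n".join(rows) + "\n")


# -- full pipeline ---------------------------------------------------------

def build_case(case: SyntheticCase, params: ModelParams,
               rng: np.random.Generator) -> tuple[SimulationGrid, tuple[int, int]]:
    """Image + polylines -> ready-to-run simulation grid.

    Places the initial proliferative cells, rasterizes and hemodynamically
    adapts the vasculature, attaches it to the grid and equilibrates the
    initial oxygen field."""
    grid = SimulationGrid(params)
    fills = case.fill_probs if case.fill_probs is not None else DEFAULT_FILL_PROBS
    density = tumour_from_image(case.image, case.thresholds, params, rng,
                                fill_probs=fills)
    n_cells = place_cells(grid, density, rng)
    network, entry_node = vessels_from_polylines(
        case.polylines, case.entry_point, params, case.entry_polyline)
    build_initial_vasculature(network, entry_node, params)
    grid.network = network
    network.sync_grid(grid)
    grid.O[:, :] = steady_oxygen(grid)
    logger.info("case seed=%s: %d initial cells, %d vessel segments",
                case.seed, n_cells, len(network))
    return grid, entry_node
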