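# Model and methods

`angioca` simulates the growth of a small vascularized tumour in a thin
tissue sheet (the setting is a tumour graft in a mouse ear pinna imaged
through the skin) as a hybrid, multiscale system: discrete cells on a
lattice, continuous reaction-diffusion fields, and a discrete vessel
network embedded in an implicit capillary bed.

## Lattice and scales

The domain is a square grid of `grid_n x grid_n` elements (default
200 x 200) with spacing `dx = 0.02` mm, one tumour-cell diameter, giving a
4 x 4 mm field of view.  Each element holds at most one cell.  Vessels
live on the *corner lattice*: a segment occupies either an element edge
(length `dx`, shared by the two flanking elements, so each counts half)
or an element diagonal (length `dx*sqrt(2)`, counted fully).  The
per-element vessel weight

    W_ij = sum_segments (L_edge/2 or L_diag) + E_ij

couples the network and the capillary density `E` to the fields.  The
automaton step is 1 h; 28 simulated days is the standard run.

## Cells

States: proliferative (P), quiescent (Q), apoptotic (A), necrotic (N).
P is the default under normal oxygen.  Oxygen arrest is G1-gated: a P
cell with local oxygen below `O_quiescence` arrests only while in G1;
quiescent cells revert to P as soon as oxygen is back above the
threshold; any living cell below `O_necrosis` dies.  Dead states are
absorbing; dead cells stop consuming oxygen and keep occupying their
element for `lysis_delay` (48 h) before the element is freed.

The cycle is G1 -> S -> G2 -> M with S = 8 h, G2 = 4 h, M = 1 h fixed and
G1 carrying the rest of the cycle duration `mu`.  The initial duration is
`mu_0 = 34` h, a mid-range doubling time for U87-MG glioma cells.
Daughters draw their cycle from a Gaussian centred on the mother's `mu`
(SD `sigma_cycle = 0.2` h, truncated at 3 SD); only the G1 share absorbs
the change.  Initial cells are placed desynchronized (cycle position
uniform over the cycle).

Division requires room: a free Moore neighbour, or failing that, one
neighbour cell that can itself be pushed into a free element of its own
Moore neighbourhood (a single-row push, never a longer chain).  A
division-ready cell that finds no room retries every step for
`division_retry_window` (24 h) and then enters apoptosis.  Under hourly
scheduling a completed mitosis may overshoot the hour boundary; the
overshoot is credited to the daughters' G1 clocks so the scheme does not
systematically stretch the effective cycle.

## Fields

Four diffusive species on the lattice, all concentrations normalized:

    dV/dt = D_V lap V + alpha_V [Q] - nu_V V - lambda_V W min(V, V_max)
    dO/dt = D_O lap O + gamma_v W (O_v - O) - k O
    dp/dt = D_p lap p + alpha_p [P] - nu_p p
    dm/dt = D_m lap m + alpha_m [n] - nu_m m

with no-flux boundaries (the surrounding tissue continues beyond the
frame; there is no flux data to impose anything else).  `[Q]`, `[P]`,
`[n]` indicate quiescent cells, proliferative cells and active sprout
edges.  Oxygen uptake `k` is `k_P = 2 k_0` under P cells, `k_Q = k_0`
under Q cells, zero under dead cells and `k_0` in normal tissue.

Rate constants follow the published parameter set for this model family
(D_V = 0.104, D_O = 2.41e-3, D_p = 1.73e-3, D_m = 10.4e-3 mm^2/h;
alpha_V = 0.0145, alpha_p = 3600, alpha_m = 130; nu_V = 0.65, nu_p = 0.21,
nu_m = 1.30; lambda_V = 1, V_max = 0.06; gamma_v = 4.8 x R/R_min;
k_0 = 2.4).  Where the printed units of alpha_V and the k's mix seconds
with the hourly rates of their siblings, they are read as h^-1-equivalent
rates acting on normalized concentrations; for the quasi-steady oxygen
field only the ratios D_O/k and gamma/k enter, so this choice does not
affect the oxygen solution.

**Oxygen normalization.** `O = 1` is defined as the physiological steady
state under an intact capillary bed: with `E_0 = 1` this fixes the
intravascular level `O_v = 1 + k_0/(gamma E_0) = 1.5`.

**Numerics.** V, p and m are integrated by forward Euler with the 5-point
flux-form Laplacian, each species sub-stepping at 0.9x its own explicit
stability limit `dx^2/(4D)` (compiled inner loops; the kernels are tested
to match the plain single-step reference path to machine precision).
Sources are frozen over each 1 h automaton step.  The flux form conserves
mass exactly under pure diffusion (verified to 1e-12 relative over 1e4
steps).  Oxygen equilibrates on seconds, far below the hourly step, so
the default mode solves its linear steady state directly once per step
(conjugate gradients, diagonal preconditioner, warm-started from the
previous step, relative tolerance 1e-8, direct sparse fallback).  An
explicit oxygen mode is kept for validation; its stability limit includes
the absorption term (`8 D_O/dx^2 + max(G + k)`), and the two modes agree
to a fraction of a percent.  Negative values produced by reaction terms
are clamped to zero.

## Vasculature and angiogenesis

The implicit capillary field `E = E_0` supplies the baseline oxygen
exchange `gamma E`.  Tumour proteases destroy it locally and
irreversibly (`E -> 0` wherever `p > p_degrade`).  Discrete vessels add
permeability-scaled exchange `gamma (R/R_min) L` per segment; matrix
integrity decays at `matrix_rate * m` per hour under sprout proteases and
biases tip migration.

Sprouting follows the standard lattice scheme: initiation on perfused
vessel nodes where `V > V_sprout`, stochastic with probability increasing
in V, with a minimum spacing (4 elements) between active origins; tips
step at most once per hour (probability `tip_move_prob`) onto edges or
diagonals, weighted by `exp(chi dV)` toward higher VEGF with a preference
for degraded matrix, never through necrotic debris; branching with
probability 0.05 per step where `V > 2 V_sprout`; anastomosis on contact
with any other vessel.  A tip must take at least `sprout_min_steps` (4)
steps before it may rejoin the network, which suppresses degenerate
immediate loop-backs.  Because every sprout originates on the perfused
network, a closed loop is a flow path: on anastomosis the sprout's
segments -- and those of a contacted unperfused sprout -- are marked
perfused.  Only perfused neovessels exchange oxygen; all segments count
in the VEGF-consumption weight (selectable).

Perfused neovessels carry a permeability multiplier `neo_perm_factor`
(default 30).  At face value a single capillary-calibre segment
(`R_neo = 6` um) adds only ~0.1 /h of exchange, far too little to
re-oxygenate an element against quiescent uptake of 2.4 /h; immature
angiogenic vessels are however strongly hyperpermeable (the same leakage
that lets fluorescent dextran stain the tissue around a sprouting front),
and the multiplier represents that.  It is a calibration constant, like
the sprouting probabilities, and all are exposed in the configuration.

## Hemodynamic initialization

The segmented vessel polylines are rasterized onto the corner lattice.
The reference vessel (the one carrying the flow entry point) is fixed at
80 um diameter; all others start at 30 um.  Poiseuille conductances
`pi R^4 / (8 eta L)` with constant viscosity (no Fahraeus-Lindqvist
correction) define a linear Kirchhoff system; 13 kPa is imposed at the
entry node and 2 kPa at every degree-1 vessel endpoint on the domain
border (mid-vessel nodes grazing the border carry no condition).
Diameters then adapt iteratively: each non-reference segment updates its
log-radius by a wall-shear stimulus `log10(tau/tau_ref)`, a metabolic
(low-flow) stimulus `k_m log10(1 + Q_ref/Q)` capped so that zero-flow
dead ends shrink rather than blow up, and a constant shrinking tendency,
clamped to [3, 150] um, until the largest relative change falls below
1e-4.  The procedure is deterministic and its fixed point is the initial
vascular condition; flow is not re-solved during growth.  Flow units are
arbitrary but internally consistent (only the pressures are physical),
so `tau_ref` and `Q_ref` are scaled to the fixture networks' typical
shear (~10) and flow (~2e4).

## Initialization from images and the synthetic generator

A fluorescence-like grayscale image is thresholded at three ascending
levels into nested low/medium/high-density regions; each region is
resized (area-averaged) to the grid, realized as Bernoulli occupancy at
per-zone fill probabilities via grey-level Gaussian noise +
re-thresholding, and only the largest connected component (after a
2-element dilation) is kept — scattered cells outside the bulk are
dropped.  Every occupied element receives a P cell.

No real images ship with the package, so a seeded generator emulates the
experimental inputs: a wobbly-boundary blob with a dense core (fill
0.85), a medium annulus (0.5) and a broad sparse outer zone (per-case
fill 0.12-0.18), multiplicative speckle for the granular day-3 texture, a
few faint scattered specks outside the bulk, and 3-6 vessel polylines.
The vasculature comprises one border-to-border main vessel passing well
clear of the blob (its border end is the pressure entry), exactly one
feeding branch that leaves the main vessel, turns at 8-12 elements from
the local (wobbled) tumour rim and runs tangentially to the border so it
always carries flow — the rim distance of this branch is the case
property that controls when angiogenic sprouts can reach the hypoxic
tissue — and 1-3 further branches kept clear of the tumour.  Blob radius
(+-8%), density-zone radii and sparse fill vary between seeds, mirroring
a real tumour batch.

## Calibration

The thresholds the underlying model leaves free (`O_quiescence`,
`O_necrosis`, `p_degrade`, `V_sprout`, the sprouting constants and
`neo_perm_factor`) were calibrated once, against the qualitative and
quantitative timeline this model family reports for U87 ear-pinna
grafts: all cells proliferative at day 0, roughly 30% still proliferative
at day 3 with the remainder quiescent, a minimum proliferative fraction
near 10% around day 13, and renewed growth visible from day 17 driven by
angiogenesis.  The resulting defaults:

- `O_quiescence = 0.5` — arrest at half the physiological level.
- `O_necrosis = 0.002` — necrosis only under essentially complete
  anoxia.  With a higher threshold virtually the whole graft necroses
  within a day, which contradicts the reported dynamics in which the
  non-proliferative population is quiescent, not dead.
- `p_degrade = 2900` — just above the protease level of the sparse zone
  at its initial density, so the sparse tumour regions survive the first
  days and then tip into quiescence one locale at a time as gap-filling
  proliferation pushes their local protease production past the
  threshold; at the steady protease level of a compacted proliferating
  front, so no self-sustaining rim persists.
- `mu_0 = 34 h` — a mid-range doubling time for this glioma line; a
  shorter cycle makes both the initial arrest wave and the overall growth
  unrealistically fast.
- `V_sprout = 2.4e-3` with `sprout_prob_scale = 0.08`,
  `tip_move_prob = 0.5`, `neo_perm_factor = 30` — VEGF at the feeding
  branch crosses the threshold late in the second week, so oxygen
  delivery by perfused neovessels becomes population-relevant around
  days 13-17.

The dynamics this produces: the dense core and medium annulus quiesce
within ~1 day (their protease output destroys the capillary bed under
them almost immediately); the sparse zone proliferates and densifies —
the tumour gets more compact rather than larger, as the real grafts do —
while successive locales cross the degradation threshold and arrest; the
proliferative fraction declines smoothly until angiogenic sprouts,
recruited by the VEGF of the growing quiescent mass, anastomose and
re-oxygenate tissue, reverting quiescent cells near neovessels.

## Batch analyses

Growth curves (daily living-cell count, equivalently effective area) of a
batch are normalized each by its trapezoid integral over days 0-28; the
day at which the across-case SD of the normalized curves is minimal marks
the angiogenic bottleneck — slower-growing tumours carry a larger hypoxic
fraction, mount a stronger angiogenic response and catch up, so the
normalized curves cross during the avascular-to-vascular handover.  The
apparent area closes the living-cell mask with a disk of radius 2
elements, fills holes and measures the largest component — the area an
edge-delineating image measurement would report.  Texture histograms
min-max normalize intensities over tumour pixels only and use 64 uniform
bins with unit-integral normalization; simulated intensity images are
rendered from local cell density in a 3x3 window with P cells weighted
brighter.  The proliferative-fraction series reports, per day, the mean
across cases of n_P/(n_P+n_Q) and the SD of that mean.

## Problem sizes

The standard study — and what `scripts/acceptance.py` and the acceptance
tests re-run — is 7 synthetic cases (seeds 1-7) on the full 200 x 200
grid for 28 simulated days, about 70-80 seconds per case on one CPU.  Unit tests use
30-120 element grids and runs of 0-4 simulated days.

## Limitations

- Strictly 2D; one cell per element, no compaction, no pressure effects
  on proliferation and no vaso-occlusion.
- No vessel regression or pruning; total neovessel length is
  non-decreasing.
- Flow and diameter adaptation act only at initialization, not during
  growth.
- Constant blood viscosity; flow units arbitrary.
- The synthetic generator emulates the geometry and texture of
  fluorescence inputs, not their optics (no depth integration, no
  photobleaching); absolute areas and fold changes therefore track the
  model's 2D dynamics, which grow faster than the 3D-projected
  experimental areas, and passing batch tests demonstrates internal
  consistency of the model under these synthetic conditions rather than
  agreement with any particular animal.
- The seven synthetic cases share one geometry family and end up with
  nearly identical normalized growth-curve shapes (effective-area fold
  ~6-7 for every case).  The across-case SD of the integral-normalized
  curves is therefore noise-dominated and its argmin is not a robust
  bottleneck marker on this batch: an interior dip does appear around
  days 16-18, but the global minimum typically falls at the start of the
  window.  Detecting the bottleneck day reliably requires the inter-case
  diversity of growth shapes (intrinsic growth rates, vascular
  configurations) that image-derived real cases carry; the detector
  itself is exercised against constructed curve families in the tests.
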