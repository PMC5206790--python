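"""Quantitative readouts: areas, normalized growth curves, texture
histograms, proliferative-fraction dynamics and bottleneck detection.

Two area notions are tracked.  The *effective* area is the area actually
occupied by living cells (cell count x dx^2, since each cell fills one
element).  The *apparent* area delineates the tumour edge the way an
image-based measurement would: the living-cell mask is morphologically
closed (disk of radius 2 elements), holes are filled, and the largest
component is measured, so internal gaps count toward the area.

Growth curves of a batch of cases are made comparable by dividing each by
its trapezoid integral over the observation window; the day at which the
across-case standard deviation of the normalized curves is minimal marks
the angiogenic bottleneck -- the convergence point between avascular and
vascular growth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_closing, binary_fill_holes, uniform_filter
from skimage.measure import label
from skimage.morphology import disk

from .core import P, Q

logger = logging.getLogger("angioca")


# -- areas -----------------------------------------------------------------

def effective_area(mask: np.ndarray, dx: float) -> float:
    """Area occupied by cells: element count x dx^2 (mm^2)."""
    return float(np.sum(mask)) * dx * dx


def apparent_area(mask: np.ndarray, dx: float, closing_radius: int = 2) -> float:
    """Area enclosed by the delineated tumour edge (mm^2).

    Morphological closing + hole filling on the largest connected
    component; empty masks return 0 with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        logger.warning("apparent_area: empty mask")
        return 0.0
    closed = binary_closing(mask, structure=disk(closing_radius))
    filled = binary_fill_holes(closed)
    comp = label(filled, connectivity=2)
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    largest = comp == sizes.argmax()
    return float(np.sum(largest)) * dx * dx


# -- normalized growth curves and the bottleneck ---------------------------

@dataclass
class CurveSet:
    """k curves sampled on a common day grid."""

    days: np.ndarray              # shape (T,)
    values: np.ndarray            # shape (k, T)

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.days.size:
            raise ValueError("curves and day grid have mismatched lengths")


def normalize_curves(curves: CurveSet) -> CurveSet:
    """Divide each curve by its trapezoid integral over the day grid, so
    every normalized curve integrates to 1."""
    integrals = np.trapezoid(curves.values, curves.days, axis=1)
    if np.any(integrals <= 0):
        raise ValueError("cannot normalize a curve with non-positive integral")
    return CurveSet(curves.days, curves.values / integrals[:, None])


def bottleneck_day(curves: CurveSet) -> tuple[float, np.ndarray]:
    """Day minimizing the across-curve SD of the normalized curves.

    Returns ``(day, sd_profile)``; ties break toward the earliest day.
    Input curves are normalized internally, so the result is invariant
    under per-curve rescaling.
    """
    if curves.values.shape[0] < 2:
        raise ValueError("bottleneck detection needs at least 2 curves")
    norm = normalize_curves(curves)
    sd = norm.values.std(axis=0, ddof=1)
    return float(curves.days[int(np.argmin(sd))]), sd


# -- texture ---------------------------------------------------------------

def render_intensity(state: np.ndarray, window: int = 3) -> np.ndarray:
    """Fluorescence-style intensity image of the automaton state.

    Local cell density in a ``window`` x ``window`` mean filter, with
    proliferative cells weighted brighter than quiescent ones (dead cells
    dimmer still), mirroring how dense proliferating regions fluoresce.
    """
    weights = np.zeros_like(state, dtype=float)
    weights[state == P] = 1.0
    weights[state == Q] = 0.6
    weights[(state != 0) & (state != P) & (state != Q)] = 0.25
    return uniform_filter(weights, size=window, mode="constant")


def intensity_histogram(image: np.ndarray, mask: np.ndarray,
                        bins: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of min-max-normalized intensities over tumour pixels only,
    normalized to unit integral.  Returns ``(bin_centres, density)``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("intensity_histogram: empty tumour mask")
    vals = np.asarray(image, dtype=float)[mask]
    lo, hi = vals.min(), vals.max()
    if hi - lo < 1e-300:
        logger.warning("intensity_histogram: constant image; degenerate "
                       "single-bin histogram")
        vals = np.zeros_like(vals)
    else:
        vals = (vals - lo) / (hi - lo)
    density, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0), density=True)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, density


# -- population dynamics ---------------------------------------------------

def pq_fraction_series(records: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-day proliferative fraction n_P / (n_P + n_Q) across cases.

    Returns a frame with columns day, mean, sd (SD of the mean across
    cases), n_cases.  Days where a case has no living cells are treated as
    missing for that case.
    """
    if not records:
        raise ValueError("need at least one growth record")
    per_case = []
    for rec in records:
        alive = rec["n_P"] + rec["n_Q"]
        frac = np.where(alive > 0, rec["n_P"] / alive.replace(0, np.nan), np.nan)
        per_case.append(pd.Series(frac, index=rec["day"].values))
    table = pd.concat(per_case, axis=1)
    mean = table.mean(axis=1, skipna=True)
    k = table.notna().sum(axis=1)
    sd_mean = table.std(axis=1, ddof=1) / np.sqrt(k.clip(lower=1))
    return pd.DataFrame({"day": mean.index, "mean": mean.values,
                         "sd": sd_mean.values, "n_cases": k.values})


def growth_fold_change(record: pd.DataFrame,
                       column: str = "apparent_area_mm2") -> float:
    """Day-last / day-0 ratio of the apparent area of one record."""
    first = record.iloc[0][column]
    if first <= 0:
        raise ValueError("zero initial area; fold change undefined")
    return float(record.iloc[-1][column] / first)


def batch_fold_change(records: list[pd.DataFrame],
                      column: str = "apparent_area_mm2") -> tuple[float, float]:
    """Mean and SD of the fold change across a batch of records."""
    folds = np.array([growth_fold_change(r, column) for r in records])
    return float(folds.mean()), float(folds.std(ddof=1)) if len(folds) > 1 else 0.0


def growth_curves(records: list[pd.DataFrame],
                  column: str = "effective_area_mm2") -> CurveSet:
    """Stack per-case daily curves (by default the effective area, i.e. the
    living-cell count up to the dx^2 factor) into a CurveSet."""
    days = np.asarray(records[0]["day"].values, dtype=float)
    for rec in records[1:]:
        if not np.array_equal(rec["day"].values, days):
            raise ValueError("records are not on a common day grid")
    values = np.stack([rec[column].values for rec in records])
    return CurveSet(days, values)
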