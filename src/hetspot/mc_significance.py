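"""Monte Carlo significance of the intensity surface.

Registry cases are known only at village resolution, so two placement
processes drive the inference:

* **Restricted, controlled (RCMC)** — the *observed* cases of each village
  are scattered ("deconstructed") over that village's own cells with
  probability proportional to within-village expected-case mass; village
  counts are preserved exactly.
* **Unrestricted, controlled (UCMC)** — *null* case sets of the same county
  total are scattered over all county cells proportional to expected mass,
  ignoring village boundaries.  The null hypothesis is therefore "cases
  follow the demographic risk surface exactly".

Each deconstruction realization yields an intensity surface (hetkde) and a
cellwise Monte Carlo p-value p = (#{null ≥ actual} + 1)/(k + 1) against the
shared null ensemble.  Repeating the deconstruction r times propagates the
address uncertainty into a mean and standard deviation of p per cell; a
cell is a significant hotspot when mean_p + 2·std_p < α.  Running the rule
across several bandwidth settings and counting flags per cell gives the
consensus map of "certain" hotspots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Surface
from .hetkde import KdeSpec, intensity_from_mass, smooth_mass_surface
from .spatial_prep import VillagePartition

__all__ = [
    "McSpec",
    "SignificanceGrids",
    "deconstruct_restricted",
    "simulate_null_unrestricted",
    "mc_pvalue",
    "run_mc",
    "consensus_overlap",
]


@dataclass(frozen=True)
class McSpec:
    """Simulation sizes and significance threshold.

    ``k_sims`` null simulations bound the attainable p from below at
    1/(k_sims+1); with the default 999 the smallest p is 0.001.
    ``r_realizations`` deconstruction repeats feed mean_p/std_p (≥2 so the
    standard deviation exists).  ``alpha`` is the hotspot threshold; the
    reference analysis uses 0.001 and 0.005.
    """

    k_sims: int = 999
    r_realizations: int = 19
    alpha: float = 0.005
    seed: int | None = None
    cold_spots: bool = False

    def __post_init__(self) -> None:
        if self.k_sims < 1:
            raise ValueError("k_sims must be >= 1")
        if self.r_realizations < 2:
            raise ValueError("r_realizations must be >= 2 (std_p needs >= 2)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if 1.0 / (self.k_sims + 1) > self.alpha:
            warnings.warn(
                f"min attainable p-value 1/(k_sims+1) = {1.0/(self.k_sims+1):.4g} "
                f"exceeds alpha = {self.alpha:g}: no cell can ever be flagged",
                stacklevel=2,
            )


@dataclass
class SignificanceGrids:
    """mean/std p-value grids and the binary hotspot mask."""

    mean_p: Surface
    std_p: Surface
    hotspot: Surface
    cold_mask: Surface | None = field(default=None)


def _village_cell_probs(partition: VillagePartition, expected: Surface):
    """Per-village flat cell indices and expectation-proportional probabilities."""
    owner = partition.cell_index(expected.grid).ravel()
    mass = np.nan_to_num(expected.values, nan=0.0).ravel()
    out = {}
    for pos, vid in enumerate(partition.village_ids):
        idx = np.nonzero(owner == pos)[0]
        m = mass[idx]
        tot = m.sum()
        out[vid] = (idx, m / tot if tot > 0 else None)
    return out


def _points_from_cells(flat_idx: np.ndarray, counts: np.ndarray, grid) -> np.ndarray:
    """Cell-center coordinates repeated by per-cell counts."""
    rows, cols = np.divmod(flat_idx, grid.ncols)
    x = grid.x0 + (cols + 0.5) * grid.cell_size
    y = grid.y0 + (rows + 0.5) * grid.cell_size
    return np.repeat(np.column_stack([x, y]), counts, axis=0)


def deconstruct_restricted(
    case_counts,
    partition: VillagePartition,
    expected: Surface,
    rng: np.random.Generator,
    _probs=None,
) -> np.ndarray:
    """One restricted deconstruction: unit-weight points per village.

    ``case_counts`` maps village_id -> non-negative integer count.  Each
    village's cases land on its own cells, multinomially with probability
    proportional to the expected-case surface; totals per village are exact.
    """
    counts = pd.Series(case_counts)
    if (counts < 0).any() or not np.allclose(counts, counts.round()):
        raise ValueError("case counts must be non-negative integers")
    probs = _probs if _probs is not None else _village_cell_probs(partition, expected)
    pieces = []
    for vid, n in counts.items():
        n = int(n)
        if n == 0:
            continue
        if vid not in probs:
            raise ValueError(f"unknown village {vid!r}")
        idx, p = probs[vid]
        if p is None:
            raise ValueError(
                f"village {vid!r} has {n} cases but zero expected mass in its cells"
            )
        alloc = rng.multinomial(n, p)
        nz = alloc > 0
        pieces.append(_points_from_cells(idx[nz], alloc[nz], expected.grid))
    if not pieces:
        return np.empty((0, 2))
    return np.vstack(pieces)


def simulate_null_unrestricted(
    total_cases: int,
    expected: Surface,
    rng: np.random.Generator,
    _flat=None,
) -> np.ndarray:
    """One unrestricted null: county total scattered over all cells by expected mass."""
    if total_cases < 0:
        raise ValueError("total_cases must be non-negative")
    if total_cases == 0:
        return np.empty((0, 2))
    if _flat is None:
        mass = np.nan_to_num(expected.values, nan=0.0).ravel()
        tot = mass.sum()
        if tot <= 0:
            raise ValueError("expected surface has no positive mass")
        _flat = mass / tot
    alloc = rng.multinomial(int(total_cases), _flat)
    nz = np.nonzero(alloc)[0]
    return _points_from_cells(nz, alloc[nz], expected.grid)


def mc_pvalue(actual: Surface, null_surfaces: list[Surface]) -> Surface:
    """Cellwise p = (#{null ≥ actual} + 1) / (k + 1); ties count as ≥."""
    if len(null_surfaces) < 1:
        raise ValueError("need at least one null surface")
    k = len(null_surfaces)
    kge = np.zeros(actual.grid.shape)
    for s in null_surfaces:
        actual.require_same_grid(s)
        kge += (s.values >= actual.values).astype(float)
    return Surface(actual.grid, (kge + 1.0) / (k + 1.0))


def run_mc(
    case_counts,
    partition: VillagePartition,
    expected: Surface,
    kde_spec: KdeSpec,
    mc_spec: McSpec,
    rng: np.random.Generator | None = None,
) -> SignificanceGrids:
    """Full RCMC/UCMC significance analysis under one bandwidth setting.

    One shared ensemble of ``k_sims`` null intensity surfaces is compared
    against ``r_realizations`` restricted deconstructions of the observed
    counts, so std_p isolates the placement (address) uncertainty of the
    observed cases.  Cells where the intensity ratio is undefined (background
    below floor) carry NaN p-values and are never flagged.
    """
    if rng is None:
        rng = np.random.default_rng(mc_spec.seed)
    counts = pd.Series(case_counts)
    total = int(counts.sum())
    grid = expected.grid

    probs = _village_cell_probs(partition, expected)
    mass = np.nan_to_num(expected.values, nan=0.0).ravel()
    flat = mass / mass.sum()

    # for fixed bandwidths the smoothed background is shared by every draw
    bg_density = (
        smooth_mass_surface(Surface(grid, np.nan_to_num(expected.values, nan=0.0)),
                            kde_spec.h, kde_spec.kernel)
        if kde_spec.bandwidth_mode == "fixed"
        else None
    )

    def intensity(count_raster: np.ndarray) -> Surface:
        if count_raster.sum() == 0:
            return Surface.zeros(grid)
        return intensity_from_mass(
            Surface(grid, count_raster), expected, kde_spec, bg_density
        ).ratio

    def restricted_counts() -> np.ndarray:
        out = np.zeros(grid.n_cells)
        for vid, n in counts.items():
            n = int(n)
            if n == 0:
                continue
            idx, p = probs[vid]
            if p is None:
                raise ValueError(
                    f"village {vid!r} has {n} cases but zero expected mass in its cells"
                )
            out[idx] += rng.multinomial(n, p)
        return out.reshape(grid.shape)

    if (counts < 0).any() or not np.allclose(counts, counts.round()):
        raise ValueError("case counts must be non-negative integers")
    actuals = [intensity(restricted_counts()) for _ in range(mc_spec.r_realizations)]
    kge = np.zeros((mc_spec.r_realizations,) + grid.shape)
    kle = np.zeros_like(kge) if mc_spec.cold_spots else None
    for _ in range(mc_spec.k_sims):
        null_counts = rng.multinomial(total, flat).astype(float).reshape(grid.shape)
        null_ratio = intensity(null_counts)
        for r, act in enumerate(actuals):
            kge[r] += null_ratio.values >= act.values
            if kle is not None:
                kle[r] += null_ratio.values <= act.values

    undef = np.zeros(grid.shape, dtype=bool)
    for act in actuals:
        undef |= np.isnan(act.values)

    pv = (kge + 1.0) / (mc_spec.k_sims + 1.0)
    pv[:, undef] = np.nan
    mean_p = pv.mean(axis=0)
    std_p = pv.std(axis=0, ddof=0)
    hot = (mean_p + 2.0 * std_p < mc_spec.alpha) & ~undef
    grids = SignificanceGrids(
        Surface(grid, mean_p),
        Surface(grid, std_p),
        Surface(grid, hot.astype(float)),
    )
    if kle is not None:
        pl = (kle + 1.0) / (mc_spec.k_sims + 1.0)
        pl[:, undef] = np.nan
        cold = (pl.mean(axis=0) + 2.0 * pl.std(axis=0, ddof=0) < mc_spec.alpha) & ~undef
        grids.cold_mask = Surface(grid, cold.astype(float))
    return grids


def consensus_overlap(masks: list[Surface], quorum: int | None = None) -> Surface:
    """Cellwise count of bandwidth settings flagging the cell.

    With ``quorum`` given, also thresholds the count: cells flagged by at
    least ``quorum`` settings are the "certain" hotspots (returned as a
    second surface attribute would be overkill — threshold the counts).
    """
    if len(masks) < 1:
        raise ValueError("need at least one mask")
    first = masks[0]
    total = np.zeros(first.grid.shape)
    for m in masks:
        first.require_same_grid(m)
        total += np.nan_to_num(m.values, nan=0.0)
    counts = Surface(first.grid, total)
    if quorum is not None:
        return Surface(first.grid, (total >= quorum).astype(float))
    return counts
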