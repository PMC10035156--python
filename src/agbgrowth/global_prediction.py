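"""Aggregation of per-PFT posterior predictions over age-class fraction grids.

A grid cell holds, for each plant functional type, the areal fractions of
forest in 15 ten-year age classes [0,10), [10,20), ..., [130,140), [140,inf),
represented by their midpoints 5, 15, ..., 135, 145 years.  The cell's
current AGB is the fraction-weighted sum of posterior-quantile predictions
at each class midpoint under the cell's climate (quantile-then-aggregate:
the class prediction is a posterior quantile, typically the median, and the
weighted sum is taken afterwards); the saturated AGB applies the same total
forest fraction to the posterior quantile of the truncated asymptote mu.
The accumulation potential is saturated minus current — the headroom left
for biomass growth — and is nonnegative by the Monod bound y <= mu.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .records_io import (PFT, NormalizedClimate, normalize_climate,
                         DataError, ConfigurationError)
from .bayes_fit import PosteriorSample, _draw_curves
from .growth_model import monod_agb

logger = logging.getLogger("agbgrowth")

N_AGE_CLASSES = 15


def class_midpoints() -> np.ndarray:
    """Representative ages of the 15 age classes: 5, 15, ..., 135, 145 yr."""
    return np.arange(5.0, 150.0, 10.0)


@dataclass
class GridCell:
    """One 0.5-degree cell: climate plus per-PFT age-class areal fractions."""

    cell_id: str
    lat: float
    lon: float
    map_mm: float
    mat_c: float
    fractions: dict[PFT, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = 0.0
        for pft, w in self.fractions.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (N_AGE_CLASSES,):
                raise ValueError(f"{pft.value}: expected {N_AGE_CLASSES} "
                                 f"age-class fractions, got {w.shape}")
            if np.any(w < 0):
                raise ValueError("areal fractions must be >= 0")
            self.fractions[pft] = w
            total += float(w.sum())
        if total > 1.0 + 1e-9:
            raise ValueError(f"cell {self.cell_id}: total forest fraction "
                             f"{total:.4f} exceeds 1")

    @property
    def climate(self) -> NormalizedClimate:
        return normalize_climate(self.map_mm, self.mat_c)

    def forest_fraction(self, pft: PFT) -> float:
        w = self.fractions.get(pft)
        return 0.0 if w is None else float(w.sum())


@dataclass
class AgeClassGrid:
    cells: list[GridCell]

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)


@dataclass
class CellPrediction:
    """Per-PFT and total current/saturated AGB and accumulation potential
    (Mg ha^-1) at the posterior median, with quartile variants."""

    cell_id: str
    current: dict[PFT, float]
    saturated: dict[PFT, float]
    potential: dict[PFT, float]
    total_current: float
    total_saturated: float
    total_potential: float
    quartiles: dict[str, dict[PFT, float]] = field(default_factory=dict)


def _require_posteriors(posteriors: Mapping[PFT, PosteriorSample],
                        cell: GridCell) -> None:
    for pft in cell.fractions:
        if cell.forest_fraction(pft) > 0 and pft not in posteriors:
            raise ConfigurationError(
                f"cell {cell.cell_id}: no posterior for {pft.value}")


def _class_predictions(sample: PosteriorSample, z: NormalizedClimate,
                       quantile: float) -> np.ndarray:
    """Posterior-quantile AGB at each of the 15 class midpoints."""
    mu, r = _draw_curves(sample.flat(), 0.0, z)
    ages = class_midpoints()
    y = monod_agb(mu[:, None], r[:, None], ages[None, :])    # (draws, 15)
    return np.quantile(y, quantile, axis=0)


def cell_current_agb(posteriors: Mapping[PFT, PosteriorSample],
                     cell: GridCell, quantile: float = 0.5
                     ) -> tuple[dict[PFT, float], float]:
    """Fraction-weighted current AGB per PFT and the all-PFT total."""
    _require_posteriors(posteriors, cell)
    z = cell.climate
    per_pft: dict[PFT, float] = {}
    for pft, w in cell.fractions.items():
        if w.sum() == 0.0:
            per_pft[pft] = 0.0
            continue
        yq = _class_predictions(posteriors[pft], z, quantile)
        per_pft[pft] = float(np.dot(w, yq))
    return per_pft, float(sum(per_pft.values()))


def cell_saturated_agb(posteriors: Mapping[PFT, PosteriorSample],
                       cell: GridCell, quantile: float = 0.5
                       ) -> tuple[dict[PFT, float], float]:
    """Total-forest-fraction-scaled posterior quantile of the truncated
    saturation level mu, per PFT and total (same areal basis as current)."""
    _require_posteriors(posteriors, cell)
    z = cell.climate
    per_pft: dict[PFT, float] = {}
    for pft, w in cell.fractions.items():
        wsum = float(w.sum())
        if wsum == 0.0:
            per_pft[pft] = 0.0
            continue
        mu, _ = _draw_curves(posteriors[pft].flat(), 0.0, z)
        per_pft[pft] = wsum * float(np.quantile(mu, quantile))
    return per_pft, float(sum(per_pft.values()))


def cell_potential(posteriors: Mapping[PFT, PosteriorSample],
                   cell: GridCell) -> CellPrediction:
    """Accumulation potential (saturated - current) at the median, with
    lower/upper-quartile variants for the uncertainty maps."""
    cur, tot_cur = cell_current_agb(posteriors, cell, 0.5)
    sat, tot_sat = cell_saturated_agb(posteriors, cell, 0.5)
    pot = {pft: sat[pft] - cur[pft] for pft in cur}
    quartiles: dict[str, dict[PFT, float]] = {}
    for label, q in (("q25", 0.25), ("q75", 0.75)):
        cq, _ = cell_current_agb(posteriors, cell, q)
        sq, _ = cell_saturated_agb(posteriors, cell, q)
        quartiles[f"current_{label}"] = cq
        quartiles[f"saturated_{label}"] = sq
        quartiles[f"potential_{label}"] = {p: sq[p] - cq[p] for p in cq}
    return CellPrediction(cell_id=cell.cell_id, current=cur, saturated=sat,
                          potential=pot, total_current=tot_cur,
                          total_saturated=tot_sat,
                          total_potential=tot_sat - tot_cur,
                          quartiles=quartiles)


def summarize_potential(grid: AgeClassGrid,
                        posteriors: Mapping[PFT, PosteriorSample],
                        pft: PFT) -> tuple[float, float]:
    """Unweighted mean and SD of per-cell accumulation potential for one PFT
    over the cells where that PFT is present (forest fraction > 0).

    Cells with non-finite climate are skipped with a logged count.  The SD is
    the population SD over qualifying cells (a single cell gives SD 0).
    """
    values = []
    n_skipped = 0
    for cell in grid:
        if not (np.isfinite(cell.map_mm) and np.isfinite(cell.mat_c)):
            n_skipped += 1
            continue
        if cell.forest_fraction(pft) <= 0:
            continue
        pred = cell_potential(posteriors, cell)
        values.append(pred.potential[pft])
    if n_skipped:
        logger.warning("summarize_potential: skipped %d cells without climate",
                       n_skipped)
    if not values:
        raise DataError(f"no cells with {pft.value} present")
    arr = np.asarray(values)
    return float(arr.mean()), float(arr.std())


# ---------------------------------------------------------------------------
# Long-format grid CSV I/O (cell_id, lat, lon, map, mat, pft, age_class_index,
# fraction)


def read_grid(path: str | Path, delimiter: str = ",") -> AgeClassGrid:
    path = Path(path)
    by_cell: dict[str, dict] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        required = {"cell_id", "lat", "lon", "map", "mat", "pft",
                    "age_class_index", "fraction"}
        if reader.fieldnames is None or not required <= set(
                h.strip().lower() for h in reader.fieldnames):
            raise ConfigurationError(f"{path}: grid file must have columns "
                                     f"{sorted(required)}")
        for row in reader:
            row = {k.strip().lower(): v for k, v in row.items()}
            cid = row["cell_id"]
            info = by_cell.setdefault(cid, {
                "lat": float(row["lat"]), "lon": float(row["lon"]),
                "map": float(row["map"]), "mat": float(row["mat"]),
                "fractions": {}})
            pft = PFT.parse(row["pft"])
            w = info["fractions"].setdefault(pft, np.zeros(N_AGE_CLASSES))
            k = int(row["age_class_index"])
            if not 0 <= k < N_AGE_CLASSES:
                raise DataError(f"{path}: age_class_index {k} out of range")
            w[k] = float(row["fraction"])
    cells = [GridCell(cid, info["lat"], info["lon"], info["map"], info["mat"],
                      info["fractions"]) for cid, info in by_cell.items()]
    if not cells:
        raise DataError(f"{path}: no grid cells")
    return AgeClassGrid(cells)


def write_grid(grid: AgeClassGrid, path: str | Path,
               delimiter: str = ",") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["cell_id", "lat", "lon", "map", "mat", "pft",
                         "age_class_index", "fraction"])
        for cell in grid:
            for pft, w in cell.fractions.items():
                for k, frac in enumerate(w):
                    writer.writerow([cell.cell_id, repr(cell.lat),
                                     repr(cell.lon), repr(cell.map_mm),
                                     repr(cell.mat_c), pft.value, k,
                                     repr(float(frac))])


def predict_grid(grid: AgeClassGrid,
                 posteriors: Mapping[PFT, PosteriorSample]
                 ) -> list[CellPrediction]:
    """Cell-by-cell accumulation potential for a whole grid, skipping cells
    without finite climate (logged)."""
    out = []
    n_skipped = 0
    for cell in grid:
        if not (np.isfinite(cell.map_mm) and np.isfinite(cell.mat_c)):
            n_skipped += 1
            continue
        out.append(cell_potential(posteriors, cell))
    if n_skipped:
        logger.warning("predict_grid: skipped %d cells without climate",
                       n_skipped)
    return out
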