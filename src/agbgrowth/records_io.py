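"""Plot-record I/O, climate normalization, and dataset splitting.

Observed forest plots carry above-ground biomass (AGB, Mg ha^-1), stand age
(years), a plant functional type (PFT), and site climate (mean annual
precipitation MAP in mm, mean annual temperature MAT in degrees C).  The
growth model works on climate covariates normalized to roughly unit scale,

    z1 = (MAP - 800) / 500,        z2 = (MAT - 7) / 7,

so that intercepts of the four PFTs are directly comparable at the reference
climate MAP = 800 mm, MAT = 7 C and the slope coefficients live on similar
scales.  Slopes are converted back to per-mm / per-degree units only at the
reporting boundary (see :func:`slope_scale`).
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("agbgrowth")

# Normalization constants: dataset-wide climate means and scale divisors.
MAP_CENTER_MM = 800.0
MAP_SCALE_MM = 500.0
MAT_CENTER_C = 7.0
MAT_SCALE_C = 7.0

REQUIRED_COLUMNS = ("agb", "age", "pft", "map", "mat")
OPTIONAL_COLUMNS = ("lat", "lon")


class PFT(str, enum.Enum):
    """The four leaf-form x leaf-phenology plant functional types."""

    BROADLEAF_DECIDUOUS = "broadleaf_deciduous"
    BROADLEAF_EVERGREEN = "broadleaf_evergreen"
    NEEDLELEAF_DECIDUOUS = "needleleaf_deciduous"
    NEEDLELEAF_EVERGREEN = "needleleaf_evergreen"

    @classmethod
    def parse(cls, label: str) -> "PFT":
        """Normalize a free-form label ('Broadleaf Deciduous', 'BD', ...)."""
        key = label.strip().lower().replace(" ", "_").replace("-", "_")
        aliases = {
            "bd": cls.BROADLEAF_DECIDUOUS,
            "be": cls.BROADLEAF_EVERGREEN,
            "nd": cls.NEEDLELEAF_DECIDUOUS,
            "ne": cls.NEEDLELEAF_EVERGREEN,
        }
        if key in aliases:
            return aliases[key]
        try:
            return cls(key)
        except ValueError:
            raise ValueError(f"unknown plant functional type label: {label!r}") from None


class DataError(ValueError):
    """Raised when input data cannot support the requested operation."""


class ConfigurationError(ValueError):
    """Raised for malformed configuration (e.g. a missing required column)."""


@dataclass(frozen=True)
class NormalizedClimate:
    """Dimensionless climate covariates z1 (MAP) and z2 (MAT)."""

    z1: float
    z2: float


@dataclass(frozen=True)
class AGBRecord:
    """One observed plot.

    Attributes
    ----------
    agb_obs : float
        Observed above-ground biomass, Mg ha^-1 (>= 0; zero is legal for very
        young stands but is flagged at load).
    age : float
        Stand age in years, strictly positive (the observation SD is
        proportional to the mean, which vanishes at age 0).
    pft : PFT
    map_mm, mat_c : float
        Site mean annual precipitation (mm) and temperature (C).
    lat, lon : float or None
        Optional plot coordinates, decimal degrees.
    """

    agb_obs: float
    age: float
    pft: PFT
    map_mm: float
    mat_c: float
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        for name in ("agb_obs", "age", "map_mm", "mat_c"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.agb_obs < 0:
            raise ValueError("agb_obs >= 0 violated")
        if self.age <= 0:
            raise ValueError("age > 0 violated")
        if self.map_mm < 0:
            raise ValueError("map_mm >= 0 violated")
        if self.lat is not None and not -90 <= self.lat <= 90:
            raise ValueError("lat not in [-90, 90]")
        if self.lon is not None and not -180 <= self.lon <= 180:
            raise ValueError("lon not in [-180, 180]")

    @property
    def climate(self) -> NormalizedClimate:
        return normalize_climate(self.map_mm, self.mat_c)


@dataclass
class LoadReport:
    """Counts of rows rejected per validation rule during a read."""

    n_read: int = 0
    n_accepted: int = 0
    rejections: dict[str, int] = field(default_factory=dict)
    n_zero_agb: int = 0

    def reject(self, rule: str) -> None:
        self.rejections[rule] = self.rejections.get(rule, 0) + 1

    @property
    def n_rejected(self) -> int:
        return sum(self.rejections.values())


@dataclass
class Dataset:
    """An ordered collection of plot records, optionally single-PFT."""

    records: list[AGBRecord]
    pft_label: PFT | None = None
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        if self.pft_label is None:
            pfts = {r.pft for r in self.records}
            if len(pfts) == 1:
                self.pft_label = next(iter(pfts))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized view: (agb, age, z1, z2) as float arrays."""
        agb = np.array([r.agb_obs for r in self.records], dtype=float)
        age = np.array([r.age for r in self.records], dtype=float)
        z1 = (np.array([r.map_mm for r in self.records]) - MAP_CENTER_MM) / MAP_SCALE_MM
        z2 = (np.array([r.mat_c for r in self.records]) - MAT_CENTER_C) / MAT_SCALE_C
        return agb, age, z1, z2

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset([self.records[i] for i in indices], pft_label=self.pft_label)

    def split_by_pft(self) -> dict[PFT, "Dataset"]:
        """Disjoint, exhaustive per-PFT subsets (fitting is per PFT)."""
        out: dict[PFT, Dataset] = {}
        for pft in PFT:
            recs = [r for r in self.records if r.pft == pft]
            if recs:
                out[pft] = Dataset(recs, pft_label=pft)
        return out


# ---------------------------------------------------------------------------
# Climate normalization and slope-scale conversion


def normalize_climate(map_mm, mat_c) -> NormalizedClimate:
    """Affine-rescale (MAP, MAT) to the dimensionless covariates (z1, z2)."""
    map_mm = np.asarray(map_mm, dtype=float)
    mat_c = np.asarray(mat_c, dtype=float)
    if not (np.all(np.isfinite(map_mm)) and np.all(np.isfinite(mat_c))):
        raise ValueError("climate inputs must be finite")
    z1 = (map_mm - MAP_CENTER_MM) / MAP_SCALE_MM
    z2 = (mat_c - MAT_CENTER_C) / MAT_SCALE_C
    return NormalizedClimate(float(z1) if z1.ndim == 0 else z1,
                             float(z2) if z2.ndim == 0 else z2)


def denormalize_climate(z: NormalizedClimate) -> tuple[float, float]:
    """Inverse of :func:`normalize_climate`; exact affine round-trip."""
    return (z.z1 * MAP_SCALE_MM + MAP_CENTER_MM, z.z2 * MAT_SCALE_C + MAT_CENTER_C)


_SCALE = {"MAP": MAP_SCALE_MM, "MAT": MAT_SCALE_C}


def slope_scale(beta: float, covariate: str, direction: str) -> float:
    """Convert a slope between normalized-covariate and original units.

    ``to_original`` divides by the normalization scale (500 mm for MAP, 7 C
    for MAT) giving per-mm / per-degree effects; ``to_normalized`` multiplies.
    The two directions are exact inverses.
    """
    cov = covariate.upper()
    if cov not in _SCALE:
        raise ValueError(f"unknown covariate {covariate!r}; expected MAP or MAT")
    if direction == "to_original":
        return beta / _SCALE[cov]
    if direction == "to_normalized":
        return beta * _SCALE[cov]
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# Reading / writing delimited record tables


def _parse_row(row: dict[str, str], report: LoadReport) -> AGBRecord | None:
    try:
        agb = float(row["agb"])
        age = float(row["age"])
        map_mm = float(row["map"])
        mat_c = float(row["mat"])
    except (TypeError, ValueError):
        report.reject("non-numeric cell")
        return None
    lat = lon = None
    for key in OPTIONAL_COLUMNS:
        raw = row.get(key)
        if raw not in (None, ""):
            try:
                val = float(raw)
            except ValueError:
                report.reject("non-numeric cell")
                return None
            if key == "lat":
                lat = val
            else:
                lon = val
    try:
        pft = PFT.parse(row["pft"])
    except ValueError:
        report.reject("unknown pft")
        return None
    if not np.isfinite(agb) or agb < 0:
        report.reject("agb >= 0")
        return None
    if not np.isfinite(age) or age <= 0:
        report.reject("age > 0")
        return None
    try:
        rec = AGBRecord(agb, age, pft, map_mm, mat_c, lat, lon)
    except ValueError as exc:
        report.reject(str(exc))
        return None
    if agb == 0:
        report.n_zero_agb += 1
    return rec


def read_records(path: str | Path, delimiter: str = ",") -> Dataset:
    """Read plot records from a delimited text file with header.

    Required columns (case-insensitive): agb, age, pft, map, mat; optional
    lat, lon.  Invalid rows are dropped and counted per rule in the returned
    dataset's ``load_report``; a missing column raises
    :class:`ConfigurationError`, zero valid rows :class:`DataError`.
    """
    path = Path(path)
    report = LoadReport()
    records: list[AGBRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise DataError(f"{path}: empty file")
        header = [h.strip().lower() for h in reader.fieldnames]
        for col in REQUIRED_COLUMNS:
            if col not in header:
                raise ConfigurationError(f"{path}: missing required column {col!r}")
        for raw in reader:
            report.n_read += 1
            row = {h: v for h, v in zip(header, raw.values())}
            rec = _parse_row(row, report)
            if rec is not None:
                records.append(rec)
    if report.n_rejected:
        logger.warning("%s: rejected %d of %d rows: %s", path,
                       report.n_rejected, report.n_read, report.rejections)
    if not records:
        raise DataError(f"{path}: no valid rows")
    report.n_accepted = len(records)
    return Dataset(records, load_report=report)


def write_records(data: Dataset | Iterable[AGBRecord], path: str | Path,
                  delimiter: str = ",") -> None:
    """Write records as CSV; read_records on the output reproduces the data."""
    path = Path(path)
    records = list(data)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))
        for r in records:
            writer.writerow([repr(r.agb_obs), repr(r.age), r.pft.value,
                             repr(r.map_mm), repr(r.mat_c),
                             "" if r.lat is None else repr(r.lat),
                             "" if r.lon is None else repr(r.lon)])


# ---------------------------------------------------------------------------
# Train/test splitting


def train_test_split(data: Dataset, train_fraction: float = 0.7,
                     seed: int = 0) -> tuple[Dataset, Dataset]:
    """Seeded random partition into disjoint, exhaustive train/test subsets.

    The train size is round-half-up of n * train_fraction.  The same seed
    always yields the same partition.
    """
    n = len(data)
    if n < 2:
        raise DataError("need at least 2 records to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(n * train_fraction + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return data.subset(train_idx.tolist()), data.subset(test_idx.tolist())
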