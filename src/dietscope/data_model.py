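"""Domain types and delimited-text I/O for gut-content and site tables.

The two record types mirror the field data: one :class:`GutRecord` per
dissected fish and one :class:`Site` per sampled population. Pooling
per-fish counts over a population yields a :class:`DietCountMatrix`
(populations x countable categories), from which per-population diet
proportion vectors are derived with detritus and unidentifiable material
excluded (they have no counts).

All tables are plain CSV/TSV with a header; ordering of populations and
categories is lexicographic everywhere so outputs are deterministic and
diffable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .categories import (
    ALL_CATEGORIES,
    COUNTABLE_CATEGORIES,
    DETRITUS,
    UNIDENTIFIABLE,
)
from .errors import (
    EmptyInputError,
    SchemaError,
    UnknownPopulationError,
    ValidationError,
    VocabularyError,
)

logger = logging.getLogger(__name__)

SEXES = ("F", "M")
PREGNANCY_STATES = ("yes", "no", "not-applicable")

#: Non-prey columns of the gut-record schema, in file order.
GUT_RECORD_FIXED_COLUMNS = (
    "fish_id",
    "population_id",
    "sex",
    "sl_mm",
    "gut_length_mm",
    "fullness",
    "pregnant",
)
GUT_RECORD_FLAG_COLUMNS = ("detritus_present", "unidentifiable_present")

SITE_COLUMNS = (
    "population_id",
    "country",
    "latitude",
    "longitude",
    "conductivity",
    "dissolved_oxygen",
    "ph",
    "water_temperature",
    "daily_mean_temp",
    "daily_max_temp",
    "daily_min_temp",
    "precipitation",
)


@dataclass
class GutRecord:
    """Gut contents and morphometrics of a single dissected fish.

    ``standard_length`` (SL) and ``gut_length`` are in mm; ``fullness``
    (GF) is a score in [0, 1]. ``prey_counts`` maps countable category
    codes to non-negative integer counts; detritus and unidentifiable
    material are presence/absence flags only.
    """

    fish_id: str
    population_id: str
    sex: str
    standard_length: float
    gut_length: float | None
    fullness: float | None
    pregnant: str
    prey_counts: dict[str, int]
    detritus_present: bool
    unidentifiable_present: bool

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"fish {self.fish_id!r}: sex must be F or M, got {self.sex!r}")
        if not (self.standard_length > 0 and math.isfinite(self.standard_length)):
            raise ValidationError(
                f"fish {self.fish_id!r}: standard_length must be > 0 mm, got {self.standard_length}"
            )
        if self.gut_length is not None and not (self.gut_length >= 0):
            raise ValidationError(
                f"fish {self.fish_id!r}: gut_length must be >= 0 mm, got {self.gut_length}"
            )
        if self.fullness is not None and not (0.0 <= self.fullness <= 1.0):
            raise ValidationError(
                f"fish {self.fish_id!r}: fullness must be in [0, 1], got {self.fullness}"
            )
        if self.pregnant not in PREGNANCY_STATES:
            raise ValidationError(
                f"fish {self.fish_id!r}: pregnant must be one of {PREGNANCY_STATES}, got {self.pregnant!r}"
            )
        if self.sex == "M" and self.pregnant != "not-applicable":
            raise ValidationError(
                f"fish {self.fish_id!r}: males must have pregnant='not-applicable'"
            )
        for code, count in self.prey_counts.items():
            if code not in COUNTABLE_CATEGORIES:
                raise VocabularyError(
                    f"fish {self.fish_id!r}: {code!r} is not a countable prey category"
                )
            if not (isinstance(count, (int, np.integer)) and count >= 0):
                raise ValidationError(
                    f"fish {self.fish_id!r}: count for {code} must be a non-negative integer, got {count!r}"
                )
        # normalise to the full countable vocabulary
        self.prey_counts = {c: int(self.prey_counts.get(c, 0)) for c in COUNTABLE_CATEGORIES}

    @property
    def total_prey(self) -> int:
        return sum(self.prey_counts.values())

    @property
    def relative_gut_length(self) -> float | None:
        """RGL = gut length / SL; None when gut length was not measured."""
        if self.gut_length is None:
            return None
        return self.gut_length / self.standard_length

    @property
    def is_empty(self) -> bool:
        """Completely empty gut: no counts, no detritus, no unidentifiable."""
        return (
            self.total_prey == 0
            and not self.detritus_present
            and not self.unidentifiable_present
        )

    @property
    def is_detritus_or_unid_only(self) -> bool:
        """No countable prey but detritus and/or unidentifiable material present."""
        return self.total_prey == 0 and (self.detritus_present or self.unidentifiable_present)

    def n_food_categories(self) -> int:
        """Number of distinct food categories in the gut.

        Countable categories with a positive count, plus detritus if
        present. Unidentifiable material is a residual class, not a food
        category, so it does not contribute.
        """
        k = sum(1 for c in COUNTABLE_CATEGORIES if self.prey_counts[c] > 0)
        if self.detritus_present:
            k += 1
        return k

    def contains(self, category: str) -> bool:
        """Presence of a category (countable, DET, or UNID) in this gut."""
        if category == DETRITUS:
            return self.detritus_present
        if category == UNIDENTIFIABLE:
            return self.unidentifiable_present
        if category not in COUNTABLE_CATEGORIES:
            raise VocabularyError(f"unknown category {category!r}")
        return self.prey_counts[category] > 0


@dataclass
class Site:
    """Location and environment/climate of one sampled population."""

    population_id: str
    country: str
    latitude: float
    longitude: float
    conductivity: float       # mS/cm
    dissolved_oxygen: float   # mg/L
    ph: float
    water_temperature: float  # deg C, in situ
    daily_mean_temp: float    # deg C, gridded climate
    daily_max_temp: float
    daily_min_temp: float
    precipitation: float      # mm

    def __post_init__(self) -> None:
        pid = self.population_id
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValidationError(f"site {pid!r}: latitude {self.latitude} outside [-90, 90]")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValidationError(f"site {pid!r}: longitude {self.longitude} outside [-180, 180]")
        if self.conductivity < 0:
            raise ValidationError(f"site {pid!r}: conductivity must be >= 0 mS/cm")
        if self.dissolved_oxygen < 0:
            raise ValidationError(f"site {pid!r}: dissolved oxygen must be >= 0 mg/L")
        if not (0.0 <= self.ph <= 14.0):
            raise ValidationError(f"site {pid!r}: pH {self.ph} outside [0, 14]")
        if self.precipitation < 0:
            raise ValidationError(f"site {pid!r}: precipitation must be >= 0 mm")
        if not (self.daily_min_temp <= self.daily_mean_temp <= self.daily_max_temp):
            raise ValidationError(
                f"site {pid!r}: require daily_min <= daily_mean <= daily_max, got "
                f"{self.daily_min_temp}, {self.daily_mean_temp}, {self.daily_max_temp}"
            )

    ENVIRONMENT_VARIABLES = (
        "latitude",
        "longitude",
        "conductivity",
        "dissolved_oxygen",
        "ph",
        "water_temperature",
        "daily_mean_temp",
        "daily_max_temp",
        "daily_min_temp",
        "precipitation",
    )


@dataclass
class ReadReport:
    """Summary of a table read: rows seen, rows rejected, reasons."""

    n_rows: int
    n_rejected: int
    rejected: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class DietCountMatrix:
    """Pooled prey counts: populations (rows) x countable categories (columns)."""

    counts: pd.DataFrame  # int cells, lexicographic row/column order

    def __post_init__(self) -> None:
        self.counts = self.counts.sort_index().reindex(
            columns=sorted(self.counts.columns)
        )

    @property
    def population_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def categories(self) -> list[str]:
        return list(self.counts.columns)

    def row(self, population_id: str) -> pd.Series:
        if population_id not in self.counts.index:
            raise UnknownPopulationError(
                f"population {population_id!r} not in matrix "
                f"(have: {', '.join(self.population_ids)})"
            )
        return self.counts.loc[population_id]

    def total(self, population_id: str) -> int:
        return int(self.row(population_id).sum())


@dataclass
class DietProportionVector:
    """Per-category diet proportions for one population (detritus excluded).

    ``is_zero`` flags a population with no counted prey at all: the vector
    is all zeros (never NaN) and downstream overlap computations treat it
    as undefined rather than as a real diet.
    """

    population_id: str
    proportions: pd.Series
    is_zero: bool

    @property
    def values(self) -> np.ndarray:
        return self.proportions.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_TRUE_STRINGS = {"true", "1", "yes", "y", "t"}
_FALSE_STRINGS = {"false", "0", "no", "n", "f"}


def _parse_bool(value, column: str, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float)):
        if value in (0, 1):
            return bool(value)
        raise ValidationError(f"row {row}: {column} must be boolean-like, got {value!r}")
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise ValidationError(f"row {row}: {column} must be boolean-like, got {value!r}")


def _sep(dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")


def read_gut_records(
    path: str | Path,
    dialect: Literal["csv", "tsv"] = "csv",
    on_error: Literal["raise", "skip"] = "raise",
) -> tuple[list[GutRecord], ReadReport]:
    """Read a per-fish gut-content table.

    Returns the validated records (row order preserved) together with a
    :class:`ReadReport`. With ``on_error="raise"`` (default) the first
    invalid row aborts the read with a :class:`ValidationError` citing the
    row number; with ``"skip"`` invalid rows are dropped and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype={"fish_id": str, "population_id": str})

    missing = [c for c in GUT_RECORD_FIXED_COLUMNS + GUT_RECORD_FLAG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")

    known = set(GUT_RECORD_FIXED_COLUMNS) | set(GUT_RECORD_FLAG_COLUMNS)
    prey_columns = [c for c in df.columns if c not in known]
    unknown = [c for c in prey_columns if c not in COUNTABLE_CATEGORIES]
    if unknown:
        raise VocabularyError(
            f"{path.name}: column(s) {', '.join(map(repr, unknown))} are not in the "
            f"prey-category vocabulary ({', '.join(ALL_CATEGORIES)})"
        )

    records: list[GutRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            counts = {}
            for c in prey_columns:
                v = rowd[c]
                if pd.isna(v):
                    v = 0
                fv = float(v)
                if fv < 0 or fv != int(fv):
                    raise ValidationError(
                        f"row {i}: count for {c} must be a non-negative integer, got {v!r}"
                    )
                counts[c] = int(fv)
            gl = rowd["gut_length_mm"]
            fu = rowd["fullness"]
            rec = GutRecord(
                fish_id=str(rowd["fish_id"]),
                population_id=str(rowd["population_id"]),
                sex=str(rowd["sex"]).strip(),
                standard_length=float(rowd["sl_mm"]),
                gut_length=None if pd.isna(gl) else float(gl),
                fullness=None if pd.isna(fu) else float(fu),
                pregnant=str(rowd["pregnant"]).strip(),
                prey_counts=counts,
                detritus_present=_parse_bool(rowd["detritus_present"], "detritus_present", i),
                unidentifiable_present=_parse_bool(
                    rowd["unidentifiable_present"], "unidentifiable_present", i
                ),
            )
        except (ValidationError, VocabularyError) as exc:
            if on_error == "raise":
                raise ValidationError(f"row {i}: {exc}") from exc
            rejected.append((i, str(exc)))
            continue
        records.append(rec)

    report = ReadReport(n_rows=len(df), n_rejected=len(rejected), rejected=rejected)
    if rejected:
        logger.warning("%s: rejected %d of %d rows", path.name, len(rejected), len(df))
    return records, report


def gut_records_to_frame(records: Sequence[GutRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "fish_id": r.fish_id,
            "population_id": r.population_id,
            "sex": r.sex,
            "sl_mm": r.standard_length,
            "gut_length_mm": np.nan if r.gut_length is None else r.gut_length,
            "fullness": np.nan if r.fullness is None else r.fullness,
            "pregnant": r.pregnant,
        }
        row.update({c: r.prey_counts[c] for c in COUNTABLE_CATEGORIES})
        row["detritus_present"] = r.detritus_present
        row["unidentifiable_present"] = r.unidentifiable_present
        rows.append(row)
    columns = (
        list(GUT_RECORD_FIXED_COLUMNS) + list(COUNTABLE_CATEGORIES) + list(GUT_RECORD_FLAG_COLUMNS)
    )
    return pd.DataFrame(rows, columns=columns)


def write_gut_records(
    records: Sequence[GutRecord], path: str | Path, dialect: Literal["csv", "tsv"] = "csv"
) -> None:
    gut_records_to_frame(records).to_csv(path, sep=_sep(dialect), index=False)


def read_sites(path: str | Path, dialect: Literal["csv", "tsv"] = "csv") -> list[Site]:
    """Read a per-population site table (one row per population)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype={"population_id": str, "country": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    ids = df["population_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"{path.name}: duplicate population_id(s): {', '.join(dupes)}")
    sites = []
    for i, row in df.iterrows():
        try:
            sites.append(
                Site(
                    population_id=str(row["population_id"]),
                    country=str(row["country"]),
                    **{c: float(row[c]) for c in SITE_COLUMNS[2:]},
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i + 1}: {exc}") from exc
    return sites


def sites_to_frame(sites: Sequence[Site]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(s, c) for c in SITE_COLUMNS} for s in sites])


def write_sites(sites: Sequence[Site], path: str | Path, dialect: Literal["csv", "tsv"] = "csv") -> None:
    sites_to_frame(sites).to_csv(path, sep=_sep(dialect), index=False)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def pool_counts(records: Iterable[GutRecord]) -> DietCountMatrix:
    """Pool per-fish prey counts into a population x category count matrix."""
    records = list(records)
    if not records:
        raise EmptyInputError("pool_counts: no records supplied")
    pops = sorted({r.population_id for r in records})
    data = pd.DataFrame(0, index=pops, columns=list(COUNTABLE_CATEGORIES), dtype=int)
    for r in records:
        for c in COUNTABLE_CATEGORIES:
            data.loc[r.population_id, c] += r.prey_counts[c]
    return DietCountMatrix(counts=data)


def to_proportions(matrix: DietCountMatrix, population_id: str) -> DietProportionVector:
    """Diet proportion vector for one population (detritus excluded).

    Populations with no counted prey yield a flagged all-zero vector,
    never NaN.
    """
    row = matrix.row(population_id)
    total = row.sum()
    if total == 0:
        logger.warning("population %s has no counted prey; proportions undefined", population_id)
        return DietProportionVector(
            population_id=population_id,
            proportions=row.astype(float),
            is_zero=True,
        )
    return DietProportionVector(
        population_id=population_id,
        proportions=row / total,
        is_zero=False,
    )


def records_by_population(records: Iterable[GutRecord]) -> dict[str, list[GutRecord]]:
    out: dict[str, list[GutRecord]] = {}
    for r in records:
        out.setdefault(r.population_id, []).append(r)
    return {k: out[k] for k in sorted(out)}
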