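"""Per-population dietary composition indices.

Implements the standard gut-content descriptors for a population of fish:

* frequency of occurrence, ``FO = 100 * (guts containing the item) / n``
  (detritus included, since presence/absence needs no counts);
* percent by number, ``%N_i = 100 * count_i / sum(counts)`` over the
  countable categories;
* index of relative importance in three variants (Hyslop-style
  ``(%N + %V) * %FO`` with %V = 0 when no volumetric data exist,
  ``%FO * %N``, and ``FO * raw count``) — the variant is always recorded
  in the output because published IRI values are not comparable across
  variants;
* Shannon–Wiener diversity ``H = -sum p_i log p_i`` of the countable diet;
* per-specimen relative niche width, the number of food categories in a
  gut scaled to [0, 1] against the K categories available in the study
  (detritus counts as a category; default K = 11);
* gut-condition percentages (completely empty; detritus/unidentifiable
  only) and mean relative gut length / gut fullness by sex.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .categories import (
    COUNTABLE_CATEGORIES,
    DEFAULT_TOTAL_CATEGORIES,
    DETRITUS,
    UNIDENTIFIABLE,
)
from .data_model import DietCountMatrix, GutRecord, pool_counts, records_by_population
from .errors import EmptyInputError, UnknownPopulationError, ValidationError

logger = logging.getLogger(__name__)

IriVariant = Literal["hyslop_nv", "fo_times_n", "raw_count"]
RnwVariant = Literal["zero_anchored", "proportion"]
FoDenominator = Literal["all_guts", "nonempty_guts"]

_LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0, 2: 2.0, 10: 10.0}


@dataclass
class MetricsConfig:
    """Options for the composition indices; defaults follow common practice."""

    iri_variant: IriVariant = "hyslop_nv"
    shannon_base: float | str = "e"
    rnw_variant: RnwVariant = "zero_anchored"
    fo_denominator: FoDenominator = "all_guts"
    total_categories: int | None = None  # K for RNW; None -> 11 (10 prey + detritus)


@dataclass
class SexSummary:
    n: int
    mean: float | None
    sd: float | None


@dataclass
class PopulationDietSummary:
    """Per-population diet summary (one row of a Table-1-style report)."""

    population_id: str
    n_fish: int
    fo: dict[str, float]                 # percent, includes DET and UNID
    percent_number: dict[str, float]     # percent, countable only
    iri: dict[str, float]                # countable only
    iri_variant: str
    shannon_h: float
    shannon_flagged_zero: bool
    mean_rnw: float | None
    empty_percent: float
    detritus_or_unid_only_percent: float
    rgl_by_sex: dict[str, SexSummary] = field(default_factory=dict)
    gf_by_sex: dict[str, SexSummary] = field(default_factory=dict)
    n_missing_gut_length: int = 0
    n_missing_fullness: int = 0


def frequency_of_occurrence(
    records: Sequence[GutRecord],
    category: str,
    denominator: FoDenominator = "all_guts",
) -> float:
    """Percent of guts in which ``category`` occurs.

    ``denominator="all_guts"`` uses every examined gut (the default);
    ``"nonempty_guts"`` restricts to guts with any content (counts,
    detritus, or unidentifiable material).
    """
    records = list(records)
    if not records:
        raise EmptyInputError("frequency_of_occurrence: no records")
    if denominator == "all_guts":
        denom = len(records)
    elif denominator == "nonempty_guts":
        denom = sum(1 for r in records if not r.is_empty)
        if denom == 0:
            logger.warning("all guts empty; FO undefined, returning 0")
            return 0.0
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    hits = sum(1 for r in records if r.contains(category))
    return 100.0 * hits / denom


def percent_number(matrix: DietCountMatrix, population_id: str) -> dict[str, float]:
    """%N per countable category; flagged all-zero for prey-free populations."""
    row = matrix.row(population_id)
    total = row.sum()
    if total == 0:
        logger.warning("population %s: no counted prey, %%N set to zero", population_id)
        return {c: 0.0 for c in matrix.categories}
    return {c: 100.0 * row[c] / total for c in matrix.categories}


def relative_importance(
    fo: float,
    pn: float,
    pv: float | None = None,
    variant: IriVariant = "hyslop_nv",
    raw_count: int | None = None,
) -> float:
    """Index of relative importance for one category.

    hyslop_nv: ``(%N + %V) * %FO`` with %V treated as 0 when volume data
    are absent; fo_times_n: ``%FO * %N``; raw_count: ``FO(%) * count``.
    """
    if fo < 0 or pn < 0 or (pv is not None and pv < 0):
        raise ValidationError("relative_importance: inputs must be non-negative")
    if variant == "hyslop_nv":
        return (pn + (pv or 0.0)) * fo
    if variant == "fo_times_n":
        return fo * pn
    if variant == "raw_count":
        if raw_count is None:
            raise ValidationError("raw_count variant requires the raw count")
        if raw_count < 0:
            raise ValidationError("relative_importance: inputs must be non-negative")
        return fo * raw_count
    raise ValueError(f"unknown IRI variant {variant!r}")


def shannon_index(counts: Iterable[float], base: float | str = "e") -> float:
    """Shannon–Wiener diversity of a count vector (detritus excluded upstream).

    All-zero counts yield 0 with a warning rather than NaN.
    """
    arr = np.asarray(list(counts), dtype=float)
    if np.any(arr < 0):
        raise ValidationError("shannon_index: counts must be non-negative")
    total = arr.sum()
    if total == 0:
        logger.warning("shannon_index: all counts zero, returning flagged 0")
        return 0.0
    p = arr[arr > 0] / total
    b = _LOG_BASES.get(base, None)
    if b is None:
        b = float(base)
    return float(-(p * (np.log(p) / np.log(b))).sum()) + 0.0  # avoid -0.0


def relative_niche_width(
    record: GutRecord,
    total_categories: int = DEFAULT_TOTAL_CATEGORIES,
    variant: RnwVariant = "zero_anchored",
) -> float | None:
    """Per-specimen dietary breadth scaled to [0, 1].

    With k food categories in the gut (countable categories with a
    positive count, plus detritus) and K categories available:
    ``zero_anchored`` gives ``(k - 1) / (K - 1)`` so a single-category
    diet maps to 0 and a full diet to 1; ``proportion`` gives ``k / K``.
    Returns None for a gut with no food categories (excluded from
    population means).
    """
    if total_categories < 2:
        raise ValidationError("relative_niche_width: K must be >= 2")
    k = record.n_food_categories()
    if k == 0:
        return None
    if k > total_categories:
        raise ValidationError(
            f"record {record.fish_id!r}: {k} categories exceeds K={total_categories}"
        )
    if variant == "zero_anchored":
        return (k - 1) / (total_categories - 1)
    if variant == "proportion":
        return k / total_categories
    raise ValueError(f"unknown RNW variant {variant!r}")


def _sex_summary(values: list[float]) -> SexSummary:
    if not values:
        return SexSummary(n=0, mean=None, sd=None)
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return SexSummary(n=len(arr), mean=float(arr.mean()), sd=sd)


def gut_condition_summary(records: Sequence[GutRecord]) -> dict:
    """Empty / detritus-or-unidentifiable-only percentages and trait means.

    Percentages are of all examined guts. RGL and GF means/SDs are split
    by sex; records missing gut length or fullness are skipped with a
    logged count.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("gut_condition_summary: no records")
    n = len(records)
    n_empty = sum(1 for r in records if r.is_empty)
    n_det_only = sum(1 for r in records if r.is_detritus_or_unid_only)
    rgl: dict[str, list[float]] = {"F": [], "M": []}
    gf: dict[str, list[float]] = {"F": [], "M": []}
    n_missing_gl = n_missing_fu = 0
    for r in records:
        v = r.relative_gut_length
        if v is None:
            n_missing_gl += 1
        else:
            rgl[r.sex].append(v)
        if r.fullness is None:
            n_missing_fu += 1
        else:
            gf[r.sex].append(r.fullness)
    if n_missing_gl:
        logger.info("gut_condition_summary: %d records missing gut length", n_missing_gl)
    if n_missing_fu:
        logger.info("gut_condition_summary: %d records missing fullness", n_missing_fu)
    return {
        "n_fish": n,
        "empty_percent": 100.0 * n_empty / n,
        "detritus_or_unid_only_percent": 100.0 * n_det_only / n,
        "rgl_by_sex": {s: _sex_summary(v) for s, v in rgl.items()},
        "gf_by_sex": {s: _sex_summary(v) for s, v in gf.items()},
        "n_missing_gut_length": n_missing_gl,
        "n_missing_fullness": n_missing_fu,
    }


def summarize_population(
    records: Sequence[GutRecord],
    matrix: DietCountMatrix | None = None,
    config: MetricsConfig | None = None,
) -> list[PopulationDietSummary]:
    """Assemble the full per-population diet summary table.

    One :class:`PopulationDietSummary` per population, lexicographic
    order. ``matrix`` may be supplied to reuse an existing pooled count
    matrix; it must cover every population in ``records``.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("summarize_population: no records")
    config = config or MetricsConfig()
    if matrix is None:
        matrix = pool_counts(records)
    by_pop = records_by_population(records)
    for pid in by_pop:
        if pid not in matrix.population_ids:
            raise UnknownPopulationError(f"population {pid!r} missing from count matrix")

    k_total = config.total_categories or DEFAULT_TOTAL_CATEGORIES
    out = []
    for pid, recs in by_pop.items():
        fo = {
            c: frequency_of_occurrence(recs, c, config.fo_denominator)
            for c in list(COUNTABLE_CATEGORIES) + [DETRITUS, UNIDENTIFIABLE]
        }
        pn = percent_number(matrix, pid)
        row = matrix.row(pid)
        iri = {
            c: relative_importance(
                fo[c], pn[c], variant=config.iri_variant, raw_count=int(row[c])
            )
            for c in matrix.categories
        }
        h = shannon_index(row.to_numpy(), base=config.shannon_base)
        flagged = row.sum() == 0
        rnws = [
            v
            for r in recs
            if (v := relative_niche_width(r, k_total, config.rnw_variant)) is not None
        ]
        cond = gut_condition_summary(recs)
        out.append(
            PopulationDietSummary(
                population_id=pid,
                n_fish=len(recs),
                fo=fo,
                percent_number=pn,
                iri=iri,
                iri_variant=config.iri_variant,
                shannon_h=h,
                shannon_flagged_zero=bool(flagged),
                mean_rnw=float(np.mean(rnws)) if rnws else None,
                empty_percent=cond["empty_percent"],
                detritus_or_unid_only_percent=cond["detritus_or_unid_only_percent"],
                rgl_by_sex=cond["rgl_by_sex"],
                gf_by_sex=cond["gf_by_sex"],
                n_missing_gut_length=cond["n_missing_gut_length"],
                n_missing_fullness=cond["n_missing_fullness"],
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[PopulationDietSummary]):
    """Flatten summaries into a Table-1-style DataFrame (one row per population)."""
    import pandas as pd

    rows = []
    for s in summaries:
        row: dict = {"population_id": s.population_id, "n_fish": s.n_fish}
        row[f"FO_{DETRITUS}"] = s.fo[DETRITUS]
        for c in COUNTABLE_CATEGORIES:
            row[f"FO_{c}"] = s.fo[c]
            row[f"IRI_{c}"] = s.iri[c]
        row["shannon_H"] = s.shannon_h
        row["mean_RNW"] = s.mean_rnw
        row["empty_percent"] = s.empty_percent
        row["det_or_unid_only_percent"] = s.detritus_or_unid_only_percent
        for sex in ("F", "M"):
            row[f"RGL_mean_{sex}"] = s.rgl_by_sex[sex].mean
            row[f"RGL_sd_{sex}"] = s.rgl_by_sex[sex].sd
            row[f"GF_mean_{sex}"] = s.gf_by_sex[sex].mean
            row[f"GF_sd_{sex}"] = s.gf_by_sex[sex].sd
        rows.append(row)
    return pd.DataFrame(rows)
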