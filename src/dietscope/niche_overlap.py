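"""Pairwise dietary niche overlap and matrix correlation.

Two classical overlap indices over population diet-proportion vectors
(detritus excluded, since it has no counts):

* Schoener's proportional similarity ``C = 1 - 0.5 * sum_i |p_i - q_i|``;
* Pianka's symmetric index
  ``O = sum_i p_i q_i / sqrt(sum_i p_i^2 * sum_i q_i^2)``.

Both range from 0 (disjoint diets) to 1 (identical proportion vectors).
Values above 0.6 are conventionally read as biologically significant
overlap; the mask uses a strict ``>``.

A permutation Mantel test relates an overlap (similarity) matrix to a
geographic distance matrix: the statistic is the Pearson correlation of
the strict lower triangles and the null is built by permuting one
matrix's rows and columns simultaneously. For small matrices (n <= 7)
the full permutation group is enumerated instead of sampled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DietCountMatrix, Site, to_proportions
from .errors import InsufficientDataError, UndefinedOverlapError, ValidationError

EARTH_RADIUS_KM = 6371.0088

OverlapIndex = Literal["schoener", "pianka"]
Alternative = Literal["two_sided", "greater", "less"]


@dataclass
class OverlapResult:
    """Symmetric population x population overlap matrix with significance mask.

    Cells are NaN where overlap is undefined (a population with no counted
    prey); such cells are always False in the mask.
    """

    index_name: str
    matrix: pd.DataFrame
    significance_mask: pd.DataFrame
    threshold: float = 0.6

    @property
    def population_ids(self) -> list[str]:
        return list(self.matrix.index)

    def lower_triangle(self) -> np.ndarray:
        """Vectorized strict lower triangle (each unordered pair once)."""
        vals = self.matrix.to_numpy(dtype=float)
        i, j = np.tril_indices(vals.shape[0], k=-1)
        return vals[i, j]


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int | None
    alternative: str
    method: str  # "permutation" or "exact_enumeration"


def _check_proportions(p: np.ndarray, q: np.ndarray) -> None:
    if p.shape != q.shape:
        raise ValidationError("overlap: proportion vectors must share category order")
    if np.any(p < 0) or np.any(q < 0):
        raise ValidationError("overlap: proportions must be non-negative")


def _as_vector(p) -> np.ndarray:
    if hasattr(p, "is_zero"):
        if p.is_zero:
            raise UndefinedOverlapError(
                f"population {p.population_id!r} has no counted prey; overlap undefined"
            )
        return p.values
    return np.asarray(p, dtype=float)


def schoener_overlap(p, q) -> float:
    """Schoener's proportional similarity between two diet proportion vectors.

    Computed as ``sum_i min(p_i, q_i)``, algebraically identical to
    ``1 - 0.5 * sum_i |p_i - q_i|`` for vectors on the simplex but exact
    at the 0 (disjoint) anchor in floating point.
    """
    pv, qv = _as_vector(p), _as_vector(q)
    _check_proportions(pv, qv)
    if pv.sum() == 0 or qv.sum() == 0:
        raise UndefinedOverlapError("overlap undefined for an all-zero proportion vector")
    c = float(np.minimum(pv, qv).sum())
    if c > 1.0 or abs(c - 1.0) < 1e-12:
        c = 1.0
    return c


def pianka_overlap(p, q) -> float:
    """Pianka's symmetric overlap between two diet proportion vectors."""
    pv, qv = _as_vector(p), _as_vector(q)
    _check_proportions(pv, qv)
    denom = math.sqrt((pv**2).sum() * (qv**2).sum())
    if denom == 0:
        raise UndefinedOverlapError("overlap undefined for an all-zero proportion vector")
    return float(np.clip((pv * qv).sum() / denom, 0.0, 1.0))


_INDEX_FUNCS = {"schoener": schoener_overlap, "pianka": pianka_overlap}


def overlap_matrix(
    matrix: DietCountMatrix,
    index: OverlapIndex = "schoener",
    threshold: float = 0.6,
) -> OverlapResult:
    """All pairwise overlaps from pooled population counts.

    Populations with zero counted prey produce NaN rows/columns (overlap
    undefined, never coerced to 0) and are excluded from the mask.
    """
    pops = matrix.population_ids
    if len(pops) < 2:
        raise InsufficientDataError("overlap_matrix: need >= 2 populations")
    func = _INDEX_FUNCS[index]
    props = {p: to_proportions(matrix, p) for p in pops}
    n = len(pops)
    vals = np.full((n, n), np.nan)
    for a in range(n):
        if not props[pops[a]].is_zero:
            vals[a, a] = 1.0
        for b in range(a):
            pa, pb = props[pops[a]], props[pops[b]]
            if pa.is_zero or pb.is_zero:
                continue
            v = func(pa, pb)
            vals[a, b] = vals[b, a] = v
    df = pd.DataFrame(vals, index=pops, columns=pops)
    mask = df.gt(threshold) & df.notna()
    return OverlapResult(index_name=index, matrix=df, significance_mask=mask, threshold=threshold)


def correlate_overlap_indices(
    a: OverlapResult,
    b: OverlapResult,
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float]:
    """Correlation between two overlap matrices over their unordered pairs.

    Each off-diagonal pair enters once (strict lower triangle); pairs
    undefined in either matrix are dropped pairwise.
    """
    if a.population_ids != b.population_ids:
        raise ValidationError("correlate_overlap_indices: population sets differ")
    x, y = a.lower_triangle(), b.lower_triangle()
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientDataError("correlate_overlap_indices: need >= 3 valid pairs")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two points (decimal degrees)."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def haversine_matrix(sites: Sequence[Site]) -> pd.DataFrame:
    """Symmetric great-circle distance matrix (km) between sampling sites."""
    sites = sorted(sites, key=lambda s: s.population_id)
    ids = [s.population_id for s in sites]
    n = len(sites)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            d = haversine_km(
                sites[i].latitude, sites[i].longitude, sites[j].latitude, sites[j].longitude
            )
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=ids, columns=ids)


def _tri_vector(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise InsufficientDataError("mantel: zero variance in a triangle vector")
    return float((xc * yc).sum() / denom)


def _coerce_square(m, name: str) -> np.ndarray:
    arr = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError(f"mantel: {name} must be a square matrix")
    if not np.allclose(arr, arr.T, equal_nan=True):
        raise ValidationError(f"mantel: {name} must be symmetric")
    return arr


def mantel_test(
    a,
    b,
    n_permutations: int = 10_000,
    seed: int | None = None,
    alternative: Alternative = "two_sided",
) -> MantelResult:
    """Permutation Mantel test between two symmetric matrices.

    The statistic is the Pearson correlation of the strict lower
    triangles; the null distribution comes from simultaneous row/column
    permutations of ``b``. For n <= 7 all n! relabelings are enumerated
    (``method = "exact_enumeration"``; the identity counts, so the p-value
    is exact). Otherwise ``n_permutations`` random permutations are drawn
    and the p-value uses the add-one estimator, so it is never 0.

    Diagonals are ignored. ``a`` may be a distance matrix and ``b`` a
    similarity (overlap) matrix: the sign of ``r`` then encodes the
    distance-vs-similarity direction, and the default two-sided
    alternative is appropriate.
    """
    A = _coerce_square(a, "A")
    B = _coerce_square(b, "B")
    if A.shape != B.shape:
        raise ValidationError("mantel: matrices must have the same size")
    n = A.shape[0]
    if n < 3:
        raise InsufficientDataError("mantel: need n >= 3")
    if np.isnan(_tri_vector(A)).any() or np.isnan(_tri_vector(B)).any():
        raise ValidationError("mantel: off-diagonal NaNs are not allowed")

    x = _tri_vector(A)
    r_obs = _pearson(x, _tri_vector(B))

    def perm_r(perm: np.ndarray) -> float:
        return _pearson(x, _tri_vector(B[np.ix_(perm, perm)]))

    def exceeds(r_perm: float) -> bool:
        if alternative == "two_sided":
            return abs(r_perm) >= abs(r_obs) - 1e-12
        if alternative == "greater":
            return r_perm >= r_obs - 1e-12
        if alternative == "less":
            return r_perm <= r_obs + 1e-12
        raise ValueError(f"unknown alternative {alternative!r}")

    if n <= 7:
        perms = list(itertools.permutations(range(n)))
        count = sum(exceeds(perm_r(np.array(p))) for p in perms)
        return MantelResult(
            r=r_obs,
            p_value=count / len(perms),
            n_permutations=len(perms),
            seed=seed,
            alternative=alternative,
            method="exact_enumeration",
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if exceeds(perm_r(perm)):
            count += 1
    return MantelResult(
        r=r_obs,
        p_value=(count + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
        seed=seed,
        alternative=alternative,
        method="permutation",
    )


def two_triangle_table(schoener: OverlapResult, pianka: OverlapResult) -> pd.DataFrame:
    """Combined report: Pianka in the lower triangle, Schoener in the upper."""
    if schoener.population_ids != pianka.population_ids:
        raise ValidationError("two_triangle_table: population sets differ")
    pops = schoener.population_ids
    s = schoener.matrix.to_numpy(dtype=float)
    p = pianka.matrix.to_numpy(dtype=float)
    n = len(pops)
    out = np.full((n, n), np.nan)
    iu = np.triu_indices(n, k=1)
    il = np.tril_indices(n, k=-1)
    out[iu] = s[iu]
    out[il] = p[il]
    return pd.DataFrame(out, index=pops, columns=pops)
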