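"""Environment/climate PCA and association with population diet metrics.

The site table mixes units (mS/cm, mg/L, degrees C, mm, decimal degrees),
so the PCA runs on the correlation matrix: every variable is centred and
scaled to unit variance first. Components are retained up to the smallest
number whose cumulative explained-variance ratio reaches the threshold
(default 0.90), and each component's sign is fixed so that its
largest-magnitude loading is positive — a deterministic convention that
makes outputs reproducible across runs and platforms.

Population-level diet metrics (Shannon diversity, IRI, FO, ...) are then
regressed on the retained component scores by OLS, and per-population
prey totals (or empty-gut proportions) are correlated with each score by
Pearson correlation. With a handful of sites these analyses have very low
power; every report carries an explicit low-power warning when n < 15.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import GutRecord, Site, records_by_population, sites_to_frame
from .errors import (
    CompletenessError,
    InsufficientDataError,
    ValidationError,
)

logger = logging.getLogger(__name__)

LOW_POWER_N = 15


@dataclass
class PcaResult:
    variable_names: list[str]
    site_ids: list[str]
    loadings: pd.DataFrame            # variables x components
    explained_variance_ratio: np.ndarray
    retained: int
    scores: pd.DataFrame              # sites x components (all components)
    standardized: pd.DataFrame        # centred/scaled input, for reconstruction
    retain_threshold: float

    @property
    def retained_scores(self) -> pd.DataFrame:
        return self.scores.iloc[:, : self.retained]


@dataclass
class AssociationReport:
    metric: str
    slopes: list[tuple[str, float, float, float]]  # (PC, slope, std_error, p)
    overall_p: float | None
    r_squared: float | None
    n_sites: int
    low_power_warning: bool = False
    note: str | None = None


def pca_environment(
    sites: Sequence[Site],
    standardize: bool = True,
    retain_threshold: float = 0.90,
    variables: Sequence[str] | None = None,
) -> PcaResult:
    """PCA of the site environment/geography/climate matrix.

    Missing cells are refused (no imputation); a zero-variance variable is
    an error naming the variable. ``retained`` is the smallest number of
    components whose cumulative explained-variance ratio reaches
    ``retain_threshold``.
    """
    sites = sorted(sites, key=lambda s: s.population_id)
    if len(sites) < 3:
        raise InsufficientDataError("pca_environment: need >= 3 sites")
    variables = list(variables or Site.ENVIRONMENT_VARIABLES)
    if len(variables) < 2:
        raise ValidationError("pca_environment: need >= 2 variables")
    df = sites_to_frame(sites).set_index("population_id")[variables].astype(float)
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise CompletenessError(f"pca_environment: missing cells in {bad}; imputation refused")

    X = df.to_numpy()
    mean = X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = [v for v, s in zip(variables, sd) if s == 0]
        if zero:
            raise ValidationError(f"pca_environment: zero-variance variable(s): {zero}")
        Z = (X - mean) / sd
    else:
        Z = X - mean

    # SVD of the centred/scaled matrix; components = right singular vectors
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    ncomp = min(len(sites) - 1, len(variables))
    U, s, Vt = U[:, :ncomp], s[:ncomp], Vt[:ncomp]
    var = s**2
    ratio = var / var.sum()

    loadings = Vt.T.copy()
    scores = Z @ loadings
    # deterministic sign: largest-|loading| positive per component
    for j in range(ncomp):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    cum = np.cumsum(ratio)
    retained = int(np.searchsorted(cum, retain_threshold - 1e-12) + 1)
    retained = min(retained, ncomp)

    comp_names = [f"PC{i + 1}" for i in range(ncomp)]
    return PcaResult(
        variable_names=variables,
        site_ids=list(df.index),
        loadings=pd.DataFrame(loadings, index=variables, columns=comp_names),
        explained_variance_ratio=ratio,
        retained=retained,
        scores=pd.DataFrame(scores, index=df.index, columns=comp_names),
        standardized=pd.DataFrame(Z, index=df.index, columns=variables),
        retain_threshold=retain_threshold,
    )


def regress_metric_on_pcs(
    metric: pd.Series | dict[str, float],
    pca: PcaResult,
    metric_name: str = "metric",
) -> AssociationReport:
    """OLS of a per-population metric on the retained component scores."""
    metric = pd.Series(metric, dtype=float)
    missing = [p for p in pca.site_ids if p not in metric.index]
    if missing:
        raise ValidationError(f"metric {metric_name!r} missing populations: {missing}")
    y = metric.loc[pca.site_ids].to_numpy()
    n = len(y)

    if np.allclose(y, y[0]):
        logger.warning("metric %s has zero variance; association undefined", metric_name)
        return AssociationReport(
            metric=metric_name,
            slopes=[(pc, 0.0, np.nan, 1.0) for pc in pca.retained_scores.columns],
            overall_p=None,
            r_squared=None,
            n_sites=n,
            low_power_warning=n < LOW_POWER_N,
            note="zero-variance metric",
        )

    k = pca.retained
    note = None
    if k > n - 2:
        k = max(1, n - 2)
        note = f"rank warning: retained PCs reduced from {pca.retained} to {k} (n = {n})"
        logger.warning(note)
    scores = pca.scores.iloc[:, :k]
    X = sm.add_constant(scores.to_numpy())
    fit = sm.OLS(y, X).fit()
    slopes = [
        (pc, float(fit.params[i + 1]), float(fit.bse[i + 1]), float(fit.pvalues[i + 1]))
        for i, pc in enumerate(scores.columns)
    ]
    return AssociationReport(
        metric=metric_name,
        slopes=slopes,
        overall_p=float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else None,
        r_squared=float(fit.rsquared),
        n_sites=n,
        low_power_warning=n < LOW_POWER_N,
        note=note,
    )


def correlate_with_pcs(
    values: pd.Series | dict[str, float],
    pca: PcaResult,
    name: str = "values",
) -> list[tuple[str, float, float]]:
    """Pearson correlation of a per-population quantity with each retained PC."""
    values = pd.Series(values, dtype=float)
    missing = [p for p in pca.site_ids if p not in values.index]
    if missing:
        raise ValidationError(f"{name!r} missing populations: {missing}")
    v = values.loc[pca.site_ids].to_numpy()
    if np.allclose(v, v[0]):
        logger.warning("%s has zero variance; correlations flagged NaN", name)
        return [(pc, float("nan"), float("nan")) for pc in pca.retained_scores.columns]
    out = []
    for pc in pca.retained_scores.columns:
        res = stats.pearsonr(v, pca.scores[pc].to_numpy())
        out.append((pc, float(res.statistic), float(res.pvalue)))
    return out


def correlate_consumption_with_pcs(
    records: Sequence[GutRecord], pca: PcaResult
) -> list[tuple[str, float, float]]:
    """Total prey consumed per population vs. each retained PC (Pearson)."""
    by_pop = records_by_population(records)
    totals = {p: float(sum(r.total_prey for r in recs)) for p, recs in by_pop.items()}
    return correlate_with_pcs(totals, pca, name="total_prey")


def correlate_empty_guts_with_pcs(
    records: Sequence[GutRecord], pca: PcaResult
) -> list[tuple[str, float, float]]:
    """Per-population proportion of empty guts vs. each retained PC (Pearson)."""
    by_pop = records_by_population(records)
    props = {
        p: sum(1 for r in recs if r.is_empty) / len(recs) for p, recs in by_pop.items()
    }
    return correlate_with_pcs(props, pca, name="empty_gut_proportion")
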