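"""Size- and population-structured feeding models.

Per-category presence/absence of a food item in a fish's gut is modelled
with a binomial GLM (logit link):

    presence ~ SL + population + SL:population

and the three continuous gut traits (relative gut length RGL, gut
fullness GF, relative niche width RNW) with gamma GLMs (log link) of the
same structure. The single interaction term is screened first: if its
p-value exceeds 0.2 (strict), the model is refitted without it, and the
dropped term is kept in the report in brackets.

Two population codings are available. ``numeric_as_paper`` maps the
lexicographically sorted population ids onto the ordinals 1..n and enters
them as a single numeric covariate, which yields one Population
coefficient per model; ``categorical`` uses conventional treatment-coded
dummies and a likelihood-ratio block test for the interaction, and is the
statistically preferable choice. Sex is deliberately excluded as a
covariate: in strongly size-dimorphic poeciliids sex and SL are nearly
collinear, so SL carries the sex signal.

A permutation-based joint population statistic (summed deviance
reduction across the three trait responses, population labels permuted)
stands in for an omnibus multivariate gamma model, whose exact
construction is not uniquely defined; it is reported separately from the
per-response fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .categories import COUNTABLE_CATEGORIES, DETRITUS, UNIDENTIFIABLE
from .data_model import GutRecord
from .diet_metrics import relative_niche_width
from .errors import (
    DegenerateResponseError,
    EmptyInputError,
    InsufficientDataError,
    ValidationError,
)

logger = logging.getLogger(__name__)

Coding = Literal["numeric_as_paper", "categorical"]
TraitName = Literal["RGL", "GF", "RNW"]

PRUNE_ALPHA_DEFAULT = 0.2


@dataclass
class TermEstimate:
    name: str
    estimate: float
    std_error: float
    statistic: float
    p_value: float


@dataclass
class GlmFit:
    """One fitted (and possibly interaction-pruned) GLM."""

    response: str
    family: str                      # "binomial" | "gamma"
    link: str                        # "logit" | "log"
    population_coding: str
    terms: list[TermEstimate]
    interaction_retained: bool
    interaction_p: float | None      # screening p-value of the interaction
    dropped_interaction: list[TermEstimate] = field(default_factory=list)
    converged: bool = True
    diagnostic: str | None = None
    n_used: int = 0
    # refit context, kept so prune_interaction() can re-apply the rule
    _frame: pd.DataFrame | None = field(default=None, repr=False)
    _prune_alpha: float = field(default=PRUNE_ALPHA_DEFAULT, repr=False)

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass
class TukeyResult:
    response: str
    pairs: list[tuple[str, str, float, float, bool]]  # (a, b, meandiff, p_adj, significant)
    alpha: float = 0.05
    dropped_populations: list[str] = field(default_factory=list)


@dataclass
class JointPopulationTest:
    """Permutation test of an overall population effect on the trait responses."""

    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    per_response: dict[str, float]


# ---------------------------------------------------------------------------
# model frame construction
# ---------------------------------------------------------------------------

def population_ordinals(records: Sequence[GutRecord]) -> dict[str, int]:
    """Lexicographically sorted population ids mapped onto 1..n."""
    return {p: i + 1 for i, p in enumerate(sorted({r.population_id for r in records}))}


def model_frame(records: Sequence[GutRecord]) -> pd.DataFrame:
    """Per-fish model frame with SL, population codings, traits and presences."""
    records = list(records)
    if not records:
        raise EmptyInputError("model_frame: no records")
    ords = population_ordinals(records)
    rows = []
    for r in records:
        row = {
            "fish_id": r.fish_id,
            "population": r.population_id,
            "pop": ords[r.population_id],
            "sl": r.standard_length,
            "sex": r.sex,
            "pregnant": r.pregnant,
            "rgl": np.nan if r.relative_gut_length is None else r.relative_gut_length,
            "gf": np.nan if r.fullness is None else r.fullness,
        }
        rnw = relative_niche_width(r)
        row["rnw"] = np.nan if rnw is None else rnw
        for c in COUNTABLE_CATEGORIES:
            row[f"present_{c}"] = int(r.prey_counts[c] > 0)
        row[f"present_{DETRITUS}"] = int(r.detritus_present)
        row[f"present_{UNIDENTIFIABLE}"] = int(r.unidentifiable_present)
        rows.append(row)
    return pd.DataFrame(rows)


_TRAIT_COLUMN = {"RGL": "rgl", "GF": "gf", "RNW": "rnw"}


def _family(name: str):
    if name == "binomial":
        return sm.families.Binomial()
    if name == "gamma":
        return sm.families.Gamma(link=sm.families.links.Log())
    raise ValueError(name)


def _pop_term(coding: Coding) -> str:
    return "pop" if coding == "numeric_as_paper" else "C(population)"


def _safe_fit(formula: str, df: pd.DataFrame, family_name: str):
    """Fit a GLM, returning (results, diagnostic). Never a silent bad fit."""
    try:
        res = smf.glm(formula, data=df, family=_family(family_name)).fit(maxiter=200)
    except PerfectSeparationError as exc:
        return None, f"perfect separation: {exc}"
    except (np.linalg.LinAlgError, ValueError) as exc:
        return None, f"fit failed: {exc}"
    if not getattr(res, "converged", True):
        return res, "IRLS did not converge"
    if not np.all(np.isfinite(res.bse)) or np.any(res.bse <= 0):
        return res, "unstable standard errors (possible separation)"
    return res, None


def _terms_of(res) -> list[TermEstimate]:
    stat = res.tvalues  # z for GLM (params / bse)
    return [
        TermEstimate(
            name=name,
            estimate=float(res.params[name]),
            std_error=float(res.bse[name]),
            statistic=float(stat[name]),
            p_value=float(res.pvalues[name]),
        )
        for name in res.params.index
    ]


def _interaction_pvalue(
    df: pd.DataFrame, response: str, family_name: str, coding: Coding
):
    """(full results, interaction p, diagnostic). Wald z for the single numeric
    term; likelihood-ratio block test for the categorical dummy block."""
    pop = _pop_term(coding)
    full_formula = f"{response} ~ sl + {pop} + sl:{pop}"
    full, diag = _safe_fit(full_formula, df, family_name)
    if diag is not None:
        return full, None, diag
    if coding == "numeric_as_paper":
        return full, float(full.pvalues["sl:pop"]), None
    reduced, diag = _safe_fit(f"{response} ~ sl + {pop}", df, family_name)
    if diag is not None:
        return full, None, diag
    lr = 2.0 * (full.llf - reduced.llf)
    df_diff = full.df_model - reduced.df_model
    p = float(sps.chi2.sf(max(lr, 0.0), df_diff)) if df_diff > 0 else 1.0
    return full, p, None


def _fit_with_pruning(
    df: pd.DataFrame,
    response: str,
    family_name: str,
    link: str,
    coding: Coding,
    prune_alpha: float,
    response_label: str,
) -> GlmFit:
    if df["population"].nunique() < 2:
        raise InsufficientDataError(f"{response_label}: need >= 2 populations")
    y = df[response]
    if y.nunique() <= 1:
        raise DegenerateResponseError(
            f"{response_label}: response is constant ({y.iloc[0]!r} for every record)"
        )
    full, inter_p, diag = _interaction_pvalue(df, response, family_name, coding)
    if diag is not None:
        return GlmFit(
            response=response_label,
            family=family_name,
            link=link,
            population_coding=coding,
            terms=_terms_of(full) if full is not None else [],
            interaction_retained=True,
            interaction_p=inter_p,
            converged=False,
            diagnostic=diag,
            n_used=len(df),
            _frame=df,
            _prune_alpha=prune_alpha,
        )
    full_terms = _terms_of(full)
    inter_terms = [t for t in full_terms if ":" in t.name]
    if inter_p > prune_alpha:  # strict: p exactly at the threshold is retained
        pop = _pop_term(coding)
        reduced, diag = _safe_fit(f"{response} ~ sl + {pop}", df, family_name)
        return GlmFit(
            response=response_label,
            family=family_name,
            link=link,
            population_coding=coding,
            terms=_terms_of(reduced) if reduced is not None else [],
            interaction_retained=False,
            interaction_p=inter_p,
            dropped_interaction=inter_terms,
            converged=diag is None,
            diagnostic=diag,
            n_used=len(df),
            _frame=df,
            _prune_alpha=prune_alpha,
        )
    return GlmFit(
        response=response_label,
        family=family_name,
        link=link,
        population_coding=coding,
        terms=full_terms,
        interaction_retained=True,
        interaction_p=inter_p,
        n_used=len(df),
        _frame=df,
        _prune_alpha=prune_alpha,
    )


# ---------------------------------------------------------------------------
# public fitting operations
# ---------------------------------------------------------------------------

def fit_presence_glm(
    records: Sequence[GutRecord],
    category: str,
    coding: Coding = "numeric_as_paper",
    prune_alpha: float = PRUNE_ALPHA_DEFAULT,
) -> GlmFit:
    """Binomial (logit) GLM of a food category's presence on SL and population.

    ``category`` may be any countable code or DET (11 models in a full
    sweep). The interaction-pruning rule is applied automatically.
    """
    if category not in COUNTABLE_CATEGORIES and category not in (DETRITUS, UNIDENTIFIABLE):
        raise ValidationError(f"unknown category {category!r}")
    df = model_frame(records)
    col = f"present_{category}"
    if df[col].sum() == 0:
        raise DegenerateResponseError(f"category {category} absent from every gut")
    return _fit_with_pruning(
        df, col, "binomial", "logit", coding, prune_alpha, response_label=f"presence_{category}"
    )


def prune_interaction(fit: GlmFit) -> GlmFit:
    """Re-apply the interaction-screening rule to a fitted model.

    Idempotent: a fit whose interaction was already dropped (or retained
    at p <= alpha) is returned unchanged.
    """
    if fit._frame is None:
        raise ValidationError("prune_interaction: fit carries no refit context")
    if not fit.interaction_retained:
        return fit
    if fit.interaction_p is not None and fit.interaction_p <= fit._prune_alpha:
        return fit
    resp_col = _response_column(fit)
    refit = _fit_with_pruning(
        fit._frame,
        resp_col,
        fit.family,
        fit.link,
        fit.population_coding,  # type: ignore[arg-type]
        fit._prune_alpha,
        response_label=fit.response,
    )
    return refit


def _response_column(fit: GlmFit) -> str:
    if fit.response.startswith("presence_"):
        return "present_" + fit.response.split("_", 1)[1]
    return _TRAIT_COLUMN[fit.response]


def fit_trait_glm(
    records: Sequence[GutRecord],
    response: TraitName,
    coding: Coding = "numeric_as_paper",
    prune_alpha: float = PRUNE_ALPHA_DEFAULT,
    zero_policy: Literal["exclude", "shift"] = "exclude",
) -> GlmFit:
    """Gamma (log link) GLM of a gut trait on SL and population.

    Gamma support is strictly positive, so zero trait values (e.g. an
    empty gut's fullness) are excluded by default with a logged count;
    ``zero_policy="shift"`` instead adds half the smallest positive value.
    Records missing the trait are always skipped.
    """
    df = model_frame(records)
    col = _TRAIT_COLUMN[response]
    n_missing = int(df[col].isna().sum())
    df = df.dropna(subset=[col])
    n_zero = int((df[col] <= 0).sum())
    if zero_policy == "exclude":
        df = df[df[col] > 0].copy()
    elif zero_policy == "shift":
        pos = df.loc[df[col] > 0, col]
        if pos.empty:
            raise DegenerateResponseError(f"{response}: no positive values to anchor the shift")
        df = df.copy()
        df[col] = df[col] + pos.min() / 2.0
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if n_missing or n_zero:
        logger.info(
            "fit_trait_glm %s: skipped %d missing, %s %d non-positive values",
            response, n_missing, zero_policy + "d", n_zero,
        )
    if df.empty:
        raise EmptyInputError(f"{response}: no usable records after exclusions")
    return _fit_with_pruning(
        df, col, "gamma", "log", coding, prune_alpha, response_label=response
    )


def joint_population_test(
    records: Sequence[GutRecord],
    responses: Sequence[TraitName] = ("RGL", "GF", "RNW"),
    n_permutations: int = 499,
    seed: int | None = None,
) -> JointPopulationTest:
    """Permutation test of a joint population effect on the trait responses.

    The statistic sums, over responses, the deviance explained by adding
    population (numeric coding) to a SL-only gamma model; the null
    permutes population labels across fish.
    """
    df0 = model_frame(records)

    def stat_for(df: pd.DataFrame) -> tuple[float, dict[str, float]]:
        total = 0.0
        per = {}
        for resp in responses:
            col = _TRAIT_COLUMN[resp]
            sub = df.dropna(subset=[col])
            sub = sub[sub[col] > 0]
            base, d1 = _safe_fit(f"{col} ~ sl", sub, "gamma")
            full, d2 = _safe_fit(f"{col} ~ sl + pop", sub, "gamma")
            if d1 is not None or d2 is not None:
                raise DegenerateResponseError(f"joint test: {resp} model failed ({d1 or d2})")
            per[resp] = float(base.deviance - full.deviance)
            total += per[resp]
        return total, per

    obs, per_response = stat_for(df0)
    rng = np.random.default_rng(seed)
    count = 0
    pop_labels = df0["population"].to_numpy()
    pop_ords = df0["pop"].to_numpy()
    for _ in range(n_permutations):
        perm = rng.permutation(len(df0))
        dfp = df0.copy()
        dfp["population"] = pop_labels[perm]  # dtypes preserved column-wise
        dfp["pop"] = pop_ords[perm]
        s, _ = stat_for(dfp)
        if s >= obs - 1e-12:
            count += 1
    return JointPopulationTest(
        statistic=obs,
        p_value=(count + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
        seed=seed,
        per_response=per_response,
    )


def tukey_population_contrasts(
    records: Sequence[GutRecord],
    response: TraitName,
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey HSD comparison of a gut trait's mean across all population pairs."""
    df = model_frame(records)
    col = _TRAIT_COLUMN[response]
    df = df.dropna(subset=[col])
    sizes = df.groupby("population").size()
    dropped = sorted(sizes[sizes < 2].index)
    if dropped:
        logger.warning("tukey %s: dropping populations with <2 values: %s", response, dropped)
        df = df[~df["population"].isin(dropped)]
    if df["population"].nunique() < 2:
        raise InsufficientDataError(f"tukey {response}: need >= 2 usable populations")
    res = pairwise_tukeyhsd(df[col].to_numpy(), df["population"].to_numpy(), alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    pairs = [
        (str(row["group1"]), str(row["group2"]), float(row["meandiff"]),
         float(row["p-adj"]), bool(row["reject"]))
        for _, row in frame.iterrows()
    ]
    return TukeyResult(response=response, pairs=pairs, alpha=alpha, dropped_populations=dropped)


def pregnancy_posthoc(records: Sequence[GutRecord], category: str) -> GlmFit:
    """Female-only binomial GLM: food-category presence ~ pregnancy state.

    The coefficient for pregnancy is on the log-odds scale with
    non-pregnant females as the reference, so a negative estimate means
    pregnant females were less likely to have consumed the category.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("pregnancy_posthoc: no records")
    males = [r.fish_id for r in records if r.sex != "F"]
    if males:
        raise ValidationError(
            f"pregnancy_posthoc: records must be females only (found males: {males[:3]}...)"
        )
    df = model_frame(records)
    classes = set(df["pregnant"])
    if not {"yes", "no"} <= classes:
        raise DegenerateResponseError(
            f"pregnancy_posthoc: need both pregnant and non-pregnant females, got {sorted(classes)}"
        )
    df["pregnant_bin"] = (df["pregnant"] == "yes").astype(int)
    col = f"present_{category}"
    if col not in df.columns:
        raise ValidationError(f"unknown category {category!r}")
    if df[col].nunique() <= 1:
        raise DegenerateResponseError(f"category {category}: presence constant among females")
    res, diag = _safe_fit(f"{col} ~ pregnant_bin", df, "binomial")
    return GlmFit(
        response=f"presence_{category}~pregnancy",
        family="binomial",
        link="logit",
        population_coding="n/a",
        terms=_terms_of(res) if res is not None else [],
        interaction_retained=False,
        interaction_p=None,
        converged=diag is None,
        diagnostic=diag,
        n_used=len(df),
        _frame=df,
    )


def fit_all_presence_glms(
    records: Sequence[GutRecord],
    coding: Coding = "numeric_as_paper",
    prune_alpha: float = PRUNE_ALPHA_DEFAULT,
) -> dict[str, GlmFit | None]:
    """The full 11-model sweep (10 prey categories + detritus).

    Categories absent from every gut are reported as None with a log line
    rather than aborting the sweep.
    """
    out: dict[str, GlmFit | None] = {}
    for c in list(COUNTABLE_CATEGORIES) + [DETRITUS]:
        try:
            out[c] = fit_presence_glm(records, c, coding=coding, prune_alpha=prune_alpha)
        except DegenerateResponseError as exc:
            logger.warning("presence GLM skipped for %s: %s", c, exc)
            out[c] = None
    return out
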