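"""Cross-source assumption checks.

Two checks probe whether the survey and the service log describe the same
population.  First, if program knowledge is uneven across subgroups, parts of
the population may have effectively zero probability of appearing in the
service count: a weighted chi-square compares trait distributions between
respondents who have and have not heard of the program.  Second, survey
respondents who report service use should resemble the deduplicated service
clients themselves: a weighted logistic regression of data source on the
trait (with fixed site terms, and a likelihood-ratio test for trait-by-site
interaction) checks this.

Survey rows carry RDS-II weights normalized to mean 1 within site; service
rows are unweighted.  The weighted chi-square applies no design-effect
correction, so its p-values are anti-conservative under recruitment
clustering — treat them as descriptive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import ProgramVisit, RecruitmentForest, SiteMeta
from .rds import EstimationError, rds2_weights

__all__ = [
    "TraitComparison",
    "pooled_respondents",
    "program_person_records",
    "weighted_chi2",
    "knowledge_association",
    "source_comparison",
]


@dataclass
class TraitComparison:
    """Result of one trait's cross-group comparison."""

    trait: str
    table: pd.DataFrame  # weighted counts, categories x groups
    chi2_stat: float
    p_value: float
    interaction_p: float
    n_sites_pooled: int
    method: str
    notes: list[str] = field(default_factory=list)

    @property
    def proportions(self) -> pd.DataFrame:
        """Per-group weighted proportions (columns sum to 1)."""
        return self.table / self.table.sum(axis=0)


def pooled_respondents(forests: Iterable[RecruitmentForest]) -> pd.DataFrame:
    """Pool sites into one respondent table with mean-1 normalized weights.

    Weights are inverse-degree, rescaled to mean 1 within each site so that no
    site dominates purely through its degree scale.  Respondents without a
    valid degree get weight NaN and are excluded from weighted analyses.
    """
    rows = []
    for forest in forests:
        w = rds2_weights(forest, normalize="mean1")
        for r in forest:
            rows.append(
                {
                    "respondent_id": r.respondent_id,
                    "site_id": r.site_id,
                    "weight": w.get(r.respondent_id, np.nan),
                    "attended_program": r.attended_program,
                    "heard_of_program": r.heard_of_program,
                    **r.traits,
                }
            )
    return pd.DataFrame(rows)


def program_person_records(
    visits: Iterable[ProgramVisit],
    meta: SiteMeta,
    min_age: int = 18,
) -> pd.DataFrame:
    """Deduplicate the visit log into person records for source comparison.

    One row per eligible client; traits come from her most recent in-window
    visit (demographics may change between visits, and the latest record is
    closest in time to the survey).
    """
    start, end = meta.window
    best: dict[str, ProgramVisit] = {}
    for v in visits:
        if v.site_id != meta.site_id or not (start <= v.visit_date < end) or v.age_at_visit < min_age:
            continue
        cur = best.get(v.client_id)
        if cur is None or v.visit_date > cur.visit_date:
            best[v.client_id] = v
    rows = [
        {"client_id": v.client_id, "site_id": v.site_id, "age_at_visit": v.age_at_visit, **dict(v.traits)}
        for v in best.values()
    ]
    return pd.DataFrame(rows)


def weighted_chi2(
    table: pd.DataFrame,
) -> tuple[float, float]:
    """Pearson chi-square on a weighted contingency table.

    Expected counts are the usual product-of-margins construction on the
    weighted totals; with all weights equal this is exactly the classical
    Pearson statistic on raw counts.
    """
    obs = table.to_numpy(dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total <= 0:
        raise EstimationError("empty contingency table")
    expected = row @ col / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, float(stats.chi2.sf(stat, df))


def _weighted_table(df: pd.DataFrame, trait: str, group: str, weight: str | None) -> pd.DataFrame:
    w = df[weight] if weight else pd.Series(1.0, index=df.index)
    table = df.assign(_w=w).pivot_table(
        index=trait, columns=group, values="_w", aggfunc="sum", fill_value=0.0, observed=True
    )
    dead = table.index[(table.sum(axis=1) == 0)]
    if len(dead):
        warnings.warn(f"trait {trait}: dropping empty categories {list(dead)}", stacklevel=3)
        table = table.drop(index=dead)
    return table


def _lr_interaction_p(df: pd.DataFrame, outcome: str, trait: str, weight: str) -> float:
    """Likelihood-ratio p-value for trait x site interaction in a weighted logistic model."""
    if df["site_id"].nunique() < 2:
        return float("nan")
    try:
        full = sm.GLM.from_formula(
            f"{outcome} ~ C({trait}) * C(site_id)",
            data=df,
            family=sm.families.Binomial(),
            freq_weights=df[weight].to_numpy(),
        ).fit()
        reduced = sm.GLM.from_formula(
            f"{outcome} ~ C({trait}) + C(site_id)",
            data=df,
            family=sm.families.Binomial(),
            freq_weights=df[weight].to_numpy(),
        ).fit()
    except Exception:
        return float("nan")
    lr = 2.0 * (full.llf - reduced.llf)
    df_diff = full.df_model - reduced.df_model
    if df_diff <= 0:
        return float("nan")
    return float(stats.chi2.sf(max(lr, 0.0), df_diff))


def knowledge_association(
    forests: Iterable[RecruitmentForest],
    trait: str,
    min_nonmissing: float = 0.9,
) -> TraitComparison:
    """Weighted chi-square of a trait against program knowledge, pooled over sites.

    Tests whether respondents who have ever heard of the program differ from
    those who have not on the given trait, using RDS-II weights normalized to
    mean 1 within site.  Also reports a likelihood-ratio p-value for
    trait-by-site interaction from a weighted logistic model of knowledge.
    """
    df = pooled_respondents(forests)
    known = df["heard_of_program"].notna()
    if known.mean() < min_nonmissing:
        raise EstimationError(
            f"heard_of_program observed for only {known.mean():.0%} of respondents "
            f"(need >= {min_nonmissing:.0%})"
        )
    df = df[known & df[trait].notna() & df["weight"].notna()].copy()
    if df[trait].nunique() < 2:
        raise EstimationError(f"trait {trait!r} has a single category; no contrast to test")
    df["heard"] = df["heard_of_program"].astype(int)
    table = _weighted_table(df, trait, "heard", "weight")
    stat, p = weighted_chi2(table)
    interaction_p = _lr_interaction_p(df, "heard", trait, "weight")
    return TraitComparison(
        trait=trait,
        table=table,
        chi2_stat=stat,
        p_value=p,
        interaction_p=interaction_p,
        n_sites_pooled=df["site_id"].nunique(),
        method="weighted_chi2",
        notes=["weights normalized to mean 1 within site; no design-effect correction"],
    )


def source_comparison(
    rds_attenders: pd.DataFrame,
    program_clients: pd.DataFrame,
    trait: str,
) -> TraitComparison:
    """Weighted logistic comparison of survey-reported attenders vs program clients.

    ``rds_attenders`` holds one row per survey respondent who reported
    attendance, with columns ``site_id``, ``weight`` (mean-1 normalized
    RDS-II) and the trait; ``program_clients`` holds one row per deduplicated
    client with ``site_id`` and the trait (weight 1).  The model regresses the
    source indicator on the trait plus fixed site terms; the trait p-value is
    a joint Wald test, and the interaction p-value a likelihood-ratio test of
    trait-by-site terms.
    """
    a = rds_attenders[[c for c in ("site_id", "weight", trait) if c in rds_attenders.columns]].copy()
    if "weight" not in a.columns:
        a["weight"] = 1.0
    a["source"] = 1
    b = program_clients[[c for c in ("site_id", trait) if c in program_clients.columns]].copy()
    b["weight"] = 1.0
    b["source"] = 0
    df = pd.concat([a, b], ignore_index=True)
    df = df[df[trait].notna() & df["weight"].notna()]
    df[trait] = df[trait].astype(str)
    if df[trait].nunique() < 2:
        raise EstimationError(f"trait {trait!r} has a single category; no contrast to test")
    notes: list[str] = []
    multi_site = df["site_id"].nunique() > 1
    formula = f"source ~ C({trait})" + (" + C(site_id)" if multi_site else "")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM.from_formula(
            formula, data=df, family=sm.families.Binomial(), freq_weights=df["weight"].to_numpy()
        )
        try:
            res = model.fit()
        except Exception as exc:  # complete separation or non-convergence
            raise EstimationError(f"logistic fit failed: {exc}") from exc
    trait_params = [name for name in res.params.index if name.startswith(f"C({trait})")]
    if np.abs(res.params[trait_params]).max() > 15:
        notes.append("possible complete separation: trait coefficient at boundary; p-value unreliable")
    contrast = np.zeros((len(trait_params), len(res.params)))
    for i, name in enumerate(trait_params):
        contrast[i, list(res.params.index).index(name)] = 1.0
    wald = res.wald_test(contrast, scalar=True)
    table = _weighted_table(df, trait, "source", "weight")
    interaction_p = _lr_interaction_p(df, "source", trait, "weight") if multi_site else float("nan")
    return TraitComparison(
        trait=trait,
        table=table.rename(columns={0: "program", 1: "rds"}),
        chi2_stat=float(wald.statistic),
        p_value=float(wald.pvalue),
        interaction_p=interaction_p,
        n_sites_pooled=df["site_id"].nunique(),
        method="weighted_logistic",
        notes=notes or ["RDS rows weighted (mean-1 normalized), program rows unweighted"],
    )
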