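"""Model/results interface tying the pipeline together.

`ServiceMultiplierModel` is constructed from a site's data (recruitment
forest, visit log, site metadata) and `fit()` returns a
`ServiceMultiplierResults` carrying the size estimate, its uncertainty, the
intermediate quantities (M, P and their SEs) and the assumption diagnostics,
with a `summary()` table in the spirit of statsmodels results objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .data import (
    ProgramVisit,
    RecruitmentForest,
    SiteMeta,
    read_program_log,
    read_rds_survey,
    read_site_meta,
)
from .diagnostics import (
    BottleneckSeries,
    ConvergenceSeries,
    HomophilyResult,
    bottleneck_series,
    convergence_series,
    recruitment_homophily,
)
from .multiplier import SizeEstimate, smm_estimate
from .program import ProgramCount, count_unique_attenders, poisson_se
from .rds import WeightedProportion, bootstrap_se, rds2_proportion

__all__ = ["ServiceMultiplierModel", "ServiceMultiplierResults", "estimate_from_summary"]


class ServiceMultiplierModel:
    """Service multiplier population size model for one site.

    Parameters
    ----------
    forest : RecruitmentForest
        The site's RDS recruitment structure.
    visits : sequence of ProgramVisit
        Raw service visit log for the same site.
    meta : SiteMeta
        Survey date, reference-window length, census denominator.
    trait : str
        Binary survey indicator defining P (default the service-attendance
        report, matching the multiplier's definition).
    min_age : int
        Visit-level eligibility cut applied to the service log.
    """

    def __init__(
        self,
        forest: RecruitmentForest,
        visits: Sequence[ProgramVisit],
        meta: SiteMeta,
        trait: str = "attended_program",
        min_age: int = 18,
    ) -> None:
        self.forest = forest
        self.visits = list(visits)
        self.meta = meta
        self.trait = trait
        self.min_age = min_age

    @classmethod
    def from_files(
        cls,
        rds_path,
        visits_path,
        meta_path,
        site_id: str | None = None,
        trait: str = "attended_program",
        min_age: int = 18,
        schema=None,
    ) -> "ServiceMultiplierModel":
        """Build a model for one site from the three flat files."""
        forests = read_rds_survey(rds_path, schema=schema)
        if site_id is None:
            if len(forests) != 1:
                raise ValueError(f"file holds sites {sorted(forests)}; pass site_id")
            site_id = next(iter(forests))
        log = read_program_log(visits_path)
        metas = read_site_meta(meta_path)
        return cls(forests[site_id], log.for_site(site_id), metas[site_id], trait, min_age)

    def fit(
        self, reps: int = 1000, seed: int | None = None, level: float = 0.95
    ) -> "ServiceMultiplierResults":
        """Estimate N = M/P with bootstrap var(P) and delta-method SE.

        ``reps=0`` skips the bootstrap (point estimate only).
        """
        count = count_unique_attenders(self.visits, self.meta, self.min_age)
        if reps:
            wp = bootstrap_se(self.forest, self.trait, reps=reps, seed=seed, level=level)
        else:
            wp = rds2_proportion(self.forest, self.trait)
            wp.se_p = 0.0
        estimate = smm_estimate(count, wp, self.meta, level=level, sample_size=len(self.forest))
        return ServiceMultiplierResults(self, estimate, level)

    def diagnostics(self) -> dict:
        """Convergence, bottleneck (multi-seed only) and homophily checks."""
        out: dict = {
            "convergence": convergence_series(self.forest, self.trait),
            "homophily": recruitment_homophily(self.forest, self.trait),
        }
        if len(self.forest.seeds()) >= 2:
            out["bottleneck"] = bottleneck_series(self.forest, self.trait)
        return out


@dataclass
class ServiceMultiplierResults:
    """Fitted service multiplier estimate for one site."""

    model: ServiceMultiplierModel | None
    estimate: SizeEstimate
    level: float = 0.95

    @property
    def n_hat(self) -> float:
        return self.estimate.n_hat

    @property
    def se_n(self) -> float:
        return self.estimate.se_n

    @property
    def p(self) -> WeightedProportion:
        return self.estimate.p

    @property
    def m(self) -> ProgramCount:
        return self.estimate.m

    def conf_int(self) -> tuple[float, float]:
        return self.estimate.ci_low, self.estimate.ci_high

    def to_row(self) -> dict:
        """One flat record per site (the shape of a published results table)."""
        e = self.estimate
        return {
            "site_id": e.site_id,
            "rds_sample_size": len(self.model.forest) if self.model else None,
            "m": e.m.m,
            "se_m": e.m.se_m,
            "p_pct": 100 * e.p.p_hat,
            "se_p_pct": 100 * e.p.se_p if not math.isnan(e.p.se_p) else None,
            "p_ci_low_pct": 100 * e.p.ci_low if not math.isnan(e.p.ci_low) else None,
            "p_ci_high_pct": 100 * e.p.ci_high if not math.isnan(e.p.ci_high) else None,
            "n_hat": e.n_hat,
            "se_n": e.se_n,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "fsw_density_pct": e.fsw_density_pct,
        }

    def summary(self) -> str:
        e = self.estimate
        pct = int(round(self.level * 100))
        lines = [
            "Service Multiplier Population Size Estimate",
            "=" * 52,
            f"Site:                         {e.site_id}",
        ]
        if self.model is not None:
            lines.append(f"RDS sample size:              {len(self.model.forest)}")
        lines += [
            f"Service count M:              {e.m.m}  (SE {e.m.se_m:.1f})",
            f"Reported use P:               {100 * e.p.p_hat:.1f}%"
            + ("" if math.isnan(e.p.se_p) else f"  (SE {100 * e.p.se_p:.1f}%)"),
            f"Population size N = M/P:      {e.n_hat:.0f}  (SE {e.se_n:.1f})",
            f"{pct}% CI:                      {e.ci_low:.0f} - {e.ci_high:.0f}",
        ]
        if e.fsw_density_pct is not None:
            lines.append(f"Percent of women 15-49:       {e.fsw_density_pct:.1f}%")
        lines.append("-" * 52)
        lines.append("SE(N) by delta method; var(M) Poisson, var(P) chain bootstrap.")
        return "\n".join(lines)


def estimate_from_summary(
    site_id: str,
    m: int,
    p_hat: float,
    se_p: float = float("nan"),
    census_women_15_49: int | None = None,
    level: float = 0.95,
) -> ServiceMultiplierResults:
    """Size estimate from published summary inputs (M and P) alone.

    For re-deriving a results table from printed per-site values when the
    microdata are unavailable: M gets its Poisson SE, P and its SE are taken
    as given, and N, its delta-method SE, CI and census density are computed.
    """
    import datetime as dt

    count = ProgramCount(
        site_id=site_id,
        m=m,
        se_m=poisson_se(m),
        window=(dt.date.min, dt.date.max),
        n_raw_visits=m,
        n_dropped_underage=0,
        n_dropped_out_of_window=0,
    )
    wp = WeightedProportion(p_hat=p_hat, se_p=se_p)
    meta = SiteMeta(
        site_id=site_id,
        survey_date=dt.date(2013, 11, 1),
        window_months=6,
        census_women_15_49=census_women_15_49,
    )
    estimate = smm_estimate(count, wp, meta, level=level, sample_size=None)
    return ServiceMultiplierResults(None, estimate, level)
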