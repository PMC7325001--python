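"""RDS assumption diagnostics: convergence series, bottleneck series, homophily.

Chain-referral estimates start at the purposively chosen seeds and should
"forget" them as waves accumulate.  The convergence series tracks the
cumulative RDS-II estimate of a trait as respondents accrue in interview
order; a series still drifting at the close of the study signals residual
seed dependence.  Bottleneck series compute the same thing per seed tree:
tracks failing to approach a shared value suggest a fragmented network or a
chain stuck in a subgroup.  Recruitment homophily compares observed
recruiter-recruit trait matches with the count expected under random
recruitment; a ratio near 1 is consistent with random mixing on the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import RecruitmentForest
from .rds import EstimationError, TraitSelector, _trait_fn, rds2_proportion

__all__ = [
    "ConvergenceSeries",
    "BottleneckSeries",
    "HomophilyResult",
    "convergence_series",
    "bottleneck_series",
    "recruitment_homophily",
    "plot_convergence",
    "plot_bottleneck",
]


@dataclass
class ConvergenceSeries:
    """Cumulative RDS-II estimates in interview order.

    A prefix with no usable respondent yet (all degrees invalid or trait
    missing) yields NaN.  ``stable`` flags whether every cumulative estimate
    over the last quarter of the sample sits within ``stability_tol`` of the
    final estimate — a numeric stand-in for the visual "has it flattened?"
    judgement.
    """

    site_id: str
    trait: str
    cumulative_n: np.ndarray
    p_hat_cum: np.ndarray
    stability_tol: float = 0.02

    @property
    def final(self) -> float:
        return float(self.p_hat_cum[-1])

    @property
    def stable(self) -> bool:
        tail = self.p_hat_cum[int(np.floor(0.75 * len(self.p_hat_cum))):]
        tail = tail[~np.isnan(tail)]
        if tail.size == 0:
            return False
        return bool(np.max(np.abs(tail - self.final)) < self.stability_tol)


@dataclass
class BottleneckSeries:
    """One convergence series per seed, each over that seed's tree only."""

    site_id: str
    trait: str
    per_seed: dict[str, ConvergenceSeries] = field(default_factory=dict)

    @property
    def final_spread(self) -> float:
        finals = [s.final for s in self.per_seed.values() if not np.isnan(s.final)]
        return float(max(finals) - min(finals)) if finals else float("nan")


@dataclass(frozen=True)
class HomophilyResult:
    """Recruitment homophily: observed over chance-expected trait matches."""

    site_id: str
    trait: str
    h: float
    n_pairs: int
    observed_matches: int
    expected_matches: float


def _ordered(forest: RecruitmentForest):
    return sorted(forest, key=lambda r: (r.recruitment_order, r.respondent_id))


def _cumulative(forest: RecruitmentForest, respondents, trait: TraitSelector, trait_name: str):
    fn = _trait_fn(trait)
    n = len(respondents)
    cum_n = np.arange(1, n + 1)
    p_cum = np.full(n, np.nan)
    num = den = 0.0
    for i, r in enumerate(respondents):
        if r.degree and r.degree >= 1:
            y = fn(r)
            if y is not None:
                den += 1.0 / r.degree
                num += float(y) / r.degree
        if den > 0:
            p_cum[i] = num / den
    return ConvergenceSeries(forest.site_id, trait_name, cum_n, p_cum)


def convergence_series(forest: RecruitmentForest, trait: TraitSelector) -> ConvergenceSeries:
    """Cumulative RDS-II estimate over the whole site, in interview order.

    Ties in recruitment order break lexicographically on respondent id.  The
    final value equals :func:`rdsmm.rds.rds2_proportion` on the full sample.
    """
    name = trait if isinstance(trait, str) else getattr(trait, "__name__", "trait")
    return _cumulative(forest, _ordered(forest), trait, name)


def bottleneck_series(forest: RecruitmentForest, trait: TraitSelector) -> BottleneckSeries:
    """Per-seed cumulative estimates; requires >= 2 seeds."""
    seeds = forest.seeds()
    if len(seeds) < 2:
        raise EstimationError(
            "bottleneck series needs >= 2 seeds; use convergence_series for a single chain"
        )
    name = trait if isinstance(trait, str) else getattr(trait, "__name__", "trait")
    result = BottleneckSeries(forest.site_id, name)
    for seed in seeds:
        tree_ids = set(forest.subtree_ids(seed.respondent_id))
        members = [r for r in _ordered(forest) if r.respondent_id in tree_ids]
        result.per_seed[seed.respondent_id] = _cumulative(forest, members, trait, name)
    return result


def recruitment_homophily(forest: RecruitmentForest, trait: TraitSelector) -> HomophilyResult:
    """Ratio of observed recruiter-recruit trait matches to those expected by chance.

    Expected matches use the recruit-side marginal prevalence q: a recruiter
    with the trait is matched by chance with probability q, one without it
    with probability 1-q.  h = 1 indicates random mixing; h > 1 means
    recruiters preferentially recruited their own kind.
    """
    fn = _trait_fn(trait)
    pairs: list[tuple[bool, bool]] = []  # (recruiter status, recruit status)
    for r in forest:
        if r.recruiter_id is None:
            continue
        y_recruit = fn(r)
        y_recruiter = fn(forest[r.recruiter_id])
        if y_recruit is None or y_recruiter is None:
            continue
        pairs.append((y_recruiter, y_recruit))
    if not pairs:
        raise EstimationError("no recruiter-recruit pair with both trait values observed")
    q = sum(y for _, y in pairs) / len(pairs)
    observed = sum(a == b for a, b in pairs)
    expected = sum(q if a else (1.0 - q) for a, _ in pairs)
    if expected == 0:
        raise EstimationError("expected matches is zero; homophily undefined")
    name = trait if isinstance(trait, str) else getattr(trait, "__name__", "trait")
    return HomophilyResult(
        site_id=forest.site_id,
        trait=name,
        h=observed / expected,
        n_pairs=len(pairs),
        observed_matches=observed,
        expected_matches=expected,
    )


# -- plotting -----------------------------------------------------------------


def plot_convergence(series: ConvergenceSeries, ax=None):
    """Cumulative RDS-II estimate vs cumulative sample size."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(series.cumulative_n, series.p_hat_cum, lw=1.5)
    ax.axhline(series.final, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("Cumulative sample size")
    ax.set_ylabel(f"Cumulative RDS-II estimate of {series.trait}")
    ax.set_title(f"Site {series.site_id} convergence")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_bottleneck(series: BottleneckSeries, ax=None):
    """Per-seed cumulative RDS-II estimates on one axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for seed_id, s in series.per_seed.items():
        ax.plot(s.cumulative_n, s.p_hat_cum, lw=1.2, label=f"seed {seed_id}")
    ax.set_xlabel("Cumulative sample size (within seed tree)")
    ax.set_ylabel(f"Cumulative RDS-II estimate of {series.trait}")
    ax.set_title(f"Site {series.site_id} bottleneck")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize="small")
    return ax
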