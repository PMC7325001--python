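"""RDS-II (Volz-Heckathorn) proportion estimation with chain-bootstrap uncertainty.

RDS recruits over the social network, so high-degree individuals are
over-sampled roughly in proportion to their degree.  The RDS-II estimator
corrects this with inverse-degree weights:

    p_hat = sum_{i: y_i = 1} 1/d_i  /  sum_i 1/d_i

Uncertainty comes from a tree bootstrap: seeds are resampled with replacement
and each recruitment chain is regrown by resampling recruits with replacement
at every node, preserving the dependence structure of chain-referral data that
an iid bootstrap would ignore.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data import RDSRespondent, RecruitmentForest

__all__ = [
    "WeightedProportion",
    "EstimationError",
    "rds2_proportion",
    "bootstrap_se",
    "rds2_weights",
]

TraitSelector = str | Callable[[RDSRespondent], bool | None]


class EstimationError(ValueError):
    """Raised when the weighted estimate is undefined for the given data."""


@dataclass
class WeightedProportion:
    """An RDS-II weighted proportion P with its uncertainty.

    ``weights`` are the normalized inclusion weights (summing to 1 over the
    ``n_used`` respondents that entered the estimate).
    """

    p_hat: float
    se_p: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_used: int = 0
    weights: dict[str, float] = field(default_factory=dict)
    n_excluded_degree: int = 0
    n_excluded_trait: int = 0


def _trait_fn(trait: TraitSelector) -> Callable[[RDSRespondent], bool | None]:
    if callable(trait):
        return trait
    name = trait

    def fn(r: RDSRespondent) -> bool | None:
        v = r.trait_value(name)
        if v is None:
            return None
        if isinstance(v, bool):
            return v
        return str(v).strip().lower() in ("1", "true", "yes", "y")

    return fn


def _included(forest: RecruitmentForest, trait: TraitSelector):
    """Respondents usable for estimation: valid degree and observed trait."""
    fn = _trait_fn(trait)
    rows: list[tuple[RDSRespondent, bool]] = []
    n_bad_degree = n_bad_trait = 0
    for r in forest:
        if r.degree is None or r.degree < 1:
            n_bad_degree += 1
            continue
        y = fn(r)
        if y is None:
            n_bad_trait += 1
            continue
        rows.append((r, y))
    return rows, n_bad_degree, n_bad_trait


def rds2_proportion(forest: RecruitmentForest, trait: TraitSelector) -> WeightedProportion:
    """Point estimate of the trait prevalence under RDS-II weighting.

    Seeds are included.  Respondents with missing/zero degree or a missing
    trait are excluded and counted.  Raises :class:`EstimationError` when no
    respondent is usable.
    """
    rows, n_bad_degree, n_bad_trait = _included(forest, trait)
    if not rows:
        raise EstimationError(
            f"site {forest.site_id}: no respondent with valid degree and observed trait"
        )
    inv = np.array([1.0 / r.degree for r, _ in rows])
    y = np.array([yi for _, yi in rows], dtype=float)
    denom = inv.sum()
    p_hat = float((inv * y).sum() / denom)
    weights = {r.respondent_id: float(w / denom) for (r, _), w in zip(rows, inv)}
    return WeightedProportion(
        p_hat=p_hat,
        n_used=len(rows),
        weights=weights,
        n_excluded_degree=n_bad_degree,
        n_excluded_trait=n_bad_trait,
    )


def rds2_weights(forest: RecruitmentForest, normalize: str = "mean1") -> dict[str, float]:
    """Inverse-degree weights for respondents with a valid degree.

    ``normalize="mean1"`` rescales to mean 1 within the site (the convention
    used when pooling sites for cross-source regressions); ``"sum1"`` rescales
    to sum 1.
    """
    inv = {r.respondent_id: 1.0 / r.degree for r in forest if r.degree and r.degree >= 1}
    if not inv:
        raise EstimationError(f"site {forest.site_id}: all degrees missing or zero")
    total = sum(inv.values())
    if normalize == "sum1":
        return {k: v / total for k, v in inv.items()}
    if normalize == "mean1":
        mean = total / len(inv)
        return {k: v / mean for k, v in inv.items()}
    raise ValueError(f"unknown normalization {normalize!r}")


# -- tree bootstrap -----------------------------------------------------------


def _regrow(
    forest: RecruitmentForest,
    node_id: str,
    rng: np.random.Generator,
    out: list[str],
    cap: int,
) -> None:
    """Regrow one chain: emit the node, then recurse into a with-replacement
    resample of its recruits (same brood size as observed)."""
    stack = [node_id]
    while stack and len(out) < cap:
        nid = stack.pop()
        out.append(nid)
        kids = forest._children[nid]
        if kids:
            picks = rng.integers(0, len(kids), size=len(kids))
            stack.extend(kids[i] for i in picks)


def bootstrap_se(
    forest: RecruitmentForest,
    trait: TraitSelector,
    reps: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> WeightedProportion:
    """Tree-bootstrap SE and percentile CI for the RDS-II proportion.

    Each replicate resamples the seeds with replacement and regrows every
    chain by resampling recruits with replacement at each node.  Replicate
    size is capped at 4x the observed sample to bound the (rare) growth that
    duplicated subtrees can cause.  Deterministic given ``seed``.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if len(forest) < 2:
        raise EstimationError("bootstrap needs at least 2 respondents")
    point = rds2_proportion(forest, trait)
    fn = _trait_fn(trait)
    rng = np.random.default_rng(seed)
    seed_ids = [r.respondent_id for r in forest.seeds()]
    cap = 4 * len(forest)

    # precompute per-respondent (1/d, y) for fast accumulation
    contrib: dict[str, tuple[float, float]] = {}
    for r in forest:
        if r.degree and r.degree >= 1:
            y = fn(r)
            if y is not None:
                contrib[r.respondent_id] = (1.0 / r.degree, float(y))

    estimates = np.empty(reps)
    for b in range(reps):
        for _attempt in range(100):
            sample: list[str] = []
            picks = rng.integers(0, len(seed_ids), size=len(seed_ids))
            for i in picks:
                _regrow(forest, seed_ids[i], rng, sample, cap)
            num = den = 0.0
            for rid in sample:
                c = contrib.get(rid)
                if c is not None:
                    den += c[0]
                    num += c[0] * c[1]
            if den > 0:
                estimates[b] = num / den
                break
        else:  # pragma: no cover - requires pathological data
            raise EstimationError("bootstrap failed: no usable respondents drawn in 100 attempts")

    alpha = 1.0 - level
    point.se_p = float(np.std(estimates, ddof=1))
    point.ci_low = float(np.quantile(estimates, alpha / 2))
    point.ci_high = float(np.quantile(estimates, 1 - alpha / 2))
    return point
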