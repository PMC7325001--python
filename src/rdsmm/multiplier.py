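"""The service multiplier estimate N = M / P with delta-method uncertainty.

M is the deduplicated count of service users in the reference window and P the
RDS-II weighted proportion of survey respondents reporting service use in the
same window.  First-order (delta-method) propagation of the two variances
gives

    var(N) = var(M)/mu_p^2 + mu_m^2 * var(P) / mu_p^4

with var(M) = M under the Poisson assumption and var(P) from the chain
bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

from .data import SiteMeta
from .program import ProgramCount
from .rds import EstimationError, WeightedProportion

__all__ = ["SizeEstimate", "smm_estimate", "delta_se", "normal_ci"]


@dataclass(frozen=True)
class SizeEstimate:
    """Population size estimate with its uncertainty and all inputs."""

    site_id: str
    n_hat: float
    se_n: float
    ci_low: float
    ci_high: float
    p: WeightedProportion
    m: ProgramCount
    fsw_density_pct: float | None = None

    @property
    def n_hat_rounded(self) -> int:
        return round(self.n_hat)


def delta_se(m: ProgramCount, p: WeightedProportion) -> float:
    """Delta-method SE of M/P combining Poisson var(M)=M and var(P)=se_p^2."""
    if p.p_hat <= 0:
        raise EstimationError("p_hat must be positive")
    var_m = m.se_m**2
    var_p = 0.0 if math.isnan(p.se_p) else p.se_p**2
    var_n = var_m / p.p_hat**2 + (m.m**2) * var_p / p.p_hat**4
    return math.sqrt(var_n)


def normal_ci(n_hat: float, se_n: float, level: float = 0.95) -> tuple[float, float]:
    """Symmetric normal interval, lower bound truncated at zero."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    return max(0.0, n_hat - z * se_n), n_hat + z * se_n


def smm_estimate(
    m: ProgramCount,
    p: WeightedProportion,
    meta: SiteMeta | None = None,
    level: float = 0.95,
    sample_size: int | None = None,
) -> SizeEstimate:
    """Combine a program count and an RDS-II proportion into a size estimate.

    ``meta`` supplies the census denominator for the population-density
    percentage; ``sample_size`` (the RDS sample size) triggers a warning when
    the estimate falls below it, which is logically impossible.
    """
    if p.p_hat <= 0:
        raise EstimationError(
            "p_hat = 0: no survey respondent reports service use (no overlap between sources)"
        )
    n_hat = m.m / p.p_hat
    se_n = delta_se(m, p)
    ci_low, ci_high = normal_ci(n_hat, se_n, level)
    density = None
    if meta is not None and meta.census_women_15_49:
        density = 100.0 * n_hat / meta.census_women_15_49
    n_sample = sample_size if sample_size is not None else p.n_used
    if n_sample and n_hat < n_sample:
        warnings.warn(
            f"site {m.site_id}: estimated population ({n_hat:.0f}) is below the "
            f"RDS sample size ({n_sample}); the estimate is logically impossible",
            stacklevel=2,
        )
    return SizeEstimate(
        site_id=m.site_id,
        n_hat=n_hat,
        se_n=se_n,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        m=m,
        fsw_density_pct=density,
    )
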