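"""Published per-site summary inputs from the 2013 nine-site Zimbabwe FSW study.

These are the printed inputs of the multiplier calculation — RDS sample size,
the deduplicated six-month program count M, the RDS-II weighted percentage P
reporting program use (with its printed SE), and the 2012 census count of
women aged 15-49 — for the nine small-town sites where the *Sisters with a
Voice* program operated alongside the survey.  They allow the full results
table (N, SE, CI, density) to be re-derived from summary data when the
microdata are unavailable; see :func:`rdsmm.model.estimate_from_summary`.

Note: site 1's printed SE for M (7.4) is inconsistent with the Poisson rule
sqrt(57) = 7.55 used everywhere else; the package always computes sqrt(M).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SiteSummary", "ZIMBABWE_2013"]


@dataclass(frozen=True)
class SiteSummary:
    site_id: str
    rds_sample_size: int
    m: int
    p_pct: float  # printed RDS-II weighted % reporting program use
    se_p_pct: float  # printed SE of that percentage
    census_women_15_49: int


ZIMBABWE_2013: dict[str, SiteSummary] = {
    s.site_id: s
    for s in (
        SiteSummary("1", 220, 57, 20.3, 4.5, 33302),
        SiteSummary("2", 196, 100, 25.0, 4.9, 8399),
        SiteSummary("3", 153, 111, 46.1, 5.7, 8694),
        SiteSummary("4", 202, 372, 68.7, 4.0, 15407),
        SiteSummary("5", 197, 84, 20.6, 7.8, 10329),
        SiteSummary("6", 200, 28, 14.3, 4.2, 7484),
        SiteSummary("7", 165, 34, 11.0, 1.9, 26745),
        SiteSummary("8", 198, 46, 16.7, 4.8, 9085),
        SiteSummary("9", 208, 165, 20.5, 4.2, 30633),
    )
}
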