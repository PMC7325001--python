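"""Service-side arithmetic: deduplicate the visit log into the multiplier count M.

M is the number of distinct clients with at least one eligible visit inside the
reference window.  Visits are assumed to arrive at a constant rate, so M is
treated as Poisson and its standard error is sqrt(M).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable

from .data import ProgramVisit, SiteMeta

__all__ = ["ProgramCount", "count_unique_attenders", "poisson_se"]


@dataclass(frozen=True)
class ProgramCount:
    """Deduplicated windowed service count with its Poisson SE and drop audit."""

    site_id: str
    m: int
    se_m: float
    window: tuple[dt.date, dt.date]
    n_raw_visits: int
    n_dropped_underage: int
    n_dropped_out_of_window: int
    n_dropped_missing_id: int = 0


def poisson_se(m: int) -> float:
    """SE of a Poisson count with mean m: sqrt(m)."""
    if m < 0:
        raise ValueError("count must be non-negative")
    return math.sqrt(m)


def count_unique_attenders(
    visits: Iterable[ProgramVisit],
    meta: SiteMeta,
    min_age: int = 18,
) -> ProgramCount:
    """Count distinct clients with an in-window visit at age >= ``min_age``.

    The window is the half-open interval [survey_date - window_months,
    survey_date).  A client counts if *any* of her in-window visits meets the
    age cut; under-age visits are eligibility-filtered per visit, mirroring the
    survey's own >=18 criterion.  Drop counts are per visit, not per client.
    """
    start, end = meta.window
    if start >= end:
        raise ValueError(f"empty reference window {start}..{end}")
    eligible_clients: set[str] = set()
    n_raw = n_underage = n_out = n_missing = 0
    for v in visits:
        n_raw += 1
        if not v.client_id:
            n_missing += 1
            continue
        if v.site_id != meta.site_id:
            raise ValueError(f"visit by {v.client_id} is from site {v.site_id}, expected {meta.site_id}")
        if not (start <= v.visit_date < end):
            n_out += 1
            continue
        if v.age_at_visit < min_age:
            n_underage += 1
            continue
        eligible_clients.add(v.client_id)
    m = len(eligible_clients)
    return ProgramCount(
        site_id=meta.site_id,
        m=m,
        se_m=poisson_se(m),
        window=(start, end),
        n_raw_visits=n_raw,
        n_dropped_underage=n_underage,
        n_dropped_out_of_window=n_out,
        n_dropped_missing_id=n_missing,
    )
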