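"""Domain types and flat-file I/O for RDS surveys, program visit logs and site metadata.

An RDS (respondent-driven sampling) survey is a chain-referral sample: a few
purposively chosen *seeds* (wave 0) each receive a small number of coupons and
recruit peers, who recruit further peers, and so on.  The recruitment structure
is therefore a forest, one tree per seed.  Each respondent reports a personal
network size (*degree*), which RDS-II estimation uses as an inverse inclusion
weight, plus binary service-use indicators and categorical traits.

The service side is a visit log: one row per clinic visit with a stable client
identifier, visit date and age at visit; extra columns are kept as categorical
traits so client demographics can be compared against the survey.
"""

from __future__ import annotations

import calendar
import csv
import datetime as dt
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RDSRespondent",
    "RecruitmentForest",
    "ProgramVisit",
    "ProgramLog",
    "SiteMeta",
    "StructuralError",
    "read_rds_survey",
    "write_rds_survey",
    "read_program_log",
    "write_program_log",
    "read_site_meta",
    "write_site_meta",
    "shift_months",
]


class StructuralError(ValueError):
    """Recruitment structure violates forest invariants (cycle, dangling link, ...)."""


# Canonical survey columns; anything else in the file becomes a trait.
_RDS_COLUMNS = (
    "respondent_id",
    "recruiter_id",
    "site_id",
    "wave",
    "recruitment_order",
    "degree",
    "attended_program",
    "heard_of_program",
)

_VISIT_COLUMNS = ("client_id", "site_id", "visit_date", "age_at_visit")

_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n"}


def _parse_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("", "na", "nan", "none"):
        return None
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def shift_months(date: dt.date, months: int) -> dt.date:
    """Shift a date by whole calendar months, clamping the day to month end."""
    month_index = date.year * 12 + (date.month - 1) + months
    year, month = divmod(month_index, 12)
    month += 1
    day = min(date.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


@dataclass
class RDSRespondent:
    """One surveyed individual.

    ``degree`` is the reported personal network size d_i — the number of
    eligible peers the respondent would consider recruiting — and drives the
    RDS-II weight 1/d_i.  ``recruiter_id`` is None exactly for seeds (wave 0).
    """

    respondent_id: str
    site_id: str
    recruiter_id: str | None = None
    wave: int = 0
    recruitment_order: int = 0
    degree: int | None = None
    attended_program: bool | None = None
    heard_of_program: bool | None = None
    traits: dict[str, str] = field(default_factory=dict)

    @property
    def is_seed(self) -> bool:
        return self.recruiter_id is None

    def trait_value(self, name: str) -> bool | str | None:
        if name in ("attended_program", "heard_of_program"):
            return getattr(self, name)
        return self.traits.get(name)


@dataclass
class RecruitmentForest:
    """A site's full coupon-chain structure: seeds and their recruitment trees."""

    site_id: str
    respondents: list[RDSRespondent]
    max_coupons: int = 2

    def __post_init__(self) -> None:
        self._by_id = {r.respondent_id: r for r in self.respondents}
        if len(self._by_id) != len(self.respondents):
            seen: set[str] = set()
            dupes = sorted(
                {r.respondent_id for r in self.respondents if r.respondent_id in seen or seen.add(r.respondent_id)}
            )
            raise StructuralError(f"duplicate respondent ids in site {self.site_id}: {dupes}")
        self._children: dict[str, list[str]] = {r.respondent_id: [] for r in self.respondents}
        for r in self.respondents:
            if r.recruiter_id is not None:
                if r.recruiter_id not in self._by_id:
                    raise StructuralError(
                        f"respondent {r.respondent_id!r} names unknown recruiter {r.recruiter_id!r}"
                    )
                self._children[r.recruiter_id].append(r.respondent_id)
        self._recompute_waves()
        self.validate()

    # -- structure -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.respondents)

    def __iter__(self) -> Iterator[RDSRespondent]:
        return iter(self.respondents)

    def __getitem__(self, respondent_id: str) -> RDSRespondent:
        return self._by_id[respondent_id]

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [(r.recruiter_id, r.respondent_id) for r in self.respondents if r.recruiter_id is not None]

    def seeds(self) -> list[RDSRespondent]:
        return [r for r in self.respondents if r.is_seed]

    def children(self, respondent_id: str) -> list[RDSRespondent]:
        return [self._by_id[c] for c in self._children[respondent_id]]

    def subtree_ids(self, seed_id: str) -> list[str]:
        """All respondents in the tree rooted at ``seed_id`` (BFS order)."""
        out: list[str] = []
        queue = deque([seed_id])
        while queue:
            rid = queue.popleft()
            out.append(rid)
            queue.extend(self._children[rid])
        return out

    def _recompute_waves(self) -> None:
        # BFS depth from each seed; detects cycles (unvisited nodes with recruiters).
        depth: dict[str, int] = {}
        queue = deque(r.respondent_id for r in self.respondents if r.is_seed)
        for rid in queue:
            depth[rid] = 0
        while queue:
            rid = queue.popleft()
            for child in self._children[rid]:
                depth[child] = depth[rid] + 1
                queue.append(child)
        unreached = [r.respondent_id for r in self.respondents if r.respondent_id not in depth]
        if unreached:
            raise StructuralError(
                f"cycle in recruitment links at site {self.site_id}: "
                f"respondents {sorted(unreached)} are not reachable from any seed"
            )
        for r in self.respondents:
            if r.wave and r.wave != depth[r.respondent_id]:
                logger.warning(
                    "site %s: supplied wave %d for %s disagrees with recruiter-link depth %d; using the latter",
                    self.site_id,
                    r.wave,
                    r.respondent_id,
                    depth[r.respondent_id],
                )
            r.wave = depth[r.respondent_id]

    def validate(self) -> None:
        for r in self.respondents:
            if r.is_seed != (r.wave == 0):
                raise StructuralError(f"respondent {r.respondent_id}: wave/seed mismatch")
            if len(self._children[r.respondent_id]) > self.max_coupons:
                raise StructuralError(
                    f"respondent {r.respondent_id} has "
                    f"{len(self._children[r.respondent_id])} recruits (> {self.max_coupons} coupons)"
                )
            if r.recruiter_id is not None:
                rec = self._by_id[r.recruiter_id]
                if rec.recruitment_order >= r.recruitment_order:
                    raise StructuralError(
                        f"recruiter {rec.respondent_id} interviewed after recruit {r.respondent_id}"
                    )


@dataclass(frozen=True)
class ProgramVisit:
    """One row of the service-program visit log."""

    client_id: str
    site_id: str
    visit_date: dt.date
    age_at_visit: int
    traits: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.client_id:
            raise ValueError("client_id must be non-empty")

    def trait_value(self, name: str) -> str | None:
        return dict(self.traits).get(name)


@dataclass
class ProgramLog:
    """Parsed visit log plus bookkeeping on rows dropped at read time."""

    visits: list[ProgramVisit]
    n_dropped_missing_id: int = 0

    def __len__(self) -> int:
        return len(self.visits)

    def __iter__(self) -> Iterator[ProgramVisit]:
        return iter(self.visits)

    def for_site(self, site_id: str) -> list[ProgramVisit]:
        return [v for v in self.visits if v.site_id == site_id]


@dataclass(frozen=True)
class SiteMeta:
    """Per-site reference data: survey date, recall-window length, census denominator."""

    site_id: str
    survey_date: dt.date
    window_months: int = 6
    census_women_15_49: int | None = None

    def __post_init__(self) -> None:
        if self.window_months <= 0:
            raise ValueError("window_months must be positive")

    @property
    def window(self) -> tuple[dt.date, dt.date]:
        """Half-open reference interval [survey_date - window_months, survey_date)."""
        return shift_months(self.survey_date, -self.window_months), self.survey_date


# -- readers / writers --------------------------------------------------------


def _apply_schema(df: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return df


def read_rds_survey(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    max_coupons: int = 2,
) -> dict[str, RecruitmentForest]:
    """Read an RDS survey flat file into per-site recruitment forests.

    ``schema`` maps canonical column names (``respondent_id``, ``recruiter_id``,
    ``site_id``, ``degree``, ``attended_program``, ``heard_of_program``,
    ``recruitment_order``, ``wave``) to the file's column names, so external
    exports can be adapted without editing the file.  Columns not in the
    canonical set are retained as categorical traits.  Waves are recomputed
    from recruiter links and checked against any supplied wave column.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = _apply_schema(pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False), schema)
    for col in ("respondent_id", "recruiter_id", "site_id", "degree"):
        if col not in df.columns:
            raise ValueError(f"survey file {path} lacks required column {col!r}")
    trait_cols = [c for c in df.columns if c not in _RDS_COLUMNS]

    forests: dict[str, RecruitmentForest] = {}
    n_missing_degree = 0
    for site_id, site_df in df.groupby("site_id", sort=True):
        respondents = []
        for order, (_, row) in enumerate(site_df.iterrows()):
            raw_degree = str(row["degree"]).strip()
            degree = int(float(raw_degree)) if raw_degree not in ("", "na", "nan", "none", "NA") else None
            if degree is None:
                n_missing_degree += 1
            respondents.append(
                RDSRespondent(
                    respondent_id=str(row["respondent_id"]).strip(),
                    site_id=str(site_id),
                    recruiter_id=(str(row["recruiter_id"]).strip() or None),
                    wave=int(row["wave"]) if "wave" in row and str(row["wave"]).strip() else 0,
                    recruitment_order=(
                        int(row["recruitment_order"])
                        if "recruitment_order" in row and str(row["recruitment_order"]).strip()
                        else order
                    ),
                    degree=degree,
                    attended_program=_parse_bool(row.get("attended_program")),
                    heard_of_program=_parse_bool(row.get("heard_of_program")),
                    traits={c: str(row[c]) for c in trait_cols if str(row[c]).strip()},
                )
            )
        forests[str(site_id)] = RecruitmentForest(str(site_id), respondents, max_coupons=max_coupons)
    if n_missing_degree:
        logger.warning("%d respondents have missing degree; they are excluded from weighted estimation", n_missing_degree)
    return forests


def write_rds_survey(forests: Iterable[RecruitmentForest], path: str | Path) -> None:
    """Write forests to RFC-4180 CSV readable by :func:`read_rds_survey`."""
    forests = list(forests)
    trait_names = sorted({t for f in forests for r in f for t in r.traits})
    fields = list(_RDS_COLUMNS) + trait_names
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for forest in forests:
            for r in forest:
                row = {
                    "respondent_id": r.respondent_id,
                    "recruiter_id": r.recruiter_id or "",
                    "site_id": r.site_id,
                    "wave": r.wave,
                    "recruitment_order": r.recruitment_order,
                    "degree": "" if r.degree is None else r.degree,
                    "attended_program": "" if r.attended_program is None else int(r.attended_program),
                    "heard_of_program": "" if r.heard_of_program is None else int(r.heard_of_program),
                }
                row.update({t: r.traits.get(t, "") for t in trait_names})
                writer.writerow(row)


def read_program_log(path: str | Path, schema: Mapping[str, str] | None = None) -> ProgramLog:
    """Read a visit log.  Rows with an empty client_id are dropped and counted;
    an unparseable date raises with the offending line number."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = _apply_schema(pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False), schema)
    for col in ("client_id", "site_id", "visit_date", "age_at_visit"):
        if col not in df.columns:
            raise ValueError(f"visit log {path} lacks required column {col!r}")
    trait_cols = [c for c in df.columns if c not in _VISIT_COLUMNS]

    visits: list[ProgramVisit] = []
    n_missing = 0
    for idx, row in df.iterrows():
        cid = str(row["client_id"]).strip()
        if not cid:
            n_missing += 1
            continue
        line_no = int(idx) + 2  # header is line 1
        try:
            date = dt.date.fromisoformat(str(row["visit_date"]).strip())
        except ValueError as exc:
            raise ValueError(f"{path} line {line_no}: bad visit_date {row['visit_date']!r}: {exc}") from None
        try:
            age = int(float(row["age_at_visit"]))
        except ValueError:
            raise ValueError(f"{path} line {line_no}: bad age_at_visit {row['age_at_visit']!r}") from None
        visits.append(
            ProgramVisit(
                client_id=cid,
                site_id=str(row["site_id"]).strip(),
                visit_date=date,
                age_at_visit=age,
                traits=tuple((c, str(row[c])) for c in trait_cols if str(row[c]).strip()),
            )
        )
    if n_missing:
        logger.warning("visit log %s: dropped %d rows with empty client_id", path, n_missing)
    return ProgramLog(visits=visits, n_dropped_missing_id=n_missing)


def write_program_log(log: ProgramLog | Sequence[ProgramVisit], path: str | Path) -> None:
    visits = list(log)
    trait_names = sorted({k for v in visits for k, _ in v.traits})
    fields = list(_VISIT_COLUMNS) + trait_names
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for v in visits:
            row = {
                "client_id": v.client_id,
                "site_id": v.site_id,
                "visit_date": v.visit_date.isoformat(),
                "age_at_visit": v.age_at_visit,
            }
            row.update({k: val for k, val in v.traits})
            writer.writerow(row)


def read_site_meta(path: str | Path) -> dict[str, SiteMeta]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    metas: dict[str, SiteMeta] = {}
    for _, row in df.iterrows():
        census = str(row.get("census_women_15_49", "")).strip()
        metas[str(row["site_id"])] = SiteMeta(
            site_id=str(row["site_id"]),
            survey_date=dt.date.fromisoformat(str(row["survey_date"]).strip()),
            window_months=int(row.get("window_months", 6) or 6),
            census_women_15_49=int(float(census)) if census else None,
        )
    return metas


def write_site_meta(metas: Iterable[SiteMeta], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["site_id", "survey_date", "window_months", "census_women_15_49"])
        for m in metas:
            writer.writerow(
                [m.site_id, m.survey_date.isoformat(), m.window_months, m.census_women_15_49 or ""]
            )
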