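import datetime as dt

import pytest

from rdsmm.data import ProgramVisit, RDSRespondent, RecruitmentForest, SiteMeta


def make_respondent(
    rid,
    recruiter=None,
    site="s1",
    order=0,
    degree=5,
    attended=None,
    heard=None,
    traits=None,
):
    return RDSRespondent(
        respondent_id=rid,
        site_id=site,
        recruiter_id=recruiter,
        wave=0,
        recruitment_order=order,
        degree=degree,
        attended_program=attended,
        heard_of_program=heard,
        traits=traits or {},
    )


def make_forest(rows, site="s1", max_coupons=2):
    """rows: iterable of (rid, recruiter, degree, attended) in interview order."""
    respondents = [
        make_respondent(rid, recruiter, site=site, order=i, degree=deg, attended=att)
        for i, (rid, recruiter, deg, att) in enumerate(rows)
    ]
    return RecruitmentForest(site, respondents, max_coupons=max_coupons)


@pytest.fixture
def chain_forest():
    """One seed, chain of 3 recruits, mixed trait."""
    return make_forest(
        [("a", None, 2, True), ("b", "a", 4, False), ("c", "b", 1, True), ("d", "c", 2, False)]
    )


@pytest.fixture
def site_meta():
    return SiteMeta(site_id="s1", survey_date=dt.date(2013, 11, 1), window_months=6, census_women_15_49=8399)


def make_visit(cid, date, age=25, site="s1", traits=()):
    return ProgramVisit(client_id=cid, site_id=site, visit_date=date, age_at_visit=age, traits=tuple(traits))
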