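"""Synthetic networked populations, coupon-chain RDS samples and visit logs.

The generator produces the three inputs the estimation pipeline consumes —
an RDS recruitment forest, a program visit log and site metadata — from a
population with known ground truth, so that every stage can be tested for
recovery and for the direction of bias under assumption violations.

The population is an undirected social network with a heavy-tailed
(negative-binomial) degree distribution wired by a configuration model; a
binary service-attendance trait is assigned independently of degree.  A
homophily dial rewires cross-group edges into within-group edges, making the
network trait-assortative without changing the degree sequence.  RDS
recruitment then mimics field practice: purposively chosen seeds, a fixed
number of coupons, random recruitment among *unsampled* neighbours (sampling
without replacement — deliberately violating the estimator's
with-replacement assumption, exactly as real surveys do), a wave cap and a
target sample size.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .data import ProgramVisit, RDSRespondent, RecruitmentForest, SiteMeta

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_population",
    "simulate_rds",
    "simulate_program_log",
    "simulate_study",
]

_DEFAULT_SURVEY_DATE = dt.date(2013, 11, 1)


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of a synthetic study site.

    Defaults mirror the field design the package targets: 6 seeds, 2 coupons
    per respondent, 5 recruitment waves after the seeds, and a target sample
    of roughly 200 from a small-town hidden population.
    """

    n_true: int = 500  # true population size
    p_true: float = 0.3  # true attendance prevalence
    mean_degree: float = 10.0  # mean personal network size
    degree_dispersion: float = 3.0  # negative-binomial shape (smaller = heavier tail)
    trait_homophily: float = 0.0  # excess within-group edge propensity (0 = none)
    n_seeds: int = 6
    seed_policy: str = "uniform"  # or "attender_biased"
    seed_attender_prob: float = 5.0 / 6.0  # P(seed is an attender) under attender_biased
    coupons_per_respondent: int = 2
    coupon_return_prob: float = 0.9
    target_sample: int = 200
    max_waves: int = 5
    visit_rate: float = 2.0  # mean program visits per attender in the window
    underage_frac: float = 0.0  # extra under-18 clients as a fraction of attenders
    rng_seed: int = 0
    site_id: str = "sim"

    def __post_init__(self) -> None:
        if self.target_sample > self.n_true:
            raise ValueError("target_sample cannot exceed n_true")
        if self.n_seeds < 1:
            raise ValueError("need at least one seed")
        if not 0 < self.coupon_return_prob <= 1:
            raise ValueError("coupon_return_prob must be in (0, 1]")
        if self.seed_policy not in ("uniform", "attender_biased"):
            raise ValueError(f"unknown seed_policy {self.seed_policy!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class SimTruth:
    """Realized ground truth attached to a synthetic site."""

    config: SimConfig
    degrees: np.ndarray
    attendance: np.ndarray  # boolean per person
    largest_cc_frac: float

    @property
    def n_attenders(self) -> int:
        return int(self.attendance.sum())

    @property
    def realized_prevalence(self) -> float:
        return float(self.attendance.mean())

    def write_sidecar(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "n_attenders": self.n_attenders,
            "realized_prevalence": self.realized_prevalence,
            "mean_degree_realized": float(self.degrees.mean()),
            "largest_cc_frac": self.largest_cc_frac,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, stream])


def simulate_population(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[nx.Graph, SimTruth]:
    """Draw the social network and the attendance trait.

    Degrees are negative-binomial (clamped to >= 1) wired by a configuration
    model; self-loops and parallel edges are discarded.  When
    ``trait_homophily`` h > 0, a fraction h/(1+h) of cross-group edges are
    rewired pairwise into within-group edges, preserving each node's degree.
    """
    rng = rng or _rng(config, 0)
    r = config.degree_dispersion
    if r <= 0 or config.mean_degree <= 0:
        raise ValueError("mean_degree and degree_dispersion must be positive")
    p_nb = r / (r + config.mean_degree)
    degrees = np.maximum(1, rng.negative_binomial(r, p_nb, size=config.n_true))
    if degrees.sum() % 2:
        degrees[rng.integers(config.n_true)] += 1
    graph = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    graph = nx.Graph(graph)
    graph.remove_edges_from(nx.selfloop_edges(graph))

    attendance = rng.random(config.n_true) < config.p_true

    if config.trait_homophily > 0:
        _rewire_homophily(graph, attendance, config.trait_homophily, rng)

    realized = np.array([graph.degree(i) for i in range(config.n_true)])
    cc = max(nx.connected_components(graph), key=len)
    truth = SimTruth(
        config=config,
        degrees=realized,
        attendance=attendance,
        largest_cc_frac=len(cc) / config.n_true,
    )
    return graph, truth


def _rewire_homophily(
    graph: nx.Graph, trait: np.ndarray, h: float, rng: np.random.Generator
) -> None:
    """Convert cross-group edge pairs into within-group pairs, degree-preserving.

    Target fraction of cross edges removed is h/(1+h): h=0 leaves the graph
    untouched, h=1 halves cross-group edges, h→inf removes nearly all.
    """
    cross = [(u, v) for u, v in graph.edges if trait[u] != trait[v]]
    rng.shuffle(cross)
    target = int(round(h / (1.0 + h) * len(cross) / 2.0))
    done = 0
    it = iter(cross)
    for (u, v), (x, y) in zip(it, it):
        if done >= target:
            break
        if trait[x] != trait[u]:
            x, y = y, x
        # now trait[u]==trait[x], trait[v]==trait[y]
        if u == x or v == y or graph.has_edge(u, x) or graph.has_edge(v, y):
            continue
        if not (graph.has_edge(u, v) and graph.has_edge(x, y)):
            continue
        graph.remove_edge(u, v)
        graph.remove_edge(x, y)
        graph.add_edge(u, x)
        graph.add_edge(v, y)
        done += 1


def _draw_seeds(truth: SimTruth, config: SimConfig, rng: np.random.Generator) -> list[int]:
    n = config.n_true
    if config.seed_policy == "uniform":
        return list(rng.choice(n, size=config.n_seeds, replace=False))
    attenders = np.flatnonzero(truth.attendance)
    others = np.flatnonzero(~truth.attendance)
    seeds: list[int] = []
    pool_a, pool_o = list(attenders), list(others)
    for _ in range(config.n_seeds):
        take_attender = rng.random() < config.seed_attender_prob
        pool = pool_a if (take_attender and pool_a) else (pool_o if pool_o else pool_a)
        idx = int(rng.integers(len(pool)))
        seeds.append(pool.pop(idx))
    return seeds


def simulate_rds(
    graph: nx.Graph,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> RecruitmentForest:
    """Run coupon-chain recruitment over the network.

    Seeds are drawn per ``seed_policy``; each interviewed respondent offers
    coupons to uniformly chosen *unsampled* neighbours, each returned with
    ``coupon_return_prob``.  Recruitment proceeds breadth-first by wave and
    stops at ``target_sample`` or ``max_waves``.  Reported degree is the true
    network degree.
    """
    rng = rng or _rng(config, 1)
    seeds = _draw_seeds(truth, config, rng)
    sampled: dict[int, int] = {}  # node -> enrollment order
    respondents: list[RDSRespondent] = []
    queue: list[tuple[int, int, int | None]] = []  # (node, wave, recruiter order)
    for s in seeds:
        sampled[s] = len(sampled)
        queue.append((s, 0, None))

    i = 0
    while i < len(queue):
        node, wave, recruiter_order = queue[i]
        order = sampled[node]
        respondents.append(
            RDSRespondent(
                respondent_id=f"R{order:05d}",
                site_id=config.site_id,
                recruiter_id=None if recruiter_order is None else f"R{recruiter_order:05d}",
                wave=wave,
                recruitment_order=order,
                degree=int(graph.degree(node)),
                attended_program=bool(truth.attendance[node]),
                heard_of_program=True,
            )
        )
        if wave < config.max_waves and len(sampled) < config.target_sample:
            unsampled = [v for v in graph.neighbors(node) if v not in sampled]
            k = min(config.coupons_per_respondent, len(unsampled))
            if k:
                picks = rng.choice(len(unsampled), size=k, replace=False)
                for j in picks:
                    if len(sampled) >= config.target_sample:
                        break
                    if rng.random() < config.coupon_return_prob:
                        recruit = unsampled[j]
                        sampled[recruit] = len(sampled)
                        queue.append((recruit, wave + 1, order))
        i += 1

    if len(respondents) < config.target_sample:
        warnings.warn(
            f"recruitment exhausted at {len(respondents)} of {config.target_sample} "
            f"(waves <= {config.max_waves}); returning partial forest",
            stacklevel=2,
        )
    respondents.sort(key=lambda r: r.recruitment_order)
    return RecruitmentForest(
        config.site_id, respondents, max_coupons=config.coupons_per_respondent
    )


def simulate_program_log(
    truth: SimTruth,
    config: SimConfig,
    meta: SiteMeta,
    rng: np.random.Generator | None = None,
) -> list[ProgramVisit]:
    """Generate the service visit log implied by the attendance truth.

    Every attender makes a zero-truncated Poisson(``visit_rate``) number of
    visits at uniform dates in the reference window, under a stable client
    id.  ``underage_frac`` injects extra under-18 clients (as a fraction of
    attenders) that downstream eligibility filtering must remove.
    """
    rng = rng or _rng(config, 2)
    start, end = meta.window
    span = (end - start).days
    visits: list[ProgramVisit] = []

    def _dates(k: int) -> list[dt.date]:
        return [start + dt.timedelta(days=int(d)) for d in rng.integers(0, span, size=k)]

    for person in np.flatnonzero(truth.attendance):
        k = 0
        while k == 0:
            k = int(rng.poisson(config.visit_rate))
        age = int(rng.integers(18, 50))
        for date in _dates(k):
            visits.append(
                ProgramVisit(
                    client_id=f"C{person:05d}",
                    site_id=meta.site_id,
                    visit_date=date,
                    age_at_visit=age,
                )
            )
    n_under = int(round(config.underage_frac * truth.n_attenders))
    for j in range(n_under):
        age = int(rng.integers(15, 18))
        for date in _dates(1 + int(rng.poisson(0.5))):
            visits.append(
                ProgramVisit(
                    client_id=f"U{j:04d}",
                    site_id=meta.site_id,
                    visit_date=date,
                    age_at_visit=age,
                )
            )
    visits.sort(key=lambda v: (v.visit_date, v.client_id))
    return visits


def simulate_study(
    config: SimConfig,
    survey_date: dt.date = _DEFAULT_SURVEY_DATE,
    census_women_15_49: int | None = 10000,
) -> tuple[RecruitmentForest, list[ProgramVisit], SiteMeta, SimTruth]:
    """Generate one full synthetic site: forest, visit log, metadata, truth."""
    meta = SiteMeta(
        site_id=config.site_id,
        survey_date=survey_date,
        window_months=6,
        census_women_15_49=census_women_15_49,
    )
    graph, truth = simulate_population(config)
    forest = simulate_rds(graph, truth, config)
    visits = simulate_program_log(truth, config, meta)
    return forest, visits, meta, truth
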