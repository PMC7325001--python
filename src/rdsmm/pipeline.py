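"""End-to-end orchestration: files in, results tables and diagnostics out."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .comparison import knowledge_association, pooled_respondents, program_person_records, source_comparison
from .data import read_program_log, read_rds_survey, read_site_meta
from .diagnostics import plot_bottleneck, plot_convergence
from .model import ServiceMultiplierModel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_full_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and site."""


@dataclass
class RunConfig:
    rds_path: str
    visits_path: str
    site_meta_path: str
    out_dir: str
    trait: str = "attended_program"
    comparison_traits: list[str] = field(default_factory=list)
    reps: int = 1000
    seed: int = 0
    min_age: int = 18
    plots: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(stage: str, site: str | None = None):
    loc = f"stage {stage}" + (f", site {site}" if site else "")

    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"{loc}: {exc}") from exc
            return False

    return _ctx()


def run_full_pipeline(config: RunConfig) -> dict:
    """Run estimation, diagnostics and cross-source comparisons for every site.

    Writes a per-site results table (``table_estimates.csv``), diagnostics
    CSVs, comparison tables and a machine-readable ``summary.json`` (stable
    byte-for-byte across reruns with the same config).  Returns the bundle as
    a dict.
    """
    for p in (config.rds_path, config.visits_path, config.site_meta_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("read"):
        forests = read_rds_survey(config.rds_path)
        log = read_program_log(config.visits_path)
        metas = read_site_meta(config.site_meta_path)

    rows, homophily_rows, conv_rows, bott_rows = [], [], [], []
    summary: dict = {
        "tool": {"name": "rdsmm", "version": __version__},
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "sites": {},
    }
    for site_id in sorted(forests):
        forest = forests[site_id]
        if site_id not in metas:
            raise PipelineError(f"stage meta, site {site_id}: no site metadata")
        model = ServiceMultiplierModel(
            forest, log.for_site(site_id), metas[site_id], config.trait, config.min_age
        )
        with _stage("estimate", site_id):
            res = model.fit(reps=config.reps, seed=config.seed)
        rows.append(res.to_row())
        with _stage("diagnostics", site_id):
            diag = model.diagnostics()
        conv = diag["convergence"]
        conv_rows += [
            {"site_id": site_id, "cumulative_n": int(n), "p_hat_cum": p}
            for n, p in zip(conv.cumulative_n, conv.p_hat_cum)
        ]
        if "bottleneck" in diag:
            for seed_id, s in diag["bottleneck"].per_seed.items():
                bott_rows += [
                    {"site_id": site_id, "seed": seed_id, "cumulative_n": int(n), "p_hat_cum": p}
                    for n, p in zip(s.cumulative_n, s.p_hat_cum)
                ]
        hom = diag["homophily"]
        homophily_rows.append(
            {
                "site_id": site_id,
                "homophily": hom.h,
                "n_pairs": hom.n_pairs,
                "observed_matches": hom.observed_matches,
                "expected_matches": hom.expected_matches,
            }
        )
        summary["sites"][site_id] = {
            **{k: _jsonable(v) for k, v in res.to_row().items()},
            "homophily": hom.h,
            "convergence_stable": conv.stable,
        }
        if config.plots:
            import matplotlib

            matplotlib.use("Agg")
            ax = plot_convergence(conv)
            ax.figure.savefig(out / f"convergence_{site_id}.png", dpi=120)
            if "bottleneck" in diag:
                ax = plot_bottleneck(diag["bottleneck"])
                ax.figure.savefig(out / f"bottleneck_{site_id}.png", dpi=120)

    comparisons = []
    if config.comparison_traits:
        with _stage("comparisons"):
            pooled = pooled_respondents(forests.values())
            attenders = pooled[pooled["attended_program"] == True]  # noqa: E712
            clients = pd.concat(
                [
                    program_person_records(log.for_site(s), metas[s], config.min_age)
                    for s in sorted(forests)
                    if s in metas
                ],
                ignore_index=True,
            )
            for t in config.comparison_traits:
                record: dict = {"trait": t}
                try:
                    ka = knowledge_association(forests.values(), t)
                    record["knowledge_chi2"] = ka.chi2_stat
                    record["knowledge_p"] = ka.p_value
                    record["knowledge_interaction_p"] = ka.interaction_p
                except Exception as exc:
                    record["knowledge_error"] = str(exc)
                if t in clients.columns:
                    try:
                        sc = source_comparison(attenders, clients, t)
                        record["source_wald_stat"] = sc.chi2_stat
                        record["source_p"] = sc.p_value
                        record["source_interaction_p"] = sc.interaction_p
                    except Exception as exc:
                        record["source_error"] = str(exc)
                comparisons.append(record)
        summary["comparisons"] = [{k: _jsonable(v) for k, v in r.items()} for r in comparisons]

    pd.DataFrame(rows).to_csv(out / "table_estimates.csv", index=False)
    pd.DataFrame(conv_rows).to_csv(out / "convergence.csv", index=False)
    pd.DataFrame(bott_rows).to_csv(out / "bottleneck.csv", index=False)
    pd.DataFrame(homophily_rows).to_csv(out / "homophily.csv", index=False)
    if comparisons:
        pd.DataFrame(comparisons).to_csv(out / "comparisons.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    logger.info("pipeline complete: %d sites -> %s (config %s)", len(forests), out, config.config_hash())
    return {
        "estimates": pd.DataFrame(rows),
        "homophily": pd.DataFrame(homophily_rows),
        "convergence": pd.DataFrame(conv_rows),
        "bottleneck": pd.DataFrame(bott_rows),
        "comparisons": pd.DataFrame(comparisons) if comparisons else None,
        "summary": summary,
    }


def _jsonable(v):
    if v is None or isinstance(v, (str, int, bool)):
        return v
    f = float(v)
    return None if math.isnan(f) else f
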