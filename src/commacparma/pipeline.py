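"""End-to-end pipeline: join, preprocess, COMMA and CPARMA for every pair."""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .comma import CommaConfig, PairwiseSummary, SolverStatus, competition_profile
from .community import join_models
from .cparma import CparmaConfig, InteractionClassification, InteractionVerdict, classify_pair
from .model_io import load_model
from .preprocessing import preprocess

log = logging.getLogger("commacparma")


@dataclass
class RunConfig:
    alpha: float = 0.1
    beta: float = 0.01
    epsilon: float = 0.01
    demand_fraction: float = 1.0
    fva_tolerance: float = 1e-6
    zero_tolerance: float = 1e-9
    default_bound: float = 1000.0
    solver_name: str = "glpk"
    output_dir: str = "results"
    log_level: str = "INFO"
    seed: int = 0

    def comma(self) -> CommaConfig:
        return CommaConfig(alpha=self.alpha, beta=self.beta,
                           zero_tolerance=self.zero_tolerance)

    def cparma(self) -> CparmaConfig:
        return CparmaConfig(alpha=self.alpha, epsilon=self.epsilon,
                            demand_fraction=self.demand_fraction,
                            zero_tolerance=self.zero_tolerance)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class PairReport:
    pair: tuple[str, str]
    summary: PairwiseSummary
    classifications: list[InteractionClassification]
    wall_time_s: float


@dataclass
class ReportBundle:
    pairs: list[PairReport] = field(default_factory=list)

    @property
    def n_solver_errors(self) -> int:
        n = 0
        for p in self.pairs:
            n += p.summary.n_errors
            n += sum(1 for c in p.classifications if c.verdict == InteractionVerdict.ERROR)
        return n

    def competition_table(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            for r in p.summary.per_metabolite:
                rows.append({
                    "species_a": p.pair[0],
                    "species_b": p.pair[1],
                    "metabolite": r.metabolite,
                    "verdict": r.verdict.value if r.verdict else "error",
                    "solver_status": r.solver_status.value,
                    "n_active_exchanges": len(r.active_exchanges or ()),
                })
        return pd.DataFrame(rows)

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "species_a": p.pair[0],
                "species_b": p.pair[1],
                "n_overlapped": p.summary.n_overlapped,
                "n_competed": p.summary.n_competed,
                "competition_score": p.summary.competition_score,
                "wall_time_s": round(p.wall_time_s, 3),
            }
            for p in self.pairs
        ])

    def interaction_table(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            for c in p.classifications:
                rows.append({
                    "metabolite": c.metabolite,
                    "giver": c.giver,
                    "consumer": c.consumer,
                    "demanded_flux": round(c.demanded_flux, 6),
                    "verdict": c.verdict.value,
                    "env_probe": c.environment_supplement_feasible,
                    "forced_probe": c.forced_supply_feasible,
                })
        return pd.DataFrame(rows)


def run_pipeline(model_paths: list[str | Path], config: RunConfig | None = None) -> ReportBundle:
    """Join all models pairwise, preprocess, and run both feasibility programs.

    Every unordered species pair is analysed in its own two-species joint
    model (the all-pairs layout used for small communities).
    """
    config = config or RunConfig()
    if len(model_paths) < 2:
        raise ValueError("need at least two model paths")
    logging.basicConfig(
        level=config.log_level,
        format="%(asctime)s %(levelname)s %(name)s %(message)s",
    )
    models = [load_model(p) for p in model_paths]
    bundle = ReportBundle()
    for m1, m2 in itertools.combinations(models, 2):
        t0 = time.perf_counter()
        log.info("joining pair %s / %s", m1.model_id, m2.model_id)
        community = join_models([m1, m2], exchange_bound=config.default_bound)
        pre = preprocess(community, fva_tolerance=config.fva_tolerance,
                         zero_tolerance=config.zero_tolerance)
        summary = competition_profile(pre, config=config.comma())
        classifications = classify_pair(pre, config=config.cparma())
        bundle.pairs.append(PairReport(
            pair=(m1.model_id, m2.model_id),
            summary=summary,
            classifications=classifications,
            wall_time_s=time.perf_counter() - t0,
        ))
        log.info(
            "pair %s/%s: %d overlapped, %d competed",
            m1.model_id, m2.model_id,
            summary.n_overlapped, summary.n_competed,
        )
    return bundle


def write_reports(bundle: ReportBundle, config: RunConfig, output_dir: str | Path) -> None:
    """Write summary/competition/interaction TSVs, JSON, and resolved config."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.summary_table().to_csv(out / "summary.tsv", sep="\t", index=False)
    bundle.competition_table().to_csv(out / "competition.tsv", sep="\t", index=False)
    bundle.interaction_table().to_csv(out / "interactions.tsv", sep="\t", index=False)
    payload = {
        "summary": bundle.summary_table().to_dict(orient="records"),
        "interactions": bundle.interaction_table().to_dict(orient="records"),
        "n_solver_errors": bundle.n_solver_errors,
    }
    (out / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))
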