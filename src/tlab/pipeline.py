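"""End-to-end orchestration: predict -> generate -> score -> fit -> decide.

`replicate_all` runs the full desk-scale re-analysis across the five
emulated designs: synthetic rating tables are generated (distributional or
model-driven), collapsed to participant scores, fitted with the robust
t-model (one-group against zero for the factorial designs, two-group for the
three two-claim contrasts), classified with the HDI + ROPE rule, and mapped
to hypothesis verdicts.  Every stage's outputs, seeds and wall-clock are
recorded in a manifest so any stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decisions import Rope, compute_scores, hypothesis_verdicts, rope_decision
from .models import Scenario, predict_experiment, second_claim_posterior
from .robust import (
    REDUCED_SAMPLER,
    ObservationSet,
    PosteriorSummary,
    RobustModelSpec,
    SamplerConfig,
    fit,
)
from .society import SocietyConfig, run as run_society
from .synth import (
    EXPERIMENTS,
    PRIMARY_FACTOR,
    OAScenario,
    RatingTable,
    default_design,
    default_params,
    generate_change_design,
    generate_exp3_design,
    model_driven_generate,
)

__all__ = ["RunConfig", "RunManifest", "replicate_all", "predict_table", "simulate_experiment"]

# analysis name (as consumed by hypothesis_verdicts) per experiment and level
_ANALYSIS_NAMES = {
    "source_reliability": {"high": "reliable_sources", "low": "unreliable_sources"},
    "claim_expectedness": {"expected": "expected_claims", "unexpected": "unexpected_claims"},
}
_EXP3_CONTRASTS = [("expected", "null"), ("null", "unexpected"), ("expected", "unexpected")]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    mode: str  # "predict" | "simulate_experiment" | "replicate_all" | "society"
    seed: int
    out_dir: Path
    experiments: tuple[str, ...] = EXPERIMENTS
    model_driven: bool = False
    faithful: bool = False  # full-length chains instead of the reduced default
    rope: Rope = field(default_factory=Rope)
    n_per_condition: int | None = None
    society: SocietyConfig | None = None

    def sampler(self, seed: int) -> SamplerConfig:
        base = SamplerConfig() if self.faithful else REDUCED_SAMPLER
        return SamplerConfig(steps=base.steps, burn_in=base.burn_in, seed=seed)


@dataclass
class RunManifest:
    """Provenance record: what was run, with which seeds, producing which files."""

    config_hash: str
    version: str
    seeds: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    wall_clock: dict[str, float] = field(default_factory=dict)

    def check_outputs(self) -> None:
        missing = [p for p in self.outputs.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in asdict(config).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _spawn_seeds(seed: int, names: list[str]) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(names))
    return {name: int(s % (2**31)) for name, s in zip(names, state)}


class _StageLog:
    """JSON-lines structured log of pipeline stages."""

    def __init__(self, path: Path):
        self.path = path
        path.write_text("")

    def event(self, **fields) -> None:
        with open(self.path, "a") as fh:
            fh.write(json.dumps(fields) + "\n")


def predict_table(scenario: Scenario | None = None) -> pd.DataFrame:
    """Qualitative predictions of both models across all conditions.

    Includes the two-claim carry-over rows (second-claim belief relative to
    its 0.5 prior after an expected vs. unexpected first claim) and a
    ``diverges`` flag marking conditions where the two models disagree —
    the anti-reliability signature.
    """
    scenario = scenario or Scenario()
    rows = []
    for model in ("bh", "oa"):
        for rec in predict_experiment(model, scenario):
            rows.append(
                {
                    "model": rec.model,
                    "condition": rec.condition,
                    "quantity": rec.quantity,
                    "direction": rec.direction,
                    "delta": rec.delta,
                }
            )
    # Two-claim paradigm: second-claim posterior after an expected/unexpected
    # first assertion, for each model's natural reliability prior.
    from .models import ReliabilityGrid, oa_from_bh, BHState

    grids = {
        "bh": oa_from_bh(BHState(0.5, 0.5, 0.5)).reliability_marginal(),
        "oa": ReliabilityGrid.uniform(101),
    }
    for model, grid in grids.items():
        for label, prior in scenario.claim_priors.items():
            post, _ = second_claim_posterior(prior, 0.5, grid)
            delta = post - 0.5
            rows.append(
                {
                    "model": model,
                    "condition": f"exp3/{label}-first",
                    "quantity": "second_claim_belief_change",
                    "direction": "increase" if delta > 1e-12 else ("decrease" if delta < -1e-12 else "none"),
                    "delta": delta,
                }
            )
    frame = pd.DataFrame(rows)
    pivot = frame.pivot_table(
        index=["condition", "quantity"], columns="model", values="direction", aggfunc="first"
    )
    disagreement = pivot[pivot["bh"] != pivot["oa"]].index
    frame["diverges"] = frame.set_index(["condition", "quantity"]).index.isin(disagreement)
    return frame


def _generate(experiment: str, config: RunConfig, seed: int) -> RatingTable:
    design = default_design(experiment, config.n_per_condition)
    if config.model_driven:
        return model_driven_generate(design, OAScenario(), seed=seed)
    params = default_params(experiment, seed=seed)
    if design.is_change_design:
        return generate_change_design(design, params)
    return generate_exp3_design(design, params)


def _decision_payload(summary: PosteriorSummary, rope: Rope) -> tuple[dict, float, "object"]:
    es_hdi = summary.hdi("effect_size")
    decision = rope_decision(es_hdi, rope)
    payload = {
        "posterior": summary.summary(),
        "effect_size_hdi": list(es_hdi),
        "rope": [rope.lower, rope.upper],
        "decision": decision.decision,
        "overlap_length": decision.overlap_length,
        "hdi_fraction_in_rope": decision.hdi_fraction_in_rope,
    }
    return payload, summary.mean("effect_size"), decision


def analyze_experiment(
    table: RatingTable,
    rope: Rope,
    sampler_seed: int,
    config: RunConfig,
) -> tuple[dict, dict[str, tuple]]:
    """Score one experiment's table and run its fits and ROPE decisions.

    Factorial designs get one one-group fit (comparison value 0) per level of
    the design's primary factor, collapsed over the other factor.  The
    two-claim design gets a two-group fit per contrast, sharing a single
    normality parameter across groups.
    """
    scores = compute_scores(table)
    experiment = table.design.experiment
    report: dict = {"experiment": experiment, "analyses": {}}
    analyses: dict[str, tuple] = {}
    sub_seed = sampler_seed
    if table.design.is_change_design:
        factor = PRIMARY_FACTOR[experiment]
        for level, name in _ANALYSIS_NAMES[factor].items():
            values = scores.values(**{factor: level})
            summary = fit(
                ObservationSet(values),
                RobustModelSpec(kind="one_group", comparison_value=0.0),
                config.sampler(sub_seed),
            )
            sub_seed += 1
            payload, es_mean, decision = _decision_payload(summary, rope)
            report["analyses"][name] = payload
            analyses[name] = (decision, es_mean)
    else:
        for g1, g2 in _EXP3_CONTRASTS:
            v1 = scores.values(first_claim_condition=g1)
            v2 = scores.values(first_claim_condition=g2)
            obs = ObservationSet(
                np.concatenate([v1, v2]),
                np.array([g1] * len(v1) + [g2] * len(v2)),
            )
            summary = fit(
                ObservationSet(obs.values, obs.groups),
                RobustModelSpec(kind="two_group"),
                config.sampler(sub_seed),
            )
            sub_seed += 1
            name = f"{g1}_vs_{g2}"
            payload, es_mean, decision = _decision_payload(summary, rope)
            report["analyses"][name] = payload
            analyses[name] = (decision, es_mean)
    report["verdicts"] = hypothesis_verdicts(analyses)
    return report, analyses


def replicate_all(config: RunConfig) -> RunManifest:
    """Run the full pipeline over the configured experiments; returns the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), version=__version__)
    log = _StageLog(out_dir / "run_log.jsonl")
    seed_names = [f"{stage}:{exp}" for exp in config.experiments for stage in ("gen", "fit")]
    seeds = _spawn_seeds(config.seed, seed_names)
    manifest.seeds = seeds
    consolidated: dict = {"config_hash": manifest.config_hash, "experiments": {}}
    stage = "start"
    try:
        for experiment in config.experiments:
            stage = f"generate:{experiment}"
            t0 = time.perf_counter()
            table = _generate(experiment, config, seeds[f"gen:{experiment}"])
            table_path = out_dir / f"{experiment}_ratings.csv"
            table.to_csv(table_path)
            manifest.outputs[f"{experiment}_ratings"] = str(table_path)
            manifest.wall_clock[stage] = time.perf_counter() - t0
            log.event(stage=stage, seed=seeds[f"gen:{experiment}"], rows=len(table.data))

            stage = f"analyze:{experiment}"
            t0 = time.perf_counter()
            report, _ = analyze_experiment(
                table, config.rope, seeds[f"fit:{experiment}"], config
            )
            report_path = out_dir / f"{experiment}_report.json"
            with open(report_path, "w") as fh:
                json.dump(report, fh, indent=2)
            manifest.outputs[f"{experiment}_report"] = str(report_path)
            manifest.wall_clock[stage] = time.perf_counter() - t0
            consolidated["experiments"][experiment] = report
            log.event(stage=stage, seed=seeds[f"fit:{experiment}"], verdicts=report["verdicts"])
    except Exception as exc:
        partial = out_dir / "manifest_partial.json"
        manifest.write(partial)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    consolidated_path = out_dir / "consolidated_report.json"
    with open(consolidated_path, "w") as fh:
        json.dump(consolidated, fh, indent=2)
    manifest.outputs["consolidated_report"] = str(consolidated_path)
    manifest_path = out_dir / "manifest.json"
    manifest.write(manifest_path)
    manifest.check_outputs()
    return manifest


def simulate_experiment(config: RunConfig, experiment: str) -> RunManifest:
    """Generate + analyze a single experiment (a one-design replicate_all)."""
    sub = RunConfig(
        mode="simulate_experiment",
        seed=config.seed,
        out_dir=config.out_dir,
        experiments=(experiment,),
        model_driven=config.model_driven,
        faithful=config.faithful,
        rope=config.rope,
        n_per_condition=config.n_per_condition,
    )
    return replicate_all(sub)


def society_run(config: RunConfig) -> RunManifest:
    """Run the agent-society simulation and write trajectories + summaries."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    soc_config = config.society or SocietyConfig(seed=config.seed)
    manifest = RunManifest(config_hash=_config_hash(config), version=__version__)
    t0 = time.perf_counter()
    trajectories, summary = run_society(soc_config)
    traj_path = out_dir / "society_trajectories.csv"
    trajectories.to_csv(traj_path, index=False)
    summary_path = out_dir / "society_summary.csv"
    summary.to_frame().to_csv(summary_path, index=False)
    manifest.outputs["trajectories"] = str(traj_path)
    manifest.outputs["summary"] = str(summary_path)
    manifest.wall_clock["society"] = time.perf_counter() - t0
    manifest.seeds["society"] = soc_config.seed
    manifest.write(out_dir / "manifest.json")
    manifest.check_outputs()
    return manifest
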