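"""End-to-end pipeline: configuration, orchestration, and result bundles.

A :class:`RunConfig` mirrors the CLI flags one-to-one and round-trips
through YAML/JSON.  :func:`run_pipeline` wires the stages together:

    filter network -> build target-centric networks -> fit + cross-validate
    -> exclude poor models -> knockout simulation -> effect indices ->
    per-structure specificity tables -> result tables + manifest

One global seed fans out to stable per-stage, per-target child seeds so any
stage can be re-run independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .effects import compute_effect_profile, rank_spec, EffectProfile
from .expression import ExpressionMatrix, load_expression_matrix, write_area_values
from .models import fit_target_centric, TargetCentricModel
from .network import (
    GeneNetwork,
    NetworkError,
    build_target_centric,
    filter_by_score,
    filter_by_type,
    read_edge_tsv,
    rewire,
)
from .stats import read_gmt

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    """All knobs of an end-to-end run; defaults follow the study protocol."""

    network: str = ""
    expression: str = ""
    metadata: str = ""
    objectives: str = ""  # GMT file; first set is the objective set
    targets: str = "all"  # "all" or a path to a one-gene-per-line list
    out: str = "results"
    score_threshold: float = 0.9
    interaction_types: list[str] = field(default_factory=list)  # empty = keep all
    max_error: float = 0.25
    cv_repetitions: int = 1000
    test_fraction: float = 0.1
    baseline_mode: str = "observed"
    top_n: int = 100
    n_random: int = 1000
    rewire_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise PipelineError("score_threshold must be in [0, 1]")
        if not 0.0 < self.test_fraction < 1.0:
            raise PipelineError("test_fraction must be in (0, 1)")
        if not 0.0 <= self.rewire_fraction <= 1.0:
            raise PipelineError("rewire_fraction must be in [0, 1]")
        if self.max_error < 0 or self.cv_repetitions < 1 or self.top_n < 1:
            raise PipelineError("invalid threshold/repetition settings")
        if self.baseline_mode not in ("observed", "predicted"):
            raise PipelineError("baseline_mode must be 'observed' or 'predicted'")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise PipelineError("config file must hold a mapping")
        return cls.from_dict(data)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def child_seed(seed: int, *key: int) -> int:
    """Stable derived seed (< 2**31) for an independent pipeline stage."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    """In-memory view of one run (everything also lands on disk)."""

    config: RunConfig
    models: dict[str, TargetCentricModel]
    profiles: dict[str, EffectProfile]
    rank_tables: dict[str, "pd.DataFrame"]  # structure -> RankSpec table
    status: dict[str, str]  # target -> ok|no_objective_neighbours|all_models_excluded
    manifest: dict


def _load_inputs(config: RunConfig) -> tuple[GeneNetwork, ExpressionMatrix, set[str], list[str]]:
    net = read_edge_tsv(config.network)
    if config.interaction_types:
        net = filter_by_type(net, config.interaction_types)
    net = filter_by_score(net, config.score_threshold)
    if config.rewire_fraction > 0:
        net = rewire(net, config.rewire_fraction, seed=child_seed(config.seed, 1))
    matrix = load_expression_matrix(config.expression, config.metadata)
    gmt = read_gmt(config.objectives)
    if not gmt:
        raise PipelineError("objective GMT file holds no gene set")
    objective_set = set(next(iter(gmt.values())))

    shared = net.nodes & set(matrix.genes)
    if not shared:
        raise PipelineError(
            "incompatible inputs: no shared genes between network and expression"
        )
    frac = len(shared) / max(len(net.nodes), 1)
    if frac < 1.0:
        logger.warning(
            "partial gene-namespace overlap: %d/%d network genes have expression",
            len(shared),
            len(net.nodes),
        )
    if config.targets == "all":
        candidates = sorted(shared - objective_set)
    else:
        requested = [
            line.strip()
            for line in Path(config.targets).read_text().splitlines()
            if line.strip()
        ]
        candidates = [t for t in requested if t in net.nodes]
        skipped = set(requested) - set(candidates)
        if skipped:
            logger.warning("targets absent from network skipped: %s", sorted(skipped)[:5])
    return net, matrix, objective_set, candidates


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute the whole knockout-effect pipeline for all requested targets.

    Targets without objective neighbours, or whose objective models are all
    excluded by the cross-validation filter, are recorded in the per-target
    status map rather than aborting the run (their counts end up in the
    manifest, since surviving-model counts are a headline output).
    """
    import pandas as pd

    net, matrix, objective_set, candidates = _load_inputs(config)

    models: dict[str, TargetCentricModel] = {}
    profiles: dict[str, EffectProfile] = {}
    status: dict[str, str] = {}
    for t_index, target in enumerate(candidates):
        try:
            tcn = build_target_centric(net, target, objective_set)
        except NetworkError:
            status[target] = "no_objective_neighbours"
            logger.info("target %s skipped: no objective neighbours", target)
            continue
        tcm = fit_target_centric(
            matrix,
            tcn,
            max_error=config.max_error,
            cv_repetitions=config.cv_repetitions,
            test_fraction=config.test_fraction,
            seed=child_seed(config.seed, 2, t_index),
        )
        if not tcm.usable:
            status[target] = "all_models_excluded"
            continue
        models[target] = tcm
        profiles[target] = compute_effect_profile(
            tcm, matrix, baseline_mode=config.baseline_mode
        )
        status[target] = "ok"

    rank_tables: dict[str, pd.DataFrame] = {}
    if profiles:
        for structure in matrix.structures:
            rows = [
                (t, p.per_structure[structure], p.fold_change[structure])
                for t, p in sorted(profiles.items())
            ]
            rank_tables[structure] = rank_spec(rows)

    manifest = {
        "tool": "brainko",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_targets_attempted": len(candidates),
        "n_no_objective_neighbours": sum(
            1 for s in status.values() if s == "no_objective_neighbours"
        ),
        "n_all_models_excluded": sum(
            1 for s in status.values() if s == "all_models_excluded"
        ),
        "n_usable_targets": len(profiles),
        "n_objective_models_excluded": sum(len(m.excluded) for m in models.values()),
        "n_objective_models_surviving": sum(
            len(m.objective_models) for m in models.values()
        ),
        "per_target_status": status,
    }

    result = PipelineResult(
        config=config,
        models=models,
        profiles=profiles,
        rank_tables=rank_tables,
        status=status,
        manifest=manifest,
    )
    if write_outputs:
        _write_bundle(result, matrix)
    return result


def _write_bundle(result: PipelineResult, matrix: ExpressionMatrix) -> None:
    out = Path(result.config.out)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"# config_hash={result.config.config_hash()}\n"

    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    result.config.write(out / "config.yaml")

    with (out / "effects.tsv").open("w") as fh:
        fh.write(tag)
        fh.write("target\tstructure\tRsT\tFCsT\tRankSpec\n")
        spec = {
            (row["gene"], s): row["rank_spec"]
            for s, table in result.rank_tables.items()
            for _, row in table.iterrows()
        }
        for target in sorted(result.profiles):
            p = result.profiles[target]
            for s in sorted(p.per_structure):
                fh.write(
                    f"{target}\t{s}\t{p.per_structure[s]:.6g}\t{p.fold_change[s]:.6g}\t"
                    f"{spec.get((target, s), float('nan')):.6g}\n"
                )
            fh.write(f"{target}\t__all__\t{p.whole:.6g}\tNA\tNA\n")

    with (out / "per_area_effects.tsv").open("w") as fh:
        fh.write(tag)
        fh.write("target\tarea\tRpT\n")
        for target in sorted(result.profiles):
            for area, value in result.profiles[target].per_area.items():
                fh.write(f"{target}\t{area}\t{value:.6g}\n")

    for structure, table in result.rank_tables.items():
        path = out / f"rank_spec_{structure}.tsv"
        with path.open("w") as fh:
            fh.write(tag)
            table.to_csv(fh, sep="\t", index=False)
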