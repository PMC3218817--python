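"""End-to-end orchestration: ingest or simulate counts, filter identifications,
compute enrichment, call interactors, compare against prior lists.

The stage order mirrors the bench workflow it models: purification (or its
simulation) -> search-engine identification consensus -> enrichment against
the matched control -> k-of-n consensus call -> cross-study comparison.  A
run log records every threshold and the seed, plus proteins in/out at each
stage, so the filter cascade is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

from .consensus import (
    CallingConfig,
    InteractorCall,
    accepted_interactors,
    call_interactors,
    write_call_report,
)
from .enrichment import QualificationRule, enrichment_table, read_ratio_table
from .identification import consensus_proteins, filter_matrix, read_identifications
from .lists import NamedProteinList, classify_novelty, novelty_counts, read_protein_list
from .matrix import SpectralCountMatrix
from .simulate import SimulationConfig, simulate_experiment, write_ground_truth

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """One pipeline run.  Exactly one of ratios / counts / simulate is the
    count source."""

    out_dir: Path
    ratios: Path | None = None
    counts: Path | None = None
    simulate: SimulationConfig | None = None
    ident_a: Path | None = None
    ident_b: Path | None = None
    ident_threshold: float = 0.95
    calling: CallingConfig = field(default_factory=CallingConfig)
    priors: tuple[Path, ...] = ()
    seed: int | None = None

    def __post_init__(self):
        sources = [s is not None for s in (self.ratios, self.counts, self.simulate)]
        if sum(sources) != 1:
            raise ValueError("exactly one of ratios, counts or simulate must be given")
        for p in filter(None, (self.ratios, self.counts, self.ident_a, self.ident_b)):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for p in self.priors:
            if not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class PipelineResult:
    calls: list[InteractorCall]
    report_paths: dict[str, Path]
    exit_status: int = 0


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a flat YAML key-value document."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    base = Path(path).parent

    def _p(key):
        return (base / raw[key]) if key in raw and raw[key] is not None else None

    sim = None
    if raw.get("simulate"):
        sim_keys = (
            "n_background n_interactors capture_prob bg_mean enrich_factor "
            "leak_mean bait_mean n_fractions dispersion"
        ).split()
        kwargs = {k: raw[k] for k in sim_keys if k in raw}
        if "conditions" in raw:
            kwargs["conditions"] = tuple(raw["conditions"])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        sim = SimulationConfig(**kwargs)
    rule = QualificationRule(
        fold_threshold=float(raw.get("fold", 3.0)),
        inclusive=bool(raw.get("inclusive", True)),
    )
    calling = CallingConfig(
        k_min_support=int(raw.get("k", 2)),
        n_conditions=int(raw.get("n_conditions", 4)),
        rule=rule,
        bait_id=str(raw.get("bait", CallingConfig().bait_id)),
    )
    priors = tuple(base / p for p in raw.get("priors", []))
    return PipelineConfig(
        out_dir=base / raw.get("out", "out"),
        ratios=_p("ratios"),
        counts=_p("counts"),
        simulate=sim,
        ident_a=_p("ident_a"),
        ident_b=_p("ident_b"),
        ident_threshold=float(raw.get("ident_threshold", 0.95)),
        calling=calling,
        priors=priors,
        seed=int(raw["seed"]) if "seed" in raw else None,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the stages and write calls.tsv, an optional comparison report and
    a run log under ``config.out_dir``.  Identical config and seed give
    byte-identical outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        "insitap pipeline run",
        f"seed: {config.seed}",
        f"identification threshold: {config.ident_threshold}",
        f"fold threshold: {config.calling.rule.fold_threshold} "
        f"(inclusive={config.calling.rule.inclusive})",
        f"k_min_support: {config.calling.k_min_support}",
        f"bait: {config.calling.bait_id}",
    ]
    paths: dict[str, Path] = {}

    if config.ratios is not None:
        table, genes, conditions = read_ratio_table(config.ratios)
        log_lines.append(f"ratio table: {config.ratios} ({len(table)} proteins)")
    else:
        if config.simulate is not None:
            sim = config.simulate
            if config.seed is not None:
                sim = replace(sim, seed=config.seed)
            matrix, truth = simulate_experiment(sim)
            truth_path = out / "ground_truth.tsv"
            write_ground_truth(truth, truth_path, sim.conditions)
            paths["ground_truth"] = truth_path
            counts_path = out / "counts.tsv"
            matrix.to_tsv(counts_path)
            paths["counts"] = counts_path
            log_lines.append(
                f"simulated: {matrix.n_proteins} proteins "
                f"({len(truth.interactor_ids)} true interactors), seed {sim.seed}"
            )
        else:
            matrix = SpectralCountMatrix.from_tsv(config.counts)
            log_lines.append(f"counts: {config.counts} ({matrix.n_proteins} proteins)")
        if config.ident_a and config.ident_b:
            accepted = consensus_proteins(
                read_identifications(config.ident_a),
                read_identifications(config.ident_b),
                config.ident_threshold,
            )
            before = matrix.n_proteins
            matrix = filter_matrix(matrix, accepted)
            log_lines.append(
                f"identification consensus: {before} -> {matrix.n_proteins} proteins"
            )
        table = enrichment_table(matrix)
        genes = dict(matrix.genes)
        conditions = matrix.conditions

    calls = call_interactors(table, config.calling, genes=genes, conditions=conditions)
    accepted = accepted_interactors(calls)
    log_lines.append(f"called: {len(calls)} proteins, {len(accepted)} accepted interactors")

    calls_path = out / "calls.tsv"
    write_call_report(calls, calls_path, conditions=conditions)
    paths["calls"] = calls_path

    if config.priors:
        ours = NamedProteinList.from_iterable(
            "this_run", [c.gene or c.protein_id for c in accepted]
        )
        priors = [read_protein_list(p) for p in config.priors]
        classification = classify_novelty(ours, priors)
        novel, known = novelty_counts(classification)
        comparison_path = out / "comparison.tsv"
        with open(comparison_path, "w") as fh:
            fh.write("gene\tstatus\tprior_studies\n")
            for gene, labels in classification.items():
                status = "known" if labels else "novel"
                fh.write(f"{gene}\t{status}\t{','.join(labels)}\n")
        paths["comparison"] = comparison_path
        log_lines.append(f"novelty: {novel} novel, {known} known")

    log_path = out / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    paths["log"] = log_path
    return PipelineResult(calls=calls, report_paths=paths, exit_status=0)
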