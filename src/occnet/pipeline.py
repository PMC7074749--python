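"""End-to-end orchestration: matrix in, paper-style table panel out.

``run`` chains the analysis stages — all-pairs Fisher testing with BH
correction, empirical FDR on fixed-margin nulls, sign classification on
occupancy-preserving nulls, confidence-1 rule mining, network construction,
topology panels with Erdos-Renyi baselines, modularity partitioning, spatial
module profiles and hub analysis — and writes every result table under one
output directory. ``simulate`` writes a synthetic community in the input
formats ``run`` consumes.

Stage seeds are derived from the master seed by fixed offsets (+1 empirical
FDR, +2 sign classification, +3 ER baselines), so a run is reproducible
end-to-end from the single seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    FragmentAnnotation,
    PresenceAbsenceMatrix,
    SampleMetadata,
    ValidationError,
    read_annotations,
    read_metadata,
    write_annotations,
    write_edge_list,
    write_graphml,
    write_metadata,
    write_rules,
)
from .cooccurrence import (
    all_pairs_test,
    classify_sign,
    estimate_fdr,
    results_frame,
    summarize,
)
from .profiles import module_core_profile
from .rules import mine_rules, rule_type_breakdown
from .synthetic import SyntheticCommunity, SyntheticConfig, generate
from .topology import (
    build_cooccurrence_network,
    build_rule_network,
    hub_neighborhood,
    hub_roles,
    modularity_partition,
    rule_cooccurrence_intersection,
    topology,
)

log = logging.getLogger("occnet")


@dataclass(frozen=True)
class PipelineConfig:
    matrix_path: str
    annotation_path: str
    metadata_path: str
    output_dir: str
    alpha: float = 0.05
    fdr_reps: int = 100
    sign_reps: int = 1000
    sign_level: float = 0.95
    min_support: int = 1
    er_reps: int = 100
    top_k: int = 25
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.sign_level < 1):
            raise ValidationError("alpha and sign_level must lie in (0, 1)")
        for name in ("fdr_reps", "sign_reps", "er_reps"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.min_support < 1 or self.top_k < 1:
            raise ValidationError("min_support and top_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)


@dataclass
class PipelineResult:
    summary: object
    results: list
    rules: list
    cooccurrence_network: nx.Graph
    rule_network: nx.DiGraph
    cooccurrence_topology: object
    rule_topology: object
    partition: object | None
    profile: object | None
    hub_report: object
    rule_breakdown: object
    output_dir: Path


def simulate(config: SyntheticConfig, output_dir: str | Path) -> SyntheticCommunity:
    """Generate a synthetic community and write it in the pipeline input formats."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    community = generate(config)
    community.matrix.write(out / "matrix.tsv")
    write_annotations(community.annotations, out / "annotations.tsv")
    write_metadata(community.metadata, out / "metadata.tsv")
    community.truth.to_json(out / "ground_truth.json")
    log.info(
        "simulated %d fragments x %d samples -> %s",
        community.matrix.n_fragments,
        community.matrix.n_samples,
        out,
    )
    return community


def _validate_inputs(
    matrix: PresenceAbsenceMatrix,
    annotations: dict[str, FragmentAnnotation],
    metadata: dict[str, SampleMetadata],
) -> None:
    problems = []
    if matrix.n_fragments < 2:
        problems.append("matrix has fewer than two fragments")
    un_annotated = [f for f in matrix.fragment_ids if f not in annotations]
    if un_annotated:
        problems.append(f"fragments without annotation: {un_annotated[:5]} ...")
    un_meta = [s for s in matrix.sample_ids if s not in metadata]
    if un_meta:
        problems.append(f"samples without metadata: {un_meta[:5]} ...")
    if problems:
        raise ValidationError("; ".join(problems))


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis chain; deterministic under ``config.seed``."""
    config.validate()
    matrix = PresenceAbsenceMatrix.read(config.matrix_path)
    annotations = read_annotations(config.annotation_path)
    metadata = read_metadata(config.metadata_path)
    _validate_inputs(matrix, annotations, metadata)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- co-occurrence stage
    results = all_pairs_test(matrix, alpha=config.alpha)
    n_sig = sum(r.significant for r in results)
    log.info("tested %d pairs, %d significant at alpha=%g", len(results), n_sig, config.alpha)
    fdr = estimate_fdr(
        matrix, n_reps=config.fdr_reps, alpha=config.alpha, seed=config.seed + 1
    )
    results = classify_sign(
        matrix, results, n_reps=config.sign_reps, level=config.sign_level,
        seed=config.seed + 2,
    )
    summary = summarize(results, annotations, n_fragments=matrix.n_fragments, fdr=fdr)
    results_frame(results).to_csv(out / "pair_results.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps(dataclasses.asdict(summary), indent=1))

    # --- rule mining stage
    rules = mine_rules(matrix, min_support=config.min_support)
    sig_pairs = {r.pair for r in results if r.significant}
    breakdown = rule_type_breakdown(rules, annotations, sig_pairs)
    write_rules(rules, out / "rules.tsv", annotations, sig_pairs)
    (out / "rule_breakdown.json").write_text(json.dumps(breakdown.as_dict(), indent=1))
    log.info("mined %d confidence-1 rules (%d also correlated)",
             breakdown.total, breakdown.n_also_correlated)

    # --- network stage
    cnet = build_cooccurrence_network(results, annotations)
    rnet = build_rule_network(rules, annotations)
    ctop = rtop = None
    if cnet.number_of_nodes() >= 3:
        ctop = topology(cnet, matrix.n_fragments, er_reps=config.er_reps,
                        er_seed=config.seed + 3)
        (out / "topology_cooccurrence.json").write_text(json.dumps(ctop.as_dict(), indent=1))
    if rnet.number_of_nodes() >= 3:
        rtop = topology(rnet, matrix.n_fragments, er_reps=config.er_reps,
                        er_seed=config.seed + 3)
        (out / "topology_rules.json").write_text(json.dumps(rtop.as_dict(), indent=1))
    write_graphml(cnet, out / "cooccurrence_network.graphml")
    write_graphml(rnet, out / "rule_network.graphml")
    write_edge_list(cnet, out / "cooccurrence_edges.tsv")
    write_edge_list(rnet, out / "rule_edges.tsv")
    n_int, frac_int, _ = rule_cooccurrence_intersection(rnet, cnet)
    log.info("networks: %d/%d co-occurrence nodes/edges, %d/%d rule nodes/edges, "
             "%d rules also correlated (%.1f%%)",
             cnet.number_of_nodes(), cnet.number_of_edges(),
             rnet.number_of_nodes(), rnet.number_of_edges(), n_int, 100 * frac_int)

    # --- modules and spatial profiles
    partition = profile = None
    try:
        partition = modularity_partition(cnet)
    except ValidationError:
        log.info("no positive edges; skipping modularity")
    if partition is not None:
        pd.DataFrame(
            sorted(partition.membership.items()), columns=["fragment", "module"]
        ).to_csv(out / "modules.tsv", sep="\t", index=False)
        profile = module_core_profile(matrix, metadata, partition)
        profile.fractions.to_csv(out / "module_profiles.tsv", sep="\t", index=False)
        profile.module_means.to_csv(out / "module_means.tsv", sep="\t", index=False)
        log.info("modularity Q=%.3f with %d modules (%d with > 3 fragments)",
                 partition.q, partition.n_modules, partition.n_modules_gt3)

    # --- hubs
    report = None
    if rnet.number_of_nodes() > 0:
        report = hub_roles(rnet, k=config.top_k, annotations=annotations)
        rows = [
            {"fragment": n, "role": report.roles[n], "in_degree": report.in_degree[n],
             "out_degree": report.out_degree[n], "domain": annotations[n].domain}
            for n in sorted(rnet.nodes)
        ]
        pd.DataFrame(rows).to_csv(out / "hub_report.tsv", sep="\t", index=False)
        for hub in report.top_targets[:3]:
            neigh = hub_neighborhood(rnet, cnet, hub)
            write_graphml(neigh.as_multigraph(), out / f"neighborhood_{hub}.graphml")

    _write_log(config, out)
    return PipelineResult(
        summary=summary,
        results=results,
        rules=rules,
        cooccurrence_network=cnet,
        rule_network=rnet,
        cooccurrence_topology=ctop,
        rule_topology=rtop,
        partition=partition,
        profile=profile,
        hub_report=report,
        rule_breakdown=breakdown,
        output_dir=out,
    )


def _write_log(config: PipelineConfig, out: Path) -> None:
    lines = [f"occnet {__version__}", f"numpy {np.__version__}", f"networkx {nx.__version__}"]
    lines += [f"{k} = {v}" for k, v in dataclasses.asdict(config).items()]
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")
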