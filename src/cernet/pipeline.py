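"""End-to-end driver: expression tables in, ranked ceRNA axes out.

Stage order: per-dataset differential expression -> cross-dataset
consensus -> coexpression screens (lncRNA-mRNA positive synergy,
intersected across datasets; miRNA-mRNA negative) -> multi-source target
evidence filtered and intersected with the negative correlations ->
duplex scanning of miRNAs against lncRNAs -> direction resolution ->
triple assembly -> network and degree -> core-axis ranking.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import io as cio
from .assembly import (AxisScoreWeights, CeRNANetwork, CeRNATriple, RankedAxis,
                       TripleProvenance, assemble_triples, build_network,
                       rank_core_axes, resolve_node_directions)
from .coexpression import (CoexprThresholds, CorrelationPair, correlate_all,
                           intersect_pair_sets, screen_negative, screen_pairs)
from .diffexpr import (ConfigError, ConsensusRecord, DERecord, DEThresholds,
                       ExpressionDataset, ModerationParams, THRESHOLD_PRESETS,
                       apply_thresholds, consensus_sets, fit_de)
from .duplex import (DuplexHit, DuplexScoring, DuplexThresholds, EnergyModel,
                     scan_all, screen_hits)
from .evidence import EvidenceTable, TargetPair, filter_by_support, intersect_with_corr
from .synthetic import StudyBundle

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineSettings:
    """Analysis parameters shared by in-memory and file-driven runs."""

    de_thresholds: dict[str, DEThresholds] = field(default_factory=lambda: {
        "mRNA": DEThresholds("adjusted", 0.05, 1.0),
        "lncRNA": DEThresholds("adjusted", 0.05, 1.0),
        "miRNA": DEThresholds("adjusted", 0.05, 1.0),
    })
    moderation: ModerationParams = field(default_factory=ModerationParams)
    lnc_mrna_thresholds: CoexprThresholds = field(
        default_factory=lambda: CoexprThresholds("positive_synergy", 0.7, 0.05))
    mir_mrna_p_max: float | None = None          # negative rule: no p gate
    mir_mrna_dataset: str | None = None          # default: first dataset
    min_sources: int = 6
    duplex_scoring: DuplexScoring = field(default_factory=DuplexScoring)
    duplex_thresholds: DuplexThresholds = field(default_factory=DuplexThresholds)
    energy_model: EnergyModel = field(default_factory=EnergyModel)
    direction_policies: dict[str, str] | None = None
    axis_weights: AxisScoreWeights = field(default_factory=AxisScoreWeights)
    include_coexpr_edges: bool = True


@dataclass
class PipelineResult:
    """All intermediates and outputs of one analysis run."""

    de_tables: dict[str, list[DERecord]]             # dataset_id -> records
    consensus: list[ConsensusRecord]
    directions: dict[str, str]
    lnc_mrna_pairs: list[CorrelationPair]
    negative_pairs: list[CorrelationPair]
    predicted_pairs: list[TargetPair]
    mir_mrna_pairs: list[TargetPair]
    duplex_hits: list[DuplexHit]
    mir_lnc_hits: list[DuplexHit]
    triples: list[CeRNATriple]
    network: CeRNANetwork
    ranked_axes: list[RankedAxis]

    def stage_counts(self) -> dict[str, int]:
        return {
            "de_significant": sum(1 for recs in self.de_tables.values()
                                  for r in recs if r.direction != "ns"),
            "consensus_features": len(self.consensus),
            "lnc_mrna_pairs": len(self.lnc_mrna_pairs),
            "negative_mir_mrna_pairs": len(self.negative_pairs),
            "predicted_pairs": len(self.predicted_pairs),
            "mir_mrna_pairs": len(self.mir_mrna_pairs),
            "mir_lnc_pairs": len(self.mir_lnc_hits),
            "triples": len(self.triples),
            "network_nodes": self.network.graph.number_of_nodes(),
            "network_edges": self.network.graph.number_of_edges(),
        }


def _subset(dataset: ExpressionDataset, feature_ids: Sequence[str]) -> ExpressionDataset:
    keep = [f for f in dataset.feature_ids if f in set(feature_ids)]
    return ExpressionDataset(dataset.dataset_id, dataset.molecule_kind,
                             dataset.matrix.loc[keep], dataset.sample_metadata,
                             dataset.design)


def analyze_bundle(bundle: StudyBundle,
                   settings: PipelineSettings = PipelineSettings()) -> PipelineResult:
    """Run the full analysis on an in-memory bundle."""
    by_key = bundle.datasets_by_id()
    dataset_ids = sorted({ds for ds, _ in by_key})

    # 1. differential expression per dataset and molecule kind
    de_tables: dict[str, list[DERecord]] = {ds: [] for ds in dataset_ids}
    for (ds_id, kind), dataset in sorted(by_key.items()):
        records = fit_de(dataset, settings.moderation)
        thr = settings.de_thresholds.get(kind)
        if thr is None:
            raise ConfigError(f"no DE thresholds configured for kind {kind!r}")
        de_tables[ds_id].extend(apply_thresholds(records, thr))

    # 2. consensus and direction resolution
    consensus = consensus_sets(de_tables)
    directions = resolve_node_directions(consensus, settings.direction_policies)
    sig_by_kind: dict[str, list[str]] = {"mRNA": [], "lncRNA": [], "miRNA": []}
    for rec in consensus:
        sig_by_kind[rec.molecule_kind].append(rec.feature_id)

    # 3. lncRNA-mRNA positive synergy per dataset, intersected
    per_dataset_pairs = []
    for ds_id in dataset_ids:
        lnc = _subset(by_key[(ds_id, "lncRNA")], sig_by_kind["lncRNA"])
        mrna = _subset(by_key[(ds_id, "mRNA")], sig_by_kind["mRNA"])
        if not lnc.feature_ids or not mrna.feature_ids:
            per_dataset_pairs.append([])
            continue
        pairs = correlate_all(lnc, mrna, "lnc_mrna")
        per_dataset_pairs.append(screen_pairs(pairs, settings.lnc_mrna_thresholds))
    lnc_mrna_pairs = intersect_pair_sets(per_dataset_pairs)

    # 4. miRNA-mRNA negative correlation (single source dataset)
    mm_ds = settings.mir_mrna_dataset or dataset_ids[0]
    mir = _subset(by_key[(mm_ds, "miRNA")], sig_by_kind["miRNA"])
    mrna = _subset(by_key[(mm_ds, "mRNA")], sig_by_kind["mRNA"])
    if mir.feature_ids and mrna.feature_ids:
        negative_pairs = screen_negative(
            correlate_all(mir, mrna, "mir_mrna"), settings.mir_mrna_p_max)
    else:
        negative_pairs = []

    # 5. evidence filter and intersection
    predicted = filter_by_support(bundle.evidence, settings.min_sources)
    mir_mrna_pairs = intersect_with_corr(predicted, negative_pairs)

    # 6. duplex scan of consensus miRNAs against consensus lncRNAs
    mirnas = {m: bundle.mirna_sequences[m] for m in sig_by_kind["miRNA"]
              if m in bundle.mirna_sequences}
    lncrnas = {l: bundle.lncrna_sequences[l] for l in sig_by_kind["lncRNA"]
               if l in bundle.lncrna_sequences}
    duplex_hits = scan_all(mirnas, lncrnas, settings.duplex_scoring,
                           settings.energy_model,
                           min_report_score=settings.duplex_thresholds.score_min)
    mir_lnc_hits = screen_hits(duplex_hits, settings.duplex_thresholds)

    # 7. triple assembly with provenance
    mir_lnc = [(h.mirna_id, h.target_id) for h in mir_lnc_hits]
    mir_mrna = [(p.mirna_id, p.mrna_id) for p in mir_mrna_pairs]
    lnc_mrna = [(p.a_id, p.b_id) for p in lnc_mrna_pairs]
    triples = assemble_triples(mir_lnc, mir_mrna, lnc_mrna, directions)
    lnc_map = {p.key: p for p in lnc_mrna_pairs}
    mm_map = {p.key: p for p in mir_mrna_pairs}
    hit_map = {(h.mirna_id, h.target_id): h for h in mir_lnc_hits}
    for t in triples:
        cp = lnc_map[(t.lncrna_id, t.mrna_id)]
        tp = mm_map[(t.mirna_id, t.mrna_id)]
        h = hit_map[(t.mirna_id, t.lncrna_id)]
        t.provenance = TripleProvenance(
            lnc_mrna_r=dict(cp.r_by_dataset), mir_mrna_r=tp.r,
            evidence_support=tp.support, duplex_score=h.score,
            duplex_energy=h.energy)

    # 8. network, degree, axis ranking
    network = build_network(triples, directions, settings.include_coexpr_edges)
    ranked = rank_core_axes(triples, network, de_tables, settings.axis_weights)

    return PipelineResult(de_tables, consensus, directions, lnc_mrna_pairs,
                          negative_pairs, predicted, mir_mrna_pairs,
                          duplex_hits, mir_lnc_hits, triples, network, ranked)


# ------------------------------------------------------------- file-driven run

@dataclass
class DatasetSpec:
    dataset_id: str
    molecule_kind: str
    matrix: str
    metadata: str
    design: str = "paired"
    probe_map: str | None = None


@dataclass
class PipelineConfig:
    """File-level configuration for a pipeline run."""

    datasets: list[DatasetSpec]
    evidence: str
    mirna_fasta: str
    lncrna_fasta: str
    out_dir: str
    seed: int = 0
    settings: PipelineSettings = field(default_factory=PipelineSettings)

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ConfigError("pipeline config lists no datasets")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        datasets = [DatasetSpec(**d) for d in raw.pop("datasets", [])]
        settings = PipelineSettings()
        s = raw.pop("settings", {}) or {}
        if "de_thresholds" in s:
            settings.de_thresholds = {
                kind: (THRESHOLD_PRESETS[v] if isinstance(v, str)
                       else DEThresholds(**v))
                for kind, v in s["de_thresholds"].items()}
        if "min_sources" in s:
            settings.min_sources = int(s["min_sources"])
        if "duplex_thresholds" in s:
            settings.duplex_thresholds = DuplexThresholds(**s["duplex_thresholds"])
        if "lnc_mrna_thresholds" in s:
            settings.lnc_mrna_thresholds = CoexprThresholds(**s["lnc_mrna_thresholds"])
        if "moderation" in s:
            settings.moderation = ModerationParams(**s["moderation"])
        return cls(datasets=datasets, settings=settings, **raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stage_counts: dict[str, int]
    output_paths: dict[str, str]
    started: str
    finished: str

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")
        return Path(path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline from files and write all intermediates."""
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    datasets = [cio.read_expression(d.matrix, d.metadata, d.dataset_id,
                                    d.molecule_kind, d.design, d.probe_map)
                for d in config.datasets]
    evidence = EvidenceTable.from_tsv(config.evidence)
    bundle = StudyBundle(datasets=datasets, evidence=evidence,
                         mirna_sequences=cio.read_fasta(config.mirna_fasta),
                         lncrna_sequences=cio.read_fasta(config.lncrna_fasta),
                         truth=None, config=None)
    result = analyze_bundle(bundle, config.settings)

    paths: dict[str, str] = {}
    for ds_id, records in sorted(result.de_tables.items()):
        paths[f"de.{ds_id}"] = str(cio.write_de_table(records, out / f"de.{ds_id}.tsv"))
    paths["lnc_mrna_pairs"] = str(cio.write_correlation_pairs(
        result.lnc_mrna_pairs, out / "lnc_mrna_pairs.tsv"))
    paths["mir_mrna_pairs"] = str(cio.write_target_pairs(
        result.mir_mrna_pairs, out / "mir_mrna_pairs.tsv"))
    paths["triples"] = str(cio.write_triples(result.triples, out / "triples.tsv"))
    sif, attrs = cio.write_network(result.network, out)
    paths["network_sif"] = str(sif)
    paths["network_nodes"] = str(attrs)

    manifest = RunManifest(
        config={"datasets": [dataclasses.asdict(d) for d in config.datasets],
                "evidence": config.evidence, "out_dir": config.out_dir},
        version=__version__, seed=config.seed,
        stage_counts=result.stage_counts(), output_paths=paths,
        started=started, finished=time.strftime("%Y-%m-%dT%H:%M:%S"))
    manifest.to_json(out / "manifest.json")
    logger.info("pipeline finished: %s", manifest.stage_counts)
    return manifest
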