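"""ceRNA triple assembly, network construction and core-axis ranking.

A lncRNA-miRNA-mRNA triple is emitted when the lncRNA and the mRNA are
both targeted by the same miRNA (miRNA-lncRNA duplex evidence and
miRNA-mRNA prediction+anticorrelation evidence), the lncRNA and mRNA are
synergistically coexpressed, their differential-expression directions
agree, and the miRNA's direction (when determined) opposes them — the
sponge topology.  The resulting tripartite network is analyzed with
unweighted degree centrality, and candidate core axes are ranked by a
composite of node degree, effect size and cross-dataset reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .diffexpr import ConfigError, ConsensusRecord, DERecord, DOWN, NS, UP

UNDETERMINED = "undetermined"


@dataclass
class TripleProvenance:
    """Edge-level evidence carried along with an assembled triple."""

    lnc_mrna_r: dict[str, float] = field(default_factory=dict)  # dataset -> r
    mir_mrna_r: float | None = None
    evidence_support: int | None = None
    duplex_score: float | None = None
    duplex_energy: float | None = None


@dataclass
class CeRNATriple:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    lnc_direction: str
    mrna_direction: str
    mirna_direction: str            # up / down / undetermined
    provenance: TripleProvenance = field(default_factory=TripleProvenance)

    def __post_init__(self) -> None:
        if self.lnc_direction != self.mrna_direction:
            raise ConfigError("lncRNA and mRNA directions must agree in a triple")
        if self.mirna_direction not in (UP, DOWN, UNDETERMINED):
            raise ConfigError(f"bad miRNA direction {self.mirna_direction!r}")
        if self.mirna_direction != UNDETERMINED and \
                self.mirna_direction == self.mrna_direction:
            raise ConfigError("a determined miRNA direction must oppose the mRNA's")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lncrna_id, self.mirna_id, self.mrna_id)


@dataclass(frozen=True)
class AxisScoreWeights:
    """Weights of the composite axis score; must sum to 1."""

    w_degree: float = 1.0 / 3.0
    w_logfc: float = 1.0 / 3.0
    w_reproducibility: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.w_degree, self.w_logfc, self.w_reproducibility) < 0:
            raise ConfigError("axis weights must be >= 0")
        if abs(self.w_degree + self.w_logfc + self.w_reproducibility - 1.0) > 1e-9:
            raise ConfigError("axis weights must sum to 1")


EDGE_KINDS = ("mir_lnc", "mir_mrna", "lnc_mrna_coexpr")


@dataclass
class CeRNANetwork:
    """Tripartite network over assembled triples.

    ``graph`` is an undirected networkx graph whose nodes carry ``kind``
    and ``direction`` attributes and whose edges carry ``edge_kind``;
    degree counts unweighted incident edges of all kinds unless the
    network was built with ``regulatory_only``.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[tuple[str, dict]]:
        return sorted(self.graph.nodes(data=True))

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        return sorted((min(u, v), max(u, v), d["edge_kind"])
                      for u, v, d in self.graph.edges(data=True))

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node])

    def degrees(self) -> dict[str, int]:
        return {n: int(d) for n, d in self.graph.degree()}


def resolve_node_directions(consensus: Sequence[ConsensusRecord],
                            policy_by_kind: Mapping[str, str] | None = None
                            ) -> dict[str, str]:
    """Map consensus features to regulatory directions.

    ``policy_by_kind`` maps molecule kind to "exclude" (drop features whose
    datasets disagree on direction) or "undetermined" (retain them without
    a direction).  Default: exclude for mRNA and lncRNA, undetermined for
    miRNA, matching the convention that a miRNA whose trend cannot be
    determined still appears in the network without an arrow.
    """
    policies = {"mRNA": "exclude", "lncRNA": "exclude", "miRNA": "undetermined"}
    if policy_by_kind:
        for kind, pol in policy_by_kind.items():
            if pol not in ("exclude", "undetermined"):
                raise ConfigError(f"unknown direction policy {pol!r}")
            policies[kind] = pol
    directions: dict[str, str] = {}
    for rec in consensus:
        if rec.consistent:
            directions[rec.feature_id] = rec.consensus_direction
        elif policies.get(rec.molecule_kind, "exclude") == "undetermined":
            directions[rec.feature_id] = UNDETERMINED
        # else excluded entirely
    return directions


def assemble_triples(mir_lnc: Iterable[tuple[str, str]],
                     mir_mrna: Iterable[tuple[str, str]],
                     lnc_mrna: Iterable[tuple[str, str]],
                     directions: Mapping[str, str],
                     provenance: Mapping[tuple[str, str, str], TripleProvenance]
                     | None = None) -> list[CeRNATriple]:
    """Emit every (lncRNA, miRNA, mRNA) satisfying the ceRNA membership rules.

    Inputs are pair sets keyed (mirna, lncrna), (mirna, mrna) and
    (lncrna, mrna) respectively; ``directions`` maps feature ids to
    up/down/undetermined.  A triple is emitted iff all three edges exist,
    the lncRNA and mRNA share a determined direction, and the miRNA is
    either undetermined or opposite.  Output sorted by
    (lncrna_id, mirna_id, mrna_id).
    """
    mir_lnc_set = set(mir_lnc)
    mir_mrna_set = set(mir_mrna)
    lnc_mrna_set = set(lnc_mrna)
    triples: list[CeRNATriple] = []
    for m, l in sorted(mir_lnc_set):
        d_l = directions.get(l)
        if d_l not in (UP, DOWN):
            continue
        d_m = directions.get(m)
        if d_m is None:
            continue
        for m2, g in sorted(mir_mrna_set):
            if m2 != m:
                continue
            d_g = directions.get(g)
            if d_g != d_l:
                continue
            if (l, g) not in lnc_mrna_set:
                continue
            if d_m != UNDETERMINED and d_m == d_g:
                continue
            prov = (provenance or {}).get((l, m, g), TripleProvenance())
            triples.append(CeRNATriple(l, m, g, d_l, d_g, d_m, prov))
    triples.sort(key=lambda t: t.key)
    return triples


def build_network(triples: Sequence[CeRNATriple],
                  directions: Mapping[str, str] | None = None,
                  include_coexpr_edges: bool = True) -> CeRNANetwork:
    """Build the tripartite graph and per-node unweighted degrees.

    Each triple contributes a mir_lnc and a mir_mrna regulatory edge plus,
    when ``include_coexpr_edges`` (default), the dashed lnc_mrna synergy
    edge; duplicate edges across triples collapse.
    """
    g = nx.Graph()
    directions = directions or {}
    for t in triples:
        g.add_node(t.lncrna_id, kind="lncRNA",
                   direction=directions.get(t.lncrna_id, t.lnc_direction))
        g.add_node(t.mirna_id, kind="miRNA",
                   direction=directions.get(t.mirna_id, t.mirna_direction))
        g.add_node(t.mrna_id, kind="mRNA",
                   direction=directions.get(t.mrna_id, t.mrna_direction))
        g.add_edge(t.mirna_id, t.lncrna_id, edge_kind="mir_lnc")
        g.add_edge(t.mirna_id, t.mrna_id, edge_kind="mir_mrna")
        if include_coexpr_edges:
            g.add_edge(t.lncrna_id, t.mrna_id, edge_kind="lnc_mrna_coexpr")
    return CeRNANetwork(g)


def _minmax(values: Mapping[str, float]) -> dict[str, float]:
    if not values:
        return {}
    lo, hi = min(values.values()), max(values.values())
    if hi == lo:
        return {k: 1.0 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


@dataclass
class RankedAxis:
    triple: CeRNATriple
    score: float
    degree_component: float
    logfc_component: float
    reproducibility_component: float


def rank_core_axes(triples: Sequence[CeRNATriple], network: CeRNANetwork,
                   de_tables: Mapping[str, Sequence[DERecord]],
                   weights: AxisScoreWeights = AxisScoreWeights()
                   ) -> list[RankedAxis]:
    """Rank triples as candidate core regulatory axes.

    Score = w_degree * mean min-max-normalized node degree
          + w_logfc * mean (across members and datasets) min-max-normalized |logFC|
          + w_repro * mean fraction of datasets where each member is
            significant with its consensus direction.
    Ties broken lexicographically by (lncrna_id, mirna_id, mrna_id).
    """
    if not triples:
        return []
    norm_degree = _minmax({n: float(d) for n, d in network.graph.degree()})

    # per-dataset min-max normalization of |logFC|, then lookup maps
    abs_lfc_norm: dict[str, dict[str, float]] = {}
    sig_dir: dict[str, dict[str, str]] = {}
    for ds_id, records in de_tables.items():
        abs_lfc_norm[ds_id] = _minmax({r.feature_id: abs(r.logFC) for r in records})
        sig_dir[ds_id] = {r.feature_id: r.direction for r in records}

    def member_logfc(fid: str) -> float:
        vals = [m[fid] for m in abs_lfc_norm.values() if fid in m]
        return float(np.mean(vals)) if vals else 0.0

    def member_repro(fid: str, direction: str) -> float:
        present = [m for m in sig_dir.values() if fid in m]
        if not present:
            return 0.0
        hits = sum(1 for m in present
                   if m[fid] != NS and (direction == UNDETERMINED
                                        or m[fid] == direction))
        return hits / len(present)

    out: list[RankedAxis] = []
    for t in triples:
        members = [(t.lncrna_id, t.lnc_direction),
                   (t.mirna_id, t.mirna_direction),
                   (t.mrna_id, t.mrna_direction)]
        deg = float(np.mean([norm_degree.get(fid, 0.0) for fid, _ in members]))
        lfc = float(np.mean([member_logfc(fid) for fid, _ in members]))
        rep = float(np.mean([member_repro(fid, d) for fid, d in members]))
        score = (weights.w_degree * deg + weights.w_logfc * lfc
                 + weights.w_reproducibility * rep)
        out.append(RankedAxis(t, score, deg, lfc, rep))
    out.sort(key=lambda a: (-a.score, a.triple.key))
    return out


def validate_triples(triples: Sequence[CeRNATriple],
                     mir_lnc: Iterable[tuple[str, str]],
                     mir_mrna: Iterable[tuple[str, str]],
                     lnc_mrna: Iterable[tuple[str, str]],
                     directions: Mapping[str, str]) -> bool:
    """Re-check every emitted triple against the four membership predicates."""
    mir_lnc_set, mir_mrna_set, lnc_mrna_set = set(mir_lnc), set(mir_mrna), set(lnc_mrna)
    for t in triples:
        if (t.mirna_id, t.lncrna_id) not in mir_lnc_set:
            return False
        if (t.mirna_id, t.mrna_id) not in mir_mrna_set:
            return False
        if (t.lncrna_id, t.mrna_id) not in lnc_mrna_set:
            return False
        d_l, d_g = directions.get(t.lncrna_id), directions.get(t.mrna_id)
        d_m = directions.get(t.mirna_id)
        if d_l != d_g or d_l not in (UP, DOWN) or d_m is None:
            return False
        if d_m != UNDETERMINED and d_m == d_g:
            return False
    return True
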