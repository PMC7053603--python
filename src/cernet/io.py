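"""Readers and writers for the pipeline's exchange formats.

Tables travel as UTF-8 TSV with a header row; networks as SIF plus a node
attribute table; sequences as FASTA (via Biopython); ground truth and run
manifests as JSON.  All writers emit deterministically ordered output.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assembly import CeRNANetwork, CeRNATriple
from .coexpression import CorrelationPair
from .diffexpr import DERecord, ExpressionDataset, InputError, de_table
from .evidence import TargetPair
from .synthetic import PlantedTriple, StudyBundle, SyntheticTruth


# ---------------------------------------------------------------- expression

def write_expression(dataset: ExpressionDataset, out_dir: str | Path) -> tuple[Path, Path]:
    """Write matrix and metadata TSVs; returns their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{dataset.dataset_id}.{dataset.molecule_kind}"
    matrix_path = out / f"{stem}.expr.tsv"
    meta_path = out / f"{dataset.dataset_id}.samples.tsv"
    dataset.matrix.to_csv(matrix_path, sep="\t", index_label="feature_id")
    dataset.sample_metadata.to_csv(meta_path, sep="\t", index=False)
    return matrix_path, meta_path


def read_expression(matrix_tsv: str | Path, metadata_tsv: str | Path,
                    dataset_id: str, molecule_kind: str, design: str = "paired",
                    probe_map_tsv: str | Path | None = None) -> ExpressionDataset:
    """Load and validate an expression dataset from TSV files.

    When a probe map (columns ``probe_id``, ``feature_id``) is given, rows
    are collapsed to features keeping the probe with the highest mean
    expression.
    """
    matrix = pd.read_csv(matrix_tsv, sep="\t", index_col=0)
    try:
        matrix = matrix.astype(float)
    except ValueError as exc:
        raise InputError(f"non-numeric expression cell in {matrix_tsv}: {exc}") from exc
    meta = pd.read_csv(metadata_tsv, sep="\t", dtype=str)
    missing = set(matrix.columns) - set(meta.get("sample_id", []))
    if missing:
        raise InputError(
            f"metadata {metadata_tsv} missing sample(s) {sorted(missing)[:5]}")
    if probe_map_tsv is not None:
        matrix = collapse_probes(matrix, pd.read_csv(probe_map_tsv, sep="\t"))
    meta = meta.set_index("sample_id").loc[list(matrix.columns)].reset_index()
    return ExpressionDataset(dataset_id, molecule_kind, matrix, meta, design)


def collapse_probes(matrix: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level rows to features by highest mean expression."""
    for col in ("probe_id", "feature_id"):
        if col not in probe_map.columns:
            raise InputError(f"probe map lacks column {col!r}")
    mapping = probe_map.set_index("probe_id")["feature_id"]
    keep = matrix.index.intersection(mapping.index)
    sub = matrix.loc[keep].copy()
    sub["__feature"] = mapping.loc[keep].values
    sub["__mean"] = sub.drop(columns="__feature").mean(axis=1)
    best = (sub.sort_values("__mean", ascending=False)
               .drop_duplicates("__feature"))
    out = best.set_index("__feature").drop(columns="__mean")
    out.index.name = "feature_id"
    return out.sort_index()


# ---------------------------------------------------------------- pair tables

def write_de_table(records: Sequence[DERecord], path: str | Path) -> Path:
    df = de_table(records).sort_values("feature_id")
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_correlation_pairs(pairs: Sequence[CorrelationPair], path: str | Path) -> Path:
    dataset_ids = sorted({ds for p in pairs for ds in p.r_by_dataset})
    rows = []
    for p in sorted(pairs, key=lambda q: q.key):
        row = {"a_id": p.a_id, "b_id": p.b_id, "kind": p.pair_kind,
               "r": p.r, "p": p.p, "n": p.n}
        for ds in dataset_ids:
            row[f"r_{ds}"] = p.r_by_dataset.get(ds, np.nan)
        rows.append(row)
    cols = ["a_id", "b_id", "kind", "r", "p", "n"] + [f"r_{d}" for d in dataset_ids]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return Path(path)


def write_target_pairs(pairs: Sequence[TargetPair], path: str | Path) -> Path:
    df = pd.DataFrame(
        [(p.mirna_id, p.mrna_id, p.support, p.r) for p in sorted(pairs, key=lambda q: q.key)],
        columns=["mirna_id", "mrna_id", "support", "r"])
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_triples(triples: Sequence[CeRNATriple], path: str | Path) -> Path:
    rows = []
    for t in sorted(triples, key=lambda q: q.key):
        pr = t.provenance
        rows.append({
            "lncrna_id": t.lncrna_id, "mirna_id": t.mirna_id, "mrna_id": t.mrna_id,
            "lnc_direction": t.lnc_direction, "mrna_direction": t.mrna_direction,
            "mirna_direction": t.mirna_direction,
            "mir_mrna_r": pr.mir_mrna_r, "evidence_support": pr.evidence_support,
            "duplex_score": pr.duplex_score, "duplex_energy": pr.duplex_energy,
            **{f"lnc_mrna_r_{ds}": r for ds, r in sorted(pr.lnc_mrna_r.items())},
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


# ------------------------------------------------------------------- network

def write_network(network: CeRNANetwork, out_dir: str | Path) -> tuple[Path, Path]:
    """Write SIF (source, edge_kind, target) and a node-attribute TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sif_path = out / "network.sif"
    attr_path = out / "nodes.tsv"
    with open(sif_path, "w") as fh:
        for u, v, kind in network.edges:
            fh.write(f"{u}\t{kind}\t{v}\n")
    rows = [(n, d.get("kind", ""), d.get("direction", ""), network.degree(n))
            for n, d in network.nodes]
    pd.DataFrame(rows, columns=["id", "kind", "direction", "degree"]) \
        .to_csv(attr_path, sep="\t", index=False)
    return sif_path, attr_path


def read_sif(path: str | Path) -> list[tuple[str, str, str]]:
    edges = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            u, kind, v = line.rstrip("\n").split("\t")
            edges.append((u, kind, v))
    return edges


# ----------------------------------------------------------------- sequences

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> Path:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sorted(sequences.items())]
    SeqIO.write(records, str(path), "fasta")
    return Path(path)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# --------------------------------------------------------------- truth / JSON

def write_truth(truth: SyntheticTruth, path: str | Path) -> Path:
    payload = {
        "planted_triples": [asdict(t) for t in truth.planted_triples],
        "planted_de": dict(sorted(truth.planted_de.items())),
        "planted_sites": {f"{m}|{l}": list(iv)
                          for (m, l), iv in sorted(truth.planted_sites.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return Path(path)


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    truth = SyntheticTruth()
    truth.planted_triples = [PlantedTriple(**t) for t in payload["planted_triples"]]
    truth.planted_de = dict(payload["planted_de"])
    truth.planted_sites = {tuple(key.split("|")): tuple(iv)
                           for key, iv in payload["planted_sites"].items()}
    return truth


def write_bundle(bundle: StudyBundle, out_dir: str | Path) -> dict[str, str]:
    """Serialize a full synthetic bundle; returns a path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for ds in bundle.datasets:
        m, s = write_expression(ds, out)
        paths[f"{ds.dataset_id}.{ds.molecule_kind}"] = str(m)
        paths[f"{ds.dataset_id}.samples"] = str(s)
    bundle.evidence.to_tsv(out / "evidence.tsv")
    paths["evidence"] = str(out / "evidence.tsv")
    paths["mirna_fasta"] = str(write_fasta(bundle.mirna_sequences, out / "mirna.fa"))
    paths["lncrna_fasta"] = str(write_fasta(bundle.lncrna_sequences, out / "lncrna.fa"))
    paths["truth"] = str(write_truth(bundle.truth, out / "truth.json"))
    return paths
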