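"""Synthetic multi-dataset study bundles with planted ceRNA structure.

The generator emulates the statistical design the pipeline assumes: several
pseudo-datasets of paired tumor/normal log2 expression for mRNAs, lncRNAs
and miRNAs, with a configurable number of planted lncRNA-miRNA-mRNA triples
whose members are differentially expressed (miRNA opposite in sign to the
mRNA and lncRNA) and coupled through a Gaussian structural chain
(miRNA -> mRNA -> lncRNA) so that miRNA-mRNA correlation is negative and
lncRNA-mRNA correlation positive, with strength set by
``coupling_strength``.  It also fabricates the side inputs of the later
stages: a multi-source target-evidence table with tunable sensitivity and
false-positive rate, lncRNA/miRNA sequences with planted complementarity
sites, and qPCR/stage/score tables for the validation statistics.  Ground
truth is returned alongside so that every downstream stage can be tested
for recovery without external downloads.

All randomness flows from one master seed through named per-component
streams, so identical configs give byte-identical bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexpr import ConfigError, ExpressionDataset
from .duplex import reverse_complement
from .evidence import DEFAULT_SOURCE_NAMES, EvidenceTable

# stream indices for per-component child seeds
_STREAMS = {"baseline": 1, "expression": 2, "evidence": 3,
            "sequences": 4, "validation": 5}


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[component]]))


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic bundle.

    Counts and rates describe the planted structure; ``effect_logfc`` and
    ``noise_sd`` are in log2 units, and ``coupling_strength`` in (0, 1]
    sets the within-triple correlation magnitude.
    """

    n_mrna: int = 200
    n_lncrna: int = 50
    n_mirna: int = 20
    n_pairs_per_dataset: tuple[int, ...] = (10, 10)
    n_planted_triples: int = 10
    n_planted_de_singletons: int = 5
    effect_logfc: float = 2.0
    noise_sd: float = 0.5
    coupling_strength: float = 0.9
    evidence_n_sources: int = 12
    evidence_sensitivity: float = 0.9
    evidence_fpr: float = 0.02
    seed: int = 0
    # secondary knobs
    decoy_factor: int = 5
    mirna_length: int = 22
    lncrna_length: int = 300
    site_mode: str = "strong"            # "strong" (full) or "weak" (seed-only)
    ct_noise_sd: float = 0.2
    planted_ddct: float = 2.0
    n_validation_per_group: int = 10
    roc_separation: float = 3.0

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_planted_triples",
                     "n_planted_de_singletons", "evidence_n_sources",
                     "decoy_factor", "mirna_length", "lncrna_length",
                     "n_validation_per_group"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd must be > 0")
        for name in ("evidence_sensitivity", "evidence_fpr"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0.0 < self.coupling_strength <= 1.0:
            raise ConfigError("coupling_strength must be in (0, 1]")
        if self.n_planted_triples > min(self.n_mrna, self.n_lncrna, self.n_mirna):
            raise ConfigError(
                "n_planted_triples exceeds the smallest molecule-class size")
        if self.site_mode not in ("strong", "weak"):
            raise ConfigError("site_mode must be 'strong' or 'weak'")
        if any(n < 2 for n in self.n_pairs_per_dataset):
            raise ConfigError("n_pairs_per_dataset entries must be >= 2")
        self.n_pairs_per_dataset = tuple(int(n) for n in self.n_pairs_per_dataset)


@dataclass
class PlantedTriple:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    direction: str              # shared mRNA/lncRNA direction; miRNA opposite


@dataclass
class SyntheticTruth:
    planted_triples: list[PlantedTriple] = field(default_factory=list)
    planted_de: dict[str, str] = field(default_factory=dict)
    planted_sites: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)


@dataclass
class StudyBundle:
    datasets: list[ExpressionDataset]
    evidence: EvidenceTable
    mirna_sequences: dict[str, str]
    lncrna_sequences: dict[str, str]
    truth: SyntheticTruth | None
    config: SimulationConfig | None

    def datasets_by_id(self) -> dict[tuple[str, str], ExpressionDataset]:
        return {(d.dataset_id, d.molecule_kind): d for d in self.datasets}


def _feature_ids(config: SimulationConfig) -> dict[str, list[str]]:
    return {
        "mRNA": [f"MRNA{i + 1:04d}" for i in range(config.n_mrna)],
        "lncRNA": [f"LNC{i + 1:04d}" for i in range(config.n_lncrna)],
        "miRNA": [f"MIR{i + 1:04d}" for i in range(config.n_mirna)],
    }


def _plant_truth(config: SimulationConfig) -> SyntheticTruth:
    ids = _feature_ids(config)
    truth = SyntheticTruth()
    for i in range(config.n_planted_triples):
        direction = "down" if i % 2 == 0 else "up"
        opposite = "up" if direction == "down" else "down"
        t = PlantedTriple(ids["lncRNA"][i], ids["miRNA"][i], ids["mRNA"][i], direction)
        truth.planted_triples.append(t)
        truth.planted_de[t.mrna_id] = direction
        truth.planted_de[t.lncrna_id] = direction
        truth.planted_de[t.mirna_id] = opposite
    # independent DE singletons, after the triple block of each class
    for kind in ("mRNA", "lncRNA", "miRNA"):
        start = config.n_planted_triples
        for j in range(config.n_planted_de_singletons):
            idx = start + j
            if idx >= len(ids[kind]):
                break
            truth.planted_de[ids[kind][idx]] = "up" if j % 2 == 0 else "down"
    return truth


def generate_study(config: SimulationConfig) -> StudyBundle:
    """Generate the full bundle: expression, evidence, sequences, truth."""
    truth = _plant_truth(config)
    ids = _feature_ids(config)
    base_rng = component_rng(config.seed, "baseline")
    baselines = {kind: base_rng.uniform(6.0, 12.0, size=len(ids[kind]))
                 for kind in ("mRNA", "lncRNA", "miRNA")}

    expr_rng = component_rng(config.seed, "expression")
    effect = config.effect_logfc
    sd = config.noise_sd
    c = config.coupling_strength
    triple_index = {t.mrna_id: t for t in truth.planted_triples}
    sign = {"up": 1.0, "down": -1.0}

    datasets: list[ExpressionDataset] = []
    for d_idx, n_pairs in enumerate(config.n_pairs_per_dataset):
        ds_id = f"SIM{d_idx + 1:02d}"
        subjects = [f"subj{p + 1:02d}" for p in range(n_pairs)]
        sample_ids = [f"{ds_id}_{s}_{cond}" for s in subjects for cond in ("T", "N")]
        meta = pd.DataFrame({
            "sample_id": sample_ids,
            "subject_id": [s for s in subjects for _ in range(2)],
            "condition": ["tumor", "normal"] * n_pairs,
        })
        tumor_flag = np.array([cond == "T" for _ in subjects for cond in ("T", "N")],
                              dtype=float)
        n_samp = 2 * n_pairs

        mats = {kind: np.empty((len(ids[kind]), n_samp)) for kind in ids}
        # null + singleton features first: mean + effect*T + noise
        for kind in ids:
            z = expr_rng.standard_normal((len(ids[kind]), n_samp))
            delta = np.zeros(len(ids[kind]))
            for row, fid in enumerate(ids[kind]):
                if fid in truth.planted_de and fid not in (
                        [t.lncrna_id for t in truth.planted_triples]
                        + [t.mirna_id for t in truth.planted_triples]
                        + [t.mrna_id for t in truth.planted_triples]):
                    delta[row] = sign[truth.planted_de[fid]] * effect
            mats[kind][:] = (baselines[kind][:, None] + delta[:, None] * tumor_flag
                             + sd * z)
        # planted triples: Gaussian chain miRNA -> mRNA -> lncRNA
        for t in truth.planted_triples:
            s_g = sign[t.direction]
            z_m = expr_rng.standard_normal(n_samp)
            z_g = expr_rng.standard_normal(n_samp)
            z_l = expr_rng.standard_normal(n_samp)
            u_g = -c * z_m + math.sqrt(1.0 - c * c) * z_g
            u_l = c * u_g + math.sqrt(1.0 - c * c) * z_l
            i_m = ids["miRNA"].index(t.mirna_id)
            i_g = ids["mRNA"].index(t.mrna_id)
            i_l = ids["lncRNA"].index(t.lncrna_id)
            mats["miRNA"][i_m] = (baselines["miRNA"][i_m]
                                  - s_g * effect * tumor_flag + sd * z_m)
            mats["mRNA"][i_g] = (baselines["mRNA"][i_g]
                                 + s_g * effect * tumor_flag + sd * u_g)
            mats["lncRNA"][i_l] = (baselines["lncRNA"][i_l]
                                   + s_g * effect * tumor_flag + sd * u_l)
        for kind in ("mRNA", "lncRNA", "miRNA"):
            matrix = pd.DataFrame(mats[kind], index=ids[kind], columns=sample_ids)
            datasets.append(ExpressionDataset(ds_id, kind, matrix, meta.copy(),
                                              design="paired"))

    evidence = generate_evidence(truth, config)
    mirna_seqs, lncrna_seqs = generate_sequences(truth, config)
    return StudyBundle(datasets, evidence, mirna_seqs, lncrna_seqs, truth, config)


def generate_evidence(truth: SyntheticTruth, config: SimulationConfig) -> EvidenceTable:
    """Simulate the multi-source target-prediction table.

    Each true (miRNA, mRNA) pair gets per-source presence flags with
    probability ``evidence_sensitivity``; ``decoy_factor`` times as many
    non-pairs are sampled as decoys flagged with probability
    ``evidence_fpr``.  The sampling order (true flags, decoy choice, decoy
    flags) is fixed, so the stream is reproducible.
    """
    if config.evidence_n_sources < 1:
        raise ConfigError("evidence_n_sources must be >= 1")
    rng = component_rng(config.seed, "evidence")
    sources = tuple(DEFAULT_SOURCE_NAMES[:config.evidence_n_sources]) if \
        config.evidence_n_sources <= len(DEFAULT_SOURCE_NAMES) else \
        tuple(f"source{i + 1}" for i in range(config.evidence_n_sources))
    ids = _feature_ids(config)
    true_pairs = [(t.mirna_id, t.mrna_id) for t in truth.planted_triples]
    rows = []
    flags_true = rng.random((len(true_pairs), len(sources))) < config.evidence_sensitivity
    for (m, g), fl in zip(true_pairs, flags_true):
        rows.append((m, g, *fl.astype(int)))
    all_pairs = [(m, g) for m in ids["miRNA"] for g in ids["mRNA"]]
    decoy_candidates = [p for p in all_pairs if p not in set(true_pairs)]
    n_decoys = min(config.decoy_factor * len(true_pairs), len(decoy_candidates))
    if n_decoys > 0:
        decoy_idx = rng.choice(len(decoy_candidates), size=n_decoys, replace=False)
        flags_decoy = rng.random((n_decoys, len(sources))) < config.evidence_fpr
        for idx, fl in zip(decoy_idx, flags_decoy):
            m, g = decoy_candidates[idx]
            rows.append((m, g, *fl.astype(int)))
    df = pd.DataFrame(rows, columns=["mirna_id", "mrna_id", *sources])
    return EvidenceTable(df, sources)


def generate_sequences(truth: SyntheticTruth, config: SimulationConfig
                       ) -> tuple[dict[str, str], dict[str, str]]:
    """Random-composition sequences with planted complementarity sites.

    Returns ``(mirna_sequences, lncrna_sequences)``.  For every planted
    (miRNA, lncRNA) pair the reverse complement of the miRNA (full length
    for strong sites, seed positions 2-8 only for weak sites) is embedded
    at a recorded 1-based inclusive interval on the target 5'->3' strand;
    the interval is stored in ``truth.planted_sites``.
    """
    rng = component_rng(config.seed, "sequences")
    bases = np.array(list("ACGU"))
    ids = _feature_ids(config)
    mirna_seqs = {m: "".join(rng.choice(bases, size=config.mirna_length))
                  for m in ids["miRNA"]}
    lncrna_seqs = {l: "".join(rng.choice(bases, size=config.lncrna_length))
                   for l in ids["lncRNA"]}
    for t in truth.planted_triples:
        mi = mirna_seqs[t.mirna_id]
        site = (reverse_complement(mi) if config.site_mode == "strong"
                else reverse_complement(mi[1:8]))
        target = lncrna_seqs[t.lncrna_id]
        if len(target) < len(site):
            raise ConfigError(
                f"lncrna_length {len(target)} shorter than planted site "
                f"({len(site)} nt)")
        pos = int(rng.integers(0, len(target) - len(site) + 1))
        lncrna_seqs[t.lncrna_id] = (target[:pos] + site + target[pos + len(site):])
        truth.planted_sites[(t.mirna_id, t.lncrna_id)] = (pos + 1, pos + len(site))
    return mirna_seqs, lncrna_seqs


def generate_validation_tables(config: SimulationConfig
                               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fixtures for the validation statistics.

    Returns ``(ct_table, stage_table, score_table)``: a qPCR Ct table with
    a planted group-level ddCt, a tumor-stage label table (T1/T2/T3), and
    a diagnostic score table with class separation ``roc_separation`` (in
    units of the within-class standard deviation; ``inf`` gives disjoint
    supports and hence AUC 1).
    """
    rng = component_rng(config.seed, "validation")
    n = config.n_validation_per_group
    groups = ["case"] * n + ["control"] * n
    sample_ids = [f"V{i + 1:03d}" for i in range(2 * n)]
    ct_ref = rng.normal(15.0, config.ct_noise_sd, size=2 * n)
    ct_target = np.concatenate([
        rng.normal(20.0 + config.planted_ddct, config.ct_noise_sd, size=n),
        rng.normal(20.0, config.ct_noise_sd, size=n),
    ])
    ct_table = pd.DataFrame({"sample_id": sample_ids, "group": groups,
                             "ct_target": ct_target, "ct_reference": ct_ref})

    stages = [("T1", "T2", "T3")[i % 3] for i in range(2 * n)]
    stage_table = pd.DataFrame({"sample_id": sample_ids, "stage": stages})

    labels = np.array([1] * n + [0] * n)
    if math.isinf(config.roc_separation):
        pos = rng.uniform(2.0, 3.0, size=n)
        neg = rng.uniform(0.0, 1.0, size=n)
    else:
        pos = rng.normal(config.roc_separation, 1.0, size=n)
        neg = rng.normal(0.0, 1.0, size=n)
    score_table = pd.DataFrame({"sample_id": sample_ids, "label": labels,
                                "score": np.concatenate([pos, neg])})
    return ct_table, stage_table, score_table
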