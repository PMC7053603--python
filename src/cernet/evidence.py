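"""Multi-source miRNA-target prediction evidence.

Target predictions are ingested as a table with one 0/1 presence column per
prediction source (twelve by default, mirroring the common aggregator
databases).  A pair is treated as predicted when it is supported by at
least ``min_sources`` sources, and the predicted set is then intersected
with the expression-derived negative-correlation pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coexpression import CorrelationPair
from .diffexpr import ConfigError, InputError

DEFAULT_SOURCE_NAMES = (
    "miRWalk", "MicroT4", "miRanda", "miRBridge", "miRDB", "miRMap",
    "miRNAMap", "PICTAR2", "PITA", "RNA22", "RNAhybrid", "Targetscan",
)


@dataclass
class TargetPair:
    """A predicted miRNA-mRNA pair with its provenance annotations."""

    mirna_id: str
    mrna_id: str
    support: int
    r: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.mrna_id)


@dataclass
class EvidenceTable:
    """Per-pair presence flags across prediction sources.

    ``table`` has columns ``mirna_id``, ``mrna_id`` and one 0/1 column per
    source name; ``support`` is derived as the row sum of the flags.
    """

    table: pd.DataFrame
    source_names: tuple[str, ...] = DEFAULT_SOURCE_NAMES

    def __post_init__(self) -> None:
        self.source_names = tuple(self.source_names)
        for col in ("mirna_id", "mrna_id"):
            if col not in self.table.columns:
                raise InputError(f"evidence table lacks column {col!r}")
        missing = [s for s in self.source_names if s not in self.table.columns]
        if missing:
            raise InputError(f"evidence table lacks source column(s) {missing}")
        flags = self.table[list(self.source_names)].to_numpy()
        if not np.isin(flags, (0, 1)).all():
            raise InputError("source flags must be 0/1")
        if self.table.duplicated(subset=["mirna_id", "mrna_id"]).any():
            raise InputError("duplicate (mirna_id, mrna_id) rows in evidence table")

    @property
    def n_sources(self) -> int:
        return len(self.source_names)

    @property
    def support(self) -> pd.Series:
        return self.table[list(self.source_names)].sum(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        cols = ["mirna_id", "mrna_id", *self.source_names]
        self.table[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EvidenceTable":
        df = pd.read_csv(path, sep="\t")
        sources = tuple(c for c in df.columns if c not in ("mirna_id", "mrna_id"))
        return cls(df, sources)


def filter_by_support(evidence: EvidenceTable, min_sources: int = 6) -> list[TargetPair]:
    """Keep pairs supported by at least ``min_sources`` sources (inclusive)."""
    if min_sources < 1:
        raise ConfigError(f"min_sources must be >= 1, got {min_sources}")
    if min_sources > evidence.n_sources:
        raise ConfigError(
            f"min_sources={min_sources} exceeds the {evidence.n_sources} "
            "available sources")
    support = evidence.support
    kept = evidence.table.loc[support >= min_sources, ["mirna_id", "mrna_id"]]
    out = [TargetPair(m, g, int(s))
           for (m, g), s in zip(kept.itertuples(index=False, name=None),
                                support[support >= min_sources])]
    out.sort(key=lambda p: p.key)
    return out


def intersect_with_corr(predicted: Sequence[TargetPair],
                        correlated: Sequence[CorrelationPair]) -> list[TargetPair]:
    """Pairs present in both inputs, keyed on (mirna_id, mrna_id).

    Correlation pairs must be of kind ``mir_mrna`` with the miRNA as
    ``a_id``; the output carries both the support count and r.
    """
    for c in correlated:
        if c.pair_kind != "mir_mrna":
            raise InputError(
                f"expected mir_mrna correlation pairs, got {c.pair_kind!r}")
    corr_map = {c.key: c for c in correlated}
    out = [TargetPair(p.mirna_id, p.mrna_id, p.support, corr_map[p.key].r)
           for p in predicted if p.key in corr_map]
    out.sort(key=lambda p: p.key)
    return out
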