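"""Pearson coexpression screening between molecule classes.

lncRNA-mRNA candidate pairs are kept when they are strongly positively
correlated (synergistic expression, r and p gates) in every dataset;
miRNA-mRNA pairs are kept when negatively correlated, reflecting the
repressive action of a miRNA on its targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .diffexpr import ConfigError, ExpressionDataset, InputError

logger = logging.getLogger(__name__)

PAIR_KINDS = ("lnc_mrna", "mir_mrna")


@dataclass
class CorrelationPair:
    """A correlated feature pair with its significance test.

    ``r_by_dataset`` is populated by :func:`intersect_pair_sets` so that a
    retained pair carries the per-dataset coefficients it survived with.
    """

    a_id: str
    b_id: str
    pair_kind: str
    r: float
    p: float
    n: int
    dataset_id: str | None = None
    r_by_dataset: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pair_kind not in PAIR_KINDS:
            raise ConfigError(f"pair_kind must be one of {PAIR_KINDS}")
        if self.n < 3:
            raise InputError("correlation requires n >= 3 samples")
        if abs(self.r) > 1 + 1e-12:
            raise InputError(f"|r| must be <= 1, got {self.r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.a_id, self.b_id)


@dataclass(frozen=True)
class CoexprThresholds:
    """Screening mode and gates.

    ``positive_synergy`` keeps r > r_min and p < p_max (strict); it is the
    lncRNA-mRNA rule.  ``negative_only`` keeps r < 0 with no p gate, the
    miRNA-mRNA rule (an optional p gate can be supplied via ``p_max``).
    """

    mode: str = "positive_synergy"
    r_min: float = 0.7
    p_max: float | None = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("positive_synergy", "negative_only"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "positive_synergy" and not (0.0 < self.r_min < 1.0):
            raise ConfigError(f"r_min must be in (0,1), got {self.r_min}")


def pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of Pearson r via t = r*sqrt((n-2)/(1-r^2)), n-2 df.

    |r| = 1 maps to p = 0 exactly.
    """
    r = np.asarray(r, dtype=float)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def correlate_all(set_a: ExpressionDataset, set_b: ExpressionDataset,
                  pair_kind: str) -> list[CorrelationPair]:
    """All-pairs Pearson correlations over the shared ordered sample list.

    Zero-variance features are skipped with a warning; both datasets must
    present identical sample_id sequences (tumor and normal alike).
    """
    if list(set_a.matrix.columns) != list(set_b.matrix.columns):
        raise InputError(
            f"datasets {set_a.dataset_id!r} and {set_b.dataset_id!r} do not "
            "share an identical ordered sample list")
    a = set_a.matrix.to_numpy(dtype=float)
    b = set_b.matrix.to_numpy(dtype=float)
    n = a.shape[1]
    if n < 3:
        raise InputError("correlation requires at least 3 shared samples")

    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    a_sd = np.sqrt((a_c ** 2).sum(axis=1))
    b_sd = np.sqrt((b_c ** 2).sum(axis=1))
    a_ok = a_sd > 0
    b_ok = b_sd > 0
    n_skipped = int((~a_ok).sum() + (~b_ok).sum())
    if n_skipped:
        logger.warning("skipping %d zero-variance feature(s) in correlation "
                       "between %s and %s", n_skipped, set_a.dataset_id,
                       set_b.dataset_id)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a_c @ b_c.T) / np.outer(a_sd, b_sd)
    r = np.clip(r, -1.0, 1.0)
    p = pearson_p(r, n)

    a_ids = set_a.feature_ids
    b_ids = set_b.feature_ids
    out: list[CorrelationPair] = []
    for i in np.nonzero(a_ok)[0]:
        for j in np.nonzero(b_ok)[0]:
            out.append(CorrelationPair(a_ids[i], b_ids[j], pair_kind,
                                       float(r[i, j]), float(p[i, j]), n,
                                       dataset_id=set_a.dataset_id))
    return out


def screen_pairs(pairs: Sequence[CorrelationPair],
                 thresholds: CoexprThresholds) -> list[CorrelationPair]:
    """Apply the mode's gates (strict inequalities)."""
    if thresholds.mode == "positive_synergy":
        return [p for p in pairs
                if p.r > thresholds.r_min and p.p < thresholds.p_max]
    # negative_only: no p gate by design; see screen_negative for the
    # optional gated variant
    return [p for p in pairs if p.r < 0]


def screen_negative(pairs: Sequence[CorrelationPair],
                    p_max: float | None = None) -> list[CorrelationPair]:
    """Keep negatively correlated pairs; optional p gate (off by default)."""
    kept = [p for p in pairs if p.r < 0]
    if p_max is not None:
        kept = [p for p in kept if p.p < p_max]
    return kept


def intersect_pair_sets(sets: Sequence[Sequence[CorrelationPair]]) -> list[CorrelationPair]:
    """Pairs present in every set, keyed on (a_id, b_id).

    The retained record is the first set's record annotated with every
    dataset's r value in ``r_by_dataset``.
    """
    if not sets:
        raise InputError("intersect_pair_sets requires at least one set")
    maps = [{p.key: p for p in s} for s in sets]
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    out: list[CorrelationPair] = []
    for key in sorted(common):
        first = maps[0][key]
        rec = CorrelationPair(first.a_id, first.b_id, first.pair_kind,
                              first.r, first.p, first.n,
                              dataset_id=first.dataset_id)
        for m in maps:
            p = m[key]
            rec.r_by_dataset[p.dataset_id or f"set{maps.index(m)}"] = p.r
        out.append(rec)
    return out
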