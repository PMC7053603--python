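"""Downstream diagnostics: gene-set enrichment, ROC/AUC, and 2^-ddCt.

Enrichment uses the hypergeometric upper tail P(X >= k) against a
user-supplied universe, or its conservative EASE variant (overlap reduced
by one before taking the tail), with Benjamini-Hochberg adjustment within
each collection category.  ROC curves are built over all distinct score
thresholds with trapezoidal AUC, which equals the Mann-Whitney statistic
with half credit for ties.  Relative qPCR quantification follows the
2^-ddCt convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .diffexpr import InputError, bh_adjust


@dataclass
class GeneSet:
    """A named gene set from a collection such as GO or KEGG."""

    name: str
    category: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise InputError(f"gene set {self.name!r} has no members")


@dataclass
class EnrichmentResult:
    name: str
    category: str
    k: int                  # overlap count
    overlap: tuple[str, ...]
    K: int                  # set size within the universe
    n: int                  # query size
    N: int                  # universe size
    p: float
    adj_p: float
    method: str


def read_gmt(path: str | Path, category: str | None = None) -> list[GeneSet]:
    """Read a GMT gene-set file (name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"malformed GMT line: {line[:80]!r}")
            name, desc = parts[0], parts[1]
            members = frozenset(g for g in parts[2:] if g)
            sets.append(GeneSet(name, category or desc or "geneset", members))
    return sets


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def enrich_sets(query: Iterable[str], universe: Iterable[str],
                collections: Sequence[GeneSet],
                method: str = "ease") -> list[EnrichmentResult]:
    """Test the query gene list against each gene set.

    ``hypergeometric`` tests P(X >= k); ``ease`` replaces k with
    max(k - 1, 0) before taking the tail (the conservative DAVID-style
    variant).  Sets are intersected with the universe before sizing; BH
    adjustment is applied within each category; results sorted by p
    ascending, ties by (category, name).
    """
    if method not in ("hypergeometric", "ease"):
        raise InputError(f"unknown enrichment method {method!r}")
    query_set = frozenset(query)
    universe_set = frozenset(universe)
    if not query_set <= universe_set:
        missing = sorted(query_set - universe_set)[:5]
        raise InputError(f"query gene(s) not in universe, e.g. {missing}")
    N = len(universe_set)
    n = len(query_set)
    results: list[EnrichmentResult] = []
    for gs in collections:
        members = gs.members & universe_set
        if not members:
            continue
        overlap = tuple(sorted(query_set & members))
        k = len(overlap)
        k_eff = max(k - 1, 0) if method == "ease" else k
        p = hypergeom_tail(k_eff, N, len(members), n)
        results.append(EnrichmentResult(gs.name, gs.category, k, overlap,
                                        len(members), n, N, p, math.nan, method))
    # BH within each category
    by_cat: dict[str, list[int]] = {}
    for idx, r in enumerate(results):
        by_cat.setdefault(r.category, []).append(idx)
    for idxs in by_cat.values():
        adj = bh_adjust([results[i].p for i in idxs])
        for i, a in zip(idxs, adj):
            results[i].adj_p = float(a)
    results.sort(key=lambda r: (r.p, r.category, r.name))
    return results


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def roc_curve_auc(scores: Sequence[float], labels: Sequence[int],
                  positive_is_high: bool = True) -> ROCResult:
    """ROC curve over all distinct thresholds with trapezoidal AUC.

    ``labels`` are 0/1 with 1 the positive class.  No automatic direction
    flipping is performed; set ``positive_is_high=False`` when low scores
    indicate the positive class.  The curve runs from (0, 0) to (1, 1);
    the trapezoidal area equals the Mann-Whitney U statistic divided by
    n_pos * n_neg, crediting ties 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise InputError("scores and labels must be equal-length vectors")
    if not np.isin(y, (0, 1)).all():
        raise InputError("labels must be 0/1")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("ROC requires both classes to be present")
    if not positive_is_high:
        s = -s
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    # accumulate over blocks of tied scores so ties contribute diagonally
    distinct = np.nonzero(np.diff(s_sorted))[0]
    block_ends = np.r_[distinct, s_sorted.size - 1]
    tp = np.cumsum(y_sorted)[block_ends]
    fp = np.cumsum(1 - y_sorted)[block_ends]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = np.r_[np.inf, s_sorted[block_ends]]
    return ROCResult(thresholds, fpr, tpr, auc, n_pos, n_neg)


STAGE_GROUPS = {"T1": "early", "T2": "early", "T3": "advanced"}


def group_stages(stages: Sequence[str]) -> list[str]:
    """Collapse tumor stage labels: T1 and T2 -> early, T3 -> advanced."""
    out = []
    for label in stages:
        norm = str(label).strip().upper()
        if norm not in STAGE_GROUPS:
            raise InputError(f"unmapped stage label {label!r}")
        out.append(STAGE_GROUPS[norm])
    return out


@dataclass
class FoldChange:
    delta_ct_case: float
    delta_ct_control: float
    ddct: float
    fold: float


def ddct_fold_change(ct_target_case: float, ct_ref_case: float,
                     ct_target_control: float, ct_ref_control: float) -> FoldChange:
    """Relative quantification by the 2^-ddCt convention.

    dCt = Ct_target - Ct_reference per group; ddCt = dCt_case - dCt_control;
    fold = 2^-ddCt.
    """
    for v in (ct_target_case, ct_ref_case, ct_target_control, ct_ref_control):
        if not math.isfinite(v):
            raise InputError("Ct values must be finite")
    d_case = ct_target_case - ct_ref_case
    d_control = ct_target_control - ct_ref_control
    ddct = d_case - d_control
    return FoldChange(d_case, d_control, ddct, 2.0 ** (-ddct))


def ddct_fold_change_groups(ct_target_case: Sequence[float],
                            ct_ref_case: Sequence[float],
                            ct_target_control: Sequence[float],
                            ct_ref_control: Sequence[float]) -> FoldChange:
    """Group-level 2^-ddCt: average each group's dCt before differencing."""
    d_case = float(np.mean(np.asarray(ct_target_case, dtype=float)
                           - np.asarray(ct_ref_case, dtype=float)))
    d_control = float(np.mean(np.asarray(ct_target_control, dtype=float)
                              - np.asarray(ct_ref_control, dtype=float)))
    if not (math.isfinite(d_case) and math.isfinite(d_control)):
        raise InputError("Ct values must be finite")
    ddct = d_case - d_control
    return FoldChange(d_case, d_control, ddct, 2.0 ** (-ddct))


def two_group_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Unpaired two-sided t-test comparing two groups (utility)."""
    res = sps.ttest_ind(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    return float(res.statistic), float(res.pvalue)
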