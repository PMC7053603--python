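"""Per-dataset differential expression for paired or two-group designs.

The workhorse is an empirical-Bayes moderated t-test in the limma style:
per-feature residual variances are shrunk toward a pooled prior estimated
by fitting a scaled F-distribution to the observed variances, and the
resulting t-statistics gain the prior degrees of freedom.  Plain t-tests
are available by disabling moderation.  Adjustment for multiple testing
uses the Benjamini-Hochberg step-up procedure, and up/down calls are made
with strict p-value and |log2 fold change| thresholds.  Cross-dataset
consensus intersects the significant sets and flags features whose
direction of change disagrees between datasets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

MOLECULE_KINDS = ("mRNA", "lncRNA", "miRNA")
UP, DOWN, NS = "up", "down", "ns"


class InputError(ValueError):
    """Raised when an input table violates a contract."""


class ConfigError(ValueError):
    """Raised when a configuration value is invalid."""


@dataclass
class ExpressionDataset:
    """A log2-scale feature x sample expression matrix with sample metadata.

    Parameters
    ----------
    dataset_id : str
        Identifier of the (pseudo-)dataset.
    molecule_kind : {"mRNA", "lncRNA", "miRNA"}
    matrix : pandas.DataFrame
        Features in rows, samples in columns, log2 scale, all finite.
    sample_metadata : pandas.DataFrame
        Columns ``sample_id``, ``subject_id``, ``condition`` with condition
        in {"tumor", "normal"}; one row per matrix column, same order.
    design : {"paired", "group"}
        Paired designs require exactly one tumor and one normal sample per
        subject.
    """

    dataset_id: str
    molecule_kind: str
    matrix: pd.DataFrame
    sample_metadata: pd.DataFrame
    design: str = "paired"

    def __post_init__(self) -> None:
        if self.molecule_kind not in MOLECULE_KINDS:
            raise ConfigError(f"molecule_kind must be one of {MOLECULE_KINDS}, "
                              f"got {self.molecule_kind!r}")
        if self.design not in ("paired", "group"):
            raise ConfigError(f"design must be 'paired' or 'group', got {self.design!r}")
        meta = self.sample_metadata
        for col in ("sample_id", "subject_id", "condition"):
            if col not in meta.columns:
                raise InputError(f"sample_metadata lacks required column {col!r}")
        if meta["sample_id"].duplicated().any():
            dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise InputError(f"duplicated sample_id {dup!r}")
        if list(self.matrix.columns) != list(meta["sample_id"]):
            raise InputError("matrix columns do not match metadata sample_ids "
                             "(same ids, same order required)")
        if self.matrix.index.duplicated().any():
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise InputError(f"duplicated feature id {dup!r}")
        bad = set(meta["condition"]) - {"tumor", "normal"}
        if bad:
            raise InputError(f"unknown condition label(s) {sorted(bad)}")
        values = self.matrix.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise InputError(
                f"non-finite value at feature {self.matrix.index[r]!r}, "
                f"sample {self.matrix.columns[c]!r}")
        if self.design == "paired":
            counts = meta.groupby("subject_id")["condition"].value_counts().unstack(fill_value=0)
            ok = (counts.get("tumor", 0) == 1) & (counts.get("normal", 0) == 1)
            if not np.all(ok):
                subj = counts.index[~np.asarray(ok)][0]
                raise InputError(
                    f"paired design requires one tumor and one normal sample per "
                    f"subject; subject {subj!r} violates this")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.matrix.index)

    def condition_matrix(self, condition: str) -> pd.DataFrame:
        ids = self.sample_metadata.loc[
            self.sample_metadata["condition"] == condition, "sample_id"]
        return self.matrix[list(ids)]


@dataclass(frozen=True)
class DEThresholds:
    """Significance gates for up/down calls (strict inequalities)."""

    p_field: str = "adjusted"      # "raw" or "adjusted"
    p_max: float = 0.05
    abs_logfc_min: float = 1.0

    def __post_init__(self) -> None:
        if self.p_field not in ("raw", "adjusted"):
            raise ConfigError(f"p_field must be 'raw' or 'adjusted', got {self.p_field!r}")
        if not (0.0 < self.p_max <= 1.0):
            raise ConfigError(f"p_max must be in (0, 1], got {self.p_max}")
        if self.abs_logfc_min < 0:
            raise ConfigError(f"abs_logfc_min must be >= 0, got {self.abs_logfc_min}")


#: Per-dataset threshold presets used by the original five-accession study design.
THRESHOLD_PRESETS: dict[str, DEThresholds] = {
    "GSE61850": DEThresholds("adjusted", 0.05, 1.0),
    "GSE103909": DEThresholds("raw", 0.05, 0.585),
    "GSE57555_mrna": DEThresholds("adjusted", 0.05, 1.0),
    "GSE57555_mirna": DEThresholds("raw", 0.05, 0.263),
    "GSE53992": DEThresholds("raw", 0.05, 0.0),
    "GSE53870": DEThresholds("adjusted", 0.05, 0.585),
}


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes variance moderation settings.

    When ``enabled``, the prior degrees of freedom and prior variance are
    estimated from the data unless supplied explicitly.  When disabled the
    statistic reduces to the ordinary t-test.
    """

    enabled: bool = True
    prior_df: float | None = None
    prior_var: float | None = None

    def __post_init__(self) -> None:
        if self.prior_df is not None and not self.prior_df > 0:
            raise ConfigError(f"prior_df must be > 0, got {self.prior_df}")
        if self.prior_var is not None and not self.prior_var > 0:
            raise ConfigError(f"prior_var must be > 0, got {self.prior_var}")


@dataclass
class DERecord:
    """Differential-expression result for one feature."""

    feature_id: str
    molecule_kind: str
    logFC: float
    t_stat: float
    p: float
    adj_p: float
    direction: str = NS


@dataclass
class ConsensusRecord:
    """Cross-dataset consensus membership for one feature."""

    feature_id: str
    molecule_kind: str
    directions: dict[str, str]          # dataset_id -> up/down
    consistent: bool
    consensus_direction: str            # up / down / undetermined


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} ( p_(j) * n / j ) over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise InputError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise InputError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration on 1/trigamma."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate prior df and prior variance of a scaled-F variance model.

    Moment-matching on log variances: E[log s2] and Var[log s2] are
    expressed through digamma/trigamma functions of the residual and prior
    degrees of freedom.  Returns ``(prior_df, prior_var)``; prior_df may be
    ``inf`` when the observed spread of log-variances is no larger than
    expected under a single common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if s2.size == 0:
        raise InputError("no finite variances to fit")
    # guard against exact zeros before taking logs
    tiny = np.max(s2) * 1e-12 if np.max(s2) > 0 else 1e-300
    z = np.log(np.maximum(s2, tiny))
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    if e.size < 2:
        return math.inf, float(np.exp(emean))
    evar = float(np.sum((e - emean) ** 2) / (e.size - 1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        s2_prior = float(np.exp(emean + special.digamma(df_prior / 2.0)
                                - math.log(df_prior / 2.0)))
    else:
        df_prior = math.inf
        s2_prior = float(np.exp(emean))
    return df_prior, s2_prior


def squeeze_var(s2: np.ndarray, df: float,
                prior_df: float | None = None,
                prior_var: float | None = None) -> tuple[np.ndarray, float, float]:
    """Shrink per-feature variances toward the fitted (or given) prior.

    Returns ``(posterior_var, prior_df, prior_var)`` with
    ``posterior = (d0*s0 + d*s2) / (d0 + d)``.
    """
    s2 = np.asarray(s2, dtype=float)
    if prior_df is None or prior_var is None:
        fit_d0, fit_s0 = fit_f_dist(s2, df)
        prior_df = fit_d0 if prior_df is None else prior_df
        prior_var = fit_s0 if prior_var is None else prior_var
    if math.isinf(prior_df):
        post = np.full_like(s2, prior_var)
    else:
        post = (prior_df * prior_var + df * s2) / (prior_df + df)
    return post, float(prior_df), float(prior_var)


def _paired_stats(dataset: ExpressionDataset) -> tuple[np.ndarray, np.ndarray, float, float]:
    meta = dataset.sample_metadata
    tumor = meta[meta["condition"] == "tumor"].set_index("subject_id")["sample_id"]
    normal = meta[meta["condition"] == "normal"].set_index("subject_id")["sample_id"]
    subjects = sorted(tumor.index)
    n = len(subjects)
    if n < 2:
        raise InputError("paired design requires at least 2 subject pairs")
    diffs = (dataset.matrix[[tumor[s] for s in subjects]].to_numpy()
             - dataset.matrix[[normal[s] for s in subjects]].to_numpy())
    logfc = diffs.mean(axis=1)
    s2 = diffs.var(axis=1, ddof=1)
    return logfc, s2, float(n - 1), 1.0 / math.sqrt(n)


def _group_stats(dataset: ExpressionDataset) -> tuple[np.ndarray, np.ndarray, float, float]:
    tum = dataset.condition_matrix("tumor").to_numpy()
    nor = dataset.condition_matrix("normal").to_numpy()
    n1, n2 = tum.shape[1], nor.shape[1]
    if n1 < 2 or n2 < 2:
        raise InputError("group design requires at least 2 samples per condition")
    logfc = tum.mean(axis=1) - nor.mean(axis=1)
    s2 = ((tum.var(axis=1, ddof=1) * (n1 - 1) + nor.var(axis=1, ddof=1) * (n2 - 1))
          / (n1 + n2 - 2))
    return logfc, s2, float(n1 + n2 - 2), math.sqrt(1.0 / n1 + 1.0 / n2)


def fit_de(dataset: ExpressionDataset,
           moderation: ModerationParams = ModerationParams()) -> list[DERecord]:
    """Fit per-feature differential expression (tumor minus normal).

    Paired designs test the within-pair log2 differences; group designs use
    the pooled-variance two-sample statistic.  With moderation enabled the
    residual variances are squeezed toward the empirical-Bayes prior and the
    t-statistics gain the prior degrees of freedom (capped at the pooled
    residual df, matching the reference empirical-Bayes implementation).

    Returns records with ``p`` and ``adj_p`` filled and ``direction`` left
    as "ns"; apply :func:`apply_thresholds` to set directions.
    """
    if dataset.design == "paired":
        logfc, s2, df, stdev_unscaled = _paired_stats(dataset)
    else:
        logfc, s2, df, stdev_unscaled = _group_stats(dataset)

    n_feat = logfc.size
    if moderation.enabled:
        post_var, prior_df, _ = squeeze_var(s2, df, moderation.prior_df,
                                            moderation.prior_var)
        if math.isinf(prior_df):
            df_total = np.full(n_feat, math.inf)
        else:
            df_total = np.minimum(df + prior_df, df * n_feat)
        denom = stdev_unscaled * np.sqrt(post_var)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, logfc / denom, np.sign(logfc) * np.inf)
        t = np.where((denom == 0) & (logfc == 0), 0.0, t)
        finite_df = np.isfinite(df_total)
        p = np.empty(n_feat)
        p[finite_df] = 2.0 * stats.t.sf(np.abs(t[finite_df]), df_total[finite_df])
        p[~finite_df] = 2.0 * stats.norm.sf(np.abs(t[~finite_df]))
        p = np.where(np.isinf(t), 0.0, p)
        p = np.where((denom == 0) & (logfc == 0), 1.0, p)
    else:
        denom = stdev_unscaled * np.sqrt(s2)
        zero_var = denom == 0
        if zero_var.any():
            logger.warning(
                "%d feature(s) with zero residual variance and moderation "
                "disabled in dataset %s; reporting p=0 where |logFC|>0",
                int(zero_var.sum()), dataset.dataset_id)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(zero_var, np.sign(logfc) * np.inf, logfc / np.where(zero_var, 1.0, denom))
        t = np.where(zero_var & (logfc == 0), 0.0, t)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(zero_var, np.where(logfc == 0, 1.0, 0.0), p)

    adj = bh_adjust(np.clip(p, 0.0, 1.0))
    return [
        DERecord(fid, dataset.molecule_kind, float(lf), float(tt), float(pp), float(ap))
        for fid, lf, tt, pp, ap in zip(dataset.feature_ids, logfc, t, p, adj)
    ]


def apply_thresholds(records: Sequence[DERecord],
                     thresholds: DEThresholds) -> list[DERecord]:
    """Set up/down/ns directions with strict inequalities on p and |logFC|."""
    out = []
    for rec in records:
        value = rec.adj_p if thresholds.p_field == "adjusted" else rec.p
        if value < thresholds.p_max and rec.logFC > thresholds.abs_logfc_min:
            direction = UP
        elif value < thresholds.p_max and rec.logFC < -thresholds.abs_logfc_min:
            direction = DOWN
        else:
            direction = NS
        out.append(DERecord(rec.feature_id, rec.molecule_kind, rec.logFC,
                            rec.t_stat, rec.p, rec.adj_p, direction))
    return out


def consensus_sets(de_tables: Mapping[str, Sequence[DERecord]]) -> list[ConsensusRecord]:
    """Intersect significant features across datasets of the same kind.

    A feature enters the consensus only if it is significant (direction is
    not "ns") in every supplied dataset of its molecule kind.  Features with
    conflicting significant directions are flagged ``consistent=False`` and
    get ``consensus_direction="undetermined"``.
    """
    if not de_tables:
        raise InputError("consensus_sets requires at least one DE table")
    # dataset ids per kind, feature directions per kind
    kind_datasets: dict[str, set[str]] = {}
    kind_feature_dirs: dict[str, dict[str, dict[str, str]]] = {}
    for ds_id, records in de_tables.items():
        for rec in records:
            kind_datasets.setdefault(rec.molecule_kind, set()).add(ds_id)
            if rec.direction != NS:
                kind_feature_dirs.setdefault(rec.molecule_kind, {}) \
                    .setdefault(rec.feature_id, {})[ds_id] = rec.direction
    out: list[ConsensusRecord] = []
    for kind in sorted(kind_feature_dirs):
        needed = kind_datasets[kind]
        for fid in sorted(kind_feature_dirs[kind]):
            dirs = kind_feature_dirs[kind][fid]
            if set(dirs) != needed:
                continue  # not significant everywhere
            values = set(dirs.values())
            consistent = len(values) == 1
            out.append(ConsensusRecord(
                feature_id=fid,
                molecule_kind=kind,
                directions=dict(sorted(dirs.items())),
                consistent=consistent,
                consensus_direction=values.pop() if consistent else "undetermined",
            ))
    return out


def de_table(records: Sequence[DERecord]) -> pd.DataFrame:
    """Tabulate DE records (feature_id, kind, logFC, t, p, adj_p, direction)."""
    return pd.DataFrame(
        [(r.feature_id, r.molecule_kind, r.logFC, r.t_stat, r.p, r.adj_p, r.direction)
         for r in records],
        columns=["feature_id", "kind", "logFC", "t", "p", "adj_p", "direction"],
    )
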