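"""Differential expression: moderated/plain t, BH adjustment, consensus."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cernet.diffexpr import (ConsensusRecord, DERecord, DEThresholds,
                             ExpressionDataset, InputError, ModerationParams,
                             apply_thresholds, bh_adjust, consensus_sets,
                             fit_de)
from conftest import paired_dataset


def bh_bruteforce(pvals):
    """Literal step-up: adj_(i) = min_{j>=i} p_(j)*n/j, capped at 1."""
    p = list(pvals)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    for rank_pos, i in enumerate(order):
        candidates = [p[order[j]] * n / (j + 1) for j in range(rank_pos, n)]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestPlainT:
    def test_paired_diffs_1_2_3(self):
        # tumor - normal diffs are (1, 2, 3): logFC 2, t = 2/(1/sqrt(3))
        ds = paired_dataset([[1, 0, 2, 0, 3, 0]])
        (rec,) = fit_de(ds, ModerationParams(enabled=False))
        assert rec.logFC == pytest.approx(2.0)
        assert rec.t_stat == pytest.approx(3.4641, abs=1e-4)
        assert rec.p == pytest.approx(2 * sps.t.sf(2 / (1 / math.sqrt(3)), 2))

    def test_identical_tumor_normal_is_ns(self):
        ds = paired_dataset([[5, 5, 7, 7, 6, 6]])
        (rec,) = apply_thresholds(fit_de(ds, ModerationParams(enabled=False)),
                                  DEThresholds())
        assert rec.logFC == 0.0
        assert rec.direction == "ns"
        assert rec.p == 1.0

    def test_zero_variance_nonzero_logfc_reports_p0(self, caplog):
        # constant within-pair difference of 1 in every pair
        ds = paired_dataset([[2, 1, 3, 2, 4, 3]])
        with caplog.at_level("WARNING"):
            (rec,) = fit_de(ds, ModerationParams(enabled=False))
        assert rec.p == 0.0
        assert rec.logFC == pytest.approx(1.0)
        assert "zero residual variance" in caplog.text

    def test_plain_p_matches_t_cdf_on_random_matrices(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(8, 1, size=(30, 10))
        ds = paired_dataset(mat)
        recs = fit_de(ds, ModerationParams(enabled=False))
        diffs = mat[:, ::2] - mat[:, 1::2]
        t_ref = diffs.mean(1) / (diffs.std(1, ddof=1) / np.sqrt(5))
        p_ref = 2 * sps.t.sf(np.abs(t_ref), 4)
        assert np.allclose([r.t_stat for r in recs], t_ref, atol=1e-12)
        assert np.allclose([r.p for r in recs], p_ref, atol=1e-12)

    def test_group_design(self):
        vals = np.array([[3.0, 3.5, 4.0, 1.0, 1.5, 2.0]])
        meta = pd.DataFrame({"sample_id": list("abcdef"),
                             "subject_id": list("abcdef"),
                             "condition": ["tumor"] * 3 + ["normal"] * 3})
        matrix = pd.DataFrame(vals, columns=list("abcdef"), index=["g"])
        ds = ExpressionDataset("d", "mRNA", matrix, meta, "group")
        (rec,) = fit_de(ds, ModerationParams(enabled=False))
        t_ref, p_ref = sps.ttest_ind([3.0, 3.5, 4.0], [1.0, 1.5, 2.0])
        assert rec.logFC == pytest.approx(2.0)
        assert rec.t_stat == pytest.approx(t_ref)
        assert rec.p == pytest.approx(p_ref)


class TestModeratedT:
    def test_matches_limma_reference(self):
        """Frozen reference computed with limma (eBayes on a blocked paired
        fit) for this exact seeded fixture."""
        rng = np.random.default_rng(777)
        mat = rng.normal(8, 1, size=(40, 8))
        mat[:5, ::2] += 1.5
        recs = fit_de(paired_dataset(mat), ModerationParams())
        expected = {  # feature -> (logFC, t, p, adj_p)
            "f0": (1.8327448463, 3.4316669927, 9.79641038312e-3, 0.202961687285),
            "f1": (0.6457531398, 1.3059949276, 0.230036561936, 0.56883550417),
            "f2": (2.2786291473, 2.5610754279, 3.52839049724e-2, 0.330894365078),
            "f3": (0.3252820315, 0.7144049489, 0.496522822603, 0.783620194304),
            "f4": (1.6327821512, 3.4068730239, 1.01480843642e-2, 0.202961687285),
            "f5": (-0.9463635816, -1.2293287118, 0.255975976876, 0.56883550417),
        }
        by_id = {r.feature_id: r for r in recs}
        for fid, (lfc, t, p, ap) in expected.items():
            r = by_id[fid]
            assert r.logFC == pytest.approx(lfc, abs=1e-9)
            assert r.t_stat == pytest.approx(t, abs=1e-8)
            assert r.p == pytest.approx(p, rel=1e-8)
            assert r.adj_p == pytest.approx(ap, rel=1e-8)

    def test_infinite_prior_df_limit(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(0, 1, size=(10, 8))
        prior_var = 0.8
        recs = fit_de(paired_dataset(mat),
                      ModerationParams(prior_df=math.inf, prior_var=prior_var))
        logfc = (mat[:, ::2] - mat[:, 1::2]).mean(1)
        t_ref = logfc / math.sqrt(prior_var / 4)  # u = 1/sqrt(n_pairs)
        assert np.allclose([r.t_stat for r in recs], t_ref, atol=1e-12)
        # infinite df: p from the normal limit
        assert np.allclose([r.p for r in recs],
                           2 * sps.norm.sf(np.abs(t_ref)), atol=1e-12)

    def test_insufficient_samples_error(self):
        with pytest.raises(InputError):
            fit_de(paired_dataset([[1.0, 0.0]]))  # a single subject pair


class TestBHAdjust:
    @pytest.mark.parametrize("pvals,expected", [
        ([0.04], [0.04]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ([0.05, 0.01], [0.05, 0.02]),
    ])
    def test_examples(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(InputError):
            bh_adjust([-0.1])

    def test_matches_bruteforce_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 60)))
            adj = bh_adjust(p)
            assert np.allclose(adj, bh_bruteforce(p), atol=1e-12)
            assert np.allclose(adj, multipletests(p, method="fdr_bh")[1],
                               atol=1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(12)
        p = rng.random(200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestThresholds:
    def rec(self, logfc, p=0.5, adj_p=0.5):
        return DERecord("f", "mRNA", logfc, 0.0, p, adj_p)

    def test_adjusted_up(self):
        (r,) = apply_thresholds([self.rec(1.2, adj_p=0.01)],
                                DEThresholds("adjusted", 0.05, 1.0))
        assert r.direction == "up"

    def test_raw_field_with_low_logfc_gate(self):
        (r,) = apply_thresholds([self.rec(0.6, p=0.03, adj_p=0.2)],
                                DEThresholds("raw", 0.05, 0.585))
        assert r.direction == "up"

    def test_boundary_logfc_is_ns(self):
        (r,) = apply_thresholds([self.rec(1.0, adj_p=0.001)],
                                DEThresholds("adjusted", 0.05, 1.0))
        assert r.direction == "ns"

    def test_down_call(self):
        (r,) = apply_thresholds([self.rec(-2.0, adj_p=0.001)],
                                DEThresholds("adjusted", 0.05, 1.0))
        assert r.direction == "down"


class TestConsensus:
    def mk(self, fid, direction, kind="lncRNA"):
        return DERecord(fid, kind, 1.0 if direction == "up" else -1.0,
                        0.0, 0.01, 0.01, direction)

    def test_conflicting_direction_flagged(self):
        recs = consensus_sets({"A": [self.mk("l1", "up")],
                               "B": [self.mk("l1", "down")]})
        (r,) = recs
        assert r.consistent is False
        assert r.consensus_direction == "undetermined"

    def test_single_dataset_significance_not_in_consensus(self):
        recs = consensus_sets({"A": [self.mk("l1", "up")],
                               "B": [self.mk("l1", "ns")]})
        assert recs == []

    def test_intersection_semantics(self):
        t1 = [self.mk(f, "up", "mRNA") for f in "ABC"]
        t2 = [self.mk(f, "up", "mRNA") for f in "BCD"]
        recs = consensus_sets({"d1": t1, "d2": t2})
        assert sorted(r.feature_id for r in recs) == ["B", "C"]
        assert all(r.consensus_direction == "up" and r.consistent for r in recs)

    def test_empty_input_error(self):
        with pytest.raises(InputError):
            consensus_sets({})


class TestDatasetValidation:
    def test_paired_duplicate_condition_rejected(self):
        meta = pd.DataFrame({"sample_id": ["a", "b", "c", "d"],
                             "subject_id": ["s1", "s1", "s1", "s2"],
                             "condition": ["tumor", "tumor", "normal", "normal"]})
        matrix = pd.DataFrame(np.zeros((1, 4)), columns=list("abcd"), index=["f"])
        with pytest.raises(InputError, match="one tumor and one normal"):
            ExpressionDataset("d", "mRNA", matrix, meta, "paired")

    def test_nonfinite_rejected(self):
        ds = paired_dataset([[1, 2, 3, 4]])
        bad = ds.matrix.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(InputError, match="non-finite"):
            ExpressionDataset("d", "mRNA", bad, ds.sample_metadata, "paired")
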