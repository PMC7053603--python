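"""Synthetic-study generator: planted structure, streams, determinism."""

import numpy as np
import pandas as pd
import pytest

from cernet.diffexpr import ConfigError
from cernet.duplex import reverse_complement
from cernet.synthetic import (SimulationConfig, component_rng,
                              generate_evidence, generate_sequences,
                              generate_study, generate_validation_tables)
from cernet.stats import ddct_fold_change_groups, roc_curve_auc


def logfc_of(dataset, feature_id):
    meta = dataset.sample_metadata
    tum = meta.loc[meta.condition == "tumor", "sample_id"]
    nor = meta.loc[meta.condition == "normal", "sample_id"]
    row = dataset.matrix.loc[feature_id]
    return row[tum].mean() - row[nor].mean()


class TestConfigValidation:
    def test_negative_count_named(self):
        with pytest.raises(ConfigError, match="n_mrna"):
            SimulationConfig(n_mrna=-1)

    def test_too_many_triples(self):
        with pytest.raises(ConfigError, match="n_planted_triples"):
            SimulationConfig(n_mirna=3, n_planted_triples=5)

    def test_probability_bounds(self):
        with pytest.raises(ConfigError, match="evidence_sensitivity"):
            SimulationConfig(evidence_sensitivity=1.5)


class TestExpression:
    def test_noise_free_limit_logfc(self):
        config = SimulationConfig(n_mrna=6, n_lncrna=6, n_mirna=6,
                                  n_planted_triples=1, n_planted_de_singletons=1,
                                  n_pairs_per_dataset=(6,), noise_sd=1e-12,
                                  effect_logfc=2.0, seed=5)
        bundle = generate_study(config)
        by = bundle.datasets_by_id()
        t = bundle.truth.planted_triples[0]
        assert t.direction == "down"
        assert logfc_of(by[("SIM01", "mRNA")], t.mrna_id) == pytest.approx(-2.0, abs=1e-9)
        assert logfc_of(by[("SIM01", "lncRNA")], t.lncrna_id) == pytest.approx(-2.0, abs=1e-9)
        assert logfc_of(by[("SIM01", "miRNA")], t.mirna_id) == pytest.approx(2.0, abs=1e-9)

    def test_no_planted_triples_all_null(self):
        config = SimulationConfig(n_mrna=5, n_lncrna=5, n_mirna=5,
                                  n_planted_triples=0, n_planted_de_singletons=0,
                                  n_pairs_per_dataset=(5,), noise_sd=1e-12, seed=5)
        bundle = generate_study(config)
        assert bundle.truth.planted_triples == []
        assert bundle.truth.planted_de == {}
        for ds in bundle.datasets:
            for fid in ds.feature_ids:
                assert abs(logfc_of(ds, fid)) < 1e-9

    def test_same_directions_across_datasets(self, small_config):
        bundle = generate_study(small_config)
        by = bundle.datasets_by_id()
        for t in bundle.truth.planted_triples:
            signs = [np.sign(logfc_of(by[(ds, "mRNA")], t.mrna_id))
                     for ds in ("SIM01", "SIM02")]
            assert signs[0] == signs[1]

    def test_determinism(self, small_config):
        b1 = generate_study(small_config)
        b2 = generate_study(small_config)
        for d1, d2 in zip(b1.datasets, b2.datasets):
            pd.testing.assert_frame_equal(d1.matrix, d2.matrix)
        pd.testing.assert_frame_equal(b1.evidence.table, b2.evidence.table)
        assert b1.lncrna_sequences == b2.lncrna_sequences
        assert b1.truth == b2.truth

    def test_planted_correlation_structure(self):
        """Planted lncRNA-mRNA r > 0.7 and miRNA-mRNA r < 0 in >= 95% of seeds."""
        config = dict(n_mrna=4, n_lncrna=4, n_mirna=4, n_planted_triples=1,
                      n_planted_de_singletons=0, n_pairs_per_dataset=(10,),
                      coupling_strength=0.9)
        ok = 0
        n_seeds = 200
        for seed in range(n_seeds):
            bundle = generate_study(SimulationConfig(seed=seed, **config))
            by = bundle.datasets_by_id()
            t = bundle.truth.planted_triples[0]
            g = by[("SIM01", "mRNA")].matrix.loc[t.mrna_id]
            l = by[("SIM01", "lncRNA")].matrix.loc[t.lncrna_id]
            m = by[("SIM01", "miRNA")].matrix.loc[t.mirna_id]
            r_lg = np.corrcoef(l, g)[0, 1]
            r_mg = np.corrcoef(m, g)[0, 1]
            ok += (r_lg > 0.7) and (r_mg < 0)
        assert ok / n_seeds >= 0.95


class TestEvidence:
    def test_perfect_sensitivity_zero_fpr(self, small_config):
        bundle = generate_study(small_config)
        config = SimulationConfig(**{**small_config.__dict__,
                                     "evidence_sensitivity": 1.0,
                                     "evidence_fpr": 0.0})
        ev = generate_evidence(bundle.truth, config)
        true_pairs = {(t.mirna_id, t.mrna_id) for t in bundle.truth.planted_triples}
        support = ev.support
        for idx, row in ev.table.iterrows():
            expected = config.evidence_n_sources \
                if (row.mirna_id, row.mrna_id) in true_pairs else 0
            assert support[idx] == expected

    def test_twelve_flags_per_row(self, default_bundle):
        assert default_bundle.evidence.n_sources == 12
        flags = default_bundle.evidence.table.iloc[:, 2:]
        assert flags.shape[1] == 12
        assert flags.isin([0, 1]).all().all()

    def test_true_pair_flags_match_stream_replay(self, small_config):
        """Re-simulate the documented sampling order with the same stream."""
        config = SimulationConfig(**{**small_config.__dict__,
                                     "evidence_sensitivity": 0.5})
        bundle = generate_study(config)
        ev = generate_evidence(bundle.truth, config)
        rng = component_rng(config.seed, "evidence")
        n_true = len(bundle.truth.planted_triples)
        expected = (rng.random((n_true, 12)) < 0.5).astype(int)
        got = ev.table.iloc[:n_true, 2:].to_numpy()
        assert (got == expected).all()


class TestSequences:
    def test_strong_site_is_exact_reverse_complement(self, default_bundle):
        truth = default_bundle.truth
        for (mirna_id, lncrna_id), (start, end) in truth.planted_sites.items():
            target = default_bundle.lncrna_sequences[lncrna_id]
            mirna = default_bundle.mirna_sequences[mirna_id]
            assert target[start - 1:end] == reverse_complement(mirna)
            assert end - start + 1 == len(mirna)

    def test_weak_site_is_seed_complement_only(self, small_config):
        config = SimulationConfig(**{**small_config.__dict__, "site_mode": "weak"})
        bundle = generate_study(config)
        for (mirna_id, lncrna_id), (start, end) in bundle.truth.planted_sites.items():
            target = bundle.lncrna_sequences[lncrna_id]
            mirna = bundle.mirna_sequences[mirna_id]
            assert target[start - 1:end] == reverse_complement(mirna[1:8])
            assert end - start + 1 == 7

    def test_target_shorter_than_site_rejected(self, small_config):
        config = SimulationConfig(**{**small_config.__dict__, "lncrna_length": 10})
        bundle = generate_study(SimulationConfig(
            **{**small_config.__dict__, "lncrna_length": 30}))
        with pytest.raises(ConfigError, match="lncrna_length"):
            generate_sequences(bundle.truth, config)


class TestValidationTables:
    def test_planted_ddct_recovered_noise_free(self):
        config = SimulationConfig(planted_ddct=0.0, ct_noise_sd=1e-12, seed=3)
        ct, _, _ = generate_validation_tables(config)
        case = ct[ct.group == "case"]
        control = ct[ct.group == "control"]
        fc = ddct_fold_change_groups(case.ct_target, case.ct_reference,
                                     control.ct_target, control.ct_reference)
        assert fc.fold == pytest.approx(1.0, abs=1e-9)

    def test_planted_ddct_two_gives_quarter_fold(self):
        config = SimulationConfig(planted_ddct=2.0, ct_noise_sd=1e-12, seed=3)
        ct, _, _ = generate_validation_tables(config)
        case = ct[ct.group == "case"]
        control = ct[ct.group == "control"]
        fc = ddct_fold_change_groups(case.ct_target, case.ct_reference,
                                     control.ct_target, control.ct_reference)
        assert fc.fold == pytest.approx(0.25, abs=1e-9)

    def test_infinite_separation_gives_auc_one(self):
        config = SimulationConfig(roc_separation=float("inf"), seed=3)
        _, _, scores = generate_validation_tables(config)
        assert roc_curve_auc(scores.score, scores.label).auc == 1.0

    def test_stage_labels_and_determinism(self):
        config = SimulationConfig(seed=9)
        ct1, st1, sc1 = generate_validation_tables(config)
        ct2, st2, sc2 = generate_validation_tables(config)
        assert set(st1.stage) <= {"T1", "T2", "T3"}
        pd.testing.assert_frame_equal(ct1, ct2)
        pd.testing.assert_frame_equal(st1, st2)
        pd.testing.assert_frame_equal(sc1, sc2)
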