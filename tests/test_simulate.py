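"""The synthetic-data generator: determinism, planted truth, and calibration."""

import numpy as np
import pandas as pd
import pytest

from crosstalk.datatypes import ExpressionDataset
from crosstalk.exceptions import ConfigError
from crosstalk.meta import hedges_g
from crosstalk.simulate import (GeneratorConfig, SyntheticTruth,
                                generate_meta_cohorts,
                                generate_paired_compartments, generate_study,
                                read_truth, write_truth)


def small_config(**kw):
    base = dict(n_genes=120, n_datasets=2, n_case=10, n_control=10,
                n_planted_degs=10, n_paired_cohorts=2, n_patients=20,
                n_planted_pairs=5, seed=11)
    base.update(kw)
    return GeneratorConfig(**base)


class TestMetaCohorts:
    def test_shapes_groups_and_truth(self):
        cfg = small_config()
        datasets, truth = generate_meta_cohorts(cfg, "tubule")
        assert len(datasets) == 2
        for ds in datasets:
            assert ds.values.shape == (120, 20)
            assert ds.n_case == 10 and ds.n_control == 10
            assert ds.meta_ready
        assert len(truth.degs) == 10
        assert set(truth.degs["true_g"].abs()) == {cfg.effect_size_true}
        assert (truth.degs["true_g"] < 0).sum() == 5  # half down-regulated

    def test_null_config_has_empty_truth(self):
        datasets, truth = generate_meta_cohorts(small_config(n_planted_degs=0))
        assert truth.degs.empty
        assert len(datasets) == 2

    def test_deterministic_under_seed(self):
        a, _ = generate_meta_cohorts(small_config())
        b, _ = generate_meta_cohorts(small_config())
        for da, db in zip(a, b):
            pd.testing.assert_frame_equal(da.values, db.values)

    def test_planted_effect_recovered_on_hedges_scale(self):
        """Average Hedges' g over planted genes approaches effect_size_true
        at n=100/100 (within ~2 SE of the mean over planted genes)."""
        cfg = GeneratorConfig(n_genes=400, n_datasets=1, n_case=100,
                              n_control=100, n_planted_degs=50, seed=5)
        (ds,), truth = generate_meta_cohorts(cfg)
        signed = []
        for _, row in truth.degs.iterrows():
            g, _ = hedges_g(ds.case_matrix().loc[row.gene],
                            ds.control_matrix().loc[row.gene])
            signed.append(g * np.sign(row.true_g))
        assert np.mean(signed) == pytest.approx(1.0, abs=0.06)

    def test_zero_effect_plants_are_indistinguishable(self):
        cfg = small_config(effect_size_true=0.0, n_case=30, n_control=30)
        (ds, _), truth = generate_meta_cohorts(cfg)
        gs = [hedges_g(ds.case_matrix().loc[g], ds.control_matrix().loc[g])[0]
              for g in truth.degs["gene"]]
        assert abs(np.mean(gs)) < 0.2


class TestPairedCompartments:
    def test_patient_ids_shared_and_single_group(self):
        cohorts, truth = generate_paired_compartments(small_config())
        assert len(cohorts) == 2
        for tub, glom in cohorts:
            assert isinstance(tub, ExpressionDataset)
            assert set(tub.patient_id) == set(glom.patient_id)
            assert not tub.meta_ready  # correlation-only cohorts
        assert len(truth.pairs) == 5

    def test_planted_correlation_near_target(self):
        """Sample correlation of a planted pair at rho=0.9, n=200 falls in
        the Fisher-z 95% band [0.85, 0.94]."""
        cfg = GeneratorConfig(n_genes=60, n_paired_cohorts=1, n_patients=200,
                              n_planted_pairs=8, rho_true=0.9, seed=21)
        cohorts, truth = generate_paired_compartments(cfg)
        tub, glom = cohorts[0]
        for _, row in truth.pairs.iterrows():
            r = np.corrcoef(tub.values.loc[row.tubule_gene],
                            glom.values.loc[row.glom_gene])[0, 1]
            assert 0.85 <= r <= 0.94

    def test_negative_rho_gives_negative_sample_correlation(self):
        cfg = GeneratorConfig(n_genes=40, n_planted_degs=10, n_paired_cohorts=1,
                              n_patients=100, n_planted_pairs=4, rho_true=-0.85,
                              seed=3)
        cohorts, truth = generate_paired_compartments(cfg)
        tub, glom = cohorts[0]
        assert (truth.pairs["sign"] == "neg").all()
        for _, row in truth.pairs.iterrows():
            r = np.corrcoef(tub.values.loc[row.tubule_gene],
                            glom.values.loc[row.glom_gene])[0, 1]
            assert r < -0.6

    def test_non_planted_pairs_stay_null(self):
        cfg = GeneratorConfig(n_genes=80, n_paired_cohorts=1, n_patients=40,
                              n_planted_pairs=0, seed=9)
        cohorts, _ = generate_paired_compartments(cfg)
        tub, glom = cohorts[0]
        r = np.corrcoef(tub.values.to_numpy(), glom.values.to_numpy())[:80, 80:]
        assert np.abs(r).max() < 0.7


class TestStudyAndTruthIO:
    def test_study_pairs_drawn_from_planted_degs(self):
        collection, truth = generate_study(small_config())
        collection.validate()
        tub_degs = truth.deg_genes("tubule")
        glom_degs = truth.deg_genes("glomerulus")
        for _, row in truth.pairs.iterrows():
            assert row.tubule_gene in tub_degs
            assert row.glom_gene in glom_degs
        assert len(collection.paired_cohorts) == 2

    def test_truth_round_trip(self, tmp_path):
        _, truth = generate_study(small_config())
        write_truth(truth, tmp_path)
        back = read_truth(tmp_path)
        pd.testing.assert_frame_equal(truth.degs, back.degs, check_dtype=False)
        pd.testing.assert_frame_equal(truth.pairs, back.pairs,
                                      check_dtype=False)

    def test_empty_truth_round_trips_header_only(self, tmp_path):
        write_truth(SyntheticTruth(), tmp_path)
        back = read_truth(tmp_path)
        assert back.degs.empty and back.pairs.empty
        assert list(back.pairs.columns) == ["tubule_gene", "glom_gene",
                                            "rho_true", "sign"]

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_genes=10, n_planted_degs=20).validate()
        with pytest.raises(ConfigError):
            GeneratorConfig(rho_true=1.0).validate()
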