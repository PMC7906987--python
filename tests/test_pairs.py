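"""Paired-cohort screening, consensus intersection, and the pair network."""

import numpy as np
import pytest

from conftest import make_dataset
from crosstalk.datatypes import AnalysisConfig
from crosstalk.exceptions import DataValidationError
from crosstalk.pairs import (CorrelatedPair, CorrelationTriple, build_network,
                             find_pairs_one_cohort, intersect_pairs, pairs_table)


def paired_cohort(rng, n_genes=10, n_patients=20, planted=None, cohort="c1"):
    """Two compartment datasets over the same patients; ``planted`` maps
    (tub_idx, glom_idx) -> rho used in the shared-latent construction."""
    patients = [f"{cohort}_p{i}" for i in range(n_patients)]
    xt = rng.normal(size=(n_genes, n_patients))
    xg = rng.normal(size=(n_genes, n_patients))
    for (i, j), rho in (planted or {}).items():
        z = rng.normal(size=n_patients)
        a, b = np.sqrt(abs(rho)), np.sqrt(1 - abs(rho))
        xt[i] = a * z + b * rng.normal(size=n_patients)
        xg[j] = np.sign(rho) * a * z + b * rng.normal(size=n_patients)
    tub = make_dataset(xt, dataset_id=f"{cohort}_tub", compartment="tubule",
                       n_case=n_patients, patients=patients)
    glom = make_dataset(xg, dataset_id=f"{cohort}_glm", compartment="glomerulus",
                        n_case=n_patients, patients=patients)
    return tub, glom


def triple(r, n=20, p=1e-6):
    return CorrelationTriple(r, p, r, p, r, p, n)


class TestFindPairsOneCohort:
    def test_identical_vectors_retained_with_unit_coefficients(self, rng):
        tub, glom = paired_cohort(rng, n_genes=4, n_patients=10)
        glom.values.iloc[2] = tub.values.iloc[1].to_numpy()
        found = find_pairs_one_cohort(tub, glom, tub.genes, glom.genes,
                                      AnalysisConfig())
        t = found[("g1", "g2")]
        assert t.r_pearson == pytest.approx(1.0)
        assert t.rho_spearman == pytest.approx(1.0)
        assert t.tau_kendall == pytest.approx(1.0)

    def test_strong_planted_pair_recovered(self, rng):
        hits = 0
        for rep in range(10):
            tub, glom = paired_cohort(rng, n_genes=8, n_patients=40,
                                      planted={(0, 5): 0.95})
            found = find_pairs_one_cohort(tub, glom, tub.genes, glom.genes,
                                          AnalysisConfig())
            hits += ("g0", "g5") in found
        assert hits >= 9

    def test_independent_genes_not_retained(self, rng):
        tub, glom = paired_cohort(rng, n_genes=30, n_patients=40)
        found = find_pairs_one_cohort(tub, glom, tub.genes, glom.genes,
                                      AnalysisConfig())
        assert found == {}

    def test_negative_pair_carries_negative_sign(self, rng):
        tub, glom = paired_cohort(rng, n_genes=6, n_patients=40,
                                  planted={(1, 2): -0.95})
        found = find_pairs_one_cohort(tub, glom, tub.genes, glom.genes,
                                      AnalysisConfig())
        assert found[("g1", "g2")].sign() == -1

    def test_missing_deg_genes_skipped(self, rng):
        tub, glom = paired_cohort(rng, n_genes=4, n_patients=12)
        found = find_pairs_one_cohort(tub, glom, ["g0", "absent"], tub.genes,
                                      AnalysisConfig())
        assert all(k[0] != "absent" for k in found)

    def test_no_shared_patients_is_an_error(self, rng):
        tub, _ = paired_cohort(rng, cohort="a")
        _, glom = paired_cohort(rng, cohort="b")
        with pytest.raises(DataValidationError, match="patients"):
            find_pairs_one_cohort(tub, glom, tub.genes, glom.genes,
                                  AnalysisConfig())


class TestIntersectPairs:
    def test_only_universal_pairs_survive(self):
        per = {
            "c1": {("A", "B"): triple(0.9), ("C", "D"): triple(0.8)},
            "c2": {("A", "B"): triple(0.85)},
            "c3": {("A", "B"): triple(0.8), ("E", "F"): triple(0.9)},
            "c4": {("A", "B"): triple(0.95)},
        }
        pairs = intersect_pairs(per)
        assert [p.key for p in pairs] == [("A", "B")]
        assert pairs[0].consensus_sign == "pos"
        assert set(pairs[0].per_cohort) == {"c1", "c2", "c3", "c4"}

    def test_sign_conflict_rejected_by_default(self):
        per = {"c1": {("A", "B"): triple(0.9)},
               "c2": {("A", "B"): triple(-0.9)}}
        assert intersect_pairs(per) == []
        kept = intersect_pairs(per, require_sign_consistency=False)
        assert len(kept) == 1

    def test_single_cohort_is_identity(self):
        per = {"c1": {("A", "B"): triple(0.9), ("C", "D"): triple(-0.8)}}
        pairs = intersect_pairs(per)
        assert {p.key for p in pairs} == {("A", "B"), ("C", "D")}

    def test_output_subset_of_every_input_and_idempotent(self, rng):
        sets = {}
        for c in range(3):
            keys = {(f"t{i}", f"g{i}") for i in rng.integers(0, 12, size=8)}
            sets[f"c{c}"] = {k: triple(0.8) for k in keys}
        pairs = intersect_pairs(sets)
        found = {p.key for p in pairs}
        for pairset in sets.values():
            assert found <= set(pairset)
        again = intersect_pairs({c: {p.key: t for p in pairs
                                     for cc, t in p.per_cohort.items() if cc == c}
                                 for c in sets} if pairs else sets)
        if pairs:
            assert {p.key for p in again} == found


class TestNetwork:
    def test_hub_degree_counts_partners(self):
        partners = ["C1QB", "CASP1", "CD53", "HCLS1", "ITGB2", "LAPTM5",
                    "LY86", "SRGN", "TYROBP"]
        pairs = [CorrelatedPair(t, "IRF8", {"c1": triple(0.8)}, "pos")
                 for t in partners]
        net = build_network(pairs)
        assert net.degree("IRF8") == 9
        assert net.nodes["IRF8"]["side"] == "glomerulus"

    def test_single_pair_network(self):
        net = build_network([CorrelatedPair("WFDC2", "PEX19",
                                            {"c1": triple(-0.8)}, "neg")])
        assert net.number_of_nodes() == 2 and net.number_of_edges() == 1
        assert net.edges["WFDC2", "PEX19"]["sign"] == "neg"

    def test_gene_on_both_sides_labelled_both(self):
        pairs = [CorrelatedPair("A", "B", {"c": triple(0.8)}, "pos"),
                 CorrelatedPair("B", "C", {"c": triple(0.8)}, "pos")]
        net = build_network(pairs)
        assert net.nodes["B"]["side"] == "both"

    def test_empty_input_is_an_error(self):
        with pytest.raises(DataValidationError):
            build_network([])

    def test_pairs_table_one_row_per_pair(self):
        pairs = [CorrelatedPair("A", "B", {"c1": triple(0.8), "c2": triple(0.7)},
                                "pos")]
        t = pairs_table(pairs)
        assert len(t) == 1
        assert t.at[0, "c1.r_pearson"] == pytest.approx(0.8)
        assert t.at[0, "median_r"] == pytest.approx(0.75)
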