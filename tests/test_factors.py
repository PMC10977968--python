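"""Factor derivation rules, highlighting screens, and factor clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from genegap.factors import (apply_screen_fdr, associated_factors,
                             cluster_factors, compute_gravy,
                             derive_factor_table, screen_binary_factor,
                             screen_continuous_factor, screen_factors)
from genegap.hits import FocusStudy


class TestGravy:
    def test_kyte_doolittle_examples(self):
        assert compute_gravy("AAA") == pytest.approx(1.8)
        assert compute_gravy("AW") == pytest.approx(0.45)

    def test_sec_and_pyl_ignored(self):
        assert compute_gravy("AUA") == pytest.approx(1.8)
        assert np.isnan(compute_gravy("UO"))

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            compute_gravy("AXZ")

    def test_matches_biopython_on_standard_sequences(self):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis
        rng = np.random.default_rng(0)
        aas = list("ARNDCQEGHILKMFPSTWYV")
        for _ in range(5):
            seq = "".join(rng.choice(aas, size=60))
            assert compute_gravy(seq) == pytest.approx(
                ProteinAnalysis(seq).gravy(), rel=1e-9)


class TestDerivation:
    def test_gene_length_is_chromosomal_span(self, toy_registry):
        transcripts = pd.DataFrame({
            "entrez_id": [1, 1], "chromosome": ["1", "1"],
            "start": [100, 300], "end": [500, 900]})
        table = derive_factor_table({"transcripts": transcripts}, toy_registry)
        assert table.loc[1, "gene_length"] == 800

    def test_primate_specific_rule(self, toy_registry):
        homologene = pd.DataFrame({
            "group_id": ["H1", "H1", "H2", "H2", "H3"],
            "tax_id": [9606, 9598, 9606, 10090, 9606],
            "entrez_id": [1, 901, 2, 902, 3]})
        table = derive_factor_table(
            {"homologene": homologene, "primate_taxids": {9598}}, toy_registry)
        assert table.loc[1, "primate_specific"] == 1.0  # chimp only
        assert table.loc[2, "primate_specific"] == 0.0  # mouse homolog
        assert np.isnan(table.loc[4, "primate_specific"])  # no homology info
        assert table.loc[2, "homolog_in_mouse"] == 1.0
        assert table.loc[1, "homolog_in_mouse"] == 0.0

    def test_model_organism_zero_resolution_rule(self, toy_registry):
        homologene = pd.DataFrame({
            "group_id": ["H1", "H1", "H2", "H2"],
            "tax_id": [9606, 10090, 9606, 10090],
            "entrez_id": [1, 901, 2, 902]})
        org = pd.DataFrame({"tax_id": [10090], "entrez_id": [901],
                            "pmid": [5000]})
        table = derive_factor_table(
            {"homologene": homologene, "org_mentions": org,
             "primate_taxids": set()}, toy_registry)
        assert table.loc[1, "mouse_publications"] == 1.0
        assert table.loc[2, "mouse_publications"] == 0.0  # homolog, no pubs
        assert np.isnan(table.loc[3, "mouse_publications"])  # no homolog

    def test_membership_and_hpa_factors(self, toy_registry):
        sources = {
            "addgene": pd.DataFrame({"GeneID": [1, 3]}),
            "hpa": pd.DataFrame({
                "GeneID": [1, 2], "Antibody": ["HPA1", ""],
                "Protein class": ["Predicted membrane protein", "Enzymes"],
                "Evidence": ["Evidence at protein level",
                             "Evidence at transcript level"]}),
            "pli": pd.DataFrame({"GeneID": [1, 2], "pLI": [0.99, 0.2]}),
        }
        table = derive_factor_table(sources, toy_registry)
        assert table.loc[1, "has_plasmid"] == 1.0
        assert table.loc[2, "has_plasmid"] == 0.0
        assert table.loc[1, "has_antibody"] == 1.0
        assert table.loc[2, "has_antibody"] == 0.0
        assert table.loc[1, "membrane_protein"] == 1.0
        assert table.loc[1, "pli_intolerant"] == 1.0
        assert table.loc[2, "pli_intolerant"] == 0.0

    def test_missing_source_emits_all_na_with_warning(self, toy_registry, caplog):
        with caplog.at_level("WARNING"):
            table = derive_factor_table({}, toy_registry)
        assert table["gravy"].isna().all()
        assert "kinds" in table.attrs

    def test_expression_summaries(self, toy_registry):
        tissue = pd.DataFrame({
            "GeneID": [1, 1, 1, 1], "Tissue": list("abcd"),
            "nTPM": [0.0, 0.5, 2.0, 10.0]})
        table = derive_factor_table({"hpa_tissue": tissue}, toy_registry)
        assert table.loc[1, "median_ntpm"] == pytest.approx(1.25)
        assert table.loc[1, "frac_tissues_detected"] == pytest.approx(0.5)


class TestScreens:
    def test_binary_screen_matches_contingency_oracle(self):
        # highlighted: 25 genes (20 factor-true), rest: 25 (10 true)
        hl = set(range(25))
        hits = set(range(50))
        values = pd.Series({g: float(g < 20 or 25 <= g < 35) for g in hits})
        res = screen_binary_factor("CRISPR", "f", hits, hl, values)
        # table (20,10,5,15): OR = (20*15)/(10*5) = 6
        assert res.effect == pytest.approx(6.0)
        assert res.n_highlighted == 25 and res.n_not_highlighted == 25

    def test_complemented_factor_gives_reciprocal_or(self):
        rng = np.random.default_rng(1)
        hits = set(range(60))
        hl = set(range(20))
        values = pd.Series({g: float(rng.random() < 0.4 + 0.3 * (g in hl))
                            for g in hits})
        a = screen_binary_factor("GWAS", "f", hits, hl, values)
        b = screen_binary_factor("GWAS", "f", hits, hl, 1.0 - values)
        assert b.effect == pytest.approx(1.0 / a.effect)

    def test_continuous_screen_pair_enumeration(self):
        hits = {1, 2, 3, 4}
        hl = {1, 2}
        values = pd.Series({1: 2.0, 2: 4.0, 3: 1.0, 4: 3.0})
        res = screen_continuous_factor("APMS", "f", hits, hl, values)
        assert res.effect == pytest.approx(0.75)

    def test_identical_factor_gives_half_with_tie_flag(self):
        hits = {1, 2, 3, 4}
        values = pd.Series({g: 1.0 for g in hits})
        res = screen_continuous_factor("APMS", "f", hits, {1, 2}, values)
        assert res.effect == 0.5 and "all_tied" in res.flags

    def test_na_genes_dropped_per_test(self):
        hits = {1, 2, 3, 4}
        values = pd.Series({1: 1.0, 2: np.nan, 3: 0.0, 4: 0.0})
        res = screen_binary_factor("GWAS", "f", hits, {1, 2}, values)
        assert res.n_highlighted == 1

    def test_screen_invariant_to_gene_ordering(self, small_corpus):
        reg = small_corpus.registry()
        m = small_corpus.mentions(reg)
        studies = small_corpus.studies(reg, m)
        table = small_corpus.factor_table()
        a = screen_factors(studies, m, table)
        b = screen_factors(list(reversed(studies)),
                           m.sample(frac=1, random_state=0), table)
        pd.testing.assert_frame_equal(a, b)


class TestFdr:
    def test_all_p_one_yields_nothing(self):
        df = pd.DataFrame({
            "kind": ["binary"] * 3, "assay": ["CRISPR", "GWAS", "APMS"],
            "factor": ["f"] * 3, "p": [1.0, 1.0, 1.0]})
        out = apply_screen_fdr(df)
        assert (out["q"] == 1.0).all()
        assert (out["stars"] == "").all()
        assert associated_factors(out, 0.05) == []

    def test_pooling_scope_per_panel_vs_per_assay(self):
        df = pd.DataFrame({
            "kind": ["binary"] * 4,
            "assay": ["A", "A", "B", "B"],
            "factor": ["f1", "f2", "f1", "f2"],
            "p": [0.01, 0.8, 0.9, 0.95]})
        panel = apply_screen_fdr(df, scope="panel")
        per_assay = apply_screen_fdr(df, scope="per_assay")
        assert panel.loc[0, "q"] == pytest.approx(0.04)
        assert per_assay.loc[0, "q"] == pytest.approx(0.02)

    def test_star_annotation_thresholds(self):
        df = pd.DataFrame({
            "kind": ["continuous"] * 3, "assay": ["A"] * 3,
            "factor": ["a", "b", "c"],
            "p": [1e-6, 1e-6, 1e-6]})
        out = apply_screen_fdr(df)
        assert (out["stars"] == "***").all()


class TestClustering:
    def test_duplicated_factor_merges_first_at_zero_distance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=100)
        table = pd.DataFrame({"a": base, "b": base.copy(),
                              "c": rng.normal(size=100)})
        z, order, _ = cluster_factors(table)
        first = sorted([order[int(z[0, 0])], order[int(z[0, 1])]])
        assert first == ["a", "b"]
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_correlated_blocks_recovered_at_k2(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=200)
        v = rng.normal(size=200)
        table = pd.DataFrame({
            "u1": u + 0.1 * rng.normal(size=200),
            "u2": -u + 0.1 * rng.normal(size=200),  # |rho| metric joins it
            "v1": v + 0.1 * rng.normal(size=200),
            "v2": v + 0.1 * rng.normal(size=200),
        })
        z, order, labels = cluster_factors(table, n_clusters=2)
        lab = dict(zip(order, labels))
        assert lab["u1"] == lab["u2"] != lab["v1"] == lab["v2"]

    def test_degenerate_factor_excluded(self):
        table = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [4.0, 3, 2, 1],
                              "const": [1.0, 1, 1, 1]})
        z, order, _ = cluster_factors(table)
        assert "const" not in order and len(order) == 2

    def test_fewer_than_two_factors_rejected(self):
        with pytest.raises(ValueError):
            cluster_factors(pd.DataFrame({"a": [1.0, 2, 3]}))
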