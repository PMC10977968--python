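"""FMUG-style gene-list filtering: predicates, context filters, export."""

import numpy as np
import pandas as pd
import pytest

from genegap.attention import count_articles_per_gene
from genegap.fmug import (ContextFilter, FilterSpec, Predicate, apply_filters,
                          context_attention, export_result, parse_predicate,
                          resolve_identifiers)


@pytest.fixture()
def factor_table(toy_registry):
    return pd.DataFrame({
        "n_articles": [2.0, 2.0, 1.0, 0.0, 0.0],
        "has_plasmid": [1.0, 0.0, 1.0, np.nan, 0.0],
        "gravy": [-0.5, 0.3, np.nan, 0.1, -1.0],
    }, index=pd.Index([1, 2, 3, 4, 6], name="entrez_id"))


@pytest.fixture()
def profile(toy_mentions, toy_articles, toy_registry):
    return count_articles_per_gene(toy_mentions, toy_articles, toy_registry)


class TestResolve:
    def test_resolution_order_and_unmatched(self, toy_registry):
        resolved, unmatched = resolve_identifiers(
            ["1", "B2", "c3", "NOPE"], toy_registry)
        assert resolved == [1, 2, 3]
        assert unmatched == ["NOPE"]

    def test_ambiguous_caseinsensitive_symbol_rejected(self, toy_registry_df):
        df = toy_registry_df.copy()
        df.loc[df["GeneID"] == 2, "Symbol"] = "a1"  # clashes with A1 casefolded
        from genegap.corpus import load_gene_registry
        reg = load_gene_registry(df)
        resolved, unmatched = resolve_identifiers(["A1", "a1"], reg)
        assert resolved == [1, 2]  # exact matches still unambiguous
        _, unmatched2 = resolve_identifiers(["A1x".lower()], reg)
        assert unmatched2  # unknown stays unmatched


class TestApplyFilters:
    def test_empty_spec_is_identity_on_registry(self, factor_table, profile,
                                                toy_registry):
        res = apply_filters(["A1", "B2", "NOPE"], factor_table, profile,
                            FilterSpec(), toy_registry)
        assert res.passing_genes == (1, 2)
        assert res.unmatched_identifiers == ("NOPE",)

    def test_hand_enumerable_conjunction(self, factor_table, profile,
                                         toy_registry):
        spec = FilterSpec(predicates=(
            Predicate("n_articles", "le", 2.0),
            Predicate("has_plasmid", "is_true"),
        ))
        res = apply_filters(["1", "2", "3", "4", "6"], factor_table, profile,
                            spec, toy_registry)
        # plasmid true and <=2 articles: genes 1 and 3; gene 4 is NA -> out
        assert res.passing_genes == (1, 3)

    def test_na_passes_when_allowed(self, factor_table, profile, toy_registry):
        spec = FilterSpec(predicates=(
            Predicate("has_plasmid", "is_true", na_passes=True),))
        res = apply_filters(["1", "3", "4"], factor_table, profile, spec,
                            toy_registry)
        assert res.passing_genes == (1, 3, 4)

    def test_unknown_factor_rejected_before_filtering(self, factor_table,
                                                      profile, toy_registry):
        spec = FilterSpec(predicates=(Predicate("nope", "is_true"),))
        with pytest.raises(ValueError, match="nope"):
            apply_filters(["1"], factor_table, profile, spec, toy_registry)

    def test_empty_input_warns(self, factor_table, profile, toy_registry,
                               caplog):
        with caplog.at_level("WARNING"):
            res = apply_filters([], factor_table, profile, FilterSpec(),
                                toy_registry)
        assert res.passing_genes == ()

    def test_adding_predicates_never_enlarges(self, factor_table, profile,
                                              toy_registry):
        genes = ["1", "2", "3", "4", "6"]
        preds = [Predicate("n_articles", "le", 2.0),
                 Predicate("has_plasmid", "is_true"),
                 Predicate("gravy", "ge", -0.6)]
        prev = None
        for k in range(len(preds) + 1):
            res = apply_filters(genes, factor_table, profile,
                                FilterSpec(predicates=tuple(preds[:k])),
                                toy_registry)
            if prev is not None:
                assert set(res.passing_genes) <= prev
            prev = set(res.passing_genes)

    def test_article_feedback_is_consistent(self, factor_table, profile,
                                            toy_registry):
        spec = FilterSpec(predicates=(Predicate("n_articles", "le", 1.0),))
        res = apply_filters(["1", "2", "3"], factor_table, profile, spec,
                            toy_registry)
        assert res.n_articles_passing <= res.n_articles_input
        assert res.n_articles_input == sum(profile.count(g)
                                           for g in res.input_genes)


class TestContext:
    def test_context_count_by_hand(self, toy_mentions, toy_articles):
        # D1 tags primary articles 101, 102; gene 1 mentioned in both
        assert context_attention(1, "D1", toy_mentions, toy_articles) == 2
        assert context_attention(2, "D1", toy_mentions, toy_articles) == 1
        # gene 2's D2 articles: 105 only (104 is a review)
        assert context_attention(2, "D2", toy_mentions, toy_articles) == 1

    def test_unknown_mesh_id_is_zero_with_warning(self, toy_mentions,
                                                  toy_articles, caplog):
        with caplog.at_level("WARNING"):
            assert context_attention(1, "D9", toy_mentions, toy_articles) == 0

    def test_context_filter_keeps_unstudied_in_context(
            self, factor_table, profile, toy_registry, toy_mentions,
            toy_articles):
        spec = FilterSpec(context_filters=(
            ContextFilter("D1", max_articles_in_context=0,
                          min_articles_overall=1),))
        res = apply_filters(["1", "2", "3"], factor_table, profile, spec,
                            toy_registry, mentions=toy_mentions,
                            articles=toy_articles)
        # gene 3 is studied (1 article) but untouched by the D1 literature;
        # genes 1 and 2 both appear in D1-tagged articles -> fail
        assert res.passing_genes == (3,)


class TestExport:
    def test_round_trip_and_line_count(self, tmp_path, factor_table, profile,
                                       toy_registry):
        res = apply_filters(["1", "2", "3"], factor_table, profile,
                            FilterSpec(), toy_registry)
        out = tmp_path / "passing.tsv"
        export_result(res, out)
        lines = out.read_text().splitlines()
        assert len(lines) == 4  # header + 3 genes
        back = pd.read_csv(out, sep="\t")
        assert tuple(back["entrez_id"]) == res.passing_genes

    def test_empty_result_is_header_only(self, tmp_path, factor_table, profile,
                                         toy_registry):
        res = apply_filters(["NOPE"], factor_table, profile, FilterSpec(),
                            toy_registry)
        out = tmp_path / "empty.tsv"
        export_result(res, out)
        assert len(out.read_text().splitlines()) == 1

    def test_byte_stable(self, tmp_path, factor_table, profile, toy_registry):
        res = apply_filters(["1", "2"], factor_table, profile, FilterSpec(),
                            toy_registry)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_result(res, p1)
        export_result(res, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestDefaultPanel:
    def test_one_representative_per_cluster(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=150)
        v = rng.normal(size=150)
        table = pd.DataFrame({
            "u1": u, "u2": u + 0.05 * rng.normal(size=150),
            "v1": v, "v2": v + 0.05 * rng.normal(size=150),
        })
        from genegap.fmug import default_factor_panel
        panel = default_factor_panel(table, n_clusters=2)
        assert len(panel) == 2
        assert len({p[0] for p in panel}) == 2  # one from each block


class TestParsePredicate:
    def test_forms(self):
        assert parse_predicate("n_articles<=10") == Predicate("n_articles",
                                                              "le", 10.0)
        assert parse_predicate("gravy>=0") == Predicate("gravy", "ge", 0.0)
        assert parse_predicate("has_plasmid is_true") == Predicate(
            "has_plasmid", "is_true")
        with pytest.raises(ValueError):
            parse_predicate("what")
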