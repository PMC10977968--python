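"""Synthetic bibliometric corpus with known ground-truth effects.

Generates a complete corpus — gene registry, articles, title/abstract
mentions, citations, per-assay repository evidence and factor sources — in
the same tab-delimited dialects the readers accept, so every pipeline
stage can be exercised end-to-end without external downloads.

The generative model:

* Per-gene literature attention is a discretized log-normal (heavy tail),
  realized as single-gene background articles plus a configurable share of
  two-gene articles.
* Each focus study samples hit genes uniformly from the protein-coding
  registry; each hit is highlighted in the reporting title/abstract with
  probability ``logistic(logit(base_highlight_rate) + beta_highlight *
  log10(attention + 1))`` — ``beta_highlight = 0`` is the unbiased null,
  positive values reproduce preferential highlighting of well-studied
  genes. Citing articles mention each hit by the analogous rule with their
  own base rate.
* Citations are negative-binomial with log-mean shifted by ``gamma_cite *
  log10(attention + 1)`` (negative values make articles on less-studied
  genes accrue more citations); per-MeSH-term overrides inject
  term-specific effects.
* Factors are generated conditional on the realized highlighting labels so
  a configured odds ratio or common-language F holds in expectation;
  infeasible effects raise, naming the factor.

Identical seeds give byte-identical output files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtri

from . import attention as attention_mod
from . import corpus as corpus_mod
from . import hits as hits_mod

logger = logging.getLogger(__name__)

__all__ = ["FactorSpec", "SyntheticConfig", "SyntheticCorpus",
           "generate_corpus", "truth_report", "recovery_factor_panel",
           "null_factor_panel", "null_config"]

BACKGROUND_PMID0 = 1_000_000
FOCUS_PMID0 = 500_000
CITING_PMID0 = 700_000


@dataclass(frozen=True)
class FactorSpec:
    """One synthetic factor: ``effect`` is the true odds ratio (binary) or
    common-language F (continuous) versus highlighting; None means null."""

    name: str
    kind: str  # "binary" | "continuous"
    effect: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"factor {self.name}: unknown kind {self.kind!r}")


def recovery_factor_panel() -> tuple[FactorSpec, ...]:
    """Three injected factors (odds ratio 4 / F 0.75) among twenty nulls."""
    injected = (
        FactorSpec("bin_effect", "binary", 4.0),
        FactorSpec("cont_effect_a", "continuous", 0.75),
        FactorSpec("cont_effect_b", "continuous", 0.75),
    )
    nulls = tuple(FactorSpec(f"bin_null_{i}", "binary") for i in range(10)) + \
        tuple(FactorSpec(f"cont_null_{i}", "continuous") for i in range(10))
    return injected + nulls


def null_factor_panel(n_binary: int = 10, n_continuous: int = 10) -> tuple[FactorSpec, ...]:
    return tuple(FactorSpec(f"bin_null_{i}", "binary") for i in range(n_binary)) + \
        tuple(FactorSpec(f"cont_null_{i}", "continuous") for i in range(n_continuous))


@dataclass(frozen=True)
class SyntheticConfig:
    """All distributions, effect sizes and the mandatory seed."""

    seed: int
    n_genes: int = 2000
    frac_protein_coding: float = 0.55
    frac_symbol_undefined: float = 0.02
    attention_lognormal: tuple[float, float] = (1.0, 1.5)  # (mu, sigma)
    multi_gene_article_fraction: float = 0.30
    year_range: tuple[int, int] = (1990, 2021)
    n_focus_per_assay: int = 3
    hits_per_study: tuple[int, int] = (100, 300)  # uniform inclusive
    base_highlight_rate: float = 0.15
    beta_highlight: float = 1.0
    n_citing_per_focus: int = 5
    citing_base_rate: float = 0.01
    citation_negbin: tuple[float, float] = (10.0, 1.0)  # (mean, dispersion)
    gamma_cite: float = -0.5
    mesh_terms: tuple[str, ...] = ("D000001", "D000002", "D000003",
                                   "D000004", "D000005")
    mesh_gamma: Mapping[str, float] = field(default_factory=dict)
    factors: tuple[FactorSpec, ...] = field(default_factory=recovery_factor_panel)
    binary_prevalence: float = 0.30
    # emit the factor-derivation source tables (off for corpora that only
    # exercise the screens, where they are dead weight)
    derivation_sources: bool = True

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        for p in (self.frac_protein_coding, self.base_highlight_rate,
                  self.citing_base_rate, self.binary_prevalence,
                  self.multi_gene_article_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        names = [f.name for f in self.factors]
        if len(names) != len(set(names)):
            raise ValueError("duplicate factor names")


@dataclass
class SyntheticCorpus:
    """All generated tables (dialect column headers) plus ground truth."""

    config: SyntheticConfig
    registry_df: pd.DataFrame
    articles_df: pd.DataFrame
    gene2pubmed_df: pd.DataFrame
    pubtator_df: pd.DataFrame
    citation_links_df: pd.DataFrame
    orcs_index_df: pd.DataFrame
    orcs_genes_df: pd.DataFrame
    gxa_df: pd.DataFrame
    biogrid_df: pd.DataFrame
    gwas_df: pd.DataFrame
    gene_intervals_df: pd.DataFrame
    factor_values_df: pd.DataFrame  # injected-spec factors, genes x factors
    factor_kinds: dict[str, str]
    factor_sources: dict[str, object]
    truth_df: pd.DataFrame
    attention_counts: pd.Series  # ground-truth background mention counts

    # -- parsed views through the real readers --------------------------------

    def registry(self) -> pd.DataFrame:
        return corpus_mod.load_gene_registry(self.registry_df)

    def articles(self) -> pd.DataFrame:
        return corpus_mod.load_articles(self.articles_df)

    def mentions(self, registry: pd.DataFrame | None = None,
                 articles: pd.DataFrame | None = None) -> pd.DataFrame:
        return corpus_mod.resolve_mentions(
            self.gene2pubmed_df, self.pubtator_df,
            self.articles() if articles is None else articles,
            self.registry() if registry is None else registry)

    def studies(self, registry: pd.DataFrame | None = None,
                mentions: pd.DataFrame | None = None) -> list[hits_mod.FocusStudy]:
        reg = self.registry() if registry is None else registry
        out = (hits_mod.extract_crispr_hits(self.orcs_index_df,
                                            self.orcs_genes_df, reg)
               + hits_mod.extract_transcriptomic_hits(self.gxa_df, reg)
               + hits_mod.extract_apms_hits(self.biogrid_df, reg)
               + hits_mod.extract_gwas_hits(self.gwas_df, reg,
                                            self.gene_intervals_df))
        links = corpus_mod.load_citation_links(self.citation_links_df)
        out = hits_mod.attach_citing_articles(out, links)
        m = self.mentions(registry=reg) if mentions is None else mentions
        return hits_mod.admit_studies(out, m)

    def attention_profile(self, registry=None, mentions=None, articles=None,
                          **kwargs) -> attention_mod.AttentionProfile:
        reg = self.registry() if registry is None else registry
        art = self.articles() if articles is None else articles
        m = self.mentions(registry=reg, articles=art) if mentions is None else mentions
        focus = set(self.orcs_index_df["PUBMED_ID"].astype(int)) \
            | set(self.gxa_df["pmid"].astype(int)) \
            | set(self.biogrid_df["Pubmed ID"].astype(int)) \
            | set(self.gwas_df["PUBMEDID"].astype(int))
        kwargs.setdefault("exclude_pmids", focus)
        return attention_mod.count_articles_per_gene(m, art, reg, **kwargs)

    def factor_table(self) -> pd.DataFrame:
        t = self.factor_values_df.copy()
        t.attrs["kinds"] = dict(self.factor_kinds)
        return t

    # -- dialect file output --------------------------------------------------

    def write(self, outdir: PathLike | str) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "registry.tsv": self.registry_df,
            "articles.tsv": self.articles_df,
            "gene2pubmed.tsv": self.gene2pubmed_df,
            "pubtator.tsv": self.pubtator_df,
            "citation_links.tsv": self.citation_links_df,
            "orcs_index.tsv": self.orcs_index_df,
            "orcs_genes.tsv": self.orcs_genes_df,
            "gxa_analytics.tsv": self.gxa_df,
            "biogrid.tsv": self.biogrid_df,
            "gwas_associations.tsv": self.gwas_df,
            "gene_intervals.tsv": self.gene_intervals_df,
            "truth.tsv": self.truth_df,
        }
        for fname, df in tables.items():
            corpus_mod.write_tsv(df, out / fname)
        fv = self.factor_values_df.reset_index()
        corpus_mod.write_tsv(fv, out / "factor_table.tsv")
        src_dir = out / "factor_sources"
        src_dir.mkdir(exist_ok=True)
        for name, obj in self.factor_sources.items():
            if name == "sequences":
                with open(src_dir / "sequences.fasta", "w") as fh:
                    for g, seq in sorted(dict(obj).items()):
                        fh.write(f">{g}\n{seq}\n")
            elif name == "primate_taxids":
                pd.DataFrame({"tax_id": sorted(obj)}).to_csv(
                    src_dir / "primate_taxids.tsv", sep="\t", index=False,
                    lineterminator="\n")
            else:
                corpus_mod.write_tsv(obj, src_dir / f"{name}.tsv")


# ---------------------------------------------------------------------------


def _highlight_probability(attention: np.ndarray, base_rate: float,
                           beta: float) -> np.ndarray:
    return expit(logit(base_rate) + beta * np.log10(attention + 1.0))


def _negbin(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-9)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def _binary_factor_probs(orv: float, q0: float, name: str) -> float:
    if not (orv > 0 and math.isfinite(orv)):
        raise ValueError(f"factor {name}: odds ratio {orv} infeasible")
    odds1 = orv * q0 / (1.0 - q0)
    return odds1 / (1.0 + odds1)


def _continuous_factor_shift(f: float, name: str) -> float:
    if not (0.0 < f < 1.0):
        raise ValueError(f"factor {name}: common-language F {f} infeasible "
                         "(must lie strictly in (0, 1))")
    return math.sqrt(2.0) * float(ndtri(f))


def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate the full corpus for ``config`` (deterministic in the seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = np.arange(1, n + 1)
    is_pc = rng.random(n) < config.frac_protein_coding
    if is_pc.sum() < 10:
        is_pc[:10] = True
    symbol_undefined = rng.random(n) < config.frac_symbol_undefined

    # --- registry -----------------------------------------------------------
    n_syn = rng.integers(0, 6, size=n)
    registry_df = pd.DataFrame({
        "GeneID": gene_ids,
        "Ensembl": [f"ENSG{g:011d}" for g in gene_ids],
        "Symbol": ["-" if u else f"GG{g}" for g, u in zip(gene_ids, symbol_undefined)],
        "Synonyms": ["-" if k == 0 else "|".join(f"GG{g}S{j}" for j in range(k))
                     for g, k in zip(gene_ids, n_syn)],
        "type_of_gene": np.where(is_pc, "protein-coding", "ncRNA"),
    })

    # --- gene intervals (used for GWAS containment and gene length) ---------
    chroms = (gene_ids % 22 + 1).astype(str)
    slot = np.arange(n) // 22
    starts = 1 + slot * 100_000
    lengths = rng.integers(5_000, 50_000, size=n)
    gene_intervals_df = pd.DataFrame({
        "GeneID": gene_ids, "chrom": chroms,
        "start": starts, "end": starts + lengths,
    })

    # --- background literature ---------------------------------------------
    mu, sigma = config.attention_lognormal
    att_counts = np.floor(rng.lognormal(mu, sigma, size=n)).astype(int)
    gene_of_mention = np.repeat(gene_ids, att_counts)
    rng.shuffle(gene_of_mention)
    m_total = gene_of_mention.size
    f2 = config.multi_gene_article_fraction
    n_two = int(f2 * m_total / (1.0 + f2))
    pair_genes = gene_of_mention[: 2 * n_two]
    single_genes = gene_of_mention[2 * n_two:]
    n_articles_bg = n_two + single_genes.size
    bg_pmids = BACKGROUND_PMID0 + np.arange(n_articles_bg)
    mention_pmid = np.concatenate([
        np.repeat(bg_pmids[:n_two], 2), bg_pmids[n_two:]])
    mention_gene = np.concatenate([pair_genes, single_genes])
    bg_mentions = pd.DataFrame({"pmid": mention_pmid, "entrez_id": mention_gene})
    bg_mentions = bg_mentions.drop_duplicates()
    realized_counts = (bg_mentions.groupby("entrez_id").size()
                       .reindex(gene_ids, fill_value=0))

    y0, y1 = config.year_range
    bg_years = rng.integers(y0, y1 + 1, size=n_articles_bg)
    bg_mesh = rng.choice(np.array(config.mesh_terms), size=n_articles_bg)

    counts_series = pd.Series(att_counts, index=gene_ids)
    # citations: popularity of the article = mean attention of its genes
    att_of_mention = counts_series.reindex(bg_mentions["entrez_id"]).to_numpy()
    art_pop = (pd.Series(att_of_mention, index=bg_mentions["pmid"].to_numpy())
               .groupby(level=0).mean()
               .reindex(bg_pmids).fillna(0.0).to_numpy())
    mean0, disp = config.citation_negbin
    gammas = np.array([config.mesh_gamma.get(t, config.gamma_cite)
                       for t in bg_mesh])
    cite_mean = mean0 * np.exp(gammas * np.log10(art_pop + 1.0))
    bg_citations = _negbin(rng, cite_mean, disp)

    # a few review articles plus single-source rows exercising the
    # resolution rule (they never become resolved mentions)
    n_review = max(2, n_articles_bg // 50)
    review_pmids = bg_pmids[-1] + 1 + np.arange(n_review)
    review_genes = rng.choice(gene_ids, size=n_review)
    noise_g2p = pd.DataFrame({"pmid": review_pmids, "entrez_id": review_genes})
    n_disagree = max(2, n_articles_bg // 100)
    dis_pmids = rng.choice(bg_pmids, size=n_disagree, replace=False)
    dis_genes = rng.choice(gene_ids, size=n_disagree)

    # --- focus studies ------------------------------------------------------
    pc_genes = gene_ids[is_pc]
    att_map = counts_series
    focus_rows = []       # (pmid, assay, hit gene, highlighted?)
    focus_articles = []   # (pmid, year)
    pmid_cursor = FOCUS_PMID0
    for assay in hits_mod.ASSAYS:
        for _ in range(config.n_focus_per_assay):
            pmid = pmid_cursor
            pmid_cursor += 1
            k = int(rng.integers(config.hits_per_study[0],
                                 config.hits_per_study[1] + 1))
            k = min(k, pc_genes.size)
            hit_genes = rng.choice(pc_genes, size=k, replace=False)
            p_hl = _highlight_probability(
                att_map.loc[hit_genes].to_numpy(dtype=float),
                config.base_highlight_rate, config.beta_highlight)
            hl = rng.random(k) < p_hl
            year = int(rng.integers(2012, 2018))
            focus_articles.append((pmid, assay, year))
            for g, h in zip(hit_genes, hl):
                focus_rows.append((pmid, assay, int(g), bool(h)))
    focus_df = pd.DataFrame(focus_rows,
                            columns=["pmid", "assay", "entrez_id", "highlighted"])

    # --- citing articles ----------------------------------------------------
    citing_rows = []   # mentions in citing articles
    citing_links = []
    citing_articles = []
    citing_cursor = CITING_PMID0
    for pmid, assay, year in focus_articles:
        hits = focus_df.loc[focus_df["pmid"] == pmid, "entrez_id"].to_numpy()
        p_cit = _highlight_probability(
            att_map.loc[hits].to_numpy(dtype=float),
            config.citing_base_rate, config.beta_highlight)
        for _ in range(config.n_citing_per_focus):
            cp = citing_cursor
            citing_cursor += 1
            citing_links.append((cp, pmid))
            citing_articles.append((cp, int(rng.integers(year + 1, 2023))))
            mentioned = hits[rng.random(hits.size) < p_cit]
            for g in mentioned:
                citing_rows.append((cp, int(g)))

    # --- article table ------------------------------------------------------
    focus_pmids = np.array([p for p, _, _ in focus_articles])
    focus_years = np.array([y for _, _, y in focus_articles])
    citing_pmids = np.array([p for p, _ in citing_articles], dtype=int)
    citing_years = np.array([y for _, y in citing_articles], dtype=int)
    n_focus, n_citing = focus_pmids.size, citing_pmids.size
    articles_df = pd.DataFrame({
        "pmid": np.concatenate([bg_pmids, review_pmids, focus_pmids, citing_pmids]),
        "year": np.concatenate([bg_years, np.full(n_review, y1), focus_years,
                                citing_years]),
        "is_research_article": [1] * n_articles_bg + [0] * n_review
        + [1] * (n_focus + n_citing),
        "citation_count": np.concatenate([
            bg_citations, np.zeros(n_review, int),
            _negbin(rng, np.full(n_focus, mean0), disp),
            _negbin(rng, np.full(n_citing, mean0), disp)]),
        "mesh_terms": np.concatenate([
            bg_mesh, rng.choice(np.array(config.mesh_terms), size=n_review),
            rng.choice(np.array(config.mesh_terms), size=n_focus),
            rng.choice(np.array(config.mesh_terms), size=n_citing)]),
    })

    # --- mention sources (gene2pubmed + pubtator dialects) ------------------
    hl_mentions = focus_df[focus_df["highlighted"]][["pmid", "entrez_id"]]
    citing_mentions = pd.DataFrame(citing_rows, columns=["pmid", "entrez_id"])
    all_mentions = pd.concat([bg_mentions, hl_mentions, citing_mentions],
                             ignore_index=True).drop_duplicates()
    g2p_extra = pd.concat([noise_g2p,
                           pd.DataFrame({"pmid": dis_pmids, "entrez_id": dis_genes})],
                          ignore_index=True)
    g2p_all = pd.concat([all_mentions, g2p_extra], ignore_index=True)
    g2p_all = g2p_all.drop_duplicates().sort_values(["pmid", "entrez_id"])
    gene2pubmed_df = pd.DataFrame({
        "tax_id": 9606, "GeneID": g2p_all["entrez_id"].to_numpy(),
        "PubMed_ID": g2p_all["pmid"].to_numpy()})
    pub_all = pd.concat([all_mentions, noise_g2p], ignore_index=True)
    pub_all = pub_all.drop_duplicates().sort_values(["pmid", "entrez_id"])
    pubtator_df = pd.DataFrame({
        "PMID": pub_all["pmid"].to_numpy(), "Type": "Gene",
        "Identifier": pub_all["entrez_id"].to_numpy()})
    # review pmids appear in both sources but are non-primary, so they are
    # never resolved; dis_pmids rows appear in gene2pubmed only.

    citation_links_df = pd.DataFrame(citing_links,
                                     columns=["citing_pmid", "cited_pmid"])

    # --- assay evidence dialects -------------------------------------------
    by_assay = {a: focus_df[focus_df["assay"] == a] for a in hits_mod.ASSAYS}

    crispr = by_assay["CRISPR"]
    orcs_index_df = pd.DataFrame({
        "SCREEN_ID": [f"S{p}" for p in crispr["pmid"].unique()],
        "PUBMED_ID": crispr["pmid"].unique(),
        "ORGANISM_OFFICIAL": "Homo sapiens",
        "SCREEN_TYPE": "Negative Selection Knockout",
        "FULL_SIZE_GENOME": "yes",
    })
    non_hits = []
    for p in crispr["pmid"].unique():
        pool = np.setdiff1d(pc_genes, crispr.loc[crispr["pmid"] == p, "entrez_id"])
        extra = rng.choice(pool, size=min(50, pool.size), replace=False)
        non_hits.append(pd.DataFrame({"SCREEN_ID": f"S{p}", "IDENTIFIER_ID": extra,
                                      "HIT": "NO"}))
    orcs_genes_df = pd.concat(
        [pd.DataFrame({"SCREEN_ID": [f"S{p}" for p in crispr["pmid"]],
                       "IDENTIFIER_ID": crispr["entrez_id"], "HIT": "YES"})]
        + non_hits, ignore_index=True)

    tr = by_assay["TRANSCRIPTOMICS"]
    gxa_parts = []
    for p in tr["pmid"].unique():
        hits = tr.loc[tr["pmid"] == p, "entrez_id"].to_numpy()
        pool = np.setdiff1d(pc_genes, hits)
        nulls = rng.choice(pool, size=min(300, pool.size), replace=False)
        gxa_parts.append(pd.DataFrame({
            "comparison_id": f"C{p}", "pmid": p,
            "GeneID": np.concatenate([hits, nulls]),
            "p_value": np.concatenate([
                np.full(hits.size, 1e-8),
                rng.uniform(0.3, 1.0, size=nulls.size)]),
            "log2foldchange": rng.normal(0, 2, size=hits.size + nulls.size),
        }))
    gxa_df = pd.concat(gxa_parts, ignore_index=True)

    ap = by_assay["APMS"]
    biogrid_df = pd.DataFrame({
        "Pubmed ID": ap["pmid"].to_numpy(),
        "Entrez Gene Interactor B": ap["entrez_id"].to_numpy(),
        "Organism Interactor B": 9606,
        "Experimental System": "Affinity Capture-MS",
        "Throughput": "High Throughput",
    })

    gw = by_assay["GWAS"]
    iv = gene_intervals_df.set_index("GeneID")
    gw_start = iv.loc[gw["entrez_id"], "start"].to_numpy()
    gw_end = iv.loc[gw["entrez_id"], "end"].to_numpy()
    snp_pos = gw_start + rng.integers(0, gw_end - gw_start)
    gwas_df = pd.DataFrame({
        "PUBMEDID": gw["pmid"].to_numpy(),
        "SNPS": [f"rs{i}" for i in range(len(gw))],
        "CHR_ID": iv.loc[gw["entrez_id"], "chrom"].to_numpy(),
        "CHR_POS": snp_pos,
    })
    # intergenic SNPs: positions in the gaps between gene slots
    n_inter = max(5, len(gw) // 10)
    inter_chrom = rng.choice(chroms, size=n_inter)
    inter_pos = 95_000 + rng.integers(0, 4_000, size=n_inter) \
        + 100_000 * rng.integers(0, max(1, n // 22), size=n_inter)
    gwas_df = pd.concat([gwas_df, pd.DataFrame({
        "PUBMEDID": rng.choice(gw["pmid"].unique(), size=n_inter),
        "SNPS": [f"rsI{i}" for i in range(n_inter)],
        "CHR_ID": inter_chrom, "CHR_POS": inter_pos,
    })], ignore_index=True)

    # --- injected factors ---------------------------------------------------
    hl_genes = set(focus_df.loc[focus_df["highlighted"], "entrez_id"])
    label = np.array([g in hl_genes for g in gene_ids])
    fcols: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    truth_rows = []
    for spec in config.factors:
        kinds[spec.name] = spec.kind
        if spec.kind == "binary":
            q0 = config.binary_prevalence
            q1 = q0 if spec.effect is None else _binary_factor_probs(
                spec.effect, q0, spec.name)
            p = np.where(label, q1, q0)
            fcols[spec.name] = (rng.random(n) < p).astype(float)
        else:
            delta = 0.0 if spec.effect is None else _continuous_factor_shift(
                spec.effect, spec.name)
            fcols[spec.name] = rng.normal(0.0, 1.0, size=n) + delta * label
        if spec.effect is not None:
            truth_rows.append((spec.name, spec.kind, spec.effect))
    factor_values_df = pd.DataFrame(fcols, index=pd.Index(gene_ids,
                                                          name="entrez_id"))
    truth_df = pd.DataFrame(truth_rows,
                            columns=["factor", "kind", "true_effect"])

    factor_sources = (
        _derivation_sources(rng, registry_df, gene_intervals_df, gwas_df, is_pc)
        if config.derivation_sources else {})

    return SyntheticCorpus(
        config=config, registry_df=registry_df, articles_df=articles_df,
        gene2pubmed_df=gene2pubmed_df, pubtator_df=pubtator_df,
        citation_links_df=citation_links_df, orcs_index_df=orcs_index_df,
        orcs_genes_df=orcs_genes_df, gxa_df=gxa_df, biogrid_df=biogrid_df,
        gwas_df=gwas_df, gene_intervals_df=gene_intervals_df,
        factor_values_df=factor_values_df, factor_kinds=kinds,
        factor_sources=factor_sources, truth_df=truth_df,
        attention_counts=realized_counts,
    )


AA = np.array(list("ARNDCQEGHILKMFPSTWYV"))
PRIMATE_TAXIDS = (9598, 9601, 9544)  # chimpanzee, orangutan, macaque


def _derivation_sources(rng, registry_df, gene_intervals_df, gwas_df, is_pc):
    """Dialect source tables for the factor-derivation rules (catalog
    memberships, expression, homology, sequences); independent of the
    injected screen factors."""
    gene_ids = registry_df["GeneID"].to_numpy()
    n = gene_ids.size

    def subset(frac):
        mask = rng.random(n) < frac
        return pd.DataFrame({"GeneID": gene_ids[mask]})

    hpa = pd.DataFrame({
        "GeneID": gene_ids,
        "Antibody": np.where(rng.random(n) < 0.6,
                             [f"HPA{i:06d}" for i in range(n)], ""),
        "Protein class": np.where(rng.random(n) < 0.25,
                                  "Predicted membrane protein", "Enzymes"),
        "Evidence": np.where(rng.random(n) < 0.7,
                             "Evidence at protein level",
                             "Evidence at transcript level"),
    })
    n_tissue = 8
    hpa_tissue = pd.DataFrame({
        "GeneID": np.repeat(gene_ids, n_tissue),
        "Tissue": np.tile([f"tissue_{t}" for t in range(n_tissue)], n),
        "nTPM": np.round(rng.lognormal(0.0, 1.5, size=n * n_tissue), 3),
    })
    hpa_celline = pd.DataFrame({
        "GeneID": gene_ids,
        "nTPM": np.round(rng.lognormal(0.0, 1.5, size=n), 3),
    })
    pli = pd.DataFrame({"GeneID": gene_ids,
                        "pLI": np.round(rng.beta(0.3, 0.3, size=n), 4)})

    taxa = [10090, 10116, 6239, 7227, 559292, 7955]
    hom_rows = []
    org_gene = 900_000
    org_mention_rows = []
    org_pmid = 3_000_000
    for i, g in enumerate(gene_ids):
        if rng.random() > 0.8:
            continue  # no homology group
        gid = f"H{g}"
        hom_rows.append((gid, 9606, g))
        if rng.random() < 0.05:  # primate-only group
            hom_rows.append((gid, int(rng.choice(PRIMATE_TAXIDS)), org_gene))
            org_gene += 1
            continue
        for t in taxa:
            if rng.random() < 0.6:
                hom_rows.append((gid, t, org_gene))
                n_pub = int(rng.poisson(1.0))
                for _ in range(n_pub):
                    org_mention_rows.append((t, org_gene, org_pmid))
                    org_pmid += 1
                org_gene += 1
    homologene = pd.DataFrame(hom_rows, columns=["group_id", "tax_id", "entrez_id"])
    org_mentions = pd.DataFrame(org_mention_rows,
                                columns=["tax_id", "entrez_id", "pmid"])

    n_seq = min(n, 300)
    sequences = {
        int(g): "".join(rng.choice(AA, size=int(rng.integers(50, 200))))
        for g in gene_ids[:n_seq]
    }
    transcripts = pd.DataFrame({
        "entrez_id": gene_intervals_df["GeneID"],
        "chromosome": gene_intervals_df["chrom"],
        "start": gene_intervals_df["start"],
        "end": gene_intervals_df["end"],
    })
    gwas_loci = pd.DataFrame({
        "chromosome": gwas_df["CHR_ID"].astype(str),
        "position": gwas_df["CHR_POS"].astype(int),
    })
    intervals = transcripts.rename(columns={"chromosome": "chromosome"})

    return {
        "hpa": hpa, "hpa_tissue": hpa_tissue, "hpa_celline": hpa_celline,
        "addgene": subset(0.4), "chembl": subset(0.25), "patents": subset(0.3),
        "druggable": subset(0.2), "idg": subset(0.15),
        "hpo_mendelian": subset(0.2), "pli": pli,
        "homologene": homologene, "org_mentions": org_mentions,
        "primate_taxids": set(PRIMATE_TAXIDS),
        "sequences": sequences, "transcripts": transcripts,
        "gwas_loci": gwas_loci, "gene_intervals": intervals,
    }


def truth_report(config: SyntheticConfig) -> pd.DataFrame:
    """Ground-truth table of injected effects for ``config`` (factor, kind,
    true effect) plus the highlighting and citation coefficients."""
    rows = [(f.name, f.kind, f.effect) for f in config.factors
            if f.effect is not None]
    df = pd.DataFrame(rows, columns=["factor", "kind", "true_effect"])
    df.attrs["beta_highlight"] = config.beta_highlight
    df.attrs["gamma_cite"] = config.gamma_cite
    return df


def null_config(seed: int, **overrides) -> SyntheticConfig:
    """A fully null corpus: no highlighting bias, no citation-popularity
    dependence, no factor effects."""
    base = dict(seed=seed, beta_highlight=0.0, gamma_cite=0.0,
                factors=null_factor_panel())
    base.update(overrides)
    return SyntheticConfig(**base)
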