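"""Bibliometric corpus model: genes, articles, title/abstract mentions.

Inputs are tab-delimited tables in resource-style dialects (an NCBI-Gene
style registry, gene2pubmed-style article-gene links, PubTator-style
title/abstract annotations, an iCite-style article table with citation
counts, year and MeSH terms). Dialects are declared as column-name mappings
so differently-headed files can be adapted without code changes.

A gene mention is *resolved* only when the gene is annotated in the
title/abstract by the PubTator-style source AND the article carries the
gene in the gene2pubmed-style source AND the article is a primary research
article. Reviews stay in the article table but never contribute mentions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "REGISTRY_DIALECT",
    "ARTICLE_DIALECT",
    "GENE2PUBMED_DIALECT",
    "PUBTATOR_DIALECT",
    "CITATION_LINK_DIALECT",
    "load_gene_registry",
    "load_articles",
    "load_citation_links",
    "resolve_mentions",
    "write_tsv",
]

# Default dialects: {canonical name: column header in the file}.
REGISTRY_DIALECT: dict[str, str] = {
    "entrez_id": "GeneID",
    "ensembl_id": "Ensembl",
    "symbol": "Symbol",
    "synonyms": "Synonyms",
    "type_of_gene": "type_of_gene",
}
ARTICLE_DIALECT: dict[str, str] = {
    "pmid": "pmid",
    "year": "year",
    "is_primary_research": "is_research_article",
    "citations_total": "citation_count",
    "mesh_terms": "mesh_terms",
}
GENE2PUBMED_DIALECT: dict[str, str] = {
    "tax_id": "tax_id",
    "entrez_id": "GeneID",
    "pmid": "PubMed_ID",
}
PUBTATOR_DIALECT: dict[str, str] = {
    "pmid": "PMID",
    "type": "Type",
    "entrez_id": "Identifier",
}
CITATION_LINK_DIALECT: dict[str, str] = {
    "citing_pmid": "citing_pmid",
    "cited_pmid": "cited_pmid",
}

HUMAN_TAX_ID = 9606
NA_SYMBOL = "-"


@dataclass(frozen=True)
class GeneRecord:
    entrez_id: int
    ensembl_id: str
    symbol: str
    symbol_defined: bool
    is_protein_coding: bool
    n_synonyms: int


def _read_table(source, dialect: Mapping[str, str]) -> pd.DataFrame:
    """Read ``source`` (path or DataFrame) and rename columns to canonical
    names; raises naming the first missing required column."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", comment="#", dtype=str,
                         keep_default_na=False)
    for canonical, header in dialect.items():
        if header not in df.columns:
            raise ValueError(f"required column '{header}' ({canonical}) missing")
    return df.rename(columns={v: k for k, v in dialect.items()})


def load_gene_registry(
    source: PathLike | str | pd.DataFrame,
    dialect: Mapping[str, str] = REGISTRY_DIALECT,
) -> pd.DataFrame:
    """Load the gene registry; admit only genes whose Entrez<->Ensembl
    mapping is one-to-one.

    Returns a DataFrame indexed by ``entrez_id`` with columns
    ``ensembl_id, symbol, symbol_defined, is_protein_coding, n_synonyms``.
    Genes with a missing Ensembl ID or an ambiguous (one-to-many or
    many-to-one) mapping are excluded; the exclusion count is logged.
    """
    df = _read_table(source, dialect)
    if df.empty:
        logger.warning("gene registry source is empty")
        return pd.DataFrame(
            columns=["ensembl_id", "symbol", "symbol_defined",
                     "is_protein_coding", "n_synonyms"]
        ).rename_axis("entrez_id")
    df["entrez_id"] = df["entrez_id"].astype(int)
    n_input = len(df)
    df = df[(df["ensembl_id"] != NA_SYMBOL) & (df["ensembl_id"] != "")]
    # one-to-one Entrez<->Ensembl only
    df = df[~df["entrez_id"].duplicated(keep=False)]
    df = df[~df["ensembl_id"].duplicated(keep=False)]
    n_excluded = n_input - len(df)
    if n_excluded:
        logger.info("registry: excluded %d genes with missing/ambiguous "
                    "Entrez<->Ensembl mapping", n_excluded)
    out = pd.DataFrame({
        "entrez_id": df["entrez_id"],
        "ensembl_id": df["ensembl_id"],
        "symbol": df["symbol"],
        "symbol_defined": df["symbol"] != NA_SYMBOL,
        "is_protein_coding": df["type_of_gene"] == "protein-coding",
        "n_synonyms": [
            0 if s in ("", NA_SYMBOL) else len(s.split("|"))
            for s in df["synonyms"]
        ],
    }).set_index("entrez_id")
    return out


def load_articles(
    source: PathLike | str | pd.DataFrame,
    dialect: Mapping[str, str] = ARTICLE_DIALECT,
) -> pd.DataFrame:
    """Load the iCite-style article table.

    Returns a DataFrame indexed by ``pmid`` with ``year`` (int),
    ``is_primary_research`` (bool), ``citations_total`` (int) and
    ``mesh_terms`` (frozenset of MeSH IDs, pipe-separated in the file).
    """
    df = _read_table(source, dialect)
    df["pmid"] = df["pmid"].astype(int)
    if df["pmid"].duplicated().any():
        raise ValueError("duplicate pmid in article table")
    df["year"] = df["year"].astype(int)
    truthy = {"1", "true", "True", "yes", "Y"}
    df["is_primary_research"] = df["is_primary_research"].astype(str).isin(truthy)
    df["citations_total"] = df["citations_total"].astype(int)
    df["mesh_terms"] = [
        frozenset(t for t in str(s).split("|") if t and t != NA_SYMBOL)
        for s in df["mesh_terms"]
    ]
    return df.set_index("pmid")[
        ["year", "is_primary_research", "citations_total", "mesh_terms"]
    ]


def load_citation_links(
    source: PathLike | str | pd.DataFrame,
    dialect: Mapping[str, str] = CITATION_LINK_DIALECT,
) -> pd.DataFrame:
    """Load citing->cited PMID links as an integer two-column DataFrame."""
    df = _read_table(source, dialect)
    df["citing_pmid"] = df["citing_pmid"].astype(int)
    df["cited_pmid"] = df["cited_pmid"].astype(int)
    return df[["citing_pmid", "cited_pmid"]].drop_duplicates().reset_index(drop=True)


def resolve_mentions(
    gene2pubmed: PathLike | str | pd.DataFrame,
    pubtator: PathLike | str | pd.DataFrame,
    articles: pd.DataFrame,
    registry: pd.DataFrame | None = None,
    g2p_dialect: Mapping[str, str] = GENE2PUBMED_DIALECT,
    pubtator_dialect: Mapping[str, str] = PUBTATOR_DIALECT,
) -> pd.DataFrame:
    """Resolve title/abstract gene mentions.

    A (pmid, entrez_id) pair is resolved when it appears in both the
    gene2pubmed-style and the PubTator-style source and the article is a
    primary research article. Records referencing unknown pmids (or genes
    outside ``registry`` when given) are counted and dropped. Returns a
    deduplicated DataFrame with columns ``pmid, entrez_id``, sorted for
    determinism.
    """
    g2p = _read_table(gene2pubmed, g2p_dialect)
    g2p = g2p[g2p["tax_id"].astype(int) == HUMAN_TAX_ID]
    g2p = g2p[["pmid", "entrez_id"]].astype(int)

    pub = _read_table(pubtator, pubtator_dialect)
    pub = pub[pub["type"] == "Gene"]
    pub = pub.rename(columns={"pmid": "pmid"})
    pub = pub[["pmid", "entrez_id"]].astype(int)

    merged = g2p.merge(pub.drop_duplicates(), on=["pmid", "entrez_id"])
    merged = merged.drop_duplicates()

    known = merged["pmid"].isin(articles.index)
    if (~known).any():
        logger.info("resolve_mentions: dropped %d rows with unknown pmid",
                    int((~known).sum()))
    merged = merged[known]

    primary = articles.loc[merged["pmid"], "is_primary_research"].to_numpy()
    merged = merged[primary]

    if registry is not None:
        in_reg = merged["entrez_id"].isin(registry.index)
        if (~in_reg).any():
            logger.info("resolve_mentions: dropped %d rows with gene outside "
                        "the registry", int((~in_reg).sum()))
        merged = merged[in_reg]

    return merged.sort_values(["pmid", "entrez_id"]).reset_index(drop=True)


def write_tsv(df: pd.DataFrame, path: PathLike | str, index: bool = False) -> None:
    """Write a table as TSV with unix newlines (byte-stable output)."""
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
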