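"""Per-assay hit-gene extraction from repository-style evidence tables.

Each extractor turns one evidence dialect into a set of :class:`FocusStudy`
objects — one per reporting article (PMID) — holding that study's unique
hit genes restricted to protein-coding registry genes:

* CRISPR: genome-wide knockout screens in human, hits = flagged genes,
  unioned across an article's qualifying screens.
* Transcriptomics: differential expression called at BH q < threshold
  within each comparison (re-adjusting raw p-values; pre-adjusted q-values
  are used as-is), unioned across an article's comparisons.
* AP-MS: prey genes of high-throughput Affinity Capture-MS interactions.
* GWAS: genes containing an associated SNP; interval containment uses
  1-based half-open [start, end) gene spans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .corpus import _read_table
from .stats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "ASSAYS",
    "FocusStudy",
    "extract_crispr_hits",
    "extract_transcriptomic_hits",
    "extract_apms_hits",
    "extract_gwas_hits",
    "attach_citing_articles",
    "admit_studies",
]

ASSAYS = ("CRISPR", "TRANSCRIPTOMICS", "APMS", "GWAS")

ORCS_INDEX_DIALECT = {
    "screen_id": "SCREEN_ID",
    "pmid": "PUBMED_ID",
    "organism": "ORGANISM_OFFICIAL",
    "screen_type": "SCREEN_TYPE",
    "genome_wide": "FULL_SIZE_GENOME",
}
ORCS_GENE_DIALECT = {
    "screen_id": "SCREEN_ID",
    "entrez_id": "IDENTIFIER_ID",
    "hit": "HIT",
}
GXA_DIALECT = {
    "comparison_id": "comparison_id",
    "pmid": "pmid",
    "entrez_id": "GeneID",
    "p_value": "p_value",
    "log_fold_change": "log2foldchange",
}
BIOGRID_DIALECT = {
    "pmid": "Pubmed ID",
    "prey_entrez_id": "Entrez Gene Interactor B",
    "prey_organism": "Organism Interactor B",
    "evidence_code": "Experimental System",
    "throughput": "Throughput",
}
GWAS_ASSOC_DIALECT = {
    "pmid": "PUBMEDID",
    "snp_id": "SNPS",
    "chromosome": "CHR_ID",
    "position": "CHR_POS",
}
GENE_INTERVAL_DIALECT = {
    "entrez_id": "GeneID",
    "chromosome": "chrom",
    "start": "start",
    "end": "end",
}


@dataclass(frozen=True)
class FocusStudy:
    """A reporting article, its assay, its unique hit genes and its citers."""

    pmid: int
    assay: str
    hits: frozenset[int]
    citing_pmids: frozenset[int] = field(default=frozenset())

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")


def _protein_coding(registry: pd.DataFrame) -> set[int]:
    return set(registry.index[registry["is_protein_coding"]])


def _truthy(s: pd.Series) -> pd.Series:
    return s.astype(str).isin({"1", "true", "True", "yes", "YES", "Y"})


def extract_crispr_hits(
    index_source, gene_source, registry: pd.DataFrame,
    index_dialect: Mapping[str, str] = ORCS_INDEX_DIALECT,
    gene_dialect: Mapping[str, str] = ORCS_GENE_DIALECT,
) -> list[FocusStudy]:
    """One study per PMID with genome-wide human CRISPR knockout screens;
    hits are the union of flagged genes across the article's screens."""
    idx = _read_table(index_source, index_dialect)
    genes = _read_table(gene_source, gene_dialect)
    pc = _protein_coding(registry)

    no_pmid = (idx["pmid"].astype(str) == "") | (idx["pmid"].astype(str) == "-")
    if no_pmid.any():
        logger.info("CRISPR: skipped %d screens without a pmid", int(no_pmid.sum()))
    idx = idx[~no_pmid]
    keep = (
        (idx["organism"] == "Homo sapiens")
        & (idx["screen_type"].str.contains("Knockout", case=False))
        & _truthy(idx["genome_wide"])
    )
    idx = idx[keep]

    hits = genes[_truthy(genes["hit"])]
    hits = hits.merge(idx[["screen_id", "pmid"]], on="screen_id")
    hits["entrez_id"] = hits["entrez_id"].astype(int)
    hits = hits[hits["entrez_id"].isin(pc)]

    studies = []
    for pmid, grp in hits.groupby(hits["pmid"].astype(int)):
        studies.append(FocusStudy(pmid=int(pmid), assay="CRISPR",
                                  hits=frozenset(grp["entrez_id"])))
    return studies


def extract_transcriptomic_hits(
    source, registry: pd.DataFrame, q_threshold: float = 0.05,
    dialect: Mapping[str, str] = GXA_DIALECT,
    values_are_adjusted: bool = False,
) -> list[FocusStudy]:
    """Differential-expression hits at BH FDR q < ``q_threshold``.

    ``p_value`` entries are BH-adjusted within each comparison unless
    ``values_are_adjusted`` says they are already q-values. Rows with a
    p-value outside [0, 1] are rejected and logged.
    """
    df = _read_table(source, dialect)
    df["entrez_id"] = df["entrez_id"].astype(int)
    df["pmid"] = df["pmid"].astype(int)
    df["p_value"] = pd.to_numeric(df["p_value"], errors="coerce")
    bad = df["p_value"].isna() | (df["p_value"] < 0) | (df["p_value"] > 1)
    if bad.any():
        logger.info("transcriptomics: rejected %d rows with invalid p-values",
                    int(bad.sum()))
        df = df[~bad]
    pc = _protein_coding(registry)

    hit_frames = []
    for _, grp in df.groupby("comparison_id", sort=True):
        q = grp["p_value"].to_numpy() if values_are_adjusted else bh_fdr(grp["p_value"])
        hit_frames.append(grp.loc[np.asarray(q) < q_threshold,
                                  ["pmid", "entrez_id"]])
    if not hit_frames:
        return []
    hits = pd.concat(hit_frames)
    hits = hits[hits["entrez_id"].isin(pc)]
    return [
        FocusStudy(pmid=int(pmid), assay="TRANSCRIPTOMICS",
                   hits=frozenset(grp["entrez_id"]))
        for pmid, grp in hits.groupby("pmid")
        if len(grp)
    ]


def extract_apms_hits(
    source, registry: pd.DataFrame,
    dialect: Mapping[str, str] = BIOGRID_DIALECT,
) -> list[FocusStudy]:
    """Prey genes of high-throughput Affinity Capture-MS interactions."""
    df = _read_table(source, dialect)
    missing = (df["evidence_code"].astype(str) == "") | (df["evidence_code"] == "-")
    if missing.any():
        logger.info("AP-MS: skipped %d rows without an evidence code",
                    int(missing.sum()))
        df = df[~missing]
    keep = (
        (df["evidence_code"] == "Affinity Capture-MS")
        & (df["throughput"].str.contains("High Throughput", case=False))
        & (df["prey_organism"].astype(str) == "9606")
    )
    df = df[keep]
    df["entrez_id"] = df["prey_entrez_id"].astype(int)
    pc = _protein_coding(registry)
    df = df[df["entrez_id"].isin(pc)]
    return [
        FocusStudy(pmid=int(pmid), assay="APMS", hits=frozenset(grp["entrez_id"]))
        for pmid, grp in df.groupby(df["pmid"].astype(int))
        if len(grp)
    ]


def extract_gwas_hits(
    source, registry: pd.DataFrame, gene_intervals,
    dialect: Mapping[str, str] = GWAS_ASSOC_DIALECT,
    interval_dialect: Mapping[str, str] = GENE_INTERVAL_DIALECT,
) -> list[FocusStudy]:
    """Genes containing an associated SNP (1-based, half-open [start, end)).

    SNPs with no usable coordinates are skipped and logged; intergenic SNPs
    contribute no hit.
    """
    df = _read_table(source, dialect)
    df["chromosome"] = df["chromosome"].astype(str)
    iv = _read_table(gene_intervals, interval_dialect)
    iv["entrez_id"] = iv["entrez_id"].astype(int)
    iv["chromosome"] = iv["chromosome"].astype(str)
    iv["start"] = iv["start"].astype(int)
    iv["end"] = iv["end"].astype(int)

    pos = pd.to_numeric(df["position"], errors="coerce")
    usable = pos.notna() & (pos >= 1) & (df["chromosome"].astype(str) != "")
    if (~usable).any():
        logger.info("GWAS: skipped %d SNPs without usable coordinates",
                    int((~usable).sum()))
    df = df[usable].assign(position=pos[usable].astype(int))

    merged = df.merge(iv, on="chromosome")
    inside = (merged["position"] >= merged["start"]) & (merged["position"] < merged["end"])
    merged = merged[inside]
    pc = _protein_coding(registry)
    merged = merged[merged["entrez_id"].isin(pc)]
    return [
        FocusStudy(pmid=int(pmid), assay="GWAS", hits=frozenset(grp["entrez_id"]))
        for pmid, grp in merged.groupby(merged["pmid"].astype(int))
        if len(grp)
    ]


def attach_citing_articles(
    studies: Iterable[FocusStudy], citation_links: pd.DataFrame
) -> list[FocusStudy]:
    """Fill each study's ``citing_pmids`` from a citing->cited link table."""
    by_cited = citation_links.groupby("cited_pmid")["citing_pmid"].agg(frozenset)
    return [
        replace(s, citing_pmids=by_cited.get(s.pmid, frozenset()))
        for s in studies
    ]


def admit_studies(
    studies: Iterable[FocusStudy], mentions: pd.DataFrame,
    require_mentioned_hit: bool = True,
) -> list[FocusStudy]:
    """Admit studies with non-empty hits; by default additionally require
    that at least one hit gene has a resolved mention somewhere in the
    corpus (the study-collection criterion)."""
    mentioned_genes = set(mentions["entrez_id"])
    out = []
    for s in studies:
        if not s.hits:
            continue
        if require_mentioned_hit and not (set(s.hits) & mentioned_genes):
            logger.info("study %d: no hit gene mentioned anywhere; not admitted",
                        s.pmid)
            continue
        out.append(s)
    return out
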