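"""Gene-level factors and their association with title/abstract highlighting.

Derives a genes x factors table from per-resource dialect tables (protein
atlas style annotation, plasmid/compound/patent/druggability catalogs,
loss-of-function intolerance, homology groups, transcript spans, protein
sequences, GWAS loci, model-organism literature), then screens every
factor against highlighting per assay: binary factors with an odds ratio +
Woolf CI + two-sided Fisher exact test on the 2x2 table over unique hit
genes, continuous factors with the common-language effect size F and a
two-sided Mann-Whitney U test. Benjamini-Hochberg correction is pooled per
panel (binary / continuous) across assays. A hierarchical clustering of
the factors (rank correlation with 0/1 coding, distance 1 - |rho|, average
linkage) summarizes their redundancy.

Derivation rules of note:

* GRAVY is the mean Kyte-Doolittle hydropathy, ignoring Sec (U) and Pyl (O).
* Gene length is the span of the longest transcript on the chromosome.
* A gene is primate-specific when all other members of its homology group
  belong to primate genomes.
* Model-organism publication counts resolve to 0 for genes with a homolog
  but no publications, and to NA for genes without a homolog.
* GWAS loci are mapped to the nearest gene on the chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .attention import AttentionProfile
from .hits import FocusStudy
from .leakage import highlighted_in_reporting
from .stats import (ContingencyTable, bh_fdr, common_language_f, fisher_exact,
                    mann_whitney_u, odds_ratio_ci)

logger = logging.getLogger(__name__)

__all__ = [
    "KYTE_DOOLITTLE",
    "FactorAssociation",
    "compute_gravy",
    "read_fasta_sequences",
    "derive_factor_table",
    "highlighting_by_assay",
    "screen_binary_factor",
    "screen_continuous_factor",
    "screen_factors",
    "apply_screen_fdr",
    "associated_factors",
    "cluster_factors",
]

KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
IGNORED_RESIDUES = frozenset("UO")  # Selenocysteine, Pyrrolysine

HUMAN_TAX_ID = 9606
MODEL_ORGANISMS = {
    "mouse": 10090, "rat": 10116, "worm": 6239, "fly": 7227,
    "yeast": 559292, "zebrafish": 7955,
}


def compute_gravy(protein_sequence: str) -> float:
    """Grand average of hydropathy (Kyte-Doolittle), skipping U and O.

    Returns NaN when no scoreable residue remains; unknown residues raise.
    """
    scores = []
    for res in protein_sequence.upper():
        if res in IGNORED_RESIDUES:
            continue
        if res not in KYTE_DOOLITTLE:
            raise ValueError(f"unknown amino-acid code {res!r}")
        scores.append(KYTE_DOOLITTLE[res])
    if not scores:
        logger.info("GRAVY undefined: no scoreable residues")
        return float("nan")
    return float(np.mean(scores))


def read_fasta_sequences(path) -> dict[int, str]:
    """Protein sequences keyed by Entrez ID from a FASTA file whose record
    ids are the Entrez IDs."""
    from Bio import SeqIO
    return {int(rec.id): str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


@dataclass(frozen=True)
class FactorAssociation:
    """Association of one factor with highlighting in one assay."""

    assay: str
    factor: str
    kind: str  # "binary" | "continuous"
    effect: float  # OR (binary) or common-language F (continuous)
    ci_low: float
    ci_high: float
    p: float
    q: float
    n_highlighted: int
    n_not_highlighted: int
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Factor table derivation


def _membership(registry: pd.DataFrame, members: Iterable[int]) -> pd.Series:
    m = set(int(g) for g in members)
    return pd.Series([g in m for g in registry.index], index=registry.index)


def _gene_length(transcripts: pd.DataFrame) -> pd.Series:
    """Chromosomal span of a gene's transcripts: the longest stretch they
    cover, max(end) - min(start) over half-open intervals."""
    t = transcripts.copy()
    g = t.groupby(t["entrez_id"].astype(int))
    return g["end"].max().astype(int) - g["start"].min().astype(int)


def _nearest_gene_counts(loci: pd.DataFrame, intervals: pd.DataFrame) -> pd.Series:
    """Count GWAS loci per nearest gene (distance 0 inside the span)."""
    counts: dict[int, int] = {}
    iv = intervals.copy()
    iv["entrez_id"] = iv["entrez_id"].astype(int)
    for chrom, snps in loci.groupby("chromosome"):
        genes = iv[iv["chromosome"] == chrom]
        if genes.empty:
            continue
        starts = genes["start"].astype(int).to_numpy()
        ends = genes["end"].astype(int).to_numpy()
        ids = genes["entrez_id"].to_numpy()
        pos = snps["position"].astype(int).to_numpy()[:, None]
        dist = np.maximum.reduce([starts[None, :] - pos,
                                  pos - (ends[None, :] - 1),
                                  np.zeros((pos.shape[0], starts.size), int)])
        nearest = ids[np.argmin(dist, axis=1)]
        for g in nearest:
            counts[int(g)] = counts.get(int(g), 0) + 1
    return pd.Series(counts, dtype=float)


def _homology_factors(homologene: pd.DataFrame, registry: pd.DataFrame,
                      primate_taxids: set[int]) -> dict[str, pd.Series]:
    """Per-organism homolog flags and the primate-specific flag."""
    h = homologene.copy()
    h["tax_id"] = h["tax_id"].astype(int)
    h["entrez_id"] = h["entrez_id"].astype(int)
    human = h[h["tax_id"] == HUMAN_TAX_ID]
    gene_to_group = dict(zip(human["entrez_id"], human["group_id"]))
    group_taxa = h.groupby("group_id")["tax_id"].agg(set)

    out: dict[str, pd.Series] = {}
    for name, taxid in MODEL_ORGANISMS.items():
        flags = []
        for g in registry.index:
            grp = gene_to_group.get(g)
            flags.append(bool(grp is not None and taxid in group_taxa[grp]))
        out[f"homolog_in_{name}"] = pd.Series(flags, index=registry.index)

    primate = []
    for g in registry.index:
        grp = gene_to_group.get(g)
        if grp is None:
            primate.append(np.nan)  # no homology information
        else:
            others = group_taxa[grp] - {HUMAN_TAX_ID}
            primate.append(float(bool(others) and others <= primate_taxids
                                 or not others))
    out["primate_specific"] = pd.Series(primate, index=registry.index)
    return out


def _model_organism_publications(
    homologene: pd.DataFrame, org_mentions: pd.DataFrame, registry: pd.DataFrame
) -> dict[str, pd.Series]:
    """Articles on each organism's homologs of a human gene.

    Genes with a homolog but no publications resolve to 0; genes without a
    homolog to NA.
    """
    h = homologene.copy()
    h["tax_id"] = h["tax_id"].astype(int)
    h["entrez_id"] = h["entrez_id"].astype(int)
    human = h[h["tax_id"] == HUMAN_TAX_ID][["group_id", "entrez_id"]]
    human = human.rename(columns={"entrez_id": "human_entrez_id"})

    m = org_mentions.copy()
    m["tax_id"] = m["tax_id"].astype(int)
    m["entrez_id"] = m["entrez_id"].astype(int)
    pubs = m.groupby(["tax_id", "entrez_id"])["pmid"].nunique()

    out: dict[str, pd.Series] = {}
    for name, taxid in MODEL_ORGANISMS.items():
        org = h[h["tax_id"] == taxid].merge(human, on="group_id")
        if org.empty:
            out[f"{name}_publications"] = pd.Series(np.nan, index=registry.index)
            continue
        org["n_pubs"] = [pubs.get((taxid, g), 0) for g in org["entrez_id"]]
        per_gene = org.groupby("human_entrez_id")["n_pubs"].sum()
        out[f"{name}_publications"] = per_gene.reindex(registry.index).astype(float)
    return out


def derive_factor_table(
    sources: Mapping[str, object],
    registry: pd.DataFrame,
    attention: AttentionProfile | None = None,
) -> pd.DataFrame:
    """Build the genes x factors table from per-resource dialect tables.

    ``sources`` maps source names to DataFrames (or, for ``sequences``, a
    mapping entrez_id -> amino-acid string). Recognized sources: ``hpa``,
    ``hpa_tissue``, ``hpa_celline``, ``addgene``, ``chembl``, ``patents``,
    ``druggable``, ``idg``, ``hpo_mendelian``, ``pli``, ``homologene`` (+
    ``primate_taxids``), ``org_mentions``, ``transcripts``, ``sequences``,
    ``gwas_loci`` (+ ``gene_intervals``). A missing source emits its
    factors as all-NA with a warning. Factor kinds are recorded in
    ``DataFrame.attrs['kinds']``.
    """
    idx = registry.index
    cols: dict[str, pd.Series] = {}
    kinds: dict[str, str] = {}

    def add(name: str, kind: str, series: pd.Series | None) -> None:
        kinds[name] = kind
        if series is None:
            logger.warning("factor %s: source missing, emitted all-NA", name)
            cols[name] = pd.Series(np.nan, index=idx)
        else:
            cols[name] = series.reindex(idx).astype(float)

    # registry-intrinsic factors
    add("symbol_undefined", "binary", (~registry["symbol_defined"]).astype(float))
    add("n_synonyms", "continuous", registry["n_synonyms"].astype(float))
    if attention is not None:
        add("n_articles", "continuous", attention.counts.astype(float))
    else:
        add("n_articles", "continuous", None)

    # simple catalog memberships
    for name, key, col in [
        ("has_plasmid", "addgene", "GeneID"),
        ("has_compound", "chembl", "GeneID"),
        ("has_patent", "patents", "GeneID"),
        ("druggable", "druggable", "GeneID"),
        ("idg_understudied", "idg", "GeneID"),
        ("mendelian", "hpo_mendelian", "GeneID"),
    ]:
        src = sources.get(key)
        add(name, "binary",
            None if src is None
            else _membership(registry, src[col].astype(int)).astype(float))

    hpa = sources.get("hpa")
    if hpa is not None:
        h = hpa.copy()
        h["GeneID"] = h["GeneID"].astype(int)
        h = h.set_index("GeneID")
        add("has_antibody", "binary",
            (h["Antibody"].astype(str).str.strip() != "").astype(float))
        add("membrane_protein", "binary",
            h["Protein class"].astype(str)
            .str.contains("membrane protein", case=False).astype(float))
        add("protein_evidence", "binary",
            (h["Evidence"] == "Evidence at protein level").astype(float))
    else:
        for name in ("has_antibody", "membrane_protein", "protein_evidence"):
            add(name, "binary", None)

    pli = sources.get("pli")
    if pli is not None:
        p = pli.copy()
        p["GeneID"] = p["GeneID"].astype(int)
        s = p.set_index("GeneID")["pLI"].astype(float)
        add("pli_score", "continuous", s)
        add("pli_intolerant", "binary", (s > 0.9).astype(float))
    else:
        add("pli_score", "continuous", None)
        add("pli_intolerant", "binary", None)

    tissue = sources.get("hpa_tissue")
    if tissue is not None:
        t = tissue.copy()
        t["GeneID"] = t["GeneID"].astype(int)
        t["nTPM"] = t["nTPM"].astype(float)
        g = t.groupby("GeneID")["nTPM"]
        add("median_ntpm", "continuous", g.median())
        add("frac_tissues_detected", "continuous", g.agg(lambda v: (v >= 1).mean()))
    else:
        add("median_ntpm", "continuous", None)
        add("frac_tissues_detected", "continuous", None)

    celline = sources.get("hpa_celline")
    add("hela_ntpm", "continuous",
        None if celline is None else
        celline.assign(GeneID=lambda d: d["GeneID"].astype(int))
        .set_index("GeneID")["nTPM"].astype(float))

    transcripts = sources.get("transcripts")
    add("gene_length", "continuous",
        None if transcripts is None else _gene_length(transcripts))

    seqs = sources.get("sequences")
    if seqs is not None:
        add("gravy", "continuous",
            pd.Series({int(g): compute_gravy(s) for g, s in dict(seqs).items()}))
    else:
        add("gravy", "continuous", None)

    homologene = sources.get("homologene")
    if homologene is not None:
        primates = set(int(t) for t in sources.get("primate_taxids", [HUMAN_TAX_ID]))
        primates.add(HUMAN_TAX_ID)
        for name, series in _homology_factors(homologene, registry, primates).items():
            add(name, "binary", series.astype(float))
        org = sources.get("org_mentions")
        if org is not None:
            for name, series in _model_organism_publications(
                    homologene, org, registry).items():
                add(name, "continuous", series)
        else:
            for name in MODEL_ORGANISMS:
                add(f"{name}_publications", "continuous", None)
    else:
        for name in MODEL_ORGANISMS:
            add(f"homolog_in_{name}", "binary", None)
            add(f"{name}_publications", "continuous", None)
        add("primate_specific", "binary", None)

    loci = sources.get("gwas_loci")
    intervals = sources.get("gene_intervals")
    if loci is not None and intervals is not None:
        add("n_gwas_hits", "continuous",
            _nearest_gene_counts(loci, intervals).reindex(idx).fillna(0.0))
    else:
        add("n_gwas_hits", "continuous", None)

    table = pd.DataFrame(cols, index=idx)
    table.index.name = "entrez_id"
    table.attrs["kinds"] = kinds
    return table


# ---------------------------------------------------------------------------
# Screens


def highlighting_by_assay(
    studies: Iterable[FocusStudy], mentions: pd.DataFrame
) -> dict[str, tuple[set[int], set[int]]]:
    """Per assay: (unique hit genes, unique highlighted-in-reporting genes)."""
    out: dict[str, tuple[set[int], set[int]]] = {}
    for s in studies:
        hits, hl = out.setdefault(s.assay, (set(), set()))
        hits |= set(s.hits)
        hl |= highlighted_in_reporting(s, mentions)
    return out


def screen_binary_factor(
    assay: str, factor: str, hits: set[int], highlighted: set[int],
    values: pd.Series,
) -> FactorAssociation:
    """Odds ratio + Woolf CI + two-sided Fisher p for one binary factor.

    The 2x2 table is over unique hit genes, {factor true, false} x
    {highlighted, not}; genes with NA factor values are dropped.
    """
    not_hl = set(hits) - set(highlighted)
    hl_vals = values.reindex(sorted(highlighted)).dropna()
    nh_vals = values.reindex(sorted(not_hl)).dropna()
    flags: list[str] = []
    if hl_vals.empty or nh_vals.empty:
        return FactorAssociation(assay, factor, "binary", np.nan, np.nan,
                                 np.nan, np.nan, np.nan, len(hl_vals),
                                 len(nh_vals), ("undefined_effect",))
    t = ContingencyTable(a=int((hl_vals > 0).sum()), b=int((nh_vals > 0).sum()),
                         c=int((hl_vals == 0).sum()), d=int((nh_vals == 0).sum()))
    orci = odds_ratio_ci(t)
    fet = fisher_exact(t)
    flags.extend(orci.flags)
    return FactorAssociation(
        assay=assay, factor=factor, kind="binary", effect=orci.effect,
        ci_low=orci.ci_low, ci_high=orci.ci_high, p=fet.p_value, q=np.nan,
        n_highlighted=len(hl_vals), n_not_highlighted=len(nh_vals),
        flags=tuple(flags))


def screen_continuous_factor(
    assay: str, factor: str, hits: set[int], highlighted: set[int],
    values: pd.Series,
) -> FactorAssociation:
    """Common-language F + two-sided Mann-Whitney p for one continuous factor."""
    not_hl = set(hits) - set(highlighted)
    hl_vals = values.reindex(sorted(highlighted)).dropna()
    nh_vals = values.reindex(sorted(not_hl)).dropna()
    if hl_vals.empty or nh_vals.empty:
        return FactorAssociation(assay, factor, "continuous", np.nan, np.nan,
                                 np.nan, np.nan, np.nan, len(hl_vals),
                                 len(nh_vals), ("all_na",))
    flags: list[str] = []
    if hl_vals.nunique() == 1 and nh_vals.nunique() == 1 \
            and hl_vals.iloc[0] == nh_vals.iloc[0]:
        return FactorAssociation(assay, factor, "continuous", 0.5, np.nan,
                                 np.nan, 1.0, np.nan, len(hl_vals),
                                 len(nh_vals), ("all_tied",))
    f = common_language_f(hl_vals, nh_vals)
    mwu = mann_whitney_u(hl_vals, nh_vals)
    return FactorAssociation(
        assay=assay, factor=factor, kind="continuous", effect=f,
        ci_low=np.nan, ci_high=np.nan, p=mwu.p_value, q=np.nan,
        n_highlighted=len(hl_vals), n_not_highlighted=len(nh_vals),
        flags=tuple(flags))


def screen_factors(
    studies: Iterable[FocusStudy],
    mentions: pd.DataFrame,
    factor_table: pd.DataFrame,
    kinds: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Screen every factor against highlighting in every assay.

    Returns one row per (assay, factor), sorted, with the q column unset
    until :func:`apply_screen_fdr`.
    """
    kinds = dict(kinds or factor_table.attrs.get("kinds", {}))
    by_assay = highlighting_by_assay(studies, mentions)
    rows = []
    for assay in sorted(by_assay):
        hits, hl = by_assay[assay]
        for factor in factor_table.columns:
            kind = kinds.get(factor, "continuous")
            fn = screen_binary_factor if kind == "binary" else screen_continuous_factor
            rows.append(fn(assay, factor, hits, hl, factor_table[factor]))
    df = pd.DataFrame([vars(a) for a in rows])
    return df.sort_values(["kind", "assay", "factor"]).reset_index(drop=True)


STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def apply_screen_fdr(associations: pd.DataFrame, scope: str = "panel") -> pd.DataFrame:
    """Benjamini-Hochberg q-values pooled per panel (binary / continuous).

    ``scope='per_assay'`` pools within each (kind, assay) instead. Adds the
    ``q`` and ``stars`` columns.
    """
    df = associations.copy()
    group_cols = ["kind"] if scope == "panel" else ["kind", "assay"]
    df["q"] = np.nan
    for _, idx in df.groupby(group_cols).groups.items():
        sub = df.loc[idx]
        tested = sub["p"].notna()
        if tested.any():
            df.loc[sub.index[tested], "q"] = bh_fdr(sub.loc[tested, "p"])
    def star(q: float) -> str:
        if not np.isfinite(q):
            return ""
        for thr, s in STAR_THRESHOLDS:
            if q < thr:
                return s
        return ""
    df["stars"] = [star(q) for q in df["q"]]
    return df


def associated_factors(associations: pd.DataFrame, q_threshold: float = 0.001) -> list[str]:
    """Factors significant (q < threshold) in at least one assay."""
    sig = associations[associations["q"] < q_threshold]
    return sorted(sig["factor"].unique())


def cluster_factors(
    factor_table: pd.DataFrame, n_clusters: int | None = None
) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    """Average-linkage hierarchical clustering of factors.

    Pairwise association is the Spearman correlation on mid-ranks with
    binary factors coded 0/1, pairwise-complete over genes; the distance is
    1 - |rho|. Factors with fewer than two distinct non-NA values are
    excluded (logged). Returns (linkage matrix, factor order, flat cluster
    labels or None).
    """
    usable = [c for c in factor_table.columns
              if factor_table[c].dropna().nunique() >= 2]
    dropped = set(factor_table.columns) - set(usable)
    if dropped:
        logger.info("clustering: excluded degenerate factors %s", sorted(dropped))
    if len(usable) < 2:
        raise ValueError("need at least 2 non-degenerate factors to cluster")
    sub = factor_table[usable].astype(float)
    rho = sub.corr(method="spearman", min_periods=2)
    dist = (1.0 - rho.abs()).to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.nan_to_num(dist, nan=1.0)
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, n_clusters, criterion="maxclust") if n_clusters else None
    return z, usable, labels
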