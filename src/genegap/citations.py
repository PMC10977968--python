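"""Does focusing on less-studied genes cost citations?

The unit of analysis is the gene: for a readout year Y, each gene
contributes one point (x = number of its single-gene articles published
before Y, y = median citations of its single-gene articles published in
Y). Only articles with exactly one distinct resolved gene mention in the
title/abstract enter, so a gene's popularity and its articles' citations
are unambiguous. Association is the Spearman rank correlation with a
seeded percentile-bootstrap confidence interval, optionally stratified by
MeSH term (with Benjamini-Hochberg correction across terms) or tracked
year by year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import TestResult, bh_fdr, bootstrap_spearman_ci, spearman_rho

logger = logging.getLogger(__name__)

__all__ = [
    "MeshScreenRow",
    "select_single_gene_articles",
    "gene_year_points",
    "popularity_citation_correlation",
    "yearly_correlation_series",
    "mesh_stratified_screen",
    "top_cited_ratio",
]


@dataclass(frozen=True)
class MeshScreenRow:
    mesh_id: str
    rho: float
    p: float
    q: float
    n_points: int

    @property
    def direction(self) -> int:
        return 0 if not np.isfinite(self.rho) else int(np.sign(self.rho))


def select_single_gene_articles(
    mentions: pd.DataFrame, articles: pd.DataFrame
) -> pd.DataFrame:
    """Articles with exactly one distinct resolved gene mention.

    Returns a DataFrame indexed by pmid with columns ``entrez_id, year,
    citations_total, mesh_terms``.
    """
    counts = mentions.drop_duplicates().groupby("pmid")["entrez_id"].nunique()
    single = counts.index[counts == 1]
    one = (mentions[mentions["pmid"].isin(single)]
           .drop_duplicates().set_index("pmid")["entrez_id"])
    out = articles.loc[one.index, ["year", "citations_total", "mesh_terms"]].copy()
    out.insert(0, "entrez_id", one)
    return out


def gene_year_points(
    single_gene_articles: pd.DataFrame, year: int, prior_cutoff: int | None = None
) -> pd.DataFrame:
    """One point per gene: prior article count (strictly before
    ``prior_cutoff``, default = ``year``) vs median citations of the gene's
    articles published in ``year``. Genes without an article in ``year``
    contribute no point."""
    cutoff = year if prior_cutoff is None else prior_cutoff
    sga = single_gene_articles
    prior = (sga[sga["year"] < cutoff].groupby("entrez_id").size()
             .rename("n_prior_articles"))
    in_year = sga[sga["year"] == year]
    med = (in_year.groupby("entrez_id")["citations_total"].median()
           .rename("median_citations"))
    points = med.to_frame()
    points["n_prior_articles"] = prior.reindex(points.index, fill_value=0).astype(int)
    points["year"] = year
    points.index.name = "entrez_id"
    return points[["n_prior_articles", "median_citations", "year"]]


def popularity_citation_correlation(
    single_gene_articles: pd.DataFrame,
    year: int,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    min_genes: int = 3,
) -> TestResult:
    """Spearman correlation of per-gene prior popularity vs median
    citations in ``year``, with a percentile bootstrap CI over genes."""
    pts = gene_year_points(single_gene_articles, year)
    if len(pts) < min_genes:
        raise ValueError(f"only {len(pts)} genes with articles in {year} "
                         f"(need >= {min_genes})")
    x = pts["n_prior_articles"].to_numpy(dtype=float)
    y = pts["median_citations"].to_numpy(dtype=float)
    base = spearman_rho(x, y)
    lo, hi = bootstrap_spearman_ci(np.column_stack([x, y]), n_boot=n_boot,
                                   seed=seed)
    return TestResult(statistic=base.statistic, p_value=base.p_value,
                      effect=base.effect, ci_low=lo, ci_high=hi,
                      flags=base.flags + (f"n={len(pts)}",))


def yearly_correlation_series(
    single_gene_articles: pd.DataFrame,
    years: Sequence[int],
    n_boot: int = 1000,
    seed: int = 0,
    min_genes: int = 50,
) -> dict[int, TestResult]:
    """One correlation per year; years with fewer than ``min_genes`` gene
    points are absent from the output (logged)."""
    rng = np.random.default_rng(seed)
    out: dict[int, TestResult] = {}
    for yr in years:
        try:
            out[yr] = popularity_citation_correlation(
                single_gene_articles, yr, n_boot=n_boot, seed=rng,
                min_genes=min_genes)
        except ValueError:
            logger.info("year %d below the %d-gene minimum; omitted", yr, min_genes)
    return out


def mesh_stratified_screen(
    single_gene_articles: pd.DataFrame,
    mesh_terms: Iterable[str],
    year: int,
    q_threshold: float = 0.01,
    min_points: int = 20,
) -> list[MeshScreenRow]:
    """Per-MeSH-term popularity/citation correlation with BH across terms.

    Each term's correlation is computed on the articles tagged with the
    term (prior counts are within-term). Terms below ``min_points`` gene
    points yield an NA row.
    """
    rows: list[tuple[str, float, float, int]] = []
    for term in mesh_terms:
        sub = single_gene_articles[
            [term in ts for ts in single_gene_articles["mesh_terms"]]
        ]
        pts = gene_year_points(sub, year)
        if len(pts) < min_points:
            rows.append((term, np.nan, np.nan, len(pts)))
            continue
        res = spearman_rho(pts["n_prior_articles"], pts["median_citations"])
        rows.append((term, res.effect, res.p_value, len(pts)))

    ps = np.array([r[2] for r in rows], dtype=float)
    tested = np.isfinite(ps)
    qs = np.full(ps.shape, np.nan)
    if tested.any():
        qs[tested] = bh_fdr(ps[tested])
    out = [MeshScreenRow(mesh_id=t, rho=r, p=p, q=q, n_points=n)
           for (t, r, p, n), q in zip(rows, qs)]
    n_sig = sum(1 for r in out if np.isfinite(r.q) and r.q < q_threshold)
    logger.info("MeSH screen: %d/%d terms significant at q<%g",
                n_sig, len(out), q_threshold)
    return out


def top_cited_ratio(
    single_gene_articles: pd.DataFrame,
    year: int,
    n_popularity_bins: int = 10,
    citation_quantile: float = 0.10,
) -> pd.DataFrame:
    """Per gene-popularity bin: P(article in top citation quantile) /
    P(article in bottom citation quantile), within ``year``.

    Popularity bins are quantile bins of each article's gene's prior
    article count; "most/lowly cited" are the top/bottom
    ``citation_quantile`` of citations among the year's articles. Empty
    bins yield NA. The configuration is recorded in ``DataFrame.attrs``.
    """
    sga = single_gene_articles
    prior = sga[sga["year"] < year].groupby("entrez_id").size()
    in_year = sga[sga["year"] == year].copy()
    if in_year.empty:
        raise ValueError(f"no articles in year {year}")
    in_year["popularity"] = prior.reindex(in_year["entrez_id"],
                                          fill_value=0).to_numpy()
    cites = in_year["citations_total"].to_numpy(dtype=float)
    hi_cut = np.quantile(cites, 1 - citation_quantile)
    lo_cut = np.quantile(cites, citation_quantile)
    in_year["top_cited"] = cites >= hi_cut
    in_year["bottom_cited"] = cites <= lo_cut
    in_year["bin"] = pd.qcut(in_year["popularity"].rank(method="first"),
                             n_popularity_bins, labels=False)
    rows = []
    for b in range(n_popularity_bins):
        grp = in_year[in_year["bin"] == b]
        if grp.empty:
            rows.append((b, np.nan, 0))
            continue
        p_top = grp["top_cited"].mean()
        p_bot = grp["bottom_cited"].mean()
        ratio = np.nan if p_bot == 0 else p_top / p_bot
        rows.append((b, ratio, len(grp)))
    out = pd.DataFrame(rows, columns=["popularity_bin", "top_to_bottom_ratio",
                                      "n_articles"])
    out.attrs["config"] = {"year": year, "n_popularity_bins": n_popularity_bins,
                           "citation_quantile": citation_quantile}
    return out
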