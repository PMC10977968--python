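"""Per-gene literature attention: article counts and percentile ranks.

Attention is the number of primary research articles mentioning a gene in
its title/abstract, computed over the whole corpus minus configurable
exclusions: the focus-study PMIDs themselves (so the high-throughput
experiments do not count toward the attention they are being compared
against), an optional publication-year cutoff (e.g. the pre-2003
literature, before completion of the Human Genome Project), and an
optional one-random-gene-per-article control that neutralizes multi-gene
abstracts. Percentiles are mid-rank based over the protein-coding
registry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .stats import percentile_rank

logger = logging.getLogger(__name__)

__all__ = ["AttentionProfile", "count_articles_per_gene",
           "attention_quantile_flag", "write_profile"]


@dataclass(frozen=True)
class AttentionProfile:
    """Per-gene article counts and percentile ranks.

    ``counts``/``percentiles`` are indexed by every protein-coding registry
    gene (genes never mentioned have count 0). ``variant`` records which
    exclusions produced the profile.
    """

    counts: pd.Series
    percentiles: pd.Series
    variant: str
    excluded_pmids: frozenset[int] = field(default=frozenset())

    def count(self, gene: int) -> int:
        return int(self.counts.get(gene, 0))

    def percentile(self, gene: int) -> float:
        return float(self.percentiles.get(gene, np.nan))


def count_articles_per_gene(
    mentions: pd.DataFrame,
    articles: pd.DataFrame,
    registry: pd.DataFrame,
    exclude_pmids: Iterable[int] = (),
    cutoff_year: int | None = None,
    one_random_gene: bool = False,
    seed: int | np.random.Generator | None = None,
) -> AttentionProfile:
    """Count title/abstract mentions per gene under the stated exclusions.

    ``cutoff_year`` keeps only articles with year < cutoff (strict). Under
    ``one_random_gene`` each remaining article contributes exactly one
    uniformly chosen mentioned gene (seeded and reproducible).
    """
    excl = frozenset(int(p) for p in exclude_pmids)
    m = mentions[~mentions["pmid"].isin(excl)]
    if cutoff_year is not None:
        years = articles.loc[m["pmid"], "year"].to_numpy()
        m = m[years < cutoff_year]
        if m.empty:
            logger.warning("cutoff_year=%s precedes every article: all-zero "
                           "attention counts", cutoff_year)
    variant = "full"
    if cutoff_year is not None:
        variant = f"pre_cutoff({cutoff_year})"
    if one_random_gene:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        m = m.sort_values(["pmid", "entrez_id"])  # order-independent draws
        picks = []
        for pmid, grp in m.groupby("pmid", sort=True):
            genes = grp["entrez_id"].to_numpy()
            picks.append((pmid, int(genes[rng.integers(0, genes.size)])))
        m = pd.DataFrame(picks, columns=["pmid", "entrez_id"])
        variant += "+one_random_gene" if variant != "full" else ""
        if variant == "full":
            variant = "one_random_gene"

    pc_genes = registry.index[registry["is_protein_coding"]]
    raw = m.groupby("entrez_id").size()
    counts = raw.reindex(pc_genes, fill_value=0).astype(int)
    counts.index.name = "entrez_id"
    pct = percentile_rank(counts.to_dict(), pc_genes)
    percentiles = pd.Series(pct, name="percentile").reindex(pc_genes)
    percentiles.index.name = "entrez_id"
    return AttentionProfile(counts=counts, percentiles=percentiles,
                            variant=variant, excluded_pmids=excl)


def attention_quantile_flag(
    profile: AttentionProfile, genes: Iterable[int], top_fraction: float = 0.20
) -> float:
    """Fraction of ``genes`` in the top ``top_fraction`` of the attention
    distribution (percentile >= 100*(1 - top_fraction))."""
    gs = [g for g in genes]
    if not gs:
        raise ValueError("empty gene set: top-quantile fraction undefined")
    threshold = 100.0 * (1.0 - top_fraction)
    in_top = sum(1 for g in gs if profile.percentile(g) >= threshold)
    return in_top / len(gs)


def write_profile(profile: AttentionProfile, path) -> None:
    """Export counts as a two-column TSV (entrez_id, count) plus a JSON
    sidecar recording the variant and exclusions."""
    import json
    from pathlib import Path

    df = profile.counts.rename("count").reset_index()
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    meta = {"variant": profile.variant,
            "n_excluded_pmids": len(profile.excluded_pmids),
            "n_genes": int(profile.counts.size)}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")
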