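"""Where hit genes are lost between assay output and titles/abstracts.

For each assay, compares three gene sets on the attention scale: all
protein-coding registry genes, the unique hit genes of the assay's focus
studies, and the hit genes *highlighted* — i.e. carrying a resolved
title/abstract mention — in the reporting articles (and, independently, in
articles citing them). Unique hit genes are counted once across studies.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .attention import AttentionProfile, attention_quantile_flag
from .hits import FocusStudy
from .stats import TestResult, mann_whitney_u

logger = logging.getLogger(__name__)

__all__ = ["LeakageSummary", "highlighted_in_reporting", "highlighted_in_citing",
           "summarize_leakage", "format_percent", "write_summaries"]


@dataclass(frozen=True)
class LeakageSummary:
    assay: str
    n_focus_studies: int
    n_citing_articles: int
    n_unique_hits: int
    n_highlighted_reporting: int
    n_highlighted_citing: int
    pct_highlighted_reporting: float
    pct_highlighted_citing: float
    mwu_hits_vs_registry: TestResult | None
    mwu_highlighted_vs_hits: TestResult | None
    top20_fraction_hits: float
    top20_fraction_highlighted: float | None

    def to_dict(self) -> dict:
        d = {
            "assay": self.assay,
            "n_focus_studies": self.n_focus_studies,
            "n_citing_articles": self.n_citing_articles,
            "n_unique_hits": self.n_unique_hits,
            "n_highlighted_reporting": self.n_highlighted_reporting,
            "n_highlighted_citing": self.n_highlighted_citing,
            "pct_highlighted_reporting": format_percent(self.pct_highlighted_reporting),
            "pct_highlighted_citing": format_percent(self.pct_highlighted_citing),
        }
        if self.mwu_highlighted_vs_hits is not None:
            d["p_highlighted_vs_hits"] = self.mwu_highlighted_vs_hits.p_value
        if self.mwu_hits_vs_registry is not None:
            d["p_hits_vs_registry"] = self.mwu_hits_vs_registry.p_value
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _mention_genes_for(pmids: Iterable[int], mentions: pd.DataFrame) -> set[int]:
    pm = set(int(p) for p in pmids)
    sel = mentions[mentions["pmid"].isin(pm)]
    return set(int(g) for g in sel["entrez_id"])


def highlighted_in_reporting(study: FocusStudy, mentions: pd.DataFrame) -> set[int]:
    """Hit genes with a resolved mention in the study's own title/abstract."""
    return set(study.hits) & _mention_genes_for([study.pmid], mentions)


def highlighted_in_citing(study: FocusStudy, mentions: pd.DataFrame) -> set[int]:
    """Hit genes mentioned in any article citing the study, irrespective of
    whether the reporting article highlighted them."""
    if not study.citing_pmids:
        return set()
    return set(study.hits) & _mention_genes_for(study.citing_pmids, mentions)


def format_percent(pct: float) -> str:
    """Render a percentage at the reporting precision: two significant
    figures below 1%, three otherwise."""
    if pct == 0:
        return "0.0"
    sig = 2 if pct < 1.0 else 3
    exponent = math.floor(math.log10(abs(pct)))
    decimals = max(sig - 1 - exponent, 0)
    return f"{pct:.{decimals}f}"


def write_summaries(summaries: Iterable[LeakageSummary], path) -> None:
    """Write one TSV row per assay summary."""
    rows = [s.to_dict() for s in summaries]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def summarize_leakage(
    studies: Iterable[FocusStudy],
    mentions: pd.DataFrame,
    profile: AttentionProfile,
    top_fraction: float = 0.20,
) -> LeakageSummary:
    """Summarize one assay's studies: unique hits, highlighted fractions,
    and Mann-Whitney comparisons on the attention counts.

    Highlighted gene sets are deduplicated at the (study, gene) level
    before the union across studies, so a gene highlighted by several
    studies counts once.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("no admitted studies")
    assays = {s.assay for s in studies}
    if len(assays) != 1:
        raise ValueError(f"studies span multiple assays: {sorted(assays)}")
    assay = assays.pop()

    hits: set[int] = set()
    hl_rep: set[int] = set()
    hl_cit: set[int] = set()
    citing: set[int] = set()
    for s in studies:
        hits |= set(s.hits)
        hl_rep |= highlighted_in_reporting(s, mentions)
        hl_cit |= highlighted_in_citing(s, mentions)
        citing |= set(s.citing_pmids)
    if not hits:
        raise ValueError("zero unique hit genes")

    registry_counts = profile.counts.to_numpy(dtype=float)
    hit_counts = [float(profile.count(g)) for g in sorted(hits)]
    mwu_hits = mann_whitney_u(hit_counts, registry_counts)
    mwu_hl = (mann_whitney_u([float(profile.count(g)) for g in sorted(hl_rep)],
                             hit_counts)
              if hl_rep else None)

    return LeakageSummary(
        assay=assay,
        n_focus_studies=len(studies),
        n_citing_articles=len(citing),
        n_unique_hits=len(hits),
        n_highlighted_reporting=len(hl_rep),
        n_highlighted_citing=len(hl_cit),
        pct_highlighted_reporting=100.0 * len(hl_rep) / len(hits),
        pct_highlighted_citing=100.0 * len(hl_cit) / len(hits),
        mwu_hits_vs_registry=mwu_hits,
        mwu_highlighted_vs_hits=mwu_hl,
        top20_fraction_hits=attention_quantile_flag(profile, hits, top_fraction),
        top20_fraction_highlighted=(
            attention_quantile_flag(profile, hl_rep, top_fraction)
            if hl_rep else None
        ),
    )
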