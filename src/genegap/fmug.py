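"""Filter a user gene list by the factor table: "find my understudied genes".

Takes a hit list (symbols or Entrez IDs), resolves identifiers against the
registry, applies a conjunction of factor predicates plus optional
context-aware literature filters (e.g. genes studied in general but not
yet within a disease's MeSH-tagged literature), and reports before/after
attention feedback: the number of articles about the input genes and about
the genes that passed. All computation is local; nothing touches the
network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .attention import AttentionProfile

logger = logging.getLogger(__name__)

__all__ = ["Predicate", "ContextFilter", "FilterSpec", "FilterResult",
           "resolve_identifiers", "apply_filters", "context_attention",
           "export_result", "parse_predicate", "default_factor_panel"]

COMPARATORS = ("eq", "le", "ge", "is_true", "is_false", "is_na_ok")


@dataclass(frozen=True)
class Predicate:
    factor: str
    comparator: str
    threshold: float | None = None
    na_passes: bool = False

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.comparator in ("eq", "le", "ge") and self.threshold is None:
            raise ValueError(f"comparator {self.comparator!r} needs a threshold")

    def mask(self, values: pd.Series) -> pd.Series:
        v = values.astype(float)
        if self.comparator == "eq":
            out = v == self.threshold
        elif self.comparator == "le":
            out = v <= self.threshold
        elif self.comparator == "ge":
            out = v >= self.threshold
        elif self.comparator == "is_true":
            out = v > 0
        elif self.comparator == "is_false":
            out = v == 0
        else:  # is_na_ok: pass-through, NA explicitly allowed
            return pd.Series(True, index=values.index)
        if self.na_passes:
            out = out | v.isna()
        else:
            out = out & v.notna()
        return out


@dataclass(frozen=True)
class ContextFilter:
    """Keep genes with at most ``max_articles_in_context`` articles tagged
    with ``mesh_id`` while having at least ``min_articles_overall``."""

    mesh_id: str
    max_articles_in_context: int = 0
    min_articles_overall: int = 0


@dataclass(frozen=True)
class FilterSpec:
    predicates: tuple[Predicate, ...] = ()
    context_filters: tuple[ContextFilter, ...] = ()


@dataclass(frozen=True)
class FilterResult:
    input_genes: tuple[int, ...]
    passing_genes: tuple[int, ...]
    snapshot: pd.DataFrame  # per passing gene: factor values + n_articles
    n_articles_input: int
    n_articles_passing: int
    unmatched_identifiers: tuple[str, ...] = field(default=())


def default_factor_panel(factor_table: pd.DataFrame,
                         n_clusters: int = 8) -> list[str]:
    """One representative factor per correlation cluster.

    Clusters the factors (rank correlation, 1 - |rho| distance, average
    linkage) and picks from each cluster the factor with the highest mean
    |rho| to its cluster mates (the medoid; singleton clusters represent
    themselves). The full table stays available behind the extended option.
    """
    from .factors import cluster_factors
    _, order, labels = cluster_factors(factor_table,
                                       n_clusters=min(n_clusters,
                                                      len(factor_table.columns)))
    rho = factor_table[order].astype(float).corr(method="spearman",
                                                 min_periods=2).abs()
    panel: list[str] = []
    for k in sorted(set(labels)):
        members = [f for f, lab in zip(order, labels) if lab == k]
        if len(members) == 1:
            panel.append(members[0])
            continue
        mean_rho = rho.loc[members, members].mean(axis=1)
        panel.append(mean_rho.idxmax())
    return sorted(panel)


def parse_predicate(expr: str) -> Predicate:
    """Parse a textual predicate like ``"n_articles<=10"`` or
    ``"has_plasmid is_true"``."""
    for op, name in (("<=", "le"), (">=", "ge"), ("==", "eq"), ("=", "eq")):
        if op in expr:
            factor, thr = expr.split(op, 1)
            return Predicate(factor.strip(), name, float(thr))
    parts = expr.split()
    if len(parts) == 2 and parts[1] in COMPARATORS:
        return Predicate(parts[0], parts[1])
    raise ValueError(f"cannot parse predicate {expr!r}")


def resolve_identifiers(
    identifiers: Iterable[str], registry: pd.DataFrame
) -> tuple[list[int], list[str]]:
    """Resolve symbols/Entrez IDs to registry genes.

    Resolution order: exact Entrez ID, exact symbol, case-insensitive
    symbol. Ambiguous case-insensitive symbols and unknown identifiers go
    to the unmatched list (never silently dropped).
    """
    by_symbol: dict[str, list[int]] = {}
    by_casefold: dict[str, list[int]] = {}
    for g, sym in registry["symbol"].items():
        by_symbol.setdefault(sym, []).append(g)
        by_casefold.setdefault(sym.casefold(), []).append(g)
    resolved: list[int] = []
    unmatched: list[str] = []
    for ident in identifiers:
        ident = str(ident).strip()
        if not ident:
            continue
        if ident.isdigit() and int(ident) in registry.index:
            resolved.append(int(ident))
            continue
        cands = by_symbol.get(ident) or by_casefold.get(ident.casefold()) or []
        if len(cands) == 1:
            resolved.append(cands[0])
        else:
            if len(cands) > 1:
                logger.warning("identifier %r matches %d genes; rejected",
                               ident, len(cands))
            unmatched.append(ident)
    return resolved, unmatched


def context_attention(
    gene: int, mesh_id: str, mentions: pd.DataFrame, articles: pd.DataFrame
) -> int:
    """Primary research articles tagged with ``mesh_id`` mentioning ``gene``."""
    tagged = articles.index[
        articles["is_primary_research"].to_numpy()
        & np.array([mesh_id in ts for ts in articles["mesh_terms"]])
    ]
    if len(tagged) == 0:
        logger.warning("MeSH id %r tags no article", mesh_id)
        return 0
    sel = mentions[(mentions["entrez_id"] == gene) & mentions["pmid"].isin(tagged)]
    return int(sel["pmid"].nunique())


def apply_filters(
    gene_list: Sequence[str],
    factor_table: pd.DataFrame,
    profile: AttentionProfile,
    spec: FilterSpec,
    registry: pd.DataFrame,
    mentions: pd.DataFrame | None = None,
    articles: pd.DataFrame | None = None,
) -> FilterResult:
    """Apply the conjunction of ``spec``'s predicates to a user gene list.

    Unknown factor names raise before any filtering. Context filters
    require ``mentions`` and ``articles``.
    """
    for pred in spec.predicates:
        if pred.factor not in factor_table.columns and pred.factor != "n_articles":
            raise ValueError(f"unknown factor {pred.factor!r}")
    if spec.context_filters and (mentions is None or articles is None):
        raise ValueError("context filters need mentions and articles")

    genes, unmatched = resolve_identifiers(gene_list, registry)
    genes = sorted(dict.fromkeys(genes))
    if not genes:
        logger.warning("no input gene resolved against the registry")

    table = factor_table.reindex(genes)
    if "n_articles" not in table.columns:
        table = table.assign(n_articles=[profile.count(g) for g in genes])
    mask = pd.Series(True, index=table.index)
    for pred in spec.predicates:
        mask &= pred.mask(table[pred.factor])
    for ctx in spec.context_filters:
        ctx_counts = pd.Series(
            [context_attention(g, ctx.mesh_id, mentions, articles) for g in genes],
            index=table.index)
        overall = pd.Series([profile.count(g) for g in genes], index=table.index)
        mask &= (ctx_counts <= ctx.max_articles_in_context)
        mask &= (overall >= ctx.min_articles_overall)

    passing = [int(g) for g in table.index[mask]]
    return FilterResult(
        input_genes=tuple(genes),
        passing_genes=tuple(passing),
        snapshot=table.loc[passing].copy(),
        n_articles_input=int(sum(profile.count(g) for g in genes)),
        n_articles_passing=int(sum(profile.count(g) for g in passing)),
        unmatched_identifiers=tuple(unmatched),
    )


def export_result(result: FilterResult, path: PathLike | str,
                  fmt: str = "tsv") -> None:
    """Write the passing genes + factor snapshot; byte-stable output."""
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    df = result.snapshot.copy()
    df.insert(0, "entrez_id", result.passing_genes)
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")
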