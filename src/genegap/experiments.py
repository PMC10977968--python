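"""Replicated end-to-end experiments on synthetic corpora.

These drive the whole pipeline — corpus generation, mention resolution, hit
extraction, attention profiling, screens — across seeded replicates, and
summarize calibration (type-I error, interval coverage under the null) and
recovery (does the pipeline detect the effects the generator injected).
They back both the acceptance checks and the reproduction script.

Replicate seeds are spawned from one master seed via ``SeedSequence`` and
kept below 2**31.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attention import count_articles_per_gene
from .citations import popularity_citation_correlation, select_single_gene_articles
from .factors import (apply_screen_fdr, associated_factors,
                      highlighting_by_assay, screen_factors)
from .hits import FocusStudy
from .leakage import LeakageSummary, summarize_leakage
from .simulate import (SyntheticConfig, generate_corpus, null_config,
                       recovery_factor_panel)
from .stats import mann_whitney_u

logger = logging.getLogger(__name__)

__all__ = ["spawn_seeds", "leakage_from_counts", "null_calibration",
           "effect_recovery", "citation_direction_recovery"]

# readout year for the popularity-vs-citations analyses (articles published
# in this year against each gene's article count before it)
CITATION_READOUT_YEAR = 2015


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """``n`` independent per-replicate seeds derived from ``master_seed``."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def leakage_from_counts(assay: str, n_hits: int, n_highlighted_reporting: int,
                        n_highlighted_citing: int) -> LeakageSummary:
    """Leakage summary for one assay reconstructed from per-assay counts.

    Builds the smallest corpus realizing the counts — one focus study whose
    hit genes are 1..n_hits, with the first ``n_highlighted_reporting``
    mentioned in the reporting article and the first
    ``n_highlighted_citing`` in a citing article — and summarizes it with
    the ordinary pipeline. Useful to turn published per-assay counts into
    the percentages a report prints.
    """
    genes = np.arange(1, n_hits + 1)
    focus_pmid, citing_pmid = 10, 11
    mentions = pd.DataFrame({
        "pmid": np.concatenate([
            np.full(n_highlighted_reporting, focus_pmid),
            np.full(n_highlighted_citing, citing_pmid)]),
        "entrez_id": np.concatenate([
            genes[:n_highlighted_reporting], genes[:n_highlighted_citing]]),
    })
    study = FocusStudy(pmid=focus_pmid, assay=assay,
                       hits=frozenset(int(g) for g in genes),
                       citing_pmids=frozenset({citing_pmid}))
    registry = pd.DataFrame({
        "ensembl_id": "", "symbol": "", "symbol_defined": True,
        "is_protein_coding": True, "n_synonyms": 0,
    }, index=pd.Index(genes, name="entrez_id"))
    articles = pd.DataFrame({
        "year": 2020, "is_primary_research": True, "citations_total": 0,
        "mesh_terms": [frozenset()] * 2,
    }, index=pd.Index([focus_pmid, citing_pmid], name="pmid"))
    profile = count_articles_per_gene(mentions, articles, registry,
                                      exclude_pmids={focus_pmid})
    return summarize_leakage([study], mentions, profile)


def _pipeline(corpus):
    reg = corpus.registry()
    art = corpus.articles()
    m = corpus.mentions(reg, art)
    studies = corpus.studies(reg, m)
    return reg, art, m, studies


@dataclass(frozen=True)
class NullCalibration:
    n_replicates: int
    n_genes: int
    binary_type1_rate: float
    continuous_type1_rate: float
    or_ci_coverage: float
    bootstrap_spearman_coverage: float


def null_calibration(n_replicates: int = 200, n_genes: int = 2000,
                     master_seed: int = 0) -> NullCalibration:
    """Calibration under the fully null generator (no highlighting bias, no
    factor effects, no citation-popularity dependence).

    Pools the per-(factor, assay) screen tests across replicates for the
    empirical type-I rate at alpha = 0.05 and the Woolf OR CI coverage of
    1; one bootstrap Spearman CI per replicate scores coverage of rho = 0.
    """
    bin_rej = bin_n = cont_rej = cont_n = 0
    or_cover = or_n = 0
    boot_cover = 0
    for seed in spawn_seeds(master_seed, n_replicates):
        cfg = null_config(seed, n_genes=n_genes, derivation_sources=False)
        corpus = generate_corpus(cfg)
        reg, art, m, studies = _pipeline(corpus)
        screen = apply_screen_fdr(screen_factors(studies, m,
                                                 corpus.factor_table()))
        b = screen[screen["kind"] == "binary"]
        c = screen[screen["kind"] == "continuous"]
        bin_rej += int((b["p"] < 0.05).sum())
        bin_n += int(b["p"].notna().sum())
        cont_rej += int((c["p"] < 0.05).sum())
        cont_n += int(c["p"].notna().sum())
        defined = b[np.isfinite(b["ci_low"]) & np.isfinite(b["ci_high"])]
        or_cover += int(((defined["ci_low"] <= 1.0)
                         & (1.0 <= defined["ci_high"])).sum())
        or_n += len(defined)
        sga = select_single_gene_articles(m, art)
        res = popularity_citation_correlation(sga, CITATION_READOUT_YEAR,
                                              n_boot=1000, seed=seed)
        boot_cover += int(res.ci_low <= 0.0 <= res.ci_high)
    return NullCalibration(
        n_replicates=n_replicates, n_genes=n_genes,
        binary_type1_rate=bin_rej / bin_n,
        continuous_type1_rate=cont_rej / cont_n,
        or_ci_coverage=or_cover / or_n,
        bootstrap_spearman_coverage=boot_cover / n_replicates,
    )


@dataclass(frozen=True)
class EffectRecovery:
    n_replicates: int
    n_genes: int
    mwu_highlight_rate: float       # replicates with highlighted > hits, p<0.01
    exact_factor_recovery_rate: float  # FDR<0.001 set == injected set
    any_false_positive_rate: float
    injected_factors: tuple[str, ...]


def effect_recovery(n_replicates: int = 100, n_genes: int = 2000,
                    master_seed: int = 0) -> EffectRecovery:
    """Recovery under the biased generator: highlighting log-odds slope 1.0
    and three injected factors (odds ratio 4 / F 0.75) among twenty nulls.

    Per replicate: (a) the leakage stage's Mann-Whitney comparison of
    attention for highlighted versus all hit genes, on the unique gene sets
    pooled over the four assays; (b) whether the factor screen flags
    exactly the injected factors at FDR < 0.001 (significant in >= 1 assay).
    """
    panel = recovery_factor_panel()
    injected = {f.name for f in panel if f.effect is not None}
    mwu_ok = exact = fp_any = 0
    for seed in spawn_seeds(master_seed, n_replicates):
        cfg = SyntheticConfig(seed=seed, n_genes=n_genes, beta_highlight=1.0,
                              factors=panel, derivation_sources=False)
        corpus = generate_corpus(cfg)
        reg, art, m, studies = _pipeline(corpus)
        profile = corpus.attention_profile(registry=reg, mentions=m,
                                           articles=art)
        hits: set[int] = set()
        hl: set[int] = set()
        for h, l in highlighting_by_assay(studies, m).values():
            hits |= h
            hl |= l
        res = mann_whitney_u([float(profile.count(g)) for g in sorted(hl)],
                             [float(profile.count(g)) for g in sorted(hits)])
        median_hl = np.median([profile.percentile(g) for g in hl])
        median_hits = np.median([profile.percentile(g) for g in hits])
        mwu_ok += int(res.p_value < 0.01 and median_hl > median_hits)
        screen = apply_screen_fdr(screen_factors(studies, m,
                                                 corpus.factor_table()))
        flagged = set(associated_factors(screen, q_threshold=0.001))
        exact += int(flagged == injected)
        fp_any += int(bool(flagged - injected))
    return EffectRecovery(
        n_replicates=n_replicates, n_genes=n_genes,
        mwu_highlight_rate=mwu_ok / n_replicates,
        exact_factor_recovery_rate=exact / n_replicates,
        any_false_positive_rate=fp_any / n_replicates,
        injected_factors=tuple(sorted(injected)),
    )


@dataclass(frozen=True)
class CitationRecovery:
    n_replicates: int
    n_genes: int
    gamma_cite: float
    negative_rho_rate: float  # rho < 0 with bootstrap CI excluding 0
    mean_rho: float


def citation_direction_recovery(n_replicates: int = 50, n_genes: int = 8000,
                                master_seed: int = 0,
                                gamma_cite: float = -0.5) -> CitationRecovery:
    """Direction recovery for the citation analysis: with a negative
    popularity coefficient on citations, the per-gene Spearman correlation
    of prior popularity versus median citations should come out negative
    with a bootstrap CI excluding zero."""
    ok = 0
    rhos = []
    for seed in spawn_seeds(master_seed, n_replicates):
        cfg = SyntheticConfig(seed=seed, n_genes=n_genes,
                              gamma_cite=gamma_cite,
                              derivation_sources=False)
        corpus = generate_corpus(cfg)
        reg = corpus.registry()
        art = corpus.articles()
        m = corpus.mentions(reg, art)
        sga = select_single_gene_articles(m, art)
        res = popularity_citation_correlation(sga, CITATION_READOUT_YEAR,
                                              n_boot=1000, seed=seed)
        rhos.append(res.effect)
        ok += int(res.effect < 0.0 and res.ci_high < 0.0)
    return CitationRecovery(
        n_replicates=n_replicates, n_genes=n_genes, gamma_cite=gamma_cite,
        negative_rho_rate=ok / n_replicates, mean_rho=float(np.mean(rhos)),
    )
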