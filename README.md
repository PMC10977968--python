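# genegap

Understudied human genes are routinely *hits* in genome-wide assays —
CRISPR knockout screens, transcriptomics, AP-MS interactomics, GWAS — yet
rarely make it into the title or abstract of the article reporting the
experiment, or of the articles citing it. `genegap` is a bibliometric
pipeline for quantifying that leak and probing what drives it, aimed at
meta-researchers and at scientists who want to surface understudied genes
from their own hit lists.

## What it computes

**Attention.** A gene's attention is the number of primary research
articles mentioning it in the title/abstract, where a mention counts only
if both a gene2pubmed-style link and a PubTator-style title/abstract
annotation agree. Percentile ranks over protein-coding genes use mid-ranks,
100·(rank − ½)/n.

**Leakage.** Per assay, the pipeline extracts each focus study's hit genes
from repository-style evidence (CRISPR hit flags; differential expression
at Benjamini–Hochberg q < 0.05 per comparison; high-throughput Affinity
Capture-MS preys; SNPs falling inside gene spans, 1-based half-open), then
compares three gene sets on the attention scale: all protein-coding genes,
unique hits, and hits *highlighted* in reporting (or citing) titles/
abstracts, with two-sided Mann–Whitney U tests.

**Citation impact.** For articles with exactly one resolved gene, the
Spearman correlation ρ between a gene's prior article count and the median
citations of its articles in a readout year, with a seeded percentile
bootstrap CI (n = 1000), optionally per MeSH term with BH correction
across terms.

**Factor screen.** A genes × factors table (plasmid/compound/antibody/
patent availability, pLI > 0.9, primate specificity, GRAVY, gene length,
nTPM summaries, model-organism literature, …) is screened against
highlighting per assay: binary factors with the odds ratio
OR = ad/bc, Woolf CI and two-sided Fisher exact test; continuous factors
with the common-language effect size F = U/(n₁n₂) (AUROC) and
Mann–Whitney U; BH-corrected per panel. Hierarchical clustering
(1 − |ρ| distance, average linkage) summarizes factor redundancy.

**FMUG-style filtering.** `genegap filter` takes a gene list, applies
factor predicates and context-aware literature filters (e.g. "studied in
general but absent from the literature of MeSH term D000544"), and reports
article counts before and after. Everything runs locally.

**Synthetic corpora.** Because the original resource snapshots are not
redistributable, `genegap simulate` generates complete corpora in every
reader dialect with known ground truth: log-normal attention, highlighting
probability logistic in log₁₀(attention + 1), negative-binomial citations
with a popularity coefficient, and factors with configured OR/F effects.

## Worked example

```python
from genegap.simulate import SyntheticConfig, generate_corpus
from genegap.leakage import summarize_leakage

c = generate_corpus(SyntheticConfig(seed=1, n_genes=2000))
reg, art = c.registry(), c.articles()
m = c.mentions(reg, art)
studies = c.studies(reg, m)
prof = c.attention_profile(registry=reg, mentions=m, articles=art)
s = summarize_leakage([x for x in studies if x.assay == "CRISPR"], m, prof)
print(s.to_json())
```

prints

```json
{
  "assay": "CRISPR",
  "n_focus_studies": 3,
  "n_citing_articles": 15,
  "n_unique_hits": 465,
  "n_highlighted_reporting": 119,
  "n_highlighted_citing": 41,
  "pct_highlighted_reporting": "25.6",
  "pct_highlighted_citing": "8.82",
  "p_highlighted_vs_hits": 0.001212193536907844,
  "p_hits_vs_registry": 0.5264815220062806
}
```

Read: of 465 unique CRISPR hit genes, 25.6% were highlighted in a
reporting title/abstract and 8.82% in a citing one. The hits themselves
are indistinguishable from the registry on attention (p = 0.53), but the
highlighted subset is significantly better studied than the hits
(p = 0.0012) — the generator's default highlighting bias (log-odds slope
1.0 per decade of attention) recovered by the leakage stage: 19.8% of hits
but 32.8% of highlighted genes sit in the top-20% attention quantile.

## Command line

```sh
genegap simulate --config cfg.yaml --out corpus/ --seed 9
genegap filter --genes hits.txt --factors factor_table.tsv \
    --attention attention.tsv --registry registry.tsv \
    --where "n_articles<=10" --where "has_plasmid is_true" --out passing.tsv
```

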