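# Methods

## The measurement model

The pipeline treats "a gene is mentioned in the title/abstract of a
primary research article" as the unit of scholarly attention. A mention is
*resolved* only when two independent annotation sources agree — a
gene2pubmed-style article–gene link and a PubTator-style title/abstract
annotation — and the article is a primary research article. Reviews remain
in the article table (they can cite and be counted) but never contribute
mentions. Restricting to the double-annotated intersection trades recall
for precision; it is the right trade for counting, where false mentions
inflate attention for popular genes.

The gene universe is a registry admitting only genes with a one-to-one
Entrez↔Ensembl mapping; hit extraction and percentile ranks are further
restricted to protein-coding genes. Percentiles are mid-rank based,
100·(rank − ½)/n, so a fully tied distribution sits at 50 and the
estimator is invariant under strictly monotone transforms of the counts.

## Hit extraction rules

* **CRISPR**: genome-wide human knockout screens with a PMID; a study's
  hits are the union of flagged genes over its qualifying screens.
* **Transcriptomics**: within each comparison, differential expression is
  called at Benjamini–Hochberg q < 0.05; raw p-values are adjusted here,
  pre-adjusted q-values are honoured as-is. The threshold is a parameter
  (for sensitivity sweeps).
* **AP-MS**: prey genes of interactions with evidence code
  "Affinity Capture-MS" labelled high-throughput.
* **GWAS**: SNPs inside a gene span. Containment uses 1-based half-open
  intervals [start, end): a SNP at `start` is inside, at `end` is not.
  Whether "within a gene" should include flanking regulatory sequence is
  undecidable from the rule's plain wording; the half-open genomic span is
  the convention used throughout and is documented in the reader.

A focus study is admitted when at least one of its hit genes has a
resolved mention somewhere in the corpus (configurable off). Attention
profiles exclude the focus studies' own PMIDs so an experiment cannot
contribute to the attention it is compared against; excluding citing PMIDs
as well is available and used where ground-truth background counts are
needed exactly.

## Statistical conventions

* **Mann–Whitney U** (two-sided): mid-rank ties; exact enumeration for
  tie-free samples with n₁·n₂ ≤ 400, otherwise the normal approximation
  with tie and continuity corrections. U is reported for the first group.
* **Common-language effect size** F = (wins + ½·ties)/(n₁n₂) = U/(n₁n₂),
  identical to the AUROC of one group against the other.
* **Odds ratio**: OR = ad/bc on the {factor true/false} × {highlighted or
  not} table over unique hit genes; 95% CI by the Woolf log method; any
  zero cell triggers the Haldane–Anscombe +0.5 correction of all cells
  (flagged); an empty row or column leaves the effect undefined rather
  than infinite.
* **Fisher exact** (two-sided): probability-mass ordering — the p-value
  sums hypergeometric masses of all tables with fixed margins no more
  probable than the observed one (the convention of mainstream libraries).
* **Benjamini–Hochberg**: step-up adjusted p-values; rejection at
  q ≤ q\*. For the factor screen, pooling is per panel (binary /
  continuous) across assays, because a single star scheme annotates each
  panel; per-assay pooling is available via `scope="per_assay"`.
* **Spearman ρ**: mid-rank Pearson with the two-sided t-approximation
  p = 2·SF(|ρ|·√((n−2)/(1−ρ²))). The source analysis cites an external
  description without formulas; the t-approximation is the default of the
  scientific Python stack and accurate for the n used here (≥ 50).
* **Bootstrap CI for ρ**: percentile 2.5/97.5 over n_boot = 1000 pair
  resamples, fully determined by the seed. Degenerate resamples (a
  constant margin) are redrawn and counted; persistently constant data
  raise instead of returning a vacuous interval.

## Citation analysis

The unit is the gene: x = number of its single-gene articles strictly
before the readout year, y = median citations of its single-gene articles
published in that year. Only articles with exactly one distinct resolved
gene enter, so popularity and citations attach unambiguously. The default
readout year is 2015 throughout (late enough for citations to accrue in
the emulated corpora, mirroring the usual design). MeSH-stratified screens
recompute both axes within the term's tagged articles and require a
minimum of 20 gene points per term (the inclusion floor is not published;
20 keeps ρ estimates out of the small-sample regime). The top-cited ratio
uses gene-popularity quantile bins (default deciles) and defines most/
lowly cited as the top/bottom decile of citations within the year; both
choices are parameters recorded in the output metadata, since the original
binning is not published.

## Factor table

Derivation rules follow the catalogued sources: membership flags from
plasmid/compound/patent/druggability/Mendelian/IDG lists; antibody,
membrane-protein and protein-evidence flags from the protein-atlas-style
table; pLI with the >0.9 intolerance flag; median nTPM and fraction of
tissues at ≥1 nTPM; GRAVY as mean Kyte–Doolittle hydropathy ignoring
selenocysteine and pyrrolysine (NaN when nothing scoreable remains);
gene length as the chromosomal extent of a gene's transcripts,
max(end) − min(start) over half-open spans; GWAS locus counts by
nearest-gene mapping; per-organism homolog flags; model-organism
publication counts resolving to 0 for genes with a homolog but no
articles and NA for genes without a homolog; primate specificity when all
non-human members of the homology group are primates (NA when the gene has
no homology group at all — absence of evidence is not treated as
specificity). A missing source emits its factors as all-NA with a warning
rather than failing the table. Genes with NA factor values are dropped per
test, never imputed; the per-test group sizes are reported.

Factor clustering codes binary factors 0/1, computes pairwise-complete
Spearman correlations, and clusters on 1 − |ρ| with average linkage —
sign-blind because a factor and its complement carry the same information.
Factors with fewer than two distinct values are excluded (logged).

## Synthetic corpus generator

The generator emulates the study conditions end to end and is itself
tested code. Defaults (all overridable in `SyntheticConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | registry size |
| `frac_protein_coding` | 0.55 | ≈ protein-coding share of an Entrez↔Ensembl-resolved registry |
| `attention_lognormal` | (1.0, 1.5) | log-normal (μ, σ) of per-gene article counts — heavy right tail, median ≈ 3, long tail past 100 |
| `multi_gene_article_fraction` | 0.30 | share of gene-focused articles with two genes (≈ the published 30.4% multi-gene share) |
| `n_focus_per_assay` | 3 | focus studies per assay |
| `hits_per_study` | (100, 300) | uniform hit-list size |
| `base_highlight_rate` | 0.15 | highlight probability at zero attention |
| `beta_highlight` | 1.0 | highlighting log-odds per decade of attention; 0 = unbiased null |
| `n_citing_per_focus`, `citing_base_rate` | 5, 0.01 | citing articles and their per-hit mention base rate (same logistic form) |
| `citation_negbin` | (10, 1) | negative-binomial mean and dispersion of citations |
| `gamma_cite` | −0.5 | citation log-mean shift per decade of gene popularity (negative: understudied-gene articles accrue more citations) |
| `factors` | 3 effects among 20 nulls | injected OR = 4 (binary) and F = 0.75 (continuous) |

Binary factors with a target odds ratio are generated conditional on the
realized highlighting labels by solving the prevalence among positives
from the base prevalence (0.30); continuous factors with target F shift a
unit normal by √2·Φ⁻¹(F). Unreachable effects (OR ≤ 0, F ∉ (0,1)) raise,
naming the factor. Identical seeds give byte-identical output files.

What the generator does *not* emulate: article text, co-citation
structure, temporal drift of attention, correlated factor blocks (unless
configured), between-assay correlation of hit propensity, and annotation
errors. Passing tests therefore certify the pipeline's logic and
calibration, not the published corpus-specific magnitudes, which depend on
versioned external database snapshots.

## Problem sizes and replication design

Replicated experiments (`genegap.experiments`) spawn per-replicate seeds
from one master seed via `SeedSequence`. Null calibration uses 200
replicates at 2000 genes; effect recovery 100 replicates at 2000 genes;
the citation-direction experiment 50 replicates at 8000 genes — the
per-gene citation readout keeps only one year's single-gene articles, so
this analysis gets the larger registry (~800 gene points per replicate) to
make a single replicate's bootstrap CI informative at the configured
effect (mean ρ ≈ −0.18). The replicate-level highlighted-vs-hits check
pools the four assays' unique hit and highlighted sets, matching the
replication-level claim (highlighted genes are better studied than hits)
rather than any single assay's power at this scaled-down study count.

## Known limitations

* Dialect readers cover the documented column subsets, not every field of
  the real downloads; dialects are remappable per source.
* The screens treat genes as independent; co-membership of hits in the
  same study induces dependence that the BH correction does not model
  (the null calibration shows the realized type-I rates stay nominal).
* Identifier resolution in the filter handles Entrez IDs and symbols
  (exact, then case-insensitive); aliases/synonym lookup is not attempted,
  ambiguous symbols are rejected, and unmatched identifiers are reported
  rather than dropped.
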