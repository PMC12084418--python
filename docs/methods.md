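# Methods

This note records the statistical conventions, default parameters and
design choices behind `carekit`, and what the synthetic-data experiments
do and do not demonstrate.

## Outlier model

For one gene and one comparator cohort, the overexpression threshold is
Tukey's upper fence, `Q75 + 1.5·(Q75 − Q25)`, of the cohort's log2(TPM+1)
values. Conventions pinned throughout (they change calls at boundaries):

- Quartiles use linear interpolation between order statistics
  (`numpy.quantile`'s default). The same convention is used in every test
  oracle.
- The comparison is strict: the focus value must *exceed* the fence.
- An absolute expression floor (default 1.0 log2(TPM+1) ≈ 1 TPM,
  configurable, 0 disables) suppresses calls on genes whose focus
  expression is too low to be clinically reportable regardless of
  statistical extremity.
- Only overexpression is called; an under-expression mirror is out of
  scope by design.

Tukey fences behave characteristically on zero-inflated data: once ≥ 25%
of a cohort's values for a gene are exact zeros, `Q25 = 0` and the fence
becomes `2.5·Q75`, which for well-expressed genes can exceed the focus
value even under a large planted shift. This is not treated as a defect —
it is what the rule computes — but it is why recovery is evaluated on the
union of the pan-cancer and pan-disease outlier lists (both appear in
every report): a gene missed by one arm on a zero-heavy cohort is caught
by the other.

## Gene filters (pan-cancer universe)

1. **Expression filter**: a gene is dropped when its fraction of exact
   zeros across the comparator compendium is ≥ 0.80. The boundary is
   inclusive (a gene zero in exactly 80% of samples is dropped).
2. **Variance filter**: the survivors are sorted by population variance
   (ddof = 0) ascending and exactly `floor(0.20 · n_survivors)` are
   dropped, regardless of absolute variance. Ties are broken by gene
   symbol so the cut is deterministic; with the tie-break, the kept set
   does not depend on the variance denominator for untied data.

The pan-disease analysis uses the full, unfiltered gene list. Filters are
computed on the compendium *excluding* the focus sample, so the gene
universe is a property of the comparator set, not of the patient.

## Molecular similarity

Spearman ρ is the Pearson correlation of mid-ranks (average ranks over
ties). A vector with zero rank variance is "not comparable" (NaN
sentinel) and its pairs are excluded from the percentile pool. The
neighbor threshold is the 95th percentile — linear-interpolation
convention — of all n(n−1)/2 within-compendium pairwise ρ; the focus
sample does not enter the pool, and "above the percentile" is a strict
`>`. Correlations are computed on the pan-cancer filtered gene universe
(configurable). For large compendia the O(n²) pool can be replaced by a
seeded uniform subsample (`max_pairs`); exact mode is the default and the
subsampled threshold converges to it as the subsample grows.

Because the threshold is the top 5% of *all* pairs, a typical member of a
typical disease cluster exceeds it only for the tightest slice of its own
cluster: small or empty first-degree sets are expected behavior, not a
bug, and mirror what happens to genuinely rare diseases in real compendia.

## Cohorts and aggregation

The four personalized cohorts are built exactly as named: same diagnosis;
first-degree neighbors; first- plus second-degree neighbors (samples
above-threshold-correlated with a first-degree neighbor but not with the
focus); and all samples of the diseases appearing among the top-6 most
correlated samples (ties at the 6th position break by sample id). A
cohort is usable when it has ≥ `min_cohort_size` members (default 20 —
quartiles of tiny cohorts are unstable). When fewer than two *distinct*
usable cohorts exist (distinct = differing by at least one member), a
single merged cohort equal to the deduplicated union of the four is used
and the ≥2-of-4 rule degrades to `min(2, n_usable)` = 1-of-1. The merged
fallback, like every other degradation (subsampled percentile pool,
skipped QC), is recorded in the report's provenance block; nothing
degrades silently.

A neighbor-label concordance flagger stands in for the manual review of
the most-similar-samples table used to catch batch effects and
mislabelled samples: each sample's fraction of same-disease labels among
its k nearest neighbors (default k = 5) is computed, and samples below a
configurable fraction (default 0.5) are flagged for review — never
excluded automatically. Samples whose disease has fewer than k other
members are exempt, since their neighborhood cannot be label-concordant
even in a perfect embedding.

## Enrichment and druggability

Gene-set over-representation uses the hypergeometric upper tail
`P[X ≥ x]` with universe M, in-universe set size m, query size N and
overlap x, followed by Benjamini–Hochberg across all sets of a
collection (α = 0.05, configurable). The universe is the gene space the
query was drawn from — the filtered pan-cancer universe for pan-cancer
outliers, the full list for pan-disease — so the test's null matches the
sampling space of the outliers. Genes in sets but outside the universe
are ignored for set size (the standard overlap convention).

Drug annotation is a case-insensitive join against a snapshot interaction
table filtered at read time to four curated cancer sources; genes without
interactions receive explicit empty annotations. Analytical-strength
labels on actionable findings are free text supplied in configuration and
echoed verbatim — they are never computed.

## MEND quality gate

Reads are classified by three booleans (mapped, exonic, duplicate;
exonic ⇒ mapped is enforced) and MEND = mapped ∧ exonic ∧ ¬duplicate.
The gate passes at ≥ 10 million MEND reads by default (the cited QC
framework's convention; configurable). The module deliberately operates
on abstract flag records or a flags TSV, not on alignments: the QC
concept is fully exercised by the boolean classification, and a BAM
adapter is an extension point.

## Synthetic compendium generator

Values are drawn directly on the log2(TPM+1) scale:
`x = max(0, base_g + effect_{d,g} + ε)`, then set to 0 with probability
`zero_inflation`, with `base_g ~ N(baseline_mean, baseline_sd)` per gene,
`effect_{d,g} ~ N(0, disease_effect_sd)` per disease × gene, and
`ε ~ N(0, noise_sd)` per value. Defaults: 5 diseases × 30 samples, 2,000
genes, baseline 3.0 ± 1.5, effect sd 1.0, noise sd 0.5, zero inflation
0.2, 40 planted genes shifted by +6 log2 units. A Gaussian-in-log model
was chosen over a count model because the pipeline consumes log2(TPM+1)
directly and never touches counts; this is the minimal structure that
exercises the filters (zeros), similarity (disease clusters) and outlier
calling (the planted shift).

Generator choices worth knowing:

- The focus sample is excluded from the compendium; prior samples of the
  same patient can be injected (`n_prior_focus_samples`) to reproduce the
  rare-disease topology in which the only same-diagnosis samples are the
  patient's own earlier tumors.
- Planted outlier genes receive the delta *after* the zero-inflation draw
  and are themselves exempt from zero inflation in the focus sample: a
  planted outlier is overexpressed by construction, otherwise dropout
  alone would erase a fixed fraction of plantings regardless of pipeline
  quality.
- Clipping at 0 preserves non-negativity and adds a small one-sided
  excess of zeros for low-baseline genes; the generator's zero-fraction
  test bounds accommodate it.

What the generator does **not** emulate: library-size or GC biases, batch
effects beyond the disease term (a batch term is an extension point),
gene–gene correlation structure within a disease, and the heavy-tailed,
bimodal zero patterns of real bulk compendia (zeros here are uniform
dropout). Passing the recovery experiments therefore demonstrates the
machinery is correct under the stated model, not that real-data recall
would match.

## Problem sizes and determinism

The test suite and the acceptance script run on compendia of 100–2,000
genes and 30–163 samples, with 10 generator seeds for the recovery study
and 5 for the null study — sizes at which every brute-force oracle
(full sorts, pair scans, combinatorial sums) is exact and fast. Every
random draw flows from an explicit seed; a run is byte-identical given
the same inputs, configuration and seed, and the report's provenance
carries the seed, a configuration digest and input digests.

## Known limitations

- Symbol-based gene identity (upper-cased); no Ensembl/HGNC mapping.
- Dense matrices only; missing values are rejected rather than imputed.
- The ≥ 80% zero filter and 20% variance cut are the pinned defaults of
  the procedure; both are configurable but have no data-driven tuning.
- Under-expression outliers, fusion/mutation calling and rank-based
  (GSEA-style) enrichment are out of scope.
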