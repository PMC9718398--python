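# Methods

## Scope and data model

The pipeline consumes five kinds of input, all plain text: post-search BioID
prey tables (one row per bait × condition × prey, carrying the average
spectral count across biological replicates, the unique-peptide count, the
iProphet protein probability and the prey protein length), gene-level CRISPR
NormZ tables and guide-level D0/D14 count tables, GMT gene-set collections,
known-interaction edge tables (two-column or BioGRID-TAB3-style), and
survival cohorts (time, event, per-gene expression). All gene symbols are
mapped into one namespace at read time: upper-cased, whitespace-stripped,
with an optional isoform-suffix delimiter; joins across tables rely on this.

Raw spectra and sequencing reads are out of scope: the prey tables are taken
after search-engine/TPP processing, and guide counts after read alignment
and quantification.

## Confidence and contaminant filtering

A prey record is kept iff `iprophet_prob >= 0.9` and `unique_peptides >= 1`
(both thresholds inclusive, as literal readings of the stated criteria) and
the prey is not a contaminant. The unique-peptide count is interpreted as
pooled across the two biological replicates; a stricter per-replicate
reading can be emulated by supplying per-replicate tables. The default
contaminant list contains the promiscuous binders AHNAK, PRKDC, TOP1, HLCS,
FLNB, PRKAA1, PRKAA2; the biotin-dependent carboxylases PC, PCCA, PCCB,
MCCC1, MCCC2, ACACA, ACACB (endogenously biotinylated, hence enriched by
streptavidin regardless of bait); lysozyme; and the prefix classes `KRT*`,
`RPL*`, `RPS*`. No complete machine-readable list accompanies the original
criteria, so this explicit list is the package's own reproducible choice and
can be replaced from a file (one symbol per line, trailing `*` marks a
prefix). The filter emits a per-rule removal report; a record violating
several rules increments each matching counter.

## Complex-level set algebra

Complex interactomes are intersection specifications: a prey belongs to the
result iff it appears in every `include` bait and no `exclude` bait. The
shipped defaults read "exclusive" literally — BCDX2 = include
{RAD51B, RAD51C, RAD51D, XRCC2}, exclude {XRCC3}; CX3 = include
{RAD51C, XRCC3}, exclude the other three; all-common = include all five,
exclude none — and operate on the untreated condition by default. Both the
bait sets and the condition are parameters, so the non-exclusive reading is
one flag away. Upset decomposition assigns every prey to the exact signature
of baits that detected it; the cells partition the prey union by
construction.

## Abundance and differential scoring

SAF = AvgSpec / protein length (aa) corrects spectral counts for protein
size. Matrix exports use log2(SAF). A prey absent from a bait/condition is
imputed at an average spectral count of zero, which has no finite log2;
imputed cells are therefore carried as −inf with an explicit boolean mask,
and exports/clustering replace them with a configurable floor (default: the
minimum observed finite log2-SAF minus 1). This makes downstream clustering
deterministic instead of depending on silent NaN handling.

The replication-stress differential is computed on raw average spectral
counts, exactly as defined: `log2FC = log2((HU + 1) / (untreated + 1))`,
one value per prey in the union of the two condition-specific prey sets,
with absent preys contributing zero. The HU-responder rule is two-sided,
|log2FC| > 1 (strict), combined with |NormZ| > 2 (strict) in the chronic-HU
CRISPR screen. NSAF (SAF renormalised to sum to one per run) is available
behind a flag but is not the default, since the plain SAF is what the
downstream analyses are defined on.

## drugZ-style screen scoring

Gene essentiality/sensitization scores are NormZ values. When only guide
counts are available the package scores them with a deliberately simplified
drugZ-style scheme: (1) each sample is scaled to a fixed 10^7 library size —
a fixed target rather than a data-dependent one so that scores are exactly
invariant to per-sample depth; (2) per replicate, guide fold change
`fc = log2((D14 + 0.5) / (D0 + 0.5))`; (3) guide z-scores against the
replicate's empirical mean and SD (a whole-library null, without the
published drugZ's empirical-Bayes variance moderation); (4) gene score =
sum of guide z-scores across guides and replicates divided by the square
root of the number summed; (5) rank-based inverse-normal transform (Blom
offsets) of gene scores to NormZ. Depleted genes are negative. Because of
the final transform, under a null screen the fraction of genes below −1.5
is Φ(−1.5) ≈ 6.7% by construction. External gene-level NormZ tables can be
supplied directly to bypass this scorer; the downstream rules consume only
ranks and thresholds.

Threshold classifiers are strict inequalities (NormZ exactly at the
threshold is excluded) and missing cells never count toward a tally.
Chemogenomic clustering is agglomerative (SciPy linkage) on the gene ×
screen NormZ matrix; defaults are Euclidean distance with complete linkage
(the common heatmap default — the original analysis names neither), with
correlation distance and average/Ward linkage available. Missing cells are
excluded pairwise from distances (scikit-learn's NaN-aware Euclidean, or
pandas' pairwise Pearson) or imputed at zero by configuration; ties are
broken by input order and cluster ids are relabelled by first appearance,
so assignments are deterministic given data and parameters.

## Overrepresentation analysis

For a query of n genes in a universe of N with a term annotating K universe
genes and overlapping the query in k, p = P(X ≥ k) under the hypergeometric
distribution (one-sided: only over-representation is tested), with
Benjamini–Hochberg q-values across all tested terms. Terms with zero
universe overlap are skipped; query genes outside the universe are dropped
with a warning. The default universe is the collection's gene union
(optionally intersected with the detectable preys); the choice is exposed
because enrichment services rarely state theirs. Evidence-code filtering
(e.g. dropping electronically inferred annotations) is an input-side
concern: GMT files are expected pre-filtered.

## Survival screening

Kaplan–Meier estimation and the two-group log-rank test come from
lifelines. The prognostic screen dichotomises each gene's expression —
median split by default, or a "best cutoff" scan over the patient-distinct
expression values between the 25th and 75th percentiles (median always
included) keeping the split that minimises the log-rank p. The best-cutoff
mode is anti-conservative by construction (it minimises over many tests);
the number of cutoffs scanned is recorded in every result for multiplicity
disclosure. No correction across genes is applied to the significance flag
(raw p < α is the screened criterion); a BH column is emitted alongside for
transparency. Degenerate inputs are explicit: constant expression or a
split leaving a group empty yields p = 1 with a warning; a pair of groups
with zero events yields statistic 0, p = 1. Effect direction is the sign of
the event rate per unit follow-up time, high- vs low-expression group.

## Network assembly

The BioID network is a star per bait (bait–prey edges tagged `bioid`);
self-loops are dropped and shared preys connect multiple baits.
Augmentation adds prey–prey edges from catalogue exports only when both
endpoints are already nodes — the node set never changes — with symbol
pairs canonicalised (sorted) before deduplication and provenance tags
unioned across sources, making repeated augmentation idempotent. Exports
are GraphML and a plain edge-list TSV.

## Synthetic-data generator

The generator emulates the study design end to end: five baits × two
conditions × two biological replicates. Planted structure: 945 all-common
preys, 97 BCDX2-exclusive, 46 CX3-exclusive (the complex-level set sizes of
the emulated study), 100 bait-specific preys per bait, and 300 background
binders whose membership signatures are drawn uniformly from the non-empty
bait subsets *excluding* the three reserved signatures — this exclusion is
what makes the planted sets identifiable from the tables alone. Spectral
counts are negative binomial (mean 10, size 2; overdispersion is the norm
in spectral counting — the count model is the generator's, not a claim
about any particular dataset), detection probability 0.9, and 5% decoy
records with low iProphet probabilities or zero unique peptides.
Contaminants from the default list are injected with high confidence scores
so that their removal is attributable to the contaminant rule.

Fifty all-common preys are HU-modulated with a ±2 log2 shift of their mean
count (alternating sign). In **noiseless mode** (detection probability 1,
no decoys, condition-paired counts derived deterministically from one base
draw, modulated baselines clamped ≥ 4) the |log2FC| > 1 calls equal the
planted set exactly: unmodulated preys have identical counts in both
conditions, and the clamp guarantees the shifted ratio clears the threshold
at the smallest admissible baseline.

Screens: 50 planted essentials among 2000 neutral genes, 4 guides per gene,
2 replicates; D0 counts negative binomial around 500, D14 Poisson around
the D0 count times fitness (0.1 for essentials — i.e. D14 at 10% of the D0
expectation — and 1 otherwise). Chemogenomic NormZ profiles are standard
normal with planted olaparib sensitizers (< −1.5 in two of three screens)
and HU-screen scores of |NormZ| > 2.5 for the HU-modulated preys. Cohorts:
500 patients, log-normal i.i.d. expression, exponential survival with
baseline hazard 0.02/month multiplied by the hazard ratio (default 2) for
each planted hazardous gene when expression exceeds its median, independent
exponential censoring capped at 120 months.

What the generator does **not** emulate: correlated prey abundances and
shared-peptide effects, batch structure between runs, guide-efficiency
heterogeneity, screen–screen correlation in chemogenomic profiles, and
non-proportional hazards or covariate structure in cohorts. Passing tests
therefore demonstrate correctness of the computations and calibration of
the statistics under these idealised conditions, not robustness to every
artefact of real data.

## Validation suite and problem sizes

`proximap.validation` (driven by `scripts/acceptance.py` and
`tests/test_acceptance.py`) computes: the SAF and log2FC formula identities
and antisymmetry over 1000 random count pairs; agreement of the
intersection/upset operations with per-prey brute-force enumeration over
100 random 5-bait fixtures; agreement of the hypergeometric upper tail with
exhaustive draw enumeration for every instance with N ≤ 12; agreement of
the threshold classifiers with brute-force counting over 50 random
matrices; null-calibration fractions for the overrepresentation test (1000
query replicates against 50 terms of 120 genes in a universe of 1200 — a
design whose attainable alpha at 0.05 is 0.044, chosen so the discrete
hypergeometric null is close to continuous), the median-split log-rank
screen (200 independent genes, 500 patients) and the drugZ-style scorer
(no-effect screen, 2050 genes); and planted-truth recovery — exact Jaccard
for the three complex-level sets and the HU-responder rule in noiseless
mode, recall of the 50 planted essentials within the 50 most-depleted
NormZ ranks, and power against a planted hazard-ratio-2 gene over 40
simulated 500-patient cohorts. These problem sizes are the package's
validation design; each reported value carries its size in the JSON output.

## Known limitations

- The drugZ-style scorer is a simplification; for publication-grade screen
  scoring, supply NormZ tables from the published implementation.
- The "best cutoff" survival mode inherits the optimal-cutpoint bias; its
  raw p-values should not be reported without correction.
- Enrichment p-values depend entirely on the supplied annotation release;
  the package ships no annotation data.
- The exclusive reading of the complex-level intersections is a documented
  interpretation; the plain-intersection reading is available through
  custom `IntersectionSpec`s.
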