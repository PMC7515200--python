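# Methods

This note documents the models, parameters, numerical choices and open
design decisions behind `enhancerlink`, and states precisely what the
synthetic fixtures do and do not demonstrate.

## Coordinate and data conventions

All genomic coordinates are 0-based half-open internally. BED/narrowPeak
files are read as-is; GTF (1-based inclusive) converts TSSs as `start−1`
(+ strand) / `end−1` (− strand); probe-manifest positions are assumed
1-based and shifted on read. Chromosome names are "chr"-prefixed; readers
accept an option to add or strip the prefix for mixed sources. Missing
beta values stay missing — they are excluded from every mean and fraction
and are never imputed. Expression matrices carry a `transform` tag
(`linear` or `log2p1`); fold changes use the linear scale and correlations
the log scale, making an otherwise implicit choice explicit.

## Enhancer-probe atlas

Peak datasets of the same kind are pooled by union (`merge_gap_bp = 0`);
a `min_dataset_support ≥ k` vote is available but off by default, since
peak collections from many cell types are deliberately permissive. A probe
is assigned by its single CpG coordinate — HM450 probes are point
annotations and no window is justified. TSS distance is point-to-point and
strand-ignored; a probe is retained iff its minimum distance over all
transcript TSSs is strictly greater than `tss_exclusion_bp` (default
1,500 bp). Using all transcripts rather than one TSS per gene is the
stricter reading and is the default (`one_per_gene` reverses it). Atlas
size is monotone: non-increasing in the exclusion distance, non-decreasing
in the number of peak datasets.

## Probe classification

Cutoffs (defaults): `unmeth = 0.2`, `meth = 0.8`, `tumor_hyper = 0.6`,
`tumor_hypo = 0.4`, `min_tumor_fraction = 0.05`,
`max_missing_fraction = 0.2`. The differential rules require a *fraction*
of tumor samples beyond the tumor cutoff rather than a count, so cohorts
of any size behave consistently. The four rules are not strictly mutually
exclusive: a bimodal tumor distribution can satisfy a constitutive mean
rule and a differential subset rule at once (e.g. 90% of tumors at β=0.95
and 10% at β=0.3 is both "methylated" by means and "hypomethylated" by
subset). The differential call wins — it is the biologically informative
one — and this precedence is fixed in code and covered by tests. All
cutoffs are echoed into the output header of every classification file.

## TR–probe linking

Tumor samples are split at each differential probe into
`low = {β < 0.4}` and `high = {β > 0.8}` (defaults tied to the
classification cutoffs so "a subset of tumors" means the same thing in
both stages); both groups must reach `min_group_size = 5`. The default
statistic is the one-sided Wilcoxon rank-sum for higher TR expression in
the low-methylation (enhancer-active) group — the same comparison serves
both directions, since "lower expression in the hypermethylated subset"
is the identical one-sided test with the groups' roles swapped. The exact
null distribution is used when the pooled size is ≤25 and tie-free,
otherwise the tie-corrected normal approximation. A permutation variant
(`test=permutation_z`) permutes sample labels of the z-scored rank sum
with a seeded generator and converges to the rank-sum p, providing an
internal cross-check. BH adjustment is applied within each direction
across all TR×probe tests (a single documented default; per-TR or
per-probe families are plausible alternatives and the choice is
config-visible in every output header). Links with adjusted p < 0.05 are
kept. TRs missing from the expression matrix are skipped and logged,
never imputed.

## Network summaries

TR ranks count *distinct* linked probes per direction; ties break by gene
name so tables are reproducible. Default flag thresholds: 50+ links for
activated TRs, 10+ for inactivated. Pairwise TR correlation is Pearson r²
of log-scale expression across tumor samples. Per-sample link burden
counts link records `(tr, probe)` whose probe has β below
`active_beta_cutoff = 0.4` in that sample; TR expression is deliberately
not an additional condition (simplest consistent definition — a sample
"has" an enhancer link when that enhancer is demethylated in it).
Subgroups: burden 0 ⇒ `no_link`; otherwise burden at or above the 0.90
burden quantile ⇒ `highly_linked` (ties inclusive). Heatmap export writes
betas raw in [0,1]; continuous covariate tracks are min–max scaled after
replacing zeros with the minimum non-zero value (so zero-coded "absent"
entries do not stretch the scale); constant covariates export as 0.5 with
a warning. Row/column orders come from average-linkage hierarchical
clustering with Euclidean distance — seedless and deterministic; missing
betas are row-mean-filled for the distance computation only.

## Survival

Quartile stratification takes the top and bottom ⌊n/4⌋ samples by value
with stable sample-ID tie-breaking; the middle half is excluded. All
samples with non-missing feature and survival fields enter the cut.
Kaplan–Meier estimation and the two-group log-rank test are delegated to
lifelines and verified in tests against an independently coded
product-limit form and an O−E/hypergeometric-variance accumulation. The
per-feature screen reports *raw* log-rank p-values (BH-adjusted values are
added as a transparency column, not used for flagging) and enforces
directionality: a feature is flagged only when p < α **and** the
hypothesized extreme group (low methylation, or high expression) has the
worse final survival estimate. Under the null this flags at ≈ α/2, which
the calibration test checks over 1,000 simulated features.

## Target genes

Candidate targets are genes with ≥1 TSS within `window_bp = 1,000,000` of
the probe, distance measured probe-point to TSS-point (enhancer–promoter
framing; anchoring to gene bodies would be the main alternative).
Upregulation is a per-gene Welch t-test (tumor vs normal, log scale) with
BH across all genes at α = 0.05. TAD sources are kept separate —
`same_tad_<source>` per Hi-C cell line plus an all-sources conjunction —
and TADs must be non-overlapping within a source (validated; overlap is an
error). Knockdown support requires adjusted p < 0.05 **and** log2FC < 0 in
the experiment's DE table; no fold-change floor is imposed beyond the
sign.

## Motif scanning

Windows are ±`half_window_bp` around the probe (default 1,117 bp — half
the mean enhancer length of the pooled peak set; `half_mean_enhancer_size`
recomputes it for any region list). Scores are
`Σ log2((p + pc·bg)/bg)` with pseudocount 1e-3; p-values are exact tail
probabilities of the score under the background model, computed by dynamic
programming over the score lattice discretized at 1/1000 bit (the same
approach FIMO uses); tests verify equality with exhaustive enumeration up
to width 6. Threshold 1e-4, both strands, background uniform by default.
Windows containing N at a scored offset skip that offset. A probe counts
as hit when **any** PWM variant of the motif set matches (pooled-per-TR
rule, matching the use of multiple motif databases per factor).

## Synthetic fixtures

The generator emulates the statistical structure the pipeline detects,
not array chemistry. Betas are drawn from low/high-mode Beta distributions
(Beta(5,45) / Beta(45,5)) plus clipped Gaussian noise (σ = 0.02),
respecting the [0,1] support and bimodality of real arrays. Default study
conditions: 20 normals, 200 tumors, 2,000 probes, 3,000 genes, 100-TR
catalogue, three planted activated TRs with 60 linked probes each,
Δβ = 0.5, +2 SD log-expression shift in a 40% tumor subset. Survival times
are exponential with hazard `baseline · HR^burden` (HR = 1.01 per planted
link, baseline 1/1,500 days, independent exponential censoring), so the
burden subgroup comparison has recoverable truth. The motif sub-fixture
lives on its own contig: a sharp consensus (dominant probability 0.997) is
planted at the centre of 60 of 100 windows, and chance off-target
occurrences of the consensus or its reverse complement are scrubbed by
single-base mutation — a fixture-construction step that makes the planted
fraction exact, not a property of real genomes.

What passing on these fixtures shows: the stages implement their stated
rules, recover planted effects of the stated size, and are calibrated
under their nulls. What it does not show: robustness to tumor purity,
batch effects, probe cross-reactivity, clonal heterogeneity, copy-number
confounding of expression, or non-exponential survival — none of which
the generator models.

## Numerical and reproducibility notes

Every stochastic component takes an explicit seed; the permutation test
consumes a seeded generator, and two pipeline runs with the same config
and seed produce byte-identical artifacts (matrix TSVs are written at
`%.17g` and read back with round-trip float parsing). Each pipeline stage
writes a manifest with the package version, seed, full parameter echo, and
SHA-256 of every input. Problem sizes used by the test suite and the
acceptance script (e.g. 400-probe null fixtures across 20 seeds, 1,000
null survival features, default-size recovery runs) were chosen to make
the statistical checks stable while keeping a full run to a few minutes on
a single CPU.

## Known limitations

- The published-scale analysis (hundreds of TCGA samples against
  consortium epigenome compendia) needs external downloads and the
  original tool's exact cutoff settings; this package exposes every such
  cutoff as configuration but ships only desk-scale synthetic validation.
- GTF parsing covers the gene/transcript features of GENCODE-style files
  only; IDAT parsing and array normalization are out of scope (betas are
  consumed as given).
- The link test is an association screen between methylation-defined
  groups; it is not causal inference, and no mediation or eQTM modelling
  is attempted.
- Survival analysis is limited to KM/log-rank on quartile extremes; no
  Cox regression or covariate adjustment.
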