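# Methods

`erlnc` implements the computational arc of a hormone-receptor-regulated
lncRNA study: catalog assembly and evidence annotation, binding-site
category enrichment against a random-placement null, pairwise nonparametric
differential expression with candidate nomination, gene-signature concept
enrichment, and a dichotomized-biomarker prognosis workflow.  Every stage
runs on synthetic data with planted ground truth, so each statistical claim
the package makes is checked by recovery of structure that was put in by
construction.

## Coordinate conventions and interval logic

All internal coordinates are 0-based half-open `[start, end)`; GTF/GFF3
1-based inclusive coordinates are converted at the file boundary and
nowhere else.  Overlap is strand-agnostic (ChIP peaks carry no strand);
only promoter windows are strand-aware.  The TSS is `locus.start` on the
plus strand and `locus.end - 1` on the minus strand.  The promoter window
defaults to 2,000 bp upstream and 500 bp downstream of the TSS — a
conventional window, exposed in `PromoterSpec`, since "the promoter" is not
a precisely defined genomic object.  Bulk overlap queries go through an
interval tree whose results are property-tested against a brute-force
all-pairs scan.

## Catalog and evidence flags

The lncRNA catalog is the union of annotation sources restricted to
entries at least 200 nt long (the conventional lncRNA length floor).
Duplicates collapse on exact coordinate identity rather than ID strings,
because different annotation sources use different ID namespaces; the
first-seen ID is kept and all contributing sources are recorded.

A lncRNA is *intergenic* iff its locus span shares zero base pairs with
every protein-coding locus span, strand-agnostic; half-open abutment counts
as non-overlapping.  Evidence flags per entry:

- `er_promoter` / `ar_promoter`: any receptor peak overlaps the promoter
  window (any-bp overlap).
- `ere_full` / `ere_half`: the estrogen response element consensus
  (`AGGTCANNNTGACCT`, half-site `AGGTCA`) scanned on both strands of the
  genomic sequence under each ER peak that overlaps the promoter.  With no
  genome sequence the flags are `None` (unknown), never `False`.
- `h3k4me3_promoter`: active promoter mark over the promoter window;
  `h3k36me3_body`: elongation mark over the locus span; the repressive
  marks (H3K9me3, H3K27me3) flag overlap with locus *or* promoter, since
  repressive domains are broad and their position relative to the TSS is
  not the signal of interest.

## Peak categories and the permutation null

Each peak is assigned to exactly one of promoter / exonic / intronic /
intergenic by its midpoint, with precedence promoter > exonic > intronic >
intergenic.  Midpoint assignment guarantees a partition, so category
fractions sum to one exactly (count arithmetic, no floats).

The null model re-places each peak independently and uniformly: a
chromosome is drawn with probability proportional to its usable length
(length − peak length + 1), the start uniformly within it; peak lengths are
preserved, placements may overlap each other, and an optional exclusion
list is honoured by rejection sampling (1,000 attempts before erroring).
The null is deliberately simple — no GC matching, no gap awareness — and
is documented as a choice, not an inference about any particular dataset.
Enrichment is one-sided with add-one correction:

    p = (1 + #{null fraction >= observed fraction}) / (n_perm + 1)

so p is bounded below by 1/(n_perm + 1); the bound is reported alongside p.
Default `n_perm` is 1,000 (resolution 1e-3); resolving p-values near 3e-5
requires >= 33,332 permutations and is left to configuration.  Mark-overlap
enrichment uses any-bp overlap of whole peaks (co-occupancy, not location
class) and restricts the null to the supplied intergenic segments.
Calibration is tested: with peaks drawn from the null itself, P(p <= α)
stays within +0.02 of α at α ∈ {0.05, 0.1} over 500 replicates.

## Differential expression and nomination

Expression values are RPKM-like positive continuous numbers.  Each
contrast uses the two-sample Wilcoxon rank-sum test: exact enumeration when
`n_x * n_y <= 400` and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections (the exact path is
verified against a full enumeration oracle).  Benjamini–Hochberg runs
*within* each contrast, since the study design reports per-contrast
significant sets.  Direction is the sign of the median difference —
consistent with a rank-based test — and the log2 fold change used for
ranking is `log2((median_b + 0.1)/(median_a + 0.1))`; the 0.1 pseudocount
(in expression units) guards against RPKM zeros.

Nomination filters the annotated catalog to intergenic, receptor-bound,
significantly up-regulated features (q <= 0.01 in benign-vs-tumour by
default, histone evidence optional), then sorts by (q ascending, |log2FC|
descending, feature id).  The tie-break chain is fully specified so output
is reproducible and input-order invariant.

## Signatures and concept enrichment

A fold-change signature keeps genes with `log2((b + 1)/(a + 1))` strictly
greater than the threshold (default 2); per-condition summaries are means
over replicates, degenerating to the single value for one-sample cell-line
comparisons.  A signature×concept association is a 2×2 table over a
declared universe, scored by the odds ratio `(ad)/(bc)` — with the
Haldane–Anscombe 0.5 correction only when a zero cell exists — and a
one-sided Fisher exact p computed as the upper hypergeometric tail
(verified against exhaustive tail summation on universes <= 60).  The
universe defaults to the union of all concept genes plus the signature and
must be overridable: enrichment p-values are only meaningful relative to a
stated universe.  The network export is hub-and-spoke: one node per
concept passing `OR > 2, p < 1e-6` (both configurable — figure-specific
thresholds of 2.0 and 3.0 exist in this analysis tradition), with size,
direction, tumour-type, OR and p attributes for rendering in a graph tool;
layout itself is out of scope.

## Prognosis workflow

The probe-selection step picks the probe region with minimal *technical
variance*, operationalized as the median over samples of the within-sample
variance among the region's probes.  This is an explicit design choice —
the term is not standardized — chosen because between-probe disagreement
within one sample is technical, not biological, variation.

The marker is dichotomized at the cut maximizing sensitivity ×
specificity, with candidate cuts at midpoints of consecutive sorted unique
scores and `score >= cut` classifying high.  The cut is learned on a
training split and applied to a held-out split (single-cohort use is
possible but optimistic).  Endpoints are used both ways deliberately:
time-to-event for Kaplan–Meier and the log-rank test (biochemical
recurrence and metastasis), binary for odds ratios and AUC (all four
endpoints).  KM uses the product-limit estimator with the convention that
subjects censored at an event time remain at risk.  Univariable ORs are
`ad/bc` with Wald CIs; multivariable ORs come from a maximum-likelihood
logistic model (Newton, |Δ| < 1e-8, <= 100 iterations) and perfect
separation raises an explicit error rather than returning silent output.
AUC is the Mann–Whitney rank statistic with half credit for ties; its 95%
CI uses the DeLong placement-variance estimator.  Case–cohort /
nested-case–control sampling weights are not implemented: synthetic
cohorts are simple random samples, and weighting schemes are out of scope.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of (config, seed); one master seed fans
out to per-generator child seeds through fixed spawn keys, so individual
inputs can be regenerated independently.  Defaults (the study conditions):

| parameter | default | rationale |
|---|---|---|
| genome | 2 × 3 Mb | desk-scale; gene footprint ~28% |
| coding / lncRNA genes | 250 / 400 | enough for stable category fractions |
| intergenic lncRNA fraction | 0.56 | matches the ~56% intergenic share typical of lncRNA catalogs |
| expression groups | 26 / 40 / 7 | benign / PCa / NEPC cohort design |
| planted receptor targets | 50 | nomination-scale candidate set |
| planted fold change | 4× in PCa | clearly detectable at n=26/40 under σ=0.5 |
| expression noise | lognormal, σ=0.5 | rank-test only needs ordering; lognormal keeps RPKM-like positive values |
| peaks / promoter enrichment | 300 / 0.5 | each planted promoter expects ~3 targeted peaks |
| concept compendium | 30 concepts of 200 genes, 5 planted with >= 100/200 signature overlap, universe 10,000 | planted associations clear OR>2, p<1e-6 by construction |
| cohort | n=594, β=0.7, 50% censoring | two-cohort pooled design scale; detectable hazard ratio e^0.7 ≈ 2 |

Peaks targeted at planted promoters receive p-value scores in [1e-12,
1e-6] and background peaks [1e-5, 1e-1], so planted peaks rank first under
ascending-p ranking.  Cohort event times are exponential with hazard
`h0 · exp(β · high)`; censoring is independent uniform `U(0, c_max)` with
`c_max` solved numerically from the closed-form censoring probability of
the exponential model, plus an administrative follow-up cap at 15 years.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: read-level noise and mapping artifacts;
count-based (negative binomial) expression with mean–variance coupling;
correlated gene–gene expression structure; GC/mappability bias in peak
placement; linkage between clinical covariates and the marker (covariates
are independent by default, so adjusted and unadjusted ORs coincide up to
noise); genome gaps and chromosome-specific peak biology.  Recovery of
planted structure demonstrates the statistical machinery is correct, not
that real catalogs of this kind are complete or unconfounded.

## Numerical choices and degenerate inputs

- Empirical p-values use add-one correction and can never be 0.
- Constant expression features get p = 1 and direction `none`.
- Identical score vectors admit no cut-point candidates: an error, not a
  guess.  Cut-point ties go to the lowest cut.
- A fold-change threshold is strict (`>`): a gene at exactly log2FC = 2 is
  excluded.
- Percentile rank uses the `<=` convention: a feature's own median counts,
  so the lowest of n features sits at 100/n, the highest at 100.
- BH on an empty vector returns an empty vector; p outside [0, 1] is an
  error.
- Logistic coefficients with |β| > 15 are treated as separation and raise.

## Problem sizes used in the test suite

The suite runs the full default study (650 genes, 300 peaks, 73 samples,
594 patients) end to end, 500-replicate null calibrations at n_perm = 99,
100-seed null DE screens at 1,000 features, and 20-seed power runs at
n = 500 — sizes chosen so every calibration property is measurable with
comfortable margins while the whole suite stays interactive.
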