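# erlnc

Nomination of hormone-receptor-regulated long non-coding RNAs from ChIP-seq
binding and multi-group expression, with the downstream analyses such a
study needs: binding-category enrichment against a random-placement null,
gene-signature concept networks, and a dichotomized-biomarker prognosis
workflow.  Written for computational biologists who want each of those
stages as a tested, seeded, reusable library — exercisable end to end on
synthetic data with planted ground truth, no downloads required.

## The problem

Steroid receptors such as ERα bind thousands of sites across a tumour
genome, most of them outside protein-coding genes.  Which long non-coding
RNAs (lncRNAs, >= 200 nt) are plausibly under receptor control?  The
pipeline answers with a conjunction of evidence per lncRNA:

1. **Catalog** — union of annotation sources, length-filtered,
   deduplicated by coordinates; each entry classified *intergenic* iff its
   locus shares zero bp with every coding locus.
2. **Binding** — a receptor peak in the strand-aware promoter window
   (default TSS −2000/+500), estrogen-response-element motifs
   (`AGGTCAnnnTGACCT`, half-site `AGGTCA`) under the peaks, and histone
   marks (H3K4me3 promoter, H3K36me3 body; H3K9me3/H3K27me3 repressive).
3. **Enrichment** — peak midpoints partitioned into promoter / exonic /
   intronic / intergenic; the observed category fraction tested against
   peaks re-placed uniformly at random, with one-sided empirical
   p = (1 + #{null >= obs}) / (n_perm + 1).
4. **Differential expression** — pairwise Wilcoxon rank-sum across tissue
   groups (benign / PCa / NEPC), Benjamini–Hochberg within contrast;
   candidates = intergenic ∧ receptor-bound ∧ up-regulated at q <= 0.01,
   ranked by (q, |log2FC|, id).
5. **Signatures** — genes with log2FC > 2 between conditions; association
   with a concept (gene set) scored by the 2×2 odds ratio (Haldane 0.5
   correction on zero cells) and one-sided Fisher exact p; concepts with
   OR > 2, p < 1e-6 exported as a hub-and-spoke GraphML network.
6. **Prognosis** — marker dichotomized at the cut maximizing
   sensitivity × specificity on a training split; Kaplan–Meier + log-rank
   on the held-out split; univariable and logistic-adjusted odds ratios;
   AUC with DeLong 95% CI.

The `erlnc.simulate` module generates every input with planted truth (which
lncRNAs are receptor targets, which features are differentially expressed,
which concepts are associated, the true marker log-hazard β), so the whole
pipeline is testable by recovery.

## Worked example

The numbered drivers under `analysis/` run the full synthetic study
(seed 13; intermediate files under `scratch/study/`, tables under
`results/`):

```bash
python analysis/01_simulate.py
python analysis/02_catalog_annotation.py
python analysis/03_binding_enrichment.py
python analysis/04_differential_expression.py
python analysis/05_signatures_concepts.py
python analysis/06_prognosis.py
```

Selected output, with what it means:

```
catalog: 400 lncRNAs (all >= 200 nt)
  intergenic: 195 / 400 (48.8%)
  ER binding in promoter: 81; AR binding in promoter: 66
```

The catalog stage found 81 lncRNAs with an ER peak in the promoter window;
50 of these are planted targets, the rest receive peaks by chance.

```
promoter fraction 0.633 vs null mean 0.227: p = 0.001 (floor 0.001)
active-mark overlap of intergenic peaks: 48.4% vs null 5.7%: p = 0.002
```

63.3% of peaks sit in promoters, versus 22.7% expected under uniform
placement — the permutation p is at its resolution floor (999
permutations).  Peaks outside gene bodies co-occur with active marks far
above the placement null, mirroring how binding in open, marked chromatin
is detected.

```
benign vs PCa: 51 differentially expressed at FDR<0.01 (50 up in PCa)
nominated: 48 intergenic ER-bound up-regulated lncRNAs
  vs planted truth (50): precision 1.00, recall 0.96
```

The DE + nomination funnel recovers 48 of the 50 planted receptor-target
lncRNAs with no false nominations.

```
 BCR: cut 7.01 (sens 0.60 x spec 0.59); OR 4.00 [2.46, 6.53]; AUC 0.684; log-rank p 3.49e-07
 MET: cut 6.77 (sens 0.59 x spec 0.52); OR 1.60 [1.01, 2.54]; AUC 0.545; log-rank p 0.0224
```

On the 594-patient synthetic cohort (true log-hazard β = 0.7), the
cut-point learned on the training half separates recurrence-free survival
in the test half for both time-to-event endpoints.

A `erlnc` command-line entry point exposes the same stages
(`erlnc simulate|catalog|enrich|de|nominate|signature|concepts|prognosis|run`);
see `erlnc --help`.

## Layout

```
src/erlnc/        library: intervals, catalog, enrichment, diffexpr,
                  signatures, prognosis, simulate, pipeline, cli
analysis/         numbered narrative drivers over the library
tests/            pytest suite (unit, property, acceptance)
scripts/          acceptance.py
docs/methods.md   models, parameters, design choices, limitations
```
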