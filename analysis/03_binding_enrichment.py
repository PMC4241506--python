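#!/usr/bin/env python
"""Where does the receptor bind?  Category fractions and permutation tests.

Classifies every ER peak midpoint into promoter / exonic / intronic /
intergenic, then asks whether the promoter fraction exceeds the uniform
random-placement null, and whether intergenic peaks (outside any gene span)
co-occur with active histone marks more than placement within the
intergenic space would predict.  Writes results/enrichment.json.
"""
import json
from pathlib import Path

import pandas as pd

from erlnc.catalog import PromoterSpec
from erlnc.enrichment import (GenomeSpec, annotation_fractions,
                              mark_overlap_enrichment, permutation_enrichment)
from erlnc.intervals import GenomicInterval, read_bed, read_gene_models

import sys
sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "scripts"))
from acceptance import intergenic_complement  # noqa: E402

ROOT = Path(__file__).resolve().parent.parent
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"
SEED = 13


def main() -> None:
    genes = read_gene_models(STUDY / "genes.gtf", "gtf")
    peaks = read_bed(STUDY / "er_peaks.bed")
    sizes = pd.read_csv(STUDY / "chrom_sizes.tsv", sep="\t", index_col=0)
    genome = GenomeSpec(chrom_lengths=sizes.iloc[:, 0].to_dict())
    prom = PromoterSpec()

    fractions = annotation_fractions(peaks, genes, prom)
    print("peak category fractions:",
          {k: round(v, 3) for k, v in fractions.items()})
    enr = permutation_enrichment(peaks, genes, prom, "promoter", genome,
                                 n_perm=999, seed=SEED)
    print(f"promoter fraction {enr.observed_fraction:.3f} vs null mean "
          f"{enr.null_fractions.mean():.3f}: p = {enr.p_empirical:.4g} "
          f"(floor {enr.p_resolution:.4g})")

    space = intergenic_complement(genes, genome)
    total_space = sum(len(s) for s in space)
    covered = {iv.chrom: [] for iv in space}
    inter_peaks = []
    for p in peaks:
        if any(s.chrom == p.chrom and s.start <= p.midpoint < s.end for s in space):
            inter_peaks.append(p)
    marks = [GenomicInterval(q.chrom, q.start, q.end)
             for m in ("H3K4me3", "H3K36me3")
             for q in read_bed(STUDY / f"{m}.bed")]
    mk = mark_overlap_enrichment(inter_peaks, marks, space, n_perm=499, seed=SEED + 1)
    print(f"intergenic peaks: {len(inter_peaks)} / {len(peaks)} "
          f"(intergenic space {total_space / genome.total_bp:.1%} of genome)")
    print(f"active-mark overlap of intergenic peaks: "
          f"{mk.observed_fraction:.1%} vs null {mk.null_fractions.mean():.1%}: "
          f"p = {mk.p_empirical:.4g}")

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "enrichment.json").write_text(json.dumps({
        "category_fractions": fractions,
        "promoter_enrichment": {"observed": enr.observed_fraction,
                                "null_mean": float(enr.null_fractions.mean()),
                                "p": enr.p_empirical, "n_perm": enr.n_perm},
        "active_mark_overlap": {"observed": mk.observed_fraction,
                                "null_mean": float(mk.null_fractions.mean()),
                                "p": mk.p_empirical, "n_perm": mk.n_perm,
                                "n_intergenic_peaks": len(inter_peaks)},
    }, indent=1))
    print(f"wrote {RESULTS / 'enrichment.json'}")


if __name__ == "__main__":
    main()
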