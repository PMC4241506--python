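#!/usr/bin/env python
"""Pairwise DE across benign/PCa/NEPC and nomination of receptor-target lncRNAs.

Runs the Wilcoxon/BH differential-expression stage on both contrasts, joins
the significant up-regulated features with the annotated catalog (run
02_catalog_annotation.py first) and ranks the nominated candidates.
Compares the candidate set against the planted ground truth.  Writes
results/de.tsv and results/candidates.tsv.
"""
import json
from pathlib import Path

import pandas as pd

from erlnc.diffexpr import ExpressionMatrix, pairwise_de

ROOT = Path(__file__).resolve().parent.parent
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"
FDR = 0.01


def main() -> None:
    matrix = ExpressionMatrix.from_tsv(STUDY / "expression.tsv", STUDY / "groups.tsv")
    contrasts = [("benign", "PCa"), ("PCa", "NEPC")]
    de = pairwise_de(matrix, contrasts, fdr_max=FDR)
    de_df = pd.DataFrame([{"feature_id": r.feature_id,
                           "contrast": f"{r.contrast[0]}|{r.contrast[1]}",
                           "p_raw": r.p_raw, "q_bh": r.q_bh,
                           "direction": r.direction, "log2fc": r.log2fc}
                          for r in de])
    RESULTS.mkdir(exist_ok=True)
    de_df.to_csv(RESULTS / "de.tsv", sep="\t", index=False, float_format="%.6g")
    for a, b in contrasts:
        sub = de_df[de_df["contrast"] == f"{a}|{b}"]
        n_sig = int((sub["q_bh"] <= FDR).sum())
        n_up = int(((sub["q_bh"] <= FDR) & (sub["direction"] == "up")).sum())
        print(f"{a} vs {b}: {n_sig} differentially expressed at FDR<{FDR} "
              f"({n_up} up in {b})")

    catalog = pd.read_csv(RESULTS / "catalog.tsv", sep="\t")
    bp = de_df[de_df["contrast"] == "benign|PCa"].rename(
        columns={"feature_id": "gene_id"})
    merged = catalog.merge(bp, on="gene_id")
    keep = (merged["intergenic"] & merged["er_promoter"]
            & (merged["q_bh"] <= FDR) & (merged["direction"] == "up"))
    cand = merged[keep].copy()
    cand["_absfc"] = cand["log2fc"].abs()
    cand = cand.sort_values(["q_bh", "_absfc", "gene_id"],
                            ascending=[True, False, True],
                            kind="mergesort").drop(columns="_absfc")
    cand.to_csv(RESULTS / "candidates.tsv", sep="\t", index=False,
                float_format="%.6g")

    truth = set(json.loads((STUDY / "ground_truth.json").read_text())
                ["planted_er_lncrnas"])
    got = set(cand["gene_id"])
    tp = len(got & truth)
    print(f"nominated: {len(got)} intergenic ER-bound up-regulated lncRNAs")
    print(f"  vs planted truth ({len(truth)}): precision "
          f"{tp / max(len(got), 1):.2f}, recall {tp / len(truth):.2f}")
    print(f"wrote {RESULTS / 'de.tsv'} and {RESULTS / 'candidates.tsv'}")


if __name__ == "__main__":
    main()
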