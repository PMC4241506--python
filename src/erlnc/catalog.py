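"""lncRNA catalog assembly, intergenic classification and evidence annotation.

The catalog is the union of one or more annotation sources restricted to
long (>= 200 nt by default) non-coding transcripts.  Each entry is then
annotated with the evidence used for nomination: receptor binding in the
promoter window, estrogen-response-element (ERE) motifs under the binding
peaks, and four histone marks (H3K4me3 / H3K36me3 active, H3K9me3 /
H3K27me3 repressive).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GeneModel, GenomicInterval, IntervalIndex, PeakInterval

__all__ = [
    "PromoterSpec",
    "LncRNACatalog",
    "AnnotatedLncRNA",
    "assemble_catalog",
    "classify_intergenic",
    "promoter_window",
    "scan_ere",
    "annotate_catalog",
    "annotation_table",
    "ERE_FULL",
    "ERE_HALF",
]

#: Full palindromic ERE consensus; N matches any base.
ERE_FULL = "AGGTCANNNTGACCT"
#: ERE half-site.
ERE_HALF = "AGGTCA"

VALID_MARKS = ("H3K4me3", "H3K36me3", "H3K9me3", "H3K27me3")


@dataclass(frozen=True)
class PromoterSpec:
    """Strand-aware promoter window around the TSS (bp up- and downstream)."""

    upstream_bp: int = 2000
    downstream_bp: int = 500

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("promoter extents must be >= 0")
        if self.upstream_bp == 0 and self.downstream_bp == 0:
            raise ValueError("promoter window cannot be empty")


@dataclass
class LncRNACatalog:
    """Deduplicated lncRNA gene models plus per-entry source provenance."""

    entries: list[GeneModel]
    provenance: dict[str, list[str]]
    min_length_nt: int = 200

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return [g.gene_id for g in self.entries]


@dataclass
class AnnotatedLncRNA:
    """One catalog entry with every nomination evidence flag.

    ERE flags are ``None`` (unknown) when no genome sequence was supplied;
    they are booleans otherwise, computed on the sequence under each ER
    peak overlapping the promoter window.
    """

    gene: GeneModel
    intergenic: bool
    er_promoter: bool
    ar_promoter: bool
    ere_full: bool | None
    ere_half: bool | None
    h3k4me3_promoter: bool
    h3k36me3_body: bool
    h3k9me3: bool
    h3k27me3: bool


def assemble_catalog(sources: Sequence[Sequence[GeneModel]],
                     source_names: Sequence[str] | None = None,
                     min_length_nt: int = 200) -> LncRNACatalog:
    """Union annotation sources into a length-filtered lncRNA catalog.

    Only ``gene_type == "lncRNA"`` entries with locus span >= min_length_nt
    are kept.  Duplicates are collapsed on exact (chrom, strand, start, end)
    identity — sources use different ID namespaces — keeping the first-seen
    ID and recording every contributing source name.
    """
    if not sources:
        raise ValueError("at least one annotation source is required")
    if source_names is None:
        source_names = [f"source_{i}" for i in range(len(sources))]
    if len(source_names) != len(sources):
        raise ValueError("source_names must match sources")
    seen: dict[tuple, GeneModel] = {}
    provenance: dict[str, list[str]] = {}
    for name, source in zip(source_names, sources):
        for gene in source:
            if gene.gene_type != "lncRNA" or gene.length < min_length_nt:
                continue
            key = (gene.locus.chrom, gene.locus.strand, gene.locus.start, gene.locus.end)
            if key in seen:
                prov = provenance[seen[key].gene_id]
                if name not in prov:
                    prov.append(name)
            else:
                seen[key] = gene
                provenance[gene.gene_id] = [name]
    return LncRNACatalog(entries=list(seen.values()), provenance=provenance,
                         min_length_nt=min_length_nt)


def classify_intergenic(lnc: GeneModel, coding_index: IntervalIndex | Sequence[GeneModel]) -> bool:
    """True iff the lncRNA locus shares zero bp with every coding locus.

    Strand-agnostic; half-open abutment (lnc.end == coding.start) counts as
    non-overlapping.
    """
    if not isinstance(coding_index, IntervalIndex):
        coding_index = IntervalIndex(g.locus for g in coding_index
                                     if g.gene_type == "coding")
    return not coding_index.any_overlap(lnc.locus)


def promoter_window(gene: GeneModel, spec: PromoterSpec = PromoterSpec(),
                    chrom_length: int | None = None) -> GenomicInterval:
    """Strand-aware promoter interval around the TSS, clipped at >= 0.

    Plus strand: ``[tss - upstream, tss + downstream)``.  Minus strand the
    window is mirrored: ``[tss - downstream + 1, tss + upstream + 1)``.
    """
    tss = gene.tss
    if gene.locus.strand == "-":
        start = tss - spec.downstream_bp + 1
        end = tss + spec.upstream_bp + 1
    else:
        start = tss - spec.upstream_bp
        end = tss + spec.downstream_bp
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(gene.locus.chrom, start, max(end, start + 1), gene.locus.strand)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _match_positions(seq: str, consensus: str, max_mismatch: int) -> list[int]:
    hits = []
    w = len(consensus)
    for i in range(len(seq) - w + 1):
        mism = 0
        for a, b in zip(seq[i:i + w], consensus):
            if b == "N":
                continue
            if a != b:  # N in the sequence never matches a fixed base
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            hits.append(i)
    return hits


def scan_ere(sequence: str, mode: str = "full", max_mismatch: int = 0) -> list[tuple[int, str]]:
    """Scan a sequence for ERE motifs on both strands.

    Returns ``(offset, strand)`` hits in forward-strand coordinates, sorted
    left to right (``+`` before ``-`` at equal offset).  ``mode`` selects
    the full palindromic consensus or the half-site; mismatches are counted
    only at non-N consensus positions.
    """
    sequence = sequence.upper()
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    consensus = {"full": ERE_FULL, "half": ERE_HALF}.get(mode)
    if consensus is None:
        raise ValueError(f"unknown mode {mode!r}")
    w = len(consensus)
    hits = [(off, "+") for off in _match_positions(sequence, consensus, max_mismatch)]
    rc = _revcomp(sequence)
    n = len(sequence)
    for off in _match_positions(rc, consensus, max_mismatch):
        hits.append((n - off - w, "-"))
    return sorted(hits)


def annotate_catalog(catalog: LncRNACatalog,
                     er_peaks: Sequence[PeakInterval],
                     ar_peaks: Sequence[PeakInterval],
                     marks: Mapping[str, Sequence[GenomicInterval]],
                     coding: Sequence[GeneModel] = (),
                     genome_seq: Mapping[str, str] | None = None,
                     promoter: PromoterSpec = PromoterSpec(),
                     ere_max_mismatch: int = 0) -> list[AnnotatedLncRNA]:
    """Attach every nomination evidence flag to each catalog entry.

    Promoter flags (ER, AR, H3K4me3) use any-bp overlap with the strand-aware
    promoter window; H3K36me3 uses the gene locus span; the repressive marks
    (H3K9me3, H3K27me3) use locus-or-promoter overlap.  ERE flags are scanned
    on the genomic sequence under every ER peak overlapping the promoter and
    are ``None`` when no sequence is available.
    """
    unknown = set(marks) - set(VALID_MARKS)
    if unknown:
        raise ValueError(f"unknown histone mark(s): {sorted(unknown)}")
    er_index = IntervalIndex()
    for p in er_peaks:
        er_index.add(p, p)
    ar_index = IntervalIndex()
    for p in ar_peaks:
        ar_index.add(p, p)
    mark_index = {m: IntervalIndex(ivs) for m, ivs in marks.items()}
    coding_index = IntervalIndex(g.locus for g in coding if g.gene_type == "coding")

    out: list[AnnotatedLncRNA] = []
    for gene in catalog.entries:
        prom = promoter_window(gene, promoter)
        locus = gene.locus
        er_hits = er_index.overlapping(prom)
        ere_full = ere_half = None
        if genome_seq is not None:
            ere_full = ere_half = False
            chrom_seq = genome_seq.get(locus.chrom, "")
            for pk in er_hits:
                seq = chrom_seq[pk.start:pk.end]
                if not seq:
                    continue
                if not ere_full and scan_ere(seq, "full", ere_max_mismatch):
                    ere_full = True
                if not ere_half and scan_ere(seq, "half", ere_max_mismatch):
                    ere_half = True
                if ere_full and ere_half:
                    break

        def _mark(name: str, where: str) -> bool:
            idx = mark_index.get(name)
            if idx is None:
                return False
            if where == "promoter":
                return idx.any_overlap(prom)
            if where == "body":
                return idx.any_overlap(locus)
            return idx.any_overlap(locus) or idx.any_overlap(prom)

        out.append(AnnotatedLncRNA(
            gene=gene,
            intergenic=classify_intergenic(gene, coding_index),
            er_promoter=bool(er_hits),
            ar_promoter=ar_index.any_overlap(prom),
            ere_full=ere_full,
            ere_half=ere_half,
            h3k4me3_promoter=_mark("H3K4me3", "promoter"),
            h3k36me3_body=_mark("H3K36me3", "body"),
            h3k9me3=_mark("H3K9me3", "either"),
            h3k27me3=_mark("H3K27me3", "either"),
        ))
    return out


def annotation_table(annotated: Sequence[AnnotatedLncRNA]) -> pd.DataFrame:
    """Flat TSV-ready table: one row per lncRNA, one column per flag."""
    rows = []
    for a in annotated:
        loc = a.gene.locus
        rows.append({
            "gene_id": a.gene.gene_id, "chrom": loc.chrom, "start": loc.start,
            "end": loc.end, "strand": loc.strand, "length_nt": a.gene.length,
            "intergenic": a.intergenic, "er_promoter": a.er_promoter,
            "ar_promoter": a.ar_promoter, "ere_full": a.ere_full,
            "ere_half": a.ere_half, "h3k4me3_promoter": a.h3k4me3_promoter,
            "h3k36me3_body": a.h3k36me3_body, "h3k9me3": a.h3k9me3,
            "h3k27me3": a.h3k27me3,
        })
    return pd.DataFrame(rows)
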