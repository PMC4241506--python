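"""Genomic interval primitives and BED / GTF / GFF3 readers and writers.

All internal coordinates are 0-based half-open ``[start, end)``; GTF/GFF3
1-based inclusive coordinates are converted at the file boundary.  Overlap
arithmetic is strand-agnostic: ChIP peaks carry no strand.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakInterval",
    "GeneModel",
    "IntervalIndex",
    "FormatError",
    "overlap_bp",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
]


class FormatError(ValueError):
    """Malformed record in a genomic text format (carries the line number)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PeakInterval(GenomicInterval):
    """A ChIP peak: an interval plus an identifier and a score.

    The score is either a peak-caller p-value (smaller = stronger binding)
    or a signal/enrichment value; which one is declared out of band via
    ``score_semantics`` wherever ranking direction matters.
    """

    name: str = "."
    score: float | None = None


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of base pairs shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with exon structure and a strand-aware TSS.

    ``gene_type`` is one of ``coding``, ``lncRNA`` or ``other``.  The TSS is
    the 5' end of the locus: ``locus.start`` on the plus strand and
    ``locus.end - 1`` (the last covered base) on the minus strand.
    """

    gene_id: str
    gene_type: str
    locus: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.gene_type not in ("coding", "lncRNA", "other"):
            raise ValueError(f"invalid gene_type {self.gene_type!r}")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for ex in exons:
            if ex.chrom != self.locus.chrom:
                raise ValueError(f"{self.gene_id}: exon on wrong chromosome")
            if ex.start < self.locus.start or ex.end > self.locus.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        if self.locus.strand == "-":
            return self.locus.end - 1
        return self.locus.start

    @property
    def length(self) -> int:
        return len(self.locus)


class IntervalIndex:
    """Per-chromosome interval tree for bulk overlap queries.

    Results are equivalent to a brute-force all-pairs scan; order of
    returned payloads follows insertion order for determinism.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval, payload=None) -> None:
        self._trees[iv.chrom].addi(iv.start, iv.end, (self._n, payload if payload is not None else iv))
        self._n += 1

    def overlapping(self, query: GenomicInterval) -> list:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = tree.overlap(query.start, query.end)
        return [d for _, d in sorted(h.data for h in hits)]

    def stab(self, chrom: str, point: int) -> list:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.at(point)
        return [d for _, d in sorted(h.data for h in hits)]

    def any_overlap(self, query: GenomicInterval) -> bool:
        tree = self._trees.get(query.chrom)
        return bool(tree is not None and tree.overlap(query.start, query.end))


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[PeakInterval]:
    """Read a 3-6 column BED file into peaks (native 0-based half-open).

    Columns 4 and 5 map to ``name`` and ``score``; ``track``, ``browser``
    and ``#`` comment lines are skipped.  Malformed records raise
    :class:`FormatError` with the offending line number.
    """
    peaks: list[PeakInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric coordinate") from exc
            if start >= end or start < 0:
                raise FormatError(f"line {lineno}: invalid interval {start}..{end}")
            name = fields[3] if len(fields) > 3 else "."
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            peaks.append(PeakInterval(chrom, start, end, strand, name=name, score=score))
    return peaks


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    return format(score, "g")


def write_bed(peaks: Sequence[PeakInterval], path) -> None:
    """Write peaks as 5-column BED (6 columns when any peak is stranded)."""
    stranded = any(p.strand != "." for p in peaks)
    with open(path, "w") as fh:
        for p in peaks:
            cols = [p.chrom, str(p.start), str(p.end), p.name, _fmt_score(p.score)]
            if stranded:
                cols.append(p.strand)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

_TYPE_MAP = {
    "protein_coding": "coding",
    "coding": "coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "lnc_RNA": "lncRNA",
}


def _parse_attrs(text: str, dialect: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if dialect == "gtf":
        for chunk in text.strip().split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            key, _, val = chunk.partition(" ")
            attrs[key] = val.strip().strip('"')
    else:  # gff3
        for chunk in text.strip().split(";"):
            if not chunk:
                continue
            key, _, val = chunk.partition("=")
            attrs[key.strip()] = val.strip()
    return attrs


def read_gene_models(path, dialect: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF or GFF3.

    Requires ``gene`` records (locus span, strand, ``gene_id`` and
    ``gene_type``/``gene_biotype`` attributes) and attaches ``exon`` records
    by ``gene_id``.  1-based inclusive file coordinates become internal
    0-based half-open.  An exon lacking ``gene_id`` or falling outside its
    declared gene span raises :class:`FormatError`.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    genes: dict[str, dict] = {}
    exons: dict[str, list[GenomicInterval]] = defaultdict(list)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"line {lineno}: expected 9 columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attr_text = fields[:9]
            if feature not in ("gene", "transcript", "exon"):
                continue
            attrs = _parse_attrs(attr_text, dialect)
            gene_id = attrs.get("gene_id") or (attrs.get("ID") if feature == "gene" else None)
            if not gene_id:
                raise FormatError(f"line {lineno}: missing gene_id attribute")
            try:
                start = int(start1) - 1  # GTF/GFF3 are 1-based inclusive
                end = int(end1)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric coordinate") from exc
            if feature == "gene":
                raw_type = attrs.get("gene_type") or attrs.get("gene_biotype") or "other"
                genes[gene_id] = {
                    "locus": GenomicInterval(chrom, start, end, strand if strand in "+-" else "."),
                    "gene_type": _TYPE_MAP.get(raw_type, "other"),
                    "lineno": lineno,
                }
                order.append(gene_id)
            elif feature == "exon":
                exons[gene_id].append(GenomicInterval(chrom, start, end, strand if strand in "+-" else "."))
    models = []
    for gid in order:
        rec = genes[gid]
        try:
            models.append(
                GeneModel(gene_id=gid, gene_type=rec["gene_type"], locus=rec["locus"],
                          exons=tuple(exons.get(gid, ())))
            )
        except ValueError as exc:
            raise FormatError(f"gene {gid}: {exc}") from exc
    return models


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GTF (gene + exon records, 1-based inclusive)."""
    inv_type = {"coding": "protein_coding", "lncRNA": "lncRNA", "other": "other"}
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{inv_type[g.gene_type]}";'
            loc = g.locus
            fh.write("\t".join([loc.chrom, "erlnc", "gene", str(loc.start + 1), str(loc.end),
                                ".", loc.strand if loc.strand in "+-" else ".", ".", attrs]) + "\n")
            for ex in g.exons:
                fh.write("\t".join([ex.chrom, "erlnc", "exon", str(ex.start + 1), str(ex.end),
                                    ".", loc.strand if loc.strand in "+-" else ".", ".", attrs]) + "\n")
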