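"""Peak category assignment and random-placement permutation enrichment.

Peaks are assigned to one of four genomic categories (promoter, exonic,
intronic, intergenic) by their midpoint, with precedence promoter > exonic
> intronic > intergenic so that category fractions always sum to one.  The
null model re-places each peak uniformly across the genome (chromosome
drawn with probability proportional to its usable length, start uniform),
preserving peak lengths; enrichment is scored with a one-sided empirical
p-value with add-one correction, so p is bounded below by 1/(n_perm + 1).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .catalog import PromoterSpec, promoter_window
from .intervals import GeneModel, GenomicInterval, PeakInterval

__all__ = [
    "GenomeSpec",
    "EnrichmentResult",
    "CATEGORIES",
    "categorize_peak",
    "annotation_fractions",
    "randomize_peaks",
    "permutation_enrichment",
    "mark_overlap_enrichment",
]

CATEGORIES = ("promoter", "exonic", "intronic", "intergenic")


@dataclass(frozen=True)
class GenomeSpec:
    """Sampling space of the null: chromosome lengths plus excluded regions."""

    chrom_lengths: Mapping[str, int]
    excluded: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("empty genome")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"{chrom}: non-positive length")
        for iv in self.excluded:
            L = self.chrom_lengths.get(iv.chrom)
            if L is None or iv.end > L:
                raise ValueError(f"excluded region {iv} outside genome bounds")

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass
class EnrichmentResult:
    """Observed fraction vs the random-placement null."""

    observed_fraction: float
    null_fractions: np.ndarray
    p_empirical: float
    n_perm: int
    seed: int
    category: str | None = None

    @property
    def p_resolution(self) -> float:
        return 1.0 / (self.n_perm + 1)


def _merge(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Merge intervals into sorted disjoint (starts, ends) arrays."""
    if not intervals:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    intervals.sort()
    starts, ends = [], []
    cs, ce = intervals[0]
    for s, e in intervals[1:]:
        if s <= ce:
            ce = max(ce, e)
        else:
            starts.append(cs)
            ends.append(ce)
            cs, ce = s, e
    starts.append(cs)
    ends.append(ce)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _stab(starts: np.ndarray, ends: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Boolean membership of points in a merged disjoint interval set."""
    if starts.size == 0:
        return np.zeros(points.shape, dtype=bool)
    idx = np.searchsorted(starts, points, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(points.shape, dtype=bool)
    hit[ok] = points[ok] < ends[idx[ok]]
    return hit


class _CategoryIndex:
    """Merged per-chromosome coverage for promoter/exonic/genic classes."""

    def __init__(self, genes: Sequence[GeneModel], promoter: PromoterSpec):
        prom: dict[str, list] = {}
        exon: dict[str, list] = {}
        genic: dict[str, list] = {}
        for g in genes:
            w = promoter_window(g, promoter)
            prom.setdefault(w.chrom, []).append((w.start, w.end))
            genic.setdefault(g.locus.chrom, []).append((g.locus.start, g.locus.end))
            for ex in g.exons:
                exon.setdefault(ex.chrom, []).append((ex.start, ex.end))
        self.prom = {c: _merge(v) for c, v in prom.items()}
        self.exon = {c: _merge(v) for c, v in exon.items()}
        self.genic = {c: _merge(v) for c, v in genic.items()}

    def categorize_points(self, chroms: Sequence[str], points: np.ndarray) -> np.ndarray:
        """Category codes (index into CATEGORIES) for midpoints, vectorized."""
        points = np.asarray(points)
        codes = np.full(points.shape, 3, dtype=np.int8)  # intergenic
        chroms = np.asarray(chroms)
        for chrom in np.unique(chroms):
            m = chroms == chrom
            pts = points[m]
            empty = (np.empty(0, dtype=np.int64),) * 2
            in_prom = _stab(*self.prom.get(chrom, empty), pts)
            in_exon = _stab(*self.exon.get(chrom, empty), pts)
            in_gene = _stab(*self.genic.get(chrom, empty), pts)
            sub = np.full(pts.shape, 3, dtype=np.int8)
            sub[in_gene] = 2
            sub[in_exon] = 1
            sub[in_prom] = 0
            codes[m] = sub
        return codes


def categorize_peak(peak: GenomicInterval, genes: Sequence[GeneModel],
                    promoter: PromoterSpec = PromoterSpec()) -> str:
    """Category of the peak midpoint with promoter > exonic > intronic precedence."""
    index = genes if isinstance(genes, _CategoryIndex) else _CategoryIndex(genes, promoter)
    code = index.categorize_points([peak.chrom], np.asarray([peak.midpoint]))[0]
    return CATEGORIES[code]


def annotation_fractions(peaks: Sequence[GenomicInterval], genes: Sequence[GeneModel],
                         promoter: PromoterSpec = PromoterSpec()) -> dict[str, float]:
    """Fraction of peaks per category; exact count ratios, summing to 1."""
    if not peaks:
        raise ValueError("no peaks supplied")
    index = genes if isinstance(genes, _CategoryIndex) else _CategoryIndex(genes, promoter)
    codes = index.categorize_points([p.chrom for p in peaks],
                                    np.asarray([p.midpoint for p in peaks]))
    counts = np.bincount(codes, minlength=4)
    n = len(peaks)
    return {cat: int(c) / n for cat, c in zip(CATEGORIES, counts)}


# ---------------------------------------------------------------------------
# Null placement
# ---------------------------------------------------------------------------

def _segment_placement(seg_lengths: np.ndarray, peak_lengths: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Place peaks uniformly over segments, weights = usable length per segment.

    Returns (segment index, start offset within segment) per peak.  Segments
    shorter than a peak get zero weight for that peak.
    """
    K = seg_lengths.size
    n = peak_lengths.size
    # usable[k] = seg_lengths[k] - len + 1, clipped at 0, varies per peak
    usable = np.maximum(seg_lengths[None, :] - peak_lengths[:, None] + 1, 0)
    totals = usable.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("a peak is longer than every available segment")
    u = (rng.random(n) * totals).astype(np.int64)
    u = np.minimum(u, totals - 1)
    cum = np.cumsum(usable, axis=1)
    seg_idx = (u[:, None] >= cum).sum(axis=1)
    prev = np.where(seg_idx > 0, np.take_along_axis(cum, np.maximum(seg_idx - 1, 0)[:, None],
                                                    axis=1)[:, 0], 0)
    starts = u - prev
    return seg_idx, starts


def _excluded_by_chrom(genome: GenomeSpec) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list] = {}
    for iv in genome.excluded:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: _merge(v) for c, v in by_chrom.items()}


def _overlaps_merged(starts: np.ndarray, ends: np.ndarray,
                     s: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Any-bp overlap of [s, e) with a merged disjoint interval set."""
    if starts.size == 0:
        return np.zeros(s.shape, dtype=bool)
    return np.searchsorted(starts, e, side="left") > np.searchsorted(ends, s, side="right")


def _randomize_arrays(peak_lengths: np.ndarray, genome: GenomeSpec,
                      rng: np.random.Generator,
                      max_attempts: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome index and start per peak under the uniform-genome null."""
    chrom_names = list(genome.chrom_lengths)
    chrom_lengths = np.asarray([genome.chrom_lengths[c] for c in chrom_names], dtype=np.int64)
    excl = _excluded_by_chrom(genome)
    chrom_idx, starts = _segment_placement(chrom_lengths, peak_lengths, rng)
    if excl:
        bad = np.ones(peak_lengths.size, dtype=bool)
        for _ in range(max_attempts):
            bad_new = np.zeros(peak_lengths.size, dtype=bool)
            for ci, cname in enumerate(chrom_names):
                if cname not in excl:
                    continue
                m = chrom_idx == ci
                es, ee = excl[cname]
                bad_new[m] = _overlaps_merged(es, ee, starts[m], starts[m] + peak_lengths[m])
            bad = bad_new
            if not bad.any():
                break
            ridx, rstart = _segment_placement(chrom_lengths, peak_lengths[bad], rng)
            chrom_idx[bad], starts[bad] = ridx, rstart
        else:
            pass
        if bad.any():
            raise RuntimeError("could not place peaks outside excluded regions "
                               f"after {max_attempts} attempts")
    return chrom_idx, starts


def randomize_peaks(peaks: Sequence[GenomicInterval], genome: GenomeSpec,
                    seed: int) -> list[GenomicInterval]:
    """Independently re-place each peak uniformly, preserving its length."""
    rng = np.random.default_rng(seed)
    lengths = np.asarray([len(p) for p in peaks], dtype=np.int64)
    chrom_names = list(genome.chrom_lengths)
    chrom_idx, starts = _randomize_arrays(lengths, genome, rng)
    return [GenomicInterval(chrom_names[ci], int(s), int(s + L))
            for ci, s, L in zip(chrom_idx, starts, lengths)]


def _empirical_p(observed: float, null: np.ndarray) -> float:
    return (1 + int(np.sum(null >= observed))) / (null.size + 1)


def permutation_enrichment(peaks: Sequence[GenomicInterval], genes: Sequence[GeneModel],
                           promoter: PromoterSpec, category: str, genome: GenomeSpec,
                           n_perm: int = 1000, seed: int = 0) -> EnrichmentResult:
    """One-sided enrichment of a category fraction vs random placement.

    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    index = _CategoryIndex(genes, promoter)
    cat_code = CATEGORIES.index(category)
    obs = annotation_fractions(peaks, index, promoter)[category]
    rng = np.random.default_rng(seed)
    lengths = np.asarray([len(p) for p in peaks], dtype=np.int64)
    chrom_names = np.asarray(list(genome.chrom_lengths))
    n = lengths.size
    null = np.empty(n_perm)
    for i in range(n_perm):
        chrom_idx, starts = _randomize_arrays(lengths, genome, rng)
        mids = starts + lengths // 2
        codes = index.categorize_points(chrom_names[chrom_idx], mids)
        null[i] = np.sum(codes == cat_code) / n
    return EnrichmentResult(observed_fraction=obs, null_fractions=null,
                            p_empirical=_empirical_p(obs, null), n_perm=n_perm,
                            seed=seed, category=category)


def mark_overlap_enrichment(intergenic_peaks: Sequence[GenomicInterval],
                            mark_intervals: Sequence[GenomicInterval],
                            intergenic_space: Sequence[GenomicInterval],
                            n_perm: int = 1000, seed: int = 0) -> EnrichmentResult:
    """Enrichment of any-bp mark overlap among intergenic peaks.

    The null re-places whole peaks uniformly within the supplied intergenic
    segments (segment drawn with probability proportional to usable length).
    """
    if not intergenic_space:
        raise ValueError("empty intergenic space")
    if not intergenic_peaks:
        raise ValueError("no peaks supplied")
    segs = list(intergenic_space)
    seg_lengths = np.asarray([len(s) for s in segs], dtype=np.int64)
    marks_by_chrom: dict[str, list] = {}
    for iv in mark_intervals:
        marks_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {c: _merge(v) for c, v in marks_by_chrom.items()}

    def _frac(chroms: np.ndarray, starts: np.ndarray, lengths: np.ndarray) -> float:
        hit = np.zeros(starts.shape, dtype=bool)
        for chrom, (ms, me) in merged.items():
            m = chroms == chrom
            hit[m] = _overlaps_merged(ms, me, starts[m], starts[m] + lengths[m])
        return float(hit.mean())

    lengths = np.asarray([len(p) for p in intergenic_peaks], dtype=np.int64)
    obs = _frac(np.asarray([p.chrom for p in intergenic_peaks]),
                np.asarray([p.start for p in intergenic_peaks], dtype=np.int64), lengths)
    rng = np.random.default_rng(seed)
    seg_chroms = np.asarray([s.chrom for s in segs])
    seg_starts = np.asarray([s.start for s in segs], dtype=np.int64)
    null = np.empty(n_perm)
    for i in range(n_perm):
        seg_idx, offs = _segment_placement(seg_lengths, lengths, rng)
        null[i] = _frac(seg_chroms[seg_idx], seg_starts[seg_idx] + offs, lengths)
    return EnrichmentResult(observed_fraction=obs, null_fractions=null,
                            p_empirical=_empirical_p(obs, null), n_perm=n_perm,
                            seed=seed, category="mark_overlap")
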