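"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: a small two-
chromosome genome with coding and lncRNA gene models, receptor ChIP peaks
with configurable promoter enrichment, histone-mark interval sets, a
three-group expression matrix (benign / PCa / NEPC, 26/40/7 samples by
default) with planted up-regulated lncRNAs, a concept compendium with
planted associations, and a two-endpoint survival cohort with a marker-
dependent hazard.  All generators are pure functions of (config, seed);
one master seed fans out to per-generator child seeds by fixed offsets.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .catalog import ERE_FULL, PromoterSpec, promoter_window
from .diffexpr import ExpressionMatrix
from .enrichment import GenomeSpec, _merge, _overlaps_merged, _randomize_arrays
from .intervals import GeneModel, GenomicInterval, PeakInterval, write_bed, write_gene_models
from .prognosis import COVARIATE_NAMES, SurvivalCohort
from .signatures import Concept, write_concepts_tsv

__all__ = [
    "SimConfig",
    "GroundTruth",
    "child_seed",
    "gen_genome_and_annotation",
    "gen_peaks",
    "gen_marks",
    "gen_expression",
    "gen_concepts",
    "gen_cohort",
    "simulate_all",
    "write_fasta",
    "read_fasta",
]

# fixed offsets for master-seed fan-out
_OFFSETS = {"genome": 0, "peaks": 1, "marks": 2, "expression": 3,
            "concepts": 4, "cohort": 5, "ar_peaks": 6}


def child_seed(master_seed: int, stream: str) -> int:
    """Deterministic per-generator child seed (< 2**31)."""
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(_OFFSETS[stream],))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome, assay and cohort data.

    The three-group sample sizes (26/40/7), the 4-fold planted effect and
    the 594-patient cohort mirror the study design this pipeline emulates;
    the genome itself is a small desk-scale stand-in.
    """

    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 3_000_000,
                                                         "chr2": 3_000_000})
    n_coding: int = 250
    n_lncrna: int = 400
    frac_intergenic: float = 0.56
    coding_length: tuple[int, int] = (2_000, 6_000)
    lncrna_length: tuple[int, int] = (300, 3_000)
    n_exons: tuple[int, int] = (1, 3)
    promoter: PromoterSpec = field(default_factory=PromoterSpec)
    # receptor peaks
    n_peaks: int = 300
    peak_length: tuple[int, int] = (200, 400)
    promoter_enrichment: float = 0.5
    n_planted_er: int = 50
    ere_fraction: float = 0.9
    # expression
    group_sizes: tuple[int, int, int] = (26, 40, 7)
    group_labels: tuple[str, str, str] = ("benign", "PCa", "NEPC")
    de_fold: float = 4.0
    noise_sigma: float = 0.5
    base_log_mean: float = 1.5
    base_log_spread: float = 1.0
    # concepts
    universe_size: int = 10_000
    signature_size: int = 200
    concept_size: int = 200
    n_concepts: int = 30
    n_planted_concepts: int = 5
    planted_overlap: int = 100
    # cohort
    cohort_n: int = 594
    censoring_rate: float = 0.5
    marker_beta: float = 0.7
    baseline_hazard_bcr: float = 0.08
    baseline_hazard_met: float = 0.04
    followup_horizon: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_intergenic <= 1 and 0 <= self.promoter_enrichment <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        for n in (self.n_coding, self.n_lncrna, self.n_peaks, self.cohort_n):
            if n <= 0:
                raise ValueError("counts must be positive")


@dataclass
class GroundTruth:
    """Planted structure recorded by the generators (the recovery oracle)."""

    planted_er_lncrnas: set = field(default_factory=set)
    planted_de: dict = field(default_factory=dict)
    planted_concept_hits: set = field(default_factory=set)
    planted_signature: set = field(default_factory=set)
    ere_lncrnas: set = field(default_factory=set)
    true_marker_beta: float = 0.0
    seeds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "planted_er_lncrnas": sorted(self.planted_er_lncrnas),
            "planted_de": {f"{a}|{b}": sorted(v) for (a, b), v in self.planted_de.items()},
            "planted_concept_hits": sorted(self.planted_concept_hits),
            "planted_signature": sorted(self.planted_signature),
            "ere_lncrnas": sorted(self.ere_lncrnas),
            "true_marker_beta": self.true_marker_beta,
            "seeds": self.seeds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def _place_nonoverlapping(rng, chrom_lengths: dict, length: int,
                          occupied: dict, max_attempts: int = 10_000):
    chroms = list(chrom_lengths)
    weights = np.asarray([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(max_attempts):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        L = chrom_lengths[chrom]
        if L <= length:
            continue
        start = int(rng.integers(0, L - length))
        occ = occupied.setdefault(chrom, [])
        if occ:
            s_arr, e_arr = _merge(list(occ))
            if _overlaps_merged(s_arr, e_arr, np.asarray([start]),
                                np.asarray([start + length]))[0]:
                continue
        occ.append((start, start + length))
        return chrom, start
    raise RuntimeError(f"could not place a {length} bp gene after {max_attempts} attempts")


def _make_exons(rng, locus: GenomicInterval, n_exon_range: tuple[int, int]):
    n = int(rng.integers(n_exon_range[0], n_exon_range[1] + 1))
    L = len(locus)
    if n == 1 or L < 6 * n:
        return (locus,)
    # split the locus into 2n-1 blocks, alternating exon / intron
    cuts = np.sort(rng.choice(np.arange(1, L), size=2 * n - 2, replace=False))
    bounds = np.concatenate([[0], cuts, [L]])
    exons = []
    for i in range(0, 2 * n - 1, 2):
        s, e = int(bounds[i]), int(bounds[i + 1])
        if e > s:
            exons.append(GenomicInterval(locus.chrom, locus.start + s,
                                         locus.start + e, locus.strand))
    return tuple(exons)


def gen_genome_and_annotation(config: SimConfig, seed: int):
    """Generate (GenomeSpec, gene models, sequence, partial GroundTruth).

    Coding genes never overlap each other; each lncRNA is intergenic with
    probability ``frac_intergenic``, else placed to overlap a random coding
    gene.  The sequence is i.i.d. uniform A/C/G/T; a fraction of the planted
    receptor-target lncRNAs get an exact full ERE embedded mid-promoter.
    """
    footprint = (self_mean(config.coding_length) * config.n_coding
                 + self_mean(config.lncrna_length) * config.n_lncrna)
    if footprint >= 0.6 * sum(config.chrom_lengths.values()):
        raise ValueError("expected gene footprint exceeds 60% of the genome")
    rng = np.random.default_rng(seed)
    genome = GenomeSpec(chrom_lengths=dict(config.chrom_lengths))
    occupied: dict[str, list] = {}
    genes: list[GeneModel] = []
    for i in range(config.n_coding):
        length = int(rng.integers(*config.coding_length))
        chrom, start = _place_nonoverlapping(rng, config.chrom_lengths, length, occupied)
        strand = "+" if rng.random() < 0.5 else "-"
        locus = GenomicInterval(chrom, start, start + length, strand)
        genes.append(GeneModel(f"CODING{i:05d}", "coding", locus,
                               _make_exons(rng, locus, config.n_exons)))
    coding = list(genes)
    lnc_occupied = {c: list(v) for c, v in occupied.items()}
    for i in range(config.n_lncrna):
        length = int(rng.integers(*config.lncrna_length))
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < config.frac_intergenic:
            chrom, start = _place_nonoverlapping(rng, config.chrom_lengths, length,
                                                 lnc_occupied)
        else:  # overlap a random coding gene by at least 1 bp
            host = coding[int(rng.integers(len(coding)))]
            chrom = host.locus.chrom
            lo = max(0, host.locus.start - length + 1)
            hi = min(config.chrom_lengths[chrom] - length, host.locus.end - 1)
            start = int(rng.integers(lo, hi + 1))
        locus = GenomicInterval(chrom, start, start + length, strand)
        genes.append(GeneModel(f"LNC{i:05d}", "lncRNA", locus,
                               _make_exons(rng, locus, config.n_exons)))

    # pick planted receptor targets among intergenic lncRNAs
    coding_merged = {c: _merge([(g.locus.start, g.locus.end) for g in coding
                                if g.locus.chrom == c]) for c in config.chrom_lengths}
    intergenic_lnc = []
    for g in genes:
        if g.gene_type != "lncRNA":
            continue
        ms, me = coding_merged[g.locus.chrom]
        if not _overlaps_merged(ms, me, np.asarray([g.locus.start]),
                                np.asarray([g.locus.end]))[0]:
            intergenic_lnc.append(g)
    n_planted = min(config.n_planted_er, len(intergenic_lnc))
    planted_idx = rng.choice(len(intergenic_lnc), size=n_planted, replace=False)
    planted = [intergenic_lnc[i] for i in sorted(planted_idx)]

    # i.i.d. sequence with EREs embedded mid-promoter for a fraction of targets
    seq_arrays = {c: rng.integers(0, 4, size=L, dtype=np.int8)
                  for c, L in config.chrom_lengths.items()}
    ere_ids: set[str] = set()
    alphabet = np.frombuffer(b"ACGT", dtype=np.int8)
    motif = np.frombuffer(ERE_FULL.replace("N", "A").encode(), dtype=np.int8)
    motif_codes = np.searchsorted(alphabet, motif)
    for g in planted:
        if rng.random() >= config.ere_fraction:
            continue
        prom = promoter_window(g, config.promoter,
                               chrom_length=config.chrom_lengths[g.locus.chrom])
        mid = prom.midpoint
        arr = seq_arrays[g.locus.chrom]
        if 0 <= mid and mid + len(motif_codes) <= arr.size:
            arr[mid:mid + len(motif_codes)] = motif_codes
            ere_ids.add(g.gene_id)
    lut = np.frombuffer(b"ACGT", dtype="S1")
    sequence = {c: arr.astype(np.uint8) for c, arr in seq_arrays.items()}
    sequence = {c: lut[a].tobytes().decode() for c, a in sequence.items()}

    truth = GroundTruth(planted_er_lncrnas={g.gene_id for g in planted},
                        ere_lncrnas=ere_ids, seeds={"genome": seed})
    return genome, genes, sequence, truth


def self_mean(pair: tuple[int, int]) -> float:
    return (pair[0] + pair[1]) / 2.0


# ---------------------------------------------------------------------------
# peaks and marks
# ---------------------------------------------------------------------------

def gen_peaks(genes: Sequence[GeneModel], genome: GenomeSpec, config: SimConfig,
              seed: int, target_ids: set | None = None,
              prefix: str = "peak") -> tuple[list[PeakInterval], set]:
    """Receptor peaks: promoter-targeted with probability ``promoter_enrichment``.

    A targeted peak is centred uniformly within a random planted-target
    promoter window; the rest are placed by the uniform-genome null.  Scores
    are peak-caller-style p-values drawn so targeted peaks rank first.
    Returns the peaks and the ids of the lncRNAs that actually received a
    targeted peak.
    """
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in genes}
    targets = sorted(target_ids or ())
    hit_ids: set[str] = set()
    peaks: list[PeakInterval] = []
    chrom_names = list(genome.chrom_lengths)
    lengths = rng.integers(config.peak_length[0], config.peak_length[1] + 1,
                           size=config.n_peaks).astype(np.int64)
    planted_mask = (rng.random(config.n_peaks) < config.promoter_enrichment) \
        if targets else np.zeros(config.n_peaks, dtype=bool)
    bg_idx, bg_starts = _randomize_arrays(lengths[~planted_mask], genome, rng)
    bg_iter = iter(zip(bg_idx, bg_starts))
    for i in range(config.n_peaks):
        L = int(lengths[i])
        if planted_mask[i]:
            gid = targets[int(rng.integers(len(targets)))]
            g = by_id[gid]
            prom = promoter_window(g, config.promoter,
                                   chrom_length=genome.chrom_lengths[g.locus.chrom])
            centre = int(rng.integers(prom.start, prom.end))
            start = max(0, centre - L // 2)
            start = min(start, genome.chrom_lengths[g.locus.chrom] - L)
            chrom = g.locus.chrom
            score = 10.0 ** (-rng.uniform(6, 12))
            hit_ids.add(gid)
        else:
            ci, start = next(bg_iter)
            chrom, start = chrom_names[ci], int(start)
            score = 10.0 ** (-rng.uniform(1, 5))
        peaks.append(PeakInterval(chrom, start, start + L, ".",
                                  name=f"{prefix}{i:05d}", score=score))
    return peaks, hit_ids


def gen_marks(genes: Sequence[GeneModel], genome: GenomeSpec, config: SimConfig,
              seed: int, active_ids: set | None = None) -> dict:
    """Histone-mark interval sets.

    Active marks follow transcription: H3K4me3 covers the promoters and
    H3K36me3 the bodies of the 'active' genes (the planted targets plus a
    random fifth of the rest).  Repressive marks are random placements.
    """
    rng = np.random.default_rng(seed)
    active_ids = set(active_ids or ())
    k4, k36 = [], []
    for g in genes:
        active = g.gene_id in active_ids or rng.random() < 0.2
        if not active:
            continue
        prom = promoter_window(g, config.promoter,
                               chrom_length=genome.chrom_lengths[g.locus.chrom])
        k4.append(GenomicInterval(prom.chrom, prom.start, prom.end))
        k36.append(GenomicInterval(g.locus.chrom, g.locus.start, g.locus.end))
    rep_lengths = rng.integers(500, 2_000, size=120).astype(np.int64)
    ci, starts = _randomize_arrays(rep_lengths, genome, rng)
    chrom_names = list(genome.chrom_lengths)
    rep = [GenomicInterval(chrom_names[c], int(s), int(s + L))
           for c, s, L in zip(ci, starts, rep_lengths)]
    return {"H3K4me3": k4, "H3K36me3": k36,
            "H3K9me3": rep[:60], "H3K27me3": rep[60:]}


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gen_expression(genes: Sequence[GeneModel], config: SimConfig, seed: int,
                   planted_ids: set | None = None) -> tuple[ExpressionMatrix, GroundTruth]:
    """Lognormal three-group expression with planted fold change in PCa.

    Baseline per-feature means are lognormal; planted features are
    multiplied by ``de_fold`` in the PCa group only, so they are up in
    PCa vs benign and down in NEPC vs PCa.
    """
    rng = np.random.default_rng(seed)
    feature_ids = [g.gene_id for g in genes if g.gene_type == "lncRNA"]
    planted = set(planted_ids or ())
    n_b, n_p, n_n = config.group_sizes
    labels = config.group_labels
    sample_ids = ([f"benign{i:03d}" for i in range(n_b)]
                  + [f"pca{i:03d}" for i in range(n_p)]
                  + [f"nepc{i:03d}" for i in range(n_n)])
    group = dict(zip(sample_ids, [labels[0]] * n_b + [labels[1]] * n_p + [labels[2]] * n_n))
    n_feat, n_samp = len(feature_ids), len(sample_ids)
    mu = rng.normal(config.base_log_mean, config.base_log_spread, size=n_feat)
    values = np.exp(mu[:, None] + config.noise_sigma * rng.standard_normal((n_feat, n_samp)))
    pca_cols = np.arange(n_b, n_b + n_p)
    planted_rows = [i for i, f in enumerate(feature_ids) if f in planted]
    values[np.ix_(planted_rows, pca_cols)] *= config.de_fold
    matrix = ExpressionMatrix(feature_ids, sample_ids, values, group)
    truth = GroundTruth(planted_de={(labels[0], labels[1]): set(planted)},
                        seeds={"expression": seed})
    return matrix, truth


# ---------------------------------------------------------------------------
# concepts
# ---------------------------------------------------------------------------

def gen_concepts(config: SimConfig, seed: int) -> tuple[list[Concept], object, GroundTruth]:
    """Concept compendium with planted signature associations.

    Returns (concepts, signature, truth).  Planted concepts draw
    ``planted_overlap`` genes from the planted signature and the rest
    uniformly; null concepts are uniform draws from the universe.
    """
    rng = np.random.default_rng(seed)
    universe = [f"G{i:05d}" for i in range(config.universe_size)]
    sig_idx = rng.choice(config.universe_size, size=config.signature_size, replace=False)
    signature_genes = frozenset(universe[i] for i in sig_idx)
    sig_list = sorted(signature_genes)
    non_sig = sorted(set(universe) - signature_genes)
    concepts: list[Concept] = []
    planted_names: set[str] = set()
    for i in range(config.n_concepts):
        name = f"concept{i:03d}"
        if i < config.n_planted_concepts:
            k = min(config.planted_overlap, len(sig_list))
            from_sig = rng.choice(len(sig_list), size=k, replace=False)
            rest = rng.choice(len(non_sig), size=config.concept_size - k, replace=False)
            genes = frozenset([sig_list[j] for j in from_sig]
                              + [non_sig[j] for j in rest])
            planted_names.add(name)
        else:
            idx = rng.choice(config.universe_size, size=config.concept_size, replace=False)
            genes = frozenset(universe[j] for j in idx)
        concepts.append(Concept(name=name, genes=genes,
                                direction="over" if rng.random() < 0.7 else "under",
                                tumor_type="prostate" if rng.random() < 0.5 else "other"))
    from .signatures import GeneSignature
    signature = GeneSignature(name="planted_signature", genes=signature_genes)
    truth = GroundTruth(planted_concept_hits=planted_names,
                        planted_signature=set(signature_genes),
                        seeds={"concepts": seed})
    return concepts, signature, truth


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

def _uniform_censor_bound(hazards: np.ndarray, target: float) -> float:
    """Upper bound c for C ~ U(0, c) giving the target censoring probability.

    For T ~ Exp(h), P(censored) = E[(1 - exp(-h c)) / (h c)] averaged over
    the per-subject hazards; monotone decreasing in c.
    """
    def censored_prob(c):
        x = hazards * c
        return float(np.mean((1 - np.exp(-x)) / x)) - target
    return brentq(censored_prob, 1e-6, 1e6)


def gen_cohort(config: SimConfig, seed: int) -> tuple[SurvivalCohort, GroundTruth]:
    """Survival cohort with a bimodal marker and marker-dependent hazards.

    Event times are exponential with hazard ``h0 * exp(beta * high)``;
    censoring is independent uniform, calibrated to the configured rate,
    with administrative follow-up capped at the horizon.  Binary endpoints
    are event-by-horizon; GS>7 and PCSM are marker-dependent Bernoulli.
    """
    rng = np.random.default_rng(seed)
    n = config.cohort_n
    high = rng.random(n) < 0.5
    marker = np.where(high, rng.normal(8.0, 1.0, n), rng.normal(5.0, 1.0, n))
    beta = config.marker_beta
    out = {"id": [f"pt{i:04d}" for i in range(n)], "marker_expression": marker}
    for ep, h0 in (("bcr", config.baseline_hazard_bcr),
                   ("met", config.baseline_hazard_met)):
        hazards = h0 * np.exp(beta * high.astype(float))
        T = rng.exponential(1.0 / hazards)
        if 0 < config.censoring_rate < 1:
            c_max = _uniform_censor_bound(hazards, config.censoring_rate)
            C = rng.uniform(0, c_max, n)
        else:
            C = np.full(n, np.inf) if config.censoring_rate == 0 else np.zeros(n)
        C = np.minimum(C, config.followup_horizon)
        out[f"time_{ep}"] = np.minimum(T, C)
        out[f"event_{ep}"] = (T <= C).astype(int)
    out["event_pcsm"] = (rng.random(n) <
                         _sigmoid(-2.2 + beta * high.astype(float))).astype(int)
    out["gs_gt7"] = (rng.random(n) <
                     _sigmoid(-1.0 + beta * high.astype(float))).astype(int)
    probs = {"pT3plus": 0.3, "LNI": 0.1, "SMS": 0.25, "SVI": 0.15, "ECE": 0.35,
             "adjuvant_radiation": 0.15, "adjuvant_hormone": 0.2}
    for cov, p in probs.items():
        out[cov] = (rng.random(n) < p).astype(int)
    out["pPSA"] = np.exp(rng.normal(np.log(10.0), 0.5, n))
    cohort = SurvivalCohort(pd.DataFrame(out))
    truth = GroundTruth(true_marker_beta=beta, seeds={"cohort": seed})
    return cohort, truth


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# FASTA + one-call driver
# ---------------------------------------------------------------------------

def write_fasta(sequence: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sequence:
            fh.write(f">{chrom}\n")
            seq = sequence[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def simulate_all(config: SimConfig, seed: int, outdir=None):
    """Run every generator off one master seed; optionally write the files.

    Returns a dict of in-memory objects plus the merged ground truth.  With
    ``outdir`` set, writes genes.gtf, er/ar peak BEDs, per-mark BEDs,
    genome.fa, chrom_sizes.tsv, expression/groups TSVs, concepts.tsv,
    cohort.tsv and ground_truth.json.
    """
    genome, genes, sequence, truth = gen_genome_and_annotation(
        config, child_seed(seed, "genome"))
    er_peaks, er_hit = gen_peaks(genes, genome, config, child_seed(seed, "peaks"),
                                 target_ids=truth.planted_er_lncrnas, prefix="er")
    ar_targets = set(sorted(truth.planted_er_lncrnas)[: len(truth.planted_er_lncrnas) // 2])
    ar_cfg = replace(config, promoter_enrichment=config.promoter_enrichment / 2)
    ar_peaks, _ = gen_peaks(genes, genome, ar_cfg, child_seed(seed, "ar_peaks"),
                            target_ids=ar_targets, prefix="ar")
    marks = gen_marks(genes, genome, config, child_seed(seed, "marks"),
                      active_ids=truth.planted_er_lncrnas)
    matrix, expr_truth = gen_expression(genes, config, child_seed(seed, "expression"),
                                        planted_ids=truth.planted_er_lncrnas)
    concepts, signature, concept_truth = gen_concepts(config, child_seed(seed, "concepts"))
    cohort, cohort_truth = gen_cohort(config, child_seed(seed, "cohort"))

    truth.planted_de = expr_truth.planted_de
    truth.planted_concept_hits = concept_truth.planted_concept_hits
    truth.planted_signature = concept_truth.planted_signature
    truth.true_marker_beta = cohort_truth.true_marker_beta
    truth.seeds.update({**expr_truth.seeds, **concept_truth.seeds,
                        **cohort_truth.seeds, "master": seed})

    data = {"genome": genome, "genes": genes, "sequence": sequence,
            "er_peaks": er_peaks, "ar_peaks": ar_peaks, "marks": marks,
            "expression": matrix, "concepts": concepts, "signature": signature,
            "cohort": cohort, "truth": truth}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_models(genes, outdir / "genes.gtf")
        write_bed(er_peaks, outdir / "er_peaks.bed")
        write_bed(ar_peaks, outdir / "ar_peaks.bed")
        for mark, ivs in marks.items():
            write_bed([PeakInterval(iv.chrom, iv.start, iv.end, name=f"{mark}_{i}")
                       for i, iv in enumerate(ivs)], outdir / f"{mark}.bed")
        write_fasta(sequence, outdir / "genome.fa")
        pd.Series(genome.chrom_lengths, name="length").rename_axis("chrom") \
            .to_csv(outdir / "chrom_sizes.tsv", sep="\t")
        matrix.to_frame().rename_axis("feature_id") \
            .to_csv(outdir / "expression.tsv", sep="\t")
        pd.Series(matrix.group, name="group").rename_axis("sample_id") \
            .to_csv(outdir / "groups.tsv", sep="\t")
        write_concepts_tsv(concepts, outdir / "concepts.tsv")
        cohort.to_tsv(outdir / "cohort.tsv")
        truth.to_json(outdir / "ground_truth.json")
    return data
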