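"""End-to-end orchestration: files in, candidate/enrichment/network/prognosis out.

``run_pipeline`` reads every input from paths declared in a
:class:`PipelineConfig`, executes the stages (catalog annotation, binding
enrichment, differential expression, nomination, concept network, marker
prognosis) and writes their outputs plus a machine-readable provenance
record into a run directory.  Stage outputs are identical to invoking the
stage functions directly with the same inputs and seed; a stage failure
removes the partially written run directory and re-raises with the stage
name.
"""
from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import (PromoterSpec, annotate_catalog, annotation_table,
                      assemble_catalog)
from .diffexpr import ExpressionMatrix, NominationCriteria, nominate_candidates, pairwise_de
from .enrichment import GenomeSpec, annotation_fractions, mark_overlap_enrichment, \
    permutation_enrichment
from .intervals import GenomicInterval, read_bed, read_gene_models
from .prognosis import SurvivalCohort, evaluate_marker
from .signatures import build_concept_network, read_concepts_tsv, GeneSignature
from .simulate import read_fasta

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("erlnc")


@dataclass
class PipelineConfig:
    """Paths and settings for a full run (all paths checked before compute)."""

    genes_gtf: str
    er_bed: str
    expression_tsv: str
    groups_tsv: str
    chrom_sizes_tsv: str
    ar_bed: str | None = None
    marks: dict = field(default_factory=dict)  # mark name -> BED path
    genome_fasta: str | None = None
    concepts_tsv: str | None = None
    cohort_tsv: str | None = None
    promoter: PromoterSpec = field(default_factory=PromoterSpec)
    criteria: NominationCriteria = field(default_factory=NominationCriteria)
    contrasts: tuple = (("benign", "PCa"), ("PCa", "NEPC"))
    enrichment_category: str = "intergenic"
    n_perm: int = 1000
    signature_or_min: float = 2.0
    signature_p_max: float = 1e-6
    cohort_train_frac: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "promoter" in raw:
            raw["promoter"] = PromoterSpec(**raw["promoter"])
        if "criteria" in raw:
            crit = raw["criteria"]
            if "contrast" in crit:
                crit["contrast"] = tuple(crit["contrast"])
            raw["criteria"] = NominationCriteria(**crit)
        if "contrasts" in raw:
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        return cls(**raw)

    def validate_paths(self) -> None:
        required = {"genes_gtf": self.genes_gtf, "er_bed": self.er_bed,
                    "expression_tsv": self.expression_tsv,
                    "groups_tsv": self.groups_tsv,
                    "chrom_sizes_tsv": self.chrom_sizes_tsv}
        optional = {"ar_bed": self.ar_bed, "genome_fasta": self.genome_fasta,
                    "concepts_tsv": self.concepts_tsv, "cohort_tsv": self.cohort_tsv,
                    **{f"marks[{k}]": v for k, v in self.marks.items()}}
        for label, path in {**required, **optional}.items():
            if label in required and path is None:
                raise FileNotFoundError(f"config is missing required input {label}")
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label}: no such file {path!r}")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in vars(obj).items() if not k.startswith("_")}
    return str(obj)


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute every configured stage and write the run directory.

    Always produced: candidates.tsv, catalog.tsv, de.tsv, enrich.json,
    provenance.json, run.log.  network.graphml and prognosis.json are
    produced when the concept compendium / cohort inputs are configured.
    """
    config.validate_paths()
    outdir = Path(outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "setup"
    try:
        stage = "inputs"
        genes = read_gene_models(config.genes_gtf, "gtf")
        coding = [g for g in genes if g.gene_type == "coding"]
        lnc_sources = [[g for g in genes if g.gene_type == "lncRNA"]]
        er_peaks = read_bed(config.er_bed)
        ar_peaks = read_bed(config.ar_bed) if config.ar_bed else []
        marks = {name: [GenomicInterval(p.chrom, p.start, p.end)
                        for p in read_bed(path)]
                 for name, path in config.marks.items()}
        sizes = pd.read_csv(config.chrom_sizes_tsv, sep="\t", index_col=0)
        genome = GenomeSpec(chrom_lengths=sizes.iloc[:, 0].to_dict())
        genome_seq = read_fasta(config.genome_fasta) if config.genome_fasta else None
        matrix = ExpressionMatrix.from_tsv(config.expression_tsv, config.groups_tsv)

        stage = "catalog"
        catalog = assemble_catalog(lnc_sources, source_names=["genes_gtf"])
        annotated = annotate_catalog(catalog, er_peaks, ar_peaks, marks,
                                     coding=coding, genome_seq=genome_seq,
                                     promoter=config.promoter)
        annotation_table(annotated).to_csv(outdir / "catalog.tsv", sep="\t", index=False)
        log.info("catalog: %d lncRNAs, %d intergenic", len(annotated),
                 sum(a.intergenic for a in annotated))

        stage = "enrichment"
        enr = permutation_enrichment(er_peaks, genes, config.promoter,
                                     config.enrichment_category, genome,
                                     n_perm=config.n_perm, seed=config.seed)
        fractions = annotation_fractions(er_peaks, genes, config.promoter)
        enrich_out = {"fractions": fractions, "category": enr.category,
                      "observed_fraction": enr.observed_fraction,
                      "null_mean": float(enr.null_fractions.mean()),
                      "p_empirical": enr.p_empirical,
                      "p_resolution": enr.p_resolution,
                      "n_perm": enr.n_perm, "seed": enr.seed}
        (outdir / "enrich.json").write_text(json.dumps(enrich_out, indent=1,
                                                       default=_json_default))
        log.info("enrichment: %s fraction %.3f p=%.4g", enr.category,
                 enr.observed_fraction, enr.p_empirical)

        stage = "differential expression"
        de = pairwise_de(matrix, list(config.contrasts), fdr_max=config.criteria.fdr_max)
        pd.DataFrame([{"feature_id": r.feature_id,
                       "contrast": f"{r.contrast[0]}|{r.contrast[1]}",
                       "statistic": r.statistic, "p_raw": r.p_raw,
                       "q_bh": r.q_bh, "direction": r.direction,
                       "log2fc": r.log2fc} for r in de]) \
            .to_csv(outdir / "de.tsv", sep="\t", index=False,
                    float_format="%.6g")

        stage = "nomination"
        candidates = nominate_candidates(annotated, de, config.criteria)
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False,
                          float_format="%.6g")
        log.info("nomination: %d candidates", len(candidates))

        if config.concepts_tsv:
            stage = "concept network"
            concepts = read_concepts_tsv(config.concepts_tsv)
            sig_genes = frozenset(candidates["feature_id"]) if len(candidates) else frozenset()
            signature = GeneSignature(name="nominated", genes=sig_genes)
            network = build_concept_network(signature, concepts,
                                            or_min=config.signature_or_min,
                                            p_max=config.signature_p_max)
            network.write_graphml(outdir / "network.graphml")
            network.write_sif(outdir / "network.sif")
            log.info("network: %d passing concepts", len(network.associations))

        if config.cohort_tsv:
            stage = "prognosis"
            cohort = SurvivalCohort.from_tsv(config.cohort_tsv)
            rng = np.random.default_rng(config.seed)
            n = len(cohort)
            train_mask = np.zeros(n, dtype=bool)
            train_mask[rng.choice(n, size=int(round(config.cohort_train_frac * n)),
                                  replace=False)] = True
            train = SurvivalCohort(cohort.table[train_mask].reset_index(drop=True))
            test = SurvivalCohort(cohort.table[~train_mask].reset_index(drop=True))
            report = evaluate_marker(train, test, covariates=cohort.covariates)
            (outdir / "prognosis.json").write_text(
                json.dumps(report, indent=1, default=_json_default))
            log.info("prognosis: endpoints %s", sorted(report))

        stage = "provenance"
        provenance = {"config_hash": config.content_hash(), "seed": config.seed,
                      "erlnc_version": __version__,
                      "config": asdict(config)}
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=1, sort_keys=True, default=str))
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        log.removeHandler(handler)
        handler.close()
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    log.removeHandler(handler)
    handler.close()
    return outdir
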