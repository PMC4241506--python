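"""Fold-change signatures, concept (gene-set) enrichment and correlations.

A signature is the set of genes whose log2 fold change between two
conditions strictly exceeds a threshold (default > 2).  Concepts are named
gene sets; the association between a signature and a concept is a 2x2
contingency table scored by an odds ratio (Haldane 0.5 correction on zero
cells) and a one-sided Fisher exact p (hypergeometric tail).  Passing
associations are exported as a hub-and-spoke network with the attributes a
graph tool needs for rendering (size, direction, tumor type, OR, p).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSignature",
    "Concept",
    "ConceptAssociation",
    "ConceptNetwork",
    "fold_change_signature",
    "top_k",
    "concept_association",
    "build_concept_network",
    "correlated_gene_set",
    "intersect_signatures",
    "paired_logfc_correlation",
    "read_concepts_tsv",
    "write_concepts_tsv",
]


@dataclass
class GeneSignature:
    name: str
    genes: frozenset[str]
    source_contrast: str = ""
    threshold: float | None = None

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class Concept:
    """A named over/under-expression gene set from one dataset comparison."""

    name: str
    genes: frozenset[str]
    direction: str = "over"
    tumor_type: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"concept {self.name!r} is empty")
        if self.direction not in ("over", "under"):
            raise ValueError(f"invalid direction {self.direction!r}")


@dataclass
class ConceptAssociation:
    concept: Concept
    odds_ratio: float
    p_value: float
    a: int  # |signature ∩ concept|
    b: int  # |signature \ concept|
    c: int  # |concept \ signature|
    d: int  # |universe \ (signature ∪ concept)|


@dataclass
class ConceptNetwork:
    graph: nx.Graph
    hub: str
    associations: list[ConceptAssociation]

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_sif(self, path) -> None:
        with open(path, "w") as fh:
            for u, v in sorted(self.graph.edges()):
                fh.write(f"{u}\tassociated_with\t{v}\n")


def fold_change_signature(expr_a: Mapping[str, float] | pd.Series,
                          expr_b: Mapping[str, float] | pd.Series,
                          name: str = "signature",
                          log2fc_min: float = 2.0,
                          pseudocount: float = 1.0) -> GeneSignature:
    """Genes with log2((b + pc)/(a + pc)) strictly greater than the threshold.

    Per-condition values are already summarized (mean over replicates, or a
    single sample's value for cell-line comparisons).
    """
    a = pd.Series(expr_a, dtype=float)
    b = pd.Series(expr_b, dtype=float)
    if set(a.index) != set(b.index):
        raise ValueError("conditions must cover the same feature set")
    b = b.reindex(a.index)
    log2fc = np.log2((b + pseudocount) / (a + pseudocount))
    genes = frozenset(log2fc.index[log2fc > log2fc_min])
    return GeneSignature(name=name, genes=genes, threshold=log2fc_min)


def top_k(signature_scores: Mapping[str, float] | pd.Series, k: int = 1000,
          name: str = "top_k") -> GeneSignature:
    """The k highest-scoring genes (ties broken by gene id, ascending)."""
    s = pd.Series(signature_scores, dtype=float)
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return GeneSignature(name=name, genes=frozenset(order[:k]))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:  # Haldane-Anscombe correction
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def concept_association(signature: GeneSignature, concept: Concept,
                        universe: frozenset[str] | set[str]) -> ConceptAssociation:
    """2x2 association between a signature and a concept within a universe.

    p is the one-sided (enrichment) Fisher exact probability, i.e. the upper
    hypergeometric tail P(X >= a) with X ~ Hypergeom(N=|U|, K=|concept|,
    n=|signature|).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    sig = signature.genes & universe
    con = concept.genes & universe
    a = len(sig & con)
    b = len(sig - con)
    c = len(con - sig)
    d = len(universe) - a - b - c
    p = float(stats.hypergeom.sf(a - 1, len(universe), len(con), len(sig)))
    return ConceptAssociation(concept=concept, odds_ratio=_odds_ratio(a, b, c, d),
                              p_value=min(p, 1.0), a=a, b=b, c=c, d=d)


def build_concept_network(signature: GeneSignature, concepts: Sequence[Concept],
                          or_min: float = 2.0, p_max: float = 1e-6,
                          universe: frozenset[str] | None = None) -> ConceptNetwork:
    """Hub-and-spoke network of concepts passing OR/p filters.

    The universe defaults to the union of all concept genes plus the
    signature.  Node attributes: size, direction, tumor_type; edge
    attributes: odds_ratio (weight), p_value.  Node order is deterministic
    (concept name).
    """
    if universe is None:
        universe = frozenset(signature.genes).union(*(c.genes for c in concepts)) \
            if concepts else frozenset(signature.genes)
    g = nx.Graph()
    g.add_node(signature.name, size=len(signature.genes), kind="signature")
    passing: list[ConceptAssociation] = []
    for concept in sorted(concepts, key=lambda c: c.name):
        assoc = concept_association(signature, concept, universe)
        if assoc.odds_ratio > or_min and assoc.p_value < p_max:
            passing.append(assoc)
            g.add_node(concept.name, size=len(concept.genes), kind="concept",
                       direction=concept.direction, tumor_type=concept.tumor_type)
            g.add_edge(signature.name, concept.name, weight=assoc.odds_ratio,
                       odds_ratio=assoc.odds_ratio, p_value=assoc.p_value)
    return ConceptNetwork(graph=g, hub=signature.name, associations=passing)


def correlated_gene_set(matrix, target_feature: str, r_min: float = 0.5,
                        method: str = "pearson") -> GeneSignature:
    """Features whose expression correlates with the target strictly above r_min.

    ``matrix`` is an :class:`~erlnc.diffexpr.ExpressionMatrix`; the target
    itself is excluded from the result.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if target_feature not in matrix.feature_ids:
        raise KeyError(target_feature)
    if len(matrix.sample_ids) < 3:
        raise ValueError("need >= 3 samples")
    values = matrix.values
    t_idx = matrix.feature_ids.index(target_feature)
    target = values[t_idx]
    if np.all(target == target[0]):
        raise ValueError("zero-variance target feature")
    if method == "spearman":
        values = stats.rankdata(values, axis=1)
        target = stats.rankdata(target)
    vc = values - values.mean(axis=1, keepdims=True)
    tc = target - target.mean()
    denom = np.sqrt((vc ** 2).sum(axis=1) * (tc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ tc) / denom
    keep = [fid for i, fid in enumerate(matrix.feature_ids)
            if i != t_idx and np.isfinite(r[i]) and r[i] > r_min]
    return GeneSignature(name=f"corr_{target_feature}", genes=frozenset(keep),
                         threshold=r_min)


def intersect_signatures(a: GeneSignature, b: GeneSignature) -> GeneSignature:
    return GeneSignature(name=f"{a.name}&{b.name}", genes=a.genes & b.genes)


def paired_logfc_correlation(paired_tumour: Mapping[str, Sequence[float]] | pd.DataFrame,
                             paired_benign: Mapping[str, Sequence[float]] | pd.DataFrame,
                             feature_a: str, feature_b: str,
                             method: str = "pearson",
                             pseudocount: float = 1.0) -> float:
    """Correlation of per-pair log2 fold changes between two features.

    Each column map holds per-feature vectors over matched tumour/benign
    pairs; the log2((tumour + pc)/(benign + pc)) vectors of the two features
    are correlated (Pearson or Spearman).
    """
    tum = pd.DataFrame(paired_tumour, dtype=float)
    ben = pd.DataFrame(paired_benign, dtype=float)
    for f in (feature_a, feature_b):
        if f not in tum.columns or f not in ben.columns:
            raise KeyError(f)
    if len(tum) != len(ben) or len(tum) < 3:
        raise ValueError("need >= 3 matched pairs")
    fc = np.log2((tum[[feature_a, feature_b]].to_numpy() + pseudocount)
                 / (ben[[feature_a, feature_b]].to_numpy() + pseudocount))
    if method == "pearson":
        return float(stats.pearsonr(fc[:, 0], fc[:, 1]).statistic)
    if method == "spearman":
        return float(stats.spearmanr(fc[:, 0], fc[:, 1]).statistic)
    raise ValueError(f"unknown method {method!r}")


def read_concepts_tsv(path) -> list[Concept]:
    """Concept compendium TSV: concept_name, direction, tumor_type, gene_id."""
    df = pd.read_csv(path, sep="\t")
    concepts = []
    for (name, direction, tumor), sub in df.groupby(
            ["concept_name", "direction", "tumor_type"], sort=True):
        concepts.append(Concept(name=name, genes=frozenset(sub["gene_id"]),
                                direction=direction, tumor_type=tumor))
    return concepts


def write_concepts_tsv(concepts: Sequence[Concept], path) -> None:
    rows = [(c.name, c.direction, c.tumor_type, g)
            for c in concepts for g in sorted(c.genes)]
    pd.DataFrame(rows, columns=["concept_name", "direction", "tumor_type", "gene_id"]) \
        .to_csv(path, sep="\t", index=False)
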