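"""Pathway over-representation per cluster and a randomized-cluster null.

Each cluster contributes a gene set (by default its *enriched* target
genes); every pathway in a GMT-style collection is then tested for
over-representation of that set against the annotation gene universe with
a one-tailed Fisher's exact test, and p-values are Holm-adjusted across
pathways within the cluster.

To check that clusters capture pathway-coherent pharmacology rather than
multiplicity artifacts, ``randomized_pathway_null`` permutes compounds
across the fixed cluster-size partition, reruns the whole gene-set
derivation and pathway testing, and counts significant pathways per
replicate: real data should beat the null distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import ContingencyTable, fisher_one_tailed, enrich_clusters
from .som import ClusterAssignment

logger = logging.getLogger(__name__)


@dataclass
class PathwayCollection:
    """Named gene sets over a gene universe (GMT semantics)."""

    gene_sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.gene_sets.items():
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")
        members = set().union(*self.gene_sets.values()) if self.gene_sets else set()
        if not self.universe:
            self.universe = set(members)
        elif not members <= self.universe:
            raise ValueError("pathway genes outside the declared universe")

    def __len__(self) -> int:
        return len(self.gene_sets)

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.gene_sets):
                desc = self.descriptions.get(name, "na")
                genes = "\t".join(sorted(self.gene_sets[name]))
                fh.write(f"{name}\t{desc}\t{genes}\n")

    @classmethod
    def read_gmt(cls, path, universe: set[str] | None = None) -> "PathwayCollection":
        gene_sets: dict[str, set[str]] = {}
        descriptions: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                gene_sets[parts[0]] = {g for g in parts[2:] if g}
                descriptions[parts[0]] = parts[1]
        return cls(gene_sets, universe or set(), descriptions)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    adjusted_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)) over the
    ascending order statistics; controls family-wise error rate.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    scaled = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted_sorted = np.maximum.accumulate(scaled)
    adjusted = np.empty_like(p)
    adjusted[order] = adjusted_sorted
    return adjusted


def pathway_enrichment(cluster_genes, collection: PathwayCollection) -> pd.DataFrame:
    """Test each pathway for over-representation of the cluster's genes.

    The 2x2 table counts genes of the universe by (in/out cluster set) x
    (in/out pathway); the upper-tail Fisher p is Holm-adjusted across the
    pathways of the collection.  Genes outside the universe are dropped
    with a warning.  Returns a frame (pathway, overlap, pathway_size,
    p_value, holm_p) sorted by raw p.
    """
    genes = set(cluster_genes)
    if not genes:
        return pd.DataFrame(columns=["pathway", "overlap", "pathway_size",
                                     "p_value", "holm_p"])
    stray = genes - collection.universe
    if stray:
        warnings.warn(f"{len(stray)} cluster genes outside the pathway universe; dropped",
                      stacklevel=2)
        genes -= stray
    N = len(collection.universe)
    rows = []
    for name in sorted(collection.gene_sets):
        pw = collection.gene_sets[name]
        a = len(genes & pw)
        b = len(genes) - a
        c = len(pw) - a
        d = N - a - b - c
        p = fisher_one_tailed(ContingencyTable(a, b, c, d))
        rows.append((name, a, len(pw), p))
    frame = pd.DataFrame(rows, columns=["pathway", "overlap", "pathway_size", "p_value"])
    frame["holm_p"] = holm_adjust(frame["p_value"].to_numpy())
    return frame.sort_values(["p_value", "pathway"], ignore_index=True)


def cluster_gene_sets(assignment: ClusterAssignment, annotations: pd.DataFrame,
                      gene_source: str = "enriched", fdr: float = 0.01) -> dict[int, set[str]]:
    """Derive the gene set each cluster contributes to pathway testing.

    ``gene_source="enriched"`` (default) runs the target-enrichment stage
    and keeps only BUM-flagged genes; ``"targeted"`` uses every gene
    annotated to a cluster member.
    """
    if gene_source == "targeted":
        ann = annotations[["compound_id", "gene"]].drop_duplicates()
        label_of = dict(zip(assignment.compound_ids, assignment.labels.tolist()))
        ann = ann[ann["compound_id"].isin(label_of)]
        ann = ann.assign(cluster=ann["compound_id"].map(label_of))
        return {int(lab): set(sub["gene"]) for lab, sub in ann.groupby("cluster")}
    if gene_source != "enriched":
        raise ValueError("gene_source must be 'enriched' or 'targeted'")
    outcome = enrich_clusters(assignment, annotations, fdr=fdr)
    flagged = outcome.results[outcome.results["enriched"]]
    return {int(lab): set(sub["gene"]) for lab, sub in flagged.groupby("cluster")}


def count_significant_pathways(assignment: ClusterAssignment, annotations: pd.DataFrame,
                               collection: PathwayCollection, alpha: float = 0.05,
                               gene_source: str = "enriched", fdr: float = 0.01) -> int:
    """Total pathways with Holm-adjusted p <= alpha, summed over clusters."""
    gene_sets = cluster_gene_sets(assignment, annotations, gene_source, fdr)
    total = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # stray genes / small BUM sets in nulls
        for genes in gene_sets.values():
            frame = pathway_enrichment(genes & collection.universe, collection)
            total += int((frame["holm_p"] <= alpha).sum())
    return total


@dataclass
class PathwayNullResult:
    actual_count: int
    null_counts: np.ndarray
    alpha: float
    n_reps: int

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.null_counts, q))

    def summary(self) -> dict[str, float]:
        return {
            "actual": float(self.actual_count),
            "null_mean": float(self.null_counts.mean()),
            "null_q025": self.quantile(0.025),
            "null_q50": self.quantile(0.5),
            "null_q95": self.quantile(0.95),
            "null_q975": self.quantile(0.975),
        }


def randomized_pathway_null(assignment: ClusterAssignment, annotations: pd.DataFrame,
                            collection: PathwayCollection, n_reps: int = 50,
                            alpha: float = 0.05, seed: int = 0,
                            gene_source: str = "enriched",
                            fdr: float = 0.01) -> PathwayNullResult:
    """Null distribution of significant-pathway counts under random clusters.

    Each replicate permutes the compound labels across the fixed
    cluster-size partition (sizes and the annotation table are untouched),
    rederives per-cluster gene sets the same way as for the real data, and
    counts pathways with Holm-adjusted p <= alpha.  The actual count on
    the unpermuted assignment is returned alongside for contrast.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    actual = count_significant_pathways(assignment, annotations, collection,
                                        alpha, gene_source, fdr)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_reps, dtype=int)
    for rep in range(n_reps):
        perm = rng.permutation(assignment.n_compounds)
        shuffled = ClusterAssignment(list(assignment.compound_ids),
                                     assignment.labels[perm])
        counts[rep] = count_significant_pathways(shuffled, annotations, collection,
                                                 alpha, gene_source, fdr)
    logger.info("pathway null: actual=%d, null mean=%.2f, null 95th=%.1f",
                actual, counts.mean(), np.quantile(counts, 0.95))
    return PathwayNullResult(actual, counts, alpha, n_reps)
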