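"""Gene-target enrichment per cluster with BUM-based FDR control.

For each (cluster, gene) pair a 2x2 contingency table is formed over the
universe of annotated compounds:

                        targets the gene    targets other genes only
    within the cluster        a                       b
    outside the cluster       c                       d

Over-representation is scored with the one-tailed (upper-tail) Fisher's
exact test, P(X >= a) with X hypergeometric under fixed marginals.  The
pooled p-values across all tested pairs are modeled as a beta-uniform
mixture (BUM; Pounds & Morris),

    f(p) = lambda + (1 - lambda) * a * p^(a - 1),     0 < a < 1,

whose upper-bound null proportion pi_ub = lambda + (1 - lambda) * a yields
a p-value threshold tau with estimated FDR(tau) equal to a chosen rate
(1% by default).  A pair is flagged enriched when p <= tau.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .som import ClusterAssignment

logger = logging.getLogger(__name__)


class ContingencyTable(NamedTuple):
    """Counts (a, b, c, d) as laid out in the module docstring."""

    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def build_contingency(cluster: int, gene: str, assignment: ClusterAssignment,
                      annotations: pd.DataFrame) -> ContingencyTable:
    """Count compounds in/out of the cluster that do/don't target the gene.

    The universe is the set of compounds carrying at least one gene
    annotation (unannotated compounds say nothing about targeting and
    would only inflate d).  ``annotations`` needs columns
    ``compound_id`` and ``gene``.
    """
    sizes = assignment.sizes()
    if cluster not in sizes:
        raise ValueError(f"cluster {cluster} not present in the assignment")
    ann = annotations[["compound_id", "gene"]].drop_duplicates()
    assigned = set(assignment.compound_ids)
    universe = set(ann["compound_id"]) & assigned
    in_cluster = set(assignment.members(cluster)) & universe
    targeters = set(ann.loc[ann["gene"] == gene, "compound_id"]) & universe
    a = len(in_cluster & targeters)
    b = len(in_cluster) - a
    c = len(targeters) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


@lru_cache(maxsize=200_000)
def _upper_tail(a: int, K: int, n: int, N: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N, K, n), by exact integer sums."""
    hi = min(K, n)
    num = sum(math.comb(K, k) * math.comb(N - K, n - k) for k in range(a, hi + 1))
    return num / math.comb(N, n)


def fisher_one_tailed(table: ContingencyTable) -> float:
    """Upper-tail Fisher's exact p-value for over-representation.

    Computed by exact integer hypergeometric enumeration, so the result
    is correct to float rounding for any table size.
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be nonnegative")
    N = a + b + c + d
    if N == 0:
        return 1.0
    return float(_upper_tail(a, a + c, a + b, N))


@dataclass(frozen=True)
class BumFit:
    """Maximum-likelihood beta-uniform mixture fit of a p-value set."""

    lambda_: float
    a_shape: float
    log_likelihood: float
    n_pvalues: int

    @property
    def pi_ub(self) -> float:
        """Upper bound on the null (uniform) proportion."""
        return self.lambda_ + (1.0 - self.lambda_) * self.a_shape

    def density(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.lambda_ + (1.0 - self.lambda_) * self.a_shape * p ** (self.a_shape - 1.0)

    def cdf(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.lambda_ * p + (1.0 - self.lambda_) * p ** self.a_shape

    def estimated_fdr(self, tau: float) -> float:
        """Estimated FDR when declaring p <= tau significant."""
        if tau <= 0.0:
            return 0.0
        return float(self.pi_ub * tau / self.cdf(np.array(tau)))


_BUM_EPS = 1e-6
_BUM_STARTS = ((0.5, 0.5), (0.9, 0.1), (0.1, 0.9), (0.7, 0.3), (0.3, 0.7))


def fit_bum(pvalues) -> BumFit:
    """Fit f(p) = lambda + (1-lambda) a p^(a-1) by maximum likelihood.

    Deterministic: bounded L-BFGS-B from five fixed starting points, best
    likelihood wins.  P-values must lie in (0, 1]; fewer than 50 of them
    triggers a warning (the mixture is weakly identified on small sets).
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to fit")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size < 50:
        warnings.warn(f"only {p.size} p-values; BUM fit may be unstable", stacklevel=2)
    logp = np.log(p)

    def nll(theta: np.ndarray) -> float:
        lam, a = theta
        dens = lam + (1.0 - lam) * a * np.exp((a - 1.0) * logp)
        return -float(np.log(dens).sum())

    best = None
    bounds = [(_BUM_EPS, 1.0 - _BUM_EPS)] * 2
    for start in _BUM_STARTS:
        res = minimize(nll, np.array(start), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    lam, a = (float(np.clip(v, _BUM_EPS, 1.0 - _BUM_EPS)) for v in best.x)
    return BumFit(lam, a, -float(best.fun), int(p.size))


def bum_fdr_cutoff(fit: BumFit, fdr: float = 0.01) -> float:
    """P-value threshold tau at which the BUM-estimated FDR equals ``fdr``.

    Solving pi_ub * tau / (lambda * tau + (1-lambda) * tau^a) = fdr gives
    the closed form

        tau = [ (pi_ub - fdr * lambda) / (fdr * (1 - lambda)) ]^(1 / (a - 1)),

    clipped to (0, 1].  When pi_ub <= fdr * lambda no positive threshold
    attains the rate and tau = 0 is returned with a warning.  Declaring
    p <= tau controls the estimated FDR at ``fdr``.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must be in (0, 1)")
    lam, a = fit.lambda_, fit.a_shape
    base = (fit.pi_ub - fdr * lam) / (fdr * (1.0 - lam))
    if base <= 0.0:
        warnings.warn("no attainable FDR cutoff (pi_ub <= fdr * lambda); tau = 0",
                      stacklevel=2)
        return 0.0
    tau = base ** (1.0 / (a - 1.0))
    return float(min(tau, 1.0))


@dataclass
class EnrichmentOutcome:
    """Results of enrich_clusters: per-pair table plus the pooled fit."""

    results: pd.DataFrame       # cluster, gene, a, b, c, d, p_value, enriched
    bum: BumFit
    tau: float
    fdr: float

    def enriched_counts(self) -> dict[int, int]:
        """Number of enriched genes per cluster (clusters with >= 1 only)."""
        flagged = self.results[self.results["enriched"]]
        return {int(k): int(v) for k, v in
                flagged.groupby("cluster").size().items()}

    def write_tsv(self, path) -> None:
        self.results.to_csv(path, sep="\t", index=False)


def enrich_clusters(assignment: ClusterAssignment, annotations: pd.DataFrame,
                    fdr: float = 0.01, annotated_universe: bool = True) -> EnrichmentOutcome:
    """Test every (cluster, gene) pair with a >= 1 and flag enrichment.

    One Fisher p-value per pair; all p-values are pooled into a single BUM
    fit, from which a global cutoff tau at the requested FDR is derived.
    Pairs with a = 0 are not tested: their p is 1 by construction and a
    mass of uninformative 1s would distort the mixture fit.

    With ``annotated_universe`` (default) the universe is restricted to
    compounds carrying at least one annotation; otherwise every assigned
    compound counts.
    """
    if assignment.n_compounds == 0:
        raise ValueError("empty assignment")
    ann = annotations[["compound_id", "gene"]].drop_duplicates()
    assigned = set(assignment.compound_ids)
    ann = ann[ann["compound_id"].isin(assigned)]
    if ann.empty:
        raise ValueError("no annotations overlap the assigned compounds")

    if annotated_universe:
        universe = set(ann["compound_id"])
    else:
        universe = assigned
    N = len(universe)

    label_of = dict(zip(assignment.compound_ids, assignment.labels.tolist()))
    cluster_universe_size: dict[int, int] = {}
    for cid in universe:
        lab = label_of[cid]
        cluster_universe_size[lab] = cluster_universe_size.get(lab, 0) + 1

    ann = ann.assign(cluster=ann["compound_id"].map(label_of))
    gene_totals = ann.groupby("gene")["compound_id"].nunique()
    pair_counts = (ann.groupby(["cluster", "gene"])["compound_id"]
                      .nunique().reset_index(name="a"))

    rows = []
    for rec in pair_counts.itertuples(index=False):
        lab, gene, a = int(rec.cluster), rec.gene, int(rec.a)
        n_in = cluster_universe_size.get(lab, 0)
        K = int(gene_totals[gene])
        b = n_in - a
        c = K - a
        d = N - n_in - c
        p = fisher_one_tailed(ContingencyTable(a, b, c, d))
        rows.append((lab, gene, a, b, c, d, p))

    results = pd.DataFrame(rows, columns=["cluster", "gene", "a", "b", "c", "d",
                                          "p_value"])
    results = results.sort_values(["cluster", "gene"], ignore_index=True)
    bum = fit_bum(results["p_value"].to_numpy())
    tau = bum_fdr_cutoff(bum, fdr)
    results["enriched"] = results["p_value"] <= tau
    n_flagged = int(results["enriched"].sum())
    logger.info("enrichment: %d/%d pairs flagged at FDR %.3g (tau = %.4g)",
                n_flagged, len(results), fdr, tau)
    return EnrichmentOutcome(results, bum, tau, fdr)
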