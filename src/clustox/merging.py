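"""Merge under-sized SOM clusters by centroid correlation.

SOM units attract unequal numbers of compounds, and very small clusters
cripple downstream enrichment tests.  Clusters smaller than ``min_size``
(default 15 compounds) are therefore absorbed into the cluster whose
centroid is most similar under Pearson correlation distance (1 - r).  The
retained label is that of the larger member of the pair, the absorbed
centroid is folded into a compound-weighted mean, and the process repeats
on the smallest remaining under-sized cluster until none is left (or a
single cluster remains).

A complete-linkage agglomeration tree over the initial centroids (the
classical hierarchical view of the same correlation distances) is attached
to the result for inspection; the merge decisions themselves use the
iterative nearest-centroid rule above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .som import ClusterAssignment, Codebook


def correlation_distance(c1: np.ndarray, c2: np.ndarray) -> float:
    """Pearson correlation distance 1 - r between two centroid vectors.

    Ranges over [0, 2]: 0 for perfectly correlated profiles, 2 for
    perfectly anti-correlated ones.  Raises ``ValueError`` for vectors of
    length < 2 or with zero variance (correlation undefined).
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if c1.shape != c2.shape or c1.ndim != 1 or c1.size < 2:
        raise ValueError("centroids must be equal-length 1-D vectors of length >= 2")
    s1 = c1 - c1.mean()
    s2 = c2 - c2.mean()
    n1 = np.sqrt((s1 ** 2).sum())
    n2 = np.sqrt((s2 ** 2).sum())
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("correlation undefined for a constant centroid")
    r = float(np.clip((s1 @ s2) / (n1 * n2), -1.0, 1.0))
    return 1.0 - r


@dataclass
class MergeResult:
    assignment: ClusterAssignment
    log: pd.DataFrame                       # absorbed, retained, distance, sizes
    centroids: dict[int, np.ndarray]        # final label -> centroid
    linkage_matrix: np.ndarray | None = None
    initial_labels: list[int] = field(default_factory=list)

    @property
    def n_merges(self) -> int:
        return len(self.log)


def _lattice_adjacent(units_a: set[int], units_b: set[int],
                      grid_d: np.ndarray) -> bool:
    for ua in units_a:
        for ub in units_b:
            if grid_d[ua, ub] <= 1.01:
                return True
    return False


def merge_small_clusters(assignment: ClusterAssignment, codebook: Codebook,
                         min_size: int = 15, max_distance: float | None = None,
                         lattice_only: bool = False) -> MergeResult:
    """Iteratively absorb clusters smaller than ``min_size``.

    At each step the smallest under-sized cluster (ties: lowest label) is
    merged with the cluster at minimal correlation distance from its
    centroid (ties: lowest label).  The label of the larger member
    survives (equal sizes: lower label); the merged centroid is the
    compound-weighted mean of the pair.  Iteration stops when every
    cluster has size >= min_size or one cluster remains.

    ``max_distance`` optionally forbids merges beyond that correlation
    distance (such clusters stay small and are reported in the log with
    a ``merged=False`` row omitted — they simply remain).  With
    ``lattice_only`` merge candidates are restricted to clusters holding
    a grid-adjacent SOM unit.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")

    labels = assignment.labels.copy()
    sizes = assignment.sizes()
    centroids: dict[int, np.ndarray] = {
        lab: codebook.weights[lab].astype(float).copy() for lab in sizes
    }
    units: dict[int, set[int]] = {lab: {lab} for lab in sizes}
    grid_d = codebook.grid_distances() if lattice_only else None

    initial_labels = sorted(sizes)
    linkage_matrix = None
    if len(initial_labels) >= 3:
        cent = np.array([centroids[lab] for lab in initial_labels])
        try:
            dm = np.array([[0.0 if i == j else correlation_distance(cent[i], cent[j])
                            for j in range(len(cent))] for i in range(len(cent))])
            linkage_matrix = linkage(squareform(dm, checks=False), method="complete")
        except ValueError:
            linkage_matrix = None

    log_rows = []
    unmergeable: set[int] = set()
    while len(sizes) > 1:
        small = sorted(lab for lab, s in sizes.items()
                       if s < min_size and lab not in unmergeable)
        if not small:
            break
        # smallest under-sized cluster first; ties broken by lowest label
        lab_small = min(small, key=lambda lab: (sizes[lab], lab))

        best_lab, best_d = None, np.inf
        for other in sorted(sizes):
            if other == lab_small:
                continue
            if grid_d is not None and not _lattice_adjacent(units[lab_small],
                                                            units[other], grid_d):
                continue
            d = correlation_distance(centroids[lab_small], centroids[other])
            if d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15 and
                                      (best_lab is None or other < best_lab)):
                best_lab, best_d = other, d
        if best_lab is None or (max_distance is not None and best_d > max_distance):
            unmergeable.add(lab_small)
            continue

        n_s, n_o = sizes[lab_small], sizes[best_lab]
        if n_o > n_s or (n_o == n_s and best_lab < lab_small):
            retained, absorbed = best_lab, lab_small
        else:
            retained, absorbed = lab_small, best_lab
        merged_centroid = (sizes[absorbed] * centroids[absorbed]
                           + sizes[retained] * centroids[retained]) / (n_s + n_o)
        labels[labels == absorbed] = retained
        sizes[retained] = n_s + n_o
        centroids[retained] = merged_centroid
        units[retained] |= units[absorbed]
        del sizes[absorbed], centroids[absorbed], units[absorbed]
        unmergeable.discard(retained)
        log_rows.append({"absorbed": absorbed, "retained": retained,
                         "distance": best_d,
                         "size_absorbed": n_s if absorbed == lab_small else n_o,
                         "size_retained": sizes[retained]})

    log = pd.DataFrame(log_rows,
                       columns=["absorbed", "retained", "distance",
                                "size_absorbed", "size_retained"])
    merged = ClusterAssignment(list(assignment.compound_ids), labels)
    return MergeResult(merged, log, centroids, linkage_matrix, initial_labels)
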