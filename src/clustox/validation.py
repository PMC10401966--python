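"""Structural validation of activity clusters via Tanimoto similarity.

If clusters of bioactivity profiles capture shared pharmacology, member
compounds should also be somewhat more similar *structurally* than random
compound pairs.  This module compares the mean Tanimoto coefficient over
within-cluster fingerprint pairs against the mean over all pairs.

Fingerprints are plain fixed-length bit vectors; any externally computed
chemical fingerprint (or the synthetic generator's planted bits) plugs in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .som import ClusterAssignment

logger = logging.getLogger(__name__)


@dataclass
class FingerprintSet:
    """compound_id -> fixed-length binary fingerprint."""

    compound_ids: list[str]
    bits: np.ndarray  # (n_compounds, n_bits) boolean

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.compound_ids):
            raise ValueError("one fixed-length bit vector per compound required")

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]

    def index_of(self) -> dict[str, int]:
        return {cid: i for i, cid in enumerate(self.compound_ids)}

    def write_tsv(self, path) -> None:
        n_hex = (self.n_bits + 3) // 4
        with open(path, "w") as fh:
            fh.write("compound_id\tn_bits\tbits_hex\n")
            for cid, row in zip(self.compound_ids, self.bits):
                value = int("".join("1" if b else "0" for b in row), 2) if self.n_bits else 0
                fh.write(f"{cid}\t{self.n_bits}\t{value:0{n_hex}x}\n")

    @classmethod
    def read_tsv(cls, path) -> "FingerprintSet":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        ids, rows = [], []
        for rec in frame.itertuples(index=False):
            n_bits = int(rec.n_bits)
            value = int(rec.bits_hex, 16)
            bitstring = format(value, f"0{n_bits}b") if n_bits else ""
            rows.append([ch == "1" for ch in bitstring])
            ids.append(rec.compound_id)
        return cls(ids, np.array(rows, dtype=bool))


def tanimoto(f1: np.ndarray, f2: np.ndarray) -> float:
    """Tanimoto (Jaccard) coefficient |A & B| / |A | B| of two bit vectors.

    The all-zero/all-zero pair is defined as similarity 1: by the
    available evidence the two fingerprints are identical.
    """
    f1 = np.asarray(f1, dtype=bool)
    f2 = np.asarray(f2, dtype=bool)
    if f1.shape != f2.shape or f1.ndim != 1:
        raise ValueError("fingerprints must be equal-length 1-D bit vectors")
    union = int(np.logical_or(f1, f2).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(f1, f2).sum()) / union


def _pair_means(bits: np.ndarray, pairs: np.ndarray) -> float:
    left = bits[pairs[:, 0]]
    right = bits[pairs[:, 1]]
    inter = np.logical_and(left, right).sum(axis=1).astype(float)
    union = np.logical_or(left, right).sum(axis=1).astype(float)
    sims = np.where(union > 0, inter / np.maximum(union, 1.0), 1.0)
    return float(sims.mean())


def _all_pairs(n: int) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


@dataclass
class SimilaritySummary:
    mean_overall: float
    mean_intra: float
    n_pairs_overall: int
    n_pairs_intra: int
    overall_exact: bool
    intra_exact: bool

    def to_dict(self) -> dict:
        return {
            "mean_overall": self.mean_overall,
            "mean_intra": self.mean_intra,
            "n_pairs_overall": self.n_pairs_overall,
            "n_pairs_intra": self.n_pairs_intra,
            "overall_exact": self.overall_exact,
            "intra_exact": self.intra_exact,
        }


def intra_inter_summary(fps: FingerprintSet, assignment: ClusterAssignment,
                        max_pairs: int = 2_000_000, seed: int = 0) -> SimilaritySummary:
    """Mean Tanimoto over all compound pairs and over within-cluster pairs.

    Pair sets larger than ``max_pairs`` are subsampled (seeded, with
    replacement across the pair index); smaller sets are enumerated
    exactly.  Every assigned compound must carry a fingerprint.
    """
    index = fps.index_of()
    missing = [cid for cid in assignment.compound_ids if cid not in index]
    if missing:
        raise ValueError(f"{len(missing)} assigned compounds lack fingerprints "
                         f"(first: {missing[0]!r})")
    rng = np.random.default_rng(seed)
    rows = np.array([index[cid] for cid in assignment.compound_ids])
    bits = fps.bits
    n = len(rows)

    n_all = n * (n - 1) // 2
    if n_all == 0:
        raise ValueError("need at least two compounds")
    overall_exact = n_all <= max_pairs
    if overall_exact:
        pairs = _all_pairs(n)
    else:
        i = rng.integers(0, n, size=max_pairs)
        j = rng.integers(0, n - 1, size=max_pairs)
        j = np.where(j >= i, j + 1, j)  # distinct partner, uniform over pairs
        pairs = np.column_stack([i, j])
    mean_overall = _pair_means(bits, np.column_stack([rows[pairs[:, 0]],
                                                      rows[pairs[:, 1]]]))
    n_overall = len(pairs)

    intra_pairs = []
    labels = assignment.labels
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if len(members) >= 2:
            local = _all_pairs(len(members))
            intra_pairs.append(np.column_stack([members[local[:, 0]],
                                                members[local[:, 1]]]))
    if not intra_pairs:
        raise ValueError("no cluster has two or more members")
    intra_pairs = np.concatenate(intra_pairs)
    intra_exact = len(intra_pairs) <= max_pairs
    if not intra_exact:
        pick = rng.choice(len(intra_pairs), size=max_pairs, replace=False)
        intra_pairs = intra_pairs[pick]
    mean_intra = _pair_means(bits, np.column_stack([rows[intra_pairs[:, 0]],
                                                    rows[intra_pairs[:, 1]]]))

    summary = SimilaritySummary(mean_overall, mean_intra, n_overall,
                                len(intra_pairs), overall_exact, intra_exact)
    logger.info("tanimoto: overall=%.3f (%d pairs), intra=%.3f (%d pairs)",
                mean_overall, n_overall, mean_intra, len(intra_pairs))
    return summary


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (pair-counting form).

    0 expected for random labelings, 1 for identical partitions.  Used to
    score recovered clusters against planted groups.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be equal-length 1-D arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least two samples")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
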