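"""Synthetic qHTS-style inputs with planted, recoverable ground truth.

Emulates the four inputs of the pipeline — an integer curve-rank activity
matrix, compound-gene annotation tables from two partially overlapping
sources, GMT pathway gene sets, and binary structure fingerprints — for a
library in which compounds belong to hidden mechanism groups:

* group members share a signature of assays on which their curve rank is
  pushed to +/- ``signal_mean`` (sign fixed per group x assay: activation
  positive, inhibition negative) on top of Gaussian noise, rounded to
  integers and clipped to the curve-rank range [-9, 9]; inactive
  compounds are pure noise around 0;
* group members are annotated to their group's planted genes with high
  probability and to background genes at a low rate; a configurable
  fraction of the library carries no annotation at all (real libraries
  map only a minority of compounds to known targets);
* each group's gene set is embedded in one planted pathway, alongside
  decoy pathways drawn from the background gene universe;
* fingerprints within a group are noisy copies of a group template, so
  within-group Tanimoto similarity is elevated by a tunable amount.

Every output is a deterministic function of ``SimulationConfig.seed``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .pathways import PathwayCollection
from .som import ActivityMatrix, CURVE_RANK_MAX, CURVE_RANK_MIN
from .validation import FingerprintSet

INACTIVE = -1  # group label for compounds without a planted mechanism


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the test conditions."""

    n_compounds: int = 500
    n_assays: int = 40
    n_groups: int = 5
    frac_inactive: float = 0.2
    signature_size: int = 6
    signal_mean: float = 7.0
    noise_sd: float = 1.0
    genes_per_group: int = 4
    p_annot_in: float = 0.9
    p_annot_bg: float = 0.01
    n_bg_genes: int = 100
    frac_unannotated: float = 0.74
    n_decoy_pathways: int = 20
    pathway_extra_genes: int = 4
    decoy_pathway_size: int = 8
    n_bits: int = 256
    template_density: float = 0.2
    intra_sim_target: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_inactive", "p_annot_in", "p_annot_bg", "frac_unannotated",
                     "template_density"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.signature_size > self.n_assays:
            raise ValueError("signature_size cannot exceed n_assays")
        if self.n_bits < 64:
            raise ValueError("n_bits must be >= 64")
        if not 0.0 < self.intra_sim_target <= 1.0:
            raise ValueError("intra_sim_target must lie in (0, 1]")


@dataclass
class GroundTruth:
    """Planted structure behind a simulated library."""

    group_of_compound: dict[str, int]            # INACTIVE for no mechanism
    planted_gene_sets: dict[int, list[str]]
    planted_pathways: dict[int, str]
    signature_assays: dict[int, list[int]] = field(default_factory=dict)
    signature_signs: dict[int, list[int]] = field(default_factory=dict)
    background_genes: list[str] = field(default_factory=list)
    signatures_overlap: bool = False

    def group_labels(self, compound_ids: list[str]) -> np.ndarray:
        return np.array([self.group_of_compound[cid] for cid in compound_ids])

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _compound_ids(n: int) -> list[str]:
    return [f"C{i:06d}" for i in range(n)]


def _planted_genes(config: SimulationConfig) -> dict[int, list[str]]:
    return {g: [f"TG{g:02d}_{j:02d}" for j in range(config.genes_per_group)]
            for g in range(config.n_groups)}


def _background_genes(config: SimulationConfig) -> list[str]:
    return [f"BG{i:04d}" for i in range(config.n_bg_genes)]


def simulate_activity_matrix(config: SimulationConfig) -> tuple[ActivityMatrix, GroundTruth]:
    """Generate the curve-rank matrix and its planted group structure.

    Signatures are disjoint blocks of assays when they fit
    (n_groups * signature_size <= n_assays); otherwise each group samples
    its signature independently and the overlap is flagged in the
    returned ground truth.
    """
    rng = np.random.default_rng([config.seed, 0])
    n, m, g = config.n_compounds, config.n_assays, config.n_groups
    ids = _compound_ids(n)
    assay_ids = [f"assay_{j:03d}" for j in range(m)]

    n_inactive = int(round(config.frac_inactive * n))
    order = rng.permutation(n)
    groups = np.full(n, INACTIVE, dtype=int)
    active = order[n_inactive:]
    groups[active] = np.arange(len(active)) % g

    overlap = g * config.signature_size > m
    signature_assays: dict[int, list[int]] = {}
    if not overlap:
        assay_order = rng.permutation(m)
        for k in range(g):
            block = assay_order[k * config.signature_size:(k + 1) * config.signature_size]
            signature_assays[k] = sorted(int(j) for j in block)
    else:
        for k in range(g):
            block = rng.choice(m, size=config.signature_size, replace=False)
            signature_assays[k] = sorted(int(j) for j in block)
    # activation (+) vs inhibition (-) fixed per (group, assay)
    signature_signs = {k: [int(s) for s in rng.choice([-1, 1], size=config.signature_size)]
                       for k in range(g)}

    values = rng.normal(0.0, config.noise_sd, size=(n, m)) if config.noise_sd > 0 \
        else np.zeros((n, m))
    for k in range(g):
        members = np.flatnonzero(groups == k)
        for j, sign in zip(signature_assays[k], signature_signs[k]):
            values[members, j] += sign * config.signal_mean
    values = np.clip(np.rint(values), CURVE_RANK_MIN, CURVE_RANK_MAX).astype(int)

    truth = GroundTruth(
        group_of_compound={cid: int(lab) for cid, lab in zip(ids, groups)},
        planted_gene_sets=_planted_genes(config),
        planted_pathways={k: f"PW_GROUP_{k:02d}" for k in range(g)},
        signature_assays=signature_assays,
        signature_signs=signature_signs,
        background_genes=_background_genes(config),
        signatures_overlap=overlap,
    )
    matrix = ActivityMatrix(ids, assay_ids, values.astype(float))
    return matrix, truth


def simulate_annotations(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Source-labelled compound-gene annotation rows with planted signal.

    Group members are annotated to each planted gene of their group with
    probability ``p_annot_in`` and to each background gene with
    ``p_annot_bg``; inactive compounds only see the background rate.  A
    fraction ``frac_unannotated`` of compounds is blanked entirely.  Each
    surviving (compound, gene) edge is attributed to "sourceA",
    "sourceB", or both, so the two sources partially overlap.

    Returns a frame with columns (source, compound_id, gene).
    """
    rng = np.random.default_rng([config.seed, 1])
    ids = sorted(truth.group_of_compound)
    bg = truth.background_genes

    blanked = set()
    if config.frac_unannotated > 0:
        n_blank = int(round(config.frac_unannotated * len(ids)))
        blanked = set(rng.choice(len(ids), size=n_blank, replace=False).tolist())

    rows: list[tuple[str, str, str]] = []
    for idx, cid in enumerate(ids):
        if idx in blanked:
            continue
        group = truth.group_of_compound[cid]
        genes: list[str] = []
        if group != INACTIVE and config.p_annot_in > 0:
            draws = rng.random(len(truth.planted_gene_sets[group]))
            genes.extend(gene for gene, u in
                         zip(truth.planted_gene_sets[group], draws)
                         if u < config.p_annot_in)
        if config.p_annot_bg > 0 and bg:
            draws = rng.random(len(bg))
            genes.extend(gene for gene, u in zip(bg, draws) if u < config.p_annot_bg)
        for gene in genes:
            u = rng.random()
            if u < 0.2:
                rows.append(("sourceA", cid, gene))
                rows.append(("sourceB", cid, gene))
            elif u < 0.6:
                rows.append(("sourceA", cid, gene))
            else:
                rows.append(("sourceB", cid, gene))
    frame = pd.DataFrame(rows, columns=["source", "compound_id", "gene"])
    return frame.sort_values(["source", "compound_id", "gene"], ignore_index=True)


def simulate_pathways(truth: GroundTruth, config: SimulationConfig) -> PathwayCollection:
    """GMT-style collection embedding each group's genes in one pathway.

    Planted pathway k contains the whole planted gene set of group k plus
    a few background genes (real pathways are larger than any one drug
    class's targets); ``n_decoy_pathways`` decoys are uniform draws from
    the whole gene universe, so their overlap with planted sets follows
    the hypergeometric baseline.
    """
    rng = np.random.default_rng([config.seed, 2])
    bg = truth.background_genes
    universe = sorted({g for genes in truth.planted_gene_sets.values() for g in genes}
                      | set(bg))
    gene_sets: dict[str, set[str]] = {}
    for k, name in sorted(truth.planted_pathways.items()):
        extra = set()
        if config.pathway_extra_genes > 0 and bg:
            n_extra = min(config.pathway_extra_genes, len(bg))
            extra = set(rng.choice(bg, size=n_extra, replace=False).tolist())
        gene_sets[name] = set(truth.planted_gene_sets[k]) | extra
    for i in range(config.n_decoy_pathways):
        size = min(config.decoy_pathway_size, len(universe))
        if size == 0:
            break
        gene_sets[f"PW_DECOY_{i:03d}"] = set(rng.choice(universe, size=size,
                                                        replace=False).tolist())
    return PathwayCollection(gene_sets, set(universe))


def expected_template_tanimoto(density: float, flip: float) -> float:
    """Expected Tanimoto of two independent noisy copies of one template.

    Template bits are Bernoulli(density); each copy flips every bit with
    probability ``flip``.  Ratio-of-expectations approximation, accurate
    for fingerprints of hundreds of bits.
    """
    d, f = density, flip
    both = d * (1 - f) ** 2 + (1 - d) * f ** 2
    either = d * (1 - f ** 2) + (1 - d) * (1 - (1 - f) ** 2)
    return both / either if either > 0 else 1.0


def _solve_flip(density: float, target: float) -> float:
    if target >= 1.0:
        return 0.0
    lo = expected_template_tanimoto(density, 0.5)
    if target < lo:
        raise ValueError(
            f"intra_sim_target={target} unreachable with flip noise "
            f"(minimum {lo:.3f} at flip=0.5); raise the target")
    return float(brentq(lambda f: expected_template_tanimoto(density, f) - target,
                        0.0, 0.5, xtol=1e-10))


def member_fingerprint(template: np.ndarray, flip: float,
                       rng: np.random.Generator) -> np.ndarray:
    """One noisy copy of a template: each bit flipped with prob ``flip``."""
    flips = rng.random(template.size) < flip
    return np.logical_xor(template, flips)


def simulate_fingerprints(truth: GroundTruth, config: SimulationConfig) -> FingerprintSet:
    """Binary fingerprints with elevated within-group Tanimoto similarity.

    Each group draws a Bernoulli(``template_density``) template; members
    are noisy copies with the flip probability solved so the expected
    within-group Tanimoto equals ``intra_sim_target``.  Inactive
    compounds draw independent bits at the members' marginal density, so
    between-group similarity sits near the random-pair baseline.
    """
    rng = np.random.default_rng([config.seed, 3])
    flip = _solve_flip(config.template_density, config.intra_sim_target)
    d, f = config.template_density, flip
    marginal = d * (1 - f) + (1 - d) * f

    ids = sorted(truth.group_of_compound)
    templates = {k: rng.random(config.n_bits) < d
                 for k in sorted({g for g in truth.group_of_compound.values()
                                  if g != INACTIVE})}
    bits = np.zeros((len(ids), config.n_bits), dtype=bool)
    for i, cid in enumerate(ids):
        group = truth.group_of_compound[cid]
        if group == INACTIVE:
            bits[i] = rng.random(config.n_bits) < marginal
        else:
            bits[i] = member_fingerprint(templates[group], flip, rng)
    return FingerprintSet(ids, bits)


def synthetic_key(compound_id: str) -> str:
    """Deterministic 14-uppercase-letter pseudo connectivity key.

    Lets simulated runs exercise the keyed annotation join without real
    structures; distinct compound IDs collide with negligible
    probability (26^-14 per pair).
    """
    digest = hashlib.sha256(compound_id.encode()).digest()
    return "".join(chr(ord("A") + b % 26) for b in digest[:14])


# Real, valid SMILES (with salt and stereo variants) for structure-mapping
# tests: each tuple is (compound_id, smiles).  Pairs that must share a
# connectivity key: ethanol/ethanol-HCl, acetic acid/sodium acetate,
# L-/D-alanine, ibuprofen/S-ibuprofen.
SMILES_LIBRARY: list[tuple[str, str]] = [
    ("ethanol", "CCO"),
    ("ethanol_hydrochloride", "CCO.Cl"),
    ("acetic_acid", "CC(=O)O"),
    ("sodium_acetate", "[Na+].CC(=O)[O-]"),
    ("aspirin", "CC(=O)OC1=CC=CC=C1C(=O)O"),
    ("caffeine", "CN1C=NC2=C1C(=O)N(C)C(=O)N2C"),
    ("l_alanine", "C[C@@H](C(=O)O)N"),
    ("d_alanine", "C[C@H](C(=O)O)N"),
    ("ibuprofen", "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O"),
    ("s_ibuprofen", "CC(C)CC1=CC=C(C=C1)[C@@H](C)C(=O)O"),
    ("benzene", "c1ccccc1"),
    ("phenol_sodium_salt", "[Na+].[O-]c1ccccc1"),
]


def write_activity_tsv(matrix: ActivityMatrix, path) -> None:
    matrix.write_tsv(path)


def write_annotations_tsv(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    truth.to_json(path)
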