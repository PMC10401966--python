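"""The generator's planted structure must be present and recoverable."""

import numpy as np
import pandas as pd
import pytest

import clustox as cx
from clustox.synthetic import (INACTIVE, expected_template_tanimoto,
                               member_fingerprint, synthetic_key)


def test_noiseless_limit_gives_exact_signatures():
    config = cx.SimulationConfig(n_compounds=60, n_assays=20, n_groups=3,
                                 frac_inactive=0.0, noise_sd=0.0,
                                 signal_mean=7.0, signature_size=4, seed=3)
    matrix, truth = cx.simulate_activity_matrix(config)
    frame = matrix.to_frame()
    for cid, group in truth.group_of_compound.items():
        row = frame.loc[cid]
        sig = truth.signature_assays[group]
        signs = dict(zip(sig, truth.signature_signs[group]))
        for j, assay in enumerate(matrix.assay_ids):
            expected = 7.0 * signs[j] if j in signs else 0.0
            assert row[assay] == expected


def test_all_inactive_degenerate_case():
    config = cx.SimulationConfig(n_compounds=50, n_assays=10, n_groups=1,
                                 frac_inactive=1.0, noise_sd=1.0, seed=5)
    matrix, truth = cx.simulate_activity_matrix(config)
    assert all(g == INACTIVE for g in truth.group_of_compound.values())
    # pure noise around zero: small mean, integer values in range
    assert abs(matrix.values.mean()) < 0.5
    assert matrix.values.min() >= -9 and matrix.values.max() <= 9


def test_curve_ranks_are_bounded_integers(sim_default):
    values = sim_default["matrix"].values
    assert np.array_equal(values, np.rint(values))
    assert values.min() >= -9 and values.max() <= 9


def test_group_centroids_separate_from_within_group_spread():
    """Between-group centroid distances exceed within-group distances."""
    config = cx.SimulationConfig(n_compounds=500, n_assays=40, n_groups=5,
                                 noise_sd=1.0, seed=7)
    matrix, truth = cx.simulate_activity_matrix(config)
    labels = truth.group_labels(matrix.compound_ids)
    centroids = {}
    within = []
    for g in range(5):
        members = matrix.values[labels == g]
        centroids[g] = members.mean(axis=0)
        within.append(np.linalg.norm(members - centroids[g], axis=1).mean())
    between = [np.linalg.norm(centroids[i] - centroids[j])
               for i in range(5) for j in range(i + 1, 5)]
    assert min(between) > max(within)


def test_annotations_saturated_and_empty_limits():
    base = dict(n_compounds=40, n_assays=10, n_groups=2, signature_size=3,
                frac_inactive=0.25, genes_per_group=3, frac_unannotated=0.0,
                seed=9)
    config = cx.SimulationConfig(p_annot_in=1.0, p_annot_bg=0.0, **base)
    matrix, truth = cx.simulate_activity_matrix(config)
    ann = cx.simulate_annotations(truth, config)
    pairs = ann[["compound_id", "gene"]].drop_duplicates()
    by_compound = pairs.groupby("compound_id")["gene"].apply(set)
    for cid, group in truth.group_of_compound.items():
        if group == INACTIVE:
            assert cid not in by_compound.index
        else:
            assert by_compound[cid] == set(truth.planted_gene_sets[group])

    config0 = cx.SimulationConfig(p_annot_in=0.0, p_annot_bg=0.0, **base)
    _, truth0 = cx.simulate_activity_matrix(config0)
    assert cx.simulate_annotations(truth0, config0).empty


def test_annotation_rate_matches_binomial_expectation():
    config = cx.SimulationConfig(n_compounds=400, n_groups=4, genes_per_group=5,
                                 frac_inactive=0.0, frac_unannotated=0.0,
                                 p_annot_in=0.8, p_annot_bg=0.02, seed=21)
    _, truth = cx.simulate_activity_matrix(config)
    ann = cx.simulate_annotations(truth, config)
    pairs = set(map(tuple, ann[["compound_id", "gene"]].drop_duplicates().values))
    for group, genes in truth.planted_gene_sets.items():
        members = [cid for cid, g in truth.group_of_compound.items() if g == group]
        n_trials = len(members) * len(genes)
        hits = sum((cid, gene) in pairs for cid in members for gene in genes)
        se = np.sqrt(0.8 * 0.2 / n_trials)
        assert abs(hits / n_trials - 0.8) <= 3 * se


def test_pathways_plant_each_group_and_decoys_follow_hypergeometric():
    config = cx.SimulationConfig(n_decoy_pathways=0, seed=13)
    _, truth = cx.simulate_activity_matrix(config)
    collection = cx.simulate_pathways(truth, config)
    assert len(collection) == config.n_groups
    for g, name in truth.planted_pathways.items():
        assert set(truth.planted_gene_sets[g]) <= collection.gene_sets[name]

    config = cx.SimulationConfig(n_decoy_pathways=200, seed=13)
    _, truth = cx.simulate_activity_matrix(config)
    collection = cx.simulate_pathways(truth, config)
    planted = {g for genes in truth.planted_gene_sets.values() for g in genes}
    universe_size = len(collection.universe)
    overlaps = [len(genes & planted) for name, genes in collection.gene_sets.items()
                if name.startswith("PW_DECOY_")]
    # decoys draw decoy_pathway_size genes uniformly: overlap ~ Hypergeom
    expected = config.decoy_pathway_size * len(planted) / universe_size
    se = np.sqrt(expected * (1 - len(planted) / universe_size) / len(overlaps))
    assert abs(np.mean(overlaps) - expected) <= 4 * se


def test_fingerprints_noiseless_and_disjoint_limits():
    config = cx.SimulationConfig(n_compounds=40, n_groups=2, frac_inactive=0.0,
                                 intra_sim_target=1.0, seed=17)
    _, truth = cx.simulate_activity_matrix(config)
    fps = cx.simulate_fingerprints(truth, config)
    labels = truth.group_labels(fps.compound_ids)
    for g in (0, 1):
        rows = fps.bits[labels == g]
        assert (rows == rows[0]).all(), "zero flip noise must copy the template"

    t1 = np.zeros(64, dtype=bool); t1[:8] = True
    t2 = np.zeros(64, dtype=bool); t2[8:16] = True
    rng = np.random.default_rng(0)
    f1 = member_fingerprint(t1, 0.0, rng)
    f2 = member_fingerprint(t2, 0.0, rng)
    assert cx.tanimoto(f1, f2) == 0.0


def test_within_group_tanimoto_hits_target():
    config = cx.SimulationConfig(n_compounds=300, n_groups=3, frac_inactive=0.0,
                                 intra_sim_target=0.5, n_bits=256, seed=19)
    _, truth = cx.simulate_activity_matrix(config)
    fps = cx.simulate_fingerprints(truth, config)
    labels = truth.group_labels(fps.compound_ids)
    sims = []
    for g in range(3):
        rows = np.flatnonzero(labels == g)
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                sims.append(cx.tanimoto(fps.bits[rows[i]], fps.bits[rows[j]]))
    assert len(sims) >= 10_000
    assert abs(np.mean(sims) - 0.5) <= 0.05


def test_expected_template_tanimoto_closed_form():
    # flip 0 -> identical copies; flip 0.5 -> the 1/3 random-bits floor
    assert expected_template_tanimoto(0.3, 0.0) == 1.0
    assert expected_template_tanimoto(0.3, 0.5) == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        cx.SimulationConfig(intra_sim_target=0.0)


def test_seed_determinism_and_sensitivity():
    config = cx.SimulationConfig(n_compounds=80, seed=23)
    out1 = cx.simulate_activity_matrix(config)
    out2 = cx.simulate_activity_matrix(config)
    assert np.array_equal(out1[0].values, out2[0].values)
    ann1 = cx.simulate_annotations(out1[1], config)
    ann2 = cx.simulate_annotations(out2[1], config)
    pd.testing.assert_frame_equal(ann1, ann2)
    fps1 = cx.simulate_fingerprints(out1[1], config)
    fps2 = cx.simulate_fingerprints(out2[1], config)
    assert np.array_equal(fps1.bits, fps2.bits)

    other = cx.SimulationConfig(n_compounds=80, seed=24)
    out3 = cx.simulate_activity_matrix(other)
    assert not np.array_equal(out1[0].values, out3[0].values)


def _distance_ratio(config):
    matrix, truth = cx.simulate_activity_matrix(config)
    labels = truth.group_labels(matrix.compound_ids)
    centroids, within = {}, []
    for g in range(config.n_groups):
        members = matrix.values[labels == g]
        centroids[g] = members.mean(axis=0)
        within.append(np.linalg.norm(members - centroids[g], axis=1).mean())
    between = np.mean([np.linalg.norm(centroids[i] - centroids[j])
                       for i in range(config.n_groups)
                       for j in range(i + 1, config.n_groups)])
    return between / np.mean(within)


def test_stronger_signal_raises_separation_in_expectation():
    lo, hi = [], []
    for seed in range(20):
        lo.append(_distance_ratio(cx.SimulationConfig(
            n_compounds=200, signal_mean=3.0, seed=seed)))
        hi.append(_distance_ratio(cx.SimulationConfig(
            n_compounds=200, signal_mean=7.0, seed=seed)))
    assert np.mean(hi) > np.mean(lo)


def test_higher_annotation_rate_raises_planted_odds_ratio():
    def mean_odds(p_in):
        odds = []
        for seed in range(20):
            config = cx.SimulationConfig(n_compounds=150, frac_inactive=0.0,
                                         frac_unannotated=0.0, p_annot_in=p_in,
                                         p_annot_bg=0.05, seed=seed)
            _, truth = cx.simulate_activity_matrix(config)
            ann = cx.simulate_annotations(truth, config)
            pairs = ann[["compound_id", "gene"]].drop_duplicates()
            sets = pairs.groupby("gene")["compound_id"].apply(set)
            for g, genes in truth.planted_gene_sets.items():
                members = {cid for cid, lab in truth.group_of_compound.items()
                           if lab == g}
                for gene in genes:
                    targ = sets.get(gene, set())
                    a = len(targ & members)
                    b = len(members) - a
                    c = len(targ) - a
                    d = config.n_compounds - a - b - c
                    odds.append((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)))
        return np.mean(odds)

    assert mean_odds(0.9) > mean_odds(0.4)


def test_synthetic_key_is_a_deterministic_14_letter_key():
    key = synthetic_key("C000123")
    assert key == synthetic_key("C000123")
    assert len(key) == 14 and key.isalpha() and key.isupper()
    assert key != synthetic_key("C000124")
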