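# Methods

## Problem setting

Quantitative high-throughput screening (qHTS) summarizes each
compound × assay concentration–response experiment as an integer *curve
rank* in [−9, 9]: magnitude reflects potency/efficacy/curve quality, sign
distinguishes activation (+) from inhibition (−). Compounds with similar
activity-rank profiles across a broad assay panel plausibly share targets or
mechanisms, so clustering profiles and asking which annotated gene targets
are over-represented in each cluster yields hypotheses about the targets of
the cluster's *unannotated* members — the starting point for repurposing.

Only compounds with a complete activity vector are clustered; incomplete
rows are dropped and counted.

## Self-organizing map

Clustering uses the classical online Kohonen SOM on the raw curve ranks
(no standardization: the scale is already common and bounded). Per presented
sample x the best-matching unit (BMU) minimizes ‖x − w_u‖₂, and every unit
updates as

    w_u ← w_u + α(t) · h(d_grid(u, BMU), r(t)) · (x − w_u)

with h either a Gaussian kernel exp(−d²/2r²) (default) or a bubble kernel
d ≤ r. α and r decay linearly from (0.5, max(grid)/2) to (0.01, 0.5) over
the configured epochs. Weights are initialized by seeded sampling of data
rows (scale-free, and exact for degenerate data); the same seed also fixes
presentation order, making training fully deterministic. Rectangular and
hexagonal lattices are supported; grid distance is the Euclidean distance in
the lattice embedding.

Grid sizing is the one genuinely open choice. The `SomConfig` default is
12×12, appropriate for a library of thousands of compounds; the pipeline's
simulated-scale default is 4×3 (~two units per expected activity profile for
the 500-compound default study). A map much finer than the data's profile
diversity splits each tight activity class across several well-populated
units, and the size-based merge step below — by design — never consolidates
clusters that are already large enough; map resolution should therefore be
chosen relative to expected diversity, not library size alone. Empty units
are simply not clusters; fewer clusters than units is normal.

Because online SOM updates are stochastic approximations, the trained
weights carry a stationary jitter of order sqrt(α_end)·σ around their
attractors; diagnostics (e.g. convergence of a 1×1 map to the data mean) are
therefore assessed at that scale rather than at machine precision, and the
quantization error (mean compound-to-BMU distance) is reported as the
training diagnostic.

## Merging small clusters

Clusters below `min_size = 15` compounds would make the downstream 2×2
enrichment tables powerless, so they are absorbed: iteratively, the smallest
under-sized cluster merges with the cluster at minimal Pearson correlation
distance (1 − r) between centroids, the *larger* member's label is retained
(ties: lower label), and the merged centroid is the compound-weighted mean.
Iteration continues until every cluster has ≥ 15 compounds or one remains;
a merged pair that is still small is re-queued. Correlation, not Euclidean
distance, drives merging because small clusters are typically peripheral
units whose profile *shape*, not magnitude, identifies their kin. An
optional `max_distance` guard can forbid merges between uncorrelated
centroids (such clusters then simply stay small), and `lattice_only`
restricts candidates to grid-adjacent units; both are off by default, since
the similarity criterion is the primary definition. A complete-linkage tree
over the initial centroids is attached to the merge result for inspection
only — the iterative nearest-centroid rule is what decides merges.
Merging is deterministic; the log records every (absorbed, retained,
distance) triple.

## Compound–gene mapping

Annotation sources key compounds by structure. Each library SMILES is
reduced to its main component — the longest dot-separated fragment, which
strips salt/counterion fragments — and converted (via RDKit) to a standard
InChIKey, of which the first 14 characters (the connectivity block) serve as
the join key. The block hashes skeleton connectivity only, so salt forms,
protonation states and stereoisomers collapse to one key. Unparseable
structures are dropped with a logged warning and counted, never fatal:
attrition is an expected property of real libraries. Source tables are
inner-joined on the key against the library, unioned, and deduplicated per
(key, gene) with provenance retained; compounds that share a connectivity
key remain distinct compounds sharing annotations (collapsing them would
silently change the enrichment universe). Simulated runs use a
deterministic pseudo-key per compound so the same join machinery is
exercised without real structures.

## Gene-target enrichment and FDR control

For each cluster and gene, the 2×2 table over the universe of *annotated*
compounds counts (a) in-cluster compounds targeting the gene, (b) in-cluster
compounds targeting only other genes, (c) out-of-cluster targeters and (d)
the remainder. Unannotated compounds are excluded from the universe by
default (configurable): they carry no information about targeting and would
only inflate d, anti-conservatively. The test is the upper-tail Fisher exact
probability P(X ≥ a), computed by exact integer hypergeometric summation
(correct to float rounding at any table size); it is invariant to
transposing the table's off-diagonal, so either reading of the 2×2 layout
gives identical results. Only pairs with a ≥ 1 are tested — a = 0 pairs have
p = 1 by construction, and including them en masse would distort the mixture
fit below.

All tested p-values are pooled into one beta-uniform mixture

    f(p) = λ + (1 − λ) · a · p^(a−1),   λ, a ∈ (0, 1),

fit by maximum likelihood (L-BFGS-B from five fixed starts; deterministic).
The fit's upper bound on the null proportion, π_ub = λ + (1 − λ)a, gives the
estimated FDR of the rule "call p ≤ τ": FDR(τ) = π_ub·τ / (λτ + (1 − λ)τ^a).
Setting this to the target q yields the closed-form threshold

    τ = [(π_ub − qλ) / (q(1 − λ))]^(1/(a−1)),

clipped to (0, 1]; π_ub − qλ = λ(1 − q) + (1 − λ)a > 0 for any valid fit, so
a positive cutoff always exists. The default q is 1%. The fit is pooled
globally rather than per cluster — one experiment, one p-value population,
one cutoff. Fewer than 50 pooled p-values triggers a warning (the mixture is
weakly identified on small sets).

## Pathway enrichment and the randomized null

Each cluster contributes its *enriched* genes (configurable: all targeted
genes) to a gene-level one-tailed Fisher test against each pathway of a
GMT collection, with the annotation gene universe as background and Holm
step-down adjustment across the collection within each cluster. To show
that significant pathways reflect cluster structure rather than
multiplicity, a randomized null permutes compound labels across the fixed
cluster-size partition — preserving sizes and the annotation table exactly —
and recomputes the entire gene-set derivation and pathway testing per
replicate; the actual count of pathways with adjusted p ≤ α (default 0.05)
is compared with the null distribution's quantiles.

## Structural validation

Binary fingerprints of uniform length are compared with the Tanimoto
coefficient |A∩B|/|A∪B|; the all-zero/all-zero pair is defined as 1
(identical by the available evidence) and logged. The summary contrasts the
mean over all unordered compound pairs with the mean over within-cluster
pairs, enumerating exactly up to `max_pairs` (default 2·10⁶) and otherwise
subsampling pairs with a seeded generator. Fingerprint provenance is
pluggable — the module computes none itself; synthetic planted bits or any
externally computed fingerprint file work alike. Cluster recovery against
planted groups is scored with the pair-counting adjusted Rand index.

## Synthetic data: what it emulates, and what not

The generator plants every signal the pipeline is supposed to find:

* **Activity**: each of `n_groups` (5) mechanism groups gets a signature of
  `signature_size` (6) assays with per-(group, assay) activation/inhibition
  sign; members get ±`signal_mean` (7) there plus N(0, `noise_sd`=1) noise
  everywhere, rounded to integers and clipped to [−9, 9] — the bounded
  integer scale is matched by construction. `frac_inactive` (0.2) of the
  library is pure noise around 0. Signatures are disjoint when they fit;
  otherwise overlap is flagged in the ground truth.
* **Annotations**: group members hit each of their group's
  `genes_per_group` (4) planted genes with `p_annot_in` (0.9) and each of
  `n_bg_genes` (100) background genes with `p_annot_bg` (0.01);
  `frac_unannotated` (0.74) of compounds carry no annotation at all,
  mirroring the minority-annotated reality of screening libraries. Edges are
  split between two sources ("sourceA"/"sourceB", 20% shared) to exercise
  the union join.
* **Pathways**: one planted pathway per group contains the group's gene set
  plus a few background genes; decoy pathways are uniform draws from the
  gene universe, so decoy/planted overlap follows the hypergeometric
  baseline.
* **Fingerprints**: each group has a Bernoulli(`template_density`=0.2)
  template; members copy it with a bit-flip probability solved (closed form
  + root finding) so the expected within-group Tanimoto equals
  `intra_sim_target` (0.5); inactive compounds draw independent bits at the
  members' marginal density, putting between-group similarity near the
  random baseline (~0.15–0.2). Targets below the 1/3 random-copy floor are
  rejected.

Everything is a deterministic function of the config seed.

What the generator does **not** emulate: assay biology and dose–response
curve fitting (curve ranks are drawn, not derived), correlated assay panels,
heavy-tailed or sparse real-world curve-rank distributions, compounds
belonging to several mechanism classes, structure-derived fingerprints, and
real annotation biases. Passing tests therefore demonstrate that the
machinery recovers planted structure under clean, well-separated conditions;
they do not certify performance on a real screening library, where signal
strength, class overlap and annotation sparsity are far less favorable.

## Numerical choices and degenerate inputs

* Fisher p-values: exact integer arithmetic (`math.comb`), cached per table.
* BUM parameters are constrained to (10⁻⁶, 1 − 10⁻⁶); p-values must lie in
  (0, 1] (exact zeros must be clipped by the caller — the pipeline never
  produces them).
* Correlation distance raises on constant centroids (correlation
  undefined); trained float centroids are never exactly constant.
* BMU ties break to the lowest unit index (distances computed directly, not
  via the expanded quadratic form, so exact ties stay exact); merge-candidate
  and retained-label ties break to the lower cluster label.
* All stage seeds derive deterministically from one global seed; reports are
  JSON with sorted keys, so identical configs and seeds give byte-identical
  reports.

## Known limitations

* The SOM grid, schedule and seed of any particular historical analysis are
  generally unreported; cluster partitions are reproducible only within this
  package's configuration, not across implementations.
* The size-threshold merge rule leaves a fragmented activity class
  fragmented when every fragment exceeds `min_size`; choose map resolution
  accordingly (see above).
* BUM-based FDR control assumes the alternative density is decreasing in p
  (a < 1); strongly discrete p-values (tiny universes) make the fit — and
  hence τ — conservative.
* The pathway test treats genes as exchangeable units and ignores gene-set
  overlap structure; Holm control is per cluster, not experiment-wide.
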