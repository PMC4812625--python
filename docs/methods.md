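# Methods

## Model and procedure

The package operates on the chain

    SMILES → standardized molecules → fingerprint feature sets
           → sparse Tanimoto matrix S → threshold networks G(t)
           → ACC(t), EN(t) scan → t_α → clustering → evaluation

**Standardization** is deliberately minimal: keep the fragment with the
most heavy atoms (ties broken toward the lexicographically smallest
canonical SMILES), perceive aromaticity, recompute the canonical SMILES.
Duplicates are removed on the canonical SMILES string, first occurrence
kept. Vendor-specific normalizations (neutralization, nitro/azide
rewrites, salt dictionaries) are out of scope; a `transform` hook lets
callers inject them. The framework's conclusions do not depend on the
standardization dialect, only on consistency within one run.

**Fingerprints** are uniformly feature sets — indices of on-bits in a
virtual bit vector of length W = max feature + 1. Extended connectivity
fingerprints of diameter *d* (d/2 neighborhood-update iterations; ECFP_4
is the default) are computed by RDKit's Morgan generator in sparse mode,
so the feature set at diameter *d* is a superset of the one at *d* − 2.
Feature values are 32-bit hashes: stable across runs and platforms,
stable across RDKit releases only per RDKit's own guarantees. Fixed-length
path-based fingerprints (1024/2048/4096 bits) and user-supplied SMARTS
structural keys are available as alternatives; no key set is bundled.

**Similarity.** Tanimoto T(A,B) = |A∩B| / |A∪B|, defined as 0 when both
sets are empty (a featureless pair carries no evidence of similarity; the
convention avoids 0/0 and matches the minimal-similarity reading). The
matrix stores each unordered pair once (the unit diagonal is implicit)
and only pairs at or above a storage floor `t_store`. Because the ≥
boundary decides edge existence, the floor test is exact: `t_store` is
read as the decimal fraction printed (0.30 = 30/100) and compared by
integer cross-multiplication, immune to floating-point round-off.
Networks can only be generated at t ≥ t_store; the package raises
otherwise rather than inventing absent pairs.

**Threshold scan.** The grid is generated by integer index (t_k = t_min +
k·step evaluated in exact rationals) so that a 0.01-step grid has no
cumulative drift. Edges are sorted by similarity once; the network at
each grid point is the suffix with s ≥ t, which equals a from-scratch
rebuild by edge nesting (a property the test suite checks against an
independent rebuild oracle). ACC is recomputed exactly per grid point;
singleton counts are reported but, per the definition, never enter ACC.

## Peak selection (t_α)

The published rule is visual — "the peak spanning the largest threshold
range". The operationalization here:

1. discard the leading plateau where ACC equals its initial value (this
   removes the trivial complete-network maximum at the grid start);
2. truncate the trailing ACC = 0 run to its first point. This is sound
   because edge sets are nested in t: a triangle-free network stays
   triangle-free, so ACC = 0 is absorbing. Without the truncation, a
   shallow bump late in the decay can claim a huge "span" across the
   structureless singleton-dominated tail up to the scan boundary and
   out-span the real peak;
3. find local maxima over the remainder, compressing flat runs to one
   candidate; the discarded plateau acts as the virtual left neighbor of
   the first run, so a monotone decline yields "no peak" rather than a
   boundary artifact;
4. iteratively merge maxima whose prominence — height above the higher
   adjacent separating minimum — is below `epsilon` (default 0.01 ACC
   units). This implements "minor peaks that are obviously part of a
   larger peak". Plain topographic prominence (as in scipy's
   `find_peaks`) is *not* used: it grants equal-height twin bumps full
   prominence and refuses to merge them across an arbitrarily shallow
   dip;
5. bound each surviving peak by the separating minima toward its
   neighbors (or the region boundary), measure the threshold span, pick
   the widest; t_α is the argmax of ACC inside it, smallest t on ties.

All four knobs (plateau handling, epsilon, span definition, tie-break)
are exposed; `epsilon` is the only one users typically touch. The
prominence threshold is an operational choice — the source material gives
no quantitative rule for when a local maximum is "shallow".

## Clustering

Strategies are pluggable (`molsimnet.clustering.STRATEGIES`); the default
is the map-equation method via python-igraph's `community_infomap`, with
`iterations` mapped to optimization trials (default 1000) and the RNG
seeded per call, so runs are deterministic given (network, method,
iterations, seed). Cluster labels are contiguous integers from 1 in order
of first appearance. Degree-0 nodes always form their own size-1
clusters. Connected components serve as a deterministic fallback strategy
and as the oracle for planted-partition tests. Exact membership produced
by a different InfoMap build may differ; only partition properties and
planted-structure recovery are contractual.

## Evaluation

Clusterings are compared over *unordered molecule pairs* of the
evaluation universe, which is the reference's molecule set: TP/FP/FN
count pairs co-clustered in both/only predicted/only reference, TN the
rest; TP+FP+TN+FN = C(n,2) always. The pairwise reading of TP/FP/TN/FN is
a design decision (declared here prominently): the measures' source does
not restate the pair universe, and both measures are invariant to
ordered-vs-unordered counting. Predicted-only molecules are ignored;
reference molecules absent from the prediction are treated as predicted
singletons (logged). Sensitivity is undefined when the reference has no
co-clustered pairs, specificity when no pair is negative in both — both
raise rather than return a sentinel. The implementation mirrors the
membership-list (CML) set-operation scheme; correctness, not the speedup,
is the contract, and an all-pairs double loop is the test oracle.

## Pseudo-reference generation

Phase one: molecules above 80 heavy atoms are excluded; pairs are
screened by HierS ring systems (fused rings merged into systems;
combinations of systems plus shortest-path linkers enumerated for up to 8
systems). Pairs with no common ring system are never analyzed; two
acyclic molecules pass the screen (rejecting them would silently drop
acyclic chemistry). Greedy seed-and-grow: the first unassigned molecule
and all screen-passing unassigned molecules form a group; the group's
common subgraph is computed *jointly* by RDKit's FMCS (elements/bond
order matching) under the tier of the group's largest member — exact
(generous timeout) below 40 heavy atoms, approximate (strict timeout,
best-so-far) up to 80 — and the cluster comprises the group members
containing that subgraph. A per-pair variant was rejected: it splits
combinatorial libraries whenever the seed's closest partner shares an
R-group, because the pair MCES then includes the R-group and excludes the
rest of the library. Clusters with fewer than two members are discarded,
so the output has no singletons. Phase two: a cluster is eliminated whole
if any member exceeds twice the MCES heavy-atom count. No Tanimoto
constraint is imposed at any point — surviving clusters may contain pairs
well below 0.5 similarity, and the test suite contains such a cluster.

Known engine limitation: FMCS returns a *connected* common subgraph,
whereas the procedure as originally described allows an MCES of several
disconnected pieces. The engine is a strategy object; a disconnected-MCES
engine can be dropped in without touching the clustering logic. The
greedy enumeration scheme itself is a simplification — the original
dataset-wide procedure is unpublished — and is deterministic under input
order.

## Synthetic data

`generate_combinatorial_libraries` emulates a small expert-curated
combinatorial reference set: 6 scaffolds, cluster sizes
30+29+28+26+24+20 = 157, two attachment points per scaffold, R-groups
sampled per seed from {C, O, N, F, Cl, Br}. The scaffolds
(methylnaphthalene, dimethylxanthine, dioxadecalin, bornane, a bicyclic
sulfone, dimethylpiperazinedione) were chosen pairwise ring-system
distinct — so the HierS screen separates them too — and chemically
de-correlated (aromatic vs aliphatic, all-carbon vs N/O/S-rich), which
keeps shared ECFP environments across libraries scarce. With these
defaults the separation property (minimum intra-cluster ECFP_4 Tanimoto
strictly above the maximum inter-cluster value) holds with a gap of about
0.21–0.27 regardless of seed; it is nevertheless verified after each
generation and resampled on failure (at most 20 retries) because custom
scaffold/R-group pools provide no such guarantee.

What the generator emulates: planted disjoint clusters, scaffold-governed
similarity, intra/inter separation. What it does not: real libraries'
heterogeneous cluster sizes and densities, overlapping chemotypes,
stereochemistry, charged species, and the heavy-tailed similarity
distributions of screening collections. Passing the recovery tests
therefore shows the pipeline is correct and self-consistent at desk
scale, not that ideal sensitivity/specificity is attainable on real
collections — on large pharmaceutical datasets the published behavior is
a sharp but imperfect optimum at t_α.

`generate_block_matrix` plants blocks with uniform similarities in
disjoint ranges and is the fixture for threshold/topology oracles;
`generate_random_network` wraps seeded G(n, p) graphs for
clustering-coefficient tests.

## Numerical choices and degenerate inputs

* ACC of the two-node complete graph is 0, not 1: both nodes have degree
  1, which the definition sends to CC = 0. The "complete network has
  ACC = 1" limit holds for n ≥ 3.
* Empty fingerprint vs anything: similarity 0; two empty sets: 0.
* `scan` at a threshold below `t_store` and clustering with unknown
  strategies raise immediately.
* Scan grids and floor comparisons use exact rationals; everything
  downstream is ordinary float arithmetic, and ACC oracle agreement is
  asserted to 1e-12.
* Problem sizes in the test suite (graphs ≤ 50 nodes for oracles, 157
  molecules end-to-end, partitions ≤ 200 molecules) are chosen to keep
  the whole suite around a minute while exercising every code path;
  they are desk-scale stand-ins for the hundreds-of-thousands-molecule
  collections the method targets.

## Limitations

* t_α selection assumes ACC(t) exhibits a genuine interior peak; diverse
  collections with weak community structure can produce flat, low curves
  where the widest-peak rule is not meaningful (`NoPeakError`).
* Tversky-style asymmetric similarity, weighted-network clustering
  coefficients, ACC approximation by sampling, and derivative-based EN(t)
  change detection are out of scope.
* The pairwise similarity matrix is quadratic in |M|; the sparse store
  with `t_store` > 0 is the intended regime for large inputs, at the cost
  of an inaccessible low-threshold scan range.
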