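# Methods

This note documents the models and procedures implemented in `sezconn`, the
parameters that matter, the numerical choices made where the conventions were
genuinely open, and what the synthetic benchmarks do and do not demonstrate.

## Data model

A **connector** is one polyadic chemical synapse: one presynaptic site and
one or more postsynaptic sites, each with a 3-D position in nm. The directed
neuron-level graph counts every postsynaptic site as one synaptic connection,
so one connector with *m* post sites contributes *m* units of edge weight and
total edge weight always equals the table's post-site count (checked as an
exact integer invariant). If a neuron appears more than once among the post
sites of one connector, each site is counted separately. Autapses are kept in
the graph but excluded from similarity scoring, and path enumeration never
traverses a self-edge. All positions are stored in nm; CLI flags accept µm
where that is the natural unit and convert on entry. Hemisphere (side) is
carried as metadata only — no mirroring or co-registration is performed.

## Morphology similarity

Skeletons are converted to dotprops: each unbranched run of the tree is
resampled at ~`spacing` intervals (default 1000 nm) and the tangent at each
point is the first principal direction of the covariance of its `k` nearest
resampled points (default k = 5). Neither value is prescribed by the score
itself; the defaults follow common dotprops practice and both are exposed in
the API and CLI. The score of query *Q* against target *T* averages, over
query points, `|q·t| · exp(−d²/2σ²)` with the nearest target point (σ default
2000 nm). The absolute value of the dot product is used because tangent sign
is meaningless (a principal direction is an axis, not a vector); a signed
product would make the score depend on arbitrary orientation choices. The raw
score is asymmetric (it is an average over *query* points); clustering
consumes the symmetrized mean (M + Mᵀ)/2.

Numerically, tangents are unit vectors only to float precision, so each term
is clipped into [0, 1] and self-similarity S(Q,Q) is exact to ~1e-15; tests
assert it at 1e-12. Nearest-neighbour search uses a k-d tree with
exact-distance ties resolved to the lowest point index, which makes scores
reproducible on degenerate (duplicated-point) inputs and lets a brute-force
O(n²) scan reproduce them to 1e-12.

## Synapse-placement similarity

Sites carry a polarity (pre/post) and are only ever matched to same-polarity
sites. For site *s* of neuron *i* with nearest same-polarity site *k* of
neuron *j*:

    f = exp(−d²ₛₖ/2σ²) · exp(−|n_is − n_jk| / (n_is + n_jk))

`n` counts same-polarity sites of the *same* neuron within radius ω of the
site, inclusive of the site itself — inclusion guarantees n ≥ 1 and a
positive denominator. The density factor penalises matching a lone synapse
against a dense cluster; note it is bounded below by e⁻¹ ≈ 0.368, so it
attenuates rather than zeroes a match (the distance factor does the zeroing).
Sites of *i* whose polarity is absent from *j* contribute 0 by default
(policy `unmatched="zero"`); the alternative `"skip"` drops them from the
mean and is appropriate when comparing neurons scored on one polarity only.
Pre and post sites are scored jointly in one average by default. Defaults
σ = ω = 2000 nm. Self-similarity is exactly 1.0 (zero distances, equal
integer densities).

The sign convention of the density exponent is the one that decreases with
density disparity; the alternative (positive) sign would reward disparity
and contradict the factor's purpose, so it is not offered.

## Connectivity similarity

For neurons *i*, *j* with partner counts A_ik, A_jk, each partner contributes
`min − C1·max·exp(−C2·min)` (C1 = 0.5, C2 = 1): matched strong partners score
~min, one-sided partners score −C1·max, and the penalty on a shared partner
decays with the matched strength. The summed raw score is normalized by its
extreme achievable values ±: min = −C1·M and max = M with M = Σ max(A_ik,
A_jk), giving [0, 1]. Entries for *i* and *j* themselves (self- and mutual
connections) are removed first; when nothing remains the score is undefined
and reported as NaN (propagated into clustering as maximal distance, with a
warning). Incoming and outgoing partner vectors are concatenated into one
direction-tagged universe by default (`direction="both"`); `"in"`/`"out"`
restrict to one direction. The score is exactly symmetric and equals 1 only
in the limit of identical, infinitely strong vectors; identical vectors beat
any single-count perturbation, which is the property the tests assert.

## Clustering

Similarity is converted to distance by d = 1 − s (the `"neg"` convention
d = −s is available behind a flag), merged by average linkage (UPGMA, via
scipy), and cut at a similarity score: the cut applies every merge with
height strictly below 1 − score_cut, so a cut at score 1 yields singletons
and "clusters formed at score 0.06" stop merging where mean inter-cluster
similarity falls below 0.06. Strict inequality was chosen so that the
score-cut = 1 limit behaves as expected even with duplicate neurons
(distance 0). Cluster labels are canonical — numbered by smallest member
id — making assignments invariant to input order. Merge tie-breaking is
delegated to scipy's deterministic implementation; ties occur on a measure-
zero set of inputs and never in the benchmarks. Missing similarities map to
maximal distance with a warning. Composition tables report per-cluster
percentages over an annotation attribute (origin, bundle, nerve) and sum to
100 per cluster.

## Paths and layers

All path analyses first drop edges below an integer synapse threshold
(default 2, applied per directed edge). For sources S and one target o:

- 1-hop: s→o edges; 2-hop: s→I→o; 3-hop: s→I1→I2→o, I1 ≠ I2.
- Intermediates must be interneuron-class — neither sensory nor output-class
  (motor/neurosecretory/serotonergic by default); PNs therefore may serve as
  intermediates. Paths are simple (no repeated neurons).
- The 3-hop search is seeded backward from the target's direct-upstream
  interneurons. Because the threshold applies to every edge, the constraint
  "I2 is direct upstream of the target" is already implied by path validity;
  the `restrict_3hop` flag is retained for interface compatibility and
  disabling it cannot remove paths (the superset property is tested).

Layers around an output o (at threshold t): **L2** = interneurons with a
≥ t edge onto o that also receive ≥ t synapses from a sensory source (i.e.
appear on a valid 2-hop path); **L3** = interneurons with a ≥ t edge onto a
direct-upstream interneuron of o and not in L2, split into **L3a** (receive
monosynaptic sensory input at t) and **L3b** (do not). L3 membership is
structural — it does not require a threshold-valid sensory edge onto the L3
neuron, which is exactly what distinguishes L3b. Sensory neurons with direct
≥ t edges are L1 sources. Convergence degree (distinct sources per
interneuron) and divergence (distinct interneuron routes per source) are
tallied over 2-hop paths. Common interneurons bridge an upstream group
(e.g. MBONs) to outputs with ≥ t edges on both legs and are reported with
their layer per output.

Percentage of synaptic connections divides a neuron's in- or outgoing
connections with a partner set by its total in that direction (NaN when the
total is zero); the ranking index divides an edge weight by the strongest
incoming edge of the same target.

## Synthetic data

The generators define the benchmark conditions; they are seeded
(numpy `default_rng`) and byte-reproducible.

**Compartment datasets** place K centroids on a cubic lattice with spacing
`centroid_sep_nm` (default 20 µm = 10σ, matching the well-separated
convergence zones the clustering is meant to resolve) and draw each sensory
neuron's presynaptic sites isotropically around its centroid with st. dev.
`spread_nm` (default 1 µm, i.e. compact glomerulus-like clouds). Each neuron
contributes 10–20 sites; 4–5 neurons per compartment keep the benchmark at
the scale of the smaller real compartments. Each site becomes a connector
onto one of a few shared relay interneurons, post site jittered ≤ 200 nm
(EM connectors are point-like at this scale). Planted labels are returned
for recovery scoring.

**Reflex connectomes** sample edges independently per ordered pair —
sensory→output with p_mono = 0.25, sensory→interneuron with 0.25,
interneuron→output with 0.20, interneuron→interneuron with 0.12, over 12
sensory, 15 interneurons and 3 outputs (motor/neurosecretory/serotonergic) —
with geometric synapse counts (p = 0.45, min 1), so that the threshold of 2
prunes a substantial fraction of edges, mirroring the use of a low absolute
threshold on real data. Connectors are materialized with polyadic fan-out
uniform on 1–3 and exactly reproduce the sampled weights (checked). Ground
truth — L1 edges, per-output L2/L3a/L3b, and the full 1/2/3-hop inventory at
the threshold — is computed at generation time with plain loops over the
sampled weight table, independent of the analysis code paths it validates.

What the benchmarks show: that the scores separate what they are built to
separate, that clustering and path enumeration are exact against independent
oracles and planted truth, and that the whole pipeline is deterministic.
What they do not show: performance on real EM data — synthetic clouds are
isotropic Gaussians without neurite geometry, the wiring model has no
community structure, degree correlations or hemispheric symmetry, and no
reconstruction noise (split/merge errors, missed synapses) is modelled.
Headline biological numbers from a full EM reconstruction are therefore out
of reach at this scale and are not claimed.

## Benchmark problem sizes

The shipped test suite and acceptance script run the oracle-equivalence
checks at 50 random pairs of ≤ 200-point clouds, 200 random annotated graphs
of ≤ 50 nodes, and 20 random UPGMA matrices; planted-compartment recovery at
K = 2…9 × 10 seeds (4 neurons, 10–20 synapses each per compartment); and
path/layer recovery on 25–50 seeded circuit instances. These sizes make the
full suite run in well under a minute while keeping every check exact
(1e-12 tolerances on scores, exact set equality on paths and layers).

## Known limitations

- Similarity scores are O(n·log n) per pair via k-d trees but matrices are
  O(N²) in the number of neurons; no blocking or parallelism is provided.
- The Newick writer emits plain labels; exotic characters in neuron ids are
  not quoted.
- Connectivity similarity on graphs with isolated vertices yields NaN rows;
  downstream clustering treats them as maximally distant rather than
  dropping them.
- The `"neg"` distance convention is provided for completeness but the
  benchmark suite exercises only d = 1 − s.
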