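# Methods

## Model and assumptions

The method assumes that functionally relevant differential-methylation genes
(driver genes) interact densely in the protein–protein interaction network,
while spurious calls scatter, and that true drivers recur across biological
replicate sets even when any single replicate set (RS) misses some of them.
Both assumptions are encoded directly: network propagation ranks genes by
interaction proximity to each differentially methylated gene (DmMG), and the
consensus stage requires edges — not genes — to recur across RSs, so a gene
can be recovered as a driver without being called in every RS, provided its
interactions are.

The network is undirected, unweighted and simple. Gene identity is exact
string match on symbols; alias resolution is deliberately out of scope
(unmatched symbols are counted and logged, not guessed). Preprocessing drops
self-interactions first, then proteins left without any interaction; the
result need not be connected — the walk's probability mass is confined to
the seed's component, which is the mathematically forced behavior of a
column-stochastic transition matrix, so connectivity is not required.

## Random Walk with Restart

`p^(t+1) = (1−λ) M p^t + λ p⁰`, with λ = 0.5, p⁰ uniform over the seeds,
column-normalized adjacency M over a lexicographic node ordering, and L1
convergence threshold 10⁻⁶ (iteration cap 10 000 as an engineering guard;
non-convergence is flagged, not fatal). Since M is column-stochastic and p⁰
normalized, ‖p^t‖₁ = 1 at every step. The iterate is tested against the
closed form λ(I − (1−λ)M)⁻¹p⁰ on random graphs.

Top-K selection (K = 10) excludes the seeds themselves: a seed trivially
ranks first, carries no new interaction information, and a (seed, seed) edge
would be a self-loop the network forbids. Ties at the K-th rank are broken
lexicographically by gene id, for bit-identical rankings across platforms.
Pipeline usage seeds one DmMG at a time; multi-seed walks are supported
because the update rule defines them.

## Degree-conditioned empirical null

Randomization is double-edge switching: Q × |E| attempted switches
(Q = 10 by default; configurable), each replacing edges (a,b),(c,d) with
(a,c),(b,d) unless a self-loop or duplicate would result, preserving every
node's exact degree. RNG streams are split per (network index, class index),
so results are independent of execution order and reproducible per seed.

Per random network and per seed-degree class, one node of that degree is
drawn uniformly — a fresh draw per network, averaging the null over
topological position within the class. Raw frequencies follow the two-stage
normalization (occurrence count ÷ class size in the reference network, then
÷ n_networks); raw values above 1 are possible in principle and preserved in
the occurrence table, with clipping to [0, 1] applied only at the fitted
surface.

The fit per seed class: lowess of raw p on log₁₀(candidate degree) with
nearest-neighbor fraction 0.7 (configurable), then isotonic projection, then
clipping. Monotonicity is *enforced*, not hoped for: raw local regression
can wiggle where degrees are sparse, while the chance of random selection
demonstrably grows with candidate degree. Degrees never observed in a
class's pool enter as p = 0 points so the surface covers the whole degree
range; queries outside the grid clamp to the boundary value; a class with
fewer than three distinct observed candidate degrees falls back to a step
function of the raw values (logged). An unknown seed degree maps to the
nearest fitted class with a warning — it cannot occur when seeds are network
nodes.

Models serialize to a flat versioned TSV with provenance (RNG seed, network
count, switching effort, K, and an order-independent hash of the edge set);
applying a model to a network with a different hash is an error. This
build-once-reuse design is what makes candidate assessment cheap: two degree
lookups and one interpolation per candidate, no walks on random networks.

## Significance filter and consensus

Keep rule: `p < α OR L = 1`, α = 0.05, strict inequality (p = 0.05 is
dropped). The L = 1 branch protects direct interactors — typically
well-connected genes whose degree alone would fail the topological test —
on the grounds that a physical interaction with the seed is itself evidence
of functional relevance. An UNREACHABLE path can only fail the L branch; it
never arises for walk candidates, which have positive probability and hence
share the seed's component.

Edge pooling admits a pair only if both endpoints are DmMGs in at least one
RS — the same RS or different ones. Recurrence in *every* RS is the default
retention rule; `min_recurrence` is exposed because sub-maximal recurrence
counts are themselves informative for display and threshold exploration.
Driver genes are exactly the nodes incident to a retained edge. A gene's
consensus hyper/hypo label is the majority vote over the RSs where it is a
DmMG, ties resolved by the sign of its globally best-FDR site.

Weighted scoring reads "lg" as log₁₀. When an edge occurs in an RS where one
endpoint is not a DmMG (the cross-RS case the endpoint rule permits), that
endpoint's FDR for the RS is gap-filled with its best FDR across all RSs;
zero FDRs are floored at a configurable 10⁻³⁰⁰.

## Differential methylation input

Site tables are tab-delimited with configurable column names; coordinates
are 0-based half-open (BED convention, matching peak-caller output), strand
carried but unused. The site-level FDR cutoff defining a DmMG defaults to
0.05 and is exposed, since upstream callers differ. "Most differentially
methylated site" is resolved as smallest FDR, ties by larger |log2fc|, then
genomic order — FDR being the ranking statistic differential peak callers
report. Genes absent from the network are kept in summaries but skipped by
propagation, with a logged count.

## Synthetic studies

The generator emulates the replicate-variance premise: a module of
`module_size` genes seeded at the highest-degree node and grown greedily by
connectivity to the module (so planted genes interact densely), observed per
RS with probability 1 − dropout as 1–3 sites each, against background genes
spuriously called with probability `background_rate`. Planted site FDRs are
log-uniform on [10⁻¹⁰, 10⁻³] and background FDRs on [10⁻³, 0.049]: both
pass the 0.05 call threshold, but the separation lets weighted-score
behavior be tested. Planting is hyper-only by default (the direction
expected under demethylase activity); a mixed-sign mode exists. Defaults —
100-node scale-free network, module 12, 4 RSs, dropout 0.3, background rate
0.02 — represent a small knockdown cohort.

What the generator does *not* emulate: read-level MeRIP-seq noise, realistic
genomic coordinates, correlated dropout between RSs, or the scale of a real
interactome (~16 000 nodes, hundreds of degree classes). Passing tests
therefore demonstrate the algorithm's contracts and statistical behavior,
not performance on any real knockdown dataset.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale as a deliberate design
choice: 100-node networks for pipeline checks, a 500-node network with 20
random networks per null model for the cross-seed robustness check, and 10
repetitions for planted-module recovery. The full protocol (100 random
networks) is the default in the API and CLI. Determinism throughout comes
from numpy Generator streams seeded per (run seed, network index, class
index); identical inputs give bit-identical outputs, including rankings and
serialized models.

## Limitations

Only a PPI reference is supported — no noncoding-RNA networks. No
multiple-testing correction is applied across candidates at the filter
stage, by design. The null conditions on degree alone; other topological
features (clustering, community structure) are not controlled. Symbol-keyed
joins between methylation calls and the network are the user's
responsibility, including organism filtering of BioGRID exports.
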