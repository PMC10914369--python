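# Methods

## Data model

A *realization* is one observed bipartite network: a map from
(consumer, resource) pairs to positive interaction weights (detection
counts). Vertex sets are implied by edges — a species "occurs" in a
realization iff it has at least one interaction there. This matters for
the partitioning: interaction-count data carry no record of a species that
was present but never interacted, so occurrence-by-interaction is the only
defensible definition of the shared-species set, and species-composition
dissimilarity (β_S) is likewise computed from interacting species only.
Consumer and resource label spaces must be disjoint; a label appearing in
both roles is rejected rather than silently treated as two vertices.

The *meta-network* is the edge-wise sum of all realizations. It is always
derived, never stored independently, so the invariant "meta = union with
summed weights" holds by construction, and species removal commutes with
aggregation.

## Dissimilarity partitioning

Every pairwise comparison aligns the two networks over their edge union
and classifies each edge: `shared` (present in both), `unique_rw`
(one-sided, both endpoints occur in both networks) or `unique_st`
(one-sided, at least one endpoint absent from one network). The binary
Sørensen components and the quantitative Bray–Curtis components are then
sums over these classes; the brute-force oracle in the test suite
re-derives every component by independent term-by-term enumeration.

Choices that the data or the framework leave open, fixed here:

* **Proportion conversion** divides each network's weights by its own
  total, *before* comparison and *after* any species removal. Removing an
  abundant species therefore rescales all remaining proportions — the
  literal consequence of "remove from the dataset, then analyse".
* **framework1, quantitative β_RW** restricts the Bray–Curtis sums to
  edges between shared species but does **not** renormalize the
  subnetwork weights; renormalizing would break the comparability with
  β_INT needed by the subtraction β_ST = β_INT − β_RW. If no
  shared-species edge exists the restricted dissimilarity is defined as 0.
* **β_S (quantitative)** uses the concatenated consumer-and-resource
  marginal interaction weights as the abundance surrogate (normalized to
  sum 1 per network when proportions are on); interaction data offer no
  other abundance measure.
* **Degenerate pairs**: comparisons involving an empty network return a
  flagged result with NaN components rather than a silent 0 or 1. Empty
  realizations can arise from leave-one-out removal and are retained so
  series length is stable.
* Components are mathematically confined to [0, 1]; additivity of
  framework2 holds to < 1e-12 in the property suite. Nothing is clipped
  inside the computation. The ratio β_RW/β_INT is reported as missing when
  β_INT = 0.

## Leave-one-out contributions

For species *i*, component X ∈ {RW, INT, ST, S} and realization *t*,
Δβ′_X,i(t) = β′_X(t) − β′_X,Δi(t), where the second term is recomputed on
the series with *i* deleted from every realization and the meta-network
rebuilt (the "reduced-dataset" reading; the alternative — comparing
against the original meta — is not what deleting a species from the data
would produce). Proportions are re-derived on the reduced networks.
Maxima are taken over non-degenerate realizations only; deltas are signed
and never clipped (a species can suppress apparent rewiring, giving
negative values).

One analytic consequence documented here because it is easy to
misexpect: a "null" species holding a constant weight share *f* of every
realization and of the meta does **not** have zero Δβ′_RW in general — its
presence rescales everyone else's proportions, so Δβ′_RW = −f·β′_RW(base).
The delta vanishes only when the base series itself shows no rewiring;
the tests assert both facts.

Cost is one vs-meta pass per species, O(S·T) pairwise partitions; the
alignment is dictionary-based, so a ~1,000-species meta-network over 8
realizations completes in minutes on one core.

## Static centralities and link flexibility

The meta-network is treated as one undirected, unweighted simple graph of
N vertices (shortest paths ignore weights; no weighting rule is defensible
for detection counts). Degree is divided by N − 1; vertex betweenness is
normalized by 2/((N−1)(N−2)) (reported as 0, flagged, when N < 3);
eigenvector centrality is the principal adjacency eigenvector scaled to
max 1, computed on the largest component with other components set to 0;
edge betweenness is divided by the N(N−1)/2 unordered pairs. Closeness
follows the convention "raw closeness / (N − 1)" with raw closeness the
reciprocal of the summed distance to reachable vertices and the component
size standing in for N on disconnected graphs; note this differs from the
more common (N−1)/Σd convention by a factor of (N−1)², so closeness values
are comparable within a network but not across conventions.

Link flexibility multiplies the two endpoints' max Δβ′_RW after min–max
scaling *within each guild* (symmetric treatment keeps the product in
[0, 1]; scaling of the consumer side can be disabled where a raw-scale
axis is wanted). A guild whose scores are all equal scales to 1
throughout. The default `min_count = 10` keeps only links observed in ten
or more samples, the usual well-observed-link threshold for
detection-count data; the ranking of links is invariant to any positive
affine rescaling of the raw scores.

## Synthetic series generator

The generator emulates a seasonal detection-count survey: T ordered
realizations, species occurring independently per realization with a
persistence probability, each occurring consumer drawing a diet
distribution over the occurring resources from a symmetric Dirichlet with
a per-consumer concentration, and a fixed per-realization count budget
allocated by one multinomial draw (equal activity per occurring
consumer). Low concentration produces sparse diets redrawn each
realization — interaction rewiring by mechanism, independent of turnover;
turnover is controlled purely by the persistence probabilities. Planted
*coordinators* are consumers with a much lower concentration than the
baseline. An infinite concentration is honoured as an exactly uniform,
non-random diet, giving the no-rewiring limit.

Defaults (one planted coordinator at concentration 0.05 vs baseline 5.0;
T = 8, 20 consumers, 100 resources, persistence 0.7, 600 counts per
realization) mirror a single season of monthly sampling at the scale of a
few hundred detection counts per month. With them, consecutive β_INT is
around 0.8 with a 30–50% rewiring share, and realization-vs-meta β′_RW
exceeds β′_ST in every month — the qualitative regime of real seasonal
predator–prey data.

What the generator deliberately does not model: resource-side rewiring
mechanisms (resource coordinators arise only indirectly through their
consumers), abundance variation among consumers, mechanistic population
dynamics, abiotic covariates, and observation error beyond multinomial
count noise. Passing recovery tests therefore show that the index detects
a diet-instability signal against realistic count noise and occupancy
turnover — not that it is robust to every failure mode of field data.

Two properties of the planted-coordinator experiment are worth keeping in
mind when interpreting it. First, under persistence 0.7 the coordinator is
present in at most 4 of 8 realizations in roughly a fifth of replicates;
its weight share in the meta-network is then small and its leave-one-out
delta can drop below the noise floor set by the 19 baseline consumers'
max-over-series statistics, so top-1 recovery saturates near 80% rather
than approaching 100%. Second, the baseline concentration of 5.0 spread
over ~70 occurring resources itself implies genuinely variable diets, so
the "null" community is not rewiring-free — recovery measures contrast,
not detection against a static background.

## Problem sizes and determinism

All stochastic tests fix their generator seeds, and the Monte-Carlo
experiments (100 replicates at the default conditions) use sub-seeds drawn
from one master generator, so every reported number is reproducible
bit-for-bit from the seed. Property suites run on randomly sampled small
networks (≤ 5×5 for oracle equivalence, 1,000 pairs for additivity), sizes
at which the brute-force oracles are exact and instantaneous.
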