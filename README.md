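# netflex

Temporal flexibility analysis of bipartite ecological interaction networks:
how much does the architecture of a consumer–resource network (who eats
whom, and how often) change between snapshots, how much of that change is
*interaction rewiring* versus *species turnover*, and which species drive
it?

The package is written for community ecologists working with time series of
weighted bipartite interaction matrices — e.g. monthly predator–prey
detection counts from diet DNA metabarcoding, or seasonal plant–pollinator
visitation counts — and for methods developers who want a tested,
scriptable implementation of network β-diversity partitioning and the
leave-one-species-out "network coordinator" index.

## The indices

For two network realizations **M**, **N** (or a realization and the
*meta-network*, the union of all realizations with summed edge weights),
total interaction dissimilarity splits additively as

    β_INT = β_RW + β_ST

where β_RW collects differences among species present in both networks
(rewiring) and β_ST collects differences involving species present in only
one (turnover). With the binary Sørensen metric and the usual a / b / c
edge-match counts,

    β_INT = (b + c) / (2a + b + c)

and two partitioning conventions are provided:

* **framework2** (common denominator, the default):
  β_RW = (b′ + c′) / (2a + b + c), β_ST = (b_ST + c_ST) / (2a + b + c),
  with b′, c′ the one-sided edges whose endpoints both occur in both
  networks and b_ST = b − b′, c_ST = c − c′. Additive by construction, both
  components nonnegative.
* **framework1** (subtraction): β_RW = (b′ + c′) / (2a′ + b′ + c′) on the
  shared-species subnetworks, β_ST = β_INT − β_RW. Kept for comparison; it
  can report zero turnover in pairs with complete turnover of one guild.

The quantitative analogue uses Bray–Curtis over the aligned edge-weight
vectors (counts converted to within-network proportions by default), with
the numerator split edge-class-wise in framework2. Species-composition
dissimilarity β_S uses the same metric on species presence (binary) or
marginal interaction weights (quantitative).

A species' contribution to flexibility is the leave-one-out index

    Δβ′_RW,i = β′_RW − β′_RW,Δi

where primes denote realization-vs-meta-network dissimilarity and β′_RW,Δi
is recomputed after deleting species *i* from every realization and
rebuilding the meta-network. The per-species maximum of Δβ′_RW,i across the
series ranks *network coordinators* — species whose presence most inflates
rewiring. Static centralities (degree, betweenness, eigenvector, closeness,
edge betweenness) and a per-link flexibility score (the product of the two
endpoints' min–max-scaled coordinator indices) support the comparison of
this dynamic view with classic static network analysis.

## Worked example

```python
from netflex import (SyntheticParams, generate_series,
                     consecutive_dissimilarity, contribution_summary)

params = SyntheticParams(seed=42)          # 8 months, 20 consumers, 100 resources
series, truth = generate_series(params)    # one planted coordinator, C001
cons = consecutive_dissimilarity(series)   # framework2, Bray-Curtis, proportions
print(cons[["pair_id", "beta_INT", "beta_RW", "beta_ST", "rw_ratio"]]
      .round(3).to_string(index=False))
```

```
 pair_id  beta_INT  beta_RW  beta_ST  rw_ratio
t01->t02     0.848    0.337    0.512     0.397
t02->t03     0.843    0.345    0.498     0.409
t03->t04     0.850    0.328    0.522     0.386
t04->t05     0.820    0.357    0.463     0.435
t05->t06     0.817    0.398    0.419     0.487
t06->t07     0.822    0.338    0.484     0.411
t07->t08     0.803    0.400    0.403     0.498
```

Consecutive snapshots differ substantially (β_INT ≈ 0.8), with rewiring
responsible for roughly 39–50% of the change (`rw_ratio` = β_RW/β_INT) and
species turnover for the rest — the signature of a community whose
architecture is flexible on both margins.

```python
summary = contribution_summary(series, components=("RW",),
                               species=sorted(series.meta.consumers))
print(summary.head(3).round(4).to_string(index=False))
```

```
species    guild  n_realizations_evaluated  max_delta_RW
   C006 consumer                         8        0.0068
   C008 consumer                         8        0.0067
   C001 consumer                         8        0.0066
```

The planted coordinator `C001` (diet concentration 0.05 against a community
baseline of 5.0) sits near the top of the ranking; in this particular draw
two baseline consumers edge past it. `recovery_experiment` quantifies that
sampling variability: across 100 independent replicates at the default
conditions the planted species takes rank 1 in roughly four out of five.

The same pipeline runs from the shell on any long-format edge table
(columns `realization`, `consumer`, `resource`, `count`):

```sh
netflex simulate --seed 42 --outdir sim/
netflex partition --input sim/interactions.tsv --outdir out/
netflex contributions --input sim/interactions.tsv --outdir out/
netflex flexibility --input sim/interactions.tsv --min-count 10 --outdir out/
```

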