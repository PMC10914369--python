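"""Pairwise network dissimilarity and its rewiring/turnover partition.

Total interaction dissimilarity between two network realizations,

    beta_INT = beta_RW + beta_ST,

is split additively into a component due to *interaction rewiring*
(beta_RW: changed interactions among species present in both networks) and
one due to *species turnover* (beta_ST: interactions involving species
present in only one network).  Two partitioning frameworks are supported:

``framework1``
    Subtraction-based: beta_RW is the dissimilarity of the shared-species
    subnetworks with its own denominator, and beta_ST = beta_INT - beta_RW.
    Additivity is not guaranteed; beta_ST can be negative and can miss real
    turnover (a pair with complete turnover of one guild can still yield
    beta_ST = 0).

``framework2``
    Common-denominator: beta_RW and beta_ST are computed directly over the
    full edge union with the same denominator as beta_INT, so the partition
    is additive by construction and both components are nonnegative.

Both the binary Sorensen metric and the quantitative Bray-Curtis metric are
implemented; with Bray-Curtis, edge counts are conventionally converted to
within-network proportions first (``proportions=True``) so that networks of
different sampling depth are comparable.

The same machinery compares each realization against the *meta-network*
(the union of all realizations); those primed indices (beta_INT', beta_RW',
beta_ST', beta_S') underlie the species-contribution analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError
from .network import (
    SHARED,
    UNIQUE_RW,
    UNIQUE_ST,
    BipartiteNetwork,
    NetworkSeries,
    align_edges,
)

FRAMEWORKS = ("framework1", "framework2")
METRICS = ("sorensen", "bray_curtis")

#: components in [0, 1] are clipped to the unit interval only on reporting;
#: raw arithmetic is never clipped
_TOL = 1e-9


@dataclass(frozen=True)
class BetaPartition:
    """The (beta_S, beta_INT, beta_RW, beta_ST) quadruple for one pair.

    ``degenerate`` is set when either network is empty; the components are
    then NaN rather than a silent 0 or 1.
    """

    beta_S: float
    beta_INT: float
    beta_RW: float
    beta_ST: float
    framework: str
    metric: str
    proportions: bool
    degenerate: bool = False

    @property
    def rw_ratio(self) -> float:
        """beta_RW / beta_INT; NaN when beta_INT is 0 or the pair is degenerate."""
        if self.degenerate or not self.beta_INT > 0:
            return math.nan
        return self.beta_RW / self.beta_INT

    def as_dict(self) -> dict:
        return {
            "beta_S": self.beta_S,
            "beta_INT": self.beta_INT,
            "beta_RW": self.beta_RW,
            "beta_ST": self.beta_ST,
            "rw_ratio": self.rw_ratio,
            "framework": self.framework,
            "metric": self.metric,
            "proportions": self.proportions,
            "degenerate": self.degenerate,
        }


def _degenerate(framework, metric, proportions) -> BetaPartition:
    nan = math.nan
    return BetaPartition(nan, nan, nan, nan, framework, metric, proportions, True)


def _sorensen_components(m, n, framework):
    aln = align_edges(m, n)
    a, b, c = aln.a, aln.b, aln.c
    denom = 2 * a + b + c
    beta_int = (b + c) / denom
    if framework == "framework2":
        beta_rw = (aln.b_rw + aln.c_rw) / denom
        beta_st = (aln.b_st + aln.c_st) / denom
    else:
        # shared-species subnetworks: a' = a, and the one-sided edges of the
        # subnetworks are exactly the unique_rw-class edges
        sub_denom = 2 * a + aln.b_rw + aln.c_rw
        beta_rw = (aln.b_rw + aln.c_rw) / sub_denom if sub_denom > 0 else 0.0
        beta_st = beta_int - beta_rw
    return beta_int, beta_rw, beta_st


def _bray_curtis_components(m, n, framework):
    aln = align_edges(m, n)
    diff = np.abs(aln.u - aln.v)
    tot = aln.u + aln.v
    denom = float(tot.sum())
    beta_int = float(diff.sum()) / denom
    rw_mask = aln.mask(SHARED, UNIQUE_RW)
    if framework == "framework2":
        beta_rw = float(diff[rw_mask].sum()) / denom
        beta_st = float(diff[~rw_mask].sum()) / denom
    else:
        sub_denom = float(tot[rw_mask].sum())
        beta_rw = float(diff[rw_mask].sum()) / sub_denom if sub_denom > 0 else 0.0
        beta_st = beta_int - beta_rw
    return beta_int, beta_rw, beta_st


def _species_dissimilarity(m, n, metric, proportions):
    """beta_S on species compositions.

    Binary: Sorensen on presence of species (both guilds pooled).
    Quantitative: Bray-Curtis on the concatenated consumer-and-resource
    marginal interaction-weight vectors, each network's vector normalized to
    sum 1 when proportions are on (marginal interaction weight is the only
    abundance surrogate in interaction-only data).
    """
    if metric == "sorensen":
        sm, sn = m.species, n.species
        a = len(sm & sn)
        b = len(sm - sn)
        c = len(sn - sm)
        return (b + c) / (2 * a + b + c)
    mm, mn = m.marginal_weights(), n.marginal_weights()
    species = sorted(set(mm) | set(mn))
    u = np.array([mm.get(s, 0.0) for s in species])
    v = np.array([mn.get(s, 0.0) for s in species])
    if proportions:
        u = u / u.sum()
        v = v / v.sum()
    return float(np.abs(u - v).sum() / (u + v).sum())


def partition_pair(
    m: BipartiteNetwork,
    n: BipartiteNetwork,
    *,
    framework: str = "framework2",
    metric: str = "bray_curtis",
    proportions: bool = True,
) -> BetaPartition:
    """Partition the dissimilarity between two networks.

    Parameters
    ----------
    m, n
        The two realizations to compare (order does not matter: every
        component is symmetric).
    framework
        ``framework2`` (common denominator, additive; the default) or
        ``framework1`` (subtraction-based).
    metric
        ``bray_curtis`` (quantitative, the default) or ``sorensen``
        (binary presence/absence of edges).
    proportions
        With ``bray_curtis``, convert each network's counts to proportions
        before comparison.  Ignored by the binary metric.

    Returns
    -------
    BetaPartition
        With ``degenerate=True`` and NaN components if either network is
        empty.
    """
    if framework not in FRAMEWORKS:
        raise ValueError(f"unknown framework {framework!r}")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if m.is_empty or n.is_empty:
        return _degenerate(framework, metric, proportions)
    beta_s = _species_dissimilarity(m, n, metric, proportions)
    if metric == "sorensen":
        beta_int, beta_rw, beta_st = _sorensen_components(m, n, framework)
    else:
        mp = m.to_proportions() if proportions else m
        np_ = n.to_proportions() if proportions else n
        beta_int, beta_rw, beta_st = _bray_curtis_components(mp, np_, framework)
    return BetaPartition(
        beta_S=beta_s,
        beta_INT=beta_int,
        beta_RW=beta_rw,
        beta_ST=beta_st,
        framework=framework,
        metric=metric,
        proportions=proportions,
    )


def _table(rows, pair_mode, framework, metric, proportions) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "pair_id": label,
                "beta_S": p.beta_S,
                "beta_INT": p.beta_INT,
                "beta_RW": p.beta_RW,
                "beta_ST": p.beta_ST,
                "rw_ratio": p.rw_ratio,
                "degenerate": p.degenerate,
            }
            for label, p in rows
        ]
    )
    df.attrs.update(
        pair_mode=pair_mode, framework=framework, metric=metric, proportions=proportions
    )
    return df


def consecutive_dissimilarity(
    series: NetworkSeries,
    *,
    framework: str = "framework2",
    metric: str = "bray_curtis",
    proportions: bool = True,
) -> pd.DataFrame:
    """Partition dissimilarity for each pair of consecutive realizations.

    Returns a tidy table with T-1 rows for T realizations; ``pair_id`` is
    ``"<from>-><to>"``.  ``rw_ratio`` (beta_RW / beta_INT) is NaN where
    beta_INT is 0.
    """
    if len(series) < 2:
        raise ValueError("consecutive dissimilarity needs at least two realizations")
    rows = []
    for (id_a, net_a), (id_b, net_b) in zip(list(series)[:-1], list(series)[1:]):
        p = partition_pair(
            net_a, net_b, framework=framework, metric=metric, proportions=proportions
        )
        rows.append((f"{id_a}->{id_b}", p))
    return _table(rows, "consecutive", framework, metric, proportions)


def vs_meta_dissimilarity(
    series: NetworkSeries,
    *,
    framework: str = "framework2",
    metric: str = "bray_curtis",
    proportions: bool = True,
) -> pd.DataFrame:
    """Primed dissimilarity of each realization against the meta-network.

    One row per realization, comparing it with the full meta-network (the
    realization's own edges included).  The components are the primed
    indices beta_INT', beta_RW', beta_ST' and beta_S'.
    """
    rows = []
    for rid, net in series:
        p = partition_pair(
            net, series.meta, framework=framework, metric=metric, proportions=proportions
        )
        rows.append((rid, p))
    return _table(rows, "vs_meta", framework, metric, proportions)


def write_dissimilarity_table(
    df: pd.DataFrame, path, *, delimiter: str = "\t", header_comments=()
) -> None:
    """Write a dissimilarity table as tidy TSV with provenance columns."""
    out = df.copy()
    out["framework"] = df.attrs.get("framework", "")
    out["metric"] = df.attrs.get("metric", "")
    out["proportions"] = df.attrs.get("proportions", "")
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep=delimiter, index=False)
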