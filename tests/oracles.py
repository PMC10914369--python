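"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's alignment/partition code paths:
edge classification is done by explicit endpoint-occurrence tests and the
numerators/denominators are accumulated term by term while looping over the
edge union.
"""

from __future__ import annotations

import numpy as np


def species_of(edges: dict) -> set:
    out = set()
    for c, r in edges:
        out.add(c)
        out.add(r)
    return out


def classify(edge, m_edges, n_edges) -> str:
    c, r = edge
    in_m = edge in m_edges
    in_n = edge in n_edges
    if in_m and in_n:
        return "shared"
    sp_m, sp_n = species_of(m_edges), species_of(n_edges)
    if c in sp_m and c in sp_n and r in sp_m and r in sp_n:
        return "unique_rw"
    return "unique_st"


def brute_partition(m_edges: dict, n_edges: dict, framework: str, metric: str,
                    proportions: bool):
    """Return (beta_S, beta_INT, beta_RW, beta_ST) by explicit enumeration."""
    m = dict(m_edges)
    n = dict(n_edges)
    if metric == "bray_curtis" and proportions:
        mt, nt = sum(m.values()), sum(n.values())
        m = {e: w / mt for e, w in m.items()}
        n = {e: w / nt for e, w in n.items()}
    union = set(m) | set(n)

    if metric == "sorensen":
        a = b = c = b_rw = c_rw = b_st = c_st = 0
        for e in union:
            cls = classify(e, m, n)
            if cls == "shared":
                a += 1
            elif e in m:
                b += 1
                if cls == "unique_rw":
                    b_rw += 1
                else:
                    b_st += 1
            else:
                c += 1
                if cls == "unique_rw":
                    c_rw += 1
                else:
                    c_st += 1
        denom = 2 * a + b + c
        beta_int = (b + c) / denom
        if framework == "framework2":
            beta_rw = (b_rw + c_rw) / denom
            beta_st = (b_st + c_st) / denom
        else:
            sub = 2 * a + b_rw + c_rw
            beta_rw = (b_rw + c_rw) / sub if sub else 0.0
            beta_st = beta_int - beta_rw
    else:
        num_tot = num_rw = num_st = denom = denom_rw = 0.0
        for e in union:
            u = m.get(e, 0.0)
            v = n.get(e, 0.0)
            d = abs(u - v)
            s = u + v
            num_tot += d
            denom += s
            if classify(e, m, n) == "unique_st":
                num_st += d
            else:
                num_rw += d
                denom_rw += s
        beta_int = num_tot / denom
        if framework == "framework2":
            beta_rw = num_rw / denom
            beta_st = num_st / denom
        else:
            beta_rw = num_rw / denom_rw if denom_rw else 0.0
            beta_st = beta_int - beta_rw

    # species-composition dissimilarity
    sp_m, sp_n = species_of(m_edges), species_of(n_edges)
    if metric == "sorensen":
        a_s = len(sp_m & sp_n)
        beta_s = (len(sp_m - sp_n) + len(sp_n - sp_m)) / (
            2 * a_s + len(sp_m - sp_n) + len(sp_n - sp_m)
        )
    else:
        marg_m: dict = {}
        marg_n: dict = {}
        for (cc, rr), w in m_edges.items():
            marg_m[cc] = marg_m.get(cc, 0.0) + w
            marg_m[rr] = marg_m.get(rr, 0.0) + w
        for (cc, rr), w in n_edges.items():
            marg_n[cc] = marg_n.get(cc, 0.0) + w
            marg_n[rr] = marg_n.get(rr, 0.0) + w
        if proportions:
            tm, tn = sum(marg_m.values()), sum(marg_n.values())
            marg_m = {s: w / tm for s, w in marg_m.items()}
            marg_n = {s: w / tn for s, w in marg_n.items()}
        num = den = 0.0
        for s in sp_m | sp_n:
            u, v = marg_m.get(s, 0.0), marg_n.get(s, 0.0)
            num += abs(u - v)
            den += u + v
        beta_s = num / den
    return beta_s, beta_int, beta_rw, beta_st


def power_iteration_eigenvector(adj: np.ndarray, iters: int = 20000, tol: float = 1e-14):
    """Principal eigenvector of a symmetric nonnegative matrix, max-scaled.

    A diagonal shift breaks the +/-lambda eigenvalue symmetry of bipartite
    adjacency matrices (which would make plain power iteration oscillate)
    without changing the eigenvectors.
    """
    shifted = adj + np.eye(adj.shape[0])
    x = np.ones(adj.shape[0])
    for _ in range(iters):
        y = shifted @ x
        y = y / np.linalg.norm(y)
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    return x / x.max()


def random_network_edges(rng, max_consumers=5, max_resources=5, weighted=True,
                         p_edge=0.45):
    """Random small bipartite edge dict (possibly retried until nonempty)."""
    consumers = [f"C{i}" for i in range(1, rng.integers(1, max_consumers + 1) + 1)]
    resources = [f"r{i}" for i in range(1, rng.integers(1, max_resources + 1) + 1)]
    while True:
        edges = {
            (c, r): float(rng.integers(1, 10)) if weighted else 1.0
            for c in consumers
            for r in resources
            if rng.random() < p_edge
        }
        if edges:
            return edges
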