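"""Weighted modularity and two-phase (Blondel/Louvain) community detection.

Modularity of a partition {c} of a weighted undirected graph is

    Q = sum_c [ W_c / m  -  gamma * (d_c / 2m)^2 ]

where W_c is the total intra-community edge weight (each edge once,
self-loops once), d_c the total weighted degree inside c (self-loops
counted twice), and m the total edge weight.  gamma is the resolution
(1.0 = plain modularity).  Isolated nodes contribute nothing to Q and are
assigned singleton communities.

The optimizer is the greedy two-phase local-move algorithm: sweep nodes in
a seeded random order, moving each to the neighboring community with the
largest positive modularity gain, until no move improves Q; then collapse
communities into super-nodes (intra-weight becomes a self-loop) and repeat
on the aggregate graph.  The aggregation convention — self-loop weight w
contributes w to W_c and 2w to d_c — makes Q invariant across levels, so
the Q reported for the final partition equals :func:`modularity` evaluated
on the original graph.

A brute-force exhaustive-partition oracle is provided for graphs of at most
12 nodes; it exists to validate the heuristic, never to replace it.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import pandas as pd
import networkx as nx


class ModularityUndefinedError(ValueError):
    """Raised for edgeless graphs, where m = 0 and Q is undefined."""


def _weights(g: nx.Graph):
    """(m, degree dict, neighbor-weight dicts, self-loop weights)."""
    k: dict = {u: 0.0 for u in g.nodes}
    nbrs: dict = {u: {} for u in g.nodes}
    self_w: dict = {u: 0.0 for u in g.nodes}
    m = 0.0
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", 1.0))
        m += w
        if u == v:
            self_w[u] += w
            k[u] += 2.0 * w
        else:
            nbrs[u][v] = nbrs[u].get(v, 0.0) + w
            nbrs[v][u] = nbrs[v].get(u, 0.0) + w
            k[u] += w
            k[v] += w
    return m, k, nbrs, self_w


def modularity(g: nx.Graph, assignment: dict, gamma: float = 1.0) -> float:
    """Evaluate Q for an explicit node -> community assignment.

    Raises :class:`ModularityUndefinedError` if the graph has no edges and
    ``KeyError``-style ``ValueError`` if the assignment misses a node.
    """
    missing = [u for u in g.nodes if u not in assignment]
    if missing:
        raise ValueError(f"assignment missing nodes: {missing[:5]}")
    m, k, nbrs, self_w = _weights(g)
    if m <= 0:
        raise ModularityUndefinedError("modularity undefined: graph has no edges")
    w_c: dict = {}
    d_c: dict = {}
    for u in g.nodes:
        c = assignment[u]
        d_c[c] = d_c.get(c, 0.0) + k[u]
        w_c[c] = w_c.get(c, 0.0) + self_w[u]
    for u, v, d in g.edges(data=True):
        if u != v and assignment[u] == assignment[v]:
            w_c[assignment[u]] = w_c.get(assignment[u], 0.0) + float(d.get("weight", 1.0))
    return sum(
        w_c.get(c, 0.0) / m - gamma * (d_c[c] / (2.0 * m)) ** 2 for c in d_c
    )


def _canonical(assignment: dict, order) -> dict:
    """Relabel communities as contiguous ints by order of first appearance."""
    relabel: dict = {}
    out = {}
    for u in order:
        c = assignment[u]
        if c not in relabel:
            relabel[c] = len(relabel)
        out[u] = relabel[c]
    return out


@dataclass(frozen=True)
class Partition:
    """A node -> community assignment with its modularity score.

    Community ids are contiguous integers from 0 in order of first
    appearance over the graph's node order.
    """

    assignment: dict
    modularity: float
    gamma: float = 1.0
    seed: int | None = None
    converged: bool = True

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> list[list]:
        """Members per community id, ordered by id."""
        out: dict[int, list] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, []).append(node)
        return [out[c] for c in sorted(out)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"disease": list(self.assignment), "community": list(self.assignment.values())}
        )


def _one_level(nodes, m, k, nbrs, self_w, gamma, rng):
    """Phase 1: local moves until a full sweep makes none. Returns node->comm."""
    comm = {u: i for i, u in enumerate(nodes)}
    # Sigma_tot per community (sum of degrees); intra weights tracked via comm.
    sigma = {comm[u]: k[u] for u in nodes}
    improved_any = False
    while True:
        moved = False
        order = list(nodes)
        rng.shuffle(order)
        for u in order:
            cu = comm[u]
            ku = k[u]
            # weight from u to each neighboring community
            w_to: dict = {}
            for v, w in nbrs[u].items():
                w_to[comm[v]] = w_to.get(comm[v], 0.0) + w
            # remove u from its community
            sigma[cu] -= ku
            w_own = w_to.get(cu, 0.0)
            # gain of staying (re-inserting into cu)
            best_c, best_gain = cu, w_own / m - gamma * ku * sigma[cu] / (2.0 * m * m)
            for c in sorted(w_to):
                if c == cu:
                    continue
                gain = w_to[c] / m - gamma * ku * sigma[c] / (2.0 * m * m)
                # strict improvement; ties go to the lowest community id,
                # which the sorted scan guarantees
                if gain > best_gain + 1e-15:
                    best_c, best_gain = c, gain
            sigma[best_c] = sigma.get(best_c, 0.0) + ku
            if best_c != cu:
                comm[u] = best_c
                moved = True
                improved_any = True
        if not moved:
            break
    return comm, improved_any


def louvain(
    g: nx.Graph,
    seed: int = 0,
    gamma: float = 1.0,
    max_passes: int = 100,
) -> Partition:
    """Greedy two-phase modularity optimization.

    Deterministic given (graph, seed, gamma).  Isolated nodes receive
    singleton communities.  If ``max_passes`` aggregation levels are
    exhausted before convergence the best partition so far is returned with
    ``converged=False``.
    """
    if g.number_of_edges() == 0:
        raise ModularityUndefinedError("community detection needs at least one edge")
    rng = random.Random(seed)
    # current mapping: original node -> super-node of the working graph
    mapping = {u: u for u in g.nodes}
    work = g
    prev_q = None
    converged = True
    for _ in range(max_passes):
        m, k, nbrs, self_w = _weights(work)
        nodes = [u for u in work.nodes if k[u] > 0]
        isolated = [u for u in work.nodes if k[u] == 0]
        comm, improved = _one_level(nodes, m, k, nbrs, self_w, gamma, rng)
        for u in isolated:
            comm[u] = ("iso", u)
        assignment = {orig: comm[mapping[orig]] for orig in g.nodes}
        q = modularity(g, assignment, gamma)
        if prev_q is not None:
            # Q never decreases across levels: each level starts from the
            # previous partition and only applies positive-gain moves.
            assert q >= prev_q - 1e-9, "modularity decreased across a pass"
        if prev_q is not None and q <= prev_q + 1e-12 and not improved:
            break
        prev_q = q
        if not improved:
            break
        # Phase 2: aggregate communities into super-nodes.
        agg = nx.Graph()
        for u in work.nodes:
            agg.add_node(comm[u])
        for u, v, d in work.edges(data=True):
            w = float(d.get("weight", 1.0))
            cu, cv = comm[u], comm[v]
            if agg.has_edge(cu, cv):
                agg[cu][cv]["weight"] += w
            else:
                agg.add_edge(cu, cv, weight=w)
        mapping = {orig: comm[mapping[orig]] for orig in g.nodes}
        work = agg
    else:
        converged = False
    assignment = {orig: mapping[orig] for orig in g.nodes}
    assignment = _canonical(assignment, list(g.nodes))
    q = modularity(g, assignment, gamma)
    return Partition(assignment, q, gamma=gamma, seed=seed, converged=converged)


def _restricted_growth_strings(n: int):
    """Yield every restricted growth string of length n in lexicographic
    order (each is a canonical community-label array; the yielded list is
    reused — copy before storing)."""
    a = [0] * n
    while True:
        yield a
        j = n - 1
        while j > 0:
            if a[j] <= max(a[:j]):
                break
            j -= 1
        if j == 0:
            return
        a[j] += 1
        for t in range(j + 1, n):
            a[t] = 0


def brute_force_best_partition(g: nx.Graph, gamma: float = 1.0) -> Partition:
    """Exhaustively enumerate set partitions and return the max-Q one.

    Refuses graphs with more than 12 nodes (Bell(12) ~ 4.2e6).  Ties are
    broken by fewest communities, then by canonical label order (the
    lexicographically first restricted growth string wins).
    """
    nodes = list(g.nodes)
    n = len(nodes)
    if n > 12:
        raise ValueError(f"brute force limited to 12 nodes, got {n}")
    if g.number_of_edges() == 0:
        raise ModularityUndefinedError("modularity undefined: graph has no edges")
    m, k, nbrs, self_w = _weights(g)
    pos = {u: i for i, u in enumerate(nodes)}
    k_arr = [k[u] for u in nodes]
    sw_arr = [self_w[u] for u in nodes]
    edges = [
        (pos[u], pos[v], float(d.get("weight", 1.0)))
        for u, v, d in g.edges(data=True)
        if u != v
    ]
    two_m = 2.0 * m
    best_q = -2.0
    best_labels: list[int] | None = None
    best_nc = n + 1
    for a in _restricted_growth_strings(n):
        nc = max(a) + 1
        w_c = [0.0] * nc
        d_c = [0.0] * nc
        for i in range(n):
            c = a[i]
            d_c[c] += k_arr[i]
            w_c[c] += sw_arr[i]
        for ui, vi, w in edges:
            if a[ui] == a[vi]:
                w_c[a[ui]] += w
        q = sum(
            w_c[c] / m - gamma * (d_c[c] / two_m) ** 2 for c in range(nc)
        )
        if q > best_q + 1e-12 or (abs(q - best_q) <= 1e-12 and nc < best_nc):
            best_q, best_labels, best_nc = q, a.copy(), nc
    assignment = {u: best_labels[pos[u]] for u in nodes}
    return Partition(assignment, best_q, gamma=gamma, seed=None)


def module_report(g: nx.Graph, partition: Partition) -> pd.DataFrame:
    """Per-community membership table, Fig-4 style.

    Communities are enumerated (module 1, 2, ...) by size descending —
    never named, to avoid taxonomic bias — and members within a module are
    listed by prevalence descending.  Columns: module, size, disease,
    prevalence, degree.
    """
    comms = partition.communities()
    comms = sorted(
        comms,
        key=lambda members: (-len(members), sorted(members)),
    )
    rows = []
    for i, members in enumerate(comms, start=1):
        ordered = sorted(
            members,
            key=lambda u: (-(g.nodes[u].get("prevalence", 0.0)), u),
        )
        for u in ordered:
            rows.append(
                {
                    "module": i,
                    "size": len(members),
                    "disease": u,
                    "prevalence": g.nodes[u].get("prevalence", float("nan")),
                    "degree": g.degree(u),
                }
            )
    return pd.DataFrame(rows, columns=["module", "size", "disease", "prevalence", "degree"])
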