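"""Prize-collecting subnetwork inference.

Given a weighted PPI ``G = (V, E)`` with edge costs ``c_e = 1 − evidence``,
node prizes ``b_i`` from an expression signature, and a set of mandatory
root genes, find a root-connected subgraph ``G′ = (V′, E′)`` minimizing

    Σ_{e∈E′} c_e − λ · Σ_{i∈V′} b_i

The tradeoff parameter λ (default 0.025) scales how much up-regulated
expression signal an interaction's evidence cost must be traded against;
larger λ grows the subnetwork.

Two solvers are provided: a deterministic greedy expansion used in the
pipeline, and an exhaustive exact solver for small instances that serves as
an optimality oracle. For a fixed node set the optimal edge set is a
minimum spanning forest anchored at the roots (edge costs are nonnegative,
so cycles never pay), which both solvers exploit.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .genomics import RootGeneSet
from .io import ExpressionSignature, PPINetwork, canonical_pair

__all__ = [
    "Subnetwork",
    "SubnetworkError",
    "KnockoutResult",
    "build_subnetwork",
    "exact_subnetwork",
    "knockout",
    "rewire",
]

_EPS = 1e-12


class SubnetworkError(ValueError):
    pass


@dataclass
class Subnetwork:
    """Inferred subgraph with the objective value it achieves."""

    parent: PPINetwork
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    roots: tuple[str, ...]
    lam: float
    prizes: Mapping[str, float]
    objective: float

    def recompute_objective(self) -> float:
        g = self.parent.graph
        cost = sum(g[u][v]["cost"] for u, v in self.edges)
        prize = sum(self.prizes.get(n, 0.0) for n in self.nodes)
        return cost - self.lam * prize

    def as_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v in self.edges:
            g.add_edge(u, v, **self.parent.graph[u][v])
        return g

    @property
    def total_prize(self) -> float:
        return sum(self.prizes.get(n, 0.0) for n in self.nodes)


def _resolve_roots(ppi: PPINetwork, roots) -> list[str]:
    if isinstance(roots, RootGeneSet):
        candidates = roots.active
    else:
        candidates = list(roots)
    present = sorted(r for r in candidates if r in ppi.graph)
    if not present:
        raise SubnetworkError(
            "no usable root gene maps into the PPI network "
            "(all roots absent or excluded as loss-of-function)"
        )
    return present


def _resolve_prizes(sig, fdr: float) -> dict[str, float]:
    if isinstance(sig, ExpressionSignature):
        return sig.prizes(fdr=fdr)
    return {g: max(float(b), 0.0) for g, b in dict(sig).items()}


def _forest_edges(
    graph: nx.Graph, nodes: Iterable[str], roots: Sequence[str]
) -> list[tuple[str, str]] | None:
    """Min-cost edge set connecting every node to some root (Kruskal with a
    zero-cost super-root over the roots); None if infeasible."""
    nodes = set(nodes)
    parent = {n: n for n in nodes}
    parent["\x00SR"] = "\x00SR"

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen: list[tuple[str, str]] = []
    for r in sorted(roots):
        parent[find(r)] = find("\x00SR")
    cand = sorted(
        (graph[u][v]["cost"], *canonical_pair(u, v))
        for u, v in graph.subgraph(nodes).edges
    )
    for c, u, v in cand:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            chosen.append((u, v))
    sr = find("\x00SR")
    if any(find(n) != sr for n in nodes):
        return None
    return chosen


def _objective(graph, edges, nodes, prizes, lam) -> float:
    return sum(graph[u][v]["cost"] for u, v in edges) - lam * sum(
        prizes.get(n, 0.0) for n in nodes
    )


def _grow_tree(graph, prizes, roots, lam, bias: float = 0.0):
    """Attach every positive-prize terminal to the root set along shortest
    paths (Prim-style growth on the implicit metric closure).

    With ``bias`` = 0 paths minimize raw edge cost; with ``bias`` = 1 each
    step is discounted by the prize of the node it reaches,
    max(c_e − λ·b_v, 0), so growth prefers prize-dense corridors. Both
    metrics are surrogates for route choice only — pruning and objectives
    always use true costs. Returns parent pointers for a forest spanning
    roots ∪ terminals ∪ connectors; unprofitable branches are removed
    afterwards by ``_strong_prune``. Deterministic: the frontier orders by
    (distance, gene symbol).
    """
    import heapq

    terminals = {n for n, b in prizes.items() if b > 0 and lam * b > _EPS and n in graph}
    intree = set(roots)
    parent: dict[str, str | None] = {r: None for r in roots}
    dist = {r: 0.0 for r in roots}
    via: dict[str, str] = {}
    heap = [(0.0, r) for r in sorted(roots)]
    heapq.heapify(heap)
    pending = terminals - intree
    while heap and pending:
        d, u = heapq.heappop(heap)
        if d > dist.get(u, float("inf")) + _EPS:
            continue
        if u in pending:
            # walk the shortest path back to the tree and absorb it
            path = [u]
            while path[-1] not in intree:
                path.append(via[path[-1]])
            for child, par in zip(path[:-1], path[1:]):
                parent[child] = par
            for n in path[:-1]:
                intree.add(n)
                dist[n] = 0.0
                heapq.heappush(heap, (0.0, n))
            pending.discard(u)
            continue
        for nbr in sorted(graph[u]):
            w = graph[u][nbr]["cost"]
            if bias:
                w = max(w - bias * lam * prizes.get(nbr, 0.0), 0.0)
            nd = d + w
            if nd < dist.get(nbr, float("inf")) - _EPS:
                dist[nbr] = nd
                via[nbr] = u
                heapq.heappush(heap, (nd, nbr))
    return parent


def _strong_prune(graph, parent, roots, prizes, lam):
    """Optimal pruning of a rooted forest: drop every subtree whose total
    prize value fails to pay for the edge connecting it (roots never drop)."""
    children: dict[str, list[str]] = {}
    tops = []
    for child, par in parent.items():
        if par is None:
            tops.append(child)
        else:
            children.setdefault(par, []).append(child)
    rootset = set(roots)

    # bottom-up pass (iterative postorder): subtree net value and root flag
    postorder: list[str] = []
    stack = list(tops)
    while stack:
        v = stack.pop()
        postorder.append(v)
        stack.extend(children.get(v, ()))
    value: dict[str, float] = {}
    forced: dict[str, bool] = {}
    keep_child: dict[tuple[str, str], bool] = {}
    for v in reversed(postorder):
        val = lam * prizes.get(v, 0.0)
        frc = v in rootset
        for c in sorted(children.get(v, ())):
            edge_cost = graph[v][c]["cost"]
            if forced[c] or value[c] - edge_cost > _EPS:
                val += value[c] - edge_cost
                frc = frc or forced[c]
                keep_child[(v, c)] = True
            else:
                keep_child[(v, c)] = False
        value[v] = val
        forced[v] = frc

    # top-down pass: materialize the kept forest
    keep_nodes: set[str] = set()
    keep_edges: set[tuple[str, str]] = set()
    stack = [t for t in tops if t in rootset or forced.get(t, False)]
    while stack:
        v = stack.pop()
        keep_nodes.add(v)
        for c in sorted(children.get(v, ())):
            if keep_child[(v, c)]:
                keep_edges.add((v, c))
                stack.append(c)
    return keep_nodes, keep_edges


def _best_path_extension(graph, nodes, prizes, lam, max_len=3):
    """Most profitable simple path of ≤ max_len new nodes leaving the set:
    Δ = Σ edge costs − λ·Σ new-node prizes. Lets the search reach a prize
    pocket whose entry is only paid off by genes further along the path."""
    best = None  # (delta, path-tuple)

    def extend(node, path, cost, gain, visited):
        nonlocal best
        delta = cost - lam * gain
        if delta < -_EPS:
            cand = (delta, tuple(path))
            if best is None or cand < best:
                best = cand
        if len(path) >= max_len:
            return
        for nxt in sorted(graph[node]):
            if nxt in nodes or nxt in visited:
                continue
            extend(
                nxt, path + [nxt], cost + graph[node][nxt]["cost"],
                gain + prizes.get(nxt, 0.0), visited | {nxt},
            )

    for start in sorted(nodes):
        for first in sorted(graph[start]):
            if first in nodes:
                continue
            extend(
                first, [first], graph[start][first]["cost"],
                prizes.get(first, 0.0), {first},
            )
    return best


def _local_search(graph, nodes, roots, prizes, lam):
    """First-improvement local search over single-node removals/additions
    plus bounded-length path additions.

    Each candidate set is re-wired with a minimum spanning forest before its
    objective is measured, so dropping a mid-path connector (which MST
    re-wiring alone can never do) or adding a shortcut node is possible.
    Deterministic: candidates scanned in lexicographic order.
    """
    rootset = set(roots)
    nodes = set(nodes)
    edges = _forest_edges(graph, nodes, roots)
    obj = _objective(graph, edges, nodes, prizes, lam)
    improved = True
    while improved:
        improved = False
        for v in sorted(nodes - rootset):
            cand_nodes = nodes - {v}
            cand_edges = _forest_edges(graph, cand_nodes, roots)
            if cand_edges is None:
                continue
            cand_obj = _objective(graph, cand_edges, cand_nodes, prizes, lam)
            if cand_obj < obj - _EPS:
                nodes, edges, obj = cand_nodes, cand_edges, cand_obj
                improved = True
                break
        if improved:
            continue
        boundary = sorted({nbr for v in nodes for nbr in graph[v]} - nodes)
        for v in boundary:
            cand_nodes = nodes | {v}
            cand_edges = _forest_edges(graph, cand_nodes, roots)
            if cand_edges is None:
                continue
            cand_obj = _objective(graph, cand_edges, cand_nodes, prizes, lam)
            if cand_obj < obj - _EPS:
                nodes, edges, obj = cand_nodes, cand_edges, cand_obj
                improved = True
                break
        if improved:
            continue
        path = _best_path_extension(graph, nodes, prizes, lam)
        if path is not None:
            cand_nodes = nodes | set(path[1])
            cand_edges = _forest_edges(graph, cand_nodes, roots)
            if cand_edges is not None:
                cand_obj = _objective(graph, cand_edges, cand_nodes, prizes, lam)
                if cand_obj < obj - _EPS:
                    nodes, edges, obj = cand_nodes, cand_edges, cand_obj
                    improved = True
        if improved:
            continue
        # on small instances, widen the neighborhood: toggle up to three
        # nodes at once (variable-neighborhood step); still plain
        # first-improvement hill climbing from the constructed start
        universe = sorted(set(graph.nodes) - rootset)
        if len(universe) <= 20:
            for k in (2, 3):
                for combo in itertools.combinations(universe, k):
                    cand_nodes = nodes.symmetric_difference(combo)
                    cand_edges = _forest_edges(graph, cand_nodes, roots)
                    if cand_edges is None:
                        continue
                    cand_obj = _objective(graph, cand_edges, cand_nodes, prizes, lam)
                    if cand_obj < obj - _EPS:
                        nodes, edges, obj = set(cand_nodes), cand_edges, cand_obj
                        improved = True
                        break
                if improved:
                    break
    return nodes, edges


def build_subnetwork(
    ppi: PPINetwork,
    sig,
    roots,
    lam: float = 0.025,
    fdr: float = 0.05,
) -> Subnetwork:
    """Deterministic grow-and-prune heuristic for the subnetwork objective.

    Growth phase: every positive-prize gene is attached to the root set
    along shortest-cost paths, so several prized genes can share (and
    jointly pay for) one expensive bridge. Pruning phase: on the resulting
    forest, every subtree whose accumulated prize value λ·Σb fails to cover
    its connecting edge cost is removed — optimal for the built forest.
    The kept node set is then re-wired with a minimum spanning forest,
    pruned again until stable, and polished with a first-improvement local
    search over single-node removals and additions. The whole procedure
    runs once under the raw-cost growth metric and once under the
    prize-discounted metric, keeping the better objective. Fully
    deterministic: ties break lexicographically on gene symbols.
    """
    if lam < 0:
        raise SubnetworkError("lambda must be nonnegative")
    root_list = _resolve_roots(ppi, roots)
    prizes = _resolve_prizes(sig, fdr)
    graph = ppi.graph
    best = None  # (objective, n_edges, node-tuple) → (nodes, edges)
    for bias in (0.0, 1.0):
        parent = _grow_tree(graph, prizes, root_list, lam, bias=bias)
        nodes, edges = _strong_prune(graph, parent, root_list, prizes, lam)
        # MST re-wiring can lower edge costs, which may expose further prunes
        for _ in range(5):
            mst = _forest_edges(graph, nodes, root_list)
            assert mst is not None, "pruned set lost root connectivity"
            parent = {}
            tree = nx.Graph(mst)
            tree.add_nodes_from(nodes)
            seen = set()
            for r in sorted(root_list):
                if r in seen:
                    continue
                parent[r] = None
                for u, v in nx.bfs_edges(tree, r, sort_neighbors=sorted):
                    parent[v] = u
                    seen.add(v)
                seen.add(r)
            new_nodes, new_edges = _strong_prune(graph, parent, root_list, prizes, lam)
            stable = new_nodes == nodes and {frozenset(e) for e in new_edges} == {
                frozenset(e) for e in edges
            }
            nodes, edges = new_nodes, new_edges
            if stable:
                break
        nodes, edges = _local_search(graph, nodes, roots=root_list, prizes=prizes, lam=lam)
        obj = _objective(graph, edges, nodes, prizes, lam)
        key = (round(obj, 12), len(edges), tuple(sorted(nodes)))
        if best is None or key < best[0]:
            best = (key, nodes, edges)
    _, nodes, edges = best
    obj = _objective(graph, edges, nodes, prizes, lam)
    return Subnetwork(
        parent=ppi,
        nodes=frozenset(nodes),
        edges=frozenset(canonical_pair(u, v) for u, v in edges),
        roots=tuple(root_list),
        lam=lam,
        prizes=dict(prizes),
        objective=obj,
    )


def exact_subnetwork(
    ppi: PPINetwork,
    sig,
    roots,
    lam: float = 0.025,
    fdr: float = 0.05,
    max_nodes: int = 16,
) -> Subnetwork:
    """Global optimum by exhaustive enumeration of root-connected node sets.

    Feasible only on tiny instances (|V| ≤ 16); intended as a test oracle for
    the greedy solver. Ties break toward fewer edges, then the
    lexicographically smallest node set.
    """
    graph = ppi.graph
    if graph.number_of_nodes() > max_nodes:
        raise SubnetworkError(
            f"exact solver refuses instances with more than {max_nodes} nodes"
        )
    root_list = _resolve_roots(ppi, roots)
    prizes = _resolve_prizes(sig, fdr)
    others = sorted(set(graph.nodes) - set(root_list))
    best = None  # (objective, n_edges, node-tuple, edges)
    for k in range(len(others) + 1):
        for combo in itertools.combinations(others, k):
            nodes = set(root_list) | set(combo)
            edges = _forest_edges(graph, nodes, root_list)
            if edges is None:
                continue
            obj = _objective(graph, edges, nodes, prizes, lam)
            key = (round(obj, 12), len(edges), tuple(sorted(nodes)))
            if best is None or key < best[0]:
                best = (key, nodes, edges)
    assert best is not None  # roots alone are always feasible
    _, nodes, edges = best
    return Subnetwork(
        parent=ppi,
        nodes=frozenset(nodes),
        edges=frozenset(canonical_pair(u, v) for u, v in edges),
        roots=tuple(root_list),
        lam=lam,
        prizes=dict(prizes),
        objective=_objective(graph, edges, nodes, prizes, lam),
    )


@dataclass
class KnockoutResult:
    subnetwork: Subnetwork
    removed: str
    jaccard: float


def knockout(net: Subnetwork, gene: str) -> KnockoutResult:
    """Rebuild the subnetwork with ``gene`` deleted from the background PPI.

    Reports the Jaccard overlap of the new node set with the original, the
    stability statistic used for single-gene deletion experiments.
    """
    if gene not in net.nodes:
        raise SubnetworkError(f"{gene!r} is not in the subnetwork")
    remaining_roots = [r for r in net.roots if r != gene]
    if not remaining_roots:
        raise SubnetworkError("cannot knock out the only root gene")
    reduced = PPINetwork(nx.restricted_view(net.parent.graph, [gene], []))
    rebuilt = build_subnetwork(
        reduced, dict(net.prizes), remaining_roots, lam=net.lam
    )
    inter = len(net.nodes & rebuilt.nodes)
    union = len(net.nodes | rebuilt.nodes)
    return KnockoutResult(rebuilt, gene, inter / union if union else 1.0)


def rewire(ppi: PPINetwork, n_swaps: int, seed: int) -> PPINetwork:
    """Degree-preserving double-edge swap null model.

    Performs up to ``n_swaps`` successful swaps (u,v),(x,y) → (u,x),(v,y);
    evidence scores travel with the surviving edge slot (the first endpoint's
    original edge). The node degree sequence is exactly preserved. Graphs
    with fewer than two edges are returned unchanged.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be nonnegative")
    edges = [
        (u, v, ppi.graph[u][v]["evidence"]) for u, v in sorted(map(tuple, ppi.graph.edges))
    ]
    if len(edges) < 2 or n_swaps == 0:
        return PPINetwork.from_edges(edges)
    rng = random.Random(seed)
    present = {canonical_pair(u, v) for u, v, _ in edges}
    done, tries = 0, 0
    max_tries = 100 * n_swaps
    while done < n_swaps and tries < max_tries:
        tries += 1
        i, j = rng.randrange(len(edges)), rng.randrange(len(edges))
        if i == j:
            continue
        u, v, ev1 = edges[i]
        x, y, ev2 = edges[j]
        if rng.random() < 0.5:
            x, y = y, x
        new1, new2 = (u, x), (v, y)
        if u == x or v == y:
            continue
        k1, k2 = canonical_pair(*new1), canonical_pair(*new2)
        if k1 == k2 or k1 in present or k2 in present:
            continue
        present.discard(canonical_pair(u, v))
        present.discard(canonical_pair(x, y))
        present.add(k1)
        present.add(k2)
        edges[i] = (u, x, ev1)
        edges[j] = (v, y, ev2)
        done += 1
    return PPINetwork.from_edges(edges)
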