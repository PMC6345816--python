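"""Random-graph generators and perturbation operators.

Three graph families back the artificial-network experiments:

* k-regular random graphs (every node has the same degree k), generated by
  the pairing model with rejection of non-simple outcomes;
* power-law configuration-model graphs whose degree sequence is drawn
  i.i.d. from P(k) proportional to k^-gamma, k >= 1;
* maximally assortative scale-free graphs, realised in their limiting form
  as a disjoint collection of k-regular blocks with block sizes
  proportional to k^-gamma — in such a graph no edge swap can raise the
  degree-assortativity coefficient.

Two perturbation operators generate "similar" second layers from a base
graph: degree-preserving edge rewiring (swap {v_i,v_j},{v_h,v_k} into
{v_i,v_k},{v_h,v_j}) and non-degree-preserving random edge
insertion/deletion.

Nodes are labelled with zero-padded string identifiers so lexicographic
order matches generation order. All entry points take an explicit integer
seed and are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netcore import UndirectedGraph

__all__ = [
    "RewiringRecord",
    "RewiringInfeasibleError",
    "PerturbationInfeasibleError",
    "gen_k_regular",
    "gen_powerlaw",
    "gen_max_assortative",
    "rewire_degree_preserving",
    "perturb_insert_delete",
]


class RewiringInfeasibleError(RuntimeError):
    """No admissible edge pair found within the attempt budget."""

    def __init__(self, step: int, attempts: int):
        super().__init__(
            f"rewiring step {step}: no valid edge pair after {attempts} attempts"
        )
        self.step = step


class PerturbationInfeasibleError(RuntimeError):
    """A deletion was drawn on an edgeless graph or an insertion on a
    complete graph."""


@dataclass(frozen=True)
class RewiringRecord:
    """Bookkeeping for one rewiring run: requested steps all completed,
    plus how many candidate draws failed the non-adjacency constraint."""

    steps_applied: int
    failed_attempts: int
    seed: int


def _labels(n: int) -> list[str]:
    width = max(4, len(str(max(n - 1, 0))))
    return [f"v{i:0{width}d}" for i in range(n)]


def _relabel_sorted(g: nx.Graph, labels: list[str]) -> UndirectedGraph:
    mapping = {old: labels[i] for i, old in enumerate(sorted(g.nodes))}
    return nx.relabel_nodes(g, mapping, copy=True)


def gen_k_regular(n: int, k: int, seed: int) -> UndirectedGraph:
    """Uniform-ish random simple k-regular graph on n string-labelled nodes.

    Requires n*k even and k < n (handshake parity / simplicity).
    """
    if k >= n or (n * k) % 2 != 0:
        raise ValueError(f"no simple {k}-regular graph on {n} nodes exists")
    g = nx.random_regular_graph(k, n, seed=seed)
    return _relabel_sorted(g, _labels(n))


def sample_powerlaw_degrees(n: int, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n degrees i.i.d. from P(k) ∝ k^-gamma on 1..n-1."""
    ks = np.arange(1, n)
    w = ks.astype(float) ** (-gamma)
    w /= w.sum()
    return rng.choice(ks, size=n, p=w)


def gen_powerlaw(n: int, gamma: float, seed: int) -> UndirectedGraph:
    """Configuration-model graph with an i.i.d. power-law degree sequence.

    Self-loops and parallel edges arising from stub pairing are discarded
    rather than rewired, so realised degrees can fall slightly below the
    drawn ones; the node count stays n with lexicographic string labels.
    """
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    if n < 10:
        raise ValueError("n must be at least 10")
    rng = np.random.default_rng(seed)
    degrees = sample_powerlaw_degrees(n, gamma, rng)
    if degrees.sum() % 2 == 1:
        degrees[int(rng.integers(n))] += 1
    multi = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(multi)  # collapses parallel edges
    g.remove_edges_from(nx.selfloop_edges(g))
    return _relabel_sorted(g, _labels(n))


def gen_max_assortative(n: int, gamma: float, seed: int) -> UndirectedGraph:
    """Disjoint union of k-regular blocks with sizes proportional to k^-gamma.

    Block k holds round(c * k^-gamma) nodes, truncated where a block would
    have fewer than k+1 nodes; odd-parity blocks drop one node. Every node's
    degree equals its block parameter, so no edge swap can increase the
    assortativity coefficient.
    """
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    rng = np.random.default_rng(seed)
    ks = np.arange(1, max(n, 2))
    w = ks.astype(float) ** (-gamma)
    counts = np.rint(n * w / w.sum()).astype(int)

    blocks: list[nx.Graph] = []
    total = 0
    for k, n_k in zip(ks, counts):
        if n_k <= k:  # a k-regular block needs more than k nodes
            continue
        if (n_k * k) % 2 == 1:
            n_k -= 1
        if n_k <= k:
            continue
        if k == 1:
            block = nx.Graph()
            perm = rng.permutation(n_k)
            block.add_nodes_from(range(n_k))
            for a, b in zip(perm[0::2], perm[1::2]):
                block.add_edge(int(a), int(b))
        else:
            block = nx.random_regular_graph(int(k), int(n_k), seed=int(rng.integers(2**31)))
        blocks.append(block)
        total += n_k

    g = nx.Graph()
    labels = _labels(total)
    offset = 0
    for block in blocks:
        mapping = {old: labels[offset + i] for i, old in enumerate(sorted(block.nodes))}
        g.update(nx.relabel_nodes(block, mapping, copy=True))
        offset += len(block.nodes)
    return g


def rewire_degree_preserving(
    g: UndirectedGraph,
    K: int,
    seed: int,
    max_attempts_per_step: int = 1000,
) -> tuple[UndirectedGraph, RewiringRecord]:
    """Apply K degree-preserving rewiring steps; the input is not mutated.

    Each step draws two distinct edges {v_i,v_j}, {v_h,v_k} with four
    distinct endpoints and a uniform pairing orientation such that
    {v_i,v_k} and {v_h,v_j} are both absent, then swaps the edge pair for
    those two. Every node keeps its degree, so the degree distribution of
    the input is preserved exactly. A step that cannot find an admissible
    pair within the attempt budget raises, reporting the step index.
    """
    if g.number_of_edges() < 2:
        raise ValueError("rewiring needs at least 2 edges")
    out = nx.Graph(g)
    rng = np.random.default_rng(seed)
    edges = [tuple(sorted(e)) for e in sorted(tuple(sorted(e)) for e in out.edges)]
    failed = 0
    for step in range(K):
        for attempt in range(max_attempts_per_step):
            m = len(edges)
            a, b = rng.integers(m), rng.integers(m)
            if a == b:
                failed += 1
                continue
            vi, vj = edges[a]
            vh, vk = edges[b]
            if rng.integers(2):  # uniform pairing orientation
                vh, vk = vk, vh
            if len({vi, vj, vh, vk}) < 4:
                failed += 1
                continue
            if out.has_edge(vi, vk) or out.has_edge(vh, vj):
                failed += 1
                continue
            out.remove_edge(vi, vj)
            out.remove_edge(vh, vk)
            out.add_edge(vi, vk)
            out.add_edge(vh, vj)
            edges[a] = tuple(sorted((vi, vk)))
            edges[b] = tuple(sorted((vh, vj)))
            break
        else:
            raise RewiringInfeasibleError(step, max_attempts_per_step)
    return out, RewiringRecord(steps_applied=K, failed_attempts=failed, seed=seed)


def perturb_insert_delete(
    g: UndirectedGraph,
    steps: int,
    p_d: float,
    seed: int,
) -> UndirectedGraph:
    """Apply sequential random edge deletions/insertions; input not mutated.

    Each step deletes a uniformly random existing edge with probability
    p_d, otherwise inserts an edge between a uniformly random currently
    non-adjacent node pair.
    """
    if not 0.0 <= p_d <= 1.0:
        raise ValueError("p_d must be a probability")
    out = nx.Graph(g)
    rng = np.random.default_rng(seed)
    nodes = sorted(out.nodes)
    n = len(nodes)
    for step in range(steps):
        if rng.random() < p_d:
            m = out.number_of_edges()
            if m == 0:
                raise PerturbationInfeasibleError(f"step {step}: no edge to delete")
            edges = sorted(tuple(sorted(e)) for e in out.edges)
            u, v = edges[int(rng.integers(m))]
            out.remove_edge(u, v)
        else:
            if out.number_of_edges() == n * (n - 1) // 2:
                raise PerturbationInfeasibleError(f"step {step}: graph is complete")
            while True:
                u, v = (nodes[int(i)] for i in rng.integers(n, size=2))
                if u != v and not out.has_edge(u, v):
                    out.add_edge(u, v)
                    break
    return out
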