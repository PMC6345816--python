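"""Exact dominating-set computation for single graphs and multilayer networks.

A dominating set U of an undirected graph G(V, E) satisfies: every v in V is
in U or adjacent to a member of U. Under the dominating-set controllability
framework, an MDS is a minimum set of driver nodes for one network. The
multilayer generalisation (a DSM, minimum: MDSM) must dominate every layer
simultaneously: for every layer G_i and every v in V_i, v is in U or has an
E_i-neighbour in U. No inter-layer edges exist; layers only interact through
the shared membership variable of each node.

Two exact routes are provided: a brute-force oracle for tiny instances, and
an integer linear program (binary x_v per universe node, one covering
constraint per node per layer). For two-layer networks a degree-1
preprocessing pass pre-pins nodes that must appear in some MDSM — the
neighbour of any unobserved leaf that exists in only one layer, or of a
shared leaf whose single edge coincides in both layers — which shrinks the
ILP substantially on sparse power-law-like networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._solver import OPTIMAL, solve_binary_min
from .netcore import (
    MultilayerNetwork,
    UndirectedGraph,
    common_nodes,
    induced_subgraph,
)

__all__ = [
    "DomSetResult",
    "PreprocessState",
    "is_dominating",
    "brute_force_mds",
    "brute_force_mdsm",
    "ilp_mds",
    "ilp_mdsm",
    "fast_mdsm_preprocess",
    "fast_mdsm",
    "mdsi",
    "sandwich_bounds",
]

BRUTE_FORCE_MDS_MAX = 25
BRUTE_FORCE_MDSM_MAX = 20


@dataclass(frozen=True)
class DomSetResult:
    """A computed (multilayer) dominating set.

    forced_subset is the pre-pinned subset V_M when two-layer preprocessing
    was used (empty otherwise). include_isolated records whether isolated
    nodes were required in the set (the original definition) or ignored.
    """

    members: frozenset[str]
    forced_subset: frozenset[str] = frozenset()
    solver_status: str = OPTIMAL
    include_isolated: bool = True

    def __post_init__(self):
        if not self.forced_subset <= self.members:
            raise ValueError("forced subset must be contained in the solution")

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


def _as_net(net: MultilayerNetwork | UndirectedGraph) -> MultilayerNetwork:
    if isinstance(net, MultilayerNetwork):
        return net
    return MultilayerNetwork([net])


def _covered(layer: UndirectedGraph, include_isolated: bool):
    """Nodes of a layer whose domination constraint is active."""
    if include_isolated:
        return layer.nodes
    return (v for v in layer.nodes if layer.degree(v) > 0)


def is_dominating(
    net: MultilayerNetwork | UndirectedGraph,
    members: frozenset[str] | set[str],
    include_isolated: bool = True,
) -> bool:
    """Certificate check: does ``members`` dominate every covered node of
    every layer by direct neighbourhood scan?"""
    net = _as_net(net)
    for layer in net:
        for v in _covered(layer, include_isolated):
            if v in members:
                continue
            if not any(u in members for u in layer.neighbors(v)):
                return False
    return True


# ---------------------------------------------------------------------------
# brute-force oracles


def _brute_force(net: MultilayerNetwork, include_isolated: bool) -> frozenset[str]:
    universe = sorted(net.universe)
    # combinations over the sorted universe enumerate, within each size,
    # in lexicographic order — the first dominating hit is the canonical one
    for size in range(len(universe) + 1):
        for cand in itertools.combinations(universe, size):
            s = set(cand)
            if is_dominating(net, s, include_isolated):
                return frozenset(s)
    raise AssertionError("full universe always dominates")  # pragma: no cover


def brute_force_mds(g: UndirectedGraph, include_isolated: bool = True) -> DomSetResult:
    """Exhaustive MDS oracle for testing; guarded at 25 nodes."""
    if len(g.nodes) > BRUTE_FORCE_MDS_MAX:
        raise ValueError(f"brute force limited to {BRUTE_FORCE_MDS_MAX} nodes")
    members = _brute_force(MultilayerNetwork([g]), include_isolated)
    return DomSetResult(members, include_isolated=include_isolated)


def brute_force_mdsm(net: MultilayerNetwork, include_isolated: bool = True) -> DomSetResult:
    """Exhaustive MDSM oracle for testing; guarded at 20 universe nodes."""
    if len(net.universe) > BRUTE_FORCE_MDSM_MAX:
        raise ValueError(f"brute force limited to {BRUTE_FORCE_MDSM_MAX} universe nodes")
    members = _brute_force(net, include_isolated)
    return DomSetResult(members, include_isolated=include_isolated)


# ---------------------------------------------------------------------------
# ILP route


def _solve_mdsm_ilp(
    net: MultilayerNetwork,
    include_isolated: bool,
    forced: frozenset[str],
    skip: dict[int, set[str]] | None = None,
    canonical: bool = False,
    time_limit: float | None = 600.0,
) -> DomSetResult:
    """Shared ILP core.

    skip maps layer index -> nodes whose covering constraint is dropped
    (used for nodes already observed by the two-layer preprocessing).
    """
    universe = sorted(net.universe)
    index = {v: i for i, v in enumerate(universe)}
    n = len(universe)

    rows: list[list[int]] = []
    for k, layer in enumerate(net):
        skipped = skip.get(k, set()) if skip else set()
        for v in _covered(layer, include_isolated):
            if v in forced or v in skipped:
                continue
            rows.append([index[v]] + [index[u] for u in layer.neighbors(v)])

    forced_idx = [index[v] for v in forced]
    sol = solve_binary_min(n, rows, forced_ones=forced_idx, time_limit=time_limit)
    opt = int(round(sol.objective))

    if canonical and n > 0:
        # second stage: pin the cardinality, minimise the sum of
        # lexicographic node ranks for a reproducible representative
        ranks = np.arange(n, dtype=float)
        sol = solve_binary_min(
            n,
            rows,
            objective=ranks,
            forced_ones=forced_idx,
            equality=(np.ones(n), float(opt)),
            time_limit=time_limit,
        )

    members = frozenset(universe[i] for i in np.flatnonzero(sol.assignment))
    assert len(members) == opt
    return DomSetResult(
        members,
        forced_subset=forced,
        solver_status=sol.status,
        include_isolated=include_isolated,
    )


def ilp_mds(
    g: UndirectedGraph,
    include_isolated: bool = True,
    canonical: bool = False,
    time_limit: float | None = 600.0,
) -> DomSetResult:
    """Exact single-layer MDS via ILP.

    minimise sum x_i subject to x_i + sum_{j: {v_j,v_i} in E} x_j >= 1 for
    every covered node. The size is unique; membership may differ between
    solvers unless ``canonical`` is set.
    """
    return _solve_mdsm_ilp(
        MultilayerNetwork([g]), include_isolated, frozenset(), None, canonical, time_limit
    )


def ilp_mdsm(
    net: MultilayerNetwork,
    include_isolated: bool = True,
    forced: set[str] | frozenset[str] = frozenset(),
    canonical: bool = False,
    time_limit: float | None = 600.0,
) -> DomSetResult:
    """Exact N-layer MDSM via ILP: one covering row per covered node per
    layer, plus x_i = 1 for every pre-pinned node in ``forced``."""
    forced = frozenset(forced)
    if not forced <= net.universe:
        raise ValueError("forced nodes must lie in the network universe")
    return _solve_mdsm_ilp(net, include_isolated, forced, None, canonical, time_limit)


# ---------------------------------------------------------------------------
# two-layer degree-1 preprocessing


@dataclass
class PreprocessState:
    """Working state of the two-layer degree-1 reduction.

    Edges of the working copies are only ever deleted; observed sets only
    grow, and a node becomes observed in a layer exactly when it gains a
    V_M neighbour there (directly by a rule firing, or by propagation).
    """

    g1: UndirectedGraph
    g2: UndirectedGraph
    v_m: set[str] = field(default_factory=set)
    observed_1: set[str] = field(default_factory=set)
    observed_2: set[str] = field(default_factory=set)


def fast_mdsm_preprocess(net: MultilayerNetwork) -> PreprocessState:
    """Determine a subset V_M guaranteed to be part of some MDSM.

    Scans nodes in lexicographic order and repeatedly applies three rules
    to unobserved leaves on the current working copies:

    * leaf v_j in layer 1 only (absent from layer 2): its unique neighbour
      v_i must dominate it in layer 1 at no extra cost — pin v_i, delete
      the leaf edge, mark v_j observed in layer 1;
    * the symmetric rule for a leaf in layer 2 only;
    * shared leaf with the same single edge {v_i, v_j} in both layers:
      pin v_i, delete the edge from both, mark v_j observed in both.

    After each sweep, observation propagates to every unobserved non-V_M
    neighbour of V_M in each layer. The loop stops when a sweep adds no
    node to V_M.
    """
    if len(net) != 2:
        raise ValueError("degree-1 preprocessing is defined for exactly 2 layers")
    state = PreprocessState(g1=nx.Graph(net[0]), g2=nx.Graph(net[1]))
    g1, g2 = state.g1, state.g2
    v1, v2 = set(net[0].nodes), set(net[1].nodes)
    scan_order = sorted(v1 | v2)

    def single_layer_rule(vi, g, other_nodes, observed):
        """Leaf rule in one layer: fire on the lexicographically smallest
        eligible neighbour v_j; returns True if the rule fired."""
        if vi not in g:
            return False
        for vj in sorted(g.neighbors(vi)):
            if (
                vj not in state.v_m
                and vj not in observed
                and g.degree(vj) == 1
                and vj not in other_nodes
            ):
                g.remove_edge(vi, vj)
                state.v_m.add(vi)
                observed.add(vj)
                return True
        return False

    def shared_leaf_rule(vi):
        if vi not in g1 or vi not in g2:
            return False
        for vj in sorted(set(g1.neighbors(vi)) & set(g2.neighbors(vi))):
            if (
                vj not in state.v_m
                and vj not in state.observed_1
                and vj not in state.observed_2
                and g1.degree(vj) == 1
                and g2.degree(vj) == 1
            ):
                g1.remove_edge(vi, vj)
                g2.remove_edge(vi, vj)
                state.v_m.add(vi)
                state.observed_1.add(vj)
                state.observed_2.add(vj)
                return True
        return False

    while True:
        before = len(state.v_m)
        for vi in scan_order:
            single_layer_rule(vi, g1, v2, state.observed_1)
            single_layer_rule(vi, g2, v1, state.observed_2)
            shared_leaf_rule(vi)
        # propagate observation from V_M through the current working edges
        for g, observed in ((g1, state.observed_1), (g2, state.observed_2)):
            for vi in list(g.nodes):
                if vi in state.v_m or vi in observed:
                    continue
                if any(vj in state.v_m for vj in g.neighbors(vi)):
                    observed.add(vi)
        if len(state.v_m) == before:
            break
    return state


def fast_mdsm(
    net: MultilayerNetwork,
    include_isolated: bool = True,
    preprocess: bool = True,
    canonical: bool = False,
    time_limit: float | None = 600.0,
) -> DomSetResult:
    """MDSM with the two-layer preprocessing when applicable.

    For N = 2 (and ``preprocess``), runs :func:`fast_mdsm_preprocess` and
    solves the reduced ILP in which every V_M node is pinned to 1 and
    observed nodes contribute no covering constraint (they already have a
    V_M neighbour). The covering rows of the remaining nodes use the
    original layer edge sets. For other N the plain ILP is used. The size
    always equals the plain ILP optimum.
    """
    if len(net) == 2 and preprocess:
        state = fast_mdsm_preprocess(net)
        skip = {0: set(state.observed_1), 1: set(state.observed_2)}
        return _solve_mdsm_ilp(
            net, include_isolated, frozenset(state.v_m), skip, canonical, time_limit
        )
    return _solve_mdsm_ilp(net, include_isolated, frozenset(), None, canonical, time_limit)


# ---------------------------------------------------------------------------
# comparison quantities


def mdsi(
    g1: UndirectedGraph,
    g2: UndirectedGraph,
    include_isolated: bool = True,
    canonical: bool = True,
    time_limit: float | None = 600.0,
) -> DomSetResult:
    """Intersection of one MDS per layer induced on the common nodes.

    The MDSI is a plain-overlap baseline: it carries no controllability
    guarantee for either layer. MDS solutions are not unique, so by default
    each per-layer MDS is the canonical (rank-minimal) representative to
    make the intersection reproducible.
    """
    v = common_nodes(g1, g2)
    mds1 = ilp_mds(induced_subgraph(g1, v), include_isolated, canonical, time_limit)
    mds2 = ilp_mds(induced_subgraph(g2, v), include_isolated, canonical, time_limit)
    return DomSetResult(mds1.members & mds2.members, include_isolated=include_isolated)


def sandwich_bounds(
    net: MultilayerNetwork,
    include_isolated: bool = True,
    time_limit: float | None = 600.0,
) -> tuple[int, int]:
    """Sandwich bounds on the MDSM size from per-layer MDS sizes:
    max_i S_MDS(G_i) <= S_MDSM <= sum_i S_MDS(G_i)."""
    sizes = [ilp_mds(g, include_isolated, time_limit=time_limit).size for g in net]
    return max(sizes), sum(sizes)
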