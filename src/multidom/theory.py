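"""Analytic estimators for multilayer dominating-set sizes.

The estimators come from a virtual layer-by-layer construction of a DSM:
take an MDS of the first layer; for each further layer, restrict to the
nodes that the accumulated set fails to dominate there, take an MDS of the
induced residual graph, and accumulate. The output is a valid DSM but not
necessarily minimum, so its size estimates an upper bound.

Analysing that construction on k-regular random layers sharing one node
universe gives the recursion

    alpha_1 = 1/(k+1),    alpha_{i+1} = alpha_i + (1/(k+1)) (1-alpha_i)^(k+1),

where alpha_N * n estimates the DSM size after N layers. On maximally
assortative scale-free layers (a collection of k-regular blocks with sizes
proportional to k^-gamma) the same argument, averaged over the block
distribution, gives

    beta_1     = [ sum_k k^-gamma / (k+1) ] / [ sum_k k^-gamma ],
    beta_{i+1} = beta_i + [ sum_k (1-beta_i)^(k+1) k^-gamma / (k+1) ]
                          / [ sum_k k^-gamma ].

A separate pair of closed forms estimates how one perturbation step of a
second layer inflates the joint dominating set. With p the probability that
a random edge endpoint lies in the base MDS (its degree-mass fraction) and
q the probability that a non-MDS node has two or more MDS neighbours, one
degree-preserving rewiring forces an extra node with probability roughly

    P_plus1 = 4 (1-q) p (1-p)^3 + 2 (1-q)^2 p^2 (1-p)^2,

and one random-insertion/deletion step (deletion probability p_d) with

    P_plus1 = 2 p_d (1-q) p (1-p).

These are mean-field estimates, not bounds; the rewiring one in particular
overshoots at large step counts because rewiring preserves hub degrees and
hubs tend to stay in the dominating set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domset import DomSetResult, ilp_mds
from .netcore import MultilayerNetwork, UndirectedGraph, induced_subgraph

__all__ = [
    "EstimateSeries",
    "PerturbationEstimate",
    "alpha_series",
    "beta_series",
    "virtual_dsm",
    "estimate_p",
    "estimate_q",
    "p_plus1_rewire",
    "p_plus1_indel",
    "predicted_ratio",
]


@dataclass(frozen=True)
class EstimateSeries:
    """alpha_i or beta_i values for i = 1..N as fractions of n."""

    model: str  # "kregular" | "assortative"
    parameter: float  # k or gamma
    values: tuple[float, ...]
    truncation: int | None = None  # k_max actually used (beta only)
    tolerance: float | None = None

    def __post_init__(self):
        vals = self.values
        if any(not (0.0 < v <= 1.0) for v in vals):
            raise ValueError("series values must lie in (0, 1]")
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("series must be non-decreasing")


@dataclass(frozen=True)
class PerturbationEstimate:
    """Empirical p and q plus the closed-form P_plus1 for one model."""

    p: float
    q: float
    p_plus1: float
    model: str  # "rewire" | "indel"
    p_d: float | None = None


def _check_prob(name: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")


def alpha_series(k: int, N: int) -> EstimateSeries:
    """DSM-fraction recursion for N k-regular random layers."""
    if k < 1 or N < 1:
        raise ValueError("k and N must be positive integers")
    values = [1.0 / (k + 1)]
    for _ in range(N - 1):
        a = values[-1]
        values.append(a + (1.0 - a) ** (k + 1) / (k + 1))
    return EstimateSeries(model="kregular", parameter=float(k), values=tuple(values))


def beta_series(
    gamma: float,
    N: int,
    k_max: int = 10**5,
    tol: float = 1e-12,
) -> EstimateSeries:
    """DSM-fraction recursion for maximally assortative scale-free layers.

    Both infinite sums are truncated at k_max or when the running k^-gamma
    term falls below tol, whichever comes first; the shared truncation
    actually used is reported on the series.
    """
    if gamma <= 1:
        raise ValueError("gamma must exceed 1 for the sums to converge")
    if N < 1:
        raise ValueError("N must be positive")
    from scipy.special import zeta as hurwitz

    ks = np.arange(1, k_max + 1, dtype=float)
    w = ks**-gamma
    cut = int(np.argmax(w < tol)) if np.any(w < tol) else len(w)
    cut = max(cut, 1)
    ks, w = ks[:cut], w[:cut]
    # analytic tails beyond the truncation: sum_{k>cut} k^-g is the Hurwitz
    # zeta, and 1/(k+1) = sum_m (-1)^(m+1) k^-m turns the numerator tail
    # into an alternating Hurwitz series that converges like (1/cut)^m
    z = float(w.sum() + hurwitz(gamma, cut + 1))
    num_tail = 0.0
    for m in range(1, 40):
        term = (-1) ** (m + 1) * float(hurwitz(gamma + m, cut + 1))
        num_tail += term
        if abs(term) < 1e-18:
            break

    values = [float((np.sum(w / (ks + 1)) + num_tail) / z)]
    for _ in range(N - 1):
        b = values[-1]
        # the (1-b)^(k+1) factor kills the tail geometrically; no correction
        inc = float(np.sum(w * (1.0 - b) ** (ks + 1) / (ks + 1)) / z)
        values.append(b + inc)
    return EstimateSeries(
        model="assortative",
        parameter=float(gamma),
        values=tuple(values),
        truncation=cut,
        tolerance=tol,
    )


def virtual_dsm(
    net: MultilayerNetwork,
    include_isolated: bool = True,
    time_limit: float | None = 600.0,
) -> DomSetResult:
    """Layer-by-layer DSM construction (valid, not necessarily minimum).

    DS_1 = MDS(G_1); for i >= 2, the residual V_i is the universe minus the
    accumulated set and minus its G_i-neighbourhood, and DS_i is an exact
    MDS of G_i(V_i). Stated for layers sharing one node universe.
    """
    universe = set(net.universe)
    for g in net:
        if set(g.nodes) != universe:
            raise ValueError("virtual procedure requires layers on the same node set")

    accumulated: set[str] = set(
        ilp_mds(net[0], include_isolated, time_limit=time_limit).members
    )
    for g in list(net)[1:]:
        dominated = set(accumulated)
        for u in accumulated:
            if u in g:
                dominated.update(g.neighbors(u))
        residual = universe - dominated
        if not residual:
            continue
        ds_i = ilp_mds(
            induced_subgraph(g, residual), include_isolated=True, time_limit=time_limit
        )
        accumulated |= set(ds_i.members)
    return DomSetResult(frozenset(accumulated), include_isolated=include_isolated)


def estimate_p(g: UndirectedGraph, mds: set[str] | frozenset[str]) -> float:
    """Degree-mass fraction of the MDS: the probability that a random
    endpoint of a random edge lies in the set."""
    if g.number_of_edges() == 0:
        raise ValueError("p is undefined on an edgeless graph")
    mds = set(mds)
    if not mds <= set(g.nodes):
        raise ValueError("mds must be a subset of the graph nodes")
    total = sum(d for _, d in g.degree())
    return sum(g.degree(v) for v in mds) / total


def estimate_q(g: UndirectedGraph, mds: set[str] | frozenset[str]) -> float:
    """Fraction of non-MDS nodes with two or more MDS neighbours."""
    mds = set(mds)
    outside = [v for v in g.nodes if v not in mds]
    if not outside:
        raise ValueError("q is undefined when the set covers all nodes")
    hits = sum(
        1 for v in outside if sum(1 for u in g.neighbors(v) if u in mds) >= 2
    )
    return hits / len(outside)


def p_plus1_rewire(p: float, q: float) -> float:
    """Probability that one degree-preserving rewiring step forces one
    extra dominating node: 4(1-q)p(1-p)^3 + 2(1-q)^2 p^2 (1-p)^2."""
    _check_prob("p", p)
    _check_prob("q", q)
    return 4 * (1 - q) * p * (1 - p) ** 3 + 2 * (1 - q) ** 2 * p**2 * (1 - p) ** 2


def p_plus1_indel(p: float, q: float, p_d: float) -> float:
    """Probability that one insertion/deletion step forces one extra
    dominating node: 2 p_d (1-q) p (1-p)."""
    _check_prob("p", p)
    _check_prob("q", q)
    _check_prob("p_d", p_d)
    return 2 * p_d * (1 - q) * p * (1 - p)


def predicted_ratio(base_size: int, K: int, p_plus1: float) -> float:
    """Theoretical linear-growth estimate of S_MDSM(G_0, G_K)/S_MDS(G_0).

    K perturbation steps each add a node with probability P_plus1, so the
    estimated joint size is base_size + K * P_plus1; the returned quantity
    is that estimate divided by the base size.
    """
    if base_size < 1:
        raise ValueError("base_size must be at least 1")
    return (base_size + K * p_plus1) / base_size
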