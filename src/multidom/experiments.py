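"""Reproducible experiment pipelines and the enrichment statistic.

The perturbation experiments quantify how the joint dominating set of a
base scale-free graph G_0 and a perturbed copy G_K grows with the number of
perturbation steps K, and compare the observed growth with the closed-form
single-step estimates. The workflow pipelines mirror the comparative
network analysis: restrict two (or N) layers to their common nodes, compute
per-layer MDS, the joint MDSM, the MDS intersection (MDSI) and — for pairs
— the MDS of the union graph. The enrichment statistic scores how strongly
a control set over-represents a functional class relative to the common
background.

Every experiment derives all randomness from one integer seed through
``numpy.random.SeedSequence`` and records parameters and per-trial seeds in
the result's ``attrs`` so runs are exactly repeatable.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import domset, generators, theory
from .netcore import (
    MultilayerNetwork,
    UndirectedGraph,
    common_nodes,
    graph_union,
    induced_subgraph,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseReport",
    "EnrichmentRecord",
    "rewiring_experiment",
    "indel_experiment",
    "multilayer_regular_experiment",
    "pairwise_workflow",
    "nlayer_workflow",
    "enrichment",
    "enrichment_batch",
    "read_annotation",
    "compare_enrichment_groups",
]


def _child_seeds(seed: int, count: int) -> list[int]:
    """Derive reproducible 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(count, dtype=np.uint64)]


# ---------------------------------------------------------------------------
# perturbation experiments


def _perturbation_table(
    kind: str,
    gamma: float,
    n: int,
    grid: Sequence[int],
    trials: int,
    seed: int,
    p_d: float | None = None,
    include_isolated: bool = True,
) -> pd.DataFrame:
    if list(grid) != sorted(grid):
        raise ValueError("perturbation grid must be sorted ascending")
    trial_seeds = _child_seeds(seed, trials)
    observed = np.zeros((trials, len(grid)))
    predicted = np.zeros((trials, len(grid)))

    for t, s in enumerate(trial_seeds):
        gen_seed, perturb_seed = _child_seeds(s, 2)
        g0 = generators.gen_powerlaw(n, gamma, gen_seed)
        base = domset.ilp_mds(g0, include_isolated)
        p = theory.estimate_p(g0, base.members)
        q = theory.estimate_q(g0, base.members)
        if kind == "rewire":
            p1 = theory.p_plus1_rewire(p, q)
        else:
            p1 = theory.p_plus1_indel(p, q, p_d)

        current = g0
        done = 0
        for j, k in enumerate(grid):
            if k > done:
                if kind == "rewire":
                    current, _ = generators.rewire_degree_preserving(
                        current, k - done, _child_seeds(perturb_seed, j + 1)[-1]
                    )
                else:
                    current = generators.perturb_insert_delete(
                        current, k - done, p_d, _child_seeds(perturb_seed, j + 1)[-1]
                    )
                done = k
            joint = domset.fast_mdsm(
                MultilayerNetwork([g0, current]), include_isolated
            )
            observed[t, j] = joint.size / base.size
            predicted[t, j] = theory.predicted_ratio(base.size, k, p1)

    col = "K" if kind == "rewire" else "steps"
    table = pd.DataFrame(
        {
            "gamma": gamma,
            col: list(grid),
            "observed_ratio": observed.mean(axis=0),
            "predicted_ratio": predicted.mean(axis=0),
            "trials": trials,
        }
    )
    table.attrs.update(
        model=kind, gamma=gamma, n=n, trials=trials, seed=seed,
        trial_seeds=trial_seeds, p_d=p_d,
    )
    return table


def rewiring_experiment(
    gamma: float,
    n: int,
    K_values: Sequence[int],
    trials: int,
    seed: int,
    include_isolated: bool = True,
) -> pd.DataFrame:
    """Joint-MDS growth under degree-preserving rewiring.

    Per trial: generate a power-law graph G_0, compute its MDS, then for
    each K (applied cumulatively so that G_K is G_0 rewired K times)
    compute S_MDSM(G_0, G_K)/S_MDS(G_0). The predicted column is the
    linear single-step estimate with p, q measured once on G_0.
    """
    return _perturbation_table("rewire", gamma, n, K_values, trials, seed,
                               include_isolated=include_isolated)


def indel_experiment(
    gamma: float,
    n: int,
    p_d: float,
    step_values: Sequence[int],
    trials: int,
    seed: int,
    include_isolated: bool = True,
) -> pd.DataFrame:
    """Same protocol under random edge insertion/deletion with deletion
    probability p_d, predicted by the insertion/deletion closed form."""
    return _perturbation_table("indel", gamma, n, step_values, trials, seed,
                               p_d=p_d, include_isolated=include_isolated)


def multilayer_regular_experiment(
    k: int,
    n: int,
    N: int,
    trials: int,
    seed: int,
    time_limit: float | None = 600.0,
) -> pd.DataFrame:
    """Layer-by-layer DSM fraction on k-regular multilayers vs alpha_i.

    Per trial, N independent k-regular random graphs are drawn on one node
    universe; for every prefix length i the table reports the mean
    virtual-procedure DSM fraction, the mean exact MDSM fraction, and the
    recursion value alpha_i.
    """
    alphas = theory.alpha_series(k, N).values
    trial_seeds = _child_seeds(seed, trials)
    virtual_frac = np.zeros((trials, N))
    mdsm_frac = np.zeros((trials, N))
    for t, s in enumerate(trial_seeds):
        layer_seeds = _child_seeds(s, N)
        layers = [generators.gen_k_regular(n, k, ls) for ls in layer_seeds]
        for i in range(1, N + 1):
            prefix = MultilayerNetwork(layers[:i])
            virtual_frac[t, i - 1] = theory.virtual_dsm(prefix, time_limit=time_limit).size / n
            mdsm_frac[t, i - 1] = domset.fast_mdsm(prefix, time_limit=time_limit).size / n
    table = pd.DataFrame(
        {
            "N": np.arange(1, N + 1),
            "virtual_fraction": virtual_frac.mean(axis=0),
            "mdsm_fraction": mdsm_frac.mean(axis=0),
            "alpha": list(alphas),
        }
    )
    table.attrs.update(k=k, n=n, trials=trials, seed=seed, trial_seeds=trial_seeds,
                       virtual_per_trial=virtual_frac.tolist(),
                       mdsm_per_trial=mdsm_frac.tolist())
    return table


# ---------------------------------------------------------------------------
# comparative workflows


@dataclass(frozen=True)
class PairwiseReport:
    """Sizes produced by the common-node comparative workflow.

    union_mds_size is only populated for pairs (the union graph of N > 2
    layers is not part of the workflow).
    """

    common_count: int
    mds_sizes: tuple[int, ...]
    mdsm_size: int
    mdsi_size: int
    union_mds_size: int | None
    wall_time_s: float
    mdsm_members: frozenset[str] = field(default_factory=frozenset)
    mdsi_members: frozenset[str] = field(default_factory=frozenset)

    @property
    def mdsm_fraction(self) -> float:
        return self.mdsm_size / self.common_count

    @property
    def mdsi_fraction(self) -> float:
        return self.mdsi_size / self.common_count


def pairwise_workflow(
    g1: UndirectedGraph,
    g2: UndirectedGraph,
    include_isolated: bool = True,
) -> PairwiseReport:
    """Two-layer comparative analysis on the common nodes V = V_1 ∩ V_2.

    Computes MDS(G_1(V)), MDS(G_2(V)), MDSM(G_1(V), G_2(V)) (with the
    two-layer preprocessing), the MDSI, and the MDS of the union graph
    G_1(V) ∪ G_2(V) as the single-network alternative.
    """
    start = time.perf_counter()
    v = common_nodes(g1, g2)
    if not v:
        raise ValueError("the two layers share no nodes")
    h1, h2 = induced_subgraph(g1, v), induced_subgraph(g2, v)
    mds1 = domset.ilp_mds(h1, include_isolated, canonical=True)
    mds2 = domset.ilp_mds(h2, include_isolated, canonical=True)
    joint = domset.fast_mdsm(MultilayerNetwork([h1, h2]), include_isolated)
    mdsi_members = mds1.members & mds2.members
    union = domset.ilp_mds(graph_union(h1, h2), include_isolated)
    return PairwiseReport(
        common_count=len(v),
        mds_sizes=(mds1.size, mds2.size),
        mdsm_size=joint.size,
        mdsi_size=len(mdsi_members),
        union_mds_size=union.size,
        wall_time_s=time.perf_counter() - start,
        mdsm_members=joint.members,
        mdsi_members=frozenset(mdsi_members),
    )


def nlayer_workflow(
    graphs: Sequence[UndirectedGraph],
    include_isolated: bool = True,
    max_layers: int | None = 6,
) -> PairwiseReport:
    """N-layer generalisation on the N-way common node intersection.

    Reports per-layer MDS sizes, the N-layer MDSM and the N-way
    intersection of the canonical per-layer MDSs.
    """
    if len(graphs) < 2:
        raise ValueError("need at least 2 layers")
    if max_layers is not None and len(graphs) > max_layers:
        raise ValueError(f"more than {max_layers} layers (pass max_layers=None to override)")
    start = time.perf_counter()
    v = set(graphs[0].nodes)
    for g in graphs[1:]:
        v &= set(g.nodes)
    if not v:
        raise ValueError("the layers share no common node")
    induced = [induced_subgraph(g, v) for g in graphs]
    mds = [domset.ilp_mds(h, include_isolated, canonical=True) for h in induced]
    joint = domset.ilp_mdsm(MultilayerNetwork(induced), include_isolated)
    inter = frozenset(set.intersection(*(set(m.members) for m in mds)))
    return PairwiseReport(
        common_count=len(v),
        mds_sizes=tuple(m.size for m in mds),
        mdsm_size=joint.size,
        mdsi_size=len(inter),
        union_mds_size=None,
        wall_time_s=time.perf_counter() - start,
        mdsm_members=joint.members,
        mdsi_members=inter,
    )


# ---------------------------------------------------------------------------
# enrichment


@dataclass(frozen=True)
class EnrichmentRecord:
    """Log-ratio enrichment of a control set in one functional class.

    score = ln[(N_p^C(F)/N_p^C) / (N_p(F)/N_p)] where N_p is the common
    background size, N_p(F) the background members carrying class F, N_p^C
    the control-set size and N_p^C(F) the control-set members carrying F.
    A control set devoid of the class is reported as -inf with the
    depleted flag (no pseudocount is applied).
    """

    control_set_kind: str
    functional_class: str
    n_p: int
    n_p_f: int
    n_p_c: int
    n_p_c_f: int
    score: float
    depleted: bool = False


def enrichment(
    n_p: int,
    n_p_f: int,
    n_p_c: int,
    n_p_c_f: int,
    control_set_kind: str = "MDSM",
    functional_class: str = "",
) -> EnrichmentRecord:
    """Exact evaluation of the enrichment log-ratio from its four counts."""
    if n_p < 1 or n_p_c < 1 or n_p_f < 1:
        raise ValueError("N_p, N_p^C and N_p(F) must all be at least 1")
    if not (n_p_c_f <= n_p_c <= n_p and n_p_c_f <= n_p_f <= n_p):
        raise ValueError(
            f"count invariants violated: ({n_p}, {n_p_f}, {n_p_c}, {n_p_c_f})"
        )
    if n_p_c_f == 0:
        return EnrichmentRecord(
            control_set_kind, functional_class, n_p, n_p_f, n_p_c, n_p_c_f,
            score=float("-inf"), depleted=True,
        )
    score = math.log((n_p_c_f / n_p_c) / (n_p_f / n_p))
    return EnrichmentRecord(
        control_set_kind, functional_class, n_p, n_p_f, n_p_c, n_p_c_f, score
    )


def read_annotation(path) -> pd.DataFrame:
    """Read a node-to-class TSV (node_id<TAB>class_label, one pair per line)."""
    table = pd.read_csv(path, sep="\t", header=None, names=["node", "klass"],
                        dtype=str, comment="#")
    return table


def enrichment_batch(
    annotation: pd.DataFrame | Mapping[str, Iterable[str]],
    control_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> list[EnrichmentRecord]:
    """Enrichment of each control set in every annotated class.

    A node carrying several class labels contributes to every class's
    counts, while N_p counts each background node once. Classes absent
    from the background are skipped with a log notice.
    """
    background = set(background)
    if isinstance(annotation, pd.DataFrame):
        pairs = annotation.itertuples(index=False)
        node_classes: dict[str, set[str]] = {}
        for node, klass in pairs:
            node_classes.setdefault(str(node), set()).add(str(klass))
    else:
        node_classes = {str(k): set(v) for k, v in annotation.items()}

    classes = sorted(set().union(*node_classes.values())) if node_classes else []
    n_p = len(background)
    records: list[EnrichmentRecord] = []
    for kind, members in control_sets.items():
        members = set(members)
        if not members <= background:
            raise ValueError(f"control set {kind!r} is not inside the background")
        n_p_c = len(members)
        for klass in classes:
            carriers = {v for v in background if klass in node_classes.get(v, ())}
            n_p_f = len(carriers)
            if n_p_f == 0:
                logger.info("class %s absent from background; skipped", klass)
                continue
            n_p_c_f = len(members & carriers)
            records.append(
                enrichment(n_p, n_p_f, n_p_c, n_p_c_f, kind, klass)
            )
    return records


def compare_enrichment_groups(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney comparison of per-pair enrichment scores
    between two lineage groups; returns (U statistic, p-value). This is a
    documented methodological choice, not a replication of any published
    significance procedure."""
    stat, pval = mannwhitneyu(scores_a, scores_b, alternative="two-sided")
    return float(stat), float(pval)
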