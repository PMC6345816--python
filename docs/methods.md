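# Methods

## The control problem

A dominating set U of an undirected graph G(V, E) is a node subset such
that every node is in U or adjacent to a member of U. Under the
dominating-set controllability framework for networks with bi-directional
edges, each dominating node receives an independent control input and
controls itself and its incident edges, so a minimum dominating set (MDS)
is a minimum driver-node set for one network.

This package studies the multilayer version. A multilayer network here is
an ordered collection 𝒢 = {G_i(V_i, E_i)} of N undirected layers whose
node sets overlap but need not coincide; layers are never physically
coupled. A dominating set for 𝒢 (DSM) must dominate every layer
simultaneously: for every i and every v ∈ V_i, v ∈ U or v has an
E_i-neighbour in U. The minimum such set (MDSM) is the smallest driver-node
set that controls all layers at once — e.g. a common enzyme set that could
control the metabolism of several species. Per-layer MDS sizes sandwich the
MDSM size:

    max_i S_MDS(G_i)  ≤  S_MDSM(𝒢)  ≤  Σ_i S_MDS(G_i),

with the lower bound attained for identical layers and the upper bound for
disjoint node sets.

The MDSI — the intersection of one MDS per layer after restriction to the
common nodes — is computed only as a plain-overlap baseline; it carries no
controllability guarantee.

## Exact computation

Both MDS and MDSM are NP-hard, but the covering ILP

    minimise Σ x_i  s.t.  x_i + Σ_{j:{v_j,v_i}∈E_k} x_j ≥ 1
                          for every layer k and every v_i ∈ V_k

is solved quickly in practice on sparse power-law-like networks. The
solver backend is HiGHS through `scipy.optimize.milp`, behind a single
narrow interface (`multidom._solver.solve_binary_min`: binary variables,
covering rows, pinned variables, optional cardinality-equality row), so a
different MILP engine could be dropped in without touching the callers.

Isolated nodes must by definition belong to every dominating set; the
`include_isolated` flag (default true) implements that original
definition, with the variant that ignores them available throughout.

For two layers a degree-1 preprocessing shrinks the ILP. Scanning nodes in
lexicographic order, on working copies of both edge sets:

* if some unobserved leaf v_j of layer 1 (current degree 1, not in V_M)
  hangs off v_i and v_j does not exist in layer 2, then v_i is pinned into
  V_M, the leaf edge is deleted and v_j is marked observed in layer 1;
* symmetrically for layer 2;
* if the same single edge {v_i, v_j} is v_j's only edge in both layers,
  v_i is pinned and v_j observed in both.

After each sweep, observation propagates to every unobserved non-V_M
neighbour of V_M in each layer; the loop stops when a sweep pins nothing
new. Pinning a leaf's unique neighbour can never hurt: some MDSM must
dominate the leaf, and its only helpers are the leaf itself or that
neighbour, and the neighbour dominates at least as much. The reduced ILP
pins x = 1 on V_M and drops the covering rows of observed nodes. Two
choices here were genuinely open:

* **Scan order.** No order is canonical; we fix lexicographic node order,
  layer-1 rule before layer-2 rule before the joint rule, so runs are
  reproducible. Any fixed order preserves the optimum, which the suite
  asserts by comparing against the plain ILP on every tested instance.
* **Edge sets in the reduced ILP.** Preprocessing deletes edges from its
  working copies, but the remaining covering rows are written over the
  *original* edge sets. Observed nodes are exactly those with a V_M
  neighbour in the original layer, so domination certificates stay valid,
  and the pinned V_M makes the two formulations equivalent; the size
  equality is again asserted on every tested instance.
* **Degenerate multiplex inputs.** When both layers share one node set the
  two exclusive-leaf rules can never fire (they require the leaf to be
  absent from the other layer) and only the shared-edge rule applies; the
  conditions are implemented verbatim, with no relaxation.

MDS solutions are not unique. Where a specific representative matters
(MDSI, byte-stable CLI output) a second solve pins the optimal cardinality
and minimises the sum of lexicographic node ranks; rank-sum ties are
theoretically possible but were never observed, and the canonicalisation
is off by default for speed.

The default solver time limit is 600 s; on timeout the solver raises
rather than returning a possibly suboptimal incumbent.

### A practical hardness boundary

Sparse scale-free instances — the regime the method targets — solve in
milliseconds even at n = 5000 (many degree-1/degree-2 nodes pin much of
the solution locally). Random k-regular graphs are the opposite extreme:
the LP relaxation is uniformly fractional (x ≡ 1/(k+1)), giving a dual
bound of n/(k+1) that branch-and-bound moves extremely slowly, so exact
MDS on a random 4-regular graph stops being routine around n ≈ 100–150
and exact 3-layer MDSM around n ≈ 60–100. The k-regular experiments below
therefore run at n = 60 by design; the scale-free experiments run at
n = 1000–5000.

## Analytic estimates

The size recursions analyse a *virtual* layer-by-layer construction:
DS_1 = MDS(G_1); for i ≥ 2, V_i is the set of nodes the accumulated set
fails to dominate in G_i, and DS_i is an MDS of the induced residual
G_i(V_i). The union is a valid DSM, not necessarily minimum. For N
k-regular random layers on one node universe, mean-field counting gives

    α_1 = 1/(k+1),   α_{i+1} = α_i + (1/(k+1)) (1−α_i)^{k+1},

and α_N·n estimates the constructed DSM size. For maximally assortative
scale-free networks — realised in their limiting form as disjoint
k-regular blocks with sizes ∝ k^−γ — averaging over the block distribution
gives

    β_1 = Σ_k k^−γ/(k+1) / Σ_k k^−γ,
    β_{i+1} = β_i + Σ_k (1−β_i)^{k+1} k^−γ/(k+1) / Σ_k k^−γ.

Numerics: both sums truncate at k_max = 10⁵ (or when the running k^−γ term
drops below 10⁻¹²), and the truncated remainders of the denominator and
the β_1 numerator are restored analytically with Hurwitz-zeta tails
(1/(k+1) expands into an alternating Hurwitz series that converges like
k_max^−m). Without the tail term the denominator alone is short by
≈ 1/k_max, which at γ = 2 shifts β_1 by ≈ 2.4·10⁻⁶ — visible against the
exact telescoping value β_1(2) = (ζ(2)−1)/ζ(2). The increments for i ≥ 2
carry a (1−β)^{k+1} factor that kills their tails geometrically, so they
need no correction.

What the recursions do and do not estimate, as measured by this package's
own experiments: on 4-regular 3-layer networks at n = 60 the *exact MDSM*
fraction lands within a few percent of α_3 (0.317 vs 0.308), while the
virtual construction itself overshoots α_3 by ~30–40% (0.40–0.43). The
mean-field step assumes the residual graph is still k-regular-like, but the
actual residual (a ≈ (1−α)^{k+1} fraction of nodes) is sparse and
fragmenting, and its MDS is far denser than 1/(k+1); the recursion is
therefore best read as an estimate of the MDSM size, matching how it is
used, rather than of the procedure it was derived from. `virtual_dsm` uses
exact ILP MDS at every stage (any heuristic MDS would only enlarge the
constructed DSM).

## Perturbation estimates

To quantify how similar two layers must be for multicontrol to stay cheap,
a second layer is derived from G_0 by K perturbation steps and
S_MDSM(G_0, G_K)/S_MDS(G_0) is tracked. Two operators:

* **Degree-preserving rewiring**: replace edges {v_i,v_j}, {v_h,v_k}
  (four distinct endpoints, uniform pairing orientation) with {v_i,v_k},
  {v_h,v_j} when both replacements are absent; degrees are untouched. A
  draw violating the constraints is rejected and redrawn, up to 1000
  attempts per step (the operator is conditional on admissible pairs
  existing; on a complete graph it correctly reports infeasibility).
* **Random insertion/deletion**: each step deletes a uniform existing
  edge with probability p_d, else inserts a uniform absent pair.

With p the degree-mass fraction of the base MDS and q the fraction of
non-MDS nodes with ≥ 2 MDS neighbours, one step forces one extra
dominating node with probability approximately

    rewiring:            P₊₁ = 4(1−q)p(1−p)³ + 2(1−q)²p²(1−p)²
    insertion/deletion:  P₊₁ = 2 p_d (1−q) p (1−p)

and the linear estimate of the K-step ratio is (S + K·P₊₁)/S, with p and q
measured once on G_0 (a flagless design choice; re-measuring per K would
only bend the line slightly). The written inequality this is derived from
compares a set size against K·P₊₁ alone, which is dimensionally odd; this
package reads K·P₊₁ as the estimated *increase* over the base MDS, the
only reading consistent with the ratio comparison actually performed.

Measured behaviour matches the qualitative claims: the observed rewiring
ratio grows much more slowly than the linear estimate (at n = 1000,
γ = 2.5, K = 200: observed ≈ 1.06 vs predicted ≈ 1.14 — rewiring preserves
hub degrees, and hubs stay in the dominating set), while the
insertion/deletion estimate tracks the observation several times more
closely (mean absolute gap ≈ 0.007 vs ≈ 0.037 on matched grids).

## Generators: what the fixtures emulate

* `gen_k_regular` — pairing-model k-regular random graphs (networkx),
  rejection until simple.
* `gen_powerlaw` — degrees drawn i.i.d. from P(k) ∝ k^−γ (k ≥ 1, capped
  at n−1), configuration-model pairing, self-loops and parallel edges
  discarded rather than rewired. Discarding slightly deflates the realised
  degrees of hubs; the tail slope of the realised distribution stays within
  ~0.3 of the drawn sequence's at n = 5000. No connectivity is enforced and
  no minimum degree above 1 is imposed (nothing in the model requires
  either).
* `gen_max_assortative` — the limiting structure of assortativity-maximal
  scale-free graphs: disjoint k-regular blocks with round(c·k^−γ) nodes,
  truncated where a block would need ≤ k nodes, odd blocks dropping one
  node. This is deliberately the limit object the β recursion describes,
  not an edge-swap maximisation procedure.

Default experiment scales follow the perturbation-study design (n = 5000,
10 trials, γ ∈ {2.1, 2.3, 2.5, 2.7}); the shipped test battery and the
acceptance script run the same pipelines at n = 60–1000 with 2–5 trials,
sizes chosen so the exact solver is routine on every instance class
involved. Synthetic fixtures share none of the biological structure of
real metabolic or interaction networks (no reaction stoichiometry, no
annotation correlation), so passing batteries demonstrate correctness of
the computations, not biological conclusions.

## Enrichment

For a control set C (MDSM or MDSI members) and functional class F over a
common background of N_p nodes: E^C(F) = ln[(N_p^C(F)/N_p^C)/(N_p(F)/N_p)].
A node with several class labels counts once per class it carries; N_p
counts nodes once. N_p^C(F) = 0 yields −∞ with a depletion flag — the
formula has no pseudocount and none is invented. Classes absent from the
background are skipped with a log notice. Group-level contrasts of
per-pair scores use a two-sided Mann–Whitney test, a documented
methodological choice rather than a replication of any published
significance procedure.

## Known limitations

* Exact k-regular computations are bounded by MILP hardness as described
  above; no approximation fallback is provided (timeouts raise).
* The α/β recursions are mean-field estimates without error bounds, and
  the rewiring P₊₁ deliberately keeps the unconstrained-choice counting
  factor 4 from its derivation.
* Canonical-MDS tie-breaking by rank sum is not a strict lexicographic
  minimum; residual ties are possible in principle.
* Directed, weighted and physically coupled (inter-layer edge) networks
  are out of contract.
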