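# Methods

## The model

`netgame` treats a small neural network — the motivating system is the
131-neuron frontal (head-ganglia) subnetwork of the *C. elegans* connectome —
as the equilibrium of a strategic network-formation game. Neurons are agents;
toward every other neuron an agent either holds a link (strategy L) or not
(strategy D). Agent *i*, facing opponent *j* in network *g*, scores the state
with a linear utility

```
u_i = 1[ij linked] · (α·D_ij + β·B_ij) + λ·S_i + ρ·P_i + θ·C_i + ω·Be_i
```

where

| term  | meaning                                        | units         |
|-------|------------------------------------------------|---------------|
| D_ij  | Euclidean soma distance                        | µm            |
| B_ij  | absolute birth-time difference                 | minutes       |
| S_i   | mean shortest-path length from *i*             | hops          |
| P_i   | PageRank of *i* (damping 0.85, uniform teleport) | —           |
| C_i   | closeness: 1 / S_i over reachable peers        | —             |
| Be_i  | betweenness, normalized by (n−1)(n−2)          | —             |

The link-cost terms D and B apply only while the link exists; the structural
terms are evaluated on whichever network state is scored. A network is
**pairwise stable** when no agent gains by unilaterally cutting one of its
links and no pair can both gain by adding the missing link between them.

The package runs the model in both directions:

* **inverse** (`fitting`): assume the observed network is pairwise stable,
  turn every unordered pair into two linear inequalities in (α, β, λ, ρ, θ,
  ω) — one per endpoint, from the utility difference between the linked and
  unlinked states of that pair with all other edges fixed — and estimate the
  coefficients by linear programming;
* **forward** (`game`): start from a directed Havel-Hakimi network realizing
  the observed in/out degree sequences, pull soma positions and birth times
  onto its nodes by ascending total-degree rank, and iterate add/delete moves
  until pairwise stability.

## Conventions of the dynamics

The game acts on unordered pairs. A pair is *linked* when any directed edge
exists between its nodes; deletion removes every such edge; addition inserts
one directed edge whose direction is a deterministic per-pair fair coin keyed
by the run seed (`edge_direction` also offers `low_to_high` and `both`).
Structural features S, C, Be are computed on the undirected projection and
PageRank on the digraph, because pairwise stability is an undirected notion
while the underlying connectome is directed.

Deletion is unilateral by default (`deletion_rule="either"`): a link falls
when *one* endpoint strictly gains from cutting it. The alternative reading —
deletion only when both endpoints gain — is available as
`deletion_rule="both"`. Addition requires both endpoints to gain strictly.
"Strictly" means an improvement above an absolute tolerance of 1e−12.
The stability checker's condition for unlinked pairs follows the standard
definition (a violation also occurs when one endpoint strictly gains and the
other is exactly indifferent); with continuous-valued attributes exact
indifference has measure zero, so the dynamics' both-strict addition rule and
the checker agree on every converged run we generate.

Each sweep visits all n(n−1)/2 pairs once in a seeded random permutation; the
dynamics stop at the first move-free sweep, or report `converged=False` after
`max_sweeps` (default 60). A node isolated by a deletion has no reachable
peer, so its S_i is set to the penalty sentinel n (the node count); this
keeps the dynamics well-defined and makes isolation costly whenever λ < 0.
The sentinel is configurable.

Features whose coefficient is exactly zero are skipped during move
evaluation; betweenness and PageRank recomputation would otherwise dominate
the run time.

## The linear program

For every unordered pair and each endpoint the constraint vector is

```
δ = (D_ij, B_ij, ΔS_i, ΔP_i, ΔC_i, ΔBe_i),   Δx = x(linked) − x(unlinked),
```

with D, B entering un-differenced because they exist only in the linked
state. Two sense conventions are first-class. `as_printed` constrains
δ·c ≤ 0 on linked pairs and δ·c ≥ 0 on unlinked pairs; it is the orientation
under which the estimate on real connectome data saturates at the all-negative
signature (α, β, θ at the −1 bound). `standard` is the reverse and is the
literal stability direction (an existing link must not profit from deletion).

The objective minimizes the sum of linked-state utilities, which is linear in
the coefficients. The system is homogeneous — the zero vector always
satisfies every constraint — so the box bounds (default [−1, 1]) and the
objective select a non-trivial vertex. Global optimality is not required;
any bounded optimum of the HiGHS solver is accepted. In `soft` mode every
constraint gets its own non-negative slack penalized in the objective
(default weight 100 per normalized unit), which is the appropriate relaxation
because the per-endpoint inequalities slightly over-constrain a genuinely
stable network: stability only forbids *jointly* profitable additions, not
every individually profitable one.

Two numerical devices matter in practice:

* **Column normalization** (`normalize=True`): each feature column is scaled
  to unit maximum magnitude before solving, and the coefficients are reported
  in that normalized space (`feature_scale` maps them back to raw units).
  Raw distance and birth-time columns are orders of magnitude larger than
  PageRank or betweenness deltas; without normalization the reported
  coefficients are meaningless across features and escape any fixed box.
* **Interval-midpoint refinement** (`refine="interval_midpoint"`): the LP
  optimum routinely sits on a degenerate face — several coefficient values
  attain (near-)optimal cost. Standard coefficient ranging resolves this:
  within the set of solutions whose total cost is at most 1% above the
  optimum, two auxiliary LPs per coefficient compute its attainable minimum
  and maximum, and the midpoint of that interval is reported. A coefficient
  whose sign the constraints pin down keeps it; one parked on an arbitrary
  vertex moves to the centre of its admissible range. This is what makes
  sign recovery on synthetic equilibria reproducible.

## Feature-scale commensurability

With coefficients of order one, raw µm/minute link costs (tens to hundreds)
dwarf the structural terms (hops and centralities of order one), and the only
equilibrium is the empty network. The utility is only meaningful when link
costs and structural terms are commensurate — equivalently, the model's
distance and birth-time inputs are normalized quantities.
`AttributeTable.unit_scaled()` provides that normalization (positions divided
by the largest single-axis extent, isotropically; birth times by their
range), and every synthetic game experiment in the package runs on
unit-scaled attributes. Estimates on raw-unit features are covariant: scaling
a feature column by *s* divides its recovered raw-unit coefficient by *s*.

## Synthetic study conditions

The generator emulates the shape of a small connectome with no download:

* n = 30 neurons by default (evolution with full feature recomputation stays
  in seconds; n = 131 with lognormal(µ=1.6, σ=0.6) degrees reproduces the
  frontal network's scale and heavy in-degree tail);
* soma positions uniform in a (50 µm)³ box; birth times uniform over 800
  minutes, or optionally a two-component mixture (60% early in the first
  quarter of the range, 40% late in the last 35%) as a crude stand-in for
  embryonic/post-embryonic neurogenesis waves — a convenience, not a
  biological claim;
* in/out degree sequences drawn i.i.d. lognormal(µ=1.0, σ=0.6), rounded,
  clipped to [0, n−1], and repaired to equal sums by seeded unit increments,
  then realized exactly by the directed Havel-Hakimi construction;
* ground-truth equilibria: a sparse random digraph (edge probability 0.12)
  evolved to convergence under known coefficients
  (−1, −0.5, −0.1, 0, −0.25, 0).

What the synthetic conditions do **not** reproduce: real lineage timing or
anatomy, synapse weights or gap-junction/chemical identity, spatial
clustering of somata, or the empirical degree-degree correlations of the
worm connectome. Equilibria under the ground-truth coefficients are sparse
(average degree ≈ 1): with all factors acting as costs, links persist mainly
where deletion would disconnect or severely lengthen paths. Tests passing on
these fixtures therefore validate the algorithms' contracts — exact stability
checking, fixed-point termination, sign-consistent inverse estimation — not
any claim about recovering the density or clustering of real connectomes.

## Random baselines

Six reference-matched generators mirror the candidate base networks the
model is compared against: distance-based Watts-Strogatz (each neuron wired
to its k = 5 nearest neighbours by soma distance, then each edge rewired
with probability 0.5 — the ring of the classical construction is replaced by
the k-nearest-neighbour graph, honouring the stated intent of distance-based
initial wiring), Chung-Lu expected-degree, power-law clustering (m = 6,
triangle probability 0.2), directed Havel-Hakimi on the reference in/out
sequences, directed scale-free growth (α = 0.15, β = 0.8, γ = 0.05,
δ_in = 0.2, δ_out = 0, stopping at the reference edge count since the node
count of this process is not guaranteed), and directed Erdős-Rényi (p = 0.5
by default, configurable — note that p ≈ 0.1 is what actually reproduces a
131-node connectome's density). Whether the Watts-Strogatz k counts
neighbours per side or in total is ambiguous in the source construction; we
use total (so minimum degree ≥ k before rewiring).

Open conventions we resolved and document: the comparison tables' single
"betweenness" value is reported as the mean normalized betweenness;
homogeneity — left undefined in the source material — is the degree-
uniformity index ⟨k⟩²/⟨k²⟩ (1 for regular graphs, small for heavy-tailed
ones); disconnected path averages run over ordered reachable pairs only.

## Known limitations

* Equilibrium non-uniqueness: the dynamics' outcome depends on sweep order
  (seeded); different seeds give different, equally valid equilibria.
* The inverse problem is set-identified, not point-identified: many
  coefficient vectors satisfy all constraints of a given equilibrium. The
  estimator recovers the sign pattern reliably, magnitudes only up to the
  geometry of the near-optimal face.
* For coefficient regimes where the S-reward and C-penalty nearly balance
  (λ ≈ −θ/S² along the operating range), the dynamics can cycle
  add/delete and hit `max_sweeps` without converging; this is reported, not
  raised.
* Betweenness-weighted utilities (ω ≠ 0) are exact but slow: every move
  evaluation recomputes full betweenness twice.
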