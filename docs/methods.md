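# Methods

## Karyotype representation

The unit of state is the homologous chromosome **pair**: a karyotype is
(M, A, c) with M biarmed (m/sm) pairs, A uniarmed (st/a) pairs and an
optional count c of CMA3-signal-bearing pairs. The four Levan-style
centromere categories are collapsed into two arm classes because the
cytogenetic narrative being modelled only ever distinguishes m-sm from
st-a; within-class centromere position, chromosome size, translocations,
polyploidy, sex chromosomes and B chromosomes are out of scope. Pair
units make every event an integer lattice step and force 2n = 2(M + A) to
stay even; formulas with odd per-class chromosome counts are rejected by
default (a lenient flag floors them to whole pairs with a warning).

Formula parsing accepts the `+`-separated `<count><category>` dialects
found in published tables (`18m-sm+26st-a`, `14sm+36st-a`, fine-grained
`4m+6sm+...`, case-insensitive, `t` counted as uniarmed). Canonical
output is always `<2M>m-sm+<2A>st-a`.

## Event model and distance

Six events with fixed effect vectors (ΔM, ΔA, Δc): fusion (+1, −2, 0),
fission (−1, +2, 0), pericentric inversion in both directions (∓1, ±1, 0),
CMA3 gain/loss (0, 0, ±1). Both inversion directions cost 1: the
narrative invokes both creation and reduction of biarmed chromosomes
without weighting, and no data here could identify asymmetric weights.
Feasibility: a fusion needs A ≥ 2, a fission or m→a inversion needs
M ≥ 1, an a→m inversion needs A ≥ 1, a CMA3 loss needs c ≥ 1, and no
event may push c above M + A.

For the arm-class component, any event path from (M1, A1) to (M2, A2)
satisfies (fissions − fusions) = ΔN and (a→m − m→a inversions) = ΔM + ΔN,
giving the lower bound d ≥ |ΔN| + |ΔM + ΔN| and a *forced* minimal
multiset (one side of each opposing pair is zero — hence the minimal
decomposition is unique as a multiset even when event orderings differ).
Whether that multiset can be ordered feasibly is decided exactly by a
dynamic program over the interleaving grid; if not, the distance falls
back to breadth-first search over the lattice. In practice the fallback
only matters at one degenerate point: the empty karyotype (0, 0) is an
isolated lattice vertex (no event enters or leaves it), so distances
between it and any other state are infinite. The test suite verifies
closed form against an independent graph-BFS oracle over every ordered
pair of states with M ≤ 12, A ≤ 25 (using a wider search lattice so no
geodesic is clipped by the test's own bounds).

The CMA3 component evolves as an independent ordered character; when both
endpoints track it, |Δc| is added to the distance. This mirrors how the
phenotype is tabulated (a separate column), and keeps the two characters'
costs additive.

## Ancestral reconstruction

Sankoff parsimony with the event distance as cost matrix. Candidate
ancestral states span the observed tip rectangle widened by a `slack` of
4 pairs per axis (clipped at zero) — enough that widening further never
changes the total cost on any dataset we generate; a fixture test checks
cost stability across slack 0/2/6. Leaves cost 0 at their observed state
and ∞ elsewhere; internal nodes are filled post-order; the minimum of the
root vector is the total cost. A pre-order sweep marks every state
attaining the optimum at each node (the MPR set, reported in full,
lexicographically ordered), and full assignments can be enumerated
lazily in lexicographic preorder sequence with a cap and truncation flag.
Branch lengths are ignored throughout: the criterion is event-count
parsimony, not likelihood. Polytomies and degree-2 nodes are handled (the
DP sums over children), so re-rooted trees score identically — costs are
symmetric.

Per-branch scenarios apply the unique minimal decomposition to each
(parent, child) state pair of a chosen assignment; branch totals then sum
exactly to the tree cost.

### Root-tie handling

On the five-species study inputs the parsimony optimum (5 rearrangements)
is attained by exactly two assignments, rooted at (8, 16) = 16m-sm+32st-a
(2n = 48) and (7, 18) = 14m-sm+36st-a (2n = 50). An ingroup-only,
symmetric-cost analysis cannot distinguish them. The package therefore
selects among *exactly tied* root states by smallest event distance to a
reference karyotype, defaulting to the ancestral cichlid karyotype 48st-a
= (0, 24): eight inversions to (8, 16) versus nine events to (7, 18).
This is the standard outgroup argument of comparative cytogenetics made
explicit and deterministic; disable it (`reference=None`) to get the
plain lexicographically smallest assignment. MPR sets always report the
full tie regardless.

The CMA3 character on the same inputs is unambiguous: root 1 pair, total
cost 2. The two unit gains on the *N. aureocephalus* branch count the
character-state change (1 → 3 pairs); whether one or two mechanistic
inversions produced that multiplication is not identifiable from counts,
and the package reports only the count-level cost.

## Synthetic data generator

The generator is the forward counterpart of the reconstruction model, not
a caricature of real cytogenetics: states evolve from a configurable root
(default the inferred clade ancestor, 16m-sm+32st-a with one CMA3 pair)
down a rooted tree; per branch, each event kind draws a Poisson count with
mean rate × exposure and the sampled events are applied in a uniformly
shuffled order. Exposure is the branch length when lengths are present
and `use_branch_lengths` is set, else 1 per branch (topology-only trees,
like the packaged fixture, always use per-branch rates). An event that is
infeasible at its moment is *skipped and logged*, not resampled — counts
stay Poisson-interpretable and there is no rejection loop at lattice
boundaries. Trees come from a pure-birth (Yule) process (dendropy), with
leaves relabelled t1…tn; a single seeded RNG stream makes every output
byte-reproducible, and the seed is echoed in all outputs.

Default rates total 0.5 expected events per branch (0.1 each for fusion,
fission and the two inversions; 0.05 for CMA3 gain and loss) — comparable
to the density of change in the study clade itself (five rearrangements
on eight branches) and deliberately illustrative: no rates are estimated
from data, and rate heterogeneity across branches is not modelled.

What passing recovery tests show — and what they do not: the simulator
emulates the event process the reconstruction assumes, so recovery
experiments measure the method's behaviour *under its own model*
(identifiability, the parsimony lower bound, root-state recovery at
moderate event densities). They cannot detect model misspecification in
real data: unequal mechanistic rates, within-class rearrangements
invisible to (M, A) counts, NOR dynamics driven by transposable elements,
or errors in the input topology.

Recovery metrics per replicate: whether the true root state (and its 2n)
lies in the root MPR set, the reconstruction cost versus the true number
of applied rearrangements (parsimony is a lower bound because the true
assignment is itself a candidate and each branch's applied sequence is a
feasible path), and the fraction of branches whose inferred minimal
multiset equals the applied multiset under the lexicographic assignment.
The packaged experiment uses 200 replicates of 20-leaf trees — large
enough for stable fractions, small enough to run in about a second.

## Numerical and implementation notes

- Cost matrices are built vectorized from the closed form; the only
  correction needed is the isolated (0, 0) state (set to ∞), a fact
  verified exhaustively rather than assumed.
- All tie-breaks are deterministic: states order by (M, A, c); the
  scenario assignment is lexicographic given the (possibly
  reference-tie-broken) root.
- Distances are cached (`lru_cache`) across the library; Sankoff DP and
  MPR marking are numpy matrix operations, so a 200-replicate recovery
  experiment completes in roughly a second on one CPU.
- Reports are written in preorder traversal order for reproducible diffs;
  Newick annotations use `[&key=value]` comment blocks that third-party
  viewers ignore.

## Known limitations

- The event model is count-level: it cannot distinguish which pairs fuse
  or invert, so histories differing only in pair identity are
  indistinguishable, and the minimal multiset is a lower bound on
  mechanistic events (the narrative itself allows "at least one"
  inversion where parsimony counts one).
- No likelihood or Bayesian machinery: no rate estimation, no
  uncertainty beyond exhaustive MPR enumeration.
- The reference tie-break injects prior knowledge; with no reference the
  root ambiguity on the study inputs is reported as-is.
- Input topologies are taken as known; phylogenetic uncertainty is not
  propagated.
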