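# Methods

## The model

A *reaction universe* is a fixed, ordered set of U candidate biochemical
reactions over metabolites with known elemental formulas. A metabolic
*genotype* is a binary vector over this set: the reactions an organism can
catalyze. One chemical element is focal (sulfur, `S`, in the real-data path;
the synthetic element `X` otherwise); the focal-element metabolites occurring
in at least one universe reaction are the candidate *sole sources*, and a
distinguished biomass reaction consumes the focal-element biomass precursors
(for sulfur: cysteine, methionine, coenzyme-A, acetyl-CoA and succinyl-CoA).
The biomass reaction is always present and never mutated.

Viability in the environment whose sole source is metabolite *s* is decided by
flux balance analysis: maximize the biomass flux subject to steady state
(S·v = 0, one mass balance per metabolite), irreversible flux bounds (each
reversible reaction is split into two irreversible fluxes), bounded uptake of
every allowed metabolite, and unbounded secretion of every metabolite. The
environment is rich in everything except the focal element: every metabolite
not containing the focal element may be taken up, plus the single designated
source. A genotype is *viable* iff the optimum exceeds 1.0e-3 flux units
(strictly). The *phenotype* is the vector of these verdicts over all candidate
sources; the *environmental demand* is the set of S sources on which viability
is required.

Derived notions follow the standard definitions of this literature: genotype
distance D = 1 − 2R_c/(N₁+N₂); minimal networks (no single deletion preserves
demand-viability), generated by randomized reaction removal from the full
universe; superessential reactions (present in all sampled minimal networks
of a demand); robustness ρ = 1 − R_ess/N; neutral and forced random walks
with sizes confined to {N, N+1} by alternating additions and deletions; and
Fisher-Wright populations (one mutation per individual per generation,
selection = uniform resampling among demand-viable mutants).

Two closed forms tie these together: the maximal equal-size genotype distance
D_max = 1 − R_SE/N, and the robustness model ρ = 1 + m − (N_min/N)(1 + m)
obtained from the empirically linear decline R_ess = N_min(1 + m) − m·N.

## Numerical choices

* **LP backend.** scipy's HiGHS solver over a sparse stoichiometric matrix
  assembled once per universe; per-call work only adjusts variable bounds
  (absent reactions and disallowed uptakes are clamped to zero). Default
  feasibility tolerances; one retry at 1e-10 on solver trouble, then an
  exception. Verdicts are insensitive to one order of magnitude around the
  default tolerance (tested).
* **Threshold semantics.** Viability requires rate > 1.0e-3 strictly; a 1e-9
  guard band absorbs solver round-off, so an optimum of exactly 1.0e-3 is
  inviable. The default uptake bound is 10 flux units per allowed metabolite —
  four orders of magnitude above the threshold, so verdicts are invariant to
  doubling it (tested). An unbounded LP (possible only for degenerate biomass
  definitions without focal-element input) counts as viable.
* **Caching.** Viability verdicts are memoized per (universe, genotype,
  source). The cache is semantically transparent (tested against a fresh
  model) and is what makes neighbor enumeration and long walks affordable.
* **Monotonicity shortcut.** Viability is monotone in the reaction set, so a
  reaction whose removal broke viability once can be retired permanently
  during network reduction; a single randomized pass therefore yields an
  exactly minimal network. The explicit single-deletion postcondition can be
  re-verified (`verify=True`, the default).
* **Degenerate inputs.** An empty genotype solves to zero biomass (inviable
  everywhere except environments whose sole source happens to be itself a
  biomass precursor of a single-precursor universe); empty demands are
  vacuously met; a universe without focal-element metabolites yields an empty
  source list and downstream modules refuse to run on empty demands.

## Walks

At size N an addition is proposed (uniform over absent reactions), at N+1 a
deletion (uniform over present reactions); rejected proposals change nothing
and do not consume the alternation turn. Proposals are scanned in a fresh
random permutation until one is acceptable — distributionally identical to
repeated uniform draws, but able to detect that no acceptable proposal exists
(the walk then terminates early with its steps recorded).

Forced walks add two constraints: additions never re-introduce a start
reaction, and no step may decrease the distance to the start. Because size-N
and size-N+1 states normalize distance differently, the non-decrease
constraint compares each proposal against the last visited state of the same
size; the shared-reaction count with the start is then a pure ratchet. D_max
is reported over visited states of the same size as the start (the equal-size
distance form 1 − R_c/N that the closed-form bound addresses); both choices
are deliberate design decisions of this implementation.

The reported D_max is a lower bound on the true maximal distance: every
demand-viable network contains some minimal network and hence the
superessential set, so D_max ≤ 1 − R_SE/N holds exactly, and walk length
only controls how closely the bound is approached.

## Synthetic universes

The generator emits universes with constructive ground truth: pathways are
explicit series of *steps* (edges of a DAG from sources to a hub, hub to
precursors), each step carrying `redundancy` interchangeable routes of
`route_steps` reactions each. Minimal networks are exactly one route choice
per needed step, so the complete minimal-set family, N_min and the
superessential set of any demand are available without search (and are
verified against brute-force subset enumeration at toy scale in the tests).
Salient design choices:

* **Two-element chemistry.** Metabolites carry formulas over {X (focal),
  C (filler)}; every conversion consumes filler, so elemental balance checks
  are exercised non-trivially and all generated reactions balance by
  construction.
* **Salvage steps** (precursor → hub) make every focal-element metabolite a
  workable sole source, matching the invariant that candidate sources are
  exactly the focal-element metabolites in reactions.
* **Topologies.** `linear` chains keep sources independent; `convergent`
  merges sources pairwise towards the hub, the funnelled structure of real
  assimilatory metabolism, under which viability on one source makes related
  sources mutationally nearby.
* **Multi-reaction routes** (`route_steps` > 1) mean a pathway swap needs
  several additions before any deletion is possible. Under the {N, N+1} size
  constraint such swaps are blocked in minimal networks and enabled by slack
  in larger ones — this is what makes the D_max gap close as N grows, the
  behavior the closed-form comparison probes. Single-step precursor routes
  (`precursor_route_steps=1`) keep some reactions substitutable by one
  addition, producing the linear decline of essential-reaction counts that
  the robustness model fits.
* **Decoys** are element-free reactions, never essential for any demand; they
  let network size vary widely relative to the demanded pathways.

What the generator does *not* emulate: realistic sulfur chemistry (oxidation
states, cofactor coupling, ATP/redox bookkeeping), shared currency
metabolites, thermodynamic constraints, and compartments. Passing tests
therefore demonstrate the correctness of the algorithms and the internal
consistency of the closed-form relations, not quantitative predictions about
real sulfur metabolism; the real-data path (KEGG flat files + SBML model
merge) exists for that purpose but ships no data.

## Study conditions and problem sizes

Desk-scale experiments run on two reference universes chosen once: a
redundant linear universe (3 sources, 3 precursors, depth 4, redundancy 2,
trunk 1, route_steps 2 with single-step precursor routes, 12 decoys; U = 63)
for the quantitative model checks, and a convergent universe (8 sources,
depth 3, 12 decoys; U = 30) for novelty and population shape checks. Minimal
network statistics use 100 replicates per demand; forced walks use several
hundred accepted steps at N between N_min and ~2·N_min; populations use
P = 10 over 150–200 generations. Exhaustive cross-checks (all 2^U genotypes
against the reachability oracle; brute-force minimal-set enumeration) are run
on universes with U ≤ 17.

At this scale the cumulative-novelty curve versus S peaks at the low-S end
and declines to (near) zero at full demand: every demanded pathway is a
sizeable fraction of a toy universe, so the combinatorial loss of gainable
sources dominates. The interior peak seen at full scale (demands small
relative to 124 sources) needs demanded pathways to be a vanishing fraction
of the universe and is not reproduced at desk scale; the shape check asserts
unimodality and the high-demand decline.

## Known limitations

* The grid orchestrator parallelizes nothing; it relies on the phenotype
  cache and per-cell resumability instead.
* Superessentiality is a replicate-intersection estimate, not a proof over
  all minimal networks (exact only where enumeration is feasible).
* The essentiality flag `full_phenotype=True` implements the literal
  definition (protect every source currently viable); the default protects
  the demanded sources only, which is what minimal-network generation
  enforces and what the robustness statistics use.
* KEGG flat-file parsing covers the ENTRY/EQUATION layout needed here, not
  every dialect of the LIGAND distribution.
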