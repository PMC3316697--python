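# Methods

## Generative models

Both models act on one aquifer with `k ∈ {1,2,3}` niches; each niche holds
at most one species (competitive exclusion), and the number of niches is
taken to equal the number of species recorded in the aquifer. An aquifer is
classified by the *largest* group of occupants descending from one
ancestral species: size 2 is a sympatric sister pair, size 3 a triplet; the
classifications are disjoint. One-niche aquifers can never hold sisters.

**Repeated colonization.** Colonization happens in `E ∈ {2,3}` discrete
events (arid periods). In event `j` every still-empty niche opens
independently with probability `p_j`; opened niches receive species drawn
uniformly *without replacement within the event* from a pool of `n ≥ k`
equally able ancestral species. Draws are independent across events, so the
same species can return. Same-event colonists are distinct species and have
had no time to diverge, so sisters require the same species in different
events; in particular a triplet needs three distinct events — this is the
reason the within-event draws must be without replacement, otherwise one
species could co-colonize two niches in one event and a third later.

The per-aquifer pair/triplet probabilities are evaluated exactly: sum over
the `(E+1)^k` niche→first-success-event assignments (a niche is first
filled in event `e` with probability `p_e ∏_{i<e}(1−p_i)`), and for each
assignment use the hypergeometric overlap of the per-event uniform species
subsets. With at most three colonists the only cases are: two events with
counts `(a,b)`, where `P(overlap ≥ 1) = 1 − C(n−a,b)/C(n,b)` and any
overlap is a pair; and one colonist in each of three events, where the
triplet (all equal) has probability `1/n²` and exactly-one-match has
probability `3(n−1)/n²`. Useful special cases that drop out of the sum:

- 2 niches, 2 events: `P_pair = 2 p1 (1−p1) p2 / n`
- 3 niches, 2 events: `P_pair = 6 p1 (1−p1) p2 / n`
- 3 niches, 3 events: `P_triplet = 6 p1 (1−p1)² p2 (1−p2) p3 / n²`

The three-niche/three-event *pair* probability includes the mixed path in
which the founder returns in one later event while an unrelated species
takes the remaining niche; the enumeration oracle in the test suite defines
(and confirms) these semantics.

**Single colonization.** One event fills each niche independently with
probability `p` (founders are distinct species); afterwards each empty
niche, taken in index order, is filled with probability `q` by a daughter
of a uniformly chosen current resident (one trial per niche; nothing
happens if the aquifer has no residents). Clade sizes do not depend on
which parent is chosen (with two founders any fill makes a pair; with one
founder all fills join the same clade), so:

- `P_pair(2) = 2 p (1−p) q`
- `P_pair(3) = 3 p² (1−p) q + 6 p (1−p)² q (1−q)`
- `P_triplet(3) = 3 p (1−p)² q²`

None of these involves the pool size, and the API enforces that (a single
scenario carrying a pool size is rejected).

**Region expectations.** Expected pair/triplet fractions weight the
per-niche-class probabilities by the census counts `a1, a2, a3` and divide
by the total `A`. There is no conditioning on non-empty aquifers: model
runs that leave an aquifer partly or fully empty stay in the denominator.
(With the in-study census 18/16/11 and `q = 1` the combined sister fraction
reduces to `(2 a2 + 3 a3) p (1−p) / A`, whose larger root at the observed
11/45 is 0.7843 — this is the convention under which the fitted probability
is meaningful.)

## Numerical choices

- **Optimizer** (`maximize_probability`): deterministic grid scan over
  `p ∈ [0,1]` at step 1e-3, then bounded Brent refinement in the bracketing
  cell to 1e-6; exact grid ties resolve to the smaller `p` (first maximum).
  The free parameter is the shared early-event probability; the final event
  probability stays as configured (conventionally 1). The three-event
  combined optimum is 0.393–0.394 for every pool size from 2 to 1000 — the
  argmax is essentially pool-free, so any valid `n` can be used to locate it.
- **Root solver** (`solve_probability_for_fraction`): sign-change bisection
  (Brent, xtol 1e-9) on the same 1e-3 grid, with grid nodes whose residual
  is below 1e-12 accepted directly (this is what returns the exact boundary
  roots {0, 1} for a target of zero). Roots are deduplicated and returned
  ascending; an unattainable target yields an empty list.
- **Percentiles**: numpy's linear interpolation between order statistics
  (`np.percentile(..., method="linear")`). The band is the (5, 95) pair by
  default.
- **Random numbers**: every region replicate draws from
  `SeedSequence(entropy=seed, spawn_key=(replicate,))`, so runs are
  reproducible and replicate results independent of evaluation order.
  The pool-size scan reuses one seed across pool sizes (common random
  numbers). The vectorized per-niche-class engine enforces within-event
  distinctness by drawing from a reduced range and re-inserting around the
  already-placed same-event species (order-statistics mapping); it is
  distribution-identical to the loopy per-aquifer reference simulator, and
  both are tested against the closed forms.
- **Degenerate inputs**: pool sizes smaller than a census's largest niche
  class are skipped by the pool-size scan (a single event can demand that
  many distinct species, so the model is undefined there); two-event
  scenarios return triplet probability exactly 0 rather than an error.

## Sister-clade detection and LTT

A sympatric sister clade is a *maximal* monophyletic group of 2–3 tips that
are all subterranean and share one aquifer (maximal: its parent clade
violates the condition, so a triplet is never double-counted as a nested
pair). Maximal same-aquifer clades larger than 3 violate the niche model
and raise an error rather than being truncated. Internal newick labels that
parse as numbers in [0,1] are read as posterior supports; `min_support`
filters clades by their own node's support, defaulting to 0 because
published analyses retained two clades with support < 0.7 after
corroboration by other methods (pass 0.7 to mirror the usual threshold);
clades without a support value always pass.

Lineage-through-time curves classify every branch as surface or
subterranean. The colonization of the subterranean habitat is unobserved
and must lie somewhere on the stem branch of each maximal all-subterranean
clade (or single subterranean tip); the `colonization_fraction` parameter
places it explicitly at that fraction along the stem from its older end
(default 0.5, the midpoint — the data cannot identify the true point, so
the choice is exposed rather than hidden). Counts at each grid age are
branches crossing that age; surface + subterranean = total by construction.
LTT requires an ultrametric tree (tip depths equal within 1e-6 of depth).

## Synthetic data

The generator emulates the study design: a pure-birth (Yule) surface
radiation with subterranean tips grafted according to simulated
colonization histories, with full ground truth retained.

- **Surface tree**: hand-rolled Yule simulation — waiting time with `k`
  lineages is Exponential(`k·λ`), from the root split until `n` tips, plus
  one final Exponential(`n·λ`) stretch; expected root age is
  `Σ_{k=2..n} 1/(kλ)`, which the tests use as the oracle. Defaults
  (60 tips, λ = 0.4/My) give a ≈9–10 My radiation, matching the emulated
  system's aridification window; the dataset generator redraws the tree
  (bounded retries) until it is deeper than the oldest event age.
- **Event ages** default to 7 and 3.5 My for two events, 7/5/3.5 for
  three, and 7 My for the single model — inside the 3–7 My radiation
  window of the emulated system; configurable.
- **Grafting**: every same-ancestor group of an aquifer becomes one subtree
  attached to a surface branch alive at the group's oldest colonization
  event. Repeated-colonization groups put their internal splits at the
  later event ages; the surface ancestor between events is treated as
  unsampled/extinct — the aridification premise of the scenario, and the
  reason observed sister groups are monophyletic at all. Single-model clade
  splits are drawn uniformly between the colonization age and the present.
  Donor branches are drawn uniformly among surface branches alive at the
  attachment age, independently per group, so one surface lineage may found
  niches in several aquifers — exactly as in the generative model, where
  every aquifer samples the same ancestral pool. Because grafting only
  inserts attachment nodes and never removes surface tips, every surface
  branch keeps a surface descendant, no spurious all-subterranean clade can
  arise, and the detector recovers the planted tally *exactly* (a tested
  invariant, not a statistical one).
- **What it does not emulate**: extinction, non-equal colonization
  propensities, sequence-level noise, uncertain tree estimation, or node
  support values. Passing round-trip tests therefore demonstrates the
  correctness of detection/tallying logic on clean topologies, not
  robustness to phylogenetic error in real data.

`recover_parameters` closes the loop (detect → tally → solve): on 200
synthetic regions generated at `p = 0.784` (single model, `q = 1`) the
median of the larger-root estimates falls within 0.1 of the truth; a
detected fraction above the model maximum yields an empty estimate with a
warning.

## Problem sizes used in the checks

Randomization bands use 10,000 replicates (the analysis convention);
simulator-vs-closed-form grids use 1e5 replicates per point with a
3-standard-error criterion; enumeration-oracle agreement is exact (1e-12);
parameter recovery uses 200 regions of 45 aquifers. The full suite runs in
well under a minute on one CPU.

## Known limitations

- Niche counts above 3 are out of scope everywhere (models, detector,
  generator); the detector treats larger same-aquifer subterranean clades
  as errors by design.
- The closed forms assume equal colonization chances across the pool
  (assumption of the repeated model); an effectively smaller pool is the
  model's own way to express unequal propensities.
- The single-model in-situ filling is one q-trial per empty niche in index
  order; at `q = 1` (the analyzed extreme) the order provably cannot affect
  the classification, and at `q < 1` the closed forms match the documented
  process exactly, but other filling conventions would give different
  formulas.
- LTT curves do not model extinction, so subterranean counts are counts of
  sampled extant lineages' ancestries, not historical diversity.
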