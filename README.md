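# sympatria

Tests of speciation mode in naturally replicated island-like habitats:
closed-form and Monte Carlo null models of aquifer colonization, sympatric
sister-clade detection on annotated phylogenies, and a synthetic-data
generator with known ground truth.

## The problem

Isolated calcrete aquifers in arid Australia each hold one to three species
of blind, wingless (stygobitic) diving beetles, descended from surface
species that went underground when the climate dried. Several aquifers hold
*sympatric sister species* — closest relatives sharing one aquifer, as
pairs or triplets. Two processes can produce that pattern:

- **repeated colonization** — the same widespread surface ancestor colonizes
  one aquifer in two or three distinct arid periods, diverging in between
  (allopatric speciation above ground, sisters by re-invasion);
- **single colonization with within-aquifer diversification** — one founder
  per occupied niche, with empty niches later filled by in-situ speciation
  of a resident (sympatric/parapatric/microallopatric speciation below
  ground).

`sympatria` implements both models and the statistics needed to decide
between them from a census of aquifers and a tally of sympatric sister
clades.

## The models

Each aquifer has `k ∈ {1,2,3}` niches, one species per niche (competitive
exclusion); the census `a1, a2, a3` (totalling `A`) counts aquifers by
niche number.

**Repeated colonization.** In event `j` (of 2 or 3) every still-empty niche
is filled independently with probability `p_j` by a species drawn uniformly
without replacement (within the event) from a pool of `n` ancestral
species; by convention the last event has probability 1. Sisters require
the *same* species in *different* events, so e.g. the two-niche/two-event
pair probability is `2 p1 (1 − p1) p2 / n`, the three-niche analogue is
`6 p1 (1 − p1) p2 / n`, and triplets are impossible with fewer than three
events. The general case is evaluated as an exact combinatorial sum over
occupancy patterns with hypergeometric cross-event match probabilities.

**Single colonization.** One event with niche colonization probability `p`
and distinct founders; each empty niche is then filled with probability `q`
by a daughter species of a resident. Pair and triplet probabilities
(`2p(1−p)q` for two niches; `3p²(1−p)q + 6p(1−p)²q(1−q)` and `3p(1−p)²q²`
for three) are free of the pool size.

Region-wide expected fractions weight these by `a1..a3` and divide by `A`.
A seeded Monte Carlo engine replicates the whole census and uses the
5th/95th percentiles of 10,000 randomizations as confidence limits.

## Worked example

```python
from sympatria import (
    AquiferCensus, ColonizationScenario, maximize_probability,
    solve_probability_for_fraction, min_pool_size_outside_band, SisterTally,
)

census = AquiferCensus.from_counts(18, 16, 11)          # 45 aquifers
observed = SisterTally(pair_aquifers=9, triplet_aquifers=2, total_aquifers=45)

# Most favourable setting for the repeated-colonization explanation:
p_star, value = maximize_probability(
    census, ColonizationScenario.repeated((0.5, 1.0), pool_size=10))
print(p_star, value)        # 0.5000 0.0544

# How large may the ancestral pool be before repeated colonization fails?
n_min = min_pool_size_outside_band(
    census, observed, n_range=range(2, 31), replicates=10_000, seed=1)
print(n_min)                # 4

# Which initial colonization probability lets within-aquifer speciation
# reproduce the observed 11/45 sister-aquifer fraction?
roots = solve_probability_for_fraction(
    census, ColonizationScenario.single(0.5, q=1.0), 11 / 45)
print(roots)                # [0.2158, 0.7842]
```

Reading: even at its optimum (`p1 = 0.5`) the repeated-colonization model
predicts a sister-aquifer fraction of only `0.544/n` (0.054 at a pool of
ten ancestral species, falling with pool size), and the
observed 11/45 ≈ 0.244 exceeds its 95th randomization percentile whenever
the ancestral pool holds 4 or more species — while phylogenies of such
radiations indicate dozens of ancestors. The single-colonization model
reproduces the observation exactly at an initial colonization probability
of ≈ 0.78 (or the mirror root 0.22).

The same analyses are scriptable from the shell:

```sh
sympatria predict --a1 18 --a2 16 --a3 11 --model single --q 1
sympatria band --a1 18 --a2 16 --a3 11 --model repeated --p 0.5 \
    --pool-range 2:30 --obs-pairs 9 --obs-triplets 2 --seed 1
sympatria synth --a1 18 --a2 16 --a3 11 --model single --p 0.784 --q 1 \
    --seed 7 --out-dir ds/
sympatria detect --tree ds/tree.nwk --metadata ds/metadata.tsv \
    --a1 18 --a2 16 --a3 11
```

`detect` finds maximal all-subterranean same-aquifer clades of size 2–3 in
a newick tree with a tip-metadata TSV (`tip_id`, `aquifer_id`, `habitat`),
and `ltt` writes surface vs subterranean lineage-through-time tables.

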