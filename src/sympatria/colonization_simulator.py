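"""Seeded Monte Carlo implementation of the colonization processes.

This is the randomization program behind the confidence bands: the same two
generative models as :mod:`sympatria.colonization_models`, but simulated —
per aquifer (:func:`simulate_aquifer`, which records the full occupancy
history used by the synthetic-data generator), per niche class in vectorized
batches (:func:`simulate_niche_class`), and per region replicate
(:func:`simulate_region`).  The 5th/95th empirical percentiles of a tally
statistic over the replicates (:func:`percentile_band`) are the confidence
limits used to compare model and observation, and
:func:`min_pool_size_outside_band` scans ancestral-pool sizes for the
smallest one at which the observed sister fraction falls above the band.

Reproducibility: every replicate draws from its own counter-based substream
``SeedSequence(entropy=seed, spawn_key=(replicate,))``, so results are
deterministic under a fixed seed and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .colonization_models import AquiferCensus, ColonizationScenario

Classification = Literal["none", "pair", "triplet"]
Statistic = Literal["pair_fraction", "triplet_fraction", "sister_fraction"]

_CLASS_NAMES = ("none", "pair", "triplet")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Occupant:
    """One filled niche: which species holds it, and how it got there."""

    niche: int
    species: int
    event: int
    origin: Literal["colonization", "in_situ_split"]


@dataclass(frozen=True)
class AquiferOutcome:
    """Final occupancy of one simulated aquifer.

    ``classification`` reflects the largest same-ancestor group: a pair when
    the largest group of occupants sharing an ancestral species (via
    cross-event recolonization or in-situ splits) has size 2, a triplet at
    size 3.
    """

    niches: int
    occupants: tuple[Occupant, ...]
    classification: Classification

    def species_group_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for occ in self.occupants:
            sizes[occ.species] = sizes.get(occ.species, 0) + 1
        return sizes


@dataclass(frozen=True)
class SisterTally:
    """Counts of pair- and triplet-aquifers in one (simulated) region."""

    pair_aquifers: int
    triplet_aquifers: int
    total_aquifers: int

    def __post_init__(self) -> None:
        if self.total_aquifers <= 0:
            raise ValueError("total_aquifers must be positive")
        if self.pair_aquifers + self.triplet_aquifers > self.total_aquifers:
            raise ValueError("pair + triplet aquifers exceed the total")

    @property
    def pair_fraction(self) -> float:
        return self.pair_aquifers / self.total_aquifers

    @property
    def triplet_fraction(self) -> float:
        return self.triplet_aquifers / self.total_aquifers

    @property
    def sister_fraction(self) -> float:
        return (self.pair_aquifers + self.triplet_aquifers) / self.total_aquifers


@dataclass(frozen=True)
class PercentileBand:
    """Empirical percentile band of a tally statistic over replicates."""

    statistic: str
    lower: float
    upper: float
    replicates: int
    mean: float
    sd: float
    levels: tuple[float, float] = (5.0, 95.0)
    seed: int | None = None

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


# ---------------------------------------------------------------------------
# Per-aquifer reference simulator (records full occupancy history)
# ---------------------------------------------------------------------------


def _classify(group_sizes: Iterable[int]) -> Classification:
    largest = max(group_sizes, default=0)
    if largest >= 3:
        return "triplet"
    if largest == 2:
        return "pair"
    return "none"


def simulate_aquifer(
    niches: int, scenario: ColonizationScenario, rng: np.random.Generator
) -> AquiferOutcome:
    """Simulate the colonization history of a single aquifer.

    Repeated model: in each event every still-empty niche opens independently
    with that event's probability and the opened niches receive distinct
    species drawn uniformly without replacement from the ancestral pool.
    Single model: one colonization event with distinct founders, then each
    remaining empty niche (in index order) is filled with probability q by a
    daughter of a uniformly chosen current resident; daughters inherit their
    founder's ancestral species id, so clades are same-species groups.
    """
    if niches not in (1, 2, 3):
        raise ValueError(f"niches must be 1, 2 or 3, got {niches}")
    occupants: list[Occupant] = []
    if scenario.model == "repeated":
        n = scenario.pool_size
        if n < niches:
            raise ValueError(f"pool_size {n} smaller than niche count {niches}")
        empty = list(range(niches))
        for event, p in enumerate(scenario.event_probs):
            opened = [i for i in empty if rng.random() < p]
            if opened:
                species = rng.choice(n, size=len(opened), replace=False)
                for niche, sp in zip(opened, species):
                    occupants.append(Occupant(niche, int(sp), event, "colonization"))
                empty = [i for i in empty if i not in opened]
    else:
        p = scenario.event_probs[0]
        q = scenario.diversification_prob
        empty = []
        for i in range(niches):
            if rng.random() < p:
                occupants.append(Occupant(i, i, 0, "colonization"))
            else:
                empty.append(i)
        for i in empty:
            if not occupants:
                break  # no residents to diversify from
            if rng.random() < q:
                parent = occupants[int(rng.integers(len(occupants)))]
                occupants.append(Occupant(i, parent.species, 0, "in_situ_split"))
    outcome = AquiferOutcome(niches=niches, occupants=tuple(occupants), classification="none")
    return AquiferOutcome(
        niches=niches,
        occupants=outcome.occupants,
        classification=_classify(outcome.species_group_sizes().values()),
    )


# ---------------------------------------------------------------------------
# Vectorized niche-class batches
# ---------------------------------------------------------------------------


def _distinct_within_event(
    r: np.ndarray, priors: list[np.ndarray], same_event: list[np.ndarray]
) -> np.ndarray:
    """Map raw draws from a reduced range onto species ids distinct from the
    same-event colonists already placed (order-statistics insertion)."""
    s = r.copy()
    if not priors:
        return s
    if len(priors) == 1:
        return s + ((same_event[0]) & (s >= priors[0]))
    lo = np.minimum(priors[0], priors[1])
    hi = np.maximum(priors[0], priors[1])
    both = same_event[0] & same_event[1]
    one0 = same_event[0] & ~same_event[1]
    one1 = same_event[1] & ~same_event[0]
    s = s + (both & (s >= lo))
    s = s + (both & (s >= hi))
    s = s + (one0 & (s >= priors[0]))
    s = s + (one1 & (s >= priors[1]))
    return s


def _repeated_batch(
    niches: int, scenario: ColonizationScenario, size: int, rng: np.random.Generator
) -> np.ndarray:
    probs = np.asarray(scenario.event_probs)
    n = scenario.pool_size
    k = niches
    u = rng.random((size, k, len(probs))) < probs
    filled = u.any(axis=2)
    fev = np.where(filled, np.argmax(u, axis=2), -1)

    # species per niche, distinct within an event
    sp = np.zeros((size, k), dtype=np.int64)
    sp[:, 0] = rng.integers(0, n, size)
    if k >= 2:
        same01 = filled[:, 0] & filled[:, 1] & (fev[:, 1] == fev[:, 0])
        r1 = np.floor(rng.random(size) * (n - same01.astype(int))).astype(np.int64)
        sp[:, 1] = _distinct_within_event(r1, [sp[:, 0]], [same01])
    if k == 3:
        same02 = filled[:, 0] & filled[:, 2] & (fev[:, 2] == fev[:, 0])
        same12 = filled[:, 1] & filled[:, 2] & (fev[:, 2] == fev[:, 1])
        t = same02.astype(int) + same12.astype(int)
        r2 = np.floor(rng.random(size) * (n - t)).astype(np.int64)
        sp[:, 2] = _distinct_within_event(r2, [sp[:, 0], sp[:, 1]], [same02, same12])

    # same species in different events => sister group (same event => distinct)
    code = np.zeros(size, dtype=np.int8)
    if k == 2:
        eq01 = filled[:, 0] & filled[:, 1] & (sp[:, 0] == sp[:, 1])
        code[eq01] = 1
    else:
        eq01 = filled[:, 0] & filled[:, 1] & (sp[:, 0] == sp[:, 1])
        eq02 = filled[:, 0] & filled[:, 2] & (sp[:, 0] == sp[:, 2])
        eq12 = filled[:, 1] & filled[:, 2] & (sp[:, 1] == sp[:, 2])
        trip = eq01 & eq02
        code[eq01 | eq02 | eq12] = 1
        code[trip] = 2
    return code


def _single_batch(
    niches: int, scenario: ColonizationScenario, size: int, rng: np.random.Generator
) -> np.ndarray:
    p = scenario.event_probs[0]
    q = scenario.diversification_prob
    k = niches
    founders = rng.random((size, k)) < p
    nf = founders.sum(axis=1)
    code = np.zeros(size, dtype=np.int8)
    if k == 1:
        return code
    fills = rng.random((size, k - 1)) < q  # one q-trial per possibly-empty niche
    if k == 2:
        code[(nf == 1) & fills[:, 0]] = 1
    else:
        code[(nf == 2) & fills[:, 0]] = 1
        one_founder = nf == 1
        code[one_founder & (fills[:, 0] ^ fills[:, 1])] = 1
        code[one_founder & fills[:, 0] & fills[:, 1]] = 2
    return code


def simulate_niche_class(
    niches: int, scenario: ColonizationScenario, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized batch of aquifer outcomes for one niche class.

    Returns an int8 array of classification codes (0 none, 1 pair,
    2 triplet), one per simulated aquifer.  Distribution-identical to
    :func:`simulate_aquifer` run ``size`` times.
    """
    if niches not in (1, 2, 3):
        raise ValueError(f"niches must be 1, 2 or 3, got {niches}")
    if size < 1:
        raise ValueError("size must be >= 1")
    if scenario.model == "repeated":
        if scenario.pool_size < niches:
            raise ValueError(
                f"pool_size {scenario.pool_size} smaller than niche count {niches}"
            )
        return _repeated_batch(niches, scenario, size, rng)
    return _single_batch(niches, scenario, size, rng)


# ---------------------------------------------------------------------------
# Region replication and percentile bands
# ---------------------------------------------------------------------------


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """The deterministic substream used for one region replicate."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(replicate,)))


def simulate_region(
    census: AquiferCensus,
    scenario: ColonizationScenario,
    replicates: int,
    seed: int,
) -> list[SisterTally]:
    """Simulate the whole aquifer census ``replicates`` times.

    Each replicate draws every aquifer of the census independently under the
    scenario and tallies pair- and triplet-aquifers.  One-niche aquifers can
    never hold sisters and are tallied without simulation.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    a = census.a
    tallies: list[SisterTally] = []
    for rep in range(replicates):
        rng = replicate_rng(seed, rep)
        pairs = trips = 0
        for k in (2, 3):
            if a[k] == 0:
                continue
            codes = simulate_niche_class(k, scenario, a[k], rng)
            pairs += int((codes == 1).sum())
            trips += int((codes == 2).sum())
        tallies.append(
            SisterTally(
                pair_aquifers=pairs,
                triplet_aquifers=trips,
                total_aquifers=census.total_aquifers,
            )
        )
    return tallies


def percentile_band(
    tallies: Sequence[SisterTally],
    statistic: Statistic = "sister_fraction",
    levels: tuple[float, float] = (5.0, 95.0),
    seed: int | None = None,
) -> PercentileBand:
    """Empirical percentile band of one tally statistic.

    Percentiles use numpy's linear interpolation between order statistics.
    """
    if len(tallies) == 0:
        raise ValueError("no tallies given")
    if statistic not in ("pair_fraction", "triplet_fraction", "sister_fraction"):
        raise ValueError(f"unknown statistic {statistic!r}")
    values = np.array([getattr(t, statistic) for t in tallies])
    lo, hi = np.percentile(values, levels, method="linear")
    return PercentileBand(
        statistic=statistic,
        lower=float(lo),
        upper=float(hi),
        replicates=len(values),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        levels=(float(levels[0]), float(levels[1])),
        seed=seed,
    )


def min_pool_size_outside_band(
    census: AquiferCensus,
    observed: "SisterTally | float",
    n_range: Sequence[int],
    replicates: int = 10_000,
    seed: int = 0,
    p1: float = 0.5,
    p_last: float = 1.0,
    statistic: Statistic = "sister_fraction",
    levels: tuple[float, float] = (5.0, 95.0),
) -> int | None:
    """Smallest pool size at which the observation exceeds the upper band.

    Scans ``n_range`` (ascending) under the two-event repeated model with
    first-event probability ``p1`` (default 0.5, the maximizing value) and
    final-event probability ``p_last``; the same seed is reused at every pool
    size (common random numbers).  Pool sizes smaller than the largest niche
    class in the census are skipped (a single event can demand that many
    distinct species).  Returns ``None`` when the observation stays inside
    or below the band across the whole range.
    """
    n_range = list(n_range)
    if any(b <= a for a, b in zip(n_range, n_range[1:])):
        raise ValueError("n_range must be strictly ascending")
    k_max = max(k for k, count in census.a.items() if count > 0)
    obs = observed if isinstance(observed, float) else getattr(observed, statistic)
    for n in n_range:
        if n < k_max:
            continue
        scenario = ColonizationScenario.repeated((p1, p_last), pool_size=n)
        tallies = simulate_region(census, scenario, replicates, seed)
        band = percentile_band(tallies, statistic, levels, seed=seed)
        if obs > band.upper:
            return n
    return None
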