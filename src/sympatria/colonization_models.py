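"""Closed-form colonization models for sympatric sister species in isolated aquifers.

Isolated calcrete aquifers behave like replicated islands: each holds at most
three niches, each niche at most one species (competitive exclusion).  Two
generative models explain how an aquifer can end up holding a *sympatric
sister pair* (or triplet) — closest relatives sharing one aquifer:

repeated colonization
    Colonization happens in ``E`` distinct arid periods (events).  In event
    ``j`` every still-empty niche is independently filled with probability
    ``p_j`` by a species drawn uniformly, without replacement within the
    event, from a pool of ``n`` ancestral surface species.  Sisters arise
    only when the *same* ancestral species colonizes the same aquifer in two
    (pair) or three (triplet) different events — same-event colonists are
    distinct species by construction and have had no time to diverge.

single colonization with within-aquifer diversification
    One colonization event fills each niche independently with probability
    ``p`` (founders are distinct species).  Each niche left empty is then
    filled with probability ``q`` by an in-situ daughter species of a
    resident, so sister pairs/triplets are clades that diversified inside
    the aquifer.  Nothing here depends on the pool size.

An aquifer is classified by its *largest* same-ancestor group: a triplet
aquifer is not also a pair aquifer.  Aquifers with a single niche can never
hold sisters.  Region-wide expectations weight the per-niche-class
probabilities by the census counts ``a1, a2, a3`` (aquifers with 1–3
niches) and divide by the total ``A``; aquifers that end up partly or fully
empty still count in the denominator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

MAX_NICHES = 3

ModelName = Literal["repeated", "single"]
Objective = Literal["pairs", "pairs_plus_triplets"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AquiferCensus:
    """Counts of aquifers by niche (= recorded species) number.

    ``aquifers_by_niche_count`` maps niche count (1, 2 or 3) to the number of
    aquifers in that class; ``total_aquifers`` is their sum.  ``aquifer_ids``
    optionally records the identities behind the counts when the census was
    read from a per-aquifer table.
    """

    total_aquifers: int
    aquifers_by_niche_count: Mapping[int, int]
    aquifer_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = dict(self.aquifers_by_niche_count)
        if set(counts) - {1, 2, 3}:
            raise ValueError(f"niche counts must be in {{1,2,3}}, got {sorted(counts)}")
        for k, v in counts.items():
            if v < 0 or int(v) != v:
                raise ValueError(f"count for {k}-niche aquifers must be a non-negative integer")
        counts = {k: int(counts.get(k, 0)) for k in (1, 2, 3)}
        if sum(counts.values()) != self.total_aquifers:
            raise ValueError(
                f"a1+a2+a3 = {sum(counts.values())} != total_aquifers = {self.total_aquifers}"
            )
        if self.total_aquifers <= 0:
            raise ValueError("census must contain at least one aquifer")
        object.__setattr__(self, "aquifers_by_niche_count", counts)

    @classmethod
    def from_counts(cls, a1: int, a2: int, a3: int) -> "AquiferCensus":
        return cls(total_aquifers=a1 + a2 + a3, aquifers_by_niche_count={1: a1, 2: a2, 3: a3})

    @classmethod
    def from_table(cls, table: "pd.DataFrame | str | Path") -> "AquiferCensus":
        """Build a census from a per-aquifer table (TSV path or DataFrame).

        Expected columns: ``aquifer_id`` and ``n_species``.
        """
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, sep="\t", dtype={"aquifer_id": str})
        missing = {"aquifer_id", "n_species"} - set(table.columns)
        if missing:
            raise ValueError(f"census table missing columns: {sorted(missing)}")
        if table["aquifer_id"].duplicated().any():
            dupes = table.loc[table["aquifer_id"].duplicated(), "aquifer_id"].tolist()
            raise ValueError(f"duplicated aquifer ids: {dupes}")
        counts = {k: 0 for k in (1, 2, 3)}
        for ns in table["n_species"]:
            ns = int(ns)
            if ns not in counts:
                raise ValueError(f"n_species must be 1-3, got {ns}")
            counts[ns] += 1
        return cls(
            total_aquifers=len(table),
            aquifers_by_niche_count=counts,
            aquifer_ids=tuple(str(a) for a in table["aquifer_id"]),
        )

    @property
    def a(self) -> dict[int, int]:
        return dict(self.aquifers_by_niche_count)


@dataclass(frozen=True)
class ColonizationScenario:
    """Parameters of one generative model.

    ``event_probs`` are the per-event niche colonization probabilities
    (length 2 or 3 for the repeated model, length 1 for the single model;
    by convention the last event probability is 1 so that every observed
    niche is filled, but any value in [0, 1] is accepted).
    ``diversification_prob`` (q) applies to the single model only,
    ``pool_size`` (n) to the repeated model only.
    """

    model: ModelName
    event_probs: tuple[float, ...]
    diversification_prob: float | None = None
    pool_size: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_probs", tuple(float(p) for p in self.event_probs))
        for p in self.event_probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"event probability {p} outside [0,1]")
        if self.model == "repeated":
            if len(self.event_probs) not in (2, 3):
                raise ValueError("repeated model needs 2 or 3 colonization events")
            if self.pool_size is None or int(self.pool_size) < 1:
                raise ValueError("repeated model needs pool_size >= 1")
            object.__setattr__(self, "pool_size", int(self.pool_size))
            if self.diversification_prob is not None:
                raise ValueError("diversification_prob applies to the single model only")
        elif self.model == "single":
            if len(self.event_probs) != 1:
                raise ValueError("single model has exactly one colonization event")
            q = 1.0 if self.diversification_prob is None else float(self.diversification_prob)
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"diversification probability {q} outside [0,1]")
            object.__setattr__(self, "diversification_prob", q)
            if self.pool_size is not None:
                raise ValueError("single model does not depend on a pool size")
        else:
            raise ValueError(f"unknown model {self.model!r}")

    @classmethod
    def repeated(cls, event_probs: Sequence[float], pool_size: int) -> "ColonizationScenario":
        return cls(model="repeated", event_probs=tuple(event_probs), pool_size=pool_size)

    @classmethod
    def single(cls, p: float, q: float = 1.0) -> "ColonizationScenario":
        return cls(model="single", event_probs=(p,), diversification_prob=q)

    def with_free_p(self, p: float) -> "ColonizationScenario":
        """Replace all early-event probabilities by ``p`` (last event kept)."""
        if self.model == "repeated":
            probs = (float(p),) * (len(self.event_probs) - 1) + (self.event_probs[-1],)
        else:
            probs = (float(p),)
        return replace(self, event_probs=probs)


@dataclass(frozen=True)
class SisterPrediction:
    """Per-niche-class probabilities and region-wide expected fractions."""

    pair_prob_by_niche: Mapping[int, float]
    triplet_prob: float
    expected_pair_fraction: float
    expected_triplet_fraction: float

    @property
    def expected_sister_fraction(self) -> float:
        return self.expected_pair_fraction + self.expected_triplet_fraction


# ---------------------------------------------------------------------------
# Repeated-colonization closed forms
#
# The probability is an exact sum over niche -> first-success-event
# assignments.  A niche is first filled in event e with probability
# p_e * prod_{i<e}(1-p_i) and never filled with prod_e (1-p_e); niches are
# independent.  Given the per-event colonist counts, event colonists are
# independent uniform without-replacement subsets of the pool, so
# cross-event species matches reduce to hypergeometric overlap terms.  With
# at most three niches the largest same-ancestor group is:
#   size 3  iff one colonist per event in three events and all three match
#            (probability 1/n^2);
#   size 2  iff two events overlap: for counts (a, b) the overlap probability
#            is 1 - C(n-a, b)/C(n, b); for counts (1,1,1) exactly-one-match
#            has probability 3(n-1)/n^2.
# ---------------------------------------------------------------------------


def _validate_repeated_args(niches: int, event_probs: Sequence[float], pool_size: int) -> tuple[float, ...]:
    if niches not in (1, 2, 3):
        raise ValueError(f"niches must be 1, 2 or 3, got {niches}")
    probs = tuple(float(p) for p in event_probs)
    if len(probs) not in (2, 3):
        raise ValueError(f"repeated model needs 2 or 3 events, got {len(probs)}")
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"event probability {p} outside [0,1]")
    if pool_size < niches:
        raise ValueError(f"pool_size {pool_size} smaller than niche count {niches}")
    return probs


def _repeated_group_probs(niches: int, probs: tuple[float, ...], n: int) -> tuple[float, float]:
    """Exact (P_pair, P_triplet) for one aquifer under repeated colonization."""
    E = len(probs)
    # P(first filled at event e), P(never filled)
    fill_p = []
    for e in range(E):
        fill_p.append(probs[e] * math.prod(1.0 - probs[i] for i in range(e)))
    never_p = math.prod(1.0 - p for p in probs)
    p_pair = 0.0
    p_trip = 0.0
    for assign in itertools.product(range(-1, E), repeat=niches):
        w = math.prod(never_p if a < 0 else fill_p[a] for a in assign)
        if w == 0.0:
            continue
        counts = sorted(c for e in range(E) if (c := sum(1 for a in assign if a == e)) > 0)
        if len(counts) <= 1:
            continue  # colonists of one event are distinct species: no sisters
        if len(counts) == 2:
            a_, b_ = counts
            overlap = 1.0 - math.comb(n - a_, b_) / math.comb(n, b_)
            p_pair += w * overlap
        else:  # one colonist in each of three events
            p_trip += w / n**2
            p_pair += w * 3.0 * (n - 1) / n**2
    return p_pair, p_trip


def pair_probability_repeated(
    niches: int, event_probs: Sequence[float], pool_size: int
) -> float:
    """P(largest same-ancestor group is a pair) under repeated colonization.

    For two niches and two events this reduces to the textbook form
    ``2 p1 (1-p1) p2 / n``; the general case (three niches and/or three
    events, including mixed paths where the founder is repeated in one later
    event while an unrelated species takes the remaining niche) is evaluated
    by the exact combinatorial sum documented above.
    """
    probs = _validate_repeated_args(niches, event_probs, pool_size)
    if niches == 1:
        return 0.0
    return _repeated_group_probs(niches, probs, pool_size)[0]


def triplet_probability_repeated(event_probs: Sequence[float], pool_size: int) -> float:
    """P(one ancestor colonizes a 3-niche aquifer in three distinct events).

    Identically zero with fewer than three colonization events.
    """
    probs = _validate_repeated_args(3, event_probs, pool_size)
    if len(probs) < 3:
        return 0.0
    return _repeated_group_probs(3, probs, pool_size)[1]


# ---------------------------------------------------------------------------
# Single-colonization (within-aquifer diversification) closed forms
# ---------------------------------------------------------------------------


def _validate_unit(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} = {value} outside [0,1]")
    return value


def pair_probability_single(niches: int, p: float, q: float) -> float:
    """P(largest within-aquifer clade is a pair) under single colonization.

    Two niches: exactly one founder (``2p(1-p)``) whose empty neighbour niche
    is filled in situ (``q``).  Three niches: either two founders with the
    one empty niche filled in situ, or one founder with exactly one of the
    two empty niches filled.  Pool-size free by construction.
    """
    if niches not in (1, 2, 3):
        raise ValueError(f"niches must be 1, 2 or 3, got {niches}")
    p = _validate_unit(p, "p")
    q = _validate_unit(q, "q")
    if niches == 1:
        return 0.0
    if niches == 2:
        return 2.0 * p * (1.0 - p) * q
    return 3.0 * p**2 * (1.0 - p) * q + 3.0 * p * (1.0 - p) ** 2 * 2.0 * q * (1.0 - q)


def triplet_probability_single(p: float, q: float) -> float:
    """P(a single founder plus two in-situ daughters fill all three niches)."""
    p = _validate_unit(p, "p")
    q = _validate_unit(q, "q")
    return 3.0 * p * (1.0 - p) ** 2 * q**2


# ---------------------------------------------------------------------------
# Region-wide expectations and inference
# ---------------------------------------------------------------------------


def expected_sister_fractions(
    census: AquiferCensus, scenario: ColonizationScenario
) -> SisterPrediction:
    """Expected region-wide fractions of pair- and triplet-aquifers.

    Weights per-niche-class probabilities by the census counts and divides
    by the total number of aquifers; single-niche aquifers contribute zero
    and aquifers that end up (partly) empty stay in the denominator.
    """
    a = census.a
    A = census.total_aquifers
    if scenario.model == "repeated":
        n = scenario.pool_size
        pair2 = pair_probability_repeated(2, scenario.event_probs, n)
        pair3 = pair_probability_repeated(3, scenario.event_probs, n)
        trip3 = triplet_probability_repeated(scenario.event_probs, n)
    else:
        p = scenario.event_probs[0]
        q = scenario.diversification_prob
        pair2 = pair_probability_single(2, p, q)
        pair3 = pair_probability_single(3, p, q)
        trip3 = triplet_probability_single(p, q)
    pair_fraction = (a[2] * pair2 + a[3] * pair3) / A
    triplet_fraction = a[3] * trip3 / A
    return SisterPrediction(
        pair_prob_by_niche={2: pair2, 3: pair3},
        triplet_prob=trip3,
        expected_pair_fraction=pair_fraction,
        expected_triplet_fraction=triplet_fraction,
    )


def _objective_fn(census: AquiferCensus, scenario: ColonizationScenario, objective: Objective):
    if objective not in ("pairs", "pairs_plus_triplets"):
        raise ValueError(f"unknown objective {objective!r}")

    def f(p: float) -> float:
        pred = expected_sister_fractions(census, scenario.with_free_p(p))
        if objective == "pairs":
            return pred.expected_pair_fraction
        return pred.expected_sister_fraction

    return f


def maximize_probability(
    census: AquiferCensus,
    scenario: ColonizationScenario,
    objective: Objective = "pairs_plus_triplets",
    grid_step: float = 1e-3,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Maximize the expected sister fraction over the shared early-event p.

    All event probabilities but the last are tied to the free parameter (the
    last stays as given in ``scenario``, conventionally 1).  Deterministic:
    a grid scan at ``grid_step`` followed by bounded Brent refinement; exact
    grid ties resolve to the smaller p (np.argmax keeps the first maximum).

    Returns ``(p_star, value)``.
    """
    f = _objective_fn(census, scenario, objective)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    values = np.array([f(p) for p in grid])
    i = int(np.argmax(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda p: -f(p), bounds=(lo, hi), method="bounded", options={"xatol": tol / 10}
    )
    p_star, value = float(res.x), float(-res.fun)
    if value < values[i]:  # refinement should never lose to the grid
        p_star, value = float(grid[i]), float(values[i])
    return p_star, value


def solve_probability_for_fraction(
    census: AquiferCensus,
    scenario: ColonizationScenario,
    observed_fraction: float,
    objective: Objective = "pairs_plus_triplets",
    grid_step: float = 1e-3,
    tol: float = 1e-9,
) -> list[float]:
    """All p in [0,1] with expected fraction equal to ``observed_fraction``.

    Sign-change bisection (Brent) on a fine grid; roots returned in
    increasing order, empty when the target exceeds the model maximum.
    """
    target = _validate_unit(observed_fraction, "observed_fraction")
    f = _objective_fn(census, scenario, objective)
    g = lambda p: f(p) - target
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    vals = np.array([g(p) for p in grid])
    roots: list[float] = []
    for j, p in enumerate(grid):
        if abs(vals[j]) <= 1e-12:
            roots.append(float(p))
        elif j > 0 and vals[j - 1] * vals[j] < 0 and abs(vals[j - 1]) > 1e-12:
            roots.append(float(brentq(g, grid[j - 1], p, xtol=tol)))
    roots.sort()
    deduped: list[float] = []
    for r in roots:
        if not deduped or r - deduped[-1] > 10 * max(tol, 1e-12):
            deduped.append(r)
    return deduped
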