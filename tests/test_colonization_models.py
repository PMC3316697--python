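"""Closed-form model probabilities, optimizer and root solver."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sympatria import (
    AquiferCensus,
    ColonizationScenario,
    expected_sister_fractions,
    maximize_probability,
    pair_probability_repeated,
    pair_probability_single,
    solve_probability_for_fraction,
    triplet_probability_repeated,
    triplet_probability_single,
)

from oracles import repeated_enumeration, single_enumeration

probs = st.floats(0.0, 1.0)


# ---------------------------------------------------------------------------
# Repeated-colonization probabilities
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "niches,event_probs,n,expected",
    [
        (2, [0.0, 1.0], 10, 0.0),  # nothing colonizes before the final event
        (2, [1.0, 1.0], 10, 0.0),  # all niches filled in event 1, no repeats
        (2, [0.5, 1.0], 10, 0.05),  # 2 p1 (1-p1) p2 / n
        (3, [0.3, 0.8], 7, 6 * 0.3 * 0.7 * 0.8 / 7),  # 6 p1 (1-p1) p2 / n
        (2, [0.5, 0.5, 1.0], 10, 2 * 0.5 * 0.5 * (1 + 0.25) / 10),
    ],
)
def test_pair_probability_repeated_known_values(niches, event_probs, n, expected):
    assert pair_probability_repeated(niches, event_probs, n) == pytest.approx(
        expected, abs=1e-12
    )


@pytest.mark.parametrize(
    "event_probs,n,expected",
    [
        ([0.4, 0.4, 1.0], 5, 6 * 0.4**2 * 0.6**3 / 25),
        ([0.0, 0.0, 1.0], 5, 0.0),  # everything arrives in the final event
        ([0.3, 0.9], 5, 0.0),  # triplets need three colonization events
        ([0.7, 1.0], 3, 0.0),
    ],
)
def test_triplet_probability_repeated_known_values(event_probs, n, expected):
    assert triplet_probability_repeated(event_probs, n) == pytest.approx(
        expected, abs=1e-12
    )


@pytest.mark.parametrize("niches", [2, 3])
@pytest.mark.parametrize("p1", [0.1, 0.3, 0.5, 0.7, 0.9])
@pytest.mark.parametrize("n", [3, 4, 7, 10])
def test_repeated_closed_forms_match_enumeration(niches, p1, n):
    """The exact combinatorial sum agrees with brute-force enumeration of
    every occupancy pattern and ordered species draw, for 2 and 3 events."""
    for event_probs in ([p1, 0.8], [p1, p1, 1.0], [p1, 0.6, 0.9]):
        pair_oracle, trip_oracle = repeated_enumeration(niches, event_probs, n)
        assert pair_probability_repeated(niches, event_probs, n) == pytest.approx(
            pair_oracle, abs=1e-12
        )
        if niches == 3:
            assert triplet_probability_repeated(event_probs, n) == pytest.approx(
                trip_oracle, abs=1e-12
            )


@given(p1=probs, n=st.integers(2, 60))
def test_repeated_pair_symmetric_in_p1(p1, n):
    """With two niches, two events and p2=1, swapping p1 and 1-p1 leaves the
    pair probability unchanged (the single first-event colonist may arrive
    under either label of the occupancy pattern)."""
    a = pair_probability_repeated(2, [p1, 1.0], n)
    b = pair_probability_repeated(2, [1.0 - p1, 1.0], n)
    assert a == pytest.approx(b, abs=1e-12)
    assert 0.0 <= a <= 1.0


@given(p1=st.floats(0.05, 0.95), p2=st.floats(0.0, 1.0))
def test_repeated_pair_strictly_decreasing_in_pool_size(p1, p2):
    """Every sister pair needs a 1/n-type species match, so a larger
    ancestral pool strictly lowers the probability."""
    for niches in (2, 3):
        values = [pair_probability_repeated(niches, [p1, max(p2, 0.1)], n) for n in (3, 5, 9, 30)]
        assert all(a > b for a, b in zip(values, values[1:]))


def test_repeated_rejects_bad_arguments():
    with pytest.raises(ValueError):
        pair_probability_repeated(2, [0.5], 10)  # one event
    with pytest.raises(ValueError):
        pair_probability_repeated(2, [0.5, 0.5, 0.5, 0.5], 10)  # four events
    with pytest.raises(ValueError):
        pair_probability_repeated(3, [0.5, 1.0], 2)  # pool smaller than niches
    with pytest.raises(ValueError):
        pair_probability_repeated(2, [1.5, 1.0], 10)
    with pytest.raises(ValueError):
        pair_probability_repeated(4, [0.5, 1.0], 10)


# ---------------------------------------------------------------------------
# Single-colonization probabilities
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "fn,args,expected",
    [
        (pair_probability_single, (2, 0.78, 1.0), 2 * 0.78 * 0.22),
        (pair_probability_single, (2, 0.3, 0.0), 0.0),  # q=0: never filled in situ
        (pair_probability_single, (3, 1.0, 1.0), 0.0),  # all niches founded
        (triplet_probability_single, (0.78, 1.0), 3 * 0.78 * 0.22**2),
        (triplet_probability_single, (0.0, 1.0), 0.0),  # no founder
        (triplet_probability_single, (1.0, 1.0), 0.0),  # no empty niches
    ],
)
def test_single_model_known_values(fn, args, expected):
    assert fn(*args) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.784, 0.95])
@pytest.mark.parametrize("q", [0.0, 0.25, 0.5, 0.8, 1.0])
def test_single_closed_forms_match_enumeration(p, q):
    for niches in (1, 2, 3):
        pair_oracle, trip_oracle = single_enumeration(niches, p, q)
        assert pair_probability_single(niches, p, q) == pytest.approx(
            pair_oracle, abs=1e-12
        )
    assert triplet_probability_single(p, q) == pytest.approx(trip_oracle, abs=1e-12)


def test_single_model_has_no_pool_size():
    """Single-colonization predictions are pool-free by construction; a pool
    size on the scenario is rejected rather than silently ignored."""
    with pytest.raises(ValueError):
        ColonizationScenario(model="single", event_probs=(0.5,), pool_size=10)


# ---------------------------------------------------------------------------
# Region-wide expectations
# ---------------------------------------------------------------------------


def test_expected_fractions_weight_census(yilgarn_census):
    scenario = ColonizationScenario.repeated((0.5, 1.0), pool_size=8)
    pred = expected_sister_fractions(yilgarn_census, scenario)
    p2 = 2 * 0.5 * 0.5 / 8
    p3 = 6 * 0.5 * 0.5 / 8
    assert pred.expected_pair_fraction == pytest.approx((16 * p2 + 11 * p3) / 45)
    assert pred.expected_triplet_fraction == 0.0
    assert pred.expected_sister_fraction == pred.expected_pair_fraction


def test_expected_fraction_zero_when_nothing_colonizes_early(yilgarn_census):
    scenario = ColonizationScenario.repeated((0.0, 1.0), pool_size=8)
    pred = expected_sister_fractions(yilgarn_census, scenario)
    assert pred.expected_sister_fraction == 0.0


@given(p=probs, q=probs)
def test_expected_fraction_is_convex_combination(yilgarn_census, p, q):
    """Region fractions are census-weighted averages: bounded by the largest
    per-niche-class probability (1-niche aquifers contribute zero)."""
    pred = expected_sister_fractions(
        yilgarn_census, ColonizationScenario.single(p, q=q)
    )
    per_class_max = max(
        pred.pair_prob_by_niche[2], pred.pair_prob_by_niche[3] + pred.triplet_prob
    )
    assert 0.0 <= pred.expected_sister_fraction <= per_class_max + 1e-12


def test_single_fraction_matches_reduced_form(yilgarn_census):
    """With q=1 the sister fraction collapses to (2 a2 + 3 a3) p(1-p) / A."""
    for p in (0.1, 0.42, 0.784):
        pred = expected_sister_fractions(
            yilgarn_census, ColonizationScenario.single(p, q=1.0)
        )
        assert pred.expected_sister_fraction == pytest.approx(
            (2 * 16 + 3 * 11) * p * (1 - p) / 45, abs=1e-12
        )


# ---------------------------------------------------------------------------
# Optimizer and root solver
# ---------------------------------------------------------------------------


def test_maximize_two_event_repeated(yilgarn_census):
    scenario = ColonizationScenario.repeated((0.2, 1.0), pool_size=10)
    p_star, value = maximize_probability(yilgarn_census, scenario, "pairs")
    assert p_star == pytest.approx(0.5, abs=1e-4)
    assert value == pytest.approx((16 * 0.05 + 11 * 0.15) / 45, rel=1e-6)


def test_maximize_single_model_symmetric(yilgarn_census):
    """Under q=1 the combined fraction is proportional to p(1-p), so the
    argmax is exactly one half."""
    scenario = ColonizationScenario.single(0.3, q=1.0)
    p_star, _ = maximize_probability(yilgarn_census, scenario, "pairs_plus_triplets")
    assert p_star == pytest.approx(0.5, abs=1e-4)


def test_solve_single_model_quadratic_roots(yilgarn_census):
    """Independent oracle: with q=1 the target fraction f solves
    c p(1-p) = f with c = (2 a2 + 3 a3)/A, a plain quadratic."""
    target = 11 / 45
    c = (2 * 16 + 3 * 11) / 45
    disc = math.sqrt(1 - 4 * target / c)
    expected = sorted([(1 - disc) / 2, (1 + disc) / 2])
    roots = solve_probability_for_fraction(
        yilgarn_census, ColonizationScenario.single(0.5, q=1.0), target
    )
    assert roots == pytest.approx(expected, abs=1e-8)


def test_solve_boundary_and_unattainable_targets(yilgarn_census):
    scenario = ColonizationScenario.single(0.5, q=1.0)
    assert solve_probability_for_fraction(yilgarn_census, scenario, 0.0) == [0.0, 1.0]
    assert solve_probability_for_fraction(yilgarn_census, scenario, 0.99) == []


# ---------------------------------------------------------------------------
# Census container
# ---------------------------------------------------------------------------


def test_census_validation():
    with pytest.raises(ValueError):
        AquiferCensus(total_aquifers=10, aquifers_by_niche_count={1: 5, 2: 4})  # 9 != 10
    with pytest.raises(ValueError):
        AquiferCensus(total_aquifers=5, aquifers_by_niche_count={1: 2, 4: 3})
    with pytest.raises(ValueError):
        AquiferCensus.from_counts(0, 0, 0)


def test_census_from_table(tmp_path):
    import pandas as pd

    table = pd.DataFrame(
        {"aquifer_id": ["q1", "q2", "q3", "q4"], "n_species": [1, 3, 2, 3]}
    )
    census = AquiferCensus.from_table(table)
    assert census.a == {1: 1, 2: 1, 3: 2}
    assert census.aquifer_ids == ("q1", "q2", "q3", "q4")

    path = tmp_path / "census.tsv"
    table.to_csv(path, sep="\t", index=False)
    assert AquiferCensus.from_table(path).a == census.a

    with pytest.raises(ValueError):
        AquiferCensus.from_table(
            pd.DataFrame({"aquifer_id": ["q1", "q1"], "n_species": [1, 2]})
        )
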