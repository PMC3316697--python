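"""Independent brute-force oracles for the colonization models.

These enumerate the generative processes directly — every niche->event fill
assignment crossed with every ordered without-replacement species draw
(repeated model), or every founder/fill bit pattern (single model) — and
never share code with the closed forms they check.
"""

import itertools
import math


def repeated_enumeration(niches: int, event_probs, pool_size: int):
    """Exact (P_pair, P_triplet) by exhaustive enumeration.

    Enumerates which event (if any) first fills each niche, then all ordered
    tuples of distinct species per event, and classifies each outcome by its
    largest same-species group across events.
    """
    E = len(event_probs)
    n = pool_size
    p_pair = p_trip = 0.0
    for assign in itertools.product(range(-1, E), repeat=niches):
        w = 1.0
        for a in assign:
            if a == -1:
                w *= math.prod(1.0 - p for p in event_probs)
            else:
                w *= event_probs[a] * math.prod(1.0 - event_probs[i] for i in range(a))
        if w == 0.0:
            continue
        counts = [sum(1 for a in assign if a == e) for e in range(E)]
        draws = [list(itertools.permutations(range(n), c)) for c in counts]
        total = math.prod(len(d) for d in draws)
        n_pair = n_trip = 0
        for combo in itertools.product(*draws):
            seen: dict[int, int] = {}
            for event_species in combo:
                for s in event_species:
                    seen[s] = seen.get(s, 0) + 1
            largest = max(seen.values(), default=0)
            if largest == 2:
                n_pair += 1
            elif largest >= 3:
                n_trip += 1
        p_pair += w * n_pair / total
        p_trip += w * n_trip / total
    return p_pair, p_trip


def single_enumeration(niches: int, p: float, q: float):
    """Exact (P_pair, P_triplet) over founder and in-situ-fill bit patterns.

    With at most one founder clade receiving all fills (single founder) or a
    single fillable niche (two founders), the clade sizes do not depend on
    which resident is chosen as parent, so enumerating bits suffices.
    """
    p_pair = p_trip = 0.0
    for founders in itertools.product((0, 1), repeat=niches):
        f = sum(founders)
        w_f = p**f * (1.0 - p) ** (niches - f)
        empties = niches - f
        if f == 0 or empties == 0:
            continue  # nothing fillable or nothing empty: largest clade is 1
        for fills in itertools.product((0, 1), repeat=empties):
            s = sum(fills)
            w = w_f * q**s * (1.0 - q) ** (empties - s)
            if f == 1:
                largest = 1 + s
            else:  # f == 2, one empty niche: the fill joins one founder clade
                largest = 2 if s else 1
            if largest == 2:
                p_pair += w
            elif largest >= 3:
                p_trip += w
    return p_pair, p_trip
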