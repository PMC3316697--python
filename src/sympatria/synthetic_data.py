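"""Synthetic annotated phylogenies with known colonization ground truth.

Emulates the study design end to end so detection, tallying and inference
can be exercised without any molecular data: a pure-birth (Yule) surface
radiation, onto which subterranean tips are grafted according to simulated
colonization histories of an aquifer census under either model.  The
resulting dataset records the full ground truth — per-aquifer outcomes, the
true parameters and the planted sister tally — and is constructed so that
:func:`sympatria.phylogeny_sisters.find_sympatric_sister_clades` recovers
the planted clades exactly:

* each same-ancestor group of one aquifer is attached as a single
  monophyletic subtree, its stem anchored on a surface branch at the age of
  the group's oldest colonization event; later colonizations (repeated
  model) or in-situ splits (single model) become its internal nodes.  The
  surface ancestor between colonization events is treated as unsampled —
  the aridification that drove the beetles underground is assumed to have
  removed it, which is also what makes real sister groups monophyletic;
* grafting inserts attachment nodes on surface branches and never removes
  surface tips, so every surface branch keeps at least one surface
  descendant and no spurious all-subterranean clade can arise.

Donor branches are drawn uniformly among surface branches alive at the
attachment age, independently per group: the same surface lineage may found
niches in several aquifers, exactly as in the generative model where every
aquifer samples the same ancestral pool.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .colonization_models import (
    AquiferCensus,
    ColonizationScenario,
    solve_probability_for_fraction,
)
from .colonization_simulator import (
    AquiferOutcome,
    SisterTally,
    _classify,
    simulate_aquifer,
)
from .phylogeny_sisters import AnnotatedTree, annotate_tree

DEFAULT_EVENT_AGES = {1: (7.0,), 2: (7.0, 3.5), 3: (7.0, 5.0, 3.5)}


@dataclass(frozen=True)
class GroupTruth:
    """One planted same-ancestor group (singleton, pair or triplet)."""

    aquifer_id: str
    species: int
    tip_ids: tuple[str, ...]
    colonization_age: float
    split_ages: tuple[float, ...]  # descending; empty for singletons

    @property
    def size(self) -> int:
        return len(self.tip_ids)


@dataclass
class SyntheticDataset:
    """An annotated tree plus the ground truth that generated it."""

    annotated_tree: AnnotatedTree
    metadata: pd.DataFrame
    census: AquiferCensus
    scenario: ColonizationScenario
    event_ages: tuple[float, ...]
    seed: int
    outcomes: dict[str, AquiferOutcome]
    groups: tuple[GroupTruth, ...]
    true_tally: SisterTally

    def write(self, outdir: "str | Path") -> dict[str, Path]:
        """Emit newick + metadata TSV + ground-truth JSON into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": outdir / "tree.nwk",
            "metadata": outdir / "metadata.tsv",
            "truth": outdir / "truth.json",
        }
        self.annotated_tree.write_newick(paths["tree"])
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        truth = {
            "seed": self.seed,
            "scenario": {
                "model": self.scenario.model,
                "event_probs": list(self.scenario.event_probs),
                "diversification_prob": self.scenario.diversification_prob,
                "pool_size": self.scenario.pool_size,
            },
            "event_ages": list(self.event_ages),
            "census": {
                "total_aquifers": self.census.total_aquifers,
                "aquifers_by_niche_count": {
                    str(k): v for k, v in self.census.a.items()
                },
            },
            "true_tally": {
                "pair_aquifers": self.true_tally.pair_aquifers,
                "triplet_aquifers": self.true_tally.triplet_aquifers,
                "total_aquifers": self.true_tally.total_aquifers,
            },
            "classifications": {
                aq: out.classification for aq, out in self.outcomes.items()
            },
            "groups": [
                {
                    "aquifer_id": g.aquifer_id,
                    "species": g.species,
                    "tip_ids": list(g.tip_ids),
                    "colonization_age": g.colonization_age,
                    "split_ages": list(g.split_ages),
                }
                for g in self.groups
            ],
        }
        paths["truth"].write_text(json.dumps(truth, indent=1))
        return paths


# ---------------------------------------------------------------------------
# Yule surface radiation
# ---------------------------------------------------------------------------


def generate_surface_tree(
    n_tips: int,
    birth_rate: float,
    rng: "int | np.random.Generator",
    label_format: str = "surf{:03d}",
) -> dendropy.Tree:
    """Simulate an ultrametric pure-birth tree with ``n_tips`` extant tips.

    Waiting times while k lineages exist are Exponential(k * birth_rate);
    the simulation starts at the root split (two lineages) and, after the
    n-th lineage appears, runs one final Exponential(n * birth_rate) stretch
    before the present.  The expected root age is therefore
    ``sum_{k=2..n} 1/(k * birth_rate)``.  Branch lengths are in the inverse
    units of ``birth_rate`` (million years for a per-My rate).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not birth_rate > 0:
        raise ValueError("birth_rate must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    tree = dendropy.Tree()
    root = tree.seed_node
    # pending = lineages not yet split, with the depth at which they started
    pending: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        pending.append((child, 0.0))
    t = 0.0
    while len(pending) < n_tips:
        t += rng.exponential(1.0 / (len(pending) * birth_rate))
        i = int(rng.integers(len(pending)))
        node, start = pending.pop(i)
        node.edge.length = t - start
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            pending.append((child, t))
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    tns = dendropy.TaxonNamespace()
    for j, (node, start) in enumerate(pending):
        node.edge.length = t - start
        node.taxon = tns.new_taxon(label=label_format.format(j))
    tree.taxon_namespace = tns
    root.edge.length = None
    for node in tree.postorder_node_iter():
        node.age = 0.0 if node.is_leaf() else max(
            c.age + c.edge.length for c in node.child_nodes()
        )
        node.is_surface = True
    return tree


# ---------------------------------------------------------------------------
# Grafting colonization histories onto the surface tree
# ---------------------------------------------------------------------------


def _groups_from_outcome(
    aquifer_id: str,
    outcome: AquiferOutcome,
    event_ages: Sequence[float],
    rng: np.random.Generator,
) -> list[GroupTruth]:
    """Split an aquifer outcome into same-ancestor groups with graft ages."""
    by_species: dict[int, list] = {}
    for occ in outcome.occupants:
        by_species.setdefault(occ.species, []).append(occ)
    groups = []
    for species, occs in sorted(by_species.items()):
        if occs[0].origin == "colonization" and all(
            o.origin == "colonization" for o in occs
        ) and len({o.event for o in occs}) == len(occs) and len(occs) > 1:
            # repeated colonizations: splits at the later event ages
            ages = sorted((event_ages[o.event] for o in occs), reverse=True)
            col_age, split_ages = ages[0], tuple(ages[1:])
        else:
            # single-model clade (or singleton of either model)
            col_age = event_ages[min(o.event for o in occs)]
            split_ages = tuple(
                sorted((rng.uniform(0.0, col_age) for _ in occs[1:]), reverse=True)
            )
        tip_ids = tuple(
            f"{aquifer_id}s{occ.niche}" for occ in sorted(occs, key=lambda o: o.niche)
        )
        groups.append(GroupTruth(aquifer_id, species, tip_ids, col_age, split_ages))
    return groups


def _build_group_subtree(group: GroupTruth) -> dendropy.Node:
    """Caterpillar subtree of the group's tips with splits at the given ages.

    The returned node's age equals the group's crown (oldest split) for
    multi-tip groups, or 0 for a singleton tip; the caller supplies the stem
    up to the attachment age.
    """
    nodes = []
    for tip_id in group.tip_ids:
        leaf = dendropy.Node()
        leaf.age = 0.0
        leaf.is_surface = False
        leaf._pending_label = tip_id
        nodes.append(leaf)
    current = nodes[-1]
    for split_age, tip in zip(sorted(group.split_ages), reversed(nodes[:-1])):
        joint = dendropy.Node()
        joint.age = split_age
        joint.is_surface = False
        joint.add_child(current)
        current.edge.length = joint.age - current.age
        joint.add_child(tip)
        tip.edge.length = joint.age - tip.age
        current = joint
    return current


def _graft(tree: dendropy.Tree, group: GroupTruth, rng: np.random.Generator) -> None:
    """Attach a group subtree on a uniformly chosen surface branch alive at
    the group's colonization age."""
    t = group.colonization_age
    candidates = [
        node
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
        and node.is_surface
        and node.age <= t < node.parent_node.age
    ]
    if not candidates:
        raise ValueError(
            f"no surface lineage alive at age {t}; event ages exceed the tree depth"
        )
    donor = candidates[int(rng.integers(len(candidates)))]
    parent = donor.parent_node
    attach = dendropy.Node()
    attach.age = t
    attach.is_surface = True
    parent.remove_child(donor)
    parent.add_child(attach)
    attach.edge.length = parent.age - t
    attach.add_child(donor)
    donor.edge.length = t - donor.age
    subtree = _build_group_subtree(group)
    attach.add_child(subtree)
    subtree.edge.length = t - subtree.age


def generate_colonization_dataset(
    census: AquiferCensus,
    scenario: ColonizationScenario,
    event_ages: "Sequence[float] | None" = None,
    seed: int = 0,
    surface_tips: int = 60,
    birth_rate: float = 0.4,
    max_tree_draws: int = 100,
) -> SyntheticDataset:
    """Generate a full annotated dataset with known ground truth.

    Simulates every aquifer of the census under ``scenario``, generates a
    Yule surface radiation (redrawn until its root age exceeds the oldest
    event age, bounded by ``max_tree_draws``), and grafts each same-ancestor
    group as one subtree.  ``event_ages`` (My, strictly decreasing, one per
    colonization event) default to 7/3.5 for two events, 7/5/3.5 for three
    and 7 for the single model, inside the radiation window of the system
    being emulated.
    """
    if event_ages is None:
        event_ages = DEFAULT_EVENT_AGES[len(scenario.event_probs)]
    event_ages = tuple(float(a) for a in event_ages)
    if len(event_ages) != len(scenario.event_probs):
        raise ValueError("need one event age per colonization event")
    if any(b >= a for a, b in zip(event_ages, event_ages[1:])) or event_ages[-1] <= 0:
        raise ValueError("event ages must be strictly decreasing and positive")

    ss = np.random.SeedSequence(seed)
    rng_outcomes, rng_tree, rng_graft = map(np.random.default_rng, ss.spawn(3))

    # per-aquifer colonization histories
    outcomes: dict[str, AquiferOutcome] = {}
    idx = 0
    for k in (1, 2, 3):
        for _ in range(census.a[k]):
            idx += 1
            outcomes[f"A{idx:03d}"] = simulate_aquifer(k, scenario, rng_outcomes)

    # surface radiation, conditioned on being older than the first event
    tree = None
    for _ in range(max_tree_draws):
        candidate = generate_surface_tree(surface_tips, birth_rate, rng_tree)
        if candidate.seed_node.age > event_ages[0]:
            tree = candidate
            break
    if tree is None:
        raise ValueError(
            f"no surface tree deeper than the oldest event age {event_ages[0]} "
            f"in {max_tree_draws} draws; raise surface_tips or lower birth_rate"
        )

    groups: list[GroupTruth] = []
    for aquifer_id, outcome in outcomes.items():
        groups.extend(_groups_from_outcome(aquifer_id, outcome, event_ages, rng_graft))
    # oldest attachments first so younger grafts see the updated branches
    for group in sorted(groups, key=lambda g: (-g.colonization_age, g.aquifer_id)):
        _graft(tree, group, rng_graft)

    # register grafted tips in the taxon namespace
    tns = tree.taxon_namespace
    for node in tree.leaf_node_iter():
        label = getattr(node, "_pending_label", None)
        if label is not None:
            node.taxon = tns.new_taxon(label=label)

    rows = []
    for leaf in tree.leaf_node_iter():
        sub = not leaf.is_surface
        rows.append(
            {
                "tip_id": leaf.taxon.label,
                "aquifer_id": leaf.taxon.label.rsplit("s", 1)[0] if sub else "",
                "habitat": "subterranean" if sub else "surface",
            }
        )
    metadata = pd.DataFrame(rows, columns=["tip_id", "aquifer_id", "habitat"])

    pair_count = sum(1 for o in outcomes.values() if o.classification == "pair")
    trip_count = sum(1 for o in outcomes.values() if o.classification == "triplet")
    true_tally = SisterTally(
        pair_aquifers=pair_count,
        triplet_aquifers=trip_count,
        total_aquifers=census.total_aquifers,
    )

    annotated = annotate_tree(tree, metadata)
    return SyntheticDataset(
        annotated_tree=annotated,
        metadata=metadata,
        census=census,
        scenario=scenario,
        event_ages=event_ages,
        seed=seed,
        outcomes=outcomes,
        groups=tuple(groups),
        true_tally=true_tally,
    )


# ---------------------------------------------------------------------------
# Closing the loop: detect -> tally -> solve
# ---------------------------------------------------------------------------


def recover_parameters(
    dataset: SyntheticDataset, model: "str | None" = None
) -> list[float]:
    """Estimate the colonization probability back from a synthetic dataset.

    Runs sister-clade detection and tallying on the dataset's tree, then
    solves the named model family (default: the generating family, with
    q = 1 and final event probability 1) for the observed sister fraction.
    Returns the roots in increasing order; an empty list (with a warning)
    means the observed fraction exceeds the model maximum.
    """
    from .phylogeny_sisters import find_sympatric_sister_clades, tally_observed

    model = model or dataset.scenario.model
    clades = find_sympatric_sister_clades(dataset.annotated_tree)
    if clades:
        tally = tally_observed(clades, dataset.census)
        fraction = tally.sister_fraction
    else:
        fraction = 0.0
    if model == "single":
        family = ColonizationScenario.single(0.5, q=1.0)
    else:
        family = ColonizationScenario.repeated(
            (0.5,) * (len(dataset.scenario.event_probs) - 1) + (1.0,),
            pool_size=dataset.scenario.pool_size,
        )
    roots = solve_probability_for_fraction(dataset.census, family, fraction)
    if not roots:
        warnings.warn(
            f"observed sister fraction {fraction:.4f} exceeds the {model} model "
            "maximum; no colonization probability reproduces it",
            stacklevel=2,
        )
    return roots
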