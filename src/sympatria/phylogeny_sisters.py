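"""Sister-clade detection and lineage-through-time curves on annotated trees.

The observed side of the speciation test: a rooted, time-calibrated
phylogeny whose tips carry an aquifer id and a habitat class (``surface`` or
``subterranean``).  A *sympatric sister clade* is a maximal monophyletic
group of 2 or 3 tips that are all subterranean and all from one aquifer —
the groups the colonization models predict.  Lineage-through-time curves
split the lineage count at each past age into surface and subterranean
classes, placing the (unobserved) colonization of the subterranean habitat
at a configurable fraction along the stem branch of each maximal
subterranean clade.

Branch lengths are in million years; ages are measured back from the
present (tip age 0 on an ultrametric tree).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .colonization_models import AquiferCensus
from .colonization_simulator import SisterTally

HABITATS = ("surface", "subterranean")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class AnnotatedTree:
    """A rooted dendropy tree with per-tip aquifer/habitat annotations.

    Leaf nodes carry ``aquifer_id`` (None for surface tips) and ``habitat``;
    internal nodes carry ``support`` (posterior probability or None) and all
    nodes carry ``age`` (max distance to a descendant tip).
    """

    tree: dendropy.Tree

    @property
    def depth(self) -> float:
        return float(self.tree.seed_node.age)

    def leaf_nodes(self):
        return self.tree.leaf_node_iter()

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tip_id": leaf.taxon.label,
                "aquifer_id": leaf.aquifer_id if leaf.aquifer_id is not None else "",
                "habitat": leaf.habitat,
            }
            for leaf in self.leaf_nodes()
        ]
        return pd.DataFrame(rows, columns=["tip_id", "aquifer_id", "habitat"])

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = []
        for leaf in self.leaf_nodes():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths.append(d)
        depths = np.asarray(depths)
        span = depths.max() - depths.min()
        return bool(span <= rel_tol * max(depths.max(), 1e-300))

    def write_newick(self, path: "str | Path | None" = None) -> str:
        text = self.tree.as_string(schema="newick", suppress_rooting=True)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class SisterClade:
    """A maximal monophyletic group of 2-3 subterranean tips of one aquifer."""

    aquifer_id: str
    tip_ids: tuple[str, ...]
    crown_age: float
    stem_support: float | None

    @property
    def size(self) -> int:
        return len(self.tip_ids)


# ---------------------------------------------------------------------------
# Reading / annotating
# ---------------------------------------------------------------------------


def _set_node_ages(tree: dendropy.Tree) -> None:
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.age = 0.0
        else:
            node.age = max(c.age + (c.edge.length or 0.0) for c in node.child_nodes())


def _parse_support(label: "str | None") -> float | None:
    if label is None:
        return None
    try:
        value = float(label)
    except ValueError:
        return None
    return value if 0.0 <= value <= 1.0 else None


def annotate_tree(tree: dendropy.Tree, metadata: pd.DataFrame) -> AnnotatedTree:
    """Attach aquifer/habitat labels from a metadata table onto a tree.

    ``metadata`` needs columns ``tip_id``, ``aquifer_id``, ``habitat``; every
    tree tip must appear exactly once and vice versa.
    """
    missing_cols = {"tip_id", "aquifer_id", "habitat"} - set(metadata.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    if metadata["tip_id"].duplicated().any():
        dupes = metadata.loc[metadata["tip_id"].duplicated(), "tip_id"].tolist()
        raise ValueError(f"duplicated tip ids in metadata: {dupes}")
    by_tip = metadata.set_index("tip_id")

    tip_labels = set()
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else None
        if label is None:
            raise ValueError("tree contains an unlabelled tip")
        tip_labels.add(label)
        if label not in by_tip.index:
            raise ValueError(f"tip {label!r} missing from metadata")
        row = by_tip.loc[label]
        habitat = str(row["habitat"])
        if habitat not in HABITATS:
            raise ValueError(f"tip {label!r}: habitat must be one of {HABITATS}, got {habitat!r}")
        aquifer = row["aquifer_id"]
        aquifer = None if pd.isna(aquifer) or str(aquifer) == "" else str(aquifer)
        if habitat == "subterranean" and aquifer is None:
            raise ValueError(f"subterranean tip {label!r} has no aquifer id")
        leaf.habitat = habitat
        leaf.aquifer_id = aquifer
    unknown = set(by_tip.index) - tip_labels
    if unknown:
        raise ValueError(f"metadata rows for unknown tips: {sorted(unknown)}")

    for node in tree.preorder_node_iter():
        if node.edge.length is not None and node.edge.length < 0:
            raise ValueError("negative branch length in tree")
        if not node.is_leaf():
            node.support = _parse_support(node.label)
    _set_node_ages(tree)
    return AnnotatedTree(tree=tree)


def read_annotated_tree(
    newick: "str | Path", metadata: "pd.DataFrame | str | Path"
) -> AnnotatedTree:
    """Read a newick tree (text or file path) plus a tip-metadata table (TSV).

    Internal node labels that parse as numbers in [0, 1] are kept as node
    supports.
    """
    if isinstance(newick, Path) or (isinstance(newick, str) and "(" not in newick):
        newick = Path(newick).read_text()
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        rooting="default-rooted",
    )
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, sep="\t", dtype=str, keep_default_na=False)
    return annotate_tree(tree, metadata)


# ---------------------------------------------------------------------------
# Sister-clade detection
# ---------------------------------------------------------------------------


def _uniform_subterranean_aquifer(node) -> "tuple[str | None, int]":
    """(aquifer id if every descendant tip is subterranean and shares it,
    else None; number of descendant tips).  Requires children annotated."""
    if node.is_leaf():
        aq = node.aquifer_id if node.habitat == "subterranean" else None
        node._ss_aquifer, node._ss_ntips = aq, 1
        return aq, 1
    aqs = {c._ss_aquifer for c in node.child_nodes()}
    ntips = sum(c._ss_ntips for c in node.child_nodes())
    aq = aqs.pop() if len(aqs) == 1 and None not in aqs else None
    node._ss_aquifer, node._ss_ntips = aq, ntips
    return aq, ntips


def find_sympatric_sister_clades(
    annotated: AnnotatedTree, min_support: float = 0.0
) -> list[SisterClade]:
    """Detect maximal same-aquifer all-subterranean clades of size 2-3.

    A post-order scan marks every node whose descendant tips are all
    subterranean and share one aquifer; only *maximal* such nodes (whose
    parent does not qualify) are reported, so a triplet is never also
    counted as a nested pair.  A maximal clade with more than three tips
    violates the niche model and raises.  When node supports are present a
    clade whose own (stem) support is below ``min_support`` is dropped.
    """
    tree = annotated.tree
    clades: list[SisterClade] = []
    for node in tree.postorder_node_iter():
        _uniform_subterranean_aquifer(node)
    for node in tree.postorder_node_iter():
        if node._ss_aquifer is None or node._ss_ntips < 2:
            continue
        parent = node.parent_node
        if parent is not None and parent._ss_aquifer is not None:
            continue  # not maximal
        if node._ss_ntips > 3:
            raise ValueError(
                f"aquifer {node._ss_aquifer!r} has a same-aquifer subterranean clade of "
                f"{node._ss_ntips} tips; the niche model allows at most 3 species per aquifer"
            )
        support = getattr(node, "support", None)
        if support is not None and support < min_support:
            continue
        tips = tuple(sorted(leaf.taxon.label for leaf in node.leaf_iter()))
        clades.append(
            SisterClade(
                aquifer_id=node._ss_aquifer,
                tip_ids=tips,
                crown_age=float(node.age),
                stem_support=support,
            )
        )
    clades.sort(key=lambda c: (c.aquifer_id, c.tip_ids))
    return clades


def tally_observed(clades: Sequence[SisterClade], census: AquiferCensus) -> SisterTally:
    """Tally pair- and triplet-aquifers from detected clades over a census.

    An aquifer is a triplet-aquifer when its largest clade has 3 tips, a
    pair-aquifer when it has 2; more than three sister tips in one aquifer
    violate the niche model and raise.
    """
    by_aquifer: dict[str, list[SisterClade]] = {}
    for clade in clades:
        by_aquifer.setdefault(clade.aquifer_id, []).append(clade)
    if census.aquifer_ids is not None:
        unknown = set(by_aquifer) - set(census.aquifer_ids)
        if unknown:
            raise ValueError(f"clades reference aquifers outside the census: {sorted(unknown)}")
    pairs = trips = 0
    for aquifer, group in by_aquifer.items():
        total_tips = sum(c.size for c in group)
        if total_tips > 3:
            raise ValueError(
                f"aquifer {aquifer!r} holds {total_tips} sister tips; at most 3 allowed"
            )
        largest = max(c.size for c in group)
        if largest == 3:
            trips += 1
        else:
            pairs += 1
    return SisterTally(
        pair_aquifers=pairs, triplet_aquifers=trips, total_aquifers=census.total_aquifers
    )


# ---------------------------------------------------------------------------
# Lineage-through-time curves
# ---------------------------------------------------------------------------


def ltt_counts(
    annotated: AnnotatedTree,
    ages: Sequence[float],
    colonization_fraction: float = 0.5,
) -> pd.DataFrame:
    """Surface and subterranean lineage counts at each grid age.

    Every maximal all-subterranean clade (including single subterranean
    tips) is assumed to have colonized the subterranean habitat somewhere on
    its stem branch; ``colonization_fraction`` places that point as a
    fraction of the stem measured from its older (rootward) end, so 0 dates
    the colonization at the stem's origin and 1 at the clade's crown.  The
    stem branch counts as surface above the colonization point and as
    subterranean below it; all branches inside the clade are subterranean,
    everything else is surface.  At each age the two counts sum to the total
    number of lineages alive.

    Requires an ultrametric tree (tip ages equal within 1e-6 of tree depth).
    """
    if not 0.0 <= colonization_fraction <= 1.0:
        raise ValueError("colonization_fraction must be in [0,1]")
    if not annotated.is_ultrametric():
        raise ValueError("LTT curves require an ultrametric tree")
    tree = annotated.tree

    # maximal all-subterranean clades (habitat only; aquifers may differ)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._all_sub = node.habitat == "subterranean"
        else:
            node._all_sub = all(c._all_sub for c in node.child_nodes())

    # classified intervals (lo_age, hi_age, is_subterranean) per branch
    intervals: list[tuple[float, float, bool]] = []
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        lo, hi = float(node.age), float(parent.age)
        if hi <= lo:
            continue  # zero-length branch, never counted
        if not node._all_sub:
            intervals.append((lo, hi, False))
        elif parent._all_sub:
            intervals.append((lo, hi, True))  # inside a subterranean clade
        else:  # stem branch: colonization point splits it
            col_age = hi - colonization_fraction * (hi - lo)
            if col_age < hi:
                intervals.append((col_age, hi, False))
            if lo < col_age:
                intervals.append((lo, col_age, True))

    ages = np.asarray(list(ages), dtype=float)
    surface = np.zeros(len(ages), dtype=int)
    subterranean = np.zeros(len(ages), dtype=int)
    for lo, hi, is_sub in intervals:
        alive = (ages >= lo) & (ages < hi)
        if is_sub:
            subterranean += alive
        else:
            surface += alive
    return pd.DataFrame(
        {"age": ages, "surface_count": surface, "subterranean_count": subterranean}
    )
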