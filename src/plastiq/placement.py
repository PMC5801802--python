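"""Dollo placement of gene-inactivation events on a species tree.

Under a Dollo model a functional gene is lost at most once per lineage
and never regained, so an event shared by a set of species maps to the
stem branch of their most recent common ancestor.  When the MRCA
subtree contains species that lack the event, the placement is flagged
inconsistent (homoplasy or undetected loss) rather than silently split
into multiple origins.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

from .shared import SharedEvent
from .pseudogene import InactivatingMutation


@dataclass
class PlacedEvent:
    event: SharedEvent | InactivatingMutation
    branch: str  # stem branch, named by its child node
    consistent: bool
    note: str = ""

    @property
    def gene(self) -> str:
        return self.event.gene

    @property
    def kind(self) -> str:
        return self.event.kind

    @property
    def species_set(self) -> frozenset[str]:
        if isinstance(self.event, SharedEvent):
            return self.event.species_set
        return frozenset({self.event.species})


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return "+".join(leaves)


def ensure_branch_names(tree: dendropy.Tree) -> None:
    """Name every unnamed internal node by its sorted leaf set."""
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label and (node.taxon is None or not node.taxon.label):
            node.label = _node_name(node)


def place_event(
    event: SharedEvent | InactivatingMutation,
    tree: dendropy.Tree,
) -> PlacedEvent:
    """Place one event on the stem branch of its species set's MRCA."""
    tree.is_rooted = True
    if isinstance(event, SharedEvent):
        species = sorted(event.species_set)
    else:
        species = [event.species]
    taxa = {l.taxon.label for l in tree.leaf_node_iter()}
    for s in species:
        if s not in taxa:
            raise ValueError(f"species {s!r} is not a leaf of the tree")
    if len(species) == 1:
        leaf = next(
            l for l in tree.leaf_node_iter() if l.taxon.label == species[0]
        )
        return PlacedEvent(event=event, branch=_node_name(leaf), consistent=True)
    mrca = tree.mrca(taxon_labels=species)
    subtree = sorted(l.taxon.label for l in mrca.leaf_iter())
    consistent = subtree == species
    note = "" if consistent else (
        "subtree also contains " + ", ".join(sorted(set(subtree) - set(species)))
    )
    return PlacedEvent(
        event=event, branch=_node_name(mrca), consistent=consistent, note=note
    )


def decorate_tree(
    placements: list[PlacedEvent],
    tree: dendropy.Tree,
) -> tuple[str, pd.DataFrame]:
    """Annotate tree branches with their events.

    Returns a Newick string whose branches carry comment labels listing
    the placed gene names (homoplastic events marked with '*'), and a
    table with one row per placement.
    """
    ensure_branch_names(tree)
    by_branch: dict[str, list[PlacedEvent]] = {}
    rows = []
    for p in placements:
        by_branch.setdefault(p.branch, []).append(p)
        rows.append(
            {
                "branch": p.branch,
                "gene": p.gene,
                "kind": p.kind,
                "consistent": p.consistent,
                "species": ",".join(sorted(p.species_set)),
                "note": p.note,
            }
        )
    annotated = tree.clone(depth=1)
    ensure_branch_names(annotated)
    for node in annotated.preorder_node_iter():
        name = _node_name(node)
        events_here = by_branch.get(name, [])
        if events_here:
            label = ",".join(
                p.gene + ("" if p.consistent else "*") for p in events_here
            )
            node.annotations.add_new("events", label)
    newick = annotated.as_string(
        schema="newick", suppress_annotations=False
    ).strip()
    table = pd.DataFrame(
        rows, columns=["branch", "gene", "kind", "consistent", "species", "note"]
    )
    return newick, table
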