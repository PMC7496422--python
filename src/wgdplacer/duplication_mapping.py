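"""PUG-style mapping of gene-tree duplications onto a species tree.

A duplication node is a gene-tree internal node two of whose child subtrees
share at least one taxon. Each duplication node yields exactly one event
(pair-level counting would inflate counts quadratically), which is mapped to
the species-tree MRCA of all taxa below the node. Tallies count events whose
duplication-node bootstrap support passes a threshold; a node lacking a
support value fails the filter unless filtering is disabled (conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .trees_io import GeneTree, SpeciesTree, TreeValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DuplicationEvent:
    orthogroup_id: str | None
    node_index: int                 # preorder index of the node in its gene tree
    support: float | None
    left_taxa: frozenset[str]
    right_taxa: frozenset[str]
    all_taxa: frozenset[str]        # union over all child subtrees of the node
    child_supports: tuple[float | None, ...] = ()
    species_node_id: str | None = None

    @property
    def shared_taxa(self) -> frozenset[str]:
        return self.left_taxa & self.right_taxa


@dataclass
class DuplicationTally:
    """Per species-node counts of support-passing duplication events."""

    counts: dict[str, int]
    min_support: float | None
    n_events_considered: int = 0
    n_events_counted: int = 0

    def argmax(self) -> str:
        return max(sorted(self.counts), key=lambda k: self.counts[k])


def find_duplication_nodes(gt: GeneTree) -> list[DuplicationEvent]:
    """Every internal node whose child subtrees share a taxon, in preorder.

    For a polytomy the node counts once if any two children share a taxon;
    the recorded left/right sets are the first sharing pair in child order.
    """
    root_children = gt.tree.seed_node.child_nodes()
    if len(root_children) > 2:
        raise TreeValidationError(
            "basal polytomy: tree is effectively unrooted; "
            "root it with an outgroup first"
        )
    events = []
    for idx, nd in enumerate(gt.tree.preorder_node_iter()):
        if nd.is_leaf():
            continue
        children = nd.child_nodes()
        child_taxa = [gt.node_taxa(ch) for ch in children]
        pair = None
        for i in range(len(children)):
            for j in range(i + 1, len(children)):
                if child_taxa[i] & child_taxa[j]:
                    pair = (i, j)
                    break
            if pair:
                break
        if pair is None:
            continue
        i, j = pair
        events.append(DuplicationEvent(
            orthogroup_id=gt.orthogroup_id,
            node_index=idx,
            support=getattr(nd.edge, "support", None),
            left_taxa=child_taxa[i],
            right_taxa=child_taxa[j],
            all_taxa=frozenset().union(*child_taxa),
            child_supports=tuple(getattr(ch.edge, "support", None)
                                 for ch in children),
        ))
    return events


def map_to_species_tree(ev: DuplicationEvent,
                        sp: SpeciesTree) -> DuplicationEvent | None:
    """Attach the species-tree MRCA of the event's taxa; None if unmappable."""
    try:
        node_id = sp.mrca(ev.all_taxa)
    except TreeValidationError as exc:
        log.info("dropping event in %s: %s", ev.orthogroup_id, exc)
        return None
    return replace(ev, species_node_id=node_id)


def tally(events, sp: SpeciesTree, min_support: float | None = 80.0,
          support_mode: str = "node") -> DuplicationTally:
    """Count mapped events per species node, one per gene-tree node.

    ``min_support=None`` disables the filter (events without supports then
    count). ``support_mode="children"`` additionally requires every child
    edge of the duplication node to pass the threshold.
    """
    counts = {node_id: 0 for node_id in sp.node_ids}
    result = DuplicationTally(counts=counts, min_support=min_support)
    for ev in events:
        if ev.species_node_id is None:
            raise ValueError("tally() requires mapped events")
        result.n_events_considered += 1
        if min_support is not None:
            if ev.support is None or ev.support < min_support:
                continue
            if support_mode == "children" and any(
                s is None or s < min_support for s in ev.child_supports
            ):
                continue
        counts[ev.species_node_id] += 1
        result.n_events_counted += 1
    return result


def map_gene_trees(gene_trees, sp: SpeciesTree):
    """find -> map over many trees; returns (mapped events, skip log)."""
    mapped, skipped = [], []
    for gt in gene_trees:
        for ev in find_duplication_nodes(gt):
            m = map_to_species_tree(ev, sp)
            if m is None:
                skipped.append((gt.orthogroup_id, ev.node_index, "unknown_taxon"))
            else:
                mapped.append(m)
    return mapped, skipped
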