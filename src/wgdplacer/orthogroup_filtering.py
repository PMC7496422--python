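"""Matrix-hygiene cascade applied to orthogroups before tree-based analyses.

The cascade runs in a fixed order, mirroring standard phylotranscriptomic
practice: (1) taxon occupancy -- an orthogroup must contain at least
``floor(fraction * n_taxa)`` distinct taxa; (2) alignment gap fraction --
at most ``max_gap`` of the alignment matrix may be gap characters; (3)
paralog pruning -- in-paralog clades are collapsed to a single
representative and the largest clade in which no taxon appears twice is
kept, provided it still holds ``min_taxa`` taxa (PhyloTreePruner-style).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .trees_io import GeneTree


class ValidationError(ValueError):
    pass


@dataclass
class Orthogroup:
    """Aligned sequences for one orthogroup, keyed by (taxon, gene_id)."""

    orthogroup_id: str
    sequences: dict[tuple[str, str], str]
    gap_char: str = "-"

    def __post_init__(self):
        if not self.sequences:
            raise ValidationError(f"{self.orthogroup_id}: empty orthogroup")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValidationError(
                f"{self.orthogroup_id}: ragged alignment (lengths {sorted(lengths)})"
            )

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(taxon for taxon, _ in self.sequences)

    def sequences_for(self, taxon: str) -> dict[str, str]:
        return {g: s for (t, g), s in self.sequences.items() if t == taxon}


# ---------------------------------------------------------------------------
# stage 1: taxon occupancy


def occupancy_threshold(n_taxa: int, fraction: float) -> int:
    """Minimum distinct-taxon count for an occupancy fraction.

    Uses floor, so 80% of 74 taxa is 59 -- fractional taxa never round up.
    """
    if n_taxa < 1:
        raise ValidationError("n_taxa must be >= 1")
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction {fraction} outside (0, 1]")
    return math.floor(fraction * n_taxa + 1e-9)


def passes_occupancy(og: Orthogroup, min_taxon_count: int) -> bool:
    return len(og.taxa) >= min_taxon_count


# ---------------------------------------------------------------------------
# stage 2: gap fraction


def gap_fraction_filter(og: Orthogroup, max_gap: float,
                        per_sequence: bool = False) -> tuple[bool, float]:
    """(pass, measured gap fraction).

    Default measures gaps over the whole alignment matrix; ``per_sequence``
    instead fails the orthogroup if any single sequence exceeds ``max_gap``
    (and reports the worst per-sequence fraction).
    """
    length = og.alignment_length
    if length == 0:
        raise ValidationError(f"{og.orthogroup_id}: zero-length alignment")
    fractions = [s.count(og.gap_char) / length for s in og.sequences.values()]
    if per_sequence:
        measured = max(fractions)
    else:
        measured = sum(fractions) / len(fractions)
    return measured <= max_gap, measured


# ---------------------------------------------------------------------------
# stage 3: paralog pruning


def _collapse_in_paralogs(gt: GeneTree, seq_lengths) -> GeneTree:
    """Replace every maximal single-taxon clade by one representative leaf.

    The representative is the longest sequence (ties and missing lengths:
    lexicographically smallest gene_id); its branch length becomes the path
    length from the clade's stem to the kept leaf. Collapsing proceeds
    top-down, so only maximal single-taxon clades are replaced.
    """
    from .trees_io import _fmt_length, _fmt_support

    def keep_leaf(leaves):
        def key(lf):
            ln = -1 if seq_lengths is None else seq_lengths.get(
                (lf.taxon_name, lf.gene_id), -1)
            return (-ln, lf.gene_id)
        return min(leaves, key=key)

    def path_length(top, leaf):
        total, any_len = 0.0, False
        cur = leaf
        while cur is not top:
            if cur.edge.length is not None:
                total, any_len = total + cur.edge.length, True
            cur = cur.parent_node
        return total, any_len

    def rec(nd, is_root):
        leaves = [nd] if nd.is_leaf() else list(nd.leaf_iter())
        taxa = {lf.taxon_name for lf in leaves}
        if len(taxa) == 1:
            kept = keep_leaf(leaves)
            below, any_below = path_length(nd, kept)
            stem = nd.edge.length
            if is_root:
                length = below if (any_below and not nd.is_leaf()) else None
            elif stem is None and not any_below:
                length = None
            else:
                length = (stem or 0.0) + below
            return f"{kept.taxon.label}{_fmt_length(length)}"
        inner = ",".join(rec(ch, False) for ch in nd.child_nodes())
        sup = _fmt_support(getattr(nd.edge, "support", None))
        length = "" if is_root else _fmt_length(nd.edge.length)
        return f"({inner}){sup}{length}"

    root = gt.tree.seed_node
    text = rec(root, True) + ";"
    if root.is_leaf() or len({lf.taxon_name for lf in root.leaf_iter()}) == 1:
        # whole tree collapses to one leaf; wrap so newick stays parseable
        text = f"({text[:-1]});"
    return GeneTree.from_newick(text, gt.scheme, gt.orthogroup_id)


def prune_paralogs(gt: GeneTree, min_taxa: int,
                   seq_lengths: dict[tuple[str, str], int] | None = None
                   ) -> GeneTree | None:
    """PhyloTreePruner-style pruning to a maximal duplicate-free clade.

    Returns the pruned tree, or ``None`` when the best duplicate-free clade
    holds fewer than ``min_taxa`` taxa. Tie-breaks among equally large
    clades: the one closer to the root wins, then the lexicographically
    smallest leaf-label set.
    """
    collapsed = _collapse_in_paralogs(gt, seq_lengths)
    tree = collapsed.tree

    best = None
    best_key = None
    for depth, nd in _preorder_with_depth(tree):
        leaves = [nd] if nd.is_leaf() else list(nd.leaf_iter())
        taxa = [lf.taxon_name for lf in leaves]
        if len(set(taxa)) != len(taxa):
            continue
        labels = tuple(sorted(lf.taxon.label for lf in leaves))
        key = (-len(leaves), depth, labels)
        if best_key is None or key < best_key:
            best, best_key = nd, key
    assert best is not None  # leaves are always duplicate-free
    if len(best_key[2]) < min_taxa:
        return None
    if best is tree.seed_node:
        return collapsed
    subtree_newick = _subtree_newick(collapsed, best)
    return GeneTree.from_newick(subtree_newick, collapsed.scheme,
                                collapsed.orthogroup_id)


def _preorder_with_depth(tree):
    stack = [(0, tree.seed_node)]
    while stack:
        depth, nd = stack.pop()
        yield depth, nd
        for ch in reversed(nd.child_nodes()):
            stack.append((depth + 1, ch))


def _subtree_newick(gt: GeneTree, nd) -> str:
    from .trees_io import _fmt_length, _fmt_support

    def rec(n):
        if n.is_leaf():
            return f"{n.taxon.label}{_fmt_length(n.edge.length)}"
        inner = ",".join(rec(c) for c in n.child_nodes())
        sup = _fmt_support(getattr(n.edge, "support", None))
        return f"({inner}){sup}{_fmt_length(n.edge.length)}"

    if nd.is_leaf():
        return f"{nd.taxon.label};"
    inner = ",".join(rec(c) for c in nd.child_nodes())
    return f"({inner});"


# ---------------------------------------------------------------------------
# cascade + report


@dataclass
class FilterReport:
    """Counts per stage and one fate line per orthogroup."""

    entering: int = 0
    after_occupancy: int = 0
    after_gap: int = 0
    after_prune: int = 0
    fates: dict[str, str] = field(default_factory=dict)

    def record(self, og_id: str, fate: str):
        self.fates[og_id] = fate

    def to_rows(self):
        return [(og_id, fate) for og_id, fate in sorted(self.fates.items())]


def run_filter_cascade(orthogroups: dict[str, Orthogroup],
                       gene_trees: dict[str, GeneTree],
                       n_taxa: int,
                       occupancy_fraction: float = 0.80,
                       max_gap: float = 0.40,
                       min_taxa: int = 10,
                       per_sequence_gaps: bool = False):
    """occupancy -> gap -> prune, in that fixed order.

    Returns ``(pruned_trees, surviving_orthogroups, report)`` where
    ``surviving_orthogroups`` are those passing occupancy + gap (the set
    whose unpruned trees feed duplication mapping) and ``pruned_trees`` maps
    orthogroup_id to the pruned single-copy tree for those that also pass
    pruning.
    """
    report = FilterReport(entering=len(orthogroups))
    min_count = occupancy_threshold(n_taxa, occupancy_fraction)
    survivors: dict[str, Orthogroup] = {}
    pruned: dict[str, GeneTree] = {}

    for og_id in sorted(orthogroups):
        og = orthogroups[og_id]
        if not passes_occupancy(og, min_count):
            report.record(og_id, f"occupancy:{len(og.taxa)}<{min_count}")
            continue
        report.after_occupancy += 1
        ok, frac = gap_fraction_filter(og, max_gap, per_sequence_gaps)
        if not ok:
            report.record(og_id, f"gaps:{frac:.3f}>{max_gap}")
            continue
        report.after_gap += 1
        survivors[og_id] = og
        gt = gene_trees.get(og_id)
        if gt is None:
            report.record(og_id, "no_gene_tree")
            continue
        seq_lengths = {
            key: len(seq) - seq.count(og.gap_char)
            for key, seq in og.sequences.items()
        }
        result = prune_paralogs(gt, min_taxa, seq_lengths)
        if result is None:
            report.record(og_id, f"pruned:<{min_taxa}_taxa")
            continue
        report.after_prune += 1
        pruned[og_id] = result
        report.record(og_id, "pass")

    return pruned, survivors, report
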