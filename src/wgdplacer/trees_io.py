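"""Tree containers and newick I/O for the WGD placement pipeline.

Two thin wrappers around :mod:`dendropy` trees are provided:

* :class:`SpeciesTree` -- the rooted species phylogeny duplications are
  mapped onto. Internal nodes carry stable ``node_id`` strings (taken from
  internal newick labels when present, auto-assigned in preorder otherwise);
  leaf node_ids are the taxon labels themselves.
* :class:`GeneTree` -- one orthogroup's tree. Leaf labels encode
  ``<taxon><delimiter><gene_id>`` (see :class:`LeafLabelScheme`), internal
  newick labels are read as bootstrap supports (RAxML dialect) and stored on
  edges so they survive rerooting, and branch lengths are interpreted as Ks
  units throughout.

Newick writing is done by this module so the canonical form is fully
specified: branch lengths with 6 decimals, supports/ids as internal labels,
child order preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy


class NewickParseError(ValueError):
    """Malformed newick; message names the offending line/column."""


class TreeValidationError(ValueError):
    """Structurally valid newick that violates a domain invariant."""


class UnrootableError(ValueError):
    """No outgroup leaf present (or no ingroup leaf left)."""


class NestedOutgroupError(UnrootableError):
    """Outgroup leaves span the basal polytomy; no rooting edge exists."""


@dataclass(frozen=True)
class LeafLabelScheme:
    """How gene-tree leaf labels encode (taxon, gene_id)."""

    delimiter: str = "|"
    taxon_index: int = 0  # 0: taxon first, 1: gene_id first

    def split(self, label: str) -> tuple[str, str]:
        parts = label.split(self.delimiter)
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise TreeValidationError(
                f"leaf label {label!r} does not parse as "
                f"<taxon>{self.delimiter}<gene_id>"
            )
        taxon, gene = (parts[0], parts[1]) if self.taxon_index == 0 else (parts[1], parts[0])
        return taxon, gene

    def join(self, taxon: str, gene_id: str) -> str:
        if self.delimiter in taxon:
            raise TreeValidationError(
                f"delimiter {self.delimiter!r} occurs inside taxon name {taxon!r}"
            )
        first, second = (taxon, gene_id) if self.taxon_index == 0 else (gene_id, taxon)
        return f"{first}{self.delimiter}{second}"


DEFAULT_SCHEME = LeafLabelScheme()


# ---------------------------------------------------------------------------
# low-level parse / write helpers


def _read_dendropy(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several tokenizer subclasses
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate gene leaf label: {exc}") from exc
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        where = f" (line {line}, column {col})" if col is not None else ""
        raise NewickParseError(f"malformed newick{where}: {exc}") from exc


def _fmt_length(x: float | None) -> str:
    return "" if x is None else f":{x:.6f}"


def _fmt_support(x: float | None) -> str:
    if x is None:
        return ""
    return f"{x:g}"


def _write_gene_newick(tree: dendropy.Tree) -> str:
    def rec(nd) -> str:
        if nd.is_leaf():
            return f"{nd.taxon.label}{_fmt_length(nd.edge.length)}"
        inner = ",".join(rec(ch) for ch in nd.child_nodes())
        sup = _fmt_support(getattr(nd.edge, "support", None))
        length = "" if nd.parent_node is None else _fmt_length(nd.edge.length)
        return f"({inner}){sup}{length}"

    return rec(tree.seed_node) + ";"


def _write_species_newick(tree: dendropy.Tree) -> str:
    def rec(nd) -> str:
        if nd.is_leaf():
            return f"{nd.taxon.label}{_fmt_length(nd.edge.length)}"
        inner = ",".join(rec(ch) for ch in nd.child_nodes())
        length = "" if nd.parent_node is None else _fmt_length(nd.edge.length)
        return f"({inner}){nd.node_id}{length}"

    return rec(tree.seed_node) + ";"


def _mrca_of_nodes(nodes):
    """MRCA via ancestor-path prefix intersection (nodes in one tree)."""
    if not nodes:
        raise ValueError("need at least one node")
    paths = []
    for nd in nodes:
        path = []
        cur = nd
        while cur is not None:
            path.append(cur)
            cur = cur.parent_node
        paths.append(list(reversed(path)))
    shortest = min(len(p) for p in paths)
    mrca = paths[0][0]
    for depth in range(shortest):
        candidate = paths[0][depth]
        if all(p[depth] is candidate for p in paths):
            mrca = candidate
        else:
            break
    return mrca


# ---------------------------------------------------------------------------
# species tree


class SpeciesTree:
    """Rooted species phylogeny with stable node ids."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._validate_and_index()

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        tree = _read_dendropy(text)
        counter = 0
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                nd.node_id = nd.taxon.label
            elif nd.label not in (None, ""):
                nd.node_id = str(nd.label)
            else:
                nd.node_id = f"N{counter}"
                counter += 1
        return cls(tree)

    def _validate_and_index(self):
        self._by_id = {}
        self._leaf_by_taxon = {}
        for nd in self.tree.preorder_node_iter():
            if nd.node_id in self._by_id:
                raise TreeValidationError(f"duplicate node_id {nd.node_id!r}")
            self._by_id[nd.node_id] = nd
            if not nd.is_leaf() and len(nd.child_nodes()) < 2:
                raise TreeValidationError("internal node with a single child")
            if nd.is_leaf():
                if nd.taxon.label in self._leaf_by_taxon:
                    raise TreeValidationError(
                        f"duplicate taxon label {nd.taxon.label!r}"
                    )
                self._leaf_by_taxon[nd.taxon.label] = nd

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self._leaf_by_taxon)

    @property
    def node_ids(self) -> list[str]:
        return [nd.node_id for nd in self.tree.preorder_node_iter()]

    @property
    def root_id(self) -> str:
        return self.tree.seed_node.node_id

    def node(self, node_id: str):
        try:
            return self._by_id[node_id]
        except KeyError:
            raise TreeValidationError(f"unknown node_id {node_id!r}") from None

    def mrca(self, taxa) -> str:
        taxa = set(taxa)
        missing = taxa - self.taxa
        if missing:
            raise TreeValidationError(f"unknown taxa: {sorted(missing)}")
        nodes = [self._leaf_by_taxon[t] for t in taxa]
        return _mrca_of_nodes(nodes).node_id

    def leaf_taxa(self, node_id: str) -> frozenset[str]:
        nd = self.node(node_id)
        if nd.is_leaf():
            return frozenset({nd.taxon.label})
        return frozenset(lf.taxon.label for lf in nd.leaf_iter())

    def depth(self, node_id: str) -> float:
        """Sum of branch lengths from this node down to any leaf is not
        well-defined off-ultrametric trees; depth here is root-to-node."""
        nd = self.node(node_id)
        d = 0.0
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        return d

    def write(self) -> str:
        return _write_species_newick(self.tree)


# ---------------------------------------------------------------------------
# gene tree


class GeneTree:
    """One orthogroup's rooted gene tree (leaf labels = taxon + gene id)."""

    def __init__(self, tree: dendropy.Tree, scheme: LeafLabelScheme,
                 orthogroup_id: str | None = None):
        self.tree = tree
        self.scheme = scheme
        self.orthogroup_id = orthogroup_id
        self._validate()

    @classmethod
    def from_newick(cls, text: str, scheme: LeafLabelScheme = DEFAULT_SCHEME,
                    orthogroup_id: str | None = None) -> "GeneTree":
        tree = _read_dendropy(text)
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            support = None
            if nd.label not in (None, ""):
                try:
                    support = float(nd.label)
                except ValueError:
                    raise TreeValidationError(
                        f"internal label {nd.label!r} is not a bootstrap support"
                    ) from None
            nd.edge.support = support
        return cls(tree, scheme, orthogroup_id)

    def _validate(self):
        seen = set()
        for nd in self.tree.preorder_node_iter():
            if nd.edge.length is not None and nd.edge.length < 0:
                raise TreeValidationError("negative branch length")
            if nd.is_leaf():
                taxon, gene = self.scheme.split(nd.taxon.label)
                if (taxon, gene) in seen:
                    raise TreeValidationError(
                        f"duplicate gene {gene!r} for taxon {taxon!r}"
                    )
                seen.add((taxon, gene))
                nd.taxon_name, nd.gene_id = taxon, gene
            else:
                sup = getattr(nd.edge, "support", None)
                if sup is not None and not (0.0 <= sup <= 100.0):
                    raise TreeValidationError(f"support {sup} outside [0, 100]")

    # -- queries ----------------------------------------------------------
    def leaves(self):
        return list(self.tree.leaf_node_iter())

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(lf.taxon_name for lf in self.leaves())

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.leaves()]

    def node_taxa(self, nd) -> frozenset[str]:
        if nd.is_leaf():
            return frozenset({nd.taxon_name})
        return frozenset(lf.taxon_name for lf in nd.leaf_iter())

    def mrca(self, leaf_nodes):
        return _mrca_of_nodes(list(leaf_nodes))

    def bipartitions(self) -> set[frozenset]:
        """Unrooted-sense bipartitions, each keyed by the side that does not
        contain the reference (lexicographically smallest) leaf label."""
        labels = set(self.leaf_labels())
        ref = min(labels)
        splits = set()
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is None or nd.is_leaf():
                continue
            below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            key = below if ref not in below else frozenset(labels - below)
            if 1 < len(key) < len(labels) - 1:  # non-trivial splits only
                splits.add(key)
        return splits

    def write(self) -> str:
        return _write_gene_newick(self.tree)

    def copy(self) -> "GeneTree":
        return GeneTree.from_newick(self.write(), self.scheme, self.orthogroup_id)


# ---------------------------------------------------------------------------
# public operations


def parse_newick(text: str, scheme: LeafLabelScheme = DEFAULT_SCHEME,
                 orthogroup_id: str | None = None) -> GeneTree:
    return GeneTree.from_newick(text, scheme, orthogroup_id)


def parse_species_tree(text: str) -> SpeciesTree:
    return SpeciesTree.from_newick(text)


def root_with_outgroup(gt: GeneTree, outgroup_taxa) -> GeneTree:
    """Root on the edge separating the outgroup clade from the ingroup.

    The rooting edge is the one above the smallest clade (under the current
    reading of the tree) containing every outgroup leaf present; if that
    clade is the whole tree, the complementary ingroup clade is used instead.
    Bootstrap supports are re-attached by bipartition identity, so they stay
    with the same unrooted split. Trees in which the outgroup straddles the
    basal polytomy raise :class:`NestedOutgroupError` (skip-and-log policy).
    """
    outgroup_taxa = set(outgroup_taxa)
    work = gt.copy()
    tree = work.tree

    labels = set(work.leaf_labels())
    ref = min(labels)
    support_by_split: dict[frozenset, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        sup = getattr(nd.edge, "support", None)
        if sup is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        key = below if ref not in below else frozenset(labels - below)
        support_by_split[key] = sup

    out_leaves = [lf for lf in work.leaves() if lf.taxon_name in outgroup_taxa]
    in_leaves = [lf for lf in work.leaves() if lf.taxon_name not in outgroup_taxa]
    if not out_leaves:
        raise UnrootableError(
            f"no outgroup leaf present (outgroups: {sorted(outgroup_taxa)})"
        )
    if not in_leaves:
        raise UnrootableError("every leaf belongs to the outgroup")

    target = _mrca_of_nodes(out_leaves)
    if target is tree.seed_node:
        target = _mrca_of_nodes(in_leaves)
        if target is tree.seed_node:
            raise NestedOutgroupError(
                "outgroup leaves straddle the root; no rooting edge exists"
            )

    length = target.edge.length
    half = None if length is None else length / 2.0
    tree.reroot_at_edge(target.edge, length1=half, length2=half,
                        suppress_unifurcations=True)

    # re-attach supports to the surviving bipartitions
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        key = below if ref not in below else frozenset(labels - below)
        nd.edge.support = support_by_split.get(key)

    return GeneTree(tree, work.scheme, work.orthogroup_id)


def mrca(tree: SpeciesTree, taxa) -> str:
    """node_id of the most recent common ancestor of ``taxa``."""
    return tree.mrca(taxa)
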