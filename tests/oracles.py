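"""Independent brute-force oracles used by the test suite.

Deliberately written in a different style from the package code (recursive
enumeration, ancestor-set intersection, character loops) so agreement is
meaningful.
"""

from Bio.Data import CodonTable

_CT = CodonTable.unambiguous_dna_by_id[1]
CODE = dict(_CT.forward_table)
STOPS = set(_CT.stop_codons)
SENSE = sorted(CODE)


# ---------------------------------------------------------------------------
# NG86


def oracle_syn_sites(codon: str) -> float:
    """Synonymous-site count of one codon: synonymous single-base changes / 3
    (changes into stop codons are nonsynonymous)."""
    count = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            nb = codon[:pos] + base + codon[pos + 1 :]
            if nb not in STOPS and CODE[nb] == CODE[codon]:
                count += 1
    return count / 3.0


def _all_paths(c1: str, c2: str):
    """All orderings of the single-base steps from c1 to c2, as codon lists."""
    if c1 == c2:
        return [[c1]]
    out = []
    for pos in range(3):
        if c1[pos] != c2[pos]:
            step = c1[:pos] + c2[pos] + c1[pos + 1 :]
            for rest in _all_paths(step, c2):
                out.append([c1] + rest)
    return out


def oracle_diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """Path-averaged (synonymous, nonsynonymous) differences; mutation paths
    whose intermediates hit a stop codon are excluded unless all do."""
    paths = _all_paths(c1, c2)
    if len(paths) == 1 and len(paths[0]) == 1:
        return 0.0, 0.0
    scored = []
    for path in paths:
        blocked = any(c in STOPS for c in path[1:-1])
        sd = nd = 0.0
        for a, b in zip(path, path[1:]):
            if a in STOPS or b in STOPS:
                nd += 1
            elif CODE[a] == CODE[b]:
                sd += 1
            else:
                nd += 1
        scored.append((blocked, sd, nd))
    usable = [(s, n) for blocked, s, n in scored if not blocked]
    if not usable:
        usable = [(s, n) for _, s, n in scored]
    return (sum(s for s, _ in usable) / len(usable),
            sum(n for _, n in usable) / len(usable))


def stop_path_exists(c1: str, c2: str) -> bool:
    return any(any(c in STOPS for c in path[1:-1])
               for path in _all_paths(c1, c2))


# ---------------------------------------------------------------------------
# trees


def oracle_mrca(sp, taxa) -> str:
    """Species-tree MRCA by intersecting root-to-leaf ancestor id paths."""
    paths = []
    for taxon in taxa:
        nd = sp.node(taxon)
        ids = []
        while nd is not None:
            ids.append(nd.node_id)
            nd = nd.parent_node
        paths.append(list(reversed(ids)))
    common = None
    for path in paths:
        common = path if common is None else [
            a for a, b in zip(common, path) if a == b
        ]
    return common[-1]


def oracle_duplication_nodes(gt):
    """Gene-tree duplication nodes = {MRCA(g1, g2): same-taxon leaf pairs},
    deduplicated; returns the set of node objects."""
    leaves = gt.leaves()
    found = set()
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            if a.taxon_name != b.taxon_name:
                continue
            anc_a = []
            nd = a
            while nd is not None:
                anc_a.append(nd)
                nd = nd.parent_node
            nd = b
            while nd is not None:
                if nd in anc_a:
                    found.add(nd)
                    break
                nd = nd.parent_node
    return found


def oracle_tally(gt, sp, min_support):
    """Per species-node duplicate counts from the pair-MRCA oracle."""
    counts = {}
    for nd in oracle_duplication_nodes(gt):
        sup = getattr(nd.edge, "support", None)
        if min_support is not None and (sup is None or sup < min_support):
            continue
        taxa = {lf.taxon_name for lf in nd.leaf_iter()}
        node_id = oracle_mrca(sp, sorted(taxa))
        counts[node_id] = counts.get(node_id, 0) + 1
    return counts


def oracle_gap_count(sequences) -> int:
    total = 0
    for seq in sequences:
        for ch in seq:
            if ch == "-":
                total += 1
    return total


# ---------------------------------------------------------------------------
# pruning


def oracle_best_distinct_clade(gt, seq_lengths=None):
    """(size, taxa) of the best duplicate-free clade after collapsing
    maximal single-taxon clades, by exhaustive enumeration."""

    def to_tuple(nd):
        if nd.is_leaf():
            return (nd.taxon_name, nd.gene_id)
        return tuple(to_tuple(ch) for ch in nd.child_nodes())

    def leaves_of(t):
        if isinstance(t[0], str) and len(t) == 2 and not isinstance(t[0], tuple):
            return [t]
        out = []
        for ch in t:
            out.extend(leaves_of(ch))
        return out

    def collapse(t):
        lvs = leaves_of(t)
        taxa = {lf[0] for lf in lvs}
        if len(taxa) == 1:
            if seq_lengths is None:
                rep = min(lvs, key=lambda lf: lf[1])
            else:
                rep = min(lvs, key=lambda lf: (-seq_lengths.get(lf, -1), lf[1]))
            return rep
        return tuple(collapse(ch) for ch in t)

    def clades(t):
        yield t
        if not (isinstance(t[0], str) and len(t) == 2 and not isinstance(t[0], tuple)):
            for ch in t:
                yield from clades(ch)

    collapsed = collapse(to_tuple(gt.tree.seed_node))
    best = (0, frozenset())
    for clade in clades(collapsed):
        lvs = leaves_of(clade)
        taxa = [lf[0] for lf in lvs]
        if len(set(taxa)) == len(taxa) and len(lvs) > best[0]:
            best = (len(lvs), frozenset(taxa))
    return best
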