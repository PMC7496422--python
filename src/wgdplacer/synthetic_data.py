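"""Gene-family simulator emulating the statistical structure of a
phylo-transcriptomic WGD study.

Each family starts as a single gene lineage at the species-tree root and
evolves down the tree: along every branch, duplications and losses arrive
as independent Poisson processes with rates ``lambda`` and ``mu`` per gene
lineage per Ks unit; at a whole-genome-duplication episode every lineage
alive at that instant duplicates with retention probability ``r``. An
episode declared "at node v" is realized midway along the branch subtending
v (at the root itself for the root node): any point on that branch maps to
v under MRCA-based duplication mapping, while a node-pinned event would be
exactly coeval with one of the adjacent speciations and make
ortholog/paralog bookending degenerate by construction.

Branch lengths are in Ks units; per-branch multiplicative lognormal noise
(mean 1) models among-gene rate heterogeneity, and the *noisy* lengths are
the truth: codon sequences are evolved along them with a
synonymous-substitutions-only process (see :mod:`wgdplacer.codons`), so a
pair's true Ks is its path length in the emitted gene tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import codons
from .orthogroup_filtering import Orthogroup
from .trees_io import GeneTree, LeafLabelScheme, DEFAULT_SCHEME, SpeciesTree

# desk-scale stand-in for a transcriptome study's species tree: six ingroup
# taxa, two outgroups, ultrametric in Ks units. A WGD midway along the
# branch above node "ab" sits at Ks depth 0.2, i.e. a paralog peak at 0.4.
DEFAULT_SPECIES_TREE = (
    "(((((A:0.15,B:0.15)ab:0.10,C:0.25)abc:0.15,"
    "(D:0.20,E:0.20)de:0.20)abcde:0.15,F:0.55)ingroup:0.20,"
    "(Og1:0.375,Og2:0.375)outs:0.375)root;"
)
DEFAULT_OUTGROUPS = ("Og1", "Og2")


@dataclass(frozen=True)
class WGDEpisode:
    node_id: str
    retention: float

    def __post_init__(self):
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError(f"retention {self.retention} outside [0, 1]")


@dataclass
class SimConfig:
    species_tree: str = DEFAULT_SPECIES_TREE
    duplication_rate: float = 0.1        # per lineage per Ks unit
    loss_rate: float = 0.1
    wgd_episodes: tuple[WGDEpisode, ...] = ()
    rate_noise_sigma: float = 0.1        # lognormal sd, mean-1 multiplier
    codon_length: int = 300              # codons per gene
    n_families: int = 300
    bootstrap_support: tuple = ("constant", 100.0)   # or ("uniform", lo, hi)
    seed: int = 0
    scheme: LeafLabelScheme = DEFAULT_SCHEME

    def __post_init__(self):
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.codon_length < 30:
            raise ValueError("codon_length must be >= 30 codons")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")


@dataclass(eq=False)  # identity semantics: nodes are dict keys
class SimNode:
    """Node of a simulated gene tree; ``length`` is the edge above (Ks)."""

    event: str                      # "speciation" | "duplication" | "wgd" | "leaf"
    length: float = 0.0
    children: list = field(default_factory=list)
    taxon: str | None = None
    gene_id: str | None = None
    support: float | None = None
    wgd_node_id: str | None = None  # episode node for event == "wgd"

    def leaves(self):
        if not self.children:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def walk(self):
        yield self
        for ch in self.children:
            yield from ch.walk()


@dataclass
class SimFamily:
    orthogroup_id: str
    root: SimNode

    def pairwise_ks(self) -> dict[tuple[str, str], float]:
        """True Ks of every leaf pair = path length in the emitted tree."""
        depths = {}

        def rec(nd, path):
            if not nd.children:
                depths[nd] = path + nd.length
                return
            for ch in nd.children:
                rec(ch, path + nd.length)

        rec(self.root, -self.root.length)  # root edge does not exist
        leaves = self.root.leaves()
        out = {}

        def label(lf):
            return (lf.taxon, lf.gene_id)

        for i, a in enumerate(leaves):
            for b in leaves[i + 1 :]:
                mrca_depth = _mrca_depth(self.root, a, b)
                out[(label(a), label(b))] = (
                    depths[a] + depths[b] - 2.0 * mrca_depth
                )
        return out


def _mrca_depth(root, a, b):
    """Depth (from root, in Ks) of the MRCA of two leaves."""
    path_a = _path_to(root, a)
    path_b = _path_to(root, b)
    depth = 0.0
    last_common_depth = 0.0
    for na, nb in zip(path_a, path_b):
        if na is not nb:
            break
        if na is not root:
            depth += na.length
        last_common_depth = depth
    return last_common_depth


def _path_to(root, leaf):
    path = []

    def rec(nd):
        path.append(nd)
        if nd is leaf:
            return True
        for ch in nd.children:
            if rec(ch):
                return True
        path.pop()
        return False

    rec(root)
    return path


@dataclass
class SimTruth:
    families: list[SimFamily]
    episodes: tuple[WGDEpisode, ...]
    species_tree_newick: str


@dataclass
class SimResult:
    gene_trees: dict[str, GeneTree]
    orthogroups: dict[str, Orthogroup]
    truth: SimTruth
    species_tree: SpeciesTree


# ---------------------------------------------------------------------------
# the generator


def _collapse_or_node(event, children, **kw):
    surviving = [c for c in children if c is not None]
    if not surviving:
        return None
    if len(surviving) == 1:
        return surviving[0]
    return SimNode(event=event, children=surviving, **kw)


def simulate_families(cfg: SimConfig, with_sequences: bool = True) -> SimResult:
    """Simulate gene families, gene trees, and codon alignments.

    Families with fewer than two surviving leaves are discarded and
    resampled (with a retry budget); the generator is a pure function of
    the config, including its seed.
    """
    rng = np.random.default_rng(cfg.seed)
    sp = SpeciesTree.from_newick(cfg.species_tree)
    episodes = {ep.node_id: ep for ep in cfg.wgd_episodes}
    unknown = set(episodes) - set(sp.node_ids)
    if unknown:
        raise ValueError(f"WGD episode at unknown species node(s): {sorted(unknown)}")
    lam, mu = cfg.duplication_rate, cfg.loss_rate
    total_rate = lam + mu

    def bd_segment(remaining, cont):
        """One gene lineage across a Ks span; cont() yields what follows."""
        while True:
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
            if wait >= remaining:
                node = cont()
                if node is not None:
                    node = _shallow_with_extra_length(node, remaining)
                return node
            if rng.random() < lam / total_rate:   # duplication
                left = bd_segment(remaining - wait, cont)
                right = bd_segment(remaining - wait, cont)
                node = _collapse_or_node("duplication", [left, right])
                if node is not None:
                    node = _shallow_with_extra_length(node, wait)
                return node
            return None                            # loss

    def _shallow_with_extra_length(node, extra):
        node.length += extra
        return node

    def at_species_node(sp_node):
        if sp_node.is_leaf():
            return SimNode(event="leaf", taxon=sp_node.taxon.label)
        children = [enter_branch(ch) for ch in sp_node.child_nodes()]
        return _collapse_or_node("speciation", children)

    def enter_branch(sp_child):
        b = sp_child.edge.length
        if b is None:
            raise ValueError("species tree branch without a Ks length")
        ep = episodes.get(sp_child.node_id)

        def arrive():
            return at_species_node(sp_child)

        if ep is None or ep.retention == 0.0:
            return bd_segment(b, arrive)

        def midpoint():
            if rng.random() < ep.retention:
                left = bd_segment(b / 2.0, arrive)
                right = bd_segment(b / 2.0, arrive)
                return _collapse_or_node("wgd", [left, right],
                                         wgd_node_id=ep.node_id)
            return bd_segment(b / 2.0, arrive)

        return bd_segment(b / 2.0, midpoint)

    def simulate_root():
        root_ep = episodes.get(sp.root_id)
        if root_ep is not None and root_ep.retention > 0.0 \
                and rng.random() < root_ep.retention:
            return _collapse_or_node(
                "wgd",
                [at_species_node(sp.tree.seed_node),
                 at_species_node(sp.tree.seed_node)],
                wgd_node_id=sp.root_id,
            )
        return at_species_node(sp.tree.seed_node)

    families: list[SimFamily] = []
    attempts = 0
    budget = 200 * cfg.n_families
    while len(families) < cfg.n_families:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"family simulation retry budget exhausted after {attempts} "
                f"attempts ({len(families)}/{cfg.n_families} families; "
                f"loss rate {mu} may be too high for this tree)"
            )
        root = simulate_root()
        if root is None or len(root.leaves()) < 2:
            continue
        og_id = f"OG{len(families):04d}"
        _apply_rate_noise(root, rng, cfg.rate_noise_sigma)
        _assign_gene_ids(root)
        _assign_supports(root, rng, cfg.bootstrap_support)
        families.append(SimFamily(orthogroup_id=og_id, root=root))

    truth = SimTruth(families=families, episodes=tuple(cfg.wgd_episodes),
                     species_tree_newick=sp.write())
    gene_trees = {
        fam.orthogroup_id: GeneTree.from_newick(
            _sim_newick(fam.root, cfg.scheme), cfg.scheme, fam.orthogroup_id
        )
        for fam in families
    }
    orthogroups = {}
    if with_sequences:
        for fam in families:
            orthogroups[fam.orthogroup_id] = _evolve_orthogroup(
                fam, cfg.codon_length, rng, cfg.scheme
            )
    return SimResult(gene_trees=gene_trees, orthogroups=orthogroups,
                     truth=truth, species_tree=sp)


def _apply_rate_noise(root: SimNode, rng, sigma: float):
    for nd in root.walk():
        if nd is root:
            nd.length = 0.0
            continue
        if sigma > 0:
            nd.length *= float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))


def _assign_gene_ids(root: SimNode):
    for i, lf in enumerate(root.leaves(), start=1):
        lf.gene_id = f"g{i}"


def _assign_supports(root: SimNode, rng, dist):
    kind = dist[0]
    for nd in root.walk():
        if nd.children and nd is not root:
            if kind == "constant":
                nd.support = float(dist[1])
            elif kind == "uniform":
                nd.support = float(rng.uniform(dist[1], dist[2]))
            else:
                raise ValueError(f"unknown bootstrap distribution {dist!r}")
    for nd in root.walk():
        if nd.children and nd is root:
            nd.support = None


def _sim_newick(root: SimNode, scheme: LeafLabelScheme) -> str:
    # 12 significant digits so in-memory path lengths match the truth to
    # well below 1e-9 (downstream canonical writing still rounds to 6)
    def rec(nd, is_root):
        if not nd.children:
            return f"{scheme.join(nd.taxon, nd.gene_id)}:{nd.length:.12g}"
        inner = ",".join(rec(ch, False) for ch in nd.children)
        sup = "" if nd.support is None else f"{nd.support:g}"
        length = "" if is_root else f":{nd.length:.12g}"
        return f"({inner}){sup}{length}"

    return rec(root, True) + ";"


# ---------------------------------------------------------------------------
# codon sequences


def _evolve_orthogroup(fam: SimFamily, n_codons: int, rng,
                       scheme: LeafLabelScheme) -> Orthogroup:
    """Evolve codons down the gene tree: synonymous substitutions only, so
    divergence per synonymous site equals branch length (time t = Ks/3, see
    :func:`wgdplacer.codons.synonymous_rate_matrix`)."""
    sequences: dict[tuple[str, str], str] = {}

    def sample_child(seq_idx, ks_len):
        p = codons.synonymous_transition_matrix(ks_len / 3.0)
        cdf = np.cumsum(p[seq_idx], axis=1)
        u = rng.random(len(seq_idx))
        return (cdf < u[:, None]).sum(axis=1)

    def rec(nd, seq_idx):
        if not nd.children:
            sequences[(nd.taxon, nd.gene_id)] = codons.decode_codons(seq_idx)
            return
        for ch in nd.children:
            rec(ch, sample_child(seq_idx, ch.length))

    root_seq = rng.integers(0, codons.N_SENSE, size=n_codons)
    rec(fam.root, root_seq)
    return Orthogroup(orthogroup_id=fam.orthogroup_id, sequences=sequences)


def emit_codon_pairs(ks_values, n_codons: int, seed: int,
                     ) -> list[tuple[str, str]]:
    """Standalone codon-alignment pairs at given true Ks divergences.

    Each pair descends from a random ancestor of ``n_codons`` sense codons,
    with each lineage evolved for half the target Ks. Negative or
    non-finite targets raise (flagged unreachable).
    """
    rng = np.random.default_rng(seed)
    out = []
    for ks in ks_values:
        if not math.isfinite(ks) or ks < 0:
            raise ValueError(f"unreachable target Ks {ks}")
        anc = rng.integers(0, codons.N_SENSE, size=n_codons)
        p = codons.synonymous_transition_matrix(ks / 6.0)
        seqs = []
        for _ in range(2):
            cdf = np.cumsum(p[anc], axis=1)
            u = rng.random(n_codons)
            seqs.append((cdf < u[:, None]).sum(axis=1))
        out.append((codons.decode_codons(seqs[0]),
                    codons.decode_codons(seqs[1])))
    return out
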