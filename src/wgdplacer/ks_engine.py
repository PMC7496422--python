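"""Synonymous-divergence (Ks) estimation and mixture modelling.

Ks between two aligned coding sequences is estimated with Nei-Gojobori
(1986) counting: synonymous sites S and path-averaged synonymous
differences sd give ps = sd/S, corrected for multiple hits with
Jukes-Cantor, Ks = -(3/4) ln(1 - (4/3) ps). Paralog-age distributions are
assembled in two modes: *pairwise* (every within-taxon pair of an
orthogroup contributes, FASTKs-style) and *node* (one value per gene-tree
duplication node, the median Ks of the same-taxon paralog pairs spanning
it, DupPipe-style). Peaks are found by fitting 1..k_max univariate Gaussian
mixtures by EM and choosing the component count with the lowest BIC.

The retention window [ks_min, ks_max] drops the near-zero peak of recent
tandem duplicates and the saturated tail before any mixture is fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from . import codons
from .orthogroup_filtering import Orthogroup, ValidationError
from .trees_io import GeneTree

DEFAULT_KS_WINDOW = (0.01, 2.0)


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# NG86 estimator


@dataclass(frozen=True)
class KsResult:
    ks: float
    ka: float
    ps: float
    pn: float
    S: float
    N: float
    sd: float
    nd: float
    n_codons: int
    saturated: bool


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ks_ng86(seq1: str, seq2: str, min_codons: int = 10) -> KsResult:
    """NG86 Ks (and Ka) for one pair of same-length coding sequences.

    Codon columns containing gaps or ambiguity in either sequence are
    masked out; a stop codon in either sequence raises. ``ps >= 3/4`` is
    beyond the Jukes-Cantor horizon: the value is flagged saturated and
    reported as +inf (distribution builders drop it).
    """
    if len(seq1) != len(seq2):
        raise ValidationError(
            f"sequence lengths differ ({len(seq1)} vs {len(seq2)})"
        )
    c1 = codons.encode_codons(seq1)
    c2 = codons.encode_codons(seq2)
    mask = (c1 >= 0) & (c2 >= 0)
    n_codons = int(mask.sum())
    if n_codons < min_codons:
        raise InsufficientDataError(
            f"only {n_codons} comparable codons (< {min_codons})"
        )
    a, b = c1[mask], c2[mask]
    sites = codons.ng86_site_counts()
    S = float(sites[a].sum() + sites[b].sum()) / 2.0
    N = 3.0 * n_codons - S
    sd_tab, nd_tab = codons.ng86_diff_tables()
    sd = float(sd_tab[a, b].sum())
    nd = float(nd_tab[a, b].sum())
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    return KsResult(ks=ks, ka=ka, ps=ps, pn=pn, S=S, N=N, sd=sd, nd=nd,
                    n_codons=n_codons, saturated=not math.isfinite(ks))


# ---------------------------------------------------------------------------
# distributions


@dataclass
class KsDistribution:
    """Ks values for one taxon (paralogs) or taxon pair (orthologs)."""

    values: np.ndarray
    mode: str                      # "pairwise" | "node"
    source: str                    # taxon or "taxonA--taxonB"
    window: tuple[float, float] = DEFAULT_KS_WINDOW
    n_raw: int = 0                 # values before windowing / saturation drop

    @classmethod
    def from_values(cls, values, mode: str, source: str,
                    window=DEFAULT_KS_WINDOW) -> "KsDistribution":
        if mode not in ("pairwise", "node"):
            raise ValidationError(f"unknown mode {mode!r}")
        raw = list(values)
        arr = np.asarray([v for v in raw if math.isfinite(v)], dtype=float)
        lo, hi = window
        kept = arr[(arr >= lo) & (arr <= hi)]
        return cls(values=np.sort(kept), mode=mode, source=source,
                   window=window, n_raw=len(raw))

    def __len__(self):
        return len(self.values)

    @property
    def median(self) -> float:
        if len(self.values) == 0:
            raise InsufficientDataError(f"no Ks values for {self.source}")
        return float(np.median(self.values))


def paralog_pairs_pairwise(og: Orthogroup, taxon: str):
    """All unordered within-taxon gene pairs of one orthogroup."""
    genes = sorted(og.sequences_for(taxon))
    return [(genes[i], genes[j])
            for i in range(len(genes)) for j in range(i + 1, len(genes))]


def pairwise_ks_distribution(orthogroups, taxon: str,
                             window=DEFAULT_KS_WINDOW) -> KsDistribution:
    """FASTKs-style paralog ages: every within-taxon pair of every orthogroup."""
    values = []
    for og in orthogroups:
        seqs = og.sequences_for(taxon)
        for g1, g2 in paralog_pairs_pairwise(og, taxon):
            try:
                values.append(ks_ng86(seqs[g1], seqs[g2]).ks)
            except (InsufficientDataError, ValueError):
                continue
    return KsDistribution.from_values(values, "pairwise", taxon, window)


def node_paralog_pairs(gt: GeneTree, event):
    """Same-taxon gene pairs whose MRCA is the event's duplication node."""
    nodes = list(gt.tree.preorder_node_iter())
    nd = nodes[event.node_index]
    children = nd.child_nodes()
    leaf_sets = []
    for ch in children:
        leaves = [ch] if ch.is_leaf() else list(ch.leaf_iter())
        by_taxon: dict[str, list] = {}
        for lf in leaves:
            by_taxon.setdefault(lf.taxon_name, []).append(lf.gene_id)
        leaf_sets.append(by_taxon)
    pairs = []
    for i in range(len(children)):
        for j in range(i + 1, len(children)):
            for taxon in sorted(set(leaf_sets[i]) & set(leaf_sets[j])):
                for g1 in leaf_sets[i][taxon]:
                    for g2 in leaf_sets[j][taxon]:
                        pairs.append((taxon, g1, g2))
    return pairs


def paralog_ks_node_based(gt: GeneTree, events, og: Orthogroup,
                          window=DEFAULT_KS_WINDOW,
                          summary: str = "median",
                          restrict_taxon: str | None = None) -> list[float]:
    """DupPipe-style ages: one Ks per duplication node (median over its
    same-taxon cross-subtree pairs; mean available by flag). Nodes with no
    estimable pair are skipped. ``restrict_taxon`` limits the contributing
    pairs to one taxon's paralogs (per-taxon distributions)."""
    if summary not in ("median", "mean"):
        raise ValidationError(f"unknown summary {summary!r}")
    out = []
    for ev in events:
        vals = []
        for taxon, g1, g2 in node_paralog_pairs(gt, ev):
            if restrict_taxon is not None and taxon != restrict_taxon:
                continue
            try:
                s1 = og.sequences[(taxon, g1)]
                s2 = og.sequences[(taxon, g2)]
                r = ks_ng86(s1, s2)
            except (KeyError, ValueError):
                continue
            if not r.saturated:
                vals.append(r.ks)
        if vals:
            out.append(float(np.median(vals) if summary == "median"
                             else np.mean(vals)))
    return out


def node_ks_distribution(tree_event_og_triples, source: str,
                         window=DEFAULT_KS_WINDOW,
                         summary: str = "median",
                         restrict_taxon: str | None = None) -> KsDistribution:
    values = []
    for gt, events, og in tree_event_og_triples:
        values.extend(paralog_ks_node_based(gt, events, og, window, summary,
                                            restrict_taxon))
    return KsDistribution.from_values(values, "node", source, window)


# ---------------------------------------------------------------------------
# mixture models


@dataclass
class MixtureFit:
    """1..k_max univariate Gaussian mixtures with per-k BIC; min-BIC wins."""

    n: int
    fits: dict[int, dict] = field(default_factory=dict)
    selected_k: int = 0
    log_scale: bool = False

    @property
    def selected(self) -> dict:
        return self.fits[self.selected_k]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "selected_k": self.selected_k,
            "log_scale": self.log_scale,
            "fits": {
                str(k): {key: (list(v) if isinstance(v, np.ndarray) else v)
                         for key, v in fit.items()}
                for k, fit in self.fits.items()
            },
        }


def fit_mixture(dist: KsDistribution | np.ndarray, k_max: int = 4,
                seed: int = 0, n_init: int = 10,
                log_scale: bool = False) -> MixtureFit:
    """EM-fitted Gaussian mixtures for k = 1..k_max, selected by BIC.

    BIC = p ln(n) - 2 lnL with p = 3k - 1 free parameters, which is what
    scikit-learn reports for a one-dimensional full-covariance mixture.
    Each k gets ``n_init`` k-means++-seeded restarts.
    """
    values = dist.values if isinstance(dist, KsDistribution) else np.asarray(dist, float)
    if len(values) < 20:
        raise InsufficientDataError(
            f"insufficient data: {len(values)} Ks values (< 20)"
        )
    x = np.log(values) if log_scale else values
    X = x.reshape(-1, 1)
    result = MixtureFit(n=len(values), log_scale=log_scale)
    best_bic = math.inf
    for k in range(1, k_max + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=n_init, init_params="k-means++",
                             max_iter=500, random_state=seed)
        gm.fit(X)
        order = np.argsort(gm.means_.ravel())
        weights = gm.weights_.ravel()[order]
        means = gm.means_.ravel()[order]
        sds = np.sqrt(gm.covariances_.reshape(-1)[order])
        loglik = float(gm.score(X) * len(X))
        bic = float(gm.bic(X))
        result.fits[k] = {
            "weights": weights, "means": means, "sds": sds,
            "log_likelihood": loglik, "bic": bic,
            "converged": bool(gm.converged_),
        }
        if bic < best_bic:
            best_bic = bic
            result.selected_k = k
    return result


def dominant_component(fit: MixtureFit) -> tuple[float, float, float]:
    """(mean, sd, weight) of the heaviest component of the selected model."""
    sel = fit.selected
    i = int(np.argmax(sel["weights"]))
    return float(sel["means"][i]), float(sel["sds"][i]), float(sel["weights"][i])


def plot_distribution(dist: KsDistribution, fit: MixtureFit | None,
                      path: str, bins: int = 40):
    """Histogram of a Ks distribution with the fitted mixture density."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(dist.values, bins=bins, density=True, color="0.7",
            edgecolor="white")
    if fit is not None:
        xs = np.linspace(dist.window[0], dist.window[1], 400)
        sel = fit.selected
        total = np.zeros_like(xs)
        for w, m, s in zip(sel["weights"], sel["means"], sel["sds"]):
            total += w * norm.pdf(xs, m, s)
        ax.plot(xs, total, color="C3", lw=1.5)
    ax.set_xlabel("Ks")
    ax.set_ylabel("density")
    ax.set_title(f"{dist.source} ({dist.mode}, n={len(dist)})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
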