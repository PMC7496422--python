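"""Ortholog-divergence bookending of candidate whole-genome duplications.

A candidate WGD has a paralog-age peak (Ks). For a pair of species, the
ortholog-divergence peak estimates when they split. If the split is older
(larger Ks) than the paralog peak, the two species cannot share the event;
if younger, they must. Verdicts within a margin ``delta`` of equality are
ambiguous -- the classic degenerate case of an event coeval with a
speciation. Competing placement hypotheses (species-tree nodes) are scored
against the verdict table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ks_engine import (InsufficientDataError, KsDistribution, fit_mixture,
                        ks_ng86, DEFAULT_KS_WINDOW)
from .orthogroup_filtering import ValidationError
from .trees_io import SpeciesTree

DEFAULT_DELTA = 0.05


@dataclass
class OrthologDivergence:
    taxon_a: str
    taxon_b: str
    distribution: KsDistribution
    peak_median: float
    peak_mixture_mean: float | None

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.taxon_a, self.taxon_b)))


@dataclass
class WGDCandidate:
    name: str                           # e.g. "Th-alpha"-style label
    focal_taxa: tuple[str, ...]
    paralog_peak: float
    paralog_peak_sd: float = float("nan")
    evidence: dict = field(default_factory=dict)   # tally / pairwise / node flags

    def __post_init__(self):
        if not self.paralog_peak > 0:
            raise ValidationError("paralog peak must be positive")


@dataclass
class BookendVerdict:
    candidate: str
    taxon_a: str
    taxon_b: str
    ortholog_peak: float
    paralog_peak: float
    delta: float
    verdict: str                        # shared | not_shared | ambiguous


@dataclass
class PlacementHypothesis:
    label: str
    node_id: str

    def implied_pattern(self, sp: SpeciesTree, pairs) -> dict:
        """shared iff both taxa descend from the hypothesis node."""
        clade = sp.leaf_taxa(self.node_id)
        return {
            tuple(sorted(p)): ("shared" if p[0] in clade and p[1] in clade
                               else "not_shared")
            for p in pairs
        }


def ortholog_divergence(taxon_a: str, taxon_b: str, orthogroups,
                        window=DEFAULT_KS_WINDOW,
                        min_orthogroups: int = 20) -> OrthologDivergence:
    """Cross-taxon ortholog Ks peak for one species pair.

    Per orthogroup containing both taxa, the minimum-Ks cross-taxon pair is
    taken as the putative ortholog pair (duplicate retention makes larger
    cross-taxon Ks values paralog comparisons). The peak is the median of
    the windowed values; the 1-component mixture mean is also reported.
    """
    if taxon_a == taxon_b:
        raise ValidationError("ortholog divergence needs two distinct taxa")
    values = []
    n_shared = 0
    for og in orthogroups:
        seqs_a = og.sequences_for(taxon_a)
        seqs_b = og.sequences_for(taxon_b)
        if not seqs_a or not seqs_b:
            continue
        n_shared += 1
        best = None
        for sa in seqs_a.values():
            for sb in seqs_b.values():
                try:
                    r = ks_ng86(sa, sb)
                except ValueError:
                    continue
                if not r.saturated and (best is None or r.ks < best):
                    best = r.ks
        if best is not None:
            values.append(best)
    if n_shared < min_orthogroups:
        raise InsufficientDataError(
            f"insufficient data: only {n_shared} orthogroups contain both "
            f"{taxon_a} and {taxon_b} (< {min_orthogroups})"
        )
    dist = KsDistribution.from_values(
        values, "pairwise", f"{min(taxon_a, taxon_b)}--{max(taxon_a, taxon_b)}",
        window,
    )
    if len(dist) == 0:
        raise InsufficientDataError(
            f"no ortholog Ks values inside the window for {dist.source}"
        )
    mixture_mean = None
    try:
        fit = fit_mixture(dist, k_max=1, seed=0)
        mixture_mean = float(fit.fits[1]["means"][0])
    except InsufficientDataError:
        pass
    return OrthologDivergence(
        taxon_a=taxon_a, taxon_b=taxon_b, distribution=dist,
        peak_median=dist.median, peak_mixture_mean=mixture_mean,
    )


def bookend(candidate: WGDCandidate, div: OrthologDivergence,
            delta: float = DEFAULT_DELTA) -> BookendVerdict:
    """Ortholog peak older than the paralog peak by > delta: not shared;
    younger by > delta: shared; otherwise ambiguous."""
    ortho, para = div.peak_median, candidate.paralog_peak
    if not (np.isfinite(ortho) and np.isfinite(para)):
        raise ValidationError("bookend requires finite peaks")
    if ortho - para > delta:
        verdict = "not_shared"
    elif para - ortho > delta:
        verdict = "shared"
    else:
        verdict = "ambiguous"
    return BookendVerdict(
        candidate=candidate.name, taxon_a=div.taxon_a, taxon_b=div.taxon_b,
        ortholog_peak=ortho, paralog_peak=para, delta=delta, verdict=verdict,
    )


def evaluate_hypotheses(hypotheses, verdicts, tally, sp: SpeciesTree,
                        delta: float = DEFAULT_DELTA) -> dict:
    """Rank placement hypotheses by agreement with the verdict table.

    Score = fraction of non-ambiguous verdicts matching the hypothesis'
    implied shared/not-shared pattern; ties are broken by the duplication
    tally at the hypothesis node. Hypotheses with identical implied
    patterns over the sampled pairs are flagged as degenerate (they cannot
    be distinguished by bookending -- e.g. one clade-wide event vs. two
    coeval events), as are distinct hypotheses whose scores tie.
    """
    pairs = sorted({tuple(sorted((v.taxon_a, v.taxon_b))) for v in verdicts})
    rows = []
    patterns = {}
    for hyp in hypotheses:
        if hyp.node_id not in sp.node_ids:
            raise ValidationError(f"hypothesis node {hyp.node_id!r} not in species tree")
        pattern = hyp.implied_pattern(sp, pairs)
        patterns[hyp.label] = pattern
        usable = [v for v in verdicts if v.verdict != "ambiguous"]
        if usable:
            matches = sum(
                1 for v in usable
                if pattern[tuple(sorted((v.taxon_a, v.taxon_b)))] == v.verdict
            )
            score = matches / len(usable)
        else:
            score = 0.0
        count = tally.counts.get(hyp.node_id, 0) if tally is not None else 0
        rows.append({
            "label": hyp.label,
            "node_id": hyp.node_id,
            "pattern_score": score,
            "tally": count,
            "implied_pattern": {f"{a}--{b}": s for (a, b), s in pattern.items()},
        })
    rows.sort(key=lambda r: (-r["pattern_score"], -r["tally"], r["label"]))

    degenerate_groups = []
    by_pattern: dict[tuple, list[str]] = {}
    for label, pattern in patterns.items():
        key = tuple(sorted(pattern.items()))
        by_pattern.setdefault(key, []).append(label)
    for labels in by_pattern.values():
        if len(labels) > 1:
            degenerate_groups.append(sorted(labels))

    tied_top = [r["label"] for r in rows
                if rows and r["pattern_score"] == rows[0]["pattern_score"]]
    notes = []
    if degenerate_groups:
        notes.append(
            "indistinguishable implied patterns (a single clade-wide event "
            "cannot be told from coeval independent events): "
            + "; ".join(", ".join(g) for g in sorted(degenerate_groups))
        )
    if len(tied_top) > 1:
        notes.append("top hypotheses tie on pattern score: "
                     + ", ".join(sorted(tied_top)))
    return {
        "ranking": rows,
        "n_verdicts": len(verdicts),
        "n_ambiguous": sum(1 for v in verdicts if v.verdict == "ambiguous"),
        "degenerate_groups": sorted(degenerate_groups),
        "notes": notes,
    }
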