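import numpy as np
import pytest

from wgdplacer import (PlacementHypothesis, SimConfig, WGDCandidate,
                       WGDEpisode, bookend, evaluate_hypotheses,
                       ortholog_divergence, simulate_families)
from wgdplacer.duplication_mapping import DuplicationTally
from wgdplacer.ks_engine import InsufficientDataError
from wgdplacer.orthogroup_filtering import ValidationError
from wgdplacer.wgd_inference import BookendVerdict, OrthologDivergence


def _div(peak, a="X", b="Y"):
    from wgdplacer.ks_engine import KsDistribution
    dist = KsDistribution.from_values([peak], "pairwise", f"{a}--{b}",
                                      window=(0.0, 10.0))
    return OrthologDivergence(a, b, dist, peak_median=peak,
                              peak_mixture_mean=peak)


def _candidate(peak, name="W"):
    return WGDCandidate(name=name, focal_taxa=("X",), paralog_peak=peak)


class TestBookendRule:
    @pytest.mark.parametrize("ortho,para,verdict", [
        (0.7, 0.4, "not_shared"),
        (0.2, 0.4, "shared"),
        (0.41, 0.40, "ambiguous"),
    ])
    def test_rule_examples(self, ortho, para, verdict):
        v = bookend(_candidate(para), _div(ortho), delta=0.05)
        assert v.verdict == verdict

    def test_monotone_in_ortholog_peak(self):
        """Raising the ortholog peak can only move the verdict along
        shared -> ambiguous -> not_shared."""
        order = {"shared": 0, "ambiguous": 1, "not_shared": 2}
        prev = -1
        for ortho in np.linspace(0.1, 0.9, 30):
            v = bookend(_candidate(0.4), _div(float(ortho)), delta=0.05)
            assert order[v.verdict] >= prev
            prev = order[v.verdict]

    def test_infinite_peak_rejected(self):
        with pytest.raises(ValidationError):
            bookend(_candidate(0.4), _div(float("inf")))


@pytest.fixture(scope="module")
def sim():
    cfg = SimConfig(n_families=40, seed=21, codon_length=200,
                    duplication_rate=0.0, loss_rate=0.0,
                    rate_noise_sigma=0.0)
    return simulate_families(cfg)


class TestOrthologDivergence:
    def test_sister_pair_recovers_split_ks(self, sim):
        # A and B diverge at Ks 0.30 on the bundled species tree
        div = ortholog_divergence("A", "B", sim.orthogroups.values())
        assert div.peak_median == pytest.approx(0.30, abs=0.03)

    def test_symmetry(self, sim):
        ab = ortholog_divergence("A", "B", sim.orthogroups.values())
        ba = ortholog_divergence("B", "A", sim.orthogroups.values())
        assert ab.peak_median == ba.peak_median

    def test_same_taxon_rejected(self, sim):
        with pytest.raises(ValidationError):
            ortholog_divergence("A", "A", sim.orthogroups.values())

    def test_insufficient_orthogroups(self, sim):
        few = list(sim.orthogroups.values())[:5]
        with pytest.raises(InsufficientDataError):
            ortholog_divergence("A", "B", few)


class TestHypotheses:
    def _tally(self, sp, counts):
        full = {n: 0 for n in sp.node_ids}
        full.update(counts)
        return DuplicationTally(counts=full, min_support=80.0)

    def _verdict(self, a, b, verdict, para=0.4):
        ortho = {"shared": para - 0.2, "not_shared": para + 0.2,
                 "ambiguous": para + 0.01}[verdict]
        return BookendVerdict("W", a, b, ortho, para, 0.05, verdict)

    def test_true_node_ranks_first(self, species_tree):
        verdicts = [self._verdict("A", "B", "shared"),
                    self._verdict("A", "C", "not_shared"),
                    self._verdict("A", "D", "not_shared")]
        hyps = [PlacementHypothesis("H1", "ab"),
                PlacementHypothesis("H2", "abc"),
                PlacementHypothesis("H3", "abcde"),
                PlacementHypothesis("H4", "A")]
        report = evaluate_hypotheses(hyps, verdicts,
                                     self._tally(species_tree, {"ab": 30}),
                                     species_tree)
        assert report["ranking"][0]["label"] == "H1"
        assert report["ranking"][0]["pattern_score"] == 1.0

    def test_all_ambiguous_ties_at_zero_and_is_reported(self, species_tree):
        verdicts = [self._verdict("A", "B", "ambiguous"),
                    self._verdict("A", "C", "ambiguous")]
        hyps = [PlacementHypothesis("H1", "ab"),
                PlacementHypothesis("H2", "abc")]
        report = evaluate_hypotheses(hyps, verdicts,
                                     self._tally(species_tree, {}),
                                     species_tree)
        scores = {r["label"]: r["pattern_score"] for r in report["ranking"]}
        assert scores == {"H1": 0.0, "H2": 0.0}
        assert any("tie" in note for note in report["notes"])

    def test_identical_patterns_flagged_degenerate(self, species_tree):
        # over the single sampled pair (A, B) a WGD at "ab" and one at
        # "abc" imply the same shared pattern
        verdicts = [self._verdict("A", "B", "shared")]
        hyps = [PlacementHypothesis("H1", "ab"),
                PlacementHypothesis("H2", "abc")]
        report = evaluate_hypotheses(hyps, verdicts,
                                     self._tally(species_tree, {}),
                                     species_tree)
        assert ["H1", "H2"] in report["degenerate_groups"]

    def test_unknown_hypothesis_node_rejected(self, species_tree):
        with pytest.raises(ValidationError):
            evaluate_hypotheses([PlacementHypothesis("H1", "zzz")], [],
                                self._tally(species_tree, {}), species_tree)

    def test_end_to_end_simulation_ranks_true_node_first(self, species_tree):
        from wgdplacer import find_duplication_nodes, map_gene_trees, tally
        from wgdplacer.ks_engine import node_ks_distribution, fit_mixture
        from wgdplacer.ks_engine import dominant_component
        cfg = SimConfig(n_families=60, seed=22, codon_length=200,
                        duplication_rate=0.05, loss_rate=0.05,
                        wgd_episodes=(WGDEpisode("ab", 0.7),))
        res = simulate_families(cfg)
        events, _ = map_gene_trees(res.gene_trees.values(), res.species_tree)
        counts = tally(events, res.species_tree, 80.0)
        assert counts.argmax() == "ab"

        triples = []
        for og_id, gt in res.gene_trees.items():
            evs = [e for e in find_duplication_nodes(gt)
                   if "A" in e.shared_taxa]
            if evs:
                triples.append((gt, evs, res.orthogroups[og_id]))
        node_dist = node_ks_distribution(triples, "A", restrict_taxon="A")
        fit = fit_mixture(node_dist, seed=22)
        peak, _, _ = dominant_component(fit)
        cand = WGDCandidate("W", ("A",), paralog_peak=peak)

        verdicts = []
        for other in ("B", "C", "D"):
            div = ortholog_divergence("A", other, res.orthogroups.values())
            verdicts.append(bookend(cand, div))
        hyps = [PlacementHypothesis("H1", "ab"),
                PlacementHypothesis("H2", "abc"),
                PlacementHypothesis("H3", "abcde"),
                PlacementHypothesis("H4", "A")]
        report = evaluate_hypotheses(hyps, verdicts, counts, res.species_tree)
        assert report["ranking"][0]["label"] == "H1"
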