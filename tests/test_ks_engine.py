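import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import (SENSE, oracle_diff_counts, oracle_syn_sites,
                     stop_path_exists)

from wgdplacer import (Orthogroup, fit_mixture, ks_ng86, parse_newick,
                       paralog_ks_node_based, paralog_pairs_pairwise,
                       find_duplication_nodes)
from wgdplacer.ks_engine import (InsufficientDataError, KsDistribution,
                                 _jc_correct)


class TestNG86:
    def test_identical_sequences_are_zero(self):
        seq = "ATGGCTGCTAAAGCTGCTGCTGCTGCTGCTGCT"[:30]
        r = ks_ng86(seq, seq)
        assert r.ks == 0.0 and r.ka == 0.0

    def test_worked_example_single_synonymous_change(self):
        # 10 glycine codons; one third-position change GGT->GGC
        s1 = "GGT" * 10
        s2 = "GGC" + "GGT" * 9
        r = ks_ng86(s1, s2)
        assert r.S == pytest.approx(10.0)
        assert r.sd == pytest.approx(1.0)
        assert r.ps == pytest.approx(0.1)
        assert r.ks == pytest.approx(0.1073, abs=5e-5)

    def test_symmetry_over_random_pairs(self, rng):
        for _ in range(100):
            idx1 = rng.integers(0, 61, 30)
            idx2 = rng.integers(0, 61, 30)
            s1 = "".join(SENSE[i] for i in idx1)
            s2 = "".join(SENSE[i] for i in idx2)
            a = ks_ng86(s1, s2)
            b = ks_ng86(s2, s1)
            assert a.ks == b.ks and a.S == b.S and a.sd == b.sd

    def test_saturated_pair_flagged_infinite(self):
        r = ks_ng86("GGA" * 20, "GGC" * 20)  # every syn site differs
        assert r.saturated and math.isinf(r.ks)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop codon"):
            ks_ng86("TAA" + "GGT" * 9, "GGT" * 10)

    def test_too_few_comparable_codons(self):
        with pytest.raises(InsufficientDataError):
            ks_ng86("GGT" * 5, "GGT" * 5)

    def test_gapped_codons_masked(self):
        s1 = "---" + "GGT" * 10
        s2 = "GGT" + "GGT" * 10
        assert ks_ng86(s1, s2).n_codons == 10

    def test_site_counts_match_oracle_for_all_codons(self):
        from wgdplacer.codons import CODON_INDEX, ng86_site_counts
        sites = ng86_site_counts()
        for codon in SENSE:
            assert sites[CODON_INDEX[codon]] == pytest.approx(
                oracle_syn_sites(codon), abs=1e-12), codon

    def test_biopython_cross_check_on_stop_free_pairs(self, rng):
        """NG86 dS agrees with Bio.codonalign on codon pairs whose mutation
        paths avoid stop codons (Biopython averages over stop-crossing
        paths, classic NG86 excludes them)."""
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        checked = 0
        while checked < 20:
            idx1 = rng.integers(0, 61, 40)
            idx2 = rng.integers(0, 61, 40)
            pairs = [(SENSE[i], SENSE[j]) for i, j in zip(idx1, idx2)]
            if any(stop_path_exists(a, b) for a, b in pairs):
                continue
            s1 = "".join(p[0] for p in pairs)
            s2 = "".join(p[1] for p in pairs)
            r = ks_ng86(s1, s2)
            if r.saturated:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dn, ds = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
            assert r.ks == pytest.approx(ds, abs=1e-6)
            checked += 1

    @given(st.floats(0.0, 0.74))
    @settings(max_examples=100, deadline=None)
    def test_jc_correction_strictly_increasing(self, p):
        eps = 1e-6
        if p + eps < 0.75:
            assert _jc_correct(p + eps) > _jc_correct(p)


class TestPairs:
    def _og(self, copies):
        seqs = {("A", f"g{i}"): "GGT" * 10 for i in range(1, copies + 1)}
        seqs[("B", "g1")] = "GGT" * 10
        return Orthogroup("og", seqs)

    def test_three_copies_give_three_pairs(self):
        assert len(paralog_pairs_pairwise(self._og(3), "A")) == 3

    def test_single_copy_gives_none(self):
        assert paralog_pairs_pairwise(self._og(1), "A") == []

    def test_counts_match_binomial(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 8))
            pairs = paralog_pairs_pairwise(self._og(n), "A")
            assert len(pairs) == n * (n - 1) // 2


class TestNodeKs:
    def test_single_cross_pair_gives_its_ks(self):
        gt = parse_newick("(B|g1,(A|g1,A|g2)90);")
        og = Orthogroup("og", {
            ("A", "g1"): "GGT" * 20,
            ("A", "g2"): "GGC" * 5 + "GGT" * 15,
            ("B", "g1"): "GGT" * 20,
        })
        events = find_duplication_nodes(gt)
        values = paralog_ks_node_based(gt, events, og, window=(0.0, 5.0))
        expected = ks_ng86("GGT" * 20, "GGC" * 5 + "GGT" * 15).ks
        assert values == [pytest.approx(expected)]

    def test_node_value_is_median_of_cross_pairs(self):
        gt = parse_newick("(B|g1,((A|g1,A|g2),A|g3)90);")
        og = Orthogroup("og", {
            ("A", "g1"): "GGT" * 20,
            ("A", "g2"): "GGC" * 2 + "GGT" * 18,
            ("A", "g3"): "GGC" * 6 + "GGT" * 14,
            ("B", "g1"): "GGT" * 20,
        })
        events = find_duplication_nodes(gt)
        assert len(events) == 2
        # outer A node spans pairs (g1,g3),(g2,g3); inner node spans (g1,g2)
        values = paralog_ks_node_based(gt, events, og, window=(0.0, 5.0))
        k13 = ks_ng86(og.sequences[("A", "g1")], og.sequences[("A", "g3")]).ks
        k23 = ks_ng86(og.sequences[("A", "g2")], og.sequences[("A", "g3")]).ks
        k12 = ks_ng86(og.sequences[("A", "g1")], og.sequences[("A", "g2")]).ks
        assert sorted(values) == pytest.approx(
            sorted([np.median([k13, k23]), k12]))

    def test_node_mode_never_larger_than_pairwise(self, rng):
        from wgdplacer import SimConfig, WGDEpisode, simulate_families
        from wgdplacer.ks_engine import pairwise_ks_distribution
        res = simulate_families(SimConfig(
            n_families=25, seed=5, codon_length=60,
            wgd_episodes=(WGDEpisode("ab", 0.8),)))
        window = (0.0, 10.0)
        for taxon in ("A", "B"):
            pw = pairwise_ks_distribution(res.orthogroups.values(), taxon,
                                          window)
            node_vals = []
            for og_id, gt in res.gene_trees.items():
                events = find_duplication_nodes(gt)
                node_vals.extend(paralog_ks_node_based(
                    gt, events, res.orthogroups[og_id], window,
                    restrict_taxon=taxon))
            assert len(node_vals) <= len(pw)


class TestMixture:
    def test_single_component_recovered(self):
        rng = np.random.default_rng(1)
        fit = fit_mixture(rng.normal(0.4, 0.05, 500), seed=1)
        assert fit.selected_k == 1
        assert fit.selected["means"][0] == pytest.approx(0.4, abs=0.02)

    def test_two_components_recovered(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0.1, 0.02, 250),
                            rng.normal(0.4, 0.03, 250)])
        fit = fit_mixture(x, seed=2)
        assert fit.selected_k == 2
        assert fit.selected["means"] == pytest.approx([0.1, 0.4], abs=0.02)

    def test_weights_sum_to_one_and_bic_is_minimal(self):
        rng = np.random.default_rng(3)
        fit = fit_mixture(rng.normal(0.3, 0.05, 200), seed=3)
        for k, entry in fit.fits.items():
            assert entry["weights"].sum() == pytest.approx(1.0, abs=1e-9)
        best = fit.fits[fit.selected_k]["bic"]
        assert all(best <= e["bic"] for e in fit.fits.values())

    def test_bic_formula_matches_definition(self):
        rng = np.random.default_rng(4)
        fit = fit_mixture(rng.normal(0.3, 0.05, 100), seed=4)
        for k, entry in fit.fits.items():
            p = 3 * k - 1
            expected = p * np.log(fit.n) - 2.0 * entry["log_likelihood"]
            assert entry["bic"] == pytest.approx(expected, rel=1e-9)

    def test_insufficient_data_raises(self):
        with pytest.raises(InsufficientDataError, match="insufficient"):
            fit_mixture(np.linspace(0.1, 0.5, 19))

    def test_distribution_windowing_drops_tandem_peak_and_saturation(self):
        values = [0.001, 0.005, 0.3, 0.4, 2.5, float("inf")]
        dist = KsDistribution.from_values(values, "pairwise", "A",
                                          window=(0.01, 2.0))
        assert list(dist.values) == [0.3, 0.4]
        assert dist.n_raw == 6
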