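import numpy as np
import pytest

from wgdplacer import (SimConfig, WGDEpisode, emit_codon_pairs, ks_ng86,
                       simulate_families)
from wgdplacer.codons import STOP_CODONS
from wgdplacer.synthetic_data import DEFAULT_SPECIES_TREE


def _codons(seq):
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


class TestGeneTreeShapes:
    def test_no_events_reproduces_species_tree(self, species_tree):
        cfg = SimConfig(duplication_rate=0.0, loss_rate=0.0, n_families=5,
                        rate_noise_sigma=0.0, seed=1, codon_length=30)
        res = simulate_families(cfg, with_sequences=False)
        for gt in res.gene_trees.values():
            labels = sorted(lf.taxon_name for lf in gt.leaves())
            assert labels == sorted(species_tree.taxa)
            # one copy per taxon and species-tree topology
            sp_splits = {
                frozenset(species_tree.leaf_taxa(n))
                for n in species_tree.node_ids
                if not species_tree.node(n).is_leaf()
            }
            gt_splits = {
                gt.node_taxa(nd)
                for nd in gt.tree.preorder_node_iter() if not nd.is_leaf()
            }
            assert gt_splits <= sp_splits

    def test_full_retention_wgd_doubles_descendant_taxa(self):
        cfg = SimConfig(duplication_rate=0.0, loss_rate=0.0, n_families=10,
                        rate_noise_sigma=0.0, seed=2, codon_length=30,
                        wgd_episodes=(WGDEpisode("ab", 1.0),))
        res = simulate_families(cfg, with_sequences=False)
        for gt in res.gene_trees.values():
            counts = {}
            for lf in gt.leaves():
                counts[lf.taxon_name] = counts.get(lf.taxon_name, 0) + 1
            assert counts["A"] == 2 and counts["B"] == 2
            assert all(counts[t] == 1 for t in counts if t not in "AB")

    def test_wgd_duplications_map_to_episode_node(self, species_tree):
        from wgdplacer import map_gene_trees, tally
        cfg = SimConfig(duplication_rate=0.0, loss_rate=0.0, n_families=10,
                        rate_noise_sigma=0.0, seed=3, codon_length=30,
                        wgd_episodes=(WGDEpisode("ab", 1.0),))
        res = simulate_families(cfg, with_sequences=False)
        events, skipped = map_gene_trees(res.gene_trees.values(), species_tree)
        assert not skipped
        assert len(events) == 10
        assert {ev.species_node_id for ev in events} == {"ab"}

    def test_noiseless_path_lengths_match_truth(self):
        """Pairwise path sums in the emitted newick (independent oracle:
        dendropy's phylogenetic distance matrix) equal SimTruth Ks."""
        cfg = SimConfig(duplication_rate=0.3, loss_rate=0.1, n_families=8,
                        rate_noise_sigma=0.0, seed=4, codon_length=30,
                        wgd_episodes=(WGDEpisode("ab", 0.5),))
        res = simulate_families(cfg, with_sequences=False)
        for fam in res.truth.families:
            truth = fam.pairwise_ks()
            gt = res.gene_trees[fam.orthogroup_id]
            pdm = gt.tree.phylogenetic_distance_matrix()
            for (la, lb), ks in truth.items():
                ta = gt.tree.taxon_namespace.get_taxon(f"{la[0]}|{la[1]}")
                tb = gt.tree.taxon_namespace.get_taxon(f"{lb[0]}|{lb[1]}")
                assert pdm.patristic_distance(ta, tb) == pytest.approx(
                    ks, abs=1e-9)

    def test_extinct_world_exhausts_retry_budget(self):
        cfg = SimConfig(duplication_rate=0.0, loss_rate=50.0, n_families=2,
                        seed=5, codon_length=30)
        with pytest.raises(RuntimeError, match="retry budget"):
            simulate_families(cfg, with_sequences=False)


class TestDeterminismAndNeutrality:
    def _render(self, res):
        trees = {k: t.write() for k, t in res.gene_trees.items()}
        seqs = {k: dict(o.sequences) for k, o in res.orthogroups.items()}
        return trees, seqs

    def test_same_config_same_bytes(self):
        cfg = SimConfig(n_families=10, seed=6, codon_length=40,
                        wgd_episodes=(WGDEpisode("ab", 0.5),))
        a = self._render(simulate_families(cfg))
        b = self._render(simulate_families(cfg))
        assert a == b

    def test_zero_retention_equals_no_episode_run(self):
        base = dict(n_families=10, seed=7, codon_length=40)
        res_r0 = simulate_families(SimConfig(
            wgd_episodes=(WGDEpisode("ab", 0.0),), **base))
        res_none = simulate_families(SimConfig(**base))
        assert self._render(res_r0) == self._render(res_none)

    def test_family_counts_reconcile(self):
        cfg = SimConfig(n_families=15, seed=8, codon_length=30)
        res = simulate_families(cfg, with_sequences=False)
        assert len(res.truth.families) == 15
        assert sorted(res.gene_trees) == sorted(
            f.orthogroup_id for f in res.truth.families)


class TestSequences:
    def test_target_zero_gives_identical_pair(self):
        (a, b), = emit_codon_pairs([0.0], 50, seed=9)
        assert a == b

    def test_no_stop_codons_ever(self):
        cfg = SimConfig(n_families=10, seed=10, codon_length=50,
                        wgd_episodes=(WGDEpisode("ab", 0.8),))
        res = simulate_families(cfg)
        for og in res.orthogroups.values():
            for seq in og.sequences.values():
                assert not set(_codons(seq)) & STOP_CODONS
        for a, b in emit_codon_pairs([0.2, 0.5, 1.0], 100, seed=11):
            assert not set(_codons(a)) & STOP_CODONS
            assert not set(_codons(b)) & STOP_CODONS

    def test_estimator_recovers_target_quickly(self):
        pairs = emit_codon_pairs([0.4] * 60, 300, seed=12)
        ests = [ks_ng86(a, b).ks for a, b in pairs]
        assert np.mean(ests) == pytest.approx(0.4, abs=0.05)

    def test_unreachable_target_flagged(self):
        with pytest.raises(ValueError, match="unreachable"):
            emit_codon_pairs([-0.1], 50, seed=13)

    def test_uniform_bootstrap_supports_in_range(self):
        cfg = SimConfig(n_families=5, seed=14, codon_length=30,
                        bootstrap_support=("uniform", 40.0, 90.0),
                        duplication_rate=0.3)
        res = simulate_families(cfg, with_sequences=False)
        sups = [
            nd.edge.support
            for gt in res.gene_trees.values()
            for nd in gt.tree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]
        assert sups and all(40.0 <= s <= 90.0 for s in sups)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(codon_length=10)
        with pytest.raises(ValueError):
            WGDEpisode("ab", 1.5)
        with pytest.raises(ValueError, match="unknown species node"):
            simulate_families(SimConfig(
                n_families=2, codon_length=30,
                wgd_episodes=(WGDEpisode("nope", 0.5),)))
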