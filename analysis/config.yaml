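# Desk-scale WGD-placement study: 8-taxon species tree (6 ingroup taxa,
# outgroups Og1/Og2), one WGD episode midway along the branch above node
# "ab" with 50% duplicate retention, background duplication/loss at
# 0.1 events per lineage per Ks unit, lognormal rate noise sigma = 0.1.
delimiter: '|'
taxon_index: 0
occupancy_fraction: 0.8
max_gap: 0.4
min_taxa: 4            # the world has 8 taxa; the 10-taxon default would
                       # reject everything at desk scale
per_sequence_gaps: false
min_support: 80.0
support_mode: node
outgroups: [Og1, Og2]
ks_min: 0.01
ks_max: 2.0
k_max: 4
ks_taxa: []
delta: 0.05
candidate_name: WGD-1
focal_taxon: A
peak_source: node
bookend_pairs:
- [A, B]
- [A, C]
- [A, D]
hypothesis_nodes:
  H1: ab        # on the branch above the A+B ancestor (the truth)
  H2: abc       # one node deeper
  H3: abcde     # deeper still
  H4: A         # private to A, after the A--B split
seed: 42
simulate:
  n_families: 300
  codon_length: 300
  duplication_rate: 0.1
  loss_rate: 0.1
  rate_noise_sigma: 0.1
  wgd_episodes:
  - {node_id: ab, retention: 0.5}
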