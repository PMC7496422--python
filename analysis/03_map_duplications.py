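#!/usr/bin/env python
"""Map gene-tree duplication nodes onto the species tree (PUG-style).

Gene trees (duplicates retained) are outgroup-rooted, duplication nodes
are mapped to the species-tree MRCA of their taxa, and counts are tallied
per node for duplication nodes with bootstrap support >= 80. The argmax
node is the phylogenomic WGD placement.
"""

import logging
from pathlib import Path

from wgdplacer import PipelineConfig
from wgdplacer.pipeline import stage_map_duplications

HERE = Path(__file__).resolve().parent
RUN_DIR = HERE.parent / "results" / "main_run"

logging.basicConfig(level=logging.INFO, format="%(message)s")
cfg = PipelineConfig.load(HERE / "config.yaml")
counts = stage_map_duplications(cfg, RUN_DIR)
top = sorted(counts, key=counts.get, reverse=True)[:3]
print("top duplication tallies:",
      ", ".join(f"{n}={counts[n]}" for n in top))
print(f"phylogenomic placement: node {top[0]}")
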