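#!/usr/bin/env python
"""Matrix hygiene: 80% taxon occupancy, <= 40% gaps, paralog pruning.

Mirrors the standard phylotranscriptomic cascade (at desk scale the
pruning cutoff is 4 taxa of 8). Orthogroups surviving occupancy + gaps
feed the duplication mapping; those also surviving pruning would be the
single-copy set used for species-tree inference.
"""

import logging
from pathlib import Path

from wgdplacer import PipelineConfig
from wgdplacer.pipeline import stage_filter

HERE = Path(__file__).resolve().parent
RUN_DIR = HERE.parent / "results" / "main_run"

logging.basicConfig(level=logging.INFO, format="%(message)s")
cfg = PipelineConfig.load(HERE / "config.yaml")
summary = stage_filter(cfg, RUN_DIR)
print("filter cascade "
      f"{summary['entering']} -> {summary['after_occupancy']} (occupancy) "
      f"-> {summary['after_gap']} (gaps) -> {summary['after_prune']} (pruned)")
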