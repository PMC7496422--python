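"""End-to-end orchestration: simulate -> filter -> map -> Ks -> mixtures ->
bookend -> hypotheses, with one YAML config and machine-readable reports.

Every stage is a pure function of (inputs on disk, config, seed); rerunning
with the same config reproduces all outputs byte-identically. Reports are
plain TSV/JSON; the manifest records the config hash, seed, library
versions, and a sha256 per report file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .duplication_mapping import find_duplication_nodes, map_gene_trees, tally
from .ks_engine import (InsufficientDataError, KsDistribution,
                        dominant_component, fit_mixture,
                        node_ks_distribution, pairwise_ks_distribution)
from .orthogroup_filtering import Orthogroup, run_filter_cascade
from .synthetic_data import (DEFAULT_OUTGROUPS, DEFAULT_SPECIES_TREE,
                             SimConfig, WGDEpisode, simulate_families)
from .trees_io import (GeneTree, LeafLabelScheme, SpeciesTree,
                       UnrootableError, root_with_outgroup)
from .wgd_inference import (PlacementHypothesis, WGDCandidate, bookend,
                            evaluate_hypotheses, ortholog_divergence)

log = logging.getLogger("wgdplacer.pipeline")

REPORT_FILES = (
    "filter_report.tsv",
    "duplication_tally.tsv",
    "ks_values.tsv",
    "mixtures.json",
    "bookend_verdicts.tsv",
    "hypotheses.json",
    "manifest.json",
)


@dataclass
class PipelineConfig:
    # leaf label scheme
    delimiter: str = "|"
    taxon_index: int = 0
    # filtering thresholds (defaults follow standard practice for this
    # kind of study: 80% occupancy, 40% gaps, 10-taxon pruning cutoff)
    occupancy_fraction: float = 0.80
    max_gap: float = 0.40
    min_taxa: int = 10
    per_sequence_gaps: bool = False
    # duplication mapping
    min_support: float | None = 80.0
    support_mode: str = "node"
    outgroups: list = field(default_factory=lambda: list(DEFAULT_OUTGROUPS))
    # Ks / mixtures
    ks_min: float = 0.01
    ks_max: float = 2.0
    k_max: int = 4
    ks_taxa: list = field(default_factory=list)   # empty: all ingroup taxa
    # bookending
    delta: float = 0.05
    candidate_name: str = "WGD-1"
    focal_taxon: str | None = None
    peak_source: str = "node"                     # node | pairwise
    bookend_pairs: list = field(default_factory=list)
    hypothesis_nodes: dict = field(default_factory=dict)  # label -> node_id
    # provenance
    seed: int = 0
    # optional simulation block; when present the pipeline generates its
    # own inputs under <run>/data
    simulate: dict | None = None

    def __post_init__(self):
        if not 0.0 < self.occupancy_fraction <= 1.0:
            raise ValueError("occupancy_fraction outside (0, 1]")
        if not 0.0 <= self.max_gap <= 1.0:
            raise ValueError("max_gap outside [0, 1]")
        if self.min_taxa < 1 or self.k_max < 1:
            raise ValueError("min_taxa and k_max must be >= 1")
        if self.ks_min >= self.ks_max:
            raise ValueError("ks_min must be < ks_max")
        if self.peak_source not in ("node", "pairwise"):
            raise ValueError(f"unknown peak_source {self.peak_source!r}")

    # -- serialization ----------------------------------------------------
    @property
    def scheme(self) -> LeafLabelScheme:
        return LeafLabelScheme(self.delimiter, self.taxon_index)

    @property
    def window(self) -> tuple[float, float]:
        return (self.ks_min, self.ks_max)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**(yaml.safe_load(text) or {}))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())

    def sim_config(self) -> SimConfig:
        block = dict(self.simulate or {})
        episodes = tuple(
            WGDEpisode(e["node_id"], float(e["retention"]))
            for e in block.pop("wgd_episodes", [])
        )
        block.setdefault("species_tree", DEFAULT_SPECIES_TREE)
        if "bootstrap_support" in block:
            block["bootstrap_support"] = tuple(block["bootstrap_support"])
        return SimConfig(wgd_episodes=episodes, seed=self.seed,
                         scheme=self.scheme, **block)


# ---------------------------------------------------------------------------
# run directory helpers


def _data_dir(run_dir: Path) -> Path:
    return Path(run_dir) / "data"


def _reports_dir(run_dir: Path) -> Path:
    d = Path(run_dir) / "reports"
    d.mkdir(parents=True, exist_ok=True)
    return d


def load_inputs(cfg: PipelineConfig, run_dir):
    """Read species tree, gene trees, and alignments from <run>/data."""
    data = _data_dir(Path(run_dir))
    sp = SpeciesTree.from_newick((data / "species_tree.nwk").read_text())
    scheme = cfg.scheme
    gene_trees: dict[str, GeneTree] = {}
    for path in sorted((data / "gene_trees").glob("*.nwk")):
        og_id = path.stem
        gene_trees[og_id] = GeneTree.from_newick(path.read_text(), scheme, og_id)
    orthogroups: dict[str, Orthogroup] = {}
    for path in sorted((data / "alignments").glob("*.fasta")):
        og_id = path.stem
        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            taxon, gene = scheme.split(rec.id)
            seqs[(taxon, gene)] = str(rec.seq)
        orthogroups[og_id] = Orthogroup(orthogroup_id=og_id, sequences=seqs)
    return sp, gene_trees, orthogroups


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, run_dir) -> dict:
    run_dir = Path(run_dir)
    data = _data_dir(run_dir)
    (data / "gene_trees").mkdir(parents=True, exist_ok=True)
    (data / "alignments").mkdir(parents=True, exist_ok=True)
    sim_cfg = cfg.sim_config()
    result = simulate_families(sim_cfg)
    (data / "species_tree.nwk").write_text(result.species_tree.write() + "\n")
    for og_id in sorted(result.gene_trees):
        (data / "gene_trees" / f"{og_id}.nwk").write_text(
            result.gene_trees[og_id].write() + "\n"
        )
    scheme = cfg.scheme
    for og_id in sorted(result.orthogroups):
        og = result.orthogroups[og_id]
        records = [
            SeqRecord(Seq(seq), id=scheme.join(taxon, gene), description="")
            for (taxon, gene), seq in sorted(og.sequences.items())
        ]
        SeqIO.write(records, str(data / "alignments" / f"{og_id}.fasta"),
                    "fasta")
    truth = {
        "episodes": [
            {"node_id": ep.node_id, "retention": ep.retention}
            for ep in result.truth.episodes
        ],
        "n_families": len(result.truth.families),
    }
    (data / "truth.json").write_text(json.dumps(truth, indent=2,
                                                sort_keys=True) + "\n")
    log.info("simulated %d families on %d taxa",
             len(result.truth.families), len(result.species_tree.taxa))
    return truth


def stage_filter(cfg: PipelineConfig, run_dir) -> dict:
    run_dir = Path(run_dir)
    sp, gene_trees, orthogroups = load_inputs(cfg, run_dir)
    pruned, survivors, report = run_filter_cascade(
        orthogroups, gene_trees, n_taxa=len(sp.taxa),
        occupancy_fraction=cfg.occupancy_fraction, max_gap=cfg.max_gap,
        min_taxa=cfg.min_taxa, per_sequence_gaps=cfg.per_sequence_gaps,
    )
    reports = _reports_dir(run_dir)
    df = pd.DataFrame(report.to_rows(), columns=["orthogroup_id", "fate"])
    df.to_csv(reports / "filter_report.tsv", sep="\t", index=False)
    summary = {
        "entering": report.entering,
        "after_occupancy": report.after_occupancy,
        "after_gap": report.after_gap,
        "after_prune": report.after_prune,
    }
    (reports / "filter_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (reports / "survivors.txt").write_text(
        "\n".join(sorted(survivors)) + "\n" if survivors else "")
    log.info("filter cascade: %d -> %d -> %d -> %d",
             report.entering, report.after_occupancy, report.after_gap,
             report.after_prune)
    return summary


def _rooted_survivor_trees(cfg: PipelineConfig, sp, gene_trees, survivors):
    rooted, skipped = {}, []
    for og_id in sorted(survivors):
        gt = gene_trees.get(og_id)
        if gt is None:
            skipped.append((og_id, "no_gene_tree"))
            continue
        try:
            rooted[og_id] = root_with_outgroup(gt, cfg.outgroups)
        except UnrootableError as exc:
            skipped.append((og_id, f"unrootable:{exc}"))
    return rooted, skipped


def _survivor_ids(run_dir) -> list[str]:
    path = _reports_dir(Path(run_dir)) / "survivors.txt"
    if not path.exists():
        raise FileNotFoundError("run the filter stage first")
    return [line for line in path.read_text().splitlines() if line]


def stage_map_duplications(cfg: PipelineConfig, run_dir) -> dict:
    run_dir = Path(run_dir)
    sp, gene_trees, _ = load_inputs(cfg, run_dir)
    survivors = _survivor_ids(run_dir)
    rooted, skipped = _rooted_survivor_trees(cfg, sp, gene_trees, survivors)
    events, dropped = map_gene_trees(rooted.values(), sp)
    counts = tally(events, sp, cfg.min_support, cfg.support_mode)
    reports = _reports_dir(run_dir)

    pd.DataFrame(
        [
            {
                "orthogroup_id": ev.orthogroup_id,
                "node_index": ev.node_index,
                "support": ev.support,
                "species_node_id": ev.species_node_id,
                "shared_taxa": ",".join(sorted(ev.shared_taxa)),
                "taxa": ",".join(sorted(ev.all_taxa)),
            }
            for ev in events
        ],
        columns=["orthogroup_id", "node_index", "support", "species_node_id",
                 "shared_taxa", "taxa"],
    ).to_csv(reports / "duplication_events.tsv", sep="\t", index=False)

    pd.DataFrame(
        [{"species_node_id": k, "count": counts.counts[k]}
         for k in sorted(counts.counts)],
    ).to_csv(reports / "duplication_tally.tsv", sep="\t", index=False)

    pd.DataFrame(skipped + dropped, columns=["orthogroup_id", "reason"]
                 ).to_csv(reports / "mapping_skips.tsv", sep="\t", index=False)

    annotated = sp.write()
    for node_id in sorted(counts.counts):
        annotated = annotated.replace(
            f"){node_id}", f"){node_id}_dups{counts.counts[node_id]}", 1)
    (reports / "species_tree_annotated.nwk").write_text(annotated + "\n")
    log.info("mapped %d events (%d counted at support >= %s) from %d trees",
             counts.n_events_considered, counts.n_events_counted,
             cfg.min_support, len(rooted))
    return {k: counts.counts[k] for k in sorted(counts.counts)}


def _ks_taxa(cfg: PipelineConfig, sp) -> list[str]:
    if cfg.ks_taxa:
        return list(cfg.ks_taxa)
    return sorted(sp.taxa - set(cfg.outgroups))


def stage_ks(cfg: PipelineConfig, run_dir) -> pd.DataFrame:
    run_dir = Path(run_dir)
    sp, gene_trees, orthogroups = load_inputs(cfg, run_dir)
    survivors = _survivor_ids(run_dir)
    ogs = [orthogroups[i] for i in survivors if i in orthogroups]
    rooted, _ = _rooted_survivor_trees(cfg, sp, gene_trees, survivors)
    rows = []
    for taxon in _ks_taxa(cfg, sp):
        dist = pairwise_ks_distribution(ogs, taxon, cfg.window)
        rows.extend({"mode": "pairwise", "source": taxon, "ks": v}
                    for v in dist.values)
        triples = []
        for og_id, gt in sorted(rooted.items()):
            if og_id not in orthogroups:
                continue
            events = [ev for ev in find_duplication_nodes(gt)
                      if taxon in ev.shared_taxa]
            if events:
                triples.append((gt, events, orthogroups[og_id]))
        node_dist = node_ks_distribution(triples, taxon, cfg.window,
                                         restrict_taxon=taxon)
        rows.extend({"mode": "node", "source": taxon, "ks": v}
                    for v in node_dist.values)
    df = pd.DataFrame(rows, columns=["mode", "source", "ks"])
    df.to_csv(_reports_dir(run_dir) / "ks_values.tsv", sep="\t", index=False,
              float_format="%.6f")
    log.info("Ks stage: %d values across %d distributions",
             len(df), df.groupby(["mode", "source"]).ngroups if len(df) else 0)
    return df


def stage_fit_mixtures(cfg: PipelineConfig, run_dir) -> dict:
    run_dir = Path(run_dir)
    reports = _reports_dir(run_dir)
    df = pd.read_csv(reports / "ks_values.tsv", sep="\t")
    out = {}
    for (mode, source), grp in sorted(df.groupby(["mode", "source"])):
        dist = KsDistribution.from_values(grp["ks"], mode, source, cfg.window)
        key = f"{mode}:{source}"
        try:
            fit = fit_mixture(dist, k_max=cfg.k_max, seed=cfg.seed)
        except InsufficientDataError as exc:
            out[key] = {"error": str(exc), "n": len(dist)}
            continue
        entry = fit.to_dict()
        mean, sd, weight = dominant_component(fit)
        entry["dominant_component"] = {"mean": mean, "sd": sd, "weight": weight}
        entry["median"] = dist.median
        out[key] = entry
    (reports / "mixtures.json").write_text(
        json.dumps(out, indent=2, sort_keys=True) + "\n")
    log.info("fitted mixtures for %d distributions", len(out))
    return out


def _candidate_from_reports(cfg: PipelineConfig, run_dir) -> WGDCandidate:
    reports = _reports_dir(Path(run_dir))
    mixtures = json.loads((reports / "mixtures.json").read_text())
    focal = cfg.focal_taxon
    if focal is None:
        raise ValueError("config needs focal_taxon for bookending")
    key = f"{cfg.peak_source}:{focal}"
    entry = mixtures.get(key)
    if entry is None or "error" in entry:
        # fall back to the other mode before giving up
        alt = "pairwise" if cfg.peak_source == "node" else "node"
        entry = mixtures.get(f"{alt}:{focal}")
        if entry is None or "error" in entry:
            raise InsufficientDataError(
                f"no usable mixture fit for focal taxon {focal!r}")
    dom = entry["dominant_component"]
    evidence = {}
    tally_path = reports / "duplication_tally.tsv"
    if tally_path.exists():
        tdf = pd.read_csv(tally_path, sep="\t")
        evidence["duplication_tally_argmax"] = str(
            tdf.sort_values(["count", "species_node_id"],
                            ascending=[False, True]).iloc[0]["species_node_id"])
    return WGDCandidate(
        name=cfg.candidate_name, focal_taxa=(focal,),
        paralog_peak=float(dom["mean"]), paralog_peak_sd=float(dom["sd"]),
        evidence=evidence,
    )


def stage_bookend(cfg: PipelineConfig, run_dir) -> pd.DataFrame:
    run_dir = Path(run_dir)
    _, _, orthogroups = load_inputs(cfg, run_dir)
    survivors = _survivor_ids(run_dir)
    ogs = [orthogroups[i] for i in survivors if i in orthogroups]
    candidate = _candidate_from_reports(cfg, run_dir)
    rows = []
    for pair in cfg.bookend_pairs:
        a, b = pair
        div = ortholog_divergence(a, b, ogs, cfg.window)
        v = bookend(candidate, div, cfg.delta)
        rows.append({
            "candidate": v.candidate, "taxon_a": v.taxon_a, "taxon_b": v.taxon_b,
            "ortholog_peak": v.ortholog_peak, "paralog_peak": v.paralog_peak,
            "delta": v.delta, "verdict": v.verdict,
        })
    df = pd.DataFrame(rows, columns=["candidate", "taxon_a", "taxon_b",
                                     "ortholog_peak", "paralog_peak", "delta",
                                     "verdict"])
    df.to_csv(_reports_dir(run_dir) / "bookend_verdicts.tsv", sep="\t",
              index=False, float_format="%.6f")
    log.info("bookended %d taxon pairs against %s (paralog peak %.3f)",
             len(df), candidate.name, candidate.paralog_peak)
    return df


def stage_hypotheses(cfg: PipelineConfig, run_dir) -> dict:
    from .duplication_mapping import DuplicationTally
    from .wgd_inference import BookendVerdict

    run_dir = Path(run_dir)
    reports = _reports_dir(run_dir)
    sp, _, _ = load_inputs(cfg, run_dir)
    vdf = pd.read_csv(reports / "bookend_verdicts.tsv", sep="\t")
    verdicts = [
        BookendVerdict(r.candidate, r.taxon_a, r.taxon_b, r.ortholog_peak,
                       r.paralog_peak, r.delta, r.verdict)
        for r in vdf.itertuples()
    ]
    tdf = pd.read_csv(reports / "duplication_tally.tsv", sep="\t")
    counts = DuplicationTally(
        counts={str(r.species_node_id): int(r.count) for r in tdf.itertuples()},
        min_support=cfg.min_support,
    )
    hyps = [PlacementHypothesis(label, node_id)
            for label, node_id in sorted(cfg.hypothesis_nodes.items())]
    report = evaluate_hypotheses(hyps, verdicts, counts, sp, cfg.delta)
    (reports / "hypotheses.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    if report["ranking"]:
        log.info("top hypothesis: %s at node %s (score %.2f, tally %d)",
                 report["ranking"][0]["label"], report["ranking"][0]["node_id"],
                 report["ranking"][0]["pattern_score"],
                 report["ranking"][0]["tally"])
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(cfg: PipelineConfig, run_dir) -> dict:
    import sklearn
    import dendropy
    import numpy

    run_dir = Path(run_dir)
    reports = _reports_dir(run_dir)
    resolved = cfg.to_yaml()
    (run_dir / "resolved_config.yaml").write_text(resolved)
    manifest = {
        "config_sha256": hashlib.sha256(resolved.encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": {
            "wgdplacer": __version__,
            "numpy": numpy.__version__,
            "scikit-learn": sklearn.__version__,
            "dendropy": dendropy.__version__,
        },
        "reports": {
            p.name: _sha256(p)
            for p in sorted(reports.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (reports / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def run_pipeline(cfg: PipelineConfig, run_dir) -> dict:
    """All stages in order; returns the manifest."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    if cfg.simulate is not None:
        stage_simulate(cfg, run_dir)
    stage_filter(cfg, run_dir)
    stage_map_duplications(cfg, run_dir)
    stage_ks(cfg, run_dir)
    stage_fit_mixtures(cfg, run_dir)
    if cfg.bookend_pairs and cfg.focal_taxon:
        stage_bookend(cfg, run_dir)
        if cfg.hypothesis_nodes:
            stage_hypotheses(cfg, run_dir)
    return write_manifest(cfg, run_dir)
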