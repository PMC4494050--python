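"""Configuration and the one-command pipeline runner.

``PipelineConfig`` gathers every stage threshold in one place: the 6-bp
index, the 34-bp clip probe span, the mean-quality floor of 15, the 400-bp
expected insert (pairs accepted up to twice that), the +/-2 bp within-taxon
merge window, the +/-10 bp cross-taxon orthology window, the +/-100 bp audit
window, the two-presence informative-character rule, and the validation
panel criteria (>10 read pairs, +/-1 kb TE-free, 1 kb isolation).

``run_pipeline`` executes simulate -> process -> map -> call -> matrix ->
tree in order, writes per-stage outputs and a per-taxon count report
(total pairs, pairs with the expected SINE prefix, pairs mapped, sites
identified, mean coverage per site), and is fully deterministic under its
seeds.  Everything runs single-threaded; results never depend on
parallelism.
"""
from __future__ import annotations

import logging
import os
from dataclasses import asdict, dataclass, field, fields
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import alignment, dollo, orthology, read_processing, site_calling
from .errors import ConfigError
from .simulate import SimConfig, run_simulation

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    index_length: int = 6
    clip_probe_len: int = 34
    min_clip_match: int = 17
    max_clip_mismatch_frac: float = 0.1
    min_mean_qual: float = 15.0
    min_clipped_len: int = 20
    kmer_size: int = 20
    max_mismatch_frac: float = 0.1
    expected_insert: int = 400
    max_pair_distance: int = 800
    within_taxon_window: int = 2
    cross_taxon_window: int = 10
    audit_window: int = 100
    min_reads_per_site: int = 1
    informative_min_presences: int = 2
    validation_te_free: int = 1000
    validation_isolation: int = 1000
    validation_min_read_pairs: int = 11
    primer_flank: int = 100
    low_coverage_frac: float = 0.05
    low_coverage_taxa: List[str] = field(default_factory=list)
    orientation_aware: bool = True
    five_prime_offset: bool = True
    search_strategy: str = "exhaustive"
    n_random_addition: int = 10
    bootstrap_replicates: int = 1000
    seed: int = 0
    sim: Optional[SimConfig] = None

    def __post_init__(self):
        positive = ("index_length", "clip_probe_len", "min_clip_match",
                    "kmer_size", "expected_insert", "max_pair_distance",
                    "within_taxon_window", "cross_taxon_window",
                    "audit_window", "validation_te_free",
                    "validation_isolation", "primer_flank",
                    "n_random_addition", "bootstrap_replicates")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("max_clip_mismatch_frac", "max_mismatch_frac",
                     "low_coverage_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.min_mean_qual < 0 or self.min_mean_qual > 93:
            raise ConfigError("min_mean_qual must be a Phred score in [0, 93]")
        if self.search_strategy not in ("exhaustive", "heuristic"):
            raise ConfigError("search_strategy must be exhaustive|heuristic")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)

    # -- serialization (lossless round trip) -------------------------------

    def to_yaml(self, path: str):
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def process_config(self, index_map: Dict[str, str],
                       consensus: str) -> read_processing.ProcessConfig:
        return read_processing.ProcessConfig(
            index_map=index_map,
            clip_probe=consensus[:self.clip_probe_len],
            min_clip_match=self.min_clip_match,
            max_clip_mismatch_frac=self.max_clip_mismatch_frac,
            min_mean_qual=self.min_mean_qual,
            min_clipped_len=self.min_clipped_len)


@dataclass
class PipelineResult:
    outdir: str
    report: pd.DataFrame
    sites: List[site_calling.ConsolidatedSite]
    loci: List[orthology.InsertionLocus]
    matrix: orthology.CharacterMatrix
    informative: orthology.CharacterMatrix
    n_excluded: int
    tree: dollo.Tree
    score: int
    stats: dollo.ParsimonyStats
    support: Dict


def run_pipeline(config: PipelineConfig, outdir: str,
                 inputs: Optional[Dict[str, str]] = None) -> PipelineResult:
    """Run the full pipeline into ``outdir``.

    ``inputs`` supplies paths (r1, r2, reference, consensus, index_map); when
    omitted, ``config.sim`` must be set and a synthetic dataset is generated
    first.  Raises ConfigError before any stage runs when inputs are missing.
    """
    os.makedirs(outdir, exist_ok=True)
    if inputs is None:
        if config.sim is None:
            raise ConfigError("no inputs given and no simulation configured")
        sim_out = run_simulation(config.sim, os.path.join(outdir, "sim"))
        inputs = dict(sim_out["paths"])
    for key in ("r1", "r2", "reference", "consensus", "index_map"):
        if key not in inputs or not os.path.exists(inputs[key]):
            raise ConfigError(f"missing required input: {key}")

    index_map = _read_index_map(inputs["index_map"])
    consensus = _read_single_fasta(inputs["consensus"])
    pconfig = config.process_config(index_map, consensus)

    # ---- process ---------------------------------------------------------
    pairs = read_processing.read_pairs_fastq(inputs["r1"], inputs["r2"])
    processed = read_processing.process_pairs(pairs, pconfig)
    read_processing.write_taxon_fastqs(processed, os.path.join(outdir,
                                                               "processed"))

    # ---- map -------------------------------------------------------------
    reference = alignment.Reference.from_fasta(inputs["reference"],
                                               k=config.kmer_size)
    evidence: List[alignment.SiteEvidence] = []
    mapped_all: List[alignment.MappedPair] = []
    map_counts: Dict[str, alignment.MappingResult] = {}
    for taxon in sorted(processed.pairs_by_taxon):
        res = alignment.map_pairs(
            processed.pairs_by_taxon[taxon], reference, taxon,
            expected_insert=config.expected_insert,
            max_pair_distance=config.max_pair_distance,
            max_mismatch_frac=config.max_mismatch_frac,
            five_prime_offset=config.five_prime_offset)
        map_counts[taxon] = res
        evidence.extend(res.evidence)
        mapped_all.extend(res.mapped)
    alignment.write_sam(mapped_all, reference.lengths,
                        os.path.join(outdir, "mapped.sam"))
    alignment.evidence_to_bed(evidence, os.path.join(outdir, "evidence.bed"))

    # ---- call ------------------------------------------------------------
    sites = site_calling.consolidate_sites(
        evidence, window=config.within_taxon_window,
        min_reads=config.min_reads_per_site)
    site_calling.write_sites_tsv(sites, os.path.join(outdir, "sites.tsv"))
    hist, frac10 = site_calling.neighbor_distance_audit(
        evidence, window=config.audit_window)
    _write_histogram(hist, frac10, os.path.join(outdir,
                                                "read_neighbor_audit.tsv"))
    curve = site_calling.saturation_curve(
        evidence, fractions=(0.1, 0.25, 0.5, 0.75, 1.0), seed=config.seed,
        window=config.within_taxon_window)
    with open(os.path.join(outdir, "saturation.tsv"), "w") as fh:
        fh.write("fraction\tunique_sites\n")
        for f, n in curve:
            fh.write(f"{f}\t{n}\n")

    # ---- matrix ----------------------------------------------------------
    loci = orthology.group_orthologs(
        sites, window=config.cross_taxon_window,
        orientation_aware=config.orientation_aware)
    orthology.loci_to_bed(loci, os.path.join(outdir, "loci.bed"))
    xhist, xfrac10 = orthology.cross_taxon_offset_audit(
        sites, window=config.audit_window,
        orientation_aware=config.orientation_aware)
    _write_histogram(xhist, xfrac10,
                     os.path.join(outdir, "cross_taxon_offsets.tsv"))
    taxa = sorted(index_map)
    low = list(config.low_coverage_taxa) or orthology.detect_low_coverage_taxa(
        {t: c.repaired for t, c in processed.counts.items()},
        frac_of_median=config.low_coverage_frac)
    matrix = orthology.code_matrix(loci, taxa, low_coverage_taxa=low)
    informative, n_excluded = orthology.filter_informative(
        matrix, min_presences=config.informative_min_presences)
    matrix.to_nexus(os.path.join(outdir, "matrix_full.nex"))
    informative.to_nexus(os.path.join(outdir, "matrix_informative.nex"))
    informative.to_tsv(os.path.join(outdir, "matrix_informative.tsv"))

    # ---- tree ------------------------------------------------------------
    trees, score = dollo.search_trees(
        informative, strategy=config.search_strategy,
        n_random_addition=config.n_random_addition, seed=config.seed)
    support, labeled = dollo.bootstrap(
        informative, n_replicates=config.bootstrap_replicates,
        strategy=config.search_strategy,
        n_random_addition=config.n_random_addition, seed=config.seed)
    stats = dollo.parsimony_stats(labeled, informative)
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(labeled.to_newick() + "\n")
    _write_stats(stats, score, os.path.join(outdir, "parsimony_stats.tsv"))
    _write_support(support, os.path.join(outdir, "bipartitions.tsv"))

    # ---- report ----------------------------------------------------------
    report = _build_report(processed, map_counts, sites, taxa)
    report.to_csv(os.path.join(outdir, "report.tsv"), sep="\t", index=False)
    return PipelineResult(outdir=outdir, report=report, sites=sites,
                          loci=loci, matrix=matrix, informative=informative,
                          n_excluded=n_excluded, tree=labeled, score=score,
                          stats=stats, support=support)


def _build_report(processed: read_processing.ProcessResult,
                  map_counts, sites, taxa) -> pd.DataFrame:
    rows = []
    for taxon in taxa:
        c = processed.counts.get(taxon, read_processing.StageCounts())
        m = map_counts.get(taxon)
        n_sites = sum(1 for s in sites if s.taxon == taxon)
        n_reads = sum(s.read_count for s in sites if s.taxon == taxon)
        n_mapped = len(m.mapped) if m else 0
        rows.append({
            "taxon": taxon,
            "total_read_pairs": c.demuxed,
            "pairs_with_expected_sine": c.clipped,
            "pct_with_expected_sine": round(100.0 * c.clipped / c.demuxed, 2)
            if c.demuxed else 0.0,
            "pairs_retained": c.repaired,
            "pairs_mapped": n_mapped,
            "pct_mapped": round(100.0 * n_mapped / c.demuxed, 2)
            if c.demuxed else 0.0,
            "sites_identified": n_sites,
            "mean_coverage_per_site": round(n_reads / n_sites, 2)
            if n_sites else 0.0,
        })
    return pd.DataFrame(rows)


def _write_histogram(hist, frac10, path: str):
    with open(path, "w") as fh:
        fh.write(f"# fraction_within_10bp\t"
                 f"{'NA' if frac10 is None else round(frac10, 4)}\n")
        fh.write("distance\tcount\n")
        for d in sorted(hist):
            fh.write(f"{d}\t{hist[d]}\n")


def _write_stats(stats: dollo.ParsimonyStats, score: int, path: str):
    with open(path, "w") as fh:
        fh.write("length\tCI\tRI\tRC\tHI\tmin_steps\tmax_steps\n")
        fh.write(f"{stats.length}\t{stats.ci:.4f}\t{stats.ri:.4f}\t"
                 f"{stats.rc:.4f}\t{stats.hi:.4f}\t{stats.min_steps}\t"
                 f"{stats.max_steps}\n")


def _write_support(support: Dict, path: str):
    with open(path, "w") as fh:
        fh.write("clade\tsupport_pct\n")
        for clade in sorted(support, key=lambda c: (len(c), sorted(c))):
            fh.write(",".join(sorted(clade)) + f"\t{support[clade]:.1f}\n")


def _read_index_map(path: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            taxon, idx = line.split()[:2]
            out[taxon] = idx.upper()
    return out


def _read_single_fasta(path: str) -> str:
    from Bio import SeqIO
    recs = list(SeqIO.parse(path, "fasta"))
    if not recs:
        raise ConfigError(f"no sequence in {path}")
    return str(recs[0].seq).upper()
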