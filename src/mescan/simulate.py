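"""Synthetic ME-Scan data: reference, insertion histories, and paired reads.

The simulator emulates a targeted SINE-capture sequencing experiment over a
known species tree.  Insertion loci obey a Dollo-compliant generative model:
each locus is gained on exactly one branch of the ingroup tree and is present
in every descendant leaf unless a (default-off) precise-excision loss removes
it on a later branch.  Loci are planted in reference coordinates at a minimum
spacing so that downstream isolation criteria are exercisable.

Each sampled read pair mirrors the two-read capture anatomy:

* the SINE read carries ``ves_prefix_len`` bases of the element consensus
  followed by the genomic flank adjacent to the insertion point on the
  insertion's 3' side (in insertion orientation), truncated to read length;
* the flanking read carries the taxon's 6-bp library index followed by
  genomic sequence from the far end of a ~400 bp fragment, read back toward
  the insertion (so a mapped pair faces inward at the expected insert size).

Per-base substitution errors and truncated-normal Phred+33 qualities are
applied; one taxon may be designated a near-empty "failed library".  All
randomness flows from a single seed, so outputs are byte-identical between
runs with the same configuration.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .dollo import Node, Tree
from .errors import ConfigError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Study-condition knobs for the simulator (defaults are the conditions
    the pipeline is validated under)."""

    n_taxa: int = 7
    tree_shape: str = "random"          # newick string or "random"
    genome_length: int = 1_100_000
    n_chromosomes: int = 2
    n_loci: int = 500
    gain_rate_per_branch: Optional[float] = None  # if set, n_loci ~ Poisson
    loss_rate: float = 0.0
    near_parallel_rate: float = 0.0
    sine_consensus: Optional[str] = None  # random 200-mer when None
    sine_length: int = 200
    read_length: int = 100
    index_length: int = 6
    ves_prefix_len: int = 30            # within the 17-34 bp capture span
    insert_size_mean: float = 400.0
    insert_size_sd: float = 50.0
    per_taxon_read_pairs: Optional[Dict[str, int]] = None
    default_read_pairs: int = 37_500   # ~75 pairs per locus at 500 loci
    failed_taxon: Optional[str] = None
    failed_depth_frac: float = 0.0005   # depth of the failed library
    error_rate: float = 0.0
    qual_mean: float = 35.0
    qual_sd: float = 4.0
    min_spacing: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ConfigError("n_taxa must be >= 3")
        if self.genome_length < self.n_loci * self.min_spacing:
            raise ConfigError(
                "genome_length must be >= n_loci * min_spacing so loci can "
                "be placed at the required isolation")
        for name in ("loss_rate", "near_parallel_rate", "error_rate",
                     "failed_depth_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.sine_consensus is not None:
            self.sine_consensus = self.sine_consensus.upper()
            self.sine_length = len(self.sine_consensus)
        if self.ves_prefix_len > self.sine_length:
            raise ConfigError("ves_prefix_len exceeds SINE consensus length")
        if self.index_length + 1 > self.read_length:
            raise ConfigError("index_length must leave room in the read")
        if self.ves_prefix_len + 1 > self.read_length:
            raise ConfigError("ves_prefix_len must leave room in the read")

    def taxa(self) -> List[str]:
        if self.tree_shape != "random":
            return sorted(Tree.from_newick(self.tree_shape).leaves())
        return [f"T{i + 1}" for i in range(self.n_taxa)]

    def read_pairs_for(self, taxon: str) -> int:
        if self.per_taxon_read_pairs and taxon in self.per_taxon_read_pairs:
            return self.per_taxon_read_pairs[taxon]
        if taxon == self.failed_taxon:
            return max(1, round(self.default_read_pairs
                                * self.failed_depth_frac))
        return self.default_read_pairs


def study_config(seed: int, error_rate: float = 0.0, **overrides) -> SimConfig:
    """The canonical simulated study: 7 ingroup taxa, 500 loss-free loci,
    ~75 read pairs per locus per taxon, and one failed library at 0.05 %
    depth.

    Depth and the failed-library fraction follow the read-pairs-to-
    insertions ratios of a real single-lane capture experiment; the failed
    taxon sits in a cherry (sister to one other taxon), the situation a
    failed library of a species with a near-conspecific relative in the
    panel creates.  A cherry placement also makes the failed taxon's
    position statistically identifiable at all: with absences coded
    missing, only loci gained on its cherry stem pin it, so a basal failed
    taxon would be a pure wildcard no amount of bootstrap could support.
    """
    params = dict(
        n_taxa=7,
        tree_shape="(((((T1,T2),T3),T4),T5),(T6,T7));",
        genome_length=1_100_000,
        n_chromosomes=2,
        n_loci=500,
        default_read_pairs=37_500,
        failed_taxon="T7",
        failed_depth_frac=0.0005,
        error_rate=error_rate,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


@dataclass(frozen=True)
class TruthInsertion:
    """Ground-truth insertion locus in reference coordinates.

    ``position`` is the 1-based coordinate of the reference base immediately
    5' of the insertion point (the convention the caller recovers).
    """

    locus_id: str
    chromosome: str
    position: int
    orientation: str                    # '+' or '-'
    taxa_present: FrozenSet[str]


# --------------------------------------------------------------------------
# Tree simulation
# --------------------------------------------------------------------------


def simulate_tree(config: SimConfig) -> Tree:
    """A rooted binary ingroup tree, either the configured shape or a random
    topology built by sequential joining (deterministic under the seed)."""
    if config.tree_shape != "random":
        tree = Tree.from_newick(config.tree_shape)
        leaves = tree.leaves()
        if len(leaves) != config.n_taxa:
            raise ConfigError(
                f"tree_shape has {len(leaves)} leaves, n_taxa={config.n_taxa}")
        if len(set(leaves)) != len(leaves):
            raise ConfigError("tree_shape has duplicate leaf names")
        _check_binary(tree.root)
        return tree
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    nodes = [Node(name=t) for t in config.taxa()]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = Node(children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return Tree(nodes[0])


def _check_binary(n: Node):
    if n.is_leaf:
        return
    if len(n.children) != 2:
        raise ConfigError("tree_shape must be strictly binary")
    for c in n.children:
        _check_binary(c)


# --------------------------------------------------------------------------
# Reference genome
# --------------------------------------------------------------------------


def simulate_reference(config: SimConfig) -> Dict[str, str]:
    """Random uniform-composition chromosomes named chr1..chrN."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    per = config.genome_length // config.n_chromosomes
    ref = {}
    for i in range(config.n_chromosomes):
        n = per if i < config.n_chromosomes - 1 else (
            config.genome_length - per * (config.n_chromosomes - 1))
        ref[f"chr{i + 1}"] = rng.choice(_BASES, size=n).tobytes().decode()
    return ref


def simulate_sine_consensus(config: SimConfig) -> str:
    if config.sine_consensus is not None:
        return config.sine_consensus
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    return rng.choice(_BASES, size=config.sine_length).tobytes().decode()


# --------------------------------------------------------------------------
# Insertion histories
# --------------------------------------------------------------------------


def _edges_with_leafsets(tree: Tree) -> List[Tuple[Node, FrozenSet[str]]]:
    """Every node paired with its leaf set; the edge above the root is the
    edge above the whole ingroup."""
    out: List[Tuple[Node, FrozenSet[str]]] = []

    def rec(n: Node) -> FrozenSet[str]:
        if n.is_leaf:
            s = frozenset([n.name])
        else:
            s = frozenset().union(*(rec(c) for c in n.children))
        out.append((n, s))
        return s

    rec(tree.root)
    return out


def _apply_losses(gain_node: Node, rng, loss_rate: float) -> FrozenSet[str]:
    """Leaves retaining the insertion after per-branch precise-excision
    losses below the gain."""
    kept: List[str] = []

    def rec(n: Node):
        if n.is_leaf:
            kept.append(n.name)
            return
        for c in n.children:
            if loss_rate > 0 and rng.random() < loss_rate:
                continue
            rec(c)

    rec(gain_node)
    return frozenset(kept)


def _place_positions(config: SimConfig, ref: Dict[str, str], n: int, rng
                     ) -> List[Tuple[str, int]]:
    """Positions at >= min_spacing pairwise (within chromosome), away from
    chromosome ends so read fragments never run off."""
    margin = int(config.insert_size_mean + 4 * config.insert_size_sd
                 + config.read_length)
    chroms = sorted(ref)
    lengths = np.array([len(ref[c]) for c in chroms], dtype=float)
    alloc = np.floor(lengths / lengths.sum() * n).astype(int)
    i = 0
    while alloc.sum() < n:                 # distribute remainder
        alloc[i % len(chroms)] += 1
        i += 1
    out: List[Tuple[str, int]] = []
    # guard leaves room for the boundary nudge without breaching min_spacing
    spacing = config.min_spacing + 2 * _BOUNDARY_TRIES
    for chrom, k in zip(chroms, alloc):
        if k == 0:
            continue
        usable = len(ref[chrom]) - 2 * margin
        slack = usable - k * spacing
        if slack < 0:
            raise ConfigError(
                f"cannot place {k} loci at spacing {config.min_spacing} "
                f"on {chrom} (length {len(ref[chrom])})")
        cuts = np.sort(rng.random(int(k))) * slack
        for j in range(int(k)):
            pos = margin + int(cuts[j]) + j * spacing + spacing // 2
            out.append((chrom, pos + 1))   # 1-based
    return out


_BOUNDARY_TRIES = 16


def _well_defined_boundary(chrom: str, pos: int, orient: str,
                           consensus: str, prefix_len: int) -> int:
    """Nudge an insertion point so the first flank base in the SINE read
    does not continue the element consensus.

    The SINE/genome boundary inside a read is only recoverable when the
    flank stops matching the consensus; a flank that happens to continue it
    would shift every read of the locus by the same amount.  Real loci with
    such flanks would be called with a small systematic offset (absorbed by
    the +/-2 bp merge window); the simulator excludes them so ground-truth
    coordinates are exact.
    """
    if prefix_len >= len(consensus) or prefix_len >= 34:
        return pos
    next_base = consensus[prefix_len]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for _ in range(_BOUNDARY_TRIES):
        if orient == "+":
            flank_base = chrom[pos]            # ref base pos+1, 1-based
            if flank_base != next_base:
                return pos
            pos += 1
        else:
            flank_base = comp[chrom[pos - 2]]  # revcomp of ref base pos-1
            if flank_base != next_base:
                return pos
            pos -= 1
    return pos


def simulate_insertions(tree: Tree, config: SimConfig,
                        reference: Dict[str, str]) -> List[TruthInsertion]:
    """Plant loci with a single gain each (plus optional losses and optional
    deliberate near-parallel neighbors)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    consensus = simulate_sine_consensus(config)
    edges = _edges_with_leafsets(tree)
    if config.gain_rate_per_branch is not None:
        n_loci = int(rng.poisson(config.gain_rate_per_branch * len(edges)))
    else:
        n_loci = config.n_loci
    positions = _place_positions(config, reference, n_loci, rng)
    rng.shuffle(positions)

    truth: List[TruthInsertion] = []
    for i, (chrom, pos) in enumerate(positions):
        while True:
            gain_node, _ = edges[int(rng.integers(len(edges)))]
            present = _apply_losses(gain_node, rng, config.loss_rate)
            if present:
                break
        orient = "+" if rng.random() < 0.5 else "-"
        pos = _well_defined_boundary(reference[chrom], pos, orient,
                                     consensus, config.ves_prefix_len)
        truth.append(TruthInsertion(
            locus_id=f"locus_{i + 1:05d}", chromosome=chrom, position=pos,
            orientation=orient, taxa_present=present))

    if config.near_parallel_rate > 0:
        extra: List[TruthInsertion] = []
        for ins in truth:
            if rng.random() >= config.near_parallel_rate:
                continue
            offset = int(rng.integers(1, 26)) * (1 if rng.random() < 0.5 else -1)
            gain_node, _ = edges[int(rng.integers(len(edges)))]
            present = _apply_losses(gain_node, rng, config.loss_rate)
            if not present:
                continue
            orient = "+" if rng.random() < 0.5 else "-"
            pos = _well_defined_boundary(
                reference[ins.chromosome], ins.position + offset, orient,
                consensus, config.ves_prefix_len)
            extra.append(TruthInsertion(
                locus_id=f"{ins.locus_id}_np", chromosome=ins.chromosome,
                position=pos, orientation=orient, taxa_present=present))
        truth.extend(extra)
    return truth


# --------------------------------------------------------------------------
# Read simulation
# --------------------------------------------------------------------------


def _make_indices(taxa: Sequence[str], config: SimConfig) -> Dict[str, str]:
    """Unique taxon indices with pairwise Hamming distance >= 2."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    chosen: List[str] = []
    while len(chosen) < len(taxa):
        cand = rng.choice(_BASES, size=config.index_length).tobytes().decode()
        if all(sum(a != b for a, b in zip(cand, c)) >= 2 for c in chosen):
            chosen.append(cand)
    return dict(zip(sorted(taxa), chosen))


def _apply_errors(seq: str, rng, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < error_rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def _qual_string(n: int, rng, config: SimConfig) -> str:
    q = np.rint(rng.normal(config.qual_mean, config.qual_sd, size=n))
    q = np.clip(q, 2, 40).astype(np.uint8) + 33
    return q.tobytes().decode()


@dataclass
class SimulatedReads:
    r1: List[Tuple[str, str, str]]      # (title, seq, qual) flanking reads
    r2: List[Tuple[str, str, str]]      # SINE reads
    index_map: Dict[str, str]
    pair_counts: Dict[Tuple[str, str], int]  # (taxon, locus_id) -> sampled pairs
    n_resampled: int = 0


def simulate_reads(truth: Sequence[TruthInsertion], reference: Dict[str, str],
                   config: SimConfig) -> SimulatedReads:
    """Sample read pairs per taxon from its present loci.

    Loci whose fragment would run off the chromosome end are resampled (and
    counted); with the default placement margins this never triggers.
    """
    if not truth:
        raise ConfigError("no truth insertions to sequence")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
    consensus = simulate_sine_consensus(config)
    prefix = consensus[:config.ves_prefix_len]
    taxa = sorted({t for ins in truth for t in ins.taxa_present})
    index_map = _make_indices(taxa, config)
    flank_len = config.read_length - config.index_length
    ves_genomic_len = config.read_length - config.ves_prefix_len

    r1: List[Tuple[str, str, str]] = []
    r2: List[Tuple[str, str, str]] = []
    pair_counts: Dict[Tuple[str, str], int] = {}
    n_resampled = 0
    serial = 0
    for taxon in taxa:
        loci = [ins for ins in truth if taxon in ins.taxa_present]
        n_pairs = config.read_pairs_for(taxon)
        for _ in range(n_pairs):
            for _attempt in range(100):
                ins = loci[int(rng.integers(len(loci)))]
                chrom = reference[ins.chromosome]
                frag = int(round(rng.normal(config.insert_size_mean,
                                            config.insert_size_sd)))
                frag = max(frag, config.read_length + 10)
                p = ins.position
                if ins.orientation == "+":
                    if p + frag > len(chrom):
                        n_resampled += 1
                        continue
                    ves_genomic = chrom[p:p + ves_genomic_len]
                    flank = revcomp(chrom[p + frag - flank_len:p + frag])
                else:
                    if p - frag < 1:
                        n_resampled += 1
                        continue
                    ves_genomic = revcomp(chrom[p - 1 - ves_genomic_len:p - 1])
                    flank = chrom[p - frag - 1:p - frag - 1 + flank_len]
                break
            else:
                raise ConfigError(
                    f"could not draw a fragment for {ins.locus_id}")
            serial += 1
            pair_counts[(taxon, ins.locus_id)] = \
                pair_counts.get((taxon, ins.locus_id), 0) + 1
            title = f"pair{serial:08d} taxon={taxon} locus={ins.locus_id}"
            flank_seq = _apply_errors(index_map[taxon] + flank, rng,
                                      config.error_rate)
            ves_seq = _apply_errors(prefix + ves_genomic, rng,
                                    config.error_rate)
            r1.append((title, flank_seq,
                       _qual_string(len(flank_seq), rng, config)))
            r2.append((title, ves_seq,
                       _qual_string(len(ves_seq), rng, config)))
    return SimulatedReads(r1=r1, r2=r2, index_map=index_map,
                          pair_counts=pair_counts, n_resampled=n_resampled)


# --------------------------------------------------------------------------
# File emission
# --------------------------------------------------------------------------


def write_fastq(records: Sequence[Tuple[str, str, str]], path: str):
    with open(path, "w") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


def write_fasta(seqs: Dict[str, str], path: str, width: int = 70):
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def run_simulation(config: SimConfig, outdir: str) -> Dict[str, object]:
    """Generate and write a full synthetic dataset; returns paths plus the
    in-memory objects for programmatic use."""
    os.makedirs(outdir, exist_ok=True)
    tree = simulate_tree(config)
    reference = simulate_reference(config)
    consensus = simulate_sine_consensus(config)
    truth = simulate_insertions(tree, config, reference)
    reads = simulate_reads(truth, reference, config)

    paths = {
        "reference": os.path.join(outdir, "reference.fa"),
        "consensus": os.path.join(outdir, "sine_consensus.fa"),
        "tree": os.path.join(outdir, "true_tree.nwk"),
        "truth": os.path.join(outdir, "truth_sites.tsv"),
        "index_map": os.path.join(outdir, "index_map.tsv"),
        "r1": os.path.join(outdir, "reads_R1.fastq"),
        "r2": os.path.join(outdir, "reads_R2.fastq"),
    }
    write_fasta(reference, paths["reference"])
    write_fasta({"sine_consensus": consensus}, paths["consensus"])
    with open(paths["tree"], "w") as fh:
        fh.write(tree.to_newick() + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("taxon\tchromosome\tposition\torientation\tlocus_id\tn_pairs\n")
        for ins in sorted(truth, key=lambda i: (i.chromosome, i.position)):
            for taxon in sorted(ins.taxa_present):
                n = reads.pair_counts.get((taxon, ins.locus_id), 0)
                fh.write(f"{taxon}\t{ins.chromosome}\t{ins.position}\t"
                         f"{ins.orientation}\t{ins.locus_id}\t{n}\n")
    with open(paths["index_map"], "w") as fh:
        for taxon in sorted(reads.index_map):
            fh.write(f"{taxon}\t{reads.index_map[taxon]}\n")
    write_fastq(reads.r1, paths["r1"])
    write_fastq(reads.r2, paths["r2"])
    return {"paths": paths, "tree": tree, "reference": reference,
            "consensus": consensus, "truth": truth, "reads": reads}
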