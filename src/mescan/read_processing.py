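"""Demultiplexing, SINE-prefix clipping, quality filtering, and re-pairing.

Pooled capture libraries carry a 6-bp taxon index at the 5' end of the
flanking read; demultiplexing is by exact match only (one mismatch, or an N,
excludes the pair).  The SINE read must begin with a recognizable prefix of
the first 34 bp of the element consensus; the matched span is clipped off so
that only genomic sequence is mapped.  Reads whose mean Phred+33 quality is
below 15 are removed (a mean of exactly 15 is kept).  Because the two mate
files are filtered independently, surviving streams are re-synchronized by
pair id, with unmatched mates set aside as orphans.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConfigError, DataError, ParseError

CLIPPED = "clipped"
NO_SINE = "no_sine"
TOO_SHORT = "too_short"


@dataclass
class IndexedReadPair:
    """One flanking read and one SINE-anchored read with qualities."""

    pair_id: str
    flank_seq: str
    flank_quals: str
    ves_seq: str
    ves_quals: str
    assigned_taxon: Optional[str] = None
    clip_len: Optional[int] = None

    def __post_init__(self):
        if len(self.flank_seq) != len(self.flank_quals) \
                or len(self.ves_seq) != len(self.ves_quals):
            raise DataError(
                f"pair {self.pair_id}: sequence/quality length mismatch")


@dataclass
class ProcessConfig:
    index_map: Dict[str, str] = field(default_factory=dict)
    clip_probe: str = ""                # 5' 34 bp of the SINE consensus
    min_clip_match: int = 17
    max_clip_mismatch_frac: float = 0.1
    min_mean_qual: float = 15.0
    min_clipped_len: int = 20
    clip_mismatch_penalty: int = 4

    def __post_init__(self):
        if self.index_map:
            idx = list(self.index_map.values())
            if len(set(idx)) != len(idx):
                raise ConfigError("duplicate index sequence in index_map")
            if len({len(i) for i in idx}) != 1:
                raise ConfigError("indices must all have the same length")
        if self.clip_probe and not (
                0 < self.min_clip_match <= len(self.clip_probe)):
            raise ConfigError("min_clip_match must be in (0, len(clip_probe)]")

    @property
    def index_length(self) -> int:
        return len(next(iter(self.index_map.values())))


def read_pairs_fastq(r1_path: str, r2_path: str) -> Iterator[IndexedReadPair]:
    """Stream (flanking, SINE) read pairs from two synchronized FASTQ files."""
    with open(r1_path) as f1, open(r2_path) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
                FastqGeneralIterator(f1), FastqGeneralIterator(f2)):
            pid1, pid2 = t1.split()[0], t2.split()[0]
            if pid1 != pid2:
                raise DataError(f"unsynchronized mates: {pid1} vs {pid2}")
            yield IndexedReadPair(pair_id=pid1, flank_seq=s1.upper(),
                                  flank_quals=q1, ves_seq=s2.upper(),
                                  ves_quals=q2)


# --------------------------------------------------------------------------
# Demultiplexing
# --------------------------------------------------------------------------


def demultiplex(pairs: Iterable[IndexedReadPair], config: ProcessConfig
                ) -> Tuple[Dict[str, List[IndexedReadPair]], int]:
    """Assign pairs to taxa by exact index match; strip the index bases.

    Returns (taxon -> assigned pairs, number of discarded pairs).
    """
    if not config.index_map:
        raise ConfigError("index_map is empty")
    by_index = {v: k for k, v in config.index_map.items()}
    n = config.index_length
    out: Dict[str, List[IndexedReadPair]] = {t: [] for t in config.index_map}
    discarded = 0
    for pair in pairs:
        taxon = by_index.get(pair.flank_seq[:n])
        if taxon is None:
            discarded += 1
            continue
        out[taxon].append(replace(
            pair, flank_seq=pair.flank_seq[n:], flank_quals=pair.flank_quals[n:],
            assigned_taxon=taxon))
    return out, discarded


# --------------------------------------------------------------------------
# SINE-prefix clipping
# --------------------------------------------------------------------------


def clip_sine_prefix(pair: IndexedReadPair, config: ProcessConfig
                     ) -> Tuple[str, Optional[IndexedReadPair]]:
    """Clip the SINE-consensus prefix off the SINE read.

    Scans candidate clip lengths from ``min_clip_match`` up to the probe
    length, scoring matches minus a mismatch penalty, and clips the
    best-scoring span provided its mismatch fraction stays within bounds.
    Returns (status, clipped pair) where status is ``clipped``, ``no_sine``
    (no acceptable prefix; pair discarded) or ``too_short`` (clip would leave
    fewer than ``min_clipped_len`` genomic bases).
    """
    probe = config.clip_probe
    read = pair.ves_seq
    max_l = min(len(probe), len(read))
    if max_l < config.min_clip_match:
        return NO_SINE, None
    mism = np.cumsum(np.frombuffer(read[:max_l].encode(), dtype=np.uint8)
                     != np.frombuffer(probe[:max_l].encode(), dtype=np.uint8))
    best_l, best_score = None, None
    for length in range(config.min_clip_match, max_l + 1):
        m = int(mism[length - 1])
        if m > config.max_clip_mismatch_frac * length:
            continue
        score = (length - m) - config.clip_mismatch_penalty * m
        if best_score is None or score > best_score:
            best_l, best_score = length, score
    if best_l is None:
        return NO_SINE, None
    if len(read) - best_l < config.min_clipped_len:
        return TOO_SHORT, None
    return CLIPPED, replace(pair, ves_seq=read[best_l:],
                            ves_quals=pair.ves_quals[best_l:],
                            clip_len=best_l)


# --------------------------------------------------------------------------
# Quality filtering
# --------------------------------------------------------------------------


def mean_phred(quals: str, record_id: str = "?") -> float:
    if not quals:
        raise ParseError(f"record {record_id}: empty quality string")
    arr = np.frombuffer(quals.encode(), dtype=np.uint8)
    if arr.min() < 33 or arr.max() > 126:
        raise ParseError(f"record {record_id}: quality characters outside "
                         "Phred+33 range")
    return float(arr.mean()) - 33.0


def quality_filter(pair: IndexedReadPair, config: ProcessConfig) -> bool:
    """Keep the pair iff both mates' mean Phred quality is >= the threshold
    (reads averaging exactly the threshold are kept)."""
    return (mean_phred(pair.ves_quals, pair.pair_id) >= config.min_mean_qual
            and mean_phred(pair.flank_quals, pair.pair_id)
            >= config.min_mean_qual)


# --------------------------------------------------------------------------
# Re-pairing
# --------------------------------------------------------------------------


def repair_streams(ves_items: Iterable[Tuple[str, object]],
                   flank_items: Iterable[Tuple[str, object]]
                   ) -> Tuple[List[Tuple[str, object, object]],
                              List[Tuple[str, str, object]]]:
    """Re-synchronize independently filtered mate streams by pair id.

    Returns (pairs, orphans): pairs is ``(pair_id, ves, flank)`` for ids
    present in both streams, sorted by id; orphans is ``(pair_id, which,
    record)`` for the rest.  Duplicate ids in either stream are an error.
    """
    ves: Dict[str, object] = {}
    for pid, rec in ves_items:
        if pid in ves:
            raise DataError(f"duplicate pair_id in SINE-read stream: {pid}")
        ves[pid] = rec
    flank: Dict[str, object] = {}
    for pid, rec in flank_items:
        if pid in flank:
            raise DataError(f"duplicate pair_id in flanking-read stream: {pid}")
        flank[pid] = rec
    shared = sorted(set(ves) & set(flank))
    pairs = [(pid, ves[pid], flank[pid]) for pid in shared]
    orphans = [(pid, "ves", ves[pid]) for pid in sorted(set(ves) - set(flank))]
    orphans += [(pid, "flank", flank[pid])
                for pid in sorted(set(flank) - set(ves))]
    return pairs, orphans


# --------------------------------------------------------------------------
# Whole-stage driver
# --------------------------------------------------------------------------


@dataclass
class StageCounts:
    """Per-taxon record conservation ledger for the processing stage."""

    demuxed: int = 0
    clipped: int = 0
    no_sine: int = 0
    too_short: int = 0
    ves_qual_fail: int = 0
    flank_qual_fail: int = 0
    repaired: int = 0
    orphans: int = 0


@dataclass
class ProcessResult:
    pairs_by_taxon: Dict[str, List[IndexedReadPair]]
    orphans_by_taxon: Dict[str, List[Tuple[str, str, IndexedReadPair]]]
    counts: Dict[str, StageCounts]
    n_input: int
    n_index_discarded: int


def process_pairs(pairs: Iterable[IndexedReadPair], config: ProcessConfig
                  ) -> ProcessResult:
    """Demultiplex, clip, quality-filter (each mate independently, as the
    mate files are processed separately) and re-pair."""
    pairs = list(pairs)
    by_taxon, discarded = demultiplex(pairs, config)
    out_pairs: Dict[str, List[IndexedReadPair]] = {}
    out_orphans: Dict[str, List] = {}
    counts: Dict[str, StageCounts] = {}
    for taxon, assigned in by_taxon.items():
        c = StageCounts(demuxed=len(assigned))
        ves_stream: List[Tuple[str, IndexedReadPair]] = []
        flank_stream: List[Tuple[str, IndexedReadPair]] = []
        for pair in assigned:
            status, clipped = clip_sine_prefix(pair, config)
            if status == NO_SINE:
                c.no_sine += 1
            elif status == TOO_SHORT:
                c.too_short += 1
            else:
                c.clipped += 1
                if mean_phred(clipped.ves_quals, pair.pair_id) \
                        >= config.min_mean_qual:
                    ves_stream.append((pair.pair_id, clipped))
                else:
                    c.ves_qual_fail += 1
            if mean_phred(pair.flank_quals, pair.pair_id) \
                    >= config.min_mean_qual:
                flank_stream.append((pair.pair_id, pair))
            else:
                c.flank_qual_fail += 1
        repaired, orphans = repair_streams(ves_stream, flank_stream)
        kept = [v for _, v, _ in repaired]
        c.repaired = len(kept)
        c.orphans = len(orphans)
        out_pairs[taxon] = kept
        out_orphans[taxon] = orphans
        counts[taxon] = c
    return ProcessResult(pairs_by_taxon=out_pairs, orphans_by_taxon=out_orphans,
                         counts=counts, n_input=len(pairs),
                         n_index_discarded=discarded)


def write_taxon_fastqs(result: ProcessResult, outdir: str):
    """Per-taxon `{taxon}.flank.fastq` / `{taxon}.ves.fastq` files for the
    surviving pairs, plus `{taxon}.orphans.fastq` for mates whose partner
    was filtered away."""
    import os
    os.makedirs(outdir, exist_ok=True)
    for taxon, kept in result.pairs_by_taxon.items():
        with open(os.path.join(outdir, f"{taxon}.flank.fastq"), "w") as ff, \
                open(os.path.join(outdir, f"{taxon}.ves.fastq"), "w") as vf:
            for p in kept:
                ff.write(f"@{p.pair_id}\n{p.flank_seq}\n+\n{p.flank_quals}\n")
                vf.write(f"@{p.pair_id}\n{p.ves_seq}\n+\n{p.ves_quals}\n")
        orphans = result.orphans_by_taxon.get(taxon, [])
        if orphans:
            with open(os.path.join(outdir, f"{taxon}.orphans.fastq"),
                      "w") as of:
                for pid, which, rec in orphans:
                    seq, quals = ((rec.ves_seq, rec.ves_quals)
                                  if which == "ves"
                                  else (rec.flank_seq, rec.flank_quals))
                    of.write(f"@{pid} {which}\n{seq}\n+\n{quals}\n")
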