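"""Reference placement of processed read pairs and insertion-site evidence.

A minimal ungapped seed-and-extend mapper places each mate on the reference:
non-overlapping k-mers of the read are looked up in a sorted k-mer table of
the genome, every candidate diagonal is scored by full-length mismatch count
(forward and reverse complement), and all minimum-mismatch placements are
returned so multi-mapping is visible.  Externally produced alignments can be
ingested from SAM instead; both routes yield identical evidence.

Accepted pairs must sit on one chromosome, on opposite strands, facing each
other, with an outer fragment span no larger than twice the expected insert
(~400 bp); among valid placements the combination closest to the expected
insert wins, and ambiguous pairs are rejected outright because a wrong
coordinate is worse than a lost read here.  The insertion site of an accepted
pair is the reference base immediately 5' of the SINE read's aligned span:
one before the alignment start on the plus strand, one past the alignment end
on the minus strand.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from Bio import SeqIO

from .errors import ConfigError, DataError
from .simulate import revcomp

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


@dataclass(frozen=True)
class Placement:
    chromosome: str
    start: int                  # 1-based inclusive
    end: int
    strand: str                 # '+' or '-'
    mismatches: int


@dataclass(frozen=True)
class MappedPair:
    taxon: str
    chromosome: str
    ves_strand: str
    ves_span: Tuple[int, int]   # 1-based inclusive
    flank_span: Tuple[int, int]
    mapq_unique: bool
    pair_id: str = ""


@dataclass(frozen=True)
class SiteEvidence:
    taxon: str
    chromosome: str
    position: int               # 1-based insertion-site coordinate
    orientation: str


class Reference:
    """Reference genome with a sorted k-mer seed table."""

    def __init__(self, chrom_seqs: Dict[str, str], k: int = 20):
        if k < 8 or k > 32:
            raise ConfigError("seed length k must be in [8, 32]")
        self.k = k
        self.chroms = sorted(chrom_seqs)
        self.lengths = {c: len(chrom_seqs[c]) for c in self.chroms}
        self._offsets: Dict[str, int] = {}
        codes = []
        off = 0
        gap = np.full(k, 4, dtype=np.uint8)  # sentinel kills cross-chrom seeds
        for c in self.chroms:
            self._offsets[c] = off
            arr = _CODE[np.frombuffer(chrom_seqs[c].encode(), dtype=np.uint8)]
            codes.append(arr)
            codes.append(gap)
            off += len(arr) + k
        self.codes = np.concatenate(codes) if codes else np.empty(0, np.uint8)
        self._starts = np.array([self._offsets[c] for c in self.chroms])
        self._ends = self._starts + np.array([self.lengths[c]
                                              for c in self.chroms])
        self._build_index()

    @classmethod
    def from_fasta(cls, path: str, k: int = 20) -> "Reference":
        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(path, "fasta")}
        if not seqs:
            raise DataError(f"no sequences in {path}")
        return cls(seqs, k=k)

    def _build_index(self):
        k = self.k
        n = self.codes.size
        if n < k:
            self._kmer_sorted = np.empty(0, np.uint64)
            self._kmer_pos = np.empty(0, np.int64)
            return
        vals = np.zeros(n - k + 1, dtype=np.uint64)
        bad = np.zeros(n - k + 1, dtype=bool)
        for j in range(k):
            window = self.codes[j:j + n - k + 1]
            vals = (vals << np.uint64(2)) | (window & np.uint8(3))
            bad |= window > 3
        pos = np.flatnonzero(~bad)
        vals = vals[pos]
        order = np.argsort(vals, kind="stable")
        self._kmer_sorted = vals[order]
        self._kmer_pos = pos[order].astype(np.int64)

    def seed_hits(self, kmer_codes: np.ndarray) -> np.ndarray:
        """Global start positions of an exact k-mer (codes array, length k)."""
        if (kmer_codes > 3).any():
            return np.empty(0, np.int64)
        val = np.uint64(0)
        for c in kmer_codes:
            val = (val << np.uint64(2)) | np.uint64(c)
        lo = np.searchsorted(self._kmer_sorted, val, side="left")
        hi = np.searchsorted(self._kmer_sorted, val, side="right")
        return self._kmer_pos[lo:hi]

    def locate(self, gpos: int, length: int) -> Optional[Tuple[str, int]]:
        """Map a global start to (chromosome, 1-based start); None when the
        span would cross a chromosome boundary."""
        i = np.searchsorted(self._ends, gpos, side="right")
        if i >= len(self.chroms):
            return None
        if gpos < self._starts[i] or gpos + length > self._ends[i]:
            return None
        return self.chroms[i], int(gpos - self._starts[i]) + 1

    def fetch_codes(self, gpos: int, length: int) -> np.ndarray:
        return self.codes[gpos:gpos + length]


def map_read(seq: str, reference: Reference,
             max_mismatch_frac: float = 0.1) -> List[Placement]:
    """All minimum-mismatch ungapped placements of a read (both strands)."""
    best: List[Placement] = []
    best_mm: Optional[int] = None
    length = len(seq)
    k = reference.k
    if length < k:
        return []
    cutoff = int(max_mismatch_frac * length)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        codes = _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
        offsets = list(range(0, length - k + 1, k))
        if offsets[-1] != length - k:
            offsets.append(length - k)
        candidates = set()
        for off in offsets:
            for hit in reference.seed_hits(codes[off:off + k]):
                candidates.add(int(hit) - off)
        for gstart in candidates:
            loc = reference.locate(gstart, length)
            if loc is None:
                continue
            mm = int(np.count_nonzero(
                reference.fetch_codes(gstart, length) != codes))
            if mm > cutoff:
                continue
            chrom, start = loc
            p = Placement(chromosome=chrom, start=start,
                          end=start + length - 1, strand=strand,
                          mismatches=mm)
            if best_mm is None or mm < best_mm:
                best, best_mm = [p], mm
            elif mm == best_mm:
                best.append(p)
    return sorted(best, key=lambda p: (p.chromosome, p.start, p.strand))


def pair_and_filter(ves_placements: Sequence[Placement],
                    flank_placements: Sequence[Placement],
                    taxon: str = "", pair_id: str = "",
                    expected_insert: int = 400,
                    max_pair_distance: int = 800) -> Optional[MappedPair]:
    """Select the properly oriented placement combination, or reject.

    Valid combinations share a chromosome, have mates on opposite strands
    facing each other, and an outer span (fragment length) at most
    ``max_pair_distance``.  The combination with span closest to
    ``expected_insert`` wins; a tie between distinct placements, or no valid
    combination, rejects the pair.
    """
    candidates = []
    for v in ves_placements:
        for f in flank_placements:
            if v.chromosome != f.chromosome or v.strand == f.strand:
                continue
            plus, minus = (v, f) if v.strand == "+" else (f, v)
            if plus.start > minus.end:
                continue                      # not facing inward
            span = minus.end - plus.start + 1
            if span > max_pair_distance:
                continue
            candidates.append((abs(span - expected_insert), v, f))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[0])
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        _, v0, f0 = candidates[0]
        _, v1, f1 = candidates[1]
        if (v0, f0) != (v1, f1):
            return None                       # ambiguous placement
    _, v, f = candidates[0]
    return MappedPair(taxon=taxon, chromosome=v.chromosome,
                      ves_strand=v.strand, ves_span=(v.start, v.end),
                      flank_span=(f.start, f.end), mapq_unique=True,
                      pair_id=pair_id)


def extract_site(pair: MappedPair,
                 chrom_lengths: Dict[str, int],
                 five_prime_offset: bool = True) -> Optional[SiteEvidence]:
    """Insertion-site evidence from an accepted pair.

    With the default convention the site is the reference base immediately
    preceding the SINE read's 5'-most aligned base; ``five_prime_offset=False``
    instead reports the first aligned base (a uniform 1 bp shift that leaves
    clustering unchanged).  Sites falling off the chromosome are dropped.
    """
    off = 1 if five_prime_offset else 0
    if pair.ves_strand == "+":
        position = pair.ves_span[0] - off
    else:
        position = pair.ves_span[1] + off
    if position < 1 or position > chrom_lengths[pair.chromosome]:
        logger.info("site for %s off chromosome end; dropped", pair.pair_id)
        return None
    return SiteEvidence(taxon=pair.taxon, chromosome=pair.chromosome,
                        position=position, orientation=pair.ves_strand)


# --------------------------------------------------------------------------
# Pipeline-level mapping driver
# --------------------------------------------------------------------------


@dataclass
class MappingResult:
    mapped: List[MappedPair]
    n_input: int
    n_rejected: int
    evidence: List[SiteEvidence]
    n_sites_dropped: int


def map_pairs(pairs, reference: Reference, taxon: str,
              expected_insert: int = 400, max_pair_distance: int = 800,
              max_mismatch_frac: float = 0.1,
              five_prime_offset: bool = True) -> MappingResult:
    """Map processed pairs for one taxon and extract site evidence."""
    mapped: List[MappedPair] = []
    evidence: List[SiteEvidence] = []
    n_rej = 0
    n_drop = 0
    for p in pairs:
        vp = map_read(p.ves_seq, reference, max_mismatch_frac)
        fp = map_read(p.flank_seq, reference, max_mismatch_frac)
        if not vp or not fp:
            n_rej += 1
            continue
        mp = pair_and_filter(vp, fp, taxon=taxon, pair_id=p.pair_id,
                             expected_insert=expected_insert,
                             max_pair_distance=max_pair_distance)
        if mp is None:
            n_rej += 1
            continue
        mapped.append(mp)
        ev = extract_site(mp, reference.lengths, five_prime_offset)
        if ev is None:
            n_drop += 1
        else:
            evidence.append(ev)
    return MappingResult(mapped=mapped, n_input=len(pairs), n_rejected=n_rej,
                         evidence=evidence, n_sites_dropped=n_drop)


# --------------------------------------------------------------------------
# SAM interchange (pysam; proper pairs carry flag 0x2 like the upstream
# samtools -f 0x002 filter)
# --------------------------------------------------------------------------


def write_sam(mapped: Iterable[MappedPair], chrom_lengths: Dict[str, int],
              path: str):
    chroms = sorted(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in chroms],
        "RG": [],
    }
    taxa = sorted({m.taxon for m in mapped})
    header["RG"] = [{"ID": t, "SM": t} for t in taxa]
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for m in mapped:
            for which, span, strand in (
                    ("flank", m.flank_span,
                     "-" if m.ves_strand == "+" else "+"),
                    ("ves", m.ves_span, m.ves_strand)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = m.pair_id or f"{m.taxon}:{span[0]}"
                length = span[1] - span[0] + 1
                a.query_sequence = "N" * length
                a.flag = (0x1 | 0x2
                          | (0x40 if which == "flank" else 0x80)
                          | (0x10 if strand == "-" else 0)
                          | (0x20 if strand == "+" else 0))
                a.reference_id = tid[m.chromosome]
                a.reference_start = span[0] - 1
                a.cigarstring = f"{length}M"
                a.mapping_quality = 60 if m.mapq_unique else 0
                mate = m.ves_span if which == "flank" else m.flank_span
                a.next_reference_id = tid[m.chromosome]
                a.next_reference_start = mate[0] - 1
                a.set_tag("RG", m.taxon)
                out.write(a)


def ingest_sam(path: str, default_taxon: Optional[str] = None
               ) -> List[MappedPair]:
    """Read properly paired primary alignments from SAM into MappedPairs.

    The SINE read is the second-in-pair mate; taxon comes from the RG tag
    (or ``default_taxon``).  Pairs failing the proper-pair flag, or with a
    missing mate, are skipped.
    """
    first: Dict[str, object] = {}
    second: Dict[str, object] = {}
    with pysam.AlignmentFile(path, "r") as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.is_proper_pair:
                continue
            (first if rec.is_read1 else second)[rec.query_name] = (
                rec.reference_name, rec.reference_start + 1,
                rec.reference_end, rec.is_reverse,
                rec.get_tag("RG") if rec.has_tag("RG") else default_taxon,
                rec.mapping_quality)
    out: List[MappedPair] = []
    for name in sorted(set(first) & set(second)):
        fc, fs, fe, frev, ftax, fq = first[name]
        vc, vs, ve, vrev, vtax, vq = second[name]
        if fc != vc:
            continue
        taxon = vtax or ftax or default_taxon
        if taxon is None:
            raise DataError(f"no read group or taxon for {name}")
        out.append(MappedPair(
            taxon=taxon, chromosome=vc,
            ves_strand="-" if vrev else "+", ves_span=(vs, ve),
            flank_span=(fs, fe), mapq_unique=(vq > 0 and fq > 0),
            pair_id=name))
    return out


def evidence_to_bed(evidence: Iterable[SiteEvidence], path: str):
    """6-column BED-like TSV: chrom, pos-1, pos, taxon, count=1, strand."""
    with open(path, "w") as fh:
        for ev in evidence:
            fh.write(f"{ev.chromosome}\t{ev.position - 1}\t{ev.position}\t"
                     f"{ev.taxon}\t1\t{ev.orientation}\n")
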