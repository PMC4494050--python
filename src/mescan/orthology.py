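"""Cross-taxon orthology grouping, character-matrix coding, and validation
locus selection.

Insertion sites called independently in different taxa are treated as the
same ancestral insertion (one orthologous locus) when they map within 10 bp
of each other in the same orientation; grouping is single-linkage per
(chromosome, orientation).  Loci become binary characters: present (1) when
a taxon contributed a site, absent (0) otherwise — except for designated
low-coverage ("failed library") taxa, whose absences are coded missing (?)
because a failed library cannot attest absence.  An artificial all-absent
ancestor row roots later parsimony analyses; characters present in fewer
than two ingroup taxa are autapomorphies (or empty) and are excluded from
the informative matrix.

Validation-panel selection mirrors the wet-lab screening criteria: a
candidate locus needs more than ten supporting read pairs in some taxon, no
annotated transposable element within +/-1 kb, and no distinct called
insertion within 1 kb.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree

from .errors import ConfigError, DataError
from .site_calling import ConsolidatedSite

logger = logging.getLogger(__name__)

ANCESTOR = "ANCESTOR"


@dataclass
class InsertionLocus:
    locus_id: str
    chromosome: str
    ref_position: int
    orientation: str
    per_taxon_state: Dict[str, str] = field(default_factory=dict)
    per_taxon_support: Dict[str, int] = field(default_factory=dict)
    member_positions: Dict[str, int] = field(default_factory=dict)


def group_orthologs(sites: Iterable[ConsolidatedSite], window: int = 10,
                    orientation_aware: bool = True) -> List[InsertionLocus]:
    """Single-linkage clusters of called sites within ``window`` bp, one
    locus per cluster.

    The locus coordinate is the position of the highest-support member (ties
    to the smallest coordinate).  Two sites from the same taxon falling into
    one cluster merge with a warning — presence is binary, but this flags a
    possible under-split duplicate.
    """
    grouped: Dict[Tuple[str, str], List[ConsolidatedSite]] = defaultdict(list)
    for s in sites:
        key = (s.chromosome, s.orientation if orientation_aware else "*")
        grouped[key].append(s)
    loci: List[InsertionLocus] = []
    for (chrom, orient), members in sorted(grouped.items()):
        members.sort(key=lambda s: s.position)
        cluster: List[ConsolidatedSite] = []
        for s in members:
            if cluster and s.position - cluster[-1].position > window:
                loci.append(_make_locus(chrom, orient, cluster))
                cluster = []
            cluster.append(s)
        if cluster:
            loci.append(_make_locus(chrom, orient, cluster))
    loci.sort(key=lambda l: (l.chromosome, l.ref_position, l.orientation))
    for i, l in enumerate(loci):
        l.locus_id = f"locus_{i + 1:06d}"
    return loci


def _make_locus(chrom: str, orient: str,
                cluster: Sequence[ConsolidatedSite]) -> InsertionLocus:
    support: Dict[str, int] = defaultdict(int)
    member_pos: Dict[str, int] = {}
    taxa_seen: Set[str] = set()
    for s in cluster:
        if s.taxon in taxa_seen:
            logger.warning(
                "two sites from %s merged into one locus near %s:%d "
                "(possible undercalled duplicate)", s.taxon, chrom, s.position)
        taxa_seen.add(s.taxon)
        support[s.taxon] += s.read_count
        member_pos.setdefault(s.taxon, s.position)
    rep = max(cluster, key=lambda s: (s.read_count, -s.position))
    return InsertionLocus(
        locus_id="", chromosome=chrom, ref_position=rep.position,
        orientation=orient if orient != "*" else rep.orientation,
        per_taxon_state={t: "1" for t in taxa_seen},
        per_taxon_support=dict(support), member_positions=member_pos)


# --------------------------------------------------------------------------
# Character matrix
# --------------------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """taxa x loci matrix over {0, 1, ?} with an all-absent ancestor row."""

    taxa: List[str]                    # ancestor included
    locus_ids: List[str]
    states: np.ndarray                 # dtype '<U1', shape (n_taxa, n_loci)
    ancestor: str = ANCESTOR
    positions: Optional[List[Tuple[str, int]]] = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype="<U1")
        if self.states.shape != (len(self.taxa), len(self.locus_ids)):
            raise DataError("matrix shape does not match taxa x loci")
        anc_row = self.states[self.taxa.index(self.ancestor)]
        if not (anc_row == "0").all():
            raise DataError("ancestor row must be all-absent")

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]

    def ingroup(self) -> List[str]:
        return [t for t in self.taxa if t != self.ancestor]

    def resample_columns(self, seed: int) -> "CharacterMatrix":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, self.n_characters, size=self.n_characters)
        return CharacterMatrix(
            taxa=list(self.taxa),
            locus_ids=[self.locus_ids[i] for i in idx],
            states=self.states[:, idx], ancestor=self.ancestor,
            positions=[self.positions[i] for i in idx]
            if self.positions else None)

    # -- serialization -----------------------------------------------------

    def to_nexus(self, path: str):
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(self.taxa)} "
                     f"NCHAR={self.n_characters};\n")
            fh.write("  FORMAT DATATYPE=STANDARD SYMBOLS=\"01\" MISSING=? "
                     "INTERLEAVE=NO;\n  MATRIX\n")
            width = max(len(t) for t in self.taxa) + 2
            for i, t in enumerate(self.taxa):
                fh.write(f"    {t:<{width}}{''.join(self.states[i])}\n")
            fh.write("  ;\nEND;\n")

    def to_tsv(self, path: str):
        with open(path, "w") as fh:
            fh.write("taxon\t" + "\t".join(self.locus_ids) + "\n")
            for i, t in enumerate(self.taxa):
                fh.write(t + "\t" + "\t".join(self.states[i]) + "\n")

    @classmethod
    def from_tsv(cls, path: str, ancestor: str = ANCESTOR) -> "CharacterMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            locus_ids = header[1:]
            taxa, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                taxa.append(parts[0])
                rows.append(parts[1:])
        return cls(taxa=taxa, locus_ids=locus_ids,
                   states=np.array(rows, dtype="<U1"), ancestor=ancestor)

    @classmethod
    def from_nexus(cls, path: str, ancestor: str = ANCESTOR
                   ) -> "CharacterMatrix":
        import dendropy
        dm = dendropy.StandardCharacterMatrix.get(path=path, schema="nexus")
        taxa = [t.label for t in dm.taxon_namespace]
        rows = []
        for t in dm.taxon_namespace:
            rows.append([str(ch) for ch in dm[t].symbols_as_list()])
        n = len(rows[0])
        return cls(taxa=taxa, locus_ids=[f"char_{j + 1}" for j in range(n)],
                   states=np.array(rows, dtype="<U1"), ancestor=ancestor)


def code_matrix(loci: Sequence[InsertionLocus], taxa: Sequence[str],
                low_coverage_taxa: Sequence[str] = (),
                ancestor: str = ANCESTOR) -> CharacterMatrix:
    """Presence/absence/missing coding with an appended all-absent ancestor.

    Normal taxa absent from a locus are 0; low-coverage taxa absent from a
    locus are ? (their library cannot attest absence); contributors are 1.
    """
    taxa = list(taxa)
    low = set(low_coverage_taxa)
    if not low.issubset(taxa):
        raise ConfigError("low_coverage_taxa must be a subset of taxa")
    for l in loci:
        unknown = set(l.per_taxon_state) - set(taxa)
        if unknown:
            raise DataError(f"locus {l.locus_id} references unknown taxa "
                            f"{sorted(unknown)}")
    ordered = sorted(loci, key=lambda l: (l.chromosome, l.ref_position,
                                          l.orientation))
    n_taxa = len(taxa) + 1
    states = np.full((n_taxa, len(ordered)), "0", dtype="<U1")
    for j, l in enumerate(ordered):
        for i, t in enumerate(taxa):
            if l.per_taxon_state.get(t) == "1":
                states[i, j] = "1"
            elif t in low:
                states[i, j] = "?"
    return CharacterMatrix(taxa=taxa + [ancestor],
                           locus_ids=[l.locus_id for l in ordered],
                           states=states, ancestor=ancestor,
                           positions=[(l.chromosome, l.ref_position)
                                      for l in ordered])


def filter_informative(matrix: CharacterMatrix, min_presences: int = 2
                       ) -> Tuple[CharacterMatrix, int]:
    """Retain characters with >= ``min_presences`` definite-presence ingroup
    taxa; singletons (and empty columns) are excluded and counted."""
    anc_i = matrix.taxa.index(matrix.ancestor)
    ingroup_rows = [i for i in range(len(matrix.taxa)) if i != anc_i]
    n_present = (matrix.states[ingroup_rows] == "1").sum(axis=0)
    keep = n_present >= min_presences
    filtered = CharacterMatrix(
        taxa=list(matrix.taxa),
        locus_ids=[lid for lid, k in zip(matrix.locus_ids, keep) if k],
        states=matrix.states[:, keep], ancestor=matrix.ancestor,
        positions=[p for p, k in zip(matrix.positions, keep) if k]
        if matrix.positions else None)
    return filtered, int((~keep).sum())


def detect_low_coverage_taxa(pair_counts: Mapping[str, int],
                             frac_of_median: float = 0.05) -> List[str]:
    """Taxa whose retained read pairs fall below ``frac_of_median`` of the
    median taxon (the generalized "failed library" rule)."""
    if not pair_counts:
        return []
    med = float(np.median(list(pair_counts.values())))
    return sorted(t for t, n in pair_counts.items() if n < frac_of_median * med)


# --------------------------------------------------------------------------
# Validation-panel selection
# --------------------------------------------------------------------------


@dataclass
class ValidationLocus:
    locus_id: str
    chromosome: str
    position: int
    orientation: str
    max_support: int
    primer_window: Tuple[int, int]
    expected_size_difference: int


def select_validation_loci(loci: Sequence[InsertionLocus],
                           te_annotation: Mapping[str, Sequence[Tuple[int, int]]],
                           n: int, sine_length: int,
                           min_read_pairs: int = 11,
                           isolation: int = 1000,
                           te_free: int = 1000,
                           primer_flank: int = 100,
                           seed: Optional[int] = None
                           ) -> List[ValidationLocus]:
    """Sample a PCR-validation panel from loci meeting all three criteria.

    1. no annotated TE interval within +/-``te_free`` bp of the site;
    2. supported by >= ``min_read_pairs`` read pairs in some taxon
       ("greater than ten" = at least 11);
    3. no other called locus within ``isolation`` bp.

    ``te_annotation`` maps chromosome to (start, end) 1-based inclusive
    intervals.  When fewer than ``n`` loci qualify, all are returned with a
    warning.  The filled/empty amplicon size difference equals the element
    length.
    """
    trees: Dict[str, IntervalTree] = {}
    for chrom, ivals in te_annotation.items():
        t = IntervalTree()
        for s, e in ivals:
            t[s:e + 1] = True
        trees[chrom] = t
    by_chrom: Dict[str, List[int]] = defaultdict(list)
    for l in loci:
        by_chrom[l.chromosome].append(l.ref_position)
    for v in by_chrom.values():
        v.sort()

    candidates: List[ValidationLocus] = []
    for l in loci:
        support = max(l.per_taxon_support.values(), default=0)
        if support < min_read_pairs:
            continue
        t = trees.get(l.chromosome)
        if t is not None and t.overlap(l.ref_position - te_free,
                                       l.ref_position + te_free + 1):
            continue
        pos_list = by_chrom[l.chromosome]
        i = pos_list.index(l.ref_position)
        if (i > 0 and l.ref_position - pos_list[i - 1] <= isolation) or \
                (i + 1 < len(pos_list)
                 and pos_list[i + 1] - l.ref_position <= isolation):
            continue
        candidates.append(ValidationLocus(
            locus_id=l.locus_id, chromosome=l.chromosome,
            position=l.ref_position, orientation=l.orientation,
            max_support=support,
            primer_window=(l.ref_position - primer_flank,
                           l.ref_position + primer_flank),
            expected_size_difference=sine_length))
    if len(candidates) <= n:
        if len(candidates) < n:
            logger.warning("only %d of %d requested validation loci qualify",
                           len(candidates), n)
        return candidates
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(candidates), size=n, replace=False))
    return [candidates[i] for i in idx]


def read_bed_intervals(path: str) -> Dict[str, List[Tuple[int, int]]]:
    """BED (0-based half-open) to 1-based inclusive intervals per chrom."""
    out: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            out[parts[0]].append((int(parts[1]) + 1, int(parts[2])))
    return dict(out)


# --------------------------------------------------------------------------
# Cross-taxon positional audit
# --------------------------------------------------------------------------


def cross_taxon_offset_audit(sites: Iterable[ConsolidatedSite],
                             window: int = 100,
                             orientation_aware: bool = True
                             ) -> Tuple[Dict[int, int], Optional[float]]:
    """Between-taxon nearest-site offset histogram.

    For every ordered taxon pair and every site of the first taxon, the
    absolute offset to the nearest site of the second taxon (same chromosome
    and, by default, same orientation) is tabulated when it falls within
    +/-``window`` bp.  Returns (offset -> count, fraction of tabulated
    offsets <= 10 bp).
    """
    by_taxon: Dict[str, Dict[Tuple[str, str], List[int]]] = defaultdict(
        lambda: defaultdict(list))
    for s in sites:
        key = (s.chromosome, s.orientation if orientation_aware else "*")
        by_taxon[s.taxon][key].append(s.position)
    for d in by_taxon.values():
        for v in d.values():
            v.sort()
    taxa = sorted(by_taxon)
    if len(taxa) < 2:
        return {}, None
    hist: Dict[int, int] = defaultdict(int)
    for ta in taxa:
        for tb in taxa:
            if ta == tb:
                continue
            for key, pos_a in by_taxon[ta].items():
                pos_b = by_taxon[tb].get(key)
                if not pos_b:
                    continue
                arr_b = np.asarray(pos_b)
                for p in pos_a:
                    i = int(np.searchsorted(arr_b, p))
                    d = None
                    if i < len(arr_b):
                        d = abs(int(arr_b[i]) - p)
                    if i > 0:
                        d2 = abs(p - int(arr_b[i - 1]))
                        d = d2 if d is None else min(d, d2)
                    if d is not None and d <= window:
                        hist[d] += 1
    total = sum(hist.values())
    if total == 0:
        return {}, None
    frac10 = sum(c for d, c in hist.items() if d <= 10) / total
    return dict(sorted(hist.items())), frac10


def loci_to_bed(loci: Iterable[InsertionLocus], path: str):
    with open(path, "w") as fh:
        for l in loci:
            support = sum(l.per_taxon_support.values())
            fh.write(f"{l.chromosome}\t{l.ref_position - 1}\t"
                     f"{l.ref_position}\t{l.locus_id}\t{support}\t"
                     f"{l.orientation}\n")
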