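# Methods

`mescan` reconstructs a retrotransposon-insertion phylogeny from targeted
SINE-capture sequencing. This note documents the model behind each stage,
the parameters that matter, what the simulator does and does not emulate,
and the numerical choices made where the procedure was genuinely open.

## The data model

A capture library enriches ~550 bp genomic fragments containing a targeted
SINE (here, a Ves-family element of vesper bats). Paired-end 100 nt
sequencing of such a fragment yields:

* a **SINE read** that begins with a short prefix of the element consensus
  (17–34 bp; 30 bp by default here) and continues into the genomic DNA
  adjacent to the insertion, and
* a **flanking read** that begins with a 6 bp library index identifying the
  taxon, followed by genomic DNA roughly one insert size (~400 bp) away
  from the insertion point.

The **insertion site** is defined as the reference base immediately 5' of
the SINE read's aligned genomic portion: on the plus strand the base before
the alignment start, on the minus strand the base after the alignment end.
An alternative convention (the first aligned base itself) is selectable via
`five_prime_offset=False`; it shifts every site by exactly 1 bp and
therefore changes no clustering or downstream character.

## Read processing

* **Demultiplexing** is by exact match of the flanking read's first 6 bases
  against the index table. One mismatch — or an N — excludes the pair. No
  fuzzy rescue is attempted; indices are generated with pairwise Hamming
  distance ≥ 2 so a single error cannot silently reassign a read.
* **SINE-prefix clipping** scans clip lengths L from `min_clip_match` (17,
  the lower end of the expected SINE span in the read) to the 34 bp probe
  length and scores each candidate as `matches − 4·mismatches`, requiring a
  mismatch fraction ≤ 10 %. The best-scoring span is removed. The penalty
  of 4 keeps a sequencing error inside the true prefix from truncating the
  clip, while making spurious extension into genomic sequence unprofitable
  unless several bases match by chance; chance extension is bounded by the
  4 bp between the default 30 bp prefix and the 34 bp probe, so a clipped
  read starts within ±4 bp (almost always ±1 bp) of the true genomic
  boundary, which the ±2 bp site consolidation absorbs. Reads without an
  acceptable prefix are discarded ("no expected SINE"); reads left with
  < 20 genomic bases are discarded separately as unmappable.
* **Quality filtering** removes any read whose mean Phred+33 score is below
  15; a mean of exactly 15 is kept (the rule is "less than 15"). The filter
  is applied to each mate independently (so effectively both mates must
  pass), since whether the original protocol filtered the flanking mate too
  is not documented.
* **Re-pairing**: because the two mate files are filtered independently,
  surviving streams are intersected by pair id; unmatched mates are kept as
  orphans. Output order is sorted by pair id, hence deterministic.

Every stage satisfies kept + discarded = input; this is asserted in tests.

## Mapping and proper-pair selection

A minimal ungapped seed-and-extend mapper stands in for a general-purpose
aligner, which would be overkill for synthetic references: the reference is
indexed by sorted 20-mers (2-bit encoded); non-overlapping read k-mers
propose candidate diagonals; each candidate is scored by full-length
mismatch count (≤ 10 % allowed), on both strands; **all** minimum-mismatch
placements are returned so multi-mapping is observable. Pre-mapped SAM can
be ingested instead (proper-pair flag 0x2, read group = taxon); both routes
yield identical site evidence on the same reads, which is tested.

A pair is accepted when some placement combination puts the mates on one
chromosome, on opposite strands, facing inward, with an outer fragment span
≤ 800 bp (twice the 400 bp expected insert); among valid combinations the
one closest to 400 bp wins. Ambiguous pairs — a tie between distinct
placements — are rejected rather than placed arbitrarily, because site
positions feed presence/absence characters where a false coordinate is
worse than a lost read.

## Site calling and orthology

Within one (taxon, chromosome, orientation) group, raw per-read site
positions are merged by **single-linkage chaining with adjacent gap ≤ 2 bp**
and the chain is called at its modal position (tie → smallest coordinate).
Chaining, rather than a fixed 5 bp window, is what reproduces the canonical
example — candidates 100/101/102 with 10/1/140 reads merge and the call is
102. Consolidation is idempotent and order-independent, and matches the
brute-force transitive closure of the |Δpos| ≤ 2 relation (tested against
that oracle).

Across taxa, called sites within **10 bp** in the **same orientation** are
grouped into one orthologous locus (single-linkage again; checked against
the same oracle at window 10). Orientation is part of the key because two
independent insertions at one spot in opposite orientations are
distinguishable by construction of the capture assay; a flag disables this
for sensitivity analyses. The locus coordinate is the highest-support
member's position — a reporting choice only; it affects no character.

Characters are coded 1 (taxon contributed a site), 0 (absent), or ? for
**low-coverage taxa**, whose failed libraries cannot attest absence.
Low-coverage taxa are either configured explicitly or detected as taxa with
retained pairs < 5 % of the median taxon. An artificial all-absent ancestor
row roots the analysis. Characters with fewer than two definite presences
among the ingroup (autapomorphies and empty columns) are excluded;
constant-presence columns are retained, since only singletons are excluded
by the rule.

Validation-panel selection mirrors wet-lab screening: ≥ 11 supporting read
pairs in some taxon ("more than ten"), no annotated TE within ±1 kb, no
other called locus within 1 kb; `n` candidates are sampled with a seed, and
each is reported with a ±100 bp primer window and an expected filled/empty
amplicon size difference equal to the element length.

## Dollo parsimony

Each character may be gained once and lost arbitrarily often. The score of
a character on a rooted tree is computed by placing the gain on the branch
above the MRCA of all definite presences and counting one loss per maximal
subtree below it whose definite leaves are all absent (subtrees that are
entirely missing-data resolve cost-free): `steps = 1 + losses`, or 0 when
no definite presence exists. This equals the exhaustive minimum over all
single-gain ancestral assignments; the test suite sweeps every rooted
topology with ≤ 6 leaves × every state vector over {0,1,?} against an
independent brute-force enumerator. Identical columns are
pattern-compressed (weight = multiplicity) before search.

**Search.** Exhaustive search enumerates all rooted ingroup topologies
((2n−3)!! of them; 10,395 at 7 ingroup taxa) and returns every
minimum-score tree; it refuses above 9 leaves including the ancestor.
Heuristic search does seeded random-addition stepwise insertion followed by
first-improvement hill climbing over the SPR neighborhood (which contains
all NNI moves) to a local optimum, best of 10 replicates by default. On
every instance where both run, the heuristic attains the exhaustive
minimum (tested).

**Bootstrap.** Characters are resampled with replacement to the original
count; the search is re-run per replicate (on the exhaustive path this is a
single matrix product of precomputed topology × pattern scores against the
replicate weights, so thousands of replicates are cheap); a clade is
credited only when it appears in **every** equally best tree of the
replicate (strict-consensus counting). This makes a single replicate give
supports in {0, 100} and prevents ties from inflating support — the cost is
that a taxon whose placement the data genuinely cannot pin (e.g. a failed
library with almost no reads) drags down the support of every clade its
wandering placement can disrupt, which is the honest answer.

**Fit statistics.** With S the tree length, M the sum over characters of
the minimum conceivable steps (1 per character with any definite presence)
and G the sum of worst-case steps under a single gain (1 + number of
definite-absence ingroup leaves), the package reports CI = M/S,
HI = 1 − CI, RI = (G−S)/(G−M), RC = CI·RI. G under Dollo has no single
published convention; the worst-case-single-gain definition used here need
not match every legacy program's internal bookkeeping, so RI/RC values are
comparable within this package rather than across programs. S = 0 reports
all indices as 1.0 and is flagged degenerate.

## The simulator

The simulator generates: a uniform-random reference (default 1.1 Mb over 2
chromosomes); a known rooted binary ingroup tree (given shape or random
joining); loss-free Dollo-compliant insertion histories (each locus gained
on exactly one uniformly chosen branch; optional per-branch precise-excision
losses via `loss_rate`; optional deliberate near-parallel insertions within
25 bp via `near_parallel_rate`); and reads with the exact two-read anatomy
above, per-base substitution errors, and truncated-normal Phred+33
qualities (mean 35, sd 4, floored at 2, capped at 40 — only the filter
threshold is externally specified, so the quality model is a free choice).
Insertions live purely in reference coordinates; per-taxon genomes are
never materialized, because the pipeline only ever observes
reference-mapped positions. Insertion points are nudged (by ≤ 16 bp, with
spacing guarded accordingly) so that the first flank base in the SINE read
does not continue the element consensus: when it does, the SINE/genome
boundary inside the read is intrinsically ambiguous and every read of the
locus would clip long by the same amount, shifting the call systematically
by 1–4 bp. Real loci with consensus-continuing flanks (~25 % per extra
matching base) would show exactly that small offset — absorbed by the
±2 bp merge and ±10 bp orthology windows — but excluding them from the
generator keeps ground-truth coordinates exact, which is what the
error-free recovery tests assert. Loci are spaced ≥ 2 kb apart (stick-breaking
placement with guaranteed minimum gaps) so the ±1 kb validation criteria
and ±100 bp audit windows are meaningful. A fixed seed makes every output
byte-identical.

Not modeled: target-site duplications (the calling logic never uses them),
indel errors, adapter read-through, PCR duplicates, repeat-induced
multi-mapping beyond chance k-mer collisions, and real library-size biases
(coverage per locus is a free parameter instead). Passing tests therefore
demonstrate the correctness of the computational pipeline under its stated
read model, not robustness to every artifact of real capture libraries.

### Canonical study conditions

`mescan.simulate.study_config(seed)` freezes the simulated analog of a
single-lane, seven-taxon capture experiment used by the acceptance tests:
500 loss-free loci; per-taxon depth 37,500 pairs (= 75 pairs per locus,
matching the ~10 M read pairs per ~130 k insertions of a real lane); one
failed library at 0.05 % of normal depth (19 pairs — the real failed
library held ~5.8 k of ~10 M); failed-taxon absences coded ?. The true tree
shape is fixed as `(((((T1,T2),T3),T4),T5),(T6,T7))` with the failed taxon
T7 sister to T6, mirroring the real failed library, whose species has a
near-conspecific relative in the panel. The cherry placement matters
statistically: with absences missing, only loci gained on the failed
taxon's cherry stem pin its position (expected pins ≈ Binom(19, ~1/3) ≈ 6,
enough for > 95 % bootstrap support), whereas a basal failed taxon would be
an unpinnable wildcard no amount of sequencing of the *other* taxa could
place. At these sizes the full pipeline runs in ~2 minutes on one CPU;
the acceptance suite runs it twice (error-free, and at error rate 0.005).

## Known limitations

* The mapper is ungapped; an indel near an insertion site loses the read
  rather than shifting the site.
* Exhaustive search is capped at 9 leaves (topology count grows as
  (2n−3)!!); larger panels must use the heuristic, which is a local search
  without optimality guarantees.
* Strict-consensus bootstrap counting under-reports support in the presence
  of wildcard taxa (see above) — by design.
* With `near_parallel_rate > 0` the 10 bp orthology window can merge truly
  independent insertions planted ≤ 10 bp apart in the same orientation;
  this is the method's documented blind spot, not a bug.
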