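"""Demultiplexing, SINE-prefix clipping, quality filter, and re-pairing."""
import pytest

from mescan import (ConfigError, DataError, IndexedReadPair, ParseError,
                    ProcessConfig, clip_sine_prefix, demultiplex, mean_phred,
                    process_pairs, quality_filter, repair_streams)
from mescan.read_processing import CLIPPED, NO_SINE, TOO_SHORT

PROBE = "ACGTACGTGGCCAATTCCGGAATTGGCCAATTGG"  # 34 bp


def make_pair(pair_id="p1", flank="ACGTAC" + "A" * 94, ves=None,
              flank_q=None, ves_q=None):
    if ves is None:
        ves = PROBE[:30] + "A" * 70
    return IndexedReadPair(
        pair_id=pair_id, flank_seq=flank,
        flank_quals=flank_q or "I" * len(flank),
        ves_seq=ves, ves_quals=ves_q or "I" * len(ves))


def config(**kw):
    params = dict(index_map={"T1": "ACGTAC", "T2": "TTTTTT"},
                  clip_probe=PROBE)
    params.update(kw)
    return ProcessConfig(**params)


class TestDemultiplex:
    def test_exact_match_assigns_and_strips_index(self):
        by_taxon, discarded = demultiplex([make_pair()], config())
        assert discarded == 0
        [p] = by_taxon["T1"]
        assert p.assigned_taxon == "T1"
        assert p.flank_seq == "A" * 94
        assert len(p.flank_quals) == 94

    def test_one_mismatch_discards(self):
        pair = make_pair(flank="ACGTAA" + "A" * 94)
        by_taxon, discarded = demultiplex([pair], config())
        assert discarded == 1
        assert not by_taxon["T1"] and not by_taxon["T2"]

    def test_n_in_index_discards(self):
        pair = make_pair(flank="NCGTAC" + "A" * 94)
        _, discarded = demultiplex([pair], config())
        assert discarded == 1

    def test_duplicate_index_rejected(self):
        with pytest.raises(ConfigError):
            config(index_map={"T1": "ACGTAC", "T2": "ACGTAC"})

    def test_empty_index_map_rejected(self):
        with pytest.raises(ConfigError):
            demultiplex([make_pair()], config(index_map={}))

    def test_conservation(self):
        pairs = [make_pair("a"), make_pair("b", flank="GGGGGG" + "A" * 94),
                 make_pair("c", flank="TTTTTT" + "C" * 94)]
        by_taxon, discarded = demultiplex(pairs, config())
        assert sum(map(len, by_taxon.values())) + discarded == len(pairs)


class TestClip:
    def test_clean_prefix_clipped(self):
        status, clipped = clip_sine_prefix(make_pair(), config())
        assert status == CLIPPED
        assert clipped.clip_len == 30
        assert clipped.ves_seq == "A" * 70
        assert len(clipped.ves_quals) == 70

    def test_no_similarity_discards(self):
        pair = make_pair(ves="T" * 100)
        status, clipped = clip_sine_prefix(pair, config())
        assert status == NO_SINE and clipped is None

    def test_two_mismatches_in_thirty_still_clip(self):
        ves = list(PROBE[:30])
        ves[5] = "A" if ves[5] != "A" else "C"
        ves[20] = "A" if ves[20] != "A" else "C"
        pair = make_pair(ves="".join(ves) + "A" * 70)
        status, clipped = clip_sine_prefix(pair, config())
        assert status == CLIPPED
        assert clipped.ves_seq.endswith("A" * 60)

    def test_short_remainder_discarded_separately(self):
        pair = make_pair(ves=PROBE[:30] + "T" * 10)
        status, clipped = clip_sine_prefix(pair, config())
        assert status == TOO_SHORT and clipped is None

    def test_clipping_is_idempotent(self):
        status, clipped = clip_sine_prefix(make_pair(), config())
        assert status == CLIPPED
        status2, _ = clip_sine_prefix(clipped, config())
        assert status2 == NO_SINE  # prefix no longer present


class TestQualityFilter:
    def test_mean_exactly_fifteen_kept(self):
        # '0' encodes Q15; "less than 15" removes, so mean == 15 is kept
        pair = make_pair(flank_q="0" * 100, ves_q="0" * 100)
        assert quality_filter(pair, config())

    def test_q13_discarded(self):
        pair = make_pair(ves_q="." * 100)
        assert not quality_filter(pair, config())

    def test_mixed_mean_below_threshold_discarded(self):
        # 60 bases at Q20 ('5'), 40 at Q7 ('('): mean by direct summation
        quals = "5" * 60 + "(" * 40
        expected = (20 * 60 + 7 * 40) / 100
        assert expected == pytest.approx(14.8)
        assert mean_phred(quals) == pytest.approx(expected)
        assert not quality_filter(make_pair(ves_q=quals), config())

    def test_both_mates_must_pass(self):
        assert not quality_filter(make_pair(flank_q="." * 100), config())

    def test_malformed_quality_string_identifies_record(self):
        with pytest.raises(ParseError, match="p9"):
            mean_phred("II" + chr(10) + "I", record_id="p9")


class TestRepair:
    def test_set_intersection(self):
        ves = [(str(i), f"v{i}") for i in (1, 2, 3)]
        flank = [(str(i), f"f{i}") for i in (2, 3, 4)]
        pairs, orphans = repair_streams(ves, flank)
        assert [p[0] for p in pairs] == ["2", "3"]
        assert sorted(o[0] for o in orphans) == ["1", "4"]

    def test_disjoint_sets_all_orphans(self):
        pairs, orphans = repair_streams([("1", "v")], [("2", "f")])
        assert pairs == [] and len(orphans) == 2

    def test_identical_sets_no_orphans(self):
        pairs, orphans = repair_streams([("1", "v")], [("1", "f")])
        assert len(pairs) == 1 and orphans == []

    def test_duplicate_pair_id_raises(self):
        with pytest.raises(DataError):
            repair_streams([("1", "a"), ("1", "b")], [])


class TestWholeStage:
    def test_conservation_at_every_stage(self, small_dataset):
        from mescan.read_processing import read_pairs_fastq
        paths = small_dataset["paths"]
        cfg = ProcessConfig(
            index_map=small_dataset["reads"].index_map,
            clip_probe=small_dataset["consensus"][:34])
        pairs = list(read_pairs_fastq(paths["r1"], paths["r2"]))
        result = process_pairs(pairs, cfg)
        demux_total = sum(c.demuxed for c in result.counts.values())
        assert demux_total + result.n_index_discarded == result.n_input
        for c in result.counts.values():
            assert c.clipped + c.no_sine + c.too_short == c.demuxed
            ves_pass = c.clipped - c.ves_qual_fail
            flank_pass = c.demuxed - c.flank_qual_fail
            assert ves_pass + flank_pass == 2 * c.repaired + c.orphans

    def test_error_free_demultiplex_is_fully_correct(self, small_dataset):
        from mescan.read_processing import read_pairs_fastq
        paths = small_dataset["paths"]
        cfg = ProcessConfig(index_map=small_dataset["reads"].index_map,
                            clip_probe=small_dataset["consensus"][:34])
        pairs = list(read_pairs_fastq(paths["r1"], paths["r2"]))
        by_taxon, discarded = demultiplex(pairs, cfg)
        assert discarded == 0
        # truth taxon is recorded in the read title
        truth = {}
        with open(paths["r1"]) as fh:
            for line in fh:
                if line.startswith("@pair"):
                    pid, taxon_kv, _ = line[1:].split()
                    truth[pid] = taxon_kv.split("=")[1]
        for taxon, assigned in by_taxon.items():
            for p in assigned:
                assert truth[p.pair_id] == taxon
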