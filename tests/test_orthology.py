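"""Orthology grouping, matrix coding, informative filtering, validation
panel selection, and cross-taxon audits."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mescan import (CharacterMatrix, ConfigError, ConsolidatedSite, DataError,
                    code_matrix, cross_taxon_offset_audit,
                    detect_low_coverage_taxa, filter_informative,
                    group_orthologs, select_validation_loci)
from tests.test_site_calling import brute_force_clusters


def site(taxon, pos, chrom="chr1", orient="+", count=5):
    return ConsolidatedSite(taxon=taxon, chromosome=chrom, position=pos,
                            orientation=orient, read_count=count,
                            member_positions={pos: count})


class TestGrouping:
    def test_sites_within_ten_bp_merge(self):
        loci = group_orthologs([site("T1", 100), site("T2", 108)])
        assert len(loci) == 1
        assert loci[0].per_taxon_state == {"T1": "1", "T2": "1"}

    def test_sites_eleven_bp_apart_split(self):
        loci = group_orthologs([site("T1", 100), site("T2", 111)])
        assert len(loci) == 2

    def test_opposite_orientations_never_merge(self):
        loci = group_orthologs([site("T1", 100, orient="+"),
                                site("T2", 100, orient="-")])
        assert len(loci) == 2
        assert {l.orientation for l in loci} == {"+", "-"}

    def test_orientation_blind_mode_merges(self):
        loci = group_orthologs([site("T1", 100, orient="+"),
                                site("T2", 100, orient="-")],
                               orientation_aware=False)
        assert len(loci) == 1

    def test_representative_is_highest_support(self):
        loci = group_orthologs([site("T1", 100, count=3),
                                site("T2", 105, count=9)])
        assert loci[0].ref_position == 105

    def test_same_taxon_duplicates_merge_with_support_summed(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="mescan.orthology"):
            loci = group_orthologs([site("T1", 100, count=3),
                                    site("T1", 106, count=4)])
        assert len(loci) == 1
        assert loci[0].per_taxon_support == {"T1": 7}
        assert any("undercalled" in r.message for r in caplog.records)

    @given(st.lists(st.integers(min_value=1, max_value=500),
                    min_size=1, max_size=40, unique=True))
    @settings(max_examples=200, derandomize=True)
    def test_clusters_match_transitive_closure(self, positions):
        """Single-linkage grouping equals the brute-force transitive closure
        of the <= 10 bp relation (one taxon per site so every member
        position is observable)."""
        sites = [site(f"X{p}", p) for p in positions]
        loci = group_orthologs(sites, window=10)
        got = {frozenset(l.member_positions.values()) for l in loci}
        assert got == brute_force_clusters(positions, 10)


class TestMatrix:
    TAXA = ["A", "B", "C", "L"]

    def test_coding_with_low_coverage_taxon(self):
        loci = group_orthologs([site("A", 100), site("B", 105)])
        m = code_matrix(loci, self.TAXA, low_coverage_taxa=["L"])
        col = {t: m.states[m.taxa.index(t), 0] for t in m.taxa}
        assert col == {"A": "1", "B": "1", "C": "0", "L": "?",
                       m.ancestor: "0"}

    def test_low_coverage_presence_still_one(self):
        loci = group_orthologs([site("L", 100)])
        m = code_matrix(loci, self.TAXA, low_coverage_taxa=["L"])
        assert m.states[m.taxa.index("L"), 0] == "1"
        assert (m.states[m.taxa.index("A"), 0] ==
                m.states[m.taxa.index(m.ancestor), 0] == "0")

    def test_no_low_coverage_no_missing(self):
        loci = group_orthologs([site("A", 100), site("B", 2000)])
        m = code_matrix(loci, self.TAXA)
        assert not (m.states == "?").any()

    def test_unknown_taxon_raises(self):
        loci = group_orthologs([site("X", 100)])
        with pytest.raises(DataError):
            code_matrix(loci, self.TAXA)

    def test_column_order_by_position(self):
        loci = group_orthologs([site("A", 5000), site("A", 100),
                                site("B", 900, chrom="chr2")])
        m = code_matrix(loci, self.TAXA)
        assert m.positions == [("chr1", 100), ("chr1", 5000), ("chr2", 900)]


class TestInformativeFilter:
    def make(self, cols):
        taxa = list("ABCDEFG")
        states = [[c[i] for c in cols] for i in range(7)] + [["0"] * len(cols)]
        return CharacterMatrix(taxa=taxa + ["ANC"],
                               locus_ids=[f"l{i}" for i in range(len(cols))],
                               states=np.array(states, dtype="<U1"),
                               ancestor="ANC")

    def test_singleton_excluded(self):
        m, n_exc = filter_informative(self.make(["1000000"]))
        assert m.n_characters == 0 and n_exc == 1

    def test_two_presences_retained(self):
        m, n_exc = filter_informative(self.make(["1100000"]))
        assert m.n_characters == 1 and n_exc == 0

    def test_all_present_retained(self):
        """Only singletons are excluded; constant-presence columns stay."""
        m, _ = filter_informative(self.make(["1111111"]))
        assert m.n_characters == 1

    def test_missing_does_not_count_as_presence(self):
        m, n_exc = filter_informative(self.make(["1?00000"]))
        assert m.n_characters == 0 and n_exc == 1

    def test_conservation(self):
        cols = ["1100000", "1000000", "1111111", "0100000"]
        m, n_exc = filter_informative(self.make(cols))
        assert m.n_characters + n_exc == len(cols)

    def test_nexus_round_trip(self, tmp_path):
        m = self.make(["1100000", "10?0010"])
        path = str(tmp_path / "m.nex")
        m.to_nexus(path)
        back = CharacterMatrix.from_nexus(path, ancestor="ANC")
        assert back.taxa == m.taxa
        assert (back.states == m.states).all()


class TestLowCoverageDetection:
    def test_failed_library_detected(self):
        counts = {"A": 1000, "B": 1200, "C": 900, "L": 10}
        assert detect_low_coverage_taxa(counts) == ["L"]

    def test_no_failure_no_detection(self):
        assert detect_low_coverage_taxa({"A": 1000, "B": 900}) == []


class TestValidationPanel:
    def make_loci(self):
        return group_orthologs([
            site("T1", 10_000, count=25),       # clean candidate
            site("T1", 20_000, count=10),       # support too low (10 < 11)
            site("T1", 30_000, count=25),       # TE 500 bp away
            site("T1", 40_000, count=25),       # other locus 800 bp away
            site("T2", 40_800, count=25),
        ])

    def test_criteria_applied(self):
        loci = self.make_loci()
        te = {"chr1": [(30_500, 30_700)]}
        panel = select_validation_loci(loci, te, n=10, sine_length=200,
                                       seed=0)
        assert [v.position for v in panel] == [10_000]
        v = panel[0]
        assert v.primer_window == (9_900, 10_100)
        assert v.expected_size_difference == 200

    def test_locus_isolated_beyond_1kb_accepted(self):
        loci = group_orthologs([site("T1", 10_000, count=25),
                                site("T2", 11_200, count=25)])
        panel = select_validation_loci(loci, {}, n=10, sine_length=200,
                                       seed=0)
        assert len(panel) == 2

    def test_sampling_is_seeded(self):
        loci = group_orthologs([site("T1", p, count=25)
                                for p in range(10_000, 40_000, 3000)])
        a = select_validation_loci(loci, {}, n=3, sine_length=200, seed=4)
        b = select_validation_loci(loci, {}, n=3, sine_length=200, seed=4)
        assert [v.locus_id for v in a] == [v.locus_id for v in b]


class TestCrossTaxonAudit:
    def test_identical_site_lists_give_zero_offsets(self):
        sites = [site("T1", p) for p in (100, 5000)] + \
                [site("T2", p) for p in (100, 5000)]
        hist, frac = cross_taxon_offset_audit(sites)
        assert set(hist) == {0} and frac == 1.0

    def test_single_taxon_empty(self):
        assert cross_taxon_offset_audit([site("T1", 100)]) == ({}, None)

    def test_unrelated_sites_outside_window_excluded(self):
        sites = [site("T1", 100), site("T2", 10_000)]
        hist, frac = cross_taxon_offset_audit(sites, window=100)
        assert hist == {} and frac is None
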