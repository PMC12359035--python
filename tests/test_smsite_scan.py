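"""Motif compilation, Sm-site scanning, gene summaries and mimic searches."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smsite.annotation_io import Region, TranscriptModel
from smsite.reference import (
    brute_force_5ss,
    brute_force_branchpoints,
    positionwise_scan,
)
from smsite.smsite_scan import (
    MOTIFS,
    SmSiteHit,
    compile_motif,
    merge_annotations,
    resolve_structure,
    scan_5ss,
    scan_branchpoints,
    scan_sm_sites,
    summarize_gene,
)

# AU-rich alphabet so random sequences actually contain degenerate-site hits
rna_text = st.text(alphabet="AUUGC", min_size=30, max_size=400)


class TestCompileMotif:
    def test_u1_accepts_only_itself(self):
        m = compile_motif("AUUUGUG")
        assert m.matches("AUUUGUG")
        assert m.matches("ATTTGTG")  # DNA alphabet folds onto U
        assert not m.matches("AUUUGUA")

    def test_nc_expansion_is_32(self):
        from itertools import product

        m = compile_motif("AUNUKUN")
        n = sum(m.matches("".join(p)) for p in product("ACGU", repeat=7))
        assert n == 4 * 2 * 4

    def test_empty_and_illegal_patterns_rejected(self):
        with pytest.raises(ValueError):
            compile_motif("")
        with pytest.raises(ValueError, match="X"):
            compile_motif("AUX")

    def test_subject_n_never_matches(self):
        m = compile_motif("AUNUKUN")
        assert not m.matches("AUNUGUA")


class TestScanSmSites:
    def test_u2_site_yields_u2_and_nc_with_windows(self):
        seq = "C" * 100 + "AUUUUUG" + "C" * 193
        hits = scan_sm_sites("t1", seq)
        assert {(h.motif_name, h.start) for h in hits} == {("U2", 100), ("NC", 100)}
        for h in hits:
            assert len(h.upstream_seq) == 100
            assert len(h.downstream_seq) == 50

    def test_u5_site_is_not_a_u2_site(self):
        seq = "C" * 50 + "AUUUUUUG" + "C" * 50
        hits = scan_sm_sites("t1", seq)
        assert {(h.motif_name, h.start) for h in hits} == {("U5", 50), ("NC", 50)}

    def test_short_downstream_tail_discards_hit(self):
        # motif ends 10 nt before the 3' end: under the >= 16 nt rule the
        # hit is dropped (the U4atac case)
        seq = "C" * 50 + "AUUUUUG" + "C" * 10
        assert scan_sm_sites("t1", seq) == []

    def test_mutated_sites_never_match(self):
        for mutant in ("ACCCCCG", "ACUCUCG"):
            seq = "G" * 60 + mutant + "G" * 60
            assert scan_sm_sites("t1", seq) == []

    @settings(max_examples=60, deadline=None)
    @given(rna_text)
    def test_scanner_equals_positionwise_rescan(self, seq):
        hits = scan_sm_sites("t", seq)
        for motif in MOTIFS:
            mine = sorted(h.start for h in hits if h.motif_name == motif.name)
            mlen = len(motif.pattern)
            oracle = [
                s
                for s in positionwise_scan(seq, motif.pattern)
                if len(seq) - (s + mlen) >= 16
            ]
            assert mine == oracle

    @settings(max_examples=60, deadline=None)
    @given(rna_text)
    def test_canonical_hits_are_nc_hits(self, seq):
        hits = scan_sm_sites("t", seq)
        nc_starts = {h.start for h in hits if h.motif_name == "NC"}
        for h in hits:
            if h.motif_name in ("U1", "U2", "U5"):
                assert h.start in nc_starts

    def test_region_assignment_from_transcript(self):
        t = TranscriptModel(
            "t1", "g1", exons=[(0, 300)], cds_start=50, cds_end=150, chrom="c"
        )
        seq = "C" * 200 + "AUUUUUG" + "C" * 93
        hits = scan_sm_sites("t1", seq, transcript=t)
        assert all(h.region == Region.THREE_UTR for h in hits)


def _retained(hit):
    return resolve_structure(hit, True, True)


class TestSummarizeGene:
    def _t(self, length=300):
        return TranscriptModel(
            "t1", "g1", exons=[(0, length)], cds_start=50, cds_end=150, chrom="c"
        )

    def test_canonical_subtraction(self):
        seq = "C" * 100 + "AUUUUUG" + "C" * 193
        hits = [_retained(h) for h in scan_sm_sites("t1", seq)]
        s = summarize_gene(hits, self._t())
        assert (s.n_U2, s.n_NC_raw) == (1, 1)
        assert (s.canonical_total, s.nc_true) == (1, 0)

    def test_empty_hits(self):
        s = summarize_gene([], self._t())
        assert s.canonical_total == 0 and s.nc_true == 0 and s.n_NC_raw == 0

    def test_nc_only_site_counts_as_true_noncanonical(self):
        seq = "C" * 40 + "AUAUGUA" + "C" * 60
        hits = [_retained(h) for h in scan_sm_sites("t1", seq)]
        s = summarize_gene(hits, self._t())
        assert (s.canonical_total, s.nc_true) == (0, 1)

    def test_unresolved_hits_rejected(self):
        seq = "C" * 100 + "AUUUUUG" + "C" * 193
        hits = scan_sm_sites("t1", seq)
        with pytest.raises(ValueError, match="structure"):
            summarize_gene(hits, self._t())

    def test_region_counts_follow_site_start(self):
        seq = "C" * 60 + "AUUUUUG" + "C" * 233
        hits = [_retained(h) for h in scan_sm_sites("t1", seq)]
        s = summarize_gene(hits, self._t())
        assert s.region_counts[("canonical", Region.CDS)] == 1
        assert s.region_counts[("noncanonical", Region.CDS)] == 1


def _hit(tid, start, motif="U2", down="C" * 20):
    return SmSiteHit(
        transcript_id=tid,
        motif_name=motif,
        start=start,
        site_seq="AUUUUUG",
        upstream_seq="",
        downstream_seq=down,
    )


class TestMergeAnnotations:
    def test_idempotent(self):
        hits = [_hit("t1", 5), _hit("t1", 40)]
        assert merge_annotations(hits, hits) == sorted(
            hits, key=lambda h: (h.transcript_id, h.start, h.motif_name)
        )

    def test_union_semantics(self):
        h1, h2, h3 = _hit("t1", 5, down="A" * 20), _hit("t1", 40), _hit("t2", 7)
        merged = merge_annotations([h1, h2], [h2, h3])
        assert merged == sorted(
            [h1, h2, h3], key=lambda h: (h.transcript_id, h.start, h.motif_name)
        )

    def test_commutative(self):
        a = [_hit("t1", 5), _hit("t1", 40, down="G" * 20)]
        b = [_hit("t1", 40, down="G" * 20), _hit("t3", 2)]
        assert merge_annotations(a, b) == merge_annotations(b, a)

    def test_differing_downstream_keeps_both(self):
        h1 = _hit("t1", 5, down="C" * 20)
        h2 = _hit("t1", 5, down="C" * 19 + "A")
        merged = merge_annotations([h1], [h2])
        assert len(merged) == 2


class TestMimics:
    def test_5ss_exact(self):
        hits = scan_5ss("t", "GGCAGGUAAGUGG")
        assert [(h.kind, h.start) for h in hits] == [("ss5_exact", 2)]

    def test_5ss_mismatch_bulge(self):
        hits = scan_5ss("t", "GGCAGGUAAGCGG", allow_bulge=True)
        assert [(h.kind, h.start) for h in hits] == [("ss5_bulge_mismatch", 2)]

    def test_5ss_deletion_bulge(self):
        hits = scan_5ss("t", "GGCAGGUAGUGG", allow_bulge=True)
        assert ("ss5_bulge_deletion", 2) in [(h.kind, h.start) for h in hits]

    def test_no_bulge_calls_without_flag(self):
        assert scan_5ss("t", "GGCAGGUAAGCGG") == []

    @settings(max_examples=60, deadline=None)
    @given(rna_text)
    def test_5ss_equals_brute_force(self, seq):
        for allow in (False, True):
            mine = {h.start: h.kind for h in scan_5ss("t", seq, allow_bulge=allow)}
            assert mine == brute_force_5ss(seq, allow)

    @pytest.mark.parametrize(
        "seq,mode,expected",
        [
            ("CUGACCCC", "consensus", [0]),
            ("CACUGACA", "stringent", [0]),
            ("AAAAAAAA", "consensus", []),
            ("AAAAAAAA", "stringent", []),
        ],
    )
    def test_branchpoint_examples(self, seq, mode, expected):
        assert [h.start for h in scan_branchpoints("t", seq, mode)] == expected

    @settings(max_examples=40, deadline=None)
    @given(rna_text)
    def test_branchpoints_equal_brute_force(self, seq):
        for mode in ("consensus", "stringent"):
            mine = [h.start for h in scan_branchpoints("t", seq, mode)]
            assert mine == brute_force_branchpoints(seq, mode)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            scan_branchpoints("t", "ACGU", "loose")
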