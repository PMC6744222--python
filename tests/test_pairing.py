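"""Transcript filtering, ORF extraction, reciprocal-best-hit pairing."""

import numpy as np
import pytest

from pogdiv import TranscriptSet, extract_cds, filter_sequences, find_single_copy_pairs
from pogdiv.pairing import NoOrfError


def _random_cds(rng, n_codons):
    from pogdiv.codons import SENSE_CODONS

    return "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, n_codons))


class TestFilter:
    def test_short_sequence_removed(self):
        ts = TranscriptSet("x", [("s1", "A" * 29), ("s2", "A" * 30)])
        out = filter_sequences(ts, min_len=30, max_stop_frac=0.2)
        assert [sid for sid, _ in out.records] == ["s2"]

    def test_empty_set_passes_through(self):
        out = filter_sequences(TranscriptSet("x", []), 30, 0.2)
        assert out.records == []

    def test_stop_fraction_in_frame_zero(self):
        # 20 codons, 5 stops in frame 0 = 25% > 20%
        seq = ("TAA" * 5 + "AAA" * 15)
        assert len(seq) == 60
        ts = TranscriptSet("x", [("bad", seq), ("good", "AAA" * 20)])
        out = filter_sequences(ts, min_len=30, max_stop_frac=0.2)
        assert [sid for sid, _ in out.records] == ["good"]

    def test_all_removed_warns_not_errors(self):
        ts = TranscriptSet("x", [("s1", "A" * 10)])
        with pytest.warns(UserWarning):
            out = filter_sequences(ts, min_len=30, max_stop_frac=0.2)
        assert len(out) == 0

    def test_order_preserved(self):
        ts = TranscriptSet("x", [(f"s{i}", "A" * 40) for i in range(5)])
        out = filter_sequences(ts, 30, 0.2)
        assert [sid for sid, _ in out.records] == [f"s{i}" for i in range(5)]


class TestExtractCds:
    def test_stop_excluded(self):
        # frame-0 run ends at the TGA stop, which is excluded; the TTA codon
        # blocks the reverse strand (its complement is a TAA stop)
        assert extract_cds("ATGTTAAAATGA", min_orf_codons=2) == "ATGTTAAAA"

    def test_all_n_dropped(self):
        with pytest.raises(NoOrfError):
            extract_cds("N" * 60, min_orf_codons=2)

    def test_clean_cds_is_identity(self, rng):
        cds = _random_cds(rng, 50)
        assert extract_cds(cds) == cds

    def test_reverse_complement_orf_found(self, rng):
        from Bio.Seq import Seq

        # the mid-sequence TTA becomes a TAA stop on the opposite strand,
        # so only the reverse frame holds the full-length ORF
        cds = _random_cds(rng, 20) + "TTA" + _random_cds(rng, 19)
        assert extract_cds(str(Seq(cds).reverse_complement())) == cds

    def test_result_in_frame_without_stops(self, rng):
        from pogdiv.codons import encode_codons

        # random transcript with junk: extracted ORF must be a clean frame
        raw = _random_cds(rng, 30) + "TAG" + _random_cds(rng, 12)
        orf = extract_cds(raw, min_orf_codons=5)
        assert len(orf) % 3 == 0
        encode_codons(orf)  # raises on stops/ambiguity


class TestRBH:
    def test_self_pair(self, rng):
        seq = _random_cds(rng, 60)
        a = TranscriptSet("a", [("x1", seq)])
        b = TranscriptSet("b", [("y1", seq)])
        pairs = find_single_copy_pairs(a, b, min_score=10, cds_mode="passthrough")
        assert len(pairs) == 1
        assert (pairs[0].id_a, pairs[0].id_b) == ("x1", "y1")

    def test_unique_maxima_give_three_pairs(self, rng):
        seqs = [_random_cds(rng, 80) for _ in range(3)]
        a = TranscriptSet("a", [(f"a{i}", s) for i, s in enumerate(seqs)])
        b = TranscriptSet("b", [(f"b{i}", s) for i, s in enumerate(seqs)])
        pairs = find_single_copy_pairs(a, b, min_score=10, cds_mode="passthrough")
        assert sorted((p.id_a, p.id_b) for p in pairs) == [
            ("a0", "b0"), ("a1", "b1"), ("a2", "b2"),
        ]

    def test_non_reciprocal_hit_excluded(self, rng):
        y = _random_cds(rng, 80)
        x = y[:120] + _random_cds(rng, 40)  # half-similar to y
        z = y  # identical to y, so y's best hit is z, not x
        a = TranscriptSet("a", [("x", x), ("z", z)])
        b = TranscriptSet("b", [("y", y)])
        pairs = find_single_copy_pairs(a, b, min_score=10, cds_mode="passthrough")
        assert [(p.id_a, p.id_b) for p in pairs] == [("z", "y")]

    def test_symmetry(self, rng):
        seqs = [_random_cds(rng, 70) for _ in range(4)]
        a = TranscriptSet("a", [(f"a{i}", s) for i, s in enumerate(seqs)])
        # b holds mutated copies in shuffled order
        order = [2, 0, 3, 1]
        b_records = []
        for j, i in enumerate(order):
            s = list(seqs[i])
            s[30] = "A" if s[30] != "A" else "C"
            b_records.append((f"b{j}", "".join(s)))
        b = TranscriptSet("b", b_records)
        ab = {(p.id_a, p.id_b) for p in find_single_copy_pairs(a, b, 10, "passthrough")}
        ba = {(p.id_b, p.id_a) for p in find_single_copy_pairs(b, a, 10, "passthrough")}
        assert ab == ba and len(ab) == 4

    def test_min_score_cutoff(self, rng):
        a = TranscriptSet("a", [("x", _random_cds(rng, 50))])
        b = TranscriptSet("b", [("y", _random_cds(rng, 50))])
        assert find_single_copy_pairs(a, b, min_score=1e6, cds_mode="passthrough") == []
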