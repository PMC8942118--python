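"""I/O containers: BED/SAM parsing, fragment inference, chains, sequences."""

from __future__ import annotations

import random

import numpy as np
import pysam
import pytest

from chipq.genomic_io import (FragmentSet, Genome, GenomicInterval, ParseError,
                              RegionSet, extract_sequence, liftover,
                              read_bedgraph, read_chain, read_fragments,
                              read_regions, write_bedgraph)

# ---------------------------------------------------------------------------
# regions / BED


class TestReadRegions:
    def test_bed6_field_mapping(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\ttRNA-X\t0\t+\n")
        rs = read_regions(p)
        iv = rs[0]
        assert (iv.chrom, iv.start, iv.end, iv.name, iv.strand) == \
            ("chr1", 100, 200, "tRNA-X", "+")

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_regions(p)) == 0

    def test_unsorted_input_is_sorted(self, tmp_path):
        rng = random.Random(42)
        rows = [("chr%d" % rng.randint(1, 3), rng.randint(0, 10_000))
                for _ in range(10)]
        p = tmp_path / "u.bed"
        p.write_text("".join(f"{c}\t{s}\t{s + 50}\tr{i}\t0\t+\n"
                             for i, (c, s) in enumerate(rows)))
        rs = read_regions(p)
        expected = sorted(((c, s, f"r{i}") for i, (c, s) in enumerate(rows)))
        assert [(iv.chrom, iv.start, iv.name) for iv in rs] == expected

    def test_missing_name_generated(self, tmp_path):
        p = tmp_path / "n.bed"
        p.write_text("chr1\t10\t20\n")
        assert read_regions(p)[0].name == "chr1:10-20"

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "d.bed"
        p.write_text("chr1\t10\t20\tx\t0\t+\nchr1\t30\t40\tx\t0\t+\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_regions(p)

    @pytest.mark.parametrize("line", ["chr1\t100", "chr1\tabc\t200",
                                      "chr1\t200\t100\tr\t0\t+"])
    def test_malformed_line_names_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\tok\t0\t+\n" + line + "\n")
        with pytest.raises(ParseError, match=":2"):
            read_regions(p)

    def test_bed_round_trip_byte_identical(self, tmp_path):
        text = ("chr1\t100\t200\ta\t0\t+\n"
                "chr1\t300\t400\tb\t0\t-\n"
                "chr2\t50\t120\tc\t0\t+\n")
        p = tmp_path / "rt.bed"
        p.write_text(text)
        out = tmp_path / "rt2.bed"
        read_regions(p).to_bed(out)
        assert out.read_text() == text

    def test_tsv_table_dialect(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("chrom\tstart\tend\tname\tstrand\nchr1\t5\t25\tg1\t-\n")
        rs = read_regions(p, format="tsv")
        assert rs[0].strand == "-" and rs[0].name == "g1"


def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10, "x")
    with pytest.raises(ValueError):
        GenomicInterval("", 0, 10, "x")
    iv = GenomicInterval("chr1", 99, 200, "x", "-")
    assert iv.five_prime == 200 and iv.centre == 149
    assert iv.display() == "chr1:100-200(-)"


# ---------------------------------------------------------------------------
# fragments


def _write_sam(path, records, chrom_lengths):
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": c, "LN": l} for c, l in chrom_lengths.items()]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            out.write(rec)


def _aln(header, name, chrom, pos, length=36, flag=0, tlen=0, pnext=0):
    a = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
    a.query_name = name
    a.flag = flag
    if not (flag & 0x4):
        a.reference_id = 0
        a.reference_start = pos
        a.cigarstring = f"{length}M"
        a.mapping_quality = 60
    a.query_sequence = "A" * length
    a.template_length = tlen
    a.next_reference_start = pnext
    return a


class TestReadFragments:
    HEADER = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100_000}]}

    def test_proper_pair_collapsed_to_template_span(self, tmp_path):
        # mates at [100,150) + and [220,270) - : one fragment [100,270)
        recs = [
            _aln(self.HEADER, "t1", "chr1", 100, 50, flag=99, tlen=170, pnext=220),
            _aln(self.HEADER, "t1", "chr1", 220, 50, flag=147, tlen=-170, pnext=100),
        ]
        p = tmp_path / "p.sam"
        _write_sam(p, recs, {"chr1": 100_000})
        fs = read_fragments(p)
        assert list(fs) == [("chr1", 100, 270)]
        assert fs.total_fragments == 1

    def test_single_end_extension_3prime(self, tmp_path):
        recs = [_aln(self.HEADER, "f", "chr1", 100, 36, flag=0),
                _aln(self.HEADER, "r", "chr1", 500, 36, flag=16)]
        p = tmp_path / "s.sam"
        _write_sam(p, recs, {"chr1": 100_000})
        fs = read_fragments(p, single_end_extension=200)
        assert ("chr1", 100, 300) in list(fs)      # + strand extends right
        assert ("chr1", 336, 536) in list(fs)      # - strand extends left

    def test_mixed_sam_matches_hand_template_count(self, tmp_path):
        # 50 records: 15 proper pairs (30 recs), 14 single-end, 2 unmapped,
        # 4 orphan-paired -> 15 + 14 + 4 = 33 templates
        rng = random.Random(7)
        recs = []
        for i in range(15):
            s = rng.randint(0, 50_000)
            tl = rng.randint(100, 400)
            recs.append(_aln(self.HEADER, f"p{i}", "chr1", s, 36, flag=99,
                             tlen=tl, pnext=s + tl - 36))
            recs.append(_aln(self.HEADER, f"p{i}", "chr1", s + tl - 36, 36,
                             flag=147, tlen=-tl, pnext=s))
        for i in range(14):
            recs.append(_aln(self.HEADER, f"s{i}", "chr1",
                             rng.randint(0, 50_000), 36,
                             flag=16 if i % 2 else 0))
        for i in range(2):
            recs.append(_aln(self.HEADER, f"u{i}", "chr1", 0, 36, flag=0x4))
        for i in range(4):
            recs.append(_aln(self.HEADER, f"o{i}", "chr1",
                             rng.randint(0, 50_000), 36, flag=0x1 | 0x8))
        assert len(recs) == 50
        p = tmp_path / "m.sam"
        _write_sam(p, recs, {"chr1": 100_000})
        fs = read_fragments(p)
        assert fs.total_fragments == 33

    def test_total_invariant_under_record_order(self, tmp_path, tiny_mcf7):
        frags, _ = tiny_mcf7
        sub = list(frags)[:200]
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        p1.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in sub))
        shuffled = sub[:]
        random.Random(3).shuffle(shuffled)
        p2.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in shuffled))
        a, b = read_fragments(p1), read_fragments(p2)
        assert a.total_fragments == b.total_fragments == 200
        for chrom in a.chroms:
            assert np.array_equal(a.fragments(chrom)[0], b.fragments(chrom)[0])

    def test_sam_round_trip(self, tmp_path, tiny_mcf7):
        frags, _ = tiny_mcf7
        sub = FragmentSet(list(frags)[:100], total_fragments=500)
        p = tmp_path / "rt.sam"
        sub.to_sam(p, {"chr1": 600_000, "chr2": 600_000})
        back = read_fragments(p)
        assert list(back) == list(sub)
        assert back.total_fragments == 500  # carried via @CO comment

    def test_bed_round_trip_with_library_size(self, tmp_path):
        fs = FragmentSet([("chr1", 5, 105), ("chr1", 50, 250)],
                         total_fragments=1000)
        p = tmp_path / "f.bed"
        fs.to_bed(p)
        back = read_fragments(p)
        assert back.total_fragments == 1000
        assert list(back) == [("chr1", 5, 105), ("chr1", 50, 250)]

    def test_invalid_fragment_rejected(self):
        with pytest.raises(ValueError):
            FragmentSet([("chr1", 10, 10)])
        with pytest.raises(ValueError):
            FragmentSet([("chr1", 10, 20)], total_fragments=0)


# ---------------------------------------------------------------------------
# sequences


class TestExtractSequence:
    GENOME = Genome({"c": "AACGTACG"})

    def test_direct_slice(self):
        iv = GenomicInterval("c", 3, 7, "x")
        assert extract_sequence(self.GENOME, iv, 0) == "GTAC"

    def test_flank_clipped_to_chromosome(self):
        iv = GenomicInterval("c", 3, 7, "x")
        assert extract_sequence(self.GENOME, iv, 100) == "AACGTACG"

    def test_flank_arithmetic(self):
        iv = GenomicInterval("c", 2, 5, "x")
        seq = extract_sequence(self.GENOME, iv, 2)
        up = min(2, 2)     # clipped upstream flank
        down = min(2, 8 - 5)
        assert len(seq) == (5 - 2) + up + down
        assert seq == "AACGTAC"

    def test_unknown_chromosome(self):
        with pytest.raises(KeyError):
            extract_sequence(self.GENOME, GenomicInterval("zz", 0, 5, "x"), 0)

    def test_fasta_round_trip(self, tmp_path):
        p = tmp_path / "g.fa"
        self.GENOME.to_fasta(p)
        g2 = Genome.from_fasta(p)
        assert g2.sequence("c") == "AACGTACG"


# ---------------------------------------------------------------------------
# chains / liftover


def _chain_text(header, blocks):
    lines = [header]
    lines += ["\t".join(str(x) for x in b) for b in blocks]
    return "\n".join(lines) + "\n\n"


@pytest.fixture
def regions_chr1():
    return RegionSet([GenomicInterval("chr1", 100, 300, "a", "+"),
                      GenomicInterval("chr1", 650, 800, "b", "+"),
                      GenomicInterval("chr1", 400, 700, "straddle", "+")],
                     assembly="asmA")


class TestLiftover:
    def test_identity_chain(self, tmp_path, regions_chr1):
        p = tmp_path / "id.chain"
        p.write_text(_chain_text(
            "chain 100 chr1 10000 + 0 10000 chr1 10000 + 0 10000 1", [(10000,)]))
        res = liftover(regions_chr1, read_chain(p, "asmA", "asmB"))
        assert res.remap_rate == 1.0
        for iv in res.mapped:
            orig = regions_chr1[iv.name]
            assert (iv.start, iv.end) == (orig.start, orig.end)

    def test_offset_chain_shifts_coordinates(self, tmp_path, regions_chr1):
        # target has 100 bp inserted upstream of everything
        p = tmp_path / "off.chain"
        p.write_text(_chain_text(
            "chain 100 chr1 10000 + 0 10000 chr1 10100 + 100 10100 1",
            [(10000,)]))
        res = liftover(regions_chr1, read_chain(p, "asmA", "asmB"))
        for iv in res.mapped:
            orig = regions_chr1[iv.name]
            assert (iv.start, iv.end) == (orig.start + 100, orig.end + 100)

    def test_source_gap_straddler_unmapped(self, tmp_path, regions_chr1):
        # source blocks [0,500) and [600,1100) -> a region crossing the gap
        # fails; a region inside the second block maps with offset -100
        p = tmp_path / "gap.chain"
        p.write_text(_chain_text(
            "chain 100 chr1 10000 + 0 1100 chr1 10000 + 0 1000 1",
            [(500, 100, 0), (500,)]))
        res = liftover(regions_chr1, read_chain(p, "asmA", "asmB"))
        assert "straddle" in res.unmapped
        mapped = {iv.name: iv for iv in res.mapped}
        assert (mapped["a"].start, mapped["a"].end) == (100, 300)
        assert (mapped["b"].start, mapped["b"].end) == (550, 700)
        assert res.remap_rate == pytest.approx(2 / 3)

    def test_target_gap_breaks_contiguity(self, tmp_path):
        # source contiguous but the target image is split: unmapped
        p = tmp_path / "tg.chain"
        p.write_text(_chain_text(
            "chain 100 chr1 10000 + 0 1000 chr1 10000 + 0 1100 1",
            [(500, 0, 100), (500,)]))
        rs = RegionSet([GenomicInterval("chr1", 400, 600, "cross", "+")], "asmA")
        res = liftover(rs, read_chain(p, "asmA", "asmB"))
        assert res.unmapped == ["cross"]

    def test_inverse_chain_round_trip(self, tmp_path, regions_chr1):
        fwd = tmp_path / "f.chain"
        fwd.write_text(_chain_text(
            "chain 100 chr1 10000 + 0 1100 chr1 10000 + 50 1050 1",
            [(500, 100, 0), (500,)]))
        inv = tmp_path / "i.chain"
        inv.write_text(_chain_text(
            "chain 100 chr1 10000 + 50 1050 chr1 10000 + 0 1100 1",
            [(500, 0, 100), (500,)]))
        first = liftover(regions_chr1, read_chain(fwd, "asmA", "asmB"))
        back = liftover(first.mapped, read_chain(inv, "asmB", "asmA"))
        assert back.remap_rate == 1.0
        for iv in back.mapped:
            orig = regions_chr1[iv.name]
            assert (iv.start, iv.end) == (orig.start, orig.end)

    def test_minus_strand_chain(self, tmp_path):
        # one 1000 bp block aligned to the reverse strand of a 1000 bp target
        p = tmp_path / "m.chain"
        p.write_text(_chain_text(
            "chain 100 chr1 1000 + 0 1000 chrT 1000 - 0 1000 1", [(1000,)]))
        rs = RegionSet([GenomicInterval("chr1", 100, 300, "x", "+")], "asmA")
        res = liftover(rs, read_chain(p, "asmA", "asmB"))
        iv = res.mapped["x"]
        assert (iv.start, iv.end, iv.strand) == (700, 900, "-")

    def test_assembly_mismatch_raises(self, tmp_path, regions_chr1):
        p = tmp_path / "id.chain"
        p.write_text(_chain_text(
            "chain 100 chr1 10000 + 0 10000 chr1 10000 + 0 10000 1", [(10000,)]))
        with pytest.raises(ValueError, match="does not match"):
            liftover(regions_chr1, read_chain(p, "asmZ", "asmB"))


# ---------------------------------------------------------------------------
# bedGraph


def test_bedgraph_round_trip(tmp_path):
    vals = np.array([0, 0, 1.5, 1.5, 2.0, 0, 3.0, 3.0, 3.0, 0], dtype=float)
    p = tmp_path / "t.bedgraph"
    write_bedgraph(p, "chr1", 1000, vals)
    back = read_bedgraph(p, "chr1", 1000, len(vals))
    assert np.array_equal(back, vals)
    # runs of equal values are merged
    assert sum(1 for _ in open(p)) == 3
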