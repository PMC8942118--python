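"""PWM construction, scanning, exact p-values and neighborhood reports."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chipq.genomic_io import Genome, GenomicInterval, RegionSet
from chipq.motifs import (CONSENSUS, DEFAULT_MIN_P, PWM, builtin_motifs,
                          consensus_to_pwm, pwm_pvalue, read_meme_motifs,
                          reverse_complement, scan, scan_neighborhood)


def brute_scan(sequence: str, pwm: PWM, min_p: float):
    """Reference all-offset scorer: score every window on both strands with
    per-position grid lookups and filter by pwm.pvalue."""
    g, cols5 = pwm._grid()
    code = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    hits = []
    L, w = len(sequence), pwm.width
    for strand in ("+", "-"):
        seq = sequence if strand == "+" else reverse_complement(sequence)
        for off in range(L - w + 1):
            s = sum(cols5[k, code[seq[off + k]]] for k in range(w)) * g
            p = pwm.pvalue(s)
            if p <= min_p:
                fwd = off if strand == "+" else L - off - w
                hits.append((fwd, strand, round(s, 9), p))
    return sorted(hits)


class TestConsensusToPwm:
    def test_single_a_column_arithmetic(self):
        pwm = consensus_to_pwm("A", pseudocount=0.25)
        assert np.allclose(pwm.probs[0], [0.625, 0.125, 0.125, 0.125])
        assert pwm.log_odds[0, 0] == pytest.approx(np.log2(0.625 / 0.25))
        assert pwm.log_odds[0, 0] == pytest.approx(1.3219, abs=1e-4)

    def test_n_column_equals_background(self):
        pwm = consensus_to_pwm("N")
        assert np.allclose(pwm.probs[0], 0.25)
        assert np.allclose(pwm.log_odds[0], 0.0)

    def test_ere_consensus_structure(self):
        pwm = consensus_to_pwm(CONSENSUS["ERE"])
        assert pwm.width == 13
        for col in (5, 6, 7):  # the 3 bp spacer
            assert np.allclose(pwm.probs[col], 0.25)

    def test_degenerate_iupac_shares(self):
        pwm = consensus_to_pwm("R", pseudocount=0.25)
        assert np.allclose(pwm.probs[0], [0.375, 0.125, 0.375, 0.125])

    def test_invalid_character(self):
        with pytest.raises(ValueError, match="IUPAC"):
            consensus_to_pwm("GGXCA")

    def test_column_sum_invariant(self):
        for pwm in builtin_motifs().values():
            assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)


class TestPvalue:
    @pytest.mark.parametrize("consensus", ["GGTC", "GGTCA", "GGTCAN"])
    def test_matches_exhaustive_enumeration(self, consensus):
        pwm = consensus_to_pwm(consensus)
        g, cols5 = pwm._grid()
        w = pwm.width
        ints = np.array([sum(cols5[k, b] for k, b in enumerate(word))
                         for word in itertools.product(range(4), repeat=w)])
        for q in np.linspace(pwm.min_score, pwm.max_score, 13):
            # quantize the query onto the same grid, clamped to the
            # achievable maximum (the p-value's defined semantics)
            qi = min(int(np.rint(q / g)), int(ints.max()))
            enum_p = float(np.mean(ints >= qi))
            assert pwm.pvalue(q) == pytest.approx(enum_p, abs=1e-12)

    def test_bounds(self):
        pwm = consensus_to_pwm("GGTCA")
        assert pwm.pvalue(pwm.max_score + 1.0) == 0.0
        assert pwm.pvalue(pwm.min_score - 1.0) == 1.0
        assert pwm.pvalue(pwm.max_score) == pytest.approx(4 ** -5)

    def test_monotone_non_increasing(self):
        pwm = builtin_motifs()["A-box"]
        grid = np.linspace(pwm.min_score - 1, pwm.max_score + 1, 200)
        ps = [pwm.pvalue(s) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_exact_match_probabilities_of_bundled_motifs(self):
        m = builtin_motifs()
        # products of per-column max-base counts over 4^width
        assert m["ERE"].pvalue(m["ERE"].max_score) == \
            pytest.approx(4 ** 3 / 4 ** 13)
        assert m["A-box"].pvalue(m["A-box"].max_score) == \
            pytest.approx(2 * 2 * 2 * 4 ** 4 / 4 ** 12)
        assert m["B-box"].pvalue(m["B-box"].max_score) == \
            pytest.approx(4 ** 2 / 4 ** 9)
        assert m["half-ERE"].pvalue(m["half-ERE"].max_score) == \
            pytest.approx(4 ** -5)


class TestScan:
    def test_planted_ere_found_on_plus(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        seq = seq[:400] + "GGTCAAAATGACC" + seq[413:]
        hits = scan(seq, builtin_motifs()["ERE"], "both", 1e-4)
        assert any(h.offset == 400 and h.strand == "+" for h in hits)

    def test_planted_revcomp_found_on_minus(self):
        # B-box is not palindromic, so the reverse complement is a clean
        # minus-strand test; forward-coordinate offset is preserved
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        word = "GTTCGAATC"  # a max-scoring B-box instantiation
        planted = reverse_complement(word)
        seq = seq[:300] + planted + seq[300 + len(planted):]
        hits = scan(seq, builtin_motifs()["B-box"], "both", 1e-4)
        minus = [h for h in hits if h.strand == "-"]
        assert any(h.offset == 300 for h in minus)
        # oracle: scanning the reverse-complemented sequence on + finds it
        rc_hits = scan(reverse_complement(seq), builtin_motifs()["B-box"],
                       "+", 1e-4)
        assert any(len(seq) - h.offset - 9 == 300 for h in rc_hits)

    @pytest.mark.parametrize("motif", ["ERE", "B-box"])
    def test_matches_brute_force_on_random_sequences(self, motif):
        pwm = builtin_motifs()[motif]
        rng = np.random.default_rng(17)
        for _ in range(10):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
            got = sorted((h.offset, h.strand, round(h.score, 9), h.p_value)
                         for h in scan(seq, pwm, "both", 0.01))
            assert got == brute_scan(seq, pwm, 0.01)

    def test_short_sequence_empty(self):
        assert scan("GGT", builtin_motifs()["ERE"]) == []

    def test_n_in_sequence_scores_background(self):
        pwm = consensus_to_pwm("GGTCA")
        hits_n = scan("N" * 20, pwm, "+", min_p=1.1)  # keep everything
        # every window is all-N: score == sum of background expectations
        g, cols5 = pwm._grid()
        expected = float(cols5[:, 4].sum() * g)
        assert all(h.score == pytest.approx(expected) for h in hits_n)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=13, max_size=80))
    def test_strand_symmetry_property(self, seq):
        pwm = builtin_motifs()["B-box"]
        minus = scan(seq, pwm, "-", min_p=0.05)
        plus_of_rc = scan(reverse_complement(seq), pwm, "+", min_p=0.05)
        got = sorted((h.offset, round(h.score, 9)) for h in minus)
        expected = sorted((len(seq) - h.offset - pwm.width, round(h.score, 9))
                          for h in plus_of_rc)
        assert got == expected

    def test_palindromic_ere_strands_agree(self):
        rng = np.random.default_rng(23)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        pwm = builtin_motifs()["ERE"]
        plus = {(h.offset, round(h.score, 9))
                for h in scan(seq, pwm, "+", min_p=0.05)}
        minus = {(h.offset, round(h.score, 9))
                 for h in scan(seq, pwm, "-", min_p=0.05)}
        assert plus == minus


class TestScanNeighborhood:
    def test_planted_boxes_found_ere_absent(self, tiny_sim):
        cfg, genome, annotations, truth = tiny_sim
        report = scan_neighborhood(genome, annotations["tdna"], flank=5000)
        assert report.fraction_found("A-box") == 1.0
        assert report.fraction_found("B-box") == 1.0
        assert report.fraction_found("ERE") == 0.0
        assert report.fraction_found("half-ERE") == 0.0
        # hits at the exact planted genomic positions
        planted = {(p["region"], p["motif"]): p for p in truth.planted_motifs
                   if p["motif"] in ("A-box", "B-box")}
        hits = report.hits.set_index(["region", "motif"])
        for (region, motif), p in planted.items():
            sub = report.hits[(report.hits.region == region)
                              & (report.hits.motif == motif)]
            assert p["genomic_start"] in set(sub.genomic_start)

    def test_control_locus_reports_ere_at_minus_585(self, tiny_sim):
        cfg, genome, annotations, truth = tiny_sim
        report = scan_neighborhood(genome, annotations["control"], flank=5000)
        assert report.found("GREB1-like", "ERE")
        ere_hits = report.hits[(report.hits.region == "GREB1-like")
                               & (report.hits.motif == "ERE")]
        assert -585 in set(ere_hits.offset_from_start)
        assert not report.found("BC200-like", "ERE")

    def test_gff_output(self, tiny_sim, tmp_path):
        cfg, genome, annotations, truth = tiny_sim
        report = scan_neighborhood(genome, annotations["control"], flank=2000)
        p = tmp_path / "hits.tsv"
        report.to_gff_tsv(p)
        import pandas as pd

        df = pd.read_csv(p, sep="\t")
        assert {"seqid", "motif", "start", "end", "strand",
                "p_value"} <= set(df.columns)
        assert (df["start"] >= 1).all()


def test_meme_minimal_round_trip(tmp_path):
    text = """MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF toy
letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0
0.970 0.010 0.010 0.010
0.010 0.970 0.010 0.010
0.010 0.010 0.010 0.970
"""
    p = tmp_path / "m.meme"
    p.write_text(text)
    motifs = read_meme_motifs(p)
    assert "toy" in motifs
    pwm = motifs["toy"]
    assert pwm.width == 3
    hits = scan("GGACTGG", pwm, "+", min_p=1.1)
    best = max(hits, key=lambda h: h.score)
    assert best.offset == 2  # ACT
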