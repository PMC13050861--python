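"""SSR scanner, motif canonicalization, summaries and primer screening."""

import itertools

import numpy as np
import pytest

from _oracles import brute_force_ssrs, insilico_pcr_hits, repeat_rich_sequence
from popkit import ssr
from popkit.ssr import (
    DEFAULT_THRESHOLDS,
    PrimerPair,
    canonical_motif,
    filter_primer_pairs,
    insilico_pcr_unique,
    primer_violations,
    reverse_complement,
    scan_sequence,
    scan_ssrs,
    summarize_motifs,
)


class TestScanner:
    def test_mono_threshold_boundary(self):
        loci = scan_sequence("s", "CC" + "A" * 10 + "GG")
        assert len(loci) == 1
        (l,) = loci
        assert (l.start, l.end, l.motif, l.n_repeats) == (2, 12, "A", 10)

    def test_below_threshold_tri(self):
        seq = "CGCGCG" + "ATG" * 4 + "CGCGCG"
        assert scan_sequence("s", seq) == []

    def test_run_reported_at_smallest_period(self):
        loci = scan_sequence("s", "GG" + "AT" * 6 + "GG")
        assert len(loci) == 1
        assert loci[0].unit_len == 2 and loci[0].n_repeats == 6

    def test_non_acgt_breaks_runs(self):
        assert scan_sequence("s", "A" * 6 + "N" + "A" * 6) == []
        loci = scan_sequence("s", "A" * 10 + "N" + "A" * 10)
        assert len(loci) == 2

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = repeat_rich_sequence(rng, 50_000)
        loci = scan_sequence("s", seq)
        got = {(l.start, l.end, l.unit_len, l.motif) for l in loci}
        expected = brute_force_ssrs(seq, DEFAULT_THRESHOLDS)
        assert got == expected
        assert len(got) > 20

    def test_strand_symmetry_of_canonical_classes(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ATATCG"), size=20_000))
        fwd = sorted(l.canonical for l in scan_sequence("s", seq))
        rev = sorted(l.canonical for l in scan_sequence("s", reverse_complement(seq)))
        assert fwd == rev

    def test_no_overlapping_same_class_loci(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("AT"), size=20_000))
        loci = scan_sequence("s", seq)
        by_key: dict = {}
        for l in loci:
            by_key.setdefault((l.canonical, l.unit_len), []).append((l.start, l.end))
        for spans in by_key.values():
            spans.sort()
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                assert s2 >= e1

    def test_table_round_trip(self):
        loci = scan_sequence("tr1", "CC" + "A" * 12 + "GG" + "AT" * 7)
        df = ssr.loci_to_table(loci)
        assert ssr.table_to_loci(df) == loci


class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "motif,expected",
        [("TA", "AT"), ("ATT", "AAT"), ("A", "A"), ("T", "A"), ("GT", "AC")],
    )
    def test_examples(self, motif, expected):
        assert canonical_motif(motif) == expected

    def test_trinucleotide_partition(self):
        prims = [
            "".join(m)
            for m in itertools.product("ACGT", repeat=3)
            if ssr._is_primitive("".join(m))
        ]
        assert len(prims) == 60  # 64 minus AAA/CCC/GGG/TTT
        classes = {canonical_motif(m) for m in prims}
        assert len(classes) == 10
        non_prim_classes = {canonical_motif(b * 1) for b in "ACGT"}
        assert non_prim_classes == {"A", "C"}

    def test_rotation_and_strand_invariance(self):
        for motif in ("ACG", "AATG", "CGTAG"):
            base = canonical_motif(motif)
            for i in range(len(motif)):
                rot = motif[i:] + motif[:i]
                assert canonical_motif(rot) == base
                assert canonical_motif(reverse_complement(rot)) == base

    def test_rejects_bad_characters(self):
        with pytest.raises(ValueError):
            canonical_motif("ANT")


class TestSummary:
    def test_single_locus_is_hundred_percent(self):
        loci = scan_sequence("s", "A" * 10)
        summary = summarize_motifs(loci)
        assert summary.total == 1
        assert summary.by_unit.loc[1, "percent"] == 100.00
        assert summary.by_class.loc[(1, "A"), "percent_within_unit"] == 100.00

    def test_percentages_recompute_from_counts(self):
        df = ssr.repeat_type_percentages({1: 26631, 2: 22842, 3: 12210, 4: 5103, 5: 709, 6: 753})
        assert df.attrs["total"] == 68248
        assert df["percent"].tolist() == [39.02, 33.47, 17.89, 7.48, 1.04, 1.10]

    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ATATCG"), size=30_000))
        summary = summarize_motifs(scan_sequence("s", seq))
        assert summary.by_unit["count"].sum() == summary.total
        for u in summary.by_unit.index:
            sub = summary.by_class.loc[u]
            assert sub["count"].sum() == summary.by_unit.loc[u, "count"]


def _random_primer(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


class TestPrimerFilter:
    def test_length_violation(self):
        p = PrimerPair(_random_primer(np.random.default_rng(0), 17),
                       _random_primer(np.random.default_rng(1), 20), 150)
        assert "length" in primer_violations(p)

    def test_tm_difference_violation(self):
        p = PrimerPair("A" * 20, "C" * 20, 150, tm_f=60.0, tm_r=63.0,
                       gc_f=50.0, gc_r=50.0)
        assert "dTm > 2" in primer_violations(p)

    def test_matches_independent_recheck(self):
        """Dual-implementation check of all five constraints on 100 candidates."""
        from Bio.Seq import Seq
        from Bio.SeqUtils import MeltingTemp, gc_fraction

        rng = np.random.default_rng(11)
        candidates = [
            PrimerPair(
                _random_primer(rng, int(rng.integers(15, 31))),
                _random_primer(rng, int(rng.integers(15, 31))),
                int(rng.integers(50, 400)),
            )
            for _ in range(100)
        ]
        accepted, rejected = filter_primer_pairs(candidates)

        def ok(pair):
            for s in (pair.forward_seq, pair.reverse_seq):
                if not 18 <= len(s) <= 27:
                    return False
                gc = gc_fraction(s) * 100
                if not 40 <= gc <= 80:
                    return False
                tm = MeltingTemp.Tm_NN(Seq(s), Na=50, dnac1=250, dnac2=0)
                if not 58 <= tm <= 65:
                    return False
            tm_f = MeltingTemp.Tm_NN(Seq(pair.forward_seq), Na=50, dnac1=250, dnac2=0)
            tm_r = MeltingTemp.Tm_NN(Seq(pair.reverse_seq), Na=50, dnac1=250, dnac2=0)
            if abs(tm_f - tm_r) > 2:
                return False
            return 100 <= pair.product_size <= 300

        assert set(map(id, accepted)) == {id(p) for p in candidates if ok(p)}
        assert len(accepted) + len(rejected) == 100


class TestInsilicoPCR:
    def _toy(self, rng):
        return [
            ("t1", _random_primer(rng, 500)),
            ("t2", _random_primer(rng, 500)),
            ("t3", _random_primer(rng, 500)),
        ]

    def test_unique_region(self):
        rng = np.random.default_rng(0)
        seqs = self._toy(rng)
        fwd, rev_rc = "ACGTACGTACGTACGTACGT", "TTGGCCAATTGGCCAATTGG"
        insert = fwd + _random_primer(rng, 110) + rev_rc
        seqs[0] = ("t1", seqs[0][1][:100] + insert + seqs[0][1][100:])
        pair = PrimerPair(fwd, reverse_complement(rev_rc), 150)
        assert insilico_pcr_unique(pair, seqs)

    def test_duplicated_region_fails(self):
        rng = np.random.default_rng(0)
        seqs = self._toy(rng)
        fwd, rev_rc = "ACGTACGTACGTACGTACGT", "TTGGCCAATTGGCCAATTGG"
        insert = fwd + _random_primer(rng, 110) + rev_rc
        seqs[0] = ("t1", seqs[0][1][:100] + insert + seqs[0][1][100:])
        seqs[1] = ("t2", seqs[1][1][:50] + insert + seqs[1][1][50:])
        pair = PrimerPair(fwd, reverse_complement(rev_rc), 150)
        assert not insilico_pcr_unique(pair, seqs)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(9)
        seqs = [("t", "".join(rng.choice(list("AC"), size=2000)))]
        for trial in range(50):
            i = int(rng.integers(0, 1800))
            fwd = seqs[0][1][i : i + 18]
            j = int(rng.integers(i + 50, min(i + 350, 1982)))
            rev_rc = seqs[0][1][j : j + 18]
            pair = PrimerPair(fwd, reverse_complement(rev_rc), j + 18 - i)
            assert insilico_pcr_unique(pair, seqs) == (
                insilico_pcr_hits(fwd, rev_rc, seqs) == 1
            )


def test_read_fasta_round_trip(tmp_path):
    fa = tmp_path / "toy.fa"
    fa.write_text(">tr1 desc\nACGTACGT\nACGT\n>tr2\nTTTT\n")
    recs = ssr.read_fasta(fa)
    assert recs == [("tr1", "ACGTACGTACGT"), ("tr2", "TTTT")]
    loci = scan_ssrs(recs)
    assert loci == []
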