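import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ezgkit.motifs import (
    IUPAC_CODES,
    BackgroundModel,
    IupacMotif,
    MotifError,
    MotifHit,
    SequenceSetIndex,
    candidate_space_size,
    discover,
    evaluate_query,
    expansion_jaccard,
    iupac_expand,
    iupac_revcomp,
    motif_stats,
    read_fasta,
    scan,
    stats_to_frame,
    write_bed,
    write_fasta,
)
from ezgkit.simulate import SimulationConfig, simulate_upstream

PATTERNS = st.text(alphabet=sorted(IUPAC_CODES), min_size=1, max_size=8)


def regex_scan_oracle(pattern, sequences):
    """Independent oracle: overlapping regex search of both strands."""

    def rx(pat):
        return re.compile(
            "(?=(" + "".join(f"[{IUPAC_CODES[c]}]" for c in pat) + "))"
        )

    hits = set()
    rc = iupac_revcomp(pattern).pattern
    for name, seq in sequences.items():
        for m in rx(pattern).finditer(seq):
            hits.add((name, m.start(), "+"))
        for m in rx(rc).finditer(seq):
            hits.add((name, m.start(), "-"))
    return hits


class TestIupacAlgebra:
    def test_expand_vbrggta_is_18_words(self):
        words = iupac_expand("VBRGGTA")
        assert len(words) == 18  # 3*3*2*1*1*1*1
        assert "CTAGGTA" in words and "AGGGGTA" in words

    def test_expand_concrete_and_n(self):
        assert iupac_expand("ACGT") == {"ACGT"}
        assert iupac_expand("N") == {"A", "C", "G", "T"}

    def test_expansion_size_matches_product(self):
        assert IupacMotif("VBRGGTA").expansion_size == 18
        assert IupacMotif("NN").expansion_size == 16

    def test_revcomp_of_vbrggta(self):
        assert iupac_revcomp("VBRGGTA").pattern == "TACCYVB"

    def test_revcomp_palindrome(self):
        assert iupac_revcomp("ACGT").pattern == "ACGT"

    @given(PATTERNS)
    def test_revcomp_involution(self, pattern):
        assert iupac_revcomp(iupac_revcomp(pattern)).pattern == pattern.upper()

    @given(PATTERNS)
    def test_revcomp_preserves_expansion_size(self, pattern):
        assert (
            IupacMotif(pattern).expansion_size
            == iupac_revcomp(pattern).expansion_size
        )

    def test_invalid_code_rejected(self):
        with pytest.raises(MotifError):
            IupacMotif("ACGX")
        with pytest.raises(MotifError):
            IupacMotif("")

    def test_jaccard(self):
        assert expansion_jaccard("VBRGGTA", "VBRGGTA") == 1.0
        # VYRGGTA expands to 12 words, all inside VBRGGTA's 18
        assert expansion_jaccard("VYRGGTA", "VBRGGTA") == pytest.approx(12 / 18)


class TestScan:
    def test_definition_hit(self):
        hits = scan("VBRGGTA", {"s": "CTAGGTA"})
        assert (
            MotifHit("s", 0, "+") in hits
        )  # C in V, T in B, A in R, GGTA literal

    def test_definition_miss(self):
        plus = [h for h in scan("VBRGGTA", {"s": "CAGGTAG"}) if h.strand == "+"]
        assert plus == []  # position 2 'G'... pattern needs R G G T A tail

    def test_minus_strand_anchoring(self):
        # TACCTAG revcomp contains CTAGGTA at plus-strand start 0
        hits = scan("VBRGGTA", {"s": "TACCTAG"})
        assert hits == [MotifHit("s", 0, "-")]

    def test_motif_longer_than_sequence_no_hits(self):
        assert scan("VBRGGTA", {"s": "ACG"}) == []

    def test_sequence_n_matches_only_motif_n(self):
        assert scan("ANT", {"s": "ANT"})[0].strand == "+"
        assert [h for h in scan("AAT", {"s": "ANT"}) if h.strand == "+"] == []

    def test_palindromic_position_counts_twice(self):
        hits = scan("ACGT", {"s": "ACGT"})
        assert {h.strand for h in hits} == {"+", "-"}
        assert len(hits) == 2

    def test_regex_oracle_random_sequences(self):
        rng = np.random.default_rng(3)
        for pattern in ["VBRGGTA", "RY", "TANGT", "SWSW"]:
            seqs = {
                f"s{i}": "".join(rng.choice(list("ACGT"), size=250))
                for i in range(8)
            }
            got = {(h.sequence_id, h.start, h.strand) for h in scan(pattern, seqs)}
            assert got == regex_scan_oracle(pattern, seqs)

    def test_strand_flip_property(self):
        rng = np.random.default_rng(4)
        seqs = {"s": "".join(rng.choice(list("ACGT"), size=500))}
        fwd = {(h.start, h.strand) for h in scan("VBRGGTA", seqs)}
        rev = {
            (h.start, "+" if h.strand == "-" else "-")
            for h in scan(iupac_revcomp("VBRGGTA"), seqs)
        }
        assert fwd == rev


class TestBackground:
    def test_from_sequences(self):
        bg = BackgroundModel.from_sequences({"a": "AACG", "b": "TTTT"})
        assert bg.frequencies == pytest.approx([0.25, 0.125, 0.125, 0.5])

    def test_motif_prob_equals_expansion_enumeration(self):
        rng = np.random.default_rng(8)
        f = rng.dirichlet(np.ones(4))
        bg = BackgroundModel(f)
        for pattern in ["VBR", "NWS", "ACGT", "YRY"]:
            by_expansion = sum(
                np.prod([bg.frequencies["ACGT".index(b)] for b in word])
                for word in iupac_expand(pattern)
            )
            assert bg.motif_prob(pattern) == pytest.approx(by_expansion)

    def test_frequency_floor(self):
        bg = BackgroundModel([1.0, 0.0, 0.0, 0.0])
        assert (bg.frequencies > 0).all()
        assert bg.frequencies.sum() == pytest.approx(1.0)


class TestMotifStats:
    def test_absent_motif_nonpositive_sig(self):
        seqs = {"a": "AAAAAAAAAA", "b": "AAAAAAAAAA"}
        s = motif_stats("CCCC", seqs, n_candidates_tested=100)
        assert s.count == 0
        assert s.sig_value <= 0  # E = n_candidates >= 1

    def test_coverage_half(self):
        seqs = {
            "a": "AACAGGTAGAA",
            "b": "TTTTTTTTTTT",
            "c": "AACAGGTAGAA",
            "d": "TTTTTTTTTTT",
        }
        s = motif_stats("CAGGTAG", seqs)
        assert s.coverage == pytest.approx(0.5)

    def test_count_at_least_covered(self):
        cfg = SimulationConfig(seed=3, gc_content=0.3)
        seqs, _ = simulate_upstream(cfg, 30)
        s = motif_stats("VBRGGTA", seqs)
        assert s.count >= s.n_covered

    def test_sig_monotone_in_count(self):
        from ezgkit.motifs import _sig_values

        sigs = _sig_values(np.array([1, 5, 10, 20]), 200, np.array([0.01] * 4), 2.0)
        assert (np.diff(sigs) > 0).all()

    def test_planted_motif_large_positive_sig(self):
        cfg = SimulationConfig(seed=5, gc_content=0.22, motif_coverage=0.635)
        seqs, _ = simulate_upstream(cfg, 61)
        s = motif_stats(
            "VBRGGTA", seqs, n_candidates_tested=candidate_space_size(7, 4)
        )
        assert s.sig_value > 2


class TestDiscover:
    def test_determinism(self):
        cfg = SimulationConfig(seed=13, gc_content=0.25)
        seqs, _ = simulate_upstream(cfg, 20)
        a = discover(seqs, length_range=(5, 7), beam_width=10)
        b = discover(seqs, length_range=(5, 7), beam_width=10)
        assert [(s.motif.pattern, s.sig_value, s.count) for s in a] == [
            (s.motif.pattern, s.sig_value, s.count) for s in b
        ]

    def test_rejects_empty_or_single(self):
        with pytest.raises(MotifError):
            discover({})
        with pytest.raises(MotifError):
            discover({"only": "ACGTACGT"})

    def test_planted_recovery_small(self):
        cfg = SimulationConfig(seed=2, gc_content=0.22, motif_coverage=0.8)
        seqs, _ = simulate_upstream(cfg, 40)
        ranked = discover(seqs, length_range=(6, 8), beam_width=30)
        best = max(
            ranked[:5],
            key=lambda s: max(
                expansion_jaccard(s.motif, "VBRGGTA"),
                expansion_jaccard(iupac_revcomp(s.motif), "VBRGGTA"),
            ),
        )
        assert (
            max(
                expansion_jaccard(best.motif, "VBRGGTA"),
                expansion_jaccard(iupac_revcomp(best.motif), "VBRGGTA"),
            )
            >= 0.5
        )

    def test_background_only_no_strong_motif(self):
        hits = 0
        for seed in (301, 302, 303):
            cfg = SimulationConfig(
                seed=seed, gc_content=0.22, motif_coverage=0.0
            )
            seqs, _ = simulate_upstream(cfg, 40)
            ranked = discover(seqs, length_range=(5, 8), beam_width=25)
            hits += ranked[0].sig_value <= 2
        assert hits >= 2

    def test_stats_invariants(self):
        cfg = SimulationConfig(seed=2, gc_content=0.3, motif_coverage=0.5)
        seqs, _ = simulate_upstream(cfg, 25)
        for s in discover(seqs, length_range=(6, 7), beam_width=10)[:10]:
            assert 0.0 <= s.coverage <= 1.0
            assert s.count >= s.n_covered
            assert s.algorithm in ("beam", "prism")


class TestEvaluateQuery:
    def test_planted_positive_random_negative(self):
        planted, _ = simulate_upstream(
            SimulationConfig(seed=6, gc_content=0.22, motif_coverage=0.635), 61
        )
        random_set, _ = simulate_upstream(
            SimulationConfig(seed=106, gc_content=0.22, motif_coverage=0.0), 61
        )
        out = evaluate_query(
            "VBRGGTA", {"planted": planted, "random": random_set}
        )
        assert out["planted"].sig_value > 0
        assert out["random"].sig_value <= 0
        assert out["planted"].algorithm == "query"

    def test_empty_set_rejected(self):
        with pytest.raises(MotifError):
            evaluate_query("VBRGGTA", {})
        with pytest.raises(MotifError):
            evaluate_query("VBRGGTA", {"empty": {}})


class TestIO:
    def test_fasta_roundtrip(self, tmp_path):
        seqs = {"s1": "ACGTACGT", "s2": "TTTTGGGG"}
        path = tmp_path / "seqs.fasta"
        write_fasta(seqs, path)
        assert read_fasta(path) == seqs

    def test_bed_output(self, tmp_path):
        hits = scan("CAGGTAG", {"s": "AACAGGTAGAA"})
        path = tmp_path / "hits.bed"
        write_bed(hits, "CAGGTAG", path)
        lines = path.read_text().strip().split("\n")
        assert lines[0].split("\t") == ["s", "2", "9", "CAGGTAG", "0", "+"]

    def test_stats_frame_columns(self):
        seqs = {"a": "AACAGGTAGAA", "b": "AACAGGTAGAA"}
        df = stats_to_frame([motif_stats("CAGGTAG", seqs)])
        assert list(df.columns) == [
            "motif",
            "count",
            "sig_value",
            "coverage",
            "algorithm",
        ]


class TestCoverageOracle:
    def test_coverage_equals_regex_oracle(self):
        rng = np.random.default_rng(9)
        for trial in range(20):
            seqs = {
                f"s{i}": "".join(rng.choice(list("ACGT"), size=80))
                for i in range(10)
            }
            pattern = ["RGGTA", "SWS", "CAGGTM", "YYYY"][trial % 4]
            s = motif_stats(pattern, seqs)
            oracle_hits = regex_scan_oracle(pattern, seqs)
            covered = len({h[0] for h in oracle_hits})
            assert s.n_covered == covered
            assert s.count == len(oracle_hits)


def test_candidate_space_size_small_cases():
    # L=1: 4 concrete + 11 degenerate = 15 single-column codes
    assert candidate_space_size(1, 1) == 15
    assert candidate_space_size(1, 0) == 4
    # L=2, d<=1: 16 concrete + 2*11*4 one-degenerate
    assert candidate_space_size(2, 1) == 16 + 88
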