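"""Scanner unit tests: index construction, both repeat types, conventions,
overlap counting, monotonicity, and agreement with the quadratic oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitorepeats import (
    Genome,
    abundance,
    brute_force_repeats,
    build_kmer_index,
    find_direct_repeats,
    find_inverted_repeats,
    scan_all,
)
from mitorepeats.oracle import OracleCapError
from mitorepeats.repeats import ConventionError

dna = st.text(alphabet="ACGT", min_size=20, max_size=200)


def catalogs_equal(a, b):
    return (
        a.count == b.count
        and a.distinct_kmers == b.distinct_kmers
        and [(o.position, o.kmer) for o in a.occurrences]
        == [(o.position, o.kmer) for o in b.occurrences]
    )


class TestKmerIndex:
    def test_overlapping_windows(self):
        idx = build_kmer_index(Genome("g", "AAAAAA"), 5)
        assert idx.positions == {"AAAAA": [0, 1]}

    def test_single_window(self):
        assert build_kmer_index(Genome("g", "ACGTG"), 5).positions == {
            "ACGTG": [0]
        }

    def test_ambiguous_windows_skipped(self):
        assert build_kmer_index(Genome("g", "ACNGT"), 3).positions == {}

    def test_k_longer_than_linear_genome_gives_empty_index(self, caplog):
        idx = build_kmer_index(Genome("g", "ACGT"), 10)
        assert idx.positions == {}

    def test_circular_adds_wraparound_windows(self):
        idx = build_kmer_index(Genome("g", "ACGTT", circular=True), 3)
        # 5 rotational windows: ACG CGT GTT TTA TAC
        assert sum(len(v) for v in idx.positions.values()) == 5
        assert idx.positions["TTA"] == [3]
        assert idx.positions["TAC"] == [4]


class TestDirectRepeats:
    def test_homopolymer_overlap_counting(self):
        cat = find_direct_repeats(Genome("g", "AAAAAA"), 5)
        assert cat.positions == [0, 1]
        assert cat.count == 2

    def test_separated_copies(self):
        cat = find_direct_repeats(Genome("g", "ACGTGACGTG"), 5)
        assert [(o.position, o.kmer) for o in cat.occurrences] == [
            (0, "ACGTG"),
            (5, "ACGTG"),
        ]

    def test_all_distinct_kmers(self):
        assert find_direct_repeats(Genome("g", "ACGTGCATAC"), 5).count == 0

    @pytest.mark.parametrize("m", [1, 2, 5])
    def test_overlap_counting_rule(self, m):
        # "A" * (k+m) has exactly m+1 direct occurrences at length k
        k = 7
        cat = find_direct_repeats(Genome("g", "A" * (k + m)), k)
        assert cat.count == m + 1

    def test_conventions(self):
        # AAAAAAA: one 5-mer at 3 positions -> occ 3, distinct 1, pairs 3
        g = Genome("g", "AAAAAAA")
        assert find_direct_repeats(g, 5, "occurrence").count == 3
        assert find_direct_repeats(g, 5, "distinct").count == 1
        assert find_direct_repeats(g, 5, "pairs").count == 3

    def test_unknown_convention(self):
        with pytest.raises(ConventionError):
            find_direct_repeats(Genome("g", "ACGTACGT"), 5, "bogus")


class TestInvertedRepeats:
    def test_reverse_complement_cross_match(self):
        assert find_inverted_repeats(Genome("g", "AAAAATTTTT"), 5).count == 6

    def test_no_inverted_matches(self):
        assert find_inverted_repeats(Genome("g", "ACGTGACGTG"), 5).count == 0

    def test_palindrome_self_match_flag(self):
        g = Genome("g", "TGAATTCA")
        assert find_inverted_repeats(g, 6).count == 3
        assert (
            find_inverted_repeats(g, 6, include_self_palindrome=False).count
            == 2
        )

    def test_repeated_palindrome_kept_without_self_matches(self):
        # GAATTC twice: each copy matches the other even with self off
        g = Genome("g", "GAATTCAAAGAATTC")
        cat = find_inverted_repeats(g, 6, include_self_palindrome=False)
        assert {o.position for o in cat.occurrences} >= {0, 9}


class TestScanAll:
    def test_planted_duplication_recovered_exactly(self, rng):
        from tests.conftest import random_genome

        base = random_genome(rng, 100, id="p")
        k = 12
        word = base.sequence[10:10 + k]
        seq = base.sequence[:60] + word + base.sequence[60 + k:]
        g = Genome("p", seq)
        truth = brute_force_repeats(g, k, "direct")
        prof = scan_all(g, 5, 15)
        assert prof.count(k, "direct") == truth.count

    def test_short_genome_gives_zero_row(self):
        prof = scan_all(Genome("g", "ACG"), 5, 8)
        assert all(prof.count(k, t) == 0
                   for k in prof.ks for t in ("direct", "inverted"))

    def test_empty_genome_rejected(self):
        with pytest.raises(Exception):
            scan_all(Genome("g", ""), 5, 8)

    def test_abundance_cells_consistent(self, rng):
        from tests.conftest import random_genome

        g = random_genome(rng, 800)
        prof = scan_all(g, 5, 12)
        for k in prof.ks:
            for t in ("direct", "inverted"):
                assert prof.abundance(k, t) == pytest.approx(
                    prof.count(k, t) / (g.length / 1000)
                )


class TestAbundance:
    @pytest.mark.parametrize(
        "count,length,expected",
        [(3500, 17500, 200.0), (0, 12345, 0.0), (3150, 17500, 180.0)],
    )
    def test_values(self, count, length, expected):
        assert abundance(count, length) == pytest.approx(expected)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            abundance(1, 0)


class TestOracleAgreement:
    @given(dna, st.integers(5, 12), st.booleans())
    def test_direct_and_inverted_match_oracle(self, seq, k, circular):
        g = Genome("h", seq, circular=circular)
        for conv in ("occurrence", "distinct", "pairs"):
            assert catalogs_equal(
                find_direct_repeats(g, k, conv),
                brute_force_repeats(g, k, "direct", conv),
            )
            for incl in (True, False):
                assert catalogs_equal(
                    find_inverted_repeats(g, k, conv, incl),
                    brute_force_repeats(g, k, "inverted", conv, incl),
                )

    def test_oracle_cap(self):
        g = Genome("g", "A" * 5000)
        with pytest.raises(OracleCapError):
            brute_force_repeats(g, 5, "direct")


class TestSymmetries:
    @given(dna)
    def test_reverse_complement_symmetry(self, seq):
        from mitorepeats import reverse_complement

        g = Genome("g", seq)
        h = Genome("g", reverse_complement(seq))
        for k in (5, 7):
            assert (
                find_direct_repeats(g, k).count
                == find_direct_repeats(h, k).count
            )
            assert (
                find_inverted_repeats(g, k).count
                == find_inverted_repeats(h, k).count
            )

    @given(dna)
    def test_monotonicity_in_k(self, seq):
        g = Genome("g", seq)
        prof = scan_all(g, 5, 12)
        for t in ("direct", "inverted"):
            counts = [prof.count(k, t) for k in prof.ks]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_determinism(self, rng):
        from tests.conftest import random_genome

        g = random_genome(rng, 500)
        a = scan_all(g, 5, 10).to_json_dict()
        b = scan_all(Genome(g.id, g.sequence), 5, 10).to_json_dict()
        assert a == b
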