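"""Exact direct and inverted repeat enumeration over a k-mer position index.

The scan follows the strategy of sliding a window one nucleotide at a time
along the forward strand (5'->3'), recording every distinct k-mer with all of
its start positions, then asking which k-mers recur (direct repeats) and which
k-mers' reverse complements occur anywhere on the forward strand (inverted
repeats -- equivalently, a match against the complementary strand read
3'->5'). Overlapping occurrences are deliberately counted as independent
findings.

Three counting conventions are supported, because "number of repeats" is
ambiguous between them:

``occurrence``
    every position whose k-mer is repeated (direct) or has an inverted
    match (inverted); the default.
``distinct``
    number of distinct k-mer strings that are repeated / matched.
``pairs``
    number of matching window pairs: sum of C(m, 2) over repeated k-mers
    for direct repeats; for inverted repeats, sum of m_w * m_rc over
    complementary k-mer couples plus, for palindromic k-mers,
    C(m, 2) same-word pairs and (optionally) the m self-matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Tuple

from .genome import Genome, UNAMBIGUOUS, reverse_complement
from .profiles import ProfileMatrix

logger = logging.getLogger(__name__)

DIRECT = "direct"
INVERTED = "inverted"
REPEAT_TYPES = (DIRECT, INVERTED)
CONVENTIONS = ("occurrence", "distinct", "pairs")

#: Default repeat-length range, in base pairs.
K_MIN_DEFAULT = 5
K_MAX_DEFAULT = 30


class ConventionError(ValueError):
    """Unknown counting-convention token."""


def _check_convention(convention: str) -> None:
    if convention not in CONVENTIONS:
        raise ConventionError(
            f"unknown counting convention {convention!r}; "
            f"expected one of {CONVENTIONS}"
        )


@dataclass(frozen=True)
class RepeatOccurrence:
    """One window of a repeat on the forward strand (0-based start)."""

    kmer: str
    position: int
    k: int
    repeat_type: str


@dataclass
class RepeatCatalog:
    """All occurrences of one repeat type at one k for one genome.

    ``occurrences`` always lists every qualifying forward-strand window
    (the occurrence convention), sorted by position with no duplicates;
    ``count`` is convention-dependent and equals ``len(occurrences)`` only
    under the default occurrence convention.
    """

    genome_id: str
    k: int
    repeat_type: str
    occurrences: List[RepeatOccurrence] = field(default_factory=list)
    count: int = 0
    distinct_kmers: int = 0
    convention: str = "occurrence"

    @property
    def positions(self) -> List[int]:
        return [o.position for o in self.occurrences]


@dataclass
class KmerIndex:
    """Forward-strand k-mer -> ascending 0-based start positions.

    Windows containing any non-{A,C,G,T} character are skipped (exact-match
    semantics are undefined for ambiguity codes). Redundant window strings
    collapse onto one key.
    """

    k: int
    positions: Dict[str, List[int]] = field(default_factory=dict)

    def multiplicity(self, kmer: str) -> int:
        return len(self.positions.get(kmer, ()))


def iter_windows(genome: Genome, k: int) -> Iterator[Tuple[int, str]]:
    """Yield (start, k-mer) advancing one nucleotide at a time.

    Linear genomes yield L-k+1 windows; circular genomes additionally yield
    the k-1 origin-spanning windows, so every one of the L rotational start
    positions appears once.
    """
    seq = genome.sequence
    length = len(seq)
    if genome.circular and length >= k:
        seq = seq + seq[: k - 1]
        n_windows = length
    else:
        n_windows = length - k + 1
    for p in range(max(n_windows, 0)):
        kmer = seq[p : p + k]
        if set(kmer) <= UNAMBIGUOUS:
            yield p, kmer


def build_kmer_index(genome: Genome, k: int) -> KmerIndex:
    """Index every valid k-mer window of ``genome`` by start position."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if genome.length < 1:
        raise ValueError("cannot index an empty genome")
    index = KmerIndex(k=k)
    if not genome.circular and k > genome.length:
        logger.warning(
            "k=%d exceeds length %d of linear genome %s; empty index",
            k, genome.length, genome.id,
        )
        return index
    for p, kmer in iter_windows(genome, k):
        index.positions.setdefault(kmer, []).append(p)
    return index


def _catalog_from_matches(
    genome: Genome,
    k: int,
    repeat_type: str,
    convention: str,
    matched: Dict[str, List[int]],
    count_by_convention: Dict[str, int],
) -> RepeatCatalog:
    occ = sorted(
        (RepeatOccurrence(kmer=w, position=p, k=k, repeat_type=repeat_type)
         for w, ps in matched.items() for p in ps),
        key=lambda o: o.position,
    )
    return RepeatCatalog(
        genome_id=genome.id,
        k=k,
        repeat_type=repeat_type,
        occurrences=occ,
        count=count_by_convention[convention],
        distinct_kmers=len(matched),
        convention=convention,
    )


def find_direct_repeats(
    genome: Genome, k: int, convention: str = "occurrence"
) -> RepeatCatalog:
    """All forward-strand windows whose k-mer occurs at >= 2 positions."""
    _check_convention(convention)
    index = build_kmer_index(genome, k)
    matched = {w: ps for w, ps in index.positions.items() if len(ps) >= 2}
    counts = {
        "occurrence": sum(len(ps) for ps in matched.values()),
        "distinct": len(matched),
        "pairs": sum(len(ps) * (len(ps) - 1) // 2 for ps in matched.values()),
    }
    return _catalog_from_matches(genome, k, DIRECT, convention, matched, counts)


def find_inverted_repeats(
    genome: Genome,
    k: int,
    convention: str = "occurrence",
    include_self_palindrome: bool = True,
) -> RepeatCatalog:
    """Forward-strand windows whose reverse complement occurs on the forward
    strand (i.e. the window recurs on the complementary strand, inverted).

    A palindromic k-mer (equal to its own reverse complement) always matches
    its own locus when the complementary strand is read back; with
    ``include_self_palindrome`` off, a palindromic k-mer whose only inverted
    match is that mirrored self-locus is excluded.
    """
    _check_convention(convention)
    index = build_kmer_index(genome, k)
    matched: Dict[str, List[int]] = {}
    n_occ = 0
    n_pairs = 0
    seen_couples: set = set()
    for w, ps in index.positions.items():
        rc = reverse_complement(w)
        m_w = len(ps)
        if rc == w:
            if m_w >= 2 or include_self_palindrome:
                matched[w] = ps
                n_occ += m_w
                n_pairs += m_w * (m_w - 1) // 2
                if include_self_palindrome:
                    n_pairs += m_w
        else:
            m_rc = index.multiplicity(rc)
            if m_rc >= 1:
                matched[w] = ps
                n_occ += m_w
                couple = tuple(sorted((w, rc)))
                if couple not in seen_couples:
                    seen_couples.add(couple)
                    n_pairs += m_w * m_rc
    counts = {"occurrence": n_occ, "distinct": len(matched), "pairs": n_pairs}
    return _catalog_from_matches(
        genome, k, INVERTED, convention, matched, counts
    )


def abundance(count: int, genome_length: int) -> float:
    """Repeat abundance in repeats per Kbp: count / (length / 1000)."""
    if genome_length <= 0:
        raise ValueError(f"genome_length must be positive, got {genome_length}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return count / (genome_length / 1000.0)


def scan_all(
    genome: Genome,
    k_min: int = K_MIN_DEFAULT,
    k_max: int = K_MAX_DEFAULT,
    convention: str = "occurrence",
    include_self_palindrome: bool = True,
) -> ProfileMatrix:
    """Count direct and inverted repeats at every length k_min..k_max.

    Returns a :class:`~mitorepeats.profiles.ProfileMatrix` holding one
    (count, repeats/Kbp) cell per k per repeat type.
    """
    if not (1 <= k_min <= k_max):
        raise ValueError(f"need 1 <= k_min <= k_max, got {k_min}..{k_max}")
    if genome.length == 0:
        raise ValueError("cannot scan an empty genome")
    _check_convention(convention)
    counts: Dict[int, Dict[str, int]] = {}
    for k in range(k_min, k_max + 1):
        counts[k] = {
            DIRECT: find_direct_repeats(genome, k, convention).count,
            INVERTED: find_inverted_repeats(
                genome, k, convention, include_self_palindrome
            ).count,
        }
    return ProfileMatrix.from_counts(
        genome_id=genome.id,
        length_bp=genome.length,
        convention=convention,
        counts=counts,
    )


def catalogs_all(
    genome: Genome,
    k_min: int = K_MIN_DEFAULT,
    k_max: int = K_MAX_DEFAULT,
    convention: str = "occurrence",
    include_self_palindrome: bool = True,
) -> List[RepeatCatalog]:
    """Full occurrence catalogs for every (k, repeat type) in range."""
    out: List[RepeatCatalog] = []
    for k in range(k_min, k_max + 1):
        out.append(find_direct_repeats(genome, k, convention))
        out.append(
            find_inverted_repeats(genome, k, convention, include_self_palindrome)
        )
    return out
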