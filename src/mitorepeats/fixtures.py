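"""Synthetic sequence generators with known ground truth.

Two generators live here:

* :func:`generate_fixture` plants direct/inverted repeat copies at known
  coordinates in an i.i.d. background and rejection-resamples until the
  brute-force oracle confirms that the planted occurrences are the ONLY
  repeats at the planted lengths. The emitted truth catalog is therefore
  exact by construction.
* :func:`synthetic_mitogenome` emulates a mitogenome-like input at realistic
  scale (~17 Kbp, AT-rich vertebrate mtDNA composition, a control-region
  tandem repeat array, a gene-dense annotation) without per-occurrence
  ground truth; it is the input for cohort-level and pipeline runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import Feature, FeatureTable
from .genome import Genome, reverse_complement
from .oracle import brute_force_repeats
from .repeats import DIRECT, INVERTED, RepeatCatalog, RepeatOccurrence

BASES = "ACGT"

#: Vertebrate-mtDNA-like base composition: AT-rich with the heavy-strand
#: skew (A over T, C over G) that depresses reverse-complement matches
#: relative to same-strand matches.
MITO_COMPOSITION: Dict[str, float] = {"A": 0.34, "C": 0.29, "G": 0.11, "T": 0.26}


@dataclass(frozen=True)
class PlantedRepeat:
    """One repeat to plant: k, type, copy number, optional fixed positions."""

    k: int
    repeat_type: str
    n_copies: int = 2
    positions: Optional[Tuple[int, ...]] = None


@dataclass
class FixtureSpec:
    """Recipe for a ground-truth fixture sequence."""

    length: int
    base_composition: Dict[str, float] = field(
        default_factory=lambda: {b: 0.25 for b in BASES}
    )
    planted: List[PlantedRepeat] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.base_composition.get(b, 0.0) for b in BASES)
        if not np.isclose(total, 1.0):
            raise ValueError(f"base composition sums to {total}, not 1")
        for p in self.planted:
            if p.n_copies < 2:
                raise ValueError("planted repeats need >= 2 copies")
            if p.positions is not None:
                if len(p.positions) != p.n_copies:
                    raise ValueError("positions length != n_copies")
                for pos in p.positions:
                    if not (0 <= pos <= self.length - p.k):
                        raise ValueError(f"planted position {pos} does not fit")


class InfeasibleFixtureError(RuntimeError):
    """Rejection sampling failed to produce a collision-free background."""


def _random_sequence(
    rng: np.random.Generator, length: int, composition: Dict[str, float]
) -> np.ndarray:
    probs = np.array([composition.get(b, 0.0) for b in BASES])
    probs = probs / probs.sum()
    return rng.choice(np.frombuffer(BASES.encode(), dtype=np.uint8),
                      size=length, p=probs)


def _random_kmer(rng: np.random.Generator, k: int, avoid_palindrome: bool) -> str:
    while True:
        w = "".join(rng.choice(list(BASES), size=k))
        if not avoid_palindrome or w != reverse_complement(w):
            return w


def _choose_positions(
    rng: np.random.Generator,
    length: int,
    k: int,
    n: int,
    taken: List[Tuple[int, int]],
) -> List[int]:
    """Non-overlapping random starts, also avoiding previously taken spans."""
    positions: List[int] = []
    for _ in range(2000):
        if len(positions) == n:
            break
        pos = int(rng.integers(0, length - k + 1))
        span = (pos, pos + k)
        clash = any(s < span[1] and span[0] < e
                    for s, e in itertools.chain(taken,
                        ((p, p + k) for p in positions)))
        if not clash:
            positions.append(pos)
    if len(positions) < n:
        raise InfeasibleFixtureError(
            f"could not place {n} non-overlapping {k}-mers in {length} bp"
        )
    return positions


def _truth_catalogs(
    genome_id: str, planted_windows: List[Tuple[int, str]], ks: Sequence[int]
) -> Dict[Tuple[int, str], RepeatCatalog]:
    """Expected occurrence catalogs implied by the planted windows alone.

    Planted copies longer than k contribute every length-k sub-window: a
    pair of identical 15-mers is also a pair of identical 12-mers at each
    shared offset, so truth at a shorter checked k must include those.
    """
    truth: Dict[Tuple[int, str], RepeatCatalog] = {}
    for k in ks:
        wins = [
            (p + j, w[j : j + k])
            for p, w in planted_windows
            for j in range(len(w) - k + 1)
        ]
        kmers = [w for _, w in wins]
        direct = sorted(
            (p, w) for p, w in wins if kmers.count(w) >= 2
        )
        inverted = sorted(
            (p, w) for p, w in wins if reverse_complement(w) in kmers
        )
        for rtype, occ in ((DIRECT, direct), (INVERTED, inverted)):
            truth[(k, rtype)] = RepeatCatalog(
                genome_id=genome_id,
                k=k,
                repeat_type=rtype,
                occurrences=[
                    RepeatOccurrence(kmer=w, position=p, k=k, repeat_type=rtype)
                    for p, w in occ
                ],
                count=len(occ),
                distinct_kmers=len({w for _, w in occ}),
                convention="occurrence",
            )
    return truth


def generate_fixture(
    spec: FixtureSpec,
    genome_id: str = "fixture",
    ensure_clean_ks: Optional[Sequence[int]] = None,
    max_attempts: int = 60,
) -> Tuple[Genome, Dict[Tuple[int, str], RepeatCatalog]]:
    """Build a fixture sequence whose repeat content at the planted lengths
    is exactly the planted truth, verified by the brute-force oracle.

    ``ensure_clean_ks`` lists the lengths that must be free of accidental
    repeats beyond the truth; it defaults to the planted ks. Returns
    ``(genome, truth)`` with truth keyed by ``(k, repeat_type)``.
    """
    spec.validate()
    check_ks = sorted(
        set(ensure_clean_ks if ensure_clean_ks is not None
            else [p.k for p in spec.planted])
    )
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_attempts):
        arr = _random_sequence(rng, spec.length, spec.base_composition)
        taken: List[Tuple[int, int]] = []
        planted_windows: List[Tuple[int, str]] = []
        try:
            for plant in spec.planted:
                w = _random_kmer(rng, plant.k, avoid_palindrome=True)
                if plant.positions is not None:
                    positions = list(plant.positions)
                else:
                    positions = _choose_positions(
                        rng, spec.length, plant.k, plant.n_copies, taken
                    )
                for i, pos in enumerate(positions):
                    if plant.repeat_type == DIRECT:
                        word = w
                    else:
                        # alternate word / reverse complement across copies
                        word = w if i % 2 == 0 else reverse_complement(w)
                    arr[pos : pos + plant.k] = np.frombuffer(
                        word.encode(), dtype=np.uint8
                    )
                    taken.append((pos, pos + plant.k))
                    planted_windows.append((pos, word))
        except InfeasibleFixtureError:
            continue
        genome = Genome(id=genome_id, sequence=arr.tobytes().decode("ascii"))
        truth = _truth_catalogs(genome_id, planted_windows, check_ks)
        if all(
            _occ_set(brute_force_repeats(genome, k, rtype)) ==
            _occ_set(truth[(k, rtype)])
            for k in check_ks
            for rtype in (DIRECT, INVERTED)
        ):
            return genome, truth
    raise InfeasibleFixtureError(
        f"no collision-free background found in {max_attempts} attempts "
        f"(length {spec.length}, ks {check_ks}); use a longer sequence or "
        "larger planted k"
    )


def _occ_set(catalog: RepeatCatalog) -> set:
    return {(o.position, o.kmer) for o in catalog.occurrences}


# --- realistic-scale cohort material ----------------------------------------

def synthetic_mitogenome(
    genome_id: str,
    seed: int,
    length: int = 17000,
    composition: Optional[Dict[str, float]] = None,
    control_region_bp: int = 1200,
    motif_len: int = 40,
    motif_copies: int = 4,
    extra_dispersed: int = 0,
    extra_inverted_pairs: int = 0,
    circular: bool = True,
    taxonomy: Optional[Dict[str, str]] = None,
) -> Genome:
    """A mitogenome-like sequence at realistic scale.

    The final ``control_region_bp`` emulate the D-loop: they carry a tandem
    array of ``motif_copies`` copies of a random ``motif_len``-mer, the kind
    of repeat-rich control region mitogenomes actually show.
    ``extra_dispersed`` additionally sprinkles that many extra copies of a
    12-mer over the gene-coding body, and ``extra_inverted_pairs`` plants
    that many word / reverse-complement couples there, to model outlier
    genomes rich in direct or inverted repeats respectively.
    """
    comp = composition or MITO_COMPOSITION
    rng = np.random.default_rng(seed)
    arr = _random_sequence(rng, length, comp)
    cr_start = length - control_region_bp
    motif = "".join(rng.choice(list(BASES), size=motif_len))
    pos = cr_start + int(rng.integers(0, max(control_region_bp
                                             - motif_len * motif_copies, 1)))
    for _ in range(motif_copies):
        arr[pos : pos + motif_len] = np.frombuffer(motif.encode(), np.uint8)
        pos += motif_len
    if extra_dispersed:
        word = "".join(rng.choice(list(BASES), size=12))
        starts = rng.integers(0, cr_start - 12, size=extra_dispersed)
        for p in starts:
            arr[p : p + 12] = np.frombuffer(word.encode(), np.uint8)
    if extra_inverted_pairs:
        word = _random_kmer(rng, 12, avoid_palindrome=True)
        rc = reverse_complement(word)
        starts = rng.integers(0, cr_start - 12, size=2 * extra_inverted_pairs)
        for i, p in enumerate(starts):
            w = word if i % 2 == 0 else rc
            arr[p : p + 12] = np.frombuffer(w.encode(), np.uint8)
    return Genome(
        id=genome_id,
        sequence=arr.tobytes().decode("ascii"),
        circular=circular,
        taxonomy=taxonomy,
    )


def synthetic_feature_table(
    genome: Genome,
    n_genes: int = 13,
    n_trna: int = 22,
    control_region_bp: int = 1200,
) -> FeatureTable:
    """Gene-dense annotation matching :func:`synthetic_mitogenome`.

    Genes and tRNAs tile the body of the molecule back to back (mitogenomes
    are compact); the final ``control_region_bp`` stay unannotated except
    for a D-loop feature, which is non-genic by convention.
    """
    length = genome.length
    body = length - control_region_bp
    features: List[Feature] = []
    # interleave the large genes with tRNA punctuation, GenBank-style
    slots = n_genes + n_trna
    trna_len = 70
    gene_len = (body - n_trna * trna_len) // n_genes
    pos = 0
    gene_i = trna_i = 0
    for s in range(slots):
        if s % 3 == 2 and trna_i < n_trna:
            flen, ftype = trna_len, "tRNA"
            name = f"trn{trna_i}"
            trna_i += 1
        elif gene_i < n_genes:
            flen, ftype = gene_len, "gene"
            name = f"gene{gene_i}"
            gene_i += 1
        else:
            flen, ftype, name = trna_len, "tRNA", f"trn{trna_i}"
            trna_i += 1
        end = min(pos + flen, body)
        if pos < end:
            features.append(Feature(type=ftype, start=pos, end=end, name=name))
        pos = end
    features.append(Feature(type="D-loop", start=body, end=length,
                            name="control region"))
    return FeatureTable(
        genome_id=genome.id, length=length,
        features=features, circular=genome.circular,
    )
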