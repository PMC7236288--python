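"""Independent quadratic repeat oracle: every window against every window.

Used only for verification. Each valid k-mer window is encoded as a base-4
integer, and the full pairwise equality matrix between windows (direct) or
between forward windows and windows of the reverse-complemented sequence
(inverted) is materialised. No code is shared with the dict-index scanner
in :mod:`mitorepeats.repeats`, so agreement between the two is meaningful.

Cost is Theta(n^2) memory and time per call; a cap on genome length keeps
that bounded.
"""

from __future__ import annotations

import numpy as np

from .genome import Genome, reverse_complement
from .repeats import (
    DIRECT,
    INVERTED,
    ConventionError,
    CONVENTIONS,
    RepeatCatalog,
    RepeatOccurrence,
)

#: Refuse sequences longer than this (quadratic cost guard).
ORACLE_LENGTH_CAP = 4000

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


class OracleCapError(ValueError):
    """Sequence too long for the quadratic oracle."""


def _window_codes(sequence: str, k: int, circular: bool):
    """Return (start positions, base-4 integer codes) of valid windows."""
    seq = sequence + (sequence[: k - 1] if circular and len(sequence) >= k else "")
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = (len(sequence) if circular else len(sequence) - k + 1)
    n = max(n, 0)
    if n == 0 or len(arr) < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)[:n]
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k, dtype=np.int64)
    vals = windows @ powers
    return np.nonzero(valid)[0].astype(np.int64), vals[valid]


def brute_force_repeats(
    genome: Genome,
    k: int,
    repeat_type: str,
    convention: str = "occurrence",
    include_self_palindrome: bool = True,
    length_cap: int = ORACLE_LENGTH_CAP,
) -> RepeatCatalog:
    """Quadratic all-pairs repeat search; contract identical to the scanners."""
    if genome.length > length_cap:
        raise OracleCapError(
            f"genome length {genome.length} exceeds oracle cap {length_cap}"
        )
    if convention not in CONVENTIONS:
        raise ConventionError(f"unknown counting convention {convention!r}")
    if repeat_type == DIRECT:
        return _direct(genome, k, convention)
    if repeat_type == INVERTED:
        return _inverted(genome, k, convention, include_self_palindrome)
    raise ValueError(f"unknown repeat type {repeat_type!r}")


def _make_catalog(genome, k, repeat_type, convention, positions, count, distinct):
    seq = genome.sequence
    ext = seq + seq[: k - 1] if genome.circular else seq
    occurrences = [
        RepeatOccurrence(kmer=ext[p : p + k], position=int(p), k=k,
                         repeat_type=repeat_type)
        for p in sorted(int(x) for x in positions)
    ]
    return RepeatCatalog(
        genome_id=genome.id,
        k=k,
        repeat_type=repeat_type,
        occurrences=occurrences,
        count=int(count),
        distinct_kmers=int(distinct),
        convention=convention,
    )


def _direct(genome: Genome, k: int, convention: str) -> RepeatCatalog:
    pos, vals = _window_codes(genome.sequence, k, genome.circular)
    if vals.size == 0:
        return _make_catalog(genome, k, DIRECT, convention, [], 0, 0)
    eq = vals[:, None] == vals[None, :]
    np.fill_diagonal(eq, False)
    hit = eq.any(axis=1)
    occ_positions = pos[hit]
    n_occ = int(hit.sum())
    distinct = int(np.unique(vals[hit]).size)
    n_pairs = int(eq.sum()) // 2
    count = {"occurrence": n_occ, "distinct": distinct, "pairs": n_pairs}[convention]
    return _make_catalog(genome, k, DIRECT, convention, occ_positions, count, distinct)


def _inverted(
    genome: Genome, k: int, convention: str, include_self_palindrome: bool
) -> RepeatCatalog:
    length = genome.length
    pos_f, vals_f = _window_codes(genome.sequence, k, genome.circular)
    rc_seq = reverse_complement(genome.sequence)
    pos_r, vals_r = _window_codes(rc_seq, k, genome.circular)
    if vals_f.size == 0 or vals_r.size == 0:
        return _make_catalog(genome, k, INVERTED, convention, [], 0, 0)
    match = vals_f[:, None] == vals_r[None, :]
    # the rc-strand window starting at mirror(p) reads the same physical
    # site as the forward window at p; drop those self matches if asked
    if genome.circular:
        mirror = (length - k - pos_f) % length
    else:
        mirror = length - k - pos_f
    r_index = {int(q): j for j, q in enumerate(pos_r)}
    self_cells = []
    for i, q in enumerate(mirror):
        j = r_index.get(int(q))
        if j is not None and match[i, j]:
            self_cells.append((i, j))
    if not include_self_palindrome:
        for i, j in self_cells:
            match[i, j] = False
        n_self = 0
    else:
        n_self = len(self_cells)
    hit = match.any(axis=1)
    occ_positions = pos_f[hit]
    n_occ = int(hit.sum())
    distinct = int(np.unique(vals_f[hit]).size)
    # every unordered site pair appears twice in the matrix except the
    # palindromic self matches, which appear once
    n_pairs = (int(match.sum()) + n_self) // 2
    count = {"occurrence": n_occ, "distinct": distinct, "pairs": n_pairs}[convention]
    return _make_catalog(
        genome, k, INVERTED, convention, occ_positions, count, distinct
    )
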