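"""Composition-preserving randomization null for repeat abundance.

Each control replicate is a uniform random permutation of the genome's
characters, so length and exact per-base counts (hence GC content) are
preserved. Replicates are scanned exactly like the biological sequence and
summarised into a null ensemble.

Reproducibility contract: replicate ``r`` of a run seeded with ``seed``
draws from ``numpy.random.default_rng(SeedSequence(entropy=seed,
spawn_key=(r,)))``. The rule is deterministic and independent of replicate
order, so ensembles are portable across runs and machines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

from .genome import Genome
from .profiles import ProfileMatrix
from .repeats import K_MAX_DEFAULT, K_MIN_DEFAULT, scan_all


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """The documented sub-seed rule: spawn_key = (replicate index,)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(replicate,))
    )


def shuffle_sequence(sequence: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of the characters of ``sequence``."""
    if not sequence:
        raise ValueError("cannot shuffle an empty sequence")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return rng.permutation(arr).tobytes().decode("ascii")


@dataclass
class NullEnsemble:
    """Replicate profiles of shuffled copies of one genome, with summaries."""

    genome_id: str
    n_replicates: int
    seed: int
    replicate_profiles: List[ProfileMatrix] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean and SD of abundance per (k, repeat type) across replicates."""
        frames = []
        for r, prof in enumerate(self.replicate_profiles):
            f = prof.to_frame()
            f["replicate"] = r
            frames.append(f)
        long = pd.concat(frames, ignore_index=True)
        return (
            long.groupby(["k", "repeat_type"])["abundance"]
            .agg(["mean", "std"])
            .reset_index()
        )

    def mean_profile(self) -> ProfileMatrix:
        """Per-(k,type) mean abundance over replicates, as a pseudo-profile.

        Counts hold the mean count (possibly fractional); abundances are
        exact means. Used for the cohort's random-source rows.
        """
        first = self.replicate_profiles[0]
        ks = first.ks
        mean_counts: Dict[int, Dict[str, float]] = {}
        for k in ks:
            mean_counts[k] = {}
            for t in first.counts[k]:
                mean_counts[k][t] = float(
                    np.mean([p.counts[k][t] for p in self.replicate_profiles])
                )
        prof = ProfileMatrix.from_counts(
            genome_id=first.genome_id,
            length_bp=first.length_bp,
            convention=first.convention,
            counts=mean_counts,
        )
        return prof

    def max_k_with_repeats(self, repeat_type: str) -> int:
        """Largest k at which any replicate shows a nonzero count (0 if none)."""
        best = 0
        for prof in self.replicate_profiles:
            for k in prof.ks:
                if prof.counts[k][repeat_type] > 0:
                    best = max(best, k)
        return best

    def to_json_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "replicates": [p.to_json_dict() for p in self.replicate_profiles],
        }


def build_null(
    genome: Genome,
    n_replicates: int = 10,
    seed: int = 0,
    k_min: int = K_MIN_DEFAULT,
    k_max: int = K_MAX_DEFAULT,
    convention: str = "occurrence",
    include_self_palindrome: bool = True,
) -> NullEnsemble:
    """Shuffle ``genome`` ``n_replicates`` times and scan each replicate."""
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    profiles: List[ProfileMatrix] = []
    for r in range(n_replicates):
        rng = replicate_rng(seed, r)
        shuffled = Genome(
            id=f"{genome.id}|shuffle{r}",
            sequence=shuffle_sequence(genome.sequence, rng),
            circular=genome.circular,
            taxonomy=genome.taxonomy,
        )
        prof = scan_all(
            shuffled, k_min, k_max, convention, include_self_palindrome
        )
        # profile reported under the source genome id
        prof.genome_id = genome.id
        profiles.append(prof)
    return NullEnsemble(
        genome_id=genome.id,
        n_replicates=n_replicates,
        seed=seed,
        replicate_profiles=profiles,
    )
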