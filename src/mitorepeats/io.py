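"""File ingestion and serialization: FASTA, GenBank, catalog/profile files.

FASTA and GenBank parsing is delegated to Biopython's SeqIO; coordinates
arrive from Biopython already 0-based half-open, which is also the internal
convention. All human-facing output coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

from .annotation import Feature, FeatureTable
from .genome import Genome
from .profiles import ProfileMatrix
from .randomize import NullEnsemble
from .repeats import RepeatCatalog, RepeatOccurrence

logger = logging.getLogger(__name__)

CATALOG_COLUMNS = ("genome_id", "k", "repeat_type", "kmer",
                   "start_1based", "end_1based")


class ParseError(ValueError):
    pass


def read_fasta(path) -> List[Genome]:
    """Read one Genome per FASTA record (ids = first header token)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    genomes = []
    for rec in records:
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: record {rec.id!r} has no sequence")
        genomes.append(Genome(id=rec.id, sequence=str(rec.seq)))
    return genomes


def read_genbank(path) -> Tuple[Genome, FeatureTable]:
    """Read sequence plus feature annotations from a GenBank flat file.

    The circular flag is taken from the LOCUS topology field. Simple
    features use their 0-based half-open location directly; two-part
    compound locations (origin-wrapping on circular records) are stored as
    two intervals; other compound locations are skipped with a warning.
    """
    path = Path(path)
    rec = next(SeqIO.parse(str(path), "genbank"), None)
    if rec is None:
        raise ParseError(f"{path}: no GenBank record found")
    if len(rec.seq) == 0:
        raise ParseError(f"{path}: record {rec.id!r} has no sequence")
    circular = rec.annotations.get("topology", "linear") == "circular"
    genome = Genome(id=rec.id, sequence=str(rec.seq), circular=circular)
    features: List[Feature] = []
    for feat in rec.features:
        if feat.type == "source":
            continue
        name = ""
        for key in ("gene", "product", "note"):
            if key in feat.qualifiers:
                name = feat.qualifiers[key][0]
                break
        loc = feat.location
        strand = loc.strand if loc.strand is not None else 1
        if isinstance(loc, CompoundLocation):
            if len(loc.parts) == 2 and circular:
                parts = loc.parts
            else:
                logger.warning(
                    "%s: skipping feature %s with unsupported compound "
                    "location %s", path, feat.type, loc,
                )
                continue
        else:
            parts = [loc]
        for part in parts:
            start, end = int(part.start), int(part.end)
            if not (0 <= start < end <= len(rec.seq)):
                raise ParseError(
                    f"{path}: feature {feat.type} location [{start},{end}) "
                    f"outside sequence of length {len(rec.seq)}"
                )
            features.append(Feature(
                type=feat.type, start=start, end=end,
                strand=int(strand), name=name,
            ))
    table = FeatureTable(
        genome_id=rec.id, length=len(rec.seq),
        features=features, circular=circular,
    )
    table.validate()
    return genome, table


def read_metadata(path) -> pd.DataFrame:
    """Read the per-genome metadata TSV (genome_id, species, order)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "genome_id" not in df.columns:
        raise ParseError(f"{path}: metadata needs a genome_id column")
    return df


# --- catalog TSV -------------------------------------------------------------

def write_catalog(catalog: RepeatCatalog, path) -> None:
    rows = [
        {
            "genome_id": catalog.genome_id,
            "k": occ.k,
            "repeat_type": occ.repeat_type,
            "kmer": occ.kmer,
            "start_1based": occ.position + 1,
            "end_1based": occ.position + occ.k,
        }
        for occ in catalog.occurrences
    ]
    pd.DataFrame(rows, columns=list(CATALOG_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_catalog(path) -> RepeatCatalog:
    """Re-read a catalog TSV (occurrence convention implied)."""
    df = pd.read_csv(path, sep="\t")
    occurrences = [
        RepeatOccurrence(
            kmer=row.kmer,
            position=int(row.start_1based) - 1,
            k=int(row.k),
            repeat_type=row.repeat_type,
        )
        for row in df.itertuples()
    ]
    if occurrences:
        gid = df["genome_id"].iloc[0]
        k = int(df["k"].iloc[0])
        rtype = df["repeat_type"].iloc[0]
    else:
        gid, k, rtype = "", 0, ""
    return RepeatCatalog(
        genome_id=gid, k=k, repeat_type=rtype,
        occurrences=occurrences, count=len(occurrences),
        distinct_kmers=len({o.kmer for o in occurrences}),
        convention="occurrence",
    )


# --- profile / ensemble JSON -------------------------------------------------

def write_profile(profile: ProfileMatrix, path) -> None:
    with open(path, "w") as fh:
        json.dump(profile.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_profile(path) -> ProfileMatrix:
    with open(path) as fh:
        return ProfileMatrix.from_json_dict(json.load(fh))


def write_ensemble(ensemble: NullEnsemble, path) -> None:
    with open(path, "w") as fh:
        json.dump(ensemble.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_ensemble_abundances(ensemble: NullEnsemble, path) -> None:
    """Per-replicate abundance TSV: replicate, k, repeat_type, abundance."""
    frames = []
    for r, prof in enumerate(ensemble.replicate_profiles):
        f = prof.to_frame()
        f.insert(0, "replicate", r)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
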