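"""Genic/non-genic classification of repeat occurrences and map export.

Feature annotations (typically from a GenBank record) are collapsed into a
per-position genic mask: positions covered by genes, CDS, tRNA or rRNA
features are genic; the control region (D-loop) and intergenic spacers are
non-genic. Repeat occurrences are then classified against the mask and the
regional bias is quantified as an enrichment ratio with a binomial test
against the genic length fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .repeats import RepeatCatalog

logger = logging.getLogger(__name__)

#: Feature types treated as genic by default; D-loop and misc features are not.
DEFAULT_GENIC_TYPES = frozenset({"gene", "CDS", "tRNA", "rRNA"})

GENIC = "genic"
NON_GENIC = "non_genic"


@dataclass(frozen=True)
class Feature:
    """One annotated interval, internal 0-based half-open coordinates."""

    type: str
    start: int
    end: int
    strand: int = 1
    name: str = ""


@dataclass
class FeatureTable:
    """Feature annotations for one genome."""

    genome_id: str
    length: int
    features: List[Feature] = field(default_factory=list)
    circular: bool = False

    def validate(self) -> None:
        for f in self.features:
            if not (0 <= f.start < f.end <= self.length):
                raise ValueError(
                    f"feature {f.name or f.type} [{f.start},{f.end}) outside "
                    f"genome bounds [0,{self.length})"
                )


@dataclass
class GenicMask:
    """Per-position genic flag for one genome."""

    genome_id: str
    mask: np.ndarray  # bool, length == genome length

    @property
    def genic_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0

    def __len__(self) -> int:
        return len(self.mask)


def build_genic_mask(
    features: FeatureTable,
    genic_types: Iterable[str] = DEFAULT_GENIC_TYPES,
) -> GenicMask:
    """Union of all features whose type is in ``genic_types``."""
    features.validate()
    genic_types = set(genic_types)
    mask = np.zeros(features.length, dtype=bool)
    for f in features.features:
        if f.type in genic_types:
            mask[f.start : f.end] = True
    return GenicMask(genome_id=features.genome_id, mask=mask)


def classify_occurrences(
    catalog: RepeatCatalog,
    mask: GenicMask,
    rule: str = "majority",
) -> pd.DataFrame:
    """Label every occurrence genic or non-genic.

    ``majority``: genic when strictly more than half of the k bases lie on
    genic positions; exact ties (possible for even k) take the label of the
    start base. ``start``: the start base alone decides. Windows of circular
    genomes may wrap; positions are taken modulo the genome length.
    """
    length = len(mask)
    rows = []
    for occ in catalog.occurrences:
        if occ.position >= length or occ.k > length:
            raise ValueError(
                f"occurrence at {occ.position} (k={occ.k}) outside mask of "
                f"length {length}; catalog and mask must describe the same "
                "genome"
            )
        # origin-wrapping windows of circular genomes fold back onto the start
        idx = np.arange(occ.position, occ.position + occ.k) % length
        genic_bases = int(mask.mask[idx].sum())
        if rule == "start":
            label = GENIC if mask.mask[occ.position % length] else NON_GENIC
        elif rule == "majority":
            if genic_bases * 2 > occ.k:
                label = GENIC
            elif genic_bases * 2 < occ.k:
                label = NON_GENIC
            else:
                label = GENIC if mask.mask[occ.position % length] else NON_GENIC
        else:
            raise ValueError(f"unknown classification rule {rule!r}")
        rows.append({
            "genome_id": catalog.genome_id,
            "k": occ.k,
            "repeat_type": occ.repeat_type,
            "kmer": occ.kmer,
            "position": occ.position,
            "genic_bases": genic_bases,
            "label": label,
        })
    cols = ["genome_id", "k", "repeat_type", "kmer", "position",
            "genic_bases", "label"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class RegionBias:
    """Genic-vs-non-genic occurrence bias for one catalog.

    ``enrichment`` is the genic share of occurrences divided by the genic
    length fraction: 1 means no bias, >1 genic preference, <1 non-genic
    preference. The p value is a two-sided binomial test of the genic
    occurrence count against the genic length fraction.
    """

    n_genic: int
    n_nongenic: int
    genic_fraction: float
    enrichment: float
    p_value: float

    def to_json_dict(self) -> dict:
        return {
            "n_genic": self.n_genic,
            "n_nongenic": self.n_nongenic,
            "genic_fraction": self.genic_fraction,
            "enrichment": self.enrichment,
            "p_value": self.p_value,
        }


def region_bias(classified: pd.DataFrame, mask: GenicMask) -> RegionBias:
    """Quantify the genic/non-genic distribution bias of classified repeats."""
    if classified.empty:
        raise ValueError("region bias is undefined with zero occurrences")
    n_genic = int((classified["label"] == GENIC).sum())
    n_total = int(len(classified))
    frac = mask.genic_fraction
    share = n_genic / n_total
    if frac in (0.0, 1.0):
        enrichment = 1.0 if share == frac else (0.0 if frac == 1.0 else np.inf)
        p = 1.0 if share == frac else 0.0
    else:
        enrichment = share / frac
        p = float(sps.binomtest(n_genic, n_total, frac).pvalue)
    return RegionBias(
        n_genic=n_genic,
        n_nongenic=n_total - n_genic,
        genic_fraction=frac,
        enrichment=float(enrichment),
        p_value=p,
    )


# --- map / tree-annotation export -------------------------------------------

MAP_COLUMNS = ("genome_id", "track", "name", "start_1based", "end_1based",
               "strand", "k", "repeat_type")


def export_map(
    catalog: RepeatCatalog,
    features: Optional[FeatureTable],
    path,
) -> None:
    """Write a BED-like TSV with a repeat track and an optional feature track.

    Output coordinates are 1-based inclusive (GenBank convention); internal
    coordinates are 0-based half-open, so [start, start+k) becomes
    (start+1, start+k).
    """
    rows = []
    for occ in catalog.occurrences:
        rows.append({
            "genome_id": catalog.genome_id,
            "track": "repeat",
            "name": occ.kmer,
            "start_1based": occ.position + 1,
            "end_1based": occ.position + occ.k,
            "strand": "+",
            "k": occ.k,
            "repeat_type": occ.repeat_type,
        })
    if features is not None:
        for f in features.features:
            rows.append({
                "genome_id": features.genome_id,
                "track": "feature",
                "name": f.name or f.type,
                "start_1based": f.start + 1,
                "end_1based": f.end,
                "strand": "+" if f.strand >= 0 else "-",
                "k": "",
                "repeat_type": f.type,
            })
    pd.DataFrame(rows, columns=list(MAP_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_map(path) -> pd.DataFrame:
    """Read a map track written by :func:`export_map`."""
    return pd.read_csv(path, sep="\t")


def map_intervals(df: pd.DataFrame, track: str = "repeat") -> List[Tuple[int, int]]:
    """Internal 0-based half-open intervals of one track of a map file."""
    sub = df[df["track"] == track]
    return [
        (int(s) - 1, int(e))
        for s, e in zip(sub["start_1based"], sub["end_1based"])
    ]


def render_linear_map(
    catalog: RepeatCatalog,
    features: Optional[FeatureTable],
    path,
) -> None:
    """Minimal linear map image: feature boxes below, repeat ticks above."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 2))
    length = features.length if features else max(
        (o.position + o.k for o in catalog.occurrences), default=1
    )
    if features is not None:
        for f in features.features:
            ax.axvspan(f.start, f.end, ymin=0.05, ymax=0.40, alpha=0.3,
                       color="tab:blue")
    for occ in catalog.occurrences:
        ax.vlines(occ.position, 0.55, 0.95, color="tab:red", lw=0.6)
    ax.set_xlim(0, length)
    ax.set_yticks([])
    ax.set_xlabel("position (bp)")
    ax.set_title(
        f"{catalog.genome_id}: {catalog.repeat_type} repeats, k={catalog.k}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_tree_annotations(
    cohort: pd.DataFrame, k: int, repeat_type: str, path,
    source: str = "biological",
) -> None:
    """Write a simple-bar-chart annotation file for interactive tree viewers.

    One data line per genome (canonically sorted by id):
    ``genome_id,abundance``. The header declares a minimal SIMPLEBAR
    dataset so the file can be dropped onto an iTOL-style viewer.
    """
    from .profiles import abundance_column

    col = abundance_column(k, repeat_type)
    sub = cohort[cohort["source"] == source].sort_values("genome_id")
    lines = [
        "DATASET_SIMPLEBAR",
        "SEPARATOR COMMA",
        f"DATASET_LABEL,{repeat_type} repeats k={k} (repeats/Kbp)",
        "COLOR,#c0392b",
        "DATA",
    ]
    for _, row in sub.iterrows():
        lines.append(f"{row['genome_id']},{row[col]:.6g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
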