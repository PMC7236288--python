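"""Per-genome repeat profiles and cohort-level abundance tables.

A ProfileMatrix is the (k x repeat-type) grid of repeat counts and
abundances (repeats per Kbp) for one genome. A cohort table stacks these
per-genome abundances, one row per (genome, source) with source either
``biological`` or ``random`` (the shuffled control), plus a taxonomic
order label used for per-order summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BIOLOGICAL = "biological"
RANDOM = "random"
KNOWN_ORDERS = ("Anura", "Caudata", "Gymnophiona")
UNKNOWN_ORDER = "unknown"


def abundance_column(k: int, repeat_type: str) -> str:
    """Cohort-table column name for the abundance at one (k, type)."""
    return f"{repeat_type}_k{k}"


@dataclass
class ProfileMatrix:
    """Counts and abundances over k x {direct, inverted} for one genome."""

    genome_id: str
    length_bp: int
    convention: str
    counts: Dict[int, Dict[str, int]]
    abundances: Dict[int, Dict[str, float]] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls,
        genome_id: str,
        length_bp: int,
        convention: str,
        counts: Dict[int, Dict[str, int]],
    ) -> "ProfileMatrix":
        if length_bp <= 0:
            raise ValueError("length_bp must be positive")
        abundances = {
            k: {t: c / (length_bp / 1000.0) for t, c in row.items()}
            for k, row in counts.items()
        }
        return cls(genome_id, length_bp, convention, counts, abundances)

    @property
    def ks(self) -> List[int]:
        return sorted(self.counts)

    def count(self, k: int, repeat_type: str) -> int:
        return self.counts[k][repeat_type]

    def abundance(self, k: int, repeat_type: str) -> float:
        return self.abundances[k][repeat_type]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: k, repeat_type, count, abundance."""
        rows = [
            {"k": k, "repeat_type": t, "count": c,
             "abundance": self.abundances[k][t]}
            for k, row in sorted(self.counts.items())
            for t, c in sorted(row.items())
        ]
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "length_bp": self.length_bp,
            "convention": self.convention,
            "counts": {str(k): dict(v) for k, v in sorted(self.counts.items())},
            "abundance": {
                str(k): dict(v) for k, v in sorted(self.abundances.items())
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ProfileMatrix":
        counts = {int(k): {t: int(c) for t, c in v.items()}
                  for k, v in d["counts"].items()}
        return cls.from_counts(
            d["genome_id"], int(d["length_bp"]), d["convention"], counts
        )


def build_cohort(
    biological: Sequence[ProfileMatrix],
    random_means: Optional[Mapping[str, ProfileMatrix]] = None,
    orders: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Assemble the cohort abundance table.

    Parameters
    ----------
    biological:
        One profile per genome.
    random_means:
        genome_id -> profile of per-(k,type) mean abundance over the
        shuffled replicates (each genome contributes one averaged row for
        the random source, matching how control points are plotted).
    orders:
        genome_id -> taxonomic order label; missing ids get ``unknown``.
    """
    orders = dict(orders or {})
    rows = []
    for prof in biological:
        rows.append(_cohort_row(prof, BIOLOGICAL, orders))
    if random_means:
        for gid in sorted(random_means):
            rows.append(_cohort_row(random_means[gid], RANDOM, orders))
    if not rows:
        raise ValueError("cohort is empty")
    return pd.DataFrame(rows)


def _cohort_row(prof: ProfileMatrix, source: str, orders: Mapping[str, str]) -> dict:
    row = {
        "genome_id": prof.genome_id,
        "source": source,
        "order": orders.get(prof.genome_id, UNKNOWN_ORDER),
        "length_bp": prof.length_bp,
    }
    for k in prof.ks:
        for t, a in prof.abundances[k].items():
            row[abundance_column(k, t)] = a
    return row


def cohort_composition(order_counts: Mapping[str, int]) -> pd.DataFrame:
    """Share of each taxonomic order in a cohort, as integer percentages.

    Given ``{order: n_genomes}`` returns a table with columns ``n``,
    ``share`` (fraction) and ``share_percent`` (rounded to the nearest
    integer percent).
    """
    total = sum(order_counts.values())
    if total <= 0:
        raise ValueError("order counts must sum to a positive total")
    df = pd.DataFrame(
        {"n": pd.Series(dict(order_counts), dtype=int)}
    ).sort_index()
    df["share"] = df["n"] / total
    df["share_percent"] = (df["share"] * 100).round().astype(int)
    return df


@dataclass
class SourceComparison:
    """Biological-vs-random comparison at one (k, repeat type)."""

    k: int
    repeat_type: str
    n: Dict[str, int]
    mean: Dict[str, float]
    variance: Dict[str, float]
    more_abundant: Optional[str]
    levene: "object"  # TestResult
    welch: "object"   # TestResult
    ecdfs: Dict[str, "object"]

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "repeat_type": self.repeat_type,
            "n": self.n,
            "mean": self.mean,
            "variance": self.variance,
            "more_abundant": self.more_abundant,
            "levene": self.levene.to_json_dict(),
            "welch": self.welch.to_json_dict(),
        }


def compare_sources(
    cohort: pd.DataFrame, k: int, repeat_type: str
) -> SourceComparison:
    """Compare biological against randomized abundances at one (k, type).

    Runs the Brown-Forsythe (Levene) variance-homogeneity test and Welch's
    heteroscedastic ANOVA (two groups here, so Welch F = Welch t^2), with
    the halved-degrees-of-freedom p value attached to both.
    """
    from .stats import adjust_df_half, ecdf, levene_test, welch_anova

    col = abundance_column(k, repeat_type)
    if col not in cohort.columns:
        raise KeyError(f"cohort has no column {col!r}")
    groups: Dict[str, np.ndarray] = {}
    for source in (BIOLOGICAL, RANDOM):
        vals = cohort.loc[cohort["source"] == source, col].to_numpy(float)
        if vals.size == 0:
            raise ValueError(f"cohort has no {source!r} rows at {col}")
        if vals.size < 2:
            raise ValueError(
                f"need >= 2 {source!r} genomes to compare sources at {col}"
            )
        groups[source] = vals
    glist = [groups[BIOLOGICAL], groups[RANDOM]]
    lev = adjust_df_half(levene_test(glist))
    wel = adjust_df_half(welch_anova(glist))
    means = {s: float(np.mean(v)) for s, v in groups.items()}
    if np.isclose(means[BIOLOGICAL], means[RANDOM], rtol=1e-12, atol=0.0):
        more = None
    else:
        more = max(means, key=means.get)
    return SourceComparison(
        k=k,
        repeat_type=repeat_type,
        n={s: int(v.size) for s, v in groups.items()},
        mean=means,
        variance={s: float(np.var(v, ddof=1)) for s, v in groups.items()},
        more_abundant=more,
        levene=lev,
        welch=wel,
        ecdfs={s: ecdf(v) for s, v in groups.items()},
    )


def order_summary(
    cohort: pd.DataFrame,
    k: int,
    repeat_type: str,
    atypical_sd: float = 2.0,
    source: str = BIOLOGICAL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-order abundance summary with atypical-genome flags.

    A genome is flagged atypical when its abundance exceeds the cohort mean
    by more than ``atypical_sd`` cohort standard deviations at this
    (k, repeat type). Returns ``(per-order table, atypical table)``.
    """
    col = abundance_column(k, repeat_type)
    sub = cohort[cohort["source"] == source]
    if sub.empty:
        raise ValueError(f"no rows with source {source!r}")
    per_order = []
    for order, grp in sub.groupby("order"):
        if grp.empty:  # defensive; groupby never yields empty groups
            logger.warning("order %s empty, omitted from summary", order)
            continue
        per_order.append({
            "order": order,
            "n": int(len(grp)),
            "mean": float(grp[col].mean()),
            "median": float(grp[col].median()),
        })
    table = pd.DataFrame(per_order).set_index("order")
    mu = float(sub[col].mean())
    sd = float(sub[col].std(ddof=1)) if len(sub) > 1 else 0.0
    cutoff = mu + atypical_sd * sd
    atyp = sub[sub[col] > cutoff][["genome_id", "order", col]].copy()
    atyp = atyp.rename(columns={col: "abundance"}).reset_index(drop=True)
    atyp["cutoff"] = cutoff
    return table, atyp
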