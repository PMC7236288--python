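"""End-to-end run orchestration: scan -> null -> cohort stats -> mapping.

Outputs are diffable text files (TSV/JSON) under one output directory,
listed with content checksums in a run manifest together with the
configuration and seeds that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import __version__
from .annotation import (
    DEFAULT_GENIC_TYPES,
    FeatureTable,
    build_genic_mask,
    classify_occurrences,
    export_map,
    export_tree_annotations,
    region_bias,
)
from .genome import Genome
from .io import (
    read_fasta,
    read_genbank,
    read_metadata,
    write_catalog,
    write_ensemble,
    write_ensemble_abundances,
    write_profile,
)
from .profiles import build_cohort, compare_sources, order_summary
from .randomize import build_null
from .repeats import K_MAX_DEFAULT, K_MIN_DEFAULT, catalogs_all, scan_all

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the standard protocol:
    repeat lengths 5-30 bp, occurrence counting, 10 shuffle replicates."""

    k_min: int = K_MIN_DEFAULT
    k_max: int = K_MAX_DEFAULT
    convention: str = "occurrence"
    circular: bool = False
    include_self_palindrome: bool = True
    n_replicates: int = 10
    seed: int = 0
    genic_types: Tuple[str, ...] = tuple(sorted(DEFAULT_GENIC_TYPES))
    atypical_sd: float = 2.0
    report_ks: Tuple[int, ...] = (5, 6, 7, 8, 9)
    outdir: str = "mitorepeats_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("genic_types", "report_ks"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genic_types"] = list(d["genic_types"])
        d["report_ks"] = list(d["report_ks"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(
    paths: Sequence, circular_default: bool
) -> Tuple[List[Genome], Dict[str, FeatureTable], Dict[str, str]]:
    genomes: List[Genome] = []
    features: Dict[str, FeatureTable] = {}
    failures: Dict[str, str] = {}
    for p in paths:
        p = Path(p)
        try:
            if p.suffix.lower() in {".gb", ".gbk", ".genbank"}:
                g, ft = read_genbank(p)
                genomes.append(g)
                features[g.id] = ft
            else:
                for g in read_fasta(p):
                    if circular_default and not g.circular:
                        g = Genome(g.id, g.sequence, circular=True,
                                   taxonomy=g.taxonomy)
                    genomes.append(g)
        except Exception as exc:  # isolate per-input failures
            logger.error("failed to read %s: %s", p, exc)
            failures[str(p)] = str(exc)
    return genomes, features, failures


def run_pipeline(
    config: RunConfig,
    inputs: Sequence,
    metadata_path: Optional[str] = None,
) -> Path:
    """Execute the full analysis and write all artifacts under the outdir.

    Per-genome failures are isolated and recorded in the manifest; the run
    only fails outright when no genome can be processed at all.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes, features, failures = _load_inputs(inputs, config.circular)
    report_ks = [k for k in config.report_ks
                 if config.k_min <= k <= config.k_max]

    orders: Dict[str, str] = {}
    if metadata_path:
        meta = read_metadata(metadata_path)
        if "order" in meta.columns:
            orders = dict(zip(meta["genome_id"], meta["order"]))

    outputs: List[Path] = []
    profiles = []
    random_means = {}
    for genome in genomes:
        try:
            logger.info("scanning %s (%d bp)", genome.id, genome.length)
            for catalog in catalogs_all(
                genome, config.k_min, config.k_max, config.convention,
                config.include_self_palindrome,
            ):
                path = outdir / (
                    f"catalog_{genome.id}_k{catalog.k}_{catalog.repeat_type}.tsv"
                )
                write_catalog(catalog, path)
                outputs.append(path)
            prof = scan_all(
                genome, config.k_min, config.k_max, config.convention,
                config.include_self_palindrome,
            )
            ppath = outdir / f"profile_{genome.id}.json"
            write_profile(prof, ppath)
            outputs.append(ppath)
            profiles.append(prof)

            logger.info("building null ensemble for %s", genome.id)
            ens = build_null(
                genome, config.n_replicates, config.seed,
                config.k_min, config.k_max, config.convention,
                config.include_self_palindrome,
            )
            epath = outdir / f"null_{genome.id}.json"
            write_ensemble(ens, epath)
            outputs.append(epath)
            tpath = outdir / f"null_{genome.id}_abundances.tsv"
            write_ensemble_abundances(ens, tpath)
            outputs.append(tpath)
            random_means[genome.id] = ens.mean_profile()

            if genome.id in features:
                ft = features[genome.id]
                mask = build_genic_mask(ft, config.genic_types)
                for k in report_ks:
                    for rtype in ("direct", "inverted"):
                        from .repeats import (find_direct_repeats,
                                              find_inverted_repeats)
                        cat = (find_direct_repeats(genome, k, "occurrence")
                               if rtype == "direct" else
                               find_inverted_repeats(genome, k, "occurrence",
                                   config.include_self_palindrome))
                        mpath = outdir / f"map_{genome.id}_k{k}_{rtype}.tsv"
                        export_map(cat, ft, mpath)
                        outputs.append(mpath)
                        classified = classify_occurrences(cat, mask)
                        if not classified.empty:
                            bias = region_bias(classified, mask)
                            bpath = outdir / (
                                f"bias_{genome.id}_k{k}_{rtype}.json"
                            )
                            bpath.write_text(
                                json.dumps(bias.to_json_dict(), indent=1)
                                + "\n"
                            )
                            outputs.append(bpath)
        except Exception as exc:
            logger.error("genome %s failed: %s", genome.id, exc)
            failures[genome.id] = str(exc)

    if not profiles:
        raise RuntimeError(
            f"all inputs failed: {failures if failures else 'no genomes'}"
        )

    cohort = build_cohort(profiles, random_means, orders)
    cpath = outdir / "cohort.tsv"
    cohort.to_csv(cpath, sep="\t", index=False)
    outputs.append(cpath)

    report = {}
    for k in report_ks:
        for rtype in ("direct", "inverted"):
            try:
                cmp_res = compare_sources(cohort, k, rtype)
                report[f"{rtype}_k{k}"] = cmp_res.to_json_dict()
                for source, e in cmp_res.ecdfs.items():
                    epath = outdir / f"ecdf_{rtype}_k{k}_{source}.tsv"
                    with open(epath, "w") as fh:
                        fh.write("abundance\tcumulative_proportion\n")
                        for v, pr in zip(e.values, e.proportions):
                            fh.write(f"{v:.6g}\t{pr:.6g}\n")
                    outputs.append(epath)
            except (ValueError, KeyError) as exc:
                report[f"{rtype}_k{k}"] = {"error": str(exc)}
    rpath = outdir / "comparison_report.json"
    rpath.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    outputs.append(rpath)

    if orders:
        for k in report_ks:
            for rtype in ("direct", "inverted"):
                table, atyp = order_summary(
                    cohort, k, rtype, config.atypical_sd
                )
                spath = outdir / f"order_summary_{rtype}_k{k}.tsv"
                table.to_csv(spath, sep="\t")
                outputs.append(spath)
                if not atyp.empty:
                    apath = outdir / f"atypical_{rtype}_k{k}.tsv"
                    atyp.to_csv(apath, sep="\t", index=False)
                    outputs.append(apath)
                ipath = outdir / f"itol_{rtype}_k{k}.txt"
                export_tree_annotations(cohort, k, rtype, ipath)
                outputs.append(ipath)

    manifest = {
        "package": "mitorepeats",
        "version": __version__,
        "config": config.to_dict(),
        "n_genomes": len(profiles),
        "failures": failures,
        "files": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(outputs)
        },
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return outdir
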