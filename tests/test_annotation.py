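"""Genic-mask construction, occurrence classification, region bias and the
map / tree-annotation exports."""

import numpy as np
import pandas as pd
import pytest

from mitorepeats import Genome, find_direct_repeats
from mitorepeats.annotation import (
    Feature,
    FeatureTable,
    GENIC,
    NON_GENIC,
    GenicMask,
    build_genic_mask,
    classify_occurrences,
    export_map,
    export_tree_annotations,
    map_intervals,
    read_map,
    region_bias,
)
from mitorepeats.repeats import RepeatCatalog, RepeatOccurrence


def simple_table(length=200, genes=((0, 100),)):
    feats = [Feature("gene", s, e, name=f"gene{i}")
             for i, (s, e) in enumerate(genes)]
    return FeatureTable("g", length, feats)


def catalog_at(positions, k=5, length=200, genome_id="g"):
    return RepeatCatalog(
        genome_id=genome_id, k=k, repeat_type="direct",
        occurrences=[RepeatOccurrence("A" * k, p, k, "direct")
                     for p in sorted(positions)],
        count=len(positions), distinct_kmers=1, convention="occurrence",
    )


class TestGenicMask:
    def test_half_genic(self):
        mask = build_genic_mask(simple_table())
        assert mask.genic_fraction == pytest.approx(0.5)
        assert mask.genic_fraction == pytest.approx(mask.mask.mean())

    def test_no_features_all_nongenic(self):
        mask = build_genic_mask(FeatureTable("g", 200, []))
        assert mask.genic_fraction == 0.0

    def test_overlapping_genes_union(self):
        mask = build_genic_mask(simple_table(genes=((0, 100), (50, 150))))
        assert mask.genic_fraction == pytest.approx(0.75)

    def test_dloop_not_genic(self):
        ft = FeatureTable("g", 200, [Feature("gene", 0, 100),
                                     Feature("D-loop", 100, 200)])
        assert build_genic_mask(ft).genic_fraction == pytest.approx(0.5)

    def test_out_of_bounds_feature_rejected(self):
        ft = FeatureTable("g", 100, [Feature("gene", 50, 150)])
        with pytest.raises(ValueError):
            build_genic_mask(ft)


class TestClassify:
    def test_fully_genic_and_fully_intergenic(self):
        mask = build_genic_mask(simple_table())
        df = classify_occurrences(catalog_at([10, 150]), mask)
        assert list(df["label"]) == [GENIC, NON_GENIC]

    def test_majority_rule_odd_k(self):
        # gene covers [0,100); a 9-mer at 96 has 4 genic bases -> non-genic,
        # at 95 it has 5 genic bases -> genic
        mask = build_genic_mask(simple_table())
        df = classify_occurrences(catalog_at([95, 96], k=9), mask)
        assert list(df["label"]) == [GENIC, NON_GENIC]

    def test_tie_takes_start_base_label(self):
        mask = build_genic_mask(simple_table())
        # k=8 at 96: 4 genic / 4 non-genic; start base 96 is genic
        df = classify_occurrences(catalog_at([96], k=8), mask)
        assert list(df["label"]) == [GENIC]

    def test_every_occurrence_labelled(self, rng):
        mask = build_genic_mask(simple_table())
        positions = rng.integers(0, 195, size=50)
        df = classify_occurrences(catalog_at(sorted(set(positions))), mask)
        assert set(df["label"]) <= {GENIC, NON_GENIC}
        assert len(df) == len(set(positions))

    def test_length_mismatch_rejected(self):
        mask = build_genic_mask(simple_table(length=50, genes=((0, 10),)))
        with pytest.raises(ValueError):
            classify_occurrences(catalog_at([150]), mask)


class TestRegionBias:
    def test_all_genic_enrichment_two(self):
        mask = build_genic_mask(simple_table())
        df = classify_occurrences(catalog_at([0, 20, 40]), mask)
        bias = region_bias(df, mask)
        assert bias.enrichment == pytest.approx(2.0)
        assert bias.n_genic == 3 and bias.n_nongenic == 0

    def test_all_nongenic_enrichment_zero(self):
        mask = build_genic_mask(simple_table())
        df = classify_occurrences(catalog_at([120, 140]), mask)
        assert region_bias(df, mask).enrichment == pytest.approx(0.0)

    def test_uniform_placement_enrichment_near_one(self):
        mask = build_genic_mask(simple_table())
        df = classify_occurrences(
            catalog_at(range(0, 191, 2)), mask
        )
        bias = region_bias(df, mask)
        assert bias.enrichment == pytest.approx(1.0, abs=0.1)
        assert bias.p_value > 0.05

    def test_uniform_sampling_converges_to_one(self, rng):
        mask = build_genic_mask(simple_table(length=1000,
                                             genes=((0, 500),)))
        enrichments = []
        for n in (50, 500, 5000):
            pos = sorted(set(rng.integers(0, 995, size=n).tolist()))
            df = classify_occurrences(catalog_at(pos, length=1000), mask)
            enrichments.append(abs(region_bias(df, mask).enrichment - 1))
        assert enrichments[-1] < 0.1

    def test_empty_rejected(self):
        mask = build_genic_mask(simple_table())
        with pytest.raises(ValueError):
            region_bias(pd.DataFrame(columns=["label"]), mask)


class TestExports:
    def test_map_coordinates_one_based_inclusive(self, tmp_path):
        path = tmp_path / "map.tsv"
        export_map(catalog_at([0, 5]), simple_table(), path)
        df = read_map(path)
        rep = df[df["track"] == "repeat"]
        assert list(rep["start_1based"]) == [1, 6]
        assert list(rep["end_1based"]) == [5, 10]

    def test_empty_catalog_header_only(self, tmp_path):
        path = tmp_path / "map.tsv"
        export_map(catalog_at([]), None, path)
        df = read_map(path)
        assert df.empty

    def test_round_trip_intervals(self, tmp_path):
        cat = catalog_at([3, 17, 60], k=7)
        path = tmp_path / "map.tsv"
        export_map(cat, simple_table(), path)
        got = map_intervals(read_map(path))
        assert got == [(p, p + 7) for p in (3, 17, 60)]

    def test_tree_annotation_file(self, tmp_path):
        from mitorepeats import ProfileMatrix, build_cohort

        profs = [
            ProfileMatrix.from_counts(g, 10000, "occurrence",
                                      {9: {"direct": c, "inverted": 0}})
            for g, c in (("b", 500), ("a", 1000), ("c", 0))
        ]
        cohort = build_cohort(profs)
        path = tmp_path / "itol.txt"
        export_tree_annotations(cohort, 9, "direct", path)
        lines = path.read_text().strip().splitlines()
        data = lines[lines.index("DATA") + 1:]
        assert data == ["a,100", "b,50", "c,0"]

    def test_tree_annotation_sort_invariance(self, tmp_path):
        from mitorepeats import ProfileMatrix, build_cohort

        profs = [
            ProfileMatrix.from_counts(g, 10000, "occurrence",
                                      {9: {"direct": c, "inverted": 0}})
            for g, c in (("b", 500), ("a", 1000))
        ]
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        export_tree_annotations(build_cohort(profs), 9, "direct", p1)
        export_tree_annotations(build_cohort(profs[::-1]), 9, "direct", p2)
        assert p1.read_text() == p2.read_text()
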