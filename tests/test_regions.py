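import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolsweep.regions import (
    GeneModel,
    Region,
    annotate_regions,
    call_window_outliers,
    cross_method_common,
    hypergeometric_enrichment,
    merge_top_positions,
    read_gene_models,
    shared_across_comparisons,
)

from oracles import brute_hypergeom_p


def track_of(values, chrom="1"):
    n = len(values)
    mids = np.arange(1, n + 1) * 10_000
    return pd.DataFrame(
        {"chrom": chrom, "start_pos": mids - 500, "end_pos": mids + 500,
         "mid_pos": mids, "n_snps": 625, "stat": "fst", "value": values}
    )


def positions_frame(pos, chrom="1"):
    return pd.DataFrame({"chrom": chrom, "mid_pos": pos})


class TestOutlierCalling:
    def test_exact_count_without_ties(self):
        rng = np.random.default_rng(0)
        track = track_of(rng.permutation(10_000).astype(float))
        tops = call_window_outliers(track, "upper", 0.001)
        assert len(tops) == 10
        assert set(tops["value"]) == set(range(9_990, 10_000))

    def test_lower_tail(self):
        rng = np.random.default_rng(1)
        track = track_of(rng.permutation(5_000).astype(float))
        tops = call_window_outliers(track, "lower", 0.001)
        assert len(tops) == 5 and tops["value"].max() == 4

    def test_all_tied_returns_all_with_warning(self):
        track = track_of(np.full(100, 0.5))
        with pytest.warns(UserWarning):
            tops = call_window_outliers(track, "upper", 0.001)
        assert len(tops) == 100

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            call_window_outliers(track_of([]), "upper")


class TestMerging:
    def test_worked_example(self):
        regs = merge_top_positions(positions_frame([1_000_000, 1_050_000, 1_300_000]))
        assert len(regs) == 2
        assert (regs[0].left, regs[0].right) == (1_000_000, 1_050_000)
        assert (regs[1].left, regs[1].right) == (1_300_000, 1_300_000)

    def test_boundary_gap_merges(self):
        regs = merge_top_positions(positions_frame([100_000, 200_000]))
        assert len(regs) == 1  # gap of exactly 100 kb still merges

    def test_single_position(self):
        regs = merge_top_positions(positions_frame([42]))
        assert len(regs) == 1 and regs[0].left == regs[0].right == 42

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(min_value=1, max_value=10_000_000), min_size=1,
                 max_size=60, unique=True)
    )
    def test_partition_and_idempotence(self, pos):
        frame = positions_frame(sorted(pos))
        regs = merge_top_positions(frame)
        merged = sorted(p for r in regs for p in r.top_positions)
        assert merged == sorted(pos)  # partition: nothing lost or duplicated
        again = merge_top_positions(
            pd.concat([positions_frame(r.top_positions) for r in regs])
        )
        assert [(r.left, r.right) for r in again] == [(r.left, r.right) for r in regs]


class TestAnnotation:
    genes = [
        GeneModel("inside_flank", "1", 960_000, 970_000),
        GeneModel("too_far_left", "1", 900_000, 940_000),
        GeneModel("other_chrom", "2", 1_000_000, 1_010_000),
    ]

    def test_flank_overlap_rules(self):
        region = Region("1", 1_000_000, 1_050_000, [1_000_000, 1_050_000])
        [annotated] = annotate_regions([region], self.genes, flank=50_000)
        assert annotated.genes == ["inside_flank"]

    def test_zero_flank_abutting_excluded(self):
        region = Region("1", 1_000, 2_000, [1_000])
        gene = GeneModel("abut", "1", 2_001, 3_000)
        [annotated] = annotate_regions([region], [gene], flank=0)
        assert annotated.genes == []

    def test_missing_chromosome_warns(self):
        region = Region("9", 100, 200, [100])
        with pytest.warns(UserWarning, match="absent"):
            [annotated] = annotate_regions([region], self.genes)
        assert annotated.genes == []

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(3)
        genes = [
            GeneModel(f"g{k}", str(rng.integers(1, 4)), int(s), int(s + rng.integers(1, 50_000)))
            for k, s in enumerate(rng.integers(1, 5_000_000, size=300))
        ]
        regions = [
            Region(str(rng.integers(1, 4)), int(p), int(p + rng.integers(0, 200_000)), [int(p)])
            for p in rng.integers(1, 5_000_000, size=50)
        ]
        flank = 50_000
        annotated = annotate_regions(regions, genes, flank)
        for r in annotated:
            expected = sorted(
                g.gene_id for g in genes
                if g.chrom == r.chrom
                and g.start <= r.right + flank
                and g.end >= max(1, r.left - flank)
            )
            assert sorted(r.genes) == expected

    def test_gff3_reading(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=geneA;Name=alpha\n"
            "1\tsrc\tmRNA\t1000\t2000\t.\t+\t.\tID=geneA.t1;Parent=geneA\n"
            "2\tsrc\tgene\t500\t800\t.\t-\t.\tID=geneB\n"
        )
        genes = read_gene_models(str(gff))
        assert [(g.gene_id, g.chrom, g.start, g.end) for g in genes] == [
            ("geneA", "1", 1000, 2000),
            ("geneB", "2", 500, 800),
        ]


class TestCrossMethod:
    def test_common_signal_instance(self):
        # window mid 24.42 Mb vs marker 24.39 Mb: 30 kb <= 50 kb -> common
        win = pd.DataFrame({"chrom": ["Oni06"], "mid_pos": [24_420_000]})
        mark = pd.DataFrame({"chrom": ["Oni06"], "pos": [24_390_000]})
        common = cross_method_common(win, mark)
        assert len(common) == 1 and common["distance"].iloc[0] == 30_000

    def test_boundary_inclusive(self):
        win = pd.DataFrame({"chrom": ["1"], "mid_pos": [1_000_000]})
        mark = pd.DataFrame({"chrom": ["1"], "pos": [1_050_000]})
        assert len(cross_method_common(win, mark)) == 1

    def test_different_chromosomes_never_common(self):
        win = pd.DataFrame({"chrom": ["1"], "mid_pos": [1_000_000]})
        mark = pd.DataFrame({"chrom": ["2"], "pos": [1_000_000]})
        assert len(cross_method_common(win, mark)) == 0


class TestSharedAcrossComparisons:
    def region(self, left, right, chrom="1"):
        return Region(chrom, left, right, [left])

    def test_supported_by_four_of_five(self):
        sets = {f"cmp{k}": [self.region(1_000_000, 1_100_000)] for k in range(4)}
        sets["cmp4"] = [self.region(9_000_000, 9_100_000)]
        out = shared_across_comparisons(sets, min_comparisons=2)
        assert len(out) == 1
        assert out[0].comparisons == [f"cmp{k}" for k in range(4)]

    def test_chain_components(self):
        sets = {
            "A": [self.region(1_000_000, 1_200_000)],
            "B": [self.region(1_250_000, 1_400_000)],  # overlaps A only via flank
            "C": [self.region(1_450_000, 1_600_000)],  # overlaps B only via flank
        }
        out = shared_across_comparisons(sets, min_comparisons=2)
        assert len(out) == 1 and out[0].comparisons == ["A", "B", "C"]
        assert (out[0].left, out[0].right) == (1_000_000, 1_600_000)

    def test_min_comparisons_not_met(self):
        sets = {f"cmp{k}": [self.region(1_000_000, 1_100_000)] for k in range(4)}
        assert shared_across_comparisons(sets, min_comparisons=5) == []


class TestEnrichment:
    def test_query_equals_universe(self):
        mapping = {f"g{k}": {"T1" if k < 5 else "T2"} for k in range(10)}
        df = hypergeometric_enrichment(set(mapping), mapping)
        assert (df["p"] == 1.0).all()

    def test_closed_form_term(self):
        # N=100, K=10, n=10, k=10: p = 1/C(100,10)
        mapping = {f"g{k}": ({"T"} if k < 10 else {"other"}) for k in range(100)}
        query = {f"g{k}" for k in range(10)}
        df = hypergeometric_enrichment(query, mapping).set_index("term")
        assert df.loc["T", "p"] == pytest.approx(brute_hypergeom_p(100, 10, 10, 10), rel=1e-9)

    def test_min_count_rule(self):
        mapping = {f"g{k}": ({"T"} if k == 0 else {"other"}) for k in range(50)}
        df = hypergeometric_enrichment({"g0"}, mapping).set_index("term")
        assert df.loc["T", "overlap"] == 1
        assert not df.loc["T", "enriched"]  # needs > 1 gene regardless of p

    def test_pvalues_super_uniform_under_random_query(self):
        rng = np.random.default_rng(4)
        genes = [f"g{k}" for k in range(200)]
        mapping = {g: {f"T{rng.integers(0, 20)}"} for g in genes}
        hits = total = 0
        for _ in range(300):
            query = set(rng.choice(genes, size=15, replace=False))
            df = hypergeometric_enrichment(query, mapping)
            hits += int((df["p"] < 0.05).sum())
            total += len(df)
        frac = hits / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert frac <= 0.05 + 3 * se

    def test_empty_query(self):
        assert len(hypergeometric_enrichment(set(), {"g": {"T"}})) == 0
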