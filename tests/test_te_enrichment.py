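"""Flank windows, coverage, the permutation null and the Mann-Whitney test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from far_expand.io_annotations import GeneRecord, GenomicInterval, ScaffoldIndex, TERecord
from far_expand.te_enrichment import (
    UndefinedDensityError,
    flank_windows,
    group_mean_density,
    mann_whitney_u,
    merge_intervals,
    permutation_test,
    te_density,
)


def brute_force_covered_bp(gene, tes, w, index):
    """Per-base boolean-array coverage count over the clipped flanks."""
    length = index[gene.interval.scaffold]
    mask = np.zeros(length, dtype=bool)
    for te in tes:
        if te.interval.scaffold == gene.interval.scaffold:
            mask[te.interval.start : te.interval.end] = True
    up = mask[max(0, gene.interval.start - w) : gene.interval.start]
    down = mask[gene.interval.end : min(length, gene.interval.end + w)]
    return int(up.sum() + down.sum()), len(up) + len(down)


def pair_count_u(x, y):
    """O(n1*n2) Mann-Whitney U oracle."""
    return sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in x for yj in y)


class TestFlankWindows:
    def test_interior_gene_has_two_full_windows(self, example_gene, scaffold_index):
        fw = flank_windows(example_gene, 10_000, scaffold_index)
        assert [(w.start, w.end) for w in fw.windows] == [(40_000, 50_000), (51_000, 61_000)]
        assert fw.total_len == 20_000

    def test_gene_near_scaffold_start_clips_upstream(self, scaffold_index):
        gene = GeneRecord("g", GenomicInterval("scaf1", 2_000, 3_000))
        fw = flank_windows(gene, 10_000, scaffold_index)
        assert (fw.windows[0].start, fw.windows[0].end) == (0, 2_000)
        assert fw.total_len == 12_000

    def test_gene_spanning_whole_scaffold_has_no_flanks(self):
        index = ScaffoldIndex({"s": 5_000})
        gene = GeneRecord("g", GenomicInterval("s", 0, 5_000))
        assert flank_windows(gene, 10_000, index).total_len == 0

    def test_unknown_scaffold_raises(self, example_gene):
        with pytest.raises(KeyError):
            flank_windows(example_gene, 10_000, ScaffoldIndex({"other": 10}))


class TestMergeIntervals:
    @pytest.mark.parametrize(
        "spans,expected",
        [
            ([(45_000, 47_000), (46_000, 48_000)], [(45_000, 48_000)]),
            ([(10, 20), (20, 30)], [(10, 30)]),
            ([], []),
            ([(5, 8), (1, 2)], [(1, 2), (5, 8)]),
        ],
    )
    def test_examples(self, spans, expected):
        intervals = [GenomicInterval("s", a, b) for a, b in spans]
        assert [(iv.start, iv.end) for iv in merge_intervals(intervals)] == expected

    def test_rejects_mixed_scaffolds(self):
        with pytest.raises(ValueError):
            merge_intervals([GenomicInterval("a", 0, 1), GenomicInterval("b", 0, 1)])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)), max_size=30))
    def test_union_of_bases_preserved_and_disjoint(self, spans):
        intervals = [GenomicInterval("s", a, a + l) for a, l in spans]
        merged = merge_intervals(intervals)
        mask = np.zeros(600, dtype=bool)
        for iv in intervals:
            mask[iv.start : iv.end] = True
        merged_mask = np.zeros(600, dtype=bool)
        for iv in merged:
            assert not merged_mask[iv.start : iv.end].any()  # pairwise disjoint
            merged_mask[iv.start : iv.end] = True
        assert (mask == merged_mask).all()
        starts = [iv.start for iv in merged]
        assert starts == sorted(starts)


class TestTeDensity:
    def test_overlapping_tes_counted_once(self, example_gene, example_tes, scaffold_index):
        rec = te_density(example_gene, example_tes, 10_000, scaffold_index)
        assert (rec.covered_bp, rec.total_bp) == (5_000, 20_000)
        assert rec.density == 0.25

    def test_no_tes_gives_zero(self, example_gene, scaffold_index):
        assert te_density(example_gene, [], 10_000, scaffold_index).density == 0.0

    def test_te_covering_both_windows_gives_one(self, example_gene, scaffold_index):
        blanket = [TERecord(GenomicInterval("scaf1", 30_000, 70_000))]
        assert te_density(example_gene, blanket, 10_000, scaffold_index).density == 1.0

    def test_category_restricts_to_matching_records(
        self, example_gene, example_tes, scaffold_index
    ):
        rec = te_density(example_gene, example_tes, 10_000, scaffold_index, category="II")
        assert rec.covered_bp == 2_000  # only the DNA element downstream

    def test_zero_flank_raises_undefined_density(self):
        index = ScaffoldIndex({"s": 1_000})
        gene = GeneRecord("g", GenomicInterval("s", 0, 1_000))
        with pytest.raises(UndefinedDensityError):
            te_density(gene, [], 10_000, index)

    def test_matches_per_base_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            n_scaf = rng.integers(1, 4)
            index = ScaffoldIndex({f"s{i}": int(rng.integers(200, 2_000)) for i in range(n_scaf)})
            scafs = list(index.lengths)
            tes = []
            for _ in range(rng.integers(0, 50)):
                s = scafs[rng.integers(len(scafs))]
                start = int(rng.integers(0, index[s] - 1))
                end = int(rng.integers(start + 1, min(index[s], start + 200) + 1))
                tes.append(TERecord(GenomicInterval(s, start, end)))
            s = scafs[rng.integers(len(scafs))]
            gstart = int(rng.integers(0, index[s] - 10))
            gene = GeneRecord("g", GenomicInterval(s, gstart, gstart + 10))
            w = int(rng.integers(10, 400))
            expected_cov, expected_total = brute_force_covered_bp(gene, tes, w, index)
            if expected_total == 0:
                continue
            rec = te_density(gene, tes, w, index)
            assert (rec.covered_bp, rec.total_bp) == (expected_cov, expected_total)

    def test_adding_te_inside_flank_never_decreases_density(
        self, example_gene, example_tes, scaffold_index
    ):
        base = te_density(example_gene, example_tes, 10_000, scaffold_index).density
        extra = example_tes + [TERecord(GenomicInterval("scaf1", 42_000, 42_500))]
        assert te_density(example_gene, extra, 10_000, scaffold_index).density >= base


class TestGroupMean:
    def test_mean_and_singleton(self):
        recs = [
            te_density_record("a", "FAR-A", 2_000, 10_000),
            te_density_record("b", "FAR-A", 4_000, 10_000),
            te_density_record("c", "non-FAR-A", 7_000, 10_000),
        ]
        assert group_mean_density(recs, "FAR-A") == pytest.approx(0.3)
        assert group_mean_density(recs, "non-FAR-A") == pytest.approx(0.7)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            group_mean_density([], "FAR-A")


def te_density_record(gene_id, group, covered, total):
    from far_expand.te_enrichment import DensityRecord

    return DensityRecord(gene_id, group, "all", covered, total)


def _uniform_genome(densities, index_len=100_000):
    """One gene per 30 kb slot whose flank coverage equals the given density."""
    index = ScaffoldIndex({"s": 30_000 * len(densities)})
    genes, tes = [], []
    for i, d in enumerate(densities):
        start = 30_000 * i + 11_000
        genes.append(GeneRecord(f"g{i}", GenomicInterval("s", start, start + 1_000)))
        covered = int(d * 10_000)
        if covered:
            # fill the start of each flank window
            tes.append(TERecord(GenomicInterval("s", start - 10_000, start - 10_000 + covered)))
            tes.append(TERecord(GenomicInterval("s", start + 1_000, start + 1_000 + covered)))
    return index, genes, tes


class TestPermutationTest:
    def test_focal_equal_to_pool_gives_p_one(self):
        index, genes, tes = _uniform_genome([0.1, 0.4, 0.7, 0.9])
        result = permutation_test(genes, genes, tes, 10_000, index, n_perm=200, seed=1)
        assert result.n_ge == result.n_perm
        assert result.p_empirical == 1.0

    def test_extreme_focal_pair_matches_hypergeometric_rate(self):
        # 2 focal genes at density 1.0 in a pool of 20 (18 at 0.0): a replicate
        # ties the observed mean only when it redraws both focal genes,
        # probability (2/20)(1/19) = 1/190.
        densities = [1.0, 1.0] + [0.0] * 18
        index, genes, tes = _uniform_genome(densities)
        result = permutation_test(genes[:2], genes, tes, 10_000, index, n_perm=1000, seed=7)
        assert result.p_empirical == (result.n_ge + 1) / 1001
        # n_ge ~ Binomial(1000, 1/190): mean 5.3, sd 2.3; allow 5 sd
        assert 0 <= result.n_ge <= 17

    def test_reproducible_and_invariant_to_pool_order(self):
        index, genes, tes = _uniform_genome([0.1, 0.2, 0.5, 0.6, 0.8, 0.3])
        focal = genes[:2]
        a = permutation_test(focal, genes, tes, 10_000, index, n_perm=300, seed=9)
        b = permutation_test(focal, genes, tes, 10_000, index, n_perm=300, seed=9)
        c = permutation_test(focal, list(reversed(genes)), tes, 10_000, index, n_perm=300, seed=9)
        assert a == b
        assert a.p_empirical == c.p_empirical

    def test_empirical_p_uniform_under_exchangeability(self):
        """When focal genes are drawn from the same coverage law as the pool,
        the empirical p-value is approximately uniform on (0, 1]."""
        from far_expand.synthetic_data import SimulationConfig, null_config, simulate_genome_with_tes

        pvals = []
        for run in range(400):
            config = null_config(
                SimulationConfig(seed=5_000 + run, n_genes=80, n_focal=8, n_nonfocal=0,
                                 n_scaffolds=4)
            )
            genome = simulate_genome_with_tes(config)
            result = permutation_test(
                genome.focal, genome.genes, genome.tes, config.flank_w, genome.index,
                n_perm=99, seed=9_000 + run,
            )
            pvals.append(result.p_empirical)
        pvals = np.sort(pvals)
        grid = np.arange(1, len(pvals) + 1) / len(pvals)
        ks = np.max(np.abs(pvals - grid))
        # KS sampling error ~1.36/sqrt(400)=0.068 at the 5% level, plus 1/100
        # granularity of the 99-permutation p grid
        assert ks < 0.09

    def test_pool_smaller_than_focal_rejected(self):
        index, genes, tes = _uniform_genome([0.1, 0.2])
        with pytest.raises(ValueError):
            permutation_test(genes, genes[:1], tes, 10_000, index, n_perm=10, seed=0)

    def test_exclude_focal_shrinks_pool(self):
        index, genes, tes = _uniform_genome([0.9, 0.8, 0.1, 0.2, 0.3, 0.15])
        result = permutation_test(
            genes[:2], genes, tes, 10_000, index, n_perm=100, seed=0, exclude_focal=True
        )
        assert result.n_pool == 4


class TestMannWhitney:
    def test_fully_separated_samples_give_u_zero(self):
        assert mann_whitney_u([1, 2], [3, 4]).u_statistic == 0.0

    def test_identical_samples_give_half_of_n1_n2(self):
        result = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert result.u_statistic == pytest.approx(4.5)
        assert result.method == "normal_tie_corrected"  # ties force the normal path

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_u_matches_pair_count_oracle_and_complements(self):
        rng = np.random.default_rng(3)
        for _ in range(80):
            n1, n2 = rng.integers(1, 13, size=2)
            x = rng.integers(0, 8, size=n1).astype(float)  # many ties
            y = rng.integers(0, 8, size=n2).astype(float)
            ux = mann_whitney_u(x, y).u_statistic
            uy = mann_whitney_u(y, x).u_statistic
            assert ux == pytest.approx(pair_count_u(x, y))
            assert ux + uy == pytest.approx(n1 * n2)

    def test_exact_small_sample_p_matches_scipy_exact(self):
        x = [1.2, 3.4, 5.1]
        y = [0.3, 2.2, 4.0, 6.5]
        result = mann_whitney_u(x, y)
        assert result.method == "exact"
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert result.p_value == pytest.approx(ref.pvalue)

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = rng.normal(0.5, size=30)
        result = mann_whitney_u(x, y)
        assert result.method == "normal_tie_corrected"
        ref = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert result.p_value == pytest.approx(ref.pvalue)

    def test_exact_method_refuses_ties(self):
        with pytest.raises(ValueError, match="ties"):
            mann_whitney_u([1, 1], [1, 2], method="exact")
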