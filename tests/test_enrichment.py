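import math
import subprocess

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import comb

from microdna.enrichment import (
    flank_enrichment,
    fold_enrichment,
    observed_counts,
    shuffle_intervals,
)
from microdna.intervals import GenomicInterval, IntervalIndex

from conftest import make_cluster


def half_covered_toy():
    """Single 100 kb chromosome with features covering exactly 50%."""
    feats = [GenomicInterval("chr1", i * 200, i * 200 + 100)
             for i in range(500)]
    return {"chr1": 100_000}, IntervalIndex(feats)


def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by hypergeometric enumeration: sum the
    probabilities of all tables (fixed margins) no more likely than the
    observed one."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    def prob(x):
        return (comb(row1, x, exact=True) * comb(row2, col1 - x, exact=True)
                / comb(n, col1, exact=True))
    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestShuffleNull:
    def test_whole_genome_category_saturates(self):
        sizes = {"chr1": 10_000}
        cat = IntervalIndex([GenomicInterval("chr1", 0, 10_000)])
        clusters = [make_cluster("chr1", i * 100, i * 100 + 50, f"s{i}")
                    for i in range(20)]
        null = shuffle_intervals(clusters, sizes, {"all": cat}, n=50, seed=1)
        assert (null.counts["all"] == 20).all()
        assert null.expected["all"] == 20

    def test_binomial_expectation_on_half_covered_genome(self):
        sizes, idx = half_covered_toy()
        rng = np.random.default_rng(5)
        clusters = [make_cluster("chr1", int(p), int(p) + 1, f"s{i}")
                    for i, p in enumerate(rng.integers(0, 99_999, 200))]
        null = shuffle_intervals(clusters, sizes, {"cat": idx}, n=1000, seed=2)
        se = math.sqrt(200 * 0.25)
        assert abs(null.expected["cat"] - 100) <= 3 * se

    def test_seeded_determinism(self):
        sizes, idx = half_covered_toy()
        clusters = [make_cluster("chr1", 100, 400)]
        a = shuffle_intervals(clusters, sizes, {"cat": idx}, n=100, seed=9)
        b = shuffle_intervals(clusters, sizes, {"cat": idx}, n=100, seed=9)
        assert (a.counts["cat"] == b.counts["cat"]).all()

    def test_oversized_cluster_raises(self):
        with pytest.raises(ValueError, match="longer than every chromosome"):
            shuffle_intervals(
                [make_cluster("chr1", 0, 2_000)], {"chr1": 1_000}, {}, n=1
            )

    def test_median_stability_when_doubling_iterations(self):
        sizes, idx = half_covered_toy()
        rng = np.random.default_rng(6)
        clusters = [make_cluster("chr1", int(p), int(p) + 200, f"s{i}")
                    for i, p in enumerate(rng.integers(0, 99_000, 300))]
        e1 = shuffle_intervals(clusters, sizes, {"cat": idx},
                               n=1000, seed=3).expected["cat"]
        e2 = shuffle_intervals(clusters, sizes, {"cat": idx},
                               n=2000, seed=3).expected["cat"]
        assert abs(e2 - e1) / e1 < 0.02

    def test_observed_counts_match_bedtools_intersect(self, tmp_path):
        # independent oracle: bedtools intersect -u on the same intervals
        sizes, idx = half_covered_toy()
        rng = np.random.default_rng(7)
        clusters = [make_cluster("chr1", int(p), int(p) + 150, f"s{i}")
                    for i, p in enumerate(rng.integers(0, 99_000, 50))]
        a = tmp_path / "clusters.bed"
        b = tmp_path / "feats.bed"
        a.write_text("".join(
            f"chr1\t{c.interval.start}\t{c.interval.end}\n" for c in clusters
        ))
        b.write_text("".join(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\n" for iv in idx
        ))
        out = subprocess.run(
            ["bedtools", "intersect", "-u", "-a", str(a), "-b", str(b)],
            capture_output=True, text=True, check=True,
        )
        n_bedtools = len(out.stdout.splitlines())
        assert observed_counts(clusters, {"cat": idx})["cat"] == n_bedtools


class TestFoldEnrichment:
    def _null(self, expected, total):
        from microdna.enrichment import ShuffleNull
        return ShuffleNull(11, 0, {"cat": np.full(11, expected)},
                           n_clusters=total)

    def test_identity_fold(self):
        r = fold_enrichment(10, self._null(10, 100), "cat")
        assert r.fold == 1.0 and r.p_value > 0.99

    def test_fisher_matches_enumeration_oracle(self):
        r = fold_enrichment(10, self._null(5, 100), "cat")
        want = fisher_two_sided_oracle(10, 90, 5, 95)
        assert r.p_value == pytest.approx(want, rel=1e-9)
        assert r.p_value == pytest.approx(0.2827638, abs=1e-6)

    def test_zero_expected_cases(self):
        r = fold_enrichment(3, self._null(0, 100), "cat")
        assert math.isinf(r.fold)
        r0 = fold_enrichment(0, self._null(0, 100), "cat")
        assert math.isnan(r0.fold) and r0.p_value == 1.0

    def test_unbiased_clusters_have_fold_near_one(self):
        sizes, idx = half_covered_toy()
        rng = np.random.default_rng(8)
        starts = rng.integers(0, 99_900, 2_000)
        clusters = [make_cluster("chr1", int(s), int(s) + 100, f"s{i}")
                    for i, s in enumerate(starts)]
        null = shuffle_intervals(clusters, sizes, {"cat": idx}, n=300, seed=4)
        obs = observed_counts(clusters, {"cat": idx})["cat"]
        r = fold_enrichment(obs, null, "cat")
        assert 0.9 <= r.fold <= 1.1


class TestFlankEnrichment:
    def test_features_only_inside_regions_closed_form(self):
        sizes = {"chr1": 1_000_000}
        regions = [GenomicInterval("chr1", 20_000 + i * 30_000,
                                   21_000 + i * 30_000) for i in range(20)]
        feats = IntervalIndex([
            GenomicInterval("chr1", r.start + 100, r.start + 200)
            for r in regions
        ])
        r = flank_enrichment(regions, feats, sizes)
        # oracle: two-sided binomial by pmf enumeration
        pmf = [sps.binom.pmf(k, 20, 1 / 3) for k in range(21)]
        want = sum(p for p in pmf if p <= pmf[20] * (1 + 1e-9))
        assert r.p_value == pytest.approx(want, rel=1e-9)
        assert r.p_value == pytest.approx((1 / 3) ** 20, rel=1e-6)

    def test_uniform_features_not_significant(self):
        sizes = {"chr1": 1_000_000}
        rng = np.random.default_rng(10)
        feats = IntervalIndex([
            GenomicInterval("chr1", int(s), int(s) + 100)
            for s in rng.integers(0, 999_000, 2_000)
        ])
        regions = [GenomicInterval("chr1", 20_000 + i * 30_000,
                                   22_000 + i * 30_000) for i in range(30)]
        r = flank_enrichment(regions, feats, sizes)
        assert 0.6 <= r.fold <= 1.4
        assert r.p_value > 0.01

    def test_region_at_chromosome_start_clips_flank(self):
        sizes = {"chr1": 100_000}
        regions = [GenomicInterval("chr1", 0, 1_000)]
        feats = IntervalIndex([GenomicInterval("chr1", 100, 200)])
        r = flank_enrichment(regions, feats, sizes)
        assert r.observed == 1


class TestNullCalibration:
    def test_fisher_pvalues_calibrated_under_uniform_generator(self, toy):
        # unbiased placement: across 100 replicates no category should be
        # called significant at 0.05 in more than 7% of replicates
        _, _, bundle = toy
        cats = {
            "genic": bundle.genes, "exonic": bundle.exons,
            "intronic": bundle.introns, "promoter": bundle.promoters,
            "active": bundle.open_chromatin,
        }
        sizes = bundle.chrom_sizes
        chroms = list(sizes)
        rng = np.random.default_rng(77)
        hits = {cat: 0 for cat in cats}
        n_reps = 100
        for rep in range(n_reps):
            clusters = []
            for i in range(150):
                L = int(rng.integers(100, 500))
                chrom = chroms[int(rng.integers(len(chroms)))]
                s = int(rng.integers(0, sizes[chrom] - L))
                clusters.append(make_cluster(chrom, s, s + L, f"s{i}"))
            null = shuffle_intervals(clusters, sizes, cats, n=200,
                                     seed=1000 + rep)
            obs = observed_counts(clusters, cats)
            for cat in cats:
                if fold_enrichment(obs[cat], null, cat).p_value < 0.05:
                    hits[cat] += 1
        for cat, h in hits.items():
            assert h / n_reps <= 0.07, (cat, h)

    def test_open_bias_raises_active_fold(self, toy):
        _, _, bundle = toy
        from microdna.samples import SampleMeta
        from microdna.synthetic import CircleModel, simulate_circles
        sizes = bundle.chrom_sizes
        cats = {"active": bundle.open_chromatin}
        folds = []
        for bias in (1.0, 6.0):
            model = CircleModel(open_chromatin_bias=bias, exon_bias=1.0,
                                promoter_bias=1.0, n_circles_base=600,
                                seed=55)
            circles = simulate_circles(
                bundle, model, [SampleMeta("x", "MTX", "R", "NT")]
            )
            clusters = [make_cluster(c.interval.chrom, c.interval.start,
                                     c.interval.end, "x") for c in circles]
            null = shuffle_intervals(clusters, sizes, cats, n=300, seed=56)
            obs = observed_counts(clusters, cats)["active"]
            folds.append(fold_enrichment(obs, null, "active").fold)
        assert folds[1] > folds[0]
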