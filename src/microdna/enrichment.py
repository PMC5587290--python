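"""Non-randomness tests for microDNA loci.

Two complementary nulls:

* a shuffle null — every cluster is re-placed uniformly at random
  genome-wide with its length preserved, 1000 times; the per-category
  median overlap count is the expected value, fold = observed/expected,
  significance by two-sided Fisher's exact test;
* a flank null — features overlapping the regions of interest are compared
  with features overlapping same-sized windows 5 kb up- and downstream,
  with a binomial test (expected share 1/3: one region window against two
  flank windows of the same size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .intervals import GenomicInterval, IntervalIndex
from .junctions import MicroDNACluster

logger = logging.getLogger(__name__)


@dataclass
class ShuffleNull:
    n_iterations: int
    seed: int
    counts: dict[str, np.ndarray]       # per category: count per iteration
    expected: dict[str, float] = field(init=False)
    n_clusters: int = 0

    def __post_init__(self) -> None:
        self.expected = {
            cat: float(np.median(arr)) for cat, arr in self.counts.items()
        }


@dataclass
class EnrichmentResult:
    category: str
    observed: float
    expected: float
    fold: float          # observed/expected; inf when expected == 0 < observed
    p_value: float
    test: str            # "fisher" or "binomial"


def shuffle_intervals(
    clusters: Sequence[MicroDNACluster],
    chrom_sizes: Mapping[str, int],
    categories: Mapping[str, IntervalIndex],
    n: int = 1000,
    seed: int = 0,
) -> ShuffleNull:
    """Length-preserving uniform re-placement null.

    Each iteration re-places every cluster uniformly over all placeable
    positions genome-wide (chromosome chosen proportionally to
    length - cluster_length + 1, offset uniform) and records how many
    shuffled clusters overlap each category by >= 1 bp.
    """
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    lengths = np.array([c.interval.length for c in clusters], dtype=np.int64)
    max_size = sizes.max() if len(sizes) else 0
    for c in clusters:
        if c.interval.length > max_size:
            raise ValueError(
                f"cluster {c.interval.chrom}:{c.interval.start}-"
                f"{c.interval.end} is longer than every chromosome"
            )
    rng = np.random.default_rng(seed)
    counts = {cat: np.zeros(n, dtype=np.int64) for cat in categories}
    m = len(clusters)
    for it in range(n):
        placeable = np.maximum(sizes[None, :] - lengths[:, None] + 1, 0)
        probs = placeable / placeable.sum(axis=1, keepdims=True)
        cum = np.cumsum(probs, axis=1)
        u = rng.random(m)
        chrom_idx = (u[:, None] > cum).sum(axis=1)
        offs_max = placeable[np.arange(m), chrom_idx]
        starts = (rng.random(m) * offs_max).astype(np.int64)
        ends = starts + lengths
        for cat, idx in categories.items():
            hit = np.zeros(m, dtype=bool)
            for ci, chrom in enumerate(chroms):
                sel = chrom_idx == ci
                if sel.any():
                    hit[sel] = idx.overlaps_any_vec(chrom, starts[sel], ends[sel])
            counts[cat][it] = int(hit.sum())
    return ShuffleNull(n, seed, counts, n_clusters=m)


def observed_counts(
    clusters: Sequence[MicroDNACluster],
    categories: Mapping[str, IntervalIndex],
) -> dict[str, int]:
    out = {}
    for cat, idx in categories.items():
        out[cat] = sum(
            idx.overlaps_any(c.interval.chrom, c.interval.start, c.interval.end)
            for c in clusters
        )
    return out


def fold_enrichment(
    observed: int, null: ShuffleNull, category: str
) -> EnrichmentResult:
    """Fold = observed/expected with a two-sided Fisher's exact test on
    [[observed_in, total - observed_in], [expected_in, total - expected_in]]
    (the expected median rounded to a count; totals = number of clusters)."""
    expected = null.expected[category]
    total = null.n_clusters
    if expected == 0 and observed == 0:
        logger.warning("category %s: observed and expected both 0", category)
        return EnrichmentResult(category, 0, 0.0, float("nan"), 1.0, "fisher")
    if expected == 0:
        logger.warning("category %s: expected 0 with observed %d", category,
                       observed)
        fold = float("inf")
    else:
        fold = observed / expected
    exp_int = int(round(expected))
    table = [
        [observed, max(total - observed, 0)],
        [exp_int, max(total - exp_int, 0)],
    ]
    p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return EnrichmentResult(category, observed, expected, fold, p, "fisher")


def enrichment_table(
    clusters: Sequence[MicroDNACluster],
    chrom_sizes: Mapping[str, int],
    categories: Mapping[str, IntervalIndex],
    n: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Observed vs shuffle-expected fold enrichment for every category."""
    null = shuffle_intervals(clusters, chrom_sizes, categories, n=n, seed=seed)
    obs = observed_counts(clusters, categories)
    return [fold_enrichment(obs[cat], null, cat) for cat in categories]


def flank_enrichment(
    regions: Sequence[GenomicInterval],
    features: IntervalIndex,
    chrom_sizes: Mapping[str, int],
    flank_distance: int = 5000,
    expected_proportion: float = 1 / 3,
    category: str = "",
) -> EnrichmentResult:
    """Feature density in regions vs same-sized windows 5 kb away.

    For each region two flank windows of the region's own length are laid
    out `flank_distance` bp up- and downstream (clipped at chromosome
    ends). Feature intervals overlapping any region window are counted
    against those overlapping any flank window, and the region share is
    binomial-tested against `expected_proportion` (default 1/3: one region
    window vs two equally sized flank windows; set 1/2 to weigh a single
    flank). Two-sided p.
    """
    n_region = 0
    n_flank = 0
    n_clipped = 0
    any_flank = False
    for r in regions:
        size = chrom_sizes[r.chrom]
        L = r.length
        n_region += len(features.overlapping(r.chrom, r.start, r.end))
        up = (max(0, r.start - flank_distance - L),
              max(0, r.start - flank_distance))
        down = (min(size, r.end + flank_distance),
                min(size, r.end + flank_distance + L))
        for s, e in (up, down):
            if e - s < L:
                n_clipped += 1
            if e > s:
                any_flank = True
                n_flank += len(features.overlapping(r.chrom, s, e))
    if regions and not any_flank:
        raise ValueError("no flank window could be constructed for any region")
    if n_clipped:
        logger.info("%d flank windows clipped at chromosome ends", n_clipped)
    total = n_region + n_flank
    expected = total * expected_proportion
    fold = n_region / expected if expected > 0 else float("nan")
    if total == 0:
        p = 1.0
    else:
        p = float(
            sps.binomtest(n_region, total, expected_proportion,
                          alternative="two-sided").pvalue
        )
    return EnrichmentResult(category, n_region, expected, fold, p, "binomial")
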