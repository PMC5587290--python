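# Methods

## Coordinates and file dialects

All internal coordinates are 0-based half-open. The chimeric-junction
dialect is the 14-column STAR `Chimeric.out.junction` layout: donor
chromosome/position/strand, acceptor chromosome/position/strand, junction
type, repeat lengths, read name, and two segment start/CIGAR pairs. File
positions are 1-based; the donor column holds the first base *past* the
circle body (STAR reports the first intron base of a splice-like junction),
so for a circle `[start, end)` the emitter writes donor `end + 1` and
acceptor `start + 1`, and the parser subtracts 1 from both. Emitter and
parser are exact inverses, so noise-free round trips recover circle
boundaries exactly.

## Cluster calling

A junction is *circular-consistent* when donor and acceptor share a
chromosome and strand and the acceptor lies upstream of the donor —
head-to-tail geometry that a read crossing a circular junction produces.
Two junctions support the same circle when **both** breakpoints lie within
`extension` bp (default 10) of each other; requiring only one end would
merge distinct circles sharing a single breakpoint. Cluster membership is
the transitive closure of this pairwise relation (union-find over a
sorted-by-acceptor sweep; along any chain, consecutive acceptors differ by
at most `extension`, so only acceptor-near pairs need checking). The
closure makes the result independent of input order; the suite verifies
equivalence with a brute-force closure oracle on random instances. The
cluster interval is `[min acceptor, max donor)`; support counts unique
read names; clusters outside 20–2000 bp (or below `min_support`, default
1 — no support threshold is imposed by default) are dropped and counted.

The island method accepts a mapped read only when its leading and trailing
soft-clips are identical (exact string match, ≥ 5 nt — shorter clips
nominate too many spurious junctions). The clip is the circle tail read
through the junction, so the nominated circle spans the mapped segment
plus one clip length; nominations then flow through the same clustering.
On noise-free synthetic data both callers return identical intervals
(tested).

## Annotation and group tables

Feature flags use a minimum overlap of 1 bp and are non-exclusive
indicators (a cluster can be both exonic and intronic). `NA` means
overlapping neither a gene feature nor a promoter; a promoter-only cluster
is therefore not NA. Promoters are the 2 kb strand-aware upstream of each
TSS, clipped at chromosome edges. `Active`/`Inactive` partition clusters
by open-chromatin overlap, so Active + Inactive = Total holds row-wise in
every group table (asserted end-to-end). Unique cluster identity is
(sample, chrom, start, end); group totals sum over the group's samples, so
a locus recurring in two samples counts twice — this convention also makes
treated-fraction percentages exact functions of the group totals.

TSS distance profiles place each cluster by its center (removing
size-distribution bias), orient offsets by gene strand (upstream negative)
and normalize counts by the total number of clusters. Feature position
profiles report the mean number of feature intervals covering each offset
from cluster centers, without strand orientation. GC is (G+C)/(A+C+G+T)
with N excluded from the denominator; the two 1 kb flanks are pooled into
one value per cluster, and cluster-vs-flank vectors are compared with a
two-sided Mann-Whitney test.

## Enrichment nulls

The shuffle null re-places every cluster uniformly at random genome-wide
with its length preserved: a chromosome is chosen proportionally to its
placeable length (L − cluster length + 1) and the offset uniformly, which
makes placement uniform over all genomic positions; no exclusion regions
are applied. The default 1000 iterations record per-category overlap
counts; the expected value is the per-category median, fold is
observed/expected, and significance comes from a two-sided Fisher's exact
test on [[observed, total − observed], [expected, total − expected]] with
the median rounded to a count — a deliberately simple 2×2 whose
calibration under an unbiased generator is verified (≤ 7% of replicates
significant at 0.05). Doubling the iteration count moves the expected
medians by < 2% (tested).

The flank null compares feature counts in regions against two same-sized
windows 5 kb up- and downstream, binomial-testing the region share against
1/3 (one region window vs two flank windows of equal size; a
`expected_proportion=1/2` switch weighs a single flank instead). Flank
windows are clipped at chromosome ends and clips are logged. P-values are
reported raw, without multiple-testing correction.

## Intersects

Cluster intersects merge the union of a group's clusters into continual
segments at ≥ 1 bp overlap (touching intervals do not merge); every
cluster whose segment contains clusters from ≥ 2 samples counts, and the
counting unit is the cluster, not the segment, so intersect totals match
the group tables. Gene intersects require only a shared host gene (any
gene, when a cluster spans several). Shared-gene structure across the four
condition groups is a Venn partition of gene identities; expected
partitions come from re-placing all clusters uniformly (length preserved,
default 1000 iterations, per-cell median) and are compared with a
chi-square statistic Σ(O−E)²/E over cells with E > 0, df = cells − 1.
Cells whose expected median is 0 drop out of the statistic, which makes
the test conservative when sharing is rare; the directional property
(observed sharing exceeds the expected median on hotspot data) is tested
separately.

## Size statistics

Summaries report the mean, the central 95 percentile range (2.5th–97.5th)
and the IQR, using numpy's linear-interpolation percentiles; the central
range is a percentile spread of the lengths themselves, not a standard
error of the mean. The ladder period estimator bins lengths at 10 bp,
trims the histogram to its occupied support (otherwise the step at the
distribution's edges masquerades as low-lag structure), subtracts a moving
average normalized by in-window coverage (default 500 bp window), and
scans the autocorrelation of the residual over lags 50–500 bp. The
reported period is the lag of the maximum; significance requires the peak
to exceed the 95th percentile of the same statistic over 200 random bin
permutations, which preserve the count distribution but destroy
periodicity. Combs at 150/190/230 bp are recovered exactly and uniform
lengths are non-significant (tested). Mann-Whitney contrasts use the
exact null when the smaller group has ≤ 8 observations and the
tie-corrected normal approximation otherwise; both modes are exposed so
the exact mode can be checked against full enumeration.

## Synthetic generator

The generator emulates the study design, not read-level sequencing
physics. The toy genome has fixed-length chromosomes; disjoint 2 kb
open-chromatin blocks covering a target fraction (default 10%); genes with
UTR/exon/intron structure (exons 200 bp, introns 800 bp), random strand,
2 kb promoters and TSSs, placed with promoter-sized clearance; H3K9ac
peaks near 70% of TSSs and repressive marks (H3K27me3/H3K9me3) away from
genes; SINE/LINE/LTR repeats at configurable densities. Sequence GC is
0.55 inside open chromatin and 0.40 outside, so chromatin-biased circles
are GC-enriched relative to their flanks, mirroring the expected
direction.

Circle sizes come from a Gaussian mixture with component means
`10 + k·190` bp (k = 1…10), weights decaying from the k=1 (~200 bp) and
k=2 (~390 bp) components, and sds growing 28→44 bp; draws outside
20–2000 bp are resampled. The 190 bp spacing encodes internucleosomal
apoptotic laddering; the two leading components give the characteristic
~200/~400 bp peaks. Loci are drawn by rejection sampling with
multiplicative weights for open-chromatin (default 3.0), exon (1.5) and
promoter (1.9) overlap, so with open-bias b and effective open hit
fraction f the open share is bf/(bf + 1 − f) (verified against a Monte
Carlo oracle). Treated samples get a 2.0× count multiplier and a +50 bp
size shift; sensitive samples a 1.5× count multiplier; counts are Poisson
around the scaled base (default 200 circles per untreated resistant
sample). Reads per circle are Poisson(3) truncated at ≥ 1 so every circle
is in principle detectable; background junctions (random geometry, 5% of
true lines) provide noise; breakpoint jitter beyond 10 bp voids the
recovery guarantee and triggers a warning. Everything derives from
`numpy.random.default_rng(seed)`, giving byte-identical outputs per seed.

The generator does **not** model sequencing error, base qualities,
rolling-circle amplification chimeras, inter-chromosomal artifacts as
signal, or mappability; passing tests demonstrate the analysis logic and
its calibration, not performance on real libraries.

## Problem sizes and numerical choices

Tests run the generator at 10⁵–10⁶ bp genomes with tens of genes and
10²–10⁴ circles, and the calibration suites use 100 replicates with
200–1000 shuffle iterations — sizes chosen so the full suite exercises
every statistical claim while staying comfortably interactive. The
acceptance script simulates 10,000 sizes for the period estimate.
Percent formatting rounds half-up to one decimal. Fisher/chi-square/
Mann-Whitney implementations are scipy's; the package's own statistics
(shuffle null, partition chi-square, periodicity permutation test) are
validated against closed forms, enumeration oracles, or bedtools where an
independent route exists.

## Known limitations

Only head-to-tail same-strand circles are modeled; inverted or
inter-chromosomal eccDNA structures are out of scope. The island method
requires exact clip matches and equal clip lengths, so sequencing errors
in real data would reduce its sensitivity. The Fisher 2×2 built from a
shuffle median treats the expected count as if observed, which is a
pragmatic approximation; its null calibration is verified empirically
rather than derived. Group totals count recurring loci per sample, so
tables are not de-duplicated across samples within a group.
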