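"""Synthetic genome, annotation and microDNA read simulation.

The generator produces a small genome with gene models, open-chromatin and
histone tracks, then simulates circular DNA molecules whose sizes follow an
internucleosomal laddering mixture (components spaced ~190 bp apart, peaks
near 200 and 400 bp) and whose loci are biased toward open chromatin, exons
and promoters. Junction evidence is written in the 14-column STAR
Chimeric.out.junction dialect, optionally accompanied by SAM records carrying
identical leading/trailing soft-clips for the island caller.

Everything is seeded: identical seeds give byte-identical output files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .intervals import GenomicInterval, IntervalIndex
from .samples import SampleMeta

# Structural constants of the toy genome (bp)
EXON_LENGTH = 200
INTRON_LENGTH = 800
OPEN_BLOCK_LENGTH = 2000
REPEAT_LENGTH = 300
HISTONE_PEAK_WIDTH = 1000
H3K9AC_TSS_FRACTION = 0.7
EXPRESSED_FRACTION = 0.6
REPRESSIVE_PEAK_DENSITY = 0.02  # fraction of genome per repressive mark

CIRCLE_MIN = 20
CIRCLE_MAX = 2000


@dataclass
class ToyGenomeSpec:
    """Parameters of the synthetic genome and its annotation tracks."""

    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 60
    exons_per_gene: int = 4
    utr_length: int = 200
    promoter_length: int = 2000
    repeat_density: dict[str, float] = field(
        default_factory=lambda: {"SINE": 0.03, "LINE": 0.03, "LTR": 0.02}
    )
    open_chromatin_fraction: float = 0.10
    gc_open: float = 0.55
    gc_closed: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (
            ("open_chromatin_fraction", self.open_chromatin_fraction),
            ("gc_open", self.gc_open),
            ("gc_closed", self.gc_closed),
            *((f"repeat_density[{k}]", v) for k, v in self.repeat_density.items()),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")

    @property
    def gene_length(self) -> int:
        return (
            2 * self.utr_length
            + self.exons_per_gene * EXON_LENGTH
            + max(0, self.exons_per_gene - 1) * INTRON_LENGTH
        )


@dataclass
class AnnotationBundle:
    """Indexed genomic annotation tracks used throughout the analysis."""

    chrom_sizes: dict[str, int]
    genes: IntervalIndex
    exons: IntervalIndex
    introns: IntervalIndex
    utr5: IntervalIndex
    utr3: IntervalIndex
    promoters: IntervalIndex
    tss: list[GenomicInterval]
    expressed_tss: list[GenomicInterval]
    open_chromatin: IntervalIndex
    histone: dict[str, IntervalIndex]
    repeats: dict[str, IntervalIndex]


@dataclass(frozen=True)
class CircleRecord:
    """Ground-truth simulated circle (for recovery checks)."""

    sample_id: str
    interval: GenomicInterval
    true_length: int

    def __post_init__(self) -> None:
        if self.true_length != self.interval.length:
            raise ValueError("true_length must equal interval length")
        if not CIRCLE_MIN <= self.true_length <= CIRCLE_MAX:
            raise ValueError(
                f"circle length {self.true_length} outside "
                f"[{CIRCLE_MIN}, {CIRCLE_MAX}]"
            )


@dataclass
class CircleModel:
    """Generative model for circle counts, sizes and loci.

    Sizes come from a Gaussian mixture whose component means sit at
    ``ladder_offset + k * ladder_period`` — the apoptotic laddering pattern,
    with the k=1 and k=2 components (near 200 and 400 bp) dominating.
    Loci are sampled with multiplicative weights for open chromatin, exon
    and promoter overlap. Treated samples get more and longer circles;
    sensitive samples get more circles.
    """

    ladder_period: int = 190
    ladder_offset: int = 10
    #: (multiple k, weight, sd): component mean = ladder_offset + k * period
    ladder_components: tuple[tuple[int, float, float], ...] = (
        (1, 1.0, 28.0),
        (2, 0.55, 28.0),
        (3, 0.28, 30.0),
        (4, 0.15, 32.0),
        (5, 0.08, 34.0),
        (6, 0.045, 36.0),
        (7, 0.025, 38.0),
        (8, 0.014, 40.0),
        (9, 0.008, 42.0),
        (10, 0.005, 44.0),
    )
    open_chromatin_bias: float = 3.0
    exon_bias: float = 1.5
    promoter_bias: float = 1.9
    treatment_count_multiplier: float = 2.0
    treatment_size_shift: int = 50
    sensitivity_count_multiplier: float = 1.5
    n_circles_base: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 0 for _, w, _ in self.ladder_components):
            raise ValueError("ladder component weights must be >= 0")
        for name in ("open_chromatin_bias", "exon_bias", "promoter_bias"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def component_means(self) -> np.ndarray:
        return np.array(
            [self.ladder_offset + k * self.ladder_period
             for k, _, _ in self.ladder_components],
            dtype=float,
        )

    def mixture_mean(self) -> float:
        """Analytic mean length of the (untruncated) size mixture."""
        w = np.array([w for _, w, _ in self.ladder_components])
        return float(np.sum(w * self.component_means()) / np.sum(w))


@dataclass
class NoiseParams:
    jitter: int = 0          # max |bp| perturbation of each breakpoint
    background: float = 0.05  # false junction lines per true junction line


# ---------------------------------------------------------------------------
# genome generation


def _place_disjoint(
    rng: np.random.Generator, n: int, length: int, chrom_len: int,
    margin: int, track: str,
) -> list[int]:
    """n disjoint starts for intervals of `length`, each preceded by `margin`
    free bp (also before the first interval). Raises on infeasible packing."""
    if n == 0:
        return []
    unit = length + margin
    slack = chrom_len - n * unit - margin
    if slack < 0:
        raise ValueError(
            f"infeasible packing for track '{track}': "
            f"{n} x {length} bp (+{margin} bp margins) exceeds "
            f"chromosome length {chrom_len}"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    return [int(margin + cuts[i] + i * unit) for i in range(n)]


def _split_counts(total: int, n_bins: int) -> list[int]:
    base, rem = divmod(total, n_bins)
    return [base + (1 if i < rem else 0) for i in range(n_bins)]


def generate_toy_genome(
    spec: ToyGenomeSpec, outdir: str | Path | None = None
) -> tuple[dict[str, str], AnnotationBundle]:
    """Build the synthetic genome and annotation bundle.

    Returns the chromosome sequences and the indexed bundle; when `outdir`
    is given, also writes genome.fa plus BED/GTF/narrowPeak tracks there.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    chrom_sizes = {c: spec.chrom_length for c in chrom_names}
    L = spec.chrom_length

    open_ivs: list[GenomicInterval] = []
    gene_ivs: list[GenomicInterval] = []
    exon_ivs: list[GenomicInterval] = []
    intron_ivs: list[GenomicInterval] = []
    utr5_ivs: list[GenomicInterval] = []
    utr3_ivs: list[GenomicInterval] = []
    prom_ivs: list[GenomicInterval] = []
    tss_list: list[GenomicInterval] = []
    expressed: list[GenomicInterval] = []

    # open chromatin: disjoint fixed-size blocks covering the target fraction
    n_open_per_chrom = {
        c: int(round(spec.open_chromatin_fraction * L / OPEN_BLOCK_LENGTH))
        for c in chrom_names
    }
    for chrom in chrom_names:
        starts = _place_disjoint(
            rng, n_open_per_chrom[chrom], OPEN_BLOCK_LENGTH, L, 0,
            "open_chromatin",
        )
        open_ivs.extend(
            GenomicInterval(chrom, s, s + OPEN_BLOCK_LENGTH) for s in starts
        )

    # genes: disjoint, with promoter-sized clearance between and before them
    gene_counts = _split_counts(spec.n_genes, spec.n_chromosomes)
    gid = 0
    for chrom, n_chrom_genes in zip(chrom_names, gene_counts):
        starts = _place_disjoint(
            rng, n_chrom_genes, spec.gene_length, L, spec.promoter_length,
            "genes",
        )
        for s in starts:
            gid += 1
            name = f"gene{gid}"
            strand = "+" if rng.random() < 0.5 else "-"
            e = s + spec.gene_length
            gene_ivs.append(GenomicInterval(chrom, s, e, strand, name))
            # block layout 5'->3': utr5, exon, (intron, exon)*, utr3
            blocks: list[tuple[str, int]] = [("utr5", spec.utr_length)]
            for i in range(spec.exons_per_gene):
                if i > 0:
                    blocks.append(("intron", INTRON_LENGTH))
                blocks.append(("exon", EXON_LENGTH))
            blocks.append(("utr3", spec.utr_length))
            if strand == "-":
                blocks = blocks[::-1]
            pos = s
            for kind, blen in blocks:
                iv = GenomicInterval(chrom, pos, pos + blen, strand, name)
                {"utr5": utr5_ivs, "utr3": utr3_ivs,
                 "exon": exon_ivs, "intron": intron_ivs}[kind].append(iv)
                pos += blen
            if strand == "+":
                tss_pos = s
                prom = GenomicInterval(
                    chrom, max(0, s - spec.promoter_length), s, strand, name
                ) if s > 0 else None
            else:
                tss_pos = e - 1
                prom = GenomicInterval(
                    chrom, e, min(L, e + spec.promoter_length), strand, name
                ) if e < L else None
            if prom is not None:
                prom_ivs.append(prom)
            tss = GenomicInterval(chrom, tss_pos, tss_pos + 1, strand, name)
            tss_list.append(tss)
            if rng.random() < EXPRESSED_FRACTION:
                expressed.append(tss)

    # histone marks: H3K9ac near a fraction of TSSs; repressive marks away
    # from gene bodies and promoters
    histone: dict[str, list[GenomicInterval]] = {
        "H3K9ac": [], "H3K27me3": [], "H3K9me3": []
    }
    for tss in tss_list:
        if rng.random() < H3K9AC_TSS_FRACTION:
            off = int(rng.integers(-200, 201))
            c = tss.start + off
            s = max(0, c - HISTONE_PEAK_WIDTH // 2)
            e = min(L, c + HISTONE_PEAK_WIDTH // 2)
            if e > s:
                histone["H3K9ac"].append(GenomicInterval(tss.chrom, s, e))
    gene_idx_tmp = IntervalIndex(gene_ivs + prom_ivs)
    n_rep = int(round(REPRESSIVE_PEAK_DENSITY * L / HISTONE_PEAK_WIDTH))
    for mark in ("H3K27me3", "H3K9me3"):
        for chrom in chrom_names:
            placed = 0
            tries = 0
            while placed < n_rep and tries < 50 * n_rep:
                tries += 1
                s = int(rng.integers(0, L - HISTONE_PEAK_WIDTH + 1))
                if not gene_idx_tmp.overlaps_any(chrom, s, s + HISTONE_PEAK_WIDTH):
                    histone[mark].append(
                        GenomicInterval(chrom, s, s + HISTONE_PEAK_WIDTH)
                    )
                    placed += 1

    repeats: dict[str, list[GenomicInterval]] = {}
    for cls, dens in spec.repeat_density.items():
        ivs = []
        for chrom in chrom_names:
            n = int(round(dens * L / REPEAT_LENGTH))
            starts = rng.integers(0, L - REPEAT_LENGTH + 1, size=n)
            ivs.extend(
                GenomicInterval(chrom, int(s), int(s) + REPEAT_LENGTH, ".", cls)
                for s in sorted(starts)
            )
        repeats[cls] = ivs

    open_index = IntervalIndex(open_ivs)

    # sequence: GC probability gc_open inside open chromatin, gc_closed outside
    genome: dict[str, str] = {}
    base_lut = np.frombuffer(b"ATGC", dtype="S1")
    for chrom in chrom_names:
        gc_p = np.full(L, spec.gc_closed)
        for iv in open_ivs:
            if iv.chrom == chrom:
                gc_p[iv.start:iv.end] = spec.gc_open
        is_gc = rng.random(L) < gc_p
        half = rng.integers(0, 2, size=L)
        codes = is_gc.astype(np.int8) * 2 + half.astype(np.int8)
        genome[chrom] = base_lut[codes].tobytes().decode("ascii")

    bundle = AnnotationBundle(
        chrom_sizes=chrom_sizes,
        genes=IntervalIndex(gene_ivs),
        exons=IntervalIndex(exon_ivs),
        introns=IntervalIndex(intron_ivs),
        utr5=IntervalIndex(utr5_ivs),
        utr3=IntervalIndex(utr3_ivs),
        promoters=IntervalIndex(prom_ivs),
        tss=tss_list,
        expressed_tss=expressed,
        open_chromatin=open_index,
        histone={k: IntervalIndex(v) for k, v in histone.items()},
        repeats={k: IntervalIndex(v) for k, v in repeats.items()},
    )

    if outdir is not None:
        _write_tracks(Path(outdir), genome, bundle)
    return genome, bundle


def _write_bed(path: Path, ivs, score: str = "0") -> None:
    with open(path, "w") as fh:
        for iv in sorted(ivs, key=lambda v: (v.chrom, v.start, v.end)):
            name = iv.name or "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def _write_tracks(outdir: Path, genome: dict[str, str], bundle: AnnotationBundle) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "genome.fa", genome)
    with open(outdir / "genome.chrom.sizes", "w") as fh:
        for chrom, size in bundle.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    with open(outdir / "genes.gtf", "w") as fh:
        for g in bundle.genes:
            attrs = f'gene_id "{g.name}";'
            fh.write(
                f"{g.chrom}\ttoy\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
        for ex in bundle.exons:
            attrs = f'gene_id "{ex.name}";'
            fh.write(
                f"{ex.chrom}\ttoy\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\t{attrs}\n"
            )
    _write_bed(outdir / "genes.bed", bundle.genes)
    _write_bed(outdir / "exons.bed", bundle.exons)
    _write_bed(outdir / "introns.bed", bundle.introns)
    _write_bed(outdir / "utr5.bed", bundle.utr5)
    _write_bed(outdir / "utr3.bed", bundle.utr3)
    _write_bed(outdir / "promoters.bed", bundle.promoters)
    _write_bed(outdir / "tss.bed", bundle.tss)
    _write_bed(outdir / "expressed_tss.bed", bundle.expressed_tss)
    _write_bed(outdir / "open_chromatin.bed", bundle.open_chromatin)
    reps = [iv for cls in sorted(bundle.repeats) for iv in bundle.repeats[cls]]
    _write_bed(outdir / "repeats.bed", reps)
    for mark, idx in sorted(bundle.histone.items()):
        with open(outdir / f"{mark}.narrowPeak", "w") as fh:
            for i, iv in enumerate(
                sorted(idx, key=lambda v: (v.chrom, v.start, v.end))
            ):
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{mark}_{i + 1}\t"
                    f"500\t.\t5.0\t-1\t-1\t{iv.length // 2}\n"
                )


def write_fasta(path: Path, genome: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# circle simulation


def _draw_length(rng: np.random.Generator, model: CircleModel, shift: int) -> int:
    w = np.array([w for _, w, _ in model.ladder_components])
    probs = w / w.sum()
    means = model.component_means()
    sds = np.array([sd for _, _, sd in model.ladder_components])
    while True:
        k = rng.choice(len(probs), p=probs)
        length = int(round(rng.normal(means[k] + shift, sds[k])))
        if CIRCLE_MIN <= length <= CIRCLE_MAX:
            return length


def simulate_circles(
    bundle: AnnotationBundle, model: CircleModel, samples: list[SampleMeta]
) -> list[CircleRecord]:
    """Draw circles per sample with group-dependent counts, laddered sizes
    and chromatin-biased loci (rejection sampling on category weights)."""
    if not bundle.chrom_sizes or max(bundle.chrom_sizes.values()) < CIRCLE_MIN:
        raise ValueError("empty or too-short genome: cannot place circles")
    rng = np.random.default_rng(model.seed)
    chroms = list(bundle.chrom_sizes)
    max_w = (
        max(model.open_chromatin_bias, 1.0)
        * max(model.exon_bias, 1.0)
        * max(model.promoter_bias, 1.0)
    )
    records: list[CircleRecord] = []
    for sample in samples:
        mult = 1.0
        if sample.treatment == "T":
            mult *= model.treatment_count_multiplier
        if sample.sensitivity == "S":
            mult *= model.sensitivity_count_multiplier
        n = int(rng.poisson(model.n_circles_base * mult))
        shift = model.treatment_size_shift if sample.treatment == "T" else 0
        for _ in range(n):
            length = _draw_length(rng, model, shift)
            sizes = np.array([bundle.chrom_sizes[c] for c in chroms], dtype=float)
            placeable = np.maximum(sizes - length + 1, 0)
            if placeable.sum() == 0:
                raise ValueError(f"no chromosome can host a {length} bp circle")
            cprobs = placeable / placeable.sum()
            while True:
                ci = rng.choice(len(chroms), p=cprobs)
                chrom = chroms[ci]
                s = int(rng.integers(0, bundle.chrom_sizes[chrom] - length + 1))
                e = s + length
                w = 1.0
                if bundle.open_chromatin.overlaps_any(chrom, s, e):
                    w *= model.open_chromatin_bias
                if bundle.exons.overlaps_any(chrom, s, e):
                    w *= model.exon_bias
                if bundle.promoters.overlaps_any(chrom, s, e):
                    w *= model.promoter_bias
                if rng.random() < w / max_w:
                    break
            records.append(
                CircleRecord(
                    sample.sample_id,
                    GenomicInterval(chrom, s, e),
                    length,
                )
            )
    return records


def simulate_lengths(
    model: CircleModel, n: int, seed: int | None = None, shift: int = 0
) -> np.ndarray:
    """Draw n circle lengths from the laddering size mixture alone."""
    rng = np.random.default_rng(model.seed if seed is None else seed)
    return np.array([_draw_length(rng, model, shift) for _ in range(n)])


# ---------------------------------------------------------------------------
# junction emission


@dataclass
class EmitResult:
    junction_paths: dict[str, Path]
    sam_paths: dict[str, Path]
    truth_paths: dict[str, Path]
    n_true_lines: dict[str, int]
    n_background: dict[str, int]


SAM_CLIP_LENGTH = 10  # soft-clip length carried on each emitted SAM read


def emit_chimeric_junctions(
    circles: list[CircleRecord],
    outdir: str | Path,
    chrom_sizes: dict[str, int],
    samples: list[SampleMeta] | None = None,
    reads_per_circle: float = 3.0,
    noise: NoiseParams | None = None,
    seed: int = 0,
    genome: dict[str, str] | None = None,
    write_sam: bool = False,
) -> EmitResult:
    """Write one STAR-dialect chimeric junction file per sample.

    Each circle [start, end) yields >= 1 junction line (truncated-Poisson
    read count) with donor column = end + 1 and acceptor column = start + 1
    in 1-based file coordinates (the donor column holds the first base past
    the circle body, mirroring STAR's intron-first-base convention), each
    perturbed by up to `noise.jitter` bp. Background lines with random
    breakpoint geometry are added at `noise.background` per true line.
    With `write_sam`, the same junction reads are emitted as SAM records
    whose identical leading/trailing soft-clips wrap the circle junction.
    """
    noise = noise or NoiseParams()
    if noise.jitter > 10:
        warnings.warn(
            f"jitter {noise.jitter} > 10 bp breaks the recovery guarantee of "
            "the default 10 bp cluster extension",
            stacklevel=2,
        )
    if write_sam and genome is None:
        raise ValueError("write_sam requires the genome sequences")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    if samples is not None:
        sample_ids = [s.sample_id for s in samples]
    else:
        sample_ids = list(dict.fromkeys(c.sample_id for c in circles))
    by_sample: dict[str, list[CircleRecord]] = {sid: [] for sid in sample_ids}
    for c in circles:
        by_sample.setdefault(c.sample_id, []).append(c)

    chroms = list(chrom_sizes)
    result = EmitResult({}, {}, {}, {}, {})
    for sid in by_sample:
        jpath = outdir / f"{sid}.Chimeric.out.junction"
        tpath = outdir / f"{sid}.truth.bed"
        lines: list[str] = []
        sam_reads: list[tuple[str, int, int, str]] = []  # (chrom, s, e, name)
        n_true = 0
        for ci, circ in enumerate(by_sample[sid]):
            n_reads = 0
            while n_reads == 0:
                n_reads = int(rng.poisson(reads_per_circle))
            for ri in range(n_reads):
                jd = int(rng.integers(-noise.jitter, noise.jitter + 1)) if noise.jitter else 0
                ja = int(rng.integers(-noise.jitter, noise.jitter + 1)) if noise.jitter else 0
                size = chrom_sizes[circ.interval.chrom]
                acc = min(max(circ.interval.start + ja, 0), size - 2)
                don = min(max(circ.interval.end + jd, acc + 1), size)
                name = f"{sid}:c{ci}:r{ri}"
                lines.append(_junction_line(circ.interval.chrom, don, acc, name))
                sam_reads.append((circ.interval.chrom, acc, don, name))
                n_true += 1
        n_bg = int(round(noise.background * n_true))
        for bi in range(n_bg):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            size = chrom_sizes[chrom]
            a = int(rng.integers(0, size))
            b = int(rng.integers(0, size))
            sd_, sa_ = rng.choice(["+", "-"], size=2)
            name = f"{sid}:bg{bi}"
            lines.append(
                "\t".join(
                    [chrom, str(a + 1), sd_, chrom, str(b + 1), sa_,
                     "0", "-1", "-1", name, str(max(1, a - 40)), "40M60S",
                     str(b + 1), "60M40S"]
                )
            )
        with open(jpath, "w") as fh:
            fh.write("".join(f"{ln}\n" for ln in lines))
        with open(tpath, "w") as fh:
            for ci, circ in enumerate(by_sample[sid]):
                fh.write(
                    f"{circ.interval.chrom}\t{circ.interval.start}\t"
                    f"{circ.interval.end}\t{sid}:c{ci}\t0\t+\n"
                )
        result.junction_paths[sid] = jpath
        result.truth_paths[sid] = tpath
        result.n_true_lines[sid] = n_true
        result.n_background[sid] = n_bg
        if write_sam:
            spath = outdir / f"{sid}.sam"
            _write_sam(spath, sam_reads, genome, chrom_sizes)
            result.sam_paths[sid] = spath
    return result


def _junction_line(chrom: str, donor0: int, acceptor0: int, name: str) -> str:
    """14-column STAR-dialect line from internal 0-based breakpoints."""
    donor_file = donor0 + 1
    acceptor_file = acceptor0 + 1
    return "\t".join(
        [chrom, str(donor_file), "+", chrom, str(acceptor_file), "+",
         "0", "-1", "-1", name, str(max(1, donor_file - 40)), "40M60S",
         str(acceptor_file), "60M40S"]
    )


def _write_sam(
    path: Path,
    reads: list[tuple[str, int, int, str]],
    genome: dict[str, str],
    chrom_sizes: dict[str, int],
) -> None:
    k = SAM_CLIP_LENGTH
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, size in chrom_sizes.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{size}\n")
        for chrom, s, e, name in reads:
            seq_chrom = genome[chrom]
            if e - s <= k:  # too short to carry both clips; emit unclipped
                seq = seq_chrom[s:e]
                cigar = f"{e - s}M"
            else:
                wrap = seq_chrom[e - k:e]
                seq = wrap + seq_chrom[s:e - k] + wrap
                cigar = f"{k}S{e - k - s}M{k}S"
            fh.write(
                f"{name}\t0\t{chrom}\t{s + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"
            )
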