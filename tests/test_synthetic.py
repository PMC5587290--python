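import filecmp

import numpy as np
import pytest
from scipy.signal import argrelmax

from microdna.intervals import IntervalIndex
from microdna.samples import SampleMeta
from microdna.synthetic import (
    CircleModel,
    NoiseParams,
    ToyGenomeSpec,
    emit_chimeric_junctions,
    generate_toy_genome,
    simulate_circles,
    simulate_lengths,
)


class TestGenerateToyGenome:
    def test_no_genes_still_emits_open_chromatin(self, tmp_path):
        spec = ToyGenomeSpec(n_chromosomes=1, chrom_length=100_000,
                             n_genes=0, seed=1)
        _, bundle = generate_toy_genome(spec, tmp_path)
        assert len(bundle.genes) == 0 and len(bundle.exons) == 0
        assert len(bundle.open_chromatin) > 0
        assert (tmp_path / "open_chromatin.bed").stat().st_size > 0
        assert (tmp_path / "genes.bed").exists()

    def test_deterministic_under_fixed_seed(self, tmp_path):
        spec = ToyGenomeSpec(n_chromosomes=1, chrom_length=100_000,
                             n_genes=10, seed=7)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_toy_genome(spec, d1)
        generate_toy_genome(spec, d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert filecmp.cmp(d1 / f, d2 / f, shallow=False), f

    def test_gc_composition_matches_spec(self, tmp_path):
        # oracle: direct base counting over the emitted FASTA
        spec = ToyGenomeSpec(n_chromosomes=1, chrom_length=1_000_000,
                             n_genes=0, open_chromatin_fraction=0.2, seed=3)
        generate_toy_genome(spec, tmp_path)
        seqs = {}
        name = None
        with open(tmp_path / "genome.fa") as fh:
            for line in fh:
                if line.startswith(">"):
                    name = line[1:].strip()
                    seqs[name] = []
                else:
                    seqs[name].append(line.strip())
        seq = "".join(seqs["chr1"])
        open_ivs = []
        with open(tmp_path / "open_chromatin.bed") as fh:
            for line in fh:
                f = line.split("\t")
                open_ivs.append((int(f[1]), int(f[2])))
        open_bases = "".join(seq[s:e] for s, e in open_ivs)
        mask = np.zeros(len(seq), dtype=bool)
        for s, e in open_ivs:
            mask[s:e] = True
        closed_bases = "".join(np.array(list(seq))[~mask])

        def gc(s):
            return (s.count("G") + s.count("C")) / len(s)

        assert abs(gc(open_bases) - 0.55) < 0.02
        assert abs(gc(closed_bases) - 0.40) < 0.02

    def test_promoters_are_strand_aware_upstream_of_tss(self, toy):
        _, _, bundle = toy
        proms = {p.name: p for p in bundle.promoters}
        for tss in bundle.tss:
            p = proms[tss.name]
            if tss.strand == "+":
                assert p.end == tss.start and p.end - p.start <= 2000
            else:
                assert p.start == tss.start + 1

    def test_infeasible_packing_names_track(self):
        spec = ToyGenomeSpec(n_chromosomes=1, chrom_length=5_000,
                             n_genes=50, seed=0)
        with pytest.raises(ValueError, match="genes"):
            generate_toy_genome(spec)


class TestSimulateCircles:
    def test_zero_base_count_gives_empty_list(self, toy, samples_mtx):
        _, _, bundle = toy
        model = CircleModel(n_circles_base=0, seed=1)
        assert simulate_circles(bundle, model, samples_mtx) == []

    def test_degenerate_open_bias_confines_circles_to_open_chromatin(
        self, toy, samples_mtx
    ):
        _, _, bundle = toy
        model = CircleModel(open_chromatin_bias=1e9, n_circles_base=50, seed=2)
        circles = simulate_circles(bundle, model, samples_mtx[:1])
        assert circles
        for c in circles:
            assert bundle.open_chromatin.overlaps_any(
                c.interval.chrom, c.interval.start, c.interval.end
            )

    def test_lengths_within_window_and_ladder_spacing(self):
        # oracle: local maxima of the 10 bp histogram via argrelmax
        lens = simulate_lengths(CircleModel(seed=5), 10_000)
        assert lens.min() >= 20 and lens.max() <= 2000
        counts, _ = np.histogram(lens, bins=np.arange(0, 2010, 10))
        # smooth lightly so shot noise does not split peaks
        sm = np.convolve(counts, np.ones(3) / 3, mode="same")
        peaks = argrelmax(sm, order=5)[0] * 10
        big = [p for p in peaks if sm[p // 10] > 0.25 * sm.max()]
        gaps = np.diff(big)
        assert len(gaps) >= 1
        assert all(abs(g - 190) <= 10 for g in gaps)

    def test_treated_samples_get_more_and_longer_circles(self, toy):
        _, _, bundle = toy
        model = CircleModel(n_circles_base=300, seed=6)
        t = SampleMeta("t", "MTX", "R", "T")
        nt = SampleMeta("nt", "MTX", "R", "NT")
        circles = simulate_circles(bundle, model, [t, nt])
        lens = {"t": [], "nt": []}
        for c in circles:
            lens[c.sample_id].append(c.true_length)
        assert len(lens["t"]) > len(lens["nt"])
        assert np.mean(lens["t"]) > np.mean(lens["nt"])

    def test_open_chromatin_fraction_matches_binomial_expectation(self, toy):
        _, _, bundle = toy
        model = CircleModel(open_chromatin_bias=3.0, exon_bias=1.0,
                            promoter_bias=1.0, n_circles_base=2000, seed=8)
        s = SampleMeta("x", "MTX", "R", "NT")
        circles = simulate_circles(bundle, model, [s])
        hits = sum(
            bundle.open_chromatin.overlaps_any(
                c.interval.chrom, c.interval.start, c.interval.end
            )
            for c in circles
        )
        # effective open fraction for these circle lengths under uniform
        # placement, estimated by an independent Monte Carlo oracle
        lens = np.array([c.true_length for c in circles])
        rng = np.random.default_rng(99)
        chroms = list(bundle.chrom_sizes)
        m = 20_000
        draw = rng.choice(lens, size=m)
        u_hits = 0
        for L in draw:
            chrom = chroms[int(rng.integers(len(chroms)))]
            s = int(rng.integers(0, bundle.chrom_sizes[chrom] - L + 1))
            u_hits += bundle.open_chromatin.overlaps_any(chrom, s, s + int(L))
        f_eff = u_hits / m
        b = 3.0
        p = b * f_eff / (b * f_eff + (1 - f_eff))
        se = np.sqrt(p * (1 - p) / len(circles))
        assert abs(hits / len(circles) - p) < 3 * se

    def test_empty_genome_raises(self, samples_mtx):
        from microdna.synthetic import AnnotationBundle
        empty = AnnotationBundle(
            chrom_sizes={}, genes=IntervalIndex(), exons=IntervalIndex(),
            introns=IntervalIndex(), utr5=IntervalIndex(),
            utr3=IntervalIndex(), promoters=IntervalIndex(), tss=[],
            expressed_tss=[], open_chromatin=IntervalIndex(), histone={},
            repeats={},
        )
        with pytest.raises(ValueError):
            simulate_circles(empty, CircleModel(), samples_mtx)


class TestEmitJunctions:
    def test_zero_circles_zero_background_empty_file(self, tmp_path):
        res = emit_chimeric_junctions(
            [], tmp_path, {"chr1": 10_000},
            samples=[SampleMeta("s1", "MTX", "R", "NT")],
            noise=NoiseParams(0, 0.0), seed=0,
        )
        assert res.junction_paths["s1"].read_text() == ""

    def test_hand_coordinate_conversion(self, tmp_path):
        # circle chr1:1000-1400 (0-based half-open): the donor column holds
        # the first base past the circle body -> 1401 in 1-based file
        # coordinates; acceptor column holds the first circle base -> 1001
        from microdna.intervals import GenomicInterval
        from microdna.synthetic import CircleRecord
        circ = CircleRecord("s1", GenomicInterval("chr1", 1000, 1400), 400)
        res = emit_chimeric_junctions(
            [circ], tmp_path, {"chr1": 10_000},
            reads_per_circle=3.0, noise=NoiseParams(0, 0.0), seed=1,
        )
        lines = res.junction_paths["s1"].read_text().splitlines()
        assert len(lines) == res.n_true_lines["s1"] >= 1
        for ln in lines:
            f = ln.split("\t")
            assert len(f) == 14
            assert (f[0], f[1], f[2], f[3], f[4], f[5]) == (
                "chr1", "1401", "+", "chr1", "1001", "+"
            )
        # parser inverts the emitter exactly
        from microdna.junctions import parse_chimeric_junctions
        recs = parse_chimeric_junctions(res.junction_paths["s1"])
        assert all(r.pos_donor == 1400 and r.pos_acceptor == 1000 for r in recs)

    def test_line_conservation_and_determinism(self, toy, samples_mtx, tmp_path):
        _, _, bundle = toy
        model = CircleModel(n_circles_base=40, seed=3)
        circles = simulate_circles(bundle, model, samples_mtx)
        kw = dict(chrom_sizes=bundle.chrom_sizes, samples=samples_mtx,
                  noise=NoiseParams(2, 0.05), seed=9)
        r1 = emit_chimeric_junctions(circles, tmp_path / "a", **kw)
        r2 = emit_chimeric_junctions(circles, tmp_path / "b", **kw)
        for sid in r1.junction_paths:
            t1 = r1.junction_paths[sid].read_text()
            assert t1 == r2.junction_paths[sid].read_text()
            n_lines = len(t1.splitlines())
            assert n_lines == r1.n_true_lines[sid] + r1.n_background[sid]

    def test_large_jitter_warns(self, tmp_path):
        with pytest.warns(UserWarning, match="jitter"):
            emit_chimeric_junctions(
                [], tmp_path, {"chr1": 1000},
                samples=[SampleMeta("s1", "MTX", "R", "NT")],
                noise=NoiseParams(jitter=15), seed=0,
            )
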