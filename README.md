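# microdna

Detection and genomic characterization of **microDNA** — small
extrachromosomal circular DNAs (eccDNA) shed from unique genomic loci —
from chimeric-junction sequencing evidence, for studies comparing circle
production across cell lines, drug treatments and sensitivity phenotypes.

The package targets experiments in which circle-enriched DNA from
lymphoblastoid cell lines (drug-sensitive/resistant, treated/untreated with
methotrexate or L-asparaginase) is sequenced and aligned with a chimera-aware
aligner. It answers four questions about the resulting circles:

1. **Where do they come from?** Clusters are annotated against exons,
   introns, UTRs, 2-kb promoters, open chromatin, histone marks and repeat
   classes; non-randomness is tested against a length-preserving shuffle
   null (fold = observed / median-of-1000-shuffles, Fisher's exact test)
   and a 5-kb flank null (binomial test).
2. **What size are they?** Mean/central-95%/IQR summaries, plus a ladder
   periodicity estimate: the 10-bp size histogram is detrended and its
   autocorrelation scanned for the internucleosomal ~190 bp period typical
   of apoptotic DNA fragmentation.
3. **How do groups differ?** Mann-Whitney length contrasts and the treated
   share of unique circles per drug and phenotype, with chi-square tests.
4. **Are they reproducible across samples?** Cluster intersects (positional
   sharing within merged segments), gene intersects (same host gene),
   Venn partitions of circle-derived genes across groups, and
   expected-by-chance levels from random re-placement.

## Circle calling

A read that traverses a circular junction aligns as an intrachromosomal
chimera with head-to-tail geometry: same chromosome, same strand, acceptor
breakpoint upstream of the donor. Junctions whose breakpoint pairs lie
within 10 bp of each other at **both** ends are grouped (transitively) into
a cluster; the cluster interval runs from the minimum acceptor to the
maximum donor position, and clusters outside 20–2000 bp are dropped. An
alternative *island method* nominates circles from reads enclosed by
identical leading/trailing soft-clips (the clip is the circle tail read
through the junction) and feeds them into the same clustering.

A seeded synthetic-data generator (toy genome, annotation tracks, biased
circle placement, STAR-style `Chimeric.out.junction` emission with
configurable jitter/background noise, optional SAM) makes the full pipeline
testable without sequencing data.

## Worked example

```python
from microdna import (ToyGenomeSpec, CircleModel, NoiseParams,
                      generate_toy_genome, simulate_circles,
                      emit_chimeric_junctions, default_sample_sheet)
from microdna.junctions import call_clusters_from_file
from microdna.size_stats import estimate_periodicity, size_summary

spec = ToyGenomeSpec(n_chromosomes=2, chrom_length=200_000, n_genes=20, seed=7)
genome, bundle = generate_toy_genome(spec)
samples = [s for s in default_sample_sheet(1) if s.drug == "MTX"]
circles = simulate_circles(bundle, CircleModel(n_circles_base=150, seed=11), samples)
res = emit_chimeric_junctions(circles, "out", bundle.chrom_sizes,
                              samples=samples, noise=NoiseParams(jitter=5),
                              seed=12)
clusters = [c for s in samples
            for c in call_clusters_from_file(res.junction_paths[s.sample_id],
                                             sample_id=s.sample_id)]
lengths = [c.length for c in clusters]
summ = size_summary(lengths)
est = estimate_periodicity(lengths, seed=0)
print(f"{len(clusters)} clusters, mean {summ.mean:.0f} bp, "
      f"IQR {summ.iqr[0]:.0f}-{summ.iqr[1]:.0f} bp, "
      f"ladder period {est.period} bp (significant={est.significant})")
```

prints

```
1137 clusters, mean 443 bp, IQR 243-575 bp, ladder period 190 bp (significant=True)
```

The circles recovered from jittered junction reads include every simulated
circle (treated samples get twice the base count, sensitive samples 1.5x,
so four samples yield ~1125 true circles) plus a few background-noise
calls; their sizes follow
the generator's laddering mixture (components every 190 bp, dominated by
the ~200 and ~390 bp peaks), and the estimator recovers the 190 bp period.

The same stages run end-to-end from a shell:

```sh
microdna run-all --outdir run1 --seed 7        # simulate -> full report
microdna detect sample1.Chimeric.out.junction --out clusters.bed
```

`run-all` writes per-sample cluster BEDs, the per-group feature count
table, enrichment/intersect/size/periodicity TSVs and a `manifest.json`
recording seeds, parameters and per-stage record counts.

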