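import pytest

from microdna.junctions import ChimericJunction, MicroDNACluster
from microdna.intervals import GenomicInterval
from microdna.samples import default_sample_sheet
from microdna.synthetic import ToyGenomeSpec, generate_toy_genome


@pytest.fixture(scope="session")
def toy():
    """Small deterministic genome + annotation bundle shared across tests."""
    spec = ToyGenomeSpec(
        n_chromosomes=2, chrom_length=200_000, n_genes=20, seed=7
    )
    genome, bundle = generate_toy_genome(spec)
    return spec, genome, bundle


@pytest.fixture(scope="session")
def samples_mtx():
    """One sample per MTX condition cell (4 samples)."""
    return [s for s in default_sample_sheet(1) if s.drug == "MTX"]


def make_junction(acceptor, donor, read_id, chrom="chr1", strand="+"):
    return ChimericJunction(
        read_id=read_id,
        chrom_donor=chrom, pos_donor=donor, strand_donor=strand,
        chrom_acceptor=chrom, pos_acceptor=acceptor, strand_acceptor=strand,
    )


def make_cluster(chrom, start, end, sample_id="s1", support=1):
    return MicroDNACluster(
        sample_id, GenomicInterval(chrom, start, end), support,
        frozenset({f"{sample_id}:{chrom}:{start}"}),
    )


def brute_force_components(junctions, extension):
    """Independent oracle: transitive closure of the pairwise relation
    'same chrom & strand, both breakpoints within extension bp', computed
    by repeated merging of index sets."""
    n = len(junctions)
    comps = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for a in range(len(comps)):
            for b in range(a + 1, len(comps)):
                if any(
                    junctions[i].chrom_donor == junctions[j].chrom_donor
                    and junctions[i].strand_donor == junctions[j].strand_donor
                    and abs(junctions[i].pos_acceptor - junctions[j].pos_acceptor) <= extension
                    and abs(junctions[i].pos_donor - junctions[j].pos_donor) <= extension
                    for i in comps[a] for j in comps[b]
                ):
                    comps[a] |= comps[b]
                    del comps[b]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(c) for c in comps}


def random_junctions(rng, n, span=2000, ext_scale=30):
    """Random circular-consistent junctions with clumpy breakpoints."""
    out = []
    for i in range(n):
        acc = int(rng.integers(0, span))
        length = int(rng.integers(20, 500))
        acc += int(rng.integers(0, ext_scale))
        out.append(make_junction(acc, acc + length, f"r{i}"))
    return out
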