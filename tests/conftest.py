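import numpy as np
import pytest

from i3utr.gene_models import GeneModel, GenomicInterval
from i3utr.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def plus_gene() -> GeneModel:
    """Single-exon + strand gene: CDS [100,400), 3'UTR [400,1000), junction 400."""
    return GeneModel(
        "geneA",
        "geneA",
        "chr1",
        "+",
        [GenomicInterval("chr1", 100, 400, "+")],
        [GenomicInterval("chr1", 400, 1000, "+")],
    )


@pytest.fixture
def minus_gene() -> GeneModel:
    """- strand gene: 3'UTR [100,600), CDS [600,900), junction 600."""
    return GeneModel(
        "geneB",
        "geneB",
        "chr1",
        "-",
        [GenomicInterval("chr1", 600, 900, "-")],
        [GenomicInterval("chr1", 100, 600, "-")],
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default 30-gene synthetic scenario, one fixed seed for the session."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def tiny_dataset():
    """A fast 2-replicate subset for pipeline plumbing tests."""
    from i3utr.simulate import default_designs

    designs = [d for d in default_designs() if d.gene_id in
               ("gI01", "gII02", "gIII01", "gU02", "gS01")]
    return simulate_dataset(
        SimulationConfig(seed=7, n_replicates=2, n_ests=50), designs
    )


def make_sam(path, reads, chrom="chr1", chrom_len=100_000):
    """Write a tiny coordinate-sorted BAM + index from (name, pos, cigar, mapq).

    Positions are 0-based; returns the BAM path.
    """
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": chrom_len}]}
    bam = str(path)
    with pysam.AlignmentFile(bam, "wb", header=header) as fh:
        for name, pos, cigar, mapq in sorted(reads, key=lambda r: r[1]):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = name
            a.reference_id = 0
            a.reference_start = pos
            a.cigarstring = cigar
            a.mapping_quality = mapq
            a.query_sequence = "A" * sum(
                n for n, op in _cigar_query_lengths(cigar)
            )
            a.flag = 0
            fh.write(a)
    pysam.index(bam)
    return bam


def _cigar_query_lengths(cigar):
    import re

    for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        if op in "MIS=X":
            yield int(n), op


def brute_force_region_counts(reads, intervals, min_mapq=20):
    """Oracle: per-base depth and read count by iterating reads x positions.

    ``reads`` are (name, pos, cigar, mapq); deletions/introns in the CIGAR
    are handled by walking the reference consumption explicitly.
    """
    import re

    positions = sorted({p for iv in intervals for p in range(iv.start, iv.end)})
    depth = {p: 0 for p in positions}
    names = set()
    for name, pos, cigar, mapq in reads:
        if mapq < min_mapq:
            continue
        ref = pos
        covered = []
        for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
            n = int(n)
            if op in "M=X":
                covered.extend(range(ref, ref + n))
                ref += n
            elif op in "DN":
                ref += n
        hit = False
        for p in covered:
            if p in depth:
                depth[p] += 1
                hit = True
        if hit:
            names.add(name)
    return depth, len(names)


def bruteforce_consensus_peaks(fpkm_arrays, threshold, min_run, min_reps):
    """Independent oracle: explicit per-base boolean matrix + linear run scan."""
    above = np.vstack(fpkm_arrays) > threshold
    consensus = [int(c) >= min_reps for c in above.sum(axis=0).tolist()]
    runs, start = [], None
    for i, ok in enumerate(consensus + [False]):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= min_run:
                runs.append((start, i))
            start = None
    return runs
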