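"""Per-region read counting, effective length, and normalized expression.

Expression here is reads per effective-kilobase per million mapped reads,
where the effective length of a region is the number of its bases with
non-zero coverage (not the annotated length). Reads are counted once per
region they overlap by at least one base, so a read straddling the CDS-3'UTR
junction contributes to both regions' counts — but only once to the gene-level
expressed filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gene_models import GeneModel

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_READS = 5


@dataclass
class CoverageTrack:
    """Per-base depth over one gene region for one replicate.

    ``depth`` is transcript-oriented (index 0 is the region's 5' end on the
    transcript); ``total_mapped_reads`` is the replicate's library size.
    """

    replicate_id: str
    depth: np.ndarray
    total_mapped_reads: int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")
        if (self.depth < 0).any():
            raise ValueError("depth must be non-negative")

    @property
    def effective_length_bp(self) -> int:
        return int(np.count_nonzero(self.depth))


@dataclass
class RegionExpression:
    read_count: int
    effective_length_bp: int
    expression: float


def normalized_expression(
    read_count: int, effective_length_bp: int, total_mapped_reads: int
) -> float:
    """reads / (effective length in kb x library size in millions).

    Zero reads give expression 0 regardless of effective length; a positive
    count with zero effective length is an impossible state.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    if read_count == 0:
        return 0.0
    if effective_length_bp == 0:
        raise ValueError(
            "impossible state: reads assigned to a region with zero covered bases"
        )
    return read_count / (
        (effective_length_bp / 1_000) * (total_mapped_reads / 1_000_000)
    )


def is_expressed(
    read_count_cds: int,
    read_count_utr: int,
    n_straddling: int = 0,
    min_reads: int = DEFAULT_MIN_READS,
) -> bool:
    """Gene-level expressed filter: total assigned reads >= ``min_reads``.

    ``n_straddling`` is the number of junction-straddling reads already
    present in both per-region counts; it is subtracted so each read counts
    once in the gene total.
    """
    if min(read_count_cds, read_count_utr, n_straddling) < 0:
        raise ValueError("read counts must be non-negative")
    return read_count_cds + read_count_utr - n_straddling >= min_reads


def region_expression(track: CoverageTrack, read_count: int) -> RegionExpression:
    return RegionExpression(
        read_count=read_count,
        effective_length_bp=track.effective_length_bp,
        expression=normalized_expression(
            read_count, track.effective_length_bp, track.total_mapped_reads
        ),
    )


# ---------------------------------------------------------------------------
# BAM ingestion
# ---------------------------------------------------------------------------


def _keep_read(read, min_mapq: int) -> bool:
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and read.mapping_quality >= min_mapq
    )


def region_coverage(
    bam_path: str | Path,
    model: GeneModel,
    region: str,
    replicate_id: str = "rep",
    total_mapped_reads: int | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> tuple[CoverageTrack, int]:
    """Per-base depth over a gene region and the count of reads assigned to it.

    A primary alignment with MAPQ >= ``min_mapq`` overlapping the region by
    >= 1 aligned base is assigned to it. Depth is computed from aligned
    blocks (CIGAR-aware), then orientated 5'->3' on the transcript. When
    ``total_mapped_reads`` is not given, the number of kept primary
    alignments in the whole file is used.
    """
    import pysam

    intervals = model.region_intervals(region)
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if model.chrom not in bam.references:
            raise ValueError(f"chromosome {model.chrom!r} absent from {bam_path}")
        if total_mapped_reads is None:
            total_mapped_reads = sum(
                1 for r in bam.fetch(until_eof=True) if _keep_read(r, min_mapq)
            )
            if total_mapped_reads == 0:
                warnings.warn(f"{bam_path}: no usable alignments")
                total_mapped_reads = 1
        depth_parts: dict[int, np.ndarray] = {
            i: np.zeros(iv.length, dtype=np.int64)
            for i, iv in enumerate(intervals)
        }
        assigned: set[str] = set()
        for i, iv in enumerate(intervals):
            arr = depth_parts[i]
            for read in bam.fetch(iv.chrom, iv.start, iv.end):
                if not _keep_read(read, min_mapq):
                    continue
                hit = False
                for b_start, b_end in read.get_blocks():
                    lo, hi = max(b_start, iv.start), min(b_end, iv.end)
                    if lo < hi:
                        arr[lo - iv.start : hi - iv.start] += 1
                        hit = True
                if hit:
                    assigned.add(read.query_name)
    ordered = (
        [depth_parts[i] for i in range(len(intervals))]
        if model.strand == "+"
        else [depth_parts[i][::-1] for i in reversed(range(len(intervals)))]
    )
    depth = np.concatenate(ordered) if ordered else np.zeros(0, dtype=np.int64)
    track = CoverageTrack(replicate_id, depth, total_mapped_reads)
    return track, len(assigned)


def count_straddling_reads(
    bam_path: str | Path, model: GeneModel, min_mapq: int = DEFAULT_MIN_MAPQ
) -> int:
    """Number of reads whose aligned blocks touch both the CDS and the 3'UTR."""
    import pysam

    span = model.span
    n = 0
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam.fetch(span.chrom, span.start, span.end):
            if not _keep_read(read, min_mapq):
                continue
            blocks = read.get_blocks()

            def touches(ivs) -> bool:
                return any(
                    max(bs, iv.start) < min(be, iv.end)
                    for bs, be in blocks
                    for iv in ivs
                )

            if touches(model.cds_intervals) and touches(model.utr3_intervals):
                n += 1
    return n


# ---------------------------------------------------------------------------
# bedGraph ingestion
# ---------------------------------------------------------------------------


def read_bedgraph(path: str | Path) -> dict[str, list[tuple[int, int, float]]]:
    """Parse a bedGraph file into {chrom: [(start, end, value), ...]}."""
    out: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
            out.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
    for runs in out.values():
        runs.sort()
    return out


def coverage_from_bedgraph(
    bedgraph: dict[str, list[tuple[int, int, float]]] | str | Path,
    model: GeneModel,
    region: str,
    replicate_id: str,
    total_mapped_reads: int,
) -> CoverageTrack:
    """Build a transcript-oriented CoverageTrack for a region from bedGraph runs.

    bedGraph carries depth only; per-region read counts must come from a
    companion count table (see :func:`read_region_counts`).
    """
    if not isinstance(bedgraph, dict):
        bedgraph = read_bedgraph(bedgraph)
    runs = bedgraph.get(model.chrom, [])
    intervals = model.region_intervals(region)
    parts = []
    for iv in intervals:
        arr = np.zeros(iv.length, dtype=np.int64)
        for s, e, v in runs:
            lo, hi = max(s, iv.start), min(e, iv.end)
            if lo < hi:
                arr[lo - iv.start : hi - iv.start] = int(round(v))
        parts.append(arr)
    if model.strand == "-":
        parts = [p[::-1] for p in reversed(parts)]
    depth = np.concatenate(parts) if parts else np.zeros(0, dtype=np.int64)
    return CoverageTrack(replicate_id, depth, total_mapped_reads)


def read_region_counts(path: str | Path) -> dict[tuple[str, str], int]:
    """Read a TSV of per-gene-region read counts: gene_id, region, read_count."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "region", "read_count"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: columns {sorted(required)} required")
    return {
        (str(r.gene_id), str(r.region).upper()): int(r.read_count)
        for r in df.itertuples()
    }
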