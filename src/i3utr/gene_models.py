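"""Gene models: strand-aware CDS and 3'UTR interval sets with a defined junction.

All internal coordinates are 0-based half-open (BED convention); the GTF/GFF3
reader converts from 1-based closed at the boundary. "Upstream"/"downstream"
are always transcript-oriented: on the minus strand they run right-to-left in
genomic coordinates.

The junction is the transcript position where the coding sequence ends and the
3'UTR begins (the stop-codon boundary). On the plus strand it equals the
maximal CDS end; on the minus strand, the minimal CDS start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

Strand = Literal["+", "-"]

_UTR3_FEATURES = {"three_prime_utr", "three_prime_UTR", "3UTR", "UTR3"}


class AnnotationError(ValueError):
    """Raised when an annotation file cannot be parsed into gene models."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: Strand = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class FlankBin:
    """One transcript-oriented bin flanking the CDS-3'UTR junction.

    ``offset`` is signed in bin units: -1 is the bin immediately 5' (CDS side)
    of the junction, +1 immediately 3' (UTR side). ``partial`` marks bins
    clipped at the gene boundary.
    """

    offset: int
    interval: GenomicInterval
    partial: bool = False


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Union of intervals: sorted, disjoint, adjacent runs merged."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            last = out[-1]
            if iv.end > last.end:
                out[-1] = GenomicInterval(
                    last.chrom, last.start, iv.end, last.strand
                )
        else:
            out.append(iv)
    return out


def subtract_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference a \\ b, both assumed merged; preserves a's strand."""
    out: list[GenomicInterval] = []
    for iv in a:
        cuts = [
            (max(iv.start, x.start), min(iv.end, x.end))
            for x in b
            if x.chrom == iv.chrom and x.start < iv.end and x.end > iv.start
        ]
        pos = iv.start
        for cs, ce in sorted(cuts):
            if cs > pos:
                out.append(GenomicInterval(iv.chrom, pos, cs, iv.strand))
            pos = max(pos, ce)
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end, iv.strand))
    return out


def total_length(intervals: Sequence[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


@dataclass
class GeneModel:
    """CDS and 3'UTR interval model for one gene.

    ``cds_intervals`` and ``utr3_intervals`` are sorted by genomic start,
    internally and mutually disjoint. ``junction`` is a genomic coordinate:
    for ``+`` genes the half-open boundary where the CDS ends (the junction
    base itself belongs to the 3'UTR side); mirrored on ``-``.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: Strand
    cds_intervals: list[GenomicInterval]
    utr3_intervals: list[GenomicInterval]
    junction: int = field(init=False)

    def __post_init__(self) -> None:
        self.cds_intervals = merge_intervals(self.cds_intervals)
        self.utr3_intervals = merge_intervals(self.utr3_intervals)
        if not self.cds_intervals or not self.utr3_intervals:
            raise ValueError(
                f"{self.gene_id}: both a CDS and a 3'UTR are required"
            )
        overlap = sum(
            c.overlap_bp(u)
            for c in self.cds_intervals
            for u in self.utr3_intervals
        )
        if overlap:
            # bases claimed by both unions are assigned to the CDS
            self.utr3_intervals = subtract_intervals(
                self.utr3_intervals, self.cds_intervals
            )
            if not self.utr3_intervals:
                raise ValueError(f"{self.gene_id}: 3'UTR fully inside CDS")
        if self.strand == "+":
            self.junction = max(iv.end for iv in self.cds_intervals)
        else:
            self.junction = min(iv.start for iv in self.cds_intervals)

    @property
    def cds_length(self) -> int:
        return total_length(self.cds_intervals)

    @property
    def utr3_length(self) -> int:
        return total_length(self.utr3_intervals)

    @property
    def span(self) -> GenomicInterval:
        """Genomic span from first CDS/UTR base to last."""
        ivs = self.cds_intervals + self.utr3_intervals
        return GenomicInterval(
            self.chrom,
            min(iv.start for iv in ivs),
            max(iv.end for iv in ivs),
            self.strand,
        )

    def region_intervals(self, region: str) -> list[GenomicInterval]:
        region = region.upper()
        if region == "CDS":
            return self.cds_intervals
        if region in ("UTR3", "3UTR", "UTR"):
            return self.utr3_intervals
        raise ValueError(f"unknown region {region!r}")

    # -- spliced (transcript-oriented) coordinate helpers -----------------

    def spliced_length(self, region: str) -> int:
        return total_length(self.region_intervals(region))

    def genomic_to_spliced(self, region: str, pos: int) -> int | None:
        """Map a genomic position into 5'->3' offsets within the spliced region."""
        ivs = self.region_intervals(region)
        order = ivs if self.strand == "+" else list(reversed(ivs))
        off = 0
        for iv in order:
            if iv.contains(pos):
                return off + (
                    pos - iv.start if self.strand == "+" else iv.end - 1 - pos
                )
            off += iv.length
        return None

    def spliced_to_genomic(
        self, region: str, start: int, end: int
    ) -> list[GenomicInterval]:
        """Project a spliced [start, end) window back to genomic intervals."""
        if not 0 <= start < end <= self.spliced_length(region):
            raise ValueError(f"spliced window [{start},{end}) out of range")
        ivs = self.region_intervals(region)
        order = ivs if self.strand == "+" else list(reversed(ivs))
        out: list[GenomicInterval] = []
        off = 0
        for iv in order:
            lo, hi = max(start, off), min(end, off + iv.length)
            if lo < hi:
                if self.strand == "+":
                    out.append(
                        GenomicInterval(
                            iv.chrom, iv.start + lo - off, iv.start + hi - off, "+"
                        )
                    )
                else:
                    out.append(
                        GenomicInterval(
                            iv.chrom, iv.end - (hi - off), iv.end - (lo - off), "-"
                        )
                    )
            off += iv.length
        return merge_intervals(out)


def junction_flank(
    model: GeneModel, bin_size: int, n_bins: int
) -> list[FlankBin]:
    """Transcript-oriented fixed-width bins on each side of the junction.

    Bin -1 covers the ``bin_size`` bases immediately 5' of the junction (CDS
    side), bin +1 the bases immediately 3' (UTR side). Bins are clipped to
    the gene span and flagged partial when clipped; bins falling entirely
    outside the span are dropped.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    span = model.span
    sign = 1 if model.strand == "+" else -1
    bins: list[FlankBin] = []
    for k in range(-n_bins, n_bins + 1):
        if k == 0:
            continue
        # transcript offsets of the bin relative to the junction
        t_lo, t_hi = (k * bin_size, (k + 1) * bin_size) if k < 0 else (
            (k - 1) * bin_size,
            k * bin_size,
        )
        g = sorted((model.junction + sign * t_lo, model.junction + sign * t_hi))
        lo, hi = max(g[0], span.start), min(g[1], span.end)
        if lo >= hi:
            continue
        partial = (hi - lo) < bin_size
        bins.append(
            FlankBin(k, GenomicInterval(model.chrom, lo, hi, model.strand), partial)
        )
    return bins


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------


def load_gene_models(
    annotation_file: str | Path,
    transcript_policy: str = "union",
) -> list[GeneModel]:
    """Parse GTF/GFF3 or BED12 into one :class:`GeneModel` per gene.

    Multi-transcript genes are collapsed under ``transcript_policy``:
    ``union`` takes the union of CDS intervals and of 3'UTR intervals across
    transcripts (shared bases go to the CDS); ``longest_transcript`` keeps
    the transcript with the longest CDS+UTR extent. Genes lacking a CDS or a
    3'UTR, or with CDS on both strands, are skipped with a warning.
    """
    path = Path(annotation_file)
    if transcript_policy not in ("union", "longest_transcript"):
        raise ValueError(f"unknown transcript_policy {transcript_policy!r}")
    suffix = path.suffix.lower()
    if suffix == ".bed":
        per_tx = _parse_bed12(path)
    elif suffix in (".gtf", ".gff", ".gff3"):
        per_tx = _parse_gxf(path)
    else:
        raise AnnotationError(f"unrecognized annotation format: {path.name}")
    return _collapse(per_tx, transcript_policy)


def _collapse(per_tx: dict, transcript_policy: str) -> list[GeneModel]:
    models: list[GeneModel] = []
    for gene_id in sorted(per_tx):
        transcripts = per_tx[gene_id]
        strands = {t["strand"] for t in transcripts.values()}
        if len(strands) > 1:
            warnings.warn(f"{gene_id}: CDS on both strands; gene skipped")
            continue
        if transcript_policy == "longest_transcript":
            def extent(t: dict) -> int:
                return total_length(t["cds"]) + total_length(t["utr3"])

            best = max(transcripts.values(), key=extent)
            cds, utr3 = best["cds"], best["utr3"]
            name, chrom, strand = best["gene_name"], best["chrom"], best["strand"]
        else:
            cds = [iv for t in transcripts.values() for iv in t["cds"]]
            utr3 = [iv for t in transcripts.values() for iv in t["utr3"]]
            any_t = next(iter(transcripts.values()))
            name, chrom, strand = any_t["gene_name"], any_t["chrom"], any_t["strand"]
        if not cds or not utr3:
            missing = "CDS" if not cds else "3'UTR"
            warnings.warn(f"{gene_id}: missing {missing}; gene skipped")
            continue
        try:
            models.append(
                GeneModel(gene_id, name, chrom, strand, cds, utr3)
            )
        except ValueError as exc:
            warnings.warn(f"{gene_id}: {exc}; gene skipped")
    return models


def _parse_gxf(path: Path) -> dict:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises a zoo of exception types
        raise AnnotationError(f"cannot parse {path.name}: {exc}") from exc

    def attr(feat, *keys: str) -> str | None:
        for k in keys:
            if k in feat.attributes:
                return feat.attributes[k][0]
        return None

    per_tx: dict[str, dict[str, dict]] = {}
    explicit_utr: set[str] = set()
    for feat in db.all_features():
        ftype = feat.featuretype
        is_cds = ftype == "CDS"
        is_utr3 = ftype in _UTR3_FEATURES
        is_exon = ftype == "exon"
        if not (is_cds or is_utr3 or is_exon):
            continue
        gid = attr(feat, "gene_id", "gene", "Parent")
        tid = attr(feat, "transcript_id", "ID", "Parent") or gid
        if gid is None:
            raise AnnotationError(
                f"{path.name}: feature at line with no gene_id "
                f"({feat.seqid}:{feat.start}-{feat.end})"
            )
        gname = attr(feat, "gene_name") or gid
        tx = per_tx.setdefault(gid, {}).setdefault(
            tid,
            {
                "gene_name": gname,
                "chrom": feat.seqid,
                "strand": feat.strand,
                "cds": [],
                "utr3": [],
                "exon": [],
            },
        )
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if is_cds:
            tx["cds"].append(iv)
        elif is_utr3:
            tx["utr3"].append(iv)
            explicit_utr.add(gid)
        else:
            tx["exon"].append(iv)
    # no explicit 3'UTR features: derive as exonic minus CDS, 3' of the CDS
    for gid, txs in per_tx.items():
        if gid in explicit_utr:
            continue
        for tx in txs.values():
            if tx["cds"] and tx["exon"]:
                tx["utr3"] = _utr3_from_exons(
                    merge_intervals(tx["exon"]), merge_intervals(tx["cds"]),
                    tx["strand"],
                )
    return per_tx


def _utr3_from_exons(
    exons: list[GenomicInterval],
    cds: list[GenomicInterval],
    strand: Strand,
) -> list[GenomicInterval]:
    non_cds = subtract_intervals(exons, cds)
    if strand == "+":
        junction = max(iv.end for iv in cds)
        return [iv for iv in non_cds if iv.start >= junction]
    junction = min(iv.start for iv in cds)
    return [iv for iv in non_cds if iv.end <= junction]


def _parse_bed12(path: Path) -> dict:
    per_tx: dict[str, dict[str, dict]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(
                    f"{path.name}:{lineno}: BED12 requires 12 fields, got {len(f)}"
                )
            try:
                chrom, start = f[0], int(f[1])
                name, strand = f[3], f[5]
                thick_start, thick_end = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path.name}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationError(
                    f"{path.name}:{lineno}: block count mismatch"
                )
            # name convention: gene_id or gene_id|transcript_id
            gid, _, tid = name.partition("|")
            tid = tid or gid
            exons = [
                GenomicInterval(chrom, start + s, start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
            cds: list[GenomicInterval] = []
            if thick_start < thick_end:
                thick = GenomicInterval(chrom, thick_start, thick_end, strand)
                for ex in exons:
                    ov = ex.overlap_bp(thick)
                    if ov:
                        cds.append(
                            GenomicInterval(
                                chrom,
                                max(ex.start, thick_start),
                                min(ex.end, thick_end),
                                strand,
                            )
                        )
            utr3 = (
                _utr3_from_exons(merge_intervals(exons), merge_intervals(cds), strand)
                if cds
                else []
            )
            per_tx.setdefault(gid, {})[tid] = {
                "gene_name": gid,
                "chrom": chrom,
                "strand": strand,
                "cds": cds,
                "utr3": utr3,
            }
    return per_tx


def write_bed12(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12, one line per gene (CDS = thick region).

    Round-trips through :func:`load_gene_models` as long as CDS and 3'UTR
    are genomically contiguous on the 3' side (the BED12 thick region cannot
    encode a CDS interleaved with UTR exons, which never arises here).
    """
    with open(path, "w") as fh:
        for m in models:
            exons = merge_intervals(m.cds_intervals + m.utr3_intervals)
            start = exons[0].start
            end = exons[-1].end
            thick_lo = min(iv.start for iv in m.cds_intervals)
            thick_hi = max(iv.end for iv in m.cds_intervals)
            sizes = ",".join(str(iv.length) for iv in exons)
            offs = ",".join(str(iv.start - start) for iv in exons)
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(start),
                        str(end),
                        m.gene_id,
                        "0",
                        m.strand,
                        str(thick_lo),
                        str(thick_hi),
                        "0",
                        str(len(exons)),
                        sizes,
                        offs,
                    ]
                )
                + "\n"
            )


def write_region_bed6(models: Sequence[GeneModel], path: str | Path) -> None:
    """Per-gene region BED6 (name = gene_id|CDS or gene_id|UTR3)."""
    with open(path, "w") as fh:
        for m in models:
            for label, ivs in (("CDS", m.cds_intervals), ("UTR3", m.utr3_intervals)):
                for iv in ivs:
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                        f"{m.gene_id}|{label}\t0\t{m.strand}\n"
                    )
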