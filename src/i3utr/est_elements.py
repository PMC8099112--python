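"""EST/fragment classification against gene models and element-track alignment.

Fragments (e.g. ESTs) are classified by their overlap with a gene's CDS and
3'UTR interval sets: 3'UTR-only, CDS-only, junction-spanning ("mixed"), or
outside the gene. Because coordinates are half-open, a fragment ending
exactly at the junction touches only the CDS side; the junction base itself
belongs to the 3'UTR.

Element tracks (CpG islands, TF clusters, miRNA sites, H3K27ac, DNase) are
assigned by midpoint to consensus peaks, valleys or elsewhere within the
gene span, with a length-preserving uniform-placement permutation test
supplying an empirical enrichment p-value.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .gene_models import FlankBin, GeneModel, GenomicInterval, junction_flank
from .peaks import PeakSet


class FragmentClass(str, enum.Enum):
    UTR_ONLY = "UTR_ONLY"
    CDS_ONLY = "CDS_ONLY"
    MIXED = "MIXED"
    OUTSIDE = "OUTSIDE"


class ElementCategory(str, enum.Enum):
    CpG = "CpG"
    TF_cluster = "TF_cluster"
    miRNA_site = "miRNA_site"
    H3K27ac = "H3K27ac"
    DNase = "DNase"
    other = "other"


@dataclass
class ESTClassSummary:
    gene_id: str
    n_total: int
    n_utr_only: int
    n_cds_only: int
    n_mixed: int
    n_outside: int
    n_spanning_internal_valley: int = 0

    @property
    def frac_utr_only(self) -> float:
        return self.n_utr_only / self.n_total if self.n_total else float("nan")

    @property
    def frac_cds_only(self) -> float:
        return self.n_cds_only / self.n_total if self.n_total else float("nan")

    @property
    def frac_mixed(self) -> float:
        return self.n_mixed / self.n_total if self.n_total else float("nan")


@dataclass
class JunctionBinProfile:
    """Per-250-bp-bin EST overlap fractions around the CDS-3'UTR junction."""

    bin_size: int
    bins: list[FlankBin]
    fractions: dict[int, float]  # signed bin offset -> fraction of n_total


@dataclass
class ElementOverlapReport:
    category: str
    n_in_peaks: int
    n_in_valleys: int
    n_elsewhere: int
    n_outside_gene: int = 0
    empirical_p: float | None = None

    @property
    def n_total(self) -> int:
        return self.n_in_peaks + self.n_in_valleys + self.n_elsewhere

    @property
    def peak_fraction(self) -> float:
        return self.n_in_peaks / self.n_total if self.n_total else float("nan")


def _overlap_bp(
    fragment: GenomicInterval, intervals: Sequence[GenomicInterval]
) -> int:
    return sum(fragment.overlap_bp(iv) for iv in intervals)


def classify_fragment(
    fragment: GenomicInterval, model: GeneModel, min_overlap_bp: int = 1
) -> FragmentClass:
    """UTR_ONLY / CDS_ONLY / MIXED / OUTSIDE by >= min_overlap_bp overlap."""
    in_cds = _overlap_bp(fragment, model.cds_intervals) >= min_overlap_bp
    in_utr = _overlap_bp(fragment, model.utr3_intervals) >= min_overlap_bp
    if in_cds and in_utr:
        return FragmentClass.MIXED
    if in_utr:
        return FragmentClass.UTR_ONLY
    if in_cds:
        return FragmentClass.CDS_ONLY
    return FragmentClass.OUTSIDE


def _valley_genomic_spans(
    peakset: PeakSet, model: GeneModel
) -> list[GenomicInterval]:
    spans = []
    for vs, ve in peakset.valleys:
        pieces = model.spliced_to_genomic("UTR3", vs, ve)
        spans.append(
            GenomicInterval(
                model.chrom,
                min(p.start for p in pieces),
                max(p.end for p in pieces),
                model.strand,
            )
        )
    return spans


def summarize_ests(
    fragments: Sequence[GenomicInterval],
    model: GeneModel,
    peakset: PeakSet | None = None,
    bin_size: int = 250,
    n_bins: int = 8,
    min_overlap_bp: int = 1,
) -> tuple[ESTClassSummary, JunctionBinProfile]:
    """Class counts/fractions, junction-bin profile, and valley-spanning count.

    Fractions are over fragments overlapping the gene (OUTSIDE fragments are
    excluded from ``n_total`` and reported separately). A fragment "spans"
    an internal valley when its genomic extent covers the valley's full
    genomic span. The junction profile reports, for each signed ``bin_size``
    bin around the junction, the fraction of counted ESTs overlapping it.
    """
    counts = {c: 0 for c in FragmentClass}
    kept: list[GenomicInterval] = []
    for frag in fragments:
        c = classify_fragment(frag, model, min_overlap_bp)
        counts[c] += 1
        if c is not FragmentClass.OUTSIDE:
            kept.append(frag)
    n_total = len(kept)

    n_span = 0
    if peakset is not None and peakset.valleys:
        # only valleys strictly between two peaks count as internal
        internal = [
            (vs, ve)
            for vs, ve in peakset.valleys
            if any(p.end <= vs for p in peakset.peaks)
            and any(ve <= p.start for p in peakset.peaks)
        ]
        ps_internal = PeakSet(peakset.gene_id, peakset.peaks, internal)
        for span in _valley_genomic_spans(ps_internal, model):
            n_span += sum(
                1
                for frag in kept
                if frag.chrom == span.chrom
                and frag.start <= span.start
                and frag.end >= span.end
            )

    bins = junction_flank(model, bin_size, n_bins)
    fractions = {
        b.offset: (
            sum(1 for frag in kept if frag.overlap_bp(b.interval) >= 1) / n_total
            if n_total
            else float("nan")
        )
        for b in bins
    }
    summary = ESTClassSummary(
        gene_id=model.gene_id,
        n_total=n_total,
        n_utr_only=counts[FragmentClass.UTR_ONLY],
        n_cds_only=counts[FragmentClass.CDS_ONLY],
        n_mixed=counts[FragmentClass.MIXED],
        n_outside=counts[FragmentClass.OUTSIDE],
        n_spanning_internal_valley=n_span,
    )
    return summary, JunctionBinProfile(bin_size, bins, fractions)


# ---------------------------------------------------------------------------
# Element tracks
# ---------------------------------------------------------------------------


def _region_lookup(
    peakset: PeakSet, model: GeneModel
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    peak_ivs = [iv for p in peakset.peaks for iv in
                (p.genomic_intervals or model.spliced_to_genomic("UTR3", p.start, p.end))]
    valley_ivs = [
        iv
        for vs, ve in peakset.valleys
        for iv in model.spliced_to_genomic("UTR3", vs, ve)
    ]
    return peak_ivs, valley_ivs


def _assign_midpoint(
    mid: int,
    peak_ivs: Sequence[GenomicInterval],
    valley_ivs: Sequence[GenomicInterval],
    span: GenomicInterval,
) -> str:
    if not span.contains(mid):
        return "outside"
    if any(iv.contains(mid) for iv in peak_ivs):
        return "peak"
    if any(iv.contains(mid) for iv in valley_ivs):
        return "valley"
    return "elsewhere"


def element_overlap(
    elements: Sequence[tuple[GenomicInterval, str]],
    peakset: PeakSet,
    model: GeneModel,
) -> dict[str, ElementOverlapReport]:
    """Assign each element by midpoint to peak / valley / elsewhere, per category.

    Elements whose midpoint falls outside the gene span are excluded from the
    three in-gene counts and tallied separately.
    """
    peak_ivs, valley_ivs = _region_lookup(peakset, model)
    span = model.span
    reports: dict[str, ElementOverlapReport] = {}
    for iv, category in elements:
        rep = reports.setdefault(
            category, ElementOverlapReport(category, 0, 0, 0, 0)
        )
        where = _assign_midpoint(
            (iv.start + iv.end) // 2, peak_ivs, valley_ivs, span
        )
        if where == "peak":
            rep.n_in_peaks += 1
        elif where == "valley":
            rep.n_in_valleys += 1
        elif where == "elsewhere":
            rep.n_elsewhere += 1
        else:
            rep.n_outside_gene += 1
    return reports


def element_permutation_test(
    elements: Sequence[GenomicInterval],
    peakset: PeakSet,
    model: GeneModel,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Empirical p-value for peak enrichment of one element category.

    Null: each element is placed uniformly (length-preserving) within the
    gene span, independently; the statistic is the fraction of elements whose
    midpoint lands in a consensus peak.  p = (1 + #{null >= observed}) /
    (1 + n_perm), so p is never 0 and is deterministic given the seed.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if not elements:
        raise ValueError("at least one element required")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    span = model.span
    peak_ivs, valley_ivs = _region_lookup(peakset, model)
    peak_bp = sum(iv.length for iv in peak_ivs)
    if peak_bp >= span.length:
        warnings.warn("peaks cover the entire gene span; test degenerate, p=1")
        return 1.0

    def peak_fraction(mids: np.ndarray) -> np.ndarray:
        hit = np.zeros(mids.shape, dtype=bool)
        for iv in peak_ivs:
            hit |= (mids >= iv.start) & (mids < iv.end)
        return hit.mean(axis=-1)

    obs_mids = np.array([(iv.start + iv.end) // 2 for iv in elements])
    observed = float(peak_fraction(obs_mids))
    lengths = np.array([iv.length for iv in elements])
    # uniform start in [span.start, span.end - len]; midpoint follows
    max_start = np.maximum(span.end - lengths, span.start + 1)
    starts = rng.integers(
        span.start, max_start, size=(n_perm, len(elements))
    )
    mids = starts + lengths // 2
    null = peak_fraction(mids)
    return float((1 + int((null >= observed - 1e-12).sum())) / (1 + n_perm))


# ---------------------------------------------------------------------------
# BED6 I/O
# ---------------------------------------------------------------------------


def read_bed6(
    path: str | Path, with_category: bool = False
) -> list[tuple[GenomicInterval, str]]:
    """Read BED6 into (interval, name) pairs.

    With ``with_category`` the element category is taken from column 7 when
    present, else from the name field.
    """
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            name = f[3] if len(f) > 3 else f"feature{lineno}"
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
            label = f[6] if (with_category and len(f) > 6) else name
            out.append(
                (GenomicInterval(f[0], int(f[1]), int(f[2]), strand), label)
            )
    return out


def write_bed6(
    records: Sequence[tuple[GenomicInterval, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for iv, name in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
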