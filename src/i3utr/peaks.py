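"""Replicate-consensus 3'UTR coverage peak/valley calling and pattern typing.

A peak is a maximal run of more than 150 bp in which per-base coverage FPKM
exceeds 100 in every required replicate; a valley is the opposite (at or
below threshold in every required replicate), restricted to the annotated
3'UTR. Per-base FPKM treats each base as a 1-bp feature:

    fpkm[i] = depth[i] / (0.001 kb x total_mapped_reads / 1e6)
            = depth[i] x 1e9 / total_mapped_reads

so peak calls are invariant to scaling depth and library size together.

Pattern types of 3'UTR expression:

* TYPE_I   — two or more discrete peaks inside the 3'UTR proper, separated
             by at least one valley;
* TYPE_II  — a single peak continuous with (or starting within 50 bp of)
             the CDS junction, running into a short 3'UTR;
* TYPE_III — a long 3'UTR with peaks, where above-threshold CDS coverage is
             confined to a short leading stretch adjacent to the junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .gene_models import GeneModel, GenomicInterval


class PatternType(str, Enum):
    TYPE_I = "TYPE_I"
    TYPE_II = "TYPE_II"
    TYPE_III = "TYPE_III"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class PeakParams:
    fpkm_threshold: float = 100.0
    min_run_bp: int = 151  # strictly > 150 bp
    min_replicates: int | None = None  # None: all supplied replicates
    short_utr_max_bp: int = 1000
    long_utr_min_bp: int = 2000
    junction_slack_bp: int = 50
    cds_terminal_fraction: float = 0.25
    consensus: str = "per_base"  # or "per_replicate_intersection"

    def __post_init__(self) -> None:
        if self.fpkm_threshold <= 0:
            raise ValueError("fpkm_threshold must be positive")
        if self.min_run_bp < 1:
            raise ValueError("min_run_bp must be >= 1")
        if self.consensus not in ("per_base", "per_replicate_intersection"):
            raise ValueError(f"unknown consensus mode {self.consensus!r}")

    def required_replicates(self, n_supplied: int) -> int:
        k = self.min_replicates if self.min_replicates is not None else n_supplied
        if not 1 <= k <= n_supplied:
            raise ValueError(
                f"min_replicates={k} incompatible with {n_supplied} replicates"
            )
        return k


@dataclass
class Peak:
    """A consensus peak in spliced 3'UTR coordinates (offsets from junction)."""

    start: int
    end: int
    mean_fpkm_per_replicate: list[float]
    n_supporting_replicates: int
    genomic_intervals: list[GenomicInterval] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    gene_id: str
    peaks: list[Peak]
    valleys: list[tuple[int, int]]
    pattern_type: PatternType = PatternType.UNCLASSIFIED
    rule_trace: str = ""


def per_base_fpkm(depth: np.ndarray, total_mapped_reads: int) -> np.ndarray:
    """Depth normalized as 1-bp features per kb per million mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return np.asarray(depth, dtype=float) * 1e9 / total_mapped_reads


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as half-open (start, end)."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def _stack(fpkm_arrays: Sequence[np.ndarray]) -> np.ndarray:
    if not fpkm_arrays:
        raise ValueError("at least one replicate array required")
    lengths = {len(a) for a in fpkm_arrays}
    if len(lengths) > 1:
        raise ValueError(f"replicate arrays of unequal length: {sorted(lengths)}")
    return np.vstack([np.asarray(a, dtype=float) for a in fpkm_arrays])


def call_consensus_peaks(
    fpkm_arrays: Sequence[np.ndarray],
    params: PeakParams = PeakParams(),
) -> list[Peak]:
    """Maximal runs > ``min_run_bp - 1`` where FPKM > threshold in enough replicates.

    Default consensus intersects bases first (FPKM strictly above threshold
    at the same base in >= min_replicates replicates) and then applies the
    run-length bound. The ``per_replicate_intersection`` mode instead calls
    length-filtered peaks per replicate and intersects the resulting
    intervals, re-applying the length bound to the intersection.
    """
    mat = _stack(fpkm_arrays)
    k = params.required_replicates(mat.shape[0])
    above = mat > params.fpkm_threshold
    if params.consensus == "per_base":
        consensus = above.sum(axis=0) >= k
    else:
        per_rep = np.zeros_like(above)
        for i in range(above.shape[0]):
            for s, e in _runs(above[i]):
                if e - s >= params.min_run_bp:
                    per_rep[i, s:e] = True
        consensus = per_rep.sum(axis=0) >= k
    peaks = []
    for s, e in _runs(consensus):
        if e - s >= params.min_run_bp:
            means = mat[:, s:e].mean(axis=1)
            n_support = int((above[:, s:e].all(axis=1)).sum())
            peaks.append(
                Peak(
                    start=s,
                    end=e,
                    mean_fpkm_per_replicate=[float(m) for m in means],
                    n_supporting_replicates=n_support,
                )
            )
    return peaks


def call_valleys(
    fpkm_arrays: Sequence[np.ndarray],
    peaks: Sequence[Peak],
    params: PeakParams = PeakParams(),
) -> list[tuple[int, int]]:
    """Maximal runs > ``min_run_bp - 1`` at or below threshold in enough replicates.

    The <= threshold condition complements the strict peak inequality, so
    every base decided in all replicates belongs to at most one of the two
    sets. Valleys lie within the annotated 3'UTR by construction (the input
    arrays cover exactly the spliced 3'UTR).
    """
    mat = _stack(fpkm_arrays)
    k = params.required_replicates(mat.shape[0])
    below = (mat <= params.fpkm_threshold).sum(axis=0) >= k
    # never label peak interior as valley, whatever the replicate rule
    for p in peaks:
        below[p.start : p.end] = False
    return [(s, e) for s, e in _runs(below) if e - s >= params.min_run_bp]


def project_peaks(peakset: PeakSet, model: GeneModel) -> PeakSet:
    """Fill each peak's genomic projection through the spliced 3'UTR map."""
    for p in peakset.peaks:
        p.genomic_intervals = model.spliced_to_genomic("UTR3", p.start, p.end)
    return peakset


def classify_pattern(
    peakset: PeakSet,
    model: GeneModel,
    cds_fpkm_arrays: Sequence[np.ndarray] | None,
    params: PeakParams = PeakParams(),
) -> PatternType:
    """Assign the gene's 3'UTR expression pattern type; records a rule trace.

    Rules are tried in order TYPE_I, TYPE_II, TYPE_III; a gene matching none
    (including any gene without peaks) is UNCLASSIFIED.
    """
    peaks, valleys = peakset.peaks, peakset.valleys
    utr_len = model.utr3_length
    trace: list[str] = []

    if not peaks:
        peakset.pattern_type = PatternType.UNCLASSIFIED
        peakset.rule_trace = "no peaks"
        return peakset.pattern_type

    # CDS consensus above-threshold runs, transcript-oriented (index 0 = CDS 5')
    cds_above_runs: list[tuple[int, int]] = []
    if cds_fpkm_arrays is not None and len(cds_fpkm_arrays) > 0:
        mat = _stack(cds_fpkm_arrays)
        k = params.required_replicates(mat.shape[0])
        mask = (mat > params.fpkm_threshold).sum(axis=0) >= k
        cds_above_runs = _runs(mask)

    # TYPE_I: >= 2 peaks fully inside the UTR with a valley between some pair
    if len(peaks) >= 2:
        has_between_valley = any(
            any(p1.end <= vs and ve <= p2.start for vs, ve in valleys)
            for p1, p2 in zip(peaks, peaks[1:])
        )
        if has_between_valley:
            peakset.pattern_type = PatternType.TYPE_I
            peakset.rule_trace = (
                f"{len(peaks)} internal peaks with interleaving valley"
            )
            return peakset.pattern_type
        trace.append(f"{len(peaks)} peaks but no interleaving valley")

    # TYPE_II: single junction-contiguous peak into a short UTR
    if len(peaks) == 1 and utr_len <= params.short_utr_max_bp:
        p = peaks[0]
        abuts = p.start == 0
        near = p.start <= params.junction_slack_bp and _cds_reaches_junction(
            cds_above_runs, model.cds_length, params.junction_slack_bp
        )
        if abuts or near:
            peakset.pattern_type = PatternType.TYPE_II
            peakset.rule_trace = (
                f"single peak at offset {p.start} bp, UTR {utr_len} bp "
                f"<= {params.short_utr_max_bp}"
            )
            return peakset.pattern_type
        trace.append(f"short UTR but peak starts at {p.start} bp")
    elif len(peaks) == 1:
        trace.append(f"single peak, UTR {utr_len} bp not short")

    # TYPE_III: long UTR with peaks; CDS expression confined near the junction
    if utr_len >= params.long_utr_min_bp:
        limit = params.cds_terminal_fraction * model.cds_length
        terminal_ok = all(
            (model.cds_length - s) <= limit for s, _e in cds_above_runs
        ) and len(cds_above_runs) > 0
        no_cds_signal = len(cds_above_runs) == 0
        if terminal_ok:
            peakset.pattern_type = PatternType.TYPE_III
            peakset.rule_trace = (
                f"long UTR ({utr_len} bp) with CDS signal confined to "
                f"terminal {limit:.0f} bp"
            )
            return peakset.pattern_type
        trace.append(
            "long UTR but CDS signal "
            + ("absent" if no_cds_signal else "not junction-confined")
        )

    peakset.pattern_type = PatternType.UNCLASSIFIED
    peakset.rule_trace = "; ".join(trace) or "no rule matched"
    return peakset.pattern_type


def _cds_reaches_junction(
    cds_above_runs: list[tuple[int, int]], cds_length: int, slack: int
) -> bool:
    return any(cds_length - e <= slack for _s, e in cds_above_runs)


def call_gene_peakset(
    gene_id: str,
    utr_fpkm_arrays: Sequence[np.ndarray],
    model: GeneModel | None = None,
    cds_fpkm_arrays: Sequence[np.ndarray] | None = None,
    params: PeakParams = PeakParams(),
) -> PeakSet:
    """Convenience: peaks + valleys + (optionally) pattern type for one gene."""
    peaks = call_consensus_peaks(utr_fpkm_arrays, params)
    valleys = call_valleys(utr_fpkm_arrays, peaks, params)
    ps = PeakSet(gene_id=gene_id, peaks=peaks, valleys=valleys)
    if model is not None:
        project_peaks(ps, model)
        classify_pattern(ps, model, cds_fpkm_arrays, params)
    return ps
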