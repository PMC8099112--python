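"""Synthetic RNA-seq coverage with designed 3'UTR peak/valley architecture.

The generator emulates what the analysis consumes: per-base coverage over
genes whose 3'UTRs carry designed peaks and valleys, replicate-to-replicate
count noise (Poisson per base, or Gamma-Poisson per tile for overdispersion),
library-size differences between replicates, EST interval sets with a
specified class mixture, and genomic element tracks placed into designed
peaks or valleys. Every design carries its ground truth (true expression
ratio, peak boundaries, pattern type, EST labels, element placement) so the
whole pipeline can be checked closed-loop.

Designed FPKM converts to expected depth through the inverse of the per-base
FPKM convention: expected depth[i] = fpkm[i] x library_size / 1e9. The
default library size of 5e8 mapped reads (deep, pooled-replicate scale) puts
the FPKM=100 decision boundary at depth 50, where Poisson fluctuations
cannot fragment a designed >150-bp run at twice-threshold FPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gene_models import GeneModel, GenomicInterval
from .peaks import PatternType
from .ratios import GeneClass

DEFAULT_LIBRARY_SIZE = 500_000_000
DEFAULT_VALLEY_FLOOR_FPKM = 20.0
# lowest simulated background: keeps every designed region covered so the
# effective-length estimator stays close to the annotated length
MIN_BACKGROUND_FPKM = 5.0


@dataclass(frozen=True)
class PeakBlueprint:
    """A designed 3'UTR peak: [offset, offset+length) bp 3' of the junction."""

    offset_bp: int
    length_bp: int
    fpkm: float

    def __post_init__(self) -> None:
        if self.offset_bp < 0 or self.length_bp <= 0 or self.fpkm <= 0:
            raise ValueError(f"invalid peak blueprint {self}")

    @property
    def end_bp(self) -> int:
        return self.offset_bp + self.length_bp


@dataclass
class GeneDesign:
    """Ground-truth design for one synthetic gene.

    ``designed_ratio`` is the target 3'UTR share of expression; the CDS
    background FPKM is solved from it (clamped below at the valley floor so
    no designed region drops to zero coverage). ``true_ratio`` is the exact
    expected ratio realized by the final profiles and is what the truth
    table records. ``cds_terminal_boost`` = (run_bp, fpkm) raises the CDS
    stretch adjacent to the junction, as in genes whose expression starts in
    a short leading CDS and runs into a long 3'UTR.
    """

    gene_id: str
    cds_length_bp: int
    utr3_length_bp: int
    strand: str = "+"
    designed_ratio: float = 0.5
    peak_blueprints: list[PeakBlueprint] = field(default_factory=list)
    valley_floor_fpkm: float = DEFAULT_VALLEY_FLOOR_FPKM
    cds_terminal_boost: tuple[int, float] | None = None
    n_cds_exons: int = 1
    pattern_type_truth: PatternType = PatternType.UNCLASSIFIED
    expressed_truth: bool = True

    def __post_init__(self) -> None:
        if self.cds_length_bp < 1 or self.utr3_length_bp < 1:
            raise ValueError(f"{self.gene_id}: empty CDS or 3'UTR")
        if self.expressed_truth and not 0 < self.designed_ratio < 1:
            raise ValueError(f"{self.gene_id}: designed_ratio must be in (0,1)")
        bps = sorted(self.peak_blueprints, key=lambda b: b.offset_bp)
        for a, b in zip(bps, bps[1:]):
            if a.end_bp > b.offset_bp:
                raise ValueError(f"{self.gene_id}: overlapping peak blueprints")
        if bps and bps[-1].end_bp > self.utr3_length_bp:
            raise ValueError(f"{self.gene_id}: peak blueprint outside 3'UTR")
        if self.cds_terminal_boost is not None:
            run, fpkm = self.cds_terminal_boost
            if not 0 < run <= self.cds_length_bp:
                raise ValueError(f"{self.gene_id}: bad terminal boost run")
        self.peak_blueprints = bps

    # -- expected (noise-free) FPKM profiles, transcript-oriented ---------

    def utr_fpkm_profile(self) -> np.ndarray:
        if not self.expressed_truth:
            return np.zeros(self.utr3_length_bp)
        prof = np.full(self.utr3_length_bp, self.valley_floor_fpkm)
        for bp in self.peak_blueprints:
            prof[bp.offset_bp : bp.end_bp] = bp.fpkm
        return prof

    def cds_background_fpkm(self) -> float:
        """CDS background solving mean(CDS) for the designed ratio, clamped."""
        if not self.expressed_truth:
            return 0.0
        mu_u = float(self.utr_fpkm_profile().mean())
        mu_c = mu_u * (1 - self.designed_ratio) / self.designed_ratio
        boost_bp, boost_fpkm = self.cds_terminal_boost or (0, 0.0)
        b = (mu_c * self.cds_length_bp - boost_fpkm * boost_bp) / max(
            self.cds_length_bp - boost_bp, 1
        )
        return max(b, MIN_BACKGROUND_FPKM)

    def cds_fpkm_profile(self) -> np.ndarray:
        if not self.expressed_truth:
            return np.zeros(self.cds_length_bp)
        prof = np.full(self.cds_length_bp, self.cds_background_fpkm())
        if self.cds_terminal_boost is not None:
            run, fpkm = self.cds_terminal_boost
            prof[self.cds_length_bp - run :] = fpkm  # adjacent to the junction
        return prof

    @property
    def true_ratio(self) -> float:
        """Exact expected fractional ratio under the realized profiles."""
        if not self.expressed_truth:
            return float("nan")
        mu_u = float(self.utr_fpkm_profile().mean())
        mu_c = float(self.cds_fpkm_profile().mean())
        return mu_u / (mu_u + mu_c)

    def true_class(
        self, hi_threshold: float = 0.6, lo_threshold: float = 0.4
    ) -> GeneClass:
        if not self.expressed_truth:
            return GeneClass.NOT_EXPRESSED
        r = self.true_ratio
        if r > hi_threshold:
            return GeneClass.HI_UTR
        if r < lo_threshold:
            return GeneClass.HI_CDS
        return GeneClass.INTERMEDIATE


@dataclass
class SimulationConfig:
    n_replicates: int = 4
    library_size: int = DEFAULT_LIBRARY_SIZE
    library_size_jitter: tuple[float, float] = (0.8, 1.2)
    read_length: int = 100
    noise: str = "poisson"  # "poisson" | "negative_binomial" | "none"
    nb_dispersion: float = 0.1
    nb_tile_bp: int = 50
    est_mixture: tuple[float, float, float] = (0.85, 0.05, 0.10)
    n_ests: int = 200
    est_length_range: tuple[int, int] = (150, 600)
    element_placement: dict[str, tuple[int, str, int]] = field(
        default_factory=lambda: {
            "miRNA_site": (5, "peaks", 8),
            "CpG": (2, "valleys", 300),
            "TF_cluster": (3, "valleys", 120),
            "H3K27ac": (2, "valleys", 350),
            "DNase": (2, "valleys", 150),
        }
    )
    chrom: str = "chrS"
    intergenic_gap_bp: int = 10_000
    intron_bp: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.est_mixture) - 1.0) > 1e-9:
            raise ValueError("est_mixture must sum to 1")
        if self.noise not in ("poisson", "negative_binomial", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.n_replicates < 1 or self.library_size <= 0:
            raise ValueError("need >= 1 replicate and a positive library size")


# ---------------------------------------------------------------------------
# gene model construction
# ---------------------------------------------------------------------------


def generate_gene_models(
    config: SimulationConfig, designs: Sequence[GeneDesign]
) -> list[GeneModel]:
    """Lay designs head-to-tail on one synthetic chromosome.

    CDS exons (``n_cds_exons``, equal split, fixed introns) run 5'->3' into a
    single contiguous 3'UTR exon; minus-strand genes mirror genomically.
    """
    ids = [d.gene_id for d in designs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in designs")
    models = []
    cursor = 1000
    for d in designs:
        exon_len, rem = divmod(d.cds_length_bp, d.n_cds_exons)
        sizes = [exon_len + (1 if i < rem else 0) for i in range(d.n_cds_exons)]
        cds: list[GenomicInterval] = []
        if d.strand == "+":
            pos = cursor
            for sz in sizes:
                cds.append(GenomicInterval(config.chrom, pos, pos + sz, "+"))
                pos += sz + config.intron_bp
            pos -= config.intron_bp  # junction = end of last CDS exon
            utr = [GenomicInterval(config.chrom, pos, pos + d.utr3_length_bp, "+")]
            end = pos + d.utr3_length_bp
        else:
            # transcript runs right-to-left: UTR leftmost, CDS exons after
            pos = cursor
            utr = [GenomicInterval(config.chrom, pos, pos + d.utr3_length_bp, "-")]
            pos += d.utr3_length_bp
            for sz in reversed(sizes):
                cds.append(GenomicInterval(config.chrom, pos, pos + sz, "-"))
                pos += sz + config.intron_bp
            end = pos - config.intron_bp
        models.append(
            GeneModel(d.gene_id, d.gene_id, config.chrom, d.strand, cds, utr)
        )
        cursor = end + config.intergenic_gap_bp
    return models


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------


def _noisy_depth(
    expected: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.noise == "none":
        return np.round(expected).astype(np.int64)
    if config.noise == "poisson":
        return rng.poisson(expected).astype(np.int64)
    # Gamma-Poisson: one multiplicative factor per tile (overdispersion
    # correlated over ~read-length scales, as in real coverage)
    n = len(expected)
    n_tiles = (n + config.nb_tile_bp - 1) // config.nb_tile_bp
    shape = 1.0 / config.nb_dispersion
    factors = rng.gamma(shape, 1.0 / shape, size=n_tiles)
    lam = expected * np.repeat(factors, config.nb_tile_bp)[:n]
    return rng.poisson(lam).astype(np.int64)


@dataclass
class ReplicateCoverage:
    replicate_id: str
    total_mapped_reads: int
    # gene_id -> region ("CDS"/"UTR3") -> transcript-oriented depth array
    depth: dict[str, dict[str, np.ndarray]]
    read_counts: dict[tuple[str, str], int]


def simulate_coverage(
    designs: Sequence[GeneDesign],
    config: SimulationConfig,
    replicate_index: int,
    rng: np.random.Generator,
) -> ReplicateCoverage:
    """One replicate: noisy depth per gene region plus derived read counts.

    The replicate's library size is the configured size times a jitter
    factor; expected depth scales with the actual library so designed FPKM
    is library-invariant, as real normalized coverage is. Read counts are
    the aligned-base count divided by the read length.
    """
    lo, hi = config.library_size_jitter
    lib = int(round(config.library_size * rng.uniform(lo, hi)))
    depth: dict[str, dict[str, np.ndarray]] = {}
    counts: dict[tuple[str, str], int] = {}
    for d in designs:
        per_region = {}
        for region, profile in (
            ("CDS", d.cds_fpkm_profile()),
            ("UTR3", d.utr_fpkm_profile()),
        ):
            expected = profile * lib / 1e9
            arr = _noisy_depth(expected, config, rng)
            per_region[region] = arr
            counts[(d.gene_id, region)] = int(round(arr.sum() / config.read_length))
        depth[d.gene_id] = per_region
    return ReplicateCoverage(f"rep{replicate_index + 1}", lib, depth, counts)


# ---------------------------------------------------------------------------
# ESTs and element tracks
# ---------------------------------------------------------------------------


def _oriented_region_span(model: GeneModel, region: str) -> GenomicInterval:
    """Largest single genomic interval of a region (synthetic UTRs have one)."""
    ivs = model.region_intervals(region)
    return max(ivs, key=lambda iv: iv.length)


def simulate_ests(
    design: GeneDesign,
    model: GeneModel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[GenomicInterval, str]]:
    """Draw ESTs per class mixture; returns (interval, true class) pairs.

    UTR-only and CDS-only ESTs are placed uniformly inside a single exon of
    their region; junction-spanning ESTs get at least one base on each side.
    """
    lo_len, hi_len = config.est_length_range
    n_per = rng.multinomial(config.n_ests, config.est_mixture)
    labels = ("UTR_ONLY", "CDS_ONLY", "MIXED")
    utr_iv = _oriented_region_span(model, "UTR3")
    # CDS exon adjacent to the junction (for the CDS side of mixed ESTs)
    if model.strand == "+":
        cds_adj = max(model.cds_intervals, key=lambda iv: iv.end)
    else:
        cds_adj = min(model.cds_intervals, key=lambda iv: iv.start)
    out: list[tuple[GenomicInterval, str]] = []
    for label, n in zip(labels, n_per):
        for _ in range(int(n)):
            if label == "MIXED":
                length = int(rng.integers(lo_len, hi_len + 1))
                utr_side = int(rng.integers(1, max(2, min(length - 1, utr_iv.length))))
                cds_side = min(length - utr_side, cds_adj.length)
                if model.strand == "+":
                    start = model.junction - cds_side
                    end = model.junction + utr_side
                else:
                    start = model.junction - utr_side
                    end = model.junction + cds_side
                out.append(
                    (GenomicInterval(model.chrom, start, end, model.strand), label)
                )
                continue
            host = utr_iv if label == "UTR_ONLY" else cds_adj
            if host.length < lo_len:
                raise ValueError(
                    f"{design.gene_id}: region too short ({host.length} bp) for "
                    f"a {label} EST of >= {lo_len} bp"
                )
            length = int(rng.integers(lo_len, min(hi_len, host.length) + 1))
            start = int(rng.integers(host.start, host.end - length + 1))
            out.append(
                (
                    GenomicInterval(model.chrom, start, start + length, model.strand),
                    label,
                )
            )
    return out


def _designed_valleys(design: GeneDesign) -> list[tuple[int, int]]:
    """Complement of the peak blueprints within the 3'UTR (spliced offsets)."""
    gaps, pos = [], 0
    for bp in design.peak_blueprints:
        if bp.offset_bp > pos:
            gaps.append((pos, bp.offset_bp))
        pos = bp.end_bp
    if pos < design.utr3_length_bp:
        gaps.append((pos, design.utr3_length_bp))
    return gaps


def simulate_elements(
    design: GeneDesign,
    model: GeneModel,
    config: SimulationConfig,
    rng: np.random.Generator,
    strict: bool = True,
) -> list[tuple[GenomicInterval, str]]:
    """Place element intervals into designed peaks or valleys, per category.

    The config's placement table maps category -> (count, target, length).
    Raises when a requested placement has no window long enough; with
    ``strict=False`` such categories are skipped for this gene instead.
    """
    out: list[tuple[GenomicInterval, str]] = []
    for category in sorted(config.element_placement):
        count, target, length = config.element_placement[category]
        if target == "peaks":
            windows = [
                (bp.offset_bp, bp.end_bp) for bp in design.peak_blueprints
            ]
        elif target == "valleys":
            windows = _designed_valleys(design)
        else:
            raise ValueError(f"unknown placement target {target!r}")
        windows = [(s, e) for s, e in windows if e - s >= length]
        if count and not windows:
            if strict:
                raise ValueError(
                    f"{design.gene_id}: no {target} window of >= {length} bp "
                    f"for {category}"
                )
            continue
        for _ in range(count):
            w = windows[int(rng.integers(len(windows)))]
            off = int(rng.integers(w[0], w[1] - length + 1))
            for giv in model.spliced_to_genomic("UTR3", off, off + length):
                out.append((giv, category))
    return out


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    designs: list[GeneDesign]
    models: list[GeneModel]
    replicates: list[ReplicateCoverage]
    ests: dict[str, list[tuple[GenomicInterval, str]]]
    elements: dict[str, list[tuple[GenomicInterval, str]]]

    @property
    def truth(self) -> pd.DataFrame:
        rows = []
        for d in self.designs:
            rows.append(
                {
                    "gene_id": d.gene_id,
                    "strand": d.strand,
                    "cds_length_bp": d.cds_length_bp,
                    "utr3_length_bp": d.utr3_length_bp,
                    "true_ratio": d.true_ratio,
                    "true_class": d.true_class().value,
                    "pattern_type": d.pattern_type_truth.value,
                    "n_peaks": len(d.peak_blueprints),
                    "peak_bounds": ";".join(
                        f"{b.offset_bp}-{b.end_bp}" for b in d.peak_blueprints
                    ),
                    "expressed": d.expressed_truth,
                }
            )
        return pd.DataFrame(rows)

    def model_for(self, gene_id: str) -> GeneModel:
        return next(m for m in self.models if m.gene_id == gene_id)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        return write_dataset(self, Path(out_dir))


def simulate_dataset(
    config: SimulationConfig | None = None,
    designs: Sequence[GeneDesign] | None = None,
) -> SyntheticDataset:
    """Generate the full dataset (models, coverage, ESTs, elements) in memory.

    Deterministic given ``config.seed``: all randomness flows from one
    generator in a fixed order.
    """
    config = config or SimulationConfig()
    designs = list(designs) if designs is not None else default_designs()
    if not designs:
        raise ValueError("at least one gene design required")
    rng = np.random.default_rng(config.seed)
    models = generate_gene_models(config, designs)
    by_id = {m.gene_id: m for m in models}
    replicates = [
        simulate_coverage(designs, config, r, rng)
        for r in range(config.n_replicates)
    ]
    ests, elements = {}, {}
    for d in designs:
        if d.expressed_truth:
            ests[d.gene_id] = simulate_ests(d, by_id[d.gene_id], config, rng)
        if d.peak_blueprints and _designed_valleys(d):
            elements[d.gene_id] = simulate_elements(
                d, by_id[d.gene_id], config, rng, strict=False
            )
    return SyntheticDataset(config, designs, models, replicates, ests, elements)


# ---------------------------------------------------------------------------
# default scenario: 30 genes covering all pattern types
# ---------------------------------------------------------------------------


def default_designs() -> list[GeneDesign]:
    """30 genes: the three peak patterns, designed ratios spanning 0.05-0.95,
    plus unpeaked and silent genes. Peak FPKMs sit at >= 2x the calling
    threshold and valley floors at <= half of it."""
    designs: list[GeneDesign] = []
    # multi-peak genes (discrete internal peaks with a valley between)
    for i, (ratio, utr, pk_fpkm, strand, nexon) in enumerate(
        [
            (0.95, 3000, 400.0, "+", 1),
            (0.85, 2600, 300.0, "-", 1),
            (0.75, 3600, 250.0, "+", 2),
            (0.70, 2400, 500.0, "+", 1),
            (0.50, 3000, 300.0, "-", 1),
            (0.30, 2800, 400.0, "+", 1),
            (0.15, 2600, 350.0, "-", 1),
            (0.05, 3200, 200.0, "+", 1),
        ]
    ):
        third = utr // 3
        designs.append(
            GeneDesign(
                gene_id=f"gI{i + 1:02d}",
                cds_length_bp=1200,
                utr3_length_bp=utr,
                strand=strand,
                designed_ratio=ratio,
                peak_blueprints=[
                    PeakBlueprint(200, min(400, third - 250), pk_fpkm),
                    PeakBlueprint(2 * third, min(500, third - 200), pk_fpkm),
                ],
                n_cds_exons=nexon,
                pattern_type_truth=PatternType.TYPE_I,
            )
        )
    # junction-contiguous single peak into a short 3'UTR
    for i, (ratio, utr, pk_fpkm, strand) in enumerate(
        [
            (0.70, 1000, 400.0, "-"),
            (0.65, 600, 400.0, "+"),
            (0.55, 800, 300.0, "-"),
            (0.45, 500, 350.0, "+"),
            (0.35, 900, 300.0, "+"),
            (0.20, 700, 250.0, "-"),
            (0.10, 600, 300.0, "+"),
            (0.05, 800, 300.0, "+"),
        ]
    ):
        designs.append(
            GeneDesign(
                gene_id=f"gII{i + 1:02d}",
                cds_length_bp=1000,
                utr3_length_bp=utr,
                strand=strand,
                designed_ratio=ratio,
                peak_blueprints=[PeakBlueprint(0, utr - 200, pk_fpkm)],
                pattern_type_truth=PatternType.TYPE_II,
            )
        )
    # long 3'UTR, one broad peak; CDS signal confined to a short stretch
    # adjacent to the junction
    for i, (ratio, utr, pk_fpkm, strand, nexon) in enumerate(
        [
            (0.90, 4000, 500.0, "+", 1),
            (0.85, 3000, 400.0, "-", 1),
            (0.80, 5000, 350.0, "+", 1),
            (0.75, 2600, 300.0, "+", 2),
            (0.70, 3400, 300.0, "-", 1),
            (0.65, 2200, 250.0, "+", 1),
        ]
    ):
        designs.append(
            GeneDesign(
                gene_id=f"gIII{i + 1:02d}",
                cds_length_bp=1200,
                utr3_length_bp=utr,
                strand=strand,
                designed_ratio=ratio,
                peak_blueprints=[PeakBlueprint(300, utr - 900, pk_fpkm)],
                cds_terminal_boost=(200, 250.0),
                n_cds_exons=nexon,
                pattern_type_truth=PatternType.TYPE_III,
            )
        )
    # expressed but unpeaked (uniform sub-threshold 3'UTR coverage)
    for i, (ratio, utr, strand) in enumerate(
        [(0.90, 1600, "+"), (0.60, 1400, "-"), (0.40, 1800, "+"), (0.08, 1500, "+")]
    ):
        designs.append(
            GeneDesign(
                gene_id=f"gU{i + 1:02d}",
                cds_length_bp=900,
                utr3_length_bp=utr,
                strand=strand,
                designed_ratio=ratio,
                valley_floor_fpkm=60.0,
                pattern_type_truth=PatternType.UNCLASSIFIED,
            )
        )
    # mid-length UTR with a single internal (non-junction) peak: no rule fits
    for i, (ratio, strand) in enumerate([(0.80, "+"), (0.25, "-")]):
        designs.append(
            GeneDesign(
                gene_id=f"gM{i + 1:02d}",
                cds_length_bp=1000,
                utr3_length_bp=1500,
                strand=strand,
                designed_ratio=ratio,
                peak_blueprints=[PeakBlueprint(500, 400, 300.0)],
                pattern_type_truth=PatternType.UNCLASSIFIED,
            )
        )
    # silent genes (below the expressed filter)
    for i in range(2):
        designs.append(
            GeneDesign(
                gene_id=f"gS{i + 1:02d}",
                cds_length_bp=800,
                utr3_length_bp=1200,
                strand="+" if i == 0 else "-",
                expressed_truth=False,
                pattern_type_truth=PatternType.UNCLASSIFIED,
            )
        )
    assert len(designs) == 30
    return designs


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_gtf(
    models: Sequence[GeneModel], path: str | Path, source: str = "i3utr_sim"
) -> None:
    """GTF (1-based closed) with gene/transcript/exon/CDS/three_prime_utr rows."""
    with open(path, "w") as fh:
        for m in models:
            exons = sorted(
                m.cds_intervals + m.utr3_intervals, key=lambda iv: iv.start
            )
            lo, hi = exons[0].start + 1, exons[-1].end
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1"; '
                f'gene_name "{m.gene_name}";'
            )

            def row(ftype: str, s: int, e: int) -> str:
                return (
                    f"{m.chrom}\t{source}\t{ftype}\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )

            fh.write(row("gene", lo, hi))
            fh.write(row("transcript", lo, hi))
            for iv in exons:
                fh.write(row("exon", iv.start + 1, iv.end))
            for iv in m.cds_intervals:
                fh.write(row("CDS", iv.start + 1, iv.end))
            for iv in m.utr3_intervals:
                fh.write(row("three_prime_utr", iv.start + 1, iv.end))


def write_bedgraph(
    rep: ReplicateCoverage, models: Sequence[GeneModel], path: str | Path
) -> None:
    """Genomic bedGraph of one replicate's depth (run-length encoded)."""
    lines: list[tuple[str, int, int, int]] = []
    for m in models:
        per_region = rep.depth[m.gene_id]
        for region in ("CDS", "UTR3"):
            depth = per_region[region]
            ivs = m.region_intervals(region)
            order = ivs if m.strand == "+" else list(reversed(ivs))
            off = 0
            for iv in order:
                arr = depth[off : off + iv.length]
                off += iv.length
                garr = arr if m.strand == "+" else arr[::-1]
                # run-length encode
                change = np.flatnonzero(np.diff(garr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(garr)]))
                for s, e in zip(starts, ends):
                    v = int(garr[s])
                    if v > 0:
                        lines.append((iv.chrom, iv.start + int(s), iv.start + int(e), v))
    lines.sort()
    with open(path, "w") as fh:
        for chrom, s, e, v in lines:
            fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def write_dataset(ds: SyntheticDataset, out_dir: Path) -> dict[str, Path]:
    """Write annotation, per-replicate coverage + counts, ESTs, elements, truth."""
    from .est_elements import write_bed6
    from .gene_models import write_bed12

    out_dir.mkdir(parents=True, exist_ok=True)
    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    paths["gtf"] = out_dir / "genes.gtf"
    write_gtf(ds.models, paths["gtf"])
    paths["bed12"] = out_dir / "genes.bed"
    write_bed12(ds.models, paths["bed12"])

    lib_rows = []
    for rep in ds.replicates:
        bg = out_dir / f"coverage_{rep.replicate_id}.bedgraph"
        write_bedgraph(rep, ds.models, bg)
        paths[f"bedgraph_{rep.replicate_id}"] = bg
        counts = pd.DataFrame(
            [
                {"gene_id": g, "region": r, "read_count": c}
                for (g, r), c in sorted(rep.read_counts.items())
            ]
        )
        cp = out_dir / f"counts_{rep.replicate_id}.tsv"
        counts.to_csv(cp, sep="\t", index=False)
        paths[f"counts_{rep.replicate_id}"] = cp
        lib_rows.append(
            {"replicate_id": rep.replicate_id, "total_mapped_reads": rep.total_mapped_reads}
        )
    paths["libraries"] = out_dir / "libraries.tsv"
    pd.DataFrame(lib_rows).to_csv(paths["libraries"], sep="\t", index=False)

    est_records = [
        (iv, f"{g}|{label}")
        for g in sorted(ds.ests)
        for iv, label in ds.ests[g]
    ]
    paths["ests"] = out_dir / "ests.bed"
    write_bed6(est_records, paths["ests"])

    elem_records = [
        (iv, f"{g}|{cat}")
        for g in sorted(ds.elements)
        for iv, cat in ds.elements[g]
    ]
    paths["elements"] = out_dir / "elements.bed"
    write_bed6(elem_records, paths["elements"])

    paths["truth_genes"] = truth_dir / "genes.tsv"
    ds.truth.to_csv(paths["truth_genes"], sep="\t", index=False)
    est_truth = pd.DataFrame(
        [
            {"gene_id": g, "chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "true_class": label}
            for g in sorted(ds.ests)
            for iv, label in ds.ests[g]
        ]
    )
    paths["truth_ests"] = truth_dir / "ests.tsv"
    est_truth.to_csv(paths["truth_ests"], sep="\t", index=False)
    return paths
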