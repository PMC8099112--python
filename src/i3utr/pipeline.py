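"""End-to-end pipeline: models -> coverage -> ratios -> peaks -> ESTs/elements.

Consumes an annotation (GTF/GFF3/BED12), per-replicate coverage (bedGraph +
per-region read-count table + library sizes; or BAM), and optional EST and
element BED6 tracks; writes stage TSV/BED outputs and a run manifest.
Outputs are a pure function of (inputs, config): re-running with the same
config reproduces identical files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage import (
    CoverageTrack,
    coverage_from_bedgraph,
    is_expressed,
    normalized_expression,
    read_bedgraph,
    read_region_counts,
    region_coverage,
)
from .est_elements import (
    element_overlap,
    element_permutation_test,
    read_bed6,
    summarize_ests,
)
from .gene_models import GeneModel, GenomicInterval, load_gene_models
from .peaks import PeakParams, PeakSet, call_gene_peakset, per_base_fpkm
from .ratios import (
    ClassificationParams,
    GeneClass,
    GeneRatioRecord,
    classify_records,
    export_class_lists,
    records_to_frame,
    replicate_concordance,
)


@dataclass
class ReplicateInput:
    replicate_id: str
    coverage_path: Path  # bedGraph or BAM
    counts_path: Path | None = None  # required for bedGraph
    total_mapped_reads: int | None = None  # required for bedGraph


@dataclass
class RunConfig:
    annotation: Path
    replicates: list[ReplicateInput]
    out_dir: Path
    est_bed: Path | None = None
    element_bed: Path | None = None
    transcript_policy: str = "union"
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    peak_params: PeakParams = field(default_factory=PeakParams)
    ratio_basis: str = "expression"  # or "mean-depth"
    concordance_metric: str = "jaccard"
    min_mapq: int = 20
    n_perm: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.annotation).exists():
            raise FileNotFoundError(f"annotation not found: {self.annotation}")
        if not self.replicates:
            raise ValueError("at least one replicate input required")
        for rep in self.replicates:
            if not Path(rep.coverage_path).exists():
                raise FileNotFoundError(
                    f"{rep.replicate_id}: coverage not found: {rep.coverage_path}"
                )
            if str(rep.coverage_path).endswith((".bedgraph", ".bg", ".bedGraph")):
                if rep.counts_path is None or rep.total_mapped_reads is None:
                    raise ValueError(
                        f"{rep.replicate_id}: bedGraph input needs a read-count "
                        "table and total_mapped_reads"
                    )
        if self.ratio_basis not in ("expression", "mean-depth"):
            raise ValueError(f"unknown ratio_basis {self.ratio_basis!r}")
        # ClassificationParams / PeakParams validate themselves on construction

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def p(x):
            q = Path(x)
            return q if q.is_absolute() else base / q

        reps = [
            ReplicateInput(
                replicate_id=r["replicate_id"],
                coverage_path=p(r["coverage"]),
                counts_path=p(r["counts"]) if r.get("counts") else None,
                total_mapped_reads=r.get("total_mapped_reads"),
            )
            for r in raw["replicates"]
        ]
        return cls(
            annotation=p(raw["annotation"]),
            replicates=reps,
            out_dir=p(raw.get("out_dir", "i3utr_out")),
            est_bed=p(raw["est_bed"]) if raw.get("est_bed") else None,
            element_bed=p(raw["element_bed"]) if raw.get("element_bed") else None,
            transcript_policy=raw.get("transcript_policy", "union"),
            classification=ClassificationParams(
                hi_threshold=raw.get("hi_threshold", 0.6),
                lo_threshold=raw.get("lo_threshold", 0.4),
                min_reads=raw.get("min_reads", 5),
            ),
            peak_params=PeakParams(
                fpkm_threshold=raw.get("fpkm_threshold", 100.0),
                min_run_bp=raw.get("min_run_bp", 151),
                min_replicates=raw.get("min_replicates"),
                consensus=raw.get("consensus", "per_base"),
            ),
            ratio_basis=raw.get("ratio_basis", "expression"),
            concordance_metric=raw.get("concordance_metric", "jaccard"),
            min_mapq=raw.get("min_mapq", 20),
            n_perm=raw.get("n_perm", 1000),
            seed=raw.get("seed", 0),
        )


@dataclass
class PipelineResult:
    models: list[GeneModel]
    # replicate_id -> gene_id -> region -> (CoverageTrack, read_count)
    coverage: dict[str, dict[str, dict[str, tuple[CoverageTrack, int]]]]
    records_per_replicate: dict[str, list[GeneRatioRecord]]
    pooled_records: list[GeneRatioRecord]
    concordance: pd.DataFrame
    peaksets: dict[str, PeakSet]
    est_summaries: pd.DataFrame | None
    element_reports: pd.DataFrame | None
    out_dir: Path


def _load_replicate(
    rep: ReplicateInput, models: list[GeneModel], min_mapq: int
) -> dict[str, dict[str, tuple[CoverageTrack, int]]]:
    out: dict[str, dict[str, tuple[CoverageTrack, int]]] = {}
    path = str(rep.coverage_path)
    if path.endswith((".bedgraph", ".bg", ".bedGraph")):
        bg = read_bedgraph(rep.coverage_path)
        counts = read_region_counts(rep.counts_path)
        for m in models:
            out[m.gene_id] = {
                region: (
                    coverage_from_bedgraph(
                        bg, m, region, rep.replicate_id, rep.total_mapped_reads
                    ),
                    counts.get((m.gene_id, region), 0),
                )
                for region in ("CDS", "UTR3")
            }
    else:
        for m in models:
            out[m.gene_id] = {
                region: region_coverage(
                    rep.coverage_path,
                    m,
                    region,
                    rep.replicate_id,
                    rep.total_mapped_reads,
                    min_mapq,
                )
                for region in ("CDS", "UTR3")
            }
    return out


def _gene_record(
    gene_id: str,
    cds: tuple[CoverageTrack, int],
    utr: tuple[CoverageTrack, int],
    params: ClassificationParams,
    ratio_basis: str,
) -> GeneRatioRecord:
    (cds_track, cds_count), (utr_track, utr_count) = cds, utr
    expressed = is_expressed(cds_count, utr_count, min_reads=params.min_reads)
    if ratio_basis == "mean-depth":
        cds_expr = float(cds_track.depth.mean()) if len(cds_track.depth) else 0.0
        utr_expr = float(utr_track.depth.mean()) if len(utr_track.depth) else 0.0
    else:
        cds_expr = normalized_expression(
            cds_count, cds_track.effective_length_bp, cds_track.total_mapped_reads
        )
        utr_expr = normalized_expression(
            utr_count, utr_track.effective_length_bp, utr_track.total_mapped_reads
        )
    return GeneRatioRecord(gene_id, utr_expr, cds_expr, expressed)


def _pooled_record(
    gene_id: str,
    per_rep: list[dict[str, tuple[CoverageTrack, int]]],
    params: ClassificationParams,
    ratio_basis: str,
) -> GeneRatioRecord:
    """Pool replicates: summed counts, pooled depth, summed library sizes."""
    pooled = {}
    for region in ("CDS", "UTR3"):
        depth = np.sum([r[region][0].depth for r in per_rep], axis=0)
        lib = sum(r[region][0].total_mapped_reads for r in per_rep)
        count = sum(r[region][1] for r in per_rep)
        pooled[region] = (CoverageTrack("pooled", depth, lib), count)
    return _gene_record(gene_id, pooled["CDS"], pooled["UTR3"], params, ratio_basis)


def run_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {
            "hi_threshold": config.classification.hi_threshold,
            "lo_threshold": config.classification.lo_threshold,
            "min_reads": config.classification.min_reads,
            "fpkm_threshold": config.peak_params.fpkm_threshold,
            "min_run_bp": config.peak_params.min_run_bp,
            "min_replicates": config.peak_params.min_replicates,
            "consensus": config.peak_params.consensus,
            "ratio_basis": config.ratio_basis,
            "concordance_metric": config.concordance_metric,
            "transcript_policy": config.transcript_policy,
            "min_mapq": config.min_mapq,
            "n_perm": config.n_perm,
            "seed": config.seed,
        },
        "inputs": {},
        "stages": [],
        "warnings": [],
    }
    for label, path in [("annotation", config.annotation)] + [
        (f"coverage_{r.replicate_id}", r.coverage_path) for r in config.replicates
    ]:
        manifest["inputs"][label] = {
            "path": str(path),
            "md5": hashlib.md5(Path(path).read_bytes()).hexdigest(),
        }

    # stage: models ------------------------------------------------------
    models = load_gene_models(config.annotation, config.transcript_policy)
    if not models:
        raise RuntimeError("stage models: no usable gene models in annotation")
    manifest["stages"].append({"models": {"n_genes": len(models)}})

    # stage: coverage ----------------------------------------------------
    coverage = {
        rep.replicate_id: _load_replicate(rep, models, config.min_mapq)
        for rep in config.replicates
    }
    cov_rows = [
        {
            "gene_id": m.gene_id,
            "replicate_id": rid,
            "region": region,
            "read_count": cnt,
            "effective_length_bp": trk.effective_length_bp,
            "expression": normalized_expression(
                cnt, trk.effective_length_bp, trk.total_mapped_reads
            ),
        }
        for rid, per_gene in coverage.items()
        for m in models
        for region, (trk, cnt) in per_gene[m.gene_id].items()
    ]
    pd.DataFrame(cov_rows).to_csv(out / "region_expression.tsv", sep="\t", index=False)
    manifest["stages"].append(
        {"coverage": {"n_replicates": len(coverage), "n_rows": len(cov_rows)}}
    )

    # stage: ratios ------------------------------------------------------
    records_per_rep: dict[str, list[GeneRatioRecord]] = {}
    for rid, per_gene in coverage.items():
        recs = [
            _gene_record(
                m.gene_id,
                per_gene[m.gene_id]["CDS"],
                per_gene[m.gene_id]["UTR3"],
                config.classification,
                config.ratio_basis,
            )
            for m in models
        ]
        records_per_rep[rid] = classify_records(recs, config.classification)
    pooled = classify_records(
        [
            _pooled_record(
                m.gene_id,
                [coverage[rid][m.gene_id] for rid in coverage],
                config.classification,
                config.ratio_basis,
            )
            for m in models
        ],
        config.classification,
    )
    records_to_frame(pooled).to_csv(out / "gene_ratios.tsv", sep="\t", index=False)
    for rid, recs in records_per_rep.items():
        records_to_frame(recs).to_csv(
            out / f"gene_ratios_{rid}.tsv", sep="\t", index=False
        )
    shares = export_class_lists(pooled, out, config.classification)
    conc_rows = []
    rids = sorted(records_per_rep)
    for i, a in enumerate(rids):
        for b in rids[i + 1 :]:
            hi_a = {r.gene_id for r in records_per_rep[a] if r.klass is GeneClass.HI_UTR}
            hi_b = {r.gene_id for r in records_per_rep[b] if r.klass is GeneClass.HI_UTR}
            if not hi_a and not hi_b:
                manifest["warnings"].append(
                    f"concordance {a} vs {b}: both Hi sets empty"
                )
                continue
            c = replicate_concordance(hi_a, hi_b, config.concordance_metric)
            conc_rows.append(
                {
                    "replicate_a": a,
                    "replicate_b": b,
                    "set_a_size": c.set_a_size,
                    "set_b_size": c.set_b_size,
                    "intersection": c.intersection_size,
                    "percent_identity": c.percent_identity,
                    "metric": c.metric,
                }
            )
    concordance = pd.DataFrame(conc_rows)
    concordance.to_csv(out / "concordance.tsv", sep="\t", index=False)
    manifest["stages"].append({"ratios": shares})

    # stage: peaks -------------------------------------------------------
    peaksets: dict[str, PeakSet] = {}
    peak_rows, valley_rows, pattern_rows = [], [], []
    for m in models:
        utr_fpkm = [
            per_base_fpkm(
                coverage[rid][m.gene_id]["UTR3"][0].depth,
                coverage[rid][m.gene_id]["UTR3"][0].total_mapped_reads,
            )
            for rid in rids
        ]
        cds_fpkm = [
            per_base_fpkm(
                coverage[rid][m.gene_id]["CDS"][0].depth,
                coverage[rid][m.gene_id]["CDS"][0].total_mapped_reads,
            )
            for rid in rids
        ]
        ps = call_gene_peakset(
            m.gene_id, utr_fpkm, m, cds_fpkm, config.peak_params
        )
        peaksets[m.gene_id] = ps
        for k, p in enumerate(ps.peaks, 1):
            for iv in p.genomic_intervals:
                peak_rows.append(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{m.gene_id}|peak{k}\t"
                    f"{np.mean(p.mean_fpkm_per_replicate):.1f}\t{m.strand}"
                )
        for k, (vs, ve) in enumerate(ps.valleys, 1):
            for iv in m.spliced_to_genomic("UTR3", vs, ve):
                valley_rows.append(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{m.gene_id}|valley{k}\t0\t{m.strand}"
                )
        pattern_rows.append(
            {
                "gene_id": m.gene_id,
                "n_peaks": len(ps.peaks),
                "pattern_type": ps.pattern_type.value,
                "rule_trace": ps.rule_trace,
            }
        )
    (out / "peaks.bed").write_text("\n".join(peak_rows) + ("\n" if peak_rows else ""))
    (out / "valleys.bed").write_text(
        "\n".join(valley_rows) + ("\n" if valley_rows else "")
    )
    pd.DataFrame(pattern_rows).to_csv(out / "patterns.tsv", sep="\t", index=False)
    manifest["stages"].append({"peaks": {"n_peaks": sum(len(p.peaks) for p in peaksets.values())}})

    # stage: ESTs --------------------------------------------------------
    est_df = None
    if config.est_bed is not None and Path(config.est_bed).exists():
        ests = read_bed6(config.est_bed)
        est_df = _est_stage(ests, models, peaksets, out)
        manifest["stages"].append({"ests": {"n_genes": len(est_df)}})
    else:
        manifest["stages"].append({"ests": "skipped (no EST bed supplied)"})

    # stage: elements ----------------------------------------------------
    elem_df = None
    if config.element_bed is not None and Path(config.element_bed).exists():
        elements = read_bed6(config.element_bed, with_category=True)
        elem_df = _element_stage(
            elements, models, peaksets, out, config.n_perm, config.seed
        )
        manifest["stages"].append({"elements": {"n_rows": len(elem_df)}})
    else:
        manifest["stages"].append({"elements": "skipped (no element bed supplied)"})

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return PipelineResult(
        models=models,
        coverage=coverage,
        records_per_replicate=records_per_rep,
        pooled_records=pooled,
        concordance=concordance,
        peaksets=peaksets,
        est_summaries=est_df,
        element_reports=elem_df,
        out_dir=out,
    )


def _split_gene_label(name: str) -> tuple[str | None, str]:
    gene, sep, label = name.partition("|")
    return (gene, label) if sep else (None, name)


def _est_stage(
    ests: list[tuple[GenomicInterval, str]],
    models: list[GeneModel],
    peaksets: dict[str, PeakSet],
    out: Path,
) -> pd.DataFrame:
    """Assign ESTs to genes (by name tag, else gene-span overlap) and summarize."""
    rows, bin_rows = [], []
    by_id = {m.gene_id: m for m in models}
    for m in models:
        span = m.span
        mine = [
            iv
            for iv, name in ests
            if (_split_gene_label(name)[0] == m.gene_id)
            or (_split_gene_label(name)[0] not in by_id and iv.overlap_bp(span) > 0)
        ]
        if not mine:
            continue
        summary, profile = summarize_ests(mine, m, peaksets.get(m.gene_id))
        rows.append(
            {
                "gene_id": m.gene_id,
                "n_total": summary.n_total,
                "n_utr_only": summary.n_utr_only,
                "n_cds_only": summary.n_cds_only,
                "n_mixed": summary.n_mixed,
                "n_outside": summary.n_outside,
                "frac_utr_only": summary.frac_utr_only,
                "frac_cds_only": summary.frac_cds_only,
                "frac_mixed": summary.frac_mixed,
                "n_spanning_internal_valley": summary.n_spanning_internal_valley,
            }
        )
        for off in sorted(profile.fractions):
            bin_rows.append(
                {
                    "gene_id": m.gene_id,
                    "bin_offset": off,
                    "est_fraction": profile.fractions[off],
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "est_summary.tsv", sep="\t", index=False)
    pd.DataFrame(bin_rows).to_csv(out / "junction_bins.tsv", sep="\t", index=False)
    return df


def _element_stage(
    elements: list[tuple[GenomicInterval, str]],
    models: list[GeneModel],
    peaksets: dict[str, PeakSet],
    out: Path,
    n_perm: int,
    seed: int,
) -> pd.DataFrame:
    rows = []
    rng = np.random.default_rng(seed)
    by_id = {m.gene_id: m for m in models}
    for m in models:
        span = m.span
        mine = [
            (iv, _split_gene_label(name)[1])
            for iv, name in elements
            if (_split_gene_label(name)[0] == m.gene_id)
            or (_split_gene_label(name)[0] not in by_id and iv.overlap_bp(span) > 0)
        ]
        if not mine:
            continue
        ps = peaksets[m.gene_id]
        reports = element_overlap(mine, ps, m)
        for category in sorted(reports):
            rep = reports[category]
            p = None
            members = [iv for iv, c in mine if c == category]
            if rep.n_total > 0 and ps.peaks:
                p = element_permutation_test(
                    [iv for iv in members], ps, m, n_perm=n_perm, seed=rng
                )
            rows.append(
                {
                    "gene_id": m.gene_id,
                    "category": category,
                    "n_in_peaks": rep.n_in_peaks,
                    "n_in_valleys": rep.n_in_valleys,
                    "n_elsewhere": rep.n_elsewhere,
                    "n_outside_gene": rep.n_outside_gene,
                    "peak_fraction": rep.peak_fraction,
                    "empirical_p": p,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "element_overlap.tsv", sep="\t", index=False)
    return df
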