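import warnings

import pytest

from i3utr.gene_models import (
    GeneModel,
    GenomicInterval,
    junction_flank,
    load_gene_models,
    merge_intervals,
    subtract_intervals,
    write_bed12,
)

GTF_ONE_GENE = """\
chr1\tsrc\tgene\t101\t1000\t.\t+\t.\tgene_id "geneA"; transcript_id "geneA.t1";
chr1\tsrc\texon\t101\t1000\t.\t+\t.\tgene_id "geneA"; transcript_id "geneA.t1";
chr1\tsrc\tCDS\t101\t400\t.\t+\t.\tgene_id "geneA"; transcript_id "geneA.t1";
chr1\tsrc\tthree_prime_utr\t401\t1000\t.\t+\t.\tgene_id "geneA"; transcript_id "geneA.t1";
"""

BED12_ONE_GENE = "chr1\t100\t1000\tgeneA\t0\t+\t100\t400\t0\t1\t900\t0\n"


def test_gtf_and_bed12_encodings_give_identical_model(tmp_path):
    """1-based closed GTF and 0-based half-open BED12 converge internally."""
    gtf = tmp_path / "g.gtf"
    gtf.write_text(GTF_ONE_GENE)
    bed = tmp_path / "g.bed"
    bed.write_text(BED12_ONE_GENE)
    (m_gtf,) = load_gene_models(gtf)
    (m_bed,) = load_gene_models(bed)
    for m in (m_gtf, m_bed):
        assert m.junction == 400
        assert m.cds_length == 300
        assert m.utr3_length == 600
    assert m_gtf.cds_intervals == m_bed.cds_intervals
    assert m_gtf.utr3_intervals == m_bed.utr3_intervals


def test_utr_derived_from_exon_minus_cds_when_no_utr_feature(tmp_path):
    gtf = tmp_path / "g.gtf"
    gtf.write_text(
        'chr1\ts\texon\t101\t1000\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        'chr1\ts\tCDS\t101\t400\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
    )
    (m,) = load_gene_models(gtf)
    assert m.utr3_intervals == [GenomicInterval("chr1", 400, 1000, "+")]


def test_union_policy_merges_transcript_utrs(tmp_path):
    """UTRs [400,1000) and [400,1500) across transcripts union to [400,1500)."""
    rows = []
    for tid, utr_end in (("t1", 1000), ("t2", 1500)):
        rows += [
            f'chr1\ts\texon\t101\t{utr_end}\t.\t+\t.\tgene_id "g"; transcript_id "{tid}";',
            f'chr1\ts\tCDS\t101\t400\t.\t+\t.\tgene_id "g"; transcript_id "{tid}";',
            f'chr1\ts\tthree_prime_utr\t401\t{utr_end}\t.\t+\t.\tgene_id "g"; transcript_id "{tid}";',
        ]
    gtf = tmp_path / "g.gtf"
    gtf.write_text("\n".join(rows) + "\n")
    (m,) = load_gene_models(gtf, "union")
    assert m.utr3_intervals == [GenomicInterval("chr1", 400, 1500, "+")]
    (m_longest,) = load_gene_models(gtf, "longest_transcript")
    assert m_longest.utr3_intervals == [GenomicInterval("chr1", 400, 1500, "+")]


def test_gene_missing_utr_is_skipped_with_warning(tmp_path):
    gtf = tmp_path / "g.gtf"
    gtf.write_text(
        'chr1\ts\texon\t101\t400\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        'chr1\ts\tCDS\t101\t400\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
    )
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        assert load_gene_models(gtf) == []
    assert any("skipped" in str(w.message) for w in rec)


def test_bed12_round_trip(default_dataset, tmp_path):
    path = tmp_path / "rt.bed"
    write_bed12(default_dataset.models, path)
    reloaded = {m.gene_id: m for m in load_gene_models(path)}
    assert set(reloaded) == {m.gene_id for m in default_dataset.models}
    for m in default_dataset.models:
        r = reloaded[m.gene_id]
        assert r.cds_intervals == m.cds_intervals
        assert r.utr3_intervals == m.utr3_intervals
        assert r.junction == m.junction


def test_cds_and_utr_disjoint_and_nonempty(default_dataset):
    for m in default_dataset.models:
        assert m.cds_length >= 1 and m.utr3_length >= 1
        for c in m.cds_intervals:
            for u in m.utr3_intervals:
                assert c.overlap_bp(u) == 0


def test_overlapping_regions_resolved_to_cds():
    m = GeneModel(
        "g", "g", "chr1", "+",
        [GenomicInterval("chr1", 100, 450, "+")],
        [GenomicInterval("chr1", 400, 1000, "+")],
    )
    assert m.utr3_intervals == [GenomicInterval("chr1", 450, 1000, "+")]
    assert m.junction == 450


@pytest.mark.parametrize(
    "strand,junction,expected_up,expected_down",
    [("+", 400, (150, 400), (400, 650)), ("-", 600, (600, 850), (350, 600))],
)
def test_junction_flank_bins_are_transcript_oriented(
    plus_gene, minus_gene, strand, junction, expected_up, expected_down
):
    model = plus_gene if strand == "+" else minus_gene
    bins = {b.offset: b for b in junction_flank(model, 250, 1)}
    assert model.junction == junction
    assert (bins[-1].interval.start, bins[-1].interval.end) == expected_up
    assert (bins[1].interval.start, bins[1].interval.end) == expected_down


def test_junction_flank_clips_to_gene_span(plus_gene):
    # gene span starts at 100; the second upstream bin [-2] would reach -100
    bins = {b.offset: b for b in junction_flank(plus_gene, 250, 2)}
    assert bins[-2].interval.start == 100
    assert bins[-2].partial
    assert not bins[-1].partial


def test_interval_set_arithmetic():
    a = [GenomicInterval("c", 0, 100), GenomicInterval("c", 50, 150)]
    assert merge_intervals(a) == [GenomicInterval("c", 0, 150)]
    diff = subtract_intervals(
        [GenomicInterval("c", 0, 100)], [GenomicInterval("c", 40, 60)]
    )
    assert diff == [GenomicInterval("c", 0, 40), GenomicInterval("c", 60, 100)]


def test_spliced_projection_round_trip(minus_gene):
    # minus strand: spliced UTR offset 0 is the genomic base just left of 600
    assert minus_gene.genomic_to_spliced("UTR3", 599) == 0
    assert minus_gene.genomic_to_spliced("UTR3", 100) == 499
    ivs = minus_gene.spliced_to_genomic("UTR3", 0, 100)
    assert ivs == [GenomicInterval("chr1", 500, 600, "-")]
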