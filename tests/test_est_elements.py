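import numpy as np
import pytest

from i3utr.est_elements import (
    FragmentClass,
    classify_fragment,
    element_overlap,
    element_permutation_test,
    read_bed6,
    summarize_ests,
    write_bed6,
)
from i3utr.gene_models import GenomicInterval
from i3utr.peaks import Peak, PeakSet


def iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


@pytest.mark.parametrize(
    "frag,expected",
    [
        ((500, 800), FragmentClass.UTR_ONLY),
        ((350, 450), FragmentClass.MIXED),     # straddles junction at 400
        ((150, 250), FragmentClass.CDS_ONLY),
        ((2000, 2100), FragmentClass.OUTSIDE),
        ((300, 400), FragmentClass.CDS_ONLY),  # ends at junction: CDS side only
        ((400, 500), FragmentClass.UTR_ONLY),  # junction base is 3'UTR side
    ],
)
def test_fragment_classification(plus_gene, frag, expected):
    assert classify_fragment(iv(*frag), plus_gene) is expected


def test_min_overlap_raises_the_bar(plus_gene):
    frag = iv(390, 405)  # 10 bp CDS, 5 bp UTR
    assert classify_fragment(frag, plus_gene) is FragmentClass.MIXED
    assert classify_fragment(frag, plus_gene, min_overlap_bp=6) is FragmentClass.CDS_ONLY
    assert classify_fragment(frag, plus_gene, min_overlap_bp=11) is FragmentClass.OUTSIDE


def test_summary_counts_and_fractions(plus_gene):
    frags = (
        [iv(450 + 10 * i, 600 + 10 * i) for i in range(8)]  # 8 UTR-only
        + [iv(120, 200)]                                      # 1 CDS-only
        + [iv(380, 460)]                                      # 1 mixed
    )
    summary, _profile = summarize_ests(frags, plus_gene)
    assert (summary.n_utr_only, summary.n_cds_only, summary.n_mixed) == (8, 1, 1)
    assert summary.frac_utr_only == pytest.approx(0.8)
    assert summary.frac_cds_only == pytest.approx(0.1)
    assert summary.frac_mixed == pytest.approx(0.1)
    assert summary.n_total == 10


def test_ests_ending_at_junction_are_never_mixed(plus_gene):
    frags = [iv(300, 400), iv(250, 400)]
    summary, _ = summarize_ests(frags, plus_gene)
    assert summary.n_mixed == 0
    assert summary.n_cds_only == 2


def test_valley_spanning_count(plus_gene):
    # UTR spliced coords: valley [400,800) of the 600-bp UTR -> genomic [800,1200)?
    # plus_gene UTR is [400,1000): use valley (100, 400) -> genomic [500,800)
    ps = PeakSet(
        "geneA",
        peaks=[Peak(0, 100, [200.0], 1), Peak(400, 600, [200.0], 1)],
        valleys=[(100, 400)],
    )
    summary, _ = summarize_ests(
        [iv(450, 850), iv(450, 700)], plus_gene, peakset=ps
    )
    assert summary.n_spanning_internal_valley == 1


def test_summary_partition_matches_bruteforce_on_random_fragments(plus_gene):
    rng = np.random.default_rng(17)
    for _ in range(200):
        frags = []
        for _i in range(int(rng.integers(1, 40))):
            s = int(rng.integers(0, 1500))
            frags.append(iv(s, s + int(rng.integers(20, 700))))
        summary, _ = summarize_ests(frags, plus_gene)
        # oracle: per-base overlap with each region
        n = {c: 0 for c in FragmentClass}
        for f in frags:
            cds = sum(
                1 for p in range(f.start, f.end)
                if any(c.contains(p) for c in plus_gene.cds_intervals)
            )
            utr = sum(
                1 for p in range(f.start, f.end)
                if any(u.contains(p) for u in plus_gene.utr3_intervals)
            )
            key = (
                FragmentClass.MIXED if cds and utr
                else FragmentClass.UTR_ONLY if utr
                else FragmentClass.CDS_ONLY if cds
                else FragmentClass.OUTSIDE
            )
            n[key] += 1
        assert summary.n_utr_only == n[FragmentClass.UTR_ONLY]
        assert summary.n_cds_only == n[FragmentClass.CDS_ONLY]
        assert summary.n_mixed == n[FragmentClass.MIXED]
        assert summary.n_outside == n[FragmentClass.OUTSIDE]
        assert summary.n_total + summary.n_outside == len(frags)


def _peakset(peaks, valleys=()):
    return PeakSet(
        "geneA",
        peaks=[Peak(s, e, [200.0], 1) for s, e in peaks],
        valleys=list(valleys),
    )


def test_element_midpoint_assignment(plus_gene):
    # UTR spliced [0,600) = genomic [400,1000); peak (100,300) = [500,700)
    ps = _peakset([(100, 300)], [(300, 550)])
    elements = [
        (iv(510, 520), "miRNA_site"),   # midpoint 515 in peak
        (iv(720, 780), "CpG"),          # midpoint in valley [700,950)
        (iv(150, 160), "TF_cluster"),   # midpoint in CDS: elsewhere
        (iv(5000, 5100), "CpG"),        # outside gene span
    ]
    reports = element_overlap(elements, ps, plus_gene)
    assert reports["miRNA_site"].n_in_peaks == 1
    assert reports["miRNA_site"].peak_fraction == 1.0
    assert reports["CpG"].n_in_valleys == 1
    assert reports["CpG"].n_outside_gene == 1
    assert reports["TF_cluster"].n_elsewhere == 1


def test_permutation_test_enrichment_and_degenerate_cases(plus_gene):
    # peaks cover [500,700): 200 bp of the 900-bp span
    ps = _peakset([(100, 300)])
    inside = [iv(510 + 20 * i, 518 + 20 * i) for i in range(5)]
    p = element_permutation_test(inside, ps, plus_gene, n_perm=1000, seed=0)
    assert p <= 0.01  # null exceedance bounded by (200/900)^5 per permutation
    # peaks covering the whole span: degenerate
    ps_full = _peakset([(0, 600)])
    ps_full.peaks[0].genomic_intervals = [iv(100, 1000)]
    with pytest.warns(UserWarning, match="degenerate"):
        assert element_permutation_test(inside, ps_full, plus_gene, 10, 0) == 1.0
    with pytest.raises(ValueError):
        element_permutation_test(inside, ps, plus_gene, n_perm=0)
    with pytest.raises(ValueError):
        element_permutation_test([], ps, plus_gene)


def test_permutation_p_deterministic_given_seed(plus_gene):
    ps = _peakset([(100, 300)])
    els = [iv(420 + 50 * i, 470 + 50 * i) for i in range(4)]
    p1 = element_permutation_test(els, ps, plus_gene, n_perm=500, seed=123)
    p2 = element_permutation_test(els, ps, plus_gene, n_perm=500, seed=123)
    assert p1 == p2


def test_bed6_round_trip(tmp_path):
    records = [(iv(10, 50), "a|CpG"), (iv(60, 90, strand="-"), "b|miRNA_site")]
    path = tmp_path / "x.bed"
    write_bed6(records, path)
    assert read_bed6(path) == records
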