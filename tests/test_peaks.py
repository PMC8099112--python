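import numpy as np
import pytest

from i3utr.gene_models import GeneModel, GenomicInterval
from i3utr.peaks import (
    PatternType,
    PeakParams,
    PeakSet,
    call_consensus_peaks,
    call_gene_peakset,
    call_valleys,
    classify_pattern,
    per_base_fpkm,
)

from conftest import bruteforce_consensus_peaks


def const(fpkm, n):
    return np.full(n, float(fpkm))


def profile(n, segments, floor=0.0):
    """Array of length n with (start, end, value) segments over a floor."""
    a = np.full(n, float(floor))
    for s, e, v in segments:
        a[s:e] = v
    return a


def test_per_base_fpkm_unit_cases():
    np.testing.assert_allclose(per_base_fpkm(np.ones(10), 10**9), np.ones(10))
    np.testing.assert_allclose(
        per_base_fpkm(2 * np.ones(4), 2 * 10**9), np.ones(4)
    )
    assert per_base_fpkm(np.array([5]), 10**7)[0] == pytest.approx(500.0)
    with pytest.raises(ValueError):
        per_base_fpkm(np.ones(3), 0)


def test_single_run_in_all_replicates_is_one_peak():
    arrs = [profile(1000, [(100, 300, 200.0)]) for _ in range(4)]
    (peak,) = call_consensus_peaks(arrs)
    assert (peak.start, peak.end) == (100, 300)
    assert peak.n_supporting_replicates == 4


@pytest.mark.parametrize("run_len,n_peaks", [(150, 0), (151, 1), (152, 1)])
def test_run_length_bound_is_strictly_greater_than_150(run_len, n_peaks):
    arrs = [profile(1000, [(100, 100 + run_len, 200.0)]) for _ in range(4)]
    assert len(call_consensus_peaks(arrs)) == n_peaks


def test_threshold_is_strictly_greater_than_100():
    arrs = [profile(1000, [(100, 400, 100.0)]) for _ in range(4)]
    assert call_consensus_peaks(arrs) == []
    arrs = [profile(1000, [(100, 400, 100.0 + 1e-9)]) for _ in range(4)]
    assert len(call_consensus_peaks(arrs)) == 1


def test_peak_requires_all_replicates_by_default():
    above = profile(1000, [(100, 300, 200.0)])
    arrs = [above, above, above, const(0, 1000)]
    assert call_consensus_peaks(arrs) == []
    assert len(call_consensus_peaks(arrs, PeakParams(min_replicates=3))) == 1


def test_consensus_matches_bruteforce_oracle_on_random_profiles():
    rng = np.random.default_rng(42)
    params = PeakParams()
    for _ in range(200):
        n = int(rng.integers(200, 3000))
        n_rep = int(rng.integers(1, 7))
        # piecewise-constant profiles with values straddling the threshold
        vals = np.array([0.0, 50.0, 99.9, 100.0, 100.1, 150.0, 400.0])
        arrs = []
        for _r in range(n_rep):
            n_seg = int(rng.integers(1, 12))
            edges = np.sort(rng.integers(0, n, size=n_seg))
            arr = np.repeat(
                rng.choice(vals, size=n_seg + 1),
                np.diff(np.concatenate(([0], edges, [n]))),
            )
            arrs.append(arr)
        peaks = call_consensus_peaks(arrs, params)
        oracle = bruteforce_consensus_peaks(arrs, 100.0, 151, n_rep)
        assert [(p.start, p.end) for p in peaks] == oracle


def test_valleys_complement_peaks():
    # uniform sub-threshold UTR: one valley covering everything
    arrs = [const(50, 1000) for _ in range(4)]
    assert call_valleys(arrs, []) == [(0, 1000)]
    # two 300-bp peaks with a 400-bp gap: the gap is the (only internal) valley
    arrs = [
        profile(1000, [(0, 300, 200.0), (700, 1000, 200.0)]) for _ in range(4)
    ]
    peaks = call_consensus_peaks(arrs)
    valleys = call_valleys(arrs, peaks)
    assert valleys == [(300, 700)]
    # a 100-bp gap is too short to be a valley
    arrs = [
        profile(700, [(0, 300, 200.0), (400, 700, 200.0)]) for _ in range(4)
    ]
    peaks = call_consensus_peaks(arrs)
    assert call_valleys(arrs, peaks) == []


def test_peaks_and_valleys_never_overlap():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(400, 2000))
        arrs = [rng.choice([0.0, 150.0], size=n) for _ in range(3)]
        peaks = call_consensus_peaks(arrs)
        valleys = call_valleys(arrs, peaks)
        occupied = np.zeros(n, dtype=int)
        for p in peaks:
            occupied[p.start : p.end] += 1
        for s, e in valleys:
            occupied[s:e] += 1
        assert occupied.max() <= 1


def test_peak_calls_invariant_to_joint_depth_library_scaling():
    rng = np.random.default_rng(9)
    depth = rng.integers(0, 40, size=2000)
    for scale in (1, 5, 20):
        arrs = [per_base_fpkm(depth * scale, 10**8 * scale)] * 4
        ref = [per_base_fpkm(depth, 10**8)] * 4
        assert [
            (p.start, p.end) for p in call_consensus_peaks(arrs)
        ] == [(p.start, p.end) for p in call_consensus_peaks(ref)]


def test_unequal_replicate_lengths_rejected():
    with pytest.raises(ValueError, match="unequal"):
        call_consensus_peaks([const(0, 10), const(0, 11)])


def _model(cds_len=1000, utr_len=1000):
    return GeneModel(
        "g", "g", "chr1", "+",
        [GenomicInterval("chr1", 0, cds_len, "+")],
        [GenomicInterval("chr1", cds_len, cds_len + utr_len, "+")],
    )


def test_pattern_type_i_multiple_internal_peaks():
    utr = [profile(3000, [(200, 600, 300.0), (2000, 2500, 300.0)], floor=20.0)] * 4
    cds = [const(20, 1000)] * 4
    ps = call_gene_peakset("g", utr, _model(1000, 3000), cds)
    assert ps.pattern_type is PatternType.TYPE_I


def test_pattern_type_ii_junction_peak_short_utr():
    utr = [profile(600, [(0, 450, 300.0)], floor=20.0)] * 4
    cds = [const(300, 1000)] * 4
    ps = call_gene_peakset("g", utr, _model(1000, 600), cds)
    assert ps.pattern_type is PatternType.TYPE_II


def test_pattern_type_iii_long_utr_confined_cds():
    utr = [profile(2500, [(300, 1800, 300.0)], floor=20.0)] * 4
    cds = [profile(1200, [(1000, 1200, 250.0)], floor=10.0)] * 4
    ps = call_gene_peakset("g", utr, _model(1200, 2500), cds)
    assert ps.pattern_type is PatternType.TYPE_III


def test_pattern_unclassified_without_peaks():
    utr = [const(20, 1500)] * 4
    ps = call_gene_peakset("g", utr, _model(1000, 1500), [const(20, 1000)] * 4)
    assert ps.pattern_type is PatternType.UNCLASSIFIED
    assert ps.rule_trace == "no peaks"


def test_pattern_long_utr_with_spread_cds_not_type_iii():
    utr = [profile(2500, [(300, 1800, 300.0)], floor=20.0)] * 4
    cds = [const(300, 1200)] * 4  # CDS hot everywhere: not junction-confined
    ps = call_gene_peakset("g", utr, _model(1200, 2500), cds)
    assert ps.pattern_type is PatternType.UNCLASSIFIED


def test_per_replicate_intersection_mode_differs_when_runs_misalign():
    # replicate runs individually long but overlapping by < 151 bp:
    # per-base consensus keeps only the shared part (too short); the
    # per-replicate mode intersects called peaks with the same result, but
    # a shared long run passes in both modes
    a = profile(1000, [(0, 400, 200.0)])
    b = profile(1000, [(300, 800, 200.0)])
    for mode in ("per_base", "per_replicate_intersection"):
        peaks = call_consensus_peaks([a, b], PeakParams(consensus=mode))
        assert peaks == []
    shared = profile(1000, [(100, 500, 200.0)])
    for mode in ("per_base", "per_replicate_intersection"):
        peaks = call_consensus_peaks([shared, shared], PeakParams(consensus=mode))
        assert [(p.start, p.end) for p in peaks] == [(100, 500)]


def test_noisy_boundaries_recovered_within_25bp():
    """Poisson noise at 2x-threshold peak / 0.5x valley FPKM: boundaries
    within +-25 bp in >= 95% of seeded trials."""
    rng = np.random.default_rng(11)
    lib = 500_000_000
    expected = profile(2000, [(400, 900, 200.0)], floor=50.0) * lib / 1e9
    ok = 0
    trials = 100
    for _ in range(trials):
        arrs = [
            per_base_fpkm(rng.poisson(expected), lib) for _ in range(4)
        ]
        peaks = call_consensus_peaks(arrs)
        if len(peaks) == 1 and abs(peaks[0].start - 400) <= 25 and abs(
            peaks[0].end - 900
        ) <= 25:
            ok += 1
    assert ok >= 95
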