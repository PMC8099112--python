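import filecmp

import numpy as np
import pytest

from i3utr.est_elements import classify_fragment
from i3utr.gene_models import load_gene_models
from i3utr.peaks import PeakParams, call_consensus_peaks, per_base_fpkm
from i3utr.simulate import (
    GeneDesign,
    PeakBlueprint,
    SimulationConfig,
    default_designs,
    generate_gene_models,
    simulate_coverage,
    simulate_dataset,
    simulate_elements,
    simulate_ests,
)


def test_default_scenario_composition():
    designs = default_designs()
    assert len(designs) == 30
    ratios = [d.true_ratio for d in designs if d.expressed_truth]
    assert min(ratios) <= 0.1 and max(ratios) >= 0.9
    types = {d.pattern_type_truth.value for d in designs}
    assert {"TYPE_I", "TYPE_II", "TYPE_III", "UNCLASSIFIED"} <= types


def test_identical_seed_reproduces_dataset_files(tmp_path):
    cfg = SimulationConfig(seed=5, n_replicates=2, n_ests=40)
    designs = default_designs()[:4]
    p1 = simulate_dataset(cfg, designs).write(tmp_path / "a")
    p2 = simulate_dataset(cfg, designs).write(tmp_path / "b")
    for key in p1:
        assert filecmp.cmp(p1[key], p2[key], shallow=False), key


def test_different_seeds_differ():
    designs = default_designs()[:2]
    d1 = simulate_dataset(SimulationConfig(seed=1, n_replicates=1), designs)
    d2 = simulate_dataset(SimulationConfig(seed=2, n_replicates=1), designs)
    g = designs[0].gene_id
    assert not np.array_equal(
        d1.replicates[0].depth[g]["UTR3"], d2.replicates[0].depth[g]["UTR3"]
    )


def test_written_annotation_round_trips_through_loader(tiny_dataset, tmp_path):
    paths = tiny_dataset.write(tmp_path)
    for key in ("gtf", "bed12"):
        loaded = {m.gene_id: m for m in load_gene_models(paths[key])}
        for m in tiny_dataset.models:
            r = loaded[m.gene_id]
            assert r.cds_intervals == m.cds_intervals
            assert r.utr3_intervals == m.utr3_intervals
            assert r.junction == m.junction


def test_duplicate_gene_ids_rejected():
    d = default_designs()[0]
    with pytest.raises(ValueError, match="duplicate"):
        generate_gene_models(SimulationConfig(), [d, d])


def test_invalid_designs_rejected():
    with pytest.raises(ValueError, match="overlap"):
        GeneDesign(
            "g", 900, 2000,
            peak_blueprints=[PeakBlueprint(0, 500, 200), PeakBlueprint(400, 300, 200)],
        )
    with pytest.raises(ValueError, match="outside"):
        GeneDesign("g", 900, 1000, peak_blueprints=[PeakBlueprint(800, 400, 200)])


def test_noise_free_coverage_reproduces_blueprints_exactly():
    cfg = SimulationConfig(seed=0, noise="none", library_size_jitter=(1.0, 1.0))
    design = GeneDesign(
        "g", 1200, 3000, designed_ratio=0.7,
        peak_blueprints=[PeakBlueprint(200, 400, 300.0), PeakBlueprint(2000, 500, 300.0)],
    )
    rng = np.random.default_rng(0)
    rep = simulate_coverage([design], cfg, 0, rng)
    fpkm = per_base_fpkm(rep.depth["g"]["UTR3"], rep.total_mapped_reads)
    peaks = call_consensus_peaks([fpkm] * 4, PeakParams())
    assert [(p.start, p.end) for p in peaks] == [(200, 600), (2000, 2500)]


def test_designed_fpkm_to_depth_inverse():
    cfg = SimulationConfig(
        seed=0, noise="none", library_size=10**8, library_size_jitter=(1.0, 1.0)
    )
    design = GeneDesign(
        "g", 900, 1000, designed_ratio=0.5,
        peak_blueprints=[PeakBlueprint(0, 1000, 200.0)],
    )
    rep = simulate_coverage([design], cfg, 0, np.random.default_rng(0))
    assert rep.total_mapped_reads == 10**8
    np.testing.assert_array_equal(rep.depth["g"]["UTR3"], np.full(1000, 20))


def test_est_labels_agree_with_classifier(tiny_dataset):
    """Closed loop: every simulated EST is classified as its truth label."""
    for gene_id, ests in tiny_dataset.ests.items():
        model = tiny_dataset.model_for(gene_id)
        for interval, label in ests:
            assert classify_fragment(interval, model).value == label


def test_est_mixture_extremes():
    cfg = SimulationConfig(seed=3, est_mixture=(1.0, 0.0, 0.0), n_ests=50)
    design = default_designs()[0]
    ds = simulate_dataset(cfg, [design])
    labels = {lab for _, lab in ds.ests[design.gene_id]}
    assert labels == {"UTR_ONLY"}
    cfg = SimulationConfig(seed=3, est_mixture=(0.0, 0.0, 1.0), n_ests=10)
    ds = simulate_dataset(cfg, [design])
    model = ds.model_for(design.gene_id)
    for interval, lab in ds.ests[design.gene_id]:
        assert lab == "MIXED"
        assert interval.start < model.junction < interval.end


def test_elements_land_in_designed_regions(tiny_dataset):
    from i3utr.est_elements import element_overlap
    from i3utr.peaks import Peak, PeakSet
    from i3utr.simulate import _designed_valleys

    for gene_id, elements in tiny_dataset.elements.items():
        design = next(d for d in tiny_dataset.designs if d.gene_id == gene_id)
        model = tiny_dataset.model_for(gene_id)
        ps = PeakSet(
            gene_id,
            peaks=[
                Peak(b.offset_bp, b.end_bp, [b.fpkm], 1)
                for b in design.peak_blueprints
            ],
            valleys=_designed_valleys(design),
        )
        reports = element_overlap(elements, ps, model)
        for category, rep in reports.items():
            if category == "miRNA_site":
                assert rep.peak_fraction == 1.0
            else:
                assert rep.n_in_valleys == rep.n_total


def test_element_placement_errors_when_no_window():
    design = GeneDesign(
        "g", 900, 1000, designed_ratio=0.5,
        peak_blueprints=[PeakBlueprint(0, 1000, 200.0)],  # no valley at all
    )
    cfg = SimulationConfig()
    models = generate_gene_models(cfg, [design])
    with pytest.raises(ValueError, match="no valleys window|no valley|window"):
        simulate_elements(design, models[0], cfg, np.random.default_rng(0))


def test_negative_binomial_noise_is_overdispersed():
    cfg_p = SimulationConfig(seed=4, noise="poisson", library_size_jitter=(1.0, 1.0))
    cfg_nb = SimulationConfig(
        seed=4, noise="negative_binomial", nb_dispersion=0.5,
        library_size_jitter=(1.0, 1.0),
    )
    design = GeneDesign(
        "g", 900, 4000, designed_ratio=0.5,
        peak_blueprints=[PeakBlueprint(0, 4000, 200.0)],
    )
    var = {}
    for name, cfg in (("p", cfg_p), ("nb", cfg_nb)):
        rep = simulate_coverage([design], cfg, 0, np.random.default_rng(cfg.seed))
        var[name] = rep.depth["g"]["UTR3"].var()
    assert var["nb"] > 2 * var["p"]
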