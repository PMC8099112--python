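"""Simulate the default 30-gene dataset and run the full pipeline on it.

Writes the synthetic files (GTF, per-replicate bedGraph + counts, EST and
element BEDs, ground truth), runs every stage, and compares the recovered
per-gene class and pattern type with the designed truth.
"""

import tempfile
from pathlib import Path

import pandas as pd

from i3utr.pipeline import ReplicateInput, RunConfig, run_pipeline
from i3utr.simulate import SimulationConfig, simulate_dataset

root = Path(tempfile.mkdtemp(prefix="i3utr_demo_"))
ds = simulate_dataset(SimulationConfig(seed=1))
paths = ds.write(root / "data")
libs = (
    pd.read_csv(paths["libraries"], sep="\t")
    .set_index("replicate_id")["total_mapped_reads"].to_dict()
)
config = RunConfig(
    annotation=paths["gtf"],
    replicates=[
        ReplicateInput(r.replicate_id, paths[f"bedgraph_{r.replicate_id}"],
                       paths[f"counts_{r.replicate_id}"], libs[r.replicate_id])
        for r in ds.replicates
    ],
    out_dir=root / "out",
    est_bed=paths["ests"],
    element_bed=paths["elements"],
    n_perm=200,
    seed=2,
)
result = run_pipeline(config)

truth = ds.truth.set_index("gene_id")
rows = []
for rec in result.pooled_records:
    t = truth.loc[rec.gene_id]
    ps = result.peaksets[rec.gene_id]
    rows.append({
        "gene": rec.gene_id,
        "ratio": None if rec.ratio is None else round(rec.ratio, 3),
        "true_ratio": round(t.true_ratio, 3) if t.expressed else None,
        "class": rec.klass.value,
        "true_class": t.true_class,
        "pattern": ps.pattern_type.value,
        "true_pattern": t.pattern_type,
        "peaks": len(ps.peaks),
    })
df = pd.DataFrame(rows)
print(df.to_string(index=False))
n_class = (df["class"] == df["true_class"]).sum()
n_pat = (df["pattern"] == df["true_pattern"]).sum()
print(f"\nclass recovered for {n_class}/{len(df)} genes, "
      f"pattern type for {n_pat}/{len(df)}")
print(f"replicate Hi-set concordance (Jaccard %):\n"
      f"{result.concordance[['replicate_a', 'replicate_b', 'percent_identity']].to_string(index=False)}")
print(f"\nall stage outputs under {result.out_dir}")
# Estimated ratios track the designed truth to ~3 decimals at this depth;
# the few class mismatches (if any) sit inside the 0.4-0.6 gray band where
# the Hi/Lo calls are intentionally undecided.
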