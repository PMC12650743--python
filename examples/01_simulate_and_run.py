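"""Simulate a blood RNA-seq study and run the full DiRT pipeline.

Generates counts with per-gene time-point batch drift and 10 planted
2-fold DEGs, runs abundance filtering, the CPM/RLE/TMM baselines, the
candidate-index scan, pair tests and the index-validity filter, then
prints the pipeline funnel and the best-ranked targets.
"""

import warnings

import numpy as np

from dirtnorm import RunConfig, SimConfig, run_pipeline, simulate_counts

warnings.filterwarnings("ignore")

cfg = SimConfig(
    n_genes=600,
    controls_per_tp=8,
    cases_per_tp=8,
    n_timepoints=3,
    batch_mode="module",
    batch_log_sd=0.4,
    dispersion=0.02,
    n_degs=10,
    fold_range=(2.0, 2.0),
    n_stable_pairs=10,
    seed=42,
)
counts, design, truth = simulate_counts(cfg)
result = run_pipeline(counts, design, RunConfig(n_top=600))

print("pipeline funnel (pair counts in/out of each stage):")
for stage, n in result.funnel.items():
    print(f"  {stage}: {n}")

print("\ntop 10 targets by best adjusted p (planted DEGs marked *):")
for _, row in result.summaries.table.head(10).iterrows():
    mark = "*" if row.target_gene in truth.deg_ids else " "
    print(
        f" {mark} {row.target_gene} / index {row.best_index_gene}  "
        f"p_adj={row.best_p_adj:.2e}  ({row.n_valid_pairs} valid pairs)"
    )

degs = sorted(truth.deg_ids)
best = result.summaries.table.set_index("target_gene")["best_p_adj"]
dirt_med = np.median([best.get(g, 1.0) for g in degs])
cpm = result.gene_stats["cpm"].set_index("gene_id")["p_adj"]
cpm_med = np.median([cpm.get(g, 1.0) for g in degs])
print(
    f"\nmedian adjusted p over the {len(degs)} planted DEGs: "
    f"DiRT {dirt_med:.2e} vs CPM-scale t-test {cpm_med:.2e}"
)
print("smaller is better: the ratio transform cancels the per-gene batch "
      "drift that inflates the CPM-scale within-group variance.")
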