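"""Full pipeline: cluster systems by dynamic signature and localize the
time window where a variant diverges from the reference.

Ward clustering of the pairwise normalized-DTW matrix separates the
systems; PELT on the smoothed cross-system deviation profile marks where
along the trajectory the variant's contact dynamics depart from the
reference -- here, at the planted latent-state boundary.
"""

from netmd import GeneratorSpec, generate_ensemble
from netmd.pipeline import PipelineConfig, run_pipeline

spec = GeneratorSpec(
    n_systems=2, replicas_per_system=3, n_frames=150, length_jitter=10,
    n_residues=24, vocabulary_size=100, n_states=2, canonical_boundaries=(75,),
    condition_edges=15, outlier=None, seed=4,
)
tables, truth = generate_ensemble(spec)

config = PipelineConfig(out_dir="scratch/example_run", seed=4, epochs=40, cp_window=11)
result = run_pipeline(config, tables=tables)

sol = result.cluster_solution
print(f"selected k = {sol.k} clusters ({sol.criterion} criterion)")
for rid in sorted(sol.assignment):
    print(f"  {rid} (true system {truth.system_of[rid]}) -> cluster {sol.assignment[rid]}")

import numpy as np

for pair, cps in result.changepoints.items():
    print(f"change points for {pair} (consensus-axis frames): {cps}")
bary = result.consensus["S0"]
best_i = int(np.argmin(bary.normalized_costs))
truth_frame = truth.replica_boundaries[bary.replica_ids[best_i]][0]
truth_t = next(
    t for t, fr in enumerate(bary.associations[best_i]) if truth_frame in fr
)
print(f"ground-truth divergence onset on the consensus axis: {truth_t}")
print("a detected change point near that index localizes the variant effect")
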