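"""Detect drug-induced hypoconnectivity in resting-state networks.

Simulates a vehicle group whose 48 regions organize into four coupled
modules (within-module correlation 0.6) and a drug group whose generating
covariance off-diagonals are scaled by 0.3 (global hypoconnectivity).  Both
groups run through the full chain: preprocessing, region time courses,
pairwise Pearson/Fisher-Z edges, one-group t Z-score matrices, |Z| >= 2.3
thresholding, degree centrality, and the per-subregion paired comparison.
"""

import numpy as np

import phmri
from phmri import RestingSimConfig
from phmri.pipelines import run_connectivity_study, simulate_resting_group
from phmri.synthetic import block_covariance

n_regions = 48
atlas = phmri.generate_atlas(n_regions, (32, 32, 16), seed=3)
cov_vehicle = block_covariance([10, 10, 10, 10, 8], within=0.6)
cov_drug = cov_vehicle.copy()
cov_drug[~np.eye(n_regions, dtype=bool)] *= 0.3

vehicle = simulate_resting_group(
    atlas, RestingSimConfig(node_covariance=cov_vehicle), 6, seed=10, label="veh")
drug = simulate_resting_group(
    atlas, RestingSimConfig(node_covariance=cov_drug), 7, seed=11, label="drug")

subregions = {
    "sensorimotor": list(range(1, 11)),
    "thalamus": list(range(11, 21)),
    "prefrontal": list(range(21, 31)),
    "basal_ganglia": list(range(31, 41)),
}
res = run_connectivity_study({"vehicle": vehicle, "drug": drug}, atlas, subregions)

print("Per-subregion degree centrality (mean +/- SD across member regions):")
print(res["degree_comparison"].to_string(index=False))
print("\nDirection '>' with p < 0.05 in every subregion means the vehicle")
print("network holds significantly more suprathreshold connections than the")
print("drug network - the planted global hypoconnectivity, recovered.")
print(f"\nMean degree: vehicle {res['vehicle']['network'].degrees.mean():.1f}, "
      f"drug {res['drug']['network'].degrees.mean():.1f} "
      f"(|Z| threshold 2.3, {len(res['vehicle']['node_ids'])} nodes)")
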