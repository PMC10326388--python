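"""Simulate a four-dose drug-challenge study and recover its inverted-U
dose-response.

Builds a 40-region synthetic atlas, simulates 6 vehicle and 3 x 7 drug
subjects whose planted regions respond at 0 / 0.5 / 2 / 0.5 percent
(inverted-U across doses), maps per-subject activation, counts per-region
activated voxels, and runs the Kruskal-Wallis dose comparison plus the
vehicle-versus-peak-dose rank-sum post-hoc with an across-region FDR
boundary.
"""

import phmri
from phmri import PhmriSimConfig
from phmri.pipelines import activation_study_from_sim

atlas = phmri.generate_atlas(40, (32, 32, 16), seed=7)
planted = frozenset({3, 7, 11, 19, 23, 31})
res = activation_study_from_sim(
    atlas, PhmriSimConfig(active_regions=planted), seed=42
)

kw = res["kruskal_wallis"]
print("Top of the dose-response table (per-group median voxel counts; the")
print("middle dose should dominate in planted regions", sorted(planted), "):")
print(kw.head(8).to_string(index=False))

ref, peak = res["posthoc_groups"]
ph = res["posthoc"]
print(f"\n{ref} vs {peak} rank-sum post-hoc (exact small-sample p-values):")
print(ph.head(8).to_string(index=False))
print(f"\nAcross-region FDR boundary p = {res['fdr_boundary_p']:.4f}")
print("Regions above were significant after the step-up filter; a planted")
print("region appearing here with direction '<' means the drug group's")
print("activated volume exceeded vehicle, as designed.")
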