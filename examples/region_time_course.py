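"""Percent-change time course of responding regions and the group x time
repeated-measures test.

Simulates a 2%-amplitude drug group (n = 7) against vehicle (n = 6),
extracts each subject's composite region time course, and tests the
group x time interaction with per-acquisition Welch contrasts at the
Sidak-corrected level.
"""

import numpy as np

import phmri
from phmri import PhmriSimConfig
from phmri.group_stats import rm_anova_interaction
from phmri.pipelines import simulate_phmri_study

atlas = phmri.generate_atlas(12, (24, 24, 12), seed=5)
regions = {2, 5, 9}
sim = PhmriSimConfig(
    active_regions=frozenset(regions),
    n_per_group={"vehicle": 6, "3mg": 7},
    amplitude_by_dose={"vehicle": 0.0, "3mg": 2.0},
)
study = simulate_phmri_study(atlas, sim, seed=8)

courses = {
    dose: np.vstack([phmri.time_course(scan, atlas, regions)
                     for scan, _ in subjects])
    for dose, subjects in study.items()
}
res = rm_anova_interaction(courses, compare_from=sim.onset_acquisition)

plateau = courses["3mg"][:, 300:].mean()
print(f"Drug-group plateau percent change (acquisitions 300+): {plateau:.2f}%")
print(f"Group x time interaction: F({res['df_interaction'][0]}, "
      f"{res['df_interaction'][1]}) = {res['F_interaction']:.1f}, "
      f"p = {res['p_interaction']:.2e}")
pt = res["per_timepoint"]
late = pt[pt["acquisition"] >= 286]
print(f"Sidak per-test alpha over {len(pt)} post-injection acquisitions: "
      f"{res['sidak_alpha']:.3e}")
print(f"Fraction of acquisitions 286+ individually significant: "
      f"{late['significant'].mean():.2f}")
print("A strong interaction with late-acquisition separation is the")
print("signature of a slow drug response riding on a flat vehicle course.")
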