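"""Quantify depolarization-induced suppression of inhibition (DSI).

Generates IPSC amplitude trials for a control cohort (endocannabinoid-
mediated suppression present) and an AM251 cohort (CB1 receptors blocked,
smaller effect), then summarizes percent suppression per cell and per
condition, including the paired pre/post and unpaired condition tests.
Also shows the 80->20 % decay measurement on an analytic IPSC.
"""
import math

import numpy as np
import pandas as pd

from id2phys import dsi, synth

trials = pd.concat([
    synth.gen_dsi_cohort(n_cells=18, mean_suppression=16.0, cell_sd=8.5,
                         condition="control", seed=1),
    synth.gen_dsi_cohort(n_cells=11, mean_suppression=8.0, cell_sd=3.3,
                         condition="AM251", seed=2),
])
per_cell, summary = dsi.dsi_summary(trials)

for cond, e in summary["conditions"].items():
    print(f"{cond:8s}: {e['mean_suppression_pct']:5.1f} +- "
          f"{e['sem_suppression_pct']:.1f} % suppression (n={e['n_cells']}), "
          f"pre-vs-post p={e['p_pre_vs_post']:.2g}")
print(f"control vs AM251 (unpaired): p={summary['p_control_vs_am251']:.3f}")

dt = 0.05
for label, tau in (("slow (NGFC-like) IPSC", 36.8), ("fast IPSC", 11.5)):
    t = np.arange(0, 15 * tau, dt)
    d = dsi.decay_80_20(150.0 * np.exp(-t / tau), dt, 0)
    print(f"{label}: 80->20 % decay = {d:.1f} ms (tau ln4 = {tau * math.log(4):.1f})")
print()
print("CB1 blockade roughly halves the planted suppression; the decay")
print("measure separates slow neurogliaform IPSCs from fast ones.")
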