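"""Quantify sensor specificity from in vitro ROI timelapses.

Simulates per-cell fluorescence traces for a strong ligand (histamine-like,
~150% response), a weak cross-reactive ligand (~12%), and a buffer control;
computes peak dF/F0 per cell, screens +/-2 SD outliers, and compares
ligands to the control with Welch ANOVA + Monte-Carlo Dunnett.
"""

import numpy as np

from peribout import dff_response, gen_roi_trace, outlier_filter, welch_anova_dunnett

LIGANDS = {"HBSS": 0.0, "histamine": 1.5, "acetylcholine": 0.12}
N_CELLS = 30

groups = []
for gi, (name, amp) in enumerate(LIGANDS.items()):
    rng = np.random.default_rng(100 + gi)
    peaks = []
    for cell in range(N_CELLS):
        jitter = max(0.0, amp * (1 + rng.normal(0, 0.25)))
        trace = gen_roi_trace(
            baseline_f=100.0, peak_dff=jitter, noise_sd=1.5, seed=int(rng.integers(2**31))
        )
        peaks.append(dff_response(trace)[1])
    kept, removed = outlier_filter(peaks)
    print(f"{name:14s} peak dF/F0 = {np.mean(kept):.3f} +/- {np.std(kept, ddof=1):.3f} "
          f"({removed.size} of {N_CELLS} cells removed as >2 SD outliers)")
    groups.append(kept)

res = welch_anova_dunnett(groups, control_index=0, n_mc=100_000, seed=0)
print(f"\nWelch ANOVA: F({res.df1:.0f},{res.df2:.1f}) = {res.F:.1f}, p = {res.p:.3g}")
for name, p in zip(LIGANDS, res.dunnett_p):
    if p is not None:
        print(f"  {name} vs HBSS: Dunnett p = {p:.4g}")
print("\nA ~1.5 dF/F0 histamine response versus ~0.12 for acetylcholine is the")
print("order-of-magnitude specificity margin the sensor needs for in vivo use.")
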