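"""Estimate per-subject atrophy rates and compare groups statistically.

Simulates per-visit indicator trajectories with group-dependent annual
decline, fits each subject's slope by linear least squares, and runs the
gatekept Kruskal-Wallis / Mann-Whitney / Holm analysis on the rates.
"""

import numpy as np
import pandas as pd

import mtlmorph as m

rng = np.random.default_rng(5)
true_rates = {"AD": -0.09, "MCI": -0.05, "NC": -0.03}
visits = np.array([0.0, 0.5, 1.0, 1.5, 2.0])

rows = []
for group, rate in true_rates.items():
    for i in range(15):
        base = rng.normal(-1.0, 0.2)
        for t in visits:
            rows.append({
                "subject_id": f"{group}{i:02d}", "group": group,
                "visit_time_years": t,
                "gmv_voi": base + rate * t + rng.normal(0, 0.03),
                "thickness_voi": 0.1 * (base + rate * t) + rng.normal(0, 0.004),
            })
table = pd.DataFrame(rows)

rates = m.estimate_rates(table)
print("mean recovered GMV indicator rate per year:")
print(rates.groupby("group")["gmv_rate"].mean().round(4))
print(f"(true rates: {true_rates})\n")

res = m.compare_groups(
    {g: rates.loc[rates.group == g, "gmv_rate"].to_numpy() for g in true_rates}
)
print(f"Kruskal-Wallis H = {res.H:.2f}, p = {res.p_overall:.2g}")
for (a, b), d in (res.pairwise or {}).items():
    flag = "*" if d["significant"] else " "
    print(f"  {a} vs {b}: U = {d['U']:5.1f}, Holm-corrected p = {d['p_corrected']:.4f} {flag}")

print(
    "\nPairwise tests run only because the omnibus test was significant;\n"
    "starred pairs differ at the Holm-corrected 0.05 level."
)
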