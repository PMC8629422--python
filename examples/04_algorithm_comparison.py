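"""Small-scale comparison of the three search algorithms.

Runs 30 trials per controller from the center start and reports success
rate, search time and SPT (success percentage per second), plus Fisher and
Steel-Dwass statistics.  (The full experiment uses 300+ trials per
controller per scenario; see scripts/acceptance.py.)
"""

import numpy as np

import surgecast as sc

plume = sc.PlumeConfig()
trial = sc.TrialConfig(record=False)
results = {}
for name in ("mim2", "surge_zigzag", "casting"):
    ts = sc.run_batch(plume, sc.make_controller(name), trial, n=30, base_seed=0)
    m = sc.metrics(ts)
    results[name] = (ts, m)
    mean_t = m.search_times.mean() if m.n_success else float("nan")
    print(f"{name:13s} success {m.success_rate:5.1%}   "
          f"mean time {mean_t:6.1f} s   SPT {m.spt:.3f} %/s")

mim2, sz, cast = (results[k][0] for k in ("mim2", "surge_zigzag", "casting"))
table = np.array([[mim2.success_count, mim2.n - mim2.success_count],
                  [cast.success_count, cast.n - cast.success_count]])
print(f"\nFisher exact, MiM2 vs casting success: p = {sc.fisher_exact(table):.2g}")
p = sc.steel_dwass([mim2.search_times, sz.search_times, cast.search_times])
print(f"Steel-Dwass, casting vs MiM2 search times: p = {p[2, 0]:.2g}")
print()
print("Casting reaches the source fastest when it succeeds (it never stops")
print("moving), but the surge-driven controllers succeed more often from the")
print("plume centerline; SPT trades the two off.")
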