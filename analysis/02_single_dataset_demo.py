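#!/usr/bin/env python
"""Analyze one simulated registry-style dataset with every method.

Simulates a single cohort (n = 5000) under the high-missingness mixed
pattern, then estimates the always-vs-never ATE by (a) the complete-data
reference, (b) censoring-based IPW with total weights, and (c) MI with
chained equations, including a nonparametric bootstrap CI for the IPW
analysis.  Writes results/demo_estimates.csv.
"""

import sys
import time
from pathlib import Path

import pandas as pd

import tvmiss as tv

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    coeffs = tv.default_coefficients()
    spec = tv.ScenarioSpec(name="demo", pattern="mixed", level="high",
                           n=5000, n_reps=2, m_imputations=25, base_seed=2023)
    panel = tv.generate_complete_panel(spec, coeffs, seed=20)
    blanked = tv.impose_missingness(panel, spec, coeffs, seed=21)
    s = tv.missingness_summary(blanked)
    print(f"simulated n={panel.n}, realized missingness: "
          f"{s['nonmonotone']:.1%} intermittent + {s['monotone']:.1%} drop-out")

    rows = []

    est, se = tv.sw_msm_estimate(panel)
    rows.append(("complete_data_reference", est, se))
    est, se = tv.ipw_estimate(blanked)
    rows.append(("IPW", est, se))
    est, se = tv.mi_estimate(blanked, M=spec.m_imputations, n_iter=5, seed=22)
    rows.append(("MI_linear", est, se))

    for name, est, se in rows:
        print(f"  {name:<24s} ATE = {est:+.4f}  (model SE {se:.4f})")

    t0 = time.time()
    ci = tv.bootstrap_ci(blanked, lambda p: tv.ipw_estimate(p)[0],
                         b_boot=200, seed=23)
    print(f"  IPW bootstrap 95% CI: [{ci['lower']:+.4f}, {ci['upper']:+.4f}] "
          f"({ci['n_success']} resamples, {time.time() - t0:.0f}s)")
    print(f"  (true ATE of the generating model: {coeffs.target_ate:+.2f})")

    df = pd.DataFrame(rows, columns=["method", "ate", "se"])
    df.to_csv(OUT / "demo_estimates.csv", index=False)
    print(f"\nwrote {OUT / 'demo_estimates.csv'}")


if __name__ == "__main__":
    sys.exit(main())
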