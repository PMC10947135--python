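#!/usr/bin/env python
"""Collect the grid results into a single Markdown report.

Reads the CSVs written by 03-05, prints the headline comparisons and
writes results/summary.md.
"""

import sys
from pathlib import Path

import pandas as pd

OUT = Path(__file__).resolve().parents[1] / "results"

FILES = {
    "Normal outcome": "normal_grid.csv",
    "Skewed outcome": "skew_grid.csv",
    "Misspecification": "misspec_grid.csv",
}


def main():
    sections = []
    for title, fname in FILES.items():
        path = OUT / fname
        if not path.exists():
            print(f"skipping {title}: {path} not found (run scripts 03-05 first)")
            continue
        df = pd.read_csv(path)
        cols = ["scenario", "method", "n_reps", "mean_est", "bias",
                "emp_se", "rmse", "mcse_bias"]
        table = df[cols].round(4)
        sections.append(f"## {title}\n\n{table.to_markdown(index=False)}\n")
        print(f"\n### {title}")
        print(table.to_string(index=False))

    if sections:
        text = "# Simulation performance summary\n\n" + "\n".join(sections)
        (OUT / "summary.md").write_text(text)
        print(f"\nwrote {OUT / 'summary.md'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
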