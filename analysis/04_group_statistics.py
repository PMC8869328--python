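"""Summarize the Kruskal-Wallis group comparisons.

Reads results/study/group_tests.csv and reports, per band and measure, how
many electrodes separate the three groups at p < 0.05, plus the
whole-network clustering-coefficient tests.
"""

from pathlib import Path

import pandas as pd

STUDY = Path("results/study")
ALPHA = 0.05


def main() -> None:
    df = pd.read_csv(STUDY / "group_tests.csv")
    per_electrode = df[df["electrode"] != "global"]
    print(f"per-electrode Kruskal-Wallis tests (p < {ALPHA}):")
    for (band, measure), sub in per_electrode.groupby(["band", "measure"]):
        sig = int((sub["p"] < ALPHA).sum())
        print(f"  {measure:5s} {band:5s}: {sig}/{len(sub)} electrodes significant "
              f"(median p = {sub['p'].median():.2e})")
    print("whole-network clustering tests:")
    for _, row in df[df["electrode"] == "global"].iterrows():
        print(f"  {row['measure']:15s} {row['band']:5s}: H={row['H']:.2f} p={row['p']:.2e}")


if __name__ == "__main__":
    main()
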