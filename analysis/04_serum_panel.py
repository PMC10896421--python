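#!/usr/bin/env python
"""Genotype comparison of the synthetic serum clinical-chemistry panels.

Applies the same ANOVA -> pool -> Student's t machinery to each analyte
of the young-adult and aged panels and reports the detected elevation of
KO over WT.  Writes results/serum_statistics.csv.

Requires analysis/01_simulate_cohorts.py to have been run first.
"""

import argparse
from pathlib import Path

import pandas as pd

from cryoredox.stats import compare_serum

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.parse_args()

    rows = []
    for panel in ("young", "aged"):
        path = ROOT / "results" / f"serum_{panel}.csv"
        if not path.exists():
            raise SystemExit(f"{path} missing: run 01_simulate_cohorts.py first")
        table = pd.read_csv(path)
        print(f"== serum panel: {panel} ==")
        for analyte in sorted(table["analyte"].unique()):
            res = compare_serum(table, analyte)
            if res.pooled:
                tt = res.ttest
                elevation = 100.0 * (tt.mean_ko - tt.mean_wt) / tt.mean_wt
                print(f"  {analyte:>12}: KO {elevation:+6.1f}% vs WT, "
                      f"p = {tt.p:.4f}")
                rows.append(dict(panel=panel, analyte=analyte, pooled=True,
                                 elevation_pct=elevation, t=tt.t, p=tt.p))
            else:
                print(f"  {analyte:>12}: sexes not pooled")
                rows.append(dict(panel=panel, analyte=analyte, pooled=False,
                                 elevation_pct=None, t=None, p=None))

    out = ROOT / "results" / "serum_statistics.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
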