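#!/usr/bin/env python
"""Cohort-level statistics on the processed per-animal summaries.

Per tissue: two-way genotype x sex ANOVA on the per-animal mean redox
ratios, the sex-pooling decision, the WT-vs-KO Student's t-test where
pooling is allowed, and the percent RR change (KO-denominator
convention).  Writes results/cohort_statistics.csv and prints a short
narrative per tissue.

Requires analysis/02_process_volumes.py to have been run first.
"""

import argparse
from pathlib import Path

import pandas as pd

from cryoredox.io import _cohort_row
from cryoredox.stats import pool_and_test, two_way_anova

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--tissues", nargs="+", default=["liver", "kidney"])
    args = ap.parse_args()

    rows = []
    for tissue in args.tissues:
        path = ROOT / "results" / tissue / "animal_summaries.csv"
        if not path.exists():
            raise SystemExit(f"{path} missing: run 02_process_volumes.py first")
        summaries = pd.read_csv(path)
        anova = two_way_anova(summaries)
        sidedness = "one" if tissue == "liver" else "two"
        direction = "wt_greater" if tissue == "liver" else None
        res = pool_and_test(summaries, anova, sidedness=sidedness,
                            direction=direction, tissue=tissue)
        rows.append(_cohort_row(tissue, res))

        print(f"== {tissue} ==")
        print(f"  ANOVA: genotype p={anova.genotype.p:.4f}, "
              f"sex p={anova.sex.p:.4f}, interaction p={anova.interaction.p:.4f}")
        if res.pooled:
            tt = res.ttest
            print(f"  sexes pooled; {sidedness}-sided t({tt.df:.0f}) = {tt.t:.3f}, "
                  f"p = {tt.p:.4f}")
            print(f"  mean RR: WT {tt.mean_wt:.3f} +/- {tt.sem_wt:.3f} SEM, "
                  f"KO {tt.mean_ko:.3f} +/- {tt.sem_ko:.3f} SEM")
            print(f"  RR change (KO-denominator): {res.percent_change:.2f}%")
        else:
            print("  sex effect or interaction significant: sexes not pooled")
            for sex, tt in res.per_sex.items():
                print(f"    {sex}: t = {tt.t:.3f}, p = {tt.p:.4f}")

    out = ROOT / "results" / "cohort_statistics.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
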