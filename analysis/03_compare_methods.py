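#!/usr/bin/env python
"""Agreement analysis of the quantification methods.

Reads the per-slide measurements from 02 and runs the full battery against
the stereology reference: summary statistics, Pearson correlations, Friedman
test with Wilcoxon/Bonferroni post-hoc pairs, raw and ln regression, and
Bland-Altman plots.  Tables and figures land in results/report/.
"""

import argparse
from pathlib import Path

import pandas as pd

from fibroquant.agreement_stats import (
    MethodMeasurements,
    bland_altman,
    fit_regression,
    format_p,
    friedman_test,
    pairs_table,
    pearson_matrix,
    summarize_methods,
    wilcoxon_pairs,
)
from fibroquant.pipeline import DEFAULT_FRIEDMAN_COLUMNS, DEFAULT_PAIRS
from fibroquant.plots import bland_altman_plot, regression_plot


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--measurements", type=Path, default=Path("results/study/measurements.csv"))
    ap.add_argument("--reference", default="stereology")
    ap.add_argument("--out", type=Path, default=Path("results/report"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    df = pd.read_csv(args.measurements).set_index("slide_id")
    df = df.drop(columns=["true_fibrosis_pct"], errors="ignore")
    m = MethodMeasurements(df)

    summary = summarize_methods(m)
    summary.reset_index(names="method").to_csv(args.out / "summary.csv", index=False, float_format="%.6f")
    print("summary (fibrosis % per method):")
    print(summary[["mean", "median", "std", "range"]].round(2).to_string())

    corr, _ = pearson_matrix(m)
    corr.reset_index(names="method").to_csv(args.out / "correlations.csv", index=False, float_format="%.6f")
    print("\nPearson r vs the stereology reference:")
    for method in df.columns:
        if method != args.reference:
            print(f"  {method:18s} r = {corr.loc[method, args.reference]:.3f}")

    fr = friedman_test(m, [c for c in DEFAULT_FRIEDMAN_COLUMNS if c in df.columns])
    print(f"\nFriedman chi2({fr.df}) = {fr.chi_square:.3f}, p = {format_p(fr.p_value)}")

    pairs = [p for p in DEFAULT_PAIRS if p[0] in df.columns and p[1] in df.columns]
    table = pairs_table(wilcoxon_pairs(m, pairs))
    table.reset_index().to_csv(args.out / "pairs.csv", index=False, float_format="%.6f")
    print("\npost-hoc Wilcoxon pairs (Bonferroni alpha "
          f"{0.05 / len(pairs):.4f}):")
    print(table[["mean_difference", "sd_difference", "z", "p_display"]].round(3).to_string())

    ref = m.column(args.reference)
    for method in df.columns:
        if method == args.reference:
            continue
        ba = bland_altman(ref, m.column(method))
        bland_altman_plot(ba, f"{method} vs {args.reference}", args.out / f"bland_altman_{method}.png")
        for transform in ("raw", "ln"):
            fit = fit_regression(ref, m.column(method), transform)
            regression_plot(fit, args.reference, method, args.out / f"regression_{method}_{transform}.png")
    print(f"\nplots and tables written to {args.out}")


if __name__ == "__main__":
    main()
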