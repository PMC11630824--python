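#!/usr/bin/env python
"""Memorability, interdependence, and intrusions as functions of relatedness.

For every experiment and experimental condition: per-pair memorability
(condition minus Control recall proportion) regressed on the condition's
relatedness axis, a thirds split testing interference vs facilitation at
low vs high relatedness, duo interdependence against its mismatched-pairing
95th-percentile threshold, and supplemental-into-base intrusion rates in
the target-change condition.  Also pools the two stimulus sets on the
common GloVe metric per delay.  Writes results/relatedness/*.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd
import scipy.stats as sps

from remindings.io import write_table
from remindings.metrics import interdependence, intrusion_rates, memorability
from remindings.stats import (
    combine_stimulus_sets,
    relatedness_regression,
    thirds_split_test,
)

from experiments import scored_named

OUT = Path("results/relatedness")
MAIN = ("narrower_5min", "narrower_48hr", "wider_5min", "wider_48hr")
CONDITIONS = ("DeltaTarget", "DeltaCue", "DeltaBoth")


def main() -> None:
    reg_rows, thirds_rows, dep_rows, intr_rows = [], [], [], []
    glove_mem: dict[tuple[str, str], pd.DataFrame] = {}
    for name in MAIN:
        ds = scored_named(name)
        for cond in CONDITIONS:
            mem = memorability(ds, cond)
            fit = relatedness_regression(mem)
            reg_rows.append(
                dict(experiment=name, condition=cond, outcome="memorability",
                     slope=fit.slope, intercept=fit.intercept,
                     r_squared=fit.r_squared, p_slope=fit.p_slope,
                     p_intercept=fit.p_intercept, n=fit.n)
            )
            th = thirds_split_test(mem)
            th.insert(0, "condition", cond)
            th.insert(0, "experiment", name)
            thirds_rows.append(th)

            dep = interdependence(ds, cond)
            dfit = relatedness_regression(dep.table, value_col="dependence")
            dep_rows.append(
                dict(experiment=name, condition=cond, outcome="dependence",
                     slope=dfit.slope, r_squared=dfit.r_squared,
                     p_slope=dfit.p_slope, threshold_95=dep.threshold_95,
                     frac_above_threshold=float(
                         (dep.table["dependence"] > dep.threshold_95).mean()
                     ), n=dfit.n)
            )
            # re-express memorability on GloVe for the pooled-set analysis
            glove_mem[(name, cond)] = memorability(ds, cond, metric="glove")

        intr = intrusion_rates(ds)
        r, p = sps.pearsonr(intr["relatedness"], intr["intrusion_rate"])
        intr_rows.append(
            dict(experiment=name, condition="DeltaTarget", pearson_r=r,
                 r_squared=r * r, p=p, mean_rate=intr["intrusion_rate"].mean())
        )

    pooled_rows = []
    for delay in ("5min", "48hr"):
        for cond in CONDITIONS:
            fit = combine_stimulus_sets(
                glove_mem[(f"narrower_{delay}", cond)],
                glove_mem[(f"wider_{delay}", cond)],
            )
            pooled_rows.append(
                dict(delay=delay, condition=cond, slope=fit.slope,
                     r_squared=fit.r_squared, p_slope=fit.p_slope, n=fit.n)
            )

    write_table(pd.DataFrame(reg_rows), OUT / "memorability_regressions.csv")
    write_table(pd.concat(thirds_rows, ignore_index=True), OUT / "thirds_tests.csv")
    write_table(pd.DataFrame(dep_rows), OUT / "dependence_regressions.csv")
    write_table(pd.DataFrame(intr_rows), OUT / "intrusion_correlations.csv")
    write_table(pd.DataFrame(pooled_rows), OUT / "pooled_glove_regressions.csv")

    reg = pd.DataFrame(reg_rows)
    sig = reg[reg.p_slope < 0.05]
    print(f"memorability-relatedness regressions: {len(sig)}/{len(reg)} significant")
    for _, row in sig.iterrows():
        print(
            f"  {row.experiment} {row.condition}: r2 = {row.r_squared:.2f}, "
            f"slope = {row.slope:.2f}, p = {row.p_slope:.2g}"
        )
    th = pd.concat(thirds_rows, ignore_index=True)
    cross = th[(th.third == "low") & (th.t < 0) & (th.p < 0.05)]
    for _, row in cross.iterrows():
        hi = th[(th.experiment == row.experiment) & (th.condition == row.condition)
                & (th.third == "high")].iloc[0]
        if hi.t > 0 and hi.p < 0.05:
            print(
                f"  crossover in {row.experiment} {row.condition}: "
                f"low third t({row.df}) = {row.t:.1f}, "
                f"high third t({hi.df}) = {hi.t:.1f}"
            )
    intr = pd.DataFrame(intr_rows)
    for _, row in intr[intr.p < 0.05].iterrows():
        print(
            f"  intrusions vs relatedness in {row.experiment}: "
            f"r = {row.pearson_r:.2f}, p = {row.p:.2g}"
        )


if __name__ == "__main__":
    main()
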