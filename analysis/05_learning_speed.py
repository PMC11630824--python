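#!/usr/bin/env python
"""Learning speed: rounds to criterion by condition and relatedness.

Base pairs drop out of study after their first correct retrieval; the
number of rounds that takes is the learning-speed outcome.  Reports the
per-condition means (the NoChange < DeltaCue < DeltaTarget < DeltaBoth <=
Control ordering) and the correlation between per-pair mean rounds and
relatedness within each changed condition.  Writes
results/learning/*.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd
import scipy.stats as sps

from remindings.io import write_table
from remindings.metrics import trials_to_criterion

from experiments import scored_named

OUT = Path("results/learning")
MAIN = ("narrower_5min", "narrower_48hr", "wider_5min", "wider_48hr")


def main() -> None:
    cond_rows, corr_rows = [], []
    for name in MAIN:
        ds = scored_named(name)
        per_pair, per_subject = trials_to_criterion(ds, "base")
        means = per_subject.groupby("condition")["mean_rounds"].mean()
        cond_rows.append(dict(experiment=name, **means.to_dict()))
        for cond in ("DeltaTarget", "DeltaCue", "DeltaBoth"):
            sub = per_pair[per_pair.condition == cond]
            r, p = sps.pearsonr(sub["relatedness"], sub["mean_rounds"])
            corr_rows.append(
                dict(experiment=name, condition=cond, pearson_r=r,
                     r_squared=r * r, p=p, n=len(sub))
            )
        order = means.sort_values()
        print(
            f"{name}: rounds to criterion "
            + " < ".join(f"{c} ({v:.2f})" for c, v in order.items())
        )
    write_table(pd.DataFrame(cond_rows), OUT / "rounds_by_condition.csv")
    write_table(pd.DataFrame(corr_rows), OUT / "rounds_vs_relatedness.csv")
    corr = pd.DataFrame(corr_rows)
    neg = corr[(corr.pearson_r < 0) & (corr.p < 0.05)]
    print(
        f"relatedness sped learning (negative correlation, p < 0.05) in "
        f"{len(neg)}/{len(corr)} condition x experiment cells"
    )


if __name__ == "__main__":
    main()
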