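#!/usr/bin/env python
"""Overall condition effects on base-pair memory.

For each of the four main experiments: a one-way repeated-measures ANOVA
over the five conditions, followed by the ten pairwise within-subject
t-tests with Benjamini-Hochberg correction.  Writes
results/condition_effects/{anova.csv, pairwise_<experiment>.csv} and prints
the condition ordering each experiment produced.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from remindings.io import write_table
from remindings.metrics import condition_means
from remindings.stats import pairwise_t_fdr, rm_anova

from experiments import scored_named

OUT = Path("results/condition_effects")
MAIN = ("narrower_5min", "narrower_48hr", "wider_5min", "wider_48hr")


def main() -> None:
    anova_rows = []
    for name in MAIN:
        ds = scored_named(name)
        wide = condition_means(ds)
        res = rm_anova(wide)
        anova_rows.append(
            dict(experiment=name, F=res.F, df_num=res.df_num,
                 df_den=res.df_den, p=res.p)
        )
        pw = pairwise_t_fdr(wide)
        write_table(pw, OUT / f"pairwise_{name}.csv")
        order = wide.mean().sort_values(ascending=False)
        print(
            f"{name}: F({res.df_num},{res.df_den}) = {res.F:.1f}, "
            f"p = {res.p:.2g}; condition order "
            + " > ".join(f"{c} ({v:.2f})" for c, v in order.items())
        )
    write_table(pd.DataFrame(anova_rows), OUT / "anova.csv")


if __name__ == "__main__":
    main()
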