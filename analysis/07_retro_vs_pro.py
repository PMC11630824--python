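#!/usr/bin/env python
"""Retroactive vs proactive memory benefits, NoChange-baselined.

Compares base-pair memory between list orders after re-expressing each
subject's condition means relative to their own NoChange mean (the positive
control).  Three comparisons on the narrower-set 48 hr experiments: retro
vs pro, flipped-test vs pro, and retro vs flipped-test (the last expecting
no differences, since both expose base pairs to retroactive effects).
Writes results/order_contrasts.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from remindings.io import write_table
from remindings.metrics import condition_means
from remindings.stats import order_contrast

from experiments import scored_named

OUT = Path("results")

COMPARISONS = (
    ("narrower_48hr_retro", "narrower_48hr"),
    ("narrower_48hr_flipped", "narrower_48hr"),
    ("narrower_48hr_retro", "narrower_48hr_flipped"),
)


def main() -> None:
    wides = {
        name: condition_means(scored_named(name))
        for name in {n for pair in COMPARISONS for n in pair}
    }
    frames = []
    for a, b in COMPARISONS:
        out = order_contrast(wides[a], wides[b], label_a=a, label_b=b)
        out.insert(0, "comparison", f"{a}_vs_{b}")
        out = out.rename(columns={f"mean_{a}": "mean_a", f"mean_{b}": "mean_b"})
        frames.append(out)
        sig = out[(out.mean_diff > 0) & (out.p_fdr < 0.05)]["condition"].tolist()
        print(
            f"{a} vs {b}: advantage for first-named experiment in "
            f"{sig or 'no'} conditions"
        )
    write_table(pd.concat(frames, ignore_index=True), OUT / "order_contrasts.csv")


if __name__ == "__main__":
    main()
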