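"""Stimuli, conditions, and the five-way counterbalanced design.

A paired-associate two-list experiment: subjects first learn a list of
*supplemental* cue-target pairs and then a list of *base* pairs.  Each base
pair belongs, for a given subject, to one of five within-subject conditions
describing how its supplemental counterpart relates to it:

* ``NoChange``   - supplemental pair identical to the base pair (A-B, A-B)
* ``DeltaTarget``- same cue, related target (A-B, A-D)
* ``DeltaCue``   - related cue, same target (A-B, C-B)
* ``DeltaBoth``  - both words replaced by related ones (A-B, C-D)
* ``Control``    - no supplemental counterpart at all

Base pairs are split into five counterbalance groups; condition assignment
rotates group -> condition across subjects so that over any block of five
consecutive subjects every pair serves every condition exactly once.
Relatedness between a word and its replacement is quantified on two metrics:
free-association strength (``AS``, directional, in [0, 1]) and GloVe
embedding cosine similarity (``glove``, symmetric, roughly in [-1, 1]).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "DesignConfig",
    "DesignError",
    "CONDITION_ORDER",
    "EXPERIMENTAL_CONDITIONS",
    "METRIC_RANGES",
    "DEFAULT_METRIC_SPANS",
    "build_stimulus_set",
    "build_counterbalance",
    "validate_counterbalance",
]


class DesignError(ValueError):
    """Raised when a requested design is internally inconsistent."""


class Condition(str, enum.Enum):
    NO_CHANGE = "NoChange"
    DELTA_TARGET = "DeltaTarget"
    DELTA_CUE = "DeltaCue"
    DELTA_BOTH = "DeltaBoth"
    CONTROL = "Control"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed rotation order used by the counterbalance.
CONDITION_ORDER: tuple[Condition, ...] = (
    Condition.NO_CHANGE,
    Condition.DELTA_TARGET,
    Condition.DELTA_CUE,
    Condition.DELTA_BOTH,
    Condition.CONTROL,
)

EXPERIMENTAL_CONDITIONS: tuple[Condition, ...] = tuple(
    c for c in CONDITION_ORDER if c is not Condition.CONTROL
)

#: Legal range of each relatedness metric.
METRIC_RANGES: dict[str, tuple[float, float]] = {
    "AS": (0.0, 1.0),
    "glove": (-1.0, 1.0),
}

#: Default sampled span per metric: the narrower stimulus set spans
#: association strengths 0.03-0.96, the wider one GloVe cosines -0.14-0.95.
DEFAULT_METRIC_SPANS: dict[str, tuple[float, float]] = {
    "AS": (0.03, 0.96),
    "glove": (-0.14, 0.95),
}

STIMULUS_COLUMNS = [
    "pair_id",
    "base_cue",
    "base_target",
    "alt_cue",
    "alt_target",
    "cue_rel_AS",
    "target_rel_AS",
    "cue_rel_glove",
    "target_rel_glove",
    "counterbalance_group",
]

DESIGN_COLUMNS = ["subject_id", "pair_id", "condition"]


@dataclass
class DesignConfig:
    """Parameters of one experiment's design.

    ``n_supplemental_pairs`` is derived: every base pair except the Control
    fifth has a supplemental counterpart, so ``n_supp = n_base - n_base/5``
    (36 for the default 45-pair set).
    """

    n_subjects: int = 200
    n_base_pairs: int = 45
    delay_label: str = "forty_eight_hr"  # or "five_min"
    relatedness_metric: str = "AS"  # or "glove"
    list_order: str = "proactive"  # or "retroactive" / "flipped_test"
    seed: int = 0
    range_spec: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_base_pairs % 5 != 0:
            raise DesignError(
                f"n_base_pairs must be divisible by 5, got {self.n_base_pairs}"
            )
        if self.n_subjects < 1:
            raise DesignError("n_subjects must be positive")
        if self.delay_label not in ("five_min", "forty_eight_hr"):
            raise DesignError(f"unknown delay_label {self.delay_label!r}")
        if self.relatedness_metric not in METRIC_RANGES:
            raise DesignError(
                f"unknown relatedness_metric {self.relatedness_metric!r}"
            )
        if self.list_order not in ("proactive", "retroactive", "flipped_test"):
            raise DesignError(f"unknown list_order {self.list_order!r}")
        if self.range_spec is None:
            self.range_spec = DEFAULT_METRIC_SPANS[self.relatedness_metric]

    @property
    def n_supplemental_pairs(self) -> int:
        return self.n_base_pairs - self.n_base_pairs // 5

    @property
    def mu_label(self) -> str:
        return "mu_5min" if self.delay_label == "five_min" else "mu_48hr"


# ---------------------------------------------------------------------------
# synthetic word tokens

_CONSONANTS = "bcdfghjklmnprstvwz"
_VOWELS = "aeiou"
_PATTERNS = ("cvc", "cvcv", "vcvc", "cvcvc", "cvvc")


def _one_token(rng: np.random.Generator) -> str:
    pattern = _PATTERNS[rng.integers(len(_PATTERNS))]
    return "".join(
        _VOWELS[rng.integers(len(_VOWELS))]
        if ch == "v"
        else _CONSONANTS[rng.integers(len(_CONSONANTS))]
        for ch in pattern
    )


def _unique_tokens(n: int, rng: np.random.Generator) -> list[str]:
    """Pronounceable 3-5 letter pseudo-words, unique by rejection sampling."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        tok = _one_token(rng)
        if tok not in seen:
            seen.add(tok)
            out.append(tok)
    return out


# ---------------------------------------------------------------------------
# stimulus sets


def _map_to_other_metric(
    values: np.ndarray, span: tuple[float, float], metric: str, rng: np.random.Generator
) -> np.ndarray:
    """Fill the secondary metric: a noisy monotone remapping of the primary.

    AS and GloVe cosine are correlated but far from linearly related in
    norms; a rank-preserving affine map plus noise, clipped to the metric's
    legal range, reproduces that loose coupling.
    """
    lo, hi = span
    frac = (values - lo) / (hi - lo) if hi > lo else np.zeros_like(values)
    other_lo, other_hi = DEFAULT_METRIC_SPANS[metric]
    mapped = other_lo + frac * (other_hi - other_lo)
    mapped = mapped + rng.normal(0.0, 0.08, size=values.shape)
    legal_lo, legal_hi = METRIC_RANGES[metric]
    return np.clip(mapped, legal_lo, legal_hi)


def build_stimulus_set(
    n_pairs: int = 45,
    metric: str = "AS",
    range_spec: tuple[float, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a synthetic stimulus table of ``n_pairs`` base pairs.

    Each entry carries a base cue/target, the replacement cue/target used in
    the DeltaCue/DeltaTarget/DeltaBoth conditions, cue- and target-relatedness
    on both metrics (the chosen ``metric`` sampled uniformly over
    ``range_spec``, the other derived), and a counterbalance group in 0..4.

    Returns a :class:`pandas.DataFrame` with :data:`STIMULUS_COLUMNS`.
    """
    if n_pairs % 5 != 0:
        raise DesignError(f"n_pairs must be divisible by 5, got {n_pairs}")
    if metric not in METRIC_RANGES:
        raise DesignError(f"unknown metric {metric!r}")
    if range_spec is None:
        range_spec = DEFAULT_METRIC_SPANS[metric]
    lo, hi = range_spec
    legal_lo, legal_hi = METRIC_RANGES[metric]
    if not (lo < hi):
        raise ValueError(f"empty relatedness range {range_spec!r}")
    if lo < legal_lo or hi > legal_hi:
        raise ValueError(
            f"range {range_spec!r} outside legal {metric} range "
            f"[{legal_lo}, {legal_hi}]"
        )

    rng = np.random.default_rng(seed)
    words = _unique_tokens(4 * n_pairs, rng)
    cue_rel = rng.uniform(lo, hi, size=n_pairs)
    target_rel = rng.uniform(lo, hi, size=n_pairs)
    other = "glove" if metric == "AS" else "AS"
    cue_other = _map_to_other_metric(cue_rel, range_spec, other, rng)
    target_other = _map_to_other_metric(target_rel, range_spec, other, rng)

    df = pd.DataFrame(
        {
            "pair_id": [f"P{i:03d}" for i in range(n_pairs)],
            "base_cue": words[0::4],
            "base_target": words[1::4],
            "alt_cue": words[2::4],
            "alt_target": words[3::4],
            f"cue_rel_{metric}": cue_rel,
            f"target_rel_{metric}": target_rel,
            f"cue_rel_{other}": cue_other,
            f"target_rel_{other}": target_other,
            "counterbalance_group": np.arange(n_pairs) % 5,
        }
    )
    df = df[STIMULUS_COLUMNS]
    df.attrs["metric"] = metric
    df.attrs["range_spec"] = tuple(range_spec)
    return df


# ---------------------------------------------------------------------------
# counterbalance


def build_counterbalance(
    config: DesignConfig, stimuli: pd.DataFrame
) -> pd.DataFrame:
    """Assign each base pair to a condition per subject by rotation.

    Subject ``s`` (0-based) maps counterbalance group ``g`` to
    ``CONDITION_ORDER[(g + s) % 5]``; every pair therefore serves each
    condition exactly once per aligned block of five subjects.

    Returns a long DataFrame ``subject_id, pair_id, condition``.
    """
    if len(stimuli) != config.n_base_pairs:
        raise DesignError(
            f"stimulus count {len(stimuli)} != n_base_pairs {config.n_base_pairs}"
        )
    groups = stimuli["counterbalance_group"].to_numpy()
    pair_ids = stimuli["pair_id"].to_numpy()
    frames = []
    for s in range(config.n_subjects):
        cond = [CONDITION_ORDER[(g + s) % 5].value for g in groups]
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": f"S{s:04d}",
                    "pair_id": pair_ids,
                    "condition": cond,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out


def validate_counterbalance(
    assignments: pd.DataFrame, stimuli: pd.DataFrame | None = None
) -> list[str]:
    """Check counterbalance invariants; return a list of violation messages.

    Per subject: equal condition cell sizes and (if ``stimuli`` given) one
    shared condition per counterbalance group.  Across subjects: within each
    complete, aligned block of five subjects every pair must serve every
    condition exactly once; partial trailing blocks are skipped for that
    check but still validated per subject.
    """
    if assignments.empty:
        raise ValueError("empty assignments")
    report: list[str] = []
    subjects = sorted(assignments["subject_id"].unique())
    n_pairs = assignments["pair_id"].nunique()
    per_cond = n_pairs // 5

    by_subject = dict(tuple(assignments.groupby("subject_id", sort=True)))
    for sid in subjects:
        sub = by_subject[sid]
        counts = sub["condition"].value_counts()
        for cond in CONDITION_ORDER:
            if counts.get(cond.value, 0) != per_cond:
                report.append(
                    f"subject {sid}: condition {cond.value} has "
                    f"{counts.get(cond.value, 0)} pairs, expected {per_cond}"
                )
        if stimuli is not None:
            merged = sub.merge(
                stimuli[["pair_id", "counterbalance_group"]], on="pair_id"
            )
            bad = merged.groupby("counterbalance_group")["condition"].nunique()
            for g, k in bad.items():
                if k != 1:
                    report.append(
                        f"subject {sid}: counterbalance group {g} mixes "
                        f"{k} conditions"
                    )

    # complete blocks of five consecutive subjects
    for b in range(len(subjects) // 5):
        block = subjects[5 * b : 5 * b + 5]
        blk = assignments[assignments["subject_id"].isin(block)]
        cell = blk.groupby(["pair_id", "condition"]).size()
        for pid in blk["pair_id"].unique():
            for cond in CONDITION_ORDER:
                k = cell.get((pid, cond.value), 0)
                if k != 1:
                    report.append(
                        f"block {b} (subjects {block[0]}..{block[-1]}): pair "
                        f"{pid} appears {k} times in {cond.value}, expected 1"
                    )
    return report


def condition_relatedness_column(condition: Condition | str, metric: str) -> str | None:
    """Column of the stimulus table carrying a condition's relatedness axis."""
    condition = Condition(condition)
    if condition is Condition.DELTA_TARGET:
        return f"target_rel_{metric}"
    if condition is Condition.DELTA_CUE:
        return f"cue_rel_{metric}"
    return None


def condition_relatedness(
    stimuli: pd.DataFrame, condition: Condition | str, metric: str, combine: str = "sum"
) -> pd.Series:
    """Per-pair relatedness on the axis a condition varies.

    DeltaTarget -> target relatedness, DeltaCue -> cue relatedness,
    DeltaBoth -> cue and target combined (``sum`` for the analysis tables,
    ``mean`` for the simulator's internal scale), NoChange -> the metric's
    maximum (the identity point), Control -> NaN.
    """
    condition = Condition(condition)
    cue = stimuli[f"cue_rel_{metric}"]
    target = stimuli[f"target_rel_{metric}"]
    if condition is Condition.DELTA_TARGET:
        rel = target.copy()
    elif condition is Condition.DELTA_CUE:
        rel = cue.copy()
    elif condition is Condition.DELTA_BOTH:
        rel = cue + target if combine == "sum" else (cue + target) / 2.0
    elif condition is Condition.NO_CHANGE:
        rel = pd.Series(METRIC_RANGES[metric][1], index=stimuli.index)
    else:  # Control
        rel = pd.Series(np.nan, index=stimuli.index)
    rel.index = stimuli["pair_id"].to_numpy()
    rel.name = "relatedness"
    return rel
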