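"""Per-pair quantities: scoring, exclusions, memorability, interdependence,
intrusions, and trials to criterion.

*Memorability* of a base pair in an experimental condition is the proportion
of subjects recalling it in that condition minus the proportion recalling it
in the Control condition - positive values mean proactive facilitation,
negative proactive interference.  *Interdependence* of a base/supplemental
duo is the across-subject frequency with which the two members were both
recalled or both forgotten; each matched duo is judged against the 95th
percentile of the same statistic over mismatched duos (base pair i paired
with supplemental pair j != i from the same counterbalance group, so that
the mismatched statistic uses exactly the same subjects and condition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Condition, condition_relatedness
from .simulate import SubjectDataset, supplemental_words

__all__ = [
    "score_responses",
    "apply_exclusions",
    "memorability",
    "interdependence",
    "intrusion_rates",
    "trials_to_criterion",
    "condition_means",
    "DependenceTable",
    "MissingCellError",
    "PipelineError",
]

EXCLUSION_Z = -4.0


class MissingCellError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


def _normalize(s: pd.Series | np.ndarray) -> np.ndarray:
    return np.char.lower(np.char.strip(np.asarray(s, dtype=str)))


def _within_edit1(a: str, b: str) -> bool:
    if a == b:
        return True
    import edlib

    return edlib.align(a, b, k=1)["editDistance"] in (0, 1)


def _matches(resp: np.ndarray, target: np.ndarray, leniency: str) -> np.ndarray:
    exact = resp == target
    if leniency == "exact":
        return exact
    if leniency != "edit1":
        raise ValueError(f"unknown leniency rule {leniency!r}")
    out = exact.copy()
    for i in np.flatnonzero(~exact):
        if resp[i] and _within_edit1(resp[i], target[i]):
            out[i] = True
    return out


def score_responses(dataset: SubjectDataset, leniency: str = "exact") -> SubjectDataset:
    """Recompute ``correct`` and ``intrusion`` flags from response strings.

    A response is correct when it matches the studied target of that phase
    after normalization (lowercase, trimmed); with ``leniency='edit1'`` a
    single edit is tolerated.  A base-test response is an intrusion when it
    matches the pair's *supplemental* target while that target differs from
    the base target.
    """
    if leniency not in ("exact", "edit1"):
        raise ValueError(f"unknown leniency rule {leniency!r}")
    trials = dataset.trials.copy()
    stim = dataset.stimuli
    conds = trials["condition"].to_numpy()
    idx = stim.set_index("pair_id")
    base_tgt = idx.loc[trials["pair_id"], "base_target"].to_numpy()
    supp_cue, supp_tgt = supplemental_words(
        idx.loc[trials["pair_id"]].reset_index(), conds
    )
    studied = np.where(
        np.isin(trials["phase"], ["base_learning", "base_test"]),
        base_tgt,
        supp_tgt,
    )
    resp = _normalize(trials["response"])
    studied_n = _normalize(studied)
    correct = _matches(resp, studied_n, leniency) & (studied_n != "")
    supp_n = _normalize(supp_tgt)
    base_n = _normalize(base_tgt)
    is_base_test = (trials["phase"] == "base_test").to_numpy()
    intrusion = (
        is_base_test
        & ~correct
        & (supp_n != base_n)
        & (supp_n != "")
        & _matches(resp, supp_n, leniency)
    )
    trials["correct"] = correct
    trials["intrusion"] = intrusion
    out = SubjectDataset(
        config=dataset.config,
        params=dataset.params,
        stimuli=dataset.stimuli,
        assignments=dataset.assignments,
        trials=trials,
        latents=dataset.latents,
        phase_order=dataset.phase_order,
    )
    return out


def apply_exclusions(dataset: SubjectDataset):
    """Drop subjects whose overall final-test recall is more than four
    standard deviations below the sample mean.

    The z-score pools accuracy over both test lists and is computed once
    from the full sample (no re-iteration after removal).  Returns the
    filtered dataset and a per-subject report
    (``subject_id, prop_recalled, z, excluded``).
    """
    tests = dataset.trials[
        dataset.trials["phase"].isin(["base_test", "supplemental_test"])
    ]
    props = tests.groupby("subject_id")["correct"].mean()
    if len(props) < 2:
        raise PipelineError("need at least two subjects to compute exclusions")
    mean, sd = props.mean(), props.std(ddof=1)
    z = (props - mean) / sd if sd > 0 else props * 0.0
    excluded = z < EXCLUSION_Z
    report = pd.DataFrame(
        {
            "subject_id": props.index,
            "prop_recalled": props.to_numpy(),
            "z": z.to_numpy(),
            "excluded": excluded.to_numpy(),
        }
    ).reset_index(drop=True)
    if excluded.all():
        raise PipelineError("exclusion rule removed every subject")
    keep = set(props.index[~excluded])
    filtered = SubjectDataset(
        config=dataset.config,
        params=dataset.params,
        stimuli=dataset.stimuli,
        assignments=dataset.assignments[
            dataset.assignments["subject_id"].isin(keep)
        ].reset_index(drop=True),
        trials=dataset.trials[
            dataset.trials["subject_id"].isin(keep)
        ].reset_index(drop=True),
        latents=(
            None
            if dataset.latents is None
            else dataset.latents[
                dataset.latents["subject_id"].isin(keep)
            ].reset_index(drop=True)
        ),
        phase_order=dataset.phase_order,
    )
    return filtered, report


def _cell_proportions(dataset: SubjectDataset, phase: str = "base_test") -> pd.DataFrame:
    """Per (pair, condition) recall proportion over that cell's subjects."""
    tests = dataset.trials[dataset.trials["phase"] == phase]
    g = tests.groupby(["pair_id", "condition"])["correct"]
    out = g.agg(["mean", "size"]).rename(
        columns={"mean": "prop_recalled", "size": "n_subjects"}
    )
    return out.reset_index()


def memorability(
    dataset: SubjectDataset,
    condition: Condition | str,
    metric: str | None = None,
) -> pd.DataFrame:
    """Per-pair memorability table for one condition.

    Columns: ``pair_id, condition, n_subjects, prop_recalled, prop_control,
    memorability, relatedness``.  The relatedness column follows the
    condition's axis (target relatedness for DeltaTarget, cue for DeltaCue,
    the cue+target *sum* for DeltaBoth).
    """
    condition = Condition(condition)
    metric = metric or dataset.config.relatedness_metric
    cells = _cell_proportions(dataset)
    want = cells[cells["condition"] == condition.value].set_index("pair_id")
    ctrl = cells[cells["condition"] == Condition.CONTROL.value].set_index("pair_id")
    all_pairs = dataset.stimuli["pair_id"]
    for pid in all_pairs:
        if pid not in want.index:
            raise MissingCellError(
                f"no subjects contributed pair {pid} in {condition.value}"
            )
        if pid not in ctrl.index:
            raise MissingCellError(f"no Control subjects for pair {pid}")
    rel = condition_relatedness(dataset.stimuli, condition, metric, combine="sum")
    out = pd.DataFrame(
        {
            "pair_id": all_pairs.to_numpy(),
            "condition": condition.value,
            "n_subjects": want.loc[all_pairs, "n_subjects"].to_numpy(),
            "prop_recalled": want.loc[all_pairs, "prop_recalled"].to_numpy(),
            "prop_control": ctrl.loc[all_pairs, "prop_recalled"].to_numpy(),
        }
    )
    if condition is Condition.CONTROL:
        out["memorability"] = 0.0
    else:
        out["memorability"] = out["prop_recalled"] - out["prop_control"]
    out["relatedness"] = rel.loc[all_pairs].to_numpy()
    out.attrs["metric"] = metric
    out.attrs["condition"] = condition.value
    return out


@dataclass
class DependenceTable:
    """Matched-duo interdependence plus its mismatched-pairing null."""

    table: pd.DataFrame          # pair_id, condition, n_subjects, dependence, relatedness
    null_values: np.ndarray      # pooled mismatched-duo dependence values
    threshold_95: float          # 95th percentile (linear interpolation)
    condition: str
    metric: str


def interdependence(
    dataset: SubjectDataset,
    condition: Condition | str,
    metric: str | None = None,
    restrict_to_group: bool = True,
) -> DependenceTable:
    """Duo interdependence against the mismatched-pairing null.

    For each base pair i the matched statistic is, over the subjects who had
    pair i in ``condition``, the fraction for whom the base and supplemental
    tests agreed (both correct or both incorrect).  The null pools the same
    statistic for every ordered mismatched duo (base i, supplemental j),
    i != j; by default j ranges over i's counterbalance group so the
    mismatched outcomes come from the same subjects and condition
    (``restrict_to_group=False`` lifts that restriction for sensitivity
    analyses).
    """
    condition = Condition(condition)
    if condition is Condition.CONTROL:
        raise ValueError("Control pairs have no supplemental counterpart")
    metric = metric or dataset.config.relatedness_metric

    trials = dataset.trials
    base = trials[trials["phase"] == "base_test"]
    supp = trials[trials["phase"] == "supplemental_test"]
    bmat = base.pivot(index="subject_id", columns="pair_id", values="correct")
    smat = supp.pivot(index="subject_id", columns="pair_id", values="correct")
    cond_mat = base.pivot(index="subject_id", columns="pair_id", values="condition")

    stim = dataset.stimuli.set_index("pair_id")
    pair_ids = list(stim.index)
    groups = stim["counterbalance_group"]

    matched = {}
    n_cell = {}
    null_values: list[float] = []
    for g, members in groups.groupby(groups):
        gp = list(members.index)
        # subjects holding this group in `condition` (all group members share it)
        subj_mask = cond_mat[gp[0]] == condition.value
        subs = cond_mat.index[subj_mask.fillna(False)]
        if len(subs) == 0:
            raise MissingCellError(
                f"no subjects hold counterbalance group {g} in {condition.value}"
            )
        B = bmat.loc[subs, gp].to_numpy(dtype=float)
        S = smat.loc[subs, gp].to_numpy(dtype=float)
        n = len(subs)
        agree = (B.T @ S + (1.0 - B).T @ (1.0 - S)) / n  # [i, j] base i vs supp j
        for a, pid in enumerate(gp):
            matched[pid] = agree[a, a]
            n_cell[pid] = n
        null_values.extend(agree[~np.eye(len(gp), dtype=bool)].ravel())

    if not restrict_to_group:
        null_values = []
        # every ordered mismatched duo regardless of group, computed per pair's
        # own condition subjects against all other pairs' supplemental outcomes
        for pid in pair_ids:
            subj_mask = cond_mat[pid] == condition.value
            subs = cond_mat.index[subj_mask.fillna(False)]
            b = bmat.loc[subs, pid].to_numpy(dtype=float)
            for other in pair_ids:
                if other == pid:
                    continue
                s = smat.loc[subs, other].to_numpy(dtype=float)
                ok = np.isfinite(s)
                if ok.sum() == 0:
                    continue
                null_values.append(
                    float(np.mean(b[ok] * s[ok] + (1 - b[ok]) * (1 - s[ok])))
                )

    null_arr = np.asarray(null_values, dtype=float)
    if null_arr.size == 0:
        raise MissingCellError(
            "no mismatched duos available for the null distribution "
            "(need at least two pairs per counterbalance group)"
        )
    threshold = float(np.quantile(null_arr, 0.95))  # linear interpolation
    rel = condition_relatedness(dataset.stimuli, condition, metric, combine="sum")
    table = pd.DataFrame(
        {
            "pair_id": pair_ids,
            "condition": condition.value,
            "n_subjects": [n_cell[p] for p in pair_ids],
            "dependence": [matched[p] for p in pair_ids],
            "relatedness": rel.loc[pair_ids].to_numpy(),
        }
    )
    table.attrs["metric"] = metric
    table.attrs["condition"] = condition.value
    return DependenceTable(
        table=table,
        null_values=null_arr,
        threshold_95=threshold,
        condition=condition.value,
        metric=metric,
    )


def intrusion_rates(
    dataset: SubjectDataset,
    condition: Condition | str = Condition.DELTA_TARGET,
    metric: str | None = None,
) -> pd.DataFrame:
    """Per-pair rate of supplemental-target intrusions on the base test."""
    condition = Condition(condition)
    metric = metric or dataset.config.relatedness_metric
    base = dataset.trials[
        (dataset.trials["phase"] == "base_test")
        & (dataset.trials["condition"] == condition.value)
    ]
    if base.empty:
        raise MissingCellError(f"no base-test records in {condition.value}")
    g = base.groupby("pair_id")["intrusion"].agg(["mean", "size"])
    rel = condition_relatedness(dataset.stimuli, condition, metric, combine="sum")
    out = pd.DataFrame(
        {
            "pair_id": g.index.to_numpy(),
            "condition": condition.value,
            "n_subjects": g["size"].to_numpy(),
            "intrusion_rate": g["mean"].to_numpy(),
            "relatedness": rel.loc[g.index].to_numpy(),
        }
    ).reset_index(drop=True)
    out.attrs["metric"] = metric
    return out


def trials_to_criterion(
    dataset: SubjectDataset,
    which_list: str = "base",
    metric: str | None = None,
):
    """Rounds to first correct retrieval during drop-out learning.

    Pairs never learned within ``max_rounds`` are counted at ``max_rounds``
    and flagged.  Returns ``(per_pair, per_subject)``: per-pair mean rounds
    over each condition cell's subjects (with the condition's relatedness
    attached), and per-subject mean rounds per condition.
    """
    if which_list not in ("base", "supplemental"):
        raise ValueError(f"unknown list {which_list!r}")
    phase = f"{which_list}_learning"
    learn = dataset.trials[dataset.trials["phase"] == phase]
    if learn.empty:
        raise MissingCellError(f"no learning records for {which_list} list")
    metric = metric or dataset.config.relatedness_metric
    max_rounds = dataset.params.max_rounds

    grp = learn.groupby(["subject_id", "pair_id"])
    rounds = grp["round"].max()
    learned = grp["correct"].any()
    rounds = rounds.where(learned, max_rounds)
    cond = grp["condition"].first()
    per_sp = pd.DataFrame(
        {
            "rounds": rounds,
            "learned": learned,
            "condition": cond,
        }
    ).reset_index()

    pp = per_sp.groupby(["pair_id", "condition"]).agg(
        mean_rounds=("rounds", "mean"),
        n_subjects=("rounds", "size"),
        n_unlearned=("learned", lambda s: int((~s).sum())),
    ).reset_index()
    rels = []
    for cnd in pp["condition"].unique():
        r = condition_relatedness(dataset.stimuli, cnd, metric, combine="sum")
        sel = pp["condition"] == cnd
        rels.append(pd.Series(r.loc[pp.loc[sel, "pair_id"]].to_numpy(), index=pp.index[sel]))
    pp["relatedness"] = pd.concat(rels).sort_index()

    per_subject = (
        per_sp.groupby(["subject_id", "condition"])["rounds"].mean().reset_index()
        .rename(columns={"rounds": "mean_rounds"})
    )
    pp.attrs["metric"] = metric
    return pp, per_subject


def condition_means(
    dataset: SubjectDataset, phase: str = "base_test"
) -> pd.DataFrame:
    """Wide per-subject condition means (subjects x conditions) of recall."""
    tests = dataset.trials[dataset.trials["phase"] == phase]
    wide = tests.pivot_table(
        index="subject_id", columns="condition", values="correct", aggfunc="mean"
    )
    wide.columns.name = None
    return wide
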