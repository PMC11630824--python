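import numpy as np
import pandas as pd
import pytest

from remindings.design import (
    Condition,
    DesignConfig,
    build_counterbalance,
    build_stimulus_set,
)
from remindings.simulate import (
    SimParams,
    SubjectDataset,
    simulate_experiment,
    supplemental_words,
)


def make_manual_dataset(
    base_correct: np.ndarray,
    supp_correct: np.ndarray | None = None,
    n_pairs: int | None = None,
    metric: str = "AS",
    seed: int = 0,
    base_responses: dict | None = None,
) -> SubjectDataset:
    """Build a dataset with hand-specified base/supplemental test outcomes.

    ``base_correct`` is (n_subjects, n_pairs) booleans; the counterbalance is
    the standard rotation.  ``base_responses`` optionally overrides the
    response string for specific ``(subject_index, pair_index)`` cells.
    """
    base_correct = np.asarray(base_correct, dtype=bool)
    n_subjects, np_ = base_correct.shape
    n_pairs = n_pairs or np_
    stim = build_stimulus_set(n_pairs, metric, seed=seed)
    cfg = DesignConfig(
        n_subjects=n_subjects, n_base_pairs=n_pairs,
        relatedness_metric=metric, seed=seed,
    )
    asg = build_counterbalance(cfg, stim)
    cond = asg.pivot(index="subject_id", columns="pair_id", values="condition")
    pair_ids = stim["pair_id"].to_numpy()
    cond = cond.loc[:, pair_ids]
    rows = []
    wrong = 0
    for s in range(n_subjects):
        sid = f"S{s:04d}"
        conds = cond.iloc[s].to_numpy()
        scue, stgt = supplemental_words(stim, conds)
        for i, pid in enumerate(pair_ids):
            ok = bool(base_correct[s, i])
            resp = stim["base_target"].iloc[i] if ok else f"x{wrong}9"
            wrong += 1
            if base_responses and (s, i) in base_responses:
                resp = base_responses[(s, i)]
                ok = resp == stim["base_target"].iloc[i]
            rows.append(
                dict(subject_id=sid, phase="base_test", round=0, pair_id=pid,
                     condition=conds[i], cue_shown=stim["base_cue"].iloc[i],
                     response=resp, correct=ok, intrusion=False)
            )
        if supp_correct is not None:
            for i, pid in enumerate(pair_ids):
                if conds[i] == Condition.CONTROL.value:
                    continue
                ok = bool(supp_correct[s, i])
                resp = stgt[i] if ok else f"x{wrong}9"
                wrong += 1
                rows.append(
                    dict(subject_id=sid, phase="supplemental_test", round=0,
                         pair_id=pid, condition=conds[i], cue_shown=scue[i],
                         response=resp, correct=ok, intrusion=False)
                )
    trials = pd.DataFrame(rows)
    return SubjectDataset(
        config=cfg, params=SimParams(seed=seed), stimuli=stim,
        assignments=asg, trials=trials,
    )


@pytest.fixture(scope="session")
def sim_glove_48hr():
    """A modest simulated experiment (wider set, 48 hr) shared across tests."""
    cfg = DesignConfig(
        n_subjects=60, relatedness_metric="glove",
        delay_label="forty_eight_hr", seed=42,
    )
    return simulate_experiment(cfg, SimParams(seed=42))
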