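"""Shared experiment roster for the analysis scripts.

Each named experiment fixes the stimulus set (narrower = association
strength, wider = GloVe cosine), the retention delay, the list order, and a
reproducible seed.  Scripts rebuild datasets from these definitions so they
can run independently of each other.
"""

from remindings.design import DesignConfig, build_stimulus_set
from remindings.metrics import apply_exclusions, score_responses
from remindings.simulate import SimParams, SubjectDataset, simulate_experiment

ROOT_SEED = 2024
N_SUBJECTS = 200

#: materials are fixed per stimulus set and reused across the experiments
#: that share it (as in the study); only the subject samples are redrawn
SET_SEEDS = {"AS": ROOT_SEED + 100, "glove": ROOT_SEED + 200}

EXPERIMENTS: dict[str, dict] = {
    "narrower_5min": dict(metric="AS", delay="five_min", order="proactive", offset=1),
    "narrower_48hr": dict(metric="AS", delay="forty_eight_hr", order="proactive", offset=2),
    "wider_5min": dict(metric="glove", delay="five_min", order="proactive", offset=3),
    "wider_48hr": dict(metric="glove", delay="forty_eight_hr", order="proactive", offset=4),
    "narrower_48hr_retro": dict(metric="AS", delay="forty_eight_hr", order="retroactive", offset=5),
    "narrower_48hr_flipped": dict(metric="AS", delay="forty_eight_hr", order="flipped_test", offset=6),
}


def stimulus_set(metric: str):
    return build_stimulus_set(45, metric=metric, seed=SET_SEEDS[metric])


def simulate_named(name: str, n_subjects: int = N_SUBJECTS) -> SubjectDataset:
    spec = EXPERIMENTS[name]
    seed = ROOT_SEED + spec["offset"]
    cfg = DesignConfig(
        n_subjects=n_subjects,
        relatedness_metric=spec["metric"],
        delay_label=spec["delay"],
        list_order=spec["order"],
        seed=seed,
    )
    params = SimParams(seed=seed, item_seed=SET_SEEDS[spec["metric"]])
    return simulate_experiment(cfg, params, stimuli=stimulus_set(spec["metric"]))


def scored_named(name: str, n_subjects: int = N_SUBJECTS) -> SubjectDataset:
    ds = score_responses(simulate_named(name, n_subjects))
    ds, _ = apply_exclusions(ds)
    return ds
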