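"""Reminding-based generative model of two-list paired-associate memory.

The simulator produces trial-level learning-to-criterion and delayed-test
data whose statistical structure matches what the analysis pipeline expects
from human subjects: relatedness-dependent proactive facilitation and
interference, interdependent base/supplemental duo outcomes, source
intrusions that decline with relatedness, and a retroactive-over-proactive
asymmetry.

Everything lives on the logit scale.  Per subject ``s`` and base pair ``i``:

* ability ``alpha_s ~ N(0, subject_sd^2)``; item difficulties
  ``delta_i ~ N(0, item_sd^2)`` drawn separately for the base and the
  supplemental member of a duo;
* the condition-specific relatedness ``r_i`` (target relatedness for
  DeltaTarget, cue relatedness for DeltaCue, the cue/target mean for
  DeltaBoth, the metric maximum for NoChange);
* a *reminding* event ``R_i ~ Bernoulli(logistic(rho0 + rho1 * r_i))``
  during second-list learning (forced for NoChange, impossible for
  Control).  A reminding integrates the two traces: it adds a facilitation
  boost ``beta_F``, removes the competitor penalty ``beta_I`` that an
  un-integrated DeltaTarget competitor would otherwise exert, couples the
  duo through a shared latent ``c_i ~ N(0, coupling_sd^2)``, and - because
  the reminding is itself a retrieval event for the earlier pair - grants
  the first-learned list's pair an extra ``retrieval_practice_boost``.
  (NoChange repeats are plain restudy of the same association, so they get
  no differential retrieval-practice boost; see the methods note.)
* test recall succeeds when ``logistic(mu_delay + alpha_s - delta_i +
  effects) > u``;
* on a failed DeltaTarget base test the supplemental target intrudes with
  probability ``(1 - R_i) * intrusion_base`` - successful remindings
  prevent the source confusion;
* learning rounds to criterion follow a truncated geometric law with
  per-round success ``logistic(learn_intercept + learn_slope * r_i *
  [second list, non-Control] + alpha_s - delta_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .design import (
    Condition,
    DesignConfig,
    METRIC_RANGES,
    build_counterbalance,
    build_stimulus_set,
)

__all__ = [
    "SimParams",
    "SubjectDataset",
    "SimulationError",
    "simulate_experiment",
    "expected_recall_probability",
    "supplemental_words",
]

PHASES = (
    "supplemental_learning",
    "base_learning",
    "base_test",
    "supplemental_test",
)

TRIAL_COLUMNS = [
    "subject_id",
    "phase",
    "round",
    "pair_id",
    "condition",
    "cue_shown",
    "response",
    "correct",
    "intrusion",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimParams:
    """Generative parameters (logit scale unless noted)."""

    subject_sd: float = 0.8      # sd of subject ability alpha_s
    item_sd: float = 0.5         # sd of item difficulty delta_i
    mu_5min: float = 1.5         # baseline recall logit, 5 min delay
    mu_48hr: float = -0.5        # baseline recall logit, 48 hr delay
    remind_intercept: float = -2.0   # rho0
    remind_slope: float = 4.0        # rho1, per unit relatedness
    facilitation: float = 1.0        # beta_F, boost when reminded
    interference: float = 1.2       # beta_I, un-integrated DeltaTarget penalty
    delta_cue_interference: float = 0.0  # optional small DeltaCue penalty
    coupling_sd: float = 1.5         # sigma_c, shared duo latent when reminded
    intrusion_base: float = 0.4      # pi, P(supplemental target | failed, not reminded)
    stray_intrusion_rate: float = 0.05  # other-duo supplemental targets on failures
    learn_intercept: float = -0.5    # lambda0
    learn_slope: float = 1.0         # lambda1, relatedness effect on learning
    retrieval_practice_boost: float = 1.0  # beta_R, first-learned list when reminded
    max_rounds: int = 20
    seed: int = 0
    #: item difficulties belong to the materials, not the subject sample;
    #: experiments sharing a stimulus set should share this seed so that
    #: between-experiment contrasts are not diluted by item redraws
    item_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("subject_sd", "item_sd", "coupling_sd", "facilitation",
                     "interference", "retrieval_practice_boost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("intrusion_base", "stray_intrusion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(**d)


@dataclass
class SubjectDataset:
    """Trial-level data plus the design and latent state that produced it.

    ``trials`` uses :data:`TRIAL_COLUMNS`; ``round`` is 0 for test-phase
    records.  ``latents`` (one row per subject x base pair) retains
    ``alpha``, the two item difficulties, the reminding indicator, the
    coupling draw, and the internal relatedness, for oracle tests.
    ``phase_order`` records the order the phases were run in.
    """

    config: DesignConfig
    params: SimParams
    stimuli: pd.DataFrame
    assignments: pd.DataFrame
    trials: pd.DataFrame
    latents: pd.DataFrame | None = None
    phase_order: tuple[str, ...] = PHASES

    def subjects(self) -> list[str]:
        return sorted(self.assignments["subject_id"].unique())


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def supplemental_words(stimuli: pd.DataFrame, conditions: np.ndarray):
    """Supplemental-list cue and target per pair given condition labels.

    NoChange keeps both words; DeltaTarget keeps the cue and swaps the
    target; DeltaCue swaps the cue; DeltaBoth swaps both.  Control has no
    supplemental pair (returned words are empty strings).
    """
    base_cue = stimuli["base_cue"].to_numpy()
    base_tgt = stimuli["base_target"].to_numpy()
    alt_cue = stimuli["alt_cue"].to_numpy()
    alt_tgt = stimuli["alt_target"].to_numpy()
    cue = np.where(
        np.isin(conditions, [Condition.DELTA_CUE.value, Condition.DELTA_BOTH.value]),
        alt_cue,
        base_cue,
    )
    tgt = np.where(
        np.isin(conditions, [Condition.DELTA_TARGET.value, Condition.DELTA_BOTH.value]),
        alt_tgt,
        base_tgt,
    )
    is_control = conditions == Condition.CONTROL.value
    cue = np.where(is_control, "", cue)
    tgt = np.where(is_control, "", tgt)
    return cue, tgt


def _internal_relatedness(
    stimuli: pd.DataFrame, conditions: np.ndarray, metric: str
) -> np.ndarray:
    """Condition-specific r on the metric's own scale (DeltaBoth uses the
    cue/target mean so r stays in range; NoChange sits at the metric max)."""
    cue = stimuli[f"cue_rel_{metric}"].to_numpy()
    tgt = stimuli[f"target_rel_{metric}"].to_numpy()
    r = np.full(len(stimuli), np.nan)
    r = np.where(conditions == Condition.DELTA_TARGET.value, tgt, r)
    r = np.where(conditions == Condition.DELTA_CUE.value, cue, r)
    r = np.where(conditions == Condition.DELTA_BOTH.value, (cue + tgt) / 2.0, r)
    r = np.where(
        conditions == Condition.NO_CHANGE.value, METRIC_RANGES[metric][1], r
    )
    return r


def _rounds_to_criterion(
    p: np.ndarray, max_rounds: int, rng: np.random.Generator
):
    """First-success round of a truncated geometric; (rounds, learned)."""
    u = rng.uniform(size=p.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.ceil(np.log1p(-u) / np.log1p(-np.clip(p, 1e-12, 1 - 1e-12)))
    k = np.where(p >= 1.0, 1.0, k)
    k = np.where(p <= 0.0, np.inf, k)
    learned = k <= max_rounds
    rounds = np.where(learned, k, max_rounds).astype(int)
    return rounds, learned


def _learning_records(
    subject_id: str,
    phase: str,
    pair_ids: np.ndarray,
    conditions: np.ndarray,
    cues: np.ndarray,
    targets: np.ndarray,
    rounds: np.ndarray,
    learned: np.ndarray,
    wrong_counter: list[int],
) -> pd.DataFrame:
    reps = rounds
    n_rows = int(reps.sum())
    pid = np.repeat(pair_ids, reps)
    cond = np.repeat(conditions, reps)
    cue = np.repeat(cues, reps)
    tgt = np.repeat(targets, reps)
    last = np.repeat(rounds, reps)
    lrn = np.repeat(learned, reps)
    rnd = np.concatenate([np.arange(1, k + 1) for k in reps]) if n_rows else np.array([], int)
    correct = (rnd == last) & lrn
    resp = np.where(correct, tgt, "")
    wrong = ~correct
    n_wrong = int(wrong.sum())
    start = wrong_counter[0]
    junk = np.array([f"x{start + j}9" for j in range(n_wrong)])
    wrong_counter[0] = start + n_wrong
    resp = resp.astype(object)
    resp[wrong] = junk
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "phase": phase,
            "round": rnd,
            "pair_id": pid,
            "condition": cond,
            "cue_shown": cue,
            "response": resp,
            "correct": correct,
            "intrusion": False,
        }
    )


def simulate_experiment(
    config: DesignConfig,
    params: SimParams | None = None,
    stimuli: pd.DataFrame | None = None,
    keep_latents: bool = True,
) -> SubjectDataset:
    """Simulate one full experiment under the generative model.

    Deterministic for a fixed ``(config, params)``: item-level draws come
    from a dedicated stream, and each subject's draws come from the
    substream ``default_rng([params.seed, 1, subject_index])`` so a prefix
    of subjects is reproducible regardless of the total count.
    """
    params = params or SimParams()
    if stimuli is None:
        stimuli = build_stimulus_set(
            config.n_base_pairs,
            metric=config.relatedness_metric,
            range_spec=config.range_spec,
            seed=config.seed,
        )
    assignments = build_counterbalance(config, stimuli)
    metric = config.relatedness_metric
    n_pairs = config.n_base_pairs
    pair_ids = stimuli["pair_id"].to_numpy()
    base_cue = stimuli["base_cue"].to_numpy()
    base_tgt = stimuli["base_target"].to_numpy()
    mu = getattr(params, config.mu_label)

    item_seed = params.item_seed if params.item_seed is not None else params.seed
    item_rng = np.random.default_rng([item_seed, 0])
    delta_base = item_rng.normal(0.0, params.item_sd, size=n_pairs)
    delta_supp = item_rng.normal(0.0, params.item_sd, size=n_pairs)

    # which list is learned first / tested first (see design.list_order)
    base_first = config.list_order in ("retroactive", "flipped_test")
    if config.list_order == "proactive":
        phase_order = (
            "supplemental_learning", "base_learning",
            "base_test", "supplemental_test",
        )
    elif config.list_order == "retroactive":
        phase_order = (
            "base_learning", "supplemental_learning",
            "base_test", "supplemental_test",
        )
    else:  # flipped_test
        phase_order = (
            "base_learning", "supplemental_learning",
            "supplemental_test", "base_test",
        )

    cond_by_subject = (
        assignments.pivot(index="subject_id", columns="pair_id", values="condition")
        .loc[:, pair_ids]
    )
    subject_ids = cond_by_subject.index.to_numpy()

    trial_frames: list[pd.DataFrame] = []
    latent_frames: list[pd.DataFrame] = []
    all_supp_targets = np.unique(
        np.concatenate([stimuli["base_target"].to_numpy(),
                        stimuli["alt_target"].to_numpy()])
    )

    for s_idx, sid in enumerate(subject_ids):
        rng = np.random.default_rng([params.seed, 1, s_idx])
        wrong_counter = [0]
        conds = cond_by_subject.iloc[s_idx].to_numpy()
        is_control = conds == Condition.CONTROL.value
        is_nochange = conds == Condition.NO_CHANGE.value
        is_dtarget = conds == Condition.DELTA_TARGET.value
        is_dcue = conds == Condition.DELTA_CUE.value
        supp_mask = ~is_control

        alpha = rng.normal(0.0, params.subject_sd)
        r = _internal_relatedness(stimuli, conds, metric)
        p_remind = _logistic(params.remind_intercept + params.remind_slope * r)
        reminded = rng.uniform(size=n_pairs) < p_remind
        reminded = np.where(is_nochange, True, reminded)
        reminded = np.where(is_control, False, reminded)
        coupling = np.where(
            reminded, rng.normal(0.0, params.coupling_sd, size=n_pairs), 0.0
        )
        supp_cue, supp_tgt = supplemental_words(stimuli, conds)

        # ---- learning phases -------------------------------------------
        r_learn = np.where(is_control | np.isnan(r), 0.0, r)
        # second-learned list gets the relatedness scaffold
        base_r_term = 0.0 if base_first else params.learn_slope * r_learn
        supp_r_term = params.learn_slope * r_learn if base_first else 0.0

        p_base_learn = _logistic(
            params.learn_intercept + base_r_term + alpha - delta_base
        )
        base_rounds, base_learned = _rounds_to_criterion(
            p_base_learn, params.max_rounds, rng
        )
        base_learn_df = _learning_records(
            sid, "base_learning", pair_ids, conds, base_cue, base_tgt,
            base_rounds, base_learned, wrong_counter,
        )

        p_supp_learn = _logistic(
            params.learn_intercept + supp_r_term + alpha - delta_supp
        )[supp_mask]
        supp_rounds, supp_learned = _rounds_to_criterion(
            p_supp_learn, params.max_rounds, rng
        )
        supp_learn_df = _learning_records(
            sid, "supplemental_learning", pair_ids[supp_mask], conds[supp_mask],
            supp_cue[supp_mask], supp_tgt[supp_mask],
            supp_rounds, supp_learned, wrong_counter,
        )

        # ---- test phases ------------------------------------------------
        remindedf = reminded.astype(float)
        boost_eligible = remindedf * (~is_nochange) * (~is_control)
        interference_term = (
            (1.0 - remindedf) * params.interference * is_dtarget
            + (1.0 - remindedf) * params.delta_cue_interference * is_dcue
        )
        common = (
            mu + alpha + remindedf * params.facilitation
            - interference_term + coupling
        )
        base_logit = common - delta_base + (
            params.retrieval_practice_boost * boost_eligible if base_first else 0.0
        )
        supp_logit = common - delta_supp + (
            0.0 if base_first else params.retrieval_practice_boost * boost_eligible
        )

        base_correct = rng.uniform(size=n_pairs) < _logistic(base_logit)
        supp_correct = rng.uniform(size=n_pairs) < _logistic(supp_logit)

        # base-test responses: target if correct; on DeltaTarget failures the
        # supplemental target intrudes with prob (1-R)*pi; other failures are
        # junk tokens, occasionally another duo's supplemental target
        base_resp = np.where(base_correct, base_tgt, "").astype(object)
        u_intr = rng.uniform(size=n_pairs)
        intrusion = (
            ~base_correct
            & is_dtarget
            & (u_intr < (1.0 - remindedf) * params.intrusion_base)
        )
        base_resp[intrusion] = supp_tgt[intrusion]
        plain_fail = ~base_correct & ~intrusion
        stray = plain_fail & (rng.uniform(size=n_pairs) < params.stray_intrusion_rate)
        for i in np.flatnonzero(stray):
            choices = all_supp_targets[
                (all_supp_targets != supp_tgt[i]) & (all_supp_targets != base_tgt[i])
            ]
            base_resp[i] = choices[rng.integers(len(choices))]
        rest = plain_fail & ~stray
        n_rest = int(rest.sum())
        base_resp[rest] = [
            f"x{wrong_counter[0] + j}9" for j in range(n_rest)
        ]
        wrong_counter[0] += n_rest

        base_test_df = pd.DataFrame(
            {
                "subject_id": sid,
                "phase": "base_test",
                "round": 0,
                "pair_id": pair_ids,
                "condition": conds,
                "cue_shown": base_cue,
                "response": base_resp,
                "correct": base_correct,
                "intrusion": intrusion,
            }
        )

        supp_resp = np.where(supp_correct, supp_tgt, "").astype(object)
        supp_fail = supp_mask & ~supp_correct
        n_sf = int(supp_fail.sum())
        supp_resp[supp_fail] = [f"x{wrong_counter[0] + j}9" for j in range(n_sf)]
        wrong_counter[0] += n_sf
        supp_test_df = pd.DataFrame(
            {
                "subject_id": sid,
                "phase": "supplemental_test",
                "round": 0,
                "pair_id": pair_ids[supp_mask],
                "condition": conds[supp_mask],
                "cue_shown": supp_cue[supp_mask],
                "response": supp_resp[supp_mask],
                "correct": supp_correct[supp_mask],
                "intrusion": False,
            }
        )

        by_phase = {
            "supplemental_learning": supp_learn_df,
            "base_learning": base_learn_df,
            "base_test": base_test_df,
            "supplemental_test": supp_test_df,
        }
        trial_frames.extend(by_phase[p] for p in phase_order)

        if keep_latents:
            latent_frames.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "pair_id": pair_ids,
                        "condition": conds,
                        "alpha": alpha,
                        "delta_base": delta_base,
                        "delta_supp": delta_supp,
                        "relatedness": r,
                        "reminded": reminded,
                        "coupling": coupling,
                        "learned_base": base_learned,
                        "learned_supp": np.where(
                            supp_mask,
                            np.isin(
                                pair_ids, pair_ids[supp_mask][supp_learned]
                            ),
                            False,
                        ),
                    }
                )
            )

    trials = pd.concat(trial_frames, ignore_index=True)
    trials["correct"] = trials["correct"].astype(bool)
    trials["intrusion"] = trials["intrusion"].astype(bool)
    latents = pd.concat(latent_frames, ignore_index=True) if keep_latents else None
    return SubjectDataset(
        config=config,
        params=params,
        stimuli=stimuli,
        assignments=assignments,
        trials=trials,
        latents=latents,
        phase_order=phase_order,
    )


# ---------------------------------------------------------------------------
# closed-form marginal (oracle for the simulator)


def expected_recall_probability(
    params: SimParams,
    condition: Condition | str,
    relatedness: float | None,
    delay: str = "forty_eight_hr",
    order_role: str = "second_learned",
    which_list: str = "base",
    n_nodes: int = 80,
) -> float:
    """Model-implied marginal recall probability for one condition cell.

    Integrates the logistic success probability over ``alpha``, ``delta``,
    the coupling latent and the reminding indicator.  Because those latents
    enter the logit additively, the triple Gaussian integral collapses to a
    single Gauss-Hermite quadrature over their sum.  ``order_role`` states
    whether the tested list was learned first or second.
    """
    condition = Condition(condition)
    if order_role not in ("first_learned", "second_learned"):
        raise ValueError(f"unknown order_role {order_role!r}")
    mu = params.mu_5min if delay == "five_min" else params.mu_48hr
    if condition is Condition.CONTROL:
        p_remind = 0.0
    elif condition is Condition.NO_CHANGE:
        p_remind = 1.0
    else:
        if relatedness is None or not np.isfinite(relatedness):
            raise SimulationError(
                f"condition {condition.value} requires a relatedness value"
            )
        p_remind = float(
            _logistic(params.remind_intercept + params.remind_slope * relatedness)
        )

    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    weights = weights / np.sqrt(2.0 * np.pi)

    def branch(reminded: bool) -> float:
        m = mu + (params.facilitation if reminded else 0.0)
        if not reminded and condition is Condition.DELTA_TARGET:
            m -= params.interference
        if not reminded and condition is Condition.DELTA_CUE:
            m -= params.delta_cue_interference
        if (
            reminded
            and order_role == "first_learned"
            and condition not in (Condition.NO_CHANGE, Condition.CONTROL)
        ):
            m += params.retrieval_practice_boost
        var = params.subject_sd**2 + params.item_sd**2
        if reminded:
            var += params.coupling_sd**2
        s = np.sqrt(var)
        vals = _logistic(m + s * nodes)
        out = float(np.sum(weights * vals))
        if not np.isfinite(out):
            raise SimulationError(
                f"quadrature failed (m={m}, s={s}, nodes={n_nodes})"
            )
        return out

    return (1.0 - p_remind) * branch(False) + p_remind * branch(True)
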