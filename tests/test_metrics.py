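"""Scoring, exclusions, memorability, interdependence, intrusions, and
learning speed, each against hand-computed or exhaustively enumerated
oracles on small fixtures."""

import numpy as np
import pandas as pd
import pytest

from remindings.design import Condition, DesignConfig, build_counterbalance, build_stimulus_set
from remindings.metrics import (
    DependenceTable,
    MissingCellError,
    PipelineError,
    apply_exclusions,
    condition_means,
    interdependence,
    intrusion_rates,
    memorability,
    score_responses,
    trials_to_criterion,
)
from remindings.simulate import SimParams, simulate_experiment, supplemental_words

from conftest import make_manual_dataset


class TestScoreResponses:
    def _dataset_with_responses(self, responses):
        return make_manual_dataset(
            np.zeros((5, 5), dtype=bool), base_responses=responses, seed=2
        )

    def test_case_and_whitespace_normalized(self):
        ds = make_manual_dataset(np.zeros((5, 5), dtype=bool), seed=2)
        tgt = ds.stimuli["base_target"].iloc[0]
        ds.trials.loc[
            (ds.trials.pair_id == "P000") & (ds.trials.subject_id == "S0000"),
            "response",
        ] = tgt.upper() + " "
        scored = score_responses(ds)
        row = scored.trials[
            (scored.trials.pair_id == "P000") & (scored.trials.subject_id == "S0000")
        ].iloc[0]
        assert bool(row.correct)

    def test_supplemental_target_is_intrusion(self):
        ds = make_manual_dataset(np.zeros((5, 5), dtype=bool), seed=2)
        # find a subject/pair cell in the DeltaTarget condition
        cell = ds.trials[ds.trials.condition == "DeltaTarget"].iloc[0]
        alt = ds.stimuli.set_index("pair_id").loc[cell.pair_id, "alt_target"]
        ds.trials.loc[cell.name, "response"] = alt
        scored = score_responses(ds)
        row = scored.trials.loc[cell.name]
        assert bool(row.intrusion) and not bool(row.correct)

    def test_edit1_leniency_on_intrusions(self):
        ds = make_manual_dataset(np.zeros((5, 5), dtype=bool), seed=2)
        cell = ds.trials[ds.trials.condition == "DeltaTarget"].iloc[0]
        alt = ds.stimuli.set_index("pair_id").loc[cell.pair_id, "alt_target"]
        typo = ("q" + alt[1:])  # one substitution
        assert typo != alt
        ds.trials.loc[cell.name, "response"] = typo
        strict = score_responses(ds, "exact").trials.loc[cell.name]
        lenient = score_responses(ds, "edit1").trials.loc[cell.name]
        assert not bool(strict.intrusion)
        assert bool(lenient.intrusion)

    def test_edit1_leniency_on_correctness(self):
        ds = make_manual_dataset(np.zeros((5, 5), dtype=bool), seed=2)
        idx = ds.trials.index[0]
        tgt = ds.stimuli.set_index("pair_id").loc[ds.trials.loc[idx, "pair_id"], "base_target"]
        ds.trials.loc[idx, "response"] = tgt[:-1]  # one deletion
        assert not bool(score_responses(ds, "exact").trials.loc[idx, "correct"])
        assert bool(score_responses(ds, "edit1").trials.loc[idx, "correct"])

    def test_unknown_leniency_rejected(self):
        ds = make_manual_dataset(np.zeros((2, 5), dtype=bool))
        with pytest.raises(ValueError):
            score_responses(ds, "soundex")

    def test_simulator_flags_are_reproduced(self, sim_glove_48hr):
        rescored = score_responses(sim_glove_48hr)
        orig = sim_glove_48hr.trials
        pd.testing.assert_series_equal(rescored.trials["correct"], orig["correct"])
        pd.testing.assert_series_equal(rescored.trials["intrusion"], orig["intrusion"])


class TestApplyExclusions:
    def test_homogeneous_sample_keeps_everyone(self, sim_glove_48hr):
        filtered, report = apply_exclusions(sim_glove_48hr)
        assert not report["excluded"].any()
        assert filtered.trials.shape == sim_glove_48hr.trials.shape

    def test_constructed_outlier_excluded(self):
        rng = np.random.default_rng(0)
        correct = rng.uniform(size=(200, 45)) < 0.9
        correct[0] = False  # one subject recalls nothing
        ds = make_manual_dataset(correct)
        filtered, report = apply_exclusions(ds)
        rep = report.set_index("subject_id")
        assert bool(rep.loc["S0000", "excluded"])
        assert rep["excluded"].sum() == 1
        assert "S0000" not in filtered.trials.subject_id.unique()

    def test_two_subjects_hand_z(self):
        correct = np.array([[True] * 5, [False] * 5])
        ds = make_manual_dataset(correct)
        _, report = apply_exclusions(ds)
        rep = report.set_index("subject_id")
        # props 1.0 and 0.0: mean .5, sd ~.7071 -> z = -0.7071, not excluded
        assert rep.loc["S0001", "z"] == pytest.approx(-np.sqrt(0.5), abs=1e-9)
        assert not rep["excluded"].any()

    def test_single_subject_error(self):
        ds = make_manual_dataset(np.ones((1, 5), dtype=bool))
        with pytest.raises(PipelineError):
            apply_exclusions(ds)


class TestMemorability:
    def test_control_rows_are_zero(self, sim_glove_48hr):
        mem = memorability(sim_glove_48hr, Condition.CONTROL)
        assert (mem["memorability"] == 0.0).all()

    def test_extreme_cell(self):
        # all subjects recall pair P000 under DeltaCue, none under Control
        n = 10
        stim = build_stimulus_set(5, seed=4)
        cfg = DesignConfig(n_subjects=n, n_base_pairs=5, seed=4)
        asg = build_counterbalance(cfg, stim)
        cond = asg.pivot(index="subject_id", columns="pair_id", values="condition")
        correct = np.zeros((n, 5), dtype=bool)
        for s in range(n):
            correct[s, 0] = cond.iloc[s]["P000"] == "DeltaCue"
        ds = make_manual_dataset(correct, seed=4)
        mem = memorability(ds, Condition.DELTA_CUE).set_index("pair_id")
        assert mem.loc["P000", "memorability"] == pytest.approx(1.0)

    def test_hand_counted_proportions(self):
        rng = np.random.default_rng(8)
        correct = rng.uniform(size=(10, 5)) < 0.5
        ds = make_manual_dataset(correct, seed=8)
        mem = memorability(ds, Condition.DELTA_TARGET).set_index("pair_id")
        # brute-force count over the raw assignment table
        cond = ds.assignments.pivot(
            index="subject_id", columns="pair_id", values="condition"
        )
        pair_ids = list(ds.stimuli["pair_id"])
        for j, pid in enumerate(pair_ids):
            for label, col in (("DeltaTarget", "prop_recalled"), ("Control", "prop_control")):
                subs = [s for s in range(10) if cond.iloc[s][pid] == label]
                expect = np.mean([correct[s, j] for s in subs])
                assert mem.loc[pid, col] == pytest.approx(expect)

    def test_memorability_antisymmetry(self, sim_glove_48hr):
        mem = memorability(sim_glove_48hr, Condition.DELTA_CUE)
        flipped = mem["prop_control"] - mem["prop_recalled"]
        assert np.allclose(flipped, -mem["memorability"])

    def test_delta_both_relatedness_is_sum(self, sim_glove_48hr):
        mem = memorability(sim_glove_48hr, Condition.DELTA_BOTH)
        stim = sim_glove_48hr.stimuli.set_index("pair_id")
        expect = (
            stim.loc[mem["pair_id"], "cue_rel_glove"].to_numpy()
            + stim.loc[mem["pair_id"], "target_rel_glove"].to_numpy()
        )
        assert np.allclose(mem["relatedness"], expect)


class TestInterdependence:
    def test_ceiling_degenerate(self):
        ds = make_manual_dataset(
            np.ones((10, 10), dtype=bool), supp_correct=np.ones((10, 10), dtype=bool)
        )
        dep = interdependence(ds, Condition.DELTA_TARGET)
        assert np.allclose(dep.table["dependence"], 1.0)
        assert np.allclose(dep.null_values, 1.0)
        assert dep.threshold_95 == pytest.approx(1.0)

    def test_independent_coin_flips_near_half(self):
        rng = np.random.default_rng(3)
        n = 40 * 5  # 40 subjects per condition cell
        base = rng.uniform(size=(n, 45)) < 0.5
        supp = rng.uniform(size=(n, 45)) < 0.5
        ds = make_manual_dataset(base, supp_correct=supp)
        dep = interdependence(ds, Condition.DELTA_CUE)
        se = np.sqrt(0.25 / 40) / np.sqrt(45)
        assert abs(dep.table["dependence"].mean() - 0.5) < 3 * se

    def test_eight_subject_exhaustive_enumeration(self):
        """Matched values, every mismatched duo, and the 95th-percentile
        threshold agree with a plain-loop enumeration."""
        rng = np.random.default_rng(5)
        base = rng.uniform(size=(8, 45)) < 0.6
        supp = rng.uniform(size=(8, 45)) < 0.6
        ds = make_manual_dataset(base, supp_correct=supp, seed=5)
        cond_name = "DeltaTarget"
        dep = interdependence(ds, cond_name)

        cond = ds.assignments.pivot(
            index="subject_id", columns="pair_id", values="condition"
        )
        stim = ds.stimuli.set_index("pair_id")
        pair_ids = list(stim.index)
        col = {p: j for j, p in enumerate(pair_ids)}
        null_oracle, matched_oracle = [], {}
        for g in sorted(stim["counterbalance_group"].unique()):
            members = [p for p in pair_ids if stim.loc[p, "counterbalance_group"] == g]
            subs = [s for s in range(8) if cond.iloc[s][members[0]] == cond_name]
            assert subs, "every group must serve every condition"
            for pi in members:
                agree = [base[s, col[pi]] == supp[s, col[pi]] for s in subs]
                matched_oracle[pi] = np.mean(agree)
                for pj in members:
                    if pj == pi:
                        continue
                    vals = [base[s, col[pi]] == supp[s, col[pj]] for s in subs]
                    null_oracle.append(np.mean(vals))
        got = dep.table.set_index("pair_id")["dependence"]
        for pid, v in matched_oracle.items():
            assert got[pid] == pytest.approx(v)
        assert len(dep.null_values) == len(null_oracle) == 5 * 9 * 8
        assert sorted(dep.null_values) == pytest.approx(sorted(null_oracle))
        assert dep.threshold_95 == pytest.approx(
            np.quantile(np.asarray(null_oracle), 0.95)
        )

    def test_null_size_for_default_design(self, sim_glove_48hr):
        dep = interdependence(sim_glove_48hr, Condition.DELTA_BOTH)
        assert len(dep.null_values) == 5 * 9 * 8  # groups x 9 x 8 = 360

    def test_control_rejected(self, sim_glove_48hr):
        with pytest.raises(ValueError):
            interdependence(sim_glove_48hr, Condition.CONTROL)

    def test_independence_regime_exceedance_near_five_percent(self):
        """With coupling and subject variance off, matched duos escape the
        95th-percentile null threshold at roughly the nominal 5% rate."""
        rates = []
        for seed in range(12):
            p = SimParams(seed=seed, coupling_sd=0.0, subject_sd=0.0)
            ds = simulate_experiment(
                DesignConfig(n_subjects=50, seed=seed), p, keep_latents=False
            )
            for cond in ("DeltaTarget", "DeltaCue", "DeltaBoth", "NoChange"):
                dep = interdependence(ds, cond)
                rates.append((dep.table["dependence"] > dep.threshold_95).mean())
        assert 0.02 < np.mean(rates) < 0.09


class TestIntrusions:
    def test_mechanism_off_gives_zero(self):
        p = SimParams(seed=9, intrusion_base=0.0, stray_intrusion_rate=0.0)
        ds = simulate_experiment(
            DesignConfig(n_subjects=30, seed=9), p, keep_latents=False
        )
        rates = intrusion_rates(ds)
        assert (rates["intrusion_rate"] == 0.0).all()

    def test_hand_counted_rate(self):
        n = 40 * 5
        ds = make_manual_dataset(np.zeros((n, 45), dtype=bool), seed=6)
        # make exactly 2 of the 40 DeltaTarget subjects of pair P000 intrude
        stim = ds.stimuli.set_index("pair_id")
        cells = ds.trials[
            (ds.trials.pair_id == "P000") & (ds.trials.condition == "DeltaTarget")
        ]
        assert len(cells) == 40
        ds.trials.loc[cells.index[:2], "response"] = stim.loc["P000", "alt_target"]
        ds = score_responses(ds)
        rates = intrusion_rates(ds).set_index("pair_id")
        assert rates.loc["P000", "intrusion_rate"] == pytest.approx(0.05)

    def test_rate_decreases_with_relatedness(self):
        cfg = DesignConfig(
            n_subjects=500, relatedness_metric="glove", seed=11
        )
        ds = simulate_experiment(cfg, SimParams(seed=11), keep_latents=False)
        rates = intrusion_rates(ds)
        r = np.corrcoef(rates["relatedness"], rates["intrusion_rate"])[0, 1]
        assert r < -0.3


class TestTrialsToCriterion:
    def test_floor_all_round_one(self):
        cfg = DesignConfig(n_subjects=2, n_base_pairs=5, seed=1)
        p = SimParams(seed=1, learn_intercept=30.0, subject_sd=0, item_sd=0)
        ds = simulate_experiment(cfg, p)
        per_pair, per_subject = trials_to_criterion(ds, "base")
        assert (per_pair["mean_rounds"] == 1.0).all()
        assert (per_subject["mean_rounds"] == 1.0).all()

    def test_hand_mean(self):
        # pair learned on rounds 1, 2, 3 across three subjects -> mean 2
        rows = []
        for s, k in enumerate((1, 2, 3)):
            for r in range(1, k + 1):
                rows.append(
                    dict(subject_id=f"S{s:04d}", phase="base_learning", round=r,
                         pair_id="P000", condition="Control", cue_shown="cue",
                         response="tgt" if r == k else "x", correct=r == k,
                         intrusion=False)
                )
        stim = build_stimulus_set(5, seed=0)
        ds = make_manual_dataset(np.zeros((3, 5), dtype=bool), seed=0)
        ds.trials = pd.concat([ds.trials, pd.DataFrame(rows)], ignore_index=True)
        per_pair, _ = trials_to_criterion(ds, "base")
        assert per_pair.set_index("pair_id").loc["P000", "mean_rounds"] == pytest.approx(2.0)

    def test_unlearned_counted_at_max_rounds_and_flagged(self):
        cfg = DesignConfig(n_subjects=2, n_base_pairs=5, seed=2)
        p = SimParams(seed=2, learn_intercept=-30.0, max_rounds=4,
                      subject_sd=0, item_sd=0)
        ds = simulate_experiment(cfg, p)
        per_pair, _ = trials_to_criterion(ds, "base")
        assert (per_pair["mean_rounds"] == 4.0).all()
        assert (per_pair["n_unlearned"] > 0).all()

    def test_relatedness_speeds_learning(self):
        cfg = DesignConfig(n_subjects=400, relatedness_metric="glove", seed=15)
        ds = simulate_experiment(cfg, SimParams(seed=15), keep_latents=False)
        per_pair, _ = trials_to_criterion(ds, "base")
        for cond in ("DeltaCue", "DeltaTarget"):
            sub = per_pair[per_pair.condition == cond]
            r = np.corrcoef(sub["relatedness"], sub["mean_rounds"])[0, 1]
            assert r < 0, cond


class TestCellCounts:
    def test_denominators_are_fifth_of_subjects(self):
        cfg = DesignConfig(n_subjects=50, seed=3)
        ds = simulate_experiment(cfg, SimParams(seed=3), keep_latents=False)
        mem = memorability(ds, Condition.DELTA_TARGET)
        assert (mem["n_subjects"] == 10).all()
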