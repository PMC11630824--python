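"""Schema-validated readers/writers, run configuration, and the end-to-end
pipeline runner (design -> simulate -> metrics -> stats -> surface).

All tables are UTF-8 comma-separated text with a mandatory header row and
floats serialized at 10 significant digits, which keeps reruns of the same
configuration byte-identical and hashable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import (
    Condition,
    DesignConfig,
    DESIGN_COLUMNS,
    EXPERIMENTAL_CONDITIONS,
    STIMULUS_COLUMNS,
    build_counterbalance,
    build_stimulus_set,
    validate_counterbalance,
)
from .metrics import (
    apply_exclusions,
    condition_means,
    interdependence,
    intrusion_rates,
    memorability,
    trials_to_criterion,
)
from .simulate import (
    PHASES,
    SimParams,
    SubjectDataset,
    TRIAL_COLUMNS,
    simulate_experiment,
)
from .stats import pairwise_t_fdr, relatedness_regression, rm_anova, thirds_split_test
from .surface import assemble_osgood

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_trials",
    "write_trials",
    "read_stimuli",
    "write_stimuli",
    "read_design",
    "write_design",
    "write_table",
    "load_dataset",
    "save_dataset",
    "run_pipeline",
    "read_params",
    "write_params",
]

log = logging.getLogger("remindings")

FLOAT_FORMAT = "%.10g"


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_stimuli(stimuli: pd.DataFrame, path) -> Path:
    return write_table(stimuli[STIMULUS_COLUMNS], path)


def read_stimuli(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, STIMULUS_COLUMNS, path)
    return df


def write_design(assignments: pd.DataFrame, path) -> Path:
    return write_table(assignments[DESIGN_COLUMNS], path)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, DESIGN_COLUMNS, path)
    valid = {c.value for c in Condition}
    bad = ~df["condition"].isin(valid)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise SchemaError(
            f"{path}: unknown condition {df.loc[bad, 'condition'].iloc[0]!r} "
            f"at line {line}"
        )
    return df


def write_trials(trials: pd.DataFrame, path) -> Path:
    extras = [c for c in trials.columns if c not in TRIAL_COLUMNS]
    return write_table(trials[TRIAL_COLUMNS + extras], path)


def read_trials(path) -> pd.DataFrame:
    """Read a trials table, validating the schema row by row.

    ``round`` is 0 for test-phase records.  Unknown columns are preserved.
    A malformed phase or round raises :class:`SchemaError` naming the line.
    """
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    _check_columns(df, TRIAL_COLUMNS, path)
    if df.empty:
        df["correct"] = df.get("correct", pd.Series(dtype=bool)).astype(bool)
        df["intrusion"] = df.get("intrusion", pd.Series(dtype=bool)).astype(bool)
        df["round"] = df.get("round", pd.Series(dtype=int)).astype(int)
        return df
    bad_phase = ~df["phase"].isin(PHASES)
    if bad_phase.any():
        line = int(df.index[bad_phase][0]) + 2
        raise SchemaError(
            f"{path}: unknown phase {df.loc[bad_phase, 'phase'].iloc[0]!r} "
            f"at line {line}"
        )
    rounds = pd.to_numeric(df["round"], errors="coerce")
    bad_round = rounds.isna() | (rounds < 0) | (rounds != rounds.astype(int))
    if bad_round.any():
        line = int(df.index[bad_round][0]) + 2
        raise SchemaError(f"{path}: malformed round value at line {line}")
    df["round"] = rounds.astype(int)
    for col in ("correct", "intrusion"):
        df[col] = (
            df[col].astype(str).str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
        )
        if df[col].isna().any():
            line = int(df.index[df[col].isna()][0]) + 2
            raise SchemaError(f"{path}: malformed {col} flag at line {line}")
        df[col] = df[col].astype(bool)
    return df


def write_params(params: SimParams, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))
    return path


def read_params(path) -> SimParams:
    return SimParams.from_dict(yaml.safe_load(Path(path).read_text()))


def save_dataset(dataset: SubjectDataset, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    paths = {
        "stimuli": write_stimuli(dataset.stimuli, out / "stimuli.csv"),
        "design": write_design(dataset.assignments, out / "design.csv"),
        "trials": write_trials(dataset.trials, out / "trials.csv"),
    }
    meta = {
        "config": dataclasses.asdict(dataset.config),
        "params": dataset.params.to_dict(),
        "phase_order": list(dataset.phase_order),
        "version": __version__,
    }
    meta_path = out / "dataset.yaml"
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))
    paths["meta"] = meta_path
    return paths


def load_dataset(in_dir) -> SubjectDataset:
    in_dir = Path(in_dir)
    meta = yaml.safe_load((in_dir / "dataset.yaml").read_text())
    cfg = meta["config"]
    cfg["range_spec"] = tuple(cfg["range_spec"]) if cfg.get("range_spec") else None
    config = DesignConfig(**cfg)
    params = SimParams.from_dict(meta["params"])
    return SubjectDataset(
        config=config,
        params=params,
        stimuli=read_stimuli(in_dir / "stimuli.csv"),
        assignments=read_design(in_dir / "design.csv"),
        trials=read_trials(in_dir / "trials.csv"),
        latents=None,
        phase_order=tuple(meta["phase_order"]),
    )


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclasses.dataclass
class RunConfig:
    """One experiment run end to end.  Round-trips losslessly through YAML;
    every random stage derives its seed from ``design.seed``."""

    design: DesignConfig = dataclasses.field(default_factory=DesignConfig)
    sim: SimParams = dataclasses.field(default_factory=SimParams)
    conditions: tuple[str, ...] = tuple(c.value for c in EXPERIMENTAL_CONDITIONS)
    leniency: str = "exact"
    n_perm: int = 1000
    alpha: float = 0.01
    bandwidth: float | None = None
    n_grid: int = 41
    out_dir: str = "results/run"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["design"]["range_spec"] = list(self.design.range_spec)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        dc = dict(d.pop("design", {}))
        if dc.get("range_spec"):
            dc["range_spec"] = tuple(dc["range_spec"])
        d["design"] = DesignConfig(**dc)
        d["sim"] = SimParams.from_dict(d.pop("sim", {}))
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and write a manifest of artifacts.

    Stages: design -> simulate -> score/exclude -> per-condition metric
    tables -> condition statistics -> Osgood surface grids.  Rerunning the
    same configuration reproduces byte-identical tables.  A stage failure
    aborts with the stage name and leaves a ``FAILED`` marker naming it.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info(
        "remindings %s pipeline: root seed %d, %d subjects",
        __version__, config.design.seed, config.design.n_subjects,
    )
    produced: dict[str, Path] = {}
    stage = "design"
    try:
        stimuli = build_stimulus_set(
            config.design.n_base_pairs,
            metric=config.design.relatedness_metric,
            range_spec=config.design.range_spec,
            seed=config.design.seed,
        )
        assignments = build_counterbalance(config.design, stimuli)
        problems = validate_counterbalance(assignments, stimuli)
        if problems:
            raise RuntimeError(f"invalid counterbalance: {problems[:3]}")
        produced["stimuli"] = write_stimuli(stimuli, out / "stimuli.csv")
        produced["design"] = write_design(assignments, out / "design.csv")

        stage = "simulate"
        dataset = simulate_experiment(config.design, config.sim, stimuli=stimuli)
        produced["trials"] = write_trials(dataset.trials, out / "trials.csv")

        stage = "metrics"
        from .metrics import score_responses

        dataset = score_responses(dataset, leniency=config.leniency)
        dataset, report = apply_exclusions(dataset)
        produced["exclusions"] = write_table(report, out / "exclusions.csv")
        mem_tables = {}
        for cond in config.conditions:
            mem = memorability(dataset, cond)
            mem_tables[cond] = mem
            produced[f"memorability_{cond}"] = write_table(
                mem, out / f"memorability_{cond}.csv"
            )
            dep = interdependence(dataset, cond)
            tab = dep.table.copy()
            tab["threshold_95"] = dep.threshold_95
            produced[f"dependence_{cond}"] = write_table(
                tab, out / f"dependence_{cond}.csv"
            )
        intr = intrusion_rates(dataset)
        produced["intrusions"] = write_table(intr, out / "intrusions.csv")
        ttc_pair, ttc_subj = trials_to_criterion(dataset, "base")
        produced["learning_per_pair"] = write_table(
            ttc_pair, out / "learning_per_pair.csv"
        )
        produced["learning_per_subject"] = write_table(
            ttc_subj, out / "learning_per_subject.csv"
        )

        stage = "stats"
        wide = condition_means(dataset)
        anova = rm_anova(wide)
        pairwise = pairwise_t_fdr(wide)
        produced["pairwise"] = write_table(pairwise, out / "pairwise_t_fdr.csv")
        reg_rows = []
        for cond, mem in mem_tables.items():
            if cond == Condition.NO_CHANGE.value:
                continue
            fit = relatedness_regression(mem)
            thirds = thirds_split_test(mem)
            produced[f"thirds_{cond}"] = write_table(
                thirds, out / f"thirds_{cond}.csv"
            )
            reg_rows.append(
                {
                    "condition": cond,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "p_slope": fit.p_slope,
                    "p_intercept": fit.p_intercept,
                    "n": fit.n,
                }
            )
        produced["regressions"] = write_table(
            pd.DataFrame(reg_rows), out / "regressions.csv"
        )
        report_txt = out / "stats_report.txt"
        report_txt.write_text(
            "condition effect: F({},{}) = {:.4g}, p = {:.4g}\n".format(
                anova.df_num, anova.df_den, anova.F, anova.p
            )
        )
        produced["stats_report"] = report_txt

        stage = "surface"
        summary = assemble_osgood(
            {c: t for c, t in mem_tables.items()},
            stimuli=stimuli,
            metric=config.design.relatedness_metric,
            bandwidth=config.bandwidth,
            n_grid=config.n_grid,
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=config.design.seed,
        )
        grid = summary.both_surface
        surf_df = pd.DataFrame(
            {
                "cue_rel": np.repeat(grid.grid_cue, len(grid.grid_target)),
                "target_rel": np.tile(grid.grid_target, len(grid.grid_cue)),
                "z": grid.z.ravel(),
                "lower": grid.lower_bound.ravel(),
                "upper": grid.upper_bound.ravel(),
                "significant": grid.significant.ravel(),
                "support": grid.support_mask.ravel(),
            }
        )
        produced["surface"] = write_table(surf_df, out / "surface_memorability.csv")
    except Exception as exc:  # persist partial outputs under a failure marker
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "root_seed": config.design.seed,
        "phase_order": list(dataset.phase_order),
        "config": config.to_dict(),
        "files": {
            name: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
            for name, p in sorted(produced.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %d artifacts in %s", len(produced), out)
    return manifest
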