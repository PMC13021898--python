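"""Reproducible end-to-end synthetic studies.

:func:`run_full_study` regenerates the whole study from one seed: per
participant it builds the experiment's trial plan (with balanced
counterbalancing flags), simulates the synthetic observer over it, pools the
logs and runs the experiment's analysis, writing tidy CSV tables and a JSON
run report.  Every output is stamped with a hash of the run configuration;
writing into a results directory produced under a different configuration is
refused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis as ana
from . import design as dsg
from . import observer as obs
from .io import write_trial_log

__all__ = ["RunConfig", "run_full_study", "analyze_log", "config_hash"]

_EXPERIMENTS = ("1a", "1b", "2", "3")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full synthetic study run.

    ``n_participants_single`` covers the single-task experiments (1a, 1b, 2);
    ``n_participants_switch`` covers the task-switching experiment (3); the
    defaults are the original sample sizes (42 and 30).  ``seed`` drives
    every stochastic stage through per-(experiment, participant) substreams.
    """

    out_dir: str = "rsk_study"
    seed: int = 0
    n_participants_single: int = 42
    n_participants_switch: int = 30
    experiments: tuple = _EXPERIMENTS
    observer: obs.ObserverParams = field(default_factory=obs.default_params)
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        unknown = set(self.experiments) - set(_EXPERIMENTS)
        if unknown:
            raise ValueError(f"unknown experiments: {sorted(unknown)}")
        if self.n_participants_single < 1 or self.n_participants_switch < 1:
            raise ValueError("participant counts must be positive")


def config_hash(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("out_dir")  # the same run may be written anywhere
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _substream_seed(seed: int, experiment: str, participant: int) -> int:
    entropy = [seed, _EXPERIMENTS.index(experiment), participant]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def build_study_log(
    experiment: str,
    n_participants: int,
    seed: int,
    params: obs.ObserverParams | None = None,
    dt_ms: float = 1.0,
) -> pd.DataFrame:
    """Generate plans and simulate observers for one experiment; pooled log."""
    params = params or obs.default_params()
    flags = dsg.counterbalancing_assignment(n_participants)
    logs = []
    for _, row in flags.iterrows():
        pid = int(row["participant_id"])
        s_design = _substream_seed(seed, experiment, pid)
        s_observer = _substream_seed(seed, experiment, pid + 100_000)
        if experiment in ("1a", "1b"):
            plan = dsg.build_design(experiment, s_design)
        elif experiment == "2":
            plan = dsg.build_design(experiment, s_design, first_task=row["first_task"])
        else:
            plan = dsg.build_design(
                experiment,
                s_design,
                first_task=row["first_task"],
                csi_block_order=row["csi_block_order"],
                color_mapping_flipped=bool(row["color_mapping_flipped"]),
            )
        logs.append(
            obs.simulate_participant(
                plan, params, seed=s_observer, participant_id=pid, dt_ms=dt_ms
            )
        )
    return pd.concat(logs, ignore_index=True)


def _impute_missing_cells(wide: pd.DataFrame) -> pd.DataFrame:
    """Fill empty subject x cell RT means with the subject's own grand mean.

    At the lowest coherences a participant can lose every trial of a small
    cell to errors; the omnibus ANOVA needs a complete grid, so such cells
    (typically a fraction of a percent) are imputed neutrally.
    """
    return wide.apply(lambda row: row.fillna(row.mean()), axis=1)


def _rm_anova_imputed(
    data: pd.DataFrame, dv: str, within: list[str]
) -> ana.AnovaResult:
    levels = [sorted(data[f].dropna().unique().tolist()) for f in within]
    grid = pd.MultiIndex.from_product(levels, names=within)
    wide = data.pivot_table(
        index="participant_id", columns=within, values=dv, aggfunc="mean",
        observed=True,
    )
    if len(within) == 1:
        wide.columns = pd.MultiIndex.from_arrays([wide.columns], names=within)
    wide = _impute_missing_cells(wide.reindex(columns=grid))
    tidy = wide.stack(list(range(len(within))), future_stack=True).rename(dv).reset_index()
    return ana.rm_anova(tidy, dv, within)


def analyze_log(
    log: pd.DataFrame, experiment: str, config: ana.CleaningConfig | None = None
) -> dict:
    """Run the experiment's analysis chain on a pooled trial log.

    Returns a dict of result tables (DataFrames) and summary dicts.  ANOVAs
    and t-tests require at least two participants and are skipped (with a
    note) otherwise.
    """
    config = config or ana.CleaningConfig()
    n_participants = int(log["participant_id"].nunique())
    out: dict = {"experiment": experiment, "n_participants": n_participants}
    _, _, out["exclusions"] = ana.clean_trials(log, config)
    multi = n_participants >= 2

    if experiment == "1a":
        keys = ["majority_color", "motion_coherence", "direction"]
        out["cells"] = ana.cell_summary(log, ["participant_id"] + keys, config)
        if multi:
            rt_cells = out["cells"].dropna(subset=["mean_log_rt"])
            out["rt_anova"] = _rm_anova_imputed(
                rt_cells, "mean_log_rt", keys
            ).to_frame()
            out["accuracy_anova"] = _rm_anova_imputed(
                out["cells"], "arcsine_accuracy", keys
            ).to_frame()
    elif experiment == "1b":
        keys = ["majority_color", "color_coherence"]
        out["cells"] = ana.cell_summary(log, ["participant_id"] + keys, config)
        if multi:
            rt_cells = out["cells"].dropna(subset=["mean_log_rt"])
            out["rt_anova"] = _rm_anova_imputed(rt_cells, "mean_log_rt", keys).to_frame()
            out["accuracy_anova"] = _rm_anova_imputed(
                out["cells"], "arcsine_accuracy", keys
            ).to_frame()
    elif experiment == "2":
        reg_rows = []
        for task in (dsg.MOTION, dsg.COLOR):
            for outcome in ("rt", "accuracy"):
                r = ana.regress_target_distractor(log, task, outcome, config)
                for pred, row in r.coefficients.iterrows():
                    reg_rows.append(
                        {
                            "task": task,
                            "outcome": outcome,
                            "predictor": pred,
                            "beta": row["beta"],
                            "t": row["t"],
                            "p": row["p"],
                            "F": r.f_value,
                            "df_model": r.df_model,
                            "df_resid": r.df_resid,
                            "model_p": r.p_value,
                            "adj_r_squared": r.adj_r_squared,
                        }
                    )
        out["regressions"] = pd.DataFrame(reg_rows)
        if multi:
            chance_rows = []
            _, acc_log, _ = ana.clean_trials(log, config)
            for task, target_col, minimum in (
                (dsg.MOTION, "motion_coherence", min(dsg.MOTION_COHERENCE_LEVELS)),
                (dsg.COLOR, "color_coherence", min(dsg.COLOR_COHERENCE_LEVELS)),
            ):
                sub = acc_log[
                    (acc_log["task"] == task) & (acc_log[target_col] == minimum)
                ]
                for congruent, grp in sub.groupby(
                    sub["congruent"].astype("boolean"), observed=True
                ):
                    accs = grp.groupby("participant_id")["correct"].mean()
                    r = ana.chance_level_test(accs.to_numpy(dtype=float))
                    chance_rows.append(
                        {
                            "task": task,
                            "target_coherence": minimum,
                            "congruent": bool(congruent),
                            "mean_accuracy": r.mean_accuracy,
                            "t": r.t,
                            "p": r.p,
                            "d": r.d,
                        }
                    )
            out["chance_tests"] = pd.DataFrame(chance_rows)
    elif experiment == "3":
        costs = ana.compute_costs(log, config)
        out["costs"] = costs.per_cell
        out["cost_summary"] = costs.summary()
        if multi:
            out["cost_significance"] = ana.cost_significance_summary(costs)
            sig = out["cost_significance"].set_index("cost")
            out["table4_flags"] = {
                cost: {
                    "short_csi_significant": bool(sig.loc[cost, "p_short"] < 0.05),
                    "long_csi_significant": bool(sig.loc[cost, "p_long"] < 0.05),
                    "preparatory_reduction_significant": bool(
                        sig.loc[cost, "p_preparatory_reduction"] < 0.05
                    ),
                }
                for cost in ana.CostTable.COST_COLUMNS
            }
            cells = ana.cell_summary(
                log,
                ["participant_id", "csi_ms", "sequence_type", "congruent"],
                config,
            )
            within = ["csi_ms", "sequence_type", "congruent"]
            out["rt_anova"] = ana.rm_anova(cells, "mean_log_rt", within).to_frame()
            cells["error_pct"] = 100.0 * (1.0 - cells["accuracy"])
            out["error_anova"] = ana.rm_anova(cells, "error_pct", within).to_frame()
            asym = ana.asymmetry_analysis(log, config)
            out["asymmetry_costs"] = asym.costs
            out["asymmetry_rt_anova"] = asym.rt_anova.to_frame()
            out["asymmetry_error_anova"] = asym.error_anova.to_frame()
    else:
        raise ValueError(f"unknown experiment {experiment!r}")

    if not multi:
        out["note"] = "single participant: group-level tests skipped"
    if n_participants < 10:
        out["warning"] = f"low power: only {n_participants} participants"
    return out


def _write_results(results: dict, out_dir: Path, prefix: str, stamp: str) -> dict:
    paths = {}
    report_extras = {}
    for name, value in results.items():
        if isinstance(value, pd.DataFrame):
            path = out_dir / f"{prefix}_{name}.csv"
            with path.open("w") as fh:
                fh.write(f"# config {stamp}\n")
                value.to_csv(fh, index=False)
            paths[name] = str(path)
        else:
            report_extras[name] = value
    return {"paths": paths, "report": report_extras}


def run_full_study(config: RunConfig = RunConfig()) -> dict:
    """Generate, simulate and analyze the configured experiments.

    Fully deterministic given ``config``; returns the run report (also
    written to ``out_dir/report.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = config_hash(config)
    report_path = out_dir / "report.json"
    if report_path.exists():
        previous = json.loads(report_path.read_text())
        if previous.get("config_hash") != stamp:
            raise RuntimeError(
                f"{out_dir} holds results from a different configuration "
                f"({previous.get('config_hash')} != {stamp}); refusing to mix"
            )
    report: dict = {"config_hash": stamp, "seed": config.seed, "experiments": {}}

    for experiment in config.experiments:
        n = (
            config.n_participants_switch
            if experiment == "3"
            else config.n_participants_single
        )
        try:
            log = build_study_log(
                experiment, n, config.seed, config.observer, config.dt_ms
            )
            log_path = out_dir / f"exp{experiment}_log.csv"
            write_trial_log(log, log_path, extra_header=f"config {stamp}")
            results = analyze_log(log, experiment)
        except Exception as exc:  # noqa: BLE001 — surface the failing stage
            raise RuntimeError(
                f"experiment {experiment} failed (seed {config.seed}): {exc}"
            ) from exc
        written = _write_results(results, out_dir, f"exp{experiment}", stamp)
        entry = {
            "n_participants": n,
            "log": str(log_path),
            "tables": written["paths"],
        }
        entry.update(
            {k: v for k, v in written["report"].items() if k != "experiment"}
        )
        report["experiments"][experiment] = entry
    report_path.write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report
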