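"""Statistical pipeline for RSK trial logs.

Implements the study's analysis chain:

1. cleaning — drop trials faster than 200 ms and the first trial of each
   block; errors (and timeouts, scored as errors) are additionally excluded
   from RT analyses;
2. transforms — natural-log RTs and arcsine-square-root accuracies, with
   back-transforms for descriptive reporting (back-transformed mean log RT is
   the geometric mean);
3. target/distractor multiple regression per task (standardized OLS on
   observations aggregated per participant x unique stimulus);
4. switch / mixing / error cost estimation per participant x CSI x
   congruency cell;
5. repeated-measures ANOVA for arbitrary fully-crossed within designs, with
   Greenhouse-Geisser epsilon and partial eta squared;
6. one-tailed one-sample chance-level tests;
7. the switch-cost asymmetry decomposition by switch direction and previous
   congruency.

Accuracy proportions are computed per cell *before* the arcsine transform
(trial-level 0/1 arcsine is degenerate).  Cost differences use raw error
percentages; the omnibus ANOVAs can be run on either scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .design import (
    COLOR,
    MOTION,
    ResponseMapping,
    attach_previous_congruency,
    signed_distractor_congruence,
)

__all__ = [
    "CleaningConfig",
    "SchemaError",
    "clean_trials",
    "transform_rt",
    "back_transform_rt",
    "transform_acc",
    "back_transform_acc",
    "cell_summary",
    "RegressionResult",
    "regress_target_distractor",
    "CostTable",
    "compute_costs",
    "EffectResult",
    "AnovaResult",
    "rm_anova",
    "ChanceTestResult",
    "chance_level_test",
    "AsymmetryResult",
    "asymmetry_analysis",
    "cost_significance_summary",
    "bonferroni_pairwise",
]

_REQUIRED_COLUMNS = [
    "participant_id",
    "block_index",
    "trial_index",
    "task",
    "sequence_type",
    "correct_response",
    "response",
    "rt_ms",
    "correct",
]


class SchemaError(ValueError):
    """A trial log is missing required columns."""


@dataclass(frozen=True)
class CleaningConfig:
    """Trial-exclusion rules applied before any statistic."""

    min_rt_ms: float = 200.0
    drop_block_first: bool = True
    errors_excluded_from_rt: bool = True
    timeouts_as_errors: bool = True

    def __post_init__(self) -> None:
        if self.min_rt_ms < 0:
            raise ValueError("min_rt_ms must be non-negative")


def clean_trials(
    log: pd.DataFrame, config: CleaningConfig = CleaningConfig()
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Split a raw trial log into RT and accuracy analysis sets.

    Returns ``(rt_log, accuracy_log, report)``.  Both sets exclude
    anticipations (RT below ``min_rt_ms``) and block-first trials.  The
    accuracy set keeps errors and timeouts (scored as errors); the RT set
    further drops them.  The exclusion filters commute, so the retained sets
    do not depend on application order.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in log.columns]
    if missing:
        raise SchemaError(f"trial log is missing columns: {missing}")

    timeout = log["response"].isna()
    fast = log["rt_ms"].notna() & (log["rt_ms"] < config.min_rt_ms)
    block_first = (
        (log["trial_index"] == 0)
        if config.drop_block_first
        else pd.Series(False, index=log.index)
    )

    keep = ~fast & ~block_first
    acc_log = log[keep].copy()
    if config.timeouts_as_errors:
        acc_log.loc[timeout[keep].values, "correct"] = False
    acc_log["correct"] = acc_log["correct"].astype("boolean").fillna(False)

    rt_keep = keep & ~timeout
    if config.errors_excluded_from_rt:
        correct = log["correct"].astype("boolean").fillna(False)
        rt_keep &= correct.astype(bool)
    rt_log = log[rt_keep].copy()

    report = {
        "n_input": int(len(log)),
        "n_fast": int(fast.sum()),
        "n_block_first": int((block_first & ~fast).sum()),
        "n_timeout": int((timeout & keep).sum()),
        "n_error_excluded_from_rt": int((keep & ~timeout & ~rt_keep).sum()),
        "n_accuracy": int(len(acc_log)),
        "n_rt": int(len(rt_log)),
    }
    return rt_log, acc_log, report


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def transform_rt(rt_ms):
    """Natural log of RT; requires positive RTs."""
    rt = np.asarray(rt_ms, dtype=float)
    if np.any(rt[~np.isnan(rt)] <= 0):
        raise ValueError("RTs must be positive")
    return np.log(rt)


def back_transform_rt(log_rt):
    return np.exp(np.asarray(log_rt, dtype=float))


def transform_acc(p):
    """Variance-stabilizing arcsine-square-root transform of a proportion."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr[~np.isnan(p_arr)] < 0) | (p_arr[~np.isnan(p_arr)] > 1)):
        raise ValueError("proportions must be in [0, 1]")
    return np.arcsin(np.sqrt(p_arr))


def back_transform_acc(x):
    return np.sin(np.asarray(x, dtype=float)) ** 2


def _geometric_mean_rt(series: pd.Series) -> float:
    return float(np.exp(np.mean(np.log(series.to_numpy(dtype=float)))))


def cell_summary(
    log: pd.DataFrame,
    by: Sequence[str],
    config: CleaningConfig = CleaningConfig(),
) -> pd.DataFrame:
    """Per-cell descriptives: n, mean log RT, geometric-mean RT, accuracy.

    RT descriptives come from the RT set, accuracy from the accuracy set; the
    back-transformed mean log RT equals the geometric mean of retained RTs.
    """
    rt_log, acc_log, _ = clean_trials(log, config)
    by = list(by)
    rt = (
        rt_log.groupby(by, dropna=False, observed=True)["rt_ms"]
        .agg(n_rt="size", mean_log_rt=lambda s: float(np.mean(np.log(s))))
        .reset_index()
    )
    rt["rt_ms"] = back_transform_rt(rt["mean_log_rt"])
    acc = (
        acc_log.groupby(by, dropna=False, observed=True)["correct"]
        .agg(n="size", accuracy="mean")
        .reset_index()
    )
    acc["arcsine_accuracy"] = transform_acc(acc["accuracy"].astype(float))
    return acc.merge(rt, on=by, how="left")


# ---------------------------------------------------------------------------
# target / distractor regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """Standardized OLS fit of an outcome on target and distractor predictors."""

    outcome: str
    task: str
    coefficients: pd.DataFrame  # index: predictor; columns: beta, t, p
    f_value: float
    df_model: int
    df_resid: int
    p_value: float
    adj_r_squared: float
    r_squared: float
    nobs: int
    #: standardized design matrix (constant, target, distractor) and outcome,
    #: kept so fits can be re-derived or residuals inspected
    design: np.ndarray | None = None
    outcome_values: np.ndarray | None = None
    params: np.ndarray | None = None


_STIMULUS_KEYS = ["motion_coherence", "direction", "color_coherence", "majority_color"]


def regress_target_distractor(
    log: pd.DataFrame,
    task: str,
    outcome: str = "rt",
    config: CleaningConfig = CleaningConfig(),
    mapping: ResponseMapping = ResponseMapping(),
) -> RegressionResult:
    """Multiple regression of performance on target coherence and signed
    distractor congruence for one task.

    Observations are aggregated per participant x unique stimulus: mean log
    RT (RT outcome) or the arcsine-transformed proportion correct (accuracy
    outcome).  Outcome and predictors are z-scored, so the reported slopes
    are standardized betas.
    """
    if outcome not in ("rt", "accuracy"):
        raise ValueError("outcome must be 'rt' or 'accuracy'")
    rt_log, acc_log, _ = clean_trials(log, config)
    source = (rt_log if outcome == "rt" else acc_log).query("task == @task")
    keys = ["participant_id"] + _STIMULUS_KEYS
    if outcome == "rt":
        cells = (
            source.assign(_y=lambda d: np.log(d["rt_ms"].astype(float)))
            .groupby(keys, observed=True)["_y"]
            .mean()
            .reset_index()
        )
    else:
        cells = (
            source.groupby(keys, observed=True)["correct"]
            .mean()
            .reset_index()
            .rename(columns={"correct": "_p"})
        )
        cells["_y"] = transform_acc(cells["_p"].astype(float))
    cells["task"] = task
    cells["target"] = 100.0 * (
        cells["motion_coherence"] if task == MOTION else cells["color_coherence"]
    )
    cells["distractor"] = [
        signed_distractor_congruence(row, mapping) for _, row in cells.iterrows()
    ]

    def z(x):
        x = np.asarray(x, dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise np.linalg.LinAlgError("constant predictor: design is rank deficient")
        return (x - x.mean()) / sd

    X = sm.add_constant(
        np.column_stack([z(cells["target"]), z(cells["distractor"])])
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    fit = sm.OLS(z(cells["_y"]), X).fit()
    coefficients = pd.DataFrame(
        {
            "beta": fit.params[1:],
            "t": fit.tvalues[1:],
            "p": fit.pvalues[1:],
        },
        index=["target_coherence", "distractor_congruence"],
    )
    return RegressionResult(
        outcome=outcome,
        task=task,
        coefficients=coefficients,
        f_value=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
        adj_r_squared=float(fit.rsquared_adj),
        r_squared=float(fit.rsquared),
        nobs=int(fit.nobs),
        design=X,
        outcome_values=np.asarray(fit.model.endog, dtype=float),
        params=np.asarray(fit.params, dtype=float),
    )


# ---------------------------------------------------------------------------
# switch / mixing costs
# ---------------------------------------------------------------------------


@dataclass
class CostTable:
    """Per participant x CSI x congruency switch and mixing costs.

    ``per_cell`` columns: participant_id, csi_ms, congruent, switch_cost_ms,
    error_cost_pct, rt_mixing_cost_ms, er_mixing_cost_pct.  Costs are
    switch - repeat and repeat - single differences of cell geometric-mean
    RTs (ms) and raw error percentages.  Cells with no retained trials yield
    NaN and are listed in ``missing_cells``.
    """

    per_cell: pd.DataFrame
    missing_cells: list = field(default_factory=list)

    COST_COLUMNS = (
        "switch_cost_ms",
        "error_cost_pct",
        "rt_mixing_cost_ms",
        "er_mixing_cost_pct",
    )

    def per_participant_by_csi(self) -> pd.DataFrame:
        """Costs averaged over congruency, one row per participant x CSI."""
        return (
            self.per_cell.groupby(["participant_id", "csi_ms"], observed=True)[
                list(self.COST_COLUMNS)
            ]
            .mean()
            .reset_index()
        )

    def summary(self) -> pd.DataFrame:
        """Across-participant mean and SD of each cost, per CSI."""
        by_csi = self.per_participant_by_csi()
        return (
            by_csi.groupby("csi_ms")[list(self.COST_COLUMNS)]
            .agg(["mean", "std"])
            .reset_index()
        )


def _rt_cells(rt_log: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    return (
        rt_log.groupby(by, observed=True)["rt_ms"]
        .apply(_geometric_mean_rt)
        .rename("rt")
        .reset_index()
    )


def _error_cells(acc_log: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    return (
        acc_log.groupby(by, observed=True)["correct"]
        .apply(lambda s: 100.0 * (1.0 - float(s.astype(float).mean())))
        .rename("error_pct")
        .reset_index()
    )


def compute_costs(
    log: pd.DataFrame, config: CleaningConfig = CleaningConfig()
) -> CostTable:
    """Switch, error and mixing costs from a task-switching trial log.

    The log is cleaned, cell means are formed per participant x CSI x
    congruency x sequence type (geometric-mean RT; raw error percentage), and
    the two differences are taken: switch - repeat (switch cost, error cost)
    and repeat - single (RT- and ER-mixing costs).
    """
    log = log.copy()
    log["congruent"] = log["congruent"].astype("boolean")
    rt_log, acc_log, _ = clean_trials(log, config)
    by = ["participant_id", "csi_ms", "congruent", "sequence_type"]
    rt = _rt_cells(rt_log, by)
    err = _error_cells(acc_log, by)
    cells = rt.merge(err, on=by, how="outer")

    wide = cells.pivot_table(
        index=["participant_id", "csi_ms", "congruent"],
        columns="sequence_type",
        values=["rt", "error_pct"],
        observed=True,
    )
    missing = [
        (idx, measure, seq)
        for (measure, seq) in wide.columns
        for idx in wide.index[wide[(measure, seq)].isna()]
    ]
    out = pd.DataFrame(index=wide.index)
    out["switch_cost_ms"] = wide[("rt", "switch")] - wide[("rt", "repeat")]
    out["error_cost_pct"] = wide[("error_pct", "switch")] - wide[("error_pct", "repeat")]
    out["rt_mixing_cost_ms"] = wide[("rt", "repeat")] - wide[("rt", "single")]
    out["er_mixing_cost_pct"] = (
        wide[("error_pct", "repeat")] - wide[("error_pct", "single")]
    )
    return CostTable(per_cell=out.reset_index(), missing_cells=missing)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------


@dataclass
class EffectResult:
    F: float
    df1: int
    df2: int
    p: float
    epsilon: float
    df1_gg: float
    df2_gg: float
    p_gg: float
    eta_p_sq: float
    ss_effect: float
    ss_error: float


@dataclass
class AnovaResult:
    """Within-subject ANOVA table keyed by effect (factors joined with ':')."""

    effects: dict[str, EffectResult]
    n_subjects: int

    def __getitem__(self, key: str) -> EffectResult:
        return self.effects[key]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.effects.items():
            rows.append(
                {
                    "effect": name,
                    "F": e.F,
                    "df1": e.df1,
                    "df2": e.df2,
                    "p": e.p,
                    "epsilon": e.epsilon,
                    "p_gg": e.p_gg,
                    "eta_p_sq": e.eta_p_sq,
                }
            )
        return pd.DataFrame(rows)


def _orthonormal_parts(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal mean row (1 x k) and contrast rows ((k-1) x k)."""
    q, _ = np.linalg.qr(np.ones((k, 1)), mode="complete")
    basis = q.T
    mean_row = basis[:1]
    if mean_row[0, 0] < 0:  # fix the sign so the mean row is +1/sqrt(k)
        mean_row = -mean_row
    return mean_row, basis[1:]


def _rm_anova_wide(Y: np.ndarray, factor_levels: list[tuple[str, int]]) -> dict:
    """Core within-subject ANOVA on a wide (subjects x cells) matrix.

    Cells must be ordered as ``itertools.product`` over the factors in the
    given order.  Returns a dict of effect name -> EffectResult covering all
    main effects and interactions.
    """
    n, p = Y.shape
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 subjects")
    if p != int(np.prod([k for _, k in factor_levels])):
        raise ValueError("cell count does not match the factor grid")
    grand = Y.mean(axis=0)
    centered = Y - grand
    # numerical-zero threshold: sums of squares this far below the data's
    # total variation are rounding residue, not signal
    total_ss = float(np.sum((Y - Y.mean()) ** 2))
    zero_tol = total_ss * 1e-14 + 1e-300
    parts = {name: _orthonormal_parts(k) for name, k in factor_levels}
    results: dict[str, EffectResult] = {}
    names = [name for name, _ in factor_levels]
    for r in range(1, len(names) + 1):
        for subset in itertools.combinations(names, r):
            M = np.ones((1, 1))
            for name, _k in factor_levels:
                mean_row, contrasts = parts[name]
                M = np.kron(M, contrasts if name in subset else mean_row)
            df1 = M.shape[0]
            z_mean = M @ grand
            Z_centered = centered @ M.T  # (n, df1)
            ss_effect = float(n * np.sum(z_mean**2))
            ss_error = float(np.sum(Z_centered**2))
            if ss_effect < zero_tol:
                ss_effect = 0.0
            if ss_error < zero_tol:
                ss_error = 0.0
            df2 = (n - 1) * df1
            if ss_error > 0:
                F = (ss_effect / df1) / (ss_error / df2)
            else:
                F = 0.0 if ss_effect == 0 else np.inf
            p_unc = float(st.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
            if df1 > 1:
                S = np.cov(Z_centered, rowvar=False)
                tr = float(np.trace(S))
                tr2 = float(np.sum(S * S.T))
                eps = (tr**2) / (df1 * tr2) if tr2 > 0 else 1.0
                eps = float(np.clip(eps, 1.0 / df1, 1.0))
            else:
                eps = 1.0
            df1_gg, df2_gg = eps * df1, eps * df2
            p_gg = float(st.f.sf(F, df1_gg, df2_gg)) if np.isfinite(F) else 0.0
            denom = ss_effect + ss_error
            eta = ss_effect / denom if denom > 0 else 0.0
            results[":".join(subset)] = EffectResult(
                F=float(F),
                df1=df1,
                df2=df2,
                p=p_unc,
                epsilon=eps,
                df1_gg=df1_gg,
                df2_gg=df2_gg,
                p_gg=p_gg,
                eta_p_sq=float(eta),
                ss_effect=ss_effect,
                ss_error=ss_error,
            )
    return results


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "participant_id",
) -> AnovaResult:
    """Repeated-measures ANOVA over fully-crossed within-subject factors.

    ``data`` is tidy (one or more rows per subject x cell; duplicates are
    averaged).  Every subject must contribute every cell, otherwise a
    balanced-design error is raised.  Each effect is tested against its own
    subject-interaction error term; the Greenhouse-Geisser epsilon estimated
    from the effect's contrast covariance is always reported, with
    ``epsilon = 1`` for single-df effects.
    """
    within = list(within)
    levels = [sorted(data[f].dropna().unique().tolist()) for f in within]
    grid = pd.MultiIndex.from_product(levels, names=within)
    wide = data.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="mean", observed=True
    )
    if len(within) == 1:
        wide.columns = pd.MultiIndex.from_arrays([wide.columns], names=within)
    wide = wide.reindex(columns=grid)
    if wide.isna().any().any():
        n_missing = int(wide.isna().sum().sum())
        raise ValueError(
            f"unbalanced design: {n_missing} missing subject x cell values"
        )
    results = _rm_anova_wide(
        wide.to_numpy(dtype=float), [(f, len(l)) for f, l in zip(within, levels)]
    )
    return AnovaResult(effects=results, n_subjects=wide.shape[0])


def bonferroni_pairwise(
    data: pd.DataFrame,
    dv: str,
    factor: str,
    subject: str = "participant_id",
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise paired t-tests across a factor's levels.

    The family size is the number of pairwise comparisons among the levels.
    """
    wide = data.pivot_table(
        index=subject, columns=factor, values=dv, aggfunc="mean", observed=True
    )
    levels = list(wide.columns)
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for a, b in pairs:
        t, p = st.ttest_rel(wide[a], wide[b])
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "mean_diff": float((wide[a] - wide[b]).mean()),
                "t": float(t),
                "p": float(p),
                "p_bonferroni": float(min(1.0, p * len(pairs))),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chance-level test
# ---------------------------------------------------------------------------


@dataclass
class ChanceTestResult:
    mean_accuracy: float
    t: float
    p: float
    d: float
    n: int
    degenerate: bool = False


def chance_level_test(
    accuracies,
    chance: float = 0.5,
    transform: bool = False,
) -> ChanceTestResult:
    """One-tailed one-sample t-test of participant accuracies against chance.

    Tests the alternative "mean accuracy > chance".  With ``transform=True``
    both the accuracies and the chance value are arcsine-transformed first.
    Cohen's d is (mean - chance) / sd.  Zero-variance inputs are flagged as
    degenerate.
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 participants")
    target = chance
    values = acc
    if transform:
        values = transform_acc(acc)
        target = float(transform_acc(chance))
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        if mean == target:
            return ChanceTestResult(float(acc.mean()), 0.0, 0.5, 0.0, acc.size, True)
        sign = np.sign(mean - target)
        return ChanceTestResult(
            float(acc.mean()),
            float(sign * np.inf),
            0.0 if sign > 0 else 1.0,
            float(sign * np.inf),
            acc.size,
            True,
        )
    t, p = st.ttest_1samp(values, target, alternative="greater")
    return ChanceTestResult(
        mean_accuracy=float(acc.mean()),
        t=float(t),
        p=float(p),
        d=(mean - target) / sd,
        n=int(acc.size),
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# switch-cost asymmetry
# ---------------------------------------------------------------------------


@dataclass
class AsymmetryResult:
    """Switch and error costs by CSI x switch direction x previous congruency.

    ``costs`` columns: participant_id, csi_ms, switch_direction
    ('to_motion'/'to_color'), prev_congruent, switch_cost_ms, error_cost_pct.
    The two ANOVA tables test the 2x2x2 within design on each cost.
    """

    costs: pd.DataFrame
    rt_anova: AnovaResult
    error_anova: AnovaResult


def asymmetry_analysis(
    log: pd.DataFrame,
    config: CleaningConfig = CleaningConfig(),
) -> AsymmetryResult:
    """Decompose the switch cost by switch direction and previous congruency.

    Previous congruency is (re)attached from each trial's predecessor within
    its block before cleaning removes any trial; block-first trials have no
    defined predecessor and drop out of the factor.  Each switch cell is
    compared against the repeat trials of the same target task and CSI
    (direction-matched baseline).
    """
    log = attach_previous_congruency(log)
    log["congruent"] = log["congruent"].astype("boolean")
    rt_log, acc_log, _ = clean_trials(log, config)

    def cost_frame(frame: pd.DataFrame, value_from, value_name: str) -> pd.DataFrame:
        switches = frame[
            (frame["sequence_type"] == "switch")
            & frame["congruency_n_minus_1"].notna()
        ].copy()
        switches["prev_congruent"] = switches["congruency_n_minus_1"].astype(bool)
        sw = value_from(
            switches, ["participant_id", "csi_ms", "task", "prev_congruent"]
        )
        repeats = frame[frame["sequence_type"] == "repeat"]
        base = value_from(repeats, ["participant_id", "csi_ms", "task"]).rename(
            columns={sw.columns[-1]: "_baseline"}
        )
        merged = sw.merge(base, on=["participant_id", "csi_ms", "task"], how="left")
        merged[value_name] = merged[sw.columns[-1]] - merged["_baseline"]
        merged["switch_direction"] = "to_" + merged["task"].astype(str)
        return merged[
            ["participant_id", "csi_ms", "switch_direction", "prev_congruent", value_name]
        ]

    rt_costs = cost_frame(rt_log, _rt_cells, "switch_cost_ms")
    err_costs = cost_frame(acc_log, _error_cells, "error_cost_pct")
    costs = rt_costs.merge(
        err_costs,
        on=["participant_id", "csi_ms", "switch_direction", "prev_congruent"],
        how="outer",
    )
    within = ["csi_ms", "switch_direction", "prev_congruent"]
    rt_anova = rm_anova(costs, "switch_cost_ms", within)
    error_anova = rm_anova(costs, "error_cost_pct", within)
    return AsymmetryResult(costs=costs, rt_anova=rt_anova, error_anova=error_anova)


# ---------------------------------------------------------------------------
# cost significance summary (per-CSI tests and preparatory reduction)
# ---------------------------------------------------------------------------


def cost_significance_summary(cost_table: CostTable) -> pd.DataFrame:
    """Per-cost significance at each CSI plus the preparatory-reduction test.

    Each cost is tested against zero per CSI with a one-sample t-test across
    participants (costs averaged over congruency first); the preparatory
    reduction is the CSI main effect of the 2 (CSI) x 2 (Congruency)
    repeated-measures ANOVA on that cost.
    """
    by_csi = cost_table.per_participant_by_csi()
    csis = sorted(by_csi["csi_ms"].unique())
    rows = []
    for cost in CostTable.COST_COLUMNS:
        row: dict = {"cost": cost}
        for csi in csis:
            vals = by_csi.loc[by_csi["csi_ms"] == csi, cost].dropna()
            t, p = st.ttest_1samp(vals, 0.0)
            label = "short" if csi == min(csis) else "long"
            row[f"mean_{label}"] = float(vals.mean())
            row[f"p_{label}"] = float(p)
        anova = rm_anova(cost_table.per_cell, cost, ["csi_ms", "congruent"])
        row["p_preparatory_reduction"] = anova["csi_ms"].p_gg
        row["p_congruency"] = anova["congruent"].p_gg
        rows.append(row)
    return pd.DataFrame(rows)
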