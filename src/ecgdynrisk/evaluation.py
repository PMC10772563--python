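"""Model evaluation: time-varying AUROC, calibration, bootstrap, importance.

Discrimination is assessed per 90-day interval: among the rows at risk in
interval k, the time-specific AUROC is the probability that an event row
receives a higher predicted risk than a non-event row (ties get half
credit).  The unweighted mean and SD over valid intervals up to the horizon
(16 intervals = 48 months by default) summarise the model as the mean
time-varying AUROC.  Intervals with fewer than 2 events or 2 non-events are
flagged and excluded from the mean.

Uncertainty comes from a patient-level bootstrap (patients resampled with
replacement, all their rows together); calibration from the decile method;
feature attribution from permutation importance with 5 repeats per feature;
subgroup (fairness) analysis repeats the AUROC summary within caller-chosen
subpopulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_HORIZON_INTERVALS = 16  # 48 months of 90-day intervals
MIN_EVENTS = 2
MIN_NONEVENTS = 2


def time_specific_auroc(pred: np.ndarray, event: np.ndarray) -> float:
    """AUROC of one interval: P(p_case > p_control) + 1/2 P(tie).

    Computed from rank sums (Mann-Whitney); requires at least one event and
    one non-event row.
    """
    pred = np.asarray(pred, float)
    event = np.asarray(event, int)
    n1 = int(event.sum())
    n0 = event.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("interval needs at least one event and one non-event")
    ranks = rankdata(pred)
    u = ranks[event == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def interval_aurocs(
    rows: pd.DataFrame,
    pred_col: str = "pred",
    horizon: int = DEFAULT_HORIZON_INTERVALS,
    min_events: int = MIN_EVENTS,
    min_nonevents: int = MIN_NONEVENTS,
) -> pd.DataFrame:
    """Per-interval AUROC with at-risk/event counts; degenerate ones flagged.

    Returns a table with one row per interval k < horizon present in the
    data: n_at_risk, n_events, auroc (NaN when degenerate), valid flag.
    """
    recs = []
    for k, g in rows[rows["k"] < horizon].groupby("k"):
        d = g["event"].to_numpy(int)
        n1, n0 = int(d.sum()), int((1 - d).sum())
        valid = n1 >= min_events and n0 >= min_nonevents
        auc = time_specific_auroc(g[pred_col], d) if valid else np.nan
        recs.append(
            {"k": int(k), "n_at_risk": len(g), "n_events": n1,
             "auroc": auc, "valid": valid}
        )
    return pd.DataFrame(recs)


def mean_time_varying_auroc(per_interval: pd.DataFrame) -> tuple[float, float]:
    """Unweighted mean and SD of the valid time-specific AUROCs."""
    vals = per_interval.loc[per_interval["valid"], "auroc"].to_numpy(float)
    if vals.size == 0:
        raise ValueError("no valid intervals to average")
    return float(vals.mean()), float(vals.std(ddof=0))


def bootstrap_ci(
    rows: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile CI from a patient-level bootstrap.

    Unique patients are drawn with replacement; each draw carries all of the
    patient's rows.  ``statistic`` maps a row table to a scalar; draws where
    it is undefined (raises ValueError) are skipped.
    """
    pids = np.array(sorted(rows["patient_id"].unique()))
    if pids.size < 2:
        raise ValueError("bootstrap needs at least 2 patients")
    by_pid = {pid: g for pid, g in rows.groupby("patient_id")}
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        draw = rng.choice(pids, size=pids.size, replace=True)
        sample = pd.concat([by_pid[pid] for pid in draw], ignore_index=True)
        try:
            stats.append(statistic(sample))
        except ValueError:
            continue
    if not stats:
        raise ValueError("statistic undefined on every bootstrap sample")
    lo, hi = np.percentile(stats, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


def calibration_deciles(
    pred: np.ndarray, event: np.ndarray, n_groups: int = 10
) -> pd.DataFrame:
    """Decile calibration table: mean predicted risk vs observed event rate.

    Rows are ranked by predicted risk and cut at the decile quantiles of the
    prediction distribution, so tied predictions stay in one group (group
    counts then differ by the tie-group sizes; heavy ties can merge groups,
    the all-tied input degenerating to a single group).
    """
    pred = np.asarray(pred, float)
    event = np.asarray(event, int)
    if pred.size < n_groups:
        raise ValueError(f"need at least {n_groups} rows")
    edges = np.unique(np.quantile(pred, np.linspace(0, 1, n_groups + 1)[1:-1]))
    group = np.searchsorted(edges, pred, side="right")
    recs = []
    for gi in np.unique(group):
        m = group == gi
        recs.append(
            {"decile": int(gi), "n": int(m.sum()),
             "mean_pred": float(pred[m].mean()),
             "obs_rate": float(event[m].mean())}
        )
    return pd.DataFrame(recs)


def calibration_slope(table: pd.DataFrame) -> float:
    """OLS slope of observed event rate on mean predicted risk across groups."""
    x = table["mean_pred"].to_numpy(float)
    y = table["obs_rate"].to_numpy(float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("calibration slope needs >= 2 distinct groups")
    return float(np.polyfit(x, y, 1)[0])


def permutation_importance(
    forest,
    rows: pd.DataFrame,
    features: Sequence[str] | None = None,
    repeats: int = 5,
    seed: int = 0,
    horizon: int = DEFAULT_HORIZON_INTERVALS,
) -> pd.DataFrame:
    """Permutation importance against the mean time-varying AUROC.

    For each feature and repeat, the feature's column is shuffled across the
    test rows, predictions are recomputed, and the importance is the drop
    (baseline minus permuted mean time-varying AUROC).  Both latent and
    clinical features are eligible.  Returns one row per feature with the
    mean over ``repeats`` and the per-repeat values.
    """
    feats = list(features) if features is not None else list(forest.feature_cols)
    unknown = [f for f in feats if f not in rows.columns]
    if unknown:
        raise ValueError(f"unknown features {unknown}")
    base_rows = rows.assign(pred=forest.predict_proba(rows))
    baseline, _ = mean_time_varying_auroc(interval_aurocs(base_rows, horizon=horizon))
    rng = np.random.default_rng(seed)
    recs = []
    for f in feats:
        drops = []
        for _ in range(repeats):
            shuffled = rows.copy()
            shuffled[f] = rng.permutation(shuffled[f].to_numpy())
            shuffled["pred"] = forest.predict_proba(shuffled)
            m, _ = mean_time_varying_auroc(
                interval_aurocs(shuffled, horizon=horizon)
            )
            drops.append(baseline - m)
        recs.append(
            {"feature": f, "importance": float(np.mean(drops)),
             **{f"repeat_{i}": float(v) for i, v in enumerate(drops)}}
        )
    return pd.DataFrame(recs).sort_values(
        "importance", ascending=False, ignore_index=True
    )


def subgroup_performance(
    rows: pd.DataFrame,
    group_col: str,
    pred_col: str = "pred",
    horizon: int = DEFAULT_HORIZON_INTERVALS,
) -> pd.DataFrame:
    """Mean time-varying AUROC per subgroup, with sizes; degenerate flagged."""
    recs = []
    for val, g in rows.groupby(group_col):
        per = interval_aurocs(g, pred_col, horizon=horizon)
        try:
            m, s = mean_time_varying_auroc(per)
            flagged = False
        except ValueError:
            m, s, flagged = np.nan, np.nan, True
        recs.append(
            {group_col: val, "n_patients": g["patient_id"].nunique(),
             "n_rows": len(g), "mean_auroc": m, "sd_auroc": s,
             "degenerate": flagged}
        )
    return pd.DataFrame(recs)


@dataclass
class EvalReport:
    """Bundle of the evaluation outputs for one fitted model."""

    per_interval: pd.DataFrame
    mean_auroc: float
    sd_auroc: float
    calibration: pd.DataFrame | None = None
    bootstrap_ci_auroc: tuple[float, float] | None = None
    subgroups: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mean_auroc": self.mean_auroc,
            "sd_auroc": self.sd_auroc,
            "per_interval": self.per_interval.to_dict(orient="records"),
            "calibration": (
                self.calibration.to_dict(orient="records")
                if self.calibration is not None else None
            ),
            "bootstrap_ci_auroc": self.bootstrap_ci_auroc,
            "subgroups": {
                k: v.to_dict(orient="records") for k, v in self.subgroups.items()
            },
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate_model(
    forest,
    rows: pd.DataFrame,
    horizon: int = DEFAULT_HORIZON_INTERVALS,
    n_boot: int = 0,
    seed: int = 0,
    subgroup_cols: Sequence[str] = (),
) -> EvalReport:
    """Full evaluation of a fitted forest on (test) CPIU rows."""
    rows = rows.assign(pred=forest.predict_proba(rows))
    per = interval_aurocs(rows, horizon=horizon)
    mean_auc, sd_auc = mean_time_varying_auroc(per)
    cal = calibration_deciles(rows["pred"].to_numpy(), rows["event"].to_numpy())
    ci = None
    if n_boot > 0:
        def stat(sample: pd.DataFrame) -> float:
            m, _ = mean_time_varying_auroc(
                interval_aurocs(sample, horizon=horizon)
            )
            return m

        ci = bootstrap_ci(rows, stat, n_boot=n_boot, seed=seed)
    subgroups = {c: subgroup_performance(rows, c, horizon=horizon)
                 for c in subgroup_cols}
    return EvalReport(
        per_interval=per, mean_auroc=mean_auc, sd_auroc=sd_auc,
        calibration=cal, bootstrap_ci_auroc=ci, subgroups=subgroups,
    )


def plot_auroc_over_time(per_interval: pd.DataFrame, path: str | Path) -> None:
    """AUROC-vs-interval figure (one line, 95% band omitted when absent)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ok = per_interval[per_interval["valid"]]
    ax.plot(ok["k"] * 3, ok["auroc"], marker="o")
    ax.axhline(0.5, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("Follow-up (months)")
    ax.set_ylabel("Time-specific AUROC")
    ax.set_ylim(0.3, 1.0)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_calibration(table: pd.DataFrame, path: str | Path) -> None:
    """Decile calibration figure: observed vs predicted with identity line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(table["mean_pred"], table["obs_rate"], marker="o", ls="-")
    lim = max(table["mean_pred"].max(), table["obs_rate"].max()) * 1.1
    ax.plot([0, lim], [0, lim], color="grey", ls="--", lw=0.8)
    ax.set_xlabel("Mean predicted risk")
    ax.set_ylabel("Observed event rate")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
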