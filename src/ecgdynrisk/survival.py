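"""Person-period restructuring and the Poisson-splitting hazard forest.

The longitudinal record is partitioned into 90-day counting-process
information units (CPIUs): one row per patient-interval carrying the risk
time tau (<= 90 days), the event indicator, the static baseline covariates
and the latent ECG features in force at the interval start (last value
carried forward).  On these rows a random forest is grown whose split
criterion is the improvement in Poisson log-likelihood of event counts with
a log-risk-time offset, and whose leaves hold Bayes-shrunk hazard rates
lambda = (D + a) / (T + b) with prior mean equal to the marginal event rate.
Averaging leaf rates over trees yields a piecewise-constant hazard per
subject; 1 - exp(-lambda * tau) converts it to an interval event
probability.

A baseline-frozen comparator (the "static" model) runs the same machinery
with every patient's latent features pinned to their day-0 values, isolating
the contribution of the time-varying ECG information.  A time-varying Cox
model over the same counting-process rows is available for standard
inference (delegated to lifelines).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .vae import latent_names

INTERVAL_DAYS = 90

#: Baseline covariate columns are everything except these bookkeeping columns.
CPIU_META_COLS = (
    "patient_id", "k", "start_day", "tau", "event",
    "ecg_day", "ecg_age", "carried_forward",
)


# ---------------------------------------------------------------------------
# Feature table: imputation + encoding
# ---------------------------------------------------------------------------


@dataclass
class FeatureEncoder:
    """Fitted imputation/encoding state, tagged with its training patients.

    Columns with >= ``drop_threshold`` missing (measured on the training
    fold) are excluded; remaining continuous missing values are filled by
    iterative random-forest imputation fitted on the training fold only;
    categorical (object/category) columns are one-hot encoded and binary
    integer flags pass through; continuous columns are z-scored with
    training-fold statistics.
    """

    drop_threshold: float = 0.30
    rf_trees: int = 30
    max_iter: int = 5
    seed: int = 0
    # fitted state
    dropped: list[str] = field(default_factory=list)
    cont_cols: list[str] = field(default_factory=list)
    flag_cols: list[str] = field(default_factory=list)
    dummy_cols: list[str] = field(default_factory=list)
    means: dict[str, float] = field(default_factory=dict)
    stds: dict[str, float] = field(default_factory=dict)
    train_ids: frozenset = frozenset()
    _imputer: object | None = None

    def fit(self, baseline: pd.DataFrame, train_ids: Iterable[str]) -> "FeatureEncoder":
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer

        self.train_ids = frozenset(train_ids)
        tr = baseline[baseline["patient_id"].isin(self.train_ids)]
        if tr.empty:
            raise ValueError("no training patients found in baseline table")
        cols = [c for c in baseline.columns if c != "patient_id"]
        self.dropped = [
            c for c in cols if tr[c].isna().mean() >= self.drop_threshold
        ]
        kept = [c for c in cols if c not in self.dropped]
        cat = [c for c in kept if baseline[c].dtype == object
               or str(baseline[c].dtype) == "category"]
        num = [c for c in kept if c not in cat]
        # integer 0/1 flags are already one-hot; everything else is continuous
        self.flag_cols = [
            c for c in num
            if set(pd.unique(tr[c].dropna())) <= {0, 1}
        ]
        self.cont_cols = [c for c in num if c not in self.flag_cols]
        self.dummy_cols = []
        for c in cat:
            self.dummy_cols += [
                f"{c}={v}" for v in sorted(tr[c].dropna().unique().astype(str))
            ]
        num_all = self.cont_cols + self.flag_cols
        if any(tr[c].isna().all() for c in num_all):
            raise ValueError("a retained column is entirely missing in training data")
        self._imputer = IterativeImputer(
            estimator=RandomForestRegressor(
                n_estimators=self.rf_trees, random_state=self.seed, n_jobs=1
            ),
            max_iter=self.max_iter, random_state=self.seed,
            sample_posterior=False,
        )
        self._imputer.fit(tr[num_all].to_numpy(float))
        imputed = pd.DataFrame(
            self._imputer.transform(tr[num_all].to_numpy(float)),
            columns=num_all,
        )
        for c in self.cont_cols:
            self.means[c] = float(imputed[c].mean())
            sd = float(imputed[c].std(ddof=0))
            self.stds[c] = sd if sd > 0 else 1.0
        return self

    def transform(self, baseline: pd.DataFrame) -> pd.DataFrame:
        if self._imputer is None:
            raise RuntimeError("encoder must be fitted first")
        num_all = self.cont_cols + self.flag_cols
        out = pd.DataFrame({"patient_id": baseline["patient_id"].to_numpy()})
        imputed = pd.DataFrame(
            self._imputer.transform(baseline[num_all].to_numpy(float)),
            columns=num_all,
        )
        for c in self.cont_cols:
            out[c] = (imputed[c].to_numpy() - self.means[c]) / self.stds[c]
        for c in self.flag_cols:
            out[c] = np.round(imputed[c].to_numpy()).clip(0, 1)
        for dc in self.dummy_cols:
            c, v = dc.split("=", 1)
            col = baseline[c].astype(str).fillna("")
            out[dc] = (col == v).astype(float)
        return out

    @property
    def feature_cols(self) -> list[str]:
        return self.cont_cols + self.flag_cols + self.dummy_cols


def impute_and_encode(
    baseline: pd.DataFrame,
    train_ids: Iterable[str] | None = None,
    drop_threshold: float = 0.30,
    seed: int = 0,
) -> tuple[pd.DataFrame, FeatureEncoder]:
    """Fit the encoder on ``train_ids`` (default: everyone) and transform all."""
    ids = list(train_ids) if train_ids is not None else list(baseline["patient_id"])
    enc = FeatureEncoder(drop_threshold=drop_threshold, seed=seed).fit(baseline, ids)
    return enc.transform(baseline), enc


def split_cohort(
    patient_ids: Sequence[str],
    ratio: float = 0.8,
    seed: int = 0,
    stratify: Mapping[str, int] | None = None,
) -> tuple[list[str], list[str]]:
    """Patient-level train/test split (all of a patient's rows stay together).

    With ``stratify`` (patient -> label, e.g. the event indicator) the split
    is performed within each label group so fold event rates stay close.
    """
    ids = list(patient_ids)
    if len(ids) < 5:
        raise ValueError("need at least 5 patients to split")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    if stratify is None:
        groups = [ids]
    else:
        by: dict[int, list[str]] = {}
        for pid in ids:
            by.setdefault(int(stratify[pid]), []).append(pid)
        groups = list(by.values())
    for grp in groups:
        perm = rng.permutation(len(grp))
        n_train = int(round(ratio * len(grp)))
        train += [grp[i] for i in perm[:n_train]]
        test += [grp[i] for i in perm[n_train:]]
    return sorted(train), sorted(test)


# ---------------------------------------------------------------------------
# CPIU construction
# ---------------------------------------------------------------------------


def build_cpius(
    outcomes: pd.DataFrame,
    codes: pd.DataFrame,
    baseline_features: pd.DataFrame | None = None,
    interval: int = INTERVAL_DAYS,
) -> pd.DataFrame:
    """Partition each patient's follow-up into person-period rows.

    ``codes`` is a tidy latent table (patient_id, day, AE0..); features for
    interval k are those of the most recent ECG with day <= k*interval (last
    value carried forward — no within-interval look-ahead).  The final row's
    risk time is the remainder of follow-up; an event or censoring exactly
    at an interval boundary closes the previous interval (no zero-length
    rows).  ``baseline_features`` (patient_id + encoded covariates) are
    merged onto every row when given.
    """
    lat_cols = [c for c in codes.columns if c.startswith("AE")]
    if not lat_cols:
        raise ValueError("codes table has no AE* latent columns")
    rows = []
    codes = codes.sort_values(["patient_id", "day"])
    grouped = {pid: g for pid, g in codes.groupby("patient_id")}
    for rec in outcomes.itertuples(index=False):
        pid = rec.patient_id
        end = float(rec.event_day) if rec.event == 1 else float(rec.fu_days)
        if pid not in grouped:
            raise ValueError(f"patient {pid} has no latent codes")
        g = grouped[pid]
        days = g["day"].to_numpy(float)
        if days.min() > 0:
            raise ValueError(f"patient {pid} lacks a day-0 latent code")
        if end <= 0:
            raise ValueError(f"patient {pid} has non-positive follow-up")
        n_full = int(end // interval)
        rem = end - n_full * interval
        ks = list(range(n_full)) + ([n_full] if rem > 0 else [])
        for k in ks:
            start = k * interval
            tau = interval if (k < n_full) else rem
            is_last = k == ks[-1]
            # LVCF: most recent ECG at or before the interval start
            j = int(np.searchsorted(days, start, side="right")) - 1
            ecg_day = float(days[j])
            row = {
                "patient_id": pid, "k": k, "start_day": float(start),
                "tau": float(tau), "event": int(rec.event) if is_last else 0,
                "ecg_day": ecg_day, "ecg_age": float(start - ecg_day),
                "carried_forward": bool(k > 0 and ecg_day <= (k - 1) * interval),
            }
            for c in lat_cols:
                row[c] = float(g[c].to_numpy()[j])
            rows.append(row)
    df = pd.DataFrame(rows)
    if baseline_features is not None:
        df = df.merge(baseline_features, on="patient_id", how="left")
    return df


def cpiu_feature_cols(rows: pd.DataFrame) -> list[str]:
    """All model features of a CPIU table (baseline + latent, no bookkeeping)."""
    return [c for c in rows.columns if c not in CPIU_META_COLS]


def freeze_baseline_features(
    rows: pd.DataFrame, cols: Sequence[str] | None = None
) -> pd.DataFrame:
    """Replace time-varying columns by each patient's interval-0 values.

    Default columns are the AE* latents; the result feeds the static
    comparator so that it sees only implantation-time ECG information.
    """
    cols = list(cols) if cols is not None else [
        c for c in rows.columns if c.startswith("AE")
    ]
    out = rows.copy()
    first = rows[rows["k"] == 0].set_index("patient_id")
    for c in cols:
        out[c] = first.loc[out["patient_id"], c].to_numpy()
    out[["ecg_day", "ecg_age"]] = 0.0
    out["carried_forward"] = out["k"] > 0
    return out


# ---------------------------------------------------------------------------
# Poisson splitting
# ---------------------------------------------------------------------------


def _poisson_term(d, t):
    """D * log(D / T) with the 0 * log 0 = 0 convention, vectorised."""
    d = np.asarray(d, float)
    t = np.asarray(t, float)
    return np.where(d > 0, d * (np.log(np.maximum(d, 1e-300)) - np.log(t)), 0.0)


def poisson_split_gain(
    events: np.ndarray, risktime: np.ndarray, left_mask: np.ndarray
) -> float:
    """Poisson log-likelihood improvement of one candidate split.

    Profile log-likelihood of the event counts with log-risk-time offset:
    gain = sum_children D_c log(D_c/T_c) - D log(D/T).  Non-negative for
    every admissible split; both children must carry positive risk time.
    """
    events = np.asarray(events, float)
    risktime = np.asarray(risktime, float)
    left_mask = np.asarray(left_mask, bool)
    dl, tl = events[left_mask].sum(), risktime[left_mask].sum()
    dr, tr = events[~left_mask].sum(), risktime[~left_mask].sum()
    if tl <= 0 or tr <= 0:
        raise ValueError("both children must have positive risk time")
    d, t = dl + dr, tl + tr
    return float(_poisson_term(dl, tl) + _poisson_term(dr, tr) - _poisson_term(d, t))


@dataclass
class _Tree:
    feature: np.ndarray   # -1 marks a leaf
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray     # leaf hazard per day

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if idx.size == 0:
                continue
            f = self.feature[node]
            if f < 0:
                out[idx] = self.value[node]
                continue
            go_left = X[idx, f] <= self.threshold[node]
            stack.append((self.left[node], idx[go_left]))
            stack.append((self.right[node], idx[~go_left]))
        return out


@dataclass
class Hyperparams:
    """Forest hyperparameters (grid-searchable)."""

    n_trees: int = 300
    mtry: int | None = None          # default sqrt(p)
    min_node_events: int = 5         # nodes with fewer events become leaves
    min_node_rows: int = 10
    max_depth: int = 20
    prior_b: float = 90.0            # prior pseudo risk time (one CPIU)
    max_thresholds: int = 32

    def resolve_mtry(self, p: int) -> int:
        return self.mtry if self.mtry else max(int(np.sqrt(p)), 1)


class HazardForest:
    """Ensemble of Poisson-split trees with Bayes leaf hazard rates.

    Trees are grown on patient-level bootstrap resamples (all of a patient's
    CPIU rows enter together).  Each leaf stores
    lambda = (D + a) / (T + b) with a = r0 * b, r0 the bootstrap-sample
    marginal event rate, so the prior mean equals the marginal hazard and
    ``prior_b`` sets its weight in risk-time units.
    """

    def __init__(self, hyper: Hyperparams, feature_cols: Sequence[str], seed: int = 0):
        self.hyper = hyper
        self.feature_cols = list(feature_cols)
        self.seed = seed
        self.trees: list[_Tree] = []
        self.root_rate_: float | None = None
        self.train_patients_: frozenset = frozenset()

    # -- growing ------------------------------------------------------------

    def _grow_tree(self, X, d, tau, rng) -> _Tree:
        hp = self.hyper
        mtry = hp.resolve_mtry(X.shape[1])
        r0 = d.sum() / tau.sum()
        a, b = r0 * hp.prior_b, hp.prior_b
        feature, threshold, left, right, value = [], [], [], [], []

        def new_node():
            feature.append(-1)
            threshold.append(0.0)
            left.append(-1)
            right.append(-1)
            value.append(0.0)
            return len(feature) - 1

        def grow(idx: np.ndarray, depth: int) -> int:
            node = new_node()
            D, T = d[idx].sum(), tau[idx].sum()
            split = None
            if (
                depth < hp.max_depth
                and D >= hp.min_node_events
                and idx.size >= hp.min_node_rows
            ):
                split = self._best_split(X, d, tau, idx, mtry, rng)
            if split is None:
                value[node] = (D + a) / (T + b)
                return node
            f, thr = split
            go_left = X[idx, f] <= thr
            feature[node] = f
            threshold[node] = thr
            left[node] = grow(idx[go_left], depth + 1)
            right[node] = grow(idx[~go_left], depth + 1)
            return node

        grow(np.arange(X.shape[0]), 0)
        return _Tree(
            feature=np.array(feature), threshold=np.array(threshold),
            left=np.array(left), right=np.array(right), value=np.array(value),
        )

    def _best_split(self, X, d, tau, idx, mtry, rng):
        hp = self.hyper
        D, T = d[idx].sum(), tau[idx].sum()
        parent = _poisson_term(D, T)
        best_gain, best = 1e-10, None
        feats = rng.choice(X.shape[1], size=min(mtry, X.shape[1]), replace=False)
        for f in feats:
            x = X[idx, f]
            order = np.argsort(x, kind="stable")
            xs = x[order]
            pos = np.nonzero(xs[:-1] < xs[1:])[0]
            if pos.size == 0:
                continue
            if pos.size > hp.max_thresholds:
                pos = pos[
                    np.linspace(0, pos.size - 1, hp.max_thresholds).astype(int)
                ]
            dcum = np.cumsum(d[idx][order])
            tcum = np.cumsum(tau[idx][order])
            DL, TL = dcum[pos], tcum[pos]
            DR, TR = D - DL, T - TL
            with np.errstate(divide="ignore", invalid="ignore"):
                gain = _poisson_term(DL, TL) + _poisson_term(DR, TR) - parent
            gain[(TL <= 0) | (TR <= 0)] = -np.inf
            j = int(np.argmax(gain))
            if gain[j] > best_gain:
                best_gain = float(gain[j])
                best = (int(f), float((xs[pos[j]] + xs[pos[j] + 1]) / 2.0))
        return best

    def fit(self, rows: pd.DataFrame, seed: int | None = None) -> "HazardForest":
        """Grow the forest on a CPIU table; needs at least one event."""
        seed = self.seed if seed is None else seed
        X = rows[self.feature_cols].to_numpy(float)
        d = rows["event"].to_numpy(float)
        tau = rows["tau"].to_numpy(float)
        if rows.empty or d.sum() == 0:
            raise ValueError("cannot fit a hazard forest without events")
        pids = rows["patient_id"].to_numpy()
        uniq = np.unique(pids)
        by_pid = {pid: np.nonzero(pids == pid)[0] for pid in uniq}
        self.root_rate_ = float(d.sum() / tau.sum())
        self.train_patients_ = frozenset(uniq.tolist())
        root = np.random.SeedSequence(seed)
        streams = root.spawn(self.hyper.n_trees)
        self.trees = []
        for s in streams:
            rng = np.random.default_rng(s)
            boot = rng.choice(uniq, size=uniq.size, replace=True)
            bidx = np.concatenate([by_pid[pid] for pid in boot])
            if d[bidx].sum() == 0:  # resample until the bootstrap has events
                continue
            self.trees.append(self._grow_tree(X[bidx], d[bidx], tau[bidx], rng))
        if not self.trees:
            raise ValueError("no tree could be grown (no events in bootstraps)")
        return self

    # -- prediction ---------------------------------------------------------

    def predict_hazard(self, rows: pd.DataFrame) -> np.ndarray:
        """Per-row hazard per day: mean of leaf rates across trees."""
        missing = [c for c in self.feature_cols if c not in rows.columns]
        if missing:
            raise ValueError(f"feature schema mismatch; missing {missing}")
        X = rows[self.feature_cols].to_numpy(float)
        out = np.zeros(X.shape[0])
        for tree in self.trees:
            out += tree.predict(X)
        return out / len(self.trees)

    def predict_proba(
        self, rows: pd.DataFrame, planned_tau: float = float(INTERVAL_DAYS)
    ) -> np.ndarray:
        """Interval event probability 1 - exp(-lambda * tau)."""
        lam = self.predict_hazard(rows)
        return 1.0 - np.exp(-lam * planned_tau)

    def to_header(self) -> dict:
        return {
            "n_trees": len(self.trees),
            "feature_cols": self.feature_cols,
            "hyperparams": self.hyper.__dict__,
            "seed": self.seed,
            "root_rate": self.root_rate_,
        }

    # -- persistence (NPZ tree arrays + JSON hyperparameter header) ---------

    def save(self, path) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        arrays = {}
        for i, t in enumerate(self.trees):
            arrays[f"t{i}_feature"] = t.feature
            arrays[f"t{i}_threshold"] = t.threshold
            arrays[f"t{i}_left"] = t.left
            arrays[f"t{i}_right"] = t.right
            arrays[f"t{i}_value"] = t.value
        np.savez(path.with_suffix(".npz"), **arrays)
        header = self.to_header()
        header["train_patients"] = sorted(self.train_patients_)
        path.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, path) -> "HazardForest":
        import json
        from pathlib import Path

        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        hyper = Hyperparams(**header["hyperparams"])
        forest = cls(hyper, header["feature_cols"], header["seed"])
        forest.root_rate_ = header["root_rate"]
        forest.train_patients_ = frozenset(header.get("train_patients", []))
        data = np.load(path.with_suffix(".npz"))
        forest.trees = [
            _Tree(
                feature=data[f"t{i}_feature"], threshold=data[f"t{i}_threshold"],
                left=data[f"t{i}_left"], right=data[f"t{i}_right"],
                value=data[f"t{i}_value"],
            )
            for i in range(header["n_trees"])
        ]
        return forest


def fit_hazard_forest(
    rows: pd.DataFrame,
    hyper: Hyperparams | None = None,
    seed: int = 0,
    feature_cols: Sequence[str] | None = None,
) -> HazardForest:
    """Fit the dynamic hazard forest on CPIU rows."""
    hyper = hyper or Hyperparams()
    cols = list(feature_cols) if feature_cols is not None else cpiu_feature_cols(rows)
    return HazardForest(hyper, cols, seed).fit(rows)


def fit_static_model(
    rows: pd.DataFrame,
    hyper: Hyperparams | None = None,
    seed: int = 0,
    feature_cols: Sequence[str] | None = None,
) -> HazardForest:
    """Baseline-frozen comparator: same machinery, day-0 latents everywhere."""
    return fit_hazard_forest(freeze_baseline_features(rows), hyper, seed, feature_cols)


def predict_hazard(forest: HazardForest, rows: pd.DataFrame):
    """Convenience: (lambda per day, interval event probability) per row."""
    lam = forest.predict_hazard(rows)
    return lam, 1.0 - np.exp(-lam * INTERVAL_DAYS)


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------


def tune_hyperparams(
    rows: pd.DataFrame,
    grid: Sequence[Hyperparams] | None = None,
    seed: int = 0,
    n_folds: int = 5,
    feature_cols: Sequence[str] | None = None,
    horizon_intervals: int = 16,
) -> tuple[Hyperparams, pd.DataFrame]:
    """5-fold patient-wise CV over a hyperparameter grid.

    The selection criterion is the mean out-of-fold time-varying AUROC; ties
    break toward smaller forests (fewer trees, then larger terminal nodes).
    Returns the winning configuration and the full CV table.
    """
    from .evaluation import interval_aurocs, mean_time_varying_auroc

    if grid is None:
        p = len(feature_cols or cpiu_feature_cols(rows))
        grid = [
            Hyperparams(n_trees=nt, mtry=mt, min_node_events=ev)
            for nt in (100, 300)
            for mt in (max(int(np.sqrt(p)), 1), max(p // 3, 1))
            for ev in (5, 15)
        ]
    if not grid:
        raise ValueError("grid must be non-empty")
    cols = list(feature_cols) if feature_cols is not None else cpiu_feature_cols(rows)
    pids = np.array(sorted(rows["patient_id"].unique()))
    rng = np.random.default_rng(seed)
    fold_of = dict(zip(pids[rng.permutation(pids.size)],
                       np.arange(pids.size) % n_folds))
    records = []
    for gi, hp in enumerate(grid):
        scores = []
        for fold in range(n_folds):
            val_ids = {pid for pid, f in fold_of.items() if f == fold}
            tr = rows[~rows["patient_id"].isin(val_ids)]
            va = rows[rows["patient_id"].isin(val_ids)]
            if tr["event"].sum() == 0 or va["event"].sum() == 0:
                continue
            forest = HazardForest(hp, cols, seed).fit(tr)
            va = va.assign(pred=forest.predict_proba(va))
            per = interval_aurocs(va, "pred", horizon=horizon_intervals)
            try:
                m, _ = mean_time_varying_auroc(per)
            except ValueError:
                continue
            scores.append(m)
        records.append(
            {"grid_index": gi, "mean_cv_auroc": float(np.mean(scores)) if scores
             else np.nan, "n_folds_used": len(scores), **hp.__dict__}
        )
    table = pd.DataFrame(records)
    ranked = table.sort_values(
        ["mean_cv_auroc", "n_trees", "min_node_events"],
        ascending=[False, True, False],
    )
    best = grid[int(ranked.iloc[0]["grid_index"])]
    return best, table


# ---------------------------------------------------------------------------
# Time-varying Cox regression (delegated to lifelines)
# ---------------------------------------------------------------------------


def fit_time_varying_cox(
    rows: pd.DataFrame,
    feature_cols: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cox model with time-varying covariates on counting-process rows.

    CPIU rows are mapped to (start, stop, event] episodes and fit with
    lifelines' ``CoxTimeVaryingFitter``.  Returns one row per covariate with
    the hazard ratio, its confidence interval and the p-value.
    Non-convergence surfaces as an error rather than being ignored.
    """
    from lifelines import CoxTimeVaryingFitter
    from lifelines.exceptions import ConvergenceError

    cols = list(feature_cols) if feature_cols is not None else cpiu_feature_cols(rows)
    df = rows[["patient_id", "start_day", "tau", "event", *cols]].copy()
    df["stop_day"] = df["start_day"] + df["tau"]
    df = df.drop(columns="tau")
    ctv = CoxTimeVaryingFitter(alpha=alpha)
    try:
        ctv.fit(
            df, id_col="patient_id", event_col="event",
            start_col="start_day", stop_col="stop_day",
        )
    except ConvergenceError as err:
        raise RuntimeError(f"time-varying Cox model did not converge: {err}") from err
    summ = ctv.summary
    out = pd.DataFrame(
        {
            "covariate": summ.index,
            "hr": np.exp(summ["coef"]).to_numpy(),
            "hr_lower": np.exp(summ["coef lower 95%"]).to_numpy(),
            "hr_upper": np.exp(summ["coef upper 95%"]).to_numpy(),
            "p": summ["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out
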