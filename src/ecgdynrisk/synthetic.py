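"""Seed-reproducible synthetic cohort: ECGs, covariates, drift and events.

The generator provides everything the downstream pipeline consumes, with
known ground truth so that parameter recovery can be tested:

* 10-second 6-limb-lead ECGs built from a Gaussian-sum beat model for leads
  I and II (one Gaussian per P/Q/R/S/T wave), with the remaining limb leads
  derived through the Einthoven/Goldberger identities, plus additive noise
  and low-frequency baseline wander;
* per-patient morphology drift over follow-up as a Gaussian random walk on a
  90-day grid (T-wave amplitude, T-wave width, heart rate);
* a baseline covariate table mirroring a typical ICD-cohort roster, with
  missingness injected completely at random;
* event times drawn from a piecewise-constant hazard on the 90-day grid that
  depends on the current (drifted) morphology and on baseline covariates;
* an irregular ECG visit process with a guaranteed day-0 recording.

Arrhythmia waveforms themselves are never modelled — only event times.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_WINDOW, LIMB_LEADS, BeatTemplate, EcgRecording

WAVES = ("P", "Q", "R", "S", "T")

#: Interval of the piecewise-constant hazard grid, in days.
GRID_DAYS = 90


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------


@dataclass
class MorphologyParams:
    """Gaussian-sum beat morphology for leads I and II.

    Each of the five canonical waves (P, Q, R, S, T) is one Gaussian with an
    amplitude per lead (mV), a centre relative to the R peak (s) and a width
    (s); centres and widths are shared between the two measured leads.
    ``t_inversion`` multiplies the T amplitude in both leads (−1 flips it).
    """

    amps_i: dict[str, float]
    amps_ii: dict[str, float]
    centers: dict[str, float]
    widths: dict[str, float]
    heart_rate: float = 60.0
    t_inversion: float = 1.0

    def __post_init__(self) -> None:
        for name, d in (("amps_i", self.amps_i), ("amps_ii", self.amps_ii),
                        ("centers", self.centers), ("widths", self.widths)):
            missing = set(WAVES) - set(d)
            if missing:
                raise ValueError(f"{name} missing waves {sorted(missing)}")
        if any(self.widths[w] <= 0 for w in WAVES):
            raise ValueError("wave widths must be positive")
        if self.amps_ii["R"] <= 0 or self.amps_i["R"] <= 0:
            raise ValueError("R amplitude must be positive")
        c = [self.centers[w] for w in WAVES]
        if not all(a < b for a, b in zip(c, c[1:])):
            raise ValueError("wave centers must be ordered P < Q < R < S < T")
        if not 30.0 <= self.heart_rate <= 180.0:
            raise ValueError("heart rate must lie in [30, 180] bpm")

    @property
    def beat_period(self) -> float:
        return 60.0 / self.heart_rate

    def effective_amp(self, lead: str, wave: str) -> float:
        amps = self.amps_i if lead == "I" else self.amps_ii
        a = amps[wave]
        return a * self.t_inversion if wave == "T" else a

    def copy(self) -> "MorphologyParams":
        return MorphologyParams(
            amps_i=dict(self.amps_i), amps_ii=dict(self.amps_ii),
            centers=dict(self.centers), widths=dict(self.widths),
            heart_rate=self.heart_rate, t_inversion=self.t_inversion,
        )


#: Population-typical morphology (amplitudes in mV, times in seconds).
_DEFAULT_MORPH = dict(
    amps_i={"P": 0.08, "Q": -0.06, "R": 0.70, "S": -0.15, "T": 0.22},
    amps_ii={"P": 0.15, "Q": -0.10, "R": 1.10, "S": -0.25, "T": 0.35},
    centers={"P": -0.17, "Q": -0.04, "R": 0.0, "S": 0.045, "T": 0.30},
    widths={"P": 0.025, "Q": 0.010, "R": 0.012, "S": 0.010, "T": 0.060},
)


def default_morphology() -> MorphologyParams:
    """The population-typical beat used as the centre of patient draws."""
    return MorphologyParams(
        amps_i=dict(_DEFAULT_MORPH["amps_i"]),
        amps_ii=dict(_DEFAULT_MORPH["amps_ii"]),
        centers=dict(_DEFAULT_MORPH["centers"]),
        widths=dict(_DEFAULT_MORPH["widths"]),
    )


def sample_morphology(rng: np.random.Generator) -> MorphologyParams:
    """Draw one patient's baseline morphology around the population default.

    Amplitudes get ~15% multiplicative jitter, widths ~10%, the T centre and
    heart rate moderate Gaussian jitter — enough between-patient variation
    for the encoder to have something to learn, while staying physiological.
    """
    m = default_morphology()
    for amps in (m.amps_i, m.amps_ii):
        for w in WAVES:
            amps[w] *= float(np.exp(rng.normal(0.0, 0.15)))
    for w in WAVES:
        m.widths[w] *= float(np.exp(rng.normal(0.0, 0.10)))
    m.centers["T"] = float(np.clip(m.centers["T"] + rng.normal(0.0, 0.02), 0.15, 0.45))
    m.heart_rate = float(np.clip(rng.normal(68.0, 10.0), 45.0, 110.0))
    return m


def _beat_sum(params: MorphologyParams, lead: str, t_rel: np.ndarray) -> np.ndarray:
    """Sum of wave Gaussians at times relative to the R peak (no wrapping)."""
    out = np.zeros_like(t_rel, dtype=float)
    for w in WAVES:
        a = params.effective_amp(lead, w)
        c, b = params.centers[w], params.widths[w]
        out += a * np.exp(-((t_rel - c) ** 2) / (2.0 * b * b))
    return out


def r_peak_times(
    params: MorphologyParams, duration: float, first_r: float = 0.4
) -> np.ndarray:
    """Ground-truth R-peak times of :func:`synthesize_ecg` output."""
    period = params.beat_period
    n = int(np.floor((duration - first_r) / period)) + 1
    return first_r + period * np.arange(max(n, 0))


def synthesize_ecg(
    params: MorphologyParams,
    duration: float = 10.0,
    fs: int = 250,
    noise_sd: float = 0.0,
    wander_amp: float = 0.0,
    seed: int = 0,
    patient_id: str = "synthetic",
    day: int = 0,
    first_r: float = 0.4,
) -> EcgRecording:
    """Render a 6-limb-lead ECG from a beat morphology.

    Leads I and II are periodic Gaussian-sum beat trains; III, aVR, aVL and
    aVF follow from the Einthoven/Goldberger identities (III = II − I,
    aVR = −(I+II)/2, aVL = I − II/2, aVF = II − I/2) before noise.  Each lead
    then receives independent additive Gaussian noise (``noise_sd`` mV) and a
    low-frequency cosine baseline wander (frequency <= 0.5 Hz, amplitude
    ``wander_amp`` mV, random phase).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs not in (250, 500):
        raise ValueError(f"unsupported sampling rate {fs}; use 250 or 500")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    period = params.beat_period
    # Phase-wrap so the beat repeats exactly with the beat period.
    t_rel = np.mod(t - first_r + period / 2.0, period) - period / 2.0
    lead_i = _beat_sum(params, "I", t_rel)
    lead_ii = _beat_sum(params, "II", t_rel)
    mat = np.empty((6, n))
    mat[0] = lead_i
    mat[1] = lead_ii
    mat[2] = lead_ii - lead_i              # III
    mat[3] = -(lead_i + lead_ii) / 2.0     # aVR
    mat[4] = lead_i - lead_ii / 2.0        # aVL
    mat[5] = lead_ii - lead_i / 2.0        # aVF
    if wander_amp > 0:
        for li in range(6):
            f = rng.uniform(0.1, 0.5)
            phase = rng.uniform(0, 2 * np.pi)
            mat[li] += wander_amp * np.cos(2 * np.pi * f * t + phase)
    if noise_sd > 0:
        mat += rng.normal(0.0, noise_sd, size=mat.shape)
    return EcgRecording(patient_id=patient_id, day=day, fs=fs, signal=mat)


def beat_template_matrix(
    params: MorphologyParams,
    window: tuple[int, int] = DEFAULT_WINDOW,
    fs: int = 250,
) -> np.ndarray:
    """Analytic noiseless mean-beat (6 leads x L samples, mV).

    This is the closed form of what preprocessing recovers from a clean
    recording: the Gaussian-sum beat evaluated on the R-aligned window, with
    derived leads from the same identities as :func:`synthesize_ecg`.
    """
    pre, post = window
    t_rel = (np.arange(-pre, post)) / fs
    lead_i = _beat_sum(params, "I", t_rel)
    lead_ii = _beat_sum(params, "II", t_rel)
    return np.stack(
        [
            lead_i,
            lead_ii,
            lead_ii - lead_i,
            -(lead_i + lead_ii) / 2.0,
            lead_i - lead_ii / 2.0,
            lead_ii - lead_i / 2.0,
        ]
    )


def analytic_template(
    params: MorphologyParams,
    patient_id: str,
    day: int,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> BeatTemplate:
    """Noiseless, normalised template straight from the morphology."""
    from .preprocess import normalize01

    tpl = BeatTemplate(
        patient_id=patient_id, day=day,
        waveforms=beat_template_matrix(params, window), window=window,
    )
    return normalize01(tpl)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryConfig:
    """Morphology drift and ECG visit process over follow-up.

    Drifting parameters follow a Gaussian random walk on the 90-day grid;
    ``*_step_sd`` are the per-90-day step standard deviations.  Visits occur
    at day 0 and then at gaps ~ Normal(visit_gap_mean, visit_gap_sd^2) days,
    truncated below at ``visit_gap_min`` (defaults emulate roughly bi-yearly
    follow-up).  ``horizon_days`` is the administrative censoring horizon.
    """

    t_amp_step_sd: float = 0.0
    t_width_step_sd: float = 0.0
    heart_rate_step_sd: float = 0.0
    drift_model: str = "random_walk"
    horizon_days: int = 1440
    visit_gap_mean: float = 180.0
    visit_gap_sd: float = 45.0
    visit_gap_min: float = 30.0

    def __post_init__(self) -> None:
        for name in ("t_amp_step_sd", "t_width_step_sd", "heart_rate_step_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.horizon_days <= 0:
            raise ValueError("horizon must be positive")


@dataclass
class PatientTrajectory:
    """Ground-truth drift of one patient: grid values plus visit snapshots."""

    params0: MorphologyParams
    #: morphology in force on each 90-day interval k = 0 .. n_intervals-1
    interval_params: list[MorphologyParams]
    #: (day, params) at each ECG visit; day 0 always present
    visits: list[tuple[int, MorphologyParams]]

    @property
    def n_intervals(self) -> int:
        return len(self.interval_params)

    def t_amp_series(self) -> np.ndarray:
        """Lead-II effective T amplitude per interval (the hazard driver)."""
        return np.array(
            [p.effective_amp("II", "T") for p in self.interval_params]
        )


def _drifted(params0: MorphologyParams, d_t_amp: float, d_t_width: float,
             d_hr: float) -> MorphologyParams:
    p = params0.copy()
    # T amplitude drifts additively in lead II and proportionally in lead I,
    # so the two measured leads stay morphologically consistent.
    base_ii = params0.amps_ii["T"]
    scale = (base_ii + d_t_amp) / base_ii if base_ii != 0 else 1.0
    p.amps_ii["T"] = base_ii + d_t_amp
    p.amps_i["T"] = params0.amps_i["T"] * scale
    p.widths["T"] = max(params0.widths["T"] + d_t_width, 0.02)
    p.heart_rate = float(np.clip(params0.heart_rate + d_hr, 30.0, 180.0))
    return p


def generate_trajectory(
    params0: MorphologyParams,
    cfg: TrajectoryConfig,
    horizon: int | None = None,
    seed: int | np.random.Generator = 0,
) -> PatientTrajectory:
    """Random-walk drift on the 90-day grid, sampled at irregular visits.

    The walk value for interval k applies to days [90k, 90(k+1)); a visit on
    day d therefore carries the interval-floor(d/90) morphology.  With all
    step SDs zero every visit shares ``params0``.
    """
    horizon = int(horizon if horizon is not None else cfg.horizon_days)
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_int = int(np.ceil(horizon / GRID_DAYS))

    def walk(sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros(n_int)
        steps = rng.normal(0.0, sd, size=n_int)
        steps[0] = 0.0  # interval 0 carries the baseline value
        return np.cumsum(steps)

    w_amp = walk(cfg.t_amp_step_sd)
    w_wid = walk(cfg.t_width_step_sd)
    w_hr = walk(cfg.heart_rate_step_sd)
    interval_params = [
        _drifted(params0, w_amp[k], w_wid[k], w_hr[k]) for k in range(n_int)
    ]

    days = [0]
    while True:
        gap = max(rng.normal(cfg.visit_gap_mean, cfg.visit_gap_sd), cfg.visit_gap_min)
        nxt = days[-1] + int(round(gap))
        if nxt > horizon:
            break
        days.append(nxt)
    visits = [
        (d, interval_params[min(d // GRID_DAYS, n_int - 1)]) for d in days
    ]
    return PatientTrajectory(
        params0=params0, interval_params=interval_params, visits=visits
    )


# ---------------------------------------------------------------------------
# Baseline covariates
# ---------------------------------------------------------------------------


@dataclass
class BaselineConfig:
    """Prevalences and missingness of the baseline covariate table.

    The roster mirrors a typical ICD cohort: demographics, aetiology,
    prevention indication, arrhythmia history, medication flags and a few
    laboratory values.  ``lab_missing_frac`` of each lab value is removed
    completely at random; ``high_missing_col`` is removed at
    ``high_missing_frac`` (>= 30%) to exercise the column-exclusion rule
    downstream.
    """

    sex_male_prev: float = 0.745
    ischaemic_prev: float = 0.416
    primary_prevention_prev: float = 0.605
    prior_vtvf_prev: float = 0.406
    lvef_le_35_prev: float = 0.606
    beta_blocker_prev: float = 0.766
    amiodarone_prev: float = 0.088
    age_mean: float = 61.7
    age_sd: float = 13.9
    lab_missing_frac: float = 0.10
    high_missing_col: str = "nt_probnp"
    high_missing_frac: float = 0.35

    CATEGORICAL = (
        "sex_male", "ischaemic", "primary_prevention", "prior_vtvf",
        "lvef_le_35", "beta_blocker", "amiodarone",
    )
    LABS = ("creatinine", "potassium", "nt_probnp")


def generate_baseline(
    n_patients: int,
    seed: int | np.random.Generator = 0,
    cfg: BaselineConfig | None = None,
) -> pd.DataFrame:
    """Draw the baseline table: one row per patient, missingness injected MCAR."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    cfg = cfg or BaselineConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n_patients)],
            "age": np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n_patients), 18, 95),
            "sex_male": (rng.random(n_patients) < cfg.sex_male_prev).astype(int),
            "ischaemic": (rng.random(n_patients) < cfg.ischaemic_prev).astype(int),
            "primary_prevention": (
                rng.random(n_patients) < cfg.primary_prevention_prev
            ).astype(int),
            "prior_vtvf": (rng.random(n_patients) < cfg.prior_vtvf_prev).astype(int),
            "lvef_le_35": (rng.random(n_patients) < cfg.lvef_le_35_prev).astype(int),
            "beta_blocker": (
                rng.random(n_patients) < cfg.beta_blocker_prev
            ).astype(int),
            "amiodarone": (rng.random(n_patients) < cfg.amiodarone_prev).astype(int),
            "creatinine": rng.normal(100.0, 45.0, n_patients).clip(40, 400),
            "potassium": rng.normal(4.3, 0.4, n_patients).clip(2.8, 6.5),
            "nt_probnp": np.exp(rng.normal(6.5, 1.0, n_patients)),
        }
    )
    for col in BaselineConfig.LABS:
        frac = (
            cfg.high_missing_frac if col == cfg.high_missing_col
            else cfg.lab_missing_frac
        )
        mask = rng.random(n_patients) < frac
        df.loc[mask, col] = np.nan
    return df


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------


@dataclass
class HazardSpec:
    """Piecewise-constant hazard on the 90-day grid.

    lambda_k = baseline_hazard * exp(coef_t_amp * (Tamp_k − t_amp_ref)
    + sum_c coef_baseline[c] * X_c), with Tamp_k the lead-II effective T-wave
    amplitude in force on interval k.  A positive ``coef_t_amp`` with a
    drifting T amplitude is the planted time-varying signal the dynamic
    model should exploit.
    """

    baseline_hazard: float = 5e-4
    coef_t_amp: float = 0.0
    t_amp_ref: float = _DEFAULT_MORPH["amps_ii"]["T"]
    coef_baseline: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_hazard < 0:
            raise ValueError("baseline hazard must be non-negative")

    def hazard_per_day(
        self, t_amp: np.ndarray, covariates: Mapping[str, float]
    ) -> np.ndarray:
        lin = self.coef_t_amp * (np.asarray(t_amp, dtype=float) - self.t_amp_ref)
        for col, beta in self.coef_baseline.items():
            lin = lin + beta * float(covariates[col])
        return self.baseline_hazard * np.exp(lin)


def simulate_events(
    trajectories: Mapping[str, PatientTrajectory],
    baseline: pd.DataFrame,
    spec: HazardSpec,
    horizon: int = 1440,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw event/censoring times from the piecewise-constant hazard.

    For each 90-day interval the event probability is 1 − exp(−lambda*tau)
    (tau = 90 or the remainder at the horizon); the event day is uniform
    within the triggering interval.  Patients without an event are censored
    administratively at the horizon.  Returns columns patient_id, fu_days,
    event, event_day (NaN when censored).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = baseline.set_index("patient_id")
    rows = []
    for pid in baseline["patient_id"]:
        traj = trajectories[pid]
        if traj.n_intervals * GRID_DAYS < horizon:
            raise ValueError(f"trajectory of {pid} does not cover the horizon")
        lam = spec.hazard_per_day(traj.t_amp_series(), cov.loc[pid])
        event, fu, eday = 0, horizon, np.nan
        n_int = int(np.ceil(horizon / GRID_DAYS))
        for k in range(n_int):
            tau = min(GRID_DAYS, horizon - k * GRID_DAYS)
            p = 1.0 - np.exp(-lam[k] * tau)
            if rng.random() < p:
                event = 1
                eday = k * GRID_DAYS + rng.uniform(0.0, tau)
                # Keep at least one day of follow-up so day-0 data precede it.
                eday = float(np.ceil(max(eday, 1.0)))
                fu = eday
                break
        rows.append(
            {"patient_id": pid, "fu_days": float(fu), "event": event,
             "event_day": eday}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Everything needed to draw a cohort, in one reproducible bundle."""

    n_patients: int = 200
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    trajectory: TrajectoryConfig = field(
        default_factory=lambda: TrajectoryConfig(t_amp_step_sd=0.08)
    )
    hazard: HazardSpec = field(
        default_factory=lambda: HazardSpec(
            baseline_hazard=1.2e-4,
            coef_t_amp=-4.0,
            coef_baseline={"prior_vtvf": 0.7, "lvef_le_35": 0.4},
        )
    )
    horizon_days: int = 1440
    ecg_duration: float = 10.0
    ecg_fs: int = 250
    ecg_noise_sd: float = 0.03
    ecg_wander_amp: float = 0.10

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticCohort:
    """Baseline table, outcome table and per-patient ECG material.

    ``trajectories`` carry the ground truth; raw recordings are rendered
    lazily by :meth:`recordings` (or bypassed via :meth:`templates`, the
    analytic noiseless mean-beats — the fast path for large simulations).
    Visits after a patient's event/censoring day are dropped so that no
    recording post-dates the outcome.
    """

    config: CohortConfig
    seed: int
    baseline: pd.DataFrame
    outcomes: pd.DataFrame
    trajectories: dict[str, PatientTrajectory]

    def _kept_visits(self, pid: str) -> list[tuple[int, MorphologyParams]]:
        end = float(self.outcomes.set_index("patient_id").loc[pid, "fu_days"])
        return [(d, p) for d, p in self.trajectories[pid].visits if d <= end]

    def kept_visits(self, pid: str) -> list[tuple[int, MorphologyParams]]:
        """(day, ground-truth morphology) pairs for a patient's retained visits."""
        return self._kept_visits(pid)

    def visit_days(self) -> dict[str, list[int]]:
        return {pid: [d for d, _ in self._kept_visits(pid)]
                for pid in self.baseline["patient_id"]}

    def templates(self, window: tuple[int, int] = DEFAULT_WINDOW) -> list[BeatTemplate]:
        """Analytic noiseless normalised templates at every kept visit."""
        out = []
        for pid in self.baseline["patient_id"]:
            for day, params in self._kept_visits(pid):
                out.append(analytic_template(params, pid, day, window))
        return out

    def recordings(self) -> list[EcgRecording]:
        """Render full raw ECGs (noise + wander) at every kept visit."""
        cfg = self.config
        ss = np.random.SeedSequence([self.seed, 0xECF])
        out = []
        for pid in self.baseline["patient_id"]:
            for day, params in self._kept_visits(pid):
                child = int(
                    np.random.default_rng(ss.spawn(1)[0]).integers(0, 2**31 - 1)
                )
                out.append(
                    synthesize_ecg(
                        params, cfg.ecg_duration, cfg.ecg_fs,
                        noise_sd=cfg.ecg_noise_sd, wander_amp=cfg.ecg_wander_amp,
                        seed=child, patient_id=pid, day=day,
                    )
                )
        return out

    def write(self, outdir: str | Path, write_ecgs: bool = False) -> dict:
        """Write baseline/outcome CSVs plus a JSON manifest (and ECG CSV)."""
        from .preprocess import recordings_to_frame

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.baseline.to_csv(outdir / "baseline.csv", index=False)
        self.outcomes.to_csv(outdir / "outcomes.csv", index=False)
        manifest = {
            "seed": self.seed,
            "n_patients": int(self.config.n_patients),
            "config": _jsonable(self.config.to_dict()),
            "files": ["baseline.csv", "outcomes.csv"],
        }
        if write_ecgs:
            recordings_to_frame(self.recordings()).to_csv(
                outdir / "ecgs_long.csv", index=False
            )
            manifest["files"].append("ecgs_long.csv")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def generate_cohort(
    cfg: CohortConfig | None = None, seed: int = 0
) -> SyntheticCohort:
    """Draw a full cohort: baseline, per-patient drift, events, visit days.

    All randomness descends from ``seed`` through independent named streams,
    so identical (config, seed) pairs give bitwise-identical tables.
    """
    cfg = cfg or CohortConfig()
    root = np.random.SeedSequence(seed)
    s_base, s_morph, s_traj, s_event = root.spawn(4)
    baseline = generate_baseline(
        cfg.n_patients, np.random.default_rng(s_base), cfg.baseline
    )
    morph_rng = np.random.default_rng(s_morph)
    traj_streams = s_traj.spawn(cfg.n_patients)
    trajectories: dict[str, PatientTrajectory] = {}
    for i, pid in enumerate(baseline["patient_id"]):
        params0 = sample_morphology(morph_rng)
        trajectories[pid] = generate_trajectory(
            params0, cfg.trajectory, cfg.horizon_days,
            np.random.default_rng(traj_streams[i]),
        )
    outcomes = simulate_events(
        trajectories, baseline, cfg.hazard, cfg.horizon_days,
        np.random.default_rng(s_event),
    )
    return SyntheticCohort(
        config=cfg, seed=seed, baseline=baseline, outcomes=outcomes,
        trajectories=trajectories,
    )
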