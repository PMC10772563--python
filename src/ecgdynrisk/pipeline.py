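"""End-to-end experiment orchestration with staged, hash-chained artifacts.

The experiment is a chain of stages — simulate, preprocess, train-vae,
encode, build-cpiu, fit, evaluate, interpret — each reading the previous
stage's files from a shared output directory and writing its own, plus a
JSON manifest recording the configuration hash, seeds, row counts and the
SHA-256 of every output.  Rerunning a stage whose configuration and inputs
are unchanged is a no-op; a missing upstream artifact raises a dependency
error naming it.  Everything is reproducible from the config and its seeds
alone; no stage touches the network.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import evaluation, interpret, preprocess, survival, synthetic, vae

log = logging.getLogger("ecgdynrisk")

STAGES = (
    "simulate", "preprocess", "train-vae", "encode",
    "build-cpiu", "fit", "evaluate", "interpret",
)

OUTCOME_LABELS = ("any-therapy", "shock-only", "mortality")


class DependencyError(RuntimeError):
    """An upstream stage artifact is missing or unreadable."""


@dataclass
class Seeds:
    simulation: int = 1
    split: int = 2
    vae: int = 3
    forest: int = 4
    bootstrap: int = 5


@dataclass
class ExperimentConfig:
    """Single source of truth for one experiment run.

    ``single_lead`` switches the encoder input to lead II only (same code
    path, smaller input dimension); ``outcome_label`` selects which outcome
    table column set drives the supervised stage (the synthetic generator
    emits one outcome process; alternative labels are supplied by pointing
    ``outcome_file`` at a different table with the same layout).
    """

    seeds: Seeds = field(default_factory=Seeds)
    n_patients: int = 200
    horizon_days: int = 1440
    use_raw_ecg: bool = False
    t_amp_step_sd: float = 0.08
    hazard_coef_t_amp: float = -4.0
    baseline_hazard: float = 1.2e-4
    # VAE
    single_lead: bool = False
    hidden_sizes: tuple[int, int, int] = (256, 128, 64)
    latent_dim: int = 16
    beta: float = 1.0
    vae_epochs: int = 60
    vae_batch: int = 128
    vae_lr: float = 1e-3
    pretrain_pool: int = 0
    pretrain_epochs: int = 40
    # supervised stage
    interval_days: int = 90
    split_ratio: float = 0.8
    tune: bool = False
    n_trees: int = 150
    min_node_events: int = 5
    horizon_intervals: int = 16
    n_boot: int = 0
    outcome_label: str = "any-therapy"
    outcome_file: str | None = None

    def __post_init__(self) -> None:
        if self.interval_days <= 0:
            raise ValueError("interval length must be positive")
        if self.outcome_label not in OUTCOME_LABELS:
            raise ValueError(f"outcome_label must be one of {OUTCOME_LABELS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seeds = Seeds(**raw.pop("seeds", {}))
        cfg = cls(seeds=seeds, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_path(outdir: Path, stage: str) -> Path:
    return outdir / f"manifest_{stage.replace('-', '_')}.json"


def _require(outdir: Path, *names: str) -> list[Path]:
    paths = []
    for name in names:
        p = outdir / name
        if not p.exists():
            raise DependencyError(
                f"missing upstream artifact '{name}' in {outdir}; "
                "run the producing stage first"
            )
        paths.append(p)
    return paths


def _write_manifest(
    outdir: Path, stage: str, cfg: ExperimentConfig,
    inputs: Sequence[Path], outputs: Sequence[Path], extra: dict | None = None,
) -> dict:
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seeds": dataclasses.asdict(cfg.seeds),
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    if extra:
        manifest.update(extra)
    _manifest_path(outdir, stage).write_text(json.dumps(manifest, indent=2))
    return manifest


def _is_fresh(outdir: Path, stage: str, cfg: ExperimentConfig,
              inputs: Sequence[Path]) -> bool:
    mp = _manifest_path(outdir, stage)
    if not mp.exists():
        return False
    try:
        m = json.loads(mp.read_text())
    except json.JSONDecodeError:
        return False
    if m.get("config_hash") != cfg.config_hash():
        return False
    if set(m.get("inputs", {})) != {p.name for p in inputs}:
        return False
    for p in inputs:
        if m["inputs"].get(p.name) != _sha256(p):
            return False
    return all((outdir / name).exists() for name in m.get("outputs", {}))


# ---------------------------------------------------------------------------
# Stage bodies
# ---------------------------------------------------------------------------


def _cohort_config(cfg: ExperimentConfig) -> synthetic.CohortConfig:
    return synthetic.CohortConfig(
        n_patients=cfg.n_patients,
        trajectory=synthetic.TrajectoryConfig(
            t_amp_step_sd=cfg.t_amp_step_sd, horizon_days=cfg.horizon_days
        ),
        hazard=synthetic.HazardSpec(
            baseline_hazard=cfg.baseline_hazard,
            coef_t_amp=cfg.hazard_coef_t_amp,
            coef_baseline={"prior_vtvf": 0.7, "lvef_le_35": 0.4},
        ),
        horizon_days=cfg.horizon_days,
    )


def _stage_simulate(cfg: ExperimentConfig, outdir: Path):
    cohort = synthetic.generate_cohort(_cohort_config(cfg), seed=cfg.seeds.simulation)
    cohort.write(outdir, write_ecgs=cfg.use_raw_ecg)
    outputs = [outdir / "baseline.csv", outdir / "outcomes.csv"]
    if cfg.use_raw_ecg:
        outputs.append(outdir / "ecgs_long.csv")
    else:
        preprocess.write_templates(cohort.templates(), outdir / "templates.csv")
        outputs += [outdir / "templates.csv", outdir / "templates.json"]
    return [], outputs, {"n_patients": cfg.n_patients,
                         "n_events": int(cohort.outcomes["event"].sum())}


def _stage_preprocess(cfg: ExperimentConfig, outdir: Path):
    if not cfg.use_raw_ecg:
        # the simulate stage already emitted analytic templates
        inputs = _require(outdir, "templates.csv")
        return inputs, inputs, {"passthrough": True}
    (ecg_path,) = _require(outdir, "ecgs_long.csv")
    recs = preprocess.frame_to_recordings(pd.read_csv(ecg_path))
    templates = preprocess.preprocess_cohort(recs)
    preprocess.write_templates(templates, outdir / "templates.csv")
    return [ecg_path], [outdir / "templates.csv", outdir / "templates.json"], {
        "n_recordings": len(recs), "n_templates": len(templates)
    }


def _template_matrix(cfg: ExperimentConfig, templates) -> tuple[np.ndarray, list]:
    """Stack templates into the encoder input matrix (single-lead aware)."""
    if cfg.single_lead:
        rows = [t.waveforms[t.leads.index("II")] for t in templates]
    else:
        rows = [t.vector for t in templates]
    return np.stack(rows), [(t.patient_id, t.day) for t in templates]


def _load_templates(outdir: Path):
    (tpl_path,) = _require(outdir, "templates.csv")
    return preprocess.frame_to_templates(pd.read_csv(tpl_path)), tpl_path


def _stage_train_vae(cfg: ExperimentConfig, outdir: Path):
    templates, tpl_path = _load_templates(outdir)
    (base_path,) = _require(outdir, "baseline.csv")
    baseline = pd.read_csv(base_path)
    train_ids, test_ids = survival.split_cohort(
        list(baseline["patient_id"]), cfg.split_ratio, cfg.seeds.split
    )
    (outdir / "split.json").write_text(
        json.dumps({"train": train_ids, "test": test_ids}, indent=2)
    )
    X, keys = _template_matrix(cfg, templates)
    model = vae.build_vae(
        X.shape[1], cfg.hidden_sizes, cfg.latent_dim, cfg.beta, cfg.seeds.vae
    )
    if cfg.pretrain_pool > 0:
        rng = np.random.default_rng(cfg.seeds.vae)
        pool = np.stack([
            _template_matrix(
                cfg,
                [synthetic.analytic_template(
                    synthetic.sample_morphology(rng), "pool", 0
                )],
            )[0][0]
            for _ in range(cfg.pretrain_pool)
        ])
        vae.train(model, pool, cfg.pretrain_epochs, cfg.vae_batch, cfg.vae_lr,
                  seed=cfg.seeds.vae, mode="pretrain")
    train_set = frozenset(train_ids)
    mask = np.array([pid in train_set for pid, _ in keys])
    vae.train(model, X[mask], cfg.vae_epochs, cfg.vae_batch, cfg.vae_lr,
              seed=cfg.seeds.vae + 1, mode="finetune")
    model.save(outdir / "vae_model")
    outputs = [outdir / "vae_model.npz", outdir / "vae_model.json",
               outdir / "split.json"]
    return [tpl_path, base_path], outputs, {
        "n_train_templates": int(mask.sum()), "epochs": model.epoch
    }


def _stage_encode(cfg: ExperimentConfig, outdir: Path):
    templates, tpl_path = _load_templates(outdir)
    _require(outdir, "vae_model.npz", "vae_model.json")
    model = vae.VaeModel.load(outdir / "vae_model")
    X, keys = _template_matrix(cfg, templates)
    mu, _ = model.encode(X)
    codes = pd.DataFrame(mu, columns=vae.latent_names(model.latent_dim))
    codes.insert(0, "day", [d for _, d in keys])
    codes.insert(0, "patient_id", [p for p, _ in keys])
    codes.to_csv(outdir / "latents.csv", index=False)
    return [tpl_path, outdir / "vae_model.npz"], [outdir / "latents.csv"], {
        "n_codes": len(codes)
    }


def _stage_build_cpiu(cfg: ExperimentConfig, outdir: Path):
    inputs = _require(outdir, "latents.csv", "baseline.csv", "split.json")
    outcome_name = cfg.outcome_file or "outcomes.csv"
    inputs += _require(outdir, outcome_name)
    codes = pd.read_csv(outdir / "latents.csv")
    baseline = pd.read_csv(outdir / "baseline.csv")
    outcomes = pd.read_csv(outdir / outcome_name)
    split = json.loads((outdir / "split.json").read_text())
    feats, enc = survival.impute_and_encode(
        baseline, split["train"], seed=cfg.seeds.split
    )
    rows = survival.build_cpius(outcomes, codes, feats, cfg.interval_days)
    rows.to_csv(outdir / "cpiu.csv", index=False)
    (outdir / "encoder.json").write_text(json.dumps(
        {"dropped": enc.dropped, "feature_cols": enc.feature_cols,
         "train_ids_sha": hashlib.sha256(
             ",".join(sorted(enc.train_ids)).encode()).hexdigest()[:16]},
        indent=2,
    ))
    return inputs, [outdir / "cpiu.csv", outdir / "encoder.json"], {
        "n_rows": len(rows), "n_events": int(rows["event"].sum())
    }


def _split_rows(outdir: Path, rows: pd.DataFrame):
    split = json.loads((outdir / "split.json").read_text())
    return (
        rows[rows["patient_id"].isin(split["train"])],
        rows[rows["patient_id"].isin(split["test"])],
    )


def _stage_fit(cfg: ExperimentConfig, outdir: Path):
    inputs = _require(outdir, "cpiu.csv", "split.json")
    rows = pd.read_csv(outdir / "cpiu.csv")
    train_rows, _ = _split_rows(outdir, rows)
    hyper = survival.Hyperparams(
        n_trees=cfg.n_trees, min_node_events=cfg.min_node_events
    )
    if cfg.tune:
        hyper, cv_table = survival.tune_hyperparams(
            train_rows, seed=cfg.seeds.forest,
            horizon_intervals=cfg.horizon_intervals,
        )
        cv_table.to_csv(outdir / "cv_table.csv", index=False)
    dyn = survival.fit_hazard_forest(train_rows, hyper, cfg.seeds.forest)
    sta = survival.fit_static_model(train_rows, hyper, cfg.seeds.forest)
    dyn.save(outdir / "forest_dynamic")
    sta.save(outdir / "forest_static")
    outputs = [outdir / f"forest_{kind}{ext}" for kind in ("dynamic", "static")
               for ext in (".npz", ".json")]
    if cfg.tune:
        outputs.append(outdir / "cv_table.csv")
    return inputs, outputs, {"hyperparams": hyper.__dict__}


def _stage_evaluate(cfg: ExperimentConfig, outdir: Path):
    inputs = _require(outdir, "cpiu.csv", "split.json",
                      "forest_dynamic.npz", "forest_static.npz")
    rows = pd.read_csv(outdir / "cpiu.csv")
    _, test_rows = _split_rows(outdir, rows)
    outputs = []
    summary = {}
    for kind in ("dynamic", "static"):
        forest = survival.HazardForest.load(outdir / f"forest_{kind}")
        rws = test_rows
        if kind == "static":
            rws = survival.freeze_baseline_features(test_rows)
        report = evaluation.evaluate_model(
            forest, rws, horizon=cfg.horizon_intervals,
            n_boot=cfg.n_boot, seed=cfg.seeds.bootstrap,
            subgroup_cols=("sex_male", "ischaemic"),
        )
        report.to_json(outdir / f"eval_{kind}.json")
        evaluation.plot_auroc_over_time(
            report.per_interval, outdir / f"auroc_{kind}.png"
        )
        evaluation.plot_calibration(
            report.calibration, outdir / f"calibration_{kind}.png"
        )
        outputs += [outdir / f"eval_{kind}.json"]
        summary[kind] = {"mean_auroc": report.mean_auroc,
                         "sd_auroc": report.sd_auroc}
    dyn = survival.HazardForest.load(outdir / "forest_dynamic")
    imp = evaluation.permutation_importance(
        dyn, test_rows, repeats=5, seed=cfg.seeds.bootstrap,
        horizon=cfg.horizon_intervals,
    )
    imp.to_csv(outdir / "importance.csv", index=False)
    outputs.append(outdir / "importance.csv")
    return inputs, outputs, summary


def _stage_interpret(cfg: ExperimentConfig, outdir: Path):
    inputs = _require(outdir, "latents.csv", "vae_model.npz")
    model = vae.VaeModel.load(outdir / "vae_model")
    codes = pd.read_csv(outdir / "latents.csv")
    results = interpret.traverse_all(model, codes)
    stacked = pd.concat(
        [r.to_frame().assign(latent=f"AE{j}") for j, r in results.items()],
        ignore_index=True,
    )
    stacked.to_csv(outdir / "traversal.csv", index=False)
    # pick the most variable dimension for the figure
    spread = {j: float(np.ptp(r.grid_values)) for j, r in results.items()}
    j_star = max(spread, key=spread.get)
    interpret.plot_traversal_heatmap(
        results[j_star], outdir / "traversal_heatmap.png",
        [f"p{p}" for p in interpret.TRAVERSAL_PERCENTILES],
    )
    outputs = [outdir / "traversal.csv"]
    return inputs, outputs, {"figure_latent": f"AE{j_star}"}


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "train-vae": _stage_train_vae,
    "encode": _stage_encode,
    "build-cpiu": _stage_build_cpiu,
    "fit": _stage_fit,
    "evaluate": _stage_evaluate,
    "interpret": _stage_interpret,
}


def run_stage(stage: str, cfg: ExperimentConfig, outdir: str | Path) -> dict:
    """Run one stage; no-op when its config and inputs are unchanged."""
    if stage not in _STAGE_FNS:
        raise ValueError(f"unknown stage '{stage}'; choose from {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mp = _manifest_path(outdir, stage)
    if mp.exists():
        try:
            prev_inputs = [
                outdir / n for n in json.loads(mp.read_text()).get("inputs", {})
            ]
        except json.JSONDecodeError:
            prev_inputs = []
        if all(p.exists() for p in prev_inputs) and _is_fresh(
            outdir, stage, cfg, prev_inputs
        ):
            log.info("stage %s up to date - skipping", stage)
            return json.loads(mp.read_text())
    log.info("running stage %s (config %s)", stage, cfg.config_hash())
    inputs, outputs, extra = _STAGE_FNS[stage](cfg, outdir)
    manifest = _write_manifest(outdir, stage, cfg, inputs, outputs, extra)
    log.info("stage %s done: %s", stage, {p.name for p in outputs})
    return manifest


def run_all(cfg: ExperimentConfig, outdir: str | Path) -> dict[str, dict]:
    """Run the whole chain in order; returns the manifests per stage."""
    return {stage: run_stage(stage, cfg, outdir) for stage in STAGES}
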