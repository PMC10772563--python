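# ecgdynrisk

Dynamic prediction of malignant ventricular arrhythmia from longitudinal
ECGs in ICD patients.

Patients with an implantable cardioverter-defibrillator (ICD) accumulate
resting ECGs over years of follow-up.  Static risk models see only the
implantation-time snapshot; `ecgdynrisk` implements the full dynamic
alternative and the controlled comparison between the two, for
methodologists working on time-varying risk prediction:

1. **Templates** — each 10-s 6-limb-lead recording is filtered
   (Savitzky–Golay + low-resolution Fourier-cosine detrending), R peaks are
   detected on lead II, and R-aligned beats are averaged into one
   min–max-normalised mean-beat template per lead (175 samples/lead at
   250 Hz).
2. **Latents** — a β-VAE (3-layer ReLU encoder, 16-variable Gaussian
   latent space AE0…AE15, mirrored decoder; loss = MSE + β·KL from the
   ELBO) compresses each template to 16 posterior means.
3. **Person-periods** — follow-up is split into 90-day counting-process
   information units (CPIUs) carrying risk time τ, event indicator d,
   baseline covariates and the last-value-carried-forward latents.
4. **Hazard forest** — trees grown on patient-level bootstraps split by
   Poisson log-likelihood gain Σ D_c log(D_c/T_c) − D log(D/T); leaves hold
   Bayes-shrunk rates λ = (D + a)/(T + b) with prior mean equal to the
   marginal hazard; the interval event probability is 1 − exp(−λ·90).
   A baseline-frozen twin of the same forest is the static comparator.
5. **Evaluation & interpretation** — time-specific AUROC per interval and
   its unweighted mean over 48 months, decile calibration, patient-level
   bootstrap CIs, permutation feature importance (5 repeats), subgroup
   performance, latent factor traversal at cohort percentiles, and a
   time-varying Cox model (lifelines) for hazard-ratio inference.

Because clinical ICD data cannot be shipped, the package includes a
first-class synthetic cohort generator: Gaussian-sum limb-lead beats with
per-patient morphology, a random-walk T-amplitude drift on the 90-day grid,
ICD-cohort-style baseline covariates with injected missingness, irregular
visit times, and event times drawn from a piecewise-constant hazard tied to
the drifting morphology.  Every stage is tested against this ground truth.
See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from ecgdynrisk import experiments, synthetic, vae

# encoder trained on a 5,000-template synthetic pool (~2 min on one core)
model, holdout = experiments.train_pool_vae(5000, seed=0, epochs=200)
xh = model.reconstruct(holdout)
r = np.nanmean([vae.reconstruction_metrics(x, h, with_dtw=False).r
                for x, h in zip(holdout, xh)])
print(f"held-out reconstruction r = {r:.3f}")

# one paired dynamic-vs-static comparison on a drifting 1,000-patient cohort
res = experiments.dynamic_vs_static(model, seed=100, n_patients=1000)
print(f"dynamic {res.dynamic_auroc:.3f}  static {res.static_auroc:.3f}  "
      f"gap {res.gap:+.3f}")
```

Output (seeds as shown):

```
held-out reconstruction r = 0.980
dynamic 0.675  static 0.575  gap +0.099
```

The encoder reconstructs held-out templates at r ≈ 0.98, and on a cohort
whose hazard follows the drifting T-wave amplitude the dynamic model beats
its baseline-frozen twin by ≈ 0.10 mean time-varying AUROC — the planted
time-varying signal is recovered through the whole pipeline.  With drift
disabled the two arms coincide and the gap is 0.

A file-based flow with staged artifacts, manifests and figures is available
as a CLI:

```bash
ecgdynrisk run-all --outdir out            # simulate → … → interpret
ecgdynrisk simulate --config exp.yaml --outdir out
```

Stages are hash-chained: rerunning an unchanged stage is a no-op, and a
missing upstream artifact raises a dependency error naming it.

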