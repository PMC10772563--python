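"""Beta-variational autoencoder over mean-beat templates.

A fully-connected VAE: three encoder layers with ReLU activations feed two
affine heads producing the posterior mean and log-variance of a 16-variable
Gaussian latent space; the reparameterised sample drives a three-layer
symmetric decoder.  The training loss is the negative evidence lower bound
with a mean-squared-error reconstruction term and a beta-weighted
Kullback-Leibler divergence to the standard-normal prior:

    total = MSE(x, x_hat) + beta * KL(q(z|x) || N(0, I))
    KL    = -1/2 * sum_i (1 + log sigma_i^2 - mu_i^2 - sigma_i^2)

Implemented directly in NumPy (forward, backward and Adam), which keeps the
model deterministic, dependency-light and fast enough for template-sized
inputs.  Downstream features are the posterior means mu, exported under the
names AE0..AE15.

Reconstruction quality is summarised by Pearson r, RMSE, percentage
root-mean-square difference (PRD) and dynamic time warping (DTW) distance,
all computed after min-max normalising both signals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

LATENT_NAMES = tuple(f"AE{i}" for i in range(16))


def latent_names(latent_dim: int) -> tuple[str, ...]:
    return tuple(f"AE{i}" for i in range(latent_dim))


# ---------------------------------------------------------------------------
# Loss pieces (closed forms, used by training and by tests)
# ---------------------------------------------------------------------------


@dataclass
class VaeLoss:
    """ELBO decomposition: total = recon + beta * kl."""

    recon: float
    kl: float
    beta: float

    @property
    def total(self) -> float:
        return self.recon + self.beta * self.kl


def vae_loss(
    x: np.ndarray, x_hat: np.ndarray, mu: np.ndarray, logvar: np.ndarray,
    beta: float = 1.0,
) -> VaeLoss:
    """Evaluate the beta-VAE loss for a batch (or a single vector).

    ``recon`` is the element-wise mean squared error; ``kl`` is the analytic
    Gaussian KL summed over latent dimensions and averaged over the batch.
    """
    x, x_hat = np.atleast_2d(x), np.atleast_2d(x_hat)
    mu, logvar = np.atleast_2d(mu), np.atleast_2d(logvar)
    if x.shape != x_hat.shape or mu.shape != logvar.shape:
        raise ValueError("shape mismatch between inputs")
    if not (np.isfinite(x_hat).all() and np.isfinite(mu).all()
            and np.isfinite(logvar).all()):
        raise FloatingPointError("non-finite values in loss inputs")
    recon = float(np.mean((x - x_hat) ** 2))
    kl_per = -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar), axis=1)
    return VaeLoss(recon=recon, kl=float(np.mean(kl_per)), beta=beta)


def sample_latent(
    mu: np.ndarray, logvar: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Reparameterised draw z = mu + sigma * eps, eps ~ N(0, I)."""
    mu, logvar = np.asarray(mu, float), np.asarray(logvar, float)
    if mu.shape != logvar.shape:
        raise ValueError("mu and logvar shapes differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape)


@dataclass
class LatentCode:
    """Posterior parameters for one template: mean, log-variance, names."""

    mu: np.ndarray
    logvar: np.ndarray
    patient_id: str | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float).reshape(-1)
        self.logvar = np.asarray(self.logvar, float).reshape(-1)
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar must have equal length")
        if not np.isfinite(self.logvar).all():
            raise ValueError("log-variance must be finite")

    @property
    def names(self) -> tuple[str, ...]:
        return latent_names(self.mu.size)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class VaeModel:
    """Fully-connected beta-VAE with 3 encoder and 3 decoder layers.

    Parameters are plain NumPy arrays; ``seed`` fixes the initialisation.
    ``hidden_sizes`` lists the three encoder widths (the decoder mirrors
    them); the default latent dimension is 16.
    """

    def __init__(
        self,
        input_dim: int,
        hidden_sizes: Sequence[int] = (512, 256, 128),
        latent_dim: int = 16,
        beta: float = 1.0,
        seed: int = 0,
    ) -> None:
        if len(hidden_sizes) != 3:
            raise ValueError("exactly 3 encoder hidden sizes are required")
        if input_dim <= latent_dim:
            raise ValueError("input_dim must exceed latent_dim")
        if beta < 0:
            raise ValueError("beta must be >= 0")
        self.input_dim = int(input_dim)
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        self.latent_dim = int(latent_dim)
        self.beta = float(beta)
        self.seed = int(seed)
        self.epoch = 0
        self.history: dict[str, list[float]] = {"train": [], "val": []}
        rng = np.random.default_rng(seed)
        h1, h2, h3 = self.hidden_sizes
        enc_dims = [(input_dim, h1), (h1, h2), (h2, h3)]
        dec_dims = [(latent_dim, h3), (h3, h2), (h2, h1), (h1, input_dim)]
        self.enc_W = [_glorot(rng, a, b) for a, b in enc_dims]
        self.enc_b = [np.zeros(b) for _, b in enc_dims]
        self.W_mu = _glorot(rng, h3, latent_dim)
        self.b_mu = np.zeros(latent_dim)
        self.W_lv = _glorot(rng, h3, latent_dim)
        self.b_lv = np.zeros(latent_dim)
        self.dec_W = [_glorot(rng, a, b) for a, b in dec_dims]
        self.dec_b = [np.zeros(b) for _, b in dec_dims]

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return (
            self.enc_W + self.enc_b + [self.W_mu, self.b_mu, self.W_lv, self.b_lv]
            + self.dec_W + self.dec_b
        )

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward ------------------------------------------------------------

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and log-variance; deterministic given parameters."""
        h = np.atleast_2d(np.asarray(x, float))
        if h.shape[1] != self.input_dim:
            raise ValueError(
                f"input dim {h.shape[1]} != model input_dim {self.input_dim}"
            )
        for W, b in zip(self.enc_W, self.enc_b):
            h = np.maximum(h @ W + b, 0.0)
        return h @ self.W_mu + self.b_mu, h @ self.W_lv + self.b_lv

    def decode(self, z: np.ndarray) -> np.ndarray:
        h = np.atleast_2d(np.asarray(z, float))
        if h.shape[1] != self.latent_dim:
            raise ValueError(f"latent dim {h.shape[1]} != {self.latent_dim}")
        for i, (W, b) in enumerate(zip(self.dec_W, self.dec_b)):
            h = h @ W + b
            if i < len(self.dec_W) - 1:
                h = np.maximum(h, 0.0)
        return h

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Deterministic reconstruction through the posterior mean."""
        mu, _ = self.encode(x)
        out = self.decode(mu)
        return out[0] if np.asarray(x).ndim == 1 else out

    def encode_code(
        self, x: np.ndarray, patient_id: str | None = None, day: int | None = None
    ) -> LatentCode:
        mu, lv = self.encode(x)
        return LatentCode(mu=mu[0], logvar=lv[0], patient_id=patient_id, day=day)

    # -- backward -----------------------------------------------------------

    def _forward_cache(self, x: np.ndarray, eps: np.ndarray):
        acts_e = [x]
        h = x
        for W, b in zip(self.enc_W, self.enc_b):
            h = np.maximum(h @ W + b, 0.0)
            acts_e.append(h)
        mu = h @ self.W_mu + self.b_mu
        lv = h @ self.W_lv + self.b_lv
        z = mu + np.exp(0.5 * lv) * eps
        acts_d = [z]
        g = z
        for i, (W, b) in enumerate(zip(self.dec_W, self.dec_b)):
            g = g @ W + b
            if i < len(self.dec_W) - 1:
                g = np.maximum(g, 0.0)
            acts_d.append(g)
        return acts_e, mu, lv, z, acts_d

    def _backward(self, x, eps):
        """Gradient of the batch loss w.r.t. every parameter (hand-derived)."""
        B = x.shape[0]
        acts_e, mu, lv, z, acts_d = self._forward_cache(x, eps)
        x_hat = acts_d[-1]
        grads: dict[int, np.ndarray] = {}
        params = self.parameters()

        def gid(arr):
            for i, p in enumerate(params):
                if p is arr:
                    return i
            raise KeyError  # pragma: no cover

        # reconstruction path: the optimised objective weights the squared
        # error by its sum over features (unit-variance Gaussian decoder), so
        # beta = 1 is the standard ELBO; the reported VaeLoss keeps the
        # mean-MSE convention.
        delta = 2.0 * (x_hat - x) / B
        dW_dec = [None] * len(self.dec_W)
        db_dec = [None] * len(self.dec_b)
        for i in range(len(self.dec_W) - 1, -1, -1):
            inp = acts_d[i]
            dW_dec[i] = inp.T @ delta
            db_dec[i] = delta.sum(axis=0)
            delta = delta @ self.dec_W[i].T
            if i > 0:
                delta = delta * (acts_d[i] > 0)
        dz = delta  # gradient at z
        # KL path (batch mean of the analytic Gaussian KL)
        dmu = dz + self.beta * mu / B
        dlv = dz * 0.5 * np.exp(0.5 * lv) * eps \
            + self.beta * 0.5 * (np.exp(lv) - 1.0) / B
        henc = acts_e[-1]
        grads[gid(self.W_mu)] = henc.T @ dmu
        grads[gid(self.b_mu)] = dmu.sum(axis=0)
        grads[gid(self.W_lv)] = henc.T @ dlv
        grads[gid(self.b_lv)] = dlv.sum(axis=0)
        delta = (dmu @ self.W_mu.T + dlv @ self.W_lv.T) * (henc > 0)
        for i in range(len(self.enc_W) - 1, -1, -1):
            inp = acts_e[i]
            grads[gid(self.enc_W[i])] = inp.T @ delta
            grads[gid(self.enc_b[i])] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.enc_W[i].T) * (acts_e[i] > 0)
        for i, (gW, gb) in enumerate(zip(dW_dec, db_dec)):
            grads[gid(self.dec_W[i])] = gW
            grads[gid(self.dec_b[i])] = gb
        loss = vae_loss(x, x_hat, mu, lv, self.beta)
        return [grads[i] for i in range(len(params))], loss

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint: NPZ of parameters plus a JSON architecture descriptor."""
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path.with_suffix(".npz"), **arrays)
        desc = {
            "input_dim": self.input_dim, "hidden_sizes": list(self.hidden_sizes),
            "latent_dim": self.latent_dim, "beta": self.beta, "seed": self.seed,
            "epoch": self.epoch,
        }
        path.with_suffix(".json").write_text(json.dumps(desc, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "VaeModel":
        path = Path(path)
        desc = json.loads(path.with_suffix(".json").read_text())
        model = cls(
            desc["input_dim"], desc["hidden_sizes"], desc["latent_dim"],
            desc["beta"], desc["seed"],
        )
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
        model.epoch = desc.get("epoch", 0)
        return model


def build_vae(
    input_dim: int,
    hidden_sizes: Sequence[int] = (512, 256, 128),
    latent_dim: int = 16,
    beta: float = 1.0,
    seed: int = 0,
) -> VaeModel:
    """Construct a beta-VAE with seeded Glorot initialisation."""
    return VaeModel(input_dim, hidden_sizes, latent_dim, beta, seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    model: VaeModel,
    templates: np.ndarray,
    epochs: int = 100,
    batch: int = 128,
    lr: float = 1e-3,
    seed: int = 0,
    mode: str = "pretrain",
    val_frac: float = 0.10,
    patience: int = 20,
) -> VaeModel:
    """Stochastic-gradient training of the ELBO (Adam, seeded shuffling).

    ``mode='pretrain'`` trains from the current (typically fresh) weights on
    a large generic pool; ``mode='finetune'`` continues from pretrained
    weights on the cohort of interest — the two modes share the machinery
    and differ only in provenance bookkeeping.  A ``val_frac`` split drives
    early stopping (best-validation weights are restored); with 0 epochs the
    model is returned unchanged.
    """
    if mode not in ("pretrain", "finetune"):
        raise ValueError("mode must be 'pretrain' or 'finetune'")
    X = np.atleast_2d(np.asarray(templates, float))
    if X.shape[1] != model.input_dim:
        raise ValueError(f"template dim {X.shape[1]} != {model.input_dim}")
    if epochs == 0:
        return model
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    n_val = max(int(round(val_frac * n)), 1) if n >= 10 else 0
    perm = rng.permutation(n)
    Xval, Xtr = X[perm[:n_val]], X[perm[n_val:]]
    opt = _Adam(model.parameters(), lr=lr)
    best_val, best_state, since_best = np.inf, None, 0
    for _ in range(epochs):
        order = rng.permutation(Xtr.shape[0])
        ep_loss, nb = 0.0, 0
        for start in range(0, Xtr.shape[0], batch):
            xb = Xtr[order[start : start + batch]]
            eps = rng.standard_normal((xb.shape[0], model.latent_dim))
            grads, loss = model._backward(xb, eps)
            opt.step(model.parameters(), grads)
            # track the optimised (sum-scaled) objective
            ep_loss += loss.recon * model.input_dim + model.beta * loss.kl
            nb += 1
        model.epoch += 1
        model.history["train"].append(ep_loss / max(nb, 1))
        if n_val:
            mu, lv = model.encode(Xval)
            vl = vae_loss(Xval, model.decode(mu), mu, lv, model.beta)
            # early stopping tracks the optimised (sum-scaled) objective
            vloss = vl.recon * model.input_dim + model.beta * vl.kl
            model.history["val"].append(vloss)
            if vloss < best_val - 1e-6:
                best_val, since_best = vloss, 0
                best_state = [p.copy() for p in model.parameters()]
            else:
                since_best += 1
                if since_best >= patience:
                    break
    if best_state is not None:
        for p, s in zip(model.parameters(), best_state):
            p[...] = s
    return model


# ---------------------------------------------------------------------------
# Reconstruction metrics
# ---------------------------------------------------------------------------


@dataclass
class ReconMetrics:
    """Per-signal reconstruction summary (both signals min-max normalised)."""

    r: float
    rmse: float
    prd: float
    dtw: float


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Dynamic-time-warping cost: Euclidean local distance, unit steps.

    Classic O(n*m) dynamic programme with (i-1,j), (i,j-1), (i-1,j-1) moves;
    returns the accumulated cost of the optimal alignment path.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = a.size, b.size
    prev = np.full(m + 1, np.inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur = np.full(m + 1, np.inf)
        cost = np.abs(a[i - 1] - b)
        # cur[j] = cost[j-1] + min(prev[j], prev[j-1], cur[j-1])
        stacked = np.minimum(prev[1:], prev[:-1])
        acc = np.inf
        for j in range(1, m + 1):
            acc = cost[j - 1] + min(stacked[j - 1], acc)
            cur[j] = acc
        prev = cur
    return float(prev[m])


def reconstruction_metrics(
    x: np.ndarray, x_hat: np.ndarray, with_dtw: bool = True
) -> ReconMetrics:
    """Pearson r, RMSE, PRD (%) and DTW between signal and reconstruction.

    Both signals are min-max normalised first.  PRD uses the normalised
    input's raw energy in the denominator: 100 * sqrt(sum (x-x_hat)^2 /
    sum x^2).  A constant signal leaves r undefined (NaN).  ``with_dtw=False``
    skips the quadratic-time DTW (reported NaN) for bulk summaries.
    """
    x, x_hat = np.asarray(x, float).ravel(), np.asarray(x_hat, float).ravel()
    if x.size != x_hat.size:
        raise ValueError("signals must have equal length")
    xn, yn = _minmax(x), _minmax(x_hat)
    if np.std(xn) == 0 or np.std(yn) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(xn, yn)[0, 1])
    rmse = float(np.sqrt(np.mean((xn - yn) ** 2)))
    denom = float(np.sum(xn**2))
    prd = float(100.0 * np.sqrt(np.sum((xn - yn) ** 2) / denom)) if denom > 0 else np.nan
    dtw = dtw_distance(xn, yn) if with_dtw else np.nan
    return ReconMetrics(r=r, rmse=rmse, prd=prd, dtw=dtw)


def codes_to_frame(codes: Sequence[LatentCode]) -> "pd.DataFrame":
    """Latent codes as a tidy table: patient_id, day, AE0..AE15."""
    import pandas as pd

    rows = []
    for c in codes:
        row = {"patient_id": c.patient_id, "day": c.day}
        row.update({n: v for n, v in zip(c.names, c.mu)})
        rows.append(row)
    return pd.DataFrame(rows)
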