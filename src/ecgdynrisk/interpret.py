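"""Latent-space interpretation: factor traversal and latent correlations.

To see what a latent dimension encodes, its value in a reference latent
vector is swept across the cohort's 5th, 25th, 75th and 95th percentiles
while all other dimensions stay fixed, and each setting is decoded.  The
absolute difference between each decoded template and the reference
reconstruction, per sample, forms a heatmap localising the morphological
region the dimension controls (e.g. the T wave).  Complementarily, latent
variables are correlated against interpretable features — generator ground
truth or simple measurements taken from the templates themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .vae import VaeModel, latent_names

TRAVERSAL_PERCENTILES = (5, 25, 75, 95)


def latent_percentiles(
    codes: np.ndarray | pd.DataFrame,
    percentiles: Sequence[float] = TRAVERSAL_PERCENTILES,
    min_codes: int = 20,
) -> pd.DataFrame:
    """Empirical per-dimension percentiles of the cohort latent codes.

    ``codes`` is (n, latent_dim) or a tidy table with AE* columns.  Linear
    interpolation (NumPy default) between order statistics.  Returns a table
    indexed by latent name with one column per requested percentile.
    """
    if isinstance(codes, pd.DataFrame):
        cols = [c for c in codes.columns if c.startswith("AE")]
        mat = codes[cols].to_numpy(float)
        names = cols
    else:
        mat = np.atleast_2d(np.asarray(codes, float))
        names = list(latent_names(mat.shape[1]))
    if mat.shape[0] < min_codes:
        raise ValueError(f"need at least {min_codes} codes, got {mat.shape[0]}")
    vals = np.percentile(mat, percentiles, axis=0)  # (n_pct, latent_dim)
    return pd.DataFrame(
        vals.T, index=names, columns=[f"p{int(p)}" for p in percentiles]
    )


@dataclass
class TraversalResult:
    """Decoded templates and difference heatmap for one latent dimension."""

    latent_index: int
    reference: np.ndarray
    grid_values: np.ndarray            # one latent value per grid point
    reconstructions: np.ndarray        # (n_grid, template_len)
    reference_reconstruction: np.ndarray
    heatmap: np.ndarray                # (n_grid, template_len), >= 0

    def to_frame(self) -> pd.DataFrame:
        """Stacked long format: grid point, sample index, value, |diff|."""
        rows = []
        for gi, v in enumerate(self.grid_values):
            rows.append(
                pd.DataFrame(
                    {
                        "grid_value": v,
                        "sample_index": np.arange(self.reconstructions.shape[1]),
                        "reconstruction": self.reconstructions[gi],
                        "abs_diff": self.heatmap[gi],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def traverse_latent(
    model: VaeModel,
    j: int,
    grid_values: Sequence[float],
    reference: np.ndarray,
) -> TraversalResult:
    """Sweep latent dimension ``j`` over ``grid_values`` and decode.

    All other dimensions stay at the reference value; the heatmap is the
    per-sample absolute difference from the reference reconstruction.
    Setting a grid value equal to the reference's own j-th entry reproduces
    the reference reconstruction exactly.
    """
    reference = np.asarray(reference, float).reshape(-1)
    if reference.size != model.latent_dim:
        raise ValueError("reference length must equal the latent dimension")
    if not 0 <= j < model.latent_dim:
        raise ValueError(f"latent index {j} out of range")
    ref_recon = model.decode(reference)[0]
    grid = np.asarray(list(grid_values), float)
    zs = np.tile(reference, (grid.size, 1))
    zs[:, j] = grid
    recons = model.decode(zs)
    return TraversalResult(
        latent_index=j, reference=reference, grid_values=grid,
        reconstructions=recons, reference_reconstruction=ref_recon,
        heatmap=np.abs(recons - ref_recon),
    )


def traverse_all(
    model: VaeModel,
    codes: pd.DataFrame | np.ndarray,
    reference: np.ndarray | None = None,
) -> dict[int, TraversalResult]:
    """Traverse every latent dimension at the cohort percentiles.

    The default reference is the element-wise median of the cohort latent
    means — a 'typical' point of the latent space whose reconstruction
    serves as the mean waveform being perturbed.
    """
    pct = latent_percentiles(codes)
    if isinstance(codes, pd.DataFrame):
        mat = codes[[c for c in codes.columns if c.startswith("AE")]].to_numpy(float)
    else:
        mat = np.atleast_2d(np.asarray(codes, float))
    if reference is None:
        reference = np.median(mat, axis=0)
    return {
        j: traverse_latent(model, j, pct.iloc[j].to_numpy(), reference)
        for j in range(model.latent_dim)
    }


def correlate_latents(
    codes: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each latent with each interpretable feature.

    Rows must be aligned (same length, same order).  Zero-variance columns
    yield NaN entries.  The returned table is (latents x features); the
    number of complete pairs is in ``.attrs['n']``.
    """
    lat_cols = [c for c in codes.columns if c.startswith("AE")]
    feat_cols = [c for c in features.columns
                 if features[c].dtype.kind in "fi"]
    if len(codes) != len(features):
        raise ValueError("codes and features must have aligned rows")
    out = pd.DataFrame(index=lat_cols, columns=feat_cols, dtype=float)
    for lc in lat_cols:
        x = codes[lc].to_numpy(float)
        for fc in feat_cols:
            y = features[fc].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                out.loc[lc, fc] = np.nan
            else:
                out.loc[lc, fc] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    out.attrs["n"] = len(codes)
    return out


def template_measurements(
    waveform: np.ndarray,
    window: tuple[int, int],
    fs: int = 250,
    qrs_halfwidth_frac: float = 0.5,
) -> dict[str, float]:
    """Simple interpretable measurements from one (lead) mean-beat waveform.

    ``r_amplitude``: value at the R sample (the window's alignment point);
    ``qrs_width_s``: width of the region around R above half the R-to-
    baseline excursion; ``t_amplitude``: extremum in the 150-400 ms
    post-R region relative to the waveform median (sign preserved, so
    inverted T waves come out negative).
    """
    w = np.asarray(waveform, float)
    pre, _ = window
    baseline = float(np.median(w))
    r_amp = float(w[pre] - baseline)
    half = baseline + qrs_halfwidth_frac * r_amp
    above = w >= half if r_amp >= 0 else w <= half
    left = pre
    while left > 0 and above[left - 1]:
        left -= 1
    right = pre
    while right < w.size - 1 and above[right + 1]:
        right += 1
    t_lo, t_hi = pre + int(0.15 * fs), min(pre + int(0.40 * fs), w.size)
    seg = w[t_lo:t_hi] - baseline
    t_amp = float(seg[np.argmax(np.abs(seg))]) if seg.size else np.nan
    return {
        "r_amplitude": r_amp,
        "qrs_width_s": (right - left + 1) / fs,
        "t_amplitude": t_amp,
    }


def plot_traversal_heatmap(
    result: TraversalResult, path: str | Path, percentile_labels: Sequence[str] = ()
) -> None:
    """Render the traversal as overlaid reconstructions plus a heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(percentile_labels) or [f"{v:.2f}" for v in result.grid_values]
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(8, 5), sharex=True,
        gridspec_kw={"height_ratios": [2, 1]},
    )
    ax0.plot(result.reference_reconstruction, color="black", lw=1.5,
             label="reference")
    for gi, lab in enumerate(labels):
        ax0.plot(result.reconstructions[gi], lw=0.9, label=lab)
    ax0.legend(fontsize=7, ncol=3)
    ax0.set_ylabel("normalised amplitude")
    ax1.imshow(result.heatmap, aspect="auto", cmap="magma",
               interpolation="nearest")
    ax1.set_yticks(range(len(labels)), labels)
    ax1.set_xlabel("sample index (leads concatenated)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
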