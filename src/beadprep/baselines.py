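"""Simplified comparator pipelines: Illumina, Noob and dasen-like.

* Illumina: subtract the 5th percentile of each channel's negative-control
  intensities; values below that percentile get a small constant.  Dye
  bias is removed by rescaling each sample's channels so its control
  red/green ratio matches a reference sample's.
* Noob: normal-exponential convolution (normexp) background correction
  with the background normal estimated from out-of-band reads, followed
  by the Illumina-style dye step with the across-sample mean control
  intensities as the reference.
* dasen-like: add the per-sample offset between type II and type I
  intensity medians to type I intensities, then quantile-normalize within
  {meth, unmeth} x {I, II} subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .core import MethylDataset, oob_intensities
from .manifest import ProbeManifest
from .normalization import _qnorm_matrix

__all__ = [
    "NormexpParams",
    "illumina_bgcorrect",
    "illumina_dye_norm",
    "noob_correct",
    "dasen",
    "illumina_correct_raw",
    "noob_correct_raw",
]

EPS = 1.0  # "constant close to 0" for the Illumina floor
FLOOR = 1.0


@dataclass(frozen=True)
class NormexpParams:
    mu_b: float
    sigma_b: float
    alpha: float  # exponential signal mean

    def __post_init__(self) -> None:
        if not (self.sigma_b > 0 and self.alpha > 0):
            raise ValueError("sigma_b and alpha must be positive")


def illumina_bgcorrect(channel: np.ndarray, negctrls: np.ndarray) -> np.ndarray:
    """Subtract the 5th percentile of the channel's negative controls."""
    neg = np.asarray(negctrls, dtype=float)
    if neg.size < 10:
        raise ValueError("need at least 10 negative controls")
    q05 = float(np.percentile(neg, 5))
    x = np.asarray(channel, dtype=float)
    return np.where(x < q05, EPS, x - q05)


def illumina_dye_norm(raw, reference: int | str = 0):
    """Scale each sample's green channel so control red/green ratios match.

    ``reference`` is a sample index, or ``"mean"`` for the across-sample
    average control intensities (the Noob variant).
    """
    red_c = raw.normctrl_red.mean(axis=0)
    grn_c = raw.normctrl_grn.mean(axis=0)
    if (red_c <= 0).any() or (grn_c <= 0).any():
        raise ValueError("zero control intensity sum")
    ratio = red_c / grn_c
    if reference == "mean":
        ref_ratio = float(red_c.mean() / grn_c.mean())
    else:
        ref_ratio = float(ratio.iloc[reference] if isinstance(reference, int) else ratio[reference])
    out = raw.copy()
    for sample in raw.samples:
        scale = float(ratio[sample]) / ref_ratio
        for block in ("grn", "negctrl_grn", "normctrl_grn", "bisulfite_grn"):
            df = getattr(out, block)
            df[sample] = df[sample].to_numpy() * scale
    return out


def _normexp_posterior_mean(x: np.ndarray, p: NormexpParams) -> np.ndarray:
    """Closed-form E[S | X = x] for the normexp model, floored.

    The posterior of S given X=x is N(x - mu_b - sigma_b^2/alpha,
    sigma_b^2) truncated at 0; the expectation uses the scaled
    complementary error function for numerical stability in the far tail.
    """
    mu_sf = x - p.mu_b - p.sigma_b**2 / p.alpha
    z = mu_sf / p.sigma_b
    # phi(z)/Phi(z) computed via erfcx to stay finite for very negative z
    ratio = np.sqrt(2.0 / np.pi) / special.erfcx(-z / np.sqrt(2.0))
    return np.maximum(mu_sf + p.sigma_b * ratio, FLOOR)


def noob_correct(inband: np.ndarray, oob: np.ndarray) -> np.ndarray:
    """Normexp background correction with out-of-band background estimates."""
    oob = np.asarray(oob, dtype=float).ravel()
    if oob.size < 100:
        raise ValueError(f"need at least 100 out-of-band values, got {oob.size}")
    mu_b = float(oob.mean())
    sigma_b = float(oob.std(ddof=1))
    if sigma_b == 0:
        raise ValueError("degenerate out-of-band variance")
    x = np.asarray(inband, dtype=float)
    alpha = max(float(x.mean()) - mu_b, 10.0)  # exponential-mean MLE given (mu_b, sigma_b)
    return _normexp_posterior_mean(x, NormexpParams(mu_b, sigma_b, alpha))


def dasen(methyl: MethylDataset, manifest: ProbeManifest) -> MethylDataset:
    """Type I/II intensity offset adjustment plus subset quantile normalization."""
    if len(methyl.sample_ids) < 2:
        raise ValueError("dasen needs at least 2 samples")
    df = manifest.df.loc[methyl.probe_ids]
    is_i = (df["design_type"] == "I").to_numpy()
    is_ii = ~is_i
    out = methyl.copy()
    for signal in ("meth", "unmeth"):
        mat = getattr(out, signal)
        offset = np.median(mat[is_ii], axis=0) - np.median(mat[is_i], axis=0)
        # no flooring: rank-based normalization replaces values anyway, and
        # clipping would create ties that break exact column equality
        mat[is_i] = mat[is_i] + offset[None, :]
        for sel in (is_i, is_ii):
            if sel.sum() >= 2:
                mat[sel] = _qnorm_matrix(mat[sel], out.mask[sel])
    return out


# ---------------------------------------------------------------------------
# whole-array application helpers used by the pipeline driver
# ---------------------------------------------------------------------------

def illumina_correct_raw(raw, reference: int | str = 0):
    """Illumina background subtraction then reference dye normalization."""
    out = raw.copy()
    for sample in raw.samples:
        neg_r = raw.negctrl_red[sample].to_numpy()
        neg_g = raw.negctrl_grn[sample].to_numpy()
        for block, neg in (
            ("red", neg_r),
            ("normctrl_red", neg_r),
            ("bisulfite_red", neg_r),
            ("grn", neg_g),
            ("normctrl_grn", neg_g),
            ("bisulfite_grn", neg_g),
        ):
            df = getattr(out, block)
            df[sample] = illumina_bgcorrect(df[sample].to_numpy(), neg)
    return illumina_dye_norm(out, reference=reference)


def noob_correct_raw(raw, manifest: ProbeManifest):
    """Per-sample, per-channel normexp correction then mean-reference dye step."""
    out = raw.copy()
    for channel in ("Red", "Grn"):
        oob = oob_intensities(raw, manifest, channel)
        inband_addr = manifest.inband_addresses(channel)
        mat = getattr(out, "red" if channel == "Red" else "grn")
        ctrl_blocks = (
            ("normctrl_red", "bisulfite_red") if channel == "Red" else ("normctrl_grn", "bisulfite_grn")
        )
        for sample in raw.samples:
            o = oob[sample].to_numpy()
            mu_b = float(o.mean())
            sigma_b = float(o.std(ddof=1))
            if sigma_b == 0:
                raise ValueError(f"sample {sample}: degenerate out-of-band variance")
            inb = mat.loc[inband_addr, sample].to_numpy()
            alpha = max(float(inb.mean()) - mu_b, 10.0)
            params = NormexpParams(mu_b, sigma_b, alpha)
            mat.loc[inband_addr, sample] = _normexp_posterior_mean(inb, params)
            for block in ctrl_blocks:
                df = getattr(out, block)
                df[sample] = _normexp_posterior_mean(df[sample].to_numpy(), params)
    return illumina_dye_norm(out, reference="mean")
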