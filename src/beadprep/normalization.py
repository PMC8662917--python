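"""Inter-array subset quantile normalization and RCP probe-type calibration.

Quantile normalization is applied to intensities within each of six
subsets — {methylated, unmethylated} x {type I Red, type I Grn, type II} —
so that chemically distinct probe populations are never pooled.

RCP (regression on correlated probes) removes the compression of type II
beta distributions relative to type I.  Pairs of type I and type II
probes less than ``max_dist`` bp apart measure near-identical methylation,
so the quantile-quantile relation between their betas identifies the
distortion; an OLS fit on the logit scale of the paired empirical
quantiles gives a per-sample affine calibration that is applied to every
type II beta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import BetaMatrix, MethylDataset
from .manifest import ProbeManifest

__all__ = [
    "RcpPair",
    "RcpCalibration",
    "quantile_normalize_subsets",
    "find_rcp_pairs",
    "fit_rcp",
    "apply_rcp",
]

log = logging.getLogger(__name__)

LOGIT_CLIP = 1e-6
N_QUANTILES = 500


@dataclass(frozen=True)
class RcpPair:
    probe_i: str  # type I member
    probe_ii: str  # type II member
    distance: int


@dataclass(frozen=True)
class RcpCalibration:
    intercept: float
    slope: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("RCP slope must be positive (order-preserving)")


# ---------------------------------------------------------------------------
# subset quantile normalization
# ---------------------------------------------------------------------------

def _qnorm_matrix(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of ``values`` in place of a copy.

    Masked entries are excluded from the quantile pool and left unchanged.
    The target distribution is the across-sample mean of order statistics
    (columns with missing entries contribute via linear interpolation of
    their quantile function); rank ties map to the average target value.
    """
    n, k = values.shape
    out = values.copy()
    counts = (~mask).sum(axis=0)
    grid = np.linspace(0.0, 1.0, n)
    # target: mean over columns of each column's empirical quantile function
    target = np.zeros(n)
    for j in range(k):
        col = values[~mask[:, j], j]
        if col.size == n:
            target += np.sort(col)  # exact order statistics for complete columns
        else:
            target += np.quantile(col, grid)
    target /= k
    for j in range(k):
        obs = ~mask[:, j]
        col = values[obs, j]
        nc = col.size
        r = rankdata(col, method="average")  # 1..nc, fractional on ties
        # scale factor is exactly 1.0 when the column is complete, keeping
        # the fixed-point/idempotence property bit-exact
        pos = (r - 1.0) * ((n - 1.0) / (nc - 1.0)) if nc > 1 else np.zeros_like(r)
        out[obs, j] = np.interp(pos, np.arange(n), target)
    return out


def quantile_normalize_subsets(methyl: MethylDataset, manifest: ProbeManifest) -> MethylDataset:
    """Quantile-normalize meth and unmeth within the six design subsets."""
    if len(methyl.sample_ids) < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    df = manifest.df.loc[methyl.probe_ids]
    strata = {
        "I-Red": ((df["design_type"] == "I") & (df["color_channel"] == "Red")).to_numpy(),
        "I-Grn": ((df["design_type"] == "I") & (df["color_channel"] == "Grn")).to_numpy(),
        "II": (df["design_type"] == "II").to_numpy(),
    }
    out = methyl.copy()
    for name, sel in strata.items():
        if sel.sum() < 2:
            log.warning("subset %s has fewer than 2 probes; skipped", name)
            continue
        for signal in ("meth", "unmeth"):
            mat = getattr(out, signal)
            mat[sel] = _qnorm_matrix(mat[sel], out.mask[sel])
    return out


# ---------------------------------------------------------------------------
# RCP
# ---------------------------------------------------------------------------

def find_rcp_pairs(manifest: ProbeManifest, max_dist: int = 50) -> list[RcpPair]:
    """Type I / type II probe pairs closer than ``max_dist`` bp.

    Each type II probe is paired with its nearest type I probe on the same
    chromosome (ties broken toward the lower genomic position).
    """
    df = manifest.df.reset_index(drop=True)
    if df["position"].isna().any():
        raise ValueError("manifest lacks genomic coordinates")
    pairs: list[RcpPair] = []
    for chrom, sub in df.groupby("chrom", sort=False):
        t1 = sub[sub["design_type"] == "I"].sort_values(["position", "probe_id"])
        t2 = sub[sub["design_type"] == "II"]
        if t1.empty or t2.empty:
            continue
        pos1 = t1["position"].to_numpy(dtype=np.int64)
        ids1 = t1["probe_id"].to_numpy()
        pos2 = t2["position"].to_numpy(dtype=np.int64)
        ids2 = t2["probe_id"].to_numpy()
        # nearest sorted type I neighbour on each side of every type II probe
        right = np.searchsorted(pos1, pos2)
        left = np.clip(right - 1, 0, len(pos1) - 1)
        right = np.clip(right, 0, len(pos1) - 1)
        d_left = np.abs(pos1[left] - pos2)
        d_right = np.abs(pos1[right] - pos2)
        # tie (equidistant) -> lower position, i.e. the left neighbour
        take_left = d_left <= d_right
        j = np.where(take_left, left, right)
        dmin = np.where(take_left, d_left, d_right)
        for m in np.flatnonzero(dmin < max_dist):
            pairs.append(
                RcpPair(probe_i=str(ids1[j[m]]), probe_ii=str(ids2[m]), distance=int(dmin[m]))
            )
    return pairs


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, LOGIT_CLIP, 1.0 - LOGIT_CLIP)
    return np.log(p / (1.0 - p))


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def fit_rcp(beta: BetaMatrix, pairs: list[RcpPair], min_pairs: int = 50) -> dict[str, RcpCalibration]:
    """Per-sample logit-scale quantile calibration from RCP pairs."""
    idx = {p: i for i, p in enumerate(beta.probe_ids)}
    ii = np.array([idx[p.probe_i] for p in pairs if p.probe_i in idx and p.probe_ii in idx])
    jj = np.array([idx[p.probe_ii] for p in pairs if p.probe_i in idx and p.probe_ii in idx])
    grid = (np.arange(N_QUANTILES) + 0.5) / N_QUANTILES
    out: dict[str, RcpCalibration] = {}
    for k, sample in enumerate(beta.sample_ids):
        bi = beta.values[ii, k]
        bii = beta.values[jj, k]
        ok = ~(np.isnan(bi) | np.isnan(bii))
        if ok.sum() < min_pairs:
            raise ValueError(
                f"sample {sample}: only {int(ok.sum())} usable RCP pairs (< {min_pairs})"
            )
        qi = _logit(np.quantile(bi[ok], grid))
        qii = _logit(np.quantile(bii[ok], grid))
        if np.ptp(qii) == 0 or np.ptp(qi) == 0:
            raise ValueError(f"sample {sample}: degenerate variance in RCP quantiles")
        m, c = np.polyfit(qii, qi, 1)
        if m <= 0:
            raise ValueError(f"sample {sample}: non-positive RCP slope {m:.3f}")
        out[sample] = RcpCalibration(intercept=float(c), slope=float(m), n_pairs=int(ok.sum()))
    return out


def apply_rcp(
    beta: BetaMatrix, calib: dict[str, RcpCalibration], manifest: ProbeManifest
) -> BetaMatrix:
    """Calibrate every type II beta through the per-sample logit-affine map."""
    out = beta.copy()
    df = manifest.df.loc[beta.probe_ids]
    sel = (df["design_type"] == "II").to_numpy()
    for k, sample in enumerate(beta.sample_ids):
        cal = calib[sample]
        col = out.values[sel, k]
        ok = ~np.isnan(col)
        z = _logit(col[ok])
        col[ok] = np.clip(_expit(cal.intercept + cal.slope * z), 0.0, 1.0)
        out.values[sel, k] = col
    return out
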