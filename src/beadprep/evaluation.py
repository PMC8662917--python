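"""Concordance and reliability statistics for duplicate and standard samples.

Methylation betas are bimodal (most CpGs near 0 or 1), so the plain
Pearson correlation between any two arrays — even unrelated people — is
driven by the per-probe means and typically exceeds 0.98.  The statistics
here remove that artifact:

* centered correlation — the per-probe population mean is subtracted and
  the correlation computed on the residuals (0 expected for unrelated
  samples, 1 for perfect duplicates);
* mean absolute difference between duplicate measurements;
* per-probe one-way random-effects ICC(1,1) from the duplicate ANOVA,
  with the conventional reliability classes (< 0.5 poor, 0.5-0.75
  moderate, 0.75-0.9 good, >= 0.9 excellent);
* KDE mode of a beta distribution and its mean deviation from nominal
  levels in titration standards;
* paired two-sided Wilcoxon signed-rank test for pipeline comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DuplicateDesign",
    "centered_correlation",
    "mean_abs_diff",
    "icc_oneway",
    "classify_icc",
    "density_mode",
    "mode_deviation",
    "paired_wilcoxon",
]

log = logging.getLogger(__name__)

ICC_CLASSES = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent"))
KDE_GRID = np.linspace(-0.05, 1.05, 512)


@dataclass(frozen=True)
class DuplicateDesign:
    pairs: list[tuple[str, str]]
    population: list[str]

    def __post_init__(self) -> None:
        if not self.population:
            raise ValueError("population must be non-empty")
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"pair members must be distinct ({a})")


def centered_correlation(
    beta_a: np.ndarray, beta_b: np.ndarray, probe_means: np.ndarray
) -> float:
    """Pearson correlation of mean-centered betas over joint probes.

    Returns NaN when either residual vector has zero variance or fewer
    than 3 joint probes are available.
    """
    a = np.asarray(beta_a, dtype=float)
    b = np.asarray(beta_b, dtype=float)
    m = np.asarray(probe_means, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b) | np.isnan(m))
    if ok.sum() < 3:
        return float("nan")
    ra = a[ok] - m[ok]
    rb = b[ok] - m[ok]
    if np.std(ra) == 0 or np.std(rb) == 0:
        return float("nan")
    return float(np.corrcoef(ra, rb)[0, 1])


def mean_abs_diff(beta_a: np.ndarray, beta_b: np.ndarray) -> float:
    """Mean |beta_a - beta_b| over jointly non-missing probes."""
    a = np.asarray(beta_a, dtype=float)
    b = np.asarray(beta_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.any():
        return float("nan")
    return float(np.mean(np.abs(a[ok] - b[ok])))


def icc_oneway(duplicates: np.ndarray, min_pairs: int = 3) -> np.ndarray:
    """One-way random-effects ICC(1,1) per probe.

    ``duplicates`` has shape (probes, pairs, 2).  With k = 2 replicates
    per pair the estimator is (MSB - MSW) / (MSB + MSW); probes with
    fewer than ``min_pairs`` complete pairs get NaN.  Negative estimates
    are reported as-is.
    """
    x = np.asarray(duplicates, dtype=float)
    if x.ndim != 3 or x.shape[2] != 2:
        raise ValueError("expected array of shape (probes, pairs, 2)")
    complete = ~np.isnan(x).any(axis=2)  # (probes, pairs)
    n = complete.sum(axis=1).astype(float)
    xz = np.where(complete[:, :, None], x, 0.0)
    pair_mean = xz.mean(axis=2)
    grand = np.where(n > 0, (pair_mean * complete).sum(axis=1) / np.maximum(n, 1), np.nan)
    ssb = (((pair_mean - grand[:, None]) ** 2) * complete).sum(axis=1)
    ssw = ((xz[:, :, 0] - xz[:, :, 1]) ** 2 / 2.0 * complete).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        msb = ssb * 2.0 / (n - 1.0)
        msw = ssw / n
        icc = (msb - msw) / (msb + msw)
    icc[n < min_pairs] = np.nan
    return icc


def classify_icc(icc: float) -> str:
    """Reliability class; boundaries 0.5/0.75/0.9 assigned upward."""
    if np.isnan(icc):
        raise ValueError("ICC is missing")
    for bound, name in ICC_CLASSES:
        if icc < bound:
            return name
    raise AssertionError("unreachable")


def density_mode(betas: np.ndarray, design_type: np.ndarray | None = None,
                 stratum: str | None = None) -> float:
    """Location of the global KDE maximum of a beta distribution.

    Gaussian kernel, Silverman bandwidth, 512-point grid on [-0.05, 1.05];
    ties break toward the lower mode.  ``stratum`` ("I" or "II") restricts
    to one probe design given the matching ``design_type`` array.
    """
    v = np.asarray(betas, dtype=float).ravel()
    if stratum is not None:
        if design_type is None:
            raise ValueError("stratum filter requires design_type")
        v = v[np.asarray(design_type).ravel() == stratum]
    v = v[~np.isnan(v)]
    if v.size < 100:
        raise ValueError(f"need at least 100 betas, got {v.size}")
    if np.ptp(v) == 0:
        return float(v[0])  # degenerate bandwidth guard
    kde = stats.gaussian_kde(v, bw_method="silverman")
    dens = kde(KDE_GRID)
    return float(np.clip(KDE_GRID[int(np.argmax(dens))], 0.0, 1.0))


def mode_deviation(betas_by_sample: list[np.ndarray], nominal_levels: list[float]) -> float:
    """Mean |KDE mode - nominal level| across titration samples."""
    if len(betas_by_sample) != len(nominal_levels):
        raise ValueError("one nominal level per sample required")
    devs = [
        abs(density_mode(b) - lvl) for b, lvl in zip(betas_by_sample, nominal_levels)
    ]
    return float(np.mean(devs))


def paired_wilcoxon(stats_a: np.ndarray, stats_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired statistics."""
    a = np.asarray(stats_a, dtype=float)
    b = np.asarray(stats_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    if np.all(d == 0):
        log.warning("all paired differences are ties; p = 1")
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(a, b, alternative="two-sided")
    return float(res.pvalue)
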