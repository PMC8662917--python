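"""Quality control: detection p-values, masking, sample flags, imputation.

Thresholds follow the standard screen for these arrays: a data point is
excluded when its detection p-value exceeds 1e-6 or it was measured from
fewer than 3 beads; a sample is flagged when more than 5% of its data
points are low-quality or its mean bisulfite-conversion control intensity
falls below 5500.  All comparisons are strict, exactly as stated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import BetaMatrix, MethylDataset

__all__ = [
    "QCThresholds",
    "QCReport",
    "detection_pvalue",
    "mask_low_quality",
    "flag_samples",
    "impute_masked",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    detection_p_max: float = 1e-6
    min_beads: int = 3
    max_lowq_fraction: float = 0.05
    min_bisulfite_intensity: float = 5500.0

    def __post_init__(self) -> None:
        if not (
            self.detection_p_max > 0
            and self.min_beads > 0
            and 0 < self.max_lowq_fraction < 1
            and self.min_bisulfite_intensity > 0
        ):
            raise ValueError("invalid QC thresholds")


@dataclass
class QCReport:
    samples: pd.DataFrame  # fraction_lowq, mean_bisulfite_intensity, flagged, reasons
    mask: np.ndarray  # probe x sample
    probe_lowq_fraction: np.ndarray  # fraction of samples masked, per probe
    unimputable_probes: list[str] = field(default_factory=list)


def detection_pvalue(
    methyl: MethylDataset,
    negctrl_red: pd.DataFrame,
    negctrl_grn: pd.DataFrame,
) -> np.ndarray:
    """Upper-tail probability of total signal under the background null.

    Per sample, the null for M+U is normal with mean ``mu_R + mu_G`` and
    variance ``sd_R^2 + sd_G^2`` estimated from that sample's negative
    controls.
    """
    if len(negctrl_red) < 10 or len(negctrl_grn) < 10:
        raise ValueError("need at least 10 negative controls per channel")
    total = methyl.meth + methyl.unmeth
    p = np.empty_like(total)
    for k, sample in enumerate(methyl.sample_ids):
        r = negctrl_red[sample].to_numpy(dtype=float)
        g = negctrl_grn[sample].to_numpy(dtype=float)
        loc = r.mean() + g.mean()
        scale = float(np.sqrt(r.std(ddof=1) ** 2 + g.std(ddof=1) ** 2))
        if scale == 0:
            raise ValueError(f"sample {sample}: negative controls have zero variance")
        p[:, k] = stats.norm.sf(total[:, k], loc=loc, scale=scale)
    return p


def mask_low_quality(
    methyl: MethylDataset,
    nbeads: np.ndarray,
    pvals: np.ndarray,
    thresholds: QCThresholds = QCThresholds(),
) -> MethylDataset:
    """Union the existing mask with the detection-p / bead-count screen."""
    if nbeads.shape != methyl.meth.shape or pvals.shape != methyl.meth.shape:
        raise ValueError("nbeads/pvals shape does not match dataset")
    out = methyl.copy()
    out.mask |= (pvals > thresholds.detection_p_max) | (nbeads < thresholds.min_beads)
    return out


def flag_samples(
    mask: np.ndarray,
    sample_ids: list[str],
    bisulfite_intensity: pd.Series | None,
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Flag samples with too many low-quality points or dim bisulfite controls."""
    frac = mask.mean(axis=0)
    rows = []
    for k, sample in enumerate(sample_ids):
        reasons: list[str] = []
        if frac[k] > thresholds.max_lowq_fraction:
            reasons.append("lowq_fraction")
        if bisulfite_intensity is None:
            log.warning("no bisulfite controls; intensity flag skipped")
            bis = np.nan
            reasons.append("no_bisulfite_controls")
        else:
            bis = float(bisulfite_intensity[sample])
            if bis < thresholds.min_bisulfite_intensity:
                reasons.append("bisulfite_intensity")
        rows.append(
            {
                "sample_id": sample,
                "fraction_lowq": float(frac[k]),
                "mean_bisulfite_intensity": bis,
                "flagged": bool(reasons),
                "reasons": ",".join(reasons),
            }
        )
    return QCReport(
        samples=pd.DataFrame(rows).set_index("sample_id"),
        mask=mask,
        probe_lowq_fraction=mask.mean(axis=1),
    )


def impute_masked(beta: BetaMatrix) -> tuple[BetaMatrix, list[str]]:
    """Fill missing betas with the probe's across-sample median.

    Fully-missing probe rows are left missing and reported back rather
    than fabricated.  Observed values are never altered.
    """
    out = beta.copy()
    v = out.values
    missing = np.isnan(v)
    unimputable: list[str] = []
    with np.errstate(all="ignore"):
        med = np.nanmedian(np.where(missing, np.nan, v), axis=1)
    for i in np.flatnonzero(missing.any(axis=1)):
        if np.isnan(med[i]):
            unimputable.append(out.probe_ids[i])
            continue
        v[i, missing[i]] = med[i]
    return out, unimputable
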