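"""RELIC-style dye-bias correction.

Cy3 (green) and Cy5 (red) fluorescence have different gains, which biases
betas of type II probes and of type I probes in opposite channels.  Paired
internal normalization controls interrogate the same target in both
channels, so on the log scale their red and green intensities are related
by an affine map per array.  That map, ``log(red) = a + b*log(grn)``, is
fitted by OLS per sample and then applied to every green intensity on the
array, putting green on the red scale (red is the reference channel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LogLinearMap", "extract_control_pairs", "fit_relic", "apply_relic", "relic_correct_raw"]

PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class LogLinearMap:
    intercept: float
    slope: float
    n_controls: int
    r2: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("RELIC slope must be positive")


def extract_control_pairs(raw, sample: str) -> np.ndarray:
    """(n_controls, 2) array of (red, grn) control intensities + pseudocount."""
    if len(raw.normctrl_red) == 0:
        raise ValueError("no paired normalization controls in dataset")
    red = raw.normctrl_red[sample].to_numpy(dtype=float) + PSEUDOCOUNT
    grn = raw.normctrl_grn[sample].to_numpy(dtype=float) + PSEUDOCOUNT
    pairs = np.column_stack([red, grn])
    if len(pairs) < 10:
        raise ValueError(f"insufficient dye controls: {len(pairs)} < 10")
    return pairs


def fit_relic(pairs: np.ndarray) -> LogLinearMap:
    """OLS of log(red) on log(grn) over control pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if len(pairs) < 10:
        raise ValueError(f"insufficient dye controls: {len(pairs)} < 10")
    lr = np.log(pairs[:, 0])
    lg = np.log(pairs[:, 1])
    if np.ptp(lg) == 0:
        raise ValueError("zero variance in log green control intensities")
    b, a = np.polyfit(lg, lr, 1)
    resid = lr - (a + b * lg)
    sst = float(np.sum((lr - lr.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    return LogLinearMap(intercept=float(a), slope=float(b), n_controls=len(pairs), r2=r2)


def apply_relic(grn: np.ndarray, m: LogLinearMap) -> np.ndarray:
    """Map green intensities onto the red scale; red stays untouched."""
    g = np.asarray(grn, dtype=float)
    out = np.exp(m.intercept + m.slope * np.log(g + PSEUDOCOUNT)) - PSEUDOCOUNT
    return np.maximum(out, 0.0)


def relic_correct_raw(raw, audit: dict | None = None):
    """Fit and apply per-sample dye correction to all green intensities.

    Corrects the probe green matrix and every green control block (so a
    refit on corrected controls is the identity map).  Returns the
    corrected dataset and per-sample fitted maps.
    """
    out = raw.copy()
    maps: dict[str, LogLinearMap] = {}
    for sample in raw.samples:
        pairs = extract_control_pairs(raw, sample)
        m = fit_relic(pairs)
        maps[sample] = m
        for block in ("grn", "negctrl_grn", "normctrl_grn", "bisulfite_grn"):
            df = getattr(out, block)
            df[sample] = apply_relic(df[sample].to_numpy(), m)
    if audit is not None:
        audit["relic"] = {
            s: {"intercept": m.intercept, "slope": m.slope, "r2": m.r2, "n": m.n_controls}
            for s, m in maps.items()
        }
    return out, maps
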