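"""Pipeline orchestration: preprocess, evaluate, compare.

Stage order for the full model-based pipeline: background correction,
dye-bias correction, optional inter-array quantile normalization,
probe-type (RCP) calibration, then quality control, filtering of
low-quality data points and imputation.  Detection p-values and bead
counts are taken from the raw signals before any correction; the
resulting mask is applied to the final betas.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import baselines, relic
from .background import enmix_correct_raw
from .core import BetaMatrix, MethylDataset, RawDataset, compute_beta, probe_nbeads, to_methyl
from .evaluation import (
    centered_correlation,
    icc_oneway,
    mean_abs_diff,
    paired_wilcoxon,
)
from .manifest import ProbeManifest
from .normalization import apply_rcp, find_rcp_pairs, fit_rcp, quantile_normalize_subsets
from .qc import QCReport, QCThresholds, detection_pvalue, flag_samples, impute_masked, mask_low_quality

__all__ = ["PipelineConfig", "PipelineResult", "PIPELINES", "run_pipeline", "run_evaluation", "run_comparison"]

log = logging.getLogger(__name__)

PIPELINES = ("enmix", "illumina", "noob", "dasen", "raw")


@dataclass
class PipelineConfig:
    pipeline: str = "enmix"
    bgcorr: bool | None = None  # None = pipeline default
    dyecorr: bool | None = None
    qnorm: bool = False  # inter-array normalization, off unless samples homogeneous
    rcp: bool | None = None
    qc: bool = True
    impute: bool | None = None
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    rcp_max_dist: int = 50
    beta_offset: float = 100.0
    seed: int = 0
    n_workers: int = 1
    fit_subsample: int | None = 4000

    def __post_init__(self) -> None:
        if self.pipeline not in PIPELINES:
            raise ValueError(
                f"unknown pipeline {self.pipeline!r}; valid: {', '.join(PIPELINES)}"
            )

    def to_yaml(self) -> str:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = QCThresholds(**d["thresholds"])
        return cls(**d)


@dataclass
class PipelineResult:
    beta: BetaMatrix
    qc: QCReport | None
    audit: dict


def run_pipeline(raw: RawDataset, manifest: ProbeManifest, config: PipelineConfig) -> PipelineResult:
    """Run one named preprocessing pipeline end to end."""
    audit: dict = {"pipeline": config.pipeline, "stages": [], "timing": {}}
    t0 = time.time()

    def stage(name: str) -> None:
        audit["stages"].append(name)
        audit["timing"][name] = round(time.time() - t0, 3)

    # QC inputs from raw signals, before any correction
    methyl_raw = to_methyl(raw, manifest)
    pvals = nbeads = None
    if config.qc:
        pvals = detection_pvalue(methyl_raw, raw.negctrl_red, raw.negctrl_grn)
        nbeads = probe_nbeads(raw, manifest)
        stage("detection_p")

    name = config.pipeline
    data = raw
    if name == "enmix":
        if config.bgcorr is not False:
            data, bg_audit = enmix_correct_raw(
                data,
                manifest,
                fit_subsample=config.fit_subsample,
                seed=config.seed,
                n_workers=config.n_workers,
            )
            audit["background"] = {
                s: {
                    lab: {
                        "bg_mu": m.bg.mu,
                        "bg_sigma": m.bg.sigma,
                        "pi_exp": m.sig.pi_exp,
                        "lambda": m.sig.lam,
                        "mu_s": m.sig.mu_s,
                        "sigma_s": m.sig.sigma_s,
                        "converged": m.sig.converged,
                    }
                    for lab, m in mods.items()
                }
                for s, mods in bg_audit.items()
            }
            stage("enmix_background")
        if config.dyecorr is not False:
            data, _ = relic.relic_correct_raw(data, audit)
            stage("relic")
        methyl = to_methyl(data, manifest)
        if config.qnorm:
            methyl = quantile_normalize_subsets(methyl, manifest)
            stage("quantile_normalization")
        beta = compute_beta(methyl, offset=config.beta_offset)
        if config.rcp is not False:
            pairs = find_rcp_pairs(manifest, max_dist=config.rcp_max_dist)
            try:
                calib = fit_rcp(beta, pairs)
                beta = apply_rcp(beta, calib, manifest)
                audit["rcp"] = {
                    s: {"intercept": c.intercept, "slope": c.slope, "n_pairs": c.n_pairs}
                    for s, c in calib.items()
                }
            except ValueError as err:
                log.warning("RCP skipped: %s", err)
                audit["rcp"] = {"skipped": str(err)}
            stage("rcp")
    elif name == "illumina":
        data = baselines.illumina_correct_raw(data, reference=0)
        stage("illumina_correction")
        beta = compute_beta(to_methyl(data, manifest), offset=config.beta_offset)
    elif name == "noob":
        data = baselines.noob_correct_raw(data, manifest)
        stage("noob_correction")
        beta = compute_beta(to_methyl(data, manifest), offset=config.beta_offset)
    elif name == "dasen":
        methyl = baselines.dasen(to_methyl(data, manifest), manifest)
        stage("dasen")
        beta = compute_beta(methyl, offset=config.beta_offset)
    else:  # raw
        beta = compute_beta(methyl_raw, offset=config.beta_offset)
        stage("raw_beta")

    qc_report = None
    if config.qc:
        masked = mask_low_quality(methyl_raw, nbeads, pvals, config.thresholds)
        beta.values[masked.mask] = np.nan
        qc_report = flag_samples(
            masked.mask, list(raw.samples), data.bisulfite_intensity(), config.thresholds
        )
        stage("qc_mask")
        do_impute = config.impute if config.impute is not None else (name == "enmix")
        if do_impute:
            beta, unimputable = impute_masked(beta)
            qc_report.unimputable_probes = unimputable
            stage("imputation")
    audit["timing"]["total"] = round(time.time() - t0, 3)
    return PipelineResult(beta=beta, qc=qc_report, audit=audit)


# ---------------------------------------------------------------------------
# evaluation over duplicate designs
# ---------------------------------------------------------------------------

def _pair_stats(
    beta: BetaMatrix, pairs: list[tuple[str, str]], leave_pair_out: bool = False
) -> pd.DataFrame:
    """Per-pair centered correlation and mean absolute difference.

    Population means for centering use all samples by default; with
    ``leave_pair_out`` the evaluated pair is excluded from its own means
    (removes the small in-sample centering bias, relevant only for small
    populations).
    """
    col = {s: k for k, s in enumerate(beta.sample_ids)}
    for a, b in pairs:
        if a not in col or b not in col:
            raise ValueError(f"pair ({a},{b}) references a missing sample")
    means = np.nanmean(beta.values, axis=1)
    rows = []
    for a, b in pairs:
        va, vb = beta.values[:, col[a]], beta.values[:, col[b]]
        if leave_pair_out and beta.values.shape[1] > 2:
            rest = [k for k in range(beta.values.shape[1]) if k not in (col[a], col[b])]
            means = np.nanmean(beta.values[:, rest], axis=1)
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "centered_correlation": centered_correlation(va, vb, means),
                "mean_abs_diff": mean_abs_diff(va, vb),
            }
        )
    return pd.DataFrame(rows)


def run_evaluation(
    beta: BetaMatrix, pairs: list[tuple[str, str]], leave_pair_out: bool = False
) -> dict:
    """Per-pair concordance statistics and per-probe ICCs for one beta matrix."""
    per_pair = _pair_stats(beta, pairs, leave_pair_out=leave_pair_out)
    col = {s: k for k, s in enumerate(beta.sample_ids)}
    cube = np.stack(
        [np.stack([beta.values[:, col[a]], beta.values[:, col[b]]], axis=1) for a, b in pairs],
        axis=1,
    )  # probes x pairs x 2
    icc = icc_oneway(cube)
    summary = {
        "n_pairs": len(pairs),
        "mean_centered_correlation": float(np.nanmean(per_pair["centered_correlation"])),
        "mean_abs_diff": float(np.nanmean(per_pair["mean_abs_diff"])),
        "median_icc": float(np.nanmedian(icc)),
        "fraction_icc_gt_0.75": float(np.nanmean(icc > 0.75)),
    }
    return {"per_pair": per_pair, "icc": icc, "summary": summary}


def run_comparison(
    betas: Mapping[str, BetaMatrix], pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Head-to-head win fractions and Wilcoxon p per pipeline pair and statistic."""
    if len(betas) < 2:
        raise ValueError("need at least two pipelines to compare")
    stats_by_pipe = {
        name: _pair_stats(beta, pairs) for name, beta in betas.items()
    }
    rows = []
    higher_better = {"centered_correlation": True, "mean_abs_diff": False}
    for (na, nb) in itertools.combinations(betas, 2):
        for stat, hb in higher_better.items():
            va = stats_by_pipe[na][stat].to_numpy()
            vb = stats_by_pipe[nb][stat].to_numpy()
            better_a = (va > vb) if hb else (va < vb)
            better_b = (vb > va) if hb else (vb < va)
            rows.append(
                {
                    "pipeline_a": na,
                    "pipeline_b": nb,
                    "statistic": stat,
                    "win_fraction_a": float(np.mean(better_a)),
                    "win_fraction_b": float(np.mean(better_b)),
                    "tie_fraction": float(np.mean(~(better_a | better_b))),
                    "wilcoxon_p": paired_wilcoxon(va, vb),
                }
            )
    return pd.DataFrame(rows)
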