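"""Synthetic two-channel BeadChip generator with known ground truth.

The generator reproduces the structure preprocessing has to contend
with: Infinium I/II chemistry with out-of-band reads, truncated-normal
optical background, a multiplicative green-channel dye gain, logit-scale
compression of type II betas (probe-type bias), negative / paired
normalization / bisulfite controls, bead counts, technical duplicates and
titrated methylation standards.

Population structure: per-probe population mean methylation is drawn from
a bimodal mixture (40% low Beta(1,15), 40% high Beta(15,1), 20%
intermediate Uniform(0.2,0.8)), matching the empirical fact that most
CpGs sit near 0% or 100% methylation; individual samples deviate from the
probe mean on the logit scale with roughly 0.05 beta-scale standard
deviation.

Artifacts vary between arrays (each sample draws its own dye gain,
background level and compression factor around the configured values);
that between-array variation is what model-based preprocessing removes
and what drives duplicate-concordance gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CT_BISULFITE, CT_NEGATIVE, CT_NORM, RawDataset
from .manifest import ProbeManifest, ProbeRecord

__all__ = [
    "SimConfig",
    "SimTruth",
    "build_manifest",
    "simulate_population",
    "simulate_intensities",
    "simulate_duplicates",
    "simulate_mixture_series",
    "MIXTURE_LEVELS",
    "MIXTURE_REPLICATES",
]

# titration design: nominal methylation levels and replicate counts
MIXTURE_LEVELS = (0.0, 0.05, 0.10, 0.20, 0.40, 0.50, 0.60, 0.80, 1.00)
MIXTURE_REPLICATES = (10, 3, 2, 3, 3, 2, 3, 3, 10)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator; defaults are the test-bed conditions."""

    n_probes: int = 10_000
    fraction_type_i: float = 0.28  # 450K-like share of Infinium I probes
    n_samples: int = 2
    n_duplicate_pairs: int = 1
    # per-probe population mean mixture
    mixture_weights: tuple[float, float, float] = (0.4, 0.4, 0.2)
    beta_noise_sd: float = 0.05  # individual deviation, beta scale
    # intensity artifacts
    dye_factor: float = 1.25  # green-channel gain
    dye_log_sd: float = 0.05  # per-array lognormal jitter of the gain
    bg_mu: float = 300.0
    bg_sd: float = 50.0
    bg_sample_log_sd: float = 0.1  # per-array lognormal jitter of bg_mu
    signal_median: float = 5000.0  # total per-probe signal, lognormal median
    signal_log_sd: float = 0.4
    kappa: float = 0.6  # type II logit compression factor
    kappa_sd: float = 0.05  # per-array jitter
    # controls and beads
    n_negctrl: int = 100
    n_normctrl: int = 30
    n_bisulfite: int = 20
    bisulfite_mean: float = 8000.0
    low_bead_fraction: float = 0.001
    rcp_close_fraction: float = 0.05  # type II probes placed < 50 bp from a type I
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction_type_i < 1:
            raise ValueError("fraction_type_i must be in (0,1)")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9 or any(
            w < 0 for w in self.mixture_weights
        ):
            raise ValueError("mixture weights must be non-negative and sum to 1")
        for name in ("dye_factor", "bg_mu", "bg_sd", "signal_median", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.kappa <= 1:
            raise ValueError("kappa must be in (0,1]")

    def artifact_free(self) -> "SimConfig":
        """Conditions with negligible artifacts (pipeline should be ~identity)."""
        return replace(
            self,
            dye_factor=1.0,
            dye_log_sd=0.0,
            bg_mu=2.0,
            bg_sd=0.5,
            bg_sample_log_sd=0.0,
            kappa=1.0,
            kappa_sd=0.0,
            low_bead_fraction=0.0,
        )


@dataclass
class SimTruth:
    true_beta: np.ndarray  # probe x sample
    probe_means: np.ndarray
    sample_ids: list[str]
    config: SimConfig
    nominal_levels: list[float] | None = None
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def build_manifest(config: SimConfig) -> ProbeManifest:
    """Synthetic manifest on one chromosome with RCP-pairable probes."""
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_probes
    is_i = rng.random(n) < config.fraction_type_i
    color = np.where(rng.random(n) < 0.5, "Red", "Grn")
    positions = 1000 * (np.arange(n, dtype=np.int64) + 1)

    # move a fraction of type II probes next to a type I neighbour (<50 bp)
    i_idx = np.flatnonzero(is_i)
    ii_idx = np.flatnonzero(~is_i)
    n_close = int(round(config.rcp_close_fraction * len(ii_idx)))
    n_close = min(n_close, len(i_idx))
    if n_close:
        chosen_ii = rng.choice(ii_idx, size=n_close, replace=False)
        chosen_i = rng.choice(i_idx, size=n_close, replace=False)
        positions[chosen_ii] = positions[chosen_i] + 30

    records = []
    addr = 1000
    for j in range(n):
        pid = f"cg{j:07d}"
        if is_i[j]:
            records.append(
                ProbeRecord(
                    probe_id=pid,
                    design_type="I",
                    color_channel=str(color[j]),
                    address_a=addr,
                    address_b=addr + 1,
                    chrom="chr1",
                    position=int(positions[j]),
                )
            )
            addr += 2
        else:
            records.append(
                ProbeRecord(
                    probe_id=pid,
                    design_type="II",
                    color_channel=None,
                    address_a=addr,
                    address_b=None,
                    chrom="chr1",
                    position=int(positions[j]),
                )
            )
            addr += 1

    ctrl_rows = []
    for _ in range(config.n_negctrl):
        ctrl_rows.append((addr, CT_NEGATIVE, "Both"))
        addr += 1
    for _ in range(config.n_normctrl):
        ctrl_rows.append((addr, CT_NORM, "Both"))
        addr += 1
    for _ in range(config.n_bisulfite):
        ctrl_rows.append((addr, CT_BISULFITE, "Both"))
        addr += 1
    controls = pd.DataFrame(ctrl_rows, columns=["address", "control_type", "expected_channel"])
    return ProbeManifest(records=records, controls=controls)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def simulate_population(config: SimConfig) -> SimTruth:
    """Draw per-probe population means and individual true betas."""
    rng = np.random.default_rng(config.seed + 2)
    n, k = config.n_probes, config.n_samples
    w = config.mixture_weights
    comp = rng.choice(3, size=n, p=list(w))
    means = np.empty(n)
    means[comp == 0] = rng.beta(1, 15, size=int((comp == 0).sum()))
    means[comp == 1] = rng.beta(15, 1, size=int((comp == 1).sum()))
    means[comp == 2] = rng.uniform(0.2, 0.8, size=int((comp == 2).sum()))

    if config.beta_noise_sd > 0:
        # logit-normal individual deviation with ~beta_noise_sd spread on the
        # beta scale (delta method; damped at the extremes)
        slope = np.maximum(means * (1 - means), config.beta_noise_sd)
        sd_logit = config.beta_noise_sd / slope
        z = _logit(means)[:, None] + sd_logit[:, None] * rng.standard_normal((n, k))
        beta = _expit(z)
    else:
        beta = np.repeat(means[:, None], k, axis=1)
    return SimTruth(
        true_beta=beta,
        probe_means=means,
        sample_ids=[f"S{i:03d}" for i in range(k)],
        config=config,
    )


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

def simulate_intensities(truth: SimTruth, manifest: ProbeManifest | None = None) -> RawDataset:
    """Generate a RawDataset from true betas with all configured artifacts."""
    config = truth.config
    if manifest is None:
        manifest = build_manifest(config)
    rng = np.random.default_rng(config.seed + 3)
    df = manifest.df
    n = len(df)
    samples = truth.sample_ids
    k = len(samples)
    if truth.true_beta.shape != (n, k):
        raise ValueError("truth does not match manifest size")

    is_ii = (df["design_type"] == "II").to_numpy()
    is_i_red = ((df["design_type"] == "I") & (df["color_channel"] == "Red")).to_numpy()
    is_i_grn = ((df["design_type"] == "I") & (df["color_channel"] == "Grn")).to_numpy()
    addr_a = df["address_a"].to_numpy(dtype=np.int64)
    addr_b_raw = df["address_b"].to_numpy()
    all_addr = manifest.probe_addresses()
    addr_pos = pd.Series(np.arange(len(all_addr)), index=all_addr)

    red = np.zeros((len(all_addr), k))
    grn = np.zeros((len(all_addr), k))

    def tn(mu, sd, size):
        """Normal truncated at zero via rejection-free resampling fallback."""
        x = rng.normal(mu, sd, size=size)
        bad = x < 0
        while bad.any():
            x[bad] = rng.normal(mu, sd, size=int(bad.sum()))
            bad = x < 0
        return x

    d_arr = np.empty(k)
    bgmu_arr = np.empty(k)
    kappa_arr = np.empty(k)
    for s in range(k):
        d = config.dye_factor * np.exp(
            rng.normal(0.0, config.dye_log_sd) if config.dye_log_sd > 0 else 0.0
        )
        bg_mu = config.bg_mu * np.exp(
            rng.normal(0.0, config.bg_sample_log_sd) if config.bg_sample_log_sd > 0 else 0.0
        )
        kap = float(np.clip(rng.normal(config.kappa, config.kappa_sd), 0.05, 1.0)) \
            if config.kappa_sd > 0 else config.kappa
        d_arr[s], bgmu_arr[s], kappa_arr[s] = d, bg_mu, kap

        b = truth.true_beta[:, s].copy()
        b[is_ii] = _expit(kap * _logit(b[is_ii]))
        total = rng.lognormal(np.log(config.signal_median), config.signal_log_sd, size=n)
        m_sig = b * total
        u_sig = (1.0 - b) * total

        bg = lambda size: tn(bg_mu, config.bg_sd, size)

        pa = addr_pos.loc[addr_a].to_numpy()
        # type II: meth read in green at address A, unmeth in red at address A
        red[pa[is_ii], s] = u_sig[is_ii] + bg(int(is_ii.sum()))
        grn[pa[is_ii], s] = d * (m_sig[is_ii] + bg(int(is_ii.sum())))
        for sel, inband in ((is_i_red, "Red"), (is_i_grn, "Grn")):
            pb = addr_pos.loc[addr_b_raw[sel].astype(np.int64)].to_numpy()
            pA = pa[sel]
            m_in = m_sig[sel] + bg(int(sel.sum()))
            u_in = u_sig[sel] + bg(int(sel.sum()))
            oob_b = bg(int(sel.sum()))
            oob_a = bg(int(sel.sum()))
            if inband == "Red":
                red[pb, s] = m_in
                red[pA, s] = u_in
                grn[pb, s] = d * oob_b
                grn[pA, s] = d * oob_a
            else:
                grn[pb, s] = d * m_in
                grn[pA, s] = d * u_in
                red[pb, s] = oob_b
                red[pA, s] = oob_a

    # controls ------------------------------------------------------------
    neg_addr = manifest.control_addresses(CT_NEGATIVE)
    norm_addr = manifest.control_addresses(CT_NORM)
    bis_addr = manifest.control_addresses(CT_BISULFITE)
    neg_r = np.empty((len(neg_addr), k))
    neg_g = np.empty((len(neg_addr), k))
    nrm_r = np.empty((len(norm_addr), k))
    nrm_g = np.empty((len(norm_addr), k))
    bis_r = np.empty((len(bis_addr), k))
    bis_g = np.empty((len(bis_addr), k))
    # normalization controls span low-to-high intensity (wide spread keeps the
    # per-sample log-log control regression well conditioned)
    norm_target = rng.lognormal(np.log(5000.0), 0.7, size=len(norm_addr))
    for s in range(k):
        d, bg_mu = d_arr[s], bgmu_arr[s]
        bg = lambda size: tn(bg_mu, config.bg_sd, size)
        neg_r[:, s] = bg(len(neg_addr))
        neg_g[:, s] = d * bg(len(neg_addr))
        # one bead population read in both channels: shared realized intensity,
        # channel-specific background and gain
        realized = norm_target * np.exp(rng.normal(0.0, 0.05, size=len(norm_addr)))
        nrm_r[:, s] = realized + bg(len(norm_addr))
        nrm_g[:, s] = d * (realized + bg(len(norm_addr)))
        bis_r[:, s] = config.bisulfite_mean * np.exp(
            rng.normal(0.0, 0.1, size=len(bis_addr))
        ) + bg(len(bis_addr))
        bis_g[:, s] = d * (
            config.bisulfite_mean * np.exp(rng.normal(0.0, 0.1, size=len(bis_addr)))
            + bg(len(bis_addr))
        )

    nbeads = 3 + rng.poisson(12.0, size=(len(all_addr), k))
    if config.low_bead_fraction > 0:
        low = rng.random((len(all_addr), k)) < config.low_bead_fraction
        nbeads[low] = rng.integers(0, 3, size=int(low.sum()))

    def frame(values, index):
        return pd.DataFrame(values, index=pd.Index(index, name="address"), columns=samples)

    return RawDataset(
        samples=list(samples),
        red=frame(red, all_addr),
        grn=frame(grn, all_addr),
        nbeads=frame(nbeads, all_addr),
        negctrl_red=frame(neg_r, neg_addr),
        negctrl_grn=frame(neg_g, neg_addr),
        normctrl_red=frame(nrm_r, norm_addr),
        normctrl_grn=frame(nrm_g, norm_addr),
        bisulfite_red=frame(bis_r, bis_addr),
        bisulfite_grn=frame(bis_g, bis_addr),
    )


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

def simulate_duplicates(config: SimConfig) -> tuple[SimTruth, RawDataset, ProbeManifest]:
    """Technical duplicates: shared true betas, independent artifacts."""
    if config.n_duplicate_pairs < 1:
        raise ValueError("need at least one duplicate pair")
    base = simulate_population(replace(config, n_samples=config.n_duplicate_pairs))
    sample_ids: list[str] = []
    pairs: list[tuple[str, str]] = []
    cols = []
    for i in range(config.n_duplicate_pairs):
        a, b = f"P{i:03d}a", f"P{i:03d}b"
        sample_ids.extend([a, b])
        pairs.append((a, b))
        cols.extend([base.true_beta[:, i], base.true_beta[:, i]])
    truth = SimTruth(
        true_beta=np.column_stack(cols),
        probe_means=base.probe_means,
        sample_ids=sample_ids,
        config=replace(config, n_samples=2 * config.n_duplicate_pairs),
        duplicate_pairs=pairs,
    )
    manifest = build_manifest(config)
    raw = simulate_intensities(truth, manifest)
    return truth, raw, manifest


def simulate_mixture_series(
    config: SimConfig,
    levels: Sequence[float] = MIXTURE_LEVELS,
    replicates: Sequence[int] = MIXTURE_REPLICATES,
) -> tuple[SimTruth, RawDataset, ProbeManifest]:
    """Isogenic titration standards: every probe at the sample's nominal level."""
    if any(not 0 <= lv <= 1 for lv in levels):
        raise ValueError("levels must be within [0,1]")
    if len(levels) != len(replicates):
        raise ValueError("one replicate count per level required")
    sample_ids = []
    nominal = []
    for lv, r in zip(levels, replicates):
        for j in range(r):
            sample_ids.append(f"L{int(round(lv * 100)):03d}r{j}")
            nominal.append(float(lv))
    beta = np.tile(np.asarray(nominal), (config.n_probes, 1))
    truth = SimTruth(
        true_beta=beta,
        probe_means=beta.mean(axis=1),
        sample_ids=sample_ids,
        config=replace(config, n_samples=len(sample_ids)),
        nominal_levels=nominal,
    )
    manifest = build_manifest(config)
    raw = simulate_intensities(truth, manifest)
    return truth, raw, manifest
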