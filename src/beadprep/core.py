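"""Core containers and chemistry-aware assembly of two-channel scans.

The flow is: per-sample red/green :class:`~beadprep.idat.ChannelScan` pairs
are assembled into a :class:`RawDataset` (address-level intensity matrices
plus control blocks), which is mapped to methylated/unmethylated signals
per probe (:class:`MethylDataset`) using the manifest chemistry, from which
beta values (:class:`BetaMatrix`) are computed.

Channel conventions (Illumina):

* type II probes: methylated signal is the green read at AddressA,
  unmethylated the red read at AddressA;
* type I probes: both signals come from the probe's declared channel,
  methylated at AddressB and unmethylated at AddressA.  The reads of the
  same two addresses in the *opposite* channel are the out-of-band (oob)
  intensities, which carry background fluorescence only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .idat import ChannelScan
from .manifest import ProbeManifest

__all__ = [
    "RawDataset",
    "MethylDataset",
    "BetaMatrix",
    "AssemblyError",
    "assemble",
    "to_methyl",
    "compute_beta",
    "oob_intensities",
]

# control_type vocabulary used by the simulator and bundle format
CT_NEGATIVE = "NEGATIVE"
CT_NORM = "NORM_PAIRED"
CT_BISULFITE = "BISULFITE"


class AssemblyError(ValueError):
    """Raised when scans and manifest cannot be combined."""


@dataclass
class RawDataset:
    """Address-level two-channel intensities plus control blocks.

    ``red``/``grn`` hold every genomic-probe address (rows) by sample
    (columns); a type I probe's out-of-band reads are simply its rows in
    the opposite channel's matrix.  Control blocks are indexed by control
    address.
    """

    samples: list[str]
    red: pd.DataFrame
    grn: pd.DataFrame
    nbeads: pd.DataFrame
    negctrl_red: pd.DataFrame
    negctrl_grn: pd.DataFrame
    normctrl_red: pd.DataFrame
    normctrl_grn: pd.DataFrame
    bisulfite_red: pd.DataFrame
    bisulfite_grn: pd.DataFrame

    def __post_init__(self) -> None:
        for name in (
            "red",
            "grn",
            "nbeads",
            "negctrl_red",
            "negctrl_grn",
            "normctrl_red",
            "normctrl_grn",
            "bisulfite_red",
            "bisulfite_grn",
        ):
            df = getattr(self, name)
            if list(df.columns) != list(self.samples):
                raise AssemblyError(f"{name} columns do not match sample ordering")
            if name != "nbeads" and (df.to_numpy() < 0).any():
                raise AssemblyError(f"{name} contains negative intensities")

    def copy(self) -> "RawDataset":
        return RawDataset(
            samples=list(self.samples),
            **{
                name: getattr(self, name).copy()
                for name in (
                    "red",
                    "grn",
                    "nbeads",
                    "negctrl_red",
                    "negctrl_grn",
                    "normctrl_red",
                    "normctrl_grn",
                    "bisulfite_red",
                    "bisulfite_grn",
                )
            },
        )

    def bisulfite_intensity(self) -> pd.Series:
        """Per-sample mean bisulfite-control intensity over both channels."""
        both = pd.concat([self.bisulfite_red, self.bisulfite_grn])
        return both.mean(axis=0)


@dataclass
class MethylDataset:
    """Per-probe methylated/unmethylated signals with an exclusion mask."""

    meth: np.ndarray  # probe x sample, float, >= 0
    unmeth: np.ndarray
    mask: np.ndarray  # bool; True = excluded data point
    probe_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if not (self.meth.shape == self.unmeth.shape == self.mask.shape):
            raise ValueError("meth/unmeth/mask shapes differ")
        if self.meth.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match probe/sample ids")

    def copy(self) -> "MethylDataset":
        return MethylDataset(
            self.meth.copy(),
            self.unmeth.copy(),
            self.mask.copy(),
            list(self.probe_ids),
            list(self.sample_ids),
        )


@dataclass
class BetaMatrix:
    """Probe x sample methylation proportions in [0,1]; NaN marks missing."""

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("beta matrix shape does not match ids")
        ok = np.isnan(v) | ((v >= 0.0) & (v <= 1.0))
        if not ok.all():
            raise ValueError("beta values outside [0,1]")

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.values.copy(), list(self.probe_ids), list(self.sample_ids))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)
        df.index.name = "probe_id"
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "BetaMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                         float_precision="round_trip")
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns])


def _group_scans(
    scans: Iterable[ChannelScan],
) -> dict[str, dict[str, ChannelScan]]:
    grouped: dict[str, dict[str, ChannelScan]] = {}
    for scan in scans:
        grouped.setdefault(scan.sample_id, {})[scan.channel] = scan
    for sample, chans in grouped.items():
        if set(chans) != {"Red", "Grn"}:
            raise AssemblyError(
                f"sample {sample} is missing a channel (has {sorted(chans)})"
            )
    return grouped


def assemble(scans: Iterable[ChannelScan], manifest: ProbeManifest) -> RawDataset:
    """Combine per-sample Red+Grn scans into a :class:`RawDataset`.

    Every address in the manifest (probe and control) must be present in
    every scan of both channels.
    """
    grouped = _group_scans(scans)
    samples = list(grouped)
    probe_addr = pd.Index(manifest.probe_addresses(), name="address")

    ctrl = manifest.controls
    neg_addr = pd.Index(manifest.control_addresses(CT_NEGATIVE), name="address")
    norm_addr = pd.Index(manifest.control_addresses(CT_NORM), name="address")
    bis_addr = pd.Index(manifest.control_addresses(CT_BISULFITE), name="address")

    def _block(index: pd.Index, channel: str, col: str) -> pd.DataFrame:
        cols = {}
        for sample in samples:
            scan = grouped[sample][channel]
            missing = index.difference(scan.data.index)
            if len(missing):
                raise AssemblyError(
                    f"sample {sample} {channel} scan lacks addresses "
                    f"{sorted(missing[:10].tolist())}"
                    + ("..." if len(missing) > 10 else "")
                )
            cols[sample] = scan.data.loc[index, col].to_numpy()
        return pd.DataFrame(cols, index=index)

    return RawDataset(
        samples=samples,
        red=_block(probe_addr, "Red", "mean"),
        grn=_block(probe_addr, "Grn", "mean"),
        nbeads=_block(probe_addr, "Grn", "nbeads").combine(
            _block(probe_addr, "Red", "nbeads"), np.minimum
        ),
        negctrl_red=_block(neg_addr, "Red", "mean"),
        negctrl_grn=_block(neg_addr, "Grn", "mean"),
        normctrl_red=_block(norm_addr, "Red", "mean"),
        normctrl_grn=_block(norm_addr, "Grn", "mean"),
        bisulfite_red=_block(bis_addr, "Red", "mean"),
        bisulfite_grn=_block(bis_addr, "Grn", "mean"),
    )


def to_methyl(raw: RawDataset, manifest: ProbeManifest) -> MethylDataset:
    """Map channel/address intensities to per-probe meth/unmeth signals."""
    df = manifest.df
    n_probes, n_samples = len(df), len(raw.samples)
    meth = np.empty((n_probes, n_samples))
    unmeth = np.empty((n_probes, n_samples))

    red = raw.red
    grn = raw.grn
    for chan, mat in (("Red", red), ("Grn", grn)):
        sel = (df["design_type"] == "I") & (df["color_channel"] == chan)
        idx = np.flatnonzero(sel.to_numpy())
        if len(idx):
            a = df.loc[sel, "address_a"].to_numpy(dtype=np.int64)
            b = df.loc[sel, "address_b"].to_numpy(dtype=np.int64)
            meth[idx] = mat.loc[b].to_numpy()
            unmeth[idx] = mat.loc[a].to_numpy()
    sel2 = df["design_type"] == "II"
    idx2 = np.flatnonzero(sel2.to_numpy())
    if len(idx2):
        a2 = df.loc[sel2, "address_a"].to_numpy(dtype=np.int64)
        meth[idx2] = grn.loc[a2].to_numpy()
        unmeth[idx2] = red.loc[a2].to_numpy()

    mask = np.zeros((n_probes, n_samples), dtype=bool)
    return MethylDataset(
        meth=meth,
        unmeth=unmeth,
        mask=mask,
        probe_ids=list(df["probe_id"]),
        sample_ids=list(raw.samples),
    )


def probe_nbeads(raw: RawDataset, manifest: ProbeManifest) -> np.ndarray:
    """Per-probe bead counts (minimum over the probe's addresses)."""
    df = manifest.df
    a = df["address_a"].to_numpy(dtype=np.int64)
    nb = raw.nbeads.loc[a].to_numpy(dtype=float)
    has_b = df["address_b"].notna().to_numpy()
    if has_b.any():
        b = df.loc[has_b, "address_b"].to_numpy(dtype=np.int64)
        nb[has_b] = np.minimum(nb[has_b], raw.nbeads.loc[b].to_numpy(dtype=float))
    return nb.astype(np.int64)


def compute_beta(methyl: MethylDataset, offset: float = 100.0) -> BetaMatrix:
    """Beta = meth / (meth + unmeth + offset); masked or 0/0 points are NaN."""
    if offset < 0:
        raise ValueError("offset must be non-negative")
    denom = methyl.meth + methyl.unmeth + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, methyl.meth / np.where(denom > 0, denom, 1.0), np.nan)
    beta = np.clip(beta, 0.0, 1.0)
    beta[methyl.mask] = np.nan
    return BetaMatrix(beta, list(methyl.probe_ids), list(methyl.sample_ids))


def oob_intensities(raw: RawDataset, manifest: ProbeManifest, channel: str) -> pd.DataFrame:
    """Out-of-band reads observed in ``channel`` (background-only by design)."""
    addr = manifest.oob_addresses(channel)
    mat = raw.red if channel == "Red" else raw.grn
    return mat.loc[addr]
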